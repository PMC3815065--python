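name	derived_sites
C1
C2	c5
C3	c1,c5
C4	c4
C5	c3,c4,c7,c16
C6	c3,c4,c7,c8,c16
C7	c3,c4,c7,c8,c13,c16
C8	c3,c4,c6,c7,c8,c9,c14,c15,c16
C9	c3,c4,c6,c7,c8,c9,c10,c14,c15,c16
C10	c2,c3,c4,c6,c7,c8,c9,c10,c12,c14,c15,c16
C11	c1,c2,c3,c4,c6,c7,c8,c9,c10,c11,c12,c14,c15,c16
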