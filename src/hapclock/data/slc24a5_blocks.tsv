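# b37/hg19 coordinates (1-based inclusive) of the four LD blocks around SLC24A5
name	start	end
A	48321236	48370103
B	48370104	48390052
C	48390053	48468019
D	48468020	48517471
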