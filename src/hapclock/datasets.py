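"""Shipped reference inputs for the SLC24A5 region analysis.

These fixtures hold the published inputs the pipeline consumes: the b37
block coordinates, the 16 core-region SNPs and the 11 common haplotypes
defined over them, the per-population haplotype counts, and the dating
summary (chromosome counts, difference totals and effective sample sizes
per population).  Calibration constants for the human-chimpanzee clock are
exposed as module constants.

Note the core-SNP *positions* are synthetic placeholders (evenly spaced in
block C); rs IDs, allele states and everything else are authoritative.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .blocks import BlockPartition
from .classify import HaplotypeDefinitionTable
from .hapio import read_haplotype_definitions, read_site_annotation
from .types import SiteAnnotation

#: Human-chimpanzee alignment summary over the C+D region.
CHIMP_DIFF_COUNT = 1227
CHIMP_ALIGNED_LENGTH = 125_531

#: Length of the C+D dating region in nt (full region, not aligned length).
CD_REGION_LENGTH = 127_419

#: Multiplicative correction for variants undetected at ~5x coverage,
#: obtained by inverting the detection-power curve over the C11+D4
#: variant-frequency spectrum.
UNDERCOUNT_FACTOR = 1.58

#: Substitution-class homogeneity between the C11+D4 variants and the
#: human-chimpanzee alignment (chi-square statistic and degrees of freedom).
HOMOGENEITY_CHI2 = 4.42
HOMOGENEITY_DF = 5

#: Nicknames of the 16 core SNPs, in genomic order.
CORE_SITE_LABELS = tuple(f"c{i}" for i in range(1, 17))

#: The classifying functional site (rs1426654, the A111T coding SNP).
KEY_SITE = "c11"


def _data_path(name: str):
    return resources.files("hapclock.data") / name


def load_block_partition() -> BlockPartition:
    """The four published LD blocks (A-D) in b37 coordinates."""
    df = pd.read_csv(_data_path("slc24a5_blocks.tsv"), sep="\t", comment="#")
    return BlockPartition(
        blocks=[(r.name, int(r.start), int(r.end)) for r in df.itertuples(index=False)]
    )


def load_core_sites() -> list[SiteAnnotation]:
    """The 16 core-region SNPs (synthetic positions, see module docstring)."""
    with resources.as_file(_data_path("core_sites.tsv")) as path:
        return read_site_annotation(path)


def load_core_definitions() -> HaplotypeDefinitionTable:
    """The 11 common core haplotypes (C1-C11) over the 16 SNPs."""
    with resources.as_file(_data_path("core_haplotypes.tsv")) as path:
        return read_haplotype_definitions(
            path, site_universe=CORE_SITE_LABELS, key_site=KEY_SITE
        )


def load_hapmap_counts() -> pd.DataFrame:
    """Published per-population counts of the common core haplotypes.

    Ambiguity classes that could not be resolved in particular samples are
    kept as their own rows (``C2/C3``, ``C6/C7``).
    """
    df = pd.read_csv(_data_path("hapmap_counts.tsv"), sep="\t", index_col=0)
    df.index.name = "haplotype"
    return df


def load_dating_inputs() -> pd.DataFrame:
    """Published dating inputs per population sample (see file header)."""
    return pd.read_csv(_data_path("dating_inputs.tsv"), sep="\t", comment="#")
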