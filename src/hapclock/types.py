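"""Core domain types shared across the pipeline.

Conventions
-----------
* Genomic coordinates are 1-based and inclusive throughout.
* Alleles in a :class:`PhasedPanel` are coded against the ancestral state:
  ``0`` = ancestral, ``1`` = derived, :data:`MISSING` (``-1``) = no call.
  MISSING is an explicit third state and is never silently imputed;
  operations that consume panels document their MISSING policy.
* Sites are strictly biallelic.  An ancestral state may be recorded as
  unknown (:data:`UNKNOWN_ALLELE`), in which case the coding of the two
  observed alleles is arbitrary but fixed, and rooting logic ignores the
  site.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

#: Allele code for a missing call (explicit third state, never imputed).
MISSING: int = -1

#: Marker for an unknown ancestral state (e.g. a recurrent indel whose
#: pre-human state cannot be inferred from outgroups).
UNKNOWN_ALLELE: str = "?"


class HapclockError(ValueError):
    """Base class for domain errors raised by this package."""


@dataclass(frozen=True)
class SiteAnnotation:
    """A single biallelic polymorphic site.

    Parameters
    ----------
    site_id:
        Unique identifier (an rs ID for real data, synthetic otherwise).
    position:
        1-based genomic coordinate in nucleotides.
    ancestral_allele:
        The allele inferred to predate the human lineage, or
        :data:`UNKNOWN_ALLELE` when outgroup comparison is inconclusive.
    derived_allele:
        The mutated allele.
    nickname:
        Optional short label used in haplotype definitions (e.g. ``c11``).
    kind:
        ``"SNP"`` or ``"indel"``.
    """

    site_id: str
    position: int
    ancestral_allele: str
    derived_allele: str
    nickname: str | None = None
    kind: str = "SNP"

    def __post_init__(self) -> None:
        if self.position < 1:
            raise HapclockError(f"site {self.site_id}: position must be >= 1")
        if self.ancestral_allele == self.derived_allele:
            raise HapclockError(
                f"site {self.site_id}: ancestral and derived alleles are identical"
            )
        if self.kind not in ("SNP", "indel"):
            raise HapclockError(f"site {self.site_id}: kind must be SNP or indel")

    @property
    def ancestral_known(self) -> bool:
        return self.ancestral_allele != UNKNOWN_ALLELE

    @property
    def label(self) -> str:
        """Nickname if present, else the site id."""
        return self.nickname if self.nickname else self.site_id


@dataclass
class PhasedPanel:
    """A matrix of phased chromosomes over annotated biallelic sites.

    ``alleles`` has shape ``(n_chromosomes, n_sites)`` with entries
    0 (ancestral), 1 (derived) or MISSING.  Each chromosome is identified
    by a ``(sample_id, haplotype_index)`` pair and carries a population
    label.
    """

    sites: list[SiteAnnotation]
    chrom_ids: list[tuple[str, int]]
    populations: list[str]
    alleles: np.ndarray

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        n_chrom, n_sites = len(self.chrom_ids), len(self.sites)
        if self.alleles.shape != (n_chrom, n_sites):
            raise HapclockError(
                f"allele matrix shape {self.alleles.shape} does not match "
                f"{n_chrom} chromosomes x {n_sites} sites"
            )
        if len(self.populations) != n_chrom:
            raise HapclockError("one population label required per chromosome")
        if len(set(self.chrom_ids)) != n_chrom:
            raise HapclockError("(sample_id, haplotype_index) pairs must be unique")
        ids = [s.site_id for s in self.sites]
        if len(set(ids)) != n_sites:
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise HapclockError(f"duplicate site ids: {dupes}")
        pos = [s.position for s in self.sites]
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise HapclockError("site positions must be strictly increasing")
        bad = ~np.isin(self.alleles, (0, 1, MISSING))
        if bad.any():
            raise HapclockError("allele codes must be 0, 1 or MISSING")

    @property
    def n_chrom(self) -> int:
        return len(self.chrom_ids)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def site_index(self) -> dict[str, int]:
        """Map site label (nickname preferred) -> column index."""
        return {s.label: j for j, s in enumerate(self.sites)}

    def chrom_name(self, i: int) -> str:
        sample, hap = self.chrom_ids[i]
        return f"{sample}:{hap}"

    def subset_sites(self, indices: Sequence[int]) -> "PhasedPanel":
        indices = list(indices)
        return PhasedPanel(
            sites=[self.sites[j] for j in indices],
            chrom_ids=list(self.chrom_ids),
            populations=list(self.populations),
            alleles=self.alleles[:, indices],
        )

    def subset_chromosomes(self, indices: Sequence[int]) -> "PhasedPanel":
        indices = list(indices)
        return PhasedPanel(
            sites=list(self.sites),
            chrom_ids=[self.chrom_ids[i] for i in indices],
            populations=[self.populations[i] for i in indices],
            alleles=self.alleles[indices, :],
        )


@dataclass
class RecombinationMap:
    """Piecewise-constant recombination rates, cM/Mb, 1-based inclusive."""

    intervals: list[tuple[int, int, float]]

    def __post_init__(self) -> None:
        prev_end = 0
        for start, end, rate in self.intervals:
            if end < start:
                raise HapclockError(f"interval ({start}, {end}) has end < start")
            if start <= prev_end:
                raise HapclockError("map intervals must be sorted and non-overlapping")
            if rate < 0:
                raise HapclockError("recombination rates must be >= 0")
            prev_end = end

    def covers(self, start: int, end: int) -> bool:
        """True if [start, end] is contained in the union of intervals with no gaps."""
        pos = start
        for s, e, _ in self.intervals:
            if e < pos:
                continue
            if s > pos:
                return False
            pos = e + 1
            if pos > end:
                return True
        return pos > end


@dataclass
class PairwiseAlignment:
    """Two gapped nucleotide sequences of equal length; gap character '-'."""

    seq_a: str
    seq_b: str

    def __post_init__(self) -> None:
        if len(self.seq_a) != len(self.seq_b):
            raise HapclockError(
                f"aligned sequences differ in length "
                f"({len(self.seq_a)} vs {len(self.seq_b)})"
            )
        self.seq_a = self.seq_a.upper()
        self.seq_b = self.seq_b.upper()
        for i, (a, b) in enumerate(zip(self.seq_a, self.seq_b)):
            if a == "-" and b == "-":
                raise HapclockError(f"column {i + 1} is gapped in both sequences")

    def __len__(self) -> int:
        return len(self.seq_a)


def hap_string(vector: Iterable[int]) -> str:
    """Render an allele vector as a compact 0/1/. string ('.' = MISSING)."""
    return "".join("." if a == MISSING else str(int(a)) for a in vector)
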