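"""Assign phased chromosomes to named haplotypes and tabulate by population.

A haplotype definition names the subset of sites at which the haplotype
carries the derived allele (all other sites in the definition universe are
ancestral).  A chromosome that matches exactly one definition at every
non-missing site receives that name; missing data can leave several
definitions compatible, in which case the chromosome is assigned the whole
ambiguity set (reported as e.g. ``C6/C7``).  Chromosomes matching no
definition fall into residual classes split by the key functional site:
``other-d`` (derived at the key site) and ``other-a`` (ancestral).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import MISSING, HapclockError, PhasedPanel

#: Residual class labels for chromosomes matching no named definition.
OTHER_DERIVED = "other-d"
OTHER_ANCESTRAL = "other-a"

#: Separator used to render an ambiguity set as a single label.
AMBIGUITY_SEP = "/"


@dataclass
class HaplotypeDefinitionTable:
    """Named haplotypes as sets of derived-allele site nicknames.

    Parameters
    ----------
    entries:
        Mapping of haplotype name to the set of site labels carrying the
        derived allele.  The all-ancestral haplotype has an empty set.
    site_universe:
        Ordered labels of the sites over which the definitions are read.
    key_site:
        Label of the classifying functional site used to split residual
        chromosomes into derived/ancestral classes.
    common_freq_threshold:
        Pooled-sample frequency below which a haplotype is considered
        rare (used by reporting, not by assignment).
    """

    entries: dict[str, frozenset[str]]
    site_universe: tuple[str, ...]
    key_site: str = "c11"
    common_freq_threshold: float = 0.005

    def __post_init__(self) -> None:
        universe = set(self.site_universe)
        if self.key_site not in universe:
            raise HapclockError(f"key site {self.key_site!r} not in site universe")
        seen: dict[frozenset[str], str] = {}
        for name, derived in self.entries.items():
            derived = frozenset(derived)
            self.entries[name] = derived
            unknown = derived - universe
            if unknown:
                raise HapclockError(
                    f"haplotype {name}: unknown site nicknames {sorted(unknown)}"
                )
            if derived in seen:
                raise HapclockError(
                    f"haplotypes {seen[derived]} and {name} have identical derived sets"
                )
            seen[derived] = name

    def names(self) -> list[str]:
        return list(self.entries)

    def pattern(self, name: str) -> np.ndarray:
        """0/1 vector over the site universe for a named haplotype."""
        derived = self.entries[name]
        return np.array(
            [1 if lab in derived else 0 for lab in self.site_universe], dtype=np.int8
        )

    def matrix(self) -> np.ndarray:
        """Stacked patterns, one row per definition in entry order."""
        return np.vstack([self.pattern(n) for n in self.entries])


@dataclass
class AssignmentResult:
    """Per-chromosome haplotype labels plus per-population counts."""

    assignments: pd.DataFrame  # columns: sample, hap_index, population, label
    counts: pd.DataFrame  # rows: labels, columns: populations
    key_site: str

    def label_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)


def _ambiguity_label(names: list[str]) -> str:
    return AMBIGUITY_SEP.join(names)


def assign_haplotypes(
    panel: PhasedPanel, defs: HaplotypeDefinitionTable
) -> AssignmentResult:
    """Label every chromosome with a haplotype name, ambiguity set or residual class.

    The panel must contain every site in the definition universe (matched
    by nickname/label); missing calls are tolerated and produce ambiguity
    sets when they leave more than one definition compatible.  Named
    definitions take precedence over the residual classes: a chromosome
    compatible with at least one definition is never assigned ``other-*``.
    Every chromosome receives exactly one label, so label counts always
    sum to the number of chromosomes.
    """
    index = panel.site_index()
    missing_cols = [lab for lab in defs.site_universe if lab not in index]
    if missing_cols:
        raise HapclockError(
            f"panel lacks definition sites {missing_cols}; cannot classify"
        )
    cols = [index[lab] for lab in defs.site_universe]
    sub = panel.alleles[:, cols]
    key_col = list(defs.site_universe).index(defs.key_site)

    patterns = defs.matrix()  # (n_defs, n_universe)
    names = defs.names()

    labels: list[str] = []
    for i in range(panel.n_chrom):
        vec = sub[i]
        observed = vec != MISSING
        compatible = [
            names[k]
            for k in range(len(names))
            if np.array_equal(patterns[k][observed], vec[observed])
        ]
        if len(compatible) == 1:
            labels.append(compatible[0])
        elif compatible:
            labels.append(_ambiguity_label(compatible))
        else:
            key = vec[key_col]
            if key == MISSING:
                labels.append(_ambiguity_label([OTHER_DERIVED, OTHER_ANCESTRAL]))
            elif key == 1:
                labels.append(OTHER_DERIVED)
            else:
                labels.append(OTHER_ANCESTRAL)

    assignments = pd.DataFrame(
        {
            "sample": [s for s, _ in panel.chrom_ids],
            "hap_index": [h for _, h in panel.chrom_ids],
            "population": panel.populations,
            "label": labels,
        }
    )
    counts = tabulate_counts_frame(assignments)
    return AssignmentResult(assignments=assignments, counts=counts, key_site=defs.key_site)


def _label_sort_key(label: str) -> tuple[int, str]:
    # named classes first (input order is lost; sort lexically with numeric
    # awareness so C2 < C10), ambiguity sets next, residual classes last
    if label in (OTHER_DERIVED, OTHER_ANCESTRAL):
        return (2, label)
    if AMBIGUITY_SEP in label:
        return (1, _natural(label))
    return (0, _natural(label))


def _natural(label: str) -> str:
    out = []
    num = ""
    for ch in label:
        if ch.isdigit():
            num += ch
        else:
            if num:
                out.append(num.zfill(6))
                num = ""
            out.append(ch)
    if num:
        out.append(num.zfill(6))
    return "".join(out)


def tabulate_counts_frame(assignments: pd.DataFrame) -> pd.DataFrame:
    table = (
        assignments.groupby(["label", "population"], sort=False)
        .size()
        .unstack(fill_value=0)
    )
    table = table.reindex(sorted(table.index, key=_label_sort_key))
    table = table[sorted(table.columns)]
    table.columns.name = None
    table.index.name = "haplotype"
    return table


def tabulate_counts(
    assignment: AssignmentResult,
    merge: dict[str, list[str]] | None = None,
) -> pd.DataFrame:
    """Counts per label and population, optionally merging population columns.

    ``merge`` maps a new column name to the populations it pools, e.g.
    ``{"EAS": ["CHB", "CHD", "JPT"]}``.  Unmentioned populations keep their
    own columns.  Zero cells are retained.
    """
    counts = assignment.counts.copy()
    if merge is None:
        return counts
    merged = {}
    consumed: set[str] = set()
    for new, pops in merge.items():
        unknown = [p for p in pops if p not in counts.columns]
        if unknown:
            raise HapclockError(f"merge group {new!r}: unknown populations {unknown}")
        merged[new] = counts[pops].sum(axis=1)
        consumed.update(pops)
    for pop in counts.columns:
        if pop not in consumed:
            merged[pop] = counts[pop]
    out = pd.DataFrame(merged)
    out.index.name = "haplotype"
    return out


def derived_allele_share(
    counts: pd.DataFrame, haplotype: str, defs: HaplotypeDefinitionTable
) -> float:
    """Percentage of key-site derived chromosomes carried by one haplotype.

    Computed as ``100 * n(haplotype) / (n(haplotype) + n(other-d))``: the
    named haplotype must itself carry the derived allele at the key site,
    and ``other-d`` collects every other derived-carrying chromosome.
    """
    if haplotype not in defs.entries:
        raise HapclockError(f"unknown haplotype {haplotype!r}")
    if defs.key_site not in defs.entries[haplotype]:
        raise HapclockError(
            f"haplotype {haplotype} is not derived at key site {defs.key_site}"
        )
    if haplotype not in counts.index:
        raise HapclockError(f"counts table has no row {haplotype!r}")
    focal = float(counts.loc[haplotype].sum())
    other = float(counts.loc[OTHER_DERIVED].sum()) if OTHER_DERIVED in counts.index else 0.0
    return 100.0 * focal / (focal + other)
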