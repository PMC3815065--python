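"""Single-crossover explanations of haplotypes and breakpoint localization.

A child haplotype is "explained" by an ordered parent pair when one
crossover — left parent contributing everything up to some point, right
parent everything after — reproduces the child with zero mismatches.
Any residual mismatch is treated as a separate mutation event and handled
upstream (as with the A111T mutation arising on an already-recombinant
background), so no mismatch tolerance is offered here.

The crossover can only be localized between the two *informative* sites
(sites where the parents differ) flanking the switch; that pair of
positions is the breakpoint interval.  Only single crossovers are modeled.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .types import HapclockError, SiteAnnotation


@dataclass(frozen=True)
class CrossoverHypothesis:
    """A single-crossover explanation of ``child`` from an ordered parent pair.

    ``breakpoint_interval`` holds the positions of the two informative
    sites flanking the crossover; ``informative_support`` counts the
    informative sites uniquely matching the left and right parent on their
    respective sides.  ``trivial`` marks a pure-parent match (no crossover
    needed), reported with a degenerate interval at the region edge.
    """

    child: str
    parent_left: str
    parent_right: str
    breakpoint_interval: tuple[int, int]
    informative_support: tuple[int, int]
    trivial: bool = False

    @property
    def interval_width(self) -> int:
        return self.breakpoint_interval[1] - self.breakpoint_interval[0]

    @property
    def min_support(self) -> int:
        return min(self.informative_support)


def _check_strings(sites: Sequence[SiteAnnotation], *haps: str) -> None:
    n = len(sites)
    for h in haps:
        if len(h) != n:
            raise HapclockError(
                f"haplotype length {len(h)} does not match {n} annotated sites"
            )
        if any(c not in "01" for c in h):
            raise HapclockError("haplotype strings must be 0/1 with no MISSING")


def _single_order(
    child: str, left: str, right: str, sites: Sequence[SiteAnnotation]
) -> CrossoverHypothesis | None:
    """Best hypothesis with ``left`` on the left and ``right`` on the right."""
    # shared sites must match the child outright
    for c, a, b in zip(child, left, right):
        if a == b and c != a:
            return None
    inf = [i for i, (a, b) in enumerate(zip(left, right)) if a != b]
    matches_left = [child[i] == left[i] for i in inf]
    # need a prefix of True followed by all False
    k = 0
    while k < len(matches_left) and matches_left[k]:
        k += 1
    if any(matches_left[k:]):
        return None
    positions = [sites[i].position for i in inf]
    if k == len(inf):  # pure left parent (or parents identical)
        edge = sites[-1].position
        return CrossoverHypothesis(
            child=child,
            parent_left=left,
            parent_right=right,
            breakpoint_interval=(edge, edge),
            informative_support=(len(inf), 0),
            trivial=True,
        )
    if k == 0:  # pure right parent: defer to the mirrored order
        return None
    return CrossoverHypothesis(
        child=child,
        parent_left=left,
        parent_right=right,
        breakpoint_interval=(positions[k - 1], positions[k]),
        informative_support=(k, len(inf) - k),
    )


def explain_by_crossover(
    child: str,
    parent_a: str,
    parent_b: str,
    sites: Sequence[SiteAnnotation],
) -> CrossoverHypothesis | None:
    """Explain ``child`` as one crossover between the parents, if possible.

    Both parent orders are tried; the hypothesis with the narrowest
    breakpoint interval wins (ties go to ``parent_a`` on the left).
    Returns None when no zero-mismatch single crossover exists.
    """
    _check_strings(sites, child, parent_a, parent_b)
    candidates = [
        h
        for h in (
            _single_order(child, parent_a, parent_b, sites),
            _single_order(child, parent_b, parent_a, sites),
        )
        if h is not None
    ]
    if not candidates:
        return None
    return min(candidates, key=lambda h: (h.trivial, h.interval_width))


def scan_parent_pairs(
    child: str,
    candidates: Iterable[str],
    sites: Sequence[SiteAnnotation],
) -> list[CrossoverHypothesis]:
    """All single-crossover explanations of ``child`` from candidate parents.

    Every ordered pair of distinct candidates is tested; hypotheses are
    ranked by ``min(informative_support)`` descending, then by interval
    width ascending, so trivial pure-parent matches sort last.
    """
    candidates = list(dict.fromkeys(candidates))
    if len(candidates) < 2:
        raise HapclockError("need at least two candidate parents")
    _check_strings(sites, child, *candidates)
    out = []
    for i, a in enumerate(candidates):
        for b in candidates[i + 1 :]:
            h = explain_by_crossover(child, a, b, sites)
            if h is not None:
                out.append(h)
    out.sort(key=lambda h: (-h.min_support, h.interval_width, h.parent_left, h.parent_right))
    return out


def reciprocal_product(
    hypothesis: CrossoverHypothesis, sites: Sequence[SiteAnnotation]
) -> str:
    """The complementary crossover product (right parent's left segment joined
    to left parent's right segment at the same breakpoint interval).

    At sites inside the breakpoint interval the parents agree (the interval
    is delimited by informative sites), so the reciprocal is well defined.
    """
    left, right = hypothesis.parent_left, hypothesis.parent_right
    lo, hi = hypothesis.breakpoint_interval
    out = []
    for site, a, b in zip(sites, left, right):
        if site.position <= lo:
            out.append(b)
        elif site.position >= hi:
            out.append(a)
        else:  # inside the interval: parents agree here
            out.append(a)
    return "".join(out)


def crossover_report(
    hypotheses: Sequence[CrossoverHypothesis], sites: Sequence[SiteAnnotation]
):
    """Tabulate hypotheses: child, parents, flanking site ids, interval width."""
    import pandas as pd

    by_pos = {s.position: s for s in sites}
    rows = []
    for h in hypotheses:
        lo, hi = h.breakpoint_interval
        rows.append(
            {
                "child": h.child,
                "parent_left": h.parent_left,
                "parent_right": h.parent_right,
                "flank_left": by_pos[lo].site_id,
                "flank_right": by_pos[hi].site_id,
                "interval_nt": h.interval_width,
                "support_left": h.informative_support[0],
                "support_right": h.informative_support[1],
                "trivial": h.trivial,
            }
        )
    return pd.DataFrame(rows)
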