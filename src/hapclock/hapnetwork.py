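"""Rooted nearest-neighbor haplotype networks with recurrent-site detection.

A panel is collapsed into haplotype classes (identical allele strings over
the retained sites).  Classes are linked by a deterministic greedy
procedure: starting from singleton components, the two components whose
closest node pair has minimal Hamming distance are joined repeatedly until
the graph is connected.  On tree-like data this reproduces a minimum
spanning tree of the true genealogy.  Each edge is labeled with the set of
sites that differ between its endpoints, so under infinite sites every
mutated site appears on exactly one edge; a site appearing on two or more
edges is the signature of recombination (or recurrent mutation) and is
reported by :func:`find_recurrent_sites`.

The network is rooted at the all-ancestral haplotype when it is observed,
else at the observed haplotype closest to the all-ancestral string.  Sites
whose ancestral state is unknown are ignored when measuring distance to
the ancestral string but keep their place in edge labels.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .types import MISSING, HapclockError, PhasedPanel, SiteAnnotation

logger = logging.getLogger(__name__)


@dataclass
class HaplotypeNetwork:
    """Rooted graph of haplotype classes with mutation-labeled edges.

    Nodes are allele strings over ``retained_sites``; node attributes carry
    ``count`` (occurrences), ``populations`` (a Counter), ``name`` (optional
    display label) and ``displayed`` (False for classes below the display
    frequency).  Edge attribute ``sites`` is the frozenset of differing
    site labels.
    """

    graph: nx.Graph
    root: str
    retained_sites: list[SiteAnnotation]
    dropped_chromosomes: int = 0

    @property
    def site_labels(self) -> list[str]:
        return [s.label for s in self.retained_sites]

    def node_for(self, haplotype: str) -> dict:
        return self.graph.nodes[haplotype]

    def adjacent(self, a: str, b: str) -> bool:
        return self.graph.has_edge(a, b)

    def edge_sites(self, a: str, b: str) -> frozenset[str]:
        return self.graph.edges[a, b]["sites"]


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _diff_sites(a: str, b: str, labels: list[str]) -> frozenset[str]:
    return frozenset(lab for x, y, lab in zip(a, b, labels) if x != y)


def retained_site_indices(panel: PhasedPanel, min_variant_freq: float) -> list[int]:
    """Columns whose pooled minor-allele frequency (among calls) passes the filter."""
    keep = []
    for j in range(panel.n_sites):
        col = panel.alleles[:, j]
        obs = col != MISSING
        n = int(obs.sum())
        if n == 0:
            continue
        f = float((col[obs] == 1).sum()) / n
        if min(f, 1.0 - f) >= min_variant_freq:
            keep.append(j)
    return keep


def build_network(
    panel: PhasedPanel,
    min_variant_freq: float = 0.01,
    min_hap_freq: float = 0.005,
    names: dict[str, str] | None = None,
) -> HaplotypeNetwork:
    """Collapse a panel into haplotype classes and link them into a network.

    Sites with pooled minor-allele frequency below ``min_variant_freq`` are
    removed; chromosomes with MISSING calls at any retained site are dropped
    (their number is logged and recorded on the result).  Classes below
    ``min_hap_freq`` stay in the graph but are flagged ``displayed=False``.
    ``names`` optionally maps allele strings to display labels.

    Components are joined greedily at minimal Hamming distance; ties are
    broken by the lexicographically smallest (sorted) pair of allele
    strings, then by total count of the pair descending.  The result is
    deterministic and invariant to chromosome order.
    """
    if panel.n_chrom == 0:
        raise HapclockError("empty panel")
    keep = retained_site_indices(panel, min_variant_freq)
    # an empty retained set is legal: the panel collapses to one class
    sub = panel.subset_sites(keep)

    complete = ~(sub.alleles == MISSING).any(axis=1)
    dropped = int((~complete).sum())
    if dropped:
        logger.info("dropped %d chromosomes with MISSING at retained sites", dropped)
    if not complete.any():
        raise HapclockError("no complete chromosomes after filtering")
    alleles = sub.alleles[complete]
    pops = [p for p, ok in zip(sub.populations, complete) if ok]

    strings = ["".join(str(int(a)) for a in row) for row in alleles]
    counts = Counter(strings)
    pop_comp: dict[str, Counter] = {}
    for s, p in zip(strings, pops):
        pop_comp.setdefault(s, Counter())[p] += 1

    total = sum(counts.values())
    labels = [s.label for s in sub.sites]

    graph = nx.Graph()
    for s in sorted(counts):
        graph.add_node(
            s,
            count=counts[s],
            populations=pop_comp[s],
            displayed=counts[s] / total >= min_hap_freq,
            name=(names or {}).get(s),
        )

    nodes = sorted(counts)
    comp = {s: i for i, s in enumerate(nodes)}
    pair_dist = {
        (a, b): _hamming(a, b) for i, a in enumerate(nodes) for b in nodes[i + 1 :]
    }
    while len(set(comp.values())) > 1:
        best = None
        for (a, b), d in pair_dist.items():
            if comp[a] == comp[b]:
                continue
            key = (d, (a, b), -(counts[a] + counts[b]))
            if best is None or key < best:
                best = key
        d, (a, b), _ = best
        graph.add_edge(a, b, sites=_diff_sites(a, b, labels), distance=d)
        old, new = comp[b], comp[a]
        for s in comp:
            if comp[s] == old:
                comp[s] = new

    anc_known = [s.ancestral_known for s in sub.sites]
    all_anc = "0" * len(labels)

    def root_dist(s: str) -> int:
        return sum(
            x != y for x, y, k in zip(s, all_anc, anc_known) if k
        )

    root = min(nodes, key=lambda s: (root_dist(s), s))
    return HaplotypeNetwork(
        graph=graph, root=root, retained_sites=list(sub.sites), dropped_chromosomes=dropped
    )


def find_recurrent_sites(network: HaplotypeNetwork) -> dict[str, list[tuple[str, str]]]:
    """Sites mutating on more than one edge, with the edges they appear on.

    Under infinite sites on a recombination-free genealogy every site
    appears on exactly one edge, so a non-empty result flags recombination
    (or genuinely recurrent mutation) involving those sites.
    """
    where: dict[str, list[tuple[str, str]]] = {}
    for a, b in sorted(network.graph.edges):
        for site in network.graph.edges[a, b]["sites"]:
            where.setdefault(site, []).append((a, b))
    return {site: edges for site, edges in sorted(where.items()) if len(edges) >= 2}


def shared_derived_counts(
    network: HaplotypeNetwork, split: set[str] | list[str]
) -> int:
    """Number of retained sites whose derived allele is carried by every
    haplotype in ``split`` and by none outside it.

    This is the support count for a candidate early-branching partition;
    the choice between alternative topologies is left to the user.
    """
    nodes = list(network.graph.nodes)
    inside = set(split)
    unknown = inside - set(nodes)
    if unknown:
        raise HapclockError(f"split names unknown haplotypes: {sorted(unknown)}")
    support = 0
    for j, _site in enumerate(network.retained_sites):
        carriers = {s for s in nodes if s[j] == "1"}
        if carriers == inside:
            support += 1
    return support
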