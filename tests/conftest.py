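import numpy as np
import pytest

from hapclock import datasets
from hapclock.simdata import SimConfig, simulate_classified_panel
from hapclock.types import PhasedPanel, SiteAnnotation


@pytest.fixture(scope="session")
def core_sites():
    return datasets.load_core_sites()


@pytest.fixture(scope="session")
def core_defs():
    return datasets.load_core_definitions()


@pytest.fixture(scope="session")
def common_hap_panel(core_defs, core_sites):
    """Equal-count panel of the 11 common core haplotypes."""
    table = {name: {"POP": 10} for name in core_defs.names()}
    return simulate_classified_panel(
        SimConfig(
            model="classified",
            frequency_table=table,
            definitions=core_defs,
            sites=core_sites,
        )
    )


@pytest.fixture()
def pattern_string(core_defs):
    """Render a named haplotype definition as a 0/1 string."""

    def _render(name):
        return "".join(str(int(x)) for x in core_defs.pattern(name))

    return _render


def make_panel(rows, positions=None, populations=None, ancestral="A", derived="G"):
    """Small helper to build a panel from 0/1/MISSING row vectors."""
    rows = np.asarray(rows, dtype=np.int8)
    n, m = rows.shape
    positions = positions or list(range(1, m + 1))
    sites = [
        SiteAnnotation(
            site_id=f"s{p}", position=p, ancestral_allele=ancestral, derived_allele=derived
        )
        for p in positions
    ]
    return PhasedPanel(
        sites=sites,
        chrom_ids=[(f"ind{i // 2}", i % 2) for i in range(n)],
        populations=populations or ["POP"] * n,
        alleles=rows,
    )
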