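"""Session-scoped synthetic fixtures shared by the test modules."""

from __future__ import annotations

import pytest

from screditome.editcall import site_depths
from screditome.synthetic import SimConfig, simulate

from helpers import call_sim

# Three populations from distinct lineage branches: fast enough for
# per-test use, still exercises strand split and lineage bookkeeping.
SMALL_TYPES = ("HSC", "MLP", "MEP")


def small_config(**overrides) -> SimConfig:
    base = dict(
        cell_types=SMALL_TYPES,
        cells_per_type=15,
        n_genes=6,
        n_editing_sites=25,
        n_snps=8,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def small_sim():
    """Default study conditions at reduced population count (seed 7)."""
    return simulate(small_config(), seed=7)


@pytest.fixture(scope="session")
def clean_sim():
    """Noiseless fixture: no sequencing error, high editing levels, 60x.

    All 8 populations, so lineage-group patterns are well defined; used
    for the exactness checks (element labels, patterns, edited cells,
    depth filter)."""
    cfg = SimConfig(error_rate=0.0, phi_levels=(0.5, 0.8, 1.0), mean_depth=60)
    return simulate(cfg, seed=11)


@pytest.fixture(scope="session")
def clean_called(clean_sim):
    """(by_type, sites_by_type) for the noiseless fixture."""
    return call_sim(clean_sim)


@pytest.fixture(scope="session")
def clean_depths(clean_sim, clean_called):
    """Measured filtered depth at every planted site per cell type."""
    by_type, _ = clean_called
    positions = [(r.chrom, int(r.pos0)) for r in clean_sim.truth.sites.itertuples()]
    return {ct: site_depths(by_type[ct], positions) for ct in clean_sim.config.cell_types}
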