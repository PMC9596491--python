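import numpy as np
import pandas as pd
import pytest

from sexscan import GenomeLayout, Region, SexMap, SimConfig, SnpTable, simulate_population


def make_table(genotypes, depths=None, scaffold="s1", positions=None, samples=None):
    """Hand-build a SnpTable from a (sites x samples) genotype list."""
    g = np.asarray(genotypes, dtype=np.int8)
    n_sites, n_samples = g.shape
    if depths is None:
        depths = np.full_like(g, 10, dtype=np.int32)
    else:
        depths = np.asarray(depths, dtype=np.int32)
    if positions is None:
        positions = np.arange(1, n_sites + 1) * 100
    if samples is None:
        samples = [f"s{i + 1}" for i in range(n_samples)]
    bases = ["A", "C", "G", "T"]
    sites = pd.DataFrame(
        {
            "scaffold": [scaffold] * n_sites,
            "pos": positions,
            "ref": [bases[i % 4] for i in range(n_sites)],
            "alt": [bases[(i + 1) % 4] for i in range(n_sites)],
        }
    )
    return SnpTable(sites=sites, genotypes=g, depths=depths, samples=list(samples))


def make_sex_map(n_males, n_females, male_prefix="m", female_prefix="f"):
    d = {f"{male_prefix}{i + 1}": "male" for i in range(n_males)}
    d.update({f"{female_prefix}{i + 1}": "female" for i in range(n_females)})
    return SexMap(d)


def small_layout():
    """Desk-scale layout for fast tests: two autosomes + a 12 Mb X scaffold."""
    return GenomeLayout(
        scaffolds=[("auto_1", 30_000_000), ("auto_2", 25_000_000),
                   ("sex_1", 12_000_000)],
        regions=[
            Region("sex_1", 1, 2_000_000, "PAR1"),
            Region("sex_1", 2_000_001, 9_000_000, "HRX"),
            Region("sex_1", 9_000_001, 12_000_000, "PAR2"),
        ],
    )


def autosomal_layout(length=60_000_000):
    return GenomeLayout(scaffolds=[("auto_1", length)])


def small_sim_config(seed=11, **kwargs):
    defaults = dict(seed=seed, layout=small_layout(), snp_spacing=10_000.0)
    defaults.update(kwargs)
    return SimConfig(**defaults)


def autosomal_sim_config(seed=7, **kwargs):
    defaults = dict(
        seed=seed,
        layout=autosomal_layout(),
        snp_spacing=10_000.0,
        gametolog_fraction=0.0,
        x_poly_fraction=0.0,
    )
    defaults.update(kwargs)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def default_sim():
    """The default study-condition simulation (seed 1, 25+25 samples)."""
    return simulate_population(SimConfig(seed=1))


@pytest.fixture(scope="session")
def small_sim():
    return simulate_population(small_sim_config())
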