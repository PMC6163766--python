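import pytest

import degenpanel as dp


@pytest.fixture(scope="session")
def family_small():
    """3 clades x 5 members, 300 codons; quick enough for many tests."""
    spec = dp.FamilySpec(
        n_clades=3,
        members_per_clade=5,
        gene_len=300,
        conserved_windows=((35, 75),),
        rng_seed=7,
    )
    return dp.simulate_family(spec)


@pytest.fixture(scope="session")
def panel_small(family_small):
    collection, pal, _ = family_small
    return dp.design_panel(collection, pal)


@pytest.fixture(scope="session")
def family_benchmark():
    """The benchmark study conditions: 200 sequences in 12 clades, 400-codon
    genes with one conserved 40-codon core, log-normal abundances."""
    spec = dp.FamilySpec(
        n_clades=12,
        members_per_clade=dp.split_members(200, 12),
        gene_len=400,
        conserved_windows=((35, 75),),
        p_cons=0.01,
        p_var_between=0.15,
        p_var_within=0.02,
        rng_seed=1,
    )
    return dp.simulate_family(spec)


@pytest.fixture(scope="session")
def panel_benchmark(family_benchmark):
    collection, pal, _ = family_benchmark
    return dp.design_panel(collection, pal)
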