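import pytest

from retrosilence.config import SimConfig
from retrosilence import synthetic as syn


def tiny_config(seed: int = 0, **overrides) -> SimConfig:
    """A very small world for unit tests: 400 kb genome, 3 families."""
    kw = dict(
        seed=seed,
        genome_length=400_000,
        n_families=3,
        n_copies_per_family=4,
        n_genes=8,
        consensus_lengths=(1_500, 2_200),
        readthrough_model={
            "n_driven_pairs": 2,
            "readthrough_strength": 0.5,
            "min_distance": 4_000,
            "max_distance": 10_000,
            "extension": 1_000,
            "driven_gene_base_rate": 2.0,
            "driver_families": ["L1Md_A"],
        },
        library_sizes={"rnaseq": 4_000, "wgbs_depth": 2, "small_rna": 4_000, "race": 2_000},
        expr_model={
            **SimConfig().expr_model,
            "n_direct_response_genes": 2,
        },
    )
    kw.update(overrides)
    return SimConfig(**kw)


@pytest.fixture(scope="session")
def tiny_world() -> syn.World:
    return syn.build_world(tiny_config(seed=0))


@pytest.fixture(scope="session")
def tiny_world_seed1() -> syn.World:
    return syn.build_world(tiny_config(seed=1))
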