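import random

import pytest
from hypothesis import settings

settings.register_profile("repeatable", derandomize=True, deadline=None)
settings.load_profile("repeatable")

from mulescan import Sequence, SimConfig, TirModel, simulate


def random_dna(rng: random.Random, n: int, alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(alphabet) for _ in range(n))


@pytest.fixture
def rng() -> random.Random:
    return random.Random(20110901)


@pytest.fixture(scope="session")
def small_sim():
    """A compact genome with all four structural classes plus decoys."""
    cfg = SimConfig(
        seed=42,
        genome_len=60_000,
        n_full_full=4,
        n_long_short=2,
        n_short_short=2,
        n_solo=2,
        n_decayed=2,
    )
    genome, hosts, truth = simulate(cfg)
    from mulescan import StructuralClass

    first = truth.by_class(StructuralClass.FULL_FULL)[0]
    template = genome.residues[first.left_tir[0] : first.left_tir[1]]
    model = TirModel(Sequence("consensus", template))
    return cfg, genome, truth, model
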