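import numpy as np
import pytest

from primereval.registry import load_registry
from primereval.synth import (PrimerPlant, SyntheticConfig, fig1_fixture,
                              generate)


@pytest.fixture(scope="session")
def registry():
    return load_registry()


@pytest.fixture(scope="session")
def fig1():
    """Small deterministic database with the canonical depth shape."""
    return fig1_fixture(n_records=150, seed=11)


@pytest.fixture(scope="session")
def planted(registry):
    """Full-length records with exact planted mismatch fractions."""
    cfg = SyntheticConfig(
        n_records=100, seed=7, ref_length=600,
        plants=[
            PrimerPlant(registry.primer("F2"), {1: 0.3}),
            PrimerPlant(registry.primer("R6"), {1: 0.1, 2: 0.1}),
        ],
        group_proportions={"Pr": 0.5, "Cy": 0.3},
        env_fractions={"Soil": 0.4, "Sea": 0.2},
        span="full")
    return generate(cfg)


def random_degenerate(rng, length, max_code_multiplicity=2, n_ambiguous=3):
    """A random primer sequence with a few degenerate positions."""
    from primereval.iupac import DEGENERACY_SETS
    codes_by_mult = {}
    for c, s in DEGENERACY_SETS.items():
        codes_by_mult.setdefault(len(s), []).append(c)
    seq = [("ACGT")[rng.integers(4)] for _ in range(length)]
    amb_positions = rng.choice(length, size=min(n_ambiguous, length),
                               replace=False)
    pool = [c for m, cs in codes_by_mult.items()
            if 1 < m <= max_code_multiplicity for c in cs] + ["I"]
    for p in amb_positions:
        seq[p] = pool[rng.integers(len(pool))]
    return "".join(seq)
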