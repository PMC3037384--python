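import numpy as np
import pytest

from dispos.model import (
    BackgroundModel,
    ClassPriors,
    FlankingModel,
    PWM,
    PositionPrior,
    ZoopsParams,
)
from dispos.seqdata import Sequence, build_dataset


def random_simplex(rng, k=4, n=None):
    a = rng.gamma(1.0, size=(n, k) if n else k) + 0.05
    return a / a.sum(axis=-1, keepdims=True)


def random_zoops(rng, L, w):
    """A random, fully interior ZOOPS parameter set."""
    return ZoopsParams(
        p_occ=float(rng.uniform(0.05, 0.95)),
        strand_weight=float(rng.uniform(0.1, 0.9)),
        pwm=PWM(random_simplex(rng, 4, w)),
        flanking=FlankingModel(random_simplex(rng)),
        position=PositionPrior(
            gamma=float(rng.uniform(0.0, 1.0)),
            xi=float(rng.uniform(-2.0, L)),
            omega=float(rng.uniform(0.5, 5.0)),
            alpha_shape=float(rng.uniform(-3.0, 3.0)),
        ),
    )


def random_sequences(rng, n, L, prefix="s"):
    return [
        Sequence(id=f"{prefix}{i}", residues="".join(rng.choice(list("ACGT"), L)))
        for i in range(n)
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def tiny_dataset(rng):
    """4 + 4 random 12-mers, one class each."""
    fg = random_sequences(rng, 4, 12, "f")
    bg = random_sequences(rng, 4, 12, "b")
    return build_dataset(fg, bg, tss_offset=-12)


@pytest.fixture
def toy_model(rng):
    fg = random_zoops(rng, 12, 3)
    bg = BackgroundModel(
        order=2,
        conditional=random_simplex(rng, 4, 16),
        initial=random_simplex(rng, 4, 2),
    )
    return fg, bg, ClassPriors(pi_fg=0.45)
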