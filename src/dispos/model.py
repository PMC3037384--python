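"""The ZOOPS sequence model and its posteriors.

A promoter either contains no binding site (occurrence indicator c = 0) or
exactly one (c = 1) at an unknown start u on either strand.  Non-site
positions are emitted by an order-0 flanking model F, the site by a position
weight matrix M (applied to the forward sequence or its reverse complement),
and the start position by a mixture of a discretized skew normal and a
uniform distribution over the valid starts.  The control class is modeled by
a homogeneous Markov chain of configurable order.

All likelihood computation is carried out in log space with log-sum-exp.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
from scipy.special import log_ndtr, logsumexp

from .seqdata import ALPHABET, Sequence, encode

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)
_SIMPLEX_TOL = 1e-9


class ModelError(ValueError):
    """Raised when model parameters violate an invariant."""


def _check_simplex(p: np.ndarray, what: str) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if (p < 0).any():
        raise ModelError(f"{what}: negative probability")
    if abs(p.sum() - 1.0) > 1e-6:
        raise ModelError(f"{what}: probabilities sum to {p.sum()}, not 1")
    return p


@dataclass
class PWM:
    """Position weight matrix: per-column letter probabilities, shape (w, 4)."""

    probs: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.atleast_2d(np.asarray(self.probs, dtype=float))
        if self.probs.shape[0] < 1 or self.probs.shape[1] != 4:
            raise ModelError(f"PWM must be (w, 4); got {self.probs.shape}")
        for j, col in enumerate(self.probs):
            _check_simplex(col, f"PWM column {j}")

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    def log_probs(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.log(self.probs)

    def reverse_complement(self) -> "PWM":
        """PWM describing the same motif read on the opposite strand."""
        return PWM(self.probs[::-1, ::-1].copy())

    @classmethod
    def uniform(cls, width: int) -> "PWM":
        return cls(np.full((width, 4), 0.25))


@dataclass
class FlankingModel:
    """Order-0 model for the non-site positions of a site-bearing sequence."""

    probs: np.ndarray

    def __post_init__(self) -> None:
        self.probs = _check_simplex(np.asarray(self.probs, dtype=float), "flanking")
        if self.probs.shape != (4,):
            raise ModelError("flanking model needs exactly 4 probabilities")

    def log_probs(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.log(self.probs)

    @classmethod
    def uniform(cls) -> "FlankingModel":
        return cls(np.full(4, 0.25))


@dataclass
class PositionPrior:
    """Mixture of a uniform and a discretized skew-normal start distribution.

    ``gamma`` is the weight of the uniform component; the skew normal has
    location ``xi`` (bp, internal start coordinates), scale ``omega`` (bp)
    and shape ``alpha_shape`` (dimensionless; 0 recovers a Gaussian).  The
    density is evaluated at integer starts and renormalized over the valid
    range, so the prior is exact on its discrete support.
    """

    gamma: float = 1.0
    xi: float = 0.0
    omega: float = 50.0
    alpha_shape: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.gamma <= 1.0:
            raise ModelError(f"gamma must be in [0,1]; got {self.gamma}")
        if self.omega <= 0:
            raise ModelError(f"omega must be > 0; got {self.omega}")

    def log_skew_normal(self, y: np.ndarray) -> np.ndarray:
        """Unnormalized log density of the skew normal at positions y."""
        z = (np.asarray(y, dtype=float) - self.xi) / self.omega
        return (
            np.log(2.0)
            - np.log(self.omega)
            - 0.5 * z * z
            - _LOG_SQRT_2PI
            + log_ndtr(self.alpha_shape * z)
        )

    def shifted(self, delta: float) -> "PositionPrior":
        """Same prior with the location moved by ``delta`` bp."""
        return PositionPrior(self.gamma, self.xi + delta, self.omega, self.alpha_shape)


def position_log_pmf(prior: PositionPrior, L: int, w: int) -> np.ndarray:
    """Log pmf of the site start over the valid starts 0 .. L - w."""
    if w > L:
        raise ModelError(f"motif width {w} exceeds sequence length {L}")
    n = L - w + 1
    log_uniform = -np.log(n)
    if prior.gamma >= 1.0:
        return np.full(n, log_uniform)
    log_g = prior.log_skew_normal(np.arange(n))
    log_g = log_g - logsumexp(log_g)
    if prior.gamma <= 0.0:
        return log_g
    return np.logaddexp(
        np.log(prior.gamma) + log_uniform,
        np.log1p(-prior.gamma) + log_g,
    )


def position_pmf(prior: PositionPrior, L: int, w: int) -> np.ndarray:
    """Probability of each valid start 0 .. L - w; sums to 1."""
    return np.exp(position_log_pmf(prior, L, w))


@dataclass
class ZoopsParams:
    """Full foreground generative model."""

    p_occ: float
    pwm: PWM
    flanking: FlankingModel
    position: PositionPrior
    strand_weight: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_occ <= 1.0:
            raise ModelError(f"p_occ must be in [0,1]; got {self.p_occ}")
        if not 0.0 <= self.strand_weight <= 1.0:
            raise ModelError(f"strand_weight must be in [0,1]")

    @property
    def width(self) -> int:
        return self.pwm.width


@dataclass
class BackgroundModel:
    """Homogeneous Markov chain of order d over {A,C,G,T}.

    ``conditional`` has shape (4**d, 4): one letter distribution per length-d
    context (contexts enumerated base-4, most significant digit = oldest
    letter).  ``initial`` has shape (d, 4): independent letter distributions
    for the first d positions, where no full context exists yet.
    """

    order: int
    conditional: np.ndarray
    initial: np.ndarray

    def __post_init__(self) -> None:
        if self.order < 0:
            raise ModelError("order must be >= 0")
        self.conditional = np.asarray(self.conditional, dtype=float)
        self.initial = np.asarray(self.initial, dtype=float).reshape(self.order, 4)
        if self.conditional.shape != (4**self.order, 4):
            raise ModelError(
                f"conditional must be ({4**self.order}, 4); got {self.conditional.shape}"
            )
        for i, row in enumerate(self.conditional):
            _check_simplex(row, f"background context {i}")
        for i, row in enumerate(self.initial):
            _check_simplex(row, f"background initial position {i}")

    @classmethod
    def uniform(cls, order: int) -> "BackgroundModel":
        return cls(
            order=order,
            conditional=np.full((4**order, 4), 0.25),
            initial=np.full((order, 4), 0.25),
        )

    @classmethod
    def from_sequences(
        cls, seqs: list[Sequence], order: int, pseudo: float = 1.0
    ) -> "BackgroundModel":
        """Smoothed maximum-likelihood fit from observed (d+1)-mer counts."""
        cond = np.full((4**order, 4), pseudo, dtype=float)
        init = np.full((order, 4), pseudo, dtype=float)
        for s in seqs:
            x = s.encode().astype(np.int64)
            for k in range(min(order, len(x))):
                init[k, x[k]] += 1
            if len(x) > order:
                ctx = context_codes(x, order)
                np.add.at(cond, (ctx, x[order:]), 1.0)
        cond /= cond.sum(axis=1, keepdims=True)
        init /= init.sum(axis=1, keepdims=True)
        return cls(order=order, conditional=cond, initial=init)


def context_codes(x: np.ndarray, order: int) -> np.ndarray:
    """Base-4 codes of the length-``order`` context preceding each position
    ``order .. len(x)-1``."""
    x = np.asarray(x, dtype=np.int64)
    if order == 0:
        return np.zeros(len(x), dtype=np.int64)
    n = len(x) - order
    codes = np.zeros(n, dtype=np.int64)
    for k in range(order):
        codes = codes * 4 + x[k : k + n]
    return codes


@dataclass
class ClassPriors:
    """Prior class probabilities (foreground, background)."""

    pi_fg: float

    def __post_init__(self) -> None:
        if not 0.0 < self.pi_fg < 1.0:
            raise ModelError("pi_fg must be strictly inside (0,1)")

    @property
    def pi_bg(self) -> float:
        return 1.0 - self.pi_fg


# ---------------------------------------------------------------------------
# likelihoods and posteriors


def _window_scores(x: np.ndarray, log_table: np.ndarray) -> np.ndarray:
    """Sum of log_table[j, x[u+j]] over j for every start u (length L-w+1)."""
    w = log_table.shape[0]
    windows = np.lib.stride_tricks.sliding_window_view(x, w)
    return log_table[np.arange(w), windows].sum(axis=1)


def _component_log_probs(
    x: np.ndarray, params: ZoopsParams
) -> tuple[float, np.ndarray, np.ndarray]:
    """Log joint probabilities of (x, c, u, strand) for every component.

    Returns (log P(x, c=0), log P(x, c=1, u, fwd), log P(x, c=1, u, rev)).
    """
    L = len(x)
    w = params.width
    if w > L:
        raise ModelError(f"motif width {w} exceeds sequence length {L}")
    log_f = params.flanking.log_probs()
    total_flank = log_f[x].sum()

    with np.errstate(divide="ignore"):
        log_no_site = np.log1p(-params.p_occ) + total_flank if params.p_occ < 1 else -np.inf
        log_p_occ = np.log(params.p_occ) if params.p_occ > 0 else -np.inf
        log_sw = np.log(params.strand_weight) if params.strand_weight > 0 else -np.inf
        log_sw_rc = (
            np.log1p(-params.strand_weight) if params.strand_weight < 1 else -np.inf
        )

    log_t = position_log_pmf(params.position, L, w)
    # flanking contribution with the window removed
    win_flank = _window_scores(x, np.tile(log_f, (w, 1)))
    flank_part = total_flank - win_flank

    log_m = params.pwm.log_probs()
    log_m_rc = params.pwm.reverse_complement().log_probs()
    fwd = log_p_occ + log_t + flank_part + log_sw + _window_scores(x, log_m)
    rev = log_p_occ + log_t + flank_part + log_sw_rc + _window_scores(x, log_m_rc)
    return log_no_site, fwd, rev


def zoops_log_likelihood(x: Sequence | np.ndarray | str, params: ZoopsParams) -> float:
    """Log P(x | foreground model), marginalized over c, u and strand."""
    xarr = _as_codes(x)
    log_c0, fwd, rev = _component_log_probs(xarr, params)
    return float(logsumexp(np.concatenate(([log_c0], fwd, rev))))


def joint_binding_posterior(
    x: Sequence | np.ndarray | str, params: ZoopsParams
) -> tuple[np.ndarray, np.ndarray, float]:
    """Posterior P(c=1, u, strand | x) for every start u, plus P(c=0 | x).

    Returns (fwd, rev, p_no_site); fwd[u] + rev[u] summed over u plus
    p_no_site equals 1.
    """
    xarr = _as_codes(x)
    log_c0, fwd, rev = _component_log_probs(xarr, params)
    total = logsumexp(np.concatenate(([log_c0], fwd, rev)))
    return np.exp(fwd - total), np.exp(rev - total), float(np.exp(log_c0 - total))


def occurrence_posterior(x: Sequence | np.ndarray | str, params: ZoopsParams) -> float:
    """P(c=1 | x): posterior probability that the sequence carries a site."""
    fwd, rev, p0 = joint_binding_posterior(x, params)
    return float(fwd.sum() + rev.sum())


def background_log_likelihood(
    x: Sequence | np.ndarray | str, bg: BackgroundModel
) -> float:
    """Log probability of x under the order-d Markov control model."""
    xarr = _as_codes(x).astype(np.int64)
    if len(xarr) < bg.order:
        raise ModelError(f"sequence shorter than background order {bg.order}")
    with np.errstate(divide="ignore"):
        log_init = np.log(bg.initial)
        log_cond = np.log(bg.conditional)
    total = sum(log_init[k, xarr[k]] for k in range(bg.order))
    if len(xarr) > bg.order:
        ctx = context_codes(xarr, bg.order)
        total += log_cond[ctx, xarr[bg.order:]].sum()
    return float(total)


def class_log_likelihoods(
    x: Sequence | np.ndarray | str,
    fg: ZoopsParams,
    bg: BackgroundModel,
    priors: ClassPriors,
) -> tuple[float, float]:
    """(log pi_fg + log P(x|fg), log pi_bg + log P(x|bg))."""
    s = np.log(priors.pi_fg) + zoops_log_likelihood(x, fg)
    t = np.log(priors.pi_bg) + background_log_likelihood(x, bg)
    return s, t


def class_posterior(
    x: Sequence | np.ndarray | str,
    fg: ZoopsParams,
    bg: BackgroundModel,
    priors: ClassPriors,
) -> float:
    """P(foreground | x) via Bayes' rule in log space."""
    if priors.pi_fg >= 1.0:
        return 1.0
    s, t = class_log_likelihoods(x, fg, bg, priors)
    return float(np.exp(s - np.logaddexp(s, t)))


def _as_codes(x: Sequence | np.ndarray | str) -> np.ndarray:
    if isinstance(x, Sequence):
        return x.encode()
    if isinstance(x, str):
        return encode(x)
    return np.asarray(x, dtype=np.int8)


# ---------------------------------------------------------------------------
# serialization


@dataclass
class TrainedModel:
    """A trained classifier: foreground ZOOPS model, background Markov model,
    class priors, and the optimization history that produced them."""

    fg: ZoopsParams
    bg: BackgroundModel
    priors: ClassPriors
    objective: float = float("nan")
    heuristic_history: list[dict[str, Any]] = field(default_factory=list)
    restart_objectives: list[float] = field(default_factory=list)
    tss_offset: int = -500
    sequence_length: int | None = None

    def to_dict(self) -> dict[str, Any]:
        fg = self.fg
        return {
            "alphabet": ALPHABET,
            "pwm": fg.pwm.probs.tolist(),
            "flanking": fg.flanking.probs.tolist(),
            "position_prior": {
                "gamma": fg.position.gamma,
                "xi": fg.position.xi,
                "xi_tss": fg.position.xi + self.tss_offset,
                "omega": fg.position.omega,
                "alpha_shape": fg.position.alpha_shape,
            },
            "p_occ": fg.p_occ,
            "strand_weight": fg.strand_weight,
            "background": {
                "order": self.bg.order,
                "conditional": self.bg.conditional.tolist(),
                "initial": self.bg.initial.tolist(),
            },
            "class_priors": {"pi_fg": self.priors.pi_fg, "pi_bg": self.priors.pi_bg},
            "training": {
                "objective": self.objective,
                "heuristic_history": self.heuristic_history,
                "restart_objectives": self.restart_objectives,
                "tss_offset": self.tss_offset,
                "sequence_length": self.sequence_length,
            },
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "TrainedModel":
        pos = d["position_prior"]
        fg = ZoopsParams(
            p_occ=d["p_occ"],
            strand_weight=d["strand_weight"],
            pwm=PWM(np.array(d["pwm"])),
            flanking=FlankingModel(np.array(d["flanking"])),
            position=PositionPrior(
                gamma=pos["gamma"],
                xi=pos["xi"],
                omega=pos["omega"],
                alpha_shape=pos["alpha_shape"],
            ),
        )
        bg = BackgroundModel(
            order=d["background"]["order"],
            conditional=np.array(d["background"]["conditional"]),
            initial=np.array(d["background"]["initial"]),
        )
        tr = d.get("training", {})
        return cls(
            fg=fg,
            bg=bg,
            priors=ClassPriors(pi_fg=d["class_priors"]["pi_fg"]),
            objective=tr.get("objective", float("nan")),
            heuristic_history=tr.get("heuristic_history", []),
            restart_objectives=tr.get("restart_objectives", []),
            tss_offset=tr.get("tss_offset", -500),
            sequence_length=tr.get("sequence_length"),
        )

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))
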