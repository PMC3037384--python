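"""Discriminative parameter estimation and the motif-length heuristic.

Parameters of the foreground ZOOPS model, the background Markov model and
the class priors are fitted jointly by maximizing the *supervised
posterior*: the sum over sequences of the log class posterior
log P(y_i | x_i, theta) plus a log prior over theta.  The prior combines
symmetric Dirichlet/Beta terms (uniform pseudo-data with configurable
equivalent sample sizes) on all probability parameters with Gaussian terms
on the positional location and shape and a Gamma term on the positional
scale.

Optimization runs on unconstrained transforms (log-odds against the last
letter for probability simplexes, logits for scalar probabilities, log for
the positional scale) with analytic gradients, using a quasi-Newton method
with line search.  A phase-shift heuristic shifts, truncates or expands the
motif window between optimization rounds, with a cycle history guaranteeing
termination; the whole procedure is restarted from random initializations
and the restart with the highest supervised posterior wins (ties broken by
lowest restart index).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy import sparse
from scipy.optimize import minimize
from scipy.special import gammaln, log_ndtr, logsumexp
from scipy.stats import norm

from .model import (
    BackgroundModel,
    ClassPriors,
    FlankingModel,
    ModelError,
    PWM,
    PositionPrior,
    TrainedModel,
    ZoopsParams,
)
from .seqdata import FOREGROUND, LabeledDataset

logger = logging.getLogger(__name__)

_EPS = 1e-12
#: reference width for the width-equalized motif prior (see log_prior)
_WIDTH_REFERENCE = 50
#: optimism charge per PWM column (its free-parameter count) applied in the
#: width equalization, so that cross-width comparison does not reward the
#: ~0.5 log-unit-per-parameter noise fit a discriminatively trained column
#: extracts from finite data
_COLUMN_COMPLEXITY = 3.0


# ---------------------------------------------------------------------------
# configuration


@dataclass
class Hyperparams:
    """Hyper-parameters of the composite prior.

    Equivalent sample sizes (ESS) spread uniform pseudo-data over each
    probability simplex: a K-simplex with ESS e receives a symmetric
    Dirichlet with concentration 1 + e/K per component, whose mode is the
    uniform distribution.  The positional location xi gets a broad Gaussian,
    the shape a Gaussian centered at 0 (no skew), the scale omega a Gamma,
    and the uniform-mixture weight gamma a Beta(2, 2).
    """

    ess_motif: float = 4.0
    ess_flanking: float = 4.0
    ess_background: float = 4.0
    ess_class: float = 4.0
    ess_occurrence: float = 4.0
    xi_prior_mean: float = 125.0
    xi_prior_sd: float = 125.0
    shape_prior_mean: float = 0.0
    shape_prior_sd: float = 4.0
    omega_prior_shape: float = 2.0
    omega_prior_rate: float = 0.032
    gamma_prior: tuple[float, float] = (2.0, 2.0)

    def __post_init__(self) -> None:
        for name in (
            "ess_motif", "ess_flanking", "ess_background",
            "ess_class", "ess_occurrence",
        ):
            if getattr(self, name) <= 0:
                raise ModelError(f"{name} must be > 0")
        if self.xi_prior_sd <= 0 or self.shape_prior_sd <= 0:
            raise ModelError("prior standard deviations must be > 0")
        if self.omega_prior_shape <= 0 or self.omega_prior_rate <= 0:
            raise ModelError("Gamma prior parameters must be > 0")

    @classmethod
    def default_for(cls, L: int, w: int) -> "Hyperparams":
        """Length-aware defaults: xi centered mid-range with sd L/2; omega
        Gamma with mean L/4."""
        mid = (L - w) / 2.0
        return cls(
            xi_prior_mean=mid,
            xi_prior_sd=L / 2.0,
            omega_prior_shape=2.0,
            omega_prior_rate=2.0 / (L / 4.0),
        )


@dataclass
class OptimizerConfig:
    restarts: int = 50
    max_iterations: int = 500
    rel_tolerance: float = 1e-6
    seed: int = 1
    init_motif_length: int = 15
    adjust_length: bool = True
    max_motif_length: int = 30
    min_motif_length: int = 4
    insignificance_drop: float = 0.20
    detection_pvalue: float = 1e-4
    bg_order: int = 1
    strand_weight: float = 0.5
    init_candidates: int = 30
    polish: bool = True

    def __post_init__(self) -> None:
        if self.restarts < 1:
            raise ModelError("restarts must be >= 1")
        if not (self.min_motif_length <= self.init_motif_length <= self.max_motif_length):
            raise ModelError("need min <= init <= max motif length")
        if not 0.0 < self.insignificance_drop < 1.0:
            raise ModelError("insignificance_drop must be in (0, 1)")
        if not 0.0 < self.detection_pvalue <= 1.0:
            raise ModelError("detection_pvalue must be in (0, 1]")


# ---------------------------------------------------------------------------
# unconstrained transforms


def _simplex_to_eta(p: np.ndarray) -> np.ndarray:
    p = np.clip(np.asarray(p, dtype=float), _EPS, None)
    return np.log(p[..., :3]) - np.log(p[..., 3:4])


def _eta_to_simplex(eta: np.ndarray) -> np.ndarray:
    full = np.concatenate([eta, np.zeros(eta.shape[:-1] + (1,))], axis=-1)
    full -= full.max(axis=-1, keepdims=True)
    e = np.exp(full)
    return e / e.sum(axis=-1, keepdims=True)

def _simplex_grad(g: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Chain a gradient w.r.t. log p (natural scale) to the log-odds eta."""
    total = g.sum(axis=-1, keepdims=True)
    return (g - p * total)[..., :3]


def _logit(p: float) -> float:
    p = min(max(p, _EPS), 1.0 - _EPS)
    return math.log(p) - math.log1p(-p)


def _sigmoid(x: float) -> float:
    return float(0.5 * (1.0 + math.tanh(0.5 * x)))


# ---------------------------------------------------------------------------
# batched ZOOPS computations


class _ZoopsBatch:
    """Per-dataset precomputation for vectorized ZOOPS likelihoods."""

    def __init__(self, X: np.ndarray, w: int):
        X = np.asarray(X)
        self.X = X
        self.N, self.L = X.shape
        self.w = w
        if w > self.L:
            raise ModelError(f"motif width {w} exceeds sequence length {self.L}")
        self.S = self.L - w + 1
        # (N, S, w) window letter codes
        self.windows = np.ascontiguousarray(
            np.lib.stride_tricks.sliding_window_view(X, w, axis=1).astype(np.int64)
        )
        # sparse one-hot encodings of all windows against a flat (w, 4)
        # table; window scores and their gradients are then single
        # sparse mat-vec products.  Forward strand uses column j / letter l;
        # the reverse complement uses mirrored column w-1-j / complement 3-l.
        j = np.arange(w, dtype=np.int64)
        idx_fwd = (j * 4 + self.windows).reshape(-1)
        idx_rc = ((w - 1 - j) * 4 + (3 - self.windows)).reshape(-1)
        nnz = idx_fwd.size
        ones = np.ones(nnz)
        indptr = np.arange(0, nnz + 1, w)
        self.onehot_fwd = sparse.csr_matrix(
            (ones, idx_fwd.astype(np.int32), indptr), shape=(self.N * self.S, 4 * w)
        )
        self.onehot_rc = sparse.csr_matrix(
            (ones, idx_rc.astype(np.int32), indptr), shape=(self.N * self.S, 4 * w)
        )
        self.letter_counts = np.stack([(X == a).sum(axis=1) for a in range(4)], axis=1)

    def component_log_probs(
        self, params: ZoopsParams
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Vectorized log P(x_i, c, u, strand); also returns log T for reuse."""
        from .model import position_log_pmf

        log_f = params.flanking.log_probs()
        total_flank = self.letter_counts @ log_f
        log_m_flat = params.pwm.log_probs().ravel()
        shape = (self.N, self.S)
        pwm_fwd = (self.onehot_fwd @ log_m_flat).reshape(shape)
        pwm_rev = (self.onehot_rc @ log_m_flat).reshape(shape)
        win_flank = (self.onehot_fwd @ np.tile(log_f, self.w)).reshape(shape)

        log_t = position_log_pmf(params.position, self.L, self.w)
        with np.errstate(divide="ignore"):
            lp = np.log(params.p_occ) if params.p_occ > 0 else -np.inf
            lq = np.log1p(-params.p_occ) if params.p_occ < 1 else -np.inf
            lsw = np.log(params.strand_weight) if params.strand_weight > 0 else -np.inf
            lsw_rc = (
                np.log1p(-params.strand_weight)
                if params.strand_weight < 1
                else -np.inf
            )
        shared = lp + log_t[None, :] + total_flank[:, None] - win_flank
        fwd = shared + lsw + pwm_fwd
        rev = shared + lsw_rc + pwm_rev
        c0 = lq + total_flank
        return c0, fwd, rev, log_t

    def log_likelihoods(self, params: ZoopsParams) -> np.ndarray:
        c0, fwd, rev, _ = self.component_log_probs(params)
        comps = np.concatenate([c0[:, None], fwd, rev], axis=1)
        return logsumexp(comps, axis=1)

    def occurrence_posteriors(self, params: ZoopsParams) -> np.ndarray:
        c0, fwd, rev, _ = self.component_log_probs(params)
        comps = np.concatenate([c0[:, None], fwd, rev], axis=1)
        ll = logsumexp(comps, axis=1)
        return -np.expm1(c0 - ll)


def occurrence_posteriors(params: ZoopsParams, X: np.ndarray) -> np.ndarray:
    """P(c=1 | x) for each row of the (N, L) code matrix X."""
    return _ZoopsBatch(X, params.width).occurrence_posteriors(params)


def count_predicted_promoters(params: ZoopsParams, fg_X: np.ndarray) -> int:
    """Number of foreground sequences with occurrence posterior > 0.5."""
    if params.p_occ == 0:
        return 0
    return int((occurrence_posteriors(params, fg_X) > 0.5).sum())


# ---------------------------------------------------------------------------
# the supervised-posterior problem


class MspProblem:
    """Supervised-posterior objective and analytic gradient on the
    unconstrained parameter vector.

    The vector layout is: PWM log-odds (w x 3), flanking log-odds (3),
    background initial log-odds (d x 3), background conditional log-odds
    (4^d x 3), logit p_occ, logit pi_fg, logit gamma, xi, log omega,
    alpha_shape.
    """

    def __init__(
        self,
        data: LabeledDataset,
        hyper: Hyperparams,
        w: int,
        bg_order: int = 1,
        strand_weight: float = 0.5,
    ):
        self.data = data
        self.hyper = hyper
        self.w = w
        self.d = bg_order
        self.strand_weight = strand_weight
        X = data.encoded().astype(np.int64)
        self.X = X
        self.y = data.labels.astype(float)
        self.N, self.L = X.shape
        self.batch = _ZoopsBatch(X, w)

        d = bg_order
        self.init_letters = X[:, :d] if d > 0 else np.zeros((self.N, 0), dtype=np.int64)
        n_ctx = 4**d
        ctx_counts = np.zeros((self.N, n_ctx, 4))
        if self.L > d:
            codes = np.zeros((self.N, self.L - d), dtype=np.int64)
            for k in range(d):
                codes = codes * 4 + X[:, k : k + self.L - d]
            seq_idx = np.repeat(np.arange(self.N), self.L - d)
            np.add.at(
                ctx_counts, (seq_idx, codes.ravel(), X[:, d:].ravel()), 1.0
            )
        self.ctx_counts = ctx_counts
        self.n_params = (
            self.w * 3 + 3 + self.d * 3 + (4**self.d) * 3 + 6
        )

    # -- packing ------------------------------------------------------------

    def pack(
        self, fg: ZoopsParams, bg: BackgroundModel, priors: ClassPriors
    ) -> np.ndarray:
        if fg.width != self.w or bg.order != self.d:
            raise ModelError("parameter shapes do not match problem definition")
        parts = [
            _simplex_to_eta(fg.pwm.probs).ravel(),
            _simplex_to_eta(fg.flanking.probs).ravel(),
            _simplex_to_eta(bg.initial).ravel() if self.d > 0 else np.empty(0),
            _simplex_to_eta(bg.conditional).ravel(),
            [
                _logit(fg.p_occ),
                _logit(priors.pi_fg),
                _logit(fg.position.gamma),
                fg.position.xi,
                math.log(fg.position.omega),
                fg.position.alpha_shape,
            ],
        ]
        return np.concatenate([np.asarray(p, dtype=float) for p in parts])

    def unpack(
        self, vec: np.ndarray
    ) -> tuple[ZoopsParams, BackgroundModel, ClassPriors]:
        w, d = self.w, self.d
        i = 0
        pwm_eta = vec[i : i + w * 3].reshape(w, 3); i += w * 3
        flank_eta = vec[i : i + 3]; i += 3
        init_eta = vec[i : i + d * 3].reshape(d, 3); i += d * 3
        cond_eta = vec[i : i + (4**d) * 3].reshape(4**d, 3); i += (4**d) * 3
        p_occ_l, pi_l, gamma_l, xi, log_omega, alpha = vec[i : i + 6]
        fg = ZoopsParams(
            p_occ=_sigmoid(p_occ_l),
            strand_weight=self.strand_weight,
            pwm=PWM(_eta_to_simplex(pwm_eta)),
            flanking=FlankingModel(_eta_to_simplex(flank_eta)),
            position=PositionPrior(
                gamma=_sigmoid(gamma_l),
                xi=float(xi),
                omega=float(np.exp(log_omega)),
                alpha_shape=float(alpha),
            ),
        )
        bg = BackgroundModel(
            order=d,
            conditional=_eta_to_simplex(cond_eta),
            initial=_eta_to_simplex(init_eta) if d > 0 else np.zeros((0, 4)),
        )
        return fg, bg, ClassPriors(pi_fg=_sigmoid(pi_l))

    # -- objective ----------------------------------------------------------

    def value(self, vec: np.ndarray) -> float:
        return self.value_and_grad(vec)[0]

    def value_and_grad(self, vec: np.ndarray) -> tuple[float, np.ndarray]:
        fg, bg, priors = self.unpack(vec)
        hyper = self.hyper
        w, d, N, S = self.w, self.d, self.N, self.batch.S

        c0, fwd, rev, log_t = self.batch.component_log_probs(fg)
        comps = np.concatenate([c0[:, None], fwd, rev], axis=1)
        ll_fg = logsumexp(comps, axis=1)
        resp = np.exp(comps - ll_fg[:, None])
        r0, rf, rr = resp[:, 0], resp[:, 1 : S + 1], resp[:, S + 1 :]

        log_init = np.log(np.clip(bg.initial, _EPS, None))
        log_cond = np.log(np.clip(bg.conditional, _EPS, None))
        ll_bg = self.ctx_counts.reshape(N, -1) @ log_cond.ravel()
        if d > 0:
            ll_bg = ll_bg + np.take_along_axis(
                log_init[None, :, :].repeat(N, axis=0),
                self.init_letters[:, :, None], axis=2,
            )[:, :, 0].sum(axis=1)

        s = math.log(priors.pi_fg) + ll_fg
        t = math.log(priors.pi_bg) + ll_bg
        lse = np.logaddexp(s, t)
        cond_ll = float(np.sum(np.where(self.y == 1, s, t) - lse))
        p_fg = np.exp(s - lse)
        weight = self.y - p_fg  # d cond_ll / d s_i

        value = cond_ll + self._log_prior_value(fg, bg, priors)

        # ---- gradients ----------------------------------------------------
        grad = np.zeros_like(vec)

        wf = weight[:, None] * rf
        wr = weight[:, None] * rr
        wsum = wf + wr
        # natural gradients w.r.t. log-probabilities
        g_pwm = (
            self.batch.onehot_fwd.T @ wf.ravel()
            + self.batch.onehot_rc.T @ wr.ravel()
        ).reshape(w, 4)
        g_flank = weight @ self.letter_counts_float()
        g_flank -= (
            (self.batch.onehot_fwd.T @ wsum.ravel()).reshape(w, 4).sum(axis=0)
        )

        # occurrence probability (logit scale)
        g_p_occ = float(weight @ ((1.0 - r0) - fg.p_occ))

        # position prior
        q = wsum.sum(axis=0)  # sum_i weight_i * P(u | x_i, c=1)
        g_gamma_l, g_xi, g_lomega, g_alpha = self._position_grads(fg.position, q, log_t)

        # background (conditional log-likelihood part; weight enters with -)
        g_cond = -np.tensordot(weight, self.ctx_counts, axes=1)
        g_init = np.zeros((d, 4))
        for k in range(d):
            g_init[k] = -np.bincount(self.init_letters[:, k], weights=weight, minlength=4)

        g_pi = float(weight.sum())

        # ---- prior gradients (natural scale, then chain) -------------------
        conc_m = 1.0 + hyper.ess_motif / 4.0
        conc_f = 1.0 + hyper.ess_flanking / 4.0
        conc_b = 1.0 + hyper.ess_background / 4.0
        a_occ = 1.0 + hyper.ess_occurrence / 2.0
        a_cls = 1.0 + hyper.ess_class / 2.0
        g_pwm += conc_m - 1.0
        g_flank += conc_f - 1.0
        g_cond += conc_b - 1.0
        if d > 0:
            g_init += conc_b - 1.0
        g_p_occ += (a_occ - 1.0) * (1.0 - fg.p_occ) - (a_occ - 1.0) * fg.p_occ
        g_pi += (a_cls - 1.0) * (1.0 - priors.pi_fg) - (a_cls - 1.0) * priors.pi_fg
        ga, gb = hyper.gamma_prior
        gm = fg.position.gamma
        g_gamma_l += (ga - 1.0) * (1.0 - gm) - (gb - 1.0) * gm
        g_xi += -(fg.position.xi - hyper.xi_prior_mean) / hyper.xi_prior_sd**2
        g_alpha += -(fg.position.alpha_shape - hyper.shape_prior_mean) / hyper.shape_prior_sd**2
        g_lomega += (hyper.omega_prior_shape - 1.0) - hyper.omega_prior_rate * fg.position.omega

        # ---- assemble -----------------------------------------------------
        i = 0
        grad[i : i + w * 3] = _simplex_grad(g_pwm, fg.pwm.probs).ravel(); i += w * 3
        grad[i : i + 3] = _simplex_grad(g_flank, fg.flanking.probs); i += 3
        if d > 0:
            grad[i : i + d * 3] = _simplex_grad(g_init, bg.initial).ravel()
        i += d * 3
        grad[i : i + (4**d) * 3] = _simplex_grad(g_cond, bg.conditional).ravel()
        i += (4**d) * 3
        grad[i : i + 6] = [g_p_occ, g_pi, g_gamma_l, g_xi, g_lomega, g_alpha]
        return value, grad

    def letter_counts_float(self) -> np.ndarray:
        return self.batch.letter_counts.astype(float)

    def _position_grads(
        self, prior: PositionPrior, q: np.ndarray, log_t: np.ndarray
    ) -> tuple[float, float, float, float]:
        """Gradients of sum_u q_u * log T(u) w.r.t. (logit gamma, xi,
        log omega, alpha)."""
        S = len(log_t)
        gm = prior.gamma
        y = np.arange(S, dtype=float)
        z = (y - prior.xi) / prior.omega
        az = prior.alpha_shape * z
        # hazard ratio phi(az)/Phi(az), stable for very negative az
        rho = np.exp(norm.logpdf(az) - log_ndtr(az))

        # responsibilities of the two mixture components within T(u)
        if gm >= 1.0:
            a_u = np.ones(S)
        elif gm <= 0.0:
            a_u = np.zeros(S)
        else:
            a_u = np.exp(math.log(gm) - math.log(S) - log_t)
        b_u = 1.0 - a_u

        # d log T(u) / d logit(gamma)
        dgamma = a_u * (1.0 - gm) - b_u * gm

        # normalized skew-normal log density derivatives
        log_g = prior.log_skew_normal(y)
        soft = np.exp(log_g - logsumexp(log_g))
        dxi_g = z / prior.omega - (prior.alpha_shape / prior.omega) * rho
        dlo_g = (z * z - 1.0) - prior.alpha_shape * z * rho
        dal_g = z * rho
        dxi = b_u * (dxi_g - soft @ dxi_g)
        dlo = b_u * (dlo_g - soft @ dlo_g)
        dal = b_u * (dal_g - soft @ dal_g)
        return float(q @ dgamma), float(q @ dxi), float(q @ dlo), float(q @ dal)

    def _log_prior_value(
        self, fg: ZoopsParams, bg: BackgroundModel, priors: ClassPriors
    ) -> float:
        return log_prior(fg, bg, priors, self.hyper)


def _log_dirichlet(p: np.ndarray, conc: float) -> float:
    """Symmetric Dirichlet log density; -inf on the simplex boundary when
    the concentration exceeds 1."""
    p = np.asarray(p, dtype=float)
    k = p.shape[-1]
    norm_const = gammaln(k * conc) - k * gammaln(conc)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = (conc - 1.0) * np.log(p)
    terms = np.where((p == 0) & (conc == 1.0), 0.0, terms)
    return float(norm_const * (p.size // k) + np.sum(terms))


def log_prior(
    fg: ZoopsParams,
    bg: BackgroundModel,
    priors: ClassPriors,
    hyper: Hyperparams,
) -> float:
    """Log density of the composite prior at the given parameters.

    Boundary parameters (zero probabilities under a concentration > 1)
    yield -inf.
    """
    h = hyper
    conc_m = 1.0 + h.ess_motif / 4.0
    total = _log_dirichlet(fg.pwm.probs, conc_m)
    # width equalization: pad the motif prior with virtual uniform columns up
    # to a fixed reference width.  A column equal to the flanking distribution
    # leaves the ZOOPS likelihood unchanged, so models of different widths
    # describe the same data distribution; without this constant the
    # supervised posterior would reward wide windows by one Dirichlet-density
    # term per extra column, biasing restart selection against trimmed motifs.
    total += (_WIDTH_REFERENCE - fg.width) * (
        _log_dirichlet(np.full(4, 0.25), conc_m) + _COLUMN_COMPLEXITY
    )
    total += _log_dirichlet(fg.flanking.probs, 1.0 + h.ess_flanking / 4.0)
    total += _log_dirichlet(bg.conditional, 1.0 + h.ess_background / 4.0)
    if bg.order > 0:
        total += _log_dirichlet(bg.initial, 1.0 + h.ess_background / 4.0)
    total += _log_dirichlet(
        np.array([fg.p_occ, 1.0 - fg.p_occ]), 1.0 + h.ess_occurrence / 2.0
    )
    total += _log_dirichlet(
        np.array([priors.pi_fg, priors.pi_bg]), 1.0 + h.ess_class / 2.0
    )
    ga, gb = h.gamma_prior
    gm = fg.position.gamma
    total += gammaln(ga + gb) - gammaln(ga) - gammaln(gb)
    with np.errstate(divide="ignore"):
        total += (ga - 1.0) * np.log(gm) + (gb - 1.0) * np.log1p(-gm)
    total += norm.logpdf(fg.position.xi, h.xi_prior_mean, h.xi_prior_sd)
    total += norm.logpdf(fg.position.alpha_shape, h.shape_prior_mean, h.shape_prior_sd)
    k, r = h.omega_prior_shape, h.omega_prior_rate
    om = fg.position.omega
    total += (k - 1.0) * math.log(om) - r * om + k * math.log(r) - gammaln(k)
    return float(total)


def msp_objective(
    fg: ZoopsParams,
    bg: BackgroundModel,
    priors: ClassPriors,
    data: LabeledDataset,
    hyper: Hyperparams,
) -> float:
    """Supervised posterior: sum_i log P(y_i | x_i) + log prior."""
    problem = MspProblem(
        data, hyper, w=fg.width, bg_order=bg.order, strand_weight=fg.strand_weight
    )
    return problem.value(problem.pack(fg, bg, priors))


# ---------------------------------------------------------------------------
# numerical optimization


@dataclass
class OptimizeResult:
    fg: ZoopsParams
    bg: BackgroundModel
    priors: ClassPriors
    objective: float
    n_iterations: int
    converged: bool


def optimize(
    fg: ZoopsParams,
    bg: BackgroundModel,
    priors: ClassPriors,
    data: LabeledDataset,
    hyper: Hyperparams,
    config: OptimizerConfig,
) -> OptimizeResult:
    """Maximize the supervised posterior from the given starting point."""
    problem = MspProblem(
        data, hyper, w=fg.width, bg_order=bg.order, strand_weight=fg.strand_weight
    )
    x0 = problem.pack(fg, bg, priors)
    start_val = problem.value(x0)
    if not np.isfinite(start_val):
        raise ModelError("non-finite objective at the starting point")

    def neg(vec: np.ndarray) -> tuple[float, np.ndarray]:
        v, g = problem.value_and_grad(vec)
        if not np.isfinite(v):
            raise FloatingPointError("non-finite objective during optimization")
        return -v, -g

    res = minimize(
        neg,
        x0,
        jac=True,
        method="L-BFGS-B",
        options={
            "maxiter": config.max_iterations,
            "ftol": config.rel_tolerance,
            "gtol": 1e-7,
        },
    )
    final = -float(res.fun)
    if final < start_val:  # L-BFGS never accepts a worse point, but be safe
        final, res.x = start_val, x0
    fg2, bg2, pr2 = problem.unpack(res.x)
    return OptimizeResult(
        fg=fg2, bg=bg2, priors=pr2, objective=final,
        n_iterations=int(res.nit), converged=bool(res.success),
    )


# ---------------------------------------------------------------------------
# phase shift and motif-length adjustment


@dataclass(frozen=True)
class Modification:
    """A window modification: drop ``left``/``right`` border columns and/or
    add ``add_left``/``add_right`` fresh uniform columns."""

    kind: str  # shift_left | shift_right | truncate | expand
    left: int = 0   # columns dropped at the left border
    right: int = 0  # columns dropped at the right border
    add_left: int = 0
    add_right: int = 0

    @property
    def width_delta(self) -> int:
        return self.add_left + self.add_right - self.left - self.right

    @property
    def offset_delta(self) -> int:
        """Shift of the window start relative to the modeled sites."""
        return self.left - self.add_left


def shift_right(k: int) -> Modification:
    return Modification("shift_right", left=k, add_right=k)


def shift_left(k: int) -> Modification:
    return Modification("shift_left", right=k, add_left=k)


def truncate(left: int, right: int) -> Modification:
    return Modification("truncate", left=left, right=right)


def expand() -> Modification:
    return Modification("expand", add_left=1, add_right=1)


def apply_modification(params: ZoopsParams, mod: Modification,
                       min_motif_length: int = 1) -> ZoopsParams:
    """Apply a window modification to the foreground parameters.

    Overlapping PWM columns are copied bit-exactly, newly exposed columns are
    initialized uniform, and the positional location is shifted so that the
    implied site placement is preserved.
    """
    w = params.width
    new_w = w + mod.width_delta
    if new_w < min_motif_length:
        raise ModelError(
            f"modification would shrink the motif to {new_w} < {min_motif_length}"
        )
    kept = params.pwm.probs[mod.left : w - mod.right]
    cols = np.vstack(
        [np.full((mod.add_left, 4), 0.25), kept, np.full((mod.add_right, 4), 0.25)]
    )
    return replace(
        params,
        pwm=PWM(cols),
        position=params.position.shifted(mod.offset_delta),
    )


def count_detected_promoters(
    params: ZoopsParams,
    fg_X: np.ndarray,
    ctrl_X: np.ndarray,
    pvalue: float,
) -> int:
    """Foreground promoters carrying at least one detectable site.

    A position is detectable when its strand-summed joint posterior exceeds
    all but a fraction ``pvalue`` of the per-position scores on the control
    set (the empirical p-value criterion used for site calling).  Unlike the
    raw occurrence posterior, this count responds to the informativeness of
    the motif columns: discriminative training tends to push p_occ high,
    which makes P(c=1|x) > 0.5 nearly always true and useless as a signal.
    """
    w = params.width
    fg_scores = _position_score_matrix(params, fg_X)
    ctrl = np.sort(_position_score_matrix(params, ctrl_X).ravel())
    n = ctrl.size
    # p-value of s is (# ctrl > s)/n; detected iff strictly below threshold
    pvals = (n - np.searchsorted(ctrl, fg_scores, side="right")) / n
    return int((pvals < pvalue).any(axis=1).sum())


def _position_score_matrix(params: ZoopsParams, X: np.ndarray) -> np.ndarray:
    """(N, S) strand-summed joint posteriors P(c=1, u | x)."""
    batch = _ZoopsBatch(X, params.width)
    c0, fwd, rev, _ = batch.component_log_probs(params)
    comps = np.concatenate([c0[:, None], fwd, rev], axis=1)
    ll = logsumexp(comps, axis=1)
    S = batch.S
    post = np.exp(comps - ll[:, None])
    return post[:, 1 : S + 1] + post[:, S + 1 :]


def insignificant_positions(
    params: ZoopsParams,
    fg_X: np.ndarray,
    ctrl_X: np.ndarray,
    config: OptimizerConfig,
) -> tuple[int, int]:
    """Largest contiguous border-column counts whose removal keeps the number
    of promoters predicted to contain a site within the configured budget.

    Each side is probed independently from the full model; removal means
    truncating the window (re-normalized position prior over the shorter
    window's start range).
    """
    w = params.width
    base = count_detected_promoters(
        params, fg_X, ctrl_X, config.detection_pvalue
    )
    if base == 0:
        return 0, 0
    floor_count = (1.0 - config.insignificance_drop) * base

    def probe(side: str) -> int:
        best = 0
        for k in range(1, w):
            mod = truncate(k, 0) if side == "left" else truncate(0, k)
            trimmed = apply_modification(params, mod, min_motif_length=1)
            count = count_detected_promoters(
                trimmed, fg_X, ctrl_X, config.detection_pvalue
            )
            if count >= floor_count:
                best = k
            else:
                break
        return best

    left, right = probe("left"), probe("right")
    # keep the documented invariant left + right < w
    while left + right >= w:
        if right >= left and right > 0:
            right -= 1
        elif left > 0:
            left -= 1
    return left, right


def propose_modification(
    left: int,
    right: int,
    w: int,
    history: set[tuple[int, int]],
    config: OptimizerConfig,
    offset: int = 0,
) -> Optional[Modification]:
    """Rule table mapping insignificant border counts to a window move.

    Returns None when no admissible move exists or the resulting
    (length, cumulative offset) state was already visited.
    """
    if left + right >= w:
        raise ModelError("insignificant positions must leave at least one column")
    if left > 0 and right == 0:
        mod = shift_right(left)
    elif right > 0 and left == 0:
        mod = shift_left(right)
    elif left > 0 and right > 0:
        if w - left - right < config.min_motif_length:
            return None
        mod = truncate(left, right)
    else:
        if w + 2 > config.max_motif_length:
            return None
        mod = expand()
    state = (w + mod.width_delta, offset + mod.offset_delta)
    if state in history:
        return None
    return mod


def polish_foreground(
    params: ZoopsParams,
    fg_X: np.ndarray,
    hyper: Hyperparams,
    max_iter: int = 100,
) -> ZoopsParams:
    """Self-consistent polish of the reported PWM and position distribution.

    Once the two classes separate, the conditional likelihood carries almost
    no gradient for the foreground emission parameters (the per-sequence
    weights 1 - P(y|x) vanish), so the discriminatively trained PWM columns
    and position distribution can be under-determined even when site
    placement is accurate.  This step runs expectation-maximization on the
    foreground set with the strand weight, background model and class priors
    frozen: the E-step computes the site posteriors P(c=1, u, strand | x)
    under the current parameters; the M-step re-estimates the PWM from the
    posterior-weighted site alignments, the flanking model from the expected
    non-site letters, the occurrence probability from the total site mass
    (each with its pseudo-counts), and refits (gamma, xi, omega, alpha) to
    the posterior start-position mass.  Because the posteriors are anchored
    at the discriminatively selected motif, the polish calibrates that
    motif's description rather than drifting to merely over-represented
    signal; the reported matrix is the model's account of the sites it
    believes in, in the same way a logo built from predicted sites is.
    Re-estimating flanking and p_occ matters: their discriminatively trained
    values can be far from the data's letter statistics (only ratios are
    identified once classes separate), which would poison the E-step.
    """
    from .model import position_log_pmf

    w = params.width
    L = fg_X.shape[1]
    batch = _ZoopsBatch(fg_X, w)

    def neg_position(vec: np.ndarray, q: np.ndarray) -> float:
        gamma_l, xi, log_omega, alpha = vec
        prior = PositionPrior(
            gamma=_sigmoid(gamma_l), xi=float(xi),
            omega=float(np.exp(log_omega)), alpha_shape=float(alpha),
        )
        val = float(q @ position_log_pmf(prior, L, w))
        ga, gb = hyper.gamma_prior
        gm = min(max(prior.gamma, _EPS), 1 - _EPS)
        val += (ga - 1.0) * math.log(gm) + (gb - 1.0) * math.log1p(-gm)
        val -= 0.5 * ((xi - hyper.xi_prior_mean) / hyper.xi_prior_sd) ** 2
        val -= 0.5 * ((alpha - hyper.shape_prior_mean) / hyper.shape_prior_sd) ** 2
        val += (hyper.omega_prior_shape - 1.0) * log_omega
        val -= hyper.omega_prior_rate * prior.omega
        return -val

    current = params
    p0 = current.position
    x0 = np.array([_logit(p0.gamma), p0.xi, math.log(p0.omega), p0.alpha_shape])
    pseudo_m = hyper.ess_motif / 4.0
    pseudo_f = hyper.ess_flanking / 4.0
    a_occ = 1.0 + hyper.ess_occurrence / 2.0
    S = batch.S
    total_letters = batch.letter_counts.sum(axis=0).astype(float)

    for _ in range(max_iter):
        c0, fwd, rev, _ = batch.component_log_probs(current)
        comps = np.concatenate([c0[:, None], fwd, rev], axis=1)
        ll = logsumexp(comps, axis=1)
        resp = np.exp(comps - ll[:, None])
        rf, rr = resp[:, 1 : S + 1], resp[:, S + 1 :]
        q = (rf + rr).sum(axis=0)
        if q.sum() <= 0:
            return params

        site_counts = (
            batch.onehot_fwd.T @ rf.ravel() + batch.onehot_rc.T @ rr.ravel()
        ).reshape(w, 4)
        counts = site_counts + pseudo_m
        new_pwm = counts / counts.sum(axis=1, keepdims=True)

        # expected non-site letters: everything not emitted by the motif
        flank_counts = total_letters - site_counts.sum(axis=0) + pseudo_f
        new_flank = flank_counts / flank_counts.sum()

        occ_mass = float(q.sum())
        new_p_occ = (occ_mass + a_occ - 1.0) / (batch.N + 2.0 * (a_occ - 1.0))
        new_p_occ = min(max(new_p_occ, _EPS), 1.0 - _EPS)

        res = minimize(neg_position, x0, args=(q,), method="Nelder-Mead",
                       options={"maxiter": 2000, "xatol": 1e-6, "fatol": 1e-9})
        gamma_l, xi, log_omega, alpha = res.x
        new_position = PositionPrior(
            gamma=_sigmoid(gamma_l), xi=float(xi),
            omega=float(np.exp(log_omega)), alpha_shape=float(alpha),
        )
        moved = max(
            float(np.max(np.abs(new_pwm - current.pwm.probs))),
            float(np.max(np.abs(new_flank - current.flanking.probs))),
            float(np.max(np.abs(res.x - x0))),
            abs(new_p_occ - current.p_occ),
        )
        current = replace(
            current,
            pwm=PWM(new_pwm),
            flanking=FlankingModel(new_flank),
            position=new_position,
            p_occ=new_p_occ,
        )
        x0 = res.x
        if moved < 1e-5:
            break
    return current


# ---------------------------------------------------------------------------
# full training loop


def _seed_pwm(codes: np.ndarray) -> np.ndarray:
    """Subsequence-seeded PWM smoothed with uniform pseudo-counts (ESS 4)."""
    w = len(codes)
    pwm = np.full((w, 4), 1.0)
    pwm[np.arange(w), codes] += 1.0
    return pwm / pwm.sum(axis=1, keepdims=True)


def _initial_params(
    data: LabeledDataset,
    w: int,
    hyper: Hyperparams,
    config: OptimizerConfig,
    rng: np.random.Generator,
) -> tuple[ZoopsParams, BackgroundModel, ClassPriors]:
    """Restart initialization.

    A pool of candidate length-w foreground subsequences is drawn at random;
    each seeds a smoothed PWM, and the candidate whose full parameter set
    scores highest under the supervised posterior wins.  A single random
    subsequence rarely overlaps a true site, so screening a modest pool per
    restart makes restarts vastly more productive while the per-restart
    randomness keeps them diverse.  Position prior starts near-uniform
    (gamma = 0.9); flanking and background start from observed letter
    statistics; p_occ starts at 0.5.
    """
    fg_seqs = data.foreground()
    L = data.length
    X = data.encoded()
    counts = np.array([(X == a).sum() for a in range(4)], dtype=float) + 1.0
    flank = counts / counts.sum()

    bg = BackgroundModel.from_sequences(data.background(), order=config.bg_order)
    priors = ClassPriors(pi_fg=float(np.clip(data.labels.mean(), 0.05, 0.95)))

    def candidate(codes: np.ndarray) -> ZoopsParams:
        return ZoopsParams(
            p_occ=0.5,
            strand_weight=config.strand_weight,
            pwm=PWM(_seed_pwm(codes)),
            flanking=FlankingModel(flank),
            position=PositionPrior(
                gamma=0.9, xi=(L - w) / 2.0, omega=L / 6.0, alpha_shape=0.0
            ),
        )

    n_cand = max(1, config.init_candidates)
    seq_idx = rng.integers(len(fg_seqs), size=n_cand)
    starts = rng.integers(L - w + 1, size=n_cand)
    problem = MspProblem(
        data, hyper, w=w, bg_order=config.bg_order,
        strand_weight=config.strand_weight,
    )
    best_fg, best_val = None, -np.inf
    for si, st in zip(seq_idx, starts):
        codes = fg_seqs[si].encode()[st : st + w]
        fg = candidate(codes)
        val = problem.value(problem.pack(fg, bg, priors))
        if val > best_val:
            best_fg, best_val = fg, val
    assert best_fg is not None
    return best_fg, bg, priors


def train_dispom(
    data: LabeledDataset,
    hyper: Hyperparams | None = None,
    config: OptimizerConfig | None = None,
) -> TrainedModel:
    """Multi-restart discriminative training with the length heuristic.

    Each restart alternates numerical optimization with one heuristic step
    (shift / truncate / expand, guided by insignificant border positions)
    until no admissible modification remains; the restart with the highest
    supervised posterior wins.
    """
    config = config or OptimizerConfig()
    hyper = hyper or Hyperparams.default_for(data.length, config.init_motif_length)
    if not (data.labels == FOREGROUND).any() or not (data.labels == 0).any():
        raise ModelError("training needs at least one sequence per class")

    fg_X = data.subset(FOREGROUND).encoded().astype(np.int64)
    ctrl_X = data.subset(0).encoded().astype(np.int64)
    rng = np.random.default_rng(config.seed)
    restart_seeds = rng.integers(0, 2**31 - 1, size=config.restarts)

    best: TrainedModel | None = None
    restart_objectives: list[float] = []
    failures: list[str] = []
    for ridx, rseed in enumerate(restart_seeds):
        try:
            result, history = _run_restart(
                data, fg_X, ctrl_X, hyper, config,
                np.random.default_rng(int(rseed)),
            )
        except (ModelError, FloatingPointError) as exc:
            failures.append(f"restart {ridx}: {exc}")
            restart_objectives.append(float("-inf"))
            continue
        restart_objectives.append(result.objective)
        logger.info(
            "restart %d: objective %.4f, width %d, %d heuristic steps",
            ridx, result.objective, result.fg.width, len(history),
        )
        if best is None or result.objective > best.objective:
            best = TrainedModel(
                fg=result.fg,
                bg=result.bg,
                priors=result.priors,
                objective=result.objective,
                heuristic_history=history,
                tss_offset=data.tss_offset,
                sequence_length=data.length,
            )
    if best is None:
        raise ModelError("all restarts diverged: " + "; ".join(failures))
    best.restart_objectives = restart_objectives
    if config.polish:
        best.fg = polish_foreground(best.fg, fg_X, hyper)
        if config.adjust_length:
            trimmed = _trim_uninformative_borders(best.fg, config)
            if trimmed.width != best.fg.width:
                best.fg = polish_foreground(trimmed, fg_X, hyper)
                best.heuristic_history.append(
                    {"modification": "ic-trim", "width": best.fg.width,
                     "objective": best.objective}
                )
    return best


def _trim_uninformative_borders(
    params: ZoopsParams, config: OptimizerConfig, ic_threshold: float = 0.25
) -> ZoopsParams:
    """Drop border columns below the information-content threshold (bits).

    The effective length of a motif is conventionally taken without border
    positions carrying less than 0.25 bit; after the polish, window columns
    that only ever covered flanking sequence converge to the flanking
    distribution and are removed here, with the positional location shifted
    to keep site placement fixed.  Never trims below the minimum length.
    """
    probs = params.pwm.probs
    with np.errstate(divide="ignore", invalid="ignore"):
        ic = 2.0 + np.where(probs > 0, probs * np.log2(probs), 0.0).sum(axis=1)
    w = len(ic)
    lo, hi = 0, w
    while lo < hi and ic[lo] < ic_threshold:
        lo += 1
    while hi > lo and ic[hi - 1] < ic_threshold:
        hi -= 1
    lo = min(lo, w - config.min_motif_length)
    hi = max(hi, lo + config.min_motif_length)
    if lo <= 0 and hi >= w:
        return params
    return apply_modification(
        params, truncate(lo, w - hi), config.min_motif_length
    )


def _run_restart(
    data: LabeledDataset,
    fg_X: np.ndarray,
    ctrl_X: np.ndarray,
    hyper: Hyperparams,
    config: OptimizerConfig,
    rng: np.random.Generator,
) -> tuple[OptimizeResult, list[dict]]:
    fg, bg, priors = _initial_params(
        data, config.init_motif_length, hyper, config, rng
    )
    history_states: set[tuple[int, int]] = {(fg.width, 0)}
    offset = 0
    history: list[dict] = []
    result = optimize(fg, bg, priors, data, hyper, config)
    history.append(
        {"modification": "initial", "width": result.fg.width,
         "objective": result.objective}
    )
    pre_expand: OptimizeResult | None = None
    while config.adjust_length:
        left, right = insignificant_positions(result.fg, fg_X, ctrl_X, config)
        if pre_expand is not None and (left, right) != (0, 0):
            # the freshly added columns stayed insignificant: the expansion
            # bought nothing, so fall back to the pre-expansion optimum
            result = pre_expand
            history.append(
                {"modification": "revert-expand", "width": result.fg.width,
                 "objective": result.objective}
            )
            break
        mod = propose_modification(
            left, right, result.fg.width, history_states, config, offset
        )
        if mod is None:
            break
        pre_expand = result if mod.kind == "expand" else None
        new_fg = apply_modification(result.fg, mod, config.min_motif_length)
        offset += mod.offset_delta
        history_states.add((new_fg.width, offset))
        result = optimize(new_fg, result.bg, result.priors, data, hyper, config)
        history.append(
            {"modification": mod.kind, "width": result.fg.width,
             "objective": result.objective}
        )
        logger.info(
            "heuristic step: %s -> width %d, objective %.4f",
            mod.kind, result.fg.width, result.objective,
        )
    return result, history
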