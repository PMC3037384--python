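"""Binding-site calling with control-derived empirical p-values.

For every valid start position of a sequence the strand-summed posterior
P(c=1, u | x) under the foreground model is computed.  The same score is
computed for every position of every control sequence, yielding an empirical
background score distribution; the p-value of a score is the fraction of
control scores that strictly exceed it.  Sites are predicted wherever the
p-value falls below a threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import TrainedModel, ZoopsParams, joint_binding_posterior
from .seqdata import Sequence


class PredictionError(ValueError):
    pass


@dataclass
class BackgroundScoreDistribution:
    """Sorted multiset of per-position posterior scores from the control set."""

    scores: np.ndarray  # ascending

    def __post_init__(self) -> None:
        self.scores = np.sort(np.asarray(self.scores, dtype=float))

    def __len__(self) -> int:
        return len(self.scores)


@dataclass(frozen=True)
class SitePrediction:
    """One predicted binding site."""

    sequence_id: str
    start: int          # internal 0-based start
    start_tss: int      # TSS-relative start
    strand: str         # '+' or '-'
    score: float        # strand-summed joint posterior P(c=1, u | x)
    p_value: float


def _position_scores(
    x: Sequence, params: ZoopsParams
) -> tuple[np.ndarray, np.ndarray]:
    """(strand-summed scores, argmax strand codes 0=+/1=-) per start."""
    fwd, rev, _ = joint_binding_posterior(x, params)
    return fwd + rev, (rev > fwd).astype(int)


def background_distribution(
    control: list[Sequence], model: TrainedModel
) -> BackgroundScoreDistribution:
    """Score every valid position of every control sequence.

    Both strands are pooled into the strand-summed per-position score, so the
    distribution holds exactly one score per (sequence, position) pair.
    """
    if not control:
        raise PredictionError("control set must be non-empty")
    parts = [_position_scores(x, model.fg)[0] for x in control]
    return BackgroundScoreDistribution(np.concatenate(parts))


def empirical_pvalue(score: float, bg: BackgroundScoreDistribution) -> float:
    """Fraction of background scores strictly greater than ``score``."""
    if len(bg) == 0:
        raise PredictionError("background distribution is empty")
    n_greater = len(bg.scores) - np.searchsorted(bg.scores, score, side="right")
    return float(n_greater) / len(bg.scores)


def call_sites(
    data: list[Sequence],
    model: TrainedModel,
    bg: BackgroundScoreDistribution,
    threshold: float = 1e-3,
) -> list[SitePrediction]:
    """Predict all positions with empirical p-value strictly below the
    threshold.

    Each prediction carries the strand of the larger strand-specific
    posterior; the result is sorted by ascending p-value, then sequence id,
    then position.  Thresholds sweep out nested prediction sets.
    """
    if not 0.0 <= threshold <= 1.0:
        raise PredictionError("threshold must be in [0, 1]")
    out: list[SitePrediction] = []
    nbg = len(bg.scores)
    for x in data:
        scores, strands = _position_scores(x, model.fg)
        n_greater = nbg - np.searchsorted(bg.scores, scores, side="right")
        pvals = n_greater / nbg
        for u in np.flatnonzero(pvals < threshold):
            out.append(
                SitePrediction(
                    sequence_id=x.id,
                    start=int(u),
                    start_tss=int(u) + model.tss_offset,
                    strand="-" if strands[u] else "+",
                    score=float(scores[u]),
                    p_value=float(pvals[u]),
                )
            )
    out.sort(key=lambda s: (s.p_value, s.sequence_id, s.start))
    return out


def predictions_to_intervals(
    predictions: list[SitePrediction], width: int
) -> dict[str, list[tuple[int, int]]]:
    """Group predictions into 0-based half-open intervals per sequence id."""
    out: dict[str, list[tuple[int, int]]] = {}
    for p in predictions:
        out.setdefault(p.sequence_id, []).append((p.start, p.start + width))
    return out
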