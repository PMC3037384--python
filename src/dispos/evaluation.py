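"""Assessment machinery: nucleotide-level precision/recall, PR curves,
motif comparison by normalized Euclidean distance, information-content
border trimming, IUPAC consensus scanning, and 2x2 contingency statistics.

Nucleotide recall r_n is the fraction of annotated site nucleotides that are
covered by predictions; nucleotide precision p_n is the fraction of
predicted nucleotides that fall inside annotated sites.  Sweeping the
prediction threshold over a ranked prediction list yields the nucleotide
precision-recall curve.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass

import numpy as np
from scipy.stats import fisher_exact as _scipy_fisher
from scipy.stats import norm

from .model import PWM
from .seqdata import Sequence, reverse_complement

logger = logging.getLogger(__name__)

Intervals = dict[str, list[tuple[int, int]]]

IUPAC_CODES = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


class EvaluationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# nucleotide-level precision / recall


def _covered(intervals: list[tuple[int, int]]) -> set[int]:
    out: set[int] = set()
    for start, end in intervals:
        if end <= start:
            raise EvaluationError(f"empty or inverted interval ({start}, {end})")
        out.update(range(start, end))
    return out


def nucleotide_pr(predicted: Intervals, truth: Intervals) -> tuple[float, float]:
    """(recall, precision) on the nucleotide level.

    When nothing is predicted, precision is reported as 1 by convention
    (and logged); recall is undefined for empty truth and raises.
    """
    truth_nt = {(sid, p) for sid, ivs in truth.items() for p in _covered(ivs)}
    if not truth_nt:
        raise EvaluationError("truth annotation is empty; recall undefined")
    pred_nt = {(sid, p) for sid, ivs in predicted.items() for p in _covered(ivs)}
    tp = len(pred_nt & truth_nt)
    rn = tp / len(truth_nt)
    if not pred_nt:
        logger.debug("no nucleotides predicted; reporting precision = 1")
        return rn, 1.0
    return rn, tp / len(pred_nt)


@dataclass(frozen=True)
class PRPoint:
    threshold: float
    recall: float
    precision: float


def pr_curve(
    ranked: list[tuple[str, int, int, float]],
    truth: Intervals,
) -> list[PRPoint]:
    """Precision-recall curve over prefixes of a ranked prediction list.

    ``ranked`` holds (sequence_id, start, end, rank_score) tuples ordered
    best-first (for p-value ranking, ascending p-value); one point is
    emitted per distinct rank score, computed on the prefix up to and
    including all predictions at that score.
    """
    truth_nt = {(sid, p) for sid, ivs in truth.items() for p in _covered(ivs)}
    if not truth_nt:
        raise EvaluationError("truth annotation is empty; recall undefined")
    points: list[PRPoint] = []
    pred_nt: set[tuple[str, int]] = set()
    tp = 0
    i = 0
    n = len(ranked)
    while i < n:
        score = ranked[i][3]
        while i < n and ranked[i][3] == score:
            sid, start, end, _ = ranked[i]
            for p in range(start, end):
                if (sid, p) not in pred_nt:
                    pred_nt.add((sid, p))
                    if (sid, p) in truth_nt:
                        tp += 1
            i += 1
        points.append(
            PRPoint(
                threshold=score,
                recall=tp / len(truth_nt),
                precision=tp / len(pred_nt) if pred_nt else 1.0,
            )
        )
    return points


def precision_at_recall(points: list[PRPoint], recall: float) -> float:
    """Precision at the first curve point reaching the given recall
    (0 if the curve never gets there)."""
    for pt in points:
        if pt.recall >= recall:
            return pt.precision
    return 0.0


# ---------------------------------------------------------------------------
# motif-level comparison


def information_content(column: np.ndarray) -> float:
    """Information content of one PWM column in bits: 2 + sum p log2 p."""
    p = np.asarray(column, dtype=float)
    if abs(p.sum() - 1.0) > 1e-6 or (p < 0).any():
        raise EvaluationError("column is not a probability vector")
    nz = p[p > 0]
    return float(2.0 + np.sum(nz * np.log2(nz)))


def trim_low_ic_borders(pwm: PWM, ic_threshold: float = 0.25) -> PWM:
    """Strip border columns with information content below the threshold.

    Trimming is iterative from both ends and never removes interior columns;
    if every column is below the threshold an error is raised.
    """
    ics = [information_content(col) for col in pwm.probs]
    lo, hi = 0, pwm.width
    while lo < hi and ics[lo] < ic_threshold:
        lo += 1
    while hi > lo and ics[hi - 1] < ic_threshold:
        hi -= 1
    if lo == hi:
        raise EvaluationError("all columns fall below the IC threshold")
    return PWM(pwm.probs[lo:hi].copy())


def normalized_euclidean_distance(
    pwm_a: PWM,
    pwm_b: PWM,
    allow_rc: bool = True,
    min_overlap: int | None = None,
) -> float:
    """Alignment-minimized column distance between two PWMs, in [0, 1].

    For every relative offset with at least ``min_overlap`` aligned columns
    (default min(w_a, w_b, 5)) — and optionally for the reverse complement
    of ``pwm_b`` — the mean over aligned columns of the Euclidean distance
    between the column vectors divided by sqrt(2) is computed; the minimum
    over offsets and orientations is returned.
    """
    if min_overlap is None:
        min_overlap = min(pwm_a.width, pwm_b.width, 5)
    if min_overlap < 1 or min(pwm_a.width, pwm_b.width) < min_overlap:
        raise EvaluationError("no admissible alignment offset")
    candidates = [pwm_b.probs]
    if allow_rc:
        candidates.append(pwm_b.reverse_complement().probs)
    a = pwm_a.probs
    best = np.inf
    for b in candidates:
        wa, wb = len(a), len(b)
        for off in range(-(wb - min_overlap), wa - min_overlap + 1):
            ja = slice(max(0, off), min(wa, off + wb))
            jb = slice(max(0, -off), min(wb, wa - off))
            seg_a, seg_b = a[ja], b[jb]
            if len(seg_a) < min_overlap:
                continue
            d = np.linalg.norm(seg_a - seg_b, axis=1) / math.sqrt(2.0)
            best = min(best, float(d.mean()))
    return best


def aligned_column_tv(
    pwm_a: PWM,
    pwm_b: PWM,
    allow_rc: bool = True,
    min_overlap: int | None = None,
) -> np.ndarray:
    """Per-column total-variation distances at the best alignment.

    The alignment (offset and orientation) minimizing the normalized
    Euclidean distance is selected; for each aligned column pair the total
    variation 0.5 * sum |a - b| is returned.
    """
    if min_overlap is None:
        min_overlap = min(pwm_a.width, pwm_b.width, 5)
    if min_overlap < 1 or min(pwm_a.width, pwm_b.width) < min_overlap:
        raise EvaluationError("no admissible alignment offset")
    candidates = [pwm_b.probs]
    if allow_rc:
        candidates.append(pwm_b.reverse_complement().probs)
    a = pwm_a.probs
    best_d, best_tv = np.inf, None
    for b in candidates:
        wa, wb = len(a), len(b)
        for off in range(-(wb - min_overlap), wa - min_overlap + 1):
            ja = slice(max(0, off), min(wa, off + wb))
            jb = slice(max(0, -off), min(wb, wa - off))
            seg_a, seg_b = a[ja], b[jb]
            if len(seg_a) < min_overlap:
                continue
            d = float(
                (np.linalg.norm(seg_a - seg_b, axis=1) / math.sqrt(2.0)).mean()
            )
            if d < best_d:
                best_d = d
                best_tv = 0.5 * np.abs(seg_a - seg_b).sum(axis=1)
    assert best_tv is not None
    return best_tv


# ---------------------------------------------------------------------------
# consensus scanning


def iupac_regex(pattern: str) -> re.Pattern[str]:
    parts = []
    for c in pattern.upper():
        if c not in IUPAC_CODES:
            raise EvaluationError(f"invalid IUPAC letter {c!r}")
        letters = IUPAC_CODES[c]
        parts.append(letters if len(letters) == 1 else f"[{letters}]")
    return re.compile("".join(parts))


@dataclass
class ScanResult:
    """Per-sequence consensus matches: (internal start, strand) pairs."""

    sequence_id: str
    matches: list[tuple[int, str]]

    @property
    def matched(self) -> bool:
        return bool(self.matches)


def scan_consensus(
    seqs: list[Sequence],
    pattern: str,
    window: tuple[int, int] | None = None,
    both_strands: bool = True,
    tss_offset: int = -500,
) -> list[ScanResult]:
    """Scan for an IUPAC consensus inside a TSS-relative window.

    ``window`` is a closed TSS-relative interval such as (-250, -1); the
    whole match footprint must lie inside it, on the forward strand or (if
    ``both_strands``) on the reverse strand.  Matches are reported as
    internal forward-strand start positions.
    """
    rx = iupac_regex(pattern)
    m = len(pattern)
    out: list[ScanResult] = []
    for s in seqs:
        L = len(s)
        if window is None:
            lo, hi = 0, L
        else:
            lo, hi = window[0] - tss_offset, window[1] - tss_offset + 1
            if lo < 0 or hi > L or lo >= hi:
                raise EvaluationError(
                    f"window {window} outside sequence span of {s.id!r}"
                )
        region = s.residues[lo:hi]
        matches = [(lo + mt.start(), "+") for mt in rx.finditer(region)]
        if both_strands:
            rc = reverse_complement(region)
            n = len(region)
            for mt in rx.finditer(rc):
                fwd_start = lo + n - mt.start() - m
                matches.append((fwd_start, "-"))
        matches.sort()
        out.append(ScanResult(sequence_id=s.id, matches=matches))
    return out


# ---------------------------------------------------------------------------
# 2x2 contingency statistics


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts of (fg match, fg no-match, bg match, bg no-match)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise EvaluationError("contingency counts must be non-negative")
        if self.a + self.b < 1 or self.c + self.d < 1:
            raise EvaluationError("each class needs at least one observation")


def contingency_stats(t: ContingencyTable2x2) -> dict[str, float]:
    """Sensitivity, false positive rate, precision and F measure.

    Sn = a/(a+b), FPR = c/(c+d), precision = a/(a+c) (0 when nothing
    matches), F = harmonic mean of precision and Sn (0 when both are 0).
    """
    sn = t.a / (t.a + t.b)
    fpr = t.c / (t.c + t.d)
    precision = t.a / (t.a + t.c) if t.a + t.c > 0 else 0.0
    f = (
        2.0 * precision * sn / (precision + sn)
        if precision + sn > 0
        else 0.0
    )
    return {"Sn": sn, "FPR": fpr, "precision": precision, "F": f}


def fisher_exact_onesided(t: ContingencyTable2x2) -> float:
    """One-sided Fisher's exact test for enrichment of matches in the
    foreground (hypergeometric upper tail)."""
    _, p = _scipy_fisher([[t.a, t.b], [t.c, t.d]], alternative="greater")
    return float(p)


def binomial_proportion_test_onesided(
    k1: int, n1: int, k2: int, n2: int, direction: str = "greater"
) -> float:
    """Two-proportion z-test with pooled variance, one-sided.

    Tests H1: p1 > p2 (``direction='greater'``) or p1 < p2
    (``direction='less'``).  A degenerate pooled proportion (0 or 1) gives
    p = 1, logged.
    """
    if direction not in ("greater", "less"):
        raise EvaluationError("direction must be 'greater' or 'less'")
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2) or n1 < 1 or n2 < 1:
        raise EvaluationError("counts out of range")
    p1, p2 = k1 / n1, k2 / n2
    pooled = (k1 + k2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        logger.debug("degenerate pooled proportion %g; returning p = 1", pooled)
        return 1.0
    se = math.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
    z = (p1 - p2) / se
    return float(norm.sf(z) if direction == "greater" else norm.cdf(z))


def read_pwm_table(path: str) -> PWM:
    """Read a tab-separated 4-column PWM; count matrices are normalized."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", ">", "//")):
                continue
            fields = line.split()
            # TRANSFAC-like rows carry a leading position label (01, 02, ...)
            # and may append a consensus letter; keep the 4 numeric columns
            if fields and not _is_number(fields[0]):
                fields = fields[1:]
            elif len(fields) >= 5 and _is_integer(fields[0]):
                fields = fields[1:]
            if len(fields) < 4:
                continue
            rows.append([float(v) for v in fields[:4]])
    if not rows:
        raise EvaluationError(f"no matrix rows found in {path}")
    mat = np.asarray(rows, dtype=float)
    if (mat < 0).any():
        raise EvaluationError("matrix entries must be non-negative")
    return PWM(mat / mat.sum(axis=1, keepdims=True))


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def _is_integer(tok: str) -> bool:
    try:
        int(tok)
        return True
    except ValueError:
        return False
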