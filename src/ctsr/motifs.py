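"""PWM log-odds scoring with an exact null distribution.

Position probability matrices are turned into integer log-odds matrices
(milli-bit resolution) so the exact distribution of scores of random
background words can be computed by per-position convolution. A scan
threshold is the smallest score whose null tail probability is ≤ alpha,
mirroring FIMO-style p-value filtering; promoters are scanned on both
strands and every window at or above the threshold is reported.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .types import MotifHit, PWM
from .promoters import reverse_complement

log = logging.getLogger("ctsr")

SCALE = 1000  # integer score units per bit
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class ScoringMatrix:
    """Integer-scaled log-odds matrix for one PWM."""

    motif_id: str
    tf_name: str
    int_matrix: np.ndarray  # w x 4, units of 1/SCALE bits
    background: tuple[float, float, float, float]
    scale: int = SCALE

    @property
    def width(self) -> int:
        return self.int_matrix.shape[0]

    def bits(self) -> np.ndarray:
        return self.int_matrix / self.scale


@dataclass
class ScoreNull:
    """Exact background distribution of integer window scores."""

    min_score: int
    pmf: np.ndarray  # probability of score min_score + i

    def sf(self, score: int) -> float:
        """P(window score >= score) under the background."""
        i = score - self.min_score
        if i <= 0:
            return 1.0
        if i >= self.pmf.size:
            return 0.0
        return float(self.pmf[i:].sum())

    def threshold(self, alpha: float) -> int:
        """Smallest integer score s with P(score >= s) <= alpha."""
        tail = np.cumsum(self.pmf[::-1])[::-1]
        ok = np.flatnonzero(tail <= alpha)
        if ok.size == 0:
            log.warning(
                "alpha=%g below the minimum achievable tail %g; using max score",
                alpha, float(tail[-1]),
            )
            return self.min_score + self.pmf.size - 1
        return self.min_score + int(ok[0])


def pwm_log_odds(
    pwm: PWM,
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25),
    pseudocount: float = 1e-4,
) -> ScoringMatrix:
    """Integer-scaled log2 odds of the PWM against the background.

    score(i, b) = log2((p_ib + pseudocount·bg_b) / ((1 + pseudocount)·bg_b)),
    rounded to 1/SCALE bit.
    """
    bg = np.asarray(background, dtype=float)
    if bg.shape != (4,) or np.any(bg <= 0) or abs(bg.sum() - 1) > 1e-6:
        raise ValueError("background must be 4 positive probabilities summing to 1")
    adjusted = (pwm.matrix + pseudocount * bg[None, :]) / (1.0 + pseudocount)
    bits = np.log2(adjusted / bg[None, :])
    return ScoringMatrix(
        pwm.motif_id, pwm.tf_name,
        np.round(bits * SCALE).astype(np.int64),
        tuple(bg),
    )


def score_distribution(sm: ScoringMatrix) -> ScoreNull:
    """Exact null pmf of window scores via per-position convolution."""
    bg = np.asarray(sm.background)
    pmf = np.array([1.0])
    offset = 0
    for i in range(sm.width):
        row = sm.int_matrix[i]
        lo, hi = int(row.min()), int(row.max())
        new = np.zeros(pmf.size + (hi - lo), dtype=float)
        for b in range(4):
            shift = int(row[b]) - lo
            new[shift:shift + pmf.size] += pmf * bg[b]
        pmf = new
        offset += lo
    return ScoreNull(offset, pmf)


def score_pvalue_threshold(
    sm: ScoringMatrix,
    alpha: float = 1e-4,
    null: ScoreNull | None = None,
) -> tuple[int, ScoreNull]:
    """Scan threshold (integer score) at tail probability alpha, plus the null."""
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    null = null or score_distribution(sm)
    return null.threshold(alpha), null


def _encode(sequence: str) -> np.ndarray:
    return np.array([_BASE_INDEX.get(b, -1) for b in sequence.upper()], dtype=np.int64)


def _window_scores(idx: np.ndarray, sm: ScoringMatrix) -> np.ndarray:
    """Integer score per window start; windows containing N get -inf."""
    w = sm.width
    n_win = idx.size - w + 1
    if n_win <= 0:
        return np.empty(0, dtype=float)
    bad = (idx < 0).astype(np.int64)
    bad_cum = np.concatenate(([0], np.cumsum(bad)))
    has_n = (bad_cum[w:] - bad_cum[:-w]) > 0
    safe = np.where(idx < 0, 0, idx)
    total = np.zeros(n_win, dtype=np.int64)
    for j in range(w):
        total += sm.int_matrix[j, safe[j:j + n_win]]
    scores = total.astype(float)
    scores[has_n] = -np.inf
    return scores


def scan_promoter(
    sequence: str,
    sm: ScoringMatrix,
    threshold: int,
    null: ScoreNull | None = None,
    gene_id: str = "",
) -> list[MotifHit]:
    """Report every window on either strand scoring >= threshold.

    Reverse-strand matches are reported at the forward-sequence offset of
    the window they cover. Windows containing non-ACGT bases are skipped.
    """
    w = sm.width
    L = len(sequence)
    if L < w:
        return []
    hits: list[MotifHit] = []
    fwd = _window_scores(_encode(sequence), sm)
    rev = _window_scores(_encode(reverse_complement(sequence)), sm)
    for off in np.flatnonzero(fwd >= threshold):
        s = int(fwd[off])
        hits.append(MotifHit(
            gene_id, sm.motif_id, int(off), "+", s / sm.scale,
            null.sf(s) if null else 1.0,
        ))
    for off_rc in np.flatnonzero(rev >= threshold):
        s = int(rev[off_rc])
        hits.append(MotifHit(
            gene_id, sm.motif_id, int(L - w - off_rc), "-", s / sm.scale,
            null.sf(s) if null else 1.0,
        ))
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits
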