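"""Alignment and statistical comparison of predicted vs experimental PWMs.

Columns are compared with an information-content-weighted Pearson
correlation: ``score(n, m) = PCC(n, m) * IC(m) / 2`` where ``m`` is the
experimental column.  The IC weight down-weights uninformative
experimental columns; a column with IC < 0.5 bits can never reach a score
of 0.25, the threshold used to call a column correctly predicted.

Matrices are compared by ungapped local alignment: over both orientations
of the experimental matrix (reverse complement included), all offsets and
all contiguous windows of at least ``min_overlap`` columns, the window
with the maximum summed column score wins.  Significance is assessed
against randomized matrices assembled by sampling columns (with
replacement) from a background pool -- in practice, columns drawn from a
motif database for the matching organism -- giving an empirical p-value
with the (k+1)/(n+1) estimator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .motif_io import PWM, information_content, trim_pwm

_EPS = 1e-12


@dataclass
class AlignmentResult:
    """Best ungapped local alignment of a predicted and experimental PWM.

    ``offset`` is the position of the predicted matrix's first column
    relative to the experimental matrix's first column, in the coordinates
    of the *oriented* experimental matrix (forward, or its reverse
    complement when ``orientation == 'revcomp'``).  ``pred_span`` and
    ``exp_span`` are half-open column intervals of equal length.
    """

    offset: int
    orientation: str
    pred_span: Tuple[int, int]
    exp_span: Tuple[int, int]
    column_scores: List[float]
    total_score: float
    pred_ncols: int = 0
    exp_ncols: int = 0

    @property
    def span_length(self) -> int:
        return self.pred_span[1] - self.pred_span[0]


@dataclass
class NullModel:
    """Background column pool and sampling settings for empirical p-values."""

    background_columns: np.ndarray
    n_random: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        cols = np.asarray(self.background_columns, dtype=float)
        if cols.ndim != 2 or cols.shape[1] != 4 or cols.shape[0] == 0:
            raise ValueError("background pool must be a non-empty (n, 4) array")
        if np.any(cols < 0) or np.any(np.abs(cols.sum(axis=1) - 1.0) > 1e-6):
            raise ValueError("background pool columns must be probability vectors")
        if self.n_random < 1:
            raise ValueError("n_random must be at least 1")
        self.background_columns = cols


def column_score(pred_col: Sequence[float], exp_col: Sequence[float]) -> float:
    """IC-weighted Pearson correlation of two PWM columns, in [-1, 1].

    The Pearson correlation treats the four probabilities as paired
    observations; a zero-variance (uniform) column has no preference and
    its correlation is defined as 0.  The product with IC(exp)/2 bounds
    the score by IC(exp)/2, so low-IC experimental columns score low no
    matter how well they are matched.
    """
    p = np.asarray(pred_col, dtype=float)
    e = np.asarray(exp_col, dtype=float)
    ic = information_content(e)  # validates e
    information_content(p)  # validates p
    a = p - p.mean()
    b = e - e.mean()
    na, nb = np.sqrt(a @ a), np.sqrt(b @ b)
    if na < _EPS or nb < _EPS:
        return 0.0
    return float((a @ b) / (na * nb) * ic / 2.0)


def _score_matrix(pred: np.ndarray, exp: np.ndarray) -> np.ndarray:
    """(P, E) matrix of column scores between two probability matrices."""
    a = pred - pred.mean(axis=1, keepdims=True)
    b = exp - exp.mean(axis=1, keepdims=True)
    na = np.linalg.norm(a, axis=1)
    nb = np.linalg.norm(b, axis=1)
    denom = np.outer(na, nb)
    with np.errstate(invalid="ignore", divide="ignore"):
        pcc = np.where(denom < _EPS, 0.0, (a @ b.T) / np.where(denom < _EPS, 1.0, denom))
    ic = np.array([information_content(c) for c in exp])
    return pcc * (ic / 2.0)[None, :]


def _revcomp_matrix(m: np.ndarray) -> np.ndarray:
    return m[::-1, ::-1]


def align_pwms(pred: PWM, exp: PWM, min_overlap: int = 3) -> AlignmentResult:
    """Maximum-scoring ungapped local alignment of two PWMs.

    Both orientations of the experimental matrix are considered.  Ties are
    broken toward the shorter span (the tightest window achieving the
    maximum), then the forward orientation, then the smaller offset, then
    the smaller window start.
    """
    P, E = len(pred), len(exp)
    if P == 0 or E == 0:
        raise ValueError("cannot align an empty PWM")
    if min_overlap < 1:
        raise ValueError("min_overlap must be at least 1")
    if min(P, E) < min_overlap:
        raise ValueError(
            f"matrices of {P} and {E} columns cannot overlap by {min_overlap}"
        )
    best = None
    best_key = None
    for orientation, exp_m in (("forward", exp.matrix),
                               ("revcomp", _revcomp_matrix(exp.matrix))):
        S = _score_matrix(pred.matrix, exp_m)
        is_fwd = 1 if orientation == "forward" else 0
        for d in range(-(P - min_overlap), E - min_overlap + 1):
            i0 = max(0, -d)
            i1 = min(P, E - d)
            L = i1 - i0
            if L < min_overlap:
                continue
            ii = np.arange(i0, i1)
            diag = S[ii, ii + d]
            csum = np.concatenate([[0.0], np.cumsum(diag)])
            for length in range(min_overlap, L + 1):
                for s in range(0, L - length + 1):
                    total = csum[s + length] - csum[s]
                    key = (total, -length, is_fwd, -d, -(i0 + s))
                    if best_key is None or key > best_key:
                        best_key = key
                        ps = i0 + s
                        best = AlignmentResult(
                            offset=d, orientation=orientation,
                            pred_span=(ps, ps + length),
                            exp_span=(ps + d, ps + d + length),
                            column_scores=[float(v) for v in diag[s:s + length]],
                            total_score=float(total),
                            pred_ncols=P, exp_ncols=E,
                        )
    assert best is not None
    return best


def _max_window_scores(S3: np.ndarray, min_overlap: int) -> np.ndarray:
    """Best local-alignment total for each of a batch of score matrices.

    ``S3`` has shape (n, P, E); returns the (n,) maxima over all offsets
    and windows of length >= min_overlap (one orientation; call twice and
    take the elementwise max for both orientations).
    """
    n, P, E = S3.shape
    out = np.full(n, -np.inf)
    for d in range(-(P - min_overlap), E - min_overlap + 1):
        i0 = max(0, -d)
        i1 = min(P, E - d)
        L = i1 - i0
        if L < min_overlap:
            continue
        ii = np.arange(i0, i1)
        diag = S3[:, ii, ii + d]  # (n, L)
        csum = np.concatenate([np.zeros((n, 1)), np.cumsum(diag, axis=1)], axis=1)
        for length in range(min_overlap, L + 1):
            sums = csum[:, length:] - csum[:, :L - length + 1]
            np.maximum(out, sums.max(axis=1), out=out)
    return out


def empirical_pvalue(pred: PWM, exp: PWM, null: NullModel,
                     min_overlap: int = 3,
                     observed: Optional[float] = None) -> float:
    """Empirical p-value of the observed alignment score.

    ``n_random`` null matrices with the same column count as ``exp`` are
    assembled by sampling columns uniformly with replacement from the
    background pool, aligned to ``pred`` with the same procedure, and the
    p-value is ``(1 + #{null >= observed}) / (n_random + 1)`` -- never
    exactly zero, and conservative on ties.
    """
    if observed is None:
        observed = align_pwms(pred, exp, min_overlap=min_overlap).total_score
    E = len(exp)
    P = len(pred)
    if min(P, E) < min_overlap:
        raise ValueError("alignment not feasible at this min_overlap")
    rng = np.random.default_rng(null.seed)
    pool = null.background_columns
    idx = rng.integers(0, len(pool), size=(null.n_random, E))
    S_pool = _score_matrix(pred.matrix, pool)          # (P, n_pool)
    S_pool_c = _score_matrix(pred.matrix, pool[:, ::-1])  # vs complemented cols
    S3_f = np.transpose(S_pool[:, idx], (1, 0, 2))     # (n, P, E)
    S3_r = np.transpose(S_pool_c[:, idx[:, ::-1]], (1, 0, 2))
    null_best = np.maximum(_max_window_scores(S3_f, min_overlap),
                           _max_window_scores(S3_r, min_overlap))
    k = int(np.sum(null_best >= observed - _EPS))
    return (1 + k) / (null.n_random + 1)


def fraction_correct_columns(result: AlignmentResult,
                             threshold: float = 0.25) -> float:
    """Fraction of experimental columns whose aligned score reaches the bar.

    The denominator is the full (trimmed) experimental column count, so
    experimental columns outside the aligned window count as incorrect.
    """
    if result.exp_ncols <= 0:
        raise ValueError("alignment result lacks the experimental column count")
    n_correct = sum(1 for s in result.column_scores if s >= threshold)
    return n_correct / result.exp_ncols


def classify_column_composition(col: Sequence[float]) -> str:
    """'CG_rich' if C+G > 0.75, 'AT_rich' if A+T > 0.75, else 'mixed'."""
    p = np.asarray(col, dtype=float)
    information_content(p)  # validates
    cg = p[1] + p[2]
    if cg > 0.75:
        return "CG_rich"
    if (p[0] + p[3]) > 0.75:
        return "AT_rich"
    return "mixed"


def protein_correct(predicted_arrays: Sequence[PWM],
                    experimental: Sequence[PWM],
                    null: NullModel,
                    alpha_level: float = 0.05,
                    min_overlap: int = 3,
                    trim_threshold: float = 0.5,
                    ) -> Tuple[bool, Tuple[Optional[PWM], Optional[PWM], float]]:
    """Protein-level call: does any array match any experimental PWM?

    Experimental PWMs are IC-trimmed first.  The protein is called
    correctly predicted iff the minimum empirical p-value over all
    (array, experimental PWM) pairs is at most ``alpha_level``; the
    minimizing pair is returned alongside.
    """
    if not predicted_arrays or not experimental:
        raise ValueError("need at least one predicted array and one experimental PWM")
    trimmed = []
    for e in experimental:
        t = trim_pwm(e, trim_threshold)
        if len(t) == 0:
            warnings.warn(f"experimental PWM {e.name!r} is empty after trimming; "
                          "excluded from alignment")
            continue
        if len(t) < min_overlap:
            warnings.warn(f"experimental PWM {e.name!r} shorter than min_overlap "
                          "after trimming; excluded from alignment")
            continue
        trimmed.append(t)
    if not trimmed:
        raise ValueError("all experimental PWMs are empty after trimming")
    best_p = np.inf
    best_pair: Tuple[Optional[PWM], Optional[PWM], float] = (None, None, np.inf)
    for arr in predicted_arrays:
        for e in trimmed:
            p = empirical_pvalue(arr, e, null, min_overlap=min_overlap)
            if p < best_p:
                best_p = p
                best_pair = (arr, e, p)
    return best_p <= alpha_level, best_pair
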