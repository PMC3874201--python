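"""From interface scores to PWMs: Boltzmann conversion and array merging.

Each finger's 256 possible 4-bp subsites are treated as the states of a
statistical-mechanical system.  With the scorer's output y_i taken as
negatively proportional to the binding energy of state i, the occupancy of
state i is

    P_i = bg(i) * exp(lambda * y_i) / Z,

where lambda converts scores into units of kT (default 4), bg(i) is the
product of background nucleotide probabilities over the site (uniform by
default) and Z normalizes.  Per-position nucleotide probabilities are the
marginals of this 256-state distribution; for linear scorers the score is
additive over base positions, so the marginals factorize and can be
computed per position without enumerating states.

Fingers arrayed on DNA bind overlapping subsites: the 3' base of one
finger's subsite is the 5' base of the next (N-adjacent) finger's subsite.
The junction column is a weighted geometric mean of the two per-finger
predictions, weight ``alpha`` (default 0.75) on the N-adjacent finger's
b1 column -- its a6 contact sits closer to the primary DNA strand.  An
n-finger array therefore yields a PWM of 3n+1 columns, with the
C-terminal finger's subsite 5'-most (fingers run antiparallel to the
primary strand, the standard Zif268 geometry).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np

from .domains import ZFArray
from .encoding import ALL_SITES, BASES
from .motif_io import PWM
from .scoring import Scorer, ScoringModel, site_scores_of

_DEGENERATE_MASS = 1e-12


class DegenerateJunctionWarning(UserWarning):
    """Two junction columns share no support; a uniform column was emitted."""


@dataclass
class BoltzmannParams:
    """Score-to-probability conversion parameters.

    ``lam`` converts scores into units of kT (default 4; larger
    values sharpen the PWM).  ``background`` is the a-priori nucleotide
    distribution (A, C, G, T), uniform by default.
    """

    lam: float = 4.0
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("lambda must be positive")
        self.background = np.asarray(self.background, dtype=float)
        if self.background.shape != (4,) or np.any(self.background < 0) \
                or abs(self.background.sum() - 1.0) > 1e-9:
            raise ValueError("background must be a probability 4-vector")


@dataclass
class SiteDistribution:
    """Boltzmann occupancy over the 256 4-bp states (ALL_SITES order)."""

    probs: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (256,):
            raise ValueError("need one probability per 4-mer state")
        if abs(self.probs.sum() - 1.0) > 1e-9 or np.any(self.probs < 0):
            raise ValueError("state probabilities must form a distribution")

    def as_dict(self) -> Dict[str, float]:
        return dict(zip(ALL_SITES, self.probs))

    def __getitem__(self, site: str) -> float:
        return float(self.probs[ALL_SITES.index(site.upper())])


_BASE_AT = np.array([[BASES.index(s[pos]) for s in ALL_SITES] for pos in range(4)])


def site_probabilities(scorer: Scorer, finger,
                       params: Optional[BoltzmannParams] = None) -> SiteDistribution:
    """Boltzmann occupancy of every 4-bp site for one finger.

    ``P_i = bg(i) exp(lambda y_i) / Z``; weights are computed after
    subtracting the maximum exponent, so large scores cannot overflow.
    """
    params = params or BoltzmannParams()
    y = site_scores_of(scorer, finger)
    with np.errstate(divide="ignore"):
        log_bg = np.log(params.background)  # -inf for zero-probability bases
    logw = params.lam * y + sum(log_bg[_BASE_AT[pos]] for pos in range(4))
    logw -= logw.max()
    w = np.exp(logw)
    return SiteDistribution(w / w.sum())


def finger_pwm(scorer: Scorer, finger,
               params: Optional[BoltzmannParams] = None) -> PWM:
    """4-column PWM of one finger's subsite (b1..b4, 5'->3').

    Column ``pos`` is the marginal of the Boltzmann site distribution at
    that base position.  Linear scorers use the factorized per-position
    form, which is exactly equivalent to the 256-state marginalization;
    any other scorer is marginalized by full enumeration.
    """
    params = params or BoltzmannParams()
    if isinstance(scorer, ScoringModel) and scorer.is_linear:
        e = scorer.position_energies(finger)  # (pos, base)
        logw = params.lam * e
        with np.errstate(divide="ignore"):
            logw = logw + np.log(params.background)[None, :]
        logw -= logw.max(axis=1, keepdims=True)
        w = np.exp(logw)
        matrix = w / w.sum(axis=1, keepdims=True)
    else:
        dist = site_probabilities(scorer, finger, params)
        matrix = np.zeros((4, 4))
        for pos in range(4):
            for bi in range(4):
                matrix[pos, bi] = dist.probs[_BASE_AT[pos] == bi].sum()
    name = getattr(finger, "name", "") or "finger"
    return PWM(matrix, name=name, source="predicted")


def merge_junction(p_prev: np.ndarray, p_next: np.ndarray,
                   alpha: float = 0.75) -> np.ndarray:
    """Merge the overlapping junction column of two adjacent fingers.

    ``p ~ p_prev**alpha * p_next**(1 - alpha)``, renormalized; ``p_prev``
    is the b1 column of the N-adjacent (preceding) finger and ``p_next``
    the b4 column of the following finger.  ``alpha = 1`` returns
    ``p_prev`` exactly, ``alpha = 0`` returns ``p_next``, ``alpha = 0.5``
    is the normalized geometric mean.  If the two columns share no
    support, a uniform column is returned with a warning.
    """
    p_prev = np.asarray(p_prev, dtype=float)
    p_next = np.asarray(p_next, dtype=float)
    for p in (p_prev, p_next):
        if p.shape != (4,) or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-6:
            raise ValueError("junction inputs must be probability 4-vectors")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    if alpha == 1.0:
        return p_prev.copy()
    if alpha == 0.0:
        return p_next.copy()
    merged = p_prev ** alpha * p_next ** (1.0 - alpha)
    mass = merged.sum()
    if mass < _DEGENERATE_MASS:
        warnings.warn("junction columns share no support; emitting uniform",
                      DegenerateJunctionWarning)
        return np.full(4, 0.25)
    return merged / mass


def array_pwm(scorer: Scorer, array: ZFArray,
              params: Optional[BoltzmannParams] = None,
              alpha: float = 0.75) -> PWM:
    """Merged PWM for an n-finger array: 3n+1 columns, 5'->3'.

    The C-terminal finger's subsite is 5'-most.  Each junction column is
    ``merge_junction`` of the N-adjacent finger's b1 column (weight
    ``alpha``) with the following finger's b4 column.
    """
    params = params or BoltzmannParams()
    per_finger = [finger_pwm(scorer, f, params).matrix for f in array.fingers]
    n = len(per_finger)
    columns: List[np.ndarray] = []
    degenerate: List[int] = []
    # walk fingers C->N (5'->3' on the site).  The junction column between
    # finger k and its N-adjacent neighbour k-1 is simultaneously finger
    # k's b4 and finger k-1's b1, so each finger after the first emits only
    # its b2 and b3 columns between junctions.
    for k in range(n - 1, -1, -1):
        cur = per_finger[k]
        if k == n - 1:
            columns.extend(cur[:3])  # b1, b2, b3 of the C-terminal finger
        else:
            columns.extend(cur[1:3])  # b2, b3 (b1 was merged into the junction)
        if k > 0:
            prev_b1 = per_finger[k - 1][0]
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always", DegenerateJunctionWarning)
                col = merge_junction(prev_b1, cur[3], alpha)
            if any(issubclass(c.category, DegenerateJunctionWarning) for c in caught):
                degenerate.append(len(columns))
            columns.append(col)
        else:
            columns.append(cur[3])
    name = getattr(array, "name", "") or f"array_{n}f"
    out = PWM(np.vstack(columns), name=name, source="predicted")
    out.degenerate_columns = degenerate
    return out
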