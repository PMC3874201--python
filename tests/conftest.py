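"""Shared fixtures and independent oracles for the test suite."""

import numpy as np
import pytest

import zfpwm as z
from zfpwm import encoding, scoring
from zfpwm.encoding import ALL_SITES, AMINO_ACIDS


def random_pwm(rng, n_cols, alpha=0.5, name="random"):
    """A random PWM with Dirichlet(alpha) columns (low alpha -> sharp)."""
    return z.PWM(rng.dirichlet([alpha] * 4, size=n_cols), name=name)


def random_linear_model(rng, contact_model=None, scale=1.0):
    cm = contact_model or z.CANONICAL
    return scoring.ScoringModel(
        kind=f"linear_{cm.name}", contact_model=cm,
        w=scale * rng.standard_normal(cm.dims), degree=1)


def random_residues(rng):
    return tuple(rng.choice(list(AMINO_ACIDS), size=4))


def brute_force_finger_pwm(model, finger, params=None):
    """Marginalize the Boltzmann site distribution by direct enumeration.

    Independent of the package's prediction path: scores come from
    ``model.score`` one site at a time and the softmax/marginals are
    computed locally.
    """
    from zfpwm.prediction import BoltzmannParams

    params = params or BoltzmannParams()
    y = np.array([model.score(finger, s) for s in ALL_SITES])
    bg = np.array([np.prod([params.background["ACGT".index(b)] for b in s])
                   for s in ALL_SITES])
    w = bg * np.exp(params.lam * (y - y.max()))
    p = w / w.sum()
    out = np.zeros((4, 4))
    for s, pi in zip(ALL_SITES, p):
        for pos, b in enumerate(s):
            out[pos, "ACGT".index(b)] += pi
    return out


def brute_force_align(pred, exp, min_overlap=3):
    """Exhaustive (orientation, offset, window) enumeration oracle.

    Returns the best total score and the winning candidate under the same
    tie-break convention as ``align_pwms`` (shorter span, forward, smaller
    offset, smaller start) — but built by literal enumeration of windows
    with per-column scores from ``column_score``.
    """
    from zfpwm.alignment import column_score

    best_key, best = None, None
    for orientation, exp_m in (("forward", exp.matrix),
                               ("revcomp", exp.matrix[::-1, ::-1])):
        P, E = len(pred.matrix), len(exp_m)
        is_fwd = 1 if orientation == "forward" else 0
        for d in range(-P + 1, E):
            for start in range(P):
                for length in range(min_overlap, P + 1):
                    i, j = start, start + d
                    if i + length > P or j < 0 or j + length > E:
                        continue
                    scores = [column_score(pred.matrix[i + k], exp_m[j + k])
                              for k in range(length)]
                    total = sum(scores)
                    key = (total, -length, is_fwd, -d, -start)
                    if best_key is None or key > best_key:
                        best_key = key
                        best = dict(total=total, orientation=orientation,
                                    offset=d, pred_span=(i, i + length),
                                    scores=scores)
    return best


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture(scope="session")
def planted():
    """A two-finger planted scenario shared across tests (read-only)."""
    from zfpwm.synth import PlantedScenario

    return PlantedScenario(contact_model=z.CANONICAL, seed=3, n_fingers=2)


@pytest.fixture(scope="session")
def trained_planted(planted):
    """Recovered, standardized scorer for the shared scenario."""
    examples = planted.training_set(2000, 2000, margin=0.1)
    model = scoring.train_linear(examples, model=z.CANONICAL, regularization=100.0)
    return planted.standardize(model)
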