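"""Empirical contact-energy scorers for finger-DNA interfaces.

A scorer maps an encoded interface vector x to a real score interpreted as
a negative binding energy.  Linear models carry an explicit weight vector
w (the abc-th entry is the empirical contact energy of amino acid a with
base b at contact c) and score w.x; the degree-2 polynomial model scores
with the homogeneous kernel K(x, z) = (x.z)^2, realised through its exact
explicit quadratic feature map so that the origin constraint (score of the
all-zero vector is exactly 0 -- no intercept) holds by construction.

Models are max-margin fits (soft-margin SVM, hinge loss, no intercept).
The ``auto`` regularization setting uses the classic heuristic
C = 1 / mean(||x||^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import sparse
from sklearn.svm import LinearSVC

from . import encoding
from .encoding import (ALL_SITES, AMINO_ACIDS, BASES, CANONICAL, CONTACT_MODELS,
                       EXPANDED, ContactModel, encode_interface)

MODEL_FORMAT_VERSION = 1
_SQRT2 = np.sqrt(2.0)


@dataclass
class TrainingExample:
    """One labelled (recognition helix, 4-bp site) binding example.

    ``residues`` are the helix residues at positions (-1, 2, 3, 6);
    ``label`` is +1 (binds) or -1 (does not bind).
    """

    residues: Tuple[str, str, str, str]
    site: str
    label: int

    def __post_init__(self) -> None:
        self.residues = tuple(self.residues)
        if len(self.residues) != 4:
            raise ValueError("need the 4 residues at helix positions (-1, 2, 3, 6)")
        if self.label not in (-1, 1):
            raise ValueError(f"label must be +1 or -1, got {self.label}")
        self.site = self.site.upper()
        if len(self.site) != 4 or any(b not in BASES for b in self.site):
            raise ValueError(f"site must be a 4-mer over ACGT, got {self.site!r}")


def _quad_dim(d: int) -> int:
    return d * (d + 1) // 2


def _pair_index(i: int, j: int, d: int) -> int:
    """Triangular index of the unordered pair (i <= j) in d dims."""
    return i * d - i * (i - 1) // 2 + (j - i)


def _quad_features(indices: Sequence[int], d: int) -> Tuple[List[int], List[float]]:
    """Explicit feature map of K(x, z) = (x.z)^2 for a binary sparse x."""
    idx: List[int] = []
    val: List[float] = []
    srt = sorted(indices)
    for a, i in enumerate(srt):
        idx.append(_pair_index(i, i, d))
        val.append(1.0)
        for j in srt[a + 1:]:
            idx.append(_pair_index(i, j, d))
            val.append(_SQRT2)
    return idx, val


@dataclass
class ScoringModel:
    """A trained (or hand-constructed) interface scorer.

    ``kind`` is one of ``linear_canonical``, ``linear_expanded``,
    ``polynomial_canonical`` or ``custom``.  For linear kinds ``w`` has the
    contact model's dimensionality; for the polynomial kind ``w`` lives in
    the quadratic feature space of the canonical encoding.
    """

    kind: str
    contact_model: ContactModel
    w: np.ndarray
    degree: int = 1
    metadata: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        expected = (self.contact_model.dims if self.degree == 1
                    else _quad_dim(self.contact_model.dims))
        if self.w.shape != (expected,):
            raise ValueError(
                f"weight vector has {self.w.shape}, expected ({expected},) "
                f"for {self.kind}"
            )

    @property
    def is_linear(self) -> bool:
        return self.degree == 1

    def score(self, finger, site: str) -> float:
        """Score one interface; exact dot product / kernel expansion."""
        vec = encode_interface(finger, site, self.contact_model)
        if self.degree == 1:
            return float(self.w[list(vec.nonzero_indices)].sum())
        idx, val = _quad_features(vec.nonzero_indices, self.contact_model.dims)
        return float(np.dot(self.w[idx], val))

    def position_energies(self, finger) -> np.ndarray:
        """(4, 4) table e[pos, base] of per-position score contributions.

        Only valid for linear models, where every contact touches exactly
        one base position, so the total score is additive:
        ``score(finger, site) = sum_pos e[pos, site[pos]]``.
        """
        if not self.is_linear:
            raise ValueError("per-position energies exist only for linear models")
        res = encoding._specificity_residues(finger)
        by_pos = dict(zip((-1, 2, 3, 6), res))
        e = np.zeros((4, 4))
        for c, (hpos, bpos) in enumerate(self.contact_model.contacts):
            aa = by_pos[hpos].upper()
            if aa == "X":
                continue
            for bi, b in enumerate(BASES):
                e[bpos - 1, bi] += self.w[encoding.feature_index(aa, b, c,
                                                                 self.contact_model)]
        return e

    def site_scores(self, finger) -> np.ndarray:
        """Scores of all 256 sites in :data:`~zfpwm.encoding.ALL_SITES` order."""
        if self.is_linear:
            e = self.position_energies(finger)
            # lexicographic enumeration factorizes over positions
            return (e[0][:, None, None, None] + e[1][None, :, None, None]
                    + e[2][None, None, :, None] + e[3][None, None, None, :]).ravel()
        return np.array([self.score(finger, s) for s in ALL_SITES])


Scorer = Union[ScoringModel, Callable[[object, str], float]]


def site_scores_of(scorer: Scorer, finger) -> np.ndarray:
    """All-256-site scores for a ScoringModel or a custom (finger, site) callable."""
    if isinstance(scorer, ScoringModel):
        return scorer.site_scores(finger)
    return np.array([float(scorer(finger, s)) for s in ALL_SITES])


# ---------------------------------------------------------------------------
# training


def _design_matrix(examples: Sequence[TrainingExample], model: ContactModel,
                   degree: int) -> Tuple[sparse.csr_matrix, np.ndarray]:
    if not examples:
        raise ValueError("no training examples")
    y = np.array([ex.label for ex in examples], dtype=float)
    if len(set(y)) < 2:
        raise ValueError("training needs at least one example of each label")
    rows: List[int] = []
    cols: List[int] = []
    vals: List[float] = []
    d = model.dims
    for r, ex in enumerate(examples):
        vec = encode_interface(ex.residues, ex.site, model)
        if degree == 1:
            idx, val = list(vec.nonzero_indices), [1.0] * len(vec.nonzero_indices)
        else:
            idx, val = _quad_features(vec.nonzero_indices, d)
        rows.extend([r] * len(idx))
        cols.extend(idx)
        vals.extend(val)
    dim = d if degree == 1 else _quad_dim(d)
    X = sparse.csr_matrix((vals, (rows, cols)), shape=(len(examples), dim))
    return X, y


def _fit(X: sparse.csr_matrix, y: np.ndarray,
         regularization: Union[str, float]) -> Tuple[np.ndarray, float]:
    if regularization == "auto":
        sq_norms = np.asarray(X.multiply(X).sum(axis=1)).ravel()
        C = float(1.0 / sq_norms.mean())
    else:
        C = float(regularization)
        if C <= 0:
            raise ValueError("regularization parameter must be positive")
    clf = LinearSVC(C=C, loss="hinge", fit_intercept=False, dual=True,
                    tol=1e-7, max_iter=500_000, random_state=0)
    clf.fit(X, y)
    return clf.coef_.ravel().copy(), C


def train_linear(examples: Sequence[TrainingExample],
                 model: ContactModel = EXPANDED,
                 regularization: Union[str, float] = "auto") -> ScoringModel:
    """Fit a linear max-margin contact-energy model (no intercept)."""
    X, y = _design_matrix(examples, model, degree=1)
    w, C = _fit(X, y, regularization)
    return ScoringModel(
        kind=f"linear_{model.name}", contact_model=model, w=w, degree=1,
        metadata={"n_train": len(examples), "C": C},
    )


def train_polynomial(examples: Sequence[TrainingExample],
                     degree: int = 2,
                     model: ContactModel = CANONICAL,
                     regularization: Union[str, float] = "auto") -> ScoringModel:
    """Fit the degree-2 homogeneous polynomial-kernel model (no intercept)."""
    if degree != 2:
        raise ValueError("only degree=2 is supported")
    X, y = _design_matrix(examples, model, degree=2)
    w, C = _fit(X, y, regularization)
    return ScoringModel(
        kind=f"polynomial_{model.name}", contact_model=model, w=w, degree=2,
        metadata={"n_train": len(examples), "C": C},
    )


def standardize_scores(model: ScoringModel, fingers: Sequence,
                       target_std: float = 1.0) -> ScoringModel:
    """Rescale the weight vector so site scores have a fixed spread.

    Binary bind/no-bind data identify the *direction* of the weight vector
    but not its scale, while the Boltzmann conversion at fixed lambda is
    scale-sensitive; standardizing the score SD over a calibration sample
    of (finger, site) pairs fixes the energy units.  The score is linear
    in ``w`` for both linear and polynomial kinds, so scaling ``w`` scales
    every score by the same factor.
    """
    scores = np.concatenate([model.site_scores(f) for f in fingers])
    sd = float(scores.std())
    if sd <= 0:
        raise ValueError("cannot standardize a constant scorer")
    out = ScoringModel(kind=model.kind, contact_model=model.contact_model,
                       w=model.w * (target_std / sd), degree=model.degree,
                       metadata=dict(model.metadata))
    out.metadata["score_scale"] = target_std / sd
    return out


# ---------------------------------------------------------------------------
# persistence (versioned key-value text with explicit index layout)


def _layout_string(model: ContactModel) -> str:
    contacts = ",".join(f"({h},{b})" for h, b in model.contacts)
    return (f"contact-major idx=c*80+b*20+a; contacts={contacts}; "
            f"bases={BASES}; aa={AMINO_ACIDS}")


def save_model(model: ScoringModel, path) -> None:
    """Write a scorer as versioned key-value text (nonzero weights only)."""
    lines = [
        "# zfpwm scoring model",
        f"format_version: {MODEL_FORMAT_VERSION}",
        f"kind: {model.kind}",
        f"contact_model: {model.contact_model.name}",
        f"degree: {model.degree}",
        f"index_layout: {_layout_string(model.contact_model)}",
    ]
    for k, v in sorted(model.metadata.items()):
        lines.append(f"meta.{k}: {v}")
    lines.append("weights:")
    nz = np.nonzero(model.w)[0]
    for i in nz:
        lines.append(f"{i} {model.w[i]:.17g}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_model(path) -> ScoringModel:
    """Read a scorer saved by :func:`save_model`; scores round-trip exactly."""
    header: Dict[str, str] = {}
    weights: List[Tuple[int, float]] = []
    in_weights = False
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if line == "weights:":
            in_weights = True
            continue
        if in_weights:
            i, v = line.split()
            weights.append((int(i), float(v)))
        else:
            key, _, val = line.partition(":")
            header[key.strip()] = val.strip()
    version = int(header.get("format_version", "-1"))
    if version != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format version {version}")
    cm = CONTACT_MODELS[header["contact_model"]]
    degree = int(header.get("degree", "1"))
    dim = cm.dims if degree == 1 else _quad_dim(cm.dims)
    w = np.zeros(dim)
    for i, v in weights:
        w[i] = v
    metadata = {k[5:]: v for k, v in header.items() if k.startswith("meta.")}
    return ScoringModel(kind=header["kind"], contact_model=cm, w=w,
                        degree=degree, metadata=metadata)


# ---------------------------------------------------------------------------
# training-example TSV (helix(-1), helix(2), helix(3), helix(6), site, label)


def read_training_tsv(path) -> List[TrainingExample]:
    examples = []
    for line_no, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 6:
            raise ValueError(f"{path}:{line_no}: expected 6 tab-separated fields")
        examples.append(TrainingExample(residues=tuple(parts[:4]),
                                        site=parts[4], label=int(parts[5])))
    return examples


def write_training_tsv(examples: Iterable[TrainingExample], path) -> None:
    lines = ["#helix(-1)\thelix(2)\thelix(3)\thelix(6)\tsite\tlabel"]
    for ex in examples:
        lines.append("\t".join([*ex.residues, ex.site, str(ex.label)]))
    Path(path).write_text("\n".join(lines) + "\n")
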