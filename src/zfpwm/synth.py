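"""Synthetic data generators with the statistical structure the method assumes.

A *planted scenario* fixes a ground-truth contact-energy weight vector w*,
derives "true" per-finger and per-array PWMs from it through the Boltzmann
conversion, and emits (a) labelled finger-site training pairs consistent
with sign(w*.x), (b) noisy "experimental" PWMs -- Dirichlet-resampled
copies of a true motif embedded between low-information flanking columns,
optionally reverse-complemented -- and (c) background column pools for the
alignment null model.  Every generator is reproducible from its seed.

Because bind/no-bind labels identify only the direction of the weight
vector, planted and recovered scorers are standardized to unit score-SD
over a shared calibration sample before PWMs are compared (see
:func:`zfpwm.scoring.standardize_scores`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .domains import ZFArray, ZincFinger
from .encoding import AMINO_ACIDS, BASES, EXPANDED, ContactModel
from .motif_io import PWM, ProteinRecord
from .prediction import BoltzmannParams, array_pwm, finger_pwm
from .scoring import ScoringModel, TrainingExample, standardize_scores

_RESAMPLE_CAP = 1_000_000

#: helix scaffold: C-x2-C-x12-H-x3-H with the 7 helix residues at h-7..h-1
_FINGER_PREFIX = "FQCRICMRNFS"
_FINGER_SUFFIX = "HIRTH"
#: linker filler alphabet free of C and H so detection cannot misfire
_LINKER_ALPHABET = "TGEKPSQARNV"
#: helix alphabet for sequence-level constructs (no C/H, which could create
#: spurious coordinating residues inside the scaffold)
SEQUENCE_SAFE_AMINO_ACIDS = "".join(a for a in AMINO_ACIDS if a not in "CH")


def make_finger(helix: str, offset: int = 0) -> ZincFinger:
    """A ZincFinger with the given 7-residue helix at synthetic coordinates."""
    if len(helix) != 7:
        raise ValueError("helix must have 7 residues (-1, 1..6)")
    return ZincFinger(start=offset, end=offset + 26,
                      cys1=offset + 2, cys2=offset + 5,
                      his1=offset + 18, his2=offset + 22, helix=helix)


def finger_sequence(helix: str) -> str:
    """Embed a 7-residue helix into a canonical C2H2 scaffold."""
    if len(helix) != 7:
        raise ValueError("helix must have 7 residues")
    return _FINGER_PREFIX + helix + _FINGER_SUFFIX


def synthetic_protein(helices: Sequence[str], linker: int = 9,
                      protein_id: str = "synthetic") -> ProteinRecord:
    """A protein with one scaffolded finger per helix and fixed linkers.

    ``linker`` counts the residues between one finger's last His and the
    next finger's first Cys (canonical arrays use 9-12).  Helices
    containing C or H may shift the detected domain boundaries; use
    :data:`SEQUENCE_SAFE_AMINO_ACIDS` for sequence-level constructs.
    """
    if linker < 2:
        raise ValueError("the scaffold needs a linker of at least 2 residues")
    filler_len = linker - 2  # the scaffold contributes 'FQ' before its Cys
    filler = (_LINKER_ALPHABET * (filler_len // len(_LINKER_ALPHABET) + 1))[:filler_len]
    parts = [finger_sequence(h) for h in helices]
    seq = "MA" + filler.join(parts) + "GSGS"
    return ProteinRecord(id=protein_id, sequence=seq)


def random_helix(rng: np.random.Generator,
                 alphabet: str = AMINO_ACIDS) -> str:
    """A uniformly random 7-residue recognition helix."""
    return "".join(rng.choice(list(alphabet), size=7))


def planted_weights(contact_model: ContactModel = EXPANDED,
                    seed: int = 0) -> ScoringModel:
    """A random Gaussian contact-energy vector as a linear ScoringModel."""
    rng = np.random.default_rng(seed)
    w = rng.standard_normal(contact_model.dims)
    return ScoringModel(kind=f"linear_{contact_model.name}",
                        contact_model=contact_model, w=w, degree=1,
                        metadata={"planted": True, "seed": seed})


def _site_probs(cg_bias: float) -> np.ndarray:
    if not -1.0 < cg_bias < 1.0:
        raise ValueError("cg_bias must lie in (-1, 1)")
    return np.array([1 - cg_bias, 1 + cg_bias, 1 + cg_bias, 1 - cg_bias]) / 4.0


def generate_training_set(w_star: ScoringModel, n_pos: int, n_neg: int,
                          margin: float = 0.1, seed: int = 0,
                          cg_bias: float = 0.0) -> List[TrainingExample]:
    """Labelled finger-site pairs consistent with the planted scorer.

    Random (helix, site) pairs are labelled +1 when ``w*.x >= margin`` and
    -1 when ``w*.x <= -margin``; pairs inside the dead zone are rejected
    and resampled.  Class counts are exact.  ``cg_bias > 0`` over-samples
    C/G bases in sites, mirroring the composition bias of literature-derived
    training collections.
    """
    if n_pos < 1 or n_neg < 1:
        raise ValueError("need at least one example of each class")
    if margin < 0:
        raise ValueError("margin must be non-negative")
    rng = np.random.default_rng(seed)
    base_p = _site_probs(cg_bias)
    examples: List[TrainingExample] = []
    need_pos, need_neg = n_pos, n_neg
    aa = list(AMINO_ACIDS)
    bases = list(BASES)
    for _ in range(_RESAMPLE_CAP):
        if need_pos == 0 and need_neg == 0:
            return examples
        residues = tuple(rng.choice(aa, size=4))
        site = "".join(rng.choice(bases, size=4, p=base_p))
        y = w_star.score(residues, site)
        if y >= margin and need_pos > 0:
            examples.append(TrainingExample(residues, site, +1))
            need_pos -= 1
        elif y <= -margin and need_neg > 0:
            examples.append(TrainingExample(residues, site, -1))
            need_neg -= 1
    raise RuntimeError(
        f"could not draw {n_pos}+{n_neg} examples at margin {margin} within "
        f"{_RESAMPLE_CAP} attempts"
    )


def generate_experimental_pwm(true_pwm: PWM,
                              dirichlet_concentration: float = 50.0,
                              n_flank: int = 2,
                              revcomp_prob: float = 0.0,
                              seed: int = 0,
                              flank_concentration: float = 30.0) -> PWM:
    """A noisy 'experimental' copy of a true motif with low-IC flanks.

    Each column is resampled from a Dirichlet centred on the true column
    (``alpha = concentration * p``); ``n_flank`` near-uniform columns
    (Dirichlet centred on uniform at ``flank_concentration``) are appended
    on each side, and the whole matrix is reverse-complemented with
    probability ``revcomp_prob``.
    """
    rng = np.random.default_rng(seed)

    def _dirichlet(center: np.ndarray, conc: float) -> np.ndarray:
        alpha = np.maximum(conc * center, 1e-9)
        g = rng.gamma(alpha)
        return g / g.sum()

    cols = [_dirichlet(c, dirichlet_concentration) for c in true_pwm.matrix]
    uniform = np.full(4, 0.25)
    left = [_dirichlet(uniform, flank_concentration) for _ in range(n_flank)]
    right = [_dirichlet(uniform, flank_concentration) for _ in range(n_flank)]
    matrix = np.vstack(left + cols + right) if (left or right or cols) \
        else np.zeros((0, 4))
    pwm = PWM(matrix, name=f"{true_pwm.name}_exp", source="experimental")
    if rng.random() < revcomp_prob:
        pwm = PWM(pwm.matrix[::-1, ::-1].copy(), name=pwm.name, source="experimental")
    return pwm


def generate_background_columns(n: int, dirichlet_alpha: float = 1.0,
                                seed: int = 0) -> np.ndarray:
    """A pool of ``n`` random probability columns, Dirichlet(alpha) each.

    ``alpha = 1`` (flat Dirichlet) gives columns with mean IC around 0.7
    bits, comparable to the mix of informative and uninformative columns
    in curated motif databases.
    """
    if n < 1:
        raise ValueError("need at least one background column")
    rng = np.random.default_rng(seed)
    return rng.dirichlet([dirichlet_alpha] * 4, size=n)


@dataclass
class PlantedScenario:
    """Ground truth + generators for end-to-end tests of the pipeline.

    The planted weight vector is standardized to unit score-SD over the
    scenario's calibration fingers, so margins and lambda act on a fixed
    scale.  ``true_*_pwm`` use the planted scorer; a recovered scorer
    should be passed through :meth:`standardize` before comparison.
    """

    contact_model: ContactModel = EXPANDED
    seed: int = 0
    n_fingers: int = 2
    linker: int = 9
    n_calibration_fingers: int = 50
    params: BoltzmannParams = field(default_factory=BoltzmannParams)

    def __post_init__(self) -> None:
        rng = np.random.default_rng(self.seed)
        raw = planted_weights(self.contact_model, seed=int(rng.integers(2**31)))
        self.helices = [random_helix(rng, SEQUENCE_SAFE_AMINO_ACIDS)
                        for _ in range(self.n_fingers)]
        self.calibration_fingers = [tuple(rng.choice(list(AMINO_ACIDS), size=4))
                                    for _ in range(self.n_calibration_fingers)]
        self.w_true = standardize_scores(raw, self.calibration_fingers)

    @property
    def fingers(self) -> List[ZincFinger]:
        return [make_finger(h, offset=40 * i) for i, h in enumerate(self.helices)]

    @property
    def array(self) -> ZFArray:
        fingers = self.fingers
        return ZFArray(fingers, linkers=[self.linker] * (len(fingers) - 1))

    def protein(self, protein_id: str = "planted") -> ProteinRecord:
        return synthetic_protein(self.helices, linker=self.linker,
                                 protein_id=protein_id)

    def standardize(self, model: ScoringModel) -> ScoringModel:
        """Rescale a recovered scorer onto the scenario's energy scale."""
        return standardize_scores(model, self.calibration_fingers)

    def training_set(self, n_pos: int = 1312, n_neg: int = 8081,
                     margin: float = 0.1, seed: Optional[int] = None,
                     cg_bias: float = 0.0) -> List[TrainingExample]:
        return generate_training_set(self.w_true, n_pos, n_neg, margin=margin,
                                     seed=self.seed + 1 if seed is None else seed,
                                     cg_bias=cg_bias)

    def true_finger_pwm(self, finger) -> PWM:
        return finger_pwm(self.w_true, finger, self.params)

    def true_array_pwm(self, alpha: float = 0.75) -> PWM:
        return array_pwm(self.w_true, self.array, self.params, alpha=alpha)

    def experimental_pwm(self, dirichlet_concentration: float = 50.0,
                         n_flank: int = 2, revcomp_prob: float = 0.0,
                         seed: Optional[int] = None) -> PWM:
        return generate_experimental_pwm(
            self.true_array_pwm(), dirichlet_concentration=dirichlet_concentration,
            n_flank=n_flank, revcomp_prob=revcomp_prob,
            seed=self.seed + 2 if seed is None else seed)
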