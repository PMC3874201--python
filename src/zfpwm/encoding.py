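"""Binary feature encoding of a zinc finger-DNA subsite interface.

Each finger contacts a 4-bp subsite (bases b1..b4, 5'->3').  Two contact
maps are supported:

* ``canonical`` -- the four classic contacts a6-b1, a3-b2, a(-1)-b3, a2-b4;
* ``expanded``  -- the canonical four plus a2-b3, a(-1)-b4 and a6-b2.

An interface is the sparse indicator vector x with x[a, b, c] = 1 when
amino acid ``a`` and base ``b`` form contact ``c``.  The index layout is
contact-major: ``idx = c*80 + b*20 + a`` with contacts in the order listed
above, bases in A,C,G,T order and amino acids alphabetical.  This layout
is versioned in saved weight files so externally trained vectors stay
portable.  An unknown residue X produces no indicator for its contacts
(zero contribution to any score).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import List, Sequence, Tuple, Union

import numpy as np

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
BASES = "ACGT"
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: (helix position, base position) pairs
CANONICAL_CONTACTS: Tuple[Tuple[int, int], ...] = ((6, 1), (3, 2), (-1, 3), (2, 4))
EXPANDED_CONTACTS: Tuple[Tuple[int, int], ...] = CANONICAL_CONTACTS + (
    (2, 3), (-1, 4), (6, 2))


@dataclass(frozen=True)
class ContactModel:
    """An ordered set of (helix position, base position) contacts."""

    name: str
    contacts: Tuple[Tuple[int, int], ...]

    @property
    def n_contacts(self) -> int:
        return len(self.contacts)

    @property
    def dims(self) -> int:
        return self.n_contacts * len(BASES) * len(AMINO_ACIDS)


CANONICAL = ContactModel("canonical", CANONICAL_CONTACTS)
EXPANDED = ContactModel("expanded", EXPANDED_CONTACTS)
CONTACT_MODELS = {"canonical": CANONICAL, "expanded": EXPANDED}


@dataclass
class InterfaceVector:
    """Sparse binary interface representation (indices of the 1-entries)."""

    dims: int
    nonzero_indices: Tuple[int, ...]
    model: ContactModel

    def to_dense(self) -> np.ndarray:
        v = np.zeros(self.dims)
        v[list(self.nonzero_indices)] = 1.0
        return v


def feature_index(aa: str, base: str, contact: int, model: ContactModel) -> int:
    """Index of the (amino acid, base, contact) indicator under the layout."""
    return contact * 80 + _BASE_INDEX[base] * 20 + _AA_INDEX[aa]


HelixLike = Union["ZincFinger", Sequence[str]]  # noqa: F821 (duck-typed)


def _specificity_residues(finger: HelixLike) -> Tuple[str, str, str, str]:
    """Residues at helix positions (-1, 2, 3, 6) from a finger or 4-tuple."""
    res = getattr(finger, "specificity_residues", None)
    if res is not None:
        return tuple(res)
    res = tuple(finger)
    if len(res) != 4:
        raise ValueError(
            "expected a ZincFinger or the 4 residues at positions (-1, 2, 3, 6)"
        )
    return res


def encode_interface(finger: HelixLike, site: str,
                     model: ContactModel = EXPANDED) -> InterfaceVector:
    """Encode a (finger, 4-bp site) interface as a sparse indicator vector.

    ``finger`` may be a :class:`~zfpwm.domains.ZincFinger` or just the four
    residues at helix positions (-1, 2, 3, 6).  Exactly one index is set
    per contact whose residue is a standard amino acid; residues given as
    ``X`` contribute nothing.
    """
    site = site.upper()
    if len(site) != 4 or any(b not in _BASE_INDEX for b in site):
        raise ValueError(f"site must be a 4-mer over ACGT, got {site!r}")
    res = _specificity_residues(finger)
    by_pos = dict(zip((-1, 2, 3, 6), res))
    idx = []
    for c, (hpos, bpos) in enumerate(model.contacts):
        aa = by_pos[hpos].upper()
        if aa == "X":
            continue
        if aa not in _AA_INDEX:
            raise ValueError(f"non-standard residue {aa!r} at helix position {hpos}")
        idx.append(feature_index(aa, site[bpos - 1], c, model))
    return InterfaceVector(dims=model.dims, nonzero_indices=tuple(idx), model=model)


def enumerate_sites() -> List[str]:
    """All 256 4-bp sites in lexicographic A<C<G<T order."""
    return ["".join(s) for s in product(BASES, repeat=4)]


ALL_SITES = enumerate_sites()
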