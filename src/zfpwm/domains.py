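"""Detection of C2H2 zinc-finger domains and their recognition helices.

A Cys2His2 zinc finger is a ~28-residue beta-beta-alpha domain whose zinc
ion is coordinated by two cysteines and two histidines.  The residues of
the recognition helix are numbered relative to the helix start: position
-1 immediately precedes the helix and positions 1..6 follow, with -1, 2,
3 and 6 being the primary DNA-specificity positions.  Anchoring on the
first zinc-coordinating histidine at index ``h`` within the domain, the
helix positions -1..6 occupy indices ``h-7 .. h-1`` (the classic Zif268
convention).

Detection uses a regular-expression matcher with the default pattern
``C-x(1,5)-C-x(10,14)-H-x(3,6)-H`` scanned left to right without overlap;
lazy quantifiers anchor each coordinating residue at its earliest legal
position.  Externally computed domain coordinates (e.g. from an HMM scan)
can be imported from a tab-delimited table instead.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

from .motif_io import ProteinRecord

#: default C2H2 pattern; lazy quantifiers pick the most N-terminal legal
#: coordinating residues.  Set ``allow_cchc=True`` to accept a terminal Cys.
_PATTERN_HH = re.compile(r"C.{1,5}?C.{10,14}?H.{3,6}?H")
_PATTERN_HC = re.compile(r"C.{1,5}?C.{10,14}?H.{3,6}?[HC]")

#: helix positions carried by every finger, in order
HELIX_POSITIONS = (-1, 1, 2, 3, 4, 5, 6)
#: the four primary specificity positions
SPECIFICITY_POSITIONS = (-1, 2, 3, 6)


class MalformedFingerError(ValueError):
    """Raised when a putative domain cannot host a full recognition helix."""


@dataclass
class ZincFinger:
    """One C2H2 domain within a protein.

    ``start``/``end`` delimit the domain as a 0-based half-open span;
    ``cys1 < cys2 < his1 < his2`` are the absolute positions of the
    zinc-coordinating residues; ``helix`` holds the seven residues at
    helix positions -1, 1, 2, 3, 4, 5, 6.
    """

    start: int
    end: int
    cys1: int
    cys2: int
    his1: int
    his2: int
    helix: str

    def __post_init__(self) -> None:
        if not (self.cys1 < self.cys2 < self.his1 < self.his2):
            raise MalformedFingerError(
                "zinc-coordinating residues out of order: "
                f"C{self.cys1} C{self.cys2} H{self.his1} H{self.his2}"
            )
        if len(self.helix) != len(HELIX_POSITIONS):
            raise MalformedFingerError(
                f"helix must have exactly {len(HELIX_POSITIONS)} residues, "
                f"got {self.helix!r}"
            )

    def helix_residue(self, position: int) -> str:
        """Residue at a helix position in ``HELIX_POSITIONS``."""
        return self.helix[HELIX_POSITIONS.index(position)]

    @property
    def specificity_residues(self) -> Tuple[str, str, str, str]:
        """Residues at positions (-1, 2, 3, 6)."""
        return tuple(self.helix_residue(p) for p in SPECIFICITY_POSITIONS)


@dataclass
class ZFArray:
    """Consecutive fingers (N->C) acting as one DNA-binding unit.

    ``linkers[i]`` counts the residues strictly between the last histidine
    of finger ``i`` and the first cysteine of finger ``i+1``.
    """

    fingers: List[ZincFinger]
    linkers: List[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.fingers:
            raise ValueError("a ZF array needs at least one finger")
        if len(self.linkers) != len(self.fingers) - 1:
            raise ValueError("need exactly one linker count per adjacent pair")

    def __len__(self) -> int:
        return len(self.fingers)


def extract_helix_positions(domain_seq: str, his_index: int) -> Tuple[str, str, str, str]:
    """Residues at helix positions (-1, 2, 3, 6) of a domain subsequence.

    ``his_index`` is the index (within ``domain_seq``) of the first
    zinc-coordinating histidine; positions map to indices
    ``-1 -> h-7``, ``2 -> h-5``, ``3 -> h-4``, ``6 -> h-1``.
    """
    h = his_index
    if h < 7:
        raise MalformedFingerError(
            f"first coordinating His at offset {h} leaves no room for the helix"
        )
    return (domain_seq[h - 7], domain_seq[h - 5], domain_seq[h - 4], domain_seq[h - 1])


def _finger_from_span(sequence: str, start: int, end: int,
                      allow_cchc: bool = False) -> ZincFinger:
    sub = sequence[start:end]
    pattern = _PATTERN_HC if allow_cchc else _PATTERN_HH
    m = pattern.search(sub)
    if m is None:
        raise MalformedFingerError(
            f"span {start}:{end} does not match the C2H2 pattern"
        )
    return _finger_from_match(sequence, start + m.start(), start + m.end())


_PATTERN_GROUPED = re.compile(r"C.{1,5}?(C).{10,14}?(H).{3,6}?([HC])")


def _finger_from_match(sequence: str, start: int, end: int) -> ZincFinger:
    sub = sequence[start:end]
    m = _PATTERN_GROUPED.fullmatch(sub)
    if m is None:
        raise MalformedFingerError(f"{sub!r} is not a C2H2 match")
    cys1, cys2 = 0, m.start(1)
    his1, his2 = m.start(2), m.start(3)
    if his1 < 7:
        raise MalformedFingerError(
            f"first coordinating His at offset {his1} leaves no room for the helix"
        )
    helix = sub[his1 - 7:his1]
    return ZincFinger(
        start=start, end=end,
        cys1=start + cys1, cys2=start + cys2,
        his1=start + his1, his2=start + his2,
        helix=helix,
    )


def find_c2h2_domains(protein: ProteinRecord, allow_cchc: bool = False) -> List[ZincFinger]:
    """Scan a protein for C2H2 fingers, left to right, non-overlapping.

    Returns fingers in N->C order; an empty list when nothing matches.
    Putative matches whose helix would run out of the domain are skipped.
    """
    pattern = _PATTERN_HC if allow_cchc else _PATTERN_HH
    seq = protein.sequence
    fingers: List[ZincFinger] = []
    pos = 0
    while True:
        m = pattern.search(seq, pos)
        if m is None:
            break
        try:
            fingers.append(_finger_from_match(seq, m.start(), m.end()))
        except MalformedFingerError:
            pass
        pos = m.end()
    return fingers


def linker_length(prev: ZincFinger, nxt: ZincFinger) -> int:
    """Residues strictly between ``prev``'s last His and ``nxt``'s first Cys."""
    return nxt.cys1 - prev.his2 - 1


def build_arrays(fingers: Sequence[ZincFinger], max_linker: int = 12) -> List[ZFArray]:
    """Group N->C-ordered fingers into arrays by linker length.

    Consecutive fingers separated by at most ``max_linker`` residues
    (counted between the last His and the next first Cys) share an array;
    longer linkers split arrays.  Single-finger arrays are legal.
    """
    if max_linker < 0:
        raise ValueError("max_linker must be non-negative")
    arrays: List[ZFArray] = []
    cur: List[ZincFinger] = []
    cur_linkers: List[int] = []
    for f in fingers:
        if cur:
            gap = linker_length(cur[-1], f)
            if gap <= max_linker:
                cur.append(f)
                cur_linkers.append(gap)
                continue
            arrays.append(ZFArray(cur, cur_linkers))
            cur, cur_linkers = [], []
        cur = [f]
        cur_linkers = []
    if cur:
        arrays.append(ZFArray(cur, cur_linkers))
    return arrays


def helix_signature(fingers: Sequence[ZincFinger], sep: str = "-") -> str:
    """Concatenated -1..6 helices; equal signatures mark redundant proteins."""
    if not fingers:
        raise ValueError("helix signature of an empty finger list")
    return sep.join(f.helix for f in fingers)


def read_domain_table(path, proteins: Sequence[ProteinRecord],
                      allow_cchc: bool = False) -> Dict[str, List[ZincFinger]]:
    """Import externally computed domain coordinates (HMM-scan parity path).

    The table is tab-delimited ``protein_id  start  end`` with 0-based
    half-open spans.  Fingers are reconstructed from each span with the
    built-in pattern so that helix residues are populated.
    """
    by_id = {p.id: p for p in proteins}
    out: Dict[str, List[ZincFinger]] = {p.id: [] for p in proteins}
    for line_no, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{line_no}: expected protein_id<TAB>start<TAB>end")
        pid, start, end = parts[0], int(parts[1]), int(parts[2])
        if pid not in by_id:
            continue
        out[pid].append(_finger_from_span(by_id[pid].sequence, start, end, allow_cchc))
    for pid in out:
        out[pid].sort(key=lambda f: f.start)
    return out
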