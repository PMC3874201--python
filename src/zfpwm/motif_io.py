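"""Reading, writing and elementary transforms of position weight matrices.

A PWM is stored column-major as an ``(L, 4)`` float array of per-position
nucleotide probabilities in fixed A, C, G, T order.  Matrices read from
files may contain counts; every column is normalized to sum to one on
read.  No pseudocounts are added anywhere: downstream information-content
and correlation computations use the ``0 * log2(0) = 0`` convention and
must tolerate exact zeros.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Sequence

import numpy as np
from Bio import SeqIO, motifs as bio_motifs

NUCLEOTIDES = "ACGT"
#: formats whose parsing/writing is delegated to Bio.motifs
_BIO_FORMATS = {"jaspar": "jaspar", "meme_minimal": "minimal", "transfac": "transfac"}
PWM_FORMATS = ("jaspar", "meme_minimal", "transfac", "tsv")

_COLUMN_TOL = 1e-9


class MotifFormatError(ValueError):
    """Raised when a matrix file cannot be parsed or normalized."""


@dataclass
class PWM:
    """Position weight matrix over (A, C, G, T).

    Parameters
    ----------
    matrix : (L, 4) array-like
        Per-column nucleotide probabilities; rows are positions 5'->3'.
    name : str
        Free-text identifier.
    source : str
        One of ``predicted``, ``experimental``, ``randomized``.
    degenerate_columns : list of int
        Indices of columns that were replaced by a uniform fallback
        during junction merging (empty for ordinary matrices).
    """

    matrix: np.ndarray
    name: str = ""
    source: str = "experimental"
    degenerate_columns: List[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.size == 0:
            m = m.reshape(0, 4)
        if m.ndim != 2 or m.shape[1] != 4:
            raise MotifFormatError(f"PWM matrix must be (L, 4), got shape {m.shape}")
        if np.any(m < 0):
            raise MotifFormatError("PWM entries must be non-negative")
        if len(m) and np.any(np.abs(m.sum(axis=1) - 1.0) > _COLUMN_TOL):
            raise MotifFormatError("every PWM column must sum to 1")
        self.matrix = m

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def columns(self) -> List[np.ndarray]:
        return [self.matrix[i] for i in range(len(self))]

    def information_content(self) -> np.ndarray:
        """Per-column IC in bits, shape ``(L,)``."""
        return np.array([information_content(c) for c in self.matrix])

    def consensus(self) -> str:
        if not len(self):
            return ""
        return "".join(NUCLEOTIDES[i] for i in self.matrix.argmax(axis=1))


@dataclass
class ProteinRecord:
    """A protein sequence with an identifier; sequence is upper-cased."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError(f"protein {self.id!r} has an empty sequence")


def read_fasta(path) -> List[ProteinRecord]:
    """Read protein sequences from a FASTA file."""
    records = [
        ProteinRecord(id=rec.id, sequence=str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    return records


def information_content(column: Sequence[float]) -> float:
    """IC of one probability column: ``2 + sum_b p_b log2 p_b`` bits.

    Uses the convention ``0 * log2(0) = 0``; the result lies in [0, 2].
    """
    p = np.asarray(column, dtype=float)
    if p.shape != (4,) or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-6:
        raise ValueError(f"not a probability 4-vector: {column!r}")
    nz = p[p > 0]
    return float(2.0 + np.sum(nz * np.log2(nz)))


def trim_pwm(pwm: PWM, ic_threshold: float = 0.5) -> PWM:
    """Strip low-information columns from both ends.

    Columns with IC below ``ic_threshold`` are removed from the 5' and 3'
    ends until a high-IC column is met; interior columns are never touched.
    The result may be empty.
    """
    lo, hi = 0, len(pwm)
    while lo < hi and information_content(pwm.matrix[lo]) < ic_threshold:
        lo += 1
    while hi > lo and information_content(pwm.matrix[hi - 1]) < ic_threshold:
        hi -= 1
    return PWM(pwm.matrix[lo:hi].copy(), name=pwm.name, source=pwm.source)


def reverse_complement(pwm: PWM) -> PWM:
    """Reverse column order and complement each column (A<->T, C<->G)."""
    return PWM(pwm.matrix[::-1, ::-1].copy(), name=pwm.name, source=pwm.source)


# ---------------------------------------------------------------------------
# file formats


def _normalize_counts(raw: np.ndarray) -> np.ndarray:
    """Column-normalize a raw (L, 4) count/frequency matrix."""
    raw = np.asarray(raw, dtype=float)
    if raw.size == 0:
        return raw.reshape(0, 4)
    if np.any(raw < 0):
        raise MotifFormatError("negative matrix entry")
    sums = raw.sum(axis=1)
    if np.any(sums <= 0):
        raise MotifFormatError("unnormalizable column (sum of entries is zero)")
    return raw / sums[:, None]


def _matrix_from_bio(motif) -> np.ndarray:
    counts = motif.counts
    return np.array([[counts[b][i] for b in NUCLEOTIDES] for i in range(motif.length)])


def _bio_motif(pwm: PWM, name: str):
    # Bio.motifs wants counts; frequencies are scaled to large pseudo-counts
    # so low-precision writers (JASPAR prints 2 decimals) still round-trip —
    # read_pwm re-normalizes every column, so the scale is invisible.
    counts = {b: [float(pwm.matrix[i, j]) * 1e6 for i in range(len(pwm))]
              for j, b in enumerate(NUCLEOTIDES)}
    motif = bio_motifs.Motif(alphabet="ACGT", counts=counts)
    motif.name = name or "motif"
    motif.matrix_id = name or "motif"
    return motif


def read_pwm(path, format: str = "jaspar") -> PWM:
    """Read a single PWM from ``path`` in the given dialect.

    Counts are converted to frequencies by per-column normalization; a
    column of all zeros is an error.  Supported formats: ``jaspar``,
    ``meme_minimal``, ``transfac`` and ``tsv`` (4 labelled rows A,C,G,T).
    """
    if format not in PWM_FORMATS:
        raise ValueError(f"unknown PWM format {format!r}")
    text = Path(path).read_text()
    if not text.strip():
        raise MotifFormatError(f"empty file: {path}")
    name = _sniff_name(text, format) or Path(path).stem
    if _is_empty_matrix(text, format):
        return PWM(np.zeros((0, 4)), name=name, source="experimental")
    if format == "tsv":
        raw = _parse_tsv(text)
    else:
        try:
            parsed = bio_motifs.parse(io.StringIO(text), _BIO_FORMATS[format])
            parsed = list(parsed)
        except Exception as exc:  # malformed under the dialect
            raise MotifFormatError(f"cannot parse {path} as {format}: {exc}") from exc
        if not parsed:
            raise MotifFormatError(f"no motif found in {path}")
        motif = parsed[0]
        if motif.name:
            name = motif.name
        raw = _matrix_from_bio(motif)
    return PWM(_normalize_counts(raw), name=name, source="experimental")


def write_pwm(pwm: PWM, path, format: str = "jaspar") -> None:
    """Write ``pwm`` to ``path``; the file is re-readable by :func:`read_pwm`."""
    if format not in PWM_FORMATS:
        raise ValueError(f"unknown PWM format {format!r}")
    name = pwm.name or Path(path).stem
    if format == "tsv":
        text = _format_tsv(pwm)
    elif len(pwm) == 0:
        text = _empty_matrix_text(name, format)
    elif format == "meme_minimal":
        text = _format_meme(pwm, name)
    else:
        motif = _bio_motif(pwm, name)
        text = bio_motifs.write([motif], _BIO_FORMATS[format])
    Path(path).write_text(text)


# -- tsv dialect (4 labelled rows A/C/G/T, tab-separated values) ------------


def _parse_tsv(text: str) -> np.ndarray:
    rows = {}
    for line in text.splitlines():
        line = line.rstrip()
        if not line or line.startswith("#") or line.startswith(">"):
            continue
        parts = line.split("\t")
        label = parts[0].strip()
        if label not in NUCLEOTIDES:
            raise MotifFormatError(f"unexpected row label {label!r} in TSV matrix")
        rows[label] = [float(v) for v in parts[1:] if v.strip()]
    if sorted(rows) != sorted(NUCLEOTIDES):
        raise MotifFormatError("TSV matrix must have exactly the four rows A,C,G,T")
    lengths = {len(v) for v in rows.values()}
    if len(lengths) != 1:
        raise MotifFormatError("TSV matrix rows have unequal lengths")
    return np.array([rows[b] for b in NUCLEOTIDES]).T


def _format_tsv(pwm: PWM) -> str:
    lines = [f"# zfpwm matrix: {pwm.name}"]
    for j, b in enumerate(NUCLEOTIDES):
        vals = "\t".join(f"{v:.8f}" for v in pwm.matrix[:, j])
        lines.append(f"{b}\t{vals}" if len(pwm) else b)
    return "\n".join(lines) + "\n"


# -- empty matrices (legal after trimming) ----------------------------------


def _empty_matrix_text(name: str, format: str) -> str:
    if format == "jaspar":
        return f">{name}\n" + "".join(f"{b} [ ]\n" for b in NUCLEOTIDES)
    if format == "meme_minimal":
        return (_MEME_HEADER + f"MOTIF {name}\n"
                "letter-probability matrix: alength= 4 w= 0 nsites= 20 E= 0\n")
    if format == "transfac":
        return f"ID {name}\nBF {name}\nP0      A      C      G      T\nXX\n//\n"
    raise AssertionError(format)


def _is_empty_matrix(text: str, format: str) -> bool:
    if format == "tsv":
        return False  # _parse_tsv handles zero-width rows naturally
    if format == "jaspar":
        data = [l for l in text.splitlines() if l.strip() and not l.startswith(">")]
        return bool(data) and not any(any(ch.isdigit() for ch in l) for l in data)
    if format == "meme_minimal":
        return "w= 0" in text
    if format == "transfac":
        return not any(l[:2].isdigit() for l in text.splitlines() if len(l) >= 2)
    return False


def _sniff_name(text: str, format: str) -> str:
    for line in text.splitlines():
        if format == "jaspar" and line.startswith(">"):
            return line[1:].split()[0] if line[1:].split() else ""
        if format == "meme_minimal" and line.startswith("MOTIF"):
            parts = line.split()
            return parts[1] if len(parts) > 1 else ""
        if format == "transfac" and line.startswith("ID"):
            parts = line.split()
            return parts[1] if len(parts) > 1 else ""
    return ""


_MEME_HEADER = """MEME version 4

ALPHABET= ACGT

strands: + -

Background letter frequencies
A 0.25 C 0.25 G 0.25 T 0.25

"""


def _format_meme(pwm: PWM, name: str) -> str:
    lines = [
        _MEME_HEADER + f"MOTIF {name}",
        # large nsites: the minimal-format parser reconstructs integer
        # counts as freq*nsites, so a big denominator preserves precision
        f"letter-probability matrix: alength= 4 w= {len(pwm)} nsites= 1000000 E= 0",
    ]
    for row in pwm.matrix:
        lines.append(" " + " ".join(f"{v:.8f}" for v in row))
    return "\n".join(lines) + "\n"


def text_logo(pwm: PWM, height: int = 8) -> str:
    """Plain-text logo: per column, letters stacked by probability mass."""
    if not len(pwm):
        return "(empty matrix)\n"
    ic = pwm.information_content()
    out = []
    for i, col in enumerate(pwm.matrix):
        order = np.argsort(col)[::-1]
        stack = "".join(
            NUCLEOTIDES[j] * int(round(col[j] * height)) for j in order if col[j] > 0
        )
        out.append(f"{i + 1:3d}  IC={ic[i]:4.2f}  {stack}")
    return "\n".join(out) + "\n"
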