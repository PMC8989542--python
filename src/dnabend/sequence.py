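"""DNA sequence handling: validation, reverse complement, one-hot encoding,
sliding-window extraction and FASTA input.

Conventions used throughout the package:

* sequences are plain uppercase strings over the alphabet ``{A, C, G, T, N}``;
  lowercase (soft-masked) input is folded to uppercase on entry;
* one-hot channel order is ``(A, C, G, T)``; an ``N`` encodes as the uniform
  row ``(0.25, 0.25, 0.25, 0.25)``;
* genomic coordinates are 1-based inclusive.  The score of a 50-bp window
  starting at position ``start`` is anchored at its 25th base,
  ``center = start + 24``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, List, Sequence

import numpy as np
from Bio import SeqIO

ALPHABET = "ACGTN"
BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: index of each base in the one-hot channel order (A, C, G, T); N -> 4
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
BASE_INDEX["N"] = 4

# row 4 is the N row: uniform over the four bases
_ENCODE_TABLE = np.vstack([np.eye(4), np.full(4, 0.25)])

_CODE_LOOKUP = np.full(256, -1, dtype=np.int8)
for _b, _i in BASE_INDEX.items():
    _CODE_LOOKUP[ord(_b)] = _i
    _CODE_LOOKUP[ord(_b.lower())] = _i


class InvalidSequenceError(ValueError):
    """Raised when a sequence contains characters outside {A,C,G,T,N}."""


class SequenceTooShortError(ValueError):
    """Raised when a sequence is shorter than the requested window width."""


def clean_sequence(seq: str) -> str:
    """Uppercase-fold ``seq`` and verify it is over {A,C,G,T,N}."""
    s = seq.upper()
    if not s:
        raise InvalidSequenceError("empty sequence")
    stripped = s.translate(str.maketrans("", "", ALPHABET))
    if stripped:
        raise InvalidSequenceError(
            f"sequence contains invalid characters: {sorted(set(stripped))[:5]}"
        )
    return s


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement; ``N`` maps to ``N``."""
    s = clean_sequence(seq)
    return s.translate(_COMPLEMENT)[::-1]


def encode_bases(seq: str) -> np.ndarray:
    """Integer codes A=0, C=1, G=2, T=3, N=4 as an int8 array."""
    codes = _CODE_LOOKUP[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (codes < 0).any():
        bad = sorted({c for c, k in zip(seq, codes) if k < 0})
        raise InvalidSequenceError(f"sequence contains invalid characters: {bad[:5]}")
    return codes


def decode_bases(codes: np.ndarray) -> str:
    return "".join(ALPHABET[c] for c in np.asarray(codes))


def one_hot_encode(seq: str) -> np.ndarray:
    """Encode a sequence as an L x 4 matrix, channel order (A, C, G, T).

    Unambiguous bases give unit rows; ``N`` gives the uniform row.  Every row
    sums to 1.
    """
    return _ENCODE_TABLE[encode_bases(seq)]


def one_hot_encode_batch(seqs: Sequence[str]) -> np.ndarray:
    """Encode equal-length sequences as an (n, L, 4) array."""
    if not seqs:
        raise ValueError("empty sequence batch")
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise ValueError("sequences in a batch must have equal length")
    flat = encode_bases("".join(seqs))
    return _ENCODE_TABLE[flat].reshape(len(seqs), L, 4)


def decode_one_hot(matrix: np.ndarray) -> str:
    """Inverse of :func:`one_hot_encode` for N-free encodings (argmax rule)."""
    m = np.asarray(matrix)
    if m.ndim != 2 or m.shape[1] != 4:
        raise ValueError("expected an L x 4 one-hot matrix")
    return "".join(BASES[i] for i in m.argmax(axis=1))


@dataclass(frozen=True)
class GenomicWindow:
    """A fixed-width window in 1-based inclusive coordinates.

    The score anchor (``center``) is the 25th base of a 50-bp window, i.e.
    ``start + 24``; for general width the anchor is the left-of-center base
    ``start + (width - 1) // 2``.
    """

    start: int
    width: int = 50
    chrom: str | None = None

    @property
    def end(self) -> int:
        return self.start + self.width - 1

    @property
    def center(self) -> int:
        return self.start + (self.width - 1) // 2


def sliding_windows(seq: str, width: int = 50, step: int = 1) -> List[GenomicWindow]:
    """All width-bp windows of ``seq`` at the given step, 1-based starts.

    For an N-free sequence of length L at step 1 this yields L - width + 1
    windows with centers ``25 .. L - 25`` (width 50).
    """
    L = len(seq)
    if width < 1 or step < 1:
        raise ValueError("width and step must be positive")
    if L < width:
        raise SequenceTooShortError(
            f"sequence length {L} is shorter than window width {width}"
        )
    return [GenomicWindow(start=s, width=width) for s in range(1, L - width + 2, step)]


@dataclass
class FastaRecord:
    """One FASTA record: identifier and uppercase-folded sequence."""

    id: str
    seq: str

    def __len__(self) -> int:
        return len(self.seq)


def read_fasta(path: str | Path) -> List[FastaRecord]:
    """Read a (multi-record, possibly wrapped) FASTA file.

    Lowercase soft-masking is folded to uppercase; characters outside
    {A,C,G,T,N} or an empty body raise :class:`InvalidSequenceError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise InvalidSequenceError(f"no FASTA records found in {path}")
    out = []
    for rec in records:
        body = str(rec.seq)
        if not body:
            raise InvalidSequenceError(f"record {rec.id!r} has an empty body")
        out.append(FastaRecord(id=rec.id, seq=clean_sequence(body)))
    return out


def write_fasta(records: Iterable[FastaRecord], path: str | Path, wrap: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), wrap):
                fh.write(rec.seq[i : i + wrap] + "\n")
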