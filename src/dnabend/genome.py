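"""Genome- and library-scale C-score prediction.

A chromosome or long fragment is scored with a 1-bp sliding window of
50-bp fragments; the score of the window starting at 1-based position
``start`` is anchored at its 25th base (``center = start + 24``), so an
N-free sequence of length L yields a track over centers ``25 .. L - 25``.
Windows containing N are skipped and emit no score (track gaps), never an
imputed value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence

import numpy as np

from .model import IRLSTMRegressor
from .sequence import clean_sequence, encode_bases, SequenceTooShortError

_ENCODE_TABLE = np.vstack([np.eye(4), np.full(4, 0.25)])


@dataclass
class CScoreTrack:
    """Per-base-pair C-scores at 1-based center coordinates."""

    chrom: str
    positions: np.ndarray  # strictly increasing 1-based centers
    scores: np.ndarray
    window_width: int = 50

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.positions) != len(self.scores):
            raise ValueError("positions and scores length mismatch")
        if len(self.positions) > 1 and not (np.diff(self.positions) > 0).all():
            raise ValueError("positions must be strictly increasing")

    def __len__(self) -> int:
        return len(self.positions)

    def as_dense(self) -> tuple[int, np.ndarray]:
        """(offset, values) where values[i] is the score at position
        offset + i, NaN in gaps."""
        lo, hi = int(self.positions[0]), int(self.positions[-1])
        dense = np.full(hi - lo + 1, np.nan)
        dense[self.positions - lo] = self.scores
        return lo, dense


def predict_track(
    model: IRLSTMRegressor,
    seq: str,
    chrom: str = "seq",
    batch_size: int = 1024,
) -> CScoreTrack:
    """Sliding-window C-score track of ``seq`` (length >= 50).

    Batching is a throughput knob only; results are independent of
    ``batch_size``.
    """
    s = clean_sequence(seq)
    width = model.input_length
    L = len(s)
    if L < width:
        raise SequenceTooShortError(
            f"sequence length {L} < window width {width}"
        )
    codes = encode_bases(s)
    n_windows = L - width + 1
    # windows overlapping an N are skipped (no fabricated scores)
    has_n = np.convolve((codes == 4).astype(int), np.ones(width, dtype=int), "valid") > 0
    starts = np.flatnonzero(~has_n)  # 0-based window starts
    if len(starts) == 0:
        return CScoreTrack(chrom, np.empty(0, dtype=np.int64), np.empty(0))

    window_codes = np.lib.stride_tricks.sliding_window_view(codes, width)[starts]
    scores = np.empty(len(starts))
    half = model.detrend_b_ * 0.5
    for i in range(0, len(starts), batch_size):
        block = window_codes[i : i + batch_size]
        x = _ENCODE_TABLE[block]
        fwd = model.network_.forward(x, training=False)
        rev = model.network_.forward(x[:, ::-1, ::-1], training=False)
        scores[i : i + batch_size] = model.detrend_a_ + half * (fwd + rev)
    centers = starts + 1 + (width - 1) // 2  # 1-based start + 24
    return CScoreTrack(chrom, centers.astype(np.int64), scores, window_width=width)


def mean_library_cscore(
    model: IRLSTMRegressor, seqs: Sequence[str], batch_size: int = 1024
) -> np.ndarray:
    """Per-sequence mean of all sliding-window C-scores (e.g. the mean over
    the 41 windows of a 90-bp fragment, centers 25..65)."""
    return np.array(
        [predict_track(model, s, batch_size=batch_size).scores.mean() for s in seqs]
    )


# ---------------------------------------------------------------- track I/O

def _contiguous_blocks(positions: np.ndarray) -> List[tuple[int, int]]:
    """(start_index, stop_index) pairs of runs with step exactly 1."""
    if len(positions) == 0:
        return []
    breaks = np.flatnonzero(np.diff(positions) != 1)
    starts = np.concatenate([[0], breaks + 1])
    stops = np.concatenate([breaks + 1, [len(positions)]])
    return list(zip(starts, stops))


def write_wig(track: CScoreTrack, path) -> None:
    """Write a fixedStep WIG file (1-based, step 1); N-gaps break blocks."""
    with open(path, "w") as fh:
        fh.write(f'track type=wiggle_0 name="{track.chrom}_cscore"\n')
        for i0, i1 in _contiguous_blocks(track.positions):
            fh.write(
                f"fixedStep chrom={track.chrom} start={track.positions[i0]} step=1\n"
            )
            fh.write("\n".join(f"{v:.6f}" for v in track.scores[i0:i1]) + "\n")


def read_wig(path) -> CScoreTrack:
    positions: List[int] = []
    scores: List[float] = []
    chrom = "seq"
    pos = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("track"):
                continue
            if line.startswith("fixedStep"):
                fields = dict(kv.split("=") for kv in line.split()[1:])
                chrom = fields["chrom"]
                pos = int(fields["start"])
                step = int(fields.get("step", 1))
                if step != 1:
                    raise ValueError("only step=1 tracks supported")
                continue
            if pos is None:
                raise ValueError("WIG data before any fixedStep header")
            positions.append(pos)
            scores.append(float(line))
            pos += 1
    return CScoreTrack(chrom, np.array(positions), np.array(scores))


def write_bedgraph(track: CScoreTrack, path) -> None:
    """BED-style half-open 0-based intervals of width 1: center c maps to
    [c-1, c)."""
    with open(path, "w") as fh:
        for p, v in zip(track.positions, track.scores):
            fh.write(f"{track.chrom}\t{p - 1}\t{p}\t{v:.6f}\n")


def read_bedgraph(path) -> CScoreTrack:
    chroms: List[str] = []
    positions: List[int] = []
    scores: List[float] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, start, end, value = line.split()
            if int(end) - int(start) != 1:
                raise ValueError("bedGraph intervals must have width 1")
            chroms.append(chrom)
            positions.append(int(start) + 1)
            scores.append(float(value))
    if len(set(chroms)) > 1:
        raise ValueError("multi-chromosome bedGraph: read per chromosome")
    return CScoreTrack(chroms[0] if chroms else "seq", np.array(positions, dtype=int), np.array(scores))


def write_track_tsv(track: CScoreTrack, path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tposition\tc_score\n")
        for p, v in zip(track.positions, track.scores):
            fh.write(f"{track.chrom}\t{p}\t{v:.6f}\n")
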