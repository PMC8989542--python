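"""Feature-anchored signal analytics.

These are the analyses run around genomic anchors — nucleosome dyads,
TSSs, transcription-factor binding sites: per-offset dinucleotide-class
frequency profiles, strand-aware mean-signal profiles, quartile
stratification by anchor score, exact-length poly(dA:dT) tract detection,
and PWM refinement of peak regions.

Coordinates are 1-based inclusive internally; BED6 interchange converts
explicitly at the boundary (BED is 0-based half-open).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, List, Sequence, Set

import numpy as np
import pandas as pd

from .genome import CScoreTrack
from .markov import PWM
from .sequence import BASES, encode_bases, reverse_complement

logger = logging.getLogger(__name__)

WW_DINUCLEOTIDES = frozenset({"AA", "AT", "TA", "TT"})
SS_DINUCLEOTIDES = frozenset({"GG", "GC", "CG", "CC"})


@dataclass
class FeatureAnchorSet:
    """Genomic anchors: (chrom, 1-based position, strand, optional score)."""

    chrom: np.ndarray
    position: np.ndarray
    strand: np.ndarray | None = None
    score: np.ndarray | None = None
    name: str = "anchors"

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.position = np.asarray(self.position, dtype=np.int64)
        n = len(self.position)
        if self.strand is None:
            self.strand = np.full(n, "+", dtype=object)
        else:
            self.strand = np.asarray(self.strand, dtype=object)
            if not set(np.unique(self.strand)) <= {"+", "-"}:
                raise ValueError("strand must be '+' or '-'")
        if self.score is not None:
            self.score = np.asarray(self.score, dtype=float)
        for arr in (self.chrom, self.strand):
            if len(arr) != n:
                raise ValueError("anchor field lengths differ")
        if self.score is not None and len(self.score) != n:
            raise ValueError("anchor field lengths differ")

    def __len__(self) -> int:
        return len(self.position)

    def subset(self, idx, name: str | None = None) -> "FeatureAnchorSet":
        idx = np.asarray(idx)
        return FeatureAnchorSet(
            chrom=self.chrom[idx],
            position=self.position[idx],
            strand=self.strand[idx],
            score=None if self.score is None else self.score[idx],
            name=name or self.name,
        )

    def to_bed6(self, path, feature_width: int = 1) -> None:
        """BED6 export; the 1-based anchor p becomes the half-open interval
        [p-1, p-1+feature_width)."""
        score = self.score if self.score is not None else np.zeros(len(self))
        pd.DataFrame(
            {
                "chrom": self.chrom,
                "start": self.position - 1,
                "end": self.position - 1 + feature_width,
                "name": [f"{self.name}_{i}" for i in range(len(self))],
                "score": score,
                "strand": self.strand,
            }
        ).to_csv(path, sep="\t", header=False, index=False)

    @classmethod
    def from_bed6(cls, path, name: str | None = None) -> "FeatureAnchorSet":
        df = pd.read_csv(
            path, sep="\t", header=None,
            names=["chrom", "start", "end", "name", "score", "strand"],
        )
        return cls(
            chrom=df["chrom"].to_numpy(dtype=object),
            position=df["start"].to_numpy(dtype=np.int64) + 1,
            strand=df["strand"].to_numpy(dtype=object),
            score=df["score"].to_numpy(dtype=float),
            name=name or "anchors",
        )


@dataclass
class ProfileMatrix:
    """Per-offset mean signal around anchors, with contributing counts."""

    offsets: np.ndarray
    mean: np.ndarray
    count: np.ndarray

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {"offset": self.offsets, "mean": self.mean, "count": self.count}
        ).to_csv(path, sep="\t", index=False)


def dinucleotide_profile(
    seqs: Sequence[str], motif_class: Iterable[str]
) -> np.ndarray:
    """Fraction of sequences whose 2-mer at (t, t+1) is in ``motif_class``,
    for each position t in 1..L-1 of an equal-length alignment."""
    if not seqs:
        raise ValueError("empty sequence set")
    L = len(seqs[0])
    if L < 2 or any(len(s) != L for s in seqs):
        raise ValueError("sequences must be equal length >= 2")
    motifs = {m.upper() for m in motif_class}
    if any(len(m) != 2 or set(m) - set(BASES) for m in motifs):
        raise ValueError("motif class must contain 2-mers over ACGT")
    mat = encode_bases("".join(seqs)).reshape(len(seqs), L).astype(np.int64)
    if (mat > 3).any():
        raise ValueError("sequences must be N-free")
    codes = mat[:, :-1] * 4 + mat[:, 1:]
    class_codes = np.array(
        sorted(encode_bases(m)[0] * 4 + encode_bases(m)[1] for m in motifs)
    )
    return np.isin(codes, class_codes).mean(axis=0)


def aligned_mean_profile(
    track: CScoreTrack,
    anchors: FeatureAnchorSet,
    flank: int,
) -> ProfileMatrix:
    """Strand-aware mean signal profile around anchors.

    For offset d the contribution of a + anchor at p is the track value at
    p + d, and of a - anchor the value at p - d; positions missing from the
    track (gaps, chromosome edges) are excluded from both mean and count.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    lo, dense = track.as_dense()
    offsets = np.arange(-flank, flank + 1)
    sign = np.where(anchors.strand == "+", 1, -1)
    # query positions: (n_anchors, n_offsets)
    q = anchors.position[:, None] + sign[:, None] * offsets[None, :]
    idx = q - lo
    valid = (idx >= 0) & (idx < len(dense))
    vals = np.full(q.shape, np.nan)
    vals[valid] = dense[idx[valid]]
    finite = np.isfinite(vals)
    count = finite.sum(axis=0)
    if count.sum() == 0:
        raise ValueError("no anchor overlaps the track")
    with np.errstate(invalid="ignore"):
        mean = np.where(count > 0, np.nansum(vals, axis=0) / np.maximum(count, 1), np.nan)
    return ProfileMatrix(offsets=offsets, mean=mean, count=count)


def quartile_stratify(anchors: FeatureAnchorSet) -> List[FeatureAnchorSet]:
    """Partition anchors into score quartiles Q1 (lowest) .. Q4 (highest).

    Cutpoints are the 25/50/75 empirical percentiles (linear interpolation);
    scores tied with a cutpoint fall in the lower quartile.
    """
    if anchors.score is None or np.isnan(anchors.score).any():
        raise ValueError("all anchors need scores for quartile stratification")
    cuts = np.percentile(anchors.score, [25, 50, 75])
    group = (anchors.score[:, None] > cuts[None, :]).sum(axis=1)
    return [
        anchors.subset(np.flatnonzero(group == g), name=f"{anchors.name}_Q{g + 1}")
        for g in range(4)
    ]


def find_polyA_tracts(
    seq: str, exact_len: int, chrom: str = "seq"
) -> FeatureAnchorSet:
    """Maximal pure-A or pure-T runs of exactly ``exact_len`` bp.

    The anchor is the run center (left-of-center base for even lengths);
    strand is '+' for A-runs and '-' for T-runs.  A run longer than
    ``exact_len`` is *not* reported at any sub-window (maximality).
    """
    if exact_len < 1:
        raise ValueError("exact_len must be >= 1")
    codes = encode_bases(seq.upper())
    positions: List[int] = []
    strands: List[str] = []
    n = len(codes)
    i = 0
    while i < n:
        b = codes[i]
        j = i
        while j < n and codes[j] == b:
            j += 1
        if j - i == exact_len and b in (0, 3):  # A=0, T=3
            start_1based = i + 1
            positions.append(start_1based + (exact_len - 1) // 2)
            strands.append("+" if b == 0 else "-")
        i = j
    return FeatureAnchorSet(
        chrom=np.full(len(positions), chrom, dtype=object),
        position=np.array(positions, dtype=np.int64),
        strand=np.array(strands, dtype=object),
        name=f"polyA_{exact_len}",
    )


def _log_odds(pwm: PWM, background: float = 0.25, pseudo: float = 1e-3) -> np.ndarray:
    return np.log((pwm.matrix + pseudo) / (background + pseudo))


def pwm_refine_sites(
    genome_seq: str,
    regions: FeatureAnchorSet,
    pwm: PWM,
    radius: int = 100,
    chrom: str | None = None,
) -> FeatureAnchorSet:
    """Refine approximate peak centers to exact motif positions.

    Each region (anchor +/- ``radius``) is scanned with the PWM log-odds
    score on both strands (the reverse strand scores the reverse
    complement); the maximum becomes the refined anchor, placed at the
    motif center, with the winning score and strand.  Ties break to the
    leftmost position, then to the + strand.  Regions too short for the
    motif are skipped with a warning.
    """
    codes = encode_bases(genome_seq.upper())
    if (codes > 3).any():
        # N bases would need masking; keep the scan simple and explicit
        raise ValueError("genome sequence must be N-free for PWM scanning")
    n = len(codes)
    w = pwm.width
    lo_fwd = _log_odds(pwm)
    lo_rev = _log_odds(pwm.reverse_complement())

    out_chrom, out_pos, out_strand, out_score = [], [], [], []
    for a in range(len(regions)):
        p = int(regions.position[a])
        start = max(1, p - radius)
        end = min(n, p + radius)
        seg = codes[start - 1 : end]
        if len(seg) < w:
            logger.warning(
                "region at %s:%d shorter than PWM width %d; skipped",
                regions.chrom[a], p, w,
            )
            continue
        wins = np.lib.stride_tricks.sliding_window_view(seg, w)
        cols = np.arange(w)
        s_fwd = lo_fwd[cols, wins].sum(axis=1)
        s_rev = lo_rev[cols, wins].sum(axis=1)
        # tie-break: leftmost, then '+': argmax returns the first maximum,
        # and we compare forward before reverse at equal score/position.
        i_fwd, i_rev = int(s_fwd.argmax()), int(s_rev.argmax())
        best_f, best_r = s_fwd[i_fwd], s_rev[i_rev]
        if best_r > best_f or (best_r == best_f and i_rev < i_fwd):
            idx, strand, score = i_rev, "-", best_r
        else:
            idx, strand, score = i_fwd, "+", best_f
        motif_start = start + idx  # 1-based start of motif window
        out_chrom.append(regions.chrom[a] if chrom is None else chrom)
        out_pos.append(motif_start + (w - 1) // 2)
        out_strand.append(strand)
        out_score.append(float(score))
    return FeatureAnchorSet(
        chrom=np.array(out_chrom, dtype=object),
        position=np.array(out_pos, dtype=np.int64),
        strand=np.array(out_strand, dtype=object),
        score=np.array(out_score, dtype=float),
        name=f"{regions.name}_refined",
    )


def standardize_track(track: CScoreTrack) -> CScoreTrack:
    """Z-score a signal track (mean 0, sd 1 over its scored positions) —
    the normalization applied to occupancy/positioning scores before
    profiling so they are comparable with the genome average."""
    sd = track.scores.std()
    if sd == 0:
        raise ValueError("constant track cannot be standardized")
    return CScoreTrack(
        chrom=track.chrom,
        positions=track.positions.copy(),
        scores=(track.scores - track.scores.mean()) / sd,
        window_width=track.window_width,
    )
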