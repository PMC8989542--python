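"""Synthetic loop-seq-style libraries and genomes with a documented
ground-truth cyclizability oracle.

The oracle is a *test scaffold*, not a claim about true DNA mechanics: it
encodes, in closed form, the three sequence determinants that dominate
measured intrinsic cyclizability — phase-coherent 10-bp periodicity of
WW (= AA/AT/TA/TT) dinucleotides, overall WW content, and the stiffness
penalty of poly(dA:dT) tracts::

    score(s) = w_per * A(s) + w_ww * f_WW(s) - w_polyA * P(s)

where ``f_WW`` is the fraction of dinucleotide positions carrying a WW
2-mer, ``A`` is the phase-coherent periodicity amplitude
``(2/L) * |sum_t I_WW(t) * exp(2*pi*i*t/period)|``, and ``P`` sums
``max(0, run_length - 4)`` over maximal pure-A and pure-T runs.  Libraries
pair sequences with ``oracle + Gaussian noise`` labels, standardized to
mean 0 / sd 1 like a real training library.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from itertools import groupby
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .profiles import FeatureAnchorSet
from .sequence import BASES, encode_bases
from .training import SequenceLibrary, standardize_labels
from .markov import PWM

_LOOKUP = np.array(list(BASES))


@dataclass(frozen=True)
class OracleParams:
    """Weights and shape of the synthetic cyclizability oracle.

    w_per : weight of the 10-bp periodicity amplitude (default 1.0)
    w_ww : weight of WW-dinucleotide content (default 0.5)
    w_polyA : penalty per poly(dA:dT) base beyond run length 4 (default 0.3)
    period : periodicity in bp (default 10.0; 10.5 is the other natural choice)
    noise_sd : sd of the additive Gaussian label noise (default 0.3)
    """

    w_per: float = 1.0
    w_ww: float = 0.5
    w_polyA: float = 0.3
    period: float = 10.0
    noise_sd: float = 0.3

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.period <= 0:
            raise ValueError("period must be positive")


def _polyA_penalty(codes: np.ndarray) -> float:
    pen = 0
    for base, run in groupby(codes):
        if base in (0, 3):  # A or T
            pen += max(0, sum(1 for _ in run) - 4)
    return float(pen)


def oracle_score(seq: str, params: OracleParams = OracleParams()) -> float:
    """Noiseless ground-truth cyclizability of a sequence (length >= 10)."""
    codes = encode_bases(seq.upper())
    L = len(codes)
    if L < 10:
        raise ValueError("oracle is defined for sequences of length >= 10")
    if (codes > 3).any():
        raise ValueError("oracle sequences must be N-free")
    is_at = (codes == 0) | (codes == 3)
    ww = is_at[:-1] & is_at[1:]  # WW 2-mer starting at t (0-based)
    f_ww = float(ww.mean())
    t = np.arange(1, L)  # 1-based dinucleotide start positions
    amp = (2.0 / L) * abs(np.sum(ww * np.exp(2j * np.pi * t / params.period)))
    pen = _polyA_penalty(codes)
    return params.w_per * float(amp) + params.w_ww * f_ww - params.w_polyA * pen


def oracle_scores(seqs: Sequence[str], params: OracleParams = OracleParams()) -> np.ndarray:
    return np.array([oracle_score(s, params) for s in seqs])


LIBRARY_CLASSES = ("random", "periodic", "polyA")


#: G+C fraction of the periodic-class background.  Rotationally positioned
#: nucleosomal sequence shows WW at one helical phase and GG/GC/CG/CC at the
#: counter-phase, so the inter-word background is SS-enriched.
_PERIODIC_BG_GC = 0.7


def _plant_periodic(codes: np.ndarray, rng: np.random.Generator, period: float) -> None:
    """Plant 4-bp A/T words at period-spaced starts (random global phase)
    on a G/C-enriched background."""
    L = len(codes)
    gc = _PERIODIC_BG_GC
    codes[:] = rng.choice(4, size=L, p=[(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    step = int(round(period))
    phase = int(rng.integers(0, step))
    for start in range(phase, L, step):
        stop = min(start + 4, L)
        codes[start:stop] = np.where(rng.random(stop - start) < 0.5, 0, 3)


def _plant_polyA(codes: np.ndarray, rng: np.random.Generator) -> None:
    L = len(codes)
    run = int(rng.integers(5, 10))
    base = 0 if rng.random() < 0.5 else 3
    start = int(rng.integers(0, L - run + 1))
    codes[start : start + run] = base


def make_library(
    n: int,
    L: int = 50,
    mix: Tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3),
    params: OracleParams = OracleParams(),
    seed: int = 0,
    name: str = "synthetic",
    standardize: bool = True,
) -> SequenceLibrary:
    """Generate a loop-seq-like library of ``n`` L-bp sequences.

    ``mix`` gives the class fractions of (random, periodic-enriched,
    polyA-enriched) sequences.  Labels are ``oracle + N(0, noise_sd)``,
    standardized to mean 0 / sd 1 (like a real training library).  The
    class of each sequence is recorded in ``metadata['classes']``.
    """
    mix_arr = np.asarray(mix, dtype=float)
    if mix_arr.shape != (3,) or (mix_arr < 0).any() or abs(mix_arr.sum() - 1.0) > 1e-9:
        raise ValueError("mix must be 3 non-negative fractions summing to 1")
    rng = np.random.default_rng(seed)
    classes = rng.choice(3, size=n, p=mix_arr)
    seqs: List[str] = []
    for cls in classes:
        codes = rng.integers(0, 4, size=L)
        if cls == 1:
            _plant_periodic(codes, rng, params.period)
        elif cls == 2:
            _plant_polyA(codes, rng)
        seqs.append("".join(_LOOKUP[codes]))
    labels = oracle_scores(seqs, params)
    if params.noise_sd > 0:
        labels = labels + rng.normal(0.0, params.noise_sd, size=n)
    lib = SequenceLibrary(
        name=name,
        sequences=seqs,
        labels=labels,
        metadata={
            "classes": np.array(LIBRARY_CLASSES, dtype=object)[classes].tolist(),
            "oracle_params": asdict(params),
            "seed": seed,
        },
    )
    if standardize:
        lib, _, _ = standardize_labels(lib)
    return lib


# ------------------------------------------------------------ genome plants

def _place(
    occupied: np.ndarray, footprint: int, rng: np.random.Generator, tries: int = 200
) -> int:
    """Random non-overlapping 0-based start for a footprint; error when the
    plan cannot be placed."""
    L = len(occupied)
    if footprint > L:
        raise ValueError("feature larger than genome")
    for _ in range(tries):
        start = int(rng.integers(0, L - footprint + 1))
        if not occupied[start : start + footprint].any():
            occupied[start : start + footprint] = True
            return start
    raise ValueError("could not place all features: genome too crowded")


def make_synthetic_genome(
    length: int,
    n_nucleosomes: int = 0,
    nucleosome_halfwidth: int = 70,
    polyA_tract_lengths: Sequence[int] = (),
    pwm: PWM | None = None,
    n_pwm_sites: int = 0,
    seed: int = 0,
    chrom: str = "chrSynth",
) -> Tuple[str, Dict[str, FeatureAnchorSet]]:
    """A uniform-background genome with planted features and truth anchors.

    Plants (greedy non-overlapping random placement; error if impossible):

    * nucleosome-like elements — 4-bp WW words at 10-bp spacing across
      dyad +/- ``nucleosome_halfwidth``; truth anchor at the dyad;
    * poly(dA:dT) tracts of stated *exact* lengths (guard bases flank each
      run so maximality holds); anchor at the run center, strand + for A
      and - for T runs;
    * PWM sites drawn column-wise from the motif, planted on a random
      strand; anchor at the motif center with that strand.
    """
    rng = np.random.default_rng(seed)
    codes = rng.integers(0, 4, size=length)
    occupied = np.zeros(length, dtype=bool)
    truth: Dict[str, FeatureAnchorSet] = {}

    dyads = []
    footprint = 2 * nucleosome_halfwidth + 1
    for _ in range(n_nucleosomes):
        start = _place(occupied, footprint, rng)
        dyad = start + nucleosome_halfwidth  # 0-based
        for off in range(-nucleosome_halfwidth, nucleosome_halfwidth + 1, 10):
            s = dyad + off
            stop = min(s + 4, length)
            codes[s:stop] = np.where(rng.random(stop - s) < 0.5, 0, 3)
        dyads.append(dyad + 1)
    if n_nucleosomes:
        truth["nucleosomes"] = FeatureAnchorSet(
            chrom=np.full(len(dyads), chrom, dtype=object),
            position=np.array(dyads, dtype=np.int64),
            score=rng.random(len(dyads)),  # NCP-like positioning strength
            name="nucleosomes",
        )

    tract_pos, tract_strand = [], []
    for tract_len in polyA_tract_lengths:
        start = _place(occupied, tract_len + 2, rng)  # +2 guard bases
        base = 0 if rng.random() < 0.5 else 3
        other = [b for b in (1, 2)]  # C/G guards never extend an A/T run
        codes[start] = other[int(rng.integers(0, 2))]
        codes[start + 1 : start + 1 + tract_len] = base
        codes[start + 1 + tract_len] = other[int(rng.integers(0, 2))]
        run_start_1b = start + 2  # 1-based first base of the run
        tract_pos.append(run_start_1b + (tract_len - 1) // 2)
        tract_strand.append("+" if base == 0 else "-")
    if polyA_tract_lengths:
        truth["polyA"] = FeatureAnchorSet(
            chrom=np.full(len(tract_pos), chrom, dtype=object),
            position=np.array(tract_pos, dtype=np.int64),
            strand=np.array(tract_strand, dtype=object),
            name="polyA",
        )

    if pwm is not None and n_pwm_sites > 0:
        w = pwm.width
        site_pos, site_strand = [], []
        motifs = pwm.sample(n_pwm_sites, rng)
        # sites are planted in isolation (a margin on each side stays
        # feature-free) so every refinement region contains one true site
        margin = 150
        for i in range(n_pwm_sites):
            start = _place(occupied, w + 2 * margin, rng) + margin
            motif = motifs[i]
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "-":
                motif = 3 - motif[::-1]  # reverse complement in code space
            codes[start : start + w] = motif
            site_pos.append(start + 1 + (w - 1) // 2)
            site_strand.append(strand)
        truth["pwm_sites"] = FeatureAnchorSet(
            chrom=np.full(len(site_pos), chrom, dtype=object),
            position=np.array(site_pos, dtype=np.int64),
            strand=np.array(site_strand, dtype=object),
            name="pwm_sites",
        )

    return "".join(_LOOKUP[codes]), truth
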