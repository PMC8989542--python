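"""Time-dependent (position-inhomogeneous) Markov-chain sequence models and
the motif-simulation machinery of the simulation studies.

An order-k time-dependent Markov chain fitted on an alignment of
equal-length sequences stores, for every position t, the conditional
distribution of the base at t given the previous ``min(t, k)`` bases.
Sampling from it preserves the position-specific (k+1)-mer distribution of
the training alignment exactly in expectation — the property that makes
these models the right null for asking how much of a signal is explained
by local k-mer composition.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import List, Sequence

import numpy as np

from .sequence import BASES, encode_bases

_N_BASES = 4


def _encode_matrix(seqs: Sequence[str]) -> np.ndarray:
    if not seqs:
        raise ValueError("empty sequence set")
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise ValueError("aligned sequences must have equal length")
    mat = encode_bases("".join(seqs)).reshape(len(seqs), L).astype(np.int64)
    if (mat > 3).any():
        raise ValueError("aligned sequences must be N-free")
    return mat


class TimeDependentMarkovChain:
    """Order-k position-specific Markov model over {A,C,G,T}.

    Parameters
    ----------
    order : int in {1, 2, 3}
        Context length; higher orders were not found worthwhile at
        desk-scale sample sizes (parameter count grows as 4^k).
    pseudocount : float >= 0
        Additive smoothing per (context, base) cell; 0 reproduces training
        k-mer frequencies exactly.  Never-seen contexts fall back to the
        uniform distribution.

    Attributes
    ----------
    tables_ : list of arrays
        ``tables_[t]`` has shape (4^min(t, order), 4): conditional
        distributions at position t (0-based) given the previous
        min(t, order) bases, contexts coded base-4 (A=0..T=3), oldest base
        most significant.
    length_ : int
        Alignment length L.
    """

    def __init__(self, order: int = 1, pseudocount: float = 0.0) -> None:
        if order not in (1, 2, 3):
            raise ValueError("order must be 1, 2 or 3")
        if pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")
        self.order = order
        self.pseudocount = pseudocount

    # ------------------------------------------------------------------ fit
    def fit(self, sequences: Sequence[str]) -> "TimeDependentMarkovChain":
        mat = _encode_matrix(sequences)
        n, L = mat.shape
        self.length_ = L
        self.n_training_ = n
        self.tables_ = []
        for t in range(L):
            k = min(t, self.order)
            n_ctx = _N_BASES**k
            ctx = np.zeros(n, dtype=np.int64)
            for j in range(t - k, t):
                ctx = ctx * _N_BASES + mat[:, j]
            counts = np.bincount(
                ctx * _N_BASES + mat[:, t], minlength=n_ctx * _N_BASES
            ).reshape(n_ctx, _N_BASES).astype(float)
            counts += self.pseudocount
            totals = counts.sum(axis=1, keepdims=True)
            probs = np.full((n_ctx, _N_BASES), 0.25)
            seen = totals[:, 0] > 0
            probs[seen] = counts[seen] / totals[seen]
            self.tables_.append(probs)
        return self

    # --------------------------------------------------------------- sample
    def sample(self, n: int, seed: int = 0) -> List[str]:
        """Draw ``n`` sequences left to right from the fitted conditionals."""
        if not hasattr(self, "tables_"):
            raise RuntimeError("fit the model before sampling")
        rng = np.random.default_rng(seed)
        L = self.length_
        out = np.empty((n, L), dtype=np.int64)
        ctx = np.zeros(n, dtype=np.int64)
        for t in range(L):
            k = min(t, self.order)
            probs = self.tables_[t][ctx]  # (n, 4)
            cum = probs.cumsum(axis=1)
            u = rng.random(n)
            base = (u[:, None] >= cum).sum(axis=1)
            out[:, t] = base
            if t + 1 < L:
                k_next = min(t + 1, self.order)
                ctx = (ctx * _N_BASES + base) % (_N_BASES**k_next)
        lookup = np.array(list(BASES))
        return ["".join(row) for row in lookup[out]]

    # ---------------------------------------------------- analytic k-mer law
    def implied_kmer_distribution(self, k: int) -> np.ndarray:
        """Exact position-specific k-mer law implied by the fitted model.

        Returns an (L - k + 1, 4^k) array: row i is the distribution of the
        k-mer starting at position i (0-based) under the model, computed by
        dynamic programming over context joints (no sampling noise).  For
        k <= order + 1 and pseudocount 0 this equals the training k-mer
        frequencies exactly.
        """
        if k < 1:
            raise ValueError("k must be >= 1")
        L = self.length_
        m = max(self.order, k - 1)  # window length carried through the DP
        # joint over the last min(t+1, m) bases after emitting position t
        joint = self.tables_[0][0].copy()  # t = 0: distribution over 1 base
        width = 1
        kmer_rows = []

        def emit(joint_w: np.ndarray, w: int) -> None:
            # record k-mer law for the k-mer ending at current position
            if w >= k:
                kmer_rows.append(
                    joint_w.reshape(_N_BASES ** (w - k), _N_BASES**k).sum(axis=0)
                )

        emit(joint, width)
        for t in range(1, L):
            kt = min(t, self.order)
            table = self.tables_[t]  # (4^kt, 4)
            # context = last kt bases of the carried window
            lead = _N_BASES ** (width - kt)
            j = joint.reshape(lead, _N_BASES**kt)
            # new joint over (window, next base)
            nj = j[:, :, None] * table[None, :, :]
            width += 1
            joint = nj.reshape(-1)
            if width > m + 1:
                # drop the oldest base
                joint = joint.reshape(_N_BASES, -1).sum(axis=0)
                width -= 1
            emit(joint, width)
        return np.vstack(kmer_rows)

    # ---------------------------------------------------------- persistence
    def to_json(self) -> str:
        import json

        return json.dumps(
            {
                "order": self.order,
                "pseudocount": self.pseudocount,
                "length": self.length_,
                "tables": [t.tolist() for t in self.tables_],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "TimeDependentMarkovChain":
        import json

        d = json.loads(text)
        model = cls(order=d["order"], pseudocount=d["pseudocount"])
        model.length_ = d["length"]
        model.tables_ = [np.array(t) for t in d["tables"]]
        return model


def empirical_kmer_distribution(seqs: Sequence[str], k: int) -> np.ndarray:
    """Position-specific empirical k-mer frequencies of an alignment:
    (L - k + 1, 4^k), rows summing to 1."""
    mat = _encode_matrix(seqs)
    n, L = mat.shape
    rows = []
    for t in range(L - k + 1):
        code = np.zeros(n, dtype=np.int64)
        for j in range(t, t + k):
            code = code * _N_BASES + mat[:, j]
        rows.append(np.bincount(code, minlength=_N_BASES**k) / n)
    return np.vstack(rows)


def fit_marginal(seqs: Sequence[str]) -> np.ndarray:
    """Marginal A/C/G/T composition over all positions of all sequences."""
    codes = encode_bases("".join(seqs))
    if (codes > 3).any():
        raise ValueError("sequences must be N-free")
    return np.bincount(codes, minlength=_N_BASES) / len(codes)


def simulate_random(
    composition: Sequence[float], length: int, n: int, seed: int = 0
) -> List[str]:
    """i.i.d. sequences with the given base composition at every position."""
    comp = np.asarray(composition, dtype=float)
    if comp.shape != (4,) or (comp < 0).any() or abs(comp.sum() - 1.0) > 1e-9:
        raise ValueError("composition must be 4 non-negative values summing to 1")
    rng = np.random.default_rng(seed)
    draws = rng.choice(4, size=(n, length), p=comp)
    lookup = np.array(list(BASES))
    return ["".join(row) for row in lookup[draws]]


def select_top_decile(
    seqs: Sequence[str], scores: Sequence[float]
) -> tuple[List[str], np.ndarray]:
    """Items whose score lies strictly above the empirical 90th percentile
    (linear-interpolation quantile definition)."""
    scores = np.asarray(scores, dtype=float)
    if len(seqs) != len(scores):
        raise ValueError("seqs and scores length mismatch")
    if len(scores) == 0:
        raise ValueError("empty input")
    cut = float(np.percentile(scores, 90))
    keep = np.flatnonzero(scores > cut)
    return [seqs[i] for i in keep], scores[keep]


# -------------------------------------------------------------------- PWMs

@dataclass
class PWM:
    """Position weight matrix: per-position base probabilities, rows are
    positions, columns the (A, C, G, T) channels."""

    matrix: np.ndarray
    name: str = "pwm"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM matrix must be (width, 4)")
        if (self.matrix < 0).any():
            raise ValueError("PWM entries must be non-negative")
        sums = self.matrix.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("PWM columns must each sum to 1")

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    def reverse_complement(self) -> "PWM":
        return PWM(self.matrix[::-1, ::-1], name=self.name + "_rc")

    @classmethod
    def from_counts(cls, counts: np.ndarray, name: str = "pwm") -> "PWM":
        counts = np.asarray(counts, dtype=float)
        return cls(counts / counts.sum(axis=1, keepdims=True), name=name)

    @classmethod
    def from_jaspar(cls, path) -> "PWM":
        """Read a JASPAR-style text matrix::

            >MA0000.0 NAME
            A [ 1 2 3 ... ]
            C [ ... ]
            G [ ... ]
            T [ ... ]

        Counts or probabilities; rows are column-normalized on load.  Plain
        4-row whitespace matrices (no brackets/labels) are also accepted.
        """
        name = Path(str(path)).stem
        rows: dict[str, List[float]] = {}
        order = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith(">"):
                    name = line[1:].split()[0]
                    continue
                token = line[0].upper()
                if token in "ACGT" and (line[1:].lstrip().startswith("[") or not line[1].isdigit()):
                    values = line[1:].strip().strip("[]").split()
                    rows[token] = [float(v) for v in values]
                    order.append(token)
                else:
                    order.append(str(len(order)))
                    rows[order[-1]] = [float(v) for v in line.split()]
        if set("ACGT") <= set(rows):
            counts = np.array([rows[b] for b in "ACGT"]).T
        elif len(rows) == 4:
            counts = np.array([rows[k] for k in order]).T
        else:
            raise ValueError("unrecognized PWM file layout")
        return cls.from_counts(counts, name=name)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """(n, width) integer base codes drawn column-wise."""
        out = np.empty((n, self.width), dtype=np.int64)
        cum = self.matrix.cumsum(axis=1)
        u = rng.random((n, self.width))
        for j in range(self.width):
            out[:, j] = (u[:, j][:, None] >= cum[j][None, :]).sum(axis=1)
        return out


def simulate_pwm_padded(
    pwm: PWM,
    total_length: int = 201,
    n: int = 1000,
    seed: int = 0,
    pad_composition: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
) -> List[str]:
    """Motif draws embedded centrally in random flanks.

    Each sequence is ``pad + motif + pad`` where the motif is drawn
    column-wise from the PWM and the two equal-length pads are i.i.d. under
    ``pad_composition``.  For a 19-wide motif and total length 201 the pads
    are 91 bp each (motif occupies 1-based positions 92..110).
    """
    pad_len, rem = divmod(total_length - pwm.width, 2)
    if rem != 0 or pad_len < 0:
        nearest = pwm.width + 2 * max(0, round((total_length - pwm.width) / 2))
        raise ValueError(
            f"total_length - width must be even and non-negative; "
            f"nearest valid total_length is {nearest}"
        )
    comp = np.asarray(pad_composition, dtype=float)
    if comp.shape != (4,) or abs(comp.sum() - 1.0) > 1e-9:
        raise ValueError("pad composition must be 4 values summing to 1")
    rng = np.random.default_rng(seed)
    motif = pwm.sample(n, rng)
    pads = rng.choice(4, size=(n, 2 * pad_len), p=comp)
    full = np.concatenate([pads[:, :pad_len], motif, pads[:, pad_len:]], axis=1)
    lookup = np.array(list(BASES))
    return ["".join(row) for row in lookup[full]]
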