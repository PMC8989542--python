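"""Training-protocol operations: label standardization, k-fold cross
validation with early stopping, detrend calibration and Pearson evaluation.

Loop-seq-style cyclizability labels are comparable across libraries only up
to an additive library-specific constant, so correlation (not absolute
error) is the evaluation metric, and training labels are standardized to
zero mean / unit variance — the C-score scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import KFold

from .model import DegenerateLabelsError, IRLSTMRegressor, fit_detrend_values


@dataclass
class SequenceLibrary:
    """Fixed-length sequences paired with real-valued cyclizability labels.

    ``label_offset_note`` records that measured scores are comparable across
    libraries only up to an additive library constant.
    """

    name: str
    sequences: List[str]
    labels: np.ndarray
    metadata: dict = field(default_factory=dict)
    label_offset_note: str = (
        "scores comparable across libraries only up to an additive constant"
    )

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=float)
        if len(self.sequences) != len(self.labels):
            raise ValueError("sequences and labels length mismatch")

    def __len__(self) -> int:
        return len(self.sequences)

    def subset(self, idx, name: str | None = None) -> "SequenceLibrary":
        idx = np.asarray(idx)
        return SequenceLibrary(
            name=name or self.name,
            sequences=[self.sequences[i] for i in idx],
            labels=self.labels[idx],
            metadata=dict(self.metadata),
        )

    def to_tsv(self, path) -> None:
        pd.DataFrame({"sequence": self.sequences, "score": self.labels}).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path, name: str | None = None) -> "SequenceLibrary":
        path = Path(path)
        sep = "," if path.suffix.lower() == ".csv" else "\t"
        df = pd.read_csv(path, sep=sep)
        if not {"sequence", "score"} <= set(df.columns):
            raise ValueError("library file needs 'sequence' and 'score' columns")
        return cls(
            name=name or path.stem,
            sequences=[s.upper() for s in df["sequence"]],
            labels=df["score"].to_numpy(dtype=float),
        )


@dataclass
class CVResult:
    fold_assignments: np.ndarray
    per_fold_models: List[IRLSTMRegressor]
    per_fold_pearson: List[float]
    best_fold_index: int

    def report(self) -> pd.DataFrame:
        rows = []
        for f, (m, r) in enumerate(zip(self.per_fold_models, self.per_fold_pearson)):
            n_test = int((self.fold_assignments == f + 1).sum())
            rows.append(
                {
                    "fold": f + 1,
                    "n_train": int(len(self.fold_assignments)) - n_test,
                    "n_test": n_test,
                    "pearson": r,
                    "epochs_run": m.n_epochs_,
                }
            )
        return pd.DataFrame(rows)


def standardize_labels(lib: SequenceLibrary) -> tuple[SequenceLibrary, float, float]:
    """Standardize a library's labels to sample mean 0 and sample sd 1.

    Returns the standardized library plus the constants needed to un-scale.
    """
    mean = float(lib.labels.mean())
    std = float(lib.labels.std())
    if std == 0.0:
        raise DegenerateLabelsError("labels have zero variance; cannot standardize")
    out = SequenceLibrary(
        name=lib.name,
        sequences=list(lib.sequences),
        labels=(lib.labels - mean) / std,
        metadata={**lib.metadata, "label_mean": mean, "label_std": std},
    )
    return out, mean, std


def kfold_split(n: int, k: int = 10, seed: int = 0) -> np.ndarray:
    """Random fold assignment 1..k per item; fold sizes differ by at most 1."""
    if n < k:
        raise ValueError(f"cannot split {n} items into {k} folds")
    assignments = np.empty(n, dtype=int)
    splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    for fold, (_, test_idx) in enumerate(splitter.split(np.arange(n)), start=1):
        assignments[test_idx] = fold
    return assignments


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation; errors on constant input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("pearson needs two equal-length vectors of length >= 2")
    if x.std() == 0.0 or y.std() == 0.0:
        raise DegenerateLabelsError("correlation undefined for constant vector")
    return float(stats.pearsonr(x, y)[0])


def train_model(
    train: SequenceLibrary,
    val: SequenceLibrary | None = None,
    config: dict | None = None,
    seed: int = 0,
) -> IRLSTMRegressor:
    """Fit an IR+LSTM model on a (standardized) library.

    ``config`` overrides estimator parameters (e.g. ``max_epochs``,
    ``batch_size``, ``patience``, ``learning_rate``).  When ``val`` is None
    an internal 10% split handles early stopping and detrend calibration.
    """
    params = dict(random_state=seed)
    if config:
        params.update(config)
    est = IRLSTMRegressor(**params)
    if val is not None:
        if len(val) == 0:
            raise ValueError("empty validation set")
        est.fit(train.sequences, train.labels, X_val=val.sequences, y_val=val.labels)
    else:
        est.fit(train.sequences, train.labels)
    return est


def fit_detrend(model: IRLSTMRegressor, calib: SequenceLibrary) -> tuple[float, float]:
    """Calibrate the linear detrend of ``model`` on a held-out library.

    Regresses calibration labels on the model's raw reverse-complement-
    averaged outputs and stores ``(a, b)`` on the model so that
    ``predict`` applies ``a + b * raw``.
    """
    raw = model.raw_scores(calib.sequences)
    a, b = fit_detrend_values(raw, calib.labels)
    model.detrend_a_, model.detrend_b_ = a, b
    return a, b


def cross_validate(
    lib: SequenceLibrary,
    config: dict | None = None,
    k: int = 10,
    seed: int = 0,
) -> CVResult:
    """k-fold cross validation of the IR+LSTM on a standardized library.

    Per fold: train on the other k-1 folds (an internal validation split is
    carved from them for early stopping and detrend calibration) and report
    Pearson correlation on the held-out fold.  The best fold is the one
    maximizing held-out Pearson, ties broken by lowest fold index.
    """
    assignments = kfold_split(len(lib), k=k, seed=seed)
    models: List[IRLSTMRegressor] = []
    pearsons: List[float] = []
    for fold in range(1, k + 1):
        test_idx = np.flatnonzero(assignments == fold)
        train_idx = np.flatnonzero(assignments != fold)
        model = train_model(lib.subset(train_idx), config=config, seed=seed + fold)
        pred = model.predict([lib.sequences[i] for i in test_idx])
        pearsons.append(pearson(pred, lib.labels[test_idx]))
        models.append(model)
    best = int(np.argmax(pearsons))
    return CVResult(
        fold_assignments=assignments,
        per_fold_models=models,
        per_fold_pearson=pearsons,
        best_fold_index=best,
    )
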