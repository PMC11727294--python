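"""Sequence regression from PPG segments to MAP, with LOSO evaluation.

The regressor is a lightweight convolutional random-kernel model in the
ROCKET family: a bank of random 1-D convolution kernels (random length,
weights, bias, dilation and input channel) is applied to each 5 x 2000
segment; each kernel contributes two pooled features (max activation and
proportion of positive values).  Together with simple per-channel summary
statistics these feed a standardized ridge readout.  The model is a
scikit-learn estimator and composes with sklearn model selection.

Evaluation uses leave-one-subject-out (LOSO) splits: each subject is held
out once as the test set, one further subject serves as validation, and
the remainder (about two thirds of the data) trains the model, so no
subject leaks between fit and evaluation.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.linear_model import RidgeCV
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_is_fitted

from .metrics import AgreementReport, paired_agreement
from .ppg import PPGSegment
from .trace import ValidationError


def _segments_to_tensor(segments: Sequence[PPGSegment]) -> np.ndarray:
    X = np.stack([s.features for s in segments])
    if X.ndim != 3:
        raise ValidationError("expected a (n, channels, length) stack")
    return X


class RandomKernelMAPRegressor(BaseEstimator, RegressorMixin):
    """Random-convolution-kernel regressor from PPG segments to MAP.

    Parameters
    ----------
    n_kernels : int
        Size of the random kernel bank.
    kernel_lengths : tuple of int
        Candidate kernel lengths, drawn uniformly per kernel.
    max_dilation_exp : int
        Dilations are 2**U{0..max_dilation_exp} (realized by strided input).
    alphas : array-like
        Ridge regularization grid for the cross-validated readout.
    random_state : int
        Seeds the kernel bank; the model is deterministic given it.
    """

    def __init__(
        self,
        n_kernels: int = 150,
        kernel_lengths: tuple[int, ...] = (7, 9, 11),
        max_dilation_exp: int = 4,
        alphas: tuple[float, ...] = (0.1, 1.0, 10.0, 100.0, 1000.0),
        random_state: int = 0,
    ):
        self.n_kernels = n_kernels
        self.kernel_lengths = kernel_lengths
        self.max_dilation_exp = max_dilation_exp
        self.alphas = alphas
        self.random_state = random_state

    def _make_kernels(self, n_channels: int) -> list[dict]:
        rng = np.random.default_rng(self.random_state)
        kernels = []
        for _ in range(self.n_kernels):
            length = int(rng.choice(self.kernel_lengths))
            w = rng.normal(0.0, 1.0, size=length)
            w -= w.mean()
            kernels.append(
                {
                    "weights": w,
                    "bias": float(rng.uniform(-1.0, 1.0)),
                    "dilation": int(2 ** rng.integers(0, self.max_dilation_exp + 1)),
                    "channel": int(rng.integers(0, n_channels)),
                }
            )
        return kernels

    def _transform(self, X: np.ndarray) -> np.ndarray:
        n, n_ch, _ = X.shape
        # per-channel scale normalization: derivative channels span orders
        # of magnitude, which would otherwise dominate the kernel responses
        feats = np.empty((n, 2 * len(self.kernels_) + 3 * n_ch))
        for i in range(n):
            col = 0
            for k in self.kernels_:
                x = X[i, k["channel"], :: k["dilation"]]
                scale = np.std(x) or 1.0
                conv = np.convolve(x / scale, k["weights"], mode="valid") + k["bias"]
                feats[i, col] = conv.max()
                feats[i, col + 1] = np.mean(conv > 0)
                col += 2
            for c in range(n_ch):
                x = X[i, c]
                feats[i, col : col + 3] = (x.mean(), x.std(), np.ptp(x))
                col += 3
        return feats

    def fit(self, X, y):
        """Fit on segments: X is (n, 5, length) or a list of PPGSegment."""
        if len(X) and isinstance(X[0], PPGSegment):
            X = _segments_to_tensor(X)
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 3:
            raise ValidationError("X must be (n_segments, n_channels, n_samples)")
        self.n_channels_ = X.shape[1]
        self.kernels_ = self._make_kernels(self.n_channels_)
        self.readout_ = make_pipeline(
            StandardScaler(), RidgeCV(alphas=np.asarray(self.alphas))
        )
        self.readout_.fit(self._transform(X), y)
        return self

    def predict(self, X):
        check_is_fitted(self, "readout_")
        if len(X) and isinstance(X[0], PPGSegment):
            X = _segments_to_tensor(X)
        X = np.asarray(X, dtype=float)
        return self.readout_.predict(self._transform(X))


def loso_folds(subject_ids: Sequence[str]) -> list[dict]:
    """Leave-one-subject-out folds with a rotating validation subject.

    Each subject is the test set once; the next subject (cyclically) is
    validation; the rest train.  Needs >= 3 subjects.
    """
    subjects = list(dict.fromkeys(subject_ids))
    if len(subjects) < 3:
        raise ValidationError("LOSO needs at least 3 subjects")
    folds = []
    for i, test in enumerate(subjects):
        val = subjects[(i + 1) % len(subjects)]
        train = [s for s in subjects if s not in (test, val)]
        folds.append({"train": train, "val": val, "test": test})
    return folds


def train_predict(
    segments: Sequence[PPGSegment],
    model: Optional[RandomKernelMAPRegressor] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """LOSO train/predict over labeled segments.

    Returns one row per held-out segment: subject_id, start_time, y_true,
    y_pred, and the training-set mean label (the predict-the-mean baseline
    for that fold).
    """
    segments = list(segments)
    if not segments:
        raise ValidationError("no segments")
    by_subject: dict[str, list[PPGSegment]] = {}
    for s in segments:
        by_subject.setdefault(s.subject_id, []).append(s)
    folds = loso_folds(list(by_subject))
    rows = []
    for k, fold in enumerate(folds):
        train_segs = [s for sid in fold["train"] for s in by_subject[sid]]
        test_segs = by_subject[fold["test"]]
        est = model or RandomKernelMAPRegressor(random_state=seed + k)
        est = est.__class__(**{**est.get_params(), "random_state": seed + k})
        y_train = np.array([s.label for s in train_segs])
        est.fit(train_segs, y_train)
        y_pred = est.predict(test_segs)
        for s, yp in zip(test_segs, y_pred):
            rows.append(
                {
                    "subject_id": s.subject_id,
                    "start_time": s.start_time,
                    "y_true": s.label,
                    "y_pred": float(yp),
                    "train_mean": float(y_train.mean()),
                }
            )
    return pd.DataFrame(rows)


def evaluate_ppg(predictions: pd.DataFrame) -> dict[str, AgreementReport]:
    """Per-subject agreement between predicted and reference MAP."""
    out = {}
    for sid, grp in predictions.groupby("subject_id"):
        out[sid] = paired_agreement(
            grp["y_pred"].to_numpy(), grp["y_true"].to_numpy()
        )
    return out


def loso_summary(predictions: pd.DataFrame) -> dict[str, float]:
    """Pooled LOSO RMSE and the pooled predict-the-mean baseline RMSE."""
    err = predictions["y_pred"] - predictions["y_true"]
    base = predictions["train_mean"] - predictions["y_true"]
    return {
        "rmse": float(np.sqrt(np.mean(err**2))),
        "baseline_rmse": float(np.sqrt(np.mean(base**2))),
        "n_segments": int(len(predictions)),
    }
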