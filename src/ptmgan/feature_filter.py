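"""Pearson-correlation feature screening.

Features whose absolute Pearson correlation exceeds a threshold are discarded.
Two modes are provided:

``feature-label`` (default)
    Drop a column when ``|r(column, numeric class label)| > threshold``. Class
    labels enter as their integer indices (1..K); this encoding is arbitrary
    and configurable to a one-vs-rest per-class max-|r| via ``label_mode``.

``feature-feature``
    Greedy scan in column order; drop a column when ``|r| > threshold``
    against any column retained so far (redundancy screening).

Zero-variance columns are always removed first. The mask is fitted on
training rows only and then applied unchanged to validation/test folds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .encoders import FeatureMatrix


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation of two equal-length non-constant vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("inputs must be equal-length 1-D vectors of length >= 2")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant input has undefined correlation")
    xc, yc = x - x.mean(), y - y.mean()
    return float((xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc)))


@dataclass
class SelectionMask:
    """Kept-column record of a fitted correlation screen."""

    kept: np.ndarray
    mode: str
    threshold: float
    n_features_in: int
    scheme_summary: dict = field(default_factory=dict)

    def __post_init__(self):
        self.kept = np.asarray(self.kept, dtype=int)
        if len(self.kept) and (
            np.any(np.diff(self.kept) <= 0)
            or self.kept[0] < 0
            or self.kept[-1] >= self.n_features_in
        ):
            raise ValueError("kept indices must be strictly increasing and in range")

    def to_json(self, path) -> None:
        payload = {
            "mode": self.mode,
            "threshold": self.threshold,
            "n_features_in": self.n_features_in,
            "kept": self.kept.tolist(),
            "scheme_summary": self.scheme_summary,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "SelectionMask":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            np.array(payload["kept"], dtype=int),
            payload["mode"],
            payload["threshold"],
            payload["n_features_in"],
            payload.get("scheme_summary", {}),
        )


def fit_pcc_filter(
    fm: FeatureMatrix,
    labels: Optional[np.ndarray] = None,
    mode: str = "feature-label",
    threshold: float = 0.5,
    label_mode: str = "index",
) -> SelectionMask:
    """Fit a correlation screen on a training feature matrix.

    ``label_mode='index'`` correlates against the raw 1..K class index;
    ``label_mode='ovr-max'`` takes, per column, the maximum |r| over the K
    one-vs-rest indicator vectors.
    """
    X = fm.X
    n = X.shape[1]
    stds = X.std(axis=0)
    nonconst = stds > 0
    if mode == "feature-label":
        if labels is None:
            raise ValueError("feature-label mode needs labels")
        y = np.asarray(labels, dtype=float)
        Xc = X - X.mean(axis=0)
        denom = np.sqrt((Xc**2).sum(axis=0))
        denom[denom == 0] = np.inf
        if label_mode == "index":
            yc = y - y.mean()
            r = np.abs(Xc.T @ yc) / (denom * np.sqrt(yc @ yc))
        elif label_mode == "ovr-max":
            r = np.zeros(n)
            for cls in np.unique(y):
                ind = (y == cls).astype(float)
                ic = ind - ind.mean()
                r = np.maximum(r, np.abs(Xc.T @ ic) / (denom * np.sqrt(ic @ ic)))
        else:
            raise ValueError(f"unknown label_mode {label_mode!r}")
        keep = nonconst & (r <= threshold)
        kept = np.flatnonzero(keep)
    elif mode == "feature-feature":
        order = np.flatnonzero(nonconst)
        Xc = (X[:, order] - X[:, order].mean(axis=0)) / (
            stds[order] * np.sqrt(X.shape[0])
        )
        kept_local: list = []
        for j in range(len(order)):
            if kept_local:
                r = np.abs(Xc[:, kept_local].T @ Xc[:, j])
                if (r > threshold).any():
                    continue
            kept_local.append(j)
        kept = order[kept_local]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if len(kept) == 0:
        raise ValueError("correlation screen removed every feature")
    summary = (
        fm.provenance.iloc[kept]["scheme"].value_counts().to_dict()
        if fm.provenance is not None
        else {}
    )
    return SelectionMask(kept, mode, threshold, n, summary)


def apply_mask(mask: SelectionMask, fm: FeatureMatrix) -> FeatureMatrix:
    """Apply a fitted mask; surviving columns keep their provenance."""
    if fm.n_features != mask.n_features_in:
        raise ValueError("feature matrix width differs from the fitted width")
    return fm.subset(mask.kept)


@dataclass
class PccFilter:
    """Convenience fit/transform wrapper around the correlation screen."""

    mode: str = "feature-label"
    threshold: float = 0.5
    label_mode: str = "index"
    mask_: Optional[SelectionMask] = None

    def fit(self, fm: FeatureMatrix, labels=None) -> "PccFilter":
        self.mask_ = fit_pcc_filter(fm, labels, self.mode, self.threshold, self.label_mode)
        return self

    def transform(self, fm: FeatureMatrix) -> FeatureMatrix:
        if self.mask_ is None:
            raise RuntimeError("filter is not fitted")
        return apply_mask(self.mask_, fm)

    def fit_transform(self, fm: FeatureMatrix, labels=None) -> FeatureMatrix:
        return self.fit(fm, labels).transform(fm)
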