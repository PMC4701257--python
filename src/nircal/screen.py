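"""Spectral description by PCA and the two outlier-elimination criteria.

The Global-H statistic is the Mahalanobis distance of a spectrum in
standardized principal-component (or latent-factor) score space divided by
the number of factors, so its training-set mean is ~1 and the conventional
threshold H > 3 marks a spectrum from a different population.  The T
criterion flags chemistry outliers: samples whose calibration residual
exceeds 2.5 residual standard deviations are removed and the model refit,
for at most a configured number of passes.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA

__all__ = [
    "SpectralPCA",
    "OutlierRecord",
    "OutlierReport",
    "global_h",
    "eliminate_h",
    "eliminate_t",
]


class SpectralPCA(BaseEstimator):
    """PCA of pretreated spectra keeping enough components for a target
    explained-variance fraction (default 0.99).

    Fitted attributes: ``mean_``, ``components_``, ``explained_variance_ratio_``,
    ``n_components_``, ``score_std_`` (per-factor sample SD of training scores).
    """

    def __init__(self, target_variance: float = 0.99):
        self.target_variance = target_variance

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("PCA needs a matrix with at least 2 samples")
        if not (0.0 < self.target_variance <= 1.0):
            raise ValueError("target_variance must be in (0, 1]")
        total_var = float(((X - X.mean(axis=0)) ** 2).sum())
        if total_var <= 1e-30:
            raise ValueError("matrix has no spectral variance (rank 0)")
        n_comp = self.target_variance if self.target_variance < 1.0 else min(X.shape) - 1
        self._pca = PCA(n_components=n_comp, svd_solver="full").fit(X)
        self.mean_ = self._pca.mean_
        self.components_ = self._pca.components_
        self.explained_variance_ratio_ = self._pca.explained_variance_ratio_
        self.n_components_ = self._pca.n_components_
        self.score_std_ = self.transform(X).std(axis=0, ddof=1)
        return self

    def transform(self, X):
        return self._pca.transform(np.asarray(X, dtype=float))

    def fit_transform(self, X, y=None):
        return self.fit(X).transform(X)


def global_h(scores: np.ndarray, scale: np.ndarray | None = None) -> np.ndarray:
    """Global H: mean over factors of the squared standardized score.

    ``H_i = (1/k) * sum_f (t_if / s_f)^2`` with ``s_f`` the per-factor score
    SD.  With sample-SD scaling the training-set mean of H is (n-1)/n.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    if scores.shape[1] < 1:
        raise ValueError("need at least one factor")
    s = scores.std(axis=0, ddof=1) if scale is None else np.asarray(scale, dtype=float)
    if np.any(s <= 0) or not np.all(np.isfinite(s)):
        raise ValueError("zero or invalid score variance in some factor")
    return ((scores / s) ** 2).mean(axis=1)


@dataclass
class OutlierRecord:
    sample_id: object
    h: float | None = None
    t: float | None = None
    eliminated: bool = False
    reason: str | None = None  # "H" or "T"
    pass_index: int = 0


@dataclass
class OutlierReport:
    """Audit trail of the elimination procedure."""

    records: list[OutlierRecord] = field(default_factory=list)

    def eliminated_ids(self, reason: str | None = None) -> list:
        return [r.sample_id for r in self.records
                if r.eliminated and (reason is None or r.reason == reason)]

    @property
    def n_eliminated(self) -> int:
        return sum(r.eliminated for r in self.records)

    def extend(self, other: "OutlierReport") -> None:
        self.records.extend(other.records)

    def to_records(self) -> list[dict]:
        return [asdict(r) for r in self.records]

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_records(), indent=2, default=str)
        if path is not None:
            Path(path).write_text(text)
        return text


def eliminate_h(
    X: np.ndarray,
    threshold: float = 3.0,
    target_variance: float = 0.99,
    sample_ids=None,
) -> tuple[np.ndarray, OutlierReport]:
    """Single-pass spectral outlier elimination on Global H.

    Fits a PCA on the pretreated matrix, computes H for every sample and
    removes all samples with H > threshold simultaneously.  Returns the
    boolean keep-mask and the report.  Raises if elimination would leave
    fewer than ``2 * n_components`` samples.
    """
    X = np.asarray(X, dtype=float)
    ids = np.arange(X.shape[0]) if sample_ids is None else np.asarray(sample_ids, dtype=object)
    pca = SpectralPCA(target_variance=target_variance).fit(X)
    h = global_h(pca.transform(X), scale=pca.score_std_)
    flagged = h > threshold
    if X.shape[0] - int(flagged.sum()) < 2 * pca.n_components_:
        raise ValueError(
            f"H elimination would leave {X.shape[0] - int(flagged.sum())} samples "
            f"for {pca.n_components_} components; model unidentifiable"
        )
    report = OutlierReport([
        OutlierRecord(sample_id=ids[i], h=float(h[i]), eliminated=bool(flagged[i]),
                      reason="H" if flagged[i] else None, pass_index=0)
        for i in range(X.shape[0])
    ])
    return ~flagged, report


def eliminate_t(
    y: np.ndarray,
    y_hat: np.ndarray,
    refit=None,
    threshold: float = 2.5,
    max_passes: int = 2,
    sample_ids=None,
) -> tuple[np.ndarray, OutlierReport]:
    """Chemistry-residual outlier elimination, iterated with refitting.

    ``t_i = e_i / s_e`` with ``s_e`` the sample SD of residuals; samples
    with |t| > threshold are removed and, when a ``refit`` callable
    ``(kept_mask) -> y_hat_on_kept`` is supplied, the model is refit and
    the criterion re-applied, up to ``max_passes`` times or until no sample
    is flagged.  Returns the keep-mask over the original samples and the
    report (one record per sample and pass evaluated).
    """
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    n = y.size
    ids = np.arange(n) if sample_ids is None else np.asarray(sample_ids, dtype=object)
    keep = np.ones(n, dtype=bool)
    report = OutlierReport()
    current_hat = y_hat
    for pass_index in range(1, max_passes + 1):
        resid = y[keep] - current_hat
        s_e = resid.std(ddof=1) if resid.size > 1 else 0.0
        if s_e <= 0:
            warnings.warn("zero residual SD; no T elimination performed")
            break
        t = resid / s_e
        flagged = np.abs(t) > threshold
        idx = np.flatnonzero(keep)
        for j, i in enumerate(idx):
            report.records.append(OutlierRecord(
                sample_id=ids[i], t=float(t[j]), eliminated=bool(flagged[j]),
                reason="T" if flagged[j] else None, pass_index=pass_index))
        if not flagged.any():
            break
        keep[idx[flagged]] = False
        if refit is None or pass_index == max_passes:
            break
        current_hat = refit(keep)
    return keep, report
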