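"""Modified partial least squares (MPLS) regression, single response.

MPLS is the PLS1 variant in which, after each latent factor has been
extracted, the spectral residuals at each wavelength are divided by their
standard deviations before the next factor is computed.  The per-factor
scaling vectors are stored with the factor weights so prediction replays
the exact training transform sequence; with all scalings forced to one the
algorithm reduces to standard NIPALS PLS1.

Fitting recursion (X column-centered, y centered):

    w_f  ∝ X'y   (unit norm)
    t_f  = X w_f
    p_f  = X't_f / t_f't_f,   q_f = y't_f / t_f't_f
    X   <- (X - t_f p_f') / s_f      (s_f: per-column residual SD)
    y   <- y - q_f t_f

The affine prediction map collapses to an equivalent linear form
``y = b0 + sum_l beta_l x_l`` on the pretreated wavelength grid, computed
by reverse accumulation through the per-factor maps; the factor recursion
and the collapsed form agree to numerical precision and the equality is
enforced in the test suite.

The module also provides grouped cross-validation (default six groups,
seeded random partition, pretreatment refit inside each fold) and the full
calibration loop with Global-H and T outlier elimination.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin, clone

from . import assess
from .pretreat import MathTreatment
from .screen import OutlierReport, eliminate_h

__all__ = [
    "MPLSRegression",
    "CVResult",
    "FittedCalibration",
    "fit_mpls",
    "cross_validate",
    "fit_with_elimination",
    "coefficient_extrema",
    "save_model",
    "load_model",
]


class MPLSRegression(RegressorMixin, BaseEstimator):
    """Modified PLS1 with between-factor residual standardization.

    Parameters
    ----------
    n_factors : int
        Number of latent factors to extract (0 gives the mean model).
    scale_residuals : bool
        If False the residual scalings are fixed at 1 and the model is
        standard PLS1.

    Fitted attributes
    -----------------
    x_mean_, y_mean_ : centering state.
    weights_, x_loadings_, residual_scales_ : (k, p) per-factor vectors.
    y_loadings_ : (k,) score-to-response coefficients.
    coef_, intercept_ : collapsed linear form on the pretreated grid.
    n_factors_ : factors actually extracted (may stop early on exact fit).
    """

    def __init__(self, n_factors: int = 10, scale_residuals: bool = True):
        self.n_factors = n_factors
        self.scale_residuals = scale_residuals

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2 or X.shape[0] != y.size:
            raise ValueError("X must be (n_samples, n_channels) matching y")
        n, p = X.shape
        if self.n_factors < 0:
            raise ValueError("n_factors must be >= 0")
        if self.n_factors > min(n - 1, p):
            raise ValueError(
                f"n_factors={self.n_factors} exceeds min(n_samples - 1, channels)"
                f" = {min(n - 1, p)}"
            )
        if y.std() <= 0:
            raise ValueError("response has zero variance")
        self.x_mean_ = X.mean(axis=0)
        self.y_mean_ = float(y.mean())
        Xc = X - self.x_mean_
        yc = y - self.y_mean_
        W, P, Q, S = [], [], [], []
        for _ in range(self.n_factors):
            w = Xc.T @ yc
            norm_w = np.linalg.norm(w)
            if norm_w <= 1e-12 * max(1.0, np.abs(yc).max()):
                break  # response fully deflated; stop early
            w /= norm_w
            t = Xc @ w
            tt = float(t @ t)
            if tt <= 1e-30:
                break
            pvec = Xc.T @ t / tt
            q = float(yc @ t / tt)
            Xc = Xc - np.outer(t, pvec)
            yc = yc - q * t
            if self.scale_residuals:
                s = Xc.std(axis=0, ddof=1)
                bad = s <= 1e-12
                if bad.any():
                    warnings.warn(
                        f"{int(bad.sum())} residual columns have zero SD; scale set to 1")
                    s = np.where(bad, 1.0, s)
                Xc = Xc / s
            else:
                s = np.ones(p)
            W.append(w)
            P.append(pvec)
            Q.append(q)
            S.append(s)
        self.n_factors_ = len(W)
        self.weights_ = np.array(W).reshape(self.n_factors_, p)
        self.x_loadings_ = np.array(P).reshape(self.n_factors_, p)
        self.y_loadings_ = np.array(Q)
        self.residual_scales_ = np.array(S).reshape(self.n_factors_, p)
        self.coef_, self.intercept_ = self._collapse()
        return self

    def _collapse(self) -> tuple[np.ndarray, float]:
        # reverse accumulation of beta' = sum_f q_f w_f' M_f with
        # M_{f+1} = D_f^{-1} (I - p_f w_f') M_f; O(k p) total.
        r = np.zeros(self.x_mean_.size)
        for f in range(self.n_factors_ - 1, -1, -1):
            u = r / self.residual_scales_[f]
            r = self.y_loadings_[f] * self.weights_[f] + u - (u @ self.x_loadings_[f]) * self.weights_[f]
        return r, self.y_mean_ - float(r @ self.x_mean_)

    def predict(self, X, n_factors: int | None = None):
        """Predict by replaying the stored factor recursion."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.x_mean_.size:
            raise ValueError("channel grid differs from the fitted model")
        k = self.n_factors_ if n_factors is None else min(n_factors, self.n_factors_)
        Xc = X - self.x_mean_
        y_hat = np.full(X.shape[0], self.y_mean_)
        for f in range(k):
            t = Xc @ self.weights_[f]
            y_hat = y_hat + self.y_loadings_[f] * t
            Xc = (Xc - np.outer(t, self.x_loadings_[f])) / self.residual_scales_[f]
        return y_hat

    def predict_all_factors(self, X) -> np.ndarray:
        """Predictions at every factor count: (n_samples, n_factors_+1),
        column f using f factors (column 0 is the training mean)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Xc = X - self.x_mean_
        out = np.empty((X.shape[0], self.n_factors_ + 1))
        y_hat = np.full(X.shape[0], self.y_mean_)
        out[:, 0] = y_hat
        for f in range(self.n_factors_):
            t = Xc @ self.weights_[f]
            y_hat = y_hat + self.y_loadings_[f] * t
            Xc = (Xc - np.outer(t, self.x_loadings_[f])) / self.residual_scales_[f]
            out[:, f + 1] = y_hat
        return out

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "n_factors": self.n_factors,
            "scale_residuals": self.scale_residuals,
            "n_factors_": self.n_factors_,
            "x_mean": self.x_mean_.tolist(),
            "y_mean": self.y_mean_,
            "weights": self.weights_.tolist(),
            "x_loadings": self.x_loadings_.tolist(),
            "y_loadings": self.y_loadings_.tolist(),
            "residual_scales": self.residual_scales_.tolist(),
            "coef": self.coef_.tolist(),
            "intercept": self.intercept_,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MPLSRegression":
        model = cls(n_factors=d["n_factors"], scale_residuals=d["scale_residuals"])
        model.n_factors_ = d["n_factors_"]
        model.x_mean_ = np.asarray(d["x_mean"], dtype=float)
        model.y_mean_ = float(d["y_mean"])
        p = model.x_mean_.size
        model.weights_ = np.asarray(d["weights"], dtype=float).reshape(model.n_factors_, p)
        model.x_loadings_ = np.asarray(d["x_loadings"], dtype=float).reshape(model.n_factors_, p)
        model.y_loadings_ = np.asarray(d["y_loadings"], dtype=float)
        model.residual_scales_ = np.asarray(d["residual_scales"], dtype=float).reshape(model.n_factors_, p)
        model.coef_ = np.asarray(d["coef"], dtype=float)
        model.intercept_ = float(d["intercept"])
        return model


def fit_mpls(X, y, n_factors: int, scale_residuals: bool = True) -> MPLSRegression:
    """Fit an MPLS model on pretreated spectra (thin wrapper)."""
    return MPLSRegression(n_factors=n_factors, scale_residuals=scale_residuals).fit(X, y)


@dataclass
class CVResult:
    """Grouped cross-validation outcome."""

    groups: np.ndarray            # group index per sample
    rmsecv_curve: np.ndarray      # RMSECV at 0..max factors (index = factor count)
    n_factors: int                # argmin of the curve over factor counts >= 1
    predictions: np.ndarray       # per-sample CV prediction at n_factors

    @property
    def rmsecv(self) -> float:
        return float(self.rmsecv_curve[self.n_factors])


def cross_validate(
    X,
    y,
    treatment: MathTreatment | None = None,
    n_groups: int = 6,
    max_factors: int = 16,
    rng=None,
    factor_rule: str = "min",
) -> CVResult:
    """Grouped cross-validation with in-fold pretreatment refitting.

    The samples are partitioned into ``n_groups`` groups by a seeded random
    assignment; each group is predicted by a model trained on the others,
    with the pretreatment state and the MPLS factors refit inside every
    fold (no information leaks from the held-out group).  RMSECV at each
    factor count pools the held-out errors over all samples.

    ``factor_rule`` selects the factor count: ``"min"`` (default) takes the
    global minimum of the RMSECV curve; ``"one_se"`` takes the most
    parsimonious count whose RMSECV is within one standard error
    (rmsecv_min / sqrt(n)) of the minimum — the classic guard against
    over-fitting, useful when interpretable regression vectors matter.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if n < n_groups:
        raise ValueError("fewer samples than cross-validation groups")
    rng = np.random.default_rng(rng)
    perm = rng.permutation(n)
    groups = np.empty(n, dtype=int)
    for g, chunk in enumerate(np.array_split(perm, n_groups)):
        if chunk.size < 2:
            raise ValueError("a cross-validation group has fewer than 2 samples")
        groups[chunk] = g
    fold_caps = []
    for g in range(n_groups):
        n_train = int((groups != g).sum())
        fold_caps.append(min(max_factors, n_train - 1, X.shape[1]))
    k_max = min(fold_caps)
    preds = np.empty((n, k_max + 1))
    for g in range(n_groups):
        train = groups != g
        test = ~train
        if treatment is not None:
            t = clone(treatment)
            X_train = t.fit_transform(X[train])
            X_test = t.transform(X[test])
        else:
            X_train, X_test = X[train], X[test]
        model = MPLSRegression(n_factors=k_max).fit(X_train, y[train])
        block = model.predict_all_factors(X_test)
        if block.shape[1] < k_max + 1:  # early stop in a fold: pad with last column
            pad = np.repeat(block[:, -1:], k_max + 1 - block.shape[1], axis=1)
            block = np.hstack([block, pad])
        preds[test] = block
    errors = preds - y[:, None]
    curve = np.sqrt((errors ** 2).mean(axis=0))
    best = int(np.argmin(curve[1:]) + 1)
    if factor_rule == "one_se":
        threshold = curve[best] * (1.0 + 1.0 / np.sqrt(n))
        best = int(np.flatnonzero(curve[1:] <= threshold)[0] + 1)
    elif factor_rule != "min":
        raise ValueError(f"unknown factor_rule {factor_rule!r}")
    return CVResult(groups=groups, rmsecv_curve=curve, n_factors=best,
                    predictions=preds[:, best])


@dataclass
class FittedCalibration:
    """Outcome of the full calibration loop for one element."""

    element: str
    treatment: MathTreatment          # fitted on the final survivors
    model: MPLSRegression
    cv: CVResult
    summary: assess.CalibrationSummary
    outliers: OutlierReport
    ids: np.ndarray                   # surviving sample ids
    y: np.ndarray                     # surviving reference values
    wavelengths: np.ndarray = field(default=None)  # type: ignore[assignment]

    def predict(self, X_raw) -> np.ndarray:
        return self.model.predict(self.treatment.transform(np.atleast_2d(X_raw)))


def fit_with_elimination(
    X,
    y,
    treatment: MathTreatment | str,
    element: str = "",
    sample_ids=None,
    n_groups: int = 6,
    h_threshold: float = 3.0,
    t_threshold: float = 2.5,
    max_t_passes: int = 2,
    max_factors: int = 16,
    target_variance: float = 0.99,
    wavelengths=None,
    rng=None,
    factor_rule: str = "min",
) -> FittedCalibration:
    """Full calibration loop for one element.

    pretreat -> Global-H elimination (single pass) -> cross-validated factor
    selection -> fit -> T elimination (refit and re-cross-validate after
    each pass, at most ``max_t_passes``) -> final model and summary on the
    surviving samples.
    """
    from .pretreat import parse_treatment

    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    ids = np.arange(y.size) if sample_ids is None else np.asarray(sample_ids, dtype=object)
    if isinstance(treatment, str):
        treatment = parse_treatment(treatment, wavelengths=wavelengths)
    rng = np.random.default_rng(rng)

    # spectral criterion on the pretreated full candidate set
    t_full = clone(treatment)
    Xp_full = t_full.fit_transform(X)
    keep_h, report = eliminate_h(Xp_full, threshold=h_threshold,
                                 target_variance=target_variance, sample_ids=ids)
    keep = keep_h.copy()

    def _calibrate(mask):
        t_fit = clone(treatment)
        Xp = t_fit.fit_transform(X[mask])
        cv = cross_validate(X[mask], y[mask], treatment=treatment,
                            n_groups=n_groups, max_factors=max_factors, rng=rng,
                            factor_rule=factor_rule)
        model = MPLSRegression(n_factors=cv.n_factors).fit(Xp, y[mask])
        return t_fit, Xp, cv, model

    t_fit, Xp, cv, model = _calibrate(keep)
    for pass_index in range(1, max_t_passes + 1):
        resid = y[keep] - model.predict(Xp)
        s_e = resid.std(ddof=1)
        if s_e <= 0:
            warnings.warn("zero residual SD; T criterion skipped")
            break
        tvals = resid / s_e
        flagged = np.abs(tvals) > t_threshold
        idx = np.flatnonzero(keep)
        from .screen import OutlierRecord
        for j in np.flatnonzero(flagged):
            report.records.append(OutlierRecord(
                sample_id=ids[idx[j]], t=float(tvals[j]), eliminated=True,
                reason="T", pass_index=pass_index))
        if not flagged.any():
            break
        keep[idx[flagged]] = False
        t_fit, Xp, cv, model = _calibrate(keep)

    if int(keep.sum()) < 3 * model.n_factors_:
        raise ValueError(
            f"only {int(keep.sum())} survivors for {model.n_factors_} factors")

    summary = assess.calibration_summary(
        element, str(treatment), y[keep], model.predict(Xp),
        cv.predictions, cv.rmsecv, n_factors=model.n_factors_)
    return FittedCalibration(
        element=element, treatment=t_fit, model=model, cv=cv, summary=summary,
        outliers=report, ids=ids[keep], y=y[keep],
        wavelengths=getattr(t_fit, "wavelengths_", None),
    )


def coefficient_extrema(model: MPLSRegression, wavelengths, top_k: int = 2):
    """Wavelengths of the k largest |beta| with their signed values."""
    wavelengths = np.asarray(wavelengths, dtype=float)
    beta = model.coef_
    if wavelengths.size != beta.size:
        raise ValueError("wavelength grid does not match the coefficient vector")
    order = np.argsort(-np.abs(beta))[:top_k]
    return [(float(wavelengths[i]), float(beta[i])) for i in order]


def save_model(calibration: FittedCalibration, path: str | Path) -> None:
    """Serialize a fitted calibration (model + treatment state) to JSON."""
    t = calibration.treatment
    params = dict(t.get_params())
    if params.get("wavelengths") is not None:
        params["wavelengths"] = np.asarray(params["wavelengths"]).tolist()
    payload = {
        "schema": "nircal-model/1",
        "element": calibration.element,
        "treatment_params": params,
        "treatment_msc_reference": _msc_reference(t),
        "n_channels_in": int(t.n_channels_in_),
        "model": calibration.model.to_dict(),
        "wavelengths": np.asarray(calibration.wavelengths).tolist()
        if calibration.wavelengths is not None else None,
    }
    Path(path).write_text(json.dumps(payload))


def _msc_reference(treatment: MathTreatment):
    for step in getattr(treatment, "steps_", []):
        if hasattr(step, "reference_"):
            return np.asarray(step.reference_).tolist()
    return None


def load_model(path: str | Path) -> FittedCalibration:
    """Reload a serialized calibration; prediction-ready (no CV/summary)."""
    d = json.loads(Path(path).read_text())
    t = MathTreatment(**d["treatment_params"])
    n_in = int(d["n_channels_in"])
    # rebuild the transform chain structure on a placeholder of the right
    # width, then overwrite the MSC reference so prediction state is exact
    placeholder = np.vstack([np.linspace(0.0, 1.0, n_in),
                             np.linspace(0.0, 2.0, n_in) ** 2 + 0.1])
    t.fit(placeholder)
    if d["treatment_msc_reference"] is not None:
        for step in t.steps_:
            if hasattr(step, "reference_"):
                step.reference_ = np.asarray(d["treatment_msc_reference"], dtype=float)
    model = MPLSRegression.from_dict(d["model"])
    return FittedCalibration(
        element=d["element"], treatment=t, model=model, cv=None, summary=None,
        outliers=None, ids=None, y=None,
        wavelengths=np.asarray(d["wavelengths"]) if d["wavelengths"] is not None else None,
    )
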