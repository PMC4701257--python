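"""Scatter corrections and derivative math treatments for NIR spectra.

Scatter corrections
    * SNV — standard normal variate: per-spectrum centering and scaling
      to unit sample SD.  Stateless.
    * MSC — multiplicative scatter correction: each spectrum is regressed
      on the *training-set* mean spectrum by OLS, ``x ~ a + b*m``, and
      corrected as ``(x - a)/b``.  The reference mean is fitted once and
      reused unchanged at prediction time.
    * Detrend — subtraction of a least-squares quadratic baseline in
      wavelength (degree configurable).  Stateless.
    * SNV-Detrend — SNV followed by detrend.

Derivative / smoothing
    The classic four-number treatment code ``D,G,S1,S2`` is read as
    (derivative order, gap width, first smoothing segment, second smoothing
    segment), all in channels: boxcar-smooth with segment S1, apply the gap
    difference ``x(i + ceil(G/2)) - x(i - floor(G/2))`` D times, then
    boxcar-smooth with segment S2.  Edge channels without full support are
    trimmed, never padded, and the retained wavelength subgrid is tracked.

Treatment strings such as ``"Standard MSC 1,4,4,1"`` or ``"SNV only
2,4,4,1"`` are parsed by :func:`parse_treatment`; ``"None 0,0,1,1"`` is the
identity.  The composition order is scatter correction first, derivative
second (configurable).
"""

from __future__ import annotations

import re

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "SNV",
    "MSC",
    "Detrend",
    "GapSegmentDerivative",
    "MathTreatment",
    "parse_treatment",
    "snv",
    "detrend",
    "msc_fit_apply",
    "msc_apply",
    "gap_segment_derivative",
]

_SCATTER_NAMES = ("none", "snv", "msc", "detrend", "snv-detrend")

_CANONICAL = {
    "none": "None",
    "snv": "SNV only",
    "msc": "Standard MSC",
    "detrend": "Detrend only",
    "snv-detrend": "SNV-Detrend",
}


def _as_matrix(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.ndim != 2:
        raise ValueError("expected a spectrum or a samples x channels matrix")
    return X


class SNV(TransformerMixin, BaseEstimator):
    """Standard normal variate: row-wise (x - mean)/SD with n-1 denominator."""

    def fit(self, X, y=None):
        _as_matrix(X)
        return self

    def transform(self, X):
        X = _as_matrix(X)
        if X.shape[1] < 2:
            raise ValueError("SNV needs at least 2 channels")
        mu = X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1, ddof=1, keepdims=True)
        if np.any(sd <= 0):
            raise ValueError("SNV undefined for a constant spectrum")
        return (X - mu) / sd


class MSC(TransformerMixin, BaseEstimator):
    """Multiplicative scatter correction against the training mean spectrum."""

    def fit(self, X, y=None):
        X = _as_matrix(X)
        if X.shape[0] < 2:
            raise ValueError("MSC needs at least 2 training spectra")
        self.reference_ = X.mean(axis=0)
        return self

    def transform(self, X):
        m = self.reference_
        X = _as_matrix(X)
        if X.shape[1] != m.size:
            raise ValueError("channel count differs from the MSC reference")
        mm = m.mean()
        denom = float(((m - mm) ** 2).sum())
        if denom <= 0:
            raise ValueError("MSC reference spectrum is constant")
        b = (X - X.mean(axis=1, keepdims=True)) @ (m - mm) / denom
        if np.any(np.abs(b) < 1e-12):
            raise ValueError("MSC slope is zero for at least one spectrum")
        a = X.mean(axis=1) - b * mm
        return (X - a[:, None]) / b[:, None]


class Detrend(TransformerMixin, BaseEstimator):
    """Remove a least-squares polynomial (default quadratic) in wavelength.

    The residual is orthogonal to the polynomial basis {1, lambda, ...,
    lambda^degree}.  If no wavelength grid is given the channel index is
    used; the correction is identical for any affine relabelling of the
    axis, since the basis span is unchanged.
    """

    def __init__(self, degree: int = 2, wavelengths=None):
        self.degree = degree
        self.wavelengths = wavelengths

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        X = _as_matrix(X)
        p = X.shape[1]
        if p < self.degree + 1:
            raise ValueError("detrend needs more channels than the polynomial degree")
        w = np.arange(p, dtype=float) if self.wavelengths is None else np.asarray(self.wavelengths, float)
        if w.size != p:
            raise ValueError("wavelength grid does not match channel count")
        # scaled axis for conditioning; same column span as {1, w, w^2, ...}
        span = float(np.ptp(w))
        z = (w - w.mean()) / (span / 2 if span > 0 else 1.0)
        V = np.vander(z, self.degree + 1, increasing=True)
        coef, *_ = np.linalg.lstsq(V, X.T, rcond=None)
        return X - (V @ coef).T


class GapSegmentDerivative(TransformerMixin, BaseEstimator):
    """Gap-segment derivative with boxcar smoothing and edge trimming.

    Parameters mirror the four-number treatment code: ``derivative`` (D),
    ``gap`` (G), ``smooth1`` (S1), ``smooth2`` (S2), all in channels.
    ``D=0, S1=S2=1`` is the identity.  The fitted attribute
    ``wavelengths_`` holds the retained subgrid after trimming (input grid
    required via ``wavelengths``; channel indices used otherwise).
    """

    def __init__(self, derivative: int = 0, gap: int = 0, smooth1: int = 1,
                 smooth2: int = 1, wavelengths=None):
        self.derivative = derivative
        self.gap = gap
        self.smooth1 = smooth1
        self.smooth2 = smooth2
        self.wavelengths = wavelengths

    def _check(self, p: int) -> np.ndarray:
        if self.derivative < 0 or self.smooth1 < 1 or self.smooth2 < 1:
            raise ValueError("invalid derivative/smoothing parameters")
        if self.derivative >= 1 and self.gap < 1:
            raise ValueError("derivative order >= 1 requires gap >= 1")
        w = (np.arange(p, dtype=float) if self.wavelengths is None
             else np.asarray(self.wavelengths, dtype=float))
        if w.size != p:
            raise ValueError("wavelength grid does not match channel count")
        return w

    def fit(self, X, y=None):
        X = _as_matrix(X)
        _, self.wavelengths_ = self._apply(X[:1], self._check(X.shape[1]))
        return self

    def transform(self, X):
        X = _as_matrix(X)
        out, self.wavelengths_ = self._apply(X, self._check(X.shape[1]))
        return out

    def _apply(self, X, w):
        X, w = _boxcar(X, self.smooth1, w)
        if self.derivative >= 1:
            for _ in range(self.derivative):
                X, w = _gap_difference(X, self.gap, w)
        X, w = _boxcar(X, self.smooth2, w)
        return X, w


def _boxcar(X: np.ndarray, segment: int, w: np.ndarray):
    if segment <= 1:
        return X, w
    if X.shape[1] < segment:
        raise ValueError("smoothing segment exceeds spectrum length")
    out = sliding_window_view(X, segment, axis=1).mean(axis=-1)
    # representative channel: forward-biased centre for even segments
    lo = segment // 2
    return out, w[lo:lo + out.shape[1]]


def _gap_difference(X: np.ndarray, gap: int, w: np.ndarray):
    fwd = (gap + 1) // 2
    back = gap // 2
    n = X.shape[1]
    if n - fwd - back < 1:
        raise ValueError("gap exceeds spectrum length")
    out = X[:, back + fwd:] - X[:, :n - back - fwd]
    return out, w[back:back + out.shape[1]]


class MathTreatment(TransformerMixin, BaseEstimator):
    """Full math treatment: scatter correction composed with a derivative.

    ``scatter`` is one of ``none | snv | msc | detrend | snv-detrend``.
    MSC is the only stateful step: its reference mean is captured in
    :meth:`fit` on training data and reused verbatim for prediction.
    Default composition order is scatter first, then derivative
    (``scatter_first=False`` swaps it).  ``wavelengths_`` holds the grid
    retained after derivative trimming.
    """

    def __init__(self, scatter: str = "none", derivative: int = 0, gap: int = 0,
                 smooth1: int = 1, smooth2: int = 1, detrend_degree: int = 2,
                 scatter_first: bool = True, wavelengths=None):
        self.scatter = scatter
        self.derivative = derivative
        self.gap = gap
        self.smooth1 = smooth1
        self.smooth2 = smooth2
        self.detrend_degree = detrend_degree
        self.scatter_first = scatter_first
        self.wavelengths = wavelengths

    def _scatter_steps(self):
        name = self.scatter.lower().replace("_", "-")
        if name not in _SCATTER_NAMES:
            raise ValueError(f"unknown scatter correction {self.scatter!r}")
        if name == "none":
            return []
        if name == "snv":
            return [SNV()]
        if name == "msc":
            return [MSC()]
        if name == "detrend":
            return [Detrend(degree=self.detrend_degree, wavelengths=self.wavelengths)]
        return [SNV(), Detrend(degree=self.detrend_degree, wavelengths=self.wavelengths)]

    def fit(self, X, y=None):
        X = _as_matrix(X)
        deriv = GapSegmentDerivative(self.derivative, self.gap, self.smooth1,
                                     self.smooth2, wavelengths=self.wavelengths)
        steps = ([*self._scatter_steps(), deriv] if self.scatter_first
                 else [deriv, *self._scatter_steps()])
        # note: when the derivative runs first, stateless scatter steps see the
        # trimmed grid; Detrend must then use the retained wavelengths
        out = X
        for step in steps:
            if isinstance(step, Detrend) and not self.scatter_first:
                step.wavelengths = deriv.wavelengths_
            out = step.fit(out).transform(out)
        self.steps_ = steps
        self.wavelengths_ = deriv.wavelengths_
        self.n_channels_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = _as_matrix(X)
        if X.shape[1] != self.n_channels_in_:
            raise ValueError("channel count differs from the fitted grid")
        out = X
        for step in self.steps_:
            out = step.transform(out)
        return out

    def __str__(self) -> str:
        name = _CANONICAL[self.scatter.lower().replace("_", "-")]
        return f"{name} {self.derivative},{self.gap},{self.smooth1},{self.smooth2}"


_TREATMENT_RE = re.compile(
    r"^\s*(?P<scatter>[A-Za-z -]*?)\s*(?P<code>\d+\s*,\s*\d+\s*,\s*\d+\s*,\s*\d+)\s*$"
)


def parse_treatment(text: str, wavelengths=None, **kwargs) -> MathTreatment:
    """Parse a treatment string as printed in calibration tables.

    Accepts e.g. ``"Standard MSC 1,4,4,1"``, ``"SNV only2,4,4,1"``,
    ``"None 0,0,1,1"``, ``"Detrend only 2,10,10,1"``, ``"SNV-DT 2,4,4,1"``
    (case-insensitive; the filler words "only"/"standard" are ignored).
    """
    m = _TREATMENT_RE.match(text)
    if not m:
        raise ValueError(f"cannot parse treatment string {text!r}")
    raw = m.group("scatter").lower().replace("standard", "").replace("only", "").strip()
    raw = raw.replace(" ", "-") or "none"
    aliases = {"dt": "detrend", "snv-dt": "snv-detrend", "snvdt": "snv-detrend"}
    scatter = aliases.get(raw, raw)
    if scatter not in _SCATTER_NAMES:
        raise ValueError(f"unknown scatter keyword {m.group('scatter')!r}")
    d, g, s1, s2 = (int(v) for v in m.group("code").split(","))
    return MathTreatment(scatter=scatter, derivative=d, gap=g, smooth1=s1,
                         smooth2=s2, wavelengths=wavelengths, **kwargs)


# ---------------------------------------------------------------------------
# thin functional wrappers


def snv(x):
    """SNV-correct one spectrum or a matrix of spectra."""
    out = SNV().fit_transform(x)
    return out[0] if np.asarray(x).ndim == 1 else out


def detrend(x, wavelengths=None, degree: int = 2):
    """Detrend one spectrum or a matrix of spectra."""
    out = Detrend(degree=degree, wavelengths=wavelengths).fit_transform(x)
    return out[0] if np.asarray(x).ndim == 1 else out


def msc_fit_apply(X):
    """Fit MSC on a training matrix; returns (corrected X, fitted MSC)."""
    est = MSC().fit(X)
    return est.transform(X), est


def msc_apply(state: MSC, x):
    """Apply a fitted MSC to new spectra."""
    out = state.transform(x)
    return out[0] if np.asarray(x).ndim == 1 else out


def gap_segment_derivative(x, derivative: int, gap: int, smooth1: int = 1,
                           smooth2: int = 1, wavelengths=None):
    """Apply the D,G,S1,S2 treatment; returns (output, retained wavelengths)."""
    est = GapSegmentDerivative(derivative, gap, smooth1, smooth2, wavelengths)
    out = est.fit_transform(x)
    if np.asarray(x).ndim == 1:
        out = out[0]
    return out, est.wavelengths_
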