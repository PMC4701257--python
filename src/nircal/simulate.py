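"""Seeded generator of propolis-like NIR datasets.

The generator emulates the statistical structure a mineral calibration of
propolis rests on: 91 samples from three regions (Chile 52, Galicia 16,
Castilla-León 23) with region-specific element distributions, strong
inter-element correlations (Ca–Mg 0.97, Cr–Ni 0.90, ...), triplicate
scanning, and the scatter artifacts of diffuse-reflectance measurement.

Concentrations
    Per region and element, a log-normal truncated to the tabulated range,
    with the location parameter solved so the truncated mean matches the
    tabulated mean (concentrations are positive and right-skewed).  The
    inter-element dependence is a Gaussian copula; the latent correlations
    are adjusted (NORTA-style, on a fixed common-random-number sample) so
    the *Pearson* correlations of the simulated concentrations hit the
    targets, and the adjusted matrix is projected to the nearest positive
    definite correlation matrix before use.

Spectra
    A fixed organic-matrix baseline (water O-H overtone bands near 1400 and
    1900 nm, a flavonoid band in the 1510-1550 nm region, a gentle slope)
    plus, per element, Gaussian absorption bands centered at the
    wavelengths where real calibrations localize that element's signal,
    with amplitude proportional to concentration (a linear-mixture,
    Beer-Lambert-like model).  Band amplitudes are free parameters of the
    simulation: each element's ``band_strength`` sets the absorbance SD its
    concentration signal contributes across the population, chosen so
    calibration quality spans the realistic range (strong for K/P/Zn, weak
    for Cr/Ni/Cu).  Observed replicate spectra add multiplicative and
    additive scatter, a linear tilt, and white instrument noise:

        observed = m_s * m_r * clean + a_s + a_r + tilt * z(lambda) + eps

    with sample-level (``_s``) and replicate-level (``_r``) scatter terms.

Everything is driven by a single integer seed; identical configuration and
seed reproduce the dataset byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io import DEFAULT_LOQ, ELEMENTS, ReferenceTable, SpectraSet, default_grid

__all__ = [
    "REGION_STATS",
    "CORRELATION_TARGETS",
    "BAND_LIBRARY",
    "BandSignature",
    "SyntheticConfig",
    "SimulatedDataset",
    "nearest_correlation_matrix",
    "sample_concentrations",
    "generate_spectra",
    "make_dataset",
    "implant_outliers",
]

#: Per-region element statistics: (mean, range_min, range_max) in mg/kg;
#: None for a range endpoint below the quantification limit.
REGION_STATS: dict[str, dict] = {
    "Chile": {
        "n": 52,
        "Al": (354.9, 156.0, 833.9), "Ca": (910.4, 274.0, 5173.0),
        "Fe": (536.6, 181.8, 1538.0), "K": (550.0, 267.0, 1841.2),
        "Mg": (261.8, 75.1, 1398.0), "P": (228.8, 118.1, 402.0),
        "Cr": (3.1, 1.4, 5.5), "Cu": (1.6, None, 6.2), "Ni": (1.2, None, 9.7),
        "Pb": (2.6, None, 8.0), "Zn": (57.8, 5.5, 105.0),
    },
    "Galicia": {
        "n": 16,
        "Al": (105.2, 43.0, 193.7), "Ca": (563.2, 219.1, 1176.1),
        "Fe": (245.8, 46.1, 656.7), "K": (1522.1, 359.0, 3182.1),
        "Mg": (206.4, 63.5, 427.0), "P": (307.5, 152.3, 729.0),
        "Cr": (2.7, 0.8, 7.5), "Cu": (5.4, None, 33.4), "Ni": (1.4, 0.5, 4.0),
        "Pb": (2.2, None, 6.0), "Zn": (89.8, 17.4, 460.7),
    },
    "Castilla-Leon": {
        "n": 23,
        "Al": (213.2, 78.6, 518.4), "Ca": (847.3, 416.7, 2169.2),
        "Fe": (295.8, 104.5, 874.0), "K": (1569.4, 685.9, 4428.3),
        "Mg": (190.6, 88.2, 460.3), "P": (198.5, 116.0, 327.7),
        "Cr": (5.7, 2.3, 48.9), "Cu": (2.8, None, 7.2), "Ni": (2.4, 0.6, 29.9),
        "Pb": (15.5, None, 74.0), "Zn": (54.4, 11.1, 145.3),
    },
}

#: Target pairwise Pearson correlations between element concentrations.
CORRELATION_TARGETS: dict[tuple[str, str], float] = {
    ("Ca", "Mg"): 0.97, ("Cr", "Ni"): 0.90, ("Al", "Fe"): 0.57,
    ("Ca", "Fe"): 0.36, ("Fe", "Mg"): 0.35, ("Fe", "Zn"): 0.31,
    ("Mg", "P"): 0.31, ("K", "Pb"): 0.33, ("K", "P"): 0.28,
    ("Cu", "K"): 0.26, ("Al", "K"): -0.29, ("Fe", "K"): -0.32,
}


@dataclass
class BandSignature:
    """Absorption bands linked to one element.

    ``bands`` is a list of (center nm, width nm, relative weight); the
    element's overall coupling is ``band_strength`` — the absorbance SD its
    concentration signal contributes across the simulated population.
    """

    element: str
    bands: list[tuple[float, float, float]]
    band_strength: float


#: Band centers follow the wavelengths at which real propolis calibrations
#: localize each element's regression signal; widths ~12 nm; the second
#: band carries 60% of the weight of the first.  Strengths (absorbance SD
#: contributed) grade from strong (K, P, Zn) to weak (Cr, Cu, Ni).
BAND_LIBRARY: dict[str, BandSignature] = {
    "Al": BandSignature("Al", [(1330.0, 12.0, 1.0), (1556.0, 12.0, 0.6)], 0.030),
    "Ca": BandSignature("Ca", [(1500.0, 12.0, 1.0), (1542.0, 12.0, 0.6)], 0.035),
    "Fe": BandSignature("Fe", [(1228.0, 12.0, 1.0), (1112.0, 12.0, 0.6)], 0.025),
    "K":  BandSignature("K",  [(1480.0, 12.0, 1.0), (1224.0, 12.0, 0.6)], 0.100),
    "Mg": BandSignature("Mg", [(1520.0, 12.0, 1.0), (1532.0, 12.0, 0.6)], 0.022),
    "P":  BandSignature("P",  [(1554.0, 12.0, 1.0), (1968.0, 12.0, 0.6)], 0.070),
    "Cr": BandSignature("Cr", [(1366.0, 12.0, 1.0), (1590.0, 12.0, 0.6)], 0.007),
    "Cu": BandSignature("Cu", [(1244.0, 12.0, 1.0), (1356.0, 12.0, 0.6)], 0.010),
    "Ni": BandSignature("Ni", [(1520.0, 12.0, 1.0), (1558.0, 12.0, 0.6)], 0.006),
    "Pb": BandSignature("Pb", [(1820.0, 12.0, 1.0), (1968.0, 12.0, 0.6)], 0.022),
    "Zn": BandSignature("Zn", [(1816.0, 12.0, 1.0), (1976.0, 12.0, 0.6)], 0.060),
}

#: Organic-matrix baseline bands shared by all samples: water O-H overtones
#: near 1400/1900 nm and the flavonoid aromatic band in 1510-1550 nm.
MATRIX_BANDS: list[tuple[float, float, float]] = [
    (1400.0, 55.0, 0.35),
    (1900.0, 65.0, 0.55),
    (1530.0, 40.0, 0.18),
]


@dataclass
class SyntheticConfig:
    """All knobs of the generator; defaults are the emulated study design."""

    n_samples: int = 91
    region_counts: dict[str, int] = field(
        default_factory=lambda: {"Chile": 52, "Galicia": 16, "Castilla-Leon": 23})
    correlations: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(CORRELATION_TARGETS))
    bands: dict[str, BandSignature] = field(default_factory=lambda: dict(BAND_LIBRARY))
    elements: tuple[str, ...] = ELEMENTS
    wavelength_start: float = 1100.0
    wavelength_stop: float = 2000.0
    wavelength_step: float = 2.0
    # scatter artifacts (sample level)
    mult_log_sd: float = 0.04        # log-SD of the multiplicative factor
    add_sd: float = 0.02             # SD of the additive offset (absorbance)
    tilt_sd: float = 0.004           # SD of the linear tilt across the range
    # replicate-level repack scatter
    rep_mult_log_sd: float = 0.01
    rep_add_sd: float = 0.005
    # white instrument noise per recorded channel (absorbance)
    noise_sd: float = 0.0015
    # indirect-association noise: the spectrum responds to the organically
    # bound fraction, a noisy proxy of the ICP concentration.  Values are
    # SD of the proxy error as a fraction of the element's population SD;
    # the ceiling on achievable R^2 is 1/(1 + a^2).  Defaults grade from
    # tightly coupled (K, P) to weakly coupled (Cr, Ni).
    association_sd: dict[str, float] = field(default_factory=lambda: {
        "K": 0.23, "P": 0.25, "Zn": 0.39, "Ca": 0.45, "Al": 0.52,
        "Mg": 0.65, "Pb": 0.65, "Fe": 0.67, "Cu": 0.75, "Ni": 0.96,
        "Cr": 1.04})
    n_replicates: int = 3
    # fraction of lowest values reported below LOQ, per element
    nd_fraction: dict[str, float] = field(
        default_factory=lambda: {"Cu": 0.06, "Ni": 0.04, "Pb": 0.06})
    loq: float = DEFAULT_LOQ
    n_calibration: int = 71
    n_validation: int = 20
    seed: int = 0

    def grid(self) -> np.ndarray:
        return default_grid(self.wavelength_start, self.wavelength_stop,
                            self.wavelength_step)

    def region_of(self) -> np.ndarray:
        """Region label per sample, scaled to ``n_samples`` by proportion."""
        names = list(self.region_counts)
        counts = np.array([self.region_counts[r] for r in names], dtype=float)
        scaled = counts / counts.sum() * self.n_samples
        n_per = np.floor(scaled).astype(int)
        # distribute the remainder by largest fractional part
        for i in np.argsort(-(scaled - n_per))[: self.n_samples - n_per.sum()]:
            n_per[i] += 1
        return np.repeat(names, n_per)


# ---------------------------------------------------------------------------
# truncated log-normal marginals


def _trunc_lognorm_moments(mu: float, sigma: float, lo: float, hi: float):
    a = (np.log(lo) - mu) / sigma
    b = (np.log(hi) - mu) / sigma
    z = stats.norm.cdf(b) - stats.norm.cdf(a)
    if z <= 0:
        return lo, lo ** 2
    m1 = np.exp(mu + 0.5 * sigma ** 2) * (
        stats.norm.cdf(b - sigma) - stats.norm.cdf(a - sigma)) / z
    m2 = np.exp(2 * mu + 2 * sigma ** 2) * (
        stats.norm.cdf(b - 2 * sigma) - stats.norm.cdf(a - 2 * sigma)) / z
    return float(m1), float(m2)


def _solve_marginal(mean: float, lo: float | None, hi: float, loq: float):
    """Truncated log-normal (mu, sigma, lo, hi) matching mean and range.

    sigma spans the log-range over four SDs; mu is solved so the truncated
    mean equals the target (moment adjustment).
    """
    lo = max(lo if lo is not None else loq, 1e-6)
    if lo >= hi:
        raise ValueError(f"infeasible range [{lo}, {hi}]")
    if not (lo < mean < hi):
        raise ValueError(f"mean {mean} outside range [{lo}, {hi}]")
    # spread from the log-range over four SDs; when the lower end is only a
    # quantification limit the printed range exaggerates the true spread, so
    # the effective span is capped at 1.5 decades
    sigma = (np.log(hi) - np.log(max(lo, hi / 30.0))) / 4.0
    f = lambda mu: _trunc_lognorm_moments(mu, sigma, lo, hi)[0] - mean
    mu = optimize.brentq(f, np.log(lo) - 6 * sigma, np.log(hi) + 6 * sigma, xtol=1e-10)
    return float(mu), float(sigma), float(lo), float(hi)


def _trunc_lognorm_ppf(u: np.ndarray, mu: float, sigma: float, lo: float, hi: float):
    fa = stats.norm.cdf((np.log(lo) - mu) / sigma)
    fb = stats.norm.cdf((np.log(hi) - mu) / sigma)
    z = stats.norm.ppf(fa + np.clip(u, 1e-12, 1 - 1e-12) * (fb - fa))
    return np.clip(np.exp(mu + sigma * z), lo, hi)


def _pooled_sd(element: str, cfg: SyntheticConfig) -> float:
    """Analytic SD of an element over the configured region mixture."""
    weights, m1s, m2s = [], [], []
    for region, count in cfg.region_counts.items():
        mean, lo, hi = REGION_STATS[region][element]
        mu, sigma, lo, hi = _solve_marginal(mean, lo, hi, cfg.loq)
        m1, m2 = _trunc_lognorm_moments(mu, sigma, lo, hi)
        weights.append(count)
        m1s.append(m1)
        m2s.append(m2)
    w = np.asarray(weights, dtype=float)
    w /= w.sum()
    e1 = float(w @ np.asarray(m1s))
    e2 = float(w @ np.asarray(m2s))
    return float(np.sqrt(max(e2 - e1 ** 2, 1e-12)))


# ---------------------------------------------------------------------------
# correlation machinery


def nearest_correlation_matrix(C: np.ndarray, tol: float = 1e-8,
                               max_iter: int = 50) -> tuple[np.ndarray, float]:
    """Project to the nearest positive-definite correlation matrix
    (eigenvalue clipping with diagonal renormalization, iterated).

    Returns the projected matrix and the Frobenius distance moved.
    """
    C = np.asarray(C, dtype=float)
    A = (C + C.T) / 2.0
    for _ in range(max_iter):
        vals, vecs = np.linalg.eigh(A)
        if vals.min() >= tol and np.allclose(np.diag(A), 1.0, atol=1e-12):
            break
        vals = np.clip(vals, tol, None)
        A = (vecs * vals) @ vecs.T
        d = np.sqrt(np.diag(A))
        A = A / np.outer(d, d)
        np.fill_diagonal(A, 1.0)
    return A, float(np.linalg.norm(A - C))


def complete_correlation_matrix(C: np.ndarray, fixed: np.ndarray,
                                eig_floor: float = 1e-3, max_iter: int = 1000,
                                tol: float = 1e-8) -> tuple[np.ndarray, float]:
    """Positive-definite completion holding the ``fixed`` entries exact.

    Only some pairwise correlations are specified; the rest are free.  The
    free entries (initialized in ``C``, typically at 0) are moved by
    alternating projections between the PSD cone (eigenvalues floored at
    ``eig_floor``) and the set of matrices with the fixed entries and unit
    diagonal.  If the fixed entries are jointly infeasible the result is the
    nearest-PD compromise and the residual deviation shows in the returned
    distance.  Returns (completed matrix, Frobenius distance from ``C``).
    """
    C = np.asarray(C, dtype=float)
    fixed = np.asarray(fixed, dtype=bool) | np.eye(C.shape[0], dtype=bool)
    A = (C + C.T) / 2.0
    for _ in range(max_iter):
        vals, vecs = np.linalg.eigh(A)
        if vals.min() >= eig_floor * (1 - 1e-6):
            if np.abs((A - C)[fixed]).max() < tol:
                break
        A = (vecs * np.clip(vals, eig_floor, None)) @ vecs.T
        A[fixed] = C[fixed]
    A = (A + A.T) / 2.0
    if np.linalg.eigvalsh(A).min() <= 0:  # infeasible fixed entries
        A, _ = nearest_correlation_matrix(A, tol=eig_floor)
    return A, float(np.linalg.norm(A - C))


def _adjust_latent_correlation(target_r: float, ppf_i, ppf_j,
                               z_common: np.ndarray) -> float:
    """NORTA adjustment: latent normal correlation whose copula yields the
    target Pearson correlation after the marginal transforms.

    Uses a fixed common-random-number sample for a smooth, monotone
    estimate of r(rho), solved by bisection.
    """
    z0, z1 = z_common

    def realized(rho: float) -> float:
        za = z0
        zb = rho * z0 + np.sqrt(max(1.0 - rho ** 2, 0.0)) * z1
        x = ppf_i(stats.norm.cdf(za))
        yv = ppf_j(stats.norm.cdf(zb))
        return float(np.corrcoef(x, yv)[0, 1])

    lo, hi = (-0.999, 0.999)
    if realized(hi) < target_r:
        return hi if target_r > 0 else lo
    if realized(lo) > target_r:
        return lo
    return float(optimize.brentq(lambda r: realized(r) - target_r, lo, hi, xtol=1e-4))


def _build_latent_matrix(cfg: SyntheticConfig, marginals: dict[str, tuple],
                         z_common) -> tuple[np.ndarray, float]:
    k = len(cfg.elements)
    C = np.eye(k)
    fixed = np.zeros((k, k), dtype=bool)
    index = {e: i for i, e in enumerate(cfg.elements)}
    for (a, b), r in cfg.correlations.items():
        if a not in index or b not in index:
            continue
        ppf_a = lambda u, m=marginals[a]: _trunc_lognorm_ppf(u, *m)
        ppf_b = lambda u, m=marginals[b]: _trunc_lognorm_ppf(u, *m)
        rho = _adjust_latent_correlation(r, ppf_a, ppf_b, z_common)
        i, j = index[a], index[b]
        C[i, j] = C[j, i] = rho
        fixed[i, j] = fixed[j, i] = True
    return complete_correlation_matrix(C, fixed)


# ---------------------------------------------------------------------------
# generator operations


def sample_concentrations(cfg: SyntheticConfig, rng=None,
                          return_truth: bool = False):
    """Draw the reference-chemistry table for the configured population.

    Gaussian-copula draw per region with NORTA-adjusted, nearest-PD latent
    correlations; marginals truncated to the per-region ranges.  The
    configured fraction of lowest Cu/Ni/Pb values is censored to below-LOQ
    (``Nd``) in the reported table; with ``return_truth`` the uncensored
    values, region labels and copula diagnostics are returned too.
    """
    rng = np.random.default_rng(cfg.seed if rng is None else rng)
    regions = cfg.region_of()
    ids = np.array([f"S{i + 1:03d}" for i in range(len(regions))], dtype=object)
    # fixed CRN sample for the latent-correlation adjustment (config-level
    # calibration, deliberately independent of the user's seed)
    z_rng = np.random.default_rng(20151103)
    z_common = z_rng.standard_normal((2, 4000))
    values = np.empty((len(regions), len(cfg.elements)))
    diagnostics = {}
    for region in cfg.region_counts:
        mask = regions == region
        if not mask.any():
            continue
        marginals = {
            e: _solve_marginal(*REGION_STATS[region][e], loq=cfg.loq)
            for e in cfg.elements
        }
        latent, dist = _build_latent_matrix(cfg, marginals, z_common)
        diagnostics[region] = {"projection_distance": dist,
                               "latent": latent.tolist()}
        L = np.linalg.cholesky(latent)
        Z = rng.standard_normal((int(mask.sum()), len(cfg.elements))) @ L.T
        U = stats.norm.cdf(Z)
        for j, e in enumerate(cfg.elements):
            values[mask, j] = _trunc_lognorm_ppf(U[:, j], *marginals[e])
    truth_values = pd.DataFrame(values, index=ids, columns=list(cfg.elements))
    censored = truth_values.copy()
    below = pd.DataFrame(False, index=ids, columns=list(cfg.elements))
    for e, frac in cfg.nd_fraction.items():
        if e not in censored.columns or frac <= 0:
            continue
        cutoff = censored[e].quantile(frac)
        mask = censored[e] <= cutoff
        below[e] = mask
        censored.loc[mask, e] = np.nan
    table = ReferenceTable(values=censored, below_loq=below, loq=cfg.loq)
    if return_truth:
        truth = {"regions": dict(zip(ids, regions)),
                 "true_values": truth_values,
                 "copula": diagnostics}
        return table, truth
    return table


def _gaussian(wl: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((wl - center) / width) ** 2)


def baseline_spectrum(wl: np.ndarray) -> np.ndarray:
    """Fixed organic-matrix baseline (absorbance)."""
    out = 0.5 + 0.25 * (wl - wl[0]) / (wl[-1] - wl[0])
    for center, width, amp in MATRIX_BANDS:
        out = out + amp * _gaussian(wl, center, width)
    return out


def band_amplitudes(cfg: SyntheticConfig) -> dict[str, float]:
    """Absorbance per mg/kg per element: band_strength / pooled SD, so the
    concentration signal of element e contributes ~band_strength absorbance
    SD at its primary band center."""
    return {e: cfg.bands[e].band_strength / _pooled_sd(e, cfg)
            for e in cfg.elements if e in cfg.bands}


def clean_spectra(values: pd.DataFrame, cfg: SyntheticConfig) -> np.ndarray:
    """Noise- and scatter-free spectra for the given true concentrations."""
    wl = cfg.grid()
    amps = band_amplitudes(cfg)
    base = baseline_spectrum(wl)
    out = np.tile(base, (len(values), 1))
    for e, amp in amps.items():
        shape = np.zeros_like(wl)
        for center, width, weight in cfg.bands[e].bands:
            shape += weight * _gaussian(wl, center, width)
        out += np.outer(values[e].to_numpy(dtype=float) * amp, shape)
    return out


def generate_spectra(concs: ReferenceTable, cfg: SyntheticConfig, rng=None,
                     true_values: pd.DataFrame | None = None) -> SpectraSet:
    """Replicate spectra for the given concentrations.

    Censored (Nd) cells fall back to LOQ/2 unless the uncensored
    ``true_values`` are supplied.  Scatter has a sample-level component
    (multiplicative factor, offset, tilt) and a replicate-level component;
    white noise is added per recorded channel.
    """
    rng = np.random.default_rng(cfg.seed + 1 if rng is None else rng)
    values = true_values if true_values is not None else concs.values.fillna(cfg.loq / 2)
    wl = cfg.grid()
    if cfg.association_sd:
        # spectra respond to the organically bound fraction: a per-sample
        # noisy proxy of the reference concentration
        values = values.copy()
        for e, frac in cfg.association_sd.items():
            if e in values.columns and frac > 0:
                sd = _pooled_sd(e, cfg)
                values[e] = values[e] + rng.normal(0.0, frac * sd, size=len(values))
    clean = clean_spectra(values, cfg)
    n = clean.shape[0]
    tilt_axis = (wl - wl.mean()) / (wl[-1] - wl[0])
    rows, ids, reps = [], [], []
    for i in range(n):
        m_s = np.exp(rng.normal(0.0, cfg.mult_log_sd))
        a_s = rng.normal(0.0, cfg.add_sd)
        tilt = rng.normal(0.0, cfg.tilt_sd)
        for r in range(cfg.n_replicates):
            m_r = np.exp(rng.normal(0.0, cfg.rep_mult_log_sd))
            a_r = rng.normal(0.0, cfg.rep_add_sd)
            eps = rng.normal(0.0, cfg.noise_sd, size=wl.size) if cfg.noise_sd > 0 else 0.0
            rows.append(m_s * m_r * clean[i] + a_s + a_r + tilt * tilt_axis + eps)
            ids.append(concs.sample_ids[i])
            reps.append(f"r{r + 1}")
    return SpectraSet(
        wavelengths=wl,
        absorbance=np.vstack(rows),
        sample_ids=np.array(ids, dtype=object),
        replicate=np.array(reps, dtype=object) if cfg.n_replicates > 1 else None,
    )


@dataclass
class SimulatedDataset:
    spectra: SpectraSet
    reference: ReferenceTable
    truth: dict

    @property
    def calibration_ids(self) -> list:
        return self.truth["calibration_ids"]

    @property
    def validation_ids(self) -> list:
        return self.truth["validation_ids"]


def make_dataset(cfg: SyntheticConfig | None = None,
                 outdir: str | Path | None = None) -> SimulatedDataset:
    """Full dataset: replicate spectra, censored reference table and the
    truth record (true concentrations, band amplitudes, copula diagnostics,
    noise levels, calibration/validation split)."""
    cfg = cfg or SyntheticConfig()
    rng = np.random.default_rng(cfg.seed)
    reference, truth = sample_concentrations(cfg, rng=rng, return_truth=True)
    spectra = generate_spectra(reference, cfg, rng=rng,
                               true_values=truth["true_values"])
    ids = reference.sample_ids
    if cfg.n_calibration + cfg.n_validation != len(ids):
        raise ValueError("calibration + validation sizes must equal n_samples")
    perm = rng.permutation(len(ids))
    truth["calibration_ids"] = [str(s) for s in ids[np.sort(perm[:cfg.n_calibration])]]
    truth["validation_ids"] = [str(s) for s in ids[np.sort(perm[cfg.n_calibration:])]]
    truth["band_amplitudes"] = band_amplitudes(cfg)
    truth["band_centers"] = {e: [b[0] for b in sig.bands]
                             for e, sig in cfg.bands.items()}
    truth["noise"] = {"noise_sd": cfg.noise_sd, "mult_log_sd": cfg.mult_log_sd,
                      "add_sd": cfg.add_sd, "tilt_sd": cfg.tilt_sd,
                      "rep_mult_log_sd": cfg.rep_mult_log_sd,
                      "rep_add_sd": cfg.rep_add_sd}
    truth["target_correlations"] = {f"{a}-{b}": r
                                    for (a, b), r in cfg.correlations.items()}
    truth["seed"] = cfg.seed
    dataset = SimulatedDataset(spectra=spectra, reference=reference, truth=truth)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        spectra.write_csv(outdir / "spectra.csv")
        reference.write_csv(outdir / "reference.csv")
        payload = dict(truth)
        payload["true_values"] = truth["true_values"].to_dict(orient="index")
        (outdir / "truth.json").write_text(json.dumps(payload, indent=2, default=str))
    return dataset


def implant_outliers(
    dataset: SimulatedDataset,
    element: str = "K",
    n_spectral: int = 3,
    n_chemical: int = 2,
    rng=None,
) -> tuple[SpectraSet, ReferenceTable, dict]:
    """Copy the dataset with implanted outliers for screening tests.

    Spectral outliers: all replicate rows of the chosen samples are scaled
    tenfold and given a large spurious band (gross contamination).
    Chemical outliers: the element's reference value is replaced by a
    grossly wrong one (mean + 8 population SD) while the spectrum is left
    intact.  Returns modified copies and the implanted ids.
    """
    rng = np.random.default_rng(rng)
    spectra, reference = dataset.spectra, dataset.reference
    cal_ids = [s for s in dataset.calibration_ids
               if not bool(reference.below_loq[element].loc[s])]
    chosen = rng.choice(np.asarray(cal_ids, dtype=object),
                        size=n_spectral + n_chemical, replace=False)
    spectral_ids = list(chosen[:n_spectral])
    chemical_ids = list(chosen[n_spectral:])
    absorbance = spectra.absorbance.copy()
    wl = spectra.wavelengths
    spur = 5.0 * _gaussian(wl, 1700.0, 30.0)
    for sid in spectral_ids:
        rows = np.flatnonzero(spectra.sample_ids == sid)
        absorbance[rows] = absorbance[rows] * 10.0 + spur
    new_spectra = SpectraSet(wavelengths=wl, absorbance=absorbance,
                             sample_ids=spectra.sample_ids.copy(),
                             replicate=None if spectra.replicate is None
                             else spectra.replicate.copy())
    values = reference.values.copy()
    col = values[element].dropna()
    wrong = col.mean() + 8.0 * col.std(ddof=1)
    for sid in chemical_ids:
        values.loc[sid, element] = wrong
    new_reference = ReferenceTable(values=values,
                                   below_loq=reference.below_loq.copy(),
                                   loq=reference.loq)
    return new_spectra, new_reference, {"spectral": spectral_ids,
                                        "chemical": chemical_ids}
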