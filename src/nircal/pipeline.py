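"""Study orchestration: per-element treatment grid search, calibration with
outlier elimination, external validation and report generation.

Each element is calibrated independently; a failure for one element is
recorded and does not stop the others.  All randomness flows from the
config seed through per-element spawned generators, so a config plus input
files fully determines every number in the report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assess, mpls
from .io import ELEMENTS, ReferenceTable, SpectraSet, align, average_replicates
from .pretreat import parse_treatment

__all__ = [
    "DEFAULT_TREATMENT_GRID",
    "PipelineConfig",
    "GridSearchResult",
    "ElementResult",
    "RunReport",
    "grid_search",
    "calibrate_element",
    "run_calibration",
    "run_external",
]

log = logging.getLogger(__name__)

REPORT_SCHEMA = "nircal-report/1"

#: Scatter options crossed with the derivative codes seen in practice.
DEFAULT_TREATMENT_GRID: tuple[str, ...] = tuple(
    f"{scatter} {code}"
    for scatter in ("None", "SNV only", "Standard MSC", "Detrend only", "SNV-Detrend")
    for code in ("0,0,1,1", "1,4,4,1", "2,4,4,1", "2,10,10,1")
)


@dataclass
class PipelineConfig:
    elements: tuple[str, ...] = ELEMENTS
    treatments: tuple[str, ...] = DEFAULT_TREATMENT_GRID
    n_groups: int = 6
    h_threshold: float = 3.0
    t_threshold: float = 2.5
    max_t_passes: int = 2
    max_factors: int = 16
    target_variance: float = 0.99
    loq_policy: str = "drop"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.h_threshold <= 0 or self.t_threshold <= 0:
            raise ValueError("outlier thresholds must be positive")
        if not self.treatments:
            raise ValueError("treatment grid is empty")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        for key in ("elements", "treatments"):
            if key in known and known[key] is not None:
                known[key] = tuple(known[key])
        return cls(**known)


@dataclass
class GridSearchResult:
    best_treatment: str
    leaderboard: pd.DataFrame  # columns: treatment, n_factors, rmsecv


def grid_search(X, y, grid, wavelengths=None, n_groups: int = 6,
                max_factors: int = 16, rng=None) -> GridSearchResult:
    """Cross-validate every treatment; winner has the lowest RMSECV at its
    selected factor count (ties: fewer factors, then grid order).

    The CV partition is drawn once and shared by all treatments so the
    comparison is paired.
    """
    if not grid:
        raise ValueError("treatment grid is empty")
    rng = np.random.default_rng(rng)
    partition_seed = int(rng.integers(2 ** 31))
    rows = []
    failures = {}
    for order, text in enumerate(grid):
        try:
            treatment = parse_treatment(text, wavelengths=wavelengths)
            cv = mpls.cross_validate(X, y, treatment=treatment, n_groups=n_groups,
                                     max_factors=max_factors,
                                     rng=np.random.default_rng(partition_seed))
            rows.append({"treatment": text, "n_factors": cv.n_factors,
                         "rmsecv": cv.rmsecv, "order": order})
        except Exception as exc:  # noqa: BLE001 - per-treatment isolation
            failures[text] = str(exc)
            log.warning("treatment %r failed: %s", text, exc)
    if not rows:
        raise RuntimeError(f"all treatments failed: {failures}")
    board = pd.DataFrame(rows).sort_values(
        ["rmsecv", "n_factors", "order"]).reset_index(drop=True)
    return GridSearchResult(best_treatment=board.loc[0, "treatment"],
                            leaderboard=board.drop(columns="order"))


@dataclass
class ElementResult:
    element: str
    treatment: str
    calibration: mpls.FittedCalibration
    extrema: list[tuple[float, float]]
    leaderboard: pd.DataFrame | None = None
    error: str | None = None


@dataclass
class RunReport:
    """Everything a calibration run produced, with self-auditing export."""

    config: PipelineConfig
    results: dict[str, ElementResult] = field(default_factory=dict)
    external: dict[str, assess.ExternalValidationSummary] = field(default_factory=dict)
    errors: dict[str, str] = field(default_factory=dict)

    def summaries(self) -> list[assess.CalibrationSummary]:
        return [r.calibration.summary for r in self.results.values()
                if r.calibration is not None]

    def self_audit(self) -> None:
        """Verify the internal relations of every row before writing."""
        for s in self.summaries():
            lo, hi = assess.estimation_bounds(s.mean, s.sd)
            assert abs(s.est_min - lo) < 1e-9 and abs(s.est_max - hi) < 1e-9
            assert abs(s.rpd - s.sd / s.rmsecv) < 1e-9
            assert 0.0 <= s.r2 <= 1.0
        for e in self.external.values():
            n = e.n
            lhs = e.rmsep ** 2
            rhs = e.bias ** 2 + e.rmsep_c ** 2 * (n - 1) / n
            assert abs(lhs - rhs) <= 1e-9 * max(1.0, lhs)
            assert abs(e.rpd - e.sd / e.rmsep_c) < 1e-9

    def calibration_table(self) -> pd.DataFrame:
        rows = []
        for element, r in self.results.items():
            s = r.calibration.summary
            rows.append({
                "Constituent": element, "Math treatment": s.treatment, "N": s.n,
                "Mean": round(s.mean, 1), "SD": round(s.sd, 1),
                "Est. Min": round(s.est_min, 1), "Est. Max": round(s.est_max, 1),
                "RMSEC": round(s.rmsec, 1), "R2": round(s.r2, 2),
                "RMSECV": round(s.rmsecv, 1), "RPD": round(s.rpd, 1),
            })
        return pd.DataFrame(rows)

    def validation_table(self) -> pd.DataFrame:
        rows = []
        for element, e in self.external.items():
            rows.append({
                "Constituent": element, "Mean": round(e.mean, 1),
                "SD": round(e.sd, 1), "Est. Min": round(e.est_min, 1),
                "Est. Max": round(e.est_max, 1), "RMSEP": round(e.rmsep, 1),
                "RMSEP(C)": round(e.rmsep_c, 1), "RPD": round(e.rpd, 1),
            })
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        self.self_audit()
        out = {
            "schema": REPORT_SCHEMA,
            "seed": self.config.seed,
            "config": {k: list(v) if isinstance(v, tuple) else v
                       for k, v in vars(self.config).items()},
            "elements": {},
            "external": {k: v.to_dict() for k, v in self.external.items()},
            "errors": self.errors,
        }
        for element, r in self.results.items():
            cal = r.calibration
            out["elements"][element] = {
                "treatment": r.treatment,
                "summary": cal.summary.to_dict(),
                "n_eliminated": cal.outliers.n_eliminated,
                "eliminated": cal.outliers.to_records(),
                "coefficient_extrema": r.extrema,
                "leaderboard": (r.leaderboard.to_dict(orient="records")
                                if r.leaderboard is not None else None),
            }
        return out

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(
            json.dumps(self.to_dict(), indent=2, default=_json_default, sort_keys=True))
        self.calibration_table().to_csv(outdir / "calibration_table.csv", index=False)
        if self.external:
            self.validation_table().to_csv(outdir / "validation_table.csv", index=False)
        for element, r in self.results.items():
            mpls.save_model(r.calibration, outdir / f"model_{element}.json")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return str(obj)


def calibrate_element(spectra: SpectraSet, reference: ReferenceTable, element: str,
                      cfg: PipelineConfig, rng) -> ElementResult:
    """Align, grid-search the treatment, then calibrate with elimination."""
    aligned = align(spectra, reference, element, loq_policy=cfg.loq_policy)
    search = grid_search(aligned.X, aligned.y, cfg.treatments,
                         wavelengths=aligned.wavelengths, n_groups=cfg.n_groups,
                         max_factors=cfg.max_factors, rng=rng)
    calibration = mpls.fit_with_elimination(
        aligned.X, aligned.y, search.best_treatment, element=element,
        sample_ids=aligned.ids, n_groups=cfg.n_groups,
        h_threshold=cfg.h_threshold, t_threshold=cfg.t_threshold,
        max_t_passes=cfg.max_t_passes, max_factors=cfg.max_factors,
        target_variance=cfg.target_variance, wavelengths=aligned.wavelengths,
        rng=rng)
    extrema = mpls.coefficient_extrema(calibration.model, calibration.wavelengths)
    return ElementResult(element=element, treatment=search.best_treatment,
                         calibration=calibration, extrema=extrema,
                         leaderboard=search.leaderboard)


def run_calibration(spectra: SpectraSet, reference: ReferenceTable,
                    cfg: PipelineConfig | None = None) -> RunReport:
    """Calibrate every configured element; failures are isolated."""
    cfg = cfg or PipelineConfig()
    report = RunReport(config=cfg)
    seeds = np.random.SeedSequence(cfg.seed).spawn(len(cfg.elements))
    for element, seq in zip(cfg.elements, seeds):
        try:
            report.results[element] = calibrate_element(
                spectra, reference, element, cfg, rng=np.random.default_rng(seq))
        except Exception as exc:  # noqa: BLE001 - per-element isolation
            log.error("calibration of %s failed: %s", element, exc)
            report.errors[element] = str(exc)
    return report


def run_external(models: dict[str, mpls.FittedCalibration],
                 spectra: SpectraSet, reference: ReferenceTable,
                 loq_policy: str = "drop") -> dict[str, assess.ExternalValidationSummary]:
    """Apply saved calibrations to a validation set (averaged replicates)."""
    averaged = average_replicates(spectra)
    out: dict[str, assess.ExternalValidationSummary] = {}
    for element, calibration in models.items():
        aligned = align(averaged, reference, element, loq_policy=loq_policy)
        y_pred = calibration.predict(aligned.X)
        out[element] = assess.external_validate(aligned.y, y_pred, element=element)
    return out
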