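"""Spectra and reference-chemistry tables: reading, writing, alignment.

Two wide-CSV dialects are supported:

* **Spectra CSV** — first column ``sample_id``, optional second column
  ``replicate``, remaining headers are wavelengths in nm on a uniform grid.
  Cell values are absorbance, log(1/R).
* **Reference CSV** — first column ``sample_id``, remaining columns element
  symbols; cells are concentrations in mg/kg, or the token ``Nd`` for a
  value below the quantification limit (default 0.01 mg/kg).

The default spectral grid is 1100–2000 nm in 2 nm steps (451 channels),
the working range of a fiber-optic NIR reflectance probe.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ELEMENTS",
    "DEFAULT_LOQ",
    "ND_TOKEN",
    "FormatError",
    "SpectraSet",
    "ReferenceTable",
    "Aligned",
    "default_grid",
    "read_spectra",
    "write_spectra",
    "average_replicates",
    "read_reference",
    "write_reference",
    "align",
]

log = logging.getLogger(__name__)

#: Element columns of the reference chemistry, mg/kg.
ELEMENTS = ("Al", "Ca", "Fe", "K", "Mg", "P", "Cr", "Cu", "Ni", "Pb", "Zn")

#: Quantification limit (mg/kg) below which cells carry the ``Nd`` token.
DEFAULT_LOQ = 0.01

ND_TOKEN = "Nd"


class FormatError(ValueError):
    """Raised when an input table violates the expected dialect."""


def default_grid(start: float = 1100.0, stop: float = 2000.0, step: float = 2.0) -> np.ndarray:
    """Uniform wavelength grid in nm, endpoints inclusive (default 451 channels)."""
    n = int(round((stop - start) / step)) + 1
    return start + step * np.arange(n)


def _check_grid(wavelengths: np.ndarray) -> None:
    w = np.asarray(wavelengths, dtype=float)
    if w.ndim != 1 or w.size < 2:
        raise FormatError("wavelength grid must be 1-D with at least 2 channels")
    d = np.diff(w)
    if np.any(d <= 0):
        raise FormatError("wavelengths must be strictly increasing")
    if not np.allclose(d, d[0], rtol=1e-8, atol=1e-9):
        raise FormatError("wavelength grid is not uniform")


@dataclass
class SpectraSet:
    """A block of NIR spectra on a shared uniform wavelength grid.

    Rows may be replicate scans of the same sample; ``replicate`` then holds
    a per-row replicate label and ``sample_ids`` may repeat.  After
    :func:`average_replicates` the ids are unique and ``replicate`` is None.
    """

    wavelengths: np.ndarray
    absorbance: np.ndarray
    sample_ids: np.ndarray
    replicate: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.absorbance = np.atleast_2d(np.asarray(self.absorbance, dtype=float))
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        _check_grid(self.wavelengths)
        if self.absorbance.shape != (self.sample_ids.size, self.wavelengths.size):
            raise FormatError(
                f"absorbance shape {self.absorbance.shape} does not match "
                f"{self.sample_ids.size} ids x {self.wavelengths.size} channels"
            )
        if not np.all(np.isfinite(self.absorbance)):
            raise FormatError("absorbance contains non-finite values")
        if self.replicate is not None:
            self.replicate = np.asarray(self.replicate, dtype=object)
            if self.replicate.size != self.sample_ids.size:
                raise FormatError("replicate labels do not match row count")
            pairs = list(zip(self.sample_ids, self.replicate))
            if len(set(pairs)) != len(pairs):
                raise FormatError("duplicate (sample_id, replicate) rows")
        else:
            if len(set(self.sample_ids)) != self.sample_ids.size:
                raise FormatError("duplicate sample ids without replicate labels")

    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_channels(self) -> int:
        return self.absorbance.shape[1]

    def to_frame(self) -> pd.DataFrame:
        cols = {"sample_id": self.sample_ids}
        if self.replicate is not None:
            cols["replicate"] = self.replicate
        frame = pd.DataFrame(cols)
        spec = pd.DataFrame(self.absorbance, columns=[_fmt_wl(w) for w in self.wavelengths])
        return pd.concat([frame, spec], axis=1)

    def write_csv(self, path: str | Path) -> None:
        # %.17g guarantees float64 round-trip through the text form
        self.to_frame().to_csv(path, index=False, float_format="%.17g")


def _fmt_wl(w: float) -> str:
    return f"{w:g}"


def read_spectra(path: str | Path) -> SpectraSet:
    """Read a wide spectra CSV (see module docstring for the dialect)."""
    frame = pd.read_csv(path, float_precision="round_trip")
    if frame.shape[1] < 3:
        raise FormatError("spectra file needs an id column and >= 2 wavelengths")
    cols = list(frame.columns)
    id_col = cols[0]
    rep_col = cols[1] if cols[1].strip().lower() == "replicate" else None
    wl_cols = cols[2:] if rep_col else cols[1:]
    try:
        wavelengths = np.array([float(c) for c in wl_cols])
    except ValueError as exc:
        raise FormatError(f"non-numeric wavelength header: {exc}") from None
    _check_grid(wavelengths)
    values = frame[wl_cols].to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise FormatError("absorbance contains missing or non-finite cells")
    return SpectraSet(
        wavelengths=wavelengths,
        absorbance=values,
        sample_ids=frame[id_col].astype(str).to_numpy(dtype=object),
        replicate=frame[rep_col].astype(str).to_numpy(dtype=object) if rep_col else None,
    )


def write_spectra(spectra: SpectraSet, path: str | Path) -> None:
    spectra.write_csv(path)


def average_replicates(spectra: SpectraSet) -> SpectraSet:
    """Average replicate scans per sample (arithmetic mean per channel).

    Sample order follows first occurrence.  Idempotent on an already
    averaged set.
    """
    if spectra.replicate is None:
        return SpectraSet(
            wavelengths=spectra.wavelengths,
            absorbance=spectra.absorbance.copy(),
            sample_ids=spectra.sample_ids.copy(),
        )
    order: list[object] = []
    groups: dict[object, list[int]] = {}
    for i, sid in enumerate(spectra.sample_ids):
        if sid not in groups:
            groups[sid] = []
            order.append(sid)
        groups[sid].append(i)
    means = np.vstack([spectra.absorbance[groups[sid]].mean(axis=0) for sid in order])
    return SpectraSet(
        wavelengths=spectra.wavelengths,
        absorbance=means,
        sample_ids=np.array(order, dtype=object),
    )


@dataclass
class ReferenceTable:
    """Per-sample element concentrations (mg/kg) with below-LOQ flags.

    ``values`` has NaN where a cell is below the quantification limit;
    ``below_loq`` is the corresponding boolean mask.
    """

    values: pd.DataFrame
    below_loq: pd.DataFrame = field(default=None)  # type: ignore[assignment]
    loq: float = DEFAULT_LOQ

    def __post_init__(self) -> None:
        if self.below_loq is None:
            self.below_loq = self.values.isna()
        if self.values.index.has_duplicates:
            raise FormatError("duplicate sample ids in reference table")
        with np.errstate(invalid="ignore"):
            if (self.values.to_numpy(dtype=float) < 0).any():
                raise FormatError("negative concentration in reference table")

    @property
    def sample_ids(self) -> np.ndarray:
        return self.values.index.to_numpy(dtype=object)

    @property
    def elements(self) -> list[str]:
        return list(self.values.columns)

    def to_frame(self) -> pd.DataFrame:
        out = self.values.astype(object).copy()
        out[self.below_loq] = ND_TOKEN
        return out

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index_label="sample_id", float_format="%.17g")


def read_reference(path: str | Path, loq: float = DEFAULT_LOQ) -> ReferenceTable:
    """Read a reference-chemistry CSV; ``Nd`` cells are flagged below-LOQ."""
    frame = pd.read_csv(path, index_col=0, float_precision="round_trip")
    frame.index = frame.index.astype(str)
    mask = frame.apply(lambda c: c.astype(str).str.strip().str.lower() == ND_TOKEN.lower())
    values = frame.mask(mask)
    try:
        values = values.astype(float)
    except ValueError as exc:
        raise FormatError(f"non-numeric concentration cell: {exc}") from None
    return ReferenceTable(values=values, below_loq=mask, loq=loq)


def write_reference(table: ReferenceTable, path: str | Path) -> None:
    table.write_csv(path)


@dataclass
class Aligned:
    """Matched spectra/chemistry block for one element."""

    X: np.ndarray
    y: np.ndarray
    ids: np.ndarray
    wavelengths: np.ndarray
    n_dropped: int = 0


def align(
    spectra: SpectraSet,
    reference: ReferenceTable,
    element: str,
    loq_policy: str = "drop",
) -> Aligned:
    """Match spectra rows with an element's concentrations by sample id.

    Replicates are averaged first.  Samples missing from either block are
    dropped; below-LOQ cells are handled per ``loq_policy``:

    * ``"drop"`` (default) — exclude the sample from this element,
    * ``"zero"`` — substitute 0,
    * ``"half_loq"`` — substitute LOQ/2.
    """
    if element not in reference.values.columns:
        raise KeyError(f"element {element!r} not in reference table")
    if loq_policy not in ("drop", "zero", "half_loq"):
        raise ValueError(f"unknown loq_policy {loq_policy!r}")
    avg = average_replicates(spectra)
    ref_ids = set(reference.sample_ids)
    rows, ids, y = [], [], []
    n_dropped = 0
    col = reference.values[element]
    flag = reference.below_loq[element]
    for i, sid in enumerate(avg.sample_ids):
        if sid not in ref_ids:
            n_dropped += 1
            continue
        if bool(flag.loc[sid]):
            if loq_policy == "drop":
                n_dropped += 1
                continue
            val = 0.0 if loq_policy == "zero" else reference.loq / 2.0
        else:
            val = float(col.loc[sid])
        rows.append(i)
        ids.append(sid)
        y.append(val)
    n_dropped += len(ref_ids - set(avg.sample_ids))
    if not rows:
        raise ValueError(f"no usable samples for element {element!r}")
    if n_dropped:
        log.info("align(%s): dropped %d samples (missing or below LOQ)", element, n_dropped)
    return Aligned(
        X=avg.absorbance[rows],
        y=np.asarray(y, dtype=float),
        ids=np.array(ids, dtype=object),
        wavelengths=avg.wavelengths,
        n_dropped=n_dropped,
    )
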