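"""Spectral preprocessing chain.

The chain reduces instrument noise, removes the water-dominated O-H
stretch region, corrects baseline drift and puts spectra on a common
scale, and is applied identically at train and predict time:

1. Savitzky-Golay smoothing (or derivative, if ``derivative_order`` > 0);
2. truncation to the fingerprint window (default 1800-900 cm^-1, which
   discards the broad water absorption above 1800 cm^-1 entirely);
3. baseline correction (rubberband by default: the lower convex hull of
   the spectrum is subtracted);
4. normalization (unit Euclidean norm by default).

Training uses per-patient replicate averages (``patient_mean``);
prediction preprocesses each replicate independently (``per_replicate``)
so the replicate-consensus vote has three independent inputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .spectra_io import PatientRecord, SpectralDataset, Spectrum, WavenumberGrid

BASELINE_METHODS = ("rubberband", "polynomial", "none")
NORMALIZATIONS = ("vector_unit_norm", "amide_I_peak", "none")

#: window, in cm^-1, searched for the Amide I maximum when normalizing to it
AMIDE_I_WINDOW = (1620.0, 1680.0)


@dataclass(frozen=True)
class PreprocConfig:
    smooth_window: int = 9
    smooth_polyorder: int = 2
    truncate_to: tuple = (1800.0, 900.0)
    baseline_method: str = "rubberband"
    baseline_poly_order: int = 2
    normalization: str = "vector_unit_norm"
    derivative_order: int = 0

    def __post_init__(self) -> None:
        if self.smooth_window < 5 or self.smooth_window % 2 == 0:
            raise ValueError("smooth_window must be an odd integer >= 5")
        if self.smooth_polyorder >= self.smooth_window:
            raise ValueError("smooth_polyorder must be < smooth_window")
        hi, lo = self.truncate_to
        if hi <= lo:
            raise ValueError("truncate_to must be (high, low) with high > low")
        if self.baseline_method not in BASELINE_METHODS:
            raise ValueError(f"baseline_method must be one of {BASELINE_METHODS}")
        if self.normalization not in NORMALIZATIONS:
            raise ValueError(f"normalization must be one of {NORMALIZATIONS}")
        if self.derivative_order not in (0, 1, 2):
            raise ValueError("derivative_order must be 0, 1 or 2")
        if self.derivative_order > self.smooth_polyorder:
            raise ValueError("derivative_order must be <= smooth_polyorder")

    def to_dict(self) -> dict:
        return {
            "smooth_window": self.smooth_window,
            "smooth_polyorder": self.smooth_polyorder,
            "truncate_to": list(self.truncate_to),
            "baseline_method": self.baseline_method,
            "baseline_poly_order": self.baseline_poly_order,
            "normalization": self.normalization,
            "derivative_order": self.derivative_order,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PreprocConfig":
        d = dict(d)
        if "truncate_to" in d:
            d["truncate_to"] = tuple(d["truncate_to"])
        return cls(**d)


def average_replicates(record: PatientRecord) -> Spectrum:
    """Pointwise arithmetic mean of a patient's raw replicates."""
    if not record.replicates:
        raise ValueError(f"patient {record.patient_id} has no replicates")
    stack = np.vstack([s.absorbance for s in record.replicates])
    return Spectrum(
        record.grid,
        stack.mean(axis=0),
        {"patient_id": record.patient_id, "n_averaged": str(len(record.replicates))},
    )


def _lower_hull_baseline(x_asc: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Rubberband baseline: piecewise-linear interpolant of the lower
    convex hull of (x, y), with x ascending.  Monotone-chain construction,
    so degenerate (collinear) inputs are handled exactly."""
    hull: list[int] = []
    for i in range(x_asc.size):
        while len(hull) >= 2:
            j, k = hull[-2], hull[-1]
            # keep only right turns (lower hull); drop k if (j,k,i) is not
            # strictly convex from below
            cross = (x_asc[k] - x_asc[j]) * (y[i] - y[j]) - (
                x_asc[i] - x_asc[j]
            ) * (y[k] - y[j])
            if cross >= 0.0:
                break
            hull.pop()
        hull.append(i)
    idx = np.asarray(hull)
    return np.interp(x_asc, x_asc[idx], y[idx])


def rubberband_baseline(spectrum: Spectrum) -> np.ndarray:
    """Baseline estimate on the spectrum's own (descending) grid."""
    x_asc = spectrum.grid.values[::-1]
    y_asc = spectrum.absorbance[::-1]
    return _lower_hull_baseline(x_asc, y_asc)[::-1]


def truncate_spectrum(spectrum: Spectrum, high: float, low: float) -> Spectrum:
    g = spectrum.grid.values
    if high > g[0] + 1e-9 or low < g[-1] - 1e-9:
        raise ValueError(
            f"truncation window ({high}, {low}) outside grid span ({g[0]}, {g[-1]})"
        )
    mask = (g <= high + 1e-9) & (g >= low - 1e-9)
    return Spectrum(WavenumberGrid(g[mask]), spectrum.absorbance[mask], spectrum.meta)


def preprocess_spectrum(s: Spectrum, cfg: PreprocConfig) -> Spectrum:
    """Apply the ordered chain: smooth/derivative, truncate, baseline,
    normalize.  The output grid is the truncated grid."""
    g = s.grid.values
    y = savgol_filter(
        s.absorbance,
        cfg.smooth_window,
        cfg.smooth_polyorder,
        deriv=cfg.derivative_order,
        delta=s.grid.spacing,
    )
    if cfg.derivative_order % 2 == 1:
        y = -y  # grid runs high-to-low; d/d(wavenumber) flips sign

    out = truncate_spectrum(Spectrum(s.grid, y, s.meta), *cfg.truncate_to)
    g, y = out.grid.values, out.absorbance

    if cfg.baseline_method == "rubberband":
        y = y - rubberband_baseline(out)
    elif cfg.baseline_method == "polynomial":
        # fit on a centered, scaled axis for conditioning
        t = (g - g.mean()) / (g[0] - g[-1])
        coef = np.polynomial.polynomial.polyfit(t, y, cfg.baseline_poly_order)
        y = y - np.polynomial.polynomial.polyval(t, coef)

    if cfg.normalization == "vector_unit_norm":
        nrm = float(np.linalg.norm(y))
        if nrm == 0.0:
            raise ValueError("cannot unit-normalize an all-zero spectrum")
        y = y / nrm
    elif cfg.normalization == "amide_I_peak":
        win = (g <= AMIDE_I_WINDOW[1]) & (g >= AMIDE_I_WINDOW[0])
        if not win.any():
            raise ValueError("Amide I window not inside the truncated grid")
        peak = float(np.max(np.abs(y[win])))
        if peak == 0.0:
            raise ValueError("zero Amide I peak; cannot normalize")
        y = y / peak

    if not np.all(np.isfinite(y)):
        raise ValueError("preprocessing produced non-finite values")
    return Spectrum(out.grid, y, {**s.meta, "preprocessed": "true"})


def preprocess_dataset(
    dataset: SpectralDataset, cfg: PreprocConfig, mode: str = "patient_mean"
) -> SpectralDataset:
    """Preprocess a cohort.

    ``patient_mean``: average each patient's raw replicates, then run the
    chain once per patient (the training-time convention).
    ``per_replicate``: run the chain on every replicate independently
    (the prediction-time convention feeding the replicate consensus).
    """
    if mode not in ("patient_mean", "per_replicate"):
        raise ValueError("mode must be 'patient_mean' or 'per_replicate'")
    records = []
    shared_grid = None
    for p in dataset.patients:
        if mode == "patient_mean":
            reps = [preprocess_spectrum(average_replicates(p), cfg)]
        else:
            reps = [preprocess_spectrum(s, cfg) for s in p.replicates]
        shared_grid = reps[0].grid
        records.append(PatientRecord(p.patient_id, p.label, reps, dict(p.covariates)))
    if shared_grid is None:
        shared_grid = WavenumberGrid(
            truncate_spectrum(
                Spectrum(dataset.grid, np.zeros(dataset.grid.n_points)),
                *cfg.truncate_to,
            ).grid.values
        )
    meta = {**dataset.meta, "preprocess_mode": mode, "preproc": cfg.to_dict()}
    return SpectralDataset(records, shared_grid, meta)


def dataset_matrix(dataset: SpectralDataset):
    """Stack a preprocessed dataset into (X, y, ids): one row per spectrum.

    y is 1 for positive, 0 for negative; unknown labels are excluded.
    """
    rows, ys, ids = [], [], []
    for p in dataset.patients:
        if p.label == "unknown":
            continue
        for s in p.replicates:
            rows.append(s.absorbance)
            ys.append(1 if p.label == "positive" else 0)
            ids.append(p.patient_id)
    return np.vstack(rows), np.asarray(ys, dtype=int), ids
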