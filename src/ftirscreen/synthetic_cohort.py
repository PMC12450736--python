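"""Seeded synthetic ATR-FTIR urine cohorts.

Real biofluid spectra are dominated by broad water absorption above
~2800 cm^-1, a crowded fingerprint region (1800-900 cm^-1) of overlapping
biomolecular bands, slow baseline drift, and correlated within-patient
replicates.  The generator emulates exactly that structure so the entire
downstream pipeline (preprocessing, MC-GA-LDA, consensus prediction,
cohort statistics) can be exercised end to end without any external data:

* a descending ~1,715-point grid over 4000-400 cm^-1 (4 cm^-1 instrument
  resolution, ~2.1 cm^-1 digitization);
* a shared band structure of Gaussian (optionally Lorentzian) peaks, with
  class-dependent amplitude offsets planted at the seven diagnostic bands
  reported for endometriosis urine (1660, 1646, 1593, 1462, 1150, 1063,
  1025 cm^-1), alternating in sign between the lipid/protein and
  carbohydrate regions;
* a broad water envelope (O-H stretch hump plus the 1635 cm^-1 bending
  band) identical in both classes;
* per-replicate random low-order polynomial baseline drift and i.i.d.
  point noise, plus a per-patient offset shared by that patient's
  replicates (so within-patient variance < between-patient variance);
* a categorical questionnaire table drawn with exact per-group counts.

Triplicate acquisition and a balanced 50/50 cohort of 100 patients are
the defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .spectra_io import (
    PatientRecord,
    SpectralDataset,
    Spectrum,
    WavenumberGrid,
    default_grid,
)


@dataclass(frozen=True)
class BandSpec:
    """One absorption band: a Gaussian (or Lorentzian) of given center
    (cm^-1), width (sigma / half-width, cm^-1) and amplitude, plus a
    signed amplitude offset applied to the positive class."""

    center: float
    width: float
    base_amplitude: float
    class_effect: float = 0.0
    shape: str = "gaussian"

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("band width must be > 0")
        if self.base_amplitude < 0:
            raise ValueError("base_amplitude must be >= 0")
        if self.shape not in ("gaussian", "lorentzian"):
            raise ValueError("shape must be 'gaussian' or 'lorentzian'")

    def profile(self, wavenumbers: np.ndarray, amplitude: float) -> np.ndarray:
        d = wavenumbers - self.center
        if self.shape == "gaussian":
            return amplitude * np.exp(-0.5 * (d / self.width) ** 2)
        return amplitude / (1.0 + (d / self.width) ** 2)


#: The seven diagnostic band centers (cm^-1): lipid CH2 1462, C=C 1660,
#: Amide II 1593, Amide I 1646, C-O 1150, ribose 1063, glycogen 1025.
DIAGNOSTIC_CENTERS = (1462.0, 1660.0, 1593.0, 1646.0, 1150.0, 1063.0, 1025.0)

#: Default class-effect amplitude at the diagnostic bands, in absorbance
#: units before normalization (a few percent of the local band amplitude).
DEFAULT_EFFECT = 0.004


def default_bands(effect: float = DEFAULT_EFFECT) -> tuple:
    """The default urine-like band set.

    Background bands carry no class information; the seven diagnostic
    bands get alternating-sign amplitude offsets so the two group means
    differ in both the 1700-1550 (lipid/protein) and 1200-1000
    (carbohydrate) regions.
    """
    background = [
        BandSpec(2925.0, 18.0, 0.06),   # CH3/CH2 asymmetric stretch
        BandSpec(2855.0, 15.0, 0.04),   # CH2 symmetric stretch
        BandSpec(1550.0, 30.0, 0.10),   # amide envelope shoulder
        BandSpec(1400.0, 22.0, 0.22),   # COO- symmetric stretch (urea region)
        BandSpec(1240.0, 18.0, 0.06),   # amide III / phosphate
        BandSpec(1100.0, 35.0, 0.10),   # broad C-O envelope
        BandSpec(980.0, 14.0, 0.05),
        BandSpec(870.0, 12.0, 0.04),
    ]
    diag_amp = {
        1462.0: 0.12, 1660.0: 0.30, 1593.0: 0.22, 1646.0: 0.28,
        1150.0: 0.10, 1063.0: 0.12, 1025.0: 0.10,
    }
    diagnostic = [
        BandSpec(c, 9.0, diag_amp[c], class_effect=((-1) ** i) * effect)
        for i, c in enumerate(DIAGNOSTIC_CENTERS)
    ]
    return tuple(background + diagnostic)


@dataclass(frozen=True)
class CohortConfig:
    n_patients: int = 100
    prevalence_in_cohort: float = 0.5
    replicates_per_patient: int = 3
    bands: tuple = field(default_factory=default_bands)
    noise_sd: float = 0.008
    baseline_amplitude: float = 0.03
    water_region_amplitude: float = 0.45
    patient_effect_sd: float = 0.02
    seed: int = 0
    grid_high: float = 4000.0
    grid_low: float = 400.0
    grid_points: int = 1715

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        if not 0.0 <= self.prevalence_in_cohort <= 1.0:
            raise ValueError("prevalence_in_cohort must be in [0, 1]")
        if self.replicates_per_patient < 1:
            raise ValueError("replicates_per_patient must be >= 1")
        for name in ("noise_sd", "baseline_amplitude",
                     "water_region_amplitude", "patient_effect_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        span = (self.grid_high, self.grid_low)
        for b in self.bands:
            if not (span[1] <= b.center <= span[0]):
                raise ValueError(f"band center {b.center} outside grid span {span}")

    def grid(self) -> WavenumberGrid:
        return default_grid(self.grid_high, self.grid_low, self.grid_points)


def null_config(seed: int = 0, **overrides) -> CohortConfig:
    """The zero-signal control: identical band structure, every
    class_effect forced to 0."""
    bands = tuple(replace(b, class_effect=0.0) for b in default_bands())
    return CohortConfig(bands=bands, seed=seed, **overrides)


def _water_envelope(w: np.ndarray, amplitude: float) -> np.ndarray:
    """Broad O-H stretch hump above ~2800 cm^-1 plus the 1635 cm^-1
    water bending band; identical in both classes."""
    stretch = amplitude * np.exp(-0.5 * ((w - 3400.0) / 260.0) ** 2)
    bend = 0.35 * amplitude * np.exp(-0.5 * ((w - 1635.0) / 45.0) ** 2)
    return stretch + bend


def clean_class_spectrum(config: CohortConfig, positive: bool) -> np.ndarray:
    """Noise-free class template: band sum (+ class effects for the
    positive class) plus the water envelope."""
    w = config.grid().values
    y = _water_envelope(w, config.water_region_amplitude)
    for b in config.bands:
        amp = b.base_amplitude + (b.class_effect if positive else 0.0)
        y = y + b.profile(w, amp)
    return y


def generate_cohort(config: CohortConfig) -> list:
    """Generate a seeded cohort of :class:`PatientRecord`.

    Deterministic for a fixed config+seed.  Positive-label count is
    ``round(n * prevalence)`` exactly; label order is randomized.  Each
    replicate spectrum is::

        class template + patient offset + random quadratic baseline
        + i.i.d. N(0, noise_sd) point noise

    with the patient offset shared across that patient's replicates.
    """
    rng = np.random.default_rng(config.seed)
    grid = config.grid()
    w = grid.values
    n = config.n_patients
    if n == 0:
        return []

    n_pos = int(np.floor(n * config.prevalence_in_cohort + 0.5))
    labels = np.array(["negative"] * n, dtype=object)
    labels[rng.permutation(n)[:n_pos]] = "positive"

    templates = {
        "positive": clean_class_spectrum(config, True),
        "negative": clean_class_spectrum(config, False),
    }

    # centered/scaled axis for baseline polynomials
    t = (w - w.mean()) / (w[0] - w[-1])

    covar = questionnaire_for_cohort(labels, seed=int(rng.integers(2**31)))

    records = []
    width = max(3, len(str(n)))
    for i in range(n):
        pid = f"P{i + 1:0{width}d}"
        label = str(labels[i])
        offset = rng.normal(0.0, config.patient_effect_sd)
        reps = []
        for r in range(config.replicates_per_patient):
            coef = rng.normal(0.0, config.baseline_amplitude, size=3)
            baseline = coef[0] + coef[1] * t + coef[2] * t**2
            noise = rng.normal(0.0, config.noise_sd, size=w.size)
            y = templates[label] + offset + baseline + noise
            reps.append(Spectrum(grid, y, {"patient_id": pid, "replicate": str(r)}))
        records.append(PatientRecord(pid, label, reps, covar.iloc[i].to_dict()))
    return records


def generate_dataset(config: CohortConfig) -> SpectralDataset:
    """Cohort wrapped as a :class:`SpectralDataset`."""
    return SpectralDataset(
        generate_cohort(config), config.grid(), {"generator_seed": str(config.seed)}
    )


# ---------------------------------------------------------------------------
# Questionnaire covariates
# ---------------------------------------------------------------------------

#: Per-group "Yes" fractions (negative, positive) for the questionnaire
#: variables of the reference 50/50 cohort, reconstructed from the
#: printed per-group counts out of 50.
TABLE1_PROPORTIONS = {
    "painful_periods": (0.92, 0.90),
    "pain_during_intercourse": (0.66, 0.74),
    "pain_burning_during_urination": (0.32, 0.30),
    "painful_bowel_movements": (0.38, 0.42),
    "infertility": (0.12, 0.12),
    "other_gynaecological_diseases": (0.44, 0.12),
    "family_history_of_endometriosis": (0.26, 0.16),
    "pain_on_bimanual_examination": (0.76, 0.74),
    "palpable_masses_on_bimanual_examination": (0.06, 0.20),
    "cervix_injury": (0.04, 0.12),
}

#: Age summaries (mean, sd) per group for the continuous covariate.
AGE_SUMMARY = {"negative": (42.0, 8.1), "positive": (39.0, 7.9)}


def generate_questionnaire(
    n_per_group: int,
    proportions: dict | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Binary questionnaire with exact per-group counts.

    ``proportions`` maps variable name -> (negative-group fraction,
    positive-group fraction) of "Yes" answers.  Per group and variable,
    exactly ``round(n_per_group * fraction)`` patients are "Yes"; which
    patients is randomized under ``seed``.  Age is drawn normally from
    the per-group summaries.
    """
    if n_per_group < 0:
        raise ValueError("n_per_group must be >= 0")
    if proportions is None:
        proportions = TABLE1_PROPORTIONS
    for var, (f0, f1) in proportions.items():
        if not (0.0 <= f0 <= 1.0 and 0.0 <= f1 <= 1.0):
            raise ValueError(f"fractions for {var!r} must be in [0, 1]")

    rng = np.random.default_rng(seed)
    frames = []
    for gi, group in enumerate(("negative", "positive")):
        data = {"group": [group] * n_per_group}
        mu, sd = AGE_SUMMARY[group]
        data["age"] = np.round(rng.normal(mu, sd, size=n_per_group), 1)
        for var, fracs in proportions.items():
            k = int(np.floor(n_per_group * fracs[gi] + 0.5))
            col = np.array(["No"] * n_per_group, dtype=object)
            col[rng.permutation(n_per_group)[:k]] = "Yes"
            data[var] = col
        frames.append(pd.DataFrame(data))
    return pd.concat(frames, ignore_index=True)


def questionnaire_for_cohort(labels: np.ndarray, seed: int = 0) -> pd.DataFrame:
    """Questionnaire rows aligned to an arbitrary label vector.

    Counts are exact per group at the reference fractions; rows are then
    mapped back onto the cohort's label order.
    """
    labels = np.asarray(labels, dtype=object)
    out = pd.DataFrame(index=range(labels.size), dtype=object)
    for group in ("negative", "positive"):
        idx = np.where(labels == group)[0]
        q = generate_questionnaire(idx.size, seed=seed + (0 if group == "negative" else 1))
        q = q[q["group"] == group].reset_index(drop=True)
        for col in q.columns:
            if col not in out.columns:
                out[col] = pd.Series([None] * labels.size, dtype=object)
            out.loc[idx, col] = q[col].values
    return out


def covariates_frame(records: list) -> pd.DataFrame:
    """Collect per-patient covariates into one table (patient_id, group,
    then questionnaire fields)."""
    rows = []
    for p in records:
        row = {"patient_id": p.patient_id, "group": p.label}
        row.update(p.covariates)
        rows.append(row)
    return pd.DataFrame(rows)
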