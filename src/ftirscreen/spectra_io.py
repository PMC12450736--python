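"""Spectral data containers and exchange-format I/O.

Containers
----------
:class:`WavenumberGrid`, :class:`Spectrum`, :class:`PatientRecord` and
:class:`SpectralDataset` are the in-memory objects every stage of the
pipeline consumes.  Wavenumbers are stored high-to-low (instrument
convention); readers that encounter ascending data flip it and record the
fact in metadata rather than silently reordering.

Formats
-------
* Wide CSV — one row per replicate: ``patient_id``, ``replicate``,
  ``label``, then one column per wavenumber (header carries the grid).
* JCAMP-DX 4.24 (minimal subset) — single-spectrum IR exchange files with
  ``XYDATA=(X++(Y..Y))`` blocks in AFFN form.

No resampling or interpolation happens in I/O: grid mismatches between
files are an error, and regridding is an explicit preprocessing decision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALID_LABELS = ("positive", "negative", "unknown")

#: tolerance for declaring grid spacing uniform (cm^-1)
GRID_UNIFORMITY_TOL = 1e-6


class FormatError(ValueError):
    """A file does not conform to the expected exchange format."""


@dataclass(frozen=True)
class WavenumberGrid:
    """A strictly decreasing, uniformly spaced wavenumber axis in cm^-1."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 2:
            raise ValueError("grid needs at least two wavenumbers")
        d = np.diff(v)
        if not np.all(d < 0):
            raise ValueError("wavenumber grid must be strictly decreasing")
        if np.ptp(d) > GRID_UNIFORMITY_TOL:
            raise ValueError("wavenumber grid must be uniformly spaced")
        object.__setattr__(self, "values", v)

    @property
    def n_points(self) -> int:
        return int(self.values.size)

    @property
    def spacing(self) -> float:
        """Absolute step between adjacent points, cm^-1."""
        return float(abs(self.values[1] - self.values[0]))

    def __eq__(self, other) -> bool:  # value semantics
        return isinstance(other, WavenumberGrid) and np.array_equal(
            self.values, other.values
        )

    def __hash__(self) -> int:
        return hash(self.values.tobytes())

    def allclose(self, other: "WavenumberGrid", tol: float = 1e-9) -> bool:
        return self.n_points == other.n_points and bool(
            np.allclose(self.values, other.values, atol=tol, rtol=0.0)
        )


def default_grid(
    high: float = 4000.0, low: float = 400.0, n_points: int = 1715
) -> WavenumberGrid:
    """The instrument-style acquisition grid: 4000-400 cm^-1, ~2.1 cm^-1
    spacing, ~1,700 variables."""
    return WavenumberGrid(np.linspace(high, low, n_points))


@dataclass
class Spectrum:
    """One measurement: a wavenumber grid plus an absorbance vector."""

    grid: WavenumberGrid
    absorbance: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        a = np.asarray(self.absorbance, dtype=float)
        if a.ndim != 1 or a.size != self.grid.n_points:
            raise ValueError(
                f"absorbance length {a.size} != grid length {self.grid.n_points}"
            )
        if not np.all(np.isfinite(a)):
            raise ValueError("absorbance contains non-finite values")
        self.absorbance = a
        self.meta = dict(self.meta)


@dataclass
class PatientRecord:
    """All measurements and questionnaire covariates for one patient."""

    patient_id: str
    label: str
    replicates: list  # list[Spectrum], shared grid
    covariates: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.label not in VALID_LABELS:
            raise ValueError(f"label must be one of {VALID_LABELS}, got {self.label!r}")
        grids = {s.grid for s in self.replicates}
        if len(grids) > 1:
            raise ValueError(f"patient {self.patient_id}: replicates on different grids")

    @property
    def grid(self) -> WavenumberGrid:
        if not self.replicates:
            raise ValueError(f"patient {self.patient_id} has no replicates")
        return self.replicates[0].grid


@dataclass
class SpectralDataset:
    """A cohort of patients sharing one wavenumber grid."""

    patients: list  # list[PatientRecord]
    grid: WavenumberGrid
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [p.patient_id for p in self.patients]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate patient ids in dataset")
        for p in self.patients:
            if p.replicates and p.grid != self.grid:
                raise ValueError(f"patient {p.patient_id} not on the shared grid")

    def __len__(self) -> int:
        return len(self.patients)

    def labels(self) -> dict:
        return {p.patient_id: p.label for p in self.patients}

    def subset(self, ids) -> "SpectralDataset":
        wanted = set(ids)
        return SpectralDataset(
            [p for p in self.patients if p.patient_id in wanted], self.grid,
            dict(self.meta),
        )


# ---------------------------------------------------------------------------
# Wide CSV
# ---------------------------------------------------------------------------

_META_COLS = ("patient_id", "replicate", "label")


def write_wide_csv(dataset: SpectralDataset, path) -> None:
    """One row per replicate; header = patient_id, replicate, label, then
    the wavenumbers of the shared grid."""
    rows = []
    for p in dataset.patients:
        for i, s in enumerate(p.replicates):
            rows.append(
                [p.patient_id, i, p.label] + list(s.absorbance)
            )
    cols = list(_META_COLS) + [repr(float(w)) for w in dataset.grid.values]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def read_wide_csv(path) -> SpectralDataset:
    """Parse a wide-CSV cohort; rows are grouped into PatientRecords.

    Ascending wavenumber headers are flipped to the stored descending
    convention (recorded in dataset meta).  Non-numeric headers, ragged
    or non-finite rows and duplicate (patient, replicate) pairs are
    format errors.
    """
    df = pd.read_csv(path, dtype={"patient_id": str})
    for c in _META_COLS:
        if c not in df.columns:
            raise FormatError(f"missing required column {c!r}")
    wn_cols = [c for c in df.columns if c not in _META_COLS]
    try:
        wns = np.array([float(c) for c in wn_cols])
    except ValueError as exc:
        raise FormatError(f"non-numeric wavenumber header: {exc}") from exc
    if wns.size < 2:
        raise FormatError("fewer than two wavenumber columns")

    flipped = False
    if wns[1] > wns[0]:  # ascending input: normalize
        wns = wns[::-1]
        wn_cols = wn_cols[::-1]
        flipped = True
    grid = WavenumberGrid(wns)

    absorb = df[wn_cols].to_numpy(dtype=float)
    bad = ~np.isfinite(absorb)
    if bad.any():
        row = int(np.where(bad.any(axis=1))[0][0])
        raise FormatError(f"non-finite absorbance in data row {row}")

    seen = set()
    patients: dict[str, dict] = {}
    for i, (_, row) in enumerate(df.iterrows()):
        pid = str(row["patient_id"])
        rep = row["replicate"]
        key = (pid, rep)
        if key in seen:
            raise FormatError(f"duplicate (patient, replicate) pair {key} at row {i}")
        seen.add(key)
        label = str(row["label"])
        if label not in VALID_LABELS:
            label = "unknown"
        rec = patients.setdefault(pid, {"label": label, "reps": []})
        if rec["label"] != label:
            raise FormatError(f"patient {pid} has conflicting labels")
        rec["reps"].append(
            (rep, Spectrum(grid, absorb[i], {"patient_id": pid, "replicate": str(rep)}))
        )

    records = []
    for pid, rec in patients.items():
        reps = [s for _, s in sorted(rec["reps"], key=lambda t: t[0])]
        records.append(PatientRecord(pid, rec["label"], reps))
    meta = {"source": str(path)}
    if flipped:
        meta["flipped_to_descending"] = "true"
    return SpectralDataset(records, grid, meta)


# ---------------------------------------------------------------------------
# JCAMP-DX 4.24 (minimal single-spectrum subset)
# ---------------------------------------------------------------------------

_REQUIRED_LDRS = ("FIRSTX", "LASTX", "NPOINTS")


def write_jcampdx(spectrum: Spectrum, path, title: str = "spectrum") -> None:
    """Write an AFFN ``(X++(Y..Y))`` JCAMP-DX file (>= 8 significant
    digits per ordinate, so round-trips are faithful well past 6)."""
    g = spectrum.grid.values
    y = spectrum.absorbance
    lines = [
        f"##TITLE={title}",
        "##JCAMP-DX=4.24",
        "##DATA TYPE=INFRARED SPECTRUM",
        "##XUNITS=1/CM",
        "##YUNITS=ABSORBANCE",
        f"##FIRSTX={float(g[0])!r}",
        f"##LASTX={float(g[-1])!r}",
        f"##NPOINTS={g.size}",
        "##XFACTOR=1.0",
        "##YFACTOR=1.0",
        "##XYDATA=(X++(Y..Y))",
    ]
    per_line = 6
    for i in range(0, y.size, per_line):
        chunk = y[i : i + per_line]
        lines.append(
            " ".join([f"{g[i]:.6f}"] + [f"{v:.10g}" for v in chunk])
        )
    lines.append("##END=")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


def read_jcampdx(path) -> Spectrum:
    """Read the minimal JCAMP-DX subset written by :func:`write_jcampdx`.

    Ascending-X files are flipped to the descending storage convention
    and flagged in ``meta``.
    """
    ldrs: dict[str, str] = {}
    data_lines: list[str] = []
    in_data = False
    with open(path, "r", encoding="utf-8") as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith("##"):
                key, _, val = line[2:].partition("=")
                key = key.strip().upper()
                if key == "XYDATA":
                    in_data = True
                    ldrs[key] = val.strip()
                elif key == "END":
                    in_data = False
                else:
                    ldrs[key] = val.strip()
            elif in_data:
                data_lines.append(line)

    for key in _REQUIRED_LDRS:
        if key not in ldrs:
            raise FormatError(f"missing required record ##{key}=")
    if "XYDATA" not in ldrs:
        raise FormatError("missing required record ##XYDATA=")

    firstx = float(ldrs["FIRSTX"])
    lastx = float(ldrs["LASTX"])
    npoints = int(ldrs["NPOINTS"])
    yfactor = float(ldrs.get("YFACTOR", "1.0"))

    ys: list[float] = []
    for line in data_lines:
        toks = line.replace(",", " ").split()
        if not toks:
            continue
        ys.extend(float(t) * yfactor for t in toks[1:])  # first token is X
    if len(ys) != npoints:
        raise FormatError(
            f"NPOINTS={npoints} but data block carries {len(ys)} ordinates"
        )

    x = np.linspace(firstx, lastx, npoints)
    y = np.asarray(ys, dtype=float)
    meta = {"title": ldrs.get("TITLE", ""), "source": str(path)}
    if firstx < lastx:  # ascending file: normalize to descending storage
        x = x[::-1]
        y = y[::-1]
        meta["flipped_to_descending"] = "true"
    return Spectrum(WavenumberGrid(x), y, meta)
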