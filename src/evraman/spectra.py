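"""Core data model and I/O for Raman spectra.

A :class:`Spectrum` is a single acquisition: a strictly increasing wavenumber
axis (cm^-1) with one intensity value per point and acquisition metadata
(sample id, class label, donor id, optional map position in µm).  A
:class:`SpectralDataset` is a cohort of spectra resampled onto one common
axis, stored as an n x p matrix with aligned label vectors — the container
every multivariate step in this package operates on.

Two plain-text dialects are supported: ``two_column`` files (wavenumber,
intensity pairs, ``#`` comments allowed) as exported by most instrument
software, and a ``long_format`` delimited table with one row per measured
point, which round-trips whole datasets losslessly.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CLASS_LABELS",
    "Spectrum",
    "SpectralWindowSet",
    "SpectralDataset",
    "SpectrumParseError",
    "SpectrumValidationError",
    "read_spectrum",
    "read_dataset",
    "write_dataset",
    "crop_to_windows",
    "resample_common_axis",
]

#: Recognised class labels: the three EV source cytotypes, plus labels for
#: substrate/background map points, pure-compound reference spectra and
#: unannotated input.
CLASS_LABELS = ("BM-MSC", "ASC", "DF", "background", "reference", "unknown")

LONG_FORMAT_COLUMNS = (
    "sample_id",
    "class_label",
    "donor_id",
    "map_x",
    "map_y",
    "wavenumber",
    "intensity",
)


class SpectrumParseError(ValueError):
    """A text spectrum file could not be parsed (message names the line)."""


class SpectrumValidationError(ValueError):
    """A spectrum or dataset violates a structural invariant."""


def _as_float_array(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise SpectrumValidationError(f"{name} must be one-dimensional")
    if not np.all(np.isfinite(arr)):
        raise SpectrumValidationError(f"{name} contains non-finite values")
    return arr


@dataclass
class Spectrum:
    """One Raman acquisition on its native wavenumber axis.

    Parameters
    ----------
    wavenumbers
        Strictly increasing Raman shifts in cm^-1, length >= 2.
    intensities
        Detector counts (arbitrary units), same length as `wavenumbers`.
    meta
        Free-form metadata; recognised keys are ``sample_id``,
        ``class_label`` (one of :data:`CLASS_LABELS`), ``donor_id`` and the
        optional map coordinates ``map_x`` / ``map_y`` in µm.
    """

    wavenumbers: np.ndarray
    intensities: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.wavenumbers = _as_float_array(self.wavenumbers, "wavenumbers")
        self.intensities = _as_float_array(self.intensities, "intensities")
        if len(self.wavenumbers) != len(self.intensities):
            raise SpectrumValidationError(
                "wavenumbers and intensities differ in length "
                f"({len(self.wavenumbers)} vs {len(self.intensities)})"
            )
        if len(self.wavenumbers) < 2:
            raise SpectrumValidationError("a spectrum needs at least 2 points")
        dw = np.diff(self.wavenumbers)
        if np.any(dw == 0):
            w = self.wavenumbers[:-1][dw == 0][0]
            raise SpectrumValidationError(f"duplicate wavenumber {w:g}")
        if np.any(dw < 0):
            raise SpectrumValidationError("wavenumbers must be strictly increasing")
        label = self.meta.get("class_label", "unknown")
        if label not in CLASS_LABELS:
            raise SpectrumValidationError(f"unknown class_label {label!r}")

    # convenience accessors -------------------------------------------------
    @property
    def sample_id(self) -> str:
        return str(self.meta.get("sample_id", ""))

    @property
    def class_label(self) -> str:
        return str(self.meta.get("class_label", "unknown"))

    @property
    def donor_id(self) -> str:
        return str(self.meta.get("donor_id", ""))

    @property
    def map_x(self):
        return self.meta.get("map_x")

    @property
    def map_y(self):
        return self.meta.get("map_y")

    def __len__(self) -> int:
        return len(self.wavenumbers)

    def with_intensities(self, intensities) -> "Spectrum":
        """Copy carrying the same axis and metadata with new intensities."""
        return Spectrum(self.wavenumbers.copy(), np.asarray(intensities, float),
                        dict(self.meta))


@dataclass
class SpectralWindowSet:
    """Sorted, pairwise-disjoint closed wavenumber intervals [lo, hi] in cm^-1.

    The defaults are the two regions most informative for biological
    specimens: the fingerprint region 500-1800 cm^-1 and the CH-stretch
    (high-wavenumber) region 2600-3200 cm^-1.
    """

    windows: tuple = ((500.0, 1800.0), (2600.0, 3200.0))

    def __post_init__(self):
        wins = [(float(lo), float(hi)) for lo, hi in self.windows]
        for lo, hi in wins:
            if not lo < hi:
                raise SpectrumValidationError(f"window [{lo}, {hi}] has lo >= hi")
        wins.sort()
        for (lo1, hi1), (lo2, hi2) in zip(wins, wins[1:]):
            if hi1 >= lo2:
                raise SpectrumValidationError(
                    f"windows [{lo1}, {hi1}] and [{lo2}, {hi2}] overlap"
                )
        self.windows = tuple(wins)

    def contains(self, wavenumbers) -> np.ndarray:
        """Boolean mask of axis points inside any closed window."""
        w = np.asarray(wavenumbers, float)
        mask = np.zeros(w.shape, dtype=bool)
        for lo, hi in self.windows:
            mask |= (w >= lo) & (w <= hi)
        return mask

    def grid(self, step: float) -> np.ndarray:
        """Concatenated grid {lo, lo+step, ..., <= hi} for each window."""
        if step <= 0:
            raise SpectrumValidationError("grid step must be positive")
        parts = []
        for lo, hi in self.windows:
            npts = int(math.floor((hi - lo) / step + 1e-9)) + 1
            parts.append(lo + step * np.arange(npts))
        return np.concatenate(parts)

    def segment_slices(self, axis: np.ndarray) -> list:
        """Slices of `axis` falling in each window (windows in order)."""
        out = []
        for lo, hi in self.windows:
            idx = np.nonzero((axis >= lo) & (axis <= hi))[0]
            if idx.size:
                out.append(slice(idx[0], idx[-1] + 1))
        return out


@dataclass
class SpectralDataset:
    """n spectra on one common axis: an n x p matrix plus label vectors."""

    axis: np.ndarray
    matrix: np.ndarray
    labels: np.ndarray
    donors: np.ndarray
    ids: np.ndarray
    map_x: np.ndarray | None = None  # NaN marks absent coordinates
    map_y: np.ndarray | None = None

    def __post_init__(self):
        self.axis = _as_float_array(self.axis, "axis")
        if np.any(np.diff(self.axis) <= 0):
            raise SpectrumValidationError("axis must be strictly increasing")
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise SpectrumValidationError("matrix must be 2-D")
        n, p = self.matrix.shape
        if p != len(self.axis):
            raise SpectrumValidationError(
                f"matrix has {p} columns but axis has {len(self.axis)} points"
            )
        if not np.all(np.isfinite(self.matrix)):
            raise SpectrumValidationError("matrix contains non-finite values")
        self.labels = np.asarray(self.labels, dtype=object)
        self.donors = np.asarray(self.donors, dtype=object)
        self.ids = np.asarray(self.ids, dtype=object)
        for name, vec in (("labels", self.labels), ("donors", self.donors),
                          ("ids", self.ids)):
            if len(vec) != n:
                raise SpectrumValidationError(f"{name} has length {len(vec)}, expected {n}")
        for name in ("map_x", "map_y"):
            vec = getattr(self, name)
            if vec is not None:
                vec = np.asarray(vec, dtype=float)
                if len(vec) != n:
                    raise SpectrumValidationError(f"{name} has length {len(vec)}, expected {n}")
                setattr(self, name, vec)

    @property
    def n_spectra(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_points(self) -> int:
        return self.matrix.shape[1]

    def spectrum(self, i: int) -> Spectrum:
        meta = {"sample_id": self.ids[i], "class_label": self.labels[i],
                "donor_id": self.donors[i]}
        if self.map_x is not None and np.isfinite(self.map_x[i]):
            meta["map_x"] = float(self.map_x[i])
        if self.map_y is not None and np.isfinite(self.map_y[i]):
            meta["map_y"] = float(self.map_y[i])
        return Spectrum(self.axis.copy(), self.matrix[i].copy(), meta)

    def spectra(self) -> list:
        return [self.spectrum(i) for i in range(self.n_spectra)]

    def with_matrix(self, matrix) -> "SpectralDataset":
        return SpectralDataset(self.axis.copy(), matrix, self.labels.copy(),
                               self.donors.copy(), self.ids.copy(),
                               None if self.map_x is None else self.map_x.copy(),
                               None if self.map_y is None else self.map_y.copy())


# ---------------------------------------------------------------------------
# reading

_DELIMS = re.compile(r"[,\t ]+")


def _parse_two_column(path: Path) -> Spectrum:
    wn, it = [], []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = [p for p in _DELIMS.split(line) if p]
            if len(parts) != 2:
                raise SpectrumParseError(
                    f"{path}: line {lineno}: expected 2 numeric fields, got {len(parts)}"
                )
            try:
                w, v = float(parts[0]), float(parts[1])
            except ValueError as exc:
                raise SpectrumParseError(
                    f"{path}: line {lineno}: malformed numeric field ({exc})"
                ) from None
            wn.append(w)
            it.append(v)
    if len(wn) < 2:
        raise SpectrumValidationError(f"{path}: fewer than 2 data points")
    wn = np.asarray(wn)
    it = np.asarray(it)
    # instrument exports use both ascending and descending axes
    order = np.argsort(wn, kind="stable")
    wn, it = wn[order], it[order]
    if np.any(np.diff(wn) == 0):
        dup = wn[:-1][np.diff(wn) == 0][0]
        raise SpectrumValidationError(f"{path}: duplicate wavenumber {dup:g}")
    return Spectrum(wn, it, {"sample_id": path.stem, "class_label": "unknown"})


def _sniff_sep(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    if "\t" in header:
        return "\t"
    if "," in header:
        return ","
    return r"\s+"


def _parse_long_format(path: Path) -> list:
    table = pd.read_csv(path, sep=_sniff_sep(path), comment="#",
                        float_precision="round_trip")
    missing = [c for c in LONG_FORMAT_COLUMNS if c not in table.columns]
    if missing:
        raise SpectrumParseError(f"{path}: missing columns {missing}")
    spectra = []
    for sid in table["sample_id"].drop_duplicates():
        sub = table[table["sample_id"] == sid]
        wn = sub["wavenumber"].to_numpy(dtype=float)
        it = sub["intensity"].to_numpy(dtype=float)
        order = np.argsort(wn, kind="stable")
        wn, it = wn[order], it[order]
        if np.any(np.diff(wn) == 0):
            dup = wn[:-1][np.diff(wn) == 0][0]
            raise SpectrumValidationError(
                f"{path}: sample {sid!r}: duplicate wavenumber {dup:g}"
            )
        meta = {
            "sample_id": str(sid),
            "class_label": str(sub["class_label"].iloc[0]),
            "donor_id": "" if pd.isna(sub["donor_id"].iloc[0]) else str(sub["donor_id"].iloc[0]),
        }
        mx, my = sub["map_x"].iloc[0], sub["map_y"].iloc[0]
        if pd.notna(mx):
            meta["map_x"] = float(mx)
        if pd.notna(my):
            meta["map_y"] = float(my)
        spectra.append(Spectrum(wn, it, meta))
    return spectra


def read_spectrum(path, dialect: str = "two_column"):
    """Read one spectrum (``two_column``) or a list (``long_format``).

    Descending axes are silently reordered; duplicate wavenumbers within one
    spectrum and malformed numeric fields raise with the offending location.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "two_column":
        return _parse_two_column(path)
    if dialect == "long_format":
        return _parse_long_format(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def read_dataset(path) -> SpectralDataset:
    """Read a long-format table whose spectra all share one axis."""
    spectra = read_spectrum(path, dialect="long_format")
    if not spectra:
        raise SpectrumValidationError(f"{path}: no spectra")
    axis = spectra[0].wavenumbers
    for s in spectra[1:]:
        if len(s) != len(axis) or not np.array_equal(s.wavenumbers, axis):
            raise SpectrumValidationError(
                f"{path}: sample {s.sample_id!r} is not on the common axis; "
                "use resample_common_axis on the spectrum list instead"
            )
    return dataset_from_spectra(spectra, axis)


def dataset_from_spectra(spectra: Sequence[Spectrum], axis: np.ndarray) -> SpectralDataset:
    """Stack spectra already sharing `axis` into a dataset (row order kept)."""
    matrix = np.stack([s.intensities for s in spectra])
    has_map = any(s.map_x is not None or s.map_y is not None for s in spectra)
    map_x = map_y = None
    if has_map:
        map_x = np.array([np.nan if s.map_x is None else s.map_x for s in spectra])
        map_y = np.array([np.nan if s.map_y is None else s.map_y for s in spectra])
    return SpectralDataset(
        axis=np.asarray(axis, float),
        matrix=matrix,
        labels=[s.class_label for s in spectra],
        donors=[s.donor_id for s in spectra],
        ids=[s.sample_id for s in spectra],
        map_x=map_x,
        map_y=map_y,
    )


# ---------------------------------------------------------------------------
# writing

def write_dataset(d: SpectralDataset, path) -> None:
    """Write a dataset as a long-format CSV that round-trips bit-for-bit.

    Floats are printed with 17 significant digits, which reproduces IEEE
    doubles exactly on re-read; absent map coordinates are emitted as empty
    fields and come back absent.
    """
    path = Path(path)
    n, p = d.matrix.shape
    fmt = "%.17g"
    with open(path, "w") as fh:
        fh.write(",".join(LONG_FORMAT_COLUMNS) + "\n")
        for i in range(n):
            mx = ""
            my = ""
            if d.map_x is not None and np.isfinite(d.map_x[i]):
                mx = fmt % d.map_x[i]
            if d.map_y is not None and np.isfinite(d.map_y[i]):
                my = fmt % d.map_y[i]
            prefix = f"{d.ids[i]},{d.labels[i]},{d.donors[i]},{mx},{my},"
            for j in range(p):
                fh.write(prefix + (fmt % d.axis[j]) + "," + (fmt % d.matrix[i, j]) + "\n")


# ---------------------------------------------------------------------------
# cropping and resampling

def crop_to_windows(s: Spectrum, w: SpectralWindowSet) -> Spectrum:
    """Keep exactly the points whose wavenumber lies in a closed window."""
    mask = w.contains(s.wavenumbers)
    if not mask.any():
        raise SpectrumValidationError(
            f"no points in windows for sample {s.sample_id!r}"
        )
    return Spectrum(s.wavenumbers[mask], s.intensities[mask], dict(s.meta))


def resample_common_axis(
    spectra: Iterable[Spectrum],
    step: float = 1.0,
    w: SpectralWindowSet | None = None,
) -> SpectralDataset:
    """Linear-interpolate spectra onto one common per-window grid.

    Every spectrum must cover each window within an edge tolerance of one
    `step`; the windows are concatenated in ascending order into a single
    feature vector, as all multivariate stages analyse both regions jointly.
    """
    w = w or SpectralWindowSet()
    spectra = list(spectra)
    if not spectra:
        raise SpectrumValidationError("no spectra to resample")
    axis = w.grid(step)
    rows = []
    for s in spectra:
        for lo, hi in w.windows:
            if s.wavenumbers[0] > lo + step + 1e-9 or s.wavenumbers[-1] < hi - step - 1e-9:
                raise SpectrumValidationError(
                    f"sample {s.sample_id!r} does not cover window [{lo:g}, {hi:g}]"
                )
        rows.append(np.interp(axis, s.wavenumbers, s.intensities))
    has_map = any(s.map_x is not None or s.map_y is not None for s in spectra)
    map_x = map_y = None
    if has_map:
        map_x = np.array([np.nan if s.map_x is None else s.map_x for s in spectra])
        map_y = np.array([np.nan if s.map_y is None else s.map_y for s in spectra])
    return SpectralDataset(
        axis, np.stack(rows),
        [s.class_label for s in spectra],
        [s.donor_id for s in spectra],
        [s.sample_id for s in spectra],
        map_x, map_y,
    )
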