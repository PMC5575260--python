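"""Baseline removal, unit-vector normalisation and wavenumber alignment.

The preprocessing chain mirrors standard practice for Raman spectra of
biological material: a sixth-order polynomial baseline removes the broad
autofluorescence background, unit-vector (L2) normalisation makes band
intensities comparable across acquisitions, and a rigid wavenumber-shift
alignment compensates small post-acquisition calibration drifts (thermal
drift of the spectrograph), anchored in practice by the sharp 1003 cm^-1
phenylalanine band.

The baseline is an iterative *modified polyfit* (modpoly): fit a polynomial,
clip the spectrum to the fit wherever it lies above it, refit, and repeat
until the working curve stops changing.  This converges to a lower-envelope
polynomial that passes under the Raman bands instead of through them; a
single unmasked fit is available via ``BaselineConfig(iterative=False)``.
All heavy routines have matrix (whole-dataset) variants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spectra import (
    SpectralDataset,
    SpectralWindowSet,
    Spectrum,
    SpectrumValidationError,
)

__all__ = [
    "BaselineConfig",
    "AlignConfig",
    "BaselineResult",
    "AlignResult",
    "baseline_correct",
    "baseline_correct_matrix",
    "baseline_correct_dataset",
    "vector_normalize",
    "normalize_matrix",
    "normalize_dataset",
    "align_axis",
    "align_dataset",
]


@dataclass
class BaselineConfig:
    """Parameters of the polynomial baseline.

    poly_order : polynomial degree (default 6).
    max_iter   : cap on modpoly iterations.
    rel_tol    : relative-change convergence threshold on the working curve.
    per_window : fit each spectral window independently (default), so the
                 gap between the fingerprint and CH-stretch regions does not
                 constrain the fit.
    iterative  : modpoly when True; a single unmasked polynomial fit when
                 False.
    """

    poly_order: int = 6
    max_iter: int = 100
    rel_tol: float = 1e-6
    per_window: bool = True
    iterative: bool = True

    def __post_init__(self):
        if self.poly_order < 0:
            raise ValueError("poly_order must be >= 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.rel_tol <= 0:
            raise ValueError("rel_tol must be positive")


@dataclass
class AlignConfig:
    """Rigid-shift alignment parameters.

    max_shift   : half-width of the shift search interval, cm^-1.
    anchor_band : band around which the correlation is evaluated (default the
                  1003 cm^-1 phenylalanine ring-breathing peak); the search
                  falls back to the full overlap when the anchor region is
                  outside the axis or nearly empty.
    anchor_halfwidth : half-width of the anchor region, cm^-1.
    resolution  : grid resolution of the shift search, cm^-1.
    """

    max_shift: float = 5.0
    anchor_band: float | None = 1003.0
    anchor_halfwidth: float = 20.0
    resolution: float = 0.1

    def __post_init__(self):
        if self.max_shift <= 0:
            raise ValueError("max_shift must be positive")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")


@dataclass
class BaselineResult:
    corrected: Spectrum
    baseline: Spectrum
    converged: bool
    n_iter: int

    def __iter__(self):  # allows `corrected, baseline = baseline_correct(...)`
        return iter((self.corrected, self.baseline))


@dataclass
class AlignResult:
    aligned: Spectrum
    shift: float
    at_boundary: bool

    def __iter__(self):
        return iter((self.aligned, self.shift))


# ---------------------------------------------------------------------------
# baseline

def _segments(axis: np.ndarray, windows: SpectralWindowSet | None,
              per_window: bool) -> list:
    if not per_window:
        return [slice(0, len(axis))]
    if windows is not None:
        segs = windows.segment_slices(axis)
        if segs:
            return segs
    # infer window boundaries from gaps in the (possibly cropped) axis
    d = np.diff(axis)
    med = np.median(d)
    breaks = np.nonzero(d > 5 * med)[0]
    edges = [0, *[b + 1 for b in breaks], len(axis)]
    return [slice(a, b) for a, b in zip(edges, edges[1:])]


def _modpoly_segment(x: np.ndarray, Y: np.ndarray, cfg: BaselineConfig):
    """Modpoly baselines for all rows of Y over one axis segment.

    Returns (baselines, converged flags, iterations used)."""
    n, p = Y.shape
    if p <= cfg.poly_order + 1:
        raise SpectrumValidationError(
            f"segment has {p} points; need more than poly_order+1 = {cfg.poly_order + 1}"
        )
    # scale the axis to [-1, 1] for a well-conditioned Vandermonde matrix
    mid = 0.5 * (x[0] + x[-1])
    half = 0.5 * (x[-1] - x[0])
    V = np.polynomial.polynomial.polyvander((x - mid) / half, cfg.poly_order)
    Q, _ = np.linalg.qr(V)

    def project(W):
        return (Q @ (Q.T @ W.T)).T

    fitted = project(Y)
    if not cfg.iterative:
        return fitted, np.ones(n, bool), np.ones(n, int)

    work = Y.copy()
    converged = np.zeros(n, bool)
    iters = np.full(n, cfg.max_iter, int)
    for it in range(1, cfg.max_iter + 1):
        fitted = project(work)
        new = np.minimum(work, fitted)
        num = np.linalg.norm(new - work, axis=1)
        den = np.linalg.norm(work, axis=1)
        rel = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
        newly = ~converged & (rel < cfg.rel_tol)
        iters[newly] = it
        converged |= newly
        work = new
        if converged.all():
            break
    return fitted, converged, iters


def baseline_correct_matrix(
    axis: np.ndarray,
    Y: np.ndarray,
    cfg: BaselineConfig | None = None,
    windows: SpectralWindowSet | None = None,
):
    """Baselines for every row of an n x p matrix; returns (corrected,
    baseline, converged, n_iter) arrays."""
    cfg = cfg or BaselineConfig()
    Y = np.asarray(Y, float)
    baselines = np.empty_like(Y)
    converged = np.ones(Y.shape[0], bool)
    iters = np.zeros(Y.shape[0], int)
    for seg in _segments(axis, windows, cfg.per_window):
        b, c, it = _modpoly_segment(axis[seg], Y[:, seg], cfg)
        baselines[:, seg] = b
        converged &= c
        iters = np.maximum(iters, it)
    return Y - baselines, baselines, converged, iters


def baseline_correct(
    s: Spectrum,
    cfg: BaselineConfig | None = None,
    windows: SpectralWindowSet | None = None,
) -> BaselineResult:
    """Estimate and subtract the autofluorescence baseline of one spectrum.

    ``corrected + baseline`` reproduces the input exactly (the corrected
    spectrum is computed by subtraction).  Non-convergence within
    ``max_iter`` sets ``converged=False`` on the result; it is not an error.
    """
    corrected, baseline, conv, iters = baseline_correct_matrix(
        s.wavenumbers, s.intensities[None, :], cfg, windows
    )
    return BaselineResult(
        corrected=s.with_intensities(corrected[0]),
        baseline=s.with_intensities(baseline[0]),
        converged=bool(conv[0]),
        n_iter=int(iters[0]),
    )


def baseline_correct_dataset(
    d: SpectralDataset,
    cfg: BaselineConfig | None = None,
    windows: SpectralWindowSet | None = None,
):
    """Dataset variant; returns (corrected dataset, baseline matrix, converged)."""
    corrected, baselines, conv, _ = baseline_correct_matrix(d.axis, d.matrix, cfg, windows)
    return d.with_matrix(corrected), baselines, conv


# ---------------------------------------------------------------------------
# normalisation

def vector_normalize(s: Spectrum) -> Spectrum:
    """Scale to unit Euclidean (L2) norm."""
    norm = float(np.linalg.norm(s.intensities))
    if norm == 0.0:
        raise SpectrumValidationError(f"zero-norm spectrum {s.sample_id!r}")
    return s.with_intensities(s.intensities / norm)


def normalize_matrix(Y: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(Y, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise SpectrumValidationError("zero-norm spectrum in matrix")
    return Y / norms


def normalize_dataset(d: SpectralDataset) -> SpectralDataset:
    return d.with_matrix(normalize_matrix(d.matrix))


# ---------------------------------------------------------------------------
# alignment

def _correlation_grid(reference: Spectrum, cfg: AlignConfig,
                      lo: float, hi: float) -> np.ndarray:
    """Reference axis points usable for every candidate shift."""
    ax = reference.wavenumbers
    mask = (ax >= lo + cfg.max_shift) & (ax <= hi - cfg.max_shift)
    if cfg.anchor_band is not None:
        anchor = mask & (np.abs(ax - cfg.anchor_band) <= cfg.anchor_halfwidth)
        if anchor.sum() >= 20:
            mask = anchor
    if mask.sum() < 4:
        raise SpectrumValidationError(
            "insufficient overlap between spectrum and reference for alignment"
        )
    return ax[mask]


def align_axis(s: Spectrum, reference: Spectrum,
               cfg: AlignConfig | None = None) -> AlignResult:
    """Find and apply the rigid shift best matching `s` to `reference`.

    The shift delta maximising the Pearson correlation between
    ``s(w - delta)`` and the reference over their common support is located
    by grid search on [-max_shift, +max_shift] at `resolution`; ties are
    broken toward the smaller |delta|.  An optimum at the search boundary is
    flagged (possible drift larger than max_shift) but still applied.
    """
    cfg = cfg or AlignConfig()
    lo = max(s.wavenumbers[0], reference.wavenumbers[0])
    hi = min(s.wavenumbers[-1], reference.wavenumbers[-1])
    if lo >= hi:
        raise SpectrumValidationError("spectrum and reference do not overlap")
    grid = _correlation_grid(reference, cfg, lo, hi)
    ref_vals = np.interp(grid, reference.wavenumbers, reference.intensities)
    ref_c = ref_vals - ref_vals.mean()
    ref_n = np.linalg.norm(ref_c)

    nsteps = int(round(cfg.max_shift / cfg.resolution))
    deltas = cfg.resolution * np.arange(-nsteps, nsteps + 1)
    best_delta, best_corr = 0.0, -np.inf
    for delta in deltas:
        vals = np.interp(grid - delta, s.wavenumbers, s.intensities)
        c = vals - vals.mean()
        cn = np.linalg.norm(c)
        corr = 0.0 if cn == 0 or ref_n == 0 else float(c @ ref_c) / (cn * ref_n)
        if corr > best_corr + 1e-12 or (
            abs(corr - best_corr) <= 1e-12 and abs(delta) < abs(best_delta)
        ):
            best_corr, best_delta = corr, delta
    if best_delta == 0.0:
        aligned = s.with_intensities(s.intensities.copy())
    else:
        aligned = s.with_intensities(
            np.interp(s.wavenumbers - best_delta, s.wavenumbers, s.intensities)
        )
    at_boundary = abs(abs(best_delta) - cfg.max_shift) < 0.5 * cfg.resolution
    return AlignResult(aligned, float(best_delta), at_boundary)


def align_dataset(d: SpectralDataset, cfg: AlignConfig | None = None,
                  reference: np.ndarray | None = None):
    """Align every dataset row to a reference (default: per-channel median).

    The median spectrum of the cohort is a robust, parameter-free drift
    reference.  Returns (aligned dataset, shifts, boundary flags)."""
    cfg = cfg or AlignConfig()
    if reference is None:
        reference = np.median(d.matrix, axis=0)
    ref = Spectrum(d.axis, np.asarray(reference, float), {"sample_id": "reference",
                                                          "class_label": "reference"})
    rows, shifts, flags = [], [], []
    for i in range(d.n_spectra):
        res = align_axis(d.spectrum(i), ref, cfg)
        rows.append(res.aligned.intensities)
        shifts.append(res.shift)
        flags.append(res.at_boundary)
    return d.with_matrix(np.stack(rows)), np.asarray(shifts), np.asarray(flags)
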