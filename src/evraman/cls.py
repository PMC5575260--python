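"""Classical least-squares (CLS) unmixing against a reference library.

CLS rests on the premise that the spectrum of a mixture is a linear
combination of the spectra of its pure ingredients.  Here the targets are
usually PC loadings, which are signed difference spectra, so the fit is
*unconstrained*: negative coefficients are meaningful (a component loading
on the negative lobe of a PC).  References are unit-L2-normalised before
fitting so coefficient magnitudes are comparable across references.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectra import Spectrum, SpectrumValidationError

__all__ = ["LIPID_NAMES", "ReferenceLibrary", "CLSFitResult", "cls_fit"]

#: Default membrane-lipid reference panel: cholesterol, ceramide,
#: sphingomyelin, ganglioside GM1, phosphatidylcholine,
#: phosphatidylethanolamine, phosphatidic acid.
LIPID_NAMES = ("Chol", "Cer", "SM", "GM1", "PCh", "PE", "PA")


@dataclass
class ReferenceLibrary:
    """Named, unit-normalised reference spectra on one common axis."""

    names: list
    spectra: np.ndarray  # m x p, one reference per row
    axis: np.ndarray

    def __post_init__(self):
        self.names = list(self.names)
        self.spectra = np.asarray(self.spectra, float)
        self.axis = np.asarray(self.axis, float)
        if len(set(self.names)) != len(self.names):
            raise SpectrumValidationError("reference names must be unique")
        if self.spectra.ndim != 2 or self.spectra.shape[0] != len(self.names):
            raise SpectrumValidationError("one spectrum row per reference name")
        if self.spectra.shape[1] != len(self.axis):
            raise SpectrumValidationError("reference spectra do not match the axis")
        norms = np.linalg.norm(self.spectra, axis=1)
        if np.any(norms == 0):
            raise SpectrumValidationError("zero-norm reference spectrum")
        if not np.allclose(norms, 1.0, atol=1e-9):
            self.spectra = self.spectra / norms[:, None]

    @classmethod
    def from_spectra(cls, spectra, names=None) -> "ReferenceLibrary":
        """Build from :class:`Spectrum` objects (e.g. two_column files)."""
        spectra = list(spectra)
        if names is None:
            names = [s.sample_id for s in spectra]
        axis = spectra[0].wavenumbers
        for s in spectra[1:]:
            if len(s) != len(axis) or not np.array_equal(s.wavenumbers, axis):
                raise SpectrumValidationError(
                    f"reference {s.sample_id!r} is not on the common axis"
                )
        return cls(names, np.stack([s.intensities for s in spectra]), axis)

    def __len__(self) -> int:
        return len(self.names)


@dataclass
class CLSFitResult:
    """Signed CLS coefficients with the relative-residual percent error."""

    names: list
    coefficients: np.ndarray
    percent_error: float
    residual: np.ndarray
    intercept: float | None = None

    def coefficient(self, name: str) -> float:
        return float(self.coefficients[self.names.index(name)])

    def as_dict(self) -> dict:
        return {n: float(c) for n, c in zip(self.names, self.coefficients)}


def _collinear_pair(G: np.ndarray, names) -> tuple:
    Gn = G / np.linalg.norm(G, axis=0, keepdims=True)
    C = np.abs(Gn.T @ Gn)
    np.fill_diagonal(C, 0.0)
    i, j = np.unravel_index(np.argmax(C), C.shape)
    return names[min(i, j)], names[max(i, j)]


def cls_fit(target, lib: ReferenceLibrary, intercept: bool = False,
            cond_limit: float = 1e10) -> CLSFitResult:
    """Ordinary least-squares decomposition of `target` over the library.

    The solution is unconstrained (signed); with ``intercept`` a constant
    offset column is fitted alongside the references but reported
    separately.  ``percent_error`` is 100 * ||residual|| / ||target|| (L2).
    """
    if isinstance(target, Spectrum):
        if len(target) != len(lib.axis) or not np.array_equal(
            target.wavenumbers, lib.axis
        ):
            raise SpectrumValidationError("target axis does not match the library")
        t = target.intensities
    else:
        t = np.asarray(target, float)
        if t.ndim != 1 or len(t) != lib.spectra.shape[1]:
            raise SpectrumValidationError(
                f"target has {t.shape} values; library axis has {lib.spectra.shape[1]}"
            )
    G = lib.spectra.T
    if intercept:
        G = np.column_stack([G, np.ones(G.shape[0])])
    gram = G.T @ G
    if np.linalg.cond(gram) >= cond_limit:
        a, b = _collinear_pair(lib.spectra.T, lib.names)
        raise SpectrumValidationError(
            f"reference library is rank-deficient (collinear pair: {a}, {b})"
        )
    coef, *_ = np.linalg.lstsq(G, t, rcond=None)
    residual = t - G @ coef
    tnorm = np.linalg.norm(t)
    pct = 100.0 * np.linalg.norm(residual) / tnorm if tnorm > 0 else 0.0
    if intercept:
        return CLSFitResult(list(lib.names), coef[:-1], float(pct), residual,
                            intercept=float(coef[-1]))
    return CLSFitResult(list(lib.names), coef, float(pct), residual)
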