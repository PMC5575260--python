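"""Vesicle/background separation within a Raman map by two-class HCA.

Maps are acquired on a coarse grid over an air-dried drop, so many points
fall on bare substrate.  Agglomerative hierarchical clustering of the
preprocessed map spectra, cut at two clusters, separates vesicle-bearing
points from background; the cluster with the higher mean integrated
intensity over the CH-stretch band (2850-2950 cm^-1, dominated by lipids)
is labelled *vesicle*.  Clustering is purely spectral — map coordinates play
no part.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage

from .spectra import Spectrum, SpectrumValidationError

__all__ = ["RamanMap", "MapPartition", "hca_filter_map", "CH_STRETCH_BAND"]

#: Lipid CH2/CH3 stretch band used to identify the vesicle cluster, cm^-1.
CH_STRETCH_BAND = (2850.0, 2950.0)


@dataclass
class RamanMap:
    """A set of map-acquired spectra sharing one axis, with positions in µm."""

    spectra: list
    grid_note: str = ""

    def __post_init__(self):
        if len(self.spectra) < 4:
            raise SpectrumValidationError("a map needs at least 4 spectra")
        axis = self.spectra[0].wavenumbers
        for s in self.spectra:
            if not isinstance(s, Spectrum):
                raise SpectrumValidationError("map entries must be Spectrum objects")
            if s.map_x is None or s.map_y is None:
                raise SpectrumValidationError(
                    f"map spectrum {s.sample_id!r} lacks map coordinates"
                )
            if len(s.wavenumbers) != len(axis) or not np.array_equal(s.wavenumbers, axis):
                raise SpectrumValidationError("map spectra must share one axis")

    @property
    def axis(self) -> np.ndarray:
        return self.spectra[0].wavenumbers

    def matrix(self) -> np.ndarray:
        return np.stack([s.intensities for s in self.spectra])


@dataclass
class MapPartition:
    """Two-class partition of a map with the dendrogram merge heights."""

    assignments: list
    linkage_summary: np.ndarray
    vesicle_fraction: float
    degenerate: bool = False
    warnings: list = field(default_factory=list)


def _band_intensity(axis: np.ndarray, Y: np.ndarray, band) -> np.ndarray:
    lo, hi = band
    mask = (axis >= lo) & (axis <= hi)
    if mask.sum() >= 2:
        return np.trapezoid(Y[:, mask], axis[mask], axis=1)
    return None


def hca_filter_map(m: RamanMap, linkage_method: str = "ward",
                   metric: str = "euclidean") -> MapPartition:
    """Partition a preprocessed map into vesicle and background spectra.

    Spectra should already be baseline-corrected and unit-normalised on a
    common axis.  The result is deterministic for a fixed input order, and
    permuting the input permutes the assignments identically.
    """
    if linkage_method not in ("ward", "average", "complete"):
        raise ValueError(f"unsupported linkage {linkage_method!r}")
    Y = m.matrix()
    notes = []

    if np.allclose(Y, Y[0], rtol=0.0, atol=0.0):
        return MapPartition(
            assignments=["vesicle"] * len(m.spectra),
            linkage_summary=np.zeros(0),
            vesicle_fraction=1.0,
            degenerate=True,
            warnings=["all spectra identical; single degenerate cluster"],
        )

    Z = linkage(Y, method=linkage_method, metric=metric)
    clusters = fcluster(Z, t=2, criterion="maxclust")

    score = _band_intensity(m.axis, Y, CH_STRETCH_BAND)
    if score is None:
        notes.append(
            "CH-stretch band absent from axis; using total integrated intensity"
        )
        warnings.warn(notes[-1], stacklevel=2)
        score = np.trapezoid(Y, m.axis, axis=1)

    means = {c: score[clusters == c].mean() for c in np.unique(clusters)}
    vesicle_cluster = max(sorted(means), key=lambda c: means[c])
    assignments = ["vesicle" if c == vesicle_cluster else "background"
                   for c in clusters]
    return MapPartition(
        assignments=assignments,
        linkage_summary=Z[:, 2].copy(),
        vesicle_fraction=float(np.mean(clusters == vesicle_cluster)),
        degenerate=False,
        warnings=notes,
    )
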