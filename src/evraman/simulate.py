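"""Synthetic Raman spectra with known ground truth.

The generator emulates the statistical structure of an EV Raman study in
which three cytotypes (BM-MSC, ASC, DF) are measured over a handful of
donors with >= 10 replicate spectra each, in the fingerprint (500-1800
cm^-1) and CH-stretch (2600-3200 cm^-1) windows.  Each synthetic spectrum
is built as

    sum_r  w_r * reference_r        (7 membrane-lipid references)
  + protein/nucleic-acid band block (Phe 1003, amide III 1200-1300,
                                     CH 1450 and 2940 cm^-1, NA 720-820)
  + random 6th-order polynomial autofluorescence baseline
  + additive Gaussian detector noise,

with a donor-level multiplicative perturbation of band amplitudes shared by
all spectra of one donor.  The default class contrasts encode the lipidomic
signature the analysis is meant to recover: sphingomyelin enriched in ASC
EVs, ganglioside GM1 and phosphatidylcholine enriched in BM-MSC and DF EVs.
All outputs are deterministic functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .cls import LIPID_NAMES, ReferenceLibrary
from .spectra import SpectralDataset, SpectralWindowSet, Spectrum

__all__ = [
    "Band",
    "ClassSpec",
    "GeneratorConfig",
    "default_config",
    "make_reference_library",
    "generate_dataset",
    "generate_map",
]


@dataclass
class Band:
    """A single vibrational band: Lorentzian (natural Raman line shape) or
    Gaussian, parameterised by center (cm^-1), FWHM (cm^-1) and peak height."""

    center: float
    fwhm: float
    amplitude: float
    shape: str = "lorentzian"

    def __post_init__(self):
        if self.fwhm <= 0:
            raise ValueError("fwhm must be positive")
        if self.amplitude < 0:
            raise ValueError("amplitude must be nonnegative")
        if self.shape not in ("lorentzian", "gaussian"):
            raise ValueError(f"unknown band shape {self.shape!r}")

    def profile(self, axis: np.ndarray) -> np.ndarray:
        x = np.asarray(axis, float) - self.center
        if self.shape == "lorentzian":
            hw = 0.5 * self.fwhm
            return self.amplitude * hw**2 / (x**2 + hw**2)
        return self.amplitude * np.exp(-4.0 * np.log(2.0) * x**2 / self.fwhm**2)


def _band_sum(axis: np.ndarray, bands, scales=None) -> np.ndarray:
    out = np.zeros(len(axis))
    for i, b in enumerate(bands):
        s = 1.0 if scales is None else scales[i]
        out += s * b.profile(axis)
    return out


# ---------------------------------------------------------------------------
# reference library

# Band tables (center, fwhm, height) for the 7 lipid standards.  Centers
# follow the usual literature assignments: sterol ring modes at 537/614/702
# cm^-1 for cholesterol (ester), the 1127 cm^-1 band shared by ceramides,
# the 718 cm^-1 choline headgroup band of SM and PCh, acyl-chain C-C
# stretches near 1060-1100 cm^-1, CH2 twist near 1300, CH deformation near
# 1440, C=O ester near 1735 and the CH2/CH3 stretch complex at 2850-3010.
_LIPID_BANDS = {
    "Chol": [(537, 12, 0.60), (614, 10, 0.35), (702, 10, 0.95), (740, 10, 0.20),
             (960, 12, 0.25), (1130, 14, 0.45), (1442, 18, 0.80), (1672, 14, 0.45),
             (2868, 24, 0.55), (2935, 26, 0.35)],
    "Cer":  [(723, 12, 0.30), (885, 12, 0.55), (1063, 12, 0.45), (1127, 12, 0.95),
             (1296, 14, 0.85), (1440, 16, 0.60), (1650, 16, 0.50),
             (2880, 20, 0.60)],
    "SM":   [(718, 10, 0.95), (875, 12, 0.35), (1064, 12, 0.55), (1086, 12, 0.45),
             (1127, 12, 0.40), (1296, 12, 0.50), (1440, 18, 0.70), (1735, 14, 0.20),
             (2850, 20, 0.45), (2930, 22, 0.55)],
    "GM1":  [(545, 14, 0.40), (890, 14, 0.50), (1054, 12, 0.60), (1076, 12, 0.40),
             (1140, 14, 0.75), (1342, 16, 0.50), (1458, 18, 0.60), (1655, 18, 0.55),
             (2890, 24, 0.50), (2940, 24, 0.40)],
    "PCh":  [(718, 10, 0.70), (875, 12, 0.40), (968, 12, 0.35), (1064, 12, 0.45),
             (1094, 12, 0.50), (1265, 14, 0.60), (1301, 12, 0.75), (1440, 18, 0.65),
             (1657, 16, 0.55), (1735, 14, 0.35), (2850, 20, 0.50), (3010, 16, 0.45)],
    "PE":   [(760, 12, 0.70), (875, 12, 0.30), (1064, 12, 0.50), (1085, 12, 0.45),
             (1230, 14, 0.40), (1298, 12, 0.75), (1440, 16, 0.55), (1656, 16, 0.45),
             (1735, 14, 0.25), (2885, 20, 0.55), (2960, 20, 0.40)],
    "PA":   [(524, 12, 0.45), (870, 12, 0.50), (978, 12, 0.35), (1046, 12, 0.70),
             (1096, 12, 0.55), (1178, 12, 0.30), (1298, 12, 0.55), (1440, 16, 0.60),
             (1735, 14, 0.35), (2852, 20, 0.55), (2922, 22, 0.45)],
}

#: Protein / nucleic-acid band block common to all vesicle spectra:
#: nucleic-acid ring breathing 720-820, phenylalanine 1003, C-C/PO2 1090,
#: amide III 1240, CH deformation 1450, amide I 1660, CH stretch 2940 cm^-1.
_COMMON_BANDS = [
    Band(780, 22, 0.25), Band(1003, 8, 0.60), Band(1090, 18, 0.20),
    Band(1240, 40, 0.35), Band(1450, 20, 0.90), Band(1660, 26, 0.60),
    Band(2940, 30, 1.00),
]


def make_reference_library(axis=None, seed: int = 0) -> ReferenceLibrary:
    """Deterministic 7-lipid reference library on `axis`.

    Each reference is a sum of >= 4 Lorentzian bands with per-seed jitter on
    centers (sd 1 cm^-1) and heights (5%), unit-normalised; the panel is
    constructed so that all pairwise cosine similarities stay below 0.8.
    """
    if axis is None:
        axis = SpectralWindowSet().grid(1.0)
    axis = np.asarray(axis, float)
    if axis[-1] - axis[0] < 300:
        raise ValueError("axis too short to place the reference bands")
    rng = np.random.default_rng(seed)
    rows = []
    for name in LIPID_NAMES:
        bands = _LIPID_BANDS[name]
        jitter_c = rng.normal(0.0, 1.0, size=len(bands))
        jitter_a = 1.0 + rng.normal(0.0, 0.05, size=len(bands))
        profile = np.zeros(len(axis))
        for (c, w, a), dc, da in zip(bands, jitter_c, jitter_a):
            profile += Band(c + dc, w, a * max(da, 0.1)).profile(axis)
        if profile.max() <= 0:
            raise ValueError("axis too short to place the reference bands")
        rows.append(profile)
    return ReferenceLibrary(list(LIPID_NAMES), np.stack(rows), axis)


# ---------------------------------------------------------------------------
# cohort generator

@dataclass
class ClassSpec:
    """One cytotype: lipid mixture weights, class-specific extra bands and
    cohort size (donors and total replicate spectra, split near-evenly)."""

    name: str
    lipid_weights: np.ndarray
    extra_bands: list = field(default_factory=list)
    n_donors: int = 3
    n_spectra: int = 50

    def __post_init__(self):
        self.lipid_weights = np.asarray(self.lipid_weights, float)
        if len(self.lipid_weights) != len(LIPID_NAMES):
            raise ValueError(f"need {len(LIPID_NAMES)} lipid weights")
        if np.any(self.lipid_weights < 0):
            raise ValueError("lipid weights must be nonnegative")
        if self.n_donors < 1 or self.n_spectra < self.n_donors:
            raise ValueError("invalid cohort size")

    def donor_counts(self) -> list:
        base, extra = divmod(self.n_spectra, self.n_donors)
        return [base + (1 if i < extra else 0) for i in range(self.n_donors)]


@dataclass
class GeneratorConfig:
    """Full description of a synthetic cohort.

    noise_sd and baseline_scale are fractions of the maximum band signal;
    donor_effect_sd is the sd of the multiplicative band-amplitude
    perturbation shared by all spectra of one donor.
    """

    classes: list
    noise_sd: float = 0.01
    donor_effect_sd: float = 0.05
    baseline_scale: float = 0.5
    baseline_coeffs_range: tuple = (-1.0, 1.0)
    protein_weight: float = 1.0
    windows: SpectralWindowSet = field(default_factory=SpectralWindowSet)
    step: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.donor_effect_sd < 0:
            raise ValueError("donor_effect_sd must be >= 0")
        names = [c.name for c in self.classes]
        if len(set(names)) != len(names):
            raise ValueError("class names must be unique")

    @property
    def n_spectra(self) -> int:
        return sum(c.n_spectra for c in self.classes)

    def axis(self) -> np.ndarray:
        return self.windows.grid(self.step)


#                       Chol   Cer    SM   GM1   PCh    PE    PA
_DEFAULT_WEIGHTS = {
    "BM-MSC": (0.50, 0.35, 0.25, 0.60, 0.55, 0.30, 0.20),
    "ASC":    (0.50, 0.30, 0.75, 0.15, 0.20, 0.30, 0.20),
    "DF":     (0.45, 0.30, 0.25, 0.50, 0.55, 0.25, 0.20),
}


def default_config(seed: int = 0, **overrides) -> GeneratorConfig:
    """The default three-class cohort: 3/4/3 donors, 50/105/43 spectra.

    SM is weighted up for ASC EVs and GM1/PCh for BM-MSC and DF EVs; small
    class-specific protein bands (tryptophan 1337 for BM-MSC, the ceramide/
    C-N 1127 band for ASC, proline 853/920 for DF) provide the secondary
    fingerprint differences seen between cytotypes.
    """
    classes = [
        ClassSpec("BM-MSC", _DEFAULT_WEIGHTS["BM-MSC"],
                  [Band(1337, 12, 0.20)], n_donors=3, n_spectra=50),
        ClassSpec("ASC", _DEFAULT_WEIGHTS["ASC"],
                  [Band(1127, 10, 0.25)], n_donors=4, n_spectra=105),
        ClassSpec("DF", _DEFAULT_WEIGHTS["DF"],
                  [Band(853, 12, 0.18), Band(920, 12, 0.12)],
                  n_donors=3, n_spectra=43),
    ]
    return GeneratorConfig(classes=classes, seed=seed, **overrides)


def _random_baseline(rng, axis_scaled: np.ndarray, scale: float,
                     coeff_range) -> np.ndarray:
    lo, hi = coeff_range
    coeffs = rng.uniform(lo, hi, size=7)  # 6th-order polynomial
    base = np.polynomial.polynomial.polyval(axis_scaled, coeffs)
    return scale * base


def _signal_components(cfg: GeneratorConfig, lib: ReferenceLibrary,
                       axis: np.ndarray, spec: ClassSpec):
    """Unit-normalised component spectra stacked for fast mixing:
    7 lipid references, the common protein block, then extra bands."""
    protein = _band_sum(axis, _COMMON_BANDS)
    protein /= np.linalg.norm(protein)
    comps = [lib.spectra, protein[None, :]]
    for b in spec.extra_bands:
        prof = b.profile(axis)
        n = np.linalg.norm(prof)
        comps.append((prof / n * b.amplitude)[None, :] if n > 0 else prof[None, :])
    return np.vstack(comps)


def generate_dataset(cfg: GeneratorConfig):
    """Generate the cohort; returns (SpectralDataset, truth).

    `truth` maps each class name to its lipid weight vector.  Spectra are
    emitted in config order (class by class, donor by donor), on the common
    grid of the configured windows.
    """
    rng = np.random.default_rng(cfg.seed)
    axis = cfg.axis()
    xs = (axis - axis[0]) / (axis[-1] - axis[0]) * 2.0 - 1.0
    lib = make_reference_library(axis, seed=cfg.seed)

    rows, labels, donors, ids = [], [], [], []
    truth = {}
    for spec in cfg.classes:
        truth[spec.name] = spec.lipid_weights.copy()
        comps = _signal_components(cfg, lib, axis, spec)
        weights = np.concatenate([
            spec.lipid_weights,
            [cfg.protein_weight],
            np.ones(len(spec.extra_bands)),
        ])
        for di, count in enumerate(spec.donor_counts()):
            donor = f"{spec.name}-donor{di + 1}"
            factors = 1.0 + cfg.donor_effect_sd * rng.standard_normal(len(weights))
            factors = np.clip(factors, 0.1, None)
            mean_signal = (weights * factors) @ comps
            peak = float(mean_signal.max())
            for ri in range(count):
                baseline = _random_baseline(rng, xs, cfg.baseline_scale * peak,
                                            cfg.baseline_coeffs_range)
                noise = rng.normal(0.0, cfg.noise_sd * peak, size=len(axis))
                rows.append(mean_signal + baseline + noise)
                labels.append(spec.name)
                donors.append(donor)
                ids.append(f"{donor}-rep{ri + 1:02d}")
    d = SpectralDataset(axis, np.stack(rows), labels, donors, ids)
    return d, truth


# ---------------------------------------------------------------------------
# map generator

def generate_map(cfg: GeneratorConfig, background_fraction: float,
                 nx: int = 10, ny: int = 10, step_um: float = 25.0,
                 class_name: str | None = None):
    """Generate an nx x ny Raman map; returns (RamanMap, truth assignments).

    A `background_fraction` of grid points carry substrate-only spectra
    (baseline + noise, no vesicle bands); the rest carry vesicle spectra of
    one class drawn as in :func:`generate_dataset` from a single donor.
    """
    from .mapfilter import RamanMap  # local import to avoid a cycle

    if not 0 <= background_fraction < 1:
        raise ValueError("background_fraction must be in [0, 1)")
    if nx * ny < 4 or nx < 1 or ny < 1:
        raise ValueError("degenerate map grid")
    rng = np.random.default_rng(cfg.seed)
    axis = cfg.axis()
    xs = (axis - axis[0]) / (axis[-1] - axis[0]) * 2.0 - 1.0
    lib = make_reference_library(axis, seed=cfg.seed)

    spec = cfg.classes[0] if class_name is None else next(
        c for c in cfg.classes if c.name == class_name
    )
    comps = _signal_components(cfg, lib, axis, spec)
    weights = np.concatenate([
        spec.lipid_weights, [cfg.protein_weight], np.ones(len(spec.extra_bands)),
    ])
    factors = np.clip(1.0 + cfg.donor_effect_sd * rng.standard_normal(len(weights)),
                      0.1, None)
    signal = (weights * factors) @ comps
    peak = float(signal.max())

    n = nx * ny
    n_bg = int(round(background_fraction * n))
    bg_idx = set(rng.choice(n, size=n_bg, replace=False).tolist())
    spectra, truth = [], []
    for i in range(n):
        ix, iy = divmod(i, ny)
        is_bg = i in bg_idx
        baseline = _random_baseline(rng, xs, cfg.baseline_scale * peak,
                                    cfg.baseline_coeffs_range)
        noise = rng.normal(0.0, cfg.noise_sd * peak, size=len(axis))
        vals = baseline + noise + (0.0 if is_bg else signal)
        meta = {
            "sample_id": f"map-{ix:02d}-{iy:02d}",
            "class_label": "background" if is_bg else spec.name,
            "donor_id": f"{spec.name}-map-donor",
            "map_x": ix * step_um,
            "map_y": iy * step_um,
        }
        spectra.append(Spectrum(axis.copy(), vals, meta))
        truth.append("background" if is_bg else "vesicle")
    note = f"{nx}x{ny} grid, {step_um} um steps, {n_bg} background points"
    return RamanMap(spectra, grid_note=note), truth
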