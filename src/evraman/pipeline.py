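"""End-to-end orchestration from a single YAML config.

Stage order is fixed: crop -> baseline -> normalise -> align -> resample ->
(optional HCA background filter) -> PCA -> LOOCV-LDA -> confusion metrics ->
ANOVA and Wilks' Lambda on PC1/PC2 scores -> CLS unmixing of the PC1/PC2
loadings against the lipid reference library.  All randomness derives from
the single config seed, so identical configs produce byte-identical
reports.

Config layout (all keys optional unless noted)::

    seed: 1
    generator:            # either this block ...
      default: true       # start from the built-in three-class cohort
      noise_sd: 0.01
      donor_effect_sd: 0.05
    inputs:               # ... or a long-format table of real spectra
      path: spectra.csv
    preprocess:
      windows: [[500, 1800], [2600, 3200]]
      step: 1.0
      baseline: {poly_order: 6, max_iter: 100, rel_tol: 1.0e-6,
                 per_window: true, iterative: true}
      align: {max_shift: 5.0, anchor_band: 1003.0}
    map_filter: {enabled: false, linkage: ward}
    analysis: {n_pcs: 25, loocv_mode: paper, ridge: 1.0e-8}
    cls: {enabled: true}
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import chemometrics as chem
from .cls import cls_fit
from .mapfilter import RamanMap, hca_filter_map
from .preprocess import (
    AlignConfig,
    BaselineConfig,
    align_dataset,
    baseline_correct_dataset,
    normalize_dataset,
)
from .simulate import GeneratorConfig, default_config, generate_dataset, make_reference_library
from .spectra import (
    SpectralDataset,
    SpectralWindowSet,
    crop_to_windows,
    dataset_from_spectra,
    read_spectrum,
    resample_common_axis,
)

__all__ = ["PipelineError", "RunReport", "run_pipeline", "preprocess_dataset"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunReport:
    """Machine-readable record of one pipeline run."""

    config_echo: dict
    seed: int
    stage_counts: dict = field(default_factory=dict)
    var_fraction: list = field(default_factory=list)
    confusion: dict = field(default_factory=dict)
    metrics: dict = field(default_factory=dict)
    anova: dict = field(default_factory=dict)
    wilks: dict = field(default_factory=dict)
    cls_fits: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def to_json(self, indent: int = 2) -> str:
        payload = {
            "config_echo": self.config_echo,
            "seed": self.seed,
            "stage_counts": self.stage_counts,
            "var_fraction": self.var_fraction,
            "confusion": self.confusion,
            "metrics": self.metrics,
            "anova": self.anova,
            "wilks": self.wilks,
            "cls_fits": self.cls_fits,
            "warnings": self.warnings,
        }
        return json.dumps(payload, indent=indent)

    @classmethod
    def from_json(cls, text: str) -> "RunReport":
        data = json.loads(text)
        return cls(
            config_echo=data["config_echo"], seed=data["seed"],
            stage_counts=data["stage_counts"], var_fraction=data["var_fraction"],
            confusion=data["confusion"], metrics=data["metrics"],
            anova=data["anova"], wilks=data["wilks"], cls_fits=data["cls_fits"],
            warnings=data["warnings"],
        )

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(self.to_json() + "\n")
        if self.confusion:
            classes = self.confusion["classes"]
            lines = ["true\\predicted," + ",".join(classes)]
            for c, row in zip(classes, self.confusion["counts"]):
                lines.append(c + "," + ",".join(str(v) for v in row))
            (outdir / "confusion.csv").write_text("\n".join(lines) + "\n")
        if self.cls_fits:
            lines = ["target," + ",".join(next(iter(self.cls_fits.values()))
                                          ["coefficients"].keys()) + ",percent_error"]
            for pc, fit in self.cls_fits.items():
                coeffs = ",".join("%.17g" % v for v in fit["coefficients"].values())
                lines.append(f"{pc},{coeffs},%.17g" % fit["percent_error"])
            (outdir / "cls_fits.csv").write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# preprocessing entry point shared by pipeline and tests

def preprocess_dataset(
    d: SpectralDataset,
    windows: SpectralWindowSet | None = None,
    baseline_cfg: BaselineConfig | None = None,
    align_cfg: AlignConfig | None = None,
):
    """Baseline-correct, unit-normalise and median-align a dataset.

    The dataset must already be on a common axis (generator output, or real
    spectra after crop + resample).  Returns (dataset, info dict)."""
    windows = windows or SpectralWindowSet()
    corrected, _, converged = baseline_correct_dataset(d, baseline_cfg, windows)
    normalized = normalize_dataset(corrected)
    aligned, shifts, boundary = align_dataset(normalized, align_cfg)
    info = {
        "baseline_converged": bool(converged.all()),
        "max_abs_shift": float(np.max(np.abs(shifts))) if len(shifts) else 0.0,
        "boundary_shifts": int(boundary.sum()),
    }
    return aligned, info


# ---------------------------------------------------------------------------
# config handling

_KNOWN_TOP = {"seed", "generator", "inputs", "preprocess", "map_filter",
              "analysis", "cls"}


def _load_config(config) -> dict:
    if isinstance(config, dict):
        return dict(config)
    text = Path(config).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise PipelineError("config", "config file must contain a mapping")
    return data


def _validate_config(cfg: dict) -> None:
    unknown = set(cfg) - _KNOWN_TOP
    if unknown:
        raise PipelineError("config", f"unknown config keys: {sorted(unknown)}")
    if ("generator" in cfg) == ("inputs" in cfg):
        raise PipelineError(
            "config", "exactly one of 'generator' or 'inputs' is required"
        )


def _generator_from_config(block: dict, seed: int) -> GeneratorConfig:
    block = dict(block or {})
    block.pop("default", None)
    allowed = {"noise_sd", "donor_effect_sd", "baseline_scale",
               "protein_weight", "step"}
    unknown = set(block) - allowed
    if unknown:
        raise PipelineError("config", f"unknown generator keys: {sorted(unknown)}")
    return default_config(seed=seed, **block)


def build_windows(pp: dict) -> SpectralWindowSet:
    if "windows" in (pp or {}):
        return SpectralWindowSet(tuple(tuple(w) for w in pp["windows"]))
    return SpectralWindowSet()


# ---------------------------------------------------------------------------
# the pipeline

def run_pipeline(config) -> RunReport:
    """Execute the full analysis described by a config file or dict."""
    cfg = _load_config(config)
    _validate_config(cfg)
    seed = int(cfg.get("seed", 0))
    pp = cfg.get("preprocess", {}) or {}
    analysis = cfg.get("analysis", {}) or {}
    n_pcs = int(analysis.get("n_pcs", 25))
    loocv_mode = analysis.get("loocv_mode", "paper")
    ridge = float(analysis.get("ridge", 1e-8))
    windows = build_windows(pp)
    step = float(pp.get("step", 1.0))
    baseline_cfg = BaselineConfig(**(pp.get("baseline", {}) or {}))
    align_cfg = AlignConfig(**(pp.get("align", {}) or {}))

    report = RunReport(config_echo=cfg, seed=seed)
    counts = report.stage_counts

    # ingest ---------------------------------------------------------------
    if "generator" in cfg:
        gen_cfg = _generator_from_config(cfg["generator"], seed)
        n_expected = gen_cfg.n_spectra
        if n_pcs > n_expected - 1:
            raise PipelineError(
                "config", f"n_pcs={n_pcs} exceeds n-1={n_expected - 1}"
            )
        d, _truth = generate_dataset(gen_cfg)
        counts["ingest"] = {"in": n_expected, "out": d.n_spectra}
    else:
        path = (cfg["inputs"] or {}).get("path")
        if not path or not Path(path).exists():
            raise PipelineError("ingest", f"input file not found: {path}")
        spectra = read_spectrum(path, dialect="long_format")
        spectra = [crop_to_windows(s, windows) for s in spectra]
        d = resample_common_axis(spectra, step=step, w=windows)
        counts["ingest"] = {"in": len(spectra), "out": d.n_spectra}
        if n_pcs > d.n_spectra - 1:
            raise PipelineError(
                "config", f"n_pcs={n_pcs} exceeds n-1={d.n_spectra - 1}"
            )

    # preprocess -----------------------------------------------------------
    try:
        d, info = preprocess_dataset(d, windows, baseline_cfg, align_cfg)
    except Exception as exc:  # structured stage error
        raise PipelineError("preprocess", str(exc)) from exc
    counts["preprocess"] = {"in": d.n_spectra, "out": d.n_spectra}
    if not info["baseline_converged"]:
        report.warnings.append("baseline did not converge for some spectra")
    if info["boundary_shifts"]:
        report.warnings.append(
            f"{info['boundary_shifts']} spectra aligned at the shift boundary"
        )

    # optional map filter --------------------------------------------------
    mf = cfg.get("map_filter", {}) or {}
    if mf.get("enabled", False):
        if d.map_x is None or d.map_y is None:
            raise PipelineError("map_filter", "dataset has no map coordinates")
        m = RamanMap(d.spectra())
        part = hca_filter_map(m, linkage_method=mf.get("linkage", "ward"))
        keep = [i for i, a in enumerate(part.assignments) if a == "vesicle"]
        counts["map_filter"] = {"in": d.n_spectra, "out": len(keep)}
        d = SpectralDataset(d.axis, d.matrix[keep], d.labels[keep],
                            d.donors[keep], d.ids[keep],
                            None if d.map_x is None else d.map_x[keep],
                            None if d.map_y is None else d.map_y[keep])
        report.warnings.extend(part.warnings)

    # PCA ------------------------------------------------------------------
    try:
        pca = chem.fit_pca(d, n_pcs)
    except Exception as exc:
        raise PipelineError("pca", str(exc)) from exc
    counts["pca"] = {"in": d.n_spectra, "out": d.n_spectra}
    report.var_fraction = [float(v) for v in pca.var_fraction]

    # LOOCV-LDA ------------------------------------------------------------
    try:
        cm = chem.loocv_classify(d, n_pcs=n_pcs, mode=loocv_mode, ridge=ridge)
    except Exception as exc:
        raise PipelineError("loocv", str(exc)) from exc
    counts["loocv"] = {"in": d.n_spectra, "out": int(cm.total)}
    report.confusion = {"classes": cm.classes,
                        "counts": cm.counts.tolist()}
    metrics = chem.confusion_metrics(cm)
    report.metrics = {
        "sensitivity": metrics.sensitivity,
        "specificity": metrics.specificity,
        "accuracy": metrics.accuracy,
        "macro_sensitivity": metrics.macro_sensitivity,
        "macro_specificity": metrics.macro_specificity,
        "macro_accuracy": metrics.macro_accuracy,
    }
    report.warnings.extend(metrics.warnings)

    # separation tests on PC1/PC2 -----------------------------------------
    for j, pc in enumerate(("PC1", "PC2")):
        if j < pca.scores.shape[1]:
            a = chem.anova_scores(pca.scores[:, j], d.labels)
            report.anova[pc] = {"F": a.F, "p": a.p,
                                "df": [a.df_between, a.df_within]}
    k_w = min(2, pca.scores.shape[1])
    w = chem.wilks_test(pca.scores[:, :k_w], d.labels)
    report.wilks = {"lambda": w.lam, "statistic": w.statistic,
                    "df": w.df, "p": w.p}

    # CLS unmixing of PC loadings ------------------------------------------
    cls_block = cfg.get("cls", {}) or {}
    if cls_block.get("enabled", True):
        lib = make_reference_library(d.axis, seed=seed)
        for j, pc in enumerate(("PC1", "PC2")):
            if j < pca.loadings.shape[0]:
                fit = cls_fit(pca.loadings[j], lib)
                report.cls_fits[pc] = {
                    "coefficients": fit.as_dict(),
                    "percent_error": fit.percent_error,
                }
    return report
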