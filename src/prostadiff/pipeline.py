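"""End-to-end orchestration: simulate, train, fit, analyze.

The canonical experiment sequence mirrors the study this package
implements: (1) simulate per-model training corpora and train one regressor
per model (training happens once and is reused across subjects);
(2) simulate the 3-class cohort; (3) fit every model to every patient
volume (the ADC map by log-linear fit on the clinical scheme, IVIM, DKI
and VERDICT by the trained networks) and summarize ROIs by their median;
(4) compare true-positive vs false-positive lesions and false-positive
lesions vs normal tissue (Wilcoxon + Shapiro-Wilk), compute ROC/AUC and
the PPV/NPV-maximizing thresholds, and the voxel-wise cross-model
parameter correlation panel.

Every stage is deterministic under the root seed of the run configuration;
a manifest (config hash, seeds, package version) is written next to the
outputs so any stage can be re-run bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .fitting import FitterConfig, FittedEstimator, compute_adc_map, fit_volume, train_fitter
from .scheme import AcquisitionScheme, read_scheme, verdict_scheme, write_cohort_table
from .signals import D_IC_DEFAULT, D_VASC_DEFAULT
from .stats import (
    DEFAULT_CORRELATION_PAIRS,
    GroupComparison,
    ROCResult,
    compare_groups,
    parameter_correlations,
    roc_analysis,
)
from .synth import Cohort, CohortSpec, PriorBox, generate_cohort, generate_training_set

logger = logging.getLogger("prostadiff")

FITTED_MODELS = ("IVIM", "DKI", "VERDICT")  # ADC is fitted log-linearly, not learned


@dataclass
class RunConfig:
    """Configuration of a full synthetic run (YAML-loadable)."""

    scheme_path: str | None = None
    models: tuple[str, ...] = ("ADC", "IVIM", "DKI", "VERDICT")
    n_train: int = 100_000
    snr: float | None = 35.0
    seed: int = 0
    d_IC: float = D_IC_DEFAULT
    d_VASC: float = D_VASC_DEFAULT
    fitter: FitterConfig = field(default_factory=FitterConfig)
    cohort: CohortSpec = field(default_factory=CohortSpec)
    priors: PriorBox = field(default_factory=PriorBox)
    outdir: str = "run"

    def scheme(self) -> AcquisitionScheme:
        return read_scheme(self.scheme_path) if self.scheme_path else verdict_scheme()


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML run configuration; nested sections map onto the dataclasses."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    fitter = FitterConfig(**raw.pop("fitter", {}))
    cohort_kwargs = raw.pop("cohort", {})
    if "models" not in cohort_kwargs and "models" in raw:
        cohort_kwargs["models"] = tuple(raw["models"])
    priors = PriorBox(raw.pop("priors", {}))
    if "d_IC" not in raw or "d_VASC" not in raw:
        logger.warning(
            "compartment diffusivities not set in config; using package defaults "
            "d_IC=%.1f, d_VASC=%.1f um^2/ms (fixed constants of the VERDICT model)",
            D_IC_DEFAULT,
            D_VASC_DEFAULT,
        )
    cohort = CohortSpec(priors=priors, **cohort_kwargs)
    cfg = RunConfig(fitter=fitter, cohort=cohort, priors=priors, **raw)
    cfg = dataclasses.replace(cfg, models=tuple(cfg.models))
    return cfg


def config_hash(cfg: RunConfig) -> str:
    def enc(o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return {f.name: enc(getattr(o, f.name)) for f in dataclasses.fields(o)}
        if isinstance(o, dict):
            return {str(k): enc(v) for k, v in sorted(o.items(), key=lambda kv: str(kv[0]))}
        if isinstance(o, (list, tuple)):
            return [enc(v) for v in o]
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        return o

    blob = json.dumps(enc(cfg), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(cfg: RunConfig, outdir: str | Path, stage: str) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "stage": stage,
        "package_version": __version__,
        "config_hash": config_hash(cfg),
        "seed": cfg.seed,
        "config": json.loads(json.dumps(dataclasses.asdict(cfg), default=str)),
    }
    path = outdir / f"manifest_{stage}.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def train_all(cfg: RunConfig) -> dict[str, FittedEstimator]:
    """Simulate a training corpus and train one regressor per learned model."""
    scheme = cfg.scheme()
    estimators: dict[str, FittedEstimator] = {}
    for k, model in enumerate(m for m in cfg.models if m in FITTED_MODELS):
        ds = generate_training_set(
            model, scheme, cfg.priors, n=cfg.n_train, snr=cfg.snr, seed=cfg.seed + 1000 + k
        )
        fitter = dataclasses.replace(cfg.fitter, seed=cfg.seed + 2000 + k)
        estimators[model] = train_fitter(ds, fitter, cfg.priors)
        logger.info(
            "trained %s: best epoch %d, validation MSE %.3g",
            model,
            estimators[model].best_epoch,
            estimators[model].validation_mse,
        )
    return estimators


def fit_cohort(
    cohort: Cohort, estimators: dict[str, FittedEstimator]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fit every model to every patient volume.

    Returns ``(cohort_table, voxel_frame)``: the per-ROI median/IQR summary
    table and a voxel-level frame (one row per ROI voxel, one column per
    parameter across all models) used for the correlation panel.
    """
    tables: list[pd.DataFrame] = []
    voxel_cols: dict[tuple[str, str], dict[str, np.ndarray]] = {}

    for model, per_patient in cohort.volumes.items():
        scheme = cohort.schemes[model]
        for pid, vol in per_patient.items():
            if model == "ADC":
                adc = compute_adc_map(vol, scheme.b * 1e3)
                maps = {"d": adc}
                rows = []
                for entry in cohort.roi_table.entries:
                    if entry.patient_id != pid or entry.voxel_indices.shape[0] == 0:
                        continue
                    ii, jj, kk = entry.voxel_indices.T
                    vals = adc[ii, jj, kk]
                    vals = vals[np.isfinite(vals)]
                    q1, med, q3 = np.percentile(vals, [25, 50, 75])
                    rows.append(
                        dict(patient_id=pid, tissue_class=entry.tissue_class, parameter="d",
                             median=float(med), iqr=float(q3 - q1))
                    )
                tables.append(pd.DataFrame(rows))
            else:
                maps, roi_rows = fit_volume(
                    estimators[model], vol, scheme, cohort.roi_table, patient_id=pid
                )
                tables.append(roi_rows)
            for entry in cohort.roi_table.entries:
                if entry.patient_id != pid or entry.voxel_indices.shape[0] == 0:
                    continue
                ii, jj, kk = entry.voxel_indices.T
                key = (pid, entry.tissue_class)
                store = voxel_cols.setdefault(key, {})
                for name, arr in maps.items():
                    store[name] = arr[ii, jj, kk]

    table = pd.concat(tables, ignore_index=True)
    frames = []
    for (pid, cls), params in voxel_cols.items():
        df = pd.DataFrame(params)
        df.insert(0, "patient_id", pid)
        df.insert(1, "tissue_class", cls)
        frames.append(df)
    voxel_frame = pd.concat(frames, ignore_index=True)
    return table, voxel_frame


@dataclass
class AnalysisBundle:
    """Statistics outputs of one cohort: comparisons, ROC set, correlations."""

    comparisons: list[GroupComparison]
    roc: list[ROCResult]
    correlations: pd.DataFrame
    skipped: list[str] = field(default_factory=list)

    def comparison_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(c) for c in self.comparisons])

    def roc_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.roc:
            rows.append(
                dict(
                    parameter=r.parameter,
                    positive_class=r.positive_class,
                    negative_class=r.negative_class,
                    auc=r.auc,
                    orientation=r.orientation,
                    ppv_max_threshold=r.ppv_max["threshold"],
                    ppv_max=r.ppv_max["ppv"],
                    npv_max_threshold=r.npv_max["threshold"],
                    npv_max=r.npv_max["npv"],
                    degenerate=r.degenerate,
                )
            )
        return pd.DataFrame(rows)


def analyze_cohort(
    table: pd.DataFrame, voxel_frame: pd.DataFrame | None = None
) -> AnalysisBundle:
    """Run every group comparison, ROC curve and correlation the sequence reports.

    TP-vs-FP comparisons run for every parameter present; FP-vs-NT runs
    when normal-tissue ROIs exist, otherwise that section is marked
    skipped.  ROC positive classes: TP against FP, and FP against NT.
    """
    params = sorted(table["parameter"].unique())
    classes = set(table["tissue_class"].unique())
    comparisons: list[GroupComparison] = []
    rocs: list[ROCResult] = []
    skipped: list[str] = []

    pairs = [("TP", "FP")]
    if "NT" in classes:
        pairs.append(("FP", "NT"))
    else:
        skipped.append("FP-vs-NT (no normal-tissue ROIs in cohort)")

    for class_a, class_b in pairs:
        for p in params:
            n_a = ((table["parameter"] == p) & (table["tissue_class"] == class_a)).sum()
            n_b = ((table["parameter"] == p) & (table["tissue_class"] == class_b)).sum()
            if min(n_a, n_b) < 5:
                skipped.append(f"{p} {class_a}-vs-{class_b} (too few ROIs)")
                continue
            unpaired = n_a != n_b
            comparisons.append(compare_groups(table, p, class_a, class_b, unpaired=unpaired))
            rocs.append(roc_analysis(table, p, class_a, class_b))

    if voxel_frame is not None:
        avail = [
            (x, y)
            for x, y in DEFAULT_CORRELATION_PAIRS
            if x in voxel_frame.columns and y in voxel_frame.columns
        ]
        correlations = parameter_correlations(voxel_frame, avail)
    else:
        correlations = parameter_correlations(
            table.pivot_table(index=["patient_id", "tissue_class"], columns="parameter",
                              values="median").reset_index(),
        )
    return AnalysisBundle(comparisons, rocs, correlations, skipped)


def save_bundle(bundle: AnalysisBundle, outdir: str | Path) -> None:
    """Write tidy CSVs plus a JSON summary of the analysis bundle."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle.comparison_frame().to_csv(outdir / "comparisons.csv", index=False)
    bundle.roc_frame().to_csv(outdir / "roc.csv", index=False)
    bundle.correlations.to_csv(outdir / "correlations.csv", index=False)
    curves = []
    for r in bundle.roc:
        for t, se, sp in zip(r.thresholds, r.sensitivity, r.specificity):
            curves.append(
                dict(parameter=r.parameter, positive_class=r.positive_class,
                     negative_class=r.negative_class, threshold=t,
                     sensitivity=se, specificity=sp)
            )
    pd.DataFrame(curves).to_csv(outdir / "roc_curves.csv", index=False)
    summary = {
        "skipped": bundle.skipped,
        "n_comparisons": len(bundle.comparisons),
        "significant_p05": [
            f"{c.parameter} {c.class_a}-vs-{c.class_b}"
            for c in bundle.comparisons
            if c.p_value < 0.05
        ],
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2))


def plot_bundle(bundle: AnalysisBundle, table: pd.DataFrame, outdir: str | Path) -> None:
    """Boxplot and ROC figures (PNG) for the analysis bundle."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    params = sorted(table["parameter"].unique())
    ncols = 4
    nrows = -(-len(params) // ncols)
    fig, axes = plt.subplots(nrows, ncols, figsize=(3.2 * ncols, 2.6 * nrows), squeeze=False)
    order = [c for c in ("TP", "FP", "NT") if c in set(table["tissue_class"])]
    for ax, p in zip(axes.ravel(), params):
        data = [
            table[(table["parameter"] == p) & (table["tissue_class"] == c)]["median"] for c in order
        ]
        ax.boxplot(data, tick_labels=order)
        ax.set_title(p)
    for ax in axes.ravel()[len(params):]:
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(outdir / "boxplots.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 5))
    for r in bundle.roc:
        if r.positive_class != "TP":
            continue
        fpr = 1.0 - r.specificity
        idx = np.lexsort((r.sensitivity, fpr))
        ax.plot(fpr[idx], r.sensitivity[idx], label=f"{r.parameter} (AUC={r.auc:.2f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(outdir / "roc_tp_vs_fp.png", dpi=120)
    plt.close(fig)


def run_full(cfg: RunConfig) -> tuple[pd.DataFrame, AnalysisBundle]:
    """Convenience driver: train, simulate the cohort, fit, analyze, write outputs."""
    outdir = Path(cfg.outdir)
    write_manifest(cfg, outdir, "run")
    estimators = train_all(cfg)
    cohort = generate_cohort(
        dataclasses.replace(cfg.cohort, seed=cfg.seed + 3000, snr=cfg.snr, priors=cfg.priors),
        cfg.scheme(),
    )
    table, voxel_frame = fit_cohort(cohort, estimators)
    write_cohort_table(table, outdir / "cohort_table.csv")
    bundle = analyze_cohort(table, voxel_frame)
    save_bundle(bundle, outdir)
    plot_bundle(bundle, table, outdir)
    return table, bundle
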