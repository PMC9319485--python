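"""Synthetic signal generation: DNN training corpora and a 3-class cohort.

Two generators live here.

``generate_training_set`` draws model parameters uniformly and independently
from biophysically plausible intervals (:class:`PriorBox`), evaluates the
noise-free forward model over every scheme row, and corrupts each of three
direction-replicates with Rician noise at the requested SNR before
averaging them — mirroring an isotropic acquisition in three orthogonal
gradient directions whose magnitude images are averaged.

``generate_cohort`` builds a synthetic stand-in for a clinical cohort:
19 patients with a true-positive (TP) lesion ROI plus a contralateral
normal-tissue (NT) ROI, and 19 patients with a false-positive (FP) lesion
ROI.  Class-level parameter distributions are truncated normals whose
default means encode the qualitative separations expected between
cancerous, benign-disease and normal prostate tissue (higher f_IC and K in
cancer; lower diffusivities and vascular/EES fractions).  These defaults
are synthetic constructions for testing the pipeline, not clinical values.

Noise convention: signals are normalized so S(b=0) = 1, and the Rician
noise SD is sigma = 1/SNR relative to that unit b=0 amplitude.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .scheme import AcquisitionScheme, ROIEntry, ROITable, clinical_adc_scheme
from .signals import D_IC_DEFAULT, D_VASC_DEFAULT, MODEL_PARAM_NAMES, batch_signals

logger = logging.getLogger("prostadiff")

#: number of independently-noised gradient-direction replicates averaged per row
N_DIRECTIONS = 3

_DEFAULT_INTERVALS: dict[str, dict[str, tuple[float, float]]] = {
    "ADC": {"d": (0.1, 3.5)},
    "IVIM": {"f": (0.01, 0.99), "D": (0.5, 3.0), "Dstar": (0.5, 3.0)},
    "DKI": {"D_K": (0.5, 3.0), "K": (0.01, 2.99)},
    "VERDICT": {
        "f_IC": (0.01, 0.99),
        "f_EES": (0.01, 0.99),
        "R": (0.01, 15.0),
        "d_EES": (0.5, 3.0),
    },
}


@dataclass(frozen=True)
class PriorBox:
    """Closed per-parameter intervals used for sampling, NLLS bounds and output rescaling.

    The IVIM/DKI/VERDICT defaults are the published training intervals; the
    ADC interval is a package choice (the ADC map is fitted log-linearly,
    not learned).
    """

    intervals: Mapping[str, Mapping[str, tuple[float, float]]] = field(
        default_factory=lambda: _DEFAULT_INTERVALS
    )

    def __post_init__(self):
        merged = {m: dict(_DEFAULT_INTERVALS[m]) for m in _DEFAULT_INTERVALS}
        for model, d in self.intervals.items():
            if model not in merged:
                raise ValueError(f"unknown model {model!r}")
            merged[model].update(d)
        for model, d in merged.items():
            for name, (lo, hi) in d.items():
                if name not in MODEL_PARAM_NAMES[model]:
                    raise ValueError(f"unknown parameter {name!r} for model {model}")
                if not lo < hi:
                    raise ValueError(f"{model}.{name}: lower bound {lo} must be < upper {hi}")
        object.__setattr__(self, "intervals", merged)

    def bounds(self, model: str) -> tuple[np.ndarray, np.ndarray]:
        names = MODEL_PARAM_NAMES[model]
        lo = np.array([self.intervals[model][n][0] for n in names])
        hi = np.array([self.intervals[model][n][1] for n in names])
        return lo, hi

    def sample(self, model: str, n: int, rng: np.random.Generator) -> np.ndarray:
        """Uniform independent draws; VERDICT is rejection-sampled to f_IC + f_EES <= 1."""
        lo, hi = self.bounds(model)
        if model != "VERDICT":
            return rng.uniform(lo, hi, size=(n, lo.size))
        out = np.empty((0, lo.size))
        draws = 0
        while out.shape[0] < n:
            m = n - out.shape[0]
            cand = rng.uniform(lo, hi, size=(2 * m, lo.size))
            draws += 2 * m
            cand = cand[cand[:, 0] + cand[:, 1] <= 1.0]
            out = np.vstack([out, cand])
            if draws > 100 * n:
                raise RuntimeError(
                    "VERDICT rejection sampling exceeded 100 draws per sample; "
                    "check the prior intervals"
                )
        return out[:n]


DEFAULT_PRIORS = PriorBox()


def add_rician_noise(S, sigma: float, rng: np.random.Generator):
    """Rician-corrupted magnitude signal sqrt((S + e1)^2 + e2^2), e_i ~ N(0, sigma)."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    S = np.asarray(S, dtype=float)
    if sigma == 0:
        return S.copy()
    e1 = rng.normal(0.0, sigma, size=S.shape)
    e2 = rng.normal(0.0, sigma, size=S.shape)
    return np.sqrt((S + e1) ** 2 + e2**2)


def sigma_from_snr(snr: float | None) -> float:
    """Noise SD relative to the unit b=0 signal; ``None`` or ``inf`` means noise-free."""
    if snr is None or np.isinf(snr):
        return 0.0
    if snr <= 0:
        raise ValueError("SNR must be positive")
    return 1.0 / snr


def _noisy_direction_average(
    clean: np.ndarray, sigma: float, rng: np.random.Generator, n_directions: int = N_DIRECTIONS
) -> np.ndarray:
    """Average ``n_directions`` independently Rician-noised replicates of ``clean``."""
    if sigma == 0:
        return clean.copy()
    acc = np.zeros_like(clean)
    for _ in range(n_directions):
        acc += add_rician_noise(clean, sigma, rng)
    return acc / n_directions


@dataclass
class VoxelDataset:
    """Simulated signals (N x scheme rows) with optional ground-truth parameters."""

    signals: np.ndarray
    model: str
    truth: np.ndarray | None = None
    param_names: tuple[str, ...] = ()
    snr: float | None = None
    seed: int | None = None
    train_fraction: float = 0.8

    def __post_init__(self):
        self.signals = np.atleast_2d(np.asarray(self.signals, dtype=float))
        if np.any(self.signals < 0):
            raise ValueError("signals must be >= 0")
        if self.truth is not None:
            self.truth = np.atleast_2d(np.asarray(self.truth, dtype=float))
            if self.truth.shape[0] != self.signals.shape[0]:
                raise ValueError("truth and signals row counts differ")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train fraction must be in (0, 1)")

    def __len__(self) -> int:
        return self.signals.shape[0]

    @property
    def validation_fraction(self) -> float:
        return 1.0 - self.train_fraction


def generate_training_set(
    model: str,
    scheme: AcquisitionScheme,
    priors: PriorBox = DEFAULT_PRIORS,
    n: int = 100_000,
    snr: float | None = 35.0,
    seed: int = 0,
    train_fraction: float = 0.8,
) -> VoxelDataset:
    """Simulate ``n`` voxel signal vectors with uniform-prior ground truth.

    Parameters are drawn uniformly within ``priors`` (VERDICT rejection-
    sampled to the fraction-sum constraint), the noise-free forward signal
    is evaluated on every scheme row (b = 0 rows give exactly 1), and three
    direction-replicates are independently Rician-noised at sigma = 1/SNR
    and averaged.  Fully deterministic under ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if model not in MODEL_PARAM_NAMES:
        raise ValueError(f"unknown model {model!r}")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    params = priors.sample(model, n, rng)
    clean = batch_signals(model, scheme, params)
    sigma = sigma_from_snr(snr)
    signals = _noisy_direction_average(clean, sigma, rng)
    return VoxelDataset(
        signals=signals,
        model=model,
        truth=params,
        param_names=MODEL_PARAM_NAMES[model],
        snr=snr,
        seed=seed,
        train_fraction=train_fraction,
    )


# ---------------------------------------------------------------------------
# synthetic 3-class cohort
# ---------------------------------------------------------------------------

# (mean, sd) of the truncated-normal ROI-level distribution per tissue class.
# Synthetic defaults encoding the expected qualitative separations:
# f_IC and K higher in TP than FP than NT; diffusivities (d, D, D_K, d_EES),
# IVIM f and f_EES lower in TP than FP; D lower in FP than NT.
_DEFAULT_CLASS_DISTRIBUTIONS: dict[str, dict[str, dict[str, tuple[float, float]]]] = {
    "ADC": {
        "TP": {"d": (0.95, 0.15)},
        "FP": {"d": (1.45, 0.20)},
        "NT": {"d": (1.70, 0.25)},
    },
    "IVIM": {
        "TP": {"f": (0.12, 0.05), "D": (0.90, 0.18), "Dstar": (2.0, 0.5)},
        "FP": {"f": (0.26, 0.07), "D": (1.35, 0.22), "Dstar": (2.0, 0.5)},
        "NT": {"f": (0.30, 0.08), "D": (1.75, 0.25), "Dstar": (2.0, 0.5)},
    },
    "DKI": {
        "TP": {"D_K": (1.05, 0.18), "K": (1.25, 0.20)},
        "FP": {"D_K": (1.60, 0.22), "K": (0.85, 0.15)},
        "NT": {"D_K": (1.95, 0.25), "K": (0.65, 0.15)},
    },
    "VERDICT": {
        "TP": {"f_IC": (0.55, 0.10), "f_EES": (0.22, 0.08), "R": (7.5, 1.5), "d_EES": (1.30, 0.35)},
        "FP": {"f_IC": (0.38, 0.10), "f_EES": (0.42, 0.10), "R": (7.0, 1.5), "d_EES": (1.90, 0.35)},
        "NT": {"f_IC": (0.22, 0.08), "f_EES": (0.52, 0.10), "R": (7.0, 2.0), "d_EES": (2.10, 0.35)},
    },
}

#: per-parameter SD of the within-ROI voxelwise jitter around the ROI-level draw
_DEFAULT_VOXEL_JITTER: dict[str, float] = {
    "d": 0.05, "f": 0.02, "D": 0.05, "Dstar": 0.10,
    "D_K": 0.05, "K": 0.05,
    "f_IC": 0.02, "f_EES": 0.02, "R": 0.30, "d_EES": 0.05,
}

#: per-patient volume grid (x, y, z); lesion ROI occupies x < 3, the
#: contralateral normal-tissue ROI x >= 3
_GRID_SHAPE = (6, 6, 3)


@dataclass
class CohortSpec:
    """Design of the synthetic cohort (counts, class distributions, noise, seed)."""

    n_per_group: int = 19
    voxels_per_roi: int = 54
    snr: float | None = 35.0
    seed: int = 0
    models: tuple[str, ...] = ("ADC", "IVIM", "DKI", "VERDICT")
    class_param_distributions: Mapping[str, Mapping[str, Mapping[str, tuple[float, float]]]] = (
        field(default_factory=lambda: _DEFAULT_CLASS_DISTRIBUTIONS)
    )
    voxel_jitter: Mapping[str, float] = field(default_factory=lambda: _DEFAULT_VOXEL_JITTER)
    priors: PriorBox = field(default_factory=PriorBox)

    def __post_init__(self):
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        max_roi = _GRID_SHAPE[0] // 2 * _GRID_SHAPE[1] * _GRID_SHAPE[2]
        if not 1 <= self.voxels_per_roi <= max_roi:
            raise ValueError(f"voxels_per_roi must be in [1, {max_roi}]")
        for model in self.models:
            dists = self.class_param_distributions[model]
            for cls, params in dists.items():
                if cls not in ("TP", "FP", "NT"):
                    raise ValueError(f"unknown tissue class {cls!r}")
                for name, (mean, _sd) in params.items():
                    lo, hi = self.priors.intervals[model][name]
                    if not lo <= mean <= hi:
                        raise ValueError(
                            f"{model}.{name} class-{cls} mean {mean} outside prior [{lo}, {hi}]"
                        )


@dataclass
class Cohort:
    """Synthetic cohort: per-model 4-D volumes per patient, ROIs, and ground truth."""

    volumes: dict[str, dict[str, np.ndarray]]  # model -> patient_id -> 4-D array
    schemes: dict[str, AcquisitionScheme]
    roi_table: ROITable
    truth: pd.DataFrame  # columns: patient_id, tissue_class, parameter, value
    spec: CohortSpec

    @property
    def patient_ids(self) -> list[str]:
        first = next(iter(self.volumes.values()))
        return list(first)


def _truncnorm(mean, sd, lo, hi, size, rng: np.random.Generator) -> np.ndarray:
    """Truncated normal by resampling (the truncation mass here is small)."""
    out = rng.normal(mean, sd, size=size)
    for _ in range(1000):
        bad = (out < lo) | (out > hi)
        if not bad.any():
            return out
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
    return np.clip(out, lo, hi)


def generate_cohort(spec: CohortSpec, scheme: AcquisitionScheme) -> Cohort:
    """Simulate the 3-class cohort on ``scheme`` (ADC volumes on the clinical 4-b scheme).

    Each of ``n_per_group`` TP patients carries a lesion ROI (class TP) and a
    contralateral normal-tissue ROI (class NT); each FP patient carries a
    single FP lesion ROI with NT-like background tissue.  Per ROI, one
    parameter vector is drawn from the class distribution, voxelwise jitter
    is added, and noisy direction-averaged signals are synthesized per model.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xC0F0]))
    sigma = sigma_from_snr(spec.snr)
    schemes = {m: (clinical_adc_scheme() if m == "ADC" else scheme) for m in spec.models}

    nx, ny, nz = _GRID_SHAPE
    lesion_idx = np.argwhere(np.ones((nx // 2, ny, nz), dtype=bool))
    contra_idx = lesion_idx + np.array([nx // 2, 0, 0])

    patients: list[tuple[str, str]] = [
        (f"TP{i + 1:02d}", "TP") for i in range(spec.n_per_group)
    ] + [(f"FP{i + 1:02d}", "FP") for i in range(spec.n_per_group)]

    volumes: dict[str, dict[str, np.ndarray]] = {m: {} for m in spec.models}
    roi_entries: list[ROIEntry] = []
    truth_rows: list[dict] = []

    for pid, lesion_class in patients:
        roi_defs = [(lesion_class, lesion_idx[: spec.voxels_per_roi])]
        if lesion_class == "TP":
            roi_defs.append(("NT", contra_idx[: spec.voxels_per_roi]))
        for cls, idx in roi_defs:
            roi_entries.append(ROIEntry(pid, cls, idx))

        for model in spec.models:
            sch = schemes[model]
            names = MODEL_PARAM_NAMES[model]
            vol = np.empty((nx, ny, nz, len(sch)))
            # background + undrawn ROIs behave like normal tissue
            regions = [(idx, cls) for cls, idx in roi_defs]
            bg_mask = np.ones(_GRID_SHAPE, dtype=bool)
            for idx, _ in regions:
                bg_mask[tuple(idx.T)] = False
            regions.append((np.argwhere(bg_mask), "NT"))

            n_rois = len(roi_defs)
            for region_no, (idx, cls) in enumerate(regions):
                dist = spec.class_param_distributions[model][cls]
                lo, hi = spec.priors.bounds(model)
                roi_mean = np.array(
                    [
                        _truncnorm(*dist[nm], lo[k], hi[k], size=(), rng=rng)
                        for k, nm in enumerate(names)
                    ]
                )
                if model == "VERDICT" and roi_mean[0] + roi_mean[1] > 1.0:
                    roi_mean[1] = 1.0 - roi_mean[0]
                nvox = idx.shape[0]
                jitter_sd = np.array([spec.voxel_jitter.get(nm, 0.0) for nm in names])
                vox = rng.normal(roi_mean, jitter_sd, size=(nvox, len(names)))
                vox = np.clip(vox, lo, hi)
                if model == "VERDICT":
                    over = vox[:, 0] + vox[:, 1] > 1.0
                    vox[over, 1] = 1.0 - vox[over, 0]
                clean = batch_signals(model, sch, vox)
                noisy = _noisy_direction_average(clean, sigma, rng)
                vol[tuple(idx.T)] = noisy
                if region_no >= n_rois:
                    continue  # background tissue: no ROI, no truth record
                for k, nm in enumerate(names):
                    truth_rows.append(
                        dict(
                            patient_id=pid,
                            tissue_class=cls,
                            parameter=nm,
                            value=float(roi_mean[k]),
                        )
                    )
            volumes[model][pid] = vol

    roi_table = ROITable(roi_entries, volume_shape=_GRID_SHAPE)
    truth = pd.DataFrame(truth_rows)
    return Cohort(volumes=volumes, schemes=schemes, roi_table=roi_table, truth=truth, spec=spec)


def write_cohort(cohort: Cohort, outdir) -> None:
    """Write cohort volumes and ROI masks as NIfTI plus the ground-truth CSV."""
    from pathlib import Path

    import nibabel as nib

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    affine = np.eye(4)
    for model, pats in cohort.volumes.items():
        for pid, vol in pats.items():
            nib.save(nib.Nifti1Image(vol, affine), str(outdir / f"{pid}_{model}.nii"))
    for e in cohort.roi_table.entries:
        mask = np.zeros(_GRID_SHAPE)
        mask[tuple(e.voxel_indices.T)] = 1.0
        nib.save(
            nib.Nifti1Image(mask, affine), str(outdir / f"{e.patient_id}_{e.tissue_class}_mask.nii")
        )
    cohort.truth.to_csv(outdir / "ground_truth.csv", index=False)
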