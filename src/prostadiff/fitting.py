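"""Voxel-wise parameter estimation.

The primary estimator is a multilayer perceptron trained on synthetic
signals: three fully connected hidden layers of 150 rectified-linear
neurons, optimized by Adam (initial learning rate 0.001, minibatches of
100 voxels, first-moment decay 0.9) against the mean squared error between
ground-truth parameters and predictions, for up to 1000 epochs with early
stopping on a 20% validation split; the weights at the epoch of minimum
validation loss are kept.  Inputs are min-max normalized per feature to
[0, 1] from the training data; targets are min-max scaled by their prior
intervals and predictions are rescaled back (and clipped to the priors).

Also here: a bounded multi-start nonlinear-least-squares (NLLS) fitter used
as an independent oracle for the network, the clinical-style ADC map
(log-linear fit over all nonzero b-values, excluding b = 0 to suppress
perfusion effects), and whole-volume prediction with per-ROI summaries.
"""

from __future__ import annotations

import logging
import pickle
from dataclasses import dataclass
from itertools import product
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from sklearn.neural_network import MLPRegressor

from .scheme import AcquisitionScheme, ROITable
from .signals import MODEL_PARAM_NAMES, batch_signals
from .synth import DEFAULT_PRIORS, PriorBox, VoxelDataset

logger = logging.getLogger("prostadiff")


@dataclass(frozen=True)
class FitterConfig:
    """Network architecture and training regimen of the voxel-wise regressor."""

    hidden_layers: int = 3
    neurons_per_layer: int = 150
    activation: str = "relu"
    epochs: int = 1000
    initial_learning_rate: float = 1e-3
    minibatch: int = 100
    momentum: float = 0.9
    early_stopping: bool = True
    validation_fraction: float = 0.2
    patience: int = 10
    tol: float = 1e-4  # minimum per-epoch improvement that resets the patience counter
    seed: int = 0

    def __post_init__(self):
        for name in ("hidden_layers", "neurons_per_layer", "epochs", "minibatch", "patience"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0 < self.validation_fraction < 1:
            raise ValueError("validation_fraction must be in (0, 1)")


@dataclass
class FittedEstimator:
    """Trained network plus the normalizations needed to use it."""

    network: MLPRegressor
    model_tag: str
    param_names: tuple[str, ...]
    input_min: np.ndarray  # per-feature training minima
    input_max: np.ndarray
    output_ranges: np.ndarray  # (P, 2) lower/upper physical bounds
    best_epoch: int
    validation_loss_curve: np.ndarray  # per-epoch validation MSE, scaled-target units
    config: FitterConfig

    @property
    def validation_mse(self) -> float:
        return float(self.validation_loss_curve[self.best_epoch - 1])


def _scale_inputs(X: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    span = np.where(hi > lo, hi - lo, 1.0)
    return (X - lo) / span


def train_fitter(
    dataset: VoxelDataset,
    config: FitterConfig = FitterConfig(),
    priors: PriorBox = DEFAULT_PRIORS,
) -> FittedEstimator:
    """Train the MLP regressor on a simulated :class:`VoxelDataset`.

    The validation split (fraction ``dataset.validation_fraction``) is held
    out inside the stochastic optimizer; the per-epoch validation loss is
    recorded and the weights from the best epoch are restored.  Training is
    deterministic under ``config.seed``.
    """
    if dataset.truth is None:
        raise ValueError("training requires a dataset with ground-truth parameters")
    X = dataset.signals
    in_lo, in_hi = X.min(axis=0), X.max(axis=0)
    Xs = _scale_inputs(X, in_lo, in_hi)

    lo, hi = priors.bounds(dataset.model)
    y = (dataset.truth - lo) / (hi - lo)

    net = MLPRegressor(
        hidden_layer_sizes=(config.neurons_per_layer,) * config.hidden_layers,
        activation=config.activation,
        solver="adam",
        learning_rate_init=config.initial_learning_rate,
        batch_size=config.minibatch,
        beta_1=config.momentum,
        max_iter=config.epochs,
        shuffle=True,
        early_stopping=config.early_stopping,
        validation_fraction=dataset.validation_fraction,
        n_iter_no_change=config.patience,
        tol=config.tol,
        random_state=config.seed,
    )
    import warnings

    with warnings.catch_warnings():
        from sklearn.exceptions import ConvergenceWarning

        warnings.simplefilter("ignore", ConvergenceWarning)
        net.fit(Xs, y if y.shape[1] > 1 else y.ravel())

    if not np.all(np.isfinite(net.loss_curve_)):
        raise RuntimeError("training diverged: non-finite loss encountered")

    # per-epoch validation R^2 -> MSE in scaled-target units (constant val split)
    if config.early_stopping:
        scores = np.asarray(net.validation_scores_)
        var_y = float(np.var(y))
        val_curve = (1.0 - scores) * var_y
        best_epoch = int(np.argmin(val_curve)) + 1
    else:
        val_curve = np.asarray(net.loss_curve_)
        best_epoch = int(np.argmin(val_curve)) + 1

    if len(val_curve) > 1 and val_curve[best_epoch - 1] >= val_curve[0] and config.epochs > 1:
        logger.warning(
            "validation loss did not improve over training (%.3g -> %.3g)",
            val_curve[0],
            val_curve[best_epoch - 1],
        )

    return FittedEstimator(
        network=net,
        model_tag=dataset.model,
        param_names=tuple(MODEL_PARAM_NAMES[dataset.model]),
        input_min=in_lo,
        input_max=in_hi,
        output_ranges=np.column_stack([lo, hi]),
        best_epoch=best_epoch,
        validation_loss_curve=val_curve,
        config=config,
    )


def predict_parameters(est: FittedEstimator, signals: np.ndarray) -> pd.DataFrame:
    """Predict physical parameters for an (N, scheme-rows) signal array.

    Predictions are rescaled to physical units and clipped to the prior
    ranges; VERDICT outputs are augmented with the residual vascular
    fraction f_VASC = max(0, 1 - f_IC - f_EES) and cellularity f_IC / R^3.
    """
    signals = np.atleast_2d(np.asarray(signals, dtype=float))
    if signals.shape[1] != est.input_min.size:
        raise ValueError(
            f"signal width {signals.shape[1]} does not match training width {est.input_min.size}"
        )
    Xs = _scale_inputs(signals, est.input_min, est.input_max)
    raw = np.atleast_2d(est.network.predict(Xs))
    if raw.shape[0] == 1 and signals.shape[0] == 1:
        raw = raw.reshape(1, -1)
    elif raw.ndim == 1 or raw.shape[0] != signals.shape[0]:
        raw = raw.reshape(signals.shape[0], -1)
    lo, hi = est.output_ranges[:, 0], est.output_ranges[:, 1]
    phys = np.clip(lo + raw * (hi - lo), lo, hi)
    out = pd.DataFrame(phys, columns=list(est.param_names))
    if est.model_tag == "VERDICT":
        out["f_VASC"] = np.clip(1.0 - out["f_IC"] - out["f_EES"], 0.0, 1.0)
        out["cellularity"] = out["f_IC"] / out["R"] ** 3
    return out


def save_estimator(est: FittedEstimator, path: str | Path) -> None:
    """Serialize the estimator bundle (weights, normalizations, config) to one file."""
    with open(path, "wb") as fh:
        pickle.dump(est, fh)


def load_estimator(path: str | Path) -> FittedEstimator:
    with open(path, "rb") as fh:
        est = pickle.load(fh)
    if not isinstance(est, FittedEstimator):
        raise TypeError(f"{path} does not contain a FittedEstimator")
    return est


# ---------------------------------------------------------------------------
# nonlinear least squares oracle
# ---------------------------------------------------------------------------


def nlls_fit(
    model: str,
    scheme: AcquisitionScheme,
    signals: np.ndarray,
    priors: PriorBox = DEFAULT_PRIORS,
    n_grid: int = 4,
    n_refine: int = 3,
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Bounded multi-start nonlinear least squares over the prior box.

    The sum-of-squares objective is evaluated on a coarse grid of
    ``n_grid`` points per parameter axis (vectorized over all voxels), and
    gradient refinement (trust-region reflective, bounded by the priors)
    runs from the ``n_refine`` best grid starts per voxel; the best
    refined solution is kept.

    Returns ``(estimates, residual_norms, degenerate_flags)``.  Voxels whose
    signal carries no usable decay (or where every start fails) are flagged
    rather than raised.
    """
    signals = np.atleast_2d(np.asarray(signals, dtype=float))
    names = MODEL_PARAM_NAMES[model]
    lo, hi = priors.bounds(model)
    n_vox = signals.shape[0]

    axes = [np.linspace(l, h, n_grid + 2)[1:-1] for l, h in zip(lo, hi)]
    grid = np.array(list(product(*axes)))
    if model == "VERDICT":
        keep = grid[:, 0] + grid[:, 1] <= 1.0
        grid = grid[keep]
    grid_sig = batch_signals(model, scheme, grid)  # (G, M)
    # SSE between every voxel and every grid point
    sse = (
        np.sum(signals**2, axis=1)[:, None]
        - 2.0 * signals @ grid_sig.T
        + np.sum(grid_sig**2, axis=1)[None, :]
    )
    start_idx = np.argsort(sse, axis=1)[:, :n_refine]

    penalty_scale = 10.0

    def residuals(p: np.ndarray, sig: np.ndarray) -> np.ndarray:
        r = batch_signals(model, scheme, p[None, :])[0] - sig
        if model == "VERDICT":
            r = np.append(r, penalty_scale * max(0.0, p[0] + p[1] - 1.0))
        return r

    eps = 1e-10
    est = np.full((n_vox, len(names)), np.nan)
    resnorm = np.full(n_vox, np.nan)
    degenerate = np.zeros(n_vox, dtype=bool)
    for i in range(n_vox):
        sig = signals[i]
        best_cost = np.inf
        best_p = None
        for j in start_idx[i]:
            try:
                sol = least_squares(
                    residuals,
                    grid[j],
                    args=(sig,),
                    bounds=(lo + eps, hi - eps),
                    method="trf",
                    xtol=1e-12,
                    ftol=1e-12,
                    gtol=1e-12,
                )
            except Exception:  # pragma: no cover - solver failure path
                continue
            if sol.cost < best_cost:
                best_cost = sol.cost
                best_p = sol.x
        if best_p is None:
            degenerate[i] = True
            logger.warning("NLLS: all starts failed for voxel %d; flagged", i)
            continue
        est[i] = best_p
        resnorm[i] = np.sqrt(2.0 * best_cost)
        # no measurable decay across the scheme -> parameters unidentified
        if np.ptp(sig) < 1e-9:
            degenerate[i] = True
    frame = pd.DataFrame(est, columns=list(names))
    if model == "VERDICT":
        frame["f_VASC"] = np.clip(1.0 - frame["f_IC"] - frame["f_EES"], 0.0, 1.0)
        frame["cellularity"] = frame["f_IC"] / frame["R"] ** 3
    return frame, resnorm, degenerate


# ---------------------------------------------------------------------------
# clinical-style ADC map
# ---------------------------------------------------------------------------


def compute_adc_map(volume: np.ndarray, b_values_smm2) -> np.ndarray:
    """Log-linear ADC map using all nonzero b-values ("all b-values except b = 0").

    Ordinary least squares of ln(signal) on -b with a free intercept, per
    voxel, over the nonzero-b rows only; excluding b = 0 suppresses the
    perfusion contribution to the estimate.  Non-positive signals are
    excluded per voxel; voxels with fewer than two usable points are NaN.

    Parameters
    ----------
    volume : 4-D array, last axis in the order of ``b_values_smm2``
    b_values_smm2 : b-values in s/mm^2

    Returns
    -------
    3-D ADC map in um^2/ms.
    """
    volume = np.asarray(volume, dtype=float)
    if volume.ndim != 4:
        raise ValueError("volume must be 4-D")
    b = np.asarray(b_values_smm2, dtype=float) * 1e-3  # -> ms/um^2
    if b.size != volume.shape[3]:
        raise ValueError("b-value count does not match 4th volume dimension")
    nz = b > 0
    if np.unique(b[nz]).size < 2:
        raise ValueError("need at least two distinct nonzero b-values for an ADC fit")

    bn = b[nz]
    sig = volume[..., nz]
    spatial = sig.shape[:3]
    sig = sig.reshape(-1, bn.size)

    adc = np.full(sig.shape[0], np.nan)
    ok = sig > 0
    usable = ok.sum(axis=1) >= 2

    all_ok = ok.all(axis=1)
    if np.any(all_ok):
        lnS = np.log(sig[all_ok])
        bc = bn - bn.mean()
        denom = np.sum(bc**2)
        slope = (lnS @ bc) / denom
        adc[all_ok] = -slope
    partial = usable & ~all_ok
    for i in np.nonzero(partial)[0]:
        m = ok[i]
        bi = bn[m]
        if np.unique(bi).size < 2:
            continue
        lnS = np.log(sig[i, m])
        bc = bi - bi.mean()
        adc[i] = -np.sum(bc * (lnS - lnS.mean())) / np.sum(bc**2)
    n_missing = int(np.sum(~usable))
    if n_missing:
        logger.warning("ADC map: %d voxels with <2 usable points flagged missing", n_missing)
    return adc.reshape(spatial)


# ---------------------------------------------------------------------------
# whole-volume fitting
# ---------------------------------------------------------------------------


def fit_volume(
    est: FittedEstimator,
    volume: np.ndarray,
    scheme: AcquisitionScheme,
    roi_table: ROITable | None = None,
    patient_id: str | None = None,
) -> tuple[dict[str, np.ndarray], pd.DataFrame]:
    """Predict parameter maps for a whole (unmasked) 4-D volume and summarize ROIs.

    Returns ``(maps, cohort_rows)`` where ``maps`` holds one 3-D array per
    (derived) parameter covering every voxel of the grid, and
    ``cohort_rows`` has one row per (patient, tissue class, parameter) with
    the ROI median and interquartile range.
    """
    volume = np.asarray(volume, dtype=float)
    if volume.ndim != 4 or volume.shape[3] != len(scheme):
        raise ValueError(
            f"volume shape {volume.shape} inconsistent with scheme of {len(scheme)} rows"
        )
    spatial = volume.shape[:3]
    signals = volume.reshape(-1, len(scheme))
    pred = predict_parameters(est, signals)
    maps = {name: pred[name].to_numpy().reshape(spatial) for name in pred.columns}

    rows: list[dict] = []
    if roi_table is not None:
        for entry in roi_table.entries:
            if patient_id is not None and entry.patient_id != patient_id:
                continue
            if entry.voxel_indices.shape[0] == 0:
                logger.warning(
                    "ROI (%s, %s) is empty; no summary rows",
                    entry.patient_id,
                    entry.tissue_class,
                )
                continue
            ii, jj, kk = entry.voxel_indices.T
            for name in pred.columns:
                vals = maps[name][ii, jj, kk]
                q1, med, q3 = np.percentile(vals, [25, 50, 75])
                rows.append(
                    dict(
                        patient_id=entry.patient_id,
                        tissue_class=entry.tissue_class,
                        parameter=name,
                        median=float(med),
                        iqr=float(q3 - q1),
                    )
                )
    cohort_rows = pd.DataFrame(rows, columns=["patient_id", "tissue_class", "parameter", "median", "iqr"])
    return maps, cohort_rows
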