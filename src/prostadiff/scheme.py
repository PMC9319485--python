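"""Acquisition schemes and file interfaces.

Canonical internal units throughout the package:

* b-value           ms/um^2   (1 ms/um^2 == 1000 s/mm^2)
* diffusivity       um^2/ms
* sphere radius     um
* times (delta, Delta, TE, TR)  ms
* gradient amplitude G          T/m

so that ``b * d`` is dimensionless and order 1 for tissue water.

A scheme file is whitespace-delimited text, one pulsed-gradient spin-echo
(PGSE) measurement per line.  Lines starting with ``#`` are comments.  The
first non-comment line is a header naming the columns, drawn from
``b G delta Delta TE TR`` in any order (``b`` in s/mm^2 as is conventional
in protocol listings, ``G`` in T/m, times in ms).  Either ``b`` or ``G``
must be present; when both are present they are cross-checked against the
PGSE relation b = gamma^2 G^2 delta^2 (Delta - delta/3).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("prostadiff")

#: proton gyromagnetic ratio, rad s^-1 T^-1
GAMMA = 2.6752218744e8

#: closed label set for cohort tissue classes
TISSUE_CLASSES = ("TP", "FP", "NT")

#: relative tolerance for cross-checking a stored b against (G, delta, Delta)
_B_CONSISTENCY_RTOL = 1e-3


class SchemeError(ValueError):
    """Malformed or physically inconsistent acquisition scheme."""


def b_from_gradient(G: float, delta: float, Delta: float) -> float:
    """Diffusion weighting of a PGSE measurement, b = gamma^2 G^2 delta^2 (Delta - delta/3).

    Parameters
    ----------
    G : gradient amplitude in T/m (>= 0)
    delta : gradient duration in ms
    Delta : gradient separation in ms, must exceed ``delta``

    Returns
    -------
    b in ms/um^2.
    """
    G = np.asarray(G, dtype=float)
    if np.any(G < 0):
        raise ValueError("gradient amplitude G must be >= 0")
    if not (0 < delta < Delta):
        raise ValueError(f"require 0 < delta < Delta, got delta={delta}, Delta={Delta}")
    delta_s = delta * 1e-3
    Delta_s = Delta * 1e-3
    b_si = GAMMA**2 * G**2 * delta_s**2 * (Delta_s - delta_s / 3.0)  # s/m^2
    return b_si * 1e-9  # s/m^2 -> ms/um^2


def gradient_from_b(b: float, delta: float, Delta: float) -> float:
    """Invert :func:`b_from_gradient`: gradient amplitude (T/m) producing ``b`` (ms/um^2)."""
    b = np.asarray(b, dtype=float)
    if np.any(b < 0):
        raise ValueError("b must be >= 0")
    if not (0 < delta < Delta):
        raise ValueError(f"require 0 < delta < Delta, got delta={delta}, Delta={Delta}")
    delta_s = delta * 1e-3
    Delta_s = Delta * 1e-3
    b_si = b * 1e9
    return np.sqrt(b_si / (GAMMA**2 * delta_s**2 * (Delta_s - delta_s / 3.0)))


@dataclass(frozen=True)
class Measurement:
    """One PGSE measurement row.

    ``b`` in ms/um^2; ``delta``, ``Delta``, ``TE``, ``TR`` in ms; ``G`` in T/m.
    """

    b: float
    delta: float
    Delta: float
    TE: float = 0.0
    TR: float = 0.0
    G: float = field(default=None)  # type: ignore[assignment]
    is_b0: bool = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.b < 0:
            raise SchemeError(f"negative b-value: {self.b}")
        if not (0 < self.delta < self.Delta):
            raise SchemeError(
                f"require 0 < delta < Delta, got delta={self.delta}, Delta={self.Delta}"
            )
        if self.G is None:
            object.__setattr__(self, "G", float(gradient_from_b(self.b, self.delta, self.Delta)))
        else:
            b_check = float(b_from_gradient(self.G, self.delta, self.Delta))
            ref = max(self.b, 1e-12)
            if self.b > 0 and abs(b_check - self.b) / ref > _B_CONSISTENCY_RTOL:
                raise SchemeError(
                    f"stored b={self.b:g} ms/um^2 disagrees with PGSE relation "
                    f"b(G={self.G:g}, delta={self.delta:g}, Delta={self.Delta:g})"
                    f"={b_check:g} by more than 0.1%"
                )
        if self.is_b0 is None:
            object.__setattr__(self, "is_b0", self.b == 0.0)
        elif self.is_b0 != (self.b == 0.0):
            raise SchemeError("is_b0 flag inconsistent with b value")


@dataclass(frozen=True)
class AcquisitionScheme:
    """An ordered set of PGSE measurements; the design every model is evaluated on."""

    rows: tuple[Measurement, ...]

    def __post_init__(self):
        object.__setattr__(self, "rows", tuple(self.rows))

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)

    @property
    def b(self) -> np.ndarray:
        """b-values in ms/um^2, scheme row order."""
        return np.array([m.b for m in self.rows])

    @property
    def b0_mask(self) -> np.ndarray:
        return np.array([m.is_b0 for m in self.rows])

    @classmethod
    def from_b_values(
        cls,
        b_smm2: Sequence[float],
        delta: Sequence[float] | float,
        Delta: Sequence[float] | float,
        TE: Sequence[float] | float = 0.0,
        TR: Sequence[float] | float = 0.0,
    ) -> "AcquisitionScheme":
        """Build a scheme from b-values given in s/mm^2 (clinical convention)."""
        b = np.asarray(b_smm2, dtype=float) * 1e-3
        n = b.size
        bc = lambda x: np.broadcast_to(np.asarray(x, dtype=float), (n,))
        rows = [
            Measurement(b=float(bi), delta=float(d), Delta=float(D), TE=float(te), TR=float(tr))
            for bi, d, D, te, tr in zip(b, bc(delta), bc(Delta), bc(TE), bc(TR))
        ]
        return cls(tuple(rows))


def verdict_scheme() -> AcquisitionScheme:
    """The bundled 10-row VERDICT-style prostate scheme.

    Five diffusion-weighted measurements at b = 90, 500, 1500, 2000 and
    3000 s/mm^2, each paired with its own b = 0 acquisition at matched
    timings, as in the optimized prostate protocol.  The gradient timings
    are *representative* values consistent with the published TE/TR ranges
    (TE 50-90 ms, TR 2482-3945 ms); the exact clinical per-b timings are
    not in the public protocol listing.
    """
    combos = [
        # (b s/mm^2, delta ms, Delta ms, TE ms, TR ms)
        (90.0, 3.9, 23.8, 50.0, 2482.0),
        (500.0, 11.4, 31.3, 65.0, 2482.0),
        (1500.0, 23.9, 43.8, 90.0, 3945.0),
        (2000.0, 14.4, 34.3, 71.0, 2482.0),
        (3000.0, 18.9, 38.8, 80.0, 3349.0),
    ]
    rows: list[Measurement] = []
    for b, d, D, te, tr in combos:
        rows.append(Measurement(b=0.0, delta=d, Delta=D, TE=te, TR=tr))
        rows.append(Measurement(b=b * 1e-3, delta=d, Delta=D, TE=te, TR=tr))
    return AcquisitionScheme(tuple(rows))


def clinical_adc_scheme() -> AcquisitionScheme:
    """The 4-b clinical diffusion scheme (b = 0, 150, 500, 1000 s/mm^2, TE 80 ms, TR 2753 ms)."""
    return AcquisitionScheme.from_b_values(
        [0.0, 150.0, 500.0, 1000.0], delta=12.0, Delta=30.0, TE=80.0, TR=2753.0
    )


# ---------------------------------------------------------------------------
# scheme file I/O
# ---------------------------------------------------------------------------

_SCHEME_COLUMNS = ("b", "G", "delta", "Delta", "TE", "TR")


def read_scheme(path: str | Path) -> AcquisitionScheme:
    """Read a whitespace-delimited scheme file (see module docstring for the dialect)."""
    path = Path(path)
    header: list[str] | None = None
    rows: list[Measurement] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            toks = line.split()
            if header is None:
                bad = [t for t in toks if t not in _SCHEME_COLUMNS]
                if bad:
                    raise SchemeError(
                        f"{path}:{lineno}: unknown scheme columns {bad}; "
                        f"expected names from {_SCHEME_COLUMNS}"
                    )
                if "b" not in toks and "G" not in toks:
                    raise SchemeError(f"{path}:{lineno}: header must contain 'b' or 'G'")
                header = toks
                continue
            if len(toks) != len(header):
                raise SchemeError(
                    f"{path}:{lineno}: expected {len(header)} columns, got {len(toks)}"
                )
            try:
                vals = {k: float(v) for k, v in zip(header, toks)}
            except ValueError as exc:
                raise SchemeError(f"{path}:{lineno}: non-numeric value ({exc})") from None
            if "delta" not in vals or "Delta" not in vals:
                raise SchemeError(f"{path}: header must contain delta and Delta columns")
            try:
                kwargs = dict(
                    delta=vals["delta"],
                    Delta=vals["Delta"],
                    TE=vals.get("TE", 0.0),
                    TR=vals.get("TR", 0.0),
                )
                if "b" in vals:
                    kwargs["b"] = vals["b"] * 1e-3  # s/mm^2 -> ms/um^2
                    if "G" in vals:
                        kwargs["G"] = vals["G"]
                else:
                    kwargs["b"] = float(b_from_gradient(vals["G"], vals["delta"], vals["Delta"]))
                    kwargs["G"] = vals["G"]
                rows.append(Measurement(**kwargs))
            except (SchemeError, ValueError) as exc:
                raise SchemeError(f"{path}:{lineno}: {exc}") from None
    if header is None or not rows:
        raise SchemeError(f"{path}: no measurements found")
    return AcquisitionScheme(tuple(rows))


def write_scheme(scheme: AcquisitionScheme, path: str | Path) -> None:
    """Write a scheme file in the b-column dialect (b in s/mm^2, 6 significant digits)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# PGSE acquisition scheme: b in s/mm^2, times in ms\n")
        fh.write("b delta Delta TE TR\n")
        for m in scheme:
            fh.write(
                f"{m.b * 1e3:.6g} {m.delta:.6g} {m.Delta:.6g} {m.TE:.6g} {m.TR:.6g}\n"
            )


# ---------------------------------------------------------------------------
# ROI tables and NIfTI interfaces
# ---------------------------------------------------------------------------


@dataclass
class ROIEntry:
    patient_id: str
    tissue_class: str
    voxel_indices: np.ndarray  # (n_voxels, 3) int

    def __post_init__(self):
        if self.tissue_class not in TISSUE_CLASSES:
            raise ValueError(
                f"tissue_class must be one of {TISSUE_CLASSES}, got {self.tissue_class!r}"
            )
        self.voxel_indices = np.atleast_2d(np.asarray(self.voxel_indices, dtype=int))
        if self.voxel_indices.size == 0:
            self.voxel_indices = self.voxel_indices.reshape(0, 3)
        if self.voxel_indices.shape[1] != 3:
            raise ValueError("voxel_indices must have shape (n, 3)")


@dataclass
class ROITable:
    """Per-(patient, tissue class) regions of interest as voxel index lists."""

    entries: list[ROIEntry]
    volume_shape: tuple[int, int, int] | None = None

    def __post_init__(self):
        seen = set()
        for e in self.entries:
            key = (e.patient_id, e.tissue_class)
            if key in seen:
                raise ValueError(f"duplicate (patient, class) pair {key}")
            seen.add(key)
            if self.volume_shape is not None and e.voxel_indices.size:
                shape = np.asarray(self.volume_shape)
                if np.any(e.voxel_indices < 0) or np.any(e.voxel_indices >= shape):
                    raise ValueError(
                        f"ROI {key} has voxel indices outside volume grid {self.volume_shape}"
                    )
            if e.voxel_indices.shape[0] == 0:
                logger.warning("empty ROI for patient %s class %s", e.patient_id, e.tissue_class)

    def __len__(self) -> int:
        return len(self.entries)

    def get(self, patient_id: str, tissue_class: str) -> ROIEntry | None:
        for e in self.entries:
            if e.patient_id == patient_id and e.tissue_class == tissue_class:
                return e
        return None


def read_dwi_volume(path: str | Path, scheme: AcquisitionScheme):
    """Load a 4-D diffusion-weighted NIfTI volume bound to its scheme.

    Returns ``(data, affine)`` where ``data`` is a float array whose 4th axis
    follows scheme row order.  Raises on dimension mismatch.
    """
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4-D volume, got shape {data.shape}")
    if data.shape[3] != len(scheme):
        raise ValueError(
            f"{path}: 4th dimension has {data.shape[3]} volumes but the scheme "
            f"has {len(scheme)} measurements"
        )
    return data, img.affine


def write_dwi_volume(data: np.ndarray, affine: np.ndarray, path: str | Path) -> None:
    import nibabel as nib

    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine), str(path))


#: value written into parameter maps where the fit is undefined
MISSING_SENTINEL = -999.0


def write_parameter_maps(
    maps: dict[str, np.ndarray], affine: np.ndarray, outdir: str | Path, prefix: str = ""
) -> dict[str, Path]:
    """Write one 3-D NIfTI per parameter; NaNs become the sentinel recorded in the header."""
    import nibabel as nib

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for name, arr in maps.items():
        arr = np.asarray(arr, dtype=np.float64).copy()
        arr[~np.isfinite(arr)] = MISSING_SENTINEL
        img = nib.Nifti1Image(arr, affine)
        img.header["descrip"] = f"missing={MISSING_SENTINEL:g}".encode()
        fname = outdir / f"{prefix}{name}.nii"
        nib.save(img, str(fname))
        written[name] = fname
    return written


def read_roi_masks(
    mask_paths: dict[tuple[str, str], str | Path], volume_shape: tuple[int, int, int]
) -> ROITable:
    """Build an :class:`ROITable` from binary 3-D NIfTI masks keyed by (patient, class)."""
    import nibabel as nib

    entries = []
    for (patient_id, tissue_class), path in mask_paths.items():
        mask = np.asarray(nib.load(str(path)).get_fdata())
        if mask.shape != tuple(volume_shape):
            raise ValueError(
                f"mask {path} shape {mask.shape} does not match volume grid {volume_shape}"
            )
        uniq = np.unique(mask)
        if not np.all(np.isin(uniq, [0.0, 1.0])):
            raise ValueError(f"mask {path} is not binary (values {uniq[:5]}...)")
        idx = np.argwhere(mask > 0)
        entries.append(ROIEntry(patient_id, tissue_class, idx))
    return ROITable(entries, volume_shape=tuple(volume_shape))


COHORT_TABLE_COLUMNS = ("patient_id", "tissue_class", "parameter", "median", "iqr")


def write_cohort_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write per-ROI parameter summaries as CSV (patient_id, tissue_class, parameter, median, iqr)."""
    missing = [c for c in COHORT_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"cohort table missing columns {missing}")
    table.loc[:, list(COHORT_TABLE_COLUMNS)].to_csv(path, index=False)


def read_cohort_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = [c for c in COHORT_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: cohort table missing columns {missing}")
    return table
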