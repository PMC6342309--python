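"""Readers and writers for CT rasters, lung masks, and cohort tables.

Everything entering the pipeline is normalised here to two in-memory
representations:

* images — lists of :class:`HUSlice` / :class:`LungMask`, one per axial slice,
  ordered cranio-caudally (index 0 most cranial), grids indexed (row, col);
* tabular data — a pandas ``DataFrame`` with the canonical cohort columns
  (see :data:`MANDATORY_COLUMNS`), one row per patient.

Supported on-disk formats: NIfTI (``.nii``/``.nii.gz``) via nibabel, DICOM
series directories via pydicom, and plain CSV grids (one file per slice) for
fixtures. The three encodings of the same grid yield identical HU values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, GeometryError, SchemaError, ValidationError

logger = logging.getLogger(__name__)

#: Hounsfield thresholds at which LAA% and Betti numbers are computed (HU).
THRESHOLDS = (-950, -910, -880)

#: Plausible CT attenuation range; values outside indicate a unit/rescale bug.
HU_RANGE = (-1100.0, 3100.0)


def metric_col(prefix: str, threshold_hu: int) -> str:
    """Canonical column name for a per-threshold metric, e.g. ``laa_pct_950``."""
    return f"{prefix}_{abs(int(threshold_hu))}"


MANDATORY_COLUMNS = (
    "patient_id",
    "age",
    "sex",
    "brinkman_index",
    "outcome",
    "lung_area",
    *(metric_col("laa_pct", t) for t in THRESHOLDS),
    *(metric_col("b0", t) for t in THRESHOLDS),
    *(metric_col("b1", t) for t in THRESHOLDS),
)

#: Optional columns passed through when present.
OPTIONAL_COLUMNS = ("malignant_tumor_history", "visual_score")

#: Covariates that must be non-missing for a row to enter the risk models.
MODELLING_COLUMNS = ("age", "sex", "brinkman_index", "outcome")


@dataclass(frozen=True)
class HUSlice:
    """One axial CT slice in Hounsfield units.

    Parameters
    ----------
    values
        2-D float array of attenuation values, indexed (row, col).
    pixel_spacing
        (row, col) spacing in mm, or ``None`` when the source format carries
        no geometry (CSV fixtures).
    slice_index
        Position of the slice in its volume, cranio-caudal ascending.
    """

    values: np.ndarray
    pixel_spacing: tuple[float, float] | None = None
    slice_index: int = 0

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 2 or arr.size == 0:
            raise ValidationError("HUSlice requires a non-empty 2-D grid")
        lo, hi = HU_RANGE
        if arr.min() < lo or arr.max() > hi:
            raise ValidationError(
                f"HU values outside plausible CT range {HU_RANGE}: "
                f"[{arr.min():.1f}, {arr.max():.1f}] — check rescale slope/intercept"
            )
        object.__setattr__(self, "values", arr)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class LungMask:
    """Binary lung mask paired with an :class:`HUSlice` of the same shape."""

    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.values) != 0
        if arr.ndim != 2 or arr.size == 0:
            raise ValidationError("LungMask requires a non-empty 2-D grid")
        object.__setattr__(self, "values", arr)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_inside(self) -> int:
        return int(self.values.sum())


# ---------------------------------------------------------------------------
# volume / mask readers
# ---------------------------------------------------------------------------


def _read_grids(path: Path, format_hint: str | None) -> tuple[list[np.ndarray], tuple[float, float] | None]:
    """Read a stack of 2-D grids plus in-plane spacing from any supported format."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"input path does not exist: {path}")
    fmt = format_hint or _sniff_format(path)
    if fmt == "nifti":
        return _read_nifti(path)
    if fmt == "dicom":
        return _read_dicom_series(path)
    if fmt == "csv":
        return _read_csv_grids(path)
    raise FormatError(f"unrecognised image format for {path}")


def _sniff_format(path: Path) -> str:
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        return "nifti"
    if name.endswith(".csv"):
        return "csv"
    if path.is_dir():
        if any(p.suffix.lower() == ".csv" for p in path.iterdir()):
            return "csv"
        return "dicom"
    raise FormatError(f"cannot infer format of {path}")


def _read_nifti(path: Path):
    import nibabel as nib

    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types
        raise FormatError(f"unreadable NIfTI file {path}: {exc}") from exc
    # get_fdata applies scl_slope/scl_inter, yielding HU directly
    data = np.asarray(img.get_fdata(dtype=np.float64))
    if data.ndim == 2:
        data = data[:, :, None]
    if data.ndim != 3:
        raise FormatError(f"expected 2-D or 3-D NIfTI, got {data.ndim}-D in {path}")
    zooms = img.header.get_zooms()
    spacing = (float(zooms[0]), float(zooms[1]))
    return [data[:, :, k] for k in range(data.shape[2])], spacing


def _read_dicom_series(path: Path):
    import pydicom

    files = sorted(p for p in path.iterdir() if p.is_file())
    datasets = []
    for f in files:
        try:
            ds = pydicom.dcmread(str(f))
        except Exception:
            continue
        if hasattr(ds, "PixelData"):
            datasets.append(ds)
    if not datasets:
        raise FormatError(f"no readable DICOM images under {path}")

    def sort_key(ds):
        ipp = getattr(ds, "ImagePositionPatient", None)
        if ipp is not None:
            return -float(ipp[2])  # superior (largest z) first = cranio-caudal
        return int(getattr(ds, "InstanceNumber", 0))

    datasets.sort(key=sort_key)
    slices = []
    spacing = None
    for ds in datasets:
        if "RescaleSlope" not in ds or "RescaleIntercept" not in ds:
            raise FormatError(
                "DICOM file lacks RescaleSlope/RescaleIntercept; refusing to "
                "interpret raw stored values as HU"
            )
        arr = ds.pixel_array.astype(np.float64)
        arr = arr * float(ds.RescaleSlope) + float(ds.RescaleIntercept)
        slices.append(arr)
        ps = getattr(ds, "PixelSpacing", None)
        if ps is not None:
            spacing = (float(ps[0]), float(ps[1]))
    return slices, spacing


def _read_csv_grids(path: Path):
    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.suffix.lower() == ".csv")
        if not files:
            raise FormatError(f"no CSV slice files under {path}")
    else:
        files = [path]
    grids = []
    for f in files:
        try:
            grids.append(np.loadtxt(f, delimiter=",", ndmin=2))
        except Exception as exc:
            raise FormatError(f"unparseable CSV grid {f}: {exc}") from exc
    return grids, None  # CSV fixtures carry no spacing metadata


def read_volume(path, format_hint: str | None = None) -> list[HUSlice]:
    """Read a CT volume as a cranio-caudally ordered list of :class:`HUSlice`.

    DICOM rescale slope/intercept and NIfTI scl scaling are applied, so values
    are Hounsfield units regardless of source format. Missing rescale tags are
    an error — raw stored values are never passed through silently.
    """
    grids, spacing = _read_grids(Path(path), format_hint)
    shapes = {g.shape for g in grids}
    if len(shapes) > 1:
        raise GeometryError(f"slices disagree in shape: {sorted(shapes)}")
    return [HUSlice(g, pixel_spacing=spacing, slice_index=k) for k, g in enumerate(grids)]


def read_mask(path, volume: list[HUSlice] | None = None, format_hint: str | None = None) -> list[LungMask]:
    """Read lung masks; any nonzero stored value maps to *inside*.

    When ``volume`` is given, the mask must match it slice-for-slice in shape.
    """
    grids, _ = _read_grids(Path(path), format_hint)
    masks = [LungMask(g) for g in grids]
    if volume is not None:
        if len(masks) != len(volume):
            raise GeometryError(
                f"mask has {len(masks)} slices but volume has {len(volume)}"
            )
        for m, s in zip(masks, volume):
            if m.shape != s.shape:
                raise GeometryError(f"mask shape {m.shape} != slice shape {s.shape}")
    return masks


def write_volume_csv(slices: list[HUSlice], out_dir) -> list[Path]:
    """Write each slice as ``slice_###.csv``; inverse of the CSV reader."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for k, s in enumerate(slices):
        p = out_dir / f"slice_{k:03d}.csv"
        np.savetxt(p, s.values, delimiter=",", fmt="%.6g")
        paths.append(p)
    return paths


def write_mask_csv(masks: list[LungMask], out_dir) -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for k, m in enumerate(masks):
        p = out_dir / f"mask_{k:03d}.csv"
        np.savetxt(p, m.values.astype(int), delimiter=",", fmt="%d")
        paths.append(p)
    return paths


# ---------------------------------------------------------------------------
# cohort tables
# ---------------------------------------------------------------------------

_SEX_MAP = {"male": "male", "m": "male", "1": "male",
            "female": "female", "f": "female", "0": "female"}
_OUTCOME_MAP = {"cancer": "cancer", "malignant": "cancer", "1": "cancer",
                "benign": "benign", "0": "benign"}


def validate_cohort(df: pd.DataFrame) -> pd.DataFrame:
    """Validate canonical cohort invariants; returns the (typed) frame.

    Adds a boolean ``complete_for_modelling`` column flagging rows whose
    modelling covariates are all present; incomplete rows are kept, never
    dropped here.
    """
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"cohort table missing canonical columns: {missing}")
    df = df.copy()
    if df["patient_id"].duplicated().any():
        dup = df.loc[df["patient_id"].duplicated(), "patient_id"].tolist()
        raise ValidationError(f"duplicate patient_id values: {dup[:5]}")
    df["sex"] = df["sex"].astype(str).str.strip().str.lower().map(_SEX_MAP)
    if df["sex"].isna().any():
        raise ValidationError("sex column contains values other than male/female")
    df["outcome"] = df["outcome"].astype(str).str.strip().str.lower().map(_OUTCOME_MAP)
    if df["outcome"].isna().any():
        raise ValidationError("outcome column contains values other than cancer/benign")
    for t in THRESHOLDS:
        laa = pd.to_numeric(df[metric_col("laa_pct", t)], errors="coerce")
        if ((laa < 0) | (laa > 100)).any():
            raise ValidationError(f"{metric_col('laa_pct', t)} outside [0, 100]")
        df[metric_col("laa_pct", t)] = laa
        for prefix in ("b0", "b1"):
            col = metric_col(prefix, t)
            vals = pd.to_numeric(df[col], errors="coerce")
            ok = vals.dropna()
            if (ok < 0).any() or not np.allclose(ok, np.round(ok)):
                raise ValidationError(f"{col} must be non-negative integer counts")
            df[col] = vals
    for col in ("age", "brinkman_index", "lung_area"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    complete = np.ones(len(df), dtype=bool)
    for col in MODELLING_COLUMNS:
        complete &= df[col].notna().to_numpy()
    df["complete_for_modelling"] = complete
    n_excluded = int((~complete).sum())
    if n_excluded:
        logger.warning("cohort: %d row(s) flagged incomplete for modelling", n_excluded)
    return df


def read_cohort(path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a per-patient cohort CSV into the canonical table.

    ``column_map`` maps canonical field name → source header, absorbing
    whatever headers the source file uses (supplementary raw-data exports
    rarely match our canonical names).
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"cohort file does not exist: {path}")
    df = pd.read_csv(path)
    if column_map:
        absent = [src for src in column_map.values() if src not in df.columns]
        if absent:
            raise SchemaError(f"column_map sources not found in file: {absent}")
        df = df.rename(columns={src: canon for canon, src in column_map.items()})
    return validate_cohort(df)


def write_cohort(df: pd.DataFrame, path) -> Path:
    """Write the canonical cohort columns (round-trips with :func:`read_cohort`)."""
    path = Path(path)
    cols = [c for c in (*MANDATORY_COLUMNS, *OPTIONAL_COLUMNS) if c in df.columns]
    df[cols].to_csv(path, index=False)
    return path
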