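"""Reading, writing and sampling of quantitative parameter maps.

A *quantitative map* is a 3-D volume whose voxel values carry physical units
(R1 in s^-1, MTsat in percent units, MD in mm^2/s, MTV as a volume
fraction).  All maps entering one analysis must live on an identical voxel
grid — this module never resamples.  Invalid voxels are NaN and stay NaN.

Region sampling follows the core-extraction convention: the outer shell of
each ROI is removed by morphological erosion (face-connected structuring
element) before voxels are pooled, to limit partial-volume contamination at
region boundaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import DataError, EmptyRegionError, GridMismatchError

__all__ = [
    "PARAMS",
    "DEFAULT_UNITS",
    "QuantitativeMap",
    "LabelVolume",
    "ROIVoxelSample",
    "load_map",
    "save_map",
    "load_labels",
    "extract_roi_voxels",
    "join_bilateral",
    "region_volume",
]

#: Recognised qMRI parameter identities.
PARAMS = ("MTV", "R1", "R2", "R2star", "MTsat", "MD")

DEFAULT_UNITS = {
    "MTV": "fraction",
    "R1": "s^-1",
    "R2": "s^-1",
    "R2star": "s^-1",
    "MTsat": "p.u.",
    "MD": "mm^2/s",
}

#: Tolerance for affine agreement between co-registered volumes.
AFFINE_ATOL = 1e-4


@dataclass
class QuantitativeMap:
    """One 3-D parametric map with its parameter identity and units.

    Parameters
    ----------
    values
        3-D float array; NaN marks invalid voxels (e.g. removed by upstream
        B1 extrapolation masking).  Never imputed.
    param
        One of :data:`PARAMS`.
    units
        Physical units string; defaults to the conventional unit for the
        parameter.
    affine
        4x4 voxel-to-world transform (NIfTI convention).
    """

    values: np.ndarray
    param: str
    units: str = ""
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise DataError(
                f"expected 3-D volume, got {self.values.ndim}-D for {self.param!r}"
            )
        if self.param not in PARAMS:
            raise DataError(f"unknown parameter {self.param!r}; expected one of {PARAMS}")
        if not self.units:
            self.units = DEFAULT_UNITS[self.param]
        self.affine = np.asarray(self.affine, dtype=float)
        if self.param == "MTV":
            finite = self.values[np.isfinite(self.values)]
            if finite.size and (finite.min() < 0 or finite.max() >= 1):
                raise DataError("MTV values must lie in [0, 1) where finite")

    @property
    def shape(self) -> tuple:
        return self.values.shape

    def same_grid(self, other: "QuantitativeMap | LabelVolume") -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=AFFINE_ATOL
        )


@dataclass
class LabelVolume:
    """Integer region-label volume plus its lookup table.

    ``region_table`` maps each nonzero label to a region name, hemisphere
    ('L', 'R' or 'none') and tissue class ('GM', 'WM', 'subcortical').
    """

    labels: np.ndarray
    region_table: pd.DataFrame
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise DataError("expected 3-D label volume")
        if not np.issubdtype(self.labels.dtype, np.integer):
            if not np.all(np.mod(self.labels[np.isfinite(self.labels)], 1) == 0):
                raise DataError("label volume must contain integers")
            self.labels = self.labels.astype(int)
        required = {"label", "name", "hemisphere", "tissue_class"}
        missing = required - set(self.region_table.columns)
        if missing:
            raise DataError(f"region table missing columns: {sorted(missing)}")
        present = set(np.unique(self.labels)) - {0}
        known = set(self.region_table["label"].astype(int))
        orphans = present - known
        if orphans:
            raise DataError(f"labels absent from region table: {sorted(orphans)}")
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def shape(self) -> tuple:
        return self.labels.shape

    def info(self, label: int) -> pd.Series:
        rows = self.region_table[self.region_table["label"] == label]
        if rows.empty:
            raise DataError(f"label {label} not in region table")
        return rows.iloc[0]


@dataclass
class ROIVoxelSample:
    """Pooled voxel values for one region, one vector per parameter.

    All vectors are aligned voxel-for-voxel and NaN-free: a voxel invalid in
    any requested map is dropped from every vector, so each fitted parameter
    sees the same pool.
    """

    region: str
    values: dict  # param -> 1-D float array
    hemisphere: str = "none"
    label: int | None = None

    def __post_init__(self):
        lengths = {p: len(v) for p, v in self.values.items()}
        if len(set(lengths.values())) > 1:
            raise DataError(f"unequal per-parameter vector lengths: {lengths}")
        for p, v in self.values.items():
            arr = np.asarray(v, dtype=float)
            if np.isnan(arr).any():
                raise DataError(f"NaN entries in ROI sample for {p!r}")
            self.values[p] = arr

    @property
    def n_voxels(self) -> int:
        if not self.values:
            return 0
        return len(next(iter(self.values.values())))

    @property
    def params(self) -> tuple:
        return tuple(sorted(self.values))

    def to_frame(self) -> pd.DataFrame:
        """Long-format export: one row per (voxel, param)."""
        rows = []
        for p in self.params:
            rows.append(
                pd.DataFrame(
                    {"region": self.region, "param": p, "value": self.values[p]}
                )
            )
        return pd.concat(rows, ignore_index=True)


def load_map(path: str | Path, param: str, units: str = "") -> QuantitativeMap:
    """Load a 3-D NIfTI volume as a :class:`QuantitativeMap`.

    Raises :class:`~mdmtv.errors.DataError` for non-3-D inputs; NaN voxels
    are preserved untouched.
    """
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise DataError(f"expected 3-D volume at {path}, got {data.ndim}-D")
    return QuantitativeMap(values=data, param=param, units=units, affine=img.affine)


def save_map(qmap: QuantitativeMap, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(qmap.values.astype(np.float64), qmap.affine), str(path))


def load_labels(path: str | Path, table_path: str | Path) -> LabelVolume:
    """Load a label NIfTI and its CSV lookup (label,name,hemisphere,tissue_class)."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise DataError(f"expected 3-D label volume at {path}, got {data.ndim}-D")
    table = pd.read_csv(table_path)
    return LabelVolume(labels=np.rint(data).astype(int), region_table=table, affine=img.affine)


def save_labels(labels: LabelVolume, path: str | Path, table_path: str | Path) -> None:
    nib.save(nib.Nifti1Image(labels.labels.astype(np.int32), labels.affine), str(path))
    labels.region_table.to_csv(table_path, index=False)


# Face-connected (6-neighbour) structuring element in 3-D.
_STRUCT_6 = ndimage.generate_binary_structure(3, 1)


def erode_mask(mask: np.ndarray, depth: int) -> np.ndarray:
    """Morphological erosion with the face-connected element, ``depth`` times."""
    if depth < 0:
        raise ValueError("erosion depth must be >= 0")
    if depth == 0:
        return mask.copy()
    return ndimage.binary_erosion(mask, structure=_STRUCT_6, iterations=depth)


def extract_roi_voxels(
    maps: dict[str, QuantitativeMap],
    labels: LabelVolume,
    region: int,
    erosion_depth: int = 1,
) -> ROIVoxelSample:
    """Pool voxel values of one (eroded) region across all requested maps.

    The ROI mask is eroded ``erosion_depth`` times with a 6-connectivity
    structuring element ("remove the outer shell, keep the core").  Voxels
    that are NaN in *any* requested map are dropped from all vectors.

    Raises
    ------
    EmptyRegionError
        If the eroded ROI contains no voxels, or none survive NaN filtering.
    GridMismatchError
        If any map's grid differs from the label grid.
    """
    for p, m in maps.items():
        if not m.same_grid(labels):
            raise GridMismatchError(
                f"map {p!r} grid {m.shape} does not match label grid {labels.shape}"
            )
    info = labels.info(region)
    mask = labels.labels == region
    if not mask.any():
        raise EmptyRegionError(f"label {region} has no voxels")
    core = erode_mask(mask, erosion_depth)
    if not core.any():
        raise EmptyRegionError(
            f"region {info['name']!r} (label {region}) empty after erosion depth {erosion_depth}"
        )
    stacked = {p: m.values[core] for p, m in maps.items()}
    valid = np.ones(int(core.sum()), dtype=bool)
    for v in stacked.values():
        valid &= np.isfinite(v)
    if not valid.any():
        raise EmptyRegionError(
            f"region {info['name']!r} (label {region}) has no NaN-free voxels"
        )
    return ROIVoxelSample(
        region=str(info["name"]),
        hemisphere=str(info["hemisphere"]),
        label=int(region),
        values={p: v[valid] for p, v in stacked.items()},
    )


def join_bilateral(left: ROIVoxelSample, right: ROIVoxelSample) -> ROIVoxelSample:
    """Concatenate the voxel pools of the two hemispheres of one region.

    Bilateral structures are analysed as a single pooled region; the result
    carries hemisphere 'none'.  An empty side (``None``) acts as the neutral
    element.
    """
    if left is None:
        return right
    if right is None:
        return left
    if left.region != right.region:
        raise DataError(f"cannot join different regions {left.region!r} / {right.region!r}")
    if left.params != right.params:
        raise DataError(
            f"mismatched parameter sets: {left.params} vs {right.params}"
        )
    if {left.hemisphere, right.hemisphere} not in ({"L", "R"},):
        warnings.warn(
            f"joining hemispheres {left.hemisphere!r} and {right.hemisphere!r} "
            f"for region {left.region!r}",
            stacklevel=2,
        )
    merged = {
        p: np.concatenate([left.values[p], right.values[p]]) for p in left.values
    }
    return ROIVoxelSample(region=left.region, hemisphere="none", label=left.label, values=merged)


def region_volume(labels: LabelVolume, region: int) -> int:
    """Voxel count of the raw (un-eroded) label — the region-volume marker."""
    labels.info(region)  # raises on unknown label
    count = int((labels.labels == region).sum())
    if count == 0:
        raise DataError(f"label {region} present in table but absent from volume")
    return count
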