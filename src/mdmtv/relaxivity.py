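"""The MDM engine: MTV binning, bin filtering, and linear dependency fits.

The multidimensional-dependency-on-MTV (MDM) signature of a brain region is
the vector of first derivatives of several qMRI parameters (R1, MTsat, MD,
R2) with respect to the macromolecular tissue volume fraction (MTV).  Each
derivative is the slope of

    qMRI parameter = a * MTV + b

fitted across MTV *bins* rather than raw voxels: voxels of a region are
pooled into equal-width MTV bins, underpopulated bins are discarded, and an
ordinary least-squares line is fitted to the per-bin medians.  Binning keeps
the fit from being dominated by the MTV values where voxels happen to be
dense.

An alternative regressor, the inverse water content 1/WC = 1/(1 - MTV), is
supported; over the physiological MTV range it is nearly linear in MTV and
yields closely ranked slopes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import (
    DegenerateRegressorError,
    EmptySignatureError,
    InsufficientBinsError,
)
from .qmaps_io import LabelVolume, QuantitativeMap, ROIVoxelSample, extract_roi_voxels

__all__ = [
    "BinningConfig",
    "BinnedProfile",
    "LinearDependency",
    "MDMSignature",
    "MinVoxelPolicy",
    "transform_regressor",
    "bin_by_mtv",
    "fit_dependency",
    "compute_signature",
    "aggregate_signatures",
    "signatures_to_frame",
]

#: Exclusion reason codes carried on signatures.
REASON_BELOW_THRESHOLD = "below-threshold"
REASON_EMPTY_REGION = "empty-region"
REASON_INSUFFICIENT_BINS = "insufficient-bins"
REASON_DEGENERATE = "degenerate-regressor"


@dataclass(frozen=True)
class BinningConfig:
    """Binning and filtering rules for the MTV axis.

    Defaults follow the standard protocol: 36 equal-width bins spanning MTV
    0.05-0.40, discarding bins holding fewer than 4% of the region's
    (in-range, NaN-free) voxels.  ``min_bins_for_fit`` guards against
    formally possible but meaningless 2-point lines.
    """

    n_bins: int = 36
    lo: float = 0.05
    hi: float = 0.40
    min_bin_frac: float = 0.04
    regressor_mode: str = "MTV"  # or "INV_WC"
    min_bins_for_fit: int = 5
    weighted: bool = False  # weight OLS by bin voxel counts (off: plain OLS)

    def __post_init__(self):
        if not self.lo < self.hi:
            raise ValueError("require lo < hi")
        if self.n_bins < 2:
            raise ValueError("require n_bins >= 2")
        if not 0 <= self.min_bin_frac < 1:
            raise ValueError("require 0 <= min_bin_frac < 1")
        if self.regressor_mode not in ("MTV", "INV_WC"):
            raise ValueError("regressor_mode must be 'MTV' or 'INV_WC'")

    @property
    def bin_width(self) -> float:
        return (self.hi - self.lo) / self.n_bins


@dataclass
class BinnedProfile:
    """Per-bin summary of one qMRI parameter against the regressor.

    ``regressor_median`` / ``q_median`` are the bin medians entering the
    fit; ``q_mad`` is the (unscaled) median absolute deviation used for the
    shaded dispersion band; ``counts`` are post-filter voxel counts and
    ``total_voxels`` the filter denominator.
    """

    param: str
    regressor_median: np.ndarray
    q_median: np.ndarray
    q_mad: np.ndarray
    counts: np.ndarray
    total_voxels: int
    config: BinningConfig

    @property
    def n_bins(self) -> int:
        return len(self.q_median)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "param": self.param,
                "regressor_median": self.regressor_median,
                "q_median": self.q_median,
                "q_mad": self.q_mad,
                "count": self.counts,
            }
        )


@dataclass
class LinearDependency:
    """Fitted linear law q = a * regressor + b for one parameter.

    The slope ``a`` is the MTV derivative (units: qMRI units per unit MTV
    fraction); ``r2_adj`` is the coefficient of determination adjusted for
    the number of bins used.
    """

    param: str
    slope: float
    intercept: float
    r2: float = float("nan")
    r2_adj: float = float("nan")
    n_bins_used: int = 0

    def predict(self, regressor) -> np.ndarray:
        return self.slope * np.asarray(regressor, dtype=float) + self.intercept


@dataclass
class MDMSignature:
    """Multidimensional MTV-derivative signature of one region.

    ``fits`` maps each included qMRI parameter to its fitted dependency;
    ``excluded`` records every requested-but-excluded parameter with a
    machine-readable reason.
    """

    region: str
    subject: str = "pooled"
    fits: dict = field(default_factory=dict)  # param -> LinearDependency
    excluded: dict = field(default_factory=dict)  # param -> reason string

    @property
    def params(self) -> tuple:
        return tuple(sorted(self.fits))

    def slopes(self, params=None) -> np.ndarray:
        params = self.params if params is None else tuple(params)
        return np.array([self.fits[p].slope for p in params])

    def intercepts(self, params=None) -> np.ndarray:
        params = self.params if params is None else tuple(params)
        return np.array([self.fits[p].intercept for p in params])


@dataclass(frozen=True)
class MinVoxelPolicy:
    """Minimum ROI voxel counts per parameter before a fit is attempted.

    Defaults mirror common practice: the high-resolution maps (MTsat, R1)
    need 500 voxels, the coarser MD map 150, and the coarsest R2 map 50.
    """

    thresholds: tuple = (("MTsat", 500), ("R1", 500), ("MD", 150), ("R2", 50))

    def __post_init__(self):
        for p, t in self.thresholds:
            if t <= 0:
                raise ValueError(f"threshold for {p!r} must be positive")

    def minimum(self, param: str) -> int:
        return dict(self.thresholds).get(param, 0)


def transform_regressor(mtv: np.ndarray, mode: str = "MTV") -> np.ndarray:
    """Map MTV values onto the chosen regressor scale.

    'MTV' is the identity; 'INV_WC' returns the inverse water content
    1/(1 - MTV), which requires MTV < 1 everywhere.
    """
    mtv = np.asarray(mtv, dtype=float)
    if mode == "MTV":
        return mtv
    if mode == "INV_WC":
        if np.any(mtv >= 1):
            raise ValueError("INV_WC regressor undefined for MTV >= 1")
        return 1.0 / (1.0 - mtv)
    raise ValueError(f"unknown regressor mode {mode!r}")


def _median_mad(x: np.ndarray) -> tuple[float, float]:
    med = float(np.median(x))
    return med, float(np.median(np.abs(x - med)))


def bin_by_mtv(
    sample: ROIVoxelSample, param: str, config: BinningConfig | None = None
) -> BinnedProfile:
    """Pool a region's voxels into equal-width MTV bins and summarise.

    Bins are half-open [edge_i, edge_{i+1}) with the last bin closed at
    ``hi``; voxels with MTV outside [lo, hi] are ignored entirely (they
    neither populate bins nor count toward the filter denominator).  Bins
    with fewer than ``min_bin_frac`` of the in-range voxels are removed.

    Raises :class:`InsufficientBinsError` when no bin survives.
    """
    config = config or BinningConfig()
    if param not in sample.values:
        raise KeyError(f"parameter {param!r} not in sample for region {sample.region!r}")
    if "MTV" not in sample.values:
        raise KeyError("sample lacks MTV values")
    mtv = sample.values["MTV"]
    q = sample.values[param]
    in_range = (mtv >= config.lo) & (mtv <= config.hi)
    mtv, q = mtv[in_range], q[in_range]
    total = int(in_range.sum())
    if total == 0:
        raise InsufficientBinsError(
            f"region {sample.region!r}: no voxels with MTV in "
            f"[{config.lo}, {config.hi}]"
        )
    idx = np.floor((mtv - config.lo) / config.bin_width).astype(int)
    np.clip(idx, 0, config.n_bins - 1, out=idx)  # closes the last bin at hi
    counts = np.bincount(idx, minlength=config.n_bins)
    min_count = config.min_bin_frac * total
    keep = np.flatnonzero(counts >= max(min_count, 1))
    if keep.size == 0:
        raise InsufficientBinsError(
            f"region {sample.region!r}: all {config.n_bins} bins below "
            f"{config.min_bin_frac:.0%} of {total} voxels"
        )
    regressor = transform_regressor(mtv, config.regressor_mode)
    reg_med = np.empty(keep.size)
    q_med = np.empty(keep.size)
    q_mad = np.empty(keep.size)
    for j, b in enumerate(keep):
        sel = idx == b
        reg_med[j] = np.median(regressor[sel])
        q_med[j], q_mad[j] = _median_mad(q[sel])
    return BinnedProfile(
        param=param,
        regressor_median=reg_med,
        q_median=q_med,
        q_mad=q_mad,
        counts=counts[keep],
        total_voxels=total,
        config=config,
    )


def fit_dependency(
    profile: BinnedProfile, min_bins_for_fit: int | None = None
) -> LinearDependency:
    """Ordinary least squares of bin-median qMRI on bin-median regressor.

    Unweighted across bins by default (set ``config.weighted`` to weight by
    voxel counts).  Reports the slope (the MTV derivative), intercept and
    R^2 adjusted for the number of bins.

    Raises
    ------
    InsufficientBinsError
        Fewer surviving bins than ``min_bins_for_fit``.
    DegenerateRegressorError
        Zero regressor variance across bins.
    """
    if min_bins_for_fit is None:
        min_bins_for_fit = profile.config.min_bins_for_fit
    x = profile.regressor_median
    y = profile.q_median
    n = len(x)
    if n < min_bins_for_fit:
        raise InsufficientBinsError(
            f"{n} surviving bins < min_bins_for_fit={min_bins_for_fit} "
            f"for {profile.param!r}"
        )
    if np.ptp(x) == 0:
        raise DegenerateRegressorError(
            f"zero regressor variance across bins for {profile.param!r}"
        )
    w = profile.counts.astype(float) if profile.config.weighted else np.ones(n)
    W = w / w.sum()
    xbar = float(W @ x)
    ybar = float(W @ y)
    sxx = float(W @ (x - xbar) ** 2)
    sxy = float(W @ ((x - xbar) * (y - ybar)))
    slope = sxy / sxx
    intercept = ybar - slope * xbar
    resid = y - (slope * x + intercept)
    ss_res = float(W @ resid**2)
    ss_tot = float(W @ (y - ybar) ** 2)
    if ss_tot == 0:
        r2 = r2_adj = 0.0  # flat response: no variance to explain
    else:
        r2 = 1.0 - ss_res / ss_tot
        r2_adj = r2 if n <= 2 else 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return LinearDependency(
        param=profile.param,
        slope=float(slope),
        intercept=float(intercept),
        r2=float(r2),
        r2_adj=float(r2_adj),
        n_bins_used=n,
    )


def compute_signature(
    maps: dict[str, QuantitativeMap],
    labels: LabelVolume,
    region: int,
    params: tuple = ("R1", "MTsat"),
    policy: MinVoxelPolicy | None = None,
    config: BinningConfig | None = None,
    erosion_depth: int = 1,
    subject: str = "pooled",
) -> MDMSignature:
    """Assemble a region's MDM signature from co-registered maps.

    For each requested parameter: the region's voxel pool (after erosion and
    NaN filtering) must reach the per-parameter minimum voxel count; the
    pool is then binned along MTV and a line fitted.  Parameters failing a
    step are excluded with a recorded reason, never silently.

    Raises :class:`EmptySignatureError` if every parameter is excluded, and
    propagates :class:`~mdmtv.errors.EmptyRegionError` if the eroded region
    is empty (caller decides how to record it).
    """
    policy = policy or MinVoxelPolicy()
    config = config or BinningConfig()
    missing = [p for p in params if p not in maps]
    if missing:
        raise KeyError(f"requested parameters without maps: {missing}")
    if "MTV" not in maps:
        raise KeyError("an MTV map is required")
    wanted = {"MTV", *params}
    sample = extract_roi_voxels(
        {p: maps[p] for p in wanted}, labels, region, erosion_depth
    )
    sig = MDMSignature(region=sample.region, subject=subject)
    for p in params:
        if sample.n_voxels < policy.minimum(p):
            sig.excluded[p] = REASON_BELOW_THRESHOLD
            continue
        try:
            profile = bin_by_mtv(sample, p, config)
            sig.fits[p] = fit_dependency(profile)
        except InsufficientBinsError:
            sig.excluded[p] = REASON_INSUFFICIENT_BINS
        except DegenerateRegressorError:
            sig.excluded[p] = REASON_DEGENERATE
    if not sig.fits:
        raise EmptySignatureError(
            f"region {sample.region!r}: all parameters excluded "
            f"({dict(sig.excluded)})"
        )
    return sig


def aggregate_signatures(signatures: list[MDMSignature]) -> MDMSignature:
    """Cross-subject aggregate: per-parameter median of slopes/intercepts.

    Only parameters included for at least one subject appear; the adjusted
    R^2 of the aggregate is the median of the per-subject values.
    """
    if not signatures:
        raise ValueError("no signatures to aggregate")
    regions = {s.region for s in signatures}
    if len(regions) > 1:
        raise ValueError(f"signatures span multiple regions: {sorted(regions)}")
    out = MDMSignature(region=signatures[0].region, subject="aggregate")
    params = sorted({p for s in signatures for p in s.fits})
    for p in params:
        deps = [s.fits[p] for s in signatures if p in s.fits]
        out.fits[p] = LinearDependency(
            param=p,
            slope=float(np.median([d.slope for d in deps])),
            intercept=float(np.median([d.intercept for d in deps])),
            r2_adj=float(np.median([d.r2_adj for d in deps])),
            n_bins_used=int(np.median([d.n_bins_used for d in deps])),
        )
    return out


def signatures_to_frame(signatures: list[MDMSignature]) -> pd.DataFrame:
    """Tidy export: one row per (subject, region, param), exclusions included."""
    rows = []
    for s in signatures:
        for p, d in sorted(s.fits.items()):
            rows.append(
                dict(
                    subject=s.subject, region=s.region, param=p,
                    slope=d.slope, intercept=d.intercept, r2_adj=d.r2_adj,
                    n_bins=d.n_bins_used, excluded=False, reason="",
                )
            )
        for p, reason in sorted(s.excluded.items()):
            rows.append(
                dict(
                    subject=s.subject, region=s.region, param=p,
                    slope=np.nan, intercept=np.nan, r2_adj=np.nan,
                    n_bins=0, excluded=True, reason=reason,
                )
            )
    return pd.DataFrame(rows)
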