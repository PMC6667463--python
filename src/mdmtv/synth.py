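"""Seedable synthetic data: phantom dilution series, brain-like map
volumes with region-specific relaxivity laws, and two-group cohorts with
planted effect sizes.

These generators are the test substrate for the whole toolkit.  They
emulate the *statistical* structure the estimators consume — per-region
voxelwise MTV distributions with linear qMRI~MTV laws plus i.i.d. Gaussian
noise, dilution series of pure components and mixtures, and between-subject
variation with planted group shifts — not MR physics or anatomy.  Every
generator is a pure function of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError
from .mixtures import ComponentLibrary, MixtureDesign, predict_mixture_dependency
from .qmaps_io import LabelVolume, QuantitativeMap
from .relaxivity import BinningConfig, MinVoxelPolicy, compute_signature, signatures_to_frame

__all__ = [
    "PhantomSpec",
    "RegionSpec",
    "BrainSpec",
    "CohortSpec",
    "simulate_phantom",
    "simulate_brain",
    "simulate_cohort",
    "default_phantom_spec",
    "default_brain_spec",
    "default_cohort_spec",
]

# Physiologically scaled default linear laws (slope per unit MTV, intercept):
# R1 ~ 0.3-1.5 s^-1 over MTV 0.05-0.40, MTsat a few p.u., MD ~ 1e-3 mm^2/s
# decreasing with MTV, R2 ~ 10-20 s^-1.  Fixture values, not claims.
_DEFAULT_LAWS = {
    "R1": (2.5, 0.25),
    "MTsat": (10.0, -0.2),
    "MD": (-1.5e-3, 1.2e-3),
    "R2": (30.0, 4.0),
}
_DEFAULT_NOISE = {"R1": 0.03, "MTsat": 0.08, "MD": 4e-5, "R2": 0.5}


@dataclass(frozen=True)
class PhantomSpec:
    """Dilution-series design for pure components and their mixtures.

    Each component has a true linear law per qMRI parameter; samples are
    scanned at each concentration (MTV value) with ``replicates``
    repetitions and additive Gaussian noise per parameter.
    """

    components: dict  # name -> {param: (slope, intercept)}
    concentrations: tuple = tuple(np.round(np.linspace(0.05, 0.40, 8), 4))
    replicates: int = 3
    noise_sd: dict = field(default_factory=lambda: dict(_DEFAULT_NOISE))
    mixtures: tuple = ()  # tuple of {component: fraction} dicts

    def __post_init__(self):
        for c in self.concentrations:
            if not 0 < c < 1:
                raise DataError(f"concentration {c} outside (0, 1)")
        for sd in self.noise_sd.values():
            if sd < 0:
                raise DataError("noise SD must be >= 0")


def default_phantom_spec(noise_scale: float = 1.0) -> PhantomSpec:
    """Three lipid-like components with distinct relaxivity signatures."""
    comps = {
        "PtdCho": {"R1": (1.2, 0.30), "MTsat": (4.0, -0.05), "R2": (18.0, 3.5)},
        "PS": {"R1": (3.0, 0.28), "MTsat": (11.0, -0.15), "R2": (40.0, 4.0)},
        "Spg": {"R1": (2.1, 0.32), "MTsat": (16.0, -0.25), "R2": (28.0, 4.5)},
    }
    noise = {p: sd * noise_scale for p, sd in _DEFAULT_NOISE.items() if p != "MD"}
    return PhantomSpec(
        components=comps,
        noise_sd=noise,
        mixtures=(
            {"PtdCho": 0.5, "PS": 0.5},
            {"PtdCho": 0.25, "PS": 0.25, "Spg": 0.5},
            {"PS": 0.3, "Spg": 0.7},
        ),
    )


def simulate_phantom(spec: PhantomSpec, seed: int = 0) -> pd.DataFrame:
    """Simulate a dilution-series table.

    Returns one row per scanned sample with columns: sample, kind
    (pure/mixture), component (name or mixture id), the design fraction of
    every component, mtv, and one column per qMRI parameter.  Mixture truth
    follows the fraction-weighted forward model.
    """
    rng = np.random.default_rng(seed)
    params = sorted(next(iter(spec.components.values())))
    library = ComponentLibrary(spec.components)
    targets: list[tuple[str, str, dict]] = [
        (name, "pure", {name: 1.0}) for name in spec.components
    ]
    for i, frac in enumerate(spec.mixtures):
        targets.append((f"mix{i + 1}", "mixture", dict(frac)))
    rows = []
    sample_id = 0
    for name, kind, fractions in targets:
        design = MixtureDesign(fractions=fractions, sum_to_one=False)
        sig = predict_mixture_dependency(library, design)
        for mtv in spec.concentrations:
            for _ in range(spec.replicates):
                row = dict(sample=sample_id, kind=kind, component=name, mtv=float(mtv))
                for comp in spec.components:
                    row[f"f_{comp}"] = fractions.get(comp, 0.0)
                for p in params:
                    true = sig.fits[p].predict(mtv)
                    row[p] = float(true + rng.normal(0.0, spec.noise_sd.get(p, 0.0)))
                rows.append(row)
                sample_id += 1
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class RegionSpec:
    """One synthetic region: voxel budget, MTV distribution and true laws."""

    name: str
    label: int
    n_voxels: int
    mtv_mean: float = 0.22
    mtv_sd: float = 0.06
    laws: dict = field(default_factory=lambda: dict(_DEFAULT_LAWS))
    noise_sd: dict = field(default_factory=lambda: dict(_DEFAULT_NOISE))
    hemisphere: str = "none"
    tissue_class: str = "GM"

    def __post_init__(self):
        if self.n_voxels <= 0:
            raise DataError("n_voxels must be positive")


@dataclass(frozen=True)
class BrainSpec:
    """Layout of synthetic regions packed into one 3-D grid.

    Regions are placed as disjoint slabs of ``block_width ** 2`` voxel
    columns stacked along the last axis, separated by a background plane so
    region masks never touch.  MTV is drawn from a per-region normal
    truncated to ``mtv_support`` (keeps the 4% bin filter meaningful).
    """

    regions: tuple  # tuple of RegionSpec
    block_width: int = 12
    mtv_support: tuple = (0.05, 0.40)

    def __post_init__(self):
        labels = [r.label for r in self.regions]
        if len(set(labels)) != len(labels):
            raise DataError("duplicate region labels")
        if self.block_width < 3:
            raise DataError("block_width must be >= 3")
        lo, hi = self.mtv_support
        if not 0 <= lo < hi < 1:
            raise DataError("mtv_support must satisfy 0 <= lo < hi < 1")

    @property
    def params(self) -> tuple:
        return tuple(sorted(self.regions[0].laws))


def default_brain_spec(n_voxels: int = 3000) -> BrainSpec:
    """Six bilateral-ish regions with distinct planted signatures."""
    presets = [
        ("thalamus", 0.24, dict(R1=(2.2, 0.28), MTsat=(9.0, -0.1), MD=(-1.2e-3, 1.15e-3), R2=(28.0, 4.2))),
        ("pallidum", 0.27, dict(R1=(2.3, 0.30), MTsat=(14.0, -0.3), MD=(-1.6e-3, 1.25e-3), R2=(36.0, 4.8))),
        ("frontal-wm", 0.30, dict(R1=(3.1, 0.22), MTsat=(17.0, -0.2), MD=(-1.9e-3, 1.3e-3), R2=(32.0, 4.0))),
    ]
    regions = []
    label = 1
    for name, mtv_mean, laws in presets:
        for hemi in ("L", "R"):
            regions.append(
                RegionSpec(
                    name=name,
                    label=label,
                    n_voxels=n_voxels,
                    mtv_mean=mtv_mean,
                    mtv_sd=0.05,
                    laws=laws,
                    hemisphere=hemi,
                    tissue_class="WM" if "wm" in name else "subcortical",
                )
            )
            label += 1
    return BrainSpec(regions=tuple(regions))


def _truncnorm(rng, mean, sd, lo, hi, size):
    if sd == 0:
        return np.full(size, mean)
    a, b = (lo - mean) / sd, (hi - mean) / sd
    dist = stats.truncnorm(a, b, loc=mean, scale=sd)
    return dist.ppf(rng.uniform(size=size))  # inverse-CDF keeps rng as the only source


def simulate_brain(
    spec: BrainSpec, seed: int = 0
) -> tuple[dict[str, QuantitativeMap], LabelVolume]:
    """Render the spec into co-registered NIfTI-ready volumes.

    Returns ``(maps, labels)`` where maps includes MTV plus one map per
    parameter; each region's qMRI values are its true line evaluated at the
    voxel's MTV plus i.i.d. Gaussian noise.
    """
    rng = np.random.default_rng(seed)
    w = spec.block_width
    heights = [int(np.ceil(r.n_voxels / (w * w))) for r in spec.regions]
    nz = sum(heights) + len(heights) + 1  # one background plane between blocks
    shape = (w + 2, w + 2, nz)
    labels = np.zeros(shape, dtype=int)
    maps = {p: np.full(shape, np.nan) for p in ("MTV", *spec.params)}
    lo, hi = spec.mtv_support
    z0 = 1
    table_rows = []
    for region, h in zip(spec.regions, heights):
        block = np.zeros((w, w, h), dtype=bool)
        flat = block.reshape(-1, order="C")
        flat[: region.n_voxels] = True
        block = flat.reshape((w, w, h))
        sub = labels[1 : w + 1, 1 : w + 1, z0 : z0 + h]
        sub[block] = region.label
        mtv = _truncnorm(rng, region.mtv_mean, region.mtv_sd, lo, hi, region.n_voxels)
        view = maps["MTV"][1 : w + 1, 1 : w + 1, z0 : z0 + h]
        view[block] = mtv
        for p in spec.params:
            slope, intercept = region.laws[p]
            noise = region.noise_sd.get(p, 0.0)
            vals = slope * mtv + intercept
            if noise > 0:
                vals = vals + rng.normal(0.0, noise, size=vals.shape)
            pview = maps[p][1 : w + 1, 1 : w + 1, z0 : z0 + h]
            pview[block] = vals
        z0 += h + 1
        table_rows.append(
            dict(
                label=region.label,
                name=region.name,
                hemisphere=region.hemisphere,
                tissue_class=region.tissue_class,
            )
        )
    qmaps = {p: QuantitativeMap(values=v, param=p) for p, v in maps.items()}
    label_volume = LabelVolume(labels=labels, region_table=pd.DataFrame(table_rows))
    return qmaps, label_volume


@dataclass(frozen=True)
class CohortSpec:
    """Two-group cohort with planted region- and marker-specific effects.

    ``baseline`` gives the young-group mean per (region, marker);
    ``between_sd`` the between-subject SD of each marker; ``planted_d``
    maps (region, marker) to a Cohen's d applied to the old group (old mean
    = young mean + d * between_sd).  Group sizes default to 23 young and 18
    old subjects, the reference study design.
    """

    regions: tuple
    markers: tuple
    baseline: dict  # (region, marker) -> mean
    between_sd: dict  # marker -> SD (or (region, marker) -> SD)
    planted_d: dict = field(default_factory=dict)  # (region, marker) -> d
    n_young: int = 23
    n_old: int = 18

    def __post_init__(self):
        if self.n_young < 2 or self.n_old < 2:
            raise DataError("group sizes must be >= 2")

    def sd_of(self, region, marker) -> float:
        if (region, marker) in self.between_sd:
            return self.between_sd[(region, marker)]
        return self.between_sd[marker]


def default_cohort_spec(
    regions=("thalamus", "pallidum", "frontal-wm", "parietal-wm", "hippocampus", "putamen"),
    markers=("dMTsat/dMTV", "MTV", "R2star", "volume"),
    planted_d: dict | None = None,
) -> CohortSpec:
    baselines = {"dMTsat/dMTV": 12.0, "MTV": 0.25, "R2star": 22.0, "volume": 5000.0}
    sds = {"dMTsat/dMTV": 1.5, "MTV": 0.015, "R2star": 2.0, "volume": 450.0}
    baseline = {(r, m): baselines[m] for r in regions for m in markers}
    return CohortSpec(
        regions=tuple(regions),
        markers=tuple(markers),
        baseline=baseline,
        between_sd={m: sds[m] for m in markers},
        planted_d=planted_d or {},
    )


def simulate_cohort(spec: CohortSpec, seed: int = 0, output: str = "markers"):
    """Draw a two-group cohort.

    ``output='markers'`` (default) returns the tidy measurement table the
    aging statistics consume: subject, group, region, marker, value.
    ``output='signatures'`` instead simulates per-subject brain volumes
    whose planted slopes carry the group shifts, runs the signature
    pipeline per subject, and returns the per-subject signature table —
    the full-pipeline variant, at whatever sizes the spec requests.
    """
    if output == "markers":
        return _simulate_marker_cohort(spec, seed)
    if output == "signatures":
        return _simulate_signature_cohort(spec, seed)
    raise ValueError(f"unknown output {output!r}")


def _simulate_marker_cohort(spec: CohortSpec, seed: int) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    rows = []
    groups = [("young", spec.n_young, "Y"), ("old", spec.n_old, "O")]
    for group, n, prefix in groups:
        for i in range(n):
            subject = f"{prefix}{i + 1:03d}"
            for region in spec.regions:
                for marker in spec.markers:
                    mu = spec.baseline[(region, marker)]
                    sd = spec.sd_of(region, marker)
                    if group == "old":
                        mu = mu + spec.planted_d.get((region, marker), 0.0) * sd
                    rows.append(
                        dict(
                            subject=subject, group=group, region=region,
                            marker=marker, value=float(rng.normal(mu, sd)),
                        )
                    )
    return pd.DataFrame(rows)


def _simulate_signature_cohort(spec: CohortSpec, seed: int) -> pd.DataFrame:
    """Per-subject map volumes -> signature pipeline -> tidy slope table.

    Markers must be of the form 'd<param>/dMTV'; the planted shift moves
    the subject's true slope for that parameter.  Sizes are deliberately
    modest (this path exists to exercise the whole chain, not for speed).
    """
    rng = np.random.default_rng(seed)
    slope_markers = {}
    for m in spec.markers:
        if not (m.startswith("d") and m.endswith("/dMTV")):
            raise DataError(f"signature mode needs d<param>/dMTV markers, got {m!r}")
        slope_markers[m] = m[1 : -len("/dMTV")]
    frames = []
    groups = [("young", spec.n_young, "Y"), ("old", spec.n_old, "O")]
    for group, n, prefix in groups:
        for i in range(n):
            subject = f"{prefix}{i + 1:03d}"
            regions = []
            for j, region in enumerate(spec.regions):
                laws = {}
                for marker, param in slope_markers.items():
                    mu = spec.baseline[(region, marker)]
                    sd = spec.sd_of(region, marker)
                    if group == "old":
                        mu = mu + spec.planted_d.get((region, marker), 0.0) * sd
                    slope = rng.normal(mu, sd)
                    intercept = _DEFAULT_LAWS.get(param, (0.0, 0.0))[1]
                    laws[param] = (slope, intercept)
                regions.append(
                    RegionSpec(
                        name=region, label=j + 1, n_voxels=1200,
                        laws=laws,
                        noise_sd={p: _DEFAULT_NOISE.get(p, 0.0) for p in laws},
                    )
                )
            brain = BrainSpec(regions=tuple(regions), block_width=8)
            maps, labels = simulate_brain(brain, seed=int(rng.integers(2**31)))
            sigs = []
            policy = MinVoxelPolicy()
            for r in regions:
                sigs.append(
                    compute_signature(
                        maps, labels, r.label, params=tuple(slope_markers.values()),
                        policy=policy, config=BinningConfig(), erosion_depth=0,
                        subject=subject,
                    )
                )
            table = signatures_to_frame(sigs)
            table["group"] = group
            frames.append(table)
    out = pd.concat(frames, ignore_index=True)
    out["marker"] = "d" + out["param"] + "/dMTV"
    out["value"] = out["slope"]
    return out[["subject", "group", "region", "marker", "value"]]
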