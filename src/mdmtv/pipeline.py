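"""Run configuration and the two end-to-end pipelines.

``run_signature_pipeline`` turns co-registered maps + labels into a tidy
per-region (optionally per-subject) signature table with explicit exclusion
reasons; ``run_aging_pipeline`` turns a cohort marker table into group
comparisons, the effect-size mosaic and inter-marker spatial correlations.
Both write a manifest recording the configuration hash and seed so a rerun
with the same config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .aging import effect_profile, run_group_comparisons, correlate_effect_profiles
from .errors import (
    ConfigError,
    DataError,
    EmptyRegionError,
    EmptySignatureError,
)
from .qmaps_io import load_labels, load_map
from .relaxivity import (
    REASON_EMPTY_REGION,
    BinningConfig,
    MinVoxelPolicy,
    compute_signature,
    signatures_to_frame,
)

logger = logging.getLogger("mdmtv")

__all__ = ["RunConfig", "run_signature_pipeline", "run_aging_pipeline"]


@dataclass
class RunConfig:
    """Validated configuration for a pipeline run."""

    maps: dict = field(default_factory=dict)  # param -> NIfTI path
    labels_path: str = ""
    region_table_path: str = ""
    cohort_path: str = ""  # tidy CSV for the aging pipeline
    params: tuple = ("R1", "MTsat")
    erosion_depth: int = 1
    regressor_mode: str = "MTV"
    n_bins: int = 36
    mtv_lo: float = 0.05
    mtv_hi: float = 0.40
    min_bin_frac: float = 0.04
    min_bins_for_fit: int = 5
    min_voxels: dict = field(default_factory=dict)  # param -> threshold override
    equal_var: bool = True
    subject: str = "pooled"
    out_dir: str = "mdmtv_out"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        try:
            raw = yaml.safe_load(Path(path).read_text()) or {}
        except (OSError, yaml.YAMLError) as exc:
            raise ConfigError(f"cannot read config {path}: {exc}") from exc
        if not isinstance(raw, dict):
            raise ConfigError("config must be a YAML mapping")
        unknown = set(raw) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.erosion_depth < 0:
            raise ConfigError("erosion_depth must be >= 0")
        try:
            self.binning()
        except ValueError as exc:
            raise ConfigError(str(exc)) from exc
        for p, path in self.maps.items():
            if not Path(path).exists():
                raise ConfigError(f"map for {p!r} not found: {path}")
        for attr in ("labels_path", "region_table_path", "cohort_path"):
            value = getattr(self, attr)
            if value and not Path(value).exists():
                raise ConfigError(f"{attr} not found: {value}")

    def binning(self) -> BinningConfig:
        return BinningConfig(
            n_bins=self.n_bins,
            lo=self.mtv_lo,
            hi=self.mtv_hi,
            min_bin_frac=self.min_bin_frac,
            regressor_mode=self.regressor_mode,
            min_bins_for_fit=self.min_bins_for_fit,
        )

    def policy(self) -> MinVoxelPolicy:
        if not self.min_voxels:
            return MinVoxelPolicy()
        merged = dict(MinVoxelPolicy().thresholds)
        merged.update(self.min_voxels)
        return MinVoxelPolicy(thresholds=tuple(sorted(merged.items())))

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _write_manifest(config: RunConfig, out: Path, outputs: list[str]) -> None:
    manifest = {
        "config_hash": config.config_hash(),
        "config": asdict(config),
        "package_version": __version__,
        "seed": config.seed,
        "outputs": outputs,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str) + "\n")


def run_signature_pipeline(config: RunConfig) -> pd.DataFrame:
    """Maps + labels -> per-region MDM signature table (CSV + manifest)."""
    if not config.maps or not config.labels_path:
        raise ConfigError("signature pipeline needs maps and labels_path")
    missing = [p for p in ("MTV", *config.params) if p not in config.maps]
    if missing:
        raise ConfigError(f"missing map path(s) for: {missing}")
    maps = {p: load_map(path, p) for p, path in config.maps.items()}
    labels = load_labels(config.labels_path, config.region_table_path)
    binning = config.binning()
    policy = config.policy()
    signatures = []
    exclusion_rows = []
    for label in sorted(labels.region_table["label"].astype(int)):
        info = labels.info(label)
        try:
            sig = compute_signature(
                maps, labels, label, params=tuple(config.params),
                policy=policy, config=binning,
                erosion_depth=config.erosion_depth, subject=config.subject,
            )
            signatures.append(sig)
            for p, reason in sig.excluded.items():
                logger.info("region %s: %s excluded (%s)", info["name"], p, reason)
        except EmptyRegionError:
            logger.info("region %s (label %d): empty after erosion", info["name"], label)
            exclusion_rows.extend(
                dict(subject=config.subject, region=info["name"], param=p,
                     slope=float("nan"), intercept=float("nan"),
                     r2_adj=float("nan"), n_bins=0, excluded=True,
                     reason=REASON_EMPTY_REGION)
                for p in config.params
            )
        except EmptySignatureError as exc:
            logger.info("%s", exc)
            exclusion_rows.extend(
                dict(subject=config.subject, region=info["name"], param=p,
                     slope=float("nan"), intercept=float("nan"),
                     r2_adj=float("nan"), n_bins=0, excluded=True,
                     reason="all-excluded")
                for p in config.params
            )
    table = signatures_to_frame(signatures)
    if exclusion_rows:
        table = pd.concat([table, pd.DataFrame(exclusion_rows)], ignore_index=True)
    table = table.sort_values(["subject", "region", "param"]).reset_index(drop=True)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table.to_csv(out / "signatures.csv", index=False)
    _write_manifest(config, out, ["signatures.csv"])
    return table


def run_aging_pipeline(config: RunConfig) -> dict:
    """Cohort marker table -> comparisons, effect mosaic, marker correlations."""
    if not config.cohort_path:
        raise ConfigError("aging pipeline needs cohort_path")
    cohort = pd.read_csv(config.cohort_path)
    if cohort.empty:
        raise DataError("cohort table is empty")
    groups = set(cohort.get("group", pd.Series(dtype=str)).unique())
    if not {"young", "old"} <= groups:
        raise DataError(f"cohort needs young and old groups, found {sorted(groups)}")
    comparisons = run_group_comparisons(cohort, equal_var=config.equal_var)
    profile = effect_profile(cohort)
    markers = list(profile.d.columns)
    corr_rows = []
    for i, a in enumerate(markers):
        for b in markers[i + 1 :]:
            slope, r2_adj, p = correlate_effect_profiles(profile.d[a], profile.d[b])
            corr_rows.append(dict(marker_a=a, marker_b=b, slope=slope, r2_adj=r2_adj, p=p))
    correlations = pd.DataFrame(corr_rows)
    mosaic = profile.d.copy()
    mosaic["dominant"] = profile.dominant
    mosaic["below_floor"] = profile.below_floor
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    comparisons.to_csv(out / "comparisons.csv", index=False)
    mosaic.to_csv(out / "effect_profile.csv", index_label="region")
    correlations.to_csv(out / "marker_correlations.csv", index=False)
    _write_manifest(
        config, out, ["comparisons.csv", "effect_profile.csv", "marker_correlations.csv"]
    )
    return {"comparisons": comparisons, "profile": profile, "correlations": correlations}
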