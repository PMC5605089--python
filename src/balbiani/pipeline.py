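"""End-to-end orchestration: manifest in, CSV results out.

A manifest CSV (columns ``oocyte_id, path, genotype``) lists the stacks to
quantify.  Each pipeline reads the stacks, runs the corresponding analysis
and writes CSVs whose headers embed the configuration hash and seed so
reruns are reproducible bit-for-bit.  Per-oocyte failures are logged and
reported, never silently dropped.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .core import Image2D, PixelCalibration, median_filter, read_image_stack
from .disassembly import (
    BbRatioConfig,
    DisassemblyRecord,
    SegmentationError,
    compute_disassembly_ratio,
    fit_ratio_regression,
    preprocess_channel,
    segment_oocyte,
)
from .puncta import (
    PunctaConfig,
    compute_density_table,
    detect_puncta,
    perimeter_band,
    segment_rois,
    two_way_anova_tukey,
)

__all__ = ["RunConfig", "run_bb_pipeline", "run_puncta_pipeline", "write_csv"]

log = logging.getLogger("balbiani")

DEFAULT_CHANNELS = ("DAPI", "DIOC6", "BUC", "CK")


@dataclass(frozen=True)
class RunConfig:
    """Full run configuration; YAML round-trippable.

    The XY pixel size is an assumed default (the acquisition's pixel size
    must be supplied for real data); the z-step default matches the 1 µm
    acquisition increment.
    """

    channels: tuple[str, ...] = DEFAULT_CHANNELS
    xy_um_per_px: float = 0.35          # assumed; override per dataset
    z_um_per_slice: float = 1.0
    bb: BbRatioConfig = field(default_factory=BbRatioConfig)
    puncta: PunctaConfig = field(default_factory=PunctaConfig)
    seed: int = 0
    out_dir: str = "results"

    @property
    def calibration(self) -> PixelCalibration:
        return PixelCalibration(self.xy_um_per_px, self.z_um_per_slice)

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        d["channels"] = list(d["channels"])
        if d["bb"].get("z_range") is not None:
            d["bb"]["z_range"] = list(d["bb"]["z_range"])
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        d = yaml.safe_load(text) or {}
        if "bb" in d:
            if d["bb"].get("z_range") is not None:
                d["bb"]["z_range"] = tuple(d["bb"]["z_range"])
            d["bb"] = BbRatioConfig(**d["bb"])
        if "puncta" in d:
            d["puncta"] = PunctaConfig(**d["puncta"])
        if "channels" in d:
            d["channels"] = tuple(d["channels"])
        return cls(**d)

    def config_hash(self) -> str:
        return hashlib.sha1(self.to_yaml().encode()).hexdigest()[:12]


def write_csv(df: pd.DataFrame, path: str | Path, config: RunConfig) -> None:
    """CSV with provenance header comments (config hash + seed)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# config_hash: {config.config_hash()}\n")
        fh.write(f"# seed: {config.seed}\n")
        df.to_csv(fh, index=False)


def read_manifest(manifest: str | Path) -> pd.DataFrame:
    df = pd.read_csv(manifest, comment="#")
    required = {"oocyte_id", "path", "genotype"}
    if not required <= set(df.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    if df.empty:
        raise ValueError("empty manifest")
    return df


def _resolve(path: str, manifest: Path) -> Path:
    p = Path(path)
    return p if p.is_absolute() else manifest.parent / p


# ---------------------------------------------------------------------------
# Bb disassembly pipeline
# ---------------------------------------------------------------------------

def run_bb_pipeline(
    config: RunConfig, manifest_path: str | Path, out_dir: str | Path | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, list[dict]]:
    """Per-oocyte disassembly records + per-genotype regression summaries.

    Returns ``(records, regressions, failures)`` and, if ``out_dir`` is set,
    writes ``bb_records.csv`` and ``bb_regression.csv`` there.
    """
    manifest_path = Path(manifest_path)
    manifest = read_manifest(manifest_path)
    records: list[DisassemblyRecord] = []
    failures: list[dict] = []
    dapi, buc = config.channels[0], config.channels[2]
    for row in manifest.itertuples(index=False):
        try:
            stack = read_image_stack(
                _resolve(row.path, manifest_path), config.channels,
                fallback_calibration=config.calibration,
            )
            dapi_img = median_filter(
                Image2D(stack.channel(dapi).sum(axis=0), stack.calibration),
                config.bb.median_radius_px,
            )
            boundary = segment_oocyte(dapi_img, config.bb)
            rec = compute_disassembly_ratio(
                stack, buc, boundary, config.bb,
                oocyte_id=str(row.oocyte_id), genotype=str(row.genotype),
            )
            records.append(rec)
            log.info(
                "bb-ratio %s: diameter=%.1fum ratio=%.3f flags=%s",
                row.oocyte_id, rec.diameter_um, rec.ratio, rec.flags or "-",
            )
        except (OSError, ValueError, SegmentationError) as exc:
            failures.append({"oocyte_id": str(row.oocyte_id), "error": str(exc)})
            log.warning("bb-ratio %s FAILED: %s", row.oocyte_id, exc)

    rec_df = pd.DataFrame(
        [
            {
                "oocyte_id": r.oocyte_id,
                "genotype": r.genotype,
                "diameter_um": r.diameter_um,
                "ratio": r.ratio,
                "total_area_um2": r.total_area_um2,
                "bb_area_um2": r.bb_area_um2,
                "intermodes_converged": r.intermodes_converged,
                "flags": ";".join(r.flags),
            }
            for r in records
        ]
    )
    reg_rows = []
    for genotype in sorted({r.genotype for r in records}):
        grp = [r for r in records if r.genotype == genotype]
        try:
            reg = fit_ratio_regression(grp)
            reg_rows.append(
                {
                    "genotype": genotype,
                    "slope": reg.slope,
                    "intercept": reg.intercept,
                    "r_squared": reg.r_squared,
                    "p_value": reg.p_value,
                    "n": reg.n,
                    "n_excluded": reg.n_excluded,
                }
            )
        except ValueError as exc:
            log.warning("regression for %s skipped: %s", genotype, exc)
    reg_df = pd.DataFrame(reg_rows)
    if out_dir is not None:
        write_csv(rec_df, Path(out_dir) / "bb_records.csv", config)
        write_csv(reg_df, Path(out_dir) / "bb_regression.csv", config)
    return rec_df, reg_df, failures


# ---------------------------------------------------------------------------
# puncta pipeline
# ---------------------------------------------------------------------------

def run_puncta_pipeline(
    config: RunConfig, manifest_path: str | Path, out_dir: str | Path | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, list[dict]]:
    """Density table + ANOVA + Tukey comparisons for a cohort.

    Returns ``(densities, anova, tukey, failures)``; CSVs are written to
    ``out_dir`` when given.
    """
    manifest_path = Path(manifest_path)
    manifest = read_manifest(manifest_path)
    dapi, dioc6, ck = config.channels[0], config.channels[1], config.channels[3]
    tables = []
    failures: list[dict] = []
    for row in manifest.itertuples(index=False):
        try:
            stack = read_image_stack(
                _resolve(row.path, manifest_path), config.channels,
                fallback_calibration=config.calibration,
            )
            dapi_img = median_filter(
                Image2D(stack.channel(dapi).sum(axis=0), stack.calibration),
                config.bb.median_radius_px,
            )
            boundary = segment_oocyte(dapi_img, config.bb)
            dioc6_img = median_filter(
                Image2D(stack.channel(dioc6).sum(axis=0), stack.calibration),
                config.bb.median_radius_px,
            )
            rois = segment_rois(dioc6_img, boundary, config.puncta)
            if rois.bb.data.any():
                rois.perimeter = perimeter_band(rois)
            ck_cfg = dataclasses.replace(
                config.bb,
                ball_radius_px=config.puncta.ck_ball_radius_px,
                median_radius_px=config.puncta.ck_median_radius_px,
            )
            ck_img = preprocess_channel(stack, ck, ck_cfg)
            pts = detect_puncta(ck_img, rois, config.puncta)
            tables.append(
                compute_density_table(
                    pts, rois, oocyte_id=str(row.oocyte_id), genotype=str(row.genotype)
                )
            )
            log.info("puncta %s: %d puncta, flags=%s", row.oocyte_id, len(pts),
                     rois.flags or "-")
        except (OSError, ValueError, SegmentationError) as exc:
            failures.append({"oocyte_id": str(row.oocyte_id), "error": str(exc)})
            log.warning("puncta %s FAILED: %s", row.oocyte_id, exc)

    density = (
        pd.concat(tables, ignore_index=True) if tables else pd.DataFrame()
    )
    try:
        res = two_way_anova_tukey(
            density, include_perimeter=config.puncta.include_perimeter_in_anova
        )
        anova = res.anova.reset_index(names="factor")
        tukey = res.tukey
    except ValueError as exc:
        log.warning("ANOVA skipped: %s", exc)
        anova, tukey = pd.DataFrame(), pd.DataFrame()
    if out_dir is not None:
        write_csv(density, Path(out_dir) / "puncta_density.csv", config)
        write_csv(anova, Path(out_dir) / "puncta_anova.csv", config)
        write_csv(tukey, Path(out_dir) / "puncta_tukey.csv", config)
    return density, anova, tukey, failures
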