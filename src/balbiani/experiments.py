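"""Reproducible simulation experiments over the full analysis chain.

Each driver generates synthetic ground truth, runs the quantification
pipelines end to end and returns summary numbers.  They are used by the
validation suite and by ``scripts/acceptance.py``; problem sizes are chosen
so a full run stays in the minutes range on one CPU (scenes are rendered at
0.7 µm/px for the disassembly experiments and 0.5 µm/px for the puncta
experiments, versus the 0.35 µm/px acquisition default).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .core import Image2D, PixelCalibration, median_filter
from .disassembly import (
    BbRatioConfig,
    RegressionResult,
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
from .synth import (
    CohortSpec,
    SceneParams,
    ground_truth_densities,
    make_cohort,
    make_scene,
    render_scene,
)

RATIO_CAL = PixelCalibration(xy_um_per_px=0.7)
PUNCTA_CAL = PixelCalibration(xy_um_per_px=0.5)


def _boundary(stack, cfg: BbRatioConfig | None = None):
    dapi = median_filter(
        Image2D(stack.channel("DAPI").sum(axis=0), stack.calibration),
        (cfg or BbRatioConfig()).median_radius_px,
    )
    return segment_oocyte(dapi, cfg)


def quantify_stack(stack, oocyte_id: str = "", genotype: str = ""):
    """DAPI boundary + Buc disassembly ratio for one rendered stack."""
    boundary = _boundary(stack)
    return compute_disassembly_ratio(
        stack, "BUC", boundary, oocyte_id=oocyte_id, genotype=genotype
    )


# ---------------------------------------------------------------------------
# disassembly-ratio recovery
# ---------------------------------------------------------------------------

def recover_f_grid(
    seed: int = 0,
    f_values: tuple[float, ...] = (0.0, 0.25, 0.5, 0.75, 1.0),
    n_seeds: int = 10,
    snr: float = 10.0,
    diameter_um: float = 110.0,
) -> pd.DataFrame:
    """Programmed vs recovered disassembly ratio over an f grid.

    Returns one row per (f, replicate) with the recovered ratio.
    """
    rows = []
    rng = np.random.default_rng([seed, 0xF6])
    for f in f_values:
        for _ in range(n_seeds):
            scene_seed = int(rng.integers(0, 2**31 - 1))
            params = SceneParams(
                oocyte_diameter_um=diameter_um,
                disassembly_fraction_f=f,
                bb_position="perinuclear" if f > 0.95 else "cortical",
                snr=snr,
            )
            scene = make_scene(params, seed=scene_seed, calibration=RATIO_CAL)
            rec = quantify_stack(render_scene(scene))
            rows.append({"f": f, "seed": scene_seed, "ratio": rec.ratio})
    return pd.DataFrame(rows)


def cohort_regressions(
    seed: int = 0, n_wt: int = 30, n_mutant: int = 15
) -> dict[str, RegressionResult]:
    """Ratio-vs-diameter regressions for synthetic WT and mutant cohorts."""
    out = {}
    for genotype, n in (("WT", n_wt), ("mutant", n_mutant)):
        spec = CohortSpec(genotype, n, seed=seed, calibration=RATIO_CAL)
        records = [
            quantify_stack(stack, oocyte_id=str(i), genotype=genotype)
            for i, (scene, stack) in enumerate(make_cohort(spec))
        ]
        out[genotype] = fit_ratio_regression(records)
    return out


def diameter_sweep(
    diameters_um: tuple[float, ...] = (50, 72, 94, 116, 138, 160),
    seed: int = 1,
) -> pd.DataFrame:
    """Noise-free equivalent-circle diameter vs programmed diameter."""
    rows = []
    for d in diameters_um:
        params = SceneParams(oocyte_diameter_um=d, bb_diameter_um=min(20.0, 0.25 * d))
        scene = make_scene(params, seed=seed, calibration=RATIO_CAL)
        stack = render_scene(scene, with_noise=False, n_slices=1)
        b = _boundary(stack)
        rows.append({"true_um": d, "measured_um": b.diameter_um})
    df = pd.DataFrame(rows)
    df["rel_error"] = (df.measured_um - df.true_um).abs() / df.true_um
    return df


# ---------------------------------------------------------------------------
# puncta density
# ---------------------------------------------------------------------------

def puncta_density_tables(
    seed: int = 0,
    n_oocytes: int = 10,
    genotype: str = "WT",
    snr: float = 10.0,
) -> pd.DataFrame:
    """Full imaging-path density tables for a cohort of intact-Bb oocytes."""
    cfg = PunctaConfig()
    ck_pre = dataclasses.replace(
        BbRatioConfig(),
        ball_radius_px=cfg.ck_ball_radius_px,
        median_radius_px=cfg.ck_median_radius_px,
    )
    rng = np.random.default_rng([seed, 0xCE])
    tables = []
    for i in range(n_oocytes):
        d = float(rng.uniform(90, 130))
        params = SceneParams(oocyte_diameter_um=d, snr=snr)
        scene = make_scene(
            params, seed=int(rng.integers(0, 2**31 - 1)), calibration=PUNCTA_CAL
        )
        stack = render_scene(scene)
        boundary = _boundary(stack)
        dioc = median_filter(
            Image2D(stack.channel("DIOC6").sum(axis=0), PUNCTA_CAL), 5
        )
        rois = segment_rois(dioc, boundary, cfg)
        if rois.bb.data.any():
            rois.perimeter = perimeter_band(rois)
        pts = detect_puncta(preprocess_channel(stack, "CK", ck_pre), rois, cfg)
        tables.append(compute_density_table(pts, rois, f"{genotype}_{i}", genotype))
    return pd.concat(tables, ignore_index=True)


def bb_cyto_density_ratio(table: pd.DataFrame) -> float:
    """Ratio of mean Bb density to mean cytoplasm density."""
    means = table.groupby("region")["density_per_um2"].mean()
    return float(means["bb"] / means["cytoplasm"])


def anova_region_power(
    seed: int = 0,
    n_replicates: int = 100,
    n_wt: int = 7,
    n_mutant: int = 10,
    alpha: float = 0.01,
) -> float:
    """Fraction of replicates where the region effect reaches significance.

    Replicate cohorts are drawn at the point-process level (Poisson puncta
    counts on generator geometry) with the study's group sizes; each is fed
    through the two-way ANOVA.
    """
    rng = np.random.default_rng([seed, 0xA0])
    hits = 0
    for _ in range(n_replicates):
        rows = []
        for genotype, n in (("WT", n_wt), ("mutant", n_mutant)):
            for i in range(n):
                d = float(rng.uniform(90, 130))
                params = SceneParams(oocyte_diameter_um=d)
                scene = make_scene(
                    params, seed=int(rng.integers(0, 2**31 - 1)), calibration=RATIO_CAL
                )
                dens = ground_truth_densities(scene)
                for region, v in dens.items():
                    rows.append(
                        {
                            "oocyte_id": f"{genotype}{i}",
                            "genotype": genotype,
                            "region": region,
                            "puncta_count": 0,
                            "region_area_um2": 1.0,
                            "density_per_um2": v,
                        }
                    )
        res = two_way_anova_tukey(pd.DataFrame(rows))
        if res.p_value("region") < alpha:
            hits += 1
    return hits / n_replicates


# ---------------------------------------------------------------------------
# structural invariants
# ---------------------------------------------------------------------------

def random_scene_params(rng) -> SceneParams:
    d = float(rng.uniform(60, 150))
    f = float(rng.uniform(0, 1))
    return SceneParams(
        oocyte_diameter_um=d,
        nucleus_offset_um=float(rng.uniform(0, 0.15 * d)),
        bb_diameter_um=float(min(20.0, 0.22 * d) * rng.uniform(0.8, 1.2)),
        bb_position="perinuclear" if rng.uniform() < 0.5 else "cortical",
        disassembly_fraction_f=f,
        snr=float(rng.uniform(8, 15)),
    )


def check_scene_invariants(seed: int = 0, n_scenes: int = 50) -> dict[str, int]:
    """Run the full chain on randomised scenes and count invariant violations."""
    rng = np.random.default_rng([seed, 0x1F])
    violations = {
        "roi_overlap": 0,
        "ratio_out_of_bounds": 0,
        "bb_exceeds_total": 0,
        "count_not_conserved": 0,
    }
    cfg = PunctaConfig()
    ck_pre = dataclasses.replace(
        BbRatioConfig(),
        ball_radius_px=cfg.ck_ball_radius_px,
        median_radius_px=cfg.ck_median_radius_px,
    )
    for _ in range(n_scenes):
        params = random_scene_params(rng)
        scene = make_scene(
            params, seed=int(rng.integers(0, 2**31 - 1)), calibration=RATIO_CAL
        )
        stack = render_scene(scene)
        boundary = _boundary(stack)
        rec = compute_disassembly_ratio(stack, "BUC", boundary)
        if not 0.0 <= rec.ratio <= 1.0:
            violations["ratio_out_of_bounds"] += 1
        if rec.bb_area_um2 > rec.total_area_um2 + 1e-9:
            violations["bb_exceeds_total"] += 1
        dioc = median_filter(
            Image2D(stack.channel("DIOC6").sum(axis=0), RATIO_CAL), 5
        )
        rois = segment_rois(dioc, boundary, cfg)
        if rois.bb.data.any():
            rois.perimeter = perimeter_band(rois)
        try:
            rois.validate()
        except AssertionError:
            violations["roi_overlap"] += 1
        pts = detect_puncta(preprocess_channel(stack, "CK", ck_pre), rois, cfg)
        table = compute_density_table(pts, rois, "x", "WT")
        partition = table[table.region.isin(["cytoplasm", "nucleus", "bb"])]
        if int(partition.puncta_count.sum()) != len(pts):
            violations["count_not_conserved"] += 1
    return violations
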