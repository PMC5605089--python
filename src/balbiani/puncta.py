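"""Region-of-interest cytokeratin puncta density analysis.

The oocyte is sectioned into nucleus, Balbiani body and cytoplasm by the
intensity of DiOC6 staining (bright Bb, mid cytoplasm, dark nucleus), plus
a perimeter band — any cytoplasm within one Bb diameter of the plasma
membrane.  Cytokeratin-positive puncta are detected by a simple threshold
and counted per region; density is puncta per µm².  Group comparisons use
a two-way ANOVA (region x genotype, type-II sums of squares for unbalanced
designs) with Tukey HSD on the region-by-genotype cell means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.morphology import erosion as _erosion, opening as _opening, disk

import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .core import BinaryMask, Image2D, PixelCalibration
from .disassembly import OocyteBoundary, _largest_component
from .threshold import (
    intermode_threshold,
    otsu_threshold,
    percentile_threshold,
    quantize_image,
    threshold_mask,
)

__all__ = [
    "RoiSet",
    "Punctum",
    "AnovaResult",
    "PunctaConfig",
    "segment_rois",
    "perimeter_band",
    "detect_puncta",
    "compute_density_table",
    "two_way_anova_tukey",
    "DENSITY_COLUMNS",
]

DENSITY_COLUMNS = [
    "oocyte_id",
    "genotype",
    "region",
    "puncta_count",
    "region_area_um2",
    "density_per_um2",
]


@dataclass(frozen=True)
class PunctaConfig:
    """Tunables of the puncta pipeline."""

    percentile_p: float = 0.5        # nucleus (low-intensity) threshold
    rim_px: int = 2                  # membrane outline thickness
    open_radius_px: int = 3          # despeckle for the nucleus mask
    min_bb_area_px: int = 20
    puncta_threshold: str | float = "mad"    # "mad", "otsu" or fixed intensity
    mad_k: float = 5.0               # spot threshold: bg median + k * MAD
    min_punctum_area_px: int = 2
    ck_ball_radius_px: int = 50      # CK background subtraction
    ck_median_radius_px: int = 0     # no smoothing: it merges/erases puncta
    include_perimeter_in_anova: bool = False


@dataclass
class RoiSet:
    """Disjoint region masks within one oocyte.

    nucleus, bb and cytoplasm partition the oocyte; the perimeter band is a
    subset of the cytoplasm; the membrane outline is the 2-px inner rim.
    """

    oocyte: BinaryMask
    membrane_outline: BinaryMask
    nucleus: BinaryMask
    bb: BinaryMask
    cytoplasm: BinaryMask
    calibration: PixelCalibration
    perimeter: BinaryMask | None = None
    flags: list[str] = field(default_factory=list)

    def region_mask(self, region: str) -> BinaryMask:
        return getattr(self, region if region != "perimeter" else "perimeter")

    def validate(self) -> None:
        o = self.oocyte.data
        n, b, c = self.nucleus.data, self.bb.data, self.cytoplasm.data
        assert not (n & b).any(), "nucleus overlaps Bb"
        assert not (c & n).any(), "cytoplasm overlaps nucleus"
        assert not (c & b).any(), "cytoplasm overlaps Bb"
        for m in (n, b, c, self.membrane_outline.data):
            assert not (m & ~o).any(), "region escapes the oocyte"
        if self.perimeter is not None:
            assert not (self.perimeter.data & ~c).any(), "perimeter escapes cytoplasm"


@dataclass(frozen=True)
class Punctum:
    """One detected cytokeratin spot."""

    centroid: tuple[float, float]
    area_px: int
    mean_intensity: float
    region: str           # bb | nucleus | cytoplasm
    in_perimeter: bool = False


def segment_rois(
    dioc6: Image2D,
    boundary: OocyteBoundary,
    cfg: PunctaConfig | None = None,
) -> RoiSet:
    """Section the oocyte into Bb / nucleus / cytoplasm from DiOC6 intensity.

    Bb: largest connected component above the Intermodes (high) threshold.
    Nucleus: largest low-intensity region (at or below the Percentile
    threshold) that does not touch the oocyte boundary, despeckled and
    hole-filled.  Cytoplasm: the remainder.  Membrane outline: inner rim.
    """
    cfg = cfg or PunctaConfig()
    inside = boundary.mask.data
    cal = dioc6.calibration
    flags: list[str] = []
    q, hist = quantize_image(dioc6, mask=inside)

    # Bb from the high Intermodes threshold
    if np.count_nonzero(hist.counts) < 2:
        bright = np.zeros_like(inside)  # uniform staining: nothing stands out
    else:
        t_hi = intermode_threshold(hist)
        bright = threshold_mask(q, t_hi, within=inside)
        if not t_hi.converged:
            flags.append("bb_threshold_fallback")
    bb = _largest_component(bright)
    if np.count_nonzero(bb) < cfg.min_bb_area_px:
        bb = np.zeros_like(inside)
        flags.append("bb_missing")

    # nucleus from the low Percentile threshold
    t_lo = percentile_threshold(hist, cfg.percentile_p)
    low = inside & (q <= t_lo.bin_index) & ~bb
    low = _opening(low, disk(cfg.open_radius_px))
    rim = inside & ~_erosion(inside, disk(cfg.rim_px))
    lab, n = ndimage.label(low)
    nucleus = np.zeros_like(inside)
    if n:
        touching = set(np.unique(lab[rim])) - {0}
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, np.arange(1, n + 1))
        for t in touching:
            sizes[t - 1] = 0
        if sizes.max() > 0:
            nucleus = lab == (int(np.argmax(sizes)) + 1)
            nucleus = ndimage.binary_fill_holes(nucleus) & inside & ~bb
    if not nucleus.any():
        flags.append("nucleus_missing")

    cytoplasm = inside & ~nucleus & ~bb
    return RoiSet(
        oocyte=BinaryMask(inside, cal),
        membrane_outline=BinaryMask(rim, cal),
        nucleus=BinaryMask(nucleus, cal),
        bb=BinaryMask(bb, cal),
        cytoplasm=BinaryMask(cytoplasm, cal),
        calibration=cal,
        flags=flags,
    )


def perimeter_band(rois: RoiSet, bb_diameter_um: float | None = None) -> BinaryMask:
    """Cytoplasm within one Bb diameter of the plasma membrane.

    ``bb_diameter_um`` defaults to the equivalent diameter of the RoiSet's
    own Bb; it must be supplied (e.g. a cohort median) when the Bb is absent.
    """
    if bb_diameter_um is None:
        if not rois.bb.data.any():
            raise ValueError(
                "Bb absent: supply bb_diameter_um (e.g. the cohort median)"
            )
        bb_diameter_um = rois.bb.equivalent_diameter_um()
    if bb_diameter_um <= 0:
        raise ValueError("bb_diameter_um must be positive")
    d_px = bb_diameter_um / rois.calibration.xy_um_per_px
    dist = ndimage.distance_transform_edt(~rois.membrane_outline.data)
    band = rois.cytoplasm.data & (dist <= d_px)
    return BinaryMask(band, rois.calibration)


def detect_puncta(
    ck: Image2D,
    rois: RoiSet,
    cfg: PunctaConfig | None = None,
) -> list[Punctum]:
    """Threshold -> 8-connected components -> size filter -> region by centroid.

    The default threshold is the robust-background rule (median + k*MAD of
    the within-oocyte intensities), the standard for sparse spot detection;
    Otsu and a fixed intensity are available alternatives.
    """
    cfg = cfg or PunctaConfig()
    inside = rois.oocyte.data
    if cfg.puncta_threshold == "mad":
        vals = ck.data[inside]
        med = float(np.median(vals))
        mad = float(np.median(np.abs(vals - med))) * 1.4826
        # floor at 5% of the dynamic range so a (near-)noiseless background
        # cannot pull the threshold into numerical dust
        t = med + max(cfg.mad_k * mad, 0.05 * (float(vals.max()) - med))
        fg = inside & (ck.data > t)
    elif cfg.puncta_threshold == "otsu":
        q, hist = quantize_image(ck, mask=inside)
        fg = threshold_mask(q, otsu_threshold(hist), within=inside)
    else:
        fg = inside & (ck.data > float(cfg.puncta_threshold))
    lab, n = ndimage.label(fg, structure=np.ones((3, 3)))
    if n == 0:
        return []
    idx = np.arange(1, n + 1)
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, idx)
    centroids = ndimage.center_of_mass(np.ones_like(lab), lab, idx)
    means = ndimage.mean(ck.data, lab, idx)
    band = rois.perimeter.data if rois.perimeter is not None else None
    out: list[Punctum] = []
    for size, (cy, cx), mi in zip(sizes, centroids, means):
        if size < cfg.min_punctum_area_px:
            continue
        iy, ix = int(round(cy)), int(round(cx))
        iy = np.clip(iy, 0, inside.shape[0] - 1)
        ix = np.clip(ix, 0, inside.shape[1] - 1)
        if rois.bb.data[iy, ix]:
            region = "bb"
        elif rois.nucleus.data[iy, ix]:
            region = "nucleus"
        elif rois.cytoplasm.data[iy, ix]:
            region = "cytoplasm"
        elif inside[iy, ix]:
            region = "cytoplasm"  # membrane rim is part of the cytoplasm
        else:
            continue
        out.append(
            Punctum(
                centroid=(float(cy), float(cx)),
                area_px=int(size),
                mean_intensity=float(mi),
                region=region,
                in_perimeter=bool(band[iy, ix]) if band is not None else False,
            )
        )
    return out


def compute_density_table(
    puncta: list[Punctum],
    rois: RoiSet,
    oocyte_id: str = "",
    genotype: str = "",
) -> pd.DataFrame:
    """Per-region puncta count, area and density (count/area in µm²).

    Regions are cytoplasm, nucleus, bb and perimeter; the perimeter overlaps
    the cytoplasm by definition.  Zero-area regions emit no row.
    """
    rows = []
    region_masks = {
        "cytoplasm": rois.cytoplasm,
        "nucleus": rois.nucleus,
        "bb": rois.bb,
        "perimeter": rois.perimeter,
    }
    for region, mask in region_masks.items():
        if mask is None:
            continue
        area = mask.area_um2
        if area <= 0:
            continue
        if region == "perimeter":
            count = sum(p.in_perimeter for p in puncta)
        else:
            count = sum(p.region == region for p in puncta)
        rows.append(
            {
                "oocyte_id": oocyte_id,
                "genotype": genotype,
                "region": region,
                "puncta_count": int(count),
                "region_area_um2": area,
                "density_per_um2": count / area,
            }
        )
    return pd.DataFrame(rows, columns=DENSITY_COLUMNS)


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

@dataclass
class AnovaResult:
    """Two-way ANOVA table plus Tukey pairwise comparisons."""

    anova: pd.DataFrame          # index: factor; columns: sum_sq, df, F, PR(>F)
    tukey: pd.DataFrame          # columns: group1, group2, meandiff, p-adj, ...
    flags: list[str] = field(default_factory=list)

    def p_value(self, factor: str) -> float:
        return float(self.anova.loc[factor, "PR(>F)"])

    def f_value(self, factor: str) -> float:
        return float(self.anova.loc[factor, "F"])


def two_way_anova_tukey(
    table: pd.DataFrame, include_perimeter: bool = False
) -> AnovaResult:
    """Density ~ region x genotype ANOVA (type II) with Tukey HSD.

    Falls back to a one-way region ANOVA for single-genotype tables and
    drops the interaction when any cell has fewer than 2 observations.
    The perimeter band is excluded from the model by default because it
    overlaps the cytoplasm region.
    """
    df = table.copy()
    if not include_perimeter:
        df = df[df["region"] != "perimeter"]
    df = df.reset_index(drop=True)
    if df["region"].nunique() < 2:
        raise ValueError("need at least two regions for an ANOVA")
    flags: list[str] = []
    genotypes = df["genotype"].nunique()
    if genotypes < 2:
        formula = "density_per_um2 ~ C(region)"
        flags.append("single_genotype_one_way")
    else:
        cell_sizes = df.groupby(["region", "genotype"]).size()
        if (cell_sizes < 2).any():
            formula = "density_per_um2 ~ C(region) + C(genotype)"
            flags.append("interaction_omitted_insufficient_replication")
        else:
            formula = "density_per_um2 ~ C(region) * C(genotype)"
    model = smf.ols(formula, data=df).fit()
    if np.allclose(model.ssr + model.ess, 0.0):
        # all observations identical: no variance anywhere -> F=0, p=1
        anova = _zero_variance_anova(
            df, genotypes >= 2, "C(region):C(genotype)" in formula
        )
        flags.append("zero_variance")
    else:
        anova = sm.stats.anova_lm(model, typ=2)
    anova.index = [_clean_term(t) for t in anova.index]

    if genotypes >= 2:
        groups = df["region"] + ":" + df["genotype"]
    else:
        groups = df["region"]
    if groups.nunique() >= 2 and len(df) > groups.nunique():
        tk = pairwise_tukeyhsd(df["density_per_um2"].to_numpy(), groups.to_numpy())
        tukey = pd.DataFrame(
            tk.summary().data[1:], columns=[str(c) for c in tk.summary().data[0]]
        )
    else:
        tukey = pd.DataFrame()
        flags.append("tukey_skipped")
    return AnovaResult(anova=anova, tukey=tukey, flags=flags)


def _clean_term(term: str) -> str:
    return (
        term.replace("C(region)", "region")
        .replace("C(genotype)", "genotype")
        .replace(":", " x ")
    )


def _zero_variance_anova(
    df: pd.DataFrame, two_way: bool, interaction: bool
) -> pd.DataFrame:
    terms = ["C(region)"]
    dfs = [df["region"].nunique() - 1]
    if two_way:
        terms.append("C(genotype)")
        dfs.append(df["genotype"].nunique() - 1)
        if interaction:
            terms.append("C(region):C(genotype)")
            dfs.append(dfs[0] * dfs[1])
    resid_df = len(df) - 1 - sum(dfs)
    rows = {
        t: {"sum_sq": 0.0, "df": float(d), "F": 0.0, "PR(>F)": 1.0}
        for t, d in zip(terms, dfs)
    }
    rows["Residual"] = {
        "sum_sq": 0.0,
        "df": float(resid_df),
        "F": np.nan,
        "PR(>F)": np.nan,
    }
    return pd.DataFrame(rows).T
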