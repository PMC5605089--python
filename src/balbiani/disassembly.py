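"""Balbiani body disassembly quantification.

Three stages, matching the published workflow:

1. oocyte boundary and diameter from the DAPI follicle-cell ring
   (percentile threshold, morphological closing, hole filling);
2. dual-threshold Buc segmentation — Otsu for the total Buc signal,
   Intermodes for the brighter Bb fraction — and the Bb/total area ratio,
   the quantitative measure of Bb disassembly (~1 intact, ->0 disassembled);
3. ordinary least-squares regression of the ratio on oocyte diameter.

Automatic quality flags replace the original interactive threshold
adjustment: flagged records can be excluded from the regression instead of
being manually corrected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats
from skimage.morphology import closing as _closing, erosion as _erosion, disk

from .core import BinaryMask, Image2D, ImageStack, preprocess_plane
from .threshold import (
    IntensityHistogram,
    intermode_threshold,
    otsu_threshold,
    percentile_threshold,
    quantize_image,
    threshold_mask,
)

__all__ = [
    "OocyteBoundary",
    "DisassemblyRecord",
    "RegressionResult",
    "BbRatioConfig",
    "SegmentationError",
    "segment_oocyte",
    "compute_disassembly_ratio",
    "fit_ratio_regression",
]


class SegmentationError(RuntimeError):
    """No usable structure found in the channel being segmented."""


@dataclass
class OocyteBoundary:
    """Whole-oocyte disk mask with its equivalent-circle diameter."""

    mask: BinaryMask
    diameter_um: float
    centroid: tuple[float, float]
    flags: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.flags


@dataclass
class DisassemblyRecord:
    """One oocyte's (diameter, Bb/total Buc ratio) data point."""

    oocyte_id: str
    genotype: str
    diameter_um: float
    ratio: float
    total_area_um2: float
    bb_area_um2: float
    intermodes_converged: bool
    flags: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.flags


@dataclass(frozen=True)
class RegressionResult:
    """OLS of ratio on diameter with the squared Pearson correlation."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int
    n_excluded: int = 0


@dataclass(frozen=True)
class BbRatioConfig:
    """Tunables of the disassembly pipeline (units noted per field)."""

    ball_radius_px: int = 50          # rolling-ball background radius
    median_radius_px: int = 5         # median filter disk radius
    projection: str = "sum"
    z_range: tuple[int, int] | None = None
    percentile_p: float = 0.5         # DAPI oocyte segmentation percentile
    close_radius_px: int = 8          # bridges gaps between follicle nuclei
    min_bb_area_px: int = 20          # suppresses specks in the Bb mask
    min_diameter_um: float = 30.0
    max_diameter_um: float = 250.0
    min_cortical_class_um2: float = 8.0  # smallest resolvable cortical Buc patch
    cortex_proximity_um: float = 8.0  # cortical Buc must sit this close to the membrane


# ---------------------------------------------------------------------------
# oocyte boundary
# ---------------------------------------------------------------------------

def _largest_component(mask: np.ndarray) -> np.ndarray:
    lab, n = ndimage.label(mask)
    if n == 0:
        return np.zeros_like(mask)
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    return lab == (int(np.argmax(sizes)) + 1)


def _equiv_diameter_px(mask: np.ndarray) -> float:
    return 2.0 * np.sqrt(np.count_nonzero(mask) / np.pi)


def _is_compact_blob(mask: np.ndarray, min_axis_ratio: float = 0.4,
                     min_solidity: float = 0.5) -> bool:
    """Distinguish a compact blob (Bb) from a thin arc or shell.

    Uses axis ratio and solidity, which — unlike perimeter-based
    circularity — are insensitive to pixel-scale boundary roughness and
    therefore to image resolution.
    """
    from skimage.measure import regionprops

    props = regionprops(mask.astype(np.uint8))
    if not props:
        return False
    p = props[0]
    if p.axis_major_length == 0:
        return True  # single pixel / tiny blob: maximally compact
    return (
        p.axis_minor_length / p.axis_major_length >= min_axis_ratio
        and p.solidity >= min_solidity
    )


def _ring_midline_diameter_px(
    q: np.ndarray, envelope: np.ndarray, cfg: "BbRatioConfig"
) -> float | None:
    """Boundary diameter at the follicle-ring midline.

    The bright follicle nuclei are isolated by Otsu within the envelope;
    the oocyte perimeter is taken halfway between the closed ring's outer
    envelope and the interior it encloses, cancelling the nuclear-thickness
    and blur-halo overshoot.  Returns None when no ring is resolved (plain
    filled disk), in which case the envelope itself is the best estimate.
    """
    counts = np.bincount(q[envelope], minlength=256)[:256]
    if np.count_nonzero(counts) < 2:
        return None
    t = otsu_threshold(IntensityHistogram.from_counts(counts))
    ring = envelope & (q > t.bin_index)
    ring_closed = _closing(ring, disk(cfg.close_radius_px))
    outer = _largest_component(ndimage.binary_fill_holes(ring_closed))
    interior = ndimage.binary_fill_holes(_largest_component(outer & ~ring_closed))
    if np.count_nonzero(interior) < 0.2 * np.count_nonzero(outer):
        return None
    return 0.5 * (_equiv_diameter_px(outer) + _equiv_diameter_px(interior))


def segment_oocyte(
    dapi: Image2D, cfg: BbRatioConfig | None = None
) -> OocyteBoundary:
    """Oocyte disk and diameter from the DAPI follicle-cell ring.

    Percentile threshold -> closing -> hole fill -> largest component gives
    the outer envelope of the ring.  Because the follicle nuclei straddle
    the oocyte surface, the envelope overshoots by about one nuclear
    half-thickness; the boundary is therefore taken at the ring midline —
    the mean of the outer-envelope and enclosed-interior equivalent
    diameters — and the reported mask is the envelope eroded to match, so
    diameter stays 2*sqrt(area/pi) of the mask.  Images without a resolved
    ring (e.g. a plain filled disk) fall back to the envelope itself.
    """
    cfg = cfg or BbRatioConfig()
    q, hist = quantize_image(dapi)
    t = percentile_threshold(hist, cfg.percentile_p)
    fg = q > t.bin_index
    if not fg.any():
        raise SegmentationError("blank DAPI channel: nothing above threshold")
    closed = _closing(fg, disk(cfg.close_radius_px))
    outer = _largest_component(ndimage.binary_fill_holes(closed))
    if not outer.any():
        raise SegmentationError("no closed region found in DAPI channel")

    mask = outer
    d_env = _equiv_diameter_px(outer)
    d_mid = _ring_midline_diameter_px(q, outer, cfg)
    if d_mid is not None:
        erode_px = int(round((d_env - d_mid) / 2.0))
        if erode_px > 0:
            mask = _erosion(outer, disk(erode_px))
            mask = _largest_component(ndimage.binary_fill_holes(mask))

    bmask = BinaryMask(mask, dapi.calibration)
    diameter = bmask.equivalent_diameter_um()
    cy, cx = ndimage.center_of_mass(mask)
    flags = []
    if not cfg.min_diameter_um <= diameter <= cfg.max_diameter_um:
        flags.append("diameter_out_of_range")
    return OocyteBoundary(bmask, diameter, (float(cy), float(cx)), flags)


# ---------------------------------------------------------------------------
# disassembly ratio
# ---------------------------------------------------------------------------

def preprocess_channel(
    stack: ImageStack, channel: str, cfg: BbRatioConfig
) -> Image2D:
    """Slice-wise background subtraction + median filter, then sum projection."""
    planes = stack.channel(channel)
    z_range = cfg.z_range or (0, stack.n_slices - 1)
    lo, hi = z_range
    processed = []
    for z in range(lo, hi + 1):
        plane = Image2D(planes[z], stack.calibration)
        processed.append(
            preprocess_plane(plane, cfg.ball_radius_px, cfg.median_radius_px).data
        )
    agg = np.sum if cfg.projection == "sum" else np.max
    return Image2D(agg(np.stack(processed), axis=0), stack.calibration)


def compute_disassembly_ratio(
    stack: ImageStack,
    buc_channel: str,
    boundary: OocyteBoundary,
    cfg: BbRatioConfig | None = None,
    oocyte_id: str = "",
    genotype: str = "",
) -> DisassemblyRecord:
    """Bb/total Buc area ratio for one oocyte.

    Otsu on the within-oocyte histogram segments total Buc; Intermodes on
    the histogram restricted to the total-Buc mask splits the brighter Bb
    fraction from the dimmer cortical signal.  When that histogram is
    effectively unimodal there is only one Buc class: a compact blob is an
    intact Bb (ratio 1), a thin cortical shell is fully relocalised Buc
    (ratio 0, empty Bb mask).
    """
    cfg = cfg or BbRatioConfig()
    px_area = stack.calibration.px_area_um2
    buc = preprocess_channel(stack, buc_channel, cfg)
    inside = boundary.mask.data
    q, hist = quantize_image(buc, mask=inside)
    if np.count_nonzero(hist.counts) < 2:
        raise SegmentationError("no Buc signal inside the oocyte")
    t_total = otsu_threshold(hist)
    total = threshold_mask(q, t_total, within=inside)
    if not total.any():
        raise SegmentationError("no Buc signal inside the oocyte")

    flags = list(boundary.flags)
    counts = np.bincount(q[total], minlength=hist.n_bins)[: hist.n_bins]
    if np.count_nonzero(counts) >= 2:
        t_bb = intermode_threshold(IntensityHistogram.from_counts(counts))
    else:
        t_bb = None
    converged = bool(t_bb is not None and t_bb.converged)
    if converged:
        bb = threshold_mask(q, t_bb, within=total)
        # a blurred edge makes Intermodes split a single class into its
        # bright core and dim rim; the split is genuine only if the dim
        # class has substance beyond the bright class's rim AND that
        # substance lies against the membrane, where relocalised Buc goes
        lower = total & ~bb
        far_cc = _largest_component(lower & ~ndimage.binary_dilation(bb, disk(2)))
        far_um2 = np.count_nonzero(far_cc) * px_area
        genuine = far_um2 >= cfg.min_cortical_class_um2
        if genuine:
            dist_in = ndimage.distance_transform_edt(inside)
            near_membrane = dist_in <= cfg.cortex_proximity_um / stack.calibration.xy_um_per_px
            genuine = float(np.mean(near_membrane[far_cc])) >= 0.5
        if not genuine:
            bb = total.copy()
            flags.append("single_buc_class")
    else:
        bb = total.copy()
        flags.append("single_buc_class")
    # the Bb is a compact blob; a thin cortical shell of the same intensity
    # class is relocalised Buc, not a Bb
    core = _largest_component(bb)
    if not core.any() or not _is_compact_blob(core):
        bb = np.zeros_like(total)
        flags.append("no_distinct_bb")

    # suppress noise specks
    lab, n = ndimage.label(bb, structure=np.ones((3, 3)))
    if n:
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, np.arange(1, n + 1))
        keep = np.flatnonzero(sizes >= cfg.min_bb_area_px) + 1
        bb = np.isin(lab, keep)

    total_area = float(np.count_nonzero(total)) * px_area
    bb_area = float(np.count_nonzero(bb)) * px_area
    ratio = bb_area / total_area
    return DisassemblyRecord(
        oocyte_id=oocyte_id,
        genotype=genotype,
        diameter_um=boundary.diameter_um,
        ratio=ratio,
        total_area_um2=total_area,
        bb_area_um2=bb_area,
        intermodes_converged=converged,
        flags=flags,
    )


# ---------------------------------------------------------------------------
# regression
# ---------------------------------------------------------------------------

def fit_ratio_regression(
    records: list[DisassemblyRecord], exclude_flagged: bool = True
) -> RegressionResult:
    """OLS of disassembly ratio on oocyte diameter (two-sided slope test).

    Records with hard quality flags (out-of-range diameter) are excluded and
    counted; informational flags about the Bb state do not exclude a record.
    """
    hard = {"diameter_out_of_range", "no_signal"}
    if exclude_flagged:
        used = [r for r in records if not (set(r.flags) & hard)]
    else:
        used = list(records)
    n_excl = len(records) - len(used)
    if len(used) < 3:
        raise ValueError(f"need at least 3 usable records, got {len(used)}")
    x = np.array([r.diameter_um for r in used])
    y = np.array([r.ratio for r in used])
    if np.ptp(x) == 0:
        raise ValueError("degenerate regression: all diameters equal")
    if np.ptp(y) == 0:
        # constant response: zero slope, no explained variance
        return RegressionResult(0.0, float(y[0]), 0.0, 1.0, len(used), n_excl)
    fit = stats.linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
        n=len(used),
        n_excluded=n_excl,
    )
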