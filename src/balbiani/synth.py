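"""Synthetic stage-I oocyte scenes with ground truth.

The study's raw microscopy is not deposited, so this module generates
ground-truthed 4-channel confocal-like images of zebrafish stage I oocytes
(50-160 µm diameter) for testing and calibration of the quantification
pipelines:

* DAPI — follicle-cell nuclei straddling the oocyte boundary (the ring that
  outlines the oocyte) over a dim intra-oocyte autofluorescence level;
* DIOC6 — mitochondria/ER dye: dark nucleus, mid cytoplasm, brighter
  cortical band, brightest Balbiani body;
* BUC — Bucky ball immunostain split between a compact bright Bb and a
  dimmer cortical arc spreading from the vegetal pole.  The disassembly
  fraction ``f`` repartitions Buc-positive *area*: the Bb disk holds
  ``f`` of the intact Bb area and the cortical arc the remaining ``1-f``,
  mirroring the progressive shrinkage of the Bb as Buc is unloaded at the
  cortex.  The Bb stays strictly brighter than the cortical signal and the
  integrated Buc intensity is independent of ``f`` (signal is moved, not
  created);
* CK — cytokeratin puncta as independent homogeneous Poisson point
  processes per region, Bb-enriched by default (4x the cytoplasmic rate).

Rendering applies a Gaussian PSF, then Poisson shot noise plus Gaussian
read noise scaled to a peak SNR.  A z-stack is emulated as three noisy
replicate slices of the same optical section.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Callable

import numpy as np
from scipy import ndimage

from .core import ImageStack, PixelCalibration, write_image_stack

__all__ = [
    "SceneParams",
    "SyntheticScene",
    "CohortSpec",
    "make_scene",
    "render_scene",
    "make_cohort",
    "wt_f_schedule",
    "mutant_f_schedule",
    "ground_truth_densities",
    "write_cohort",
    "CHANNELS",
]

CHANNELS = ("DAPI", "DIOC6", "BUC", "CK")

# rendering constants (arbitrary fluorescence units before rescaling)
DAPI_NUCLEUS_AMP = 1.0
DAPI_INTERIOR_LEVEL = 0.25     # intra-oocyte autofluorescence / out-of-focus light
DIOC6_LEVELS = {"nucleus": 0.03, "cytoplasm": 0.35, "cortex_band": 0.55, "bb": 1.0}
BUC_AMP_RATIO = 2.0            # Bb amplitude / cortical amplitude (Bb is brighter)
CK_SPOT_PEAK = 1.0
CK_DIFFUSE_LEVEL = 0.05
FOLLICLE_RADIAL_SEMI_UM = 1.8  # follicle nuclei ~4.4 x 3.6 µm ellipses
FOLLICLE_TANGENTIAL_SEMI_UM = 2.2
FOLLICLE_SPACING_UM = 6.5
CANVAS_FACTOR = 2.3            # canvas side / ring outer radius: oocyte fills ~60%
CORTEX_BAND_UM = 4.0           # membrane-adjacent band width (DiOC6, CK rates)
BUC_CORTEX_BAND_UM = 6.0       # width of the band the cortical Buc spreads in


class GeometryError(ValueError):
    """Scene geometry infeasible (nucleus or Bb does not fit in the oocyte)."""


@dataclass(frozen=True)
class SceneParams:
    """Ground-truth geometry and signal parameters of one oocyte scene.

    ``disassembly_fraction_f`` is the fraction of Buc-positive area residing
    in the Bb: 1 = intact Bb, 0 = fully cortical.
    """

    oocyte_diameter_um: float = 100.0
    nucleus_diameter_um: float | None = None  # default 0.45 x oocyte diameter
    nucleus_offset_um: float = 0.0            # displacement toward the animal pole
    bb_diameter_um: float = 20.0              # intact-Bb diameter
    bb_position: str = "perinuclear"          # or "cortical"
    disassembly_fraction_f: float = 1.0
    ck_rate_bb: float = 0.04                  # puncta / µm^2, 4x the cytoplasm
    ck_rate_cyto: float = 0.01
    ck_rate_cortex: float = 0.01
    ck_min_spacing_um: float = 1.2            # hard-core radius: puncta are objects
    snr: float = 10.0
    psf_sigma_px: float = 0.8

    def __post_init__(self) -> None:
        if not 50.0 * 0.5 <= self.oocyte_diameter_um <= 300.0:
            raise ValueError(f"unrealistic oocyte diameter {self.oocyte_diameter_um}")
        if not 0.0 <= self.disassembly_fraction_f <= 1.0:
            raise ValueError("disassembly_fraction_f must be in [0, 1]")
        for name in ("ck_rate_bb", "ck_rate_cyto", "ck_rate_cortex"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.bb_position not in ("perinuclear", "cortical"):
            raise ValueError(f"unknown bb_position {self.bb_position!r}")
        if self.snr <= 0 or self.psf_sigma_px < 0:
            raise ValueError("snr must be > 0 and psf_sigma_px >= 0")

    @property
    def nucleus_diameter(self) -> float:
        return (
            self.nucleus_diameter_um
            if self.nucleus_diameter_um is not None
            else 0.45 * self.oocyte_diameter_um
        )


@dataclass
class SyntheticScene:
    """Ground truth: region masks, puncta coordinates and parameters."""

    params: SceneParams
    calibration: PixelCalibration
    shape: tuple[int, int]
    center: tuple[float, float]
    masks: dict[str, np.ndarray]          # oocyte, nucleus, bb, cytoplasm,
    puncta: dict[str, np.ndarray]         # cortex_band, buc_cortex
    seed: int

    def region_area_um2(self, region: str) -> float:
        return float(np.count_nonzero(self.masks[region])) * self.calibration.px_area_um2

    @property
    def true_diameter_um(self) -> float:
        return self.params.oocyte_diameter_um

    @property
    def true_f(self) -> float:
        return self.params.disassembly_fraction_f

    def bb_equivalent_diameter_um(self) -> float:
        return 2.0 * np.sqrt(self.region_area_um2("bb") / np.pi)


def _disk(shape: tuple[int, int], center: tuple[float, float], radius_px: float) -> np.ndarray:
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius_px ** 2


def make_scene(
    params: SceneParams,
    seed: int = 0,
    calibration: PixelCalibration | None = None,
) -> SyntheticScene:
    """Build the ground-truth geometry and sample puncta; deterministic in (params, seed)."""
    cal = calibration or PixelCalibration()
    px = cal.xy_um_per_px
    r = params.oocyte_diameter_um / 2.0 / px
    r_nuc = params.nucleus_diameter / 2.0 / px
    f = params.disassembly_fraction_f
    r_bb0 = params.bb_diameter_um / 2.0 / px
    r_bb = r_bb0 * np.sqrt(f)

    ring_outer = r + FOLLICLE_RADIAL_SEMI_UM / px
    side = int(np.ceil(CANVAS_FACTOR * ring_outer))
    side = max(side, 64)
    c = ((side - 1) / 2.0, (side - 1) / 2.0)
    shape = (side, side)

    # vegetal pole toward +y, animal pole (nucleus offset) toward -y
    nuc_off = params.nucleus_offset_um / px
    c_nuc = (c[0] - nuc_off, c[1])
    if nuc_off + r_nuc >= r:
        raise GeometryError("nucleus does not fit inside the oocyte")

    oocyte = _disk(shape, c, r)
    nucleus = _disk(shape, c_nuc, r_nuc)

    if r_bb > 0:
        if params.bb_position == "perinuclear":
            bb_c = (c_nuc[0] + r_nuc + r_bb + 1.0, c_nuc[1])
        else:  # docked at the vegetal cortex
            bb_c = (c[0] + r - r_bb - 1.0, c[1])
        if np.hypot(bb_c[0] - c[0], bb_c[1] - c[1]) + r_bb > r:
            raise GeometryError("Balbiani body does not fit inside the oocyte")
        bb = _disk(shape, bb_c, r_bb) & oocyte & ~nucleus
    else:
        bb = np.zeros(shape, dtype=bool)

    cytoplasm = oocyte & ~nucleus & ~bb
    dist_in = ndimage.distance_transform_edt(oocyte)
    cortex_band = cytoplasm & (dist_in <= CORTEX_BAND_UM / px)

    # cortical Buc arc: the (1 - f) share of the intact Bb area, as the
    # band pixels nearest in angle to the vegetal pole; the Buc band is
    # wider than the DiOC6 cortex so the arc has a resolvable plateau
    buc_band = cytoplasm & (dist_in <= BUC_CORTEX_BAND_UM / px)
    a0_px = np.pi * r_bb0 ** 2
    n_cx = int(round((1.0 - f) * a0_px))
    buc_cortex = np.zeros(shape, dtype=bool)
    if n_cx > 0:
        band_idx = np.nonzero(buc_band)
        ang = np.abs(
            np.arctan2(band_idx[1] - c[1], band_idx[0] - c[0])
        )  # 0 at vegetal pole (+y)
        order = np.argsort(ang, kind="stable")
        take = order[: min(n_cx, len(order))]
        buc_cortex[band_idx[0][take], band_idx[1][take]] = True

    rng = np.random.default_rng([int(seed), 0xB0B])
    rates = {
        "bb": params.ck_rate_bb,
        "cortex_band": params.ck_rate_cortex,
        "cytoplasm_inner": params.ck_rate_cyto,
    }
    region_masks = {
        "bb": bb,
        "cortex_band": cortex_band,
        "cytoplasm_inner": cytoplasm & ~cortex_band,
    }
    # homogeneous rate per region with a hard-core exclusion radius: puncta
    # are physical objects and cannot overlap.  Counts are Poisson at the
    # programmed rate; positions are drawn by dart throwing.
    d_min_px = params.ck_min_spacing_um / px
    puncta: dict[str, np.ndarray] = {}
    for name, mask in region_masks.items():
        area = np.count_nonzero(mask) * cal.px_area_um2
        n = rng.poisson(rates[name] * area)
        idx = np.nonzero(mask)
        accepted: list[np.ndarray] = []
        if n > 0 and len(idx[0]) > 0:
            for _ in range(n):
                for _attempt in range(50):
                    k = int(rng.integers(0, len(idx[0])))
                    cand = np.array([idx[0][k], idx[1][k]]) + rng.uniform(-0.5, 0.5, 2)
                    if not accepted or (
                        np.hypot(*(np.asarray(accepted) - cand).T).min() >= d_min_px
                    ):
                        break
                accepted.append(cand)
        puncta[name] = (
            np.asarray(accepted) if accepted else np.zeros((0, 2), dtype=float)
        )

    masks = {
        "oocyte": oocyte,
        "nucleus": nucleus,
        "bb": bb,
        "cytoplasm": cytoplasm,
        "cortex_band": cortex_band,
        "buc_cortex": buc_cortex,
    }
    return SyntheticScene(params, cal, shape, c, masks, puncta, int(seed))


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _follicle_ring(scene: SyntheticScene) -> np.ndarray:
    """Follicle-cell nuclei: 30-60 ellipses straddling the oocyte boundary."""
    px = scene.calibration.xy_um_per_px
    r_um = scene.params.oocyte_diameter_um / 2.0
    n = int(np.clip(round(2 * np.pi * r_um / FOLLICLE_SPACING_UM), 30, 60))
    a = FOLLICLE_RADIAL_SEMI_UM / px
    b = FOLLICLE_TANGENTIAL_SEMI_UM / px
    r = r_um / px
    img = np.zeros(scene.shape)
    yy, xx = np.mgrid[: scene.shape[0], : scene.shape[1]]
    for k in range(n):
        phi = 2 * np.pi * k / n
        cy = scene.center[0] + r * np.cos(phi)
        cx = scene.center[1] + r * np.sin(phi)
        # radial/tangential ellipse
        dy, dx = yy - cy, xx - cx
        rad = dy * np.cos(phi) + dx * np.sin(phi)
        tan = -dy * np.sin(phi) + dx * np.cos(phi)
        img[(rad / a) ** 2 + (tan / b) ** 2 <= 1.0] = DAPI_NUCLEUS_AMP
    return img


def _clean_channels(scene: SyntheticScene) -> dict[str, np.ndarray]:
    """Noise-free channel images before PSF blur."""
    p = scene.params
    m = scene.masks
    dapi = _follicle_ring(scene)
    dapi[m["oocyte"] & (dapi == 0)] = DAPI_INTERIOR_LEVEL

    dioc6 = np.zeros(scene.shape)
    dioc6[m["cytoplasm"]] = DIOC6_LEVELS["cytoplasm"]
    dioc6[m["cortex_band"]] = DIOC6_LEVELS["cortex_band"]
    dioc6[m["nucleus"]] = DIOC6_LEVELS["nucleus"]
    dioc6[m["bb"]] = DIOC6_LEVELS["bb"]

    # Buc: area-repartitioned, amplitudes normalised so the integrated
    # intensity equals the intact-Bb area for every f, with the Bb strictly
    # brighter than the cortical arc
    buc = np.zeros(scene.shape)
    n_bb = np.count_nonzero(m["bb"])
    n_cx = np.count_nonzero(m["buc_cortex"])
    px = scene.calibration.xy_um_per_px
    a0_px = np.pi * (p.bb_diameter_um / 2.0 / px) ** 2
    denom = BUC_AMP_RATIO * n_bb + n_cx
    if denom > 0:
        amp_cx = a0_px / denom
        buc[m["buc_cortex"]] = amp_cx
        buc[m["bb"]] = BUC_AMP_RATIO * amp_cx

    ck = np.zeros(scene.shape)
    ck[m["cytoplasm"]] = CK_DIFFUSE_LEVEL
    sigma = max(p.psf_sigma_px, 0.5)
    spot_mass = CK_SPOT_PEAK * 2 * np.pi * sigma ** 2
    for pts in scene.puncta.values():
        for y, x in pts:
            iy, ix = int(round(y)), int(round(x))
            if 0 <= iy < scene.shape[0] and 0 <= ix < scene.shape[1]:
                ck[iy, ix] += spot_mass
    return {"DAPI": dapi, "DIOC6": dioc6, "BUC": buc, "CK": ck}


def _add_noise(clean: np.ndarray, snr: float, rng: np.random.Generator) -> np.ndarray:
    """Poisson shot noise + Gaussian read noise; total sigma at peak = peak/snr."""
    peak = float(clean.max())
    if peak <= 0:
        return np.zeros_like(clean)
    gain = 2.0 * snr ** 2 / peak                 # photons per intensity unit
    shot = rng.poisson(clean * gain) / gain
    read = rng.normal(0.0, peak / (snr * np.sqrt(2.0)), size=clean.shape)
    return np.clip(shot + read, 0.0, None)


def render_scene(
    scene: SyntheticScene,
    with_noise: bool = True,
    n_slices: int = 3,
) -> ImageStack:
    """Render the 4-channel stack: PSF blur, then per-slice noise.

    The z-stack is emulated as ``n_slices`` noisy replicates of the same
    optical section; noise-free rendering returns identical slices.
    """
    p = scene.params
    clean = _clean_channels(scene)
    if p.psf_sigma_px > 0:
        clean = {
            k: ndimage.gaussian_filter(v, p.psf_sigma_px) for k, v in clean.items()
        }
    rng = np.random.default_rng([scene.seed, 0x5EED])
    data = np.zeros((len(CHANNELS), n_slices, *scene.shape))
    for ci, name in enumerate(CHANNELS):
        for z in range(n_slices):
            data[ci, z] = (
                _add_noise(clean[name], p.snr, rng) if with_noise else clean[name]
            )
    return ImageStack(data, CHANNELS, scene.calibration)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

def wt_f_schedule(diameter_um: float) -> float:
    """Wild-type disassembly schedule: intact (f=1) up to 95 µm, linear
    decline to 0.15 at 150 µm, then 0.15."""
    if diameter_um <= 95.0:
        return 1.0
    if diameter_um >= 150.0:
        return 0.15
    return 1.0 + (0.15 - 1.0) * (diameter_um - 95.0) / (150.0 - 95.0)


def mutant_f_schedule(diameter_um: float) -> float:
    """macf1a-mutant schedule: the Bb never disassembles (f = 1)."""
    return 1.0


@dataclass(frozen=True)
class CohortSpec:
    """A simulated group of oocytes spanning stage I growth."""

    genotype: str = "WT"                      # "WT" or "mutant"
    n_oocytes: int = 30
    diameter_range_um: tuple[float, float] = (60.0, 160.0)
    f_schedule: Callable[[float], float] | None = None
    seed: int = 0
    snr: float = 10.0
    calibration: PixelCalibration | None = None

    def __post_init__(self) -> None:
        if self.n_oocytes < 1:
            raise ValueError("n_oocytes must be >= 1")
        if self.genotype not in ("WT", "mutant"):
            raise ValueError(f"unknown genotype {self.genotype!r}")

    @property
    def schedule(self) -> Callable[[float], float]:
        if self.f_schedule is not None:
            return self.f_schedule
        return wt_f_schedule if self.genotype == "WT" else mutant_f_schedule


def cohort_scene_params(spec: CohortSpec, diameter_um: float) -> SceneParams:
    """Scene parameters for one cohort member at a given diameter."""
    f = float(np.clip(spec.schedule(diameter_um), 0.0, 1.0))
    bb_d = min(20.0, 0.25 * diameter_um)
    if spec.genotype == "mutant":
        # enlarged Bb and acentric nucleus, qualitatively mirroring the
        # mutant phenotype (Bb enlarges and never disassembles)
        return SceneParams(
            oocyte_diameter_um=diameter_um,
            nucleus_offset_um=0.3 * diameter_um / 2.0,
            bb_diameter_um=1.4 * bb_d,
            bb_position="perinuclear",
            disassembly_fraction_f=f,
            snr=spec.snr,
        )
    return SceneParams(
        oocyte_diameter_um=diameter_um,
        bb_diameter_um=bb_d,
        bb_position="perinuclear" if f > 0.95 else "cortical",
        disassembly_fraction_f=f,
        snr=spec.snr,
    )


def make_cohort(
    spec: CohortSpec, render: bool = True, with_noise: bool = True
) -> list[tuple[SyntheticScene, ImageStack | None]]:
    """Generate a cohort: diameters uniform over the range, f from the schedule."""
    rng = np.random.default_rng([spec.seed, 0xC040])
    lo, hi = spec.diameter_range_um
    out = []
    for i in range(spec.n_oocytes):
        d = float(rng.uniform(lo, hi))
        scene_seed = int(rng.integers(0, 2**31 - 1))
        scene = make_scene(
            cohort_scene_params(spec, d), seed=scene_seed, calibration=spec.calibration
        )
        stack = render_scene(scene, with_noise=with_noise) if render else None
        out.append((scene, stack))
    return out


def ground_truth_densities(scene: SyntheticScene) -> dict[str, float]:
    """Per-region CK puncta densities (puncta/µm²) straight from ground truth.

    Cytoplasm combines the inner cytoplasm and the cortex band (the band is
    part of the cytoplasm); the Bb is reported separately.
    """
    px2 = scene.calibration.px_area_um2
    n_cyto = len(scene.puncta["cytoplasm_inner"]) + len(scene.puncta["cortex_band"])
    a_cyto = np.count_nonzero(scene.masks["cytoplasm"]) * px2
    n_bb = len(scene.puncta["bb"])
    a_bb = np.count_nonzero(scene.masks["bb"]) * px2
    out = {"cytoplasm": n_cyto / a_cyto if a_cyto else np.nan}
    out["bb"] = n_bb / a_bb if a_bb else np.nan
    out["nucleus"] = 0.0
    return out


# ---------------------------------------------------------------------------
# serialisation (simulate CLI backend)
# ---------------------------------------------------------------------------

def _rle_encode(mask: np.ndarray) -> dict:
    flat = mask.ravel()
    edges = np.nonzero(np.diff(flat))[0] + 1
    bounds = np.concatenate(([0], edges, [flat.size]))
    starts, lengths = [], []
    for s, e in zip(bounds[:-1], bounds[1:]):
        if flat[s]:
            starts.append(int(s))
            lengths.append(int(e - s))
    return {"shape": list(mask.shape), "starts": starts, "lengths": lengths}


def _rle_decode(rle: dict) -> np.ndarray:
    flat = np.zeros(int(np.prod(rle["shape"])), dtype=bool)
    for s, l in zip(rle["starts"], rle["lengths"]):
        flat[s : s + l] = True
    return flat.reshape(rle["shape"])


def scene_ground_truth_json(scene: SyntheticScene) -> str:
    payload = {
        "params": asdict(scene.params),
        "seed": scene.seed,
        "xy_um_per_px": scene.calibration.xy_um_per_px,
        "masks": {k: _rle_encode(v) for k, v in scene.masks.items()},
        "puncta": {k: v.tolist() for k, v in scene.puncta.items()},
    }
    return json.dumps(payload)


def write_cohort(out_dir: str | Path, specs: list[CohortSpec]) -> Path:
    """Render cohorts to OME-TIFFs + ground-truth JSONs and a manifest CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = ["oocyte_id,path,genotype"]
    for spec in specs:
        for i, (scene, stack) in enumerate(make_cohort(spec)):
            oid = f"{spec.genotype}_{spec.seed}_{i:03d}"
            tif = out_dir / f"{oid}.ome.tif"
            write_image_stack(tif, stack)
            (out_dir / f"{oid}.truth.json").write_text(
                scene_ground_truth_json(scene)
            )
            rows.append(f"{oid},{tif.name},{spec.genotype}")
    manifest = out_dir / "manifest.csv"
    manifest.write_text("\n".join(rows) + "\n")
    return manifest
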