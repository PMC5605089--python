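"""ROI segmentation, perimeter band, puncta detection and statistics."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from balbiani import (
    BinaryMask,
    Image2D,
    PixelCalibration,
    SceneParams,
)
from balbiani.core import median_filter
from balbiani.disassembly import BbRatioConfig, preprocess_channel
from balbiani.puncta import (
    PunctaConfig,
    RoiSet,
    compute_density_table,
    detect_puncta,
    perimeter_band,
    segment_rois,
    two_way_anova_tukey,
)
from balbiani.synth import make_scene, render_scene

from conftest import CAL_PUNCTA, boundary_of

CAL = CAL_PUNCTA


def _iou(a, b):
    return (a & b).sum() / max((a | b).sum(), 1)


def rois_of(scene, stack, cfg=None):
    dioc = median_filter(Image2D(stack.channel("DIOC6").sum(axis=0), stack.calibration), 5)
    return segment_rois(dioc, boundary_of(stack), cfg)


def ck_image(stack, cfg=None):
    cfg = cfg or PunctaConfig()
    base = dataclasses.replace(
        BbRatioConfig(),
        ball_radius_px=cfg.ck_ball_radius_px,
        median_radius_px=cfg.ck_median_radius_px,
    )
    return preprocess_channel(stack, "CK", base)


@pytest.fixture(scope="module")
def concentric():
    scene = make_scene(SceneParams(oocyte_diameter_um=110), seed=30, calibration=CAL)
    clean = render_scene(scene, with_noise=False, n_slices=1)
    return scene, clean


class TestSegmentRois:
    def test_noise_free_iou_against_ground_truth(self, concentric):
        scene, stack = concentric
        rois = rois_of(scene, stack)
        rois.validate()
        assert _iou(rois.oocyte.data, scene.masks["oocyte"]) >= 0.9
        assert _iou(rois.nucleus.data, scene.masks["nucleus"]) >= 0.9
        assert _iou(rois.bb.data, scene.masks["bb"]) >= 0.9
        assert _iou(rois.cytoplasm.data, scene.masks["cytoplasm"]) >= 0.9

    def test_uniform_dioc6_flags_bb_absent(self, concentric):
        scene, stack = concentric
        uniform = Image2D(
            np.where(boundary_of(stack).mask.data, 5.0, 0.0), CAL
        )
        rois = segment_rois(uniform, boundary_of(stack))
        assert not rois.bb.data.any()
        assert "bb_missing" in rois.flags

    def test_mutant_like_scene_invariants_hold(self):
        scene = make_scene(
            SceneParams(oocyte_diameter_um=120, nucleus_offset_um=18,
                        bb_diameter_um=28),
            seed=31, calibration=CAL,
        )
        stack = render_scene(scene)
        rois = rois_of(scene, stack)
        rois.validate()


class TestPerimeterBand:
    def _manual_rois(self, r_oocyte_um=50.0, r_nucleus_um=15.0, px=0.5):
        cal = PixelCalibration(xy_um_per_px=px)
        side = int(2.4 * r_oocyte_um / px)
        yy, xx = np.mgrid[0:side, 0:side]
        c = side / 2
        rr2 = (yy - c) ** 2 + (xx - c) ** 2
        oocyte = rr2 <= (r_oocyte_um / px) ** 2
        nucleus = rr2 <= (r_nucleus_um / px) ** 2
        from skimage.morphology import erosion, disk

        rim = oocyte & ~erosion(oocyte, disk(2))
        cyto = oocyte & ~nucleus
        empty = np.zeros_like(oocyte)
        return RoiSet(
            oocyte=BinaryMask(oocyte, cal),
            membrane_outline=BinaryMask(rim, cal),
            nucleus=BinaryMask(nucleus, cal),
            bb=BinaryMask(empty, cal),
            cytoplasm=BinaryMask(cyto, cal),
            calibration=cal,
        )

    def test_analytic_annulus_area(self):
        rois = self._manual_rois()
        band = perimeter_band(rois, bb_diameter_um=20.0)
        # annulus between r=50 and r=30 um, tolerance one pixel boundary band
        expected = np.pi * (50.0**2 - 30.0**2)
        tol = 2 * np.pi * (50.0 + 30.0) * 0.5 + 50
        assert abs(band.area_um2 - expected) <= tol

    def test_saturates_to_whole_cytoplasm(self):
        rois = self._manual_rois()
        band = perimeter_band(rois, bb_diameter_um=60.0)
        np.testing.assert_array_equal(band.data, rois.cytoplasm.data)

    def test_matches_bruteforce_distance_oracle(self, concentric):
        scene, stack = concentric
        rois = rois_of(scene, stack)
        band = perimeter_band(rois, bb_diameter_um=12.0)
        rim_pts = np.argwhere(rois.membrane_outline.data)
        cyto_pts = np.argwhere(rois.cytoplasm.data)
        d_px = 12.0 / CAL.xy_um_per_px
        # exhaustive nearest-rim distance per cytoplasm pixel
        from scipy.spatial import cKDTree

        dist, _ = cKDTree(rim_pts).query(cyto_pts)
        expected = np.zeros_like(band.data)
        sel = cyto_pts[dist <= d_px]
        expected[sel[:, 0], sel[:, 1]] = True
        np.testing.assert_array_equal(band.data, expected)

    def test_missing_bb_requires_explicit_diameter(self):
        rois = self._manual_rois()
        with pytest.raises(ValueError, match="cohort median"):
            perimeter_band(rois)


class TestDetectPuncta:
    def test_blank_channel_gives_no_puncta(self, concentric):
        scene, stack = concentric
        rois = rois_of(scene, stack)
        blank = Image2D(np.zeros(stack.data.shape[2:]), CAL)
        assert detect_puncta(blank, rois) == []

    def test_isolated_spots_counted_exactly(self, concentric):
        scene, stack = concentric
        rois = rois_of(scene, stack)
        rois.perimeter = perimeter_band(rois)
        data = np.zeros(stack.data.shape[2:])
        centers = [(60, 60), (90, 120), (130, 70), (150, 150), (100, 100)]
        yy, xx = np.mgrid[0 : data.shape[0], 0 : data.shape[1]]
        for cy, cx in centers:
            data += 10.0 * np.exp(-(((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * 1.2**2)))
        pts = detect_puncta(Image2D(data, CAL), rois)
        assert len(pts) == 5
        found = sorted(p.centroid for p in pts)
        for (fy, fx), (cy, cx) in zip(found, sorted(centers)):
            assert abs(fy - cy) <= 1 and abs(fx - cx) <= 1

    def test_poisson_rate_recovery(self):
        counts, expect = [], None
        for seed in range(15):
            scene = make_scene(
                SceneParams(oocyte_diameter_um=100, ck_rate_bb=0.0,
                            ck_rate_cortex=0.0),
                seed=40 + seed, calibration=CAL,
            )
            stack = render_scene(scene)
            rois = rois_of(scene, stack)
            rois.perimeter = perimeter_band(rois, bb_diameter_um=20.0)
            pts = detect_puncta(ck_image(stack), rois)
            lam_a = scene.params.ck_rate_cyto * scene.region_area_um2("cytoplasm")
            expect = lam_a
            counts.append(len(pts))
        assert abs(np.mean(counts) - expect) <= 3 * np.sqrt(expect)

    def test_min_area_filter_applies(self, concentric):
        scene, stack = concentric
        rois = rois_of(scene, stack)
        data = np.zeros(stack.data.shape[2:])
        data[100, 100] = 50.0  # single-pixel speck
        cfg = PunctaConfig(min_punctum_area_px=2, puncta_threshold=10.0)
        assert detect_puncta(Image2D(data, CAL), rois, cfg) == []


class TestDensityTable:
    def test_density_is_count_over_area(self, concentric):
        scene, stack = concentric
        rois = rois_of(scene, stack)
        rois.perimeter = perimeter_band(rois)
        pts = detect_puncta(ck_image(stack), rois)
        tab = compute_density_table(pts, rois, "oo1", "WT")
        for row in tab.itertuples():
            assert row.density_per_um2 == pytest.approx(
                row.puncta_count / row.region_area_um2
            )

    def test_zero_puncta_all_zero_density(self, concentric):
        scene, stack = concentric
        rois = rois_of(scene, stack)
        rois.perimeter = perimeter_band(rois)
        tab = compute_density_table([], rois, "oo1", "WT")
        assert (tab.density_per_um2 == 0).all()
        assert set(tab.region) == {"cytoplasm", "nucleus", "bb", "perimeter"}

    def test_count_conservation_over_partition(self, concentric):
        scene, stack = concentric
        rois = rois_of(scene, stack)
        rois.perimeter = perimeter_band(rois)
        pts = detect_puncta(ck_image(stack), rois)
        tab = compute_density_table(pts, rois, "oo1", "WT")
        partition = tab[tab.region.isin(["cytoplasm", "nucleus", "bb"])]
        assert partition.puncta_count.sum() == len(pts)


def synthetic_density_table(rng, n_wt=5, n_mut=5, bb_factor=4.0):
    rows = []
    for genotype, n in (("WT", n_wt), ("mutant", n_mut)):
        for i in range(n):
            base = rng.uniform(0.004, 0.006)
            for region, mult in (("cytoplasm", 1.0), ("nucleus", 0.2), ("bb", bb_factor)):
                rows.append(
                    {
                        "oocyte_id": f"{genotype}{i}",
                        "genotype": genotype,
                        "region": region,
                        "puncta_count": 0,
                        "region_area_um2": 1.0,
                        "density_per_um2": base * mult * rng.uniform(0.8, 1.2),
                    }
                )
    return pd.DataFrame(rows)


class TestAnova:
    def test_balanced_2x2_matches_hand_computed_sums_of_squares(self):
        # 2 regions x 2 genotypes, 3 replicates per cell
        cells = {
            ("cytoplasm", "WT"): [1.0, 2.0, 3.0],
            ("cytoplasm", "mutant"): [2.0, 3.0, 4.0],
            ("bb", "WT"): [5.0, 6.0, 7.0],
            ("bb", "mutant"): [9.0, 10.0, 11.0],
        }
        rows = [
            {"oocyte_id": f"{g}{i}", "genotype": g, "region": r,
             "puncta_count": 0, "region_area_um2": 1.0, "density_per_um2": v}
            for (r, g), vals in cells.items()
            for i, v in enumerate(vals)
        ]
        res = two_way_anova_tukey(pd.DataFrame(rows))
        y = np.array([v for vals in cells.values() for v in vals])
        grand = y.mean()
        # factor means
        m_region = {r: np.mean([v for (rr, g), vals in cells.items() for v in vals if rr == r])
                    for r in ("cytoplasm", "bb")}
        m_geno = {g: np.mean([v for (r, gg), vals in cells.items() for v in vals if gg == g])
                  for g in ("WT", "mutant")}
        ss_region = 6 * sum((m - grand) ** 2 for m in m_region.values())
        ss_geno = 6 * sum((m - grand) ** 2 for m in m_geno.values())
        cell_means = {k: np.mean(v) for k, v in cells.items()}
        ss_cells = 3 * sum(
            (cell_means[(r, g)] - grand) ** 2 for r in m_region for g in m_geno
        )
        ss_inter = ss_cells - ss_region - ss_geno
        ss_err = sum(
            (v - cell_means[k]) ** 2 for k, vals in cells.items() for v in vals
        )
        ms_err = ss_err / 8  # df = 12 - 4
        assert res.f_value("region") == pytest.approx(ss_region / 1 / ms_err)
        assert res.f_value("genotype") == pytest.approx(ss_geno / 1 / ms_err)
        assert res.f_value("region x genotype") == pytest.approx(ss_inter / 1 / ms_err)

    def test_zero_variance_gives_f_zero_p_one(self):
        rows = [
            {"oocyte_id": f"{g}{i}", "genotype": g, "region": r,
             "puncta_count": 0, "region_area_um2": 1.0, "density_per_um2": 2.5}
            for g in ("WT", "mutant") for r in ("cytoplasm", "bb") for i in range(3)
        ]
        res = two_way_anova_tukey(pd.DataFrame(rows))
        for factor in ("region", "genotype"):
            assert res.f_value(factor) == 0.0
            assert res.p_value(factor) == 1.0

    def test_tukey_adjusted_p_not_below_unadjusted_pooled_t(self):
        # the unadjusted comparison uses the same pooled error term Tukey
        # does; the studentized-range adjustment can only raise the p-value
        rng = np.random.default_rng(50)
        table = synthetic_density_table(rng)
        res = two_way_anova_tukey(table)
        df = table[table.region != "perimeter"]
        groups = (df["region"] + ":" + df["genotype"]).to_numpy()
        y = df["density_per_um2"].to_numpy()
        names, counts = np.unique(groups, return_counts=True)
        means = {g: y[groups == g].mean() for g in names}
        ss_within = sum(((y[groups == g] - means[g]) ** 2).sum() for g in names)
        df_err = len(y) - len(names)
        mse = ss_within / df_err
        for row in res.tukey.itertuples():
            n1 = (groups == row.group1).sum()
            n2 = (groups == row.group2).sum()
            se = np.sqrt(mse * (1 / n1 + 1 / n2))
            t = abs(means[row.group2] - means[row.group1]) / se
            p_unadj = 2 * stats.t.sf(t, df_err)
            assert float(getattr(row, "_4")) >= p_unadj - 1e-9  # 'p-adj'

    def test_single_genotype_falls_back_to_one_way(self):
        rng = np.random.default_rng(51)
        table = synthetic_density_table(rng, n_mut=0)
        res = two_way_anova_tukey(table)
        assert "single_genotype_one_way" in res.flags
        assert "region" in res.anova.index
        assert "genotype" not in res.anova.index

    def test_region_effect_detected_on_enriched_table(self):
        rng = np.random.default_rng(52)
        table = synthetic_density_table(rng, n_wt=7, n_mut=10)
        res = two_way_anova_tukey(table)
        assert res.p_value("region") < 0.01
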