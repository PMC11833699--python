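"""Dosimetry analysis: dose tables, energy flows, tPSF, profiles, and the
statistical machinery (Pearson, UPGMA, OLS, gated group comparison)."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nirdosim import (
    LabelAtlas,
    OpticalProperties,
    ProbabilityMaps,
    SimConfig,
    SourceSpec,
    SpectralLibrary,
    VolumeGrid,
    build_phantom,
    energy_flow,
    response_matrix,
    extract_tpsf,
    group_compare,
    hierarchical_cluster,
    linear_regression,
    pearson_matrix,
    penetration_rate,
    profile_along_ray,
    roi_dose,
    run_mc,
)

from conftest import pure_absorber_phantom, scattering_phantom


# -------------------------------------------------------------- UPGMA oracle

def brute_force_upgma(points: np.ndarray):
    """Exhaustive UPGMA: recompute all pairwise average distances each merge."""
    clusters = {i: [i] for i in range(len(points))}
    merges = []
    next_id = len(points)
    dist = {
        (i, j): float(np.linalg.norm(points[i] - points[j]))
        for i, j in itertools.combinations(range(len(points)), 2)
    }

    def cdist(a, b):
        return float(
            np.mean(
                [np.linalg.norm(points[i] - points[j]) for i in clusters[a] for j in clusters[b]]
            )
        )

    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            d = cdist(a, b)
            if best is None or d < best[0] - 1e-12:
                best = (d, a, b)
        d, a, b = best
        merges.append((a, b, d, len(clusters[a]) + len(clusters[b])))
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return merges


class TestClustering:
    def test_hand_worked_1d_case(self):
        """Points {0, 1, 5}: merge {0,1} at 1, then with {5} at (5+4)/2 = 4.5."""
        Z, _ = hierarchical_cluster(np.array([[0.0], [1.0], [5.0]]))
        assert Z[0][2] == pytest.approx(1.0)
        assert Z[1][2] == pytest.approx(4.5)
        assert set(Z[0][:2].astype(int)) == {0, 1}

    def test_identical_rows_merge_at_zero(self):
        Z, _ = hierarchical_cluster(np.array([[2.0, 3.0], [2.0, 3.0], [9.0, 9.0]]))
        assert Z[0][2] == 0.0

    def test_matches_brute_force_oracle(self, rng):
        """Merge heights and sizes equal the exhaustive recomputation on
        random instances of up to 6 rows."""
        for trial in range(20):
            n = int(rng.integers(2, 7))
            pts = rng.random((n, 3)) * 10
            Z, _ = hierarchical_cluster(pts)
            oracle = brute_force_upgma(pts)
            for row, (_, _, d, size) in zip(Z, oracle):
                assert row[2] == pytest.approx(d, abs=1e-9)
                assert int(row[3]) == size

    def test_flat_cut(self):
        pts = np.array([[0.0], [0.1], [5.0], [5.1]])
        _, flat = hierarchical_cluster(pts, n_clusters=2)
        assert flat[0] == flat[1] and flat[2] == flat[3] and flat[0] != flat[2]

    def test_nan_rows_rejected_with_names(self):
        m = pd.DataFrame(
            [[1.0, 2.0], [np.nan, 1.0]], index=["precentral", "insula"]
        )
        with pytest.raises(ValueError, match="insula"):
            hierarchical_cluster(m)


class TestPearson:
    def test_identical_and_reflected_rows(self):
        m = np.array([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [3.0, 2.0, 1.0]])
        c = pearson_matrix(m)
        assert c[0, 1] == pytest.approx(1.0)
        assert c[0, 2] == pytest.approx(-1.0)
        assert np.allclose(np.diag(c), 1.0)

    def test_hand_worked_half_correlation(self):
        """Rows (1,2,3) and (1,3,2) -> r = 0.5 by direct covariance arithmetic."""
        c = pearson_matrix(np.array([[1.0, 2.0, 3.0], [1.0, 3.0, 2.0]]))
        assert c[0, 1] == pytest.approx(0.5, abs=1e-9)

    def test_constant_row_flagged_zero(self):
        c = pearson_matrix(np.array([[1.0, 1.0, 1.0], [0.0, 1.0, 2.0]]))
        assert c[0, 1] == 0.0 and c[0, 0] == 1.0

    def test_single_column_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            pearson_matrix(np.array([[1.0], [2.0]]))


class TestRegression:
    def test_exact_fit(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        res = linear_regression(x, 2 * x)
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(0.0, abs=1e-12)
        assert res.r2 == pytest.approx(1.0)

    def test_hand_least_squares(self):
        """x=(0,1,2,3), y=(1,3,2,5): slope 1.1, intercept 1.1, R^2 = 6.05/8.75."""
        res = linear_regression([0, 1, 2, 3], [1, 3, 2, 5])
        assert res.slope == pytest.approx(1.1, abs=1e-9)
        assert res.intercept == pytest.approx(1.1, abs=1e-9)
        assert res.r2 == pytest.approx(6.05 / 8.75, abs=1e-9)
        assert res.r2 == pytest.approx(res.pearson_r**2, abs=1e-12)

    def test_slope_t_test_against_closed_form(self, rng):
        x = rng.random(12)
        y = 3 * x + rng.normal(0, 0.3, 12)
        res = linear_regression(x, y)
        # textbook t = r sqrt(n-2) / sqrt(1-r^2), two-tailed p from t(n-2)
        t = res.pearson_r * math.sqrt(10) / math.sqrt(1 - res.pearson_r**2)
        assert res.t_stat == pytest.approx(t, rel=1e-9)
        assert res.p_value == pytest.approx(2 * stats.t.sf(abs(t), 10), rel=1e-9)

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            linear_regression([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestGroupCompare:
    def test_identical_paired_samples(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        rep = group_compare(a, a.copy(), paired=True)
        assert rep.statistic == 0.0 and rep.p_value == 1.0

    def test_normal_samples_select_t_and_match_closed_form(self, rng):
        a = rng.normal(0, 1, 40)
        b = rng.normal(0.2, 1, 40)
        rep = group_compare(a, b)
        assert rep.test == "t"
        # pooled-variance two-sample t statistic, by hand
        sp = math.sqrt(((39) * a.var(ddof=1) + (39) * b.var(ddof=1)) / 78)
        t = (a.mean() - b.mean()) / (sp * math.sqrt(2 / 40))
        assert rep.statistic == pytest.approx(t, rel=1e-9)
        assert rep.p_value == pytest.approx(2 * stats.t.sf(abs(t), 78), rel=1e-9)

    def test_skewed_samples_select_wilcoxon(self, rng):
        a = rng.lognormal(0, 1.5, 60) ** 2
        b = rng.lognormal(0.2, 1.5, 60) ** 2
        rep = group_compare(a, b)
        assert rep.test == "wilcoxon_ranksum"
        assert "KS" in rep.reason or "Levene" in rep.reason

    def test_insufficient_n(self):
        with pytest.raises(ValueError, match="n >= 3"):
            group_compare([1.0, 2.0], [1.0, 2.0, 3.0])


# -------------------------------------------------------- simulation-backed

@pytest.fixture(scope="module")
def labeled_run():
    """Scattering cube with a two-region atlas and tissue maps + per-source run."""
    shape = (30, 30, 30)
    lib = SpectralLibrary(
        {
            "gray_matter": {810: OpticalProperties(0.02, 9.0, 0.89, 1.37)},
            "white_matter": {810: OpticalProperties(0.08, 40.0, 0.84, 1.38)},
        }
    )
    grid = VolumeGrid(shape)
    gm = np.zeros(shape)
    wm = np.zeros(shape)
    gm[:, :, :15] = 1.0
    wm[:, :, 15:] = 1.0
    pm = ProbabilityMaps(grid, {"gray_matter": gm, "white_matter": wm})
    phantom = build_phantom(pm, lib, [810])
    labels = np.zeros(shape, np.int32)
    labels[:15] = 1
    labels[15:] = 2
    atlas = LabelAtlas(grid, labels, {1: "left", 2: "right"})
    sources = [
        SourceSpec("disk", (0.0, 0.0, -16.0), (0.0, 0.0, 1.0), 810, radius=4.0),
        SourceSpec("disk", (0.0, -16.0, 0.0), (0.0, 1.0, 0.0), 810, radius=4.0),
    ]
    res = run_mc(
        phantom, sources, SimConfig(n_photons=8_000, seed=11, per_source=True)
    )
    return res, atlas, pm, sources, phantom


class TestRoiDose:
    def test_exhaustive_partition_sums_to_100(self, labeled_run):
        res, atlas, pm, sources, _ = labeled_run
        tab = roi_dose(res, atlas, pm, sources)
        regions = tab[tab["kind"] == "region"]
        assert regions["pct_of_absorbed"].sum() == pytest.approx(100.0, abs=0.01)
        tissues = tab[tab["kind"] == "tissue"]
        assert tissues["pct_of_absorbed"].sum() == pytest.approx(100.0, abs=0.01)

    def test_pct_of_launched_consistent(self, labeled_run):
        res, atlas, pm, sources, _ = labeled_run
        tab = roi_dose(res, atlas, pm, sources)
        regions = tab[tab["kind"] == "region"]
        assert regions["pct_of_launched"].sum() == pytest.approx(
            100 * res.absorbed.sum(), rel=1e-9
        )

    def test_empty_region_flagged(self, labeled_run):
        res, atlas, pm, sources, _ = labeled_run
        atlas2 = LabelAtlas(
            atlas.grid, atlas.labels, {**atlas.lookup, 9: "phantom_region"}
        )
        tab = roi_dose(res, atlas2, pm, sources).set_index("name")
        row = tab.loc["phantom_region"]
        assert row["pct_of_absorbed"] == 0.0 and bool(row["empty"])

    def test_grid_mismatch_rejected(self, labeled_run):
        res, atlas, pm, sources, _ = labeled_run
        small = LabelAtlas(
            VolumeGrid((5, 5, 5)), np.zeros((5, 5, 5), np.int32), {}
        )
        with pytest.raises(ValueError, match="grid"):
            roi_dose(res, small, None, sources)

    def test_penetration_rate_definition(self, labeled_run):
        res, atlas, pm, sources, _ = labeled_run
        tab = roi_dose(res, atlas, pm, sources)
        # this cube is entirely GM+WM, so everything "penetrates"
        assert penetration_rate(tab) == pytest.approx(1.0, abs=1e-6)


class TestEnergyFlow:
    def test_flow_conserves_and_matches_roi_dose(self, labeled_run):
        res, atlas, pm, sources, _ = labeled_run
        flow = energy_flow(res, atlas, pm, sources)
        # total flow equals total absorbed energy
        assert flow["energy_fraction"].sum() == pytest.approx(
            res.absorbed.sum(), abs=1e-9
        )
        # per-tissue marginals reproduce the dose table
        tab = roi_dose(res, atlas, pm, sources).set_index("name")
        for cls in ("gray_matter", "white_matter"):
            marg = flow[flow["tissue"] == cls]["energy_fraction"].sum()
            assert 100 * marg == pytest.approx(
                tab.loc[cls, "pct_of_launched"], abs=1e-9
            )

    def test_per_source_marginals(self, labeled_run):
        res, atlas, pm, sources, _ = labeled_run
        flow = energy_flow(res, atlas, pm, sources)
        for si, absorbed in enumerate(res.per_source_absorbed):
            marg = flow[flow["source"] == f"source_{si}"]["energy_fraction"].sum()
            assert marg == pytest.approx(absorbed.sum(), abs=1e-9)

    def test_missing_per_source_tallies_advises(self, labeled_run):
        _, atlas, pm, sources, phantom = labeled_run
        res2 = run_mc(phantom, sources, SimConfig(n_photons=500, seed=1))
        with pytest.raises(ValueError, match="per_source"):
            energy_flow(res2, atlas, pm, sources)

    def test_single_cell_toy_flow(self):
        """One source, one tissue, one region: a single flow = total absorbed."""
        phantom, pm = scattering_phantom(shape=(10, 10, 10))
        labels = np.ones((10, 10, 10), np.int32)
        atlas = LabelAtlas(phantom.grid, labels, {1: "all"})
        src = SourceSpec("disk", (0, 0, -6.0), (0, 0, 1.0), 810, radius=2.0)
        res = run_mc(phantom, [src], SimConfig(n_photons=2_000, seed=2, per_source=True))
        flow = energy_flow(res, atlas, pm, [src])
        inner = flow[(flow["tissue"] == "m") & (flow["region"] == "all")]
        assert len(inner) == 1
        assert inner["energy_fraction"].iloc[0] == pytest.approx(
            res.absorbed.sum(), abs=1e-9
        )


class TestResponseMatrix:
    def test_shape_order_and_nonnegativity(self, labeled_run):
        res, atlas, pm, sources, _ = labeled_run
        m = response_matrix(res, atlas)
        assert list(m.index) == ["left", "right"]  # atlas lookup order
        assert m.shape == (2, 2)
        assert (m.to_numpy() >= 0).all()

    def test_physical_scaling_linear(self, labeled_run):
        res, atlas, pm, sources, _ = labeled_run
        phys = response_matrix(res, atlas, physical=True)
        raw = response_matrix(res, atlas, physical=False)
        total_power = sum(s.power_mw for s in sources)
        np.testing.assert_allclose(phys.to_numpy(), raw.to_numpy() * total_power)

    def test_requires_per_source(self, labeled_run):
        _, atlas, pm, sources, phantom = labeled_run
        res2 = run_mc(phantom, sources, SimConfig(n_photons=500, seed=1))
        with pytest.raises(ValueError, match="per_source"):
            response_matrix(res2, atlas)


class TestTpsf:
    def test_gate_sum_equals_cw(self):
        phantom, _ = scattering_phantom(shape=(24, 24, 24))
        src = SourceSpec("disk", (0, 0, -13.0), (0, 0, 1.0), 810, radius=3.0)
        res = run_mc(phantom, [src], SimConfig(n_photons=3_000, seed=6, n_gates=6))
        roi = np.zeros((24, 24, 24), bool)
        roi[10:14, 10:14, 10:14] = True
        tpsf = extract_tpsf(res, roi)
        assert tpsf.sum() == pytest.approx(res.fluence[roi].mean(), abs=1e-9)

    def test_empty_roi_zero_series(self):
        phantom, _ = scattering_phantom(shape=(10, 10, 10))
        src = SourceSpec("disk", (0, 0, -6.0), (0, 0, 1.0), 810, radius=2.0)
        res = run_mc(phantom, [src], SimConfig(n_photons=500, seed=1, n_gates=3))
        tpsf = extract_tpsf(res, np.zeros((10, 10, 10), bool))
        assert tpsf.shape == (3,) and (tpsf == 0).all()

    def test_requires_gates(self):
        phantom, _ = scattering_phantom(shape=(10, 10, 10))
        src = SourceSpec("disk", (0, 0, -6.0), (0, 0, 1.0), 810, radius=2.0)
        res = run_mc(phantom, [src], SimConfig(n_photons=500, seed=1))
        with pytest.raises(ValueError, match="gates"):
            extract_tpsf(res, np.ones((10, 10, 10), bool))


class TestRayProfile:
    def test_homogeneous_constant_mueff(self):
        phantom, _ = scattering_phantom(mua=0.02, mus=10.0, g=0.9, shape=(30, 30, 30))
        prof = profile_along_ray(
            phantom, None, origin=(0, 0, -14.0), direction=(0, 0, 1.0), step_mm=1.0
        )
        expect = math.sqrt(3 * 0.02 * (0.02 + 1.0))
        np.testing.assert_allclose(prof.mueff, expect, rtol=1e-6)

    def test_two_layer_step_at_interface(self, two_tissue_library):
        shape = (10, 10, 30)
        a = np.zeros(shape)
        b = np.zeros(shape)
        a[:, :, :15] = 1.0
        b[:, :, 15:] = 1.0
        pm = ProbabilityMaps(VolumeGrid(shape), {"A": a, "B": b})
        phantom = build_phantom(pm, two_tissue_library, [810])
        prof = profile_along_ray(
            phantom, None, origin=(0, 0, -14.5), direction=(0, 0, 1.0), step_mm=1.0
        )
        jumps = np.flatnonzero(np.abs(np.diff(prof.mueff)) > 1e-6)
        assert len(jumps) == 1
        assert abs(jumps[0] - 14.5) <= 1.0  # transition within one voxel

    def test_absorber_fluence_monotone(self):
        phantom, _ = pure_absorber_phantom(mua=0.1)
        src = SourceSpec("disk", (0, 0, -16.0), (0, 0, 1.0), 810, radius=5.0)
        res = run_mc(phantom, [src], SimConfig(n_photons=20_000, seed=2, roulette=False))
        prof = profile_along_ray(
            phantom, res, origin=(0, 0, -14.0), direction=(0, 0, 1.0), step_mm=1.0
        )
        inside = prof.fluence_rate > 0
        assert np.all(np.diff(prof.fluence_rate[inside]) <= 1e-12)

    def test_zero_direction_rejected(self):
        phantom, _ = scattering_phantom(shape=(10, 10, 10))
        with pytest.raises(ValueError, match="nonzero"):
            profile_along_ray(phantom, None, (0, 0, 0), (0, 0, 0))
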