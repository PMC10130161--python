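"""Cross-G function, mixing score and pattern classification."""

import numpy as np
import pandas as pd
import pytest

from spatialtme import (
    PointPattern,
    Window,
    classify_pattern,
    cross_g,
    default_r_grid,
    empirical_cross_g,
    mixing_score,
    nearest_neighbor_distances,
    score_all,
    theoretical_poisson_g,
)

from conftest import CIRCLE_WINDOW


def brute_force_nn(reference, target):
    """O(n^2) oracle for nearest-neighbor distances (sqrt of summed squares,
    the same arithmetic the tree-based path uses, so equality is exact)."""
    out = []
    for r in reference:
        out.append(min(np.sqrt((r[0] - t[0]) ** 2 + (r[1] - t[1]) ** 2)
                       for t in target))
    return np.array(out)


def slow_border_g(reference, target, r_grid, window):
    """Independent reduced-sample cross-G implementation (loops, no trees)."""
    nn = brute_force_nn(reference, target)
    bdist = window.boundary_distance(reference)
    g = np.full(len(r_grid), np.nan)
    for i, r in enumerate(r_grid):
        keep = bdist >= r
        if keep.sum() == 0:
            break
        g[i] = np.mean(nn[keep] <= r)
    valid = ~np.isnan(g)
    g[valid] = np.maximum.accumulate(g[valid])
    return g


class TestNearestNeighborDistances:
    def test_three_four_five_triangle(self):
        d = nearest_neighbor_distances(np.array([[0.0, 0.0]]),
                                       np.array([[3.0, 4.0], [10.0, 0.0]]))
        assert d.tolist() == [5.0]

    def test_self_distance_excluded_when_reference_is_target(self):
        pts = np.array([[0.0, 0.0], [7.0, 0.0]])
        assert nearest_neighbor_distances(pts, pts).tolist() == [7.0, 7.0]

    def test_empty_target_signals_absent_phenotype(self):
        with pytest.raises(ValueError, match="absent"):
            nearest_neighbor_distances(np.array([[0.0, 0.0]]), np.empty((0, 2)))

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(17)
        ref, tgt = rng.random((50, 2)) * 900, rng.random((80, 2)) * 900
        np.testing.assert_allclose(nearest_neighbor_distances(ref, tgt),
                                   brute_force_nn(ref, tgt), rtol=0, atol=1e-12)


class TestEmpiricalCrossG:
    # reference points whose NN distances are exactly {2, 4, 6} um
    ref = np.array([[0.0, 0.0], [100.0, 0.0], [200.0, 0.0]])
    tgt = np.array([[2.0, 0.0], [104.0, 0.0], [206.0, 0.0]])

    def test_empirical_cdf_at_interior_radius(self):
        g = empirical_cross_g(self.ref, self.tgt, np.array([5.0]))
        assert g[0] == pytest.approx(2 / 3)

    def test_extreme_radii(self):
        g = empirical_cross_g(self.ref, self.tgt, np.array([1.0, 6.0, 50.0]))
        assert g[0] == 0.0 and g[1] == 1.0 and g[2] == 1.0

    def test_border_corrected_matches_slow_oracle(self, csr_core):
        cfg, core = csr_core
        win = cfg.window()
        ref = core.loc[core.phenotype == "CK+", ["x_um", "y_um"]].to_numpy()
        tgt = core.loc[core.phenotype == "CD3+", ["x_um", "y_um"]].to_numpy()
        r = np.linspace(0, 150, 151)
        fast = empirical_cross_g(ref, tgt, r, edge_correction="border", window=win)
        np.testing.assert_allclose(fast, slow_border_g(ref, tgt, r, win),
                                   rtol=0, atol=1e-12)

    def test_uncorrected_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(23)
        ref, tgt = rng.random((120, 2)) * 500, rng.random((150, 2)) * 500
        r = np.linspace(0, 100, 101)
        fast = empirical_cross_g(ref, tgt, r)
        slow = np.array([np.mean(brute_force_nn(ref, tgt) <= ri) for ri in r])
        np.testing.assert_array_equal(fast, slow)

    def test_curves_monotone_and_bounded(self, csr_core):
        cfg, core = csr_core
        win = cfg.window()
        ref = core.loc[core.phenotype == "CK+", ["x_um", "y_um"]].to_numpy()
        tgt = core.loc[core.phenotype == "CD3+", ["x_um", "y_um"]].to_numpy()
        for corr in ("none", "border"):
            g = empirical_cross_g(ref, tgt, np.linspace(0, 200, 201),
                                  edge_correction=corr, window=win)
            g = g[~np.isnan(g)]
            assert (np.diff(g) >= 0).all()
            assert ((g >= 0) & (g <= 1)).all()


class TestTheoreticalPoissonG:
    def test_zero_intensity_is_identically_zero(self):
        r = np.linspace(0, 100, 11)
        assert (theoretical_poisson_g(0.0, r) == 0.0).all()

    def test_zero_radius_is_zero_for_any_intensity(self):
        assert theoretical_poisson_g(250.0, np.array([0.0]))[0] == 0.0

    def test_half_life_radius(self):
        # lambda*pi*r^2 = ln 2  =>  G = 1/2
        lam_mm2 = 100.0
        r = np.sqrt(np.log(2) / (np.pi * lam_mm2 / 1e6))
        assert theoretical_poisson_g(lam_mm2, np.array([r]))[0] == pytest.approx(0.5)

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError):
            theoretical_poisson_g(-1.0, np.array([1.0]))


class TestMixingScore:
    r = np.linspace(0, 100, 101)

    def test_identical_curves_score_zero(self):
        g = theoretical_poisson_g(100.0, self.r)
        assert mixing_score(g, g, self.r) == 0.0

    def test_empty_empirical_curve_scores_100(self):
        g_theo = theoretical_poisson_g(100.0, self.r)
        assert mixing_score(np.zeros_like(self.r), g_theo, self.r) == 100.0

    def test_zero_intensity_score_undefined(self):
        zero = np.zeros_like(self.r)
        assert np.isnan(mixing_score(zero, zero, self.r))
        assert classify_pattern(float("nan")) == "NA"

    def test_score_invariant_under_rigid_motion(self, csr_core):
        cfg, core = csr_core
        win = cfg.window()
        ref = core.loc[core.phenotype == "CK+", ["x_um", "y_um"]].to_numpy()
        tgt = core.loc[core.phenotype == "CD3+", ["x_um", "y_um"]].to_numpy()
        res1 = cross_g(PointPattern(ref, win, "CK+"), PointPattern(tgt, win, "t"))
        theta = 1.1
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        shift = np.array([40.0, -260.0])
        c = np.array(win.center)
        win2 = Window.circle(tuple(c @ rot.T + shift), win.radius)
        res2 = cross_g(PointPattern(ref @ rot.T + shift, win2, "CK+"),
                       PointPattern(tgt @ rot.T + shift, win2, "t"))
        assert res2.score == pytest.approx(res1.score, abs=1e-9)


class TestClassifyPattern:
    @pytest.mark.parametrize("score,expected", [
        (0.0, "mixed"),
        (15.0, "unmixed"),
        (10.0, "mixed"),          # band boundary belongs to mixed
        (-10.0, "mixed"),
        (-25.0, "mixed (attraction)"),
        (10.0001, "unmixed"),
    ])
    def test_band_semantics(self, score, expected):
        assert classify_pattern(score) == expected


class TestScoreAll:
    def test_empty_included_list_gives_empty_table(self, small_cohort_phenotyped):
        _, cells, _, pheno = small_cohort_phenotyped
        out = score_all(cells, pheno, [], window_spec=CIRCLE_WINDOW)
        assert out.empty and "score" in out.columns

    def test_low_count_cores_marked_na(self):
        cells = pd.DataFrame({
            "subject_id": "s", "core_id": "c", "panel": 1,
            "x_um": np.linspace(10, 900, 12), "y_um": np.linspace(10, 900, 12)})
        pheno = pd.DataFrame({"CK+": [True] * 12, "CD3+": [False] * 10 + [True] * 2})
        out = score_all(cells, pheno, ["CD3+"], window_spec=CIRCLE_WINDOW)
        assert out["pattern"].tolist() == ["NA"]
        assert np.isnan(out["score"].iloc[0])

    def test_default_r_grid_caps_at_200um(self):
        assert default_r_grid(1.0)[-1] == 200.0
        assert default_r_grid(100.0)[-1] < 200.0
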