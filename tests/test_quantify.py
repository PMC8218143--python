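"""Bundle metrics, ipsi/contra normalization, exact Wilcoxon signed-rank."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from petdti.quantify import (BundleMetrics, build_report, bundle_metrics,
                             normalize_ipsi_contra, wilcoxon_signed_rank)
from petdti.tracking import FiberBundle, Streamline
from petdti.volume import Volume3D

from conftest import centered_affine


def line_streamline(start, direction, n_points, step=1.0):
    direction = np.asarray(direction, dtype=float)
    direction /= np.linalg.norm(direction)
    pts = np.asarray(start, dtype=float) + step * direction * np.arange(n_points)[:, None]
    return Streamline(pts)


class TestBundleMetrics:
    def test_two_segment_equal_weight_fa(self):
        # FA field: 0.4 for x < 0, 0.8 for x >= 0 on a 1 mm grid; a
        # streamline with one segment in each region averages to 0.6
        shape = (20, 8, 8)
        aff = centered_affine(shape, 1.0)
        fa_data = np.zeros(shape)
        idx = np.indices(shape)[0]
        x_world = aff[0, 0] * idx + aff[0, 3]
        fa_data[x_world < 0] = 0.4
        fa_data[x_world >= 0] = 0.8
        fa = Volume3D(fa_data, aff)
        sl = Streamline(np.array([[-4.0, 0.0, 0.0], [-2.0, 0.0, 0.0],
                                  [4.0, 0.0, 0.0]]))  # midpoints at -3, +1
        m = bundle_metrics(FiberBundle([sl]), fa)
        # weights 2 mm and 6 mm: (2*0.4 + 6*0.8) / 8 = 0.7
        assert m.mean_fa == pytest.approx(0.7, abs=1e-6)

    def test_identical_streamlines_definition_arithmetic(self):
        # odd grid sizes put voxel centers on integer world coordinates, so
        # every streamline point maps to a unique unambiguous voxel
        shape = (41, 9, 9)
        aff = centered_affine(shape, 1.0)
        fa = Volume3D(np.full(shape, 0.5), aff)
        sl = line_streamline([-15.0, 0.0, 0.0], [1, 0, 0], 31)  # 30 mm
        bundle = FiberBundle([Streamline(sl.points.copy()) for _ in range(10)])
        m = bundle_metrics(bundle, fa)
        assert m.fiber_count == 10
        assert m.mean_length == pytest.approx(30.0)
        # 31 unique 1 mm^3 voxels swept / 30 mm mean length
        assert m.mean_cs == pytest.approx(31.0 / 30.0, abs=1e-9)

    def test_uniform_fa_field_returns_constant(self, rng):
        shape = (16, 16, 16)
        fa = Volume3D(np.full(shape, 0.37), centered_affine(shape, 1.0))
        sls = [line_streamline(rng.uniform(-4, 4, 3), rng.normal(size=3), 8)
               for _ in range(5)]
        m = bundle_metrics(FiberBundle(sls), fa)
        assert m.mean_fa == pytest.approx(0.37, abs=1e-9)

    def test_empty_bundle_flagged_undefined(self):
        fa = Volume3D(np.zeros((4, 4, 4)), np.eye(4))
        m = bundle_metrics(FiberBundle([]), fa)
        assert not m.defined
        assert np.isnan(m.mean_fa)


class TestNormalization:
    def test_identical_bundles_give_unity(self):
        m = BundleMetrics(50, 40.0, 0.6, 2.0)
        ratios = normalize_ipsi_contra(m, m)
        assert all(v == pytest.approx(1.0) for v in ratios.values())

    def test_count_ratio(self):
        ipsi = BundleMetrics(50, 40.0, 0.6, 2.0)
        contra = BundleMetrics(100, 40.0, 0.6, 2.0)
        assert normalize_ipsi_contra(ipsi, contra)["fiber_count"] == pytest.approx(0.5)

    def test_undefined_contralateral_flagged(self):
        ipsi = BundleMetrics(50, 40.0, 0.6, 2.0)
        ratios = normalize_ipsi_contra(ipsi, BundleMetrics.undefined())
        assert all(np.isnan(v) for v in ratios.values())


def brute_force_wilcoxon(diffs):
    """Literal enumeration of all 2^n sign assignments (the oracle)."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(d)
    ws = []
    for signs in itertools.product([0, 1], repeat=n):
        ws.append((ranks * np.asarray(signs)).sum())
    ws = np.asarray(ws)
    p_le = (ws <= w_obs + 1e-9).mean()
    p_ge = (ws >= w_obs - 1e-9).mean()
    return w_obs, min(1.0, 2 * min(p_le, p_ge))


class TestWilcoxon:
    def test_three_positive_differences(self):
        res = wilcoxon_signed_rank([2.0, 3.0, 4.0], [1.0, 1.0, 1.0], mode="exact")
        assert res.statistic == 6.0
        assert res.pvalue == pytest.approx(0.25)

    def test_tied_opposite_differences(self):
        res = wilcoxon_signed_rank([1.0, 0.0], [0.0, 1.0], mode="exact")
        assert res.pvalue == pytest.approx(1.0)

    def test_all_zero_differences_flagged(self):
        res = wilcoxon_signed_rank([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert not res.defined
        assert res.n_zeros_dropped == 3

    def test_zero_differences_dropped(self):
        res = wilcoxon_signed_rank([1.0, 5.0, 2.0], [1.0, 1.0, 1.0], mode="exact")
        assert res.n_used == 2
        assert res.n_zeros_dropped == 1

    @pytest.mark.parametrize("n", range(2, 11))
    def test_exact_matches_enumeration(self, n, rng):
        for _ in range(3):
            a = rng.normal(size=n)
            b = rng.normal(size=n)
            res = wilcoxon_signed_rank(a, b, mode="exact")
            w_ref, p_ref = brute_force_wilcoxon(a - b)
            assert res.statistic == pytest.approx(w_ref)
            assert res.pvalue == pytest.approx(p_ref, abs=1e-12)

    def test_exact_matches_enumeration_with_ties(self, rng):
        for _ in range(5):
            a = rng.integers(0, 4, size=8).astype(float)
            b = rng.integers(0, 4, size=8).astype(float)
            if np.all(a == b):
                continue
            res = wilcoxon_signed_rank(a, b, mode="exact")
            _, p_ref = brute_force_wilcoxon(a - b)
            assert res.pvalue == pytest.approx(p_ref, abs=1e-12)

    def test_agrees_with_scipy_exact(self, rng):
        a = rng.normal(size=12)
        b = rng.normal(size=12)
        res = wilcoxon_signed_rank(a, b, mode="exact")
        ref = stats.wilcoxon(a, b, mode="exact", alternative="two-sided")
        assert res.pvalue == pytest.approx(ref.pvalue, abs=1e-12)

    def test_normal_approx_close_to_exact_at_n15(self, rng):
        # across many draws the approximation is close; individual draws can
        # deviate a bit more (no continuity correction by design)
        diffs = []
        for _ in range(20):
            a = rng.normal(size=15)
            b = rng.normal(size=15)
            p_exact = wilcoxon_signed_rank(a, b, mode="exact").pvalue
            p_norm = wilcoxon_signed_rank(a, b, mode="normal_approx").pvalue
            diffs.append(abs(p_exact - p_norm))
        assert np.median(diffs) < 0.03
        assert max(diffs) < 0.06

    def test_exact_mode_size_limit(self, rng):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank(rng.normal(size=30), rng.normal(size=30),
                                 mode="exact")


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.lists(st.floats(-5, 5), min_size=2, max_size=9),
       st.integers(0, 2 ** 31 - 1))
def test_wilcoxon_pvalue_valid_and_symmetric(diffs, seed):
    """p in (0, 1]; swapping the samples leaves the two-sided p unchanged."""
    a = np.asarray(diffs)
    b = np.zeros_like(a)
    if np.all(a == 0):
        return
    r1 = wilcoxon_signed_rank(a, b, mode="exact")
    r2 = wilcoxon_signed_rank(b, a, mode="exact")
    assert 0 < r1.pvalue <= 1
    assert r1.pvalue == pytest.approx(r2.pvalue, abs=1e-12)


class TestReport:
    def _metrics(self, scale=1.0):
        return {
            ("ipsilateral", 3.0): [BundleMetrics(10, 20.0, 0.5 * scale, 1.0),
                                   BundleMetrics(12, 22.0, 0.55 * scale, 1.1)],
            ("contralateral", 3.0): [BundleMetrics(20, 40.0, 0.7, 2.0),
                                     BundleMetrics(21, 41.0, 0.72, 2.1)],
            ("ipsilateral", 15.0): [BundleMetrics(18, 35.0, 0.65, 1.8),
                                    BundleMetrics(19, 36.0, 0.66, 1.9)],
            ("contralateral", 15.0): [BundleMetrics(20, 40.0, 0.7, 2.0),
                                      BundleMetrics(21, 41.0, 0.72, 2.1)],
        }

    def test_ratio_table_and_tests(self):
        rep = build_report(self._metrics())
        assert len(rep.ratios) == 4  # 2 subjects x 2 distances
        assert set(rep.tests) == {"fiber_count", "mean_length", "mean_fa", "mean_cs"}
        flags = rep.deficit_flags()
        assert flags["mean_fa"].all()  # all ratios < 1 by construction

    def test_identical_sides_give_unity_and_p_one(self):
        m = {("ipsilateral", d): [BundleMetrics(10, 20.0, 0.5, 1.0)] * 3
             for d in (3.0, 9.0)}
        m.update({("contralateral", d): [BundleMetrics(10, 20.0, 0.5, 1.0)] * 3
                  for d in (3.0, 9.0)})
        rep = build_report(m)
        assert np.allclose(rep.ratios[["fiber_count", "mean_fa"]].values, 1.0)
        for per in rep.tests.values():
            for res in per.values():
                assert not res.defined or res.pvalue == pytest.approx(1.0)

    def test_single_distance_skips_tests(self):
        m = {("ipsilateral", 3.0): BundleMetrics(10, 20.0, 0.5, 1.0),
             ("contralateral", 3.0): BundleMetrics(20, 40.0, 0.7, 2.0)}
        rep = build_report(m)
        assert rep.tests == {}
        assert any("single distance" in n for n in rep.notes)

    def test_json_round_trip(self):
        import json
        rep = build_report(self._metrics())
        payload = json.loads(rep.to_json())
        assert payload["alpha"] == 0.05
        assert len(payload["ratios"]) == 4

    def test_missing_side_rejected(self):
        with pytest.raises(ValueError, match="side"):
            build_report({("ipsilateral", 3.0): BundleMetrics(1, 1.0, 0.5, 1.0)})
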