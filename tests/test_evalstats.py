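"""Dice metrics, pooled aggregation, paired testing, and report tables."""

import itertools

import numpy as np
import pytest

from stagedseg.caseio import GeometryError
from stagedseg.evalstats import (
    agg_dsc,
    count_islands,
    dsc,
    evaluate_cases,
    report,
    wilcoxon_paired,
)
from tests.conftest import make_labelmap


def _dsc_bruteforce(pred, ref, label):
    """Independent set-based voxel counting."""
    p = {tuple(i) for i in np.argwhere(np.asarray(pred) == label)}
    r = {tuple(i) for i in np.argwhere(np.asarray(ref) == label)}
    if not p and not r:
        return 1.0
    return 2 * len(p & r) / (len(p) + len(r))


def _wilcoxon_exact_bruteforce(a, b):
    """Exact two-sided p by enumerating every sign assignment of the ranks."""
    d = np.asarray(a, float) - np.asarray(b, float)
    d = d[d != 0]
    n = len(d)
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
    w_obs = ranks[d > 0].sum()
    total = ranks.sum()
    lo, hi = min(w_obs, total - w_obs), max(w_obs, total - w_obs)
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for s, r in zip(signs, ranks) if s)
        if w <= lo or w >= hi:
            count += 1
    return count / 2**n


class TestDsc:
    def test_identity_and_disjoint(self):
        a = np.zeros((4, 4, 4), dtype=np.int16)
        a[:2] = 1
        b = np.zeros_like(a)
        b[2:] = 1
        la, lb = make_labelmap(a), make_labelmap(b)
        assert dsc(la, la, 1).value == 1.0
        assert dsc(la, lb, 1).value == 0.0

    def test_hand_built_counts(self):
        pred = np.zeros((4, 4, 4), dtype=np.int16)
        ref = np.zeros_like(pred)
        pred[0, 0, :3] = 1  # |P| = 3
        ref[0, 0, 1:4] = 1  # |R| = 3, intersection = 2
        got = dsc(make_labelmap(pred), make_labelmap(ref), 1)
        assert got.value == pytest.approx(2 * 2 / 6)

    def test_both_empty_flagged(self):
        z = make_labelmap(np.zeros((3, 3, 3), dtype=np.int16))
        got = dsc(z, z, 2)
        assert got.value == 1.0 and got.both_empty

    def test_geometry_mismatch(self):
        with pytest.raises(GeometryError):
            dsc(make_labelmap(np.zeros((3, 3, 3), dtype=np.int16)),
                make_labelmap(np.zeros((4, 4, 4), dtype=np.int16)), 1)

    def test_matches_bruteforce_on_random_grids(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            shape = tuple(rng.integers(3, 7, size=3))
            p = make_labelmap(rng.integers(0, 3, size=shape).astype(np.int16))
            r = make_labelmap(rng.integers(0, 3, size=shape).astype(np.int16))
            for label in (1, 2):
                assert dsc(p, r, label).value == pytest.approx(
                    _dsc_bruteforce(p.labels, r.labels, label), abs=1e-12
                )


class TestAggDsc:
    def test_single_pair_reduces_to_dsc(self):
        rng = np.random.default_rng(1)
        p = make_labelmap(rng.integers(0, 3, size=(5, 5, 5)).astype(np.int16))
        r = make_labelmap(rng.integers(0, 3, size=(5, 5, 5)).astype(np.int16))
        assert agg_dsc([(p, r)], 1).value == pytest.approx(dsc(p, r, 1).value)

    def test_robustness_to_single_miss(self):
        """Pooled Dice shrugs off an all-miss case that halves the mean DSC."""
        pa = np.zeros((4, 4, 4), dtype=np.int16)
        ra = np.zeros_like(pa)
        pa[0, 0, :3] = 1
        ra[0, 0, 1:4] = 1  # case A: inter 2, |P| 3, |R| 3
        pb = np.zeros_like(pa)
        rb = np.zeros_like(pa)
        pb[1, 1, 0] = 1
        rb[2, 2, 0] = 1  # case B: disjoint single voxels
        pairs = [(make_labelmap(pa), make_labelmap(ra)), (make_labelmap(pb), make_labelmap(rb))]
        assert agg_dsc(pairs, 1).value == pytest.approx(2 * 2 / (4 + 4))
        per_case = np.mean([dsc(p, r, 1).value for p, r in pairs])
        assert per_case == pytest.approx((2 / 3 + 0.0) / 2)

    def test_perfect_agreement(self):
        rng = np.random.default_rng(2)
        pairs = []
        for _ in range(3):
            m = make_labelmap(rng.integers(0, 3, size=(4, 4, 4)).astype(np.int16))
            pairs.append((m, m))
        assert agg_dsc(pairs, 1).value == 1.0

    def test_matches_pooled_bruteforce_on_random_pairs(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            pairs = []
            inter = size = 0
            for _ in range(rng.integers(1, 5)):
                shape = tuple(rng.integers(3, 6, size=3))
                p = rng.integers(0, 3, size=shape).astype(np.int16)
                r = rng.integers(0, 3, size=shape).astype(np.int16)
                inter += len({tuple(i) for i in np.argwhere(p == 2)} & {tuple(i) for i in np.argwhere(r == 2)})
                size += (p == 2).sum() + (r == 2).sum()
                pairs.append((make_labelmap(p), make_labelmap(r)))
            want = 1.0 if size == 0 else 2 * inter / size
            assert agg_dsc(pairs, 2).value == pytest.approx(want, abs=1e-12)

    def test_volume_weighting_property(self):
        """Tiling one case x8 leaves mean per-case DSC unchanged but pulls
        the pooled score toward that case."""
        pa = np.zeros((4, 4, 4), dtype=np.int16)
        ra = np.zeros_like(pa)
        pa[0, 0, :2] = 1
        ra[0, 0, :2] = 1  # perfect case
        pb = np.zeros_like(pa)
        rb = np.zeros_like(pa)
        pb[0, 0, 0] = 1
        rb[1, 1, 1] = 1  # zero case
        small = [(make_labelmap(pa), make_labelmap(ra)), (make_labelmap(pb), make_labelmap(rb))]
        big_b_p = make_labelmap(np.tile(pb, (2, 2, 2)))
        big_b_r = make_labelmap(np.tile(rb, (2, 2, 2)))
        tiled = [small[0], (big_b_p, big_b_r)]
        mean_small = np.mean([dsc(p, r, 1).value for p, r in small])
        mean_tiled = np.mean([dsc(p, r, 1).value for p, r in tiled])
        assert mean_small == pytest.approx(mean_tiled)
        assert agg_dsc(tiled, 1).value < agg_dsc(small, 1).value  # pulled toward the zero case


class TestWilcoxon:
    def test_identical_samples_degenerate(self):
        res = wilcoxon_paired([1, 2, 3, 4, 5, 6], [1, 2, 3, 4, 5, 6])
        assert res.degenerate and not res.significant

    def test_constant_shift_minimal_p(self):
        a = np.arange(8, dtype=float)
        res = wilcoxon_paired(a + 0.5, a)
        assert res.p_value == pytest.approx(2 / 2**8)
        assert res.significant

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_exact_p_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 11))
        b = rng.normal(size=n)
        a = b + rng.normal(0.3, 1.0, size=n)
        # avoid ties and zeros so the exact null applies
        res = wilcoxon_paired(a, b)
        want = _wilcoxon_exact_bruteforce(a, b)
        assert res.p_value == pytest.approx(want, abs=1e-12)

    @pytest.mark.parametrize("seed", [10, 11, 12])
    def test_untied_case_matches_scipy_exact(self, seed):
        """Independent cross-check against scipy's exact method (valid without ties)."""
        from scipy import stats as sps

        rng = np.random.default_rng(seed)
        b = rng.normal(size=9)
        a = b + rng.normal(0.2, 1.0, size=9)
        res = wilcoxon_paired(a, b)
        ref = sps.wilcoxon(a, b, zero_method="wilcox", method="exact")
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            wilcoxon_paired([1, 2], [1, 2, 3])


class TestEvaluateAndReport:
    def _fake_results(self, rng, n_cases=8, shift=0.0):
        preds, refs = {}, {}
        for i in range(n_cases):
            ref = rng.integers(0, 3, size=(6, 6, 6)).astype(np.int16)
            pred = ref.copy()
            # degrade a fraction of foreground voxels proportional to shift
            fg = np.argwhere(ref > 0)
            k = int(shift * len(fg))
            for j in range(k):
                pred[tuple(fg[j])] = 0
            preds[f"c{i}"] = make_labelmap(pred)
            refs[f"c{i}"] = make_labelmap(ref)
        return preds, refs

    def test_structure_and_scaling(self):
        rng = np.random.default_rng(5)
        preds, refs = self._fake_results(rng)
        res = evaluate_cases(preds, refs)
        assert res.n_cases == 8
        assert res.aggregated["avg_aggDSC"] == pytest.approx(
            (res.aggregated["aggDSC_GTVp"] + res.aggregated["aggDSC_GTVn"]) / 2
        )
        tables = report({"run": res})
        agg = tables["aggdsc"]
        assert set(agg.columns) >= {"config", "best_GTVp", "best_GTVn", "best_avg",
                                    "final_GTVp", "final_GTVn", "final_avg"}
        assert agg.loc[0, "final_avg"] == pytest.approx(100 * res.aggregated["avg_aggDSC"], abs=0.01)

    def test_identical_configs_no_star(self):
        rng = np.random.default_rng(6)
        preds, refs = self._fake_results(rng)
        res = evaluate_cases(preds, refs)
        tables = report({"a": res, "b": res}, comparisons=[("a", "b")])
        assert tables["significance"].loc[0, "star"] == ""

    def test_uniform_degradation_earns_star(self):
        rng = np.random.default_rng(7)
        preds, refs = self._fake_results(rng)
        worse_preds, _ = self._fake_results(np.random.default_rng(7), shift=0.5)
        good = evaluate_cases(preds, refs)
        bad = evaluate_cases(worse_preds, refs)
        tables = report({"bad": bad, "good": good}, comparisons=[("bad", "good")])
        assert tables["significance"].loc[0, "star"] == "*"

    def test_mismatched_case_sets_rejected(self):
        rng = np.random.default_rng(8)
        preds, refs = self._fake_results(rng, n_cases=4)
        with pytest.raises(ValueError, match="differ"):
            evaluate_cases({k: v for k, v in list(preds.items())[:3]}, refs)


class TestIslandCounter:
    def test_detects_components_outside_prior(self):
        pred = np.zeros((20, 20, 20), dtype=np.int16)
        prior = np.zeros_like(pred)
        prior[4:8, 4:8, 4:8] = 1
        pred[5:7, 5:7, 5:7] = 1  # inside the prior
        pred[14:16, 14:16, 14:16] = 2  # island
        pred[0:2, 17:19, 0:2] = 1  # second island
        assert count_islands(make_labelmap(pred), make_labelmap(prior)) == 2

    def test_no_islands_when_prediction_stays_inside(self):
        pred = np.zeros((10, 10, 10), dtype=np.int16)
        prior = np.zeros_like(pred)
        prior[2:8, 2:8, 2:8] = 1
        pred[3:6, 3:6, 3:6] = 1
        assert count_islands(make_labelmap(pred), make_labelmap(prior)) == 0
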