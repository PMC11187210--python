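"""Cross-omics matching, recall, DiMA and dominance classes."""

import numpy as np
import pandas as pd
import pytest

from crossmodulon.matching import (
    DiMAResult,
    MatchedPair,
    classify_dominance,
    compute_recall,
    dima,
    dimm_table,
    match_components,
    matched_subset,
    recall_quadrant,
)


def _mats(rng, n=100, k=4):
    genes = [f"g{i}" for i in range(n)]
    M = pd.DataFrame(
        rng.normal(0, 1, (n, k)), index=genes, columns=[f"c{j}" for j in range(k)]
    )
    return M


def _with_correlation(v, r, rng):
    """A vector with exact empirical Pearson correlation r to v."""
    noise = rng.normal(0, 1, v.size)
    noise = noise - noise.mean()
    v0 = v - v.mean()
    noise -= (noise @ v0) / (v0 @ v0) * v0
    return r * v0 / v0.std() + np.sqrt(1 - r**2) * noise / noise.std()


class TestMatchComponents:
    def test_identity_decomposition_self_matches(self, rng):
        M = _mats(rng)
        pairs = match_components(M, M.copy())
        assert len(pairs) == M.shape[1]
        for pair in pairs:
            assert pair.ti_indices[0] == pair.pi_index
            assert pair.pearson_r[pair.ti_indices[0]] == pytest.approx(1.0)

    @pytest.mark.parametrize("r,matched", [(0.24, False), (0.26, True)])
    def test_threshold_boundary(self, r, matched, rng):
        v = rng.normal(0, 1, 200)
        w = _with_correlation(v, r, rng)
        M_t = pd.DataFrame({"t0": v}, index=[f"g{i}" for i in range(200)])
        M_p = pd.DataFrame({"p0": w}, index=[f"g{i}" for i in range(200)])
        pairs = match_components(M_t, M_p, r_min=0.25)
        assert bool(pairs) is matched

    def test_negative_correlation_matches_by_magnitude(self, rng):
        v = rng.normal(0, 1, 200)
        M_t = pd.DataFrame({"t0": v}, index=[f"g{i}" for i in range(200)])
        M_p = pd.DataFrame({"p0": -v}, index=[f"g{i}" for i in range(200)])
        (pair,) = match_components(M_t, M_p)
        assert pair.pearson_r["t0"] == pytest.approx(-1.0)

    def test_lumped_module_matches_both_sources(self, rng):
        genes = [f"g{i}" for i in range(300)]
        t0 = np.zeros(300)
        t1 = np.zeros(300)
        t0[:30] = rng.uniform(0.5, 1, 30)
        t1[40:70] = rng.uniform(0.5, 1, 30)
        M_t = pd.DataFrame({"t0": t0, "t1": t1}, index=genes)
        M_p = pd.DataFrame({"p0": t0 + t1}, index=genes)
        (pair,) = match_components(M_t, M_p)
        assert set(pair.ti_indices) == {"t0", "t1"}
        assert all(abs(r) >= 0.25 for r in pair.pearson_r.values())

    def test_too_few_shared_features_rejected(self, rng):
        M_t = pd.DataFrame({"t0": [1.0, 2.0]}, index=["a", "b"])
        M_p = pd.DataFrame({"p0": [1.0, 2.0]}, index=["a", "b"])
        with pytest.raises(ValueError, match="shared features"):
            match_components(M_t, M_p)


class TestRecall:
    @pytest.mark.parametrize(
        "pi,ti,expected",
        [
            (set(range(8)), set(range(4)) | set(range(100, 112)), (0.5, 0.25)),
            (set("abc"), set("abc"), (1.0, 1.0)),
            (set("abc"), set("xyz"), (0.0, 0.0)),
        ],
    )
    def test_arithmetic(self, pi, ti, expected):
        pr, tr, both = compute_recall(pi, ti)
        assert (pr, tr) == pytest.approx(expected)
        assert len(both) <= min(len(pi), len(ti))

    def test_empty_side_gives_nan(self):
        pr, tr, _ = compute_recall(set(), {"a"})
        assert np.isnan(pr) and tr == 0.0

    def test_quadrants(self):
        assert recall_quadrant(0.9, 0.8) == "high/high"
        assert recall_quadrant(0.1, 0.2) == "low/low"
        assert recall_quadrant(0.9, 0.1) == "high-pi/low-ti"


def _activity_frames(ti_vals, pi_vals):
    conds = [f"c{i}" for i in range(len(ti_vals))]
    A_t = pd.DataFrame([ti_vals], index=["t0"], columns=conds)
    A_p = pd.DataFrame([pi_vals], index=["p0"], columns=conds)
    meta = pd.DataFrame(
        {
            "sample_id": conds,
            "condition_id": conds,
            "replicate": 1,
            "batch": "b0",
            "is_reference": [c == "c0" for c in conds],
        }
    )
    pair = MatchedPair(pi_index="p0", ti_indices=["t0"], pearson_r={"t0": 1.0})
    return pair, A_t, A_p, meta


class TestDiMA:
    def test_identical_series_no_differentials(self, rng):
        v = rng.laplace(0, 1, 30)
        pair, A_t, A_p, meta = _activity_frames(v, v)
        res = dima(pair, A_t, A_p, meta, meta)
        assert res.differential == []
        assert res.correlation == pytest.approx(1.0)
        assert res.dominance == "neutral"

    def test_planted_shift_flags_exactly_those_conditions(self, rng):
        v = rng.laplace(0, 1, 50)
        shifted = v.copy()
        band = 1.5
        target = [3, 11, 25, 38, 44]
        shifted[target] = v[target] + 5 * band
        pair, A_t, A_p, meta = _activity_frames(v, shifted)
        res = dima(pair, A_t, A_p, meta, meta, band=band, standardize=False)
        assert set(res.differential) == {f"c{i}" for i in target}

    def test_infinite_band_flags_nothing(self, rng):
        v = rng.laplace(0, 1, 30)
        pair, A_t, A_p, meta = _activity_frames(v, v + rng.normal(0, 5, 30))
        res = dima(pair, A_t, A_p, meta, meta, band=np.inf)
        assert res.differential == []

    def test_replicate_averaging(self, rng):
        v = np.array([1.0, 2.0, 3.0])
        conds = ["c0", "c0", "c1", "c1", "c2", "c2"]
        samples = [f"s{i}" for i in range(6)]
        A = pd.DataFrame(
            [[0.9, 1.1, 1.8, 2.2, 2.5, 3.5]], index=["t0"], columns=samples
        )
        meta = pd.DataFrame(
            {
                "sample_id": samples,
                "condition_id": conds,
                "replicate": [1, 2] * 3,
                "batch": "b0",
                "is_reference": [c == "c0" for c in conds],
            }
        )
        from crossmodulon.matching import _replicate_average

        avg = _replicate_average(A, meta)
        assert avg.loc["t0"].tolist() == pytest.approx(v.tolist())

    def test_too_few_matched_conditions_rejected(self, rng):
        pair, A_t, A_p, meta = _activity_frames([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ValueError, match="matched"):
            dima(pair, A_t, A_p, meta, meta)


class TestDominance:
    def _result(self, ti, pi, differential):
        conds = [f"c{i}" for i in range(len(ti))]
        ti_s = pd.Series(ti, index=conds)
        pi_s = pd.Series(pi, index=conds)
        return DiMAResult(
            conditions=conds,
            ti_activity=ti_s,
            pi_activity=pi_s,
            differential=differential,
            correlation=0.5,
            band=1.5,
            diff_std=pi_s - ti_s,
        )

    def test_all_ti_side_is_transcriptome_dominant(self):
        ti = [0.0] * 10 + [5.0, 6.0, 7.0]
        pi = [0.0] * 13
        res = self._result(ti, pi, ["c10", "c11", "c12"])
        assert classify_dominance(res) == "transcriptome-dominant"

    def test_no_differentials_is_neutral(self):
        res = self._result([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [])
        assert classify_dominance(res) == "neutral"

    def test_axis_exchange_swaps_label(self):
        ti = [0.0] * 10 + [5.0, 6.0, 7.0]
        pi = [0.1, -0.1] * 5 + [0.0, 0.0, 0.0]
        res = self._result(ti, pi, ["c10", "c11", "c12"])
        swapped = self._result(pi, ti, ["c10", "c11", "c12"])
        lab = classify_dominance(res)
        lab_swapped = classify_dominance(swapped)
        swap = {
            "transcriptome-dominant": "proteome-dominant",
            "proteome-dominant": "transcriptome-dominant",
            "neutral": "neutral",
        }
        assert lab_swapped == swap[lab]

    def test_mixed_sides_is_neutral(self):
        ti = [0.0] * 8 + [5.0, 0.0, 6.0, 0.0]
        pi = [0.0] * 8 + [0.0, 5.0, 0.0, 6.0]
        res = self._result(ti, pi, ["c8", "c9", "c10", "c11"])
        assert classify_dominance(res) == "neutral"


class TestDiMM:
    def test_identical_components_on_diagonal(self, rng):
        genes = [f"g{i}" for i in range(50)]
        w = rng.normal(0, 1, 50)
        M = pd.DataFrame({"t0": w}, index=genes)
        Mp = pd.DataFrame({"p0": w}, index=genes)
        pair = MatchedPair("p0", ["t0"], {"t0": 1.0})
        members = {"t0": set(genes[:5])}
        members_p = {"p0": set(genes[:5])}
        df = dimm_table(pair, M, Mp, members, members_p)
        assert np.allclose(df["ti_weight"], df["pi_weight"])
        assert df["in_both"].sum() == 5

    def test_one_sided_membership_flagged(self, rng):
        genes = [f"g{i}" for i in range(30)]
        w = rng.normal(0, 1, 30)
        pair = MatchedPair("p0", ["t0"], {"t0": 1.0})
        df = dimm_table(
            pair,
            pd.DataFrame({"t0": w}, index=genes),
            pd.DataFrame({"p0": w}, index=genes),
            {"t0": {"g0", "g1"}},
            {"p0": {"g1", "g2"}},
        )
        assert bool(df.loc["g0", "in_ti"]) and not bool(df.loc["g0", "in_pi"])
        assert bool(df.loc["g1", "in_both"])

    def test_sign_alignment_makes_correlation_positive(self, rng):
        genes = [f"g{i}" for i in range(60)]
        w = rng.normal(0, 1, 60)
        pair = MatchedPair("p0", ["t0"], {"t0": -0.9})
        df = dimm_table(
            pair,
            pd.DataFrame({"t0": w}, index=genes),
            pd.DataFrame({"p0": -w}, index=genes),
            {"t0": set()},
            {"p0": set()},
        )
        assert np.corrcoef(df["ti_weight"], df["pi_weight"])[0, 1] > 0


class TestMatchedSubset:
    def test_restricts_features_and_conditions(self, small_sim):
        meta = small_sim.metadata
        X = small_sim.transcriptome
        shared = list(X.index[:100])
        conds = ["c001", "c002", "c003"]
        sub, sub_meta = matched_subset(X, meta, shared, conds)
        assert list(sub.index) == shared
        assert set(sub_meta["condition_id"]) == set(conds)

    def test_empty_subset_rejected(self, small_sim):
        with pytest.raises(ValueError, match="empty"):
            matched_subset(
                small_sim.transcriptome, small_sim.metadata, [], ["c001"]
            )


class TestEndToEndRecovery:
    def test_planted_links_recovered_with_lumping(self, small_gt, small_compendia):
        from crossmodulon.ica import run_robust_ica
        from crossmodulon.imodulons import threshold_component
        from crossmodulon.synth import recovery_report

        Xt, Xp, _, _ = small_compendia
        dt = run_robust_ica(Xt, small_gt.config.k_t, n_runs=5, seed=0)
        dp = run_robust_ica(Xp, small_gt.config.k_p, n_runs=5, seed=1)
        members_t = {c: threshold_component(dt.M[c])[1] for c in dt.M.columns}
        members_p = {c: threshold_component(dp.M[c])[1] for c in dp.M.columns}
        pairs = match_components(
            dt.M, dp.M, members_t=members_t, members_p=members_p
        )
        sc = recovery_report(small_gt, dt, dp, pairs, members_t=members_t)
        assert sc.link_recall == 1.0
        assert sc.link_precision == 1.0
        lumped = [p for p in pairs if p.is_lumped]
        assert len(lumped) == small_gt.config.n_lumped


try:
    from hypothesis import given, settings, strategies as st

    @given(
        pi=st.sets(st.integers(0, 60), max_size=30),
        ti=st.sets(st.integers(0, 60), max_size=30),
    )
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_recall_bounds_property(pi, ti):
        """|both| never exceeds either member set; recalls stay in [0, 1]."""
        pr, tr, both = compute_recall(pi, ti)
        assert len(both) <= min(len(pi), len(ti))
        for val, side in ((pr, pi), (tr, ti)):
            if side:
                assert 0.0 <= val <= 1.0
            else:
                assert np.isnan(val)

except ImportError:  # pragma: no cover - hypothesis is an optional test dep
    pass
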