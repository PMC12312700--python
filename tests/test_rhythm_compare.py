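import numpy as np
import pandas as pd
import pytest

from circaepi.io_formats import TimeCourseMatrix
from circaepi.jtk import jtk_scan
from circaepi.rhythm_compare import (
    ElbowKMeans,
    amplitude_ttest,
    classify_pair,
    elbow_kmeans,
    funnel_groups,
    phase_amp_diff,
    phase_polar_summary,
    updown_split,
)
from circaepi.synthetic_data import funnel_spec, simulate_expression

from .conftest import ZTS8, cosine_matrix, design


def result_table(p_by_gene, lag_by_gene=None, amp_by_gene=None, period=24.0):
    """Minimal rhythm-result frame for set-algebra tests."""
    genes = list(p_by_gene)
    return pd.DataFrame(
        {
            "gene_id": genes,
            "p_adj": [p_by_gene[g] for g in genes],
            "period": period,
            "lag": [(lag_by_gene or {}).get(g, 0.0) for g in genes],
            "amp": [(amp_by_gene or {}).get(g, 1.0) for g in genes],
            "rel_amp": 0.3,
            "rhythmic": [p_by_gene[g] <= 0.05 for g in genes],
        }
    )


class TestClassifyPair:
    def test_definitions(self):
        a = result_table({"g1": 0.01, "g2": 0.01, "g3": 0.5, "g4": 0.9})
        b = result_table({"g1": 0.01, "g2": 0.2, "g3": 0.01, "g4": 0.9})
        out = classify_pair(a, b).set_index("gene_id")["pair_label"]
        assert out["g1"] == "shared"
        assert out["g2"] == "onlyA"
        assert out["g3"] == "onlyB"
        assert out["g4"] == "neither"

    def test_identical_tables_share_everything(self):
        a = result_table({"g1": 0.01, "g2": 0.5})
        out = classify_pair(a, a)["pair_label"]
        assert list(out) == ["shared", "neither"]

    def test_symmetric_under_swap(self):
        a = result_table({"g1": 0.01, "g2": 0.5, "g3": 0.01})
        b = result_table({"g1": 0.5, "g2": 0.01, "g3": 0.01})
        ab = classify_pair(a, b)["pair_label"]
        ba = classify_pair(b, a)["pair_label"]
        swap = {"onlyA": "onlyB", "onlyB": "onlyA"}
        assert list(ba) == [swap.get(x, x) for x in ab]

    def test_universe_mismatch_rejected(self):
        a = result_table({"g1": 0.01})
        b = result_table({"g2": 0.01})
        with pytest.raises(ValueError, match="universes differ"):
            classify_pair(a, b)


class TestFunnel:
    def test_set_algebra(self):
        # (cv, gf, wt, ko) rhythmicity -> expected group
        cases = {
            "b": (0.01, 0.5, 0.01, 0.5),  # lost in GF and KO -> B
            "a": (0.01, 0.5, 0.01, 0.01),  # kept in KO -> microbiota only
            "c": (0.01, 0.01, 0.01, 0.5),  # kept in GF, lost in KO -> HDAC3 only
            "n1": (0.01, 0.01, 0.01, 0.01),
            "n2": (0.5, 0.5, 0.5, 0.5),
        }
        tables = [
            result_table({g: cases[g][i] for g in cases}) for i in range(4)
        ]
        out = funnel_groups(*tables).set_index("gene_id")["funnel_group"]
        assert out["b"] == "B" and out["a"] == "A" and out["c"] == "C"
        assert out["n1"] == "none" and out["n2"] == "none"

    def test_groups_disjoint_and_exact_recovery_at_high_snr(self):
        spec = funnel_spec(
            n_a=30, n_b=30, n_c=30, n_null=60, rel_amp=0.4, noise_cv=0.02, seed=9
        )
        matrices, truth = simulate_expression(spec)
        res = {c: jtk_scan(m) for c, m in matrices.items()}
        out = funnel_groups(res["CV"], res["GF"], res["WT"], res["KO"])
        merged = out.merge(truth[["gene_id", "block"]], on="gene_id")
        for group in ("A", "B", "C"):
            sub = merged[merged["block"] == group]
            assert (sub["funnel_group"] == group).all()
        counts = merged.groupby("funnel_group")["gene_id"].count()
        assert counts.get("A", 0) + counts.get("B", 0) + counts.get("C", 0) == 90


class TestPhaseAmpDiff:
    def test_wrap_arithmetic(self):
        r1 = result_table({"g": 0.01}, lag_by_gene={"g": 2.0}, amp_by_gene={"g": 5.0})
        r2 = result_table({"g": 0.01}, lag_by_gene={"g": 22.0}, amp_by_gene={"g": 3.0})
        row = phase_amp_diff(r1, r2).iloc[0]
        assert row["phase_diff"] == pytest.approx(4.0)
        assert row["amp_diff"] == pytest.approx(2.0)

    def test_self_difference_is_zero(self):
        r = result_table({"g1": 0.01, "g2": 0.01}, lag_by_gene={"g1": 8.0, "g2": 15.0})
        out = phase_amp_diff(r, r)
        assert (out["phase_diff"] == 0).all() and (out["amp_diff"] == 0).all()

    def test_half_period_boundary_maps_to_positive(self):
        r1 = result_table({"g": 0.01}, lag_by_gene={"g": 12.0})
        r2 = result_table({"g": 0.01}, lag_by_gene={"g": 0.0})
        assert phase_amp_diff(r1, r2).iloc[0]["phase_diff"] == pytest.approx(12.0)

    def test_undefined_lag_excluded_with_warning(self):
        r1 = result_table({"g1": 0.01, "g2": 0.01}, lag_by_gene={"g1": 3.0, "g2": np.nan})
        r2 = result_table({"g1": 0.01, "g2": 0.01}, lag_by_gene={"g1": 3.0, "g2": 5.0})
        with pytest.warns(UserWarning, match="excluded 1"):
            out = phase_amp_diff(r1, r2)
        assert list(out["gene_id"]) == ["g1"]


class TestAmplitudeTtest:
    def test_identical_samples_give_null_result(self):
        t, p = amplitude_ttest([0.1, 0.3], [0.1, 0.3])
        assert t == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_swap_flips_sign_same_p(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(0.3, 0.05, 30), rng.normal(0.2, 0.05, 30)
        t1, p1 = amplitude_ttest(x, y)
        t2, p2 = amplitude_ttest(y, x)
        assert t1 == pytest.approx(-t2) and p1 == pytest.approx(p2)

    def test_separated_groups_highly_significant(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0.30, 0.05, 200)
        y = rng.normal(0.15, 0.05, 200)
        _, p = amplitude_ttest(x, y)
        assert p < 1e-4

    def test_degenerate_variance_warns(self):
        with pytest.warns(UserWarning, match="zero variance"):
            t, p = amplitude_ttest([0.2, 0.2], [0.4, 0.4])
        assert p == 1.0


class TestElbowKMeans:
    def test_k1_wss_equals_total_sum_of_squares(self):
        rng = np.random.default_rng(0)
        X = rng.normal(0, 1, (40, 8))
        est = ElbowKMeans(k_max=5, random_state=0).fit(pd.DataFrame(X))
        from circaepi.rhythm_compare import _zscore_rows

        Z = _zscore_rows(X)
        tss = ((Z - Z.mean(axis=0)) ** 2).sum()
        assert est.wss_[1] == pytest.approx(tss)

    def test_wss_non_increasing(self):
        rng = np.random.default_rng(1)
        est = ElbowKMeans(k_max=6, random_state=0).fit(
            pd.DataFrame(rng.normal(0, 1, (60, 8)))
        )
        assert (est.wss_.diff().dropna() <= 1e-9).all()

    def test_same_seed_bit_reproducible(self, samples16):
        rng = np.random.default_rng(2)
        m = TimeCourseMatrix(
            [f"g{i}" for i in range(50)], rng.lognormal(1, 1, (50, 16)), samples16
        )
        a = elbow_kmeans(m, k_max=5, seed=7)
        b = elbow_kmeans(m, k_max=5, seed=7)
        assert a.k_ == b.k_
        assert (a.labels_ == b.labels_).all()
        pd.testing.assert_series_equal(a.wss_, b.wss_)

    def test_fewer_genes_than_k_max_rejected(self):
        with pytest.raises(ValueError, match="fewer than k_max"):
            ElbowKMeans(k_max=10).fit(pd.DataFrame(np.eye(4)))

    def test_recovers_planted_archetypes(self):
        from circaepi.benchmarks import elbow_archetype_recovery

        out = elbow_archetype_recovery(seed=3, genes_per_archetype=50)
        assert out["k_selected"] == 4
        assert out["label_agreement"] >= 0.95


class TestUpdownSplit:
    def test_mean_level_rule(self, samples8):
        wt = cosine_matrix([("up", 2.0), ("down", 5.0)], samples8)
        ko = cosine_matrix([("up", 4.0), ("down", 3.0)], samples8)
        out = updown_split(wt, ko, ["up", "down"])
        assert out == {"upregulated": ["up"], "downregulated": ["down"]}

    def test_tie_goes_down_with_warning(self, samples8):
        wt = cosine_matrix([("g", 2.0)], samples8)
        ko = cosine_matrix([("g", 2.0)], samples8)
        with pytest.warns(UserWarning, match="ties"):
            out = updown_split(wt, ko, ["g"])
        assert out["downregulated"] == ["g"]

    def test_missing_gene_rejected(self, samples8):
        wt = cosine_matrix([("g", 2.0)], samples8)
        with pytest.raises(KeyError):
            updown_split(wt, wt, ["absent"])

    def test_planted_induction_recovered(self):
        samples = design(replicates=2)
        rng = np.random.default_rng(8)
        n = 50
        base = rng.lognormal(2, 0.5, n)
        wt_vals = base[:, None] * rng.lognormal(0, 0.1, (n, 16))
        ko_vals = 2 * base[:, None] * rng.lognormal(0, 0.1, (n, 16))
        ids = [f"g{i}" for i in range(n)]
        wt = TimeCourseMatrix(ids, wt_vals, samples)
        ko = TimeCourseMatrix(ids, ko_vals, design(replicates=2, condition="KO"))
        out = updown_split(wt, ko, ids)
        assert len(out["upregulated"]) >= 0.95 * n


class TestPhasePolarSummary:
    def test_single_phase_single_bin(self):
        res = result_table(
            {f"g{i}": 0.01 for i in range(10)},
            lag_by_gene={f"g{i}": 9.0 for i in range(10)},
        )
        out = phase_polar_summary(res, lag_bin_width=3.0)
        assert out.to_numpy().sum() == 10
        assert out.loc[9.0].sum() == 10

    def test_counts_conserved(self):
        rng = np.random.default_rng(5)
        lags = rng.choice(ZTS8, 200)
        res = result_table(
            {f"g{i}": 0.01 for i in range(200)},
            lag_by_gene={f"g{i}": float(lags[i]) for i in range(200)},
        )
        res["rel_amp"] = rng.uniform(0, 0.5, 200)
        out = phase_polar_summary(res)
        assert out.to_numpy().sum() == 200
        assert out.shape == (8, 5)
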