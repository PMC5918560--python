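"""OTU preprocessing, mixed models, FDR, and the twin-discordance design."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from dietindex import association as assoc


def tech_covariates(n, rng):
    return pd.DataFrame(
        {
            "depth": rng.integers(15_000, 60_000, n).astype(float),
            "run": rng.choice(["R1", "R2", "R3"], n),
            "extractor": rng.choice(["E1", "E2"], n),
            "loader": rng.choice(["L1", "L2"], n),
            "collection": rng.choice(["clinic", "post"], n),
        },
        index=[f"s{i}" for i in range(n)],
    )


class TestPrevalenceFilter:
    def test_full_prevalence_kept_boundary_dropped(self):
        rel = pd.DataFrame(
            {
                "everywhere": [0.1, 0.2, 0.3, 0.4],
                "quarter": [0.5, 0.0, 0.0, 0.0],  # exactly 25%: dropped (strict >)
                "half": [0.5, 0.5, 0.0, 0.0],
            }
        )
        kept = assoc.prevalence_filter(rel, 0.25)
        assert list(kept.columns) == ["everywhere", "half"]

    def test_surviving_count_matches_hand_count(self):
        rng = np.random.default_rng(0)
        rel = pd.DataFrame(rng.random((40, 30)) * (rng.random((40, 30)) > 0.6))
        kept = assoc.prevalence_filter(rel, 0.25)
        expected = sum(
            1 for c in rel.columns if (rel[c] > 0).sum() / len(rel) > 0.25
        )
        assert kept.shape[1] == expected


class TestLogAbundance:
    def test_zeros_replaced_by_half_min_nonzero(self):
        rel = pd.DataFrame({"a": [0.5, 0.0], "b": [0.5, 1.0]})
        logged = assoc.log10_abundance(rel)
        assert logged.loc[1, "a"] == pytest.approx(np.log10(0.25))

    def test_all_zero_table_rejected(self):
        with pytest.raises(ValueError):
            assoc.log10_abundance(pd.DataFrame({"a": [0.0, 0.0]}))


class TestResidualize:
    def test_planted_run_effect_removed(self):
        rng = np.random.default_rng(1)
        cov = tech_covariates(300, rng)
        run_effect = (cov["run"] == "R1").astype(float) * 0.8
        y = pd.DataFrame(
            {"otu1": rng.normal(size=300) + run_effect}, index=cov.index
        )
        resid = assoc.residualize_abundance(y, cov)
        r = np.corrcoef(resid["otu1"], (cov["run"] == "R1").astype(float))[0, 1]
        assert abs(r) < 1e-8

    def test_orthogonal_covariates_leave_centered_values(self):
        rng = np.random.default_rng(2)
        cov = tech_covariates(2000, rng)
        y = pd.DataFrame({"otu1": rng.normal(5.0, 1.0, 2000)}, index=cov.index)
        resid = assoc.residualize_abundance(y, cov)
        centered = y["otu1"] - y["otu1"].mean()
        assert np.abs(resid["otu1"] - centered).max() < 0.25
        assert resid["otu1"].mean() == pytest.approx(0.0, abs=1e-10)

    def test_single_sample_rejected(self):
        cov = tech_covariates(1, np.random.default_rng(3))
        y = pd.DataFrame({"otu1": [1.0]}, index=cov.index)
        with pytest.raises(ValueError):
            assoc.residualize_abundance(y, cov)

    def test_constant_covariate_dropped_with_warning(self):
        rng = np.random.default_rng(4)
        cov = tech_covariates(50, rng)
        cov["extractor"] = "E1"
        y = pd.DataFrame({"otu1": rng.normal(size=50)}, index=cov.index)
        with pytest.warns(UserWarning, match="constant"):
            assoc.residualize_abundance(y, cov)


class TestCollapseTaxonomy:
    taxonomy = pd.Series(
        {
            "o1": "k__B; p__P1; c__C1; o__O1; f__F1; g__G1",
            "o2": "k__B; p__P1; c__C1; o__O1; f__F1; g__G1",
            "o3": "k__B; p__P2; c__C2; o__O2; f__F2; g__G2",
            "o4": "k__B; p__P2; c__C2; o__O2; f__F2; g__",  # unassigned genus
        }
    )

    def counts(self):
        return pd.DataFrame(
            [[1, 2, 3, 4], [5, 6, 7, 8]],
            index=["s1", "s2"],
            columns=["o1", "o2", "o3", "o4"],
        )

    def test_hand_grouped_oracle(self):
        out = assoc.collapse_taxonomy(self.counts(), self.taxonomy, "genus")
        assert out.loc["s1", "G1"] == 3
        assert out.loc["s1", "G2"] == 3
        assert out.loc["s1", "unassigned"] == 4

    def test_per_sample_totals_conserved(self):
        counts = self.counts()
        for level in ("phylum", "family", "genus"):
            out = assoc.collapse_taxonomy(counts, self.taxonomy, level)
            np.testing.assert_array_equal(
                out.sum(axis=1).to_numpy(), counts.sum(axis=1).to_numpy()
            )

    def test_single_genus_collapses_to_column_sums(self):
        counts = self.counts()[["o1", "o2"]]
        out = assoc.collapse_taxonomy(counts, self.taxonomy, "genus")
        assert out.shape[1] == 1
        np.testing.assert_array_equal(out["G1"], counts.sum(axis=1))

    def test_unknown_level_rejected(self):
        with pytest.raises(KeyError, match="level"):
            assoc.collapse_taxonomy(self.counts(), self.taxonomy, "strain")


class TestMixedAssoc:
    def frame(self, n, rng):
        meta = pd.DataFrame(
            {
                "age": rng.normal(58, 13, n),
                "bmi": rng.normal(26, 5, n),
                "sex": rng.choice(["F", "M"], n),
                "zygosity": rng.choice(["MZ", "DZ"], n),
                "batch": rng.choice(["b1", "b2"], n),
            },
            index=[f"s{i}" for i in range(n)],
        )
        return meta

    def test_planted_standardized_slope_recovered(self):
        rng = np.random.default_rng(5)
        n = 2000
        meta = self.frame(n, rng)
        x = pd.Series(rng.normal(size=n), index=meta.index, name="hei")
        batch_fx = (meta["batch"] == "b1").astype(float) * 0.3
        y = pd.Series(
            0.1 * x + np.sqrt(1 - 0.01) * rng.normal(size=n) + batch_fx,
            index=meta.index, name="shannon",
        )
        res = assoc.mixed_assoc(y, x, meta)
        assert res.beta == pytest.approx(0.1, abs=3 * res.se)
        assert res.p < 0.05
        assert res.lrt_p < 0.05

    def test_constant_outcome_rejected(self):
        rng = np.random.default_rng(6)
        meta = self.frame(50, rng)
        y = pd.Series(1.0, index=meta.index, name="y")
        x = pd.Series(rng.normal(size=50), index=meta.index, name="x")
        with pytest.raises(ValueError, match="constant"):
            assoc.mixed_assoc(y, x, meta)

    def test_tiny_sample_falls_back_to_fixed_intercept(self):
        # 8 samples cannot support five crossed variance components
        rng = np.random.default_rng(7)
        meta = self.frame(8, rng)
        y = pd.Series(rng.normal(size=8), index=meta.index, name="y")
        x = pd.Series(rng.normal(size=8), index=meta.index, name="x")
        res = assoc.mixed_assoc(y, x, meta, fixed=(), random=("batch",))
        assert res.model in ("mixed", "ols_fallback")
        assert np.isfinite(res.p)


class TestFDR:
    def test_all_ones_stay_ones(self):
        res = assoc.fdr(np.ones(50))
        np.testing.assert_allclose(res.q, 1.0)

    def test_single_p_bounded_below_by_p(self):
        res = assoc.fdr([0.03])
        assert res.q[0] >= 0.03
        assert res.method == "bh_fallback"

    def test_strong_signals_found_with_null_fdr_controlled(self):
        rng = np.random.default_rng(8)
        m_null, m_sig = 250, 250
        z = np.concatenate([rng.normal(size=m_null), rng.normal(6, 1, m_sig)])
        p = 2 * stats.norm.sf(np.abs(z))
        res = assoc.fdr(p)
        assert res.method == "storey"
        found = res.q[m_null:] < 0.05
        assert found.mean() > 0.95
        false = (res.q[:m_null] < 0.05).sum()
        assert false <= 0.10 * (found.sum() + false)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=2, max_size=60))
    def test_q_monotone_in_p(self, pvals):
        res = assoc.fdr(np.array(pvals))
        order = np.argsort(pvals)
        assert (np.diff(res.q[order]) >= -1e-12).all()

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            assoc.fdr([])


def twelve_pair_cohort():
    """24 subjects in 12 pairs with crafted score patterns."""
    scores, pair_ids = {}, {}
    base = [10, 20, 30, 40, 50, 60, 70, 80, 90, 100, 110, 120]
    rng = np.random.default_rng(9)
    offsets = rng.uniform(-3, 3, 12)
    for p in range(12):
        a, b = f"P{p}a", f"P{p}b"
        if p < 4:  # strongly discordant
            scores[a], scores[b] = base[p] + 60 + offsets[p], base[p] - 60
        elif p < 8:  # nearly identical
            scores[a], scores[b] = base[p] + 0.5, base[p]
        else:  # moderately apart
            scores[a], scores[b] = base[p] + 20 + offsets[p], base[p]
        pair_ids[a] = pair_ids[b] = f"pair{p}"
    return pd.Series(scores, name="hei"), pd.Series(pair_ids)


def discordance_oracle(scores, pair_ids, sd_rule=1.0, n_quantiles=4):
    """Exhaustive re-derivation of the discordance filter."""
    sd = float(np.std(scores.to_numpy(), ddof=1))
    order = np.argsort(scores.to_numpy(), kind="stable")
    rank = np.empty(len(scores), dtype=int)
    rank[order] = np.arange(1, len(scores) + 1)
    quart = {s: int(np.ceil(n_quantiles * r / len(scores))) for s, r in zip(scores.index, rank)}
    hits = set()
    for pid in pair_ids.unique():
        members = list(pair_ids.index[pair_ids == pid])
        if len(members) != 2:
            continue
        a, b = members
        if abs(scores[a] - scores[b]) > sd_rule * sd and quart[a] != quart[b]:
            hits.add(pid)
    return hits


class TestDiscordantPairs:
    def test_toy_cohort_matches_exhaustive_enumeration(self):
        scores, pair_ids = twelve_pair_cohort()
        found = assoc.find_discordant_pairs(scores, pair_ids)
        assert set(found["pair_id"]) == discordance_oracle(scores, pair_ids)
        assert len(found) > 0

    def test_identical_scores_excluded(self):
        scores = pd.Series({"a": 50.0, "b": 50.0, "c": 10.0, "d": 90.0})
        pairs = pd.Series({"a": "p1", "b": "p1", "c": "p2", "d": "p2"})
        found = assoc.find_discordant_pairs(scores, pairs)
        assert "p1" not in set(found["pair_id"])

    def test_same_quartile_pair_excluded_despite_large_gap(self):
        # 16 background subjects squeeze the target pair into one quartile
        scores = {f"bg{i}": float(i) for i in range(16)}
        scores.update({"t1": 100.0, "t2": 130.0})  # both in the top quartile
        pairs = {"t1": "pt", "t2": "pt"}
        found = assoc.find_discordant_pairs(pd.Series(scores), pd.Series(pairs))
        assert len(found) == 0

    def test_healthier_member_labelled_by_higher_score(self):
        scores, pair_ids = twelve_pair_cohort()
        found = assoc.find_discordant_pairs(scores, pair_ids)
        for _, row in found.iterrows():
            assert scores[row.healthy_id] > scores[row.less_healthy_id]


class TestPairedTests:
    def make_pairs(self, n):
        pairs = pd.DataFrame(
            {
                "pair_id": [f"p{i}" for i in range(n)],
                "healthy_id": [f"h{i}" for i in range(n)],
                "less_healthy_id": [f"l{i}" for i in range(n)],
            }
        )
        return pairs

    def residual_frame(self, pairs, rng, shift=0.0):
        ids = list(pairs["healthy_id"]) + list(pairs["less_healthy_id"])
        resid = pd.DataFrame(
            rng.normal(size=(len(ids), 3)), index=ids, columns=["o1", "o2", "o3"]
        )
        resid.loc[pairs["healthy_id"], "o1"] += shift
        return resid

    def test_planted_shift_detected_with_direction(self):
        rng = np.random.default_rng(10)
        pairs = self.make_pairs(40)
        resid = self.residual_frame(pairs, rng, shift=1.5)
        out = assoc.paired_tests(resid, pairs).set_index("outcome")
        assert out.loc["o1", "q"] < 0.05
        assert out.loc["o1", "median_difference"] > 0

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(11)
        pvals = []
        for _ in range(200):
            pairs = self.make_pairs(15)
            resid = self.residual_frame(pairs, rng)
            pvals.append(assoc.paired_tests(resid, pairs)["p"].iloc[1])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_all_zero_differences_give_p_one(self):
        pairs = self.make_pairs(10)
        ids = list(pairs["healthy_id"]) + list(pairs["less_healthy_id"])
        resid = pd.DataFrame(3.14, index=ids, columns=["o1"])
        out = assoc.paired_tests(resid, pairs)
        assert out["p"].iloc[0] == 1.0

    def test_under_six_pairs_flagged_undefined(self):
        rng = np.random.default_rng(12)
        pairs = self.make_pairs(4)
        resid = self.residual_frame(pairs, rng)
        out = assoc.paired_tests(resid, pairs)
        assert out["p"].isna().all()
        assert out.attrs["underpowered"]


class TestPairDistanceRegression:
    def make_frame(self, n, rng, slope=0.0):
        d_index = rng.uniform(0, 3, n)
        frame = pd.DataFrame(
            {
                "distance": 0.3 + slope * d_index + 0.05 * rng.normal(size=n),
                "d_index": d_index,
                "d_bmi": rng.uniform(0, 5, n),
                "diff_extractor": rng.integers(0, 2, n).astype(float),
            },
            index=[f"p{i}" for i in range(n)],
        )
        return frame

    def test_null_slope_within_noise(self):
        rng = np.random.default_rng(13)
        out = assoc.pair_distance_regression(self.make_frame(200, rng))
        assert abs(out.loc["d_index", "beta"]) < 3 * out.loc["d_index", "se"]

    def test_planted_monotone_link_recovered(self):
        rng = np.random.default_rng(14)
        frame = self.make_frame(200, rng, slope=0.1)
        out = assoc.pair_distance_regression(frame)
        expected = 0.1 * frame["d_index"].std() / frame["distance"].std()
        assert out.loc["d_index", "beta"] == pytest.approx(expected, abs=3 * out.loc["d_index", "se"])
        assert out.loc["d_index", "p"] < 0.001

    def test_duplicate_pair_rows_rejected(self):
        rng = np.random.default_rng(15)
        frame = self.make_frame(20, rng)
        dup = pd.concat([frame, frame.iloc[[0]]])
        with pytest.raises(ValueError, match="duplicate"):
            assoc.pair_distance_regression(dup)

    def test_too_few_pairs_rejected(self):
        rng = np.random.default_rng(16)
        with pytest.raises(ValueError, match="fewer pairs"):
            assoc.pair_distance_regression(self.make_frame(4, rng))
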