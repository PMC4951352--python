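import numpy as np
import pandas as pd
import pytest

from reosig import signature as sig
from reosig import simulate


def pair(a, b, reo="a<b", cox_p=None, cox_hr=None):
    return sig.OrientedGenePair(a, b, high_risk_reo=reo, cox_p=cox_p, cox_hr=cox_hr)


def three_pair_signature():
    return sig.Signature(
        pairs=[pair("a1", "b1"), pair("a2", "b2"), pair("a3", "b3")]
    )


def expr_for_votes(votes_per_sample):
    """Expression matrix realizing given (v1, v2, v3) high-risk vote patterns."""
    genes = ["a1", "b1", "a2", "b2", "a3", "b3"]
    cols = {}
    for s, votes in enumerate(votes_per_sample):
        col = []
        for v in votes:  # high vote means Ea < Eb
            col += [1.0, 2.0] if v else [2.0, 1.0]
        cols[f"s{s}"] = col
    return pd.DataFrame(cols, index=genes)


class TestClassifyGps:
    @pytest.mark.parametrize(
        "votes,expected",
        [((1, 1, 0), "high"), ((1, 0, 0), "low"), ((0, 0, 0), "low"), ((1, 1, 1), "high")],
    )
    def test_two_of_three_majority_rule(self, votes, expected):
        calls = sig.classify_gps(expr_for_votes([votes]), three_pair_signature())
        assert calls.loc["s0", "label"] == expected
        assert calls.loc["s0", "votes_high"] == sum(votes)

    def test_single_sample_invariance(self):
        patterns = [(1, 1, 0), (0, 1, 0), (1, 1, 1), (0, 0, 1)]
        expr = expr_for_votes(patterns)
        together = sig.classify_gps(expr, three_pair_signature())
        for s in expr.columns:
            alone = sig.classify_gps(expr[[s]], three_pair_signature())
            assert alone.loc[s, "label"] == together.loc[s, "label"]

    def test_invariant_under_per_sample_monotone_transforms(self, small_cohort):
        expr, _, truth = small_cohort
        signature = sig.Signature(pairs=truth.planted_pairs)
        rng = np.random.default_rng(0)
        n = expr.shape[1]
        distorted = expr * rng.uniform(0.5, 3.0, n) + (expr**3) * rng.uniform(
            0.01, 0.1, n
        ) + rng.normal(0, 4, n)
        pd.testing.assert_frame_equal(
            sig.classify_gps(expr, signature), sig.classify_gps(distorted, signature)
        )

    def test_stable_under_cohort_subsetting(self, small_cohort):
        expr, _, truth = small_cohort
        signature = sig.Signature(pairs=truth.planted_pairs)
        full = sig.classify_gps(expr, signature)
        low = full.index[full["label"] == "low"]
        again = sig.classify_gps(expr, signature, samples=list(low))
        assert (again["label"] == "low").all()

    def test_missing_gene_named_in_error(self):
        expr = expr_for_votes([(1, 0, 0)]).drop(index="b2")
        with pytest.raises(KeyError, match="b2"):
            sig.classify_gps(expr, three_pair_signature())

    def test_vote_threshold_is_strict_majority(self):
        assert three_pair_signature().vote_threshold == 2
        assert sig.Signature(pairs=[pair(f"a{i}", f"b{i}") for i in range(4)]).vote_threshold == 3
        with pytest.raises(ValueError):
            sig.Signature(pairs=[pair("a", "b")], vote_threshold=2)


class TestPercentileVote:
    def test_identical_values_flag_nothing(self):
        expr = pd.DataFrame(np.full((2, 8), 5.0), index=["g0", "g1"])
        calls = sig.percentile_vote_classify(expr, {"g0": "high", "g1": "low"}, vote_min=1)
        assert (calls["label"] == "low").all()

    def test_flags_match_percentile_definition(self):
        expr = pd.DataFrame([np.arange(1.0, 11.0)], index=["g0"])
        calls = sig.percentile_vote_classify(expr, {"g0": "high"}, vote_min=1, hi_pct=80)
        cutoff = np.percentile(np.arange(1.0, 11.0), 80)
        expected_high = {c for c in expr.columns if expr.loc["g0", c] > cutoff}
        assert set(calls.index[calls["label"] == "high"]) == expected_high
        assert expected_high == {8, 9}  # values 9.0 and 10.0

    def test_reclassifying_own_low_risk_subset_changes_labels(self):
        # skewed tail: percentile cutoffs move when the cohort shrinks
        values = np.array([1.0, 2, 3, 4, 5, 6, 7, 8, 20, 40])
        expr = pd.DataFrame([values], index=["g0"])
        first = sig.percentile_vote_classify(expr, {"g0": "high"}, vote_min=1)
        low = list(first.index[first["label"] == "low"])
        second = sig.percentile_vote_classify(expr, {"g0": "high"}, vote_min=1, samples=low)
        changed = (second.loc[low, "label"] != first.loc[low, "label"]).sum()
        assert changed >= 1

    def test_vote_min_validation(self):
        expr = pd.DataFrame([[1.0, 2.0]], index=["g0"])
        with pytest.raises(ValueError):
            sig.percentile_vote_classify(expr, {"g0": "high"}, vote_min=2)


def prognostic_cohort(n=200, hr=4.0, seed=13):
    """One planted pair in a small stage II cohort."""
    config = simulate.SyntheticConfig(
        n_genes=40,
        n_stage1=0,
        n_stage2_noctx=n,
        n_stage2_ctx=0,
        n_stage34=0,
        n_planted_pairs=1,
        n_planted_de_extra=0,
        hr_true=hr,
        seed=seed,
    )
    return simulate.generate_cohort(config)


class TestPrognosticPairs:
    def test_planted_pair_retained_with_correct_orientation(self):
        expr, clinical, truth = prognostic_cohort()
        planted = truth.planted_pairs[0]
        retained = sig.prognostic_pairs(expr, clinical, [planted.key()], p_threshold=0.01)
        assert len(retained) == 1
        assert retained[0].key() == planted.key()
        # the generator plants Ea < Eb as the high-risk ordering; after
        # canonicalization the retained orientation must agree
        got = retained[0]
        votes_match = (got.gene_a, got.gene_b, got.high_risk_reo) in {
            (planted.gene_a, planted.gene_b, planted.high_risk_reo),
            (planted.gene_b, planted.gene_a, "a>b" if planted.high_risk_reo == "a<b" else "a<b"),
        }
        assert votes_match
        assert got.cox_hr > 1
        assert got.cox_p < 0.01

    def test_degenerate_partition_skipped(self):
        expr, clinical, _ = prognostic_cohort()
        expr.loc["G0001"] = 0.0
        expr.loc["G0002"] = 1.0  # Ea < Eb everywhere: one-sided partition
        retained = sig.prognostic_pairs(expr, clinical, [("G0001", "G0002")])
        assert retained == []

    def test_perfect_separation_uses_score_test_fallback(self):
        # REO separates an immortal group from an all-event group
        times = np.concatenate([np.arange(1.0, 11.0), np.full(10, 60.0)])
        events = np.concatenate([np.ones(10, int), np.zeros(10, int)])
        clinical = pd.DataFrame(
            {"rfs_time": times, "rfs_event": events},
            index=[f"s{i}" for i in range(20)],
        )
        expr = pd.DataFrame(
            {f"s{i}": ([2.0, 1.0] if i < 10 else [1.0, 2.0]) for i in range(20)},
            index=["gA", "gB"],
        )
        with pytest.warns(UserWarning, match="monotone|log-rank"):
            retained = sig.prognostic_pairs(expr, clinical, [("gA", "gB")], p_threshold=0.01)
        assert len(retained) == 1
        assert retained[0].high_risk_reo == "a>b"


class TestForwardSelect:
    def test_single_candidate_gives_single_pair_signature(self):
        expr, clinical, truth = prognostic_cohort()
        candidates = sig.prognostic_pairs(expr, clinical, [truth.planted_pairs[0].key()])
        chosen = sig.forward_select(candidates, expr, clinical)
        assert len(chosen.pairs) == 1
        assert chosen.vote_threshold == 1

    @pytest.mark.parametrize("strategy", ["ranked", "greedy"])
    def test_strong_seed_with_null_candidates_returns_seed(self, strategy):
        expr, clinical, truth = prognostic_cohort(seed=17)
        planted = truth.planted_pairs[0]
        strong = sig.prognostic_pairs(expr, clinical, [planted.key()])[0]
        rng = np.random.default_rng(17)
        null_genes = [g for g in expr.index if g not in set(planted.key())]
        nulls = [
            pair(*rng.choice(null_genes, 2, replace=False), cox_p=0.009, cox_hr=1.5)
            for _ in range(10)
        ]
        chosen = sig.forward_select([strong] + nulls, expr, clinical, strategy=strategy)
        assert chosen.pairs[0].key() == planted.key()

    def test_selected_p_value_non_increasing(self, default_cohort, recovery_run):
        expr, clinical, _ = default_cohort
        cohort = recovery_run["cohort"]
        chosen = recovery_run["signature"]
        times = clinical.loc[cohort, "rfs_time"].to_numpy()
        events = clinical.loc[cohort, "rfs_event"].to_numpy()
        from reosig import survival as surv

        p_values = []
        for k in range(1, len(chosen.pairs) + 1):
            subset = sig.Signature(pairs=chosen.pairs[:k])
            calls = sig.classify_gps(expr, subset, cohort)
            high = (calls["label"] == "high").to_numpy()
            p_values.append(surv.logrank_test(times, events, high)[1])
        assert all(b <= a * (1 + 1e-12) for a, b in zip(p_values, p_values[1:]))

    def test_empty_candidates_rejected(self, small_cohort):
        expr, clinical, _ = small_cohort
        with pytest.raises(ValueError):
            sig.forward_select([], expr, clinical)


class TestSignatureSerialization:
    def test_round_trip(self, tmp_path):
        signature = three_pair_signature()
        path = tmp_path / "sig.json"
        sig.save_signature(signature, path)
        back = sig.load_signature(path)
        assert [p.key() for p in back.pairs] == [p.key() for p in signature.pairs]
        assert back.vote_threshold == signature.vote_threshold

    def test_published_three_pair_signature(self):
        gps = sig.load_3gps()
        assert [(p.gene_a, p.gene_b) for p in gps.pairs] == [
            ("ORC1", "OLR1"),
            ("MTNR1A", "VGLL1"),
            ("RFX5", "MMP14"),
        ]
        assert all(p.high_risk_reo == "a<b" for p in gps.pairs)
        assert gps.vote_threshold == 2
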