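import numpy as np
import pandas as pd
import pytest

from pathrisk.cohort import ExpressionCohort, SampleAnnotation
from pathrisk.meta import (
    PathwayEvidence,
    combine_p,
    evidence_from_tables,
    mutation_expression_concordance,
    rank_consistency_p,
    select_candidate_pathways,
    storey_qvalues,
)
from pathrisk.variants import MutationMatrix


class TestCombineP:
    def test_fisher_closed_form(self):
        # -2(ln .5 + ln .5) = 2.7726; chi2(4) survival = e^{-x/2}(1+x/2)
        assert combine_p([0.5, 0.5], "fisher") == pytest.approx(0.5966, abs=5e-5)

    def test_wilkinson_min_closed_form(self):
        # 1 - (1 - 0.01)^3
        assert combine_p([0.01, 0.8, 0.9], "wilkinson_min") == pytest.approx(0.0297, abs=5e-5)

    def test_sum_p_small_sum(self):
        # P(U1+U2 <= 0.2) = 0.2^2/2
        assert combine_p([0.1, 0.1], "sum_p") == pytest.approx(0.02, abs=1e-12)

    @pytest.mark.parametrize("method", ["fisher", "wilkinson_min", "sum_p"])
    @pytest.mark.parametrize("p", [0.01, 0.3, 0.97])
    def test_single_p_identity(self, method, p):
        assert combine_p([p], method) == pytest.approx(p, rel=1e-9)

    @pytest.mark.parametrize("method", ["fisher", "wilkinson_min", "sum_p"])
    def test_in_unit_interval(self, method, rng):
        for _ in range(20):
            ps = rng.random(rng.integers(1, 8))
            assert 0.0 <= combine_p(ps, method) <= 1.0

    def test_zero_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            p = combine_p([0.0, 0.5], "fisher")
        assert 0.0 <= p < 1e-6


class TestRankConsistency:
    def test_middle_pathway_is_half(self):
        P = pd.DataFrame(np.tile(np.linspace(0.01, 0.99, 99)[:, None], (1, 4)))
        assert rank_consistency_p(P).iloc[49] == pytest.approx(0.5)

    def test_single_dataset_identity(self):
        P = pd.DataFrame({"d1": [0.001, 0.5, 0.9]})
        out = rank_consistency_p(P)
        # scaled ranks (r - 0.5)/3 for r = 1, 2, 3
        assert out.tolist() == pytest.approx([1 / 6, 3 / 6, 5 / 6])

    def test_monotone_transform_invariance(self, rng):
        P = pd.DataFrame(rng.random((40, 3)))
        out1 = rank_consistency_p(P)
        out2 = rank_consistency_p(P**3)  # strictly monotone in each column
        assert np.allclose(out1, out2)

    def test_missing_entries_use_observed_m(self, rng):
        P = pd.DataFrame(rng.random((20, 3)))
        P.iloc[0, 2] = np.nan
        out = rank_consistency_p(P)
        assert np.isfinite(out.iloc[0])

    def test_all_equal_column_warns(self):
        P = pd.DataFrame({"d1": [0.5, 0.5, 0.5], "d2": [0.1, 0.2, 0.3]})
        with pytest.warns(UserWarning, match="all P equal"):
            rank_consistency_p(P)

    def test_monte_carlo_oracle_moderate_tail(self, rng):
        """The combined P matches simulation from the uniform-rank null."""
        N, m = 100, 3
        target_ranks = np.array([5, 12, 9])  # within-dataset ranks of one pathway
        vals = np.linspace(0.005, 0.995, N)
        cols = {}
        for j, r in enumerate(target_ranks):
            perm = np.concatenate([[vals[r - 1]], rng.permutation(np.delete(vals, r - 1))])
            cols[f"d{j}"] = perm
        P = pd.DataFrame(cols)
        impl = rank_consistency_p(P).iloc[0]
        mean_scaled = ((target_ranks - 0.5) / N).mean()
        draws = rng.random((400_000, m)).mean(axis=1)  # i.i.d. uniform null
        mc = (draws <= mean_scaled).mean()
        se = np.sqrt(mc * (1 - mc) / 400_000)
        assert abs(impl - mc) < 3 * se


class TestStoreyQvalues:
    def test_uniform_pi0_near_one(self, rng):
        qs, pi0 = storey_qvalues(rng.random(1000))
        assert 0.85 <= pi0 <= 1.0

    def test_q_monotone_in_sorted_p(self, rng):
        ps = rng.random(200)
        qs, _ = storey_qvalues(ps)
        order = np.argsort(ps)
        assert (np.diff(qs[order]) >= -1e-12).all()

    def test_q_below_bh(self, rng):
        ps = np.concatenate([rng.uniform(0, 0.001, 50), rng.random(450)])
        qs, pi0 = storey_qvalues(ps)
        from statsmodels.stats.multitest import multipletests

        bh = multipletests(ps, method="fdr_bh")[1]
        assert (qs <= bh + 1e-12).all()

    def test_degenerate_identical(self):
        ps = np.full(20, 0.4)
        qs, pi0 = storey_qvalues(ps)
        assert pi0 == 1.0
        assert np.allclose(qs, ps)


def _ev(pw, rank_p, flags=(), datasets=("d1", "d2")):
    return PathwayEvidence(
        pathway=pw,
        p_by_dataset={d: 0.01 for d in datasets},
        rank_p=rank_p,
        flags=set(flags),
    )


class TestCandidateFunnel:
    def test_threshold_pass(self):
        cands, funnel = select_candidate_pathways([_ev("A", 0.04)], 0.05, ["d1", "d2"])
        assert [e.pathway for e in cands] == ["A"]
        assert funnel["after_brca_subgroup_filter"] == 1

    def test_flag_drops_and_funnel_decrements(self):
        evidence = [_ev("A", 0.04), _ev("B", 0.04, flags=["treatment_effect"])]
        cands, funnel = select_candidate_pathways(evidence, 0.05, ["d1", "d2"])
        assert [e.pathway for e in cands] == ["A"]
        assert funnel["rank_p_below_alpha"] == 2
        assert funnel["after_treatment_filter"] == 1

    def test_empty_evidence(self):
        cands, funnel = select_candidate_pathways([], 0.05, [])
        assert cands == []
        assert all(v == 0 for v in funnel.values())

    def test_funnel_counts_non_increasing(self, rng):
        evidence = [
            _ev(f"P{i}", float(rng.random()), flags=["brca_subgroup"] if rng.random() < 0.3 else [])
            for i in range(30)
        ]
        _, funnel = select_candidate_pathways(evidence, 0.05, ["d1", "d2"])
        vals = list(funnel.values())
        assert all(vals[i + 1] <= vals[i] for i in range(len(vals) - 1))

    def test_missing_required_dataset_dropped(self):
        e = _ev("A", 0.01, datasets=("d1",))
        _, funnel = select_candidate_pathways([e], 0.05, ["d1", "d2"])
        assert funnel["in_all_required_datasets"] == 0


def _concordance_setup(rng, n=10, n_genes=1, mutated_high=True):
    ids = [f"s{i}" for i in range(n)]
    ann = [SampleAnnotation(i, "utah", True, "BRCAX", False) for i in ids]
    expr_vals = rng.standard_normal((n, n_genes))
    genes = [f"g{j}" for j in range(n_genes)]
    expr = ExpressionCohort(pd.DataFrame(expr_vals, index=ids, columns=genes), ann)
    return ids, genes, expr


class TestConcordance:
    def test_rho_matches_rank_formula(self, rng):
        ids, genes, expr = _concordance_setup(rng)
        e = expr.matrix["g0"].to_numpy()
        mut = np.zeros(10, dtype=int)
        mut[np.argsort(e)[-3:]] = 1  # the 3 mutated samples have the 3 highest values
        gm = MutationMatrix("gene", pd.DataFrame({"g0": mut}, index=ids))
        results, skipped = mutation_expression_concordance(expr, gm, fdr_cutoff=0.2)
        # direct rank-formula oracle: Pearson correlation of the rank vectors
        r_e = pd.Series(e).rank().to_numpy()
        r_m = pd.Series(mut).rank().to_numpy()
        rho_expected = np.corrcoef(r_e, r_m)[0, 1]
        assert results[0].rho == pytest.approx(rho_expected, abs=1e-12)

    def test_constant_mutation_skipped(self, rng):
        ids, genes, expr = _concordance_setup(rng)
        gm = MutationMatrix("gene", pd.DataFrame({"g0": np.zeros(10, dtype=int)}, index=ids))
        results, skipped = mutation_expression_concordance(expr, gm, 0.2)
        assert results == []
        assert skipped == 1

    def test_null_selection_rare(self, rng):
        n, n_genes = 34, 2000
        ids = [f"s{i}" for i in range(n)]
        ann = [SampleAnnotation(i, "utah", True, "BRCAX", False) for i in ids]
        genes = [f"g{j}" for j in range(n_genes)]
        expr = ExpressionCohort(
            pd.DataFrame(rng.standard_normal((n, n_genes)), index=ids, columns=genes), ann
        )
        gm = MutationMatrix(
            "gene",
            pd.DataFrame((rng.random((n, n_genes)) < 0.2).astype(np.int8), index=ids, columns=genes),
        )
        results, _ = mutation_expression_concordance(expr, gm, fdr_cutoff=0.2)
        frac = np.mean([r.selected for r in results])
        assert frac < 0.01

    def test_too_few_shared_samples_rejected(self, rng):
        ids, genes, expr = _concordance_setup(rng, n=10)
        gm = MutationMatrix("gene", pd.DataFrame({"g0": [1, 0]}, index=ids[:2]))
        with pytest.raises(ValueError, match="shared samples"):
            mutation_expression_concordance(expr, gm, 0.2)


class TestEvidenceFromTables:
    def test_builds_flags_and_qvalues(self, rng):
        P = pd.DataFrame(rng.random((30, 2)), columns=["d1", "d2"])
        P.iloc[0, 1] = np.nan
        records = evidence_from_tables(P, flags={"0": {"treatment_effect"}})
        by_name = {r.pathway: r for r in records}
        assert "missing_in_dataset" in by_name["0"].flags
        assert "treatment_effect" in by_name["0"].flags
        finite_q = [r.q_value for r in records if not np.isnan(r.q_value)]
        assert all(0 <= q <= 1 for q in finite_q)
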