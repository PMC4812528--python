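import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from pathrisk.gene_sets import GeneSet, GeneSetCollection
from pathrisk.variants import (
    AnnotatedVariant,
    MutationMatrix,
    VariantFilterConfig,
    barnard_test,
    collapse_to_genes,
    collapse_to_pathways,
    exclude_frequent_genes,
    filter_variants,
    pathway_mutation_association,
    read_exon_bed,
    read_variants_tsv,
    select_frequency_threshold,
    write_variants_tsv,
)


def mkvar(**kw):
    base = dict(
        chrom="1", pos=100, ref="C", alt="T", gene="G1", variant_class="SNV",
        severity="HIGH", is_missense=False, pop_af_max=0.001, background_af=0.001,
        deleterious_call="NA", in_exon_pad2=True, carriers=frozenset({"s1"}),
    )
    base.update(kw)
    return AnnotatedVariant(**base)


TOY_TABLE = [
    mkvar(pos=1, pop_af_max=0.02),                                      # (a) common in population
    mkvar(pos=2, ref="C", alt="CAT", variant_class="InDel"),            # (b) rare HIGH frameshift
    mkvar(pos=3, severity="MODERATE", is_missense=True,
          deleterious_call="neutral"),                                  # (c) neutral missense
    mkvar(pos=4, severity="MODERATE", variant_class="InDel",
          ref="CA", alt="C"),                                           # (d) MODERATE InDel
    mkvar(pos=5, in_exon_pad2=False),                                   # (e) intronic HIGH
    mkvar(pos=6, carriers=frozenset({f"s{i}" for i in range(2)})),      # (f) 20% of 10 samples
]


class TestFilterCascade:
    def test_toy_table_trace(self):
        retained, counts = filter_variants(TOY_TABLE, n_samples=10)
        assert len(retained) == 2
        assert {v.pos for v in retained} == {2, 4}
        assert list(counts.values()) == [1, 0, 1, 1, 1, 0]

    def test_counts_conserve(self, rng):
        variants = []
        for i in range(60):
            variants.append(
                mkvar(
                    pos=i + 1,
                    pop_af_max=float(rng.choice([0.001, 0.05])),
                    background_af=float(rng.choice([0.001, 0.1])),
                    severity=str(rng.choice(["HIGH", "MODERATE", "LOW", "MODIFIER"])),
                    variant_class=str(rng.choice(["SNV", "InDel"])),
                    is_missense=bool(rng.random() < 0.5),
                    deleterious_call=str(rng.choice(["deleterious", "neutral", "NA"])),
                    in_exon_pad2=bool(rng.random() < 0.8),
                    carriers=frozenset(f"s{j}" for j in rng.choice(10, rng.integers(0, 5), replace=False)),
                )
            )
        retained, counts = filter_variants(variants, n_samples=10)
        assert len(retained) + sum(counts.values()) == len(variants)

    def test_empty_carriers_pass_internal_rule(self):
        v = mkvar(carriers=frozenset())
        retained, counts = filter_variants([v], n_samples=10)
        assert counts["internal_freq"] == 0
        assert len(retained) == 1

    def test_missense_na_configurable(self):
        v = mkvar(severity="MODERATE", is_missense=True, deleterious_call="NA")
        _, counts = filter_variants([v], 10)
        assert counts["missense_na"] == 1
        kept, _ = filter_variants([v], 10, VariantFilterConfig(drop_missense_na=False))
        assert len(kept) == 1

    def test_default_thresholds(self):
        cfg = VariantFilterConfig()
        assert (cfg.maf_pop, cfg.maf_background, cfg.internal_freq_max) == (0.01, 0.03, 0.15)


class TestCollapse:
    def test_multiplicity_discarded(self):
        vs = [mkvar(pos=i + 1, gene="G1", carriers=frozenset({"s1"})) for i in range(3)]
        mm = collapse_to_genes(vs, ["s1", "s2"])
        assert mm.matrix.loc["s1", "G1"] == 1
        assert mm.matrix.loc["s2", "G1"] == 0

    def test_no_variants_all_zero(self):
        mm = collapse_to_genes([], ["s1", "s2"])
        assert mm.matrix.shape == (2, 0)

    def test_shared_variant_both_carriers(self):
        mm = collapse_to_genes([mkvar(carriers=frozenset({"s1", "s2"}))], ["s1", "s2", "s3"])
        assert mm.matrix["G1"].tolist() == [1, 1, 0]

    def test_pathway_or_semantics(self):
        coll = GeneSetCollection(
            sets=[
                GeneSet("P1", "", frozenset({"G1", "G2"})),
                GeneSet("P2", "", frozenset({"G2", "G3"})),
                GeneSet("P3", "", frozenset({"G9"})),
            ]
        )
        gm = MutationMatrix(
            "gene",
            pd.DataFrame({"G1": [0, 0], "G2": [1, 0], "G3": [0, 0]}, index=["s1", "s2"]),
        )
        pm = collapse_to_pathways(gm, coll)
        assert pm.matrix.loc["s1"].tolist() == [1, 1, 0]  # shared gene lights both
        assert pm.matrix.loc["s2"].tolist() == [0, 0, 0]

    def test_pathway_dominates_genes(self, rng):
        genes = [f"G{i}" for i in range(12)]
        gm = MutationMatrix(
            "gene",
            pd.DataFrame(rng.integers(0, 2, (8, 12)), index=[f"s{i}" for i in range(8)], columns=genes),
        )
        coll = GeneSetCollection(sets=[GeneSet("P", "", frozenset(genes[:6]))])
        pm = collapse_to_pathways(gm, coll)
        expected = gm.matrix[genes[:6]].max(axis=1)
        assert (pm.matrix["P"] == expected).all()


class TestFrequencyThreshold:
    def test_two_block_breakpoint(self):
        freqs = {f"L{i}": 0.001 for i in range(50)}
        freqs.update({f"H{i}": 0.05 for i in range(10)})
        t, curve = select_frequency_threshold(freqs, (0.002, 0.10), 50)
        # brute-force oracle: count-vs-threshold curve, largest adjacent drop
        ts = np.linspace(0.002, 0.10, 50)
        counts = [sum(1 for f in freqs.values() if f > x) for x in ts]
        drops = [counts[i] - counts[i + 1] for i in range(49)]
        expected = ts[int(np.argmax(drops))]
        assert t == expected
        assert (curve["n_excluded"].to_numpy() == counts).all()

    def test_uniform_tie_breaks_to_smallest(self):
        freqs = {f"G{i}": 0.5 for i in range(20)}
        t, _ = select_frequency_threshold(freqs, (0.002, 0.10), 25)
        assert t == 0.002

    def test_all_below_grid_warns(self):
        with pytest.warns(UserWarning):
            t, _ = select_frequency_threshold({"G1": 0.0001}, (0.002, 0.10), 10)
        assert t == 0.002


class TestExcludeFrequentGenes:
    @pytest.fixture
    def gm(self):
        return MutationMatrix(
            "gene",
            pd.DataFrame(
                {"BRCA1": [1], "G1": [1], "G2": [1], "G3": [1]}, index=["s1"]
            ),
        )

    def test_always_keep_overrides(self, gm):
        out = exclude_frequent_genes(gm, {"BRCA1": 0.05, "G1": 0.05}, threshold=0.018)
        assert "BRCA1" in out.matrix.columns
        assert "G1" not in out.matrix.columns

    def test_boundary_is_strict(self, gm):
        out = exclude_frequent_genes(gm, {"G2": 0.018}, threshold=0.018)
        assert "G2" in out.matrix.columns

    def test_missing_gene_retained(self, gm):
        out = exclude_frequent_genes(gm, {}, threshold=0.018)
        assert list(out.matrix.columns) == list(gm.matrix.columns)


_ORACLE_PMF_CACHE = {}


def _oracle_pmf(n, grid):
    if n not in _ORACLE_PMF_CACHE:
        _ORACLE_PMF_CACHE[n] = stats.binom.pmf(np.arange(n + 1)[:, None], n, grid[None, :])
    return _ORACLE_PMF_CACHE[n]


def barnard_oracle(a, n1, b, n2, direction="greater"):
    """Plain-loop enumeration oracle: score statistic, dense nuisance grid,
    bounded local refinement around the best grid point."""
    def score(x, y):
        p1, p2 = x / n1, y / n2
        pooled = (x + y) / (n1 + n2)
        den = (pooled * (1 - pooled) * (1 / n1 + 1 / n2)) ** 0.5
        return 0.0 if den == 0 else (p1 - p2) / den

    t_obs = score(a, b)
    extreme = []
    for x in range(n1 + 1):
        for y in range(n2 + 1):
            t = score(x, y)
            if (direction == "greater" and t >= t_obs) or (direction == "less" and t <= t_obs):
                extreme.append((x, y))

    from math import comb

    def total_prob(pi):
        out = 0.0
        for x, y in extreme:
            out += (
                comb(n1, x) * pi**x * (1 - pi) ** (n1 - x)
                * comb(n2, y) * pi**y * (1 - pi) ** (n2 - y)
            )
        return out

    grid = np.linspace(0.001, 0.999, 999)
    pmf1 = _oracle_pmf(n1, grid)
    pmf2 = _oracle_pmf(n2, grid)
    vals = np.zeros(len(grid))
    for x, y in extreme:
        vals += pmf1[x] * pmf2[y]
    i = int(np.argmax(vals))
    lo = grid[i - 1] if i > 0 else 1e-12
    hi = grid[i + 1] if i < len(grid) - 1 else 1 - 1e-12
    res = optimize.minimize_scalar(lambda pi: -total_prob(pi), bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-12})
    return min(1.0, max(vals[i], -res.fun))


class TestBarnard:
    def test_null_table_p_one(self):
        assert barnard_test(0, 5, 0, 5) == pytest.approx(1.0, abs=1e-6)

    def test_matches_enumeration_oracle(self):
        assert barnard_test(3, 5, 0, 5, "greater") == pytest.approx(
            barnard_oracle(3, 5, 0, 5, "greater"), abs=1e-9
        )

    def test_wrong_direction_large_p(self):
        assert barnard_test(0, 5, 3, 5, "greater") >= 0.5

    def test_small_sweep_against_oracle_and_scipy(self):
        for n1, n2 in [(3, 3), (4, 2), (5, 5)]:
            for a in range(n1 + 1):
                for b in range(n2 + 1):
                    p = barnard_test(a, n1, b, n2, "greater")
                    assert p == pytest.approx(barnard_oracle(a, n1, b, n2, "greater"), abs=1e-6)
                    sp = stats.barnard_exact(
                        [[a, b], [n1 - a, n2 - b]], alternative="greater"
                    ).pvalue
                    assert p == pytest.approx(sp, abs=1e-6)

    def test_monotone_in_cases(self):
        ps = [barnard_test(a, 8, 2, 8, "greater") for a in range(9)]
        assert all(ps[i + 1] <= ps[i] + 1e-12 for i in range(8))

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            barnard_test(6, 5, 0, 5)


class TestPathwayAssociation:
    def test_all_zero_pathway_p_one(self):
        pm = MutationMatrix("pathway", pd.DataFrame({"P1": [0] * 10}, index=[f"s{i}" for i in range(10)]))
        res = pathway_mutation_association(pm, [1] * 5 + [0] * 5)
        assert res["p"].iloc[0] == 1.0

    def test_enriched_pathway_significant(self):
        col = [1] * 8 + [0] * 2 + [0] * 10  # 8/10 cases vs 0/10 controls
        pm = MutationMatrix("pathway", pd.DataFrame({"P1": col}, index=[f"s{i}" for i in range(20)]))
        res = pathway_mutation_association(pm, [1] * 10 + [0] * 10)
        assert res["p"].iloc[0] < 0.01
        assert res["p"].iloc[0] == pytest.approx(barnard_oracle(8, 10, 0, 10), abs=1e-6)

    def test_each_direction_symmetric_table(self):
        col = [1, 1, 0, 0, 1, 1, 0, 0]
        pm = MutationMatrix("pathway", pd.DataFrame({"P1": col}, index=[f"s{i}" for i in range(8)]))
        res = pathway_mutation_association(pm, [1, 1, 1, 1, 0, 0, 0, 0], mode="each-direction")
        assert res["p_greater"].iloc[0] == pytest.approx(res["p_less"].iloc[0])

    def test_null_calibration_conservative(self, rng):
        n_pw = 150
        M = (rng.random((30, n_pw)) < 0.3).astype(np.int8)
        pm = MutationMatrix("pathway", pd.DataFrame(M, index=[f"s{i}" for i in range(30)]))
        res = pathway_mutation_association(pm, [1] * 15 + [0] * 15)
        frac = (res["p"] <= 0.05).mean()
        se = np.sqrt(0.05 * 0.95 / n_pw)
        assert frac <= 0.05 + 2 * se  # exact tests are conservative


class TestIO:
    def test_tsv_round_trip(self, tmp_path):
        path = tmp_path / "v.tsv"
        write_variants_tsv(TOY_TABLE, path)
        back = read_variants_tsv(path)
        assert back == TOY_TABLE

    def test_exon_bed_padding(self, tmp_path):
        bed = tmp_path / "exons.bed"
        bed.write_text("chr1\t99\t200\nchr2\t0\t10\n")
        iv = read_exon_bed(bed, pad=2)
        # BED 0-based half-open [99,200) -> 1-based [100,200], padded -> [98,202]
        assert iv["chr1"] == [(98, 202)]
        assert iv["chr2"] == [(-1, 12)]
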