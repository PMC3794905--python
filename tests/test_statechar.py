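import itertools
from math import comb

import numpy as np
import pytest

from chromstates import statechar as sc
from chromstates.grid import WindowGrid
from chromstates.tracks_io import GeneModel


class TestMrtByState:
    def test_identical_samples(self):
        mrt = np.tile([0.2, 0.4, 0.6], 2)
        labels = np.repeat(["C1", "C2"], 3)
        summary, tests = sc.mrt_by_state(mrt, labels)
        assert tests.iloc[0]["p"] == pytest.approx(1.0, abs=1e-9)

    def test_rank_sum_equals_enumeration_oracle(self):
        """W for {1,2,3} vs {4,5,6} equals the exhaustive-arrangement oracle."""
        x, y = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        _, tests = sc.mrt_by_state(
            np.array(x + y) / 10, np.array(["C1"] * 3 + ["C2"] * 3)
        )
        W = tests.iloc[0]["rank_sum"]
        # oracle: rank-sum of the first sample over the pooled ranking
        pooled = sorted(x + y)
        W_oracle = sum(pooled.index(v) + 1 for v in x)
        assert W == W_oracle == 6
        # exhaustive null: 20 arrangements of which exactly 1 is as extreme low
        sums = sorted(
            sum(c) for c in itertools.combinations(range(1, 7), 3)
        )
        assert len(sums) == comb(6, 3) == 20
        assert sums.count(6) == 1  # the observed arrangement is the minimum

    def test_mean_mrt_increases_across_states(self, small_genome):
        summary, _ = sc.mrt_by_state(small_genome.mrt, small_genome.true_states)
        means = summary.set_index("state")["mean"]
        assert means["C1"] < means["C2"] < means["C3"] < means["C4"]

    def test_tiny_state_excluded_from_tests(self):
        mrt = np.array([0.1, 0.2, 0.3, 0.9])
        labels = np.array(["C1", "C1", "C1", "C2"])
        _, tests = sc.mrt_by_state(mrt, labels)
        assert len(tests) == 0


def _toy_grid(n=10, window=100_000):
    return WindowGrid.from_chrom_sizes({"chr1": n * window}, window)


class TestGeneStateTable:
    def test_all_genes_one_state(self):
        grid = _toy_grid()
        labels = np.array(["C1"] * 5 + ["C2"] * 5, dtype=object)
        genes = [
            GeneModel("chr1", s, s + 10_000, "+", [(s, s + 10_000)], name=f"g{s}")
            for s in (10_000, 210_000, 410_000)
        ]
        t = sc.gene_state_table(genes, labels, grid).set_index("state")
        assert t.loc["C1", "gene_fraction_pct"] == pytest.approx(100.0)
        assert t.loc["C2", "n_genes"] == 0

    def test_density_direct_count(self):
        grid = _toy_grid()
        labels = np.array(["C1"] * 10, dtype=object)  # territory = 1 Mb
        genes = [
            GeneModel("chr1", s, s + 5000, "+", [(s, s + 5000)], name=f"g{s}")
            for s in (100, 500_000)
        ]
        t = sc.gene_state_table(genes, labels, grid).set_index("state")
        assert t.loc["C1", "gene_density_per_mb"] == pytest.approx(2.0)

    def test_promoters_in_unclassified_windows_excluded(self):
        grid = _toy_grid()
        labels = np.array(["C1"] * 5 + ["D"] * 5, dtype=object)
        genes = [
            GeneModel("chr1", 100, 5000, "+", [(100, 5000)], name="a"),
            GeneModel("chr1", 600_000, 605_000, "+", [(600_000, 605_000)], name="b"),
        ]
        t = sc.gene_state_table(genes, labels, grid).set_index("state")
        assert t.loc["C1", "gene_fraction_pct"] == pytest.approx(100.0)
        assert t["n_genes"].sum() == 1

    def test_against_interval_arithmetic_oracle(self, rng):
        """Fractions/densities/coverage agree with a base-wise boolean oracle."""
        window = 1000
        n = 50
        grid = WindowGrid.from_chrom_sizes({"chr1": n * window}, window)
        labels = rng.choice(["C1", "C2", "C3", "C4", "D"], size=n).astype(object)
        genes = []
        for i in range(30):
            s = int(rng.integers(0, n * window - 200))
            e = s + int(rng.integers(100, 5000))
            e = min(e, n * window)
            genes.append(GeneModel("chr1", s, e, "+", [(s, e)], name=f"g{i}"))
        t = sc.gene_state_table(genes, labels, grid).set_index("state")
        # oracle: per-base state map and gene-body mask
        base_state = np.repeat(labels, window)
        body = np.zeros(n * window, dtype=bool)
        for g in genes:
            body[g.start:g.end] = True
        for s in ("C1", "C2", "C3", "C4"):
            territory = (base_state == s).sum()
            tss_count = sum(1 for g in genes if base_state[g.tss] == s)
            if territory:
                assert t.loc[s, "gene_density_per_mb"] == pytest.approx(
                    tss_count / (territory / 1e6)
                )
                cov = body[base_state == s].mean() * 100
                assert t.loc[s, "gene_coverage_pct"] == pytest.approx(cov)
            assert t.loc[s, "n_genes"] == tss_count


class TestExpression:
    def test_binning_rule(self):
        grid = _toy_grid(2)
        labels = np.array(["C1", "C1"], dtype=object)
        g = GeneModel("chr1", 0, 1000, "+", [(0, 1000)], name="g", rpkm=10 ** 1.024)
        _, dens = sc.expression_by_state([g], labels, grid)
        assert dens.iloc[0]["bin_left"] == pytest.approx(1.00)

    def test_all_zero_rpkm_degenerate_cdf(self):
        grid = _toy_grid(2)
        labels = np.array(["C1", "C1"], dtype=object)
        genes = [
            GeneModel("chr1", i * 100, i * 100 + 50, "+", [(i * 100, i * 100 + 50)],
                      name=f"g{i}", rpkm=0.0)
            for i in range(3)
        ]
        cdfs, dens = sc.expression_by_state(genes, labels, grid)
        x, F = cdfs["C1"]
        assert (x == -3.0).all() and F[-1] == 1.0
        assert len(dens) == 0

    def test_expressed_density_highest_in_c1(self, small_genome):
        cdfs, dens = sc.expression_by_state(
            small_genome.genes, small_genome.true_states, small_genome.grid
        )
        per_state = dens.groupby("state")["promoter_density_per_mb"].sum()
        assert per_state.idxmax() == "C1"


class TestComposition:
    @pytest.mark.parametrize("seq,expected", [("GCGC", 1.0), ("ATAT", 0.0), ("ACGTN", 0.5)])
    def test_gc_content(self, seq, expected):
        assert sc.gc_content(seq) == pytest.approx(expected)

    def test_cpg_oe_hand_case(self):
        rec = sc.cpg_oe("CCGG")
        assert (rec.n_c, rec.n_g, rec.n_cg, rec.L, rec.l) == (2, 2, 1, 4, 1)
        assert rec.cpg_oe == pytest.approx((1 / 3) / 0.25)

    def test_no_cpg_dinucleotides(self):
        rec = sc.cpg_oe("CACACAGT")
        assert rec.cpg_oe == 0.0

    def test_mask_equals_run_splitting_oracle(self, rng):
        """Counts after masking equal independent counts over the unmasked runs."""
        seq = "".join(rng.choice(list("ACGT"), size=300))
        mask = [(40, 60), (100, 130), (131, 200)]
        rec = sc.cpg_oe(seq, mask)
        runs = [seq[0:40], seq[60:100], seq[130:131], seq[200:300]]
        assert rec.n_c == sum(r.count("C") for r in runs)
        assert rec.n_g == sum(r.count("G") for r in runs)
        assert rec.n_cg == sum(r.count("CG") for r in runs)
        assert rec.L == sum(len(r) for r in runs)
        assert rec.l == len(runs)

    def test_state_composition_recovers_targets(self, small_genome):
        comp = sc.composition_by_state(
            small_genome.sequences, small_genome.cgi_masks, small_genome.true_states
        ).set_index("state")
        spec = small_genome.spec
        for s in ("C1", "C2", "C3", "C4"):
            assert comp.loc[s, "gc"] == pytest.approx(spec.seq_params[s].gc, abs=0.005)
        oe = comp["cpg_oe"]
        assert oe["C1"] > oe["C2"] > oe["C3"] > oe["C4"]


def _hypergeom_two_sided(a, b, c, d):
    """Two-sided Fisher p by summation of point probabilities <= observed."""
    n1, n2, m = a + b, c + d, a + c
    total = comb(n1 + n2, m)
    p_obs = comb(n1, a) * comb(n2, c) / total
    p = 0.0
    for x in range(max(0, m - n2), min(n1, m) + 1):
        px = comb(n1, x) * comb(n2, m - x) / total
        if px <= p_obs * (1 + 1e-12):
            p += px
    return p


class TestEnrichment:
    def test_identical_proportions(self):
        gene_states = {f"g{i}": ("C1" if i < 10 else "C2") for i in range(20)}
        gene_terms = {f"g{i}": {"T"} for i in range(0, 20, 2)}
        df = sc.term_enrichment(gene_states, gene_terms, states=("C1", "C2"))
        row = df[(df.state == "C1") & (df.term == "T")].iloc[0]
        assert row["odds_ratio"] == pytest.approx(1.0)
        assert row["p"] == pytest.approx(1.0)

    def test_against_hypergeometric_oracle(self):
        # 2x2 table (8,2; 2,8): 10 genes in-state of which 8 carry the term
        gene_states = {f"g{i}": ("C1" if i < 10 else "C2") for i in range(20)}
        terms = {f"g{i}": {"T"} for i in list(range(8)) + [10, 11]}
        df = sc.term_enrichment(gene_states, terms, states=("C1", "C2"))
        row = df[(df.state == "C1") & (df.term == "T")].iloc[0]
        assert row["odds_ratio"] == pytest.approx(16.0)
        assert row["p"] == pytest.approx(_hypergeom_two_sided(8, 2, 2, 8), rel=1e-9)

    def test_q_values_dominate_p_values(self, rng):
        gene_states = {f"g{i}": rng.choice(["C1", "C2", "C3", "C4"]) for i in range(60)}
        gene_terms = {
            f"g{i}": {t for t in "ABC" if rng.random() < 0.3} for i in range(60)
        }
        df = sc.term_enrichment(gene_states, gene_terms)
        assert (df["q"] >= df["p"] - 1e-12).all()
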