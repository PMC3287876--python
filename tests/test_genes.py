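import math

import numpy as np
import pytest

from bfscreen.bayes import (
    PriorSpec,
    exhaustive_posterior,
    log_marginal_likelihood,
    make_snp_log_posterior,
    marginals_from_exhaustive,
)
from bfscreen.genes import (
    build_gene_design,
    gene_summary_from_snp_run,
    make_gene_log_posterior,
    run_gene_screen,
)
from bfscreen.io import GeneMap, GenotypeMatrix
from bfscreen.mcmc import InclusionSummary, marginal_inclusion, run_chain


def _toy_genes(seed=0, n=120, sizes=(3, 5, 1, 2), causal_gene=0, effect=1.0):
    """Small study where the first gene's variants carry all the signal."""
    rng = np.random.default_rng(seed)
    assignment = {}
    cols = []
    vids = []
    for g, size in enumerate(sizes):
        for j in range(size):
            vid = f"G{g}_v{j}"
            vids.append(vid)
            assignment[vid] = f"G{g}"
            cols.append(rng.binomial(2, 0.3, size=n))
    values = np.column_stack(cols).astype(np.int8)
    gm = GenotypeMatrix(values, vids, [f"I{i}" for i in range(n)])
    gene_map = GeneMap(assignment=assignment)
    start = sum(sizes[:causal_gene])
    y = values[:, start : start + sizes[causal_gene]].sum(axis=1) * effect
    y = y + rng.normal(size=n)
    return gm, gene_map, y - y.mean()


class TestGeneDesign:
    def test_column_count_adds_over_genes(self):
        gm, gene_map, _ = _toy_genes(sizes=(3, 5, 1, 2))
        d = build_gene_design(["G0", "G1"], gene_map, gm)
        assert d.k == 8
        assert d.block_sizes == [3, 5]
        assert np.all(np.abs(d.columns.mean(axis=0)) < 1e-10)

    def test_single_variant_gene_reduces_to_snp_design(self):
        gm, gene_map, _ = _toy_genes(sizes=(3, 5, 1, 2))
        d = build_gene_design(["G2"], gene_map, gm)
        from bfscreen.io import center_columns

        np.testing.assert_allclose(d.columns, center_columns(gm, [8]))

    def test_activation_order_does_not_change_evidence(self):
        gm, gene_map, y = _toy_genes()
        prior = PriorSpec(m=2, model_prior="size_penalized")
        a = build_gene_design(["G0", "G3"], gene_map, gm)
        b = build_gene_design(["G3", "G0"], gene_map, gm)
        ev_a = log_marginal_likelihood(y, a.columns, prior)
        ev_b = log_marginal_likelihood(y, b.columns, prior)
        assert ev_a.log_marginal == pytest.approx(ev_b.log_marginal, abs=1e-10)

    def test_unknown_gene_rejected(self):
        gm, gene_map, _ = _toy_genes()
        with pytest.raises(ValueError, match="unknown gene"):
            build_gene_design(["NOPE"], gene_map, gm)

    def test_unmapped_variant_rejected_in_gene_mode(self):
        gm, gene_map, _ = _toy_genes()
        del gene_map.assignment["G0_v0"]
        gene_map.gene_sizes["G0"] -= 1
        with pytest.raises(ValueError, match="missing from the gene map"):
            build_gene_design(["G1"], gene_map, gm)


class TestGeneSummaryFromSnpRun:
    def _summary(self, probs, ids):
        return InclusionSummary(np.asarray(probs, float), ids, m=2, p=len(ids))

    def test_ratio_arithmetic(self):
        """A 2-variant gene with posteriors (0.4, 0.0) under the full-scale
        prior 10/24,487 scores a ratio of ~489.7."""
        gene_map = GeneMap(assignment={"v1": "G", "v2": "G"})
        s = self._summary([0.4, 0.0], ["v1", "v2"])
        df = gene_summary_from_snp_run(s, gene_map, m=10, p=24487)
        ratio = df.loc[df.gene_id == "G", "posterior_prior_ratio"].iloc[0]
        assert ratio == pytest.approx(0.2 / (10 / 24487))
        assert ratio == pytest.approx(489.74, abs=0.01)

    def test_prior_level_gives_ratio_one(self):
        gene_map = GeneMap(assignment={"v1": "G", "v2": "G"})
        s = self._summary([10 / 24487] * 2, ["v1", "v2"])
        df = gene_summary_from_snp_run(s, gene_map, m=10, p=24487)
        assert df["posterior_prior_ratio"].iloc[0] == pytest.approx(1.0)

    def test_zero_posteriors_give_zero_ratio(self):
        gene_map = GeneMap(assignment={"v1": "G"})
        s = self._summary([0.0], ["v1"])
        df = gene_summary_from_snp_run(s, gene_map, m=10, p=24487)
        assert df["posterior_prior_ratio"].iloc[0] == 0.0

    def test_gene_without_summarised_variants_excluded(self):
        gene_map = GeneMap(assignment={"v1": "G1", "vX": "G2"})
        s = self._summary([0.4], ["v1"])
        with pytest.warns(UserWarning, match="no summarised variants"):
            df = gene_summary_from_snp_run(s, gene_map, m=2, p=10)
        assert df["gene_id"].tolist() == ["G1"]


class TestGeneScreen:
    def test_signal_gene_dominates_posterior(self):
        gm, gene_map, y = _toy_genes(sizes=(3, 2, 1, 2, 2, 1), effect=1.0)
        prior = PriorSpec(m=2, model_prior="size_penalized")
        summary, chain = run_gene_screen(
            gm, gene_map, y, prior, n_iter=10_000, burn_in=500, seed=1
        )
        assert summary.probabilities[summary.factor_ids.index("G0")] > 0.9
        assert summary.probabilities.sum() == pytest.approx(2.0, abs=1e-9)

    def test_chain_matches_exhaustive_gene_enumeration(self):
        gm, gene_map, y = _toy_genes(sizes=(3, 2, 1, 2, 2, 1), effect=0.4)
        prior = PriorSpec(m=2, model_prior="size_penalized")
        gene_ids = gene_map.genes
        log_post = make_gene_log_posterior(gm, gene_map, y, prior, gene_ids)
        from bfscreen.genes import _gene_column_index

        index = _gene_column_index(gene_map, gm)
        Xc = gm.values.astype(float)
        Xc -= Xc.mean(axis=0)

        def provider(active):
            cols = np.concatenate([index[gene_ids[i]] for i in active])
            return Xc[:, cols]

        models, probs = exhaustive_posterior(y, provider, len(gene_ids), 2, prior)
        exact = marginals_from_exhaustive(models, probs, len(gene_ids))
        chain = run_chain(log_post, len(gene_ids), 2, n_iter=40_000, burn_in=500, seed=2)
        emp = marginal_inclusion(chain, len(gene_ids)).probabilities
        assert np.max(np.abs(emp - exact)) < 0.03

    def test_size_penalty_favours_smaller_gene(self):
        """Two genes with identical evidence but sizes 1 vs 3: posterior odds
        e^{+1} for the small gene (prior odds exactly e^{-(k1-k2)/2})."""
        rng = np.random.default_rng(0)
        n = 80
        col = rng.binomial(2, 0.3, size=n).astype(np.int8)
        # gene A: one variant; gene B: the same variant plus two all-zero paddings
        values = np.column_stack([col, col, np.zeros(n), np.zeros(n)]).astype(np.int8)
        gm = GenotypeMatrix(values, ["a0", "b0", "b1", "b2"], [f"I{i}" for i in range(n)])
        gene_map = GeneMap(assignment={"a0": "A", "b0": "B", "b1": "B", "b2": "B"})
        y = rng.normal(size=n)
        y -= y.mean()
        prior = PriorSpec(m=1, model_prior="size_penalized")
        dA = build_gene_design(["A"], gene_map, gm)
        dB = build_gene_design(["B"], gene_map, gm)
        evA = log_marginal_likelihood(y, dA.columns, prior)
        with pytest.warns(UserWarning, match="all-zero column"):
            evB = log_marginal_likelihood(y, dB.columns, prior)
        # identical data columns -> identical fit, but k differs by 2
        assert evB.q_gamma == pytest.approx(evA.q_gamma, rel=1e-10)
        from bfscreen.bayes import log_model_posterior, ModelEvidence

        evB_equal = ModelEvidence(evA.log_marginal, evA.q_gamma, evA.log_det_penalty, 3, n)
        odds = math.exp(
            log_model_posterior(evA, prior) - log_model_posterior(evB_equal, prior)
        )
        assert odds == pytest.approx(math.exp(1.0), rel=1e-12)

    def test_reduces_to_snp_mode_for_singleton_genes(self):
        """Every gene holding one variant + uniform prior: the gene screen is
        the SNP screen (identical chains under the same seed)."""
        gm, gene_map, y = _toy_genes(sizes=(1, 1, 1, 1, 1, 1), effect=0.8)
        prior = PriorSpec(m=2, model_prior="uniform")
        gene_ids = gene_map.genes  # G0..G5 sorted = variant order
        gene_log_post = make_gene_log_posterior(gm, gene_map, y, prior, gene_ids)
        Xc = gm.values.astype(float)
        Xc -= Xc.mean(axis=0)
        snp_log_post = make_snp_log_posterior(Xc, y, prior)
        a = run_chain(gene_log_post, 6, 2, n_iter=3_000, burn_in=100, seed=21)
        b = run_chain(snp_log_post, 6, 2, n_iter=3_000, burn_in=100, seed=21)
        np.testing.assert_array_equal(a.visits, b.visits)

    def test_duplicate_genes_split_the_posterior(self):
        """Two genes with identical columns split what a deduplicated run
        gives to one; the pair's total stays between 1x and 2x of it."""
        rng = np.random.default_rng(5)
        n = 100
        sig = rng.binomial(2, 0.3, size=n).astype(np.int8)
        other = rng.binomial(2, 0.3, size=(n, 2)).astype(np.int8)
        y = 0.8 * sig + rng.normal(size=n)
        y -= y.mean()
        prior = PriorSpec(m=1, model_prior="uniform")

        def posterior(cols_list):
            Xs = [c.astype(float) - c.mean() for c in cols_list]
            models, probs = exhaustive_posterior(
                y, lambda a: Xs[a[0]][:, None], len(Xs), 1, prior
            )
            return marginals_from_exhaustive(models, probs, len(Xs))

        dedup = posterior([sig, other[:, 0], other[:, 1]])
        dup = posterior([sig, sig, other[:, 0], other[:, 1]])
        assert dup[0] == pytest.approx(dup[1], rel=1e-9)
        assert dedup[0] <= dup[0] + dup[1] <= 2 * dedup[0] + 1e-12

    def test_m_exceeding_gene_count_rejected(self):
        gm, gene_map, y = _toy_genes()
        prior = PriorSpec(m=10, model_prior="size_penalized")
        with pytest.raises(ValueError, match="gene count"):
            run_gene_screen(gm, gene_map, y, prior, n_iter=10, seed=0)
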