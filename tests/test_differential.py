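import numpy as np
import pandas as pd
import pytest

from rdna4c import ValidationError
from rdna4c.differential import (
    CountsMatrix,
    benjamini_hochberg,
    estimate_dispersion,
    round_half_up,
    run_differential,
    size_factors,
    volcano_counts,
    volcano_table,
    wald_test,
)


def matrix(rows, samples=("c1", "c2", "h1", "h2"), index=None):
    n_c = len(samples) // 2
    conditions = {
        s: ("control" if i < n_c else "heat_shock") for i, s in enumerate(samples)
    }
    idx = index or [f"g{i}" for i in range(len(rows))]
    return CountsMatrix(
        counts=pd.DataFrame(rows, index=idx, columns=list(samples)),
        conditions=conditions,
    )


def nb_matrix(rng, mu, alpha, n_genes, lfc=None):
    """NB counts for 2v2; optional per-gene log2 fold change in heat shock."""
    mu = np.broadcast_to(np.asarray(mu, dtype=float), (n_genes,)).copy()
    lfc = np.zeros(n_genes) if lfc is None else np.broadcast_to(lfc, (n_genes,))
    cols = []
    for cond in range(4):
        m = mu * (2.0 ** lfc if cond >= 2 else 1.0)
        if alpha == 0:
            cols.append(rng.poisson(m))
        else:
            r = 1 / alpha
            cols.append(rng.negative_binomial(r, r / (r + m)))
    return matrix(np.column_stack(cols))


class TestSizeFactors:
    def test_hand_computed_median_of_ratios(self):
        cm = matrix([[100, 200], [10, 20], [50, 100]], samples=("a", "b"))
        f = size_factors(cm)
        assert f["a"] == pytest.approx(1 / np.sqrt(2), abs=1e-4)
        assert f["b"] == pytest.approx(np.sqrt(2), abs=1e-4)

    def test_identical_columns_equal_factors(self):
        cm = matrix([[5, 5, 5, 5], [80, 80, 80, 80]])
        assert np.allclose(size_factors(cm), size_factors(cm).iloc[0])

    def test_single_gene_geometric_mean(self):
        cm = matrix([[4, 1]], samples=("a", "b"))
        f = size_factors(cm)
        assert f["a"] == pytest.approx(2.0)
        assert f["b"] == pytest.approx(0.5)

    def test_matches_pydeseq2(self):
        rng = np.random.default_rng(3)
        counts = rng.integers(1, 1000, size=(60, 4))
        cm = matrix(counts)
        ours = size_factors(cm).to_numpy()
        from pydeseq2.preprocessing import deseq2_norm

        _, theirs = deseq2_norm(pd.DataFrame(counts.T))  # samples x genes
        assert np.allclose(ours, np.asarray(theirs), rtol=1e-3)


class TestDispersion:
    def test_constant_counts_zero_dispersion(self):
        cm = matrix([[7, 7, 7, 7], [3, 3, 3, 3]])
        d = estimate_dispersion(cm, size_factors(cm))
        assert (d == 0).all()

    def test_poisson_counts_estimate_near_zero(self):
        rng = np.random.default_rng(5)
        cm = nb_matrix(rng, mu=200.0, alpha=0.0, n_genes=1000)
        d = estimate_dispersion(cm, size_factors(cm))
        se = d.std() / np.sqrt(len(d))
        assert abs(d.mean()) <= max(3 * se, 0.01)

    def test_nb_alpha_half_recovered_roughly(self):
        rng = np.random.default_rng(6)
        cm = nb_matrix(rng, mu=500.0, alpha=0.5, n_genes=1000)
        d = estimate_dispersion(cm, size_factors(cm))
        assert 0.3 <= d.mean() <= 0.7


class TestBenjaminiHochberg:
    def test_hand_example_all_equal(self):
        assert np.allclose(
            benjamini_hochberg(np.array([0.01, 0.02, 0.03, 0.04])), 0.04
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_step_up_brute_force_and_statsmodels(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=50)
        got = benjamini_hochberg(p)
        # brute-force step-up
        m = len(p)
        order = np.argsort(p)
        brute = np.empty(m)
        prev = 1.0
        for rank in range(m, 0, -1):
            idx = order[rank - 1]
            prev = min(prev, p[idx] * m / rank)
            brute[idx] = prev
        assert np.allclose(got, brute)
        from statsmodels.stats.multitest import multipletests

        _, sm_adj, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(got, sm_adj)

    def test_padj_at_least_p_and_monotone(self, rng):
        p = rng.uniform(size=200)
        adj = benjamini_hochberg(p)
        assert (adj >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestWald:
    def test_equal_means_give_null_result(self):
        cm = matrix([[50, 50, 50, 50], [100, 100, 100, 100]])
        res = run_differential(cm)
        assert np.allclose(res["log2fc"], 0)
        assert np.allclose(res["p"], 1)

    def test_all_zero_gene_flagged_untested(self):
        cm = matrix([[0, 0, 0, 0], [10, 12, 50, 60]])
        res = run_differential(cm)
        row = res.loc["g0"]
        assert not row["tested"]
        assert row["p"] == 1 and row["padj"] == 1 and row["log2fc"] == 0

    def test_planted_fourfold_changes_recovered(self):
        # 200 four-fold genes among 800 nulls, so normalization has a
        # majority of unchanged genes to anchor on
        rng = np.random.default_rng(9)
        lfc = np.where(np.arange(1000) < 200, 2.0, 0.0)
        cm = nb_matrix(rng, mu=500.0, alpha=0.05, n_genes=1000, lfc=lfc)
        res = run_differential(cm).sort_index()
        planted = [f"g{i}" for i in range(200)]
        med = res.loc[planted, "log2fc"].median()
        assert 1.7 <= med <= 2.3

    def test_scaling_one_sample_scales_factor_not_lfc(self):
        rng = np.random.default_rng(12)
        base = rng.integers(10, 1000, size=(80, 4))
        cm1 = matrix(base)
        scaled = base.copy()
        scaled[:, 0] *= 3
        cm2 = matrix(scaled)
        f1, f2 = size_factors(cm1), size_factors(cm2)
        # median-of-ratios: the scaled sample's factor grows by c^((n-1)/n)
        # because the gene-wise geometric means absorb a c^(1/n) share
        assert f2.iloc[0] / f1.iloc[0] == pytest.approx(3.0 ** 0.75)
        r1 = run_differential(cm1).sort_index()
        r2 = run_differential(cm2).sort_index()
        # invariance is exact up to the epsilon pseudo-count, which does not
        # rescale with the uniform c^(1/n) shift of the normalized means
        assert np.allclose(r1["log2fc"], r2["log2fc"], atol=5e-3)

    def test_lfc_sign_agrees_with_pydeseq2_on_strong_genes(self):
        rng = np.random.default_rng(21)
        lfc = np.where(np.arange(100) < 50, 2.0, -2.0)
        cm = nb_matrix(rng, mu=400.0, alpha=0.05, n_genes=100, lfc=lfc)
        ours = run_differential(cm).sort_index()
        import anndata as ad
        from pydeseq2.dds import DeseqDataSet
        from pydeseq2.ds import DeseqStats

        adata = ad.AnnData(
            X=cm.counts.T.to_numpy(),
            obs=pd.DataFrame(
                {"condition": [cm.conditions[s] for s in cm.counts.columns]},
                index=cm.counts.columns,
            ),
        )
        dds = DeseqDataSet(adata=adata, design="~condition", quiet=True)
        dds.deseq2()
        stats = DeseqStats(
            dds, contrast=["condition", "heat_shock", "control"], quiet=True
        )
        stats.summary()
        theirs = stats.results_df["log2FoldChange"]
        theirs.index = cm.counts.index
        assert (np.sign(ours["log2fc"]) == np.sign(theirs.loc[ours.index])).all()

    def test_requires_two_replicates_per_condition(self):
        with pytest.raises(ValidationError):
            run_differential(
                CountsMatrix(
                    counts=pd.DataFrame(
                        [[1, 2, 3]], index=["g"], columns=["a", "b", "c"]
                    ),
                    conditions={"a": "control", "b": "control", "c": "heat_shock"},
                )
            )


class TestVolcano:
    def frame(self, rows):
        return pd.DataFrame(rows, columns=["log2fc", "padj"]).assign(p=lambda d: d.padj)

    def test_all_nonsignificant_when_p_one(self):
        t = volcano_table(self.frame([[3.0, 1.0], [-3.0, 1.0]]))
        assert volcano_counts(t) == {"up": 0, "down": 0, "not-significant": 2}

    def test_clear_up_call(self):
        t = volcano_table(self.frame([[3.0, 0.001]]), lfc_cut=1, padj_cut=0.05)
        assert t["class"].tolist() == ["up"]

    def test_counts_match_brute_force(self, rng):
        frame = self.frame(
            np.column_stack([rng.normal(0, 2, 300), rng.uniform(size=300)])
        )
        t = volcano_table(frame, lfc_cut=1, padj_cut=0.05)
        up = ((frame["log2fc"] > 1) & (frame["padj"] < 0.05)).sum()
        down = ((frame["log2fc"] < -1) & (frame["padj"] < 0.05)).sum()
        assert volcano_counts(t)["up"] == up
        assert volcano_counts(t)["down"] == down


def test_round_half_up():
    assert round_half_up(np.array([0.5, 1.4, 1.5, 2.5])).tolist() == [1, 1, 2, 3]
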