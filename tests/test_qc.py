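"""QC rules, normalization, TF-IDF/LSI, gene activity, consensus peaks."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from hypothesis import given, settings, strategies as st
from scipy import stats

from regnet.qc import (
    AtacQcThresholds, RnaQcThresholds, consensus_peaks, gene_activity,
    lognormalize, qc_atac, qc_rna, tfidf_lsi,
)


def _adata_from_counts(X, donors=None):
    X = sp.csr_matrix(np.asarray(X))
    obs = pd.DataFrame(index=[f"c{i}" for i in range(X.shape[0])])
    if donors is not None:
        obs["donor"] = donors
    var = pd.DataFrame(index=[f"g{j}" for j in range(X.shape[1])])
    return ad.AnnData(X=X, obs=obs, var=var)


class TestRnaQc:
    def test_feature_percentile_cut_matches_linear_interpolation(self):
        """Cells with 1..100 detected features: P1/P99 (type 7) keep 98."""
        n = 100
        X = np.zeros((n, 101))
        for i in range(n):
            X[i, : i + 1] = 1  # cell i detects i+1 features
        kept, _ = qc_rna(_adata_from_counts(X))
        lo = np.percentile(np.arange(1, 101), 1)   # 1.99
        hi = np.percentile(np.arange(1, 101), 99)  # 99.01
        expected = [f"c{i}" for i in range(n) if lo <= i + 1 <= hi]
        assert kept == expected
        assert len(kept) == 98

    def test_no_mito_exclusions_when_all_zero(self):
        X = np.ones((50, 10))
        adata = _adata_from_counts(X)
        kept, filtered = qc_rna(adata, mito_gene_ids=set())
        assert len(kept) == 50

    def test_mito_floor_applies_when_p95_below_5pct(self):
        """P95 of mito fraction 0.03 -> the applied cut is the 0.05 floor."""
        rng = np.random.default_rng(0)
        n = 200
        X = np.zeros((n, 11))
        X[:, :10] = rng.poisson(5, (n, 10)) + 1
        totals = X[:, :10].sum(1)
        mito_frac = np.full(n, 0.02)
        mito_frac[:8] = 0.045          # P95 ~ 0.045 < 0.05
        mito_frac[0] = 0.049           # above P95 but under the floor: kept
        X[:, 10] = np.round(totals * mito_frac / (1 - mito_frac))
        adata = _adata_from_counts(X)
        adata.var["is_mito"] = [False] * 10 + [True]
        kept, filtered = qc_rna(adata, mito_gene_ids={"g10"})
        cut = filtered.uns["qc_cutoffs"]["all"][2]
        assert cut == 0.05
        assert "c0" in kept
        # mito genes dropped from the retained matrix
        assert "g10" not in filtered.var_names

    def test_empty_matrix_rejected(self):
        adata = _adata_from_counts(np.ones((1, 3)))[:0]
        with pytest.raises(ValueError, match="empty"):
            qc_rna(adata)

    def test_idempotent_with_frozen_cutoffs(self, small_rna):
        adata, _ = small_rna
        kept, filtered = qc_rna(adata)
        cuts = filtered.uns["qc_cutoffs"]
        kept2, _ = qc_rna(filtered, mito_gene_ids=set(), fixed_cutoffs=cuts)
        assert kept2 == list(filtered.obs_names)


class TestAtacQc:
    def _stats(self, **over):
        base = dict(nucleosome_signal=1.0, tss_enrichment=5.0, frip=0.4,
                    peak_fragments=5000, blacklist_fraction=0.0)
        base.update(over)
        rows = [dict(base) for _ in range(100)]
        t = pd.DataFrame(rows, index=[f"c{i}" for i in range(100)])
        return t

    @pytest.mark.parametrize(
        "column,value,excluded",
        [
            ("nucleosome_signal", 4.5, True),   # > 4 excluded
            ("nucleosome_signal", 4.0, False),
            ("tss_enrichment", 2.0, False),     # rule is strictly < 2
            ("tss_enrichment", 1.9, True),
            ("frip", 0.14, True),               # < 15% excluded
            ("peak_fragments", 999, True),      # < 1000 excluded
            ("peak_fragments", 1000, False),
            ("blacklist_fraction", 0.06, True),
        ],
    )
    def test_single_rule_boundaries(self, column, value, excluded):
        t = self._stats()
        t.loc["c0", column] = value
        kept = qc_atac(t)
        assert ("c0" not in kept) == excluded

    def test_upper_fragment_tail_removed_per_sample(self):
        t = self._stats()
        t["peak_fragments"] = np.arange(2000, 2100)
        kept = qc_atac(t)
        cut = np.percentile(t["peak_fragments"], 95)
        assert all(t.loc[c, "peak_fragments"] <= cut for c in kept)

    def test_missing_column_is_schema_error(self):
        t = self._stats().drop(columns=["frip"])
        with pytest.raises(KeyError, match="frip"):
            qc_atac(t)


class TestLognormalize:
    def test_closed_form_value(self):
        X = np.array([[9.0, 81.0]])  # depth 90
        out = lognormalize(X, scale=10).toarray()
        assert out[0, 0] == pytest.approx(np.log(2.0))

    def test_zero_vector_stays_zero_and_errors_on_zero_depth(self):
        with pytest.raises(ValueError, match="zero-depth"):
            lognormalize(np.array([[0.0, 0.0]]))

    @given(st.integers(2, 20), st.integers(1, 6))
    @settings(max_examples=20, deadline=None)
    def test_depth_scaling_invariance(self, n_feat, mult):
        rng = np.random.default_rng(n_feat * 7 + mult)
        row = rng.integers(1, 20, n_feat).astype(float)
        a = lognormalize(row[None, :]).toarray()
        b = lognormalize(mult * row[None, :]).toarray()
        assert np.allclose(a, b)

    def test_monotone_within_cell(self):
        row = np.array([[1.0, 5.0, 3.0, 5.0]])
        out = lognormalize(row).toarray()[0]
        order = np.argsort(row[0])
        assert np.all(np.diff(out[order]) >= 0)


class TestLsi:
    def test_rank_one_matrix_has_negligible_second_singular_value(self):
        u = np.random.default_rng(0).poisson(5, 30) + 1.0
        v = np.random.default_rng(1).poisson(3, 20) + 1.0
        X = np.outer(u, np.ones(20))  # depth-normalized TF is constant rows
        emb = tfidf_lsi(X, dims=3)
        assert emb.singular_values[1] / emb.singular_values[0] < 1e-8

    def test_depth_tracking_component_dropped(self, small_atac):
        adata, *_ = small_atac
        emb = tfidf_lsi(adata.X, dims=8, rho_drop=0.7)
        depth = np.asarray(sp.csr_matrix(adata.X).sum(axis=1)).ravel()
        for i in emb.dropped_components:
            rho = stats.spearmanr(emb.components[:, i], depth).statistic
            assert abs(rho) >= 0.7

    def test_duplicated_cells_embed_identically(self):
        rng = np.random.default_rng(2)
        X = rng.poisson(1.0, (40, 30))
        X[13] = X[7]
        emb = tfidf_lsi(X + (X.sum(1) == 0)[:, None], dims=5)
        assert np.allclose(emb.components[7], emb.components[13], atol=1e-8)


class TestGeneActivity:
    PEAKS = pd.DataFrame(
        dict(chrom=["chrS"] * 3, start=[1000, 3000, 5000],
             end=[1200, 3200, 5200], name=["p0", "p1", "p2"])
    )

    def test_strand_aware_window_and_halfopen_end(self):
        genes = pd.DataFrame(
            [
                dict(gene_id="gp", chrom="chrS", strand="+", tss=3400,
                     start_codon=3450, intron1_start=3600, intron1_end=3800),
                dict(gene_id="gm", chrom="chrS", strand="-", tss=1000,
                     start_codon=950, intron1_start=100, intron1_end=300),
            ]
        )
        X = np.array([[1.0, 2.0, 4.0]])
        act, names = gene_activity(X, self.PEAKS, genes)
        dense = act.toarray()[0]
        # plus gene window [1400, 3600): covers p1 only
        # minus gene window [800, 3000): covers p0 only; p1 starts at 3000 (excluded)
        assert names == ["gp", "gm"]
        assert dense[0] > 0 and dense[1] > 0
        ratio = np.expm1(dense[0]) / np.expm1(dense[1])
        assert ratio == pytest.approx(2.0)  # counts 2 vs 1 at equal depth

    def test_no_fragments_gives_zero_row(self):
        genes = pd.DataFrame(
            [dict(gene_id="g", chrom="chrS", strand="+", tss=3400,
                  start_codon=3450, intron1_start=3600, intron1_end=3800)]
        )
        act, names = gene_activity(np.zeros((2, 3)), self.PEAKS, genes)
        assert act.nnz == 0

    def test_gene_without_tss_skipped_with_warning(self):
        genes = pd.DataFrame(
            [dict(gene_id="g", chrom="chrS", strand="+", tss=np.nan,
                  start_codon=100, intron1_start=200, intron1_end=300)]
        )
        with pytest.warns(UserWarning, match="lacks a TSS"):
            act, names = gene_activity(np.ones((1, 3)), self.PEAKS, genes)
        assert names == []


class TestConsensusPeaks:
    def test_fisher_combination_matches_chi2_oracle(self):
        res = consensus_peaks(
            [[(("chr1", 100, 200), 1e-6)], [(("chr1", 150, 250), 1e-6)]]
        )
        assert len(res) == 1
        stat = -2 * np.log(1e-12)
        assert stat == pytest.approx(55.26, abs=0.01)
        # chi-square tail oracle: sf(x, 4) = exp(-x/2) * (1 + x/2)
        expected_p = np.exp(-stat / 2) * (1 + stat / 2)
        assert stats.chi2.sf(stat, 4) == pytest.approx(expected_p, rel=1e-9)
        assert expected_p == pytest.approx(2.86e-11, rel=0.01)
        assert res.loc[0, "neglog10_p"] == pytest.approx(-np.log10(expected_p))
        assert (res.loc[0, "start"], res.loc[0, "end"]) == (100, 250)

    def test_single_sample_peak_dropped(self):
        res = consensus_peaks(
            [[(("chr1", 100, 200), 1e-9)], [(("chr1", 500, 600), 1e-9)]]
        )
        assert len(res) == 0

    def test_all_p_one_dropped_at_fdr(self):
        res = consensus_peaks(
            [[(("chr1", 100, 200), 1.0)], [(("chr1", 150, 250), 1.0)]]
        )
        assert len(res) == 0

    def test_output_intervals_disjoint_and_sorted_input_not_required(self):
        calls = [
            [(("chr1", 500, 600), 1e-8), (("chr1", 100, 220), 1e-8)],
            [(("chr1", 150, 250), 1e-8), (("chr1", 550, 650), 1e-8)],
        ]
        res = consensus_peaks(calls)
        res = res.sort_values("start").reset_index(drop=True)
        assert (res["start"].iloc[1:].to_numpy()
                >= res["end"].iloc[:-1].to_numpy()).all()

    def test_malformed_inputs_rejected(self):
        with pytest.raises(ValueError, match="malformed"):
            consensus_peaks([[(("chr1", 200, 100), 0.5)]])
        with pytest.raises(ValueError, match="p-value"):
            consensus_peaks([[(("chr1", 100, 200), 0.0)]])
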