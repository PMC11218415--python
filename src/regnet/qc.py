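"""Per-nucleus QC, normalization, TF-IDF/LSI, gene activity, consensus peaks.

QC rules follow the study design they emulate: RNA nuclei outside the
1st-99th percentile of detected features or above the 95th percentile of
mitochondrial transcript fraction (floored at 5%) are removed and
mitochondrial genes dropped; ATAC nuclei are screened on nucleosome signal,
TSS enrichment, fraction of reads in peaks, peak-fragment depth (lower
bound plus a per-sample upper-tail cut), and blacklist fraction. All
percentiles are linear-interpolation (type 7). Intervals are 0-based
half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class RnaQcThresholds:
    feature_pct_low: float = 1.0
    feature_pct_high: float = 99.0
    mito_pct: float = 95.0
    mito_floor: float = 0.05

    def __post_init__(self):
        if not 0 <= self.feature_pct_low < self.feature_pct_high <= 100:
            raise ValueError("feature percentiles must satisfy 0 <= low < high <= 100")


@dataclass
class AtacQcThresholds:
    nucleosome_signal_max: float = 4.0
    tss_enrichment_min: float = 2.0
    frip_min: float = 0.15
    min_peak_fragments: int = 1000
    upper_fragment_pct: float = 95.0
    blacklist_max: float = 0.05


@dataclass
class LsiEmbedding:
    components: np.ndarray          # cells x dims, standardized
    singular_values: np.ndarray
    depth_correlations: np.ndarray  # Spearman rho vs per-cell depth
    dropped_components: list = field(default_factory=list)

    def retained(self) -> np.ndarray:
        keep = [i for i in range(self.components.shape[1])
                if i not in self.dropped_components]
        return self.components[:, keep]


def qc_rna(
    adata: ad.AnnData,
    mito_gene_ids: set[str] | None = None,
    th: RnaQcThresholds | None = None,
    sample_key: str = "donor",
    fixed_cutoffs: dict | None = None,
) -> tuple[list[str], ad.AnnData]:
    """Apply the RNA QC rules; returns (kept barcodes, filtered matrix).

    Feature-count percentiles are computed per sample; the mitochondrial
    cut is max(P95 of the mito fraction, the 5% floor). Mitochondrial genes
    are dropped from the retained matrix. The realized per-sample cutoffs
    are stored in ``filtered.uns["qc_cutoffs"]``; passing them back via
    ``fixed_cutoffs`` re-applies the frozen thresholds (idempotent).
    """
    if adata.n_obs == 0:
        raise ValueError("empty matrix")
    th = th or RnaQcThresholds()
    if mito_gene_ids is None:
        if "is_mito" in adata.var:
            mito_gene_ids = set(adata.var_names[adata.var["is_mito"].to_numpy(bool)])
        else:
            mito_gene_ids = set()
    if not set(mito_gene_ids) <= set(adata.var_names):
        raise ValueError("mito gene ids must be a subset of the features")

    X = sp.csr_matrix(adata.X)
    mito_mask = adata.var_names.isin(mito_gene_ids)
    # feature counts over non-mitochondrial genes, so that re-applying the
    # frozen cutoffs to the mito-stripped matrix is idempotent
    n_features = np.asarray((X[:, ~mito_mask] > 0).sum(axis=1)).ravel()
    totals = np.asarray(X.sum(axis=1)).ravel()
    mito_counts = np.asarray(X[:, mito_mask].sum(axis=1)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, mito_counts / np.maximum(totals, 1), 0.0)

    keep = np.ones(adata.n_obs, dtype=bool)
    samples = adata.obs[sample_key] if sample_key in adata.obs else pd.Series(
        "all", index=adata.obs_names
    )
    cutoffs = {}
    for s in pd.unique(samples):
        m = (samples == s).to_numpy()
        if fixed_cutoffs is not None and s in fixed_cutoffs:
            lo, hi, mito_cut = fixed_cutoffs[s]
        else:
            lo = np.percentile(n_features[m], th.feature_pct_low)
            hi = np.percentile(n_features[m], th.feature_pct_high)
            mito_cut = max(np.percentile(mito_frac[m], th.mito_pct), th.mito_floor)
        cutoffs[s] = (float(lo), float(hi), float(mito_cut))
        keep[m] &= (n_features[m] >= lo) & (n_features[m] <= hi)
        keep[m] &= mito_frac[m] <= mito_cut
    kept = list(adata.obs_names[keep])
    filtered = adata[keep, ~mito_mask].copy()
    filtered.uns["qc_cutoffs"] = cutoffs
    return kept, filtered


REQUIRED_ATAC_COLUMNS = [
    "nucleosome_signal", "tss_enrichment", "frip", "peak_fragments",
    "blacklist_fraction",
]


def qc_atac(
    stats_table: pd.DataFrame,
    th: AtacQcThresholds | None = None,
    sample_key: str = "donor",
) -> list[str]:
    """Apply the five ATAC QC rules conjunctively; returns kept barcodes."""
    th = th or AtacQcThresholds()
    missing = [c for c in REQUIRED_ATAC_COLUMNS if c not in stats_table.columns]
    if missing:
        raise KeyError(f"per-cell stats table lacks columns: {missing}")
    t = stats_table
    keep = (
        (t["nucleosome_signal"] <= th.nucleosome_signal_max)
        & (t["tss_enrichment"] >= th.tss_enrichment_min)
        & (t["frip"] >= th.frip_min)
        & (t["peak_fragments"] >= th.min_peak_fragments)
        & (t["blacklist_fraction"] <= th.blacklist_max)
    ).to_numpy()
    samples = t[sample_key] if sample_key in t.columns else pd.Series(
        "all", index=t.index
    )
    for s in pd.unique(samples):
        m = (samples == s).to_numpy()
        cut = np.percentile(t["peak_fragments"][m], th.upper_fragment_pct)
        keep[m] &= (t["peak_fragments"][m] <= cut).to_numpy()
    return list(t.index[keep])


def lognormalize(X, scale: float = 1e4) -> sp.csr_matrix:
    """x -> ln(1 + scale * x / depth), depth-invariant per cell."""
    X = sp.csr_matrix(X, dtype=float)
    depth = np.asarray(X.sum(axis=1)).ravel()
    if np.any(depth == 0):
        bad = list(np.where(depth == 0)[0])
        raise ValueError(f"zero-depth cells at rows {bad}")
    out = X.copy()
    out.data = out.data * (scale / depth[np.repeat(np.arange(X.shape[0]),
                                                  np.diff(X.indptr))])
    out.data = np.log1p(out.data)
    return out


def tfidf_lsi(X, dims: int = 15, rho_drop: float = 0.7) -> LsiEmbedding:
    """TF-IDF weighting + truncated SVD of a cell-by-peak matrix.

    TF is count over cell depth, IDF is ln(1 + n_cells / n_cells-with-peak).
    Left singular vectors are standardized; components whose |Spearman rho|
    against per-cell depth reaches ``rho_drop`` are flagged for dropping.
    """
    import warnings

    X = sp.csr_matrix(X, dtype=float)
    n_cells, n_peaks = X.shape
    if dims >= min(n_cells, n_peaks):
        raise ValueError("dims must be smaller than both matrix dimensions")
    peak_cells = np.asarray((X > 0).sum(axis=0)).ravel()
    empty = peak_cells == 0
    if np.any(empty):
        warnings.warn(f"excluding {int(empty.sum())} all-zero peaks from LSI")
        X = X[:, ~empty]
        peak_cells = peak_cells[~empty]
    depth = np.asarray(X.sum(axis=1)).ravel()
    tf = sp.diags(1.0 / np.maximum(depth, 1e-12)) @ X
    idf = np.log1p(n_cells / peak_cells)
    mat = tf @ sp.diags(idf)
    from scipy.sparse.linalg import svds

    U, S, Vt = svds(mat, k=dims)
    order = np.argsort(S)[::-1]
    U, S = U[:, order], S[order]
    comp = U * S
    sd = comp.std(axis=0)
    comp = np.where(sd > 0, (comp - comp.mean(axis=0)) / np.where(sd > 0, sd, 1), comp)
    rho = np.array(
        [stats.spearmanr(comp[:, i], depth).statistic for i in range(dims)]
    )
    dropped = [i for i in range(dims) if abs(rho[i]) >= rho_drop]
    return LsiEmbedding(comp, S, rho, dropped)


def gene_activity(
    peak_counts,
    peaks: pd.DataFrame,
    annotation: pd.DataFrame,
    upstream: int = 2000,
    downstream: int = 200,
    scale: float = 1e4,
) -> tuple[sp.csr_matrix, list[str]]:
    """Sum fragments in the strand-aware promoter window per gene.

    The window is [TSS - upstream, TSS + downstream) on the plus strand and
    [TSS - downstream, TSS + upstream) on the minus strand (half-open, so a
    fragment starting exactly at the end coordinate is not counted); peak
    counts are apportioned to genes by ≥1 bp overlap. The result is
    log-normalized like :func:`lognormalize`, with zero-depth cells kept as
    zero rows. Genes missing a TSS are skipped with a warning.
    """
    import warnings

    X = sp.csr_matrix(peak_counts, dtype=float)
    genes = []
    cols = []
    starts = peaks["start"].to_numpy()
    ends = peaks["end"].to_numpy()
    chroms = peaks["chrom"].to_numpy()
    for row in annotation.itertuples(index=False):
        if pd.isna(row.tss):
            warnings.warn(f"gene {row.gene_id} lacks a TSS; skipped")
            continue
        tss = int(row.tss)
        if row.strand == "+":
            w0, w1 = tss - upstream, tss + downstream
        else:
            w0, w1 = tss - downstream, tss + upstream
        hit = (chroms == row.chrom) & (starts < w1) & (ends > w0)
        genes.append(row.gene_id)
        cols.append(np.where(hit)[0])
    act = np.zeros((X.shape[0], len(cols)))
    for j, c in enumerate(cols):
        if len(c):
            act[:, j] = np.asarray(X[:, c].sum(axis=1)).ravel()
    depth = act.sum(axis=1)
    nz = depth > 0
    act[nz] = np.log1p(act[nz] * scale / depth[nz, None])
    return sp.csr_matrix(act), genes


def consensus_peaks(
    per_sample_peaks: list[list[tuple]],
    min_samples: int = 2,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Combine per-sample peak calls into a consensus set.

    Each element of ``per_sample_peaks`` is a sample's list of
    ((chrom, start, end), p_value). Overlapping intervals across samples are
    grouped by single-linkage on ≥1 bp overlap; member p-values are combined
    with Fisher's method (chi-square with 2m degrees of freedom); BH FDR is
    applied across groups; groups present in at least ``min_samples``
    samples with FDR <= ``fdr`` are kept, with the union as the consensus
    interval.
    """
    records = []
    for s, lst in enumerate(per_sample_peaks):
        for (chrom, start, end), p in lst:
            if not (np.isreal(start) and np.isreal(end)) or end <= start:
                raise ValueError(f"malformed interval {(chrom, start, end)}")
            if not 0 < p <= 1:
                raise ValueError(f"p-value {p} outside (0, 1]")
            records.append((chrom, int(start), int(end), float(p), s))
    if not records:
        return pd.DataFrame(
            columns=["chrom", "start", "end", "name", "neglog10_p", "n_samples"]
        )
    df = pd.DataFrame(records, columns=["chrom", "start", "end", "p", "sample"])
    df = df.sort_values(["chrom", "start", "end"]).reset_index(drop=True)

    groups = []
    cur_chrom, cur_end, cur_idx = None, -1, []
    for row in df.itertuples():
        if row.chrom != cur_chrom or row.start >= cur_end:
            if cur_idx:
                groups.append(cur_idx)
            cur_chrom, cur_end, cur_idx = row.chrom, row.end, [row.Index]
        else:
            cur_idx.append(row.Index)
            cur_end = max(cur_end, row.end)
    if cur_idx:
        groups.append(cur_idx)

    rows = []
    for gi, idx in enumerate(groups):
        sub = df.loc[idx]
        stat = -2.0 * np.sum(np.log(sub["p"]))
        p_comb = stats.chi2.sf(stat, 2 * len(idx))
        rows.append(
            dict(
                chrom=sub["chrom"].iloc[0],
                start=int(sub["start"].min()),
                end=int(sub["end"].max()),
                name=f"consensus_{gi:05d}",
                p=p_comb,
                n_samples=sub["sample"].nunique(),
            )
        )
    out = pd.DataFrame(rows)
    out["fdr"] = multipletests(out["p"], method="fdr_bh")[1]
    out = out[(out["n_samples"] >= min_samples) & (out["fdr"] <= fdr)]
    out["neglog10_p"] = -np.log10(np.clip(out.pop("p"), 1e-300, None))
    return out.reset_index(drop=True)[
        ["chrom", "start", "end", "name", "neglog10_p", "n_samples", "fdr"]
    ]
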