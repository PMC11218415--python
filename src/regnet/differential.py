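"""Covariate selection and differential expression / accessibility.

Covariates are chosen iteratively from donor-level pseudobulk: principal
components explaining more than 10% of variance are regressed on every
candidate metadata variable; while any association survives Bonferroni
correction, the variable most associated with the top-variance PC is
selected, all features are residualized on it, and the loop repeats.

Differential testing fits a per-feature negative-binomial mixed model
(donor random intercept, log-depth offset) and Wald-tests the diagnosis
coefficient; the reference level is the control group, so positive log2
fold changes mean up in disease. Features are pre-filtered to those
detected in at least 10% of cells in both groups. Calls require
FDR < 0.05 (BH within the tested feature set) and |log2FC| >= 0.2.
Cluster markers use a Wilcoxon rank-sum test on normalized values with
|log2FC| > 0.25 and FDR < 0.01.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .glmm import GlmmFit, fit_glmm

RNA_COVARIATES = ["age", "sex", "pmi", "n_nuclei", "median_genes_per_cell",
                  "mean_library_size"]
ATAC_COVARIATES = ["age", "sex", "pmi", "n_nuclei"]


@dataclass
class CovariateSelection:
    selected: list = field(default_factory=list)
    history: list = field(default_factory=list)  # per-iteration records


def pseudobulk(X, donors, feature_names=None) -> pd.DataFrame:
    """Donor-by-feature summed counts."""
    X = sp.csr_matrix(X)
    donors = pd.Series(donors).reset_index(drop=True)
    uniq = sorted(donors.unique())
    rows = [np.asarray(X[(donors == d).to_numpy()].sum(axis=0)).ravel() for d in uniq]
    return pd.DataFrame(rows, index=uniq, columns=feature_names)


def select_covariates(
    pseudo: pd.DataFrame,
    metadata: pd.DataFrame,
    var_threshold: float = 0.10,
    alpha: float = 0.05,
    zero_frac_max: float = 0.20,
    max_iter: int = 10,
) -> CovariateSelection:
    """Iteratively pick metadata variables that drive pseudobulk variance.

    ``pseudo`` is donors x features (raw sums); features with zeros in more
    than ``zero_frac_max`` of donors are removed, the rest are centered and
    scaled before each PCA pass.
    """
    import warnings

    keep = (pseudo == 0).mean(axis=0) <= zero_frac_max
    M = pseudo.loc[:, keep].to_numpy(dtype=float)
    M = np.log1p(M / M.sum(axis=1, keepdims=True) * 1e6)  # depth-adjusted

    candidates = []
    meta = metadata.set_index("donor") if "donor" in metadata else metadata
    meta = meta.reindex(pseudo.index)
    for c in meta.columns:
        v = meta[c]
        if v.dtype == object or isinstance(v.dtype, pd.CategoricalDtype):
            codes = pd.Categorical(v).codes.astype(float)
            if len(np.unique(codes)) < 2:
                warnings.warn(f"constant metadata variable {c!r} excluded")
                continue
            candidates.append((c, codes))
        else:
            arr = pd.to_numeric(v, errors="coerce").to_numpy(dtype=float)
            if np.nanstd(arr) == 0:
                warnings.warn(f"constant metadata variable {c!r} excluded")
                continue
            candidates.append((c, arr))

    sel = CovariateSelection()
    R = M.copy()
    for it in range(max_iter):
        Z = (R - R.mean(axis=0)) / np.where(R.std(axis=0) > 0, R.std(axis=0), 1.0)
        U, S, Vt = np.linalg.svd(Z, full_matrices=False)
        var_frac = S**2 / np.sum(S**2)
        pcs = np.where(var_frac > var_threshold)[0]
        if len(pcs) == 0:
            break
        n_tests = len(pcs) * max(len(candidates), 1)
        record = dict(iteration=it, var_fracs=var_frac[pcs].tolist(), tests=[])
        best = None  # (q, var, slope) for top-variance PC association
        any_sig = False
        for pc in pcs:
            y = U[:, pc] * S[pc]
            for name, x in candidates:
                if name in sel.selected:
                    continue
                m = np.isfinite(x)
                res = stats.linregress(x[m], y[m])
                q = min(res.pvalue * n_tests, 1.0)
                record["tests"].append(dict(pc=int(pc), variable=name,
                                            p=res.pvalue, q=q))
                if q < alpha:
                    any_sig = True
                    if pc == pcs[0] and (best is None or q < best[0]):
                        best = (q, name, x)
        sel.history.append(record)
        if not any_sig:
            break
        if best is None:
            # significance only on lower PCs: take the strongest overall
            t = min((t for t in record["tests"] if t["q"] < alpha),
                    key=lambda t: t["q"])
            name = t["variable"]
            x = dict(candidates)[name]
        else:
            _, name, x = best
        sel.selected.append(name)
        xm = np.where(np.isfinite(x), x, np.nanmean(x))
        xc = (xm - xm.mean())
        denom = xc @ xc
        R = R - np.outer(xc, (xc @ R) / denom)
    return sel


@dataclass
class DifferentialResult:
    """Per-feature differential table plus the underlying fit."""

    table: pd.DataFrame  # feature, log2fc, p, fdr, frac_case, frac_ctrl, ...
    fit: GlmmFit | None = None


def nb_glmm_de(
    X,
    feature_names,
    cell_metadata: pd.DataFrame,
    covariates: list[str] = (),
    diagnosis_col: str = "diagnosis",
    reference_level: str = "Normal",
    donor_col: str = "donor",
    min_frac: float = 0.10,
) -> DifferentialResult:
    """NB mixed-model differential test of each feature on diagnosis.

    Counts are modeled with a log link, fixed diagnosis + covariate
    effects, a log per-cell-depth offset, and a donor random intercept.
    Returns every tested feature with log2FC = beta_diagnosis / ln 2,
    Wald p, and BH FDR across tested features.
    """
    X = sp.csr_matrix(X)
    n = X.shape[0]
    meta = cell_metadata.reset_index(drop=True)
    is_case = (meta[diagnosis_col] != reference_level).to_numpy().astype(float)
    if len(np.unique(meta.loc[is_case == 1, donor_col])) < 2 or len(
        np.unique(meta.loc[is_case == 0, donor_col])
    ) < 2:
        raise ValueError("need at least 2 donors per diagnosis group")

    detected = (X > 0).astype(np.int8)
    frac_case = np.asarray(detected[is_case == 1].mean(axis=0)).ravel()
    frac_ctrl = np.asarray(detected[is_case == 0].mean(axis=0)).ravel()
    tested = (frac_case >= min_frac) & (frac_ctrl >= min_frac)

    depth = np.asarray(X.sum(axis=1)).ravel()
    offset = np.log(np.maximum(depth, 1.0) / np.median(depth))
    cols = [np.ones(n), is_case]
    names = ["intercept", "diagnosis"]
    for c in covariates:
        v = pd.to_numeric(pd.Categorical(meta[c]).codes if meta[c].dtype == object
                          else meta[c], errors="coerce").to_numpy(dtype=float)
        if np.nanstd(v) == 0:
            continue
        cols.append((v - np.nanmean(v)) / np.nanstd(v))
        names.append(c)
    Xd = np.column_stack(cols)

    Y = np.asarray(X[:, tested].todense(), dtype=float).T
    fit = fit_glmm(Y, Xd, meta[donor_col].to_numpy(), offset=offset, columns=names)
    log2fc = fit.beta[:, 1] / np.log(2)
    p = fit.wald_p[:, 1].copy()
    # features degenerate after filtering (all-zero in one group) are flagged
    feats = np.asarray(feature_names)[tested]
    zero_one_group = np.asarray(
        (X[is_case == 1][:, tested].sum(axis=0) == 0)
        | (X[is_case == 0][:, tested].sum(axis=0) == 0)
    ).ravel()
    flagged = zero_one_group | ~fit.converged
    p[flagged] = np.nan
    fdr = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        fdr[ok] = multipletests(p[ok], method="fdr_bh")[1]
    table = pd.DataFrame(
        dict(
            feature=feats,
            log2fc=log2fc,
            p=p,
            fdr=fdr,
            frac_case=frac_case[tested],
            frac_ctrl=frac_ctrl[tested],
            sigma_donor2=fit.sigma2,
            phi=fit.phi,
            converged=fit.converged & ~zero_one_group,
            direction=np.where(log2fc >= 0, "up", "down"),
        )
    )
    return DifferentialResult(table=table, fit=fit)


def call_differential(
    result: DifferentialResult | pd.DataFrame,
    lfc_min: float = 0.2,
    fdr_max: float = 0.05,
) -> pd.DataFrame:
    """Threshold a differential table: |log2FC| >= lfc_min and FDR < fdr_max."""
    table = result.table if isinstance(result, DifferentialResult) else result
    called = table[
        (np.abs(table["log2fc"]) >= lfc_min) & (table["fdr"] < fdr_max)
    ].copy()
    called["direction"] = np.where(called["log2fc"] >= 0, "up", "down")
    return called.reset_index(drop=True)


def wilcoxon_markers(
    X_cluster,
    X_rest,
    feature_names,
    lfc_min: float = 0.25,
    fdr_max: float = 0.01,
) -> pd.DataFrame:
    """Wilcoxon rank-sum cluster markers on normalized values.

    log2FC is the log2 ratio of group means with pseudocount 1. Only
    features passing |log2FC| > lfc_min and FDR < fdr_max are returned,
    split into positive and negative markers by sign.
    """
    A = np.asarray(sp.csr_matrix(X_cluster).todense(), dtype=float)
    B = np.asarray(sp.csr_matrix(X_rest).todense(), dtype=float)
    if A.shape[0] < 3:
        raise ValueError("cluster has fewer than 3 cells")
    stat, p = stats.mannwhitneyu(A, B, axis=0, alternative="two-sided")
    l2fc = np.log2((A.mean(axis=0) + 1) / (B.mean(axis=0) + 1))
    fdr = multipletests(p, method="fdr_bh")[1]
    table = pd.DataFrame(
        dict(feature=feature_names, log2fc=l2fc, p=p, fdr=fdr)
    )
    out = table[(np.abs(table["log2fc"]) > lfc_min) & (table["fdr"] < fdr_max)].copy()
    out["marker_type"] = np.where(out["log2fc"] > 0, "positive", "negative")
    return out.reset_index(drop=True)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    return multipletests(np.asarray(p, dtype=float), method="fdr_bh")[1]
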