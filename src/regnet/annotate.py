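"""Cell-type annotation by label transfer, hybrid filtering, cluster
linking across modalities, and mixed-model composition testing.

Label transfer is a shared-embedding k-nearest-neighbor kernel vote: each
query cell receives a probability vector over reference labels, weighted by
a Gaussian kernel on embedding distance. Ambiguous nuclei — maximum
prediction score below 0.5 or a relative margin (x1 - x2)/x1 below 0.2
between the top two scores (the "hybrid score") — are removed as candidate
heterotypic multiplets. ATAC clusters are linked to RNA clusters by the
argmax of summed per-cell cluster prediction scores. Cluster-composition
differences between diagnosis groups are tested with a logistic mixed
model (donor random intercept), the mixed-effects association framework
used for single-cell composition analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors
from statsmodels.stats.multitest import multipletests

from .glmm import fit_glmm, lrt_pvalue


@dataclass
class PredictionScores:
    """Per-cell label probabilities plus the top-two summary scores."""

    scores: pd.DataFrame  # cells x labels, rows sum to 1
    x1: np.ndarray
    x2: np.ndarray

    @property
    def margin(self) -> np.ndarray:
        """Hybrid score (x1 - x2) / x1."""
        return (self.x1 - self.x2) / np.maximum(self.x1, 1e-300)


def prediction_scores(
    query_embedding: np.ndarray,
    reference_embedding: np.ndarray,
    reference_labels,
    k: int = 20,
) -> PredictionScores:
    """Gaussian-kernel-weighted kNN label frequencies per query cell."""
    ref = np.asarray(reference_embedding, dtype=float)
    qry = np.asarray(query_embedding, dtype=float)
    labels = pd.Categorical(reference_labels)
    if k < 1 or k > ref.shape[0]:
        raise ValueError(f"k={k} must lie in [1, n_reference={ref.shape[0]}]")
    nn = NearestNeighbors(n_neighbors=k).fit(ref)
    dist, idx = nn.kneighbors(qry)
    # bandwidth set per query cell to its kth-neighbor distance
    bw = np.maximum(dist[:, -1:], 1e-12)
    w = np.exp(-0.5 * (dist / bw) ** 2)
    w /= w.sum(axis=1, keepdims=True)
    cats = list(labels.categories)
    S = np.zeros((qry.shape[0], len(cats)))
    lab_idx = labels.codes[idx]
    for j in range(len(cats)):
        S[:, j] = np.sum(w * (lab_idx == j), axis=1)
    S /= S.sum(axis=1, keepdims=True)
    top2 = np.sort(S, axis=1)[:, ::-1][:, :2]
    return PredictionScores(
        scores=pd.DataFrame(S, columns=cats), x1=top2[:, 0], x2=top2[:, 1]
    )


def filter_hybrids(
    ps: PredictionScores, min_max: float = 0.5, min_margin: float = 0.2
) -> pd.DataFrame:
    """Drop low-confidence and hybrid cells; assign argmax labels to the rest.

    Returns a frame indexed like the score matrix with columns
    (kept, label, x1, margin).
    """
    margin = ps.margin
    keep = (ps.x1 >= min_max) & (margin >= min_margin - 1e-12)
    label = ps.scores.columns[np.argmax(ps.scores.to_numpy(), axis=1)]
    return pd.DataFrame(
        dict(kept=keep, label=label, x1=ps.x1, margin=margin), index=ps.scores.index
    )


def majority_annotate(cluster_assignments, cell_labels) -> pd.DataFrame:
    """Majority label per cluster with its fraction; ties break
    lexicographically and are flagged, as are clusters below 50% purity."""
    df = pd.DataFrame(dict(cluster=cluster_assignments, label=cell_labels))
    rows = []
    for cl, sub in df.groupby("cluster", observed=True):
        counts = sub["label"].value_counts()
        top = counts.max()
        winners = sorted(counts.index[counts == top])
        rows.append(
            dict(
                cluster=cl,
                majority_type=winners[0],
                fraction=top / len(sub),
                tie=len(winners) > 1,
                low_purity=top / len(sub) < 0.5 or len(winners) > 1,
            )
        )
    return pd.DataFrame(rows).set_index("cluster")


def link_clusters(
    atac_assignments, rna_cluster_scores: pd.DataFrame,
    atac_majority: pd.DataFrame | None = None,
    rna_majority: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Link each ATAC cluster to the RNA cluster with the largest summed
    per-cell prediction score; optionally flag cell-type concordance."""
    if len(rna_cluster_scores) == 0:
        raise ValueError("empty cluster score matrix")
    assign = pd.Series(atac_assignments, index=rna_cluster_scores.index)
    rows = []
    for cl, sub in rna_cluster_scores.groupby(assign, observed=True):
        if len(sub) == 0:
            raise ValueError(f"empty ATAC cluster {cl}")
        sums = sub.sum(axis=0)
        rna_cl = sums.idxmax()
        concordant = None
        if atac_majority is not None and rna_majority is not None:
            concordant = bool(
                atac_majority.loc[cl, "majority_type"]
                == rna_majority.loc[rna_cl, "majority_type"]
            )
        rows.append(
            dict(
                atac_cluster=cl, rna_cluster=rna_cl,
                score_sum=float(sums.max()), concordant_cell_type=concordant,
            )
        )
    return pd.DataFrame(rows).set_index("atac_cluster")


def cluster_cells(embedding: np.ndarray, k: int = 15, seed: int = 17,
                  resolution: float = 1.0) -> np.ndarray:
    """Louvain communities on the kNN graph of an embedding."""
    nn = NearestNeighbors(n_neighbors=min(k + 1, len(embedding))).fit(embedding)
    graph = nn.kneighbors_graph(mode="connectivity")
    g = nx.from_scipy_sparse_array(graph.maximum(graph.T))
    comms = nx.community.louvain_communities(g, seed=seed, resolution=resolution)
    out = np.empty(len(embedding), dtype=int)
    for i, c in enumerate(sorted(comms, key=lambda c: -len(c))):
        out[list(c)] = i
    return out


def composition_test(
    cell_clusters,
    cell_donors,
    donor_metadata: pd.DataFrame,
    fixed_covariates: list[str] = (),
    diagnosis_col: str = "diagnosis",
    reference_level: str = "Normal",
) -> pd.DataFrame:
    """Per-cluster mixed logistic test of membership on diagnosis.

    For each cluster, cell-level membership (in-cluster vs not) is modeled
    on diagnosis plus donor-level fixed covariates with a donor random
    intercept; the diagnosis p-value is a likelihood-ratio test between the
    full and the diagnosis-free fit, BH-corrected across clusters. Clusters
    absent from one diagnosis group are flagged unstable with p = NA.
    """
    clusters = pd.Series(cell_clusters).reset_index(drop=True)
    donors = pd.Series(cell_donors).reset_index(drop=True)
    meta = donor_metadata.set_index("donor") if "donor" in donor_metadata else donor_metadata
    diag = meta[diagnosis_col].reindex(donors).to_numpy()
    is_case = (diag != reference_level).astype(float)
    cols = [np.ones(len(donors)), is_case]
    names = ["intercept", "diagnosis"]
    for c in fixed_covariates:
        raw = meta[c].reindex(donors)
        if raw.dtype == object or isinstance(raw.dtype, pd.CategoricalDtype):
            v = pd.Categorical(raw).codes.astype(float)
        else:
            v = pd.to_numeric(raw, errors="coerce").to_numpy(dtype=float)
        sd = np.nanstd(v)
        if not np.isfinite(sd) or sd == 0:
            continue
        v = np.where(np.isfinite(v), v, np.nanmean(v))
        cols.append((v - v.mean()) / sd)
        names.append(c)
    X = np.column_stack(cols)
    Xr = np.delete(X, 1, axis=1)

    uniq = sorted(clusters.unique())
    Y = np.stack([(clusters == cl).to_numpy().astype(float) for cl in uniq])
    unstable = []
    for row, cl in zip(Y, uniq):
        present = {bool(b) for b in is_case[row > 0]}
        unstable.append(len(present) < 2)
    full = fit_glmm(Y, X, donors.to_numpy(), family="binomial", columns=names)
    red = fit_glmm(Y, Xr, donors.to_numpy(), family="binomial")
    p = lrt_pvalue(full, red, df=1)
    p = np.where(unstable, np.nan, p)
    out = pd.DataFrame(
        dict(
            cluster=uniq,
            odds_ratio=np.exp(full.beta[:, 1]),
            p=p,
            unstable=unstable,
        )
    )
    ok = out["p"].notna()
    out["fdr"] = np.nan
    if ok.any():
        out.loc[ok, "fdr"] = multipletests(out.loc[ok, "p"], method="fdr_bh")[1]
    return out.set_index("cluster")
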