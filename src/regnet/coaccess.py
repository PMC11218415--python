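"""Peak coaccessibility from metacell profiles.

Sparse cells are densified by summing counts over groups of k nearest
neighbors in an embedding (metacells, greedily seeded at far points and
deduplicated by member overlap). Within sliding genomic windows, a
graphical lasso with an elementwise penalty proportional to genomic
distance estimates the precision matrix of standardized peak profiles; the
coaccessibility score of a peak pair is the regularized partial
correlation -omega_ij / sqrt(omega_ii * omega_jj), averaged over the
windows covering the pair and defined as exactly 0 beyond the maximum
distance (500 kb). Cis-coaccessibility networks (CCANs) are Louvain
communities of the graph of edges with score >= 0.2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.neighbors import NearestNeighbors


@dataclass
class CoaccessConfig:
    k_neighbors: int = 50
    window_bp: int = 500_000
    score_min: float = 0.2
    distance_param: float | str = 0.25   # penalty scale s, or "auto"
    window_stride_bp: int = 250_000
    max_overlap_frac: float = 0.8
    base_penalty: float = 1e-3
    louvain_seed: int = 17
    resolution: float = 0.25

    def __post_init__(self):
        if self.window_stride_bp > self.window_bp:
            raise ValueError("stride must not exceed the window size")
        if not 0 < self.score_min < 1:
            raise ValueError("score_min must lie in (0, 1)")


def aggregate_metacells(
    embedding: np.ndarray,
    peak_counts,
    cfg: CoaccessConfig | None = None,
) -> np.ndarray:
    """Sum counts over k-nearest-neighbor groups (metacells).

    Seeds are chosen greedily at the point farthest from all previous
    seeds; a metacell sharing more than ``max_overlap_frac`` of its members
    with an earlier one is discarded. Profiles are depth-normalized to the
    median metacell depth.
    """
    cfg = cfg or CoaccessConfig()
    emb = np.asarray(embedding, dtype=float)
    X = sp.csr_matrix(peak_counts)
    n = emb.shape[0]
    k = cfg.k_neighbors
    if k > n:
        raise ValueError(f"k={k} exceeds the number of cells ({n})")
    nn = NearestNeighbors(n_neighbors=k).fit(emb)
    _, idx = nn.kneighbors(emb)

    # greedy far-point seed sweep
    seeds = [0]
    d = np.linalg.norm(emb - emb[0], axis=1)
    order = [0]
    for _ in range(n - 1):
        nxt = int(np.argmax(d))
        order.append(nxt)
        d = np.minimum(d, np.linalg.norm(emb - emb[nxt], axis=1))

    kept_sets: list[set] = []
    profiles = []
    for s in order:
        members = set(idx[s])
        if any(len(members & prev) > cfg.max_overlap_frac * k for prev in kept_sets):
            continue
        kept_sets.append(members)
        profiles.append(np.asarray(X[idx[s]].sum(axis=0)).ravel())
    M = np.asarray(profiles, dtype=float)
    depth = M.sum(axis=1)
    M = M / np.maximum(depth, 1e-12)[:, None] * np.median(depth)
    return M


def glasso_penalized(S: np.ndarray, P: np.ndarray, tol: float = 1e-4,
                     max_sweeps: int = 200) -> np.ndarray:
    """Graphical lasso with an elementwise penalty matrix, by block
    coordinate descent over columns (lasso subproblems). Returns the
    precision estimate."""
    p = S.shape[0]
    S = S.copy()
    if np.linalg.cond(S + np.diag(P.diagonal())) > 1e12:
        warnings.warn("near-singular window covariance; ridge-jittering")
        S = S + 1e-4 * np.eye(p)
    W = S + np.diag(P.diagonal())
    idx = np.arange(p)
    off_scale = np.mean(np.abs(S - np.diag(np.diag(S)))) or 1.0
    for _ in range(max_sweeps):
        W_old = W.copy()
        for j in range(p):
            rest = idx != j
            W11 = W[np.ix_(rest, rest)]
            s12 = S[rest, j]
            rho = P[rest, j]
            b = np.linalg.solve(W11, W[rest, j])
            for _ in range(100):
                b_prev = b.copy()
                for k in range(p - 1):
                    r = s12[k] - W11[k] @ b + W11[k, k] * b[k]
                    b[k] = np.sign(r) * max(abs(r) - rho[k], 0.0) / W11[k, k]
                if np.max(np.abs(b - b_prev)) < 1e-6:
                    break
            W[rest, j] = W11 @ b
            W[j, rest] = W[rest, j]
        if np.mean(np.abs(W - W_old)) < tol * off_scale:
            break
    Theta = np.zeros_like(S)
    for j in range(p):
        rest = idx != j
        b = np.linalg.solve(W[np.ix_(rest, rest)], W[rest, j])
        tjj = 1.0 / max(W[j, j] - W[rest, j] @ b, 1e-12)
        Theta[j, j] = tjj
        Theta[rest, j] = -tjj * b
    return (Theta + Theta.T) / 2


def _partial_corr(Theta: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.clip(np.diag(Theta), 1e-12, None))
    pc = -Theta / np.outer(d, d)
    np.fill_diagonal(pc, 1.0)
    return pc


def _window_scores(M, pos, cfg, s_param):
    """Accumulate per-pair (sum, count) of window partial correlations."""
    n_peaks = len(pos)
    sums = {}
    counts = {}
    Z = (M - M.mean(axis=0))
    sd = Z.std(axis=0)
    ok = sd > 0
    Z[:, ok] = Z[:, ok] / sd[ok]
    lo = pos.min()
    hi = pos.max()
    w0 = lo - (lo - 0) % cfg.window_stride_bp
    starts = np.arange(w0, hi + 1, cfg.window_stride_bp)
    for ws in starts:
        sel = np.where((pos >= ws) & (pos < ws + cfg.window_bp) & ok)[0]
        if len(sel) < 2:
            continue
        S = Z[:, sel].T @ Z[:, sel] / Z.shape[0]
        d = np.abs(pos[sel][:, None] - pos[sel][None, :]) / cfg.window_bp
        P = s_param * d + cfg.base_penalty
        np.fill_diagonal(P, 0.0)
        pc = _partial_corr(glasso_penalized(S, P))
        for a in range(len(sel)):
            for b in range(a + 1, len(sel)):
                i, j = int(sel[a]), int(sel[b])
                if abs(pos[i] - pos[j]) > cfg.window_bp:
                    continue
                key = (i, j)
                sums[key] = sums.get(key, 0.0) + pc[a, b]
                counts[key] = counts.get(key, 0) + 1
    return sums, counts


def _auto_distance_param(M, pos, cfg) -> float:
    """Smallest s for which <=5% of pairs beyond 0.75 * window are nonzero."""
    far_frac_target = 0.05
    lo_s, hi_s = 0.01, 8.0

    def far_nonzero_frac(s):
        sums, counts = _window_scores(M, pos, cfg, s)
        far = [
            abs(v / counts[k]) > 1e-6
            for k, v in sums.items()
            if abs(pos[k[0]] - pos[k[1]]) > 0.75 * cfg.window_bp
        ]
        return np.mean(far) if far else 0.0

    if far_nonzero_frac(hi_s) > far_frac_target:
        return hi_s
    for _ in range(8):
        mid = np.sqrt(lo_s * hi_s)
        if far_nonzero_frac(mid) <= far_frac_target:
            hi_s = mid
        else:
            lo_s = mid
    return hi_s


def coaccess_scores(
    metacells: np.ndarray,
    peaks: pd.DataFrame,
    cfg: CoaccessConfig | None = None,
) -> pd.DataFrame:
    """Distance-penalized regularized partial correlations per peak pair.

    Returns every pair within ``window_bp`` with its score (mean over
    covering windows) and distance; pairs beyond the window are omitted —
    their score is defined as exactly zero.
    """
    cfg = cfg or CoaccessConfig()
    M = np.asarray(metacells, dtype=float)
    if M.shape[0] < 10:
        raise ValueError("need at least 10 metacells")
    pos = ((peaks["start"] + peaks["end"]) // 2).to_numpy()
    if not np.all(np.diff(pos) >= 0):  # peaks must be position-sorted
        order = np.argsort(pos, kind="stable")
        peaks = peaks.iloc[order].reset_index(drop=True)
        M = M[:, order]
        pos = pos[order]
    s_param = cfg.distance_param
    if s_param == "auto":
        s_param = _auto_distance_param(M, pos, cfg)
    sums, counts = _window_scores(M, pos, cfg, float(s_param))
    rows = []
    names = peaks["name"].to_numpy()
    chroms = peaks["chrom"].to_numpy()
    for (i, j), ssum in sums.items():
        rows.append(
            dict(
                chrom=chroms[i],
                peak_i=names[i],
                peak_j=names[j],
                distance_bp=int(abs(pos[i] - pos[j])),
                score=ssum / counts[(i, j)],
                n_windows=counts[(i, j)],
            )
        )
    return pd.DataFrame(rows)


def extract_ccans(
    edges: pd.DataFrame,
    score_min: float = 0.2,
    seed: int = 17,
    resolution: float = 0.25,
) -> pd.DataFrame:
    """Louvain communities on the score-thresholded coaccessibility graph.

    Singleton communities are dropped; every returned member is
    coaccessible (score >= score_min) with at least one other member.
    Returns a table (ccan, peak).
    """
    if len(edges) == 0:
        return pd.DataFrame(columns=["ccan", "peak"])
    strong = edges[edges["score"] >= score_min]
    g = nx.Graph()
    for row in strong.itertuples(index=False):
        g.add_edge(row.peak_i, row.peak_j, weight=row.score)
    if g.number_of_nodes() == 0:
        return pd.DataFrame(columns=["ccan", "peak"])
    comms = nx.community.louvain_communities(g, seed=seed, resolution=resolution)
    rows = []
    cid = 0
    for c in sorted(comms, key=lambda c: (-len(c), sorted(c)[0])):
        if len(c) < 2:
            continue
        for peak in sorted(c):
            rows.append(dict(ccan=f"CCAN_{cid:04d}", peak=peak))
        cid += 1
    return pd.DataFrame(rows)
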