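"""PWM motif scanning with exact null p-values, GC-weighted binomial
enrichment, TF expression filtering, and TF-to-target network assembly.

Scan p-values are exact: for each motif the null distribution of the
log-odds score under the background base composition is computed by
dynamic programming over positions with scores binned at 1e-3, so the
tail probability P(S >= s) matches brute-force enumeration over all words
(bit-for-bit for any motif when both use the binned scores). Enrichment
follows the GC-weighting idea of n-mer/GC-corrected motif enrichment
tools: background peaks are reweighted within GC deciles to match the
target GC distribution before a one-sided binomial test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

SCORE_BIN = 1e-3
BASES = "ACGT"
_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class MotifModel:
    """A PWM with background, information content, and binned log-odds."""

    tf_name: str
    pwm: np.ndarray                  # (L, 4) probabilities, rows sum to 1
    background: np.ndarray           # (4,) probabilities
    ic: np.ndarray = field(init=False)        # (L,) bits, in [0, 2]
    logodds: np.ndarray = field(init=False)   # (L, 4) natural log
    _bins: np.ndarray = field(init=False)     # (L, 4) integer binned scores
    _tail: np.ndarray = field(init=False)     # null P(S >= s) per bin
    _offset: int = field(init=False)

    @classmethod
    def from_counts(cls, tf_name, counts, background=None, pseudocount=1e-3):
        counts = np.asarray(counts, dtype=float)
        if counts.shape[0] == 4:
            counts = counts.T  # accept (4, L) JASPAR layout
        if np.any(counts.sum(axis=1) <= 0):
            raise ValueError("motif has an all-zero position")
        if np.any(counts == 0) and pseudocount <= 0:
            warnings.warn("zero-probability PWM cell; applying pseudocount 1e-3")
            pseudocount = 1e-3
        pwm = counts + pseudocount * counts.sum(axis=1, keepdims=True)
        pwm = pwm / pwm.sum(axis=1, keepdims=True)
        bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
        bg = bg / bg.sum()
        return cls(tf_name=tf_name, pwm=pwm, background=bg)

    def __post_init__(self):
        self.pwm = np.asarray(self.pwm, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        self.ic = np.maximum(
            np.sum(self.pwm * np.log2(self.pwm / 0.25), axis=1), 0.0
        )
        self.logodds = np.log(self.pwm / self.background)
        self._bins = np.rint(self.logodds / SCORE_BIN).astype(np.int64)
        self._build_null()

    def __len__(self):
        return self.pwm.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(BASES[b] for b in np.argmax(self.pwm, axis=1))

    def _build_null(self):
        """Exact null score distribution by DP over positions."""
        lo = int(self._bins.min(axis=1).sum())
        hi = int(self._bins.max(axis=1).sum())
        dist = np.zeros(hi - lo + 1)
        dist[-lo if lo < 0 else 0] = 0.0
        # start: point mass at score 0
        dist = np.zeros(hi - lo + 1)
        dist[0 - lo] = 1.0
        cur_lo, cur_hi = 0, 0
        for j in range(len(self)):
            new_lo = cur_lo + int(self._bins[j].min())
            new_hi = cur_hi + int(self._bins[j].max())
            new = np.zeros(hi - lo + 1)
            for b in range(4):
                s = int(self._bins[j, b])
                seg = dist[cur_lo - lo: cur_hi - lo + 1]
                new[cur_lo + s - lo: cur_hi + s - lo + 1] += self.background[b] * seg
            dist = new
            cur_lo, cur_hi = new_lo, new_hi
        tail = np.cumsum(dist[::-1])[::-1]
        self._tail = tail
        self._offset = lo

    def score_pvalue(self, binned_score: int) -> float:
        """P(S >= s) under the background, exact on the binned score grid."""
        i = int(binned_score) - self._offset
        if i < 0:
            return 1.0
        if i >= len(self._tail):
            return 0.0
        return float(self._tail[i])

    def scan_scores(self, seq: str) -> np.ndarray:
        """Binned log-odds at every offset; N positions contribute 0."""
        L = len(self)
        enc = np.frombuffer(seq.encode(), dtype=np.uint8)
        code = np.full(len(seq), 4, dtype=np.int8)
        for i, b in enumerate(BASES):
            code[enc == ord(b)] = i
        n_off = len(seq) - L + 1
        if n_off <= 0:
            return np.zeros(0, dtype=np.int64)
        bins5 = np.hstack([self._bins, np.zeros((L, 1), dtype=np.int64)])
        idx = code[np.arange(n_off)[:, None] + np.arange(L)[None, :]]
        return bins5[np.arange(L)[None, :], idx].sum(axis=1)


def load_motifs(pfms: dict[str, np.ndarray], background=None) -> list[MotifModel]:
    return [MotifModel.from_counts(tf, m, background) for tf, m in pfms.items()]


def estimate_background(sequences: dict[str, str]) -> np.ndarray:
    """Strand-symmetrized base composition of a sequence set."""
    counts = np.zeros(4)
    for s in sequences.values():
        for i, b in enumerate(BASES):
            counts[i] += s.count(b)
    counts = counts + counts[::-1]  # A<->T, C<->G symmetry
    return counts / counts.sum()


def pwm_scan(
    sequences: dict[str, str],
    motifs: list[MotifModel],
    p_max: float = 5e-5,
) -> pd.DataFrame:
    """Scan both strands of every sequence; collapse overlapping same-TF
    hits to the best-scoring match. Returns (peak, tf, strand, offset,
    score, p_value) rows with p_value < p_max."""
    rows = []
    for name, seq in sequences.items():
        seq = seq.upper()
        rc = revcomp(seq)
        for m in motifs:
            L = len(m)
            cand = []
            for strand, s in (("+", seq), ("-", rc)):
                scores = m.scan_scores(s)
                for off in np.nonzero(scores * SCORE_BIN > 0)[0]:
                    p = m.score_pvalue(scores[off])
                    if p < p_max:
                        fwd_off = off if strand == "+" else len(seq) - L - off
                        cand.append((int(fwd_off), strand, int(scores[off]), p))
            # collapse overlapping windows of the same TF, keep best score
            cand.sort()
            kept = []
            for c in cand:
                if kept and c[0] < kept[-1][0] + L:
                    if c[2] > kept[-1][2]:
                        kept[-1] = c
                else:
                    kept.append(c)
            for off, strand, sc, p in kept:
                rows.append(
                    dict(peak=name, tf=m.tf_name, strand=strand, offset=off,
                         score=sc * SCORE_BIN, p_value=p)
                )
    return pd.DataFrame(
        rows, columns=["peak", "tf", "strand", "offset", "score", "p_value"]
    )


def gc_fraction(sequences: dict[str, str]) -> pd.Series:
    return pd.Series(
        {n: (s.count("G") + s.count("C")) / max(len(s), 1)
         for n, s in sequences.items()}
    )


def motif_enrichment(
    target_peaks: list[str],
    background_peaks: list[str],
    hits: pd.DataFrame,
    gc: pd.Series,
    fold_min: float = 1.2,
    fdr_max: float = 0.05,
    tfs: list[str] | None = None,
) -> pd.DataFrame:
    """GC-weighted one-sided binomial motif enrichment.

    Background peaks are reweighted within GC deciles (edges from the
    pooled GC distribution) so that the weighted background GC profile
    matches the target profile; for each TF the weighted background hit
    rate p0 (floored at 1/(2 n_bg)) feeds a binomial tail test of the
    target hit count. BH correction is applied across TFs. The
    ``reported`` flag marks fold >= fold_min and FDR <= fdr_max.
    """
    target_peaks = list(target_peaks)
    background_peaks = list(background_peaks)
    if set(target_peaks) & set(background_peaks):
        raise ValueError("target and background peak sets must be disjoint")
    n_t, n_b = len(target_peaks), len(background_peaks)
    if n_t == 0 or n_b == 0:
        raise ValueError("need non-empty target and background sets")
    edges = np.quantile(gc.loc[target_peaks + background_peaks], np.linspace(0, 1, 11))
    edges[0], edges[-1] = -np.inf, np.inf
    t_bin = np.searchsorted(edges, gc.loc[target_peaks], side="right") - 1
    b_bin = np.searchsorted(edges, gc.loc[background_peaks], side="right") - 1
    w = np.zeros(n_b)
    nonempty = [np.sum(b_bin == k) for k in range(10)]
    for k in range(10):
        t_frac = np.mean(t_bin == k)
        if t_frac == 0:
            continue
        if nonempty[k] == 0:
            near = min((kk for kk in range(10) if nonempty[kk] > 0),
                       key=lambda kk: abs(kk - k))
            warnings.warn(f"empty background GC decile {k}; borrowing from {near}")
            w[b_bin == near] += t_frac / nonempty[near]
        else:
            w[b_bin == k] += t_frac / nonempty[k]
    w = w / w.sum()

    hit_sets = hits.groupby("tf")["peak"].agg(set) if len(hits) else pd.Series(dtype=object)
    rows = []
    family = sorted(tfs) if tfs is not None else sorted(hit_sets.index)
    for tf in family:
        peaks_with = hit_sets.get(tf, set())
        k = sum(p in peaks_with for p in target_peaks)
        bg_hit = np.array([p in peaks_with for p in background_peaks], dtype=float)
        p0 = max(float(w @ bg_hit), 1.0 / (2 * n_b))
        pval = stats.binom.sf(k - 1, n_t, p0) if k > 0 else 1.0
        fold = (k / n_t) / p0
        rows.append(dict(tf=tf, k=k, n_target=n_t, p0=p0, fold=fold, p=pval))
    out = pd.DataFrame(rows, columns=["tf", "k", "n_target", "p0", "fold", "p"])
    if len(out):
        out["fdr"] = multipletests(out["p"], method="fdr_bh")[1]
        out["reported"] = (out["fold"] >= fold_min) & (out["fdr"] <= fdr_max)
    else:
        out["fdr"] = []
        out["reported"] = []
    return out


def expressed_tfs(
    X, feature_names, cluster_mask, tf_genes: dict[str, str], min_frac: float = 0.10
) -> set[str]:
    """TFs whose encoding gene is detected in >= min_frac of cluster cells.

    ``tf_genes`` maps TF name -> gene id; TFs whose gene is absent from
    the feature table are excluded (logged).
    """
    import scipy.sparse as sp

    X = sp.csr_matrix(X)
    names = list(feature_names)
    idx = {g: i for i, g in enumerate(names)}
    sub = X[np.asarray(cluster_mask)]
    out = set()
    for tf, gene in tf_genes.items():
        if gene not in idx:
            warnings.warn(f"TF {tf}: gene {gene} absent from features; excluded")
            continue
        frac = float((sub[:, idx[gene]] > 0).sum()) / sub.shape[0]
        if frac >= min_frac:
            out.add(tf)
    return out


def build_network(
    enrichments: pd.DataFrame,
    degs: pd.DataFrame,
    gwas_degs: set[str],
    expressed: set[str],
    tf_genes: dict[str, str],
    ccre_targets: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Directed TF-DEG -> GWAS-DEG edges with matched regulation sign.

    ``enrichments`` must carry columns (tf, gene[, reported]); an edge is
    emitted when the TF's encoding gene is a DEG in the cluster, the TF is
    expressed, the target gene is a GWAS-DEG, and the signs of the TF DEG
    and the target DEG agree.
    """
    deg_dir = dict(zip(degs["feature"], degs["direction"]))
    enr = enrichments
    if "reported" in enr.columns:
        enr = enr[enr["reported"]]
    rows = []
    for e in enr.itertuples(index=False):
        gene_tf = tf_genes.get(e.tf)
        target = e.gene
        if gene_tf not in deg_dir or e.tf not in expressed:
            continue
        if target not in gwas_degs or target not in deg_dir:
            continue
        if deg_dir[gene_tf] != deg_dir[target]:
            continue
        rows.append(
            dict(
                tf=e.tf, tf_gene=gene_tf, target=target,
                direction=deg_dir[target],
                tf_is_gwas_deg=gene_tf in gwas_degs,
            )
        )
    net = pd.DataFrame(
        rows, columns=["tf", "tf_gene", "target", "direction", "tf_is_gwas_deg"]
    ).drop_duplicates(["tf", "target"])
    if len(net):
        net["tf_out_degree"] = net.groupby("tf")["target"].transform("nunique")
        net["target_in_degree"] = net.groupby("target")["tf"].transform("nunique")
    else:
        net["tf_out_degree"] = []
        net["target_in_degree"] = []
    return net.reset_index(drop=True)
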