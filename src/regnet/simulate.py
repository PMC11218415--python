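"""Synthetic single-nucleus multiome with planted ground truth.

Every downstream stage of the pipeline (QC, annotation, differential
testing, coaccessibility, motif enrichment, variant scoring, LD) is
exercised on data generated here, with the planted signals recorded so that
recovery can be measured exactly.

The generative model mirrors the statistical structure the pipeline
assumes:

* RNA counts are negative binomial with a per-gene baseline, subtype marker
  shifts, a diagnosis effect of ``planted_lfc`` log2 units on a designated
  DE-gene set, a per-(gene, donor) random intercept with standard deviation
  ``donor_sd`` on the natural-log scale, and a log-normal per-cell depth
  offset. An optional donor-level confounder loads on all genes.
* ATAC counts are Poisson draws whose log-rates vary at the level of small
  cell-state neighborhoods (``state_size`` cells sharing a latent chromatin
  state). Peaks inside a planted coaccessibility block follow an AR(1)
  chain across the block (adjacent latent correlation as configured), so
  the planted conditional-independence graph is sparse and recoverable by
  partial-correlation methods; accessibility of planted DAPs shifts with
  diagnosis. The synthetic embedding stored in ``obsm`` encodes state
  proximity, standing in for the LSI embedding of real data.
* Peak sequences are random with peak-specific GC content; designated
  target peaks carry inserted motif consensus sites.
* Haplotype panels are constructed to realize requested r2 / D' per variant
  pair, and include at least one insertion and one deletion.

All generators are pure functions of :class:`SimConfig` (seed included).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

CHROM = "chrS"
WINDOW_BP = 500_000

#: Built-in motif models as JASPAR-style count matrices (rows A, C, G, T).
#: 8-bp consensus sites; under a uniform background the consensus word has
#: null probability 0.25^8 ~ 1.5e-5, inside the 5e-5 scan threshold.
DEFAULT_PFMS = {
    "TFA": "TGACTCAC",
    "TFB": "GGGCGGGG",
    "TFC": "CACGTGAC",
}


def consensus_pfm(consensus: str, dominant: float = 85.0, other: float = 5.0) -> np.ndarray:
    mat = np.full((4, len(consensus)), other)
    for j, b in enumerate(consensus):
        mat["ACGT".index(b), j] = dominant
    return mat


def default_pfms() -> dict[str, np.ndarray]:
    return {name: consensus_pfm(c) for name, c in DEFAULT_PFMS.items()}


@dataclass
class LdPairSpec:
    """A planted LD relationship between two panel variants."""

    id_a: str
    id_b: str
    r2: float
    d_sign: int = 1
    af_a: float = 0.5
    af_b: float = 0.5


@dataclass
class VariantDef:
    id: str
    pos: int  # 1-based, as in VCF
    ref: str
    alt: str
    af: float = 0.5


@dataclass
class SimConfig:
    seed: int = 0
    n_donors_per_group: int = 12
    n_cells_per_donor: int = 200
    n_genes: int = 2000
    n_peaks: int = 300
    n_subtypes: int = 2
    planted_lfc: float = 1.0          # log2 units, diagnosis effect
    frac_de: float = 0.1
    donor_sd: float = 0.3             # natural-log scale
    nb_dispersion: float = 0.5
    coaccess_blocks: list = field(
        default_factory=lambda: [((0, 10), 0.9), ((20, 30), 0.9)]
    )
    confounder_strength: float = 0.0
    motif_insert_rate: float = 0.0
    motif_targets: dict = field(default_factory=dict)  # tf -> (lo, hi) peak range
    ld_pairs: list = field(default_factory=list)
    variants: list = field(default_factory=list)
    # plumbing of the synthetic coordinate system and assay scales
    chrom_length: int = 3_000_000
    peak_spacing: int = 3_000
    peak_width: int = 200
    mean_depth_rna: float = 2_000.0
    depth_sd: float = 0.3
    n_mito_genes: int = 10
    frac_dap: float = 0.1
    dap_peaks: list | None = None      # explicit [(peak_idx, sign), ...]
    de_genes: list | None = None       # explicit [(gene_idx, sign), ...]
    atac_mean_rate: float = 0.25
    atac_state_sd: float = 1.0
    state_size: int = 50
    block_subtype: int | None = None   # restrict planted blocks to one subtype
    dap_subtype: int | None = None     # restrict planted DAP shifts to one subtype
    motif_insert_offset: int | None = None
    marker_frac: float = 0.05
    marker_lfc: float = 1.2            # natural-log subtype marker shift
    n_haplotypes: int = 100
    gwas_positions: list = field(default_factory=lambda: [100_000])

    def __post_init__(self):
        if min(self.n_genes, self.n_peaks, self.n_cells_per_donor,
               self.n_donors_per_group, self.n_subtypes) <= 0:
            raise ValueError("all dimensions must be positive")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if not 0 <= self.frac_de <= 1:
            raise ValueError("frac_de must lie in [0, 1]")
        n_de = self.frac_de * self.n_genes
        if abs(n_de - round(n_de)) > 1e-9:
            raise ValueError("frac_de * n_genes must be an integer")
        spans = []
        for (lo, hi), r in self.coaccess_blocks:
            if not (0 <= lo < hi <= self.n_peaks):
                raise ValueError(f"block ({lo}, {hi}) outside peak range")
            if not 0 <= r <= 1:
                raise ValueError("block latent correlation must lie in [0, 1]")
            span = (hi - 1 - lo) * self.peak_spacing
            if span > WINDOW_BP:
                raise ValueError(f"block ({lo}, {hi}) spans {span} bp > 500 kb")
            spans.append((lo, hi))
        spans.sort()
        for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
            if b0 < a1:
                raise ValueError("coaccess blocks overlap")
        last_peak_end = 100_000 + (self.n_peaks - 1) * self.peak_spacing + self.peak_width
        if last_peak_end + 2_000 > self.chrom_length:
            raise ValueError("chromosome length too small for the peak tiling")


@dataclass
class GroundTruth:
    """Planted signals, keyed the way downstream stages report them."""

    de_genes: dict = field(default_factory=dict)        # gene_id -> signed log2FC
    dap_peaks: dict = field(default_factory=dict)       # peak_id -> signed log2FC
    block_membership: dict = field(default_factory=dict)  # peak_id -> block index
    inserted_motifs: dict = field(default_factory=dict)   # peak_id -> [tf, ...]
    haplotype_ld: dict = field(default_factory=dict)      # "a|b" -> (r2, dprime)
    subtype_markers: dict = field(default_factory=dict)   # subtype -> [gene_id, ...]
    confounder: str | None = None

    def to_dict(self):
        return asdict(self)


# ----------------------------------------------------------------- helpers

def _donor_frame(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    D = 2 * cfg.n_donors_per_group
    donors = [f"d{i:02d}" for i in range(D)]
    diagnosis = ["Normal"] * cfg.n_donors_per_group + ["PD"] * cfg.n_donors_per_group
    return pd.DataFrame(
        dict(
            donor=donors,
            diagnosis=diagnosis,
            age=np.round(rng.normal(78, 6, D), 1),
            sex=np.tile(["F", "M"], D)[:D],
            pmi=np.round(rng.gamma(4, 1.5, D), 2),
            batch_score=rng.normal(0, 1, D),
        )
    )


def _cells_frame(cfg: SimConfig, donors: pd.DataFrame, prefix: str) -> pd.DataFrame:
    rows = []
    for _, d in donors.iterrows():
        for c in range(cfg.n_cells_per_donor):
            rows.append((f"{prefix}_{d.donor}_c{c:04d}", d.donor, d.diagnosis))
    obs = pd.DataFrame(rows, columns=["barcode", "donor", "diagnosis"]).set_index(
        "barcode"
    )
    subtype = np.arange(len(obs)) % cfg.n_subtypes
    obs["subtype"] = [f"S{s}" for s in subtype]
    for col in ["age", "sex", "pmi", "batch_score"]:
        obs[col] = donors.set_index("donor")[col].reindex(obs["donor"]).values
    return obs


def _planted_signed(n_planted, n_total, rng, explicit):
    if explicit is not None:
        return {int(i): float(s) for i, s in explicit}
    idx = np.arange(n_planted)
    signs = np.ones(n_planted)
    signs[rng.permutation(n_planted)[: n_planted // 2]] = -1.0
    return {int(i): float(s) for i, s in zip(idx, signs)}


# ----------------------------------------------------------------- RNA

def gen_rna(cfg: SimConfig) -> tuple[ad.AnnData, GroundTruth]:
    """Simulate the cell-by-gene count matrix with planted DE genes."""
    rng = np.random.default_rng(cfg.seed)
    donors = _donor_frame(cfg, rng)
    obs = _cells_frame(cfg, donors, "rna")
    n = len(obs)
    G = cfg.n_genes
    genes = [f"g{i:04d}" for i in range(G)] + [f"MT-{i}" for i in range(cfg.n_mito_genes)]
    Gt = len(genes)

    base = rng.uniform(np.log(0.2), np.log(5.0), Gt)
    base[G:] = rng.uniform(np.log(0.5), np.log(2.0), cfg.n_mito_genes)

    truth = GroundTruth()
    n_de = round(cfg.frac_de * G)
    de = _planted_signed(n_de, G, rng, cfg.de_genes)
    lfc_ln = np.zeros(Gt)
    for gi, s in de.items():
        lfc_ln[gi] = s * cfg.planted_lfc * np.log(2)
        truth.de_genes[genes[gi]] = s * cfg.planted_lfc

    # subtype markers occupy a slice of genes after the DE set
    n_mark = int(cfg.marker_frac * G)
    marker_shift = np.zeros((cfg.n_subtypes, Gt))
    for s in range(cfg.n_subtypes):
        lo = n_de + s * n_mark
        hi = min(lo + n_mark, G)
        marker_shift[s, lo:hi] = cfg.marker_lfc
        truth.subtype_markers[f"S{s}"] = [genes[i] for i in range(lo, hi)]

    donor_eff = rng.normal(0, cfg.donor_sd, (Gt, len(donors)))
    conf_loading = rng.normal(0, 1, Gt)
    truth.confounder = "batch_score"

    depth = np.exp(rng.normal(np.log(cfg.mean_depth_rna), cfg.depth_sd, n))
    log_depth_factor = np.log(depth / np.median(depth))

    d_map = {d: i for i, d in enumerate(donors["donor"])}
    d_idx = obs["donor"].map(d_map).to_numpy()
    s_idx = obs["subtype"].str.lstrip("S").astype(int).to_numpy()
    is_pd = (obs["diagnosis"] == "PD").to_numpy().astype(float)
    batch = donors["batch_score"].to_numpy()

    blocks = []
    chunk = 2_000  # cells per chunk, caps the dense intermediate
    for c0 in range(0, n, chunk):
        c1 = min(c0 + chunk, n)
        sl = slice(c0, c1)
        logmu = (
            base[:, None]
            + lfc_ln[:, None] * is_pd[None, sl]
            + marker_shift.T[:, s_idx[sl]]
            + donor_eff[:, d_idx[sl]]
            + cfg.confounder_strength * conf_loading[:, None] * batch[d_idx[sl]][None, :]
            + log_depth_factor[None, sl]
        )
        mu = np.exp(np.clip(logmu, -30, 30))
        shape = 1.0 / cfg.nb_dispersion
        lam = mu * rng.gamma(shape, cfg.nb_dispersion, mu.shape)
        blocks.append(sp.csr_matrix(rng.poisson(lam).astype(np.int32).T))
    X = sp.vstack(blocks).tocsr()

    var = pd.DataFrame(index=pd.Index(genes, name="gene_id"))
    var["is_mito"] = [g.startswith("MT-") for g in genes]
    adata = ad.AnnData(X=X, obs=obs.copy(), var=var)
    adata.obs["n_counts"] = np.asarray(X.sum(axis=1)).ravel()
    adata.obs["n_features"] = np.asarray((X > 0).sum(axis=1)).ravel()
    # donor-level depth metrics, as used in the covariate sets
    grp = adata.obs.groupby("donor", observed=True)
    adata.obs["n_nuclei"] = grp["n_counts"].transform("size")
    adata.obs["median_genes_per_cell"] = grp["n_features"].transform("median")
    adata.obs["mean_library_size"] = grp["n_counts"].transform("mean")
    return adata, truth


# ----------------------------------------------------------------- ATAC

def peak_table(cfg: SimConfig) -> pd.DataFrame:
    starts = 100_000 + np.arange(cfg.n_peaks) * cfg.peak_spacing
    return pd.DataFrame(
        dict(
            chrom=CHROM,
            start=starts,
            end=starts + cfg.peak_width,
            name=[f"peak_{i:04d}" for i in range(cfg.n_peaks)],
        )
    )


def _chain_latent(rng, n_states, length, r):
    """AR(1) chain across a block: adjacent latent correlation r."""
    z = np.empty((n_states, length))
    z[:, 0] = rng.normal(size=n_states)
    for j in range(1, length):
        z[:, j] = r * z[:, j - 1] + np.sqrt(max(1 - r * r, 0)) * rng.normal(size=n_states)
    return z


def gen_atac(cfg: SimConfig) -> tuple[ad.AnnData, pd.DataFrame, dict, GroundTruth]:
    """Simulate peak counts, peak intervals, and peak sequences.

    Returns (AnnData with per-cell QC stats in .obs and the state embedding
    in .obsm["state_coords"], peak BED table, peak sequences, ground truth).
    """
    rng = np.random.default_rng(cfg.seed + 1_000_003)
    donors = _donor_frame(cfg, np.random.default_rng(cfg.seed))  # same donors as RNA
    obs = _cells_frame(cfg, donors, "atac")
    n = len(obs)
    P = cfg.n_peaks
    peaks = peak_table(cfg)
    truth = GroundTruth()

    # cell states: groups of ~state_size cells within a subtype share a
    # latent chromatin state; the embedding encodes state proximity
    s_idx = obs["subtype"].str.lstrip("S").astype(int).to_numpy()
    state_id = np.empty(n, dtype=int)
    n_states = 0
    for s in range(cfg.n_subtypes):
        cells = np.where(s_idx == s)[0]
        cells = rng.permutation(cells)  # states mix donors, as in a real cluster
        ids = n_states + np.arange(len(cells)) // cfg.state_size
        state_id[cells] = ids
        n_states = ids.max() + 1
    centers = 5.0 * rng.normal(size=(n_states, 6))
    state_subtype = np.zeros(n_states, dtype=int)
    state_subtype[state_id] = s_idx
    centers[:, 0] += 12.0 * state_subtype  # subtypes well separated
    embedding = centers[state_id] + 0.1 * rng.normal(size=(n, 6))

    # latent log-rate structure per state
    state_z = rng.normal(0, 1, (n_states, P))  # independent background variation
    for b, ((lo, hi), r) in enumerate(cfg.coaccess_blocks):
        chain = _chain_latent(rng, n_states, hi - lo, r)
        if cfg.block_subtype is None:
            state_z[:, lo:hi] = chain
        else:  # block coaccessibility confined to one subtype's states
            mask = state_subtype == cfg.block_subtype
            state_z[mask, lo:hi] = chain[mask]
        for i in range(lo, hi):
            truth.block_membership[peaks.at[i, "name"]] = b

    block_idx = set()
    for (lo, hi), _ in cfg.coaccess_blocks:
        block_idx.update(range(lo, hi))
    n_dap = round(cfg.frac_dap * P)
    if cfg.dap_peaks is not None:
        dap = {int(i): float(s) for i, s in cfg.dap_peaks}
    else:
        free = [i for i in range(P) if i not in block_idx]
        chosen = free[:n_dap]
        signs = np.ones(len(chosen))
        signs[rng.permutation(len(chosen))[: len(chosen) // 2]] = -1.0
        dap = {int(i): float(s) for i, s in zip(chosen, signs)}
    lfc_ln = np.zeros(P)
    for pi, s in dap.items():
        lfc_ln[pi] = s * cfg.planted_lfc * np.log(2)
        truth.dap_peaks[peaks.at[pi, "name"]] = s * cfg.planted_lfc

    # subtype-preferential peaks: the anchor peaks of each subtype's RNA
    # marker genes (so gene activity mirrors the transcriptomic markers),
    # topped up with filler peaks
    n_de = len(cfg.de_genes) if cfg.de_genes is not None else round(cfg.frac_de * cfg.n_genes)
    n_mark = int(cfg.marker_frac * cfg.n_genes)
    free = [i for i in range(P) if i not in block_idx and i not in dap]
    per = max(len(free) // (4 * cfg.n_subtypes), 1)
    subtype_shift = np.zeros((cfg.n_subtypes, P))
    for s in range(cfg.n_subtypes):
        anchors = [
            3 * g for g in range(n_de + s * n_mark, n_de + (s + 1) * n_mark)
            if 3 * g < P
        ]
        subtype_shift[s, anchors] = cfg.marker_lfc
        extra = [i for i in free[s * per:(s + 1) * per] if i not in anchors]
        subtype_shift[s, extra] = cfg.marker_lfc

    d_map = {d: i for i, d in enumerate(donors["donor"])}
    d_idx = obs["donor"].map(d_map).to_numpy()
    donor_eff = rng.normal(0, cfg.donor_sd / 2, (len(donors), P))
    is_pd = (obs["diagnosis"] == "PD").to_numpy().astype(float)
    depth_factor = np.exp(rng.normal(0, cfg.depth_sd, n))

    base = np.log(cfg.atac_mean_rate) - 0.5 * cfg.atac_state_sd**2
    dap_cells = is_pd if cfg.dap_subtype is None else is_pd * (s_idx == cfg.dap_subtype)
    lograte = (
        base
        + cfg.atac_state_sd * state_z[state_id]
        + subtype_shift[s_idx]
        + donor_eff[d_idx]
        + lfc_ln[None, :] * dap_cells[:, None]
        + np.log(depth_factor)[:, None]
    )
    Y = rng.poisson(np.exp(np.clip(lograte, -30, 30))).astype(np.int32)
    X = sp.csr_matrix(Y)

    var = peaks.set_index("name")
    adata = ad.AnnData(X=X, obs=obs.copy(), var=var.copy())
    adata.obs["state"] = state_id
    adata.obsm["state_coords"] = embedding
    for j in range(embedding.shape[1]):
        adata.obs[f"state_coord_{j}"] = embedding[:, j]
    adata.obs["n_counts"] = np.asarray(X.sum(axis=1)).ravel()
    # per-cell QC metrics at realistic assay scales, as emitted by an
    # upstream fragment processor (the count matrix itself is desk-scale)
    adata.obs["peak_fragments"] = np.rint(
        np.exp(rng.normal(np.log(6000), 0.6, n)) * depth_factor
    ).astype(int)
    adata.obs["nucleosome_signal"] = rng.gamma(8, 0.25, n)
    adata.obs["tss_enrichment"] = rng.gamma(16, 0.25, n)
    adata.obs["frip"] = np.clip(rng.normal(0.35, 0.08, n), 0.01, 0.95)
    adata.obs["blacklist_fraction"] = np.clip(rng.exponential(0.01, n), 0, 0.5)
    grp = adata.obs.groupby("donor", observed=True)
    adata.obs["n_nuclei"] = grp["peak_fragments"].transform("size")

    seqs = _peak_sequences(cfg, peaks, truth, rng)
    return adata, peaks, seqs, truth


def _peak_sequences(cfg, peaks, truth, rng) -> dict[str, str]:
    pfms = default_pfms()
    seqs = {}
    gc = np.clip(rng.beta(5, 5, len(peaks)), 0.2, 0.8)
    for i, name in enumerate(peaks["name"]):
        p_gc = gc[i]
        probs = [(1 - p_gc) / 2, p_gc / 2, p_gc / 2, (1 - p_gc) / 2]
        seq = rng.choice(list("ACGT"), size=cfg.peak_width, p=probs)
        seqs[name] = "".join(seq)
    for tf, (lo, hi) in cfg.motif_targets.items():
        cons = DEFAULT_PFMS[tf] if tf in DEFAULT_PFMS else None
        if cons is None:
            raise KeyError(f"no built-in motif for TF {tf!r}")
        for i in range(lo, hi):
            if rng.random() < cfg.motif_insert_rate:
                name = peaks.at[i, "name"]
                if cfg.motif_insert_offset is not None:
                    off = cfg.motif_insert_offset
                else:
                    off = rng.integers(0, cfg.peak_width - len(cons))
                s = seqs[name]
                seqs[name] = s[:off] + cons + s[off + len(cons):]
                truth.inserted_motifs.setdefault(name, []).append(tf)
    return seqs


# ----------------------------------------------------------------- genes

def gen_annotation(cfg: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene models on the synthetic chromosome plus the GWAS SNV table.

    Genes are anchored to every third peak so that promoters and first
    introns overlap real peaks; strands alternate so strand-aware window
    logic is exercised. Returns (gene table, GWAS SNV table).
    """
    peaks = peak_table(cfg)
    n_genes = min(cfg.n_genes, cfg.n_peaks // 3)
    rows = []
    for g in range(n_genes):
        anchor = 3 * g
        ps, pe = int(peaks.at[anchor, "start"]), int(peaks.at[anchor, "end"])
        strand = "+" if g % 2 == 0 else "-"
        if strand == "+":
            sc = ps + 150
            tss = sc - 50
            intron = (sc + 250, sc + 1000)
        else:
            sc = pe - 150
            tss = sc + 50
            intron = (sc - 1000, sc - 250)
        if intron[0] < 0 or tss + 2_000 > cfg.chrom_length:
            raise ValueError("chromosome length too small for gene layout")
        rows.append(
            dict(
                gene_id=f"g{g:04d}", chrom=CHROM, strand=strand, tss=tss,
                start_codon=sc, intron1_start=intron[0], intron1_end=intron[1],
            )
        )
    genes = pd.DataFrame(rows)
    gwas = pd.DataFrame(
        dict(
            snv_id=[f"gwas_{i}" for i in range(len(cfg.gwas_positions))],
            chrom=CHROM,
            pos=list(cfg.gwas_positions),
            risk_allele=["A"] * len(cfg.gwas_positions),
        )
    )
    return genes, gwas


# ----------------------------------------------------------------- haplotypes

def _default_variants(cfg: SimConfig) -> list[VariantDef]:
    peaks = peak_table(cfg)
    p0 = int(peaks.at[1, "start"]) + 60
    p1 = int(peaks.at[2, "start"]) + 60
    p2 = int(peaks.at[3, "start"]) + 60
    g0 = cfg.gwas_positions[0]
    return [
        VariantDef("rs_a", p0 + 1, "C", "T"),
        VariantDef("rs_ins", p1 + 1, "G", "GAT"),
        VariantDef("rs_del", p2 + 1, "TAC", "T"),
        VariantDef("gwas_0", g0 + 1, "G", "A"),
    ]


def _pair_haplotypes(n_hap, pair: LdPairSpec, rng):
    """Two 0/1 haplotype columns realizing the pair's target r2 and D' sign."""
    pA, pB = pair.af_a, pair.af_b
    d_max_pos = min(pA * (1 - pB), (1 - pA) * pB)
    denom = pA * (1 - pA) * pB * (1 - pB)
    r2_max = d_max_pos**2 / denom if denom > 0 else 0.0
    if pair.r2 > r2_max + 1e-9:
        raise ValueError(
            f"infeasible LD target: r2={pair.r2} exceeds the bound "
            f"r2 <= D'^2 * {r2_max:.4f} at allele frequencies "
            f"({pA}, {pB})"
        )
    D = pair.d_sign * np.sqrt(pair.r2 * denom)
    freqs = np.array(
        [
            pA * pB + D,          # 11
            pA * (1 - pB) - D,    # 10
            (1 - pA) * pB - D,    # 01
            (1 - pA) * (1 - pB) + D,  # 00
        ]
    )
    if np.any(freqs < -1e-9):
        raise ValueError("infeasible LD target: negative haplotype frequency")
    freqs = np.clip(freqs, 0, None)
    counts = np.floor(freqs * n_hap).astype(int)
    while counts.sum() < n_hap:
        counts[np.argmax(freqs * n_hap - counts)] += 1

    def realize(counts):
        a = np.repeat([1, 1, 0, 0], counts)
        b = np.repeat([1, 0, 1, 0], counts)
        return a, b

    def realized_r2(counts):
        nh = counts.sum()
        qA = (counts[0] + counts[1]) / nh
        qB = (counts[0] + counts[2]) / nh
        dd = counts[0] / nh - qA * qB
        den = qA * (1 - qA) * qB * (1 - qB)
        return dd * dd / den if den > 0 else np.nan

    # small deterministic adjustments until the integer table matches
    for _ in range(200):
        r2 = realized_r2(counts)
        if np.isfinite(r2) and abs(r2 - pair.r2) <= 0.05:
            break
        best = None
        for i in range(4):
            for j in range(4):
                if i == j or counts[j] == 0:
                    continue
                trial = counts.copy()
                trial[i] += 1
                trial[j] -= 1
                tr2 = realized_r2(trial)
                if np.isfinite(tr2) and (best is None or abs(tr2 - pair.r2) < best[0]):
                    best = (abs(tr2 - pair.r2), trial)
        if best is None:
            break
        counts = best[1]
    a, b = realize(counts)
    perm = rng.permutation(n_hap)
    return a[perm], b[perm]


def gen_haplotypes(cfg: SimConfig) -> tuple[pd.DataFrame, np.ndarray, GroundTruth]:
    """Phased haplotype panel realizing the configured LD pairs.

    Returns (variant table with 1-based ``pos``, (n_variants, n_haplotypes)
    0/1 matrix, ground truth with realized r2 / D').
    """
    if cfg.n_haplotypes < 20:
        raise ValueError("panel must have at least 20 haplotypes")
    rng = np.random.default_rng(cfg.seed + 2_000_003)
    variants = list(cfg.variants) if cfg.variants else _default_variants(cfg)
    ld_pairs = list(cfg.ld_pairs) if cfg.ld_pairs else [
        LdPairSpec("rs_a", "gwas_0", 0.81, 1)
    ]
    vindex = {v.id: k for k, v in enumerate(variants)}
    n_hap = cfg.n_haplotypes
    H = np.zeros((len(variants), n_hap), dtype=int)
    paired = set()
    truth = GroundTruth()
    from .variants import ld_from_haplotypes  # realized values for the record

    for pair in ld_pairs:
        ia, ib = vindex[pair.id_a], vindex[pair.id_b]
        if ia in paired or ib in paired:
            raise ValueError("LD pairs must not share variants")
        H[ia], H[ib] = _pair_haplotypes(n_hap, pair, rng)
        paired.update((ia, ib))
        stats = ld_from_haplotypes(H[ia], H[ib])
        truth.haplotype_ld[f"{pair.id_a}|{pair.id_b}"] = (
            stats["r2"], stats["d_prime"]
        )
    for k, v in enumerate(variants):
        if k not in paired:
            H[k] = (rng.random(n_hap) < v.af).astype(int)
    table = pd.DataFrame(
        [dict(chrom=CHROM, pos=v.pos, id=v.id, ref=v.ref, alt=v.alt) for v in variants]
    )
    return table, H, truth


# ----------------------------------------------------------------- bundle

@dataclass
class SimBundle:
    config: SimConfig
    rna: ad.AnnData
    atac: ad.AnnData
    peaks: pd.DataFrame
    sequences: dict
    genes: pd.DataFrame
    gwas: pd.DataFrame
    variant_table: pd.DataFrame
    haplotypes: np.ndarray
    truth: GroundTruth


def simulate_study(cfg: SimConfig) -> SimBundle:
    """Generate every pipeline input for one synthetic study."""
    rna, truth_rna = gen_rna(cfg)
    atac, peaks, seqs, truth_atac = gen_atac(cfg)
    genes, gwas = gen_annotation(cfg)
    var_table, haps, truth_ld = gen_haplotypes(cfg)
    truth = GroundTruth(
        de_genes=truth_rna.de_genes,
        dap_peaks=truth_atac.dap_peaks,
        block_membership=truth_atac.block_membership,
        inserted_motifs=truth_atac.inserted_motifs,
        haplotype_ld=truth_ld.haplotype_ld,
        subtype_markers=truth_rna.subtype_markers,
        confounder=truth_rna.confounder,
    )
    return SimBundle(cfg, rna, atac, peaks, seqs, genes, gwas, var_table, haps, truth)


def write_bundle(bundle: SimBundle, outdir) -> None:
    from pathlib import Path
    from . import io as rio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rio.write_matrix(bundle.rna, outdir / "rna")
    rio.write_matrix(bundle.atac, outdir / "atac")
    rio.write_bed(bundle.peaks, outdir / "peaks.bed")
    rio.write_fasta(bundle.sequences, outdir / "peaks.fa")
    bundle.genes.to_csv(outdir / "genes.tsv", sep="\t", index=False)
    bundle.gwas.to_csv(outdir / "gwas_snvs.tsv", sep="\t", index=False)
    sample_names = [f"h{i}" for i in range(bundle.haplotypes.shape[1] // 2)]
    rio.write_vcf(
        bundle.variant_table, bundle.haplotypes, sample_names, outdir / "panel.vcf"
    )
    rio.write_jaspar(default_pfms(), outdir / "motifs.jaspar")
    rio.write_json(bundle.truth.to_dict(), outdir / "ground_truth.json")
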