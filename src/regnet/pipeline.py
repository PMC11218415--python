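"""End-to-end orchestration: from simulated multiome inputs to
unidirectional CCANs, TF regulatory networks, and prioritized variants.

``run_pipeline`` strings the module stages together the way the analysis
scripts do: QC, normalization and embeddings, clustering and cross-modality
linking, differential testing per linked cluster, coaccessibility on
disease cells, cCRE definition, GWAS mapping, motif enrichment, network
assembly, and variant prioritization. ``run_toy`` builds a small
two-cluster study with exactly one planted unidirectional CCAN, one
TF-DEG -> GWAS-DEG edge, and one high-LD motif-disrupting variant, and
returns the recovered objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from . import annotate, coaccess, cre, differential, motifs, qc, variants
from .simulate import (
    LdPairSpec, SimBundle, SimConfig, VariantDef, default_pfms,
    gen_annotation, gen_atac, gen_haplotypes, gen_rna, GroundTruth,
)


@dataclass
class PipelineResult:
    rna_clusters: np.ndarray | None = None
    atac_clusters: np.ndarray | None = None
    links: pd.DataFrame | None = None
    composition: pd.DataFrame | None = None
    degs: dict = field(default_factory=dict)      # cluster -> called DEG table
    daps: dict = field(default_factory=dict)      # cluster -> called DAP table
    edges: dict = field(default_factory=dict)     # cluster -> coaccess edges
    ccans: dict = field(default_factory=dict)     # cluster -> CCAN table
    ccres: dict = field(default_factory=dict)     # cluster -> cCRE table
    unidirectional: dict = field(default_factory=dict)
    gwas_map: pd.DataFrame | None = None
    network: pd.DataFrame | None = None
    prioritized: pd.DataFrame | None = None

    def counts(self) -> dict:
        return dict(
            unidirectional_ccans=sum(len(v) for v in self.unidirectional.values()),
            network_edges=0 if self.network is None else len(self.network),
            prioritized_variants=0 if self.prioritized is None else len(self.prioritized),
        )


def _cluster_rna(adata, seed=17, n_pcs=10, resolution=1.0):
    norm = qc.lognormalize(adata.X)
    dense = np.asarray(norm.todense())
    n_pcs = min(n_pcs, min(dense.shape) - 1)
    emb = PCA(n_components=n_pcs, random_state=0).fit_transform(dense)
    return annotate.cluster_cells(emb, seed=seed, resolution=resolution), emb, dense


def _cluster_atac(adata, seed=17, dims=10, resolution=1.0):
    lsi = qc.tfidf_lsi(adata.X, dims=min(dims, min(adata.shape) - 2))
    emb = lsi.retained()
    return annotate.cluster_cells(emb, seed=seed, resolution=resolution), emb, lsi


def run_pipeline(
    bundle: SimBundle,
    tf_genes: dict[str, str] | None = None,
    coaccess_cfg: coaccess.CoaccessConfig | None = None,
    condition: str = "PD",
    seed: int = 17,
    cluster_resolution: float = 1.0,
) -> PipelineResult:
    """Run the full analysis on a simulated study bundle."""
    res = PipelineResult()
    cfg = bundle.config

    # ---- QC ----------------------------------------------------------
    _, rna = qc.qc_rna(bundle.rna)
    kept_atac = qc.qc_atac(bundle.atac.obs)
    atac = bundle.atac[kept_atac].copy()

    # ---- clustering and linking -------------------------------------
    rna_cl, rna_emb, rna_norm = _cluster_rna(rna, seed=seed,
                                             resolution=cluster_resolution)
    atac_cl, atac_emb, _ = _cluster_atac(atac, seed=seed,
                                         resolution=cluster_resolution)
    res.rna_clusters, res.atac_clusters = rna_cl, atac_cl

    # shared space: gene-activity of ATAC cells projected on the RNA PCA
    # basis over the annotated genes
    act, act_genes = qc.gene_activity(atac.X, bundle.peaks, bundle.genes)
    shared = [g for g in act_genes if g in rna.var_names]
    rna_sub = rna_norm[:, [list(rna.var_names).index(g) for g in shared]]
    act_sub = np.asarray(act.todense())[:, [act_genes.index(g) for g in shared]]
    n_pc = max(2, min(8, len(shared) - 1))
    pca = PCA(n_components=n_pc, random_state=0).fit(rna_sub)
    ps = annotate.prediction_scores(
        pca.transform(act_sub), pca.transform(rna_sub),
        [f"R{c}" for c in rna_cl], k=min(20, rna.n_obs),
    )
    ps.scores.index = atac.obs_names
    res.links = annotate.link_clusters(
        [f"A{c}" for c in atac_cl], ps.scores
    )
    res.composition = annotate.composition_test(
        [f"R{c}" for c in rna_cl], rna.obs["donor"],
        rna.obs.drop_duplicates("donor")[["donor", "diagnosis", "age", "sex", "pmi"]],
        fixed_covariates=["age", "sex", "pmi"],
    )

    # ---- differential testing per linked cluster pair ---------------
    ann = cre.annotate_peaks(bundle.peaks, bundle.genes)
    all_deg_tables = []
    for atac_name, link in res.links.iterrows():
        rna_name = link["rna_cluster"]
        rna_mask = np.array([f"R{c}" == rna_name for c in rna_cl])
        atac_mask = np.array([f"A{c}" == atac_name for c in atac_cl])
        if rna_mask.sum() < 50 or atac_mask.sum() < 50:
            continue
        de = differential.nb_glmm_de(
            rna.X[rna_mask], rna.var_names, rna.obs.loc[rna_mask].reset_index()
        )
        degs = differential.call_differential(de)
        res.degs[atac_name] = degs
        degs = degs.assign(cluster=atac_name)
        all_deg_tables.append(degs)
        da = differential.nb_glmm_de(
            atac.X[atac_mask], atac.var_names, atac.obs.loc[atac_mask].reset_index()
        )
        res.daps[atac_name] = differential.call_differential(da)

        # coaccessibility on condition-of-interest cells in this cluster
        cmask = atac_mask & (atac.obs["diagnosis"] == condition).to_numpy()
        ccfg = coaccess_cfg or coaccess.CoaccessConfig()
        if cmask.sum() < ccfg.k_neighbors:
            continue
        M = coaccess.aggregate_metacells(atac_emb[cmask], atac.X[cmask], ccfg)
        edges = coaccess.coaccess_scores(M, bundle.peaks.assign(
            name=bundle.peaks["name"]), ccfg)
        res.edges[atac_name] = edges
        ccans = coaccess.extract_ccans(edges, ccfg.score_min, seed=ccfg.louvain_seed)
        res.ccans[atac_name] = ccans
        ccres = cre.define_ccres(edges, ann, score_min=ccfg.score_min)
        res.ccres[atac_name] = ccres
        res.unidirectional[atac_name] = cre.unidirectional_ccans(
            ccans, res.daps[atac_name], res.degs[atac_name], ccres
        )

    all_degs = (
        pd.concat(all_deg_tables, ignore_index=True)
        if all_deg_tables else pd.DataFrame(columns=["feature", "direction"])
    )
    res.gwas_map = cre.map_gwas(bundle.genes, bundle.gwas, all_degs)
    gwas_degs = set(res.gwas_map.index[res.gwas_map["is_gwas_deg"]])

    # ---- motifs and the TF network ----------------------------------
    tf_genes = tf_genes or {}
    bg = motifs.estimate_background(bundle.sequences)
    models = motifs.load_motifs(default_pfms(), background=bg)
    hits = motifs.pwm_scan(bundle.sequences, models)
    gc = motifs.gc_fraction(bundle.sequences)
    net_rows = []
    for atac_name, ccres in res.ccres.items():
        degs = res.degs.get(atac_name)
        if degs is None or not len(ccres):
            continue
        atac_mask = np.array([f"A{c}" == atac_name for c in atac_cl])
        # use the linked RNA cluster's cells for TF expression
        rna_name = res.links.loc[atac_name, "rna_cluster"]
        rna_mask = np.array([f"R{c}" == rna_name for c in rna_cl])
        expressed = motifs.expressed_tfs(
            rna.X, rna.var_names, rna_mask, tf_genes
        )
        for gene, sub in ccres.groupby("gene"):
            if gene not in gwas_degs:
                continue
            target = sorted(set(sub["distal_peak"]) | set(sub["proximal_peak"]))
            background = [p for p in bundle.peaks["name"] if p not in target]
            enr = motifs.motif_enrichment(target, background, hits, gc,
                                          tfs=[m.tf_name for m in models])
            enr = enr.assign(gene=gene)
            net = motifs.build_network(
                enr, degs, gwas_degs, expressed, tf_genes
            )
            if len(net):
                net_rows.append(net.assign(cluster=atac_name, gene=gene))
    res.network = (
        pd.concat(net_rows, ignore_index=True).drop_duplicates(["tf", "target"])
        if net_rows
        else pd.DataFrame(columns=["tf", "tf_gene", "target", "direction"])
    )

    # ---- variant effects, LD, prioritization ------------------------
    peak_by_name = bundle.peaks.set_index("name")
    effects = []
    risk = dict(zip(bundle.gwas["snv_id"], bundle.gwas["risk_allele"]))
    for _, v in bundle.variant_table.iterrows():
        if v["id"] in risk:
            continue  # GWAS index SNVs are LD anchors, not candidates
        hit_peaks = peak_by_name[
            (peak_by_name["start"] < v["pos"]) & (v["pos"] <= peak_by_name["end"])
        ]
        for pname, prow in hit_peaks.iterrows():
            ctx = bundle.sequences[pname]
            try:
                effects += variants.motif_break(
                    dict(v), ctx, int(prow["start"]), models
                )
            except ValueError:
                continue
    eff = variants.effects_table(effects)
    ld_rows = []
    gwas_ids = [i for i in bundle.variant_table["id"] if i in risk]
    for v in eff["variant"].unique() if len(eff) else []:
        for g in gwas_ids:
            ld_rows.append(
                variants.ld_stats(bundle.haplotypes, bundle.variant_table,
                                  v, g, risk.get(g))
            )
    ld = pd.DataFrame(ld_rows) if ld_rows else pd.DataFrame(
        columns=["variant_a", "variant_b", "r2", "d_prime"]
    )
    maf = pd.Series(
        np.minimum(bundle.haplotypes.mean(axis=1), 1 - bundle.haplotypes.mean(axis=1)),
        index=bundle.variant_table["id"],
    )
    tf_deg_set = {
        tf for tf, g in tf_genes.items()
        if any(g in set(t["feature"]) for t in res.degs.values())
    }
    res.prioritized = variants.prioritize(
        eff, ld, bundle.variant_table, maf=maf, tf_degs=tf_deg_set
    )
    return res


# --------------------------------------------------------------- toy study

TOY_TF_GENES = {"TFA": "g0001"}


def build_toy_bundle(seed: int = 0) -> SimBundle:
    """A two-cluster study with exactly one planted unidirectional CCAN,
    one TF-DEG -> GWAS-DEG relationship, and one high-LD disrupting
    variant."""
    cfg = SimConfig(
        seed=seed,
        n_donors_per_group=4,
        n_cells_per_donor=300,
        n_genes=60,
        n_peaks=45,
        n_subtypes=2,
        planted_lfc=1.5,
        frac_de=2 / 60,
        de_genes=[(0, 1.0), (1, 1.0)],   # target gene g0000 and TF gene g0001
        donor_sd=0.15,
        nb_dispersion=0.4,
        coaccess_blocks=[((0, 3), 0.9)],
        dap_peaks=[(0, 1.0), (1, 1.0), (2, 1.0)],
        block_subtype=0,
        dap_subtype=0,
        motif_targets={"TFA": (0, 3)},
        motif_insert_rate=1.0,
        motif_insert_offset=60,
        marker_frac=0.1,
        marker_lfc=1.5,
        state_size=8,
        atac_mean_rate=0.4,
        gwas_positions=[100_000],
    )
    rna, truth_rna = gen_rna(cfg)
    atac, peaks, seqs, truth_atac = gen_atac(cfg)
    genes, gwas = gen_annotation(cfg)

    # variants consistent with the realized sequences: one motif-breaking
    # SNV in a distal cCRE peak, one neutral insertion, one neutral
    # deletion, and the GWAS index SNV
    def _at(peak_idx, off):
        name = peaks.at[peak_idx, "name"]
        return bundle_seq[name], int(peaks.at[peak_idx, "start"]) + off

    bundle_seq = seqs
    s1, p1 = _at(1, 62)                     # inside the planted TFA site
    ref1 = s1[62]
    alt1 = "C" if ref1 != "C" else "G"
    s2, p2 = _at(4, 120)
    s0, p0 = _at(5, 150)
    sg, pg = _at(0, 0)
    refg = sg[0]
    altg = "A" if refg != "A" else "G"
    variants_list = [
        VariantDef("rs_mot", p1 + 1, ref1, alt1),
        VariantDef("rs_ins", p2 + 1, s2[120], s2[120] + "AT", af=0.3),
        VariantDef("rs_del", p0 + 1, s0[150:153], s0[150], af=0.3),
        VariantDef("gwas_0", pg + 1, refg, altg),
    ]
    gwas["pos"] = [pg + 1 - 1]  # SNV at the 0-based position used for mapping
    gwas["risk_allele"] = [altg]
    cfg2 = replace(
        cfg,
        variants=variants_list,
        ld_pairs=[LdPairSpec("rs_mot", "gwas_0", r2=0.81, d_sign=1)],
    )
    var_table, haps, truth_ld = gen_haplotypes(cfg2)
    truth = GroundTruth(
        de_genes=truth_rna.de_genes,
        dap_peaks=truth_atac.dap_peaks,
        block_membership=truth_atac.block_membership,
        inserted_motifs=truth_atac.inserted_motifs,
        haplotype_ld=truth_ld.haplotype_ld,
        subtype_markers=truth_rna.subtype_markers,
        confounder=truth_rna.confounder,
    )
    return SimBundle(cfg2, rna, atac, peaks, seqs, genes, gwas, var_table,
                     haps, truth)


def run_toy(seed: int = 0) -> tuple[PipelineResult, dict]:
    """Build and analyze the toy study; returns (result, recovered counts)."""
    bundle = build_toy_bundle(seed)
    ccfg = coaccess.CoaccessConfig(k_neighbors=10, base_penalty=0.05)
    res = run_pipeline(bundle, tf_genes=TOY_TF_GENES, coaccess_cfg=ccfg,
                       cluster_resolution=0.2)
    return res, res.counts()
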