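"""Candidate cis-regulatory elements and their integration with
differential results and GWAS loci.

A peak is *proximal* to a gene when it overlaps the strand-aware promoter
(the 2 kb region upstream of the start codon) or the first intron; a cCRE
is a distal peak coaccessible (score >= 0.2, within 500 kb) with such a
proximal peak. Unidirectional CCANs contain at least one differentially
accessible peak and at least one cCRE whose target gene is differentially
expressed, with every such signal sharing one direction (up together with
more-accessible). GWAS genes are those whose gene body lies within
±500 kb (inclusive) of a risk SNV.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

WINDOW_BP = 500_000


def _promoter(row) -> tuple[int, int]:
    sc = int(row.start_codon)
    if row.strand == "+":
        return max(sc - 2000, 0), sc
    return sc, sc + 2000


def _gene_body(row) -> tuple[int, int]:
    """Extent of the modeled gene features (TSS through intron 1)."""
    coords = [int(row.tss), int(row.start_codon)]
    if not (pd.isna(row.intron1_start) or pd.isna(row.intron1_end)):
        coords += [int(row.intron1_start), int(row.intron1_end)]
    return min(coords), max(coords)


def annotate_peaks(peaks: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Per-peak promoter / intron-1 / closest-gene annotation.

    Overlap is >=1 bp on half-open intervals. The closest gene minimizes
    distance to the gene body; exact ties break to the lexicographically
    first gene id and are flagged.
    """
    rows = []
    for p in peaks.itertuples(index=False):
        promoter_of, intron1_of = [], []
        best = (np.inf, None)
        tie = False
        for g in genes.itertuples(index=False):
            if g.chrom != p.chrom:
                continue
            ps, pe = _promoter(g)
            if p.start < pe and p.end > ps:
                promoter_of.append(g.gene_id)
            if not (pd.isna(g.intron1_start) or pd.isna(g.intron1_end)):
                if p.start < int(g.intron1_end) and p.end > int(g.intron1_start):
                    intron1_of.append(g.gene_id)
            b0, b1 = _gene_body(g)
            if p.start < b1 and p.end > b0:
                dist = 0
            else:  # bp gap between the half-open intervals
                dist = b0 - p.end if p.end <= b0 else p.start - b1
            if dist == best[0]:
                tie = True
                if str(g.gene_id) < str(best[1]):
                    best = (dist, g.gene_id)
            elif dist < best[0]:
                tie = False
                best = (dist, g.gene_id)
        rows.append(
            dict(
                peak=p.name,
                promoter_of=sorted(promoter_of),
                intron1_of=sorted(intron1_of),
                closest_gene=best[1],
                closest_distance=int(best[0]) if np.isfinite(best[0]) else None,
                closest_tie=tie,
            )
        )
    return pd.DataFrame(rows).set_index("peak")


def define_ccres(
    edges: pd.DataFrame,
    annotation: pd.DataFrame,
    score_min: float = 0.2,
    max_distance: int = WINDOW_BP,
) -> pd.DataFrame:
    """One cCRE per (distal peak, proximal peak, target gene) triple.

    An edge contributes whenever one endpoint overlaps a gene's promoter
    or first intron; the other endpoint is the distal element. A peak may
    be distal for one gene and proximal for another.
    """
    rows = []
    for e in edges.itertuples(index=False):
        if e.score < score_min or e.distance_bp > max_distance:
            continue
        for prox, dist in ((e.peak_i, e.peak_j), (e.peak_j, e.peak_i)):
            if prox not in annotation.index:
                continue
            ann = annotation.loc[prox]
            for gene in ann["promoter_of"]:
                rows.append(dict(distal_peak=dist, proximal_peak=prox,
                                 gene=gene, score=e.score, link_type="promoter"))
            for gene in ann["intron1_of"]:
                rows.append(dict(distal_peak=dist, proximal_peak=prox,
                                 gene=gene, score=e.score, link_type="intron1"))
    out = pd.DataFrame(rows, columns=["distal_peak", "proximal_peak", "gene",
                                      "score", "link_type"])
    return out.drop_duplicates(["distal_peak", "proximal_peak", "gene", "link_type"]
                               ).reset_index(drop=True)


def dap_deg_overlap(
    daps: pd.DataFrame, degs: pd.DataFrame, annotation: pd.DataFrame
) -> dict:
    """Direction-matched overlap counts between DEGs and DAP closest genes."""
    out = {}
    for dap_dir, deg_dir in (("up", "up"), ("down", "down")):
        dap_genes = {
            annotation.loc[p, "closest_gene"]
            for p in daps.loc[daps["direction"] == dap_dir, "feature"]
            if p in annotation.index
        }
        deg_genes = set(degs.loc[degs["direction"] == deg_dir, "feature"])
        inter = dap_genes & deg_genes
        out[f"{deg_dir}_degs"] = len(deg_genes)
        out[f"{dap_dir}_dap_genes"] = len(dap_genes)
        out[f"overlap_{deg_dir}"] = len(inter)
        out[f"overlap_{deg_dir}_genes"] = sorted(inter)
    return out


def unidirectional_ccans(
    ccans: pd.DataFrame,
    daps: pd.DataFrame,
    degs: pd.DataFrame,
    ccres: pd.DataFrame,
) -> pd.DataFrame:
    """CCANs whose DAPs and cCRE-linked DEGs all share one direction.

    A CCAN is kept when it contains at least one DAP and at least one cCRE
    (distal or proximal member peak) targeting a DEG, every member DAP has
    the same sign, every linked DEG has the matching sign (up together
    with more-accessible), and no opposite-direction signal appears.
    """
    dap_dir = dict(zip(daps["feature"], daps["direction"]))
    deg_dir = dict(zip(degs["feature"], degs["direction"]))
    rows = []
    for ccan_id, sub in ccans.groupby("ccan"):
        members = set(sub["peak"])
        dirs = {dap_dir[p] for p in members if p in dap_dir}
        if len(dirs) != 1:
            continue
        direction = dirs.pop()
        linked = ccres[
            ccres["distal_peak"].isin(members) | ccres["proximal_peak"].isin(members)
        ]
        target_dirs = {
            deg_dir[g] for g in linked["gene"] if g in deg_dir
        }
        if not target_dirs or target_dirs != {direction}:
            continue
        linked_degs = sorted({g for g in linked["gene"] if g in deg_dir})
        rows.append(
            dict(
                ccan=ccan_id,
                direction=direction,
                n_peaks=len(members),
                n_daps=sum(p in dap_dir for p in members),
                linked_degs=",".join(linked_degs),
            )
        )
    return pd.DataFrame(rows, columns=["ccan", "direction", "n_peaks", "n_daps",
                                       "linked_degs"])


def map_gwas(
    genes: pd.DataFrame,
    gwas_snvs: pd.DataFrame,
    degs: pd.DataFrame | None = None,
    window_bp: int = WINDOW_BP,
) -> pd.DataFrame:
    """Flag genes within ±window_bp (inclusive) of any GWAS SNV.

    Distance is measured from the SNV position to the gene body; a gene is
    additionally a GWAS-DEG when it is differentially expressed in at
    least one cluster (``degs`` needs columns feature [, cluster]).
    """
    deg_set = set() if degs is None else set(degs["feature"])
    rows = []
    for g in genes.itertuples(index=False):
        b0, b1 = _gene_body(g)
        hits = []
        for s in gwas_snvs.itertuples(index=False):
            if s.chrom != g.chrom:
                if s.chrom not in set(genes["chrom"]):
                    warnings.warn(f"GWAS SNV {s.snv_id} on unknown chromosome "
                                  f"{s.chrom}; skipped")
                continue
            pos = int(s.pos)
            dist = 0 if b0 <= pos < b1 else min(abs(pos - b0), abs(pos - (b1 - 1)))
            if dist <= window_bp:
                hits.append(s.snv_id)
        rows.append(
            dict(
                gene=g.gene_id,
                snvs=",".join(hits),
                is_gwas_gene=bool(hits),
                is_gwas_deg=bool(hits) and g.gene_id in deg_set,
            )
        )
    return pd.DataFrame(rows).set_index("gene")
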