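"""Readers and writers for the plain-text interchange formats.

Count matrices travel as MatrixMarket + barcodes/features TSVs, intervals as
BED6, gene models as a TSV, sequences as FASTA, haplotypes as VCF 4.2 with
phased genotypes, and motifs as JASPAR-format text. Everything round-trips
through the standard libraries (scipy.io, Biopython, cyvcf2).
"""

from __future__ import annotations

import json
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from Bio import SeqIO, motifs as bio_motifs
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


# ---------------------------------------------------------------- matrices

def write_matrix(adata: ad.AnnData, outdir: str | Path, prefix: str = "") -> None:
    """Write an AnnData as matrix.mtx (features x cells) + TSVs, 10x style."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = sp.csc_matrix(adata.X).T  # features x cells
    scipy.io.mmwrite(str(outdir / f"{prefix}matrix.mtx"), X)
    adata.var.to_csv(outdir / f"{prefix}features.tsv", sep="\t")
    adata.obs.to_csv(outdir / f"{prefix}barcodes.tsv", sep="\t")


def read_matrix(outdir: str | Path, prefix: str = "") -> ad.AnnData:
    outdir = Path(outdir)
    X = sp.csr_matrix(scipy.io.mmread(str(outdir / f"{prefix}matrix.mtx"))).T
    var = pd.read_csv(outdir / f"{prefix}features.tsv", sep="\t", index_col=0)
    obs = pd.read_csv(outdir / f"{prefix}barcodes.tsv", sep="\t", index_col=0)
    obs.index = obs.index.astype(str)
    var.index = var.index.astype(str)
    return ad.AnnData(X=X, obs=obs, var=var)


# ---------------------------------------------------------------- intervals

def write_bed(peaks: pd.DataFrame, path: str | Path) -> None:
    """Write a peak table (chrom, start, end[, name, score, strand]) as BED6."""
    df = peaks.copy()
    if "name" not in df:
        df["name"] = [f"peak_{i}" for i in range(len(df))]
    if "score" not in df:
        df["score"] = 0
    if "strand" not in df:
        df["strand"] = "."
    df[["chrom", "start", "end", "name", "score", "strand"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_bed(path: str | Path) -> pd.DataFrame:
    names = ["chrom", "start", "end", "name", "score", "strand"]
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = names[: df.shape[1]]
    return df


# ---------------------------------------------------------------- sequences

def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------- VCF

def write_vcf(
    variants: pd.DataFrame,
    genotypes: np.ndarray,
    sample_names: list[str],
    path: str | Path,
) -> None:
    """Write a phased VCF 4.2.

    ``variants`` needs columns (chrom, pos, id, ref, alt); ``genotypes`` is
    (n_variants, 2 * n_samples) of 0/1 haplotype alleles, adjacent columns
    forming one sample's phased pair. ``pos`` is 1-based, as in VCF.
    """
    path = Path(path)
    gt = np.asarray(genotypes, dtype=int)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(variants["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_names) + "\n"
        )
        for i, row in enumerate(variants.itertuples(index=False)):
            calls = [
                f"{gt[i, 2 * s]}|{gt[i, 2 * s + 1]}" for s in range(len(sample_names))
            ]
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.id}\t{row.ref}\t{row.alt}"
                f"\t.\tPASS\t.\tGT\t" + "\t".join(calls) + "\n"
            )


def read_vcf_haplotypes(path: str | Path) -> tuple[pd.DataFrame, np.ndarray]:
    """Read a phased VCF into a variant table + (n_variants, n_hap) 0/1 matrix."""
    from cyvcf2 import VCF

    rows, haps = [], []
    vcf = VCF(str(path))
    for rec in vcf:
        rows.append(
            dict(chrom=rec.CHROM, pos=rec.POS, id=rec.ID, ref=rec.REF, alt=rec.ALT[0])
        )
        g = np.asarray(rec.genotypes)[:, :2]  # drop phase flag column
        haps.append(g.reshape(-1))
    vcf.close()
    return pd.DataFrame(rows), np.asarray(haps, dtype=int)


# ---------------------------------------------------------------- motifs

def write_jaspar(pfms: dict[str, np.ndarray], path: str | Path) -> None:
    """Write count matrices (4 x L, rows A C G T) as JASPAR text."""
    with open(path, "w") as fh:
        for name, mat in pfms.items():
            fh.write(f">{name}\t{name}\n")
            for base, row in zip("ACGT", np.asarray(mat)):
                vals = " ".join(f"{v:.0f}" for v in row)
                fh.write(f"{base}  [ {vals} ]\n")


def read_jaspar(path: str | Path) -> dict[str, np.ndarray]:
    """Read JASPAR text into name -> (4, L) count matrices (rows A C G T)."""
    out = {}
    with open(path) as fh:
        for m in bio_motifs.parse(fh, "jaspar"):
            counts = np.array([m.counts[b] for b in "ACGT"], dtype=float)
            out[m.name] = counts
    return out


# ---------------------------------------------------------------- misc

def write_json(obj, path: str | Path) -> None:
    class _Encoder(json.JSONEncoder):
        def default(self, o):
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, set):
                return sorted(o)
            return super().default(o)

    Path(path).write_text(json.dumps(obj, indent=1, cls=_Encoder))


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())
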