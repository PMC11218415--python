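"""Generate the synthetic two-cluster multiome study used by the analysis.

The study plants: two up-regulated DEGs (one of them a TF gene), three
more-accessible DAPs forming a coaccessibility chain in one subtype, a TF
motif inserted in the chain peaks, a GWAS SNV near the target gene, and a
motif-breaking SNV in high LD with it. All inputs are written as
plain-text formats under results/study/.
"""

from pathlib import Path

from regnet.pipeline import build_toy_bundle
from regnet.simulate import write_bundle

OUT = Path(__file__).resolve().parent.parent / "results" / "study"


def main(seed: int = 0):
    bundle = build_toy_bundle(seed)
    write_bundle(bundle, OUT)
    t = bundle.truth
    print(f"study written to {OUT}")
    print(f"  cells: {bundle.rna.n_obs} RNA, {bundle.atac.n_obs} ATAC; "
          f"{bundle.rna.n_vars} genes, {len(bundle.peaks)} peaks")
    print(f"  planted DEGs: {t.de_genes}")
    print(f"  planted DAPs: {t.dap_peaks}")
    print(f"  coaccessibility block peaks: {sorted(t.block_membership)}")
    print(f"  motif insertions: {t.inserted_motifs}")
    print(f"  planted LD: {t.haplotype_ld}")


if __name__ == "__main__":
    main()
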