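"""Per-nucleus QC and normalization of the simulated study.

Applies the RNA feature-count and mitochondrial-fraction rules and the
five ATAC metrics, demonstrates the consensus-peak Fisher combination on
per-donor peak calls derived from the study peaks, and writes the kept
barcodes and the ATAC LSI embedding summary.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from regnet import qc
from regnet.pipeline import build_toy_bundle

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main(seed: int = 0):
    bundle = build_toy_bundle(seed)
    RESULTS.mkdir(exist_ok=True)

    kept_rna, rna = qc.qc_rna(bundle.rna)
    print(f"RNA QC: kept {len(kept_rna)} / {bundle.rna.n_obs} nuclei")
    kept_atac = qc.qc_atac(bundle.atac.obs)
    print(f"ATAC QC: kept {len(kept_atac)} / {bundle.atac.n_obs} nuclei")
    pd.Series(kept_rna).to_csv(RESULTS / "qc_kept_rna.tsv", sep="\t",
                               index=False, header=False)
    pd.Series(kept_atac).to_csv(RESULTS / "qc_kept_atac.tsv", sep="\t",
                                index=False, header=False)

    lsi = qc.tfidf_lsi(bundle.atac[kept_atac].X, dims=10)
    print(f"LSI: dropped depth-correlated components {lsi.dropped_components} "
          f"(rho = {np.round(lsi.depth_correlations, 2)})")

    # consensus peaks: each donor "calls" every true peak with a strong
    # p-value plus one private spurious call that the filter should drop
    rng = np.random.default_rng(seed)
    donors = bundle.rna.obs["donor"].unique()[:4]
    calls = []
    for k, d in enumerate(donors):
        mine = [
            ((r.chrom, r.start - rng.integers(0, 30), r.end + rng.integers(0, 30)),
             float(10 ** -rng.uniform(6, 9)))
            for r in bundle.peaks.itertuples(index=False)
        ]
        mine.append((("chrS", 2_000_000 + 5_000 * k, 2_000_200 + 5_000 * k), 1e-8))
        calls.append(mine)
    consensus = qc.consensus_peaks(calls)
    consensus.to_csv(RESULTS / "consensus_peaks.tsv", sep="\t", index=False)
    print(f"consensus peaks: {len(consensus)} kept from "
          f"{sum(len(c) for c in calls)} per-donor calls "
          f"(private calls dropped: {len(consensus) == len(bundle.peaks)})")


if __name__ == "__main__":
    main()
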