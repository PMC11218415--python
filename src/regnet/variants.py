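"""Allele-specific motif disruption scoring and haplotype LD statistics.

A variant's effect on a TF binding site is measured by rescanning the
reference and alternate sequence windows with an information-content (ic)
weighted match score

    score = sum_i ic_i * p_i(b_i) / sum_i ic_i * max_b p_i(b)  in [0, 1],

maximized over positions and strands; the match p-value at the best
position comes from the exact log-odds null distribution of the scan
machinery. Insertions and deletions are handled by applying the REF->ALT
edit and rescanning a window extending at least motif-length - 1 beyond
the edit on both sides. Linkage disequilibrium (D, D', r2) is computed
from phased haplotype columns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .motifs import MotifModel, revcomp


# --------------------------------------------------------------- scoring

def score_allele(window: str, motif: MotifModel) -> tuple[float, float]:
    """Best ic-weighted match score and its p-value over positions/strands."""
    window = window.upper()
    L = len(motif)
    if len(window) < L:
        raise ValueError(f"window ({len(window)} bp) shorter than motif ({L} bp)")
    ic = motif.ic
    denom = float(np.sum(ic * motif.pwm.max(axis=1)))
    best = (-np.inf, None, None, None)  # (weighted score, strand, offset, codes)
    for strand, seq in (("+", window), ("-", revcomp(window))):
        enc = np.frombuffer(seq.encode(), dtype=np.uint8)
        code = np.full(len(seq), -1, dtype=np.int64)
        for i, b in enumerate("ACGT"):
            code[enc == ord(b)] = i
        for off in range(len(seq) - L + 1):
            idx = code[off: off + L]
            pr = np.where(idx >= 0, motif.pwm[np.arange(L), np.clip(idx, 0, 3)], 0.25)
            s = float(np.sum(ic * pr)) / denom
            if s > best[0]:
                best = (s, strand, off, idx)
    s, strand, off, idx = best
    binned = int(
        np.sum(
            np.where(idx >= 0, motif._bins[np.arange(L), np.clip(idx, 0, 3)], 0)
        )
    )
    return s, motif.score_pvalue(binned)


@dataclass
class VariantEffect:
    variant_id: str
    variant_type: str       # SNV / insertion / deletion
    tf: str
    ref_score: float
    alt_score: float
    ref_p: float
    alt_p: float

    @property
    def allele_diff(self) -> float:
        return self.alt_score - self.ref_score

    @property
    def direction(self) -> str:
        return "gain" if self.allele_diff > 0 else "loss"

    @property
    def strength(self) -> str:
        return "strong" if abs(self.allele_diff) >= 0.4 else "weak"


def _variant_type(ref: str, alt: str) -> str:
    if len(ref) == len(alt) == 1:
        return "SNV"
    return "insertion" if len(alt) > len(ref) else "deletion"


def motif_break(
    variant: dict,
    ref_context: str,
    context_start: int,
    motifs: list[MotifModel],
    p_max: float = 1e-4,
) -> list[VariantEffect]:
    """Score REF vs ALT windows around a variant against each motif.

    ``variant`` needs keys (id, pos, ref, alt) with 1-based ``pos``;
    ``ref_context`` is the reference sequence starting at 0-based
    ``context_start``. Effects are kept when min(ref_p, alt_p) < p_max.
    """
    pos0 = int(variant["pos"]) - 1 - context_start
    ref, alt = variant["ref"].upper(), variant["alt"].upper()
    if pos0 < 0 or pos0 + len(ref) > len(ref_context):
        raise ValueError("variant not contained in the provided context")
    if ref_context[pos0: pos0 + len(ref)].upper() != ref:
        raise ValueError(
            f"REF mismatch at {variant['id']}: context has "
            f"{ref_context[pos0: pos0 + len(ref)]!r}, VCF says {ref!r}"
        )
    vtype = _variant_type(ref, alt)
    out = []
    for m in motifs:
        L = len(m)
        pad = L - 1
        w0 = max(pos0 - pad, 0)
        w1 = min(pos0 + len(ref) + pad, len(ref_context))
        if pos0 - w0 < pad or w1 - (pos0 + len(ref)) < pad:
            raise ValueError(
                f"context around {variant['id']} shorter than motif length - 1"
            )
        ref_win = ref_context[w0:w1]
        alt_win = (
            ref_context[w0:pos0] + alt + ref_context[pos0 + len(ref): w1]
        )
        ref_s, ref_p = score_allele(ref_win, m)
        alt_s, alt_p = score_allele(alt_win, m)
        if min(ref_p, alt_p) < p_max:
            out.append(
                VariantEffect(
                    variant_id=variant["id"], variant_type=vtype, tf=m.tf_name,
                    ref_score=ref_s, alt_score=alt_s, ref_p=ref_p, alt_p=alt_p,
                )
            )
    return out


def effects_table(effects: list[VariantEffect]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                variant=e.variant_id, type=e.variant_type, tf=e.tf,
                ref_score=e.ref_score, alt_score=e.alt_score,
                ref_p=e.ref_p, alt_p=e.alt_p, allele_diff=e.allele_diff,
                direction=e.direction, strength=e.strength,
            )
            for e in effects
        ],
        columns=["variant", "type", "tf", "ref_score", "alt_score", "ref_p",
                 "alt_p", "allele_diff", "direction", "strength"],
    )


# --------------------------------------------------------------- LD

def ld_from_haplotypes(a: np.ndarray, b: np.ndarray) -> dict:
    """D, D', r2 and haplotype frequencies from two 0/1 haplotype columns."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n = len(a)
    pA, pB = a.mean(), b.mean()
    if pA in (0.0, 1.0) or pB in (0.0, 1.0):
        return dict(p_a=pA, p_b=pB, p_ab=np.nan, d=np.nan, d_prime=np.nan,
                    r2=np.nan, note="monomorphic variant; LD undefined")
    pAB = np.mean(a * b)
    D = pAB - pA * pB
    if D >= 0:
        d_max = min(pA * (1 - pB), (1 - pA) * pB)
    else:
        d_max = min(pA * pB, (1 - pA) * (1 - pB))
    d_prime = D / d_max if d_max > 0 else np.nan
    r2 = D * D / (pA * (1 - pA) * pB * (1 - pB))
    return dict(p_a=pA, p_b=pB, p_ab=pAB, d=D, d_prime=d_prime, r2=r2, note="")


def ld_stats(
    haplotypes: np.ndarray,
    variant_table: pd.DataFrame,
    id_a: str,
    id_b: str,
    risk_allele_of_b: str | None = None,
) -> dict:
    """LD between two panel variants, with risk-phase annotation.

    ``haplotypes`` is (n_variants, n_haplotypes) of 0/1 alleles aligned to
    ``variant_table`` rows. When the GWAS risk allele of b is given, the
    phase note reports which allele of a co-occurs with it (sign of D
    under risk coding).
    """
    idx = {v: i for i, v in enumerate(variant_table["id"])}
    a = haplotypes[idx[id_a]]
    b = haplotypes[idx[id_b]]
    out = ld_from_haplotypes(a, b)
    out["variant_a"], out["variant_b"] = id_a, id_b
    if risk_allele_of_b is not None and np.isfinite(out.get("d", np.nan)):
        row_b = variant_table.set_index("id").loc[id_b]
        risk_is_alt = risk_allele_of_b == row_b["alt"]
        d_risk = out["d"] if risk_is_alt else -out["d"]
        row_a = variant_table.set_index("id").loc[id_a]
        allele = row_a["alt"] if d_risk > 0 else row_a["ref"]
        out["phase_note"] = (
            f"{id_a} allele {allele} co-occurs with risk allele "
            f"{risk_allele_of_b} of {id_b}"
        )
        out["risk_coupled_allele"] = allele
    return out


def prioritize(
    effects: pd.DataFrame,
    ld_results: pd.DataFrame,
    variant_table: pd.DataFrame,
    maf: pd.Series | None = None,
    tf_degs: set[str] | None = None,
    threshold: float = 0.5,
    maf_min: float = 0.01,
) -> pd.DataFrame:
    """Join motif effects with LD and keep r2 >= threshold and D' >= threshold.

    ``ld_results`` needs columns (variant_a, r2, d_prime[,
    risk_coupled_allele]); variants without an LD partner in the panel are
    excluded (logged), as are those below the minor-allele-frequency
    floor. The result is sorted by (r2, |allele_diff|) descending and
    annotated with whether the binding-gain allele is the risk-coupled
    allele.
    """
    import warnings

    ld = ld_results.set_index("variant_a")
    vt = variant_table.set_index("id")
    rows = []
    for e in effects.itertuples(index=False):
        if maf is not None and e.variant in maf.index and maf[e.variant] < maf_min:
            continue
        if e.variant not in ld.index:
            warnings.warn(f"variant {e.variant} has no LD partner in panel; excluded")
            continue
        rec = ld.loc[e.variant]
        if not (rec["r2"] >= threshold and rec["d_prime"] >= threshold):
            continue
        risk_allele = rec.get("risk_coupled_allele")
        gain_allele = vt.loc[e.variant, "alt" if e.allele_diff > 0 else "ref"]
        rows.append(
            dict(
                variant=e.variant, type=e.type, tf=e.tf,
                ref_score=e.ref_score, alt_score=e.alt_score,
                allele_diff=e.allele_diff, direction=e.direction,
                strength=e.strength, r2=float(rec["r2"]),
                d_prime=float(rec["d_prime"]),
                gwas_snv=rec.get("variant_b"),
                risk_concordant=(
                    None if risk_allele is None else bool(gain_allele == risk_allele)
                ),
                tf_is_deg=(e.tf in tf_degs) if tf_degs is not None else None,
            )
        )
    out = pd.DataFrame(
        rows,
        columns=["variant", "type", "tf", "ref_score", "alt_score", "allele_diff",
                 "direction", "strength", "r2", "d_prime", "gwas_snv",
                 "risk_concordant", "tf_is_deg"],
    )
    if len(out):
        out = out.sort_values(
            ["r2", "allele_diff"],
            key=lambda s: np.abs(s) if s.name == "allele_diff" else s,
            ascending=False,
        ).reset_index(drop=True)
    return out
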