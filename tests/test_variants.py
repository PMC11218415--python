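"""Allele-specific motif scoring, indel handling, LD exactness,
prioritization thresholds."""

import itertools

import numpy as np
import pandas as pd
import pytest

from regnet.motifs import MotifModel, load_motifs, revcomp
from regnet.simulate import DEFAULT_PFMS, consensus_pfm, default_pfms
from regnet.variants import (
    effects_table, ld_from_haplotypes, ld_stats, motif_break, prioritize,
    score_allele,
)

TFA = load_motifs(default_pfms())[0]
CONS = DEFAULT_PFMS["TFA"]


class TestScoreAllele:
    def test_consensus_scores_exactly_one(self):
        s, p = score_allele("AA" + CONS + "AA", TFA)
        assert s == pytest.approx(1.0)
        assert p < 1e-4

    def test_reverse_complement_scores_one(self):
        s, p = score_allele(revcomp("AA" + CONS + "AA"), TFA)
        assert s == pytest.approx(1.0)

    def test_anti_consensus_of_sharp_motif_scores_low(self):
        """For a near-deterministic PWM the worst window scores about
        p_min / p_max per position (closed-form ratio)."""
        sharp = MotifModel.from_counts("sharp", consensus_pfm("ACGTACGT",
                                                              97, 1))
        worst = "".join({"A": "C", "C": "A", "G": "T", "T": "G"}[b]
                        for b in "ACGTACGT")
        # window containing only anti-consensus letters
        s, p = score_allele(worst, sharp)
        expected_floor = sharp.pwm.min() / sharp.pwm.max()
        assert s < 0.2
        assert s >= expected_floor - 1e-9

    def test_short_window_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            score_allele("ACGT", TFA)

    def test_score_bounds_random_windows(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            w = "".join(rng.choice(list("ACGT"), 12))
            s, p = score_allele(w, TFA)
            assert 0.0 <= s <= 1.0
            assert (s == pytest.approx(1.0)) == (
                CONS in w or revcomp(CONS) in w)


def _variant(vid, pos, ref, alt):
    return dict(id=vid, pos=pos, ref=ref, alt=alt)


class TestMotifBreak:
    CONTEXT = "A" * 20 + CONS + "A" * 20  # motif at offset 20, context at 0

    def test_snv_at_top_ic_position_is_strongest_loss(self):
        """Destroying the consensus gives the largest |allele diff| among
        all single-base substitutions (exhaustive scan oracle)."""
        diffs = {}
        for off in range(len(CONS)):
            pos0 = 20 + off
            ref = self.CONTEXT[pos0]
            for alt in "ACGT":
                if alt == ref:
                    continue
                eff = motif_break(
                    _variant("v", pos0 + 1, ref, alt), self.CONTEXT, 0, [TFA]
                )
                if eff:
                    diffs[(off, alt)] = eff[0].allele_diff
        assert diffs  # consensus ref windows always pass the p filter
        assert all(d <= 0 for d in diffs.values())  # any change is a loss
        # the motif is equally sharp at every position, so the worst
        # substitutions are the within-motif ones; flanking SNVs don't appear
        assert min(diffs.values()) < -0.05

    def test_change_at_uniform_pwm_position_has_zero_diff(self):
        """A substitution at a position the motif is indifferent to
        (uniform column) leaves the match score unchanged."""
        counts = consensus_pfm("TGACTCAC", 85, 5)
        counts[:, 4] = 25.0  # position 5 carries no information
        m = MotifModel.from_counts("TFA_soft", counts)
        ctx = "A" * 20 + "TGACTCAC" + "A" * 20
        pos0 = 24  # the uniform position
        eff = motif_break(_variant("v", pos0 + 1, ctx[pos0], "G"), ctx, 0, [m])
        assert eff and eff[0].allele_diff == pytest.approx(0.0, abs=1e-12)

    def test_swap_ref_alt_flips_sign_exactly(self):
        pos0 = 22
        ref = self.CONTEXT[pos0]
        alt_context = self.CONTEXT[:pos0] + "C" + self.CONTEXT[pos0 + 1:]
        fwd = motif_break(_variant("v", pos0 + 1, ref, "C"), self.CONTEXT, 0,
                          [TFA])
        rev = motif_break(_variant("v", pos0 + 1, "C", ref), alt_context, 0,
                          [TFA])
        assert fwd and rev
        assert fwd[0].allele_diff == pytest.approx(-rev[0].allele_diff)

    def test_two_bp_deletion_in_motif_reported_as_loss(self):
        pos0 = 23
        ref = self.CONTEXT[pos0: pos0 + 3]
        eff = motif_break(_variant("v", pos0 + 1, ref, ref[0]), self.CONTEXT,
                          0, [TFA])
        assert eff
        e = eff[0]
        assert e.variant_type == "deletion"
        assert e.direction == "loss"
        assert e.alt_p > e.ref_p

    def test_insertion_type_and_strength_labels(self):
        pos0 = 24
        ref = self.CONTEXT[pos0]
        eff = motif_break(_variant("v", pos0 + 1, ref, ref + "GG"),
                          self.CONTEXT, 0, [TFA])
        assert eff and eff[0].variant_type == "insertion"
        table = effects_table(eff)
        assert set(table["strength"]) <= {"strong", "weak"}
        assert (table["strength"] == np.where(
            table["allele_diff"].abs() >= 0.4, "strong", "weak")).all()

    def test_ref_mismatch_guard(self):
        with pytest.raises(ValueError, match="REF mismatch"):
            motif_break(_variant("v", 21, "G", "T"), self.CONTEXT, 0, [TFA])

    def test_low_information_windows_filtered_by_p(self):
        ctx = "A" * 41
        eff = motif_break(_variant("v", 21, "A", "C"), ctx, 0, [TFA])
        assert eff == []


class TestLdStats:
    def test_exhaustive_panels_match_correlation_oracle(self):
        """For every haplotype table with n <= 12, r2 equals the squared
        Pearson correlation of the 0/1 columns, and D' its normalized
        bound (brute-force oracle)."""
        checked = 0
        for n in range(2, 13):
            for n11, n10, n01 in itertools.product(range(n + 1), repeat=3):
                n00 = n - n11 - n10 - n01
                if n00 < 0:
                    continue
                a = np.repeat([1, 1, 0, 0], [n11, n10, n01, n00])
                b = np.repeat([1, 0, 1, 0], [n11, n10, n01, n00])
                pA, pB = a.mean(), b.mean()
                out = ld_from_haplotypes(a, b)
                if pA in (0, 1) or pB in (0, 1):
                    assert np.isnan(out["r2"])
                    continue
                r = np.corrcoef(a, b)[0, 1]
                assert out["r2"] == pytest.approx(r * r, rel=1e-9, abs=1e-12)
                D = n11 / n - pA * pB
                d_max = (min(pA * (1 - pB), (1 - pA) * pB) if D >= 0
                         else min(pA * pB, (1 - pA) * (1 - pB)))
                assert out["d"] == pytest.approx(D, abs=1e-12)
                assert out["d_prime"] == pytest.approx(D / d_max, rel=1e-9)
                assert 0 <= out["r2"] <= 1 + 1e-12
                assert abs(out["d_prime"]) <= 1 + 1e-9
                checked += 1
        assert checked > 1000

    def test_hand_enumerated_4114_table(self):
        a = np.repeat([1, 1, 0, 0], [4, 1, 1, 4])
        b = np.repeat([1, 0, 1, 0], [4, 1, 1, 4])
        out = ld_from_haplotypes(a, b)
        assert out["d"] == pytest.approx(0.15)
        assert out["r2"] == pytest.approx(0.36)
        assert out["d_prime"] == pytest.approx(0.6)

    def test_identical_columns_perfect_ld(self):
        a = np.array([0, 1, 1, 0, 1, 0])
        out = ld_from_haplotypes(a, a)
        assert out["r2"] == pytest.approx(1.0)
        assert out["d_prime"] == pytest.approx(1.0)

    def test_independent_large_panel_near_zero(self):
        rng = np.random.default_rng(0)
        a = rng.integers(0, 2, 10_000)
        b = rng.integers(0, 2, 10_000)
        assert ld_from_haplotypes(a, b)["r2"] < 0.01

    def test_monomorphic_returns_na_with_reason(self):
        out = ld_from_haplotypes(np.zeros(10), np.array([0, 1] * 5))
        assert np.isnan(out["r2"])
        assert "monomorphic" in out["note"]

    def test_phase_note_reports_risk_coupled_allele(self):
        table = pd.DataFrame(
            dict(chrom=["chrS"] * 2, pos=[10, 20], id=["a", "b"],
                 ref=["C", "G"], alt=["T", "A"])
        )
        # alt of a always co-occurs with alt (risk) of b
        H = np.array([[1, 1, 0, 0, 1, 0], [1, 1, 0, 0, 1, 0]])
        out = ld_stats(H, table, "a", "b", risk_allele_of_b="A")
        assert out["risk_coupled_allele"] == "T"
        out2 = ld_stats(H, table, "a", "b", risk_allele_of_b="G")
        assert out2["risk_coupled_allele"] == "C"


class TestPrioritize:
    TABLE = pd.DataFrame(
        dict(chrom=["chrS"] * 3, pos=[10, 20, 30],
             id=["v1", "v2", "gwas"], ref=["C", "G", "T"],
             alt=["T", "GA", "A"])
    )

    def _effects(self, variants=("v1", "v2")):
        return pd.DataFrame(
            [dict(variant=v, type="SNV", tf="TFA", ref_score=1.0,
                  alt_score=0.4, ref_p=1e-5, alt_p=0.3,
                  allele_diff=-0.6, direction="loss", strength="strong")
             for v in variants]
        )

    def _ld(self, r2s):
        return pd.DataFrame(
            [dict(variant_a=v, variant_b="gwas", r2=r2, d_prime=max(r2, 0.6),
                  risk_coupled_allele="T")
             for v, r2 in r2s.items()]
        )

    def test_threshold_half_is_inclusive_and_049_excluded(self):
        out = prioritize(self._effects(), self._ld({"v1": 0.5, "v2": 0.49}),
                         self.TABLE)
        assert list(out["variant"]) == ["v1"]

    def test_low_maf_excluded(self):
        maf = pd.Series({"v1": 0.005, "v2": 0.4, "gwas": 0.5})
        out = prioritize(self._effects(), self._ld({"v1": 1.0, "v2": 0.9}),
                         self.TABLE, maf=maf)
        assert list(out["variant"]) == ["v2"]

    def test_missing_ld_partner_logged_and_excluded(self):
        with pytest.warns(UserWarning, match="no LD partner"):
            out = prioritize(self._effects(), self._ld({"v1": 0.9}), self.TABLE)
        assert list(out["variant"]) == ["v1"]

    def test_risk_concordance_of_gain_allele(self):
        eff = self._effects(["v1"]).assign(allele_diff=0.6, direction="gain")
        out = prioritize(eff, self._ld({"v1": 1.0}), self.TABLE)
        # gain allele is ALT ("T"), which sits on the risk haplotype
        assert bool(out["risk_concordant"].iloc[0])

    def test_sorted_by_r2_then_effect(self):
        eff = pd.concat([self._effects(["v1"]),
                         self._effects(["v2"]).assign(allele_diff=-0.2)])
        out = prioritize(eff, self._ld({"v1": 0.7, "v2": 0.9}), self.TABLE)
        assert list(out["variant"]) == ["v2", "v1"]
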