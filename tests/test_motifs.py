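"""Exact scan p-values, GC-weighted enrichment, TF filters, network rules."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from regnet.motifs import (
    MotifModel, build_network, estimate_background, expressed_tfs,
    gc_fraction, load_motifs, motif_enrichment, pwm_scan, revcomp,
)
from regnet.simulate import DEFAULT_PFMS, consensus_pfm, default_pfms


def _brute_force_tail(model: MotifModel):
    """Enumerate all words of the motif's length under its background."""
    L = len(model)
    probs = {}
    for word in itertools.product(range(4), repeat=L):
        s = sum(int(model._bins[j, b]) for j, b in enumerate(word))
        p = float(np.prod([model.background[b] for b in word]))
        probs[s] = probs.get(s, 0.0) + p
    return probs


@pytest.mark.parametrize("length", [2, 3, 5, 8])
@pytest.mark.parametrize("bg", [None, (0.3, 0.2, 0.2, 0.3)])
def test_dp_null_equals_enumeration(length, bg):
    """The DP tail equals brute-force enumeration for every attainable
    score, for motifs up to length 8 under uniform and skewed backgrounds."""
    rng = np.random.default_rng(length * 10 + (0 if bg is None else 1))
    counts = rng.integers(1, 80, (4, length)).astype(float)
    m = MotifModel.from_counts("X", counts, background=bg)
    probs = _brute_force_tail(m)
    scores = sorted(probs)
    tails = np.cumsum([probs[s] for s in reversed(scores)])[::-1]
    for s, tail in zip(scores, tails):
        assert m.score_pvalue(s) == pytest.approx(tail, rel=1e-9, abs=1e-15)


class TestScan:
    def test_consensus_hit_has_max_score_and_consensus_probability(self):
        m = load_motifs(default_pfms())[0]
        seq = "A" * 40 + DEFAULT_PFMS["TFA"] + "A" * 40
        hits = pwm_scan({"p": seq}, [m])
        hits = hits[hits["tf"] == "TFA"]
        assert len(hits) == 1
        # p-value of the top score is the background probability of the
        # single best word (the consensus)
        assert hits["p_value"].iloc[0] == pytest.approx(0.25**8, rel=1e-6)
        assert hits["offset"].iloc[0] == 40

    def test_uniform_pwm_never_hits(self):
        flat = np.full((4, 6), 25.0)
        m = MotifModel.from_counts("flat", flat)
        seqs = {"p": "ACGTACGTACGTACGTACGTGCGT"}
        assert len(pwm_scan(seqs, [m])) == 0

    def test_reverse_strand_hit_found_and_collapsed(self):
        m = load_motifs(default_pfms())[0]
        cons = DEFAULT_PFMS["TFA"]
        seq = "C" * 30 + revcomp(cons) + "C" * 30
        hits = pwm_scan({"p": seq}, [m])
        assert len(hits) == 1
        assert hits["strand"].iloc[0] == "-"
        # overlapping forward+reverse occurrences collapse to the best one
        seq2 = "C" * 30 + cons + "C" * 30
        both = pwm_scan({"p": seq2}, [m])
        assert len(both) == 1

    def test_n_bases_score_as_background(self):
        m = load_motifs(default_pfms())[0]
        seq = "N" * 20 + DEFAULT_PFMS["TFA"] + "N" * 20
        hits = pwm_scan({"p": seq}, [m])
        assert len(hits) == 1


class TestEnrichment:
    def _gc(self, names, value=0.5):
        return pd.Series(value, index=names)

    def test_binomial_tail_matches_closed_form(self):
        """k=10 of n=20 targets hit at background rate 0.1: fold 5, and the
        one-sided binomial tail 7.15e-6 (closed form)."""
        targets = [f"t{i}" for i in range(20)]
        bg = [f"b{i}" for i in range(100)]
        hits = pd.DataFrame(
            dict(peak=targets[:10] + bg[:10], tf="TFA",
                 strand="+", offset=0, score=5.0, p_value=1e-6)
        )
        res = motif_enrichment(targets, bg, hits, self._gc(targets + bg))
        row = res.set_index("tf").loc["TFA"]
        assert row["fold"] == pytest.approx(5.0)
        # closed-form tail: sum_{j>=10} C(20,j) 0.1^j 0.9^(20-j) = 7.15e-6
        oracle = sum(
            np.prod([20 - i for i in range(j)]) / np.prod(range(1, j + 1))
            * 0.1**j * 0.9 ** (20 - j)
            for j in range(10, 21)
        )
        assert oracle == pytest.approx(7.15e-6, rel=0.01)
        assert stats.binom.sf(9, 20, 0.1) == pytest.approx(oracle, rel=1e-9)
        assert row["p"] == pytest.approx(oracle, rel=1e-9)

    def test_equal_rates_give_fold_one_and_no_report(self):
        targets = [f"t{i}" for i in range(20)]
        bg = [f"b{i}" for i in range(20)]
        hits = pd.DataFrame(
            dict(peak=targets[:5] + bg[:5], tf="TFA", strand="+", offset=0,
                 score=5.0, p_value=1e-6)
        )
        res = motif_enrichment(targets, bg, hits, self._gc(targets + bg))
        row = res.set_index("tf").loc["TFA"]
        assert row["fold"] == pytest.approx(1.0)
        assert not row["reported"]

    def test_planted_motif_reported(self, small_atac):
        from regnet.motifs import pwm_scan

        adata, peaks, seqs, truth = small_atac
        bg = estimate_background(seqs)
        models = load_motifs(default_pfms(), background=bg)
        hits = pwm_scan(seqs, models)
        targets = sorted(truth.inserted_motifs)
        background = [p for p in seqs if p not in set(targets)]
        res = motif_enrichment(targets, background, hits, gc_fraction(seqs),
                               tfs=[m.tf_name for m in models])
        row = res.set_index("tf").loc["TFA"]
        assert row["reported"] and row["fold"] >= 1.2 and row["fdr"] <= 0.05

    def test_gc_weighting_corrects_composition_bias(self):
        """A GC-rich motif (TFB) called on GC-skewed targets: with weighting
        the background rate comes from GC-matched peaks."""
        rng = np.random.default_rng(0)
        targets = [f"t{i}" for i in range(20)]
        bg_rich = [f"r{i}" for i in range(50)]   # GC-rich background
        bg_poor = [f"q{i}" for i in range(50)]
        gc = pd.Series(
            {**{t: 0.7 for t in targets}, **{b: 0.7 for b in bg_rich},
             **{b: 0.3 for b in bg_poor}}
        )
        # hits occur in GC-rich peaks only, at equal rates
        hits = pd.DataFrame(
            dict(peak=targets[:8] + bg_rich[:20], tf="TFB", strand="+",
                 offset=0, score=5.0, p_value=1e-6)
        )
        res = motif_enrichment(targets, bg_rich + bg_poor, hits, gc)
        row = res.set_index("tf").loc["TFB"]
        # weighted background rate ~0.4 (from GC-matched peaks), so no
        # spurious enrichment: 8/20 = 0.4
        assert row["fold"] == pytest.approx(1.0, abs=0.05)

    def test_overlapping_sets_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            motif_enrichment(["a"], ["a", "b"], pd.DataFrame(columns=["tf", "peak"]),
                             self._gc(["a", "b"]))

    def test_label_exchange_calibration(self):
        """Random target/background splits of peaks with identical hit
        rates give approximately uniform p-values."""
        rng = np.random.default_rng(1)
        n, nt = 320, 20  # background much larger than targets, as in use
        peaks = [f"p{i}" for i in range(n)]
        with_hit = set(rng.choice(peaks, n // 3, replace=False))
        hits = pd.DataFrame(dict(peak=sorted(with_hit), tf="TFA", strand="+",
                                 offset=0, score=5.0, p_value=1e-6))
        gc = pd.Series(rng.uniform(0.3, 0.7, n), index=peaks)
        ps = []
        for _ in range(200):
            perm = rng.permutation(peaks)
            res = motif_enrichment(list(perm[:nt]), list(perm[nt:]), hits, gc)
            ps.append(res["p"].iloc[0])
        assert np.mean(np.asarray(ps) < 0.05) <= 0.07


class TestExpressedTfs:
    def _matrix(self, frac, n=1000):
        X = np.zeros((n, 1))
        X[: int(round(frac * n)), 0] = 1
        return X

    @pytest.mark.parametrize("frac,kept", [(0.10, True), (0.099, False),
                                           (0.0, False)])
    def test_detection_fraction_threshold_inclusive(self, frac, kept):
        out = expressed_tfs(self._matrix(frac), ["gTF"], np.ones(1000, bool),
                            {"TFA": "gTF"})
        assert ("TFA" in out) == kept

    def test_absent_gene_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="absent"):
            out = expressed_tfs(self._matrix(0.5), ["gOther"],
                                np.ones(1000, bool), {"TFA": "gTF"})
        assert out == set()


class TestNetwork:
    DEGS = pd.DataFrame(dict(feature=["gTF", "gT", "gDown"],
                             direction=["up", "up", "down"]))

    def _enr(self, tf="TFA", gene="gT"):
        return pd.DataFrame([dict(tf=tf, gene=gene, fold=5.0, p=1e-6,
                                  fdr=1e-5, reported=True)])

    def test_single_matched_edge(self):
        net = build_network(self._enr(), self.DEGS, {"gT"}, {"TFA"},
                            {"TFA": "gTF"})
        assert len(net) == 1
        assert net.loc[0, "tf_out_degree"] == 1
        assert net.loc[0, "target_in_degree"] == 1

    def test_non_deg_tf_excluded(self):
        net = build_network(self._enr(tf="TFB"), self.DEGS, {"gT"}, {"TFB"},
                            {"TFB": "gNotDeg"})
        assert len(net) == 0

    def test_sign_mismatch_excluded(self):
        net = build_network(self._enr(gene="gDown"), self.DEGS, {"gDown"},
                            {"TFA"}, {"TFA": "gTF"})
        assert len(net) == 0

    def test_unexpressed_tf_excluded(self):
        net = build_network(self._enr(), self.DEGS, {"gT"}, set(),
                            {"TFA": "gTF"})
        assert len(net) == 0

    def test_edge_count_monotone_in_filters(self):
        rng = np.random.default_rng(2)
        rows = []
        for i in range(40):
            rows.append(dict(tf="TFA", gene=f"g{i}", fold=rng.uniform(1, 6),
                             p=10 ** -rng.uniform(1, 8), fdr=None))
        enr = pd.DataFrame(rows)
        enr["fdr"] = enr["p"] * 2
        degs = pd.DataFrame(dict(
            feature=["gTF"] + [f"g{i}" for i in range(40)],
            direction=["up"] * 41,
        ))
        gwas = {f"g{i}" for i in range(40)}
        prev = None
        for fold_min, fdr_max in [(1.0, 0.05), (1.5, 0.05), (1.5, 0.01),
                                  (2.5, 0.001)]:
            sub = enr[(enr["fold"] >= fold_min) & (enr["fdr"] <= fdr_max)]
            net = build_network(sub, degs, gwas, {"TFA"}, {"TFA": "gTF"})
            if prev is not None:
                assert len(net) <= prev
            prev = len(net)
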