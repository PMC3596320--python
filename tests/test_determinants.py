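"""Sequence features (CAI, tAI, GC, motifs, upstream windows) and the
AIC-selected covariance model of half-life determinants."""

import math

import numpy as np
import pandas as pd
import pytest

from mrnastab import (compute_cai, compute_tai, count_motif, extract_upstream,
                      fit_covariance_model, gc_content, growth_rate_only_r2,
                      reference_codon_weights, simulate_feature_table,
                      tai_codon_weights)


class TestUpstreamExtraction:
    GENOME = ("ATGC" * 75)  # 300 nt, fully determined

    def test_plus_strand_window(self):
        out = extract_upstream(self.GENOME, 101, "+")
        assert out == self.GENOME[0:101]
        assert len(out) == 101

    def test_minus_strand_is_reverse_complement(self):
        # minus-strand "+1" is position 150; upstream runs 150..250 (101 nt)
        from Bio.Seq import Seq
        out = extract_upstream(self.GENOME, 150, "-")
        assert len(out) == 101
        assert out == str(Seq(self.GENOME[149:250]).reverse_complement())

    def test_truncation_warns(self):
        with pytest.warns(UserWarning, match="truncated"):
            out = extract_upstream(self.GENOME, 50, "+")
        assert out == self.GENOME[:50]

    def test_out_of_bounds_start_rejected(self):
        with pytest.raises(ValueError):
            extract_upstream(self.GENOME, 301, "+")

    def test_bad_strand_rejected(self):
        with pytest.raises(ValueError):
            extract_upstream(self.GENOME, 101, "*")


class TestCAI:
    # 3-gene toy reference: Ala codons GCT x3, GCC x1, GCA x1 (GCG unseen),
    # Lys codons AAA x3, AAG x1
    REF = ["GCTGCTAAA", "GCTGCAAAG", "GCCAAAAAA"]

    def test_weights_from_counts(self):
        w = reference_codon_weights(self.REF)
        assert w["GCT"] == 1.0
        assert w["GCA"] == pytest.approx(1 / 3)
        assert w["GCG"] == pytest.approx(0.5 / 3)  # pseudo-count for unseen
        assert w["AAA"] == 1.0
        assert w["AAG"] == pytest.approx(1 / 3)

    def test_optimal_gene_gives_one(self):
        w = reference_codon_weights(self.REF)
        assert compute_cai("GCTAAAGCT", w) == pytest.approx(1.0)

    def test_two_codon_geometric_mean(self):
        w = {"GCT": 1.0, "GCA": 0.25}
        assert compute_cai("GCTGCA", w) == pytest.approx(0.5)

    def test_hand_enumerated_product(self):
        w = reference_codon_weights(self.REF)
        # codons GCT, GCG, AAG, GCA -> (1 * 1/6 * 1/3 * 1/3)^(1/4)
        expected = (1.0 * (1 / 6) * (1 / 3) * (1 / 3)) ** 0.25
        assert compute_cai("GCTGCGAAGGCA", w) == pytest.approx(expected, rel=1e-12)

    def test_single_codon_families_excluded(self):
        w = reference_codon_weights(self.REF)
        # inserting Met/Trp codons (weight 1 by construction) changes nothing
        assert compute_cai("GCTGCAATGTGG", w) == pytest.approx(
            compute_cai("GCTGCA", w))

    def test_reference_scale_invariance(self):
        # scaling all counts preserves weights of observed codons (the fixed
        # pseudo-count for unseen codons shrinks relative to scaled counts)
        w1 = reference_codon_weights(self.REF)
        w2 = reference_codon_weights(self.REF * 5)
        for codon in ("GCT", "GCC", "GCA", "AAA", "AAG"):
            assert w1[codon] == pytest.approx(w2[codon], rel=1e-12)

    def test_bad_length_rejected(self):
        with pytest.raises(ValueError, match="divisible by 3"):
            compute_cai("GCTGC", {"GCT": 1.0})

    def test_matches_biopython_on_observed_codons(self):
        from Bio.SeqUtils import CodonAdaptationIndex
        ref = ["GCTGCTGCTGCAAAAAAG" * 3, "GCTGCAAAAAAAAAG" * 2]
        gene = "GCTGCAAAAAAG"
        ours = compute_cai(gene, reference_codon_weights(ref))
        theirs = CodonAdaptationIndex(ref).calculate(gene)
        assert ours == pytest.approx(theirs, rel=1e-12)


class TestTAI:
    def test_uniform_trnas_no_penalty_give_one(self):
        from Bio.Seq import Seq
        copies = {}
        for base in "ACGT":
            for b2 in "ACGT":
                for b3 in "ACGT":
                    copies[base + b2 + b3] = 1.0
        zero = {"WC": 0.0, "GU": 0.0, "IC": 0.0, "IA": 0.0, "UG": 0.0}
        assert compute_tai("GCTAAAGGT", copies, penalties=zero) == pytest.approx(1.0)

    def test_half_maximal_codon(self):
        # Ala-tRNA (AGC) x2 -> W(GCT)=2 is the max; Lys-tRNA (TTT) x1 -> W(AAA)=1
        copies = {"AGC": 2.0, "TTT": 1.0}
        w = tai_codon_weights(copies)
        assert w["AAA"] == pytest.approx(0.5)
        assert compute_tai("AAAAAA", copies) == pytest.approx(0.5)

    def test_unserved_codon_excluded_with_warning(self):
        # GGG is read by no tRNA in this toy table: excluded, not zeroing
        copies = {"AGC": 2.0, "TTT": 1.0}
        with pytest.warns(UserWarning, match="excluded"):
            assert compute_tai("AAAGGG", copies) == pytest.approx(0.5)

    def test_wobble_weight_hand_computed(self):
        # GCC read by WC GGC (x1) and inosine AGC (x2, s=0.28):
        # W = 1 + 0.72*2 = 2.44; max is GCT: 2 + 0.59*1 = 2.59
        w = tai_codon_weights({"AGC": 2.0, "GGC": 1.0})
        assert w["GCC"] == pytest.approx(2.44 / 2.59, rel=1e-12)

    def test_no_matching_trnas_rejected(self):
        with pytest.raises(ValueError):
            tai_codon_weights({})


class TestSimpleSequenceStats:
    @pytest.mark.parametrize("seq, expected", [
        ("GGCC", 1.0), ("ATAT", 0.0), ("ATGC", 0.5), ("ATGCNN", 0.5),
    ])
    def test_gc_content(self, seq, expected):
        assert gc_content(seq) == pytest.approx(expected)

    def test_gc_empty_rejected(self):
        with pytest.raises(ValueError):
            gc_content("")

    @pytest.mark.parametrize("seq, n", [
        ("AGGAGGAG", 2),          # overlapping occurrences both counted
        ("CCCCCCCC", 0),
        ("AGGAG", 1),
    ])
    def test_motif_count(self, seq, n):
        assert count_motif(seq) == n

    def test_planted_motifs_in_window(self):
        window = ("C" * 20 + "AGGAG") * 3 + "C" * 26  # 101 nt, 3 motifs
        assert len(window) == 101
        assert count_motif(window) == 3

    def test_rna_alphabet_accepted(self):
        assert count_motif("AGGAGGAG".replace("G", "G").replace("T", "U")) == 2


class TestCovarianceModel:
    def test_exact_linear_single_predictor(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=200)
        df = pd.DataFrame({"x": x, "ln_thalf": 3.0 * x + 1.0})
        fit = fit_covariance_model(df, quantitative=("x",), qualitative=())
        assert fit.terms == ["x"]
        assert fit.r_squared == pytest.approx(1.0, abs=1e-10)
        # z-scoring rescales the coefficient by the sample SD
        assert fit.params["x"] == pytest.approx(3.0 * x.std(ddof=1), rel=1e-8)

    def test_null_predictors_mostly_give_intercept_only(self):
        """AIC keeps a pure-noise term with P(chi2_1 > 2) ~ 0.16, so with two
        null candidates the intercept-only model wins ~71% of the time."""
        rng = np.random.default_rng(1)
        hits = 0
        reps = 40
        for _ in range(reps):
            df = pd.DataFrame({
                "ln_thalf": rng.normal(size=500),
                "x1": rng.normal(size=500),
                "x2": rng.normal(size=500),
            })
            fit = fit_covariance_model(df, quantitative=("x1", "x2"),
                                       qualitative=())
            hits += not fit.terms
        assert hits / reps >= 0.55

    def test_selected_aic_never_worse_than_full(self):
        df = simulate_feature_table(n_genes=200, seed=3)
        fit = fit_covariance_model(df)
        import statsmodels.formula.api as smf
        from mrnastab.determinants import _zscore, DEFAULT_QUANTITATIVE
        quants = [q for q in DEFAULT_QUANTITATIVE if q in df.columns]
        quals = [q for q in ("category", "mu_level", "motif_class")]
        z = _zscore(df.dropna(), quants)
        full = smf.ols(
            "ln_thalf ~ " + " + ".join(quants + [f"C({q})" for q in quals]),
            data=z).fit()
        assert fit.aic <= full.aic + 1e-9

    def test_standardization_invariance(self):
        df = simulate_feature_table(n_genes=150, seed=5)
        fit1 = fit_covariance_model(df)
        shifted = df.copy()
        shifted["length"] = shifted["length"] * 1000.0 + 5.0
        fit2 = fit_covariance_model(shifted)
        assert fit1.terms == fit2.terms
        assert fit1.r_squared == pytest.approx(fit2.r_squared, rel=1e-9)
        assert fit1.aic == pytest.approx(fit2.aic, abs=1e-6)

    def test_collinear_term_dropped_and_reported(self):
        df = simulate_feature_table(n_genes=100, seed=6)
        df["length_copy"] = df["length"]
        fit = fit_covariance_model(
            df, quantitative=("ln_mrna", "length", "length_copy"),
            qualitative=("mu_level",))
        assert "length_copy" in fit.dropped

    def test_recovers_generative_model(self):
        """At the default effect sizes the strong terms (concentration,
        length, growth rate) are selected and their estimates are unbiased:
        the mean over replicates sits within 3 SE of the replicate mean."""
        reps = 6
        ests = {"ln_mrna": [], "length": []}
        ses = {"ln_mrna": [], "length": []}
        for rep in range(reps):
            df = simulate_feature_table(seed=300 + rep)
            fit = fit_covariance_model(df)
            for term in ("ln_mrna", "length", "C(mu_level)"):
                assert term in fit.terms
            for name in ests:
                ests[name].append(fit.params[name])
                ses[name].append(fit.bse[name])
        for name, beta in (("ln_mrna", -0.065), ("length", -0.059)):
            se_mean = np.mean(ses[name]) / math.sqrt(reps)
            assert abs(np.mean(ests[name]) - beta) <= 3 * se_mean

    def test_pooled_r2_near_design_value(self):
        fit = fit_covariance_model(simulate_feature_table(seed=11))
        assert 0.55 <= fit.r_squared <= 0.70

    def test_growth_rate_dominates_within_condition_r2(self):
        df = simulate_feature_table(seed=11)
        pooled = fit_covariance_model(df).r_squared
        per_level = growth_rate_only_r2(df)
        assert max(per_level.values()) < 0.15
        assert pooled > 0.5
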