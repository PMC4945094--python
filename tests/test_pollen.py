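"""Pollen-typing: titration, read classification, filters and weighting."""

import numpy as np
import pandas as pd
import pytest

from xover.pollen import (AmpliconTemplate, ComplexMoleculeError, ReadEnd,
                          ReadPairRecord, aggregate_sanger, classify_pairs,
                          classify_read, estimate_concentration,
                          filter_crossover_pairs, fractional_interval_assignment,
                          poisson_concentration, pollen_cm,
                          sanger_crossover_interval)
from xover.simulate import SimConfig, revcomp, simulate_read_pairs, simulate_titration


class TestTemplate:
    def test_snp_table_derived_from_mismatches(self, small_template):
        assert list(small_template.snp_positions) == [60, 140, 230, 330]

    def test_rejects_unequal_lengths(self):
        with pytest.raises(ValueError, match="indel"):
            AmpliconTemplate.from_sequences("ACGTACGT", "ACGACGT")

    def test_rejects_too_few_snps(self):
        with pytest.raises(ValueError):
            AmpliconTemplate.from_sequences("AAAA" * 10, "AAAA" * 10)


class TestPoissonConcentration:
    def test_zero_positive(self):
        lam, (lo, hi) = poisson_concentration(0, 96, 2.0)
        assert lam == 0.0 and lo == 0.0

    def test_half_positive_closed_form(self):
        lam, _ = poisson_concentration(48, 96, 1.0)
        assert lam == pytest.approx(np.log(2))

    def test_all_positive_is_an_error(self):
        with pytest.raises(ValueError, match="dilute"):
            poisson_concentration(96, 96, 1.0)

    def test_ci_brackets_estimate(self):
        lam, (lo, hi) = poisson_concentration(30, 96, 0.5)
        assert lo < lam < hi

    def test_multi_dilution_mle_recovers_truth(self):
        tab = simulate_titration(1.5, [0.25, 0.5, 1.0], 96, seed=17)
        res = estimate_concentration(tab)
        assert res.concentration == pytest.approx(1.5, rel=0.2)
        assert res.ci[0] < res.concentration < res.ci[1]

    def test_single_dilution_mle_matches_closed_form(self):
        tab = pd.DataFrame({"input_volume": [1.0], "n_positive": [48], "n_total": [96]})
        res = estimate_concentration(tab)
        assert res.concentration == pytest.approx(np.log(2), rel=1e-6)


class TestPollenCm:
    def test_no_crossovers(self):
        assert pollen_cm(0.0, 3.5) == 0.0

    def test_symmetry_at_equal_concentrations(self):
        assert pollen_cm(2.2, 2.2) == pytest.approx(50.0)

    def test_both_zero_rejected(self):
        with pytest.raises(ValueError):
            pollen_cm(0.0, 0.0)


class TestClassifyRead:
    def test_col_read_spanning_snp(self, small_template):
        read = small_template.col_seq[50:100]  # covers SNP at 60
        end = classify_read(read, small_template)
        assert (end.haplotype, end.start, end.end, end.strand) == ("Col", 51, 100, "+")

    def test_strand_symmetry(self, small_template):
        """Reverse-complementing a read flips strand, never haplotype."""
        read = small_template.ler_seq[120:180]
        fwd = classify_read(read, small_template)
        rev = classify_read(revcomp(read), small_template)
        assert fwd.haplotype == rev.haplotype == "Ler"
        assert (fwd.start, fwd.end) == (rev.start, rev.end)
        assert {fwd.strand, rev.strand} == {"+", "-"}

    def test_inter_snp_read_is_ambiguous(self, small_template):
        read = small_template.col_seq[65:130]  # between SNPs 60 and 140
        assert classify_read(read, small_template).haplotype == "ambiguous"

    def test_error_makes_read_unmapped(self, small_template):
        read = list(small_template.col_seq[50:100])
        read[20] = {"A": "C", "C": "G", "G": "T", "T": "A"}[read[20]]
        assert classify_read("".join(read), small_template).haplotype == "unmapped"


def _pair(pid, hap1, s1, e1, st1, hap2, s2, e2, st2):
    return ReadPairRecord(pid, ReadEnd(hap1, s1, e1, st1), ReadEnd(hap2, s2, e2, st2))


class TestFilterCascade:
    def test_noiseless_library_fully_retained(self, amplicon):
        """Every classifiable crossover pair from a clean library survives."""
        snps = amplicon.snp_positions
        xo = np.array([int(snps[12]) + 4])
        pairs, _ = simulate_read_pairs(amplicon, xo, SimConfig(n_read_pairs=300), seed=1)
        records = classify_pairs(pairs, amplicon)
        classifiable = [r for r in records
                        if {r.end1.haplotype, r.end2.haplotype} == {"Col", "Ler"}]
        retained, attrition = filter_crossover_pairs(records)
        assert len(retained) == len(classifiable)
        assert attrition.loc[0, "pairs_surviving"] == len(records)

    def test_both_col_dropped_at_matched(self):
        rec = _pair("p", "Col", 10, 80, "+", "Col", 300, 370, "-")
        retained, _ = filter_crossover_pairs([rec])
        assert retained == [] and rec.status == "dropped_at:Matched"

    def test_orientation_polarity(self):
        rec = _pair("p", "Col", 10, 80, "+", "Ler", 300, 370, "-")
        retained, _ = filter_crossover_pairs([rec], orientation="ler-left")
        assert rec.status == "dropped_at:Orientate"
        rec2 = _pair("p", "Col", 10, 80, "+", "Ler", 300, 370, "-")
        retained2, _ = filter_crossover_pairs([rec2], orientation="col-left")
        assert retained2 == [rec2]

    def test_same_strand_dropped(self):
        rec = _pair("p", "Ler", 10, 80, "+", "Col", 300, 370, "+")
        filter_crossover_pairs([rec])
        assert rec.status == "dropped_at:Strand"

    def test_cascade_is_idempotent_and_conserving(self, amplicon):
        snps = amplicon.snp_positions
        rng = np.random.default_rng(5)
        xo = rng.integers(snps[8], snps[9], size=20)
        pairs, _ = simulate_read_pairs(
            amplicon, xo, SimConfig(n_read_pairs=500, per_base_error=0.005), seed=2)
        records = classify_pairs(pairs, amplicon)
        retained, attrition = filter_crossover_pairs(records)
        # conservation: drops at each stage + retained = total input
        drops = pd.Series([r.status for r in records]).value_counts()
        assert drops.get("retained", 0) == len(retained)
        assert drops.sum() == attrition.loc[0, "pairs_surviving"]
        # idempotence: re-running on retained records changes nothing
        retained2, attrition2 = filter_crossover_pairs(retained)
        assert retained2 == retained
        assert attrition2["pairs_surviving"].iloc[-1] == len(retained)


class TestFractionalAssignment:
    def test_worked_example_10_50_140(self):
        """A 200 bp gap split 10/50/140 by two internal SNPs gets raw weights
        0.05/0.25/0.70 (per-bp weight 1/200 = 0.005)."""
        rec = _pair("p", "Ler", 101, 300, "+", "Col", 501, 700, "-")
        snps = [50, 310, 360, 720]
        prof = fractional_interval_assignment([rec], snps, span_mode="inner-gap")
        np.testing.assert_allclose(prof.table["raw_weight"], [0.05, 0.25, 0.70])
        assert prof.n_pairs_used == 1

    def test_no_internal_snps_gives_unit_weight(self):
        rec = _pair("p", "Ler", 101, 300, "+", "Col", 501, 700, "-")
        prof = fractional_interval_assignment([rec], [250, 550], span_mode="inner-gap")
        assert prof.table["raw_weight"].iloc[0] == pytest.approx(1.0)

    def test_scale_invariance_of_normalized_weights(self):
        """Scaling a pair's gap and the SNP offsets by a constant leaves the
        normalized weights unchanged."""
        def profile(scale):
            rec = _pair("p", "Ler", 1, 100, "+",
                        "Col", 100 + 200 * scale + 1, 100 + 200 * scale + 100, "-")
            snps = [50, 100 + 10 * scale, 100 + 60 * scale, 100 + 200 * scale + 50]
            return fractional_interval_assignment([rec], snps, span_mode="inner-gap")
        w1 = profile(1).table["normalized_weight"].to_numpy()
        w3 = profile(3).table["normalized_weight"].to_numpy()
        np.testing.assert_allclose(w1, w3)

    def test_normalized_weights_sum_to_one(self, amplicon):
        snps = amplicon.snp_positions
        rng = np.random.default_rng(9)
        xo = rng.integers(snps[0], snps[-1], size=100)
        pairs, _ = simulate_read_pairs(amplicon, xo, SimConfig(n_read_pairs=3000), seed=3)
        retained, _ = filter_crossover_pairs(classify_pairs(pairs, amplicon))
        prof = fractional_interval_assignment(retained, snps)
        assert prof.table["normalized_weight"].sum() == pytest.approx(1.0, abs=1e-9)
        assert (prof.table["raw_weight"] >= 0).all()

    def test_overlapping_reads_dropped_at_gap(self):
        rec = _pair("p", "Ler", 101, 300, "+", "Col", 250, 449, "-")
        with pytest.raises(ValueError, match="gap"):
            fractional_interval_assignment([rec], [50, 500], span_mode="inner-gap")
        assert rec.status == "dropped_at:gap"


class TestSanger:
    def test_forced_example(self):
        assert sanger_crossover_interval("LLLCC", [10, 20, 30, 40, 50]) == (2, 3)

    def test_reverse_orientation(self):
        assert sanger_crossover_interval("CCLLL", [10, 20, 30, 40, 50]) == (1, 2)

    def test_complex_molecule_rejected(self):
        with pytest.raises(ComplexMoleculeError):
            sanger_crossover_interval("LCLCC", [10, 20, 30, 40, 50])

    def test_single_interval_carries_full_cm(self):
        molecules = ["LLCC"] * 30
        out = aggregate_sanger(molecules, [100, 200, 300, 400], amplicon_cm=0.16)
        # all crossovers in interval 1 (200-300): its cM/Mb implies the full cM
        cm = (out["cm_per_mb"] * out["width_bp"] / 1e6).sum()
        assert cm == pytest.approx(0.16)
        assert out["count"].iloc[1] == 30

    def test_complex_molecules_excluded_and_reported(self):
        molecules = ["LLCC"] * 10 + ["LCLC"] * 2 + ["LLLL"]
        out = aggregate_sanger(molecules, [100, 200, 300, 400], amplicon_cm=1.0)
        assert out.attrs["excluded"] == {"complex": 2, "non_recombinant": 1}
        assert out.attrs["n_molecules"] == 10
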