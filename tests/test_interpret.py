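"""Frequencies, third-allele screening, zygosity, parent-of-origin, cohorts."""

import math

import numpy as np
import pytest

from anchorphase.interpret import (
    assign_parent_of_origin,
    classify_zygosity,
    compute_error_metrics,
    compute_frequencies,
    detect_third_allele,
    phase_wes_only,
    summarize_cohort,
    PhasingResult,
    ThirdAllele,
)
from anchorphase.phasing import AlleleTable, ChosenISNP
from anchorphase.pipeline import phase_target
from anchorphase.simulate import simulate_target
from anchorphase.types import DNMRecord, ErrorMetrics, ErrorModel
from anchorphase.variants import ISNPCandidate, PileupColumn
from conftest import dnm_record


DNM = DNMRecord("sim1", 1000, "C", "T")


def chosen(pat="A", mat="G", linked_alt="A", agreement=0.98, pos=1500):
    """DNM alt travels with base `linked_alt`; attribution pat/mat."""
    linked_ref = mat if linked_alt == pat else pat
    return ChosenISNP(
        candidate=ISNPCandidate(
            position=pos, ref_base=pat, alt=mat, paternal_base=pat,
            maternal_base=mat, distance=pos - DNM.position,
        ),
        agreement=agreement, linked_alt_base=linked_alt,
        linked_ref_base=linked_ref, spanning=100,
    )


def table(counts):
    return AlleleTable(dnm_position=DNM.position, isnp_position=1500, counts=counts)


class TestFrequencies:
    def test_error_free_half_table(self):
        t = table({("T", "A"): 50, ("C", "G"): 50})
        f = compute_frequencies(t, DNM, chosen())
        assert f.raw_allele == f.polished_allele == 0.5

    def test_noise_pairs_removed_from_polished_denominator(self):
        t = table({("T", "A"): 40, ("C", "G"): 50, ("G", "A"): 6, ("T", "C"): 4})
        f = compute_frequencies(t, DNM, chosen())
        assert f.raw_allele == pytest.approx(0.40)
        assert f.polished_allele == pytest.approx(40 / 90)

    def test_credible_third_allele_enters_denominator(self):
        # postzygotic mixture: mutant 17, wild-type-of-mutant 33, other 50
        t = table({("T", "A"): 17, ("C", "A"): 33, ("C", "G"): 50})
        f = compute_frequencies(t, DNM, chosen(), third_credible=True)
        assert f.raw_allele == pytest.approx(0.17)
        assert f.polished_allele == pytest.approx(0.17)


class TestErrorMetrics:
    def test_error_free_table_has_zero_error(self):
        t = table({("T", "A"): 50, ("C", "G"): 50})
        m = compute_error_metrics(t, DNM, chosen())
        assert m.total_allele_error == m.max_false_allele == 0.0
        assert m.total_base_error == m.max_false_base == 0.0

    def test_isnp_column_base_error_arithmetic(self):
        col = PileupColumn(position=1500, counts={"A": 480, "G": 470, "T": 30, "C": 20})
        t = table({("T", "A"): 480, ("C", "G"): 470, ("T", "T"): 30, ("C", "C"): 20})
        m = compute_error_metrics(t, DNM, chosen(), isnp_column=col)
        assert m.max_false_base == pytest.approx(0.03)
        assert m.total_base_error == pytest.approx(0.05)

    def test_third_allele_pair_never_counted_as_false(self):
        t = table({("T", "A"): 17, ("C", "A"): 33, ("C", "G"): 50})
        m = compute_error_metrics(t, DNM, chosen())
        assert m.total_allele_error == 0.0

    def test_max_bounded_by_total_on_random_tables(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            pairs = [(a, b) for a in "ACGT*" for b in "ACGT*"]
            idx = rng.choice(len(pairs), size=rng.integers(2, 8), replace=False)
            counts = {pairs[i]: int(rng.integers(1, 100)) for i in idx}
            m = compute_error_metrics(table(counts), DNM, chosen())
            assert m.max_false_allele <= m.total_allele_error + 1e-12
            assert m.max_false_base <= m.total_base_error + 1e-12


class TestThirdAllele:
    def metrics(self, max_false=0.02):
        return ErrorMetrics(0.04, 0.02, max(0.04, 2 * max_false), max_false)

    def test_large_wt_of_mutant_pair_is_credible(self):
        t = table({("T", "A"): 17, ("C", "A"): 33, ("C", "G"): 50})
        third = detect_third_allele(t, DNM, chosen(), self.metrics())
        assert third.pair == ("C", "A")
        assert third.fraction == pytest.approx(0.33)
        assert third.credible

    def test_wrong_haplotype_pair_never_credible(self):
        # a large (alt, other-parent-base) pair is biologically irrelevant
        t = table({("T", "A"): 40, ("C", "G"): 30, ("T", "G"): 30})
        third = detect_third_allele(t, DNM, chosen(), self.metrics())
        assert third.fraction == 0.0
        assert not third.credible

    def test_below_floor_not_credible(self):
        t = table({("T", "A"): 48, ("C", "G"): 49, ("C", "A"): 3})
        third = detect_third_allele(t, DNM, chosen(), self.metrics(max_false=0.0))
        assert not third.credible

    def test_must_clear_k_times_max_false_allele(self):
        t = table({("T", "A"): 45, ("C", "G"): 45, ("C", "A"): 7, ("G", "G"): 3})
        third = detect_third_allele(t, DNM, chosen(), self.metrics(max_false=0.04))
        assert third.fraction == pytest.approx(0.07)
        assert not third.credible  # 0.07 < 2 x 0.04


def _third(frac=0.0, credible=False):
    return ThirdAllele(("C", "A"), frac, credible)


def _metrics(total_base=0.02, max_base=0.01):
    return ErrorMetrics(total_base, max_base, 0.02, 0.01)


class TestClassifyZygosity:
    def test_balanced_fraction_no_third_allele_is_prezygotic(self):
        z = classify_zygosity((70, 0.51), (1000, 0.49), 0.496, _third(), _metrics())
        assert z.zygosity == "prezygotic" and not z.ambiguous

    def test_credible_third_allele_is_postzygotic(self):
        z = classify_zygosity((70, 0.10), (1000, 0.17), 0.17, _third(0.33, True), _metrics())
        assert z.zygosity == "postzygotic"

    def test_fraction_deviation_with_base_corroboration_is_postzygotic(self):
        z = classify_zygosity((70, 0.12), (1000, 0.13), 0.12, _third(0.02), _metrics())
        assert z.zygosity == "postzygotic"

    def test_deviation_without_corroboration_is_prezygotic_with_bias_flag(self):
        # allele fraction dips but the DNM base frequency stays in band
        z = classify_zygosity((70, 0.47), (1000, 0.47), 0.38, _third(), _metrics())
        assert z.zygosity == "prezygotic"
        assert z.ambiguous
        assert "allelic_bias_suspected" in z.flags

    def test_shallow_wes_lowers_confidence_only(self):
        z = classify_zygosity((1, 1.0), (1000, 0.49), 0.50, _third(), _metrics())
        assert z.zygosity == "prezygotic"
        assert "low_wes_dnm_coverage" in z.flags


class TestParentOfOrigin:
    def test_linked_paternal_base_gives_paternal(self):
        assert assign_parent_of_origin(chosen(linked_alt="A")) == "paternal"

    def test_label_swap_flips_assignment(self):
        c = chosen(linked_alt="A")
        swapped = ChosenISNP(
            candidate=ISNPCandidate(
                position=c.position, ref_base=c.candidate.ref_base,
                alt=c.candidate.alt,
                paternal_base=c.maternal_base, maternal_base=c.paternal_base,
                distance=c.distance,
            ),
            agreement=c.agreement, linked_alt_base=c.linked_alt_base,
            linked_ref_base=c.linked_ref_base, spanning=c.spanning,
        )
        assert assign_parent_of_origin(c) == "paternal"
        assert assign_parent_of_origin(swapped) == "maternal"

    def test_low_agreement_undetermined(self):
        assert assign_parent_of_origin(chosen(agreement=0.7)) == "undetermined"


class TestPhaseWesOnly:
    def isnp(self):
        return ISNPCandidate(
            position=1500, ref_base="A", alt="G", paternal_base="A",
            maternal_base="G", distance=500,
        )

    def make_reads(self, n_mut, n_other, start=900):
        from conftest import make_read

        reads = []
        length = 700
        for i in range(n_mut):
            seq = ["A"] * length
            seq[DNM.position - start] = "T"
            seq[1500 - start] = "A"
            reads.append(make_read(start, "".join(seq), read_id=f"m{i}"))
        for i in range(n_other):
            seq = ["A"] * length
            seq[DNM.position - start] = "C"
            seq[1500 - start] = "G"
            reads.append(make_read(start, "".join(seq), read_id=f"o{i}"))
        return reads

    def test_concordant_coverage_is_acceptable(self):
        res = phase_wes_only(self.make_reads(12, 12), DNM, self.isnp())
        assert res.acceptable
        assert res.parent_of_origin == "paternal"

    def test_single_read_allele_unacceptable(self):
        res = phase_wes_only(self.make_reads(1, 40), DNM, self.isnp())
        assert not res.acceptable
        assert res.mutant_allele_reads == 1

    def test_agrees_with_long_read_pipeline_on_category_one_target(self):
        ds = simulate_target(
            seed=31, coverage=400, isnp_offsets=(1450,), dnm_offset=1500,
            error=ErrorModel(substitution_rate=0.01, indel_rate=0.0),
            with_wes_reads=True, wes_coverage=80,
        )
        dnm = dnm_record(ds)
        ont = phase_target("t", ds.reads, ds.region, dnm, wes=ds.wes)
        assert ont.category == 1
        isnp_pos = next(iter(ds.genotypes.paternal_hap))
        isnp = ISNPCandidate(
            position=isnp_pos, ref_base=ds.region.base(isnp_pos),
            alt=ds.genotypes.proband[isnp_pos][1],
            paternal_base=ds.genotypes.paternal_hap[isnp_pos],
            maternal_base=ds.genotypes.maternal_hap[isnp_pos],
            distance=isnp_pos - dnm.position,
        )
        wes_res = phase_wes_only(ds.wes_reads, dnm, isnp)
        assert wes_res.acceptable
        assert wes_res.parent_of_origin == ont.parent_of_origin == "paternal"


def result(parent="paternal", zygosity="prezygotic", polished=0.5, phased=True,
           noise=0.02, target_id="t"):
    return PhasingResult(
        target_id=target_id, category=2, phased=phased, parent_of_origin=parent,
        zygosity=zygosity, polished_allele_fraction=polished,
        metrics=ErrorMetrics(0.05, noise, 0.05, noise),
    )


class TestSummarizeCohort:
    def test_all_paternal_toy_cohort(self):
        s = summarize_cohort([result(target_id=f"t{i}") for i in range(4)])
        assert s.paternal_fraction == 1.0
        assert s.phased_fraction == 1.0

    def test_mean_and_sem_match_direct_formula(self):
        fracs = [0.5, 0.5, 0.48, 0.52]
        s = summarize_cohort([result(polished=f) for f in fracs])
        assert s.mean_prezygotic_fraction == pytest.approx(0.5)
        sd = np.std(fracs, ddof=1)
        assert s.sem_prezygotic_fraction == pytest.approx(sd / math.sqrt(4))

    def test_permutation_invariance(self):
        rs = [
            result(parent="paternal", polished=0.49),
            result(parent="maternal", polished=0.52),
            result(zygosity="postzygotic", polished=0.2),
            result(phased=False),
        ]
        a = summarize_cohort(rs)
        b = summarize_cohort(list(reversed(rs)))
        assert a == b

    def test_unphased_targets_counted_in_denominator(self):
        s = summarize_cohort([result(), result(phased=False)])
        assert s.phased_fraction == 0.5
        assert s.mean_background_noise == pytest.approx(0.02)
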