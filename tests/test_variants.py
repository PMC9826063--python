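"""Pileups, the filtered caller, WES polishing and iSNP discovery."""

import numpy as np
import pytest

import oracles
from anchorphase.trio import WesEvidence, WesSite
from anchorphase.types import DELETED, DNMRecord, PhasingError, RegionSpec
from anchorphase.variants import (
    Pileup,
    VariantCall,
    build_pileup,
    call_variants,
    classify_target,
    discover_ont_parental_isnps,
    discover_wes_isnps,
    het_confidence,
    wes_polish,
)
from conftest import dnm_record, make_read


def toy_region(length=40, start=101, base="A"):
    return RegionSpec("sim1", start, start + length - 1, base * length)


def fill_column(pileup, pos, counts, deletions=0):
    """Directly set one pileup column's counters (toy fixtures)."""
    i = pileup.region.offset(pos)
    for b, n in counts.items():
        pileup.base_counts[i, "ACGT".index(b)] = n
    pileup.deletion_counts[i] = deletions


class TestBuildPileup:
    def test_error_free_reads_over_ref(self):
        region = toy_region()
        reads = [make_read(101, "A" * 40, read_id=f"r{i}") for i in range(10)]
        col = build_pileup(reads, region).column(110)
        assert col.counts == {"A": 10, "C": 0, "G": 0, "T": 0}
        assert col.depth == 10

    def test_deletion_increments_deletion_count_only(self):
        region = toy_region()
        read = make_read(101, "A" * 10, cigar=[("M", 5), ("D", 2), ("M", 5)])
        pileup = build_pileup([read], region)
        col = pileup.column(106)
        assert col.deletions == 1
        assert sum(col.counts.values()) == 0
        assert col.depth == 1

    def test_simulated_het_site_within_binomial_noise(self, clean_dataset):
        ds = clean_dataset
        isnp = next(iter(ds.genotypes.paternal_hap))
        pileup = build_pileup(ds.reads, ds.region)
        col = pileup.column(isnp)
        pat = ds.genotypes.paternal_hap[isnp]
        n = len(ds.reads)
        sd = np.sqrt(n * 0.25)
        assert abs(col.counts[pat] - n / 2) < 4 * sd

    def test_counts_match_per_read_expansion_oracle(self):
        rng = np.random.default_rng(4)
        region = toy_region(60)
        reads = []
        for i in range(40):
            start = int(rng.integers(101, 140))
            cigar = []
            seqlen = 0
            for _ in range(int(rng.integers(1, 4))):
                op = str(rng.choice(["M", "M", "D", "I"]))
                n = int(rng.integers(1, 6))
                cigar.append((op, n))
                if op in "MI":
                    seqlen += n
            if cigar[0][0] != "M":
                cigar.insert(0, ("M", 2))
                seqlen += 2
            seq = "".join("ACGT"[j] for j in rng.integers(0, 4, size=seqlen))
            reads.append(make_read(start, seq, read_id=f"r{i}", cigar=cigar))
        pileup = build_pileup(reads, region)
        positions = range(region.start, region.end + 1)
        expected = oracles.pileup_counts(reads, positions)
        for pos in positions:
            col = pileup.column(pos)
            for b in "ACGT":
                assert col.counts[b] == expected[pos][b]
            assert col.deletions == expected[pos][DELETED]


class TestHetConfidence:
    def test_matches_enumeration_oracle_at_small_depth(self):
        cases = [(24, 25, 1), (10, 2, 0), (2, 10, 3), (20, 20, 10), (0, 30, 1)]
        for ref, alt, other in cases:
            assert het_confidence(ref, alt, other) == pytest.approx(
                oracles.het_posterior(ref, alt, other), abs=1e-9
            )

    def test_clean_het_is_confident(self):
        assert het_confidence(480, 500, 20) > 0.999


class TestCallVariants:
    def dnm(self):
        return DNMRecord("sim1", 105, "A", "G")

    def test_depth_at_most_twenty_filtered(self):
        region = toy_region()
        pileup = Pileup(region)
        fill_column(pileup, 105, {"A": 15, "G": 15})  # anchor must have depth
        fill_column(pileup, 120, {"A": 10, "C": 9})   # depth 19: out
        fill_column(pileup, 121, {"A": 10, "C": 10})  # depth 20: still out (>20 strict)
        fill_column(pileup, 122, {"A": 11, "C": 10})  # depth 21: in
        calls = call_variants(pileup, self.dnm())
        positions = {c.position for c in calls if c.genotype == "het"}
        assert 120 not in positions and 121 not in positions
        assert 122 in positions

    def test_allele_fraction_window_inclusive(self):
        region = toy_region()
        pileup = Pileup(region)
        fill_column(pileup, 105, {"A": 50, "G": 50})
        fill_column(pileup, 110, {"A": 90, "C": 10})   # 10%: out
        fill_column(pileup, 111, {"A": 80, "C": 20})   # 20%: in
        fill_column(pileup, 112, {"A": 20, "C": 80})   # 80%: in
        calls = call_variants(pileup, self.dnm())
        het_pos = {c.position for c in calls if c.genotype == "het"}
        assert 110 not in het_pos
        assert {111, 112} <= het_pos

    def test_noisy_column_fails_confidence(self):
        region = toy_region()
        pileup = Pileup(region)
        fill_column(pileup, 105, {"A": 50, "G": 50})
        # heavy third-base noise inflates the error estimate: not a clean het
        fill_column(pileup, 118, {"A": 40, "G": 20, "T": 40})
        calls = call_variants(pileup, self.dnm())
        at_118 = {c.alt for c in calls if c.position == 118 and c.genotype == "het"}
        assert "G" not in at_118  # the 20% allele drowns in the 40% third-base noise
        assert "T" in at_118      # while the balanced A/T pair is a clean het

    def test_dnm_position_admits_only_validated_alt(self):
        region = toy_region()
        pileup = Pileup(region)
        fill_column(pileup, 105, {"A": 50, "G": 40, "T": 30})
        calls = [c for c in call_variants(pileup, self.dnm()) if c.position == 105]
        assert [c.alt for c in calls] == ["G"]

    def test_dnm_site_exempt_from_af_window(self):
        # a 6% mosaic DNM is still admitted at its anchor position
        region = toy_region()
        pileup = Pileup(region)
        fill_column(pileup, 105, {"A": 940, "G": 60})
        calls = [c for c in call_variants(pileup, self.dnm()) if c.position == 105]
        assert len(calls) == 1
        assert calls[0].alt_fraction == pytest.approx(0.06)

    def test_missing_dnm_position_is_hard_error(self):
        region = toy_region()
        pileup = Pileup(region)
        fill_column(pileup, 120, {"A": 30, "C": 30})
        with pytest.raises(PhasingError, match="amplicon failed"):
            call_variants(pileup, self.dnm())

    def test_hom_alt_retained_separately(self):
        region = toy_region()
        pileup = Pileup(region)
        fill_column(pileup, 105, {"A": 50, "G": 50})
        fill_column(pileup, 130, {"C": 98, "A": 2})
        calls = [c for c in call_variants(pileup, self.dnm()) if c.position == 130]
        assert len(calls) == 1
        assert calls[0].genotype == "hom_alt"

    def test_raising_thresholds_never_adds_calls(self, noisy_dataset):
        ds = noisy_dataset
        pileup = build_pileup(ds.reads, ds.region)
        dnm = dnm_record(ds)
        base = {(c.position, c.alt) for c in call_variants(pileup, dnm)}
        stricter_depth = {
            (c.position, c.alt) for c in call_variants(pileup, dnm, min_depth=200)
        }
        stricter_conf = {
            (c.position, c.alt) for c in call_variants(pileup, dnm, min_conf=0.999)
        }
        assert stricter_depth <= base
        assert stricter_conf <= base

    def test_error_free_simulation_recovers_exactly_the_true_hets(self, clean_dataset):
        ds = clean_dataset
        pileup = build_pileup(ds.reads, ds.region)
        calls = call_variants(pileup, dnm_record(ds))
        het_pos = {c.position for c in calls if c.genotype == "het"}
        true_het = set(ds.genotypes.proband)
        assert het_pos == true_het


def _wes_with(pos, ref, genotypes, depths, background=60):
    wes = WesEvidence(coverage=[(1, 10_000, {"father": background, "mother": background, "proband": background})])
    if pos is not None:
        wes.add(WesSite(position=pos, ref=ref, genotypes=genotypes, depths=depths))
    return wes


class TestWesPolish:
    def cand(self, pos=200, ref="A", alt="C"):
        return VariantCall(
            position=pos, ref_base=ref, alt=alt, alt_fraction=0.5,
            depth=100, confidence=0.99, genotype="het",
        )

    def test_hom_ref_wes_removes_ont_het(self):
        wes = _wes_with(200, "A", {"proband": ("A", "A")}, {"proband": 60})
        assert wes_polish([self.cand()], wes) == []

    def test_implied_hom_ref_coverage_removes_false_het(self):
        wes = _wes_with(None, "A", {}, {})
        assert wes_polish([self.cand()], wes) == []

    def test_matching_wes_het_kept_and_marked(self):
        wes = _wes_with(200, "A", {"proband": ("A", "C")}, {"proband": 60})
        (kept,) = wes_polish([self.cand()], wes)
        assert kept.wes_match is True

    def test_uncovered_position_passes_through_unvalidated(self):
        wes = WesEvidence()  # no footprint at all
        (kept,) = wes_polish([self.cand()], wes)
        assert kept.wes_match is None

    def test_shallow_wes_is_uninformative_not_contradictory(self):
        wes = _wes_with(200, "A", {"proband": ("A", "A")}, {"proband": 5}, background=0)
        (kept,) = wes_polish([self.cand()], wes)
        assert kept.wes_match is None


class TestDiscoverWesIsnps:
    def site(self, pos, ref, f, m, p, df=30, dm=30, dp=30):
        return WesSite(
            position=pos, ref=ref,
            genotypes={"father": f, "mother": m, "proband": p},
            depths={"father": df, "mother": dm, "proband": dp},
        )

    def dnm(self):
        return DNMRecord("sim1", 1000, "C", "T")

    def test_opposite_homozygotes_yield_candidate(self):
        wes = WesEvidence()
        wes.add(self.site(1400, "A", ("A", "A"), ("G", "G"), ("A", "G")))
        (cand,) = discover_wes_isnps(wes, self.dnm())
        assert (cand.paternal_base, cand.maternal_base) == ("A", "G")
        assert cand.distance == 400

    def test_parent_below_five_x_excluded(self):
        wes = WesEvidence()
        wes.add(self.site(1400, "A", ("A", "A"), ("G", "G"), ("A", "G"), dm=4))
        assert discover_wes_isnps(wes, self.dnm()) == []

    def test_parent_at_exactly_five_x_included(self):
        wes = WesEvidence()
        wes.add(self.site(1400, "A", ("A", "A"), ("G", "G"), ("A", "G"), dm=5))
        assert len(discover_wes_isnps(wes, self.dnm())) == 1

    def test_both_parents_het_not_attributable(self):
        wes = WesEvidence()
        wes.add(self.site(1400, "A", ("A", "G"), ("A", "G"), ("A", "G")))
        assert discover_wes_isnps(wes, self.dnm()) == []

    def test_sites_beyond_window_ignored(self):
        wes = WesEvidence()
        wes.add(self.site(15_000, "A", ("A", "A"), ("G", "G"), ("A", "G")))
        assert discover_wes_isnps(wes, self.dnm(), window_bp=10_000) == []


class TestClassifyTarget:
    def dnm(self):
        return DNMRecord("sim1", 50_000, "C", "T")

    def isnp_at(self, distance):
        from anchorphase.variants import ISNPCandidate

        return ISNPCandidate(
            position=50_000 + distance, ref_base="A", alt="G",
            paternal_base="A", maternal_base="G", distance=distance,
        )

    def test_nearby_isnp_is_category_one(self):
        assert classify_target(self.dnm(), [self.isnp_at(150)]) == 1

    def test_kilobase_isnp_is_category_two(self):
        assert classify_target(self.dnm(), [self.isnp_at(6000)]) == 2

    def test_no_isnp_within_window_is_category_three(self):
        assert classify_target(self.dnm(), []) == 3


class TestParentalOntTyping:
    def _pileups(self, father_counts, mother_counts, pos=300, depth_scale=1):
        region = toy_region(400, start=101)
        out = []
        for counts in (father_counts, mother_counts):
            p = Pileup(region)
            fill_column(p, pos, counts)
            out.append(p)
        return out

    def cand(self, pos=300):
        return VariantCall(
            position=pos, ref_base="A", alt="G", alt_fraction=0.5,
            depth=200, confidence=0.99, genotype="het",
        )

    def dnm(self):
        return DNMRecord("sim1", 200, "C", "T")

    def test_opposite_parental_homozygotes_typed_tertiary(self):
        father, mother = self._pileups({"A": 98, "G": 2}, {"G": 97, "A": 3})
        (cand,) = discover_ont_parental_isnps(father, mother, [self.cand()], self.dnm())
        assert cand.support_category == "tertiary"
        assert (cand.paternal_base, cand.maternal_base) == ("A", "G")

    def test_both_parents_het_excluded(self):
        father, mother = self._pileups({"A": 50, "G": 48}, {"A": 49, "G": 51})
        assert discover_ont_parental_isnps(father, mother, [self.cand()], self.dnm()) == []

    def test_parent_depth_below_twenty_excluded(self):
        father, mother = self._pileups({"A": 15}, {"G": 97, "A": 3})
        assert discover_ont_parental_isnps(father, mother, [self.cand()], self.dnm()) == []

    def test_parent_depth_exactly_twenty_included(self):
        father, mother = self._pileups({"A": 20}, {"G": 97, "A": 3})
        assert len(discover_ont_parental_isnps(father, mother, [self.cand()], self.dnm())) == 1
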