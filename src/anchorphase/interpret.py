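"""Zygosity, parent-of-origin, error metrics and cohort summaries.

Given an allele table anchored on the validated DNM and the chosen iSNP,
the two credible haplotype pairs are (alt, linked-iSNP base) — the mutant
haplotype — and (ref, other-iSNP base) — the other parent's haplotype. A
"third allelic form", (ref, linked-iSNP base), is the wild-type version of
the mutant haplotype: its presence above noise is the signature of a
postzygotic (mosaic) event. Any other pair is sequencing error by
definition and is summed into the error metrics; removing those false
pairs from the denominator yields the polished mutant allele frequency.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .io_qc import AlignedRead
from .phasing import AlleleTable, ChosenISNP, split_reads_by_dnm
from .types import DELETED, DNMRecord, MATERNAL, PATERNAL, ErrorMetrics
from .variants import ISNPCandidate, PileupColumn

logger = logging.getLogger(__name__)

UNDETERMINED = "undetermined"
PREZYGOTIC = "prezygotic"
POSTZYGOTIC = "postzygotic"


def _true_pairs(dnm: DNMRecord, chosen: ChosenISNP):
    mutant = (dnm.alt_base, chosen.linked_alt_base)
    other = (dnm.ref_base, chosen.linked_ref_base)
    third = (dnm.ref_base, chosen.linked_alt_base)
    return mutant, other, third


def compute_error_metrics(
    table: AlleleTable,
    dnm: DNMRecord,
    chosen: ChosenISNP,
    isnp_column: Optional[PileupColumn] = None,
) -> ErrorMetrics:
    """Total and maximum known-false base and allele-pair fractions.

    Allele pairs outside {mutant, other-parent, candidate third allele} are
    known false. Base error is measured at the iSNP position — from the full
    pileup column when available, else from the allele-table margin — as the
    combined fraction of bases other than the two iSNP alleles; its maximum
    single component feeds the cohort background-noise report.
    """
    mutant, other, third = _true_pairs(dnm, chosen)
    credible = {mutant, other, third}
    false_fracs = [f for pair, f in table.fractions().items() if pair not in credible]
    total_allele = min(sum(false_fracs), 1.0)
    max_allele = max(false_fracs, default=0.0)

    true_bases = {chosen.linked_alt_base, chosen.linked_ref_base}
    if isnp_column is not None:
        base_fracs = [
            isnp_column.fraction(b)
            for b in list("ACGT") + [DELETED]
            if b not in true_bases
        ]
    else:
        margin: Dict[str, float] = {}
        for (b1, b2), f in table.fractions().items():
            margin[b2] = margin.get(b2, 0.0) + f
        base_fracs = [f for b, f in margin.items() if b not in true_bases]
    total_base = min(sum(base_fracs), 1.0)
    max_base = max(base_fracs, default=0.0)
    return ErrorMetrics(
        total_base_error=total_base,
        max_false_base=max_base,
        total_allele_error=total_allele,
        max_false_allele=max_allele,
    )


@dataclass(frozen=True)
class ThirdAllele:
    """The candidate wild-type-of-mutant-haplotype allele pair."""

    pair: Tuple[str, str]
    fraction: float
    credible: bool


def detect_third_allele(
    table: AlleleTable,
    dnm: DNMRecord,
    chosen: ChosenISNP,
    metrics: ErrorMetrics,
    floor: float = 0.05,
    k: float = 2.0,
) -> ThirdAllele:
    """Screen for a credible third allelic form.

    Only (DNM ref, iSNP base of the mutant haplotype) is biologically
    relevant — the wild type the mutant haplotype would carry had the DNM
    not occurred. It is credible iff its fraction exceeds
    ``max(floor, k * max_false_allele)``; any other extra pair can never be
    credible regardless of its size.
    """
    _, _, third = _true_pairs(dnm, chosen)
    frac = table.fraction(third)
    credible = frac > max(floor, k * metrics.max_false_allele)
    return ThirdAllele(pair=third, fraction=frac, credible=credible)


@dataclass(frozen=True)
class Frequencies:
    """Raw and error-polished mutant allele fractions from one table."""

    raw_allele: float
    polished_allele: float


def compute_frequencies(
    table: AlleleTable,
    dnm: DNMRecord,
    chosen: ChosenISNP,
    third_credible: bool = False,
) -> Frequencies:
    """Mutant allele fraction before and after false-allele removal.

    Raw: mutant-pair count over all spanning reads. Polished: mutant-pair
    count over credible pairs only — the mutant pair, the other-parent pair,
    and the third allelic form when credible.
    """
    mutant, other, third = _true_pairs(dnm, chosen)
    total = table.total
    raw = table.count(mutant) / total if total else 0.0
    denom = table.count(mutant) + table.count(other)
    if third_credible:
        denom += table.count(third)
    polished = table.count(mutant) / denom if denom else 0.0
    return Frequencies(raw_allele=raw, polished_allele=polished)


@dataclass(frozen=True)
class ZygosityCall:
    zygosity: str
    ambiguous: bool = False
    flags: Tuple[str, ...] = ()


def classify_zygosity(
    wes_dnm_info: Optional[Tuple[int, float]],
    ont_dnm_info: Tuple[int, float],
    polished_allele_fraction: float,
    third: ThirdAllele,
    metrics: ErrorMetrics,
    band: Tuple[float, float] = (0.40, 0.60),
) -> ZygosityCall:
    """Three-way evidence assessment of DNM timing.

    Postzygotic iff a credible third allelic form exists, or the polished
    mutant allele fraction falls outside the prezygotic band and the DNM
    base fraction in the long reads corroborates the deviation beyond the
    measured base noise. A deviation without corroboration is adjudicated
    prezygotic with an allelic-bias flag (ambiguous). Missing or shallow WES
    DNM coverage lowers confidence but classification proceeds on the
    long-read evidence alone.
    """
    lo, hi = band
    flags: List[str] = []
    if wes_dnm_info is None or wes_dnm_info[0] < 10:
        flags.append("low_wes_dnm_coverage")

    if third.credible:
        return ZygosityCall(POSTZYGOTIC, flags=tuple(flags))
    if lo <= polished_allele_fraction <= hi:
        return ZygosityCall(PREZYGOTIC, flags=tuple(flags))

    # allele fraction deviates with no third allelic form: ask the base level
    _, ont_frac = ont_dnm_info
    if ont_frac < lo:
        deviation = lo - ont_frac
    elif ont_frac > hi:
        deviation = ont_frac - hi
    else:
        deviation = 0.0
    noise = max(metrics.total_base_error, 1e-6)
    if deviation > noise:
        flags.append("no_third_allele")
        return ZygosityCall(POSTZYGOTIC, flags=tuple(flags))
    flags.append("allelic_bias_suspected")
    return ZygosityCall(PREZYGOTIC, ambiguous=True, flags=tuple(flags))


def assign_parent_of_origin(chosen: ChosenISNP, min_agreement: float = 0.90) -> str:
    """The parent whose iSNP base co-occurs with the DNM alternate allele.

    Undetermined when the linked base matches neither parental attribution
    or the mutant-haplotype purity (the majority fraction within the
    DNM-alternate read group, which alone carries the parent information)
    is below threshold.
    """
    purity = chosen.alt_agreement if chosen.alt_agreement is not None else chosen.agreement
    if purity < min_agreement:
        logger.info(
            "mutant-group purity %.3f below %.2f at iSNP %d: parent undetermined",
            purity, min_agreement, chosen.position,
        )
        return UNDETERMINED
    if chosen.linked_alt_base == chosen.paternal_base:
        return PATERNAL
    if chosen.linked_alt_base == chosen.maternal_base:
        return MATERNAL
    return UNDETERMINED


@dataclass
class PhasingResult:
    """Complete per-target outcome of anchored phasing."""

    target_id: str
    category: int
    phased: bool
    parent_of_origin: str = UNDETERMINED
    zygosity: str = UNDETERMINED
    ambiguous: bool = False
    raw_base_fraction: Optional[float] = None
    raw_allele_fraction: Optional[float] = None
    polished_allele_fraction: Optional[float] = None
    third_allele_fraction: Optional[float] = None
    third_allele_credible: bool = False
    metrics: Optional[ErrorMetrics] = None
    chosen_isnp_position: Optional[int] = None
    chosen_isnp_category: Optional[str] = None
    chosen_isnp_agreement: Optional[float] = None
    spanning_reads: int = 0
    flags: Tuple[str, ...] = ()
    unphased_reason: Optional[str] = None

    def to_dict(self) -> dict:
        out = {
            "target_id": self.target_id,
            "category": self.category,
            "phased": self.phased,
            "parent_of_origin": self.parent_of_origin,
            "zygosity": self.zygosity,
            "ambiguous": self.ambiguous,
            "raw_base_fraction": self.raw_base_fraction,
            "raw_allele_fraction": self.raw_allele_fraction,
            "polished_allele_fraction": self.polished_allele_fraction,
            "third_allele_fraction": self.third_allele_fraction,
            "third_allele_credible": self.third_allele_credible,
            "chosen_isnp_position": self.chosen_isnp_position,
            "chosen_isnp_category": self.chosen_isnp_category,
            "chosen_isnp_agreement": self.chosen_isnp_agreement,
            "spanning_reads": self.spanning_reads,
            "flags": list(self.flags),
            "unphased_reason": self.unphased_reason,
        }
        if self.metrics is not None:
            out["error_metrics"] = self.metrics.to_dict()
        return out


@dataclass
class WesPhasingResult:
    """Short-read-only phasing control for category-1 targets."""

    parent_of_origin: str
    acceptable: bool
    raw_allele_fraction: float
    mutant_allele_reads: int
    other_allele_reads: int
    table: AlleleTable


def phase_wes_only(
    wes_reads: Iterable[AlignedRead],
    dnm: DNMRecord,
    isnp: ISNPCandidate,
    min_allele_reads: int = 10,
) -> WesPhasingResult:
    """Phase with short reads alone using the same allele-table logic.

    The result is marked acceptable only when each of the two haplotype
    alleles has more than ``min_allele_reads`` supporting reads; a 1x-covered
    allele yields an unacceptable (but still reported) control.
    """
    groups = split_reads_by_dnm(wes_reads, dnm)
    counts: Dict[Tuple[str, str], int] = {}
    for read in groups.group_ref + groups.group_alt + groups.group_other:
        b1 = read.base_at(dnm.position)
        b2 = read.base_at(isnp.position)
        if b1 is None or b2 is None:
            continue
        counts[(b1, b2)] = counts.get((b1, b2), 0) + 1
    table = AlleleTable(dnm.position, isnp.position, counts)

    # the iSNP base travelling with the DNM alternate allele
    alt_pairs = {p: c for p, c in counts.items() if p[0] == dnm.alt_base and p[1] in isnp.bases}
    if not alt_pairs:
        return WesPhasingResult(UNDETERMINED, False, 0.0, 0, 0, table)
    linked = max(alt_pairs, key=lambda p: (alt_pairs[p], p))[1]
    other = isnp.paternal_base if linked == isnp.maternal_base else isnp.maternal_base
    mutant_n = counts.get((dnm.alt_base, linked), 0)
    other_n = counts.get((dnm.ref_base, other), 0)
    acceptable = mutant_n > min_allele_reads and other_n > min_allele_reads
    parent = (
        PATERNAL if linked == isnp.paternal_base
        else MATERNAL if linked == isnp.maternal_base
        else UNDETERMINED
    )
    raw = mutant_n / table.total if table.total else 0.0
    return WesPhasingResult(parent, acceptable, raw, mutant_n, other_n, table)


def _mean_sem(values: Sequence[float]) -> Tuple[Optional[float], Optional[float]]:
    if not values:
        return None, None
    arr = np.asarray(values, dtype=float)
    mean = float(arr.mean())
    sem = float(arr.std(ddof=1) / math.sqrt(len(arr))) if len(arr) > 1 else 0.0
    return mean, sem


@dataclass
class CohortSummary:
    """Aggregate statistics over a cohort of phasing results."""

    n_targets: int
    n_phased: int
    phased_fraction: float
    paternal_fraction: Optional[float]
    n_prezygotic: int
    n_postzygotic: int
    paternal_fraction_prezygotic: Optional[float]
    paternal_fraction_postzygotic: Optional[float]
    mean_prezygotic_fraction: Optional[float]
    sem_prezygotic_fraction: Optional[float]
    mean_postzygotic_fraction: Optional[float]
    sem_postzygotic_fraction: Optional[float]
    mean_background_noise: Optional[float]

    def to_dict(self) -> dict:
        return dict(self.__dict__)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.to_dict()])


def summarize_cohort(results: Sequence[PhasingResult]) -> CohortSummary:
    """Phased fraction, parent-of-origin proportions (overall and within
    zygosity strata), mean +/- SEM of polished allele fractions, and mean
    background noise (cohort mean of each target's largest false iSNP-base
    fraction). SEM is sd/sqrt(n)."""
    if not results:
        raise ValueError("at least one result required")
    phased = [r for r in results if r.phased and r.parent_of_origin != UNDETERMINED]
    pre = [r for r in phased if r.zygosity == PREZYGOTIC]
    post = [r for r in phased if r.zygosity == POSTZYGOTIC]

    def pat_frac(rs: Sequence[PhasingResult]) -> Optional[float]:
        if not rs:
            return None
        return sum(1 for r in rs if r.parent_of_origin == PATERNAL) / len(rs)

    pre_mean, pre_sem = _mean_sem(
        [r.polished_allele_fraction for r in pre if r.polished_allele_fraction is not None]
    )
    post_mean, post_sem = _mean_sem(
        [r.polished_allele_fraction for r in post if r.polished_allele_fraction is not None]
    )
    noises = [r.metrics.max_false_base for r in phased if r.metrics is not None]
    return CohortSummary(
        n_targets=len(results),
        n_phased=len(phased),
        phased_fraction=len(phased) / len(results),
        paternal_fraction=pat_frac(phased),
        n_prezygotic=len(pre),
        n_postzygotic=len(post),
        paternal_fraction_prezygotic=pat_frac(pre),
        paternal_fraction_postzygotic=pat_frac(post),
        mean_prezygotic_fraction=pre_mean,
        sem_prezygotic_fraction=pre_sem,
        mean_postzygotic_fraction=post_mean,
        sem_postzygotic_fraction=post_sem,
        mean_background_noise=float(np.mean(noises)) if noises else None,
    )
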