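"""Anchored phasing: the validated DNM allele as the fixed truth.

Reads are split by their base at the DNM position; a genuine heterozygous
variant on the same amplicon must then look effectively homozygous within
each split (one base dominating the DNM-alternate group, the other base the
reference group), because an amplicon carries no recombinants. Candidates
failing this within-group homogeneity test are sequencing noise and are
flagged discordant — this is the extra filtering the anchor buys on top of
depth/fraction/confidence thresholds.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

from .io_qc import AlignedRead
from .types import DNMRecord, PhasingError
from .variants import ISNPCandidate, VariantCall

logger = logging.getLogger(__name__)

CATEGORY_RANK = {"primary": 0, "secondary": 1, "tertiary": 2, "unvalidated": 3}


@dataclass
class SplitReadGroups:
    """Reads partitioned by their base at the DNM position."""

    dnm: DNMRecord
    group_ref: List[AlignedRead] = field(default_factory=list)
    group_alt: List[AlignedRead] = field(default_factory=list)
    group_other: List[AlignedRead] = field(default_factory=list)

    @property
    def n_covering(self) -> int:
        return len(self.group_ref) + len(self.group_alt) + len(self.group_other)

    def raw_base_fraction(self) -> float:
        """Alternate-base count over all DNM-covering reads."""
        return len(self.group_alt) / self.n_covering


def split_reads_by_dnm(reads: Iterable[AlignedRead], dnm: DNMRecord) -> SplitReadGroups:
    """Partition reads by the base they carry at the DNM position.

    Reads with any base other than the validated ref/alt, or with a deletion
    spanning the position, go to ``group_other``; reads not covering the
    position are excluded. Raises if no read covers the DNM.
    """
    groups = SplitReadGroups(dnm=dnm)
    for read in reads:
        base = read.base_at(dnm.position)
        if base is None:
            continue
        if base == dnm.alt_base:
            groups.group_alt.append(read)
        elif base == dnm.ref_base:
            groups.group_ref.append(read)
        else:
            groups.group_other.append(read)
    if groups.n_covering == 0:
        raise PhasingError(f"no reads cover the DNM at {dnm.position}")
    logger.info(
        "split at %d: ref=%d alt=%d other=%d",
        dnm.position, len(groups.group_ref), len(groups.group_alt), len(groups.group_other),
    )
    return groups


@dataclass
class LinkageInfo:
    """Within-group homogeneity of one candidate across the DNM split."""

    agreement: float                # mean of the two majority fractions
    alt_agreement: float            # majority fraction among DNM-alt reads
    ref_agreement: float            # majority fraction among DNM-ref reads
    linked_alt_base: Optional[str]  # majority base among DNM-alt reads
    linked_ref_base: Optional[str]  # majority base among DNM-ref reads
    alt_spanning: int
    ref_spanning: int
    discordant: bool
    insufficient: bool

    @property
    def spanning(self) -> int:
        return self.alt_spanning + self.ref_spanning


def _group_majority(reads: Sequence[AlignedRead], pos: int) -> Tuple[Optional[str], float, int]:
    observed = [b for b in (r.base_at(pos) for r in reads) if b is not None]
    if not observed:
        return None, 0.0, 0
    counts = Counter(observed)
    base, n = max(counts.items(), key=lambda kv: (kv[1], kv[0]))
    return base, n / len(observed), len(observed)


def find_linked_variants(
    groups: SplitReadGroups,
    candidates: Sequence[VariantCall],
    min_group_agreement: float = 0.90,
    min_group_spanning: int = 10,
) -> List[Tuple[VariantCall, LinkageInfo]]:
    """Score each candidate's agreement with the DNM read split.

    Every read carrying the DNM alternate base comes from one physical
    haplotype, so a genuine linked variant is effectively homozygous within
    ``group_alt`` (majority fraction >= ``min_group_agreement``). The
    DNM-reference group is only required to have a *different* majority
    base: for a postzygotic mosaic it legitimately mixes the wild-type
    copies of the mutant haplotype with the other parent's reads, so
    demanding homozygosity there would discard every mosaic target.
    Sequencing-noise candidates show the same majority base in both groups
    and are flagged discordant. The reported agreement score is the mean of
    the two majority fractions; candidates covered by fewer than
    ``min_group_spanning`` reads in either group are flagged insufficient.
    ``group_other`` reads are excluded throughout.
    """
    out: List[Tuple[VariantCall, LinkageInfo]] = []
    for cand in candidates:
        alt_base, alt_frac, alt_n = _group_majority(groups.group_alt, cand.position)
        ref_base, ref_frac, ref_n = _group_majority(groups.group_ref, cand.position)
        insufficient = alt_n < min_group_spanning or ref_n < min_group_spanning
        discordant = (
            alt_base is None
            or ref_base is None
            or alt_base == ref_base
            or alt_frac < min_group_agreement
        )
        info = LinkageInfo(
            agreement=(alt_frac + ref_frac) / 2.0,
            alt_agreement=alt_frac,
            ref_agreement=ref_frac,
            linked_alt_base=alt_base,
            linked_ref_base=ref_base,
            alt_spanning=alt_n,
            ref_spanning=ref_n,
            discordant=discordant,
            insufficient=insufficient,
        )
        out.append((cand, info))
    return out


def assign_support_category(
    candidate: ISNPCandidate,
    wes=None,
    parental_ont_positions: Optional[Set[int]] = None,
    wes_min_depth: int = 10,
    min_parent_depth: int = 5,
) -> str:
    """Tier of orthogonal validation for an iSNP candidate.

    primary: proband WES het matches and both parents are WES-typed;
    secondary: proband WES het matches only; tertiary: parental long-read
    typing only; unvalidated: no orthogonal support.
    """
    from .trio import attribute_alleles

    parental_ont_positions = parental_ont_positions or set()
    proband_wes = False
    parental_wes = False
    if wes is not None:
        site = wes.site(candidate.position)
        if site is not None and site.depth("proband") >= wes_min_depth:
            gt = site.genotypes.get("proband")
            if gt is not None and gt[0] != gt[1] and candidate.alt in gt:
                proband_wes = True
        if site is not None and proband_wes:
            father = site.genotypes.get("father")
            mother = site.genotypes.get("mother")
            if (
                father is not None
                and mother is not None
                and site.depth("father") >= min_parent_depth
                and site.depth("mother") >= min_parent_depth
                and attribute_alleles(site.genotypes["proband"], father, mother) is not None
            ):
                parental_wes = True
    if proband_wes and parental_wes:
        return "primary"
    if proband_wes:
        return "secondary"
    if candidate.position in parental_ont_positions:
        return "tertiary"
    return "unvalidated"


def drop_unsupported_indels(
    candidates: Sequence[VariantCall],
    supported_positions: Optional[Set[int]] = None,
) -> List[VariantCall]:
    """Remove indel candidates with no orthogonal support.

    Long-read indel calls are overwhelmingly false, so an indel is kept only
    if WES agrees (``wes_match``) or parental long-read typing supports the
    position; SNVs are never dropped by this rule.
    """
    supported_positions = supported_positions or set()
    kept = [
        c
        for c in candidates
        if not c.is_indel or c.wes_match is True or c.position in supported_positions
    ]
    n_dropped = len(candidates) - len(kept)
    if n_dropped:
        logger.info("dropped %d unsupported indel candidates", n_dropped)
    return kept


@dataclass
class ChosenISNP:
    """The selected iSNP with its split-read agreement and score parts."""

    candidate: ISNPCandidate
    agreement: float
    linked_alt_base: str
    linked_ref_base: str
    spanning: int
    alt_agreement: Optional[float] = None  # mutant-haplotype purity

    @property
    def position(self) -> int:
        return self.candidate.position

    @property
    def paternal_base(self) -> str:
        return self.candidate.paternal_base

    @property
    def maternal_base(self) -> str:
        return self.candidate.maternal_base

    @property
    def support_category(self) -> str:
        return self.candidate.support_category

    @property
    def distance(self) -> int:
        return self.candidate.distance

    def score_tuple(self) -> tuple:
        return (
            CATEGORY_RANK[self.support_category],
            -self.agreement,
            -self.spanning,
            abs(self.distance),
            self.position,
        )


def select_isnp(candidates: Sequence[ISNPCandidate]) -> Optional[ChosenISNP]:
    """Pick the best iSNP by support category, then split-read agreement,
    then spanning coverage, then proximity to the DNM, then leftmost
    position. Returns None (unphaseable) when no usable candidate remains.
    """
    usable = [
        c
        for c in candidates
        if not c.discordant
        and not c.insufficient
        and c.agreement is not None
        and c.linked_alt_base is not None
        and c.linked_ref_base is not None
        and c.paternal_base != c.maternal_base
    ]
    if not usable:
        return None
    chosen = [
        ChosenISNP(
            candidate=c,
            agreement=c.agreement,
            linked_alt_base=c.linked_alt_base,
            linked_ref_base=c.linked_ref_base,
            spanning=c.spanning,
            alt_agreement=c.alt_agreement,
        )
        for c in usable
    ]
    return min(chosen, key=ChosenISNP.score_tuple)


@dataclass
class AlleleTable:
    """Read counts per ordered (DNM-position base, iSNP-position base) pair
    over reads covering both positions; deletions tally under ``'*'``."""

    dnm_position: int
    isnp_position: int
    counts: Dict[Tuple[str, str], int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def count(self, pair: Tuple[str, str]) -> int:
        return self.counts.get(pair, 0)

    def fraction(self, pair: Tuple[str, str]) -> float:
        t = self.total
        return self.counts.get(pair, 0) / t if t else 0.0

    def fractions(self) -> Dict[Tuple[str, str], float]:
        t = self.total
        return {k: v / t for k, v in self.counts.items()} if t else {}

    def to_rows(self) -> List[dict]:
        t = self.total
        return [
            {
                "dnm_base": k[0],
                "isnp_base": k[1],
                "count": v,
                "fraction": v / t if t else 0.0,
            }
            for k, v in sorted(self.counts.items())
        ]


def build_allele_table(
    reads: Iterable[AlignedRead], dnm: DNMRecord, chosen: ChosenISNP
) -> AlleleTable:
    """Cross-tabulate bases at the DNM and chosen iSNP positions over all
    reads covering both (a deletion at either position counts under the
    distinct ``'*'`` marker; uncovered reads are excluded)."""
    table = AlleleTable(dnm_position=dnm.position, isnp_position=chosen.position)
    counts: Counter = Counter()
    for read in reads:
        b1 = read.base_at(dnm.position)
        b2 = read.base_at(chosen.position)
        if b1 is None or b2 is None:
            continue
        counts[(b1, b2)] += 1
    table.counts = dict(counts)
    return table
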