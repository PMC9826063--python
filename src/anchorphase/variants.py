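"""Pileup construction, filtered variant calling and iSNP discovery.

The caller works on raw pileups from deep amplicon long reads and applies
the study's filter chain: depth > 20x, alternate-allele fraction within
20-80%, heterozygosity confidence >= 0.96, and allele agreement with the
validated DNM at the anchor position. Surviving candidates are then
error-polished against trio WES evidence and, for intronic targets,
against parental long-read pileups.

Confidence is the posterior probability of heterozygosity under a symmetric
binomial error model with a uniform prior over {hom_ref, het, hom_alt}; the
per-base error rate is estimated from third/fourth-base and deletion counts
at the column itself.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .io_qc import AlignedRead
from .trio import WesEvidence, attribute_alleles
from .types import BASES, DELETED, DNMRecord, PhasingError, RegionSpec

logger = logging.getLogger(__name__)

_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


@dataclass
class PileupColumn:
    """Base, deletion and insertion counts at one reference position."""

    position: int
    counts: Dict[str, int]
    deletions: int = 0
    insertions: int = 0
    mean_quals: Dict[str, float] = field(default_factory=dict)

    @property
    def depth(self) -> int:
        return sum(self.counts.values()) + self.deletions

    def fraction(self, base: str) -> float:
        d = self.depth
        if d == 0:
            return 0.0
        n = self.deletions if base == DELETED else self.counts.get(base, 0)
        return n / d


class Pileup:
    """Column-per-position pileup over a region, backed by numpy counters."""

    def __init__(self, region: RegionSpec):
        self.region = region
        L = region.length
        self.base_counts = np.zeros((L, 4), dtype=np.int64)
        self.deletion_counts = np.zeros(L, dtype=np.int64)
        self.insertion_counts = np.zeros(L, dtype=np.int64)
        self.qual_sums = np.zeros((L, 4), dtype=np.float64)

    def column(self, pos: int) -> PileupColumn:
        i = self.region.offset(pos)
        counts = {b: int(self.base_counts[i, j]) for j, b in enumerate(BASES)}
        mean_quals = {
            b: float(self.qual_sums[i, j] / self.base_counts[i, j])
            for j, b in enumerate(BASES)
            if self.base_counts[i, j] > 0
        }
        return PileupColumn(
            position=pos,
            counts=counts,
            deletions=int(self.deletion_counts[i]),
            insertions=int(self.insertion_counts[i]),
            mean_quals=mean_quals,
        )

    def __iter__(self):
        for pos in range(self.region.start, self.region.end + 1):
            yield self.column(pos)

    def depth(self, pos: int) -> int:
        i = self.region.offset(pos)
        return int(self.base_counts[i].sum() + self.deletion_counts[i])


def build_pileup(reads: Iterable[AlignedRead], region: RegionSpec) -> Pileup:
    """Count bases, deletions and insertions per reference position.

    A read contributes a base at a position only where the position is
    aligned to a non-clipped, non-deleted read base; deletions are tallied
    separately. An empty read set yields an empty pileup.
    """
    from .simulate import encode_seq

    pileup = Pileup(region)
    L = region.length
    for read in reads:
        if read.contig != region.contig:
            raise ValueError(
                f"read {read.read_id} on {read.contig}, pileup region on {region.contig}"
            )
        codes = encode_seq(read.seq) if read.seq else np.zeros(0, dtype=np.uint8)
        quals = read.quals
        for ref_start, q_start, n in read.match_blocks():
            lo = max(ref_start, region.start)
            hi = min(ref_start + n - 1, region.end)
            if hi < lo:
                continue
            qs = q_start + (lo - ref_start)
            idx = np.arange(lo - region.start, hi - region.start + 1)
            block = codes[qs:qs + len(idx)]
            np.add.at(pileup.base_counts, (idx, block), 1)
            np.add.at(pileup.qual_sums, (idx, block), quals[qs:qs + len(idx)])
        for ref_start, n in read.deletion_blocks():
            lo = max(ref_start, region.start)
            hi = min(ref_start + n - 1, region.end)
            if hi >= lo:
                pileup.deletion_counts[lo - region.start:hi - region.start + 1] += 1
        for pos in read.insertion_positions():
            if region.contains(pos):
                pileup.insertion_counts[region.offset(pos)] += 1
    return pileup


@dataclass
class VariantCall:
    """A candidate variant from a pileup column.

    ``alt`` is a single base for SNVs or the ``DELETED`` marker for a
    single-base deletion allele. ``wes_match`` records the polishing
    outcome: True (agrees with WES), None (WES-uncovered), never False
    (disagreeing calls are removed).
    """

    position: int
    ref_base: str
    alt: str
    alt_fraction: float
    depth: int
    confidence: float
    genotype: str  # "het" | "hom_alt"
    source: str = "ONT_proband"
    is_indel: bool = False
    homopolymer: bool = False
    wes_match: Optional[bool] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.alt_fraction <= 1.0):
            raise ValueError("alt fraction must be in [0, 1]")

    @property
    def alleles(self) -> Tuple[str, str]:
        return (self.ref_base, self.alt)


def het_confidence(ref_count: int, alt_count: int, other_count: int) -> float:
    """Posterior probability of heterozygosity for the (ref, alt) pair.

    Genotype likelihoods are binomial on the alt count among ref+alt
    informative observations with allele probabilities {eps, 0.5, 1-eps};
    eps is half the observed third/fourth-base (plus deletion) fraction,
    floored at 1e-3. The prior is uniform.
    """
    n = ref_count + alt_count
    if n == 0:
        return 0.0
    depth = n + other_count
    eps = max(other_count / depth / 2.0, 1e-3)
    a = alt_count
    log_eps = math.log(eps)
    log_1meps = math.log1p(-eps)
    loglik = (
        a * log_eps + (n - a) * log_1meps,    # hom_ref
        n * math.log(0.5),                    # het
        (n - a) * log_eps + a * log_1meps,    # hom_alt
    )
    top = max(loglik)
    weights = [math.exp(l - top) for l in loglik]
    return weights[1] / sum(weights)


def in_homopolymer(region: RegionSpec, pos: int, min_run: int = 3) -> bool:
    """True if ``pos`` lies in or adjacent to a same-base run >= min_run."""
    from .simulate import homopolymer_run_lengths

    runs = homopolymer_run_lengths(region.reference_seq)
    i = region.offset(pos)
    lo = max(0, i - 1)
    hi = min(len(runs) - 1, i + 1)
    return bool((runs[lo:hi + 1] >= min_run).any())


def call_variants(
    pileup: Pileup,
    dnm: DNMRecord,
    min_depth: int = 20,
    af_window: Tuple[float, float] = (0.20, 0.80),
    min_conf: float = 0.96,
) -> List[VariantCall]:
    """Call filtered SNV and single-base-deletion candidates from a pileup.

    Heterozygous candidates require depth strictly above ``min_depth``,
    alternate fraction inside the inclusive ``af_window`` and het posterior
    >= ``min_conf``. At the DNM position only the validated alternate allele
    is admitted and the fraction/confidence filters do not apply (mosaic
    DNMs may sit far below the window). Homozygous-alternate calls (fraction
    above the window) are retained, flagged ``genotype='hom_alt'``, for the
    linked-variant search. Raises if the DNM position has no coverage.
    """
    region = pileup.region
    if not region.contains(dnm.position) or pileup.depth(dnm.position) == 0:
        raise PhasingError(
            f"DNM position {dnm.position} absent from pileup: amplicon failed"
        )
    lo, hi = af_window
    calls: List[VariantCall] = []
    nonzero = np.flatnonzero(
        pileup.base_counts.sum(axis=1) + pileup.deletion_counts
    )
    for i in nonzero:
        pos = region.start + int(i)
        ref = region.base(pos)
        col_counts = pileup.base_counts[i]
        deletions = int(pileup.deletion_counts[i])
        depth = int(col_counts.sum()) + deletions
        ref_count = int(col_counts[_BASE_INDEX[ref]])

        # candidate alleles: every non-reference base plus the deletion allele
        alleles: List[Tuple[str, int, bool]] = [
            (b, int(col_counts[_BASE_INDEX[b]]), False) for b in BASES if b != ref
        ]
        alleles.append((DELETED, deletions, True))

        for alt, alt_count, is_indel in alleles:
            if alt_count == 0:
                continue
            if pos == dnm.position:
                if alt != dnm.alt_base:
                    continue  # allele agreement with the validated DNM
                if depth <= min_depth:
                    continue
                other = depth - ref_count - alt_count
                calls.append(
                    VariantCall(
                        position=pos,
                        ref_base=ref,
                        alt=alt,
                        alt_fraction=alt_count / depth,
                        depth=depth,
                        confidence=het_confidence(ref_count, alt_count, other),
                        genotype="het",
                    )
                )
                continue
            if depth <= min_depth:
                continue
            frac = alt_count / depth
            if frac < lo:
                continue  # below the window for het and hom_alt alike
            other = depth - ref_count - alt_count
            if is_indel:
                other = depth - ref_count - deletions
            conf_het = het_confidence(ref_count, alt_count, other)
            hp = is_indel and in_homopolymer(region, pos)
            if lo <= frac <= hi:
                if conf_het >= min_conf:
                    calls.append(
                        VariantCall(
                            position=pos,
                            ref_base=ref,
                            alt=alt,
                            alt_fraction=frac,
                            depth=depth,
                            confidence=conf_het,
                            genotype="het",
                            is_indel=is_indel,
                            homopolymer=hp,
                        )
                    )
            elif frac > hi:
                calls.append(
                    VariantCall(
                        position=pos,
                        ref_base=ref,
                        alt=alt,
                        alt_fraction=frac,
                        depth=depth,
                        confidence=1.0 - conf_het,
                        genotype="hom_alt",
                        is_indel=is_indel,
                        homopolymer=hp,
                    )
                )
    return calls


def wes_polish(
    candidates: Sequence[VariantCall],
    wes: WesEvidence,
    wes_min_depth: int = 10,
    individual: str = "proband",
) -> List[VariantCall]:
    """Remove candidates that disagree with overlapping WES evidence.

    A candidate at a WES-covered position (depth >= ``wes_min_depth``) is
    kept only if the WES genotype contains the same alternate allele; WES
    coverage with no variant call implies homozygous reference and removes
    the candidate. Candidates at WES-uncovered positions pass through with
    ``wes_match=None`` (unvalidated). Below ``wes_min_depth`` WES is deemed
    uninformative rather than contradictory.
    """
    kept: List[VariantCall] = []
    removed = 0
    for cand in candidates:
        depth = wes.depth_at(cand.position, individual)
        if depth < wes_min_depth:
            cand.wes_match = None
            kept.append(cand)
            continue
        site = wes.site(cand.position)
        gt = site.genotypes.get(individual) if site is not None else None
        alleles = set(gt) if gt is not None else {cand.ref_base}  # implied hom-ref
        if cand.alt in alleles:
            cand.wes_match = True
            kept.append(cand)
        else:
            removed += 1
    logger.info("wes_polish: removed %d of %d candidates", removed, len(candidates))
    return kept


@dataclass
class ISNPCandidate:
    """A proband het site usable to map haplotypes to parents.

    ``support_category`` reflects orthogonal validation: primary (trio WES),
    secondary (proband WES only), tertiary (parental long reads only),
    unvalidated (none). Split-read agreement fields are filled by the
    anchored-phasing stage.
    """

    position: int
    ref_base: str
    alt: str
    paternal_base: str
    maternal_base: str
    distance: int  # signed bp to the DNM
    support_category: str = "unvalidated"
    call: Optional[VariantCall] = None
    agreement: Optional[float] = None
    alt_agreement: Optional[float] = None
    linked_alt_base: Optional[str] = None
    linked_ref_base: Optional[str] = None
    spanning: int = 0
    discordant: bool = False
    insufficient: bool = False

    @property
    def bases(self) -> Tuple[str, str]:
        return (self.paternal_base, self.maternal_base)


def discover_wes_isnps(
    wes: WesEvidence,
    dnm: DNMRecord,
    window_bp: int = 10_000,
    min_parent_depth: int = 5,
) -> List[ISNPCandidate]:
    """Trio-WES iSNPs: proband-het sites near the DNM whose alleles are
    uniquely attributable to one parent each, with both parents covered at
    >= 5x. Multi-allelic sites are excluded."""
    out: List[ISNPCandidate] = []
    for pos in sorted(wes.sites):
        if pos == dnm.position or abs(pos - dnm.position) > window_bp:
            continue
        site = wes.sites[pos]
        gt = site.genotypes.get("proband")
        if gt is None or gt[0] == gt[1]:
            continue
        if len(site.alleles()) > 2:
            continue
        if site.depth("father") < min_parent_depth or site.depth("mother") < min_parent_depth:
            continue
        father = site.genotypes.get("father")
        mother = site.genotypes.get("mother")
        if father is None or mother is None:
            continue
        attribution = attribute_alleles(gt, father, mother)
        if attribution is None:
            continue
        pat, mat = attribution
        alt = gt[0] if gt[1] == site.ref else gt[1]
        out.append(
            ISNPCandidate(
                position=pos,
                ref_base=site.ref,
                alt=alt,
                paternal_base=pat,
                maternal_base=mat,
                distance=pos - dnm.position,
                support_category="primary",
            )
        )
    return out


def classify_target(
    dnm: DNMRecord,
    wes_isnps: Sequence[ISNPCandidate],
    short_read_span: int = 300,
    long_window: int = 10_000,
    trio_window: int = 5_000,
) -> int:
    """Phasing category: 1 if a WES iSNP lies within short-read span of the
    DNM (short reads alone may phase), 2 if within the long-read window
    (proband amplicon suffices), 3 otherwise (parental long reads over
    +/- trio_window required)."""
    distances = [abs(c.distance) for c in wes_isnps]
    nearest = min(distances) if distances else None
    if nearest is not None and nearest <= short_read_span:
        return 1
    if nearest is not None and nearest <= long_window:
        return 2
    return 3


def discover_ont_parental_isnps(
    father_pileup: Pileup,
    mother_pileup: Pileup,
    candidates: Sequence[VariantCall],
    dnm: DNMRecord,
    window_bp: int = 5_000,
    parental_support_af: float = 0.20,
    min_parent_depth: int = 20,
) -> List[ISNPCandidate]:
    """Type proband het candidates from parental long-read pileups
    (category-3 targets, typically intronic iSNPs).

    A parent supports an allele when its pileup fraction is >=
    ``parental_support_af`` at depth >= ``min_parent_depth``; a candidate is
    informative when its two alleles resolve to different parents uniquely.
    """
    out: List[ISNPCandidate] = []
    for cand in candidates:
        if cand.genotype != "het" or cand.is_indel:
            continue
        if cand.position == dnm.position or abs(cand.position - dnm.position) > window_bp:
            continue
        x, y = cand.ref_base, cand.alt
        supports = {}
        ok = True
        for name, pileup in (("father", father_pileup), ("mother", mother_pileup)):
            if not pileup.region.contains(cand.position):
                ok = False
                break
            col = pileup.column(cand.position)
            if col.depth < min_parent_depth:
                logger.info(
                    "parental typing: %s depth %d < %d at %d",
                    name, col.depth, min_parent_depth, cand.position,
                )
                ok = False
                break
            supports[name] = {
                b for b in (x, y) if col.fraction(b) >= parental_support_af
            }
        if not ok:
            continue
        # genotype each parent from its supported allele set
        father_gt = tuple(sorted(supports["father"])) or None
        mother_gt = tuple(sorted(supports["mother"])) or None
        if not father_gt or not mother_gt:
            continue
        father_gt = father_gt * 2 if len(father_gt) == 1 else father_gt
        mother_gt = mother_gt * 2 if len(mother_gt) == 1 else mother_gt
        attribution = attribute_alleles((x, y), father_gt, mother_gt)
        if attribution is None:
            continue
        pat, mat = attribution
        out.append(
            ISNPCandidate(
                position=cand.position,
                ref_base=cand.ref_base,
                alt=cand.alt,
                paternal_base=pat,
                maternal_base=mat,
                distance=cand.position - dnm.position,
                support_category="tertiary",
                call=cand,
            )
        )
    return out
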