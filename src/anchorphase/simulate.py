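"""Synthetic trio / amplicon dataset generator.

Emulates the study design end to end at desk scale: a diploid trio with
Mendelian genotypes over one amplicon region, a de novo SNV placed on one
parental haplotype of the proband (optionally mosaic at fraction m),
amplicon-spanning long reads with substitution error and homopolymer-biased
indel error, and short-read WES-like trio evidence at modest coverage.

Reads are emitted already aligned (SAM-ready, with correct CIGARs against
the region reference): basecalling and alignment are out of scope, so the
simulator doubles as the alignment oracle. Every read's true haplotype and
mutant status live in a separate truth record, never in the read itself.
All randomness flows from a single numpy Generator per dataset.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from typing import Callable, Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np

from .io_qc import AlignedRead, Cigar
from .trio import WesEvidence, WesSite, attribute_alleles
from .types import (
    BASES,
    MATERNAL,
    ONT_LIKE,
    PATERNAL,
    DNMTruth,
    ErrorModel,
    Genotype,
    InformativenessError,
    RegionSpec,
    TrioGenotypes,
)

_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)
_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i


def encode_seq(seq: str) -> np.ndarray:
    """ACGT string -> uint8 codes 0..3."""
    codes = _ENCODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if codes.max(initial=0) > 3:
        raise ValueError("sequence contains non-ACGT characters")
    return codes


def decode_seq(codes: np.ndarray) -> str:
    return _BASE_BYTES[codes].tobytes().decode()


def homopolymer_run_lengths(seq: str) -> np.ndarray:
    """Length of the homopolymer run each position belongs to."""
    a = np.frombuffer(seq.encode(), dtype=np.uint8)
    if len(a) == 0:
        return np.zeros(0, dtype=np.int64)
    change = np.flatnonzero(np.diff(a)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [len(a)]))
    lengths = ends - starts
    return np.repeat(lengths, lengths)


def random_reference(length: int, rng: np.random.Generator) -> str:
    return decode_seq(rng.integers(0, 4, size=length).astype(np.uint8))


def _rng(seed=None, rng: Optional[np.random.Generator] = None) -> np.random.Generator:
    if rng is not None:
        return rng
    if seed is None:
        raise ValueError("a seed (or an explicit Generator) is required")
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# trio genotypes

SchemeSpec = Union[str, Tuple[Genotype, Genotype]]


def _scheme_genotypes(
    scheme: SchemeSpec, ref: str, rng: np.random.Generator
) -> Tuple[Genotype, Genotype]:
    """Father and mother genotypes for one designated iSNP position."""
    if isinstance(scheme, tuple):
        return scheme
    alt = BASES[(BASES.index(ref) + int(rng.integers(1, 4))) % 4]
    if scheme == "opposite_hom":
        # one parent homozygous ref, the other homozygous alt
        if rng.random() < 0.5:
            return (ref, ref), (alt, alt)
        return (alt, alt), (ref, ref)
    if scheme == "father_het":
        return (ref, alt), (ref, ref)
    if scheme == "mother_het":
        return (ref, ref), (ref, alt)
    raise ValueError(f"unknown informativeness scheme {scheme!r}")


def _informative_proband_het(
    father_gt: Genotype, mother_gt: Genotype
) -> Tuple[str, str]:
    """(paternal_base, maternal_base) for the forced proband het, or raise."""
    options = []
    for x in sorted(set(father_gt)):
        for y in sorted(set(mother_gt)):
            if x == y:
                continue
            if attribute_alleles((x, y), father_gt, mother_gt) == (x, y):
                options.append((x, y))
    if not options:
        raise InformativenessError(
            f"no informative proband heterozygote exists for father {father_gt}, "
            f"mother {mother_gt}: alleles not uniquely attributable"
        )
    return options[0]


def simulate_trio_genotypes(
    region: RegionSpec,
    isnp_positions: Sequence[int],
    schemes: Optional[Dict[int, SchemeSpec]] = None,
    seed=None,
    rng: Optional[np.random.Generator] = None,
) -> TrioGenotypes:
    """Generate Mendelian trio genotypes with an informative proband
    heterozygote at each designated iSNP position.

    Each scheme must yield a proband het whose two alleles are uniquely
    attributable to one parent each; schemes that cannot (e.g. both parents
    identically heterozygous) raise :class:`InformativenessError`.
    """
    rng = _rng(seed, rng)
    schemes = schemes or {}
    trio = TrioGenotypes(region=region)
    for pos in isnp_positions:
        if not region.contains(pos):
            raise ValueError(f"iSNP position {pos} outside region")
        ref = region.base(pos)
        father_gt, mother_gt = _scheme_genotypes(schemes.get(pos, "opposite_hom"), ref, rng)
        pat_base, mat_base = _informative_proband_het(father_gt, mother_gt)
        trio.father[pos] = tuple(father_gt)
        trio.mother[pos] = tuple(mother_gt)
        trio.proband[pos] = (pat_base, mat_base)
        trio.paternal_hap[pos] = pat_base
        trio.maternal_hap[pos] = mat_base
    return trio


def place_dnm(genotypes: TrioGenotypes, dnm: DNMTruth) -> TrioGenotypes:
    """Place a de novo SNV on the designated parental haplotype.

    Both parents must be homozygous reference at the position (otherwise the
    variant is inherited, not de novo); the alternate base is carried by
    fraction m of the origin haplotype's simulated molecules.
    """
    region = genotypes.region
    if not region.contains(dnm.position):
        raise ValueError(f"DNM position {dnm.position} outside region")
    ref = region.base(dnm.position)
    if dnm.ref_base != ref:
        raise ValueError(f"DNM ref {dnm.ref_base} != reference base {ref}")
    for name in ("father", "mother"):
        gt = genotypes.genotype_of(name, dnm.position)
        if set(gt) != {ref}:
            raise ValueError(
                f"{name} carries {gt} at position {dnm.position}: not a de novo mutation"
            )
    if dnm.position in genotypes.proband:
        raise ValueError(f"position {dnm.position} already holds a variant")
    out = dataclasses.replace(genotypes, dnm=dnm)
    out.proband = dict(genotypes.proband)
    out.proband[dnm.position] = (dnm.ref_base, dnm.alt_base)
    return out


# ---------------------------------------------------------------------------
# long reads

@dataclass(frozen=True)
class ReadTruth:
    """Ground truth for one simulated read (kept out of the SAM)."""

    read_id: str
    haplotype: str
    is_mutant: bool


@dataclass
class SpanSampler:
    """Samples (start_offset, length) for partial-span reads; the default
    pipeline uses full-length amplicon reads."""

    min_fraction: float = 0.5

    def __call__(self, rng: np.random.Generator, n: int, length: int):
        min_len = max(1, int(self.min_fraction * length))
        lens = rng.integers(min_len, length + 1, size=n)
        starts = np.array([rng.integers(0, length - l + 1) for l in lens])
        return starts, lens


def _per_position_indel_rate(reference: str, error: ErrorModel) -> np.ndarray:
    runs = homopolymer_run_lengths(reference)
    rate = np.full(len(reference), error.indel_rate, dtype=float)
    rate[runs >= error.homopolymer_min_run] *= error.homopolymer_indel_multiplier
    return np.clip(rate, 0.0, 0.9)


def _apply_indels(
    codes: np.ndarray,
    quals: np.ndarray,
    cols: np.ndarray,
    rng: np.random.Generator,
    q_error: int,
) -> Tuple[np.ndarray, np.ndarray, Cigar, int]:
    """Apply 1-bp indel events at reference columns ``cols`` of one read.

    Returns (seq codes, quals, cigar, leading reference offset). Each event
    is a deletion of the base at the column or an insertion of one random
    base after it, with equal probability.
    """
    pieces: List[np.ndarray] = []
    qpieces: List[np.ndarray] = []
    cigar: Cigar = []
    prev = 0

    def emit_match(a: int, b: int) -> None:
        if b > a:
            pieces.append(codes[a:b])
            qpieces.append(quals[a:b])
            cigar.append(("M", b - a))

    for j in cols:
        if rng.random() < 0.5:  # deletion of the base at column j
            emit_match(prev, j)
            cigar.append(("D", 1))
        else:  # insertion after column j
            emit_match(prev, j + 1)
            pieces.append(rng.integers(0, 4, size=1).astype(np.uint8))
            qpieces.append(np.array([q_error], dtype=np.int16))
            cigar.append(("I", 1))
        prev = j + 1
    emit_match(prev, len(codes))

    # merge adjacent ops of the same kind
    merged: Cigar = []
    for op, n in cigar:
        if merged and merged[-1][0] == op:
            merged[-1] = (op, merged[-1][1] + n)
        else:
            merged.append((op, n))
    offset = 0
    while merged and merged[0][0] == "D":
        offset += merged[0][1]
        merged.pop(0)
    while merged and merged[-1][0] == "D":
        merged.pop()
    seq = np.concatenate(pieces) if pieces else np.zeros(0, dtype=np.uint8)
    q = np.concatenate(qpieces) if qpieces else np.zeros(0, dtype=np.int16)
    return seq, q, merged, offset


def _simulate_reads_from_haps(
    hap_seqs: Sequence[str],
    hap_probs: Sequence[float],
    region: RegionSpec,
    n: int,
    error: ErrorModel,
    rng: np.random.Generator,
    id_prefix: str,
    span_sampler: Optional[Callable] = None,
) -> Tuple[List[AlignedRead], np.ndarray]:
    """Core read generator: draw a haplotype per read, apply substitution
    and (homopolymer-weighted) indel errors, emit aligned reads."""
    L = region.length
    haps = np.stack([encode_seq(s) for s in hap_seqs])
    probs = np.asarray(hap_probs, dtype=float)
    probs = probs / probs.sum()
    hap_idx = rng.choice(len(hap_seqs), size=n, p=probs)

    seqs = haps[hap_idx].copy()  # (n, L)
    quals = np.full((n, L), error.quality_true, dtype=np.int16)
    if error.substitution_rate > 0:
        sub_mask = rng.random((n, L)) < error.substitution_rate
        shifts = rng.integers(1, 4, size=int(sub_mask.sum()))
        seqs[sub_mask] = (seqs[sub_mask] + shifts) % 4
        quals[sub_mask] = error.quality_error

    if error.indel_rate > 0:
        p_ind = _per_position_indel_rate(region.reference_seq, error)
        ind_mask = rng.random((n, L)) < p_ind[None, :]
    else:
        ind_mask = None

    starts = np.zeros(n, dtype=int)
    lengths = np.full(n, L, dtype=int)
    if span_sampler is not None:
        starts, lengths = span_sampler(rng, n, L)

    reads: List[AlignedRead] = []
    for i in range(n):
        s, l = int(starts[i]), int(lengths[i])
        codes = seqs[i, s:s + l]
        q = quals[i, s:s + l]
        ref_start = region.start + s
        if ind_mask is not None and ind_mask[i, s:s + l].any():
            cols = np.flatnonzero(ind_mask[i, s:s + l])
            codes, q, cigar, off = _apply_indels(codes, q, cols, rng, error.quality_error)
            ref_start += off
        else:
            cigar = [("M", l)]
        reads.append(
            AlignedRead(
                read_id=f"{id_prefix}{i:06d}",
                contig=region.contig,
                start=ref_start,
                cigar=cigar,
                seq=decode_seq(codes),
                quals=q,
            )
        )
    return reads, hap_idx


def simulate_long_reads(
    genotypes: TrioGenotypes,
    dnm: Optional[DNMTruth] = None,
    coverage: int = 1000,
    error: ErrorModel = ONT_LIKE,
    seed=None,
    rng: Optional[np.random.Generator] = None,
    span_sampler: Optional[Callable] = None,
    id_prefix: str = "read",
) -> Tuple[List[AlignedRead], List[ReadTruth]]:
    """Simulate proband amplicon long reads over the trio's region.

    Haplotypes are drawn 50/50 paternal/maternal; on the DNM's origin
    haplotype a fraction m of molecules carry the alternate base. Returns
    the aligned reads and per-read truth records.
    """
    if coverage < 1:
        raise ValueError("coverage must be >= 1")
    rng = _rng(seed, rng)
    dnm = dnm if dnm is not None else genotypes.dnm
    region = genotypes.region

    pat = genotypes.haplotype_seq(PATERNAL)
    mat = genotypes.haplotype_seq(MATERNAL)
    if dnm is not None:
        tmp = dataclasses.replace(genotypes, dnm=dnm)
        m = dnm.mosaic_fraction
        origin_pat = dnm.parental_haplotype_of_origin == PATERNAL
        haps = [
            pat,
            mat,
            tmp.haplotype_seq(PATERNAL, mutant=True),
            tmp.haplotype_seq(MATERNAL, mutant=True),
        ]
        probs = [
            0.5 * (1 - m) if origin_pat else 0.5,
            0.5 if origin_pat else 0.5 * (1 - m),
            0.5 * m if origin_pat else 0.0,
            0.0 if origin_pat else 0.5 * m,
        ]
    else:
        haps = [pat, mat]
        probs = [0.5, 0.5]

    reads, hap_idx = _simulate_reads_from_haps(
        haps, probs, region, coverage, error, rng, id_prefix, span_sampler
    )
    truth = [
        ReadTruth(
            read_id=r.read_id,
            haplotype=PATERNAL if idx % 2 == 0 else MATERNAL,
            is_mutant=bool(idx >= 2),
        )
        for r, idx in zip(reads, hap_idx)
    ]
    return reads, truth


def simulate_parental_long_reads(
    genotypes: TrioGenotypes,
    coverage: int = 500,
    error: ErrorModel = ONT_LIKE,
    seed=None,
    rng: Optional[np.random.Generator] = None,
) -> Dict[str, List[AlignedRead]]:
    """Amplicon long reads for father and mother (category-3 targets).

    Parental phase is irrelevant downstream (only allele fractions are
    used), so each parent's two genotype alleles define the two haplotypes.
    """
    rng = _rng(seed, rng)
    region = genotypes.region
    out: Dict[str, List[AlignedRead]] = {}
    for name, table in (("father", genotypes.father), ("mother", genotypes.mother)):
        seqs = []
        for k in range(2):
            seq = list(region.reference_seq)
            for pos, gt in table.items():
                seq[region.offset(pos)] = gt[k]
            seqs.append("".join(seq))
        reads, _ = _simulate_reads_from_haps(
            seqs, [0.5, 0.5], region, coverage, error, rng, f"{name}_"
        )
        out[name] = reads
    return out


# ---------------------------------------------------------------------------
# WES-like short-read evidence

def simulate_wes_evidence(
    genotypes: TrioGenotypes,
    dnm: Optional[DNMTruth] = None,
    coverage_short: int = 72,
    seed=None,
    rng: Optional[np.random.Generator] = None,
    uncovered_positions: Sequence[int] = (),
    covered_intervals: Optional[Sequence[Tuple[int, int]]] = None,
    depth_overrides: Optional[Dict[Tuple[str, int], int]] = None,
) -> WesEvidence:
    """Trio genotype calls with per-position depths, as a WES caller would
    report them over the region.

    ``coverage_short=0`` or listing a position in ``uncovered_positions``
    models an exome-capture gap (e.g. intronic iSNPs). ``depth_overrides``
    pins the depth for specific (individual, position) pairs, e.g. to mimic
    a 1x-covered DNM site. Genotypes are called from binomially sampled
    allele counts; the proband's expected alternate fraction at the DNM is
    m/2.
    """
    if coverage_short < 0:
        raise ValueError("coverage must be >= 0")
    rng = _rng(seed, rng)
    dnm = dnm if dnm is not None else genotypes.dnm
    region = genotypes.region
    depth_overrides = depth_overrides or {}
    uncovered = set(uncovered_positions)
    intervals = (
        [(s, e) for s, e in covered_intervals]
        if covered_intervals is not None
        else [(region.start, region.end)]
    )

    def in_footprint(pos: int) -> bool:
        return pos not in uncovered and any(s <= pos <= e for s, e in intervals)

    wes = WesEvidence(gaps=set(uncovered))
    if coverage_short > 0:
        for s, e in intervals:
            depths = {
                name: int(rng.poisson(coverage_short))
                for name in ("father", "mother", "proband")
            }
            wes.coverage.append((s, e, depths))

    positions = sorted(set(genotypes.father) | set(genotypes.mother) | set(genotypes.proband))
    for pos in positions:
        if coverage_short == 0 or not in_footprint(pos):
            continue
        ref = region.base(pos)
        site = WesSite(position=pos, ref=ref, genotypes={}, depths={})
        for name in ("father", "mother", "proband"):
            depth = depth_overrides.get((name, pos), int(rng.poisson(coverage_short)))
            site.depths[name] = depth
            if depth == 0:
                continue
            gt = genotypes.genotype_of(name, pos)
            a, b = gt
            if a == b:
                site.genotypes[name] = gt
                site.alt_fractions[name] = 0.0 if a == ref else 1.0
                continue
            # heterozygous: sample the minor-allele count
            p = 0.5
            if dnm is not None and pos == dnm.position and name == "proband":
                p = dnm.mosaic_fraction / 2.0
            alt_n = rng.binomial(depth, p)
            frac = alt_n / depth
            site.alt_fractions[name] = frac
            if frac <= 0.1:
                site.genotypes[name] = (a, a)
            elif frac >= 0.9:
                site.genotypes[name] = (b, b)
            else:
                site.genotypes[name] = gt
        wes.add(site)
    return wes


def simulate_short_reads(
    genotypes: TrioGenotypes,
    dnm: Optional[DNMTruth] = None,
    coverage: int = 72,
    read_len: int = 150,
    error_rate: float = 0.001,
    seed=None,
    rng: Optional[np.random.Generator] = None,
) -> List[AlignedRead]:
    """Proband WES-like short reads over the region (for the short-read
    phasing control on category-1 targets)."""
    rng = _rng(seed, rng)
    region = genotypes.region
    dnm = dnm if dnm is not None else genotypes.dnm
    L = region.length
    read_len = min(read_len, L)
    n = max(1, int(round(coverage * L / read_len)))

    pat = encode_seq(genotypes.haplotype_seq(PATERNAL))
    mat = encode_seq(genotypes.haplotype_seq(MATERNAL))
    haps = [pat, mat]
    if dnm is not None:
        tmp = dataclasses.replace(genotypes, dnm=dnm)
        origin_pat = dnm.parental_haplotype_of_origin == PATERNAL
        m = dnm.mosaic_fraction
        haps += [
            encode_seq(tmp.haplotype_seq(PATERNAL, mutant=True)),
            encode_seq(tmp.haplotype_seq(MATERNAL, mutant=True)),
        ]
        probs = np.array(
            [
                0.5 * (1 - m) if origin_pat else 0.5,
                0.5 if origin_pat else 0.5 * (1 - m),
                0.5 * m if origin_pat else 0.0,
                0.0 if origin_pat else 0.5 * m,
            ]
        )
    else:
        probs = np.array([0.5, 0.5])

    reads: List[AlignedRead] = []
    hap_idx = rng.choice(len(haps), size=n, p=probs / probs.sum())
    starts = rng.integers(0, L - read_len + 1, size=n)
    for i in range(n):
        s = int(starts[i])
        codes = haps[hap_idx[i]][s:s + read_len].copy()
        if error_rate > 0:
            mask = rng.random(read_len) < error_rate
            if mask.any():
                codes[mask] = (codes[mask] + rng.integers(1, 4, size=int(mask.sum()))) % 4
        reads.append(
            AlignedRead(
                read_id=f"wes{i:06d}",
                contig=region.contig,
                start=region.start + s,
                cigar=[("M", read_len)],
                seq=decode_seq(codes),
                quals=np.full(read_len, 30, dtype=np.int16),
            )
        )
    return reads


# ---------------------------------------------------------------------------
# whole datasets

@dataclass
class SimulatedDataset:
    """Everything one target needs downstream, plus ground truth."""

    region: RegionSpec
    genotypes: TrioGenotypes
    dnm: DNMTruth
    reads: List[AlignedRead]
    truth: List[ReadTruth]
    wes: Optional[WesEvidence] = None
    wes_reads: Optional[List[AlignedRead]] = None
    parental_reads: Optional[Dict[str, List[AlignedRead]]] = None


def simulate_target(
    seed=None,
    rng: Optional[np.random.Generator] = None,
    contig: str = "sim1",
    region_start: int = 10_001,
    region_length: int = 3000,
    isnp_offsets: Sequence[int] = (1100,),
    dnm_offset: Optional[int] = None,
    origin: str = PATERNAL,
    mosaic_fraction: float = 1.0,
    coverage: int = 1000,
    error: ErrorModel = ONT_LIKE,
    wes_coverage: int = 72,
    wes_uncovered: Sequence[int] = (),
    with_wes_reads: bool = False,
    parental_coverage: int = 0,
) -> SimulatedDataset:
    """One fully simulated amplicon target with default study conditions:
    a 3 kb amplicon, the DNM at its centre, one informative SNP, deep long
    reads and modest-coverage WES trio evidence."""
    rng = _rng(seed, rng)
    reference = random_reference(region_length, rng)
    region = RegionSpec(
        contig=contig,
        start=region_start,
        end=region_start + region_length - 1,
        reference_seq=reference,
    )
    dnm_pos = region_start + (dnm_offset if dnm_offset is not None else region_length // 2)
    isnp_positions = [region_start + off for off in isnp_offsets]
    if dnm_pos in isnp_positions:
        raise ValueError("DNM and iSNP positions must differ")

    trio = simulate_trio_genotypes(region, isnp_positions, rng=rng)
    ref = region.base(dnm_pos)
    alt = BASES[(BASES.index(ref) + int(rng.integers(1, 4))) % 4]
    dnm = DNMTruth(
        position=dnm_pos,
        ref_base=ref,
        alt_base=alt,
        parental_haplotype_of_origin=origin,
        mosaic_fraction=mosaic_fraction,
    )
    trio = place_dnm(trio, dnm)

    reads, truth = simulate_long_reads(trio, coverage=coverage, error=error, rng=rng)
    wes = simulate_wes_evidence(
        trio, coverage_short=wes_coverage, rng=rng, uncovered_positions=wes_uncovered
    )
    wes_reads = (
        simulate_short_reads(trio, coverage=wes_coverage, rng=rng) if with_wes_reads else None
    )
    parental = (
        simulate_parental_long_reads(trio, coverage=parental_coverage, error=error, rng=rng)
        if parental_coverage > 0
        else None
    )
    return SimulatedDataset(
        region=region,
        genotypes=trio,
        dnm=dnm,
        reads=reads,
        truth=truth,
        wes=wes,
        wes_reads=wes_reads,
        parental_reads=parental,
    )


@dataclass(frozen=True)
class CohortTruth:
    """Ground truth labels for one cohort target."""

    target_id: str
    origin: str
    mosaic_fraction: float

    @property
    def zygosity(self) -> str:
        return "prezygotic" if self.mosaic_fraction >= 1.0 else "postzygotic"


def simulate_cohort(
    n_targets: int,
    seed=None,
    paternal_fraction: float = 0.83,
    postzygotic_fraction: float = 0.10,
    mosaic_range: Tuple[float, float] = (0.1, 0.4),
    coverage: int = 200,
    error: ErrorModel = ErrorModel(substitution_rate=0.04, indel_rate=0.0),
    **target_kwargs,
) -> Iterable[Tuple[SimulatedDataset, CohortTruth]]:
    """Yield cohort targets with study-condition truth: ~83% paternal
    origin, ~10% postzygotic with mosaic fraction uniform in [0.1, 0.4]."""
    master = np.random.default_rng(seed)
    for i in range(n_targets):
        rng = np.random.default_rng(master.integers(0, 2**31 - 1))
        origin = PATERNAL if rng.random() < paternal_fraction else MATERNAL
        if rng.random() < postzygotic_fraction:
            m = float(rng.uniform(*mosaic_range))
        else:
            m = 1.0
        ds = simulate_target(
            rng=rng,
            origin=origin,
            mosaic_fraction=m,
            coverage=coverage,
            error=error,
            **target_kwargs,
        )
        yield ds, CohortTruth(target_id=f"target{i:03d}", origin=origin, mosaic_fraction=m)


def write_truth_json(path, truth: Sequence[ReadTruth]) -> None:
    with open(path, "w") as fh:
        json.dump([dataclasses.asdict(t) for t in truth], fh, indent=1)


def read_truth_json(path) -> List[ReadTruth]:
    with open(path) as fh:
        return [ReadTruth(**d) for d in json.load(fh)]


def write_dataset(ds: SimulatedDataset, outdir) -> Dict[str, str]:
    """Write a simulated dataset as plain-text files: region FASTA, proband
    (and optional parental) SAM, trio VCF, truth JSON, manifest TSV."""
    from pathlib import Path

    from . import samio
    from .io_qc import Target, TargetManifest
    from .types import DNMRecord

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    contig_lengths = {ds.region.contig: ds.region.end}
    paths = {}

    paths["fasta"] = str(outdir / "region.fasta")
    samio.write_region_fasta(paths["fasta"], ds.region)
    paths["proband_sam"] = str(outdir / "proband.sam")
    samio.write_sam(paths["proband_sam"], ds.reads, contig_lengths)
    paths["truth"] = str(outdir / "truth.json")
    write_truth_json(paths["truth"], ds.truth)
    if ds.wes is not None:
        paths["vcf"] = str(outdir / "trio.vcf")
        samio.write_trio_vcf(paths["vcf"], ds.wes, ds.region.contig, ds.region.end)
    if ds.wes_reads is not None:
        paths["wes_sam"] = str(outdir / "proband_wes.sam")
        samio.write_sam(paths["wes_sam"], ds.wes_reads, contig_lengths)
    if ds.parental_reads:
        for name, reads in ds.parental_reads.items():
            key = f"{name}_sam"
            paths[key] = str(outdir / f"{name}.sam")
            samio.write_sam(paths[key], reads, contig_lengths)
    manifest = TargetManifest(
        [
            Target(
                sample_id="sim_target",
                contig=ds.region.contig,
                start=ds.region.start,
                end=ds.region.end,
                dnm=DNMRecord(
                    ds.region.contig, ds.dnm.position, ds.dnm.ref_base, ds.dnm.alt_base
                ),
            )
        ]
    )
    paths["manifest"] = str(outdir / "manifest.tsv")
    manifest.to_tsv(paths["manifest"])
    return paths
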