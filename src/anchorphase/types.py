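"""Core domain types shared across the pipeline.

Coordinates are 1-based inclusive everywhere user-facing (VCF convention).
Bases are uppercase single characters from ``ACGT``; a deletion spanning a
queried reference position is reported with the distinct marker ``DELETED``
(``"*"``), never as a base.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Tuple

BASES = "ACGT"
DELETED = "*"

PATERNAL = "paternal"
MATERNAL = "maternal"
PARENTS = (PATERNAL, MATERNAL)


class InformativenessError(ValueError):
    """Raised when a requested site cannot be made parentally informative."""


class PhasingError(RuntimeError):
    """Raised on hard failures (e.g. no reads cover the anchoring DNM)."""


@dataclass(frozen=True)
class RegionSpec:
    """A target amplicon region with its reference sequence.

    ``start``/``end`` are 1-based inclusive genomic coordinates;
    ``reference_seq`` covers exactly ``[start, end]``.
    """

    contig: str
    start: int
    end: int
    reference_seq: str

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"end {self.end} < start {self.start}")
        if len(self.reference_seq) != self.length:
            raise ValueError(
                f"reference length {len(self.reference_seq)} != region span {self.length}"
            )
        if set(self.reference_seq) - set(BASES):
            raise ValueError("reference sequence must be uppercase ACGT")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def offset(self, pos: int) -> int:
        """0-based offset of a 1-based position into ``reference_seq``."""
        if not self.contains(pos):
            raise ValueError(f"position {pos} outside {self.contig}:{self.start}-{self.end}")
        return pos - self.start

    def base(self, pos: int) -> str:
        return self.reference_seq[self.offset(pos)]


@dataclass(frozen=True)
class DNMRecord:
    """A validated de novo SNV anchoring the phasing of one target."""

    contig: str
    position: int
    ref_base: str
    alt_base: str
    validated: bool = True

    def __post_init__(self) -> None:
        if self.ref_base == self.alt_base:
            raise ValueError("DNM ref and alt must differ")
        for b in (self.ref_base, self.alt_base):
            if b not in BASES:
                raise ValueError(f"DNM alleles must be single bases, got {b!r}")


@dataclass(frozen=True)
class DNMTruth:
    """Ground-truth description of a simulated de novo mutation.

    ``mosaic_fraction`` m is the fraction of molecules of the origin
    haplotype that carry the alternate base: m=1 models a prezygotic
    (germline) event, m<1 a postzygotic mosaic.
    """

    position: int
    ref_base: str
    alt_base: str
    parental_haplotype_of_origin: str
    mosaic_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.ref_base == self.alt_base:
            raise ValueError("DNM ref and alt must differ")
        if self.parental_haplotype_of_origin not in PARENTS:
            raise ValueError("origin must be 'paternal' or 'maternal'")
        if not (0.0 < self.mosaic_fraction <= 1.0):
            raise ValueError("mosaic fraction must be in (0, 1]")

    def as_record(self, contig: str) -> DNMRecord:
        return DNMRecord(contig, self.position, self.ref_base, self.alt_base)


@dataclass
class ErrorModel:
    """Per-base sequencing error model for simulated long reads.

    Substituted bases are drawn uniformly from the three non-true bases.
    Indel probability is multiplied inside homopolymer runs of length
    >= ``homopolymer_min_run``.
    """

    substitution_rate: float = 0.04
    indel_rate: float = 0.01
    homopolymer_indel_multiplier: float = 5.0
    homopolymer_min_run: int = 3
    quality_true: int = 20
    quality_error: int = 10

    def __post_init__(self) -> None:
        for name in ("substitution_rate", "indel_rate"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ValueError(f"{name} must be in [0, 1), got {v}")
        if self.homopolymer_indel_multiplier < 1.0:
            raise ValueError("homopolymer multiplier must be >= 1")


#: default preset approximating raw nanopore amplicon error scale
ONT_LIKE = ErrorModel()
#: error-free preset for exact oracles
NOISELESS = ErrorModel(substitution_rate=0.0, indel_rate=0.0)


Genotype = Tuple[str, str]


@dataclass
class TrioGenotypes:
    """Diploid genotypes of father, mother and proband over one region,
    with the proband's two haplotypes labelled by parental origin.

    Haplotypes are stored as sparse substitutions on the region reference;
    positions absent from a haplotype dict carry the reference base.
    """

    region: RegionSpec
    father: Dict[int, Genotype] = field(default_factory=dict)
    mother: Dict[int, Genotype] = field(default_factory=dict)
    proband: Dict[int, Genotype] = field(default_factory=dict)
    paternal_hap: Dict[int, str] = field(default_factory=dict)
    maternal_hap: Dict[int, str] = field(default_factory=dict)
    dnm: Optional[DNMTruth] = None

    def haplotype_seq(self, parent: str, mutant: bool = False) -> str:
        """Full-length proband haplotype sequence; ``mutant=True`` places the
        DNM alternate base (only meaningful on the origin haplotype)."""
        if parent not in PARENTS:
            raise ValueError(parent)
        hap = self.paternal_hap if parent == PATERNAL else self.maternal_hap
        seq = list(self.region.reference_seq)
        for pos, base in hap.items():
            seq[self.region.offset(pos)] = base
        if mutant:
            if self.dnm is None:
                raise ValueError("no DNM placed on this trio")
            seq[self.region.offset(self.dnm.position)] = self.dnm.alt_base
        return "".join(seq)

    def genotype_of(self, individual: str, pos: int) -> Genotype:
        table = {"father": self.father, "mother": self.mother, "proband": self.proband}[individual]
        if pos in table:
            return table[pos]
        ref = self.region.base(pos)
        return (ref, ref)

    def with_dnm(self, dnm: DNMTruth) -> "TrioGenotypes":
        return replace(self, dnm=dnm)


@dataclass
class ErrorMetrics:
    """Known-false base and allele-pair fractions around one phased target.

    ``total_*`` sum all known-false fractions; ``max_*`` report the single
    most prevalent false base / allele pair. The candidate third allelic
    form (DNM wild type on the mutant haplotype's iSNP background) is by
    construction never counted as known-false.
    """

    total_base_error: float = 0.0
    max_false_base: float = 0.0
    total_allele_error: float = 0.0
    max_false_allele: float = 0.0

    def __post_init__(self) -> None:
        for v in (self.total_base_error, self.max_false_base,
                  self.total_allele_error, self.max_false_allele):
            if not (0.0 <= v <= 1.0):
                raise ValueError("error fractions must lie in [0, 1]")
        if self.max_false_base > self.total_base_error + 1e-12:
            raise ValueError("max false base exceeds total base error")
        if self.max_false_allele > self.total_allele_error + 1e-12:
            raise ValueError("max false allele exceeds total allele error")

    def to_dict(self) -> dict:
        return {
            "total_base_error": self.total_base_error,
            "max_false_base": self.max_false_base,
            "total_allele_error": self.total_allele_error,
            "max_false_allele": self.max_false_allele,
        }
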