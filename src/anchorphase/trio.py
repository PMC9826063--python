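"""Trio short-read (WES-like) genotype evidence and parental attribution.

An informative SNP (iSNP) is a proband-heterozygous site whose two alleles
can each be uniquely attributed to one parent. Attribution works by
elimination: an assignment (x paternal, y maternal) is possible iff x occurs
in the father's genotype and y in the mother's; the site is informative iff
exactly one of the two assignments is possible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

from .types import Genotype, InformativenessError

INDIVIDUALS = ("father", "mother", "proband")


def attribute_alleles(
    proband_gt: Genotype, father_gt: Genotype, mother_gt: Genotype
) -> Optional[Tuple[str, str]]:
    """Return (paternal_base, maternal_base) for a proband het genotype, or
    None when attribution is ambiguous or Mendelian-impossible."""
    x, y = proband_gt
    if x == y:
        return None
    f, m = set(father_gt), set(mother_gt)
    options = []
    if x in f and y in m:
        options.append((x, y))
    if y in f and x in m:
        options.append((y, x))
    if len(options) == 1:
        return options[0]
    return None


def require_informative(
    proband_gt: Genotype, father_gt: Genotype, mother_gt: Genotype
) -> Tuple[str, str]:
    out = attribute_alleles(proband_gt, father_gt, mother_gt)
    if out is None:
        raise InformativenessError(
            f"alleles {proband_gt} not uniquely attributable given "
            f"father {father_gt}, mother {mother_gt}"
        )
    return out


@dataclass
class WesSite:
    """Trio genotype calls with per-individual depth at one position.

    ``alt_fractions`` optionally records the observed non-reference allele
    fraction per individual (used for DNM base-frequency corroboration).
    """

    position: int
    ref: str
    genotypes: Dict[str, Genotype]
    depths: Dict[str, int]
    alt_fractions: Dict[str, float] = field(default_factory=dict)

    def depth(self, individual: str) -> int:
        return int(self.depths.get(individual, 0))

    def alleles(self) -> set:
        out = set()
        for gt in self.genotypes.values():
            out.update(gt)
        return out


@dataclass
class WesEvidence:
    """Position-indexed trio WES genotypes and depths over one region.

    ``sites`` hold explicit variant genotype calls. ``coverage`` intervals
    (start, end, per-individual depth) describe the short-read footprint at
    non-variant positions, where coverage implies a homozygous-reference
    genotype; positions outside both carry no short-read evidence (e.g.
    intronic positions outside exome capture).
    """

    sites: Dict[int, WesSite] = field(default_factory=dict)
    coverage: List[Tuple[int, int, Dict[str, int]]] = field(default_factory=list)
    gaps: set = field(default_factory=set)

    def site(self, pos: int) -> Optional[WesSite]:
        return self.sites.get(pos)

    def depth_at(self, pos: int, individual: str = "proband") -> int:
        s = self.sites.get(pos)
        if s is not None:
            return s.depth(individual)
        if pos in self.gaps:
            return 0
        for start, end, depths in self.coverage:
            if start <= pos <= end:
                return int(depths.get(individual, 0))
        return 0

    def covered(self, pos: int, individual: str = "proband", min_depth: int = 1) -> bool:
        return self.depth_at(pos, individual) >= min_depth

    def add(self, site: WesSite) -> None:
        self.sites[site.position] = site

    def __len__(self) -> int:
        return len(self.sites)
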