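"""On-disk format support: SAM, FASTA and minimal trio VCF (GT + DP).

pysam does the SAM/VCF heavy lifting; Bio.SeqIO handles FASTA. Region
FASTA records encode genomic coordinates in the description
(``region=contig:start-end``) so a round trip preserves the coordinate
system of the amplicon slice.
"""

from __future__ import annotations

import re
from typing import Dict, Iterable, List

import numpy as np
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .io_qc import AlignedRead, Cigar
from .trio import INDIVIDUALS, WesEvidence, WesSite
from .types import RegionSpec

_OP_TO_CODE = {"M": 0, "I": 1, "D": 2, "N": 3, "S": 4, "H": 5, "P": 6, "=": 7, "X": 8}
_CODE_TO_OP = {v: k for k, v in _OP_TO_CODE.items()}


def write_sam(path, reads: Iterable[AlignedRead], contig_lengths: Dict[str, int]) -> None:
    """Write reads as plain-text SAM with the given reference dictionary."""
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": name, "LN": int(length)} for name, length in contig_lengths.items()],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for read in reads:
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = read.read_id
            seg.query_sequence = read.seq
            seg.reference_name = read.contig
            seg.reference_start = read.start - 1
            seg.mapping_quality = 60
            seg.cigartuples = [(_OP_TO_CODE[op], n) for op, n in read.cigar]
            seg.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(min(int(q), 93) + 33) for q in read.quals)
            )
            flag = 0
            if read.is_secondary:
                flag |= 0x100
            if read.is_supplementary:
                flag |= 0x800
            seg.flag = flag
            out.write(seg)


def read_sam(path, include_secondary: bool = False) -> List[AlignedRead]:
    """Load mapped reads from SAM/BAM; secondary and supplementary
    alignments are excluded by default."""
    reads: List[AlignedRead] = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for seg in fh.fetch(until_eof=True):
            if seg.is_unmapped:
                continue
            if (seg.is_secondary or seg.is_supplementary) and not include_secondary:
                continue
            cigar: Cigar = [(_CODE_TO_OP[code], n) for code, n in (seg.cigartuples or [])]
            quals = (
                np.asarray(seg.query_qualities, dtype=np.int16)
                if seg.query_qualities is not None
                else np.zeros(0, dtype=np.int16)  # missing ("*")
            )
            reads.append(
                AlignedRead(
                    read_id=seg.query_name,
                    contig=seg.reference_name,
                    start=seg.reference_start + 1,
                    cigar=cigar,
                    seq=seg.query_sequence or "",
                    quals=quals,
                    is_secondary=seg.is_secondary,
                    is_supplementary=seg.is_supplementary,
                )
            )
    return reads


def write_region_fasta(path, region: RegionSpec) -> None:
    rec = SeqRecord(
        Seq(region.reference_seq),
        id=region.contig,
        description=f"region={region.contig}:{region.start}-{region.end}",
    )
    SeqIO.write([rec], str(path), "fasta")


def read_region_fasta(path) -> RegionSpec:
    rec = next(SeqIO.parse(str(path), "fasta"))
    m = re.search(r"region=(\S+):(\d+)-(\d+)", rec.description)
    if m:
        contig, start, end = m.group(1), int(m.group(2)), int(m.group(3))
    else:
        contig, start, end = rec.id, 1, len(rec.seq)
    return RegionSpec(contig=contig, start=start, end=end, reference_seq=str(rec.seq).upper())


def write_trio_vcf(path, wes: WesEvidence, contig: str, contig_length: int) -> None:
    """Write trio genotypes as a minimal VCF with GT and DP."""
    header = pysam.VariantHeader()
    header.add_line(f"##contig=<ID={contig},length={int(contig_length)}>")
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    for name in INDIVIDUALS:
        header.add_sample(name)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for pos in sorted(wes.sites):
            site = wes.sites[pos]
            alleles = [site.ref] + sorted(site.alleles() - {site.ref})
            index = {a: i for i, a in enumerate(alleles)}
            rec = out.new_record(
                contig=contig,
                start=pos - 1,
                stop=pos,
                alleles=tuple(alleles) if len(alleles) > 1 else (site.ref, "."),
            )
            for name in INDIVIDUALS:
                if name in site.genotypes:
                    gt = site.genotypes[name]
                    rec.samples[name]["GT"] = tuple(index[a] for a in gt)
                else:
                    rec.samples[name]["GT"] = (None, None)
                rec.samples[name]["DP"] = site.depth(name)
            out.write(rec)


def read_trio_vcf(path) -> WesEvidence:
    wes = WesEvidence()
    with pysam.VariantFile(str(path)) as fh:
        for rec in fh.fetch():
            alleles = [a for a in rec.alleles if a and a != "."]
            genotypes = {}
            depths = {}
            for name in rec.samples:
                sample = rec.samples[name]
                gt = sample.get("GT")
                if gt and None not in gt:
                    genotypes[name] = tuple(alleles[i] for i in gt)
                depths[name] = int(sample.get("DP") or 0)
            wes.add(
                WesSite(position=rec.pos, ref=rec.ref, genotypes=genotypes, depths=depths)
            )
    return wes
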