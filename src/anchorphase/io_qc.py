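"""Aligned-read container, read-level QC and region demultiplexing.

The pipeline's canonical in-memory read is :class:`AlignedRead`, a light
record carrying sequence, qualities and CIGAR against the region reference.
Base lookup at a reference position is resolved through the CIGAR and is
deterministic; positions inside deletions return the ``DELETED`` marker and
positions outside the aligned span (or under soft clips) return ``None``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, Iterator, List, Optional, Tuple

import numpy as np

from .types import DELETED, DNMRecord

logger = logging.getLogger(__name__)

Cigar = List[Tuple[str, int]]

_QUERY_OPS = set("MIS=X")
_REF_OPS = set("MD=X")


@dataclass
class AlignedRead:
    """One read aligned to a reference contig (1-based leftmost position)."""

    read_id: str
    contig: str
    start: int
    cigar: Cigar
    seq: str
    quals: np.ndarray
    is_secondary: bool = False
    is_supplementary: bool = False

    def __post_init__(self) -> None:
        self.quals = np.asarray(self.quals, dtype=np.int16)
        qlen = sum(n for op, n in self.cigar if op in _QUERY_OPS)
        # an empty quals array means qualities are missing (SAM "*")
        if qlen != len(self.seq) or (len(self.quals) and len(self.seq) != len(self.quals)):
            raise ValueError(
                f"{self.read_id}: CIGAR query length {qlen} != seq {len(self.seq)}"
                f" / quals {len(self.quals)}"
            )

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def reference_end(self) -> int:
        """Last reference position covered (1-based inclusive)."""
        return self.start + sum(n for op, n in self.cigar if op in _REF_OPS) - 1

    def _locate(self, pos: int) -> Optional[int]:
        """Query index aligned to reference ``pos``; -1 for deleted, None
        if not covered by a non-clipped alignment op."""
        if pos < self.start or pos > self.reference_end:
            return None
        ref = self.start
        q = 0
        for op, n in self.cigar:
            if op in "M=X":
                if ref <= pos < ref + n:
                    return q + (pos - ref)
                ref += n
                q += n
            elif op == "D":
                if ref <= pos < ref + n:
                    return -1
                ref += n
            elif op in "IS":
                q += n
        return None

    def base_at(self, pos: int) -> Optional[str]:
        """Base aligned at reference ``pos``: a base, ``DELETED`` or None."""
        idx = self._locate(pos)
        if idx is None:
            return None
        if idx < 0:
            return DELETED
        return self.seq[idx]

    def qual_at(self, pos: int) -> Optional[int]:
        idx = self._locate(pos)
        if idx is None or idx < 0 or len(self.quals) == 0:
            return None
        return int(self.quals[idx])

    def covers(self, pos: int) -> bool:
        """True iff ``pos`` is aligned to a non-clipped, non-deleted base."""
        idx = self._locate(pos)
        return idx is not None and idx >= 0

    def match_blocks(self) -> Iterator[Tuple[int, int, int]]:
        """Yield (ref_start, query_start, length) for each aligned M block."""
        ref, q = self.start, 0
        for op, n in self.cigar:
            if op in "M=X":
                yield ref, q, n
                ref += n
                q += n
            elif op == "D":
                ref += n
            elif op in "IS":
                q += n

    def deletion_blocks(self) -> Iterator[Tuple[int, int]]:
        """Yield (ref_start, length) for each deletion."""
        ref = self.start
        for op, n in self.cigar:
            if op in "M=X":
                ref += n
            elif op == "D":
                yield ref, n
                ref += n

    def insertion_positions(self) -> Iterator[int]:
        """Reference positions immediately following each insertion."""
        ref = self.start
        for op, n in self.cigar:
            if op in "M=X":
                ref += n
            elif op == "D":
                ref += n
            elif op == "I":
                yield ref


def _consume_query(cigar: Cigar, n: int) -> Tuple[Cigar, int]:
    """Remove ``n`` query bases from the left of ``cigar``.

    Returns the remaining CIGAR and the number of reference bases consumed
    (deletions flush at the cut boundary are dropped and consume reference).
    """
    out: Cigar = list(cigar)
    ref_consumed = 0
    while n > 0 and out:
        op, length = out[0]
        if op in "MIS=X":
            take = min(n, length)
            n -= take
            if op in "M=X":
                ref_consumed += take
            if take == length:
                out.pop(0)
            else:
                out[0] = (op, length - take)
        elif op == "D":
            ref_consumed += length
            out.pop(0)
        else:
            out.pop(0)
    # an alignment cannot start with a deletion
    while out and out[0][0] == "D":
        ref_consumed += out[0][1]
        out.pop(0)
    return out, ref_consumed


def trim_read(read: AlignedRead, n_left: int, n_right: int) -> AlignedRead:
    """Remove ``n_left``/``n_right`` query bases from the read ends,
    adjusting alignment start and CIGAR."""
    if n_left == 0 and n_right == 0:
        return read
    cigar, ref_off = _consume_query(read.cigar, n_left)
    # right trim: mirror the cigar
    rev = [(op, n) for op, n in reversed(cigar)]
    rev, _ = _consume_query(rev, n_right)
    cigar = [(op, n) for op, n in reversed(rev)]
    end = len(read.seq) - n_right
    return replace(
        read,
        start=read.start + ref_off,
        cigar=cigar,
        seq=read.seq[n_left:end],
        quals=read.quals[n_left:end],
    )


def qc_reads(
    reads: Iterable[AlignedRead],
    q_threshold: int = 10,
    min_len: int = 30,
    missing_quals: str = "pass",
) -> List[AlignedRead]:
    """End-trim low-quality bases and drop short reads.

    Bases are trimmed from both read ends while the terminal base quality is
    below ``q_threshold``; reads shorter than ``min_len`` after trimming are
    removed. Reads without quality values are passed through with a warning
    (``missing_quals='pass'``) or rejected (``'error'``).
    """
    kept: List[AlignedRead] = []
    n_in = n_trimmed = n_removed = 0
    for read in reads:
        n_in += 1
        if len(read.quals) == 0 and len(read.seq) > 0:
            if missing_quals == "error":
                raise ValueError(f"{read.read_id}: missing base qualities")
            logger.warning("read %s has no qualities; passed through", read.read_id)
            kept.append(read)
            continue
        q = read.quals
        left = 0
        while left < len(q) and q[left] < q_threshold:
            left += 1
        right = 0
        while right < len(q) - left and q[len(q) - 1 - right] < q_threshold:
            right += 1
        if left or right:
            n_trimmed += 1
            read = trim_read(read, left, right)
        if len(read) < min_len:
            n_removed += 1
            continue
        kept.append(read)
    logger.info(
        "qc_reads: %d in, %d end-trimmed, %d removed (<%d bp), %d kept",
        n_in, n_trimmed, n_removed, min_len, len(kept),
    )
    return kept


@dataclass(frozen=True)
class Target:
    """One pooled amplicon target: a sample, its region and its DNM."""

    sample_id: str
    contig: str
    start: int
    end: int
    dnm: DNMRecord

    def contains(self, contig: str, pos: int) -> bool:
        return contig == self.contig and self.start <= pos <= self.end


class OverlapError(ValueError):
    """Two targets in one pool overlap in genome coordinates."""


@dataclass
class TargetManifest:
    """Targets pooled on one flow cell; regions must not overlap."""

    targets: List[Target] = field(default_factory=list)

    def overlapping_pairs(self) -> List[Tuple[str, str]]:
        pairs = []
        for i, a in enumerate(self.targets):
            for b in self.targets[i + 1:]:
                if a.contig == b.contig and a.start <= b.end and b.start <= a.end:
                    pairs.append((a.sample_id, b.sample_id))
        return pairs

    def check(self) -> None:
        bad = self.overlapping_pairs()
        if bad:
            raise OverlapError(f"overlapping targets in pool: {bad}")

    @classmethod
    def from_tsv(cls, path) -> "TargetManifest":
        import pandas as pd

        df = pd.read_csv(path, sep="\t", dtype={"contig": str, "sample_id": str})
        targets = [
            Target(
                sample_id=row.sample_id,
                contig=row.contig,
                start=int(row.start),
                end=int(row.end),
                dnm=DNMRecord(row.contig, int(row.dnm_pos), row.ref, row.alt),
            )
            for row in df.itertuples()
        ]
        return cls(targets)

    def to_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            [
                {
                    "sample_id": t.sample_id,
                    "contig": t.contig,
                    "start": t.start,
                    "end": t.end,
                    "dnm_pos": t.dnm.position,
                    "ref": t.dnm.ref_base,
                    "alt": t.dnm.alt_base,
                }
                for t in self.targets
            ]
        ).to_csv(path, sep="\t", index=False)


UNASSIGNED = "unassigned"


def demultiplex_by_region(
    reads: Iterable[AlignedRead], manifest: TargetManifest
) -> Dict[str, List[AlignedRead]]:
    """Assign each pooled read to the unique target region containing its
    alignment start; reads matching no target land in ``'unassigned'``.

    Raises :class:`OverlapError` before any extraction if manifest regions
    overlap (assignment would be ambiguous).
    """
    manifest.check()
    bins: Dict[str, List[AlignedRead]] = {t.sample_id: [] for t in manifest.targets}
    bins[UNASSIGNED] = []
    for read in reads:
        for t in manifest.targets:
            if t.contains(read.contig, read.start):
                bins[t.sample_id].append(read)
                break
        else:
            bins[UNASSIGNED].append(read)
    logger.info(
        "demultiplex: %s",
        {k: len(v) for k, v in bins.items()},
    )
    return bins
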