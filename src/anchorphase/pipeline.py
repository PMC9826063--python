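"""End-to-end orchestration of anchored phasing for one target or a cohort.

The stages mirror the analysis workflow: read QC, pileup and filtered
variant calling anchored on the validated DNM, WES trio polishing and iSNP
discovery, optional parental long-read typing for intronic candidates,
DNM-split linkage vetting, iSNP selection, allele-table construction, and
finally zygosity / parent-of-origin interpretation.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import yaml

from .interpret import (
    PhasingResult,
    assign_parent_of_origin,
    classify_zygosity,
    compute_error_metrics,
    compute_frequencies,
    detect_third_allele,
)
from .io_qc import AlignedRead, qc_reads
from .phasing import (
    assign_support_category,
    build_allele_table,
    drop_unsupported_indels,
    find_linked_variants,
    select_isnp,
    split_reads_by_dnm,
)
from .trio import WesEvidence
from .types import DNMRecord, RegionSpec
from .variants import (
    ISNPCandidate,
    build_pileup,
    call_variants,
    classify_target,
    discover_ont_parental_isnps,
    discover_wes_isnps,
    wes_polish,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Every tunable threshold of the pipeline, with study defaults."""

    # read QC
    apply_qc: bool = False
    qc_quality_threshold: int = 10
    qc_min_length: int = 30
    # variant calling
    min_depth: int = 20
    af_window: Tuple[float, float] = (0.20, 0.80)
    min_confidence: float = 0.96
    # WES polishing / iSNP discovery
    wes_min_depth: int = 10
    min_parent_depth: int = 5
    isnp_window: int = 10_000
    short_read_span: int = 300
    trio_window: int = 5_000
    # parental long-read typing
    parental_support_af: float = 0.20
    parental_min_depth: int = 20
    # anchored phasing
    min_group_agreement: float = 0.90
    min_group_spanning: int = 10
    min_spanning_reads: int = 20
    # interpretation
    prezygotic_band: Tuple[float, float] = (0.40, 0.60)
    third_allele_floor: float = 0.05
    third_allele_k: float = 2.0
    min_parent_agreement: float = 0.90

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("af_window", "prezygotic_band"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        for key in ("af_window", "prezygotic_band"):
            data[key] = list(data[key])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def phase_target(
    target_id: str,
    reads: Sequence[AlignedRead],
    region: RegionSpec,
    dnm: DNMRecord,
    wes: Optional[WesEvidence] = None,
    parental_reads: Optional[Dict[str, Sequence[AlignedRead]]] = None,
    config: Optional[PipelineConfig] = None,
) -> PhasingResult:
    """Run anchored phasing for one target and interpret the outcome."""
    cfg = config or PipelineConfig()
    if cfg.apply_qc:
        reads = qc_reads(reads, cfg.qc_quality_threshold, cfg.qc_min_length)

    pileup = build_pileup(reads, region)
    calls = call_variants(
        pileup, dnm, min_depth=cfg.min_depth, af_window=cfg.af_window,
        min_conf=cfg.min_confidence,
    )
    het_calls = [c for c in calls if c.genotype == "het" and c.position != dnm.position]
    if wes is not None:
        het_calls = wes_polish(het_calls, wes, wes_min_depth=cfg.wes_min_depth)
        wes_isnps = discover_wes_isnps(
            wes, dnm, window_bp=cfg.isnp_window, min_parent_depth=cfg.min_parent_depth
        )
    else:
        wes_isnps = []
    category = classify_target(
        dnm, wes_isnps, short_read_span=cfg.short_read_span,
        long_window=cfg.isnp_window, trio_window=cfg.trio_window,
    )

    tertiary_by_pos: Dict[int, ISNPCandidate] = {}
    if parental_reads:
        father_pileup = build_pileup(parental_reads["father"], region)
        mother_pileup = build_pileup(parental_reads["mother"], region)
        for cand in discover_ont_parental_isnps(
            father_pileup, mother_pileup, het_calls, dnm,
            window_bp=cfg.trio_window,
            parental_support_af=cfg.parental_support_af,
            min_parent_depth=cfg.parental_min_depth,
        ):
            tertiary_by_pos[cand.position] = cand
    het_calls = drop_unsupported_indels(het_calls, set(tertiary_by_pos))

    groups = split_reads_by_dnm(reads, dnm)
    raw_base = groups.raw_base_fraction()
    linked = find_linked_variants(
        groups, het_calls,
        min_group_agreement=cfg.min_group_agreement,
        min_group_spanning=cfg.min_group_spanning,
    )

    wes_by_pos = {c.position: c for c in wes_isnps}
    candidates: List[ISNPCandidate] = []
    for call, info in linked:
        if call.is_indel:
            continue  # the phasing marker must be a SNP
        attribution = wes_by_pos.get(call.position) or tertiary_by_pos.get(call.position)
        if attribution is None:
            continue  # no parental attribution: unusable for parent-of-origin
        cand = ISNPCandidate(
            position=call.position,
            ref_base=call.ref_base,
            alt=call.alt,
            paternal_base=attribution.paternal_base,
            maternal_base=attribution.maternal_base,
            distance=call.position - dnm.position,
            call=call,
            agreement=info.agreement,
            alt_agreement=info.alt_agreement,
            linked_alt_base=info.linked_alt_base,
            linked_ref_base=info.linked_ref_base,
            spanning=info.spanning,
            discordant=info.discordant,
            insufficient=info.insufficient,
        )
        cand.support_category = assign_support_category(
            cand, wes, set(tertiary_by_pos),
            wes_min_depth=cfg.wes_min_depth, min_parent_depth=cfg.min_parent_depth,
        )
        candidates.append(cand)

    chosen = select_isnp(candidates)
    if chosen is None:
        return PhasingResult(
            target_id=target_id, category=category, phased=False,
            raw_base_fraction=raw_base, unphased_reason="no usable iSNP candidate",
        )

    table = build_allele_table(reads, dnm, chosen)
    if table.total < cfg.min_spanning_reads:
        return PhasingResult(
            target_id=target_id, category=category, phased=False,
            raw_base_fraction=raw_base, spanning_reads=table.total,
            unphased_reason=(
                f"only {table.total} reads span DNM and iSNP "
                f"(< {cfg.min_spanning_reads})"
            ),
        )

    metrics = compute_error_metrics(
        table, dnm, chosen, isnp_column=pileup.column(chosen.position)
    )
    third = detect_third_allele(
        table, dnm, chosen, metrics, floor=cfg.third_allele_floor, k=cfg.third_allele_k
    )
    freqs = compute_frequencies(table, dnm, chosen, third_credible=third.credible)

    wes_dnm_info = None
    if wes is not None:
        site = wes.site(dnm.position)
        if site is not None and site.depth("proband") > 0:
            wes_dnm_info = (
                site.depth("proband"),
                site.alt_fractions.get("proband", 0.0),
            )
    zyg = classify_zygosity(
        wes_dnm_info, (groups.n_covering, raw_base), freqs.polished_allele,
        third, metrics, band=cfg.prezygotic_band,
    )
    parent = assign_parent_of_origin(chosen, min_agreement=cfg.min_parent_agreement)

    return PhasingResult(
        target_id=target_id,
        category=category,
        phased=True,
        parent_of_origin=parent,
        zygosity=zyg.zygosity,
        ambiguous=zyg.ambiguous,
        raw_base_fraction=raw_base,
        raw_allele_fraction=freqs.raw_allele,
        polished_allele_fraction=freqs.polished_allele,
        third_allele_fraction=third.fraction,
        third_allele_credible=third.credible,
        metrics=metrics,
        chosen_isnp_position=chosen.position,
        chosen_isnp_category=chosen.support_category,
        chosen_isnp_agreement=chosen.agreement,
        spanning_reads=table.total,
        flags=zyg.flags,
    )
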