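"""End-to-end caller: alignments in, genotyped ME variant VCF out."""

from __future__ import annotations

import logging
from typing import Optional

import pysam

from mehunter.classify import classify_consensus, make_second_round_classifier
from mehunter.clustering import build_consensus, cluster_signatures
from mehunter.config import CallerConfig
from mehunter.genotype import MEVCall, count_reference_spanning, genotype, write_vcf
from mehunter.melib import MELibrary
from mehunter.signatures import scan_alignments

logger = logging.getLogger(__name__)


def run_caller(
    bam_path: str,
    ref_path: str,
    lib: MELibrary,
    cfg: CallerConfig,
    region: Optional[str] = None,
) -> tuple[list[MEVCall], dict]:
    """Run the full pipeline and return genotyped calls plus run stats.

    Stages: signature extraction, per-locus clustering, consensus building,
    two-round ME classification, AF-band genotyping.  Clusters that fail
    classification or genotype as sub-threshold are dropped.
    """
    signatures, span_index, stats = scan_alignments(bam_path, cfg, region=region)
    clusters = cluster_signatures(signatures, cfg)
    stats["clusters"] = len(clusters)
    model = None
    if cfg.second_round_enabled:
        model = make_second_round_classifier(cfg.second_round_plugin, lib, cfg)
    calls: list[MEVCall] = []
    with pysam.FastaFile(ref_path) as reference:
        for cluster in clusters:
            try:
                consensus = build_consensus(cluster, reference, cfg)
            except ValueError as exc:
                logger.warning("skipping cluster at %s:%d: %s", cluster.chrom, cluster.anchor_pos, exc)
                continue
            if consensus.consensus_length < cfg.min_signature_size:
                continue
            classification = classify_consensus(consensus, lib, cfg, model=model)
            if classification.me_class == "none":
                continue
            dv = cluster.support
            dr = count_reference_spanning(
                cluster.chrom,
                cluster.anchor_pos,
                span_index,
                cfg.spanning_flank,
                exclude=cluster.read_names,
            )
            gt = genotype(dv, dr, cfg)
            if gt is None:
                continue
            svlen = consensus.consensus_length if cluster.svtype == "INS" else -cluster.median_length
            calls.append(
                MEVCall(
                    chrom=cluster.chrom,
                    pos=cluster.anchor_pos,  # 1-based anchor == 0-based event start
                    svtype=cluster.svtype,
                    svlen=svlen,
                    me_class=classification.me_class,
                    gt=gt,
                    dv=dv,
                    dr=dr,
                    consensus_sequence=consensus.consensus_sequence,
                    classification_round=classification.round,
                )
            )
    calls.sort(key=lambda c: (c.chrom, c.pos, c.svtype))
    stats["calls"] = len(calls)
    logger.info("emitted %d calls from %d clusters", len(calls), len(clusters))
    return calls, stats


def call_to_vcf(
    bam_path: str,
    ref_path: str,
    lib: MELibrary,
    cfg: CallerConfig,
    out_path: str,
    region: Optional[str] = None,
    sample: str = "SAMPLE",
    explicit_del_alleles: bool = False,
    fixed_header_date: Optional[str] = None,
) -> dict:
    """Run the caller and write the VCF; returns run stats."""
    calls, stats = run_caller(bam_path, ref_path, lib, cfg, region=region)
    with pysam.FastaFile(ref_path) as reference:
        write_vcf(
            calls,
            reference,
            out_path,
            sample=sample,
            explicit_del_alleles=explicit_del_alleles,
            fixed_header_date=fixed_header_date,
        )
    return stats
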