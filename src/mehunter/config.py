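"""Caller configuration shared by every pipeline stage."""

from __future__ import annotations

from dataclasses import dataclass, field, fields


@dataclass
class CallerConfig:
    """Tunable parameters of the calling pipeline.

    Attributes
    ----------
    min_support : int
        Minimum number of distinct supporting reads for a call (the ``-s``
        command-line parameter).
    min_signature_size : int
        Smallest insertion/deletion signature (bp) harvested from alignments.
    min_mapq : int
        Alignments below this mapping quality are ignored.
    cluster_max_distance : int
        Maximum position gap (bp) when chaining signatures into a cluster.
    cluster_size_ratio : float
        Minimum min/max length ratio between a signature and the cluster's
        running median length for the signature to join.
    het_af_low, hom_af_high : float
        Allele-frequency bands for genotyping: ``af < het_af_low`` is
        filtered, ``af > hom_af_high`` is called 1/1, in between 0/1.
    sw_match, sw_mismatch, sw_gap_open, sw_gap_extend : int
        Local-alignment scoring; a gap of length L costs
        ``sw_gap_open + L * sw_gap_extend``.
    first_round_identity_threshold : float
        Minimum alignment identity for a first-round class assignment.
    first_round_coverage : float
        Minimum fraction of the template covered by the alignment for a
        first-round assignment; fragmentary matches fall through to the
        second round.
    prescreen_k, prescreen_min_fraction : int, float
        k-mer prescreen ahead of the second round: a consensus passes when at
        least ``prescreen_min_fraction`` of its distinct k-mers are shared
        with some template on either strand.
    second_round_enabled : bool
        Toggle for the second classification round (the ablation mode runs
        with this off).
    second_round_plugin : str
        Registered name of the second-round classifier plugin.
    spanning_flank : int
        Reference flank (bp) a read must span on both sides of a locus to be
        counted as reference-supporting.
    max_consensus_reads : int
        Cap on cluster members fed to the consensus builder.
    """

    min_support: int = 3
    min_signature_size: int = 30
    min_mapq: int = 20
    cluster_max_distance: int = 1000
    cluster_size_ratio: float = 0.7
    het_af_low: float = 0.2
    hom_af_high: float = 0.8
    sw_match: int = 2
    sw_mismatch: int = -4
    sw_gap_open: int = -4
    sw_gap_extend: int = -2
    first_round_identity_threshold: float = 0.7
    first_round_coverage: float = 0.5
    prescreen_k: int = 11
    prescreen_min_fraction: float = 0.2
    second_round_enabled: bool = True
    second_round_plugin: str = "kmer_profile"
    trim_polya: bool = False
    spanning_flank: int = 200
    max_consensus_reads: int = 15
    consensus_backend: str = "simple"
    seed: int = 42

    def __post_init__(self) -> None:
        if self.min_support < 1:
            raise ValueError("min_support must be >= 1")
        if not (0.0 < self.het_af_low < self.hom_af_high < 1.0):
            raise ValueError("require 0 < het_af_low < hom_af_high < 1")
        if self.prescreen_k < 4:
            raise ValueError("prescreen_k must be >= 4")
        if not (0.0 < self.cluster_size_ratio <= 1.0):
            raise ValueError("cluster_size_ratio must be in (0, 1]")
        if self.min_signature_size < 1:
            raise ValueError("min_signature_size must be >= 1")

    def replace(self, **kwargs) -> "CallerConfig":
        """Return a copy with the given fields overridden."""
        current = {f.name: getattr(self, f.name) for f in fields(self)}
        current.update(kwargs)
        return CallerConfig(**current)
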