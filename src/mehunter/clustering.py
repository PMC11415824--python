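"""Group signatures into per-locus clusters and build consensus sequences.

Clustering is single-linkage chaining over position-sorted signatures with a
size-ratio gate against the cluster's running median length.  Consensus for
insertion clusters comes from an interchangeable multiple-alignment backend
(a bundled star-alignment + column-majority implementation by default, an
abPOA binding when the optional dependency is present); deletion clusters
take the reference sequence of the deleted interval.
"""

from __future__ import annotations

import statistics
from collections import Counter
from dataclasses import dataclass
from typing import Callable, Protocol, Sequence

from Bio import Align

from mehunter.config import CallerConfig
from mehunter.signatures import Signature


@dataclass
class Cluster:
    """Signatures of one putative variant locus."""

    chrom: str
    svtype: str
    members: list[Signature]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("cluster must have at least one member")
        if any(m.chrom != self.chrom or m.svtype != self.svtype for m in self.members):
            raise ValueError("cluster members must share chrom and svtype")

    @property
    def anchor_pos(self) -> int:
        return int(statistics.median_low(sorted(m.pos for m in self.members)))

    @property
    def median_length(self) -> int:
        return int(statistics.median_low(sorted(m.length for m in self.members)))

    @property
    def support(self) -> int:
        return len({m.read_name for m in self.members})

    @property
    def read_names(self) -> set[str]:
        return {m.read_name for m in self.members}


@dataclass
class ConsensusCall:
    """A cluster together with its consensus sequence."""

    cluster: Cluster
    consensus_sequence: str

    def __post_init__(self) -> None:
        if not self.consensus_sequence:
            raise ValueError("consensus sequence must be non-empty")

    @property
    def consensus_length(self) -> int:
        return len(self.consensus_sequence)


class _OpenCluster:
    __slots__ = ("members", "last_pos", "lengths")

    def __init__(self, sig: Signature) -> None:
        self.members = [sig]
        self.last_pos = sig.pos
        self.lengths = [sig.length]

    def running_median(self) -> float:
        return statistics.median(self.lengths)

    def add(self, sig: Signature) -> None:
        self.members.append(sig)
        self.last_pos = sig.pos
        self.lengths.append(sig.length)


def cluster_signatures(signatures: Sequence[Signature], cfg: CallerConfig) -> list[Cluster]:
    """Chain signatures into clusters; drop clusters below ``min_support``.

    Signatures join an open cluster of the same svtype when the position gap
    to the cluster's last member is within ``cluster_max_distance`` and the
    min/max ratio of the signature length versus the cluster's running median
    length is at least ``cluster_size_ratio``.  Several clusters may be open
    at once, so co-located events of very different size separate cleanly.
    Input order does not matter: signatures are sorted internally.
    """
    ordered = sorted(signatures, key=lambda s: (s.chrom, s.pos, s.length, s.read_name, s.source))
    finished: list[_OpenCluster] = []
    open_by_type: dict[tuple[str, str], list[_OpenCluster]] = {}
    for sig in ordered:
        key = (sig.chrom, sig.svtype)
        open_clusters = open_by_type.setdefault(key, [])
        still_open = []
        for oc in open_clusters:
            if sig.pos - oc.last_pos > cfg.cluster_max_distance:
                finished.append(oc)
            else:
                still_open.append(oc)
        open_clusters[:] = still_open
        best = None
        best_ratio = -1.0
        for oc in open_clusters:
            med = oc.running_median()
            ratio = min(sig.length, med) / max(sig.length, med)
            if ratio >= cfg.cluster_size_ratio and ratio > best_ratio:
                best, best_ratio = oc, ratio
        if best is None:
            open_clusters.append(_OpenCluster(sig))
        else:
            best.add(sig)
    for open_clusters in open_by_type.values():
        finished.extend(open_clusters)
    clusters = [
        Cluster(oc.members[0].chrom, oc.members[0].svtype, oc.members)
        for oc in finished
    ]
    clusters.sort(key=lambda c: (c.chrom, c.anchor_pos, c.svtype))
    return [c for c in clusters if c.support >= cfg.min_support]


def clusters_to_tsv(clusters: Sequence[Cluster], out_path: str) -> None:
    """Debug dump: clusters as BED-like TSV."""
    with open(out_path, "w") as handle:
        handle.write("#chrom\tstart\tsvtype\tsupport\tmedian_length\n")
        for cluster in clusters:
            handle.write(
                f"{cluster.chrom}\t{cluster.anchor_pos}\t{cluster.svtype}\t"
                f"{cluster.support}\t{cluster.median_length}\n"
            )


class ConsensusBackend(Protocol):
    def __call__(self, sequences: Sequence[str]) -> str: ...


def _star_msa_consensus(sequences: Sequence[str]) -> str:
    """Star alignment to a centre sequence + column majority vote.

    The centre is the member of median length (ties broken lexicographically
    so runs are reproducible).  Majority ties at a column follow alphabetical
    base order A<C<G<T; a gap majority drops the column.  Insertions relative
    to the centre are kept when more than half the members carry one at that
    junction, taking the most common inserted string.
    """
    seqs = list(sequences)
    if len(seqs) == 1:
        return seqs[0]
    if len(set(seqs)) == 1:
        return seqs[0]
    centre = sorted(seqs, key=lambda s: (abs(len(s) - statistics.median(map(len, seqs))), s))[0]
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2
    aligner.mismatch_score = -4
    aligner.open_gap_score = -4
    aligner.extend_gap_score = -2
    # free end gaps: members may be ragged at the edges
    try:
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
    except AttributeError:  # older Biopython naming
        aligner.target_end_gap_score = 0.0
        aligner.query_end_gap_score = 0.0

    n = len(centre)
    columns: list[Counter] = [Counter() for _ in range(n)]
    inserts: list[Counter] = [Counter() for _ in range(n + 1)]
    for seq in seqs:
        if len(seq) == n:
            # same length as the centre: columnwise vote without alignment
            # (at long-read error rates a same-length member has no indels)
            for i, base in enumerate(seq):
                columns[i][base] += 1
            continue
        aln = aligner.align(centre, seq)[0]
        tblocks, qblocks = aln.aligned
        prev_t = prev_q = 0
        for (ts, te), (qs, qe) in zip(tblocks, qblocks):
            if ts > prev_t:  # deletion in member relative to centre
                for i in range(prev_t, ts):
                    columns[i]["-"] += 1
            if qs > prev_q and prev_t > 0 and ts < n + 1:  # internal insertion
                inserts[ts][seq[prev_q:qs]] += 1
            for i in range(ts, te):
                columns[i][seq[qs + (i - ts)]] += 1
            prev_t, prev_q = te, qe
        # trailing centre positions not covered: count as end gaps (ignored)
    out: list[str] = []
    half = len(seqs) / 2.0
    for i in range(n):
        col = columns[i]
        ins = inserts[i]
        if ins and sum(ins.values()) > half:
            out.append(sorted(ins.items(), key=lambda kv: (-kv[1], kv[0]))[0][0])
        if not col:
            out.append(centre[i])
            continue
        base, count = sorted(col.items(), key=lambda kv: (-kv[1], kv[0]))[0]
        if base != "-":
            out.append(base)
    if inserts[n] and sum(inserts[n].values()) > half:
        out.append(sorted(inserts[n].items(), key=lambda kv: (-kv[1], kv[0]))[0][0])
    return "".join(out)


def _abpoa_consensus(sequences: Sequence[str]) -> str:
    """Partial-order-alignment consensus via pyabpoa, when installed."""
    import pyabpoa  # optional dependency

    if len(sequences) == 1 or len(set(sequences)) == 1:
        return sequences[0]
    aligner = pyabpoa.msa_aligner()
    result = aligner.msa(list(sequences), out_cons=True, out_msa=False)
    return result.cons_seq[0]


CONSENSUS_BACKENDS: dict[str, ConsensusBackend] = {
    "simple": _star_msa_consensus,
    "abpoa": _abpoa_consensus,
}


class ReferenceAccessor(Protocol):
    """Anything exposing ``fetch(chrom, start, end) -> str`` (e.g. pysam.FastaFile)."""

    def fetch(self, chrom: str, start: int, end: int) -> str: ...


def build_consensus(
    cluster: Cluster,
    reference: ReferenceAccessor,
    cfg: CallerConfig,
) -> ConsensusCall:
    """Consensus sequence for one cluster.

    INS: consensus of member inserted sequences through the configured
    backend (members are capped at ``max_consensus_reads``, preferring
    lengths closest to the cluster median).  DEL: the reference sequence of
    the deleted interval ``[anchor_pos, anchor_pos + median_length)``.
    """
    if cluster.svtype == "DEL":
        start = cluster.anchor_pos
        end = start + cluster.median_length
        seq = reference.fetch(cluster.chrom, start, end).upper()
        if len(seq) != cluster.median_length or start < 0:
            raise ValueError(
                f"DEL cluster {cluster.chrom}:{start}-{end} lies outside the reference"
            )
        return ConsensusCall(cluster, seq)
    seqs = sorted(
        (m.inserted_sequence for m in cluster.members if m.inserted_sequence),
        key=lambda s: (abs(len(s) - cluster.median_length), s),
    )
    if not seqs:
        raise ValueError("INS cluster has no member with an inserted sequence")
    seqs = seqs[: cfg.max_consensus_reads]
    backend = CONSENSUS_BACKENDS[cfg.consensus_backend]
    return ConsensusCall(cluster, backend(sorted(seqs)))
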