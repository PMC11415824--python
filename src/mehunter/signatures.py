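"""Harvest insertion/deletion signatures from long-read alignments.

Two channels, in the style of cuteSV: intra-alignment CIGAR gaps (``I``/``D``
operations at or above the minimum signature size) and inter-segment gaps of
split reads reconstructed from ``SA`` tags.  A spanning-read index is built
alongside for later genotyping.
"""

from __future__ import annotations

import logging
import re
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pysam

from mehunter.config import CallerConfig

logger = logging.getLogger(__name__)

# CIGAR op codes as in the SAM spec / pysam
_OP_M, _OP_I, _OP_D, _OP_N, _OP_S, _OP_H, _OP_P, _OP_EQ, _OP_X = range(9)
_QUERY_OPS = {_OP_M, _OP_I, _OP_S, _OP_EQ, _OP_X}
_REF_OPS = {_OP_M, _OP_D, _OP_N, _OP_EQ, _OP_X}

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")
_OP_CODE = {"M": _OP_M, "I": _OP_I, "D": _OP_D, "N": _OP_N, "S": _OP_S,
            "H": _OP_H, "P": _OP_P, "=": _OP_EQ, "X": _OP_X}


class UnsortedInputError(RuntimeError):
    """Raised when the alignment input is not coordinate-sorted."""


@dataclass(frozen=True)
class Signature:
    """One putative INS/DEL event observed on one read."""

    chrom: str
    pos: int  # 0-based reference coordinate
    svtype: str  # "INS" | "DEL"
    length: int
    inserted_sequence: str  # empty for DEL
    read_name: str
    source: str  # "cigar" | "split"

    def __post_init__(self) -> None:
        if self.svtype == "INS" and self.inserted_sequence and len(self.inserted_sequence) != self.length:
            raise ValueError("INS signature length must match inserted sequence")
        if self.svtype == "DEL" and self.inserted_sequence:
            raise ValueError("DEL signature carries no inserted sequence")


@dataclass(frozen=True)
class SAPlacement:
    """One supplementary placement parsed from an SA tag."""

    chrom: str
    pos: int  # 0-based
    strand: str
    cigar: tuple[tuple[int, int], ...]


@dataclass
class AlignmentView:
    """Aligner-independent view of one alignment record."""

    read_name: str
    chrom: str
    ref_start: int
    cigar: tuple[tuple[int, int], ...]
    read_sequence: Optional[str]
    mapq: int
    is_supplementary: bool = False
    is_secondary: bool = False
    strand: str = "+"
    sa_tags: tuple[SAPlacement, ...] = ()

    @property
    def ref_end(self) -> int:
        return self.ref_start + sum(n for op, n in self.cigar if op in _REF_OPS)

    def query_length(self, with_hard_clips: bool = False) -> int:
        ops = _QUERY_OPS | {_OP_H} if with_hard_clips else _QUERY_OPS
        return sum(n for op, n in self.cigar if op in ops)


def parse_cigar_string(cigar: str) -> tuple[tuple[int, int], ...]:
    return tuple((_OP_CODE[op], int(n)) for n, op in _CIGAR_RE.findall(cigar))


def view_from_pysam(aln: pysam.AlignedSegment) -> AlignmentView:
    """Build an AlignmentView from a pysam record (must be mapped)."""
    sa_tags = []
    if aln.has_tag("SA"):
        for entry in aln.get_tag("SA").rstrip(";").split(";"):
            chrom, pos, strand, cigar, _mapq, _nm = entry.split(",")
            sa_tags.append(SAPlacement(chrom, int(pos) - 1, strand, parse_cigar_string(cigar)))
    seq = aln.query_sequence
    return AlignmentView(
        read_name=aln.query_name,
        chrom=aln.reference_name,
        ref_start=aln.reference_start,
        cigar=tuple(aln.cigartuples or ()),
        read_sequence=seq,
        mapq=aln.mapping_quality,
        is_supplementary=aln.is_supplementary,
        is_secondary=aln.is_secondary,
        strand="-" if aln.is_reverse else "+",
        sa_tags=tuple(sa_tags),
    )


def extract_cigar_signatures(aln: AlignmentView, cfg: CallerConfig) -> list[Signature]:
    """Signatures from I/D CIGAR operations of one alignment.

    An ``I`` of length >= ``min_signature_size`` yields an INS anchored at
    the reference coordinate preceding the insertion point, carrying the
    inserted read bases; a ``D`` yields a DEL at the deleted interval start.
    """
    out: list[Signature] = []
    ref = aln.ref_start
    query = 0
    for op, length in aln.cigar:
        if op == _OP_I:
            if length >= cfg.min_signature_size:
                inserted = ""
                if aln.read_sequence is not None:
                    inserted = aln.read_sequence[query : query + length]
                out.append(Signature(aln.chrom, ref, "INS", length, inserted, aln.read_name, "cigar"))
            query += length
        elif op in (_OP_D, _OP_N):
            if op == _OP_D and length >= cfg.min_signature_size:
                out.append(Signature(aln.chrom, ref, "DEL", length, "", aln.read_name, "cigar"))
            ref += length
        elif op in (_OP_M, _OP_EQ, _OP_X):
            ref += length
            query += length
        elif op == _OP_S:
            query += length
        # H and P consume neither sequence nor reference here
    return out


@dataclass(frozen=True)
class _Segment:
    ref_start: int
    ref_end: int
    query_start: int  # original-read orientation, hard clips included
    query_end: int
    strand: str


def _segment_from_cigar(ref_start: int, strand: str, cigar: tuple[tuple[int, int], ...]) -> _Segment:
    """Segment coordinates in original-read orientation from one placement."""
    left_clip = 0
    for op, n in cigar:
        if op in (_OP_S, _OP_H):
            left_clip += n
        else:
            break
    right_clip = 0
    for op, n in reversed(cigar):
        if op in (_OP_S, _OP_H):
            right_clip += n
        else:
            break
    aligned = sum(n for op, n in cigar if op in (_OP_M, _OP_I, _OP_EQ, _OP_X))
    total = left_clip + aligned + right_clip
    ref_len = sum(n for op, n in cigar if op in _REF_OPS)
    if strand == "+":
        qs = left_clip
    else:
        qs = right_clip
    return _Segment(ref_start, ref_start + ref_len, qs, qs + aligned, strand)


def extract_split_signatures(primary: AlignmentView, cfg: CallerConfig) -> list[Signature]:
    """Signatures from gaps between split-read segments of one primary.

    Adjacent same-chromosome, same-strand segments ordered by query offset
    yield an INS when the query gap exceeds the reference gap by at least
    ``min_signature_size`` and a DEL in the opposite case.  Cross-chromosome
    or cross-strand pairs are skipped (translocations/inversions are out of
    scope).
    """
    if not primary.sa_tags:
        return []
    segments = [_segment_from_cigar(primary.ref_start, primary.strand, primary.cigar)]
    for sa in primary.sa_tags:
        if sa.chrom != primary.chrom:
            continue
        segments.append(_segment_from_cigar(sa.pos, sa.strand, sa.cigar))
    segments.sort(key=lambda s: (s.query_start, s.ref_start))
    out: list[Signature] = []
    seq = primary.read_sequence
    read_len = primary.query_length(with_hard_clips=True)
    for prev, nxt in zip(segments, segments[1:]):
        if prev.strand != nxt.strand:
            continue
        # On '-', segments ascending in original-read order descend along
        # the reference, so the roles of the two segments swap.
        if prev.strand == "+":
            gap_ref = nxt.ref_start - prev.ref_end
            anchor = prev.ref_end
        else:
            gap_ref = prev.ref_start - nxt.ref_end
            anchor = nxt.ref_end
        gap_query = nxt.query_start - prev.query_end
        net = gap_query - gap_ref
        if net >= cfg.min_signature_size:
            inserted = ""
            if seq is not None and len(seq) == read_len:
                if prev.strand == "+":
                    inserted = seq[prev.query_end : prev.query_end + net]
                else:
                    # SEQ is reference-oriented: original-read offset o maps
                    # to SEQ position read_len - o
                    inserted = seq[read_len - prev.query_end - net : read_len - prev.query_end]
            if inserted and len(inserted) != net:
                inserted = ""
            out.append(
                Signature(primary.chrom, anchor, "INS", net, inserted, primary.read_name, "split")
            )
        elif -net >= cfg.min_signature_size:
            out.append(
                Signature(primary.chrom, anchor, "DEL", -net, "", primary.read_name, "split")
            )
    return out


class SpanIndex:
    """Per-chromosome index of primary-alignment reference spans.

    Used at genotyping time to count reads spanning a locus that did not
    support the variant cluster.
    """

    def __init__(self) -> None:
        self._spans: dict[str, list[tuple[int, int, str]]] = {}
        self._sorted: dict[str, tuple[list[int], list[tuple[int, int, str]]]] = {}

    def add(self, chrom: str, start: int, end: int, read_name: str) -> None:
        self._spans.setdefault(chrom, []).append((start, end, read_name))
        self._sorted.pop(chrom, None)

    def __len__(self) -> int:
        return sum(len(v) for v in self._spans.values())

    def _prepared(self, chrom: str):
        if chrom not in self._sorted:
            spans = sorted(self._spans.get(chrom, ()))
            self._sorted[chrom] = ([s for s, _, _ in spans], spans)
        return self._sorted[chrom]

    def spanning_reads(self, chrom: str, pos: int, flank: int) -> list[str]:
        """Names of reads whose span covers [pos - flank, pos + flank]."""
        starts, spans = self._prepared(chrom)
        lo, hi = pos - flank, pos + flank
        cutoff = bisect_right(starts, lo)
        return [name for start, end, name in spans[:cutoff] if end >= hi]

    def count_spanning(self, chrom: str, pos: int, flank: int, exclude: Iterable[str] = ()) -> int:
        excluded = set(exclude)
        return sum(1 for name in self.spanning_reads(chrom, pos, flank) if name not in excluded)


def _region_filter(region: Optional[str]):
    if region is None:
        return None
    m = re.fullmatch(r"([^:]+)(?::(\d+)-(\d+))?", region)
    if not m:
        raise ValueError(f"malformed region {region!r}; expected chrom or chrom:start-end")
    chrom = m.group(1)
    start = int(m.group(2)) - 1 if m.group(2) else 0
    end = int(m.group(3)) if m.group(3) else None
    return chrom, start, end


def scan_alignments(
    bam_path: str,
    cfg: CallerConfig,
    region: Optional[str] = None,
) -> tuple[list[Signature], SpanIndex, dict]:
    """Scan a coordinate-sorted SAM/BAM and collect all signatures.

    Returns the concatenated CIGAR + split signatures of all passing primary
    alignments, a :class:`SpanIndex` of their reference spans, and a stats
    dict (per-chromosome signature counts plus a skipped-read tally).

    Raises
    ------
    UnsortedInputError
        If records are observed out of coordinate order.
    """
    filt = _region_filter(region)
    signatures: list[Signature] = []
    index = SpanIndex()
    stats = {"reads_used": 0, "reads_skipped": 0, "per_chrom": {}}
    last_seen: dict[str, int] = {}
    mode = "rb" if str(bam_path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(bam_path), mode, check_sq=False) as af:
        so = (af.header.to_dict().get("HD") or {}).get("SO")
        if so is not None and so != "coordinate":
            raise UnsortedInputError(
                f"{bam_path} is not coordinate-sorted (SO:{so}); sort it first"
            )
        for rec in af.fetch(until_eof=True):
            if rec.is_unmapped:
                continue
            chrom = rec.reference_name
            if rec.reference_start < last_seen.get(chrom, -1):
                raise UnsortedInputError(
                    f"{bam_path} is not coordinate-sorted at {chrom}:{rec.reference_start}; "
                    "coordinate-sorted input is required"
                )
            last_seen[chrom] = rec.reference_start
            if rec.is_secondary or rec.is_supplementary:
                continue
            if rec.mapping_quality < cfg.min_mapq:
                stats["reads_skipped"] += 1
                continue
            if filt is not None:
                fchrom, fstart, fend = filt
                if chrom != fchrom:
                    continue
                if fend is not None and (rec.reference_end <= fstart or rec.reference_start >= fend):
                    continue
            view = view_from_pysam(rec)
            if view.read_sequence is not None and view.query_length() != len(view.read_sequence):
                logger.warning(
                    "read %s: CIGAR query length %d != sequence length %d; skipped",
                    view.read_name, view.query_length(), len(view.read_sequence),
                )
                stats["reads_skipped"] += 1
                continue
            sigs = extract_cigar_signatures(view, cfg)
            sigs.extend(extract_split_signatures(view, cfg))
            if filt is not None and filt[2] is not None:
                sigs = [s for s in sigs if filt[1] <= s.pos < filt[2]]
            signatures.extend(sigs)
            index.add(view.chrom, view.ref_start, view.ref_end, view.read_name)
            stats["reads_used"] += 1
            stats["per_chrom"][chrom] = stats["per_chrom"].get(chrom, 0) + len(sigs)
    signatures.sort(key=lambda s: (s.chrom, s.pos, s.svtype, s.length, s.read_name, s.source))
    for chrom, count in sorted(stats["per_chrom"].items()):
        logger.info("%s: %d signatures", chrom, count)
    logger.info("reads used: %d, skipped: %d", stats["reads_used"], stats["reads_skipped"])
    return signatures, index, stats
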