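"""Diploid genome and long-read simulator with analytically derived alignments.

Builds a random reference with implanted mobile-element insertions/deletions
and ordinary SVs, samples reads from the two haplotypes under a HiFi-like or
ONT-like error model, and projects each read back onto the reference through
the known haplotype coordinate map, so alignments (SAM), reads (FASTQ), and
the truth VCF are produced directly — no external aligner, fully
deterministic for a given seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pysam

from mehunter.melib import MELibrary

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_OP_M, _OP_I, _OP_D, _OP_S = 0, 1, 2, 4
_OP_CHR = {_OP_M: "M", _OP_I: "I", _OP_D: "D", _OP_S: "S"}

ERROR_MODELS = {
    "hifi_like": (0.002, 0.0005),
    "ont_like": (0.02, 0.02),
}


@dataclass
class SimParams:
    """Knobs of one simulation run.

    ``depth`` is the target fold-coverage of each haplotype, so the nominal
    sample coverage at a diploid locus is twice that of a single haplotype.
    ``substitution_rate``/``indel_rate`` default to the chosen error model's
    rates when left as None.
    """

    genome_length: int = 1_000_000
    n_mei_per_class: int = 30
    n_med_per_class: int = 30
    n_ordinary_sv: int = 60
    het_fraction: float = 0.5
    depth: float = 30.0
    read_length_mean: int = 8000
    read_length_sd: int = 1500
    error_model: str = "hifi_like"
    substitution_rate: Optional[float] = None
    indel_rate: Optional[float] = None
    l1_truncation: bool = False
    truncate_fraction: float = 0.0
    truncate_low: float = 0.35
    truncate_high: float = 0.5
    polyA_mean: int = 30
    divergence: float = 0.02
    min_event_spacing: int = 2000
    split_del_threshold: int = 1000
    chrom: str = "simchr1"
    seed: int = 42

    def __post_init__(self) -> None:
        if self.genome_length <= 10 * self.read_length_mean:
            raise ValueError("genome_length must exceed 10x read_length_mean")
        if self.error_model not in ERROR_MODELS:
            raise ValueError(f"unknown error model {self.error_model!r}")
        for name in ("n_mei_per_class", "n_med_per_class", "n_ordinary_sv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for rate in (self.substitution_rate, self.indel_rate, self.divergence):
            if rate is not None and not (0.0 <= rate <= 0.3):
                raise ValueError("rates must lie in [0, 0.3]")
        if not (0.0 <= self.het_fraction <= 1.0):
            raise ValueError("het_fraction must lie in [0, 1]")

    @property
    def rates(self) -> tuple[float, float]:
        sub, ind = ERROR_MODELS[self.error_model]
        return (
            sub if self.substitution_rate is None else self.substitution_rate,
            ind if self.indel_rate is None else self.indel_rate,
        )


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one implanted event."""

    chrom: str
    pos: int  # 0-based reference coordinate of the event start
    svtype: str
    svlen: int  # signed: positive INS, negative DEL
    me_class: str  # Alu | L1 | SVA | none (ordinary SV)
    gt: str  # "0/1" | "1/1"


@dataclass
class _Event:
    svtype: str  # INS | DEL (DEL includes implanted-then-deleted MEDs)
    me_class: str  # class or "none"
    seq: Optional[np.ndarray]  # inserted (INS) or implanted (MED) codes
    length: int
    implanted: bool  # True for MEDs: seq is spliced into the reference
    backbone_pos: int = -1
    ref_pos: int = -1
    hap1: bool = False
    hap2: bool = False

    @property
    def gt(self) -> str:
        return "1/1" if (self.hap1 and self.hap2) else "0/1"


@dataclass
class Haplotype:
    """Piecewise map from haplotype coordinates to the reference.

    ``ops`` alternate reference segments ``("R", ref_start, ref_end)`` and
    insertions ``("I", codes)``; their concatenation is the haplotype.
    """

    ops: list
    _starts: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        starts = [0]
        for op in self.ops:
            length = (op[2] - op[1]) if op[0] == "R" else len(op[1])
            starts.append(starts[-1] + length)
        self._starts = np.asarray(starts)

    @property
    def length(self) -> int:
        return int(self._starts[-1])

    def sequence(self, reference: np.ndarray) -> np.ndarray:
        parts = [
            reference[op[1] : op[2]] if op[0] == "R" else op[1] for op in self.ops
        ]
        return np.concatenate(parts) if parts else np.empty(0, dtype=np.uint8)

    def project(self, start: int, end: int, reference: np.ndarray):
        """Project haplotype interval [start, end) onto the reference.

        Returns (pieces, codes): pieces is a list of ``("M", ref_start, n)``
        and ``("I", n)`` runs in read order; codes is the read sequence.
        """
        pieces = []
        chunks = []
        lo = int(np.searchsorted(self._starts, start, side="right") - 1)
        for idx in range(lo, len(self.ops)):
            op_start = int(self._starts[idx])
            if op_start >= end:
                break
            op = self.ops[idx]
            op_len = (op[2] - op[1]) if op[0] == "R" else len(op[1])
            s = max(start, op_start) - op_start
            e = min(end, op_start + op_len) - op_start
            if e <= s:
                continue
            if op[0] == "R":
                pieces.append(("M", op[1] + s, e - s))
                chunks.append(reference[op[1] + s : op[1] + e])
            else:
                pieces.append(("I", e - s))
                chunks.append(op[1][s:e])
        codes = np.concatenate(chunks) if chunks else np.empty(0, dtype=np.uint8)
        return pieces, codes


@dataclass
class SimGenome:
    reference: np.ndarray  # uint8 codes 0..3
    haplotypes: tuple[Haplotype, Haplotype]
    truth: list[TruthRecord]
    params: SimParams

    @property
    def reference_str(self) -> str:
        return codes_to_str(self.reference)


def codes_to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def str_to_codes(seq: str) -> np.ndarray:
    lookup = np.zeros(256, dtype=np.uint8)
    for i, b in enumerate("ACGT"):
        lookup[ord(b)] = i
    return lookup[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _mutate(codes: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    out = codes.copy()
    mask = rng.random(len(out)) < rate
    n = int(mask.sum())
    if n:
        out[mask] = (out[mask] + rng.integers(1, 4, size=n).astype(np.uint8)) % 4
    return out


def _me_copy(template_codes: np.ndarray, params: SimParams, rng: np.random.Generator,
             truncate: bool, me_class: str) -> np.ndarray:
    """One diverged element copy: optional 5' truncation, substitutions, polyA."""
    seq = template_codes
    if truncate:
        frac = rng.uniform(params.truncate_low, params.truncate_high)
        seq = seq[len(seq) - max(1, int(round(frac * len(seq)))):]
    elif params.l1_truncation and me_class == "L1":
        frac = rng.uniform(0.3, 1.0)
        seq = seq[len(seq) - max(1, int(round(frac * len(seq)))):]
    seq = _mutate(seq, params.divergence, rng)
    tail = int(rng.geometric(1.0 / max(1, params.polyA_mean)))
    return np.concatenate([seq, np.zeros(tail, dtype=np.uint8)])  # code 0 == A


def _build_events(params: SimParams, lib: MELibrary, rng: np.random.Generator) -> list[_Event]:
    events: list[_Event] = []
    for me_class in ("Alu", "L1", "SVA"):
        templates = lib.by_class(me_class)
        if not templates and (params.n_mei_per_class or params.n_med_per_class):
            raise ValueError(f"library has no template for class {me_class}")
        for _ in range(params.n_mei_per_class):
            tmpl = templates[int(rng.integers(len(templates)))]
            truncate = rng.random() < params.truncate_fraction
            seq = _me_copy(str_to_codes(tmpl.sequence), params, rng, truncate, me_class)
            events.append(_Event("INS", me_class, seq, len(seq), implanted=False))
        for _ in range(params.n_med_per_class):
            tmpl = templates[int(rng.integers(len(templates)))]
            seq = _me_copy(str_to_codes(tmpl.sequence), params, rng, False, me_class)
            events.append(_Event("DEL", me_class, seq, len(seq), implanted=True))
    for i in range(params.n_ordinary_sv):
        length = int(rng.integers(50, 2001))
        if i % 2 == 0:
            seq = rng.integers(0, 4, size=length).astype(np.uint8)
            events.append(_Event("INS", "none", seq, length, implanted=False))
        else:
            events.append(_Event("DEL", "none", None, length, implanted=False))
    return events


def _place_events(events: list[_Event], params: SimParams, rng: np.random.Generator) -> None:
    """Assign non-overlapping backbone positions with minimum spacing."""
    order = rng.permutation(len(events))
    events[:] = [events[i] for i in order]
    margin = max(5000, params.min_event_spacing)
    # backbone footprint: only ordinary DELs consume backbone sequence
    footprints = [e.length if (e.svtype == "DEL" and not e.implanted) else 0 for e in events]
    n = len(events)
    if n == 0:
        return
    fixed = 2 * margin + sum(footprints) + (n - 1) * params.min_event_spacing
    free = params.genome_length - fixed
    if free <= 0:
        raise ValueError(
            f"genome of {params.genome_length} bp cannot host {n} events "
            f"with {params.min_event_spacing} bp spacing"
        )
    offsets = np.sort(rng.random(n)) * free
    cum_foot = 0
    for i, event in enumerate(events):
        event.backbone_pos = int(margin + i * params.min_event_spacing + cum_foot + offsets[i])
        cum_foot += footprints[i]
    events.sort(key=lambda e: e.backbone_pos)


def simulate_genome(params: SimParams, lib: MELibrary) -> SimGenome:
    """Build reference, two haplotypes, and the truth set.

    MEIs are diverged template copies (plus polyA) inserted into carrier
    haplotypes; MEDs are template copies spliced into the reference and
    deleted from carrier haplotypes; ordinary SVs are random-sequence
    insertions and random-interval deletions of 50-2000 bp.  Each event is
    heterozygous with probability ``het_fraction`` (carrier haplotype drawn
    uniformly), otherwise homozygous.  Identical seeds give byte-identical
    output.
    """
    rng = np.random.default_rng(params.seed)
    backbone = rng.integers(0, 4, size=params.genome_length).astype(np.uint8)
    events = _build_events(params, lib, rng)
    _place_events(events, params, rng)
    # genotype assignment
    for event in events:
        if rng.random() < params.het_fraction:
            if rng.integers(2) == 0:
                event.hap1 = True
            else:
                event.hap2 = True
        else:
            event.hap1 = event.hap2 = True
    # splice MED template copies into the reference
    ref_parts = []
    cursor = 0
    shift = 0
    for event in events:
        if event.implanted:
            ref_parts.append(backbone[cursor : event.backbone_pos])
            ref_parts.append(event.seq)
            event.ref_pos = event.backbone_pos + shift
            shift += len(event.seq)
            cursor = event.backbone_pos
        else:
            event.ref_pos = event.backbone_pos + shift
    ref_parts.append(backbone[cursor:])
    reference = np.concatenate(ref_parts)
    haplotypes = tuple(
        _haplotype_from_events(events, reference, hap_index) for hap_index in (0, 1)
    )
    truth = [
        TruthRecord(
            params.chrom,
            e.ref_pos,
            e.svtype,
            e.length if e.svtype == "INS" else -e.length,
            e.me_class,
            e.gt,
        )
        for e in events
    ]
    truth.sort(key=lambda t: t.pos)
    return SimGenome(reference, haplotypes, truth, params)


def _haplotype_from_events(events: list[_Event], reference: np.ndarray, hap_index: int) -> Haplotype:
    ops: list = []
    cursor = 0
    for event in sorted(events, key=lambda e: e.ref_pos):
        carried = event.hap1 if hap_index == 0 else event.hap2
        if not carried:
            continue
        if event.svtype == "INS":
            if event.ref_pos > cursor:
                ops.append(("R", cursor, event.ref_pos))
            ops.append(("I", event.seq))
            cursor = event.ref_pos
        else:
            if event.ref_pos > cursor:
                ops.append(("R", cursor, event.ref_pos))
            cursor = event.ref_pos + event.length
    if len(reference) > cursor:
        ops.append(("R", cursor, len(reference)))
    return Haplotype(ops)


# ---------------------------------------------------------------------------
# read sampling, error injection, and alignment projection


def _pieces_to_tokens(pieces, codes):
    """Expand projection pieces into (cigar tokens, ref_start).

    Tokens are ``[op, length]`` with op in {M, I, D, S}; leading/trailing
    insertions become soft clips.  Returns None if the read touches no
    reference base.
    """
    if not any(p[0] == "M" for p in pieces):
        return None
    tokens: list[list[int]] = []
    ref_start = None
    prev_ref_end = None
    for piece in pieces:
        if piece[0] == "M":
            _, rstart, n = piece
            if ref_start is None:
                ref_start = rstart
            elif prev_ref_end is not None and rstart > prev_ref_end:
                tokens.append([_OP_D, rstart - prev_ref_end])
            tokens.append([_OP_M, n])
            prev_ref_end = rstart + n
        else:
            tokens.append([_OP_I, piece[1]])
    # leading/trailing insertions -> soft clips
    if tokens and tokens[0][0] == _OP_I:
        tokens[0][0] = _OP_S
    if tokens and tokens[-1][0] == _OP_I:
        tokens[-1][0] = _OP_S
    return tokens, ref_start


def _apply_errors(codes, tokens, ref_start, sub_rate, indel_rate, rng):
    """Inject substitution and small indel errors into a projected read.

    Substitutions are vectorized and leave the CIGAR untouched; indel errors
    (50/50 1 bp insertion or deletion at uniform read positions) split the
    affected token.  An error deletion inside an M run becomes a 1 bp D; one
    inside an I or S run just drops the base.
    """
    codes = _mutate(codes, sub_rate, rng)
    n = len(codes)
    k = int(rng.binomial(n, indel_rate)) if indel_rate > 0 else 0
    if k == 0:
        return codes, tokens, ref_start
    positions = np.sort(rng.choice(n, size=min(k, n), replace=False))
    is_ins = rng.random(len(positions)) < 0.5
    bases = rng.integers(0, 4, size=len(positions)).astype(np.uint8)
    out_tokens: list[list[int]] = []
    seq_parts: list[np.ndarray] = []

    def push(op: int, length: int) -> None:
        if length <= 0:
            return
        if out_tokens and out_tokens[-1][0] == op:
            out_tokens[-1][1] += length
        else:
            out_tokens.append([op, length])

    qpos = 0
    pi = 0
    for op, length in tokens:
        if op == _OP_D:
            push(_OP_D, length)
            continue
        tok_end = qpos + length
        cur = qpos
        while pi < len(positions) and positions[pi] < tok_end:
            p = int(positions[pi])
            if p > cur:
                push(op, p - cur)
                seq_parts.append(codes[cur:p])
                cur = p
            if is_ins[pi]:
                push(_OP_I if op == _OP_M else op, 1)
                seq_parts.append(bases[pi : pi + 1])
            else:
                if op == _OP_M:
                    push(_OP_D, 1)
                cur = p + 1
            pi += 1
        if tok_end > cur:
            push(op, tok_end - cur)
            seq_parts.append(codes[cur:tok_end])
        qpos = tok_end
    new_codes = np.concatenate(seq_parts) if seq_parts else np.empty(0, dtype=np.uint8)
    # drop edge deletions and soft-clip edge insertions
    while out_tokens and out_tokens[0][0] == _OP_D:
        ref_start += out_tokens.pop(0)[1]
    while out_tokens and out_tokens[-1][0] == _OP_D:
        out_tokens.pop()
    if out_tokens and out_tokens[0][0] == _OP_I:
        out_tokens[0][0] = _OP_S
        if len(out_tokens) > 1 and out_tokens[1][0] == _OP_S:
            out_tokens[0][1] += out_tokens.pop(1)[1]
    if out_tokens and out_tokens[-1][0] == _OP_I:
        out_tokens[-1][0] = _OP_S
        if len(out_tokens) > 1 and out_tokens[-2][0] == _OP_S:
            out_tokens[-1][1] += out_tokens.pop(-2)[1]
    return new_codes, out_tokens, ref_start


@dataclass
class _SegmentRecord:
    name: str
    flag: int
    ref_start: int
    cigar: list  # [op, length] tokens including soft clips
    seq: str
    sa_entries: list = field(default_factory=list)


def _cigar_str(tokens) -> str:
    return "".join(f"{length}{_OP_CHR[op]}" for op, length in tokens)


def _split_segments(tokens, ref_start, threshold):
    """Split a token list at deletions >= threshold into co-linear segments."""
    segments = []
    current: list = []
    rpos = ref_start
    seg_ref_start = ref_start
    qpos = 0
    seg_q_start = 0
    for op, length in tokens:
        if op == _OP_D and length >= threshold:
            segments.append((seg_ref_start, seg_q_start, qpos, current))
            rpos += length
            seg_ref_start = rpos
            seg_q_start = qpos
            current = []
            continue
        current.append([op, length])
        if op in (_OP_M, _OP_D):
            rpos += length
        if op in (_OP_M, _OP_I, _OP_S):
            qpos += length
    segments.append((seg_ref_start, seg_q_start, qpos, current))
    return segments


def generate_alignments(genome: SimGenome, params: SimParams, rng: np.random.Generator):
    """Sample reads from both haplotypes and project them onto the reference.

    Returns a coordinate-sorted list of :class:`_SegmentRecord` and the list
    of (name, sequence, strand) tuples for FASTQ output.
    """
    sub_rate, indel_rate = params.rates
    records: list[_SegmentRecord] = []
    fastq: list[tuple[str, str, str]] = []
    for hap_index, hap in enumerate(genome.haplotypes):
        hap_len = hap.length
        n_reads = int(round(params.depth * hap_len / params.read_length_mean))
        for i in range(n_reads):
            length = int(rng.normal(params.read_length_mean, params.read_length_sd))
            length = max(500, length)
            start = int(rng.integers(-(length - 1), hap_len))
            s, e = max(0, start), min(hap_len, start + length)
            strand = "+" if rng.random() < 0.5 else "-"
            if e - s < 300:
                continue
            pieces, codes = hap.project(s, e, genome.reference)
            projected = _pieces_to_tokens(pieces, codes)
            name = f"sim_h{hap_index + 1}_{i:06d}"
            if projected is None:
                continue
            tokens, ref_start = projected
            codes, tokens, ref_start = _apply_errors(
                codes, tokens, ref_start, sub_rate, indel_rate, rng
            )
            if not any(op == _OP_M for op, _ in tokens):
                continue
            seq = codes_to_str(np.asarray(codes, dtype=np.uint8))
            fastq.append((name, seq, strand))
            base_flag = 16 if strand == "-" else 0
            segments = _split_segments(tokens, ref_start, params.split_del_threshold)
            if len(segments) == 1:
                records.append(_SegmentRecord(name, base_flag, ref_start, segments[0][3], seq))
                continue
            # choose the longest-aligned segment as primary
            def aligned_len(seg):
                return sum(n for op, n in seg[3] if op == _OP_M)

            primary_idx = max(range(len(segments)), key=lambda idx: (aligned_len(segments[idx]), -idx))
            seg_records = []
            for idx, (seg_rs, q_start, q_end, seg_tokens) in enumerate(segments):
                full = list(seg_tokens)
                left = q_start
                right = len(seq) - q_end
                if left:
                    full.insert(0, [_OP_S, left])
                if right:
                    full.append([_OP_S, right])
                flag = base_flag if idx == primary_idx else base_flag | 2048
                seg_records.append(_SegmentRecord(name, flag, seg_rs, full, seq))
            for idx, rec in enumerate(seg_records):
                rec.sa_entries = [
                    f"{params.chrom},{other.ref_start + 1},{strand},{_cigar_str(other.cigar)},60,0"
                    for j, other in enumerate(seg_records)
                    if j != idx
                ]
            records.extend(seg_records)
    records.sort(key=lambda r: (r.ref_start, r.name, r.flag))
    return records, fastq


def write_sam(records, genome: SimGenome, out_path: str) -> None:
    """Write projected alignments as coordinate-sorted SAM."""
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": genome.params.chrom, "LN": int(len(genome.reference))}],
    }
    with pysam.AlignmentFile(str(out_path), "w", header=header) as out:
        for rec in records:
            aln = pysam.AlignedSegment(out.header)
            aln.query_name = rec.name
            aln.flag = rec.flag
            aln.reference_id = 0
            aln.reference_start = rec.ref_start
            aln.mapping_quality = 60
            aln.query_sequence = rec.seq
            aln.cigartuples = [(op, length) for op, length in rec.cigar]
            if rec.sa_entries:
                aln.set_tag("SA", ";".join(rec.sa_entries) + ";")
            out.write(aln)


def write_fasta_reference(genome: SimGenome, out_path: str) -> None:
    seq = genome.reference_str
    with open(out_path, "w") as handle:
        handle.write(f">{genome.params.chrom}\n")
        for i in range(0, len(seq), 60):
            handle.write(seq[i : i + 60] + "\n")


def write_fastq(fastq_reads, out_path: str) -> None:
    from mehunter.melib import revcomp

    with open(out_path, "w") as handle:
        for name, seq, strand in fastq_reads:
            read_seq = revcomp(seq) if strand == "-" else seq
            handle.write(f"@{name}\n{read_seq}\n+\n{'I' * len(read_seq)}\n")


_TRUTH_HEADER = [
    "##fileformat=VCFv4.2",
    "##source=mehunter-simulate",
    '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">',
    '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Length of the variant (negative for deletions)">',
    '##INFO=<ID=END,Number=1,Type=Integer,Description="End position of the variant">',
    '##INFO=<ID=MECLASS,Number=1,Type=String,Description="Mobile element class or none">',
    '##ALT=<ID=INS,Description="Insertion">',
    '##ALT=<ID=DEL,Description="Deletion">',
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
]


def write_truth_vcf(genome: SimGenome, out_path: str, sample: str = "SIM") -> None:
    """Ground-truth VCF with symbolic alleles and MECLASS annotations."""
    lines = list(_TRUTH_HEADER)
    lines.insert(2, f"##contig=<ID={genome.params.chrom},length={len(genome.reference)}>")
    lines.append(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}")
    ref = genome.reference
    for i, rec in enumerate(genome.truth):
        anchor = codes_to_str(ref[rec.pos - 1 : rec.pos])
        end = rec.pos if rec.svtype == "INS" else rec.pos - rec.svlen
        info = f"SVTYPE={rec.svtype};SVLEN={rec.svlen};END={end};MECLASS={rec.me_class}"
        lines.append(
            "\t".join(
                [
                    rec.chrom,
                    str(rec.pos),  # 1-based anchor == 0-based event start
                    f"truth.{i + 1}",
                    anchor,
                    f"<{rec.svtype}>",
                    ".",
                    "PASS",
                    info,
                    "GT",
                    rec.gt,
                ]
            )
        )
    with open(out_path, "w") as handle:
        handle.write("\n".join(lines) + "\n")


def simulate_to_dir(params: SimParams, lib: MELibrary, out_dir: str, write_reads_fastq: bool = True) -> dict:
    """Run the full simulation and write ref.fa, truth.vcf, reads.sam[, reads.fq]."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genome = simulate_genome(params, lib)
    rng = np.random.default_rng(params.seed + 1)
    records, fastq = generate_alignments(genome, params, rng)
    write_fasta_reference(genome, str(out / "ref.fa"))
    write_truth_vcf(genome, str(out / "truth.vcf"))
    write_sam(records, genome, str(out / "reads.sam"))
    if write_reads_fastq:
        write_fastq(fastq, str(out / "reads.fq"))
    return {
        "genome": genome,
        "n_reads": len(fastq),
        "n_records": len(records),
        "paths": {
            "ref": str(out / "ref.fa"),
            "truth": str(out / "truth.vcf"),
            "sam": str(out / "reads.sam"),
            "fastq": str(out / "reads.fq") if write_reads_fastq else None,
        },
    }


# ---------------------------------------------------------------------------
# trio simulation


def simulate_trio(params: SimParams, lib: MELibrary, presence: float = 0.7):
    """Simulate father/mother/child genomes over one shared reference.

    Events are drawn once; each parent carries an event with probability
    ``presence`` (then het with probability ``het_fraction``).  The child is
    composed of one randomly chosen haplotype from each parent, so the truth
    trio is Mendelian-consistent by construction.

    Returns a dict with keys ``father``, ``mother``, ``child`` mapping to
    :class:`SimGenome` objects sharing the same reference array.
    """
    rng = np.random.default_rng(params.seed)
    backbone = rng.integers(0, 4, size=params.genome_length).astype(np.uint8)
    events = _build_events(params, lib, rng)
    _place_events(events, params, rng)
    ref_parts = []
    cursor = 0
    shift = 0
    for event in events:
        if event.implanted:
            ref_parts.append(backbone[cursor : event.backbone_pos])
            ref_parts.append(event.seq)
            event.ref_pos = event.backbone_pos + shift
            shift += len(event.seq)
            cursor = event.backbone_pos
        else:
            event.ref_pos = event.backbone_pos + shift
    ref_parts.append(backbone[cursor:])
    reference = np.concatenate(ref_parts)

    def draw_flags():
        flags = []
        for _ in events:
            if rng.random() >= presence:
                flags.append((False, False))
            elif rng.random() < params.het_fraction:
                flags.append((True, False) if rng.integers(2) == 0 else (False, True))
            else:
                flags.append((True, True))
        return flags

    father_flags = draw_flags()
    mother_flags = draw_flags()
    f_choice = int(rng.integers(2))
    m_choice = int(rng.integers(2))
    child_flags = [
        (father_flags[i][f_choice], mother_flags[i][m_choice]) for i in range(len(events))
    ]
    genomes = {}
    for who, flags in (("father", father_flags), ("mother", mother_flags), ("child", child_flags)):
        for event, (h1, h2) in zip(events, flags):
            event.hap1, event.hap2 = h1, h2
        haplotypes = tuple(
            _haplotype_from_events(
                [e for e in events if (e.hap1 or e.hap2)], reference, hap_index
            )
            for hap_index in (0, 1)
        )
        truth = [
            TruthRecord(params.chrom, e.ref_pos, e.svtype,
                        e.length if e.svtype == "INS" else -e.length, e.me_class, e.gt)
            for e in events
            if e.hap1 or e.hap2
        ]
        truth.sort(key=lambda t: t.pos)
        genomes[who] = SimGenome(reference, haplotypes, truth, params)
    return genomes
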