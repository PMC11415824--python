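"""Genotyping from read support and VCF 4.2 output."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

from mehunter import __version__ as _version
from mehunter.config import CallerConfig
from mehunter.signatures import SpanIndex


@dataclass(frozen=True)
class MEVCall:
    """One genotyped mobile-element variant ready for VCF emission."""

    chrom: str
    pos: int  # 1-based VCF coordinate (anchor base before the event)
    svtype: str  # INS | DEL
    svlen: int  # positive for INS, negative for DEL
    me_class: str  # Alu | L1 | SVA
    gt: str  # "0/1" | "1/1"
    dv: int
    dr: int
    consensus_sequence: str
    classification_round: str  # first | second

    def __post_init__(self) -> None:
        if self.svtype == "INS" and self.svlen <= 0:
            raise ValueError("INS calls must have positive SVLEN")
        if self.svtype == "DEL" and self.svlen >= 0:
            raise ValueError("DEL calls must have negative SVLEN")
        if self.gt not in ("0/1", "1/1"):
            raise ValueError(f"unsupported genotype {self.gt!r}")

    @property
    def end(self) -> int:
        """1-based END: POS for INS, last deleted base for DEL."""
        return self.pos if self.svtype == "INS" else self.pos - self.svlen


def genotype(dv: int, dr: int, cfg: CallerConfig) -> Optional[str]:
    """Allele-frequency-band genotype, or None for a sub-threshold no-call.

    af = dv/(dv+dr); below ``het_af_low`` the locus is filtered, above
    ``hom_af_high`` it is 1/1, in between 0/1.
    """
    if dv < 0 or dr < 0:
        raise ValueError("read counts must be non-negative")
    if dv + dr == 0:
        raise ValueError("cannot genotype a locus with zero covering reads")
    af = dv / (dv + dr)
    if af < cfg.het_af_low:
        return None
    if af > cfg.hom_af_high:
        return "1/1"
    return "0/1"


def count_reference_spanning(
    chrom: str,
    pos: int,
    index: SpanIndex,
    flank: int,
    exclude: Iterable[str] = (),
) -> int:
    """Reads spanning [pos - flank, pos + flank] that did not support the cluster."""
    return index.count_spanning(chrom, pos, flank, exclude=exclude)


_VCF_HEADER_LINES = [
    '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">',
    '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Length of the variant (negative for deletions)">',
    '##INFO=<ID=END,Number=1,Type=Integer,Description="End position of the variant">',
    '##INFO=<ID=MECLASS,Number=1,Type=String,Description="Mobile element class (Alu, L1, SVA)">',
    '##INFO=<ID=CROUND,Number=1,Type=String,Description="Classification round (first or second)">',
    '##ALT=<ID=DEL,Description="Deletion">',
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    '##FORMAT=<ID=DR,Number=1,Type=Integer,Description="Reference-spanning read count">',
    '##FORMAT=<ID=DV,Number=1,Type=Integer,Description="Variant-supporting read count">',
]


def write_vcf(
    calls: list[MEVCall],
    reference,
    out_path: str,
    sample: str = "SAMPLE",
    explicit_del_alleles: bool = False,
    fixed_header_date: Optional[str] = None,
) -> None:
    """Write calls as single-sample VCF 4.2.

    ``reference`` is a pysam.FastaFile-like accessor (``references``,
    ``get_reference_length``, ``fetch``).  INS records use REF = the base
    before the insertion and ALT = REF + consensus; DEL records use the
    symbolic ``<DEL>`` allele with END (or, with ``explicit_del_alleles``,
    REF = anchor base + deleted sequence and ALT = anchor base).  Output is
    byte-identical across runs: no timestamp is written unless
    ``fixed_header_date`` supplies one.
    """
    prev = None
    for call in calls:
        key = (call.chrom, call.pos)
        if prev is not None and key < prev:
            raise ValueError("calls must be sorted by (chrom, pos)")
        prev = key
    lines = ["##fileformat=VCFv4.2"]
    if fixed_header_date:
        lines.append(f"##fileDate={fixed_header_date}")
    lines.append(f"##source=mehunter-{_version}")
    for name in reference.references:
        lines.append(f"##contig=<ID={name},length={reference.get_reference_length(name)}>")
    lines.extend(_VCF_HEADER_LINES)
    lines.append(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}")
    for i, call in enumerate(calls):
        contig_len = reference.get_reference_length(call.chrom)
        if not (1 <= call.pos <= contig_len) or call.end > contig_len:
            raise ValueError(
                f"call at {call.chrom}:{call.pos} (END {call.end}) lies outside the reference"
            )
        anchor = reference.fetch(call.chrom, call.pos - 1, call.pos).upper()
        if call.svtype == "INS":
            ref_allele, alt_allele = anchor, anchor + call.consensus_sequence
        elif explicit_del_alleles:
            deleted = reference.fetch(call.chrom, call.pos, call.end).upper()
            ref_allele, alt_allele = anchor + deleted, anchor
        else:
            ref_allele, alt_allele = anchor, "<DEL>"
        info = (
            f"SVTYPE={call.svtype};SVLEN={call.svlen};END={call.end};"
            f"MECLASS={call.me_class};CROUND={call.classification_round}"
        )
        lines.append(
            "\t".join(
                [
                    call.chrom,
                    str(call.pos),
                    f"mehunter.{call.svtype}.{i + 1}",
                    ref_allele,
                    alt_allele,
                    ".",
                    "PASS",
                    info,
                    "GT:DR:DV",
                    f"{call.gt}:{call.dr}:{call.dv}",
                ]
            )
        )
    with open(out_path, "w") as handle:
        handle.write("\n".join(lines) + "\n")
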