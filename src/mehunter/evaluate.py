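"""Benchmarking: callset-vs-truth matching, F1/FDR metrics, trio MDR.

Matching is greedy nearest-position with a window and size-ratio gate, each
truth record usable at most once.  Calls whose locus matches but whose ME
class disagrees form their own false-positive category, mirroring the two
ways a call can be unsupported (wrong class versus wrong locus).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pysam


@dataclass(frozen=True)
class VariantRecord:
    """Minimal view of one VCF record for benchmarking."""

    chrom: str
    pos: int  # 1-based VCF POS
    svtype: str
    svlen: int  # signed
    me_class: str
    gt: str


def load_vcf_records(path: str, mev_only: bool = False) -> list[VariantRecord]:
    """Read a single-sample VCF into VariantRecords.

    ``mev_only`` drops records whose MECLASS is 'none' (the simulator's
    ordinary SVs), leaving the mobile-element truth set.
    """
    records = []
    with pysam.VariantFile(path) as vcf:
        for rec in vcf:
            info = rec.info
            svtype = info.get("SVTYPE")
            if svtype not in ("INS", "DEL"):
                raise ValueError(f"malformed record at {rec.chrom}:{rec.pos}: SVTYPE={svtype!r}")
            svlen = info.get("SVLEN")
            if isinstance(svlen, (tuple, list)):
                svlen = svlen[0]
            if svlen is None:
                raise ValueError(f"malformed record at {rec.chrom}:{rec.pos}: missing SVLEN")
            try:
                me_class = info.get("MECLASS", "none")
            except ValueError:  # MECLASS not declared in this header
                me_class = "none"
            gt = "./."
            for sample in rec.samples.values():
                alleles = sample.get("GT")
                if alleles and None not in alleles:
                    gt = "/".join(str(a) for a in sorted(alleles))
                break
            records.append(VariantRecord(rec.chrom, rec.pos, svtype, int(svlen), me_class, gt))
    records.sort(key=lambda r: (r.chrom, r.pos))
    return records


@dataclass
class MatchResult:
    tp_pairs: list[tuple[VariantRecord, VariantRecord]]  # (call, truth), class-consistent
    fp_class: list[tuple[VariantRecord, VariantRecord]]  # locus-matched, class mismatch
    fp_locus: list[VariantRecord]
    fn: list[VariantRecord]

    @property
    def tp(self) -> int:
        return len(self.tp_pairs)


def _size_ok(a: int, b: int, size_ratio: float) -> bool:
    la, lb = abs(a), abs(b)
    return min(la, lb) / max(la, lb) >= size_ratio if max(la, lb) else False


def match_calls(
    calls: Sequence[VariantRecord],
    truth: Sequence[VariantRecord],
    window: int = 1000,
    size_ratio: float = 0.7,
    class_strict: bool = False,
) -> MatchResult:
    """Greedy one-to-one matching of calls against truth.

    A call matches a truth record when chromosome and svtype agree, the
    position difference is within ``window``, and the length ratio is at
    least ``size_ratio``.  Pairs are assigned greedily by ascending position
    difference; each record participates in at most one pair.  With
    ``class_strict``, a locus-matched pair with disagreeing ME class counts
    as an FP (in the separate class category) and the truth record as FN.
    """
    candidates = []
    for ci, call in enumerate(calls):
        for ti, rec in enumerate(truth):
            if call.chrom != rec.chrom or call.svtype != rec.svtype:
                continue
            if abs(call.pos - rec.pos) > window:
                continue
            if not _size_ok(call.svlen, rec.svlen, size_ratio):
                continue
            candidates.append((abs(call.pos - rec.pos), ci, ti))
    candidates.sort()
    call_used = [False] * len(calls)
    truth_used = [False] * len(truth)
    tp_pairs, fp_class = [], []
    for _, ci, ti in candidates:
        if call_used[ci] or truth_used[ti]:
            continue
        call_used[ci] = True
        truth_used[ti] = True
        pair = (calls[ci], truth[ti])
        if class_strict and calls[ci].me_class != truth[ti].me_class:
            fp_class.append(pair)
        else:
            tp_pairs.append(pair)
    fp_locus = [c for c, used in zip(calls, call_used) if not used]
    fn = [t for t, used in zip(truth, truth_used) if not used]
    if class_strict:
        fn = fn + [t for _, t in fp_class]
        fn.sort(key=lambda r: (r.chrom, r.pos))
    return MatchResult(tp_pairs, fp_class, fp_locus, fn)


def prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    """Precision, recall, F1 with 0/0 -> 0 conventions."""
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return precision, recall, f1


@dataclass
class EvalResult:
    """Presence and genotype-aware metrics for one callset-vs-truth pair."""

    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float
    fdr: float
    gt_f1: float
    fp_class: int = 0
    per_class: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {
            "tp": self.tp, "fp": self.fp, "fn": self.fn,
            "precision": self.precision, "recall": self.recall, "f1": self.f1,
            "fdr": self.fdr, "gt_f1": self.gt_f1, "fp_class": self.fp_class,
        }
        if self.per_class:
            out["per_class"] = dict(self.per_class)
        return out


def _result_from_match(match: MatchResult) -> EvalResult:
    tp = match.tp
    fp = len(match.fp_locus) + len(match.fp_class)
    fn = len(match.fn)
    precision, recall, f1 = prf(tp, fp, fn)
    fdr = 1.0 - precision if tp + fp else 0.0
    tp_gt = sum(1 for call, rec in match.tp_pairs if call.gt == rec.gt)
    _, _, gt_f1 = prf(tp_gt, fp + (tp - tp_gt), fn + (tp - tp_gt))
    return EvalResult(tp, fp, fn, precision, recall, f1, fdr, gt_f1, fp_class=len(match.fp_class))


def evaluate_callset(
    calls: Sequence[VariantRecord],
    truth: Sequence[VariantRecord],
    window: int = 1000,
    size_ratio: float = 0.7,
    class_strict: bool = False,
) -> EvalResult:
    """Overall and per-class metrics for a callset against truth."""
    overall = _result_from_match(match_calls(calls, truth, window, size_ratio, class_strict))
    for me_class in sorted({t.me_class for t in truth} - {"none"}):
        sub_calls = [c for c in calls if c.me_class == me_class]
        sub_truth = [t for t in truth if t.me_class == me_class]
        sub = _result_from_match(match_calls(sub_calls, sub_truth, window, size_ratio, False))
        overall.per_class[me_class] = sub.to_dict()
    return overall


# ---------------------------------------------------------------------------
# trio Mendelian discordance


@dataclass
class TrioResult:
    n_sites: int
    n_discordant: int
    by_svtype: dict = field(default_factory=dict)

    @property
    def mdr(self) -> float:
        return self.n_discordant / self.n_sites if self.n_sites else 0.0

    def to_dict(self) -> dict:
        return {
            "n_sites": self.n_sites,
            "n_discordant": self.n_discordant,
            "mdr": self.mdr,
            "by_svtype": dict(self.by_svtype),
        }


def _alleles(gt: str) -> tuple[int, int]:
    a, b = gt.split("/")
    return int(a), int(b)


def is_mendelian_consistent(child: str, father: str, mother: str) -> bool:
    """Can the child genotype arise from one allele of each parent?"""
    c1, c2 = _alleles(child)
    fa = set(_alleles(father))
    mo = set(_alleles(mother))
    return (c1 in fa and c2 in mo) or (c1 in mo and c2 in fa)


def mendelian_discordance(
    child: Sequence[VariantRecord],
    father: Sequence[VariantRecord],
    mother: Sequence[VariantRecord],
    window: int = 1000,
    size_ratio: float = 0.7,
) -> TrioResult:
    """Trio MDR over the union of matched loci.

    Records of the three samples are pooled and chained into sites with the
    same window/size-ratio rule used for callset matching; a sample absent
    at a site contributes genotype 0/0.  A site is discordant when the
    child's genotype cannot be produced by one allele from each parent.
    """
    tagged = (
        [("child", r) for r in child]
        + [("father", r) for r in father]
        + [("mother", r) for r in mother]
    )
    tagged.sort(key=lambda item: (item[1].chrom, item[1].pos, item[0]))
    sites: list[dict] = []
    open_sites: list[dict] = []
    for who, rec in tagged:
        open_sites = [
            s for s in open_sites
            if s["chrom"] == rec.chrom and rec.pos - s["pos"] <= window
        ]
        home = None
        for site in open_sites:
            if (
                site["svtype"] == rec.svtype
                and who not in site["gts"]
                and _size_ok(site["svlen"], rec.svlen, size_ratio)
            ):
                home = site
                break
        if home is None:
            home = {
                "chrom": rec.chrom, "pos": rec.pos, "svtype": rec.svtype,
                "svlen": rec.svlen, "gts": {},
            }
            sites.append(home)
            open_sites.append(home)
        home["gts"][who] = rec.gt
        home["pos"] = rec.pos
    n_discordant = 0
    by_svtype: dict[str, dict] = {}
    for site in sites:
        gts = site["gts"]
        ok = is_mendelian_consistent(
            gts.get("child", "0/0"), gts.get("father", "0/0"), gts.get("mother", "0/0")
        )
        bucket = by_svtype.setdefault(site["svtype"], {"n_sites": 0, "n_discordant": 0})
        bucket["n_sites"] += 1
        if not ok:
            n_discordant += 1
            bucket["n_discordant"] += 1
    for bucket in by_svtype.values():
        bucket["mdr"] = bucket["n_discordant"] / bucket["n_sites"] if bucket["n_sites"] else 0.0
    return TrioResult(len(sites), n_discordant, by_svtype)
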