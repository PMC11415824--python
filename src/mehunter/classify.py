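"""Two-round classification of consensus sequences against the ME library.

Round one aligns each consensus to every template on both strands with a
lightweight banded affine-gap Smith-Waterman (anchored on the best shared
k-mer diagonal) and assigns a class when identity and template coverage
clear their thresholds.  Sequences left unclassified go through a k-mer
prescreen that discards obviously unrelated sequences, then to a pluggable
second-round classifier; the bundled baseline is a per-class k-mer-profile
nearest-class model standing in for a fine-tuned transformer behind the same
plugin contract.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Protocol

import numpy as np
from numba import njit

from mehunter.clustering import ConsensusCall
from mehunter.config import CallerConfig
from mehunter.melib import MELibrary, revcomp

logger = logging.getLogger(__name__)

_NEG = -(10**9)
_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i

_FULL_DP_MAX = 256  # below this size the band always covers the whole matrix
_ANCHOR_K = 11


def _encode(seq: str) -> np.ndarray:
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class SWResult:
    """Best local alignment of a consensus against one template."""

    score: int
    identity: float
    query_span: tuple[int, int]
    target_span: tuple[int, int]
    strand: str
    matches: int = 0

    @property
    def query_span_length(self) -> int:
        return self.query_span[1] - self.query_span[0]

    @property
    def target_span_length(self) -> int:
        return self.target_span[1] - self.target_span[0]


@dataclass(frozen=True)
class MEClassification:
    """Outcome of the two-round classification for one consensus."""

    me_class: str  # Alu | L1 | SVA | none
    best_template: Optional[str]
    sw: Optional[SWResult]
    round: str  # first | second | unclassified
    second_round_score: Optional[float] = None

    def __post_init__(self) -> None:
        if (self.me_class == "none") != (self.round == "unclassified"):
            raise ValueError("me_class none iff round unclassified")


@njit(cache=True)
def _pair_score(a, b, match, mismatch):
    if a == 4 or b == 4:  # N aligns to anything with zero contribution
        return 0
    if a == b:
        return match
    return mismatch


@njit(cache=True)
def _sw_full(q, t, match, mismatch, gap_open, gap_extend):
    n, m = len(q), len(t)
    H = np.zeros((n + 1, m + 1), dtype=np.int64)
    E = np.full((n + 1, m + 1), _NEG, dtype=np.int64)
    F = np.full((n + 1, m + 1), _NEG, dtype=np.int64)
    best = 0
    bi = bj = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i, j] = max(H[i, j - 1] + gap_open + gap_extend, E[i, j - 1] + gap_extend)
            F[i, j] = max(H[i - 1, j] + gap_open + gap_extend, F[i - 1, j] + gap_extend)
            h = H[i - 1, j - 1] + _pair_score(q[i - 1], t[j - 1], match, mismatch)
            if E[i, j] > h:
                h = E[i, j]
            if F[i, j] > h:
                h = F[i, j]
            if h < 0:
                h = 0
            H[i, j] = h
            if h > best:
                best = h
                bi, bj = i, j
    # traceback
    i, j = bi, bj
    matches = 0
    while i > 0 and j > 0 and H[i, j] > 0:
        h = H[i, j]
        s = _pair_score(q[i - 1], t[j - 1], match, mismatch)
        if h == H[i - 1, j - 1] + s:
            if q[i - 1] == t[j - 1] and q[i - 1] != 4:
                matches += 1
            i -= 1
            j -= 1
        elif h == E[i, j]:
            while True:
                if E[i, j] == H[i, j - 1] + gap_open + gap_extend:
                    j -= 1
                    break
                j -= 1
        else:
            while True:
                if F[i, j] == H[i - 1, j] + gap_open + gap_extend:
                    i -= 1
                    break
                i -= 1
    return best, i, bi, j, bj, matches


@njit(cache=True)
def _sw_banded(q, t, d0, band, match, mismatch, gap_open, gap_extend):
    n, m = len(q), len(t)
    width = 2 * band + 1
    H = np.zeros((n + 1, width), dtype=np.int64)
    E = np.full((n + 1, width), _NEG, dtype=np.int64)
    F = np.full((n + 1, width), _NEG, dtype=np.int64)
    best = 0
    bi = bc = 0
    for i in range(1, n + 1):
        off = i + d0 - band  # reference j of column c=0 in this row
        for c in range(width):
            j = off + c
            if j < 1 or j > m:
                H[i, c] = 0
                E[i, c] = _NEG
                F[i, c] = _NEG
                continue
            e = _NEG
            if c - 1 >= 0:
                hl = H[i, c - 1] if off + c - 1 >= 0 else 0
                e = max(hl + gap_open + gap_extend, E[i, c - 1] + gap_extend)
            elif j - 1 == 0:
                e = gap_open + gap_extend  # from H[i,0] == 0
            E[i, c] = e
            f = _NEG
            if c + 1 < width:
                f = max(H[i - 1, c + 1] + gap_open + gap_extend, F[i - 1, c + 1] + gap_extend)
            F[i, c] = f
            hd = H[i - 1, c] if off + c - 1 >= 1 else 0  # diag (i-1, j-1)
            h = hd + _pair_score(q[i - 1], t[j - 1], match, mismatch)
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            H[i, c] = h
            if h > best:
                best = h
                bi, bc = i, c
    # traceback mirrors the forward recurrences
    i, c = bi, bc
    matches = 0
    bj = bi + d0 - band + bc
    j = bj
    while i > 0 and j > 0 and H[i, c] > 0:
        h = H[i, c]
        s = _pair_score(q[i - 1], t[j - 1], match, mismatch)
        hd = H[i - 1, c] if j - 1 >= 1 else 0
        if h == hd + s:
            if q[i - 1] == t[j - 1] and q[i - 1] != 4:
                matches += 1
            i -= 1
            j -= 1
            # c unchanged: diag keeps the band column
        elif h == E[i, c]:
            while True:
                hl = H[i, c - 1] if c - 1 >= 0 else (0 if j - 1 == 0 else _NEG)
                if E[i, c] == hl + gap_open + gap_extend:
                    j -= 1
                    c -= 1
                    break
                j -= 1
                c -= 1
        else:
            while True:
                if F[i, c] == H[i - 1, c + 1] + gap_open + gap_extend:
                    i -= 1
                    c += 1
                    break
                i -= 1
                c += 1
    return best, i, bi, j, bj, matches


def _anchor_diagonal(q: np.ndarray, t: np.ndarray, k: int = _ANCHOR_K) -> Optional[int]:
    """Modal diagonal (t_pos - q_pos) over shared k-mers, or None."""
    if len(q) < k or len(t) < k:
        return None
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)

    def hashes(arr):
        valid = arr != 4
        ok = np.ones(len(arr) - k + 1, dtype=bool)
        vals = np.zeros(len(arr) - k + 1, dtype=np.int64)
        for off in range(k):
            window = arr[off : off + len(vals)]
            ok &= valid[off : off + len(vals)]
            vals += window.astype(np.int64) * powers[off]
        return vals, ok

    tv, tok = hashes(t)
    index: dict[int, list[int]] = {}
    for pos in np.nonzero(tok)[0]:
        index.setdefault(int(tv[pos]), []).append(int(pos))
    qv, qok = hashes(q)
    diag_count: dict[int, int] = {}
    for qpos in np.nonzero(qok)[0]:
        hits = index.get(int(qv[qpos]))
        if not hits:
            continue
        for tpos in hits[:8]:
            d = tpos - int(qpos)
            diag_count[d] = diag_count.get(d, 0) + 1
    if not diag_count:
        return None
    return sorted(diag_count.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]


def _sw_one_strand(q: np.ndarray, t: np.ndarray, cfg: CallerConfig):
    n, m = len(q), len(t)
    args = (cfg.sw_match, cfg.sw_mismatch, cfg.sw_gap_open, cfg.sw_gap_extend)
    if max(n, m) <= _FULL_DP_MAX:
        return _sw_full(q, t, *args)
    d0 = _anchor_diagonal(q, t)
    if d0 is None:
        return _sw_full(q, t, *args)
    band = max(64, int(0.2 * max(n, m)))
    return _sw_banded(q, t, d0, band, *args)


def smith_waterman(query: str, target: str, cfg: CallerConfig) -> SWResult:
    """Best-of-both-strands local alignment of query against target.

    ``N`` contributes zero to the score and never counts as a match.
    Identity is matches over aligned query columns.  Strand ties resolve
    to '+'.  On the minus strand, spans refer to the reverse-complemented
    query.
    """
    if not query or not target:
        raise ValueError("smith_waterman requires non-empty sequences")
    t = _encode(target)
    results = []
    for strand, qseq in (("+", query), ("-", revcomp(query))):
        score, qs, qe, ts, te, matches = _sw_one_strand(_encode(qseq), t, cfg)
        results.append((score, strand, qs, qe, ts, te, matches))
    results.sort(key=lambda r: (-r[0], r[1]))  # higher score first, '+' wins ties
    score, strand, qs, qe, ts, te, matches = results[0]
    if score <= 0:
        return SWResult(0, 0.0, (0, 0), (0, 0), "+", 0)
    identity = matches / (qe - qs) if qe > qs else 0.0
    return SWResult(int(score), identity, (qs, qe), (ts, te), strand, int(matches))


def trim_polya_tail(seq: str, min_run: int = 10) -> str:
    """Strip a terminal A-run (or leading T-run) of at least ``min_run`` bp."""
    trimmed = seq
    end = len(trimmed)
    while end > 0 and trimmed[end - 1] == "A":
        end -= 1
    if len(trimmed) - end >= min_run:
        trimmed = trimmed[:end]
    start = 0
    while start < len(trimmed) and trimmed[start] == "T":
        start += 1
    if start >= min_run:
        trimmed = trimmed[start:]
    return trimmed or seq


def classify_first_round(call: ConsensusCall, lib: MELibrary, cfg: CallerConfig) -> MEClassification:
    """Assign a class by best template alignment, or leave unclassified.

    The best-scoring template wins (ties: higher identity, then shorter
    template, then name) and its class is assigned when identity reaches
    ``first_round_identity_threshold``, the aligned query span covers at
    least half of min(consensus length, template length), and the alignment
    covers at least ``first_round_coverage`` of the template.  Fragmentary
    template matches therefore fall through to the second round, which is
    responsible for fragmented elements.
    """
    if len(lib) == 0:
        raise ValueError("cannot classify against an empty library")
    seq = call.consensus_sequence
    if cfg.trim_polya:
        seq = trim_polya_tail(seq)
    scored = []
    for template in lib:
        sw = smith_waterman(seq, template.sequence, cfg)
        scored.append((-sw.score, -sw.identity, template.length, template.name, template, sw))
    scored.sort(key=lambda r: r[:4])
    _, _, _, _, best_template, sw = scored[0]
    span_ok = sw.query_span_length >= 0.5 * min(len(seq), best_template.length)
    coverage = sw.target_span_length / best_template.length
    if (
        sw.score > 0
        and sw.identity >= cfg.first_round_identity_threshold
        and span_ok
        and coverage >= cfg.first_round_coverage
    ):
        return MEClassification(best_template.me_class, best_template.name, sw, "first")
    return MEClassification("none", best_template.name, sw, "unclassified")


def _distinct_kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def kmer_prescreen(consensus: str, lib: MELibrary, cfg: CallerConfig) -> bool:
    """True when the consensus shares enough distinct k-mers with a template.

    Checks each template on both strands; a consensus shorter than k fails.
    This plays the role of a fast preclassifier that excludes completely
    unrelated sequences before the (costlier) second round.
    """
    k = cfg.prescreen_k
    qkmers = _distinct_kmers(consensus, k)
    if not qkmers:
        return False
    for template in lib:
        tkmers = _distinct_kmers(template.sequence, k)
        tkmers |= _distinct_kmers(revcomp(template.sequence), k)
        if len(qkmers & tkmers) / len(qkmers) >= cfg.prescreen_min_fraction:
            return True
    return False


class SecondRoundClassifier(Protocol):
    """Plugin contract for the second classification round.

    ``classify`` receives the consensus sequence and the template library
    and returns ``(me_class, confidence)`` with me_class in
    {Alu, L1, SVA, none} and confidence in [0, 1]; the class is assigned
    only when confidence reaches the plugin's own ``threshold``.
    """

    threshold: float

    def classify(self, sequence: str, lib: MELibrary) -> tuple[str, float]: ...


class KmerProfileClassifier:
    """Baseline second-round model: per-class k-mer profile containment.

    For each class, the distinct k-mers (default k=6) of its templates and
    their reverse complements form the class profile; a sequence is scored
    per class by the fraction of its own k-mers contained in the profile and
    assigned to the best class when that fraction reaches ``threshold``.
    A stand-in for a fine-tuned transformer behind the same contract.
    """

    def __init__(self, lib: MELibrary, k: int = 6, threshold: float = 0.5) -> None:
        self.k = k
        self.threshold = threshold
        self._profiles: dict[str, set[str]] = {}
        for template in lib:
            kmers = _distinct_kmers(template.sequence, k)
            kmers |= _distinct_kmers(revcomp(template.sequence), k)
            self._profiles.setdefault(template.me_class, set()).update(kmers)

    def classify(self, sequence: str, lib: MELibrary) -> tuple[str, float]:
        qkmers = _distinct_kmers(sequence, self.k)
        if not qkmers:
            return "none", 0.0
        best_class, best_frac = "none", 0.0
        for me_class in sorted(self._profiles):
            frac = len(qkmers & self._profiles[me_class]) / len(qkmers)
            if frac > best_frac:
                best_class, best_frac = me_class, frac
        return best_class, best_frac


SECOND_ROUND_PLUGINS = {
    "kmer_profile": lambda lib, cfg: KmerProfileClassifier(lib),
}


def make_second_round_classifier(name: str, lib: MELibrary, cfg: CallerConfig) -> SecondRoundClassifier:
    try:
        factory = SECOND_ROUND_PLUGINS[name]
    except KeyError:
        raise ValueError(
            f"unknown second-round plugin {name!r}; registered: {sorted(SECOND_ROUND_PLUGINS)}"
        ) from None
    return factory(lib, cfg)


def classify_second_round(
    call: ConsensusCall,
    lib: MELibrary,
    model: SecondRoundClassifier,
    cfg: CallerConfig,
) -> MEClassification:
    """Delegate an unclassified consensus to the second-round plugin.

    A plugin exception is logged and leaves the call unclassified; the
    pipeline never crashes on a plugin.
    """
    try:
        me_class, confidence = model.classify(call.consensus_sequence, lib)
    except Exception:
        logger.exception("second-round plugin failed; call left unclassified")
        return MEClassification("none", None, None, "unclassified")
    if me_class != "none" and confidence >= model.threshold:
        return MEClassification(me_class, None, None, "second", second_round_score=confidence)
    return MEClassification("none", None, None, "unclassified", second_round_score=confidence)


def classify_consensus(
    call: ConsensusCall,
    lib: MELibrary,
    cfg: CallerConfig,
    model: Optional[SecondRoundClassifier] = None,
) -> MEClassification:
    """Full two-round classification of one consensus call."""
    result = classify_first_round(call, lib, cfg)
    if result.round == "first":
        return result
    if not cfg.second_round_enabled or model is None:
        return result
    if not kmer_prescreen(call.consensus_sequence, lib, cfg):
        return result
    second = classify_second_round(call, lib, model, cfg)
    return second if second.round == "second" else result
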