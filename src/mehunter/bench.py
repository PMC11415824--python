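"""Simulate-call-evaluate helper used by benchmarks and the acceptance suite."""

from __future__ import annotations

from pathlib import Path

import pysam

from mehunter.config import CallerConfig
from mehunter.evaluate import evaluate_callset, load_vcf_records
from mehunter.genotype import write_vcf
from mehunter.melib import MELibrary, builtin_library
from mehunter.pipeline import run_caller
from mehunter.simulate import SimParams, simulate_to_dir


def run_benchmark(
    out_dir: str | Path,
    seed: int,
    depth: float = 30.0,
    min_support: int = 3,
    genome_length: int = 1_000_000,
    n_mei_per_class: int = 30,
    n_med_per_class: int = 30,
    n_ordinary_sv: int = 60,
    lib: MELibrary | None = None,
    second_round_enabled: bool = True,
    window: int = 1000,
    size_ratio: float = 0.7,
    **sim_overrides,
) -> dict:
    """Simulate one replicate, run the caller, and score it against truth.

    Returns the call/truth records plus presence and genotype-aware metrics:
    ``mei_f1``/``med_f1`` (presence, per svtype), ``presence_f1`` (all MEVs),
    and ``gt_f1`` (TP requires locus, type, size, class, and genotype).
    """
    lib = lib or builtin_library()
    params = SimParams(
        genome_length=genome_length,
        n_mei_per_class=n_mei_per_class,
        n_med_per_class=n_med_per_class,
        n_ordinary_sv=n_ordinary_sv,
        depth=depth,
        seed=seed,
        **sim_overrides,
    )
    out = Path(out_dir)
    sim = simulate_to_dir(params, lib, str(out), write_reads_fastq=False)
    cfg = CallerConfig(min_support=min_support, second_round_enabled=second_round_enabled)
    calls, stats = run_caller(sim["paths"]["sam"], sim["paths"]["ref"], lib, cfg)
    vcf_path = out / "calls.vcf"
    with pysam.FastaFile(sim["paths"]["ref"]) as ref:
        write_vcf(calls, ref, str(vcf_path))
    call_records = load_vcf_records(str(vcf_path))
    all_truth = load_vcf_records(sim["paths"]["truth"])
    truth = [t for t in all_truth if t.me_class != "none"]
    ordinary = [t for t in all_truth if t.me_class == "none"]
    mei_truth = [t for t in truth if t.svtype == "INS"]
    med_truth = [t for t in truth if t.svtype == "DEL"]
    mei_calls = [c for c in call_records if c.svtype == "INS"]
    med_calls = [c for c in call_records if c.svtype == "DEL"]
    presence = evaluate_callset(call_records, truth, window, size_ratio, class_strict=False)
    strict = evaluate_callset(call_records, truth, window, size_ratio, class_strict=True)
    return {
        "params": params,
        "paths": sim["paths"],
        "stats": stats,
        "calls": call_records,
        "truth": truth,
        "ordinary_truth": ordinary,
        "mei_f1": evaluate_callset(mei_calls, mei_truth, window, size_ratio).f1,
        "med_f1": evaluate_callset(med_calls, med_truth, window, size_ratio).f1,
        "presence_f1": presence.f1,
        "presence": presence,
        "strict": strict,
        "gt_f1": strict.gt_f1,
    }


def ordinary_sv_class_fp_rate(result: dict, window: int = 1000, size_ratio: float = 0.7) -> float:
    """Fraction of ordinary (non-ME) truth SVs matched by an ME-classified call."""
    from mehunter.evaluate import match_calls

    ordinary = result["ordinary_truth"]
    if not ordinary:
        return 0.0
    match = match_calls(result["calls"], ordinary, window, size_ratio, class_strict=False)
    return match.tp / len(ordinary)
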