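import numpy as np
import pysam
import pytest

from mehunter.config import CallerConfig
from mehunter.evaluate import evaluate_callset, load_vcf_records
from mehunter.genotype import write_vcf
from mehunter.melib import builtin_library
from mehunter.pipeline import run_caller
from mehunter.simulate import SimParams, simulate_to_dir


@pytest.fixture(scope="session")
def lib():
    return builtin_library()


@pytest.fixture()
def cfg():
    return CallerConfig()


@pytest.fixture(scope="session")
def small_sim(lib, tmp_path_factory):
    """One small simulated dataset shared by read-level tests."""
    out = tmp_path_factory.mktemp("smallsim")
    params = SimParams(
        genome_length=300_000,
        n_mei_per_class=3,
        n_med_per_class=3,
        n_ordinary_sv=6,
        depth=30,
        seed=101,
    )
    result = simulate_to_dir(params, lib, str(out))
    result["params"] = params
    return result


def run_and_evaluate(sim_dir, lib, cfg, class_strict=True, write_path=None):
    """Run the caller on a simulation directory and score it against truth."""
    calls, stats = run_caller(f"{sim_dir}/reads.sam", f"{sim_dir}/ref.fa", lib, cfg)
    vcf_path = write_path or f"{sim_dir}/calls.vcf"
    with pysam.FastaFile(f"{sim_dir}/ref.fa") as ref:
        write_vcf(calls, ref, vcf_path)
    call_records = load_vcf_records(vcf_path)
    truth_records = [t for t in load_vcf_records(f"{sim_dir}/truth.vcf") if t.me_class != "none"]
    result = evaluate_callset(call_records, truth_records, class_strict=class_strict)
    return result, call_records, truth_records


def random_dna(rng, length):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])
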