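import numpy as np
import pytest

from l1trace import harvest as hv
from l1trace import simgenome as sg
from l1trace.cli import PipelineConfig, run_pipeline


@pytest.fixture(scope="session")
def demo():
    """A three-family amplification scenario with simulated genome + truth."""
    bundle = sg.demo_scenario(seed=5, n_families=3, n_inserts=60)
    genome, truth = sg.simulate_history(bundle.scenario)
    return {"bundle": bundle, "genome": genome, "truth": truth}


@pytest.fixture(scope="session")
def harvested(demo):
    elements, rejections = hv.harvest_genome(
        demo["genome"], demo["bundle"].rt_query, demo["bundle"].motif_library
    )
    return {"elements": elements, "rejections": rejections}


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """A completed end-to-end pipeline run on a small simulated scenario."""
    outdir = tmp_path_factory.mktemp("run") / "out"
    cfg = PipelineConfig(
        seed=5,
        outdir=str(outdir),
        simulate={"n_families": 3, "n_inserts": 60},
        thresholds={"bootstrap_reps": 100, "recomb_permutations": 300},
    )
    run_pipeline(cfg)
    return outdir


def tiny_family_spec(
    rng: np.random.Generator,
    name: str = "fam",
    length: int = 1000,
    n_inserts: int = 20,
    t_start: float = 10.0,
    t_end: float = 0.0,
    **kw,
) -> sg.FamilySpec:
    """A compact element for fast simulator-level tests."""
    seq = sg._random_dna(rng, length, 0.45)
    spans = {
        "5UTR": (0, length * 3 // 10),
        "ORF1": (length * 3 // 10, length // 2),
        "IGR": (length // 2, length * 11 // 20),
        "ORF2": (length * 11 // 20, length * 9 // 10),
        "3UTR": (length * 9 // 10, length),
    }
    return sg.FamilySpec(
        name=name,
        source_sequence=seq,
        feature_spans=spans,
        promoter_type=1,
        t_start=t_start,
        t_end=t_end,
        n_inserts=n_inserts,
        **kw,
    )
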