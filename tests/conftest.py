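"""Shared fixtures: a seeded planted-signal benchmark and a trained pipeline.

Heavy objects (generated benchmark tables, a trained single-target model, the
dual-target pipeline run) are session-scoped so the suite trains each model
once.  All randomness is seeded; the tuning grid used for benchmark-scale
training is the desk-scale grid documented in docs/methods.md.
"""

from __future__ import annotations

import pytest
from hypothesis import settings

from ersar.model import ModelConfig
from ersar.pipeline import PipelineConfig, save_artifact, train_target
from ersar.synth import BenchmarkSpec, generate_benchmark

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")

#: Desk-scale tuning grid for benchmark training (see docs/methods.md).
BENCH_MODEL = ModelConfig(ntree_grid=(100, 200), mtry_grid=(5, 10), seed=1)
BENCH_CONFIG = PipelineConfig(model=BENCH_MODEL)


def bench_config(seed: int) -> PipelineConfig:
    return PipelineConfig(model=ModelConfig(ntree_grid=(100, 200), mtry_grid=(5, 10), seed=seed))


@pytest.fixture(scope="session")
def benchmark():
    """Noise-free 150+150 benchmark (seed 1): records + truth manifest."""
    records, manifest = generate_benchmark(BenchmarkSpec(seed=1))
    return records, manifest


@pytest.fixture(scope="session")
def trained(benchmark):
    """Single-target pipeline result on the seed-1 benchmark."""
    records, _ = benchmark
    return train_target(records, BENCH_CONFIG, target_name="ERalpha", seed=1)


@pytest.fixture(scope="session")
def artifact_dir(tmp_path_factory, trained):
    out = tmp_path_factory.mktemp("artifact") / "alpha"
    save_artifact(trained, BENCH_CONFIG, out)
    return out


@pytest.fixture(scope="session")
def dual_tables(tmp_path_factory):
    """Two benchmark activity tables (different seeds) on disk."""
    root = tmp_path_factory.mktemp("tables")
    alpha, beta = root / "alpha.csv", root / "beta.csv"
    generate_benchmark(BenchmarkSpec(seed=11), table_path=alpha)
    generate_benchmark(BenchmarkSpec(seed=12), table_path=beta)
    return alpha, beta
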