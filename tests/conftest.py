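import json
from pathlib import Path

import numpy as np
import pytest

from vetstar.benchmark import load_benchmark, small_benchmark_config, small_train_config
from vetstar.model import build_vetstar, widen_student
from vetstar.train import train


@pytest.fixture(scope="session")
def bench(tmp_path_factory):
    """Small 256-px benchmark: (config, train_ds, val_ds, test_ds, manifest)."""
    root = tmp_path_factory.mktemp("bench")
    cfg = small_benchmark_config(root, seed=0)
    tr, va, te = load_benchmark(cfg)
    manifest = json.loads((Path(cfg.out_dir) / "manifest.json").read_text())
    return cfg, tr, va, te, manifest


@pytest.fixture(scope="session")
def trained_student(bench):
    """Reference VetStar trained on the benchmark (seed 0); shared across tests."""
    _, tr, va, _, _ = bench
    model = build_vetstar(seed=0)
    result = train(model, tr, va, small_train_config(seed=0))
    return model, result


@pytest.fixture(scope="session")
def teacher(trained_student, bench):
    """Widened (4×) teacher: function-preserving widening + short fine-tune."""
    student, _ = trained_student
    _, tr, va, _, _ = bench
    t = widen_student(student, factor=4, noise=0.02, seed=0)
    result = train(t, tr, va, small_train_config(seed=0, max_epochs=20, lr=3e-4))
    return t, result


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
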