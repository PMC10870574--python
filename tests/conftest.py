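import json
import warnings
from pathlib import Path

import pytest

from actionreview.config import GeneratorConfig, reference_corpus_config
from actionreview.generate import generate_corpus
from actionreview.pipeline import run_pipeline


@pytest.fixture(scope="session")
def small_corpus():
    """A small fully rendered corpus for unit-level checks."""
    cfg = GeneratorConfig(seed=7, n_clients=10, n_therapists=4, n_organizations=2)
    return generate_corpus(cfg)


@pytest.fixture(scope="session")
def reference_run(tmp_path_factory):
    """The seeded reference corpus pushed through the full text pipeline once.

    Returns (config, run_dir). Several detector/review/GEE checks share it.
    """
    cfg = reference_corpus_config()
    out = tmp_path_factory.mktemp("reference_run")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        run_pipeline(cfg, out, bootstrap_reps=80)
    return cfg, Path(out)


def load_json(path: Path) -> dict:
    return json.loads(Path(path).read_text())
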