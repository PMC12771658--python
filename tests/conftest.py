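import numpy as np
import pandas as pd
import pytest

from divebudget.acc_features import correlation_filter
from divebudget.classifier import evaluate, predict, stratified_split, train
from divebudget.cli_io import PipelineConfig, run_all
from divebudget.synthetic_data import (
    WorldConfig, default_signature_model, generate_labelled_features, generate_world,
)

N_PER_CLASS_200 = {b: 200 for b in ("feeding", "flying", "preening", "resting")}


@pytest.fixture(scope="session")
def labelled_200():
    """200 labelled bursts per class from the default signature model."""
    return generate_labelled_features(N_PER_CLASS_200, default_signature_model(), seed=11)


@pytest.fixture(scope="session")
def trained_200(labelled_200):
    """(model, train split, test split, EvalReport) on the 200/class set."""
    retained, _ = correlation_filter(labelled_200)
    tr, te = stratified_split(labelled_200, seed=11)
    model = train(tr, seed=11, feature_names=retained)
    report = evaluate(te["behavior"], predict(model, te), classes=model.classes)
    return model, tr, te, report


@pytest.fixture(scope="session")
def small_world():
    """2 birds x 2 days with waveforms (for fast structural checks)."""
    return generate_world(WorldConfig(n_birds=2, n_days=2, seed=5))


@pytest.fixture(scope="session")
def pipeline_report(tmp_path_factory):
    """Full run_all on the default synthetic world (one run per session)."""
    out = tmp_path_factory.mktemp("pipeline")
    cfg = PipelineConfig(out_dir=str(out), seed=123)
    return run_all(cfg)
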