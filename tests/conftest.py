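import numpy as np
import pytest

import pancrisk as pk


@pytest.fixture(scope="session")
def small_cohort():
    """A small enriched cohort with planted risk codes (shared, read-only)."""
    cfg = pk.SimConfig(
        n_patients=300,
        target_case_fraction=0.1,
        visit_rate=6.0,
        record_span_years=(2.0, 10.0),
        planted_risk_codes=(("A20", 8.0), ("M012", 8.0)),
        seed=42,
    )
    cohort, meta = pk.generate_cohort(cfg)
    return cohort, meta, cfg


@pytest.fixture(scope="session")
def small_trajectories(small_cohort):
    cohort, _, _ = small_cohort
    prepared = pk.prepare_cohort(cohort, 3)
    rng = np.random.default_rng(0)
    trajs = [
        t
        for rec in prepared
        for t in pk.sample_training_trajectories(rec, 2, rng, max_len=48, exclusion_months=3, censoring="zero_fill")
    ]
    vocab = pk.build_vocab(prepared)
    return trajs, vocab


@pytest.fixture(scope="session")
def tiny_trained_model(small_cohort):
    """A small transformer trained for a few epochs on the planted-signal cohort."""
    cohort, _, _ = small_cohort
    prepared = pk.prepare_cohort(cohort, 3)
    train_pat, dev_pat, _ = pk.split_patients(prepared, (0.8, 0.1, 0.1), 1)
    tc = pk.TrainConfig(
        L=1, H=2, d=16, lr=0.01, epochs_max=3, batch_size=64, max_len=48,
        exclusion_months=3, censoring="zero_fill", seed=1,
    )
    model, params, history = pk.train(train_pat, dev_pat, tc)
    return model, params, history
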