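"""Shared fixtures: small synthetic cohorts and a trained fold ensemble.

Everything is generated programmatically and seeded, so the suite is
fully reproducible and ships no data files.
"""

from __future__ import annotations

import numpy as np
import pytest

import bruganet as bn


def match_peaks(detected: np.ndarray, truth: np.ndarray, fs: float,
                tol_ms: float = 50.0) -> tuple[float, float]:
    """Greedy one-to-one matching of detected to planted R peaks.

    Returns (recall, precision) at the given tolerance.
    """
    detected = np.asarray(detected, dtype=float)
    truth = np.asarray(truth, dtype=float)
    tol = tol_ms / 1000.0 * fs
    used = np.zeros(len(detected), dtype=bool)
    hits = 0
    for t in truth:
        d = np.abs(detected - t)
        d[used] = np.inf
        j = int(np.argmin(d))
        if d[j] <= tol:
            used[j] = True
            hits += 1
    recall = hits / len(truth) if len(truth) else 1.0
    precision = used.sum() / len(detected) if len(detected) else 1.0
    return recall, precision


@pytest.fixture(scope="session")
def clean_spec() -> bn.CohortSpec:
    """A low-noise, artifact-free mortara cohort spec for oracle tests."""
    return bn.CohortSpec(n=1, duration_s=20.0, rr_sd=0.0, noise_sd=0.0,
                         wander_amp=0.0, powerline_amp=0.0,
                         artifact_beat_rate=0.0, dialect="mortara", seed=0)


@pytest.fixture(scope="session")
def small_cohort():
    """12 labeled records (20 s each) with the default study conditions."""
    spec = bn.CohortSpec(n=12, duration_s=20.0, seed=42)
    records, labels, truths = bn.synthesize_cohort(spec)
    return spec, records, labels, truths


@pytest.fixture(scope="session")
def fused_cohort():
    """A preprocessed 60-patient cohort: (X, y) design matrix and labels."""
    spec = bn.CohortSpec(n=60, duration_s=20.0, seed=7)
    records, y, truths = bn.synthesize_cohort(spec)
    X, ids = bn.preprocess_cohort(records)
    return X, y, truths


@pytest.fixture(scope="session")
def attribution_model(fused_cohort):
    """A single attribution-grade classifier (long training, strong
    noise and weight decay, per-lead standardized inputs) plus the
    standardized design matrix it was trained on."""
    from bruganet.importance import attribution_estimator, per_lead_standardize

    X, y, _ = fused_cohort
    Xs = per_lead_standardize(X)
    clf = attribution_estimator(random_state=0).fit(Xs, y)
    return clf, Xs, y


@pytest.fixture(scope="session")
def study_cohort_200():
    """The full-size study cohort: 200 patients, 0.3 mV effect,
    0.02 mV noise, prevalence 0.5, base seed."""
    spec = bn.CohortSpec(n=200, duration_s=20.0, effect=0.3, noise_sd=0.02,
                         prevalence=0.5, seed=0)
    records, y, _ = bn.synthesize_cohort(spec)
    X, _ = bn.preprocess_cohort(records)
    return X, y


@pytest.fixture(scope="session")
def trained_ensemble(fused_cohort):
    """A 7-fold ensemble trained on the 60-patient synthetic cohort."""
    X, y, _ = fused_cohort
    est = bn.DenseNoiseClassifier(hidden_sizes=(32, 32, 32), max_epochs=120,
                                  patience=15, batch_size=32, random_state=0)
    ens = bn.FoldEnsembleClassifier(estimator=est, random_state=3)
    return ens.fit(X, y)
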