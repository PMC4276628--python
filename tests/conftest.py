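"""Shared fixtures: generative truths, calibrated systems, observed series.

Calibration is expensive relative to a unit test, so corpora and
fitted systems are session-scoped; everything is seeded and
regenerated at run time (no stored fixtures).
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import mltkit as mk


@pytest.fixture(scope="session")
def truth_male():
    return mk.default_truth_coefficients("male")


@pytest.fixture(scope="session")
def truth_female():
    return mk.default_truth_coefficients("female")


@pytest.fixture(scope="session")
def clean_corpus(truth_male):
    """Noise-free 200-table corpus from the male truth (recovery tests)."""
    tables, truth = mk.generate_corpus(mk.CorpusConfig(n_tables=200, seed=0))
    return tables, truth


@pytest.fixture(scope="session")
def family_corpus():
    """Corpus with 5 family patterns, mild noise (pipeline calibrations)."""
    patterns = mk.family_deviation_patterns(5, spread=0.10)
    cfg = mk.CorpusConfig(n_tables=250, k_bounds=(-0.3, 0.3), noise_sd=0.005,
                          family_patterns=patterns, seed=7)
    return mk.generate_corpus(cfg)


@pytest.fixture(scope="session")
def calibrated_systems():
    """Per-sex {logquad, modlogit, family} fitted on family corpora."""
    patterns = mk.family_deviation_patterns(5, spread=0.10)
    out = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for sex in ("male", "female"):
            truth = mk.default_truth_coefficients(sex)
            tables, _ = mk.generate_corpus(
                mk.CorpusConfig(n_tables=250, k_bounds=(-0.3, 0.3), noise_sd=0.005,
                                family_patterns=patterns, coeffs=truth, seed=7))
            out[sex] = {
                "logquad": mk.fit_logquad(tables, sex),
                "modlogit": mk.build_standard(tables, sex),
                "family": mk.fit_families(tables, sex, K=5, seed=7),
            }
    return out


@pytest.fixture(scope="session")
def china_series():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return mk.generate_china_like_series()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
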