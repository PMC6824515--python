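"""Shared fixtures: small matrices and the three simulated study cohorts.

Cohort fixtures are session-scoped because simulating and scoring a cohort
(ICE, γ sweeps, three measures over all pairs) is the expensive part of the
suite and several tests interrogate different aspects of the same cohort.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from tadvar.pipeline import prepare_cohort, score_pairs
from tadvar.stats_compare import build_pair_table, run_comparison_suite
from tadvar.synthetic_data import (
    make_cohort,
    protocol_cohort_config,
    replicate_cohort_config,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def _analyse(cohort, config):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        scoring = prepare_cohort(cohort, config)
        replicate_scores, merged_scores = score_pairs(scoring)
        meta = [m for s in scoring.included_samples for m in s.meta]
        pairs = build_pair_table(meta, replicate_scores, merged_scores)
        results = run_comparison_suite(pairs)
    return scoring, pairs, results


@pytest.fixture(scope="session")
def standard_cohort_analysis():
    """10 cell types x 2 replicates, boundary perturbation 0.3 between types."""
    cohort = make_cohort(replicate_cohort_config(seed=7))
    return _analyse(cohort, {"seed": 7})


@pytest.fixture(scope="session")
def null_cohort_analysis():
    """No between-type perturbation, depth-matched scoring: no true contrast."""
    cohort = make_cohort(replicate_cohort_config(perturb_rate=0.0, seed=8))
    return _analyse(cohort, {"seed": 8, "merge_replicates": False})


@pytest.fixture(scope="session")
def protocol_cohort_analysis():
    """12 cell types x 2 samples with mixed in-situ/dilution protocols."""
    cohort = make_cohort(protocol_cohort_config(seed=9))
    return _analyse(cohort, {"seed": 9})


def contrast_results(results, contrast):
    """Index suite results by measure for one named contrast."""
    return {
        r.measure: r for r in results if r.group_a == f"{contrast}:a" and r.error is None
    }
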