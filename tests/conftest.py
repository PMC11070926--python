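"""Shared fixtures: small deterministic cohorts and group summaries."""

from __future__ import annotations

import numpy as np
import pytest

from cordrbe.actuarial import DoseGroupSummary
from cordrbe.synthetic_cohort import CohortDesign, TrueResponseParams


def make_groups(doses, probs, n_eff=1000.0, n_fractions=1, label="x", let=26.0):
    """DoseGroupSummary list with exact response probabilities."""
    out = []
    for d, p in zip(doses, probs):
        var = p * (1 - p) / n_eff if 0 < p < 1 else 0.0
        out.append(DoseGroupSummary(
            radiation_label=label, let_value=let, n_fractions=n_fractions,
            total_dose=float(d), n_crude=int(round(n_eff)), p_actuarial=float(p),
            var_p=var, n_eff=float(n_eff), r_eff=float(n_eff * p),
        ))
    return out


@pytest.fixture
def single_design():
    return CohortDesign("sim", 26.0, 35.0, 1, tuple(15.5 + i for i in range(6)))


@pytest.fixture
def split_design():
    return CohortDesign("sim", 26.0, 35.0, 2, tuple(18.0 + i for i in range(8)))


@pytest.fixture
def simple_truth():
    return TrueResponseParams(ed50_total_dose=18.0, logistic_slope=1.2)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
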