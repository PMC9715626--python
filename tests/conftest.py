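"""Shared fixtures: simulated experiments reused across the suite.

The heavyweight fixtures are session-scoped: one simulated study day
(two 600 s baseline sessions in environments A and B, template
construction, and post-teleportation test sessions with injected
out-context / mixed theta cycles) serves the integration, recovery and
direction-of-effect tests alike.
"""
from __future__ import annotations

import numpy as np
import pytest

from thetaflicker import AnalysisConfig, run_pipeline
from thetaflicker import simulate as sim
from thetaflicker.arena import Arena
from thetaflicker.classify import compute_pesi, eligible_bins
from thetaflicker.preprocess import build_templates

EXPERIMENT_SEED = 11


@pytest.fixture(scope="session")
def arena() -> Arena:
    return Arena()


@pytest.fixture(scope="session")
def cell_library(arena):
    return sim.make_cell_library(seed=3, arena=arena)


@pytest.fixture(scope="session")
def pre_sessions(cell_library, arena):
    """Two baseline sessions (A then B) with baseline-level flickers."""
    specs = [
        sim.SessionSpec("PRE1", "PRE1", "A", flicker_rate_per_1000tc=1.9, mixed_fraction=0.31),
        sim.SessionSpec("PRE2", "PRE2", "B", flicker_rate_per_1000tc=1.9, mixed_fraction=0.31),
    ]
    return sim.simulate_experiment(cell_library, specs, arena, seed=EXPERIMENT_SEED)


@pytest.fixture(scope="session")
def template_bundle(pre_sessions, arena):
    """Templates, specificity and eligibility estimated from the PRE halves."""
    templates, baseline = build_templates(
        {env: (s.track, s.spikes) for env, s in ((ss.spec.env, ss) for ss in pre_sessions.values())},
        arena,
    )
    pesi = compute_pesi(templates)
    elig = eligible_bins(pesi).eligible
    return {"templates": templates, "baseline": baseline, "pesi": pesi, "eligibility": elig}


def _post_pair(cell_library, arena, template_bundle, rate, mixed_fraction, decay, seed0):
    ss = np.random.SeedSequence(seed0)
    out = {}
    for k, (name, env) in enumerate((("POST1", "POST1"), ("POST2", "POST2"))):
        envid = "A" if k == 0 else "B"
        child = ss.spawn(2)[k]
        s = sim.simulate_session(
            sim.SessionSpec(name, name, envid), cell_library, arena, seed=child
        )
        s = sim.inject_flicker_cycles(
            s,
            rate,
            mixed_fraction,
            seed=seed0 + 100 + k,
            rate_decay=decay,
            eligibility=template_bundle["eligibility"],
            specificity=template_bundle["pesi"],
        )
        out[name] = s
    return out


@pytest.fixture(scope="session")
def recovery_experiment(pre_sessions, cell_library, arena, template_bundle):
    """PRE pair + POST pair with a high, known injection rate.

    36 events / 1000 eligible TC with 4/9 mixed gives 20 / 1000 TC of pure
    out-context cycles and 16 / 1000 TC of mixed cycles -- the parameter-
    recovery condition.
    """
    posts = _post_pair(cell_library, arena, template_bundle, 36.0, 4.0 / 9.0, 1.0, 77)
    return {**pre_sessions, **posts}


@pytest.fixture(scope="session")
def recovery_report(recovery_experiment):
    return run_pipeline(recovery_experiment, AnalysisConfig())


@pytest.fixture(scope="session")
def teleportation_experiment(pre_sessions, cell_library, arena, template_bundle):
    """The study-day conditions: baseline PRE rates, POST sessions at
    in-vivo-scale flicker rates with a ~3x within-session decay."""
    posts = _post_pair(cell_library, arena, template_bundle, 5.6, 0.36, 3.0, 55)
    return {**pre_sessions, **posts}


@pytest.fixture(scope="session")
def teleportation_report(teleportation_experiment):
    return run_pipeline(teleportation_experiment, AnalysisConfig())


@pytest.fixture(scope="session")
def null_report(pre_sessions, cell_library, arena, template_bundle):
    """Report for a POST session without any injected events (false-positive
    baseline)."""
    child = np.random.SeedSequence(991).spawn(1)[0]
    post = sim.simulate_session(
        sim.SessionSpec("POST1", "POST1", "A"), cell_library, arena, seed=child
    )
    return run_pipeline({**pre_sessions, "POST1": post}, AnalysisConfig())
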