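"""Shared fixtures: analytic grids, planted-gyre study runs, presets."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

import reefconn as rc


@pytest.fixture(scope="session")
def grid():
    return rc.GridSpec(0.0, 2000.0, 0.0, 1000.0, 40, 20)


@pytest.fixture(scope="session")
def wide_grid():
    """Large open box for uniform-flow displacement checks."""
    return rc.GridSpec(0.0, 20000.0, 0.0, 2000.0, 50, 10)


@pytest.fixture(scope="session")
def short_params():
    """Platygyra-type larval parameters capped at a 30-day drift."""
    return dataclasses.replace(rc.PRESETS["platygyra_daedalea"], t_max=30.0)


def _run_pipeline(tmp_path_factory, name, seed, perturbation):
    cfg = rc.demo_config(seed=seed)
    cfg = cfg.model_copy(
        update={"ocean": cfg.ocean.model_copy(update={"perturbation": perturbation})}
    )
    outdir = tmp_path_factory.mktemp(name)
    rc.run_pipeline(cfg, outdir)
    return outdir


@pytest.fixture(scope="session")
def demo_run(tmp_path_factory):
    """Impermeable double gyre (perturbation 0): exact transport barrier."""
    return _run_pipeline(tmp_path_factory, "demo_run", seed=11, perturbation=0.0)


@pytest.fixture(scope="session")
def weak_run(tmp_path_factory):
    """Perturbed double gyre (0.05): weak leakage across the separatrix."""
    return _run_pipeline(tmp_path_factory, "weak_run", seed=12, perturbation=0.05)


@pytest.fixture(scope="session")
def mini_sim(grid, short_params):
    """One spawning date on the perturbed gyre: trajectories, fate, events."""
    field = rc.make_double_gyre(0.05, 0.05, grid, period=10.0)
    reef = rc.make_reef_grid(
        [(950.0, 300.0), (950.0, 700.0), (1050.0, 300.0), (1050.0, 700.0)],
        4,
        grid,
        seed=3,
    )
    release = rc.release_from_reefs(reef, short_params.n_per_cell, "2000-11-10")
    traj = rc.advect(field, release, dt=0.02, t_max=30.0)
    fr = rc.sample_reef_fraction(traj, reef)
    fate = rc.integrate_fate(traj.times, fr, short_params)
    events = rc.settle_events(traj, fate, reef, short_params)
    return {
        "field": field,
        "reef": reef,
        "release": release,
        "traj": traj,
        "fr": fr,
        "fate": fate,
        "events": events,
        "params": short_params,
    }
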