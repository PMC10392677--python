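"""Shared fixtures: small synthetic systems generated at test time."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from dnamech import (SyntheticSpec, SystemLabel, build_coordinates,
                     default_system_spec, generate_helical_ensemble)
from dnamech.synthetic_data import IonModel, MeanOverride

warnings.filterwarnings("ignore", module="MDAnalysis")


def straight_spec(**kw) -> SyntheticSpec:
    """A perfectly regular fiber duplex: twist 36 deg, rise 3.4 A, all
    other parameters at their idealized zero/default values, no noise."""
    n_bp = len(kw.get("sequence", SyntheticSpec().sequence))
    steps = tuple(range(1, n_bp))
    bps = tuple(range(1, n_bp + 1))
    overrides = tuple(
        MeanOverride(p, steps, v) for p, v in
        [("shift", 0.0), ("slide", 0.0), ("rise", 3.4),
         ("tilt", 0.0), ("roll", 0.0), ("twist", 36.0)]
    ) + tuple(
        MeanOverride(p, bps, v) for p, v in
        [("shear", 0.0), ("stretch", 0.0), ("stagger", 0.0),
         ("buckle", 0.0), ("propeller", 0.0), ("opening", 0.0)]
    )
    defaults = dict(n_frames=2, covariance_scale=0.0,
                    mean_overrides=overrides, ions=IonModel(molarity=0.0))
    defaults.update(kw)
    return SyntheticSpec(**defaults)


@pytest.fixture(scope="session")
def fiber_traj():
    spec = straight_spec()
    ens = generate_helical_ensemble(spec)
    return build_coordinates(ens, spec)


@pytest.fixture(scope="session")
def wt_naked_ensemble():
    spec = default_system_spec(SystemLabel("WT", "naked"),
                               n_frames=2000, seed=11)
    return generate_helical_ensemble(spec)


@pytest.fixture(scope="session")
def small_system():
    """A bound system with scripted contacts and ions, 60 frames."""
    spec = default_system_spec(SystemLabel("WT", "E2F1DP1"),
                               n_frames=60, seed=5)
    ens = generate_helical_ensemble(spec)
    traj = build_coordinates(ens, spec)
    return spec, ens, traj
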