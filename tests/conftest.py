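"""Shared fixtures: one small phantom and solved plan reused across the
suite, plus the seeded cohort that backs the beam-angle and beam-count
studies (built once per session — it is by far the most expensive
fixture)."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

import lexiplan as lp
from lexiplan import studies


@pytest.fixture(scope="session")
def geometry():
    return studies.STUDY_GEOMETRY


@pytest.fixture(scope="session")
def small_phantom():
    return lp.generate_phantom(studies.STUDY_PHANTOM_CONFIG, seed=3)


@pytest.fixture(scope="session")
def derived(small_phantom):
    return lp.derive_structures(small_phantom)


@pytest.fixture(scope="session")
def wishlist66():
    return lp.build_wishlist(66.0)


@pytest.fixture(scope="session")
def influence_template(small_phantom, geometry):
    return lp.compute_influence(small_phantom, lp.DEFAULT_TEMPLATE_ANGLES, geometry)


@pytest.fixture(scope="session")
def fmo_plan(small_phantom, influence_template, wishlist66, derived):
    """Two-round FMO plan at the fixed template angles."""
    return lp.solve_wishlist_plan(
        small_phantom, influence_template, wishlist66, derived
    )


@pytest.fixture(scope="session")
def cohort():
    """Seeded multi-phantom beam-count study (nested 4/6/8-beam plans plus
    a fixed-template plan per subject).  Shared by the beam-angle and
    trend tests."""
    return studies.beam_count_cohort(n_subjects=10, seed=2026)


def tiny_wishlist(bound=10.0):
    """A 2-objective Mean-only wish-list on abstract structures, feasible
    with a single beam; used where the full clinical list would be
    infeasible at low beam counts."""
    return lp.WishList(
        D_p=66.0,
        hard_constraints=[
            lp.wishlist.HardConstraint("target", "Mean", bound, sense="ge"),
            lp.wishlist.HardConstraint("target", "Max", bound * 2.0),
        ],
        objectives=[
            lp.Objective(1, "avoid", "Mean", goal=0.0),
            lp.Objective(2, "other", "Mean", goal=0.0),
        ],
    )
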