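"""Cohort-level experiment arms: seeded phantom populations, the
beam-count study (4/6/8 optimized beams from one nested greedy run) and
the BAO-versus-fixed-template comparison.

These are the desk-scale analogues of a planning-study cohort: each
"subject" is a seeded phantom; per subject one greedy BAO trajectory
yields nested plans for every requested beam count, and a fixed
anterior-posterior-weighted template plan provides the no-BAO reference
arm.

Study conditions (fixed once, used by the test-suite, the examples and
the acceptance script alike):

* phantom — the compact 3 mm-voxel thorax with the PTV reaching from the
  ipsilateral lung into the mediastinum (tumor offset 55 mm), the
  dominant presentation when nodal volumes are included in the target;
* transport — 15 mm beamlets, 2 mm ray step;
* candidate arc — ipsilateral arc at 26 degree spacing (11 candidates), a
  desk-scale thinning of the clinical 5 degree arc;
* prescription 66 Gy.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .bao import DEFAULT_TEMPLATE_ANGLES, greedy_bao, plan_without_bao
from .dose import BeamGeometry, candidate_angles
from .fmo import FluencePlan
from .metrics import dose_metric, normalize_plan
from .phantom import SMALL_CONFIG, derive_structures, generate_phantom
from .wishlist import build_wishlist

STUDY_PHANTOM_CONFIG = dataclasses.replace(SMALL_CONFIG, tumor_offset_mm=(55.0, 10.0))
STUDY_GEOMETRY = BeamGeometry(beamlet_width_mm=15.0, step_mm=2.0)
STUDY_CANDIDATE_SPACING_DEG = 26.0
STUDY_D_P = 66.0


@dataclass
class Subject:
    """One cohort member: phantom seed, nested beam-count plans and the
    fixed-template reference plan (all PTV-median normalized)."""

    seed: int
    phantom: object
    plans_by_beams: dict[int, FluencePlan]
    template_plan: FluencePlan | None
    bao_result: object = field(default=None, repr=False)


def subject_seeds(n_subjects: int, seed: int) -> list[int]:
    """Independent per-subject phantom seeds derived from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_subjects)]


def beam_count_cohort(
    n_subjects: int = 10,
    seed: int = 2026,
    *,
    n_beams=(4, 6, 8),
    D_p: float = STUDY_D_P,
    with_template_arm: bool = True,
    config=None,
    geometry: BeamGeometry | None = None,
    candidate_spacing_deg: float = STUDY_CANDIDATE_SPACING_DEG,
) -> list[Subject]:
    """Run the full study on a seeded phantom population.

    Per subject: one greedy BAO trajectory to ``max(n_beams)`` beams
    (nested prefixes give every smaller count) and, optionally, a
    fixed-template plan with the clinical default 6-beam arrangement.
    """
    config = config or STUDY_PHANTOM_CONFIG
    geometry = geometry or STUDY_GEOMETRY
    wishlist = build_wishlist(D_p)
    n_max = int(max(n_beams))
    subjects = []
    for s in subject_seeds(n_subjects, seed):
        ph = generate_phantom(
            dataclasses.replace(config, prescription_Gy=D_p), seed=s
        )
        der = derive_structures(ph)
        cand = candidate_angles(ph.laterality, candidate_spacing_deg)
        result = greedy_bao(
            ph, wishlist, cand, n_beams=n_max, geometry=geometry, derived=der
        )
        plans = {
            int(k): normalize_plan(result.plans_by_k[int(k)], D_p)
            for k in n_beams
            if int(k) in result.plans_by_k
        }
        template = None
        if with_template_arm:
            template = normalize_plan(
                plan_without_bao(
                    ph, wishlist, DEFAULT_TEMPLATE_ANGLES,
                    geometry=geometry, derived=der,
                ),
                D_p,
            )
        subjects.append(Subject(s, ph, plans, template, result))
    return subjects


def cohort_metric(
    subjects: list[Subject], beams: int, structure: str, metric: str
) -> np.ndarray:
    """Per-subject dose metric for one beam count."""
    return np.array(
        [
            dose_metric(
                sub.plans_by_beams[beams].structure_dose(structure),
                metric,
                D_p=sub.plans_by_beams[beams].prescription_Gy,
            )
            for sub in subjects
        ]
    )


def beam_count_deltas(
    subjects: list[Subject], structure: str, metric: str = "D_mean",
    reference_beams: int = 6,
) -> dict[int, np.ndarray]:
    """Per-subject metric change versus the reference beam count."""
    ref = cohort_metric(subjects, reference_beams, structure, metric)
    out = {}
    for k in sorted(subjects[0].plans_by_beams):
        if k != reference_beams:
            out[k] = cohort_metric(subjects, k, structure, metric) - ref
    return out
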