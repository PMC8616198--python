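"""Integrated beam-angle optimization (BAO) over a candidate arc.

Beams are selected greedily: starting from the empty set, each iteration
runs the *full* two-round lexicographic FMO for every unused candidate
angle added to the current set, and keeps the candidate whose
goal-clamped round-1 score vector is lexicographically best (see
:meth:`lexiplan.fmo.FluencePlan.score_vector` for why that vector, and
not the final achieved values, is the sound comparison).  Judging candidates by the
same wish-list optimization that produces the final plan — rather than by
a surrogate geometric score — is what makes the angle selection
"integrated".  Ties go to the earliest candidate in the arc ordering,
which together with deterministic solvers makes runs reproducible.

The greedy scheme is this package's own search strategy; exhaustive
search over all beam subsets is exponential and only used as a test
oracle at tiny sizes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np

from .dose import candidate_angles, compute_influence
from .fmo import (
    FluencePlan,
    InfeasibleStageError,
    elastic_infeasibility,
    lexicographic_solve,
    structures_from_phantom,
)
from .phantom import Phantom, derive_structures
from .wishlist import WishList

logger = logging.getLogger(__name__)

#: Six-beam template with anterior-posterior emphasis plus obliques —
#: the class of fixed configurations the no-BAO mode emulates.
DEFAULT_TEMPLATE_ANGLES = (0.0, 35.0, 155.0, 180.0, 205.0, 325.0)

A_BETTER = "a_better"
B_BETTER = "b_better"
TIE = "tie"


def lexicographic_compare(a, b, tolerance: float = 1e-6) -> str:
    """Compare two objective vectors lexicographically (lower is better).

    The first index where the values differ by more than ``tolerance``
    decides; equal-within-tolerance entries are skipped.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"objective vectors differ in length: {a.shape} vs {b.shape}")
    for ai, bi in zip(a, b):
        if abs(ai - bi) > tolerance:
            return A_BETTER if ai < bi else B_BETTER
    return TIE


@dataclass
class BAOResult:
    """Greedy BAO trajectory: selected angles, per-iteration candidate
    scores, and the nested k-beam plans.

    Iterations listed in ``bootstrap_iterations`` had no feasible
    candidate (too few beams to honour the hard constraints); there the
    per-candidate score is the single elastic-infeasibility value and no
    plan is recorded for that beam count.
    """

    selected_angles: list[float]
    iteration_scores: list[dict[float, list[float]]]
    plans_by_k: dict[int, FluencePlan]
    n_beams: int
    bootstrap_iterations: list[int] = None  # type: ignore[assignment]

    @property
    def final_plan(self) -> FluencePlan:
        return self.plans_by_k[self.n_beams]

    def to_json(self, path=None) -> str:
        payload = {
            "selected_angles": self.selected_angles,
            "n_beams": self.n_beams,
            "iteration_scores": [
                {str(a): list(map(float, v)) for a, v in scores.items()}
                for scores in self.iteration_scores
            ],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as f:
                f.write(text)
        return text


def _solve_subset(influence_all, structures, wishlist, beam_ids):
    sub = influence_all.subset_beams(np.asarray(beam_ids))
    return lexicographic_solve(
        sub.matrix,
        wishlist,
        structures,
        angles_deg=sub.angles_deg,
        prescription_Gy=wishlist.D_p,
    )


def _prepare(phantom, wishlist, candidates, geometry, derived):
    derived = derived if derived is not None else derive_structures(phantom)
    influence_all = compute_influence(phantom, candidates, geometry)
    structures = {
        k: v
        for k, v in structures_from_phantom(phantom, influence_all, derived).items()
        if len(v) > 0
    }
    wl = wishlist.restricted_to(set(structures))
    return influence_all, structures, wl


def greedy_bao(
    phantom: Phantom,
    wishlist: WishList,
    candidates=None,
    n_beams: int = 6,
    *,
    geometry=None,
    derived=None,
    compare_tolerance: float = 1e-6,
    keep_all_k: bool = True,
) -> BAOResult:
    """Greedy sequential beam-angle selection driven by the wish-list.

    Influence is traced once for the whole candidate arc; trial beam sets
    are column subsets, so every candidate is judged by a full
    lexicographic FMO on exactly the dose model the final plan will use.
    The nested prefixes give k-beam plans for every ``k <= n_beams`` in a
    single run (``plans_by_k``).
    """
    if candidates is None:
        candidates = candidate_angles(phantom.laterality)
    candidates = np.asarray(candidates, dtype=float)
    if n_beams > len(candidates):
        raise ValueError(f"cannot select {n_beams} beams from {len(candidates)} candidates")
    influence_all, structures, wl = _prepare(
        phantom, wishlist, candidates, geometry, derived
    )

    selected: list[int] = []
    iteration_scores: list[dict[float, list[float]]] = []
    plans_by_k: dict[int, FluencePlan] = {}
    bootstrap: list[int] = []
    for k in range(1, n_beams + 1):
        best_idx = None
        best_vec = None
        best_plan = None
        scores: dict[float, list[float]] = {}
        any_feasible = False
        for ci in range(len(candidates)):
            if ci in selected:
                continue
            try:
                plan = _solve_subset(influence_all, structures, wl, selected + [ci])
            except InfeasibleStageError:
                logger.info("candidate %.1f deg infeasible at iteration %d", candidates[ci], k)
                continue
            any_feasible = True
            vec = plan.score_vector()
            scores[float(candidates[ci])] = [float(v) for v in vec]
            if best_vec is None or lexicographic_compare(vec, best_vec, compare_tolerance) == A_BETTER:
                best_idx, best_vec, best_plan = ci, vec, plan
        if not any_feasible:
            # Too few beams for the hard constraints: rank candidates by
            # how little the constraints must relax to admit any plan.
            bootstrap.append(k)
            best_s = np.inf
            for ci in range(len(candidates)):
                if ci in selected:
                    continue
                sub = influence_all.subset_beams(np.asarray(selected + [ci]))
                s = elastic_infeasibility(sub.matrix, wl, structures)
                scores[float(candidates[ci])] = [s]
                if s < best_s - compare_tolerance:
                    best_s, best_idx = s, ci
            if best_idx is None:
                raise InfeasibleStageError(
                    f"all candidate angles infeasible at BAO iteration {k}"
                )
        selected.append(best_idx)
        iteration_scores.append(scores)
        if best_plan is not None and (keep_all_k or k == n_beams):
            plans_by_k[k] = best_plan
    if n_beams not in plans_by_k:
        raise InfeasibleStageError(
            f"no feasible plan with {n_beams} beams from the candidate arc"
        )
    return BAOResult(
        selected_angles=[float(candidates[i]) for i in selected],
        iteration_scores=iteration_scores,
        plans_by_k=plans_by_k,
        n_beams=n_beams,
        bootstrap_iterations=bootstrap,
    )


def plan_without_bao(
    phantom: Phantom,
    wishlist: WishList,
    fixed_angles=DEFAULT_TEMPLATE_ANGLES,
    *,
    geometry=None,
    derived=None,
) -> FluencePlan:
    """Lexicographic FMO at user-fixed beam angles (the no-BAO mode)."""
    angles = np.asarray(fixed_angles, dtype=float)
    influence, structures, wl = _prepare(phantom, wishlist, angles, geometry, derived)
    return lexicographic_solve(
        influence.matrix,
        wl,
        structures,
        angles_deg=angles,
        prescription_Gy=wishlist.D_p,
    )


def beam_count_study(
    phantom: Phantom,
    wishlist: WishList,
    n_beams_list=(4, 6, 8),
    *,
    candidates=None,
    geometry=None,
    derived=None,
) -> dict[int, FluencePlan]:
    """Plans for several beam counts from one greedy trajectory.

    The greedy selection is nested, so the 4-, 6- and 8-beam plans share
    a common prefix of optimized angles and are produced by a single
    optimization sweep.
    """
    n_max = int(max(n_beams_list))
    result = greedy_bao(
        phantom, wishlist, candidates, n_max, geometry=geometry, derived=derived
    )
    return {int(n): result.plans_by_k[int(n)] for n in n_beams_list}
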