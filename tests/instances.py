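"""Random small FMO instances with a feasibility certificate.

Instances are abstract (random sparse nonnegative influence, random
structure row sets) rather than phantom-derived, so solver behavior is
probed over a much wider geometry class.  Feasibility is guaranteed by
construction: hard-constraint bounds are back-computed from a random
positive reference fluence, which therefore certifies the constraint set.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse

from lexiplan.wishlist import HardConstraint, Objective, WishList


def random_instance(rng, *, n_vox=80, n_blt=15, n_structs=3, n_obj=4,
                    relaxation=1.03):
    """Build (matrix, wishlist, structures, oracle_spec).

    ``oracle_spec`` is the plain-dict description consumed by the
    independent dense oracle: (hard rows, objective rows) with bounds and
    goals identical to the wish-list.
    """
    D = sparse.random(
        n_vox, n_blt, density=0.35, random_state=rng,
        data_rvs=lambda k: rng.uniform(0.2, 1.0, k),
    ).tocsr()
    # target rows: make sure each has some dose (nonzero row)
    row_nnz = np.diff(D.indptr)
    nonzero_rows = np.flatnonzero(row_nnz > 0)
    rng.shuffle(nonzero_rows)
    n_target = max(3, n_vox // 8)
    target = np.sort(nonzero_rows[:n_target])
    structures = {"target": target}
    pool = np.setdiff1d(np.arange(n_vox), target)
    for i in range(n_structs):
        take = rng.integers(3, max(4, len(pool) // n_structs))
        structures[f"oar{i}"] = np.sort(rng.choice(pool, size=take, replace=False))

    x0 = rng.uniform(0.5, 2.0, n_blt)
    d0 = D @ x0
    t_mean = float(d0[target].mean())
    hard = [
        HardConstraint("target", "Mean", t_mean, sense="ge"),
        HardConstraint("target", "Max", float(d0[target].max()) * 1.05),
    ]
    objectives = []
    for p in range(1, n_obj + 1):
        name = f"oar{(p - 1) % n_structs}"
        kind = "Mean" if rng.random() < 0.6 else "Max"
        d_s = d0[structures[name]]
        base = float(d_s.mean() if kind == "Mean" else d_s.max())
        goal = base * rng.uniform(0.1, 1.1)  # sometimes beatable, sometimes not
        sufficient = goal if rng.random() < 0.3 else None
        objectives.append(Objective(p, name, kind, goal, sufficient))

    wl = WishList(
        D_p=66.0, hard_constraints=hard, objectives=objectives,
        relaxation_factor=relaxation,
    )
    oracle_hard = [
        (target, "Mean", t_mean, "ge"),
        (target, "Max", float(d0[target].max()) * 1.05, "le"),
    ]
    oracle_obj = [
        (structures[o.structure], o.kind, o.goal, o.sufficient)
        for o in objectives
    ]
    return D, wl, structures, (oracle_hard, oracle_obj)
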