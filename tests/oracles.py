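"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately written in the most naive way possible
(plain loops, dense arrays, exhaustive enumeration) and shares no code
with the package internals it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy import optimize


# ---------------------------------------------------------------------------
# Geometry oracles

def brute_shell(ptv_mask, body_mask, spacing, d_mm):
    """Voxels whose min pairwise distance to any PTV voxel is in
    [d, d + voxel diagonal), inside the body.  O(N^2)."""
    sy, sx = spacing
    diag = math.hypot(sy, sx)
    ptv = np.argwhere(ptv_mask)
    out = np.zeros_like(ptv_mask)
    for r, c in np.argwhere(body_mask):
        best = min(
            math.hypot((r - pr) * sy, (c - pc) * sx) for pr, pc in ptv
        )
        if d_mm <= best < d_mm + diag:
            out[r, c] = True
    return out


def brute_external_ring(body_mask, ptv_mask, spacing, depth_mm=20.0, margin_mm=40.0):
    """2 cm-deep band inside the body surface minus the 4 cm-dilated PTV,
    by pairwise distances to outside-body and PTV voxel sets."""
    sy, sx = spacing
    outside = np.argwhere(~body_mask)
    ptv = np.argwhere(ptv_mask)
    out = np.zeros_like(body_mask)
    for r, c in np.argwhere(body_mask):
        d_surface = min(
            math.hypot((r - orr) * sy, (c - oc) * sx) for orr, oc in outside
        )
        d_ptv = min(math.hypot((r - pr) * sy, (c - pc) * sx) for pr, pc in ptv)
        if d_surface <= depth_mm and d_ptv > margin_mm:
            out[r, c] = True
    return out


# ---------------------------------------------------------------------------
# Dose-engine oracle

def brute_influence_entry(phantom, angle_deg, geometry, voxel_rc, beamlet_center):
    """One influence-matrix entry by direct ray marching, scalar math only."""
    g = math.radians(angle_deg)
    to_src = (math.sin(g), math.cos(g))
    lateral = (math.cos(g), -math.sin(g))
    ny, nx = phantom.grid_shape
    sy, sx = phantom.spacing_mm
    r, c = voxel_rc
    x = (c - (nx - 1) / 2) * sx
    y = ((ny - 1) / 2 - r) * sy

    dens = phantom.masks["body"].astype(float)
    dens[phantom.masks["lungs"]] = geometry.lung_density
    dens[phantom.masks["PTV"]] = 1.0

    h = geometry.step_mm
    t_max = math.hypot(ny * sy, nx * sx)
    depth = 0.0
    k = 0
    while (k + 0.5) * h < t_max:
        px = x + to_src[0] * (k + 0.5) * h
        py = y + to_src[1] * (k + 0.5) * h
        col = round(px / sx + (nx - 1) / 2)
        row = round((ny - 1) / 2 - py / sy)
        if 0 <= row < ny and 0 <= col < nx:
            depth += dens[row, col] * h
        k += 1
    primary = math.exp(-geometry.mu_per_mm * depth)

    lat = x * lateral[0] + y * lateral[1]
    s = geometry.penumbra_sigma_mm * math.sqrt(2.0)
    w = geometry.beamlet_width_mm
    prof = 0.5 * (
        math.erf((lat - beamlet_center + w / 2) / s)
        - math.erf((lat - beamlet_center - w / 2) / s)
    )
    val = primary * prof
    return val if val >= geometry.cutoff else 0.0


# ---------------------------------------------------------------------------
# Metric oracles

def brute_dvh(dose, axis):
    """Volume fraction (%) at each axis dose by exhaustive counting."""
    dose = list(dose)
    return np.array(
        [100.0 * sum(1 for d in dose if d >= a) / len(dose) for a in axis]
    )


def ltcp_direct(doses, alpha, reference):
    return sum(math.exp(-alpha * (d - reference)) for d in doses) / len(doses)


def wilcoxon_exact_enumeration(diffs):
    """Two-tailed exact signed-rank p by enumerating every sign pattern."""
    d = [x for x in diffs if x != 0]
    n = len(d)
    if n == 0:
        return 1.0
    abs_d = [abs(x) for x in d]
    order = sorted(range(n), key=lambda i: abs_d[i])
    ranks = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j + 1 < n and abs_d[order[j + 1]] == abs_d[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    w_obs = sum(r for x, r in zip(d, ranks) if x > 0)
    dist = []
    for signs in itertools.product((0, 1), repeat=n):
        dist.append(sum(r for s, r in zip(signs, ranks) if s))
    eps = 1e-9
    p_ge = sum(1 for w in dist if w >= w_obs - eps) / len(dist)
    p_le = sum(1 for w in dist if w <= w_obs + eps) / len(dist)
    return min(1.0, 2.0 * min(p_ge, p_le))


# ---------------------------------------------------------------------------
# Sequential lexicographic oracle (dense, generic-solver scripted)
#
# Wish-lists are described by plain dicts so this script cannot silently
# reuse package dataclass behavior:
#   hard:      list of (rows_array, kind, bound, sense)
#   objective: list of (structure_rows, kind, goal, sufficient)

def _dense_stage_lp(D, struct_rows, kind, extra_cons):
    """Minimize one Mean/Max objective with linprog on dense matrices.

    ``extra_cons`` is a list of (A_row_or_block, ub) already in "<=" form
    over the fluence variables.  Returns (value, x).
    """
    n = D.shape[1]
    A_list, b_list = [], []
    for A_c, ub in extra_cons:
        A_c = np.atleast_2d(A_c)
        A_list.append(A_c)
        b_list.append(np.full(A_c.shape[0], ub) if np.isscalar(ub) else ub)
    if kind == "Mean":
        c = D[struct_rows].mean(axis=0)
        A = np.vstack(A_list) if A_list else np.zeros((0, n))
        b = np.concatenate(b_list) if b_list else np.zeros(0)
        res = optimize.linprog(c, A_ub=A, b_ub=b, bounds=(0, None), method="highs")
        assert res.status == 0, res.message
        return float(res.fun), res.x
    # Max via epigraph variable appended as the last column
    c = np.zeros(n + 1)
    c[-1] = 1.0
    rows = []
    rhs = []
    for A_c, b_c in zip(A_list, b_list):
        rows.append(np.hstack([A_c, np.zeros((A_c.shape[0], 1))]))
        rhs.append(b_c)
    block = D[struct_rows]
    rows.append(np.hstack([block, -np.ones((block.shape[0], 1))]))
    rhs.append(np.zeros(block.shape[0]))
    res = optimize.linprog(
        c, A_ub=np.vstack(rows), b_ub=np.concatenate(rhs), bounds=(0, None),
        method="highs",
    )
    assert res.status == 0, res.message
    return float(res.fun), res.x[:n]


def _constraint_rows(D, rows, kind, bound, sense):
    if kind == "Max":
        A, b = D[rows], float(bound)
    else:
        A, b = D[rows].mean(axis=0), float(bound)
    if sense == "ge":
        A, b = -np.atleast_2d(A), -b
    return A, b


def sequential_lexicographic_oracle(D, hard, objectives, relaxation):
    """Scripted two-round procedure on dense matrices.

    Round 1 minimizes each objective in order, inserting the goal if met,
    else the relaxed achieved value; round 2 re-minimizes objectives
    without a sufficient value and pins them at their new optima.
    Returns (round1 values, final values, bounds) where final values are
    re-evaluated on the last fluence.
    """
    base = [_constraint_rows(D, r, k, bnd, s) for r, k, bnd, s in hard]
    inserted = {}
    round1 = []
    x = None
    for i, (rows, kind, goal, sufficient) in enumerate(objectives):
        cons = base + [v for j, v in sorted(inserted.items())]
        val, x = _dense_stage_lp(D, rows, kind, cons)
        round1.append(val)
        bound = goal if val <= goal + 1e-9 * (1 + abs(goal)) else val * relaxation
        slack = 1e-9 * (1 + abs(bound))
        inserted[i] = _constraint_rows(D, rows, kind, bound + slack, "le")
    for i, (rows, kind, goal, sufficient) in enumerate(objectives):
        if sufficient is not None:
            continue
        cons = base + [v for j, v in sorted(inserted.items())]
        val, x = _dense_stage_lp(D, rows, kind, cons)
        slack = 1e-9 * (1 + abs(val))
        inserted[i] = _constraint_rows(D, rows, kind, val + slack, "le")
    dose = D @ x
    final = []
    for rows, kind, goal, sufficient in objectives:
        final.append(
            float(dose[rows].mean() if kind == "Mean" else dose[rows].max())
        )
    return np.array(round1), np.array(final), x
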