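"""Two-round lexicographic (epsilon-constraint) fluence-map optimization.

The optimizer minimizes the wish-list objectives one at a time in
priority order, subject to the hard constraints and to bounds frozen in
for already-handled objectives:

* **Round 1** — each objective is minimized in turn.  If the optimum
  reaches the Goal value, the *Goal* (not the optimum) is inserted as a
  constraint, deliberately leaving head-room for lower priorities.  If
  the Goal is missed, the achieved value times a small relaxation factor
  is inserted instead.
* **Round 2** — every objective *without* a Sufficient value is
  re-minimized to the fullest extent, in priority order, its bound being
  replaced by the new optimum.  Objectives with a Sufficient value are
  left at it: pushing them further is by definition not wanted.

Mean and Max objectives/constraints are linear in the fluence; stages
touching only those are solved exactly as linear programs (HiGHS).  The
LTCP objective is smooth and convex, handled in log space (log-sum-exp,
whose softmax gradient has bounded norm).  Stages where LTCP appears —
as the objective or as an inserted bound — are solved by sequential
quadratic programming (SLSQP) inside an outer active-set loop: the SQP
subproblem sees only the linear constraints that are nearly active at
the warm start, violated rows are appended, and the loop repeats until
the full constraint set holds.  This keeps per-stage cost near the LP
cost while enforcing the convex LTCP bound to solver precision.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, sparse

from .wishlist import Objective, WishList, evaluate_objective

#: Relative slack added to inserted stage bounds to absorb solver round-off.
BOUND_SLACK = 1e-9

#: Feasibility tolerance (relative) for the outer active-set loop.
FEAS_TOL = 1e-8


class SolverError(RuntimeError):
    pass


class InfeasibleStageError(SolverError):
    """A stage's constraint set is infeasible; carries stage provenance."""

    def __init__(self, message, *, round_no=None, priority=None, conflicting=None):
        super().__init__(message)
        self.round_no = round_no
        self.priority = priority
        self.conflicting = conflicting


@dataclass
class StageRecord:
    """Audit record of one lexicographic minimization stage."""

    round_no: int
    priority: int
    objective: str
    achieved: float
    bound_inserted: float | None
    bound_kind: str  # "goal" | "relaxed" | "round2" | "none"
    solver_status: str


@dataclass
class FluencePlan:
    """A solved fluence plan: beam angles, fluence, dose and audit trail.

    ``dose`` lives in influence-matrix row space; ``structures`` maps
    structure names to row-index arrays so metrics can be evaluated
    without the matrix at hand.
    """

    angles_deg: np.ndarray
    fluence: np.ndarray
    dose: np.ndarray
    structures: dict[str, np.ndarray]
    achieved: list[float] = field(default_factory=list)
    stage_log: list[StageRecord] = field(default_factory=list)
    normalized: bool = False
    prescription_Gy: float | None = None

    def structure_dose(self, name: str) -> np.ndarray:
        return self.dose[self.structures[name]]

    def structure_doses(self) -> dict[str, np.ndarray]:
        return {name: self.dose[rows] for name, rows in self.structures.items()}

    def objective_vector(self) -> np.ndarray:
        """Final achieved objective values in priority order."""
        return np.asarray(self.achieved, dtype=float)

    def round1_vector(self) -> np.ndarray:
        """Round-1 stage optima in priority order.

        This is the lexicographic method's value vector: at the first
        index where two plans differ, all earlier inserted bounds
        coincide, so "smaller wins" is a sound comparison.  (The *final*
        achieved values are not comparable this way — goal/relaxation
        branching makes later entries depend on earlier slack.)
        """
        vals = [r.achieved for r in self.stage_log if r.round_no == 1]
        return np.asarray(vals, dtype=float)

    def score_vector(self) -> np.ndarray:
        """Round-1 optima clamped at their Goal values, in priority order.

        Two plans that both meet an objective's Goal are equally good on
        it by wish-list semantics (round 1 inserts the Goal either way,
        "regardless of the possibility for further improvement"), so the
        clamped entry is the Goal; a missed Goal scores the achieved
        value.  This is the vector beam-angle selection compares:
        unclamped optima would reward over-achieving high priorities at
        the expense of every priority below — exactly the greediness the
        Goal mechanism exists to suppress.
        """
        vals = [
            r.bound_inserted if r.bound_kind == "goal" else r.achieved
            for r in self.stage_log
            if r.round_no == 1
        ]
        return np.asarray(vals, dtype=float)

    def stage_log_json(self, path=None) -> str:
        text = json.dumps([dataclasses.asdict(r) for r in self.stage_log], indent=2)
        if path is not None:
            with open(path, "w") as f:
                f.write(text)
        return text


@dataclass
class _LinearBlock:
    A: sparse.csr_matrix  # rows of A x <= b
    b: np.ndarray


@dataclass
class _LTCPBound:
    structure: str
    log_bound: float
    params: object


class LexicographicOptimizer:
    """Stage-by-stage solver over one influence matrix and wish-list.

    ``structures`` maps every structure named by the wish-list to an
    array of matrix row indices.  Hard constraints on structures missing
    from the map raise ``KeyError`` — restrict the wish-list first (see
    :meth:`lexiplan.wishlist.WishList.restricted_to`).
    """

    def __init__(
        self,
        matrix: sparse.spmatrix,
        wishlist: WishList,
        structures: dict[str, np.ndarray],
        *,
        sqp_ftol: float = 1e-9,
    ):
        self.sqp_ftol = sqp_ftol
        self.matrix = sparse.csr_matrix(matrix)
        self.wishlist = wishlist
        self.structures = {
            k: np.asarray(v, dtype=np.int64) for k, v in structures.items()
        }
        self.n = self.matrix.shape[1]
        self._sub: dict[str, sparse.csr_matrix] = {}
        self._mean_row: dict[str, np.ndarray] = {}
        for name in wishlist.structure_names():
            if name not in self.structures:
                raise KeyError(f"wish-list references unknown structure {name!r}")
            rows = self.structures[name]
            if rows.size == 0:
                raise ValueError(f"structure {name!r} has no voxels")
            self._sub[name] = self.matrix[rows]
            self._mean_row[name] = np.asarray(self._sub[name].mean(axis=0)).ravel()
        self._hard = self._build_hard_block()
        self._bounds: dict[int, _LinearBlock | _LTCPBound] = {}
        self._dense: dict[str, np.ndarray] = {}
        self._ltcp_cache: dict = {}
        self.x: np.ndarray | None = None

    # -- constraint assembly -------------------------------------------------

    def _max_block(self, structure: str, bound: float) -> _LinearBlock:
        """Per-voxel upper-bound rows for a Max constraint; voxels no
        beamlet reaches are trivially satisfied and dropped."""
        A = self._sub[structure]
        nz = np.flatnonzero(np.diff(A.indptr))
        A = A[nz] if len(nz) < A.shape[0] else A
        return _LinearBlock(A, np.full(A.shape[0], bound))

    def _build_hard_block(self) -> _LinearBlock:
        rows, rhs = [], []
        for c in self.wishlist.hard_constraints:
            if c.kind == "Max":
                block = self._max_block(c.structure, c.bound_Gy)
                A, b = block.A, block.b
            elif c.kind == "Mean":
                A = sparse.csr_matrix(self._mean_row[c.structure])
                b = np.array([c.bound_Gy])
            else:
                raise ValueError(f"unknown hard-constraint kind {c.kind!r}")
            if c.sense == "ge":
                A, b = -A, -b
            rows.append(A)
            rhs.append(b)
        if not rows:
            return _LinearBlock(sparse.csr_matrix((0, self.n)), np.zeros(0))
        return _LinearBlock(sparse.vstack(rows, format="csr"), np.concatenate(rhs))

    def _linear_blocks(self):
        blocks = [self._hard]
        for prio, bound in sorted(self._bounds.items()):
            if not isinstance(bound, _LTCPBound):
                blocks.append(bound)
        return blocks

    def _ltcp_bounds(self) -> list[_LTCPBound]:
        return [b for b in self._bounds.values() if isinstance(b, _LTCPBound)]

    def _assemble(self):
        blocks = self._linear_blocks()
        A = sparse.vstack([b.A for b in blocks], format="csr")
        return A, np.concatenate([b.b for b in blocks])

    # -- LTCP helpers --------------------------------------------------------

    def _log_ltcp(self, structure: str, params, x: np.ndarray) -> tuple[float, np.ndarray]:
        """Value and gradient of log-LTCP, cached per evaluation point
        (SQP asks for function and jacobian separately)."""
        key = (structure, params.alpha_per_Gy, x.tobytes())
        hit = self._ltcp_cache.get(key)
        if hit is not None:
            return hit
        cached = self._dense.get(structure)
        if cached is None:
            cached = self._dense[structure] = np.asarray(self._sub[structure].todense())
        z = -params.alpha_per_Gy * ((cached @ x) - params.reference_Gy)
        zmax = z.max()
        ez = np.exp(z - zmax)
        s = ez.sum()
        val = float(zmax + np.log(s) - np.log(len(z)))
        grad = -params.alpha_per_Gy * ((ez / s) @ cached)
        self._ltcp_cache.clear()  # only the current point is ever re-queried
        self._ltcp_cache[key] = (val, grad)
        return val, grad

    # -- stage solvers -------------------------------------------------------

    def _solve_lp(self, c, A, b, *, context: str):
        res = optimize.linprog(c, A_ub=A, b_ub=b, bounds=(0, None), method="highs")
        if res.status == 2:
            raise InfeasibleStageError(f"infeasible constraint set at {context}")
        if res.status != 0:
            raise SolverError(f"LP solver failed at {context}: {res.message}")
        return res

    def _solve_pure_lp_stage(self, objective: Objective):
        """Exact LP solve for Mean/Max stages with no LTCP bound active."""
        A, b = self._assemble()
        if objective.kind == "Mean":
            c = self._mean_row[objective.structure]
            res = self._solve_lp(c, A, b, context=objective.label)
            return float(res.fun), np.maximum(res.x, 0.0), "optimal"
        # Max: epigraph variable t, minimize t s.t. A_S x - t <= 0.
        link = self._max_block(objective.structure, 0.0)
        A_ext = sparse.vstack(
            [
                sparse.hstack([A, sparse.csr_matrix((A.shape[0], 1))]),
                sparse.hstack([link.A, -np.ones((link.A.shape[0], 1))]),
            ],
            format="csr",
        )
        b_ext = np.concatenate([b, link.b])
        c = np.zeros(self.n + 1)
        c[-1] = 1.0
        res = self._solve_lp(c, A_ext, b_ext, context=objective.label)
        return float(res.fun), np.maximum(res.x[: self.n], 0.0), "optimal"

    def _feasible_point(self) -> np.ndarray:
        """A hard-constraint-feasible fluence, biased toward target dose so
        the LTCP exponentials start well-scaled."""
        c = -self._mean_row["PTV"] if "PTV" in self._mean_row else np.zeros(self.n)
        A, b = self._assemble()
        res = self._solve_lp(c, A, b, context="feasibility stage")
        return np.maximum(res.x, 0.0)

    def _solve_smooth_stage(self, objective: Objective):
        """SLSQP with an outer active-set loop, for stages where the LTCP
        function appears as objective or bound.

        The subproblem carries only near-active linear rows; violated
        rows of the full set are appended until none remain, so the
        returned point is feasible for the complete stage problem.
        """
        A, b = self._assemble()
        A_d = None  # dense copy built lazily per working set
        is_max = objective.kind == "Max"
        n_z = self.n + (1 if is_max else 0)

        link = self._max_block(objective.structure, 0.0) if is_max else None

        x0 = self.x if self.x is not None else self._feasible_point()
        if is_max:
            t0 = float((link.A @ x0).max()) if link.A.shape[0] else 0.0
            z0 = np.concatenate([x0, [t0 * (1 + 1e-9) + 1e-12]])
        else:
            z0 = x0

        if objective.kind == "LTCP":
            params = objective.ltcp

            def fun(z):
                return self._log_ltcp(objective.structure, params, z)[0]

            def jac(z):
                return self._log_ltcp(objective.structure, params, z)[1]

        elif objective.kind == "Mean":
            c_vec = self._mean_row[objective.structure]

            def fun(z):
                return float(c_vec @ z)

            def jac(z):
                return c_vec

        else:  # Max
            c_vec = np.zeros(n_z)
            c_vec[-1] = 1.0

            def fun(z):
                return float(z[-1])

            def jac(z):
                return c_vec

        slack0 = b - A @ x0
        working = set(np.flatnonzero(slack0 < 1.0 + FEAS_TOL * (1 + np.abs(b))).tolist())
        link_working: set[int] = set()
        if is_max:
            l_slack = z0[-1] - link.A @ x0
            link_working = set(np.flatnonzero(l_slack < 1.0).tolist())

        ltcp_cons = []
        for lb in self._ltcp_bounds():
            ltcp_cons.append(
                {
                    "type": "ineq",
                    "fun": lambda z, lb=lb: lb.log_bound
                    - self._log_ltcp(lb.structure, lb.params, z[: self.n])[0],
                    "jac": lambda z, lb=lb: np.concatenate(
                        [
                            -self._log_ltcp(lb.structure, lb.params, z[: self.n])[1],
                            np.zeros(n_z - self.n),
                        ]
                    ),
                }
            )

        z = z0
        for outer in range(30):
            rows = np.fromiter(sorted(working), dtype=np.int64, count=len(working))
            A_w = A[rows].toarray() if len(rows) else np.zeros((0, self.n))
            b_w = b[rows]
            if is_max:
                l_rows = np.fromiter(sorted(link_working), dtype=np.int64, count=len(link_working))
                L_w = link.A[l_rows].toarray() if len(l_rows) else np.zeros((0, self.n))
                A_full = np.block(
                    [
                        [A_w, np.zeros((A_w.shape[0], 1))],
                        [L_w, -np.ones((L_w.shape[0], 1))],
                    ]
                )
                b_full = np.concatenate([b_w, np.zeros(L_w.shape[0])])
            else:
                A_full, b_full = A_w, b_w
            cons = list(ltcp_cons)
            if A_full.shape[0]:
                cons.append(
                    {
                        "type": "ineq",
                        "fun": lambda zz, Af=A_full, bf=b_full: bf - Af @ zz,
                        "jac": lambda zz, Af=A_full: -Af,
                    }
                )
            res = optimize.minimize(
                fun,
                z,
                jac=jac,
                method="SLSQP",
                bounds=[(0.0, None)] * n_z,
                constraints=cons,
                options={"maxiter": 400, "ftol": self.sqp_ftol},
            )
            if res.status not in (0,):
                # Retry once from the stage's feasible start, then fall back
                # to the (slower, more robust) trust-region solver on the
                # same working-set subproblem.
                res = optimize.minimize(
                    fun,
                    z0,
                    jac=jac,
                    method="SLSQP",
                    bounds=[(0.0, None)] * n_z,
                    constraints=cons,
                    options={"maxiter": 1000, "ftol": self.sqp_ftol * 0.1},
                )
                if res.status != 0:
                    if objective.kind in ("Mean", "Max"):
                        return self._kelley_stage(objective, x0)
                    res = self._trust_region_fallback(
                        fun, jac, z0, n_z, A_full, b_full, ltcp_cons, objective
                    )
            z = res.x
            x = np.maximum(z[: self.n], 0.0)
            viol = (A @ x) - b
            tol = FEAS_TOL * (1.0 + np.abs(b))
            bad = np.flatnonzero(viol > tol)
            grew = False
            for r in bad:
                if r not in working:
                    working.add(int(r))
                    grew = True
            if is_max:
                l_viol = (link.A @ x) - z[-1]
                l_bad = np.flatnonzero(l_viol > FEAS_TOL)
                for r in l_bad:
                    if r not in link_working:
                        link_working.add(int(r))
                        grew = True
            if not grew:
                value = float(res.fun)
                return value, x, "optimal"
        raise SolverError(f"active-set loop did not converge at {objective.label}")

    def _kelley_stage(self, objective: Objective, x_feas, tol: float = 1e-6,
                      max_cuts: int = 400):
        """Cutting-plane fallback for a linear stage under LTCP bounds.

        Outer-linearizes each LTCP level set with tangent cuts placed
        where the segment from the stage's feasible start crosses the
        boundary, and re-solves the LP until the bound holds to ``tol``
        (log scale).  Slower than SQP but cannot stall, so it backs up
        the SQP path.  Kelley's tail convergence is sublinear, so if the
        cut budget runs out with only a small residual violation left
        (<= 50x tol, i.e. ~5e-5 relative on the LTCP value) the point is
        accepted; a larger residual is a genuine failure.
        """
        A, b = self._assemble()
        is_max = objective.kind == "Max"
        link = self._max_block(objective.structure, 0.0) if is_max else None
        if is_max:
            c = np.zeros(self.n + 1)
            c[-1] = 1.0
        else:
            c = self._mean_row[objective.structure]
        cuts_A: list[np.ndarray] = []
        cuts_b: list[float] = []
        for _ in range(max_cuts):
            if is_max:
                A_lp = sparse.vstack(
                    [
                        sparse.hstack([A, sparse.csr_matrix((A.shape[0], 1))]),
                        sparse.hstack([link.A, -np.ones((link.A.shape[0], 1))]),
                    ]
                    + (
                        [sparse.hstack([sparse.csr_matrix(np.array(cuts_A)),
                                        sparse.csr_matrix((len(cuts_A), 1))])]
                        if cuts_A
                        else []
                    ),
                    format="csr",
                )
                b_lp = np.concatenate(
                    [b, link.b] + ([np.array(cuts_b)] if cuts_b else [])
                )
            else:
                A_lp = (
                    sparse.vstack([A, sparse.csr_matrix(np.array(cuts_A))], format="csr")
                    if cuts_A
                    else A
                )
                b_lp = np.concatenate([b, np.array(cuts_b)]) if cuts_b else b
            res = self._solve_lp(c, A_lp, b_lp, context=objective.label)
            x = np.maximum(res.x[: self.n], 0.0)
            worst = 0.0
            for lb in self._ltcp_bounds():
                val, _ = self._log_ltcp(lb.structure, lb.params, x)
                if val > lb.log_bound + tol:
                    worst = max(worst, val - lb.log_bound)
                    g, c0 = self._boundary_cut(lb, x_feas, x, val)
                    cuts_A.append(g)
                    cuts_b.append(lb.log_bound - c0)
            if worst == 0.0:
                return float(res.fun), x, "optimal"
        if worst <= 50 * tol:
            return float(res.fun), x, "optimal_tol"
        raise SolverError(f"cutting planes did not converge at {objective.label}")

    def _boundary_cut(self, lb: _LTCPBound, x_feas, x_viol, val_viol):
        """Tangent cut to the LTCP level set at the boundary crossing of
        the segment feasible-point -> violating LP optimum."""
        x_cut, val = x_viol, val_viol
        if (
            x_feas is not None
            and self._log_ltcp(lb.structure, lb.params, x_feas)[0] <= lb.log_bound
        ):
            lo, hi = 0.0, 1.0
            dx = x_viol - x_feas
            for _ in range(60):
                mid = 0.5 * (lo + hi)
                v_mid, _ = self._log_ltcp(lb.structure, lb.params, x_feas + mid * dx)
                if v_mid > lb.log_bound:
                    hi = mid
                else:
                    lo = mid
                if hi - lo < 1e-13:
                    break
            x_cut = x_feas + hi * dx
            val, _ = self._log_ltcp(lb.structure, lb.params, x_cut)
        grad = self._log_ltcp(lb.structure, lb.params, x_cut)[1]
        # fall back to a plain cut at the violating point if the tangent
        # does not separate it (near-flat crossing)
        if val + float(grad @ (x_viol - x_cut)) <= lb.log_bound:
            g2 = self._log_ltcp(lb.structure, lb.params, x_viol)[1]
            return g2, val_viol - float(g2 @ x_viol)
        return grad, val - float(grad @ x_cut)

    def _trust_region_fallback(
        self, fun, jac, z0, n_z, A_full, b_full, ltcp_cons, objective
    ):
        cons = []
        if A_full.shape[0]:
            cons.append(optimize.LinearConstraint(A_full, -np.inf, b_full))
        for lb in self._ltcp_bounds():
            cons.append(
                optimize.NonlinearConstraint(
                    lambda z, lb=lb: self._log_ltcp(lb.structure, lb.params, z[: self.n])[0],
                    -np.inf,
                    lb.log_bound,
                    jac=lambda z, lb=lb: np.concatenate(
                        [
                            self._log_ltcp(lb.structure, lb.params, z[: self.n])[1],
                            np.zeros(n_z - self.n),
                        ]
                    )[None, :],
                )
            )
        import warnings

        with warnings.catch_warnings():
            # the quasi-Newton update warns on exactly-linear objectives
            warnings.simplefilter("ignore", UserWarning)
            res = optimize.minimize(
                fun,
                z0,
                jac=jac,
                method="trust-constr",
                bounds=optimize.Bounds(np.zeros(n_z), np.full(n_z, np.inf)),
                constraints=cons,
                options={"gtol": 1e-10, "xtol": 1e-12, "maxiter": 2000},
            )
        if res.status not in (1, 2):
            raise SolverError(
                f"stage solvers failed at {objective.label}: {res.message}"
            )
        return res

    def solve_stage(self, objective: Objective):
        """Minimize one objective under the current constraint set.

        Returns ``(achieved value, fluence, status)``; LTCP values are
        reported in natural (not log) units.
        """
        try:
            smooth = objective.kind == "LTCP" or self._ltcp_bounds()
            if smooth:
                value, x, status = self._solve_smooth_stage(objective)
                if objective.kind == "LTCP":
                    value = float(np.exp(value))
            else:
                value, x, status = self._solve_pure_lp_stage(objective)
        except InfeasibleStageError as err:
            raise InfeasibleStageError(
                f"{err} (while minimizing {objective.label})",
                priority=objective.priority,
                conflicting=self._diagnose_infeasibility(),
            ) from None
        self.x = x
        return value, x, status

    def _diagnose_infeasibility(self) -> str | None:
        """Find the first inserted bound whose addition makes the set infeasible."""
        saved = dict(self._bounds)
        try:
            self._bounds = {}
            for prio in sorted(saved):
                self._bounds[prio] = saved[prio]
                try:
                    A, b = self._assemble()
                    self._solve_lp(np.zeros(A.shape[1]), A, b, context="diagnosis")
                except InfeasibleStageError:
                    return f"bound inserted for priority {prio}"
            return "hard constraints alone"
        except Exception:  # diagnosis must never mask the original error
            return None
        finally:
            self._bounds = saved

    # -- bound bookkeeping ---------------------------------------------------

    def insert_bound(self, objective: Objective, bound: float) -> None:
        """Freeze ``objective <= bound`` (a small relative slack absorbs
        solver round-off)."""
        slack = BOUND_SLACK * (1.0 + abs(bound))
        if objective.kind == "LTCP":
            self._bounds[objective.priority] = _LTCPBound(
                structure=objective.structure,
                log_bound=float(np.log(bound)) + slack,
                params=objective.ltcp,
            )
        elif objective.kind == "Mean":
            self._bounds[objective.priority] = _LinearBlock(
                sparse.csr_matrix(self._mean_row[objective.structure]),
                np.array([bound + slack]),
            )
        elif objective.kind == "Max":
            self._bounds[objective.priority] = self._max_block(
                objective.structure, bound + slack
            )
        else:
            raise ValueError(objective.kind)


def solve_priority_stage(
    matrix,
    structures: dict[str, np.ndarray],
    wishlist: WishList,
    objective: Objective,
    inserted_bounds: dict[int, float] | None = None,
):
    """Minimize a single wish-list objective under the hard constraints
    plus previously inserted bounds ``{priority: bound}``.

    Returns ``(achieved value, fluence)``.
    """
    opt = LexicographicOptimizer(matrix, wishlist, structures)
    by_priority = {o.priority: o for o in wishlist.objectives}
    for prio, bound in (inserted_bounds or {}).items():
        opt.insert_bound(by_priority[prio], bound)
    value, x, _ = opt.solve_stage(objective)
    return value, x


def lexicographic_solve(
    matrix,
    wishlist: WishList,
    structures: dict[str, np.ndarray],
    *,
    angles_deg=None,
    prescription_Gy: float | None = None,
) -> FluencePlan:
    """Run the full two-round lexicographic optimization.

    Returns the final plan with the complete stage log; raises
    :class:`InfeasibleStageError` with stage provenance if any stage's
    constraint set is infeasible.
    """
    opt = LexicographicOptimizer(matrix, wishlist, structures)
    log: list[StageRecord] = []
    relax = wishlist.relaxation_factor
    x = None

    for obj in wishlist.objectives:  # round 1
        value, x, status = opt.solve_stage(obj)
        goal_tol = 1e-9 * (1.0 + abs(obj.goal))
        if value <= obj.goal + goal_tol:
            bound, kind = obj.goal, "goal"
        else:
            bound, kind = value * relax, "relaxed"
        opt.insert_bound(obj, bound)
        log.append(StageRecord(1, obj.priority, obj.label, value, bound, kind, status))

    for obj in wishlist.objectives:  # round 2: push non-Sufficient objectives
        if obj.sufficient is not None:
            log.append(
                StageRecord(
                    2, obj.priority, obj.label, float("nan"), None, "none", "skipped"
                )
            )
            continue
        value, x, status = opt.solve_stage(obj)
        opt.insert_bound(obj, value)
        log.append(StageRecord(2, obj.priority, obj.label, value, value, "round2", status))

    if x is None:
        raise ValueError("wish-list has no objectives to optimize")
    dose = sparse.csr_matrix(matrix) @ x
    doses_by_structure = {name: dose[rows] for name, rows in opt.structures.items()}
    achieved = [evaluate_objective(o, doses_by_structure) for o in wishlist.objectives]
    return FluencePlan(
        angles_deg=np.asarray(angles_deg if angles_deg is not None else []),
        fluence=x,
        dose=dose,
        structures=opt.structures,
        achieved=achieved,
        stage_log=log,
        prescription_Gy=prescription_Gy if prescription_Gy is not None else wishlist.D_p,
    )


@dataclass
class HardConstraintCheck:
    structure: str
    kind: str
    bound_Gy: float
    sense: str
    achieved: float
    margin: float
    passed: bool


def verify_hard_constraints(
    plan: FluencePlan, wishlist: WishList, rel_tol: float = 1e-6
) -> list[HardConstraintCheck]:
    """Evaluate every wish-list hard constraint on the final dose.

    ``margin`` is bound minus achieved for upper bounds (positive is
    good) and achieved minus bound for coverage floors.
    """
    out = []
    for c in wishlist.hard_constraints:
        if c.structure not in plan.structures:
            continue
        d = plan.structure_dose(c.structure)
        achieved = float(d.max() if c.kind == "Max" else d.mean())
        tol = rel_tol * (1.0 + abs(c.bound_Gy))
        if c.sense == "ge":
            margin = achieved - c.bound_Gy
        else:
            margin = c.bound_Gy - achieved
        out.append(
            HardConstraintCheck(
                c.structure, c.kind, c.bound_Gy, c.sense, achieved, margin,
                bool(margin >= -tol),
            )
        )
    return out


def elastic_infeasibility(
    matrix, wishlist: WishList, structures: dict[str, np.ndarray]
) -> float:
    """Minimal uniform relative relaxation of the hard constraints that
    admits some nonnegative fluence.

    Each hard-constraint row ``a.x <= b`` is relaxed to
    ``a.x <= b + s*(1+|b|)`` with a single elastic variable ``s >= 0``
    whose minimum is returned; it is 0 exactly when the hard constraints
    are feasible as stated.  Used to rank beam sets that cannot yet
    support a feasible plan (e.g. too few beams for the coverage floor
    and entrance-dose caps simultaneously).
    """
    opt = LexicographicOptimizer(matrix, wishlist, structures)
    A, b = opt._assemble()
    scale = 1.0 + np.abs(b)
    A_ext = sparse.hstack([A, sparse.csr_matrix(-scale[:, None])], format="csr")
    c = np.zeros(A_ext.shape[1])
    c[-1] = 1.0
    res = optimize.linprog(c, A_ub=A_ext, b_ub=b, bounds=(0, None), method="highs")
    if res.status != 0:
        raise SolverError(f"elastic feasibility LP failed: {res.message}")
    return float(res.fun)


def structures_from_phantom(phantom, influence, derived=None) -> dict[str, np.ndarray]:
    """Row-index map for all phantom masks plus derived shells/ring."""
    masks = dict(phantom.masks)
    if derived is not None:
        masks.update(derived.as_masks())
    return {name: influence.rows_for_mask(mask) for name, mask in masks.items()}


def solve_wishlist_plan(
    phantom, influence, wishlist: WishList, derived=None
) -> FluencePlan:
    """High-level FMO entry point: phantom + influence + wish-list -> plan.

    Derived shells and the external ring are built on demand; wish-list
    entries for structures the phantom lacks (brachial plexus) are
    dropped.
    """
    from .phantom import derive_structures

    derived = derived if derived is not None else derive_structures(phantom)
    structures = {
        k: v
        for k, v in structures_from_phantom(phantom, influence, derived).items()
        if len(v) > 0
    }
    wl = wishlist.restricted_to(set(structures))
    return lexicographic_solve(
        influence.matrix,
        wl,
        structures,
        angles_deg=influence.angles_deg,
        prescription_Gy=wishlist.D_p,
    )
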