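"""Wish-list data model for prioritized lexicographic planning.

A wish-list consists of *hard constraints* (never violated) and an
ordered list of *objectives*, each with a Goal value and optionally a
Sufficient value.  The lexicographic optimizer minimizes the objectives
in priority order; Goal/Sufficient semantics stop it from over-pursuing a
high-priority objective at the expense of lower priorities (see
:mod:`lexiplan.fmo`).

The default LA-NSCLC wish-list built by :func:`build_wishlist` encodes,
for a prescription ``D_p`` of 60/66/70 Gy:

* hard constraints — PTV Max ``1.02*D_p``, PTV Mean at least
  ``0.997*D_p`` (coverage floor), spinal canal Max 47 Gy, brachial
  plexus Max 60 Gy, shell(PTV+1cm) Max ``D_p``, shell(PTV+7cm) Max
  ``0.75*D_p``, external ring Max ``0.8*D_p``;
* 13 objectives — PTV LTCP, staged lung/heart/esophagus mean-dose
  reductions, and shell maxima steering dose conformity.

LTCP — logarithmic tumor control probability — is the convex PTV
coverage surrogate ``LTCP = mean_j exp(-alpha * (d_j - ref))`` with
reference ``0.95*D_p``; it equals 1 for a uniform dose at the reference
and decreases as coverage improves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

SUPPORTED_PRESCRIPTIONS = (60.0, 66.0, 70.0)

#: Default relaxation multiplier applied to an achieved objective value
#: when the Goal was not met (the inserted bound is achieved * factor).
DEFAULT_RELAXATION_FACTOR = 1.03


@dataclass(frozen=True)
class LTCPParams:
    """LTCP reference dose (Gy) and cell-sensitivity slope alpha (1/Gy)."""

    reference_Gy: float
    alpha_per_Gy: float

    def __post_init__(self):
        if self.reference_Gy <= 0 or self.alpha_per_Gy <= 0:
            raise ValueError("LTCP reference and alpha must be positive")


@dataclass(frozen=True)
class HardConstraint:
    structure: str
    kind: str  # "Max" | "Mean"
    bound_Gy: float
    sense: str = "le"  # "le" caps dose; "ge" is a coverage floor (PTV mean)


@dataclass(frozen=True)
class Objective:
    priority: int
    structure: str
    kind: str  # "Mean" | "Max" | "LTCP"
    goal: float
    sufficient: float | None = None
    ltcp: LTCPParams | None = None

    @property
    def label(self) -> str:
        return f"{self.priority}:{self.structure}:{self.kind}"


@dataclass
class WishList:
    D_p: float
    hard_constraints: list[HardConstraint] = field(default_factory=list)
    objectives: list[Objective] = field(default_factory=list)
    relaxation_factor: float = DEFAULT_RELAXATION_FACTOR

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.relaxation_factor <= 1.0:
            raise ValueError("relaxation factor must exceed 1")
        priorities = [o.priority for o in self.objectives]
        if priorities != list(range(1, len(priorities) + 1)):
            raise ValueError(
                f"objective priorities must be contiguous from 1, got {priorities}"
            )

    def structure_names(self) -> set[str]:
        names = {c.structure for c in self.hard_constraints}
        names.update(o.structure for o in self.objectives)
        return names

    def restricted_to(self, available: set[str]) -> "WishList":
        """Drop optional structures (e.g. brachial plexus) not present.

        Priorities are re-validated, so objectives may only be dropped if
        that keeps them contiguous; in the default list only hard
        constraints reference optional structures.
        """
        return WishList(
            D_p=self.D_p,
            hard_constraints=[
                c for c in self.hard_constraints if c.structure in available
            ],
            objectives=list(self.objectives),
            relaxation_factor=self.relaxation_factor,
        )


def ltcp_params_for(D_p: float) -> LTCPParams:
    """Prescription-dependent LTCP settings (alpha 0.85 at 60 Gy, else 0.8)."""
    alpha = 0.85 if D_p == 60.0 else 0.80
    return LTCPParams(reference_Gy=0.95 * D_p, alpha_per_Gy=alpha)


def ltcp_goal_for(D_p: float) -> float:
    return 0.14 if D_p == 60.0 else 0.12


def build_wishlist(
    D_p: float, relaxation_factor: float = DEFAULT_RELAXATION_FACTOR
) -> WishList:
    """The default LA-NSCLC wish-list for a supported prescription dose."""
    if D_p not in SUPPORTED_PRESCRIPTIONS:
        raise ValueError(
            f"unsupported prescription {D_p} Gy; expected one of {SUPPORTED_PRESCRIPTIONS}"
        )
    params = ltcp_params_for(D_p)
    g = ltcp_goal_for(D_p)
    hard = [
        HardConstraint("PTV", "Max", 1.02 * D_p),
        HardConstraint("PTV", "Mean", 0.997 * D_p, sense="ge"),
        HardConstraint("spinal_canal", "Max", 47.0),
        HardConstraint("brachial_plexus", "Max", 60.0),
        HardConstraint("shell_1cm", "Max", D_p),
        HardConstraint("shell_7cm", "Max", 0.75 * D_p),
        HardConstraint("external_ring", "Max", 0.8 * D_p),
    ]
    objectives = [
        Objective(1, "PTV", "LTCP", goal=g, sufficient=g, ltcp=params),
        Objective(2, "lungs", "Mean", goal=19.0),
        Objective(3, "shell_3mm", "Max", goal=D_p, sufficient=D_p),
        Objective(4, "shell_1cm", "Max", goal=0.9 * D_p, sufficient=0.9 * D_p),
        Objective(5, "shell_7cm", "Max", goal=0.65 * D_p),
        Objective(6, "lungs", "Mean", goal=13.0),
        Objective(7, "heart", "Mean", goal=13.0),
        Objective(8, "esophagus", "Mean", goal=18.0),
        Objective(9, "shell_3cm", "Max", goal=0.75 * D_p),
        Objective(10, "shell_7cm", "Max", goal=0.55 * D_p),
        Objective(11, "lungs", "Mean", goal=0.0),
        Objective(12, "heart", "Mean", goal=0.0),
        Objective(13, "esophagus", "Mean", goal=0.0),
    ]
    return WishList(
        D_p=D_p,
        hard_constraints=hard,
        objectives=objectives,
        relaxation_factor=relaxation_factor,
    )


def ltcp(ptv_doses, params: LTCPParams) -> float:
    """Logarithmic tumor control probability of the PTV dose vector.

    Strictly decreasing and convex in every voxel dose; equals 1 for a
    uniform dose at the reference.
    """
    return float(np.exp(log_ltcp(ptv_doses, params)))


def log_ltcp(ptv_doses, params: LTCPParams) -> float:
    """``log(LTCP)`` via a numerically stable log-sum-exp.

    The optimizer works in log space: log-sum-exp is convex with a
    softmax gradient of bounded norm, whereas the raw exponentials
    overflow for cold voxels.
    """
    d = np.asarray(ptv_doses, dtype=float)
    if d.size == 0:
        raise ValueError("LTCP of an empty PTV is undefined")
    z = -params.alpha_per_Gy * (d - params.reference_Gy)
    return float(logsumexp(z) - np.log(d.size))


def evaluate_objective(entry: Objective, structure_doses) -> float:
    """Evaluate one wish-list objective on a structure-dose mapping.

    ``structure_doses`` maps structure name -> voxel-dose vector; Mean
    and Max are in Gy, LTCP is dimensionless.
    """
    try:
        d = np.asarray(structure_doses[entry.structure], dtype=float)
    except KeyError:
        raise KeyError(
            f"objective references unknown structure {entry.structure!r}"
        ) from None
    if entry.kind == "Mean":
        return float(d.mean())
    if entry.kind == "Max":
        return float(d.max())
    if entry.kind == "LTCP":
        if entry.ltcp is None:
            raise ValueError(f"objective {entry.label} lacks LTCP parameters")
        return ltcp(d, entry.ltcp)
    raise ValueError(f"unknown objective kind {entry.kind!r}")


# ---------------------------------------------------------------------------
# YAML round-trip, so new treatment sites can be configured declaratively.

def wishlist_to_dict(wl: WishList) -> dict:
    return {
        "D_p": wl.D_p,
        "relaxation_factor": wl.relaxation_factor,
        "hard_constraints": [
            {"structure": c.structure, "kind": c.kind, "bound_Gy": c.bound_Gy,
             "sense": c.sense}
            for c in wl.hard_constraints
        ],
        "objectives": [
            {
                "priority": o.priority,
                "structure": o.structure,
                "kind": o.kind,
                "goal": o.goal,
                "sufficient": o.sufficient,
                **(
                    {"ltcp": {"reference_Gy": o.ltcp.reference_Gy,
                              "alpha_per_Gy": o.ltcp.alpha_per_Gy}}
                    if o.ltcp
                    else {}
                ),
            }
            for o in wl.objectives
        ],
    }


def wishlist_from_dict(d: dict) -> WishList:
    return WishList(
        D_p=float(d["D_p"]),
        relaxation_factor=float(d.get("relaxation_factor", DEFAULT_RELAXATION_FACTOR)),
        hard_constraints=[
            HardConstraint(
                c["structure"], c["kind"], float(c["bound_Gy"]), c.get("sense", "le")
            )
            for c in d.get("hard_constraints", [])
        ],
        objectives=[
            Objective(
                int(o["priority"]),
                o["structure"],
                o["kind"],
                float(o["goal"]),
                None if o.get("sufficient") is None else float(o["sufficient"]),
                LTCPParams(**o["ltcp"]) if "ltcp" in o else None,
            )
            for o in d.get("objectives", [])
        ],
    )


def save_wishlist_yaml(path, wl: WishList) -> None:
    import yaml

    with open(path, "w") as f:
        yaml.safe_dump(wishlist_to_dict(wl), f, sort_keys=False)


def load_wishlist_yaml(path) -> WishList:
    import yaml

    with open(path) as f:
        return wishlist_from_dict(yaml.safe_load(f))
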