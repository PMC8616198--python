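# lexiplan

Wish-list-driven lexicographic IMRT planning with integrated beam-angle
optimization, at desk scale.

`lexiplan` is a research toolkit for automated multi-criterial
radiotherapy treatment planning of locally advanced non-small-cell lung
cancer (LA-NSCLC).  It reproduces the full automated-planning chain on
synthetic thorax phantoms: a prioritized *wish-list* drives a two-round
lexicographic (epsilon-constraint) fluence-map optimization (FMO); a
greedy beam-angle optimizer (BAO) selects gantry angles from the
ipsilateral candidate arc by running that same optimization for every
candidate; the resulting plan is handed over, via dose-volume-histogram
(DVH) line objectives, to a surrogate re-optimizer standing in for a
commercial treatment planning system; and a comparison layer provides
paired Wilcoxon statistics, population DVHs with bootstrap confidence
bands, beam-angle histograms and clinical constraint audits.  It is
aimed at medical-physics researchers who want to study prioritized
optimization, beam-angle selection and automated plan handover without a
clinical TPS in the loop.

## The method in brief

A wish-list consists of hard constraints (never violated — e.g. PTV
D_max <= 1.02 D_p, spinal canal D_max <= 47 Gy, entrance-dose caps on an
external ring) and objectives with priorities, each carrying a *Goal*
and optionally a *Sufficient* value.  Objectives are minimized in
priority order; after minimizing objective k, a constraint is added so
later stages cannot undo it:

* round 1 — insert the **Goal** if it was reached (even if further
  improvement was possible), else the achieved value times a small
  relaxation (1.03);
* round 2 — re-minimize every objective **without** a Sufficient value
  to the fullest extent, in priority order.

PTV coverage is the top priority through the logarithmic tumor control
probability, a convex surrogate

    LTCP = (1/m) Σ_j exp(−α (d_j − 0.95 D_p)),   α = 0.85/0.80 Gy⁻¹,

equal to 1 at a uniform dose of 0.95 D_p and driven to its goal
(0.14 at 60 Gy, 0.12 at 66/70 Gy).  Mean/Max stages are linear programs
(HiGHS); LTCP stages are smooth convex programs solved in log space.

BAO adds beams greedily from the candidate arc (140→40° for right-sided,
320→220° for left-sided tumors, traversed ipsilaterally), scoring each
candidate by a full two-round FMO; nested prefixes of one trajectory
give 4/6/8-beam plans in a single run.  The handover samples each OAR
DVH every 0.7 Gy into line objectives, adds fixed PTV points
(D_p ± 0.5 Gy), max points and a normal-tissue objective, and the
surrogate re-optimizer rebuilds the plan from that template by
priority-weighted penalty minimization.

## Worked example

```python
from lexiplan import (build_wishlist, check_clinical_constraints,
                      generate_phantom, normalize_plan, plan_without_bao)
from lexiplan.studies import STUDY_GEOMETRY, STUDY_PHANTOM_CONFIG

phantom = generate_phantom(STUDY_PHANTOM_CONFIG, seed=3)
wishlist = build_wishlist(phantom.prescription_Gy)        # 66 Gy
plan = plan_without_bao(phantom, wishlist, geometry=STUDY_GEOMETRY)
for rec in plan.stage_log[:3]:
    print(rec.priority, rec.objective, rec.achieved, rec.bound_inserted, rec.bound_kind)
print(check_clinical_constraints(normalize_plan(plan), phantom).passed)
```

The stage log shows the lexicographic bookkeeping (excerpt from
`examples/03_lexicographic_fmo.py`):

```
p 6 6:lungs:Mean        achieved 14.0207 -> bound 14.4413 (relaxed)
p 7 7:heart:Mean        achieved 21.7294 -> bound 22.3813 (relaxed)
p 8 8:esophagus:Mean    achieved  3.0603 -> bound 18.0000 (goal)
```

Priority 8 *met* its 18 Gy goal, so the goal — not the better achieved
value — is frozen in, leaving room for the conformity and second-pass
objectives below it; priorities 6–7 missed their goals and are locked at
1.03× their optima.  The normalized plan then passes the full clinical
audit on this phantom:

```
PTV   V_95%  99.36 > 98.00  pass      lungs  V_20Gy  32.66 < 35.00  pass
heart V_30Gy 35.94 < 40.00  pass      body   D_max   67.21 < 70.62  pass
overall: pass
```

(Absolute OAR doses run above clinical values because a single axial
slice concentrates every beam in the OAR plane; see
`docs/methods.md`.)

The `examples/` directory walks through each capability: phantom and
conformity structures, the dose engine and DVH metrics, lexicographic
FMO, beam-angle optimization, the template handover, and the beam-count
study.  A thin CLI covers the same pipeline from the shell
(`lexiplan phantom`, `lexiplan plan --beams 6`, `lexiplan study-beamcount`,
`lexiplan compare`, ...).

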