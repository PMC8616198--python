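"""DVH-to-objective handover and surrogate re-optimization.

Converts an FMO plan's OAR DVHs into a patient-specific objective
template (line objectives sampled every 0.7 Gy, fixed PTV points,
priorities and NTO), writes it as XML, and rebuilds a plan from the
template alone, measuring how closely the DVHs are reproduced.
"""

import numpy as np

import lexiplan as lp
from lexiplan.handover import surrogate_reoptimize, template_from_plan, template_to_xml
from lexiplan.studies import STUDY_GEOMETRY, STUDY_PHANTOM_CONFIG

phantom = lp.generate_phantom(STUDY_PHANTOM_CONFIG, seed=3)
derived = lp.derive_structures(phantom)
influence = lp.compute_influence(phantom, lp.DEFAULT_TEMPLATE_ANGLES, STUDY_GEOMETRY)
plan = lp.normalize_plan(
    lp.solve_wishlist_plan(phantom, influence, lp.build_wishlist(66.0), derived)
)

template = template_from_plan(plan)
template_to_xml(template, "objective_template.xml")
for line in template.line_objectives:
    print(f"  {line.structure:13s} line objective: {len(line.doses_Gy)} dose-volume "
          f"points, priority {line.priority}")
print("template written to objective_template.xml")

rebuilt = surrogate_reoptimize(
    influence, template, plan.structures, x0=plan.fluence, normalize=False
)
print("\nDVH reproduction (worst deviation at any 0.7 Gy sample):")
for line in template.line_objectives:
    d = rebuilt.structure_dose(line.structure)
    achieved = 100.0 * (d[None, :] >= line.doses_Gy[:, None]).mean(axis=1)
    dev = np.abs(achieved - line.volumes_pct).max()
    print(f"  {line.structure:13s} {dev:5.2f} percentage points")
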