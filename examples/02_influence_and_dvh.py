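"""Trace a dose influence matrix and read out DVH metrics.

A uniform-fluence 3-beam plan is not a treatment plan — this just shows
the dose engine (exponential attenuation with lung transmission, Gaussian
penumbra) and the DVH/metric machinery.
"""

import numpy as np

import lexiplan as lp

phantom = lp.generate_phantom(lp.SMALL_CONFIG, seed=17)
influence = lp.compute_influence(phantom, [0.0, 120.0, 240.0], lp.BeamGeometry())
print(f"influence matrix: {influence.matrix.shape[0]} voxels x "
      f"{influence.matrix.shape[1]} beamlets, {influence.matrix.nnz} nonzeros")

dose = lp.compute_dose(influence, np.full(influence.n_beamlets, 30.0))
for name in ("PTV", "lungs", "heart", "spinal_canal"):
    d = dose[influence.rows_for_mask(phantom.masks[name])]
    print(f"  {name:13s} D_mean {lp.dose_metric(d, 'D_mean'):6.2f} Gy   "
          f"D_max {lp.dose_metric(d, 'D_max'):6.2f} Gy")

dvh = lp.compute_dvh(dose[influence.rows_for_mask(phantom.masks["PTV"])],
                     structure="PTV")
print(f"\nPTV DVH: V at half the max dose = "
      f"{dvh.volume_at(dvh.max_dose() / 2):.1f}% of the volume")
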