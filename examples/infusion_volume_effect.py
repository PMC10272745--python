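"""Effect of infusate volume (1, 2, 4 mL) at a fixed 12 mg / 1 min dose.

Larger infusate volumes push the bolus further rostral by plug flow, exposing
more of the spinal tissue early on and improving cranial delivery — the dose
itself is unchanged.
"""

import numpy as np

from itpk import (
    DoseSchedule,
    InfusionEvent,
    exposure_fraction,
    pk_metrics,
    reference_config,
    simulate,
)

params, _ = reference_config()
t_end = 7 * 24 * 60.0
threshold = 1.0  # ug/mL tissue level counted as exposed (explicit choice)

print("12 mg over 1 min at the lumbar site, varying infusate volume")
print(f"{'volume':>9}  {'cranial Cmax ug/mL':>18}  {'tissue fraction >= 1 ug/mL at 1 h':>33}")
for volume in (1.0, 2.0, 4.0):
    ev = InfusionEvent.create(volume_ml=volume, duration_min=1.0,
                              dose_ug=12000.0, site_cm=3.0)
    res = simulate(params, DoseSchedule(events=(ev,)), t_end,
                   output_times=np.linspace(0.0, t_end, 169))
    cmax = pk_metrics(res.times, res.lumped(4))["cmax"]
    frac = exposure_fraction(res, threshold=threshold, at_time=60.0)
    print(f"{volume:6.0f} mL  {cmax:18.4f}  {frac:33.2f}")
# The 1-hour exposure front tracks the plug-flow displacement V/A; by the
# next day effective dispersion has spread the residue along the whole rod,
# so early snapshots are where the volume effect on the spine is visible.
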