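"""Single 12 mg lumbar dose: spinal and systemic PK over one week.

Loads the shipped NHP reference configuration (12 mg in 1 mL over 1 min at
the lumbar site, followed by a 0.25 mL flush), integrates the 204-equation
system for 7 days and summarises exposure in lumbar CSF, plasma and cranial
tissue.
"""

import numpy as np

from itpk import (
    exposure_fraction,
    pk_metrics,
    reference_config,
    sample_region,
    simulate,
    total_mass,
)

params, schedule = reference_config()
t_end = 7 * 24 * 60.0
res = simulate(params, schedule, t_end,
               output_times=np.linspace(0.0, t_end, 169))  # hourly-ish

lumbar_csf = sample_region(res, "spinal_csf", "lumbar")
plasma = res.lumped(5)
cranial = res.lumped(4)

m_csf = pk_metrics(res.times, lumbar_csf)
m_plasma = pk_metrics(res.times, plasma)
m_cranial = pk_metrics(res.times, cranial)

print("single 12 mg / 1 mL / 1 min lumbar dose, 7-day horizon")
print(f"lumbar CSF   Cmax = {m_csf['cmax']:9.3f} ug/mL at t = {m_csf['tmax']:.0f} min")
print(f"plasma       Cmax = {m_plasma['cmax']:9.4f} ug/mL at t = {m_plasma['tmax']:.0f} min")
print(f"cranial      Cmax = {m_cranial['cmax']:9.4f} ug/mL at t = {m_cranial['tmax']:.0f} min")
frac = exposure_fraction(res, threshold=1.0, at_time=24 * 60.0)
print(f"spinal tissue fraction >= 1 ug/mL at day 1: {frac:.2f}")
print(f"drug remaining in the body at day 7: "
      f"{total_mass(res.state_at(-1), params) / 1000.0:.2f} mg of 12 mg dosed")
# The CSF peak sits at the injection site minutes after the bolus; plasma
# peaks later and lower because spinal tissue buffers the drug before it
# leaks into the circulation.
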