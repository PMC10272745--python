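"""Recover the effective dispersion coefficient from lumbar-CSF data.

Generates a noise-free synthetic lumbar-CSF concentration series under the
reference parameters (D = 0.1 cm^2/min), then refits D as the sole free
parameter from a deliberately wrong starting value — a parameter-recovery
check of the calibration machinery.
"""

import numpy as np

from itpk import (
    FitSpec,
    FreeParameter,
    fit,
    generate_synthetic,
    reference_config,
)

params, schedule = reference_config()
week = 7 * 24 * 60.0
times = np.linspace(week / 24.0, week, 24)

dataset = generate_synthetic(
    params, schedule, {"spinal_csf:lumbar": times}, noise_cv=0.0, seed=0,
    truth={"transport.dispersion_D": params.transport.dispersion_D})

spec = FitSpec(free=[FreeParameter("transport.dispersion_D", 1e-3, 10.0)])
result = fit(spec, [(dataset, schedule)], params,
             initial_guess={"transport.dispersion_D": 0.5})

true_d = params.transport.dispersion_D
got_d = result.values["transport.dispersion_D"]
print(f"generating D : {true_d:.4f} cm^2/min")
print(f"starting D   : 0.5000 cm^2/min")
print(f"recovered D  : {got_d:.4f} cm^2/min "
      f"({result.recovery['transport.dispersion_D']:.2e} relative error, "
      f"{result.nfev} simulations)")
# With noise-free data the log-space least squares lands back on the
# generating value to optimizer precision: D is well identified by the shape
# of the lumbar washout curve.
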