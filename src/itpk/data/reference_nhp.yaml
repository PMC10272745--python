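# Reference parameter set: adult non-human primate (cynomolgus monkey) scale.
#
# The effective dispersion coefficient (0.1 cm^2/min) is the value inferred
# for ASO transport in NHP spinal CSF; it is an apparent dispersion from
# pulsation-driven mixing, not molecular diffusion.  All other transport,
# exchange, clearance and partition values are documented stand-ins chosen in
# physiological NHP ranges and intended to be overridden with drug- and
# subject-specific calibrations.
#
# Units are spelled out in the key names (cm, min, mL; dose in ug).
model:
  geometry:
    length_cm: 20.0          # sacral (x=0, closed) to cervical (x=L) end
    csf_area_cm2: 0.5        # spinal CSF channel cross-section -> 10 mL CSF
    tissue_area_cm2: 0.3     # spinal cord rod cross-section -> 6 mL tissue
    n_elements: 100          # axial volume elements per distributed rod
  transport:
    dispersion_cm2_min: 0.1  # effective (geometry-induced) dispersion in CSF
    clearance_per_min:
      spinal_csf: 1.0e-4
      spinal_tissue: 5.0e-5
      cranial_csf: 1.0e-4
      cranial_tissue: 2.0e-5
      blood: 5.0e-3
      peripheral: 1.0e-4
  exchange:
    U_ml_min:                # lumped U*A exchange coefficients
      1-2: 0.2               # spinal CSF <-> spinal tissue (whole interface)
      1-5: 0.05              # spinal CSF <-> blood (whole interface)
      2-5: 0.02              # spinal tissue <-> blood (whole interface)
      1-3: 0.2               # cervical boundary <-> cranial CSF
      3-4: 0.1               # cranial CSF <-> brain
      4-5: 0.05              # brain <-> blood
      5-6: 0.5               # blood <-> peripheral
    beta:                    # trapping coefficients, 0 <= beta <= 1
      1-2: 0.05
      1-5: 0.02
      2-5: 0.05
      3-4: 0.05
      4-5: 0.5
      5-6: 0.2
  volumes_ml:
    cranial_csf: 8.0
    cranial_tissue: 72.0
    blood: 150.0
    peripheral: 2000.0
  brain_partition:
    regions: [pons, hippocampus, cerebellum, cortex]
    volumes_ml: [1.8, 1.2, 6.0, 63.0]   # cortex = V4 minus the named regions
    phi: [0.08, 0.07, 0.15, 0.70]       # sums to 1
  landmarks_fraction_of_L:
    lumbar: 0.15
    thoracic: 0.50
    cervical: 0.90
  cervical_advection: true

# Single-dose reference protocol: 12 mg in 1 mL over 1 min at the lumbar
# site, followed by a 1-min 0.25 mL drug-free flush.
schedule:
  horizon_min: 10080.0       # 7 days
  events:
    - {start_min: 0.0, dose_ug: 12000.0, volume_ml: 1.0, duration_min: 1.0,
       site_cm: 3.0, halfwidth_cm: 2.0}
    - {start_min: 1.0, dose_ug: 0.0, volume_ml: 0.25, duration_min: 1.0,
       site_cm: 3.0, halfwidth_cm: 2.0}
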