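"""Published reference regressions and acquisition constants.

These are the default generative parameters for synthetic cohorts and
phantoms: sigmoid T2*-versus-gestation trajectories per outcome group,
linear trends for maternal hemoglobin, placental volume and placental T1,
a constant-plus-tiny-slope model for maternal SpO2, outcome-group
proportions, and the six multi-echo gradient-echo (MEGE) echo times.

Outcome groups: UN = uncomplicated/normal, PA = primary adverse
(hypertensive disorders, birthweight < 5th percentile, stillbirth),
SA = secondary abnormal (other complications, e.g. spontaneous preterm
birth).  Residual SDs are RMS fit residuals in the units of each variable.
"""

from __future__ import annotations

GROUPS = ("UN", "PA", "SA")
SITES = ("OHSU", "Utah")

#: outcome-group proportions (UN, PA, SA)
GROUP_PROBS = (0.626, 0.222, 0.152)

#: probability a subject completes 1, 2 or 3 scans
SCANS_PER_SUBJECT_PROBS = (0.14, 0.20, 0.66)

#: site proportions (OHSU, Utah), 179 vs 137 of 316 subjects
SITE_PROBS = (179 / 316, 137 / 316)

#: gestational scan windows in weeks
GA_WINDOWS = ((10.0, 20.0), (20.0, 30.0), (30.0, 40.0))

#: subjects in the reference study
DEFAULT_N_SUBJECTS = 316

#: sigmoid T2* model (p1, p2, p3, p4) in ms and residual SD (ms), per group
T2STAR_SIGMOID = {
    "UN": ((-59.2, -0.24, 29.3, 84.6), 9.6),
    "PA": ((-57.6, -0.19, 25.2, 82.9), 13.8),
    "SA": ((-53.7, -0.28, 26.8, 85.4), 12.5),
}

#: sigmoid-derivative rate model (p1, p2, p3) in ms/wk and residual SD, per group
RATE_SIGMOID_DERIVATIVE = {
    "UN": ((-64.9, -0.20, 30.1), 1.2),
    "PA": ((-5574.6, -0.02, 225.9), 1.4),   # near-linear degenerate regime
    "SA": ((-79.0, -0.16, 30.7), 1.4),
}

#: linear hemoglobin model (intercept, slope per week) and residual SD, per group
HB_LINEAR = {
    "UN": ((13.27, -0.046), 1.02),
    "PA": ((13.46, -0.039), 1.04),
    "SA": ((12.65, -0.018), 0.92),
}

#: linear SpO2 model (%) — essentially constant across gestation
SPO2_LINEAR = {
    "UN": ((97.05, 0.003), 2.4),
    "PA": ((95.99, 0.052), 3.1),
    "SA": ((98.54, -0.043), 1.4),
}

#: linear placental volume model (cm^3)
VOLUME_LINEAR = {
    "UN": ((-372.4, 32.2), 122.0),
    "PA": ((-360.5, 30.0), 132.0),
    "SA": ((-383.0, 33.1), 158.0),
}

#: linear placental T1 model (ms); reference fits come from one site only
T1_LINEAR = {
    "UN": ((2513.0, -26.9), 208.0),
    "PA": ((2591.0, -31.2), 246.0),
    "SA": ((2556.0, -26.5), 158.0),
}

#: z-score moments (mean, SD) of scans against the UN reference
ZSCORE_MOMENTS = {
    "UN": (0.02, 1.00),
    "PA": (-0.92, 1.49),
    "SA": (-0.43, 1.34),
}

#: six in-phase MEGE echo times (ms)
ECHO_TIMES_MS = (4.92, 9.84, 19.68, 29.52, 36.90, 49.20)

#: acquisition voxel dimensions (mm)
VOXEL_DIMS_MM = (1.75, 1.75, 3.5)

#: fitted T2* at or above this value is treated as amniotic-fluid
#: contamination and excluded from placental summaries (ms)
T2STAR_EXCLUDE_MS = 250.0
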