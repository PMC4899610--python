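"""Published reference measurements for CL-liposome peroxidation.

These numbers are transcribed, as data, from the summary table of the
published cardiolipin-liposome peroxidation study that this package
models; they are measured inputs for the reproduction report, never
values computed by this code.  Rates are mean +/- sd in nM/min over the
stated replicates; durations are inhibition periods in minutes.  The
published derived columns (chain propagation length, inhibition
efficiency) were computed by the study from these rates with a radical
generation rate of 11.8 nM/min, itself calibrated from the
alpha-tocopherol reference run (1 uM, 170 min plateau, two radicals
trapped per molecule).
"""

from __future__ import annotations

#: Calibration inputs of the published radical-flux estimate.
REFERENCE_CALIBRATION = {
    "antioxidant": "alpha-tocopherol",
    "concentration_M": 1e-6,
    "inhibition_duration_min": 170.0,
    "stoichiometry": 2.0,
}

#: Uninhibited oxidation rate used in the published worked example, M/min.
UNINHIBITED_RATE_M_MIN = 3.3e-7

#: Transcribed summary-table rows:
#: name -> (rate nM/min, rate sd, published chain length, published
#:          efficiency, duration min or None, duration sd, n replicates)
TABLE_ROWS = {
    "Pure CL": (334.0, 32.0, 28.0, None, None, None, 5),
    "decPQH2": (3.28, 1.1, 0.28, 102, 48.7, 2.1, 3),
    "SkQ1H2": (3.87, 0.6, 0.33, 86, 58.7, 5.7, 3),
    "decUQH2": (4.49, 1.2, 0.38, 74, 114.0, 4.4, 3),
    "MitoQH2": (6.70, 2.0, 0.57, 50, 91.0, 8.9, 2),
    "Q6H2": (4.05, 0.5, 0.34, 82, 124.0, 9.0, 3),
    "Q10H2": (4.55, 0.4, 0.39, 73, 104.0, 1.0, 3),
    "alpha-tocopherol": (10.6, 0.5, 0.90, 32, 171.0, 1.0, 3),
    "HPMC": (8.62, 1.8, 0.73, 39, None, None, 5),  # duration N.A.: variable loss on incorporation
}
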