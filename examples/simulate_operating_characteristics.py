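"""Operating characteristics of the moment-based estimator by simulation.

Runs a small operating-characteristics study on the 10-study / 5-design
layout for two heterogeneity values, and prints per-parameter coverage of
nominal 95% intervals, empirical vs model-based standard errors, and the
mean truncated variance-component estimates.  (Use n_reps=3000 for
publication-grade Monte-Carlo precision of about +/-0.01 on coverage.)
"""

import netmoments as nm

config = nm.SimulationConfig(
    layout="run1",
    tau_beta_sq=[0.0, 0.168],
    tau_omega_sq=0.0,
    n_reps=500,
    seed=22,
)
metrics = nm.run_simulation_study(config, model="RI")

cols = [
    "tau_beta_sq", "tau_omega_sq", "param",
    "se_emp", "se_model", "cover", "excess_kurt",
    "e_tau_beta_sq", "e_tau_omega_sq",
]
print(metrics[cols].round(3).to_string(index=False))
print()
print(
    "cover is the fraction of 95% CIs containing the true effect (0 here);\n"
    "values above 0.95 reflect the conservatism of allowing for a\n"
    "superfluous inconsistency variance when the data are consistent.\n"
    "se_emp ~ se_model indicates the model-based uncertainty is calibrated;\n"
    "e_tau_* show the positive truncation bias of the variance estimates in\n"
    "small networks."
)
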