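"""Bias/RMSE study: closed-form estimators vs fitting, with noise.

Runs the comparison harness on a small tissue grid at two noise levels
and prints the bias of each estimator's ADC0. Closed-form rows use 1,000
Rician replicates; the iterative fitters use 50 (they are looped).
"""

import breastdwi as bd

grid = [bd.TissueState(f_ivim=f, adc0=1.2e-3, kurtosis=k)
        for f in (0.0, 0.1) for k in (0.0, 1.0)]
report = bd.compare_estimators(grid, sigmas=(0.0, 0.02), seed=1,
                               n_reps=1000, nlls_reps=50)

cols = ["estimator", "sigma", "f_true", "k_true", "bias_f", "bias_adc0",
        "rmse_adc0"]
with __import__("pandas").option_context("display.width", 120):
    print(report.table[cols].to_string(index=False,
                                       float_format=lambda v: f"{v:.3e}"))

print("\nsigma=0 rows: exact_closed_form is exact; as_printed shows the "
      "documented K>0 fraction bias; no_ivim is exact only when f=0.")
print("sigma=0.02 (SNR 50): all estimators acquire noise-driven spread; "
      "ADC0 remains within a few percent for the closed forms.")
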