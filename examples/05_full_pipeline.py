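"""The orchestrated analysis: preprocess -> model grid -> diagnostics -> PPC.

Runs the full chain on a synthetic experiment whose truth is an inverted-U
drift effect of SC, and prints the DIC model comparison, the selected
model's coefficient tests and a slice of the posterior predictive check.
Takes a minute or two.
"""

from sceneddm import run_full_analysis

report = run_full_analysis({
    "seed": 11,
    "synthetic": {
        "n_scenes": 2500,
        "n_per_condition": 60,
        "behaviour": {"n_subjects": 4, "beta1": 0.3, "beta2": -1.0},
    },
    "fit": {"chains": 2, "iterations": 600, "burn": 100, "tune": 300},
    "grid": {"covariates": ["SC"]},
    "ppc": {"n_sims": 50},
})

print("model comparison (lower DIC is better):")
print(report.grid_comparison.to_string(index=False))
print(f"\nbest model: {report.best_model}")

coef = report.posterior_summary.set_index("parameter")
for name in ("beta_v_lin", "beta_v_quad"):
    row = coef.loc[name]
    print(f"  {name}: mean {row['mean']:+.3f}, P = {row['P']:.4f} ({row.direction})")

print("\nbehaviour summary (error rate per condition x instruction):")
print(report.behaviour_summary[["condition", "instruction", "error_rate",
                                "mean_rt_correct"]].to_string(index=False))

acc = report.ppc[report.ppc["stat"] == "accuracy"]
print("\nposterior predictive check, accuracy per cell (observed vs predicted):")
print(acc[["cond", "instr", "observed", "predicted", "lo95", "hi95"]]
      .to_string(index=False))
print("\nThe quadratic-drift model wins the DIC comparison, its quadratic "
      "coefficient is credibly\nnegative, and simulated datasets from the "
      "posterior reproduce the observed accuracies.")
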