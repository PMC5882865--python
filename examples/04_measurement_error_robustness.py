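"""Identification accuracy under radar-realistic measurement errors.

Radar retrieval of insect features is far less precise than laboratory
measurement: current accuracy is about +/-40% (RMSPE) for mass and 1 Hz for
wingbeat frequency.  The four built-in error cases inject those errors into
both the training and testing cohorts (the tree is rebuilt and the SVMs
retrained on the noisy training data), quantifying how much identification
would improve if retrieval precision improved.
"""

from dtsvm import ExperimentConfig, builtin_cases, run_error_cases

reports = run_error_cases(ExperimentConfig(samples_per_class=1000, seed=1))

print("case      wingbeat   mass/lwr RMSPE   body length   mean accuracy")
for spec in builtin_cases():
    rep = reports[spec.case_label]
    bl = f"{spec.rmspe.get('body_length', 0):.0%}" if "body_length" in spec.rmspe else "-"
    print(f"{spec.case_label:9s} {spec.wingbeat_noise_std:.0f} Hz       "
          f"{spec.rmspe['mass']:.0%}              {bl:11s}   {rep.mean_accuracy:.2f}")

print("\nspecies S, V and W (distinctive wingbeat bands) under Case I: "
      + ", ".join(f"{s}={reports['Case I'].per_species_accuracy[s]:.2f}" for s in "SVW"))
print("\nHalving the mass and shape errors roughly closes half the gap to the "
      "noise-free accuracy; a 10% body-length retrieval adds a few more points.")
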