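"""Paired differential abundance with empirical-Bayes moderation.

Each protein is tested on per-subject log2(post/pre) differences; the
per-protein variances are shrunk toward a common prior before forming
the t-statistic, and Benjamini-Hochberg controls the FDR at 5% within
each intensity.
"""

from exprot import (
    SimulationParams,
    estimate_moderation,
    generate_cohort,
    paired_log_differences,
    run_differential,
)

study, truth = generate_cohort(SimulationParams(seed=1))

diffs = paired_log_differences(study, "high")
hyper = estimate_moderation(diffs.var(axis=1, ddof=1).to_numpy(), diffs.shape[1] - 1)
print(f"estimated prior: d0={hyper.d0}, s0^2={hyper.s0_sq:.4f}")
# d0 = inf means no excess variance dispersion beyond chi-square sampling:
# every protein is shrunk fully to the common variance.

for intensity in ("moderate", "high"):
    res = run_differential(study, intensity)
    n_sig = int(res["significant"].sum())
    n_up = int((res["significant"] & (res["direction"] == "up")).sum())
    print(f"{intensity}: {n_sig} significant at q<0.05 ({n_up} up, "
          f"{n_sig - n_up} down)")
# High intensity regulates roughly three times as many proteins as
# moderate intensity under the default planted fractions.
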