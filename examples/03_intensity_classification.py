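"""Partition responders across intensities and classify dose dependence.

Shared responders are classified by the magnitude ratio r (change at
high over change at moderate): r >= 1.25 is intensity-dependent, a high
fold change within 5% of the moderate one is intensity-independent,
anything else intermediate.
"""

import pandas as pd

from exprot import (
    SimulationParams,
    check_concordance,
    classify_intensity_dependence,
    generate_cohort,
    partition_by_intensity,
    run_differential,
)

study, truth = generate_cohort(SimulationParams(seed=1))
rm = run_differential(study, "moderate")
rh = run_differential(study, "high")

part = partition_by_intensity(rm, rh, alpha=0.05)
print("partition:", part.counts())

shared = sorted(part.shared)
rmi, rhi = rm.set_index("protein_id"), rh.set_index("protein_id")
shared_df = pd.DataFrame(
    {
        "protein_id": shared,
        "direction_moderate": rmi.loc[shared, "direction"].to_numpy(),
        "direction_high": rhi.loc[shared, "direction"].to_numpy(),
        "fc_moderate": rmi.loc[shared, "fold_change"].to_numpy(),
        "fc_high": rhi.loc[shared, "fold_change"].to_numpy(),
    }
)
discordant = check_concordance(shared_df)
print(f"discordant shared proteins: {len(discordant)}")
# Discordance among shared responders is expected to be (near) zero:
# planted responses are concordant, so any hits are FDR false positives.

conc = shared_df[~shared_df["protein_id"].isin(discordant)].copy()
conc["direction"] = conc["direction_high"]
classes = classify_intensity_dependence(conc)
print("dependence classes:", classes["klass"].value_counts().to_dict())
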