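import numpy as np
import pandas as pd
import pytest

from exprot.simulate import SimulationParams, generate_cohort


@pytest.fixture(scope="session")
def small_params() -> SimulationParams:
    """A scaled-down study: 200 proteins, 12 subjects, same fractions."""
    return SimulationParams(
        n_proteins=200,
        n_pqtl_proteins=60,
        n_gene_sets=12,
        set_size_range=(5, 30),
        trait_plan={"coronary_artery_disease": (6, 2), "blood_pressure": (5, 4)},
        seed=7,
    )


@pytest.fixture(scope="session")
def small_study(small_params):
    return generate_cohort(small_params)


@pytest.fixture()
def tiny_study():
    """Hand-built 3-protein, 2-subject paired study (both intensities)."""
    rows = []
    for intensity in ("moderate", "high"):
        for subj in ("P01", "P02"):
            for tp in ("pre", "post"):
                rows.append(
                    {
                        "sample_id": f"{subj}_{intensity[0].upper()}_{tp}",
                        "subject_id": subj,
                        "timepoint": tp,
                        "intensity": intensity,
                    }
                )
    samples = pd.DataFrame(rows)
    rng = np.random.default_rng(0)
    abundance = pd.DataFrame(
        rng.uniform(100, 1000, (3, len(rows))),
        index=pd.Index(["SL00001", "SL00002", "SL00003"], name="protein_id"),
        columns=[r["sample_id"] for r in rows],
    )
    proteins = pd.DataFrame(
        {
            "protein_id": ["SL00001", "SL00002", "SL00003"],
            "gene_symbol": ["GENE1", "GENE2", "GENE3"],
        }
    )
    from exprot.simulate import ProteomeStudy

    return ProteomeStudy(abundance=abundance, samples=samples, proteins=proteins)
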