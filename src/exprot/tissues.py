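"""Probabilistic tissue-source inference from transcript abundance.

Under the assumption that a circulating protein most likely derives from
tissues expressing its transcript, the probability that tissue a is the
source of a protein with per-tissue transcript levels TPM_a ... TPM_n is

    p(tissue a) = TPM_a / (TPM_a + TPM_b + ... + TPM_n),

i.e. the TPM share of that tissue (the normalizing constant is fixed so
the probabilities sum to one). Per-protein vectors are averaged with
equal weights over a protein set, then grouped into organ systems; the
profile of an exercise-regulated set is compared with the profile of the
whole platform to expose relative enrichment of donor systems.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TissueExpressionMatrix",
    "TissueProfile",
    "tissue_probability",
    "aggregate_tissue_profile",
    "platform_relative_enrichment",
]


@dataclass
class TissueExpressionMatrix:
    """Genes x tissues TPM table plus a tissue -> organ-system map."""

    tpm: pd.DataFrame
    organ_map: pd.Series  # index: tissue, value: organ system

    def __post_init__(self) -> None:
        if isinstance(self.organ_map, pd.DataFrame):
            self.organ_map = self.organ_map.set_index("tissue")["organ_system"]
        if (self.tpm.to_numpy() < 0).any():
            raise ValueError("TPM values must be nonnegative")
        missing = set(self.tpm.columns) - set(self.organ_map.index)
        if missing:
            raise ValueError(
                f"tissues without an organ system: {sorted(missing)[:5]}"
            )

    @property
    def tissues(self) -> list[str]:
        return list(self.tpm.columns)


@dataclass
class TissueProfile:
    """Per-protein and aggregate source probabilities.

    ``per_protein`` is proteins x tissues (each row sums to 1);
    ``tissue_probs`` and ``organ_probs`` are the equal-weight aggregate
    distributions; proteins with no usable expression are counted in
    ``n_proteins_dropped``.
    """

    per_protein: pd.DataFrame
    tissue_probs: pd.Series
    organ_probs: pd.Series
    n_proteins_used: int
    n_proteins_dropped: int


def tissue_probability(tpm_row) -> np.ndarray:
    """Normalize one gene's per-tissue TPM vector into source
    probabilities. Raises on an all-zero row (the source is
    unassignable; callers drop and count such proteins)."""
    x = np.asarray(tpm_row, dtype=float)
    if (x < 0).any():
        raise ValueError("TPM values must be nonnegative")
    total = x.sum()
    if total <= 0:
        raise ValueError("all-zero expression row: tissue source unassignable")
    return x / total


def aggregate_tissue_profile(
    protein_set,
    matrix: TissueExpressionMatrix,
    platform_map: pd.DataFrame,
) -> TissueProfile:
    """Equal-weight aggregate source profile of a protein set.

    Each protein maps to its gene(s) through ``platform_map``; proteins
    with several genes use the mean of the genes' probability vectors.
    Proteins with no mapped gene or only all-zero expression rows are
    dropped (and counted). The aggregate is the plain mean over used
    proteins, then summed within organ systems.
    """
    proteins = list(protein_set)
    if not proteins:
        raise ValueError("empty protein set")
    genes_of = platform_map.groupby("protein_id")["gene_symbol"].agg(list)
    tissues = matrix.tissues
    rows, used = [], []
    n_dropped = 0
    for p in proteins:
        genes = [
            g
            for g in genes_of.get(p, [])
            if g in matrix.tpm.index and matrix.tpm.loc[g].sum() > 0
        ]
        if not genes:
            n_dropped += 1
            continue
        vecs = [tissue_probability(matrix.tpm.loc[g].to_numpy()) for g in genes]
        rows.append(np.mean(vecs, axis=0))
        used.append(p)
    if not used:
        raise ValueError("no protein in the set has usable expression")
    per_protein = pd.DataFrame(
        rows, index=pd.Index(used, name="protein_id"), columns=tissues
    )
    tissue_probs = per_protein.mean(axis=0)
    organ_probs = tissue_probs.groupby(matrix.organ_map.loc[tissues].to_numpy()).sum()
    organ_probs.index.name = "organ_system"
    return TissueProfile(
        per_protein=per_protein,
        tissue_probs=tissue_probs,
        organ_probs=organ_probs,
        n_proteins_used=len(used),
        n_proteins_dropped=n_dropped,
    )


def platform_relative_enrichment(
    exercise_profile: TissueProfile, platform_profile: TissueProfile
) -> pd.DataFrame:
    """Per-organ-system ratio of an exercise profile to the platform
    profile.

    Ratio > 1 flags systems contributing relatively more protein during
    exercise than the platform baseline. Systems with zero platform
    probability but nonzero exercise probability are flagged as
    infinitely enriched rather than given a numeric ratio.
    """
    ex = exercise_profile.organ_probs
    pl = platform_profile.organ_probs
    if set(ex.index) != set(pl.index):
        raise ValueError("organ-system labels differ between profiles")
    pl = pl.loc[ex.index]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = ex.to_numpy() / pl.to_numpy()
    infinite = (pl.to_numpy() == 0) & (ex.to_numpy() > 0)
    ratio = np.where(infinite, np.nan, ratio)
    return pd.DataFrame(
        {
            "organ_system": ex.index.to_numpy(),
            "exercise_prob": ex.to_numpy(),
            "platform_prob": pl.to_numpy(),
            "ratio": ratio,
            "infinite_enrichment": infinite,
        }
    )
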