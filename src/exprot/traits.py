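"""pQTL/GWAS integration: simulated direction of exercise effects on traits.

Exercise-responsive proteins are linked to their sentinel pQTL variants,
the variants are looked up in GWAS summary statistics and filtered at
genome-wide significance (p < 5e-8, strict). Trait betas are then
harmonized to the protein-raising allele: with a* the pQTL allele that
raises the protein level, oriented_beta is the trait beta expressed per
copy of a*. The simulated effect of the exercise response follows a sign
rule — a protein that rises with exercise and whose raising allele
increases trait risk simulates increased risk, and so on. Palindromic
variants (A/T, C/G) are strand-ambiguous and excluded by default. This
is a directional simulation, not a causal estimate.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

__all__ = [
    "link_pqtls",
    "filter_gwas",
    "orient_effect",
    "simulate_direction",
    "concordance_summary",
    "forest_table",
    "run_trait_simulation",
]

logger = logging.getLogger(__name__)

GWAS_SIGNIFICANCE = 5e-8
_PALINDROMIC = ({"A", "T"}, {"C", "G"})


class AlleleMismatchError(ValueError):
    """pQTL and GWAS rows report incompatible allele pairs."""


class PalindromicVariantError(ValueError):
    """Strand-ambiguous (A/T or C/G) variant cannot be harmonized."""


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    return {effect_allele, other_allele} in _PALINDROMIC


def link_pqtls(
    responsive_proteins, catalog: pd.DataFrame
) -> tuple[pd.DataFrame, dict]:
    """All (protein, variant) pQTL links for a responsive-protein set.

    Returns the link rows and a summary with the fraction of linked
    proteins under cis control, under trans control and under both
    (fractions can sum past 1 since a protein may have links of both
    kinds).
    """
    if catalog.empty:
        raise ValueError("pQTL catalog is empty")
    responsive = set(responsive_proteins)
    links = catalog[catalog["protein_id"].isin(responsive)].reset_index(drop=True)
    kinds = links.groupby("protein_id")["cis_trans"].agg(set)
    n_linked = len(kinds)
    summary = {
        "n_responsive": len(responsive),
        "n_linked_proteins": n_linked,
        "n_links": len(links),
        "frac_linked": n_linked / len(responsive) if responsive else 0.0,
        "frac_cis": float((kinds.apply(lambda s: "cis" in s)).mean()) if n_linked else 0.0,
        "frac_trans": float((kinds.apply(lambda s: "trans" in s)).mean()) if n_linked else 0.0,
        "frac_both": float((kinds.apply(len) == 2).mean()) if n_linked else 0.0,
    }
    return links, summary


def filter_gwas(
    links: pd.DataFrame, gwas: pd.DataFrame, threshold: float = GWAS_SIGNIFICANCE
) -> pd.DataFrame:
    """Join links to GWAS rows at the same variant and keep trait
    associations with p strictly below the genome-wide threshold."""
    if gwas.empty or links.empty:
        return pd.DataFrame(
            columns=list(links.columns)
            + ["trait", "gwas_effect_allele", "gwas_other_allele", "beta_trait", "se", "gwas_p"]
        )
    g = gwas.rename(
        columns={
            "effect_allele": "gwas_effect_allele",
            "other_allele": "gwas_other_allele",
            "beta": "beta_trait",
            "p": "gwas_p",
        }
    )
    merged = links.merge(g, on="variant_id", how="inner")
    return merged[merged["gwas_p"] < threshold].reset_index(drop=True)


def orient_effect(pqtl, gwas) -> float:
    """Trait beta per copy of the protein-raising allele.

    ``pqtl`` needs effect_allele / other_allele / beta_protein; ``gwas``
    needs effect_allele / other_allele / beta (mapping-like rows). Both
    sources are assumed to report the same strand; palindromic variants
    raise :class:`PalindromicVariantError`.
    """
    p_ea, p_oa = pqtl["effect_allele"], pqtl["other_allele"]
    g_ea, g_oa = gwas["effect_allele"], gwas["other_allele"]
    if is_palindromic(p_ea, p_oa):
        raise PalindromicVariantError(
            f"palindromic alleles {p_ea}/{p_oa}: strand cannot be resolved"
        )
    if {p_ea, p_oa} != {g_ea, g_oa}:
        raise AlleleMismatchError(
            f"allele sets disagree: pQTL {p_ea}/{p_oa} vs GWAS {g_ea}/{g_oa}"
        )
    beta_protein = float(pqtl["beta_protein"])
    raising = p_ea if beta_protein > 0 else p_oa
    beta_trait = float(gwas["beta"] if "beta" in gwas else gwas["beta_trait"])
    return beta_trait if g_ea == raising else -beta_trait


def simulate_direction(exercise_direction: str, oriented_beta: float) -> str:
    """Sign rule for the simulated trait impact of a protein's exercise
    response: a rising protein whose raising allele increases risk
    simulates increased risk."""
    if exercise_direction not in ("up", "down"):
        raise ValueError(f"unknown exercise direction {exercise_direction!r}")
    if oriented_beta == 0:
        raise ValueError("oriented beta of zero: direction indeterminate")
    up = exercise_direction == "up"
    positive = oriented_beta > 0
    return "risk_increasing" if up == positive else "risk_decreasing"


def _orient_and_simulate(
    filtered: pd.DataFrame,
    directions: pd.Series,
    include_palindromic: bool = False,
) -> pd.DataFrame:
    """Build TraitEffectRecord rows from filtered link x GWAS rows.

    ``directions`` maps protein_id -> exercise direction. Palindromic
    variants and zero oriented betas are excluded (logged).
    """
    rows = []
    n_pal = n_zero = 0
    for _, r in filtered.iterrows():
        if is_palindromic(r["effect_allele"], r["other_allele"]):
            if not include_palindromic:
                n_pal += 1
                continue
        gwas_side = {
            "effect_allele": r["gwas_effect_allele"],
            "other_allele": r["gwas_other_allele"],
            "beta": r["beta_trait"],
        }
        if include_palindromic and is_palindromic(
            r["effect_allele"], r["other_allele"]
        ):
            # assume same strand: align by label match only
            beta_trait = (
                r["beta_trait"]
                if r["gwas_effect_allele"]
                == (r["effect_allele"] if r["beta_protein"] > 0 else r["other_allele"])
                else -r["beta_trait"]
            )
        else:
            beta_trait = orient_effect(r, gwas_side)
        if beta_trait == 0:
            n_zero += 1
            continue
        direction = directions.get(r["protein_id"])
        rows.append(
            {
                "protein_id": r["protein_id"],
                "trait": r["trait"],
                "variant_id": r["variant_id"],
                "cis_trans": r["cis_trans"],
                "oriented_beta": beta_trait,
                "se": r["se"],
                "exercise_direction": direction,
                "simulated_effect": simulate_direction(direction, beta_trait),
            }
        )
    if n_pal:
        logger.info("excluded %d palindromic variant links", n_pal)
    if n_zero:
        logger.info("excluded %d links with zero oriented beta", n_zero)
    return pd.DataFrame(
        rows,
        columns=[
            "protein_id",
            "trait",
            "variant_id",
            "cis_trans",
            "oriented_beta",
            "se",
            "exercise_direction",
            "simulated_effect",
        ],
    )


def concordance_summary(
    records: pd.DataFrame, trait: str, benefit_orientation: dict[str, str]
) -> tuple[int, int]:
    """(n_beneficial, n_total) proteins for one trait.

    One vote per protein: the majority simulated effect across its
    variants; proteins whose variants tie are excluded (logged). A
    protein is beneficial when its majority effect equals the configured
    beneficial direction for the trait (e.g. risk_decreasing for
    coronary disease or blood pressure).
    """
    if trait not in benefit_orientation:
        raise ValueError(f"no benefit orientation configured for trait {trait!r}")
    beneficial_effect = benefit_orientation[trait]
    sub = records[records["trait"] == trait]
    if sub.empty:
        raise ValueError(f"no records for trait {trait!r}")
    n_beneficial = n_total = 0
    for protein, grp in sub.groupby("protein_id"):
        counts = grp["simulated_effect"].value_counts()
        if len(counts) > 1 and counts.iloc[0] == counts.iloc[1]:
            logger.info("protein %s excluded: tied directions for %s", protein, trait)
            continue
        n_total += 1
        if counts.idxmax() == beneficial_effect:
            n_beneficial += 1
    return n_beneficial, n_total


def forest_table(records: pd.DataFrame, trait: str) -> pd.DataFrame:
    """Forest-plot export: per record, the oriented beta and se with the
    risk side a higher protein concentration maps to, plus the exercise
    direction arrow."""
    sub = records[records["trait"] == trait]
    out = pd.DataFrame(
        {
            "protein_id": sub["protein_id"].to_numpy(),
            "variant_id": sub["variant_id"].to_numpy(),
            "beta": sub["oriented_beta"].to_numpy(dtype=float) if len(sub) else [],
            "se": sub["se"].to_numpy(dtype=float) if len(sub) else [],
            "side": np.where(
                sub["oriented_beta"].to_numpy(dtype=float) > 0,
                "higher_risk",
                "lower_risk",
            )
            if len(sub)
            else [],
            "exercise_arrow": sub["exercise_direction"].to_numpy(),
        }
    )
    return out.sort_values(["protein_id", "variant_id"], kind="stable").reset_index(
        drop=True
    )


def run_trait_simulation(
    res_moderate: pd.DataFrame,
    res_high: pd.DataFrame,
    catalog: pd.DataFrame,
    gwas: pd.DataFrame,
    threshold: float = GWAS_SIGNIFICANCE,
    benefit_orientation: dict[str, str] | None = None,
    alpha: float = 0.05,
    include_palindromic: bool = False,
):
    """Full trait-simulation stage from two differential-result tables.

    Responsive proteins are those significant at either intensity; each
    protein's exercise direction is taken from the high-intensity result
    when responsive there (the larger response) and from the moderate
    result otherwise. Returns ``(records, link_summary, concordance)``
    where concordance maps each configured trait to (n_beneficial,
    n_total).
    """
    sig_m = res_moderate[res_moderate["q_value"] < alpha]
    sig_h = res_high[res_high["q_value"] < alpha]
    responsive = set(sig_m["protein_id"]) | set(sig_h["protein_id"])
    directions = pd.concat(
        [
            sig_m.set_index("protein_id")["direction"],
            sig_h.set_index("protein_id")["direction"],
        ]
    )
    directions = directions[~directions.index.duplicated(keep="last")]
    links, summary = link_pqtls(responsive, catalog)
    filtered = filter_gwas(links, gwas, threshold)
    records = _orient_and_simulate(filtered, directions, include_palindromic)
    concordance = {}
    if benefit_orientation:
        for trait in sorted(set(records["trait"])):
            if trait in benefit_orientation:
                concordance[trait] = concordance_summary(
                    records, trait, benefit_orientation
                )
    return records, summary, concordance
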