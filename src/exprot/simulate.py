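"""Synthetic paired exercise-proteomics studies with planted ground truth.

The generator emulates a crossover study in which the same subjects run at
a moderate and at a high intensity, with venous blood drawn immediately
before and after each bout and a fixed aptamer panel quantifying relative
protein abundance (RFU-like positive signal). Responsive proteins are
planted on the log2 scale on top of per-protein baselines and per-subject
random offsets, so that paired pre/post differencing recovers the planted
fold changes.

Three further generators produce the reference tables the downstream
stages consume: a genes x tissues TPM expression matrix with an
organ-system map, a gene-set catalog, and pQTL/GWAS summary tables with
planted allele orientations and trait directions. All generators are
driven by independent deterministic streams derived from a single seed,
so each table can be regenerated on its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

INTENSITIES = ("moderate", "high")
TIMEPOINTS = ("pre", "post")

#: unordered allele pairs that can be unambiguously strand-harmonized
_NON_PALINDROMIC_PAIRS = (("A", "C"), ("A", "G"), ("T", "C"), ("T", "G"))
_PALINDROMIC_PAIRS = (("A", "T"), ("C", "G"))

# stream ids for the per-module random generators
_STREAM_PLAN = 10
_STREAM_COHORT = 1
_STREAM_TISSUE = 2
_STREAM_GENETICS = 3
_STREAM_GENESETS = 4

# 46 human tissues (GTEx-style labels) with an organ-system grouping.
TISSUE_ORGAN_SYSTEMS: tuple[tuple[str, str], ...] = (
    ("Brain Cortex", "nervous"),
    ("Brain Cerebellum", "nervous"),
    ("Brain Hippocampus", "nervous"),
    ("Brain Hypothalamus", "nervous"),
    ("Brain Frontal Cortex", "nervous"),
    ("Brain Amygdala", "nervous"),
    ("Brain Basal Ganglia", "nervous"),
    ("Spinal Cord", "nervous"),
    ("Nerve Tibial", "nervous"),
    ("Heart Left Ventricle", "cardiovascular"),
    ("Heart Atrial Appendage", "cardiovascular"),
    ("Artery Aorta", "cardiovascular"),
    ("Artery Coronary", "cardiovascular"),
    ("Artery Tibial", "cardiovascular"),
    ("Whole Blood", "blood"),
    ("Spleen", "blood"),
    ("Muscle Skeletal", "skeletal_muscle"),
    ("Esophagus Mucosa", "gastrointestinal"),
    ("Esophagus Muscularis", "gastrointestinal"),
    ("Esophagus Gastroesophageal Junction", "gastrointestinal"),
    ("Stomach", "gastrointestinal"),
    ("Colon Transverse", "gastrointestinal"),
    ("Colon Sigmoid", "gastrointestinal"),
    ("Small Intestine Ileum", "gastrointestinal"),
    ("Liver", "gastrointestinal"),
    ("Pancreas", "gastrointestinal"),
    ("Salivary Gland", "gastrointestinal"),
    ("Minor Salivary Gland", "gastrointestinal"),
    ("Lung", "respiratory"),
    ("Kidney Cortex", "urinary"),
    ("Kidney Medulla", "urinary"),
    ("Bladder", "urinary"),
    ("Testis", "reproductive"),
    ("Prostate", "reproductive"),
    ("Ovary", "reproductive"),
    ("Uterus", "reproductive"),
    ("Vagina", "reproductive"),
    ("Fallopian Tube", "reproductive"),
    ("Thyroid", "endocrine"),
    ("Adrenal Gland", "endocrine"),
    ("Pituitary", "endocrine"),
    ("Skin Sun Exposed", "integumentary"),
    ("Skin Not Sun Exposed", "integumentary"),
    ("Breast Mammary", "integumentary"),
    ("Adipose Subcutaneous", "adipose"),
    ("Adipose Visceral", "adipose"),
)

_ORGAN_SYSTEMS = tuple(dict.fromkeys(s for _, s in TISSUE_ORGAN_SYSTEMS))

DEFAULT_TRAIT_PLAN: dict[str, tuple[int, int]] = {
    # trait -> (n proteins with a trait-significant pQTL link, n beneficial)
    "coronary_artery_disease": (15, 6),
    "blood_pressure": (14, 12),
}

#: simulated_effect value that counts as beneficial, per trait
DEFAULT_BENEFIT_ORIENTATION: dict[str, str] = {
    "coronary_artery_disease": "risk_decreasing",
    "blood_pressure": "risk_decreasing",
}


class ParameterError(ValueError):
    """Raised when simulation parameters violate a feasibility constraint."""


@dataclass(frozen=True)
class SimulationParams:
    """Study conditions for the synthetic generators.

    Defaults reproduce the shape of the underlying crossover study:
    12 subjects, a 1,305-protein aptamer panel, ~14% of the panel
    responsive to moderate-intensity and ~46% to high-intensity exercise,
    with 159/184 of the moderate responders shared with high intensity.

    Noise magnitudes are on the log2 abundance scale.
    ``within_subject_sd`` = 0.08 corresponds to a ~5.7% coefficient of
    variation per measurement, in the range reported for aptamer assay
    replicates; ``subject_sd`` captures stable between-subject offsets
    that paired differencing removes.
    """

    n_subjects: int = 12
    n_proteins: int = 1305
    frac_responsive_moderate: float = 0.14
    frac_responsive_high: float = 0.46
    frac_shared_of_moderate: float = 159 / 184
    effect_size_log2: float = 0.5
    within_subject_sd: float = 0.08
    subject_sd: float = 0.25
    frac_increasing: float = 0.65
    #: shared-protein class proportions (dependent, independent, intermediate)
    dependence_mix: tuple[float, float, float] = (22 / 159, 44 / 159, 93 / 159)
    #: planted FC_high/FC_moderate magnitude ratios per class; the values
    #: straddle the 1.25 and 1.05 classification boundaries
    dependence_ratios: tuple[float, float, float] = (1.4, 1.0, 1.12)
    baseline_log2_mean: float = 10.0
    baseline_log2_sd: float = 1.5
    n_duplicate_aptamers: int = 10
    # tissue expression table
    n_tissues: int = 46
    frac_tissue_restricted: float = 0.25
    tpm_log2_mean: float = 4.0
    tpm_log2_sd: float = 2.0
    # gene-set catalog
    n_gene_sets: int = 50
    set_size_range: tuple[int, int] = (10, 80)
    n_planted_enriched_sets: int = 4
    # genetic catalogs
    n_pqtl_proteins: int = 270
    frac_cis: float = 0.55
    frac_cis_and_trans: float = 0.16
    frac_palindromic: float = 0.10
    frac_allele_flip: float = 0.5
    trait_plan: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_TRAIT_PLAN)
    )
    n_gwas_noise_rows: int = 40
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "frac_responsive_moderate",
            "frac_responsive_high",
            "frac_shared_of_moderate",
            "frac_increasing",
            "frac_tissue_restricted",
            "frac_cis",
            "frac_cis_and_trans",
            "frac_palindromic",
            "frac_allele_flip",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_subjects", "n_proteins", "n_tissues"):
            if getattr(self, name) < 1:
                raise ParameterError(f"{name} must be positive")
        if self.n_tissues < 2:
            raise ParameterError("n_tissues must be >= 2")
        if (
            self.frac_shared_of_moderate * self.frac_responsive_moderate
            > self.frac_responsive_high + 1e-12
        ):
            raise ParameterError(
                "infeasible fractions: frac_shared_of_moderate * "
                "frac_responsive_moderate exceeds frac_responsive_high "
                "(shared responders cannot outnumber high responders)"
            )
        if abs(sum(self.dependence_mix) - 1.0) > 1e-9:
            raise ParameterError("dependence_mix must sum to 1")
        if any(m < 0 for m in self.dependence_mix):
            raise ParameterError("dependence_mix proportions must be >= 0")
        if self.n_pqtl_proteins > self.n_proteins:
            raise ParameterError("n_pqtl_proteins cannot exceed n_proteins")
        if self.frac_cis_and_trans > self.frac_cis:
            raise ParameterError("frac_cis_and_trans cannot exceed frac_cis")
        if self.within_subject_sd <= 0 or self.subject_sd < 0:
            raise ParameterError("noise standard deviations must be positive")
        lo, hi = self.set_size_range
        if not (1 <= lo <= hi):
            raise ParameterError("set_size_range must satisfy 1 <= lo <= hi")

    def with_seed(self, seed: int) -> "SimulationParams":
        return replace(self, seed=seed)

    # planted set sizes, rounded once so every consumer agrees on them
    @property
    def n_responsive_moderate(self) -> int:
        return round(self.frac_responsive_moderate * self.n_proteins)

    @property
    def n_responsive_high(self) -> int:
        return round(self.frac_responsive_high * self.n_proteins)

    @property
    def n_shared(self) -> int:
        return round(self.frac_shared_of_moderate * self.n_responsive_moderate)


@dataclass
class ProteomeStudy:
    """A paired pre/post abundance matrix with its sample annotations.

    ``abundance`` is proteins x samples on the positive signal scale;
    ``samples`` has one row per column of ``abundance`` with sample_id,
    subject_id, timepoint (pre/post) and intensity (moderate/high);
    ``proteins`` maps each aptamer/protein id to a gene symbol.
    """

    abundance: pd.DataFrame
    samples: pd.DataFrame
    proteins: pd.DataFrame

    def validate(self) -> None:
        if not self.abundance.index.is_unique:
            raise ValueError("protein ids must be unique")
        if (self.abundance.to_numpy() <= 0).any():
            raise ValueError("abundance must be strictly positive")
        if set(self.abundance.columns) != set(self.samples["sample_id"]):
            raise ValueError("sample sheet and abundance columns disagree")
        for (subject, intensity), grp in self.samples.groupby(
            ["subject_id", "intensity"]
        ):
            tps = sorted(grp["timepoint"])
            if tps != ["post", "pre"]:
                raise ValueError(
                    f"subject {subject} at {intensity} intensity does not "
                    f"have exactly one pre and one post sample (got {tps})"
                )

    @property
    def protein_ids(self) -> list[str]:
        return list(self.abundance.index)


@dataclass
class TruthTable:
    """Planted ground truth for a synthetic study.

    ``responses`` is indexed by protein id with columns
    ``responsive_moderate``, ``responsive_high``, ``direction``,
    ``log2fc_moderate``, ``log2fc_high`` and ``dependence_class``
    (dependent/independent/intermediate for shared proteins, NA
    otherwise). ``trait_links`` (set by the genetics generator) records
    the true oriented trait direction per planted pQTL/GWAS link.
    """

    responses: pd.DataFrame
    trait_links: pd.DataFrame | None = None
    planted_enriched_sets: list[str] = field(default_factory=list)

    @property
    def shared_proteins(self) -> list[str]:
        r = self.responses
        return list(r.index[r["responsive_moderate"] & r["responsive_high"]])


def platform_gene_map(params: SimulationParams) -> pd.DataFrame:
    """Deterministic protein->gene map for the synthetic aptamer panel.

    The last ``n_duplicate_aptamers`` aptamers re-target the genes of the
    first aptamers, emulating proteins measured by multiple reagents.
    """
    n = params.n_proteins
    n_dup = min(params.n_duplicate_aptamers, n // 2)
    protein_ids = [f"SL{i + 1:05d}" for i in range(n)]
    genes = [f"GENE{i + 1:05d}" for i in range(n - n_dup)]
    genes += genes[:n_dup]
    return pd.DataFrame({"protein_id": protein_ids, "gene_symbol": genes})


def _rng(params: SimulationParams, stream: int) -> np.random.Generator:
    return np.random.default_rng([params.seed, stream])


def _plan_responses(params: SimulationParams) -> pd.DataFrame:
    """Draw the planted response truth (its own stream, so the genetics
    generator can reproduce it without building the abundance matrix)."""
    rng = _rng(params, _STREAM_PLAN)
    proteins = platform_gene_map(params)["protein_id"].to_numpy()
    n = params.n_proteins
    n_mod, n_high, n_shared = (
        params.n_responsive_moderate,
        params.n_responsive_high,
        params.n_shared,
    )
    n_shared = min(n_shared, n_mod, n_high)
    n_mod_only = n_mod - n_shared
    n_high_only = n_high - n_shared
    if n_mod_only + n_high_only + n_shared > n:
        raise ParameterError(
            "planted responsive sets exceed the number of proteins"
        )

    order = rng.permutation(n)
    shared = proteins[order[:n_shared]]
    mod_only = proteins[order[n_shared : n_shared + n_mod_only]]
    high_only = proteins[
        order[n_shared + n_mod_only : n_shared + n_mod_only + n_high_only]
    ]

    truth = pd.DataFrame(
        {
            "responsive_moderate": False,
            "responsive_high": False,
            "direction": pd.Series(pd.NA, index=proteins, dtype="string"),
            "log2fc_moderate": 0.0,
            "log2fc_high": 0.0,
            "dependence_class": pd.Series(pd.NA, index=proteins, dtype="string"),
        },
        index=pd.Index(proteins, name="protein_id"),
    )
    truth.loc[shared, ["responsive_moderate", "responsive_high"]] = True
    truth.loc[mod_only, "responsive_moderate"] = True
    truth.loc[high_only, "responsive_high"] = True

    responsive = np.concatenate([shared, mod_only, high_only])
    signs = np.where(
        rng.random(responsive.size) < params.frac_increasing, 1.0, -1.0
    )
    truth.loc[responsive, "direction"] = np.where(signs > 0, "up", "down")
    mags = params.effect_size_log2 * rng.uniform(0.75, 1.25, responsive.size)

    # shared proteins: planted magnitude applies at moderate intensity and
    # the high-intensity fold change is scaled by the class ratio on the
    # linear magnitude scale
    n_dep = round(params.dependence_mix[0] * n_shared)
    n_ind = round(params.dependence_mix[1] * n_shared)
    n_dep = min(n_dep, n_shared)
    n_ind = min(n_ind, n_shared - n_dep)
    classes = np.array(
        ["dependent"] * n_dep
        + ["independent"] * n_ind
        + ["intermediate"] * (n_shared - n_dep - n_ind)
    )
    rng.shuffle(classes)
    ratio_by_class = dict(
        zip(("dependent", "independent", "intermediate"), params.dependence_ratios)
    )
    shared_mag = mags[:n_shared]
    shared_sign = signs[:n_shared]
    ratios = np.array([ratio_by_class[c] for c in classes])
    truth.loc[shared, "log2fc_moderate"] = shared_sign * shared_mag
    truth.loc[shared, "log2fc_high"] = shared_sign * (
        shared_mag + np.log2(ratios)
    )
    truth.loc[shared, "dependence_class"] = classes

    k = n_shared
    truth.loc[mod_only, "log2fc_moderate"] = (
        signs[k : k + n_mod_only] * mags[k : k + n_mod_only]
    )
    k += n_mod_only
    truth.loc[high_only, "log2fc_high"] = signs[k:] * mags[k:]
    return truth


def generate_cohort(params: SimulationParams) -> tuple[ProteomeStudy, TruthTable]:
    """Generate a paired two-intensity study and its planted truth.

    The log2 abundance of protein g in the sample of subject s is

        baseline_g + subject_offset_{g,s} + planted_log2fc (post only) + noise

    with the subject offset shared by all four of the subject's samples,
    so that pre-sample distributions are identical in law across
    intensities and paired differencing cancels the offset.
    """
    params.validate()
    truth_responses = _plan_responses(params)
    rng = _rng(params, _STREAM_COHORT)
    n, s = params.n_proteins, params.n_subjects
    proteins = truth_responses.index.to_numpy()

    baseline = rng.normal(params.baseline_log2_mean, params.baseline_log2_sd, n)
    subject_offset = rng.normal(0.0, params.subject_sd, (n, s))

    sample_rows = []
    cols = {}
    for intensity in INTENSITIES:
        fc = truth_responses[f"log2fc_{intensity}"].to_numpy()
        for j in range(s):
            subject = f"P{j + 1:02d}"
            for timepoint in TIMEPOINTS:
                sid = f"{subject}_{intensity[0].upper()}_{timepoint}"
                sample_rows.append(
                    {
                        "sample_id": sid,
                        "subject_id": subject,
                        "timepoint": timepoint,
                        "intensity": intensity,
                    }
                )
                log2sig = (
                    baseline
                    + subject_offset[:, j]
                    + (fc if timepoint == "post" else 0.0)
                    + rng.normal(0.0, params.within_subject_sd, n)
                )
                cols[sid] = np.exp2(log2sig)

    abundance = pd.DataFrame(cols, index=pd.Index(proteins, name="protein_id"))
    samples = pd.DataFrame(sample_rows)
    study = ProteomeStudy(
        abundance=abundance, samples=samples, proteins=platform_gene_map(params)
    )
    study.validate()
    return study, TruthTable(responses=truth_responses)


def generate_tissue_expression(
    params: SimulationParams,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate a genes x tissues TPM table, organ map and platform map.

    A ``frac_tissue_restricted`` fraction of genes is expressed in a
    single home tissue only (making source inference informative); the
    rest are expressed everywhere with log-normal variation.
    """
    params.validate()
    rng = _rng(params, _STREAM_TISSUE)
    nt = params.n_tissues
    base = list(TISSUE_ORGAN_SYSTEMS)
    while len(base) < nt:
        i = len(base)
        base.append((f"Tissue {i + 1}", _ORGAN_SYSTEMS[i % len(_ORGAN_SYSTEMS)]))
    tissues = [t for t, _ in base[:nt]]
    organ_map = pd.DataFrame(
        {"tissue": tissues, "organ_system": [s for _, s in base[:nt]]}
    )

    platform = platform_gene_map(params)
    genes = pd.unique(platform["gene_symbol"])
    ng = genes.size
    tpm = np.exp2(
        rng.normal(params.tpm_log2_mean, params.tpm_log2_sd, (ng, nt))
    )
    restricted = rng.random(ng) < params.frac_tissue_restricted
    home = rng.integers(0, nt, ng)
    for i in np.flatnonzero(restricted):
        row = np.zeros(nt)
        row[home[i]] = np.exp2(rng.normal(params.tpm_log2_mean + 3.0, 1.0))
        tpm[i] = row
    expr = pd.DataFrame(
        tpm, index=pd.Index(genes, name="gene_symbol"), columns=tissues
    )
    return expr, organ_map, platform


def generate_gene_sets(
    params: SimulationParams, truth: TruthTable | None = None
) -> tuple[dict[str, list[str]], list[str]]:
    """Generate a named gene-set catalog over the platform gene universe.

    The first ``n_planted_enriched_sets`` sets draw 70% of their members
    from up-regulated responsive genes (when a truth table is available),
    planting real overrepresentation signal; the rest are uniform draws.
    Returns the catalog and the list of planted enriched set names.
    """
    params.validate()
    rng = _rng(params, _STREAM_GENESETS)
    platform = platform_gene_map(params)
    universe = pd.unique(platform["gene_symbol"])
    responses = truth.responses if truth is not None else _plan_responses(params)
    gene_of = dict(zip(platform["protein_id"], platform["gene_symbol"]))
    up = responses[
        (responses["direction"] == "up")
        & (responses["responsive_moderate"] | responses["responsive_high"])
    ].index
    up_genes = pd.unique(pd.Series([gene_of[p] for p in up]))

    lo, hi = params.set_size_range
    hi = min(hi, universe.size)
    lo = min(lo, hi)
    catalog: dict[str, list[str]] = {}
    planted: list[str] = []
    for i in range(params.n_gene_sets):
        size = int(rng.integers(lo, hi + 1))
        name = f"SET:{i + 1:04d}"
        if i < params.n_planted_enriched_sets and up_genes.size > 0:
            n_sig = min(int(round(0.7 * size)), up_genes.size)
            members = set(rng.choice(up_genes, n_sig, replace=False))
            rest = np.setdiff1d(universe, list(members))
            members |= set(rng.choice(rest, size - n_sig, replace=False))
            planted.append(name)
        else:
            members = set(rng.choice(universe, size, replace=False))
        catalog[name] = sorted(members)
    return catalog, planted


def _draw_alleles(rng: np.random.Generator, palindromic: bool) -> tuple[str, str]:
    pairs = _PALINDROMIC_PAIRS if palindromic else _NON_PALINDROMIC_PAIRS
    a, b = pairs[int(rng.integers(0, len(pairs)))]
    return (a, b) if rng.random() < 0.5 else (b, a)


def generate_genetic_catalogs(
    params: SimulationParams,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate pQTL and GWAS tables with planted directional truth.

    Returns ``(pqtl, gwas, trait_truth)``. Each cataloged protein gets a
    cis sentinel, a trans sentinel, or both, at the planted ``frac_cis``
    and ``frac_cis_and_trans`` rates. For every planted trait link a
    genome-wide-significant GWAS row is written whose allele orientation
    may be flipped relative to the pQTL row (recorded in the truth), and
    whose oriented direction produces the planted beneficial/adverse
    simulated effect given the protein's planted exercise direction.
    Palindromic (A/T, C/G) decoy variants with significant trait rows are
    planted and flagged in the truth; they are strand-ambiguous and the
    harmonization stage excludes them.
    """
    params.validate()
    responses = _plan_responses(params)
    rng = _rng(params, _STREAM_GENETICS)

    responsive = responses.index[
        responses["responsive_moderate"] | responses["responsive_high"]
    ].to_numpy()
    plan = dict(params.trait_plan)
    n_trait_proteins = sum(n for n, _ in plan.values())
    if n_trait_proteins > responsive.size:
        raise ParameterError(
            "trait_plan requires more responsive proteins than are planted"
        )
    trait_proteins = rng.choice(responsive, n_trait_proteins, replace=False)
    assigned: dict[str, np.ndarray] = {}
    k = 0
    for trait, (n_links, _) in plan.items():
        assigned[trait] = trait_proteins[k : k + n_links]
        k += n_links

    rest_pool = np.setdiff1d(responses.index.to_numpy(), trait_proteins)
    n_fill = max(0, params.n_pqtl_proteins - n_trait_proteins)
    filler = rng.choice(rest_pool, min(n_fill, rest_pool.size), replace=False)
    catalog_proteins = np.concatenate([trait_proteins, filler])

    gene_pos = {
        p: (int(rng.integers(1, 23)), int(rng.integers(1, 200_000_000)))
        for p in catalog_proteins
    }

    p_cis_only = params.frac_cis - params.frac_cis_and_trans
    pqtl_rows = []
    var_counter = 0
    first_variant: dict[str, str] = {}
    palindromic_of: dict[str, bool] = {}
    for p in catalog_proteins:
        u = rng.random()
        if u < params.frac_cis_and_trans:
            kinds = ["cis", "trans"]
        elif u < params.frac_cis_and_trans + p_cis_only:
            kinds = ["cis"]
        else:
            kinds = ["trans"]
        is_trait_protein = p in trait_proteins
        for kind in kinds:
            var_counter += 1
            vid = f"rs{1_000_000 + var_counter}"
            palindromic = (not is_trait_protein) and (
                rng.random() < params.frac_palindromic
            )
            ea, oa = _draw_alleles(rng, palindromic)
            g_chrom, g_pos = gene_pos[p]
            if kind == "cis":
                chrom, pos = g_chrom, g_pos + int(rng.integers(-500_000, 500_000))
            else:
                chrom = int(1 + (g_chrom + int(rng.integers(1, 22))) % 22)
                pos = int(rng.integers(1, 200_000_000))
            beta = float(rng.uniform(0.2, 0.8) * rng.choice([-1.0, 1.0]))
            pqtl_rows.append(
                {
                    "protein_id": p,
                    "variant_id": vid,
                    "chrom": chrom,
                    "pos": max(1, pos),
                    "gene_chrom": g_chrom,
                    "gene_pos": g_pos,
                    "effect_allele": ea,
                    "other_allele": oa,
                    "beta_protein": beta,
                    "p": float(10.0 ** -rng.uniform(10, 30)),
                    "cis_trans": kind,
                }
            )
            if p not in first_variant:
                first_variant[p] = vid
            palindromic_of[vid] = palindromic
    pqtl = pd.DataFrame(pqtl_rows)

    def _gwas_row(trait, pq, z_sign, z_mag):
        """GWAS row at a pQTL variant; may flip allele labels vs the pQTL."""
        se = float(rng.uniform(0.01, 0.05))
        beta = z_sign * z_mag * se
        flip = bool(rng.random() < params.frac_allele_flip)
        ea, oa = (
            (pq["other_allele"], pq["effect_allele"])
            if flip
            else (pq["effect_allele"], pq["other_allele"])
        )
        if flip:
            beta = -beta
        from scipy.stats import norm

        return flip, {
            "variant_id": pq["variant_id"],
            "trait": trait,
            "effect_allele": ea,
            "other_allele": oa,
            "beta": float(beta),
            "se": se,
            "p": float(2.0 * norm.sf(z_mag)),
        }

    pqtl_by_variant = {r["variant_id"]: r for r in pqtl_rows}
    gwas_rows = []
    truth_rows = []
    for trait, (n_links, n_beneficial) in plan.items():
        prots = assigned[trait]
        beneficial_flags = np.zeros(len(prots), dtype=bool)
        beneficial_flags[:n_beneficial] = True
        rng.shuffle(beneficial_flags)
        for p, beneficial in zip(prots, beneficial_flags):
            pq = pqtl_by_variant[first_variant[p]]
            direction = responses.loc[p, "direction"]
            target = "risk_decreasing" if beneficial else "risk_increasing"
            # sign of the trait beta per protein-raising allele that yields
            # the target simulated effect for this exercise direction
            oriented_sign = (
                1.0
                if (direction == "up") == (target == "risk_increasing")
                else -1.0
            )
            # express on the pQTL's reported effect allele: if beta_protein
            # < 0 the protein-raising allele is the other allele
            sign_on_pqtl_ea = oriented_sign * np.sign(pq["beta_protein"])
            flip, row = _gwas_row(trait, pq, sign_on_pqtl_ea, rng.uniform(6, 12))
            gwas_rows.append(row)
            truth_rows.append(
                {
                    "protein_id": p,
                    "trait": trait,
                    "variant_id": pq["variant_id"],
                    "true_effect": target,
                    "beneficial": bool(beneficial),
                    "allele_flipped": flip,
                    "palindromic": False,
                }
            )

    # non-significant noise rows at filler variants
    filler_variants = [v for v in pqtl_by_variant if not palindromic_of[v]]
    used = {r["variant_id"] for r in gwas_rows}
    free = [v for v in filler_variants if v not in used]
    traits = list(plan)
    n_noise = min(params.n_gwas_noise_rows, len(free) * min(1, len(traits)))
    for i in range(n_noise):
        v = free[i % len(free)]
        trait = traits[i % len(traits)]
        _, row = _gwas_row(
            trait,
            pqtl_by_variant[v],
            float(rng.choice([-1.0, 1.0])),
            rng.uniform(0.5, 4.0),
        )
        gwas_rows.append(row)

    # significant palindromic decoys: flagged in truth, excluded downstream
    pal_variants = [v for v, is_pal in palindromic_of.items() if is_pal] if traits else []
    for v in pal_variants[:3]:
        trait = traits[int(rng.integers(0, len(traits)))]
        _, row = _gwas_row(
            trait, pqtl_by_variant[v], float(rng.choice([-1.0, 1.0])),
            rng.uniform(6, 12),
        )
        gwas_rows.append(row)
        truth_rows.append(
            {
                "protein_id": pqtl_by_variant[v]["protein_id"],
                "trait": trait,
                "variant_id": v,
                "true_effect": pd.NA,
                "beneficial": pd.NA,
                "allele_flipped": pd.NA,
                "palindromic": True,
            }
        )

    gwas = pd.DataFrame(gwas_rows)
    trait_truth = pd.DataFrame(truth_rows)
    return pqtl, gwas, trait_truth


def generate_all(params: SimulationParams):
    """Generate the full set of synthetic inputs for one study.

    Returns ``(study, truth, expression, organ_map, platform_map,
    gene_sets, pqtl, gwas)`` with ``truth.trait_links`` and
    ``truth.planted_enriched_sets`` populated.
    """
    study, truth = generate_cohort(params)
    expression, organ_map, platform_map = generate_tissue_expression(params)
    gene_sets, planted = generate_gene_sets(params, truth)
    pqtl, gwas, trait_truth = generate_genetic_catalogs(params)
    truth.trait_links = trait_truth
    truth.planted_enriched_sets = planted
    return study, truth, expression, organ_map, platform_map, gene_sets, pqtl, gwas
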