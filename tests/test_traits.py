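"""Allele harmonization, direction simulation and trait concordance."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from exprot.simulate import (
    DEFAULT_BENEFIT_ORIENTATION,
    generate_genetic_catalogs,
)
from exprot.traits import (
    AlleleMismatchError,
    PalindromicVariantError,
    concordance_summary,
    filter_gwas,
    forest_table,
    link_pqtls,
    orient_effect,
    simulate_direction,
)


def _pqtl(ea="A", oa="G", beta=0.5, **kw):
    return {
        "effect_allele": ea,
        "other_allele": oa,
        "beta_protein": beta,
        **kw,
    }


def _gwas(ea="A", oa="G", beta=0.1):
    return {"effect_allele": ea, "other_allele": oa, "beta": beta}


class TestLinkPqtls:
    def _catalog(self):
        return pd.DataFrame(
            {
                "protein_id": ["p1", "p1", "p2", "p3"],
                "variant_id": ["v1", "v2", "v3", "v4"],
                "cis_trans": ["cis", "trans", "cis", "trans"],
            }
        )

    def test_disjoint_responsive_set_gives_no_links(self):
        links, summary = link_pqtls({"pX"}, self._catalog())
        assert links.empty
        assert summary["n_linked_proteins"] == 0

    def test_both_cis_and_trans_counts_once_in_both(self):
        links, summary = link_pqtls({"p1", "p2"}, self._catalog())
        assert len(links) == 3
        assert summary["n_linked_proteins"] == 2
        assert summary["frac_cis"] == pytest.approx(1.0)  # p1 and p2 have cis
        assert summary["frac_trans"] == pytest.approx(0.5)  # only p1
        assert summary["frac_both"] == pytest.approx(0.5)  # only p1

    def test_planted_cis_fraction_recovered(self):
        from exprot.simulate import SimulationParams

        params = SimulationParams(
            n_proteins=600,
            n_pqtl_proteins=200,
            frac_cis=0.5,
            frac_cis_and_trans=0.0,
            trait_plan={},
            seed=13,
        )
        pqtl, _, _ = generate_genetic_catalogs(params)
        links, summary = link_pqtls(set(pqtl["protein_id"]), pqtl)
        se = np.sqrt(0.25 / summary["n_linked_proteins"])
        assert abs(summary["frac_cis"] - 0.5) < 3 * se

    def test_empty_catalog_errors(self):
        with pytest.raises(ValueError, match="empty"):
            link_pqtls({"p1"}, pd.DataFrame())


class TestFilterGwas:
    def _links(self):
        return pd.DataFrame({"protein_id": ["p1"], "variant_id": ["v1"],
                             "cis_trans": ["cis"]})

    def _gwas_table(self, p):
        return pd.DataFrame(
            {
                "variant_id": ["v1"],
                "trait": ["t"],
                "effect_allele": ["A"],
                "other_allele": ["G"],
                "beta": [0.1],
                "se": [0.02],
                "p": [p],
            }
        )

    def test_boundary_exactly_5e8_excluded(self):
        out = filter_gwas(self._links(), self._gwas_table(5e-8))
        assert out.empty

    def test_just_below_threshold_included(self):
        out = filter_gwas(self._links(), self._gwas_table(4.9e-8))
        assert len(out) == 1

    def test_empty_gwas_table(self):
        out = filter_gwas(self._links(), self._gwas_table(1e-9).iloc[:0])
        assert out.empty

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(0)
        gwas = pd.DataFrame(
            {
                "variant_id": ["v1"] * 50,
                "trait": [f"t{i}" for i in range(50)],
                "effect_allele": "A",
                "other_allele": "G",
                "beta": 0.1,
                "se": 0.02,
                "p": rng.uniform(0, 1e-6, 50),
            }
        )
        sizes = [
            len(filter_gwas(self._links(), gwas, thr))
            for thr in (1e-9, 1e-8, 5e-8, 1e-7)
        ]
        assert sizes == sorted(sizes)


class TestOrientEffect:
    def test_aligned(self):
        assert orient_effect(_pqtl(beta=0.5), _gwas(beta=0.1)) == pytest.approx(0.1)

    def test_swapped_alleles_flip(self):
        assert orient_effect(
            _pqtl(beta=0.5), _gwas(ea="G", oa="A", beta=0.1)
        ) == pytest.approx(-0.1)

    def test_negative_protein_beta_two_step_flip(self):
        # raising allele is the pQTL other allele; GWAS effect allele is the
        # pQTL effect allele -> beta reported per lowering allele -> negate
        assert orient_effect(
            _pqtl(beta=-0.5), _gwas(beta=0.1)
        ) == pytest.approx(-0.1)

    def test_allele_mismatch_errors(self):
        with pytest.raises(AlleleMismatchError):
            orient_effect(_pqtl(), _gwas(ea="A", oa="C"))

    def test_palindromic_rejected(self):
        with pytest.raises(PalindromicVariantError):
            orient_effect(_pqtl(ea="A", oa="T"), _gwas(ea="A", oa="T"))

    @settings(max_examples=60, derandomize=True)
    @given(
        beta_protein=st.floats(-1, 1).filter(lambda b: abs(b) > 1e-6),
        beta_trait=st.floats(-1, 1),
        swap=st.booleans(),
    )
    def test_orientation_involution(self, beta_protein, beta_trait, swap):
        # relabeling the GWAS alleles and negating its beta is a no-op
        g1 = _gwas(ea="G" if swap else "A", oa="A" if swap else "G", beta=beta_trait)
        g2 = _gwas(ea=g1["other_allele"], oa=g1["effect_allele"], beta=-beta_trait)
        pq = _pqtl(beta=beta_protein)
        assert orient_effect(pq, g1) == pytest.approx(orient_effect(pq, g2))


class TestSimulateDirection:
    @pytest.mark.parametrize(
        "direction,beta,expected",
        [
            ("up", 0.2, "risk_increasing"),
            ("up", -0.2, "risk_decreasing"),
            ("down", 0.2, "risk_decreasing"),
            ("down", -0.2, "risk_increasing"),
        ],
    )
    def test_sign_table(self, direction, beta, expected):
        assert simulate_direction(direction, beta) == expected

    def test_beta_flip_antisymmetry(self):
        for d in ("up", "down"):
            a = simulate_direction(d, 0.3)
            b = simulate_direction(d, -0.3)
            assert {a, b} == {"risk_increasing", "risk_decreasing"}

    def test_zero_beta_indeterminate(self):
        with pytest.raises(ValueError, match="indeterminate"):
            simulate_direction("up", 0.0)


class TestConcordanceSummary:
    def _records(self, rows):
        return pd.DataFrame(
            rows,
            columns=["protein_id", "trait", "variant_id", "simulated_effect"],
        )

    def test_unanimous_benefit(self):
        rec = self._records(
            [("p1", "bp", "v1", "risk_decreasing"), ("p2", "bp", "v2", "risk_decreasing")]
        )
        assert concordance_summary(rec, "bp", {"bp": "risk_decreasing"}) == (2, 2)

    def test_duplicate_agreeing_variants_count_once(self):
        rec = self._records(
            [
                ("p1", "bp", "v1", "risk_decreasing"),
                ("p1", "bp", "v2", "risk_decreasing"),
                ("p2", "bp", "v3", "risk_increasing"),
            ]
        )
        assert concordance_summary(rec, "bp", {"bp": "risk_decreasing"}) == (1, 2)

    def test_tied_protein_excluded(self):
        rec = self._records(
            [
                ("p1", "bp", "v1", "risk_decreasing"),
                ("p1", "bp", "v2", "risk_increasing"),
                ("p2", "bp", "v3", "risk_decreasing"),
            ]
        )
        assert concordance_summary(rec, "bp", {"bp": "risk_decreasing"}) == (1, 1)

    def test_missing_benefit_orientation_errors(self):
        rec = self._records([("p1", "bp", "v1", "risk_decreasing")])
        with pytest.raises(ValueError, match="orientation"):
            concordance_summary(rec, "bp", {})


class TestForestTable:
    def test_side_mapping_and_empty(self):
        rec = pd.DataFrame(
            {
                "protein_id": ["p1", "p2"],
                "trait": ["bp", "bp"],
                "variant_id": ["v1", "v2"],
                "oriented_beta": [0.2, -0.1],
                "se": [0.05, 0.04],
                "exercise_direction": ["up", "down"],
            }
        )
        out = forest_table(rec, "bp").set_index("protein_id")
        assert out.loc["p1", "side"] == "higher_risk"
        assert out.loc["p2", "side"] == "lower_risk"
        assert out.loc["p1", "exercise_arrow"] == "up"
        empty = forest_table(rec, "cad")
        assert len(empty) == 0
        assert list(empty.columns) == [
            "protein_id",
            "variant_id",
            "beta",
            "se",
            "side",
            "exercise_arrow",
        ]

    def test_rows_match_field_recomputation(self):
        rng = np.random.default_rng(4)
        rec = pd.DataFrame(
            {
                "protein_id": [f"p{i}" for i in range(10)],
                "trait": "bp",
                "variant_id": [f"v{i}" for i in range(10)],
                "oriented_beta": rng.normal(0, 0.2, 10),
                "se": rng.uniform(0.01, 0.05, 10),
                "exercise_direction": rng.choice(["up", "down"], 10),
            }
        )
        out = forest_table(rec, "bp").set_index("protein_id")
        for _, r in rec.iterrows():
            row = out.loc[r["protein_id"]]
            assert row["beta"] == r["oriented_beta"]
            assert row["side"] == (
                "higher_risk" if r["oriented_beta"] > 0 else "lower_risk"
            )


class TestEndToEndRecovery:
    def test_planted_truth_recovered_through_full_stage(self, small_params):
        """All clean (non-palindromic) planted links must recover their
        planted simulated direction and concordance counts."""
        from exprot.differential import run_differential
        from exprot.simulate import generate_cohort
        from exprot.traits import run_trait_simulation

        study, truth = generate_cohort(small_params)
        pqtl, gwas, trait_truth = generate_genetic_catalogs(small_params)
        rm = run_differential(study, "moderate")
        rh = run_differential(study, "high")
        records, _, concordance = run_trait_simulation(
            rm, rh, pqtl, gwas,
            benefit_orientation=dict(DEFAULT_BENEFIT_ORIENTATION),
        )
        clean = trait_truth[~trait_truth["palindromic"].astype(bool)]
        got = records.set_index(["protein_id", "trait", "variant_id"])
        n_checked = 0
        for _, row in clean.iterrows():
            key = (row["protein_id"], row["trait"], row["variant_id"])
            if key in got.index:  # protein detected as responsive
                assert got.loc[key, "simulated_effect"] == row["true_effect"]
                n_checked += 1
        assert n_checked >= 0.9 * len(clean)
        # palindromic decoys never appear in the records
        pal_variants = set(
            trait_truth.loc[trait_truth["palindromic"].astype(bool), "variant_id"]
        )
        assert not (set(records["variant_id"]) & pal_variants)
        plan = dict(small_params.trait_plan)
        for trait, (n_links, n_beneficial) in plan.items():
            assert concordance[trait] == (n_beneficial, n_links)
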