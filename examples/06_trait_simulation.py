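"""Simulate the direction of exercise effects on genetically linked traits.

Responsive proteins are linked to sentinel pQTL variants; GWAS rows at
those variants are filtered at p < 5e-8, the trait beta is oriented to
the protein-raising allele, and a sign rule turns the protein's exercise
direction into a simulated risk direction per trait. Palindromic (A/T,
C/G) variants are excluded as strand-ambiguous.
"""

from exprot import SimulationParams, generate_cohort, run_differential
from exprot.simulate import DEFAULT_BENEFIT_ORIENTATION, generate_genetic_catalogs
from exprot.traits import forest_table, run_trait_simulation

params = SimulationParams(seed=1)
study, _ = generate_cohort(params)
pqtl, gwas, truth = generate_genetic_catalogs(params)

rm = run_differential(study, "moderate")
rh = run_differential(study, "high")
records, links, concordance = run_trait_simulation(
    rm, rh, pqtl, gwas, benefit_orientation=dict(DEFAULT_BENEFIT_ORIENTATION)
)

print(f"linked proteins: {links['n_linked_proteins']} "
      f"(cis {links['frac_cis']:.0%}, trans {links['frac_trans']:.0%}, "
      f"both {links['frac_both']:.0%})")
for trait, (n_ben, n_tot) in concordance.items():
    print(f"{trait}: {n_ben} of {n_tot} proteins move in a beneficial direction")
# The generator plants 12/14 beneficial for blood pressure and 6/15 for
# coronary artery disease; full recovery shows the orientation chain
# (allele flips included) is handled correctly.

print("\nblood-pressure forest table (first rows):")
print(forest_table(records, "blood_pressure").head(5).round(3).to_string(index=False))
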