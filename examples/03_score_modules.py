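"""Score modules on bulk samples and test condition differences.

A module score is the geometric mean of its genes' linear expression,
computed as the arithmetic mean of log2(CPM+1); Mann-Whitney U compares
HIV-positive vs HIV-negative samples within each compartment.
"""

import txmod

cfg = txmod.GeneratorConfig(seed=7)
counts, meta, truth = txmod.simulate_bulk_cohort(cfg)
ref_counts, ref_meta, _ = txmod.simulate_reference_profiles(cfg)

names = [ct.name for ct in cfg.cell_types]
modules = [txmod.derive_cell_module(ref_counts, ref_meta, plan)
           for plan in txmod.default_plans(names)]

expr = txmod.normalize_log_cpm(counts)
scored = txmod.score_all_modules(expr, modules)
tests = txmod.mann_whitney_module_test(scored, meta)

print("per-module Mann-Whitney p (HIVpos vs HIVneg), by compartment:")
print(tests.pivot(index="module", columns="stratum",
                  values="pvalue").round(4).to_string())
print("\nSmall p for CD4 (depleted) and CD8_EM (expanded) in both "
      "compartments shows the scores recover the simulated composition "
      "shifts from bulk data alone.")
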