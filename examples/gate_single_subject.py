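"""Run the full gating pipeline on one synthetic subject and print the
recovered maturation profile next to the generator's ground truth.

The pipeline compensates spillover, applies the arcsinh transform, finds
the lymphocyte (CD45/SSC) or T-cell (CD3/SSC) cluster by density, places
per-marker positivity thresholds at density valleys, classifies events
through the five gate trees, and anchors absolute counts to the counting
tube's bead ratio.  Percentages are of each subset's parent gate; absolute
counts are cells/ul of whole blood.
"""

from tmaturity import load_preset
from tmaturity.pipeline import RunConfig, process_subject_tables
from tmaturity.synthetic import iter_cohort

preset = load_preset("nbs")
config = RunConfig(presets=(preset,), seed=1)
profile, tables = next(iter_cohort(preset, seed=1, n_events=30_000))
result = process_subject_tables(profile.subject_id, profile.group, tables,
                                config)

print(f"subject {result.subject_id} ({result.group} arm)")
print(f"  absolute lymphocyte count: {result.lymph_abs:7.0f} cells/ul "
      f"(true {profile.lymph_abs_true:.0f})")
print(f"  {'subset':<12} {'% parent':>9} {'true %':>7} {'cells/ul':>9}")
for name in ("T", "B", "NK", "CD4", "CD8", "RTE_CD4", "TN_CD4", "TSCM_CD4",
             "TCM_CD4", "TEM_CD4", "LTEMRA_CD4", "HTEMRA_CD4", "TD_CD4",
             "CD57_CD4", "KLRG1_CD4", "PD1_CD4"):
    st = result.stats[name]
    true_pct = profile.true_fraction(name) * 100
    print(f"  {name:<12} {st.pct_of_parent:9.2f} {true_pct:7.2f} "
          f"{st.abs_count:9.0f}")
print("recovered percentages track the latent truth to a few tenths of a "
      "point;\nabsolute counts chain the subset proportions through the "
      "bead-derived lymphocyte count.")
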