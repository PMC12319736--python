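"""Generate the synthetic study cohort and write its covariate table."""

import pandas as pd

import common

truth = common.load_truth()
common.RESULTS.mkdir(exist_ok=True)

table = pd.DataFrame({
    "subject_id": [f"sub-{i:03d}" for i in range(truth.n_subjects)],
    "role": ["template" if i < common.N_TEMPLATE else "analysis"
             for i in range(truth.n_subjects)],
    "age_pma_weeks": truth.ages.round(2),
    "sex": truth.sexes,
    "motion_level": truth.motion_levels.round(4),
})
table.to_csv(common.RESULTS / "cohort_covariates.tsv", sep="\t", index=False)

print(f"cohort: {truth.n_subjects} subjects ({common.N_TEMPLATE} template), "
      f"{truth.n_ics} networks on {truth.mesh.n_vertices} vertices, "
      f"T={truth.n_timepoints}")
print(f"ages {truth.ages.min():.1f}-{truth.ages.max():.1f} weeks PMA, "
      f"amplitude effect {common.AGE_EFFECT}/week")
print(f"wrote {common.RESULTS / 'cohort_covariates.tsv'}")
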