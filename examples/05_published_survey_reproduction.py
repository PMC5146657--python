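"""Reproduce the bundled willow survey from its published G0/G1 means.

Loads the shipped cytometry table (32 measurement groups over four
Salix species), recomputes every ratio against the diploid
S. suchowensis reference (G0/G1 mean 10739) and calls ploidy, then
tallies ploidy per species.
"""

from salixploidy import datasets
from salixploidy.pipeline import run_fcm_stage_from_means

survey = datasets.load_fcm_survey()
means = {row.accessions: float(row.g0g1_mean) for _, row in survey.iterrows()}
result = run_fcm_stage_from_means(
    means,
    reference_mean=datasets.REFERENCE_G0G1,
    reference_ploidy=datasets.REFERENCE_PLOIDY,
)

match = sum(
    call.ratio == row.ratio and f"{call.ploidy}x" == row.ploidy_level
    for call, (_, row) in zip(result.calls, survey.iterrows())
)
print(result.table[["sample_id", "g0g1_mean", "ratio", "ploidy_level"]]
      .head(8).to_string(index=False))
print(f"...\n{match} of {len(survey)} published ratio/ploidy rows reproduced")

per_acc = datasets.expand_survey_accessions(survey)
print("\nPer-species ploidy counts (one row per stand):")
print(per_acc.groupby(["species", "ploidy_level"]).size().unstack(fill_value=0))
print("\nTree willows (S. babylonica, S. matsudana) are dominantly")
print("tetraploid; shrub willows (S. integra, S. suchowensis) mostly diploid.")
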