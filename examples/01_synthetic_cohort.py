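"""Generate a synthetic glial cohort and inspect its state composition.

The generator draws per-cell marker intensities from state-specific
log-normal distributions with subject-level random effects, using the
CTRL/AD state proportions of the human temporal-cortex study as defaults.
"""

from gliaplex.synth import CohortParams, generate_intensity_dataset

params = CohortParams(cell_type="astrocyte", n_subjects_per_group=7, cells_per_subject=300, seed=1)
profiles, truth = generate_intensity_dataset(params)

print(f"cohort: {len(profiles)} astrocytes from {profiles['subject'].nunique()} subjects")
print("\nstate composition by diagnosis (%):")
comp = profiles.groupby("diagnosis")["state"].value_counts(normalize=True).unstack() * 100
print(comp.round(1)[["homeostatic", "intermediate", "reactive"]])
print("\nmedian GFAP intensity by state:")
print(profiles.groupby("state")["GFAP"].median().round(1))
# CTRL rows should sit near (49.5, 33.1, 17.5)% and AD near (19.6, 36.2, 44.2)%;
# GFAP rises monotonically from homeostatic to reactive.
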