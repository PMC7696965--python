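"""Quantify autofluorescence ROIs: normalized intensity and heterogeneity.

Tumor mucosa loses green autofluorescence (lower normalized intensity) and is
more heterogeneous (higher normalized pixel SD).
"""

from oralfusion import CohortSpec, generate_cohort, quantify_cohort

cohort = generate_cohort(CohortSpec(n_patients=35, seed=0))
features = quantify_cohort(cohort.images, channel_mode="green")

print(f"feature table: {features.shape[0]} ROIs (2 per patient)")
print(features.head(4).round(4).to_string())
print()
summary = features.groupby("tissue_class")[["norm_intensity", "norm_heterogeneity"]].mean()
print(summary.round(4).to_string())
# norm_intensity ~ 1 means the ROI matches the whole-image brightness; the
# tumor ROIs sit well below 1 (loss of autofluorescence) and carry roughly
# twice the normalized heterogeneity of normal mucosa.
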