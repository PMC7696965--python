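"""Generate a paired synthetic cohort and inspect its structure.

Each patient contributes a tumor and an adjacent-normal sample: five raw
Raman spectra per sample plus one autofluorescence image with a circular ROI
per sample.
"""

from oralfusion import CohortSpec, generate_cohort

spec = CohortSpec(n_patients=35, replicates_per_sample=5, seed=0)
cohort = generate_cohort(spec)

print(f"patients:          {spec.n_patients}")
print(f"raw Raman spectra: {len(cohort.spectra)}   (2 classes x 5 replicates each)")
print(f"images:            {len(cohort.images)}    (one per patient, 2 ROIs each)")
print(f"samples:           {cohort.manifest.groupby(['patient_id', 'tissue_class']).ngroups}")
print(f"cohort digest:     {cohort.digest()[:16]}...  (same spec => same digest)")

s = cohort.spectra[0]
print(
    f"\nfirst spectrum: {s.sample_id} replicate {s.replicate_index}, "
    f"{s.wavenumbers.size} points covering {s.wavenumbers[0]:.0f}-{s.wavenumbers[-1]:.0f} cm^-1"
)
# 350 spectra / 5 replicates = 70 samples: the averaged-spectrum count the
# downstream analysis works with.
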