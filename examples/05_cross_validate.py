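"""Cross-validated error rates: LOOCV and stratified 10-fold, per modality.

PCA is refit inside every training fold (no information from the held-out
sample leaks into the projection).  The fused model should not do worse than
the better single modality.
"""

from oralfusion import (
    CohortSpec,
    CvConfig,
    feature_matrix_from_frame,
    generate_cohort,
    kfold_cv,
    loocv,
    preprocess_cohort,
    quantify_cohort,
)

cohort = generate_cohort(CohortSpec(n_patients=35, seed=0))
rfm = feature_matrix_from_frame(preprocess_cohort(cohort.spectra), modality="raman")
vfm = feature_matrix_from_frame(
    quantify_cohort(cohort.images), ["norm_intensity", "norm_heterogeneity"], modality="velscope"
)

cfg = CvConfig(classifier="linear", n_components=2)
for name, ds in (("raman", rfm), ("velscope", vfm), ("fused", [rfm, vfm])):
    loo = loocv(ds, cfg)
    kf = kfold_cv(ds, k=10, seed=0, cfg=cfg)
    print(
        f"{name:9s}: LOOCV error {loo.error_rate:5.2f}%  "
        f"10-fold error {kf.error_rate:5.2f}%  (n = {loo.y_true.size})"
    )
# Lower is better; the fused error should be at or below both single-modality
# errors, mirroring the gain from combining independent optical evidence.
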