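"""PCA-LDA on each modality, then on the fused four-PC representation.

PC1-PC2 of the Raman spectra are concatenated with PC1-PC2 of the
autofluorescence features; the fused discriminant sees both kinds of
evidence at once.
"""

from oralfusion import (
    CohortSpec,
    confusion,
    feature_matrix_from_frame,
    fit_discriminant,
    fit_pca,
    fuse_features,
    generate_cohort,
    performance,
    predict_discriminant,
    preprocess_cohort,
    quantify_cohort,
    transform_pca,
)

cohort = generate_cohort(CohortSpec(n_patients=35, seed=0))
rfm = feature_matrix_from_frame(preprocess_cohort(cohort.spectra), modality="raman")
vfm = feature_matrix_from_frame(
    quantify_cohort(cohort.images), ["norm_intensity", "norm_heterogeneity"], modality="velscope"
)

scores = {}
for fm in (rfm, vfm):
    pca = fit_pca(fm, k=2)
    scores[fm.modality] = transform_pca(pca, fm)
    print(
        f"{fm.modality:9s} PCA: explained variance "
        f"{', '.join(f'{r:.1%}' for r in pca.explained_variance_ratio)}"
    )

datasets = dict(scores)
datasets["fused"] = fuse_features(scores["raman"], scores["velscope"])

print()
for name, ds in datasets.items():
    clf = fit_discriminant(ds, kind="linear")
    cm = confusion(ds.labels, predict_discriminant(clf, ds))
    m = performance(cm)
    print(
        f"{name:9s} LDA (training): accuracy {m.accuracy:5.1f}%  "
        f"sensitivity {m.sensitivity:5.1f}%  specificity {m.specificity:5.1f}%  "
        f"(tp={cm.tp} fp={cm.fp} tn={cm.tn} fn={cm.fn})"
    )
# These are apparent (resubstitution) numbers; see 05_cross_validate.py for
# the honest generalization estimates.
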