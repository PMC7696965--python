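"""Published confusion counts of the reference ex vivo study.

The clinical study this pipeline models (35 oral-cancer patients, paired
tumor / adjacent-normal samples, PCA-LDA and PCA-QDA on each modality and on
the fused four-PC representation) reported its results as 2x2 confusion
tables.  Those counts are inputs for metric regression: feeding them through
:func:`oralfusion.evaluation.performance` must reproduce the reported
percentages.  The counts are stored under the tumor-positive convention
(tp = tumors called tumor, tn = normals called normal).

Note: for the Raman tables the study printed sensitivity 80 / specificity
85.71, which is the normal-positive reading of the same counts; under the
tumor-positive convention used everywhere else the values are sensitivity
85.71, specificity 80.  ``REPORTED_METRICS`` carries the convention-consistent
values; accuracy is unaffected.
"""

from __future__ import annotations

REPORTED_CONFUSIONS: dict[tuple[str, str], dict[str, int]] = {
    ("velscope", "linear"): dict(tp=35, fn=0, tn=28, fp=7),
    ("velscope", "quadratic"): dict(tp=34, fn=1, tn=29, fp=6),
    ("raman", "linear"): dict(tp=30, fn=5, tn=28, fp=7),
    ("raman", "quadratic"): dict(tp=30, fn=5, tn=28, fp=7),
    ("fused", "linear"): dict(tp=35, fn=0, tn=33, fp=2),
    ("fused", "quadratic"): dict(tp=35, fn=0, tn=33, fp=2),
}

#: Reported percentages (tumor-positive convention), rounded as printed.
REPORTED_METRICS: dict[tuple[str, str], dict[str, float]] = {
    ("velscope", "linear"): dict(accuracy=90.0, sensitivity=100.0, specificity=80.0),
    ("velscope", "quadratic"): dict(accuracy=90.0, sensitivity=97.14, specificity=82.86),
    ("raman", "linear"): dict(accuracy=82.9, sensitivity=85.71, specificity=80.0),
    ("raman", "quadratic"): dict(accuracy=82.9, sensitivity=85.71, specificity=80.0),
    ("fused", "linear"): dict(accuracy=97.14, sensitivity=100.0, specificity=94.3),
    ("fused", "quadratic"): dict(accuracy=97.14, sensitivity=100.0, specificity=94.3),
}

#: Reported model and cross-validated error rates in percent, by modality.
REPORTED_ERROR_RATES: dict[str, dict[str, float]] = {
    "raman": dict(model=17.1, kfold=17.10, loocv=14.30),
    "velscope": dict(model=10.0, kfold=10.0, loocv=10.0),
    "fused": dict(model=3.0, kfold=7.0, loocv=9.0),
}
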