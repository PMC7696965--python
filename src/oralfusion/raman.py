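"""Raman spectral preprocessing.

Turns raw replicate spectra into one normalized fingerprint-region spectrum
per (patient, tissue class) sample.  The chain is fixed:

    Savitzky-Golay smoothing -> iterative-polynomial baseline subtraction ->
    crop/resample to the canonical 700..1800 cm^-1 grid -> per-spectrum
    normalization -> replicate averaging -> renormalization.

Normalizing before averaging makes the sample mean robust to acquisition-scale
drift between replicates (laser-power variation); the alternative order
(average raw, then normalize) is available via ``average_before_normalize``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .errors import (
    CoverageError,
    DegenerateInputError,
    InvalidSpecError,
    NonUniformGridError,
)
from .synthetic import Spectrum

__all__ = [
    "FINGERPRINT_LO",
    "FINGERPRINT_HI",
    "canonical_grid",
    "PreprocessConfig",
    "savitzky_golay_smooth",
    "baseline_correct",
    "crop_and_resample",
    "normalize_spectrum",
    "average_replicates",
    "preprocess_sample",
    "preprocess_cohort",
]

#: Fingerprint region bounds, cm^-1.
FINGERPRINT_LO, FINGERPRINT_HI = 700.0, 1800.0

_NORMALIZATIONS = ("minmax", "unit_area", "unit_norm")


def canonical_grid(lo: float = FINGERPRINT_LO, hi: float = FINGERPRINT_HI) -> np.ndarray:
    """The canonical 1 cm^-1 analysis grid, inclusive of both ends (1101 points)."""
    return np.arange(lo, hi + 1.0, 1.0)


@dataclass(frozen=True)
class PreprocessConfig:
    """Preprocessing parameters.

    sg_window / sg_order
        Savitzky-Golay window length (odd, >= 5) and polynomial order; order 3
        with an 11-point window preserves ~8 cm^-1-wide bands while denoising.
    baseline_poly_order / baseline_iterations
        Order and clamp-to-minimum iteration count of the iterative polynomial
        baseline estimator (modpoly-style), suited to broad fluorescence
        backgrounds.
    fingerprint_lo / fingerprint_hi
        Analysis window in cm^-1.
    normalization
        'minmax' (span exactly [0, 1]), 'unit_area' (trapezoidal integral 1)
        or 'unit_norm' (Euclidean length 1).
    average_before_normalize
        If True, replicates are averaged raw and normalized once at the end.
    """

    sg_window: int = 11
    sg_order: int = 3
    baseline_poly_order: int = 5
    baseline_iterations: int = 50
    fingerprint_lo: float = FINGERPRINT_LO
    fingerprint_hi: float = FINGERPRINT_HI
    normalization: str = "minmax"
    average_before_normalize: bool = False

    def __post_init__(self) -> None:
        if self.sg_window < 5 or self.sg_window % 2 == 0:
            raise InvalidSpecError("sg_window must be an odd integer >= 5")
        if self.sg_order >= self.sg_window:
            raise InvalidSpecError("sg_order must be < sg_window")
        if self.baseline_poly_order < 0:
            raise InvalidSpecError("baseline_poly_order must be >= 0")
        if self.baseline_iterations < 1:
            raise InvalidSpecError("baseline_iterations must be >= 1")
        if self.fingerprint_lo >= self.fingerprint_hi:
            raise InvalidSpecError("fingerprint_lo must be < fingerprint_hi")
        if self.normalization not in _NORMALIZATIONS:
            raise InvalidSpecError(f"normalization must be one of {_NORMALIZATIONS}")


def _require_uniform(w: np.ndarray) -> None:
    steps = np.diff(w)
    if steps.size and not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
        raise NonUniformGridError(
            "wavenumber grid is not uniform; resample (crop_and_resample) before smoothing"
        )


def savitzky_golay_smooth(s: Spectrum, cfg: PreprocessConfig = PreprocessConfig()) -> Spectrum:
    """Least-squares local-polynomial smoothing; the axis is unchanged.

    Edges use mirror padding so the output length equals the input length.
    Exact on polynomials of degree <= sg_order at interior points.
    """
    _require_uniform(s.wavenumbers)
    if s.intensities.size <= cfg.sg_window:
        raise InvalidSpecError("spectrum shorter than the Savitzky-Golay window")
    smoothed = savgol_filter(s.intensities, cfg.sg_window, cfg.sg_order, mode="mirror")
    return s.with_intensities(smoothed)


def _iterative_polynomial_baseline(
    w: np.ndarray, Y: np.ndarray, order: int, iterations: int
) -> np.ndarray:
    """Modpoly-style baseline for one spectrum (1-D Y) or a batch (2-D, rows).

    Repeatedly fits a polynomial and clamps the working spectrum to the
    pointwise minimum of (working, fit); peaks are progressively excluded and
    the fit relaxes onto the slowly varying background.
    """
    n = w.size
    if order >= n:
        raise InvalidSpecError("baseline polynomial order must be < number of points")
    u = np.linspace(-1.0, 1.0, n) if n > 1 else np.zeros(1)
    V = np.polynomial.polynomial.polyvander(u, order)
    pinv = np.linalg.pinv(V)
    batch = np.atleast_2d(np.asarray(Y, dtype=float))
    work = batch.T.copy()  # (n_points, n_spectra)
    base = work
    for _ in range(iterations):
        base = V @ (pinv @ work)
        work = np.minimum(work, base)
    base = base.T
    return base[0] if np.ndim(Y) == 1 else base


def baseline_correct(s: Spectrum, cfg: PreprocessConfig = PreprocessConfig()) -> Spectrum:
    """Subtract an iteratively fitted slowly varying polynomial baseline."""
    base = _iterative_polynomial_baseline(
        s.wavenumbers, s.intensities, cfg.baseline_poly_order, cfg.baseline_iterations
    )
    return s.with_intensities(s.intensities - base)


def crop_and_resample(s: Spectrum, cfg: PreprocessConfig = PreprocessConfig()) -> Spectrum:
    """Linear interpolation onto the canonical 1 cm^-1 fingerprint grid."""
    lo, hi = cfg.fingerprint_lo, cfg.fingerprint_hi
    w = s.wavenumbers
    if w[0] > lo or w[-1] < hi:
        missing = []
        if w[0] > lo:
            missing.append(f"[{lo}, {min(w[0], hi)})")
        if w[-1] < hi:
            missing.append(f"({max(w[-1], lo)}, {hi}]")
        raise CoverageError(
            f"spectrum covers [{w[0]}, {w[-1]}] cm^-1 but the fingerprint window "
            f"needs {lo}..{hi}; missing {' and '.join(missing)}"
        )
    grid = canonical_grid(lo, hi)
    return s.with_intensities(np.interp(grid, w, s.intensities), wavenumbers=grid)


def normalize_spectrum(s: Spectrum, cfg: PreprocessConfig = PreprocessConfig()) -> Spectrum:
    """Normalize intensities per the configured mode."""
    y = s.intensities
    if cfg.normalization == "minmax":
        span = y.max() - y.min()
        if span == 0:
            raise DegenerateInputError("constant spectrum cannot be min-max normalized")
        out = (y - y.min()) / span
    elif cfg.normalization == "unit_area":
        area = np.trapezoid(y, s.wavenumbers)
        if area == 0:
            raise DegenerateInputError("zero-area spectrum cannot be area-normalized")
        out = y / area
    else:  # unit_norm
        norm = np.linalg.norm(y)
        if norm == 0:
            raise DegenerateInputError("zero spectrum cannot be length-normalized")
        out = y / norm
    return s.with_intensities(out)


def average_replicates(
    replicates: list[Spectrum], cfg: PreprocessConfig | None = None
) -> Spectrum:
    """Pointwise mean of same-sample replicates; renormalized if ``cfg`` given."""
    if not replicates:
        raise InvalidSpecError("no replicates to average")
    first = replicates[0]
    for r in replicates[1:]:
        if (r.patient_id, r.tissue_class) != (first.patient_id, first.tissue_class):
            raise InvalidSpecError(
                "replicates mix samples: "
                f"{r.sample_id} vs {first.sample_id}"
            )
        if r.wavenumbers.shape != first.wavenumbers.shape or not np.allclose(
            r.wavenumbers, first.wavenumbers
        ):
            raise InvalidSpecError("replicates are not on a common wavenumber grid")
    mean = np.mean([r.intensities for r in replicates], axis=0)
    out = Spectrum(first.wavenumbers, mean, first.patient_id, first.tissue_class, None)
    if cfg is not None:
        out = normalize_spectrum(out, cfg)
    return out


def preprocess_sample(
    replicates: list[Spectrum], cfg: PreprocessConfig = PreprocessConfig()
) -> Spectrum:
    """Full chain for one sample's replicates -> one normalized spectrum."""
    stages = []
    for r in replicates:
        r = savitzky_golay_smooth(r, cfg)
        r = baseline_correct(r, cfg)
        r = crop_and_resample(r, cfg)
        if not cfg.average_before_normalize:
            r = normalize_spectrum(r, cfg)
        stages.append(r)
    return average_replicates(stages, cfg)


def _group_key(s: Spectrum) -> tuple[str, str]:
    return (s.patient_id, s.tissue_class)


def preprocess_cohort(
    spectra: list[Spectrum], cfg: PreprocessConfig = PreprocessConfig()
) -> pd.DataFrame:
    """Preprocess a whole cohort of raw spectra into one row per sample.

    Returns a DataFrame indexed by sample_id ("patient:class") with columns
    patient_id, tissue_class, then the 1101 canonical-grid intensities.  Rows
    are ordered by (patient_id, tissue_class).

    Spectra sharing the raw grid are processed as one batch (single design
    matrix for the baseline fit), which keeps 350-spectrum cohorts fast; the
    result is identical to the per-spectrum chain.
    """
    if not spectra:
        raise InvalidSpecError("no spectra to preprocess")
    groups: dict[tuple[str, str], list[Spectrum]] = {}
    for s in spectra:
        groups.setdefault(_group_key(s), []).append(s)

    ref_w = spectra[0].wavenumbers
    uniform_batch = all(
        s.wavenumbers.shape == ref_w.shape and np.array_equal(s.wavenumbers, ref_w)
        for s in spectra
    )
    processed: dict[int, Spectrum] = {}
    if uniform_batch:
        _require_uniform(ref_w)
        Y = np.vstack([s.intensities for s in spectra])
        Y = savgol_filter(Y, cfg.sg_window, cfg.sg_order, axis=1, mode="mirror")
        Y = Y - _iterative_polynomial_baseline(
            ref_w, Y, cfg.baseline_poly_order, cfg.baseline_iterations
        )
        for i, s in enumerate(spectra):
            r = crop_and_resample(s.with_intensities(Y[i]), cfg)
            if not cfg.average_before_normalize:
                r = normalize_spectrum(r, cfg)
            processed[id(s)] = r

    rows = []
    for key in sorted(groups):
        reps = groups[key]
        if uniform_batch:
            sample = average_replicates([processed[id(r)] for r in reps], cfg)
        else:
            sample = preprocess_sample(reps, cfg)
        rows.append(
            {
                "sample_id": sample.sample_id,
                "patient_id": sample.patient_id,
                "tissue_class": sample.tissue_class,
                **{f"wn_{int(w)}": v for w, v in zip(sample.wavenumbers, sample.intensities)},
            }
        )
    df = pd.DataFrame(rows).set_index("sample_id")
    return df
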