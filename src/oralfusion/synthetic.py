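"""Synthetic dual-modality oral-lesion cohorts.

Emulates the measurement design of an ex vivo oral-cancer screening study:
each patient contributes a tumor sample and an adjacent-normal sample, each
sample is measured five times by Raman spectroscopy (replicates at different
tissue locations), and each patient has one autofluorescence photograph with a
clinician-drawn circular region of interest (ROI) on the tumor and one on
normal-appearing mucosa.

The generative model is deliberately phenomenological, not physical:

* A Raman spectrum is a slowly varying fluorescence-like polynomial baseline
  plus Gaussian peaks at fixed fingerprint-region band positions plus white
  noise.  Tumor tissue multiplies the protein-associated bands (1004, 1156,
  1339, 1450, 1523, 1656 cm^-1) by an amplitude ratio > 1, reflecting the
  protein-dominated biochemistry of malignant mucosa; the lipid-associated
  1123 cm^-1 band is left unchanged.
* An autofluorescence image is a green-dominant field; the normal ROI disc
  sits at the background fluorescence level while the tumor ROI disc is dimmed
  by ``roi_intensity_drop`` (loss of autofluorescence) and has its pixel
  standard deviation inflated by ``roi_heterogeneity_gain``.
* Biological between-sample variability enters as multiplicative log-normal
  jitter (per-sample peak multipliers, per-ROI level/spread multipliers).
  These jitters are drawn identically for both tissue classes, so setting the
  tumor effect parameters to their null values makes the two classes exactly
  exchangeable.

Everything is driven by one root seed through per-patient child streams, so a
cohort is bit-reproducible and stable under subsetting of patients.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .errors import InvalidSpecError

__all__ = [
    "TISSUE_CLASSES",
    "GRID_LO",
    "GRID_HI",
    "GRID_STEP",
    "default_grid",
    "EffectParams",
    "CohortSpec",
    "Spectrum",
    "RoiRecord",
    "RoiImage",
    "Cohort",
    "synth_raman_spectrum",
    "synth_velscope_image",
    "generate_cohort",
    "save_cohort",
    "load_cohort",
]

TISSUE_CLASSES = ("normal", "tumor")

#: Raw acquisition grid (cm^-1): covers the fingerprint region with margin.
GRID_LO, GRID_HI, GRID_STEP = 600.0, 1900.0, 1.0

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def default_grid() -> np.ndarray:
    """The canonical raw wavenumber axis, 600..1900 cm^-1 at 1 cm^-1 (1301 points)."""
    return np.arange(GRID_LO, GRID_HI + GRID_STEP, GRID_STEP)


@dataclass(frozen=True)
class EffectParams:
    """Tunable class-difference and nuisance parameters of the generator.

    Parameters
    ----------
    peak_centers : tuple of float
        Raman band positions in cm^-1.
    peak_amplitudes : tuple of float
        Baseline-subtracted peak heights (a.u.) in normal tissue, one per band.
    tumor_amplitude_ratio : tuple of float
        Multiplier applied to each band's amplitude in tumor tissue
        (1.0 = band unaffected by malignancy).
    peak_fwhm : float
        Full width at half maximum of every band, cm^-1.
    baseline_poly_coeffs : tuple of float
        Ascending polynomial coefficients of the fluorescence background,
        evaluated in the scaled coordinate u = (w - w_min)/(w_max - w_min).
    noise_sd : float
        Standard deviation of iid Gaussian shot-like noise per wavenumber, a.u.
    sample_jitter_sd : float
        Log-normal sigma of per-(patient, class) per-band amplitude
        multipliers: biological heterogeneity that survives replicate
        averaging and makes cohorts imperfectly separable.
    replicate_jitter_sd : float
        Log-normal sigma of the additional per-replicate per-band multiplier
        (location-to-location variation within one sample).
    roi_intensity_drop : float
        Fractional loss of green fluorescence in the tumor ROI, in [0, 1].
    roi_heterogeneity_gain : float
        Multiplier (>= 1) on the tumor ROI pixel standard deviation.
    roi_level_jitter_sd, roi_sd_jitter_sd : float
        Log-normal sigmas of the per-ROI level and spread multipliers, drawn
        identically for both classes.
    background_green : float
        Mean green-channel value of healthy mucosa / image background (8-bit).
    background_pixel_sd : float
        Pixel noise of the green channel outside any effect.
    artifact_value : float
        Green level of injected bright out-of-ROI artifacts ("teeth").
    """

    peak_centers: tuple[float, ...] = (1004.0, 1123.0, 1156.0, 1339.0, 1450.0, 1523.0, 1656.0)
    peak_amplitudes: tuple[float, ...] = (1.0, 0.35, 0.7, 0.45, 0.8, 0.55, 0.9)
    tumor_amplitude_ratio: tuple[float, ...] = (1.7, 1.0, 1.45, 1.3, 1.55, 1.35, 1.6)
    peak_fwhm: float = 8.0
    baseline_poly_coeffs: tuple[float, ...] = (2.5, -1.8, 0.5)
    noise_sd: float = 0.02
    sample_jitter_sd: float = 0.10
    replicate_jitter_sd: float = 0.05
    roi_intensity_drop: float = 0.35
    roi_heterogeneity_gain: float = 1.8
    roi_level_jitter_sd: float = 0.24
    roi_sd_jitter_sd: float = 0.25
    background_green: float = 150.0
    background_pixel_sd: float = 6.0
    artifact_value: float = 235.0

    def __post_init__(self) -> None:
        n = len(self.peak_centers)
        if len(self.peak_amplitudes) != n or len(self.tumor_amplitude_ratio) != n:
            raise InvalidSpecError(
                "peak_centers, peak_amplitudes and tumor_amplitude_ratio must have equal length"
            )
        if self.peak_fwhm <= 0:
            raise InvalidSpecError("peak_fwhm must be > 0")
        if self.noise_sd < 0:
            raise InvalidSpecError("noise_sd must be >= 0")
        if not 0.0 <= self.roi_intensity_drop <= 1.0:
            raise InvalidSpecError("roi_intensity_drop must lie in [0, 1]")
        if self.roi_heterogeneity_gain < 1.0:
            raise InvalidSpecError("roi_heterogeneity_gain must be >= 1")
        if any(r < 0 for r in self.tumor_amplitude_ratio):
            raise InvalidSpecError("tumor_amplitude_ratio entries must be >= 0")
        for name in ("sample_jitter_sd", "replicate_jitter_sd", "roi_level_jitter_sd", "roi_sd_jitter_sd"):
            if getattr(self, name) < 0:
                raise InvalidSpecError(f"{name} must be >= 0")

    @classmethod
    def null(cls, **overrides) -> "EffectParams":
        """Parameters with no class difference (tumor == normal in distribution)."""
        base = dict(
            tumor_amplitude_ratio=tuple(1.0 for _ in cls().peak_centers),
            roi_intensity_drop=0.0,
            roi_heterogeneity_gain=1.0,
        )
        base.update(overrides)
        return cls(**base)

    @classmethod
    def deterministic(cls, **overrides) -> "EffectParams":
        """Parameters with every stochastic term switched off."""
        base = dict(
            noise_sd=0.0,
            sample_jitter_sd=0.0,
            replicate_jitter_sd=0.0,
            roi_level_jitter_sd=0.0,
            roi_sd_jitter_sd=0.0,
            background_pixel_sd=0.0,
        )
        base.update(overrides)
        return cls(**base)

    def scaled(self, factor: float) -> "EffectParams":
        """Scale every class-difference parameter by ``factor`` (nuisances untouched).

        Amplitude ratios scale as 1 + factor*(r - 1); the intensity drop is
        clipped to 0.95 so the tumor disc stays renderable.
        """
        return replace(
            self,
            tumor_amplitude_ratio=tuple(1.0 + factor * (r - 1.0) for r in self.tumor_amplitude_ratio),
            roi_intensity_drop=min(0.95, factor * self.roi_intensity_drop),
            roi_heterogeneity_gain=1.0 + factor * (self.roi_heterogeneity_gain - 1.0),
        )


@dataclass(frozen=True)
class CohortSpec:
    """Study design of one synthetic cohort.

    Defaults mirror the emulated clinical design: 35 patients, one tumor and
    one adjacent-normal sample each, five Raman replicates per sample, one
    autofluorescence image per patient with both ROIs.
    """

    n_patients: int = 35
    replicates_per_sample: int = 5
    seed: int = 0
    effect: EffectParams = field(default_factory=EffectParams)
    image_size: int = 128
    roi_radius: int = 20
    inject_artifacts: bool = False

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise InvalidSpecError("n_patients must be >= 1")
        if self.replicates_per_sample < 1:
            raise InvalidSpecError("replicates_per_sample must be >= 1")
        if self.roi_radius < 2:
            raise InvalidSpecError("roi_radius must be >= 2 px")
        if self.image_size < 4 * self.roi_radius:
            raise InvalidSpecError("image_size must be >= 4x roi_radius")


@dataclass
class Spectrum:
    """One Raman acquisition: a wavenumber axis, intensities, and provenance."""

    wavenumbers: np.ndarray
    intensities: np.ndarray
    patient_id: str
    tissue_class: str
    replicate_index: int | None = None

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavenumbers.shape != self.intensities.shape or self.wavenumbers.ndim != 1:
            raise InvalidSpecError("wavenumbers and intensities must be equal-length 1-D arrays")
        if self.wavenumbers.size >= 2 and not np.all(np.diff(self.wavenumbers) > 0):
            raise InvalidSpecError("wavenumbers must be strictly increasing")
        if not np.all(np.isfinite(self.intensities)):
            raise InvalidSpecError("intensities must be finite")
        if self.tissue_class not in TISSUE_CLASSES:
            raise InvalidSpecError(f"tissue_class must be one of {TISSUE_CLASSES}")

    @property
    def sample_id(self) -> str:
        return f"{self.patient_id}:{self.tissue_class}"

    def with_intensities(self, intensities: np.ndarray, wavenumbers: np.ndarray | None = None) -> "Spectrum":
        return Spectrum(
            wavenumbers=self.wavenumbers if wavenumbers is None else wavenumbers,
            intensities=intensities,
            patient_id=self.patient_id,
            tissue_class=self.tissue_class,
            replicate_index=self.replicate_index,
        )


@dataclass(frozen=True)
class RoiRecord:
    """A circular ROI: 0-based pixel center (cx = column, cy = row) and radius."""

    patient_id: str
    tissue_class: str
    cx: float
    cy: float
    radius: float


@dataclass
class RoiImage:
    """An 8-bit RGB autofluorescence image plus its circular ROI records."""

    pixels: np.ndarray
    rois: list[RoiRecord]
    patient_id: str

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise InvalidSpecError("pixels must be an H x W x 3 array")
        if self.pixels.dtype != np.uint8:
            raise InvalidSpecError("pixels must be 8-bit (uint8)")
        h, w, _ = self.pixels.shape
        for roi in self.rois:
            if roi.radius < 0.5:
                raise InvalidSpecError("ROI radius must be >= 0.5 px")
            if (
                roi.cx - roi.radius < 0
                or roi.cy - roi.radius < 0
                or roi.cx + roi.radius > w - 1
                or roi.cy + roi.radius > h - 1
            ):
                raise InvalidSpecError(
                    f"ROI for {roi.patient_id}/{roi.tissue_class} extends outside the image"
                )


def _gaussian_peaks(w: np.ndarray, effect: EffectParams, amplitudes: np.ndarray) -> np.ndarray:
    sigma = effect.peak_fwhm * _FWHM_TO_SIGMA
    out = np.zeros_like(w)
    for center, amp in zip(effect.peak_centers, amplitudes):
        out += amp * np.exp(-0.5 * ((w - center) / sigma) ** 2)
    return out


def baseline_profile(w: np.ndarray, effect: EffectParams) -> np.ndarray:
    """The noiseless fluorescence background on axis ``w`` (closed form)."""
    u = (w - w[0]) / (w[-1] - w[0]) if w[-1] > w[0] else np.zeros_like(w)
    return np.polynomial.polynomial.polyval(u, np.asarray(effect.baseline_poly_coeffs))


def expected_spectrum(tissue_class: str, effect: EffectParams, w: np.ndarray | None = None) -> np.ndarray:
    """Closed-form expected intensities (baseline + mean peaks, no jitter/noise)."""
    if w is None:
        w = default_grid()
    amps = np.asarray(effect.peak_amplitudes, dtype=float)
    if tissue_class == "tumor":
        amps = amps * np.asarray(effect.tumor_amplitude_ratio, dtype=float)
    return baseline_profile(w, effect) + _gaussian_peaks(w, effect, amps)


def synth_raman_spectrum(
    tissue_class: str,
    effect: EffectParams,
    rng: np.random.Generator,
    *,
    patient_id: str = "P000",
    replicate_index: int = 0,
    wavenumbers: np.ndarray | None = None,
    peak_multipliers: np.ndarray | None = None,
) -> Spectrum:
    """Draw one raw Raman spectrum.

    intensity(w) = baseline(w) + sum_i amp_i * ratio_i(class) * mult_i * G(w; c_i, sigma)
                   + N(0, noise_sd)

    ``peak_multipliers`` carries the per-sample/per-replicate jitter; when it
    is None a fresh per-call multiplier vector exp(N(0, sample_jitter_sd)) is
    drawn, so standalone draws have sample-level variability too.
    """
    if tissue_class not in TISSUE_CLASSES:
        raise InvalidSpecError(f"tissue_class must be one of {TISSUE_CLASSES}")
    w = default_grid() if wavenumbers is None else np.asarray(wavenumbers, dtype=float)
    lo, hi = w[0], w[-1]
    for center in effect.peak_centers:
        if not lo <= center <= hi:
            raise InvalidSpecError(f"peak center {center} cm^-1 lies outside the grid [{lo}, {hi}]")
    amps = np.asarray(effect.peak_amplitudes, dtype=float)
    if tissue_class == "tumor":
        amps = amps * np.asarray(effect.tumor_amplitude_ratio, dtype=float)
    if peak_multipliers is None:
        if effect.sample_jitter_sd > 0:
            peak_multipliers = np.exp(rng.normal(0.0, effect.sample_jitter_sd, size=amps.size))
        else:
            peak_multipliers = np.ones_like(amps)
    amps = amps * np.asarray(peak_multipliers, dtype=float)

    intensities = baseline_profile(w, effect) + _gaussian_peaks(w, effect, amps)
    if effect.noise_sd > 0:
        intensities = intensities + rng.normal(0.0, effect.noise_sd, size=w.size)
    return Spectrum(w, intensities, patient_id, tissue_class, replicate_index)


def _disc_mask(h: int, w: int, cx: float, cy: float, radius: float) -> np.ndarray:
    yy, xx = np.ogrid[:h, :w]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2


def synth_velscope_image(
    effect: EffectParams,
    rng: np.random.Generator,
    *,
    patient_id: str = "P000",
    size: int = 128,
    radius: int = 20,
    inject_artifacts: bool = False,
) -> RoiImage:
    """Render one green-dominant autofluorescence image with two ROI discs.

    The normal ROI is drawn at the jittered background fluorescence level;
    the tumor ROI at that level times (1 - roi_intensity_drop) with pixel
    spread times roi_heterogeneity_gain.  Per-ROI level and spread jitters are
    drawn for both classes alike so a null effect is exactly exchangeable.
    Optional bright artifacts ("teeth") are placed away from both discs to
    exercise downstream whole-image normalization.
    """
    if size < 4 * radius:
        raise InvalidSpecError("image size must be >= 4x ROI radius")
    if radius < 2:
        raise InvalidSpecError("ROI radius must be >= 2 px")
    h = w = size
    cy = h // 2
    rois = [
        RoiRecord(patient_id, "normal", cx=w // 4, cy=cy, radius=radius),
        RoiRecord(patient_id, "tumor", cx=3 * w // 4, cy=cy, radius=radius),
    ]
    d2 = (rois[0].cx - rois[1].cx) ** 2 + (rois[0].cy - rois[1].cy) ** 2
    if d2 <= (2 * radius) ** 2:
        raise InvalidSpecError("the two ROI discs overlap")

    bg = effect.background_green
    green = bg + rng.normal(0.0, effect.background_pixel_sd, size=(h, w)) if effect.background_pixel_sd > 0 else np.full((h, w), bg)

    for roi in rois:
        mask = _disc_mask(h, w, roi.cx, roi.cy, roi.radius)
        n_pix = int(mask.sum())
        level_jit = np.exp(rng.normal(0.0, effect.roi_level_jitter_sd)) if effect.roi_level_jitter_sd > 0 else 1.0
        sd_jit = np.exp(rng.normal(0.0, effect.roi_sd_jitter_sd)) if effect.roi_sd_jitter_sd > 0 else 1.0
        if roi.tissue_class == "tumor":
            level = bg * level_jit * (1.0 - effect.roi_intensity_drop)
            sd = effect.background_pixel_sd * sd_jit * effect.roi_heterogeneity_gain
        else:
            level = bg * level_jit
            sd = effect.background_pixel_sd * sd_jit
        vals = level + rng.normal(0.0, sd, size=n_pix) if sd > 0 else np.full(n_pix, level)
        green[mask] = vals

    if inject_artifacts:
        # bright blobs confined to the top rows, clear of both discs
        top = max(2, cy - radius - 14)
        for _ in range(3):
            acx = rng.uniform(10, w - 10)
            acy = rng.uniform(4, top)
            ar = rng.uniform(4, 8)
            amask = _disc_mask(h, w, acx, acy, ar)
            green[amask] = effect.artifact_value

    red = 0.45 * green
    blue = 0.30 * green
    if effect.background_pixel_sd > 0:
        red = red + rng.normal(0.0, 0.3 * effect.background_pixel_sd, size=(h, w))
        blue = blue + rng.normal(0.0, 0.3 * effect.background_pixel_sd, size=(h, w))
    pixels = np.stack([red, green, blue], axis=-1)
    pixels = np.clip(np.rint(pixels), 0, 255).astype(np.uint8)
    return RoiImage(pixels=pixels, rois=rois, patient_id=patient_id)


@dataclass
class Cohort:
    """A generated cohort: raw spectra, images, and the linking manifest."""

    spec: CohortSpec
    spectra: list[Spectrum]
    images: list[RoiImage]
    manifest: pd.DataFrame

    def digest(self) -> str:
        """SHA-256 over every artifact's bytes; equal specs give equal digests."""
        hasher = hashlib.sha256()
        hasher.update(self.manifest.to_csv(index=False).encode())
        for s in self.spectra:
            hasher.update(s.wavenumbers.tobytes())
            hasher.update(s.intensities.tobytes())
        for img in self.images:
            hasher.update(img.pixels.tobytes())
            for roi in img.rois:
                hasher.update(
                    f"{roi.patient_id}:{roi.tissue_class}:{roi.cx}:{roi.cy}:{roi.radius}".encode()
                )
        return hasher.hexdigest()


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate a full paired cohort from one root seed.

    Per patient: one child RNG stream drives (in order) the per-sample peak
    multipliers, the replicate spectra for the normal then the tumor sample,
    and finally the autofluorescence image.  The manifest has one row per raw
    spectrum (patient_id, tissue_class, replicate, sample_id, spectrum_index).
    """
    effect = spec.effect
    n_peaks = len(effect.peak_centers)
    children = np.random.SeedSequence(spec.seed).spawn(spec.n_patients)
    spectra: list[Spectrum] = []
    images: list[RoiImage] = []
    rows: list[dict] = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        pid = f"P{i:03d}"
        for cls in TISSUE_CLASSES:
            sample_mult = (
                np.exp(rng.normal(0.0, effect.sample_jitter_sd, size=n_peaks))
                if effect.sample_jitter_sd > 0
                else np.ones(n_peaks)
            )
            for rep in range(spec.replicates_per_sample):
                mult = sample_mult
                if effect.replicate_jitter_sd > 0:
                    mult = mult * np.exp(rng.normal(0.0, effect.replicate_jitter_sd, size=n_peaks))
                s = synth_raman_spectrum(
                    cls, effect, rng, patient_id=pid, replicate_index=rep, peak_multipliers=mult
                )
                rows.append(
                    dict(
                        patient_id=pid,
                        tissue_class=cls,
                        replicate=rep,
                        sample_id=s.sample_id,
                        spectrum_index=len(spectra),
                    )
                )
                spectra.append(s)
        images.append(
            synth_velscope_image(
                effect,
                rng,
                patient_id=pid,
                size=spec.image_size,
                radius=spec.roi_radius,
                inject_artifacts=spec.inject_artifacts,
            )
        )
    manifest = pd.DataFrame(rows)
    return Cohort(spec=spec, spectra=spectra, images=images, manifest=manifest)


# ---------------------------------------------------------------------------
# Disk round-trip: two-column CSV spectra, PNG images, JSON ROIs, CSV manifest.
# ---------------------------------------------------------------------------

def save_cohort(cohort: Cohort, outdir: str | Path) -> Path:
    outdir = Path(outdir)
    (outdir / "spectra").mkdir(parents=True, exist_ok=True)
    (outdir / "images").mkdir(parents=True, exist_ok=True)
    manifest = cohort.manifest.copy()
    paths = []
    for _, row in manifest.iterrows():
        s = cohort.spectra[int(row.spectrum_index)]
        rel = f"spectra/{row.patient_id}_{row.tissue_class}_r{int(row.replicate)}.csv"
        pd.DataFrame({"wavenumber": s.wavenumbers, "intensity": s.intensities}).to_csv(
            outdir / rel, index=False
        )
        paths.append(rel)
    manifest["path"] = paths
    manifest.to_csv(outdir / "manifest.csv", index=False)

    roi_records = []
    for img in cohort.images:
        Image.fromarray(img.pixels).save(outdir / "images" / f"{img.patient_id}.png")
        for roi in img.rois:
            roi_records.append(
                {
                    "patient_id": roi.patient_id,
                    "class": roi.tissue_class,
                    "cx": roi.cx,
                    "cy": roi.cy,
                    "r": roi.radius,
                }
            )
    (outdir / "rois.json").write_text(json.dumps(roi_records, indent=1))
    return outdir


def load_cohort(indir: str | Path, spec: CohortSpec | None = None) -> Cohort:
    """Load a cohort saved by :func:`save_cohort` (spec metadata optional)."""
    indir = Path(indir)
    manifest = pd.read_csv(indir / "manifest.csv")
    spectra = []
    for _, row in manifest.iterrows():
        df = pd.read_csv(indir / row.path)
        spectra.append(
            Spectrum(
                df["wavenumber"].to_numpy(),
                df["intensity"].to_numpy(),
                row.patient_id,
                row.tissue_class,
                int(row.replicate),
            )
        )
    rois = json.loads((indir / "rois.json").read_text())
    by_patient: dict[str, list[RoiRecord]] = {}
    for rec in rois:
        by_patient.setdefault(rec["patient_id"], []).append(
            RoiRecord(rec["patient_id"], rec["class"], rec["cx"], rec["cy"], rec["r"])
        )
    images = []
    for pid in sorted(by_patient):
        pixels = np.asarray(Image.open(indir / "images" / f"{pid}.png"))
        images.append(RoiImage(pixels=pixels, rois=by_patient[pid], patient_id=pid))
    if spec is None:
        n_patients = len(images)
        reps = int(manifest["replicate"].max()) + 1 if len(manifest) else 1
        spec = CohortSpec(n_patients=n_patients, replicates_per_sample=reps)
    return Cohort(spec=spec, spectra=spectra, images=images, manifest=manifest)
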