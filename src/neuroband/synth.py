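"""Seed-deterministic synthetic data with known ground truth.

Synthetic EEG is built in the frequency domain: a 1/f^beta background with a
multiplicative trough planted at the theta/alpha transition frequency, plus
Gaussian spectral peaks (theta, alpha, low-alpha and upper-alpha bumps, and
three high-frequency peaks).  Channels mix a shared oscillatory component
with channel-independent noise.  Because the target spectral density is
analytic, the alpha3/alpha2 ratio a subject will produce can be computed by
running the real band pipeline on the analytic spectrum, which is how cohort
generation calibrates the upper-alpha amplitude to a target ratio.

Volumes get ellipsoidal brain masks and lesions at stated Gaussian contrast;
thickness datasets plant group-mean differences on chosen vertex sets and
memory scores with a specified within-group correlation to regional
thickness.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from neuroband.bands import analyze_spectrum
from neuroband.morphostats import Surface, ThicknessDataset
from neuroband.spectral import (
    CHANNELS_1020,
    EegRecording,
    PowerSpectrum,
    analysis_grid,
)
from neuroband.wmh import VolumeImage


def _fwhm_to_sigma(fwhm: float) -> float:
    return fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def _gauss(f: np.ndarray, center: float, fwhm: float) -> np.ndarray:
    s = _fwhm_to_sigma(fwhm)
    return np.exp(-0.5 * ((f - center) / s) ** 2)


# ---------------------------------------------------------------------------
# EEG
# ---------------------------------------------------------------------------


@dataclass
class EegSpec:
    """Ground-truth parameters of one synthetic resting EEG recording.

    Amplitudes are spectral-density units above background; the signal scale
    is arbitrary (the band pipeline is scale invariant).  The low- and
    upper-alpha components are one-sided shoulders anchored at the alpha
    peak (decaying away from it), so raising either never displaces the
    alpha maximum — this keeps the amplitude-to-ratio calibration maps
    strictly monotone.
    """

    tf_true: float = 6.9
    iaf_true: float = 10.9
    theta_amp: float = 1.2
    alpha_amp: float = 3.5
    low_alpha_amp: float = 1.5
    upper_alpha_amp: float = 0.5
    beta_amps: tuple[float, float, float] = (0.6, 0.45, 0.35)
    beta_centers: tuple[float, float, float] = (16.5, 25.5, 38.0)
    peak_fwhm: float = 1.5
    shoulder_sigma_up: float = 0.9
    shoulder_sigma_down: float = 1.1
    shoulder_sigma_sharp: float = 0.25
    trough_depth: float = 0.45
    trough_fwhm: float = 1.2
    background_amp: float = 10.0
    background_exponent: float = 1.0
    noise_sd: float = 0.5
    n_channels: int = 19
    sampling_rate: float = 250.0
    duration: float = 300.0
    channel_mixing: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.tf_true < self.iaf_true:
            raise ValueError("tf_true must lie below iaf_true")
        if self.duration < 20.0:
            raise ValueError("duration must be at least 20 s")
        if not 0.0 <= self.channel_mixing <= 1.0:
            raise ValueError("channel_mixing must lie in [0, 1]")
        if self.background_amp <= 0 or self.sampling_rate <= 0:
            raise ValueError("background_amp and sampling_rate must be positive")
        if min(self.theta_amp, self.alpha_amp, self.low_alpha_amp) < 0 or (
            self.upper_alpha_amp < 0
        ):
            raise ValueError("peak amplitudes must be non-negative")
        if not 0.0 <= self.trough_depth < 1.0:
            raise ValueError("trough_depth must lie in [0, 1)")


def _background_density(spec: EegSpec, f: np.ndarray) -> np.ndarray:
    """Background + planted TF trough + white measurement noise floor."""
    f = np.maximum(np.asarray(f, dtype=float), 0.5)
    bg = spec.background_amp * f ** (-spec.background_exponent)
    bg = bg * (1.0 - spec.trough_depth * _gauss(f, spec.tf_true, spec.trough_fwhm))
    return bg + 2.0 * spec.noise_sd**2 / spec.sampling_rate


def _shoulder(
    f: np.ndarray, center: float, sigma_main: float, sigma_sharp: float, upward: bool
) -> np.ndarray:
    """One-sided Gaussian shoulder anchored at ``center``.

    Decays with ``sigma_main`` on the chosen side and with the much smaller
    ``sigma_sharp`` on the other, so it never forms a local maximum away from
    the anchor.
    """
    if upward:
        sig = np.where(f >= center, sigma_main, sigma_sharp)
    else:
        sig = np.where(f <= center, sigma_main, sigma_sharp)
    return np.exp(-0.5 * ((f - center) / sig) ** 2)


def _peak_density(spec: EegSpec, f: np.ndarray) -> np.ndarray:
    f = np.asarray(f, dtype=float)
    peaks = (
        spec.theta_amp * _gauss(f, spec.tf_true - 1.5, spec.peak_fwhm)
        + spec.alpha_amp * _gauss(f, spec.iaf_true, spec.peak_fwhm)
        + spec.low_alpha_amp
        * _shoulder(
            f, spec.iaf_true, spec.shoulder_sigma_down, spec.shoulder_sigma_sharp, False
        )
        + spec.upper_alpha_amp
        * _shoulder(
            f, spec.iaf_true, spec.shoulder_sigma_up, spec.shoulder_sigma_sharp, True
        )
    )
    for amp, center in zip(spec.beta_amps, spec.beta_centers):
        peaks = peaks + amp * _gauss(f, center, 2.0)
    return peaks


def spectral_density(spec: EegSpec, f: np.ndarray) -> np.ndarray:
    """Analytic target power spectral density at frequencies ``f`` (Hz)."""
    return _background_density(spec, f) + _peak_density(spec, f)


def mean_spectrum(spec: EegSpec) -> PowerSpectrum:
    """The analytic target spectrum sampled on the 2-45 Hz analysis grid."""
    grid = analysis_grid()
    return PowerSpectrum(grid, spectral_density(spec, grid), n_epochs=0)


def _realize(density: np.ndarray, n_samples: int, fs: float, rng) -> np.ndarray:
    """One time-domain realization with the given one-sided target density.

    Deterministic spectral amplitudes with uniform random phases: chunked
    periodograms then fluctuate far less than for Gaussian amplitudes.
    """
    amp = np.sqrt(np.maximum(density, 0.0) * fs * n_samples / 2.0)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=len(amp))
    coef = amp * np.exp(1j * phases)
    coef[0] = 0.0
    if n_samples % 2 == 0:
        coef[-1] = 0.0
    return np.fft.irfft(coef, n=n_samples)


def generate_eeg(spec: EegSpec) -> EegRecording:
    """Synthesize a multichannel recording matching the spec's target density.

    The oscillatory (peak) component is a mix of a shared realization and a
    per-channel one (``channel_mixing`` = shared fraction of peak power); the
    background is independent per channel.
    """
    rng = np.random.default_rng(spec.seed)
    fs = spec.sampling_rate
    n = int(round(spec.duration * fs))
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    bg_density = _background_density(spec, freqs)
    bg_density[freqs < 0.5] = 0.0
    pk_density = _peak_density(spec, freqs)
    m = spec.channel_mixing
    shared = _realize(pk_density * m, n, fs, rng)
    samples = np.empty((spec.n_channels, n))
    for c in range(spec.n_channels):
        own = _realize(pk_density * (1.0 - m), n, fs, rng)
        noise = _realize(bg_density, n, fs, rng)
        samples[c] = shared + own + noise
    labels = (
        list(CHANNELS_1020)
        if spec.n_channels == len(CHANNELS_1020)
        else [f"ch{i + 1}" for i in range(spec.n_channels)]
    )
    return EegRecording(samples, fs, labels)


def ratio_from_spec(spec: EegSpec) -> float:
    """alpha3/alpha2 ratio the band pipeline yields on the analytic spectrum."""
    return analyze_spectrum(mean_spectrum(spec))[2].alpha3_alpha2


_MAP_CACHE: dict[tuple, np.ndarray] = {}


def amplitude_ratio_map(
    spec: EegSpec, knob: str, amp_grid: np.ndarray
) -> np.ndarray:
    """Pipeline alpha3/alpha2 ratio for each amplitude of one shoulder knob.

    Maps are cached on the spec's spectral parameters (seed excluded): with
    grid-snapped anchors a cohort reuses a handful of maps.
    """
    if knob not in ("upper_alpha_amp", "low_alpha_amp"):
        raise ValueError(f"unknown calibration knob {knob!r}")
    from dataclasses import astuple

    key = (knob, tuple(np.round(amp_grid, 9)), astuple(replace(spec, seed=0)))
    if key not in _MAP_CACHE:
        _MAP_CACHE[key] = np.array(
            [ratio_from_spec(replace(spec, **{knob: float(a)})) for a in amp_grid]
        )
    return _MAP_CACHE[key]


def calibrate_ratio(
    spec: EegSpec, target_ratio: float
) -> tuple[EegSpec, float]:
    """Calibrate a shoulder amplitude so the pipeline realizes ``target_ratio``.

    Both knob maps (upper shoulder raises the ratio, lower shoulder lowers
    it) are evaluated from a zeroed-shoulder base spec through the analytic
    spectrum and the real band pipeline, checked for strict monotonicity and
    inverted by interpolation.  Returns the calibrated spec and the ratio the
    pipeline realizes on its analytic spectrum.
    """
    base = replace(spec, upper_alpha_amp=0.0, low_alpha_amp=0.0)
    base_ratio = ratio_from_spec(base)
    if target_ratio >= base_ratio:
        knob, grid = "upper_alpha_amp", np.linspace(0.0, 8.0, 49)
    else:
        knob, grid = "low_alpha_amp", np.linspace(0.0, 12.0, 49)
    ratios = amplitude_ratio_map(base, knob, grid)
    sign = 1.0 if ratios[-1] >= ratios[0] else -1.0
    if np.any(sign * np.diff(ratios) <= 0):
        raise ValueError("amplitude-to-ratio map is not strictly monotone")
    lo, hi = min(ratios[0], ratios[-1]), max(ratios[0], ratios[-1])
    if not lo <= target_ratio <= hi:
        raise ValueError(
            f"target ratio {target_ratio:.3f} outside achievable range "
            f"[{lo:.3f}, {hi:.3f}]"
        )
    amp = float(np.interp(sign * target_ratio, sign * ratios, grid))
    calibrated = replace(base, **{knob: amp})
    return calibrated, ratio_from_spec(calibrated)


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------


@dataclass
class GroupRatioSpec:
    """Target alpha3/alpha2 distribution for one group (truncated normal)."""

    mean: float
    sd: float
    lo: float
    hi: float


@dataclass
class CohortSpec:
    """Parameters of a synthetic cohort with planted group structure.

    Group ratio targets default to the low/middle/high means with draws kept
    clear of the fixed cutoffs so stratification is stable; covariates are
    drawn matched across groups unless ``inject_age_imbalance`` is set.
    """

    group_sizes: tuple[int, int, int] = (18, 38, 18)  # low, middle, high
    ratio_specs: dict[str, GroupRatioSpec] = field(
        default_factory=lambda: {
            "low": GroupRatioSpec(0.90, 0.05, 0.80, 0.96),
            "middle": GroupRatioSpec(1.08, 0.035, 1.02, 1.14),
            "high": GroupRatioSpec(1.29, 0.08, 1.19, 1.50),
        }
    )
    age_mean: float = 69.5
    age_sd: float = 7.0
    education_mean: float = 7.5
    education_sd: float = 3.8
    mmse_mean: float = 27.1
    mmse_sd: float = 1.4
    female_fraction: float = 0.69
    inject_age_imbalance: float = 0.0  # years added to the high group
    iaf_mean: float = 10.9
    iaf_sd: float = 0.8
    tf_gap: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 2 for n in self.group_sizes):
            raise ValueError("each group needs at least 2 subjects")
        for name, rs in self.ratio_specs.items():
            if not rs.lo < rs.hi or rs.sd < 0:
                raise ValueError(f"infeasible ratio spec for group {name!r}")


def _snap(freq: float, step: float = 0.5) -> float:
    """Round a frequency to the analysis grid."""
    return float(round(float(freq) / step) * step)


def _truncated_normal(rng, mean, sd, lo, hi, size):
    if sd == 0:
        return np.full(size, float(np.clip(mean, lo, hi)))
    out = np.empty(size)
    for i in range(size):
        for _ in range(1000):
            x = rng.normal(mean, sd)
            if lo <= x <= hi:
                out[i] = x
                break
        else:
            out[i] = float(np.clip(mean, lo, hi))
    return out


#: Memory-score marginals used for matched cohort draws.
MEMORY_SCORE_MODELS = {
    "babcock": (9.8, 3.8),
    "avlt_immediate": (40.0, 11.0),
    "avlt_delayed": (8.6, 4.0),
    "rey_recall": (14.0, 6.5),
}


def generate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, list[EegSpec]]:
    """Cohort table plus one calibrated EEG spec per subject.

    Each subject's target ratio is drawn from its group's truncated-normal
    spec; the upper-alpha amplitude is calibrated so the band pipeline run on
    the subject's analytic spectrum realizes that ratio, which is recorded in
    the ``alpha3_alpha2`` column.
    """
    rng = np.random.default_rng(spec.seed)
    rows: list[dict] = []
    eeg_specs: list[EegSpec] = []
    sid = 0
    for group, n in zip(("low", "middle", "high"), spec.group_sizes):
        rs = spec.ratio_specs[group]
        targets = _truncated_normal(rng, rs.mean, rs.sd, rs.lo, rs.hi, n)
        for target in targets:
            # Anchor truths are snapped to the 0.5 Hz analysis grid so the
            # detected anchors (and hence the calibration maps) are stable.
            iaf = _snap(np.clip(rng.normal(spec.iaf_mean, spec.iaf_sd), 8.5, 13.0))
            tf = _snap(
                np.clip(iaf - spec.tf_gap + rng.normal(0.0, 0.25), 4.5, iaf - 2.0)
            )
            base = EegSpec(tf_true=tf, iaf_true=iaf, seed=int(rng.integers(2**31)))
            calibrated, realized = calibrate_ratio(base, float(target))
            eeg_specs.append(calibrated)
            age = rng.normal(spec.age_mean, spec.age_sd)
            if group == "high":
                age += spec.inject_age_imbalance
            row = {
                "subject_id": f"S{sid:03d}",
                "alpha3_alpha2": realized,
                "target_ratio": float(target),
                "age": float(np.clip(age, 50, 89)),
                "sex": int(rng.random() < spec.female_fraction),
                "education": float(
                    np.clip(rng.normal(spec.education_mean, spec.education_sd), 3, 18)
                ),
                "mmse": float(np.clip(rng.normal(spec.mmse_mean, spec.mmse_sd), 23, 30)),
                "wmh_volume": float(rng.lognormal(mean=1.0, sigma=0.8)),
                "group_true": group,
            }
            for score, (m, s) in MEMORY_SCORE_MODELS.items():
                row[score] = float(max(rng.normal(m, s), 0.0))
            rows.append(row)
            sid += 1
    return pd.DataFrame(rows), eeg_specs


# ---------------------------------------------------------------------------
# Lesion volumes
# ---------------------------------------------------------------------------


def _ellipsoid_mask(
    shape: tuple[int, int, int],
    center: tuple[float, float, float],
    radii: tuple[float, float, float],
) -> np.ndarray:
    grids = np.ogrid[: shape[0], : shape[1], : shape[2]]
    acc = np.zeros(shape, dtype=float)
    for g, c, r in zip(grids, center, radii):
        acc = acc + ((g - c) / r) ** 2
    return acc <= 1.0


def generate_lesion_volume(
    shape: tuple[int, int, int] = (64, 64, 64),
    mu: float = 100.0,
    sigma: float = 10.0,
    lesions: Sequence[tuple[tuple[float, float, float], tuple[float, float, float], float]] = (),
    voxel_volume: float = 1.44,
    brain_radii: tuple[float, float, float] | None = None,
    seed: int = 0,
) -> tuple[VolumeImage, np.ndarray]:
    """FLAIR-like volume: Gaussian background in an ellipsoidal brain mask.

    ``lesions`` is a sequence of ``(center, radii, contrast)`` triples; each
    plants an ellipsoid whose mean intensity is ``mu + contrast * sigma``
    (same noise SD as the background).  Returns the volume and the truth
    lesion mask.  A lesion extending outside the brain mask is an error.
    """
    rng = np.random.default_rng(seed)
    if brain_radii is None:
        brain_radii = tuple(0.45 * s for s in shape)
    center = tuple((s - 1) / 2.0 for s in shape)
    brain = _ellipsoid_mask(shape, center, brain_radii)
    voxels = np.zeros(shape)
    voxels[brain] = rng.normal(mu, sigma, size=int(brain.sum()))
    truth = np.zeros(shape, dtype=bool)
    for les_center, les_radii, contrast in lesions:
        les = _ellipsoid_mask(shape, les_center, les_radii)
        if np.any(les & ~brain):
            raise ValueError(f"lesion at {les_center} extends outside the brain mask")
        voxels[les] = rng.normal(mu + contrast * sigma, sigma, size=int(les.sum()))
        truth |= les
    return VolumeImage(voxels, voxel_volume, brain), truth


# ---------------------------------------------------------------------------
# Thickness datasets
# ---------------------------------------------------------------------------


def build_grid_surface(
    n_rows: int, n_cols: int, vertex_area: float = 1.2
) -> Surface:
    """Rectangular-grid surface with 4-neighbor adjacency and uniform areas."""
    n = n_rows * n_cols
    neighbors: list[np.ndarray] = []
    for i in range(n):
        r, c = divmod(i, n_cols)
        nb = []
        if r > 0:
            nb.append(i - n_cols)
        if r < n_rows - 1:
            nb.append(i + n_cols)
        if c > 0:
            nb.append(i - 1)
        if c < n_cols - 1:
            nb.append(i + 1)
        neighbors.append(np.array(nb, dtype=int))
    return Surface(np.full(n, float(vertex_area)), neighbors)


@dataclass
class PlantedCluster:
    """A vertex set with per-group mean thickness (mm) and noise SD (mm)."""

    vertices: np.ndarray
    group_means: dict[str, float]
    group_sds: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=int)


@dataclass
class MemoryCorrelation:
    """Planted within-group correlation between a score and regional thickness.

    ``regional_sd`` adds a shared subject-level thickness factor over the
    region (for every subject), making the member vertices covary — without
    it the per-vertex correlations stay near zero even though the score
    correlates with the regional mean.
    """

    score: str
    group: str
    vertices: np.ndarray
    rho: float
    score_mean: float = 10.0
    score_sd: float = 4.0
    regional_sd: float = 0.0

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=int)
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError(f"infeasible correlation rho={self.rho}")


def generate_thickness_dataset(
    surface: Surface,
    groups: Sequence[str],
    planted_clusters: Sequence[PlantedCluster] = (),
    covariate_effects: dict[str, float] | None = None,
    memory_correlations: Sequence[MemoryCorrelation] = (),
    covariates: pd.DataFrame | None = None,
    baseline_mm: float = 2.4,
    noise_sd: float = 0.25,
    seed: int = 0,
) -> ThicknessDataset:
    """Thickness matrix with planted group effects, covariates and scores.

    Thickness = baseline + planted group means on cluster vertices +
    covariate effects (slope per SD of the covariate, applied surface-wide) +
    Gaussian noise.  Memory scores are generated so their within-group
    correlation with the mean thickness over the named vertices equals
    ``rho`` in population.
    """
    rng = np.random.default_rng(seed)
    groups = np.asarray(groups, dtype=object)
    n_subj, n_vert = len(groups), surface.n_vertices
    if covariates is None:
        covariates = pd.DataFrame(
            {
                "age": rng.normal(69.5, 7.0, n_subj),
                "sex": (rng.random(n_subj) < 0.69).astype(int),
                "education": rng.normal(7.5, 3.8, n_subj),
                "mmse": rng.normal(27.1, 1.4, n_subj),
                "wmh_volume": rng.lognormal(1.0, 0.8, n_subj),
            }
        )
    covariates = covariates.reset_index(drop=True)
    mean_map = np.full((n_subj, n_vert), baseline_mm)
    sd_map = np.full((n_subj, n_vert), noise_sd)
    for pc in planted_clusters:
        for g, m in pc.group_means.items():
            members = np.flatnonzero(groups == g)
            mean_map[np.ix_(members, pc.vertices)] = m
            if g in pc.group_sds:
                sd_map[np.ix_(members, pc.vertices)] = pc.group_sds[g]
    thickness = mean_map + rng.normal(0.0, 1.0, size=(n_subj, n_vert)) * sd_map
    for cov, slope in (covariate_effects or {}).items():
        x = covariates[cov].to_numpy(dtype=float)
        z = (x - x.mean()) / (x.std() or 1.0)
        thickness = thickness + np.outer(z * slope, np.ones(n_vert))
    scores: dict[str, np.ndarray] = {}
    factored: set[tuple[int, ...]] = set()
    for mc in memory_correlations:
        if mc.regional_sd > 0:
            key = tuple(np.sort(mc.vertices))
            if key not in factored:  # one shared factor per region
                factored.add(key)
                factor = rng.normal(0.0, mc.regional_sd, n_subj)
                thickness[:, mc.vertices] += factor[:, None]
        if mc.score not in scores:
            scores[mc.score] = rng.normal(mc.score_mean, mc.score_sd, n_subj)
        members = np.flatnonzero(groups == mc.group)
        regional = thickness[np.ix_(members, mc.vertices)].mean(axis=1)
        z_thick = (regional - regional.mean()) / (regional.std() or 1.0)
        noise = rng.normal(0.0, 1.0, len(members))
        z_score = mc.rho * z_thick + np.sqrt(1.0 - mc.rho**2) * noise
        scores[mc.score][members] = mc.score_mean + mc.score_sd * z_score
    memory = pd.DataFrame(scores) if scores else None
    return ThicknessDataset(
        surface=surface,
        thickness=thickness,
        covariates=covariates,
        groups=groups,
        memory_scores=memory,
    )
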