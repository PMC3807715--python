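"""Individually anchored frequency bands and relative band powers.

Two anchor frequencies drive the band construction: the theta/alpha
transition frequency TF (power minimum between the theta and alpha peaks)
and the individual alpha frequency IAF (power maximum in the extended alpha
range 5-14 Hz).  From these the eight per-subject bands are built:

    delta  = [TF-4, TF-2)          alpha3 = [IAF, IAF+2)
    theta  = [TF-2, TF)            beta1  = [IAF+2, b1)
    alpha1 = [TF, (TF+IAF)/2)      beta2  = [b1, b2)
    alpha2 = [(TF+IAF)/2, IAF)     gamma  = [b2, 45]

where b1 and b2 are the power minima between the three highest-prominence
peaks above alpha3 (IBF1, IBF2, IGF).  Relative band power is the mean over
a band's bins of power normalized by the mean power over the whole 2-45 Hz
grid; the biomarker of interest is the alpha3/alpha2 relative-power ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy import signal

from neuroband.spectral import FREQ_MAX, FREQ_STEP, PowerSpectrum

IAF_RANGE = (5.0, 14.0)
#: Fallback beta1/beta2 and beta2/gamma boundaries (Hz) when fewer than three
#: high-frequency peaks are found: nearest grid values to typical whole-sample
#: boundaries.
FALLBACK_BOUNDARIES = (19.0, 32.5)
PEAK_PROMINENCE_FRACTION = 0.05

BAND_NAMES = ("delta", "theta", "alpha1", "alpha2", "alpha3", "beta1", "beta2", "gamma")


class Band(NamedTuple):
    """A frequency interval [lo, hi), closed at ``hi`` when ``closed_hi``."""

    lo: float
    hi: float
    closed_hi: bool = False

    def contains(self, freqs: np.ndarray) -> np.ndarray:
        freqs = np.asarray(freqs, dtype=float)
        upper = freqs <= self.hi + 1e-9 if self.closed_hi else freqs < self.hi - 1e-9
        return (freqs >= self.lo - 1e-9) & upper

    @property
    def width(self) -> float:
        return self.hi - self.lo


@dataclass
class AnchorFrequencies:
    """Per-subject anchor frequencies (Hz).

    ``boundary1``/``boundary2`` are the beta1/beta2 and beta2/gamma band
    edges derived from the high-frequency peaks (or the fallback values).
    ``flags`` records every fallback or tie-break taken during detection.
    """

    tf: float
    iaf: float
    itf: float | None = None
    ibf1: float | None = None
    ibf2: float | None = None
    igf: float | None = None
    boundary1: float = FALLBACK_BOUNDARIES[0]
    boundary2: float = FALLBACK_BOUNDARIES[1]
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.tf < self.iaf:
            raise ValueError(f"TF ({self.tf}) must lie below IAF ({self.iaf})")
        if not IAF_RANGE[0] <= self.iaf <= IAF_RANGE[1]:
            raise ValueError(f"IAF {self.iaf} outside the extended alpha range {IAF_RANGE}")
        peaks = [p for p in (self.ibf1, self.ibf2, self.igf) if p is not None]
        if peaks != sorted(peaks):
            raise ValueError("high-frequency peaks must be increasing: IBF1 < IBF2 < IGF")
        if self.ibf1 is not None and self.ibf1 < self.iaf + 2:
            raise ValueError("IBF1 must lie at or above the alpha3 upper edge (IAF + 2)")
        if self.igf is not None and self.igf > FREQ_MAX:
            raise ValueError(f"IGF must not exceed {FREQ_MAX} Hz")
        if not self.iaf + 2 < self.boundary1 < self.boundary2 < FREQ_MAX:
            raise ValueError(
                "band boundaries must satisfy IAF+2 < boundary1 < boundary2 < 45"
            )


@dataclass
class IndividualBands:
    """The eight per-subject band intervals."""

    delta: Band
    theta: Band
    alpha1: Band
    alpha2: Band
    alpha3: Band
    beta1: Band
    beta2: Band
    gamma: Band

    def as_dict(self) -> dict[str, Band]:
        return {name: getattr(self, name) for name in BAND_NAMES}

    def __post_init__(self) -> None:
        bands = self.as_dict()
        for name, band in bands.items():
            if not band.lo < band.hi:
                raise ValueError(f"band {name} is empty: {band}")
        ordered = [bands[name] for name in BAND_NAMES]
        for prev, nxt in zip(ordered, ordered[1:]):
            if not np.isclose(prev.hi, nxt.lo):
                raise ValueError("bands must be contiguous and non-overlapping")
        if not np.isclose(self.alpha3.width, 2.0):
            raise ValueError("alpha3 must span exactly 2 Hz")
        if not np.isclose(self.gamma.hi, FREQ_MAX) or not self.gamma.closed_hi:
            raise ValueError(f"gamma must be closed at {FREQ_MAX} Hz")


@dataclass
class BandPowerProfile:
    """Relative band powers and the alpha3/alpha2 ratio."""

    relative_power: dict[str, float]
    alpha3_alpha2: float


class HighPeaks(NamedTuple):
    ibf1: float
    ibf2: float
    igf: float
    boundaries: tuple[float, float]
    flags: list[str]


def _local_maxima(power: np.ndarray, prominence: float | None = None) -> np.ndarray:
    """Indices of interior local maxima of ``power``."""
    peaks, _ = signal.find_peaks(power, prominence=prominence)
    return peaks


def _lowest_of_ties(candidates: np.ndarray, values: np.ndarray) -> tuple[int, bool]:
    """Best candidate index by value, ties (1e-9 relative) broken downward."""
    best = values.max()
    tol = 1e-9 * max(abs(best), 1.0)
    tied = candidates[values >= best - tol]
    return int(tied.min()), len(tied) > 1


def detect_iaf(spectrum: PowerSpectrum) -> tuple[float, list[str]]:
    """Individual alpha frequency: highest local maximum within 5-14 Hz.

    Falls back to the global maximum of the range (flag ``iaf_no_local_max``)
    when the spectrum has no interior local maximum there.  Equal-height peaks
    are resolved toward the lower frequency (flag ``iaf_tie``).
    """
    if not np.any(spectrum.power > 0):
        raise ValueError("cannot detect IAF on an all-zero spectrum")
    lo, hi = spectrum.bin_index(IAF_RANGE[0]), spectrum.bin_index(IAF_RANGE[1])
    flags: list[str] = []
    peaks = _local_maxima(spectrum.power)
    peaks = peaks[(peaks >= lo) & (peaks <= hi)]
    if len(peaks) == 0:
        flags.append("iaf_no_local_max")
        window = spectrum.power[lo : hi + 1]
        idx, tied = _lowest_of_ties(np.arange(lo, hi + 1), window)
    else:
        idx, tied = _lowest_of_ties(peaks, spectrum.power[peaks])
    if tied:
        flags.append("iaf_tie")
    return float(spectrum.freqs[idx]), flags


def detect_tf(spectrum: PowerSpectrum, iaf: float) -> tuple[float, list[str]]:
    """Theta/alpha transition: power minimum in [max(4, IAF-6), IAF-1]."""
    if iaf <= IAF_RANGE[0]:
        raise ValueError(
            f"IAF {iaf} leaves no room for a transition-frequency search window"
        )
    lo = spectrum.bin_index(max(4.0, iaf - 6.0))
    hi = spectrum.bin_index(iaf - 1.0)
    window = spectrum.power[lo : hi + 1]
    flags: list[str] = []
    idx, tied = _lowest_of_ties(np.arange(lo, hi + 1), -window)
    if tied:
        flags.append("tf_tie")
    return float(spectrum.freqs[idx]), flags


def detect_itf(spectrum: PowerSpectrum, tf: float) -> tuple[float | None, list[str]]:
    """Individual theta frequency: local maximum within the theta band [TF-2, TF)."""
    lo = max(spectrum.bin_index(max(tf - 2.0, spectrum.freqs[0])), 0)
    hi = spectrum.bin_index(tf) - 1
    if hi < lo:
        return None, ["itf_empty_band"]
    peaks = _local_maxima(spectrum.power)
    peaks = peaks[(peaks >= lo) & (peaks <= hi)]
    flags: list[str] = []
    if len(peaks) == 0:
        flags.append("itf_no_local_max")
        idx, _ = _lowest_of_ties(
            np.arange(lo, hi + 1), spectrum.power[lo : hi + 1]
        )
    else:
        idx, _ = _lowest_of_ties(peaks, spectrum.power[peaks])
    return float(spectrum.freqs[idx]), flags


def detect_high_peaks(spectrum: PowerSpectrum, alpha3_hi: float) -> HighPeaks:
    """Beta1, beta2 and gamma peaks plus the band boundaries between them.

    The three highest-prominence local maxima in (alpha3_hi, 45] become IBF1,
    IBF2 and IGF (ordered by frequency); each boundary is the frequency of the
    power minimum between consecutive peaks.  With fewer than three peaks the
    fixed fallback boundaries are used and the segment maxima stand in for the
    peaks (flag ``high_peaks_fallback``).
    """
    if alpha3_hi >= FREQ_MAX:
        raise ValueError("alpha3 upper edge must lie below 45 Hz")
    power = spectrum.power
    first = spectrum.bin_index(alpha3_hi) + 1  # strictly above alpha3
    prominence = PEAK_PROMINENCE_FRACTION * power.max() if power.max() > 0 else None
    peaks = _local_maxima(power, prominence=prominence)
    peaks = peaks[peaks >= first]
    flags: list[str] = []
    if len(peaks) >= 3:
        proms = signal.peak_prominences(power, peaks)[0]
        top3 = np.sort(peaks[np.argsort(proms)[::-1][:3]])
        f1, f2, f3 = (float(spectrum.freqs[i]) for i in top3)
        b1 = _interpeak_minimum(spectrum, top3[0], top3[1])
        b2 = _interpeak_minimum(spectrum, top3[1], top3[2])
        return HighPeaks(f1, f2, f3, (b1, b2), flags)
    flags.append("high_peaks_fallback")
    b1, b2 = FALLBACK_BOUNDARIES
    segs = [
        (first, spectrum.bin_index(b1) - 1),
        (spectrum.bin_index(b1), spectrum.bin_index(b2) - 1),
        (spectrum.bin_index(b2), len(power) - 1),
    ]
    stand_ins = []
    for lo, hi in segs:
        idx, _ = _lowest_of_ties(np.arange(lo, hi + 1), power[lo : hi + 1])
        stand_ins.append(float(spectrum.freqs[idx]))
    return HighPeaks(*stand_ins, (b1, b2), flags)


def _interpeak_minimum(spectrum: PowerSpectrum, i: int, j: int) -> float:
    inner = np.arange(i + 1, j)
    if len(inner) == 0:
        return float((spectrum.freqs[i] + spectrum.freqs[j]) / 2)
    idx, _ = _lowest_of_ties(inner, -spectrum.power[inner])
    return float(spectrum.freqs[idx])


def detect_anchors(spectrum: PowerSpectrum) -> AnchorFrequencies:
    """Run the full anchor-detection chain on one spectrum."""
    iaf, flags = detect_iaf(spectrum)
    tf, f = detect_tf(spectrum, iaf)
    flags += f
    itf, f = detect_itf(spectrum, tf)
    flags += f
    high = detect_high_peaks(spectrum, iaf + 2.0)
    flags += high.flags
    return AnchorFrequencies(
        tf=tf,
        iaf=iaf,
        itf=itf,
        ibf1=high.ibf1,
        ibf2=high.ibf2,
        igf=high.igf,
        boundary1=high.boundaries[0],
        boundary2=high.boundaries[1],
        flags=flags,
    )


def build_bands(anchors: AnchorFrequencies) -> IndividualBands:
    """Construct the eight individual band intervals from anchor frequencies."""
    tf, iaf = anchors.tf, anchors.iaf
    mid = (tf + iaf) / 2.0
    b1, b2 = anchors.boundary1, anchors.boundary2
    return IndividualBands(
        delta=Band(tf - 4.0, tf - 2.0),
        theta=Band(tf - 2.0, tf),
        alpha1=Band(tf, mid),
        alpha2=Band(mid, iaf),
        alpha3=Band(iaf, iaf + 2.0),
        beta1=Band(iaf + 2.0, b1),
        beta2=Band(b1, b2),
        gamma=Band(b2, FREQ_MAX, closed_hi=True),
    )


def relative_band_power(
    spectrum: PowerSpectrum, bands: IndividualBands
) -> BandPowerProfile:
    """Relative band powers: per-bin power over the 2-45 Hz mean, band-averaged.

    Bins below the delta band's lower edge belong to no band but still enter
    the normalization denominator.
    """
    mean_power = spectrum.power.mean()
    if mean_power <= 0:
        raise ValueError("cannot normalize an all-zero spectrum")
    rel = spectrum.power / mean_power
    out: dict[str, float] = {}
    for name, band in bands.as_dict().items():
        members = band.contains(spectrum.freqs)
        if not members.any():
            raise ValueError(f"band {name} ({band.lo}-{band.hi} Hz) contains no bins")
        out[name] = float(rel[members].mean())
    return BandPowerProfile(
        relative_power=out, alpha3_alpha2=out["alpha3"] / out["alpha2"]
    )


def analyze_spectrum(
    spectrum: PowerSpectrum,
) -> tuple[AnchorFrequencies, IndividualBands, BandPowerProfile]:
    """Anchors, bands and relative powers for one channel-collapsed spectrum."""
    anchors = detect_anchors(spectrum)
    bands = build_bands(anchors)
    return anchors, bands, relative_band_power(spectrum, bands)
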