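"""Resting EEG to a channel-collapsed power spectrum.

A recording is fragmented into consecutive non-overlapping epochs (2 s by
default), each epoch/channel is turned into a Hann-windowed periodogram
(Welch with one segment per epoch, no segment overlap), the periodograms are
averaged over epochs and then over channels, and the result is restricted to
the analysis grid of 0.5 Hz bins from 2 to 45 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal, stats

#: Analysis grid: bin centers at 2.0, 2.5, ..., 45.0 Hz (87 bins).
FREQ_MIN = 2.0
FREQ_MAX = 45.0
FREQ_STEP = 0.5
N_BINS = int(round((FREQ_MAX - FREQ_MIN) / FREQ_STEP)) + 1

DEFAULT_EPOCH_SECONDS = 2.0

#: 10-20 labels of the standard 19-channel montage.
CHANNELS_1020 = (
    "Fp1 Fp2 F7 F3 Fz F4 F8 T3 C3 Cz C4 T4 T5 P3 Pz P4 T6 O1 O2".split()
)


def analysis_grid() -> np.ndarray:
    """Return the 87-bin frequency grid in Hz."""
    return FREQ_MIN + FREQ_STEP * np.arange(N_BINS)


class InsufficientDataError(ValueError):
    """Raised when a recording is too short for the requested epoching."""


@dataclass
class EegRecording:
    """A multichannel EEG recording.

    Parameters
    ----------
    samples
        Channels x time matrix, in microvolts.
    sampling_rate
        Sampling rate in Hz.
    channel_labels
        One label per channel (10-20 names for scalp data).
    epoch_mask
        Optional sequence of *retained* epoch indices (0-based).  When set,
        :func:`epoch` drops every epoch whose index is not listed.
    """

    samples: np.ndarray
    sampling_rate: float
    channel_labels: Sequence[str] = field(default_factory=list)
    epoch_mask: Sequence[int] | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D channels x time array")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.channel_labels and len(self.channel_labels) != self.samples.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.samples.shape[0]} channels"
            )

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.sampling_rate

    def rereference_common_average(self) -> "EegRecording":
        """Return a copy re-referenced to the common average of all channels."""
        return EegRecording(
            self.samples - self.samples.mean(axis=0, keepdims=True),
            self.sampling_rate,
            list(self.channel_labels),
            None if self.epoch_mask is None else list(self.epoch_mask),
        )


@dataclass
class PowerSpectrum:
    """Channel-collapsed power spectral density on the 2-45 Hz grid.

    ``power`` is a density (unit^2/Hz) per 0.5 Hz bin; ``n_epochs`` counts the
    epochs averaged into it.
    """

    freqs: np.ndarray
    power: np.ndarray
    n_epochs: int = 0

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.freqs.shape != self.power.shape or self.freqs.ndim != 1:
            raise ValueError("freqs and power must be 1-D arrays of equal length")
        steps = np.diff(self.freqs)
        if len(steps) and not np.allclose(steps, FREQ_STEP):
            raise ValueError("frequency grid must be uniform with 0.5 Hz spacing")
        if np.any(self.power < 0):
            raise ValueError("power must be non-negative")

    def bin_index(self, freq: float) -> int:
        """Index of the grid bin whose center is ``freq`` (must be on-grid)."""
        idx = int(round((freq - self.freqs[0]) / FREQ_STEP))
        if not (0 <= idx < len(self.freqs)) or not np.isclose(self.freqs[idx], freq):
            raise ValueError(f"{freq} Hz is not on the spectrum grid")
        return idx


@dataclass
class StationarityReport:
    """Outcome of the head-vs-tail spectral stability control."""

    p_value: float
    spectrum_head: PowerSpectrum
    spectrum_tail: PowerSpectrum
    head_powers: np.ndarray
    tail_powers: np.ndarray
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must lie in [0, 1]")


def epoch(
    recording: EegRecording,
    epoch_seconds: float = DEFAULT_EPOCH_SECONDS,
) -> np.ndarray:
    """Fragment a recording into consecutive non-overlapping epochs.

    Returns an ``(n_epochs, n_channels, samples_per_epoch)`` array.  A trailing
    partial epoch is discarded; epochs excluded by the recording's
    ``epoch_mask`` are dropped.
    """
    n_per = epoch_seconds * recording.sampling_rate
    if abs(n_per - round(n_per)) > 1e-9:
        raise ValueError("epoch_seconds x sampling_rate must be an integer sample count")
    n_per = int(round(n_per))
    n_epochs = recording.n_samples // n_per
    if n_epochs == 0:
        raise InsufficientDataError(
            f"recording of {recording.duration:.2f} s is shorter than one "
            f"{epoch_seconds:.2f} s epoch"
        )
    trimmed = recording.samples[:, : n_epochs * n_per]
    epochs = trimmed.reshape(recording.n_channels, n_epochs, n_per).swapaxes(0, 1)
    if recording.epoch_mask is not None:
        mask = np.asarray(sorted(set(recording.epoch_mask)), dtype=int)
        if len(mask) and (mask.min() < 0 or mask.max() >= n_epochs):
            raise ValueError(
                f"epoch_mask indices must lie in [0, {n_epochs - 1}]"
            )
        epochs = epochs[mask]
    return epochs


def _epoch_psds(epochs: np.ndarray, sampling_rate: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-epoch, per-channel Hann periodograms restricted to the grid.

    Returns ``(freqs, psd)`` with ``psd`` of shape (n_epochs, n_channels, n_bins).
    """
    epochs = np.asarray(epochs, dtype=float)
    if epochs.ndim != 3 or epochs.shape[0] == 0:
        raise ValueError("need a non-empty (n_epochs, n_channels, n_samples) array")
    if np.isnan(epochs).any():
        raise ValueError("epochs contain NaN samples")
    n_per = epochs.shape[2]
    resolution = sampling_rate / n_per
    if abs(resolution - FREQ_STEP) > 1e-9:
        raise ValueError(
            f"epoch length yields {resolution:g} Hz resolution; "
            f"{FREQ_STEP} Hz required (500 samples at 250 Hz)"
        )
    # Welch with a single segment per epoch, Hann window, no overlap.
    freqs, psd = signal.welch(
        epochs,
        fs=sampling_rate,
        window="hann",
        nperseg=n_per,
        noverlap=0,
        detrend="constant",
        scaling="density",
        axis=-1,
    )
    lo = int(round(FREQ_MIN / FREQ_STEP))
    hi = int(round(FREQ_MAX / FREQ_STEP))
    return freqs[lo : hi + 1], psd[..., lo : hi + 1]


def compute_psd(epochs: np.ndarray, sampling_rate: float) -> PowerSpectrum:
    """Average per-channel Hann periodograms over epochs, then over channels."""
    freqs, psd = _epoch_psds(epochs, sampling_rate)
    collapsed = psd.mean(axis=(0, 1))
    return PowerSpectrum(freqs, collapsed, n_epochs=psd.shape[0])


def total_power_per_epoch(epochs: np.ndarray, sampling_rate: float) -> np.ndarray:
    """Channel-collapsed total 2-45 Hz power of each epoch (one value per epoch)."""
    _, psd = _epoch_psds(epochs, sampling_rate)
    return psd.mean(axis=1).sum(axis=-1) * FREQ_STEP


def stationarity_check(
    epochs: np.ndarray,
    sampling_rate: float,
    n_control: int = 10,
) -> StationarityReport:
    """Head-vs-tail spectral stability control.

    The channel-collapsed total 2-45 Hz power of the first ``n_control`` and
    last ``n_control`` epochs is compared by one-way ANOVA.  Identical groups
    (zero between- and within-group variance) are flagged degenerate with
    p = 1.
    """
    epochs = np.asarray(epochs, dtype=float)
    if epochs.shape[0] < 2 * n_control:
        raise InsufficientDataError(
            f"stationarity control needs >= {2 * n_control} epochs, got {epochs.shape[0]}"
        )
    head, tail = epochs[:n_control], epochs[-n_control:]
    head_tot = total_power_per_epoch(head, sampling_rate)
    tail_tot = total_power_per_epoch(tail, sampling_rate)
    pooled = np.concatenate([head_tot, tail_tot])
    degenerate = np.ptp(pooled) == 0 or np.array_equal(head_tot, tail_tot)
    if degenerate:
        p = 1.0
    else:
        p = float(stats.f_oneway(head_tot, tail_tot).pvalue)
        if np.isnan(p):  # pragma: no cover - guarded by the degenerate branch
            p, degenerate = 1.0, True
    return StationarityReport(
        p_value=p,
        spectrum_head=compute_psd(head, sampling_rate),
        spectrum_tail=compute_psd(tail, sampling_rate),
        head_powers=head_tot,
        tail_powers=tail_tot,
        degenerate=bool(degenerate),
    )


def pooled_stationarity(
    epoch_sets: Sequence[np.ndarray],
    sampling_rate: float,
    n_control: int = 10,
) -> float:
    """Cohort-level variant: head vs tail powers pooled over subjects.

    One-way ANOVA of all subjects' head epoch powers against all subjects'
    tail epoch powers.
    """
    heads, tails = [], []
    for ep in epoch_sets:
        rep = stationarity_check(ep, sampling_rate, n_control=n_control)
        heads.append(rep.head_powers)
        tails.append(rep.tail_powers)
    return float(stats.f_oneway(np.concatenate(heads), np.concatenate(tails)).pvalue)


def recording_to_spectrum(
    recording: EegRecording,
    epoch_seconds: float = DEFAULT_EPOCH_SECONDS,
    rereference: bool = False,
) -> PowerSpectrum:
    """Convenience wrapper: epoch a recording and collapse it to one spectrum."""
    if rereference:
        recording = recording.rereference_common_average()
    return compute_psd(epoch(recording, epoch_seconds), recording.sampling_rate)
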