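"""Synthetic multi-patient EEG cohort generator.

Emulates the study conditions the rest of the package is designed for:
a cohort of patients recorded on a common montage at 250 Hz, each
contributing equal amounts of normal and seizure EEG, where

* the *class* signal is a band-limited oscillation (default 4–8 Hz, a
  theta-range ictal rhythm with a weak first harmonic) plus sporadic
  spike-wave transients, present only during seizure intervals; and
* each *patient* imposes confounds that survive per-channel min-max
  normalization only partially: multiplicative per-channel gains,
  a patient-specific background rhythm (baseline spectrum shift),
  a patient-specific noise level, and jitter of the ictal frequency.

Background activity is spectrally shaped Gaussian noise with power ∝ 1/f
(so wavelet sub-band features are non-degenerate) rather than white noise.

Two independent random streams are used: a *structure* stream for patient
identities (gains, frequencies, spike times) and a *noise* stream for the
background noise, so patient identities are stable when noise is resampled.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io_segmentation import (
    MultichannelSignal,
    SegmentBatch,
    label_segments,
    annotation_to_mask,
    minmax_normalize,
    segment_signal,
    write_annotations_csv,
    write_edf_recording,
)

__all__ = ["SyntheticCohortSpec", "generate_cohort", "cohort_to_batches", "write_cohort"]


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Parameters of the synthetic cohort.

    Defaults mirror the cohort the package targets: 14 patients, 22
    channels, 250 Hz, 250 s of each class per patient.  Effect sizes are
    in units of the background noise standard deviation.
    """

    n_patients: int = 14
    n_channels: int = 22
    sampling_rate_hz: float = 250.0
    seconds_per_class_per_patient: float = 250.0
    class_band_hz: tuple[float, float] = (4.0, 8.0)
    class_amplitude: float = 2.0
    patient_gain_sd: float = 0.4
    patient_freq_jitter_hz: float = 1.0
    noise_sd: float = 1.0
    # patient-level baseline confounds
    background_rhythm_band_hz: tuple[float, float] = (3.5, 12.0)
    background_rhythm_amp: float = 2.5
    noise_level_spread: float = 0.3
    seizure_intensity_spread: float = 0.4
    spike_rate_hz: float = 0.8
    spike_amplitude: float = 3.0
    seed: int = 0

    def validate(self) -> None:
        nyquist = self.sampling_rate_hz / 2.0
        if self.n_patients < 1 or self.n_channels < 1:
            raise ValidationError("patient and channel counts must be positive")
        if self.sampling_rate_hz <= 0 or self.seconds_per_class_per_patient <= 0:
            raise ValidationError("sampling rate and duration must be positive")
        lo, hi = self.class_band_hz
        if not (0 < lo < hi < nyquist):
            raise ValidationError("class band must lie inside (0, Nyquist)")
        if self.class_amplitude < 0 or self.noise_sd < 0:
            raise ValidationError("amplitudes must be non-negative")
        if self.patient_gain_sd < 0 or self.patient_freq_jitter_hz < 0:
            raise ValidationError("spreads must be non-negative")


def _pink_noise(rng: np.random.Generator, n_channels: int, n_samples: int) -> np.ndarray:
    """Gaussian noise with power spectral density ∝ 1/f, unit variance."""
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samples)
    scale = np.empty_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    scale[0] = scale[1]  # keep DC finite
    shaped = np.fft.irfft(spec * scale[None, :], n=n_samples, axis=1)
    shaped /= shaped.std(axis=1, keepdims=True)
    return shaped


def _spike_wave(rng: np.random.Generator, n_samples: int, fs: float, rate_hz: float) -> np.ndarray:
    """Sporadic spike-wave transients: sharp spike followed by a slow wave."""
    out = np.zeros(n_samples)
    width = int(0.06 * fs)  # 60 ms spike
    wave = int(0.2 * fs)  # 200 ms slow wave
    t_spike = np.arange(-width, width)
    spike = np.exp(-0.5 * (t_spike / (width / 3.0)) ** 2)
    t_wave = np.arange(wave)
    slow = -0.5 * np.sin(np.pi * t_wave / wave)
    n_events = rng.poisson(rate_hz * n_samples / fs)
    centers = rng.integers(width, max(width + 1, n_samples - wave - width), size=n_events)
    for c in centers:
        out[c - width : c + width] += spike
        out[c + width : c + width + wave] += slow
    return out


def generate_cohort(spec: SyntheticCohortSpec) -> list[tuple[MultichannelSignal, pd.DataFrame]]:
    """Generate per-patient recordings with exact interval annotations.

    Each recording is the concatenation of ``seconds_per_class_per_patient``
    of normal background followed by the same duration of seizure activity;
    the annotation tiles the recording with two intervals.
    """
    spec.validate()
    ss = np.random.SeedSequence(spec.seed)
    structure_rng, noise_rng = [np.random.default_rng(s) for s in ss.spawn(2)]

    fs = spec.sampling_rate_hz
    n_per_class = int(round(spec.seconds_per_class_per_patient * fs))
    n_total = 2 * n_per_class
    t = np.arange(n_total) / fs
    cohort = []
    for p in range(spec.n_patients):
        # --- patient identity (structure stream) --------------------------
        gains = np.exp(structure_rng.normal(0.0, spec.patient_gain_sd, spec.n_channels))
        f_ictal = structure_rng.uniform(*spec.class_band_hz) + structure_rng.uniform(
            -spec.patient_freq_jitter_hz, spec.patient_freq_jitter_hz
        )
        f_ictal = float(np.clip(f_ictal, 0.5, fs / 2 - 1.0))
        f_bg = structure_rng.uniform(*spec.background_rhythm_band_hz)
        bg_amp = spec.background_rhythm_amp * np.exp(structure_rng.normal(0.0, 0.3))
        noise_mult = np.exp(structure_rng.normal(0.0, spec.noise_level_spread))
        intensity = np.exp(structure_rng.normal(0.0, spec.seizure_intensity_spread))
        phases = structure_rng.uniform(0.0, 2 * np.pi, spec.n_channels)
        topo = structure_rng.uniform(0.6, 1.0, spec.n_channels)  # ictal spatial profile
        spikes = _spike_wave(structure_rng, n_per_class, fs, spec.spike_rate_hz)

        # --- signal assembly ----------------------------------------------
        background = spec.noise_sd * noise_mult * _pink_noise(noise_rng, spec.n_channels, n_total)
        rhythm = bg_amp * np.sin(2 * np.pi * f_bg * t[None, :] + phases[:, None])
        x = background + rhythm

        ictal = intensity * spec.class_amplitude * (
            np.sin(2 * np.pi * f_ictal * t[n_per_class:])
            + 0.5 * np.sin(4 * np.pi * f_ictal * t[n_per_class:])
        )
        ictal = ictal + spec.spike_amplitude * spikes
        x[:, n_per_class:] += topo[:, None] * ictal[None, :]
        x *= gains[:, None]

        patient_id = f"synthetic_{p:02d}"
        signal = MultichannelSignal(
            samples=x,
            sampling_rate_hz=fs,
            channel_names=[f"EEG {c + 1:03d}" for c in range(spec.n_channels)],
            patient_id=patient_id,
        )
        annotation = pd.DataFrame(
            {
                "patient_id": [patient_id, patient_id],
                "start_s": [0.0, spec.seconds_per_class_per_patient],
                "stop_s": [
                    spec.seconds_per_class_per_patient,
                    2 * spec.seconds_per_class_per_patient,
                ],
                "label": ["bckg", "seiz"],
            }
        )
        cohort.append((signal, annotation))
    return cohort


def cohort_to_batches(
    cohort: list[tuple[MultichannelSignal, pd.DataFrame]],
    window_len: int = 250,
    overlap_fraction: float = 0.5,
) -> list[SegmentBatch]:
    """Normalize, window and label every patient's recording.

    Delegates to the segmentation pipeline; patient labels are assigned by
    cohort position (0-based).
    """
    if not cohort:
        raise ValidationError("cohort is empty")
    batches = []
    for p, (signal, annotation) in enumerate(cohort):
        normalized = minmax_normalize(signal)
        batch = segment_signal(normalized, window_len, overlap_fraction)
        mask = annotation_to_mask(annotation, signal.n_samples, signal.sampling_rate_hz)
        batches.append(label_segments(batch, mask, patient_label=p))
    return batches


def write_cohort(
    cohort: list[tuple[MultichannelSignal, pd.DataFrame]],
    out_dir: str | Path,
) -> list[tuple[Path, Path]]:
    """Write EDF files plus interval-annotation CSVs (one pair per patient)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for signal, annotation in cohort:
        edf = write_edf_recording(signal, out_dir / f"{signal.patient_id}.edf")
        csv = write_annotations_csv(annotation, out_dir / f"{signal.patient_id}.csv")
        paths.append((edf, csv))
    return paths
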