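"""Two-class synthetic resting-EEG cohort generator.

Each subject is a 19-channel record whose per-channel background is a
band-limited (0.5-32 Hz) 1/f Gaussian process plus an alpha-band (8-12 Hz)
oscillation with per-channel random amplitude, frequency and phase.  For
class ``ES`` an additional stochastic flat-spectrum (within-band) noise-burst
process is injected into a fixed subset of frontal/central/parietal channels
with amplitude proportional to the effect size ``delta``; this raises the
ordinal complexity of those channels.  ``delta = 0`` makes the two classes
identical in law.

Amplitudes are microvolt scale (background RMS ~= 10 uV).  Everything is
deterministic given the spec seed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np

from .preprocessing import EEGRecording, MONTAGE_19, write_recording_txt

ES = "ES"
PNES = "PNES"
CLASS_LABELS = (ES, PNES)

#: Channels that receive the class-dependent complexity effect.
EFFECT_CHANNELS = ("F3", "F4", "C3", "C4", "P3", "P4")

#: Target per-channel background RMS in microvolts.
BACKGROUND_RMS_UV = 10.0

#: Relative burst amplitude per effect channel (heterogeneous so that the
#: per-channel input-layer effect is graded rather than uniform).
EFFECT_CHANNEL_WEIGHTS = {
    "F3": 1.0, "F4": 1.0, "C3": 0.75, "C4": 0.75, "P3": 0.5, "P4": 0.5,
}

_CONTINUOUS_SECONDS = 1200.0  # 20-minute record in continuous mode


@dataclass(frozen=True)
class CohortSpec:
    """Geometry and effect size of a synthetic cohort."""

    n_subjects_per_class: int = 18
    epochs_per_subject: int = 214
    n_channels: int = 19
    sampling_rate: float = 256.0
    epoch_seconds: float = 2.0
    effect_size: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects_per_class < 1:
            raise ValueError("n_subjects_per_class must be >= 1")
        if self.epochs_per_subject < 1:
            raise ValueError("epochs_per_subject must be >= 1")
        if not 1 <= self.n_channels <= len(MONTAGE_19):
            raise ValueError(f"n_channels must be in 1..{len(MONTAGE_19)}")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        spe = self.epoch_seconds * self.sampling_rate
        if abs(spe - round(spe)) > 1e-9 or round(spe) < 1:
            raise ValueError(
                "epoch_seconds x sampling_rate must be a positive integer"
            )
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")

    @property
    def epoch_samples(self) -> int:
        return int(round(self.epoch_seconds * self.sampling_rate))

    @property
    def channel_names(self) -> Tuple[str, ...]:
        return MONTAGE_19[: self.n_channels]

    @property
    def n_subjects(self) -> int:
        return 2 * self.n_subjects_per_class


def _band_noise(
    rng: np.random.Generator,
    n_channels: int,
    n_samples: int,
    fs: float,
    low: float = 0.5,
    high: float = 32.0,
    alpha: float = 0.0,
) -> np.ndarray:
    """Gaussian noise synthesized in the frequency domain, strictly
    band-limited to [low, high] Hz, spectral amplitude ~ f^(-alpha/2),
    normalized per channel to unit RMS."""
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    shape = np.zeros_like(freqs)
    band = (freqs >= low) & (freqs <= min(high, fs / 2))
    shape[band] = freqs[band] ** (-alpha / 2.0)
    coeffs = (rng.standard_normal((n_channels, freqs.size))
              + 1j * rng.standard_normal((n_channels, freqs.size))) * shape
    x = np.fft.irfft(coeffs, n=n_samples, axis=1)
    rms = np.sqrt(np.mean(x ** 2, axis=1, keepdims=True))
    rms[rms == 0] = 1.0
    return x / rms


def _burst_envelope(
    rng: np.random.Generator, n_samples: int, epoch_samples: int
) -> np.ndarray:
    """0/1 envelope with one burst of random position/length (0.25-1.0 of
    the epoch) inside every consecutive epoch-length block."""
    env = np.zeros(n_samples)
    n_blocks = n_samples // epoch_samples
    frac = rng.uniform(0.25, 1.0, size=n_blocks)
    lengths = np.maximum(1, (frac * epoch_samples).astype(int))
    starts = (rng.random(n_blocks) * (epoch_samples - lengths)).astype(int)
    for b in range(n_blocks):
        s = b * epoch_samples + starts[b]
        env[s : s + lengths[b]] = 1.0
    # remainder shorter than one epoch stays burst-free
    return env


def generate_subject(
    spec: CohortSpec,
    class_label: str,
    subject_seed: int,
    continuous: bool = False,
    artifact_fraction: float = 0.3,
) -> EEGRecording:
    """Generate one subject's recording.

    In the default epoch-ready mode the record is exactly
    ``epochs_per_subject x epoch_seconds`` long with no artifact mask.  In
    ``continuous`` mode a 20-minute record is produced together with a
    random 2-s-aligned artifact mask covering ``artifact_fraction`` of the
    epoch grid, for exercising the preprocessing stage.
    """
    if class_label not in CLASS_LABELS:
        raise ValueError(f"class_label must be one of {CLASS_LABELS}")
    rng = np.random.default_rng(subject_seed)
    fs = spec.sampling_rate
    spe = spec.epoch_samples
    if continuous:
        n_samples = int(round(_CONTINUOUS_SECONDS * fs))
    else:
        n_samples = spec.epochs_per_subject * spe
    n_ch = spec.n_channels

    # 1/f background, unit RMS per channel
    x = _band_noise(rng, n_ch, n_samples, fs, alpha=1.0)

    # alpha-band oscillation with per-channel jitter
    t = np.arange(n_samples) / fs
    f0 = rng.uniform(8.0, 12.0, size=n_ch)
    amp = rng.uniform(0.4, 1.0, size=n_ch)
    phase = rng.uniform(0.0, 2 * np.pi, size=n_ch)
    x += amp[:, None] * np.sin(2 * np.pi * f0[:, None] * t[None, :]
                               + phase[:, None])

    # scale to microvolt range
    rms = np.sqrt(np.mean(x ** 2, axis=1, keepdims=True))
    x *= BACKGROUND_RMS_UV / rms

    # class effect: band-limited white-noise bursts in designated channels
    delta = spec.effect_size
    if class_label == ES and delta > 0:
        names = spec.channel_names
        for ch_name in EFFECT_CHANNELS:
            if ch_name not in names:
                continue
            ci = names.index(ch_name)
            w = EFFECT_CHANNEL_WEIGHTS[ch_name]
            noise = _band_noise(rng, 1, n_samples, fs, alpha=0.0)[0]
            env = _burst_envelope(rng, n_samples, spe)
            x[ci] += delta * w * BACKGROUND_RMS_UV * noise * env

    mask = None
    if continuous:
        n_slots = n_samples // spe
        n_bad = int(round(artifact_fraction * n_slots))
        bad = rng.choice(n_slots, size=n_bad, replace=False)
        mask = np.zeros(n_samples, dtype=bool)
        for b in bad:
            mask[b * spe : (b + 1) * spe] = True
    return EEGRecording(x, fs, spec.channel_names, mask)


def subject_seeds(spec: CohortSpec) -> np.ndarray:
    """Deterministic per-subject seeds derived from the cohort seed
    (order: all ES subjects, then all PNES subjects)."""
    return np.random.SeedSequence(spec.seed).generate_state(
        spec.n_subjects, dtype=np.uint32
    )


def generate_cohort(
    spec: CohortSpec, continuous: bool = False
) -> List[Tuple[str, str, EEGRecording]]:
    """Generate the full balanced cohort as (subject_id, class, recording)."""
    seeds = subject_seeds(spec)
    out: List[Tuple[str, str, EEGRecording]] = []
    k = 0
    for label in (ES, PNES):
        for i in range(spec.n_subjects_per_class):
            sid = f"{label}{i + 1:02d}"
            rec = generate_subject(spec, label, int(seeds[k]),
                                   continuous=continuous)
            out.append((sid, label, rec))
            k += 1
    return out


def write_cohort(
    spec: CohortSpec,
    out_dir: str | Path,
    fmt: str = "txt",
    continuous: bool = False,
) -> Path:
    """Generate and write the cohort plus a ``manifest.csv`` with columns
    (subject_id, class, file, seed).  ``fmt`` is ``txt`` or ``edf``."""
    if fmt not in ("txt", "edf"):
        raise ValueError("fmt must be 'txt' or 'edf'")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seeds = subject_seeds(spec)
    manifest = out_dir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(["subject_id", "class", "file", "seed"])
        k = 0
        for label in (ES, PNES):
            for i in range(spec.n_subjects_per_class):
                sid = f"{label}{i + 1:02d}"
                seed = int(seeds[k])
                rec = generate_subject(spec, label, seed, continuous=continuous)
                fname = f"{sid}.{fmt}"
                if fmt == "txt":
                    write_recording_txt(rec, out_dir / fname)
                else:
                    from .edf import write_edf

                    write_edf(rec, out_dir / fname, patient_id=sid)
                wr.writerow([sid, label, fname, seed])
                k += 1
    return manifest


def read_cohort(manifest: str | Path) -> List[Tuple[str, str, EEGRecording]]:
    """Load a cohort written by :func:`write_cohort`."""
    from .preprocessing import read_recording_txt

    manifest = Path(manifest)
    base = manifest.parent
    out = []
    with open(manifest, newline="") as fh:
        for row in csv.DictReader(fh):
            f = base / row["file"]
            if f.suffix == ".edf":
                from .edf import read_edf

                rec = read_edf(f)
            else:
                rec = read_recording_txt(f)
            out.append((row["subject_id"], row["class"], rec))
    return out
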