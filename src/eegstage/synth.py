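"""Synthetic multi-subject, three-class EEG generator.

The real cohort behind this pipeline is a private clinical archive, so the
package ships a generator that reproduces the *statistical structure* the
pipeline relies on: class-conditional band-power signatures in 0.5-32 Hz,
realistic artifact families (baseline drift below 0.5 Hz, 50 Hz mains,
frontal blink transients, broadband sensor noise), ~5-minute recordings at
256 or 1024 Hz, and per-subject amplitude variation.

Class signatures follow the classic EEG slowing gradient of dementia:
healthy subjects are alpha-dominant (posterior emphasis), mild cognitive
impairment shows elevated theta, and Alzheimer's disease is delta/theta
dominant with attenuated alpha. Band oscillations are synthesized as
band-pass-filtered white noise (not pure sinusoids), so segments are
non-periodic like real EEG. A single lognormal amplitude factor per subject
makes subjects internally coherent — which is exactly what makes the
subject-wise protocol harder than the segment-wise one.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .io import DatasetManifest, ManifestEntry, Recording, save_manifest, write_recording
from .montage import CANONICAL_CHANNELS, FRONTAL, LABELS, N_CHANNELS, POSTERIOR

__all__ = [
    "ClassProfile",
    "ArtifactProfile",
    "SynthSpec",
    "default_profiles",
    "null_profiles",
    "generate_class_signal",
    "inject_artifacts",
    "generate_recording",
    "generate_dataset",
    "save_dataset",
]

#: Canonical EEG rhythm bands (Hz), low edge inclusive.
BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (13.0, 32.0),
}


def _weights(emphasis: dict[str, float], default: float = 1.0) -> np.ndarray:
    w = np.full(N_CHANNELS, default)
    for name, value in emphasis.items():
        w[CANONICAL_CHANNELS.index(name)] = value
    return w


def _posterior_weights(gain: float, rest: float) -> np.ndarray:
    return _weights({ch: gain for ch in POSTERIOR}, default=rest)


def _frontal_weights(gain: float, rest: float) -> np.ndarray:
    return _weights({ch: gain for ch in FRONTAL}, default=rest)


@dataclass(frozen=True)
class ClassProfile:
    """Band-amplitude signature of one diagnostic class.

    ``band_amps`` are relative RMS amplitudes per rhythm band; the emitted
    per-channel band RMS in µV is ``amplitude_uV * band_amps[b] *
    channel_weights[b][ch]`` (times the subject's lognormal gain).
    """

    band_amps: dict[str, float]
    amplitude_uV: float = 10.0
    channel_weights: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.band_amps or min(self.band_amps.values()) < 0:
            raise ValueError("band amplitudes must be non-negative, at least one band")
        if max(self.band_amps.values()) <= 0:
            raise ValueError("at least one band amplitude must be positive")
        unknown = set(self.band_amps) - set(BANDS)
        if unknown:
            raise ValueError(f"unknown band(s): {sorted(unknown)}")

    def weight(self, band: str) -> np.ndarray:
        return self.channel_weights.get(band, np.ones(N_CHANNELS))

    def band_rms(self, band: str) -> np.ndarray:
        """Per-channel RMS amplitude (µV) contributed by one band."""
        return self.amplitude_uV * self.band_amps.get(band, 0.0) * self.weight(band)


@dataclass(frozen=True)
class ArtifactProfile:
    """Amplitudes (µV) and rates of the superimposed artifact families."""

    line_hz: float = 50.0
    line_amp: float = 20.0
    drift_hz: float = 0.2
    drift_amp: float = 50.0
    blink_rate_per_min: float = 12.0
    blink_amp: float = 100.0
    blink_width_s: float = 0.4
    white_noise_sd: float = 3.0

    def __post_init__(self) -> None:
        if not self.drift_hz < 0.5:
            raise ValueError("drift must live below 0.5 Hz")
        if not self.line_hz > 32.0:
            raise ValueError("mains frequency must sit above the 32 Hz pass-band edge")
        for v in (self.line_amp, self.drift_amp, self.blink_rate_per_min,
                  self.blink_amp, self.white_noise_sd):
            if v < 0:
                raise ValueError("artifact amplitudes/rates must be non-negative")

    @property
    def silent(self) -> bool:
        return (
            self.line_amp == 0
            and self.drift_amp == 0
            and self.white_noise_sd == 0
            and (self.blink_amp == 0 or self.blink_rate_per_min == 0)
        )


@dataclass(frozen=True)
class SynthSpec:
    """Dataset-level generation settings (the emulated study conditions)."""

    n_per_class: int = 12
    duration_s: float = 300.0
    rate_cycle: tuple[int, ...] = (256,)  # per-subject sampling rates, cycled
    profiles: dict[str, ClassProfile] | None = None
    artifacts: ArtifactProfile = field(default_factory=ArtifactProfile)
    subject_sigma: float = 0.2  # lognormal sigma of the per-subject gain
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ValueError("need at least one subject per class")
        if self.duration_s < 5:
            raise ValueError("recordings must be at least one window (5 s) long")
        if any(r not in (256, 1024) for r in self.rate_cycle):
            raise ValueError("sampling rates must be 256 or 1024 Hz")


def default_profiles() -> dict[str, ClassProfile]:
    """Separable three-class signatures (dominant band differs per class)."""
    alpha_w = _posterior_weights(1.5, 0.7)
    delta_w = _frontal_weights(1.3, 0.9)
    return {
        "HS": ClassProfile(
            band_amps={"delta": 0.5, "theta": 0.7, "alpha": 3.0, "beta": 0.8},
            channel_weights={"alpha": alpha_w, "delta": delta_w},
        ),
        "MCI": ClassProfile(
            band_amps={"delta": 0.8, "theta": 3.0, "alpha": 1.0, "beta": 0.5},
            channel_weights={"alpha": alpha_w, "delta": delta_w},
        ),
        "AD": ClassProfile(
            band_amps={"delta": 3.0, "theta": 1.2, "alpha": 0.4, "beta": 0.3},
            channel_weights={"alpha": alpha_w, "delta": delta_w},
        ),
    }


def null_profiles() -> dict[str, ClassProfile]:
    """Identical signatures for every class — no class signal by design."""
    flat = ClassProfile(band_amps={"delta": 1.0, "theta": 1.0, "alpha": 1.0, "beta": 1.0})
    return {name: flat for name in LABELS}


def _band_noise(n: int, fs: int, lo: float, hi: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance band-limited noise, one column per channel."""
    # steep edges keep each band's power inside its nominal window, so
    # configured band-amplitude ratios are recoverable from Welch spectra
    sos = butter(8, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = sosfiltfilt(sos, rng.standard_normal((n, N_CHANNELS)), axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    return x / sd


def generate_class_signal(
    profile: ClassProfile,
    duration_s: float,
    fs: int,
    rng: np.random.Generator,
    gain: float = 1.0,
) -> np.ndarray:
    """Clean (artifact-free) class signal, shape (duration*fs, 19), µV."""
    n = int(round(duration_s * fs))
    out = np.zeros((n, N_CHANNELS))
    for band, (lo, hi) in BANDS.items():
        rms = profile.band_rms(band)
        if np.all(rms == 0):
            continue
        out += _band_noise(n, fs, lo, hi, rng) * rms
    return out * gain


def inject_artifacts(rec: Recording, ap: ArtifactProfile, seed: int) -> Recording:
    """Superimpose mains, drift, frontal blinks and sensor noise.

    A zero-amplitude profile returns the input unchanged. Blink transients
    are raised-cosine pulses spatially weighted toward Fp1/Fp2.
    """
    if ap.silent:
        return rec
    rng = np.random.default_rng(seed)
    n, fs = rec.n_samples, rec.fs
    t = np.arange(n) / fs
    data = rec.data.copy()
    if ap.line_amp > 0:
        data += ap.line_amp * np.sin(2 * np.pi * ap.line_hz * t + rng.uniform(0, 2 * np.pi))[
            :, None
        ]
    if ap.drift_amp > 0:
        phases = rng.uniform(0, 2 * np.pi, N_CHANNELS)
        data += ap.drift_amp * np.sin(2 * np.pi * ap.drift_hz * t[:, None] + phases)
    if ap.blink_amp > 0 and ap.blink_rate_per_min > 0:
        blink_w = _frontal_weights(0.3, 0.05)
        for ch in ("Fp1", "Fp2"):
            blink_w[CANONICAL_CHANNELS.index(ch)] = 1.0
        n_blinks = rng.poisson(ap.blink_rate_per_min * rec.duration_s / 60.0)
        width = int(round(ap.blink_width_s * fs))
        pulse = ap.blink_amp * 0.5 * (1 - np.cos(2 * np.pi * np.arange(width) / width))
        for _ in range(n_blinks):
            start = int(rng.integers(0, max(1, n - width)))
            data[start : start + width] += pulse[: n - start, None] * blink_w
    if ap.white_noise_sd > 0:
        data += rng.normal(0.0, ap.white_noise_sd, size=data.shape)
    return rec.with_data(data)


def generate_recording(
    subject_id: str,
    label: str,
    profile: ClassProfile,
    artifacts: ArtifactProfile,
    duration_s: float,
    fs: int,
    seed: int,
    subject_sigma: float = 0.2,
) -> Recording:
    """One subject's raw (artifact-laden) recording, deterministic in seed."""
    rng = np.random.default_rng(seed)
    gain = float(np.exp(rng.normal(0.0, subject_sigma))) if subject_sigma > 0 else 1.0
    clean = generate_class_signal(profile, duration_s, fs, rng, gain=gain)
    rec = Recording(subject_id=subject_id, label=label, fs=fs, data=clean)
    return inject_artifacts(rec, artifacts, seed=int(rng.integers(0, 2**31)))


# Table-style demographics used only as manifest metadata (mean age / SD per
# class, share of male subjects).
_DEMOGRAPHICS = {"HS": (65.6, 7.9, 0.56), "MCI": (74.1, 9.4, 0.46), "AD": (78.4, 6.4, 0.41)}


def generate_dataset(spec: SynthSpec) -> tuple[DatasetManifest, list[Recording]]:
    """Generate the full labelled dataset in memory.

    Returns a manifest (paths filled with conventional file names, not yet
    written — see :func:`save_dataset`) and one Recording per subject.
    Deterministic: identical spec gives identical output.
    """
    profiles = spec.profiles or default_profiles()
    rng = np.random.default_rng(spec.seed)
    entries: list[ManifestEntry] = []
    recordings: list[Recording] = []
    i = 0
    for label in LABELS:
        mean_age, sd_age, male_share = _DEMOGRAPHICS[label]
        for k in range(spec.n_per_class):
            sid = f"{label}{k + 1:02d}"
            fs = spec.rate_cycle[i % len(spec.rate_cycle)]
            rec = generate_recording(
                sid,
                label,
                profiles[label],
                spec.artifacts,
                spec.duration_s,
                fs,
                seed=int(rng.integers(0, 2**31)),
                subject_sigma=spec.subject_sigma,
            )
            age = float(np.clip(rng.normal(mean_age, sd_age), 40, 95))
            sex = "M" if rng.random() < male_share else "F"
            entries.append(
                ManifestEntry(sid, label, round(age, 1), sex, f"{sid}.txt", fs)
            )
            recordings.append(rec)
            i += 1
    return DatasetManifest(entries=entries), recordings


def save_dataset(
    manifest: DatasetManifest,
    recordings: list[Recording],
    out_dir: str | Path,
    dialect: str = "matrix",
) -> Path:
    """Write recordings plus ``manifest.csv`` under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ext = {"matrix": ".txt", "edf": ".edf"}[dialect]
    entries = []
    for entry, rec in zip(manifest.entries, recordings):
        fname = Path(entry.path).stem + ext
        write_recording(rec, out_dir / fname, dialect)
        entries.append(replace(entry, path=fname))
    written = DatasetManifest(entries=entries, root=out_dir)
    return save_manifest(written, out_dir / "manifest.csv")
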