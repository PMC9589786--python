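"""Seeded synthetic signals and meshes with controllable geometry.

Stands in for real recordings: each class is a parametric family of
narrowband carriers / chirps with optional amplitude modulation and
band-limited noise at a stated SNR, so the spectrogram surfaces of different
classes differ in geometry in a known way.  Group identifiers emulate
patients/speakers so grouped train-test splitting is exercised.  Everything
is deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .meshing import TriMesh, build_mesh
from .preprocess import Signal, SpectrogramSurface

__all__ = [
    "ClassSpec",
    "SyntheticSpec",
    "generate_signals",
    "generate_height_field_mesh",
    "height_field_surface",
    "lung_like_spec",
    "speech_like_spec",
]


@dataclass(frozen=True)
class ClassSpec:
    """One synthetic class: a carrier band plus optional chirp/AM/noise."""

    name: str
    carrier_hz: tuple[float, float]  # carrier drawn uniformly from this band
    chirp_rate_hz_per_s: float = 0.0
    am_depth: float = 0.0  # 0 = constant envelope, 1 = full modulation
    am_rate_hz: float = 4.0
    noise_band_hz: tuple[float, float] | None = None  # band of added noise
    snr_db: float = np.inf  # inf = no white noise

    def __post_init__(self) -> None:
        lo, hi = self.carrier_hz
        if not 0 < lo <= hi:
            raise ValueError("carrier band must satisfy 0 < lo <= hi")
        if not 0.0 <= self.am_depth <= 1.0:
            raise ValueError("am_depth must be in [0, 1]")


@dataclass(frozen=True)
class SyntheticSpec:
    """A full synthetic dataset: classes, sizes, grouping, sampling."""

    classes: tuple[ClassSpec, ...]
    n_per_class: int = 20
    groups_per_class: int = 5
    duration_s: float = 1.0
    rate_hz: float = 4000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if self.groups_per_class < 1:
            raise ValueError("groups_per_class must be >= 1")
        if self.duration_s <= 0 or self.rate_hz <= 0:
            raise ValueError("duration and rate must be positive")
        nyq = self.rate_hz / 2
        for c in self.classes:
            f_end = c.carrier_hz[1] + abs(c.chirp_rate_hz_per_s) * self.duration_s
            if f_end >= nyq:
                raise ValueError(
                    f"class {c.name!r} sweeps to {f_end:g} Hz, beyond the "
                    f"Nyquist frequency {nyq:g} Hz"
                )


def _one_signal(cls: ClassSpec, spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    n = int(round(spec.duration_s * spec.rate_hz))
    t = np.arange(n) / spec.rate_hz
    f0 = rng.uniform(*cls.carrier_hz)
    phase = rng.uniform(0, 2 * np.pi)
    inst_freq = f0 + cls.chirp_rate_hz_per_s * t
    x = np.sin(2 * np.pi * np.cumsum(inst_freq) / spec.rate_hz + phase)
    if cls.am_depth > 0:
        am_phase = rng.uniform(0, 2 * np.pi)
        x *= 1.0 - cls.am_depth * 0.5 * (
            1.0 + np.sin(2 * np.pi * cls.am_rate_hz * t + am_phase)
        )
    if cls.noise_band_hz is not None:
        lo, hi = cls.noise_band_hz
        sos = sps.butter(4, [lo, hi], btype="band", fs=spec.rate_hz, output="sos")
        band_noise = sps.sosfiltfilt(sos, rng.standard_normal(n))
        band_noise *= x.std() / max(band_noise.std(), 1e-12)
        x = x + 0.5 * band_noise
    if np.isfinite(cls.snr_db):
        sig_power = float(np.mean(x**2))
        noise_power = sig_power / (10.0 ** (cls.snr_db / 10.0))
        x = x + rng.standard_normal(n) * np.sqrt(noise_power)
    return x


def generate_signals(spec: SyntheticSpec) -> tuple[list[Signal], list[str], list[str]]:
    """Generate the dataset: (signals, class labels, group labels).

    Group ids are assigned round-robin within each class (``<class>_g<k>``),
    so every class has ``groups_per_class`` distinct subjects.  Byte-identical
    output for a fixed spec (seeded).
    """
    rng = np.random.default_rng(spec.seed)
    signals: list[Signal] = []
    labels: list[str] = []
    groups: list[str] = []
    for cls in spec.classes:
        for i in range(spec.n_per_class):
            group = f"{cls.name}_g{i % spec.groups_per_class}"
            sid = f"{cls.name}_{i:03d}"
            samples = _one_signal(cls, spec, rng)
            signals.append(
                Signal(samples=samples, rate=spec.rate_hz, id=sid, group=group)
            )
            labels.append(cls.name)
            groups.append(group)
    return signals, labels, groups


def lung_like_spec(
    n_per_class: int = 20, groups_per_class: int = 5, seed: int = 0
) -> SyntheticSpec:
    """Stock scenario with low-frequency wheeze/crackle surrogates.

    Illustrative stand-ins, not acoustic models of pathology: a narrowband
    'wheeze' tone, a transient broadband 'crackle' class (AM bursts over
    band noise), and a quieter broadband 'normal' class.
    """
    return SyntheticSpec(
        classes=(
            ClassSpec("wheeze", (350.0, 450.0), am_depth=0.3, am_rate_hz=2.0, snr_db=15.0),
            ClassSpec(
                "crackle",
                (80.0, 120.0),
                am_depth=1.0,
                am_rate_hz=9.0,
                noise_band_hz=(500.0, 1200.0),
                snr_db=10.0,
            ),
            ClassSpec("normal", (100.0, 200.0), snr_db=5.0),
        ),
        n_per_class=n_per_class,
        groups_per_class=groups_per_class,
        duration_s=1.0,
        rate_hz=4000.0,
        seed=seed,
    )


def geometry_contrast_spec(
    n_per_class: int = 60, groups_per_class: int = 12, seed: int = 0
) -> SyntheticSpec:
    """Two classes with cleanly contrasting surface geometry.

    A noise-free tone (one sharp spectral ridge over a flat floor) against a
    broadband class (amplitude-modulated carrier plus band noise, rough over
    its whole band).  The distortion signatures of the two are separated by
    several standard deviations, so this is the fixture for end-to-end
    classification checks: it probes the pipeline's discriminative power
    under clean separation, not robustness to noise.
    """
    return SyntheticSpec(
        classes=(
            ClassSpec("tonal", (300.0, 600.0), snr_db=np.inf),
            ClassSpec(
                "broadband",
                (700.0, 900.0),
                am_depth=0.8,
                am_rate_hz=7.0,
                noise_band_hz=(700.0, 1500.0),
                snr_db=5.0,
            ),
        ),
        n_per_class=n_per_class,
        groups_per_class=groups_per_class,
        duration_s=1.0,
        rate_hz=4000.0,
        seed=seed,
    )


def speech_like_spec(
    n_per_class: int = 20, groups_per_class: int = 5, seed: int = 0
) -> SyntheticSpec:
    """Stock scenario with formant-style multi-band chirps."""
    return SyntheticSpec(
        classes=(
            ClassSpec("accent_a", (300.0, 500.0), chirp_rate_hz_per_s=400.0, snr_db=20.0),
            ClassSpec("accent_b", (900.0, 1100.0), chirp_rate_hz_per_s=-300.0, snr_db=20.0),
        ),
        n_per_class=n_per_class,
        groups_per_class=groups_per_class,
        duration_s=1.0,
        rate_hz=4000.0,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Direct mesh fixtures
# ---------------------------------------------------------------------------

def height_field_surface(
    kind: str, N: int, amplitude: float = 1.0, seed: int = 0
) -> SpectrogramSurface:
    """A unit-grid surface with a stated height law (flat / bumps / random)."""
    if N < 2:
        raise ValueError("N must be >= 2")
    ax = np.linspace(0.0, 1.0, N)
    xx, yy = np.meshgrid(ax, ax, indexing="xy")
    if kind == "flat":
        z = np.zeros((N, N))
    elif kind == "gaussian_bumps":
        rng = np.random.default_rng(seed)
        z = np.zeros((N, N))
        for _ in range(3):
            cx, cy = rng.uniform(0.2, 0.8, size=2)
            width = rng.uniform(0.08, 0.2)
            z += amplitude * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * width**2))
    elif kind == "random":
        from scipy.ndimage import gaussian_filter

        rng = np.random.default_rng(seed)
        rough = rng.standard_normal((N, N))
        smooth = gaussian_filter(rough, sigma=max(N / 16.0, 1.0), mode="nearest")
        peak = np.abs(smooth).max()
        z = amplitude * smooth / max(peak, 1e-12)
    else:
        raise ValueError(f"unknown height-field kind {kind!r}")
    return SpectrogramSurface(times=ax, freqs=ax, z=z)


def generate_height_field_mesh(
    kind: str, N: int, amplitude: float = 1.0, seed: int = 0
) -> TriMesh:
    """Grid mesh of a height field; ``kind='flat'`` gives z == 0."""
    return build_mesh(height_field_surface(kind, N, amplitude, seed))
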