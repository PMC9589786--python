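"""Signal conditioning and spectrogram-surface construction.

A mono recording is denoised (Savitzky-Golay smoothing for stethoscope-type
signals, undecimated-wavelet thresholding for speech-type signals) and its
time-frequency magnitude representation is resampled onto a uniform
``grid_n x grid_n`` grid and treated as the graph surface

    S = {(x, y, z(x, y)) : x in X, y in Y},

with x the time axis, y the frequency axis and z the log-magnitude.  Axes are
normalised to the unit cube so that downstream geometric quantities are
comparable across recordings; the normalisation is recorded in
:class:`ScaleMeta`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pywt
from scipy import signal as sps
from scipy.interpolate import RegularGridInterpolator
from scipy.io import wavfile

__all__ = [
    "Signal",
    "SGConfig",
    "StftParams",
    "ScaleMeta",
    "SpectrogramSurface",
    "read_wav",
    "savitzky_golay",
    "modwt_denoise",
    "compute_surface",
    "normalize_surface",
    "mel_filterbank",
    "hz_to_mel",
    "mel_to_hz",
]

_LOG_EPS = 1e-10


@dataclass(frozen=True)
class Signal:
    """A mono audio signal with provenance labels.

    ``group`` carries the patient / speaker identifier used for grouped
    train-test splitting, so recordings of one subject never straddle the
    split.
    """

    samples: np.ndarray
    rate: float
    id: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1:
            raise ValueError("Signal.samples must be one-dimensional")
        if not np.all(np.isfinite(samples)):
            raise ValueError("Signal.samples must be finite")
        if not self.rate > 0:
            raise ValueError("Signal.rate must be positive")
        object.__setattr__(self, "samples", samples)

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def duration(self) -> float:
        return len(self.samples) / self.rate


@dataclass(frozen=True)
class SGConfig:
    """Savitzky-Golay smoothing parameters.

    The window is ``2 * half_window + 1`` samples wide and a least-squares
    polynomial of degree ``degree`` is fitted in each window.  The defaults
    (degree 3, half-window 11) are the values reported to work best for lung
    sounds.
    """

    half_window: int = 11
    degree: int = 3

    def __post_init__(self) -> None:
        if self.half_window < 1:
            raise ValueError("half_window must be >= 1")
        if self.degree < 0:
            raise ValueError("degree must be >= 0")
        if self.degree >= 2 * self.half_window + 1:
            raise ValueError(
                "polynomial degree must be smaller than the window width "
                f"(degree={self.degree}, window={2 * self.half_window + 1})"
            )

    @property
    def window_length(self) -> int:
        return 2 * self.half_window + 1


@dataclass(frozen=True)
class StftParams:
    """Short-time analysis parameters.

    ``nperseg`` is shrunk automatically (powers of two, not below
    ``min_nperseg``) when a recording is too short to yield ``grid_n``
    analysis frames at the requested window length.
    """

    nperseg: int = 256
    overlap: float = 0.75
    window: str = "hann"
    n_mels: int = 64
    min_nperseg: int = 16


@dataclass(frozen=True)
class ScaleMeta:
    """Record of the axis normalisation applied to a surface."""

    time_span: tuple[float, float]
    freq_span: tuple[float, float]
    z_span: tuple[float, float]
    magnitude_transform: str
    alpha: float = 1.0

    def to_json(self) -> str:
        return json.dumps(
            {
                "time_span": list(self.time_span),
                "freq_span": list(self.freq_span),
                "z_span": list(self.z_span),
                "magnitude_transform": self.magnitude_transform,
                "alpha": self.alpha,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "ScaleMeta":
        d = json.loads(text)
        return cls(
            time_span=tuple(d["time_span"]),
            freq_span=tuple(d["freq_span"]),
            z_span=tuple(d["z_span"]),
            magnitude_transform=d["magnitude_transform"],
            alpha=float(d["alpha"]),
        )


@dataclass(frozen=True)
class SpectrogramSurface:
    """The discretised graph z(x, y) over a uniform time x frequency grid.

    After normalisation ``times``/``freqs`` run uniformly over [0, 1] and
    ``z`` lies in [0, alpha].
    """

    times: np.ndarray
    freqs: np.ndarray
    z: np.ndarray
    scale_meta: ScaleMeta = field(
        default_factory=lambda: ScaleMeta((0, 1), (0, 1), (0, 1), "identity", 1.0)
    )

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=np.float64)
        freqs = np.asarray(self.freqs, dtype=np.float64)
        z = np.asarray(self.z, dtype=np.float64)
        if z.shape != (len(freqs), len(times)):
            raise ValueError(
                f"z shape {z.shape} does not match (n_freqs={len(freqs)}, "
                f"n_times={len(times)})"
            )
        for name, ax in (("times", times), ("freqs", freqs)):
            if len(ax) >= 2 and not np.all(np.diff(ax) > 0):
                raise ValueError(f"{name} must be strictly increasing")
        if not np.all(np.isfinite(z)):
            raise ValueError("surface z values must be finite")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "freqs", freqs)
        object.__setattr__(self, "z", z)

    @property
    def grid_n(self) -> int:
        return len(self.times)

    def save_txt(self, path: str) -> None:
        """Plain-text export: z matrix plus a JSON sidecar of scale_meta."""
        header = (
            "times: " + " ".join(f"{t:.12g}" for t in self.times)
            + "\nfreqs: " + " ".join(f"{f:.12g}" for f in self.freqs)
        )
        np.savetxt(path, self.z, header=header)
        with open(str(path) + ".json", "w") as fh:
            fh.write(self.scale_meta.to_json())


def read_wav(path: str, id: str = "", group: str = "") -> Signal:
    """Read a WAV file (PCM 16/24/32-bit or float), mixing stereo to mono."""
    rate, data = wavfile.read(path)
    data = np.asarray(data)
    if data.dtype.kind == "i":
        data = data.astype(np.float64) / float(np.iinfo(data.dtype).max)
    elif data.dtype.kind == "u":  # 8-bit PCM is unsigned
        data = (data.astype(np.float64) - 128.0) / 128.0
    else:
        data = data.astype(np.float64)
    if data.ndim == 2:
        data = data.mean(axis=1)
    return Signal(samples=data, rate=float(rate), id=id or str(path), group=group)


# ---------------------------------------------------------------------------
# Savitzky-Golay smoothing
# ---------------------------------------------------------------------------

def savitzky_golay(signal: Signal, cfg: SGConfig = SGConfig()) -> Signal:
    """Least-squares polynomial smoothing in a sliding window.

    Each output sample is the centre value of the degree-``cfg.degree``
    polynomial fitted over its ``2M+1``-sample window.  At the first/last M
    samples the window is truncated on the signal side (one-sided fit), so
    the output has the same length as the input.
    """
    x = signal.samples
    M, N = cfg.half_window, cfg.degree
    if len(x) < cfg.window_length:
        raise ValueError(
            f"signal of length {len(x)} is shorter than the smoothing window "
            f"({cfg.window_length} samples)"
        )
    out = sps.savgol_filter(x, cfg.window_length, N, mode="interp")
    # Truncated one-sided windows at the edges (scipy's modes fit the last
    # full window instead, which is not the declared policy).
    n = len(x)
    for i in range(M):
        for idx, lo, hi in ((i, 0, i + M + 1), (n - 1 - i, n - i - M - 1, n)):
            w = np.arange(lo, hi)
            coeffs = np.polynomial.polynomial.polyfit(w - idx, x[lo:hi], N)
            out[idx] = coeffs[0]  # polynomial value at the sample itself
    return replace(signal, samples=out)


# ---------------------------------------------------------------------------
# Undecimated wavelet denoising
# ---------------------------------------------------------------------------

_THRESHOLD_RULES = ("universal_soft", "universal_hard", "none")


def modwt_denoise(
    signal: Signal,
    wavelet: str = "sym4",
    levels: int = 4,
    threshold_rule: str = "universal_soft",
) -> Signal:
    """Denoise via the undecimated (maximal-overlap) wavelet transform.

    The signal is decomposed with the shift-invariant stationary wavelet
    transform, detail coefficients are thresholded level-by-level with the
    universal threshold sigma * sqrt(2 log n) (sigma from the median absolute
    deviation of each level's details), and the signal is reconstructed.
    ``threshold_rule='none'`` reconstructs without thresholding
    (perfect-reconstruction mode).
    """
    if wavelet not in pywt.wavelist(kind="discrete"):
        raise ValueError(f"unknown wavelet {wavelet!r}")
    if threshold_rule not in _THRESHOLD_RULES:
        raise ValueError(
            f"unknown threshold_rule {threshold_rule!r}; expected one of "
            f"{_THRESHOLD_RULES}"
        )
    if levels < 1:
        raise ValueError("levels must be >= 1")
    x = signal.samples
    n = len(x)
    block = 2**levels
    if block > n:
        raise ValueError(
            f"{levels} levels need at least {block} samples, got {n}"
        )
    # swt needs a length divisible by 2**levels: symmetric-pad, then crop.
    pad = (-n) % block
    xp = np.pad(x, (0, pad), mode="symmetric") if pad else x
    coeffs = pywt.swt(xp, wavelet, level=levels, norm=True)
    if threshold_rule != "none":
        mode = "soft" if threshold_rule == "universal_soft" else "hard"
        new = []
        for approx, detail in coeffs:
            sigma = np.median(np.abs(detail)) / 0.6745
            thr = sigma * np.sqrt(2.0 * np.log(len(xp)))
            if thr > 0:
                detail = pywt.threshold(detail, thr, mode=mode)
            new.append((approx, detail))
        coeffs = new
    rec = pywt.iswt(coeffs, wavelet, norm=True)
    return replace(signal, samples=np.asarray(rec[:n], dtype=np.float64))


# ---------------------------------------------------------------------------
# Mel scale
# ---------------------------------------------------------------------------

def hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=np.float64) / 700.0)


def mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=np.float64) / 2595.0) - 1.0)


def mel_filterbank(
    n_mels: int, n_fft: int, rate: float, fmin: float = 0.0, fmax: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Triangular mel filterbank.

    Returns ``(weights, centers_hz)`` where ``weights`` is
    ``(n_mels, n_fft // 2 + 1)`` and rows are the overlapping triangles on
    the mel axis.
    """
    if fmax is None:
        fmax = rate / 2.0
    fft_freqs = np.fft.rfftfreq(n_fft, d=1.0 / rate)
    mel_pts = np.linspace(hz_to_mel(fmin), hz_to_mel(fmax), n_mels + 2)
    hz_pts = mel_to_hz(mel_pts)
    weights = np.zeros((n_mels, len(fft_freqs)))
    for i in range(n_mels):
        lo, mid, hi = hz_pts[i], hz_pts[i + 1], hz_pts[i + 2]
        up = (fft_freqs - lo) / max(mid - lo, 1e-12)
        down = (hi - fft_freqs) / max(hi - mid, 1e-12)
        weights[i] = np.clip(np.minimum(up, down), 0.0, None)
    return weights, hz_pts[1:-1]


# ---------------------------------------------------------------------------
# Spectrogram surface
# ---------------------------------------------------------------------------

def _pick_nperseg(n_samples: int, grid_n: int, params: StftParams) -> int:
    """Largest power-of-two window (<= params.nperseg) giving >= grid_n frames."""
    nperseg = params.nperseg
    while nperseg >= params.min_nperseg:
        hop = max(1, int(round(nperseg * (1.0 - params.overlap))))
        n_frames = 1 + (n_samples - nperseg) // hop if n_samples >= nperseg else 0
        if n_frames >= grid_n:
            return nperseg
        nperseg //= 2
    hop = max(1, int(round(params.min_nperseg * (1.0 - params.overlap))))
    min_len = params.min_nperseg + (grid_n - 1) * hop
    raise ValueError(
        f"signal too short for a {grid_n}x{grid_n} surface: need at least "
        f"{min_len} samples, got {n_samples}"
    )


def _magnitude_spectrogram(
    signal: Signal, kind: str, params: StftParams, grid_n: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    nperseg = _pick_nperseg(len(signal), grid_n, params)
    noverlap = int(round(nperseg * params.overlap))
    freqs, times, sxx = sps.spectrogram(
        signal.samples,
        fs=signal.rate,
        window=params.window,
        nperseg=nperseg,
        noverlap=noverlap,
        mode="magnitude",
    )
    if kind == "mel":
        weights, centers = mel_filterbank(params.n_mels, nperseg, signal.rate)
        sxx = weights @ (sxx**2)  # mel-weighted power
        freqs = centers
    elif kind != "stft":
        raise ValueError(f"unknown spectrogram kind {kind!r}; use 'stft' or 'mel'")
    return freqs, times, sxx


def compute_surface(
    signal: Signal,
    kind: str = "stft",
    stft_params: StftParams = StftParams(),
    grid_n: int = 64,
    alpha: float = 1.0,
) -> SpectrogramSurface:
    """Compute the normalised spectrogram surface of a signal.

    The magnitude spectrogram (mel-weighted power for ``kind='mel'``) is
    converted to log10 scale, bilinearly resampled onto a uniform
    ``grid_n x grid_n`` (time x frequency) grid, and each axis is mapped to
    [0, 1]; z is additionally scaled by ``alpha`` (the surface aspect
    factor).  Deterministic for fixed inputs.
    """
    if grid_n < 2:
        raise ValueError("grid_n must be >= 2")
    freqs, times, sxx = _magnitude_spectrogram(signal, kind, stft_params, grid_n)
    logz = np.log10(sxx + _LOG_EPS)

    gt = np.linspace(times[0], times[-1], grid_n)
    gf = np.linspace(freqs[0], freqs[-1], grid_n)
    interp = RegularGridInterpolator(
        (freqs, times), logz, method="linear", bounds_error=False, fill_value=None
    )
    ff, tt = np.meshgrid(gf, gt, indexing="ij")
    zg = interp(np.stack([ff.ravel(), tt.ravel()], axis=1)).reshape(grid_n, grid_n)

    meta = ScaleMeta(
        time_span=(float(gt[0]), float(gt[-1])),
        freq_span=(float(gf[0]), float(gf[-1])),
        z_span=(float(zg.min()), float(zg.max())),
        magnitude_transform=f"log10(magnitude + {_LOG_EPS:g})"
        if kind == "stft"
        else f"log10(mel_power + {_LOG_EPS:g})",
        alpha=alpha,
    )
    surf = SpectrogramSurface(
        times=np.linspace(0.0, 1.0, grid_n),
        freqs=np.linspace(0.0, 1.0, grid_n),
        z=zg,
        scale_meta=meta,
    )
    return normalize_surface(surf, alpha=alpha)


def normalize_surface(surface: SpectrogramSurface, alpha: float = 1.0) -> SpectrogramSurface:
    """Map times/freqs to [0, 1] and z to [0, alpha].

    Constant-z surfaces map to z == 0 (a flat surface).  Idempotent for
    matching ``alpha``: normalising a normalised surface is the identity.
    """

    def _unit(ax: np.ndarray) -> np.ndarray:
        span = ax[-1] - ax[0]
        if span <= 0:
            raise ValueError("axis span must be positive")
        return (ax - ax[0]) / span

    z = surface.z
    zmin, zmax = float(z.min()), float(z.max())
    if zmax - zmin < 1e-12:
        zn = np.zeros_like(z)
    else:
        zn = (z - zmin) / (zmax - zmin) * alpha
    return SpectrogramSurface(
        times=_unit(surface.times),
        freqs=_unit(surface.freqs),
        z=zn,
        scale_meta=replace(surface.scale_meta, alpha=alpha),
    )
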