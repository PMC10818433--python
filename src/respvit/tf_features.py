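"""Time-frequency front-ends for respiratory sound classification.

Four representations of a respiratory cycle are computed here:

* **STFT** magnitude spectrogram — linear frequency scale;
* **MFCC** — Mel filterbank log-energies decorrelated by a DCT (the log-Mel
  spectrogram itself is also exposed);
* **CQT** — constant-Q transform, geometrically spaced bins sharing one
  Q-factor, evaluated directly from windowed complex atoms;
* **cochleogram** — a gammatone filterbank whose centre frequencies follow
  the ERB-rate scale of the human cochlea, framed into per-channel energies.

Each returns a :class:`TFRepresentation` (nonnegative K x L matrix with
frequency and frame-time metadata), which :func:`to_image` converts to an
8-bit RGB raster via dB compression, per-image min-max normalization and the
Viridis colour map — the input format the Vision Transformer consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from matplotlib import colormaps
from scipy import signal as sps
from scipy.optimize import brentq
from skimage.transform import resize as _sk_resize

from .errors import ParameterError

__all__ = [
    "STFTParams", "MelParams", "CQTParams", "GammatoneFilterbank",
    "TFRepresentation", "FeatureImage",
    "stft", "mel_scale", "mel_to_hz", "mel_centre_frequencies",
    "mel_filterbank", "log_mel_spectrogram", "mfcc",
    "cqt", "cqt_frequencies",
    "erb", "gammatone_bandwidth", "erb_rate", "erb_rate_to_hz",
    "design_gammatone_bank", "gammatone_ir", "cochleogram", "to_image",
]


# ---------------------------------------------------------------------------
# containers

@dataclass(frozen=True)
class STFTParams:
    """Analysis window name, length N (samples) and hop J (samples)."""

    window: str = "hann"
    N: int = 336            # 84 ms at 4 kHz, matching the cochleogram frame
    J: int = 168            # 50% overlap

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ParameterError(f"window length N must be >= 2, got {self.N}")
        if not (1 <= self.J <= self.N):
            raise ParameterError(f"hop J must satisfy 1 <= J <= N, got J={self.J}")


@dataclass(frozen=True)
class MelParams:
    """Triangular Mel filterbank geometry and number of retained coefficients."""

    M: int = 64
    fmin: float = 0.0
    fmax: float = 2000.0
    n_mfcc: int | None = None   # defaults to min(20, M)
    log_floor: float = 1e-10

    def __post_init__(self) -> None:
        if self.M < 2:
            raise ParameterError(f"need at least 2 Mel filters, got {self.M}")
        if not (0 <= self.fmin < self.fmax):
            raise ParameterError(f"need 0 <= fmin < fmax, got [{self.fmin}, {self.fmax}]")
        if self.n_mfcc is None:
            object.__setattr__(self, "n_mfcc", min(20, self.M))
        if not (1 <= self.n_mfcc <= self.M):
            raise ParameterError(f"n_mfcc must be in [1, M], got {self.n_mfcc}")


@dataclass(frozen=True)
class CQTParams:
    """Constant-Q geometry: lowest bin frequency f1, bins/octave b, ceiling fmax."""

    f1: float = 100.0
    b: int = 12
    fmax: float = 2000.0
    window: str = "hann"
    hop_s: float = 0.042

    def __post_init__(self) -> None:
        if self.f1 <= 0:
            raise ParameterError(f"f1 must be positive, got {self.f1}")
        if self.b < 1:
            raise ParameterError(f"bins per octave must be >= 1, got {self.b}")
        if self.fmax <= self.f1:
            raise ParameterError(f"fmax must exceed f1, got {self.fmax} <= {self.f1}")


@dataclass
class GammatoneFilterbank:
    """K gammatone channels: centre frequencies, decay bandwidths, order, rate."""

    K: int
    order: int
    fc: np.ndarray          # Hz, strictly increasing
    bandwidth: np.ndarray   # b(fc) in Hz, all positive
    rate: float

    def __post_init__(self) -> None:
        self.fc = np.asarray(self.fc, dtype=np.float64)
        self.bandwidth = np.asarray(self.bandwidth, dtype=np.float64)
        if self.order < 1:
            raise ParameterError(f"filter order must be >= 1, got {self.order}")
        if self.fc.size != self.K or self.bandwidth.size != self.K:
            raise ParameterError("fc/bandwidth length must equal K")
        if np.any(np.diff(self.fc) <= 0):
            raise ParameterError("centre frequencies must be strictly increasing")
        if np.any(self.bandwidth <= 0):
            raise ParameterError("all bandwidths must be positive")


@dataclass
class TFRepresentation:
    """A K x L nonnegative time-frequency matrix with axis metadata.

    ``scale`` records the frequency-axis kind: linear (STFT), mel (log-Mel
    spectrogram), logfreq (CQT), erb (cochleogram) or cepstral (MFCC, where
    ``freqs`` holds coefficient indices and may not be in Hz).
    """

    values: np.ndarray
    freqs: np.ndarray
    frame_times: np.ndarray
    scale: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.freqs = np.asarray(self.freqs, dtype=np.float64)
        self.frame_times = np.asarray(self.frame_times, dtype=np.float64)
        if not np.all(np.isfinite(self.values)):
            raise ParameterError("TF matrix contains non-finite values")
        if self.scale != "cepstral":
            if np.any(self.values < 0):
                raise ParameterError("magnitude/energy TF matrix must be nonnegative")
            if np.any(np.diff(self.freqs) < 0):
                raise ParameterError("frequency axis must be non-decreasing")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class FeatureImage:
    """8-bit RGB raster (H x W x 3) rendered from a TFRepresentation."""

    pixels: np.ndarray
    source_scale: str

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ParameterError(f"pixels must be H x W x 3, got {self.pixels.shape}")
        if self.pixels.dtype != np.uint8:
            raise ParameterError("pixels must be uint8")


# ---------------------------------------------------------------------------
# STFT

def _frame(x: np.ndarray, N: int, J: int) -> np.ndarray:
    """Frames x into overlapping windows of length N, hop J: shape (L, N)."""
    L = 1 + (x.size - N) // J
    idx = np.arange(N)[None, :] + J * np.arange(L)[:, None]
    return x[idx]


def stft(x: np.ndarray, params: STFTParams, fs: float) -> TFRepresentation:
    """Magnitude STFT: |X(k, m)| for the N/2 + 1 non-redundant bins.

    Frame m (0-based) covers samples [m*J, m*J + N); phase is discarded.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.size < params.N:
        raise ParameterError(
            f"signal of {x.size} samples shorter than one frame (N={params.N})"
        )
    w = sps.get_window(params.window, params.N, fftbins=True)
    frames = _frame(x, params.N, params.J)
    spec = np.abs(np.fft.rfft(frames * w, n=params.N, axis=1)).T
    k = np.arange(params.N // 2 + 1)
    freqs = k * fs / params.N
    times = (np.arange(frames.shape[0]) * params.J + params.N / 2) / fs
    return TFRepresentation(spec, freqs, times, "linear")


# ---------------------------------------------------------------------------
# Mel / MFCC

def mel_scale(f):
    """Hz -> Mel: Mel(f) = 1127 ln(1 + f/700)."""
    f = np.asarray(f, dtype=np.float64)
    if np.any(f < 0):
        raise ParameterError("frequency must be nonnegative")
    out = 1127.0 * np.log1p(f / 700.0)
    return float(out) if out.ndim == 0 else out


def mel_to_hz(m):
    """Mel -> Hz, the exact inverse of :func:`mel_scale`."""
    m = np.asarray(m, dtype=np.float64)
    out = 700.0 * np.expm1(m / 1127.0)
    return float(out) if out.ndim == 0 else out


def mel_centre_frequencies(params: MelParams) -> np.ndarray:
    """The M filter peak frequencies: uniform on the Mel scale in [fmin, fmax].

    These are the design centres; on an FFT bin grid each filter peaks at the
    bin nearest its centre.
    """
    edges_mel = np.linspace(mel_scale(params.fmin), mel_scale(params.fmax), params.M + 2)
    return mel_to_hz(edges_mel[1:-1])


def mel_filterbank(fs: float, n_fft: int, params: MelParams) -> np.ndarray:
    """Triangular Mel filterbank evaluated on the rFFT bin grid: (M, K) matrix.

    Filter m rises linearly (in Hz) from edge m to centre m and falls to edge
    m+1, peak height 1; the M+2 edge/centre points are uniformly spaced on the
    Mel scale, so bandwidth grows with frequency.
    """
    if params.fmax > fs / 2:
        raise ParameterError(f"fmax {params.fmax} exceeds Nyquist {fs / 2}")
    K = n_fft // 2 + 1
    bin_freqs = np.arange(K) * fs / n_fft
    pts = mel_to_hz(
        np.linspace(mel_scale(params.fmin), mel_scale(params.fmax), params.M + 2)
    )
    H = np.zeros((params.M, K))
    for m in range(params.M):
        lo, ctr, hi = pts[m], pts[m + 1], pts[m + 2]
        up = (bin_freqs - lo) / (ctr - lo)
        down = (hi - bin_freqs) / (hi - ctr)
        H[m] = np.clip(np.minimum(up, down), 0.0, None)
    if np.any(H.max(axis=1) == 0):
        raise ParameterError(
            f"M={params.M} filters collapse on a {K}-bin grid: adjacent edges "
            "fall inside one bin; reduce M or increase n_fft"
        )
    return H


def log_mel_spectrogram(
    x: np.ndarray, stft_params: STFTParams, mel_params: MelParams, fs: float
) -> TFRepresentation:
    """log filterbank energies S_m per frame: log sum_k |X(k)|^2 H_m(k).

    A floor is applied inside the log so silent frames yield the floor value
    rather than -inf.  Values are shifted so the matrix is nonnegative
    (log energies are otherwise sign-indefinite); the shift is immaterial to
    the per-image normalization applied downstream.
    """
    rep = stft(x, stft_params, fs)
    H = mel_filterbank(fs, stft_params.N, mel_params)
    energies = H @ (rep.values ** 2)
    S = np.log(np.maximum(energies, mel_params.log_floor))
    S = S - np.log(mel_params.log_floor)   # nonnegative by construction
    return TFRepresentation(S, mel_centre_frequencies(mel_params), rep.frame_times, "mel")


def _dct_matrix(n_out: int, M: int) -> np.ndarray:
    """C[n, m] = sqrt(2/M) cos(pi n (m + 1/2) / M)."""
    n = np.arange(n_out)[:, None]
    m = np.arange(M)[None, :]
    return np.sqrt(2.0 / M) * np.cos(np.pi * n * (m + 0.5) / M)


def mfcc(
    x: np.ndarray, stft_params: STFTParams, mel_params: MelParams, fs: float
) -> TFRepresentation:
    """Mel-frequency cepstral coefficients per frame.

    Per frame: power spectrum, Mel filterbank energies, floored log, then
    Y_n = sqrt(2/M) sum_m S_m cos(pi n (m + 1/2) / M); the first ``n_mfcc``
    coefficients are retained.  Frame count equals the STFT frame count.
    """
    rep = stft(x, stft_params, fs)
    H = mel_filterbank(fs, stft_params.N, mel_params)
    energies = H @ (rep.values ** 2)
    S = np.log(np.maximum(energies, mel_params.log_floor))
    C = _dct_matrix(mel_params.n_mfcc, mel_params.M)
    Y = C @ S
    return TFRepresentation(Y, np.arange(mel_params.n_mfcc), rep.frame_times, "cepstral")


# ---------------------------------------------------------------------------
# CQT

def cqt_frequencies(params: CQTParams) -> np.ndarray:
    """Geometric bin centres f_k = f1 * 2^((k-1)/b), k = 1..K, up to fmax."""
    K = int(np.floor(params.b * np.log2(params.fmax / params.f1))) + 1
    k = np.arange(1, K + 1)
    return params.f1 * 2.0 ** ((k - 1) / params.b)


def cqt(x: np.ndarray, params: CQTParams, fs: float) -> TFRepresentation:
    """Constant-Q magnitude transform by direct atom correlation.

    Every bin shares Q = 1 / (2^(1/b) - 1), the ratio of centre frequency to
    the spacing-derived bandwidth, so atom lengths N_k = ceil(Q fs / f_k)
    shrink inversely with frequency.  Atoms are window-weighted complex
    exponentials scaled by 1/N_k, correlated with the signal at a regular hop
    and centred on each frame instant.
    """
    x = np.asarray(x, dtype=np.float64)
    freqs = cqt_frequencies(params)
    if freqs[-1] > fs / 2 + 1e-9:
        raise ParameterError(f"highest CQT bin {freqs[-1]:.1f} Hz exceeds Nyquist {fs / 2}")
    Q = 1.0 / (2.0 ** (1.0 / params.b) - 1.0)
    Nk = np.ceil(Q * fs / freqs).astype(int)
    if Nk[0] > x.size:
        raise ParameterError(
            f"longest atom ({Nk[0]} samples at {freqs[0]:.1f} Hz) exceeds signal "
            f"length {x.size}"
        )
    hop = max(1, round(params.hop_s * fs))
    centers = np.arange(0, x.size, hop)
    out = np.empty((freqs.size, centers.size))
    for ki, (fk, nk) in enumerate(zip(freqs, Nk)):
        w = sps.get_window(params.window, nk, fftbins=True)
        n = np.arange(nk)
        atom = (w / nk) * np.exp(-2j * np.pi * n * fk / fs)
        for ci, c in enumerate(centers):
            i0 = c - nk // 2
            lo, hi = max(i0, 0), min(i0 + nk, x.size)
            seg = np.zeros(nk)
            seg[lo - i0:hi - i0] = x[lo:hi]
            out[ki, ci] = np.abs(seg @ atom)
    return TFRepresentation(out, freqs, centers / fs, "logfreq")


# ---------------------------------------------------------------------------
# gammatone / cochleogram

def erb(fc):
    """Equivalent rectangular bandwidth: ERB(fc) = 24.7 (4.37 fc/1000 + 1) Hz."""
    fc = np.asarray(fc, dtype=np.float64)
    if np.any(fc < 0):
        raise ParameterError("centre frequency must be nonnegative")
    out = 24.7 * (4.37 * fc / 1000.0 + 1.0)
    return float(out) if out.ndim == 0 else out


def gammatone_bandwidth(fc):
    """Gammatone decay bandwidth b(fc) = 1.019 ERB(fc)."""
    out = 1.019 * np.asarray(erb(fc))
    return float(out) if out.ndim == 0 else out


def erb_rate(f):
    """ERB-rate (ERB-number) scale: the integral of 1/ERB from 0 to f.

    E(f) = (1000 / (24.7 * 4.37)) ln(4.37 f / 1000 + 1); uniform steps on this
    scale place one filter per equal number of ERBs, mirroring cochlear
    spacing.
    """
    f = np.asarray(f, dtype=np.float64)
    out = (1000.0 / (24.7 * 4.37)) * np.log1p(4.37 * f / 1000.0)
    return float(out) if out.ndim == 0 else out


def erb_rate_to_hz(e):
    """Inverse of :func:`erb_rate`."""
    e = np.asarray(e, dtype=np.float64)
    out = (1000.0 / 4.37) * np.expm1(e * 24.7 * 4.37 / 1000.0)
    return float(out) if out.ndim == 0 else out


def design_gammatone_bank(
    fs: float,
    K: int = 64,
    fmin: float = 100.0,
    fmax: float | None = None,
    order: int = 4,
    spacing: str = "erb",
) -> GammatoneFilterbank:
    """Design a K-channel gammatone bank between fmin and fmax (default fs/2).

    Centre frequencies are spaced uniformly on the ERB-rate scale (the
    cochlear convention); ``spacing="linear"`` gives uniform Hz spacing
    instead.  Bandwidths follow b(fc) = 1.019 ERB(fc).
    """
    if fmax is None:
        fmax = fs / 2
    if not (0 < fmin < fmax):
        raise ParameterError(f"need 0 < fmin < fmax, got [{fmin}, {fmax}]")
    if fmax > fs / 2:
        raise ParameterError(f"fmax {fmax} exceeds Nyquist {fs / 2}")
    if K < 2:
        raise ParameterError(f"need at least 2 channels, got {K}")
    if spacing == "erb":
        fc = erb_rate_to_hz(np.linspace(erb_rate(fmin), erb_rate(fmax), K))
    elif spacing == "linear":
        fc = np.linspace(fmin, fmax, K)
    else:
        raise ParameterError(f"unknown spacing {spacing!r}")
    # pin endpoints exactly (round-trip through the ERB-rate map is ~1e-13)
    fc[0], fc[-1] = fmin, fmax
    return GammatoneFilterbank(
        K=K, order=order, fc=fc, bandwidth=gammatone_bandwidth(fc), rate=fs
    )


def _envelope_cutoff(order: int, b_fc: float, rel: float = 1e-3) -> float:
    """Time at which the gammatone envelope t^(o-1) e^(-2 pi b t) decays to
    ``rel`` of its peak value."""
    beta = 2.0 * np.pi * b_fc
    if order == 1:
        return -np.log(rel) / beta
    t_peak = (order - 1) / beta

    def env(t: float) -> float:
        return t ** (order - 1) * np.exp(-beta * t)

    peak = env(t_peak)
    t_hi = 2.0 * t_peak
    while env(t_hi) > rel * peak:
        t_hi *= 2.0
    return brentq(lambda t: env(t) - rel * peak, t_peak, t_hi)


def gammatone_ir(
    fc: float,
    order: int,
    b_fc: float,
    fs: float,
    duration: float | None = None,
) -> np.ndarray:
    """Sampled gammatone impulse response, peak-normalized to unit amplitude.

    g(t) = t^(o-1) e^(-2 pi b(fc) t) cos(2 pi fc t).  If ``duration`` is None
    the response is truncated where the envelope falls below 0.1% of its peak,
    which keeps the FIR absolutely summable and deterministic.
    """
    if duration is None:
        duration = _envelope_cutoff(order, b_fc)
    if duration <= 0:
        raise ParameterError(f"duration must be positive, got {duration}")
    t = np.arange(round(duration * fs)) / fs
    g = t ** (order - 1) * np.exp(-2.0 * np.pi * b_fc * t) * np.cos(2.0 * np.pi * fc * t)
    peak = np.max(np.abs(g))
    return g / peak if peak > 0 else g


def cochleogram(
    x: np.ndarray,
    bank: GammatoneFilterbank,
    frame_len: float = 0.084,
    hop: float = 0.042,
) -> TFRepresentation:
    """Gammatone-filterbank energy map C(k, m).

    The signal is convolved with each channel's FIR gammatone response, then
    per frame the Hann-windowed energy sum C(k, m) = sum_n Xhat(k, n)^2 w(n)
    is taken, yielding a nonnegative spectrogram-like matrix on the ERB axis.
    """
    x = np.asarray(x, dtype=np.float64)
    N = round(frame_len * bank.rate)
    J = max(1, round(hop * bank.rate))
    if x.size < N:
        raise ParameterError(f"signal of {x.size} samples shorter than one frame ({N})")
    w = sps.get_window("hann", N, fftbins=True)
    L = 1 + (x.size - N) // J
    out = np.empty((bank.K, L))
    for k in range(bank.K):
        ir = gammatone_ir(bank.fc[k], bank.order, bank.bandwidth[k], bank.rate)
        filtered = sps.fftconvolve(x, ir, mode="full")[: x.size]
        frames = _frame(filtered, N, J)
        out[k] = (frames ** 2) @ w
    # clamp tiny negative round-off from fftconvolve squaring
    np.maximum(out, 0.0, out=out)
    times = (np.arange(L) * J + N / 2) / bank.rate
    return TFRepresentation(out, bank.fc.copy(), times, "erb")


# ---------------------------------------------------------------------------
# image rendering

_VIRIDIS = colormaps["viridis"]


def to_image(rep: TFRepresentation, height: int = 224, width: int = 224) -> FeatureImage:
    """Render a TF matrix as an H x W x 3 Viridis image.

    Pipeline: 10 log10 compression floored 80 dB below the matrix maximum,
    per-image min-max normalization to [0, 1], bilinear resize, re-normalize
    (so the global maximum stays at exactly 1 after interpolation), Viridis
    colour mapping, low frequencies at the bottom row.  The per-image
    normalization makes the result invariant to positive rescaling of the
    input.  For sign-indefinite (cepstral) input the dB step is skipped and
    the raw values are normalized directly.
    """
    if height < 1 or width < 1:
        raise ParameterError(f"image size must be >= 1 px, got {height}x{width}")
    V = rep.values
    if V.size == 0:
        raise ParameterError("empty TF matrix")
    if rep.scale == "cepstral":
        z = V.astype(np.float64)
    else:
        vmax = V.max()
        if vmax <= 0:
            z = np.zeros_like(V, dtype=np.float64)
        else:
            db = 10.0 * np.log10(np.maximum(V, vmax * 1e-12))
            z = np.maximum(db, 10.0 * np.log10(vmax) - 80.0)
    lo, hi = z.min(), z.max()
    z = (z - lo) / (hi - lo) if hi > lo else np.zeros_like(z)
    if z.shape != (height, width):
        z = _sk_resize(z, (height, width), order=1, mode="edge", anti_aliasing=False)
        lo, hi = z.min(), z.max()
        z = (z - lo) / (hi - lo) if hi > lo else np.zeros_like(z)
    rgba = _VIRIDIS(z[::-1, :])           # flip: low frequencies at the bottom
    pixels = np.round(rgba[..., :3] * 255.0).astype(np.uint8)
    return FeatureImage(pixels=pixels, source_scale=rep.scale)
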