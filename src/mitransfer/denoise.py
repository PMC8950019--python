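"""Wavelet band denoising.

Each EEG channel is decomposed with a discrete wavelet transform (default
Daubechies db6, periodized boundary handling) into an approximation band and
``n_levels`` dyadic detail bands, and reconstructed from the rhythm-relevant
bands only.  Periodization keeps the transform orthogonal on signals whose
length is a multiple of 2**n_levels, so band selection is then an exact
orthogonal projection (idempotent, energy-preserving across bands).  For a detail level ``D_k`` the nominal pass band is
``(fs / 2**(k+1), fs / 2**k)`` Hz; the approximation ``A_n`` covers
``(0, fs / 2**(n+1))``.  Denoising here is pure band selection — no
coefficient thresholding — so the operation is linear.

With the default depth rule the retained details straddle the sensorimotor
mu (8-12 Hz) and beta (13-22 Hz) rhythms: at fs=100 Hz a 3-level decomposition
gives bands 0-6.25 / 6.25-12.5 / 12.5-25 / 25-50 Hz and the two middle detail
bands are kept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pywt
from sklearn.base import BaseEstimator, TransformerMixin

from .trials import TrialSet

__all__ = [
    "WaveletConfig",
    "wavelet_decompose",
    "band_reconstruct",
    "denoise_trialset",
    "WaveletDenoiser",
    "auto_levels",
    "levels_for_band",
]

_MODE = "periodization"  # orthogonal on dyadic lengths; part of the format dialect


def auto_levels(fs: float, low_edge: float = 6.5) -> int:
    """Smallest depth whose approximation band falls below ``low_edge`` Hz.

    I.e. the smallest n with fs / 2**(n+1) <= low_edge, so the retained
    details can start near the mu rhythm.  Gives 3 at fs=100, 6 at fs=512.
    """
    n = 1
    while fs / 2 ** (n + 1) > low_edge:
        n += 1
    return n


@dataclass
class WaveletConfig:
    """Wavelet decomposition settings.

    ``retained_levels`` uses names "A<n>" for the approximation and "D<k>"
    (k = 1 shallowest / highest frequency) for details.  When None, the
    default retains every detail band nominally inside ``retain_band``.
    """

    wavelet_name: str = "db6"
    n_levels: int | None = None  # None -> auto from fs
    retained_levels: tuple | None = None
    retain_band: tuple = (6.0, 26.0)
    fs: float = 100.0

    def __post_init__(self) -> None:
        if self.n_levels is None:
            self.n_levels = auto_levels(self.fs)
        if self.n_levels < 1:
            raise ValueError("n_levels must be >= 1")
        valid = set(self.level_names())
        if self.retained_levels is None:
            self.retained_levels = tuple(
                levels_for_band(self, *self.retain_band)
            )
        bad = set(self.retained_levels) - valid
        if bad:
            raise ValueError(f"unknown levels {sorted(bad)}; valid: {sorted(valid)}")

    def level_names(self) -> list:
        return [f"A{self.n_levels}"] + [
            f"D{k}" for k in range(self.n_levels, 0, -1)
        ]

    def nominal_band(self, level: str) -> tuple:
        """Nominal (low, high) frequency band of a level in Hz."""
        if level.startswith("A"):
            return (0.0, self.fs / 2 ** (self.n_levels + 1))
        k = int(level[1:])
        if not 1 <= k <= self.n_levels:
            raise ValueError(f"no level {level} in a {self.n_levels}-level pyramid")
        return (self.fs / 2 ** (k + 1), self.fs / 2 ** k)


def levels_for_band(cfg: WaveletConfig, f_lo: float, f_hi: float) -> list:
    """Detail levels whose nominal band lies inside [f_lo, f_hi]."""
    out = []
    for name in cfg.level_names():
        if name.startswith("A"):
            continue
        lo, hi = cfg.nominal_band(name)
        if lo >= f_lo and hi <= f_hi:
            out.append(name)
    return out


def wavelet_decompose(x: np.ndarray, cfg: WaveletConfig) -> dict:
    """Decompose one channel into a named coefficient pyramid.

    Returns a dict mapping level names ("A<n>", "D<n>", ..., "D1") to
    coefficient arrays.  Raises if the signal is too short for the
    requested depth.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("wavelet_decompose expects a single channel (1D)")
    wavelet = pywt.Wavelet(cfg.wavelet_name)
    max_depth = pywt.dwt_max_level(len(x), wavelet.dec_len)
    if cfg.n_levels > max_depth:
        raise ValueError(
            f"signal of length {len(x)} supports at most {max_depth} "
            f"levels with {cfg.wavelet_name}, requested {cfg.n_levels}"
        )
    coeffs = pywt.wavedec(x, wavelet, mode=_MODE, level=cfg.n_levels)
    names = cfg.level_names()
    pyramid = dict(zip(names, coeffs))
    pyramid["_length"] = len(x)
    pyramid["_cfg"] = cfg
    return pyramid


def band_reconstruct(pyramid: dict, retained_levels=None) -> np.ndarray:
    """Reconstruct the signal from a subset of bands, zeroing the rest."""
    cfg: WaveletConfig = pyramid["_cfg"]
    if retained_levels is None:
        retained_levels = cfg.retained_levels
    retained = set(retained_levels)
    names = cfg.level_names()
    bad = retained - set(names)
    if bad:
        raise ValueError(f"unknown levels {sorted(bad)}; valid: {names}")
    n = pyramid["_length"]
    if not retained:
        warnings.warn("no bands retained; reconstruction is the zero signal")
        return np.zeros(n)
    coeffs = [
        pyramid[name] if name in retained else np.zeros_like(pyramid[name])
        for name in names
    ]
    y = pywt.waverec(coeffs, pywt.Wavelet(cfg.wavelet_name), mode=_MODE)
    return y[:n]


def denoise_channel(x: np.ndarray, cfg: WaveletConfig) -> np.ndarray:
    return band_reconstruct(wavelet_decompose(x, cfg), cfg.retained_levels)


def denoise_trialset(ts: TrialSet, cfg: WaveletConfig) -> TrialSet:
    """Apply band denoising channel-by-channel to every trial.

    Shape, labels and metadata are preserved.  Errors from individual
    channels are annotated with the trial and channel index.
    """
    if ts.trials and cfg.fs != ts.fs:
        raise ValueError(f"config fs={cfg.fs} does not match trial fs={ts.fs}")
    out = []
    for i, t in enumerate(ts.trials):
        data = np.empty_like(t.data)
        for c in range(t.n_channels):
            try:
                data[c] = denoise_channel(t.data[c], cfg)
            except Exception as exc:
                raise type(exc)(f"trial {i}, channel {c}: {exc}") from exc
        out.append(replace(t, data=data))
    return replace(ts, trials=out)


class WaveletDenoiser(TransformerMixin, BaseEstimator):
    """Scikit-learn transformer wrapper around wavelet band denoising.

    Operates on 3D arrays of shape (n_trials, n_channels, n_samples).
    Stateless apart from parameter validation; ``fit`` records the
    configuration actually used.

    Parameters
    ----------
    wavelet : str, default "db6"
    n_levels : int or None
        Decomposition depth; None derives it from ``fs`` so that the
        approximation band falls below the mu rhythm.
    retained_levels : tuple of str or None
        Bands to keep; None keeps details nominally inside ``retain_band``.
    retain_band : (low, high) in Hz, default (6, 26)
    fs : float, sampling rate in Hz
    """

    def __init__(self, wavelet="db6", n_levels=None, retained_levels=None,
                 retain_band=(6.0, 26.0), fs=100.0):
        self.wavelet = wavelet
        self.n_levels = n_levels
        self.retained_levels = retained_levels
        self.retain_band = retain_band
        self.fs = fs

    def _config(self) -> WaveletConfig:
        return WaveletConfig(
            wavelet_name=self.wavelet,
            n_levels=self.n_levels,
            retained_levels=(
                tuple(self.retained_levels)
                if self.retained_levels is not None else None
            ),
            retain_band=tuple(self.retain_band),
            fs=self.fs,
        )

    def fit(self, X, y=None):
        X = np.asarray(X)
        if X.ndim != 3:
            raise ValueError("expected (n_trials, n_channels, n_samples)")
        self.config_ = self._config()
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 3:
            raise ValueError("expected (n_trials, n_channels, n_samples)")
        cfg = getattr(self, "config_", None) or self._config()
        out = np.empty_like(X)
        for i in range(X.shape[0]):
            for c in range(X.shape[1]):
                out[i, c] = denoise_channel(X[i, c], cfg)
        return out
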