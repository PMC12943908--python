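"""Front-end denoising: db4 wavelet thresholding and a five-point local
cubic least-squares smoother.

The smoother fits a cubic ``p(k) = a0 + a1*k + a2*k**2 + a3*k**3`` to each
sliding five-sample window by least squares and takes the fitted value at
the window's centre — a Savitzky–Golay-type filter. Because the window is
symmetric and the odd-degree terms vanish at the centre, the interior
stencil equals the classical ``[-3, 12, 17, 12, -3] / 35`` form. Near the
ends a symmetric window is unavailable, so one-sided five-point fits are
evaluated at the appropriate off-centre offsets instead; all stencils are
derived here from the least-squares problem rather than hard-coded.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pywt

__all__ = [
    "SmootherStencils",
    "WaveletConfig",
    "derive_cubic_stencils",
    "cubic_smooth",
    "wavelet_denoise",
    "denoise_and_smooth",
]


@dataclass(frozen=True)
class SmootherStencils:
    """Fixed convolution stencils of the five-point cubic smoother.

    ``interior`` evaluates the symmetric-window fit at its centre;
    ``boundary_next_to_last`` / ``boundary_last`` evaluate the one-sided
    fit over the final five samples at offsets 3 and 4 (the second-to-last
    and last sample). The start of the signal uses the index-mirrored
    counterparts.
    """

    interior: np.ndarray
    boundary_next_to_last: np.ndarray
    boundary_last: np.ndarray

    @property
    def boundary_first(self) -> np.ndarray:
        return self.boundary_last[::-1]

    @property
    def boundary_second(self) -> np.ndarray:
        return self.boundary_next_to_last[::-1]


def _lsq_eval_row(offsets: np.ndarray, at: float, degree: int = 3) -> np.ndarray:
    """Row vector c with c @ x = value at `at` of the degree-`degree`
    least-squares polynomial fitted to samples x at the given offsets."""
    X = np.vander(np.asarray(offsets, dtype=float), degree + 1, increasing=True)
    # evaluation of fit at `at`: e(at)^T (X^T X)^{-1} X^T x
    e = np.asarray(at, dtype=float) ** np.arange(degree + 1)
    return e @ np.linalg.solve(X.T @ X, X.T)


@lru_cache(maxsize=1)
def derive_cubic_stencils() -> SmootherStencils:
    """Solve the local least-squares problems and return the stencils.

    Each stencil's coefficients sum to 1 (constants are preserved) and the
    interior stencil is symmetric; both follow from the fit.
    """
    interior = _lsq_eval_row(np.arange(-2, 3), 0.0)
    k = np.arange(5)
    return SmootherStencils(
        interior=interior,
        boundary_next_to_last=_lsq_eval_row(k, 3.0),
        boundary_last=_lsq_eval_row(k, 4.0),
    )


def cubic_smooth(signal: np.ndarray) -> np.ndarray:
    """Apply the five-point local cubic smoother; output length == input.

    Interior samples use the symmetric stencil; the last two use the
    one-sided stencils over the final five samples, and the first two use
    their mirrored counterparts. Exact (to rounding) on polynomials of
    degree ≤ 3.
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("signal must be one-dimensional")
    m = len(x)
    if m < 5:
        raise ValueError("need ≥ 5 samples for the five-point smoother")
    st = derive_cubic_stencils()
    y = np.convolve(x, st.interior[::-1], mode="same")
    y[0] = st.boundary_first @ x[:5]
    y[1] = st.boundary_second @ x[:5]
    y[-2] = st.boundary_next_to_last @ x[-5:]
    y[-1] = st.boundary_last @ x[-5:]
    return y


@dataclass
class WaveletConfig:
    """Settings for multilevel wavelet denoising.

    ``levels`` is capped at the maximum admissible depth for the signal
    length and wavelet filter; ``threshold_rule`` selects universal
    soft/hard thresholding of detail coefficients (σ estimated from the
    finest detail level via MAD/0.6745) or ``"none"`` for plain
    decomposition + reconstruction (an identity, up to rounding).

    The default depth of 2 confines thresholding to the detail bands
    above fs/8 (6.25 Hz at the 50 Hz sampling rate) — comfortably above
    the ≤3–4 Hz band where walking's fundamental and low harmonics live —
    so denoising removes broadband noise and heel-strike transients
    without biasing the gait waveform itself.
    """

    wavelet_name: str = "db4"
    levels: int = 2
    threshold_rule: str = "universal_soft"
    padding_mode: str = "symmetric"

    def __post_init__(self) -> None:
        if self.levels < 1:
            raise ValueError("levels must be ≥ 1")
        if self.threshold_rule not in ("universal_soft", "universal_hard", "none"):
            raise ValueError(
                "threshold_rule must be universal_soft, universal_hard or none"
            )


def wavelet_denoise(signal: np.ndarray, cfg: WaveletConfig | None = None) -> np.ndarray:
    """Multilevel wavelet decomposition, detail thresholding, reconstruction.

    Returns a denoised signal of the original length.
    """
    if cfg is None:
        cfg = WaveletConfig()
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("signal must be one-dimensional")
    wavelet = pywt.Wavelet(cfg.wavelet_name)
    if len(x) < wavelet.dec_len:
        raise ValueError(
            f"signal shorter than the {cfg.wavelet_name} filter support "
            f"({wavelet.dec_len} samples)"
        )
    max_level = pywt.dwt_max_level(len(x), wavelet.dec_len)
    levels = min(cfg.levels, max(max_level, 1))
    coeffs = pywt.wavedec(x, wavelet, mode=cfg.padding_mode, level=levels)
    if cfg.threshold_rule != "none":
        finest = coeffs[-1]
        sigma = np.median(np.abs(finest)) / 0.6745
        thr = sigma * np.sqrt(2.0 * np.log(len(x)))
        mode = "soft" if cfg.threshold_rule == "universal_soft" else "hard"
        coeffs = [coeffs[0]] + [
            pywt.threshold(c, thr, mode=mode) for c in coeffs[1:]
        ]
    out = pywt.waverec(coeffs, wavelet, mode=cfg.padding_mode)
    return out[: len(x)]


def denoise_and_smooth(
    signal: np.ndarray,
    wavelet_cfg: WaveletConfig | None = None,
    smoother: bool = True,
) -> np.ndarray:
    """The full preprocessing front end: wavelet denoise, then smooth."""
    out = wavelet_denoise(signal, wavelet_cfg)
    if smoother:
        out = cubic_smooth(out)
    return out
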