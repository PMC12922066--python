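"""Independent brute-force oracles used by the test suite.

These re-derive the transforms from first principles (direct convolution /
decimation, explicit leave-one-out loops, rational ANOVA arithmetic) so the
library implementations are checked against a second, independent route.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np
import pywt


def _symmetric_ext(x: np.ndarray, pad: int) -> np.ndarray:
    """Half-sample symmetric boundary extension by ``pad`` on both sides."""
    return np.concatenate([x[:pad][::-1], x, x[-pad:][::-1]])


def dwt_brute(x: np.ndarray, wavelet: str):
    """Single-level DWT by explicit convolution and dyadic decimation."""
    w = pywt.Wavelet(wavelet)
    F = w.dec_len
    ext = _symmetric_ext(np.asarray(x, float), F - 1)
    cA = np.convolve(ext, w.dec_lo, mode="valid")[1::2]
    cD = np.convolve(ext, w.dec_hi, mode="valid")[1::2]
    return cA, cD


def idwt_brute(cA: np.ndarray, cD: np.ndarray, wavelet: str) -> np.ndarray:
    """Single-level inverse DWT: zero-upsample, convolve, sum, trim."""
    w = pywt.Wavelet(wavelet)
    F = w.dec_len

    def up(c):
        u = np.zeros(2 * len(c))
        u[::2] = c
        return u

    full = np.convolve(up(cA), w.rec_lo, mode="full") + np.convolve(
        up(cD), w.rec_hi, mode="full"
    )
    out_len = 2 * len(cA) - F + 2
    return full[F - 2 : F - 2 + out_len]


def wavedec_brute(x: np.ndarray, wavelet: str, level: int):
    """Multi-level analysis; returns [cA_J, cD_J, ..., cD_1] like wavedec."""
    a = np.asarray(x, float)
    details = []
    for _ in range(level):
        a, d = dwt_brute(a, wavelet)
        details.append(d)
    return [a] + details[::-1]


def waverec_brute(coeffs, wavelet: str) -> np.ndarray:
    """Multi-level synthesis mirroring waverec's length adjustment."""
    a = coeffs[0]
    for d in coeffs[1:]:
        if len(a) > len(d):
            a = a[: len(d)]
        a = idwt_brute(a, d, wavelet)
    return a


def denoise_brute(x: np.ndarray, wavelet: str, level: int) -> np.ndarray:
    """Full denoising chain on the brute-force transform: per-band MAD sigma,
    LSMU threshold, soft shrinkage of details only, reconstruction."""
    x = np.asarray(x, float)
    n = x.size
    coeffs = wavedec_brute(x, wavelet, level)
    out = [coeffs[0]]
    for idx, d in enumerate(coeffs[1:], start=1):
        j = level - idx + 1  # coeffs[1] is the coarsest detail band
        sigma = np.median(np.abs(d - np.median(d))) / 0.6745
        lam = sigma * np.sqrt(2.0 * np.log(n) / np.log2(j + 1))
        out.append(np.sign(d) * np.maximum(np.abs(d) - lam, 0.0))
    return waverec_brute(out, wavelet)[:n]


def loocv_brute(X: np.ndarray, y: np.ndarray, fit_predict) -> float:
    """Explicit leave-one-out RMSE for an arbitrary fit/predict callable."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    residuals = []
    for i in range(y.size):
        keep = [k for k in range(y.size) if k != i]
        pred = fit_predict(X[keep], y[keep], X[i : i + 1])
        residuals.append(y[i] - float(pred))
    return float(np.sqrt(np.mean(np.square(residuals))))


def anova_rational(groups):
    """One-way ANOVA F statistic in exact rational arithmetic."""
    groups = [[Fraction(v).limit_denominator(10**9) for v in g] for g in groups]
    k = len(groups)
    n_total = sum(len(g) for g in groups)
    grand = sum(sum(g) for g in groups) / n_total
    ssb = sum(len(g) * (sum(g) / len(g) - grand) ** 2 for g in groups)
    ssw = sum(
        sum((v - sum(g) / len(g)) ** 2 for v in g) for g in groups
    )
    msb = ssb / (k - 1)
    msw = ssw / (n_total - k)
    return float(msb / msw) if msw != 0 else float("inf")


def pearson_hand(x, y) -> float:
    """Textbook Pearson formula evaluated directly."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xm, ym = x - x.mean(), y - y.mean()
    return float(np.sum(xm * ym) / np.sqrt(np.sum(xm**2) * np.sum(ym**2)))
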