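"""Wavelet soft-threshold despeckling of B-scans.

The pre-processing stage decomposes a B-scan with a 2-level discrete
wavelet transform, estimates a noise threshold

    NT = median(|p|) / alpha

from the coefficient magnitudes, shrinks coefficients by soft
thresholding, and reconstructs the image. With the default
``alpha = 0.6745``, NT coincides with the classical MAD-based estimate of
the noise standard deviation (median(|d|)/0.6745).

Which subbands are shrunk is a policy choice (``band_policy``):

* ``"details"`` (default) — shrink the detail bands LH/HL/HH at every
  level, the standard wavelet-shrinkage denoiser; the approximation band
  keeps the image's DC content.
* ``"low"`` — shrink only the final approximation (low-frequency) band.
* ``"all"`` — shrink every subband.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

BAND_POLICIES = ("details", "low", "all")
THRESHOLD_SCOPES = ("per-image", "per-band")


@dataclass(frozen=True)
class DenoiseConfig:
    alpha: float = 0.6745
    levels: int = 2
    family: str = "haar"
    band_policy: str = "details"
    threshold_scope: str = "per-image"

    def __post_init__(self):
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        if self.band_policy not in BAND_POLICIES:
            raise ValueError(f"band_policy must be one of {BAND_POLICIES}")
        if self.threshold_scope not in THRESHOLD_SCOPES:
            raise ValueError(f"threshold_scope must be one of {THRESHOLD_SCOPES}")


@dataclass
class WaveletPyramid:
    """Multi-level subband set: approximation LL_n plus (LH, HL, HH) per level.

    ``coeffs`` follows the wavedec2 convention:
    ``[LL_n, (LH_n, HL_n, HH_n), ..., (LH_1, HL_1, HH_1)]``.
    """

    coeffs: list
    family: str
    boundary_mode: str

    @property
    def levels(self) -> int:
        return len(self.coeffs) - 1

    @property
    def approx(self) -> np.ndarray:
        return self.coeffs[0]

    def detail_bands(self) -> list[np.ndarray]:
        return [band for triple in self.coeffs[1:] for band in triple]


def decompose(image: np.ndarray, config: DenoiseConfig = DenoiseConfig()) -> WaveletPyramid:
    """Multi-level 2-D DWT of a B-scan."""
    image = np.asarray(image, dtype=np.float64)
    if not np.all(np.isfinite(image)):
        raise ValueError("image must be finite-valued")
    if min(image.shape) < 2**config.levels:
        raise ValueError(
            f"image of shape {image.shape} too small for {config.levels}-level "
            f"decomposition (needs >= {2 ** config.levels} in each dimension)"
        )
    mode = "symmetric"
    coeffs = pywt.wavedec2(image, config.family, mode=mode, level=config.levels)
    return WaveletPyramid(coeffs=list(coeffs), family=config.family, boundary_mode=mode)


def reconstruct(pyramid: WaveletPyramid) -> np.ndarray:
    """Inverse DWT; exact (to float rounding) for orthonormal families."""
    return pywt.waverec2(pyramid.coeffs, pyramid.family, mode=pyramid.boundary_mode)


def noise_threshold(band: np.ndarray, alpha: float) -> float:
    """NT = median(|p_ij|) / alpha over the given coefficients."""
    band = np.asarray(band)
    if band.size == 0:
        raise ValueError("band is empty")
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    return float(np.median(np.abs(band)) / alpha)


def soft_threshold(band: np.ndarray, nt: float) -> np.ndarray:
    """Shrink toward zero: p-NT if p>NT, 0 if |p|<=NT, p+NT if p<-NT."""
    if nt < 0:
        raise ValueError("threshold must be >= 0")
    band = np.asarray(band, dtype=np.float64)
    return np.sign(band) * np.maximum(np.abs(band) - nt, 0.0)


def _selected_bands(pyramid: WaveletPyramid, policy: str):
    """Yield (level_index, band_index) addresses of bands the policy shrinks.

    band_index -1 addresses the approximation; 0..2 address (LH, HL, HH).
    """
    if policy in ("low", "all"):
        yield (0, -1)
    if policy in ("details", "all"):
        for lvl in range(1, len(pyramid.coeffs)):
            for b in range(3):
                yield (lvl, b)


def denoise(image: np.ndarray, config: DenoiseConfig = DenoiseConfig()) -> np.ndarray:
    """Despeckle one B-scan: decompose, threshold, reconstruct.

    ``threshold_scope="per-image"`` pools the selected bands' coefficients
    into a single NT for the image; ``"per-band"`` computes one NT per
    subband. Output is clipped to [0, 1] and cropped to the input shape.
    """
    image = np.asarray(image, dtype=np.float64)
    pyr = decompose(image, config)
    addresses = list(_selected_bands(pyr, config.band_policy))

    def band_at(addr):
        lvl, b = addr
        return pyr.coeffs[lvl] if b == -1 else pyr.coeffs[lvl][b]

    if config.threshold_scope == "per-image":
        pooled = np.concatenate([np.ravel(band_at(a)) for a in addresses])
        nts = {a: noise_threshold(pooled, config.alpha) for a in addresses}
    else:
        nts = {a: noise_threshold(band_at(a), config.alpha) for a in addresses}

    coeffs = [pyr.coeffs[0]] + [list(t) for t in pyr.coeffs[1:]]
    for (lvl, b) in addresses:
        if b == -1:
            coeffs[0] = soft_threshold(coeffs[0], nts[(lvl, b)])
        else:
            coeffs[lvl][b] = soft_threshold(coeffs[lvl][b], nts[(lvl, b)])
    out = pywt.waverec2([coeffs[0]] + [tuple(t) for t in coeffs[1:]],
                        config.family, mode=pyr.boundary_mode)
    out = out[: image.shape[0], : image.shape[1]]
    return np.clip(out, 0.0, 1.0)
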