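"""Synthetic T1-weighted contrast from quantitative T1 maps.

Morphometry software consumes T1-weighted images, so the matched T1 map is
converted to a virtual inversion-recovery contrast

    S = 1 - 2 * exp(-TI / T1),

with the inversion time TI virtually set to 1300 ms.  Proton density is
deliberately excluded so that no bias-field correction is needed downstream.
With white matter T1 shorter than gray matter T1, S_WM > S_GM — the
gray/white contrast segmentation relies on.  The signed signal crosses zero
at T1 = TI / ln 2 (the null point); a magnitude mode folds it to |S|.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SyntheticT1w", "synth_t1w", "DEFAULT_TI_MS"]

DEFAULT_TI_MS = 1300.0


@dataclass(frozen=True)
class SyntheticT1w:
    image: np.ndarray
    ti_ms: float
    signed: bool
    affine: np.ndarray | None = None


def synth_t1w(
    t1_map: np.ndarray,
    ti_ms: float = DEFAULT_TI_MS,
    signed: bool = True,
    affine: np.ndarray | None = None,
) -> SyntheticT1w:
    """Voxelwise S = 1 - 2 exp(-TI/T1); unmatched voxels (T1 = 0) map to 0.

    Signed output lies in (-1, 1]; magnitude output in [0, 1].  S is strictly
    decreasing in T1 at fixed TI (signed mode).
    """
    if ti_ms < 0:
        raise ValueError("inversion time must be non-negative")
    t1 = np.asarray(t1_map, dtype=float)
    if np.any(t1 < 0):
        raise ValueError("t1_map must be non-negative")
    out = np.zeros_like(t1)
    matched = t1 > 0
    with np.errstate(divide="ignore"):
        out[matched] = 1.0 - 2.0 * np.exp(-ti_ms / t1[matched])
    if not signed:
        out = np.abs(out)
    return SyntheticT1w(image=out, ti_ms=float(ti_ms), signed=signed, affine=affine)


def rescale_for_export(image: np.ndarray, out_max: int = 4095) -> np.ndarray:
    """Linear min-max rescale to [0, out_max] for integer NIfTI export."""
    lo, hi = float(np.min(image)), float(np.max(image))
    if hi == lo:
        return np.zeros_like(image)
    return (image - lo) / (hi - lo) * out_max
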