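"""Intensity transforms: raw instrument units -> display/gating scale.

Fluorescence channels are mapped through the inverse hyperbolic sine,
``asinh(x / cofactor)`` — the standard compensated-cytometry display scale:
approximately linear around zero (so negative compensated values are
well-defined) and logarithmic for bright signal.  Scatter channels stay
linear.  Every downstream gate is a threshold on this scale, and because the
transform is strictly increasing, event ranks — hence all rank-based
statistics — are unchanged by it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ParameterError

__all__ = ["TransformConfig", "asinh_scale", "inverse_asinh_scale", "scale_marker"]

#: Markers left on the linear (scatter) scale.
SCATTER_MARKERS = ("FSC", "SSC")


@dataclass
class TransformConfig:
    """Display-scale settings.

    cofactor
        Divisor applied before asinh on every fluorescence channel.  150 is
        a conventional choice for conventional-cytometer fluorescence; the
        trough-based gates only require a monotone scale, so the exact value
        is not critical.
    scatter_passthrough
        Keep FSC/SSC linear (default).
    """

    cofactor: float = 150.0
    scatter_passthrough: bool = True

    def __post_init__(self) -> None:
        if not self.cofactor > 0:
            raise ParameterError("cofactor must be positive")

    def to_config_dict(self) -> dict[str, str]:
        return {
            "transform.cofactor": str(self.cofactor),
            "transform.scatter_passthrough": str(self.scatter_passthrough).lower(),
        }


def asinh_scale(x, cofactor: float = 150.0):
    """arcsinh display scale: ``asinh(x / cofactor)``; odd, strictly increasing."""
    if not cofactor > 0:
        raise ParameterError("cofactor must be positive")
    return np.arcsinh(np.asarray(x, dtype=np.float64) / cofactor)


def inverse_asinh_scale(y, cofactor: float = 150.0):
    """Exact functional inverse of :func:`asinh_scale`: ``sinh(y) * cofactor``."""
    if not cofactor > 0:
        raise ParameterError("cofactor must be positive")
    return np.sinh(np.asarray(y, dtype=np.float64)) * cofactor


def scale_marker(values, marker: str, cfg: TransformConfig | None = None):
    """Scale one marker's raw intensities for gating.

    Scatter markers pass through linearly (by default); fluorescence markers
    go through :func:`asinh_scale` with the configured cofactor.
    """
    cfg = cfg or TransformConfig()
    if marker.upper() in SCATTER_MARKERS and cfg.scatter_passthrough:
        return np.asarray(values, dtype=np.float64)
    return asinh_scale(values, cfg.cofactor)
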