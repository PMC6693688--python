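"""Beer–Lambert starlight attenuation.

Downwelling irradiance decays exponentially with depth, T = exp(−k·z), with
k the absorption coefficient (per metre). Defaults are k = 0.0562 m⁻¹ for
non-turbid ocean water at 550 nm and a surface starlight irradiance of
1.46×10⁻¹⁰ W/cm² (0.0002 lux).

``irradiance_at_depth`` deliberately takes the transmittance as an explicit
input rather than computing it, so tabulated transmittance fractions from
other sources can be combined with a surface value directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidConfigError

__all__ = ["AttenuationModel", "transmittance", "irradiance_at_depth"]

DEFAULT_ABSORPTION_K = 0.0562  # 1/m, clear ocean water at 550 nm
DEFAULT_SURFACE_STARLIGHT = 1.46e-10  # W/cm^2 (0.0002 lux)


def transmittance(k: float, depth: float) -> float:
    """Fraction of surface irradiance reaching ``depth`` m: exp(−k·depth)."""
    if k < 0:
        raise InvalidConfigError("absorption coefficient must be >= 0")
    if depth < 0:
        raise InvalidConfigError("depth must be >= 0")
    return float(np.exp(-k * depth))


def irradiance_at_depth(surface: float, T: float) -> float:
    """Irradiance at depth given surface irradiance and a transmittance
    fraction T in [0, 1]."""
    if surface < 0:
        raise InvalidConfigError("surface irradiance must be >= 0")
    if not (0.0 <= T <= 1.0):
        raise InvalidConfigError("transmittance must be in [0, 1]")
    return float(surface * T)


@dataclass(frozen=True)
class AttenuationModel:
    absorption_k: float = DEFAULT_ABSORPTION_K
    surface_irradiance: float = DEFAULT_SURFACE_STARLIGHT

    def __post_init__(self) -> None:
        if self.absorption_k < 0 or self.surface_irradiance < 0:
            raise InvalidConfigError("model parameters must be >= 0")

    def transmittance(self, depth: float) -> float:
        return transmittance(self.absorption_k, depth)

    def irradiance(self, depth: float) -> float:
        return irradiance_at_depth(self.surface_irradiance, self.transmittance(depth))
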