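"""Two-stage generative model of visually guided size responses.

The model assumes a response (grip aperture or manual size estimate) is
produced in two stages:

1. A visual stage yields a noisy size estimate ``s_hat = s + eps_v`` where
   the visual noise obeys Weber's law: ``eps_v ~ N(0, (weber_v * s)**2)``.
2. A motor stage maps the estimate linearly into a response and adds
   implementation noise: ``GA* = k * s_hat + overshoot + eps_m`` with
   ``eps_m ~ N(0, sigma_impl**2)``.

Because the two noise sources are independent, the response SD has the
closed form ``sqrt((k * weber_v * s)**2 + sigma_impl**2)`` and the response
mean is ``k * s + overshoot``.  The apparent Weber fraction measured from
responses therefore depends on the motor mapping, not only on the visual
noise: a shallow slope ``k`` together with a large ``sigma_impl`` can hide
Weber scaling that is fully present at the visual stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .errors import InvalidParameterError

__all__ = [
    "TwoStageParams",
    "StimulusSet",
    "STANDARD_SIZES",
    "GRASP_PARAMS",
    "ESTIMATE_PARAMS",
    "DEFAULT_VISUAL_WEBER",
    "visual_estimate",
    "motor_response",
    "simulate_responses",
    "predicted_mean",
    "predicted_sd",
]


@dataclass(frozen=True)
class TwoStageParams:
    """Generative parameters for one response condition.

    Parameters
    ----------
    k : float
        Dimensionless slope of the motor mapping (response change per mm of
        estimated size).
    overshoot : float
        Intercept of the motor mapping, in mm.  For grasps this is the
        safety margin by which the aperture exceeds the object.
    sigma_impl : float
        SD of the implementation (motor execution) noise, in mm.
    weber_v : float
        Visual Weber fraction: the SD of the visual size estimate is
        ``weber_v * s``.
    """

    k: float
    overshoot: float
    sigma_impl: float
    weber_v: float

    def __post_init__(self) -> None:
        for name in ("k", "overshoot", "sigma_impl", "weber_v"):
            value = getattr(self, name)
            if not math.isfinite(float(value)):
                raise InvalidParameterError(f"{name} must be finite, got {value!r}")
        if self.sigma_impl < 0:
            raise InvalidParameterError(f"sigma_impl must be >= 0, got {self.sigma_impl}")
        if self.weber_v < 0:
            raise InvalidParameterError(f"weber_v must be >= 0, got {self.weber_v}")

    def to_json(self) -> dict:
        return {
            "k": self.k,
            "overshoot_mm": self.overshoot,
            "sigma_impl_mm": self.sigma_impl,
            "weber_v": self.weber_v,
        }

    @classmethod
    def from_json(cls, obj: Mapping) -> "TwoStageParams":
        try:
            return cls(
                k=float(obj["k"]),
                overshoot=float(obj["overshoot_mm"]),
                sigma_impl=float(obj["sigma_impl_mm"]),
                weber_v=float(obj["weber_v"]),
            )
        except KeyError as exc:
            raise InvalidParameterError(f"missing parameter field: {exc}") from exc


@dataclass(frozen=True)
class StimulusSet:
    """Ordered set of object sizes (mm) presented in an experiment."""

    sizes: tuple

    def __post_init__(self) -> None:
        sizes = tuple(float(s) for s in self.sizes)
        object.__setattr__(self, "sizes", sizes)
        if len(sizes) == 0:
            raise InvalidParameterError("stimulus set must contain at least one size")
        if any(not math.isfinite(s) or s <= 0 for s in sizes):
            raise InvalidParameterError(f"all sizes must be finite and > 0, got {sizes}")

    def __len__(self) -> int:
        return len(self.sizes)

    def __iter__(self):
        return iter(self.sizes)

    @property
    def n_distinct(self) -> int:
        return len(set(self.sizes))


#: The four object heights used throughout the experiments, in mm.
STANDARD_SIZES = StimulusSet((21.0, 28.0, 35.0, 42.0))

#: Shared visual Weber fraction assumed for both response modes.
DEFAULT_VISUAL_WEBER = 0.06

#: Grasping (maximum grip aperture) parameterization: compressed mapping
#: slope, large safety margin, large implementation noise.
GRASP_PARAMS = TwoStageParams(k=0.7, overshoot=18.0, sigma_impl=6.0, weber_v=DEFAULT_VISUAL_WEBER)

#: Manual size estimation parameterization: unity slope, small overshoot,
#: small implementation noise.
ESTIMATE_PARAMS = TwoStageParams(k=1.0, overshoot=4.0, sigma_impl=2.0, weber_v=DEFAULT_VISUAL_WEBER)


def _check_sizes(s: np.ndarray) -> np.ndarray:
    s = np.asarray(s, dtype=float)
    if not np.all(np.isfinite(s)):
        raise InvalidParameterError("object size must be finite")
    if np.any(s < 0):
        raise InvalidParameterError("object size must be >= 0")
    return s


def visual_estimate(s, weber_v: float, rng: np.random.Generator):
    """Draw a noisy visual size estimate ``s_hat``.

    The estimate is unbiased with SD proportional to size (Weber scaling):
    ``s_hat = s + N(0, (weber_v * s)**2)``.  Accepts scalar or array ``s``.
    """
    s = _check_sizes(s)
    if not math.isfinite(float(weber_v)) or weber_v < 0:
        raise InvalidParameterError(f"weber_v must be finite and >= 0, got {weber_v}")
    noise = rng.normal(0.0, 1.0, size=s.shape) * (weber_v * s)
    out = s + noise
    return out if out.shape else float(out)


def motor_response(s_hat, params: TwoStageParams, rng: np.random.Generator):
    """Map a visual estimate through the motor stage.

    Returns ``k * s_hat + overshoot + N(0, sigma_impl**2)``.
    """
    s_hat = np.asarray(s_hat, dtype=float)
    if not np.all(np.isfinite(s_hat)):
        raise InvalidParameterError("visual estimate must be finite")
    noise = rng.normal(0.0, 1.0, size=s_hat.shape) * params.sigma_impl
    out = params.k * s_hat + params.overshoot + noise
    return out if out.shape else float(out)


def simulate_responses(s, params: TwoStageParams, rng: np.random.Generator):
    """Full two-stage draw: visual estimate followed by motor mapping."""
    return motor_response(visual_estimate(s, params.weber_v, rng), params, rng)


def predicted_mean(s, params: TwoStageParams):
    """Expected response at size ``s``: ``k * s + overshoot``."""
    s = _check_sizes(s)
    out = params.k * s + params.overshoot
    return out if out.shape else float(out)


def predicted_sd(s, params: TwoStageParams):
    """Closed-form response SD at size ``s``.

    Visual noise propagated through the mapping slope and implementation
    noise add in quadrature: ``sqrt((k * weber_v * s)**2 + sigma_impl**2)``.
    """
    s = _check_sizes(s)
    out = np.sqrt((params.k * params.weber_v * s) ** 2 + params.sigma_impl**2)
    return out if out.shape else float(out)
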