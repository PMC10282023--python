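"""Samplers for the three circular families used in the power study.

* von Mises VM(mu, kappa) — the canonical unimodal symmetric circular
  distribution; kappa = 0 gives the circular uniform.
* axial von Mises — an equal mixture of VM(mu, kappa) and VM(mu + pi, kappa),
  i.e. two antipodal modes with a common concentration.
* wrapped skew-normal WSN(xi, rho, alpha) — a skew-normal variable
  xi + rho * Z reduced mod 2 pi, with Z standard skew-normal of shape alpha
  (alpha = 0 symmetric; larger |alpha| means stronger skew).

All samplers return an :class:`~circart.core.AngleSample` on [0, 2 pi) and
are deterministic given a numpy ``Generator`` (or integer seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
from scipy import stats as _sps

from .core import AngleSample, TWO_PI

__all__ = [
    "DistributionSpec",
    "von_mises",
    "axial_von_mises",
    "wrapped_skew_normal",
    "sample_von_mises",
    "sample_axial_von_mises",
    "sample_wrapped_skew_normal",
    "sample",
]

FAMILIES = ("von_mises", "axial_von_mises", "wrapped_skew_normal")

RngLike = Union[int, np.random.Generator, np.random.SeedSequence, None]


def _as_rng(rng_state: RngLike) -> np.random.Generator:
    if isinstance(rng_state, np.random.Generator):
        return rng_state
    return np.random.default_rng(rng_state)


@dataclass(frozen=True)
class DistributionSpec:
    """One of the three generative families with its parameters.

    Only the parameters relevant to the family are set: ``mu``/``kappa`` for
    the (axial) von Mises families, ``xi``/``rho``/``alpha`` for the wrapped
    skew-normal.  Angles are radians.
    """

    family: str
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; valid: {FAMILIES}")
        required = {
            "von_mises": {"mu", "kappa"},
            "axial_von_mises": {"mu", "kappa"},
            "wrapped_skew_normal": {"xi", "rho", "alpha"},
        }[self.family]
        got = set(self.params)
        if got != required:
            raise ValueError(
                f"family {self.family!r} takes parameters {sorted(required)}, got {sorted(got)}"
            )
        if self.family in ("von_mises", "axial_von_mises") and self.params["kappa"] < 0:
            raise ValueError(f"kappa must be >= 0, got {self.params['kappa']}")
        if self.family == "wrapped_skew_normal" and self.params["rho"] <= 0:
            raise ValueError(f"rho must be > 0, got {self.params['rho']}")

    def sample(self, size: int, rng_state: RngLike = None) -> AngleSample:
        return sample(self, size, rng_state)

    def describe(self) -> str:
        ps = ", ".join(f"{k}={v:g}" for k, v in sorted(self.params.items()))
        return f"{self.family}({ps})"


def von_mises(mu: float, kappa: float) -> DistributionSpec:
    """Spec for VM(mu, kappa)."""
    return DistributionSpec("von_mises", {"mu": float(mu), "kappa": float(kappa)})


def axial_von_mises(mu: float, kappa: float) -> DistributionSpec:
    """Spec for the equal mixture of VM(mu, kappa) and VM(mu + pi, kappa)."""
    return DistributionSpec("axial_von_mises", {"mu": float(mu), "kappa": float(kappa)})


def wrapped_skew_normal(xi: float, rho: float, alpha: float) -> DistributionSpec:
    """Spec for the wrapped skew-normal with location xi, scale rho, shape alpha."""
    return DistributionSpec(
        "wrapped_skew_normal", {"xi": float(xi), "rho": float(rho), "alpha": float(alpha)}
    )


def _check_size(size: int) -> None:
    if size < 1:
        raise ValueError(f"size must be >= 1, got {size}")


def sample_von_mises(mu: float, kappa: float, size: int, rng_state: RngLike = None) -> AngleSample:
    """Draw ``size`` independent angles from VM(mu, kappa).

    Uses the exact Best-Fisher rejection sampler; kappa = 0 short-circuits to
    the exact circular uniform.
    """
    if kappa < 0:
        raise ValueError(f"kappa must be >= 0, got {kappa}")
    _check_size(size)
    rng = _as_rng(rng_state)
    if kappa == 0:
        return AngleSample(rng.uniform(0.0, TWO_PI, size))
    return AngleSample(rng.vonmises(mu, kappa, size))


def sample_axial_von_mises(mu: float, kappa: float, size: int, rng_state: RngLike = None) -> AngleSample:
    """Draw from the axial mixture: each angle from VM(mu, kappa) or
    VM(mu + pi, kappa) with probability 1/2."""
    if kappa < 0:
        raise ValueError(f"kappa must be >= 0, got {kappa}")
    _check_size(size)
    rng = _as_rng(rng_state)
    if kappa == 0:
        return AngleSample(rng.uniform(0.0, TWO_PI, size))
    base = rng.vonmises(mu, kappa, size)
    flip = rng.random(size) < 0.5
    return AngleSample(base + np.where(flip, np.pi, 0.0))


def sample_wrapped_skew_normal(
    xi: float, rho: float, alpha: float, size: int, rng_state: RngLike = None
) -> AngleSample:
    """Draw from the wrapped skew-normal: (xi + rho * Z) mod 2 pi with Z
    standard skew-normal of shape alpha (Azzalini convolution form)."""
    if rho <= 0:
        raise ValueError(f"rho must be > 0, got {rho}")
    _check_size(size)
    rng = _as_rng(rng_state)
    z = _sps.skewnorm.rvs(alpha, size=size, random_state=rng)
    return AngleSample(xi + rho * z)


def sample(spec: DistributionSpec, size: int, rng_state: RngLike = None) -> AngleSample:
    """Draw ``size`` angles from the family named by ``spec``."""
    p = spec.params
    if spec.family == "von_mises":
        return sample_von_mises(p["mu"], p["kappa"], size, rng_state)
    if spec.family == "axial_von_mises":
        return sample_axial_von_mises(p["mu"], p["kappa"], size, rng_state)
    return sample_wrapped_skew_normal(p["xi"], p["rho"], p["alpha"], size, rng_state)
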