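"""Local and global friction coefficients.

Local friction treats elongation/shortening of the helix by one hydrogen
bond as 1-D Brownian motion with step length delta and waiting time tau:
D = delta^2 / (2 tau) and gamma = kB T / D.  Global friction combines the
folding rate with the accumulated squared end-to-end increments:
gamma_G = kB T / (k_fold * sum_i dx_i^2).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "KB_J_PER_K",
    "PhysicalConstants",
    "FrictionValue",
    "local_friction",
    "delta_conversion_factor",
    "global_friction",
    "round_sig",
]

#: Boltzmann constant, exact SI value (J/K).
KB_J_PER_K = 1.380649e-23

NM = 1.0e-9
PS = 1.0e-12
PER_US = 1.0e6
KG_S_PER_NG_S = 1.0e-12
KG_S_PER_UG_S = 1.0e-9


@dataclass(frozen=True)
class PhysicalConstants:
    """Thermodynamic inputs for the friction formulas.

    ``delta`` is the helix elongation per added bond, defaulting to the
    helix rise per residue (0.15 nm); ``delta_alt`` is the alternative
    cooperative-formation displacement convention (0.34 nm) whose squared
    ratio converts between the two reporting conventions.
    """

    kB: float = KB_J_PER_K
    T: float = 300.0
    delta: float = 0.15  # nm
    delta_alt: float = 0.34  # nm

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError("T must be positive")
        if self.delta <= 0 or self.delta_alt <= 0:
            raise ValueError("delta values must be positive")


DEFAULT_CONSTANTS = PhysicalConstants()


@dataclass
class FrictionValue:
    """A friction coefficient in SI units with reporting helpers."""

    value: float  # kg/s
    kind: str  # "local" | "global"
    error: float = 0.0  # kg/s
    scale_hint: str = "ng/s"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.value < 0 or self.error < 0:
            raise ValueError("friction value and error must be nonnegative")

    @property
    def ng_per_s(self) -> float:
        return self.value / KG_S_PER_NG_S

    @property
    def ug_per_s(self) -> float:
        return self.value / KG_S_PER_UG_S

    @property
    def error_ng_per_s(self) -> float:
        return self.error / KG_S_PER_NG_S

    @property
    def error_ug_per_s(self) -> float:
        return self.error / KG_S_PER_UG_S


def local_friction(
    tau_ps: float,
    consts: PhysicalConstants = DEFAULT_CONSTANTS,
    tau_err_ps: float = 0.0,
) -> FrictionValue:
    """Local friction from the Einstein relation.

    D = delta^2 / (2 tau), gamma = kB T / D = 2 kB T tau / delta^2.
    The error is propagated linearly from ``tau_err_ps``.
    """
    if tau_ps <= 0:
        raise ValueError("tau must be positive")
    if tau_err_ps < 0:
        raise ValueError("tau error must be nonnegative")
    tau_s = tau_ps * PS
    delta_m = consts.delta * NM
    diffusion = delta_m**2 / (2.0 * tau_s)
    gamma = consts.kB * consts.T / diffusion
    return FrictionValue(
        value=gamma,
        kind="local",
        error=gamma * (tau_err_ps / tau_ps),
        scale_hint="ng/s",
        provenance={
            "tau_ps": tau_ps,
            "delta_nm": consts.delta,
            "T_K": consts.T,
            "D_m2_s": diffusion,
        },
    )


def delta_conversion_factor(consts: PhysicalConstants = DEFAULT_CONSTANTS) -> float:
    """Factor (delta_alt/delta)^2 converting local friction between the two
    delta conventions (5.14 for 0.34 nm vs 0.15 nm, to 3 significant
    figures)."""
    return (consts.delta_alt / consts.delta) ** 2


def global_friction(
    k_fold_per_us: float,
    delta_x_sq_total_nm2: float,
    consts: PhysicalConstants = DEFAULT_CONSTANTS,
    k_fold_err_per_us: float = 0.0,
    delta_x_sq_err_nm2: float = 0.0,
) -> FrictionValue:
    """Global friction gamma_G = kB T / (k_fold * sum_i dx_i^2).

    ``k_fold`` in 1/us and the squared-increment total in nm^2; the result
    is in kg/s (reported in ug/s).  Errors combine by the complete
    differential rule.
    """
    if k_fold_per_us <= 0:
        raise ValueError("k_fold must be positive")
    if delta_x_sq_total_nm2 <= 0:
        raise ValueError("delta_x_sq_total must be positive")
    k_s = k_fold_per_us * PER_US
    dx2_m2 = delta_x_sq_total_nm2 * NM**2
    gamma = consts.kB * consts.T / (k_s * dx2_m2)
    rel_err = 0.0
    if k_fold_err_per_us:
        rel_err += k_fold_err_per_us / k_fold_per_us
    if delta_x_sq_err_nm2:
        rel_err += delta_x_sq_err_nm2 / delta_x_sq_total_nm2
    return FrictionValue(
        value=gamma,
        kind="global",
        error=gamma * rel_err,
        scale_hint="ug/s",
        provenance={
            "k_fold_per_us": k_fold_per_us,
            "delta_x_sq_total_nm2": delta_x_sq_total_nm2,
            "T_K": consts.T,
        },
    )


def round_sig(x: float, n_digits: int = 3) -> float:
    """Round to ``n_digits`` significant figures (report convention)."""
    if x == 0 or not np.isfinite(x):
        return x
    mag = int(np.floor(np.log10(abs(x))))
    return round(x, n_digits - 1 - mag)
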