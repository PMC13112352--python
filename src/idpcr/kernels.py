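"""Gaussian-chain averages of the screened Coulomb interaction.

Both coupling matrices of the variational equations are averages of the
Debye–Hückel potential over the Gaussian trial ensemble, in which the vector
between residues m and n has variance |m−n|·l·l_r (l_r = x·l).  With
μ = |m−n| and u = κl·sqrt(μx/6):

    J_mn(x, κl) = sqrt(3π/(2μx)) · [1 − √π·u·erfcx(u)]
    A_mn(x, κl) = (9/2)·sqrt(2π/3) · μ^(−3/2) · [1 − 2u² + 2√π·u³·erfcx(u)]

J enters the mean-field equation as (2λB/πl)·Σ ⟨q_m⟩·J_mi — i.e.
(2/πl)·J_mn is the thermally averaged pair potential ⟨exp(−κr)/r⟩ — while A
enters the conformation equation as (2λB/9πl)·x^(−3/2)·Σ ⟨q_m⟩⟨q_n⟩(m−n)²·A_mn.
Both depend on (m, n) only through the separation μ, so all matrices are
built from 1-D separation profiles.

For large u the closed forms suffer catastrophic cancellation (the brackets
decay like 3/(2u²) and 1/(2u²) while individual terms grow like u²), so the
implementation switches to the asymptotic series of erfcx beyond u = 25.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import erfcx

__all__ = [
    "KernelMatrices",
    "coupling_matrix_J",
    "conformation_matrix_A",
    "coupling_J_profile",
    "conformation_A_profile",
]

_SQRT_PI = math.sqrt(math.pi)
#: (9/2)·sqrt(2π/3), the κ = 0 amplitude of A at μ = 1.
_A0 = 4.5 * math.sqrt(2.0 * math.pi / 3.0)
#: sqrt(3π/2), the κ = 0, x = 1 amplitude of J at μ = 1.
_J0 = math.sqrt(1.5 * math.pi)

# double factorials (2j−1)!! and (2j+1)!! for the asymptotic tails
_DFACT_ODD = np.array([1, 3, 15, 105, 945, 10395, 135135, 2027025], dtype=float)

_U_SWITCH = 25.0


def _bracket_J(u: np.ndarray) -> np.ndarray:
    """1 − √π·u·erfcx(u), asymptotically 1/(2u²) − 3/(4u⁴) + ..."""
    u = np.asarray(u, dtype=float)
    out = np.empty_like(u)
    small = u <= _U_SWITCH
    out[small] = 1.0 - _SQRT_PI * u[small] * erfcx(u[small])
    if np.any(~small):
        ub = u[~small]
        inv = 1.0 / (2.0 * ub * ub)
        acc = np.zeros_like(ub)
        term = np.ones_like(ub)
        for j, dfac in enumerate(_DFACT_ODD, start=1):
            term = term * inv
            acc += ((-1) ** (j + 1)) * dfac * term
        out[~small] = acc
    return out


def _bracket_A(u: np.ndarray) -> np.ndarray:
    """1 − 2u² + 2√π·u³·erfcx(u), asymptotically 3/(2u²) − 15/(4u⁴) + ..."""
    u = np.asarray(u, dtype=float)
    out = np.empty_like(u)
    small = u <= _U_SWITCH
    us = u[small]
    out[small] = 1.0 - 2.0 * us * us + 2.0 * _SQRT_PI * us**3 * erfcx(us)
    if np.any(~small):
        ub = u[~small]
        inv = 1.0 / (2.0 * ub * ub)
        acc = np.zeros_like(ub)
        term = np.ones_like(ub)
        for j, dfac in enumerate(_DFACT_ODD[1:], start=1):  # (2j+1)!!
            term = term * inv
            acc += ((-1) ** (j + 1)) * dfac * term
        out[~small] = acc
    return out


def _check_args(x: float, kl: float) -> None:
    if x <= 0:
        raise ValueError(f"expansion factor x must be > 0, got {x}")
    if kl < 0:
        raise ValueError(f"kl must be >= 0, got {kl}")


def coupling_J_profile(sep: np.ndarray, x: float, kl: float) -> np.ndarray:
    """J as a function of separation μ ≥ 1 (vectorized)."""
    _check_args(x, kl)
    sep = np.asarray(sep, dtype=float)
    u = kl * np.sqrt(sep * x / 6.0)
    return np.sqrt(3.0 * math.pi / (2.0 * sep * x)) * _bracket_J(u)


def conformation_A_profile(sep: np.ndarray, x: float, kl: float) -> np.ndarray:
    """A as a function of separation μ ≥ 1 (vectorized)."""
    _check_args(x, kl)
    sep = np.asarray(sep, dtype=float)
    u = kl * np.sqrt(sep * x / 6.0)
    return _A0 * sep ** (-1.5) * _bracket_A(u)


def _profile_to_matrix(profile: np.ndarray, N: int) -> np.ndarray:
    mu = np.abs(np.arange(N)[:, None] - np.arange(N)[None, :])
    full = np.concatenate(([0.0], profile))  # diagonal (μ = 0) excluded -> 0
    return full[mu]


def coupling_matrix_J(N: int, x: float, kl: float) -> np.ndarray:
    """N×N ionization-coupling matrix J(x, κl); diagonal set to 0."""
    if N < 2:
        raise ValueError("N must be >= 2")
    return _profile_to_matrix(coupling_J_profile(np.arange(1, N), x, kl), N)


def conformation_matrix_A(N: int, x: float, kl: float) -> np.ndarray:
    """N×N conformation-coupling matrix A(x, κl); diagonal set to 0."""
    if N < 2:
        raise ValueError("N must be >= 2")
    return _profile_to_matrix(conformation_A_profile(np.arange(1, N), x, kl), N)


class KernelMatrices:
    """A and J evaluated at one (x, κl) point, built from separation profiles."""

    def __init__(self, N: int, x: float, kl: float):
        self.N = int(N)
        self.x = float(x)
        self.kl = float(kl)
        sep = np.arange(1, self.N)
        self.A_profile = conformation_A_profile(sep, x, kl)
        self.J_profile = coupling_J_profile(sep, x, kl)

    @property
    def A(self) -> np.ndarray:
        return _profile_to_matrix(self.A_profile, self.N)

    @property
    def J(self) -> np.ndarray:
        return _profile_to_matrix(self.J_profile, self.N)
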