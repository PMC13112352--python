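"""Independent brute-force oracles for the analytic kernels.

Two routes that never touch the closed-form kernel expressions:

* adaptive radial quadrature of the screened Coulomb potential against the
  Gaussian inter-residue distance density of the trial chain, and
* direct Monte Carlo sampling of the trial ensemble (independent Gaussian
  bonds, independent two-state residue charges).

They exist in the installed package (not only in the tests) so that every
derived reference value can be regenerated by users.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy.integrate import quad
from scipy.special import expit

from .core_model import PhysicalParams, SequenceSpec, TrialState

__all__ = [
    "OracleEstimate",
    "TrialEnsembleEstimates",
    "gaussian_screened_average",
    "gaussian_screened_r2_average",
    "sample_trial_ensemble",
]


@dataclass(frozen=True)
class OracleEstimate:
    """A brute-force estimate: value ± std_error (0 for quadrature)."""

    value: float
    std_error: float = 0.0
    n_samples: int = 0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.std_error < 0:
            raise ValueError("std_error must be >= 0")


def gaussian_screened_average(sep: int, x: float, kl: float) -> OracleEstimate:
    """⟨exp(−κr)/r⟩ over the trial-chain separation distribution, in 1/l.

    The vector between residues a distance ``sep`` apart (in monomers) is
    Gaussian with ⟨r²⟩ = sep·l·l_r; in units of l the radial density is
    4π·r²·(a/π)^{3/2}·exp(−a·r²) with a = 3/(2·sep·x).  The 1/r singularity
    is cancelled by the Jacobian, so the integrand is finite at the origin.
    At κ = 0 the closed form is sqrt(6/(π·sep·x)).
    """
    if sep < 1:
        raise ValueError("sep must be >= 1")
    if x <= 0:
        raise ValueError("x must be > 0")
    if kl < 0:
        raise ValueError("kl must be >= 0")
    a = 3.0 / (2.0 * sep * x)
    norm = 4.0 * math.pi * (a / math.pi) ** 1.5

    def integrand(r: float) -> float:
        return r * math.exp(-kl * r - a * r * r)

    upper = 12.0 / math.sqrt(a)  # ~exp(-216) tail; well beyond double precision
    value, abserr = quad(integrand, 0.0, upper, epsabs=1e-14, epsrel=1e-12, limit=200)
    value *= norm
    if abserr * norm > 1e-8 * max(abs(value), 1e-300):
        raise RuntimeError(
            f"quadrature did not converge (value {value:.3e}, err {abserr * norm:.3e})"
        )
    return OracleEstimate(value=value, std_error=0.0, n_samples=0, seed=None)


def gaussian_screened_r2_average(sep: int, x: float, kl: float) -> OracleEstimate:
    """⟨r²·exp(−κr)/r⟩ over the same separation distribution, in units of l.

    Together with :func:`gaussian_screened_average` this reconstructs the
    conformation kernel from its defining covariance,
    A = −(9π/2)·x^(−1/2)·sep^(−2)·(⟨r²v⟩ − ⟨r²⟩⟨v⟩) with ⟨r²⟩ = sep·x
    (l-units), without using the closed form.
    """
    if sep < 1:
        raise ValueError("sep must be >= 1")
    if x <= 0:
        raise ValueError("x must be > 0")
    if kl < 0:
        raise ValueError("kl must be >= 0")
    a = 3.0 / (2.0 * sep * x)
    norm = 4.0 * math.pi * (a / math.pi) ** 1.5

    def integrand(r: float) -> float:
        return r**3 * math.exp(-kl * r - a * r * r)

    upper = 12.0 / math.sqrt(a)
    value, abserr = quad(integrand, 0.0, upper, epsabs=1e-14, epsrel=1e-12, limit=200)
    value *= norm
    if abserr * norm > 1e-8 * max(abs(value), 1e-300):
        raise RuntimeError(
            f"quadrature did not converge (value {value:.3e}, err {abserr * norm:.3e})"
        )
    return OracleEstimate(value=value, std_error=0.0, n_samples=0, seed=None)


@dataclass
class TrialEnsembleEstimates:
    """Monte Carlo means over the trial ensemble."""

    re2: OracleEstimate
    mean_q: List[OracleEstimate]
    pair_potential: Dict[Tuple[int, int], OracleEstimate]


def _stderr(samples: np.ndarray) -> float:
    return float(np.std(samples, ddof=1) / math.sqrt(samples.size))


def sample_trial_ensemble(
    state: TrialState,
    seq: SequenceSpec,
    params: PhysicalParams,
    n_samples: int,
    seed: int,
    pairs: Optional[List[Tuple[int, int]]] = None,
) -> TrialEnsembleEstimates:
    """Sample the trial ensemble directly.

    Chains are built from ``N`` independent Gaussian bond vectors with
    ⟨b²⟩ = l·l_r (so ⟨R_e²⟩ = N·l·l_r over the full contour, and residues m
    and n — at positions 1..N along the walk — are separated with variance
    |m−n|·l·l_r).  Residue charge states are independent two-state draws
    with the logistic probabilities set by the converged fields.  Screened
    Coulomb pair averages (units 1/l) are returned for the 1-based residue
    ``pairs`` (all pairs if omitted — quadratic cost, use small N).
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    N = seq.N
    l = params.kuhn
    lr = state.x * l
    sigma = math.sqrt(l * lr / 3.0)  # per Cartesian component

    bonds = rng.normal(0.0, sigma, size=(n_samples, N, 3))
    re2_samples = np.sum(np.sum(bonds, axis=1) ** 2, axis=1)
    re2 = OracleEstimate(
        value=float(np.mean(re2_samples)),
        std_error=_stderr(re2_samples),
        n_samples=n_samples,
        seed=seed,
    )

    # residue positions along the walk (monomer m at the end of bond m)
    positions = np.cumsum(bonds, axis=1)

    sign = seq.charge_sign
    mean_q: List[OracleEstimate] = []
    for i in range(N):
        if sign[i] == 0.0:
            mean_q.append(OracleEstimate(0.0, 0.0, n_samples, seed))
            continue
        p_ionized = float(expit(-sign[i] * state.phi[i]))
        draws = sign[i] * (rng.random(n_samples) < p_ionized)
        mean_q.append(
            OracleEstimate(
                value=float(np.mean(draws)),
                std_error=_stderr(draws.astype(float)),
                n_samples=n_samples,
                seed=seed,
            )
        )

    if pairs is None:
        pairs = [(n + 1, m + 1) for m in range(N) for n in range(m)]
    pair_potential: Dict[Tuple[int, int], OracleEstimate] = {}
    for a_, b_ in pairs:
        r = np.linalg.norm(positions[:, b_ - 1, :] - positions[:, a_ - 1, :], axis=1)
        v = np.exp(-params.kappa * r) / (r / l)  # in units of 1/l
        pair_potential[(a_, b_)] = OracleEstimate(
            value=float(np.mean(v)),
            std_error=_stderr(v),
            n_samples=n_samples,
            seed=seed,
        )
    return TrialEnsembleEstimates(re2=re2, mean_q=mean_q, pair_potential=pair_potential)
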