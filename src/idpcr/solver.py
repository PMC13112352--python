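"""Self-consistent solution of the coupled conformation/ionization equations.

The variational treatment reduces the interacting chain to two coupled sets
of algebraic equations:

* a single equation for the expansion factor x = l_r/l,

      N(1/x − 1) + (3/2π)^{3/2} x^{−5/2} Σ_{m>n} ω_mn (m−n)^{−1/2}
        + (2λB/9πl) x^{−3/2} Σ_{m>n} ⟨q_m⟩⟨q_n⟩ (m−n)² A_mn(x, κl) = 0,

* N mean-field equations φ_i = ln10·(pH − pKA,i)
    + (2λB/πl) Σ_{m≠i} ⟨q_m⟩ J_mi(x, κl),

closed by the two-state logistic law ⟨q⟩ = −1/(1+e^{−φ}) for acids and
⟨q⟩ = 1/(1+e^{φ}) for bases.  They are solved by fixed-point iteration with
simple mixing (default ζ = 0.5) on the fields, re-solving the x-equation by
bracketed root finding at every sweep, until both x and all ⟨q_i⟩ are
stationary to the requested tolerance (default 1e-10).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from .core_model import LN10, PhysicalParams, SequenceSpec, TrialState
from .kernels import conformation_A_profile, coupling_J_profile

__all__ = [
    "SolverOptions",
    "BracketingError",
    "residual_x",
    "solve_x",
    "mean_charge",
    "field_rhs",
    "self_consistent_solve",
    "quenched_solve",
    "fixed_conformation_solve",
]

logger = logging.getLogger(__name__)

_EV_PREFACTOR = (1.5 / math.pi) ** 1.5  # (3/2π)^{3/2}


class BracketingError(RuntimeError):
    """No sign change of the x-equation residual inside the search bracket."""


@dataclass
class SolverOptions:
    """Numerical controls for the fixed-point iteration."""

    mixing: float = 0.5
    tolerance: float = 1e-10
    max_iterations: int = 10_000
    x_bracket: tuple[float, float] = (1e-3, 1e3)
    init_fields: Optional[np.ndarray] = None
    x_init: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.mixing <= 1.0):
            raise ValueError("mixing parameter must be in (0, 1]")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")
        lo, hi = self.x_bracket
        if not (0 < lo < hi):
            raise ValueError("x_bracket must satisfy 0 < lo < hi")


# ---------------------------------------------------------------------------
# the x-equation


def _charge_autocorrelation(q: np.ndarray) -> np.ndarray:
    """c[μ] = Σ_i q_i q_{i+μ} for μ = 1..N−1."""
    N = q.size
    return np.correlate(q, q, mode="full")[N:]


def residual_x(
    x: float,
    mean_q: np.ndarray,
    seq: SequenceSpec,
    params: PhysicalParams,
) -> float:
    """Left-hand side of the equation fixing the expansion factor.

    Zero at the self-consistent x.  Positive values mean the interaction
    terms outweigh the entropic restoring term at this x (net swelling
    pressure); negative values the opposite.
    """
    if x <= 0:
        raise ValueError(f"x must be > 0, got {x}")
    q = np.asarray(mean_q, dtype=float)
    N = seq.N
    if q.shape != (N,):
        raise ValueError("mean_q must have one entry per residue")
    mu = np.arange(1, N, dtype=float)

    res = N * (1.0 / x - 1.0)

    w_mu = seq.omega_by_separation()
    if w_mu is not None:
        res += _EV_PREFACTOR * x ** (-2.5) * float(w_mu[1:] @ mu ** (-0.5))

    c_mu = _charge_autocorrelation(q)
    if np.any(c_mu != 0.0):
        A = conformation_A_profile(mu, x, params.kl)
        elec_sum = float(c_mu @ (mu**2 * A))
        res += (
            2.0
            * params.bjerrum
            / (9.0 * math.pi * params.kuhn)
            * x ** (-1.5)
            * elec_sum
        )
    return res


def _interaction_free(mean_q: np.ndarray, seq: SequenceSpec) -> bool:
    return seq.omega_by_separation() is None and not np.any(
        _charge_autocorrelation(np.asarray(mean_q, dtype=float))
    )


def _residual_grid(
    xs: np.ndarray,
    mean_q: np.ndarray,
    seq: SequenceSpec,
    params: PhysicalParams,
) -> np.ndarray:
    """residual_x evaluated on an array of x values (broadcast over x and μ)."""
    q = np.asarray(mean_q, dtype=float)
    N = seq.N
    xs = np.asarray(xs, dtype=float)
    mu = np.arange(1, N, dtype=float)
    res = N * (1.0 / xs - 1.0)
    w_mu = seq.omega_by_separation()
    if w_mu is not None:
        res = res + _EV_PREFACTOR * xs ** (-2.5) * float(w_mu[1:] @ mu ** (-0.5))
    c_mu = _charge_autocorrelation(q)
    if np.any(c_mu != 0.0):
        A = np.vstack([conformation_A_profile(mu, float(x), params.kl) for x in xs])
        elec = A @ (c_mu * mu**2)
        res = res + (
            2.0 * params.bjerrum / (9.0 * math.pi * params.kuhn)
        ) * xs ** (-1.5) * elec
    return res


def solve_x(
    mean_q: np.ndarray,
    seq: SequenceSpec,
    params: PhysicalParams,
    options: Optional[SolverOptions] = None,
    x_prev: Optional[float] = None,
) -> float:
    """Root of :func:`residual_x` in the search bracket.

    An ideal chain (ω = 0, no charge correlations) returns x = 1 exactly.
    When several roots are bracketed (possible for strongly attractive
    polyampholytes, where the two-body theory starts to break down) the root
    nearest the previous iterate — i.e. the branch continuously connected to
    the ideal chain — is returned and a warning is emitted.
    """
    options = options or SolverOptions()
    if _interaction_free(mean_q, seq):
        return 1.0

    def f(x: float) -> float:
        return residual_x(x, mean_q, seq, params)

    anchor = x_prev if x_prev is not None else 1.0

    # fast path: progressively widened local brackets around the previous solution
    if x_prev is not None:
        for factor in (1.5, 5.0):
            lo, hi = x_prev / factor, x_prev * factor
            flo, fhi = f(lo), f(hi)
            if flo == 0.0:
                return lo
            if fhi == 0.0:
                return hi
            if flo * fhi < 0:
                return brentq(f, lo, hi, xtol=1e-14, rtol=1e-15)

    lo, hi = options.x_bracket
    grid = np.geomspace(lo, hi, 121)
    vals = _residual_grid(grid, mean_q, seq, params)
    zeros = grid[vals == 0.0]
    signs = np.sign(vals)
    flips = np.nonzero(signs[:-1] * signs[1:] < 0)[0]
    roots = [float(z) for z in zeros]
    for k in flips:
        roots.append(brentq(f, grid[k], grid[k + 1], xtol=1e-14, rtol=1e-15))
    if not roots:
        raise BracketingError(
            "no sign change of the x-equation in "
            f"[{lo:g}, {hi:g}]: residual ranges from {vals.min():.3e} "
            f"to {vals.max():.3e}"
        )
    if len(roots) > 1:
        warnings.warn(
            f"multiple roots of the x-equation found ({roots}); returning the "
            f"one nearest x = {anchor:g} (ideal-chain branch)",
            RuntimeWarning,
            stacklevel=2,
        )
    return min(roots, key=lambda r: abs(r - anchor))


# ---------------------------------------------------------------------------
# the mean-field equations


def mean_charge(phi: float, kind: str) -> float:
    """Average charge of a titratable residue in its mean-field."""
    if kind == "acid":
        return -float(expit(phi))
    if kind == "base":
        return float(expit(-phi))
    raise ValueError(f"kind must be 'acid' or 'base', got {kind!r}")


def _charges_from_fields(phi: np.ndarray, sign: np.ndarray) -> np.ndarray:
    """Vectorized logistic law; q = s·σ(−s·φ) with s = ±1, 0 for neutral."""
    q = np.zeros_like(sign)
    mask = sign != 0.0
    q[mask] = sign[mask] * expit(-sign[mask] * phi[mask])
    return q


def _field_targets(
    mean_q: np.ndarray,
    x: float,
    seq: SequenceSpec,
    params: PhysicalParams,
) -> np.ndarray:
    """Right-hand side of all N mean-field equations (NaN on neutral residues)."""
    N = seq.N
    J = coupling_J_profile(np.arange(1, N, dtype=float), x, params.kl)
    # symmetric Toeplitz matvec: Σ_m q_m J_{|m−i|} with J_0 ≡ 0
    kern = np.concatenate((J[::-1], [0.0], J))
    conv = np.convolve(mean_q, kern, mode="full")[N - 1 : 2 * N - 1]
    shift = 2.0 * params.bjerrum / (math.pi * params.kuhn) * conv
    base = LN10 * (params.pH - seq.pka_array)  # NaN on neutral residues
    return base + shift


def field_rhs(
    i: int,
    mean_q: np.ndarray,
    x: float,
    seq: SequenceSpec,
    params: PhysicalParams,
) -> float:
    """Mean-field equation right-hand side for residue ``i`` (1-based).

    The second term — the deviation from ln10·(pH − pKA,i) — is the
    electrostatic pKA shift induced by the rest of the chain.
    """
    res = seq.residues[i - 1]
    if res.kind == "neutral":
        raise ValueError(f"residue {i} ({res.label}) is not titratable")
    return float(_field_targets(np.asarray(mean_q, dtype=float), x, seq, params)[i - 1])


# ---------------------------------------------------------------------------
# coupled solves


def _neutral_state(seq: SequenceSpec, params: PhysicalParams,
                   options: SolverOptions) -> TrialState:
    q = np.zeros(seq.N)
    x = solve_x(q, seq, params, options)
    return TrialState(x=x, phi=np.full(seq.N, np.nan), mean_q=q,
                      iterations=0, converged=True, residual=0.0)


def self_consistent_solve(
    seq: SequenceSpec,
    params: PhysicalParams,
    options: Optional[SolverOptions] = None,
) -> TrialState:
    """Solve the fully coupled equations for conformation and ionization.

    Fields start from the ideal Henderson–Hasselbalch values (or
    ``options.init_fields``); each sweep re-solves the x-equation with the
    current charges, mixes the fields toward their targets, and updates the
    charges, until max|Δ⟨q_i⟩| and |Δx| both fall below the tolerance.
    """
    return _iterate(seq, params, options, x_fixed=None)


def fixed_conformation_solve(
    seq: SequenceSpec,
    params: PhysicalParams,
    x_fixed: float,
    options: Optional[SolverOptions] = None,
) -> TrialState:
    """Iterate only the ionization equations at a frozen expansion factor."""
    if x_fixed <= 0:
        raise ValueError("x_fixed must be > 0")
    return _iterate(seq, params, options, x_fixed=float(x_fixed))


def quenched_solve(
    fixed_q: np.ndarray,
    seq: SequenceSpec,
    params: PhysicalParams,
    options: Optional[SolverOptions] = None,
) -> float:
    """Expansion factor for fixed (quenched) charges — no field iteration."""
    return solve_x(np.asarray(fixed_q, dtype=float), seq, params, options)


def _iterate(
    seq: SequenceSpec,
    params: PhysicalParams,
    options: Optional[SolverOptions],
    x_fixed: Optional[float],
) -> TrialState:
    options = options or SolverOptions()
    sign = seq.charge_sign
    if not np.any(sign != 0.0):
        state = _neutral_state(seq, params, options)
        if x_fixed is not None:
            state.x = x_fixed
        return state

    if options.init_fields is not None:
        phi = np.asarray(options.init_fields, dtype=float).copy()
        if phi.shape != (seq.N,):
            raise ValueError("init_fields must have one entry per residue")
    else:
        phi = LN10 * (params.pH - seq.pka_array)
    phi[sign == 0.0] = np.nan
    q = _charges_from_fields(phi, sign)
    x = x_fixed if x_fixed is not None else options.x_init

    zeta = options.mixing
    delta = math.inf
    chargeable = sign != 0.0

    # Stagnation guard: plain mixing can enter a two-cycle when the coupling
    # is strong (collapsed blocky chains).  If the best residual seen in a
    # 40-sweep window stops improving, the mixing parameter is halved (down
    # to ζ/64) and the iteration continues.
    window = 40
    zeta_floor = options.mixing / 64.0
    best_prev = math.inf
    best_cur = math.inf
    in_window = 0

    for iteration in range(1, options.max_iterations + 1):
        x_new = (
            x_fixed
            if x_fixed is not None
            else solve_x(q, seq, params, options, x_prev=x)
        )
        target = _field_targets(q, x_new, seq, params)
        phi_new = phi.copy()
        phi_new[chargeable] = (1.0 - zeta) * phi[chargeable] + zeta * target[chargeable]
        q_new = _charges_from_fields(phi_new, sign)

        delta_new = max(float(np.max(np.abs(q_new - q))), abs(x_new - x))
        logger.debug("iteration %d: residual %.3e, x %.12g", iteration, delta_new, x_new)

        best_cur = min(best_cur, delta_new)
        in_window += 1
        if in_window >= window:
            if best_cur >= 0.5 * best_prev and zeta > zeta_floor:
                zeta = max(0.5 * zeta, zeta_floor)
                logger.info(
                    "iteration %d: residual stagnating at %.3e; mixing reduced to %g",
                    iteration, best_cur, zeta,
                )
            best_prev, best_cur, in_window = best_cur, math.inf, 0

        phi, q, x, delta = phi_new, q_new, x_new, delta_new
        if delta < options.tolerance:
            return TrialState(x=x, phi=phi, mean_q=q, iterations=iteration,
                              converged=True, residual=delta)

    logger.warning(
        "not converged after %d sweeps (residual %.3e)", options.max_iterations, delta
    )
    return TrialState(x=x, phi=phi, mean_q=q, iterations=options.max_iterations,
                      converged=False, residual=delta)
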