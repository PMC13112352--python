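"""Derived quantities: ionization profiles, net charge, chain size, titration
sweeps, and the isoelectric point."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core_model import PhysicalParams, SequenceSpec, TrialState
from .solver import SolverOptions, self_consistent_solve

__all__ = [
    "TitrationTable",
    "ionization_profile",
    "net_charge",
    "end_to_end",
    "titration_sweep",
    "isoelectric_point",
]


def ionization_profile(state: TrialState, seq: SequenceSpec) -> pd.DataFrame:
    """Per-residue ionization of a converged state.

    Returns a frame with one row per residue: the mean charge ``mean_q``, the
    charged fraction ``charged`` = |⟨q⟩| (what titration figures plot as the
    "degree of ionization" for acids and bases alike), and the degree of
    deprotonation ``theta`` (equal to the charged fraction for acids and to
    1 − ⟨q⟩ for bases; NaN for neutral residues).
    """
    q = state.mean_q
    sign = seq.charge_sign
    theta = np.full(seq.N, np.nan)
    theta[sign < 0] = -q[sign < 0]
    theta[sign > 0] = 1.0 - q[sign > 0]
    return pd.DataFrame(
        {
            "index": np.arange(1, seq.N + 1),
            "residue": list(seq.string),
            "kind": [r.kind for r in seq.residues],
            "pKA": seq.pka_array,
            "phi": state.phi,
            "mean_q": q,
            "charged": np.abs(q),
            "theta": theta,
        }
    )


def net_charge(state: TrialState) -> float:
    """Total average charge Σ_i ⟨q_i⟩ in elementary charges."""
    return float(np.sum(state.mean_q))


def end_to_end(state: TrialState, seq: SequenceSpec, params: PhysicalParams) -> float:
    """Root-mean-square end-to-end distance l·sqrt(N·x) of the trial chain, in Å."""
    return params.kuhn * math.sqrt(seq.N * state.x)


@dataclass
class TitrationTable:
    """Results of a pH (× salt) sweep.

    ``summary`` has one row per grid point (pH, salt, κ, net charge, x, R_e,
    iterations, converged); ``profiles`` additionally carries the per-residue
    charged fractions in columns theta_1..theta_N.
    """

    summary: pd.DataFrame
    profiles: pd.DataFrame

    def to_summary_csv(self, path) -> None:
        self.summary.to_csv(path, index=False)

    def to_tsv(self, path) -> None:
        self.profiles.to_csv(path, sep="\t", index=False)


def titration_sweep(
    seq: SequenceSpec,
    params_base: PhysicalParams,
    pH_grid: Sequence[float],
    salt_grid: Optional[Sequence[float]] = None,
    options: Optional[SolverOptions] = None,
    warm_start: bool = True,
) -> TitrationTable:
    """Solve the coupled equations on a pH (× salt) grid.

    Each grid point is warm-started from the previous pH's converged fields
    (solutions are unique for the models studied, so this only saves sweeps).
    Unconverged points are flagged in the ``converged`` column, never dropped.
    """
    pH_grid = list(pH_grid)
    if not pH_grid:
        raise ValueError("pH grid must be non-empty")
    salts: list[Optional[float]] = list(salt_grid) if salt_grid is not None else [None]
    if not salts:
        raise ValueError("salt grid must be non-empty")
    options = options or SolverOptions()

    summary_rows = []
    profile_rows = []
    for salt in salts:
        base = params_base if salt is None else params_base.at(salt=salt)
        prev: Optional[TrialState] = None
        for pH in pH_grid:
            params = base.at(pH=pH)
            opts = options
            if warm_start and prev is not None:
                opts = SolverOptions(
                    mixing=options.mixing,
                    tolerance=options.tolerance,
                    max_iterations=options.max_iterations,
                    x_bracket=options.x_bracket,
                    init_fields=prev.phi,
                    x_init=prev.x,
                    seed=options.seed,
                )
            state = self_consistent_solve(seq, params, opts)
            prev = state
            nq = net_charge(state)
            row = {
                "pH": pH,
                "salt": base.salt,
                "kappa": base.kappa,
                "net_charge": nq,
                "net_charge_per_residue": nq / seq.N,
                "x": state.x,
                "end_to_end": end_to_end(state, seq, params),
                "iterations": state.iterations,
                "converged": state.converged,
            }
            summary_rows.append(row)
            prof = dict(row)
            for i, qi in enumerate(state.mean_q, start=1):
                prof[f"theta_{i}"] = abs(qi)
            profile_rows.append(prof)
    return TitrationTable(
        summary=pd.DataFrame(summary_rows), profiles=pd.DataFrame(profile_rows)
    )


def isoelectric_point(
    seq: SequenceSpec,
    params: PhysicalParams,
    pH_window: tuple[float, float] = (0.0, 14.0),
    options: Optional[SolverOptions] = None,
    net_tolerance: float = 1e-6,
    max_bisections: int = 200,
) -> float:
    """pH at which the self-consistent net charge crosses zero.

    Bisection on the net charge (monotone non-increasing in pH for acid/base
    chains) to |net| < ``net_tolerance``.  Raises if the net charge does not
    change sign inside the window.
    """
    options = options or SolverOptions()

    def net_at(pH: float) -> float:
        return net_charge(self_consistent_solve(seq, params.at(pH=pH), options))

    lo, hi = pH_window
    f_lo, f_hi = net_at(lo), net_at(hi)
    if abs(f_lo) < net_tolerance:
        return lo
    if abs(f_hi) < net_tolerance:
        return hi
    if f_lo * f_hi > 0:
        side = "positive" if f_lo > 0 else "negative"
        raise ValueError(
            f"net charge is {side} throughout pH window [{lo}, {hi}] "
            f"(net({lo}) = {f_lo:.3g}, net({hi}) = {f_hi:.3g}); no isoelectric point"
        )
    for _ in range(max_bisections):
        mid = 0.5 * (lo + hi)
        f_mid = net_at(mid)
        if abs(f_mid) < net_tolerance:
            return mid
        if f_lo * f_mid < 0:
            hi, f_hi = mid, f_mid
        else:
            lo, f_lo = mid, f_mid
    return 0.5 * (lo + hi)
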