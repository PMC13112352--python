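"""Domain types and elementary parameter relations.

The model is a flexible heteropolymer (Edwards chain) with Kuhn length ``l``,
screened Debye–Hückel electrostatics of strength set by the Bjerrum length
``lambda_B``, optional excluded-volume interactions ``omega_mn``, and
titratable residues whose protonation states fluctuate in the constant-pH
ensemble.  All lengths are in Å, concentrations in mol/L (converted
internally to Å⁻³), and energies in units of kT.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Union

import numpy as np

__all__ = [
    "ACIDIC",
    "BASIC",
    "DEFAULT_PKA",
    "Residue",
    "SequenceSpec",
    "PhysicalParams",
    "TrialState",
    "debye_parameter",
    "bjerrum_length",
    "ideal_ionization",
]

#: Avogadro constant (1/mol).
AVOGADRO = 6.02214076e23

#: mol/L -> Å⁻³
_MOLAR_TO_ANG3 = AVOGADRO * 1e-27

# CODATA 2018 exact constants, SI units.
_ELEMENTARY_CHARGE = 1.602176634e-19
_VACUUM_PERMITTIVITY = 8.8541878128e-12
_BOLTZMANN = 1.380649e-23

#: One-letter codes treated as weak acids / weak bases; everything else is
#: neutral.  Terminal amine/carboxyl groups are not modelled.
ACIDIC = frozenset("DE")
BASIC = frozenset("KRH")

#: Default side-chain pKA values (Nozaki–Tanford).
DEFAULT_PKA: Mapping[str, float] = {
    "D": 4.0,
    "E": 4.4,
    "H": 6.3,
    "K": 10.4,
    "R": 12.0,
}

LN10 = math.log(10.0)


def debye_parameter(salt: float, bjerrum: float) -> float:
    """Debye screening parameter κ = sqrt(8π·λB·c) in Å⁻¹.

    Parameters
    ----------
    salt : float
        Monovalent salt concentration in mol/L.
    bjerrum : float
        Bjerrum length λB in Å.
    """
    if salt < 0:
        raise ValueError(f"salt concentration must be >= 0, got {salt}")
    if bjerrum <= 0:
        raise ValueError(f"Bjerrum length must be > 0, got {bjerrum}")
    c = salt * _MOLAR_TO_ANG3
    return math.sqrt(8.0 * math.pi * bjerrum * c)


def bjerrum_length(temperature: float, dielectric: float) -> float:
    """Bjerrum length e²/(4π·ε0·εr·kB·T) in Å.

    ≈ 7.1 Å for water (εr ≈ 78.4) at 298.15 K.
    """
    if temperature <= 0:
        raise ValueError(f"temperature must be > 0, got {temperature}")
    if dielectric <= 0:
        raise ValueError(f"dielectric constant must be > 0, got {dielectric}")
    lb_m = _ELEMENTARY_CHARGE**2 / (
        4.0 * math.pi * _VACUUM_PERMITTIVITY * dielectric * _BOLTZMANN * temperature
    )
    return lb_m * 1e10


def ideal_ionization(pH: float, pKA: float, kind: str) -> float:
    """Henderson–Hasselbalch ionized (charged) fraction in [0, 1].

    For an acid this is the deprotonated fraction 1/(1+10^(pKA−pH)); for a
    base it is the protonated fraction 1/(1+10^(pH−pKA)).
    """
    if kind == "acid":
        return 1.0 / (1.0 + 10.0 ** (pKA - pH))
    if kind == "base":
        return 1.0 / (1.0 + 10.0 ** (pH - pKA))
    raise ValueError(f"kind must be 'acid' or 'base', got {kind!r}")


@dataclass(frozen=True)
class Residue:
    """A single residue along the chain (1-based ``index``)."""

    index: int
    kind: str  # 'acid' | 'base' | 'neutral'
    pKA: Optional[float]
    label: str

    def __post_init__(self) -> None:
        if self.kind not in ("acid", "base", "neutral"):
            raise ValueError(f"unknown residue kind {self.kind!r}")
        if (self.pKA is None) != (self.kind == "neutral"):
            raise ValueError(
                f"residue {self.index} ({self.label}): pKA must be present "
                f"iff the residue is titratable"
            )


def _classify(label: str, pka_table: Mapping[str, float]) -> tuple[str, Optional[float]]:
    if label in ACIDIC:
        return "acid", float(pka_table[label])
    if label in BASIC:
        return "base", float(pka_table[label])
    return "neutral", None


OmegaSpec = Union[None, float, Mapping, np.ndarray]


@dataclass
class SequenceSpec:
    """An amino-acid sequence with titration identities and ω parameters.

    ``omega`` is the symmetric N×N matrix of dimensionless excluded-volume
    parameters (``None`` means ω ≡ 0, the default used for the electrostatics
    studies here).
    """

    residues: list[Residue]
    omega: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if len(self.residues) < 2:
            raise ValueError("a chain needs at least 2 residues")
        for i, r in enumerate(self.residues, start=1):
            if r.index != i:
                raise ValueError("residue indices must be 1..N in order")
        if self.omega is not None:
            self.omega = np.asarray(self.omega, dtype=float)
            if self.omega.shape != (self.N, self.N):
                raise ValueError("omega matrix must be N x N")
            if not np.allclose(self.omega, self.omega.T):
                raise ValueError("omega matrix must be symmetric")
        # cached vector views used by the solver
        kind_sign = {"acid": -1.0, "base": 1.0, "neutral": 0.0}
        self._sign = np.array([kind_sign[r.kind] for r in self.residues])
        self._pka = np.array(
            [r.pKA if r.pKA is not None else np.nan for r in self.residues]
        )

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_string(
        cls,
        sequence: str,
        pka: Optional[Mapping[str, float]] = None,
        omega: OmegaSpec = None,
    ) -> "SequenceSpec":
        """Build from a one-letter amino-acid string.

        ``pka`` optionally overrides entries of the default table.  ``omega``
        may be ``None`` (ω = 0), a scalar (uniform), a mapping keyed by
        residue-label pairs such as ``{("E", "K"): 0.5}`` (expanded
        symmetrically to all matching pairs), or a full N×N matrix.
        """
        sequence = sequence.strip().upper()
        if not sequence.isalpha():
            raise ValueError("sequence must contain only letters")
        table = dict(DEFAULT_PKA)
        if pka:
            table.update({k.upper(): float(v) for k, v in pka.items()})
        residues = []
        for i, label in enumerate(sequence, start=1):
            kind, pka_i = _classify(label, table)
            residues.append(Residue(index=i, kind=kind, pKA=pka_i, label=label))
        return cls(residues=residues, omega=_expand_omega(omega, sequence))

    @classmethod
    def from_fasta(
        cls,
        path,
        record_id: Optional[str] = None,
        pka: Optional[Mapping[str, float]] = None,
        omega: OmegaSpec = None,
    ) -> "SequenceSpec":
        """Read a sequence from a FASTA file (first record unless an id is given)."""
        from Bio import SeqIO

        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise ValueError(f"no FASTA records in {path}")
        if record_id is None:
            rec = records[0]
        else:
            matches = [r for r in records if r.id == record_id]
            if not matches:
                raise KeyError(f"record {record_id!r} not found in {path}")
            rec = matches[0]
        return cls.from_string(str(rec.seq), pka=pka, omega=omega)

    # -- views -------------------------------------------------------------

    @property
    def N(self) -> int:
        return len(self.residues)

    @property
    def string(self) -> str:
        return "".join(r.label for r in self.residues)

    @property
    def charge_sign(self) -> np.ndarray:
        """Formal charge sign per residue: −1 acid, +1 base, 0 neutral."""
        return self._sign

    @property
    def pka_array(self) -> np.ndarray:
        """pKA per residue (NaN for neutral residues)."""
        return self._pka

    @property
    def chargeable(self) -> np.ndarray:
        return self._sign != 0.0

    def omega_by_separation(self) -> Optional[np.ndarray]:
        """w[μ] = Σ_{m−n=μ} ω_mn for μ = 0..N−1 (None if ω ≡ 0)."""
        if self.omega is None:
            return None
        N = self.N
        w = np.zeros(N)
        for mu in range(1, N):
            w[mu] = np.trace(self.omega, offset=mu)
        return w


def _expand_omega(omega: OmegaSpec, sequence: str) -> Optional[np.ndarray]:
    N = len(sequence)
    if omega is None:
        return None
    if np.isscalar(omega):
        if float(omega) == 0.0:
            return None
        return np.full((N, N), float(omega))
    if isinstance(omega, Mapping):
        table = {}
        for key, val in omega.items():
            a, b = key
            table[(a.upper(), b.upper())] = float(val)
            table[(b.upper(), a.upper())] = float(val)
        mat = np.zeros((N, N))
        for m in range(N):
            for n in range(N):
                mat[m, n] = table.get((sequence[m], sequence[n]), 0.0)
        return mat
    return np.asarray(omega, dtype=float)


@dataclass
class PhysicalParams:
    """Solution conditions: pH, λB, l, and screening (κ or salt).

    If ``salt`` (mol/L) is given and ``kappa`` is not, κ is derived as
    sqrt(8π·λB·c).  ``kappa`` is in Å⁻¹.
    """

    pH: float
    bjerrum: float = 7.1
    kuhn: float = 5.8
    kappa: Optional[float] = None
    salt: Optional[float] = None

    def __post_init__(self) -> None:
        if self.bjerrum <= 0:
            raise ValueError("bjerrum must be > 0")
        if self.kuhn <= 0:
            raise ValueError("kuhn must be > 0")
        if self.kappa is None:
            if self.salt is None:
                raise ValueError("give either kappa or salt")
            self.kappa = debye_parameter(self.salt, self.bjerrum)
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")

    @property
    def kl(self) -> float:
        """Dimensionless screening strength κl."""
        return self.kappa * self.kuhn

    def at(self, **changes) -> "PhysicalParams":
        """Copy with fields replaced; κ is rederived when salt changes."""
        fields = dict(pH=self.pH, bjerrum=self.bjerrum, kuhn=self.kuhn,
                      kappa=self.kappa, salt=self.salt)
        if "salt" in changes and "kappa" not in changes:
            fields["kappa"] = None
        fields.update(changes)
        return PhysicalParams(**fields)


@dataclass
class TrialState:
    """Converged (or best-effort) variational state.

    ``x`` is the expansion factor l_r/l; ``phi`` the per-residue mean-fields
    (NaN on neutral residues); ``mean_q`` the average charges, always
    consistent with ``phi`` through the two-state logistic law.
    """

    x: float
    phi: np.ndarray
    mean_q: np.ndarray
    iterations: int = 0
    converged: bool = True
    residual: float = 0.0

    def __post_init__(self) -> None:
        if self.x <= 0:
            raise ValueError("expansion factor x must be > 0")
        self.phi = np.asarray(self.phi, dtype=float)
        self.mean_q = np.asarray(self.mean_q, dtype=float)
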