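"""Sequence fixtures: glutamate/lysine blockiness variants, homopolymers,
random blocky polyampholytes, and the sequence charge decoration metric.

The shipped 30-variant (EK)25 library is a SYNTHETIC blockiness ladder (see
the header of ``data/ek25_variants_synthetic.txt``): variant 1 is the
strictly alternating (EK)25, variant 30 the E25K25 diblock, and variants
2..29 interpolate between them with monotonically decreasing (more negative)
SCD, generated deterministically by single E↔K swaps.  It emulates the
classic 50-residue E/K variant set spanning well-mixed to fully segregated
charge patterns.
"""

from __future__ import annotations

import importlib.resources
from functools import lru_cache
from typing import Dict

import numpy as np

from .core_model import ACIDIC, BASIC

__all__ = [
    "ek_variant",
    "variant_library",
    "homopolymer",
    "random_blocky_sequence",
    "scd",
    "build_blockiness_ladder",
    "write_fasta_library",
    "read_fasta_library",
]

_DATA_FILE = "ek25_variants_synthetic.txt"
_N_VARIANTS = 30


def scd(sequence: str) -> float:
    """Sequence charge decoration: (1/N)·Σ_{m>n} σ_m σ_n √(m−n).

    σ are the formal charges (−1 for D/E, +1 for K/R/H, 0 otherwise).  More
    negative values indicate blockier (more charge-segregated) sequences;
    the metric is invariant under sequence reversal.
    """
    sig = np.array(
        [-1.0 if c in ACIDIC else 1.0 if c in BASIC else 0.0 for c in sequence.upper()]
    )
    N = sig.size
    if N == 0:
        return 0.0
    idx = np.arange(N)
    w = np.sqrt(np.abs(idx[:, None] - idx[None, :]))
    return float(sig @ w @ sig) / (2.0 * N)


def homopolymer(label: str, N: int) -> str:
    """N copies of one residue, e.g. ('E', 30) for the weak polyacid fixture."""
    label = label.strip().upper()
    if len(label) != 1 or not label.isalpha():
        raise ValueError(f"unknown residue code {label!r}")
    if N < 2:
        raise ValueError("N must be >= 2")
    return label * N


def random_blocky_sequence(
    n_acid: int, n_base: int, block_length: int, seed: int
) -> str:
    """Random E/K sequence with exact composition and tunable blockiness.

    Alternating acid/base runs are drawn with geometrically distributed
    lengths of mean ``block_length`` (clipped to the remaining composition),
    so ``block_length = 1`` gives near-alternating patterns and large values
    approach a diblock.  Deterministic for a fixed seed.
    """
    if n_acid < 0 or n_base < 0:
        raise ValueError("residue counts must be >= 0")
    if n_acid + n_base == 0:
        raise ValueError("sequence must contain at least one residue")
    if block_length < 1:
        raise ValueError("block_length must be >= 1")
    rng = np.random.default_rng(seed)
    remaining = {"E": n_acid, "K": n_base}
    current = rng.choice([c for c in "EK" if remaining[c] > 0])
    out: list[str] = []
    while remaining["E"] + remaining["K"] > 0:
        if remaining[current] == 0:
            current = "E" if current == "K" else "K"
            continue
        run = 1 if block_length == 1 else int(rng.geometric(1.0 / block_length))
        run = min(run, remaining[current])
        out.append(current * run)
        remaining[current] -= run
        current = "E" if current == "K" else "K"
    return "".join(out)


# ---------------------------------------------------------------------------
# synthetic (EK)25 blockiness ladder


def _canonical(seq: str) -> str:
    """Reversal-invariant representative (prefers E-leading strings)."""
    rev = seq[::-1]
    return seq if seq <= rev else rev


def build_blockiness_ladder(n_variants: int = _N_VARIANTS) -> Dict[int, str]:
    """Deterministically regenerate the synthetic (EK)25 variant ladder.

    Starting from the strictly alternating sequence, single E↔K swaps are
    applied, each chosen as the swap with the *smallest* strict decrease in
    SCD (gentle descent), producing a long monotone trajectory that ends in
    the diblock.  ``n_variants`` snapshots are taken at evenly spaced SCD
    values.  No randomness is involved.
    """
    N = 50
    idx = np.arange(N)
    w = np.sqrt(np.abs(idx[:, None] - idx[None, :]))
    sig = np.array([-1.0, 1.0] * 25)  # EKEK...
    traj = [sig.copy()]
    scds = [float(sig @ w @ sig) / (2 * N)]
    while True:
        ws = w @ sig
        acids = np.nonzero(sig < 0)[0]
        bases = np.nonzero(sig > 0)[0]
        # ΔSCD for swapping acid i with base j: (2/N)(ws_i − ws_j − 2 w_ij)
        delta = (2.0 / N) * (
            ws[acids][:, None] - ws[bases][None, :] - 2.0 * w[np.ix_(acids, bases)]
        )
        improving = delta < -1e-12
        if not improving.any():
            break
        masked = np.where(improving, delta, -np.inf)
        i_, j_ = np.unravel_index(int(np.argmax(masked)), masked.shape)
        sig[acids[i_]], sig[bases[j_]] = 1.0, -1.0
        traj.append(sig.copy())
        scds.append(scds[-1] + float(delta[i_, j_]))
    scds_arr = np.asarray(scds)
    targets = scds_arr[0] + (scds_arr[-1] - scds_arr[0]) * np.arange(n_variants) / (
        n_variants - 1
    )
    library = {}
    for n, t in enumerate(targets, start=1):
        pick = int(np.argmin(np.abs(scds_arr - t)))
        seq = "".join("E" if v < 0 else "K" for v in traj[pick])
        library[n] = _canonical(seq)
    return library


@lru_cache(maxsize=1)
def variant_library() -> Dict[int, str]:
    """The shipped synthetic (EK)25 variant library (numbers 1..30)."""
    text = (
        importlib.resources.files("idpcr.data").joinpath(_DATA_FILE).read_text()
    )
    library: Dict[int, str] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        num, _scd, seq = line.split()
        library[int(num)] = seq
    if sorted(library) != list(range(1, _N_VARIANTS + 1)):
        raise RuntimeError("corrupt variant library data file")
    return library


def ek_variant(n: int) -> str:
    """Variant ``n`` (1..30) of the synthetic (EK)25 blockiness ladder.

    Variant 1 is strictly alternating EKEK...; variant 30 is the E25K25
    diblock; blockiness (|SCD|) increases with the variant number.  Every
    variant has exactly 25 E and 25 K.
    """
    library = variant_library()
    if n not in library:
        raise ValueError(f"variant number must be in 1..{_N_VARIANTS}, got {n}")
    seq = library[n]
    if len(seq) != 50 or seq.count("E") != 25 or seq.count("K") != 25:
        raise RuntimeError(f"variant {n} violates the (EK)25 composition invariant")
    return seq


# ---------------------------------------------------------------------------
# FASTA round-trip helpers


def write_fasta_library(library: Dict[int, str], path) -> None:
    """Write a numbered sequence library to FASTA (ids ``variant_<n>``)."""
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    records = [
        SeqRecord(Seq(seq), id=f"variant_{n}", description="")
        for n, seq in sorted(library.items())
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta_library(path) -> Dict[int, str]:
    """Inverse of :func:`write_fasta_library`."""
    from Bio import SeqIO

    library = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id.startswith("variant_"):
            raise ValueError(f"unexpected record id {rec.id!r}")
        library[int(rec.id.split("_", 1)[1])] = str(rec.seq)
    return library
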