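# Methods

## Model and assumptions

The chain is a continuous Gaussian (Edwards) polymer of `N` residues with
Kuhn length `l`, discretized so that residues sit at contour positions
`m·l`, `m = 1..N`. Three interaction terms act on it:

* **Connectivity** — harmonic bonds; in the variational (trial) ensemble the
  vector between residues `m` and `n` is Gaussian with variance
  `|m−n|·l·l_r`, where `l_r = x·l` is the renormalized Kuhn length. All
  interaction effects on conformation are absorbed into the single scalar
  `x` (uniform expansion model); conformational heterogeneity along the
  chain (e.g. locally collapsed blocks) is outside the ansatz.
* **Excluded volume** — a contact pseudopotential with dimensionless,
  pair-resolved strength `ω_mn ≥ 0`. Negative `ω` (net two-body attraction)
  is not supported: it would require three-body terms to stabilize the
  chain.
* **Electrostatics** — the Debye–Hückel pair potential
  `λ_B·q_m·q_n·exp(−κr)/r` (energies in kT). Linear screening only: no
  counterion condensation or release, no explicit ions, no
  distance-dependent dielectric.

Acidic residues (D, E) carry charge `q ∈ {0, −1}`, basic ones (K, R, H)
`q ∈ {0, +1}`; protonation states fluctuate in the constant-pH ensemble, so
each microstate is weighted by `10^{Σ θ_s (pH − pKA_s)}`. Terminal amine and
carboxyl groups are not modelled. Side-chain pKA defaults are the
Nozaki–Tanford values (D 4.0, E 4.4, H 6.3, K 10.4, R 12.0), overridable
per residue type.

Applying the Edwards–Singh stationarity conditions simultaneously to the
squared end-to-end distance and to the charge profile yields one algebraic
equation for `x` and `N` coupled mean-field equations for the per-residue
fields `φ_i` (README for the equations). Because the trial Hamiltonian is
linear in the charges, residues titrate independently in their local fields,
and all correlations enter through the mean values `⟨q_i⟩` — a mean-field
closure in the spirit of Curie–Weiss spin models.

## The interaction kernels

Both coupling matrices are averages of the screened potential over the trial
ensemble and depend on `(m, n)` only through the separation `μ = |m−n|`.
With `u = κl·sqrt(μx/6)` and `erfcx(u) = e^{u²}·erfc(u)`:

    J_mn(x, κl) = sqrt(3π/(2μx)) · [1 − √π·u·erfcx(u)]
    A_mn(x, κl) = (9/2)·sqrt(2π/3) · μ^{−3/2} · [1 − 2u² + 2√π·u³·erfcx(u)]

`J` is (πl/2)·⟨exp(−κr)/r⟩, so the field equation's `(2λ_B/πl)·Σ⟨q⟩J` term
is exactly `λ_B·Σ⟨q⟩⟨exp(−κr)/r⟩` — the thermally averaged pair energy, and
the electrostatic pKA shift in ln10 units. `A` derives from the covariance
of `r²` with the pair potential,
`A = −(9π/2)·x^{−1/2}·μ^{−2}·(⟨r²v⟩ − ⟨r²⟩⟨v⟩)`.

Both brackets decay as `(κl)^{-2}` (3/(2u²) and 1/(2u²) respectively) in the
strong-screening limit; for `u > 25` the closed forms lose precision to
cancellation, so the implementation switches to the asymptotic series of
`erfcx` (eight terms, accurate to machine precision there). Both kernels are
validated in the test suite against an independent radial quadrature of the
defining Gaussian averages and against Monte Carlo sampling of the trial
ensemble; neither oracle touches the closed forms.

A note on the excluded-volume term of the conformation equation: its
separation weight is `(m−n)^{−1/2}` (the Gaussian contact probability
`⟨δ(r)⟩ ∝ d^{-3}` times `d² = μ·l·l_r`). This is also the unique exponent
that reproduces the Flory scaling `R ~ N^{3/5}` for a neutral swollen chain
under the uniform-expansion model.

## Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| `l` | Kuhn length | 5.8 Å | standard coarse-grained value for polypeptides |
| `λ_B` | Bjerrum length | 7.1 Å | water at ~298 K; `bjerrum_length(T, εr)` computes it (298.15 K, 78.4 → 7.15 Å) |
| `c_salt` | monovalent salt | — | sets `κ = sqrt(8π λ_B c)` after mol/L → Å⁻³ conversion; `κ` may be given directly |
| `ω` | excluded volume | 0 | scalar, per-residue-pair table, or full matrix |
| `ζ` | mixing parameter | 0.5 | fixed-point damping |
| tol | convergence tolerance | 1e-10 | on max |Δ⟨q_i⟩| and |Δx| |

## Numerical scheme

1. Initialize fields at their ideal values `φ_i = ln10·(pH − pKA,i)` (or
   user-supplied values) and `x = 1`; compute charges from the logistic law.
2. Solve the conformation equation for `x` by bracketed root finding
   (Brent), first trying progressively widened brackets around the previous
   `x`, then a 121-point log-spaced scan of `[1e-3, 1e3]`.
3. Mix the fields toward the right-hand side of the field equations with
   step `ζ`, update the charges, and repeat from 2 until both `x` and all
   `⟨q_i⟩` move less than the tolerance.

Numerical choices worth knowing:

* **Root selection.** For strongly attractive charge patterns the
  conformation equation can develop a second root at small `x` (an artifact
  of truncating at two-body interactions). When several roots are bracketed
  the solver returns the one nearest the previous iterate — the branch
  continuously connected to the ideal chain — and emits a warning. With
  `ω = 0` and strong attraction there may be *no* root (complete collapse);
  this raises a bracketing error with a diagnostic scan rather than
  returning a spurious state.
* **Stagnation guard.** Plain mixing at ζ = 0.5 can enter a two-cycle for
  strongly coupled collapsed states (e.g. an E₂₅K₂₅ diblock near its
  isoelectric point). If the best residual over a 40-sweep window stops
  halving, ζ is halved (floor ζ/64). In the weakly coupled regime this
  never triggers and the scheme is plain simple mixing.
* **Degenerate inputs.** Chains with no titratable residues skip the field
  iteration; with no interactions at all, `x = 1` is returned exactly.
  Neutral residues carry no field (NaN) and contribute nothing to any sum.
  Unconverged states are returned flagged, never silently.
* **Uniqueness.** For all systems studied here, randomized initializations
  (fields uniform in [−10, 10], `x` in [0.1, 10]) converge to the same state
  to better than 1e-8; the test suite asserts this for a moderately blocky
  E/K variant and the acceptance script re-verifies it at the reported pI.

## Study conditions and the synthetic sequence ladder

Two standard systems are used throughout tests and examples:

* **Weak polyacid**: 30×E, pKA 4.0, `l = 5.8 Å`, `λ_B = 7.1 Å`, `ω = 0`,
  salt 1e-3..1e-1 M. With purely repulsive interactions `ω = 0` is safe.
* **(EK)₂₅ polyampholytes**: 50-residue chains of 25 E + 25 K, pKA 4.4 and
  10.4, 0.015 M salt, and uniform `ω = 1`. The excluded volume here is not
  optional: near the isoelectric point blocky variants experience net
  two-body electrostatic attraction, and without a repulsive `ω` the
  conformation equation has no solution (collapse beyond the two-body
  theory). `ω = 1` is a physically reasonable dimensionless residue
  excluded volume (`v₂/l³ ~ O(1)` at `l = 5.8 Å`), chosen once; results
  reported here are insensitive to its exact value within a factor of a few.

The shipped 30-variant E/K library (`idpcr.sequences.ek_variant`) is a
**synthetic blockiness ladder**, not a transcription of any published
variant table: variant 1 is the strictly alternating (EK)₂₅, variant 30 the
E₂₅K₂₅ diblock, and variants 2–29 are generated deterministically (no RNG)
by single E↔K swaps that each decrease the sequence charge decoration
metric `SCD = (1/N)·Σ_{m>n} σ_m σ_n √(m−n)` as little as possible,
snapshotted at ~evenly spaced SCD values between −0.413 (alternating) and
−27.84 (diblock). The ladder spans the same well-mixed → fully segregated
range as the classic E/K variant sets and is shipped as a versioned text
file (`data/ek25_variants_synthetic.txt`) with a regeneration function
(`build_blockiness_ladder`) that the tests check against the file.

What the synthetic fixtures do and do not show: they exercise sequence
blockiness systematically at fixed composition, so conclusions about
blockiness trends (plateau width, collapse at pI, boundary ionization)
transfer to real E/K variant sets with matching SCD. They do not reproduce
any *specific* published variant other than 1 and 30, contain no residues
other than E/K, and say nothing about hydrophobic or other non-electrostatic
sequence effects, which the model itself omits.

On the isoelectric point of the alternating chain: with the symmetric pKA
pair (4.4, 10.4) and any E/K-symmetric `ω`, the model is exactly invariant
under charge conjugation combined with pH → 14.8 − pH, so the computed pI is
pinned to (4.4 + 10.4)/2 = 7.4. Only E/K-*asymmetric* excluded volumes (or
asymmetric compositions) can move it.

## Known limitations

* Mean-field in the charges: ionization correlations and fluctuation
  (transient-dipole) attractions are absent.
* Uniform expansion: a single `x` cannot describe tadpole or
  pearl-necklace conformations; block-resolved collapse shows up only as a
  global contraction.
* Debye–Hückel electrostatics: no counterion condensation, so strongly
  charged/low-salt regimes are treated too weakly.
* Two-body truncation: net-attractive systems without excluded volume have
  no solution instead of a collapsed globule; phase behaviour and
  multi-chain effects are out of scope.
* Titration of chain termini and of Y/C side chains is not modelled by
  default (Y/C can be added via a pKA override only by also extending the
  acid/base classification).
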