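# idpcr — charge regulation and conformation of disordered polyampholytes

`idpcr` computes the coupled ionization state and chain dimensions of
intrinsically disordered proteins (IDPs) and other flexible weak
polyelectrolytes/polyampholytes as a function of pH and salt. It is aimed at
polymer physicists and biophysicists who want sequence-resolved titration
predictions — which residues are charged, what the net charge is, how big the
chain is — in seconds rather than from constant-pH simulations.

## The model

A chain of `N` residues is described by an Edwards Hamiltonian with Kuhn
length `l`: harmonic connectivity, optional excluded-volume interactions
`ω_mn`, and screened Debye–Hückel electrostatics of strength `λ_B`
(Bjerrum length) and inverse screening length
`κ = sqrt(8π λ_B c_salt)`. Acidic (D, E) and basic (K, R, H) residues
titrate in the constant-pH ensemble with weight `10^{θ(s)(pH − pKA(s))}`,
so each residue's average charge is coupled both to the solution conditions
and to the fluctuating charges around it.

A uniform-expansion (Edwards–Singh) variational treatment reduces this to a
closed set of algebraic equations for the expansion factor `x = l_r/l` of a
renormalized Gaussian chain and a mean-field `φ_i` per titratable residue:

    N(1/x − 1) + (3/2π)^{3/2} x^{−5/2} Σ_{m>n} ω_mn (m−n)^{−1/2}
      + (2λ_B/9πl) x^{−3/2} Σ_{m>n} ⟨q_m⟩⟨q_n⟩ (m−n)² A_mn(x, κl) = 0

    φ_i = ln10·(pH − pKA,i) + (2λ_B/πl) Σ_{m≠i} ⟨q_m⟩ J_mi(x, κl)

    ⟨q_m⟩ = −1/(1+e^{−φ_m})  (acids),   ⟨q_m⟩ = 1/(1+e^{φ_m})  (bases)

The kernels `A` and `J` are Gaussian-chain averages of the screened Coulomb
potential and depend only on the residue separation `|m−n|`, `x`, and `κl`
(closed forms in terms of the scaled complementary error function; see
`docs/methods.md`). The second term of the field equation is the
electrostatic pKA shift: like-charged neighbours suppress ionization, which
produces the classic polyelectrolyte effect, enhanced ionization at chain
ends and at block boundaries, and strong sequence dependence of the net
charge and size of E/K polyampholytes.

The equations are solved by fixed-point iteration with simple mixing
(ζ = 0.5, with automatic step-size reduction if the iteration stagnates),
re-solving the conformation equation by bracketed root finding on every
sweep, to a tolerance of 1e-10 in all `⟨q_i⟩` and `x`.

## Worked example

A 30-residue weak polyacid (pKA 4.0, Kuhn length 5.8 Å, λ_B = 7.1 Å) at
pH 4 in 0.01 M salt:

```sh
$ idpcr solve --seq EEEEEEEEEEEEEEEEEEEEEEEEEEEEEE --pka E=4.0 --ph 4.0 --salt 0.01
pH 4.0  kappa 0.0327812 1/A  x 1.426676169  net -4.569643 e  Re 37.9447 A  iterations 33  converged True
```

Ideally (Henderson–Hasselbalch) half the 30 acids would be charged at
pH = pKA, i.e. a net charge of −15. Intramolecular repulsion suppresses
ionization to −4.57, and the chain is swollen (`x = 1.43`) relative to the
ideal chain, giving a root-mean-square end-to-end distance of 37.9 Å instead
of `5.8·√30 = 31.8` Å. Adding `--out DIR` writes the per-residue profile,
which is U-shaped: the chain ends (θ₁ = θ₃₀ = 0.213) ionize more than the
middle (θ₁₅ = 0.137) because they have fewer repelling neighbours.

Titration of the strictly alternating 50-mer (EK)₂₅ (variant 1 of the
shipped synthetic E/K blockiness ladder) at 0.015 M:

```sh
$ idpcr pi --variant 1 --salt 0.015 --omega 1.0 --window 4 11
pI = 7.4000  (net charge +5.712 at pH 4.0, -7.130 at pH 11.0)
```

The isoelectric point sits at the pKA midpoint (4.4 + 10.4)/2 — for an
alternating E/K chain this is exact by charge-conjugation symmetry — and the
net charge stays within ±0.2 e over pH 6–8: the zwitterionic state of
well-mixed sequences is strongly stabilized by favourable neighbour
interactions. Blockier variants (`--variant 30` is the E₂₅K₂₅ diblock) lose
this plateau and collapse much harder near their pI.

A pH sweep with per-residue output:

```sh
$ idpcr titrate --seq EEEEEEEEEE --pka E=4.0 --ph-grid 3:6:1 --salt 0.01 --out sweep/
 pH  salt    kappa  net_charge  ...        x  end_to_end  iterations  converged
3.0  0.01 0.032781   -0.600483  ... 1.016022   18.487556          25       True
4.0  0.01 0.032781   -2.024179  ... 1.170819   19.845996          40       True
5.0  0.01 0.032781   -4.602406  ... 1.718057   24.040685          44       True
6.0  0.01 0.032781   -7.912208  ... 2.644233   29.824821          31       True
```

The same functionality is available as a library
(`idpcr.self_consistent_solve`, `idpcr.titration_sweep`,
`idpcr.isoelectric_point`, ...), including brute-force validation oracles in
`idpcr.reference_oracles` (radial quadrature and Monte Carlo sampling of the
trial ensemble) that regenerate every reference value used in the tests.

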