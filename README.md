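# fidqdo — field-induced dispersion from quantum Drude oscillators

Long-range van der Waals (dispersion) forces arise from correlated quantum
charge fluctuations.  When a static external charge sits near an
interacting pair of molecules — an ion in a channel, a charged residue, a
dissolved salt — it polarizes those fluctuations and thereby *changes the
dispersion energy itself*, an effect entirely absent from force fields and
from dispersion-corrected DFT.  `fidqdo` computes this **field-induced
dispersion (FID)** for atom-pairwise quantum Drude oscillator (QDO) models,
and ships a brute-force perturbation-theory oracle for validating dispersion
formulas directly against the underlying Hamiltonian.

Each atom is a Drude oscillator: a quasiparticle of mass μ and charge −q
bound harmonically (frequency ω) to a center carrying +q.  Its multipole
polarizabilities are analytic,

    α_l = (q²/μω²) · [(2l−1)!!/l] · (ħ/2μω)^(l−1),

so α₁ = q²/μω² is classical while α₂ ∝ ħ — the FID effect is purely
quantum.  In-molecule atoms are parameterized Tkatchenko–Scheffler style,
rescaling free-atom values by Hirshfeld volume ratios
(α₁^eff = α₁^free·v, α₂^eff = α₂^free·v² with v = V_eff/V_free).

The core quantity is the leading (dipole–quadrupole, charge-linear)
field-induced term for a pair of oscillators A, B at separation R with an
external charge δ at distances R̃_A, R̃_B.  Per polarized oscillator,

    E_FID^A = −(δ/2) · α₁^B α₂^A ω_A ω_B / ((2ω_A+ω_B)(ω_A+ω_B)) · R̃_A⁻²
              · Σ_{m_A m_B} T_{2,−m_A;1,−m_B} T_{1,m_A;1,m_B} √(4−m_A²),

built from spherical multipole interaction tensors
T (Wigner 3j × irregular solid harmonic, Condon–Shortley convention);
the symmetrized pair energy for identical oscillators equidistant from the
charge collapses to

    E_FID = −3 δ α₂ α₁ / (R̃² R⁷).

A positive charge stabilizes the pair (E_FID < 0), a negative charge
destabilizes it, and the term decays one power of R faster than the London
−C₆/R⁶ attraction (C₆ = (3/2)α₁^A α₁^B ħω_Aω_B/(ω_A+ω_B), also provided as
a comparator).

The `fidqdo.oracle` module solves the same physics the hard way:
Rayleigh–Schrödinger perturbation theory (orders 1–3) for the coupled
QDO + point-charge Hamiltonian in a truncated harmonic-oscillator product
basis, with analytic Laguerre/ladder matrix elements.  Second order
reproduces London dispersion to machine precision; the charge-odd part of
third order is the field-induced term.  **Caveat found with this oracle and
documented in [`docs/methods.md`](docs/methods.md):** the closed-form pair
expression above does not coincide with the exact charge-odd third-order
energy of the model Hamiltonian — the exact leading term (also derived in
the methods note and implemented as `fid_leading_order_exact`) carries one
extra factor of the Drude charge, a different frequency weight, and a
cos θ dependence on the charge direction.  Both routes are exposed so users
can quantify the difference for their own parameterizations.

## Worked example

Generate a small seeded dimer-plus-charge system and compute its FID
report (lengths in Å, charges in e, energies in meV):

```bash
$ fid fixtures --preset random-dimer --seed 11 --out demo
$ fid compute --geometry demo/geometry.xyz --fragment-a 1-2 --fragment-b 3-4 \
      --charges demo/charges.dat --output demo/report.json
total FID: 0.01122 meV
pairwise London C6 total: 44.27 hartree*bohr^6
```

The fixture placed a −1 e charge near an (H₂)···O dimer; because the
charge is negative, the induced-dispersion contribution is positive
(destabilizing) — +0.011 meV summed over the two intermolecular atom
pairs.  `demo/report.json` holds the per-pair, per-charge decomposition.
Scanning the inter-fragment distance at a fixed 5 Å charge distance shows
the characteristic R⁻⁷ decay:

```bash
$ fid scan --rtilde 5 --rmin 4 --rmax 8 --n 5
 R_angstrom    E_FID_meV
          4 -0.000648518
    4.75683 -0.000192806
    5.65685 -5.73215e-05
    6.72717 -1.70418e-05
          8 -5.06655e-06
log-log slope d ln|E| / d ln R = -7.000000
```

`fid oracle` prints the perturbation-theory cross-check for a collinear
two-oscillator configuration, and `fid cbs` applies the two-point cubic
basis-set extrapolation E(∞) = (E(n₁)n₁³ − E(n₂)n₂³)/(n₁³ − n₂³) to
user-supplied correlated reference energies.

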