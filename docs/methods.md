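# Methods

## Model

Each atom's valence response is a quantum Drude oscillator (QDO): a
quasiparticle of mass μ and charge −q bound by an isotropic harmonic
potential of frequency ω to a fixed center carrying +q.  The system
Hamiltonian contains the unperturbed oscillators H₀, the Coulomb coupling
of every oscillator to external point charges δ_j, and the Coulomb coupling
between oscillators.  Both couplings are represented through their
spherical multipole expansions:

* charge–oscillator: H_X = δ Σ_{l≥1,m} Q_lm C*_lm(Ŝ)/|S|^{l+1}, where
  S is the vector from the oscillation center to the charge,
  Q_lm = −q d^l C_lm(d̂) is the multipole operator of the Drude
  displacement d, and C_lm = √(4π/(2l+1)) Y_lm are Racah-normalized
  harmonics (Condon–Shortley phase).  The l = 0 term cancels exactly for
  the neutral oscillator.
* oscillator–oscillator: H_XY = Σ Q^X_{l m} T_{l m;l'm'}(R) Q^Y_{l'm'},
  with the interaction tensor
  T = (−1)^{l} √((2l+2l'+1)!/((2l)!(2l')!)) · 3j(l,l',l+l'; m,m',−(m+m'))
  · I_{l+l',−(m+m')}(R) and I_{L,M}(R) = C_{LM}(R̂)/|R|^{L+1}.

These conventions are *jointly validated* in the test suite: the tensor
contraction reproduces the exact Coulomb energy of two separated neutral
point-charge clusters to truncation accuracy, the classical spherical
dipole contraction equals the Cartesian (p·p′ − 3(p·R̂)(p′·R̂))/R³ form,
and the static multipole response of a single oscillator to the charge
coupling reproduces the analytic polarizabilities

    α_l = (q²/μω²)[(2l−1)!!/l](ħ/2μω)^{l−1}

to machine precision for l = 1, 2, 3.

## Analytic field-induced dispersion (FID)

The package's central closed-form operation evaluates, per polarized
oscillator A with partner B,

    E_FID^A = −(δ/2)·α₁^B α₂^A ω_Aω_B/((2ω_A+ω_B)(ω_A+ω_B))·R̃_A⁻²
              · Σ_{m_A m_B} T_{2,−m_A;1,−m_B} T_{1,m_A;1,m_B} √(4−m_A²),

with the m-sum evaluated in a canonical pair frame whose quantization axis
lies along R_AB.  In that frame the sum equals 18/R⁷ identically, so for
two identical oscillators equidistant from the charge the symmetrized pair
energy is exactly −3δα₂α₁/(R̃²R⁷).  The formula is linear in δ (exact
sign antisymmetry), decays as R⁻⁷ and R̃⁻², and vanishes linearly in ħ
through α₂ — all properties enforced by tests.  System-level totals sum
this pair term over intermolecular atom pairs and superpose external
charges linearly; charge–charge cross terms are δ-even and of higher
order, hence outside the charge-odd quantity of interest.  R̃ is always
measured from the polarized atom's own center, not from a molecular
center of mass.

## The perturbation-theory oracle

`fidqdo.oracle` evaluates Rayleigh–Schrödinger perturbation theory, orders
1–3, in the product basis of 3D isotropic harmonic-oscillator eigenstates
(n, l, m) with 2n + l ≤ N_max per oscillator.  Matrix elements are fully
analytic: radial integrals ⟨n l | r^L | n' l'⟩ from finite Laguerre
expansion sums, angular factors from Wigner 3j symbols.  Because the basis
diagonalizes H₀, the perturbation sums run directly over the (small) set
of product states reachable from the ground state by one application of
the perturbation; third order costs a dense contraction over ~10³ states
at N_max = 10.  The truncation (charge coupling l ≤ L_max, pair coupling
l + l' ≤ L_sum, defaults 3 and 3) is part of the model definition: the
oracle isolates exactly the multipole channels the analytic formulas
resum.  First order vanishes identically (odd operators); second order
with dipole-only coupling reproduces −C₆/R⁶ with
C₆ = (3/2)α₁^Aα₁^B ħω_Aω_B/(ω_A+ω_B) to machine precision (the dipole
coupling connects the ground state to single-excitation states only, so
no basis error enters); the charge-odd part of third order, extracted as
(E₃(+δ) − E₃(−δ))/2 on the fragment-interaction energy (dimer minus
monomers, which removes the single-oscillator δ³ hyperpolarization terms),
is the field-induced dispersion.  The implementation was additionally
cross-validated against a polynomial fit in λ of the exact lowest
eigenvalue of H₀ + λH′ during development.

## Exact leading-order FID versus the closed form

Summing the third-order series exactly over the closed set of intermediate
states (the ground state connects only to states with l ≤ 2 per
oscillator within the retained channels) gives, for a charge far from
both oscillators, the *exact* charge-odd leading term

    E = Σ_{X,Y pairs} −12 δ q_X α₂^X α₁^Y ω_Y cos θ_X
                      / ((ω_X+ω_Y) R̃_X² R⁷),

where θ_X is the angle at oscillator X between the directions to its
partner and to the charge (`fid_leading_order_exact`; verified against
the numerical oracle to better than 0.5% in both collinear and bisector
geometries).  This disagrees with the closed form of the previous
section in three ways:

1. it carries one extra factor of the Drude charge q_X — unavoidable,
   since the underlying matrix element has three vertices on the
   polarized oscillator (two pair couplings and one charge coupling),
   giving amplitude ∝ q_X³q_Y², whereas α₂^X α₁^Y ∝ q_X²q_Y² (the
   α-only closed form is dimensionally a charge short of an energy);
2. its frequency weight is (4/3)ω_Y/(ω_X+ω_Y) rather than
   ω_Xω_Y/((2ω_X+ω_Y)(ω_X+ω_Y));
3. it depends on the charge *direction* through cos θ_X, whereas the
   closed form depends only on |R̃|.  The per-term ratio is
   (4/3) q_X cos θ_X (2ω_X+ω_Y)/ω_X.

Both quantities are exposed deliberately.  The closed-form route is the
package's primary surface (its internal consistency — the −3 prefactor,
the R⁻⁷ and R̃⁻² power laws, δ-antisymmetry, the ħ-linearity — holds
exactly); the oracle and the exact leading-order form quantify how far
that closed form sits from the model Hamiltonian's own perturbation
series.  One consequence worth noting: on the perpendicular bisector of
an identical pair, cos θ = R/(2R̃), so the exact charge-odd term decays
as R̃⁻³ there, not R̃⁻².

## Parameters

* μ, ω, q (atomic units).  The standard closure used throughout maps a
  polarizability triple (α₁, α₂, ω) to (μ, ω, q) via μω = 3ħα₁/4α₂ and
  q = √(α₁μω²); alternatively ω = 4C₆/(3α₁²) from the identical-atom
  London relation when only (α₁, C₆) are known.
* Hirshfeld volume ratio v (dimensionless, default 1 = free atom):
  α₁ scales as v, α₂ as v².  The ratio must come from an external
  electronic-structure calculation; the package never computes it.
* The bundled H/C/N/O table (`data/qdo_params.dat`) carries standard
  free-atom dipole polarizabilities, London-closure frequencies and
  *indicative* quadrupole polarizabilities; it is a convenience default,
  clearly marked editable, not reference data.
* Internal units are Hartree atomic units with ħ routed through a single
  `UnitSystem` object, so the classical limit ħ → 0 is one switch.
  I/O uses Å, elementary charges, and meV by default.

## Numerical choices

* Wigner 3j symbols: Racah single-sum formula in exact integer/rational
  arithmetic, converted to float at the end; validated exhaustively
  against an independent exact-rational implementation for all l ≤ 6.
* Factorials under the tensor square root are computed as exact integers
  before conversion, safe to l_A + l_B ≈ 15.
* Oracle radial integrals use exact finite Laguerre sums with gamma
  functions; alternating-sum cancellation is mild for n ≤ 5 (N_max ≤ 10)
  and is checked against direct quadrature at 1e−8.
* Degenerate denominators cannot occur (the isotropic ground state is
  unique for ω > 0); an assertion guards excitation energies > 0.
* The oracle refuses charges closer than 5·√(ħ/μω) to any center, where
  the multipole expansion of the charge coupling would be meaningless.
* Energies are reported to 4 significant figures in CLI summaries; JSON
  reports carry full double precision.

## Synthetic systems

The fixture generator produces three deterministic presets: a symmetric
("collinear") unit-parameter pair with the charge equidistant from both
centers, where the closed form applies exactly and the manifest records
the expected energy; a distance-scan variant ("bisector", R̃ = 5 Å,
R = 4–8 Å) for power-law fits; and a seeded random dimer (H/C/N/O atoms,
Hirshfeld ratios drawn from 0.7–1.1, ±1 or ±2 charges at 4–7 Å) for
symmetry and pipeline tests.  These fixtures exercise every code path but
are *not* realistic molecules: they have no electrostatics, no induction,
no geometry optimization, and their parameters are not fitted to any
species.  Tests passing on them demonstrate the algebraic and numerical
correctness of the implementation, not the accuracy of pairwise QDO-FID
for real complexes.

## Limitations

* Pairwise additive only: no many-body dispersion or screening, no
  self-consistent polarizability screening.
* The charge-odd third-order term is the lowest diagram; higher-order
  polarization–dispersion terms (which break the exact δ-antisymmetry)
  are out of scope.
* No electrostatic or induction energies; the package computes the
  dispersion modification only.
* External sources are point charges; finite dipoles or field gradients
  as sources are not implemented.
* The perturbative oracle supports at most three oscillators and relies
  on multipole-truncated couplings, so it cannot probe charge–oscillator
  overlap effects.
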