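# Methods

This note records the model content of `pespectra`, the conventions and
numerical choices that were genuinely open, and what the synthetic test
systems do and do not establish.

## Scope and roles

The package implements the *classical* side of polarizable embedding: the
environment (distributed multipoles, dipole–dipole polarizabilities,
Lennard-Jones sites, organized in fragments with exclusion lists) and its
interaction with a core region represented by point charges with masses.
Electronic structure — densities, electron–multipole integrals, Fock-matrix
contributions, self-consistent core↔environment polarization — is explicitly
out of scope; where a quantum code would supply a Hessian or dipole /
polarizability gradients, the package accepts them via the plain-text
property dump (`pespectra.io.PropertyDump`) or substitutes toy surfaces
(below).

## Interaction tensors and sign conventions

All electrostatics is built on the Cartesian interaction tensor

    T^[α](R_i, R_j) = ∂^α/∂R_j^α 1/|R_i − R_j|,

i.e. the multi-index derivative taken at the *second* argument.  Several
sign conventions circulate in the literature; rather than argue from
notation, every downstream sign in the package is pinned by physical limits
that the test suite enforces with explicit point-charge arrays:

* the |α| = 0 electrostatic term must equal the bare Coulomb charge–charge
  energy;
* a dipole-carrying site must reproduce the δ→0 limit of two charges ±μ/δ;
* a quadrupole-carrying site must reproduce a four-charge array.

With raw Cartesian moments `M^[α] = Σ_c q_c d_c^α` these limits force the
prefactor `(−1)^|α|/α!` in the electrostatic energy, and the off-diagonal
response-matrix blocks to be `−T^(2)` (so that two aligned head-to-tail
dipoles attract).  Tensors are evaluated with the point-charge limit of the
McMurchie–Davidson auxiliary recurrence, which is numerically stable for the
orders used here (≤ 2 multipole + 1 field + 2 geometric derivatives = 5; the
implementation supports 8) and is validated against symbolic
differentiation (sympy) and nested finite differences.

## Induction

Induced dipoles minimize the classical polarization functional; the linear
system `A μ = F` is solved by preconditioned conjugate gradients
(block-Jacobi with the site polarizabilities, relative residual 1e-10,
iteration cap 10 000).  The matrix is assembled densely and checked for
positive definiteness (Cholesky) — at the environment sizes this package
targets (tens of fragments) that cost is negligible, and the dense factor
doubles as the test oracle for the iterative path.  Exclusions follow the
potential file: same-fragment pairs never couple, neither in the response
matrix nor in the permanent-field sums.

Because the energy is variational in μ, the geometric gradient needs no
dipole response: `∂E_ind/∂g = −μ·∂F/∂g`.  The Hessian adds
`−(∂F/∂g₁)·A⁻¹·(∂F/∂g₂)` (one dense multi-RHS solve) plus the contraction
of μ with the second field derivatives.  Only the nuclear part of the field
moves with the core; permanent-multipole potentials contribute zero
geometric derivative.

A caveat worth stating: with a *bare* point-charge core (nuclear charges,
no electronic screening) the fields at nearby polarizable sites are much
larger than in a real embedding calculation, so induction energies of the
toy fixtures are large in magnitude (hartrees, not millihartrees).  The
response matrices remain comfortably positive definite for every shipped
configuration (smallest eigenvalues ≈ 0.06–0.14), and all identities the
tests assert are exact properties of the model, independent of this scale.

## Lennard-Jones

Plain 6-12 with Lorentz–Berthelot combination, no cutoff or switching.
Environment sites without parameters contribute nothing (one warning).
Derivatives are the standard radial closed forms; the Hessian, like the
electrostatic one, is block-diagonal over core atoms because every term
involves exactly one core atom.

## PHVA and the vibrational unit chain

The Hessian analyzed is the core–core block only; environment masses never
enter.  Mass-weighted eigenvalues convert to wavenumbers through a single
constant chain (`constants.WAVENUMBER_FROM_EIGVAL`, CODATA 2018); imaginary
frequencies are reported as negative wavenumbers, and eigenvector signs are
fixed by making the largest-magnitude component positive, so decompositions
are bit-reproducible.  Because an embedded core is not free, its low modes
mix with global translation/rotation; the package exposes both remedies —
projecting the six (five for linear cores, detected by a moment-of-inertia
ratio < 1e-8) rigid-body vectors out of the Hessian, or keeping all modes
and discarding those below a wavenumber cutoff (preset 750 cm⁻¹) — and
takes no position on which is better for a given system.  Modes with
non-positive wavenumbers are dropped before intensity evaluation: they
carry no harmonic band, and the Raman Boltzmann factor diverges at ν̃ → 0.

## Intensities and units

IR band strengths `μ_I^Q` and Raman invariants `(a_I, b_I²)` are computed in
SI internally.  The decadic attenuation prefactor `N_A/(12 ln10 ε₀ c²)` and
the cross-section prefactor `h/(8ε₀²c ν̃_I)·(ν̃₀−ν̃_I)⁴·(45a²+7b²)/45` with
the Stokes thermal factor `[1−exp(−hcν̃_I/kT)]⁻¹` follow the standard
double-harmonic conventions; the combination coefficients (45, 7) correspond
to incident light polarized perpendicular to the observation direction and
are settings, not constants.  Two anchors tie the implementation to the
printed unit tables: the conversion `C²·kg⁻¹ → D²·Å⁻²·amu⁻¹` must come out
1.4924×10¹² and `C⁴·m²·J⁻²·kg⁻¹ → Å⁴·amu⁻¹` must come out 1.3413×10³³, both
to five significant figures, from the constants table alone — no composite
factor is typed in anywhere.  The unit string sometimes attached to Raman
cross sections (C⁴·s²·J⁻¹·m⁻²·kg⁻¹) does not dimensionally match an area per
solid angle built from the standard prefactor; the package computes the
standard (area-scale) result and tags gridded Raman spectra explicitly
rather than asserting equality of the two unit readings.

Within the IR family, conversions between the μ^Q-scale, the Napierian
integrated scale (`A = N_A μ^Q/(12ε₀c²)`, m·mol⁻¹) and the decadic scale
(factor 1/ln 10; pointwise unit m²·mol⁻¹) treat the number as a
band-integrated strength; the pure relabelings within a scale
(km·mol⁻¹ = 10⁻³ m·mol⁻¹, L·mol⁻¹·cm⁻¹ = 10 m²·mol⁻¹) are exact.

Lineshape: Cauchy density with HWHM γ (preset 3.0 cm⁻¹), normalized per
wavenumber, so a band integral over wavenumber in m⁻¹ equals `A/ln10`.
Spectra live on a 0–4000 cm⁻¹ grid at 0.5 cm⁻¹ spacing by default; ensemble
spectra are plain pointwise means over snapshots on a shared grid.

## File formats

The potential-file dialect is the sectioned Dalton/PyFraME style
(`@COORDINATES` with an AA/AU unit line, `@MULTIPOLES` with ORDER 0/1/2
blocks, `@POLARIZABILITIES ORDER 1 1`, `EXCLISTS`), with quadrupoles and
polarizabilities in xx, xy, xz, yy, yz, zz order and 1-based site indices.
Parsers are strict: unknown sections, higher multipole orders, or
inconsistent counts are errors, never warnings, and exclusion rows are
symmetrized with fragments inferred as connected components of the
exclusion graph.  Geometries are standard XYZ (ångström on disk, bohr in
memory); property dumps are whitespace matrix blocks with a symmetry check
on the Hessian.  Everything is plain text.

## Synthetic fixtures: what they are and are not

The generator places water-like 3-site fragments (net charge 0, fragment
dipole ≈ 0.7 e·bohr, site polarizabilities 1.8–6 bohr³, slight anisotropy
on the oxygen) at 6–14 bohr around a rigid 4-center carbonyl-like
point-charge core, rejecting placements closer than 3 bohr to the core or
2.5 bohr to other fragments.  These defaults were chosen once as a
plausible first-solvation-shell geometry and are not tuned.  Three toy
models complete the pipeline:

* an all-pairs harmonic-spring core potential with equilibrium at the
  template geometry and distance-weighted force constants `k = 8/r³`
  (hartree/bohr²), giving bond-like stiff modes in the 1000–1800 cm⁻¹
  range;
* a dipole surface `μ = Σ q_n R_n` (template partial charges summing to
  zero; nuclear charges otherwise) plus the environment's induced dipoles,
  whose response to core motion is evaluated analytically through the
  response matrix;
* a bond-polarizability surface (per-atom isotropic term plus longitudinal
  `c_l r²` / transverse `c_t r` bond contributions), exactly rotation
  equivariant.

Snapshot ensembles apply independent Gaussian displacements to core atoms
and rigid Gaussian translations to fragments, with explicit seeds.

Passing tests on these fixtures establishes the *algebraic* correctness of
the machinery — derivative consistency, variational identities, unit
chains, invariances — under every multipole order and coupling the model
supports.  They do not establish chemical realism: the fixtures have no
electronic screening, no exchange repulsion beyond LJ, no anharmonicity,
and no configurational sampling beyond Gaussian jitter.

## Numerical choices

* Atomic units everywhere in memory; conversions only at I/O boundaries.
* Site–atom or site–site separations below 1e-6 bohr are singular errors;
  there is no short-range damping anywhere in the model.
* Finite-difference oracles in the tests use central differences with
  Richardson extrapolation (steps 1e-3/5e-4 for electrostatics and
  induction, 1e-5 for the stiffer LJ terms).
* The acceptance script exercises ten fixtures of 2–20 fragments with a
  4-atom core; these sizes keep the full derivative validation around a
  minute on one CPU while covering every term and coupling of the model.
* Constants are CODATA 2018.  `scipy.constants` (used as an independent
  oracle in tests) tracks a newer release; cross-checks therefore compare
  at 1e-7 relative, far above the inter-release drift (~1e-9) and far below
  any tolerance of interest.

## Known limitations

* Induced dipoles only; higher-order polarizabilities are a declared
  extension point (the response-matrix layout generalizes to polytensors
  but only the |β| = 1 blocks are implemented).
* No Thole-style damping or screened tensors.
* No anti-Stokes branch, resonance Raman, or local-field corrections.
* The core is classical; nothing here substitutes for the electronic
  contributions to energies or property gradients.
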