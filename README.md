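# pespectra

Classical polarizable-embedding (PE) energetics with fully analytic geometric
derivatives, and the double-harmonic IR/Raman spectral pipeline built on
partial-Hessian vibrational analysis (PHVA).

## Who this is for

Researchers in molecular modelling / structural bioinformatics who need the
*classical* machinery of fragment-based embedding — distributed multipoles,
induced dipoles, Lennard-Jones terms, and their first and second geometric
derivatives — as a standalone, testable library, together with the complete
bookkeeping that turns Hessians and property gradients into broadened,
snapshot-averaged vibrational spectra in every commonly reported unit system.
The quantum-mechanical half of an embedding calculation (densities, Fock
matrices, response equations) is deliberately out of scope: the core region
here is a point-charge proxy, and externally computed Hessians or property
gradients can be supplied through a plain-text property dump.

## The model

The embedding energy of a core region (nuclei `Z_n` at `R_n`) inside an
environment of fragments carrying sites `s` with permanent Cartesian
multipoles `M_s^[α]` (|α| ≤ 2), dipole–dipole polarizabilities `α_s`, and
Lennard-Jones parameters is

    E = E_es + E_ind + E_LJ

    E_es  = Σ_s Σ_{|α|≤K_s} (−1)^|α|/α! · M_s^[α] · Σ_n Z_n T^[α](R_s, R_n)
    E_ind = −½ μ_ind · F,     A μ_ind = F
    E_LJ  = Σ_{ns} 4ε_sn [ (σ_sn/r_ns)¹² − (σ_sn/r_ns)⁶ ]

where `T^[α](R_i,R_j) = ∂^α_{R_j} |R_i − R_j|⁻¹` is the Cartesian interaction
tensor (evaluated by a stable auxiliary recurrence to arbitrary order), `A`
is the classical linear-response matrix (inverse site polarizabilities on the
diagonal, dipole–dipole couplings off it, same-fragment pairs excluded), `F`
is the permanent field at the polarizable sites from the core nuclei and
foreign-fragment multipoles, and σ/ε combine by Lorentz–Berthelot rules.
Gradients and Hessians with respect to core coordinates are analytic
throughout (induction uses the variational property of `μ_ind`, plus one
linear solve per core coordinate for the Hessian).

From a core Hessian the PHVA pipeline produces mass-weighted normal modes
ν̃_I (with optional translation/rotation projection, or a wavenumber cutoff —
preset 750 cm⁻¹ — to drop contaminated low modes), then

* IR: `μ_I^Q = Σ_α (∂μ_α/∂Q_I)²`, reported as the molar decadic attenuation
  coefficient `ε_I(ν̃) = N_A/(12 ln10 ε₀c²) · μ_I^Q · f(ν̃; ν̃_I, γ_I)` with a
  Cauchy lineshape of HWHM γ (preset 3.0 cm⁻¹),
* Raman: invariants `a_I`, `b_I²` of the polarizability gradient and the
  absolute differential cross section
  `σ′_I = h/(8ε₀²c ν̃_I) · (ν̃₀−ν̃_I)⁴ · (45a² + 7b²)/45 · [1−e^{−hcν̃_I/kT}]⁻¹`
  (preset: 514.5 nm excitation, 298 K),
* snapshot averaging: the pointwise mean of the per-snapshot spectra.

Intensities convert between `C²·kg⁻¹`, `D²·Å⁻²·amu⁻¹`, `m·mol⁻¹`, `km·mol⁻¹`,
`m²·mol⁻¹`, `L·mol⁻¹·cm⁻¹` (IR) and `C⁴·m²·J⁻²·kg⁻¹`, `m⁴·kg⁻¹`, `Å⁴·amu⁻¹`
(Raman); every factor is derived from CODATA 2018 constants at import time.

## Worked example

Generate a toy solvated system (a 4-center carbonyl-like point-charge core
inside water-like fragments), inspect its energy decomposition, and compute a
snapshot-averaged IR spectrum:

```sh
pespectra fixture --fragments 6 --seed 7 --out demo
pespectra energy --geometry demo/fixture.xyz --potential demo/fixture.pot --out demo_en
pespectra spectrum ir --fragments 6 --seed 7 --snapshots 5 --jitter 0.03 --out demo_sp
```

The energy step prints (hartree):

```json
{
 "e_es": 0.08454197877030196,
 "e_ind": -3.256968546646095,
 "e_lj": 0.0,
 "total": -3.1724265678757932,
 "e_es_per_order": {
  "0": 0.057342185533669404,
  "1": 0.0335308029087847,
  "2": -0.006331009672152426
 }
}
```

`e_es_per_order` is the charge / dipole / quadrupole decomposition of the
electrostatic term; `e_ind` is always stabilizing (its magnitude is large
here because a bare point-charge core is unscreened — see
`docs/methods.md`). `e_lj` is zero because `.pot` files carry no
Lennard-Jones parameters; pass `--lj-table` (a whitespace `element σ ε`
table with a `# units:` header) to include them. The spectrum step prints

```
ir spectrum over 5 snapshot(s): peak 1.1696e+01 [m2/mol] at 1729.5 cm^-1
```

i.e. the strongest broadened band (the carbonyl-like stretch of the toy
core) reaches ≈ 11.7 m²·mol⁻¹ near 1730 cm⁻¹; the gridded spectrum, the
per-mode stick table and the resolved run configuration are written next to
it (`ir_spectrum.csv/.json`, `ir_modes.json`, `run.json`).

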