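# Methods

`dimerpop` models the gas-phase equilibrium among competing proton-bound
dimer complexes of isomeric molecules — the scenario behind the nominal
m/z 629 cluster ion seen in ambient-ionization (DART) spectra of
cannabinoids — and connects that equilibrium back to mass-spectral peak
assignments. This note records the model, its assumptions, the numerical
choices, and what the synthetic-data tests do and do not demonstrate.

## Composite energies

Each species is characterized at two levels of electronic-structure
theory: a geometry/frequency level supplying harmonic frequencies, the
rotational constants and `E_low`, and a larger-basis single point
supplying `E_high`. The composite 0 K energy is

    E0 = E_high + s · ZPE_raw,   ZPE_raw = ½ Σ_k h c ν_k,

with the empirical harmonic scaling factor `s = 0.967` by default (the
value appropriate for the M06-2X/6-311+G(2d,2p)-class frequencies these
records come from; any `0 < s ≤ 1` can be passed). All energy bookkeeping
is in hartree; differences are reported in kcal/mol through the pinned
conversion 1 Eh = 627.5095 kcal/mol in `dimerpop.constants`. Reports round
to one decimal in kcal/mol; full precision is kept internally.

## Binding energies and enthalpies

For a dimer D declared (in a manifest, never inferred) to form from
protonated monomer R1 and neutral monomer R2:

    ΔE_bind = E0(D) − [E0(R1) + E0(R2)]
    ΔH(T)   = H(D,T) − [H(R1,T) + H(R2,T)],   H(0) = E0

Negative values mean a bound complex. Stoichiometry (element counts and
total charge +1) is checked before any arithmetic; proton migration during
dimer optimization is why the protonated-monomer isomer must be declared
explicitly. Ranking sorts by ascending ΔH with a lexicographic name
tie-break (ties below 1e-6 kcal/mol are flagged), and assigns each dimer
`dH_rel = ΔH_i − min_j ΔH_j ≥ 0` — the relative heat of formation at
absolute zero that enters the population model. A flat constant added to
every species' E0 shifts every ΔE_bind by exactly minus that constant (the
dimer counts one species, the monomers two); only per-constituent-
consistent shifts cancel. All *relative* quantities (`dH_rel`, monomer
relative energies, mole fractions) are invariant under flat shifts.

## RRHO partition functions

`q_total = q_trans · q_rot · q_vib · q_elec` under the rigid-rotor /
harmonic-oscillator ideal-gas model:

* `q_trans = (2πmkT/h²)^{3/2} V` with V the per-molecule standard-state
  volume `kT/p°` at p° = 1 bar. The convention is explicit because it is
  inert for the target application — competing dimers are isomers, equal
  masses cancel in the mole fractions (tested) — but matters for anything
  non-isomeric.
* `q_rot`: classical asymmetric-top formula `√π/σ · T^{3/2}/√(Θ_A Θ_B Θ_C)`
  from the three rotational constants (GHz → rotational temperatures), the
  linear-rotor form `T/(σΘ)` for single-constant records. Rotor class is
  decided deterministically: constants equal within 1e-6 GHz are
  degenerate. σ defaults to 1 (these are C1-symmetry molecules) and is
  overridable per record. The classical formula carries the usual
  Euler–Maclaurin error ≈ Θ/(3T); it is below 1% for T ≥ 50 Θ, which for
  these species (Θ ~ mK) is everywhere above a few kelvin.
* `q_vib = Π_k [1 − exp(−hcν_k/kT)]^{-1}`, ZPE-referenced: the zero-point
  energy lives in E0 and only there, so q_vib → 1 as T → 0 and the
  bottom-of-well factor is never double counted. By default the same 0.967
  scaling applied to the ZPE is applied to the frequencies entering q_vib
  and the thermal corrections (`scale_qvib=True`); the toggle exists
  because scaling conventions for partition functions vary and the choice
  is a documented switch, not a guess. Plain RRHO throughout — no
  free-rotor or quasi-harmonic low-frequency treatment, no anharmonicity,
  no conformational averaging.
* `q_elec` is the ground-state degeneracy, default 1 (closed-shell
  species).

Thermal enthalpy: `H(T) = E0 + 5/2 RT (translation + pV) + rotational term
(3/2 RT nonlinear, RT linear, 0 for an atom) + Σ_k hcν_k/(e^{hcν_k/kT}−1)`.
Modes with `hcν/kT > 700` contribute nothing and are skipped to avoid
overflow at T → 0.

## Boltzmann populations

Among n competing dimers,

    X_i(T) = q_i e^{−ΔH_i/RT} / Σ_j q_j e^{−ΔH_j/RT},

with ΔH_i = `dH_rel` (0 K values by default; a finite-T ΔH(T) can be
supplied instead) and R = 1.987204×10⁻³ kcal mol⁻¹ K⁻¹. Weights are
assembled as `ln q_i − ΔH_i/RT` and the per-temperature maximum is
subtracted before exponentiation, so a 60 kcal/mol spread at 50 K cannot
underflow. The default sweep grid is 50–800 K in 5 K steps — fine enough
to bracket a dominance crossover to within one step before refinement.
`crossover_temperature` bisects the continuous model inside the grid
bracket to 0.1 K by default. A uniform shift of all ΔH_i cancels
algebraically in X_i; `sensitivity_uniform_shift` verifies this to
rounding (≤1e-12 observed), and per-entry shifts expose genuine
sensitivity. `report_at_temperature` prints populations side by side at an
instrument set temperature and at `T_set − gap_offset`, because the gas
stream actually reaching the sampling region of a DART source runs
measurably cooler (≈100 K) than the set point.

`fit_enthalpy_gap` inverts a population table by ordinary least squares on
ln(X_A/X_B) against 1/T (van 't Hoff style): slope × R is the enthalpy
gap, the intercept the log partition-function ratio. The inversion is
exact when the q-ratio is temperature independent; for real systems with
different vibrational structures it returns an effective gap.

## Mass-spectral adducts

Monoisotopic masses come from an isotope table pinned in
`dimerpop.constants` (AME2020 values, 8 d.p.), never from a dependency, so
4-decimal outputs cannot drift. Nominal masses are integer mass-number
sums. Adduct m/z for the singly charged species of interest
([M+H]⁺, [2M+H]⁺, [M+NH4]⁺, [2M+NH4]⁺, [2M]⁺·) is
`multiplier × M + delta − (m_e under the proton convention)`. The default
`h_atom` convention adds a neutral hydrogen atom mass (1.00783) with no
electron-mass correction, reproducing the conventional printed values
(C21H30O2 → 314.2246, +H → 315.2324, dimer 629.4570); the physically
strict `proton` convention (−0.00055) is a flag. Peak annotation matches
each centroid to the candidate within a ppm tolerance (default 5 ppm,
appropriate for a ~10,000-FWHM TOF), tie-breaking by |ppm| then adduct
name then formula, so results are independent of peak and candidate order.
The ppm sign convention is (observed − calc)/calc × 10⁶. Peak lists are
read from two-column text or from centroid mzML (a minimal lxml-based
reader decoding the PSI-MS-accession-keyed base64 arrays, zlib or plain,
32- or 64-bit).

## Text dialect and JSON schema

One QC-output text dialect is parsed (see `docs/qc_dialect_example.txt`):
marker lines for charge/multiplicity, stoichiometry, standard orientation,
rotational constants in GHz, `SCF Done` energies, `Frequencies --` tables,
zero-point correction, molecular mass, and a mandatory `Normal
termination` sentinel; a `--Link1--` section carries the larger-basis
single point whose energy becomes `E_high`. Truncated or unterminated
streams raise a parse error naming the missing marker; any negative
frequency raises a validation error listing the offending modes (records
are only accepted as minima when all frequencies are strictly positive and
the count is 3N−6 / 3N−5). The canonical JSON schema (version 1) stores
the same fields with fixed units (hartree, cm⁻¹, GHz, Å, amu); write∘read
is the identity, unknown fields and role/charge inconsistencies are
rejected, and a stored mass must agree with the formula mass within
0.01 amu.

## Synthetic data: what it shows and what it does not

`synthetic_data` generates records whose *structure* matches real
frequency-job output — 3N−6 strictly positive frequencies in 30–3500 cm⁻¹,
three descending rotational constants in 0.01–1 GHz (plausible magnitudes
for organic cations of tens of atoms), non-overlapping geometries, and
composite energies with injected enthalpy gaps (default spread 0, 0.4,
1.2 kcal/mol, the magnitude regime where homodimer/heterodimer competition
is interesting). Every numeric field is rounded to the precision the text
dialect prints, so render → parse round-trips bit-exactly. Dimer systems
default to *shared* vibrational/rotational structure across entries, which
makes the population closed form and the van 't Hoff inversion exact —
that is precisely what the oracle tests need. What passing these tests
does **not** show: that RRHO is adequate for floppy hydrogen-bonded
complexes (low-frequency modes are treated harmonically), or that real
isomeric dimers share partition functions (they do not; their q-ratios
drive the observed temperature dependence). Conclusions about real systems
require real frequency data fed through the same pipeline. Peak-list
generation plants adducts with ≤ `mz_jitter_ppm` mass error and noise
peaks at least 50 ppm from any candidate, so annotation recovery is a
sharp contract rather than a statistical claim.

## Problem sizes

Default test and acceptance runs use monomer-sized formulas of ~15–30
atoms (45–90 modes) and 151-point temperature grids; these sizes make
every oracle comparison exact-arithmetic-dominated and keep the whole
suite in seconds while exercising the same code paths a 100+-atom dimer
record would.

## Known limitations

* Single text dialect; other engines' outputs must be converted to the
  JSON schema externally.
* No counterpoise (BSSE) correction, no anharmonic or hindered-rotor
  corrections, no conformational ensembles per species.
* Equilibrium populations only — no kinetics of dimer formation or
  dissociation in the ion source.
* Isotope table covers the common organic/hetero elements; extend
  `constants.MONOISOTOPIC_MASS` for exotic ones.
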