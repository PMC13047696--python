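"""Reproducible synthetic fixtures for every pipeline stage.

The generators emulate the statistical structure of electronic-structure
frequency output — all-positive harmonic spectra, three rotational
constants, composite electronic energies with controlled enthalpy gaps —
and of centroided ambient-ionization spectra (a protonated-monomer base
peak, a trace proton-bound-dimer peak, noise). They make no attempt at
chemically realistic cannabinoid conformers; structural validity is the
contract: every generated record passes ``validate_minimum`` and every
rendered transcript round-trips through ``parse_qc_output`` exactly.

All numeric fields are rounded to the precision the text dialect prints,
so render → parse reproduces the generating record bit-exactly. A fixed
seed gives bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from . import constants
from .ms_adducts import (
    STANDARD_ADDUCTS,
    adduct_mz,
    formula_string,
    monoisotopic_mass,
    parse_formula,
)
from .population import DimerSystem, PopulationEntry
from .species_io import Role, SpeciesRecord
from .thermochem import partition_functions

__all__ = [
    "GeneratorConfig",
    "make_species",
    "make_dimer_system",
    "render_qc_fixture",
    "make_peaklist",
    "SystemGroundTruth",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs for the fixture generators; identical seeds give identical output.

    Frequency and rotational-constant ranges default to values plausible for
    mid-sized (tens of atoms) organic cations: 30–3500 cm^-1 and
    0.01–1 GHz.
    """

    seed: int = 0
    freq_range: tuple[float, float] = (30.0, 3500.0)
    rot_range: tuple[float, float] = (0.01, 1.0)
    energy_base: float = -1000.0  # hartree
    dH_gaps: tuple[float, ...] = (0.0, 0.4, 1.2)  # kcal/mol
    noise_peaks: int = 5
    mz_jitter_ppm: float = 2.0

    def __post_init__(self) -> None:
        if self.freq_range[0] <= 0:
            raise ValueError("minimum frequency must be positive")


_ROLE_CHARGE = {
    Role.NEUTRAL_MONOMER: 0,
    Role.PROTONATED_MONOMER: 1,
    Role.PROTON_BOUND_DIMER: 1,
}


def _grid_geometry(rng: np.random.Generator, elements: list[str]):
    """Atoms on a jittered cubic grid: spacing 1.5 Å, jitter < ±0.3 Å,
    so no two atoms can coincide."""
    n = len(elements)
    side = max(2, math.ceil(n ** (1 / 3)))
    geom = []
    for k, el in enumerate(elements):
        i, j, l = k % side, (k // side) % side, k // side**2
        base = np.array([i, j, l], dtype=float) * 1.5
        pos = base + rng.uniform(-0.3, 0.3, size=3)
        geom.append((el, *(round(float(c), 6) for c in pos)))
    return geom


def make_species(
    config: GeneratorConfig,
    role: Role | str = Role.NEUTRAL_MONOMER,
    formula: str = "C6H8O",
    label: str | None = None,
    protonation_site: int | None = None,
    with_single_point: bool = True,
) -> SpeciesRecord:
    """Generate one schema-valid species record.

    3N−6 positive frequencies are drawn from ``freq_range``, three
    rotational constants from ``rot_range`` (sorted descending), and the
    geometry places the formula's atoms without overlaps. The record always
    passes ``validate_minimum``.
    """
    role = Role(role)
    counts = parse_formula(formula)
    n_atoms = sum(counts.values())
    if n_atoms < 2:
        raise ValueError(f"need at least 2 atoms, formula {formula!r} has {n_atoms}")
    rng = np.random.default_rng(config.seed)
    n_modes = 3 * n_atoms - 6
    freqs = np.sort(rng.uniform(*config.freq_range, size=n_modes))
    freqs = [round(float(f), 4) for f in freqs]
    rot = sorted(
        (round(float(b), 6) for b in rng.uniform(*config.rot_range, size=3)),
        reverse=True,
    )
    elements = [el for el, n in counts.items() for _ in range(n)]
    geometry = _grid_geometry(rng, elements)
    e_low = round(config.energy_base + float(rng.uniform(-0.05, 0.05)), 9)
    e_high = round(e_low - float(rng.uniform(0.0, 0.02)), 9) if with_single_point else None
    zpe = round(0.5 * sum(freqs) / constants.HARTREE_IN_INV_CM, 6)
    record = SpeciesRecord(
        label=label or f"synthetic-{formula}-{config.seed}",
        formula=formula_string(counts),
        charge=_ROLE_CHARGE[role],
        multiplicity=1,
        role=role,
        protonation_site=protonation_site,
        E_low=e_low,
        E_high=e_high,
        zpe_raw=zpe,
        frequencies=freqs,
        rot_constants=rot,
        mass=round(monoisotopic_mass(counts), 5),
        geometry=geometry,
    )
    record.validate(strict=True)
    return record


@dataclass
class SystemGroundTruth:
    """What a generated dimer system actually contains, for recovery tests."""

    labels: list[str]
    gaps: list[float]  # kcal/mol, gaps[0] == 0
    shared_thermo: bool
    seed: int
    records: list[SpeciesRecord] = field(default_factory=list)


def make_dimer_system(
    config: GeneratorConfig,
    formula: str = "C12H17O2",
    shared_thermo: bool = True,
    include_translation: bool = True,
) -> tuple[DimerSystem, SystemGroundTruth]:
    """A set of competing proton-bound dimers with injected dH gaps.

    ``shared_thermo=True`` (default) gives every entry the same vibrational
    and rotational structure, so all partition-function ratios are exactly 1
    and the populations follow the closed-form Boltzmann ratio of the gaps —
    the regime where the van 't Hoff inversion recovers the gaps exactly.
    With ``shared_thermo=False`` each entry gets its own record and the
    q-ratios differ.
    """
    gaps = list(config.dH_gaps)
    if not gaps or abs(gaps[0]) > 1e-12:
        raise ValueError("dH_gaps must be non-empty with first element 0")
    labels = [f"dimer_{k + 1}" for k in range(len(gaps))]
    records = []
    for k, lbl in enumerate(labels):
        sub = config if shared_thermo else replace(config, seed=config.seed + 1000 + k)
        rec = make_species(sub, Role.PROTON_BOUND_DIMER, formula, label=lbl,
                           protonation_site=1)
        records.append(rec)

    def make_ln_q(rec: SpeciesRecord):
        def ln_q(T: float) -> float:
            return partition_functions(
                rec, T, include_translation=include_translation
            ).ln_q_total
        return ln_q

    entries = [
        PopulationEntry(lbl, make_ln_q(rec), gap)
        for lbl, rec, gap in zip(labels, records, gaps)
    ]
    system = DimerSystem(entries)
    truth = SystemGroundTruth(
        labels=labels, gaps=gaps, shared_thermo=shared_thermo,
        seed=config.seed, records=records,
    )
    return system, truth


# ---------------------------------------------------------------------------
# QC-output rendering (the inverse of species_io.parse_qc_output)
# ---------------------------------------------------------------------------

_HEADER = " Entering Gaussian System, Link 0\n"
_SEP = " " + "-" * 69 + "\n"


def _geometry_block(record: SpeciesRecord) -> str:
    lines = [
        "                         Standard orientation:\n",
        _SEP,
        " Center     Atomic      Atomic             Coordinates (Angstroms)\n",
        " Number     Number       Type             X           Y           Z\n",
        _SEP,
    ]
    for k, (el, x, y, z) in enumerate(record.geometry, 1):
        z_num = constants.ATOMIC_NUMBER[el]
        lines.append(f" {k:6d} {z_num:10d} {0:11d}    {x:11.6f} {y:11.6f} {z:11.6f}\n")
    lines.append(_SEP)
    return "".join(lines)


def render_qc_fixture(record: SpeciesRecord, dialect: str = "g16-like") -> str:
    """Render a record as a QC-output transcript that parses back exactly.

    A record carrying frequencies renders as a frequency job (energy line is
    ``E_low``); if ``E_high`` is also present a ``--Link1--`` single-point
    section is appended. A record with no frequencies renders as a
    single-point-only job whose energy line is ``E_high``.
    """
    if dialect != "g16-like":
        raise ValueError(f"unsupported dialect {dialect!r}")
    title = f" label={record.label} role={record.role.value}"
    if record.protonation_site is not None:
        title += f" site={record.protonation_site}"
    title += f" sigma={record.sigma_rot:g} gelec={record.elec_degeneracy}\n"
    charge_tag = "" if record.charge == 0 else f"({record.charge:d}+)"
    out = [
        _HEADER, _SEP, title, _SEP,
        f" Charge = {record.charge:2d} Multiplicity = {record.multiplicity}\n",
        f" Stoichiometry    {record.formula}{charge_tag}\n",
    ]
    if record.geometry:
        out.append(_geometry_block(record))
    if record.rot_constants:
        vals = "".join(f"{b:16.6f}" for b in record.rot_constants)
        out.append(f" Rotational constants (GHZ):{vals}\n")
    is_freq_job = bool(record.frequencies)
    energy = record.E_low if is_freq_job else record.E_high
    if energy is not None:
        out.append(
            f" SCF Done:  E(RM062X) = {energy:17.9f}     A.U. after   11 cycles\n"
        )
    if is_freq_job:
        out.append(" Harmonic frequencies (cm**-1):\n")
        for k in range(0, len(record.frequencies), 3):
            chunk = record.frequencies[k:k + 3]
            out.append(" Frequencies --" + "".join(f"{f:12.4f}" for f in chunk) + "\n")
        if record.zpe_raw is not None:
            out.append(
                f" Zero-point correction= {record.zpe_raw:34.6f} (Hartree/Particle)\n"
            )
    if record.mass is not None:
        out.append(f" Molecular mass: {record.mass:12.5f} amu.\n")
    out.append(" Normal termination of Gaussian 16.\n")
    if is_freq_job and record.E_high is not None:
        out += [
            " --Link1--\n",
            f" SCF Done:  E(RM062X) = {record.E_high:17.9f}     A.U. after    1 cycles\n",
            " Normal termination of Gaussian 16.\n",
        ]
    return "".join(out)


# ---------------------------------------------------------------------------
# Peak lists
# ---------------------------------------------------------------------------

def make_peaklist(
    base_formula: str,
    adduct_intensities: Mapping[str, float],
    config: GeneratorConfig,
    base_intensity: float = 1.0e6,
    mz_window: tuple[float, float] = (60.0, 700.0),
) -> tuple[list[tuple[float, float]], list[tuple[str, float]]]:
    """A centroided peak list with planted adducts plus noise.

    ``adduct_intensities`` maps adduct names (e.g. ``"[M+H]+"``) to relative
    intensities in percent of the base peak (100 = base peak). Planted m/z
    values are jittered by up to ``mz_jitter_ppm``; noise peaks are placed
    at least 50 ppm away from every standard-adduct candidate so annotation
    recovers exactly the planted set.

    Returns ``(peaks, planted)`` where planted is [(adduct name, true m/z)].
    """
    rng = np.random.default_rng(config.seed)
    peaks: list[tuple[float, float]] = []
    planted: list[tuple[str, float]] = []
    for name, rel in adduct_intensities.items():
        mz = adduct_mz(base_formula, name)
        jitter = 1.0 + float(rng.uniform(-1, 1)) * config.mz_jitter_ppm * 1e-6
        peaks.append((mz * jitter, base_intensity * rel / 100.0))
        planted.append((name, mz))
    exclusion = [adduct_mz(base_formula, a) for a in STANDARD_ADDUCTS]
    n_placed = 0
    while n_placed < config.noise_peaks:
        mz = float(rng.uniform(*mz_window))
        if all(abs(mz - c) / c > 50e-6 for c in exclusion):
            peaks.append((mz, base_intensity * float(rng.uniform(1e-4, 5e-3))))
            n_placed += 1
    peaks.sort()
    return peaks, planted
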