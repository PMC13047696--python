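"""ZPE-scaled composite energies and rigid-rotor/harmonic-oscillator
partition functions.

The composite 0 K energy of a species is

    E0 = E_high + scale * ZPE_raw,

with ``E_high`` the larger-basis single-point electronic energy and the
harmonic zero-point energy scaled by an empirical factor (default 0.967).

Partition functions follow the standard ideal-gas RRHO expressions:

* translation — per-molecule ideal-gas value at a declared standard-state
  volume (default the molar volume at 1 bar and T),
* rotation    — classical rigid-rotor (asymmetric-top / linear) value from
  the rotational constants and symmetry number,
* vibration   — ZPE-referenced harmonic product
  q_vib = prod_k 1/(1 - exp(-h c nu_k / k_B T)); the zero-point energy is
  carried in E0, never in q_vib, so the two are not double counted,
* electronic  — the ground-state degeneracy.

The vibrational frequencies entering q_vib and the thermal corrections are
scaled by the same ZPE factor by default (``scale_qvib=True``); pass
``scale_qvib=False`` to use raw harmonic frequencies there while keeping the
scaled ZPE in E0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from . import constants
from .species_io import SpeciesRecord, ROT_DEGENERACY_TOL_GHZ

__all__ = [
    "ThermoState",
    "scaled_zpe",
    "composite_energy",
    "partition_functions",
    "thermal_enthalpy",
    "ZPE_SCALE_DEFAULT",
]

ZPE_SCALE_DEFAULT = 0.967


def scaled_zpe(frequencies: Sequence[float], scale: float = ZPE_SCALE_DEFAULT) -> float:
    """Scaled harmonic zero-point energy, hartree: scale * sum(h c nu / 2).

    Linear in ``scale``; an empty mode list gives exactly 0.
    """
    if not 0 < scale <= 1:
        raise ValueError(f"scale must be in (0, 1], got {scale}")
    total = 0.0
    for k, nu in enumerate(frequencies):
        if nu <= 0:
            raise ValueError(f"non-positive frequency at mode {k}: {nu} cm^-1")
        total += nu
    return scale * 0.5 * total / constants.HARTREE_IN_INV_CM


def composite_energy(
    freq_record: SpeciesRecord,
    sp_record: SpeciesRecord | None = None,
    scale: float = ZPE_SCALE_DEFAULT,
) -> float:
    """ZPE-corrected composite electronic energy at 0 K, hartree.

    ``freq_record`` supplies the harmonic frequencies; ``sp_record`` the
    single-point energy ``E_high``. When the two jobs were combined into one
    record (E_high attached), pass that record alone.
    """
    if sp_record is None:
        sp_record = freq_record
    if (freq_record.formula, freq_record.charge) != (sp_record.formula, sp_record.charge):
        raise ValueError(
            "records describe different species: "
            f"{freq_record.formula}({freq_record.charge:+d}) vs "
            f"{sp_record.formula}({sp_record.charge:+d})"
        )
    if sp_record.E_high is None:
        raise ValueError(f"record {sp_record.label!r} has no single-point energy E_high")
    return sp_record.E_high + scaled_zpe(freq_record.frequencies, scale)


@dataclass(frozen=True)
class ThermoState:
    """Partition-function components of one species at one temperature.

    All q's are dimensionless; ``q_total`` is exactly their product and
    ``ln_q_total`` its logarithm (computed in log space, safe for large q).
    ``E0`` is the composite 0 K energy in hartree when available.
    """

    species_label: str
    T: float
    q_trans: float
    q_rot: float
    q_vib: float
    q_elec: float
    ln_q_total: float
    E0: float | None = None

    @property
    def q_total(self) -> float:
        return self.q_trans * self.q_rot * self.q_vib * self.q_elec


def _rotor_class(rot_ghz: Sequence[float], linear: bool) -> str:
    if linear or len(rot_ghz) == 1:
        return "linear"
    if len(rot_ghz) != 3:
        raise ValueError(f"expected 1 or 3 rotational constants, got {len(rot_ghz)}")
    a, b, c = rot_ghz
    eq_ab = abs(a - b) < ROT_DEGENERACY_TOL_GHZ
    eq_bc = abs(b - c) < ROT_DEGENERACY_TOL_GHZ
    if eq_ab and eq_bc:
        return "spherical"
    if eq_ab or eq_bc:
        return "symmetric"
    return "asymmetric"


def _theta_rot(B_ghz: float) -> float:
    """Rotational temperature in K for a rotational constant in GHz."""
    return constants.PLANCK_J_S * B_ghz * 1e9 / constants.BOLTZMANN_J_K


def ln_q_translational(mass_amu: float, T: float,
                       pressure_pa: float = constants.STANDARD_PRESSURE_PA) -> float:
    m = mass_amu * constants.AMU_KG
    lam_sq = constants.PLANCK_J_S ** 2 / (
        2.0 * math.pi * m * constants.BOLTZMANN_J_K * T
    )
    volume = constants.BOLTZMANN_J_K * T / pressure_pa
    return 1.5 * math.log(1.0 / lam_sq) + math.log(volume)


def ln_q_rotational(rot_ghz: Sequence[float], T: float, sigma: float,
                    linear: bool = False) -> float:
    cls = _rotor_class(rot_ghz, linear)
    if cls == "linear":
        theta = _theta_rot(rot_ghz[0])
        return math.log(T / (sigma * theta))
    thetas = [_theta_rot(b) for b in rot_ghz]
    return (
        0.5 * math.log(math.pi)
        - math.log(sigma)
        + 1.5 * math.log(T)
        - 0.5 * sum(math.log(th) for th in thetas)
    )


def ln_q_vibrational(frequencies: Sequence[float], T: float) -> float:
    """ZPE-referenced harmonic-oscillator product, in log space."""
    kT_cm = constants.KB_INV_CM_K * T
    total = 0.0
    for nu in frequencies:
        total -= math.log1p(-math.exp(-nu / kT_cm))
    return total


def partition_functions(
    record: SpeciesRecord,
    T: float,
    scale: float = ZPE_SCALE_DEFAULT,
    scale_qvib: bool = True,
    include_translation: bool = True,
    pressure_pa: float = constants.STANDARD_PRESSURE_PA,
    E0: float | None = None,
) -> ThermoState:
    """RRHO partition functions of ``record`` at temperature ``T`` (K).

    ``include_translation=False`` sets q_trans = 1, useful when comparing
    isomeric species for which the equal translational factors cancel.
    """
    if T <= 0:
        raise ValueError(f"temperature must be positive, got {T} K")
    if record.frequencies and not all(nu > 0 for nu in record.frequencies):
        raise ValueError("record has non-positive frequencies; not a validated minimum")

    if include_translation:
        if record.mass is None:
            raise ValueError(f"record {record.label!r} has no mass")
        ln_qt = ln_q_translational(record.mass, T, pressure_pa)
    else:
        ln_qt = 0.0

    if record.rot_constants:
        ln_qr = ln_q_rotational(record.rot_constants, T, record.sigma_rot, record.linear)
    elif record.n_atoms <= 1:
        ln_qr = 0.0  # atom: no rotational degrees of freedom
    else:
        raise ValueError(f"record {record.label!r} has no rotational constants")

    freqs = record.frequencies
    if scale_qvib and freqs:
        freqs = [scale * nu for nu in freqs]
    ln_qv = ln_q_vibrational(freqs, T)

    q_elec = float(record.elec_degeneracy)
    ln_total = ln_qt + ln_qr + ln_qv + math.log(q_elec)
    if E0 is None and record.E_high is not None and record.frequencies:
        E0 = composite_energy(record, scale=scale)
    return ThermoState(
        species_label=record.label,
        T=T,
        q_trans=math.exp(ln_qt),
        q_rot=math.exp(ln_qr),
        q_vib=math.exp(ln_qv),
        q_elec=q_elec,
        ln_q_total=ln_total,
        E0=E0,
    )


def _vibrational_thermal_energy(frequencies: Sequence[float], T: float) -> float:
    """ZPE-referenced vibrational thermal energy, hartree:
    sum_k (h c nu_k) / (exp(h c nu_k / k_B T) - 1)."""
    kT_cm = constants.KB_INV_CM_K * T
    total_cm = 0.0
    for nu in frequencies:
        x = nu / kT_cm
        if x > 700.0:  # exp would overflow; the mode is frozen out
            continue
        total_cm += nu / math.expm1(x)
    return total_cm / constants.HARTREE_IN_INV_CM


def thermal_enthalpy(
    record: SpeciesRecord,
    T: float,
    scale: float = ZPE_SCALE_DEFAULT,
    scale_qvib: bool = True,
    E0: float | None = None,
) -> float:
    """Ideal-gas RRHO enthalpy H(T) in hartree.

    H(T) = E0 + 3/2 RT (translation) + RT (pV) + rotational term
    (3/2 RT asymmetric/ symmetric top, RT linear, 0 for an atom) + the
    ZPE-referenced vibrational thermal energy. H(0) = E0 by construction.
    """
    if T <= 0:
        raise ValueError(f"temperature must be positive, got {T} K")
    if E0 is None:
        E0 = composite_energy(record, scale=scale)
    kT = constants.KB_HARTREE_K * T
    h = E0 + 2.5 * kT  # translation + pV
    if record.rot_constants:
        cls = _rotor_class(record.rot_constants, record.linear)
        h += kT if cls == "linear" else 1.5 * kT
    freqs = record.frequencies
    if scale_qvib and freqs:
        freqs = [scale * nu for nu in freqs]
    h += _vibrational_thermal_energy(freqs, T)
    return h
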