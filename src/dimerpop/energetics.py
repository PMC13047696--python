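"""Binding energies and enthalpy differences of proton-bound dimers.

For a dimer D formed from a protonated monomer R1 and a neutral monomer R2,

    dE_bind = E0(D) - [E0(R1) + E0(R2)]     (kcal/mol; negative = bound)
    dH      = H(D)  - [H(R1)  + H(R2)]      (same at T -> 0, where H = E0)

Every dimer/monomer triple is stoichiometry-checked (element counts of the
dimer must equal R1 + R2; total charge +1) before any arithmetic. Ranking
assigns each dimer its enthalpy relative to the most stable one
(``dH_rel >= 0``, exactly one zero per system), which is the relative heat
of formation entering the Boltzmann population model.

The pairing of each dimer with its as-optimized protonated-monomer isomer is
declared explicitly in a manifest (tab-separated: dimer label, protonated
monomer label, neutral monomer label) rather than inferred from geometry —
proton migration during dimer optimization makes the energies site-specific.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import pandas as pd

from . import constants
from .ms_adducts import parse_formula
from .species_io import SpeciesRecord

__all__ = [
    "DimerEntry",
    "StoichiometryError",
    "check_stoichiometry",
    "binding_energy",
    "enthalpy_difference",
    "rank_dimers",
    "monomer_relative_energies",
    "read_manifest",
    "compute_energy_table",
]

#: Two dimers closer than this in kcal/mol are flagged as tied in rankings.
TIE_TOL_KCAL = 1e-6


class StoichiometryError(ValueError):
    """Element or charge conservation violated by a dimer/monomer triple."""


@dataclass
class DimerEntry:
    """One dimer with its declared monomer pair and computed energetics."""

    name: str
    dimer: SpeciesRecord
    protonated_monomer: SpeciesRecord
    neutral_monomer: SpeciesRecord
    dE_bind: float | None = None  # kcal/mol
    dH: float | None = None       # kcal/mol
    dH_rel: float | None = None   # kcal/mol, >= 0 after ranking
    tied: bool = False


def check_stoichiometry(entry: DimerEntry) -> None:
    """Raise unless element counts and charge are conserved: D = R1 + R2."""
    d = parse_formula(entry.dimer.formula)
    r1 = parse_formula(entry.protonated_monomer.formula)
    r2 = parse_formula(entry.neutral_monomer.formula)
    total = dict(r1)
    for el, n in r2.items():
        total[el] = total.get(el, 0) + n
    if total != d:
        raise StoichiometryError(
            f"{entry.name}: dimer formula {entry.dimer.formula} != "
            f"{entry.protonated_monomer.formula} + {entry.neutral_monomer.formula}"
        )
    q = entry.protonated_monomer.charge + entry.neutral_monomer.charge
    if entry.dimer.charge != q or q != 1:
        raise StoichiometryError(
            f"{entry.name}: charge not conserved "
            f"({entry.dimer.charge} vs {q}; proton-bound dimers carry +1)"
        )


def _lookup(energies: Mapping[str, float], label: str) -> float:
    try:
        return energies[label]
    except KeyError:
        raise KeyError(f"no energy provided for species {label!r}") from None


def binding_energy(entry: DimerEntry, energies: Mapping[str, float]) -> float:
    """dE_bind in kcal/mol from a map of composite 0 K energies (hartree)."""
    check_stoichiometry(entry)
    de_h = (
        _lookup(energies, entry.dimer.label)
        - _lookup(energies, entry.protonated_monomer.label)
        - _lookup(energies, entry.neutral_monomer.label)
    )
    return de_h * constants.HARTREE_IN_KCAL_MOL


def enthalpy_difference(entry: DimerEntry, enthalpies: Mapping[str, float]) -> float:
    """dH in kcal/mol from a map of enthalpies H(T) (hartree)."""
    # identical arithmetic; H(0) = E0 makes the two coincide at 0 K
    return binding_energy(entry, enthalpies)


def rank_dimers(entries: Sequence[DimerEntry]) -> list[DimerEntry]:
    """Sort by ascending dH (most stable first) and assign dH_rel.

    The sort is stable with a lexicographic tie-break on name; entries whose
    gap to a neighbour is below ``TIE_TOL_KCAL`` are flagged ``tied``.
    """
    if not entries:
        raise ValueError("cannot rank an empty dimer list")
    for e in entries:
        if e.dH is None:
            raise ValueError(f"entry {e.name!r} has no dH; compute it first")
    ordered = sorted(entries, key=lambda e: (e.dH, e.name))
    h_min = ordered[0].dH
    out = [replace(e, dH_rel=e.dH - h_min) for e in ordered]
    for i, e in enumerate(out):
        tied = (i > 0 and abs(e.dH - out[i - 1].dH) < TIE_TOL_KCAL) or (
            i + 1 < len(out) and abs(e.dH - out[i + 1].dH) < TIE_TOL_KCAL
        )
        e.tied = tied
    return out


def monomer_relative_energies(
    records: Sequence[SpeciesRecord],
    energies: Mapping[str, float],
    reference_label: str,
) -> dict[str, float]:
    """Relative 0 K energies of isomeric monomers, kcal/mol vs a reference.

    All records must share one molecular formula (constitutional isomers);
    the reference maps to exactly 0.
    """
    labels = [r.label for r in records]
    if reference_label not in labels:
        raise KeyError(f"reference {reference_label!r} not among {labels}")
    formulas = {r.formula for r in records}
    if len(formulas) != 1:
        raise StoichiometryError(
            f"monomers are not isomers: multiple formulas {sorted(formulas)}"
        )
    e_ref = _lookup(energies, reference_label)
    return {
        r.label: (_lookup(energies, r.label) - e_ref) * constants.HARTREE_IN_KCAL_MOL
        for r in records
    }


# ---------------------------------------------------------------------------
# Manifest-driven batch computation
# ---------------------------------------------------------------------------

def read_manifest(stream) -> list[tuple[str, str, str, str]]:
    """Read a tab/whitespace-separated manifest:
    dimer_name  dimer_label  protonated_label  neutral_label.

    Lines starting with '#' are comments. A three-column form reuses the
    dimer label as the entry name.
    """
    text = stream if isinstance(stream, str) else stream.read()
    rows = []
    for ln, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) == 3:
            parts = [parts[0]] + parts
        if len(parts) != 4:
            raise ValueError(f"manifest line {ln}: expected 3 or 4 columns, got {len(parts)}")
        rows.append(tuple(parts))
    return rows


def compute_energy_table(
    manifest: Sequence[tuple[str, str, str, str]],
    records: Mapping[str, SpeciesRecord],
    scale: float = 0.967,
    T: float | None = None,
) -> pd.DataFrame:
    """Binding energies (and dH at ``T`` if given) for every manifest row.

    Returns a DataFrame ordered by ascending dH (or dE_bind when no T),
    with ``dH_rel`` relative to the most stable dimer. Internally full
    precision; round on output for display.
    """
    from .thermochem import composite_energy, thermal_enthalpy

    e0 = {r.label: composite_energy(r, scale=scale) for r in records.values()}
    if T is not None:
        h = {r.label: thermal_enthalpy(r, T, scale=scale, E0=e0[r.label])
             for r in records.values()}
    entries = []
    for name, d, r1, r2 in manifest:
        for lbl in (d, r1, r2):
            if lbl not in records:
                raise KeyError(f"manifest references unknown species {lbl!r}")
        entry = DimerEntry(name, records[d], records[r1], records[r2])
        entry.dE_bind = binding_energy(entry, e0)
        if T is not None:
            entry.dH = enthalpy_difference(entry, h)
        else:
            entry.dH = entry.dE_bind  # 0 K: dH == dE_bind
        entries.append(entry)
    ranked = rank_dimers(entries)
    return pd.DataFrame(
        {
            "name": [e.name for e in ranked],
            "dE_bind_kcal": [e.dE_bind for e in ranked],
            "dH_kcal": [e.dH for e in ranked],
            "dH_rel_kcal": [e.dH_rel for e in ranked],
            "tied": [e.tied for e in ranked],
        }
    )
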