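"""Species records: quantum-chemistry output parsing and canonical JSON I/O.

A :class:`SpeciesRecord` bundles everything the downstream thermochemistry
needs for one chemical species — electronic energies, harmonic frequencies,
rotational constants, geometry, charge/multiplicity and its role in the
dimer system (neutral monomer, protonated monomer, or proton-bound dimer).

Two on-disk representations are supported:

* a single plain-text QC-output dialect (Gaussian-flavoured frequency /
  single-point job transcripts; see ``docs/qc_dialect_example.txt``), and
* a canonical versioned JSON schema that decouples the rest of the package
  from that dialect.

Units are fixed: energies in hartree, frequencies in cm^-1, rotational
constants in GHz, coordinates in Å, masses in amu. Atom indices in the API
are 0-based.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field, asdict
from enum import Enum
from typing import Sequence

from . import constants
from .ms_adducts import parse_formula, monoisotopic_mass

SCHEMA_VERSION = 1

#: Two rotational constants closer than this (GHz) are treated as degenerate
#: when classifying the rotor.
ROT_DEGENERACY_TOL_GHZ = 1e-6

__all__ = [
    "Role",
    "SpeciesRecord",
    "ParseError",
    "ValidationError",
    "MinimumReport",
    "validate_minimum",
    "interatomic_distance",
    "parse_qc_output",
    "read_species_json",
    "write_species_json",
]


class Role(str, Enum):
    NEUTRAL_MONOMER = "neutral_monomer"
    PROTONATED_MONOMER = "protonated_monomer"
    PROTON_BOUND_DIMER = "proton_bound_dimer"


class ParseError(ValueError):
    """A QC-output stream is truncated or missing a required marker."""


class ValidationError(ValueError):
    """A record violates a schema rule or physical invariant."""


@dataclass
class SpeciesRecord:
    """One chemical species as extracted from electronic-structure output.

    ``E_low`` is the electronic energy at the geometry/frequency level of
    theory; ``E_high`` the larger-basis single-point energy (``None`` until a
    single-point job is attached). ``zpe_raw`` is the unscaled harmonic
    zero-point energy.
    """

    label: str
    formula: str
    charge: int
    multiplicity: int
    role: Role
    protonation_site: int | None = None
    E_low: float | None = None
    E_high: float | None = None
    zpe_raw: float | None = None
    frequencies: list[float] = field(default_factory=list)
    rot_constants: list[float] = field(default_factory=list)
    linear: bool = False
    mass: float | None = None
    sigma_rot: float = 1.0
    elec_degeneracy: int = 1
    geometry: list[tuple[str, float, float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.role = Role(self.role)
        self.geometry = [(el, float(x), float(y), float(z)) for el, x, y, z in self.geometry]

    @property
    def n_atoms(self) -> int:
        return len(self.geometry)

    @property
    def expected_mode_count(self) -> int:
        n = self.n_atoms
        if n <= 1:
            return 0
        return 3 * n - 5 if self.linear else 3 * n - 6

    def validate(self, strict: bool = True) -> None:
        """Check schema rules and physical invariants; raise on violation."""
        counts = parse_formula(self.formula)
        if any(n < 0 for n in counts.values()):
            raise ValidationError("formula: negative element count")
        if self.role is Role.NEUTRAL_MONOMER and self.charge != 0:
            raise ValidationError(
                f"role {self.role.value} requires charge 0, got {self.charge}"
            )
        if self.role in (Role.PROTONATED_MONOMER, Role.PROTON_BOUND_DIMER) and self.charge != 1:
            raise ValidationError(
                f"role {self.role.value} requires charge +1, got {self.charge}"
            )
        if self.mass is not None:
            recomputed = monoisotopic_mass(counts)
            if abs(recomputed - self.mass) > 0.01:
                raise ValidationError(
                    f"mass {self.mass} amu disagrees with formula mass "
                    f"{recomputed:.5f} amu by more than 0.01"
                )
        if self.geometry:
            geom_counts: dict[str, int] = {}
            for el, *_ in self.geometry:
                geom_counts[el] = geom_counts.get(el, 0) + 1
            if geom_counts != counts:
                raise ValidationError(
                    f"geometry element counts {geom_counts} do not match formula {self.formula}"
                )
        if strict and self.frequencies:
            report = validate_minimum(self)
            if not report.ok:
                raise ValidationError("; ".join(report.problems))
        if strict and self.role is Role.PROTON_BOUND_DIMER and not self.frequencies:
            raise ValidationError(
                "frequencies: required for role proton_bound_dimer under strict validation"
            )


@dataclass(frozen=True)
class MinimumReport:
    """Outcome of checking that a record is a true local minimum."""

    ok: bool
    problems: tuple[str, ...]


def validate_minimum(record: SpeciesRecord) -> MinimumReport:
    """Pass iff all frequencies are strictly positive and the mode count is
    3N−6 (nonlinear) / 3N−5 (linear)."""
    problems: list[str] = []
    for k, nu in enumerate(record.frequencies):
        if nu <= 0:
            kind = "imaginary frequency" if nu < 0 else "zero frequency"
            problems.append(f"{kind} at mode {k}: {nu} cm^-1")
    if record.geometry:
        expected = record.expected_mode_count
        if len(record.frequencies) != expected:
            problems.append(
                f"mode count: got {len(record.frequencies)}, expected {expected} "
                f"for {record.n_atoms} atoms ({'linear' if record.linear else 'nonlinear'})"
            )
    return MinimumReport(ok=not problems, problems=tuple(problems))


def interatomic_distance(record: SpeciesRecord, i: int, j: int) -> float:
    """Euclidean distance in Å between atoms ``i`` and ``j`` (0-based)."""
    n = record.n_atoms
    if not record.geometry:
        raise ValueError("record has no geometry")
    for idx in (i, j):
        if not 0 <= idx < n:
            raise IndexError(f"atom index {idx} out of range for {n} atoms")
    _, xi, yi, zi = record.geometry[i]
    _, xj, yj, zj = record.geometry[j]
    return math.dist((xi, yi, zi), (xj, yj, zj))


# ---------------------------------------------------------------------------
# QC-output text dialect
# ---------------------------------------------------------------------------
#
# The parser keys on the literal markers below; one annotated example lives
# in docs/qc_dialect_example.txt. A frequency job carries the geometry,
# frequency and rotational-constant blocks with its SCF energy read as E_low;
# a subsequent "Link1" section's SCF energy (larger-basis single point) is
# read as E_high. A file with no frequency block is a single-point job and
# its energy populates E_high only.

_RE_TITLE = re.compile(
    r"label=(?P<label>\S+)\s+role=(?P<role>\S+)(?:\s+site=(?P<site>\d+))?"
    r"(?:\s+sigma=(?P<sigma>[\d.]+))?(?:\s+gelec=(?P<gelec>\d+))?"
)
_RE_CHARGE = re.compile(r"Charge\s*=\s*(-?\d+)\s+Multiplicity\s*=\s*(\d+)")
_RE_STOICH = re.compile(r"Stoichiometry\s+([A-Za-z0-9]+)(\((\d+)[+-]\))?")
_RE_ROT = re.compile(r"Rotational constants \(GHZ\):\s+(.*)")
_RE_SCF = re.compile(r"SCF Done:\s+E\([^)]*\)\s*=\s*(-?\d+\.\d+)")
_RE_FREQ = re.compile(r"Frequencies\s*--\s*(.*)")
_RE_ZPE = re.compile(r"Zero-point correction=\s*(-?\d+\.\d+)")
_RE_MASS = re.compile(r"Molecular mass:\s*([\d.]+)\s*amu")
_RE_ATOM = re.compile(
    r"^\s*\d+\s+(\d+)\s+\d+\s+(-?\d+\.\d+)\s+(-?\d+\.\d+)\s+(-?\d+\.\d+)\s*$"
)

NORMAL_TERMINATION = "Normal termination"


def parse_qc_output(stream, dialect: str = "g16-like", validate: bool = True) -> SpeciesRecord:
    """Parse one QC-output transcript into a :class:`SpeciesRecord`.

    Parameters
    ----------
    stream : str or file-like
        The full text of a completed frequency or single-point job.
    dialect : str
        Only the ``"g16-like"`` text dialect is supported.
    validate : bool
        When true (default), reject streams with imaginary frequencies and
        records violating the schema invariants.
    """
    if dialect != "g16-like":
        raise ValueError(f"unsupported dialect {dialect!r}; only 'g16-like' is implemented")
    text = stream if isinstance(stream, str) else stream.read()
    if not text.strip():
        raise ParseError("empty stream: missing 'Normal termination' marker")
    # Split on Link1 so a trailing single-point section can be separated.
    sections = text.split("--Link1--")
    head = sections[0]
    if NORMAL_TERMINATION not in head:
        raise ParseError(
            "abnormal termination: missing 'Normal termination' marker (truncated output?)"
        )

    m = _RE_TITLE.search(head)
    if m is None:
        raise ParseError("missing title line (label=... role=...)")
    label = m.group("label")
    role = Role(m.group("role"))
    site = int(m.group("site")) if m.group("site") else None
    sigma = float(m.group("sigma")) if m.group("sigma") else 1.0
    gelec = int(m.group("gelec")) if m.group("gelec") else 1

    m = _RE_CHARGE.search(head)
    if m is None:
        raise ParseError("missing 'Charge = ... Multiplicity = ...' line")
    charge, multiplicity = int(m.group(1)), int(m.group(2))

    m = _RE_STOICH.search(head)
    if m is None:
        raise ParseError("missing 'Stoichiometry' line")
    formula = m.group(1)

    geometry: list[tuple[str, float, float, float]] = []
    if "Standard orientation:" in head:
        block = head.split("Standard orientation:", 1)[1]
        for line in block.splitlines():
            am = _RE_ATOM.match(line)
            if am:
                z = int(am.group(1))
                el = constants.ELEMENT_OF_Z.get(z)
                if el is None:
                    raise ParseError(f"unknown atomic number {z} in geometry block")
                geometry.append((el, float(am.group(2)), float(am.group(3)), float(am.group(4))))
            elif geometry and set(line.strip()) == {"-"}:
                break

    rot: list[float] = []
    m = _RE_ROT.search(head)
    if m:
        rot = [float(tok) for tok in m.group(1).split()]

    scf_energies = [float(e) for e in _RE_SCF.findall(head)]

    frequencies: list[float] = []
    for fm in _RE_FREQ.finditer(head):
        frequencies.extend(float(tok) for tok in fm.group(1).split())

    zpe = None
    m = _RE_ZPE.search(head)
    if m:
        zpe = float(m.group(1))

    mass = None
    m = _RE_MASS.search(head)
    if m:
        mass = float(m.group(1))

    E_low = E_high = None
    if frequencies:
        if not scf_energies:
            raise ParseError("frequency job missing 'SCF Done' energy line")
        E_low = scf_energies[0]
    elif scf_energies:
        E_high = scf_energies[0]  # single-point-only output

    # A Link1 section holds the larger-basis single point for the same species.
    for tail in sections[1:]:
        if NORMAL_TERMINATION not in tail:
            raise ParseError("abnormal termination: Link1 section not terminated")
        tail_scf = _RE_SCF.findall(tail)
        if tail_scf:
            E_high = float(tail_scf[-1])

    if validate and frequencies:
        bad = [(k, nu) for k, nu in enumerate(frequencies) if nu < 0]
        if bad:
            modes = ", ".join(f"mode {k}: {nu} cm^-1" for k, nu in bad)
            raise ValidationError(f"imaginary frequency in stream ({modes})")

    record = SpeciesRecord(
        label=label,
        formula=formula,
        charge=charge,
        multiplicity=multiplicity,
        role=role,
        protonation_site=site,
        E_low=E_low,
        E_high=E_high,
        zpe_raw=zpe,
        frequencies=frequencies,
        rot_constants=rot,
        linear=len(rot) == 1,
        mass=mass,
        sigma_rot=sigma,
        elec_degeneracy=gelec,
        geometry=geometry,
    )
    if validate:
        record.validate(strict=bool(frequencies))
    return record


# ---------------------------------------------------------------------------
# Canonical JSON schema
# ---------------------------------------------------------------------------

_REQUIRED_KEYS = ("label", "formula", "charge", "multiplicity", "role")


def write_species_json(records: SpeciesRecord | Sequence[SpeciesRecord]) -> str:
    """Serialise one record (or a list) to canonical versioned JSON."""
    single = isinstance(records, SpeciesRecord)
    items = [records] if single else list(records)
    payload = []
    for r in items:
        d = asdict(r)
        d["role"] = r.role.value
        d["geometry"] = [[el, x, y, z] for el, x, y, z in r.geometry]
        payload.append(d)
    doc = {"schema_version": SCHEMA_VERSION,
           "species": payload[0] if single else payload}
    return json.dumps(doc, indent=2)


def _record_from_dict(d: dict, validate: str) -> SpeciesRecord:
    for key in _REQUIRED_KEYS:
        if key not in d:
            raise ValidationError(f"species JSON missing required field {key!r}")
    known = {f for f in SpeciesRecord.__dataclass_fields__}
    unknown = set(d) - known
    if unknown:
        raise ValidationError(f"species JSON has unknown fields {sorted(unknown)}")
    d = dict(d)
    d["geometry"] = [tuple(a) for a in d.get("geometry", [])]
    try:
        record = SpeciesRecord(**d)
    except (TypeError, ValueError) as exc:
        raise ValidationError(str(exc)) from exc
    if validate != "none":
        record.validate(strict=validate == "strict")
    return record


def read_species_json(stream, validate: str = "strict"):
    """Read canonical species JSON; ``validate`` is strict | lenient | none.

    Returns a single :class:`SpeciesRecord` or a list, mirroring what was
    written.
    """
    text = stream if isinstance(stream, str) else stream.read()
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ValidationError(f"invalid JSON: {exc}") from exc
    if not isinstance(doc, dict) or "schema_version" not in doc:
        raise ValidationError("missing schema_version key")
    if doc["schema_version"] != SCHEMA_VERSION:
        raise ValidationError(
            f"unsupported schema_version {doc['schema_version']} (expected {SCHEMA_VERSION})"
        )
    body = doc.get("species")
    if body is None:
        raise ValidationError("missing 'species' key")
    if isinstance(body, list):
        return [_record_from_dict(d, validate) for d in body]
    return _record_from_dict(body, validate)
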