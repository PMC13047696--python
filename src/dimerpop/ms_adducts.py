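"""Adduct mass computation and centroid-peak annotation.

Implements the mass-spectral side of the dimer-identification workflow:
exact (monoisotopic) and nominal masses from molecular formulas, m/z of
monomer and dimer adducts ([M+H]+, [2M+H]+, [2M]+., ammonium adducts),
and annotation of centroided peak lists against candidate adducts within
a ppm tolerance.

Two electron-mass conventions are supported for protonated adducts:

``h_atom``
    add the mass of a hydrogen atom (1.00783 Da) with no electron-mass
    correction — the convention behind the conventional printed values
    (e.g. C21H30O2 + H -> 315.2324);
``proton``
    add a true proton, i.e. subtract the electron mass (0.00055 Da) as
    well — the physically strict m/z of a +1 cation.
"""

from __future__ import annotations

import base64
import re
import zlib
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from . import constants

__all__ = [
    "parse_formula",
    "formula_string",
    "monoisotopic_mass",
    "nominal_mass",
    "AdductSpec",
    "STANDARD_ADDUCTS",
    "adduct_mz",
    "PeakAnnotation",
    "annotate_peaks",
    "read_peaklist_text",
    "write_peaklist_text",
    "read_peaklist_mzml",
]

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Raised for unparseable formulas or unknown element symbols."""


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a plain (Hill-order) molecular formula into element counts.

    Parameters
    ----------
    formula : str
        e.g. ``"C21H30O2"``; the empty string parses to an empty count map.

    Returns
    -------
    dict mapping element symbol to a positive integer count.
    """
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(formula):
        if m.start() != pos:
            raise FormulaError(f"unparseable formula {formula!r} at position {pos}")
        pos = m.end()
        el, n = m.group(1), int(m.group(2) or 1)
        if el not in constants.MONOISOTOPIC_MASS:
            raise FormulaError(f"unknown element symbol {el!r} in {formula!r}")
        counts[el] = counts.get(el, 0) + n
    if pos != len(formula):
        raise FormulaError(f"unparseable formula {formula!r} at position {pos}")
    return counts


def formula_string(counts: Mapping[str, int]) -> str:
    """Render element counts in Hill order (C, H, then alphabetical)."""
    parts: list[str] = []
    order = [el for el in ("C", "H") if counts.get(el)]
    order += sorted(el for el in counts if el not in ("C", "H") and counts[el])
    for el in order:
        n = counts[el]
        parts.append(el + (str(n) if n != 1 else ""))
    return "".join(parts)


def monoisotopic_mass(formula: str | Mapping[str, int]) -> float:
    """Exact mass in Da: sum of most-abundant-isotope masses."""
    counts = parse_formula(formula) if isinstance(formula, str) else formula
    return sum(n * constants.MONOISOTOPIC_MASS[el] for el, n in counts.items())


def nominal_mass(formula: str | Mapping[str, int]) -> int:
    """Integer mass-number sum (nominal mass)."""
    counts = parse_formula(formula) if isinstance(formula, str) else formula
    return sum(n * constants.NOMINAL_MASS[el] for el, n in counts.items())


@dataclass(frozen=True)
class AdductSpec:
    """A singly charged adduct hypothesis: ``multiplier``·M + ``delta_formula``."""

    name: str
    multiplier: int
    delta_formula: str  # formula added to multiplier*M; "" for none
    charge: int = 1
    electron_convention: str = "h_atom"  # or "proton"

    def __post_init__(self) -> None:
        if self.multiplier < 1:
            raise ValueError("adduct multiplier must be >= 1")
        if self.charge != 1:
            raise ValueError("only singly charged (+1) adducts are supported")
        if self.electron_convention not in ("h_atom", "proton"):
            raise ValueError(f"unknown electron convention {self.electron_convention!r}")


#: The adducts encountered in ambient-ionization spectra of the cannabinoid
#: isomers: protonated monomer, proton-bound dimer, ammonium adducts, and the
#: field-desorption dimer radical cation.
STANDARD_ADDUCTS: dict[str, AdductSpec] = {
    a.name: a
    for a in (
        AdductSpec("[M+H]+", 1, "H"),
        AdductSpec("[2M+H]+", 2, "H"),
        AdductSpec("[M+NH4]+", 1, "NH4"),
        AdductSpec("[2M+NH4]+", 2, "NH4"),
        AdductSpec("[M]+.", 1, ""),
        AdductSpec("[2M]+.", 2, ""),
    )
}


def get_adduct(spec: AdductSpec | str) -> AdductSpec:
    if isinstance(spec, AdductSpec):
        return spec
    try:
        return STANDARD_ADDUCTS[spec]
    except KeyError:
        raise KeyError(
            f"unknown adduct {spec!r}; known: {sorted(STANDARD_ADDUCTS)}"
        ) from None


def adduct_mz(base_formula: str, adduct: AdductSpec | str) -> float:
    """m/z of a singly charged adduct of ``base_formula``.

    m/z = multiplier × monoisotopic(M) + monoisotopic(delta)
          − m_e (only under the ``proton`` convention).
    """
    a = get_adduct(adduct)
    mz = a.multiplier * monoisotopic_mass(base_formula)
    if a.delta_formula:
        mz += monoisotopic_mass(a.delta_formula)
    if a.electron_convention == "proton":
        mz -= constants.ELECTRON_MASS_DA
    return mz


@dataclass(frozen=True)
class PeakAnnotation:
    """A matched (observed m/z, adduct hypothesis, mass error) triple."""

    observed_mz: float
    base_formula: str
    adduct: str
    calc_mz: float
    error_ppm: float  # (observed - calc)/calc * 1e6
    relative_intensity: float  # percent of base peak


def annotate_peaks(
    peaks: Sequence[tuple[float, float]],
    base_formulas: Iterable[str],
    adducts: Iterable[AdductSpec | str],
    tol_ppm: float = 5.0,
) -> tuple[list[PeakAnnotation], list[tuple[float, float]]]:
    """Annotate centroided peaks with adduct assignments.

    Each peak is matched to the candidate (formula, adduct) whose calculated
    m/z lies within ``tol_ppm``; ties are broken by smallest absolute ppm
    error, then by adduct name, then formula (deterministic regardless of
    input order). Relative intensities are percentages of the most intense
    peak in the list.

    Returns ``(annotations, unmatched_peaks)``; an empty peak list yields
    two empty lists.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    peaks = list(peaks)
    if not peaks:
        return [], []
    candidates = sorted(
        {
            (f, get_adduct(a).name, adduct_mz(f, a))
            for f in base_formulas
            for a in adducts
        }
    )
    base_intensity = max(i for _, i in peaks)
    if base_intensity <= 0:
        raise ValueError("peak intensities must include a positive base peak")
    annotations: list[PeakAnnotation] = []
    unmatched: list[tuple[float, float]] = []
    for mz, intensity in sorted(peaks):
        best = None
        for formula, name, calc in candidates:
            ppm = (mz - calc) / calc * 1e6
            if abs(ppm) <= tol_ppm:
                key = (abs(ppm), name, formula)
                if best is None or key < best[0]:
                    best = (key, formula, name, calc, ppm)
        if best is None:
            unmatched.append((mz, intensity))
        else:
            _, formula, name, calc, ppm = best
            annotations.append(
                PeakAnnotation(
                    observed_mz=mz,
                    base_formula=formula,
                    adduct=name,
                    calc_mz=calc,
                    error_ppm=ppm,
                    relative_intensity=100.0 * intensity / base_intensity,
                )
            )
    return annotations, unmatched


# ---------------------------------------------------------------------------
# Peak-list I/O
# ---------------------------------------------------------------------------

def read_peaklist_text(stream) -> list[tuple[float, float]]:
    """Read a two-column delimited (whitespace/comma/tab) peak list.

    Lines starting with ``#`` and blank lines are skipped.
    """
    if isinstance(stream, str):
        lines = stream.splitlines()
    else:
        lines = stream.read().splitlines()
    peaks = []
    for ln, line in enumerate(lines, 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = re.split(r"[\s,;]+", line)
        if len(parts) < 2:
            raise ValueError(f"line {ln}: expected two columns (m/z, intensity)")
        peaks.append((float(parts[0]), float(parts[1])))
    return peaks


def write_peaklist_text(peaks: Sequence[tuple[float, float]]) -> str:
    lines = ["# m/z\tintensity"]
    lines += [f"{mz:.6f}\t{i:.6g}" for mz, i in peaks]
    return "\n".join(lines) + "\n"


_MZML_NS = "{http://psi.hupo.org/ms/mzml}"
_CV_MZ = "MS:1000514"
_CV_INTENSITY = "MS:1000515"
_CV_F64 = "MS:1000523"
_CV_F32 = "MS:1000521"
_CV_ZLIB = "MS:1000574"


def read_peaklist_mzml(path) -> list[tuple[float, float]]:
    """Read centroid spectra from an mzML file into one merged peak list.

    Decodes uncompressed or zlib-compressed 32/64-bit float binary arrays
    keyed on the PSI-MS controlled-vocabulary accessions. Only the m/z and
    intensity arrays are interpreted; all spectra in the file are merged.
    """
    import numpy as np
    from lxml import etree

    tree = etree.parse(str(path))
    peaks: list[tuple[float, float]] = []
    for spectrum in tree.iter(f"{_MZML_NS}spectrum"):
        arrays: dict[str, "np.ndarray"] = {}
        for bda in spectrum.iter(f"{_MZML_NS}binaryDataArray"):
            accs = {
                cv.get("accession")
                for cv in bda.iter(f"{_MZML_NS}cvParam")
            }
            kind = "mz" if _CV_MZ in accs else "intensity" if _CV_INTENSITY in accs else None
            if kind is None:
                continue
            binary = bda.find(f"{_MZML_NS}binary")
            raw = base64.b64decode(binary.text or "")
            if _CV_ZLIB in accs:
                raw = zlib.decompress(raw)
            dtype = "<f4" if _CV_F32 in accs else "<f8"
            arrays[kind] = np.frombuffer(raw, dtype=dtype).astype(float)
        if "mz" in arrays and "intensity" in arrays:
            peaks.extend(zip(arrays["mz"].tolist(), arrays["intensity"].tolist()))
    return peaks
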