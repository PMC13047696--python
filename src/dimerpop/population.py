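"""Temperature-dependent Boltzmann populations of competing proton-bound
dimers.

The mole fraction of dimer *i* among *n* isomeric complexes at temperature
T is

    X_i(T) = q_i(T) exp(-dH_i / RT) / sum_j q_j(T) exp(-dH_j / RT)

with q_i the product of translational, rotational, vibrational and
electronic partition functions and dH_i the relative heat of formation at
absolute zero (kcal/mol, >= 0, zero for the most stable dimer). R is the
gas constant in kcal mol^-1 K^-1. Weights are computed in log space with a
max-shift guard, so a 60 kcal/mol spread at 50 K does not underflow.

Because the competing dimers are isomers (equal mass), the translational
factor cancels in X_i; ``include_translation`` is exposed to make that
cancellation checkable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .constants import R_KCAL_MOL_K
from .species_io import SpeciesRecord
from .thermochem import ZPE_SCALE_DEFAULT, partition_functions

__all__ = [
    "DimerSystem",
    "PopulationTable",
    "mole_fractions",
    "temperature_sweep",
    "crossover_temperature",
    "sensitivity_uniform_shift",
    "shift_entry",
    "report_at_temperature",
    "TemperatureReport",
    "fit_enthalpy_gap",
]


@dataclass
class PopulationEntry:
    """One competing dimer: a label, a ln q(T) provider and its dH_rel."""

    label: str
    ln_q: Callable[[float], float]
    dH_rel: float  # kcal/mol, >= 0


@dataclass
class DimerSystem:
    """A named set of competing proton-bound dimers (Boltzmann ensemble)."""

    entries: list[PopulationEntry]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("a dimer system needs at least one entry")
        if len({e.label for e in self.entries}) != len(self.entries):
            raise ValueError("duplicate labels in dimer system")
        gaps = [e.dH_rel for e in self.entries]
        if min(gaps) < 0:
            raise ValueError("dH_rel values must be >= 0")
        if min(gaps) > 1e-12:
            raise ValueError("at least one entry must sit at dH_rel = 0")

    @property
    def labels(self) -> list[str]:
        return [e.label for e in self.entries]

    @property
    def n(self) -> int:
        return len(self.entries)

    @classmethod
    def from_records(
        cls,
        records: Sequence[SpeciesRecord],
        dH_rel: Mapping[str, float],
        scale: float = ZPE_SCALE_DEFAULT,
        scale_qvib: bool = True,
        include_translation: bool = True,
    ) -> "DimerSystem":
        """Build a system from species records and relative 0 K enthalpies."""

        def make_ln_q(rec: SpeciesRecord) -> Callable[[float], float]:
            def ln_q(T: float) -> float:
                return partition_functions(
                    rec, T, scale=scale, scale_qvib=scale_qvib,
                    include_translation=include_translation,
                ).ln_q_total
            return ln_q

        entries = [
            PopulationEntry(r.label, make_ln_q(r), float(dH_rel[r.label]))
            for r in records
        ]
        return cls(entries)


def _log_weights(system: DimerSystem, T: float,
                 shift: float | Mapping[str, float] = 0.0) -> np.ndarray:
    if T <= 0:
        raise ValueError(f"temperature must be positive, got {T} K")
    if isinstance(shift, Mapping):
        deltas = [shift.get(e.label, 0.0) for e in system.entries]
    else:
        deltas = [shift] * system.n
    return np.array(
        [
            e.ln_q(T) - (e.dH_rel + d) / (R_KCAL_MOL_K * T)
            for e, d in zip(system.entries, deltas)
        ]
    )


def mole_fractions(system: DimerSystem, T: float,
                   shift: float | Mapping[str, float] = 0.0) -> dict[str, float]:
    """Boltzmann mole fractions X_i at temperature T (K).

    ``shift`` adds a constant (or per-label constants) to every dH_rel in
    kcal/mol — the handle for sensitivity analyses.
    """
    lw = _log_weights(system, T, shift)
    lw -= lw.max()  # log-sum-exp guard: exact for the normalized ratio
    w = np.exp(lw)
    w /= w.sum()
    return dict(zip(system.labels, w.tolist()))


@dataclass
class PopulationTable:
    """Mole fractions of each dimer on a temperature grid."""

    T_grid: np.ndarray
    labels: list[str]
    fractions: np.ndarray  # rows = T, cols = labels
    dominant: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.T_grid = np.asarray(self.T_grid, dtype=float)
        self.fractions = np.asarray(self.fractions, dtype=float)
        rows, cols = self.fractions.shape
        if rows != len(self.T_grid) or cols != len(self.labels):
            raise ValueError("fractions shape does not match grid/labels")
        if np.any(self.fractions < -1e-15) or np.any(self.fractions > 1 + 1e-15):
            raise ValueError("fractions must lie in [0, 1]")
        sums = self.fractions.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-10):
            raise ValueError("population rows must sum to 1 within 1e-10")
        if not self.dominant:
            self.dominant = [self.labels[k] for k in self.fractions.argmax(axis=1)]

    def column(self, label: str) -> np.ndarray:
        return self.fractions[:, self.labels.index(label)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.fractions, columns=self.labels)
        df.insert(0, "T_K", self.T_grid)
        df["dominant"] = self.dominant
        return df


def temperature_sweep(
    system: DimerSystem,
    T_min: float = 50.0,
    T_max: float = 800.0,
    step: float = 5.0,
    shift: float | Mapping[str, float] = 0.0,
) -> PopulationTable:
    """Mole fractions on the grid [T_min, T_max] with spacing ``step``."""
    if T_min <= 0 or T_max <= T_min or step <= 0:
        raise ValueError("require 0 < T_min < T_max and step > 0")
    grid = np.arange(T_min, T_max + 0.5 * step, step)
    rows = [
        [mole_fractions(system, float(T), shift)[lbl] for lbl in system.labels]
        for T in grid
    ]
    return PopulationTable(T_grid=grid, labels=system.labels,
                           fractions=np.array(rows))


def crossover_temperature(
    table: PopulationTable,
    label_a: str,
    label_b: str,
    system: DimerSystem | None = None,
    tol_K: float = 0.1,
) -> float | None:
    """Temperature where X_A - X_B changes sign, or None if it never does.

    The sign change is bracketed on the table's grid; when the generating
    ``system`` is supplied the bracket is refined by bisecting the
    continuous model to ``tol_K``, otherwise linear interpolation between
    the bracketing grid points is returned.
    """
    for lbl in (label_a, label_b):
        if lbl not in table.labels:
            raise KeyError(f"label {lbl!r} not in population table")
    diff = table.column(label_a) - table.column(label_b)
    idx = None
    for k in range(len(diff) - 1):
        if diff[k] == 0.0 and diff[k + 1] != 0.0:
            idx = k
            break
        if diff[k] * diff[k + 1] < 0:
            idx = k
            break
    if idx is None:
        return None
    t_lo, t_hi = float(table.T_grid[idx]), float(table.T_grid[idx + 1])
    if system is None:
        d_lo, d_hi = diff[idx], diff[idx + 1]
        return t_lo + (t_hi - t_lo) * (0.0 - d_lo) / (d_hi - d_lo)

    def f(T: float) -> float:
        x = mole_fractions(system, T)
        return x[label_a] - x[label_b]

    f_lo = f(t_lo)
    while t_hi - t_lo > tol_K:
        t_mid = 0.5 * (t_lo + t_hi)
        f_mid = f(t_mid)
        if f_mid == 0.0:
            return t_mid
        if f_lo * f_mid < 0:
            t_hi = t_mid
        else:
            t_lo, f_lo = t_mid, f_mid
    return 0.5 * (t_lo + t_hi)


@dataclass(frozen=True)
class SensitivityReport:
    delta: float
    T_grid: np.ndarray
    max_abs_change: np.ndarray  # per temperature
    overall_max_change: float


def sensitivity_uniform_shift(
    system: DimerSystem,
    delta: float,
    T_grid: Sequence[float] | None = None,
) -> SensitivityReport:
    """Shift every dH_rel by ``delta`` kcal/mol and compare populations.

    A uniform shift cancels algebraically in the Boltzmann ratio, so the
    reported change is zero to rounding; the report makes that verifiable.
    """
    if not math.isfinite(delta):
        raise ValueError("delta must be finite")
    if T_grid is None:
        T_grid = np.arange(50.0, 800.0 + 2.5, 5.0)
    T_grid = np.asarray(T_grid, dtype=float)
    changes = []
    for T in T_grid:
        base = mole_fractions(system, float(T))
        shifted = mole_fractions(system, float(T), shift=delta)
        changes.append(max(abs(shifted[l] - base[l]) for l in system.labels))
    changes = np.array(changes)
    return SensitivityReport(
        delta=delta, T_grid=T_grid, max_abs_change=changes,
        overall_max_change=float(changes.max()),
    )


def shift_entry(system: DimerSystem, label: str, delta: float) -> Mapping[str, float]:
    """Per-entry shift map for non-uniform sensitivity runs."""
    if label not in system.labels:
        raise KeyError(f"label {label!r} not in system")
    return {label: delta}


@dataclass(frozen=True)
class TemperatureReport:
    """Populations at a set temperature and at the offset-corrected one."""

    T_set: float
    T_effective: float
    fractions_set: dict[str, float]
    fractions_effective: dict[str, float]
    dominant_set: str
    dominant_effective: str

    @property
    def robust_to_offset(self) -> bool:
        return self.dominant_set == self.dominant_effective

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                f"X({self.T_set:g} K)": self.fractions_set,
                f"X({self.T_effective:g} K)": self.fractions_effective,
            }
        )
        return df.sort_values(df.columns[0], ascending=False)


def report_at_temperature(
    system: DimerSystem, T_set: float, gap_offset: float = 0.0
) -> TemperatureReport:
    """Populations at the instrument set temperature and at
    ``T_set - gap_offset`` — the gas-stream temperature actually reaching
    the sampling gap."""
    T_eff = T_set - gap_offset
    if T_eff <= 0:
        raise ValueError("T_set - gap_offset must be positive")
    fs = mole_fractions(system, T_set)
    fe = fs if gap_offset == 0 else mole_fractions(system, T_eff)
    dom = max(fs, key=fs.get)
    dom_e = max(fe, key=fe.get)
    return TemperatureReport(T_set, T_eff, fs, fe, dom, dom_e)


def fit_enthalpy_gap(
    table: PopulationTable, label_a: str, label_b: str
) -> tuple[float, float]:
    """Recover dH(B) - dH(A) in kcal/mol from a population table.

    Fits ln(X_A/X_B) = ln(q_A/q_B) + gap/(R T) by ordinary least squares in
    1/T (a van 't Hoff-style inversion). Exact when the q-ratio is
    temperature independent (e.g. isomers sharing one vibrational/rotational
    structure); otherwise the slope estimates an effective gap.

    Returns ``(gap, ln_q_ratio_intercept)``.
    """
    xa, xb = table.column(label_a), table.column(label_b)
    if np.any(xa <= 0) or np.any(xb <= 0):
        raise ValueError("fractions must be positive for the log-ratio fit")
    y = np.log(xa / xb)
    x = 1.0 / table.T_grid
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope * R_KCAL_MOL_K), float(intercept)


def format_percent(x: float) -> str:
    """Percent formatting: one decimal at >= 10%, one significant figure
    below 1%, otherwise two significant figures."""
    p = 100.0 * x
    if p >= 10:
        return f"{p:.1f}%"
    if p >= 1:
        return f"{p:.2g}%"
    return f"{p:.1g}%"
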