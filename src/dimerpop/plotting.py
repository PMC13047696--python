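"""Minimal plotting: population curves over a temperature sweep."""

from __future__ import annotations

from .population import PopulationTable


def plot_population_table(table: PopulationTable, ax=None, percent: bool = True):
    """Line plot of mole fraction vs temperature, one curve per dimer.

    Returns the matplotlib Axes. Styling is intentionally plain.
    """
    import matplotlib
    if ax is None:
        matplotlib.use("Agg")  # headless-safe
        import matplotlib.pyplot as plt
        _, ax = plt.subplots()
    scale = 100.0 if percent else 1.0
    for label in table.labels:
        ax.plot(table.T_grid, scale * table.column(label), label=label)
    ax.set_xlabel("T (K)")
    ax.set_ylabel("mole fraction (%)" if percent else "mole fraction")
    ax.legend(fontsize="small")
    return ax
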