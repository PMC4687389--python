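"""Quick-look figures for concentration fields and profile fits."""

from __future__ import annotations

import numpy as np

from .domain import ConcentrationField, SECONDS_PER_DAY

__all__ = ["plot_concentration_profiles"]


def plot_concentration_profiles(field: ConcentrationField, observed=(), ax=None):
    """Total concentration vs depth for every output time, with observations.

    Returns the matplotlib axes.  Model curves are drawn per output time
    (labelled in effective days); observed profiles, if given, must carry
    concentrations and are drawn as points at their effective day's colour.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    colors = {}
    for i, t in enumerate(field.times):
        day = t / SECONDS_PER_DAY
        (line,) = ax.plot(field.positions * 1e3, field.total_conc[i], label=f"model d{day:g}")
        colors[round(day, 6)] = line.get_color()
    for p in observed:
        if p.conc is None:
            continue
        ax.plot(
            np.asarray(p.positions) * 1e3,
            p.conc,
            ".",
            ms=3,
            color=colors.get(round(float(p.effective_day), 6)),
            label=f"obs {p.scan_id} d{p.effective_day:g}",
        )
    ax.set_xlabel("depth from staining surface (mm)")
    ax.set_ylabel("total iodine (mmol/L)")
    ax.legend(fontsize="small")
    return ax
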