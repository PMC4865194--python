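"""Display helpers.

Numeric results always carry negative adjusted-R² fractions; hiding
them is purely a display convention, applied only here.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .rda import VarpartResult

__all__ = ["plot_varpart"]


def plot_varpart(result: VarpartResult, ax=None, hide_negative: bool = True):
    """Bar chart of variation-partitioning fractions.

    Fractions below zero (an artifact of the adjustment) are omitted
    from the display when ``hide_negative`` is set, matching common
    practice in published partition diagrams.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    items = sorted(result.fraction_table.items(), key=lambda kv: -kv[1])
    if hide_negative:
        items = [(k, v) for k, v in items if v >= 0]
    ax.bar([k for k, _ in items], [v for _, v in items], color="0.4")
    ax.axhline(0, color="k", lw=0.8)
    ax.set_ylabel("adjusted $R^2$ fraction")
    ax.set_title(f"full model adj $R^2$ = {result.full_model_r2_adj:.3f}")
    ax.tick_params(axis="x", rotation=75)
    plt.tight_layout()
    return ax
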