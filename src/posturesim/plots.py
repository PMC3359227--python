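"""Optional plotting hook: ECDF curve figures from a result bundle.

The CSVs written by :func:`posturesim.experiment.run_experiment` are the
contract; these figures are a convenience for eyeballing them.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = ["plot_ecdf_csv"]


def plot_ecdf_csv(ecdf_csv: str | Path, out_png: str | Path, title: str | None = None):
    """One panel per posture variable, one curve per window duration."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    frame = pd.read_csv(ecdf_csv)
    variables = sorted(frame["variable"].unique())
    fig, axes = plt.subplots(
        1, len(variables), figsize=(4 * len(variables), 3.5), sharey=True, squeeze=False
    )
    for ax, variable in zip(axes[0], variables):
        sub = frame[frame["variable"] == variable]
        for duration, curve in sub.groupby("window_duration_min"):
            ax.step(
                curve["value"],
                curve["cumulative_probability"],
                where="post",
                label=f"{duration} min",
            )
        ax.set_title(variable)
        ax.set_xlabel("value (deg)")
    axes[0][0].set_ylabel("cumulative probability")
    axes[0][-1].legend(fontsize=8)
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(out_png, dpi=120)
    plt.close(fig)
    return out_png
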