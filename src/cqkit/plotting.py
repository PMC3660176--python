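"""CQ distribution plots."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence, Union

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np


def plot_cq_distributions(
    groups: Mapping[str, Sequence[float]],
    dest: Union[str, Path],
    bin_width: float = 0.05,
    cq_max: float | None = 0.3,
) -> None:
    """Histogram normalized CQs per group on a shared axis.

    Bin edges start at 0 with the exact requested width, so binning is
    deterministic; the classification threshold is drawn as a dashed line.
    """
    groups = {name: list(vals) for name, vals in groups.items() if len(vals)}
    if not groups:
        raise ValueError("no non-empty CQ groups to plot")
    if bin_width <= 0:
        raise ValueError(f"bin_width must be > 0, got {bin_width}")
    top = max(max(vals) for vals in groups.values())
    edges = np.arange(0.0, top + 2 * bin_width, bin_width)

    fig, ax = plt.subplots(figsize=(7, 4))
    for name in sorted(groups):
        ax.hist(groups[name], bins=edges, alpha=0.6, label=name)
    if cq_max is not None:
        ax.axvline(cq_max, color="black", linestyle="--", linewidth=1,
                   label=f"threshold {cq_max:g}")
    ax.set_xlabel("normalized chromosome quotient")
    ax.set_ylabel("fragments")
    if len(groups) > 1 or cq_max is not None:
        ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(dest, dpi=150)
    plt.close(fig)
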