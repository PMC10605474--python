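"""Per-sample histogram of molecule sizes with fitted Gaussian components."""

from __future__ import annotations

import numpy as np

from .locus_io import DistanceSet, LocusSpec
from .sizing import SizingResult, bp_to_repeats


def plot_sample(
    dset: DistanceSet,
    result: SizingResult,
    locus: LocusSpec,
    path: str,
    bins: int = 30,
) -> None:
    """Histogram (repeat units) with component curves and a dotted red line
    marking a non-expanded allele (0 repeats)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    repeats = np.array([bp_to_repeats(d, locus) for d in dset.distances_bp])
    fig, ax = plt.subplots(figsize=(6, 4))
    counts, edges, _ = ax.hist(repeats, bins=bins, color="#7aa6c2", edgecolor="white")
    binwidth = edges[1] - edges[0]
    grid = np.linspace(repeats.min() - 3 * binwidth, repeats.max() + 3 * binwidth, 400)
    for comp in result.alleles:
        density = (
            comp.weight
            * result.n_kept
            * binwidth
            / (comp.sd_repeats * np.sqrt(2 * np.pi))
            * np.exp(-0.5 * ((grid - comp.mean_repeats) / comp.sd_repeats) ** 2)
        )
        ax.plot(grid, density, lw=2)
    ax.axvline(0.0, color="red", linestyle=":", lw=1.5)
    ax.set_xlabel("repeat units")
    ax.set_ylabel("molecule count")
    ax.set_title(f"{dset.sample_id} (n={result.n_total})")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
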