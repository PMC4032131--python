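"""Minimal dcfs bar-chart helper."""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from dcfs.stats import DCFS

__all__ = ["plot_dcfs"]


def plot_dcfs(spectra, labels: Optional[Sequence[str]] = None,
              observed: Optional[DCFS] = None, ax=None):
    """Bar chart of one or more dcfs vectors, optionally with observed points.

    ``spectra`` is a DCFS or a sequence of them; returns the matplotlib
    axes.
    """
    import matplotlib.pyplot as plt

    if isinstance(spectra, DCFS):
        spectra = [spectra]
    if ax is None:
        _, ax = plt.subplots()
    n = spectra[0].n_classes
    x = np.arange(1, n + 1)
    width = 0.8 / len(spectra)
    for k, dc in enumerate(spectra):
        p = dc.proportions
        if p is None:
            raise ValueError("cannot plot an undefined dcfs")
        label = labels[k] if labels else None
        ax.bar(x + (k - (len(spectra) - 1) / 2) * width, p, width=width, label=label)
    if observed is not None:
        ax.plot(x, observed.proportions, "ko", label="observed")
    ax.set_xlabel("derived allele count in the European panel")
    ax.set_ylabel("proportion of doubly conditioned loci")
    ax.set_xticks(x)
    if labels or observed is not None:
        ax.legend()
    return ax
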