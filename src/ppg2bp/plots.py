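"""Optional agreement plots (requires matplotlib, the ``plot`` extra)."""

from __future__ import annotations

import numpy as np

__all__ = ["save_agreement_plots"]


def save_agreement_plots(actual, estimated, path_prefix: str, target: str = "BP") -> list[str]:
    """Write a regression scatter and a Bland-Altman plot as PNG files.

    Returns the written file paths.  The scatter shows estimated against
    reference values with the identity line; the Bland-Altman panel shows
    ``estimated - reference`` against the pair mean with the mean
    difference and the md +/- 1.96 sd limits of agreement.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .evaluation import bland_altman

    a = np.asarray(actual, float)
    e = np.asarray(estimated, float)
    ba = bland_altman(a, e)
    written = []

    fig, ax = plt.subplots(figsize=(4.5, 4))
    ax.scatter(a, e, s=12, alpha=0.6)
    lims = [min(a.min(), e.min()), max(a.max(), e.max())]
    ax.plot(lims, lims, "k--", lw=1)
    ax.set_xlabel(f"Reference {target} (mmHg)")
    ax.set_ylabel(f"Estimated {target} (mmHg)")
    fig.tight_layout()
    scatter_path = f"{path_prefix}_scatter.png"
    fig.savefig(scatter_path, dpi=120)
    plt.close(fig)
    written.append(scatter_path)

    fig, ax = plt.subplots(figsize=(4.5, 4))
    mean = (a + e) / 2
    ax.scatter(mean, e - a, s=12, alpha=0.6)
    for yv, style in ((ba.md, "r-"), (ba.lower, "b--"), (ba.upper, "g--")):
        ax.axhline(yv, ls=style[1:], color=style[0], lw=1)
    ax.set_xlabel(f"Mean of reference and estimated {target} (mmHg)")
    ax.set_ylabel("Estimated - reference (mmHg)")
    fig.tight_layout()
    ba_path = f"{path_prefix}_bland_altman.png"
    fig.savefig(ba_path, dpi=120)
    plt.close(fig)
    written.append(ba_path)
    return written
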