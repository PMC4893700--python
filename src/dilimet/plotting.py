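"""Score plots with Hotelling confidence ellipses."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

from dilimet.chemometrics import hotelling_ellipse  # noqa: E402

_CLASS_COLORS = {
    "control": "tab:green",
    "oxidative_stress": "tab:blue",
    "phospholipidosis": "tab:red",
    "steatosis": "tab:purple",
}


def scores_plot(scores: np.ndarray, labels, path: str | Path | None = None,
                alpha: float = 0.05, components: tuple[int, int] = (0, 1),
                extra_scores: np.ndarray | None = None,
                extra_labels=None, title: str = ""):
    """Scatter the first two score components per class with the global
    1-alpha Hotelling ellipse; optional larger markers for projected
    external samples."""
    labels = np.asarray(list(labels))
    t = np.asarray(scores, dtype=float)[:, list(components)]
    fig, ax = plt.subplots(figsize=(5, 4.5))
    for cls in sorted(set(labels.tolist())):
        pts = t[labels == cls]
        ax.scatter(pts[:, 0], pts[:, 1], s=25,
                   color=_CLASS_COLORS.get(cls, "gray"), label=cls)
    ell = hotelling_ellipse(t, alpha=alpha)
    theta = np.linspace(0, 2 * np.pi, 200)
    ax.plot(ell.semi_axes[0] * np.cos(theta), ell.semi_axes[1] * np.sin(theta),
            color="black", lw=0.8, ls="--")
    if extra_scores is not None:
        te = np.asarray(extra_scores, dtype=float)[:, list(components)]
        elabs = np.asarray(list(extra_labels)) if extra_labels is not None else None
        for i in range(len(te)):
            color = _CLASS_COLORS.get(elabs[i], "black") if elabs is not None else "black"
            ax.scatter(te[i, 0], te[i, 1], s=90, facecolors="none",
                       edgecolors=color, linewidths=1.6)
    ax.axhline(0, color="gray", lw=0.4)
    ax.axvline(0, color="gray", lw=0.4)
    ax.set_xlabel(f"t[{components[0] + 1}]")
    ax.set_ylabel(f"t[{components[1] + 1}]")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=7)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
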