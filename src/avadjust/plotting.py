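"""Basic plotting utilities: test-information curves and the distribution
of discrimination parameters before vs after adjustment."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .grm import GrmFit, InformationCurve  # noqa: E402

__all__ = ["plot_information", "plot_discriminations"]


def plot_information(curves: dict[str, InformationCurve], path: str | Path,
                     title: str = "Test information") -> None:
    """Overlay test-information curves (one line per labelled fit) with the
    latent-score standard error on a twin axis."""
    fig, ax = plt.subplots(figsize=(7, 4.5))
    ax2 = ax.twinx()
    for label, ic in curves.items():
        ax.plot(ic.theta, ic.test_information, label=label)
        ax2.plot(ic.theta, ic.standard_error, linestyle="--", alpha=0.5)
    ax.set_xlabel(r"$\theta$")
    ax.set_ylabel("test information")
    ax2.set_ylabel("standard error (dashed)")
    ax.legend()
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_discriminations(fits: dict[str, GrmFit], path: str | Path,
                         title: str = "Discrimination parameters") -> None:
    """Violin plot of item discriminations for each labelled fit."""
    labels = list(fits)
    data = [[it.a for it in fits[lb].items] for lb in labels]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.violinplot(data, showmedians=True)
    ax.set_xticks(range(1, len(labels) + 1), labels)
    ax.set_ylabel("discrimination a")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
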