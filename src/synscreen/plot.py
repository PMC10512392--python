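"""Static plots: HIP/HOP scatter panels and ε heatmaps."""

from __future__ import annotations

import numpy as np

from .hiphop import CombinationResult, specific_set


def hiphop_scatter(r: CombinationResult, path, threshold: float = 2.0) -> None:
    """Two-panel scatter of combination fitness defects (HIP left, HOP right).

    Combination-specific strains are red, significantly sensitive strains
    (combo Z ≥ threshold but not specific) green, the rest violet.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    specific = specific_set(r, threshold)
    strains = r.strains
    panels = {
        "HIP (het-essential)": "het-essential",
        "HOP (hom-nonessential)": "hom-nonessential",
    }
    fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharey=True)
    for ax, (title, panel) in zip(axes, panels.items()):
        sel = [s for s in strains if r.combo.essentiality.get(s) == panel]
        z = r.combo.z.loc[sel]
        colors = [
            "red" if s in specific
            else ("green" if z[s] >= threshold else "violet")
            for s in sel
        ]
        ax.scatter(np.arange(len(sel)), z.to_numpy(), c=colors, s=12)
        ax.axhline(threshold, color="grey", lw=0.8, ls="--")
        ax.set_title(title)
        ax.set_xlabel("strain index")
    axes[0].set_ylabel("fitness defect (robust Z)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def epsilon_heatmap(eps: np.ndarray, doses_a, doses_b, path, title: str = "") -> None:
    """Checkerboard ε heatmap (yellow = synergy, blue = antagonism)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(eps, origin="lower", cmap="RdYlBu", vmin=-0.5, vmax=0.5)
    ax.set_xticks(range(len(doses_b)), [f"{d:g}" for d in doses_b])
    ax.set_yticks(range(len(doses_a)), [f"{d:g}" for d in doses_a])
    ax.set_xlabel("dose of drug B")
    ax.set_ylabel("dose of drug A")
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, label="epsilon")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
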