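"""Cost-effectiveness plane and acceptability-curve plots."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt


def plot_ce_plane(samples, path, wtp_reference=20_000.0, effect_label="Incremental QALYs"):
    """Scatter of bootstrap/PSA (Δeffect, Δcost) pairs with the WTP ray."""
    fig, ax = plt.subplots(figsize=(5.5, 4.5))
    ax.scatter(samples["delta_effect"] if "delta_effect" in samples else samples["delta_qaly"],
               samples["delta_cost"], s=6, alpha=0.35, edgecolors="none")
    ax.axhline(0, color="0.4", lw=0.8)
    ax.axvline(0, color="0.4", lw=0.8)
    xlim = ax.get_xlim()
    ax.plot(xlim, [wtp_reference * x for x in xlim], ls="--", color="tab:red",
            lw=0.9, label=f"WTP £{wtp_reference:,.0f}")
    ax.set_xlim(xlim)
    ax.set_xlabel(effect_label)
    ax.set_ylabel("Incremental cost (£)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=130)
    plt.close(fig)


def plot_ceac(curve, path):
    fig, ax = plt.subplots(figsize=(5.5, 4.0))
    ax.plot(curve["threshold"], curve["probability"], marker="o", ms=3)
    ax.set_xlabel("Willingness-to-pay threshold (£/QALY)")
    ax.set_ylabel("Probability cost-effective")
    ax.set_ylim(0, 1)
    fig.tight_layout()
    fig.savefig(path, dpi=130)
    plt.close(fig)
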