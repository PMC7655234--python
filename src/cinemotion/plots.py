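"""Summary figures: training-size curves and signal traces."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

__all__ = ["training_size_curves", "signal_traces"]


def training_size_curves(summary, path, mask="evaluation", stat="mean_dfe_mm"):
    """Fold-averaged DFE vs number of training images, one line per model.

    Two-signal models are drawn solid, three-signal dotted; the no-model
    baseline is annotated in the title rather than drawn (it is typically
    far above every model).
    """
    sub = summary[(summary["mask"] == mask) & (summary["model"] != "no_model")]
    base = summary[(summary["mask"] == mask) & (summary["model"] == "no_model")]
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for model, grp in sub.groupby("model"):
        style = ":" if model.count("+") >= 2 else "-"
        grp = grp.sort_values("n_train")
        ax.plot(grp["n_train"], grp[stat], style, marker="o", ms=3, label=model)
    ax.set_xlabel("number of training motion images")
    ax.set_ylabel(f"{'mean' if 'mean' in stat else '95th percentile'} DFE (mm)")
    title = f"DFE vs training size ({mask} mask)"
    if len(base):
        title += f"; no model: {base[stat].iloc[0]:.2f} mm"
    ax.set_title(title, fontsize=10)
    ax.legend(fontsize=7, ncol=2)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def signal_traces(signals: dict, path, true_trace=None):
    """Resampled surrogate signals over time, optionally with the true trace."""
    fig, axes = plt.subplots(len(signals), 1, figsize=(8, 1.6 * len(signals)), sharex=True)
    if len(signals) == 1:
        axes = [axes]
    for ax, (name, sig) in zip(axes, signals.items()):
        ax.plot(sig.sample_times_s, sig.sample_values, lw=0.8)
        ax.set_ylabel(f"{name}\n({sig.units})", fontsize=7)
        if true_trace is not None:
            p, _ = true_trace.value_at(sig.sample_times_s)
            scaled = (p - p.mean()) / (p.std() or 1) * (sig.sample_values.std() or 1)
            ax.plot(sig.sample_times_s, scaled, lw=0.6, alpha=0.5)
    axes[-1].set_xlabel("time (s)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
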