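"""Optional summary figures (matplotlib imported on demand)."""

from __future__ import annotations

from pathlib import Path

from .evaluation import CVReport

__all__ = ["plot_cv_boxplots"]


def plot_cv_boxplots(report: CVReport, outdir, metrics=("predictive_corr", "mse")):
    """Per-trait boxplots of CV metrics across replicates, one panel per
    (variant, trait), lambda on the x-axis.  Returns the written paths."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    res = report.results
    written = []
    for metric in metrics:
        sub = res[res.metric == metric]
        if sub.empty:
            continue
        traits = sorted(sub.trait_or_pair.unique())
        variants = sorted(sub.variant.unique())
        fig, axes = plt.subplots(
            len(variants), len(traits),
            figsize=(3.2 * len(traits), 2.8 * len(variants)),
            squeeze=False,
        )
        for vi, variant in enumerate(variants):
            for ti, trait in enumerate(traits):
                ax = axes[vi][ti]
                cell = sub[(sub.variant == variant) & (sub.trait_or_pair == trait)]
                lams = sorted(cell.lam.unique())
                data = [cell[cell.lam == lam].value.dropna() for lam in lams]
                ax.boxplot(data, tick_labels=[f"{lam:g}" for lam in lams])
                ax.set_title(f"{variant} {trait}", fontsize=9)
                if vi == len(variants) - 1:
                    ax.set_xlabel("lambda")
                if ti == 0:
                    ax.set_ylabel(metric)
        fig.tight_layout()
        path = outdir / f"cv_{metric}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    return written
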