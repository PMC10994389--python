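"""Conditional-probability curve plots: one panel per depression stratum,
early and late mobilisation curves with pointwise confidence bands."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .cohort import EXPOSURE_LEVELS, STRATUM_LEVELS
from .nonparametric import GroupedCPF

__all__ = ["plot_cpf_curves"]

_LABELS = {"depression": "Diagnosis of depression",
           "no_depression": "No diagnosis of depression",
           "early": "Mobilised early", "late": "Mobilised late"}


def _step_xy(times, values, horizon):
    x = np.concatenate([[0.0], np.repeat(times, 2), [horizon]])
    y = np.concatenate([[0.0, 0.0], np.repeat(values, 2)[:-1], [values[-1]]])
    return x, y


def plot_cpf_curves(grouped: GroupedCPF, path: str | Path | None = None,
                    horizon: float = 30.0):
    """Stepwise CPF curves by stratum and exposure; returns the figure."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    strata = [s for s in STRATUM_LEVELS
              if any(k[0] == s for k in grouped.curves)]
    fig, axes = plt.subplots(1, max(len(strata), 1), figsize=(6 * max(len(strata), 1), 4.5),
                             sharey=True, squeeze=False)
    for ax, stratum in zip(axes[0], strata):
        for exposure, color in zip(EXPOSURE_LEVELS, ("C0", "C1")):
            curve = grouped.curves.get((stratum, exposure))
            if curve is None or len(curve.times) == 0:
                continue
            x, y = _step_xy(curve.times, curve.cpf, horizon)
            ax.plot(x, y, color=color, label=_LABELS[exposure])
            if curve.ci_lower is not None:
                xl, yl = _step_xy(curve.times, curve.ci_lower, horizon)
                _, yh = _step_xy(curve.times, curve.ci_upper, horizon)
                ax.fill_between(xl, yl, yh, color=color, alpha=0.15, step=None)
        ax.set_title(_LABELS[stratum])
        ax.set_xlabel("Days after surgery")
        ax.set_xlim(0, horizon)
        ax.set_ylim(0, 1)
        ax.legend(loc="lower right")
    axes[0][0].set_ylabel("Conditional probability of live discharge")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
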