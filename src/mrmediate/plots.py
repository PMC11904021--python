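"""Optional matplotlib rendering of the diagnostic tables.

The analysis emits plot-ready tables (see
:func:`mrmediate.sensitivity.funnel_scatter_data`,
:func:`mrmediate.workflow.forest_table`); these helpers render them.
matplotlib is imported lazily so the core pipeline has no plotting
dependency.
"""

from __future__ import annotations

import pandas as pd


def _plt():
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    return plt


def plot_scatter(scatter: pd.DataFrame, ax=None):
    """Per-SNP effect scatter with one fitted line per estimator."""
    plt = _plt()
    ax = ax or plt.gca()
    ax.errorbar(scatter["beta_exp"], scatter["beta_out"],
                xerr=scatter["se_exp"], yerr=scatter["se_out"],
                fmt="o", ms=3, lw=0.8, color="0.3")
    xs = scatter["beta_exp"].sort_values()
    for col in [c for c in scatter.columns if c.startswith("fit_")]:
        slope = (scatter[col] / scatter["beta_exp"]).iloc[0]
        ax.plot(xs, slope * xs, label=col.removeprefix("fit_"))
    ax.set_xlabel("SNP effect on exposure")
    ax.set_ylabel("SNP effect on outcome")
    ax.legend(fontsize=8)
    return ax


def plot_funnel(funnel: pd.DataFrame, ivw_beta: float | None = None, ax=None):
    """Wald ratio vs precision; vertical line marks the pooled estimate."""
    plt = _plt()
    ax = ax or plt.gca()
    ax.scatter(funnel["ratio"], funnel["precision"], s=12, color="0.3")
    if ivw_beta is not None:
        ax.axvline(ivw_beta, color="firebrick", lw=1)
    ax.set_xlabel("Wald ratio")
    ax.set_ylabel("precision (1/SE)")
    return ax


def plot_leave_one_out(loo: pd.DataFrame, full_beta: float, ax=None):
    plt = _plt()
    ax = ax or plt.gca()
    y = range(len(loo))
    ax.errorbar(loo["beta_without"], y, xerr=1.96 * loo["se_without"],
                fmt="o", ms=3, lw=0.8, color="0.3")
    ax.axvline(full_beta, color="firebrick", lw=1)
    ax.set_yticks(list(y), loo["snp_id"], fontsize=6)
    ax.set_xlabel("IVW estimate without SNP")
    return ax


def plot_forest(forest: pd.DataFrame, ax=None):
    """Odds ratios with 95% CIs, one row per (exposure, method)."""
    plt = _plt()
    ax = ax or plt.gca()
    labels = forest["exposure"] + " / " + forest["method"]
    y = range(len(forest))
    ax.errorbar(forest["or"], y,
                xerr=[forest["or"] - forest["ci_low"], forest["ci_high"] - forest["or"]],
                fmt="s", ms=3, lw=0.8, color="0.2")
    ax.axvline(1.0, color="0.6", lw=1, ls="--")
    ax.set_yticks(list(y), labels, fontsize=6)
    ax.set_xlabel("odds ratio (95% CI)")
    return ax
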