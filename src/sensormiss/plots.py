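"""Optional figure rendering over the report tables.

Every plot consumes a report DataFrame that is also written as CSV, so
figures are a convenience view, never the canonical output.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def forest_plot(fixed_effects: pd.DataFrame, ax=None):
    """Forest plot of exponentiated fixed effects with 95% intervals.

    Parameters
    ----------
    fixed_effects : DataFrame
        Output of :func:`~sensormiss.reports.build_fixed_effects_report`
        (or the ``fixed_effects.csv`` it writes, read back with the term
        column as index).
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 0.4 * len(fixed_effects) + 1))
    terms = fixed_effects.index[::-1]
    y = np.arange(len(terms))
    sub = fixed_effects.loc[terms]
    ax.errorbar(
        sub["estimate"], y,
        xerr=[sub["estimate"] - sub["ci_low"], sub["ci_high"] - sub["estimate"]],
        fmt="o", capsize=3,
    )
    ax.axvline(1.0, color="grey", lw=0.8, ls="--")
    ax.set_yticks(y)
    ax.set_yticklabels(terms)
    ax.set_xscale("log")
    ax.set_xlabel("rate ratio (95% CI)")
    return ax


def random_effect_intervals(random_effects: pd.DataFrame, ax=None):
    """Caterpillar plot of per-group random-intercept intervals, ordered
    from least to most non-collection; intervals excluding zero are
    drawn solid black, the rest grey."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 3))
    x = np.arange(len(random_effects))
    for flag, color in ((False, "0.7"), (True, "black")):
        sub = random_effects[random_effects["excludes_zero"] == flag]
        idx = sub.index.to_numpy()
        ax.vlines(x[idx], sub["ci_low"], sub["ci_high"], color=color, lw=1)
        ax.plot(x[idx], sub["median"], ".", color=color, ms=3)
    ax.axhline(0.0, color="grey", lw=0.8, ls="--")
    ax.set_xlabel("group (ordered by median)")
    ax.set_ylabel("deviation from average log rate")
    return ax


def missingness_by_participant(summary: pd.DataFrame, ax=None):
    """Bar chart of mean proportion of missing groupings per participant,
    sorted ascending (the cohort-overview view of non-collection)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 3))
    ax.bar(
        np.arange(len(summary)), summary["mean_prop_missing"], width=1.0,
        edgecolor="none",
    )
    ax.set_xlabel("participant (ordered)")
    ax.set_ylabel("mean proportion missing")
    ax.set_ylim(0, 1)
    return ax
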