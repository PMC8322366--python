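"""Report tables: exponentiated fixed effects and random-effect intervals.

All tables are plain DataFrames intended to be written as CSV; figure
rendering is a thin optional layer on top of them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .results import NonCollectionResults


class NotConvergedError(RuntimeError):
    """Report requested from a fit that failed the convergence gate."""


def build_fixed_effects_report(
    results: NonCollectionResults, override_convergence: bool = False
) -> pd.DataFrame:
    """Exponentiated fixed-effect table (one row per modeled term).

    Columns: posterior median of exp(beta) (``estimate``, equal to the
    exponentiated posterior median since exp is monotone), ``mean_exp``
    (posterior mean of exp(beta), labeled separately because it is NOT
    exp of the mean), central 95% interval, posterior SD of beta on the
    log scale, percent change per unit ((exp(beta)-1)*100; per week for
    the time term), and a ``significant`` flag = 95% CI excludes 1.
    """
    if not results.converged and not override_convergence:
        raise NotConvergedError(
            "fit failed the convergence gate (R-hat/ESS); inspect "
            "results.diagnostics or pass override_convergence=True"
        )
    rows = []
    terms = ["alpha0"] + [f"beta[{c}]" for c in results.model.design.x_cols]
    labels = ["intercept"] + list(results.model.design.x_cols)
    for term, label in zip(terms, labels):
        d = results.param_draws(term)
        e = np.exp(d)
        lo, hi = np.percentile(e, [2.5, 97.5])
        est = float(np.median(e))
        rows.append(
            {
                "term": label,
                "estimate": est,
                "mean_exp": float(e.mean()),
                "ci_low": float(lo),
                "ci_high": float(hi),
                "sd_log": float(d.std(ddof=1)),
                "percent_change": (est - 1.0) * 100.0,
                "significant": bool(lo > 1.0 or hi < 1.0),
            }
        )
    return pd.DataFrame(rows).set_index("term")


def build_random_effects_report(
    results: NonCollectionResults, level: str = "participant"
) -> pd.DataFrame:
    """Per-group random-intercept intervals on the log scale.

    One row per group (participant or study) with the posterior median
    deviation from the grand mean and its central 95% interval, sorted
    ascending by median (least to most non-collection); ``excludes_zero``
    flags groups whose interval excludes 0.
    """
    if level == "participant":
        key, ids = "gamma", results.model.design.participant_ids
    elif level == "study":
        key, ids = "delta", results.model.design.study_ids
    else:
        raise ValueError("level must be 'participant' or 'study'")
    if key not in results.params:
        raise ValueError(f"model was fitted without the {level} random intercept")
    draws = results.params[key].reshape(-1, len(ids))
    med = np.median(draws, axis=0)
    lo, hi = np.percentile(draws, [2.5, 97.5], axis=0)
    out = pd.DataFrame(
        {
            "group": ids,
            "median": med,
            "ci_low": lo,
            "ci_high": hi,
            "excludes_zero": (lo > 0) | (hi < 0),
        }
    ).sort_values("median", kind="mergesort", ignore_index=True)
    out.attrs["n_excluding_zero"] = int(out["excludes_zero"].sum())
    return out
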