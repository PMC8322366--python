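"""Posterior results: draws, diagnostics, model comparison, summaries."""

from __future__ import annotations

import logging
import warnings
from functools import cached_property
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    import arviz as az

if TYPE_CHECKING:  # pragma: no cover
    from .model import McmcSpec, NonCollectionModel

logger = logging.getLogger(__name__)


class NonCollectionResults:
    """Fitted hierarchical NB model.

    Holds the unconstrained draws ``theta`` with shape
    ``(chain, draw, dim)`` plus the model that produced them; exposes
    constrained parameter draws, convergence diagnostics (rank-normalized
    split/folded R-hat, bulk/tail ESS), WAIC, PSIS-LOO, Bayes R² and
    report tables.
    """

    def __init__(self, model: "NonCollectionModel", mcmc: "McmcSpec", theta, stats):
        self.model = model
        self.mcmc = mcmc
        self.theta = np.asarray(theta)
        self.stats = stats
        if not np.all(np.isfinite(self.theta)):
            raise ValueError("non-finite draws")

    # ------------------------------------------------------------------
    # constrained draws
    # ------------------------------------------------------------------
    @cached_property
    def params(self) -> dict[str, np.ndarray]:
        """Constrained draws, ``(chain, draw)`` or ``(chain, draw, k)``."""
        lay, des = self.model.layout, self.model.design
        th = self.theta
        alpha0, beta = self.model.posterior.natural_fixed_effects(th)
        out: dict[str, np.ndarray] = {"alpha0": alpha0}
        if lay.p_fixed:
            out["beta"] = beta
        post = self.model.posterior
        a0_sampling = th[:, :, lay.i_alpha0]
        if lay.study_effect:
            sd = np.exp(th[:, :, lay.i_log_sigma_delta])
            out["sigma_delta"] = sd
            out["delta"] = sd[:, :, None] * th[:, :, lay.sl_delta]
        if lay.participant_effect:
            out["sigma_gamma"] = np.exp(th[:, :, lay.i_log_sigma_gamma])
            parent = a0_sampling[:, :, None] + (
                out["delta"][:, :, post._p2s] if lay.study_effect else 0.0
            )
            if post._const_idx.size:
                parent = parent + th[:, :, post._beta_pos_const] @ post._xp.T
            out["gamma"] = th[:, :, lay.sl_gamma] - parent
        if lay.sample_omega:
            out["omega"] = np.exp(th[:, :, lay.i_log_omega])
        return out

    def param_draws(self, name: str) -> np.ndarray:
        """Flattened (all chains pooled) draws of one named quantity.

        Names: ``alpha0``, ``beta[<col>]``, ``sigma_gamma``,
        ``sigma_delta``, ``omega``, ``gamma[<participant>]``,
        ``delta[<study>]``.
        """
        p, des = self.params, self.model.design
        if name in p and p[name].ndim == 2:
            return p[name].reshape(-1)
        if name.startswith("beta[") and name.endswith("]"):
            col = name[5:-1]
            return p["beta"][:, :, des.x_cols.index(col)].reshape(-1)
        if name.startswith("gamma[") and name.endswith("]"):
            return p["gamma"][:, :, des.participant_ids.index(name[6:-1])].reshape(-1)
        if name.startswith("delta[") and name.endswith("]"):
            return p["delta"][:, :, des.study_ids.index(name[6:-1])].reshape(-1)
        raise KeyError(name)

    @cached_property
    def inference_data(self) -> az.InferenceData:
        """Draws as an arviz ``InferenceData`` (posterior group only)."""
        des = self.model.design
        coords = {
            "term": des.x_cols,
            "participant": des.participant_ids,
            "study": des.study_ids,
        }
        dims = {"beta": ["term"], "gamma": ["participant"], "delta": ["study"]}
        post = {k: v for k, v in self.params.items()}
        return az.from_dict(posterior=post, coords=coords, dims=dims)

    # ------------------------------------------------------------------
    # diagnostics
    # ------------------------------------------------------------------
    @cached_property
    def diagnostics(self) -> pd.DataFrame:
        """Per-parameter convergence table.

        Columns: ``rhat_rank`` (rank-normalized split R-hat),
        ``rhat_folded`` (same on |x - median|, tail-sensitive),
        ``ess_bulk``, ``ess_tail``.  A constant chain has undefined
        R-hat, reported as +inf.
        """
        idata = self.inference_data
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rhat_rank = az.rhat(idata, method="z_scale")
            rhat_fold = az.rhat(idata, method="folded")
            ess_bulk = az.ess(idata, method="bulk")
            ess_tail = az.ess(idata, method="tail")

        rows = []
        des = self.model.design
        labels = {
            "beta": [f"beta[{c}]" for c in des.x_cols],
            "gamma": [f"gamma[{p}]" for p in des.participant_ids],
            "delta": [f"delta[{s}]" for s in des.study_ids],
        }
        for var in rhat_rank.data_vars:
            vals = [
                np.atleast_1d(np.asarray(ds[var]))
                for ds in (rhat_rank, rhat_fold, ess_bulk, ess_tail)
            ]
            names = labels.get(var, [var] * len(vals[0]))
            if len(names) != len(vals[0]):
                names = [f"{var}[{i}]" for i in range(len(vals[0]))]
            draws = self.params[var]
            if draws.ndim == 2:
                draws = draws[:, :, None]
            for i, name in enumerate(names):
                rr, rf, eb, et = (float(v[i]) for v in vals)
                if np.isnan(rr) or np.isnan(rf):
                    flat = draws[:, :, i]
                    if np.ptp(flat) == 0:
                        logger.warning("parameter %s is constant; R-hat undefined", name)
                        rr = rf = np.inf
                rows.append(
                    {
                        "parameter": name,
                        "rhat_rank": rr,
                        "rhat_folded": rf,
                        "ess_bulk": eb,
                        "ess_tail": et,
                    }
                )
        return pd.DataFrame(rows).set_index("parameter")

    @property
    def converged(self) -> bool:
        """Convergence gate: both R-hat variants <= rhat_max and per-chain
        bulk and tail ESS >= min_ess_per_chain, for every parameter."""
        d = self.diagnostics
        min_ess = self.mcmc.min_ess_per_chain * self.theta.shape[0]
        return bool(
            (d[["rhat_rank", "rhat_folded"]].max().max() <= self.mcmc.rhat_max)
            and (d[["ess_bulk", "ess_tail"]].min().min() >= min_ess)
        )

    @property
    def n_divergent(self) -> int:
        return int(sum(s.n_divergent for s in self.stats))

    # ------------------------------------------------------------------
    # model comparison
    # ------------------------------------------------------------------
    @cached_property
    def log_likelihood(self) -> np.ndarray:
        """Per-draw per-observation log likelihood, ``(chain, draw, obs)``."""
        n_chain, n_draw, _ = self.theta.shape
        n_obs = self.model.design.n_obs
        out = np.empty((n_chain, n_draw, n_obs))
        for c in range(n_chain):
            for s in range(n_draw):
                out[c, s] = self.model.posterior.log_lik_terms(self.theta[c, s])
        return out

    def waic(self) -> dict[str, float]:
        """Widely applicable information criterion, deviance scale.

        WAIC = -2 (lppd - p_waic) with lppd the summed log pointwise
        predictive density and p_waic the summed posterior variance of
        the pointwise log likelihood; SE from the pointwise deviations.
        """
        ll = self.log_likelihood.reshape(-1, self.log_likelihood.shape[-1])
        s = ll.shape[0]
        lppd_i = np.logaddexp.reduce(ll, axis=0) - np.log(s)
        p_i = ll.var(axis=0, ddof=1)
        elpd_i = lppd_i - p_i
        n = elpd_i.size
        return {
            "waic": float(-2.0 * elpd_i.sum()),
            "se": float(2.0 * np.sqrt(n * elpd_i.var(ddof=1))),
            "p_waic": float(p_i.sum()),
        }

    def loo(self) -> dict[str, float | np.ndarray]:
        """PSIS leave-one-out cross-validation, deviance scale.

        Pareto-smoothed importance sampling via arviz; observations with
        shape k > 0.7 are counted (unreliable, reported not fatal).
        """
        idata = self.inference_data
        idata.add_groups(
            log_likelihood={"y": self.log_likelihood[:, :, None, :]},
            dims={"y": ["_unit", "obs"]},
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = az.loo(idata, pointwise=True, scale="deviance")
        k = np.asarray(res.pareto_k).ravel()
        return {
            "loo": float(res.elpd_loo),
            "se": float(res.se),
            "p_loo": float(res.p_loo),
            "pareto_k": k,
            "n_high_k": int((k > 0.7).sum()),
        }

    def bayes_r2(self, return_draws: bool = False):
        """Bayesian R² for the NB response.

        Per draw: R² = var(mu) / (var(mu) + mean(mu + mu²/omega)),
        the fitted-value variance over itself plus the mean modeled
        residual variance.  Returns median and central 95% interval.
        """
        n_chain, n_draw, _ = self.theta.shape
        r2 = np.empty(n_chain * n_draw)
        omega_draws = self.params.get("omega")
        k = 0
        for c in range(n_chain):
            for s in range(n_draw):
                mu = np.exp(self.model.posterior.eta(self.theta[c, s]))
                om = (
                    float(omega_draws[c, s])
                    if omega_draws is not None
                    else self.model.spec.fixed_omega
                )
                var_mu = mu.var()
                resid = np.mean(mu + mu * mu / om)
                r2[k] = var_mu / (var_mu + resid) if (var_mu + resid) > 0 else 0.0
                k += 1
        if return_draws:
            return r2
        return {
            "median": float(np.median(r2)),
            "ci_low": float(np.percentile(r2, 2.5)),
            "ci_high": float(np.percentile(r2, 97.5)),
        }

    # ------------------------------------------------------------------
    # reports
    # ------------------------------------------------------------------
    def fixed_effects_report(self, override_convergence: bool = False) -> pd.DataFrame:
        from .reports import build_fixed_effects_report

        return build_fixed_effects_report(self, override_convergence)

    def random_effects_report(self, level: str = "participant") -> pd.DataFrame:
        from .reports import build_random_effects_report

        return build_random_effects_report(self, level)

    def summary(self, include_metrics: bool = False) -> str:
        """Human-readable fit summary (exp-scale fixed effects, random
        effect SDs, shape, diagnostics; optionally WAIC/LOO/Bayes R²)."""
        des = self.model.design
        lines = [
            "Hierarchical negative-binomial model of sensor non-collection",
            "=" * 62,
            f"Observations: {des.n_obs}   Participants: {len(des.participant_ids)}"
            f"   Studies: {len(des.study_ids)}",
            f"Chains: {self.theta.shape[0]}   Draws/chain: {self.theta.shape[1]}"
            f"   Divergences: {self.n_divergent}",
            f"Converged (R-hat <= {self.mcmc.rhat_max}, "
            f"ESS >= {self.mcmc.min_ess_per_chain:.0f}/chain): {self.converged}",
            "",
            "Fixed effects (exponentiated, rate ratios):",
        ]
        fe = self.fixed_effects_report(override_convergence=True)
        lines.append(
            fe[["estimate", "ci_low", "ci_high", "sd_log", "significant"]]
            .round(4)
            .to_string()
        )
        lines.append("")
        rows = []
        for nm, label in (
            ("sigma_gamma", "sd participant (sigma_gamma)"),
            ("sigma_delta", "sd study (sigma_delta)"),
            ("omega", "NB shape (omega)"),
        ):
            if nm in self.params:
                d = self.params[nm].reshape(-1)
                rows.append(
                    {
                        "parameter": label,
                        "median": np.median(d),
                        "ci_low": np.percentile(d, 2.5),
                        "ci_high": np.percentile(d, 97.5),
                    }
                )
        if rows:
            lines.append(pd.DataFrame(rows).set_index("parameter").round(4).to_string())
        if include_metrics:
            w, l, r2 = self.waic(), self.loo(), self.bayes_r2()
            lines += [
                "",
                f"WAIC: {w['waic']:.1f} (SE {w['se']:.1f})",
                f"LOO:  {l['loo']:.1f} (SE {l['se']:.1f}), "
                f"{l['n_high_k']} obs with Pareto k > 0.7",
                f"Bayes R2: {r2['median']:.3f} "
                f"(95% CI {r2['ci_low']:.3f}, {r2['ci_high']:.3f})",
            ]
        return "\n".join(lines)
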