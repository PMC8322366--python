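"""Bayesian hierarchical negative-binomial model of sensor non-collection.

The public modelling surface follows the Model/Results convention:
:class:`NonCollectionModel` is constructed from a participant-day panel,
its :meth:`~NonCollectionModel.fit` runs NUTS and returns a
:class:`~sensormiss.results.NonCollectionResults` carrying draws,
convergence diagnostics, model-comparison metrics and report builders.

Example
-------
>>> from sensormiss import simulate, model
>>> cfg = simulate.SimConfig(n_studies=2, participants_per_study=5,
...                          days_per_participant=10, seed=1)
>>> panel, truth = simulate.simulate_panel(simulate.generate_cohort(cfg),
...                                        simulate.GPS_TRUE_PARAMS, cfg)
>>> res = model.NonCollectionModel.from_dataframe(panel).fit(
...     model.McmcSpec(n_chains=2, n_warmup=200, n_samples=200, seed=0))
>>> print(res.summary())                                   # doctest: +SKIP
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .likelihood import (
    DesignMatrices,
    NBPosterior,
    ParamLayout,
    PriorSpec,
    build_design,
)
from .panel import complete_case_filter
from .results import NonCollectionResults
from .sampler import NutsConfig, sample_nuts
from .simulate import FIXED_EFFECT_COLS

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ModelSpec:
    """Which terms enter the model, and their priors.

    ``covariates`` lists fixed-effect design columns (subset of
    :data:`~sensormiss.simulate.FIXED_EFFECT_COLS`); reference levels
    are Android (OS), female (gender), less than a 4-year degree
    (education) and non-Hispanic White (race).  The random-intercept
    levels are individually toggleable for sensitivity refits.
    ``intercept_prior_loc`` may be the string ``"auto"``, resolving to
    the median of log1p(y) of the panel being fitted.  ``fixed_omega``
    pins the NB shape instead of sampling it (used for the Poisson-limit
    check, omega very large).
    """

    covariates: tuple[str, ...] = tuple(FIXED_EFFECT_COLS)
    participant_effect: bool = True
    study_effect: bool = True
    intercept_prior_loc: float | str = 6.7
    intercept_prior_scale: float = 2.5
    intercept_prior_df: float = 3.0
    sigma_prior_scale: float = 2.5
    sigma_prior_df: float = 3.0
    omega_prior_shape: float = 0.01
    omega_prior_rate: float = 0.01
    fixed_omega: float | None = None


@dataclass(frozen=True)
class McmcSpec:
    """Sampler settings and the convergence gate.

    Defaults follow the reference workflow: 8 independent chains, and a
    fit counts as converged only when both rank-normalized split R-hat
    variants are at most ``rhat_max`` and bulk/tail ESS reach
    ``min_ess_per_chain`` per chain.
    """

    n_chains: int = 8
    n_warmup: int = 1000
    n_samples: int = 1000
    seed: int = 0
    max_treedepth: int = 10
    target_accept: float = 0.9
    rhat_max: float = 1.01
    min_ess_per_chain: float = 100.0

    def __post_init__(self) -> None:
        if self.n_chains < 2:
            raise ValueError("need >= 2 chains for split-chain diagnostics")


class NonCollectionModel:
    """Hierarchical NB regression of daily missing measurement groupings.

    Parameters
    ----------
    panel : DataFrame
        Complete-case participant-day panel (see
        :data:`~sensormiss.panel.PANEL_COLUMNS`).  Construct via
        :meth:`from_dataframe` to apply the complete-case filter.
    spec : ModelSpec, optional
    """

    def __init__(self, panel: pd.DataFrame, spec: ModelSpec | None = None):
        self.spec = spec or ModelSpec()
        self.panel = panel.reset_index(drop=True)
        if len(self.panel) == 0:
            raise ValueError("empty panel")
        design = build_design(self.panel, list(self.spec.covariates))
        # a constant column (e.g. a race dummy with no members in this
        # panel) has an improper flat-prior posterior; drop it
        keep = [i for i in range(design.x.shape[1]) if np.ptp(design.x[:, i]) > 0]
        self.dropped_terms = [c for i, c in enumerate(design.x_cols) if i not in keep]
        if self.dropped_terms:
            logger.warning(
                "dropping constant fixed-effect column(s) %s (no variation "
                "in this panel; coefficient would be unidentified)",
                self.dropped_terms,
            )
            design = build_design(
                self.panel, [design.x_cols[i] for i in keep]
            )
        self.design: DesignMatrices = design
        if len(self.design.participant_ids) < 2:
            raise ValueError("need at least 2 participants to fit")
        loc = self.spec.intercept_prior_loc
        if loc == "auto":
            loc = float(np.median(np.log1p(self.design.y)))
        self._priors = PriorSpec(
            intercept_df=self.spec.intercept_prior_df,
            intercept_loc=float(loc),
            intercept_scale=self.spec.intercept_prior_scale,
            sigma_df=self.spec.sigma_prior_df,
            sigma_scale=self.spec.sigma_prior_scale,
            omega_shape=self.spec.omega_prior_shape,
            omega_rate=self.spec.omega_prior_rate,
        )
        self.layout = ParamLayout(
            p_fixed=self.design.x.shape[1],
            n_participants=len(self.design.participant_ids),
            n_studies=len(self.design.study_ids),
            participant_effect=self.spec.participant_effect,
            study_effect=self.spec.study_effect,
            sample_omega=self.spec.fixed_omega is None,
        )
        self.posterior = NBPosterior(
            self.design, self.layout, self._priors,
            fixed_omega=self.spec.fixed_omega, centered_qr=True,
        )

    @classmethod
    def from_dataframe(
        cls,
        panel: pd.DataFrame,
        spec: ModelSpec | None = None,
        filter_incomplete: bool = True,
    ) -> "NonCollectionModel":
        """Build a model from a panel, applying the complete-case filter.

        Participants missing any modeled covariate are dropped entirely
        (no imputation); the exclusion report is attached as
        ``model.exclusions``.
        """
        if filter_incomplete:
            panel, report = complete_case_filter(panel)
        else:
            report = pd.DataFrame(columns=["participant_id", "missing_covariates"])
        obj = cls(panel, spec)
        obj.exclusions = report
        return obj

    def initial_vector(self) -> np.ndarray:
        """Data-informed starting point: intercept at the crude log rate,
        NB shape at its method-of-moments estimate, modest random-effect
        scales, everything else at zero.  Chains jitter around this."""
        lay, des = self.layout, self.design
        theta = np.zeros(lay.dim)
        ybar = float(des.y.mean()) if des.n_obs else 1.0
        crude = math.log(ybar + 0.5) - float(des.log_e.mean())
        theta[lay.i_alpha0] = crude
        if lay.participant_effect:
            theta[lay.sl_gamma] = crude  # total intercepts start at the grand mean
            theta[lay.i_log_sigma_gamma] = math.log(0.5)
        if lay.study_effect:
            # non-centered standardized study effects start at zero
            theta[lay.i_log_sigma_delta] = math.log(0.3)
        if lay.sample_omega:
            s2 = float(des.y.var()) if des.n_obs > 1 else ybar
            om = ybar**2 / max(s2 - ybar, ybar / 10.0)
            theta[lay.i_log_omega] = math.log(min(max(om, 0.1), 10.0))
        return theta

    def _jitter_scales(self) -> np.ndarray:
        lay = self.layout
        scale = np.full(lay.dim, 0.5)
        scale[lay.sl_beta] = 0.05
        for attr in ("i_log_sigma_gamma", "i_log_sigma_delta", "i_log_omega"):
            if hasattr(lay, attr):
                scale[getattr(lay, attr)] = 0.3
        return scale

    def fit(self, mcmc: McmcSpec | None = None) -> NonCollectionResults:
        """Sample the posterior with NUTS.

        Chains run sequentially from independent jittered initializations
        seeded by spawning ``mcmc.seed``.  Non-convergence never raises:
        the returned results object carries a ``converged`` flag and the
        full diagnostics table.
        """
        mcmc = mcmc or McmcSpec()
        cfg = NutsConfig(
            n_warmup=mcmc.n_warmup,
            n_samples=mcmc.n_samples,
            max_treedepth=mcmc.max_treedepth,
            target_accept=mcmc.target_accept,
        )
        root = np.random.SeedSequence(mcmc.seed)
        center = self.initial_vector()
        jitter = self._jitter_scales()
        chains, stats = [], []
        for c, seq in enumerate(root.spawn(mcmc.n_chains)):
            rng = np.random.default_rng(seq)
            init = center + rng.uniform(-1.0, 1.0, self.layout.dim) * jitter
            draws, st = sample_nuts(self.posterior, self.layout.dim, rng, cfg, initial=init)
            logger.info(
                "chain %d/%d done: step=%.3g, divergences=%d",
                c + 1, mcmc.n_chains, st.step_size, st.n_divergent,
            )
            chains.append(draws)
            stats.append(st)
        theta = np.stack(chains)  # (chain, draw, dim)
        return NonCollectionResults(model=self, mcmc=mcmc, theta=theta, stats=stats)


def poisson_limit_spec(spec: ModelSpec | None = None, omega: float = 1e8) -> ModelSpec:
    """A copy of ``spec`` with the NB shape pinned huge, so the model
    degenerates to a Poisson GLMM (Var(y) -> mu)."""
    return replace(spec or ModelSpec(), fixed_omega=omega)
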