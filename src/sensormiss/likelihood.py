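"""Log posterior and analytic gradient of the hierarchical NB model.

The model, for participant i in study j on day d:

    y_ijd ~ NegBin(mu_ijd, omega)          Var(y) = mu + mu^2 / omega
    log mu_ijd = log E + alpha0 + beta' x_ijd + gamma_ij + delta_j
    gamma_ij ~ Normal(0, sigma_gamma^2)
    delta_j  ~ Normal(0, sigma_delta^2)

Sampling uses a mixed hierarchical parameterization chosen for the
data geometry.  Participants contribute many observations each, so the
state holds their total intercepts b_i directly (centered), with
b_i ~ Normal(a_j, sigma_gamma^2); the grand mean and study means then
drop out of the likelihood.  Studies are few (the sigma_delta
posterior reaches into its funnel near zero), so the study level is
non-centered: a_j = alpha0 + sigma_delta * u_j with u_j standard
normal.  Reported random effects are the deviations
gamma_ij = b_i - a_j and delta_j = sigma_delta * u_j.  Scale
parameters are sampled on the log scale with their Jacobians.  Priors follow
the diffuse convention of Bayesian regression software: improper flat
on beta, Student-t(3, loc, 2.5) on the intercept, half-Student-t(3, 0,
2.5) on the random-effect SDs, Gamma(0.01, 0.01) on omega.

Everything here is written for speed under MCMC: the special-function
calls (gammaln, digamma) are tabulated over the distinct values of the
bounded count y, so one posterior/gradient evaluation is a handful of
vectorized passes over the panel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import digamma, gammaln

from .simulate import FIXED_EFFECT_COLS, RACE_DUMMY_COLS

def nb_log_pmf(y, mu, omega):
    """Log pmf of the negative binomial in mean / inverse-overdispersion form.

        P(y) = Gamma(y + omega) / (Gamma(omega) y!) *
               (omega / (omega + mu))^omega * (mu / (omega + mu))^y

    Parameters may be scalars or broadcastable arrays; ``mu`` and
    ``omega`` must be strictly positive, ``y`` a non-negative integer.
    """
    y = np.asarray(y)
    mu = np.asarray(mu, dtype=float)
    omega = np.asarray(omega, dtype=float)
    if np.any(mu <= 0):
        raise ValueError("mu must be > 0")
    if np.any(omega <= 0):
        raise ValueError("omega must be > 0")
    if np.any(y < 0) or not np.issubdtype(y.dtype, np.integer):
        raise ValueError("y must be a non-negative integer")
    return (
        gammaln(y + omega)
        - gammaln(omega)
        - gammaln(y + 1)
        + omega * (np.log(omega) - np.log(omega + mu))
        + y * (np.log(mu) - np.log(omega + mu))
    )


def _student_t_logpdf(x, df, loc, scale):
    z = (x - loc) / scale
    return (
        gammaln((df + 1) / 2)
        - gammaln(df / 2)
        - 0.5 * math.log(df * math.pi)
        - math.log(scale)
        - (df + 1) / 2 * np.log1p(z * z / df)
    )


@dataclass
class PriorSpec:
    """Hyperparameters of the diffuse default priors."""

    intercept_df: float = 3.0
    intercept_loc: float = 6.7
    intercept_scale: float = 2.5
    sigma_df: float = 3.0
    sigma_scale: float = 2.5
    omega_shape: float = 0.01
    omega_rate: float = 0.01


@dataclass
class DesignMatrices:
    """Panel unpacked into arrays the sampler consumes."""

    y: np.ndarray  # (n,) int counts
    log_e: np.ndarray  # (n,) log offset
    x: np.ndarray  # (n, p) fixed-effect design, no intercept column
    x_cols: list[str]
    participant_idx: np.ndarray  # (n,) codes into participant_ids
    participant_ids: list[str]
    study_idx: np.ndarray
    study_ids: list[str]

    @property
    def n_obs(self) -> int:
        return int(self.y.size)


def build_design(panel: pd.DataFrame, covariates: list[str] | None = None) -> DesignMatrices:
    """Assemble design matrices from a complete-case panel.

    ``covariates`` selects fixed-effect columns (default: all of
    :data:`~sensormiss.simulate.FIXED_EFFECT_COLS`).  Race is expanded to
    dummies with non-Hispanic White as the reference level.
    """
    cols = list(FIXED_EFFECT_COLS) if covariates is None else list(covariates)
    unknown = set(cols) - set(FIXED_EFFECT_COLS)
    if unknown:
        raise ValueError(f"unknown covariates {sorted(unknown)}")

    work = panel.copy()
    for level, cname in RACE_DUMMY_COLS.items():
        if cname in cols:
            work[cname] = (work["race"] == level).astype(float)
    missing = [c for c in cols if work[c].isna().any()]
    if missing:
        raise ValueError(
            f"missing values in modeled covariates {missing}; "
            "run complete_case_filter first"
        )
    x = work[cols].to_numpy(dtype=float) if cols else np.empty((len(work), 0))
    p_codes, p_ids = pd.factorize(work["participant_id"], sort=True)
    s_codes, s_ids = pd.factorize(work["study_id"], sort=True)
    y = work["y_missing"].to_numpy()
    if np.any(y < 0) or np.any(y != np.floor(y)):
        raise ValueError("y_missing must be non-negative integers")
    return DesignMatrices(
        y=y.astype(np.int64),
        log_e=np.log(work["e_expected"].to_numpy(dtype=float)),
        x=np.ascontiguousarray(x),
        x_cols=cols,
        participant_idx=p_codes.astype(np.intp),
        participant_ids=list(p_ids),
        study_idx=s_codes.astype(np.intp),
        study_ids=list(s_ids),
    )


@dataclass
class ParamLayout:
    """Index map of the unconstrained sampling vector."""

    p_fixed: int
    n_participants: int
    n_studies: int
    participant_effect: bool = True
    study_effect: bool = True
    sample_omega: bool = True

    def __post_init__(self) -> None:
        i = 0
        self.i_alpha0 = i
        i += 1
        self.sl_beta = slice(i, i + self.p_fixed)
        i += self.p_fixed
        if self.participant_effect:
            self.sl_gamma = slice(i, i + self.n_participants)
            i += self.n_participants
            self.i_log_sigma_gamma = i
            i += 1
        if self.study_effect:
            self.sl_delta = slice(i, i + self.n_studies)
            i += self.n_studies
            self.i_log_sigma_delta = i
            i += 1
        if self.sample_omega:
            self.i_log_omega = i
            i += 1
        self.dim = i

    def names(self, design: DesignMatrices) -> list[str]:
        out = ["alpha0"] + [f"beta[{c}]" for c in design.x_cols]
        if self.participant_effect:
            out += [f"gamma[{p}]" for p in design.participant_ids]
            out += ["log_sigma_gamma"]
        if self.study_effect:
            out += [f"delta[{s}]" for s in design.study_ids]
            out += ["log_sigma_delta"]
        if self.sample_omega:
            out += ["log_omega"]
        return out


class NBPosterior:
    """Joint log posterior density and gradient on the unconstrained scale.

    Callable object returning ``(logp, grad)``; used both as the NUTS
    target and directly in tests against term-by-term oracles.
    """

    def __init__(
        self,
        design: DesignMatrices,
        layout: ParamLayout,
        priors: PriorSpec | None = None,
        fixed_omega: float | None = None,
        centered_qr: bool = False,
    ):
        if layout.sample_omega == (fixed_omega is not None):
            raise ValueError("set exactly one of sample_omega / fixed_omega")
        self.design = design
        self.layout = layout
        self.priors = priors or PriorSpec()
        self.fixed_omega = fixed_omega
        self.centered_qr = centered_qr
        self._pi = design.participant_idx
        self._si = design.study_idx
        self._setup_design_blocks()
        self._y = design.y
        self._yf = design.y.astype(np.float64)
        self._ymax = int(self._y.max()) if self._y.size else 0
        self._gammaln_y1 = gammaln(self._y + 1.0)
        self._gammaln_y1_sum = float(self._gammaln_y1.sum())
        self._y_sum = float(self._yf.sum())
        # multiplicity of each distinct count: lets the gammaln/digamma
        # likelihood pieces reduce at table size O(y_max), not O(n)
        self._y_counts = np.bincount(self._y, minlength=self._ymax + 1).astype(float)
        self._arange_y = np.arange(self._ymax + 1, dtype=float)
        # contiguous-group fast path: when codes are non-decreasing the
        # per-level scatter-sum is a reduceat over segment starts
        self._p_starts = self._segment_starts(self._pi, layout.n_participants)
        self._s_starts = self._segment_starts(self._si, layout.n_studies)
        # nesting map: study of each participant (hierarchical centering)
        self._p2s = np.zeros(max(layout.n_participants, 1), dtype=np.intp)
        self._p2s[self._pi] = self._si

    def _setup_design_blocks(self) -> None:
        """Reparameterize the fixed-effect design for sampling.

        With ``centered_qr`` and a participant intercept, covariates
        that are constant within participants (everything except the
        time term here) move into the prior regression for the
        participant intercepts, b_i ~ Normal(a_j + x_i' beta_c,
        sigma_gamma^2); only time-varying columns stay in the
        likelihood.  Each block is centered and thin-QR orthogonalized.
        Both moves are exact reparameterizations -- the posterior over
        the natural parameters is unchanged -- chosen purely for sampler
        geometry: they remove the ridges between coefficients, the
        intercept and the per-participant intercepts.
        """
        design, lay = self.design, self.layout
        p = design.x.shape[1]
        n = design.n_obs
        if p and lay.participant_effect and self.centered_qr and n:
            # first occurrence row of each participant (reversed fancy
            # assignment: earliest row wins)
            first = np.zeros(lay.n_participants, dtype=np.intp)
            first[self._pi[::-1]] = np.arange(n - 1, -1, -1)
            const_cols = [
                j
                for j in range(p)
                if np.array_equal(design.x[:, j], design.x[first, j][self._pi])
            ]
        else:
            first = np.zeros(lay.n_participants, dtype=np.intp)
            const_cols = []
        self._const_idx = np.asarray(const_cols, dtype=np.intp)
        self._tv_idx = np.asarray(
            [j for j in range(p) if j not in const_cols], dtype=np.intp
        )

        def center_qr(mat: np.ndarray, labels: list[str]):
            rows, cols = mat.shape
            if not self.centered_qr or cols == 0 or rows <= cols:
                return mat, np.eye(cols), np.zeros(cols)
            mean = mat.mean(axis=0)
            q, r = np.linalg.qr(mat - mean)
            diag = np.abs(np.diag(r))
            if diag.size and diag.min() <= 1e-8 * max(diag.max(), 1.0):
                bad = labels[int(diag.argmin())]
                raise ValueError(
                    f"fixed-effect design is rank deficient (column {bad!r} "
                    "is constant or collinear); drop it before fitting"
                )
            sn = math.sqrt(rows - 1)
            return np.ascontiguousarray(q * sn), np.linalg.inv(r / sn), mean

        x_tv = np.ascontiguousarray(design.x[:, self._tv_idx])
        tv_labels = [design.x_cols[j] for j in self._tv_idx]
        self._x_like, r_inv_tv, mean_tv = center_qr(x_tv, tv_labels)
        self._x_likeT = np.ascontiguousarray(self._x_like.T)

        if self._const_idx.size:
            xp = np.ascontiguousarray(design.x[first][:, self._const_idx])
            c_labels = [design.x_cols[j] for j in self._const_idx]
            self._xp, r_inv_c, mean_c = center_qr(xp, c_labels)
            self._xpT = np.ascontiguousarray(self._xp.T)
        else:
            self._xp = np.empty((lay.n_participants, 0))
            self._xpT = self._xp.T
            r_inv_c = np.eye(0)
            mean_c = np.zeros(0)

        # full-vector transforms back to the natural scale
        self._R_inv = np.zeros((p, p))
        if self._tv_idx.size:
            self._R_inv[np.ix_(self._tv_idx, self._tv_idx)] = r_inv_tv
        if self._const_idx.size:
            self._R_inv[np.ix_(self._const_idx, self._const_idx)] = r_inv_c
        self._x_mean = np.zeros(p)
        self._x_mean[self._tv_idx] = mean_tv
        self._x_mean[self._const_idx] = mean_c
        # absolute positions of each block in the sampling vector
        self._beta_pos_tv = lay.sl_beta.start + self._tv_idx
        self._beta_pos_const = lay.sl_beta.start + self._const_idx

    @staticmethod
    def _segment_starts(codes: np.ndarray, n_levels: int) -> np.ndarray | None:
        if codes.size == 0 or np.any(np.diff(codes) < 0):
            return None
        starts = np.concatenate(([0], np.flatnonzero(np.diff(codes)) + 1))
        if starts.size != n_levels:
            return None
        return starts

    def _scatter(self, g: np.ndarray, codes: np.ndarray, starts, n_levels: int):
        if starts is not None:
            return np.add.reduceat(g, starts)
        return np.bincount(codes, weights=g, minlength=n_levels)

    # -- tabulated special functions over distinct y values ------------
    # the gammaln(omega) / digamma(omega) reference is subtracted at
    # table level so per-row terms stay O(y log omega) even for huge
    # omega (Poisson limit), avoiding catastrophic cancellation
    def _gammaln_y_omega(self, omega: float) -> np.ndarray:
        table = gammaln(np.arange(self._ymax + 1) + omega) - gammaln(omega)
        return table[self._y]

    def _digamma_y_omega(self, omega: float) -> np.ndarray:
        table = digamma(np.arange(self._ymax + 1) + omega) - digamma(omega)
        return table[self._y]

    def natural_fixed_effects(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map sampling-scale draws to the natural intercept and betas.

        ``theta`` may be a vector or a stacked array ``(..., dim)``;
        returns ``(alpha0, beta)`` with the QR/centering transform
        undone (identity when ``centered_qr`` is off).
        """
        lay = self.layout
        beta = np.asarray(theta)[..., lay.sl_beta] @ self._R_inv.T
        alpha0 = np.asarray(theta)[..., lay.i_alpha0] - beta @ self._x_mean
        return alpha0, beta

    def unpack(self, theta: np.ndarray) -> dict:
        """Constrained-scale view of an unconstrained vector."""
        lay, d = self.layout, {}
        alpha0 = theta[lay.i_alpha0]
        d["alpha0"] = alpha0
        d["beta"] = theta[lay.sl_beta]
        if lay.study_effect:
            sd = math.exp(theta[lay.i_log_sigma_delta])
            d["sigma_delta"] = sd
            d["delta"] = sd * theta[lay.sl_delta]
        if lay.participant_effect:
            d["sigma_gamma"] = math.exp(theta[lay.i_log_sigma_gamma])
            parent = alpha0 + (
                d["delta"][self._p2s] if lay.study_effect else 0.0
            )
            if self._const_idx.size:
                parent = parent + self._xp @ theta[self._beta_pos_const]
            d["gamma"] = theta[lay.sl_gamma] - parent
        d["omega"] = (
            math.exp(theta[lay.i_log_omega]) if lay.sample_omega else self.fixed_omega
        )
        return d

    def eta(self, theta: np.ndarray) -> np.ndarray:
        """Linear predictor log mu per observation."""
        lay, des = self.layout, self.design
        if lay.participant_effect:
            intercepts = theta[lay.sl_gamma][self._pi]
        elif lay.study_effect:
            sd = math.exp(theta[lay.i_log_sigma_delta])
            intercepts = theta[lay.i_alpha0] + sd * theta[lay.sl_delta][self._si]
        else:
            intercepts = theta[lay.i_alpha0]
        eta = des.log_e + intercepts
        if self._tv_idx.size:
            eta = eta + self._x_like @ theta[self._beta_pos_tv]
        return eta

    def log_lik_terms(self, theta: np.ndarray) -> np.ndarray:
        """Per-observation NB log likelihood (for WAIC / LOO)."""
        d = self.unpack(theta)
        omega = d["omega"]
        eta = self.eta(theta)
        mu = np.exp(eta)
        # omega*log(omega/(omega+mu)) via log1p: stable in the Poisson
        # limit omega >> mu where the direct difference of logs cancels
        log1p_mu_om = np.log1p(mu / omega)
        return (
            self._gammaln_y_omega(omega)
            - self._gammaln_y1
            - omega * log1p_mu_om
            + self._y * (eta - math.log(omega) - log1p_mu_om)
        )

    def __call__(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        lay, des, pri = self.layout, self.design, self.priors
        y = self._y
        grad = np.zeros_like(theta)

        # reject states the sampler probes during step-size search that
        # would overflow exp(); -inf reads as a divergence upstream
        if not np.all(np.isfinite(theta)):
            return -np.inf, grad
        if lay.sample_omega and abs(theta[lay.i_log_omega]) > 50.0:
            return -np.inf, grad
        if lay.participant_effect and theta[lay.i_log_sigma_gamma] > 50.0:
            return -np.inf, grad
        if lay.study_effect and theta[lay.i_log_sigma_delta] > 50.0:
            return -np.inf, grad
        omega = (
            math.exp(theta[lay.i_log_omega]) if lay.sample_omega else self.fixed_omega
        )

        if lay.participant_effect:
            eta = des.log_e + theta[lay.sl_gamma][self._pi]
        elif lay.study_effect:
            sd_ = math.exp(theta[lay.i_log_sigma_delta])
            eta = des.log_e + theta[lay.i_alpha0] + sd_ * theta[lay.sl_delta][self._si]
        else:
            eta = des.log_e + theta[lay.i_alpha0]
        if self._tv_idx.size:
            eta = eta + self._x_like @ theta[self._beta_pos_tv]
        if eta.size and eta.max() > 250.0:  # exp would overflow downstream
            return -np.inf, grad

        yf = self._yf
        mu = np.exp(eta)
        inv_om_mu = 1.0 / (omega + mu)
        a = (yf + omega) * inv_om_mu
        l1p = np.log1p(mu / omega)
        gl_table = gammaln(self._arange_y + omega) - gammaln(omega)
        ll_core = (
            float(self._y_counts @ gl_table)
            - self._gammaln_y1_sum
            - omega * float(l1p.sum())
            + float(yf @ eta)
            - math.log(omega) * self._y_sum
            - float(yf @ l1p)
        )
        if not np.isfinite(ll_core):
            return -np.inf, grad
        # d loglik / d eta, scattered into each effect level
        g_eta = yf - mu * a
        sum_g = float(g_eta.sum())
        xtg = self._x_likeT @ g_eta if self._tv_idx.size else np.empty(0)
        g_scatter = (
            self._scatter(g_eta, self._pi, self._p_starts, lay.n_participants)
            if lay.participant_effect
            else None
        )
        d_scatter = (
            self._scatter(g_eta, self._si, self._s_starts, lay.n_studies)
            if lay.study_effect
            else None
        )
        if lay.sample_omega:
            dg_table = digamma(self._arange_y + omega) - digamma(omega)
            dom = (
                float(self._y_counts @ dg_table)
                + yf.size
                - float(l1p.sum())
                - float(a.sum())
            )

        logp = ll_core
        if self._tv_idx.size:
            grad[self._beta_pos_tv] = xtg
        a0 = theta[lay.i_alpha0]
        grad_a0 = 0.0

        def half_t_terms(i_ls, resid_ss, n_groups):
            # Normal(resid; 0, sigma^2) levels plus half-t(sigma) prior
            # and the log-transform Jacobian; returns (logp_add, grad_ls)
            sigma = math.exp(theta[i_ls])
            lp = (
                -0.5 * resid_ss / sigma**2
                - n_groups * (theta[i_ls] + 0.5 * math.log(2 * math.pi))
                + float(_student_t_logpdf(sigma, pri.sigma_df, 0.0, pri.sigma_scale))
                + math.log(2.0)
                + theta[i_ls]
            )
            g_ls = (
                resid_ss / sigma**2
                - n_groups
                - (pri.sigma_df + 1) * sigma**2
                / (pri.sigma_df * pri.sigma_scale**2 + sigma**2)
                + 1.0
            )
            return lp, g_ls, sigma

        if lay.study_effect:
            sig_d = math.exp(theta[lay.i_log_sigma_delta])
            u = theta[lay.sl_delta]
            a_vec = a0 + sig_d * u  # study intercepts, non-centered
        if lay.participant_effect:
            b = theta[lay.sl_gamma]
            grad[lay.sl_gamma] = g_scatter
            parent = a_vec[self._p2s] if lay.study_effect else a0
            if self._const_idx.size:
                parent = parent + self._xp @ theta[self._beta_pos_const]
            r_b = b - parent
            lp, g_ls, sig_g = half_t_terms(
                lay.i_log_sigma_gamma, float(r_b @ r_b), b.size
            )
            logp += lp
            grad[lay.i_log_sigma_gamma] = g_ls
            grad[lay.sl_gamma] -= r_b / sig_g**2
            pull_b = r_b / sig_g**2  # gradient flowing up to the parent level
            if self._const_idx.size:
                grad[self._beta_pos_const] = self._xpT @ pull_b
            pull_a = np.bincount(self._p2s, weights=pull_b, minlength=lay.n_studies)
        elif lay.study_effect:
            pull_a = d_scatter  # likelihood gradient lands on a_j directly
        if lay.study_effect:
            # standard-normal prior on u plus half-t prior on sigma_delta
            logp += -0.5 * float(u @ u) - u.size * 0.5 * math.log(2 * math.pi)
            logp += float(
                _student_t_logpdf(sig_d, pri.sigma_df, 0.0, pri.sigma_scale)
            ) + math.log(2.0) + theta[lay.i_log_sigma_delta]
            grad[lay.sl_delta] = sig_d * pull_a - u
            grad[lay.i_log_sigma_delta] = (
                sig_d * float(u @ pull_a)
                - (pri.sigma_df + 1) * sig_d**2
                / (pri.sigma_df * pri.sigma_scale**2 + sig_d**2)
                + 1.0
            )
            grad_a0 += float(pull_a.sum())
        elif lay.participant_effect:
            grad_a0 += float(pull_b.sum())
        else:
            grad_a0 += sum_g

        # intercept prior (applies to the centered intercept under QR)
        logp += float(
            _student_t_logpdf(a0, pri.intercept_df, pri.intercept_loc, pri.intercept_scale)
        )
        z = (a0 - pri.intercept_loc) / pri.intercept_scale
        grad[lay.i_alpha0] = grad_a0 - (
            (pri.intercept_df + 1) * z / (pri.intercept_df + z * z) / pri.intercept_scale
        )

        if lay.sample_omega:
            dll_domega = dom
            # Gamma(a, b) prior on omega with the log-transform Jacobian
            a, b = pri.omega_shape, pri.omega_rate
            logp += (
                a * math.log(b)
                - float(gammaln(a))
                + (a - 1) * math.log(omega)
                - b * omega
                + theta[lay.i_log_omega]
            )
            grad[lay.i_log_omega] = omega * dll_domega + a - b * omega

        return float(logp), grad
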