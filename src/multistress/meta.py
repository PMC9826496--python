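"""Multilevel random-effects meta-analysis of effect sizes, and the
asymmetry-accuracy Gamma regression.

The meta-analytic model for effect sizes d_i with known sampling variances
v_i is the three-level mixed model

    d_i = x_i' beta + u_study(i) + u_id(i) + e_i,
    u_study ~ N(0, tau2_study),  u_id ~ N(0, tau2_id),  e_i ~ N(0, v_i),

with observation IDs nested within studies: the study component captures
nonindependence of responses from the same study, the ID component residual
heterogeneity between observations.  Fixed effects are per-level means of a
categorical moderator (no-intercept dummy coding, so each coefficient is a
level mean with a direct Wald CI).  Variance components are estimated by
REML with non-negativity bounds; QE is the classical residual-heterogeneity
statistic of the fixed-effect (1/v_i-weighted) moderator model, and QM the
Wald chi-square omnibus test of the moderator coefficients.

The asymmetry-accuracy relationship (does prediction error |d| shrink or
grow with stressor asymmetry?) is modelled as a Gamma GLM with log link,
log E[|d|] = b0 + b1 * degree, fitted separately for the subset where
temperature prevails and the subset where the second stressor prevails.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
import statsmodels.api as sm


class UnderdeterminedError(ValueError):
    """Fewer effects than fixed-effect parameters."""


class ConvergenceError(RuntimeError):
    """The REML variance-component optimisation failed to converge."""


# ---------------------------------------------------------------------------
# Multilevel meta-analysis
# ---------------------------------------------------------------------------


class MultilevelMetaAnalysis:
    """Three-level random-effects meta-analysis model.

    Parameters
    ----------
    d : array-like
        Effect sizes (one per observation).
    v : array-like
        Known sampling variances of the effect sizes (> 0).
    study : array-like
        Study labels (outer random-effect grouping).
    obs : array-like, optional
        Observation/response IDs nested within studies; defaults to one
        distinct ID per row.
    moderator : array-like, optional
        Categorical moderator; one fixed-effect mean is estimated per level.
        Omitted: a single overall mean is estimated.

    Examples
    --------
    >>> fit = MultilevelMetaAnalysis(d, v, study, obs, moderator=level).fit()
    >>> fit.params        # per-level mean effects
    >>> fit.tau2_study, fit.tau2_id
    >>> print(fit.summary())
    """

    def __init__(self, d, v, study, obs=None, moderator=None):
        self.d = np.asarray(d, dtype=float)
        self.v = np.asarray(v, dtype=float)
        self.k = self.d.size
        if self.k == 0:
            raise ValueError("no effects supplied")
        if np.any(~np.isfinite(self.d)) or np.any(~np.isfinite(self.v)):
            raise ValueError("effects and variances must be finite")
        if np.any(self.v <= 0):
            raise ValueError("all sampling variances must be > 0")
        study = np.asarray(study)
        if study.size != self.k:
            raise ValueError("study labels must match the number of effects")
        obs = np.arange(self.k) if obs is None else np.asarray(obs)

        if moderator is None:
            self.levels = ["overall"]
            self.X = np.ones((self.k, 1))
        else:
            moderator = np.asarray(moderator)
            self.levels = sorted(pd.unique(moderator).tolist())
            self.X = np.column_stack(
                [(moderator == lev).astype(float) for lev in self.levels]
            )
        self.p = self.X.shape[1]
        if self.k < self.p:
            raise UnderdeterminedError(
                f"k = {self.k} effects cannot identify p = {self.p} level means"
            )

        # Per-study blocks; within each block a same-ID indicator matrix.
        self._blocks = []
        for s in pd.unique(study):
            idx = np.flatnonzero(study == s)
            ids = obs[idx]
            same_id = (ids[:, None] == ids[None, :]).astype(float)
            self._blocks.append((idx, same_id))

    @classmethod
    def from_dataframe(
        cls,
        frame: pd.DataFrame,
        effect_col: str = "d",
        var_col: str = "v_d",
        study_col: str = "study_id",
        obs_col: str = "response_id",
        moderator_col: Optional[str] = None,
    ) -> "MultilevelMetaAnalysis":
        return cls(
            frame[effect_col].to_numpy(),
            frame[var_col].to_numpy(),
            frame[study_col].to_numpy(),
            frame[obs_col].to_numpy() if obs_col in frame.columns else None,
            frame[moderator_col].to_numpy() if moderator_col else None,
        )

    # -- likelihood machinery ------------------------------------------------

    def _gls(self, tau2_study: float, tau2_id: float):
        """GLS pieces at fixed variance components.

        Returns (beta, cov_beta, reml_nll, logdet_V).
        """
        p = self.p
        XtViX = np.zeros((p, p))
        XtViy = np.zeros(p)
        yViy = 0.0
        logdet = 0.0
        for idx, same_id in self._blocks:
            Vs = np.diag(self.v[idx]) + tau2_id * same_id + tau2_study
            L = np.linalg.cholesky(Vs)
            logdet += 2.0 * np.sum(np.log(np.diag(L)))
            Zx = np.linalg.solve(L, self.X[idx])
            Zy = np.linalg.solve(L, self.d[idx])
            XtViX += Zx.T @ Zx
            XtViy += Zx.T @ Zy
            yViy += Zy @ Zy
        cov_beta = np.linalg.inv(XtViX)
        beta = cov_beta @ XtViy
        quad = yViy - beta @ XtViy
        sign, logdet_XtViX = np.linalg.slogdet(XtViX)
        nll = 0.5 * (logdet + logdet_XtViX + quad)
        return beta, cov_beta, nll, logdet

    def _nll(self, tau2: Sequence[float]) -> float:
        t_s, t_id = max(tau2[0], 0.0), max(tau2[1], 0.0)
        try:
            return self._gls(t_s, t_id)[2]
        except np.linalg.LinAlgError:
            return np.inf

    def fit(
        self,
        method: str = "reml",
        tau2: Optional[Sequence[float]] = None,
        maxiter: int = 500,
    ) -> "MultilevelMetaResults":
        """Fit the model.

        Parameters
        ----------
        method
            Only ``"reml"`` is implemented.
        tau2
            Optional ``(tau2_study, tau2_id)`` pair fixing the variance
            components instead of estimating them (e.g. ``(0, 0)`` for the
            fixed-effect reduction).
        """
        if method != "reml":
            raise ValueError("only REML estimation is implemented")
        converged = True
        n_iter = 0
        if tau2 is not None:
            t_s, t_id = float(tau2[0]), float(tau2[1])
            if t_s < 0 or t_id < 0:
                raise ValueError("variance components must be >= 0")
        elif self.k <= self.p:
            t_s = t_id = 0.0
        else:
            scale = float(np.var(self.d)) if self.k > 1 else 1.0
            ub = max(10.0 * scale, 1.0)
            start = max(scale / 2.0, 1e-3)
            best = None
            for x0 in ([start, start], [1e-4, start], [start, 1e-4]):
                res = optimize.minimize(
                    self._nll,
                    x0=x0,
                    method="L-BFGS-B",
                    bounds=[(0.0, ub)] * 2,
                    options={"maxiter": maxiter},
                )
                n_iter += res.nit
                if best is None or res.fun < best.fun - 1e-10:
                    best = res
            if not best.success and not np.isfinite(best.fun):
                raise ConvergenceError(
                    f"REML optimisation failed: {best.message} "
                    f"(after {n_iter} iterations)"
                )
            converged = bool(best.success)
            t_s, t_id = float(best.x[0]), float(best.x[1])

        beta, cov_beta, nll, _ = self._gls(t_s, t_id)

        # QE: residual heterogeneity of the fixed-effect (1/v-weighted) model.
        w = 1.0 / self.v
        XtWX = self.X.T @ (w[:, None] * self.X)
        beta_fe = np.linalg.solve(XtWX, self.X.T @ (w * self.d))
        resid = self.d - self.X @ beta_fe
        qe = float(resid @ (w * resid))
        qe_df = self.k - self.p
        qe_p = float(stats.chi2.sf(qe, qe_df)) if qe_df > 0 else math.nan

        # QM: Wald omnibus test of all moderator coefficients.
        qm = float(beta @ np.linalg.solve(cov_beta, beta))
        qm_df = self.p
        qm_p = float(stats.chi2.sf(qm, qm_df))

        return MultilevelMetaResults(
            model=self,
            params=pd.Series(beta, index=self.levels, name="mean_d"),
            cov_params=pd.DataFrame(cov_beta, index=self.levels, columns=self.levels),
            tau2_study=t_s,
            tau2_id=t_id,
            qe=qe,
            qe_df=qe_df,
            qe_pvalue=qe_p,
            qm=qm,
            qm_df=qm_df,
            qm_pvalue=qm_p,
            reml_nll=float(nll),
            converged=converged,
            n_iter=n_iter,
        )


@dataclass
class MultilevelMetaResults:
    """Results of a :class:`MultilevelMetaAnalysis` fit."""

    model: MultilevelMetaAnalysis
    params: pd.Series
    cov_params: pd.DataFrame
    tau2_study: float
    tau2_id: float
    qe: float
    qe_df: int
    qe_pvalue: float
    qm: float
    qm_df: int
    qm_pvalue: float
    reml_nll: float
    converged: bool
    n_iter: int

    @property
    def k(self) -> int:
        return self.model.k

    @property
    def bse(self) -> pd.Series:
        return pd.Series(
            np.sqrt(np.diag(self.cov_params.to_numpy())),
            index=self.params.index,
            name="se",
        )

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        z = stats.norm.ppf(1 - alpha / 2)
        lo = self.params - z * self.bse
        hi = self.params + z * self.bse
        return pd.DataFrame({"ci_low": lo, "ci_high": hi})

    def classify_levels(self, alpha: float = 0.05) -> pd.Series:
        """Interaction class per level from the mean effect's CI.

        'null' when the CI spans zero (observed indistinguishable from the
        null prediction), 'antagonistic' when significantly negative
        (observed smaller than predicted), 'synergistic_or_amplified' when
        significantly positive.
        """
        ci = self.conf_int(alpha)
        out = {}
        for lev in self.params.index:
            if ci.loc[lev, "ci_high"] < 0:
                out[lev] = "antagonistic"
            elif ci.loc[lev, "ci_low"] > 0:
                out[lev] = "synergistic_or_amplified"
            else:
                out[lev] = "null"
        return pd.Series(out, name="interaction_class")

    def level_table(self, alpha: float = 0.05) -> pd.DataFrame:
        """Per-level summary: mean, SE, CI, k and interaction class."""
        counts = self.model.X.sum(axis=0).astype(int)
        tab = pd.DataFrame(
            {
                "mean_d": self.params,
                "se": self.bse,
                "k": pd.Series(counts, index=self.params.index),
            }
        ).join(self.conf_int(alpha))
        tab["interaction_class"] = self.classify_levels(alpha)
        return tab

    def summary(self) -> str:
        lines = [
            "Multilevel random-effects meta-analysis (REML)",
            f"k = {self.k} effects, {len(self.model._blocks)} studies, "
            f"{self.model.p} level mean(s)",
            f"tau2_study = {self.tau2_study:.4f}   tau2_id = {self.tau2_id:.4f}",
            f"QE({self.qe_df}) = {self.qe:.3f}, p = {self.qe_pvalue:.4g}",
            f"QM({self.qm_df}) = {self.qm:.3f}, p = {self.qm_pvalue:.4g}",
            f"converged: {self.converged} ({self.n_iter} optimizer iterations)",
            "",
            self.level_table().to_string(float_format=lambda x: f"{x:.4f}"),
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "levels": list(self.params.index),
            "mean_d": self.params.tolist(),
            "se": self.bse.tolist(),
            "ci_low": self.conf_int()["ci_low"].tolist(),
            "ci_high": self.conf_int()["ci_high"].tolist(),
            "tau2_study": self.tau2_study,
            "tau2_id": self.tau2_id,
            "QE": self.qe,
            "QE_df": self.qe_df,
            "QE_pvalue": self.qe_pvalue,
            "QM": self.qm,
            "QM_df": self.qm_df,
            "QM_pvalue": self.qm_pvalue,
            "converged": self.converged,
        }


def fit_multilevel_meta(
    effects: pd.DataFrame,
    moderator_col: Optional[str] = None,
    effect_col: str = "d",
    var_col: str = "v_d",
    study_col: str = "study_id",
    obs_col: str = "response_id",
) -> MultilevelMetaResults:
    """Fit the three-level meta-analysis from a long effect-size table.

    Rows flagged as outliers or undefined must be removed by the caller (the
    pipeline does this and accounts for the exclusions).
    """
    model = MultilevelMetaAnalysis.from_dataframe(
        effects, effect_col, var_col, study_col, obs_col, moderator_col
    )
    return model.fit()


def classify_mean_effect(mean: float, ci_low: float, ci_high: float) -> str:
    """Interaction class of one pooled mean effect from its CI."""
    if ci_high < 0:
        return "antagonistic"
    if ci_low > 0:
        return "synergistic_or_amplified"
    return "null"


# ---------------------------------------------------------------------------
# Asymmetry-accuracy Gamma GLM
# ---------------------------------------------------------------------------

DEFAULT_GLM_EPSILON = 1e-9


class AsymmetryAccuracyGLM:
    """Gamma log-link regression of prediction error on stressor asymmetry.

    Models log E[|d|] = b0 + b1 * degree for one prevailing-stressor subset.
    A small constant ``epsilon`` is added to the responses of the
    temperature-prevailing subset (where exact zeros occur) so the Gamma
    likelihood is defined; ``epsilon_all=True`` applies it to every subset.

    Parameters
    ----------
    abs_d : array-like
        Absolute effect sizes (>= 0 before epsilon).
    degree : array-like
        Degrees of asymmetry (percent-effect difference).
    subset : str
        'temperature' or 'other' — which stressor prevails in this subset.
    """

    def __init__(
        self,
        abs_d,
        degree,
        subset: str = "other",
        epsilon: float = DEFAULT_GLM_EPSILON,
        epsilon_all: bool = False,
    ):
        y = np.asarray(abs_d, dtype=float)
        x = np.asarray(degree, dtype=float)
        if y.size != x.size:
            raise ValueError("abs_d and degree must have equal length")
        if y.size < 3:
            raise ValueError("need at least 3 observations per subset")
        if np.any(y < 0):
            raise ValueError("absolute effect sizes must be >= 0")
        if subset == "temperature" or epsilon_all:
            y = y + epsilon
        elif np.any(y == 0):
            raise ValueError(
                "zero responses in subset; re-fit with epsilon_all=True to "
                "add the small constant"
            )
        self.subset = subset
        self.endog = y
        self.exog = sm.add_constant(x)

    def fit(self) -> "AsymmetryAccuracyResults":
        if np.ptp(self.endog) == 0:
            # Constant response: the fit is analytic (b0 = log y, b1 = 0);
            # IRLS cannot start from a zero-deviance configuration.
            return AsymmetryAccuracyResults(
                subset=self.subset,
                intercept=float(np.log(self.endog[0])),
                slope=0.0,
                bse=(0.0, 0.0),
                dispersion=0.0,
                nobs=int(self.endog.size),
            )
        glm = sm.GLM(
            self.endog,
            self.exog,
            family=sm.families.Gamma(link=sm.families.links.Log()),
        )
        res = glm.fit()
        if not res.converged:
            raise ConvergenceError("Gamma GLM IRLS did not converge")
        return AsymmetryAccuracyResults(
            subset=self.subset,
            intercept=float(res.params[0]),
            slope=float(res.params[1]),
            bse=(float(res.bse[0]), float(res.bse[1])),
            dispersion=float(res.scale),
            nobs=int(res.nobs),
            _sm_results=res,
        )


@dataclass
class AsymmetryAccuracyResults:
    """Fitted Gamma GLM: coefficients on the log scale."""

    subset: str
    intercept: float
    slope: float
    bse: tuple
    dispersion: float
    nobs: int
    _sm_results: object = None

    def predict(self, degree) -> np.ndarray:
        """Fitted mean |d| at the given asymmetry degrees: exp(b0 + b1*x)."""
        x = np.asarray(degree, dtype=float)
        return np.exp(self.intercept + self.slope * x)

    @property
    def accuracy_trend(self) -> str:
        """'improving' if |d| shrinks with asymmetry (negative slope)."""
        return "improving" if self.slope < 0 else "worsening"

    def to_dict(self) -> dict:
        return {
            "subset": self.subset,
            "intercept": self.intercept,
            "slope": self.slope,
            "se_intercept": self.bse[0],
            "se_slope": self.bse[1],
            "dispersion": self.dispersion,
            "n": self.nobs,
            "accuracy_trend": self.accuracy_trend,
        }


def fit_gamma_glm(
    abs_effects,
    asymmetry,
    subset: str = "other",
    epsilon: float = DEFAULT_GLM_EPSILON,
    epsilon_all: bool = False,
) -> AsymmetryAccuracyResults:
    """Convenience wrapper around :class:`AsymmetryAccuracyGLM`."""
    return AsymmetryAccuracyGLM(abs_effects, asymmetry, subset, epsilon, epsilon_all).fit()
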