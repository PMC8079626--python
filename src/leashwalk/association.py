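"""Personality-behaviour association protocol.

Walk outcomes (tension metrics, behaviour rates, questionnaire factors) are
linked to handler personality through a fixed model-building protocol:

1. **Transform** the outcome (log10 or a power) so residuals are plausibly
   Gaussian; each outcome carries its own :class:`TransformSpec`.
2. **Screen** every candidate predictor in a bivariate linear model,
   keeping those with p < 0.2.  The five personality domain scores and the
   dog's behavioural level are *forced*: retained regardless of p.
3. **Fit** a linear mixed model with crossed random intercepts for
   volunteer and dog (walks are repeated measurements of both), estimated
   by maximum likelihood.
4. **Backward-eliminate** the non-forced predictor with the largest
   p >= 0.05, refitting and recording BIC until every non-forced predictor
   is significant or only forced predictors remain.
5. **Check collinearity** with variance inflation factors (flagging
   VIF >= 2) and report Shapiro-Wilk residual diagnostics.

The public surface follows the statsmodels idiom: a
:class:`WalkAssociationModel` is built from a tidy one-row-per-walk
DataFrame, and :meth:`~WalkAssociationModel.fit` /
:meth:`~WalkAssociationModel.backward_eliminate` return a
:class:`WalkAssociationResults` carrying estimates, their uncertainties,
diagnostics and a ``summary()`` table.  Estimation is delegated to
:class:`statsmodels.regression.mixed_linear_model.MixedLM`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from leashwalk.errors import ParameterError, RangeError

FORCED_DEFAULT = ("neuroticism", "extraversion", "openness", "agreeableness",
                  "conscientiousness", "dog_level")

ALPHA_SCREEN = 0.2
ALPHA_KEEP = 0.05
VIF_BOUND = 2.0


@dataclass(frozen=True)
class TransformSpec:
    """Outcome transform: identity, log10 or a power x**exponent."""

    kind: str = "identity"
    exponent: float = 1.0

    def __post_init__(self):
        if self.kind not in ("identity", "log10", "power"):
            raise ParameterError(f"unknown transform kind {self.kind!r}")
        if self.kind == "power" and self.exponent == 0:
            raise ParameterError("power transform exponent must be nonzero")

    def apply(self, values):
        return transform_outcome(values, self)

    def invert(self, values):
        values = np.asarray(values, dtype=float)
        if self.kind == "identity":
            return values
        if self.kind == "log10":
            return 10.0 ** values
        return values ** (1.0 / self.exponent)

    @property
    def label(self) -> str:
        if self.kind == "identity":
            return ""
        if self.kind == "log10":
            return "log10"
        return f"power {self.exponent:g}"


@dataclass(frozen=True)
class ModelSpec:
    """What to model: outcome + transform, forced and screened predictors,
    and the two random-intercept grouping columns."""

    outcome: str
    transform: TransformSpec = TransformSpec()
    forced: tuple = FORCED_DEFAULT
    screened: tuple = ()
    groups: tuple = ("volunteer_id", "dog_id")

    def __post_init__(self):
        if set(self.forced) & set(self.screened):
            raise ParameterError("forced and screened predictor sets must be disjoint")
        if len(self.groups) != 2:
            raise ParameterError("exactly two random-intercept grouping factors required")


@dataclass
class WalkAssociationResults:
    """Estimates and diagnostics of one fitted association model.

    Mirrors a statsmodels results object: per-predictor coefficients,
    standard errors and Wald-z p-values, the ML BIC, variance components,
    the VIF table, and (after elimination) the ordered removal trace.
    """

    spec: ModelSpec
    predictors: tuple
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    bic: float
    llf: float
    vc_variances: dict
    residual_variance: float
    nobs: int
    vif: pd.Series
    elimination_trace: list = field(default_factory=list)  # (name, p_at_removal, bic_after)
    bic_path: list = field(default_factory=list)
    shapiro_w: float = np.nan
    shapiro_p: float = np.nan
    converged: bool = True
    _resid: np.ndarray | None = None

    def summary(self) -> str:
        spec = self.spec
        out = spec.outcome if not spec.transform.label else \
            f"{spec.transform.label}({spec.outcome})"
        lines = [
            "Walk association model (linear mixed model, ML)",
            "=" * 60,
            f"Outcome: {out}    n walks: {self.nobs}",
            f"Random intercepts: {spec.groups[0]}, {spec.groups[1]} (crossed)",
            f"BIC: {self.bic:.2f}    log-likelihood: {self.llf:.2f}",
            "-" * 60,
            f"{'predictor':<22}{'beta':>10}{'SE':>10}{'p':>10}  ",
        ]
        for name in self.params.index:
            forced = " (forced)" if name in spec.forced else ""
            lines.append(
                f"{name:<22}{self.params[name]:>10.4g}{self.bse[name]:>10.4g}"
                f"{self.pvalues[name]:>10.3g}{forced}"
            )
        lines.append("-" * 60)
        vcs = "  ".join(f"{k}: {v:.4g}" for k, v in self.vc_variances.items())
        lines.append(f"Random-effect variances: {vcs}; residual: "
                     f"{self.residual_variance:.4g}")
        if len(self.vif):
            flagged = [n for n, v in self.vif.items() if v >= VIF_BOUND]
            lines.append("VIF: " + "  ".join(f"{n}: {v:.3g}" for n, v in self.vif.items())
                         + (f"  [flagged >= {VIF_BOUND:g}: {flagged}]" if flagged else ""))
        if self.elimination_trace:
            steps = ", ".join(f"{n} (p={p:.3g})" for n, p, _ in self.elimination_trace)
            lines.append(f"Eliminated (in order): {steps}")
        if np.isfinite(self.shapiro_w):
            lines.append(f"Residual Shapiro-Wilk: W={self.shapiro_w:.4f} "
                         f"p={self.shapiro_p:.3g} (diagnostic only)")
        return "\n".join(lines)


class WalkAssociationModel:
    """Mixed-model association between walk outcomes and predictors.

    Parameters
    ----------
    data : DataFrame
        Tidy table, one row per walk, containing the outcome, every
        predictor, and both grouping columns.
    spec : ModelSpec
        Outcome, transform, forced/screened predictors and grouping.
    """

    def __init__(self, data: pd.DataFrame, spec: ModelSpec):
        missing = [c for c in
                   (spec.outcome, *spec.forced, *spec.screened, *spec.groups)
                   if c not in data.columns]
        if missing:
            raise ParameterError(f"data is missing column(s): {missing}")
        self.spec = spec
        self.data = data.reset_index(drop=True).copy()
        self.data["_y"] = transform_outcome(self.data[spec.outcome].to_numpy(), spec.transform)

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, outcome: str,
                       transform: TransformSpec = TransformSpec(),
                       forced: tuple = FORCED_DEFAULT,
                       screened: tuple = (),
                       groups: tuple = ("volunteer_id", "dog_id")) -> "WalkAssociationModel":
        return cls(data, ModelSpec(outcome=outcome, transform=transform,
                                   forced=forced, screened=screened, groups=groups))

    # -- protocol stages ---------------------------------------------------

    def screen(self, alpha: float = ALPHA_SCREEN) -> tuple:
        """Bivariate screen: keep screened candidates with p < alpha.

        Forced predictors are not screened; they are always in the model.
        Constant candidates are excluded with a warning.
        """
        kept = []
        y = self.data["_y"].to_numpy()
        for cand in self.spec.screened:
            x = self.data[cand].to_numpy(float)
            if np.ptp(x) == 0:
                warnings.warn(f"candidate {cand!r} is constant; excluded from screen")
                continue
            X = sm.add_constant(x)
            p = sm.OLS(y, X).fit().pvalues[1]
            if p < alpha:
                kept.append(cand)
        return tuple(kept)

    def fit(self, predictors: tuple | None = None) -> WalkAssociationResults:
        """Fit the linear mixed model by maximum likelihood.

        ``predictors`` defaults to forced + all screened candidates (no
        screening applied); use :meth:`screen` first to apply the p < 0.2
        rule.  Random intercepts for volunteer and dog are crossed: both
        variance components apply to every walk.
        """
        if predictors is None:
            predictors = tuple(self.spec.forced) + tuple(self.spec.screened)
        preds = list(predictors)
        df = self.data
        X = df[preds].to_numpy(float) if preds else np.empty((len(df), 0))
        if preds:
            rank = np.linalg.matrix_rank(np.column_stack([np.ones(len(df)), X]))
            if rank < len(preds) + 1:
                aliased = _aliased_columns(X, preds)
                raise ParameterError(f"singular design; aliased column(s): {aliased}")

        g1, g2 = self.spec.groups
        vc = {g1: f"0 + C({g1})", g2: f"0 + C({g2})"}
        formula = "_y ~ " + (" + ".join(preds) if preds else "1")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM.from_formula(
                formula, groups=np.ones(len(df)), vc_formula=vc, data=df)
            # Powell handles variance components on the zero boundary
            # reliably, where gradient methods stall or stop early at a
            # worse optimum; its line search can however step into a
            # singular covariance region, so fall back to the default
            # gradient chain when it fails either way
            try:
                res = model.fit(reml=False, method="powell")
            except np.linalg.LinAlgError:
                res = None
            if res is None or not res.converged:
                try:
                    res2 = model.fit(reml=False)
                except np.linalg.LinAlgError:
                    res2 = None
                if res2 is not None and (
                        res is None or (res2.converged and res2.llf >= res.llf)):
                    res = res2
            if res is None:
                raise ParameterError("mixed-model likelihood optimisation failed")

        fe = res.fe_params
        names = list(fe.index)
        params = pd.Series(fe.values, index=names)
        bse = pd.Series(res.bse_fe.values, index=names)
        pvalues = pd.Series([res.pvalues[n] for n in names], index=names)

        resid = np.asarray(res.resid)
        if 3 <= len(resid) <= 5000 and np.ptp(resid) > 0:
            sw = stats.shapiro(resid)
            shapiro_w, shapiro_p = float(sw.statistic), float(sw.pvalue)
        else:
            shapiro_w = shapiro_p = np.nan

        vif = vif_check(df[preds]) if len(preds) >= 2 else pd.Series(dtype=float)
        return WalkAssociationResults(
            spec=self.spec,
            predictors=tuple(preds),
            params=params,
            bse=bse,
            pvalues=pvalues,
            bic=float(res.bic),
            llf=float(res.llf),
            vc_variances={k: float(v) for k, v in zip(res.model.exog_vc.names, res.vcomp)},
            residual_variance=float(res.scale),
            nobs=len(df),
            vif=vif,
            shapiro_w=shapiro_w,
            shapiro_p=shapiro_p,
            converged=bool(res.converged),
            _resid=resid,
        )

    def backward_eliminate(self, alpha_keep: float = ALPHA_KEEP,
                           screen_alpha: float | None = ALPHA_SCREEN) -> WalkAssociationResults:
        """Run the full protocol: screen, fit, then backward elimination.

        At each step the non-forced predictor with the largest Wald p-value
        >= ``alpha_keep`` is removed and the model refit; the removal order,
        the p-value at removal and the BIC after each refit are recorded.
        Forced predictors are never removed.  The procedure is deterministic:
        identical data yield an identical trace.
        """
        if screen_alpha is None:
            candidates = tuple(self.spec.screened)
        else:
            candidates = self.screen(alpha=screen_alpha)
        current = tuple(self.spec.forced) + candidates

        trace: list = []
        bic_path: list = []
        res = self.fit(predictors=current)
        bic_path.append(res.bic)
        while True:
            removable = [p for p in res.predictors if p not in self.spec.forced]
            if not removable:
                break
            pv = res.pvalues[removable]
            worst = pv.idxmax()
            if pv[worst] < alpha_keep:
                break
            current = tuple(p for p in res.predictors if p != worst)
            p_at_removal = float(pv[worst])
            res = self.fit(predictors=current)
            trace.append((worst, p_at_removal, res.bic))
            bic_path.append(res.bic)
        res.elimination_trace = trace
        res.bic_path = bic_path
        return res


# -- functional surface ----------------------------------------------------

def transform_outcome(values, spec: TransformSpec):
    """Apply an outcome transform elementwise."""
    x = np.asarray(values, dtype=float)
    if spec.kind == "identity":
        return x
    if spec.kind == "log10":
        bad = np.flatnonzero(x <= 0)
        if len(bad):
            raise RangeError(f"log10 transform requires positive values; "
                             f"offending row(s): {bad[:10].tolist()}")
        return np.log10(x)
    if np.any(x < 0) and not float(spec.exponent).is_integer():
        bad = np.flatnonzero(x < 0)
        raise RangeError(f"fractional power of negative value; "
                         f"offending row(s): {bad[:10].tolist()}")
    return x ** spec.exponent


def bivariate_screen(data: pd.DataFrame, outcome: str, candidates,
                     forced=FORCED_DEFAULT, alpha: float = ALPHA_SCREEN,
                     transform: TransformSpec = TransformSpec()) -> tuple:
    """Single-predictor screen; returns forced + candidates with p < alpha."""
    model = WalkAssociationModel(
        data, ModelSpec(outcome=outcome, transform=transform, forced=tuple(forced),
                        screened=tuple(c for c in candidates if c not in forced)))
    return tuple(forced) + model.screen(alpha=alpha)


def fit_mixed(data: pd.DataFrame, spec: ModelSpec) -> WalkAssociationResults:
    """Fit the mixed model for a ModelSpec without screening/elimination."""
    return WalkAssociationModel(data, spec).fit()


def backward_eliminate(data: pd.DataFrame, spec: ModelSpec,
                       alpha_keep: float = ALPHA_KEEP,
                       screen: bool = True) -> WalkAssociationResults:
    """Run screen + backward elimination for a ModelSpec."""
    return WalkAssociationModel(data, spec).backward_eliminate(
        alpha_keep=alpha_keep, screen_alpha=ALPHA_SCREEN if screen else None)


def vif_check(design: pd.DataFrame) -> pd.Series:
    """Variance inflation factor of each predictor.

    VIF_j = 1/(1 - R^2_j) from regressing predictor j on the others (with
    intercept).  A perfectly collinear column is reported as ``inf``.
    Values >= 2 indicate collinearity under the study's rule of thumb.
    """
    X = design.to_numpy(float)
    n, p = X.shape
    if p < 2:
        raise ParameterError("VIF requires at least 2 predictors")
    if n <= p:
        raise ParameterError("VIF requires more observations than predictors")
    out = {}
    for j, name in enumerate(design.columns):
        others = sm.add_constant(np.delete(X, j, axis=1))
        r2 = sm.OLS(X[:, j], others).fit().rsquared
        out[name] = np.inf if r2 >= 1 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out)


def _aliased_columns(X: np.ndarray, names: list) -> list:
    """Identify columns linearly dependent on the preceding ones."""
    aliased = []
    cols = [np.ones(X.shape[0])]
    for j, name in enumerate(names):
        trial = np.column_stack(cols + [X[:, j]])
        if np.linalg.matrix_rank(trial) == len(cols):
            aliased.append(name)
        else:
            cols.append(X[:, j])
    return aliased
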