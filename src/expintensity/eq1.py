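"""Multiplicative nonlinear regression of concentration on algorithm factors.

The model mirrors the structure of the intensity score itself: an additive
exposure part scaled by a multiplicative PPE reduction,

    Y = (alpha0 + alpha1*Mix + alpha2*Method + alpha3*Repair)
        * (1 - beta1*Gloves - beta2*PPEother)

with Y the post-application urine concentration in µg/L and all covariates
0/1 indicators.  alpha0 is the concentration at the referent level of all
factors; beta1 and beta2 are the fractional reductions for CR-glove use
and any other PPE.  The fit is ordinary least squares on the raw µg/L
scale (homoscedastic residuals), exactly as the model is written, even
though biomarker data are typically closer to lognormal — the fitted
coefficients are used to rank and calibrate, not to model the error law.

Estimation uses damped least squares (Levenberg-Marquardt) with an
analytic Jacobian and a multi-start policy: a moment-based start derived
from group geometric means plus seeded random admissible starts; the
lowest-SSE solution wins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps

from .records import ApplicatorRecord, MonitoringRecord
from .stats import monitoring_frame, spearman_rho
from .synth import TrueParams, eq1_covariates
from .weights import WeightTable, intensity_score

ALPHA_TERMS = ("mix", "method", "repair")
BETA_TERMS = ("gloves", "ppe_other")
_PARAM_BY_TERM = {
    "mix": "alpha1",
    "method": "alpha2",
    "repair": "alpha3",
    "gloves": "beta1",
    "ppe_other": "beta2",
}


class FitError(RuntimeError):
    """Raised when no optimizer start converges; carries diagnostics."""


@dataclass(frozen=True)
class ModelFit:
    """Estimates and diagnostics of the multiplicative regression."""

    alpha0: float
    alpha1: Optional[float]
    alpha2: Optional[float]
    alpha3: Optional[float]
    beta1: Optional[float]
    beta2: Optional[float]
    p_values: dict
    r_squared: float
    converged: bool
    n_used: int
    omitted_terms: tuple[str, ...]
    sse: float
    admissible: bool = True

    def coefficient(self, name: str) -> Optional[float]:
        return getattr(self, name)


class Eq1Regressor:
    """Sklearn-style estimator for the multiplicative exposure model.

    Parameters
    ----------
    n_random_starts : int, default 10
        Number of seeded random admissible starts in addition to the
        moment-based start.
    tol : float, default 1e-10
        Relative SSE convergence tolerance passed to the optimizer.
    random_state : int, default 0
        Seed for the random starts.

    Attributes (after ``fit``)
    --------------------------
    alpha0_, alpha1_, alpha2_, alpha3_, beta1_, beta2_ : float or None
        Coefficient estimates; ``None`` for omitted (constant) covariates.
    pvalues_ : dict
        Two-sided asymptotic p-values per estimated parameter.
    r_squared_ : float
        1 - SSE/SST on the raw concentration scale.
    omitted_terms_ : tuple of str
        Covariates dropped because they were constant in the data.
    converged_ : bool
    admissible_ : bool
        False when the fitted reductions satisfy beta1 + beta2 >= 1.
    """

    def __init__(self, n_random_starts: int = 10, tol: float = 1e-10,
                 random_state: int = 0):
        self.n_random_starts = n_random_starts
        self.tol = tol
        self.random_state = random_state

    def get_params(self, deep: bool = True) -> dict:
        return {
            "n_random_starts": self.n_random_starts,
            "tol": self.tol,
            "random_state": self.random_state,
        }

    def set_params(self, **params) -> "Eq1Regressor":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    # ------------------------------------------------------------------
    def fit(self, X, y) -> "Eq1Regressor":
        """Fit the model.

        ``X`` is a DataFrame with 0/1 columns among
        ``mix, method, repair, gloves, ppe_other`` (or an array with those
        five columns in order); ``y`` are concentrations in µg/L.
        """
        X = self._as_frame(X)
        y = np.asarray(y, dtype=float)
        n = y.size
        if len(X) != n:
            raise ValueError("X and y lengths differ")
        alpha_cols = [c for c in ALPHA_TERMS if c in X.columns]
        beta_cols = [c for c in BETA_TERMS if c in X.columns]
        omitted = tuple(
            c for c in alpha_cols + beta_cols if X[c].nunique() <= 1
        )
        alpha_cols = [c for c in alpha_cols if c not in omitted]
        beta_cols = [c for c in beta_cols if c not in omitted]
        n_params = 1 + len(alpha_cols) + len(beta_cols)
        if n < n_params + 1:
            raise ValueError(
                f"{n} records cannot identify {n_params} parameters"
            )
        Xa = X[alpha_cols].to_numpy(dtype=float)
        Xb = X[beta_cols].to_numpy(dtype=float)
        ka, kb = Xa.shape[1], Xb.shape[1]

        def residual(theta):
            a0, a, b = theta[0], theta[1 : 1 + ka], theta[1 + ka :]
            add = a0 + Xa @ a
            mult = 1.0 - Xb @ b
            return y - add * mult

        def jacobian(theta):
            a0, a, b = theta[0], theta[1 : 1 + ka], theta[1 + ka :]
            add = a0 + Xa @ a
            mult = 1.0 - Xb @ b
            cols = [-mult[:, None]]
            if ka:
                cols.append(-Xa * mult[:, None])
            if kb:
                cols.append(Xb * add[:, None])
            return np.hstack(cols)

        starts = self._starts(X, y, alpha_cols, beta_cols)
        best = None
        failures = []
        for theta0 in starts:
            try:
                res = optimize.least_squares(
                    residual,
                    theta0,
                    jac=jacobian,
                    method="lm",
                    ftol=self.tol,
                    xtol=1e-14,
                    gtol=1e-14,
                    max_nfev=2000,
                )
            except Exception as exc:  # pragma: no cover - defensive
                failures.append(str(exc))
                continue
            if not res.success:
                failures.append(res.message)
                continue
            if best is None or res.cost < best.cost:
                best = res
        if best is None:
            raise FitError(
                "no optimizer start converged; diagnostics: "
                + "; ".join(failures[:5])
            )

        theta = best.x
        sse = float(2.0 * best.cost)
        sst = float(((y - y.mean()) ** 2).sum())
        dof = n - n_params
        jac = jacobian(theta)
        try:
            cov = np.linalg.inv(jac.T @ jac) * (sse / dof if dof > 0 else np.nan)
            se = np.sqrt(np.diag(cov))
        except np.linalg.LinAlgError:
            se = np.full(n_params, np.nan)
        with np.errstate(divide="ignore", invalid="ignore"):
            tvals = theta / se
        pvals = 2.0 * sps.t.sf(np.abs(tvals), max(dof, 1))

        names = (
            ["alpha0"]
            + [_PARAM_BY_TERM[c] for c in alpha_cols]
            + [_PARAM_BY_TERM[c] for c in beta_cols]
        )
        est = dict(zip(names, theta))
        self.alpha0_ = float(est["alpha0"])
        for term, pname in _PARAM_BY_TERM.items():
            setattr(
                self,
                pname + "_",
                float(est[pname]) if pname in est else None,
            )
        self.pvalues_ = {nm: float(p) for nm, p in zip(names, pvals)}
        self.sse_ = sse
        self.r_squared_ = float(1.0 - sse / sst) if sst > 0 else 1.0
        self.n_used_ = int(n)
        self.omitted_terms_ = omitted
        self.converged_ = True
        b1 = self.beta1_ or 0.0
        b2 = self.beta2_ or 0.0
        self.admissible_ = b1 + b2 < 1.0
        self._alpha_cols_ = tuple(alpha_cols)
        self._beta_cols_ = tuple(beta_cols)
        return self

    def predict(self, X) -> np.ndarray:
        X = self._as_frame(X)
        add = np.full(len(X), self.alpha0_)
        for c in self._alpha_cols_:
            add = add + getattr(self, _PARAM_BY_TERM[c] + "_") * X[c].to_numpy(
                dtype=float
            )
        mult = np.ones(len(X))
        for c in self._beta_cols_:
            mult = mult - getattr(self, _PARAM_BY_TERM[c] + "_") * X[
                c
            ].to_numpy(dtype=float)
        return add * mult

    def to_model_fit(self) -> ModelFit:
        return ModelFit(
            alpha0=self.alpha0_,
            alpha1=self.alpha1_,
            alpha2=self.alpha2_,
            alpha3=self.alpha3_,
            beta1=self.beta1_,
            beta2=self.beta2_,
            p_values=dict(self.pvalues_),
            r_squared=self.r_squared_,
            converged=self.converged_,
            n_used=self.n_used_,
            omitted_terms=self.omitted_terms_,
            sse=self.sse_,
            admissible=self.admissible_,
        )

    # ------------------------------------------------------------------
    @staticmethod
    def _as_frame(X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            return X
        arr = np.asarray(X, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 5:
            raise ValueError(
                "array input must have the five columns "
                "mix, method, repair, gloves, ppe_other"
            )
        return pd.DataFrame(arr, columns=list(ALPHA_TERMS + BETA_TERMS))

    def _starts(self, X, y, alpha_cols, beta_cols) -> list[np.ndarray]:
        ka, kb = len(alpha_cols), len(beta_cols)
        ybar = float(np.mean(y))
        # moment-based start: referent-cell mean, group-mean contrasts for
        # the alphas, observed GM reductions for the betas
        ref_mask = np.ones(len(X), dtype=bool)
        for c in alpha_cols + beta_cols:
            ref_mask &= X[c].to_numpy() == 0
        a0 = float(np.mean(y[ref_mask])) if ref_mask.any() else ybar
        a0 = max(a0, 1e-6)
        alphas = []
        for c in alpha_cols:
            m = X[c].to_numpy() == 1
            alphas.append(float(np.mean(y[m]) - np.mean(y[~m])))
        betas = []
        for c in beta_cols:
            m = X[c].to_numpy() == 1
            g1 = math.exp(float(np.mean(np.log(np.maximum(y[m], 1e-12)))))
            g0 = math.exp(float(np.mean(np.log(np.maximum(y[~m], 1e-12)))))
            betas.append(min(max(1.0 - g1 / g0, 0.0), 0.85))
        starts = [np.array([a0, *alphas, *betas])]
        rng = np.random.default_rng(self.random_state)
        for _ in range(self.n_random_starts):
            ra = rng.uniform(0.0, 2.0 * max(ybar, 1e-6), size=1 + ka)
            rb = rng.uniform(0.0, 0.45, size=kb)
            starts.append(np.concatenate([ra, rb]))
        return starts


# ---------------------------------------------------------------------------
# functional wrappers over record lists


def records_to_design(
    records: Iterable[MonitoringRecord],
    method_coded_one=frozenset({"hand_spray"}),
) -> tuple[pd.DataFrame, np.ndarray]:
    """(design frame, concentrations) for a monitoring record list."""
    df = monitoring_frame(records, method_coded_one)
    X = df[["mix", "method01", "repair", "gloves", "ppe_other"]].rename(
        columns={"method01": "method"}
    )
    return X, df["concentration"].to_numpy()


def fit_eq1(
    records: Iterable[MonitoringRecord],
    method_coded_one=frozenset({"hand_spray"}),
    **regressor_kwargs,
) -> ModelFit:
    """Fit the multiplicative model to monitoring records."""
    records = list(records)
    if len(records) < 8:
        raise ValueError("at least 8 monitoring records required")
    X, y = records_to_design(records, method_coded_one)
    reg = Eq1Regressor(**regressor_kwargs).fit(X, y)
    return reg.to_model_fit()


def predict_eq1(
    fit: Union[ModelFit, TrueParams],
    record: ApplicatorRecord,
    method_coded_one=frozenset({"hand_spray"}),
    allow_negative: bool = False,
) -> float:
    """Deterministic model mean for one record's coded covariates.

    A negative predicted mean signals inadmissible parameters
    (beta1 + beta2 >= 1) and raises unless ``allow_negative`` is set —
    rank-based comparisons of predictions remain meaningful either way.
    """
    mix, method, repair, gloves, other = eq1_covariates(
        record, method_coded_one
    )
    get = lambda name: (getattr(fit, name, None) or 0.0)  # noqa: E731
    add = (
        get("alpha0")
        + get("alpha1") * mix
        + get("alpha2") * method
        + get("alpha3") * repair
    )
    mult = 1.0 - get("beta1") * gloves - get("beta2") * other
    pred = add * mult
    if pred < 0 and not allow_negative:
        raise ValueError(
            f"negative predicted mean ({pred:.3g}) for record {record.id!r}; "
            "parameters are inadmissible"
        )
    return pred


def score_vs_prediction(
    records: Iterable[MonitoringRecord],
    fit: Union[ModelFit, TrueParams],
    table: WeightTable,
    method_coded_one=frozenset({"hand_spray"}),
) -> float:
    """Spearman correlation of algorithm scores with model predictions."""
    records = list(records)
    scores = [intensity_score(r, table) for r in records]
    preds = [predict_eq1(fit, r, method_coded_one) for r in records]
    return spearman_rho(scores, preds)
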