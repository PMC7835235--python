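"""Ordinal treatment-response association.

The outcome is best overall response coded PD(0) < SD(1) < PR(2); the model is
the proportional-odds (cumulative-logit) regression

    P(Y <= k | x) = logistic(theta_k - x . beta),   theta_1 < ... < theta_{K-1},

so a positive coefficient means better response. The two-step screen of the
cohort analysis is: univariate proportional-odds fits per feature (eligibility
requires at least ``min_events`` carriers per response group for binary
features), selection at p < alpha, then a multivariable L1-penalized
cumulative-logit fit (ordered LASSO) with the penalty weight chosen by
cross-validated deviance. Cut points are never penalized.

Organized statsmodels-style: OrdinalResponseModel(y, X).fit() returns an
OrdinalResponseResults with coefficients, Wald inference and summary().
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

RESPONSE_ORDER = ("PD", "SD", "PR")


class ConvergenceError(RuntimeError):
    pass


def _encode_response(y) -> tuple[np.ndarray, list]:
    """Encode an ordinal outcome as integer codes 0..K-1."""
    if isinstance(y, pd.Series) and isinstance(y.dtype, pd.CategoricalDtype):
        cats = list(y.cat.categories)
        codes = y.cat.codes.to_numpy()
    else:
        arr = np.asarray(y)
        if arr.dtype.kind in "OUS":
            cats = [c for c in RESPONSE_ORDER if c in set(arr)]
            if not cats:
                cats = sorted(set(arr))
            lookup = {c: i for i, c in enumerate(cats)}
            codes = np.array([lookup.get(v, -1) for v in arr])
        else:
            cats = sorted(set(arr[~pd.isna(arr)]))
            lookup = {c: i for i, c in enumerate(cats)}
            codes = np.array([lookup.get(v, -1) if not pd.isna(v) else -1 for v in arr])
    return codes.astype(int), cats


class OrdinalResponseModel:
    """Proportional-odds model for an ordinal outcome.

    Parameters
    ----------
    y : ordered categorical / string / integer outcome per sample
    X : feature matrix (DataFrame or array); rows with missing y or x are
        dropped (count kept in ``n_dropped``).
    """

    def __init__(self, y, X):
        if isinstance(X, pd.Series):
            X = X.to_frame()
        X = pd.DataFrame(X)
        codes, cats = _encode_response(y)
        xvals = X.to_numpy(dtype=float)
        keep = (codes >= 0) & np.isfinite(xvals).all(axis=1)
        self.n_dropped = int((~keep).sum())
        self.y = codes[keep]
        self.X = xvals[keep]
        self.feature_names = list(X.columns)
        self.categories = cats
        self.K = len(cats)
        if len(np.unique(self.y)) < 2:
            raise ValueError("outcome must have at least 2 observed levels")
        self.n, self.p = self.X.shape
        self.n_theta = self.K - 1

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, response: str = "response",
                       features: list[str] | None = None) -> "OrdinalResponseModel":
        features = features or [c for c in df.columns if c != response]
        return cls(df[response], df[features])

    # -- likelihood machinery -------------------------------------------------

    def _split(self, w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return w[: self.n_theta], w[self.n_theta :]

    def _bounds(self, w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        theta, beta = self._split(w)
        eta = self.X @ beta
        A = np.where(self.y < self.n_theta, theta[np.minimum(self.y, self.n_theta - 1)] - eta, np.inf)
        B = np.where(self.y > 0, theta[np.maximum(self.y - 1, 0)] - eta, -np.inf)
        return A, B

    def loglike(self, w: np.ndarray) -> float:
        theta, _ = self._split(w)
        if np.any(np.diff(theta) <= 0):
            return -np.inf
        A, B = self._bounds(w)
        pi = expit(A) - expit(B)
        if np.any(pi <= 0):
            return -np.inf
        return float(np.log(pi).sum())

    @staticmethod
    def _f(x: np.ndarray) -> np.ndarray:
        """Logistic density, 0 at +/- inf."""
        F = expit(x)
        return np.where(np.isfinite(x), F * (1 - F), 0.0)

    @staticmethod
    def _fprime(x: np.ndarray) -> np.ndarray:
        F = expit(x)
        return np.where(np.isfinite(x), F * (1 - F) * (1 - 2 * F), 0.0)

    def score(self, w: np.ndarray) -> np.ndarray:
        A, B = self._bounds(w)
        pi = expit(A) - expit(B)
        gA = self._f(A) / pi
        gB = -self._f(B) / pi
        grad = np.zeros(self.n_theta + self.p)
        kA = np.where(self.y < self.n_theta, self.y, -1)
        kB = self.y - 1
        validA = kA >= 0
        validB = kB >= 0
        np.add.at(grad, kA[validA], gA[validA])
        np.add.at(grad, kB[validB], gB[validB])
        grad[self.n_theta :] = -self.X.T @ (gA + gB)
        return grad

    def hessian(self, w: np.ndarray) -> np.ndarray:
        A, B = self._bounds(w)
        pi = expit(A) - expit(B)
        fA, fB = self._f(A), self._f(B)
        hAA = self._fprime(A) / pi - (fA / pi) ** 2
        hBB = -self._fprime(B) / pi - (fB / pi) ** 2
        hAB = fA * fB / pi**2
        nt, p = self.n_theta, self.p
        H = np.zeros((nt + p, nt + p))
        kA = np.where(self.y < nt, self.y, -1)
        kB = self.y - 1
        vA, vB = kA >= 0, kB >= 0
        # theta-theta block
        np.add.at(H, (kA[vA], kA[vA]), hAA[vA])
        np.add.at(H, (kB[vB], kB[vB]), hBB[vB])
        both = vA & vB
        np.add.at(H, (kA[both], kB[both]), hAB[both])
        np.add.at(H, (kB[both], kA[both]), hAB[both])
        # theta-beta block
        wA = hAA + hAB
        wB = hBB + hAB
        tb = np.zeros((nt, p))
        if p:
            np.add.at(tb, kA[vA], -wA[vA, None] * self.X[vA])
            np.add.at(tb, kB[vB], -wB[vB, None] * self.X[vB])
            H[:nt, nt:] = tb
            H[nt:, :nt] = tb.T
            H[nt:, nt:] = self.X.T @ ((hAA + hBB + 2 * hAB)[:, None] * self.X)
        return H

    def _start_params(self) -> np.ndarray:
        cum = np.cumsum(np.bincount(self.y, minlength=self.K)[:-1]) / self.n
        cum = np.clip(cum, 1e-3, 1 - 1e-3)
        theta = np.log(cum / (1 - cum))
        theta = np.maximum.accumulate(theta + 1e-9 * np.arange(self.n_theta))
        return np.concatenate([theta, np.zeros(self.p)])

    # -- fitting --------------------------------------------------------------

    def fit(self, tol: float = 1e-8, maxiter: int = 100) -> "OrdinalResponseResults":
        """Newton maximization of the cumulative-logit likelihood."""
        w = self._start_params()
        ll = self.loglike(w)
        converged = False
        for _ in range(maxiter):
            grad = self.score(w)
            if np.max(np.abs(grad)) < tol:
                converged = True
                break
            H = self.hessian(w)
            try:
                step = np.linalg.solve(H, grad)
            except np.linalg.LinAlgError:
                step = grad / max(np.abs(np.diag(H)).max(), 1.0)
            # Newton step for a maximum: w - H^{-1} grad
            scale = 1.0
            for _ in range(40):
                w_new = w - scale * step
                ll_new = self.loglike(w_new)
                if ll_new > ll - 1e-12:
                    break
                scale *= 0.5
            else:
                break
            w, ll = w_new, ll_new
        separation = bool(np.max(np.abs(self._split(w)[1]), initial=0.0) > 30)
        H = self.hessian(w)
        try:
            cov = np.linalg.inv(-H)
            bse = np.sqrt(np.clip(np.diag(cov), 0, None))
        except np.linalg.LinAlgError:
            cov = np.full_like(H, np.nan)
            bse = np.full(len(w), np.nan)
        return OrdinalResponseResults(
            model=self, params=w, llf=ll, bse=bse, cov=cov,
            converged=converged, separation=separation,
        )

    def fit_regularized(
        self,
        lam: float | None = None,
        lambda_grid: np.ndarray | None = None,
        cv: int = 5,
        seed: int = 0,
        standardize: bool = True,
        tol: float = 1e-10,
        maxiter: int = 50_000,
    ) -> "PenalizedOrdinalResults":
        """L1-penalized cumulative-logit fit (ordered LASSO).

        Minimizes -loglik/n + lam * sum|beta| by proximal gradient with
        backtracking (the penalized objective is non-increasing by
        construction and asserted each step). With a ``lambda_grid`` the
        penalty is chosen by ``cv``-fold cross-validated deviance; continuous
        features are standardized internally and coefficients returned on the
        original scale. Cut points are never penalized.
        """
        scales = np.ones(self.p)
        centers = np.zeros(self.p)
        X = self.X.copy()
        if standardize:
            for j in range(self.p):
                col = X[:, j]
                if set(np.unique(col)) - {0.0, 1.0}:
                    centers[j] = col.mean()
                    sd = col.std()
                    scales[j] = sd if sd > 0 else 1.0
                    X[:, j] = (col - centers[j]) / scales[j]
        work = OrdinalResponseModel.__new__(OrdinalResponseModel)
        work.__dict__.update(self.__dict__)
        work.X = X

        cv_table = None
        if lam is None:
            if lambda_grid is None:
                lambda_grid = np.geomspace(0.5, 1e-3, 12)
            lam, cv_table = _choose_lambda_cv(work, np.sort(np.asarray(lambda_grid))[::-1],
                                              cv=cv, seed=seed, tol=tol, maxiter=maxiter)
        w, obj, n_iter, converged = _proximal_gradient(work, lam, tol=tol, maxiter=maxiter)
        if not converged and lam > 0:
            raise ConvergenceError(f"proximal gradient did not converge at lambda={lam}")
        theta_std, beta_std = w[: self.n_theta], w[self.n_theta :]
        # x_std.b_std = x.(b_std/s) - c.(b_std/s), so on the original scale
        # beta = b_std/s and theta = theta_std + c.beta
        beta = beta_std / scales
        theta = theta_std + centers @ beta
        return PenalizedOrdinalResults(
            model=self, lam=float(lam), theta=theta, beta=beta,
            objective=obj, n_iter=n_iter, cv_table=cv_table,
        )


def _penalized_objective(model: OrdinalResponseModel, w: np.ndarray, lam: float) -> float:
    return -model.loglike(w) / model.n + lam * np.abs(w[model.n_theta :]).sum()


def _proximal_gradient(
    model: OrdinalResponseModel, lam: float, tol: float, maxiter: int,
    w0: np.ndarray | None = None,
) -> tuple[np.ndarray, float, int, bool]:
    w = model._start_params() if w0 is None else w0.copy()
    nt = model.n_theta
    f = -model.loglike(w) / model.n
    obj = f + lam * np.abs(w[nt:]).sum()
    t = 1.0
    converged = False
    it = 0
    for it in range(1, maxiter + 1):
        grad = -model.score(w) / model.n
        while True:
            z = w - t * grad
            z[nt:] = np.sign(z[nt:]) * np.maximum(np.abs(z[nt:]) - t * lam, 0.0)
            f_new = -model.loglike(z) / model.n
            dw = z - w
            if np.isfinite(f_new) and f_new <= f + grad @ dw + (dw @ dw) / (2 * t) + 1e-14:
                break
            t *= 0.5
            if t < 1e-14:
                return w, obj, it, False
        new_obj = f_new + lam * np.abs(z[nt:]).sum()
        assert new_obj <= obj + 1e-10, "penalized objective increased"
        delta = obj - new_obj
        w, f, obj = z, f_new, new_obj
        t *= 1.25
        if delta < tol and np.max(np.abs(dw)) < 1e-9:
            converged = True
            break
    return w, obj, it, converged


def _choose_lambda_cv(
    model: OrdinalResponseModel, grid: np.ndarray, cv: int, seed: int,
    tol: float, maxiter: int,
) -> tuple[float, pd.DataFrame]:
    from sklearn.model_selection import StratifiedKFold

    folds = StratifiedKFold(n_splits=cv, shuffle=True, random_state=seed)
    dev = np.zeros((len(grid), cv))
    for f, (tr, te) in enumerate(folds.split(model.X, model.y)):
        sub = OrdinalResponseModel.__new__(OrdinalResponseModel)
        sub.__dict__.update(model.__dict__)
        sub.X, sub.y, sub.n = model.X[tr], model.y[tr], len(tr)
        hold = OrdinalResponseModel.__new__(OrdinalResponseModel)
        hold.__dict__.update(model.__dict__)
        hold.X, hold.y, hold.n = model.X[te], model.y[te], len(te)
        w = None
        for g, lam in enumerate(grid):
            w, _, _, _ = _proximal_gradient(sub, lam, tol=max(tol, 1e-8),
                                            maxiter=maxiter, w0=w)
            ll = hold.loglike(w)
            dev[g, f] = -2 * ll / hold.n if np.isfinite(ll) else np.inf
    mean_dev = dev.mean(axis=1)
    best = int(np.argmin(mean_dev))
    table = pd.DataFrame({"lambda": grid, "cv_deviance": mean_dev})
    return float(grid[best]), table


@dataclass
class OrdinalResponseResults:
    """Unpenalized proportional-odds fit with Wald inference."""

    model: OrdinalResponseModel
    params: np.ndarray
    llf: float
    bse: np.ndarray
    cov: np.ndarray
    converged: bool
    separation: bool

    @property
    def theta(self) -> np.ndarray:
        return self.params[: self.model.n_theta]

    @property
    def beta(self) -> pd.Series:
        return pd.Series(self.params[self.model.n_theta :], index=self.model.feature_names)

    @property
    def beta_se(self) -> pd.Series:
        return pd.Series(self.bse[self.model.n_theta :], index=self.model.feature_names)

    @property
    def pvalues(self) -> pd.Series:
        z = self.beta / self.beta_se
        return pd.Series(2 * norm.sf(np.abs(z)), index=self.model.feature_names)

    def summary(self) -> str:
        lines = [
            "Proportional-odds (cumulative-logit) regression",
            f"n = {self.model.n}, levels = {self.model.categories}, "
            f"log-likelihood = {self.llf:.4f}",
            f"converged = {self.converged}, separation flag = {self.separation}",
            "",
            f"{'cut point':<24}{'estimate':>12}",
        ]
        for i, th in enumerate(self.theta):
            lines.append(f"theta_{i + 1:<18}{th:>12.4f}")
        lines.append("")
        lines.append(f"{'feature':<24}{'coef':>12}{'std err':>12}{'z':>10}{'P>|z|':>12}")
        for name in self.model.feature_names:
            b, se, p = self.beta[name], self.beta_se[name], self.pvalues[name]
            z = b / se if se > 0 else np.nan
            lines.append(f"{name:<24}{b:>12.4f}{se:>12.4f}{z:>10.3f}{p:>12.4g}")
        return "\n".join(lines)


@dataclass
class PenalizedOrdinalResults:
    """Ordered-LASSO fit: sparse coefficients at the chosen penalty."""

    model: OrdinalResponseModel
    lam: float
    theta: np.ndarray
    beta: np.ndarray
    objective: float
    n_iter: int
    cv_table: pd.DataFrame | None = None

    @property
    def coefficients(self) -> pd.Series:
        return pd.Series(self.beta, index=self.model.feature_names)

    def nonzero(self, atol: float = 1e-8) -> pd.Series:
        coef = self.coefficients
        return coef[coef.abs() > atol]

    def summary(self) -> str:
        lines = [
            "L1-penalized proportional-odds regression",
            f"n = {self.model.n}, lambda = {self.lam:.6g}, iterations = {self.n_iter}",
            "cut points: " + ", ".join(f"{t:.4f}" for t in self.theta),
            "nonzero coefficients:",
        ]
        nz = self.nonzero()
        if not len(nz):
            lines.append("  (none)")
        for name, b in nz.items():
            lines.append(f"  {name:<24}{b:>12.4f}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# spec-surface convenience functions
# ---------------------------------------------------------------------------

def fit_proportional_odds(y, x) -> OrdinalResponseResults:
    """Fit a proportional-odds model to one feature or a feature matrix."""
    return OrdinalResponseModel(y, x).fit()


@dataclass
class ScreenResult:
    eligible: list[str]
    selected: list[str]
    table: pd.DataFrame
    flagged: list[str] = field(default_factory=list)


def _is_binary(col: np.ndarray) -> bool:
    return not (set(np.unique(col[np.isfinite(col)])) - {0.0, 1.0})


def univariate_screen(
    y, X: pd.DataFrame, alpha: float = 0.05, min_events: int = 5
) -> ScreenResult:
    """Univariate proportional-odds screen.

    Binary features are eligible only with at least ``min_events`` carriers in
    every observed response group; selection is p < alpha (strict).
    Non-converged or separated fits are flagged and not selected.
    """
    codes, _ = _encode_response(y)
    rows, eligible, selected, flagged = [], [], [], []
    for feat in X.columns:
        col = X[feat].to_numpy(dtype=float)
        ok = (codes >= 0) & np.isfinite(col)
        if _is_binary(col):
            events_per_group = [
                (col[ok][codes[ok] == g] == 1).sum() for g in np.unique(codes[ok])
            ]
            if min(events_per_group, default=0) < min_events:
                rows.append({"feature": feat, "eligible": False, "p": np.nan})
                continue
        if np.nanstd(col[ok]) == 0:
            rows.append({"feature": feat, "eligible": False, "p": np.nan})
            continue
        eligible.append(feat)
        try:
            res = fit_proportional_odds(pd.Series(codes, index=X.index), X[[feat]])
        except (ValueError, np.linalg.LinAlgError):
            flagged.append(feat)
            rows.append({"feature": feat, "eligible": True, "p": np.nan})
            continue
        if not res.converged or res.separation:
            flagged.append(feat)
            rows.append({"feature": feat, "eligible": True, "p": np.nan})
            continue
        p = float(res.pvalues[feat])
        rows.append({"feature": feat, "eligible": True, "p": p,
                     "beta": float(res.beta[feat])})
        if p < alpha:
            selected.append(feat)
    return ScreenResult(eligible, selected, pd.DataFrame(rows), flagged)


def ordinal_lasso(
    y, X_selected: pd.DataFrame, lambda_grid=None, seed: int = 0, cv: int = 5,
    lam: float | None = None,
) -> PenalizedOrdinalResults:
    """Multivariable ordered LASSO on the screened features."""
    if X_selected.shape[1] < 2 and lam is None:
        raise ValueError("ordered LASSO expects at least 2 selected features")
    model = OrdinalResponseModel(y, X_selected)
    return model.fit_regularized(lam=lam, lambda_grid=lambda_grid, cv=cv, seed=seed)
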