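"""Exact-enumeration Bayesian Model Averaging under the Zellner g-prior.

For a standardized response y and k standardized candidate predictors,
every one of the 2^k linear models is scored by its closed-form Bayes
factor against the null (intercept-only) model,

    log BF(M : null) = ((n - 1 - k_M)/2) * ln(1 + g)
                       - ((n - 1)/2) * ln(1 + g * (1 - R^2_M)),

with a uniform prior over models.  Posterior inclusion probabilities
(PIPs) follow by summing model posteriors, and with prior inclusion
odds of 1 a PIP maps to a per-candidate Bayes factor bf = pip/(1-pip)
(PIP 0.75 <-> BF 3, PIP 0.91 <-> BF ~10).  The default g is the unit
information prior, g = n.

When the candidate set is large relative to the number of units, a
rotation procedure enumerates overlapping windows ordered by causal
proximity, retaining the strongest candidates from each round; with
three or fewer candidates a weakly regularized linear model with a
classical 0.05 inclusion test is used instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "BMAFit",
    "BMARegressor",
    "SmallModelFit",
    "log_marginal_likelihood",
    "enumerate_bma",
    "rotation_select",
    "small_model_fit",
    "pip_to_bf",
    "bf_to_pip",
    "evidence_tier",
    "EVIDENCE_TIERS",
]

#: tier name -> (lower BF bound, upper BF bound)
EVIDENCE_TIERS: dict[str, tuple[float, float]] = {
    "null_strong": (0.0, 1.0 / 10.0),
    "null_moderate": (1.0 / 10.0, 1.0 / 3.0),
    "inconclusive": (1.0 / 3.0, 3.0),
    "moderate": (3.0, 10.0),
    "strong10": (10.0, 30.0),
    "strong30": (30.0, 100.0),
    "strong100": (100.0, np.inf),
}


def pip_to_bf(pip: float) -> float:
    """Posterior odds for inclusion under prior odds 1: pip/(1-pip)."""
    if not 0.0 <= pip <= 1.0:
        raise ValueError("pip must be in [0, 1]")
    if pip == 1.0:
        return np.inf
    return pip / (1.0 - pip)


def bf_to_pip(bf: float) -> float:
    if bf < 0:
        raise ValueError("Bayes factor must be non-negative")
    if np.isinf(bf):
        return 1.0
    return bf / (1.0 + bf)


def evidence_tier(bf: float) -> str:
    """Classify a Bayes factor into the 3/10/30/100 evidence tiers."""
    if np.isnan(bf):
        raise ValueError("cannot tier a NaN Bayes factor")
    for name, (lo, hi) in EVIDENCE_TIERS.items():
        if lo <= bf < hi:
            return name
    return "strong100"


def _standardize(a: np.ndarray) -> np.ndarray:
    sd = a.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("constant column cannot be standardized")
    return (a - a.mean(axis=0)) / sd


def log_marginal_likelihood(
    y: np.ndarray | pd.Series,
    X: np.ndarray | pd.DataFrame | None,
    g: float,
) -> float:
    """Log Bayes factor of the model spanned by X's columns vs the null.

    ``y`` and the predictors are standardized internally; the null
    (empty) model scores exactly 0.  Raises on a singular design.
    """
    yv = _standardize(np.asarray(y, dtype=float).reshape(-1, 1)).ravel()
    n = yv.shape[0]
    if X is None or (hasattr(X, "shape") and X.shape[1] == 0):
        return 0.0
    Xv = _standardize(np.asarray(X, dtype=float))
    k = Xv.shape[1]
    if k >= n - 1:
        raise ValueError(f"model size {k} must be < n - 1 = {n - 1}")
    coef, _, rank, _ = np.linalg.lstsq(
        np.column_stack([np.ones(n), Xv]), yv, rcond=None
    )
    if rank < k + 1:
        raise ValueError("singular design within the candidate subset")
    resid = yv - np.column_stack([np.ones(n), Xv]) @ coef
    r2 = 1.0 - resid @ resid / (yv @ yv)
    r2 = float(min(max(r2, 0.0), 1.0))
    return float(
        0.5 * (n - 1 - k) * np.log1p(g) - 0.5 * (n - 1) * np.log1p(g * (1.0 - r2))
    )


@dataclass
class BMAFit:
    """Posterior summary of an exact model enumeration.

    ``model_posteriors`` maps each model (tuple of candidate names) to
    its posterior probability; probabilities sum to 1.  ``pip`` is the
    per-candidate inclusion probability, ``beta_conditional`` the
    posterior-mean standardized coefficient given inclusion (g-prior
    shrinkage g/(1+g) applied), and ``beta_unconditional`` the mean over
    all models with exclusion counting as zero.
    """

    response: str
    candidates: list[str]
    g: float
    n_units: int
    pip: pd.Series
    beta_conditional: pd.Series
    beta_unconditional: pd.Series
    model_posteriors: dict[tuple[str, ...], float]

    @property
    def bf(self) -> pd.Series:
        return self.pip.map(pip_to_bf)

    @property
    def tier(self) -> pd.Series:
        return self.bf.map(evidence_tier)

    def top_models(self, n: int = 5) -> list[tuple[tuple[str, ...], float]]:
        return sorted(self.model_posteriors.items(), key=lambda kv: -kv[1])[:n]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pip": self.pip,
                "bf": self.bf,
                "tier": self.tier,
                "beta_conditional": self.beta_conditional,
                "beta_unconditional": self.beta_unconditional,
            }
        )


def _enumerate_core(
    y: np.ndarray, X: np.ndarray, g: float
) -> tuple[np.ndarray, list[tuple[int, ...]], np.ndarray, list[np.ndarray]]:
    """Score all 2^k subsets.

    Returns (log marginal likelihoods, subsets, R^2 per model, shrunk
    standardized betas per model).  Subsets are enumerated grouped by
    size and solved as batched linear systems on the correlation matrix:
    for subset S, beta_S = R_S^{-1} r_S and R^2 = r_S . beta_S.
    """
    n, k = X.shape
    Z = np.column_stack([_standardize(y.reshape(-1, 1)).ravel(), _standardize(X)])
    C = np.corrcoef(Z, rowvar=False)
    r_y = C[0, 1:]
    R = C[1:, 1:]
    shrink = g / (1.0 + g)
    lmls: list[float] = [0.0]
    subsets: list[tuple[int, ...]] = [()]
    r2s: list[float] = [0.0]
    betas: list[np.ndarray] = [np.array([])]
    for size in range(1, k + 1):
        combos = np.array(list(combinations(range(k), size)), dtype=int)
        Rsub = R[combos[:, :, None], combos[:, None, :]]
        rhs = r_y[combos]
        try:
            beta = np.linalg.solve(Rsub, rhs[..., None])[..., 0]
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                "singular design within a candidate subset"
            ) from exc
        r2 = np.clip(np.einsum("ms,ms->m", beta, rhs), 0.0, 1.0)
        lml = 0.5 * (n - 1 - size) * np.log1p(g) - 0.5 * (n - 1) * np.log1p(
            g * (1.0 - r2)
        )
        for c, l, r2v, b in zip(combos, lml, r2, beta):
            subsets.append(tuple(int(i) for i in c))
            lmls.append(float(l))
            r2s.append(float(r2v))
            betas.append(shrink * b)
    return np.array(lmls), subsets, np.array(r2s), betas


class BMARegressor(BaseEstimator, RegressorMixin):
    """Exact-enumeration g-prior BMA as a scikit-learn estimator.

    Parameters
    ----------
    g : float or "uip", default="uip"
        Zellner g; "uip" (unit information prior) sets g = n at fit
        time.
    max_candidates : int, default=20
        Enumeration guard; beyond this use :func:`rotation_select`.

    Attributes (after :meth:`fit`)
    ------------------------------
    pip_ : pandas.Series of posterior inclusion probabilities.
    beta_conditional_, beta_unconditional_ : pandas.Series.
    bf_, tier_ : pandas.Series.
    fit_ : BMAFit with the full model posterior.
    """

    def __init__(self, g: float | str = "uip", max_candidates: int = 20):
        self.g = g
        self.max_candidates = max_candidates

    def _resolve_g(self, n: int) -> float:
        if isinstance(self.g, str):
            if self.g != "uip":
                raise ValueError(f"unknown g setting {self.g!r}")
            return float(n)
        return float(self.g)

    def fit(self, X: pd.DataFrame, y: pd.Series | np.ndarray):
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X))
            X.columns = [f"x{i}" for i in range(X.shape[1])]
        names = list(X.columns)
        if len(set(names)) != len(names):
            raise ValueError("duplicate candidate names")
        k = X.shape[1]
        if k > self.max_candidates:
            raise ValueError(
                f"{k} candidates exceed the enumeration guard "
                f"({self.max_candidates}); use rotation_select"
            )
        yv = np.asarray(y, dtype=float)
        n = yv.shape[0]
        g = self._resolve_g(n)
        if k == 0:
            post = {(): 1.0}
            empty = pd.Series(dtype=float)
            self.fit_ = BMAFit(
                response=getattr(y, "name", "y") or "y",
                candidates=[],
                g=g,
                n_units=n,
                pip=empty,
                beta_conditional=empty,
                beta_unconditional=empty,
                model_posteriors=post,
            )
        else:
            lmls, subsets, _r2s, betas = _enumerate_core(yv, X.to_numpy(float), g)
            w = np.exp(lmls - lmls.max())
            post = w / w.sum()
            pip = np.zeros(k)
            beta_u = np.zeros(k)
            for prob, sub, b in zip(post, subsets, betas):
                for pos, j in enumerate(sub):
                    pip[j] += prob
                    beta_u[j] += prob * b[pos]
            pip = np.clip(pip, 0.0, 1.0)
            with np.errstate(invalid="ignore", divide="ignore"):
                beta_c = np.where(pip > 0, beta_u / pip, 0.0)
            self.fit_ = BMAFit(
                response=getattr(y, "name", "y") or "y",
                candidates=names,
                g=g,
                n_units=n,
                pip=pd.Series(pip, index=names),
                beta_conditional=pd.Series(beta_c, index=names),
                beta_unconditional=pd.Series(beta_u, index=names),
                model_posteriors={
                    tuple(names[j] for j in sub): float(p)
                    for sub, p in zip(subsets, post)
                },
            )
        self.pip_ = self.fit_.pip
        self.beta_conditional_ = self.fit_.beta_conditional
        self.beta_unconditional_ = self.fit_.beta_unconditional
        self.bf_ = self.fit_.bf
        self.tier_ = self.fit_.tier
        self.n_features_in_ = k
        self._x_mean = X.mean(axis=0)
        self._x_sd = X.std(axis=0, ddof=1)
        self._y_mean = float(np.mean(yv))
        self._y_sd = float(np.std(yv, ddof=1))
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Model-averaged prediction (unconditional posterior-mean betas)."""
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X), columns=self.pip_.index)
        z = (X.loc[:, self.pip_.index] - self._x_mean) / self._x_sd
        return self._y_mean + self._y_sd * (
            z.to_numpy(float) @ self.beta_unconditional_.to_numpy()
        )


def enumerate_bma(
    y: pd.Series | np.ndarray,
    candidates: pd.DataFrame,
    g: float | str = "uip",
) -> BMAFit:
    """Score all 2^k candidate subsets; see :class:`BMARegressor`."""
    return BMARegressor(g=g).fit(candidates, y).fit_


def rotation_select(
    y: pd.Series | np.ndarray,
    candidates: pd.DataFrame,
    g: float | str = "uip",
    window: int = 8,
    retain: int = 5,
) -> BMAFit:
    """Windowed BMA over many candidates ordered by causal proximity.

    The first ``window`` candidates (causally closest to the response
    first) are enumerated; the ``retain`` candidates with the highest
    PIPs survive and are joined by the next ``window`` candidates, the
    rounds continuing until every candidate has been evaluated.  The
    returned fit carries the final round's model posterior; candidates
    that were evaluated but never retained keep the PIP and coefficients
    from the last round in which they appeared.
    """
    names = list(candidates.columns)
    if len(names) <= 3:
        raise ValueError("3 or fewer candidates: use small_model_fit")
    if len(names) <= window:
        return enumerate_bma(y, candidates, g=g)
    last_pip: dict[str, float] = {}
    last_beta_c: dict[str, float] = {}
    last_beta_u: dict[str, float] = {}
    remaining = list(names)
    current = remaining[:window]
    remaining = remaining[window:]
    while True:
        fit = enumerate_bma(y, candidates.loc[:, current], g=g)
        for c in current:
            last_pip[c] = float(fit.pip[c])
            last_beta_c[c] = float(fit.beta_conditional[c])
            last_beta_u[c] = float(fit.beta_unconditional[c])
        if not remaining:
            break
        survivors = list(fit.pip.sort_values(ascending=False).index[:retain])
        # keep causal-proximity order among survivors and newcomers
        survivors = [c for c in current if c in set(survivors)]
        newcomers = remaining[:window]
        remaining = remaining[window:]
        current = survivors + newcomers
    pip = pd.Series({c: last_pip[c] for c in names})
    beta_c = pd.Series({c: last_beta_c[c] for c in names})
    beta_u = pd.Series({c: last_beta_u[c] for c in names})
    return BMAFit(
        response=fit.response,
        candidates=names,
        g=fit.g,
        n_units=fit.n_units,
        pip=pip,
        beta_conditional=beta_c,
        beta_unconditional=beta_u,
        model_posteriors=fit.model_posteriors,
    )


@dataclass
class SmallModelFit:
    """Weakly regularized linear fit for candidate sets of size <= 3."""

    response: str
    candidates: list[str]
    coef: pd.Series  # standardized, ridge-shrunk
    se: pd.Series
    p: pd.Series
    included: list[str]
    prior_scale: float


def small_model_fit(
    y: pd.Series | np.ndarray,
    candidates: pd.DataFrame,
    prior_scale: float = 2.5,
    alpha: float = 0.05,
) -> SmallModelFit:
    """Ridge-shrunk linear model with a classical inclusion test.

    All variables are z-scored; coefficients carry independent N(0,
    prior_scale^2) priors (a weak shrinkage at scale 2.5), and a
    candidate is included when its two-tailed coefficient test beats
    ``alpha``.  Intended for responses with three or fewer causally
    prior candidates, where model enumeration is uninformative.
    """
    names = list(candidates.columns)
    if len(names) > 3:
        raise ValueError("small_model_fit accepts at most 3 candidates")
    yv = np.asarray(y, dtype=float)
    n = yv.shape[0]
    if n < 5:
        raise ValueError("need at least 5 units")
    if not names:
        return SmallModelFit(
            response=getattr(y, "name", "y") or "y",
            candidates=[],
            coef=pd.Series(dtype=float),
            se=pd.Series(dtype=float),
            p=pd.Series(dtype=float),
            included=[],
            prior_scale=prior_scale,
        )
    X = _standardize(candidates.to_numpy(float))
    yz = _standardize(yv.reshape(-1, 1)).ravel()
    ols, _, rank, _ = np.linalg.lstsq(X, yz, rcond=None)
    if rank < len(names):
        raise ValueError("collinear candidates")
    resid = yz - X @ ols
    dof = n - len(names) - 1
    sigma2 = float(resid @ resid) / dof
    lam = sigma2 / prior_scale**2
    A = X.T @ X + lam * np.eye(len(names))
    coef = np.linalg.solve(A, X.T @ yz)
    cov = sigma2 * np.linalg.solve(A, np.linalg.solve(A, X.T @ X).T)
    se = np.sqrt(np.diag(cov))
    t = coef / se
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    coef_s = pd.Series(coef, index=names)
    p_s = pd.Series(p, index=names)
    return SmallModelFit(
        response=getattr(y, "name", "y") or "y",
        candidates=names,
        coef=coef_s,
        se=pd.Series(se, index=names),
        p=p_s,
        included=[c for c in names if p_s[c] < alpha],
        prior_scale=prior_scale,
    )
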