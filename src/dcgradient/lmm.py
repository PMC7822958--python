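"""Linear mixed-effects modelling of directed-coherence connection tables.

The models regress DC values on the within-subject factors *direction of
influences*, *hemisphere* (ipsi/contra) and *stimulation state* and on
between-subject covariates, with random intercepts for participant x
stream and participant x level-pair, fitted by maximum likelihood.
Fixed-effect terms are tested with Type III F statistics using
Satterthwaite's approximation of the denominator degrees of freedom;
non-significant highest-order interactions are removed top-down (largest
p first, one per refit, respecting marginality) to yield a parsimonious
model.  Sum-to-zero contrasts are used throughout, as Type III marginal
tests require.

The variance structure here is a plain variance-components model
(independent random intercepts, shared residual variance), so the
likelihood is profiled analytically down to the variance *ratios*
``gamma_k = tau_k / sigma^2`` and evaluated from crossproduct matrices
in O(q^3) per evaluation, independent of the number of rows.  This is
what makes the Monte-Carlo calibration suites (hundreds of fits)
tractable, and it exposes the profiled likelihood needed for the
Satterthwaite machinery.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import patsy
from scipy import optimize, stats

from .exceptions import ConfigurationError, DataError, EstimationError

_GAMMA_FLOOR = 1e-8  # variance ratios below this are treated as boundary zeros


# ---------------------------------------------------------------------------
# model specification


@dataclass(frozen=True)
class LMMSpec:
    """Fixed- and random-effects structure of a connection-table model.

    ``blocks`` lists the maximal interaction blocks; the initial model
    contains every nonempty subset of each block (all lower-order terms
    are always included with their interactions).  ``random`` lists the
    random-intercept grouping factors as tuples of column names whose
    combination identifies a group (never reduced).  ``protected`` terms
    are exempt from removal beyond the default protection of all main
    effects.
    """

    blocks: tuple[tuple[str, ...], ...]
    response: str = "dc"
    random: tuple[tuple[str, ...], ...] = (
        ("participant", "stream_id"),
        ("participant", "level_pair"),
    )
    alpha: float = 0.05
    factors: tuple[str, ...] | None = None
    center_covariates: bool = False
    protected: tuple[frozenset, ...] = ()

    @staticmethod
    def model1(alpha: float = 0.05) -> "LMMSpec":
        """Direction x hemisphere x stimulation crossed with each covariate."""
        covariates = (
            "age_at_onset",
            "duration_before_implant",
            "time_since_implant",
            "ledd",
            "vat",
        )
        blocks = tuple(
            ("direction", "hemisphere_label", "state", cov) for cov in covariates
        )
        return LMMSpec(blocks=blocks, alpha=alpha)

    @staticmethod
    def model2(alpha: float = 0.05) -> "LMMSpec":
        """Direction x stimulation x disease duration before implantation."""
        return LMMSpec(
            blocks=(("direction", "state", "duration_before_implant"),), alpha=alpha
        )

    def initial_terms(self) -> list[frozenset]:
        terms: set[frozenset] = set()
        for block in self.blocks:
            for r in range(1, len(block) + 1):
                for combo in itertools.combinations(block, r):
                    terms.add(frozenset(combo))
        return sorted(terms, key=lambda t: (len(t), tuple(sorted(t))))


def _detect_factors(data: pd.DataFrame, variables: set[str]) -> set[str]:
    factors = set()
    for v in variables:
        if not pd.api.types.is_numeric_dtype(data[v]):
            factors.add(v)
    return factors


def _term_code(term: frozenset, factors: set[str]) -> str:
    parts = []
    for v in sorted(term):
        parts.append(f"C({v}, Sum)" if v in factors else v)
    return ":".join(parts)


def prepare_connection_table(table: pd.DataFrame, cohort=None) -> pd.DataFrame:
    """Normalize a connection table for modelling.

    Adds hemisphere-specific stream ids (random-effect grouping), joins
    participant covariates from ``cohort`` (an iterable of
    ``ParticipantRecord``) when given, and casts grouping columns to
    strings for deterministic design construction.
    """
    out = table.copy()
    if cohort is not None:
        cov = pd.DataFrame(
            {
                "participant": [p.id for p in cohort],
                "side_of_onset": [p.side_of_onset for p in cohort],
                "age_at_onset": [p.age_at_onset for p in cohort],
                "duration_before_implant": [p.duration_before_implant for p in cohort],
                "time_since_implant": [p.time_since_implant for p in cohort],
                "ledd": [p.ledd for p in cohort],
                "vat": [p.vat for p in cohort],
            }
        )
        out = out.merge(cov, on="participant", how="left")
    if "stream_id" not in out.columns and {"hemisphere", "stream"} <= set(out.columns):
        out["stream_id"] = out["hemisphere"].astype(str) + out["stream"].astype(str)
    for col in ("participant", "state", "direction", "hemisphere_label",
                "level_pair", "stream_id"):
        if col in out.columns:
            out[col] = out[col].astype(str)
    return out


# ---------------------------------------------------------------------------
# variance-components likelihood core


class _VCCore:
    """Crossproduct-based profiled likelihood for a variance-components LMM.

    y = X beta + sum_k Z_k b_k + e,  b_k ~ N(0, tau_k I),  e ~ N(0, sigma^2 I).
    """

    def __init__(self, y: np.ndarray, X: np.ndarray, Z: np.ndarray,
                 block_sizes: list[int]):
        self.y = y
        self.X = X
        self.Z = Z
        self.block_sizes = list(block_sizes)
        self.n, self.p = X.shape
        self.q = Z.shape[1] if Z.size else 0
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)
        if self.q:
            self.ZtZ = Z.T @ Z
            self.ZtX = Z.T @ X
            self.Zty = Z.T @ y
        self.block_index = np.repeat(np.arange(len(block_sizes)), block_sizes)

    # -- algebra -----------------------------------------------------------

    def _whitened(self, gammas: np.ndarray):
        """Return (XtViX, XtViy, ytViy, logdetV0) for V0 = I + Z G Z'."""
        active = gammas > _GAMMA_FLOOR
        if self.q == 0 or not active.any():
            return self.XtX, self.Xty, self.yty, 0.0
        cols = np.isin(self.block_index, np.flatnonzero(active))
        g = np.repeat(gammas[active], np.asarray(self.block_sizes)[active])
        M = self.ZtZ[np.ix_(cols, cols)] + np.diag(1.0 / g)
        cho = np.linalg.cholesky(M)
        ZtX = self.ZtX[cols]
        Zty = self.Zty[cols]
        w_X = np.linalg.solve(cho, ZtX)
        w_y = np.linalg.solve(cho, Zty)
        XtViX = self.XtX - w_X.T @ w_X
        XtViy = self.Xty - w_X.T @ w_y
        ytViy = self.yty - float(w_y @ w_y)
        logdetV0 = 2.0 * np.log(np.diag(cho)).sum() + np.log(g).sum()
        return XtViX, XtViy, ytViy, logdetV0

    def gls(self, gammas: np.ndarray):
        """beta-hat, residual quadratic form and log|V0| at variance ratios."""
        XtViX, XtViy, ytViy, logdetV0 = self._whitened(gammas)
        try:
            beta = np.linalg.solve(XtViX, XtViy)
        except np.linalg.LinAlgError as exc:
            raise EstimationError("aliased fixed-effects design (singular X'V^-1X)") from exc
        rss = ytViy - float(beta @ XtViy)
        return beta, max(rss, 1e-300), logdetV0, XtViX

    def profile_loglik(self, gammas: np.ndarray, reml: bool = False) -> float:
        """Log-likelihood profiled over beta and sigma^2."""
        beta, rss, logdetV0, XtViX = self.gls(gammas)
        n, p = self.n, self.p
        if reml:
            dof = n - p
            sigma2 = rss / dof
            sign, logdetX = np.linalg.slogdet(XtViX)
            if sign <= 0:
                return -np.inf
            return -0.5 * (dof * (np.log(2 * np.pi * sigma2) + 1.0) + logdetV0 + logdetX)
        sigma2 = rss / n
        return -0.5 * (n * (np.log(2 * np.pi * sigma2) + 1.0) + logdetV0)

    def loglik(self, taus: np.ndarray, sigma2: float, reml: bool = False) -> float:
        """Log-likelihood at natural variance parameters, beta profiled."""
        gammas = np.asarray(taus, dtype=float) / sigma2
        beta, rss, logdetV0, XtViX = self.gls(gammas)
        n, p = self.n, self.p
        base = -0.5 * (n * np.log(2 * np.pi * sigma2) + logdetV0 + rss / sigma2)
        if not reml:
            return base
        sign, logdetX = np.linalg.slogdet(XtViX / sigma2)
        return base + 0.5 * p * np.log(2 * np.pi) - 0.5 * logdetX

    def cov_beta(self, taus: np.ndarray, sigma2: float) -> np.ndarray:
        gammas = np.asarray(taus, dtype=float) / sigma2
        XtViX, *_ = self._whitened(gammas)
        return sigma2 * np.linalg.inv(XtViX)

    # -- fitting -----------------------------------------------------------

    def fit(self, reml: bool = False):
        """Maximize the profiled likelihood over the variance ratios."""
        k = len(self.block_sizes)
        if k == 0:
            beta, rss, _, XtViX = self.gls(np.zeros(0))
            dof = self.n - self.p if reml else self.n
            sigma2 = rss / dof
            return _VCFit(self, np.zeros(0), sigma2, beta,
                          sigma2 * np.linalg.inv(XtViX),
                          self.profile_loglik(np.zeros(0), reml), reml, True)

        def objective(eta: np.ndarray) -> float:
            return -self.profile_loglik(np.exp(eta), reml)

        best = None
        for start in (np.full(k, np.log(0.5)), np.full(k, np.log(0.05)),
                      np.full(k, np.log(2.0))):
            res = optimize.minimize(
                objective, start, method="L-BFGS-B",
                bounds=[(-18.0, 8.0)] * k,
                options={"maxiter": 500, "ftol": 1e-10},
            )
            if best is None or res.fun < best.fun - 1e-10:
                best = res
        if not best.success:
            # L-BFGS-B line searches can terminate abnormally with
            # finite-difference gradients; polish with Nelder-Mead.
            polish = optimize.minimize(
                objective, best.x, method="Nelder-Mead",
                options={"maxiter": 2000, "xatol": 1e-8, "fatol": 1e-10},
            )
            if polish.fun <= best.fun + 1e-10:
                best = polish
        gammas = np.exp(np.clip(best.x, -18.0, 8.0))
        gammas[gammas <= 2 * np.exp(-18.0)] = 0.0
        beta, rss, _, XtViX = self.gls(gammas)
        dof = self.n - self.p if reml else self.n
        sigma2 = rss / dof
        cov = sigma2 * np.linalg.inv(XtViX)
        return _VCFit(self, gammas, sigma2, beta, cov,
                      -best.fun, reml, bool(best.success))


@dataclass
class _VCFit:
    core: _VCCore
    gammas: np.ndarray
    sigma2: float
    beta: np.ndarray
    cov_beta: np.ndarray
    loglik: float
    reml: bool
    converged: bool

    @property
    def taus(self) -> np.ndarray:
        return self.gammas * self.sigma2

    @property
    def boundary(self) -> np.ndarray:
        return self.gammas <= _GAMMA_FLOOR


# ---------------------------------------------------------------------------
# Satterthwaite machinery


class _Satterthwaite:
    """Denominator degrees of freedom for Wald F tests on a fitted LMM.

    The asymptotic covariance ``A`` of the variance parameters is the
    inverse observed information of the (beta-profiled) log-likelihood
    in log-variance coordinates; for a single contrast ``l`` the df are
    ``2 (l' Vb l)^2 / (g' A g)`` with ``g`` the gradient of ``l' Vb l``
    in the same coordinates.  Multi-df terms use the eigendecomposition
    construction: the F statistic is split into independent 1-df
    contrasts whose Satterthwaite dfs are pooled.
    """

    def __init__(self, fit: _VCFit, step: float = 1e-4):
        self.fit = fit
        self.core = fit.core
        active = ~fit.boundary
        self.active = np.flatnonzero(active)
        taus = fit.taus[self.active]
        self.eta_hat = np.log(np.concatenate([taus, [fit.sigma2]]))
        self.step = step
        self.A = self._vcov_varpar()

    def _theta(self, eta: np.ndarray) -> tuple[np.ndarray, float]:
        taus = np.zeros(len(self.fit.gammas))
        taus[self.active] = np.exp(eta[:-1])
        return taus, float(np.exp(eta[-1]))

    def _loglik_eta(self, eta: np.ndarray) -> float:
        taus, sigma2 = self._theta(eta)
        return self.core.loglik(taus, sigma2, reml=self.fit.reml)

    def _vcov_varpar(self) -> np.ndarray | None:
        m = len(self.eta_hat)
        h = self.step
        H = np.empty((m, m))
        f0 = self._loglik_eta(self.eta_hat)
        for i in range(m):
            for j in range(i, m):
                ei = np.zeros(m); ei[i] = h
                ej = np.zeros(m); ej[j] = h
                if i == j:
                    fpp = self._loglik_eta(self.eta_hat + ei)
                    fmm = self._loglik_eta(self.eta_hat - ei)
                    H[i, i] = (fpp - 2 * f0 + fmm) / h**2
                else:
                    fpp = self._loglik_eta(self.eta_hat + ei + ej)
                    fpm = self._loglik_eta(self.eta_hat + ei - ej)
                    fmp = self._loglik_eta(self.eta_hat - ei + ej)
                    fmm = self._loglik_eta(self.eta_hat - ei - ej)
                    H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h**2)
        try:
            A = np.linalg.inv(-H)
        except np.linalg.LinAlgError:
            return None
        if not np.all(np.isfinite(A)) or np.any(np.diag(A) < 0):
            return None
        return A

    def _var_contrast(self, eta: np.ndarray, l: np.ndarray) -> float:
        taus, sigma2 = self._theta(eta)
        vb = self.core.cov_beta(taus, sigma2)
        return float(l @ vb @ l)

    def contrast_df(self, l: np.ndarray) -> float:
        """Satterthwaite df for a single contrast vector on beta."""
        if self.A is None:
            return float(self.core.n - self.core.p)
        m = len(self.eta_hat)
        h = self.step
        g = np.empty(m)
        for i in range(m):
            ei = np.zeros(m); ei[i] = h
            g[i] = (
                self._var_contrast(self.eta_hat + ei, l)
                - self._var_contrast(self.eta_hat - ei, l)
            ) / (2 * h)
        denom = float(g @ self.A @ g)
        v = self._var_contrast(self.eta_hat, l)
        if denom <= 0:
            return float(self.core.n - self.core.p)
        return 2.0 * v**2 / denom

    def ftest(self, L: np.ndarray) -> tuple[float, float, float]:
        """Wald F, numerator df and pooled Satterthwaite denominator df."""
        L = np.atleast_2d(L)
        beta = self.fit.beta
        C = L @ self.fit.cov_beta @ L.T
        qdim = L.shape[0]
        try:
            Ci = np.linalg.inv(C)
        except np.linalg.LinAlgError as exc:
            raise EstimationError("non-estimable contrast (singular covariance)") from exc
        F = float(L @ beta @ (Ci @ (L @ beta))) / qdim
        if qdim == 1:
            return F, 1.0, self.contrast_df(L[0])
        lam, P = np.linalg.eigh(C)
        keep = lam > lam.max() * 1e-12
        nus = []
        for i in np.flatnonzero(keep):
            li = P[:, i] @ L
            nus.append(self.contrast_df(li))
        nus = np.asarray(nus)
        ok = nus > 2.0
        if not ok.any():
            return F, float(qdim), float(self.core.n - self.core.p)
        E = float((nus[ok] / (nus[ok] - 2.0)).sum())
        qeff = int(ok.sum())
        if E <= qeff:
            return F, float(qdim), np.inf
        return F, float(qdim), 2.0 * E / (E - qeff)


# ---------------------------------------------------------------------------
# public result object and fitting entry points


@dataclass
class LMMResult:
    """Fitted mixed model with design metadata and reduction history."""

    params: pd.Series
    cov_params: pd.DataFrame
    sigma2: float
    vcomp: dict
    loglik: float
    reml: bool
    terms: list
    spec: LMMSpec
    data: pd.DataFrame
    design_info: object
    factors: set
    converged: bool
    fit: _VCFit = field(repr=False)
    reduction_history: list = field(default_factory=list)
    control_tag: str | None = None
    _satt: _Satterthwaite | None = field(default=None, repr=False)

    @property
    def n_obs(self) -> int:
        return len(self.data)

    @property
    def singular(self) -> bool:
        """True when a random-effect variance was estimated at the zero boundary."""
        return bool(self.fit.boundary.any())

    def satterthwaite(self) -> _Satterthwaite:
        if self._satt is None:
            self._satt = _Satterthwaite(self.fit)
        return self._satt

    def term_selector(self, term: frozenset) -> np.ndarray:
        """Rows selecting the design columns of a model term."""
        name = _term_code(term, self.factors)
        slices = self.design_info.term_name_slices
        if name not in slices:
            raise ConfigurationError(f"term {name!r} not in model")
        sl = slices[name]
        p = len(self.params)
        L = np.zeros((sl.stop - sl.start, p))
        for row, col in enumerate(range(sl.start, sl.stop)):
            L[row, col] = 1.0
        return L

    def predict_rows(self, new_data: pd.DataFrame) -> np.ndarray:
        """Design rows for new data under the fitted design."""
        (mat,) = patsy.build_design_matrices([self.design_info], new_data)
        return np.asarray(mat)


def _build_random_design(data: pd.DataFrame, random: tuple[tuple[str, ...], ...]):
    blocks, sizes, names = [], [], []
    for grouping in random:
        missing = [c for c in grouping if c not in data.columns]
        if missing:
            raise DataError(f"random-effect columns missing from table: {missing}")
        combined = data[list(grouping)].astype(str).agg(":".join, axis=1)
        dummies = pd.get_dummies(combined, dtype=float)
        blocks.append(dummies.to_numpy())
        sizes.append(dummies.shape[1])
        names.append(":".join(grouping))
    Z = np.concatenate(blocks, axis=1) if blocks else np.zeros((len(data), 0))
    return Z, sizes, names


def fit_lmm(
    table: pd.DataFrame,
    spec: LMMSpec,
    terms: list[frozenset] | None = None,
    reml: bool = False,
) -> LMMResult:
    """Fit the mixed model defined by ``spec`` (maximum likelihood by default).

    ``terms`` overrides the initial term set (used by the reduction
    procedure); unbalanced session structures are handled by row
    absence, without imputation.
    """
    data = prepare_connection_table(table)
    if terms is None:
        terms = spec.initial_terms()
    variables = set().union(*terms) if terms else set()
    missing = [v for v in sorted(variables | {spec.response}) if v not in data.columns]
    if missing:
        raise DataError(f"model variables missing from table: {missing}")
    sub = data.dropna(subset=sorted(variables | {spec.response}))
    if len(sub) < len(data):
        sub = sub.reset_index(drop=True)
    if spec.factors is not None:
        factors = set(spec.factors)
    else:
        factors = _detect_factors(sub, variables)
    if spec.center_covariates:
        sub = sub.copy()
        for v in sorted(variables - factors):
            sub[v] = sub[v] - sub[v].mean()
    rhs = " + ".join([_term_code(t, factors) for t in terms]) or "1"
    y_mat, x_mat = patsy.dmatrices(
        f"{spec.response} ~ {rhs}", sub, return_type="matrix"
    )
    X = np.asarray(x_mat)
    y = np.asarray(y_mat).ravel()
    design_info = x_mat.design_info
    Z, sizes, names = _build_random_design(sub, spec.random)
    core = _VCCore(y, X, Z, sizes)
    if core.n <= core.p:
        raise DataError(
            f"model has {core.p} fixed-effect columns but only {core.n} rows"
        )
    fit = core.fit(reml=reml)
    if not fit.converged:
        raise EstimationError("variance-ratio optimizer did not converge")
    params = pd.Series(fit.beta, index=design_info.column_names)
    cov = pd.DataFrame(
        fit.cov_beta, index=design_info.column_names, columns=design_info.column_names
    )
    vcomp = {name: float(tau) for name, tau in zip(names, fit.taus)}
    return LMMResult(
        params=params,
        cov_params=cov,
        sigma2=float(fit.sigma2),
        vcomp=vcomp,
        loglik=float(fit.loglik),
        reml=reml,
        terms=list(terms),
        spec=spec,
        data=sub,
        design_info=design_info,
        factors=factors,
        converged=fit.converged,
        fit=fit,
    )


def type3_tests(result: LMMResult) -> pd.DataFrame:
    """Type III F table (one row per fixed term, Satterthwaite denominator df).

    With sum-to-zero contrasts and all lower-order terms present, the
    marginal (Type III) hypothesis for a term is that its own design
    columns vanish.
    """
    satt = result.satterthwaite()
    rows = []
    for term in sorted(result.terms, key=lambda t: (len(t), tuple(sorted(t)))):
        L = result.term_selector(term)
        F, df1, df2 = satt.ftest(L)
        p = float(stats.f.sf(F, df1, df2)) if np.isfinite(df2) else float(
            stats.chi2.sf(F * df1, df1)
        )
        rows.append(
            {
                "term": " : ".join(sorted(term)),
                "order": len(term),
                "F": F,
                "df_num": df1,
                "df_den": df2,
                "p": p,
            }
        )
    return pd.DataFrame(rows).set_index("term")


def _removable(terms: list[frozenset], protected: tuple[frozenset, ...]) -> list[frozenset]:
    """Interaction terms not nested in any other present term."""
    out = []
    for t in terms:
        if len(t) < 2 or t in protected:
            continue
        if any(t < other for other in terms):
            continue
        out.append(t)
    return out


def reduce_model(
    table: pd.DataFrame,
    spec: LMMSpec,
    reml: bool = False,
    max_steps: int = 100,
) -> LMMResult:
    """Top-down reduction: drop non-significant highest-order interactions.

    At each step the currently maximal (non-nested) interaction terms
    are tested; among those with ``p > alpha`` the one with the largest
    p is removed and the model refitted.  Main effects and protected
    terms are never removed; marginality is preserved by construction
    (only non-nested terms are candidates).  The full history is
    recorded on the returned result.
    """
    terms = spec.initial_terms()
    history: list[dict] = []
    result = fit_lmm(table, spec, terms=terms, reml=reml)
    for step in range(max_steps):
        # only the currently-maximal terms can be removed, so only they
        # need Type III p values at this step
        satt = result.satterthwaite()
        candidates = _removable(result.terms, spec.protected)
        worst, worst_p = None, -np.inf
        for t in candidates:
            F, df1, df2 = satt.ftest(result.term_selector(t))
            p = float(stats.f.sf(F, df1, df2))
            if p > spec.alpha and p > worst_p:
                worst, worst_p = t, p
        if worst is None:
            break
        history.append(
            {"step": step + 1, "term": " : ".join(sorted(worst)), "p_at_removal": worst_p}
        )
        terms = [t for t in result.terms if t != worst]
        result = fit_lmm(table, spec, terms=terms, reml=reml)
    result.reduction_history = history
    return result


def vif_check(table: pd.DataFrame, predictors: list[str]) -> pd.DataFrame:
    """Variance inflation factors of fixed-effect predictors.

    Each predictor (factors entered via sum-coded columns) is regressed
    on all the others; VIF = 1 / (1 - R^2).  Perfect collinearity is
    reported as ``inf`` and flagged.
    """
    if len(predictors) < 2:
        raise ConfigurationError("VIF needs at least two predictors")
    data = prepare_connection_table(table)
    missing = [v for v in predictors if v not in data.columns]
    if missing:
        raise DataError(f"predictors missing from table: {missing}")
    factors = _detect_factors(data, set(predictors))
    rhs = " + ".join(_term_code(frozenset([v]), factors) for v in predictors)
    X = np.asarray(patsy.dmatrix(rhs, data))
    names = patsy.dmatrix(rhs, data).design_info.column_names
    rows = []
    for j in range(1, X.shape[1]):  # skip intercept
        target = X[:, j]
        others = np.delete(X, j, axis=1)
        coef, res, rank, _ = np.linalg.lstsq(others, target, rcond=None)
        fitted = others @ coef
        sst = float(((target - target.mean()) ** 2).sum())
        sse = float(((target - fitted) ** 2).sum())
        if sst == 0:
            vif = np.inf
        else:
            r2 = 1.0 - sse / sst
            vif = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
        rows.append({"predictor": names[j], "vif": vif, "flagged": vif >= 5.0})
    return pd.DataFrame(rows).set_index("predictor")


# ---------------------------------------------------------------------------
# post-hoc machinery: LS means, simple slopes, Tukey adjustment


def _model_variables(result: LMMResult) -> tuple[set, set]:
    variables = set().union(*result.terms) if result.terms else set()
    factors = {v for v in variables if v in result.factors}
    return factors, variables - factors


def _reference_grid(result: LMMResult, focal: dict) -> pd.DataFrame:
    """Full factorial grid over model factors with covariates at their means.

    ``focal`` pins variables to given values; remaining factors vary
    over their observed levels (design rows are later averaged over
    them, which is the estimated-marginal-means convention).
    """
    factors, covariates = _model_variables(result)
    grid_vars = {}
    for v in sorted(factors):
        grid_vars[v] = [focal[v]] if v in focal else sorted(result.data[v].unique())
    for v in sorted(covariates):
        grid_vars[v] = [focal.get(v, float(result.data[v].mean()))]
    rows = [
        dict(zip(grid_vars.keys(), combo))
        for combo in itertools.product(*grid_vars.values())
    ]
    return pd.DataFrame(rows)


def _cell_row(result: LMMResult, focal: dict) -> np.ndarray:
    """Design row of an LS mean: average over non-focal factor levels."""
    grid = _reference_grid(result, focal)
    return result.predict_rows(grid).mean(axis=0)


def _tukey_p(t_abs: float, k: int, df: float) -> float:
    if k < 2:
        return float(stats.t.sf(t_abs, df) * 2.0)
    df_eff = df if np.isfinite(df) else 1e6
    return float(stats.studentized_range.sf(t_abs * np.sqrt(2.0), k, df_eff))


def _estimate_table(result: LMMResult, rows: list[tuple[dict, np.ndarray]]):
    satt = result.satterthwaite()
    beta = result.params.to_numpy()
    vb = result.cov_params.to_numpy()
    ests = []
    for cell, l in rows:
        est = float(l @ beta)
        se = float(np.sqrt(l @ vb @ l))
        df = satt.contrast_df(l)
        tcrit = stats.t.ppf(0.975, df)
        ests.append(
            {**cell, "estimate": est, "se": se, "df": df,
             "ci_lower": est - tcrit * se, "ci_upper": est + tcrit * se}
        )
    comparisons = []
    k = len(rows)
    for (cell_a, la), (cell_b, lb) in itertools.combinations(rows, 2):
        l = la - lb
        diff = float(l @ beta)
        se = float(np.sqrt(l @ vb @ l))
        df = satt.contrast_df(l)
        t = diff / se if se > 0 else np.inf
        p_unadj = float(stats.t.sf(abs(t), df) * 2.0)
        p_tukey = max(_tukey_p(abs(t), k, df), p_unadj)
        label_a = ", ".join(f"{v}={cell_a[v]}" for v in cell_a)
        label_b = ", ".join(f"{v}={cell_b[v]}" for v in cell_b)
        comparisons.append(
            {"contrast": f"({label_a}) - ({label_b})", "estimate": diff, "se": se,
             "df": df, "t": t, "p_unadjusted": p_unadj, "p_tukey": p_tukey}
        )
    return pd.DataFrame(ests), pd.DataFrame(comparisons)


def lsmeans(result: LMMResult, by: list[str]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Least-squares means per cell of ``by`` with Tukey-adjusted pairwise tests.

    Returns ``(means, comparisons)``; covariates are held at their data
    means and non-focal factors are averaged over.  Confidence bounds
    are pointwise 95% with Satterthwaite df.
    """
    factors, _ = _model_variables(result)
    unknown = [v for v in by if v not in factors]
    if unknown:
        raise ConfigurationError(f"not factors in this model: {unknown}")
    cells = [
        dict(zip(by, combo))
        for combo in itertools.product(*[sorted(result.data[v].unique()) for v in by])
    ]
    rows = [(cell, _cell_row(result, cell)) for cell in cells]
    return _estimate_table(result, rows)


def simple_slopes(
    result: LMMResult, covariate: str, by: list[str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Slope of the response on ``covariate`` within each cell of ``by``.

    The slope contrast is the exact derivative of the (linear-in-
    covariate) design row; pairwise slope differences are Tukey-adjusted
    over the cell family.
    """
    factors, covariates = _model_variables(result)
    if covariate not in covariates:
        raise ConfigurationError(f"{covariate!r} is not a covariate in this model")
    x0 = float(result.data[covariate].mean())
    h = float(result.data[covariate].std() or 1.0)
    cells = [
        dict(zip(by, combo))
        for combo in itertools.product(*[sorted(result.data[v].unique()) for v in by])
    ]
    rows = []
    for cell in cells:
        hi = _cell_row(result, {**cell, covariate: x0 + h})
        lo = _cell_row(result, {**cell, covariate: x0 - h})
        rows.append((cell, (hi - lo) / (2.0 * h)))
    return _estimate_table(result, rows)


def prediction_band(
    result: LMMResult, covariate: str, cell: dict, values: np.ndarray
) -> pd.DataFrame:
    """Pointwise 95% (non-simultaneous) band for predictions along a covariate."""
    satt = result.satterthwaite()
    beta = result.params.to_numpy()
    vb = result.cov_params.to_numpy()
    rows = []
    for v in np.asarray(values, dtype=float):
        l = _cell_row(result, {**cell, covariate: v})
        est = float(l @ beta)
        se = float(np.sqrt(l @ vb @ l))
        df = satt.contrast_df(l)
        tcrit = stats.t.ppf(0.975, df)
        rows.append(
            {covariate: v, "predicted": est, "se": se,
             "ci_lower": est - tcrit * se, "ci_upper": est + tcrit * se}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# covariate-substitution control analyses

_SUBSTITUTIONS = {
    "overall_disease_duration": {
        "derived": ("overall_disease_duration",
                    ("duration_before_implant", "time_since_implant")),
        "replaces": ("duration_before_implant", "time_since_implant"),
    },
    "chronological_age": {
        "derived": ("chronological_age",
                    ("age_at_onset", "duration_before_implant", "time_since_implant")),
        "replaces": ("age_at_onset", "duration_before_implant", "time_since_implant"),
    },
}


def covariate_substitution_refit(
    table: pd.DataFrame,
    spec: LMMSpec,
    substitution: str,
    reml: bool = False,
) -> LMMResult:
    """Control refit with time covariates replaced by a derived sum.

    ``substitution`` is ``"overall_disease_duration"`` (pre-implant
    duration + time since implantation) or ``"chronological_age"`` (sum
    of all three time covariates).  Every model block referencing a
    replaced covariate is rewritten to reference the derived one, blocks
    are deduplicated, and the same top-down reduction is run; the result
    is tagged as a control analysis.
    """
    if substitution not in _SUBSTITUTIONS:
        raise ConfigurationError(
            f"unknown substitution {substitution!r}; choose from "
            f"{sorted(_SUBSTITUTIONS)}"
        )
    rule = _SUBSTITUTIONS[substitution]
    name, components = rule["derived"]
    data = prepare_connection_table(table)
    missing = [c for c in components if c not in data.columns]
    if missing:
        raise DataError(f"cannot derive {name}: missing {missing}")
    data[name] = sum(data[c] for c in components)
    if float(data[name].std()) == 0.0:
        raise DataError(f"derived covariate {name} is constant")
    replaced = set(rule["replaces"])
    new_blocks = []
    for block in spec.blocks:
        nb = tuple(
            dict.fromkeys(name if v in replaced else v for v in block)
        )
        if nb not in new_blocks:
            new_blocks.append(nb)
    new_spec = replace(spec, blocks=tuple(new_blocks))
    result = reduce_model(data, new_spec, reml=reml)
    result.control_tag = substitution
    return result
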