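"""Menzerath-Altmann law fitting: nonlinear, simple and complex models.

The law relates constituent size to construct size as ``y = a x^b e^{cx}``
(here: call duration y against sequence length x).  On the log scale it is
linear, ``ln y = ln a + b ln x + c x``, and with c = 0 it reduces to the
log-log regression used throughout the animal-communication literature.

Model hierarchy (all Gaussian, response = ln call duration, using the
full distribution of call durations rather than sequence means):

* simple    — ln(length) fixed effect, nested random intercepts for
              individual and sequence-within-individual; fitted per
              subspecies.
* complex A — adds sex, group size, age, Elo and CSI main effects, with
              nested random intercepts population/group/individual/sequence.
* complex B — adds ln(length) x covariate interactions.
* complex C — adds a nested random slope on ln(length) per
              population:group:individual (no intercept at that level).

The three complex forms are nested, so they are compared by AIC and
likelihood-ratio tests under ML.  Estimates are reported with 95% Wald
intervals; an interval excluding zero is flagged a strong effect.

The simple model's likelihood is profiled in closed form over the fixed
effects and the residual variance, leaving a bounded 2-parameter
optimisation over the variance ratios; this makes a study-scale fit run
in milliseconds, which the parameter-recovery simulations rely on.  The
complex models go through statsmodels MixedLM with variance components.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

Z_95 = float(stats.norm.ppf(0.975))  # 1.959964...

CONTINUOUS_COVARIATES = ("group_size", "age", "elo", "csi")
COMPLEX_FORMS = ("eq4", "eq5", "eq6")


class UnderdeterminedError(ValueError):
    """Too few distinct predictor values to identify the model."""


@dataclass(frozen=True)
class MenzerathParams:
    """Parameters of ``y = a x^b e^{cx}``."""

    a: float
    b: float
    c: float = 0.0

    def __post_init__(self) -> None:
        if not self.a > 0:
            raise ValueError(f"scale parameter a must be positive, got {self.a}")

    def curve(self, x: np.ndarray | float) -> np.ndarray | float:
        x = np.asarray(x, dtype=float)
        return self.a * x**self.b * np.exp(self.c * x)


@dataclass(frozen=True)
class ModelSpec:
    """Which model form was fitted, and with what structure."""

    form: str  # simple | eq4 | eq5 | eq6
    covariates: tuple[str, ...] = ()
    interactions: bool = False
    random_slope: bool = False

    @property
    def is_nested_in(self) -> Callable[["ModelSpec"], bool]:
        order = {"eq4": 0, "eq5": 1, "eq6": 2}

        def check(other: "ModelSpec") -> bool:
            return (
                self.form in order
                and other.form in order
                and order[self.form] < order[other.form]
            )

        return check


@dataclass
class ModelFit:
    """A fitted model: estimates with Wald CIs, variances, loglik, AIC."""

    spec: ModelSpec
    estimates: dict[str, tuple[float, float, float, float]]  # point, se, lo, hi
    variance_components: dict[str, float]
    loglik: float
    n_params: int
    n_obs: int
    n_groups: dict[str, int]
    estimation_method: str = "ML"
    converged: bool = True
    scaling: dict[str, tuple[float, float]] = field(default_factory=dict)
    covariate_ranges: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def aic(self) -> float:
        return 2.0 * self.n_params - 2.0 * self.loglik

    def strong_effects(self) -> dict[str, bool]:
        """Terms whose 95% Wald interval excludes zero."""
        return {
            term: not (lo <= 0.0 <= hi)
            for term, (point, se, lo, hi) in self.estimates.items()
        }


def _wald(point: float, se: float) -> tuple[float, float, float, float]:
    return (point, se, point - Z_95 * se, point + Z_95 * se)


# ---------------------------------------------------------------------------
# Eq 1 / Eq 2: the law itself


def fit_menzerath_nonlinear(
    x: Sequence[float],
    y: Sequence[float],
    fix_c: bool = False,
) -> MenzerathParams:
    """Least-squares fit of ``y = a x^b e^{cx}`` on the log scale.

    ``ln y = ln a + b ln x + c x`` is linear in (ln a, b, c), so the fit
    is exact ordinary least squares; with ``fix_c`` the c x term is
    dropped, recovering the log-log linear form of the law.  Noiseless
    data generated from the law is recovered exactly.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any(y <= 0) or np.any(x <= 0):
        raise ValueError("durations and lengths must be positive")
    needed = 2 if fix_c else 3
    if len(np.unique(x)) < needed:
        raise UnderdeterminedError(
            f"need at least {needed} distinct lengths, got {len(np.unique(x))}"
        )
    cols = [np.ones_like(x), np.log(x)]
    if not fix_c:
        cols.append(x)
    design = np.column_stack(cols)
    coef, *_ = np.linalg.lstsq(design, np.log(y), rcond=None)
    return MenzerathParams(
        a=float(np.exp(coef[0])),
        b=float(coef[1]),
        c=0.0 if fix_c else float(coef[2]),
    )


# ---------------------------------------------------------------------------
# profiled ML for the simple model
#
# Two nested random intercepts (individual, sequence-in-individual) give a
# block covariance that inverts in closed form via per-sequence sums, so
# the likelihood is evaluated in O(n) and only the two variance ratios
# lambda = tau^2 / sigma^2 are optimised numerically.


class _NestedData:
    """Per-sequence sufficient statistics for the nested-intercept model."""

    def __init__(self, y: np.ndarray, X: np.ndarray, ind: np.ndarray, seq: np.ndarray):
        # codes: sequences nested in individuals; sort once
        seq_codes, seq_first = pd.factorize(pd.unique(seq))  # noqa: F841
        seq_idx = pd.factorize(seq)[0]
        ind_idx = pd.factorize(ind)[0]
        order = np.lexsort((seq_idx,))
        self.y = y
        self.X = X
        self.n, self.p = X.shape
        self.seq_idx = seq_idx
        self.n_seq = seq_idx.max() + 1
        self.n_s = np.bincount(seq_idx, minlength=self.n_seq).astype(float)
        # individual owning each sequence
        ind_of_seq = np.zeros(self.n_seq, dtype=int)
        ind_of_seq[seq_idx] = ind_idx
        self.ind_of_seq = ind_of_seq
        self.n_ind = ind_idx.max() + 1
        self.Sy = np.bincount(seq_idx, weights=y, minlength=self.n_seq)
        self.Sx = np.column_stack(
            [np.bincount(seq_idx, weights=X[:, j], minlength=self.n_seq) for j in range(self.p)]
        )
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)

    def profiled(self, lam_ind: float, lam_seq: float):
        """GLS pieces and log-determinant at the given variance ratios."""
        d = 1.0 + lam_seq * self.n_s  # per-sequence shrink denominators
        w = lam_seq / d
        A = self.XtX - np.einsum("s,si,sj->ij", w, self.Sx, self.Sx)
        b = self.Xty - self.Sx.T @ (w * self.Sy)
        yy = self.yty - float(w @ self.Sy**2)
        # individual level via Woodbury on the all-ones direction
        h = np.bincount(self.ind_of_seq, weights=self.n_s / d, minlength=self.n_ind)
        Ty = np.bincount(self.ind_of_seq, weights=self.Sy / d, minlength=self.n_ind)
        Tx = np.column_stack(
            [
                np.bincount(self.ind_of_seq, weights=self.Sx[:, j] / d, minlength=self.n_ind)
                for j in range(self.p)
            ]
        )
        gamma = lam_ind / (1.0 + lam_ind * h)
        A -= np.einsum("g,gi,gj->ij", gamma, Tx, Tx)
        b -= Tx.T @ (gamma * Ty)
        yy -= float(gamma @ Ty**2)
        logdet = float(np.sum(np.log(d))) + float(np.sum(np.log1p(lam_ind * h)))
        return A, b, yy, logdet

    def neg_loglik(self, lam: np.ndarray) -> float:
        A, b, yy, logdet = self.profiled(lam[0], lam[1])
        try:
            beta = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            return np.inf
        rss = yy - 2.0 * beta @ b + beta @ A @ beta
        if rss <= 0:
            return np.inf
        sigma2 = rss / self.n
        return 0.5 * (self.n * np.log(2.0 * np.pi * sigma2) + logdet + self.n)


def fit_simple(
    frame: pd.DataFrame,
    force_zero_variances: bool = False,
    method: str = "ML",
) -> ModelFit:
    """Fit ln(duration) ~ ln(length) with nested random intercepts.

    ``frame`` must have one row per call with columns ``duration_s``,
    ``length``, ``individual``, ``sequence_id``; single-call sequences
    are expected to have been excluded already.  Estimation is maximum
    likelihood (profiled in closed form; see module docstring).  With
    ``force_zero_variances`` both random-effect variances are pinned at
    zero and the fit reduces exactly to ordinary least squares — used as
    an internal consistency check.
    """
    if method != "ML":
        raise NotImplementedError("only ML estimation is implemented for the simple model")
    if (frame["length"] < 2).any():
        raise ValueError("single-call sequences must be excluded before fitting")
    y = np.log(frame["duration_s"].to_numpy(dtype=float))
    lnx = np.log(frame["length"].to_numpy(dtype=float))
    X = np.column_stack([np.ones_like(lnx), lnx])
    ind = frame["individual"].to_numpy()
    seq = frame["sequence_id"].to_numpy()
    data = _NestedData(y, X, ind, seq)
    if data.n_ind < 2:
        warnings.warn(
            "only one individual: individual-level variance is unidentifiable "
            "and will be pinned at the boundary",
            stacklevel=2,
        )

    if force_zero_variances:
        lam_hat = np.array([0.0, 0.0])
        converged = True
    else:
        results = [
            optimize.minimize(
                data.neg_loglik,
                np.asarray(start),
                method="L-BFGS-B",
                bounds=[(0.0, None), (0.0, None)],
                options={"ftol": 1e-12, "gtol": 1e-10, "maxiter": 500},
            )
            for start in ([0.3, 0.3], [1.0, 0.1], [0.01, 1.0])
        ]
        best = min(results, key=lambda r: r.fun)
        lam_hat = best.x
        # a line-search hiccup in one start is fine if another start
        # confirms the same optimum
        converged = any(r.success and r.fun <= best.fun + 1e-6 for r in results)

    A, b, yy, _ = data.profiled(lam_hat[0], lam_hat[1])
    beta = np.linalg.solve(A, b)
    rss = yy - 2.0 * beta @ b + beta @ A @ beta
    sigma2 = rss / data.n
    cov_beta = sigma2 * np.linalg.inv(A)
    ses = np.sqrt(np.diag(cov_beta))
    loglik = -data.neg_loglik(lam_hat)

    estimates = {
        "Intercept": _wald(float(beta[0]), float(ses[0])),
        "Length": _wald(float(beta[1]), float(ses[1])),
    }
    return ModelFit(
        spec=ModelSpec(form="simple"),
        estimates=estimates,
        variance_components={
            "individual": float(lam_hat[0] * sigma2),
            "sequence": float(lam_hat[1] * sigma2),
            "residual": float(sigma2),
        },
        loglik=float(loglik),
        n_params=2 + 3,  # intercept, slope, two variances, residual
        n_obs=int(data.n),
        n_groups={"individual": int(data.n_ind), "sequence": int(data.n_seq)},
        estimation_method="ML",
        converged=converged,
    )


# ---------------------------------------------------------------------------
# general hierarchical fitter
#
# The complex models add two more nested intercept levels (group,
# population) and, in the richest form, an individual-level random slope
# on ln(length).  Because every random term is either a nested intercept
# or a slope sharing the individual grouping, V / sigma^2 can be inverted
# by applying Woodbury updates level by level (sequence, then a rank-2
# block per individual for intercept+slope, then group, then population),
# so one likelihood evaluation costs O(n) regardless of the number of
# sequences.  Fixed effects and the residual variance are profiled out in
# closed form; only the variance ratios are optimised numerically.


class _HierarchicalLMM:
    """Profiled ML for nested intercepts pop/group/individual/sequence
    plus an optional individual-level random slope on ``slope_var``."""

    def __init__(
        self,
        y: np.ndarray,
        X: np.ndarray,
        codes: Mapping[str, np.ndarray],  # pop, grp, ind, seq integer codes
        slope_var: np.ndarray | None = None,
    ):
        self.n, self.p = X.shape
        self.y = y
        self.X = X
        self.codes = {k: np.asarray(v) for k, v in codes.items()}
        self.slope_var = slope_var
        ones = np.ones(self.n)
        cols = [X, y[:, None], ones[:, None]]
        self.c_ones = self.p + 1
        if slope_var is not None:
            cols.append(slope_var[:, None])
            self.c_slope = self.p + 2
        self.R = np.column_stack(cols)
        self.n_levels = {k: int(v.max()) + 1 for k, v in self.codes.items()}
        self.has_slope = slope_var is not None
        self.n_lam = 4 + (1 if self.has_slope else 0)

    def _v0inv_R(self, lam: np.ndarray) -> tuple[np.ndarray, float]:
        """Apply (V/sigma^2)^-1 to [X | y | 1 | slope]; return it and logdet."""
        lam_pop, lam_grp, lam_ind, lam_seq = lam[:4]
        lam_slope = lam[4] if self.has_slope else 0.0
        A = self.R.copy()
        logdet = 0.0

        # sequence intercepts: rank-1 per sequence on the ones direction
        seq = self.codes["seq"]
        n_s = np.bincount(seq).astype(float)
        if lam_seq > 0:
            shrink = lam_seq / (1.0 + lam_seq * n_s)
            sums = np.zeros((len(n_s), A.shape[1]))
            np.add.at(sums, seq, A)
            A -= shrink[seq, None] * sums[seq, :]
            logdet += float(np.sum(np.log1p(lam_seq * n_s)))

        # individual level: intercept (+ slope) low-rank block per individual
        ind = self.codes["ind"]
        n_ind = self.n_levels["ind"]
        if self.has_slope:
            W = np.column_stack([A[:, self.c_ones], A[:, self.c_slope]])  # M^-1 W
            C = np.column_stack([np.ones(self.n), self.slope_var])
            Lam = np.diag([lam_ind, lam_slope])
            q = 2
        else:
            W = A[:, [self.c_ones]]
            C = np.ones((self.n, 1))
            Lam = np.array([[lam_ind]])
            q = 1
        if lam_ind > 0 or (self.has_slope and lam_slope > 0):
            # K_i = W_i' M^-1 W_i, T_i = W_i' M^-1 R via per-individual sums
            K = np.zeros((n_ind, q, q))
            np.add.at(K, ind, C[:, :, None] * W[:, None, :])
            T = np.zeros((n_ind, q, A.shape[1]))
            np.add.at(T, ind, C[:, :, None] * A[:, None, :])
            Q = np.empty_like(T)
            for i in range(n_ind):
                IKL = np.eye(q) + K[i] @ Lam
                logdet += float(np.log(np.linalg.det(IKL)))
                Q[i] = Lam @ np.linalg.solve(IKL, T[i])
            A -= np.einsum("nk,nkj->nj", W, Q[ind])

        # group and population: rank-1 on the ones direction
        for lam_level, key in ((lam_grp, "grp"), (lam_pop, "pop")):
            if lam_level <= 0:
                continue
            code = self.codes[key]
            u = A[:, self.c_ones].copy()
            h = np.bincount(code, weights=u, minlength=self.n_levels[key])
            sums = np.zeros((self.n_levels[key], A.shape[1]))
            np.add.at(sums, code, A)
            gamma = lam_level / (1.0 + lam_level * h)
            A -= u[:, None] * (gamma[:, None] * sums)[code, :]
            logdet += float(np.sum(np.log1p(lam_level * h)))
        return A, logdet

    def _gls(self, lam: np.ndarray):
        A, logdet = self._v0inv_R(lam)
        G = self.R.T @ A  # R' V0^-1 R
        XtVX = G[: self.p, : self.p]
        XtVy = G[: self.p, self.p]
        ytVy = G[self.p, self.p]
        beta = np.linalg.solve(XtVX, XtVy)
        rss = ytVy - beta @ XtVy
        return beta, XtVX, rss, logdet

    def neg_loglik(self, lam: np.ndarray) -> float:
        try:
            beta, _, rss, logdet = self._gls(lam)
        except np.linalg.LinAlgError:
            return np.inf
        if rss <= 0 or not np.isfinite(rss):
            return np.inf
        sigma2 = rss / self.n
        return 0.5 * (self.n * np.log(2.0 * np.pi * sigma2) + logdet + self.n)

    def fit(self, starts: Sequence[Sequence[float]] | None = None):
        if starts is None:
            base = [0.1] * self.n_lam
            starts = [base, [0.5] * self.n_lam, [0.02] * self.n_lam]
        results = [
            optimize.minimize(
                self.neg_loglik,
                np.asarray(s, dtype=float),
                method="L-BFGS-B",
                bounds=[(0.0, None)] * self.n_lam,
                options={"ftol": 1e-12, "gtol": 1e-10, "maxiter": 500},
            )
            for s in starts
        ]
        best = min(results, key=lambda r: r.fun)
        converged = any(r.success and r.fun <= best.fun + 1e-6 for r in results)
        lam = best.x
        beta, XtVX, rss, _ = self._gls(lam)
        sigma2 = rss / self.n
        cov_beta = sigma2 * np.linalg.inv(XtVX)
        return {
            "lam": lam,
            "beta": beta,
            "se": np.sqrt(np.diag(cov_beta)),
            "sigma2": float(sigma2),
            "loglik": float(-best.fun),
            "converged": bool(converged),
        }


# ---------------------------------------------------------------------------
# complex models


def _standardize(frame: pd.DataFrame, columns: Iterable[str]):
    scaled = frame.copy()
    scaling = {}
    for col in columns:
        mean = float(frame[col].mean())
        sd = float(frame[col].std(ddof=0))
        if sd == 0:
            raise ValueError(f"covariate {col!r} has zero variance")
        scaled[col] = (frame[col] - mean) / sd
        scaling[col] = (mean, sd)
    return scaled, scaling


def fit_complex(
    frame: pd.DataFrame,
    form: str = "eq6",
    standardize: bool = True,
) -> ModelFit:
    """Fit one of the three complex model forms on carrion-crow calls.

    ``frame`` needs per-call columns ``duration_s``, ``length``,
    ``population``, ``group``, ``individual``, ``sequence_id``, ``sex``
    (F/M) and the continuous covariates ``group_size``, ``age``, ``elo``,
    ``csi``.  Continuous covariates are z-scored by default (coefficients
    are then per-SD; the scaling is stored for back-transformation).
    Covariates with zero variance are dropped with an explicit warning.
    Fitted by ML so that AIC/LRT comparisons are valid.
    """
    if form not in COMPLEX_FORMS:
        raise ValueError(f"form must be one of {COMPLEX_FORMS}, got {form!r}")
    if (frame["length"] < 2).any():
        raise ValueError("single-call sequences must be excluded before fitting")

    df = frame.copy()
    df["lny"] = np.log(df["duration_s"].astype(float))
    df["lnlen"] = np.log(df["length"].astype(float))
    # composite labels realise the nesting
    df["pop"] = df["population"].astype(str)
    df["grp"] = df["pop"] + "/" + df["group"].astype(str)
    df["ind"] = df["grp"] + "/" + df["individual"].astype(str)
    df["seq"] = df["ind"] + "/" + df["sequence_id"].astype(str)
    df["sex_m"] = (df["sex"].astype(str) == "M").astype(float)  # F is reference

    covariates = []
    dropped = []
    if df["sex_m"].nunique() > 1:
        covariates.append("sex_m")
    else:
        dropped.append("sex")
    cont = []
    for col in CONTINUOUS_COVARIATES:
        if df[col].astype(float).std(ddof=0) > 0:
            cont.append(col)
            covariates.append(col)
        else:
            dropped.append(col)
    for name in dropped:
        warnings.warn(f"covariate {name!r} has zero variance; dropped from the model",
                      stacklevel=2)
    scaling = {}
    if standardize and cont:
        df, scaling = _standardize(df, cont)

    ranges = {c: (float(df[c].min()), float(df[c].max())) for c in covariates}

    rename = {"lnlen": "Length", "sex_m": "Sex (M vs. F)", "group_size": "Group Size",
              "age": "Age", "elo": "ELO", "csi": "CSI"}
    y = df["lny"].to_numpy(dtype=float)
    lnlen = df["lnlen"].to_numpy(dtype=float)
    cols = [np.ones_like(y), lnlen]
    names = ["Intercept", "Length"]
    for cov_name in covariates:
        cols.append(df[cov_name].to_numpy(dtype=float))
        names.append(rename[cov_name])
    if form in ("eq5", "eq6"):
        for cov_name in covariates:
            cols.append(lnlen * df[cov_name].to_numpy(dtype=float))
            names.append(f"Length: {rename[cov_name]}")
    X = np.column_stack(cols)

    codes = {
        key: pd.factorize(df[col])[0]
        for key, col in (("pop", "pop"), ("grp", "grp"), ("ind", "ind"), ("seq", "seq"))
    }
    model = _HierarchicalLMM(
        y, X, codes, slope_var=lnlen if form == "eq6" else None
    )
    result = model.fit()

    estimates = {
        name: _wald(float(b), float(se))
        for name, b, se in zip(names, result["beta"], result["se"])
    }
    sigma2 = result["sigma2"]
    lam = result["lam"]
    vcomp = {
        "population": float(lam[0] * sigma2),
        "group": float(lam[1] * sigma2),
        "individual": float(lam[2] * sigma2),
        "sequence": float(lam[3] * sigma2),
        "residual": float(sigma2),
    }
    if form == "eq6":
        vcomp["individual_slope"] = float(lam[4] * sigma2)

    n_params = X.shape[1] + len(lam) + 1  # fixed effects + variances + residual
    spec = ModelSpec(
        form=form,
        covariates=tuple(covariates),
        interactions=form in ("eq5", "eq6"),
        random_slope=form == "eq6",
    )
    return ModelFit(
        spec=spec,
        estimates=estimates,
        variance_components=vcomp,
        loglik=result["loglik"],
        n_params=n_params,
        n_obs=int(len(df)),
        n_groups={
            "population": int(df["pop"].nunique()),
            "group": int(df["grp"].nunique()),
            "individual": int(df["ind"].nunique()),
            "sequence": int(df["seq"].nunique()),
        },
        estimation_method="ML",
        converged=result["converged"],
        scaling=scaling,
        covariate_ranges=ranges,
    )


# ---------------------------------------------------------------------------
# model comparison


def likelihood_ratio_test(small: ModelFit, big: ModelFit) -> tuple[float, int, float]:
    """LRT statistic, df and p-value for a nested pair fitted by ML."""
    if small.estimation_method != "ML" or big.estimation_method != "ML":
        raise ValueError("LRT requires ML fits")
    if small.n_obs != big.n_obs:
        raise ValueError("LRT requires fits on identical data rows")
    if not small.spec.is_nested_in(big.spec):
        raise ValueError(
            f"{small.spec.form} is not nested in {big.spec.form}; LRT refused"
        )
    statistic = 2.0 * (big.loglik - small.loglik)
    df = big.n_params - small.n_params
    p = float(stats.chi2.sf(max(statistic, 0.0), df)) if df > 0 else float("nan")
    return float(statistic), int(df), p


def compare_models(fits: Sequence[ModelFit]) -> pd.DataFrame:
    """AIC table with ΔAIC, best-model flag and LRTs for nested pairs.

    The best model is the one with the lowest AIC; it is only flagged a
    clear winner when ΔAIC to the runner-up exceeds 2.
    """
    if len({f.n_obs for f in fits}) != 1:
        raise ValueError("model comparison requires fits on identical data rows")
    rows = []
    best_aic = min(f.aic for f in fits)
    aics = sorted(f.aic for f in fits)
    decisive = len(aics) < 2 or (aics[1] - aics[0]) > 2.0
    for i, fit in enumerate(fits):
        row = {
            "model": fit.spec.form,
            "loglik": fit.loglik,
            "n_params": fit.n_params,
            "AIC": fit.aic,
            "dAIC": fit.aic - best_aic,
            "best": bool(fit.aic == best_aic and decisive),
            "LRT_vs": "",
            "LRT_stat": np.nan,
            "LRT_df": np.nan,
            "LRT_p": np.nan,
        }
        for other in fits:
            if other.spec.is_nested_in(fit.spec) and (
                row["LRT_vs"] == "" or other.n_params > [
                    f for f in fits if f.spec.form == row["LRT_vs"]
                ][0].n_params
            ):
                statistic, df, p = likelihood_ratio_test(other, fit)
                row.update(LRT_vs=other.spec.form, LRT_stat=statistic, LRT_df=df, LRT_p=p)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# prediction


def predict_curves(
    fit: ModelFit,
    profile: Mapping[str, float | str] | None = None,
    lengths: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Predicted duration vs sequence length for a covariate profile.

    Covariates absent from ``profile`` sit at their reference level (sex
    F) or mean (continuous, i.e. 0 after z-scoring).  Continuous profile
    values are given on the original scale and standardized internally;
    values outside the observed range trigger an extrapolation warning.
    Returns a frame with columns length, ln_length, predicted_duration
    and the effective slope of the profile.
    """
    profile = dict(profile or {})
    lengths = np.asarray(lengths if lengths is not None else np.arange(2, 11))

    def get(term: str) -> float:
        return fit.estimates[term][0] if term in fit.estimates else 0.0

    slope = get("Length")
    level = get("Intercept")
    sex = profile.pop("sex", "F")
    if str(sex) == "M":
        level += get("Sex (M vs. F)")
        slope += get("Length: Sex (M vs. F)")
    pretty = {"group_size": "Group Size", "age": "Age", "elo": "ELO", "csi": "CSI"}
    for name, value in profile.items():
        if name not in pretty:
            raise KeyError(f"unknown covariate {name!r}")
        z = float(value)
        if name in fit.scaling:
            mean, sd = fit.scaling[name]
            z = (z - mean) / sd
        if name in fit.covariate_ranges:
            lo, hi = fit.covariate_ranges[name]
            if not lo <= z <= hi:
                warnings.warn(
                    f"profile value for {name!r} lies outside the observed "
                    f"range; prediction is an extrapolation",
                    stacklevel=2,
                )
        level += get(pretty[name]) * z
        slope += get(f"Length: {pretty[name]}") * z

    lnx = np.log(lengths.astype(float))
    pred = np.exp(level + slope * lnx)
    return pd.DataFrame(
        {
            "length": lengths,
            "ln_length": lnx,
            "predicted_duration": pred,
            "effective_slope": slope,
        }
    )
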