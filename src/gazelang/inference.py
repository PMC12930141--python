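"""Association model between scan-pattern similarity and sentence similarity.

The response is the pairwise scan-pattern similarity; fixed effects are
Semantics (semantic similarity), Syntax (tree-kernel similarity), Language
(same vs different; reference different), Scene (same vs different;
reference different/between) and Phase (during vs before; reference
before), with all interactions up to the five-way term. Random intercepts
are fitted for the three unordered grouping keys: participant pair, item
pair and cue pair.

Estimation is maximum likelihood (not REML, for comparability of
fixed-effect tests) of the linear mixed model

    y = X beta + sum_k Z_k u_k + e,   u_k ~ N(0, s2 g_k I),  e ~ N(0, s2 I)

with the variance ratios g_k profiled: for fixed g the GLS estimate of
beta and the ML estimate of s2 are closed-form via the Woodbury identity
on the q x q system (q = total number of random-intercept levels), so the
optimizer works in only three log-variance-ratio parameters. This keeps a
fit on hundreds of thousands of rows in the seconds range. Inference on
the fixed effects uses asymptotic Wald statistics (t = beta/se, 95% CI),
conditional on the estimated variance ratios, as mixed-model software
conventionally reports them.

Standardized coefficients come from an identical refit on z-scored
continuous variables (response included) with the binary factors coded
-0.5/+0.5.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.optimize
import scipy.sparse

from .errors import ConvergenceError, DataError

logger = logging.getLogger(__name__)

Z975 = 1.959963984540054

BASE_TERMS = ("Semantics", "Syntax", "Language", "Scene", "Phase")
TERM_COLUMNS = {
    "Semantics": "sem_sim",
    "Syntax": "syn_sim",
    "Language": "same_language",
    "Scene": "same_scene",
    "Phase": "phase",
}


@dataclass(frozen=True)
class ModelSpec:
    """Fixed- and random-effect structure of the association model."""

    response: str = "scan_sim"
    max_order: int = 5
    random_factors: tuple[str, ...] = ("participant_pair", "item_pair", "cue_pair")


@dataclass
class ModelFit:
    """Fitted association model: coefficient table, variance components, diagnostics."""

    terms: list[str]
    beta: np.ndarray
    se: np.ndarray
    std_beta: np.ndarray
    cov_beta: np.ndarray
    variance_components: dict[str, float]
    residual_variance: float
    loglik: float
    n: int
    converged: bool
    boundary: bool
    dropped_terms: list[str] = field(default_factory=list)
    spec: ModelSpec = field(default_factory=ModelSpec)

    @property
    def t_values(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.se > 0, self.beta / self.se, 0.0)

    @property
    def ci_low(self) -> np.ndarray:
        return self.beta - Z975 * self.se

    @property
    def ci_high(self) -> np.ndarray:
        return self.beta + Z975 * self.se

    def summary(self) -> pd.DataFrame:
        """Coefficient table: beta, standardized beta, 95% CI, t."""
        return pd.DataFrame(
            {
                "term": self.terms,
                "beta": self.beta,
                "std_beta": self.std_beta,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "t_value": self.t_values,
            }
        )

    def coef(self, term: str) -> float:
        return float(self.beta[self.terms.index(term)])

    def linear_combination(self, weights: Mapping[str, float]) -> tuple[float, float, float, float]:
        """Estimate, se and Wald 95% CI of a linear combination of terms.

        Terms absent from the fitted model (dropped or never built)
        contribute nothing.
        """
        w = np.zeros(len(self.terms))
        for term, weight in weights.items():
            if term in self.terms:
                w[self.terms.index(term)] = weight
        est = float(w @ self.beta)
        se = float(np.sqrt(max(w @ self.cov_beta @ w, 0.0)))
        return est, se, est - Z975 * se, est + Z975 * se

    def slope_by_phase(self, term: str = "Semantics") -> dict[str, tuple[float, float, float]]:
        """Per-phase slope of a continuous predictor at reference factor levels.

        BEFORE: the main effect; DURING: main effect + term x Phase
        interaction. Returns {phase: (estimate, ci_low, ci_high)}.
        """
        before = self.linear_combination({term: 1.0})
        during = self.linear_combination({term: 1.0, f"{term} x Phase": 1.0})
        return {
            "before": (before[0], before[2], before[3]),
            "during": (during[0], during[2], during[3]),
        }

    def predict(self, pair_table: pd.DataFrame) -> np.ndarray:
        """Population-level predictions (X beta) for pair-table rows."""
        X, names = build_design(pair_table, self.spec)
        keep = [names.index(t) for t in self.terms]
        return X[:, keep] @ self.beta


# ---------------------------------------------------------------------------
# Design matrix
# ---------------------------------------------------------------------------


def model_terms(max_order: int = 5) -> list[tuple[str, ...]]:
    """Interaction structure: all subsets of the base terms up to max_order."""
    out = []
    for order in range(1, max_order + 1):
        out.extend(itertools.combinations(range(len(BASE_TERMS)), order))
    return [tuple(BASE_TERMS[i] for i in combo) for combo in out]


def term_name(combo: tuple[str, ...]) -> str:
    return " x ".join(combo)


def build_design(
    pair_table: pd.DataFrame,
    spec: ModelSpec | None = None,
    standardized: bool = False,
) -> tuple[np.ndarray, list[str]]:
    """Design matrix with intercept and all interaction columns.

    Treatment coding (0 = reference: different language, different scene,
    before phase) for the headline fit; ``standardized=True`` z-scores the
    continuous predictors and codes the factors -0.5/+0.5.
    """
    if spec is None:
        spec = ModelSpec()
    base = {}
    base["Semantics"] = pair_table["sem_sim"].to_numpy(dtype=float)
    base["Syntax"] = pair_table["syn_sim"].to_numpy(dtype=float)
    base["Language"] = pair_table["same_language"].to_numpy(dtype=float)
    base["Scene"] = pair_table["same_scene"].to_numpy(dtype=float)
    phase = pair_table["phase"].astype(str).str.lower().eq("during").to_numpy(dtype=float)
    base["Phase"] = phase
    if standardized:
        for key in ("Semantics", "Syntax"):
            v = base[key]
            sd = v.std(ddof=0)
            base[key] = (v - v.mean()) / sd if sd > 0 else v - v.mean()
        for key in ("Language", "Scene", "Phase"):
            base[key] = base[key] - 0.5
    combos = model_terms(spec.max_order)
    n = len(pair_table)
    cols = [np.ones(n)]
    names = ["(Intercept)"]
    for combo in combos:
        col = np.ones(n)
        for t in combo:
            col = col * base[t]
        cols.append(col)
        names.append(term_name(combo))
    return np.column_stack(cols), names


# ---------------------------------------------------------------------------
# Profiled-ML fitter for crossed random intercepts
# ---------------------------------------------------------------------------


@dataclass
class _MLParts:
    beta: np.ndarray
    cov_beta: np.ndarray
    sigma2: float
    gammas: np.ndarray
    loglik: float
    converged: bool
    boundary: bool


def _profiled_ml(
    y: np.ndarray,
    X: np.ndarray,
    factor_codes: Sequence[np.ndarray],
    factor_sizes: Sequence[int],
) -> _MLParts:
    n, p = X.shape
    if not factor_codes:
        # plain OLS (no random factors): ML residual variance
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        sigma2 = float(resid @ resid) / n
        XtX = X.T @ X
        cov = sigma2 * np.linalg.pinv(XtX)
        ll = -0.5 * (n * np.log(2 * np.pi * max(sigma2, 1e-300)) + n)
        return _MLParts(beta, cov, sigma2, np.zeros(0), ll, True, False)

    blocks = []
    for codes, size in zip(factor_codes, factor_sizes):
        data = np.ones(n)
        blocks.append(
            scipy.sparse.csr_matrix((data, (np.arange(n), codes)), shape=(n, size))
        )
    Z = scipy.sparse.hstack(blocks, format="csr")
    q_sizes = np.asarray(factor_sizes)
    q = int(q_sizes.sum())
    ZtZ = (Z.T @ Z).toarray()
    ZtX = Z.T @ X
    Zty = Z.T @ y
    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)
    block_ix = np.repeat(np.arange(len(factor_sizes)), q_sizes)

    def parts_at(theta: np.ndarray):
        gam = np.exp(theta)
        A = ZtZ + np.diag(1.0 / gam[block_ix])
        try:
            c, low = scipy.linalg.cho_factor(A, check_finite=False)
        except np.linalg.LinAlgError:
            return None
        logdetA = 2.0 * float(np.sum(np.log(np.diag(c))))
        AinvZtX = scipy.linalg.cho_solve((c, low), ZtX, check_finite=False)
        AinvZty = scipy.linalg.cho_solve((c, low), Zty, check_finite=False)
        XtVinvX = XtX - ZtX.T @ AinvZtX
        XtVinvy = Xty - ZtX.T @ AinvZty
        ytVinvy = yty - float(Zty @ AinvZty)
        try:
            beta = np.linalg.solve(XtVinvX, XtVinvy)
        except np.linalg.LinAlgError:
            beta, *_ = np.linalg.lstsq(XtVinvX, XtVinvy, rcond=None)
        rVr = max(ytVinvy - float(beta @ XtVinvy), 1e-12)
        sigma2 = rVr / n
        logdetV = logdetA + float(q_sizes @ theta)
        neg2ll = n * np.log(2 * np.pi * sigma2) + logdetV + n
        return neg2ll, beta, sigma2, XtVinvX

    def objective(theta: np.ndarray) -> float:
        res = parts_at(theta)
        return 1e12 if res is None else res[0]

    theta0 = np.full(len(factor_sizes), np.log(0.1))
    opt = scipy.optimize.minimize(
        objective,
        theta0,
        method="L-BFGS-B",
        bounds=[(-14.0, 8.0)] * len(factor_sizes),
        options={"maxiter": 200},
    )
    res = parts_at(opt.x)
    if res is None:
        raise ConvergenceError(
            "mixed-model likelihood evaluation failed at optimum",
            diagnostics={"message": str(opt.message)},
        )
    neg2ll, beta, sigma2, XtVinvX = res
    gammas = np.exp(opt.x)
    cov_beta = sigma2 * np.linalg.pinv(XtVinvX)
    boundary = bool(np.any(opt.x <= -13.5))
    return _MLParts(
        beta=beta,
        cov_beta=cov_beta,
        sigma2=sigma2,
        gammas=gammas,
        loglik=-0.5 * neg2ll,
        converged=bool(opt.success),
        boundary=boundary,
    )


def _independent_columns(X: np.ndarray) -> np.ndarray:
    """Indices of a maximal linearly independent, non-constant column subset."""
    keep = [0]  # intercept
    sds = X.std(axis=0)
    candidates = [j for j in range(1, X.shape[1]) if sds[j] > 0]
    for j in candidates:
        trial = keep + [j]
        if np.linalg.matrix_rank(X[:, trial]) == len(trial):
            keep.append(j)
    return np.array(keep)


def fit_association_model(
    pair_table: pd.DataFrame,
    spec: ModelSpec | None = None,
) -> ModelFit:
    """Fit the random-intercept association model on a long pair table.

    Constant or collinear fixed-effect columns (e.g. a single-language
    study) are dropped and reported in ``dropped_terms``. Variance
    components estimated at (numerically) zero set the ``boundary`` flag
    rather than triggering a refit.
    """
    if spec is None:
        spec = ModelSpec()
    df = pair_table.dropna(subset=[spec.response, "sem_sim", "syn_sim"])
    if len(df) == 0:
        raise DataError("empty pair table")
    y = df[spec.response].to_numpy(dtype=float)
    X, names = build_design(df, spec)

    factor_codes, factor_sizes = [], []
    for fac in spec.random_factors:
        codes, uniques = pd.factorize(df[fac])
        factor_codes.append(codes.astype(np.int64))
        factor_sizes.append(len(uniques))

    if np.ptp(y) == 0.0:
        # degenerate constant response: intercept = constant, all slopes 0
        p = X.shape[1]
        beta = np.zeros(p)
        beta[0] = y[0]
        vc = {f: 0.0 for f in spec.random_factors}
        return ModelFit(
            terms=names, beta=beta, se=np.zeros(p), std_beta=np.zeros(p),
            cov_beta=np.zeros((p, p)), variance_components=vc,
            residual_variance=0.0, loglik=np.inf, n=len(df),
            converged=True, boundary=True, spec=spec,
        )

    keep = _independent_columns(X)
    dropped = [names[j] for j in range(X.shape[1]) if j not in set(keep.tolist())]
    if dropped:
        logger.info("dropping rank-deficient/constant terms: %s", dropped)
    Xk = X[:, keep]
    kept_names = [names[j] for j in keep]

    fit = _profiled_ml(y, Xk, factor_codes, factor_sizes)

    # standardized refit: z-scored continuous variables, +/-0.5 factors
    sd_y = y.std(ddof=0)
    ys = (y - y.mean()) / sd_y
    Xs, _ = build_design(df, spec, standardized=True)
    fit_s = _profiled_ml(ys, Xs[:, keep], factor_codes, factor_sizes)

    se = np.sqrt(np.clip(np.diag(fit.cov_beta), 0.0, None))
    vc = {
        fac: float(fit.sigma2 * g)
        for fac, g in zip(spec.random_factors, fit.gammas)
    }
    return ModelFit(
        terms=kept_names,
        beta=fit.beta,
        se=se,
        std_beta=fit_s.beta,
        cov_beta=fit.cov_beta,
        variance_components=vc,
        residual_variance=float(fit.sigma2),
        loglik=float(fit.loglik),
        n=len(df),
        converged=fit.converged and fit_s.converged,
        boundary=fit.boundary,
        dropped_terms=dropped,
        spec=spec,
    )


# ---------------------------------------------------------------------------
# Descriptive summaries
# ---------------------------------------------------------------------------


def binned_summary(
    pair_table: pd.DataFrame,
    predictor: str = "sem_sim",
    bin_width: float = 0.1,
) -> pd.DataFrame:
    """Mean scan similarity over regular predictor bins, per stratum.

    The predictor is min-max rescaled to [0, 1] per study when it exceeds
    that range (dot products are unbounded); bins cover [0, 1) in
    ``bin_width`` steps with the final bin closed. Strata are
    Scene x Language x Phase; empty bins are omitted. The output carries
    ``rescaled`` metadata in ``DataFrame.attrs``.
    """
    df = pair_table.dropna(subset=["scan_sim", predictor]).copy()
    v = df[predictor].to_numpy(dtype=float)
    rescaled = False
    if len(v) and (v.min() < 0 or v.max() > 1):
        span = v.max() - v.min()
        v = (v - v.min()) / span if span > 0 else np.zeros_like(v)
        rescaled = True
    n_bins = int(round(1.0 / bin_width))
    ix = np.clip((v / bin_width).astype(int), 0, n_bins - 1)
    df["_bin"] = ix
    grouped = df.groupby(["same_scene", "same_language", "phase", "_bin"], observed=True)
    out = grouped["scan_sim"].agg(n="count", mean_scan_sim="mean", sd="std").reset_index()
    out["se"] = out["sd"] / np.sqrt(out["n"])
    out["bin_low"] = out["_bin"] * bin_width
    out["bin_high"] = out["bin_low"] + bin_width
    out = out.drop(columns=["_bin", "sd"])
    out = out[
        ["same_scene", "same_language", "phase", "bin_low", "bin_high",
         "n", "mean_scan_sim", "se"]
    ]
    out.attrs["rescaled"] = rescaled
    out.attrs["predictor"] = predictor
    return out


def similarity_correlation(pair_table: pd.DataFrame) -> dict[str, float]:
    """Pearson correlation of semantic vs syntactic similarity by language stratum.

    Computed over unique trial pairs (the two phase records of a pair share
    their sentence similarities). Zero-variance strata yield NaN with a
    ``*_undefined`` flag.
    """
    uniq = pair_table.drop_duplicates(subset=["trial_id_1", "trial_id_2"])
    out: dict[str, float] = {}
    for label, mask in (
        ("within_language", uniq["same_language"].to_numpy()),
        ("between_language", ~uniq["same_language"].to_numpy()),
    ):
        sub = uniq.loc[mask, ["sem_sim", "syn_sim"]].dropna()
        if len(sub) < 3 or sub["sem_sim"].std() == 0 or sub["syn_sim"].std() == 0:
            out[label] = float("nan")
            out[label + "_undefined"] = True
        else:
            out[label] = float(np.corrcoef(sub["sem_sim"], sub["syn_sim"])[0, 1])
    return out


def phase_association(
    pair_table: pd.DataFrame,
    predictor: str = "syn_sim",
    within_language_only: bool = True,
) -> dict[str, float]:
    """Raw per-phase Pearson association between a predictor and scan similarity."""
    df = pair_table
    if within_language_only:
        df = df[df["same_language"]]
    out = {}
    for phase, sub in df.groupby("phase"):
        sub = sub[["scan_sim", predictor]].dropna()
        if len(sub) < 3 or sub[predictor].std() == 0 or sub["scan_sim"].std() == 0:
            out[str(phase)] = float("nan")
        else:
            out[str(phase)] = float(np.corrcoef(sub[predictor], sub["scan_sim"])[0, 1])
    return out
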