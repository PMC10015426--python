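"""Empirical response surfaces over ink composition and printing pressure.

Rheological and printability yields are modeled as polynomials (quadratic
plus two-way interactions by default) of factors A (alginate mg/mL),
B (hyaluronic acid mg/mL), C (extrusion pressure kPa) and, for the angle
fidelity factor only, D (printed angle, degrees).  Terms are selected by
backward elimination under ANOVA t-tests at ``alpha = 0.1``, preserving
model hierarchy; the model as a whole is flagged significant at p <= 0.05.
Residuals may be normalized by a Box-Cox transform chosen by profile
likelihood; predictions carry 95% bands on the original scale.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "FACTOR_COLUMNS",
    "Transform",
    "FittedSurface",
    "PredictionBand",
    "full_terms",
    "term_parents",
    "correlation_matrix",
    "choose_transform",
    "fit_rsm",
    "predict_with_band",
    "significance_stars",
]

FACTOR_COLUMNS = {
    "A": "alginate_mg_ml",
    "B": "ha_mg_ml",
    "C": "pressure_kPa",
    "D": "angle_deg",
}
_COLUMN_FACTORS = {v: k for k, v in FACTOR_COLUMNS.items()}


def significance_stars(p: float) -> str:
    """ANOVA significance legend: *** <=0.001, ** <=0.01, * <=0.05, . <=0.1."""
    for thr, mark in ((0.001, "***"), (0.01, "**"), (0.05, "*"), (0.1, ".")):
        if p <= thr:
            return mark
    return ""


# --------------------------------------------------------------------------
# terms


def full_terms(factors, max_order: int = 2) -> list:
    """Candidate monomials: intercept, linear, two-way interactions, squares."""
    factors = list(factors)
    terms = ["1"] + factors
    if max_order >= 2:
        terms += [f"{a}:{b}" for a, b in itertools.combinations(factors, 2)]
        terms += [f"{f}^2" for f in factors]
    return terms


def term_parents(term: str) -> set:
    """Hierarchy parents: A:B -> {A, B}; A^2 -> {A}; linear terms -> {}."""
    if term == "1" or (":" not in term and "^" not in term):
        return set()
    if "^" in term and ":" not in term:
        return {term.split("^")[0]}
    return set(term.split(":"))


def _term_column(term: str, cols: dict) -> np.ndarray:
    if term == "1":
        return np.ones_like(next(iter(cols.values())))
    out = None
    for part in term.split(":"):
        if "^" in part:
            fac, pw = part.split("^")
            val = cols[fac] ** int(pw)
        else:
            val = cols[part]
        out = val if out is None else out * val
    return out


def _monomial_key(parts: tuple) -> str:
    """Canonical term string for a product of factors, e.g. (A, A) -> A^2."""
    if not parts:
        return "1"
    out = []
    for f in sorted(set(parts)):
        n = parts.count(f)
        out.append(f if n == 1 else f"{f}^{n}")
    return ":".join(out)


def _uncenter_coefficients(terms, beta, centers: dict) -> np.ndarray:
    """Convert centered-basis coefficients to the raw monomial basis.

    Each centered term is a product of ``(x_f - c_f)`` factors; expanding the
    products redistributes weight onto lower-order terms, which hierarchy
    guarantees are present in ``terms``.
    """
    raw = dict.fromkeys(terms, 0.0)
    for term, b in zip(terms, beta):
        expansion = {(): 1.0}
        if term != "1":
            for part in term.split(":"):
                if "^" in part:
                    fac, pw = part.split("^")
                    factors_in_part = [fac] * int(pw)
                else:
                    factors_in_part = [part]
                for f in factors_in_part:
                    nxt = {}
                    for mono, coef in expansion.items():
                        nxt[mono + (f,)] = nxt.get(mono + (f,), 0.0) + coef
                        nxt[mono] = nxt.get(mono, 0.0) - coef * centers[f]
                    expansion = nxt
        for mono, coef in expansion.items():
            key = _monomial_key(mono)
            if key not in raw:  # hierarchy should prevent this
                raise RuntimeError(f"expansion of {term} hit absent term {key}")
            raw[key] += b * coef
    return np.array([raw[t] for t in terms])


def _factor_arrays(data, factors) -> dict:
    cols = {}
    for f in factors:
        col = FACTOR_COLUMNS[f]
        if isinstance(data, pd.DataFrame):
            if col in data:
                cols[f] = np.asarray(data[col], dtype=float)
            elif f in data:
                cols[f] = np.asarray(data[f], dtype=float)
            else:
                raise KeyError(f"factor {f} ({col}) missing from data")
        else:  # mapping of scalars/arrays
            val = data.get(col, data.get(f))
            if val is None:
                raise KeyError(f"factor {f} ({col}) missing from data")
            cols[f] = np.atleast_1d(np.asarray(val, dtype=float))
    return cols


def design_matrix(data, terms, factors, centers=None) -> np.ndarray:
    """Model matrix for the given monomials; ``centers`` shifts each factor
    (standard DoE coding) so that quadratics decorrelate from linear terms."""
    cols = _factor_arrays(data, factors)
    if centers:
        cols = {f: v - centers.get(f, 0.0) for f, v in cols.items()}
    return np.column_stack([_term_column(t, cols) for t in terms])


def infer_factors(design: pd.DataFrame) -> tuple:
    """Factors present in a design table, in canonical A, B, C, D order."""
    return tuple(f for f in "ABCD" if FACTOR_COLUMNS[f] in design.columns)


# --------------------------------------------------------------------------
# transforms


@dataclass(frozen=True)
class Transform:
    """Response transform for residual normalization.

    ``kind`` is identity, log or box-cox; ``lmbda`` is the Box-Cox exponent
    (1 for identity, 0 for log).  ``apply``/``inverse`` round-trip exactly on
    positive values.
    """

    kind: str = "identity"
    lmbda: float = 1.0
    diagnostics: dict = field(default_factory=dict, compare=False)

    @classmethod
    def from_lambda(cls, lmbda: float, diagnostics: dict | None = None) -> "Transform":
        diagnostics = diagnostics or {}
        if lmbda == 1.0:
            return cls("identity", 1.0, diagnostics)
        if lmbda == 0.0:
            return cls("log", 0.0, diagnostics)
        return cls("box-cox", float(lmbda), diagnostics)

    def apply(self, y):
        y = np.asarray(y, dtype=float)
        if self.kind == "identity":
            return y
        if np.any(y <= 0):
            raise ValueError(f"{self.kind} transform requires positive values")
        if self.kind == "log":
            return np.log(y)
        return np.expm1(self.lmbda * np.log(y)) / self.lmbda

    def inverse(self, z):
        z = np.asarray(z, dtype=float)
        if self.kind == "identity":
            return z
        if self.kind == "log":
            return np.exp(z)
        # clamp the base: a wide band on the transformed scale can cross the
        # transform's domain edge (lambda*z + 1 <= 0)
        base = np.maximum(self.lmbda * z, 1e-12 - 1.0)
        return np.exp(np.log1p(base) / self.lmbda)


def choose_transform(
    design: pd.DataFrame,
    response: str,
    factors=None,
    grid=(-1.0, -0.5, 0.0, 0.5, 1.0),
) -> Transform:
    """Box-Cox exponent maximizing the profile likelihood of residual
    normality under the full quadratic model.

    The Jacobian-normalized transform makes likelihoods comparable across
    exponents; identity is kept whenever lambda = 1 lies inside the 95%
    profile-likelihood interval.  Non-positive responses restrict the choice
    to identity (with a warning).  Shapiro-Wilk statistics of the residuals
    before/after are recorded in ``Transform.diagnostics``.
    """
    factors = tuple(factors) if factors else infer_factors(design)
    y = np.asarray(design[response], dtype=float)
    if np.ptp(y) == 0:
        warnings.warn(f"{response}: constant response, degenerate fit; "
                      "identity transform", stacklevel=2)
        return Transform("identity", 1.0, {"constant_response": True})
    if np.any(y <= 0):
        warnings.warn(f"{response}: non-positive values, transform restricted "
                      "to identity", stacklevel=2)
        return Transform("identity", 1.0, {"restricted": True})

    centers = {f: float(design[FACTOR_COLUMNS[f]].mean()) for f in factors}
    X = design_matrix(design, full_terms(factors), factors, centers)
    gm = float(np.exp(np.mean(np.log(y))))
    n = y.size

    def loglik(lmbda):
        if lmbda == 0.0:
            z = gm * np.log(y)
        else:
            z = (y**lmbda - 1.0) / (lmbda * gm ** (lmbda - 1.0))
        resid = z - X @ np.linalg.lstsq(X, z, rcond=None)[0]
        ssr = float(resid @ resid)
        return -0.5 * n * np.log(max(ssr, 1e-300) / n)

    lls = {l: loglik(l) for l in grid}
    best = max(lls, key=lls.get)
    # chi-square(1) 95% cutoff on the profile likelihood
    if lls[1.0] >= lls[best] - 1.92:
        best = 1.0

    def shapiro_stat(lmbda):
        t = Transform.from_lambda(lmbda)
        z = t.apply(y)
        resid = z - X @ np.linalg.lstsq(X, z, rcond=None)[0]
        if np.ptp(resid) == 0:
            return 1.0
        return float(stats.shapiro(resid).statistic)

    diag = {
        "profile_loglik": {str(l): ll for l, ll in lls.items()},
        "shapiro_before": shapiro_stat(1.0),
        "shapiro_after": shapiro_stat(best),
    }
    return Transform.from_lambda(best, diag)


# --------------------------------------------------------------------------
# fitting


@dataclass(frozen=True)
class FittedSurface:
    """A selected polynomial response surface on a (possibly transformed)
    scale, with coefficient uncertainties for prediction bands.

    The model is estimated on mid-range-centered factors (DoE coding);
    ``coefficients`` are reported on the raw monomial basis, while
    ``coefficients_centered``, ``std_errors``, p-values and ``cov_params``
    refer to the centered basis actually fitted.
    """

    response_name: str
    factors: tuple
    transform: Transform
    terms: tuple
    centers: dict
    coefficients: np.ndarray
    coefficients_centered: np.ndarray
    std_errors: np.ndarray
    term_p_values: dict
    model_p_value: float
    r2: float
    residual_df: int
    residual_sigma: float
    cov_params: np.ndarray
    factor_ranges: dict
    significant: bool

    def _x(self, data) -> np.ndarray:
        return design_matrix(data, self.terms, self.factors, self.centers)

    def predict_transformed(self, data) -> np.ndarray:
        return self._x(data) @ self.coefficients_centered

    def predict(self, data) -> np.ndarray:
        """Predicted mean on the original response scale."""
        return self.transform.inverse(self.predict_transformed(data))

    def to_dict(self) -> dict:
        return {
            "response_name": self.response_name,
            "factors": list(self.factors),
            "transform": {"kind": self.transform.kind,
                          "lmbda": self.transform.lmbda},
            "terms": list(self.terms),
            "centers": {f: float(c) for f, c in self.centers.items()},
            "coefficients": self.coefficients.tolist(),
            "coefficients_centered": self.coefficients_centered.tolist(),
            "std_errors": self.std_errors.tolist(),
            "term_p_values": {t: float(p) for t, p in self.term_p_values.items()},
            "term_stars": {t: significance_stars(p)
                           for t, p in self.term_p_values.items()},
            "model_p_value": self.model_p_value,
            "r2": self.r2,
            "residual_df": self.residual_df,
            "residual_sigma": self.residual_sigma,
            "cov_params": self.cov_params.tolist(),
            "factor_ranges": {f: list(r) for f, r in self.factor_ranges.items()},
            "significant": self.significant,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FittedSurface":
        return cls(
            response_name=d["response_name"],
            factors=tuple(d["factors"]),
            transform=Transform.from_lambda(d["transform"]["lmbda"]),
            terms=tuple(d["terms"]),
            centers=dict(d["centers"]),
            coefficients=np.asarray(d["coefficients"], dtype=float),
            coefficients_centered=np.asarray(d["coefficients_centered"],
                                             dtype=float),
            std_errors=np.asarray(d["std_errors"], dtype=float),
            term_p_values=dict(d["term_p_values"]),
            model_p_value=d["model_p_value"],
            r2=d["r2"],
            residual_df=d["residual_df"],
            residual_sigma=d["residual_sigma"],
            cov_params=np.asarray(d["cov_params"], dtype=float),
            factor_ranges={f: tuple(r) for f, r in d["factor_ranges"].items()},
            significant=d["significant"],
        )

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


@dataclass(frozen=True)
class PredictionBand:
    """Back-transformed mean and 95% band; single-observation by default."""

    mean: float
    ci_low: float
    ci_high: float
    band: str = "prediction"
    extrapolated: bool = False


def correlation_matrix(design: pd.DataFrame, columns=None) -> pd.DataFrame:
    """Squared Pearson correlations over factor/response column pairs.

    Zero-variance columns yield undefined (NaN) entries and a warning; the
    diagonal is 1 for any non-constant column.
    """
    if columns is None:
        columns = [c for c in design.columns
                   if c != "replicate" and pd.api.types.is_numeric_dtype(design[c])]
    if len(design) < 3:
        raise ValueError("need at least 3 runs")
    data = design[columns].to_numpy(dtype=float)
    sd = data.std(axis=0)
    degenerate = [c for c, s in zip(columns, sd) if s == 0]
    if degenerate:
        warnings.warn(f"zero-variance columns flagged undefined: {degenerate}",
                      stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(data, rowvar=False)
    r2 = r**2
    for c in degenerate:
        i = columns.index(c)
        r2[i, :] = np.nan
        r2[:, i] = np.nan
    return pd.DataFrame(r2, index=columns, columns=columns)


def _distinct_runs(design: pd.DataFrame, factors) -> int:
    cols = [FACTOR_COLUMNS[f] for f in factors]
    return len(design[cols].drop_duplicates())


def fit_rsm(
    design: pd.DataFrame,
    response: str,
    factors=None,
    alpha: float = 0.1,
    max_order: int = 2,
    transform="auto",
) -> FittedSurface:
    """Fit a polynomial surface and backward-eliminate insignificant terms.

    The full candidate model (linear + two-way interactions + quadratics) is
    fitted on the transformed response; the least-significant removable term
    with p > ``alpha`` is dropped and the model refitted until every
    removable term satisfies p <= alpha.  Hierarchy is preserved: a parent
    factor is never dropped while one of its interactions or its square is
    retained (such parents may therefore stay with p > alpha).  Replicate
    runs enter as independent observations and feed the residual (pure
    error) variance.
    """
    factors = tuple(factors) if factors else infer_factors(design)
    if not factors:
        raise ValueError("no recognized factor columns in design")
    y_raw = np.asarray(design[response], dtype=float)
    if not np.all(np.isfinite(y_raw)):
        raise ValueError(f"{response}: non-finite response values")

    if transform == "auto":
        tf = choose_transform(design, response, factors)
    elif transform is None or transform == "identity":
        tf = Transform("identity", 1.0)
    elif isinstance(transform, Transform):
        tf = transform
    else:
        tf = Transform.from_lambda(float(transform))
    constant = np.ptp(y_raw) == 0
    z = tf.apply(y_raw) if not constant else y_raw.astype(float)

    terms = full_terms(factors, max_order)
    # a quadratic needs >= 3 levels, else it is collinear with the linear term
    n_levels = {f: design[FACTOR_COLUMNS[f]].nunique() for f in factors}
    terms = [t for t in terms
             if not ("^" in t and n_levels[t.split("^")[0]] < 3)]
    n_distinct = _distinct_runs(design, factors)
    while len(terms) > n_distinct and max_order >= 1:
        reduced = [t for t in terms if "^" not in t]
        if len(reduced) == len(terms):
            reduced = [t for t in terms if ":" not in t]
        if len(reduced) == len(terms):
            raise ValueError("design has too few distinct runs even for a "
                             "linear model")
        warnings.warn(
            f"{response}: {n_distinct} distinct runs cannot estimate "
            f"{len(terms)} terms; model order reduced", stacklevel=2)
        terms = reduced

    ranges = {
        f: (float(design[FACTOR_COLUMNS[f]].min()),
            float(design[FACTOR_COLUMNS[f]].max()))
        for f in factors
    }
    centers = {f: 0.5 * (lo + hi) for f, (lo, hi) in ranges.items()}

    def ols(term_list):
        X = design_matrix(design, term_list, factors, centers)
        return sm.OLS(z, X).fit()

    # rank guard: drop highest-order collinear terms until X has full rank
    while len(terms) > 1:
        X = design_matrix(design, terms, factors, centers)
        if np.linalg.matrix_rank(X) == X.shape[1]:
            break
        drop = max((t for t in terms if t != "1"),
                   key=lambda t: (len(term_parents(t)), terms.index(t)))
        warnings.warn(f"{response}: dropping collinear term {drop}",
                      stacklevel=2)
        terms = [t for t in terms if t != drop]

    fit = ols(terms)
    while True:
        pvals = dict(zip(terms, fit.pvalues))
        needed = set().union(*(term_parents(t) for t in terms)) if terms else set()
        removable = [t for t in terms if t != "1" and t not in needed]
        worst = None
        for t in removable:
            p = pvals[t]
            if (np.isnan(p) or p > alpha) and (
                    worst is None or np.nan_to_num(p, nan=np.inf)
                    > np.nan_to_num(pvals[worst], nan=np.inf)):
                worst = t
        if worst is None:
            break
        terms = [t for t in terms if t != worst]
        fit = ols(terms)

    pvals = dict(zip(terms, (float(p) for p in fit.pvalues)))
    model_p = float(fit.f_pvalue) if len(terms) > 1 else 1.0
    if np.isnan(model_p):
        model_p = 1.0
    if constant or len(terms) == 1:
        warnings.warn(f"{response}: intercept-only model, not significant",
                      stacklevel=2)

    sigma2 = float(fit.ssr / fit.df_resid) if fit.df_resid > 0 else 0.0
    beta_centered = np.asarray(fit.params, dtype=float)
    return FittedSurface(
        response_name=response,
        factors=factors,
        transform=tf,
        terms=tuple(terms),
        centers=centers,
        coefficients=_uncenter_coefficients(terms, beta_centered, centers),
        coefficients_centered=beta_centered,
        std_errors=np.asarray(fit.bse, dtype=float),
        term_p_values=pvals,
        model_p_value=model_p,
        r2=float(fit.rsquared) if not constant else 1.0,
        residual_df=int(fit.df_resid),
        residual_sigma=float(np.sqrt(sigma2)),
        cov_params=np.asarray(fit.cov_params(), dtype=float),
        factor_ranges=ranges,
        significant=(model_p <= 0.05),
    )


def predict_with_band(
    model: FittedSurface,
    point,
    band: str = "prediction",
    level: float = 0.95,
) -> PredictionBand:
    """Mean and 95% band at one factor point, back-transformed.

    ``band='prediction'`` (default) is the single-observation band used to
    validate a model with one fresh trial; ``band='mean'`` is the confidence
    band on the mean response.  Points outside the design's factor ranges
    are served with an ``extrapolated`` flag.
    """
    if band not in ("prediction", "mean"):
        raise ValueError("band must be 'prediction' or 'mean'")
    x0 = model._x(point)
    if x0.shape[0] != 1:
        raise ValueError("predict_with_band expects a single point")
    x0 = x0[0]
    mean_t = float(x0 @ model.coefficients_centered)
    var = float(x0 @ model.cov_params @ x0)
    if band == "prediction":
        var += model.residual_sigma**2
    if model.residual_df > 0 and var > 0:
        tq = stats.t.ppf(0.5 + level / 2.0, model.residual_df)
        half = tq * np.sqrt(var)
    else:
        half = 0.0
    lo_t, hi_t = mean_t - half, mean_t + half

    cols = _factor_arrays(point, model.factors)
    extrapolated = any(
        float(cols[f][0]) < model.factor_ranges[f][0] - 1e-12
        or float(cols[f][0]) > model.factor_ranges[f][1] + 1e-12
        for f in model.factors
    )

    inv = model.transform.inverse
    mean = float(inv(mean_t))
    lo, hi = sorted((float(inv(lo_t)), float(inv(hi_t))))
    return PredictionBand(mean=mean, ci_low=lo, ci_high=hi, band=band,
                          extrapolated=extrapolated)
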