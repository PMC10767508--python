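"""Pedotransfer regression: predicting log10 DT50 and log10 Kd from soil
properties.

The model family is an extended-Freundlich (log-linear) regression

    log10(DT50 or Kd) = intercept + a*depth + b*log10(CEC) + g*log10(Fe_ox)
                        + d*log10(Al_ox) + e*log10(Clay) + f*log10(SOM)
                        + l*pH

with depth coded 1 for shallow/topsoil (0-20 cm) and 0 for deep (>50 cm),
all concentration-like properties on the log10 scale and pH untransformed.
Model building considers every subset of the seven candidate terms, ranks
by AIC = n*ln(RSS/n) + 2*(p+1), and reports per-coefficient p-values with
the star convention (* P<0.05, ** P<0.01, *** P<0.005).  The coefficient
sets published for eight DT50 models and five Kd models ship as package
data and can be applied to new soils directly.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "CANDIDATE_TERMS",
    "CALIBRATION_RANGES",
    "SoilSample",
    "PedotransferModel",
    "CorrelationReport",
    "soils_to_frame",
    "pearson_matrix",
    "design_matrix",
    "fit_ols",
    "all_subsets_search",
    "predict",
    "published_models",
    "read_soils_csv",
]

#: Canonical design-matrix column order for the seven candidate terms.
CANDIDATE_TERMS = (
    "depth", "log_cec", "log_fe_ox", "log_al_ox", "log_clay", "log_som", "ph"
)

#: Soil property underlying each regression term.
_TERM_PROPERTY = {
    "depth": "depth_class", "log_cec": "cec", "log_fe_ox": "fe_ox",
    "log_al_ox": "al_ox", "log_clay": "clay", "log_som": "som", "ph": "ph",
}

#: Property ranges spanned by the calibration soils; predictions outside
#: these trigger an extrapolation warning. Units: pH (-), CEC meq/kg,
#: SOM %, clay %, Al_ox mmol/kg, Fe_ox mmol/kg.
CALIBRATION_RANGES = {
    "ph": (3.1, 7.8), "cec": (6.9, 821.0), "som": (0.3, 57.0),
    "clay": (1.0, 53.0), "al_ox": (1.2, 152.0), "fe_ox": (2.0, 897.0),
}

_STAR_THRESHOLDS = ((0.005, "***"), (0.01, "**"), (0.05, "*"))

_MAX_CANDIDATES = 15  # combinatorial guard for the exhaustive search


def significance_stars(p: float) -> str:
    for threshold, stars in _STAR_THRESHOLDS:
        if p < threshold:
            return stars
    return "ns"


@dataclass(frozen=True)
class SoilSample:
    """Measured properties of one soil, plus its sampling-depth class."""

    soil_id: str
    ph: float  # pH in 0.01 M CaCl2
    cec: float  # meq/kg
    som: float  # % dry weight, loss on ignition
    clay: float  # % < 2 um
    al_ox: float  # mmol/kg oxalate-extractable Al
    fe_ox: float  # mmol/kg oxalate-extractable Fe
    depth_class: str  # "shallow" (topsoil 0-20 cm) or "deep" (>50 cm)
    land_use: str = ""

    def __post_init__(self) -> None:
        if not 2.0 < self.ph < 11.0:
            raise ValueError(f"pH {self.ph} outside plausible range (2, 11)")
        for name in ("cec", "som", "clay", "al_ox", "fe_ox"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive (log-transformed)")
        if self.depth_class not in ("shallow", "deep"):
            raise ValueError("depth_class must be 'shallow' or 'deep'")


@dataclass
class PedotransferModel:
    """One fitted or published regression model for log10 DT50 or log10 Kd."""

    response: str  # "DT50" | "Kd"
    compound: str
    intercept: float
    coefficients: dict[str, float]  # term -> estimate, canonical subset
    significance: dict[str, str] = field(default_factory=dict)
    coef_pvalues: dict[str, float] = field(default_factory=dict)
    coef_se: dict[str, float] = field(default_factory=dict)
    r2: float = math.nan
    r2_adj: float = math.nan
    se_y: float = math.nan
    f_stat: float = math.nan
    p_value: float = math.nan
    n_obs: int = 0
    aic: float = math.nan
    source: str = "fitted"  # "fitted" | "published"

    @property
    def terms(self) -> tuple[str, ...]:
        return tuple(t for t in CANDIDATE_TERMS if t in self.coefficients)


@dataclass
class CorrelationReport:
    """Pairwise Pearson correlations among (transformed) soil properties."""

    r: pd.DataFrame
    p: pd.DataFrame
    stars: pd.DataFrame


def soils_to_frame(samples: list[SoilSample]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "soil_id": [s.soil_id for s in samples],
            "ph": [s.ph for s in samples],
            "cec": [s.cec for s in samples],
            "som": [s.som for s in samples],
            "clay": [s.clay for s in samples],
            "al_ox": [s.al_ox for s in samples],
            "fe_ox": [s.fe_ox for s in samples],
            "depth_class": [s.depth_class for s in samples],
            "land_use": [s.land_use for s in samples],
        }
    ).set_index("soil_id")


def _transformed_properties(soils: pd.DataFrame) -> pd.DataFrame:
    """log10 everything except pH; order follows the published tables."""
    out = pd.DataFrame(index=soils.index)
    for prop in ("fe_ox", "al_ox", "clay", "som", "cec"):
        if (soils[prop] <= 0).any():
            bad = soils.index[soils[prop] <= 0].tolist()
            raise ValueError(f"non-positive {prop} for soils {bad}")
        out[prop] = np.log10(soils[prop].astype(float))
    out["ph"] = soils["ph"].astype(float)
    return out


def pearson_matrix(samples: list[SoilSample] | pd.DataFrame) -> CorrelationReport:
    """Pearson correlations among soil properties on the analysis scale.

    Properties are log10-transformed except pH.  Two-sided t-test p-values
    accompany each coefficient, starred at P<0.05 / P<0.01 / P<0.005.
    """
    soils = samples if isinstance(samples, pd.DataFrame) else soils_to_frame(samples)
    if len(soils) < 3:
        raise ValueError("need at least 3 samples for correlation")
    data = _transformed_properties(soils)
    if (data.std(ddof=0) == 0).any():
        zero = data.columns[data.std(ddof=0) == 0].tolist()
        raise ValueError(f"zero-variance columns {zero}")
    cols = list(data.columns)
    r = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((len(cols), len(cols))), index=cols, columns=cols)
    for a, b in itertools.combinations(cols, 2):
        res = stats.pearsonr(data[a], data[b])
        r.loc[a, b] = r.loc[b, a] = res.statistic
        p.loc[a, b] = p.loc[b, a] = res.pvalue
    stars = p.map(significance_stars)
    np.fill_diagonal(stars.values, "")
    return CorrelationReport(r=r, p=p, stars=stars)


def design_matrix(
    soils: pd.DataFrame | list[SoilSample], terms
) -> pd.DataFrame:
    """Regression design matrix with columns in canonical order.

    ``depth`` is coded 1 = shallow, 0 = deep; log terms are base-10.  Rows
    with a non-positive value under a log term are rejected.
    """
    frame = soils if isinstance(soils, pd.DataFrame) else soils_to_frame(soils)
    unknown = set(terms) - set(CANDIDATE_TERMS)
    if unknown:
        raise ValueError(f"unknown terms {sorted(unknown)}")
    ordered = [t for t in CANDIDATE_TERMS if t in set(terms)]
    X = pd.DataFrame(index=frame.index)
    X["const"] = 1.0
    for term in ordered:
        prop = _TERM_PROPERTY[term]
        if term == "depth":
            X[term] = (frame["depth_class"] == "shallow").astype(float)
        elif term == "ph":
            X[term] = frame["ph"].astype(float)
        else:
            vals = frame[prop].astype(float)
            if (vals <= 0).any():
                bad = frame.index[vals <= 0].tolist()
                raise ValueError(
                    f"non-positive {prop} under log term for rows {bad}"
                )
            X[term] = np.log10(vals)
    return X


#: RSS at or below this is an exact fit up to round-off; its AIC degenerates
#: to -inf and parsimony breaks the resulting ties.
_RSS_FLOOR = 1e-20


def _aic(n: int, rss: float, n_terms: int) -> float:
    """Gaussian OLS AIC with the additive constant dropped:
    n*ln(RSS/n) + 2*(p+1), p = number of regression terms (intercept extra).
    """
    if rss <= _RSS_FLOOR:
        return -math.inf
    return n * math.log(rss / n) + 2 * (n_terms + 1)


def fit_ols(
    y: pd.Series | np.ndarray,
    X: pd.DataFrame,
    response: str = "DT50",
    compound: str = "",
) -> PedotransferModel:
    """Ordinary least squares of a log10 response on a design matrix.

    Reports coefficients with two-sided p-values and stars, R2, adjusted
    R2, residual standard error, the model F statistic and AIC.
    """
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    if n <= k:
        raise ValueError("need more observations than design columns")
    if np.linalg.matrix_rank(X.to_numpy()) < k:
        corr = np.corrcoef(X.drop(columns="const").to_numpy(), rowvar=False)
        raise ValueError(
            "rank-deficient design matrix; check collinear terms "
            f"{list(X.columns[1:])} (|r| max "
            f"{np.abs(corr - np.eye(len(corr))).max():.3f})"
        )
    res = sm.OLS(y, X).fit()
    terms = [c for c in X.columns if c != "const"]
    rss = float(res.ssr)
    p_count = len(terms)
    coefs = {t: float(res.params[t]) for t in terms}
    pvals = {t: float(res.pvalues[t]) for t in terms}
    pvals["intercept"] = float(res.pvalues["const"])
    ses = {t: float(res.bse[t]) for t in terms}
    ses["intercept"] = float(res.bse["const"])
    stars = {t: significance_stars(p) for t, p in pvals.items()}
    se_y = math.sqrt(rss / (n - p_count - 1))
    return PedotransferModel(
        response=response, compound=compound,
        intercept=float(res.params["const"]), coefficients=coefs,
        significance=stars, coef_pvalues=pvals, coef_se=ses,
        r2=float(res.rsquared),
        r2_adj=float(res.rsquared_adj), se_y=se_y,
        f_stat=float(res.fvalue) if p_count else math.nan,
        p_value=float(res.f_pvalue) if p_count else math.nan,
        n_obs=n, aic=_aic(n, rss, p_count), source="fitted",
    )


def all_subsets_search(
    soils: pd.DataFrame | list[SoilSample],
    y: pd.Series | np.ndarray,
    candidate_terms=CANDIDATE_TERMS,
    response: str = "DT50",
    compound: str = "",
) -> list[PedotransferModel]:
    """Exhaustive subset regression ranked ascending by AIC.

    Every subset of ``candidate_terms`` (including the intercept-only
    model) is fitted; the first element of the returned list is the
    lowest-AIC model.  Non-significant coefficients remain in the models
    and are flagged through their stars ("ns").
    """
    candidate_terms = tuple(candidate_terms)
    if len(candidate_terms) > _MAX_CANDIDATES:
        raise ValueError(
            f"refusing exhaustive search over {len(candidate_terms)} terms "
            f"(limit {_MAX_CANDIDATES})"
        )
    frame = soils if isinstance(soils, pd.DataFrame) else soils_to_frame(soils)
    models = []
    for size in range(len(candidate_terms) + 1):
        for subset in itertools.combinations(candidate_terms, size):
            X = design_matrix(frame, subset)
            models.append(fit_ols(y, X, response=response, compound=compound))
    # ties (notably exact fits at -inf) resolve to the most parsimonious model
    models.sort(key=lambda m: (m.aic, len(m.coefficients)))
    return models


def predict(model: PedotransferModel, sample: SoilSample) -> dict[str, float]:
    """Apply a pedotransfer model to one soil.

    Returns ``{"log10": yhat, "linear": 10**yhat, "rough_estimate": flag}``
    where the flag marks predicted log10 Kd above 2.  A property outside
    the calibration range triggers a warning, not a failure.
    """
    yhat = model.intercept
    for term, coef in model.coefficients.items():
        prop = _TERM_PROPERTY[term]
        if term == "depth":
            value = 1.0 if sample.depth_class == "shallow" else 0.0
        elif term == "ph":
            value = sample.ph
        else:
            raw = getattr(sample, prop)
            if raw <= 0:
                raise ValueError(f"{prop} must be positive for {term}")
            value = math.log10(raw)
        if prop in CALIBRATION_RANGES:
            lo, hi = CALIBRATION_RANGES[prop]
            raw = getattr(sample, prop)
            if not lo <= raw <= hi:
                warnings.warn(
                    f"{sample.soil_id}: {prop}={raw} outside calibration "
                    f"range [{lo}, {hi}]; prediction is an extrapolation",
                    stacklevel=2,
                )
        yhat += coef * value
    return {
        "log10": yhat,
        "linear": 10.0**yhat,
        "rough_estimate": bool(model.response == "Kd" and yhat > 2.0),
    }


def published_models() -> list[PedotransferModel]:
    """The thirteen published regression models (eight DT50, five Kd).

    Coefficients, significance stars and fit statistics are loaded from the
    version-controlled CSVs shipped with the package.  Kd models for DOX,
    FLUM and TMP do not exist: in almost all calibration soils those
    compounds had log10 Kd above 2, so no regression was attempted.
    """
    base = resources.files("soilfate") / "data"
    with resources.as_file(base / "published_models.csv") as path:
        coefs = pd.read_csv(path)
    with resources.as_file(base / "published_model_stats.csv") as path:
        statsframe = pd.read_csv(path)

    models = []
    for (response, compound), grp in coefs.groupby(
        ["response", "compound"], sort=False
    ):
        row = statsframe[
            (statsframe.response == response) & (statsframe.compound == compound)
        ].iloc[0]
        grp = grp.set_index("term")
        intercept = float(grp.loc["intercept", "estimate"])
        terms = grp.drop(index="intercept")
        models.append(
            PedotransferModel(
                response=response, compound=compound, intercept=intercept,
                coefficients={t: float(v) for t, v in terms["estimate"].items()},
                significance={t: str(s) for t, s in grp["stars"].items()
                              }.copy(),
                r2=float(row.r2), r2_adj=float(row.r2_adj),
                se_y=float(row.se_y), f_stat=float(row.f_stat),
                p_value=0.001 if str(row.p_value).strip() == "<0.001"
                else math.nan,
                n_obs=int(row.n_obs), source="published",
            )
        )
    return models


def get_published_model(response: str, compound: str) -> PedotransferModel:
    """Look up one published model; raises with an explicit reason when the
    compound has no model for that response."""
    for model in published_models():
        if model.response == response and model.compound == compound:
            return model
    if response == "Kd" and compound in ("DOX", "FLUM", "TMP"):
        raise KeyError(
            f"no published Kd model for {compound}: most calibration soils "
            "had log10 Kd above 2, so the regression was not attempted"
        )
    if response == "DT50" and compound == "ENRO":
        raise KeyError("no published DT50 model for ENRO (no usable decay data)")
    raise KeyError(f"no published {response} model for {compound!r}")


def read_soils_csv(path) -> list[SoilSample]:
    """Read soil samples from CSV with columns soil_id, ph, cec, som, clay,
    al_ox, fe_ox, depth_class[, land_use]."""
    frame = pd.read_csv(path)
    return [
        SoilSample(
            soil_id=str(row.soil_id), ph=float(row.ph), cec=float(row.cec),
            som=float(row.som), clay=float(row.clay),
            al_ox=float(row.al_ox), fe_ox=float(row.fe_ox),
            depth_class=str(row.depth_class),
            land_use=str(getattr(row, "land_use", "")),
        )
        for row in frame.itertuples(index=False)
    ]
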