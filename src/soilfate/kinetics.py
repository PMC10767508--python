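"""Degradation kinetics: FOCUS-type decay models, chi-square error levels,
model selection and DT50/DT90 derivation.

Four models describe the decline of the parent compound in soil incubation
experiments:

* ``SFO``  — single first order, ``C(t) = C0 * exp(-k t)``
* ``FOMC`` — first-order multi-compartment (Gustafson-Holden),
  ``C(t) = C0 / ((t / beta) + 1) ** alpha``
* ``DFOP`` — double first order in parallel,
  ``C(t) = C0 * (g * exp(-k1 t) + (1 - g) * exp(-k2 t))``
* ``HS``   — hockey stick: first order at rate ``k1`` until the break time
  ``t_b``, rate ``k2`` afterwards.

Model adequacy is quantified by the FOCUS chi-square error level: the
smallest relative measurement error (in percent of the mean observation) at
which a chi-square goodness-of-fit test at alpha = 0.05 would not reject the
fitted model.  The selection rule is: keep SFO when its error level is below
``sfo_threshold`` (default 5 %), otherwise take the converged biphasic model
with the lowest error level; fits whose error level exceeds ``max_threshold``
(default 10 %) are flagged as not accepted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "COMPOUNDS",
    "CANONICAL_DAYS",
    "DecaySeries",
    "KineticFit",
    "ModelSelection",
    "predict_concentration",
    "fit_model",
    "chi2_error_level",
    "derive_dt_x",
    "select_model",
    "read_decay_csv",
    "fit_decay_table",
]

#: Antibiotic identifiers handled by the study design.
COMPOUNDS = ("DOX", "ENRO", "FLUM", "LINCO", "OTC", "SDZ", "SDX", "TMP", "TYL")

#: Canonical sampling schedule of the incubation design, in days.
CANONICAL_DAYS = (0.0, 1.0, 2.0, 3.0, 7.0, 10.0, 21.0, 30.0)

#: Nominal fortification level used to normalise raw concentrations, ng/g.
NOMINAL_FORTIFICATION_NG_G = 100.0

MODEL_NAMES = ("SFO", "FOMC", "DFOP", "HS")
BIPHASIC_MODELS = ("FOMC", "DFOP", "HS")

# Parameter order per model; C0 always leads.
MODEL_PARAMS = {
    "SFO": ("C0", "k"),
    "FOMC": ("C0", "alpha", "beta"),
    "DFOP": ("C0", "k1", "k2", "g"),
    "HS": ("C0", "k1", "k2", "t_b"),
}

# Tie-break preference among biphasic models with equal error level
# (fewer parameters first is applied before this order).
_BIPHASIC_TIE_ORDER = {"DFOP": 0, "FOMC": 1, "HS": 2}

_RATE_FLOOR = 1e-8  # lower bound for rate constants; keeps DT50 finite-valued


@dataclass(frozen=True)
class DecaySeries:
    """Time course of the remaining parent fraction for one soil x compound.

    ``values`` are fractions of the nominal day-0 amount (dimensionless).
    Raw ng/g concentrations are normalised on load by
    :func:`read_decay_csv`.  Observations reported below the limit of
    detection are retained at LOD/2 and flagged in ``censored``.
    """

    soil_id: str
    compound: str
    times: np.ndarray
    values: np.ndarray
    censored: np.ndarray | None = None

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if times.ndim != 1 or values.shape != times.shape:
            raise ValueError("times and values must be 1-D and equal length")
        if times.size < 4:
            raise ValueError(
                "need at least 4 observations for 3-parameter models"
            )
        if np.any(np.diff(times) < 0):
            raise ValueError("times must be non-decreasing")
        if times[0] != 0:
            raise ValueError("series must start at day 0")
        if np.any(values < 0):
            raise ValueError("fractions must be non-negative")
        if self.censored is not None:
            cens = np.asarray(self.censored, dtype=bool)
            if cens.shape != times.shape:
                raise ValueError("censored flags must align with times")
            object.__setattr__(self, "censored", cens)

    @property
    def n_obs(self) -> int:
        return int(self.times.size)


@dataclass
class KineticFit:
    """Result of fitting one kinetic model to one decay series."""

    model: str
    estimates: dict[str, float]
    rss: float
    n_obs: int
    n_params: int
    converged: bool
    chi2_error_pct: float = math.nan
    dt50: float = math.nan
    dt90: float = math.nan
    accepted: bool = False
    extrapolated: bool = False


@dataclass
class ModelSelection:
    """Outcome of the SFO-first selection rule, with all candidates kept."""

    best: KineticFit | None
    candidates: dict[str, KineticFit] = field(default_factory=dict)
    reason: str = ""

    @property
    def accepted(self) -> bool:
        return self.best is not None and self.best.accepted


def _check_params(model: str, params: dict[str, float]) -> None:
    if model not in MODEL_PARAMS:
        raise ValueError(f"unknown kinetic model {model!r}")
    missing = set(MODEL_PARAMS[model]) - set(params)
    if missing:
        raise ValueError(f"{model}: missing parameters {sorted(missing)}")
    if params["C0"] <= 0:
        raise ValueError("C0 must be positive")
    for key in ("k", "k1", "k2", "alpha", "beta"):
        if key in MODEL_PARAMS[model] and params[key] < 0:
            raise ValueError(f"{key} must be non-negative")
    if model == "DFOP" and not 0.0 <= params["g"] <= 1.0:
        raise ValueError("DFOP pool fraction g must lie in [0, 1]")


def predict_concentration(model: str, params: dict[str, float], t) -> np.ndarray:
    """Evaluate a kinetic model at time(s) ``t`` (days).

    Returns the predicted remaining amount; non-increasing in ``t`` for all
    valid parameter values.
    """
    _check_params(model, params)
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    c0 = params["C0"]
    if model == "SFO":
        out = c0 * np.exp(-params["k"] * t)
    elif model == "FOMC":
        out = c0 / ((t / params["beta"]) + 1.0) ** params["alpha"]
    elif model == "DFOP":
        g = params["g"]
        out = c0 * (
            g * np.exp(-params["k1"] * t) + (1.0 - g) * np.exp(-params["k2"] * t)
        )
    else:  # HS
        k1, k2, t_b = params["k1"], params["k2"], params["t_b"]
        before = c0 * np.exp(-k1 * t)
        after = c0 * math.exp(-k1 * t_b) * np.exp(-k2 * (t - t_b))
        out = np.where(t <= t_b, before, after)
    return out


def _start_grid(model: str, series: DecaySeries) -> list[np.ndarray]:
    """Deterministic multi-start grid; no RNG enters the fitting path."""
    c0_init = float(series.values[series.times == 0].mean())
    if not np.isfinite(c0_init) or c0_init <= 0:
        c0_init = max(float(series.values.max()), 1e-3)
    rates = (0.01, 0.1, 1.0)
    if model == "SFO":
        return [np.array([c0_init, k]) for k in rates]
    if model == "FOMC":
        return [
            np.array([c0_init, a, b])
            for a in (0.5, 1.0, 2.0)
            for b in (1.0, 10.0, 100.0)
        ]
    if model == "DFOP":
        return [
            np.array([c0_init, k1, k2, g])
            for k1 in rates
            for k2 in rates
            for g in (0.2, 0.5, 0.8)
        ]
    # HS break-time starts at the interior quartiles of the observed times
    tmax = float(series.times[-1])
    quartiles = np.quantile(series.times, [0.25, 0.5, 0.75])
    t_bs = sorted({float(np.clip(q, 1e-3, tmax * 0.999)) for q in quartiles})
    return [
        np.array([c0_init, k1, k2, tb])
        for k1 in rates
        for k2 in rates
        for tb in t_bs
    ]


def _bounds(model: str, series: DecaySeries) -> tuple[np.ndarray, np.ndarray]:
    tmax = float(series.times[-1])
    lo = {"C0": 1e-8, "k": _RATE_FLOOR, "k1": _RATE_FLOOR, "k2": _RATE_FLOOR,
          "alpha": 1e-6, "beta": 1e-6, "g": 0.0, "t_b": 1e-6}
    hi = {"C0": np.inf, "k": np.inf, "k1": np.inf, "k2": np.inf,
          "alpha": np.inf, "beta": np.inf, "g": 1.0, "t_b": tmax}
    names = MODEL_PARAMS[model]
    return (np.array([lo[p] for p in names]), np.array([hi[p] for p in names]))


def fit_model(
    series: DecaySeries,
    model: str,
    fix_c0: float | None = None,
) -> KineticFit:
    """Fit one kinetic model by unweighted nonlinear least squares.

    A deterministic grid of starting values is tried and the converged start
    with the lowest residual sum of squares wins.  When no start converges
    the fit is returned with ``converged=False`` rather than raising.  Pass
    ``fix_c0`` to pin the initial amount instead of estimating it.
    """
    if model not in MODEL_PARAMS:
        raise ValueError(f"unknown kinetic model {model!r}")
    names = MODEL_PARAMS[model]
    n_free = len(names) - (1 if fix_c0 is not None else 0)
    if series.n_obs < n_free + 1:
        raise ValueError(
            f"{model} needs at least {n_free + 1} observations, "
            f"got {series.n_obs}"
        )
    lo, hi = _bounds(model, series)
    if fix_c0 is not None:
        lo, hi = lo[1:], hi[1:]

    def residuals(theta: np.ndarray) -> np.ndarray:
        if fix_c0 is not None:
            params = dict(zip(names[1:], theta))
            params["C0"] = fix_c0
        else:
            params = dict(zip(names, theta))
        return predict_concentration(model, params, series.times) - series.values

    best = None
    for start in _start_grid(model, series):
        x0 = np.clip(start[1:] if fix_c0 is not None else start, lo, hi)
        try:
            sol = optimize.least_squares(
                residuals, x0, bounds=(lo, hi), method="trf", xtol=1e-12,
                ftol=1e-12, gtol=1e-12, max_nfev=2000,
            )
        except Exception:
            continue
        if not sol.success:
            continue
        rss = float(np.sum(sol.fun**2))
        if best is None or rss < best[0]:
            best = (rss, sol.x)

    if best is None:
        return KineticFit(
            model=model, estimates={}, rss=math.nan, n_obs=series.n_obs,
            n_params=n_free, converged=False,
        )
    rss, theta = best
    if fix_c0 is not None:
        estimates = dict(zip(names[1:], map(float, theta)))
        estimates["C0"] = float(fix_c0)
    else:
        estimates = dict(zip(names, map(float, theta)))
    fit = KineticFit(
        model=model, estimates=estimates, rss=rss, n_obs=series.n_obs,
        n_params=n_free, converged=True,
    )
    df = fit.n_obs - fit.n_params
    if df >= 1:
        fit.chi2_error_pct = chi2_error_level(series, fit)
    fit.dt50 = derive_dt_x(model, estimates, 50.0)
    fit.dt90 = derive_dt_x(model, estimates, 90.0)
    fit.extrapolated = bool(
        np.isfinite(fit.dt50) and fit.dt50 > float(series.times[-1])
    )
    return fit


def chi2_error_level(series: DecaySeries, fit: KineticFit) -> float:
    """FOCUS chi-square error level of a fit, in percent.

    ``err = 100 / mean(obs) * sqrt(RSS / chi2_{0.95, df})`` with
    ``df = n_obs - n_params``: the smallest relative error at which the
    chi-square test at alpha = 0.05 does not reject the model.
    """
    if not fit.converged:
        raise ValueError("chi2 error level requires a converged fit")
    df = fit.n_obs - fit.n_params
    if df < 1:
        raise ValueError("chi2 error level undefined for df < 1")
    mean_obs = float(series.values.mean())
    if mean_obs <= 0:
        raise ValueError("mean observation must be positive")
    quantile = stats.chi2.ppf(0.95, df)
    return 100.0 / mean_obs * math.sqrt(fit.rss / quantile)


def derive_dt_x(model: str, params: dict[str, float], x: float) -> float:
    """Time (days) for the predicted curve to decline by ``x`` percent.

    Closed forms for SFO, FOMC and HS; bracketed root-finding on the curve
    for DFOP (|dt| <= 1e-6 d).  Returns ``inf`` when the target decline is
    never reached (non-identifiable persistence).
    """
    _check_params(model, params)
    if not 0.0 < x < 100.0:
        raise ValueError("decline percentage must lie in (0, 100)")
    target = 1.0 - x / 100.0  # remaining fraction of C0
    neg_log = -math.log(target)  # ln2 for DT50, ln10 for DT90

    if model == "SFO":
        k = params["k"]
        return neg_log / k if k > 0 else math.inf
    if model == "FOMC":
        alpha, beta = params["alpha"], params["beta"]
        if alpha <= 0 or beta <= 0:
            return math.inf
        exponent = neg_log / alpha  # (1/target)**(1/alpha) in log domain
        if exponent > 700.0:  # would overflow a double: effectively no decline
            return math.inf
        return beta * (math.exp(exponent) - 1.0)
    if model == "HS":
        k1, k2, t_b = params["k1"], params["k2"], params["t_b"]
        if k1 > 0 and neg_log / k1 <= t_b:
            return neg_log / k1
        if k2 <= 0:
            return math.inf
        return t_b + (neg_log - k1 * t_b) / k2

    # DFOP: strictly decreasing whenever a decaying pool exists
    c0 = params["C0"]

    def deficit(t: float) -> float:
        return float(predict_concentration(model, params, t)) / c0 - target

    hi = 1.0
    while deficit(hi) > 0:
        hi *= 2.0
        if hi > 1e12:
            return math.inf
    return float(optimize.brentq(deficit, 0.0, hi, xtol=1e-6))


def select_model(
    series: DecaySeries,
    sfo_threshold: float = 5.0,
    max_threshold: float = 10.0,
    fix_c0: float | None = None,
) -> ModelSelection:
    """Apply the SFO-first selection rule to one decay series.

    SFO is fitted first and kept when its chi-square error level is below
    ``sfo_threshold`` percent.  Otherwise the three biphasic models are
    fitted and the converged one with the lowest error level wins (ties to
    four decimals broken by fewer parameters, then DFOP > FOMC > HS).  The
    winner is marked ``accepted`` only when its error level does not exceed
    ``max_threshold`` percent; series failing that filter are meant to be
    discarded from downstream statistics.
    """
    candidates: dict[str, KineticFit] = {}
    sfo = fit_model(series, "SFO", fix_c0=fix_c0)
    candidates["SFO"] = sfo
    if sfo.converged and np.isfinite(sfo.chi2_error_pct) and (
        sfo.chi2_error_pct < sfo_threshold
    ):
        sfo.accepted = sfo.chi2_error_pct <= max_threshold
        return ModelSelection(best=sfo, candidates=candidates,
                              reason="SFO error level below threshold")

    for name in BIPHASIC_MODELS:
        try:
            candidates[name] = fit_model(series, name, fix_c0=fix_c0)
        except ValueError:
            continue
    usable = [
        f for f in candidates.values()
        if f.model != "SFO" and f.converged and np.isfinite(f.chi2_error_pct)
    ]
    if not usable:
        if sfo.converged and np.isfinite(sfo.chi2_error_pct):
            sfo.accepted = sfo.chi2_error_pct <= max_threshold
            return ModelSelection(best=sfo, candidates=candidates,
                                  reason="no biphasic model converged; SFO kept")
        return ModelSelection(best=None, candidates=candidates,
                              reason="no model converged")
    usable.sort(
        key=lambda f: (
            round(f.chi2_error_pct, 4),
            f.n_params,
            _BIPHASIC_TIE_ORDER[f.model],
        )
    )
    winner = usable[0]
    winner.accepted = winner.chi2_error_pct <= max_threshold
    reason = "lowest chi2 error level among biphasic fits"
    return ModelSelection(best=winner, candidates=candidates, reason=reason)


# ---------------------------------------------------------------------------
# Tabular I/O


def read_decay_csv(
    path,
    fortification_ng_g: float = NOMINAL_FORTIFICATION_NG_G,
) -> list[DecaySeries]:
    """Read a long-format decay table into :class:`DecaySeries` objects.

    Expected columns: ``soil_id, compound, day, value, unit, lod``.  Rows
    with ``unit == 'ng/g'`` are divided by the fortification level; rows
    with ``unit == 'fraction'`` are taken as is.  Values below the LOD are
    substituted by LOD/2 and flagged as censored.
    """
    frame = pd.read_csv(path)
    required = {"soil_id", "compound", "day", "value"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"decay table missing columns {sorted(missing)}")
    if "unit" not in frame.columns:
        frame["unit"] = "fraction"
    if "lod" not in frame.columns:
        frame["lod"] = np.nan

    out: list[DecaySeries] = []
    for (soil_id, compound), grp in frame.groupby(
        ["soil_id", "compound"], sort=True
    ):
        grp = grp.sort_values("day")
        values = grp["value"].to_numpy(dtype=float)
        lods = grp["lod"].to_numpy(dtype=float)
        units = grp["unit"].astype(str).str.lower().to_numpy()
        scale = np.where(units == "ng/g", fortification_ng_g, 1.0)
        censored = np.isfinite(lods) & (values < lods)
        values = np.where(censored, lods / 2.0, values) / scale
        out.append(
            DecaySeries(
                soil_id=str(soil_id), compound=str(compound),
                times=grp["day"].to_numpy(dtype=float),
                values=values, censored=censored,
            )
        )
    return out


def fit_decay_table(
    series_list: list[DecaySeries],
    sfo_threshold: float = 5.0,
    max_threshold: float = 10.0,
    fix_c0: float | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Run :func:`select_model` over many series.

    Returns the per-series fit table (one row per series, including
    per-candidate error levels) and a log of every discarded series with
    the reason.
    """
    rows = []
    log: list[str] = []
    for series in series_list:
        sel = select_model(series, sfo_threshold, max_threshold, fix_c0=fix_c0)
        row: dict[str, object] = {
            "soil_id": series.soil_id,
            "compound": series.compound,
            "n_obs": series.n_obs,
        }
        for name in MODEL_NAMES:
            fit = sel.candidates.get(name)
            row[f"chi2_err_pct_{name.lower()}"] = (
                fit.chi2_error_pct if fit is not None and fit.converged
                else math.nan
            )
        if sel.best is None:
            row.update(model="", converged=False, accepted=False,
                       dt50_days=math.nan, dt90_days=math.nan,
                       chi2_error_pct=math.nan, rss=math.nan,
                       extrapolated=False)
            log.append(
                f"{series.soil_id}/{series.compound}: discarded ({sel.reason})"
            )
        else:
            best = sel.best
            row.update(
                model=best.model, converged=best.converged,
                accepted=best.accepted, dt50_days=best.dt50,
                dt90_days=best.dt90, chi2_error_pct=best.chi2_error_pct,
                rss=best.rss, extrapolated=best.extrapolated,
            )
            for pname, val in best.estimates.items():
                row[f"param_{pname}"] = val
            if not best.accepted:
                log.append(
                    f"{series.soil_id}/{series.compound}: discarded "
                    f"(chi2 error level {best.chi2_error_pct:.2f}% exceeds "
                    f"{max_threshold}%)"
                )
            elif best.extrapolated:
                log.append(
                    f"{series.soil_id}/{series.compound}: DT50 "
                    f"{best.dt50:.1f} d extrapolated beyond the observed "
                    f"{series.times[-1]:.0f} d window"
                )
        rows.append(row)
    return pd.DataFrame(rows), log
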