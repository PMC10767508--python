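"""Synthetic study generator.

The measured per-soil data behind the published summaries are not deposited,
so this module generates a full surrogate study with the statistical
structure the analysis assumes:

* soil properties drawn from a Gaussian copula on the transformed scale
  (log10 for all but pH) with the published between-property correlation
  targets, and two-piece triangular marginals anchored at the published
  (minimum, median, maximum) of each property;
* decay time series on the canonical sampling days {0,1,2,3,7,10,21,30}
  with multiplicative lognormal measurement noise;
* column-leaching observations produced by an equilibrium split
  ``fraction_in_soil = Kd*(m/V) / (1 + Kd*(m/V))`` of the applied amount,
  with lognormal noise on both fractions;
* per-soil "true" DT50 and Kd generated from the published pedotransfer
  coefficient sets with Gaussian residuals of the published magnitude.

All randomness flows from one seed through named substreams so each stage
can be regenerated independently and reproducibly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .kinetics import CANONICAL_DAYS, DecaySeries, predict_concentration
from .mobility import LeachObservation
from .pedotransfer import PedotransferModel, SoilSample, predict, published_models

__all__ = [
    "DEFAULT_RANGES",
    "DEFAULT_CORRELATION",
    "PROPERTY_ORDER",
    "SoilGeneratorConfig",
    "StudyConfig",
    "TruthRecord",
    "StudyBundle",
    "generate_soils",
    "generate_decay",
    "generate_leach",
    "generate_study",
    "write_study_csvs",
]

#: Property order used for the correlation matrix (transformed scale).
PROPERTY_ORDER = ("fe_ox", "al_ox", "clay", "som", "cec", "ph")

#: (minimum, median, maximum) of each soil property across the calibration
#: soils. Units as in :class:`soilfate.pedotransfer.SoilSample`.
DEFAULT_RANGES = {
    "ph": (3.1, 5.9, 7.8),
    "cec": (6.9, 232.0, 821.0),
    "som": (0.3, 10.0, 57.0),
    "clay": (1.0, 16.0, 53.0),
    "al_ox": (1.2, 33.0, 152.0),
    "fe_ox": (2.0, 88.0, 897.0),
}

#: Target Pearson correlations between properties on the analysis scale
#: (log10 except pH), ordered per PROPERTY_ORDER.
DEFAULT_CORRELATION = np.array([
    #  fe_ox  al_ox   clay    som    cec     ph
    [1.00, 0.38, 0.21, 0.42, 0.37, -0.27],  # fe_ox
    [0.38, 1.00, 0.63, 0.64, 0.70, -0.14],  # al_ox
    [0.21, 0.63, 1.00, 0.31, 0.61, 0.09],   # clay
    [0.42, 0.64, 0.31, 1.00, 0.89, -0.17],  # som
    [0.37, 0.70, 0.61, 0.89, 1.00, -0.03],  # cec
    [-0.27, -0.14, 0.09, -0.17, -0.03, 1.00],  # ph
])

#: Fallback median log10 Kd for compounds without a published Kd model,
#: with a between-soil spread used when generating their truths.
_MEDIAN_LOG10_KD = {"DOX": 2.07, "FLUM": 2.07, "TMP": 2.14, "ENRO": 2.00}
_FALLBACK_KD_SPREAD = 0.2

#: Compounds with a published DT50 model (decay series are generated for
#: these; ENRO yielded no usable decay data and has none).
DECAY_COMPOUNDS = ("DOX", "FLUM", "LINCO", "OTC", "SDZ", "SDX", "TMP", "TYL")
LEACH_COMPOUNDS = DECAY_COMPOUNDS + ("ENRO",)


@dataclass
class SoilGeneratorConfig:
    n_soils: int = 29
    ranges: dict = field(default_factory=lambda: dict(DEFAULT_RANGES))
    correlation: np.ndarray = field(
        default_factory=lambda: DEFAULT_CORRELATION.copy()
    )
    shallow_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_soils < 1:
            raise ValueError("n_soils must be positive")
        if not 0.0 <= self.shallow_fraction <= 1.0:
            raise ValueError("shallow_fraction must lie in [0, 1]")
        corr = np.asarray(self.correlation, dtype=float)
        if corr.shape != (len(PROPERTY_ORDER),) * 2:
            raise ValueError("correlation must be 6x6")
        if not np.allclose(corr, corr.T):
            raise ValueError("correlation must be symmetric")
        self.correlation = corr
        for prop, (lo, med, hi) in self.ranges.items():
            if not lo <= med <= hi:
                raise ValueError(f"{prop}: need min <= median <= max")
            if prop != "ph" and lo <= 0:
                raise ValueError(f"{prop}: log-scale property must be positive")


@dataclass
class StudyConfig:
    """Full-study generation settings; defaults reproduce the published
    design (29 soils, 100 ng/g fortification, 400 ng / 5 g / 10 mL leach,
    duplicate columns)."""

    soil: SoilGeneratorConfig = field(default_factory=SoilGeneratorConfig)
    decay_times: tuple = CANONICAL_DAYS
    decay_noise_sigma: float = 0.05
    leach_cv: float = 0.05
    leach_replicates: int = 2
    applied_ng: float = 400.0
    soil_mass_g: float = 5.0
    eluate_volume_ml: float = 10.0
    lod_ng: float = 1.0
    decay_lod_fraction: float = 0.01
    seed: int = 0


@dataclass
class TruthRecord:
    """Ground truth stored alongside generated data for recovery tests."""

    soil_id: str
    compound: str
    true_dt50: float  # days; nan when the compound has no decay data
    true_kd: float  # L/kg
    kinetic_model: str = "SFO"
    kinetic_params: dict = field(default_factory=dict)
    dt50_model: str = ""  # provenance of the DT50 truth
    kd_model: str = ""


@dataclass
class StudyBundle:
    soils: list[SoilSample]
    decay: list[DecaySeries]
    leach: list[LeachObservation]
    truths: list[TruthRecord]


def _repair_correlation(corr: np.ndarray) -> np.ndarray:
    """Clip negative eigenvalues and rescale to unit diagonal so the copula
    has a valid positive semi-definite correlation matrix."""
    vals, vecs = np.linalg.eigh(corr)
    if vals.min() >= 1e-10:
        return corr
    vals = np.clip(vals, 1e-10, None)
    fixed = vecs @ np.diag(vals) @ vecs.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return fixed


def _two_piece_quantile(u: np.ndarray, lo: float, med: float, hi: float
                        ) -> np.ndarray:
    """Quantile function of a two-piece triangular distribution with mode at
    the median: density rises linearly from ``lo`` to ``med`` and falls
    linearly to ``hi``; each half carries probability 1/2, so the bounds are
    respected and the median is exact."""
    u = np.asarray(u, dtype=float)
    left = lo + (med - lo) * np.sqrt(np.clip(2.0 * u, 0.0, 1.0))
    right = hi - (hi - med) * np.sqrt(np.clip(2.0 * (1.0 - u), 0.0, 1.0))
    return np.where(u <= 0.5, left, right)


def generate_soils(
    config: SoilGeneratorConfig, rng: np.random.Generator | None = None
) -> list[SoilSample]:
    """Draw correlated soil-property vectors via a Gaussian copula.

    Normal scores with the (repaired) target correlation are mapped through
    the standard-normal CDF and then through each property's two-piece
    triangular quantile on the transformed scale; log-scale properties are
    back-transformed with ``10**x``.  Depth class is an independent
    Bernoulli(shallow_fraction) draw.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    corr = _repair_correlation(config.correlation)
    z = rng.multivariate_normal(
        np.zeros(len(PROPERTY_ORDER)), corr, size=config.n_soils,
        method="cholesky",
    )
    u = stats.norm.cdf(z)
    columns = {}
    for j, prop in enumerate(PROPERTY_ORDER):
        lo, med, hi = config.ranges[prop]
        if prop == "ph":
            columns[prop] = _two_piece_quantile(u[:, j], lo, med, hi)
        else:
            q = _two_piece_quantile(
                u[:, j], math.log10(lo), math.log10(med), math.log10(hi)
            )
            columns[prop] = 10.0**q
    shallow = rng.random(config.n_soils) < config.shallow_fraction
    width = len(str(config.n_soils))
    return [
        SoilSample(
            soil_id=f"S{i + 1:0{width}d}",
            ph=float(columns["ph"][i]), cec=float(columns["cec"][i]),
            som=float(columns["som"][i]), clay=float(columns["clay"][i]),
            al_ox=float(columns["al_ox"][i]), fe_ox=float(columns["fe_ox"][i]),
            depth_class="shallow" if shallow[i] else "deep",
            land_use="synthetic",
        )
        for i in range(config.n_soils)
    ]


def generate_decay(
    soil_id: str,
    compound: str,
    truth: TruthRecord,
    times=CANONICAL_DAYS,
    noise_sigma: float = 0.05,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> DecaySeries:
    """Decay series from a true kinetic model with multiplicative noise.

    Each observation is the model curve times ``exp(N(0, sigma))`` — a
    lognormal factor with median one, matching relative (CV-like)
    measurement error.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    times = np.asarray(times, dtype=float)
    params = truth.kinetic_params or {"C0": 1.0,
                                      "k": math.log(2.0) / truth.true_dt50}
    curve = predict_concentration(truth.kinetic_model, params, times)
    if noise_sigma > 0:
        curve = curve * np.exp(rng.normal(0.0, noise_sigma, size=times.size))
    return DecaySeries(soil_id=soil_id, compound=compound, times=times,
                       values=curve)


def generate_leach(
    soil_id: str,
    compound: str,
    true_kd: float,
    applied_ng: float = 400.0,
    soil_mass_g: float = 5.0,
    eluate_volume_ml: float = 10.0,
    cv: float = 0.05,
    lod_ng: float = 1.0,
    replicate: int = 1,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> LeachObservation:
    """One leaching replicate from an equilibrium soil/water split.

    With ``r = soil_mass/eluate_volume`` (kg/L), the sorbed fraction is
    ``Kd*r / (1 + Kd*r)``; both recovered amounts get independent lognormal
    noise of coefficient of variation ``cv``.  Whether an amount counts as
    a nondetect is decided downstream against the stored LODs.
    """
    if true_kd <= 0:
        raise ValueError("true Kd must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)
    ratio = soil_mass_g / eluate_volume_ml  # g/mL == kg/L
    frac_soil = true_kd * ratio / (1.0 + true_kd * ratio)
    amount_soil = applied_ng * frac_soil
    amount_water = applied_ng * (1.0 - frac_soil)
    if cv > 0:
        sigma = math.sqrt(math.log(1.0 + cv**2))
        amount_soil *= float(rng.lognormal(-sigma**2 / 2.0, sigma))
        amount_water *= float(rng.lognormal(-sigma**2 / 2.0, sigma))
    return LeachObservation(
        soil_id=soil_id, compound=compound, amount_soil=amount_soil,
        amount_water=amount_water, soil_mass=soil_mass_g,
        eluate_volume=eluate_volume_ml, lod_soil=lod_ng, lod_water=lod_ng,
        replicate=replicate, applied=applied_ng,
    )


def _truth_from_models(
    soil: SoilSample,
    compound: str,
    dt50_models: dict[str, PedotransferModel],
    kd_models: dict[str, PedotransferModel],
    rng: np.random.Generator,
) -> TruthRecord:
    """Per-soil true DT50/Kd from the published pedotransfer coefficient
    sets, with Gaussian residuals of magnitude se(Y); compounds without a
    published Kd model get a median-anchored lognormal Kd instead."""
    true_dt50 = math.nan
    dt50_src = ""
    if compound in dt50_models:
        model = dt50_models[compound]
        log_dt50 = predict(model, soil)["log10"] + rng.normal(0.0, model.se_y)
        true_dt50 = 10.0**log_dt50
        dt50_src = "published DT50 model + N(0, se_y)"
    if compound in kd_models:
        model = kd_models[compound]
        log_kd = predict(model, soil)["log10"] + rng.normal(0.0, model.se_y)
        kd_src = "published Kd model + N(0, se_y)"
    else:
        log_kd = _MEDIAN_LOG10_KD[compound] + rng.normal(
            0.0, _FALLBACK_KD_SPREAD
        )
        kd_src = "median log10 Kd + N(0, 0.2) (no published model)"
    params = (
        {"C0": 1.0, "k": math.log(2.0) / true_dt50}
        if math.isfinite(true_dt50) else {}
    )
    return TruthRecord(
        soil_id=soil.soil_id, compound=compound, true_dt50=true_dt50,
        true_kd=10.0**log_kd, kinetic_model="SFO", kinetic_params=params,
        dt50_model=dt50_src, kd_model=kd_src,
    )


def generate_study(config: StudyConfig | None = None) -> StudyBundle:
    """Compose soils, truths, decay series and leaching observations.

    Substreams (soils / truths / decay / leach) are spawned from the single
    study seed so each stage is independently reproducible.
    """
    if config is None:
        config = StudyConfig()
    root = np.random.SeedSequence(config.seed)
    soil_ss, truth_ss, decay_ss, leach_ss = root.spawn(4)

    soil_cfg = SoilGeneratorConfig(**{**config.soil.__dict__})
    soils = generate_soils(soil_cfg, rng=np.random.default_rng(soil_ss))

    models = published_models()
    dt50_models = {m.compound: m for m in models if m.response == "DT50"}
    kd_models = {m.compound: m for m in models if m.response == "Kd"}

    truth_rng = np.random.default_rng(truth_ss)
    decay_rng = np.random.default_rng(decay_ss)
    leach_rng = np.random.default_rng(leach_ss)

    truths: list[TruthRecord] = []
    decay: list[DecaySeries] = []
    leach: list[LeachObservation] = []
    for soil in soils:
        for compound in LEACH_COMPOUNDS:
            truth = _truth_from_models(
                soil, compound, dt50_models, kd_models, truth_rng
            )
            truths.append(truth)
            if compound in DECAY_COMPOUNDS:
                decay.append(
                    generate_decay(
                        soil.soil_id, compound, truth,
                        times=config.decay_times,
                        noise_sigma=config.decay_noise_sigma, rng=decay_rng,
                    )
                )
            for rep in range(1, config.leach_replicates + 1):
                leach.append(
                    generate_leach(
                        soil.soil_id, compound, truth.true_kd,
                        applied_ng=config.applied_ng,
                        soil_mass_g=config.soil_mass_g,
                        eluate_volume_ml=config.eluate_volume_ml,
                        cv=config.leach_cv, lod_ng=config.lod_ng,
                        replicate=rep, rng=leach_rng,
                    )
                )
    return StudyBundle(soils=soils, decay=decay, leach=leach, truths=truths)


def write_study_csvs(bundle: StudyBundle, outdir,
                     decay_lod_fraction: float = 0.01) -> dict[str, str]:
    """Write the bundle as the pipeline's input CSVs plus a truths table.

    Returns a mapping of logical name to file path.
    """
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    soils = pd.DataFrame(
        [
            {
                "soil_id": s.soil_id, "ph": s.ph, "cec": s.cec, "som": s.som,
                "clay": s.clay, "al_ox": s.al_ox, "fe_ox": s.fe_ox,
                "depth_class": s.depth_class, "land_use": s.land_use,
            }
            for s in bundle.soils
        ]
    )
    decay_rows = []
    for series in bundle.decay:
        for t, v in zip(series.times, series.values):
            decay_rows.append(
                {
                    "soil_id": series.soil_id, "compound": series.compound,
                    "day": t, "value": v, "unit": "fraction",
                    "lod": decay_lod_fraction,
                }
            )
    decay = pd.DataFrame(decay_rows)
    leach = pd.DataFrame(
        [
            {
                "soil_id": o.soil_id, "compound": o.compound,
                "replicate": o.replicate, "amount_soil_ng": o.amount_soil,
                "amount_water_ng": o.amount_water,
                "soil_mass_g": o.soil_mass,
                "eluate_volume_ml": o.eluate_volume,
                "lod_soil_ng": o.lod_soil, "lod_water_ng": o.lod_water,
                "applied_ng": o.applied,
            }
            for o in bundle.leach
        ]
    )
    truths = pd.DataFrame(
        [
            {
                "soil_id": t.soil_id, "compound": t.compound,
                "true_dt50_days": t.true_dt50, "true_kd_l_per_kg": t.true_kd,
                "kinetic_model": t.kinetic_model,
                "dt50_model": t.dt50_model, "kd_model": t.kd_model,
            }
            for t in bundle.truths
        ]
    )
    paths = {}
    for name, frame in (("soils", soils), ("decay", decay),
                        ("leach", leach), ("truths", truths)):
        path = outdir / f"{name}.csv"
        frame.to_csv(path, index=False)
        paths[name] = str(path)
    return paths
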