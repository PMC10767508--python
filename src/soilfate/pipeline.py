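"""End-to-end orchestration: kinetics -> mobility -> pedotransfer -> report.

Each stage writes a plain CSV (units embedded in the column names) and the
run assembles a reproduction report that mirrors the layout of the study's
summary tables: per-compound DT50 and log10 Kd ranges with max/min ratios,
the log10 Koc summary, the soil-property correlation matrix, and the fitted
pedotransfer model table.  Every excluded series or observation is logged
with its identifier and reason; input rows always reconcile as
used + excluded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import kinetics, mobility, pedotransfer

__all__ = ["RunConfig", "ReproductionReport", "summarize_compound",
           "run_pipeline"]


@dataclass
class RunConfig:
    soils_csv: str
    decay_csv: str
    leach_csv: str
    outdir: str = "results"
    chi2_sfo: float = 5.0
    chi2_max: float = 10.0
    kd_log_flag: float = 2.0
    som_to_oc_factor: float = mobility.VAN_BEMMELEN_FACTOR
    include_rough_in_fit: bool = False
    run_kinetics: bool = True
    run_mobility: bool = True
    run_pedotransfer: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.chi2_sfo <= 0 or self.chi2_max <= 0 or self.kd_log_flag <= 0:
            raise ValueError("thresholds must be positive")
        if self.chi2_sfo > self.chi2_max:
            raise ValueError("chi2_sfo must not exceed chi2_max")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


@dataclass
class ReproductionReport:
    dt50_summary: pd.DataFrame
    kd_summary: pd.DataFrame
    koc_summary: pd.DataFrame
    correlation: pd.DataFrame
    model_table: pd.DataFrame
    exclusions: list[str] = field(default_factory=list)

    def to_markdown(self) -> str:
        def fmt(frame: pd.DataFrame) -> str:
            out = frame.copy()
            for col in out.columns:
                if pd.api.types.is_float_dtype(out[col]):
                    if "ratio" in col:
                        out[col] = out[col].map(
                            lambda v: "" if pd.isna(v)
                            else f"{v:.2g}" if v < 100 else f"{v:.0f}"
                        )
                    else:
                        out[col] = out[col].map(
                            lambda v: "" if pd.isna(v) else f"{v:.2f}"
                        )
            return out.to_markdown(index=False)

        parts = [
            "# Reproduction report", "",
            "## DT50 per compound (days)", fmt(self.dt50_summary), "",
            "## log10 Kd per compound (L/kg)", fmt(self.kd_summary), "",
            "## log10 Koc per compound (L/kg OC)", fmt(self.koc_summary), "",
            "## Soil-property Pearson correlations (analysis scale)",
            self.correlation.round(2).to_markdown(), "",
            "## Best pedotransfer models (lowest AIC)",
            fmt(self.model_table), "",
            "## Exclusions",
        ]
        parts += [f"- {line}" for line in self.exclusions] or ["- none"]
        return "\n".join(parts) + "\n"


def summarize_compound(values, log_scale: bool = False) -> dict[str, float]:
    """Median / min / max / n and the max-min ratio for one compound.

    ``log_scale=True`` means the values are log10-transformed; the ratio is
    then computed on the back-transformed linear scale.
    """
    arr = np.asarray(list(values), dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        raise ValueError("no values to summarize")
    linear = 10.0**arr if log_scale else arr
    ratio = (
        mobility.range_ratio(linear) if arr.size >= 2 and linear.min() > 0
        else (1.0 if arr.size == 1 else math.nan)
    )
    return {
        "median": float(np.median(arr)), "min": float(arr.min()),
        "max": float(arr.max()), "n": int(arr.size), "ratio": float(ratio),
    }


def _summary_frame(frame: pd.DataFrame, value_col: str,
                   log_scale: bool) -> pd.DataFrame:
    rows = []
    for compound, grp in frame.groupby("compound", sort=True):
        vals = grp[value_col].dropna()
        if vals.empty:
            rows.append({"compound": compound, "median": math.nan,
                         "min": math.nan, "max": math.nan, "n": 0,
                         "ratio": math.nan})
            continue
        rows.append({"compound": compound, **summarize_compound(
            vals, log_scale=log_scale)})
    return pd.DataFrame(rows)


def _model_row(model: pedotransfer.PedotransferModel) -> dict:
    row = {
        "response": model.response, "compound": model.compound,
        "intercept": model.intercept,
    }
    for term in pedotransfer.CANDIDATE_TERMS:
        row[term] = model.coefficients.get(term, math.nan)
        row[f"stars_{term}"] = model.significance.get(term, "")
    row.update(r2=model.r2, r2_adj=model.r2_adj, se_y=model.se_y,
               f_stat=model.f_stat, p_value=model.p_value,
               n_obs=model.n_obs, aic=model.aic)
    return row


def run_pipeline(config: RunConfig) -> ReproductionReport:
    """Run the full chain on the configured input CSVs.

    Writes ``kinetic_fits.csv``, ``partition.csv``, ``pedotransfer_models.csv``,
    ``pedotransfer_ranking.csv``, ``report.md`` and ``run_log.txt`` under
    ``config.outdir`` and returns the assembled report.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    exclusions: list[str] = []

    soils = pedotransfer.read_soils_csv(config.soils_csv)
    soils_frame = pedotransfer.soils_to_frame(soils)
    correlation = pedotransfer.pearson_matrix(soils).r

    # --- kinetics ---------------------------------------------------------
    dt50_table = pd.DataFrame(
        columns=["soil_id", "compound", "dt50_days", "accepted"]
    )
    if config.run_kinetics:
        series = kinetics.read_decay_csv(config.decay_csv)
        fits, log = kinetics.fit_decay_table(
            series, sfo_threshold=config.chi2_sfo,
            max_threshold=config.chi2_max,
        )
        exclusions.extend(log)
        fits.to_csv(outdir / "kinetic_fits.csv", index=False)
        dt50_table = fits

    # --- mobility ---------------------------------------------------------
    kd_table = pd.DataFrame(
        columns=["soil_id", "compound", "kd_l_per_kg", "log10_kd",
                 "koc_l_per_kg_oc", "log10_koc", "rough_estimate"]
    )
    if config.run_mobility:
        observations = mobility.read_leach_csv(config.leach_csv)
        oc = {
            soil_id: mobility.som_to_oc(row["som"], config.som_to_oc_factor)
            for soil_id, row in soils_frame.iterrows()
        }
        kd_table, log = mobility.partition_table(observations, oc_percent=oc)
        exclusions.extend(log)
        kd_table.to_csv(outdir / "partition.csv", index=False)

    # --- pedotransfer -----------------------------------------------------
    best_models: list[pedotransfer.PedotransferModel] = []
    ranking_rows: list[dict] = []
    if config.run_pedotransfer:
        responses = []
        if config.run_kinetics and not dt50_table.empty:
            usable = dt50_table[dt50_table["accepted"]]
            dropped = len(dt50_table) - len(usable)
            if dropped:
                exclusions.append(
                    f"DT50 regression: {dropped} series excluded by the "
                    f"{config.chi2_max}% error-level filter"
                )
            responses.append(("DT50", usable, "dt50_days", False))
        if config.run_mobility and not kd_table.empty:
            usable = kd_table
            if not config.include_rough_in_fit:
                usable = kd_table[~kd_table["rough_estimate"]]
                dropped = len(kd_table) - len(usable)
                if dropped:
                    exclusions.append(
                        f"Kd regression: {dropped} pooled values excluded as "
                        f"rough estimates (log10 Kd > {config.kd_log_flag})"
                    )
            responses.append(("Kd", usable, "kd_l_per_kg", True))

        for response, table, col, take_log in responses:
            for compound, grp in table.groupby("compound", sort=True):
                merged = grp.merge(
                    soils_frame.reset_index(), on="soil_id", how="inner"
                ).dropna(subset=[col])
                y = np.log10(merged[col]) if take_log else np.log10(
                    merged[col]
                )
                n_terms = len(pedotransfer.CANDIDATE_TERMS)
                if len(merged) <= n_terms + 1:
                    exclusions.append(
                        f"{response}/{compound}: only {len(merged)} usable "
                        "soils; subset regression refused"
                    )
                    continue
                ranked = pedotransfer.all_subsets_search(
                    merged.set_index("soil_id"), y.to_numpy(),
                    response=response, compound=compound,
                )
                best_models.append(ranked[0])
                for rank, model in enumerate(ranked):
                    ranking_rows.append(
                        {
                            "response": response, "compound": compound,
                            "rank": rank, "terms": "+".join(model.terms),
                            "aic": model.aic, "r2": model.r2,
                            "p_value": model.p_value,
                        }
                    )
        pd.DataFrame([_model_row(m) for m in best_models]).to_csv(
            outdir / "pedotransfer_models.csv", index=False
        )
        pd.DataFrame(ranking_rows).to_csv(
            outdir / "pedotransfer_ranking.csv", index=False
        )

    # --- report -----------------------------------------------------------
    dt50_usable = (
        dt50_table[dt50_table.get("accepted", pd.Series(dtype=bool))]
        if not dt50_table.empty else dt50_table
    )
    dt50_summary = (
        _summary_frame(dt50_usable, "dt50_days", log_scale=False)
        if not dt50_usable.empty
        else pd.DataFrame(columns=["compound", "median", "min", "max", "n",
                                   "ratio"])
    )
    kd_summary = (
        _summary_frame(kd_table, "log10_kd", log_scale=True)
        if not kd_table.empty
        else pd.DataFrame(columns=["compound", "median", "min", "max", "n",
                                   "ratio"])
    )
    koc_summary = (
        _summary_frame(kd_table.dropna(subset=["log10_koc"]), "log10_koc",
                       log_scale=True)
        if "log10_koc" in kd_table and kd_table["log10_koc"].notna().any()
        else pd.DataFrame(columns=["compound", "median", "min", "max", "n",
                                   "ratio"])
    )
    model_table = (
        pd.DataFrame([_model_row(m) for m in best_models])
        if best_models else pd.DataFrame()
    )
    report = ReproductionReport(
        dt50_summary=dt50_summary, kd_summary=kd_summary,
        koc_summary=koc_summary, correlation=correlation,
        model_table=model_table, exclusions=exclusions,
    )
    (outdir / "report.md").write_text(report.to_markdown())
    (outdir / "run_log.txt").write_text(
        "\n".join(exclusions) + ("\n" if exclusions else "")
    )
    return report
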