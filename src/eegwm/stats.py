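"""ANOVA comparison of accuracy distributions and report rendering.

One-way ANOVA compares accuracy across frequency bands; a bands x
condition (actual vs permutation chance) two-way ANOVA verifies that
decoding differs from its no-information baseline. Effect size is
partial eta-squared, SS_effect / (SS_effect + SS_error); observed power
is the post-hoc noncentral-F convention with noncentrality
lambda = F * df_effect at alpha = 0.05. Accuracies enter untransformed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import pingouin as pg
from scipy.stats import f as f_dist
from scipy.stats import ncf


class StatsError(Exception):
    pass


@dataclass(frozen=True)
class AnovaResult:
    source: str
    ss_effect: float
    ss_error: float
    df_effect: int
    df_error: int
    ms_effect: float
    f: float
    p: float
    partial_eta_sq: float
    power: float


def partial_eta_sq(ss_effect: float, ss_error: float) -> float:
    """Effect size SS_eff / (SS_eff + SS_err)."""
    if ss_effect < 0 or ss_error < 0:
        raise StatsError("sums of squares must be non-negative")
    denom = ss_effect + ss_error
    return ss_effect / denom if denom else 0.0


def observed_power(
    f_value: float, df_effect: int, df_error: int, alpha: float = 0.05
) -> float:
    """Post-hoc power from the noncentral F with lambda = F * df_effect."""
    if df_effect < 1 or df_error < 1:
        raise StatsError("degrees of freedom must be positive")
    crit = f_dist.ppf(1 - alpha, df_effect, df_error)
    lam = max(float(f_value), 0.0) * df_effect
    if lam < 1e-12:  # scipy's ncf is numerically unreliable at zero noncentrality
        return float(alpha)
    return float(ncf.sf(crit, df_effect, df_error, lam))


def _result_from_row(row: pd.Series, ss_error: float, df_error: int) -> AnovaResult:
    f_value = float(row["F"])
    return AnovaResult(
        source=str(row["Source"]),
        ss_effect=float(row["SS"]),
        ss_error=float(ss_error),
        df_effect=int(row["DF"]),
        df_error=int(df_error),
        ms_effect=float(row["MS"]),
        f=f_value,
        p=float(row["p_unc"]),
        partial_eta_sq=partial_eta_sq(float(row["SS"]), float(ss_error)),
        power=observed_power(f_value, int(row["DF"]), int(df_error)),
    )


def one_way_anova(groups: dict[str, np.ndarray] | list[np.ndarray]) -> AnovaResult:
    """Standard one-way decomposition across named groups."""
    if not isinstance(groups, dict):
        groups = {f"g{i}": g for i, g in enumerate(groups)}
    if len(groups) < 2 or any(len(np.asarray(g)) < 2 for g in groups.values()):
        raise StatsError("need >= 2 groups with >= 2 values each")
    df = pd.DataFrame(
        [(name, float(v)) for name, vals in groups.items() for v in np.asarray(vals)],
        columns=["group", "y"],
    )
    tab = pg.anova(data=df, dv="y", between="group", detailed=True)
    eff = tab[tab["Source"] == "group"].iloc[0]
    err = tab[tab["Source"] == "Within"].iloc[0]
    return _result_from_row(eff, err["SS"], err["DF"])


def two_way_anova(
    values: np.ndarray, factor_band: np.ndarray, factor_condition: np.ndarray
) -> dict[str, AnovaResult]:
    """Crossed band x condition ANOVA with interaction.

    Returns results keyed "band", "condition", "interaction".
    """
    df = pd.DataFrame(
        {
            "y": np.asarray(values, dtype=float),
            "band": np.asarray(factor_band),
            "condition": np.asarray(factor_condition),
        }
    )
    cells = df.groupby(["band", "condition"]).size()
    n_bands = df["band"].nunique()
    n_cond = df["condition"].nunique()
    if len(cells) != n_bands * n_cond:
        raise StatsError("incomplete crossed design: empty cells")
    tab = pg.anova(data=df, dv="y", between=["band", "condition"])
    err = tab[tab["Source"] == "Residual"].iloc[0]
    out = {}
    for source, key in (
        ("band", "band"),
        ("condition", "condition"),
        ("band * condition", "interaction"),
    ):
        row = tab[tab["Source"] == source].iloc[0]
        out[key] = _result_from_row(row, err["SS"], err["DF"])
    return out


# ---------------------------------------------------------------------------
# report rendering


def _anova_frame(results: dict[str, AnovaResult]) -> pd.DataFrame:
    rows = []
    for scheme, r in results.items():
        rows.append(
            {
                "scheme": scheme,
                "source": r.source,
                "SS": round(r.ss_effect, 2),
                "df": r.df_effect,
                "MS": round(r.ms_effect, 2),
                "F": round(r.f, 2),
                "p": round(r.p, 4),
                "partial_eta_sq": round(r.partial_eta_sq, 2),
                "power": round(r.power, 2),
                "SS_error": round(r.ss_error, 2),
                "df_error": r.df_error,
            }
        )
    return pd.DataFrame(rows)


def render_tables(
    summaries: dict[str, dict[str, dict[str, tuple[float, float]]]],
    anovas: dict[str, dict[str, AnovaResult]],
    out_dir,
) -> list[Path]:
    """Write per-family accuracy summaries and ANOVA tables as TSV.

    ``summaries[family][scheme][band] = (mean, sd)``;
    ``anovas[family][scheme] = AnovaResult`` (one-way across bands).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for family, per_scheme in summaries.items():
        bands = list(next(iter(per_scheme.values())))
        rows = []
        for band in bands:
            row = {"band": band}
            for scheme, per_band in per_scheme.items():
                mean, sd = per_band[band]
                row[f"{scheme}_mean"] = f"{mean:.2f}"
                row[f"{scheme}_sd"] = f"{sd:.2f}"
            rows.append(row)
        path = out_dir / f"accuracy_summary_{family}.tsv"
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
        written.append(path)
    for family, per_scheme in anovas.items():
        path = out_dir / f"anova_{family}.tsv"
        _anova_frame(per_scheme).to_csv(path, sep="\t", index=False)
        written.append(path)
    return written
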