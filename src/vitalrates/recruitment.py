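"""Recruitment, source-population contribution, movement, 0+ size.

Covers the annual-scale analyses around the core growth/survival models:

- classification of "late incomers" (immigrants from the unsampled source
  reach, recognizable by an intact adipose fin at an age where local fish
  would already have been clipped) and their proportion per year;
- lagged Pearson correlations between 0+ density and older-fish density
  (recruitment-driven dynamics check);
- AIC-ranked recruitment models of 0+ September density on lagged spawner
  density and spring degree-days, with modest-df regression-spline
  candidates standing in for penalized smoothers (defensible at ~10 annual
  data points, and keeps every candidate an ordinary least-squares fit);
- the log-log regression of mean 0+ length on older-fish density and
  degree-days to 31 August;
- movement summaries and a logistic GLM of "ever sampled in more than one
  sector" on the number of years a fish was sampled;
- a hypothesis-generating flag for cohorts whose fitted growth is anomalous
  relative to the cross-cohort median (fast-growing cohorts can point to
  unobserved density crashes before the study window).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.interpolate import BSpline
from scipy.stats import pearsonr

from .modelsel import FitResult, rank_by_aic

__all__ = [
    "classify_origin",
    "incomer_proportion",
    "lagged_density_correlation",
    "fit_recruitment",
    "fit_size_at_age0",
    "movement_analysis",
    "MovementSummary",
    "flag_anomalous_cohorts",
]


def classify_origin(encounters: pd.DataFrame) -> pd.Series:
    """Early/late-incomer classification of tagged fish from fin status.

    A fish first handled (fin intact at first capture) at 0+ in September or
    1+ in June is local or an early incomer ("early"); a fish whose first
    capture is later than that must have immigrated at age 1+ September or
    older ("late").  Fish born before the fin-clip protocol started (their
    0+ September predates the first occasion) cannot be classified and are
    returned as "unknown".  Returns a Series indexed by tag id.
    """
    tags = encounters["tag_id"].fillna("").astype(str)
    df = encounters[tags.str.len() > 0].copy()
    df["date"] = pd.to_datetime(df["date"])
    df["age_years"] = pd.to_numeric(df["age_years"], errors="coerce")
    study_start_year = pd.to_datetime(encounters["date"]).dt.year.min()
    first = df.sort_values(["date", "pass"]).groupby("tag_id").first()
    month = first["date"].dt.month
    age = first["age_years"]
    cohort = first["date"].dt.year - age
    intact = first["fin_clipped"].astype(int) == 0
    at_early_stage = ((age < 1) & (month == 9)) | ((age == 1) & (month == 6))
    # intact fin past the 0+ Sep / 1+ Jun stages => immigrated at 1+ Sep or
    # older; a fin already clipped at tagging means an earlier (untagged)
    # handling, which overwhelmingly happens at 0+ September => early
    out = np.where(intact & ~at_early_stage, "late", "early")
    out = np.where(cohort < study_start_year, "unknown", out)
    return pd.Series(out, index=first.index, name="origin")


def incomer_proportion(encounters: pd.DataFrame) -> pd.DataFrame:
    """Proportion of late incomers among older fish per September occasion.

    For each September occasion: among sampled fish aged 1+ or older, the
    fraction that were never sampled at 0+ September or 1+ June (i.e. whose
    adipose fin was intact at a first capture past those stages).  Uses fin
    status, not tags, so it is invariant to the tagging threshold.  Returns
    columns ``year``, ``occasion_index``, ``n``, ``n_late``, ``proportion``,
    ``se`` (binomial).
    """
    df = encounters.copy()
    df["tag_id"] = df["tag_id"].fillna("").astype(str)
    df["date"] = pd.to_datetime(df["date"])
    df["age_years"] = pd.to_numeric(df["age_years"], errors="coerce")
    has_tags = (df["tag_id"].str.len() > 0).any()
    origin = classify_origin(df) if has_tags else pd.Series(dtype=object)
    study_start_year = df["date"].dt.year.min()

    # late status per sampled fish: intact fin now at 1+ Sep or older proves
    # a first capture past the 0+ Sep / 1+ Jun stages; previously clipped
    # fish carry their first-capture classification through their tag.
    # Fish born before the clip protocol started are unclassifiable and
    # excluded from the denominator.
    rows = []
    for occ, grp in df.groupby("occasion_index"):
        date = grp["date"].iloc[0]
        if date.month != 9:
            continue
        grp = grp[(date.year - grp["age_years"]) >= study_start_year]
        older = grp[grp["age_years"] >= 1]
        if older.empty:
            rows.append(
                {"year": date.year, "occasion_index": occ, "n": 0, "n_late": 0,
                 "proportion": np.nan, "se": np.nan}
            )
            continue
        intact = (older["fin_clipped"].astype(int) == 0).to_numpy()
        tagged_late = (
            older["tag_id"].map(origin).fillna("early") == "late"
        ).to_numpy()
        n = len(older)
        n_late = int((intact | tagged_late).sum())
        prop = n_late / n
        rows.append(
            {
                "year": date.year,
                "occasion_index": occ,
                "n": n,
                "n_late": n_late,
                "proportion": prop,
                "se": float(np.sqrt(prop * (1 - prop) / n)),
            }
        )
    return pd.DataFrame(rows)


def lagged_density_correlation(series: pd.DataFrame, lags=(1, 2)) -> pd.DataFrame:
    """Pearson correlation of 0+ density at year t with older-fish density
    at t+lag.

    ``series`` needs columns ``year``, ``d0`` (0+ density) and ``dgt0``
    (older-than-0+ density).  At least 4 overlapping year pairs per lag.
    """
    s = series.set_index("year").sort_index()
    rows = []
    for lag in lags:
        x, y = [], []
        for yr in s.index:
            if yr + lag in s.index:
                x.append(s.loc[yr, "d0"])
                y.append(s.loc[yr + lag, "dgt0"])
        if len(x) < 4:
            raise ValueError(f"fewer than 4 overlapping pairs at lag {lag}")
        r, p = pearsonr(x, y)
        rows.append({"lag": lag, "r": float(r), "p": float(p), "n_pairs": len(x)})
    return pd.DataFrame(rows)


def _spline_cols(x: np.ndarray, df: int) -> np.ndarray:
    """Fixed-df cubic regression-spline columns (no intercept column)."""
    degree = 3
    lo, hi = float(x.min()), float(x.max())
    n_interior = max(df - degree, 0)
    interior = np.quantile(x, np.linspace(0, 1, n_interior + 2)[1:-1]) if n_interior else []
    t = np.r_[[lo] * (degree + 1), interior, [hi] * (degree + 1)]
    B = BSpline.design_matrix(np.clip(x, lo, hi), t, degree).toarray()
    return B[:, 1:]


def _ols_candidates(y: np.ndarray, designs: dict[str, np.ndarray]) -> tuple[pd.DataFrame, dict]:
    fits = {}
    results = []
    for label, X in designs.items():
        Xc = sm.add_constant(X) if X is not None else np.ones((len(y), 1))
        res = sm.OLS(y, Xc).fit()
        npar = Xc.shape[1] + 1  # + residual variance
        est = pd.DataFrame({"name": [f"b{i}" for i in range(Xc.shape[1])],
                            "value": res.params, "se": res.bse})
        fits[label] = res
        results.append(FitResult(label, est, float(res.llf), npar, extra={"ols": res}))
    return rank_by_aic(results), fits


def fit_recruitment(series: pd.DataFrame, spline_df: int = 3) -> tuple[pd.DataFrame, dict]:
    """AIC-ranked models of recruitment R_t (0+ September density).

    Candidates: intercept-only, linear and modest-df spline terms in lagged
    spawner density ``ds_lag1`` and spring degree-days ``gdd_spring``.
    "No predictor wins" is a representable outcome.  ``series`` needs
    columns ``year``, ``r`` plus the predictors; spline candidates are
    skipped with a warning when df exceeds n-2.
    """
    s = series.dropna(subset=["r"]).sort_values("year")
    if len(s) < 6:
        raise ValueError("need at least 6 years of recruitment data")
    y = s["r"].to_numpy(dtype=float)
    ds = s["ds_lag1"].to_numpy(dtype=float)
    gdd = s["gdd_spring"].to_numpy(dtype=float)
    designs: dict[str, np.ndarray | None] = {
        "R ~ 1": None,
        "R ~ Ds(t-1)": ds[:, None],
        "R ~ GDD_spring": gdd[:, None],
        "R ~ Ds(t-1) + GDD_spring": np.column_stack([ds, gdd]),
    }
    if spline_df <= len(s) - 2:
        designs["R ~ s(Ds(t-1))"] = _spline_cols(ds, spline_df)
        designs["R ~ s(GDD_spring)"] = _spline_cols(gdd, spline_df)
    else:
        warnings.warn("spline candidates skipped: df exceeds n-2", stacklevel=2)
    return _ols_candidates(y, designs)


def fit_size_at_age0(series: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """AIC-ranked log-log models of mean 0+ September length.

    Candidates: intercept-only, log older-fish density, degree-days to 31
    August, both, and their interaction.  Requires positive lengths and
    densities.  Returns the ranking (with R^2 column) and fitted models.
    """
    s = series.dropna(subset=["l0_mean"]).sort_values("year")
    if len(s) < 5:
        raise ValueError("need at least 5 years")
    if (s["l0_mean"] <= 0).any() or (s["dgt0"] <= 0).any():
        raise ValueError("lengths and densities must be positive for the log-log model")
    y = np.log(s["l0_mean"].to_numpy(dtype=float))
    logd = np.log(s["dgt0"].to_numpy(dtype=float))
    gdd = s["gdd_aug"].to_numpy(dtype=float)
    gddc = gdd - gdd.mean()
    designs = {
        "logL0 ~ 1": None,
        "logL0 ~ logD": logd[:, None],
        "logL0 ~ GDD_aug": gddc[:, None],
        "logL0 ~ logD + GDD_aug": np.column_stack([logd, gddc]),
        "logL0 ~ logD * GDD_aug": np.column_stack([logd, gddc, logd * gddc]),
    }
    table, fits = _ols_candidates(y, designs)
    table["r2"] = [
        fits[m].rsquared if m in fits else np.nan for m in table["model"]
    ]
    return table, fits


@dataclass
class MovementSummary:
    """Population-level movement summary plus the years-sampled GLM."""

    per_fish: pd.DataFrame
    prop_multi_sector: float
    se_prop: float
    prop_non_adjacent: float
    glm_intercept: float
    glm_slope: float
    se_intercept: float
    se_slope: float
    glm_status: str = "ok"


def movement_analysis(encounters: pd.DataFrame) -> MovementSummary:
    """Sector-use summaries for tagged fish.

    Per fish: number of distinct sectors, number of distinct years sampled,
    whether any pair of used sectors is non-adjacent.  Population level: the
    proportion ever sampled in more than one sector (binomial SE) and a
    logistic GLM of that indicator on years sampled (more years at large ->
    more chances to be caught elsewhere).
    """
    tags_ = encounters["tag_id"].fillna("").astype(str)
    df = encounters[tags_.str.len() > 0].copy()
    if df.empty:
        raise ValueError("no tagged fish")
    df["date"] = pd.to_datetime(df["date"])
    per = (
        df.groupby("tag_id")
        .agg(
            n_sectors=("sector", "nunique"),
            n_years=("date", lambda d: d.dt.year.nunique()),
            sectors=("sector", lambda s: sorted(set(int(v) for v in s))),
        )
        .reset_index()
    )
    per["multi_sector"] = per["n_sectors"] > 1
    per["non_adjacent"] = per["sectors"].apply(
        lambda ss: any(b - a > 1 for a, b in zip(ss, ss[1:]))
    )
    n = len(per)
    prop = per["multi_sector"].mean()
    se = float(np.sqrt(prop * (1 - prop) / n))
    multi = per.loc[per["multi_sector"], ]
    prop_nonadj = float(multi["non_adjacent"].mean()) if len(multi) else 0.0

    gi = gs = sei = ses = np.nan
    status = "ok"
    if per["multi_sector"].nunique() < 2:
        status = "degenerate: response constant, GLM skipped"
    else:
        X = sm.add_constant(per["n_years"].to_numpy(dtype=float))
        try:
            res = sm.GLM(per["multi_sector"].to_numpy(dtype=float), X,
                         family=sm.families.Binomial()).fit()
            gi, gs = float(res.params[0]), float(res.params[1])
            sei, ses = float(res.bse[0]), float(res.bse[1])
        except Exception as exc:  # noqa: BLE001
            status = f"failed: {exc}"
    return MovementSummary(
        per_fish=per,
        prop_multi_sector=float(prop),
        se_prop=se,
        prop_non_adjacent=prop_nonadj,
        glm_intercept=gi,
        glm_slope=gs,
        se_intercept=sei,
        se_slope=ses,
        glm_status=status,
    )


def flag_anomalous_cohorts(
    growth_fit,
    densities: pd.DataFrame | None = None,
    reference_age: float = 3.0,
    flag_level: float = 0.995,
) -> pd.DataFrame:
    """Flag cohorts whose fitted growth is anomalous (hypothesis-generating).

    Takes a growth fit with a cohort term, predicts the mode length at
    ``reference_age`` per cohort with a delta-method CI, and flags cohorts
    whose interval excludes the cross-cohort median prediction.  Because
    every cohort is tested against the median simultaneously, the default
    per-cohort interval is wide (99.5%), keeping the family-wise false-flag
    rate near 5% for ~10 cohorts; ``flag_level`` tunes the trade-off.
    Optionally attaches density z-scores per cohort year.  The output is
    exploratory: a flag suggests (not demonstrates) unusual conditions in
    that cohort's early life, e.g. a density crash before the observation
    window.
    """
    from .growth import predict_mean_trajectory

    model = growth_fit.model
    if "cohort" not in model.levels:
        raise ValueError("growth fit must include a cohort term")
    cohorts = list(model.levels["cohort"])
    if len(cohorts) < 3:
        raise ValueError("need at least 3 fitted cohorts")
    t0 = growth_fit.params.t0
    if reference_age <= t0:
        raise ValueError(f"reference_age must exceed t0 = {t0:.2f}")
    rows = []
    for c in cohorts:
        gv = {"cohort": c}
        for term in model.k_terms + model.linf_terms:
            if term in ("sector",) and term in model.levels:
                gv["sector"] = model.levels["sector"][0]
            if term in model.scaling:
                gv[term] = model.scaling[term][0]
        pred = predict_mean_trajectory(
            growth_fit, [reference_age], group_values=gv, level=flag_level
        )
        rows.append(
            {
                "cohort": c,
                "pred_length_mm": float(pred["mode_length_mm"].iloc[0]),
                "lo": float(pred["lo"].iloc[0]),
                "hi": float(pred["hi"].iloc[0]),
            }
        )
    tab = pd.DataFrame(rows)
    med = tab["pred_length_mm"].median()
    tab["median_pred"] = med
    tab["flagged"] = (tab["lo"] > med) | (tab["hi"] < med)
    if densities is not None and {"year", "dgt0"}.issubset(densities.columns):
        d = densities.set_index("year")["dgt0"]
        z = (d - d.mean()) / (d.std() or 1.0)
        tab["density_z"] = tab["cohort"].map(z)
    tab.attrs["note"] = "hypothesis-generating cohort anomaly flags"
    return tab
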