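"""Two-pass removal (depletion) abundance and density estimation.

Electrofishing with two consecutive passes and a constant per-pass capture
probability ``p`` yields expected catches ``E[c1] = N p`` and
``E[c2] = (N - c1) p``.  The closed-form (Seber/Zippin two-pass) maximum
likelihood estimates are

    N_hat = c1^2 / (c1 - c2),    p_hat = 1 - c2 / c1,

with ``Var(N_hat) = c1^2 c2^2 (c1 + c2) / (c1 - c2)^4``.  Densities are
reported in fish per hectare: ``density = N_hat / area_m2 * 1e4``.

When the second pass does not deplete (``c2 >= c1``) the closed form breaks
down; the estimator falls back to the minimum possible abundance ``c1 + c2``
with an undefined SE and a ``method="fallback"`` flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

M2_PER_HA = 1e4

#: total wetted surface of the study stream, m^2
DEFAULT_AREA_M2 = 746.27


@dataclass
class AbundanceEstimate:
    """Removal-estimator output for one occasion x stratum cell."""

    n_hat: float
    se_n: float
    p_hat: float
    density_ha: float
    se_density_ha: float
    method: str  # "closed-form" | "fallback"
    c1: int = 0
    c2: int = 0


def density_from_abundance(n_hat: float, area_m2: float = DEFAULT_AREA_M2) -> float:
    """Convert an abundance (fish) on a surface (m^2) to fish per hectare."""
    if area_m2 <= 0:
        raise ValueError("area_m2 must be positive")
    return n_hat / area_m2 * M2_PER_HA


def two_pass_estimate(
    c1: int, c2: int, area_m2: float = DEFAULT_AREA_M2
) -> AbundanceEstimate:
    """Closed-form two-pass removal estimate from first/second-pass catches."""
    if c1 < 0 or c2 < 0:
        raise ValueError("catch counts must be non-negative")
    if area_m2 <= 0:
        raise ValueError("area_m2 must be positive")
    scale = M2_PER_HA / area_m2
    if c1 == 0 and c2 == 0:
        return AbundanceEstimate(0.0, 0.0, np.nan, 0.0, 0.0, "closed-form", 0, 0)
    if c1 <= c2:
        warnings.warn(
            f"non-depleting counts (c1={c1} <= c2={c2}); "
            "reporting minimum possible abundance c1+c2",
            stacklevel=2,
        )
        n = float(c1 + c2)
        return AbundanceEstimate(
            n, np.nan, np.nan, n * scale, np.nan, "fallback", c1, c2
        )
    n_hat = c1**2 / (c1 - c2)
    p_hat = 1.0 - c2 / c1
    var_n = c1**2 * c2**2 * (c1 + c2) / (c1 - c2) ** 4
    se_n = float(np.sqrt(var_n))
    return AbundanceEstimate(
        n_hat=float(n_hat),
        se_n=se_n,
        p_hat=float(p_hat),
        density_ha=float(n_hat * scale),
        se_density_ha=float(se_n * scale),
        method="closed-form",
        c1=int(c1),
        c2=int(c2),
    )


def removal_loglik(n: float, p: float, c1: int, c2: int) -> float:
    """Two-pass removal log-likelihood at real-valued ``n`` (gamma-continued).

    ``c1 ~ Binomial(n, p)``, ``c2 ~ Binomial(n - c1, p)`` with factorials
    continued through the gamma function so a fine real grid can be searched.
    Used by tests as an independent check on the closed form.
    """
    from scipy.special import gammaln

    if n < c1 + c2 or not (0 < p < 1):
        return -np.inf

    def logbinom(m, k):
        return gammaln(m + 1) - gammaln(k + 1) - gammaln(m - k + 1)

    ll = logbinom(n, c1) + c1 * np.log(p) + (n - c1) * np.log1p(-p)
    ll += logbinom(n - c1, c2) + c2 * np.log(p) + (n - c1 - c2) * np.log1p(-p)
    return float(ll)


def extract_removal_counts(
    encounters: pd.DataFrame, strata: pd.Series
) -> pd.DataFrame:
    """Count first- and second-pass catches per occasion x stratum.

    ``strata`` is a per-row label aligned with ``encounters``. Returns a tidy
    table with columns ``occasion_index``, ``stratum``, ``c1``, ``c2``.
    """
    df = encounters.assign(stratum=strata.values)
    counts = (
        df.groupby(["occasion_index", "stratum", "pass"], observed=True)
        .size()
        .unstack("pass", fill_value=0)
        .rename(columns={1: "c1", 2: "c2"})
        .reset_index()
    )
    for col in ("c1", "c2"):
        if col not in counts:
            counts[col] = 0
    return counts[["occasion_index", "stratum", "c1", "c2"]]


_STRATUM_RULES = ("age_class", "cohort", "length_threshold")


def density_table(
    encounters: pd.DataFrame,
    strata: str = "age_class",
    area_m2: float = DEFAULT_AREA_M2,
    length_threshold: float = 150.0,
) -> pd.DataFrame:
    """Removal density estimates per occasion and stratum.

    Stratum rules:

    - ``"age_class"``: 0+ versus older-than-0+ (``>0+``). 0+ strata are
      emitted only for September occasions because sub-yearlings emerge just
      before the June sampling and are not yet catchable then.
    - ``"cohort"``: birth-year cohorts (requires an ``age_years`` column).
    - ``"length_threshold"``: fish above/below ``length_threshold`` mm; with
      the 150 mm default the ``>threshold`` stratum is the potential-spawner
      density.

    Returns one row per occasion x stratum with the
    :class:`AbundanceEstimate` fields as columns.
    """
    if strata not in _STRATUM_RULES:
        raise ValueError(
            f"unknown stratum rule {strata!r}; supported: {', '.join(_STRATUM_RULES)}"
        )
    df = encounters.copy()
    if "age_years" in df.columns:
        age = pd.to_numeric(df["age_years"], errors="coerce")
    else:
        age = pd.Series(np.nan, index=df.index)
    age_class = np.where(age < 1.0, "0+", ">0+")

    if strata == "age_class":
        labels = pd.Series(age_class, index=df.index)
    elif strata == "cohort":
        if age.isna().all():
            raise ValueError("cohort strata require an age_years column")
        birth_year = pd.to_datetime(df["date"]).dt.year - np.floor(age).astype(int)
        labels = pd.Series("cohort-" + birth_year.astype(str), index=df.index)
    else:
        labels = pd.Series(
            np.where(
                pd.to_numeric(df["length_mm"]) > length_threshold,
                f">{length_threshold:g}mm",
                f"<={length_threshold:g}mm",
            ),
            index=df.index,
        )

    # 0+ density is estimated in September only
    month = pd.to_datetime(df["date"]).dt.month
    is_sept = (month == 9).to_numpy()
    keep = ~((age_class == "0+") & ~is_sept) if strata == "age_class" else np.ones(len(df), bool)
    counts = extract_removal_counts(df.loc[keep], labels.loc[keep])

    # report zero-catch cells explicitly: full occasion x stratum grid
    occasions = sorted(df["occasion_index"].unique())
    sept_occasions = set(df.loc[is_sept, "occasion_index"].unique())
    all_strata = sorted(counts["stratum"].unique())
    grid = pd.MultiIndex.from_product(
        [occasions, all_strata], names=["occasion_index", "stratum"]
    ).to_frame(index=False)
    if strata == "age_class":
        grid = grid[
            (grid["stratum"] != "0+") | grid["occasion_index"].isin(sept_occasions)
        ]
    counts = grid.merge(counts, how="left", on=["occasion_index", "stratum"]).fillna(
        {"c1": 0, "c2": 0}
    )

    rows = []
    for rec in counts.itertuples(index=False):
        est = two_pass_estimate(int(rec.c1), int(rec.c2), area_m2=area_m2)
        rows.append(
            {
                "occasion_index": rec.occasion_index,
                "stratum": rec.stratum,
                "c1": rec.c1,
                "c2": rec.c2,
                "n_hat": est.n_hat,
                "se_n": est.se_n,
                "p_hat": est.p_hat,
                "density_ha": est.density_ha,
                "se_density_ha": est.se_density_ha,
                "method": est.method,
            }
        )
    return pd.DataFrame(rows)
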