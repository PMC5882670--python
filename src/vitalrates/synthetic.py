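"""Synthetic source-sink tag-recapture data generator.

Emulates a biannually electrofished stream population (June/September, two
passes per occasion) in which every first-captured fish is fin-clipped, fish
above a length threshold receive a persistent tag, sub-yearlings (0+) are
catchable only in September, and older fish immigrate from an unsampled
upstream source reach ("late incomers", recognizable by their intact adipose
fin).  Growth follows the random-effects von Bertalanffy model, survival acts
between occasions as an annual rate powered by the interval length in years
(apparent survival: death and permanent emigration are not distinguished),
and movement between stream sectors is a first-order Markov step to adjacent
sectors.

Every simulated dataset comes with its ground truth (per-fish parameters,
origins, death occasions, per-occasion true abundance) so downstream
estimators can be tested by parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .growth import GrowthParams

__all__ = [
    "SimConfig",
    "SurvivalDesign",
    "TruthRecord",
    "biannual_occasions",
    "default_growth_params",
    "simulate_population",
    "simulate_temperature",
]


def biannual_occasions(
    start: str = "2004-09-15", n_occasions: int = 23
) -> list[tuple[str, str]]:
    """June-15/September-15 sampling calendar starting at ``start``.

    The default reproduces a 23-occasion design: September of year 0, then
    June and September of each following year.  Each entry is
    ``(ISO date, season of the following interval)``: a June occasion opens a
    Summer (3-month) interval, a September occasion a Winter (9-month) one.
    """
    t = pd.Timestamp(start)
    out = []
    for _ in range(n_occasions):
        season = "Summer" if t.month == 6 else "Winter"
        out.append((t.strftime("%Y-%m-%d"), season))
        t = pd.Timestamp(year=t.year + (t.month == 9), month=9 if t.month == 6 else 6, day=15)
    return out


def default_growth_params() -> GrowthParams:
    """Stream brown-trout-like growth truth: Linf ~ 330 mm, k ~ 0.3 / yr."""
    return GrowthParams(
        log_k=np.log(0.30),
        log_linf=np.log(330.0),
        t0=-0.2,
        sigma_u=0.10,
        sigma_v=0.10,
        sigma_eps=3.0,
    )


@dataclass
class SurvivalDesign:
    """Additive logit-scale design for annual apparent survival.

    ``logit(phi_annual) = intercept + cohort_effects[birth_year]
    + occasion_effects[interval_index]``; missing keys contribute 0.
    """

    intercept: float = 0.2  # logit(0.55)
    cohort_effects: Mapping[int, float] = field(default_factory=dict)
    occasion_effects: Mapping[int, float] = field(default_factory=dict)

    def annual_phi(self, birth_year: int, interval_index: int) -> float:
        eta = (
            self.intercept
            + self.cohort_effects.get(int(birth_year), 0.0)
            + self.occasion_effects.get(int(interval_index), 0.0)
        )
        return float(1.0 / (1.0 + np.exp(-eta)))


@dataclass
class SimConfig:
    """Configuration of one synthetic source-sink dataset.

    Defaults emulate the study design the package targets: 23 biannual
    occasions over 11+ years, ~300 local recruits per cohort, ~40 older
    immigrants per occasion from the unsampled source reach, per-pass capture
    probability 0.9, a 115 mm tagging threshold and 4 stream sectors on
    746.27 m^2 of stream surface.
    """

    occasions: Sequence[tuple[str, str]] = field(default_factory=biannual_occasions)
    recruitment_mean: float = 300.0
    immigration_rate: float = 40.0
    true_growth: GrowthParams = field(default_factory=default_growth_params)
    true_survival: float | SurvivalDesign = field(default_factory=SurvivalDesign)
    capture_prob: float = 0.9
    tagging_threshold: float = 115.0
    n_sectors: int = 4
    sector_linf_log_mult: Sequence[float] | None = None
    movement_prob: float = 0.10
    immigrant_age_classes: Sequence[int] = (1, 2, 3)
    n_pre_cohorts: int = 3
    area_m2: float = 746.27
    seed: int = 0

    def __post_init__(self):
        if len(self.occasions) == 0:
            raise ValueError("occasions list is empty")
        dates = [pd.Timestamp(d) for d, _ in self.occasions]
        if any(b <= a for a, b in zip(dates, dates[1:])):
            raise ValueError("occasion dates must be strictly increasing")
        if not 0.0 < self.capture_prob <= 1.0:
            raise ValueError("capture_prob must be in (0, 1]")
        if not 0.0 <= self.movement_prob <= 1.0:
            raise ValueError("movement_prob must be a probability")
        if self.recruitment_mean < 0 or self.immigration_rate < 0:
            raise ValueError("rates must be >= 0")
        if isinstance(self.true_survival, (int, float)) and not (
            0.0 <= self.true_survival <= 1.0
        ):
            raise ValueError("scalar survival must be in [0, 1]")
        if self.sector_linf_log_mult is not None and len(self.sector_linf_log_mult) != self.n_sectors:
            raise ValueError("need one Linf multiplier per sector")

    @property
    def dates(self) -> list[pd.Timestamp]:
        return [pd.Timestamp(d) for d, _ in self.occasions]

    def annual_phi(self, birth_year: int, interval_index: int) -> float:
        if isinstance(self.true_survival, SurvivalDesign):
            return self.true_survival.annual_phi(birth_year, interval_index)
        return float(self.true_survival)


@dataclass
class TruthRecord:
    """Ground truth of a simulated dataset.

    ``fish``: one row per simulated fish (including never-captured ones):
    fish_id, tag_id ('' if never tagged), cohort (birth year), origin
    ('early' local/early incomer, 'late' for older immigrants), u, v,
    entry_occasion, death_occasion (first occasion index at which the fish is
    no longer present; K if it outlives the study), sector_path.

    ``abundance``: true per-occasion abundance by age-class stratum.
    """

    fish: pd.DataFrame
    abundance: pd.DataFrame


ENCOUNTER_COLUMNS = [
    "tag_id", "date", "occasion_index", "pass", "length_mm",
    "sector", "fin_clipped", "age_years",
]


def _true_length(cfg: SimConfig, birth_year, u, v, sector, date: pd.Timestamp):
    """True length of fish at a date; age counted from mid-June emergence."""
    g = cfg.true_growth
    emergence = pd.to_datetime({"year": birth_year, "month": 6, "day": 15})
    age = (date - emergence).dt.days.to_numpy() / 365.25
    b_off = np.zeros(len(u))
    if cfg.sector_linf_log_mult is not None:
        b_off = np.asarray(cfg.sector_linf_log_mult, dtype=float)[sector - 1]
    coh_a = np.array([g.k_group.get(int(c), 0.0) for c in birth_year])
    coh_b = np.array([g.linf_group.get(int(c), 0.0) for c in birth_year])
    k = np.exp(g.log_k + coh_a + g.sigma_u * u)
    linf = np.exp(g.log_linf + coh_b + b_off + g.sigma_v * v)
    return linf * (1.0 - np.exp(-k * (age - g.t0)))


def simulate_population(config: SimConfig) -> tuple[pd.DataFrame, TruthRecord]:
    """Simulate a full tag-recapture dataset plus its ground truth.

    Deterministic for a fixed config (one seeded generator drives every
    draw).  Returns ``(encounters, truth)`` where ``encounters`` is the
    long-format table (one row per fish per capture) with columns
    ``ENCOUNTER_COLUMNS``; ``fin_clipped`` records the fin status *observed
    at capture* (0 = intact, i.e. never handled before), after which the fin
    is clipped.
    """
    rng = np.random.default_rng(config.seed)
    dates = config.dates
    K = len(dates)
    tau = np.array(
        [(b - a).days / 365.25 for a, b in zip(dates, dates[1:])]
    )  # interval lengths, years

    first_year = dates[0].year
    last_year = dates[-1].year
    sept_years = sorted({d.year for d in dates if d.month == 9})

    # --- local recruits: cohorts enter at 0+ in September of their birth year
    birth_years: list[int] = []
    entry_occ: list[int] = []
    origin: list[str] = []
    pre_cohort_years = list(range(first_year - config.n_pre_cohorts, first_year))
    sept_occ_by_year = {dates[k].year: k for k in range(K) if dates[k].month == 9}

    for year in pre_cohort_years + sept_years:
        n = rng.poisson(config.recruitment_mean)
        if year < first_year:
            # thin pre-study cohorts by survival from their 0+ September
            years_to_start = (dates[0] - pd.Timestamp(year=year, month=9, day=15)).days / 365.25
            phi = config.annual_phi(year, 0)
            n = rng.binomial(n, phi**years_to_start) if n > 0 else 0
            occ = 0
        else:
            occ = sept_occ_by_year[year]
        birth_years += [year] * n
        entry_occ += [occ] * n
        origin += ["early"] * n

    # --- incomers from the unsampled source reach; an immigrant arriving at
    # 1+ in June is an "early incomer" by the fin-clip accounting (it will
    # be clipped at a stage where locals are too), only arrivals at 1+
    # September or older are "late"
    for k in range(K):
        n = rng.poisson(config.immigration_rate)
        ages = rng.choice(np.asarray(config.immigrant_age_classes), size=n)
        for a in ages:
            birth_years.append(dates[k].year - int(a))
            entry_occ.append(k)
            is_late = int(a) >= 2 or dates[k].month == 9
            origin.append("late" if is_late else "early")

    n_fish = len(birth_years)
    birth_years = np.asarray(birth_years)
    entry_occ = np.asarray(entry_occ)
    origin = np.asarray(origin)
    u = rng.standard_normal(n_fish)
    v = rng.standard_normal(n_fish)

    # --- survival between occasions: alive[:, k] = present at occasion k
    phi_annual = np.empty((n_fish, max(K - 1, 1)))
    for k in range(K - 1):
        phi_annual[:, k] = [config.annual_phi(c, k) for c in birth_years]
    alive = np.zeros((n_fish, K), dtype=bool)
    alive[np.arange(n_fish), entry_occ] = True
    for k in range(K - 1):
        p_surv = phi_annual[:, k] ** tau[k]
        survives = rng.random(n_fish) < p_surv
        alive[:, k + 1] = (alive[:, k] & survives) | (entry_occ == k + 1)
    death_occ = np.full(n_fish, K)
    for k in range(K):
        newly_dead = (death_occ == K) & (entry_occ < k) & ~alive[:, k]
        death_occ[newly_dead] = k
        # entrants at k already alive
    # present = alive (fish enter alive and stay until death)
    present = alive

    # --- sector paths: first-order Markov walk on adjacent sectors
    sector = np.zeros((n_fish, K), dtype=int)
    sector[:, 0] = rng.integers(1, config.n_sectors + 1, size=n_fish)
    for k in range(1, K):
        cur = sector[:, k - 1].copy()
        entering = entry_occ == k
        cur[entering] = rng.integers(1, config.n_sectors + 1, size=int(entering.sum()))
        move = rng.random(n_fish) < config.movement_prob
        step = np.where(rng.random(n_fish) < 0.5, -1, 1)
        nxt = np.clip(cur + np.where(move, step, 0), 1, config.n_sectors)
        # at the boundary a blocked step bounces inward
        at_low = move & (cur == 1)
        at_high = move & (cur == config.n_sectors)
        nxt[at_low] = 2 if config.n_sectors > 1 else 1
        nxt[at_high] = max(config.n_sectors - 1, 1)
        sector[:, k] = nxt

    # --- observation process: two removal passes per occasion
    ever_caught = np.zeros(n_fish, dtype=bool)
    tagged = np.zeros(n_fish, dtype=bool)
    tag_ids = np.array([""] * n_fish, dtype=object)
    tag_counter = 0
    q = config.capture_prob
    g = config.true_growth
    rows = []
    for k in range(K):
        date = dates[k]
        age_class = date.year - birth_years
        catchable = present[:, k] & ((age_class >= 1) | (date.month == 9))
        caught1 = catchable & (rng.random(n_fish) < q)
        caught2 = catchable & ~caught1 & (rng.random(n_fish) < q)
        for pass_no, caught in ((1, caught1), (2, caught2)):
            idx = np.flatnonzero(caught)
            if idx.size == 0:
                continue
            true_len = _true_length(
                config,
                pd.Series(birth_years[idx]),
                u[idx],
                v[idx],
                sector[idx, k],
                pd.Series([date] * idx.size),
            )
            if g.sigma_eps > 0:
                obs_len = true_len + rng.normal(0.0, g.sigma_eps, size=idx.size)
            else:
                obs_len = np.asarray(true_len, dtype=float)
            obs_len = np.round(np.maximum(obs_len, 1.0))
            for j, i in enumerate(idx):
                if obs_len[j] > config.tagging_threshold and not tagged[i]:
                    tag_counter += 1
                    tag_ids[i] = f"T{tag_counter:05d}"
                    tagged[i] = True
                rows.append(
                    (
                        tag_ids[i] if tagged[i] else "",
                        date.strftime("%Y-%m-%d"),
                        k,
                        pass_no,
                        obs_len[j],
                        sector[i, k],
                        int(ever_caught[i]),
                        age_class[i],
                    )
                )
            ever_caught[idx] = True  # fin clipped after the pass

    encounters = pd.DataFrame(rows, columns=ENCOUNTER_COLUMNS)
    encounters["length_mm"] = encounters["length_mm"].astype(float)

    # --- truth tables
    fish = pd.DataFrame(
        {
            "fish_id": [f"F{i:05d}" for i in range(n_fish)],
            "tag_id": tag_ids,
            "cohort": birth_years,
            "origin": origin,
            "u": u,
            "v": v,
            "entry_occasion": entry_occ,
            "death_occasion": death_occ,
            "sector_path": [",".join(map(str, sector[i])) for i in range(n_fish)],
        }
    )
    ab_rows = []
    for k in range(K):
        age_class = dates[k].year - birth_years
        is0 = present[:, k] & (age_class < 1)
        older = present[:, k] & (age_class >= 1)
        if dates[k].month == 9:
            ab_rows.append({"occasion_index": k, "stratum": "0+", "n_true": int(is0.sum())})
        ab_rows.append({"occasion_index": k, "stratum": ">0+", "n_true": int(older.sum())})
    truth = TruthRecord(fish=fish, abundance=pd.DataFrame(ab_rows))
    return encounters, truth


def simulate_temperature(
    mean_annual: float,
    amplitude: float,
    noise_sd: float,
    n_days: int,
    seed: int = 0,
    start: str = "2004-01-01",
) -> pd.DataFrame:
    """Sinusoid-plus-noise daily water temperature series.

    ``T_d = mean_annual - amplitude * cos(2 pi (d mod 365.25) / 365.25)
    + N(0, noise_sd)``; coldest around 1 January, warmest mid-summer.
    Returns a DataFrame with ``date`` and ``value`` columns.
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    d = np.arange(n_days)
    vals = mean_annual - amplitude * np.cos(2 * np.pi * d / 365.25)
    if noise_sd > 0:
        vals = vals + rng.normal(0.0, noise_sd, size=n_days)
    idx = pd.date_range(start, periods=n_days, freq="D")
    return pd.DataFrame({"date": idx, "value": vals})


def write_dataset(
    encounters: pd.DataFrame, truth: TruthRecord, config: SimConfig, out_dir
) -> dict[str, str]:
    """Write encounters/truth CSVs and a YAML config snapshot to ``out_dir``."""
    import pathlib

    import yaml

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    enc_path = out / "encounters.csv"
    truth_path = out / "truth_fish.csv"
    ab_path = out / "truth_abundance.csv"
    cfg_path = out / "sim_config.yaml"
    encounters.to_csv(enc_path, index=False)
    truth.fish.to_csv(truth_path, index=False)
    truth.abundance.to_csv(ab_path, index=False)
    cfg = {
        "occasions": [list(o) for o in config.occasions],
        "recruitment_mean": config.recruitment_mean,
        "immigration_rate": config.immigration_rate,
        "capture_prob": config.capture_prob,
        "tagging_threshold": config.tagging_threshold,
        "n_sectors": config.n_sectors,
        "movement_prob": config.movement_prob,
        "area_m2": config.area_m2,
        "seed": config.seed,
        "growth": {
            "log_k": config.true_growth.log_k,
            "log_linf": config.true_growth.log_linf,
            "t0": config.true_growth.t0,
            "sigma_u": config.true_growth.sigma_u,
            "sigma_v": config.true_growth.sigma_v,
            "sigma_eps": config.true_growth.sigma_eps,
        },
    }
    with open(cfg_path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return {
        "encounters": str(enc_path),
        "truth_fish": str(truth_path),
        "truth_abundance": str(ab_path),
        "config": str(cfg_path),
    }
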