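"""End-to-end analysis driver: simulate/load -> densities -> growth ->
survival -> recruitment & movement -> anomaly flags, with seeded
reproducibility and a run manifest.

One root seed drives everything: per-stage generators are spawned from a
``numpy.random.SeedSequence`` so stages can be re-run in isolation with the
same draws.  Two runs with identical config and seed produce byte-identical
result CSVs.
"""

from __future__ import annotations

import hashlib
import json
import pathlib
import time
from typing import Any, Callable

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cjs import CJSModelSpec, build_capture_histories, rank_cjs_models
from .early import density_dependence_regression, overwinter_records, sigma0_by_year
from .env import compute_gdd
from .growth import build_growth_dataset, select_growth_model
from .recruitment import (
    flag_anomalous_cohorts,
    incomer_proportion,
    lagged_density_correlation,
    movement_analysis,
)
from .removal import density_table
from .synthetic import SimConfig, simulate_population, simulate_temperature

__all__ = ["run_pipeline", "stage_seeds", "annual_series", "make_manifest"]


def stage_seeds(root_seed: int, stages: list[str]) -> dict[str, int]:
    """Deterministic per-stage seeds spawned from one root seed (< 2^31)."""
    children = np.random.SeedSequence(root_seed).spawn(len(stages))
    return {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(stages, children)
    }


def annual_series(
    encounters: pd.DataFrame,
    temperature: pd.DataFrame | None = None,
    area_m2: float = 746.27,
    spawner_threshold: float = 150.0,
    gdd_base: float = 0.0,
) -> pd.DataFrame:
    """Annual covariate table for the recruitment / 0+ size analyses.

    Per year: recruitment ``r`` (0+ September density), ``dgt0`` and ``d0``
    (September removal densities), spawner density ``ds`` (> threshold mm)
    and its lag ``ds_lag1``, spring (1 Jan - 31 May) and to-August (1 Jan -
    31 Aug) degree-days, and mean 0+ September length ``l0_mean``.
    """
    enc = encounters.copy()
    enc["date"] = pd.to_datetime(enc["date"])
    ages = density_table(enc, strata="age_class", area_m2=area_m2)
    sizes = density_table(
        enc, strata="length_threshold", area_m2=area_m2, length_threshold=spawner_threshold
    )
    occ_year = enc.groupby("occasion_index")["date"].first()
    sept_occ = {d.year: o for o, d in occ_year.items() if d.month == 9}

    rows = []
    for year, occ in sorted(sept_occ.items()):
        sub = ages[ages["occasion_index"] == occ].set_index("stratum")
        ssub = sizes[sizes["occasion_index"] == occ].set_index("stratum")
        age_y = pd.to_numeric(enc["age_years"], errors="coerce")
        zero = enc[(enc["occasion_index"] == occ) & (age_y < 1)]
        row = {
            "year": year,
            "r": sub["density_ha"].get("0+", np.nan),
            "d0": sub["density_ha"].get("0+", np.nan),
            "dgt0": sub["density_ha"].get(">0+", np.nan),
            "ds": ssub["density_ha"].get(f">{spawner_threshold:g}mm", np.nan),
            "l0_mean": float(pd.to_numeric(zero["length_mm"]).mean()) if len(zero) else np.nan,
            "gdd_spring": np.nan,
            "gdd_aug": np.nan,
        }
        if temperature is not None:
            try:
                row["gdd_spring"] = compute_gdd(
                    temperature, (f"{year}-01-01", f"{year}-05-31"), base_temp=gdd_base
                ).gdd
                row["gdd_aug"] = compute_gdd(
                    temperature, (f"{year}-01-01", f"{year}-08-31"), base_temp=gdd_base
                ).gdd
            except ValueError:
                pass
        rows.append(row)
    out = pd.DataFrame(rows)
    out["ds_lag1"] = out["ds"].shift(1)
    return out


def make_manifest(config: dict, seed: int, inputs: dict[str, str]) -> dict:
    """Run manifest: config hash, seed, version, input digests, timestamp."""
    cfg_text = yaml.safe_dump(config, sort_keys=True)
    digests = {}
    for name, path in inputs.items():
        p = pathlib.Path(path)
        if p.exists():
            digests[name] = hashlib.sha256(p.read_bytes()).hexdigest()[:16]
    return {
        "config_sha256": hashlib.sha256(cfg_text.encode()).hexdigest()[:16],
        "seed": seed,
        "version": __version__,
        "input_digests": digests,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }


def _write(df: pd.DataFrame, path: pathlib.Path):
    df.to_csv(path, index=False, float_format="%.6g")


def run_pipeline(
    config: dict[str, Any],
    out_dir,
    seed: int = 0,
    log: Callable[[str], None] = print,
) -> dict[str, str]:
    """Run the full analysis described by ``config`` into ``out_dir``.

    ``config`` either names input CSVs (``encounters``, optional
    ``temperature``) or contains a ``simulate`` block of
    :class:`~vitalrates.synthetic.SimConfig` overrides.  Any stage failure
    aborts with the stage name; partial outputs stay on disk next to a
    ``FAILED`` marker.
    """
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "FAILED").unlink(missing_ok=True)
    paths: dict[str, str] = {}
    seeds = stage_seeds(seed, ["simulate", "temperature"])
    area = float(config.get("area_m2", 746.27))
    stage = "setup"
    try:
        stage = "data"
        if "simulate" in config:
            sim_kwargs = dict(config["simulate"] or {})
            sim_kwargs.setdefault("seed", seeds["simulate"])
            sim = SimConfig(**sim_kwargs)
            area = sim.area_m2
            encounters, truth = simulate_population(sim)
            _write(encounters, out / "encounters.csv")
            _write(truth.fish, out / "truth_fish.csv")
            paths["encounters"] = str(out / "encounters.csv")
            log(f"simulated {truth.fish.shape[0]} fish, {len(encounters)} capture records")
        else:
            encounters = pd.read_csv(config["encounters"])
            paths["encounters"] = str(config["encounters"])
        temperature = None
        if "temperature" in config:
            temperature = pd.read_csv(config["temperature"])
        elif "simulate" in config:
            dates = pd.to_datetime(encounters["date"])
            n_days = (dates.max() - dates.min()).days + 400
            temperature = simulate_temperature(
                8.37, 6.0, 0.8, n_days, seed=seeds["temperature"],
                start=str((dates.min() - pd.Timedelta(days=300)).date()),
            )
            _write(temperature, out / "temperature.csv")

        stage = "density"
        dens = density_table(encounters, strata="age_class", area_m2=area)
        _write(dens, out / "density.csv")
        paths["density"] = str(out / "density.csv")
        log(f"density: {len(dens)} occasion x stratum estimates")

        stage = "growth"
        gdata = build_growth_dataset(encounters)
        candidates = [
            tuple(c) for c in config.get("growth_candidates", [(("1",), ("1",)), (("cohort",), ("cohort",))])
        ]
        gtable, gfits = select_growth_model(gdata, candidates, compute_se=True)
        _write(gtable, out / "growth_ranking.csv")
        best_growth = next(
            (f for f in gfits if f is not None and f.label == gtable.iloc[0]["model"]),
            None,
        )
        if best_growth is None:
            raise RuntimeError(
                "no growth candidate converged: "
                + "; ".join(f"{r.model}: {r.status}" for _, r in gtable.iterrows())
            )
        _write(best_growth.estimates, out / "growth_estimates.csv")
        paths["growth"] = str(out / "growth_estimates.csv")
        log(f"growth: best {gtable.iloc[0]['model']} (AIC {gtable.iloc[0]['aic']:.1f})")

        stage = "cjs"
        ch = build_capture_histories(encounters, temperature=temperature, densities=dens)
        phi_formulas = config.get("phi_formulas", ["cohort", "time", "season", "1"])
        p_formulas = config.get("p_formulas", ["time"])
        specs = [CJSModelSpec(phi=ph, p=p) for ph in phi_formulas for p in p_formulas]
        ctable, cfits = rank_cjs_models(ch, specs, compute_se=False)
        _write(ctable, out / "cjs_ranking.csv")
        best_cjs = next(
            (f for f in cfits if f is not None and f.label == ctable.iloc[0]["model"]),
            None,
        )
        if best_cjs is None:
            raise RuntimeError(
                "no CJS candidate converged: "
                + "; ".join(f"{r.model}: {r.status}" for _, r in ctable.iterrows())
            )
        _write(best_cjs.estimates, out / "cjs_estimates.csv")
        paths["cjs"] = str(out / "cjs_estimates.csv")
        log(f"cjs: best {ctable.iloc[0]['model']} (AIC {ctable.iloc[0]['aic']:.1f})")

        stage = "early-survival"
        recs = overwinter_records(encounters, densities=dens)
        sig = sigma0_by_year(recs)
        sig_tab = pd.DataFrame([vars(s) for s in sig])
        _write(sig_tab, out / "early_survival.csv")
        paths["early_survival"] = str(out / "early_survival.csv")
        usable = [s for s in sig if s.sigma_annual > 0 and np.isfinite(s.d_mean)]
        if len(usable) >= 3:
            reg = density_dependence_regression(sig)
            (out / "early_survival_regression.txt").write_text(
                f"alpha = {reg['alpha']:.4f} +- {reg['se_alpha']:.4f}\n"
                f"beta  = {reg['beta']:.4f} +- {reg['se_beta']:.4f}\n"
                f"adj R2 = {reg['r2_adj']:.3f}, p(beta) = {reg['p_beta']:.4f}, "
                f"n = {reg['n_years']}\n"
            )

        stage = "recruitment"
        ann = annual_series(encounters, temperature=temperature, area_m2=area)
        _write(ann, out / "annual_series.csv")
        try:
            rtable, _ = fit_recruitment_config(ann, config)
            _write(rtable, out / "recruitment_ranking.csv")
            log(f"recruitment: best {rtable.iloc[0]['model']}")
        except ValueError as exc:
            log(f"recruitment models skipped: {exc}")
        try:
            corr = lagged_density_correlation(ann.dropna(subset=["d0", "dgt0"]))
            _write(corr, out / "lagged_correlations.csv")
        except ValueError as exc:
            log(f"lagged correlations skipped: {exc}")
        inc = incomer_proportion(encounters)
        _write(inc, out / "incomer_proportion.csv")
        paths["incomers"] = str(out / "incomer_proportion.csv")

        stage = "movement"
        mv = movement_analysis(encounters)
        _write(mv.per_fish.drop(columns=["sectors"]), out / "movement_per_fish.csv")
        (out / "movement_summary.txt").write_text(
            f"multi-sector proportion = {mv.prop_multi_sector:.3f} +- {mv.se_prop:.3f}\n"
            f"non-adjacent (among movers) = {mv.prop_non_adjacent:.3f}\n"
            f"GLM: alpha = {mv.glm_intercept:.3f} +- {mv.se_intercept:.3f}, "
            f"beta = {mv.glm_slope:.3f} +- {mv.se_slope:.3f} [{mv.glm_status}]\n"
        )
        paths["movement"] = str(out / "movement_per_fish.csv")

        stage = "anomalies"
        try:
            if best_growth is not None and "cohort" in best_growth.model.levels:
                anom = flag_anomalous_cohorts(best_growth)
                _write(anom, out / "cohort_anomalies.csv")
                paths["anomalies"] = str(out / "cohort_anomalies.csv")
        except ValueError as exc:
            log(f"anomaly flags skipped: {exc}")

        stage = "manifest"
        manifest = make_manifest(config, seed, paths)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        paths["manifest"] = str(out / "manifest.json")
        return paths
    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc


def fit_recruitment_config(ann: pd.DataFrame, config: dict):
    from .recruitment import fit_recruitment

    usable = ann.dropna(subset=["r", "ds_lag1", "gdd_spring"])
    return fit_recruitment(usable, spline_df=int(config.get("recruitment_spline_df", 3)))
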