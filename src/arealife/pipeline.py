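"""End-to-end orchestration: denominators → TOPALS → life tables → inequity.

``run_pipeline`` chains the stages on the CSV inputs, writes every
output next to a manifest recording the configuration hash, package
versions, seed and stage timings, and returns the in-memory results.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as _io
from . import __version__
from .inequity import gap_stats, sii_table
from .lifetable import life_expectancy, summarize_draws
from .pclm import (allocate, build_exposure, census_share,
                   graduate_projections)
from .topals import DEFAULT_KNOTS, TopalsMCMC, smooth_standard

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Validated configuration for a full pipeline run."""

    deaths: str
    census: str
    projections: str
    ses: str
    adjacency: str
    units: str
    out_dir: str
    open_age: dict = field(default_factory=lambda: {"F": 103, "M": 100})
    knots: tuple = DEFAULT_KNOTS
    iterations: int = 10_000
    burn_in: int = 8_000
    thin: int = 1
    tau_spatial: float = 5.0
    tau_shape: float = 2.0
    sample_precisions: bool = False
    loess_span: float = 0.3
    pclm_lambda: float | None = None
    seed: int = 0
    sexes: tuple = ("F", "M")
    index_ages: tuple = (0, 20, 40, 60)
    census_period: int = 2010
    analysis_periods: tuple = (2015, 2016, 2017)

    def validate(self):
        if not 0 <= self.burn_in < self.iterations:
            raise ValueError("need 0 <= burn_in < iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if not 0.0 < self.loess_span <= 1.0:
            raise ValueError("loess_span must lie in (0, 1]")
        for sex in self.sexes:
            if sex not in self.open_age:
                raise ValueError(f"no open age configured for sex {sex!r}")
        bad = [a for a in self.index_ages
               if a < 0 or a > min(self.open_age[s] for s in self.sexes)]
        if bad:
            raise ValueError(f"index ages outside the age range: {bad}")
        return self

    def provenance(self) -> dict:
        """Config fields that determine the results (out_dir excluded)."""
        d = asdict(self)
        d.pop("out_dir")
        return d

    def hash(self) -> str:
        payload = json.dumps(self.provenance(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _matrix(df, value, areas, ages, fill=0.0):
    """Pivot a long (area, age) frame to an (n_areas, n_ages) array."""
    return (df.pivot_table(index="area", columns="age", values=value,
                           fill_value=fill, aggfunc="sum")
            .reindex(index=areas, columns=ages, fill_value=fill)
            .to_numpy(dtype=float))


def estimate_denominators(census, projections, units, open_age,
                          census_period, analysis_periods,
                          pclm_lambda=None) -> pd.DataFrame:
    """Two-step denominator correction.

    1. Census shares of areas within units per (age, sex) applied to
       graduated census-period projections → corrected census-period
       populations by area and single age.
    2. Shares recomputed from the corrected counts and applied to the
       graduated analysis-period projections; exposure is the sum of
       the annual allocated populations.
    """
    shares0 = census_share(census, units)
    graduated = graduate_projections(projections, open_age, lam=pclm_lambda)
    grad_census = graduated[graduated["period"] == census_period]
    corrected = allocate(grad_census, shares0, provenance="census_proportion")

    corrected_counts = corrected.rename(columns={"count": "count"})[
        ["area", "age", "sex", "count"]]
    shares1 = census_share(corrected_counts, units)
    grad_analysis = graduated[graduated["period"].isin(analysis_periods)]
    population = allocate(grad_analysis, shares1,
                          provenance="graduated_projection")
    return build_exposure(population, analysis_periods)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages and write outputs + manifest to ``config.out_dir``."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings = {}
    t0 = time.perf_counter()

    bundle = _io.read_inputs({k: getattr(config, k) for k in
                              ("deaths", "census", "projections", "ses",
                               "adjacency", "units")})
    timings["read"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    exposure = estimate_denominators(
        bundle["census"], bundle["projections"], bundle["units"],
        config.open_age, config.census_period, config.analysis_periods,
        pclm_lambda=config.pclm_lambda)
    exposure.to_csv(out / "exposure.csv", index=False)
    timings["denominators"] = time.perf_counter() - t0

    areas = np.sort(bundle["units"]["area"].unique())
    area_index = {a: i for i, a in enumerate(areas)}
    adj = bundle["adjacency"]
    edges = np.array([(area_index[a], area_index[b])
                      for a, b in adj[["area_i", "area_j"]].itertuples(index=False)
                      if a in area_index and b in area_index], dtype=int)
    ses = bundle["ses"].set_index("area").reindex(areas).reset_index()

    seeds = np.random.SeedSequence(config.seed).spawn(len(config.sexes))
    le_summaries, gap_rows, sii_frames, schedule_rows, meta = [], [], [], [], {}
    results = {"exposure": exposure}

    for sex, seed in zip(config.sexes, seeds):
        ages = np.arange(config.open_age[sex] + 1)
        deaths_sex = bundle["deaths"][bundle["deaths"]["sex"] == sex]
        D = _matrix(deaths_sex, "deaths", areas, ages)
        N = _matrix(exposure[exposure["sex"] == sex], "exposure", areas, ages)

        t0 = time.perf_counter()
        std = smooth_standard(D.sum(axis=0), N.sum(axis=0),
                              span=config.loess_span, ages=ages)
        schedule_rows.append(pd.DataFrame(
            {"age": ages, "sex": sex, "log_rate": std.log_rate}))
        timings[f"standard_{sex}"] = time.perf_counter() - t0

        t0 = time.perf_counter()
        model = TopalsMCMC(
            knots=config.knots, tau_spatial=config.tau_spatial,
            tau_shape=config.tau_shape,
            sample_precisions=config.sample_precisions,
            iterations=config.iterations, burn_in=config.burn_in,
            thin=config.thin, random_state=seed,
        ).fit(D, N, adjacency=edges, std_log_rate=std.log_rate, ages=ages)
        meta[sex] = model.meta_
        timings[f"mcmc_{sex}"] = time.perf_counter() - t0

        t0 = time.perf_counter()
        rates = model.rate_draws()
        e_draws = life_expectancy(rates, index_ages=config.index_ages)
        summary = summarize_draws(e_draws, index_ages=config.index_ages,
                                  areas=areas, sex=sex)
        le_summaries.append(summary)

        e0_points = summary.loc[summary["age"] == config.index_ages[0], "le"]
        gaps = gap_stats(e0_points.to_numpy())
        gaps["sex"] = sex
        gap_rows.append(gaps)

        e0_draws = e_draws[..., 0]
        sii = sii_table(e0_draws, ses, sex=sex)
        sii_frames.append(sii)
        results[f"model_{sex}"] = model
        timings[f"summaries_{sex}"] = time.perf_counter() - t0

    le_summary = pd.concat(le_summaries, ignore_index=True)
    le_summary.to_csv(out / "le_summary.csv", index=False)
    pd.concat(schedule_rows, ignore_index=True).to_csv(
        out / "standard_schedule.csv", index=False)
    gaps_df = pd.DataFrame(gap_rows)
    gaps_df.to_csv(out / "gaps.csv", index=False)
    sii_df = pd.concat(sii_frames, ignore_index=True)
    sii_df.to_csv(out / "sii.csv", index=False)
    with open(out / "sampler_meta.json", "w") as fh:
        json.dump(meta, fh, indent=2, default=str)

    manifest = {
        "package": "arealife",
        "version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
        "config": config.provenance(),
        "config_hash": config.hash(),
        "reconciliation": bundle["report"],
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    # timings vary run to run; kept out of the manifest so identical
    # seeds yield identical manifests
    with open(out / "timings.json", "w") as fh:
        json.dump({k: round(v, 3) for k, v in timings.items()}, fh, indent=2)
    manifest["timings_s"] = {k: round(v, 3) for k, v in timings.items()}

    results.update(le_summary=le_summary, gaps=gaps_df, sii=sii_df,
                   manifest=manifest)
    return results
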