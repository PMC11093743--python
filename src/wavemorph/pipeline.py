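"""End-to-end pipeline driver on a synthetic study system.

Stages: simulate -> inshore waves -> trend decomposition -> morphometry &
quality -> topography -> temporal model ranking -> wave-morphology
coupling -> quality geometry.  Each stage writes its tables under the
output directory; a manifest records per-stage status so partial output
from a failed run remains interpretable.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import coupling as cp
from . import io as wio
from . import morphometry as mq
from . import quality as qg
from . import simulate as sim
from . import topography as topo
from . import trends as tr
from .config import PipelineConfig

__all__ = ["run_pipeline"]

log = logging.getLogger("wavemorph.pipeline")


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run every stage on a freshly simulated world; returns a results dict.

    Raises on the first failed stage after writing the manifest; all
    completed stage outputs remain on disk.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"config": config.to_dict(), "stages": {}}
    results: dict = {}

    def stage(name):
        def deco(fn):
            t0 = time.time()
            try:
                results[name] = fn()
                manifest["stages"][name] = {
                    "status": "ok",
                    "seconds": round(time.time() - t0, 2),
                }
            except Exception as exc:
                manifest["stages"][name] = {"status": "failed", "error": str(exc)}
                wio.write_json_report(manifest, out / "manifest.json")
                log.error("stage %s failed: %s", name, exc)
                raise
            return fn

        return deco

    @stage("simulate")
    def _simulate():
        world = sim.gen_world(config.world)
        wio.write_sea_state_csv(world["waves"], out / "sea_state.csv")
        wio.write_inshore_csv(world["inshore"], out / "inshore_days.csv")
        wio.write_barnacle_csv(world["records"], out / "barnacles.csv")
        wio.write_json_report(world["truth"], out / "ground_truth.json")
        return world

    world = results["simulate"]

    @stage("trends")
    def _trends():
        fit = tr.decompose(
            world["inshore"], config.knots_trend, config.knots_seasonal
        )
        report = {
            "point_id": world["point"].point_id,
            "linear_slope_m_s_yr": fit.linear_slope,
            "slope_se": fit.slope_se,
            "slope_p": fit.slope_p,
            "seasonal_peak_doy": fit.seasonal_peak_doy,
            "lambda_trend": fit.lambda_trend,
            "lambda_seasonal": fit.lambda_seasonal,
        }
        for label, months in [
            ("winter_JFM", config.winter_months),
            ("summer_JJA", config.summer_months),
        ]:
            st = tr.subset_trend(world["inshore"], months)
            report[label] = {
                "slope_m_s_yr": st.linear_slope,
                "slope_p": st.slope_p,
                "annual_means": {int(k): float(v) for k, v in st.annual_means.items()},
            }
        wio.write_json_report(report, out / "trend_report.json")
        return fit, report

    @stage("quality")
    def _quality():
        filtered = mq.apply_study_filters(
            world["records"], min_years=config.min_years, min_dbc=config.dbc_min
        )
        by_level = mq.summarize(filtered, config.parada)
        pooled = mq.summarize(filtered, config.parada, pool_levels=True)
        by_level.to_csv(out / "summary_by_level.csv", index=False)
        pooled.to_csv(out / "summary_pooled.csv", index=False)
        return filtered, by_level, pooled

    @stage("topography")
    def _topography():
        dirs = world["waves"]["dir_deg"].to_numpy()
        rows = []
        for _, s in world["sites"].iterrows():
            coast, bathy, _ = sim.gen_coast_bathy(
                sim.CoastGenConfig(
                    center_lon=s["lon"],
                    center_lat=s["lat"],
                    orientation=s["orientation"],
                    seaward_bearing=s["seaward_bearing"],
                    true_slope=s["true_slope"],
                )
            )
            st = topo.site_topography(
                s["site_id"],
                coast,
                bathy,
                s["lon"],
                s["lat"],
                dirs,
                radius=config.circle_radius,
                transect_length=config.transect_length,
                transect_step=config.transect_step,
            )
            rows.append(
                {
                    "site_id": st.site_id,
                    "shore_normal": st.shore_normal,
                    "alpha": st.alpha,
                    "slope": st.slope,
                }
            )
        df = pd.DataFrame(rows)
        df.to_csv(out / "site_topo.csv", index=False)
        return df

    @stage("temporal_models")
    def _temporal_models():
        filtered, by_level, _ = results["quality"]
        data = filtered.copy()
        data["S"] = data["TL_mm"] / data["DBC_mm"]
        data["year"] = pd.to_datetime(data["date"]).dt.year.astype(float)
        terms = [
            "year",
            "C(level)",
            "C(site_id)",
            "year:C(level)",
            "year:C(site_id)",
            "C(level):C(site_id)",
            "year:C(level):C(site_id)",
        ]
        rank_S = cp.dredge(data, "S", terms, family="gamma_log")
        hq = by_level.copy()
        hq["HQF_adj"] = cp.adjust_unit_interval(hq["HQF"], hq["n"])
        hq["year"] = pd.to_datetime(hq["date"]).dt.year.astype(float)
        rank_H = cp.dredge(
            data=hq,
            response="HQF_adj",
            terms=[
                "year",
                "C(level)",
                "C(site_id)",
                "year:C(level)",
                "year:C(site_id)",
                "C(level):C(site_id)",
            ],
            family="gamma_log",
        )
        null_S = rank_S.loc[rank_S["terms"] == "1", "fit"].iloc[0]
        null_H = rank_H.loc[rank_H["terms"] == "1", "fit"].iloc[0]
        mcf = {
            "S": cp.mcfadden_r2(rank_S["fit"].iloc[0], null_S),
            "HQF": cp.mcfadden_r2(rank_H["fit"].iloc[0], null_H),
        }
        for name, tab in [("model_rank_S.csv", rank_S), ("model_rank_HQF.csv", rank_H)]:
            tab.drop(columns=["fit"]).to_csv(out / name, index=False)
        wio.write_json_report(mcf, out / "mcfadden.json")
        return rank_S, rank_H, mcf

    @stage("coupling")
    def _coupling():
        _, _, pooled = results["quality"]
        pooled = pooled.copy()
        pooled["year"] = pd.to_datetime(pooled["date"]).dt.year
        merged = pooled.merge(world["winter_u"], on=["site_id", "year"], how="left")
        rows = []
        for site, grp in merged.groupby("site_id"):
            res = cp.site_coupling(site, grp)
            rows.append(vars(res))
        cdf = pd.DataFrame(rows)
        cdf.to_csv(out / "coupling.csv", index=False)

        site_tab = cdf.rename(columns={"u_bar_site": "u_bar"}).merge(
            results["topography"], on="site_id"
        )
        ranked = {}
        for resp in ("r2_S", "r2_HQF"):
            tab = cp.r2_topography_models(site_tab, resp)
            tab.drop(columns=["fit"]).to_csv(out / f"model_rank_{resp}.csv", index=False)
            ranked[resp] = tab
        return cdf, site_tab, ranked

    @stage("geometry")
    def _geometry():
        _, _, pooled = results["quality"]
        gfit = qg.fit_gompertz(pooled["mean_S"].to_numpy(), pooled["HQF"].to_numpy())
        S_obs = pooled["mean_S"].to_numpy()
        s_set = [float(np.mean(S_obs)), float(np.max(S_obs)), float(np.min(S_obs))]
        report = qg.quality_domain_report(
            s_set,
            config.parada,
            legal_min_dbc=config.legal_min_dbc,
            optimum_dbc=config.optimum_dbc,
            domain=config.intersection_domain,
        )
        report.to_csv(out / "quality_domain.csv", index=False)
        wio.write_json_report(
            {"gompertz": {"A": gfit.A, "x0": gfit.x0, "b": gfit.b, "r2": gfit.r2}},
            out / "gompertz_fit.json",
        )
        return gfit, report

    wio.write_json_report(manifest, out / "manifest.json")
    return results
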