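"""End-to-end orchestration of the synthetic study.

``run_pipeline`` sequences the stages — simulate (or ingest) the study data,
build the friction surface and travel-time raster, extract covariates, split
a holdout, fit the Bayesian 3PL model, back-calculate probability curves,
thresholds and the gridded probability map, validate on the holdout and
aggregate administrative rates — writing every artefact plus a manifest
(seed, config hash, stage log) into a run directory.

All randomness fans out from the master seed through a fixed-order
``numpy.random.SeedSequence.spawn``, so each stage has its own substream and
toggling one stage never perturbs another's draws.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import aggregation, synthetic, travel, validation
from .curves import summarize_at_thresholds, threshold_floor, treatment_curve
from .irt import FeverTreatmentModel, McmcConfig, PriorSpec
from .raster import Raster
from .synthetic import LandscapeConfig, TrueParameters
from .travel import TravelTimeRaster

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("feverseek")

_STAGES = ["landscape", "clusters", "displace", "responses", "holdout", "mcmc"]


@dataclass
class RunConfig:
    """Configuration of a full run.

    Exactly one of the two modes is active: simulation (``ingest_dir`` is
    None; the synthetic generator produces the study) or ingest
    (``ingest_dir`` points at a directory of previously written artefacts).
    """

    landscape: LandscapeConfig = field(default_factory=LandscapeConfig)
    true_params: TrueParameters = field(default_factory=TrueParameters)
    priors: PriorSpec = field(default_factory=PriorSpec)
    mcmc: McmcConfig = field(default_factory=McmcConfig)
    n_clusters: int = 120
    urban_threshold: float = 100.0
    validation_fraction: float = 0.10
    thresholds: tuple = (10, 30, 60, 120)
    tier: str = "any"
    seed: int = 0
    ingest_dir: str | None = None

    def stage_seed(self, stage: str) -> int:
        """Derived integer seed (< 2^31) for one named stage."""
        children = np.random.SeedSequence(self.seed).spawn(len(_STAGES))
        ss = children[_STAGES.index(stage)]
        return int(ss.generate_state(1, np.uint32)[0] % (2 ** 31))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["thresholds"] = list(self.thresholds)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key, typ in (
            ("landscape", LandscapeConfig),
            ("true_params", TrueParameters),
            ("priors", PriorSpec),
            ("mcmc", McmcConfig),
        ):
            if key in d and isinstance(d[key], dict):
                d[key] = typ(**d[key])
        if "thresholds" in d:
            d["thresholds"] = tuple(d["thresholds"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _urban_raster(population: Raster, threshold: float) -> Raster:
    data = np.where(
        np.isfinite(population.data),
        (population.data >= threshold).astype(float),
        np.nan,
    )
    return population.copy_with(data)


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute all stages; returns the manifest dictionary.

    On a stage failure, partial outputs are retained alongside a ``FAILED``
    marker naming the stage and cause, and the exception propagates.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    artefacts: list[str] = []
    stage = "setup"

    def emit(name: str) -> Path:
        artefacts.append(name)
        return out / name

    try:
        config.to_yaml(out / "config.yaml")
        artefacts.append("config.yaml")

        # ---- stage: study data (simulate or ingest) -----------------------
        stage = "simulate" if config.ingest_dir is None else "ingest"
        log.info("stage %s", stage)
        if config.ingest_dir is None:
            scape = synthetic.generate_landscape(
                dataclasses.replace(
                    config.landscape, seed=config.stage_seed("landscape")
                )
            )
            land, elev = scape.land_class, scape.elevation
            roads, pop = scape.road_mask, scape.population
            admin, facilities = scape.admin_partition, scape.facilities
            land_classes = scape.land_classes
            for name, ras in [
                ("land_class.asc", land), ("elevation.asc", elev),
                ("roads.asc", roads), ("population.asc", pop),
                ("admin.asc", admin),
            ]:
                ras.write_ascii(emit(name))
            facilities.to_csv(emit("facilities.csv"), index=False)
            (out / "land_classes.json").write_text(json.dumps(land_classes))
            artefacts.append("land_classes.json")
        else:
            src = Path(config.ingest_dir)
            land = Raster.read_ascii(src / "land_class.asc")
            elev = Raster.read_ascii(src / "elevation.asc")
            roads = Raster.read_ascii(src / "roads.asc")
            pop = Raster.read_ascii(src / "population.asc")
            admin = Raster.read_ascii(src / "admin.asc")
            facilities = pd.read_csv(src / "facilities.csv")
            land_classes = json.loads((src / "land_classes.json").read_text())

        # ---- stage: travel time ------------------------------------------
        stage = "traveltime"
        log.info("stage traveltime")
        friction = travel.build_friction(land, roads, elev, land_classes)
        fac = (
            facilities if config.tier == "any"
            else facilities[facilities["tier"] == config.tier]
        )
        tt = travel.cost_distance(
            friction, fac[["x", "y"]].to_numpy(), tier=config.tier
        )
        tt.minutes.write_ascii(emit("travel_time.asc"))

        # ---- stage: clusters and children --------------------------------
        stage = "survey"
        log.info("stage survey")
        if config.ingest_dir is None:
            clusters = synthetic.sample_clusters(
                pop, config.n_clusters, config.urban_threshold,
                seed=config.stage_seed("clusters"),
            )
            clusters = synthetic.displace_clusters(
                clusters, seed=config.stage_seed("displace"),
                extent=pop.extent, valid_raster=tt.minutes,
            )
            children = synthetic.simulate_responses(
                clusters, tt.minutes, config.true_params,
                seed=config.stage_seed("responses"),
            )
            clusters_df = synthetic.clusters_to_frame(clusters)
            children_df = synthetic.children_to_frame(children)
            clusters_df.to_csv(emit("clusters.csv"), index=False)
            children_df.to_csv(emit("children.csv"), index=False)
        else:
            src = Path(config.ingest_dir)
            clusters_df = pd.read_csv(src / "clusters.csv")
            children_df = pd.read_csv(src / "children.csv")

        # ---- stage: holdout split ----------------------------------------
        stage = "holdout"
        log.info("stage holdout")
        train, test = validation.holdout_split(
            children_df, fraction=config.validation_fraction,
            seed=config.stage_seed("holdout"),
        )

        # ---- stage: fit ----------------------------------------------------
        stage = "fit"
        log.info("stage fit (%d responses)", int(train["y"].notna().sum()))
        model = FeverTreatmentModel(train, priors=config.priors)
        mcmc = dataclasses.replace(config.mcmc, seed=config.stage_seed("mcmc"))
        results = model.fit(mcmc)
        results.samples.to_frame().to_csv(emit("posterior_draws.csv"), index=False)
        results.summary().to_csv(emit("posterior_summary.csv"))
        report = results.convergence_report()
        (out / "convergence.json").write_text(json.dumps(report.to_dict(), indent=2))
        artefacts.append("convergence.json")

        # ---- stage: probability surfaces ----------------------------------
        stage = "summarize"
        log.info("stage summarize")
        grid = np.unique(np.concatenate(
            [np.arange(0.0, 241.0, 5.0), np.asarray(config.thresholds, float)]
        ))
        curves = []
        for residence in ("rural", "urban"):
            curve = treatment_curve(results.draw_frame(), grid, residence)
            curves.append(curve.to_frame())
        pd.concat(curves).to_csv(emit("treatment_curves.csv"), index=False)
        thr = summarize_at_thresholds(
            treatment_curve(results.draw_frame(), grid, "rural"),
            list(config.thresholds),
        )
        thr.to_csv(emit("thresholds.csv"), index=False)
        floor_med, floor_ci = threshold_floor(results.draw_frame())
        prob_map = results.probability_raster(
            tt, _urban_raster(pop, config.urban_threshold)
        )
        prob_map.write_ascii(emit("probability_map.asc"))

        # ---- stage: validation --------------------------------------------
        stage = "validate"
        log.info("stage validate")
        vreport = validation.validate(results, train, test)
        (out / "validation.json").write_text(json.dumps(vreport.to_dict(), indent=2))
        artefacts.append("validation.json")
        vreport.roc_frame().to_csv(emit("roc.csv"), index=False)

        # ---- stage: aggregation -------------------------------------------
        stage = "aggregate"
        log.info("stage aggregate")
        aggs = aggregation.admin_rates(children_df, clusters_df, admin, pop)
        aggregation.aggregates_to_frame(aggs).to_csv(
            emit("admin_rates.csv"), index=False
        )
        national = aggregation.national_summary(aggs)

        manifest = {
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "mode": "ingest" if config.ingest_dir else "simulate",
            "created": time.strftime("%Y-%m-%dT%H:%M:%S"),
            "artefacts": artefacts,
            "threshold_floor": {"median": floor_med, "ci95": list(floor_ci)},
            "national_rate_per_1000": national,
            "validation": vreport.to_dict(),
            "convergence_all_passed": report.all_passed,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return manifest
    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {stage}\ncause: {exc}\n")
        log.error("stage %s failed: %s", stage, exc)
        raise
    finally:
        log.removeHandler(handler)
        handler.close()
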