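"""End-to-end pipeline: simulate (or load) a survey, derive attributes,
describe, fit variograms, classify spatial dependence, krige, delineate
regions, and run the two-group comparison battery.

Each stage writes its outputs into the run directory and logs its
parameters; any failure halts with a stage-labelled error. A manifest
records provenance (config hash, package version, stage) for every file.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .dataset import PointDataset
from .io import read_point_csv, write_ascii_grid, write_json, write_point_csv
from .kriging import krige_map, loo_rmse
from .reference import (
    compose_survey,
    default_microbiology_config,
    default_survey_config,
    variogram_table,
)
from .regions import compare_groups, delineate_regions, hotelling_t2, pca, ward_cluster
from .soil_attributes import describe
from .synthetic import MicrobiologyConfig, simulate_microbiology, simulate_survey
from .variography import (
    empirical_variogram,
    fit_variogram,
    select_model,
    spatial_dependence_index,
)

log = logging.getLogger("soilgeo.pipeline")

DEFAULT_ATTRIBUTES = ["FCO2", "SOM", "Macro", "TPV", "Silt"]


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


def _log_transform_flags() -> dict[str, bool]:
    tab = variogram_table()
    return dict(zip(tab["attribute"], tab["log_transformed"]))


def run_pipeline(
    config: PipelineConfig,
    outdir: str | Path,
    microbiology: MicrobiologyConfig | None = None,
) -> dict:
    """Run every stage; returns a summary dict (also written as report.json)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, dict] = {}
    prov = {"config_hash": config.digest(), "version": __version__}

    def record(name: str, stage: str) -> Path:
        manifest[name] = {**prov, "stage": stage}
        return outdir / name

    # -- stage: survey -----------------------------------------------------
    try:
        if config.input_csv:
            dataset = read_point_csv(config.input_csv)
            log.info("survey: loaded %d points from %s", dataset.n, config.input_csv)
        else:
            dataset = simulate_survey(default_survey_config(seed=config.seed))
            dataset = compose_survey(dataset)
            log.info("survey: simulated %d points (seed=%d)", dataset.n, config.seed)
        attributes = config.attributes or [
            a for a in DEFAULT_ATTRIBUTES if a in dataset.attributes
        ]
        missing = [a for a in attributes if a not in dataset.attributes]
        if missing:
            raise StageError("survey", f"configured attribute(s) not in dataset: {missing}")
        write_point_csv(dataset, record("points.csv", "survey"))
    except StageError:
        raise
    except Exception as exc:
        raise StageError("survey", str(exc)) from exc

    # -- stage: descriptive ------------------------------------------------
    try:
        rows = []
        for attr in dataset.attributes:
            s = describe(dataset.values(attr))
            rows.append({"attribute": attr, "n": s.n, "mean": s.mean, "se": s.se,
                         "sd": s.sd, "minimum": s.minimum, "maximum": s.maximum,
                         "cv_percent": s.cv_percent, "skewness": s.skewness,
                         "kurtosis": s.kurtosis, "cv_class": s.cv_class})
        pd.DataFrame(rows).to_csv(record("descriptive.csv", "descriptive"),
                                  index=False, float_format="%.6g")
    except Exception as exc:
        raise StageError("descriptive", str(exc)) from exc

    # -- stage: variography ------------------------------------------------
    log_flags = _log_transform_flags()
    models = {}
    try:
        md = dataset.max_pairwise_distance()
        vario_rows, sdi_report = [], {}
        for attr in attributes:
            vals = dataset.values(attr)
            work = dataset
            logged = log_flags.get(attr, False)
            if logged:
                if np.any(vals <= 0):
                    raise ValueError(f"{attr}: log transform needs positive values")
                work = dataset.with_column(attr, np.log(vals))
            emp = empirical_variogram(work, attr, config.bin_width, config.max_lag)
            var = float(np.var(np.log(vals) if logged else vals, ddof=1))
            candidates = []
            for kind in config.candidate_kinds:
                model, diag = fit_variogram(emp, kind, config.weighting, sample_variance=var)
                diag.rmse = loo_rmse(work, attr, model)
                candidates.append((model, diag))
            ranked = select_model(candidates)
            best, diag = ranked[0]
            if logged:
                best = type(best)(best.kind, best.nugget, best.partial_sill,
                                  best.range_, attribute=attr, log_transformed=True)
            models[attr] = best
            pd.DataFrame({"lag_m": emp.lags, "semivariance": emp.semivariances,
                          "pairs": emp.pair_counts}).to_csv(
                record(f"variogram_{attr}.csv", "variography"),
                index=False, float_format="%.10g")
            vario_rows.append({
                "attribute": attr, "kind": best.kind, "nugget": best.nugget,
                "sill": best.sill, "range_m": best.range_, "log": logged,
                "ssr": diag.ssr, "r2": diag.r2, "rmse": diag.rmse,
            })
            sdi = spatial_dependence_index(best, md, config.sdi_model_factors,
                                           config.sdi_thresholds)
            sdi_report[attr] = {"sdi_percent": sdi.sdi_percent,
                                "class": sdi.dependence_class,
                                "max_distance_m": md}
            log.info("variography: %s -> %s(C0=%.4g, sill=%.4g, a=%.4g) SDI=%.2f%% (%s)",
                     attr, best.kind, best.nugget, best.sill, best.range_,
                     sdi.sdi_percent, sdi.dependence_class)
        pd.DataFrame(vario_rows).to_csv(record("models.csv", "variography"),
                                        index=False, float_format="%.10g")
        write_json(sdi_report, record("sdi.json", "sdi"))
    except StageError:
        raise
    except Exception as exc:
        raise StageError("variography", str(exc)) from exc

    # -- stage: kriging + regions ------------------------------------------
    try:
        kattr = config.krige_attribute
        if kattr not in models:
            raise StageError("kriging", f"no fitted model for krige_attribute {kattr!r}")
        model = models[kattr]
        work = dataset
        if model.log_transformed:
            work = dataset.with_column(kattr, np.log(dataset.values(kattr)))
        vmap, vvar = krige_map(work, kattr, model, cell_size=config.cell_size)
        write_ascii_grid(vmap, record(f"krige_{kattr}.asc", "kriging"))
        write_ascii_grid(vvar, record(f"krige_{kattr}_variance.asc", "kriging"))
        rmse = loo_rmse(work, kattr, model)
        write_json({"attribute": kattr, "loo_rmse": rmse,
                    "log_scale": model.log_transformed},
                   record("crossval.json", "crossval"))
        assignment = delineate_regions(vmap, config.low_band, config.high_band)
        counts = assignment.counts()
        write_json({"bands": {"R1": list(config.high_band), "R2": list(config.low_band)},
                    "counts": counts}, record("regions.json", "regions"))
        np.savetxt(record("region_labels.csv", "regions"),
                   np.where(assignment.labels == "", "unassigned",
                            assignment.labels).astype(str),
                   fmt="%s", delimiter=",")
        log.info("regions: R1=%d R2=%d unassigned=%d cells",
                 counts["R1"], counts["R2"], counts["unassigned"])
    except StageError:
        raise
    except Exception as exc:
        raise StageError("kriging", str(exc)) from exc

    # -- stage: comparison battery -----------------------------------------
    try:
        mconfig = microbiology or default_microbiology_config(seed=config.seed + 1)
        table = simulate_microbiology(mconfig)
        write_point = record("microbiology.csv", "compare")
        table.to_csv(write_point, index=False, float_format="%.10g")
        tests = compare_groups(table, alpha=config.alpha)
        a = table[table["region"] == "R1"].drop(columns="region").to_numpy()
        b = table[table["region"] == "R2"].drop(columns="region").to_numpy()
        hot = hotelling_t2(a, b)
        write_json({
            "per_variable": [t.__dict__ for t in tests],
            "hotelling": hot.__dict__,
        }, record("comparison.json", "compare"))
        x = table.drop(columns="region")
        clus = ward_cluster(x.to_numpy(), n_groups=2)
        write_json({"linkage": clus.linkage, "leaf_order": clus.leaf_order,
                    "labels": clus.labels, "cophenetic_r": clus.cophenetic_r},
                   record("clustering.json", "cluster"))
        pres = pca(x)
        write_json({"eigenvalues": pres.eigenvalues,
                    "explained_percent": pres.explained_percent,
                    "loadings": pres.loadings,
                    "retained": pres.retained,
                    "interpreted": pres.interpreted},
                   record("pca.json", "pca"))
    except StageError:
        raise
    except Exception as exc:
        raise StageError("compare", str(exc)) from exc

    # -- stage: report ------------------------------------------------------
    summary = {
        "provenance": prov,
        "n_points": dataset.n,
        "attributes": attributes,
        "sdi": sdi_report,
        "crossval_rmse": rmse,
        "region_counts": counts,
        "hotelling": hot.__dict__,
        "significant_variables": [t.variable for t in tests if t.significant],
        "pca_retained": pres.retained,
        "manifest": manifest,
    }
    write_json(summary, record("report.json", "report"))
    return summary
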