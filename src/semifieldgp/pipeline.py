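"""End-to-end orchestration: QC -> GRM -> spatial -> fit -> parameters -> CV.

Every run writes its artifacts together with a manifest (config hash, seed,
package version, per-stage status) so results are reproducible from the
config alone.  Any stage failure aborts with a stage-named error; the
manifest records the stages that completed.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
from . import __version__
from .exceptions import SemifieldError, ValidationError
from .genomics import compute_grm, filter_snps, impute_missing, read_genotypes
from .layout import build_layout
from .phenotypes import edit_records, summarize_roots
from .simulate import SimulationConfig, simulate_experiment
from .study import AboveGroundModel, RootModel
from .validation import cross_validate

__all__ = ["run_pipeline", "summarize_root_table", "PipelineError"]

ROOT_TRAITS = ("TRL", "SRL", "DRL")
ABOVE_TRAITS = ("GY", "GPC", "GNR", "TKW")


class PipelineError(SemifieldError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def summarize_root_table(images: pd.DataFrame) -> pd.DataFrame:
    """Tube x time-point root traits with line/camera metadata re-attached."""
    traits = summarize_roots(images, group_cols=("bed", "unit", "tube", "time"))
    meta_cols = [c for c in ("line", "camera") if c in images.columns]
    if meta_cols:
        meta = images.groupby(["bed", "unit", "tube", "time"], as_index=False)[meta_cols].first()
        traits = traits.merge(meta, on=["bed", "unit", "tube", "time"])
    return traits


def _config_hash(config: dict) -> str:
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def run_pipeline(config: dict, out_dir) -> dict:
    """Execute the full analysis described by ``config``; return the manifest.

    Config keys (all optional unless noted): ``seed`` (required),
    ``model`` (AM1/AM2/RM1/RM2), ``trait``, ``genotypes``/``phenotypes``/
    ``root_images`` input paths or a ``simulate`` block, ``qc``
    (max_missing, min_maf), ``spatial`` (k_neighbors, d_max), ``edit``
    (sd_limit), ``cv`` (bootstrap, level), ``scale_by_avg_diag``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "seed": config.get("seed"),
        "config_hash": _config_hash(config),
        "stages": [],
        "artifacts": [],
    }
    model_name = str(config.get("model", "AM1")).upper()
    trait = config.get("trait", "TRL" if model_name.startswith("RM") else "GY")
    if model_name.startswith("AM") and trait in ROOT_TRAITS:
        raise ValidationError(f"root trait {trait} requires an RM model")
    if model_name.startswith("RM") and trait in ABOVE_TRAITS:
        raise ValidationError(f"above-ground trait {trait} requires an AM model")
    variant = "M1" if model_name.endswith("1") else "M2"

    def _stage(name):
        manifest["stages"].append(name)

    def _write(df: pd.DataFrame, name: str, index: bool = False):
        path = out / name
        df.to_csv(path, index=index)
        manifest["artifacts"].append(name)

    try:
        stage = "inputs"
        seed = int(config.get("seed", 0))
        if "simulate" in config or "phenotypes" not in config:
            sim_cfg = SimulationConfig(seed=seed, **config.get("simulate", {}))
            sim = simulate_experiment(sim_cfg)
            geno = sim.geno
            above = sim.above
            images = sim.root_images
            _write(geno.dosages, "genotypes.csv", index=True)
            _write(above, "above_ground.csv")
            _write(images, "root_images.csv")
            _write(sim.above_truth.breeding_values, "truth_breeding_values.csv", index=True)
        else:
            geno = read_genotypes(config["genotypes"])
            above = pd.read_csv(config["phenotypes"]) if "phenotypes" in config else None
            images = pd.read_csv(config["root_images"]) if "root_images" in config else None
        _stage(stage)

        stage = "qc"
        qc = config.get("qc", {})
        geno_f, qc_report = filter_snps(
            geno,
            max_missing=qc.get("max_missing", 0.10),
            min_maf=qc.get("min_maf", 0.03),
        )
        geno_f = impute_missing(geno_f)
        (out / "qc_report.json").write_text(json.dumps(qc_report, indent=2))
        manifest["artifacts"].append("qc_report.json")
        _stage(stage)

        stage = "grm"
        grm = compute_grm(geno_f)
        _write(grm.matrix, "grm.csv", index=True)
        manifest["d_g"] = grm.avg_diag
        _stage(stage)

        stage = "layout_spatial"
        sp = config.get("spatial", {})
        if model_name.startswith("AM"):
            data = above
            row_col = "row"
        else:
            data = summarize_root_table(images)
            row_col = "tube"
        if data is None:
            raise ValidationError(f"no input data for model {model_name}")
        edit = config.get("edit", {})
        if edit.get("sd_limit"):
            data, edit_report = edit_records(
                data, [trait], sd_limit=float(edit["sd_limit"]),
                known_lines=geno_f.line_ids,
            )
            _write(edit_report, "edit_report.csv")
        layout = build_layout(
            beds=int(data["bed"].max()),
            units_per_bed=int(data["unit"].max()),
            rows_per_unit=int(data[row_col].max()) + 1,
            row_spacing=sp.get("row_spacing_m", 0.25),
            k_neighbors=sp.get("k_neighbors", 5),
            d_max=sp.get("d_max_m", 2.75),
        )
        _stage(stage)

        stage = "fit"
        cls = AboveGroundModel if model_name.startswith("AM") else RootModel
        study = cls.from_layout(
            data, grm, layout, variant=variant, trait=trait,
            k=sp.get("k_neighbors", 5), d_max=sp.get("d_max_m", 2.75),
        )
        res = study.fit()
        vc = pd.DataFrame({"estimate": res.params, "se": res.result.bse})
        _write(vc, "variance_components.csv", index=True)
        (out / "fit_summary.txt").write_text(res.summary())
        manifest["artifacts"].append("fit_summary.txt")
        manifest["converged"] = bool(res.result.converged)
        _stage(stage)

        stage = "genetic_params"
        rows = []
        for scaled in (True, False):
            gp = res.genetic_params(scale_by_avg_diag=scaled)
            for ctx, rec in gp.per_context.iterrows():
                rows.append({"context": ctx, "scaled": scaled, **rec.to_dict()})
            rows.append(
                {"context": "mean", "scaled": scaled, "sigma_p": np.nan,
                 "h2": gp.h2_mean, "H2": gp.H2_mean, "gcv": gp.gcv}
            )
        _write(pd.DataFrame(rows), "genetic_parameters.csv")
        _stage(stage)

        stage = "cv"
        cv_cfg = config.get("cv", {})
        report = cross_validate(
            res,
            bootstrap=int(cv_cfg.get("bootstrap", 10_000)),
            seed=seed,
            level=cv_cfg.get("level", "observation"),
        )
        _write(report.to_frame(), "gebv.csv", index=True)
        stats = {
            "trait": trait, "model": model_name,
            "pa": report.pa, "max_pa": report.max_pa, "acc": report.acc,
            "b_wp": report.b_wp, "pa_se": report.pa_se, "b_wp_se": report.b_wp_se,
        }
        (out / "cv_report.json").write_text(json.dumps(stats, indent=2))
        manifest["artifacts"].append("cv_report.json")
        manifest["cv"] = stats
        _stage(stage)
    except SemifieldError:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise
    except Exception as exc:  # noqa: BLE001 - re-raise with the failing stage named
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise PipelineError(stage, exc) from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
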