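"""End-to-end pipeline: simulate -> templates -> volumes -> PLS -> regression.

``run_all`` is a pure function of its configuration: every stochastic
stage draws its seed deterministically from the global ``rng_seed``, so
re-running a config reproduces the report bit for bit (checked via the
report hash).  Each stage can also be run standalone on the previous
stage's serialized outputs through the CLI subcommands.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ema as ema_mod
from . import morphometry as morpho
from . import scnpls
from .synthgen import SynthConfig, SynthCohort, generate_cohort, write_cohort
from .templates import TemplateConfig, build_region_templates

__all__ = ["RunConfig", "PipelineError", "run_all", "load_run_config",
           "config_hash", "report_hash", "SCHEMA_VERSION"]

SCHEMA_VERSION = 1
log = logging.getLogger("hipposcn")


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


@dataclass
class RunConfig:
    """Full pipeline configuration."""

    synth: SynthConfig = field(default_factory=SynthConfig)
    template: TemplateConfig = field(default_factory=TemplateConfig)
    analysis_mask_threshold: float = 0.1
    fwhm_mm: float = 8.0
    contrast: tuple[float, float] = scnpls.DEFAULT_CONTRAST
    n_perm: int = 1000
    n_boot: int = 1000
    bsr_threshold: float = scnpls.DEFAULT_BSR_THRESHOLD
    min_cluster: int = scnpls.DEFAULT_MIN_CLUSTER
    connectivity: int = 26
    association_method: str = "correlation"
    p_value_convention: str = "proportion"
    apply_compliance_filter: bool = True
    rng_seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["synth"]["grid_shape"] = list(self.synth.grid_shape)
        d["contrast"] = list(self.contrast)
        return d


def load_run_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Build a :class:`RunConfig` from a YAML file plus overrides.

    Top-level keys map to RunConfig fields; ``synth`` and ``template``
    are nested mappings.
    """
    data: dict = {}
    if path is not None:
        data = yaml.safe_load(Path(path).read_text()) or {}
    data.update({k: v for k, v in overrides.items() if v is not None})
    synth = SynthConfig(**{**data.pop("synth", {})})
    template = TemplateConfig(**{**data.pop("template", {})})
    if "grid_shape" in asdict(synth):
        synth.grid_shape = tuple(synth.grid_shape)
    cfg = RunConfig(synth=synth, template=template, **data)
    cfg.contrast = tuple(cfg.contrast)
    return cfg


def config_hash(cfg: RunConfig) -> str:
    payload = json.dumps(cfg.to_dict(), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def report_hash(report: dict) -> str:
    payload = json.dumps(
        {k: v for k, v in report.items() if k != "report_hash"}, sort_keys=True
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _derived_seeds(rng_seed: int) -> dict[str, int]:
    ss = np.random.SeedSequence(rng_seed)
    names = ["synth", "pls"]
    return {name: int(child.generate_state(1)[0] % (2**31))
            for name, child in zip(names, ss.spawn(len(names)))}


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            log.info("[%s] start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - tag and re-raise
                raise PipelineError(name, exc) from exc
            log.info("[%s] done in %.2fs", name, time.perf_counter() - t0)
            return out
        return inner
    return wrap


# ---------------------------------------------------------------------------
# Stages


@_stage("simulate")
def _simulate(cfg: RunConfig) -> SynthCohort:
    seeds = _derived_seeds(cfg.rng_seed)
    synth = replace(cfg.synth, rng_seed=seeds["synth"])
    return generate_cohort(synth)


@_stage("templates")
def _templates(cohort: SynthCohort, cfg: RunConfig) -> dict:
    return build_region_templates(cohort.subject_masks, cfg.template)


@_stage("volumes")
def _volumes(imgs: list, tpl: dict) -> pd.DataFrame:
    return morpho.volumes_table(
        imgs, tpl["anterior_left"], tpl["anterior_right"],
        tpl["posterior_left"], tpl["posterior_right"],
    )


@_stage("pls")
def _pls(imgs: list, vols: pd.DataFrame, cfg: RunConfig) -> dict:
    mask = morpho.build_analysis_mask(imgs, cfg.analysis_mask_threshold)
    cm = morpho.assemble_cohort_matrix(imgs, mask)
    smoothed_imgs = [morpho.smooth(im, cfg.fwhm_mm) for im in imgs]
    cm_smooth = morpho.assemble_cohort_matrix(smoothed_imgs, mask)
    seeds = scnpls.SeedDensityTable.from_frame(vols)
    pls = scnpls.SeedPLS(
        contrast=cfg.contrast,
        method=cfg.association_method,
        n_perm=cfg.n_perm,
        n_boot=cfg.n_boot,
        p_value_convention=cfg.p_value_convention,
        random_state=_derived_seeds(cfg.rng_seed)["pls"],
    ).fit(cm, seeds)
    scores = pls.transform(cm_smooth)
    bsr_map = cm.map_to_grid(np.nan_to_num(pls.bsr_)) if pls.bsr_ is not None else None
    clusters = []
    if bsr_map is not None:
        clusters = scnpls.extract_clusters(
            bsr_map, cfg.bsr_threshold, cfg.min_cluster, cfg.connectivity
        )
    salience_map = cm.map_to_grid(pls.saliences_)
    return {
        "pls": pls,
        "analysis_mask": mask,
        "cohort_matrix": cm,
        "cohort_matrix_smoothed": cm_smooth,
        "brain_scores": scores,
        "bsr_map": bsr_map,
        "salience_map": salience_map,
        "clusters": clusters,
        "seeds": seeds,
    }


@_stage("regress")
def _regress(table: pd.DataFrame) -> dict:
    base_cov = ["age", "sex", "n_trim_surveys"]
    models = {
        "aHPC_volume": ["aHPC_volume"] + base_cov,
        "pHPC_volume": ["pHPC_volume"] + base_cov,
        "brain_score": ["brain_score"] + base_cov,
        "brain_score_caps": ["brain_score"] + base_cov + ["caps_composite"],
    }
    out = {}
    for name, preds in models.items():
        out[name] = ema_mod.fit_poisson(table, preds)
    return out


# ---------------------------------------------------------------------------
# Orchestration


def run_all(cfg: RunConfig, outdir: str | Path | None = None) -> dict:
    """Execute every stage and return (and optionally write) the report."""
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    cohort = _simulate(cfg)
    if out is not None:
        write_cohort(cohort, out / "cohort")

    summary = ema_mod.subject_summary(cohort.ema)
    table = cohort.subjects.merge(summary, on="subject_id")
    if cfg.apply_compliance_filter:
        included = set(table.loc[table["include_flag"], "subject_id"])
    else:
        included = set(table["subject_id"])
    keep = [sid in included for sid in cohort.subject_ids]
    imgs = [
        morpho.GMImage(g, sid)
        for sid, g, k in zip(cohort.subject_ids, cohort.gm_images, keep) if k
    ]
    masks = [m for m, k in zip(cohort.subject_masks, keep) if k]
    table = table[table["subject_id"].isin(included)].reset_index(drop=True)

    tpl = _templates(
        SynthCohort(cohort.gm_images, masks, cohort.truth, cohort.subjects,
                    cohort.ema, cohort.config),
        cfg,
    )
    vols = _volumes(imgs, tpl)
    table = table.merge(vols, on="subject_id")

    pls_out = _pls(imgs, vols, cfg)
    table["brain_score"] = pls_out["brain_scores"]

    models = _regress(table)

    corr = {}
    for name, col in (("brain_score_vs_aHPC_volume", "aHPC_volume"),
                      ("brain_score_vs_pHPC_volume", "pHPC_volume"),
                      ("trim_frequency_vs_caps", "caps_composite")):
        r, p = ema_mod.pearson_r(table["brain_score" if "brain_score" in name
                                       else "trim_frequency"], table[col])
        corr[name] = {"r": r, "p": p}

    pls = pls_out["pls"]
    bsr = pls.bsr_
    reliable_pos = int(np.sum(bsr >= cfg.bsr_threshold)) if bsr is not None else 0
    reliable_neg = int(np.sum(bsr <= -cfg.bsr_threshold)) if bsr is not None else 0

    report = {
        "schema_version": SCHEMA_VERSION,
        "rng_seed": cfg.rng_seed,
        "config_hash": config_hash(cfg),
        "config": cfg.to_dict(),
        "n_subjects_total": int(cfg.synth.n_subjects),
        "n_subjects_included": int(len(table)),
        "templates": {
            "anterior_voxels": int(np.asarray(tpl["anterior"].data).sum()),
            "posterior_voxels": int(np.asarray(tpl["posterior"].data).sum()),
            "prob_threshold": cfg.template.prob_threshold,
            "posterior_cut_mm": cfg.template.posterior_cut_mm,
            "anterior_cut_mm": cfg.template.anterior_cut_mm,
        },
        "volumes": {
            "aHPC_mean": float(vols["aHPC_volume"].mean()),
            "aHPC_sd": float(vols["aHPC_volume"].std(ddof=1)),
            "pHPC_mean": float(vols["pHPC_volume"].mean()),
            "pHPC_sd": float(vols["pHPC_volume"].std(ddof=1)),
        },
        "pls": {
            "singular_value": pls.singular_value_,
            "perm_p": pls.perm_p_,
            "n_perm": cfg.n_perm,
            "n_boot": cfg.n_boot,
            "n_voxels": int(pls_out["cohort_matrix"].n_voxels),
            "n_reliable_positive_voxels": reliable_pos,
            "n_reliable_negative_voxels": reliable_neg,
        },
        "clusters": [
            {
                "peak_mm": list(c.peak_mm),
                "size_voxels": c.size_voxels,
                "peak_bsr": c.peak_bsr,
                "sign": c.sign,
            }
            for c in pls_out["clusters"]
        ],
        "correlations": corr,
        "models": {name: fit.summary_dict() for name, fit in models.items()},
    }
    report["report_hash"] = report_hash(report)

    if out is not None:
        _write_outputs(out, cfg, tpl, vols, table, pls_out, report)
    return report


def _write_outputs(out: Path, cfg: RunConfig, tpl, vols, table, pls_out,
                   report: dict) -> None:
    tpl["anterior_prob"].save(out / "template_aHPC_prob.nii.gz", cfg.template)
    tpl["posterior_prob"].save(out / "template_pHPC_prob.nii.gz", cfg.template)
    tpl["anterior"].save(out / "template_aHPC.nii.gz")
    tpl["posterior"].save(out / "template_pHPC.nii.gz")
    pls_out["analysis_mask"].save(out / "analysis_mask.nii.gz")
    pls_out["salience_map"].save(out / "salience.nii.gz")
    if pls_out["bsr_map"] is not None:
        pls_out["bsr_map"].save(out / "bsr.nii.gz")
    vols.to_csv(out / "volumes.csv", index=False)
    table[["subject_id", "brain_score"]].to_csv(
        out / "brain_scores.csv", index=False
    )
    pd.DataFrame([
        {
            "peak_x_mm": c.peak_mm[0], "peak_y_mm": c.peak_mm[1],
            "peak_z_mm": c.peak_mm[2], "size_voxels": c.size_voxels,
            "peak_bsr": c.peak_bsr, "sign": c.sign,
        }
        for c in pls_out["clusters"]
    ]).to_csv(out / "clusters.csv", index=False)
    pls = pls_out["pls"]
    (out / "pls_report.json").write_text(json.dumps({
        "singular_value": pls.singular_value_,
        "perm_p": pls.perm_p_,
        "n_perm": cfg.n_perm,
        "n_boot": cfg.n_boot,
        "contrast": list(cfg.contrast),
        "association_method": cfg.association_method,
        "rng_seed": cfg.rng_seed,
    }, indent=2))
    (out / "models_report.json").write_text(
        json.dumps(report["models"], indent=2)
    )
    pd.DataFrame([
        {"pair": k, **v} for k, v in report["correlations"].items()
    ]).to_csv(out / "correlations.csv", index=False)
    (out / "report.json").write_text(json.dumps(report, indent=2))
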