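"""End-to-end orchestration: config, staged pipeline, manifest.

The pipeline wires the stages in the order the analysis runs them:
score pairs -> shuffled null + significance -> duplicated/annotation
enrichment -> tau contrast -> region x tissue table -> capacities ->
GI and prognosis validation.  Every artifact is written to the output
directory together with a manifest recording input hashes and
parameters; a rerun with the same seed reproduces the manifest hashes.
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

from cebu import io as cio
from cebu import synthetic
from cebu.capacity import capacity_table, tissue_mean_capacity
from cebu.cscore import CScoreModel
from cebu.datatypes import SyntheticConfig
from cebu.enrichment import duplicated_enrichment, enrichment_curve
from cebu.tissue import compute_tau, region_tissue_enrichment, tau_contrast
from cebu.validation import (assign_pair_cscore, capacity_gi_correlation,
                             prognosis_auc, roc_auc)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Knobs for a full pipeline run.

    File paths may be omitted, in which case the synthetic generator
    supplies the dataset and its companion ground truths.
    """

    dependency: str | None = None
    expression: str | None = None
    annotation: str | None = None
    duplicated: str | None = None
    gi: str | None = None
    prognosis: str | None = None
    orientation: str = "auto"

    b: float = 1.0
    alpha: float = 0.05
    cscore_threshold: float = 0.25
    percentile: float = 25.0
    n_shuffles: int = 5
    seed: int = 0
    log_base: float = 2.0
    region_alpha: float = 0.05
    enrichment_cutoffs: list[float] = field(
        default_factory=lambda: [0.25, 0.35, 0.45])
    synthetic: SyntheticConfig | None = None

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0 <= self.percentile <= 100:
            raise ValueError("percentile must lie in [0, 100]")
        if self.n_shuffles < 1:
            raise ValueError("n_shuffles must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        synth = raw.pop("synthetic", None)
        raw.update({k: v for k, v in overrides.items() if v is not None})
        cfg = cls(**raw)
        if synth is not None:
            cfg.synthetic = SyntheticConfig(**synth)
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage(manifest: dict, name: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is not None:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}"
                                   ) from exc
            manifest["stages"][name] = round(dt, 3)
            logger.info("stage %s: done in %.2fs", name, dt)
    return _Timer()


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Run every stage and write the artifact bundle to ``outdir``.

    Returns the manifest dict (also written to ``manifest.json``) with
    input/output hashes, parameters and per-stage wall times.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"parameters": _config_dict(config), "stages": {},
                      "inputs": {}, "outputs": {}}

    truth = None
    ground = None
    with _stage(manifest, "load"):
        if config.dependency is not None:
            for key in ("dependency", "expression", "annotation"):
                path = getattr(config, key)
                if path is None or not Path(path).exists():
                    raise FileNotFoundError(
                        f"stage load: missing input {key!r}: {path}")
                manifest["inputs"][key] = _sha256(Path(path))
            dep = cio.read_matrix(config.dependency, "dependency",
                                  config.orientation)
            expr = cio.read_matrix(config.expression, "expression",
                                   config.orientation)
            ann = cio.read_annotation(config.annotation)
            data = cio.align_datasets(dep, expr, ann)
            duplicated = (cio.read_pair_table(config.duplicated,
                                              "duplicated")
                          if config.duplicated else None)
            gi = (cio.read_pair_table(config.gi, "gi")
                  if config.gi else None)
            prognosis = (pd.read_csv(config.prognosis, sep="\t")
                         if config.prognosis else None)
        else:
            synth_cfg = config.synthetic or SyntheticConfig(seed=config.seed)
            data, truth = synthetic.generate(synth_cfg)
            ground = synthetic.emit_ground_truths(truth, synth_cfg)
            duplicated = ground["duplicated"]
            gi = ground["gi"]
            prognosis = ground["prognosis"]
            manifest["inputs"]["synthetic"] = dataclasses.asdict(synth_cfg)

    with _stage(manifest, "cscore"):
        model = CScoreModel(data, b=config.b, alpha=config.alpha)
        results = model.fit(threshold=config.cscore_threshold)

    with _stage(manifest, "null"):
        null = model.fit_null(n_shuffles=config.n_shuffles,
                              seed=config.seed,
                              slope_min=results.slope_min)
        results.add_significance(null)
        results.to_tsv(outdir / "pairs.tsv")
        (outdir / "null.json").write_text(json.dumps({
            "mu": null.mu, "sigma": null.sigma,
            "n_shuffles": null.n_shuffles, "n_samples": null.n_samples,
            "per_shuffle": null.per_shuffle}, indent=2))

    summary: dict = {"slope_min": results.slope_min,
                     "n_records": len(results.records),
                     "null_mu": null.mu, "null_sigma": null.sigma}

    with _stage(manifest, "enrichment"):
        if duplicated is not None and len(duplicated):
            universe = results.n_scored
            dup_records = results.records
            hyper = duplicated_enrichment(dup_records, duplicated,
                                          config.cscore_threshold,
                                          universe_size=universe)
            curve = enrichment_curve(
                dup_records, duplicated, config.enrichment_cutoffs,
                universe_size=universe,
                annotated_in_universe=len(duplicated),
                log_base=config.log_base)
            curve.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
            summary["duplicated_hypergeom_p"] = hyper["p"]
            summary["enrichment_curve"] = curve["enrichment"].tolist()

    with _stage(manifest, "tau"):
        tau = compute_tau(data.expression, data.annotation)
        tau.to_csv(outdir / "tau.tsv", sep="\t")
        pairs = results.records
        usable = pairs[pairs["g1"].isin(data.expression.index)]
        if len(usable) >= 2:
            contrast = tau_contrast(
                tau.loc[usable["g1"], "tau"].to_numpy(),
                tau.loc[usable["g2"], "tau"].to_numpy())
            summary["tau_contrast"] = contrast
        else:
            # G1s live on the dependency panel only in synthetic bundles;
            # report the panel-level means instead of a paired contrast
            summary["tau_contrast"] = None
        summary["mean_tau_g2"] = float(
            tau.loc[pairs["g2"].unique(), "tau"].mean()) if len(pairs) else None

    with _stage(manifest, "regions"):
        regions = region_tissue_enrichment(
            results.records, data, cutoff=config.cscore_threshold,
            alpha=config.region_alpha)
        regions.to_csv(outdir / "regions.tsv", sep="\t")

    with _stage(manifest, "capacity"):
        caps = capacity_table(results.records, data,
                              percentile=config.percentile)
        caps.to_csv(outdir / "capacity.tsv", sep="\t", index=False)
        tissue_means = tissue_mean_capacity(caps, data.annotation)
        tissue_means.to_csv(outdir / "tissue_capacity.tsv", sep="\t")
        summary["tissue_capacity"] = tissue_means.to_dict()

    with _stage(manifest, "validate"):
        if gi is not None and len(gi):
            gi_records = assign_pair_cscore(gi, results.records)
            if len(gi_records) and gi_records["label"].nunique() == 2:
                roc = roc_auc(gi_records["assigned_cscore"],
                              gi_records["label"])
                summary["gi_auc"] = roc["auc"]
                summary["gi_auc_p"] = roc["p"]
                try:
                    corr = capacity_gi_correlation(
                        caps, gi_records, cutoff=config.cscore_threshold)
                    summary["capacity_gi_r"] = corr["r"]
                except ValueError as err:
                    logger.info("capacity-GI correlation unavailable: %s",
                                err)
                gi_records.to_csv(outdir / "gi_validation.tsv", sep="\t",
                                  index=False)
        if prognosis is not None and len(prognosis):
            cancer_tissue = _match_cancers(prognosis, data.annotation,
                                           truth)
            prog = prognosis_auc(prognosis, caps, data.annotation,
                                 results.records, cancer_tissue,
                                 cutoffs=config.enrichment_cutoffs,
                                 min_positive=50)
            prog.to_csv(outdir / "prognosis_auc.tsv", sep="\t",
                        index=False)
            if len(prog):
                summary["prognosis_auc"] = float(prog["auc"].max())

    (outdir / "summary.json").write_text(
        json.dumps(summary, indent=2, default=_jsonable))
    for f in sorted(outdir.iterdir()):
        if f.name != "manifest.json":
            manifest["outputs"][f.name] = _sha256(f)
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _match_cancers(prognosis: pd.DataFrame, annotation: pd.Series,
                   truth) -> dict[str, str]:
    """Map cancer types to tissues.

    Synthetic bundles carry one pseudo-cancer matched to the tissue with
    the highest planted-G2 expression; real tables must use tissue names
    as cancer types or provide a mapping upstream.
    """
    tissues = set(annotation.unique())
    mapping = {}
    for cancer in prognosis["cancer_type"].unique():
        if cancer in tissues:
            mapping[cancer] = cancer
        elif truth is not None:
            planted_means = truth.tissue_means.loc[
                truth.tissue_means.index.intersection(
                    prognosis["gene"].unique())]
            mapping[cancer] = planted_means.mean(axis=0).idxmax()
    return mapping


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    if config.synthetic is not None:
        d["synthetic"] = dataclasses.asdict(config.synthetic)
    return d


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
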