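"""End-to-end orchestration: geometry -> densities -> cutoffs -> labels ->
bivariate tables -> optional clustering -> optional survival.

A single YAML config drives the run; every output file is listed in a
run manifest with a content hash, and the whole pipeline is
deterministic for a fixed seed.  The replicate-reproducibility check
(Pearson correlation of paired replicate-slide densities) lives here as
a generic operation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import __version__
from . import clustering as clust
from . import geometry as geo
from . import survival as surv
from . import topography as topo

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


@dataclass
class PipelineConfig:
    """Validated pipeline settings; defaults mirror the study protocol
    (500 um margins, pooled inside density, k = 1..12 with 10 replicates,
    reference phenotype CD8-cold / CD163-cold)."""

    cells: str | None = None
    regions: str | None = None  # file or directory of per-slide GeoJSON
    clinical: str | None = None
    output: str = "immunotopo_out"
    margin_width: float = 500.0
    inside_mode: str = "pooled"
    markers: list[str] = field(default_factory=lambda: ["CD8", "CD163"])
    cutoff_source: str = "computed"  # or a CSV path with columns marker, cutoff
    run_clustering: bool = False
    clustering_methods: list[str] = field(default_factory=lambda: list(clust.METHODS))
    clustering_criteria: list[str] = field(default_factory=lambda: list(clust.CRITERIA))
    k_range: list[int] = field(default_factory=lambda: list(clust.DEFAULT_K_RANGE))
    clustering_replicates: int = 10
    run_survival: bool = False
    reference_phenotype: str = surv.REFERENCE_PHENOTYPE
    covariates: list[str] = field(default_factory=lambda: ["stage", "age", "sex"])
    seed: int = 0

    def validate(self, require_inputs: bool = True) -> None:
        if self.margin_width <= 0:
            raise ConfigError("margin_width must be positive")
        if self.inside_mode not in ("pooled", "core_only"):
            raise ConfigError(f"inside_mode must be pooled|core_only, got {self.inside_mode!r}")
        if not isinstance(self.seed, int):
            raise ConfigError("seed must be an integer")
        if len(self.markers) < 1:
            raise ConfigError("at least one marker is required")
        unknown_m = set(self.clustering_methods) - set(clust.METHODS)
        unknown_c = set(self.clustering_criteria) - set(clust.CRITERIA)
        if unknown_m or unknown_c:
            raise ConfigError(f"unknown clustering methods/criteria: {unknown_m | unknown_c}")
        if require_inputs:
            for name in ("cells", "regions"):
                p = getattr(self, name)
                if p is None:
                    raise ConfigError(f"config is missing required path {name!r}")
                if not Path(p).exists():
                    raise ConfigError(f"{name} path does not exist: {p}")
            if Path(self.cells).is_file() and Path(self.cells).stat().st_size == 0:
                raise ConfigError(f"cells file is empty: {self.cells}")
            if self.run_survival and (self.clinical is None or not Path(self.clinical).exists()):
                raise ConfigError("run_survival requires an existing clinical table")
            if self.cutoff_source != "computed" and not Path(self.cutoff_source).exists():
                raise ConfigError(f"cutoff file does not exist: {self.cutoff_source}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _load_regions(regions: str) -> dict[str, geo.RegionAnnotation]:
    p = Path(regions)
    if p.is_dir():
        return {f.stem: geo.read_region_annotation(f) for f in sorted(p.glob("*.geojson"))}
    return {p.stem: geo.read_region_annotation(p)}


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every configured stage and write a manifest.

    Any stage failure aborts with the stage name in the raised error.
    Returns the manifest dict (also written to ``manifest.json``).
    """
    config.validate(require_inputs=True)
    out = Path(config.output)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    decisions = {
        "margin_width_um": config.margin_width,
        "inside_mode": config.inside_mode,
        "tie_rule": "equal-to-cutoff is low; boundary cells go to the inner-most compartment",
        "cutoff_source": config.cutoff_source,
        "reference_phenotype": config.reference_phenotype,
    }

    stage = "geometry"
    try:
        cells = geo.read_cell_table(config.cells)
        if len(cells) == 0:
            raise ConfigError(f"cells file has no records: {config.cells}")
        annotations = _load_regions(config.regions)
        missing = sorted(set(cells["slide_id"].astype(str)) - set(annotations))
        if missing:
            raise ConfigError(f"no region annotation for slides: {missing[:5]}")
        comps = {
            sid: geo.build_compartments(ann, margin_width=config.margin_width)
            for sid, ann in annotations.items()
        }
        for sid, cs in comps.items():
            log.info("slide %s: areas mm2 %s", sid,
                     {k: round(v, 4) for k, v in cs.areas_mm2.items()})

        stage = "densities"
        dens = geo.density_table(cells, comps)
        outputs["densities"] = out / "densities.csv"
        dens.to_csv(outputs["densities"], index=False)

        stage = "cutoffs"
        if config.cutoff_source == "computed":
            cutoffs = topo.median_cutoffs(dens)
        else:
            cutoffs = pd.read_csv(config.cutoff_source).set_index("marker")["cutoff"]
        outputs["cutoffs"] = out / "cutoffs.csv"
        cutoffs.rename_axis("marker").reset_index().to_csv(outputs["cutoffs"], index=False)

        stage = "classify"
        labels = topo.classify_profile(dens, cutoffs, mode=config.inside_mode)
        outputs["labels"] = out / "labels.csv"
        labels.to_csv(outputs["labels"], index=False)

        stage = "bivariate"
        if len(config.markers) >= 2:
            a, b = config.markers[0], config.markers[1]
            la = labels[labels["marker"] == a].set_index("slide_id")["label"]
            lb = labels[labels["marker"] == b].set_index("slide_id")["label"]
            grid = topo.bivariate_table(la, lb)
            outputs["bivariate"] = out / f"bivariate_{a}_{b}.csv"
            grid.to_csv(outputs["bivariate"])

        if config.run_clustering:
            stage = "clustering"
            wide = dens.pivot_table(
                index="slide_id", columns=["marker", "compartment"], values="density"
            )
            wide = wide[[c for c in wide.columns if c[0] in config.markers]]
            runs = clust.run_protocol(
                wide.to_numpy(float),
                methods=config.clustering_methods,
                criteria=config.clustering_criteria,
                k_range=config.k_range,
                replicates=config.clustering_replicates,
                seed=config.seed,
            )
            outputs["cluster_runs"] = out / "cluster_runs.csv"
            clust.runs_to_frame(runs).to_csv(outputs["cluster_runs"], index=False)
            summary, overall_k, overall_tie = clust.modal_optimum(runs)
            summary["overall_modal_k"] = overall_k
            summary["overall_tie"] = overall_tie
            outputs["cluster_summary"] = out / "cluster_summary.csv"
            summary.to_csv(outputs["cluster_summary"], index=False)

        if config.run_survival:
            stage = "survival"
            clinical = pd.read_csv(config.clinical)
            a, b = config.markers[0], config.markers[1]
            la = labels[labels["marker"] == a].set_index("slide_id")["label"]
            lb = labels[labels["marker"] == b].set_index("slide_id")["label"]
            pheno = pd.Series(
                {
                    sid: surv.phenotype_name(la[sid], lb[sid], a, b)
                    for sid in la.index.intersection(lb.index)
                    if la[sid] is not None and lb[sid] is not None
                },
                name="phenotype",
            )
            records = clinical.set_index("patient_id").join(pheno, how="left").reset_index()
            tab = surv.phenotype_hazard_table(
                records, reference_phenotype=config.reference_phenotype,
                marker_a=a, marker_b=b, covariates=config.covariates,
            )
            outputs["cox_terms"] = out / "cox_terms.csv"
            tab["cox"].table.to_csv(outputs["cox_terms"])
            outputs["hr_table"] = out / "hr_table.csv"
            tab["hr"].to_csv(outputs["hr_table"])
            outputs["hr_table_json"] = out / "hr_table.json"
            outputs["hr_table_json"].write_text(json.dumps({
                "reference": tab["reference"],
                "hr": tab["hr"].where(tab["hr"].notna(), None).to_dict(),
                "p": tab["p"].where(tab["p"].notna(), None).to_dict(),
                "n": tab["n"].to_dict(),
            }, indent=2))
            outputs["km_curves"] = out / "km_curves.csv"
            surv.km_by_group(records.dropna(subset=["phenotype"])).to_csv(
                outputs["km_curves"], index=False
            )
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "decisions": decisions,
        "outputs": {name: {"path": str(p), "sha256": _sha256(p)} for name, p in sorted(outputs.items())},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def replicate_concordance(
    densities_a: Sequence[float], densities_b: Sequence[float]
) -> tuple[float, float]:
    """Pearson r (with two-sided p) between paired replicate-slide densities.

    The reproducibility check for a digital-pathology pipeline: paired
    densities from re-stained, re-annotated replicate slides should
    correlate strongly (the original protocol reports r > 0.74).
    """
    a = np.asarray(densities_a, dtype=float)
    b = np.asarray(densities_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired density vectors must have equal length")
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 3:
        raise ValueError("need at least 3 paired non-missing densities")
    a, b = a[ok], b[ok]
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero variance in a replicate vector")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)
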