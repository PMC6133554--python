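"""Synthetic slides and cohorts with known immune topographies.

Stands in for an IHC slide collection: tumor boundaries are radially
perturbed circles, immune cells follow a piecewise-constant
inhomogeneous Poisson process (one intensity per compartment, in
cells/mm**2), and patient outcomes follow an exponential baseline hazard
with multiplicative (proportional) effects of the bivariate phenotype
and of stage/age/sex confounders — so Cox assumptions hold exactly and
every downstream stage can be validated against known truth.

Archetype intensities are anchored to the classification cutoff: a hot
archetype puts its pooled inside intensity a separation factor above the
cutoff, an excluded archetype puts only the outer margin above it, and a
cold archetype stays below everywhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon

from . import survival as surv
from .geometry import (
    COMPARTMENTS,
    CellRecord,
    CompartmentSet,
    GeometryError,
    RegionAnnotation,
    build_compartments,
)
from .topography import LABELS, classify_topography

log = logging.getLogger(__name__)

REJECTION_RETRY_BOUND = 10**6
SHAPE_RETRY_BOUND = 20


@dataclass(frozen=True)
class ArchetypeSpec:
    """Per-compartment Poisson intensities realizing one topography label."""

    label: str
    lambda_core: float
    lambda_inner: float
    lambda_outer: float

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")
        if min(self.lambda_core, self.lambda_inner, self.lambda_outer) < 0:
            raise ValueError("intensities must be non-negative")

    def intensity(self, compartment: str) -> float:
        return {
            "TU_CORE": self.lambda_core,
            "MARG_500_IN": self.lambda_inner,
            "MARG_500_OUT": self.lambda_outer,
        }[compartment]

    def implied_label(self, cutoff: float) -> str:
        """Label the intensities themselves imply under the rule at ``cutoff``
        (inside pooled with equal weights; exact areas refine this)."""
        inside = 0.5 * (self.lambda_core + self.lambda_inner)
        return classify_topography(inside, self.lambda_outer, cutoff)

    @classmethod
    def from_label(cls, label: str, cutoff: float = 50.0, separation: float = 4.0) -> "ArchetypeSpec":
        """Canonical archetype at a given separation factor from the cutoff.

        hot: everything at separation x cutoff; cold: everything at
        cutoff / separation; excluded: outer margin high, inside low.
        """
        if separation <= 1:
            raise ValueError("separation must exceed 1")
        hi, lo = cutoff * separation, cutoff / separation
        if label == "hot":
            return cls("hot", hi, hi, hi)
        if label == "cold":
            return cls("cold", lo, lo, lo)
        if label == "excluded":
            return cls("excluded", lo, lo, hi)
        raise ValueError(f"unknown label {label!r}")


@dataclass
class SimulatedSlide:
    slide_id: str
    tumor_polygon: Polygon
    cells: pd.DataFrame  # canonical cell table (all markers)
    truth: dict[str, str]  # marker -> archetype label
    compartments: CompartmentSet = field(repr=False, default=None)


@dataclass
class SurvivalSpec:
    """Exponential baseline with multiplicative phenotype/confounder hazards."""

    baseline_rate: float = 0.05
    log_hr: Mapping[str, float] = field(default_factory=dict)  # phenotype -> log HR vs reference
    censor_rate: float = 0.02
    stage_log_hr: Mapping[str, float] = field(
        default_factory=lambda: {"I": 0.0, "II": 0.3, "III": 0.7, "IV": 1.2}
    )
    age_log_hr: float = 0.02  # per year, centered at 65
    sex_log_hr: float = 0.1  # male vs female
    reference: str = surv.REFERENCE_PHENOTYPE

    def __post_init__(self) -> None:
        if self.baseline_rate <= 0:
            raise ValueError("baseline_rate must be positive")
        if self.censor_rate < 0:
            raise ValueError("censor_rate must be non-negative")
        if self.log_hr.get(self.reference, 0.0) != 0.0:
            raise ValueError("the reference phenotype must have log_hr = 0")


@dataclass
class SimulatedCohort:
    patients: pd.DataFrame  # patient_id, time, event, stage, age, sex, phenotype, label_<A>, label_<B>
    slides: list[SimulatedSlide] | None
    markers: tuple[str, str]
    survival: SurvivalSpec


def _patient_rng(seed: int, index: int) -> np.random.Generator:
    # master seed spawns per-patient substreams: existing patients keep
    # their draws when the cohort is extended
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(index)]))


def generate_tumor_shape(
    seed: int,
    mean_radius: float = 1500.0,
    irregularity: float = 0.3,
    n_vertices: int = 64,
) -> Polygon:
    """Radially perturbed circle as a tumor boundary (simple by construction).

    Vertex angles are evenly spaced with a small jitter and radii are
    ``mean_radius * (1 + irregularity * u)`` with smooth low-order
    Fourier noise, clipped away from zero so the polygon stays
    star-shaped.  Deterministic per seed; a non-simple result is
    regenerated up to a retry bound.
    """
    if mean_radius <= 0:
        raise ValueError("mean_radius must be positive")
    if irregularity < 0:
        raise ValueError("irregularity must be >= 0")
    if n_vertices < 8:
        raise ValueError("need at least 8 vertices")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xC0FFEE]))
    for _ in range(SHAPE_RETRY_BOUND):
        base = 2.0 * np.pi * np.arange(n_vertices) / n_vertices
        jitter = rng.uniform(-0.35, 0.35, n_vertices) * (2.0 * np.pi / n_vertices)
        theta = base + jitter
        # smooth radial noise from a few Fourier modes, unit max amplitude
        noise = np.zeros(n_vertices)
        if irregularity > 0:
            amps = rng.uniform(0.3, 1.0, 4)
            phases = rng.uniform(0.0, 2.0 * np.pi, 4)
            for k, (a, ph) in enumerate(zip(amps, phases), start=1):
                noise += a * np.cos(k * theta + ph)
            noise /= np.abs(noise).max()
        radii = mean_radius * np.clip(1.0 + irregularity * noise, 0.1, None)
        poly = Polygon(np.column_stack([radii * np.cos(theta), radii * np.sin(theta)]))
        if poly.is_valid and poly.is_simple:
            return poly
    raise GeometryError(f"could not generate a simple polygon after {SHAPE_RETRY_BOUND} tries")


def _uniform_in_geometry(geom, n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform points in a geometry by bounding-box rejection sampling."""
    if n == 0:
        return np.empty((0, 2))
    minx, miny, maxx, maxy = geom.bounds
    shapely.prepare(geom)
    out = np.empty((n, 2))
    got = 0
    proposed = 0
    while got < n:
        batch = max(4 * (n - got), 256)
        proposed += batch
        if proposed > REJECTION_RETRY_BOUND:
            raise RuntimeError(f"rejection sampling exceeded {REJECTION_RETRY_BOUND} proposals")
        xy = np.column_stack(
            [rng.uniform(minx, maxx, batch), rng.uniform(miny, maxy, batch)]
        )
        keep = shapely.covers(geom, shapely.points(xy))
        take = min(int(keep.sum()), n - got)
        out[got : got + take] = xy[keep][:take]
        got += take
    return out


def simulate_cells(
    compartments: CompartmentSet,
    archetype: ArchetypeSpec,
    marker: str,
    seed: int | np.random.Generator,
    slide_id: str = "slide",
) -> pd.DataFrame:
    """Piecewise-constant Poisson point pattern over the three compartments.

    Per compartment, the cell count is Poisson(intensity x area in mm**2)
    and positions are uniform within the compartment geometry.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    for comp in COMPARTMENTS:
        lam = archetype.intensity(comp)
        area = compartments.area(comp)
        if lam > 0 and area <= 0:
            raise ValueError(f"compartment {comp} has zero area but intensity {lam}")
        if lam <= 0 or area <= 0:
            continue
        n = int(rng.poisson(lam * area))
        xy = _uniform_in_geometry(compartments[comp], n, rng)
        rows.append(xy)
    xy = np.vstack(rows) if rows else np.empty((0, 2))
    return pd.DataFrame(
        {
            "slide_id": slide_id,
            "marker": marker,
            "x_um": xy[:, 0],
            "y_um": xy[:, 1],
            "cell_class": "positive",
        }
    )


def simulate_slide(
    seed: int,
    archetypes: Mapping[str, ArchetypeSpec],
    slide_id: str = "slide",
    mean_radius: float = 1200.0,
    irregularity: float = 0.25,
    n_vertices: int = 48,
    margin_width: float = 500.0,
) -> SimulatedSlide:
    """One slide: tumor shape, compartments, and one point pattern per marker."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x51DE]))
    poly = generate_tumor_shape(seed, mean_radius, irregularity, n_vertices)
    comps = build_compartments(RegionAnnotation(tumor=poly), margin_width=margin_width)
    tables = [
        simulate_cells(comps, spec, marker, rng, slide_id=slide_id)
        for marker, spec in sorted(archetypes.items())
    ]
    cells = pd.concat(tables, ignore_index=True) if tables else pd.DataFrame()
    truth = {marker: spec.label for marker, spec in archetypes.items()}
    return SimulatedSlide(slide_id=slide_id, tumor_polygon=poly, cells=cells,
                         truth=truth, compartments=comps)


def _draw_covariates(rng: np.random.Generator) -> tuple[str, float, str]:
    stage = rng.choice(list(surv.STAGES), p=[0.2, 0.3, 0.3, 0.2])
    age = float(np.clip(rng.normal(65.0, 10.0), 30.0, 95.0))
    sex = "male" if rng.random() < 0.5 else "female"
    return str(stage), age, sex


def simulate_cohort(
    n_patients: int,
    phenotype_probs: Mapping[str, float] | Sequence[float],
    survival: SurvivalSpec | None = None,
    concordance: float | None = None,
    seed: int = 0,
    markers: tuple[str, str] = ("CD8", "CD163"),
    slides: bool = False,
    cutoff: float = 50.0,
    separation: float = 4.0,
    slide_kwargs: Mapping | None = None,
) -> SimulatedCohort:
    """Cohort with known bivariate phenotypes and proportional hazards.

    ``phenotype_probs`` is a distribution over the nine bivariate
    phenotypes (dict keyed by phenotype name, or a length-9 sequence in
    ``all_phenotypes`` order).  When ``concordance`` is given, marker B's
    label is redrawn: with that probability it copies marker A's label,
    otherwise it is drawn from B's marginal.  With ``slides=True`` each
    patient also gets a two-marker simulated slide whose archetypes match
    the phenotype (intensities at ``separation`` x ``cutoff``).
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    phenos = surv.all_phenotypes(*markers)
    if isinstance(phenotype_probs, Mapping):
        probs = np.array([float(phenotype_probs.get(ph, 0.0)) for ph in phenos])
    else:
        probs = np.asarray(phenotype_probs, dtype=float)
        if probs.shape != (9,):
            raise ValueError("phenotype_probs sequence must have length 9")
    if probs.sum() <= 0:
        raise ValueError("phenotype distribution has empty support")
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError(f"phenotype_probs must sum to 1, got {probs.sum():.12f}")
    if concordance is not None and not 0.0 <= concordance <= 1.0:
        raise ValueError("concordance must be in [0, 1]")
    survival = survival or SurvivalSpec()

    label_pairs = [(a, b) for a in LABELS for b in LABELS]
    pb = {b: sum(p for p, (_, lb) in zip(probs, label_pairs) if lb == b) for b in LABELS}

    rows = []
    slide_list: list[SimulatedSlide] | None = [] if slides else None
    for i in range(n_patients):
        rng = _patient_rng(seed, i)
        j = int(rng.choice(9, p=probs))
        la, lb = label_pairs[j]
        if concordance is not None:
            if rng.random() < concordance:
                lb = la
            else:
                pb_vals = np.array([pb[l] for l in LABELS])
                pb_vals = pb_vals / pb_vals.sum()
                lb = LABELS[int(rng.choice(3, p=pb_vals))]
        phenotype = surv.phenotype_name(la, lb, *markers)

        stage, age, sex = _draw_covariates(rng)
        lp = (
            float(survival.log_hr.get(phenotype, 0.0))
            + float(survival.stage_log_hr.get(stage, 0.0))
            + survival.age_log_hr * (age - 65.0)
            + (survival.sex_log_hr if sex == "male" else 0.0)
        )
        rate = survival.baseline_rate * np.exp(lp)
        t_event = rng.exponential(1.0 / rate)
        if survival.censor_rate > 0:
            t_cens = rng.exponential(1.0 / survival.censor_rate)
        else:
            t_cens = np.inf
        time = min(t_event, t_cens)
        event = bool(t_event <= t_cens)

        pid = f"P{i:05d}"
        rows.append((pid, time, event, stage, age, sex, phenotype, la, lb))
        if slides:
            specs = {
                markers[0]: ArchetypeSpec.from_label(la, cutoff, separation),
                markers[1]: ArchetypeSpec.from_label(lb, cutoff, separation),
            }
            sub = int(rng.integers(0, 2**31 - 1))
            slide_list.append(
                simulate_slide(sub, specs, slide_id=pid, **dict(slide_kwargs or {}))
            )

    patients = pd.DataFrame(
        rows,
        columns=["patient_id", "time", "event", "stage", "age", "sex",
                 "phenotype", f"label_{markers[0]}", f"label_{markers[1]}"],
    )
    return SimulatedCohort(patients=patients, slides=slide_list,
                           markers=markers, survival=survival)


# ---------------------------------------------------------------------------
# Exports (deterministic byte-for-byte for a fixed seed)


def export_cells_csv(slides: Sequence[SimulatedSlide], path: str | Path) -> None:
    cells = pd.concat([s.cells for s in slides], ignore_index=True)
    cells.to_csv(path, index=False, float_format="%.4f")


def export_regions_geojson(slides: Sequence[SimulatedSlide], out_dir: str | Path) -> list[Path]:
    from .geometry import write_region_annotation

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for s in slides:
        p = out_dir / f"{s.slide_id}.geojson"
        write_region_annotation(RegionAnnotation(tumor=s.tumor_polygon), p)
        paths.append(p)
    return paths


def export_cohort_csv(cohort: SimulatedCohort, path: str | Path) -> None:
    cols = ["patient_id", "time", "event", "stage", "age", "sex"]
    cohort.patients[cols].to_csv(path, index=False, float_format="%.6f")
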