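"""Hot / cold / immune-excluded classification of immune topographies.

Densities from the three compartments are reduced to an *inside* density
(tumor core pooled with the inner invasive margin, or core alone) and an
*outside* density (outer invasive margin).  Each marker gets a single
cutoff: the median density pooled over every slide, tumor entity and
compartment.  The classification rule is:

* ``hot``      — inside density strictly above the cutoff, regardless of
  the outside density;
* ``excluded`` — inside at or below the cutoff, outside strictly above;
* ``cold``     — both at or below the cutoff.

"High" always means *strictly greater than* the cutoff, so a value equal
to the median counts as low — a deterministic tie rule on a median split.
Classification uses absolute densities (cells/mm**2); the rank-based
percentile normalization here is for visualization (target plots) and
cross-entity similarity only.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .geometry import COMPARTMENTS, MARG_IN, MARG_OUT, TU_CORE

log = logging.getLogger(__name__)

LABELS = ("cold", "excluded", "hot")
#: Ring order of a target plot, outer-most ring first.
TARGET_RING_ORDER = (MARG_OUT, MARG_IN, TU_CORE)


def percentile_normalize(values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Quantile normalization with 100 quantiles: value -> percentile.

    Uses ``100 * (rank - 0.5) / n`` with average ranks for ties, so the
    output lies strictly inside (0, 100), is invariant under strictly
    monotone transforms of the input, and maps an all-tied vector to 50.
    Missing values propagate as NaN.
    """
    x = np.asarray(values, dtype=float)
    ok = np.isfinite(x)
    if not ok.any():
        raise ValueError("percentile_normalize: all values are missing")
    out = np.full(x.shape, np.nan)
    ranks = rankdata(x[ok], method="average")
    out[ok] = 100.0 * (ranks - 0.5) / ok.sum()
    return out


def median_cutoffs(density_df: pd.DataFrame, min_obs: int = 3) -> pd.Series:
    """Per-marker cutoff: median density pooled over all slides, entities
    and all three compartments (non-missing observations only)."""
    if len(density_df) == 0:
        raise ValueError("empty density table")
    cutoffs = {}
    for marker, sub in density_df.groupby("marker"):
        vals = sub["density"].to_numpy(float)
        vals = vals[np.isfinite(vals)]
        if len(vals) == 0:
            raise ValueError(f"marker {marker}: no non-missing densities")
        if len(vals) < min_obs:
            log.warning("marker %s: cutoff from only %d observations", marker, len(vals))
        cutoffs[marker] = float(np.median(vals))
    return pd.Series(cutoffs, name="cutoff").rename_axis("marker")


def pooled_inside_density(
    count_core: float, count_inner: float, area_core: float, area_inner: float
) -> float:
    """(core + inner margin) cells over (core + inner margin) area."""
    total_area = area_core + area_inner
    if total_area <= 0:
        return float("nan")
    return (count_core + count_inner) / total_area


def classify_topography(inside: float, outside: float, cutoff: float) -> str | None:
    """Apply the cold / excluded / hot rule; None when a density is missing."""
    if not cutoff > 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    if not (np.isfinite(inside) and np.isfinite(outside)):
        return None
    if inside > cutoff:
        return "hot"
    if outside > cutoff:
        return "excluded"
    return "cold"


def slide_inside_outside(density_df: pd.DataFrame, mode: str = "pooled") -> pd.DataFrame:
    """Reduce the long density table to per slide x marker inside/outside.

    ``pooled`` (default) pools the tumor core with the inner invasive
    margin by counts and areas, reflecting their high correlation;
    ``core_only`` uses the core density alone.  Slides missing a needed
    compartment get NaN and are flagged, never imputed as zero.
    """
    if mode not in ("pooled", "core_only"):
        raise ValueError(f"mode must be 'pooled' or 'core_only', got {mode!r}")
    rows = []
    for (slide, marker), sub in density_df.groupby(["slide_id", "marker"], sort=True):
        by_comp = sub.set_index("compartment")
        outside = float(by_comp["density"].get(MARG_OUT, np.nan))
        if mode == "pooled":
            if TU_CORE in by_comp.index and MARG_IN in by_comp.index:
                inside = pooled_inside_density(
                    by_comp.loc[TU_CORE, "count"],
                    by_comp.loc[MARG_IN, "count"],
                    by_comp.loc[TU_CORE, "area_mm2"],
                    by_comp.loc[MARG_IN, "area_mm2"],
                )
            else:
                inside = float("nan")
        else:
            inside = float(by_comp["density"].get(TU_CORE, np.nan))
        rows.append((slide, marker, inside, outside))
    return pd.DataFrame(rows, columns=["slide_id", "marker", "inside_density", "outside_density"])


def classify_profile(
    density_df: pd.DataFrame, cutoffs: Mapping[str, float] | pd.Series, mode: str = "pooled"
) -> pd.DataFrame:
    """Label every slide x marker; adds a ``label`` column (None = flagged missing)."""
    table = slide_inside_outside(density_df, mode=mode)
    labels = []
    for _, row in table.iterrows():
        cutoff = float(cutoffs[row["marker"]])
        labels.append(classify_topography(row["inside_density"], row["outside_density"], cutoff))
    table["label"] = labels
    n_missing = sum(lab is None for lab in labels)
    if n_missing:
        log.warning("%d slide x marker entries left unlabeled (missing compartments)", n_missing)
    return table


def compartment_correlations(
    density_df: pd.DataFrame,
    per: str = "marker",
    method: str = "pearson",
    min_pairs: int = 3,
) -> dict:
    """3x3 correlation matrix between compartment densities.

    Pairwise-complete over slides; entries backed by fewer than
    ``min_pairs`` pairs are NaN.  Returns ``{group: (corr, n_pairs)}``
    keyed by marker (``per='marker'``) or (marker, entity)
    (``per='marker_entity'``, requires an ``entity`` column).
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unsupported correlation method {method!r}")
    if per == "marker":
        keys = ["marker"]
    elif per == "marker_entity":
        keys = ["marker", "entity"]
    else:
        raise ValueError(f"per must be 'marker' or 'marker_entity', got {per!r}")
    out = {}
    for key, sub in density_df.groupby(keys if len(keys) > 1 else keys[0]):
        wide = sub.pivot_table(index="slide_id", columns="compartment", values="density", aggfunc="mean")
        wide = wide.reindex(columns=list(COMPARTMENTS))
        corr = wide.corr(method=method, min_periods=min_pairs)
        notna = wide.notna().astype(int)
        n_pairs = notna.T @ notna
        out[key] = (corr, n_pairs)
    return out


def bivariate_table(
    labels_a: Mapping[str, str] | pd.Series, labels_b: Mapping[str, str] | pd.Series
) -> pd.DataFrame:
    """3x3 phenotype count grid over slides labeled for both markers.

    Rows index marker A's label, columns marker B's.  Marginals equal
    the univariate label counts on the doubly-labeled intersection.
    """
    a = pd.Series(labels_a).dropna()
    b = pd.Series(labels_b).dropna()
    shared = a.index.intersection(b.index)
    if len(shared) == 0:
        raise ValueError("no slides are labeled for both markers")
    grid = pd.crosstab(a.loc[shared], b.loc[shared])
    grid = grid.reindex(index=list(LABELS), columns=list(LABELS), fill_value=0)
    grid.index.name, grid.columns.name = "marker_a", "marker_b"
    return grid.astype(int)


def phenotype_distribution(labels: pd.Series, entities: Mapping[str, str] | pd.Series) -> pd.DataFrame:
    """Per-entity proportions of cold / excluded / hot (rows sum to 1).

    Entities whose slides are all unlabeled are omitted with a warning.
    """
    ent = pd.Series(entities)
    df = pd.DataFrame({"label": pd.Series(labels), "entity": ent.reindex(pd.Series(labels).index)})
    df = df.dropna(subset=["label"])
    if df.empty:
        raise ValueError("no labeled slides")
    dropped = set(pd.Series(entities).unique()) - set(df["entity"].unique())
    if dropped:
        log.warning("entities with no labeled slides omitted: %s", sorted(dropped))
    counts = pd.crosstab(df["entity"], df["label"]).reindex(columns=list(LABELS), fill_value=0)
    return counts.div(counts.sum(axis=1), axis=0)


def target_plot_data(
    slide_densities: Mapping[str, float], reference: Sequence[float] | np.ndarray
) -> pd.Series:
    """Percentile-normalized ring values for one slide, outer ring first.

    Each compartment density is ranked within the reference profile's
    pooled densities for the marker (the slide's own value included), so
    a slide at the reference median sits near 50 on every ring.
    """
    ref = np.asarray(reference, dtype=float)
    ref = ref[np.isfinite(ref)]
    if len(ref) == 0:
        raise ValueError("reference profile is empty for this marker")
    rings = {}
    for comp in TARGET_RING_ORDER:
        v = float(slide_densities.get(comp, np.nan))
        if not np.isfinite(v):
            rings[comp] = float("nan")
            continue
        rings[comp] = float(percentile_normalize(np.append(ref, v))[-1])
    return pd.Series(rings, name="percentile").reindex(list(TARGET_RING_ORDER))


def plot_target(ring_percentiles: pd.Series, ax=None, cmap: str = "viridis"):
    """Render a target plot: concentric rings colored by percentile."""
    import matplotlib.pyplot as plt
    from matplotlib import colormaps
    from matplotlib.patches import Circle

    if ax is None:
        _, ax = plt.subplots(figsize=(3, 3))
    cm = colormaps[cmap]
    radii = (1.0, 0.66, 0.33)  # outer ring drawn first, core on top
    for radius, comp in zip(radii, TARGET_RING_ORDER):
        val = ring_percentiles.get(comp, float("nan"))
        color = cm(val / 100.0) if np.isfinite(val) else "lightgray"
        ax.add_patch(Circle((0, 0), radius, facecolor=color, edgecolor="black", linewidth=0.8))
    ax.set_xlim(-1.05, 1.05)
    ax.set_ylim(-1.05, 1.05)
    ax.set_aspect("equal")
    ax.axis("off")
    return ax
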