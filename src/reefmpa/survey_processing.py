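"""Reconstruction of transect fish biomass and harmonization of benthic covers.

Underwater visual census records arrive as species x size-category counts per
500 m^2 transect.  This module turns them into per-site/date observed log10
biomass (via length-weight allometry, W = a * L^b) and turns heterogeneous
benthic-cover records (2-D photo-quadrat percents, or 3-layer in-situ point
counts) into a harmonized five-category percent-cover table.
"""

from __future__ import annotations

import logging
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

# Offset added before the log10 transform so zero-biomass surveys stay finite.
LOG_OFFSET = 0.001

#: The five broad habitat categories everything is aggregated into.
BROAD_CATEGORIES = (
    "turfing algae",
    "sessile invertebrates",
    "sand",
    "canopy-forming macroalgae",
    "understorey-forming algae",
)

#: Structural layers of an in-situ quadrat, ordered top-down.
LAYERS = ("canopy", "subcanopy", "substrate")

#: Points available per in-situ quadrat layer (50-point quadrat).
QUADRAT_POINTS = 50

#: 16 fine benthic categories with their broad-category assignment
#: (None = abiotic, dropped during aggregation).
FINE_TO_BROAD = {
    "laminarian_kelp": "canopy-forming macroalgae",
    "fucalean_kelp": "canopy-forming macroalgae",
    "foliose_brown_algae": "understorey-forming algae",
    "foliose_red_algae": "understorey-forming algae",
    "foliose_green_algae": "understorey-forming algae",
    "calcified_algae": "understorey-forming algae",
    "turf_algae": "turfing algae",
    "filamentous_algae": "turfing algae",
    "sponges": "sessile invertebrates",
    "ascidians": "sessile invertebrates",
    "hard_coral": "sessile invertebrates",
    "bryozoans": "sessile invertebrates",
    "sand": "sand",
    "bare_rock": None,
    "cobble": None,
    "shell_grit": None,
}

FINE_CATEGORIES = tuple(FINE_TO_BROAD)

#: Families removed before biomass reconstruction (skates and rays, whose
#: length-weight estimates are unreliable).
DEFAULT_EXCLUDED_FAMILIES = ("Rajidae", "Dasyatidae", "Myliobatidae", "Urolophidae")


def default_category_map() -> pd.DataFrame:
    """Mapping table fine category -> broad five-category assignment."""
    return pd.DataFrame(
        {"fine": list(FINE_TO_BROAD), "broad": [FINE_TO_BROAD[c] for c in FINE_TO_BROAD]}
    )


# ---------------------------------------------------------------------------
# Size categories
# ---------------------------------------------------------------------------

def legal_size_categories(max_cm: float = 250.0) -> np.ndarray:
    """Ordered legal size-bin labels (cm).

    Total length is recorded to the nearest of: 2.5 cm steps up to 15 cm,
    5 cm steps to 30 cm, 10 cm steps to 50 cm, and 12.5 cm steps above 50 cm,
    extended to ``max_cm``.
    """
    labels = list(np.arange(2.5, 15.0 + 1e-9, 2.5))
    labels += [20.0, 25.0, 30.0, 40.0, 50.0]
    step = 62.5
    while step <= max_cm + 1e-9:
        labels.append(step)
        step += 12.5
    return np.asarray(labels)


def nearest_size_category(length_cm, labels: np.ndarray | None = None):
    """Snap true total length(s) to the nearest legal size-bin label.

    Ties between two labels are broken downward (the conservative size).
    Lengths beyond the last label map to the last label.
    """
    if labels is None:
        labels = legal_size_categories()
    arr = np.asarray(length_cm, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("fish length must be positive")
    mids = (labels[:-1] + labels[1:]) / 2.0
    # side='left': a length exactly on a midpoint falls to the lower label
    idx = np.searchsorted(mids, arr, side="left")
    out = labels[idx]
    return float(out) if np.isscalar(length_cm) else out


# ---------------------------------------------------------------------------
# Biomass reconstruction
# ---------------------------------------------------------------------------

def exclude_families(records: pd.DataFrame, exclusion_list: Iterable[str]) -> pd.DataFrame:
    """Drop records from excluded families (e.g. skates and rays)."""
    if "family" not in records.columns:
        raise KeyError("records must have a 'family' column")
    excl = set(exclusion_list)
    if not excl:
        return records.copy()
    mask = records["family"].isin(excl)
    n_removed = int(mask.sum())
    logger.info("exclude_families: removed %d of %d records", n_removed, len(records))
    return records.loc[~mask].copy()


def transect_biomass(
    records: pd.DataFrame,
    pool: pd.DataFrame,
    bias_correction: Callable[[pd.Series, np.ndarray], np.ndarray] | None = None,
) -> pd.DataFrame:
    """Reconstruct biomass (kg per 500 m^2) per transect.

    Each individual's recorded size label L is optionally corrected for diver
    bias (``bias_correction(species, L)``; identity by default), converted to
    weight with W_g = a * L^b from the species pool, and counts are summed.

    Parameters
    ----------
    records
        Columns site_id, survey_date, transect_id, species, size_class_cm, count.
    pool
        Species pool with columns species, a, b (length-weight coefficients).
    """
    missing = set(records["species"]) - set(pool["species"])
    if missing:
        raise ValueError(
            "species missing length-weight parameters: " + ", ".join(sorted(missing))
        )
    keys = ["site_id", "survey_date", "transect_id"]
    if records.empty:
        return pd.DataFrame(columns=keys + ["biomass_kg"])
    merged = records.merge(pool[["species", "a", "b"]], on="species", how="left")
    lengths = merged["size_class_cm"].to_numpy(dtype=float)
    if bias_correction is not None:
        lengths = np.asarray(bias_correction(merged["species"], lengths), dtype=float)
    weight_g = merged["a"].to_numpy() * lengths ** merged["b"].to_numpy()
    merged["biomass_kg"] = merged["count"].to_numpy() * weight_g / 1000.0
    out = merged.groupby(keys, as_index=False)["biomass_kg"].sum()
    return out


def observed_log_biomass(
    transects: pd.DataFrame, roster: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Average transect biomass within site/date, then log10(mean + 0.001).

    ``roster`` may list all surveyed transects (site_id, survey_date,
    transect_id) so that fishless transects contribute zeros to the mean.
    """
    df = transects
    if roster is not None:
        keys = ["site_id", "survey_date", "transect_id"]
        df = roster[keys].merge(transects, on=keys, how="left")
        df["biomass_kg"] = df["biomass_kg"].fillna(0.0)
    out = (
        df.groupby(["site_id", "survey_date"], as_index=False)["biomass_kg"]
        .mean()
        .rename(columns={"biomass_kg": "observed_biomass_kg"})
    )
    out["observed_log10_biomass"] = np.log10(out["observed_biomass_kg"] + LOG_OFFSET)
    return out


# ---------------------------------------------------------------------------
# Habitat harmonization
# ---------------------------------------------------------------------------

def scale_insitu_quadrat(
    layer_counts: Mapping[str, Mapping[str, float]]
) -> dict[str, float]:
    """Collapse 3-layer in-situ point counts to 2-D equivalent percent covers.

    Layers are occluded top-down: the canopy layer is retained in full, then
    the subcanopy and finally the substrate layer are truncated to whatever
    point capacity (50) remains, scaling categories within a truncated layer
    proportionally.  When the input totals 50 points or more the output sums
    to exactly 100%; totals at or below 50 points pass through unscaled
    (percent = 2 x points).
    """
    for layer in layer_counts:
        if layer not in LAYERS:
            raise ValueError(f"unknown layer {layer!r}")
        for cat, v in layer_counts[layer].items():
            if v < 0 or v > QUADRAT_POINTS:
                raise ValueError(
                    f"layer {layer!r} count for {cat!r} outside [0, {QUADRAT_POINTS}]"
                )
    out: dict[str, float] = {}
    remaining = float(QUADRAT_POINTS)
    for layer in LAYERS:
        counts = layer_counts.get(layer, {})
        total = float(sum(counts.values()))
        if total > QUADRAT_POINTS:
            raise ValueError(f"layer {layer!r} exceeds {QUADRAT_POINTS} points")
        kept = min(total, remaining)
        scale = kept / total if total > 0 else 0.0
        for cat, v in counts.items():
            out[cat] = out.get(cat, 0.0) + 2.0 * v * scale
        remaining -= kept
    return out


def harmonize_habitat(habitat: pd.DataFrame) -> pd.DataFrame:
    """Harmonize a mixed-dialect habitat table to 2-D fine-category percents.

    Photo-quadrat rows (``dialect == 'photo_quadrat'``) pass through
    unchanged; in-situ rows (``dialect == 'in_situ'``, one row per layer in a
    ``layer`` column) are collapsed with :func:`scale_insitu_quadrat`.
    Output: one row per transect with fine-category percent columns.
    """
    fine_cols = [c for c in habitat.columns if c in FINE_CATEGORIES]
    keys = ["site_id", "survey_date", "transect_id"]
    rows = []
    pq = habitat[habitat["dialect"] == "photo_quadrat"]
    for _, r in pq.iterrows():
        row = {k: r[k] for k in keys}
        row.update({c: float(r.get(c, 0.0)) for c in fine_cols})
        rows.append(row)
    ins = habitat[habitat["dialect"] == "in_situ"]
    if len(ins):
        for key_vals, grp in ins.groupby(keys, sort=False):
            layer_counts = {
                layer: {
                    c: float(sub.iloc[0][c])
                    for c in fine_cols
                    if float(sub.iloc[0][c]) > 0
                }
                for layer, sub in grp.groupby("layer")
            }
            scaled = scale_insitu_quadrat(layer_counts)
            row = dict(zip(keys, key_vals))
            row.update({c: scaled.get(c, 0.0) for c in fine_cols})
            rows.append(row)
    out = pd.DataFrame(rows, columns=keys + fine_cols)
    return out


def aggregate_habitat(
    fine_covers: pd.DataFrame, mapping: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Sum fine-category percent covers into the five broad categories.

    Abiotic categories with no broad assignment are dropped; their summed
    cover is logged.  Raises if a fine column is absent from the mapping.
    """
    if mapping is None:
        mapping = default_category_map()
    keys = ["site_id", "survey_date", "transect_id"]
    fine_cols = [c for c in fine_covers.columns if c not in keys]
    unmapped = set(fine_cols) - set(mapping["fine"])
    if unmapped:
        raise ValueError("fine categories absent from mapping: " + ", ".join(sorted(unmapped)))
    broad_of = dict(zip(mapping["fine"], mapping["broad"]))
    out = fine_covers[keys].copy()
    dropped = 0.0
    for broad in BROAD_CATEGORIES:
        cols = [c for c in fine_cols if broad_of.get(c) == broad]
        out[broad] = fine_covers[cols].sum(axis=1) if cols else 0.0
    abiotic_cols = [c for c in fine_cols if pd.isna(broad_of.get(c)) or broad_of.get(c) is None]
    if abiotic_cols:
        dropped = float(fine_covers[abiotic_cols].to_numpy().sum())
    logger.info("aggregate_habitat: dropped %.1f total percent of abiotic cover", dropped)
    return out


def site_date_habitat(transect_covers: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic mean of per-transect covers within each site/date."""
    keys = ["site_id", "survey_date"]
    value_cols = [
        c for c in transect_covers.columns if c not in keys + ["transect_id"]
    ]
    return transect_covers.groupby(keys, as_index=False)[value_cols].mean()


# ---------------------------------------------------------------------------
# End-to-end helpers
# ---------------------------------------------------------------------------

def process_fish(
    records: pd.DataFrame,
    pool: pd.DataFrame,
    exclusion_list: Sequence[str] = DEFAULT_EXCLUDED_FAMILIES,
    bias_correction: Callable | None = None,
) -> pd.DataFrame:
    """Raw survey records -> per-site/date observed log10 biomass."""
    roster = records[["site_id", "survey_date", "transect_id"]].drop_duplicates()
    filtered = exclude_families(records, exclusion_list)
    per_transect = transect_biomass(filtered, pool, bias_correction)
    return observed_log_biomass(per_transect, roster=roster)


def process_habitat(
    habitat: pd.DataFrame, mapping: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Raw mixed-dialect habitat table -> per-site/date broad covers."""
    fine = harmonize_habitat(habitat)
    broad = aggregate_habitat(fine, mapping)
    return site_date_habitat(broad)
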