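"""Synthetic temperate-reef survey generator with planted, recoverable effects.

Emulates a network of shallow rocky-reef sites along a ~3000 km coastline:
spatially autocorrelated broad-scale ocean covariates drive a baseline log10
fish biomass, biogenic habitat covers and depth add local effects, marine
protected areas (MPAs) are laid out as contiguous coastal blocks and multiply
biomass by a known factor (defaults: fully protected x1.34, partially
protected x1.10), 100x100 km grid cells carry random intercepts, and a
size-binned visual-census observation process with Poisson count noise and
length-weight allometry produces raw transect records.  Every downstream
stage of the pipeline can therefore be checked against the planted truth.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import survey_processing as sp
from .model_inference import assign_grid_cell

PROTECTION_LEVELS = ("fished", "partially protected", "fully protected")

# Observed ranges of the anthropogenic covariates across temperate Australia.
GRAVITY_RANGE = (0.57, 34856.0)
DIST_SHORE_RANGE_M = (1.0, 60447.0)
DEPTH_RANGE_M = (1.0, 25.0)

#: Auxiliary broad-scale ocean covariates (long-term surface means) besides SST.
AUX_COVARIATES = (
    "chlorophyll_mean",
    "oxygen_mean",
    "salinity_mean",
    "nitrate_mean",
    "phosphate_mean",
    "ph_mean",
    "current_velocity_mean",
    "par_mean",
    "silicate_mean",
    "sst_range",
)


class ConfigurationError(ValueError):
    """Raised when a GeneratorConfig violates its invariants."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic survey generator.

    Effect sizes are on the log10-biomass scale except the protection
    multipliers, which act multiplicatively on biomass (kg per 500 m^2).
    ``resid_sd`` (site-level residual s.d., log10 units) is a free choice not
    pinned down by any field estimate of within-region biomass variance.
    """

    n_sites: int = 1000
    prop_fully_protected: float = 0.21
    prop_partially_protected: float = 0.24
    protection_multiplier_full: float = 1.34
    protection_multiplier_partial: float = 1.10
    beta_turf: float = 0.05
    beta_sand: float = -0.05
    beta_depth: float = 0.05
    env_effect_sst: float = 0.04  # log10 biomass per deg C
    env_effect_chl: float = 0.03  # per s.d. of chlorophyll_mean
    env_effect_oxy: float = -0.02  # per s.d. of oxygen_mean
    baseline_intercept: float = 0.80
    grid_sd: float = 0.05
    resid_sd: float = 0.15
    n_species: int = 30
    transects_per_site: int = 2
    length_cv: float = 0.18  # lognormal sigma of individual lengths
    seed: int = 0

    def __post_init__(self):
        p_full, p_part = self.prop_fully_protected, self.prop_partially_protected
        if not (0 <= p_full <= 1 and 0 <= p_part <= 1 and p_full + p_part < 1):
            raise ConfigurationError("protection fractions must lie in [0,1] and sum < 1")
        if self.protection_multiplier_full <= 0 or self.protection_multiplier_partial <= 0:
            raise ConfigurationError("protection multipliers must be > 0")
        if min(self.grid_sd, self.resid_sd, self.length_cv) < 0:
            raise ConfigurationError("standard deviations must be >= 0")
        if self.n_sites < 20:
            raise ConfigurationError("n_sites must be >= 20")
        if self.n_species < 1 or self.transects_per_site < 1:
            raise ConfigurationError("n_species and transects_per_site must be >= 1")

    @property
    def multipliers(self) -> dict[str, float]:
        return {
            "fished": 1.0,
            "partially protected": self.protection_multiplier_partial,
            "fully protected": self.protection_multiplier_full,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))


def null_config(**overrides) -> GeneratorConfig:
    """Config with every planted effect (protection, habitat, depth, grid) zeroed."""
    base = dict(
        protection_multiplier_full=1.0,
        protection_multiplier_partial=1.0,
        beta_turf=0.0,
        beta_sand=0.0,
        beta_depth=0.0,
        grid_sd=0.0,
    )
    base.update(overrides)
    return GeneratorConfig(**base)


# ---------------------------------------------------------------------------
# Species pool
# ---------------------------------------------------------------------------

def default_species_pool(n_species: int = 30, seed: int = 0) -> pd.DataFrame:
    """Species pool with length-weight allometry W_g = a * L_cm^b.

    Includes two ray species (family Rajidae, ``excluded_flag``) so the
    family-exclusion filter is always exercised.
    """
    rng = np.random.default_rng(seed)
    n = max(int(n_species), 3)
    families = [f"Family_{i % 8:02d}" for i in range(n)]
    mean_len = np.clip(np.exp(rng.normal(np.log(18.0), 0.55, n)), 6.0, 70.0)
    pool = pd.DataFrame(
        {
            "species": [f"sp_{i:03d}" for i in range(n)],
            "family": families,
            "a": np.exp(rng.normal(np.log(0.013), 0.25, n)),
            "b": rng.uniform(2.85, 3.15, n),
            "mean_length_cm": mean_len,
            "excluded_flag": False,
        }
    )
    # rays: big-bodied, flagged for exclusion
    for i in (n - 2, n - 1):
        pool.loc[i, ["family", "excluded_flag"]] = ("Rajidae", True)
        pool.loc[i, "mean_length_cm"] = rng.uniform(45.0, 65.0)
    return pool


def _mean_binned_weight_g(pool: pd.DataFrame, length_cv: float, rng) -> np.ndarray:
    """Expected individual weight per species under the size-binning rule.

    Monte-Carlo estimate using the same lognormal length draw and
    nearest-size-category convention as the observation process, so that the
    reconstruction (which uses bin labels as lengths) is unbiased.
    """
    labels = sp.legal_size_categories()
    out = np.empty(len(pool))
    for i, row in enumerate(pool.itertuples()):
        lens = row.mean_length_cm * np.exp(
            rng.normal(0.0, length_cv, 3000) - length_cv**2 / 2.0
        )
        binned = sp.nearest_size_category(lens, labels)
        out[i] = float(np.mean(row.a * binned**row.b))
    return out


# ---------------------------------------------------------------------------
# Sites
# ---------------------------------------------------------------------------

def _smooth_field(x_km, y_km, rng, length_scale_km=300.0, sd=1.0, n_features=30):
    """Spatially autocorrelated Gaussian field via random Fourier features."""
    omega = rng.normal(0.0, 1.0 / length_scale_km, (n_features, 2))
    phase = rng.uniform(0.0, 2.0 * np.pi, n_features)
    proj = np.outer(x_km, omega[:, 0]) + np.outer(y_km, omega[:, 1]) + phase
    f = np.cos(proj).sum(axis=1) * np.sqrt(2.0 / n_features)
    return sd * f


def _assign_protection(order: np.ndarray, cfg: GeneratorConfig, rng):
    """Assign protection in contiguous coastal blocks (MPAs span several sites).

    Block sizes are drawn first (3-8 sites, quotas met exactly), the blocks
    are shuffled, and the remaining fished sites are split randomly into the
    gaps, so MPAs are interspersed along the whole coastline rather than
    clumped at one end.
    """
    n = len(order)
    quotas = {
        "fully protected": int(round(cfg.prop_fully_protected * n)),
        "partially protected": int(round(cfg.prop_partially_protected * n)),
    }
    blocks: list[tuple[str, int]] = []
    for level, quota in quotas.items():
        remaining = quota
        while remaining > 0:
            size = min(int(rng.integers(3, 9)), remaining)
            blocks.append((level, size))
            remaining -= size
    perm = rng.permutation(len(blocks))
    blocks = [blocks[i] for i in perm]
    n_fished = n - sum(quotas.values())
    gaps = rng.multinomial(n_fished, np.full(len(blocks) + 1, 1.0 / (len(blocks) + 1)))

    protection = np.array(["fished"] * n, dtype=object)
    mpa_id = np.array([""] * n, dtype=object)
    pos = int(gaps[0])
    for b_idx, (level, size) in enumerate(blocks):
        idx = order[pos : pos + size]
        protection[idx] = level
        mpa_id[idx] = f"MPA_{b_idx + 1:03d}"
        pos += size + int(gaps[b_idx + 1])
    return protection, mpa_id


def generate_sites(config: GeneratorConfig) -> pd.DataFrame:
    """Generate the site table: coordinates, environment, habitat truth, protection.

    Sites lie along a synthetic temperate coastline spanning well over
    1000 km.  Mean SST follows the latitudinal gradient plus a smooth
    spatially autocorrelated anomaly; auxiliary ocean covariates are smooth
    fields of their own (two of them carry real signal for the baseline, the
    rest are decoys).  Protection labels are laid out in contiguous blocks.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_sites

    t = np.sort(rng.uniform(0.0, 1.0, n))  # position along the coast
    lon = 114.5 + 38.0 * t + rng.normal(0.0, 0.08, n)
    lat = -30.5 - 13.0 * np.sin(np.pi * t) + rng.normal(0.0, 0.08, n)
    from ._geo import sinusoidal_xy_km

    x_km, y_km = sinusoidal_xy_km(lat, lon)

    sst = 13.0 + 0.60 * (lat + 44.0) + _smooth_field(x_km, y_km, rng, 400.0, 0.6) \
        + rng.normal(0.0, 0.1, n)

    aux = {}
    aux_scales = {
        "chlorophyll_mean": (0.45, 0.15),
        "oxygen_mean": (7.2, 0.35),
        "salinity_mean": (35.3, 0.25),
        "nitrate_mean": (1.8, 0.5),
        "phosphate_mean": (0.25, 0.06),
        "ph_mean": (8.07, 0.03),
        "current_velocity_mean": (0.18, 0.06),
        "par_mean": (38.0, 4.0),
        "silicate_mean": (2.2, 0.6),
        "sst_range": (6.5, 1.2),
    }
    for name in AUX_COVARIATES:
        mu, sd = aux_scales[name]
        aux[name] = mu + _smooth_field(x_km, y_km, rng, 350.0, sd) + rng.normal(0.0, sd / 4.0, n)

    depth = rng.uniform(*DEPTH_RANGE_M, n)
    physical = {
        name: rng.integers(1, 5, n) for name in ("wave_exposure", "slope", "relief", "currents")
    }
    gravity = np.exp(rng.uniform(np.log(GRAVITY_RANGE[0]), np.log(GRAVITY_RANGE[1]), n))
    dist_shore = np.exp(
        rng.uniform(np.log(DIST_SHORE_RANGE_M[0]), np.log(DIST_SHORE_RANGE_M[1]), n)
    )

    order = np.arange(n)  # sites already sorted along the coast by t
    protection, mpa_id = _assign_protection(order, config, rng)

    # true broad-category habitat covers (percent); bare substrate absorbs the rest
    alpha = np.array([2.0, 1.5, 1.5, 2.5, 2.0, 1.5])  # turf, inverts, sand, canopy, understorey, bare
    covers = rng.dirichlet(alpha, n) * 100.0
    cover_cols = {
        "cover_turf": covers[:, 0],
        "cover_inverts": covers[:, 1],
        "cover_sand": covers[:, 2],
        "cover_canopy": covers[:, 3],
        "cover_understorey": covers[:, 4],
        "cover_bare": covers[:, 5],
    }

    year = rng.integers(2018, 2023, n)
    survey_date = pd.to_datetime(
        {"year": year, "month": rng.integers(1, 13, n), "day": rng.integers(1, 29, n)}
    ).dt.strftime("%Y-%m-%d")

    sites = pd.DataFrame(
        {
            "site_id": [f"site_{i:04d}" for i in range(n)],
            "latitude": lat,
            "longitude": lon,
            "survey_date": survey_date,
            "depth_m": depth,
            "protection": protection,
            "mpa_id": mpa_id,
            "human_gravity": gravity,
            "dist_shore_m": dist_shore,
            "sst_mean": sst,
            **aux,
            **physical,
            **cover_cols,
        }
    )
    sites["grid_cell"] = assign_grid_cell(sites["latitude"], sites["longitude"])
    return sites


# ---------------------------------------------------------------------------
# Surveys
# ---------------------------------------------------------------------------

def _zscore(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std()


def generate_surveys(
    sites: pd.DataFrame, pool: pd.DataFrame, config: GeneratorConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate raw survey records and the per-site truth table.

    True site-level log10 biomass (kg per 500 m^2) is

        baseline(environment) + beta . z(turf, sand, depth)
        + log10(protection multiplier) + grid-cell intercept + N(0, resid_sd)

    Individual fish are then drawn per species and transect (Poisson counts,
    lognormal lengths snapped to the legal size bins) so that summing the
    reconstructed biomass over a site recovers the truth up to observation
    noise.  Returns ``(records, truth)``.
    """
    if pool is None or len(pool) == 0:
        raise ValueError("species pool must not be empty")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    n = len(sites)

    env_baseline = (
        config.baseline_intercept
        + config.env_effect_sst * sites["sst_mean"].to_numpy()
        + config.env_effect_chl * _zscore(sites["chlorophyll_mean"].to_numpy())
        + config.env_effect_oxy * _zscore(sites["oxygen_mean"].to_numpy())
    )
    habitat_effect = (
        config.beta_turf * _zscore(sites["cover_turf"].to_numpy())
        + config.beta_sand * _zscore(sites["cover_sand"].to_numpy())
        + config.beta_depth * _zscore(sites["depth_m"].to_numpy())
    )
    mult = sites["protection"].map(config.multipliers).to_numpy(dtype=float)
    cells = sites["grid_cell"].to_numpy()
    uniq_cells = pd.unique(cells)
    cell_fx = dict(zip(uniq_cells, rng.normal(0.0, config.grid_sd, len(uniq_cells))))
    grid_effect = np.array([cell_fx[c] for c in cells])
    noise = rng.normal(0.0, config.resid_sd, n)

    true_log10 = env_baseline + habitat_effect + np.log10(mult) + grid_effect + noise
    true_biomass_kg = 10.0**true_log10

    truth = pd.DataFrame(
        {
            "site_id": sites["site_id"],
            "survey_date": sites["survey_date"],
            "protection": sites["protection"],
            "mpa_id": sites["mpa_id"],
            "grid_cell": cells,
            "true_log10_biomass": true_log10,
            "env_baseline_log10": env_baseline,
            "habitat_effect_log10": habitat_effect,
            "grid_effect_log10": grid_effect,
            "true_lnrr": true_log10 - env_baseline,
            "planted_multiplier": mult,
        }
    )

    # --- observation process -------------------------------------------------
    included = pool[~pool["excluded_flag"]].reset_index(drop=True)
    excluded = pool[pool["excluded_flag"]].reset_index(drop=True)
    w_bar = _mean_binned_weight_g(included, config.length_cv, rng)  # grams
    # biomass shares: smaller species more abundant, mildly site-varying
    base_share = included["mean_length_cm"].to_numpy() ** -0.5
    base_share /= base_share.sum()
    shares = rng.dirichlet(base_share * 60.0, n)  # n_sites x n_species

    n_tr = config.transects_per_site
    lam = (
        true_biomass_kg[:, None, None]
        * shares[:, None, :]
        * 1000.0
        / w_bar[None, None, :]
    )  # expected counts: site x transect x species
    lam = np.broadcast_to(lam, (n, n_tr, len(included))).copy()
    counts = rng.poisson(lam)

    labels = sp.legal_size_categories()
    frames = []
    site_ids = sites["site_id"].to_numpy()
    dates = sites["survey_date"].to_numpy()
    for s_idx, srow in enumerate(included.itertuples()):
        c = counts[:, :, s_idx]  # site x transect
        total = int(c.sum())
        if total == 0:
            continue
        site_rep, tr_rep = np.nonzero(c)
        reps = c[site_rep, tr_rep]
        site_of_fish = np.repeat(site_rep, reps)
        tr_of_fish = np.repeat(tr_rep, reps)
        lens = srow.mean_length_cm * np.exp(
            rng.normal(0.0, config.length_cv, total) - config.length_cv**2 / 2.0
        )
        binned = sp.nearest_size_category(lens, labels)
        df = pd.DataFrame(
            {
                "site_idx": site_of_fish,
                "transect": tr_of_fish,
                "size_class_cm": binned,
            }
        )
        grouped = df.groupby(["site_idx", "transect", "size_class_cm"]).size()
        g = grouped.reset_index(name="count")
        g["site_id"] = site_ids[g["site_idx"]]
        g["survey_date"] = dates[g["site_idx"]]
        g["transect_id"] = "T" + (g["transect"] + 1).astype(str)
        g["species"] = srow.species
        g["family"] = srow.family
        frames.append(
            g[["site_id", "survey_date", "transect_id", "species", "family",
               "size_class_cm", "count"]]
        )

    # excluded-family records: sparse sightings, removed downstream
    for srow in excluded.itertuples():
        c = rng.poisson(0.15, (n, n_tr))
        site_rep, tr_rep = np.nonzero(c)
        if len(site_rep) == 0:
            continue
        lens = srow.mean_length_cm * np.exp(rng.normal(0.0, config.length_cv, len(site_rep)))
        g = pd.DataFrame(
            {
                "site_id": site_ids[site_rep],
                "survey_date": dates[site_rep],
                "transect_id": ["T" + str(i + 1) for i in tr_rep],
                "species": srow.species,
                "family": srow.family,
                "size_class_cm": sp.nearest_size_category(lens, labels),
                "count": c[site_rep, tr_rep],
            }
        )
        frames.append(g)

    records = pd.concat(frames, ignore_index=True)
    records = records.sort_values(
        ["site_id", "transect_id", "species", "size_class_cm"]
    ).reset_index(drop=True)
    return records, truth


# ---------------------------------------------------------------------------
# Habitat observations
# ---------------------------------------------------------------------------

#: fine-category split of each true broad cover (synthetic composition)
_BROAD_TO_FINE = {
    "cover_canopy": ("laminarian_kelp", "fucalean_kelp"),
    "cover_understorey": (
        "foliose_brown_algae",
        "foliose_red_algae",
        "foliose_green_algae",
        "calcified_algae",
    ),
    "cover_turf": ("turf_algae", "filamentous_algae"),
    "cover_inverts": ("sponges", "ascidians", "hard_coral", "bryozoans"),
    "cover_sand": ("sand",),
    "cover_bare": ("bare_rock", "cobble", "shell_grit"),
}

_SUBSTRATE_BROADS = ("cover_turf", "cover_inverts", "cover_sand", "cover_bare")


def _fine_probabilities(sites: pd.DataFrame, rng) -> pd.DataFrame:
    """Per-site fine-category cover fractions consistent with the broad truth."""
    n = len(sites)
    fine = {}
    for broad, fines in _BROAD_TO_FINE.items():
        w = rng.dirichlet(np.full(len(fines), 3.0), n)
        for j, f in enumerate(fines):
            fine[f] = sites[broad].to_numpy() / 100.0 * w[:, j]
    return pd.DataFrame(fine, columns=list(sp.FINE_CATEGORIES))


def generate_habitat(sites: pd.DataFrame, config: GeneratorConfig) -> pd.DataFrame:
    """Simulate benthic-cover observations in both recording dialects.

    A random half of the sites are scored photo-quadrat style (100 point
    intercepts per transect over the 16 fine categories, percent covers
    summing to 100); the other half are scored as 3-layer in-situ point
    counts (canopy / subcanopy / substrate, each a 50-point quadrat) whose
    totals exceed 50 whenever canopy or understorey is present, so the
    top-down harmonization path is always exercised.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    n = len(sites)
    fine_p = _fine_probabilities(sites, rng)
    insitu_mask = np.zeros(n, dtype=bool)
    insitu_mask[rng.permutation(n)[: n // 2]] = True

    fine_cols = list(sp.FINE_CATEGORIES)
    canopy_f = list(_BROAD_TO_FINE["cover_canopy"])
    under_f = list(_BROAD_TO_FINE["cover_understorey"])
    substrate_f = [f for b in _SUBSTRATE_BROADS for f in _BROAD_TO_FINE[b]]

    rows = []
    for i in range(n):
        sid = sites["site_id"].iloc[i]
        date = sites["survey_date"].iloc[i]
        p = fine_p.iloc[i].to_numpy()
        for tr in range(config.transects_per_site):
            tid = f"T{tr + 1}"
            if not insitu_mask[i]:
                pts = rng.multinomial(100, p / p.sum())
                row = {
                    "site_id": sid, "survey_date": date, "transect_id": tid,
                    "dialect": "photo_quadrat", "layer": "",
                }
                row.update({c: float(v) for c, v in zip(fine_cols, pts)})
                rows.append(row)
            else:
                # canopy and subcanopy layers: binomial point counts of their covers;
                # substrate layer: all 50 points, scored beneath the overstorey
                layer_defs = (
                    ("canopy", canopy_f, None),
                    ("subcanopy", under_f, None),
                    ("substrate", substrate_f, 50),
                )
                for layer, cats, fixed_total in layer_defs:
                    idx = [fine_cols.index(c) for c in cats]
                    pc = p[idx]
                    if fixed_total is None:
                        cnt = rng.binomial(50, np.minimum(pc, 1.0))
                        # a layer cannot exceed the 50-point quadrat in total
                        if cnt.sum() > 50:
                            cnt = np.floor(cnt * 50.0 / cnt.sum()).astype(int)
                    else:
                        share = pc / pc.sum() if pc.sum() > 0 else np.full(len(pc), 1.0 / len(pc))
                        cnt = rng.multinomial(fixed_total, share)
                    row = {
                        "site_id": sid, "survey_date": date, "transect_id": tid,
                        "dialect": "in_situ", "layer": layer,
                    }
                    row.update({c: 0.0 for c in fine_cols})
                    row.update({c: float(v) for c, v in zip(cats, cnt)})
                    rows.append(row)
    cols = ["site_id", "survey_date", "transect_id", "dialect", "layer"] + fine_cols
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# One-call dataset
# ---------------------------------------------------------------------------

def generate_dataset(config: GeneratorConfig, pool: pd.DataFrame | None = None) -> dict:
    """Generate the full synthetic dataset.

    Returns a dict with keys ``sites``, ``species``, ``fish``, ``habitat``,
    ``truth`` (all DataFrames) and ``config``.
    """
    if pool is None:
        pool = default_species_pool(config.n_species, seed=config.seed)
    sites = generate_sites(config)
    records, truth = generate_surveys(sites, pool, config)
    habitat = generate_habitat(sites, config)
    return {
        "sites": sites,
        "species": pool,
        "fish": records,
        "habitat": habitat,
        "truth": truth,
        "config": config,
    }
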