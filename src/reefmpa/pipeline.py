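"""File-based pipeline stages: simulate -> process -> counterfactual -> effects -> infer.

Each stage reads plain CSV/JSON artifacts from a run directory and writes its
own, so partial runs resume from existing intermediates.  A manifest with the
config hash, seeds and SHA-256 digests of every output file is written at the
end of a run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import counterfactual as cf
from . import effects as ef
from . import model_inference as mi
from . import survey_processing as sp
from . import synthetic_data as sd

logger = logging.getLogger(__name__)

STAGES = ("simulate", "process", "counterfactual", "effects", "infer", "report")

#: broad habitat category -> short predictor name
BROAD_TO_PREDICTOR = {
    "turfing algae": "turf",
    "sessile invertebrates": "sessile_inverts",
    "sand": "sand",
    "canopy-forming macroalgae": "canopy",
    "understorey-forming algae": "understorey",
}

HABITAT_PREDICTORS = list(BROAD_TO_PREDICTOR.values())
PHYSICAL_PREDICTORS = ["wave_exposure", "slope", "relief", "currents", "depth"]
ANTHRO_PREDICTORS = ["gravity", "dist_shore"]


def default_config(seed: int = 0) -> dict:
    """Default pipeline configuration (documented key by key in the docs)."""
    return {
        "seed": seed,
        "generator": {},  # overrides for GeneratorConfig fields
        "rf": {},  # overrides for RFSettings fields
        "inference": {
            "threshold": 0.9,
            "delta_window": 4.0,
            "cell_km": 100.0,
            "morans_permutations": 999,
        },
        "effects": {"radius_km": 20.0},
    }


def _config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True).encode()).hexdigest()[:16]


def _require(outdir: Path, name: str, producer: str) -> Path:
    p = outdir / name
    if not p.exists():
        raise FileNotFoundError(
            f"missing intermediate {name!r} in {outdir}; run the {producer!r} stage first"
        )
    return p


def _read(outdir: Path, name: str, producer: str) -> pd.DataFrame:
    return pd.read_csv(_require(outdir, name, producer))


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_simulate(config: dict, outdir: Path) -> list[str]:
    gen_kwargs = dict(config.get("generator", {}))
    gen_kwargs.setdefault("seed", config.get("seed", 0))
    gcfg = sd.GeneratorConfig(**gen_kwargs)
    data = sd.generate_dataset(gcfg)
    files = {
        "sites.csv": data["sites"],
        "species.csv": data["species"],
        "fish.csv": data["fish"],
        "habitat.csv": data["habitat"],
        "truth.csv": data["truth"],
    }
    for name, df in files.items():
        df.to_csv(outdir / name, index=False)
    gcfg.to_json(outdir / "generator_config.json")
    return list(files) + ["generator_config.json"]


def stage_process(config: dict, outdir: Path) -> list[str]:
    fish = _read(outdir, "fish.csv", "simulate")
    species = _read(outdir, "species.csv", "simulate")
    habitat = _read(outdir, "habitat.csv", "simulate")
    habitat["layer"] = habitat["layer"].fillna("")
    biomass = sp.process_fish(fish, species)
    covers = sp.process_habitat(habitat)
    biomass.to_csv(outdir / "biomass_by_site.csv", index=False)
    covers.to_csv(outdir / "habitat_by_site.csv", index=False)
    return ["biomass_by_site.csv", "habitat_by_site.csv"]


def stage_counterfactual(config: dict, outdir: Path) -> list[str]:
    sites = _read(outdir, "sites.csv", "simulate")
    biomass = _read(outdir, "biomass_by_site.csv", "process")
    rf_kwargs = dict(config.get("rf", {}))
    rf_kwargs.setdefault("seed", config.get("seed", 0))
    for key in ("ntrees_grid", "mtry_grid", "min_node_grid"):
        if key in rf_kwargs:
            rf_kwargs[key] = tuple(rf_kwargs[key])
    settings = cf.RFSettings(**rf_kwargs)
    ratios, bench = cf.run_counterfactual(sites, biomass, settings)
    ratios.to_csv(outdir / "counterfactual.csv", index=False)
    (outdir / "model_card.json").write_text(json.dumps(bench.model_card(), indent=2))
    return ["counterfactual.csv", "model_card.json"]


def stage_effects(config: dict, outdir: Path) -> list[str]:
    ratios = _read(outdir, "counterfactual.csv", "counterfactual")
    ratios["mpa_id"] = ratios["mpa_id"].fillna("")
    sites = _read(outdir, "sites.csv", "simulate")
    summary = ef.summarize_by_protection(ratios)
    summary.to_csv(outdir / "protection_summary.csv", index=False)
    radius = config.get("effects", {}).get("radius_km", 20.0)
    pairs, r = ef.control_impact_effects(ratios, sites, radius_km=radius)
    pairs["pearson_r_methods"] = r
    pairs.to_csv(outdir / "mpa_effect_pairs.csv", index=False)
    return ["protection_summary.csv", "mpa_effect_pairs.csv"]


def build_predictor_matrix(
    sites: pd.DataFrame, covers: pd.DataFrame, ratios: pd.DataFrame
) -> pd.DataFrame:
    """Join site context, harmonized habitat and response ratios per site."""
    hab = covers.rename(columns=BROAD_TO_PREDICTOR)
    df = ratios.merge(hab, on=["site_id", "survey_date"], how="inner")
    site_cols = [
        "site_id", "latitude", "longitude", "depth_m", "human_gravity",
        "dist_shore_m", "wave_exposure", "slope", "relief", "currents",
        "grid_cell",
    ]
    df = df.merge(sites[site_cols], on="site_id", how="left")
    df = df.rename(
        columns={"depth_m": "depth", "human_gravity": "gravity", "dist_shore_m": "dist_shore"}
    )
    return df


def stage_infer(config: dict, outdir: Path) -> list[str]:
    sites = _read(outdir, "sites.csv", "simulate")
    covers = _read(outdir, "habitat_by_site.csv", "process")
    ratios = _read(outdir, "counterfactual.csv", "counterfactual")
    inf_cfg = config.get("inference", {})
    df = build_predictor_matrix(sites, covers, ratios)
    continuous = HABITAT_PREDICTORS + PHYSICAL_PREDICTORS + ANTHRO_PREDICTORS
    prepared, screen = mi.prepare_predictors(df, continuous)
    screen.to_csv(outdir / "correlation_screen.csv", index=False)
    result = mi.run_inference(
        prepared,
        suites=inf_cfg.get("suites"),
        threshold=inf_cfg.get("threshold", 0.9),
        delta_window=inf_cfg.get("delta_window", 4.0),
        morans_seed=config.get("seed", 0),
        morans_permutations=inf_cfg.get("morans_permutations", 999),
    )
    written = ["correlation_screen.csv"]
    for name, suite in result.suites.items():
        fname = f"importance_{name.replace(' ', '_')}.csv"
        suite.importance.to_csv(outdir / fname, index=False)
        written.append(fname)
    mi.records_frame(result.global_records).to_csv(outdir / "model_set_global.csv", index=False)
    top = {
        "terms": list(result.top_model.terms),
        "k": result.top_model.k,
        "aicc": result.top_model.aicc,
        "reduced_predictor_set": list(result.reduced_terms),
        "estimates": result.effects.to_dict(orient="records"),
        "r2_marginal": result.r2_marginal,
        "r2_conditional": result.r2_conditional,
        "morans_i": result.morans.i,
        "morans_expected": result.morans.expected,
        "morans_p": result.morans.p_value,
    }
    (outdir / "top_model.json").write_text(json.dumps(top, indent=2))
    written += ["model_set_global.csv", "top_model.json"]
    return written


def stage_report(config: dict, outdir: Path) -> list[str]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = []
    summary = _read(outdir, "protection_summary.csv", "effects")
    ax = ef.plot_protection_summary(summary)
    ax.figure.savefig(outdir / "fig_protection_summary.png", dpi=150, bbox_inches="tight")
    plt.close(ax.figure)
    written.append("fig_protection_summary.png")
    top_path = outdir / "top_model.json"
    if top_path.exists():
        from .plotting import plot_partial_effects

        top = json.loads(top_path.read_text())
        fx = pd.DataFrame(top["estimates"])
        if len(fx):
            ax = plot_partial_effects(fx)
            ax.figure.savefig(outdir / "fig_partial_effects.png", dpi=150, bbox_inches="tight")
            plt.close(ax.figure)
            written.append("fig_partial_effects.png")
    return written


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "process": stage_process,
    "counterfactual": stage_counterfactual,
    "effects": stage_effects,
    "infer": stage_infer,
    "report": stage_report,
}


def run_pipeline(config: dict, outdir: str | Path, stages=STAGES) -> dict:
    """Run the requested stages in dependency order and write the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bad = [s for s in stages if s not in _STAGE_FUNCS]
    if bad:
        raise ValueError(f"unknown stages: {bad}")
    ordered = [s for s in STAGES if s in stages]
    outputs: list[str] = []
    for stage in ordered:
        t0 = time.time()
        produced = _STAGE_FUNCS[stage](config, outdir)
        logger.info("stage %s finished in %.1f s", stage, time.time() - t0)
        outputs += produced
    manifest = {
        "package_version": __version__,
        "config_hash": _config_hash(config),
        "seed": config.get("seed", 0),
        "stages": ordered,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "outputs": {
            name: hashlib.sha256((outdir / name).read_bytes()).hexdigest()
            for name in outputs
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate_inputs(outdir: str | Path) -> list[str]:
    """Schema and range checks on the raw input CSVs; returns problem strings."""
    outdir = Path(outdir)
    problems: list[str] = []

    fish_path = outdir / "fish.csv"
    if fish_path.exists():
        fish = pd.read_csv(fish_path)
        required = {"site_id", "survey_date", "transect_id", "species", "family",
                    "size_class_cm", "count"}
        missing = required - set(fish.columns)
        if missing:
            problems.append(f"fish.csv: missing columns {sorted(missing)}")
        else:
            legal = set(np.round(sp.legal_size_categories(), 3))
            bad = ~fish["size_class_cm"].round(3).isin(legal)
            for idx in fish.index[bad][:20]:
                problems.append(
                    f"fish.csv row {idx}: illegal size category {fish.loc[idx, 'size_class_cm']}"
                )
            if (fish["count"] < 0).any():
                problems.append("fish.csv: negative counts present")
    else:
        problems.append("fish.csv: file missing")

    hab_path = outdir / "habitat.csv"
    if hab_path.exists():
        hab = pd.read_csv(hab_path)
        fine = [c for c in hab.columns if c in sp.FINE_CATEGORIES]
        if "dialect" not in hab.columns:
            problems.append("habitat.csv: missing 'dialect' column")
        else:
            if not set(hab["dialect"]) <= {"photo_quadrat", "in_situ"}:
                problems.append("habitat.csv: unknown dialect values")
            pq = hab[hab["dialect"] == "photo_quadrat"]
            sums = pq[fine].sum(axis=1)
            for idx in pq.index[sums > 100 + 1e-9][:20]:
                problems.append(f"habitat.csv row {idx}: photo-quadrat covers sum > 100")
            ins = hab[hab["dialect"] == "in_situ"]
            layer_tot = ins[fine].sum(axis=1)
            for idx in ins.index[layer_tot > sp.QUADRAT_POINTS + 1e-9][:20]:
                problems.append(f"habitat.csv row {idx}: layer exceeds 50 points")
    else:
        problems.append("habitat.csv: file missing")

    sites_path = outdir / "sites.csv"
    if sites_path.exists():
        sites = pd.read_csv(sites_path)
        if "protection" in sites.columns:
            bad_levels = set(sites["protection"]) - set(sd.PROTECTION_LEVELS)
            if bad_levels:
                problems.append(f"sites.csv: unknown protection levels {sorted(bad_levels)}")
        else:
            problems.append("sites.csv: missing 'protection' column")
    else:
        problems.append("sites.csv: file missing")
    return problems
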