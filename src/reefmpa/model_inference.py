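"""Two-stage AICc multi-model inference for log response ratios.

Candidate linear mixed models (random intercept for 100x100 km grid cells)
relate site-level log response ratios to local biogenic habitat, physical
environment and anthropogenic predictors.  Within each predictor suite all
additive term combinations (obeying interaction hierarchy) are fitted by
maximum likelihood, ranked by AICc, and each term's importance is the sum of
Akaike weights of the models containing it.  Terms with importance >= 0.9
form a reduced set; all combinations of that set are refitted and the most
parsimonious model within DeltaAICc <= 4 of the best (lowest AICc among the
smallest-k candidates) is selected, refitted by REML, and summarized with
Nakagawa marginal/conditional R^2 and a Moran's I residual test.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from ._geo import pairwise_haversine_km, sinusoidal_xy_km

logger = logging.getLogger(__name__)

PROTECTION_TERM = "protection"
PROTECTION_REFERENCE = "fished"
PROTECTION_DUMMIES = ("partially protected", "fully protected")

#: Default predictor suites (mains; every suite also has `protection`
#: available, which each listed main may interact with).
DEFAULT_SUITES = {
    "biogenic habitat": ["turf", "sand", "sessile_inverts", "canopy", "understorey"],
    "physical environment": ["wave_exposure", "slope", "relief", "currents", "depth"],
    "anthropogenic": ["gravity", "dist_shore"],
}


# ---------------------------------------------------------------------------
# Predictor preparation
# ---------------------------------------------------------------------------

def prepare_predictors(
    data: pd.DataFrame,
    continuous: list[str],
    log10_cols: tuple[str, ...] = ("gravity", "dist_shore"),
    corr_threshold: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Transform and z-standardize predictors; screen for collinearity.

    Human gravity and distance from shore are log10 transformed before
    standardization.  All continuous predictors are centred and scaled to
    unit s.d.  Pairs with ``|r| >= corr_threshold`` are reported (and warned
    about) but never dropped automatically.

    Returns ``(prepared_frame, correlation_report)``.
    """
    out = data.copy()
    for col in continuous:
        x = out[col].to_numpy(dtype=float)
        if col in log10_cols:
            x = np.log10(x)
        sd = x.std()
        if sd == 0:
            raise ValueError(f"constant predictor column: {col!r}")
        out[col] = (x - x.mean()) / sd
    corr = out[continuous].corr().abs()
    pairs = []
    for i, a in enumerate(continuous):
        for b in continuous[i + 1:]:
            if corr.loc[a, b] >= corr_threshold:
                pairs.append({"var_a": a, "var_b": b, "abs_r": float(corr.loc[a, b])})
    report = pd.DataFrame(pairs, columns=["var_a", "var_b", "abs_r"])
    for p in pairs:
        warnings.warn(
            f"predictors {p['var_a']!r} and {p['var_b']!r} correlated (|r|={p['abs_r']:.2f})",
            stacklevel=2,
        )
    return out, report


def assign_grid_cell(lat, lon, cell_km: float = 100.0) -> np.ndarray:
    """Deterministic spatial-grid cell IDs from equal-area projected coordinates.

    Coordinates are sinusoidally projected to km and floor-divided by the
    cell size (default 100 km), giving IDs like ``'g104_-41'``.
    """
    x, y = sinusoidal_xy_km(lat, lon)
    ix = np.floor(np.asarray(x) / cell_km).astype(int)
    iy = np.floor(np.asarray(y) / cell_km).astype(int)
    ids = np.char.add(np.char.add("g", ix.astype(str)), np.char.add("_", iy.astype(str)))
    return ids


# ---------------------------------------------------------------------------
# Model enumeration and fitting
# ---------------------------------------------------------------------------

def _is_interaction(term: str) -> bool:
    return ":" in term


def _interaction_parents(term: str) -> tuple[str, str]:
    a, b = term.split(":")
    return a, b


def canonical_terms(terms) -> tuple[str, ...]:
    """Deterministic term ordering: numeric mains, protection, interactions."""
    mains = sorted(t for t in terms if not _is_interaction(t) and t != PROTECTION_TERM)
    prot = [PROTECTION_TERM] if PROTECTION_TERM in terms else []
    inter = sorted(t for t in terms if _is_interaction(t))
    return tuple(mains + prot + inter)


def enumerate_models(
    mains: list[str], interactions: list[str] | None = None
) -> list[tuple[str, ...]]:
    """All additive term combinations obeying the interaction hierarchy.

    ``interactions`` are ``'x:protection'`` strings; a model may contain one
    only if it also contains both parent mains.  The intercept-only model
    (empty tuple) is always included.
    """
    interactions = interactions or []
    models = []
    for r in range(len(mains) + 1):
        for combo in itertools.combinations(mains, r):
            present = set(combo)
            admissible = [
                t for t in interactions
                if set(_interaction_parents(t)) <= present
            ]
            for ri in range(len(admissible) + 1):
                for icombo in itertools.combinations(admissible, ri):
                    models.append(canonical_terms(set(combo) | set(icombo)))
    return models


def design_matrix(data: pd.DataFrame, terms) -> pd.DataFrame:
    """Fixed-effects design matrix for a term set.

    ``protection`` expands to treatment dummies against the fished reference;
    ``x:protection`` expands to the numeric column times each dummy.
    """
    n = len(data)
    cols: dict[str, np.ndarray] = {"Intercept": np.ones(n)}
    dummies = {}
    if PROTECTION_TERM in data.columns:
        for level in PROTECTION_DUMMIES:
            dummies[level] = (data[PROTECTION_TERM] == level).to_numpy(dtype=float)
    for term in canonical_terms(terms):
        if term == PROTECTION_TERM:
            for level in PROTECTION_DUMMIES:
                cols[f"protection[{level}]"] = dummies[level]
        elif _is_interaction(term):
            num, other = _interaction_parents(term)
            if other != PROTECTION_TERM:
                raise ValueError(f"only interactions with protection are supported: {term!r}")
            x = data[num].to_numpy(dtype=float)
            for level in PROTECTION_DUMMIES:
                cols[f"{num}:protection[{level}]"] = x * dummies[level]
        else:
            cols[term] = data[term].to_numpy(dtype=float)
    return pd.DataFrame(cols, index=data.index)


@dataclass
class LMMFit:
    """One fitted candidate mixed model."""

    terms: tuple[str, ...]
    k: int  # fixed-effect params (incl. intercept) + 2 variance components
    loglik: float
    n: int
    result: object = field(repr=False)
    converged: bool = True
    singular: bool = False


def fit_lmm(
    data: pd.DataFrame,
    terms,
    y: str = "lnrr",
    group: str = "grid_cell",
    reml: bool = False,
) -> LMMFit:
    """Fit a linear mixed model with a grid-cell random intercept.

    ML by default so that log-likelihoods are comparable across fixed-effect
    structures; REML for reporting final estimates.  A fit on the variance
    boundary (singular) is flagged but retained.
    """
    if data[group].nunique() < 2:
        raise ValueError("need >= 2 grid cells for a random intercept")
    exog = design_matrix(data, terms)
    k = exog.shape[1] + 2
    if len(data) <= k + 2:
        raise ValueError("too few observations for the requested model")
    endog = data[y].to_numpy(dtype=float)
    model = sm.MixedLM(endog, exog, groups=data[group].to_numpy())
    singular = False
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        res = None
        for method in ("bfgs", "powell", "cg"):
            res = model.fit(reml=reml, method=method, maxiter=500)
            if np.isfinite(res.llf):
                break
        for w in caught:
            msg = str(w.message).lower()
            if "boundary" in msg or "singular" in msg:
                singular = True
            if "converge" in msg and "failed" in msg:
                converged = False
    if singular:
        logger.warning("singular fit (variance on boundary) for terms %s", terms)
    return LMMFit(
        terms=canonical_terms(terms),
        k=k,
        loglik=float(res.llf),
        n=len(data),
        result=res,
        converged=converged,
        singular=singular,
    )


# ---------------------------------------------------------------------------
# Information-theoretic machinery
# ---------------------------------------------------------------------------

def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample corrected Akaike criterion: -2*ll + 2k + 2k(k+1)/(n-k-1)."""
    if n <= k + 1:
        raise ValueError("AICc requires n > k + 1")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def akaike_weights(aicc_values) -> np.ndarray:
    """Akaike weights w_i = exp(-Delta_i/2) / sum_j exp(-Delta_j/2)."""
    a = np.asarray(aicc_values, dtype=float)
    if a.size == 0:
        raise ValueError("need at least one model")
    delta = a - a.min()
    w = np.exp(-delta / 2.0)
    return w / w.sum()


@dataclass
class ModelRecord:
    """One candidate model's selection bookkeeping."""

    terms: tuple[str, ...]
    k: int
    loglik: float
    aicc: float
    delta_aicc: float = np.nan
    weight: float = np.nan
    singular: bool = False


def rank_models(fits: list[LMMFit]) -> list[ModelRecord]:
    """Attach AICc, DeltaAICc and Akaike weights to a fitted model set."""
    aiccs = np.array([aicc(f.loglik, f.k, f.n) for f in fits])
    weights = akaike_weights(aiccs)
    best = aiccs.min()
    records = [
        ModelRecord(f.terms, f.k, f.loglik, float(a), float(a - best), float(w), f.singular)
        for f, a, w in zip(fits, aiccs, weights)
    ]
    return sorted(records, key=lambda r: r.aicc)


def records_frame(records: list[ModelRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "terms": [" + ".join(r.terms) if r.terms else "(intercept)" for r in records],
            "k": [r.k for r in records],
            "loglik": [r.loglik for r in records],
            "aicc": [r.aicc for r in records],
            "delta_aicc": [r.delta_aicc for r in records],
            "weight": [r.weight for r in records],
            "singular": [r.singular for r in records],
        }
    )


def variable_importance(records: list[ModelRecord]) -> pd.DataFrame:
    """Per-term sum of Akaike weights over all models containing the term."""
    all_terms = sorted({t for r in records for t in r.terms})
    rows = [
        {
            "predictor": t,
            "importance": float(sum(r.weight for r in records if t in r.terms)),
        }
        for t in all_terms
    ]
    out = pd.DataFrame(rows, columns=["predictor", "importance"])
    return out.sort_values("importance", ascending=False, ignore_index=True)


def reduce_predictor_set(importance, threshold: float = 0.9) -> tuple[str, ...]:
    """Terms with importance >= threshold, closed under interaction hierarchy.

    ``importance`` is a mapping term -> importance or a DataFrame with
    ``predictor``/``importance`` columns (several suite tables may simply be
    concatenated; the union of qualifying terms is taken).
    """
    if isinstance(importance, pd.DataFrame):
        items = list(zip(importance["predictor"], importance["importance"]))
    else:
        items = list(importance.items())
    retained = {t for t, v in items if v >= threshold}
    for t in list(retained):
        if _is_interaction(t):
            retained.update(_interaction_parents(t))
    return canonical_terms(retained)


def select_top_model(records: list[ModelRecord], delta_window: float = 4.0) -> ModelRecord:
    """Most parsimonious model in the top set (DeltaAICc <= window).

    Among candidates within the window of the best AICc, the model with the
    fewest parameters wins; ties on k are broken by lowest AICc, then by the
    term string, making the choice independent of input order.
    """
    if not records:
        raise ValueError("need at least one model record")
    best = min(r.aicc for r in records)
    candidates = [r for r in records if r.aicc - best <= delta_window]
    return min(candidates, key=lambda r: (r.k, r.aicc, r.terms))


# ---------------------------------------------------------------------------
# Fit diagnostics
# ---------------------------------------------------------------------------

def nakagawa_r2_from_variances(var_fixed: float, var_random: float, var_resid: float):
    """Marginal and conditional R^2 from variance components."""
    total = var_fixed + var_random + var_resid
    return var_fixed / total, (var_fixed + var_random) / total


def nakagawa_r2(fit: LMMFit) -> tuple[float, float]:
    """Nakagawa marginal/conditional R^2 of a fitted mixed model.

    The fixed-effect variance is the variance of the fixed-effect linear
    predictor; the random variance is the grid-cell intercept variance.
    """
    res = fit.result
    linpred = np.asarray(res.model.exog) @ np.asarray(res.fe_params)
    var_fixed = float(np.var(linpred))
    var_random = float(np.asarray(res.cov_re)[0, 0])
    var_resid = float(res.scale)
    return nakagawa_r2_from_variances(var_fixed, var_random, var_resid)


@dataclass
class MoransIResult:
    i: float
    expected: float
    p_value: float
    n_permutations: int


def morans_i(
    residuals,
    latitude,
    longitude,
    scheme: str = "inverse_distance",
    k_neighbors: int = 8,
    n_permutations: int = 999,
    seed: int = 0,
) -> MoransIResult:
    """Moran's I spatial autocorrelation with a permutation test.

    Weights are inverse great-circle distance by default (``scheme='knn'``
    uses binary k-nearest-neighbour weights).  The permutation p-value is
    two-sided around the null expectation E[I] = -1/(n-1).
    """
    z = np.asarray(residuals, dtype=float)
    n = z.size
    if n < 10:
        raise ValueError("Moran's I needs at least 10 sites")
    d = pairwise_haversine_km(latitude, longitude)
    if scheme == "inverse_distance":
        with np.errstate(divide="ignore"):
            w = 1.0 / np.maximum(d, 1e-3)
        np.fill_diagonal(w, 0.0)
    elif scheme == "knn":
        w = np.zeros_like(d)
        np.fill_diagonal(d, np.inf)
        nn = np.argsort(d, axis=1)[:, :k_neighbors]
        rows = np.repeat(np.arange(n), k_neighbors)
        w[rows, nn.ravel()] = 1.0
    else:
        raise ValueError(f"unknown weight scheme {scheme!r}")
    s0 = w.sum()
    zc = z - z.mean()
    denom = float(zc @ zc)
    i_obs = float(n / s0 * (zc @ w @ zc) / denom)
    expected = -1.0 / (n - 1)

    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(zc) for _ in range(n_permutations)])
    i_perm = n / s0 * np.einsum("pi,ij,pj->p", perms, w, perms) / denom
    extreme = np.abs(i_perm - expected) >= abs(i_obs - expected) - 1e-15
    p = (1.0 + extreme.sum()) / (n_permutations + 1.0)
    return MoransIResult(i_obs, expected, float(p), n_permutations)


def partial_effects(fit: LMMFit, alpha: float = 0.05) -> pd.DataFrame:
    """Standardized fixed-effect estimates with Wald CIs, ordered by |estimate|.

    Protection contrasts are reported against the fished reference level.
    """
    res = fit.result
    names = list(res.model.exog_names)
    fe = np.asarray(res.fe_params)
    se = np.asarray(res.bse_fe)
    from scipy.stats import norm

    zq = norm.ppf(1 - alpha / 2)
    rows = []
    for name, est, s in zip(names, fe, se):
        if name == "Intercept":
            continue
        lo, hi = est - zq * s, est + zq * s
        rows.append(
            {
                "term": name,
                "estimate": float(est),
                "se": float(s),
                "ci95_low": float(lo),
                "ci95_high": float(hi),
                "significant": bool(lo > 0 or hi < 0),
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out = out.reindex(out["estimate"].abs().sort_values(ascending=False).index)
        out = out.reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# Suite orchestration
# ---------------------------------------------------------------------------

@dataclass
class SuiteResult:
    name: str
    records: list[ModelRecord]
    importance: pd.DataFrame  # columns: category, predictor, importance
    fits: list[LMMFit] = field(repr=False, default_factory=list)


def run_suite(
    data: pd.DataFrame,
    name: str,
    mains: list[str],
    with_protection: bool = True,
    y: str = "lnrr",
    group: str = "grid_cell",
) -> SuiteResult:
    """Fit all additive combinations of a suite's terms and rank them.

    Protection is available as a main effect in every suite and each listed
    main may interact with it.
    """
    suite_mains = list(mains) + ([PROTECTION_TERM] if with_protection else [])
    interactions = (
        [f"{m}:{PROTECTION_TERM}" for m in mains if m != PROTECTION_TERM]
        if with_protection
        else []
    )
    term_sets = enumerate_models(suite_mains, interactions)
    fits = [fit_lmm(data, ts, y=y, group=group, reml=False) for ts in term_sets]
    records = rank_models(fits)
    imp = variable_importance(records)
    imp.insert(0, "category", name)
    return SuiteResult(name=name, records=records, importance=imp, fits=fits)


@dataclass
class InferenceResult:
    suites: dict[str, SuiteResult]
    reduced_terms: tuple[str, ...]
    global_records: list[ModelRecord]
    top_model: ModelRecord
    top_fit_reml: LMMFit
    r2_marginal: float
    r2_conditional: float
    morans: MoransIResult
    effects: pd.DataFrame


def run_inference(
    data: pd.DataFrame,
    suites: dict[str, list[str]] | None = None,
    y: str = "lnrr",
    group: str = "grid_cell",
    threshold: float = 0.9,
    delta_window: float = 4.0,
    morans_seed: int = 0,
    morans_permutations: int = 999,
) -> InferenceResult:
    """Full two-stage multi-model inference.

    Stage 1 ranks each predictor suite separately and computes per-term
    importance.  Stage 2 unions the terms with importance >= ``threshold``,
    fits all combinations of that reduced set, selects the most parsimonious
    top model, refits it by REML and reports effects and diagnostics.
    """
    suites = suites or DEFAULT_SUITES
    suite_results = {
        name: run_suite(data, name, mains, y=y, group=group)
        for name, mains in suites.items()
    }
    combined = pd.concat([s.importance for s in suite_results.values()], ignore_index=True)
    reduced = reduce_predictor_set(combined[["predictor", "importance"]], threshold)

    g_mains = [t for t in reduced if not _is_interaction(t)]
    g_inter = [t for t in reduced if _is_interaction(t)]
    term_sets = enumerate_models(g_mains, g_inter)
    fits = [fit_lmm(data, ts, y=y, group=group, reml=False) for ts in term_sets]
    global_records = rank_models(fits)
    top = select_top_model(global_records, delta_window)

    top_fit = fit_lmm(data, top.terms, y=y, group=group, reml=True)
    r2m, r2c = nakagawa_r2(top_fit)
    resid = np.asarray(top_fit.result.resid)
    mi = morans_i(
        resid,
        data["latitude"],
        data["longitude"],
        seed=morans_seed,
        n_permutations=morans_permutations,
    )
    fx = partial_effects(top_fit)
    return InferenceResult(
        suites=suite_results,
        reduced_terms=reduced,
        global_records=global_records,
        top_model=top,
        top_fit_reml=top_fit,
        r2_marginal=r2m,
        r2_conditional=r2c,
        morans=mi,
        effects=fx,
    )
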