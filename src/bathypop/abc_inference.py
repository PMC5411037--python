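"""Approximate Bayesian computation over the divergence scenarios.

Model choice follows the rejection + multinomial-logistic-regression recipe:
summary statistics are standardized by the reference-table spread, the
closest fraction of simulations (Euclidean distance) is retained, and a
weighted multinomial logistic regression of scenario identity on the
summaries is evaluated at the observed point. Parameter posteriors use the
local-linear regression adjustment on logit-transformed parameters with
Epanechnikov weights; scenario confidence is measured by classifying
pseudo-observed datasets (pods), and model checking compares held-out
summary statistics of posterior-predictive simulations with the observed
ones.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression

from .coalescent_sim import (
    SENTINEL,
    SUMMARY_NAMES,
    ParameterDraw,
    ScenarioSpec,
    draw_prior_parameters,
    simulate_scenario,
    summary_statistics,
)

__all__ = [
    "ReferenceTable",
    "PosteriorSummary",
    "build_reference_table",
    "abc_model_choice",
    "abc_parameter_posterior",
    "abc_confidence",
    "abc_model_check",
    "DEFAULT_USED_STATS",
    "DEFAULT_HOLDOUT_STATS",
]

# statistics used for distances/regression vs held out for the model check
DEFAULT_USED_STATS = (
    "A_ATL", "A_MED", "HE_ATL", "HE_MED", "V_ATL", "V_MED",
    "Hn_ATL", "Hn_MED", "Hd_ATL", "Hd_MED", "k_ATL", "k_MED",
    "FST", "PHIST",
)
DEFAULT_HOLDOUT_STATS = ("D_ATL", "D_MED", "DAS", "SHARED_HAPS")


@dataclass
class ReferenceTable:
    """Simulated (scenario, parameters, summary vector) records."""

    draws: list[ParameterDraw]
    scenarios: np.ndarray  # (rows,)
    summaries: np.ndarray  # (rows, n_stats), sentinel-imputed lazily
    stat_names: tuple[str, ...] = SUMMARY_NAMES
    used_stats: tuple[str, ...] = DEFAULT_USED_STATS
    standardization: str = "meansd"  # or "mad"

    def __post_init__(self) -> None:
        self.scenarios = np.asarray(self.scenarios)
        self.summaries = np.asarray(self.summaries, dtype=float)

    # ------------------------------------------------------------------
    def _used_index(self) -> np.ndarray:
        return np.array([self.stat_names.index(s) for s in self.used_stats])

    def _imputed(self, cols: np.ndarray) -> np.ndarray:
        X = self.summaries[:, cols].copy()
        for j in range(X.shape[1]):
            bad = (X[:, j] == SENTINEL) | ~np.isfinite(X[:, j])
            if bad.any():
                good = X[~bad, j]
                X[bad, j] = good.mean() if good.size else 0.0
        return X

    def scale(self) -> tuple[np.ndarray, np.ndarray]:
        cols = self._used_index()
        X = self._imputed(cols)
        if self.standardization == "mad":
            center = np.median(X, axis=0)
            spread = np.median(np.abs(X - center), axis=0) * 1.4826
        else:
            center = X.mean(axis=0)
            spread = X.std(axis=0)
        spread[spread == 0] = 1.0
        return center, spread

    def standardized(self, observed: np.ndarray | None = None):
        cols = self._used_index()
        center, spread = self.scale()
        X = (self._imputed(cols) - center) / spread
        if observed is None:
            return X, None
        obs = np.asarray(observed, dtype=float)[cols].copy()
        bad = (obs == SENTINEL) | ~np.isfinite(obs)
        obs[bad] = center[bad]  # undefined observed entries carry no signal
        return X, (obs - center) / spread


@dataclass
class PosteriorSummary:
    """Posterior table (mean/median/mode/95% CI per parameter) + samples."""

    scenario: int
    table: pd.DataFrame
    samples: pd.DataFrame  # adjusted draws (rows = retained)
    weights: np.ndarray
    retained_index: np.ndarray


def build_reference_table(
    specs: list[ScenarioSpec],
    rows_per_scenario: int,
    n_atl: int,
    n_med: int,
    n_loci: int = 9,
    seq_len: int = 613,
    seed: int | None = None,
    mtdna_per_diploid: float = 1.0,
) -> ReferenceTable:
    """Simulate the reference table, equal rows per scenario."""
    rng = np.random.default_rng(seed)
    draws: list[ParameterDraw] = []
    scen = []
    summ = []
    for spec in specs:
        for _ in range(rows_per_scenario):
            d = draw_prior_parameters(spec, n_loci=n_loci, rng=rng)
            s = simulate_scenario(
                d, n_atl, n_med, n_loci=n_loci, seq_len=seq_len, rng=rng,
                mtdna_per_diploid=mtdna_per_diploid,
            )
            draws.append(d)
            scen.append(spec.scenario)
            summ.append(summary_statistics(s))
    return ReferenceTable(draws, np.array(scen), np.array(summ))


def _epanechnikov(d: np.ndarray, bandwidth: float) -> np.ndarray:
    u = d / bandwidth
    w = 1.0 - u**2
    w[w < 0] = 0.0
    return w


def _retain(ref: ReferenceTable, observed: np.ndarray, retained_fraction: float):
    X, obs = ref.standardized(observed)
    d = np.sqrt(((X - obs) ** 2).sum(axis=1))
    k = max(2, int(math.ceil(retained_fraction * X.shape[0])))
    order = np.argsort(d, kind="stable")
    idx = order[:k]
    bw = d[order[k - 1]]
    if bw == 0:
        bw = 1e-12
    w = _epanechnikov(d[idx], bw)
    w[w == 0] = np.min(w[w > 0]) if (w > 0).any() else 1.0
    return idx, X[idx], obs, w, d


def abc_model_choice(
    ref: ReferenceTable,
    observed: np.ndarray,
    retained_fraction: float = 0.01,
    ci_bootstraps: int = 0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Scenario posterior probabilities by weighted multinomial logistic
    regression on the retained simulations, evaluated at the observed point.

    Returns a frame indexed by scenario with columns ``p`` (and ``lo``/``hi``
    95% bootstrap bounds when ``ci_bootstraps`` > 0). Scenarios absent from
    the retained set receive probability 0 with a warning.
    """
    idx, Xr, obs, w, _ = _retain(ref, observed, retained_fraction)
    yr = ref.scenarios[idx]
    all_scen = np.unique(ref.scenarios)
    missing = [s for s in all_scen if s not in yr]
    if missing:
        warnings.warn(f"scenario(s) {missing} absent from retained set")

    def fit_probs(X, y, wts):
        present = np.unique(y)
        if present.size == 1:
            p = {int(present[0]): 1.0}
        else:
            clf = LogisticRegression(max_iter=2000, C=10.0)
            clf.fit(X, y, sample_weight=wts)
            probs = clf.predict_proba(obs[None, :])[0]
            p = {int(c): float(pr) for c, pr in zip(clf.classes_, probs)}
        return np.array([p.get(int(s), 0.0) for s in all_scen])

    probs = fit_probs(Xr, yr, w)
    out = pd.DataFrame({"p": probs}, index=pd.Index(all_scen, name="scenario"))
    if ci_bootstraps:
        rng = np.random.default_rng(seed)
        boots = []
        for _ in range(ci_bootstraps):
            bi = rng.integers(0, len(idx), size=len(idx))
            try:
                boots.append(fit_probs(Xr[bi], yr[bi], w[bi]))
            except Exception:  # singular resample
                continue
        if boots:
            B = np.array(boots)
            out["lo"] = np.percentile(B, 2.5, axis=0)
            out["hi"] = np.percentile(B, 97.5, axis=0)
    return out


# ----------------------------------------------------------------------
# parameter posteriors
# ----------------------------------------------------------------------


def _logit_scale(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    z = np.clip((x - lo) / (hi - lo), 1e-9, 1 - 1e-9)
    return np.log(z / (1 - z))


def _inv_logit_scale(y: np.ndarray, lo: float, hi: float) -> np.ndarray:
    return lo + (hi - lo) / (1.0 + np.exp(-y))


def _weighted_quantile(x: np.ndarray, w: np.ndarray, q: float) -> float:
    order = np.argsort(x)
    cw = np.cumsum(w[order])
    cw /= cw[-1]
    return float(np.interp(q, cw, x[order]))


def abc_parameter_posterior(
    ref: ReferenceTable,
    observed: np.ndarray,
    scenario: int,
    retained_fraction: float = 0.01,
    parameters: tuple[str, ...] | None = None,
    priors: dict[str, tuple[float, float]] | None = None,
) -> PosteriorSummary:
    """Regression-adjusted parameter posterior for one scenario.

    Retained parameter draws are logit-transformed to their prior bounds,
    locally (weighted least squares) regressed on the standardized summary
    offsets, adjusted to the observed point and back-transformed. The mode
    comes from a weighted Gaussian KDE (Silverman bandwidth) on the
    transformed scale. Falls back to the rejection-only posterior when the
    local regression is singular.
    """
    mask = ref.scenarios == scenario
    sub = ReferenceTable(
        [d for d, m in zip(ref.draws, mask) if m],
        ref.scenarios[mask],
        ref.summaries[mask],
        ref.stat_names,
        ref.used_stats,
        ref.standardization,
    )
    idx, Xr, obs, w, _ = _retain(sub, observed, retained_fraction)
    records = [sub.draws[i].as_dict() for i in idx]
    frame = pd.DataFrame(records)
    if parameters is None:
        parameters = tuple(
            c for c in frame.columns if c not in ("scenario",)
        )
    if priors is None:
        from .coalescent_sim import default_priors

        pri = default_priors()
        priors = {p: pri[p.replace("mu_msat_mean", "mu_msat").replace("mu_mtdna", "mu_mtdna")]
                  for p in parameters if p.replace("mu_msat_mean", "mu_msat") in pri or p in pri}
        # N_anc mirrors N_ATL's prior by default
        if "N_anc" in parameters and "N_anc" not in priors:
            priors["N_anc"] = pri["N_ATL"]

    D = Xr - obs  # summary offsets
    A = np.hstack([np.ones((D.shape[0], 1)), D])
    sw = np.sqrt(w)
    rows = []
    samples = {}
    for p in parameters:
        lo, hi = priors.get(p, (frame[p].min(), frame[p].max()))
        if hi <= lo:
            lo, hi = lo - 0.5, hi + 0.5
        y = _logit_scale(frame[p].to_numpy(dtype=float), lo, hi)
        try:
            beta, *_ = np.linalg.lstsq(A * sw[:, None], y * sw, rcond=None)
            adjusted = beta[0] + (y - A @ beta)
            if not np.all(np.isfinite(adjusted)):
                raise np.linalg.LinAlgError
        except np.linalg.LinAlgError:
            warnings.warn(f"singular local regression for {p}: rejection only")
            adjusted = y
        vals = _inv_logit_scale(adjusted, lo, hi)
        samples[p] = vals
        mean = float(np.average(vals, weights=w))
        med = _weighted_quantile(vals, w, 0.5)
        lo95 = _weighted_quantile(vals, w, 0.025)
        hi95 = _weighted_quantile(vals, w, 0.975)
        mode = _weighted_mode(adjusted, w, lo, hi)
        rows.append(
            {"parameter": p, "mean": mean, "median": med, "mode": mode,
             "ci_lower": lo95, "ci_upper": hi95}
        )
    table = pd.DataFrame(rows).set_index("parameter")
    return PosteriorSummary(scenario, table, pd.DataFrame(samples), w, idx)


def _weighted_mode(transformed: np.ndarray, w: np.ndarray, lo: float, hi: float) -> float:
    if np.allclose(transformed, transformed[0]):
        return float(_inv_logit_scale(np.array([transformed[0]]), lo, hi)[0])
    try:
        kde = gaussian_kde(transformed, weights=w)
    except np.linalg.LinAlgError:
        return float(_inv_logit_scale(np.array([np.median(transformed)]), lo, hi)[0])
    grid = np.linspace(transformed.min(), transformed.max(), 512)
    dens = kde(grid)
    return float(_inv_logit_scale(np.array([grid[np.argmax(dens)]]), lo, hi)[0])


# ----------------------------------------------------------------------
# confidence (type I / II errors)
# ----------------------------------------------------------------------


def abc_confidence(
    ref: ReferenceTable,
    specs: list[ScenarioSpec],
    chosen_scenario: int,
    n_pods: int = 100,
    n_atl: int | None = None,
    n_med: int | None = None,
    sim_kwargs: dict | None = None,
    retained_fraction: float = 0.01,
    seed: int | None = None,
) -> dict:
    """Classify pods from every scenario; report the chosen scenario's
    type I error (true but not selected) and type II error (selected though
    another scenario is true), plus the full confusion matrix."""
    rng = np.random.default_rng(seed)
    sim_kwargs = dict(sim_kwargs or {})
    scenarios = [s.scenario for s in specs]
    confusion = {s: {t: 0 for t in scenarios} for s in scenarios}
    for spec in specs:
        for _ in range(n_pods):
            d = draw_prior_parameters(spec, n_loci=sim_kwargs.get("n_loci", 9), rng=rng)
            pod = simulate_scenario(
                d, n_atl, n_med, rng=rng, **sim_kwargs
            )
            obs = summary_statistics(pod)
            probs = abc_model_choice(ref, obs, retained_fraction)
            sel = int(probs["p"].idxmax())
            confusion[spec.scenario][sel] += 1
    true_total = n_pods
    type1 = 1.0 - confusion[chosen_scenario][chosen_scenario] / true_total
    others = [s for s in scenarios if s != chosen_scenario]
    type2 = (
        sum(confusion[s][chosen_scenario] for s in others)
        / (len(others) * true_total)
        if others
        else 0.0
    )
    return {"type1": type1, "type2": type2, "confusion": confusion}


# ----------------------------------------------------------------------
# model check
# ----------------------------------------------------------------------


def abc_model_check(
    ref: ReferenceTable,
    posterior: PosteriorSummary,
    observed: np.ndarray,
    n_sim: int = 200,
    n_atl: int | None = None,
    n_med: int | None = None,
    sim_kwargs: dict | None = None,
    holdout_stats: tuple[str, ...] = DEFAULT_HOLDOUT_STATS,
    seed: int | None = None,
) -> dict:
    """Posterior-predictive check on the held-out summary statistics.

    Parameter draws are resampled from the retained set (posterior weights),
    datasets simulated, and per holdout statistic the lower-tail probability
    of the observed value reported, together with PCA coordinates of the
    simulated summary cloud and of the observed point.
    """
    if not holdout_stats:
        warnings.warn("no holdout statistics configured: model check skipped")
        return {}
    rng = np.random.default_rng(seed)
    mask = ref.scenarios == posterior.scenario
    scen_draws = [d for d, m in zip(ref.draws, mask) if m]
    w = posterior.weights / posterior.weights.sum()
    sims = []
    sim_kwargs = dict(sim_kwargs or {})
    for _ in range(n_sim):
        i = rng.choice(posterior.retained_index, p=w)
        d = scen_draws[int(i)]
        s = simulate_scenario(d, n_atl, n_med, rng=rng, **sim_kwargs)
        sims.append(summary_statistics(s))
    S = np.array(sims)
    cols = np.array([ref.stat_names.index(s) for s in holdout_stats])
    obs = np.asarray(observed, dtype=float)
    pvals = {}
    for name, c in zip(holdout_stats, cols):
        vals = S[:, c]
        vals = vals[vals != SENTINEL]
        if vals.size == 0 or obs[c] == SENTINEL:
            pvals[name] = np.nan
            continue
        pvals[name] = float((np.sum(vals <= obs[c]) + 1) / (vals.size + 1))
    # PCA overlay on all statistics (imputed + standardized by the cloud)
    allcols = np.arange(S.shape[1])
    X = S.copy()
    for j in allcols:
        bad = (X[:, j] == SENTINEL) | ~np.isfinite(X[:, j])
        if bad.any():
            good = X[~bad, j]
            X[bad, j] = good.mean() if good.size else 0.0
    center, spread = X.mean(axis=0), X.std(axis=0)
    spread[spread == 0] = 1.0
    Z = (X - center) / spread
    o = obs.copy()
    o[o == SENTINEL] = 0.0
    zo = (o - center) / spread
    pca = PCA(n_components=2)
    coords = pca.fit_transform(Z)
    obs_coord = pca.transform(zo[None, :])[0]
    return {"p_values": pvals, "sim_coords": coords, "obs_coord": obs_coord}
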