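"""Family-level single-season occupancy-detection models.

The observation model separates the probability a site is occupied (psi,
logit-linear in site elevation and the canopy-on-elevation residual) from the
probability of detection per 6-minute survey given occupancy (p, logit-linear
in survey conditions).  The baseline detection predictor is

    wind + hour + hour^2 + date + date^2 + canopy + canopy^2 + lag

where ``lag`` is a first-order Markov covariate: the observed detection at the
immediately preceding same-day ARU occasion (0 for first-of-day and all PC
occasions).  Eight further models add a method (PC/ARU) main effect and the
seven combinations of method interactions with canopy, hour and date (each
interaction carries both the linear and quadratic term), for nine models in
total.  Models are ranked by QAIC = -2 logL / max(c-hat, 1) + 2 (K + 1), with
the overdispersion c-hat estimated for the most complex model by the
MacKenzie-Bailey parametric bootstrap.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit

from .survey_data import SurveyDataset, canopy_residuals

_EPS = 1e-300

SURVEY_CONDITIONS = ("canopy", "hour", "date")


class DataInsufficientError(ValueError):
    """Too few sites with detections to fit an occupancy model."""


# ---------------------------------------------------------------------------
# detection histories
# ---------------------------------------------------------------------------

@dataclass
class DetectionHistory:
    """Site x occasion binary detections with occasion and site covariates.

    All arrays are (n_sites, n_occasions); ``np.nan`` in ``y`` marks missing
    occasions.  ``lag_prev[:, j]`` is True when occasion j's Markov covariate
    is the observed detection at occasion j-1 (same site, same day, ARU).
    Occasion covariates are stored standardized; ``scalers`` keeps the
    (mean, sd) pairs for back-transformation of prediction grids.
    """

    family: str
    site_ids: list[str]
    y: np.ndarray
    method: np.ndarray          # 1 = ARU, 0 = PC
    wind: np.ndarray
    hour: np.ndarray
    date: np.ndarray
    canopy: np.ndarray
    lag: np.ndarray
    lag_prev: np.ndarray
    elevation: np.ndarray       # (n_sites,), standardized
    canopy_resid: np.ndarray    # (n_sites,), standardized
    scalers: dict = field(default_factory=dict)
    habitats: tuple = ()

    @property
    def n_sites(self) -> int:
        return self.y.shape[0]

    @property
    def n_occasions(self) -> int:
        return self.y.shape[1]

    @property
    def mask(self) -> np.ndarray:
        return ~np.isnan(self.y)

    def n_detected_sites(self) -> int:
        return int((np.nansum(self.y, axis=1) > 0).sum())


def _standardize(x: np.ndarray, mask: np.ndarray | None = None):
    vals = x[mask] if mask is not None else x
    mu = float(np.mean(vals))
    sd = float(np.std(vals))
    if sd == 0:
        sd = 1.0
    return (x - mu) / sd, (mu, sd)


def build_history(ds: SurveyDataset, family: str,
                  habitats: tuple[str, ...] | list[str],
                  max_occasions: int = 23) -> DetectionHistory:
    """Assemble the detection history for one family over selected habitats.

    Uses every site in the habitats (PC-only sites included: they inform psi
    and the PC detection process).  Occasions are ordered PC rounds first,
    then ARU samples by (day, hour).  Continuous covariates are standardized
    over observed occasions; wind enters as numeric 0-3 (also standardized).
    """
    fam_map = ds.species_to_family()
    fam_species = set(fam_map[fam_map == family].index)
    if not fam_species:
        raise ValueError(f"family {family!r} absent from the species lookup")

    sites = ds.sites[ds.sites["habitat"].isin(habitats)].reset_index(drop=True)
    if sites.empty:
        raise ValueError(f"no sites in habitats {habitats!r}")
    site_ids = list(sites["site_id"])
    resid_all = canopy_residuals(ds.sites)

    sv = ds.surveys[ds.surveys["site_id"].isin(site_ids)].copy()
    det_sv = set(
        ds.detections.loc[ds.detections["species"].isin(fam_species), "survey_id"]
    )
    sv["detected"] = sv["survey_id"].isin(det_sv).astype(float)

    # deterministic occasion order: PC by round, then ARU by day then hour
    sv["is_aru"] = (sv["method"] == "ARU").astype(int)
    sv = sv.sort_values(
        ["site_id", "is_aru", "round_index", "day_index", "hour_index"],
        kind="mergesort",
    )

    per_site = {sid: grp for sid, grp in sv.groupby("site_id")}
    n_occ = max((len(g) for g in per_site.values()), default=0)
    if n_occ == 0:
        raise ValueError("no surveys at the selected sites")
    if n_occ > max_occasions:
        raise ValueError(f"{n_occ} occasions at one site exceeds the maximum {max_occasions}")

    n = len(site_ids)
    shape = (n, n_occ)
    y = np.full(shape, np.nan)
    method = np.zeros(shape)
    wind = np.zeros(shape)
    hour = np.zeros(shape)
    date = np.zeros(shape)
    canopy = np.zeros(shape)
    lag = np.zeros(shape)
    lag_prev = np.zeros(shape, dtype=bool)

    date0 = pd.to_datetime(ds.surveys["date"]).min()
    for i, sid in enumerate(site_ids):
        grp = per_site.get(sid)
        if grp is None:
            continue
        days = (pd.to_datetime(grp["date"]) - date0).dt.days.to_numpy(dtype=float)
        m = len(grp)
        y[i, :m] = grp["detected"].to_numpy()
        method[i, :m] = grp["is_aru"].to_numpy()
        wind[i, :m] = grp["wind_score"].to_numpy(dtype=float)
        hour[i, :m] = grp["hours_after_sunrise"].to_numpy(dtype=float)
        date[i, :m] = days
        canopy[i, :m] = grp["canopy_at_survey"].to_numpy(dtype=float)
        is_aru = grp["is_aru"].to_numpy(bool)
        day_idx = grp["day_index"].to_numpy()
        for j in range(1, m):
            if is_aru[j] and is_aru[j - 1] and day_idx[j] == day_idx[j - 1]:
                lag_prev[i, j] = True
                lag[i, j] = y[i, j - 1]

    mask = ~np.isnan(y)
    scalers = {}
    for name, arr in (("wind", wind), ("hour", hour), ("date", date), ("canopy", canopy)):
        arr_z, sc = _standardize(arr, mask)
        arr[...] = np.where(mask, arr_z, 0.0)
        scalers[name] = sc

    elev = sites["elevation"].to_numpy(dtype=float)
    cres = resid_all.reindex(site_ids).to_numpy(dtype=float)
    elev_z, sc_e = _standardize(elev)
    cres_z, sc_c = _standardize(cres)
    scalers["elevation"] = sc_e
    scalers["canopy_resid"] = sc_c

    return DetectionHistory(
        family=family, site_ids=site_ids, y=y, method=method, wind=wind,
        hour=hour, date=date, canopy=canopy, lag=lag, lag_prev=lag_prev,
        elevation=elev_z, canopy_resid=cres_z, scalers=scalers,
        habitats=tuple(habitats),
    )


# ---------------------------------------------------------------------------
# model specifications
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """One candidate detection model (occupancy predictor is fixed)."""

    name: str
    method_effect: bool = False
    interactions: tuple[str, ...] = ()

    def __post_init__(self):
        if self.interactions and not self.method_effect:
            raise ValueError("interactions require the method main effect")
        bad = set(self.interactions) - set(SURVEY_CONDITIONS)
        if bad:
            raise ValueError(f"unknown interaction term(s): {sorted(bad)}")

    def detection_terms(self) -> list[str]:
        terms = ["(Intercept)", "wind", "hour", "hour2", "date", "date2",
                 "canopy", "canopy2", "lag"]
        if self.method_effect:
            terms.append("method")
        for cov in SURVEY_CONDITIONS:
            if cov in self.interactions:
                terms += [f"method:{cov}", f"method:{cov}2"]
        return terms

    def occupancy_terms(self) -> list[str]:
        return ["(Intercept)", "elevation", "canopy_resid"]

    @property
    def K(self) -> int:
        return len(self.detection_terms()) + len(self.occupancy_terms())


def model_set() -> list[ModelSpec]:
    """The nine candidate models: baseline, +method, +method with each of the
    seven interaction combinations."""
    models = [ModelSpec("baseline"), ModelSpec("method", method_effect=True)]
    for r in (1, 2, 3):
        for combo in itertools.combinations(SURVEY_CONDITIONS, r):
            name = "method*" + "+".join(combo)
            models.append(ModelSpec(name, method_effect=True, interactions=combo))
    assert len(models) == 9
    return models


def full_model() -> ModelSpec:
    return ModelSpec("method*canopy+hour+date", method_effect=True,
                     interactions=SURVEY_CONDITIONS)


def build_design(dh: DetectionHistory, spec: ModelSpec):
    """Design tensors: X_psi (n, 3) and X_det (n, J, P) plus term names."""
    n, J = dh.y.shape
    cov = {
        "wind": dh.wind, "hour": dh.hour, "hour2": dh.hour ** 2,
        "date": dh.date, "date2": dh.date ** 2,
        "canopy": dh.canopy, "canopy2": dh.canopy ** 2,
        "lag": dh.lag, "method": dh.method,
        "method:canopy": dh.method * dh.canopy,
        "method:canopy2": dh.method * dh.canopy ** 2,
        "method:hour": dh.method * dh.hour,
        "method:hour2": dh.method * dh.hour ** 2,
        "method:date": dh.method * dh.date,
        "method:date2": dh.method * dh.date ** 2,
    }
    det_terms = spec.detection_terms()
    X_det = np.empty((n, J, len(det_terms)))
    for k, term in enumerate(det_terms):
        X_det[:, :, k] = 1.0 if term == "(Intercept)" else cov[term]
    X_psi = np.column_stack([np.ones(n), dh.elevation, dh.canopy_resid])
    return X_psi, X_det, det_terms


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def _site_components(params, X_psi, X_det, y, mask):
    n_psi = X_psi.shape[1]
    alpha, beta = params[:n_psi], params[n_psi:]
    psi = expit(X_psi @ alpha)
    eta = X_det @ beta
    p = expit(eta)
    yv = np.where(mask, y, 0.0)
    with np.errstate(divide="ignore"):
        logp = np.where(mask, yv * np.log(np.maximum(p, _EPS))
                        + (1 - yv) * np.log(np.maximum(1 - p, _EPS)), 0.0)
    log_prod = logp.sum(axis=1)
    prod = np.exp(log_prod)
    # sites with no detections over their observed occasions (including sites
    # with no observed occasions at all, whose likelihood is then psi*1+(1-psi))
    all_zero = yv.sum(axis=1) == 0
    lik = psi * prod + (1 - psi) * all_zero
    return psi, p, prod, all_zero, lik


def loglik(params: np.ndarray, dh: DetectionHistory, spec: ModelSpec) -> float:
    """Zero-inflated Bernoulli-product occupancy log-likelihood.

    ``sum_i log[ psi_i prod_j p_ij^y (1-p_ij)^(1-y) + (1-psi_i) 1{all y = 0} ]``
    with missing occasions skipped.
    """
    X_psi, X_det, _ = build_design(dh, spec)
    for arr in (X_psi, X_det):
        if not np.all(np.isfinite(arr)):
            raise ValueError("non-finite covariate values in the design")
    *_, lik = _site_components(params, X_psi, X_det, dh.y, dh.mask)
    return float(np.sum(np.log(np.maximum(lik, _EPS))))


def _negloglik_grad(params, X_psi, X_det, y, mask):
    psi, p, prod, all_zero, lik = _site_components(params, X_psi, X_det, y, mask)
    lik = np.maximum(lik, _EPS)
    nll = -np.sum(np.log(lik))
    yv = np.where(mask, y, 0.0)
    # d/d alpha: (prod - 1{all0}) psi (1-psi) x / lik
    w_psi = (prod - all_zero) * psi * (1 - psi) / lik
    g_alpha = -(X_psi.T @ w_psi)
    # d/d beta: psi prod sum_j (y - p) x_j / lik
    resid = np.where(mask, yv - p, 0.0)
    w_det = (psi * prod / lik)[:, None] * resid
    g_beta = -np.einsum("nj,njk->k", w_det, X_det)
    return nll, np.concatenate([g_alpha, g_beta])


@dataclass
class OccupancyFit:
    """Converged maximum-likelihood fit of one candidate model."""

    spec: ModelSpec
    params: np.ndarray
    param_names: list[str]
    vcov: np.ndarray | None
    loglik: float
    K: int
    converged: bool
    n_sites: int
    scalers: dict = field(default_factory=dict)
    chat: float | None = None

    def coef(self) -> pd.Series:
        return pd.Series(self.params, index=self.param_names)

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.K


def _hessian(fun_grad, params, X_psi, X_det, y, mask, eps=1e-5):
    k = len(params)
    H = np.empty((k, k))
    for i in range(k):
        d = np.zeros(k)
        d[i] = eps
        _, gp = fun_grad(params + d, X_psi, X_det, y, mask)
        _, gm = fun_grad(params - d, X_psi, X_det, y, mask)
        H[i] = (gp - gm) / (2 * eps)
    return (H + H.T) / 2


def fit(spec: ModelSpec, dh: DetectionHistory, n_starts: int = 5,
        seed: int | None = None, compute_vcov: bool = True,
        x0: np.ndarray | None = None) -> OccupancyFit:
    """Maximize the likelihood from multiple starts (quasi-Newton, analytic
    gradient); covariance from the inverse observed information."""
    if dh.n_detected_sites() < 2:
        raise DataInsufficientError(
            f"family {dh.family!r}: fewer than 2 sites with detections"
        )
    X_psi, X_det, det_terms = build_design(dh, spec)
    names = [f"psi:{t}" for t in spec.occupancy_terms()] + [f"p:{t}" for t in det_terms]
    k = len(names)
    rng = np.random.default_rng(seed)
    starts = [np.zeros(k) if x0 is None else np.asarray(x0, dtype=float)]
    starts += [rng.normal(0.0, 0.5, size=k) for _ in range(n_starts - 1)]

    best = None
    for s in starts:
        res = minimize(_negloglik_grad, s, args=(X_psi, X_det, dh.y, dh.mask),
                       jac=True, method="L-BFGS-B",
                       options={"maxiter": 500, "ftol": 1e-10, "gtol": 1e-7})
        if best is None or res.fun < best.fun - 1e-10:
            best = res
    if best is None or not np.all(np.isfinite(best.x)):
        raise RuntimeError(f"optimization failed for model {spec.name!r}")

    vcov = None
    if compute_vcov:
        H = _hessian(_negloglik_grad, best.x, X_psi, X_det, dh.y, dh.mask)
        try:
            vcov = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            vcov = np.linalg.pinv(H)
    return OccupancyFit(
        spec=spec, params=best.x, param_names=names, vcov=vcov,
        loglik=-float(best.fun), K=k, converged=bool(best.success),
        n_sites=dh.n_sites, scalers=dict(dh.scalers),
    )


# ---------------------------------------------------------------------------
# simulation from a fit (used by the goodness-of-fit bootstrap)
# ---------------------------------------------------------------------------

def simulate_history(fitted: OccupancyFit, dh: DetectionHistory,
                     rng: np.random.Generator) -> DetectionHistory:
    """Simulate a replicate detection history from the fitted model.

    The Markov lag covariate is regenerated sequentially from the *simulated*
    detections so within-day autocorrelation is propagated.
    """
    spec = fitted.spec
    X_psi, X_det, det_terms = build_design(dh, spec)
    n_psi = X_psi.shape[1]
    alpha, beta = fitted.params[:n_psi], fitted.params[n_psi:]
    lag_ix = det_terms.index("lag")
    beta_lag = beta[lag_ix]
    # detection linear predictor without the lag contribution
    eta0 = X_det @ beta - beta_lag * dh.lag

    psi = expit(X_psi @ alpha)
    z = rng.random(dh.n_sites) < psi
    y_new = np.full_like(dh.y, np.nan)
    lag_new = np.zeros_like(dh.lag)
    mask = dh.mask
    for j in range(dh.n_occasions):
        prev = np.zeros(dh.n_sites)
        if j > 0:
            prev = np.where(dh.lag_prev[:, j], np.nan_to_num(y_new[:, j - 1]), 0.0)
        p = expit(eta0[:, j] + beta_lag * prev)
        draw = (rng.random(dh.n_sites) < p) & z & mask[:, j]
        y_new[mask[:, j], j] = draw[mask[:, j]].astype(float)
        lag_new[:, j] = np.where(dh.lag_prev[:, j], np.nan_to_num(y_new[:, j - 1]), 0.0)
    out = DetectionHistory(
        family=dh.family, site_ids=dh.site_ids, y=y_new, method=dh.method,
        wind=dh.wind, hour=dh.hour, date=dh.date, canopy=dh.canopy,
        lag=lag_new, lag_prev=dh.lag_prev, elevation=dh.elevation,
        canopy_resid=dh.canopy_resid, scalers=dh.scalers, habitats=dh.habitats,
    )
    return out


def _history_probability(fitted: OccupancyFit, dh: DetectionHistory,
                         h: np.ndarray, site_idx: np.ndarray) -> np.ndarray:
    """P(observe history h | site covariates) for each site in site_idx,
    with the lag covariate implied by h itself."""
    spec = fitted.spec
    X_psi, X_det, det_terms = build_design(dh, spec)
    n_psi = X_psi.shape[1]
    alpha, beta = fitted.params[:n_psi], fitted.params[n_psi:]
    beta_lag = beta[det_terms.index("lag")]
    eta0 = (X_det @ beta - beta_lag * dh.lag)[site_idx]
    psi = expit((X_psi @ alpha)[site_idx])
    mask = dh.mask[site_idx]
    obs_cols = np.flatnonzero(mask[0])
    lag_prev = dh.lag_prev[site_idx][:, obs_cols]

    logp = np.zeros(len(site_idx))
    prev_h = 0.0
    for pos, j in enumerate(obs_cols):
        lagval = np.where(lag_prev[:, pos], prev_h, 0.0)
        p = expit(eta0[:, j] + beta_lag * lagval)
        hj = h[pos]
        logp += np.log(np.maximum(p if hj else 1 - p, _EPS))
        prev_h = float(hj)
    prob = psi * np.exp(logp)
    if not h.any():
        prob = prob + (1 - psi)
    return prob


def mb_chisq(fitted: OccupancyFit, dh: DetectionHistory,
             min_expected: float = 1.0) -> float:
    """MacKenzie-Bailey Pearson chi-square over observed detection histories.

    Sites are grouped into cohorts sharing a missingness pattern.  Histories
    with expected count below ``min_expected`` are pooled -- together with all
    unobserved histories -- into one remainder cell per cohort; without
    pooling, long nearly-unique histories contribute unbounded 1/E terms and
    the bootstrap ratio becomes meaningless.
    """
    mask = dh.mask
    ydat = dh.y
    cohorts: dict[tuple, list[int]] = {}
    for i in range(dh.n_sites):
        key = tuple(np.flatnonzero(mask[i]))
        if key:
            cohorts.setdefault(key, []).append(i)
    chi2 = 0.0
    for key, members in cohorts.items():
        idx = np.array(members)
        cols = np.array(key)
        hist = ydat[idx][:, cols].astype(int)
        uniq, counts = np.unique(hist, axis=0, return_counts=True)
        o_rem = 0.0
        e_rem = float(len(idx))
        for h, o in zip(uniq, counts):
            e = float(np.sum(_history_probability(fitted, dh, h, idx)))
            if e >= min_expected:
                chi2 += (o - e) ** 2 / e
                e_rem -= e
            else:
                o_rem += o
        # remainder: observed small-E histories plus all unobserved histories
        if e_rem > 1e-12:
            chi2 += (o_rem - e_rem) ** 2 / e_rem
    return chi2


def estimate_chat(fitted: OccupancyFit, dh: DetectionHistory, n_boot: int = 1000,
                  seed: int | None = None) -> float:
    """Overdispersion c-hat = observed chi-square / mean simulated chi-square."""
    if not np.any(np.nan_to_num(dh.y) > 0):
        raise ValueError("all-zero detection history; c-hat undefined")
    rng = np.random.default_rng(seed)
    obs = mb_chisq(fitted, dh)
    sims = np.empty(n_boot)
    for b in range(n_boot):
        dh_b = simulate_history(fitted, dh, rng)
        try:
            fit_b = fit(fitted.spec, dh_b, n_starts=1, compute_vcov=False,
                        x0=fitted.params)
        except DataInsufficientError:
            sims[b] = np.nan
            continue
        sims[b] = mb_chisq(fit_b, dh_b)
    mean_sim = float(np.nanmean(sims))
    if mean_sim <= 0:
        raise RuntimeError("degenerate goodness-of-fit bootstrap (mean chi-square 0)")
    return float(obs / mean_sim)


def qaic(fit_or_loglik, chat: float, K: int | None = None) -> float:
    """QAIC = -2 logL / max(c-hat, 1) + 2 (K + 1); the +1 accounts for c-hat."""
    if chat <= 0:
        raise ValueError("c-hat must be > 0")
    if isinstance(fit_or_loglik, OccupancyFit):
        ll, K = fit_or_loglik.loglik, fit_or_loglik.K
    else:
        ll = float(fit_or_loglik)
        if K is None:
            raise ValueError("K required when passing a bare log-likelihood")
    return -2.0 * ll / max(chat, 1.0) + 2.0 * (K + 1)


CHAT_LACK_OF_FIT = 4.0
CHAT_INSUFFICIENT = 0.3


def select_model(dh: DetectionHistory, chat: float,
                 specs: list[ModelSpec] | None = None, n_starts: int = 5,
                 seed: int | None = None):
    """Fit the nine-model set and rank by QAIC.

    Returns ``(table, best_fit, flag)``; ``flag`` is ``"lack_of_fit"`` when
    c-hat > 4, ``"insufficient_data"`` when c-hat < 0.3, else ``None``
    (flagged families have no reportable output).
    """
    specs = model_set() if specs is None else specs
    flag = None
    if chat > CHAT_LACK_OF_FIT:
        flag = "lack_of_fit"
    elif chat < CHAT_INSUFFICIENT:
        flag = "insufficient_data"

    rows, fits = [], {}
    for spec in specs:
        try:
            f = fit(spec, dh, n_starts=n_starts, seed=seed)
        except (DataInsufficientError, RuntimeError):
            continue
        f.chat = chat
        fits[spec.name] = f
        rows.append({
            "model": spec.name, "K": f.K, "logLik": f.loglik,
            "QAIC": qaic(f, chat), "converged": f.converged,
        })
    if not rows:
        raise RuntimeError("no candidate model converged")
    table = pd.DataFrame(rows).sort_values(["QAIC", "K"], kind="mergesort")
    table["dQAIC"] = table["QAIC"] - table["QAIC"].min()
    table = table.reset_index(drop=True)
    best = fits[table.loc[0, "model"]]
    return table, best, flag


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

def predict_detection(fitted: OccupancyFit, grid: pd.DataFrame, method: str,
                      chat: float = 1.0, lag: float = 0.0,
                      warn_beyond: tuple | None = None) -> pd.DataFrame:
    """Detection-probability curves with delta-method intervals.

    ``grid`` columns are in natural units (wind_score, hours_after_sunrise,
    day_of_season, canopy_cover); they are standardized with the scalers
    stored at fit time.  Logit-scale standard errors are inflated by
    sqrt(c-hat) when c-hat > 1; 84% and 95% bands are back-transformed, so
    all bounds lie in [0, 1].
    """
    from .diversity import Z84, Z95

    if fitted.vcov is None:
        raise ValueError("fit carries no covariance matrix")
    spec = fitted.spec
    det_terms = spec.detection_terms()
    n_psi = len(spec.occupancy_terms())
    beta = fitted.params[n_psi:]
    V = fitted.vcov[n_psi:, n_psi:]

    def z(name, col):
        mu, sd = fitted.scalers[name]
        return (grid[col].to_numpy(dtype=float) - mu) / sd

    wind = z("wind", "wind_score") if "wind_score" in grid else np.zeros(len(grid))
    hour = z("hour", "hours_after_sunrise") if "hours_after_sunrise" in grid else np.zeros(len(grid))
    date = z("date", "day_of_season") if "day_of_season" in grid else np.zeros(len(grid))
    canopy = z("canopy", "canopy_cover") if "canopy_cover" in grid else np.zeros(len(grid))
    m = np.full(len(grid), 1.0 if method == "ARU" else 0.0)
    cov = {
        "(Intercept)": np.ones(len(grid)), "wind": wind, "hour": hour,
        "hour2": hour ** 2, "date": date, "date2": date ** 2,
        "canopy": canopy, "canopy2": canopy ** 2,
        "lag": np.full(len(grid), lag), "method": m,
        "method:canopy": m * canopy, "method:canopy2": m * canopy ** 2,
        "method:hour": m * hour, "method:hour2": m * hour ** 2,
        "method:date": m * date, "method:date2": m * date ** 2,
    }
    X = np.column_stack([cov[t] for t in det_terms])
    eta = X @ beta
    var = np.einsum("ij,jk,ik->i", X, V, X)
    if np.any(var < -1e-8):
        raise ValueError("singular covariance: negative prediction variance")
    se = np.sqrt(np.maximum(var, 0.0))
    if chat > 1.0:
        se = se * np.sqrt(chat)
    out = grid.copy()
    out["method"] = method
    out["p_hat"] = expit(eta)
    out["se_logit"] = se
    out["lo84"] = expit(eta - Z84 * se)
    out["hi84"] = expit(eta + Z84 * se)
    out["lo95"] = expit(eta - Z95 * se)
    out["hi95"] = expit(eta + Z95 * se)
    return out
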