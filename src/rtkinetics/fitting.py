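"""Maximum-likelihood fitting of treatment-efficacy models to volume series.

The likelihood is Gaussian on log volumes with the noise scale profiled out
(its MLE is the RMS log-residual), so the objective reduces to
n/2·(log(2π·sigma_hat²) + 1).  Fits are constrained within literature
parameter ranges and multistarted from a Latin-hypercube design; per-
parameter 95% intervals come from the profile likelihood (the parameter is
pushed outward, re-optimizing all others, until the log-likelihood drops by
chi²_{0.05,1}/2 ≈ 1.921); nested models are compared with likelihood-ratio
tests; and a parsimony ladder (minimal → standard → +recruitment/
+resistance) adopts a more complex model only when it improves the fit
significantly.

Censored observations (below the CT detection limit) enter the likelihood
as exact values at the limit — the conservative convention — unless the
optional censored likelihood is enabled, in which case they contribute
normal-CDF mass below the limit and the noise scale becomes a free
parameter.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize
from scipy.stats import chi2, norm, qmc

from .kinetics import GrowthParams, InvalidParameterError, simulate
from .timecourse import TimeCourse
from .treatment import EffectModel

__all__ = [
    "FitConfig",
    "FitResult",
    "ProfileInterval",
    "SelectionResult",
    "log_likelihood",
    "profiled_sigma",
    "mean_delta_percent",
    "fit_model",
    "profile_ci",
    "lrt",
    "select_model",
    "CHI2_DROP",
]

#: Profile log-likelihood drop defining a 95% interval: chi2(1, 0.95)/2.
CHI2_DROP = float(chi2.ppf(0.95, 1)) / 2.0

_PENALTY = 1e8

#: Parameters optimized on a log10 axis (scale parameters).
_LOG_PARAMS = {"V0", "Td", "Tpot", "sigma"}

#: Literature-anchored default bounds (V0 bounds are data-driven).
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "Td": (15.0, 1000.0),
    "GF": (0.01, 0.6),
    "Tpot": (3.0, 30.0),
    "gamma": (0.0, 0.01),
    "K": (0.0, 99.9),
    "Kp": (0.0, 99.9),
    "Kq": (0.0, 99.9),
    "D": (0.05, 1.0),
    "gamma_rec": (0.011, 0.9),
    "Rini": (0.0, 0.9),
    "Rind": (0.0, 0.5),
    "sigma": (1e-3, 1.0),
}

#: Heuristic central start (literature-typical values).
_START = {
    "Td": 100.0, "GF": 0.2, "Tpot": 8.0, "gamma": 0.0, "K": 30.0, "Kp": 30.0,
    "Kq": 5.0, "D": 0.5, "gamma_rec": 0.1, "Rini": 0.2, "Rind": 0.05,
    "sigma": 0.1,
}


@dataclass(frozen=True)
class FitConfig:
    """Optimizer and ladder settings; all randomness flows from ``seed``."""

    bounds: dict = field(default_factory=dict)  # per-parameter overrides
    fixed: dict = field(default_factory=lambda: {"gamma": 0.0})
    multistart: int = 20
    seed: int = 0
    td_fallback: tuple[float, float] = (25.0, 150.0)
    rec_windows: tuple = ((1, 3), (1, 13), (14, None), (21, None))
    alpha: float = 0.05
    maxiter: int = 400
    profile_tol: float = 5e-4  # bisection tolerance, unit-box scale
    censored_likelihood: bool = False

    def bound(self, name: str, tc: TimeCourse | None = None) -> tuple[float, float]:
        if name in self.bounds:
            return self.bounds[name]
        if name == "V0":
            anchor = _v0_anchor(tc)
            return (anchor / 4.0, anchor * 4.0)
        return DEFAULT_BOUNDS[name]


def _v0_anchor(tc: TimeCourse) -> float:
    o = min(tc.observations, key=lambda o: abs(o.day))
    return o.volume_cc


@dataclass(frozen=True)
class ProfileInterval:
    low: float
    high: float
    truncated_low: bool = False
    truncated_high: bool = False


@dataclass
class FitResult:
    """A converged (or not) maximum-likelihood fit of one model variant."""

    tag: str
    params: dict  # full parameter set, fixed values included
    free_names: tuple[str, ...]
    estimates: dict
    sigma: float
    logL: float
    delta_percent: float
    n_obs: int
    n_free: int
    converged: bool
    rec_window: tuple | None = None
    fixed: dict = field(default_factory=dict)
    bounds: dict = field(default_factory=dict)
    predicted: tuple[float, ...] = ()
    ci: dict = field(default_factory=dict)
    fixed_Td: float | None = None
    companion: "FitResult | None" = None


# ---------------------------------------------------------------------------
# likelihood pieces


def log_likelihood(tc: TimeCourse, predicted, sigma: float) -> float:
    """Gaussian log-likelihood of the log volumes at a given noise scale.

    Censored points contribute as exact observations at the detection limit
    (the conservative convention used throughout the default pipeline).
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    pred = np.asarray(predicted, dtype=float)
    if pred.shape != (tc.n_obs,):
        raise ValueError("predicted must align with the observations")
    if np.any(pred <= 0):
        raise ValueError("nonpositive predicted volume: model breakdown (e.g. total kill)")
    r = np.log(np.asarray(tc.volumes)) - np.log(pred)
    return float(np.sum(norm.logpdf(r, scale=sigma)))


def profiled_sigma(observed, predicted) -> float:
    """Closed-form MLE of the noise scale: RMS of the log residuals."""
    r = np.log(np.asarray(observed, dtype=float)) - np.log(np.asarray(predicted, dtype=float))
    return float(np.sqrt(np.mean(r**2)))


def mean_delta_percent(tc: TimeCourse, predicted) -> float:
    """Goodness-of-fit: mean of 100·|V_obs − V_fit|/V_obs over observations."""
    obs = np.asarray(tc.volumes, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if pred.shape != obs.shape:
        raise ValueError("predicted must align with the observations")
    return float(np.mean(100.0 * np.abs(obs - pred) / obs))


# ---------------------------------------------------------------------------
# the optimization problem


def build_models(tag: str, p: dict, rec_window=None) -> tuple[GrowthParams, EffectModel]:
    """Growth and effect models from a full parameter dict for one tag."""
    if tag.startswith("St"):
        g = GrowthParams.from_tpot(p["Td"], p["GF"], p["Tpot"], gamma=p.get("gamma", 0.0))
    else:
        g = GrowthParams.single_population(p["Td"])
    kw: dict = {"D": p["D"]}
    if tag.startswith("St"):
        kw.update(Kp=p["Kp"], Kq=p["Kq"])
    else:
        kw.update(K=p["K"])
    if tag.endswith("Rec"):
        kw.update(gamma_rec=p["gamma_rec"], rec_window=rec_window)
    if tag.endswith("ResInit"):
        kw.update(Rini=p["Rini"])
    if tag.endswith("ResInd"):
        kw.update(Rind=p["Rind"])
    return g, EffectModel(tag=tag, **kw)


def models_from_fit(fit: "FitResult") -> tuple[GrowthParams, EffectModel]:
    """Reconstruct the fitted growth and effect models from a FitResult."""
    return build_models(fit.tag, fit.params, fit.rec_window)


def _free_names(tag: str, fixed: dict, censored_lik: bool) -> tuple[str, ...]:
    names = ["V0"]
    if "Td" not in fixed:
        names.append("Td")
    if tag.startswith("St"):
        names += ["GF", "Tpot"]
        if "gamma" not in fixed:
            names.append("gamma")
    names += ["Kp", "Kq"] if tag.startswith("St") else ["K"]
    names.append("D")
    if tag.endswith("Rec"):
        names.append("gamma_rec")
    if tag.endswith("ResInit"):
        names.append("Rini")
    if tag.endswith("ResInd"):
        names.append("Rind")
    if censored_lik:
        names.append("sigma")
    return tuple(names)


class _Problem:
    """Negative profiled log-likelihood over the unit box [0,1]^d.

    Each free parameter maps linearly (or log10-linearly for scale
    parameters) from its bounds onto one unit axis; fixed parameters are
    substituted verbatim.
    """

    def __init__(self, tc: TimeCourse, tag: str, cfg: FitConfig,
                 rec_window=None, fixed: dict | None = None,
                 bounds: dict | None = None):
        self.tc = tc
        self.tag = tag
        self.cfg = cfg
        self.rec_window = rec_window
        self.fixed = dict(cfg.fixed if fixed is None else fixed)
        self.names = _free_names(tag, self.fixed, cfg.censored_likelihood)
        self.bounds = {
            n: (bounds[n] if bounds and n in bounds else cfg.bound(n, tc)) for n in self.names
        }
        self._obs = np.asarray(tc.volumes, dtype=float)
        if np.any(self._obs <= 0):
            raise ValueError("observed volumes must be strictly positive to fit log volumes")
        self._days = tuple(tc.days)
        self._censored = np.asarray([o.censored for o in tc.observations], dtype=bool)

    # -- unit-box transform -------------------------------------------
    def to_unit(self, name: str, value: float) -> float:
        lo, hi = self.bounds[name]
        if name in _LOG_PARAMS:
            lo, hi, value = math.log10(lo), math.log10(hi), math.log10(value)
        return min(max((value - lo) / (hi - lo), 0.0), 1.0)

    def from_unit(self, name: str, x: float) -> float:
        lo, hi = self.bounds[name]
        if name in _LOG_PARAMS:
            return 10.0 ** (math.log10(lo) + x * (math.log10(hi) - math.log10(lo)))
        return lo + x * (hi - lo)

    def params_from_x(self, x) -> dict:
        p = {n: self.from_unit(n, xi) for n, xi in zip(self.names, x)}
        p.update(self.fixed)
        return p

    def x_from_params(self, p: dict):
        return np.array([self.to_unit(n, p[n]) for n in self.names])

    # -- model construction -------------------------------------------
    def _models(self, p: dict) -> tuple[GrowthParams, EffectModel]:
        return build_models(self.tag, p, self.rec_window)

    def predict(self, p: dict) -> np.ndarray:
        g, e = self._models(p)
        sched = self.tc.schedule
        t_lo = min(min(self._days), 0)
        t_hi = max(max(self._days), sched.end_day if len(sched) else 0)
        sim = simulate(g, e, sched, p["V0"], (t_lo, t_hi), sorted(set(self._days)))
        by_day = {o.day: o.volume_cc for o in sim.observations}
        return np.array([by_day[d] for d in self._days])

    # -- objective ----------------------------------------------------
    def nll(self, x) -> float:
        p = self.params_from_x(x)
        if self.tag.startswith("St") and p["Tpot"] > p["Td"]:
            return _PENALTY * (1.0 + (p["Tpot"] - p["Td"]) / p["Td"])
        try:
            pred = self.predict(p)
        except (InvalidParameterError, ValueError):
            return _PENALTY
        if not np.all(np.isfinite(pred)) or np.any(pred <= 0):
            return _PENALTY
        r = np.log(self._obs) - np.log(pred)
        if self.cfg.censored_likelihood:
            s = p["sigma"]
            ll = float(np.sum(norm.logpdf(r[~self._censored], scale=s)))
            if self._censored.any():
                ll += float(np.sum(norm.logcdf(r[self._censored] / s)))
            return -ll
        s2 = max(float(np.mean(r**2)), 1e-30)
        return 0.5 * len(r) * (math.log(2.0 * math.pi * s2) + 1.0)

    def solve(self, x0) -> optimize.OptimizeResult:
        return optimize.minimize(
            self.nll,
            np.clip(np.asarray(x0, dtype=float), 0.0, 1.0),
            method="L-BFGS-B",
            bounds=[(0.0, 1.0)] * len(self.names),
            options={"maxiter": self.cfg.maxiter, "ftol": 1e-12},
        )

    def starts(self, n: int):
        """Heuristic centre, box midpoint, and a seeded Latin hypercube."""
        pts = []
        heur = dict(_START)
        heur["V0"] = _v0_anchor(self.tc)
        pts.append(np.array([self.to_unit(nm, max(min(heur[nm], self.bounds[nm][1]),
                                                  self.bounds[nm][0])) for nm in self.names]))
        pts.append(np.full(len(self.names), 0.5))
        if n > 0:
            lhs = qmc.LatinHypercube(d=len(self.names), seed=self.cfg.seed)
            pts.extend(lhs.random(n))
        return pts


# ---------------------------------------------------------------------------
# fitting


def _result_from(problem: _Problem, res, cfg: FitConfig) -> FitResult:
    p = problem.params_from_x(res.x)
    pred = problem.predict(p)
    if cfg.censored_likelihood:
        sigma = p["sigma"]
        logL = -float(res.fun)
    else:
        sigma = profiled_sigma(problem._obs, pred)
        logL = -float(res.fun)
    n_free = len(problem.names) - (1 if cfg.censored_likelihood else 0)
    estimates = {n: p[n] for n in problem.names}
    # A usable optimum: finite, outside the penalty region.  L-BFGS-B can
    # end a line search abnormally at an already-converged point, so its
    # success flag alone is too strict for best-of-multistart.
    usable = bool(np.isfinite(res.fun)) and float(res.fun) < _PENALTY / 2
    return FitResult(
        tag=problem.tag,
        params=p,
        free_names=problem.names,
        estimates=estimates,
        sigma=sigma,
        logL=logL,
        delta_percent=mean_delta_percent(problem.tc, pred),
        n_obs=problem.tc.n_obs,
        n_free=n_free,
        converged=usable,
        rec_window=problem.rec_window,
        fixed=dict(problem.fixed),
        bounds=dict(problem.bounds),
        predicted=tuple(float(v) for v in pred),
        fixed_Td=problem.fixed.get("Td"),
    )


def fit_model(
    tc: TimeCourse,
    model: EffectModel | str,
    cfg: FitConfig | None = None,
    rec_window: tuple | None = None,
) -> FitResult:
    """Best-of-multistart constrained ML fit of one model variant.

    ``model`` may be an :class:`EffectModel` template (its tag and
    recruitment window are used) or a bare tag string.  When the series has
    no pretreatment scan the doubling time is not estimable: the fit is run
    at each fallback Td (25 and 150 days by default) and the higher-
    likelihood result is returned with the other attached as ``companion``.
    Deterministic for a given config seed.
    """
    cfg = cfg or FitConfig()
    if isinstance(model, EffectModel):
        tag = model.tag
        rec_window = rec_window or model.rec_window
    else:
        tag = model
    if tag.endswith("Rec") and rec_window is None:
        raise ValueError("recruitment model requires a rec_window")

    if not tc.pretreatment_available and "Td" not in cfg.fixed:
        fits = []
        for td in cfg.td_fallback:
            sub = replace(cfg, fixed={**cfg.fixed, "Td": float(td)})
            fits.append(fit_model(tc, tag, sub, rec_window=rec_window))
        fits.sort(key=lambda f: f.logL, reverse=True)
        best = fits[0]
        best.companion = fits[1]
        return best

    problem = _Problem(tc, tag, cfg, rec_window=rec_window)
    if len(problem.names) >= tc.n_obs:
        raise ValueError(
            f"underdetermined: {len(problem.names)} free parameters, {tc.n_obs} observations"
        )
    best = None
    for x0 in problem.starts(cfg.multistart):
        res = problem.solve(x0)
        if best is None or res.fun < best.fun:
            best = res
    return _result_from(problem, best, cfg)


# ---------------------------------------------------------------------------
# profile-likelihood intervals


def _profile_logL(tc, fit: FitResult, cfg: FitConfig, name: str, value: float, warm: dict):
    fixed = {**fit.fixed, name: value}
    prob = _Problem(tc, fit.tag, cfg, rec_window=fit.rec_window, fixed=fixed, bounds=fit.bounds)
    res = prob.solve(prob.x_from_params(warm))
    return -float(res.fun), prob.params_from_x(res.x)


def profile_ci(tc: TimeCourse, fit: FitResult, name: str, cfg: FitConfig | None = None) -> ProfileInterval:
    """Likelihood-based 95% interval for one fitted parameter.

    The parameter is stepped away from its estimate (re-optimizing all
    other free parameters, warm-started) until the profile log-likelihood
    falls below logL_best − chi²_{0.05,1}/2, then the crossing is bisected.
    Endpoints that hit the fit bounds are truncated and flagged — including
    the flat-likelihood (unidentifiable) case, where the interval spans the
    whole allowed range.  The interval is stored in ``fit.ci``.
    """
    cfg = cfg or FitConfig()
    if not fit.converged:
        raise ValueError("profile interval requires a converged fit")
    if name not in fit.free_names:
        raise ValueError(f"{name!r} is not a free parameter of this fit")
    target = fit.logL - CHI2_DROP
    # A mock problem gives the unit transform for this parameter.
    prob = _Problem(tc, fit.tag, cfg, rec_window=fit.rec_window, fixed=fit.fixed, bounds=fit.bounds)
    x_hat = prob.to_unit(name, fit.estimates[name])

    def _side(direction: int) -> tuple[float, bool]:
        warm = dict(fit.params)
        x_in, ll_in = x_hat, fit.logL
        step = 0.04
        x_out = None
        while True:
            x = x_hat + direction * step
            at_bound = x <= 0.0 or x >= 1.0
            x = min(max(x, 0.0), 1.0)
            ll, pars = _profile_logL(tc, fit, cfg, name, prob.from_unit(name, x), warm)
            if ll < target:
                x_out = x
                break
            warm, x_in, ll_in = pars, x, ll
            if at_bound:
                return prob.from_unit(name, x), True  # truncated at bound
            step *= 1.7
        while abs(x_out - x_in) > cfg.profile_tol:
            xm = 0.5 * (x_in + x_out)
            ll, pars = _profile_logL(tc, fit, cfg, name, prob.from_unit(name, xm), warm)
            if ll < target:
                x_out = xm
            else:
                warm, x_in = pars, xm
        return prob.from_unit(name, 0.5 * (x_in + x_out)), False

    lo, trunc_lo = _side(-1)
    hi, trunc_hi = _side(+1)
    interval = ProfileInterval(low=lo, high=hi, truncated_low=trunc_lo, truncated_high=trunc_hi)
    fit.ci[name] = interval
    return interval


# ---------------------------------------------------------------------------
# model comparison and selection


def _is_nested(nested_tag: str, larger_tag: str) -> bool:
    if nested_tag == larger_tag:
        return False
    if nested_tag == "M":
        return True  # every other variant extends the minimal model
    if nested_tag == "St":
        return larger_tag in ("StRec", "StResInit", "StResInd")
    return False


def lrt(nested: FitResult, larger: FitResult) -> float:
    """Likelihood-ratio p-value: 2·ΔlogL against chi² with df = Δ(free)."""
    if nested.n_obs != larger.n_obs:
        raise ValueError("likelihood-ratio test requires fits of the same data")
    if not _is_nested(nested.tag, larger.tag):
        raise ValueError(f"{nested.tag} is not nested in {larger.tag}")
    df = larger.n_free - nested.n_free
    if df <= 0:
        raise ValueError(f"larger model must have more free parameters (df={df})")
    stat = max(0.0, 2.0 * (larger.logL - nested.logL))
    return float(chi2.sf(stat, df))


@dataclass
class SelectionResult:
    """Outcome of the parsimony ladder for one time course."""

    best: FitResult
    alternates: list[FitResult]
    fits: dict[str, FitResult]
    tests: list[dict]
    companion: "SelectionResult | None" = None

    @property
    def kill_percent(self) -> float:
        p = self.best.params
        return p["K"] if self.best.tag.startswith("M") else p["Kp"]


def _ladder(tc: TimeCourse, cfg: FitConfig) -> SelectionResult:
    fits: dict[str, FitResult] = {}
    tests: list[dict] = []

    fits["M"] = fit_model(tc, "M", cfg)
    base = fits["M"]
    try:
        fits["St"] = fit_model(tc, "St", cfg)
        p = lrt(fits["M"], fits["St"])
        adopted = p < cfg.alpha
        tests.append({"nested": "M", "larger": "St", "p": p, "adopted": adopted})
        if adopted:
            base = fits["St"]
    except ValueError:
        pass  # underdetermined standard model: stay minimal

    candidates: list[FitResult] = []
    # recruitment: only the standard family has a quiescent pool to recruit
    last_day = max(tc.days)
    try:
        rec_fits = []
        for w in cfg.rec_windows:
            if w[0] > last_day:
                continue
            rec_fits.append(fit_model(tc, "StRec", cfg, rec_window=w))
        if rec_fits:
            candidates.append(max(rec_fits, key=lambda f: f.logL))
    except ValueError:
        pass
    for suffix in ("ResInit", "ResInd"):
        try:
            candidates.append(fit_model(tc, base.tag.replace("Rec", "") + suffix, cfg))
        except ValueError:
            pass

    best = base
    significant = []
    for cand in candidates:
        fits[cand.tag] = cand
        try:
            p = lrt(base, cand)
        except ValueError:
            continue
        adopted = p < cfg.alpha
        tests.append({"nested": base.tag, "larger": cand.tag, "p": p, "adopted": adopted})
        if adopted:
            significant.append(cand)
    if significant:
        best = max(significant, key=lambda f: f.logL)

    alternates = [
        f for f in fits.values() if f is not best and best.logL - f.logL <= CHI2_DROP
    ]
    alternates.sort(key=lambda f: f.logL, reverse=True)
    return SelectionResult(best=best, alternates=alternates, fits=fits, tests=tests)


def select_model(tc: TimeCourse, cfg: FitConfig | None = None) -> SelectionResult:
    """Run the parsimony ladder: M → St → (+recruitment, +resistance).

    A more complex model is adopted only when the likelihood-ratio test is
    significant at the configured level; models not significantly worse
    than the adopted one are returned as alternates.  Without pretreatment
    data the ladder is run at each fallback doubling time and the higher-
    likelihood outcome is returned, the other attached as ``companion``.
    """
    cfg = cfg or FitConfig()
    if not tc.pretreatment_available and "Td" not in cfg.fixed:
        runs = []
        for td in cfg.td_fallback:
            sub = replace(cfg, fixed={**cfg.fixed, "Td": float(td)})
            runs.append(_ladder(tc, sub))
        runs.sort(key=lambda r: r.best.logL, reverse=True)
        runs[0].companion = runs[1]
        return runs[0]
    return _ladder(tc, cfg)
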