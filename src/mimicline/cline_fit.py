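"""Equilibrium geographic cline models fitted by Metropolis–Hastings MCMC.

A geographic cline describes how a trait frequency changes along a 1D
transect.  The central shape is the sigmoid

    s(x) = (1 + tanh(2 (x - c) / w)) / 2

with center ``c`` (location of steepest change, km) and width ``w``
(inverse of the maximum slope of the unit-range sigmoid, km).  The
observed trait is ``p(x) = pmin + (pmax - pmin) * s(x)``.

Three nested model classes are supported, following the standard
fixed/free scaling and exponential-tail taxonomy of hybrid-zone cline
software:

* **I** ``fixed`` scaling, no tails — ``pmin``/``pmax`` pinned to the
  observed data extremes; free parameters ``(c, w)``.
* **II** ``free`` scaling, no tails — ``(c, w, pmin, pmax)``.
* **III** ``free`` scaling, two independently fitted exponential tails —
  adds left/right tail offsets ``deltaL, deltaR`` (km) and tail
  slope-scales ``tauL, tauR`` in [0, 1].

Tails replace the sigmoid beyond ``x < c - deltaL`` and ``x > c + deltaR``
by value-continuous exponential decays whose initial slope is ``tau``
times the sigmoid slope at the junction, so ``tau = 1`` is also
slope-continuous and ``tau = 0`` flattens immediately.

Individuals are treated as single-specimen localities: the likelihood is
a product over specimens, Bernoulli for binary traits (haplogroup,
phenotype) or Gaussian with a free residual SD for continuous traits
(ancestry proportions).  Posteriors are sampled with a component-wise
random-walk Metropolis algorithm under uniform priors, with proposal
scales adapted during burn-in and frozen afterwards.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np

_P_CLAMP = 1e-9
_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


class ClineError(ValueError):
    """Invalid cline parameters or unusable data."""


class ModelClass(str, Enum):
    I_FIXED_NONE = "I"
    II_FREE_NONE = "II"
    III_FREE_BOTH = "III"


@dataclass
class ClineModel:
    """Point parameterization of an equilibrium cline."""

    model_class: ModelClass
    c: float
    w: float
    pmin: float = 0.0
    pmax: float = 1.0
    deltaL: float = 0.0
    tauL: float = 1.0
    deltaR: float = 0.0
    tauR: float = 1.0

    def __post_init__(self) -> None:
        if self.w <= 0:
            raise ClineError(f"cline width must be positive, got {self.w}")
        if not self.pmin < self.pmax:
            raise ClineError(f"require pmin < pmax, got {self.pmin} >= {self.pmax}")
        if self.deltaL < 0 or self.deltaR < 0:
            raise ClineError("tail offsets must be >= 0")
        if not (0 <= self.tauL <= 1 and 0 <= self.tauR <= 1):
            raise ClineError("tail slope-scales tau must lie in [0, 1]")


def _sigmoid(x: np.ndarray, c: float, w: float) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(2.0 * (x - c) / w))


def _sigmoid_slope(x: float, c: float, w: float) -> float:
    t = math.tanh(2.0 * (x - c) / w)
    return (1.0 - t * t) / w


def cline_value(model: ClineModel, x) -> np.ndarray | float:
    """Evaluate the cline trait value p(x); vectorized over ``x``.

    Continuous everywhere and monotone non-decreasing in ``x`` for all
    valid parameters, including the exponential tails of model III.
    """
    scalar = np.isscalar(x)
    x = np.atleast_1d(np.asarray(x, dtype=float))
    s = _sigmoid(x, model.c, model.w)
    if model.model_class is ModelClass.III_FREE_BOTH:
        xL = model.c - model.deltaL
        left = x < xL
        if np.any(left):
            tL = math.tanh(2.0 * (xL - model.c) / model.w)
            sL = 0.5 * (1.0 + tL)
            # s -> 0 exponentially; s'(xL)/s(xL) = 2(1 - tanh)/w exactly,
            # which stays finite where s and s' individually underflow
            rate = 2.0 * (1.0 - tL) / model.w
            s[left] = sL * np.exp(model.tauL * rate * (x[left] - xL))
        xR = model.c + model.deltaR
        right = x > xR
        if np.any(right):
            tR = math.tanh(2.0 * (xR - model.c) / model.w)
            sR = 0.5 * (1.0 + tR)
            rate = 2.0 * (1.0 + tR) / model.w
            s[right] = 1.0 - (1.0 - sR) * np.exp(-model.tauR * rate * (x[right] - xR))
    p = model.pmin + (model.pmax - model.pmin) * s
    return float(p[0]) if scalar else p


def log_likelihood(
    model: ClineModel,
    x: np.ndarray,
    y: np.ndarray,
    likelihood: str = "bernoulli",
    sigma: float | None = None,
) -> float:
    """Log-likelihood of trait observations under a cline.

    ``bernoulli``: y in {0, 1}; predicted probabilities are clamped to
    [1e-9, 1 - 1e-9] so a misfit model yields a finite value.
    ``gaussian``: y in [0, 1] with residual SD ``sigma``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0:
        raise ClineError("empty data")
    p = np.asarray(cline_value(model, x), dtype=float)
    if likelihood == "bernoulli":
        p = np.clip(p, _P_CLAMP, 1.0 - _P_CLAMP)
        return float(np.sum(y * np.log(p) + (1.0 - y) * np.log1p(-p)))
    if likelihood == "gaussian":
        if sigma is None or sigma <= 0:
            raise ClineError("gaussian likelihood requires sigma > 0")
        r = (y - p) / sigma
        return float(np.sum(-0.5 * r * r - math.log(sigma) - _LOG_SQRT_2PI))
    raise ClineError(f"unknown likelihood {likelihood!r}")


def aicc(logL_max: float, k: int, n: int) -> float:
    """Akaike information criterion with the small-sample correction.

    AICc = 2k - 2 logL + 2k(k+1)/(n - k - 1); requires n > k + 1.
    """
    if n <= k + 1:
        raise ClineError(f"AICc undefined for n={n}, k={k} (need n > k + 1)")
    return 2.0 * k - 2.0 * logL_max + 2.0 * k * (k + 1) / (n - k - 1)


@dataclass
class MCMCSettings:
    """Random-walk Metropolis controls.

    ``iterations`` counts post-adaptation sweeps (one sweep updates each
    free parameter once); proposal scales are tuned toward a 0.2–0.4
    acceptance rate during the burn-in fraction and frozen afterwards.
    """

    iterations: int = 100_000
    burnin_fraction: float = 0.1
    thin: int = 10
    seed: int = 0


# free-parameter names per model class; sigma appended for gaussian fits
_PARAMS = {
    ModelClass.I_FIXED_NONE: ["c", "w"],
    ModelClass.II_FREE_NONE: ["c", "w", "pmin", "pmax"],
    ModelClass.III_FREE_BOTH: ["c", "w", "pmin", "pmax", "deltaL", "tauL", "deltaR", "tauR"],
}


@dataclass
class ClineFitResult:
    """Posterior summary of one cline fit."""

    model: ClineModel
    model_class: ModelClass
    likelihood: str
    param_names: list[str]
    posterior_samples: np.ndarray  # draws x params
    posterior_logp: np.ndarray
    posterior_logL: np.ndarray
    logL_max: float
    k: int
    n: int
    aicc: float
    center_credible_interval: tuple[float, float]
    center_support_interval: tuple[float, float]
    width_param: float
    width_inv_max_slope: float
    sigma: float | None
    seed: int
    data_fingerprint: int = 0
    acceptance_rates: dict = field(default_factory=dict)

    def posterior_median(self, name: str) -> float:
        return float(np.median(self.posterior_samples[:, self.param_names.index(name)]))


def _build_model(model_class: ModelClass, theta: np.ndarray, names: list[str],
                 pmin_fixed: float, pmax_fixed: float) -> ClineModel | None:
    kw = dict(zip(names, theta))
    sigma = kw.pop("sigma", None)
    pmin = kw.pop("pmin", pmin_fixed)
    pmax = kw.pop("pmax", pmax_fixed)
    try:
        return ClineModel(model_class=model_class, pmin=pmin, pmax=pmax, **kw)
    except ClineError:
        return None


def fit_cline(
    x: Sequence[float],
    y: Sequence[float],
    model_class: ModelClass | str = ModelClass.I_FIXED_NONE,
    likelihood: str = "bernoulli",
    mcmc: MCMCSettings | None = None,
) -> ClineFitResult:
    """Fit one cline model class to individual-level trait data.

    Uniform priors: ``c`` over the data range; ``w`` in (0, 3 * range];
    ``pmin, pmax`` in [0, 1] with ``pmin < pmax``; tail offsets in
    [0, range]; ``tau`` in [0, 1]; ``sigma`` in (0, 1] (gaussian only).
    The returned point estimate is the maximum-posterior sample; the
    center interval is reported both as the 95% equal-tailed credible
    interval and as the 2-log-likelihood support region.
    """
    model_class = ModelClass(model_class)
    mcmc = mcmc or MCMCSettings()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 10:
        raise ClineError("need at least 10 data points")
    xmin, xmax = float(np.min(x)), float(np.max(x))
    span = xmax - xmin
    if span <= 0:
        raise ClineError("data do not span a positive transect distance")

    if likelihood == "bernoulli":
        if not np.all(np.isin(y, (0.0, 1.0))):
            raise ClineError("bernoulli likelihood requires y in {0, 1}")
    elif likelihood == "gaussian":
        if np.any((y < 0) | (y > 1)):
            raise ClineError("gaussian likelihood expects trait values in [0, 1]")
    else:
        raise ClineError(f"unknown likelihood {likelihood!r}")

    # model I pins the trait bounds to the observed extremes
    if model_class is ModelClass.I_FIXED_NONE:
        pmin_fixed, pmax_fixed = float(np.min(y)), float(np.max(y))
        if not pmin_fixed < pmax_fixed:
            raise ClineError("constant trait: cline bounds degenerate under fixed scaling")
    else:
        pmin_fixed, pmax_fixed = 0.0, 1.0

    names = list(_PARAMS[model_class])
    if likelihood == "gaussian":
        names.append("sigma")
    k = len(names)

    lo = {"c": xmin, "w": 1e-6, "pmin": 0.0, "pmax": 0.0, "deltaL": 0.0,
          "tauL": 0.0, "deltaR": 0.0, "tauR": 0.0, "sigma": 1e-6}
    hi = {"c": xmax, "w": 3.0 * span, "pmin": 1.0, "pmax": 1.0, "deltaL": span,
          "tauL": 1.0, "deltaR": span, "tauR": 1.0, "sigma": 1.0}
    lower = np.array([lo[nm] for nm in names])
    upper = np.array([hi[nm] for nm in names])

    rng = np.random.default_rng(mcmc.seed)

    def log_post(theta: np.ndarray) -> tuple[float, float]:
        if np.any(theta < lower) or np.any(theta > upper):
            return -np.inf, -np.inf
        kwidx = dict(zip(names, theta))
        if "pmin" in kwidx and kwidx["pmin"] >= kwidx["pmax"]:
            return -np.inf, -np.inf
        model = _build_model(model_class, theta, names, pmin_fixed, pmax_fixed)
        if model is None:
            return -np.inf, -np.inf
        ll = log_likelihood(model, x, y, likelihood, sigma=kwidx.get("sigma"))
        if not np.isfinite(ll):
            return -np.inf, -np.inf
        return ll, ll  # flat priors: posterior = likelihood up to a constant

    # initialization: random draws until the posterior is finite
    theta = None
    for _ in range(100):
        cand = lower + (upper - lower) * rng.random(k)
        if "w" in names:
            cand[names.index("w")] = span * (0.05 + 0.5 * rng.random())
        if "pmin" in names:
            i, j = names.index("pmin"), names.index("pmax")
            a, b = sorted(rng.random(2))
            cand[i], cand[j] = a, max(b, a + 1e-3)
        lp, _ = log_post(cand)
        if np.isfinite(lp):
            theta = cand
            break
    if theta is None:
        raise ClineError("could not initialize MCMC at a finite posterior (100 tries)")

    logp, ll = log_post(theta)
    scales = 0.1 * (upper - lower)
    n_burn = max(1, int(mcmc.iterations * mcmc.burnin_fraction))
    total = n_burn + mcmc.iterations
    n_keep = mcmc.iterations // mcmc.thin
    samples = np.empty((n_keep, k))
    samp_logp = np.empty(n_keep)
    samp_ll = np.empty(n_keep)
    kept = 0
    best_logp = -np.inf
    best_theta = theta.copy()
    logL_max = -np.inf
    accept = np.zeros(k)
    window = np.zeros(k)
    acc_total = np.zeros(k)

    for it in range(total):
        for j in range(k):
            prop = theta.copy()
            prop[j] += scales[j] * rng.standard_normal()
            plp, pll = log_post(prop)
            if plp - logp > math.log(rng.random() + 1e-300):
                theta, logp, ll = prop, plp, pll
                accept[j] += 1
                acc_total[j] += 1
            window[j] += 1
        if it < n_burn:
            # tune proposal scales toward 0.2-0.4 acceptance, then freeze
            if (it + 1) % 50 == 0:
                rate = accept / window
                scales[rate > 0.4] *= 1.4
                scales[rate < 0.2] /= 1.4
                accept[:] = 0
                window[:] = 0
        else:
            if logp > best_logp:
                best_logp, best_theta = logp, theta.copy()
            if ll > logL_max:
                logL_max = ll
            i_post = it - n_burn
            if (i_post + 1) % mcmc.thin == 0 and kept < n_keep:
                samples[kept] = theta
                samp_logp[kept] = logp
                samp_ll[kept] = ll
                kept += 1

    samples = samples[:kept]
    samp_logp = samp_logp[:kept]
    samp_ll = samp_ll[:kept]

    model = _build_model(model_class, best_theta, names, pmin_fixed, pmax_fixed)
    assert model is not None
    sigma = float(best_theta[names.index("sigma")]) if "sigma" in names else None

    c_idx = names.index("c")
    c_draws = samples[:, c_idx]
    cred = (float(np.quantile(c_draws, 0.025)), float(np.quantile(c_draws, 0.975)))
    in_support = samp_ll >= logL_max - 2.0
    if np.any(in_support):
        support = (float(np.min(c_draws[in_support])), float(np.max(c_draws[in_support])))
    else:
        support = (model.c, model.c)

    n = int(x.size)
    return ClineFitResult(
        model=model,
        model_class=model_class,
        likelihood=likelihood,
        param_names=names,
        posterior_samples=samples,
        posterior_logp=samp_logp,
        posterior_logL=samp_ll,
        logL_max=float(logL_max),
        k=k,
        n=n,
        aicc=aicc(float(logL_max), k, n),
        center_credible_interval=cred,
        center_support_interval=support,
        width_param=model.w,
        width_inv_max_slope=model.w / (model.pmax - model.pmin),
        sigma=sigma,
        seed=mcmc.seed,
        data_fingerprint=hash((x.tobytes(), y.tobytes())),
        acceptance_rates={nm: float(acc_total[i] / total) for i, nm in enumerate(names)},
    )


def select_model(fits: Sequence[ClineFitResult]) -> tuple[ClineFitResult, list[dict]]:
    """Pick the minimum-AICc fit; ties go to the fit with fewer parameters.

    All fits must be on the same data.  Returns the winner and a
    delta-AICc table sorted by AICc.
    """
    if not fits:
        raise ClineError("no fits supplied")
    fingerprints = {f.data_fingerprint for f in fits}
    if len(fingerprints) > 1:
        raise ClineError("model selection requires fits on identical data")
    best = min(fits, key=lambda f: (f.aicc, f.k))
    table = [
        {
            "model_class": f.model_class.value,
            "k": f.k,
            "logL_max": f.logL_max,
            "aicc": f.aicc,
            "delta_aicc": f.aicc - best.aicc,
        }
        for f in sorted(fits, key=lambda f: (f.aicc, f.k))
    ]
    return best, table


def compare_clines(fit_a: ClineFitResult, fit_b: ClineFitResult) -> dict:
    """Center shift and width difference between two fitted clines.

    The shift posterior pairs independent posterior draws from the two
    fits (truncated to the shorter chain).
    """
    shift = fit_a.model.c - fit_b.model.c
    ia = fit_a.param_names.index("c")
    ib = fit_b.param_names.index("c")
    m = min(fit_a.posterior_samples.shape[0], fit_b.posterior_samples.shape[0])
    shift_draws = fit_a.posterior_samples[:m, ia] - fit_b.posterior_samples[:m, ib]
    return {
        "center_shift_km": float(shift),
        "width_diff_km": float(fit_a.model.w - fit_b.model.w),
        "shift_posterior": shift_draws,
        "shift_credible_interval": (
            float(np.quantile(shift_draws, 0.025)),
            float(np.quantile(shift_draws, 0.975)),
        ),
    }
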