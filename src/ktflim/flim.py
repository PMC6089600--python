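"""Bayesian inference of TCSPC fluorescence decays.

Photon-arrival histograms from individual kinetochores contain only a few
hundred photons, a regime where nonlinear least-squares lifetime fitting is
badly biased.  This module therefore treats the binned decay as a multinomial
draw from a discretized model curve and works with the full posterior over the
model parameters (uniform prior).

The model curve is the circular convolution of the measured instrument
response function (IRF) with a mixture of a noise floor and an exponential
decay model: either a single exponential ``exp(-t/tau_D)`` (no FRET) or the
two-exponential mixture

    (1 - f_FRET) * exp(-t/tau_D) + f_FRET * exp(-t/tau_FRET),

where ``f_FRET`` is the fraction of donors in the FRET (short-lifetime) state.
Exponentials are folded at the measurement window, as appropriate for
high-repetition-rate pulsed excitation, so per-bin probabilities sum to one.

Per-bin probabilities are evaluated on the fine (IRF) time base of width
``dt_fine`` and summed in groups of ``adc_ratio`` fine bins per recorded
(coarse) bin — a Riemann-sum approximation of the per-bin arrival
probability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

__all__ = [
    "IRF",
    "DecayHistogram",
    "DecayModel",
    "PosteriorGrid",
    "FretEstimate",
    "FitResult",
    "UnidentifiableError",
    "decay_model_eval",
    "fit_mle",
    "infer_posterior",
    "combine_posteriors",
    "select_model_bic",
    "fret_to_binding",
]


class UnidentifiableError(ValueError):
    """A parameter cannot be determined from the supplied data."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IRF:
    """Instrument response function on the fine time base.

    weights
        Nonnegative, unit-sum weights over the fine bins of the full
        measurement window.
    bin_width
        Fine bin width in ns.
    shift_support
        Integer range (inclusive) of IRF shifts ``bshift`` explored when the
        shift is profiled at the MLE stage.
    """

    weights: np.ndarray
    bin_width: float
    shift_support: tuple[int, int] = (-10, 10)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 1 or w.size == 0:
            raise ValueError("IRF weights must be a nonempty 1-D array")
        if np.any(w < -1e-12):
            raise ValueError("IRF weights must be nonnegative")
        s = w.sum()
        if not np.isfinite(s) or s <= 0:
            raise ValueError("IRF weights must have positive sum")
        object.__setattr__(self, "weights", np.clip(w, 0.0, None) / s)
        if self.bin_width <= 0:
            raise ValueError("IRF bin_width must be positive")

    @property
    def n_fine(self) -> int:
        return self.weights.size

    @classmethod
    def delta(cls, n_fine: int, bin_width: float, center_bin: int = 0) -> "IRF":
        """Ideal (single-bin) IRF; useful for oracles and noise-free tests."""
        w = np.zeros(n_fine)
        w[center_bin] = 1.0
        return cls(weights=w, bin_width=bin_width)


@dataclass(frozen=True)
class DecayHistogram:
    """Binned photon-arrival counts for one kinetochore (or aggregate).

    counts
        Nonnegative integer photon counts per coarse bin.
    adc_ratio
        Number of fine (IRF) bins per coarse bin (the ADC ratio K).
    irf
        The linked instrument response function, sampled at the fine bin
        width; ``len(irf.weights) == len(counts) * adc_ratio``.
    """

    counts: np.ndarray
    adc_ratio: int
    irf: IRF

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if np.any(c < 0):
            raise ValueError("counts must be nonnegative")
        if not np.allclose(c, np.round(c)):
            raise ValueError("counts must be integral")
        object.__setattr__(self, "counts", np.asarray(np.round(c), dtype=np.int64))
        if self.adc_ratio < 1:
            raise ValueError("adc_ratio must be >= 1")
        if self.irf.n_fine != self.n_bins * self.adc_ratio:
            raise ValueError(
                "IRF length %d does not match n_bins*adc_ratio = %d"
                % (self.irf.n_fine, self.n_bins * self.adc_ratio)
            )

    @property
    def n_bins(self) -> int:
        return int(np.asarray(self.counts).size)

    @property
    def coarse_bin_width(self) -> float:
        return self.adc_ratio * self.irf.bin_width

    @property
    def total_counts(self) -> int:
        return int(self.counts.sum())

    def aggregate(self, other: "DecayHistogram") -> "DecayHistogram":
        """Pool two histograms by summing counts (same binning and IRF)."""
        if other.n_bins != self.n_bins or other.adc_ratio != self.adc_ratio:
            raise ValueError("histograms have incompatible binning")
        return replace(self, counts=self.counts + other.counts)


_MODEL_PARAMS = {
    "single": ("tau_d", "noise_a"),
    "double": ("tau_d", "tau_fret", "f_fret", "noise_a"),
}


@dataclass(frozen=True)
class DecayModel:
    """Parameters of the exponential decay model.

    ``noise_a`` is the amplitude of the decay component; ``1 - noise_a`` is
    the relative weight of a time-uniform noise floor.  ``bshift`` is an
    integer shift (in fine bins) of the measured IRF relative to the true one.
    """

    kind: str
    tau_d: float
    tau_fret: float | None = None
    f_fret: float | None = None
    noise_a: float = 1.0
    bshift: int = 0

    def __post_init__(self) -> None:
        if self.kind not in _MODEL_PARAMS:
            raise ValueError("kind must be 'single' or 'double'")
        if self.tau_d <= 0:
            raise ValueError("tau_d must be positive")
        if not (0.0 < self.noise_a <= 1.0):
            raise ValueError("noise_a must be in (0, 1]")
        if self.kind == "double":
            if self.tau_fret is None or self.f_fret is None:
                raise ValueError("double model requires tau_fret and f_fret")
            if self.tau_fret <= 0:
                raise ValueError("tau_fret must be positive")
            if self.tau_fret >= self.tau_d:
                raise ValueError("tau_fret must be shorter than tau_d")
            if not (0.0 <= self.f_fret <= 1.0):
                raise ValueError("f_fret must lie in [0, 1]")

    def params(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in _MODEL_PARAMS[self.kind]}


@dataclass
class PosteriorGrid:
    """Discretized posterior density over decay-model parameters.

    axes
        Ordered mapping parameter name -> 1-D grid; the ``log_density`` array
        has one axis per entry, in order.
    """

    axes: dict[str, np.ndarray]
    log_density: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        shape = tuple(len(g) for g in self.axes.values())
        if tuple(self.log_density.shape) != shape:
            raise ValueError("log_density shape does not match axes")

    def normalize(self) -> "PosteriorGrid":
        self.log_density = self.log_density - logsumexp(self.log_density)
        self.normalized = True
        return self

    def _axis_index(self, name: str) -> int:
        try:
            return list(self.axes).index(name)
        except ValueError:
            raise KeyError(f"no axis named {name!r}") from None

    def marginal(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        """Return (grid, probability masses) for one parameter."""
        if not self.normalized:
            self.normalize()
        idx = self._axis_index(name)
        others = tuple(i for i in range(self.log_density.ndim) if i != idx)
        logm = logsumexp(self.log_density, axis=others) if others else self.log_density
        p = np.exp(logm - logsumexp(logm))
        return self.axes[name], p

    def mean(self, name: str = "f_fret") -> float:
        g, p = self.marginal(name)
        return float(np.sum(g * p))

    def sd(self, name: str = "f_fret") -> float:
        g, p = self.marginal(name)
        m = np.sum(g * p)
        return float(np.sqrt(max(np.sum((g - m) ** 2 * p), 0.0)))

    def mode(self) -> dict[str, float]:
        idx = np.unravel_index(np.argmax(self.log_density), self.log_density.shape)
        return {name: float(g[i]) for (name, g), i in zip(self.axes.items(), idx)}

    def credible_interval(self, name: str = "f_fret", level: float = 0.95) -> tuple[float, float]:
        """Central credible interval from the marginal CDF."""
        g, p = self.marginal(name)
        cdf = np.cumsum(p)
        lo = float(np.interp((1 - level) / 2, cdf, g))
        hi = float(np.interp(1 - (1 - level) / 2, cdf, g))
        return lo, hi


@dataclass(frozen=True)
class FretEstimate:
    """Combined FRET-fraction estimate for a group of kinetochores."""

    mean_f_fret: float
    sem: float
    n_kinetochores: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.mean_f_fret <= 1.0):
            raise ValueError("mean_f_fret must lie in [0, 1]")
        if self.sem < 0:
            raise ValueError("sem must be nonnegative")


@dataclass(frozen=True)
class FitResult:
    model: DecayModel
    log_likelihood: float
    se: dict[str, float]
    converged: bool
    n_free: int


# ---------------------------------------------------------------------------
# Model evaluation
# ---------------------------------------------------------------------------


def _folded_exp_masses(tau: float, n_fine: int, dt: float) -> np.ndarray:
    """Exact per-fine-bin probability masses of an exponential decay folded
    at the measurement window (periodic excitation)."""
    t0 = np.arange(n_fine) * dt
    m = np.exp(-t0 / tau) * -np.expm1(-dt / tau)
    return m / -np.expm1(-n_fine * dt / tau)


def _coarse_probs(
    fine_masses: np.ndarray, irf: IRF, adc_ratio: int, noise_a: float, bshift: int
) -> np.ndarray:
    """Convolve decay masses with the (shifted) IRF and sum to coarse bins."""
    w = np.roll(irf.weights, bshift)
    conv = np.fft.irfft(np.fft.rfft(w) * np.fft.rfft(fine_masses), n=fine_masses.size)
    conv = np.clip(conv, 0.0, None)
    fine = noise_a * conv + (1.0 - noise_a) / fine_masses.size
    return fine.reshape(-1, adc_ratio).sum(axis=1)


def decay_model_eval(
    model: DecayModel,
    n_bins: int,
    adc_ratio: int,
    irf: IRF,
) -> np.ndarray:
    """Per-coarse-bin arrival probabilities for a decay model.

    Returns a length-``n_bins`` vector of probabilities that sums to 1
    (window-folded model; the uniform noise floor is spread over the window).
    """
    n_fine = n_bins * adc_ratio
    if irf.n_fine != n_fine:
        raise ValueError("IRF length does not match n_bins * adc_ratio")
    dt = irf.bin_width
    if model.kind == "single":
        masses = _folded_exp_masses(model.tau_d, n_fine, dt)
    else:
        md = _folded_exp_masses(model.tau_d, n_fine, dt)
        mf = _folded_exp_masses(model.tau_fret, n_fine, dt)
        masses = (1.0 - model.f_fret) * md + model.f_fret * mf
    return _coarse_probs(masses, irf, adc_ratio, model.noise_a, model.bshift)


def _log_likelihood(counts: np.ndarray, probs: np.ndarray) -> float:
    """Multinomial log likelihood sum_i y_i log P_i (constant terms dropped)."""
    y = counts
    mask = y > 0
    p = probs[mask]
    if np.any(p <= 0):
        return -np.inf
    return float(np.sum(y[mask] * np.log(p)))


# ---------------------------------------------------------------------------
# Maximum likelihood
# ---------------------------------------------------------------------------

_DEFAULTS = {"tau_d": 3.75, "tau_fret": 0.75, "f_fret": 0.1, "noise_a": 1.0}
_BOUNDS = {
    "tau_d": (0.05, 20.0),
    "tau_fret": (0.01, 19.0),
    "f_fret": (0.0, 1.0),
    "noise_a": (1e-6, 1.0),
}


def _to_unconstrained(name: str, x: float) -> float:
    lo, hi = _BOUNDS[name]
    x = min(max(x, lo + 1e-12), hi - 1e-12) if name in ("f_fret", "noise_a") else max(x, lo)
    if name in ("tau_d", "tau_fret"):
        return np.log(x)
    p = (x - lo) / (hi - lo)
    return np.log(p / (1 - p))


def _from_unconstrained(name: str, u: float) -> float:
    lo, hi = _BOUNDS[name]
    if name in ("tau_d", "tau_fret"):
        return float(np.clip(np.exp(u), lo, hi))
    return float(lo + (hi - lo) / (1 + np.exp(-u)))


class _DecayObjective:
    """Negative log likelihood over the free parameters of a decay model."""

    def __init__(self, hist: DecayHistogram, kind: str, fixed: Mapping[str, float], bshift: int):
        self.hist = hist
        self.kind = kind
        self.fixed = dict(fixed)
        self.bshift = bshift
        self.free = [p for p in _MODEL_PARAMS[kind] if p not in fixed]

    def model(self, values: Mapping[str, float]) -> DecayModel:
        params = {**{p: _DEFAULTS[p] for p in _MODEL_PARAMS[self.kind]}, **self.fixed, **values}
        return DecayModel(kind=self.kind, bshift=self.bshift, **params)

    def loglik(self, values: Mapping[str, float]) -> float:
        try:
            model = self.model(values)
        except ValueError:
            return -np.inf
        probs = decay_model_eval(model, self.hist.n_bins, self.hist.adc_ratio, self.hist.irf)
        return _log_likelihood(self.hist.counts, probs)

    def neg_loglik_u(self, u: np.ndarray) -> float:
        values = {p: _from_unconstrained(p, ui) for p, ui in zip(self.free, u)}
        return -self.loglik(values)


def _numeric_se(obj: _DecayObjective, best: dict[str, float]) -> dict[str, float]:
    """Standard errors from a finite-difference Hessian of the log likelihood."""
    free = obj.free
    if not free:
        return {}
    x0 = np.array([best[p] for p in free])
    h = np.maximum(np.abs(x0) * 1e-4, 1e-6)

    def ll(x: np.ndarray) -> float:
        return obj.loglik(dict(zip(free, x)))

    n = len(free)
    H = np.zeros((n, n))
    f0 = ll(x0)
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n)
            ej = np.zeros(n)
            ei[i] = h[i]
            ej[j] = h[j]
            if i == j:
                H[i, i] = (ll(x0 + ei) - 2 * f0 + ll(x0 - ei)) / h[i] ** 2
            else:
                H[i, j] = H[j, i] = (
                    ll(x0 + ei + ej) - ll(x0 + ei - ej) - ll(x0 - ei + ej) + ll(x0 - ei - ej)
                ) / (4 * h[i] * h[j])
    try:
        cov = np.linalg.inv(-H)
        se = {p: float(np.sqrt(cov[i, i])) if cov[i, i] > 0 else np.nan for i, p in enumerate(free)}
    except np.linalg.LinAlgError:
        se = {p: np.nan for p in free}
    return se


def fit_mle(
    hist: DecayHistogram,
    kind: str = "double",
    fixed: Mapping[str, float] | None = None,
    start: Mapping[str, float] | None = None,
    fit_bshift: bool = False,
) -> FitResult:
    """Maximum-likelihood decay-model fit.

    Free parameters are those of ``kind`` not present in ``fixed``.  The IRF
    shift ``bshift`` is profiled over ``hist.irf.shift_support`` only when
    ``fit_bshift`` is true; otherwise it is fixed at 0 (or at ``fixed['bshift']``).
    """
    fixed = dict(fixed or {})
    if hist.total_counts == 0:
        raise ValueError("cannot fit an all-zero histogram")
    bshift_fixed = int(fixed.pop("bshift", 0))
    shifts = (
        range(hist.irf.shift_support[0], hist.irf.shift_support[1] + 1)
        if fit_bshift
        else [bshift_fixed]
    )

    best: tuple[float, DecayModel, dict[str, float], bool] | None = None
    for bshift in shifts:
        obj = _DecayObjective(hist, kind, fixed, bshift)
        if not obj.free:
            model = obj.model({})
            ll = obj.loglik({})
            cand = (ll, model, {}, True)
        else:
            x0 = np.array(
                [
                    _to_unconstrained(p, (start or {}).get(p, _DEFAULTS[p]))
                    for p in obj.free
                ]
            )
            res = minimize(obj.neg_loglik_u, x0, method="Nelder-Mead",
                           options={"xatol": 1e-7, "fatol": 1e-9, "maxiter": 4000})
            values = {p: _from_unconstrained(p, ui) for p, ui in zip(obj.free, res.x)}
            cand = (-res.fun, obj.model(values), values, bool(res.success))
        if best is None or cand[0] > best[0]:
            best = cand
            best_obj = obj
    ll, model, values, converged = best
    if not converged:
        warnings.warn("decay fit did not converge", RuntimeWarning)
    se = _numeric_se(best_obj, {**model.params()})
    return FitResult(model=model, log_likelihood=ll, se=se,
                     converged=converged, n_free=len(best_obj.free))


# ---------------------------------------------------------------------------
# Posterior inference
# ---------------------------------------------------------------------------

_GRID_POINTS = {"f_fret": 201, "noise_a": 21, "tau_d": 201, "tau_fret": 201}


def _default_grid(name: str, mle: FitResult | None) -> np.ndarray:
    if name == "f_fret":
        return np.linspace(0.0, 1.0, _GRID_POINTS["f_fret"])
    if name == "noise_a":
        return np.linspace(0.8, 1.0, _GRID_POINTS["noise_a"])
    # Lifetime grids centered on the MLE, +- 6 SE (fallback +- 20%).
    assert mle is not None
    center = getattr(mle.model, name)
    se = mle.se.get(name, np.nan)
    half = 6 * se if np.isfinite(se) and se > 0 else 0.2 * center
    lo = max(center - half, _BOUNDS[name][0])
    hi = min(center + half, _BOUNDS[name][1])
    return np.linspace(lo, hi, _GRID_POINTS[name])


def _grid_posterior(
    hist: DecayHistogram, kind: str, fixed: dict[str, float], grids: dict[str, np.ndarray],
    bshift: int,
) -> PosteriorGrid:
    """Log posterior on the Cartesian grid.

    Lifetime axes require one IRF convolution per grid point; the amplitude
    axes (f_fret, noise_a) are algebraic in the convolved bases and are
    vectorized.
    """
    free = list(grids)
    tau_axes = [p for p in free if p in ("tau_d", "tau_fret")]
    amp_axes = [p for p in free if p in ("f_fret", "noise_a")]
    n_bins, K, irf = hist.n_bins, hist.adc_ratio, hist.irf
    n_fine = n_bins * K
    counts = hist.counts
    w = np.roll(irf.weights, bshift)
    irf_fft = np.fft.rfft(w)

    def conv_coarse(tau: float) -> np.ndarray:
        m = _folded_exp_masses(tau, n_fine, irf.bin_width)
        conv = np.fft.irfft(irf_fft * np.fft.rfft(m), n=n_fine)
        return np.clip(conv, 0.0, None).reshape(n_bins, K).sum(axis=1)

    f_grid = grids.get("f_fret", np.array([fixed.get("f_fret", 0.0)]))
    a_grid = grids.get("noise_a", np.array([fixed.get("noise_a", 1.0)]))

    tau_shapes = [len(grids[p]) for p in tau_axes]
    amp_shape = [len(grids[p]) for p in amp_axes]
    out = np.empty(tau_shapes + amp_shape if tau_shapes or amp_shape else [1])

    def amp_block(pd: np.ndarray, pf: np.ndarray | None) -> np.ndarray:
        # (f, a) -> log lik, vectorized; collapse axes not free.
        if kind == "single" or pf is None:
            decay = np.broadcast_to(pd, (len(f_grid), n_bins))
        else:
            decay = (1 - f_grid)[:, None] * pd + f_grid[:, None] * pf
        probs = a_grid[None, :, None] * decay[:, None, :] + (1 - a_grid)[None, :, None] * (K / n_fine)
        with np.errstate(divide="ignore"):
            logp = np.where(probs > 0, np.log(np.where(probs > 0, probs, 1.0)), -np.inf)
        ll = np.einsum("fab,b->fa", logp, counts)
        # squeeze amp axes that are not free (canonical order keeps f before a)
        block = ll
        if "noise_a" not in grids:
            block = block[..., 0]
        if "f_fret" not in grids:
            block = block[0] if block.ndim else block
        return block

    if not tau_axes:
        pd = conv_coarse(fixed["tau_d"])
        pf = conv_coarse(fixed["tau_fret"]) if kind == "double" else None
        out[...] = amp_block(pd, pf)
    elif tau_axes == ["tau_d"]:
        pf = conv_coarse(fixed["tau_fret"]) if kind == "double" else None
        for i, td in enumerate(grids["tau_d"]):
            out[i] = amp_block(conv_coarse(td), pf)
    elif tau_axes == ["tau_fret"]:
        pd = conv_coarse(fixed["tau_d"])
        for i, tf in enumerate(grids["tau_fret"]):
            out[i] = amp_block(pd, conv_coarse(tf))
    else:  # both lifetimes free
        for i, td in enumerate(grids["tau_d"]):
            pd = conv_coarse(td)
            for j, tf in enumerate(grids["tau_fret"]):
                out[i, j] = amp_block(pd, conv_coarse(tf)) if tf < td else -np.inf

    axes = {p: grids[p] for p in free}
    if not axes:
        axes = {"f_fret": np.array([fixed.get("f_fret", 0.0)])}
        out = out.reshape(1)
    return PosteriorGrid(axes=axes, log_density=out).normalize()


def _gibbs_posterior(
    hist: DecayHistogram, kind: str, fixed: dict[str, float], free: list[str], bshift: int,
    n_draws: int, burn_in: int, seed: int,
) -> PosteriorGrid:
    """Metropolis-within-Gibbs sampling for > 3 free parameters.

    Draws are histogrammed onto the standard grid of each parameter; a
    split-chain Gelman-Rubin diagnostic on f_fret flags poor mixing.
    """
    rng = np.random.default_rng(seed)
    obj = _DecayObjective(hist, kind, fixed, bshift)
    mle = fit_mle(hist, kind, fixed)
    x = {p: getattr(mle.model, p) for p in free}
    steps = {p: max(mle.se.get(p, np.nan), 1e-3) if np.isfinite(mle.se.get(p, np.nan)) else
             0.05 * max(abs(x[p]), 0.1) for p in free}
    ll = obj.loglik(x)
    samples = {p: np.empty(n_draws) for p in free}
    for it in range(burn_in + n_draws):
        for p in free:
            prop = dict(x)
            prop[p] = x[p] + rng.normal(0.0, steps[p])
            lo, hi = _BOUNDS[p]
            if not (lo <= prop[p] <= hi):
                continue
            ll_prop = obj.loglik(prop)
            if np.log(rng.uniform()) < ll_prop - ll:
                x, ll = prop, ll_prop
        if it >= burn_in:
            for p in free:
                samples[p][it - burn_in] = x[p]

    # split-chain R-hat on the marginal of interest
    f = samples.get("f_fret", samples[free[0]])
    half = n_draws // 2
    chains = np.stack([f[:half], f[half : 2 * half]])
    W = chains.var(axis=1, ddof=1).mean()
    B = half * chains.mean(axis=1).var(ddof=1)
    rhat = np.sqrt(((half - 1) / half * W + B / half) / W) if W > 0 else np.inf
    if rhat > 1.1:
        warnings.warn(f"Gibbs sampler may not have mixed (split R-hat {rhat:.2f})",
                      RuntimeWarning)

    grids = {p: _default_grid(p, mle) for p in free}
    logd = np.zeros(tuple(len(grids[p]) for p in free))
    # independent-marginal density estimate from the draws (adequate for
    # reporting means/SDs; the joint draws remain available to callers)
    for i, p in enumerate(free):
        g = grids[p]
        edges = np.concatenate([[g[0] - (g[1] - g[0]) / 2],
                                (g[:-1] + g[1:]) / 2,
                                [g[-1] + (g[-1] - g[-2]) / 2]])
        h, _ = np.histogram(samples[p], bins=edges)
        with np.errstate(divide="ignore"):
            lm = np.log(h + 0.5)
        shape = [1] * len(free)
        shape[i] = len(g)
        logd = logd + lm.reshape(shape)
    post = PosteriorGrid(axes=grids, log_density=logd).normalize()
    post.samples = samples  # type: ignore[attr-defined]
    return post


def infer_posterior(
    hist: DecayHistogram,
    kind: str = "double",
    fixed: Mapping[str, float] | None = None,
    grids: Mapping[str, np.ndarray] | None = None,
    n_draws: int = 5000,
    burn_in: int = 1000,
    seed: int = 0,
) -> PosteriorGrid:
    """Posterior over the free decay-model parameters under a uniform prior.

    Grid sampling is used for up to 3 free parameters, Metropolis-within-Gibbs
    beyond that.  Lifetime grids default to MLE +- 6 SE.
    """
    fixed = dict(fixed or {})
    if hist.total_counts == 0:
        raise ValueError("cannot infer from an empty histogram")
    bshift = int(fixed.pop("bshift", 0))
    free = [p for p in _MODEL_PARAMS[kind] if p not in fixed]
    if grids is not None:
        grids = {p: np.asarray(g, dtype=float) for p, g in grids.items()}
        free = [p for p in _MODEL_PARAMS[kind] if p in grids]
        fixed = {p: v for p, v in fixed.items()}
    if len(free) > 3 and grids is None:
        return _gibbs_posterior(hist, kind, fixed, free, bshift, n_draws, burn_in, seed)
    if grids is None:
        mle = (
            fit_mle(hist, kind, fixed)
            if any(p in ("tau_d", "tau_fret") for p in free)
            else None
        )
        grids = {p: _default_grid(p, mle) for p in free}
    full_fixed = {**{p: _DEFAULTS[p] for p in _MODEL_PARAMS[kind]}, **fixed}
    return _grid_posterior(hist, kind, full_fixed, dict(grids), bshift)


def combine_posteriors(posteriors: Sequence[PosteriorGrid]) -> FretEstimate:
    """Multiply per-kinetochore posteriors and marginalize to f_FRET.

    The product of normalized posteriors over a shared grid is the posterior
    for the common FRET fraction of the group; its marginal mean and SD give
    the group estimate and its SEM.
    """
    if len(posteriors) == 0:
        raise ValueError("no posteriors to combine")
    first = posteriors[0]
    logd = np.zeros_like(first.log_density, dtype=float)
    for post in posteriors:
        if list(post.axes) != list(first.axes) or any(
            len(post.axes[k]) != len(first.axes[k]) or not np.allclose(post.axes[k], first.axes[k])
            for k in first.axes
        ):
            raise ValueError("posterior grids are incompatible")
        if not post.normalized:
            post.normalize()
        logd = logd + post.log_density
    combined = PosteriorGrid(axes=dict(first.axes), log_density=logd).normalize()
    mean = combined.mean("f_fret")
    sd = combined.sd("f_fret")
    # conflict check: every input should put nonnegligible mass near the
    # combined mean; posteriors peaked at opposite ends do not.
    for post in posteriors:
        g, p = post.marginal("f_fret")
        window = np.abs(g - mean) <= max(4 * sd, 2 * (g[1] - g[0]) if g.size > 1 else np.inf)
        if p[window].sum() < 1e-6:
            warnings.warn(
                "conflicting posteriors: an input places essentially no mass "
                "near the combined mean", RuntimeWarning)
            break
    return FretEstimate(mean_f_fret=mean, sem=sd, n_kinetochores=len(posteriors))


# ---------------------------------------------------------------------------
# Model selection and conversion
# ---------------------------------------------------------------------------


def select_model_bic(
    hist: DecayHistogram,
    fixed_single: Mapping[str, float] | None = None,
    fixed_double: Mapping[str, float] | None = None,
) -> float:
    """Delta BIC = BIC(single) - BIC(double); positive favors two exponentials.

    Both models carry the uniform noise floor fixed at ``noise_a = 1`` unless
    overridden; the sample size is the total photon count.  An exact tie
    reports 0.0 (single-exponential preferred by parsimony).
    """
    fixed_single = dict(fixed_single or {"noise_a": 1.0})
    fixed_double = dict(fixed_double or {"noise_a": 1.0})
    n = hist.total_counts
    fit1 = fit_mle(hist, "single", fixed_single)
    fit2 = fit_mle(
        hist, "double", fixed_double,
        start={"tau_d": fit1.model.tau_d},
    )
    bic1 = fit1.n_free * np.log(n) - 2 * fit1.log_likelihood
    bic2 = fit2.n_free * np.log(n) - 2 * fit2.log_likelihood
    return float(bic1 - bic2)


def fret_to_binding(f_fret: float, slope: float = 0.42) -> float:
    """Convert a FRET fraction to an NDC80-kMT binding fraction.

    The conversion factor is the calibration slope of fitted FRET fraction vs
    true bound fraction (0.42 by default).  Results outside [0, 1] are clipped
    with a warning.
    """
    if slope <= 0:
        raise ValueError("slope must be positive")
    if f_fret < 0:
        raise ValueError("f_fret must be nonnegative")
    f_bound = f_fret / slope
    if f_bound > 1.0:
        warnings.warn("binding fraction exceeded 1 and was clipped", RuntimeWarning)
        f_bound = 1.0
    return float(f_bound)
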