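"""Synthetic data generators with known ground truth.

Every generator is a pure function of its parameters and a seed, producing
the inputs the analysis pipeline consumes: TCSPC decay histograms with a
finite-width IRF, movies of oscillating sister-kinetochore pairs, tables of
(K-K distance, Aurora B concentration, binding fraction), FCS autocorrelation
curves, and exponential drug-response time courses.  Each dataset carries a
:class:`GroundTruth` of its generating parameters so recovery can be tested
without external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import erf

from .flim import IRF, DecayHistogram, DecayModel, decay_model_eval

__all__ = [
    "SimConfig",
    "GroundTruth",
    "KK_DISTRIBUTIONS",
    "gen_irf",
    "gen_decay",
    "gen_movie",
    "gen_tension_table",
    "gen_fcs_curve",
    "gen_timecourse",
]

#: Per-condition Normal(mean, SD) of the sister-kinetochore (K-K) distance
#: in micrometers.  Untreated metaphase cells sit near 1.2 um; taxol and the
#: Eg5 inhibitor STLC relax centromere tension, while the non-phosphorylatable
#: 9A-Hec1 mutant hyper-stabilizes attachments and stretches centromeres.
#: Haspin inhibition (5-ITu) leaves the distribution essentially untreated.
KK_DISTRIBUTIONS: dict[str, tuple[float, float]] = {
    "untreated": (1.19, 0.19),
    "taxol": (0.90, 0.10),
    "stlc": (0.87, 0.10),
    "hec1_9A": (1.36, 0.21),
    "haspin_5itu": (1.16, 0.18),
}

#: Donor (no-FRET) lifetime of mTurquoise2, ns.
TAU_D_DEFAULT = 3.75


@dataclass(frozen=True)
class SimConfig:
    """Shared acquisition parameters for synthetic TCSPC data.

    ``bin_width`` is the fine (IRF) bin width; recorded bins are ``adc_ratio``
    fine bins wide.  Defaults give a 12.8 ns window (64 coarse bins of 0.2 ns),
    more than 3 donor lifetimes.  ``photons_per_decay`` defaults to 300, the
    few-hundred-photon regime of a single kinetochore-timepoint.
    """

    seed: int = 0
    photons_per_decay: int = 300
    irf_center: float = 1.0
    irf_fwhm: float = 0.3
    bin_width: float = 0.0125
    adc_ratio: int = 16
    n_bins: int = 64
    condition: str = "untreated"

    def __post_init__(self) -> None:
        if self.photons_per_decay < 0:
            raise ValueError("photons_per_decay must be nonnegative")
        if self.adc_ratio < 1:
            raise ValueError("adc_ratio must be >= 1")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if self.condition not in KK_DISTRIBUTIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.window < 3 * TAU_D_DEFAULT:
            raise ValueError("measurement window must span >= 3 donor lifetimes")

    @property
    def n_fine(self) -> int:
        return self.n_bins * self.adc_ratio

    @property
    def window(self) -> float:
        return self.n_fine * self.bin_width

    def make_irf(self) -> IRF:
        return gen_irf(self.irf_center, self.irf_fwhm, self.bin_width, self.n_fine)


@dataclass(frozen=True)
class GroundTruth:
    """Generating parameters attached to every synthetic dataset."""

    true_params: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, val in self.true_params.items():
            if key.startswith("f_") and isinstance(val, (int, float)):
                if not (0.0 <= float(val) <= 1.0):
                    raise ValueError(f"fraction {key}={val} outside [0, 1]")

    def __getitem__(self, key: str) -> object:
        return self.true_params[key]


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


# ---------------------------------------------------------------------------
# IRF and decays
# ---------------------------------------------------------------------------


def gen_irf(center: float, fwhm: float, bin_width: float, n_fine_bins: int) -> IRF:
    """Gaussian instrument response integrated exactly over fine bins.

    In the limit ``fwhm -> 0`` all mass falls into the bin containing
    ``center`` (delta IRF).
    """
    if fwhm <= 0:
        raise ValueError("fwhm must be positive")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    edges = np.arange(n_fine_bins + 1) * bin_width
    z = (edges - center) / (np.sqrt(2.0) * sigma)
    cdf = 0.5 * (1.0 + erf(z))
    weights = np.diff(cdf)
    total = weights.sum()
    if total <= 0:  # pathological center far outside the window
        raise ValueError("IRF has no mass inside the measurement window")
    return IRF(weights=weights / total, bin_width=bin_width)


def gen_decay(
    model: DecayModel,
    irf: IRF,
    config: SimConfig,
    rng: np.random.Generator | int | None = None,
) -> tuple[DecayHistogram, GroundTruth]:
    """Poisson photon-count decay histogram from a decay model.

    Per-bin counts are independent Poisson draws with means
    ``photons_per_decay * P_i`` where ``P_i`` are the model's per-bin arrival
    probabilities, so the expected total equals ``photons_per_decay``.
    """
    rng = _rng(config.seed if rng is None else rng)
    probs = decay_model_eval(model, config.n_bins, config.adc_ratio, irf)
    counts = rng.poisson(config.photons_per_decay * probs)
    hist = DecayHistogram(counts=counts, adc_ratio=config.adc_ratio, irf=irf)
    truth = GroundTruth({**model.params(), "kind": model.kind,
                         "photons_per_decay": config.photons_per_decay})
    return hist, truth


# ---------------------------------------------------------------------------
# Movies of oscillating sister pairs
# ---------------------------------------------------------------------------


def _pair_trajectories(
    n_pairs: int,
    n_frames: int,
    condition: str,
    dt_s: float,
    rng: np.random.Generator,
    field_um: float,
    drift_um_per_frame: tuple[float, float],
    center_amp_um: float,
    center_period_s: float,
    breath_amp_um: float,
    breath_period_s: float,
) -> pd.DataFrame:
    """Ground-truth sister trajectories.

    Pair centers oscillate sinusoidally along the (roughly common) pair axis;
    the K-K distance breathes anti-phase about its per-pair mean, so the two
    sisters' axial velocities about the center are exactly anti-correlated.
    """
    kk_mean, kk_sd = KK_DISTRIBUTIONS[condition]
    t = np.arange(n_frames) * dt_s
    rows = []
    margin = 2.0
    min_sep = 2.0  # pair centers do not overlap in projection
    centers: list[np.ndarray] = []
    for pid in range(n_pairs):
        kk0 = max(rng.normal(kk_mean, kk_sd), 0.3)
        angle = rng.normal(0.0, 0.2)
        axis = np.array([np.cos(angle), np.sin(angle)])
        for _ in range(200):
            c0 = rng.uniform(margin, field_um - margin, size=2)
            if all(np.linalg.norm(c0 - c) >= min_sep for c in centers):
                break
        centers.append(c0)
        phase_c = rng.uniform(0, 2 * np.pi)
        phase_b = rng.uniform(0, 2 * np.pi)
        osc = (
            center_amp_um * np.sin(2 * np.pi * t / center_period_s + phase_c)
            if center_amp_um > 0
            else np.zeros_like(t)
        )
        breath = (
            breath_amp_um * np.sin(2 * np.pi * t / breath_period_s + phase_b)
            if breath_amp_um > 0
            else np.zeros_like(t)
        )
        kk = np.clip(kk0 + breath, 0.2, None)
        center = c0[None, :] + osc[:, None] * axis[None, :]
        drift = np.outer(np.arange(n_frames), np.asarray(drift_um_per_frame))
        for sister, sign in (("a", +0.5), ("b", -0.5)):
            xy = center + sign * kk[:, None] * axis[None, :] + drift
            for fi in range(n_frames):
                rows.append(
                    (fi, pid, sister, xy[fi, 0], xy[fi, 1], kk[fi], kk0, angle)
                )
    return pd.DataFrame(
        rows,
        columns=["frame", "pair_id", "sister", "x_um", "y_um", "kk_um",
                 "kk_mean_um", "axis_angle"],
    )


def gen_movie(
    n_pairs: int,
    n_frames: int,
    condition: str = "untreated",
    config: SimConfig | None = None,
    *,
    pixel_size_um: float = 0.107,
    image_shape: tuple[int, int] = (128, 128),
    dt_s: float = 13.0,
    spot_sigma_px: float = 1.3,
    spot_photons: float = 2000.0,
    read_noise_sd: float = 2.0,
    background: float = 10.0,
    drift_um_per_frame: tuple[float, float] = (0.0, 0.0),
    center_amp_um: float = 0.5,
    center_period_s: float = 120.0,
    breath_amp_um: float = 0.15,
    breath_period_s: float = 50.0,
) -> tuple[np.ndarray, pd.DataFrame, GroundTruth]:
    """Synthetic movie of Gaussian spots on oscillating sister pairs.

    Returns ``(stack, truth_tracks, truth)`` where ``stack`` is a float32
    (n_frames, ny, nx) array (TIFF-writable) with Poisson shot noise and
    Gaussian read noise, and ``truth_tracks`` holds the exact sub-pixel
    positions in micrometers.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    if condition not in KK_DISTRIBUTIONS:
        raise ValueError(f"unknown condition {condition!r}")
    config = config or SimConfig(condition=condition)
    rng = _rng(config.seed)
    ny, nx = image_shape
    field_um = min(ny, nx) * pixel_size_um
    tracks = _pair_trajectories(
        n_pairs, n_frames, condition, dt_s, rng, field_um, drift_um_per_frame,
        center_amp_um, center_period_s, breath_amp_um, breath_period_s,
    )
    stack = np.zeros((n_frames, ny, nx), dtype=np.float64)
    yy, xx = np.mgrid[0:ny, 0:nx]
    for row in tracks.itertuples(index=False):
        cx = row.x_um / pixel_size_um
        cy = row.y_um / pixel_size_um
        if not (-3 * spot_sigma_px <= cx < nx + 3 * spot_sigma_px):
            continue
        amp = spot_photons / (2 * np.pi * spot_sigma_px**2)
        stack[row.frame] += amp * np.exp(
            -((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * spot_sigma_px**2)
        )
    stack += background
    stack = rng.poisson(stack).astype(np.float64)
    stack += rng.normal(0.0, read_noise_sd, size=stack.shape)
    truth = GroundTruth(
        {
            "condition": condition,
            "kk_mean_um": KK_DISTRIBUTIONS[condition][0],
            "kk_sd_um": KK_DISTRIBUTIONS[condition][1],
            "pixel_size_um": pixel_size_um,
            "dt_s": dt_s,
            "drift_um_per_frame": tuple(drift_um_per_frame),
            "n_pairs": n_pairs,
        }
    )
    return stack.astype(np.float32), tracks, truth


# ---------------------------------------------------------------------------
# Tension-model tables, FCS curves, time courses
# ---------------------------------------------------------------------------


def gen_tension_table(
    params,
    intensity_map: tuple[float, float],
    n: int,
    noise_sd: float,
    seed: int = 0,
    dkk_range_um: tuple[float, float] = (0.7, 1.6),
) -> tuple[pd.DataFrame, GroundTruth]:
    """Rows of (K-K distance, Aurora B concentration, binding fraction).

    ``intensity_map`` is the (slope, intercept) of the linear Aurora B
    concentration vs K-K distance relation, in uM per um and uM; binding
    fractions follow the three-step activation/phosphorylation/binding model
    plus Gaussian noise.

    ``params`` combines :class:`~ktflim.tension.AuroraActivationParams` and
    :class:`~ktflim.tension.PhosBindingParams` as a tuple ``(aur, pb)``.
    """
    from .tension import binding_from_concentration

    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    aur, pb = params
    rng = _rng(seed)
    slope, intercept = intensity_map
    dkk = np.linspace(*dkk_range_um, n)
    conc = np.clip(slope * dkk + intercept, 0.0, None)
    fbound = np.array([binding_from_concentration(a, aur, pb) for a in conc])
    noisy = fbound + rng.normal(0.0, noise_sd, size=n)
    table = pd.DataFrame({"dkk_um": dkk, "aurora_uM": conc, "f_bound": noisy})
    truth = GroundTruth(
        {
            "K": aur.K, "A_star": aur.A_star, "Kphos": pb.Kphos,
            "K0": pb.K0, "K0_prime": pb.K0_prime,
            "intensity_slope": slope, "intensity_intercept": intercept,
            "noise_sd": noise_sd, "f_bound_clean": fbound,
        }
    )
    return table, truth


def gen_fcs_curve(
    model_kind: str,
    truth: Mapping[str, float],
    lags: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """FCS autocorrelation curve G(tau) from a diffusion model plus noise.

    ``model_kind='reference'`` uses the calibration-dye model parameterized by
    (V_eff, w_xy, C, D, chi2, G_inf); ``'brightness'`` the single-species
    model parameterized by (N, tau_diff, w_ratio2, chi2, G_inf).
    """
    from . import fcs

    lags = np.asarray(lags, dtype=float)
    if np.any(lags <= 0) or np.any(np.diff(lags) <= 0):
        raise ValueError("lags must be positive and strictly increasing")
    rng = _rng(seed)
    if model_kind == "reference":
        g = fcs.reference_model(
            lags, truth["V_eff"], truth["w_xy"], truth["C"], truth["D"],
            truth.get("chi2", 1.0), truth.get("G_inf", 0.0),
        )
    elif model_kind == "brightness":
        g = fcs.brightness_model(
            lags, truth["N"], truth["tau_diff"], truth["w_ratio2"],
            truth.get("chi2", 1.0), truth.get("G_inf", 0.0),
        )
    else:
        raise ValueError("model_kind must be 'reference' or 'brightness'")
    noisy = g + rng.normal(0.0, noise_sd, size=lags.size)
    curve = pd.DataFrame({"lag_s": lags, "G": noisy})
    return curve, GroundTruth({**dict(truth), "model_kind": model_kind,
                               "noise_sd": noise_sd})


def gen_timecourse(
    kind: str,
    A: float,
    tau: float,
    c: float,
    t: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Exponential drug-response time course.

    ``rising``:  y = A (1 - exp(-I(t>=0) t / tau)) + c  (e.g. NDC80 binding
    after Aurora B inhibition); ``decaying``: y = A exp(-I(t>=0) t / tau) + c
    (e.g. kinase-sensor signal).  The indicator freezes the response at its
    pre-treatment baseline for t < 0.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    if kind not in ("rising", "decaying"):
        raise ValueError("kind must be 'rising' or 'decaying'")
    t = np.asarray(t, dtype=float)
    rng = _rng(seed)
    ind = (t >= 0).astype(float)
    if kind == "rising":
        y = A * (1.0 - np.exp(-ind * t / tau)) + c
    else:
        y = A * np.exp(-ind * t / tau) + c
    noisy = y + rng.normal(0.0, noise_sd, size=t.size)
    tc = pd.DataFrame({"t_min": t, "y": noisy})
    return tc, GroundTruth({"kind": kind, "A": A, "tau": tau, "c": c,
                            "noise_sd": noise_sd})
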