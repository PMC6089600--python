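"""FCS calibration and the beta-tubulin labeling-fraction pipeline.

Two-photon fluorescence correlation spectroscopy on a reference dye of known
concentration and diffusion coefficient calibrates the effective focal
volume ``V_eff`` and radial waist ``w_xy``; a second measurement on the
labeled species yields the number of molecules ``N`` in the focal volume and
hence the molecular brightness (photon rate per molecule).  Combining the
brightness and focal volume with a bulk photon rate converts intensity to
absolute concentration, which chains into the labeled-tubulin fraction:

    polymer rate -> [labeled polymerized tubulin] -> [labeled total tubulin]
    -> labeled fraction of beta-tubulin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import closing, disk

__all__ = [
    "FcsCurve",
    "FcsReferenceFit",
    "BrightnessFit",
    "LabelingEstimate",
    "AVOGADRO_PER_UM3_PER_UM",
    "reference_model",
    "brightness_model",
    "w_z_from_veff",
    "fit_reference_fcs",
    "fit_brightness_fcs",
    "concentration_from_rate",
    "estimate_polymer_rate",
    "labeling_fraction",
]

#: molecules per um^3 in a 1 uM solution
AVOGADRO_PER_UM3_PER_UM = 602.214076


@dataclass(frozen=True)
class FcsCurve:
    lags: np.ndarray  # seconds, positive increasing
    G: np.ndarray
    count_rate: float = 0.0  # s^-1
    background_rate: float = 0.0  # s^-1

    def __post_init__(self) -> None:
        lags = np.asarray(self.lags, dtype=float)
        if np.any(lags <= 0) or np.any(np.diff(lags) <= 0):
            raise ValueError("lags must be positive and strictly increasing")
        object.__setattr__(self, "lags", lags)
        object.__setattr__(self, "G", np.asarray(self.G, dtype=float))

    @classmethod
    def from_frame(cls, df: pd.DataFrame, **kw) -> "FcsCurve":
        return cls(lags=df.iloc[:, 0].to_numpy(), G=df.iloc[:, 1].to_numpy(), **kw)


@dataclass(frozen=True)
class FcsReferenceFit:
    V_eff: float  # um^3
    w_xy: float  # nm
    w_z: float  # nm
    chi2_corr: float
    G_inf: float

    def __post_init__(self) -> None:
        if self.V_eff <= 0 or self.w_xy <= 0 or self.w_z <= 0:
            raise ValueError("geometry must be positive")


@dataclass(frozen=True)
class BrightnessFit:
    N: float
    brightness: float  # s^-1 per molecule

    def __post_init__(self) -> None:
        if self.N <= 0:
            raise ValueError("N must be positive")
        if self.brightness < 0:
            raise ValueError("brightness must be nonnegative")


@dataclass(frozen=True)
class LabelingEstimate:
    polymer_rate: float  # ms^-1
    conc_polymer_labeled: float  # uM
    conc_total_labeled: float  # uM
    labeled_fraction: float  # percent

    def __post_init__(self) -> None:
        if min(self.polymer_rate, self.conc_polymer_labeled,
               self.conc_total_labeled, self.labeled_fraction) < 0:
            raise ValueError("estimates must be nonnegative")


# ---------------------------------------------------------------------------
# Models
# ---------------------------------------------------------------------------


def w_z_from_veff(V_eff: float, w_xy_um: float) -> float:
    """Axial waist from the effective-volume relation
    w_z = (2 / pi^{3/2}) * V_eff / w_xy^2 (all lengths in um)."""
    return 2.0 / np.pi**1.5 * V_eff / w_xy_um**2


def reference_model(
    tau: np.ndarray, V_eff: float, w_xy_um: float, C_per_um3: float,
    D_um2_s: float, chi2: float = 1.0, G_inf: float = 0.0,
) -> np.ndarray:
    """Two-photon diffusion autocorrelation for a dye of known C and D.

    G(tau) = 1/(V_eff chi2 C) (1 + 8 D tau / w_xy^2)^-1
             (1 + 8 D tau / w_z^2)^-1/2 + G_inf,
    with w_z eliminated via the V_eff relation.  ``C_per_um3`` is in
    molecules per um^3.
    """
    w_z = w_z_from_veff(V_eff, w_xy_um)
    tau = np.asarray(tau, dtype=float)
    gx = 1.0 / (1.0 + 8.0 * D_um2_s * tau / w_xy_um**2)
    gz = 1.0 / np.sqrt(1.0 + 8.0 * D_um2_s * tau / w_z**2)
    return gx * gz / (V_eff * chi2 * C_per_um3) + G_inf


def brightness_model(
    tau: np.ndarray, N: float, tau_diff: float, w_ratio2: float,
    chi2: float = 1.0, G_inf: float = 0.0,
) -> np.ndarray:
    """Single-species autocorrelation with free diffusion time.

    G(tau) = 1/(N chi2) (1 + tau/tau_d)^-1
             (1 + (w_xy^2/w_z^2)(tau/tau_d))^-1/2 + G_inf.
    """
    tau = np.asarray(tau, dtype=float)
    x = tau / tau_diff
    return 1.0 / (N * chi2) / (1.0 + x) / np.sqrt(1.0 + w_ratio2 * x) + G_inf


def chi2_background(count_rate: float, background_rate: float) -> float:
    """Background correction factor (S/(S+B))^2 with S the signal rate."""
    if count_rate <= 0:
        return 1.0
    s = max(count_rate - background_rate, 0.0)
    return (s / count_rate) ** 2


# ---------------------------------------------------------------------------
# Fits
# ---------------------------------------------------------------------------


def fit_reference_fcs(
    curve: FcsCurve, known_C_molar: float, known_D_um2_s: float
) -> FcsReferenceFit:
    """Calibrate (V_eff, w_xy, G_inf) from a known-concentration dye curve."""
    if known_C_molar <= 0 or known_D_um2_s <= 0:
        raise ValueError("C and D must be positive")
    C = known_C_molar * 1e6 * AVOGADRO_PER_UM3_PER_UM  # molecules / um^3
    chi2 = chi2_background(curve.count_rate, curve.background_rate)

    def resid(x):
        V_eff, w_xy, G_inf = x
        return reference_model(curve.lags, V_eff, w_xy, C, known_D_um2_s,
                               chi2, G_inf) - curve.G

    amp0 = max(curve.G[0] - curve.G[-1], 1e-6)
    res = least_squares(resid, x0=np.array([1.0 / (amp0 * C), 0.3, curve.G[-1]]),
                        bounds=([1e-6, 1e-3, -np.inf], [np.inf, np.inf, np.inf]),
                        xtol=1e-14, ftol=1e-14, gtol=1e-14)
    if not res.success:
        raise RuntimeError("reference FCS fit did not converge")
    V_eff, w_xy_um, G_inf = res.x
    return FcsReferenceFit(
        V_eff=float(V_eff), w_xy=float(w_xy_um * 1e3),
        w_z=float(w_z_from_veff(V_eff, w_xy_um) * 1e3),
        chi2_corr=float(chi2), G_inf=float(G_inf),
    )


def fit_brightness_fcs(curve: FcsCurve, geometry: FcsReferenceFit) -> BrightnessFit:
    """Molecule number and molecular brightness with the PSF geometry fixed."""
    chi2 = chi2_background(curve.count_rate, curve.background_rate)
    if chi2 <= 0:  # no signal above background: correction degenerate
        chi2 = 1.0
    w_ratio2 = (geometry.w_xy / geometry.w_z) ** 2

    def resid(x):
        N, tau_diff, G_inf = x
        return brightness_model(curve.lags, N, tau_diff, w_ratio2, chi2, G_inf) - curve.G

    amp0 = curve.G[0] - curve.G[-1]
    if amp0 <= 0:
        raise ValueError("autocorrelation amplitude must be positive")
    res = least_squares(
        resid, x0=np.array([1.0 / (amp0 * chi2), np.median(curve.lags), curve.G[-1]]),
        bounds=([1e-9, 1e-9, -np.inf], [np.inf, np.inf, np.inf]),
        xtol=1e-14, ftol=1e-14, gtol=1e-14,
    )
    if not res.success:
        raise RuntimeError("brightness FCS fit did not converge")
    N = float(res.x[0])
    signal = curve.count_rate - curve.background_rate
    if signal <= 0:
        warnings.warn("background at or above count rate; brightness set to 0",
                      RuntimeWarning)
        signal = 0.0
    return BrightnessFit(N=N, brightness=float(signal / N))


def concentration_from_rate(
    rate_per_s: float, brightness_per_s: float, V_eff_um3: float
) -> float:
    """Bulk photon rate -> concentration in uM.

    conc = rate / (brightness * V_eff), converted from molecules/um^3.
    """
    if rate_per_s < 0:
        raise ValueError("rate must be nonnegative")
    if brightness_per_s <= 0 or V_eff_um3 <= 0:
        raise ValueError("brightness and V_eff must be positive")
    per_um3 = rate_per_s / (brightness_per_s * V_eff_um3)
    return per_um3 / AVOGADRO_PER_UM3_PER_UM


def estimate_polymer_rate(
    image: np.ndarray,
    mask: np.ndarray | None = None,
    bin_width: float | None = None,
) -> tuple[float, float, float]:
    """(total mean, cytoplasm mode, polymer rate) from a photon-rate image.

    The cytoplasmic background (monomer + nonspecific) is the mode of the
    in-cell intensity histogram; the microtubule (polymer) signal is the
    in-cell mean minus that mode.  When no mask is given the cell is
    segmented by Otsu threshold, largest connected component and a
    morphological closing.  Histogram bin width defaults to the
    Freedman-Diaconis rule.
    """
    img = np.asarray(image, dtype=float)
    if mask is None:
        thr = threshold_otsu(img)
        fg = closing(img > thr, disk(3))
        labels = cc_label(fg)
        if labels.max() == 0:
            raise ValueError("segmentation found no cell")
        largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
        mask = labels == largest
    mask = np.asarray(mask, dtype=bool)
    vals = img[mask]
    if vals.size == 0:
        raise ValueError("empty mask")
    if bin_width is None:
        iqr = np.subtract(*np.percentile(vals, [75, 25]))
        bin_width = 2 * iqr / vals.size ** (1 / 3) if iqr > 0 else 0.0
    if bin_width <= 0:
        mode = float(np.median(vals))
    else:
        edges = np.arange(vals.min(), vals.max() + bin_width, bin_width)
        if len(edges) < 2:
            mode = float(np.median(vals))
        else:
            hist, edges = np.histogram(vals, bins=edges)
            k = int(np.argmax(hist))
            mode = float((edges[k] + edges[k + 1]) / 2)
    mean = float(vals.mean())
    return mean, mode, mean - mode


def labeling_fraction(
    conc_polymer_labeled_uM: float,
    polymer_fraction_pct: float,
    total_tubulin_uM: float,
) -> tuple[float, float]:
    """Labeled-tubulin arithmetic: (total labeled conc in uM, fraction in %).

    ``polymer_fraction_pct`` is the percentage of tubulin that is polymerized
    (36% in mitotic tissue-culture cells); ``total_tubulin_uM`` the total
    tubulin dimer concentration (~20 uM).
    """
    if not (0.0 < polymer_fraction_pct <= 100.0):
        raise ValueError("polymer_fraction_pct must be in (0, 100]")
    if total_tubulin_uM <= 0:
        raise ValueError("total_tubulin_uM must be positive")
    total = conc_polymer_labeled_uM * 100.0 / polymer_fraction_pct
    fraction = total / total_tubulin_uM * 100.0
    if fraction > 100.0:
        warnings.warn("labeled fraction exceeds 100%; inputs are inconsistent",
                      RuntimeWarning)
    return float(total), float(fraction)
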