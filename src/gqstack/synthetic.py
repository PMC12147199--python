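"""Synthetic data generators: the parameter-recovery backbone of the tests.

Every input the analysis pipeline consumes can be generated here from known
ground truth, so the full workflow is testable without any external
download: SAXS curves from a known (R, H, T*) with realistic noise,
stacked-fraction series from known (s, sigma), and junction-angle mixtures
with a planted weight.  Noise-free outputs are exactly the forward models;
all generators are bit-reproducible from their seed.

The default SAXS noise model is 2% relative Gaussian, typical of a
well-exposed synchrotron curve at mid q.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .analysis import AngleHistogram
from .geometry import DEFAULT_HEIGHT, DEFAULT_RADIUS, InteractionParams
from .helix_coil import HelixCoilParams, StackedFractionSeries, stacked_fraction
from .mc import MCSettings, simulate
from .saxs import DEFAULT_N_ORIENTATIONS, SAXSProfile, default_q_grid, ensemble_intensity

__all__ = ["SyntheticSpec", "gen_saxs_curve", "gen_fn_series", "gen_beta_mixture"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Ground truth plus noise model for a synthetic data set.

    ``ground_truth`` holds whatever parameters the target generator needs:
    (R, H, T_star, n_units) for SAXS curves, (s, sigma) for stacked-fraction
    series.  ``noise_model`` is 'gaussian-relative' (sigma = level * value)
    or 'gaussian-absolute' (sigma = level).
    """

    ground_truth: dict
    noise_model: str = "gaussian-relative"
    noise_level: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.noise_level < 0:
            raise ValueError("noise_level must be >= 0")
        if self.noise_model not in ("gaussian-relative", "gaussian-absolute"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")


def gen_saxs_curve(spec: SyntheticSpec, q_grid=None,
                   mc_settings: MCSettings | None = None,
                   n_orientations: int = DEFAULT_N_ORIENTATIONS) -> SAXSProfile:
    """Simulate a chain at the ground-truth (R, H, T*) and add noise.

    The returned ``sigma_I`` column is the applied noise scale, so a
    weighted fit of the generating model has reduced chi-square ~ 1.
    """
    gt = spec.ground_truth
    R = float(gt.get("R", DEFAULT_RADIUS))
    H = float(gt.get("H", DEFAULT_HEIGHT))
    T_star = float(gt.get("T_star", 0.190))
    n_units = int(gt.get("n_units", 2))
    params = InteractionParams(T_star=T_star,
                               delta=float(gt["delta"]) if "delta" in gt
                               else InteractionParams.__dataclass_fields__["delta"].default,
                               L_max=float(gt["L_max"]) if "L_max" in gt
                               else InteractionParams.__dataclass_fields__["L_max"].default)
    mc_settings = mc_settings or MCSettings(sweeps=50_000,
                                            equilibration_sweeps=10_000,
                                            snapshot_stride=25,
                                            seed=spec.seed % (2**31))
    q = default_q_grid() if q_grid is None else np.asarray(q_grid, dtype=float)
    ens = simulate(n_units, params, mc_settings, radius=R, height=H)
    clean = ensemble_intensity(ens, q, n_orientations)
    rng = np.random.default_rng(spec.seed)
    if spec.noise_model == "gaussian-relative":
        sigma = spec.noise_level * clean.I
    else:
        sigma = np.full_like(clean.I, spec.noise_level)
    if spec.noise_level == 0:
        return SAXSProfile(q, clean.I, None, label="synthetic (noise-free)")
    noisy = clean.I + sigma * rng.standard_normal(q.size)
    return SAXSProfile(q, noisy, sigma, label="synthetic")


def gen_fn_series(spec: SyntheticSpec, n_values=(2, 3, 4)) -> StackedFractionSeries:
    """Stacked fractions from ground-truth (s, sigma) plus Gaussian noise."""
    gt = spec.ground_truth
    params = HelixCoilParams(s=float(gt["s"]), sigma=float(gt["sigma"]))
    f = np.array([stacked_fraction(int(n), params) for n in n_values])
    rng = np.random.default_rng(spec.seed)
    if spec.noise_model == "gaussian-relative":
        sigma = spec.noise_level * f
    else:
        sigma = np.full_like(f, spec.noise_level)
    if spec.noise_level > 0:
        f = np.clip(f + sigma * rng.standard_normal(f.size), 1e-6, 1 - 1e-6)
        return StackedFractionSeries(tuple(n_values), tuple(f), tuple(sigma))
    return StackedFractionSeries(tuple(n_values), tuple(f))


def gen_beta_mixture(p_true: float, low: AngleHistogram, high: AngleHistogram,
                     n_samples: int, seed: int = 0) -> AngleHistogram:
    """Multinomial sample of junction angles from p*low + (1-p)*high.

    Draws ``n_samples`` angles from the mixture of the two basis densities
    (per-bin multinomial at the shared binning) and re-histograms them,
    emulating a finite simulation's sampling noise on the angle histogram.
    """
    if not 0.0 <= p_true <= 1.0:
        raise ValueError("p_true must lie in [0, 1]")
    if not low.same_binning(high):
        raise ValueError("basis histograms must share binning")
    widths = np.diff(low.bin_edges)
    probs = (p_true * low.density + (1.0 - p_true) * high.density) * widths
    probs = np.clip(probs, 0.0, None)
    probs /= probs.sum()
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_samples, probs)
    dens = counts / (n_samples * widths)
    return AngleHistogram(low.bin_edges.copy(), dens, n_samples)
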