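"""Canned validation studies: simulation batches and estimator calibration.

The three-color scenarios mix singlets, pairs and triplets at fixed
per-image counts on a 400×400 px grid (25 nm/px, 70 nm chain spacing,
FWHM 40 nm, low noise); the four-color scenario holds 100 curled
quadruplets per image at a tenfold background.  Batches rerun the full
pipeline — simulate, render, detect, match — and report signed errors of
detected relative abundances against the ground truth, each scaled by its
own channel-B particle count.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .correction import EfficiencyModel, build_theta_mu
from .detect import DetectionParams, detect_spots_multichannel
from .matching import match, structure_names
from .network import MatchConfig
from .simulate import (
    SimScenario,
    render_sted_image,
    simulate_chain_points,
    simulate_misdetection_counts,
)

THREE_COLOR_SCENARIOS = {
    1: {"A": 50, "B": 50, "C": 50},
    2: {"AB": 50, "BC": 50, "A": 50, "B": 50, "C": 50},
    3: {"ABC": 100, "AB": 50, "BC": 50, "A": 50, "B": 50, "C": 50},
}


def three_color_scenario(number: int, seed: int = 0) -> SimScenario:
    """Scenarios 1–3 of the three-color simulation study (low noise,
    stretched triplets)."""
    return SimScenario(k=3, structure_counts=dict(THREE_COLOR_SCENARIOS[number]),
                       geometry="near_linear", noise_scale=1.0, seed=seed)


def four_color_scenario(seed: int = 0) -> SimScenario:
    """100 quadruplets per image, arbitrarily curled chains, tenfold noise."""
    return SimScenario(k=4, structure_counts={"ABCD": 100}, geometry="curled",
                       noise_scale=10.0, seed=seed)


def signed_error_batch(sc: SimScenario, n_images: int, t: float,
                       modes: tuple[str, ...] = ("I", "II"), seed: int = 0,
                       scale_channel: int = 1,
                       detection: DetectionParams | None = None) -> pd.DataFrame:
    """Pipeline errors over an image batch.

    Per image and structure: (detected count / detected scale-channel
    count) − (true count / true scale-channel count).  Image i uses seed
    ``seed + i`` throughout simulation, rendering and noise.
    """
    names = structure_names(sc.k)
    rows = []
    for i in range(n_images):
        rng = np.random.default_rng(seed + i)
        gt = simulate_chain_points(sc, rng)
        images = render_sted_image(gt, sc, rng)
        clouds = detect_spots_multichannel(images, detection)
        true_counts = gt.counts()
        n_true = len(gt.channel_coords(scale_channel))
        n_det = clouds.counts[scale_channel]
        for mode in modes:
            _, w = match(clouds, MatchConfig(t=t, mode=mode))
            for s in names:
                rows.append({"image": i, "mode": mode, "structure": s,
                             "detected": w.w[s], "true": true_counts[s],
                             "error": w.w[s] / n_det - true_counts[s] / n_true})
    return pd.DataFrame(rows)


def error_summary(errors: pd.DataFrame) -> pd.DataFrame:
    """Median and interquartile range of the signed errors per mode and
    structure."""
    return (errors.groupby(["mode", "structure"])["error"]
            .agg(median="median",
                 iqr=lambda x: float(np.subtract(*np.percentile(x, [75, 25]))))
            .reset_index())


def quadruplet_recovery_batch(n_images: int, t: float = 5.0,
                              seed: int = 0) -> np.ndarray:
    """Detected quadruplets per image (Mode II) in the four-color scenario."""
    counts = []
    for i in range(n_images):
        sc = four_color_scenario(seed=seed + i)
        rng = np.random.default_rng(seed + i)
        gt = simulate_chain_points(sc, rng)
        images = render_sted_image(gt, sc, rng)
        clouds = detect_spots_multichannel(images)
        _, w = match(clouds, MatchConfig(t=t, mode="II"))
        counts.append(w.w["ABCD"])
    return np.asarray(counts)


def estimator_calibration(n, s, n_draws: int = 10_000, alpha: float = 0.1,
                          seed: int = 0) -> dict:
    """Monte-Carlo calibration of the corrected estimator.

    Draws observed abundance vectors from the multinomial misdetection
    model at true abundances ``n`` and efficiencies ``s``; reports the
    empirical coverage (%) of the 1−α confidence region and the mean of
    each corrected abundance.
    """
    from .correction import xi_statistic

    n = np.asarray(n, dtype=float)
    model = build_theta_mu(EfficiencyModel(s))
    rng = np.random.default_rng(seed)
    n_hats = np.empty((n_draws, n.size))
    inside = 0
    for i in range(n_draws):
        W = simulate_misdetection_counts(n, model, rng)
        n_hat = model.inverse_map @ W
        n_hats[i] = n_hat
        xi, rank = xi_statistic(n_hat, n, model)
        if rank > 0 and xi <= chi2.ppf(1 - alpha, rank):
            inside += 1
    return {
        "coverage_percent": 100.0 * inside / n_draws,
        "mean_n_hat": n_hats.mean(axis=0),
        "se_n_hat": n_hats.std(axis=0, ddof=1) / np.sqrt(n_draws),
        "structures": model.structures,
    }
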