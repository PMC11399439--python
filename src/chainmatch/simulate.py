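"""Synthetic STED-like point patterns and intensity images.

Ground-truth chain structures are placed on a 400×400 px grid
(25 nm/px): the anchor particle is uniform on the image, its chain
partners sit at normally distributed link lengths around the nominal
spacing of 70 nm = 2.8 px.  Two chain geometries are provided —
``near_linear`` (three-member chains stretched approximately straight,
partners on opposite sides of the middle particle) and ``curled``
(independent uniform link angles).  Coordinates are rounded to the pixel
grid.  Particles can be Bernoulli-thinned per channel to emulate
incomplete labeling, and rendered into intensity images by superimposing
isotropic Gaussian spots (FWHM 40 nm) with Poisson shot noise on a flat
background.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .correction import EfficiencyModel, SubstructureModel, build_theta_mu
from .matching import parse_structure, structure_names
from .points import CHANNEL_LETTERS, PointCloudSet, span_name


@dataclass
class SimScenario:
    """Configuration of one synthetic imaging experiment.

    ``structure_counts`` maps contiguous structure names (``"ABC"``,
    ``"AB"``, ``"A"``, ...) to ground-truth counts per image.  Distances
    are controlled by ``t_true_nm`` (nominal chain spacing, default 70 nm)
    with per-link SD ``link_sd_px``; the rendered point-spread function
    has the stated FWHM.  ``noise_scale`` multiplies the mean Poisson
    background (1 for the low-noise setting, 10 for the high-noise one).
    """

    k: int
    structure_counts: dict[str, int] = field(default_factory=dict)
    t_true_nm: float = 70.0
    geometry: str = "near_linear"
    image_size: int = 400
    pixel_size_nm: float = 25.0
    fwhm_nm: float = 40.0
    link_sd_px: float = 0.5
    amplitude: float = 100.0
    background: float = 1.0
    noise_scale: float = 1.0
    efficiencies: list[float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.geometry not in ("near_linear", "curled"):
            raise ValueError(f"unknown geometry {self.geometry!r}")
        for name, cnt in self.structure_counts.items():
            parse_structure(name, self.k)
            if cnt < 0:
                raise ValueError(f"negative count for structure {name}")

    @property
    def t_true_px(self) -> float:
        return self.t_true_nm / self.pixel_size_nm

    @property
    def psf_sigma_px(self) -> float:
        return self.fwhm_nm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / self.pixel_size_nm


@dataclass
class GroundTruth:
    """Simulated particles with their chain memberships.

    ``chains`` is a list of (structure name, {channel: (row, col)})
    records; ``clouds`` collects the per-channel integer pixel coordinates
    in the same order.
    """

    k: int
    image_size: int
    chains: list[tuple[str, dict[int, tuple[int, int]]]]

    def counts(self) -> dict[str, int]:
        out = {name: 0 for name in structure_names(self.k)}
        for name, _ in self.chains:
            out[name] += 1
        return out

    def channel_coords(self, j: int) -> np.ndarray:
        pts = [members[j] for _, members in self.chains if j in members]
        return np.array(pts, dtype=float).reshape(-1, 2)

    def point_cloud_set(self) -> PointCloudSet:
        return PointCloudSet([self.channel_coords(j) for j in range(self.k)],
                             unit="px")


def _draw_chain(span: tuple[int, int], sc: SimScenario, rng: np.random.Generator
                ) -> dict[int, np.ndarray]:
    """One chain over ``span``; clamp-reject: redrawn whole if any member
    rounds off the grid."""
    j0, j1 = span
    length = j1 - j0 + 1
    t = sc.t_true_px
    size = sc.image_size
    for _ in range(10_000):
        pts: dict[int, np.ndarray] = {}
        if length == 1:
            pts[j0] = rng.uniform(0, size, size=2)
        else:
            # anchor the second channel of the span (channel B for ABC...)
            anchor = j0 + 1
            b = rng.uniform(0, size, size=2)
            pts[anchor] = b
            alpha = rng.uniform(0, 2 * np.pi)
            d = rng.normal(t, sc.link_sd_px)
            pts[j0] = b + d * np.array([np.cos(alpha), np.sin(alpha)])
            prev = b
            for j in range(anchor + 1, j1 + 1):
                if sc.geometry == "near_linear" and length == 3 and j == anchor + 1:
                    # stretch: third member roughly opposite the first
                    beta = alpha + np.pi + rng.normal(0, 0.2)
                else:
                    beta = rng.uniform(0, 2 * np.pi)
                d = rng.normal(t, sc.link_sd_px)
                prev = prev + d * np.array([np.cos(beta), np.sin(beta)])
                pts[j] = prev
        rounded = {j: np.rint(p).astype(int) for j, p in pts.items()}
        if all((0 <= p).all() and (p <= size - 1).all() for p in rounded.values()):
            return {j: p for j, p in rounded.items()}
    raise RuntimeError("could not place chain inside the image")


def simulate_chain_points(sc: SimScenario,
                          rng: np.random.Generator | None = None) -> GroundTruth:
    """Generate the ground-truth point pattern of one image."""
    if rng is None:
        rng = np.random.default_rng(sc.seed)
    chains = []
    for name in structure_names(sc.k):  # fixed order for reproducibility
        count = sc.structure_counts.get(name, 0)
        span = parse_structure(name, sc.k)
        for _ in range(count):
            pts = _draw_chain(span, sc, rng)
            chains.append((name, {j: (int(p[0]), int(p[1])) for j, p in pts.items()}))
    return GroundTruth(k=sc.k, image_size=sc.image_size, chains=chains)


def apply_labeling_efficiency(gt: GroundTruth, s,
                              rng: np.random.Generator | int) -> GroundTruth:
    """Bernoulli-thin every particle independently per channel.

    Survivors keep their chain membership; a chain record whose members
    are all removed disappears.  The structure label stays the *true*
    structure — detection of what remains is the matcher's job.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    s = EfficiencyModel(s).s
    if s.size != gt.k:
        raise ValueError("need one efficiency per channel")
    chains = []
    for name, members in gt.chains:
        kept = {j: xy for j, xy in members.items() if rng.random() < s[j]}
        if kept:
            chains.append((name, kept))
    return GroundTruth(k=gt.k, image_size=gt.image_size, chains=chains)


def simulate_misdetection_counts(n, eff: EfficiencyModel | SubstructureModel,
                                 rng: np.random.Generator | int) -> np.ndarray:
    """Observed abundance vector W under the multinomial misdetection model.

    Draws, per true structure, a multinomial over its detection patterns
    and aggregates pattern runs into observable structure counts via Θ.
    Bypasses imaging entirely; used to validate the correction machinery.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    model = eff if isinstance(eff, SubstructureModel) else build_theta_mu(eff)
    n = np.asarray(n)
    if n.shape != (len(model.structures),):
        raise ValueError(f"need abundances for structures {model.structures}")
    if np.any(n < 0):
        raise ValueError("abundances must be nonnegative")
    pattern_counts = np.zeros(model.theta.shape[1])
    for ni, p in zip(n, model.p_vectors):
        pattern_counts += rng.multinomial(int(ni), p)
    return model.theta @ pattern_counts


def render_sted_image(gt: GroundTruth, sc: SimScenario,
                      rng: np.random.Generator | int | None = None,
                      shot_noise: bool = True) -> list[np.ndarray]:
    """Render one intensity image per channel.

    Every particle contributes an isotropic Gaussian spot of the
    scenario's PSF width with peak expected signal ``sc.amplitude``; pixel
    values are Poisson draws around signal + background·noise_scale
    (``shot_noise=False`` returns the expected intensities instead).
    """
    if rng is None:
        rng = np.random.default_rng(sc.seed)
    elif isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    sigma = sc.psf_sigma_px
    half = int(np.ceil(4 * sigma))
    win = np.arange(-half, half + 1)
    kernel = np.exp(-(win[:, None] ** 2 + win[None, :] ** 2) / (2 * sigma**2))
    size = sc.image_size
    images = []
    for j in range(gt.k):
        signal = np.zeros((size, size))
        for r, c in gt.channel_coords(j).astype(int):
            r0, r1 = max(0, r - half), min(size, r + half + 1)
            c0, c1 = max(0, c - half), min(size, c + half + 1)
            signal[r0:r1, c0:c1] += sc.amplitude * kernel[
                r0 - r + half : r1 - r + half, c0 - c + half : c1 - c + half
            ]
        expected = signal + sc.background * sc.noise_scale
        if shot_noise:
            images.append(rng.poisson(expected).astype(np.int64))
        else:
            images.append(expected)
    return images
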