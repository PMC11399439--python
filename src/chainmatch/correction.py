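"""Unbiased correction of chain abundances for incomplete labeling.

Each particle of channel i is detected independently with probability
s_i (its labeling efficiency).  A true chain therefore shows up as one of
2^L detection patterns (L = chain length); a pattern decomposes into its
maximal contiguous runs of detected particles, each run being counted as
the corresponding shorter structure (e.g. an A·C pattern of a true ABC
triplet is counted as one A and one C singlet).  Per true structure the
pattern counts are multinomial, which yields E[W] = Θ μ n for the observed
abundance vector W: μ stacks the per-structure pattern probabilities and Θ
credits the runs of each pattern to observable structures.  Inverting Θμ
gives an unbiased estimator n̂ = (Θμ)⁻¹ W of the true abundances, with an
asymptotically normal error whose covariance follows from the multinomial
CLT; the quadratic form Ξ built from it is asymptotically chi-squared and
defines joint confidence ellipsoids.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.stats import chi2

from .matching import AbundanceCurve, AbundanceVector, structure_names, structure_spans
from .points import CHANNEL_LETTERS

#: relative singular-value cutoff below which ΘΣΘᵀ is treated as singular
RANK_TOL = 1e-10


@dataclass
class EfficiencyModel:
    """Per-channel labeling efficiencies s_1..s_k, each in (0, 1]."""

    s: np.ndarray

    def __init__(self, s):
        s = np.atleast_1d(np.asarray(s, dtype=float))
        if np.any(s <= 0) or np.any(s > 1):
            raise ValueError(
                "labeling efficiencies must lie in (0, 1]; zero efficiency "
                "makes the observation model non-invertible"
            )
        self.s = s

    @property
    def k(self) -> int:
        return self.s.size


def detection_patterns(k: int) -> list[tuple[int, ...]]:
    """All subsets of the k channels as detection patterns.

    Ordered by decreasing size with contiguous subsets (by start channel)
    before non-contiguous ones within each size; the empty pattern
    (nothing detected) comes last.  For k=3 this is
    ABC, AB, BC, AC, A, B, C, ∅.
    """
    patterns = []
    for size in range(k, 0, -1):
        subsets = [tuple(c) for c in combinations(range(k), size)]
        contiguous = [p for p in subsets if p[-1] - p[0] == size - 1]
        contiguous.sort(key=lambda p: p[0])
        rest = [p for p in subsets if p[-1] - p[0] != size - 1]
        patterns.extend(contiguous + rest)
    patterns.append(())
    return patterns


def _runs(pattern: tuple[int, ...]) -> list[tuple[int, int]]:
    """Maximal contiguous runs of a detection pattern, as channel spans."""
    runs = []
    for c in pattern:
        if runs and c == runs[-1][1] + 1:
            runs[-1] = (runs[-1][0], c)
        else:
            runs.append((c, c))
    return runs


def substructure_probabilities(structure: str | tuple[int, int],
                               eff: EfficiencyModel) -> np.ndarray:
    """Probability of each detection pattern given one true structure.

    The returned vector is indexed by ``detection_patterns(k)`` and sums
    to 1: patterns outside the structure's span have probability zero, and
    within the span each channel is detected independently with its
    efficiency.
    """
    k = eff.k
    if isinstance(structure, str):
        from .matching import parse_structure

        structure = parse_structure(structure, k)
    j0, j1 = structure
    if not (0 <= j0 <= j1 < k):
        raise ValueError(f"invalid structure span {structure}")
    span = set(range(j0, j1 + 1))
    p = np.zeros(2**k)
    for idx, pattern in enumerate(detection_patterns(k)):
        if not set(pattern) <= span:
            continue
        prob = 1.0
        for c in span:
            prob *= eff.s[c] if c in pattern else 1.0 - eff.s[c]
        p[idx] = prob
    assert abs(p.sum() - 1.0) < 1e-12
    return p


@dataclass
class SubstructureModel:
    """The (Θ, μ) machinery of the multinomial misdetection model."""

    eff: EfficiencyModel
    structures: list[str] = field(init=False)
    patterns: list[tuple[int, ...]] = field(init=False)
    p_vectors: np.ndarray = field(init=False)  # (n_struct, 2^k)
    theta: np.ndarray = field(init=False)      # (n_struct, 2^k)
    mu: np.ndarray = field(init=False)         # (2^k, n_struct)
    theta_mu: np.ndarray = field(init=False)
    inverse_map: np.ndarray = field(init=False)  # (Θμ)⁻¹

    def __post_init__(self) -> None:
        k = self.eff.k
        self.structures = structure_names(k)
        spans = structure_spans(k)
        self.patterns = detection_patterns(k)
        self.p_vectors = np.stack(
            [substructure_probabilities(s, self.eff) for s in spans]
        )
        theta = np.zeros((len(spans), 2**k))
        span_index = {s: i for i, s in enumerate(spans)}
        for pi, pattern in enumerate(self.patterns):
            for run in _runs(pattern):
                theta[span_index[run], pi] += 1
        self.theta = theta
        self.mu = self.p_vectors.T
        self.theta_mu = theta @ self.mu
        self.inverse_map = np.linalg.inv(self.theta_mu)

    @property
    def k(self) -> int:
        return self.eff.k


def build_theta_mu(eff: EfficiencyModel) -> SubstructureModel:
    """Assemble Θ, μ and (Θμ)⁻¹ for the given efficiencies."""
    return SubstructureModel(eff=eff)


@dataclass
class AbundanceEstimate:
    """Corrected abundance estimate with its asymptotic dispersion."""

    model: SubstructureModel
    W: np.ndarray
    n_hat: np.ndarray       # may contain negative entries (raw, unbiased)
    sigma: np.ndarray       # Σ(n̂), plug-in multinomial covariance (2^k square)
    quad_form: np.ndarray   # Q = (Θμ)ᵀ (ΘΣΘᵀ)⁻¹ (Θμ)
    rank: int               # degrees of freedom of Ξ

    @property
    def structures(self) -> list[str]:
        return self.model.structures


def estimate_true_abundances(W, eff_or_model) -> AbundanceEstimate:
    """Unbiased estimator n̂ = (Θμ)⁻¹ W of the true structure abundances.

    ``W`` is an observed abundance vector (array in canonical structure
    order, or an :class:`AbundanceVector`).  Negative entries of n̂ are
    reported as-is — unbiasedness requires them; clip them only as an
    explicit post-process if a nonnegative point estimate is wanted.
    """
    model = (eff_or_model if isinstance(eff_or_model, SubstructureModel)
             else build_theta_mu(eff_or_model))
    if isinstance(W, AbundanceVector):
        W = W.as_array()
    W = np.asarray(W, dtype=float)
    if W.shape != (len(model.structures),):
        raise ValueError(
            f"observed abundances have shape {W.shape}, expected "
            f"({len(model.structures)},) for structures {model.structures}"
        )
    n_hat = model.inverse_map @ W
    sigma = covariance_sigma(n_hat, model)
    quad, rank = _quad_form(model, sigma)
    return AbundanceEstimate(model=model, W=W, n_hat=n_hat, sigma=sigma,
                             quad_form=quad, rank=rank)


def covariance_sigma(n_hat, model: SubstructureModel) -> np.ndarray:
    """Plug-in covariance Σ(n̂) = Σ_i n̂_i (diag(p_i) − p_i p_iᵀ).

    Negative n̂ entries are floored at zero inside the plug-in only, so Σ
    stays positive semidefinite.
    """
    n_plug = np.clip(np.asarray(n_hat, dtype=float), 0.0, None)
    sigma = np.zeros((model.p_vectors.shape[1],) * 2)
    for ni, p in zip(n_plug, model.p_vectors):
        sigma += ni * (np.diag(p) - np.outer(p, p))
    return sigma


def _quad_form(model: SubstructureModel, sigma: np.ndarray) -> tuple[np.ndarray, int]:
    """Q = (Θμ)ᵀ (ΘΣΘᵀ)⁻ (Θμ) and the degrees of freedom.

    Uses the pseudoinverse with r = rank(ΘΣΘᵀ) when the middle matrix is
    singular (singular values below RANK_TOL × the largest).
    """
    mid = model.theta @ sigma @ model.theta.T
    svals = np.linalg.svd(mid, compute_uv=False)
    n_obs = mid.shape[0]
    if svals.size and svals[0] > 0:
        rank = int(np.sum(svals > RANK_TOL * svals[0]))
    else:
        rank = 0
    if rank == n_obs:
        mid_inv = np.linalg.inv(mid)
    else:
        mid_inv = np.linalg.pinv(mid, rcond=RANK_TOL)
    return model.theta_mu.T @ mid_inv @ model.theta_mu, rank


def xi_statistic(n_hat, n0, model: SubstructureModel,
                 sigma: np.ndarray | None = None) -> tuple[float, int]:
    """Quadratic form Ξ comparing n̂ against hypothesized abundances n0.

    Asymptotically chi-squared with as many degrees of freedom as
    observable structures (6 for k=3), or rank(ΘΣΘᵀ) when that matrix is
    singular and its pseudoinverse is used.
    """
    n_hat = np.asarray(n_hat, dtype=float)
    n0 = np.asarray(n0, dtype=float)
    if sigma is None:
        sigma = covariance_sigma(n_hat, model)
    quad, rank = _quad_form(model, sigma)
    d = n_hat - n0
    return float(d @ quad @ d), rank


@dataclass
class ConfidenceRegion:
    """Joint chi-squared ellipsoid {n0 : Ξ(n̂, n0) ≤ χ²_{r,1−α}} with
    per-structure slice intervals (other abundances fixed at n̂)."""

    alpha: float
    critical: float
    center: np.ndarray
    quad_form: np.ndarray
    rank: int
    intervals: dict[str, tuple[float, float]]

    def contains(self, n0) -> bool:
        d = np.asarray(n0, dtype=float) - self.center
        return float(d @ self.quad_form @ d) <= self.critical


def confidence_region(est: AbundanceEstimate, alpha: float) -> ConfidenceRegion:
    """Asymptotic 1−α joint confidence ellipsoid around n̂.

    The per-structure interval is the slice of the ellipsoid along that
    coordinate while fixing all other estimated abundances, i.e.
    n̂_j ± sqrt(χ²_{r,1−α} / Q_jj).  With all efficiencies equal to 1 the
    model is deterministic (rank 0) and every interval collapses to the
    point estimate.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie strictly between 0 and 1")
    crit = float(chi2.ppf(1 - alpha, est.rank)) if est.rank > 0 else 0.0
    qdiag = np.diag(est.quad_form)
    intervals = {}
    for name, center, q in zip(est.structures, est.n_hat, qdiag):
        half = np.sqrt(crit / q) if q > 0 else 0.0
        intervals[name] = (float(center - half), float(center + half))
    return ConfidenceRegion(alpha=alpha, critical=crit, center=est.n_hat,
                            quad_form=est.quad_form, rank=est.rank,
                            intervals=intervals)


@dataclass
class CorrectedCurve:
    """Pointwise corrected abundance curve with confidence bands."""

    t_grid: np.ndarray
    structures: list[str]
    w: np.ndarray        # observed counts, (n_t, n_struct)
    n_hat: np.ndarray    # corrected estimates, (n_t, n_struct)
    lo: np.ndarray
    hi: np.ndarray
    alpha: float


def corrected_abundance_curve(curve: AbundanceCurve, eff: EfficiencyModel,
                              alpha: float = 0.1) -> CorrectedCurve:
    """Apply the correction and confidence slices at every threshold.

    Bands are pointwise in t (no multiplicity adjustment across the grid).
    """
    model = build_theta_mu(eff)
    names = model.structures
    w = np.stack([v.as_array() for v in curve.vectors])
    n_hat = np.empty_like(w)
    lo = np.empty_like(w)
    hi = np.empty_like(w)
    for i in range(w.shape[0]):
        est = estimate_true_abundances(w[i], model)
        region = confidence_region(est, alpha)
        n_hat[i] = est.n_hat
        lo[i] = [region.intervals[s][0] for s in names]
        hi[i] = [region.intervals[s][1] for s in names]
    return CorrectedCurve(t_grid=curve.t_grid, structures=names, w=w,
                          n_hat=n_hat, lo=lo, hi=hi, alpha=alpha)
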