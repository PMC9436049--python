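"""STAPLE consensus: simultaneous truth and performance level estimation.

Fuses R binary segmentations into a per-voxel posterior probability of the
true structure while estimating each rater's sensitivity p_j and specificity
q_j by expectation-maximization. The model assumes voxel-wise independent
rater decisions given the (hidden) truth T_i:

    E-step:  W_i = a_i / (a_i + b_i)
             a_i = P(T=1) · Π_j p_j^{D_ij} (1−p_j)^{1−D_ij}
             b_i = P(T=0) · Π_j (1−q_j)^{D_ij} q_j^{1−D_ij}
    M-step:  p_j = Σ_i W_i D_ij / Σ_i W_i
             q_j = Σ_i (1−W_i)(1−D_ij) / Σ_i (1−W_i)

Products are accumulated in log space for numerical stability. Estimates are
computed over an explicit analysis region: the scalar prior and every
specificity depend on how much background is included, so the region is part
of the result.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .masks_io import MaskGrid, ObserverSet
from .agreement import EmptyRegionError

__all__ = [
    "ProbabilityMap",
    "RaterPerformance",
    "staple_em",
    "auto_prior",
    "threshold_probability",
    "initialize_parameters",
]

EPS = 1e-6  # clamp bound for probabilities
DEFAULT_P0 = 0.99999
DEFAULT_Q0 = 0.99999


@dataclass(frozen=True)
class ProbabilityMap:
    """Posterior P(T_i = 1 | ratings) per voxel; zero outside the region."""

    values: np.ndarray
    region: np.ndarray
    prior: float

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if (v < 0).any() or (v > 1).any():
            raise ValueError("posterior probabilities must lie in [0, 1]")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "region", np.asarray(self.region, dtype=bool))


@dataclass(frozen=True)
class RaterPerformance:
    """Per-rater sensitivity/specificity with the EM convergence trace."""

    sensitivity: tuple[float, ...]
    specificity: tuple[float, ...]
    iterations: int
    converged: bool
    trace: tuple[float, ...]  # per-iteration max_j(|Δp_j| + |Δq_j|)
    log_likelihood: tuple[float, ...] = ()
    warnings: tuple[str, ...] = ()

    @property
    def mean_sensitivity(self) -> float:
        return float(np.mean(self.sensitivity))

    @property
    def sd_sensitivity(self) -> float:
        return float(np.std(self.sensitivity, ddof=1))

    @property
    def mean_specificity(self) -> float:
        return float(np.mean(self.specificity))

    @property
    def sd_specificity(self) -> float:
        return float(np.std(self.specificity, ddof=1))


def initialize_parameters(
    R: int, p0: float = DEFAULT_P0, q0: float = DEFAULT_Q0
) -> RaterPerformance:
    """Uniform starting point for EM; the near-1 default is the standard
    choice and expresses initial trust in every rater."""
    if not (0.0 < p0 < 1.0 and 0.0 < q0 < 1.0):
        raise ValueError(f"p0 and q0 must lie strictly in (0, 1), got {p0}, {q0}")
    return RaterPerformance(
        sensitivity=(p0,) * R,
        specificity=(q0,) * R,
        iterations=0,
        converged=False,
        trace=(),
    )


def auto_prior(obs: ObserverSet, region: np.ndarray) -> float:
    """Scalar prior P(T=1): mean over raters of the labeled fraction of the
    region, clamped to [EPS, 1−EPS]."""
    region = np.asarray(region, dtype=bool)
    n = int(region.sum())
    if n == 0:
        raise EmptyRegionError("analysis region is empty")
    fracs = [float(m.voxels[region].sum()) / n for m in obs.masks]
    return float(np.clip(np.mean(fracs), EPS, 1.0 - EPS))


def staple_em(
    obs: ObserverSet,
    region: np.ndarray,
    prior: float | None = None,
    tol: float = 1e-6,
    max_iter: int = 100,
    init: RaterPerformance | None = None,
) -> tuple[ProbabilityMap, RaterPerformance]:
    """Run STAPLE EM over ``region``; returns posterior map and rater
    performance.

    ``prior`` of None selects the auto prior (mean labeled fraction).
    Convergence when max_j(|Δp_j| + |Δq_j|) < tol. Degenerate raters (empty
    or region-filling masks) are handled by clamping their parameters into
    [EPS, 1−EPS] with a recorded warning rather than failing.
    """
    region = np.asarray(region, dtype=bool)
    if not region.any():
        raise EmptyRegionError("analysis region is empty")
    R = obs.n_observers
    if prior is None:
        prior = auto_prior(obs, region)
    if not 0.0 < prior < 1.0:
        raise ValueError(f"prior must lie strictly in (0, 1), got {prior}")

    D = np.stack([m.voxels[region] for m in obs.masks]).astype(np.float64).T  # (N, R)
    notes: list[str] = []
    frac = D.mean(axis=0)
    for j, (lbl, f) in enumerate(zip(obs.observer_labels, frac)):
        if f == 0.0 or f == 1.0:
            msg = (
                f"observer {lbl!r} rated the entire region "
                f"{'in' if f == 1.0 else 'out'}; parameters will be clamped"
            )
            notes.append(msg)
            warnings.warn(msg, stacklevel=2)

    start = init if init is not None else initialize_parameters(R)
    p = np.clip(np.asarray(start.sensitivity, dtype=np.float64), EPS, 1 - EPS)
    q = np.clip(np.asarray(start.specificity, dtype=np.float64), EPS, 1 - EPS)
    log_prior1, log_prior0 = np.log(prior), np.log1p(-prior)

    trace: list[float] = []
    loglik: list[float] = []
    converged = False
    W = np.full(D.shape[0], prior)
    it = 0
    for it in range(1, max_iter + 1):
        # E-step (log space)
        la = log_prior1 + D @ np.log(p) + (1.0 - D) @ np.log1p(-p)
        lb = log_prior0 + D @ np.log1p(-q) + (1.0 - D) @ np.log(q)
        W = expit(la - lb)
        loglik.append(float(np.logaddexp(la, lb).sum()))

        # M-step
        sw = W.sum()
        swc = (1.0 - W).sum()
        p_new = np.clip((D.T @ W) / sw, EPS, 1.0 - EPS) if sw > 0 else p
        q_new = (
            np.clip(((1.0 - D).T @ (1.0 - W)) / swc, EPS, 1.0 - EPS)
            if swc > 0
            else q
        )

        delta = float(np.max(np.abs(p_new - p) + np.abs(q_new - q)))
        trace.append(delta)
        p, q = p_new, q_new
        if delta < tol:
            converged = True
            break

    values = np.zeros(obs.grid.shape, dtype=np.float64)
    values[region] = W
    pmap = ProbabilityMap(values=values, region=region, prior=float(prior))
    perf = RaterPerformance(
        sensitivity=tuple(float(x) for x in p),
        specificity=tuple(float(x) for x in q),
        iterations=it,
        converged=converged,
        trace=tuple(trace),
        log_likelihood=tuple(loglik),
        warnings=tuple(notes),
    )
    return pmap, perf


def threshold_probability(
    pmap: ProbabilityMap, cl: float, grid: MaskGrid
) -> MaskGrid:
    """Consensus mask at confidence level ``cl``: voxels with W ≥ cl.

    The comparison is inclusive so cl = 1.0 still selects voxels whose
    posterior is exactly one.
    """
    if not 0.0 < cl <= 1.0:
        raise ValueError(f"cl must lie in (0, 1], got {cl}")
    if pmap.values.shape != grid.shape:
        raise ValueError("probability map shape does not match the template grid")
    return grid.with_voxels((pmap.values >= cl).astype(np.uint8))
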