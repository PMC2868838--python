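"""Self-consistent pair contact probability (SCPCP) extension of the ANM.

Each non-covalent contact (i, j) carries an occupancy probability p_ij that
scales its spring constant.  The probabilities are determined
self-consistently from the thermal fluctuations of the resulting harmonic
model: a weakly fluctuating pair stays formed (p → 1), a strongly
fluctuating pair opens (p → 0), and open pairs soften the network further.
This feedback makes the model weakly non-harmonic and lets a finite system
display a cooperative, temperature-driven loss of native contacts — a
finite-size analogue of the unfolding transition.  Covalent (peptide-bond)
springs are never weighted, so single chains stay connected.

Occupancy rule (isolated in :func:`occupancy_probability` so it can be
swapped): the pair's relative displacement u = Δr_i − Δr_j is Gaussian in
the harmonic model with isotropic per-axis variance σ²/3, where

    σ²_ij = [tr M_ii + tr M_jj − 2 tr M_ij] / β

is the thermal mean-square relative distance fluctuation (M is the
pseudo-inverse of the weighted Hessian, β the inverse temperature in units
of the spring constants).  The contact is counted as formed while |u| stays
inside a capture radius R, so

    p_ij = P(|u| ≤ R) = P(χ²₃ ≤ 3R²/σ²) ,

the chi-square(3) CDF — a Boltzmann-weighted occupancy that lies in (0, 1]
by construction, tends to 1 as β → ∞ and to 0 as β → 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import gammainc

from .enm_core import InteractionSpec, bfactors as _bfactors, solve
from .structure_io import CaStructure, ContactModel

__all__ = [
    "ScpcpState",
    "occupancy_probability",
    "scpcp_solve",
    "scpcp_bfactors",
    "beta_scan",
]

#: default capture radius (Å) within which a contact counts as formed
DEFAULT_CAPTURE_RADIUS = 1.0


@dataclass(frozen=True)
class ScpcpState:
    """Converged (or truncated) state of the self-consistent iteration."""

    contact_pairs: tuple[tuple[int, int], ...]
    contact_probs: np.ndarray
    covariance: np.ndarray
    bfactors: np.ndarray
    beta: float
    iterations: int
    converged: bool
    residual: float
    disconnected: bool = False

    def __post_init__(self) -> None:
        p = np.asarray(self.contact_probs, dtype=float)
        object.__setattr__(self, "contact_probs", p)
        if p.size and (p.min() < 0.0 or p.max() > 1.0):
            raise ValueError("contact probabilities must lie in [0, 1]")
        if self.residual < 0:
            raise ValueError("residual must be non-negative")

    @property
    def mean_contact_prob(self) -> float:
        return float(self.contact_probs.mean()) if self.contact_probs.size else 1.0


def occupancy_probability(msrf: np.ndarray, beta: float, capture_radius: float) -> np.ndarray:
    """Chi-square(3) occupancy: P(|u| ≤ R) for σ² = msrf / β.

    ``msrf`` is the per-contact trace-block mean-square relative fluctuation
    of the spring-unit covariance; dividing by β converts it to a thermal
    amplitude.  Values are in (0, 1] whenever msrf is finite and positive.
    """
    msrf = np.asarray(msrf, dtype=float)
    sigma_sq = np.maximum(msrf, 0.0) / beta
    out = np.ones_like(sigma_sq)
    pos = sigma_sq > 0
    # P(chi2_3 <= x) = gammainc(3/2, x/2), with x = 3 R^2 / sigma^2
    out[pos] = gammainc(1.5, 1.5 * capture_radius**2 / sigma_sq[pos])
    return out


def _pair_msrf(cov: np.ndarray, pairs: Sequence[tuple[int, int]]) -> np.ndarray:
    out = np.empty(len(pairs))
    for k, (i, j) in enumerate(pairs):
        bi, bj = slice(3 * i, 3 * i + 3), slice(3 * j, 3 * j + 3)
        out[k] = (np.trace(cov[bi, bi]) + np.trace(cov[bj, bj])
                  - 2.0 * np.trace(cov[bi, bj]))
    return out


def scpcp_solve(
    s: CaStructure,
    c: ContactModel,
    spec: InteractionSpec | None = None,
    beta: float = 1.0,
    tol: float = 1e-6,
    max_iter: int = 200,
    damping: float = 0.5,
    capture_radius: float = DEFAULT_CAPTURE_RADIUS,
    init_probs: Sequence[float] | None = None,
) -> ScpcpState:
    """Damped fixed-point iteration for the contact probabilities.

    Starting from all-formed contacts (or ``init_probs``), each sweep
    (a) rebuilds the Hessian with every non-covalent κ_ij scaled by its
    current probability, (b) recomputes the covariance by pseudo-inversion,
    (c) updates the probabilities through the occupancy rule and (d) mixes
    old and new with weight ``damping``.  Iteration stops when the maximum
    absolute probability change drops below ``tol`` or after ``max_iter``
    sweeps.  A model that disconnects (extra vanishing modes) is flagged in
    the returned state — that is the unfolding signal — not raised.
    """
    if spec is None:
        spec = InteractionSpec()
    if beta <= 0:
        raise ValueError("beta must be positive")
    if not (0 < damping <= 1):
        raise ValueError("damping must be in (0, 1]")
    pairs = c.sorted_contacts
    probs = (np.ones(len(pairs)) if init_probs is None
             else np.asarray(init_probs, dtype=float).copy())
    if probs.shape != (len(pairs),):
        raise ValueError("init_probs length must match the contact count")

    def solve_weighted(p: np.ndarray) -> tuple[np.ndarray, bool]:
        scale = dict(zip(pairs, p.tolist()))
        disconnected = False
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            sol = solve(s, c, spec, contact_scale=scale)
            disconnected = any("disconnected" in str(w.message) for w in caught)
        return sol.covariance, disconnected

    cov, disconnected = solve_weighted(probs)
    iterations = 0
    residual = np.inf
    converged = False
    for iterations in range(1, max_iter + 1):
        target = occupancy_probability(_pair_msrf(cov, pairs), beta, capture_radius)
        if not np.all(np.isfinite(target)):
            raise FloatingPointError("non-finite probability update")
        new = (1.0 - damping) * probs + damping * target
        residual = float(np.abs(new - probs).max()) if len(pairs) else 0.0
        probs = new
        cov, disconnected = solve_weighted(probs)
        if residual < tol:
            converged = True
            break
    if not pairs:
        converged, residual, iterations = True, 0.0, 0
    if max_iter == 0:
        iterations, residual = 0, np.inf

    return ScpcpState(
        contact_pairs=pairs,
        contact_probs=probs,
        covariance=cov,
        bfactors=_bfactors(cov),
        beta=float(beta),
        iterations=iterations,
        converged=converged,
        residual=float(residual) if np.isfinite(residual) else np.inf,
        disconnected=disconnected,
    )


def scpcp_bfactors(state: ScpcpState) -> np.ndarray:
    """Isotropic B-factors from the state's covariance (same rule as the ANM)."""
    return _bfactors(state.covariance)


def beta_scan(
    s: CaStructure,
    c: ContactModel,
    spec: InteractionSpec | None = None,
    betas: Sequence[float] = (),
    warm_start: bool = True,
    **kwargs,
) -> list[ScpcpState]:
    """Solve along an ordered β sequence, warm-starting from the previous state.

    The per-β mean contact probability serves as an order parameter: scanned
    from high to low β it drops from ≈1 toward 0 — the finite-size analogue
    of an unfolding transition.  With ``warm_start=False`` every point is an
    independent cold start from all-formed contacts.
    """
    if len(betas) == 0:
        raise ValueError("betas must be non-empty")
    states: list[ScpcpState] = []
    probs: Sequence[float] | None = None
    for b in betas:
        state = scpcp_solve(s, c, spec, beta=float(b), init_probs=probs, **kwargs)
        states.append(state)
        if warm_start:
            probs = state.contact_probs
    return states
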