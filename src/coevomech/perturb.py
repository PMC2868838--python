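"""In-silico perturbation experiments on the elastic network.

Two perturbations are supported: *breaking* a single non-covalent contact
(removing its spring) and *mutating* one sequence position (changing the
κ entries of every spring touching that bead while keeping coordinates).
The mechanical impact of a perturbation is scored by the Frobenius norm of
the difference between wild-type and perturbed covariance matrices,

    f = || M^wt − M^mut ||_F ,

optionally restricted to the 3×3 blocks of a residue subset.  The batch
protocol ranks non-covalent contacts by mutual information, breaks each
one in turn, and classifies each (MI, f) point by proximity to the four
corners of the min–max normalized plane (45°, 135°, 225°, 315°): pairs
near 45° combine strong coevolutionary signal with strong mechanical
impact and are candidates for functionally key interactions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from joblib import Parallel, delayed

from .alignment_info import MIResult
from .enm_core import InteractionSpec, solve
from .structure_io import CaStructure, ContactModel, build_contacts
from .enm_core import AA20

__all__ = [
    "PerturbationRecord",
    "QuadrantAnnotation",
    "break_contact",
    "mutate_sequence",
    "frobenius_norm",
    "run_break_protocol",
    "select_top_mi_contacts",
    "annotate_quadrants",
    "chain_relative_positions",
]


@dataclass(frozen=True)
class PerturbationRecord:
    """Outcome of one perturbation: what was changed and its FN score."""

    kind: str                              # "break" or "mutate"
    target: tuple                          # (i, j) or (position, new_residue)
    fnorm: float | None = None
    bfactors: np.ndarray | None = None


@dataclass(frozen=True)
class QuadrantAnnotation:
    """(MI, FN) point classified by its nearest normalized-plane corner."""

    pair: tuple[int, int]
    mi: float
    fnorm: float
    quadrant: int                          # 45, 135, 225 or 315


def break_contact(c: ContactModel, pair: tuple[int, int]) -> ContactModel:
    """Return a contact model with one non-covalent contact removed."""
    i, j = (pair[0], pair[1]) if pair[0] < pair[1] else (pair[1], pair[0])
    if (i, j) in c.covalent_pairs:
        raise ValueError(f"pair ({i}, {j}) is covalent; only non-covalent "
                         "contacts can be broken")
    if (i, j) not in c.noncovalent_contacts:
        raise ValueError(f"pair ({i}, {j}) is not a non-covalent contact")
    distances = {p: d for p, d in c.native_distances.items() if p != (i, j)}
    return replace(
        c,
        noncovalent_contacts=c.noncovalent_contacts - {(i, j)},
        native_distances=distances,
    )


def mutate_sequence(s: CaStructure, position: int, new_residue: str) -> CaStructure:
    """Substitute the residue identity at one position; coordinates unchanged."""
    if not (0 <= position < s.n_residues):
        raise IndexError(f"position {position} out of range (N={s.n_residues})")
    if new_residue not in AA20 and new_residue != "X":
        raise ValueError(f"invalid residue code {new_residue!r}")
    names = list(s.residue_names)
    names[position] = new_residue
    return replace(s, residue_names=tuple(names))


def frobenius_norm(
    m1: np.ndarray, m2: np.ndarray, subset: Sequence[int] | None = None
) -> float:
    """Frobenius norm of (m1 − m2), optionally over a residue subset.

    With a subset, only 3×3 blocks whose row *and* column residues are both
    in the subset contribute.
    """
    m1 = np.asarray(m1, dtype=float)
    m2 = np.asarray(m2, dtype=float)
    if m1.shape != m2.shape:
        raise ValueError(f"shape mismatch: {m1.shape} vs {m2.shape}")
    diff = m1 - m2
    if subset is not None:
        n = m1.shape[0] // 3
        subset = sorted(set(int(i) for i in subset))
        if subset and not (0 <= subset[0] and subset[-1] < n):
            raise IndexError(f"subset index out of range (N={n})")
        idx = np.concatenate([np.arange(3 * i, 3 * i + 3) for i in subset]) \
            if subset else np.array([], dtype=int)
        diff = diff[np.ix_(idx, idx)]
    return float(np.linalg.norm(diff))


def _single_break(
    s: CaStructure,
    spec: InteractionSpec,
    contacts: ContactModel,
    wt_cov: np.ndarray,
    pair: tuple[int, int],
    write_bfactors: bool,
    compute_fnorm: bool,
) -> PerturbationRecord:
    sol = solve(s, break_contact(contacts, pair), spec)
    return PerturbationRecord(
        kind="break",
        target=pair,
        fnorm=frobenius_norm(wt_cov, sol.covariance) if compute_fnorm else None,
        bfactors=sol.bfactors if write_bfactors else None,
    )


def run_break_protocol(
    s: CaStructure,
    spec: InteractionSpec,
    pairs: Sequence[tuple[int, int]],
    write_bfactors: bool = False,
    compute_fnorm: bool = True,
    workers: int = 1,
) -> list[PerturbationRecord]:
    """Break each listed contact in turn against a shared wild-type solution.

    The wild-type covariance is computed once; each pair is then broken
    independently and the network re-solved.  Results are a pure function of
    (structure, spec, pair list): output order follows the pair list and is
    identical for any worker count.
    """
    contacts = build_contacts(s, spec.cutoff_sq)
    ordered = [tuple(int(x) for x in p) for p in pairs]
    for p in ordered:  # fail fast before any heavy work
        if p not in contacts.noncovalent_contacts:
            raise ValueError(f"pair {p} is not a non-covalent contact of the "
                             "wild-type model")
    wt = solve(s, contacts, spec)
    jobs = (delayed(_single_break)(s, spec, contacts, wt.covariance, p,
                                   write_bfactors, compute_fnorm)
            for p in ordered)
    return list(Parallel(n_jobs=max(1, workers), prefer="threads")(jobs))


def chain_relative_positions(s: CaStructure) -> list[int]:
    """Map residue index → position within its own chain.

    This is the homo-multimer convention: every chain maps onto the same
    alignment columns of the monomer alignment.
    """
    positions: list[int] = []
    count: dict[str, int] = {}
    for c in s.chain_ids:
        positions.append(count.get(c, 0))
        count[c] = count.get(c, 0) + 1
    return positions


def select_top_mi_contacts(
    mi: MIResult,
    c: ContactModel,
    n: int,
    positions: Sequence[int] | None = None,
) -> list[tuple[int, int]]:
    """The n non-covalent contacts with the largest MI, descending.

    ``positions`` maps residue indices to alignment columns (identity by
    default — the monomer convention).  Ties are broken by (i, j)
    lexicographic order for determinism.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    contacts = c.sorted_contacts
    if n > len(contacts):
        warnings.warn(f"requested {n} contacts but only {len(contacts)} exist; "
                      "returning all", stacklevel=2)
        n = len(contacts)

    def column(r: int) -> int:
        return positions[r] if positions is not None else r

    L = mi.mi.shape[0]
    for i, j in contacts:
        if column(i) >= L or column(j) >= L:
            raise IndexError(f"contact ({i}, {j}) maps outside the {L}-column "
                             "MI matrix; supply a position map")
    ranked = sorted(contacts, key=lambda p: (-mi.mi[column(p[0]), column(p[1])], p))
    return ranked[:n]


def annotate_quadrants(
    records: Sequence[PerturbationRecord],
    mi: MIResult,
    positions: Sequence[int] | None = None,
) -> list[QuadrantAnnotation]:
    """Classify each (MI, FN) point by its nearest normalized-plane corner.

    MI and FN are min–max normalized to [0, 1] over the batch; each pair is
    assigned the nearest of (1,1)=45°, (0,1)=135°, (0,0)=225°, (1,0)=315°.
    A constant coordinate normalizes to 0.5.  Ties prefer the higher-MI,
    then higher-FN corner.
    """
    if len(records) < 2:
        raise ValueError("quadrant normalization needs at least 2 records")

    def column(r: int) -> int:
        return positions[r] if positions is not None else r

    mis = np.array([mi.mi[column(r.target[0]), column(r.target[1])] for r in records])
    fns = np.array([r.fnorm for r in records], dtype=float)
    if np.any(~np.isfinite(fns)):
        raise ValueError("all records need a finite Frobenius norm")

    def norm(v: np.ndarray) -> np.ndarray:
        span = v.max() - v.min()
        return np.full_like(v, 0.5) if span == 0 else (v - v.min()) / span

    x, y = norm(mis), norm(fns)
    # corners ordered so that ties resolve to higher MI, then higher FN
    corners = [(45, 1.0, 1.0), (315, 1.0, 0.0), (135, 0.0, 1.0), (225, 0.0, 0.0)]
    out: list[QuadrantAnnotation] = []
    for k, r in enumerate(records):
        dists = [((x[k] - cx) ** 2 + (y[k] - cy) ** 2, idx)
                 for idx, (_, cx, cy) in enumerate(corners)]
        best = min(dists)[1]
        out.append(QuadrantAnnotation(pair=tuple(r.target), mi=float(mis[k]),
                                      fnorm=float(fns[k]), quadrant=corners[best][0]))
    return out
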