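"""Synthetic structures and alignments with known, testable properties.

Structure topologies
--------------------
``chain``   collinear beads along x at fixed spacing — the simplest
            geometry for distance arithmetic.  Note that a *collinear*
            network is mechanically degenerate (transverse displacements
            cost nothing), so it is unsuitable for tests that expect the
            generic six rigid-body zero modes; use ``helix`` for those.
``helix``   Cα-like helix (radius 2.3 Å, rise 1.5 Å, 100° twist): a generic
            3D chain geometry with exactly six rigid-body modes.
``ring``    puckered (antiprism-like) ring: non-planar, and for even N all
            beads are symmetry-equivalent, so uniform-sequence B-factor
            profiles are constant.
``dimer``   two parallel helices with distinct chain labels, close enough
            for inter-chain contacts under the default 13 Å cutoff.
``globule`` self-avoiding random placement in a sphere (min separation
            3.5 Å), rejected until connected under the default cutoff.

Alignments are drawn with independent uniform columns except for listed
covarying pairs, whose symbols are coupled through a fixed bijection with a
tunable coupling strength; at coupling 1 the pair's population MI equals
the column entropy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .alignment_info import AMINO_ACIDS, Alignment
from .structure_io import CaStructure, write_pdb

__all__ = ["ToySpec", "make_structure", "make_alignment"]

TOPOLOGIES = ("chain", "helix", "ring", "dimer", "globule")


@dataclass(frozen=True)
class ToySpec:
    """Recipe for a synthetic Cα structure."""

    topology: str = "helix"
    n_residues: int = 10
    spacing: float = 3.8
    seed: int = 0
    sequence_model: str = "fixed"   # "fixed" (poly-Ala) or "random"

    def __post_init__(self) -> None:
        if self.topology not in TOPOLOGIES:
            raise ValueError(f"unknown topology {self.topology!r}; "
                             f"choose from {TOPOLOGIES}")
        if self.n_residues < 2:
            raise ValueError("n_residues must be >= 2")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if self.sequence_model not in ("fixed", "random"):
            raise ValueError("sequence_model must be 'fixed' or 'random'")


def _sequence(spec: ToySpec, n: int, rng: np.random.Generator) -> tuple[str, ...]:
    if spec.sequence_model == "fixed":
        return tuple("A" * n)
    return tuple(str(a) for a in rng.choice(list(AMINO_ACIDS), size=n))


def _chain_coords(n: int, spacing: float) -> np.ndarray:
    return np.column_stack([spacing * np.arange(n), np.zeros(n), np.zeros(n)])


def _helix_coords(n: int, spacing: float) -> np.ndarray:
    # Calpha-helix-like geometry; `spacing` rescales the canonical 3.8 Å step
    radius, rise, twist = 2.3, 1.5, math.radians(100.0)
    t = np.arange(n)
    coords = np.column_stack([radius * np.cos(twist * t),
                              radius * np.sin(twist * t),
                              rise * t])
    step = float(np.linalg.norm(coords[1] - coords[0]))
    return coords * (spacing / step)


def _ring_coords(n: int, spacing: float) -> np.ndarray:
    # puckered ring: alternating +/- z keeps it non-planar; neighbour
    # distance equals `spacing` exactly for even n
    h = 0.35 * spacing
    chord = math.sqrt(max(spacing**2 - 4 * h**2, 1e-6))
    radius = chord / (2.0 * math.sin(math.pi / n))
    theta = 2.0 * math.pi * np.arange(n) / n
    z = h * np.where(np.arange(n) % 2 == 0, 1.0, -1.0)
    return np.column_stack([radius * np.cos(theta), radius * np.sin(theta), z])


def _globule_coords(n: int, spacing: float, rng: np.random.Generator) -> np.ndarray:
    min_sep = 3.5
    radius = max(spacing * n ** (1.0 / 3.0), 2 * min_sep)
    for _ in range(200):
        pts: list[np.ndarray] = []
        attempts = 0
        while len(pts) < n and attempts < 20000:
            attempts += 1
            p = rng.uniform(-radius, radius, size=3)
            if p @ p > radius * radius:
                continue
            if all(np.linalg.norm(p - q) >= min_sep for q in pts):
                pts.append(p)
        if len(pts) < n:
            continue
        coords = np.array(pts)
        if _connected(coords, cutoff_sq=169.0):
            return coords
    raise RuntimeError("failed to place a connected globule; try another seed")


def _connected(coords: np.ndarray, cutoff_sq: float) -> bool:
    n = len(coords)
    diff = coords[:, None, :] - coords[None, :, :]
    adj = np.einsum("ijk,ijk->ij", diff, diff) <= cutoff_sq
    seen = {0}
    stack = [0]
    while stack:
        u = stack.pop()
        for v in np.nonzero(adj[u])[0]:
            if v not in seen:
                seen.add(int(v))
                stack.append(int(v))
    return len(seen) == n


def make_structure(spec: ToySpec) -> tuple[CaStructure, str]:
    """Deterministic synthetic structure + its PDB text.

    Coordinates are rounded to 3 decimals so the PDB round-trip through
    ``read_pdb`` is lossless.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_residues
    if spec.topology == "chain":
        coords = _chain_coords(n, spec.spacing)
        chains = ("A",) * n
    elif spec.topology == "helix":
        coords = _helix_coords(n, spec.spacing)
        chains = ("A",) * n
    elif spec.topology == "ring":
        coords = _ring_coords(n, spec.spacing)
        chains = ("A",) * n
    elif spec.topology == "dimer":
        # C2-symmetric homo-dimer: chain B is chain A rotated 180° about z
        # and offset along x (R t = -t, so the swap is an exact isometry)
        half = n // 2
        a = _helix_coords(half, spec.spacing)
        rot = np.diag([-1.0, -1.0, 1.0])
        b_full = _helix_coords(n - half, spec.spacing) @ rot.T + np.array([8.0, 0.0, 0.0])
        coords = np.vstack([a, b_full])
        chains = ("A",) * half + ("B",) * (n - half)
    else:  # globule
        coords = _globule_coords(n, spec.spacing, rng)
        chains = ("A",) * n
    coords = np.round(coords, 3)
    structure = CaStructure(
        coords=coords,
        chain_ids=chains,
        residue_names=_sequence(spec, n, rng),
        residue_numbers=tuple(range(1, n + 1)),
    )
    return structure, write_pdb(structure)


#: fixed bijection coupling a covarying partner column to its source column
_COUPLING_MAP = {a: b for a, b in zip(AMINO_ACIDS, AMINO_ACIDS[::-1])}


def make_alignment(
    L: int,
    S: int,
    covarying: Sequence[tuple[int, int]] = (),
    coupling: float = 1.0,
    seed: int = 0,
) -> Alignment:
    """Synthetic alignment: uniform independent columns + planted couplings.

    Each covarying pair (i, j) redraws column j so that with probability
    ``coupling`` the symbol is a fixed bijection of column i's symbol and
    otherwise independent uniform.  At coupling 1, column j is a
    deterministic function of column i and the pair's MI equals H_i; at
    coupling 0 the population MI is zero.
    """
    if L < 1 or S < 1:
        raise ValueError("L and S must be positive")
    if not (0.0 <= coupling <= 1.0):
        raise ValueError("coupling must lie in [0, 1]")
    for (i, j) in covarying:
        if not (0 <= i < L and 0 <= j < L) or i == j:
            raise ValueError(f"bad covarying pair ({i}, {j}) for L={L}")
    rng = np.random.default_rng(seed)
    aas = np.array(list(AMINO_ACIDS))
    cols = rng.integers(0, len(aas), size=(S, L))
    symbols = aas[cols]
    for (i, j) in covarying:
        coupled = rng.random(S) < coupling
        partner = np.array([_COUPLING_MAP[c] for c in symbols[:, i]])
        symbols[coupled, j] = partner[coupled]
    seqs = tuple("".join(row) for row in symbols)
    headers = tuple(f"seq{k}" for k in range(S))
    return Alignment(sequences=seqs, headers=headers)
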