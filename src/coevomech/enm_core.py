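"""Sequence-specific anisotropic network model (ANM).

Each residue is a bead at its Cα position.  Covalent neighbours (i, i+1)
are connected by springs of uniform strength ``alpha`` (default 82); every
non-covalent contact within the distance cutoff carries a sequence-specific
spring constant κ_ij taken from a 20×20 amino-acid contact-energy table
(Miyazawa–Jernigan magnitudes for intra-chain pairs, a Keskin-style table
for inter-chain pairs; optionally their elementwise average).

For a harmonic pair potential k/2 · (s_ij − s⁰_ij)² the Hessian of the
total potential at the native state is assembled from 3×3 blocks

    H[i, j] = −(k_ij / (s⁰_ij)²) · d dᵀ,      d = r_j − r_i  (native),

with diagonal blocks enforcing translation invariance.  Its eigensystem
gives the covariance matrix via the Moore–Penrose pseudo-inverse that skips
the six vanishing rigid-body modes,

    M = Σ_{k>6} λ_k⁻¹ v_k v_kᵀ,

and isotropic B-factors as (8π²/3) times the trace of each residue's
diagonal 3×3 covariance block.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np

from .structure_io import CaStructure, ContactModel

__all__ = [
    "AA20",
    "BFACTOR_PREFACTOR",
    "InteractionTable",
    "InteractionSpec",
    "ElasticSolution",
    "TableValidationError",
    "load_interaction_tables",
    "spring_constant",
    "build_hessian",
    "decompose",
    "covariance_from_modes",
    "bfactors",
    "solve",
]

AA20 = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AA20)}

#: isotropic conversion ⟨Δr²⟩ → B; relative profiles do not depend on it
BFACTOR_PREFACTOR = 8.0 * np.pi**2 / 3.0

_ZERO_MODE_RTOL = 1e-8


class TableValidationError(ValueError):
    """Raised for asymmetric, mis-labelled or non-positive interaction tables."""


@dataclass(frozen=True)
class InteractionTable:
    """Symmetric 20×20 positive pair-weight table keyed by amino acid.

    Nonstandard residues ('X') fall back to the table's column means, so the
    Hessian stays well-defined for beads of unknown chemistry.
    """

    values: np.ndarray
    name: str = "custom"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.shape != (20, 20):
            raise TableValidationError(f"expected a 20x20 table, got {v.shape}")
        if not np.allclose(v, v.T, rtol=0, atol=1e-12):
            raise TableValidationError("interaction table must be symmetric")
        if not np.all(v > 0):
            raise TableValidationError("interaction weights must be positive")

    def get(self, res_i: str, res_j: str) -> float:
        col_mean = self.values.mean(axis=0)
        ii = _AA_INDEX.get(res_i)
        jj = _AA_INDEX.get(res_j)
        if ii is None and jj is None:
            return float(col_mean.mean())
        if ii is None:
            return float(col_mean[jj])
        if jj is None:
            return float(col_mean[ii])
        return float(self.values[ii, jj])

    def averaged_with(self, other: "InteractionTable") -> "InteractionTable":
        return InteractionTable((self.values + other.values) / 2.0,
                                name=f"avg({self.name},{other.name})")


def _parse_table_text(text: str, name: str) -> InteractionTable:
    rows: dict[str, list[float]] = {}
    header: list[str] | None = None
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if header is None:
            header = parts
            continue
        rows[parts[0]] = [float(x) for x in parts[1:]]
    if header is None or sorted(header) != sorted(AA20) or sorted(rows) != sorted(AA20):
        raise TableValidationError(
            f"table {name!r} must carry the 20 amino-acid row/column labels")
    if any(len(v) != 20 for v in rows.values()):
        raise TableValidationError(f"table {name!r} has a row of wrong length")
    # reorder into canonical alphabetical order
    col = {a: k for k, a in enumerate(header)}
    values = np.array([[rows[a][col[b]] for b in AA20] for a in AA20])
    return InteractionTable(values, name=name)


def load_interaction_tables(name: str = "MJ", source: str | None = None) -> InteractionTable:
    """Load a bundled ('MJ', 'KE') or custom 20×20 interaction table.

    ``custom`` parses whitespace-delimited text with amino-acid row/column
    labels and validates symmetry and positivity.  The bundled KE file is a
    synthetic stand-in on the MJ scale (see its header); supply the
    published matrix via ``custom`` where exact KE values matter.
    """
    key = name.upper()
    if key == "CUSTOM":
        if source is None:
            raise TableValidationError("custom table requires source text")
        return _parse_table_text(source, "custom")
    files = {"MJ": "mj.txt", "KE": "ke_synthetic.txt"}
    if key not in files:
        raise TableValidationError(f"unknown table {name!r}; use MJ, KE or custom")
    text = resources.files("coevomech.data").joinpath(files[key]).read_text()
    return _parse_table_text(text, key)


@dataclass(frozen=True)
class InteractionSpec:
    """Spring-constant parameterization of the network.

    alpha : covalent (peptide-bond) spring weight, default 82
    cutoff_sq : squared contact cutoff in Å², default 169 (= 13²)
    intra / inter : tables for same-chain / cross-chain non-covalent pairs
    average_tables : use (intra+inter)/2 for both roles
    """

    alpha: float = 82.0
    cutoff_sq: float = 169.0
    intra: InteractionTable = field(default_factory=lambda: load_interaction_tables("MJ"))
    inter: InteractionTable = field(default_factory=lambda: load_interaction_tables("KE"))
    average_tables: bool = False

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.cutoff_sq <= 0:
            raise ValueError("cutoff_sq must be positive")

    def effective_tables(self) -> tuple[InteractionTable, InteractionTable]:
        if self.average_tables:
            avg = self.intra.averaged_with(self.inter)
            return avg, avg
        return self.intra, self.inter


def spring_constant(
    spec: InteractionSpec, res_i: str, res_j: str, same_chain: bool, covalent: bool
) -> float:
    """κ for one pair: alpha if covalent, else the intra-/inter-chain table."""
    if covalent:
        return spec.alpha
    intra, inter = spec.effective_tables()
    table = intra if same_chain else inter
    return table.get(res_i, res_j)


def build_hessian(
    s: CaStructure,
    c: ContactModel,
    spec: InteractionSpec,
    contact_scale: Mapping[tuple[int, int], float] | None = None,
) -> np.ndarray:
    """Assemble the 3N×3N ANM Hessian for structure + contact model.

    ``contact_scale`` optionally multiplies individual non-covalent spring
    constants (used by the self-consistent contact-probability solver).
    """
    n = s.n_residues
    if c.n_residues != n:
        raise ValueError("contact model does not match structure size")
    H = np.zeros((3 * n, 3 * n))

    def add_pair(i: int, j: int, k: float) -> None:
        d = s.coords[j] - s.coords[i]
        s0_sq = float(d @ d)
        if s0_sq < 1e-12:
            raise FloatingPointError(f"coincident beads in pair ({i}, {j})")
        block = (k / s0_sq) * np.outer(d, d)
        sl_i, sl_j = slice(3 * i, 3 * i + 3), slice(3 * j, 3 * j + 3)
        H[sl_i, sl_j] -= block
        H[sl_j, sl_i] -= block
        H[sl_i, sl_i] += block
        H[sl_j, sl_j] += block

    for (i, j) in c.covalent_pairs:
        add_pair(i, j, spec.alpha)
    for (i, j) in c.sorted_contacts:
        k = spring_constant(spec, s.residue_names[i], s.residue_names[j],
                            same_chain=s.chain_ids[i] == s.chain_ids[j],
                            covalent=False)
        if contact_scale is not None:
            k *= float(contact_scale[(i, j)])
        add_pair(i, j, k)
    return H


def decompose(h: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigenvalues (ascending) and orthonormal eigenvectors (columns).

    For the symmetric positive-semidefinite Hessian the symmetric
    eigendecomposition coincides with the SVD.
    """
    h = np.asarray(h, dtype=float)
    if h.ndim != 2 or h.shape[0] != h.shape[1]:
        raise ValueError("Hessian must be square")
    scale = max(np.abs(h).max(), 1.0)
    if np.abs(h - h.T).max() > 1e-8 * scale:
        raise ValueError("Hessian is not symmetric within tolerance")
    eigvals, eigvecs = np.linalg.eigh((h + h.T) / 2.0)
    return eigvals, eigvecs


def covariance_from_modes(
    eigenvalues: np.ndarray, eigenvectors: np.ndarray, n_skip: int = 6
) -> np.ndarray:
    """Moore–Penrose pseudo-inverse skipping the ``n_skip`` smallest modes.

    A connected model has exactly six vanishing eigenvalues (rigid-body
    translations and rotations); a sizable eigenvalue among the skipped six
    or extra near-zero modes beyond them trigger a warning (disconnected or
    pre-stressed network), not an error.
    """
    eigenvalues = np.asarray(eigenvalues, dtype=float)
    m = eigenvalues.shape[0]
    if m <= n_skip:
        raise ValueError(f"need more than {n_skip} modes, got {m}")
    if np.any(np.diff(eigenvalues) < -1e-9 * max(abs(eigenvalues[-1]), 1.0)):
        raise ValueError("eigenvalues must be ascending")
    lam_max = abs(eigenvalues[-1])
    tol = _ZERO_MODE_RTOL * lam_max
    if n_skip > 0 and abs(eigenvalues[n_skip - 1]) > tol:
        warnings.warn(
            f"skipped mode {n_skip - 1} has eigenvalue {eigenvalues[n_skip - 1]:.3g} "
            f"(> {tol:.3g}); model may be pre-stressed", stacklevel=2)
    if abs(eigenvalues[n_skip]) <= tol:
        warnings.warn(
            "near-zero eigenvalue beyond the skipped modes; model may be "
            "disconnected", stacklevel=2)
    lam = eigenvalues[n_skip:]
    V = eigenvectors[:, n_skip:]
    return (V / lam) @ V.T


def bfactors(m: np.ndarray) -> np.ndarray:
    """Isotropic B-factors: (8π²/3) · trace of each diagonal 3×3 block."""
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1] or m.shape[0] % 3:
        raise ValueError("covariance must be 3N x 3N")
    diag = np.diagonal(m)
    return BFACTOR_PREFACTOR * diag.reshape(-1, 3).sum(axis=1)


@dataclass(frozen=True)
class ElasticSolution:
    """Full ANM solution: Hessian, eigensystem, covariance and B-factors."""

    hessian: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    covariance: np.ndarray
    bfactors: np.ndarray

    def zero_mode_count(self) -> int:
        lam_max = abs(self.eigenvalues[-1])
        return int(np.sum(np.abs(self.eigenvalues) < _ZERO_MODE_RTOL * lam_max))


def solve(
    s: CaStructure,
    c: ContactModel,
    spec: InteractionSpec | None = None,
    n_skip: int = 6,
    contact_scale: Mapping[tuple[int, int], float] | None = None,
) -> ElasticSolution:
    """Convenience pipeline: Hessian → eigensystem → covariance → B-factors."""
    if spec is None:
        spec = InteractionSpec()
    H = build_hessian(s, c, spec, contact_scale=contact_scale)
    eigvals, eigvecs = decompose(H)
    M = covariance_from_modes(eigvals, eigvecs, n_skip=n_skip)
    return ElasticSolution(hessian=H, eigenvalues=eigvals, eigenvectors=eigvecs,
                           covariance=M, bfactors=bfactors(M))
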