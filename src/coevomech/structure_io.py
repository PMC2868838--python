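"""Cα-level structure model: PDB parsing, chain selection and contact maps.

A protein is reduced to one bead per residue, placed at the Cα position.
Contacts are split into *covalent* pairs — sequence neighbours (i, i+1)
within one chain, modelling the peptide bond — and *non-covalent* contacts:
every other residue pair whose native Cα–Cα squared distance lies within a
cutoff (default 169 Å², i.e. 13 Å).
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Data.IUPACData import protein_letters_3to1
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionException

__all__ = [
    "CaStructure",
    "ContactModel",
    "PdbParseError",
    "read_pdb",
    "select_chains",
    "build_contacts",
    "write_pdb",
    "NONSTANDARD",
]

#: marker used for residues outside the 20-letter amino-acid alphabet
NONSTANDARD = "X"

_THREE_TO_ONE = {k.upper(): v for k, v in protein_letters_3to1.items()}
_ONE_TO_THREE = {v: k.upper() for k, v in protein_letters_3to1.items()}


class PdbParseError(ValueError):
    """Raised when a PDB source cannot be turned into a Cα bead model."""


@dataclass(frozen=True)
class CaStructure:
    """One bead per residue at the Cα position.

    Attributes
    ----------
    coords : (N, 3) float array, Å
    chain_ids : length-N tuple of chain labels (contiguous runs)
    residue_names : length-N tuple of one-letter codes ('X' = nonstandard)
    residue_numbers : length-N tuple of author residue numbers
    """

    coords: np.ndarray
    chain_ids: tuple[str, ...]
    residue_names: tuple[str, ...]
    residue_numbers: tuple[int, ...]

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", coords)
        n = coords.shape[0]
        if n < 2:
            raise ValueError(f"need at least 2 residues, got {n}")
        if coords.shape != (n, 3) or not np.all(np.isfinite(coords)):
            raise ValueError("coords must be a finite (N, 3) array")
        if not (len(self.chain_ids) == len(self.residue_names) == len(self.residue_numbers) == n):
            raise ValueError("per-residue field lengths disagree")
        # chain labels must form contiguous runs
        seen: set[str] = set()
        prev = None
        for c in self.chain_ids:
            if c != prev:
                if c in seen:
                    raise ValueError(f"chain {c!r} appears in non-contiguous runs")
                seen.add(c)
                prev = c
        for r in self.residue_names:
            if r != NONSTANDARD and r not in _ONE_TO_THREE:
                raise ValueError(f"unknown residue code {r!r}")

    @property
    def n_residues(self) -> int:
        return self.coords.shape[0]

    @property
    def sequence(self) -> str:
        return "".join(self.residue_names)

    def chains(self) -> tuple[str, ...]:
        out: list[str] = []
        for c in self.chain_ids:
            if not out or out[-1] != c:
                out.append(c)
        return tuple(out)


@dataclass(frozen=True)
class ContactModel:
    """Covalent bead-chain bonds plus the non-covalent contact set C.

    Pairs are stored with i < j only. ``native_distances`` carries the native
    Cα–Cα distance (Å) for every stored pair of either kind.
    """

    covalent_pairs: tuple[tuple[int, int], ...]
    noncovalent_contacts: frozenset[tuple[int, int]]
    native_distances: Mapping[tuple[int, int], float]
    cutoff_sq: float
    n_residues: int

    def __post_init__(self) -> None:
        cov = set(self.covalent_pairs)
        if cov & set(self.noncovalent_contacts):
            raise ValueError("covalent and non-covalent pair sets overlap")
        for i, j in list(cov) + list(self.noncovalent_contacts):
            if not (0 <= i < j < self.n_residues):
                raise ValueError(f"pair ({i}, {j}) out of range or unordered")

    @property
    def sorted_contacts(self) -> tuple[tuple[int, int], ...]:
        """Non-covalent contacts in deterministic (i, j) lexicographic order."""
        return tuple(sorted(self.noncovalent_contacts))


def _residue_one_letter(resname: str) -> str:
    return _THREE_TO_ONE.get(resname.strip().upper(), NONSTANDARD)


def read_pdb(source: str | Path | io.TextIOBase) -> CaStructure:
    """Parse PDB text (path, string or handle) into a Cα bead model.

    One bead per residue in file order; residues lacking a Cα atom are
    skipped.  Hetero residues that do carry a Cα (e.g. MSE) are included and
    mapped to the nonstandard marker unless they are standard amino acids.
    """
    if isinstance(source, io.TextIOBase):
        handle: io.TextIOBase = source
    else:
        text_or_path = str(source)
        if "\n" in text_or_path or text_or_path.lstrip().startswith(("ATOM", "HETATM", "HEADER", "REMARK", "MODEL", "TITLE", "CRYST")):
            handle = io.StringIO(text_or_path)
        else:
            handle = open(text_or_path)
    parser = PDBParser(PERMISSIVE=False, QUIET=True)
    try:
        structure = parser.get_structure("pdb", handle)
    except (PDBConstructionException, ValueError) as exc:
        raise PdbParseError(f"malformed PDB record: {exc}") from exc
    finally:
        if handle is not source:
            handle.close()

    try:
        model = next(structure.get_models())
    except StopIteration:
        raise PdbParseError("no model found in PDB source") from None

    coords: list[np.ndarray] = []
    chain_ids: list[str] = []
    names: list[str] = []
    numbers: list[int] = []
    for chain in model:
        for residue in chain:
            if "CA" not in residue:
                continue
            atom = residue["CA"]
            if atom.is_disordered():
                # altLoc duplicates: keep Biopython's selected conformer
                atom = atom.selected_child
            coords.append(np.asarray(atom.coord, dtype=float))
            chain_ids.append(chain.id)
            names.append(_residue_one_letter(residue.get_resname()))
            numbers.append(int(residue.id[1]))
    if len(coords) < 2:
        raise PdbParseError(
            f"found {len(coords)} Calpha ATOM record(s); need at least 2 residues")
    # PDB coordinates carry exactly 3 decimals; re-round after the float32
    # parse so fixture round-trips are lossless
    return CaStructure(
        coords=np.round(np.vstack(coords).astype(float), 3),
        chain_ids=tuple(chain_ids),
        residue_names=tuple(names),
        residue_numbers=tuple(numbers),
    )


def select_chains(s: CaStructure, chains: Sequence[str] | str) -> CaStructure:
    """Subset a structure to the given chain labels, preserving file order.

    Indices are re-based to 0..N'-1. Unknown labels raise ``LookupError``.
    """
    if isinstance(chains, str):
        chains = [chains]
    present = set(s.chain_ids)
    for label in chains:
        if label not in present:
            raise LookupError(f"chain {label!r} not present (have {sorted(present)})")
    wanted = set(chains)
    mask = np.array([c in wanted for c in s.chain_ids])
    return CaStructure(
        coords=s.coords[mask],
        chain_ids=tuple(c for c, m in zip(s.chain_ids, mask) if m),
        residue_names=tuple(r for r, m in zip(s.residue_names, mask) if m),
        residue_numbers=tuple(r for r, m in zip(s.residue_numbers, mask) if m),
    )


def build_contacts(s: CaStructure, cutoff_sq: float = 169.0) -> ContactModel:
    """Build the contact model: covalent (i, i+1) bonds plus the set C.

    Covalency is defined by adjacency within a chain, regardless of residue
    numbering gaps (the bead-chain abstraction). Any other pair with squared
    native distance ≤ ``cutoff_sq`` is a non-covalent contact.
    """
    if cutoff_sq <= 0:
        raise ValueError("cutoff_sq must be positive")
    n = s.n_residues
    diff = s.coords[:, None, :] - s.coords[None, :, :]
    dist_sq = np.einsum("ijk,ijk->ij", diff, diff)

    covalent: list[tuple[int, int]] = []
    distances: dict[tuple[int, int], float] = {}
    for i in range(n - 1):
        if s.chain_ids[i] == s.chain_ids[i + 1]:
            covalent.append((i, i + 1))
            distances[(i, i + 1)] = math.sqrt(dist_sq[i, i + 1])
    cov_set = set(covalent)

    noncov: set[tuple[int, int]] = set()
    ii, jj = np.nonzero(np.triu(dist_sq <= cutoff_sq, k=1))
    for i, j in zip(ii.tolist(), jj.tolist()):
        if (i, j) in cov_set:
            continue
        noncov.add((i, j))
        distances[(i, j)] = math.sqrt(dist_sq[i, j])

    return ContactModel(
        covalent_pairs=tuple(covalent),
        noncovalent_contacts=frozenset(noncov),
        native_distances=distances,
        cutoff_sq=float(cutoff_sq),
        n_residues=n,
    )


def write_pdb(s: CaStructure, bfactors: Sequence[float] | None = None) -> str:
    """Serialize the bead model as PDB text (one CA ATOM per residue).

    Coordinates are written at 3-decimal precision (the PDB fixed-column
    format), occupancy 1.00, with one TER per chain. ``bfactors`` fills the
    temperature-factor column (default 0.00).
    """
    if bfactors is not None and len(bfactors) != s.n_residues:
        raise ValueError("bfactors length must equal the residue count")
    lines: list[str] = []
    serial = 1
    for i in range(s.n_residues):
        resname = _ONE_TO_THREE.get(s.residue_names[i], "UNK")
        b = 0.0 if bfactors is None else float(bfactors[i])
        x, y, z = s.coords[i]
        lines.append(
            f"ATOM  {serial:5d}  CA  {resname:>3s} {s.chain_ids[i]:1s}"
            f"{s.residue_numbers[i]:4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
            f"{1.00:6.2f}{b:6.2f}           C  "
        )
        serial += 1
        last_in_chain = i == s.n_residues - 1 or s.chain_ids[i + 1] != s.chain_ids[i]
        if last_in_chain:
            lines.append(
                f"TER   {serial:5d}      {resname:>3s} {s.chain_ids[i]:1s}"
                f"{s.residue_numbers[i]:4d}"
            )
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"
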