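"""Information-theoretic analysis of multiple sequence alignments.

Columns of an alignment are treated as categorical random variables over a
22-symbol alphabet: the 20 standard amino acids, the gap character '-', and
'X' for nonstandard residues.  Marginal and joint probabilities are the
relative symbol frequencies within columns, from which per-column Shannon
entropies, joint entropies and the pairwise mutual information matrix

    MI_ij = sum_{x,y} p_ij(x, y) log2[ p_ij(x, y) / (p_i(x) p_j(y)) ]

are computed (bits).  High MI between two columns is the classic sequence
signature of coevolution.  Because the plug-in MI estimator is biased upward
at finite sample size, a shuffle null model (independent within-column
permutations, which preserve marginals but destroy inter-column
correlations) estimates the statistical relevance of observed values.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import SeqIO

__all__ = [
    "ALPHABET",
    "Alignment",
    "MIResult",
    "AlignmentFormatError",
    "read_alignment",
    "column_frequencies",
    "entropy",
    "mutual_information",
    "mi_null_model",
]

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
NONSTANDARD = "X"
#: 22-symbol alphabet: 20 amino acids + gap + nonstandard marker
ALPHABET = AMINO_ACIDS + GAP + NONSTANDARD
_CODE = {c: k for k, c in enumerate(ALPHABET)}
_K = len(ALPHABET)


class AlignmentFormatError(ValueError):
    """Raised for empty or ragged FASTA alignments."""


@dataclass(frozen=True)
class Alignment:
    """S aligned sequences of equal length L over the 22-symbol alphabet."""

    sequences: tuple[str, ...]
    headers: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.sequences) < 1:
            raise AlignmentFormatError("alignment needs at least one sequence")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise AlignmentFormatError(f"ragged sequence lengths: {sorted(lengths)}")
        for s in self.sequences:
            bad = set(s) - set(ALPHABET)
            if bad:
                raise ValueError(f"illegal characters {sorted(bad)}; sanitize on read")
        if self.headers and len(self.headers) != len(self.sequences):
            raise ValueError("headers/sequences length mismatch")

    @property
    def n_sequences(self) -> int:
        return len(self.sequences)

    @property
    def n_columns(self) -> int:
        return len(self.sequences[0])

    def encoded(self) -> np.ndarray:
        """Integer codes, shape (S, L), over the 22-symbol alphabet."""
        return np.array([[_CODE[c] for c in s] for s in self.sequences], dtype=np.int64)


@dataclass(frozen=True)
class MIResult:
    """Entropies (bits), joint entropies and the symmetric MI matrix."""

    entropy: np.ndarray        # (L,)
    joint_entropy: np.ndarray  # (L, L), diagonal = entropy
    mi: np.ndarray             # (L, L), diagonal = entropy
    null_mean: np.ndarray | None = None
    null_sd: np.ndarray | None = None


def _sanitize(seq: str) -> str:
    out = []
    dirty = False
    for c in seq.upper():
        if c == ".":
            c = GAP
        if c not in _CODE:
            dirty = True
            c = NONSTANDARD
        out.append(c)
    if dirty:
        logger.warning("nonstandard characters mapped to %r", NONSTANDARD)
    return "".join(out)


def read_alignment(source: str | Path | io.TextIOBase) -> Alignment:
    """Read a FASTA alignment; characters outside the alphabet map to 'X'."""
    if isinstance(source, io.TextIOBase):
        handle: io.TextIOBase = source
    else:
        text = str(source)
        handle = io.StringIO(text) if text.lstrip().startswith(">") else open(text)
    try:
        records = list(SeqIO.parse(handle, "fasta"))
    finally:
        if handle is not source:
            handle.close()
    if not records:
        raise AlignmentFormatError("no FASTA records found")
    seqs = tuple(_sanitize(str(r.seq)) for r in records)
    if len({len(s) for s in seqs}) != 1:
        raise AlignmentFormatError(
            f"ragged alignment: lengths {sorted({len(s) for s in seqs})}")
    return Alignment(sequences=seqs, headers=tuple(r.id for r in records))


def column_frequencies(
    a: Alignment, i: int, j: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Marginal and joint relative-frequency tables for columns i and j.

    Returns ``(p_i, p_j, p_ij)`` with shapes (22,), (22,), (22, 22); the
    marginals are exactly the joint's row and column sums.
    """
    codes = a.encoded()
    L = a.n_columns
    if not (0 <= i < L and 0 <= j < L):
        raise IndexError(f"column index out of range (L={L})")
    joint = np.bincount(codes[:, i] * _K + codes[:, j], minlength=_K * _K)
    p_ij = joint.reshape(_K, _K) / a.n_sequences
    return p_ij.sum(axis=1), p_ij.sum(axis=0), p_ij


def _entropy_from_probs(p: np.ndarray) -> float:
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def _column_entropies(codes: np.ndarray) -> np.ndarray:
    S, L = codes.shape
    out = np.empty(L)
    for i in range(L):
        out[i] = _entropy_from_probs(np.bincount(codes[:, i], minlength=_K) / S)
    return out


def entropy(a: Alignment) -> np.ndarray:
    """Per-column Shannon entropy H_i = -sum_x p_i(x) log2 p_i(x), in bits."""
    return _column_entropies(a.encoded())


def _mi_matrices(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(H, H_joint, MI) for an encoded alignment; MI from the direct double sum."""
    S, L = codes.shape
    H = _column_entropies(codes)
    Hj = np.zeros((L, L))
    MI = np.zeros((L, L))
    marg = [np.bincount(codes[:, i], minlength=_K) / S for i in range(L)]
    for i in range(L):
        Hj[i, i] = H[i]
        MI[i, i] = H[i]
        for j in range(i + 1, L):
            joint = np.bincount(codes[:, i] * _K + codes[:, j],
                                minlength=_K * _K).reshape(_K, _K) / S
            Hj[i, j] = Hj[j, i] = _entropy_from_probs(joint.ravel())
            mask = joint > 0
            prod = np.outer(marg[i], marg[j])
            mi = float((joint[mask] * np.log2(joint[mask] / prod[mask])).sum())
            MI[i, j] = MI[j, i] = mi
    return H, Hj, MI


def mutual_information(a: Alignment) -> MIResult:
    """Pairwise MI matrix plus per-column and joint entropies (bits).

    The identity MI = H_i + H_j - H_ij holds elementwise up to roundoff; the
    diagonal carries MI_ii = H_i.
    """
    H, Hj, MI = _mi_matrices(a.encoded())
    return MIResult(entropy=H, joint_entropy=Hj, mi=MI)


def mi_null_model(
    a: Alignment, n_shuffles: int = 100, seed: int | None = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Shuffle null model for MI: independent within-column permutations.

    Each shuffle permutes every column independently, preserving all
    marginal frequencies while destroying inter-column correlation; the
    returned matrices are the per-pair mean and standard deviation
    (population, ddof=0) of MI over ``n_shuffles`` replicates.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    rng = np.random.default_rng(seed)
    codes = a.encoded()
    S, L = codes.shape
    acc = np.zeros((L, L))
    acc2 = np.zeros((L, L))
    shuffled = codes.copy()
    for _ in range(n_shuffles):
        for col in range(L):
            shuffled[:, col] = codes[rng.permutation(S), col]
        _, _, mi = _mi_matrices(shuffled)
        acc += mi
        acc2 += mi * mi
    mean = acc / n_shuffles
    var = np.maximum(acc2 / n_shuffles - mean * mean, 0.0)
    return mean, np.sqrt(var)
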