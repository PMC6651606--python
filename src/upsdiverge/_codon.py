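"""Shared codon-level machinery: the standard genetic code over the 61 sense
codons and a Goldman–Yang-style (GY94) substitution model.

The rate matrix allows single-nucleotide changes only, with rate

    q_ij  ∝  pi_j * kappa^[transition] * omega^[nonsynonymous]

and is scaled so that one unit of branch length t equals one expected
substitution per codon at the given parameters.  Because the model is
time-reversible, P(t) = exp(Qt) is computed through a symmetric
eigendecomposition, which is both faster and more stable than a generic
matrix exponential and lets one factorization serve many values of t.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.Data import CodonTable

_STANDARD = CodonTable.unambiguous_dna_by_id[1]

STOP_CODONS: frozenset[str] = frozenset(_STANDARD.stop_codons)
SENSE_CODONS: tuple[str, ...] = tuple(
    sorted(c for c in _STANDARD.forward_table if set(c) <= set("ACGT"))
)
N_CODONS = len(SENSE_CODONS)  # 61
CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(SENSE_CODONS)}
AMINO_ACID: tuple[str, ...] = tuple(_STANDARD.forward_table[c] for c in SENSE_CODONS)

_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}


def _is_transition(a: str, b: str) -> bool:
    return (a in _PURINES and b in _PURINES) or (a in _PYRIMIDINES and b in _PYRIMIDINES)


def _structure() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    single = np.zeros((N_CODONS, N_CODONS), dtype=bool)
    transition = np.zeros_like(single)
    synonymous = np.zeros_like(single)
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diffs = [(a, b) for a, b in zip(ci, cj) if a != b]
            if len(diffs) != 1:
                continue
            single[i, j] = True
            a, b = diffs[0]
            transition[i, j] = _is_transition(a, b)
            synonymous[i, j] = AMINO_ACID[i] == AMINO_ACID[j]
    return single, transition, synonymous


SINGLE_NT, TRANSITION, SYNONYMOUS = _structure()

UNIFORM_FREQS = np.full(N_CODONS, 1.0 / N_CODONS)


def codon_frequencies_f3x4(seqs: list[str]) -> np.ndarray:
    """Empirical positional-nucleotide (F3x4) codon frequencies.

    Products of per-codon-position nucleotide frequencies, renormalized over
    the 61 sense codons.
    """
    counts = np.full((3, 4), 1e-8)
    order = "ACGT"
    for seq in seqs:
        for k in range(0, len(seq) - 2, 3):
            for pos in range(3):
                nt = seq[k + pos]
                if nt in order:
                    counts[pos, order.index(nt)] += 1.0
    counts /= counts.sum(axis=1, keepdims=True)
    freqs = np.array(
        [
            counts[0, order.index(c[0])]
            * counts[1, order.index(c[1])]
            * counts[2, order.index(c[2])]
            for c in SENSE_CODONS
        ]
    )
    return freqs / freqs.sum()


def rate_matrix(kappa: float, omega: float, freqs: np.ndarray | None = None) -> np.ndarray:
    """Scaled GY94 instantaneous rate matrix over the 61 sense codons."""
    if kappa <= 0 or omega <= 0:
        raise ValueError("kappa and omega must be positive")
    pi = UNIFORM_FREQS if freqs is None else np.asarray(freqs, dtype=float)
    if pi.shape != (N_CODONS,) or np.any(pi < 0) or not np.isclose(pi.sum(), 1.0):
        raise ValueError("codon frequencies must be a length-61 probability vector")
    Q = np.where(SINGLE_NT, pi[None, :], 0.0)
    Q = Q * np.where(TRANSITION, kappa, 1.0)
    Q = Q * np.where(SYNONYMOUS | ~SINGLE_NT, 1.0, omega)
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    scale = -np.dot(pi, np.diag(Q))
    if scale <= 0:
        raise ValueError("degenerate rate matrix")
    return Q / scale


def flux_fractions(kappa: float, omega: float, freqs: np.ndarray | None = None) -> tuple[float, float]:
    """(synonymous, nonsynonymous) fractions of the expected substitution flux."""
    pi = UNIFORM_FREQS if freqs is None else np.asarray(freqs, dtype=float)
    base = np.where(SINGLE_NT, pi[None, :], 0.0) * np.where(TRANSITION, kappa, 1.0)
    syn = float(pi @ np.where(SYNONYMOUS & SINGLE_NT, base, 0.0).sum(axis=1))
    non = omega * float(pi @ np.where(~SYNONYMOUS & SINGLE_NT, base, 0.0).sum(axis=1))
    total = syn + non
    return syn / total, non / total


@dataclass(frozen=True)
class CodonModel:
    """Eigendecomposition of a reversible scaled GY94 matrix.

    Reusable across branch lengths: P(t) costs one 61x61 reconstruction.
    """

    kappa: float
    omega: float
    pi: np.ndarray
    eigvals: np.ndarray
    eigvecs: np.ndarray  # of the symmetrized matrix
    sqrt_pi: np.ndarray

    @classmethod
    def build(cls, kappa: float, omega: float, freqs: np.ndarray | None = None) -> "CodonModel":
        pi = UNIFORM_FREQS if freqs is None else np.asarray(freqs, dtype=float)
        Q = rate_matrix(kappa, omega, pi)
        sqrt_pi = np.sqrt(pi)
        # reversibility: D^1/2 Q D^-1/2 is symmetric
        S = (sqrt_pi[:, None] * Q) / sqrt_pi[None, :]
        S = 0.5 * (S + S.T)
        vals, vecs = np.linalg.eigh(S)
        return cls(kappa=kappa, omega=omega, pi=pi, eigvals=vals, eigvecs=vecs, sqrt_pi=sqrt_pi)

    def transition_probs(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt); rows sum to 1."""
        if t < 0:
            raise ValueError("branch length must be non-negative")
        expd = np.exp(self.eigvals * t)
        inner = (self.eigvecs * expd[None, :]) @ self.eigvecs.T
        P = inner / self.sqrt_pi[:, None] * self.sqrt_pi[None, :]
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P


def encode_codons(seq: str) -> np.ndarray:
    """Indices into SENSE_CODONS for a gapless CDS; stops raise."""
    seq = seq.upper()
    if len(seq) % 3:
        raise ValueError("sequence length is not a multiple of 3")
    idx = np.empty(len(seq) // 3, dtype=np.int64)
    for k in range(0, len(seq), 3):
        codon = seq[k : k + 3]
        if codon in STOP_CODONS:
            raise ValueError(f"internal stop codon {codon} at codon {k // 3}")
        try:
            idx[k // 3] = CODON_INDEX[codon]
        except KeyError:
            raise ValueError(f"unrecognized codon {codon!r} at codon {k // 3}") from None
    return idx


def decode_codons(idx: np.ndarray) -> str:
    return "".join(SENSE_CODONS[i] for i in idx)
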