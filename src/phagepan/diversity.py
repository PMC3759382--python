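"""Positional diversity statistics: frequency matrices, Shannon entropy,
information content, and Kullback-Leibler divergence between rounds.

All logarithms are base 2, so entropies and divergences are in bits.  For a
position with symbol frequencies p_i over an alphabet of k symbols,

    S_obs = -sum_i p_i log2 p_i            (Shannon entropy)
    IC    = S_max - S_obs,  S_max = log2 k (sequence-logo letter height)
    D(P||Q) = sum_i P_i log2(P_i / Q_i)    (divergence of round 3 from round 0)

Frequencies can be count-weighted (abundance) or unique-weighted (each
distinct sequence counts once — the convention for repertoire logos where
peptides are not weighted by their frequency).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import entropy as _scipy_entropy
from scipy.special import rel_entr

from .scheme import DegenerateCodonScheme

DNA_ALPHABET = "ACGT"
PROTEIN_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

_ALPHABETS = {"dna": DNA_ALPHABET, "protein": PROTEIN_ALPHABET}

FREQ_TOL = 1e-9


@dataclass
class PositionFrequencyMatrix:
    """Per-position symbol frequencies for fixed-length sequences.

    ``freqs`` has shape (length, k); each row sums to 1.  ``n_sequences`` is
    the total weight behind the matrix (reads for count weighting, distinct
    sequences for unique weighting) and is what pseudocount smoothing is
    scaled against.
    """

    alphabet: str
    freqs: np.ndarray
    n_sequences: float
    weighting: str = "counts"

    def __post_init__(self) -> None:
        if self.alphabet not in _ALPHABETS:
            raise ValueError(f"alphabet must be 'dna' or 'protein', got {self.alphabet!r}")
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.freqs.ndim != 2 or self.freqs.shape[1] != len(self.symbols):
            raise ValueError("freqs must be (length, k) for the alphabet")
        if (self.freqs < -FREQ_TOL).any():
            raise ValueError("frequencies must be non-negative")
        sums = self.freqs.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("each position's frequencies must sum to 1")

    @property
    def symbols(self) -> str:
        return _ALPHABETS[self.alphabet]

    @property
    def k(self) -> int:
        return len(self.symbols)

    @property
    def length(self) -> int:
        return self.freqs.shape[0]

    def to_frame(self) -> pd.DataFrame:
        """Frequencies as a DataFrame with 1-based ``position`` column."""
        frame = pd.DataFrame(self.freqs, columns=list(self.symbols))
        frame.insert(0, "position", np.arange(1, self.length + 1))
        return frame


@dataclass
class EntropyProfile:
    """Per-position observed entropy and information content, in bits."""

    s_obs: np.ndarray
    ic: np.ndarray
    s_max: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": np.arange(1, len(self.s_obs) + 1),
                "entropy_bits": self.s_obs,
                "information_content_bits": self.ic,
            }
        )


@dataclass
class KLProfile:
    """Per-position divergence (bits) of an observed round from a reference."""

    d: np.ndarray
    pseudocount: float
    weighting: str

    @property
    def total(self) -> float:
        return float(self.d.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": np.arange(1, len(self.d) + 1),
                "kl_bits": self.d,
            }
        )


def build_pfm(
    sequences: Sequence[str] | Mapping[str, int],
    alphabet: str = "protein",
    weighting: str = "counts",
) -> PositionFrequencyMatrix:
    """Build a position frequency matrix from same-length sequences.

    ``sequences`` is either a list (each weight 1) or a sequence->count
    mapping.  ``weighting='unique'`` ignores the counts and gives each
    distinct sequence weight 1.
    """
    if alphabet not in _ALPHABETS:
        raise ValueError(f"alphabet must be 'dna' or 'protein', got {alphabet!r}")
    if weighting not in ("counts", "unique"):
        raise ValueError(f"weighting must be 'counts' or 'unique', got {weighting!r}")
    if isinstance(sequences, Mapping):
        seqs = list(sequences.keys())
        weights = [1.0] * len(seqs) if weighting == "unique" else [
            float(sequences[s]) for s in seqs
        ]
    else:
        seqs = list(dict.fromkeys(sequences)) if weighting == "unique" else list(
            sequences
        )
        weights = [1.0] * len(seqs)
    if not seqs:
        raise ValueError("cannot build a frequency matrix from no sequences")
    length = len(seqs[0])
    symbols = _ALPHABETS[alphabet]
    lut = np.full(128, -1, dtype=np.int8)
    for i, s in enumerate(symbols):
        lut[ord(s)] = i

    matrix = np.zeros((length, len(symbols)), dtype=float)
    for seq, w in zip(seqs, weights):
        if len(seq) != length:
            raise ValueError(
                f"length mismatch: expected {length}, got {len(seq)} in {seq!r}"
            )
        idx = lut[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
        if (idx < 0).any():
            bad = seq[int(np.argmax(idx < 0))]
            raise ValueError(f"symbol {bad!r} not in {alphabet} alphabet")
        matrix[np.arange(length), idx] += w
    total = matrix[0].sum()
    return PositionFrequencyMatrix(
        alphabet=alphabet,
        freqs=matrix / total,
        n_sequences=total,
        weighting=weighting,
    )


def shannon_entropy(freqs: Sequence[float] | np.ndarray, base: float = 2.0) -> float:
    """Entropy of one distribution; zero-probability terms contribute 0."""
    p = np.asarray(freqs, dtype=float)
    if (p < 0).any():
        raise ValueError("frequencies must be non-negative")
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValueError(f"frequencies sum to {p.sum()}, not 1")
    return float(_scipy_entropy(p, base=base))


def kl_divergence(
    p: Sequence[float] | np.ndarray,
    q: Sequence[float] | np.ndarray,
    base: float = 2.0,
) -> float:
    """D(P||Q) for two plain distributions; shared zeros contribute 0.

    Raises when Q is zero somewhere P is not (the divergence is infinite
    there; smooth with a pseudocount instead).
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("distributions must have the same length")
    for name, dist in (("P", p), ("Q", q)):
        if (dist < 0).any():
            raise ValueError(f"{name} has negative frequencies")
        if abs(dist.sum() - 1.0) > 1e-6:
            raise ValueError(f"{name} sums to {dist.sum()}, not 1")
    if ((q == 0) & (p > 0)).any():
        raise ValueError(
            "reference distribution is zero on the observed support; use a "
            "positive pseudocount to smooth it"
        )
    return float(rel_entr(p, q).sum() / np.log(base))


def information_content(pfm: PositionFrequencyMatrix) -> EntropyProfile:
    """Per-position information content IC = log2(k) - S_obs.

    No small-sample correction is applied: with 1e4-1e5 unique sequences
    per pool the correction is negligible for k <= 20.
    """
    s_obs = _scipy_entropy(pfm.freqs, base=2, axis=1)
    s_max = float(np.log2(pfm.k))
    return EntropyProfile(s_obs=s_obs, ic=s_max - s_obs, s_max=s_max)


def theoretical_pfm(scheme: DegenerateCodonScheme) -> PositionFrequencyMatrix:
    """Nucleotide PFM of the degenerate scheme itself: per position, the
    uniform distribution over the template character's IUPAC expansion."""
    length = scheme.hcdr3_nt_length
    matrix = np.zeros((length, 4))
    for pos in range(length):
        choices = scheme.position_choices(pos)
        for base in choices:
            matrix[pos, DNA_ALPHABET.index(base)] = 1.0 / len(choices)
    return PositionFrequencyMatrix(
        alphabet="dna", freqs=matrix, n_sequences=1.0, weighting="unique"
    )


def _smooth(pfm: PositionFrequencyMatrix, pseudocount: float) -> np.ndarray:
    if pseudocount == 0:
        return pfm.freqs
    counts = pfm.freqs * pfm.n_sequences + pseudocount
    return counts / counts.sum(axis=1, keepdims=True)


def kl_profile(
    pfm_p: PositionFrequencyMatrix,
    pfm_q: PositionFrequencyMatrix,
    pseudocount: float = 0.5,
) -> KLProfile:
    """Per-position KL divergence D(P||Q) in bits, P the later round.

    Both matrices are smoothed by adding ``pseudocount`` to each symbol's
    effective count and renormalizing, which keeps the reference
    distribution strictly positive.  With ``pseudocount=0`` a zero in the
    smoothed reference is an error: pass a positive pseudocount.
    """
    if pfm_p.alphabet != pfm_q.alphabet or pfm_p.length != pfm_q.length:
        raise ValueError("matrices must share alphabet and length")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    p = _smooth(pfm_p, pseudocount)
    q = _smooth(pfm_q, pseudocount)
    if ((q == 0) & (p > 0)).any():
        raise ValueError(
            "reference distribution is zero where the observed round is "
            "not; use a positive pseudocount to smooth it"
        )
    d = rel_entr(p, q).sum(axis=1) / np.log(2.0)
    return KLProfile(d=d, pseudocount=pseudocount, weighting=pfm_p.weighting)
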