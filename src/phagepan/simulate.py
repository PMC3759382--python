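"""Synthetic degenerate HCDR3 libraries, panning rounds, and read emission.

This module builds ground-truth pools from the (NNS)6 KBG HTK GMT scheme,
applies multiplicative per-peptide selection with optional multinomial
bottlenecks (the phage titer between panning rounds), and emits barcoded
paired-end reads with a two-level quality model, so every downstream stage
of the pipeline can be checked against an exact oracle.

The emitted amplicon is ``barcode + upstream flank + HCDR3 + downstream
flank`` (77 bp with the default fixtures).  R1 carries the amplicon strand,
R2 its reverse complement, each with independent substitution errors; an
erroneous base is flagged with the low quality score so extraction failures
are attributable.  All randomness is drawn from one seeded generator in
per-read order, so increasing the depth appends reads without perturbing
earlier ones.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .codons import revcomp, translate_hcdr3
from .fastq import PHRED_OFFSET, ReadPair, write_tsv
from .scheme import DegenerateCodonScheme, SchemeError

FREQ_TOL = 1e-9


def _as_rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class PoolComposition:
    """Ground-truth relative frequencies of 27-nt variants in one pool."""

    pool_id: str
    variants: dict[str, float]

    def __post_init__(self) -> None:
        if not self.variants:
            raise ValueError(f"pool {self.pool_id!r} has no variants")
        if any(f <= 0 for f in self.variants.values()):
            raise ValueError("variant frequencies must be strictly positive")
        total = sum(self.variants.values())
        if abs(total - 1.0) > FREQ_TOL:
            raise ValueError(
                f"frequencies of pool {self.pool_id!r} sum to {total}, not 1"
            )

    def peptide_frequencies(self) -> dict[str, float]:
        """Frequencies folded over synonymous encodings (amber TAG -> Q)."""
        out: dict[str, float] = {}
        for nt, f in self.variants.items():
            pep = translate_hcdr3(nt)
            if pep is None:
                raise ValueError(f"pool contains untranslatable variant {nt}")
            out[pep] = out.get(pep, 0.0) + f
        return out


@dataclass(frozen=True)
class FitnessLandscape:
    """Positive per-peptide selection weights; unlisted peptides get the default."""

    fitness: Mapping[str, float] = field(default_factory=dict)
    default_fitness: float = 1.0

    def __post_init__(self) -> None:
        if self.default_fitness <= 0 or any(w <= 0 for w in self.fitness.values()):
            raise ValueError("all fitness weights must be > 0")

    def weight(self, peptide: str) -> float:
        return self.fitness.get(peptide, self.default_fitness)


@dataclass(frozen=True)
class ReadEmissionConfig:
    """Sequencing-run parameters for one pool."""

    barcode: str
    depth: int
    error_rate: float = 0.0
    quality_high: int = 40
    quality_low: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.barcode) < 4 or any(c not in "ACGT" for c in self.barcode):
            raise ValueError("barcode must be an ACGT string of length >= 4")
        if not 0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must be in [0, 0.5)")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if not 0 <= self.quality_low <= self.quality_high <= 41:
            raise ValueError("require 0 <= quality_low <= quality_high <= 41")


# -- library construction -------------------------------------------------


def sample_hcdr3(
    scheme: DegenerateCodonScheme, rng_seed: int | np.random.Generator
) -> str:
    """Draw one 27-nt HCDR3 uniformly from the scheme's IUPAC expansion."""
    rng = _as_rng(rng_seed)
    return "".join(
        scheme.position_choices(i)[rng.integers(len(scheme.position_choices(i)))]
        for i in range(scheme.hcdr3_nt_length)
    )


def _sample_encodings(
    scheme: DegenerateCodonScheme,
    peptide: str,
    n_encodings: int,
    rng: np.random.Generator,
) -> list[str]:
    """Distinct nucleotide encodings of a peptide under the scheme.

    Enumerates when the synonym space is small, otherwise rejection-samples.
    """
    options = scheme.peptide_codon_options(peptide)
    total = 1
    for codons in options:
        total *= len(codons)
    n = min(n_encodings, total)
    if total <= 4 * n:
        import itertools

        all_encodings = sorted(
            "".join(codons) for codons in itertools.product(*options)
        )
        idx = rng.choice(total, size=n, replace=False)
        return [all_encodings[i] for i in sorted(idx)]
    chosen: set[str] = set()
    while len(chosen) < n:
        chosen.add("".join(codons[rng.integers(len(codons))] for codons in options))
    return sorted(chosen)


def make_initial_pool(
    scheme: DegenerateCodonScheme,
    n_variants: int,
    dominant_peptides: Sequence[str] = (),
    dominant_mass: float = 0.0,
    rng_seed: int | np.random.Generator = 0,
    encodings_per_dominant: int = 4,
    pool_id: str = "round0",
) -> PoolComposition:
    """Build a round-0 pool: a uniform random background plus dominant clones.

    ``n_variants`` distinct random 27-nt variants share ``1 - dominant_mass``
    uniformly; each dominant peptide is represented by several synonymous
    nucleotide encodings, and all dominant encodings together share
    ``dominant_mass`` equally — mirroring libraries where a couple of
    peptides, each coded by many synonymous sequences, carry most of the
    mass before selection.
    """
    if not 0 <= dominant_mass < 1:
        raise ValueError("dominant_mass must be in [0, 1)")
    if dominant_peptides and dominant_mass == 0:
        raise ValueError("dominant peptides given but dominant_mass is 0")
    if dominant_mass > 0 and not dominant_peptides:
        raise ValueError("dominant_mass > 0 requires dominant peptides")
    if n_variants < 1:
        raise ValueError("n_variants must be >= 1")
    rng = _as_rng(rng_seed)

    dominant_encodings: list[str] = []
    for pep in dominant_peptides:
        dominant_encodings.extend(
            _sample_encodings(scheme, pep, encodings_per_dominant, rng)
        )

    taken = set(dominant_encodings)
    background: list[str] = []
    while len(background) < n_variants:
        v = sample_hcdr3(scheme, rng)
        if v not in taken:
            taken.add(v)
            background.append(v)

    variants: dict[str, float] = {}
    bg_freq = (1.0 - dominant_mass) / n_variants
    for v in background:
        variants[v] = bg_freq
    if dominant_encodings:
        dom_freq = dominant_mass / len(dominant_encodings)
        for v in dominant_encodings:
            variants[v] = dom_freq
    return PoolComposition(pool_id=pool_id, variants=variants)


def apply_selection(
    pool: PoolComposition,
    landscape: FitnessLandscape,
    rounds: int = 3,
    bottleneck: int | None = None,
    rng_seed: int | np.random.Generator = 0,
    pool_id: str | None = None,
) -> PoolComposition:
    """Apply ``rounds`` panning rounds of multiplicative selection.

    Each round maps f(v) to f(v) * w(peptide(v)) and renormalizes; when
    ``bottleneck`` is given, frequencies are then replaced by proportions of
    a multinomial draw of that many phage (zero-count variants drop out),
    modelling the finite titer carried between rounds.
    """
    if rounds < 0:
        raise ValueError("rounds must be >= 0")
    if bottleneck is not None and bottleneck < 1:
        raise ValueError("bottleneck must be >= 1")
    rng = _as_rng(rng_seed)

    seqs = list(pool.variants)
    freqs = np.array([pool.variants[v] for v in seqs], dtype=float)
    weights = np.array(
        [landscape.weight(translate_hcdr3(v) or "") for v in seqs], dtype=float
    )
    for _ in range(rounds):
        freqs = freqs * weights
        freqs /= freqs.sum()
        if bottleneck is not None:
            counts = rng.multinomial(bottleneck, freqs)
            keep = counts > 0
            seqs = [s for s, k in zip(seqs, keep) if k]
            weights = weights[keep]
            freqs = counts[keep].astype(float) / bottleneck
    new_id = pool_id if pool_id is not None else pool.pool_id
    return PoolComposition(pool_id=new_id, variants=dict(zip(seqs, freqs)))


def sample_counts(
    pool: PoolComposition, depth: int, rng_seed: int | np.random.Generator
) -> dict[str, int]:
    """Multinomial read counts at ``depth`` from a pool (zero counts dropped).

    Equivalent to emitting ``depth`` error-free reads and counting them, at
    a fraction of the cost; used for counting-level simulations.
    """
    rng = _as_rng(rng_seed)
    seqs = list(pool.variants)
    probs = np.array([pool.variants[v] for v in seqs])
    counts = rng.multinomial(depth, probs / probs.sum())
    return {s: int(c) for s, c in zip(seqs, counts) if c > 0}


# -- read emission --------------------------------------------------------

_OTHER_BASES = {
    base: np.frombuffer("".join(b for b in "ACGT" if b != base).encode(), np.uint8)
    for base in "ACGT"
}


def emit_reads(
    pool: PoolComposition,
    config: ReadEmissionConfig,
    scheme: DegenerateCodonScheme,
) -> list[ReadPair]:
    """Emit ``config.depth`` barcoded paired-end reads from a pool.

    Read IDs are ``pool:index:variant`` so the ground-truth variant of every
    pair is recoverable for auditing.
    """
    rng = _as_rng(config.seed)
    seqs = list(pool.variants)
    probs = np.array([pool.variants[v] for v in seqs])
    cum = np.cumsum(probs / probs.sum())

    amplicons = [
        config.barcode + scheme.flank_upstream + v + scheme.flank_downstream
        for v in seqs
    ]
    rcs = [revcomp(a) for a in amplicons]
    length = len(amplicons[0])
    hi = chr(PHRED_OFFSET + config.quality_high)
    lo = chr(PHRED_OFFSET + config.quality_low)
    clean_qual = hi * length
    err = config.error_rate

    def mutate(seq: str) -> tuple[str, str]:
        n_err = int(rng.binomial(length, err))
        if n_err == 0:
            return seq, clean_qual
        pos = rng.choice(length, size=n_err, replace=False)
        b = bytearray(seq.encode())
        q = bytearray(clean_qual.encode())
        for p in pos:
            choices = _OTHER_BASES[chr(b[p])]
            b[p] = choices[rng.integers(3)]
            q[p] = PHRED_OFFSET + config.quality_low
        return b.decode(), q.decode()

    pairs: list[ReadPair] = []
    for i in range(config.depth):
        k = int(np.searchsorted(cum, rng.random(), side="right"))
        k = min(k, len(seqs) - 1)
        read_id = f"{pool.pool_id}:{i}:{seqs[k]}"
        if err == 0:
            pairs.append(
                ReadPair(read_id, amplicons[k], clean_qual, rcs[k], clean_qual)
            )
        else:
            r1, q1 = mutate(amplicons[k])
            r2, q2 = mutate(rcs[k])
            pairs.append(ReadPair(read_id, r1, q1, r2, q2))
    return pairs


def true_variant_of(read_id: str) -> str:
    """Ground-truth variant encoded in an emitted read ID."""
    return read_id.rsplit(":", 1)[1]


def emitted_counts(pairs: Iterable[ReadPair]) -> Counter:
    """Per-variant counts of the reads actually emitted (from read IDs)."""
    return Counter(true_variant_of(p.read_id) for p in pairs)


def inject_anchor_failures(
    pairs: Sequence[ReadPair],
    fraction: float,
    scheme: DegenerateCodonScheme,
    barcode_length: int,
    rng_seed: int | np.random.Generator = 0,
) -> tuple[list[ReadPair], int]:
    """Destroy the upstream anchor in a random fraction of R1 reads.

    One base in the middle of the R1 upstream anchor is substituted (quality
    untouched), so R1 extraction fails with ``no_anchor`` while R2 is
    intact.  Returns the modified pairs and the number injected.
    """
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must be in [0, 1]")
    rng = _as_rng(rng_seed)
    n_inject = int(round(fraction * len(pairs)))
    hit = set(rng.choice(len(pairs), size=n_inject, replace=False).tolist())
    pos = barcode_length + len(scheme.flank_upstream) // 2
    out: list[ReadPair] = []
    for i, p in enumerate(pairs):
        if i in hit:
            old = p.r1_seq[pos]
            new = "A" if old != "A" else "C"
            out.append(
                replace(p, r1_seq=p.r1_seq[:pos] + new + p.r1_seq[pos + 1 :])
            )
        else:
            out.append(p)
    return out, n_inject


# -- ground truth export --------------------------------------------------


def ground_truth_frame(
    pool: PoolComposition,
    landscape: FitnessLandscape | None = None,
    emitted: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Tabulate a pool's variants: sequence, peptide, frequency, fitness, counts."""
    rows = []
    for nt, f in pool.variants.items():
        pep = translate_hcdr3(nt)
        row = {"variant": nt, "peptide": pep, "true_frequency": f}
        if landscape is not None:
            row["fitness"] = landscape.weight(pep or "")
        if emitted is not None:
            row["emitted_count"] = emitted.get(nt, 0)
        rows.append(row)
    frame = pd.DataFrame(rows).sort_values(
        ["true_frequency", "variant"], ascending=[False, True]
    )
    return frame.reset_index(drop=True)


def write_ground_truth(
    pool: PoolComposition,
    path: str | Path,
    landscape: FitnessLandscape | None = None,
    emitted: Mapping[str, int] | None = None,
    metadata: dict | None = None,
) -> None:
    write_tsv(ground_truth_frame(pool, landscape, emitted), path, metadata)
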