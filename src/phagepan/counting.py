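"""Per-pool unique-sequence counting at nucleotide and peptide level.

The central intermediate of the analysis: for each pool, exact multiset
counts of the 27-nt HCDR3 sequences and of their translated 9-mer peptides
(synonymous encodings folded together; a suppressed amber Gln is not
distinguished from CAA/CAG glutamine at the peptide level).  The counter
also tracks how many sequences were only ever observed through the R2
rescue path, the analogue of the "uniques to R2" bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .codons import translate_hcdr3
from .fastq import write_tsv


class EmptyPoolError(ValueError):
    """An operation that needs observations was given an empty pool."""


@dataclass
class PoolCounts:
    """Observed unique sequences with counts for one pool."""

    pool_id: str
    nt_counts: dict[str, int] = field(default_factory=dict)
    pep_counts: dict[str, int] = field(default_factory=dict)
    n_reads_valid: int = 0
    n_rescued_r2: int = 0
    n_unique_r2_only: int = 0

    @classmethod
    def from_nt_counts(
        cls, pool_id: str, nt_counts: Mapping[str, int]
    ) -> "PoolCounts":
        """Build counts from a variant->count map (all R1 provenance)."""
        pc = cls(pool_id=pool_id)
        for nt, count in nt_counts.items():
            pep = translate_hcdr3(nt)
            if pep is None:
                raise ValueError(f"untranslatable HCDR3 {nt!r}")
            pc.nt_counts[nt] = pc.nt_counts.get(nt, 0) + count
            pc.pep_counts[pep] = pc.pep_counts.get(pep, 0) + count
            pc.n_reads_valid += count
        return pc

    @property
    def n_unique_nt(self) -> int:
        return len(self.nt_counts)

    @property
    def n_unique_pep(self) -> int:
        return len(self.pep_counts)


def accumulate(
    stream: Iterable[tuple[str, str, str, str]]
) -> dict[str, PoolCounts]:
    """Count a stream of ``(pool_id, hcdr3_nt, peptide, source_mate)``.

    ``n_unique_r2_only`` counts nucleotide sequences whose every observation
    in that pool came through the R2 rescue path.
    """
    pools: dict[str, PoolCounts] = {}
    seen_via_r1: dict[str, set[str]] = {}
    seen_via_r2: dict[str, set[str]] = {}
    for pool_id, nt, pep, mate in stream:
        pc = pools.get(pool_id)
        if pc is None:
            pc = pools[pool_id] = PoolCounts(pool_id=pool_id)
            seen_via_r1[pool_id] = set()
            seen_via_r2[pool_id] = set()
        pc.nt_counts[nt] = pc.nt_counts.get(nt, 0) + 1
        pc.pep_counts[pep] = pc.pep_counts.get(pep, 0) + 1
        pc.n_reads_valid += 1
        if mate == "R2":
            pc.n_rescued_r2 += 1
            seen_via_r2[pool_id].add(nt)
        else:
            seen_via_r1[pool_id].add(nt)
    for pool_id, pc in pools.items():
        pc.n_unique_r2_only = len(seen_via_r2[pool_id] - seen_via_r1[pool_id])
    return pools


def frequency_table(
    counts: PoolCounts, level: str = "peptide", weighting: str = "counts"
) -> dict[str, float]:
    """Observed frequencies at nt or peptide level.

    ``weighting='counts'`` divides each count by the total; ``'unique'``
    gives every observed sequence the same weight 1/n_unique (the
    convention in which peptides are not weighted by their frequency).
    """
    if level not in ("nt", "peptide"):
        raise ValueError(f"level must be 'nt' or 'peptide', got {level!r}")
    if weighting not in ("counts", "unique"):
        raise ValueError(f"weighting must be 'counts' or 'unique', got {weighting!r}")
    table = counts.nt_counts if level == "nt" else counts.pep_counts
    if not table:
        raise EmptyPoolError(f"pool {counts.pool_id!r} has no observations")
    if weighting == "counts":
        total = sum(table.values())
        return {s: c / total for s, c in table.items()}
    n = len(table)
    return {s: 1.0 / n for s in table}


def counts_frame(counts: PoolCounts, level: str = "nt") -> pd.DataFrame:
    """Two-column table (sequence, count), count-descending then lexicographic."""
    table = counts.nt_counts if level == "nt" else counts.pep_counts
    frame = pd.DataFrame(
        sorted(table.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["sequence", "count"],
    )
    return frame


def write_counts(
    counts: PoolCounts,
    outdir: str | Path,
    metadata: dict | None = None,
) -> dict[str, Path]:
    """Write per-pool nt and peptide count TSVs; returns the paths."""
    outdir = Path(outdir)
    paths = {}
    for level, tag in (("nt", "nt"), ("peptide", "pep")):
        path = outdir / f"{counts.pool_id}.{tag}_counts.tsv"
        write_tsv(counts_frame(counts, level), path, metadata)
        paths[level] = path
    return paths


def read_counts(
    nt_path: str | Path, pool_id: str | None = None
) -> PoolCounts:
    """Rebuild :class:`PoolCounts` from a written nt counts TSV."""
    frame = pd.read_csv(nt_path, sep="\t", comment="#")
    pid = pool_id or Path(nt_path).name.split(".")[0]
    return PoolCounts.from_nt_counts(
        pid, dict(zip(frame["sequence"], frame["count"]))
    )
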