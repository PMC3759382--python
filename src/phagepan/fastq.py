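"""Paired FASTQ streaming, quality filtering, and tabular output.

Reads are Phred+33 (CASAVA 1.8 era); qualities are kept as encoded strings
and decoded on demand.  Streaming is strict: the two mate files must stay in
lockstep, and any truncation or ID mismatch is reported with the offending
pair index.
"""

from __future__ import annotations

import gzip
import hashlib
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

PHRED_OFFSET = 33
# Phred+33 HiSeq qualities top out around Q41; anything far above that is a
# tell-tale of Phred+64 input, which we refuse rather than misread.
_MAX_PLAUSIBLE_PHRED = 45


class FastqFormatError(ValueError):
    """Malformed or inconsistent paired FASTQ input."""


@dataclass
class ReadPair:
    """One paired-end record: R1 and R2 sequences with aligned qualities."""

    read_id: str
    r1_seq: str
    r1_qual: str
    r2_seq: str
    r2_qual: str

    def __post_init__(self) -> None:
        if len(self.r1_seq) != len(self.r1_qual) or len(self.r2_seq) != len(
            self.r2_qual
        ):
            raise FastqFormatError(
                f"sequence/quality length mismatch in read {self.read_id!r}"
            )


@dataclass(frozen=True)
class QualityPolicy:
    """Quality acceptance rule.

    A read (or its HCDR3 window, when ``region='hcdr3-only'``) passes when
    its mean Phred is at least ``min_mean_phred`` *and* every base is at
    least ``min_base_phred``; both boundaries are inclusive.  N bases count
    as Phred 0.
    """

    min_mean_phred: float = 20.0
    min_base_phred: int = 10
    region: str = "whole-read"

    def __post_init__(self) -> None:
        if self.min_mean_phred < 0 or self.min_base_phred < 0:
            raise ValueError("quality thresholds must be >= 0")
        if self.region not in ("whole-read", "hcdr3-only"):
            raise ValueError(f"unknown quality region {self.region!r}")


def phred_scores(qual: str) -> np.ndarray:
    """Decode a Phred+33 quality string to integer scores."""
    scores = np.frombuffer(qual.encode("ascii"), dtype=np.uint8).astype(np.int16)
    scores -= PHRED_OFFSET
    if scores.size and (scores.min() < 0 or scores.max() > _MAX_PLAUSIBLE_PHRED):
        raise FastqFormatError(
            "quality characters outside the Phred+33 range "
            "(input may be Phred+64, which is not supported)"
        )
    return scores


def passes_quality(seq: str, qual: str, policy: QualityPolicy) -> bool:
    """Apply ``policy`` to an aligned sequence/quality pair."""
    if not seq:
        return False
    # Fast path: no N and the worst character already clears both thresholds.
    floor = max(policy.min_base_phred, math.ceil(policy.min_mean_phred))
    if "N" not in seq and min(qual) >= chr(PHRED_OFFSET + floor):
        return True
    scores = phred_scores(qual)
    if "N" in seq:
        scores = scores.copy()
        scores[np.frombuffer(seq.encode("ascii"), dtype=np.uint8) == ord("N")] = 0
    return bool(
        scores.min() >= policy.min_base_phred
        and scores.mean() >= policy.min_mean_phred
    )


def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _pair_key(read_id: str) -> str:
    # First whitespace token, with a trailing /1 or /2 mate tag removed.
    token = read_id.split()[0]
    if token.endswith(("/1", "/2")):
        token = token[:-2]
    return token


def stream_read_pairs(
    r1_path: str | Path, r2_path: str | Path
) -> Iterator[ReadPair]:
    """Yield :class:`ReadPair` from two lockstep FASTQ files (plain or gzip).

    Raises :class:`FastqFormatError` on truncated records, mate-ID
    mismatches, or files of unequal length, naming the 1-based pair index.
    """
    with _open_text(r1_path) as fh1, _open_text(r2_path) as fh2:
        it1 = FastqGeneralIterator(fh1)
        it2 = FastqGeneralIterator(fh2)
        index = 0
        while True:
            index += 1
            try:
                rec1 = next(it1, None)
            except ValueError as exc:
                raise FastqFormatError(f"R1 record {index}: {exc}") from exc
            try:
                rec2 = next(it2, None)
            except ValueError as exc:
                raise FastqFormatError(f"R2 record {index}: {exc}") from exc
            if rec1 is None and rec2 is None:
                return
            if rec1 is None or rec2 is None:
                short = "R1" if rec1 is None else "R2"
                raise FastqFormatError(
                    f"unequal file lengths: {short} exhausted at pair index {index}"
                )
            id1, seq1, q1 = rec1
            id2, seq2, q2 = rec2
            if _pair_key(id1) != _pair_key(id2):
                raise FastqFormatError(
                    f"mate ID mismatch at pair index {index}: {id1!r} vs {id2!r}"
                )
            yield ReadPair(_pair_key(id1), seq1.upper(), q1, seq2.upper(), q2)


def write_fastq(
    records: Iterable[tuple[str, str, str]], path: str | Path
) -> int:
    """Write ``(id, seq, qual)`` triples as 4-line FASTQ (gzip if ``*.gz``)."""
    n = 0
    with _open_text(path, "wt") as fh:
        for read_id, seq, qual in records:
            fh.write(f"@{read_id}\n{seq}\n+\n{qual}\n")
            n += 1
    return n


def write_read_pairs(
    pairs: Iterable[ReadPair], r1_path: str | Path, r2_path: str | Path
) -> int:
    """Write paired records to separate R1/R2 FASTQ files; returns pair count."""
    n = 0
    with _open_text(r1_path, "wt") as f1, _open_text(r2_path, "wt") as f2:
        for p in pairs:
            f1.write(f"@{p.read_id}\n{p.r1_seq}\n+\n{p.r1_qual}\n")
            f2.write(f"@{p.read_id}\n{p.r2_seq}\n+\n{p.r2_qual}\n")
            n += 1
    return n


# -- tabular output -------------------------------------------------------


def write_tsv(
    frame: pd.DataFrame, path: str | Path, metadata: dict | None = None
) -> None:
    """Write a TSV with ``# key=value`` metadata header lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}={value}\n")
        frame.to_csv(fh, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    """Read a TSV written by :func:`write_tsv`, skipping metadata lines."""
    return pd.read_csv(path, sep="\t", comment="#")


def read_tsv_metadata(path: str | Path) -> dict[str, str]:
    meta: dict[str, str] = {}
    with _open_text(path) as fh:
        for line in fh:
            if not line.startswith("# "):
                break
            key, _, value = line[2:].rstrip("\n").partition("=")
            meta[key] = value
    return meta


def config_digest(config: dict) -> str:
    """Short stable hash of a JSON-serializable configuration mapping."""
    canonical = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()[:12]
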