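"""Pool assignment, anchored HCDR3 extraction, and the R1/R2 fallback rule.

A read pair is processed in the order the sequencing pipeline dictates:
quality filter, barcode classification on the leading bases, then HCDR3
extraction by *perfect* match of the two literal anchor sequences flanking
the 27-nt insert.  R2 (reverse-complemented into amplicon orientation) is
consulted only when R1 was discarded for low quality or anchor-match
failure; a pair recovered that way is flagged as rescued, which feeds the
"unique to R2" accounting downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

from .codons import HCDR3_NT_LENGTH, revcomp, translate_hcdr3  # noqa: F401
from .fastq import QualityPolicy, ReadPair, passes_quality
from .scheme import DegenerateCodonScheme

STATUS_OK = "ok"
STATUS_NO_ANCHOR = "no_anchor"
STATUS_BAD_LENGTH = "bad_length"
STATUS_LOW_QUALITY = "low_quality"

UNCLASSIFIED = None


@dataclass(frozen=True)
class BarcodeTable:
    """Pool-ID -> barcode map with a mismatch budget.

    Barcodes must be unique, equal-length, and pairwise Hamming distance
    > 2 * max_mismatch so every assignment within the budget is unambiguous.
    """

    entries: dict[str, str]
    max_mismatch: int = 1

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("barcode table is empty")
        if self.max_mismatch < 0:
            raise ValueError("max_mismatch must be >= 0")
        barcodes = list(self.entries.values())
        lengths = {len(b) for b in barcodes}
        if len(lengths) != 1:
            raise ValueError("all barcodes must have the same length")
        if len(set(barcodes)) != len(barcodes):
            raise ValueError("barcodes must be unique")
        for i, a in enumerate(barcodes):
            for b in barcodes[i + 1 :]:
                dist = sum(x != y for x, y in zip(a, b))
                if dist <= 2 * self.max_mismatch:
                    raise ValueError(
                        f"barcodes {a!r} and {b!r} are Hamming distance {dist} "
                        f"apart; need > {2 * self.max_mismatch} for "
                        f"max_mismatch={self.max_mismatch}"
                    )
        object.__setattr__(self, "_length", next(iter(lengths)))
        object.__setattr__(
            self, "_exact", {b: pool for pool, b in self.entries.items()}
        )

    @property
    def barcode_length(self) -> int:
        return self._length  # type: ignore[attr-defined]


def assign_pool(read_seq: str, table: BarcodeTable) -> str | None:
    """Assign a read to a pool by its leading bases (prefix-anchored barcode).

    Returns the unique pool within ``max_mismatch`` substitutions, or
    ``None`` (unclassified) when no barcode qualifies or two tie at the
    minimum distance.
    """
    prefix = read_seq[: table.barcode_length]
    exact = table._exact.get(prefix)  # type: ignore[attr-defined]
    if exact is not None:
        return exact
    if table.max_mismatch == 0:
        return UNCLASSIFIED
    best_pool = None
    best_dist = table.max_mismatch + 1
    tied = False
    for pool, barcode in table.entries.items():
        dist = sum(x != y for x, y in zip(prefix, barcode))
        if dist < best_dist:
            best_pool, best_dist, tied = pool, dist, False
        elif dist == best_dist:
            tied = True
    if best_pool is None or tied or best_dist > table.max_mismatch:
        return UNCLASSIFIED
    return best_pool


@dataclass(frozen=True)
class ExtractionResult:
    """Outcome of HCDR3 extraction from one mate."""

    status: str
    hcdr3_nt: str | None = None
    source_mate: str = "R1"

    def __post_init__(self) -> None:
        if (self.status == STATUS_OK) != (self.hcdr3_nt is not None):
            raise ValueError("hcdr3_nt must be present iff status is 'ok'")
        if self.hcdr3_nt is not None and len(self.hcdr3_nt) != HCDR3_NT_LENGTH:
            raise ValueError("extracted HCDR3 must be 27 nt")

    @property
    def ok(self) -> bool:
        return self.status == STATUS_OK


def extract_hcdr3(
    read_seq: str,
    read_qual: str | None,
    scheme: DegenerateCodonScheme,
    policy: QualityPolicy | None = None,
    source_mate: str = "R1",
) -> ExtractionResult:
    """Extract the 27-nt HCDR3 between the scheme's literal anchors.

    Both anchors must occur exactly once, in order, separated by exactly
    27 nt — the perfect-match rule.  When ``policy.region == 'hcdr3-only'``
    the 27-nt window must additionally pass the quality policy.
    """
    up, down = scheme.flank_upstream, scheme.flank_downstream
    i = read_seq.find(up)
    if i < 0 or read_seq.find(up, i + 1) >= 0:
        return ExtractionResult(STATUS_NO_ANCHOR, source_mate=source_mate)
    j = read_seq.find(down)
    if j < 0 or read_seq.find(down, j + 1) >= 0:
        return ExtractionResult(STATUS_NO_ANCHOR, source_mate=source_mate)
    start = i + len(up)
    if j < start:
        return ExtractionResult(STATUS_NO_ANCHOR, source_mate=source_mate)
    if j - start != HCDR3_NT_LENGTH:
        return ExtractionResult(STATUS_BAD_LENGTH, source_mate=source_mate)
    window = read_seq[start:j]
    if policy is not None and policy.region == "hcdr3-only":
        qual_window = read_qual[start:j] if read_qual is not None else ""
        if not passes_quality(window, qual_window, policy):
            return ExtractionResult(STATUS_LOW_QUALITY, source_mate=source_mate)
    return ExtractionResult(STATUS_OK, hcdr3_nt=window, source_mate=source_mate)


def resolve_pair(
    r1_result: ExtractionResult, r2_result: ExtractionResult | None
) -> tuple[ExtractionResult, bool]:
    """Apply the fallback rule: R1 wins when ok; else R2 (flagged rescued);
    else discard carrying the R1 failure status."""
    if r1_result.ok:
        return r1_result, False
    if r2_result is not None and r2_result.ok:
        return r2_result, True
    return r1_result, False


@dataclass
class PairOutcome:
    """Final disposition of one read pair."""

    pool_id: str | None
    result: ExtractionResult
    rescued_by_r2: bool


def process_pair(
    pair: ReadPair,
    table: BarcodeTable,
    scheme: DegenerateCodonScheme,
    policy: QualityPolicy | None = None,
) -> PairOutcome:
    """Classify and extract one pair with the R1-then-R2 fallback.

    Pool assignment uses the mate actually consulted.  A pair whose R1
    succeeds but matches no barcode is unclassified without consulting R2
    (R2 is reserved for quality/anchor failures of R1).
    """
    whole_read = policy is not None and policy.region == "whole-read"

    if whole_read and not passes_quality(pair.r1_seq, pair.r1_qual, policy):
        r1_res = ExtractionResult(STATUS_LOW_QUALITY, source_mate="R1")
        pool1 = None
    else:
        r1_res = extract_hcdr3(pair.r1_seq, pair.r1_qual, scheme, policy, "R1")
        pool1 = assign_pool(pair.r1_seq, table) if r1_res.ok else None
    if r1_res.ok:
        return PairOutcome(pool1, r1_res, False)

    r2_seq = revcomp(pair.r2_seq)
    r2_qual = pair.r2_qual[::-1]
    if whole_read and not passes_quality(r2_seq, r2_qual, policy):
        r2_res: ExtractionResult | None = None
    else:
        r2_res = extract_hcdr3(r2_seq, r2_qual, scheme, policy, "R2")

    final, rescued = resolve_pair(r1_res, r2_res)
    if rescued:
        return PairOutcome(assign_pool(r2_seq, table), final, True)
    return PairOutcome(None, final, False)


@dataclass
class ClassificationSummary:
    """Per-run counters mirroring the classified/unclassified accounting."""

    total_pairs: int = 0
    classified: dict[str, int] = field(default_factory=dict)
    rescued_by_r2: dict[str, int] = field(default_factory=dict)
    unclassified: int = 0
    discard_reasons: dict[str, int] = field(default_factory=dict)

    def record(self, outcome: PairOutcome) -> None:
        self.total_pairs += 1
        if outcome.pool_id is not None and outcome.result.ok:
            self.classified[outcome.pool_id] = (
                self.classified.get(outcome.pool_id, 0) + 1
            )
            if outcome.rescued_by_r2:
                self.rescued_by_r2[outcome.pool_id] = (
                    self.rescued_by_r2.get(outcome.pool_id, 0) + 1
                )
        else:
            self.unclassified += 1
            reason = outcome.result.status if not outcome.result.ok else "no_barcode"
            self.discard_reasons[reason] = self.discard_reasons.get(reason, 0) + 1

    @property
    def n_classified(self) -> int:
        return sum(self.classified.values())


def classify_stream(
    pairs: Iterable[ReadPair],
    table: BarcodeTable,
    scheme: DegenerateCodonScheme,
    policy: QualityPolicy | None = None,
    summary: ClassificationSummary | None = None,
) -> Iterator[tuple[str, str, str, str]]:
    """Process pairs and yield ``(pool_id, hcdr3_nt, peptide, source_mate)``
    for every classified pair with a translatable HCDR3.

    Pairs whose extracted HCDR3 contains an unsuppressed stop or an
    ambiguous base are dropped and counted as ``invalid_translation``.
    """
    for pair in pairs:
        outcome = process_pair(pair, table, scheme, policy)
        if outcome.pool_id is not None and outcome.result.ok:
            peptide = translate_hcdr3(outcome.result.hcdr3_nt)
            if peptide is None:
                if summary is not None:
                    summary.total_pairs += 1
                    summary.unclassified += 1
                    summary.discard_reasons["invalid_translation"] = (
                        summary.discard_reasons.get("invalid_translation", 0) + 1
                    )
                continue
            if summary is not None:
                summary.record(outcome)
            yield (
                outcome.pool_id,
                outcome.result.hcdr3_nt,
                peptide,
                outcome.result.source_mate,
            )
        elif summary is not None:
            summary.record(outcome)
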