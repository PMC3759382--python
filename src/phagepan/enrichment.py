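"""Round-over-round enrichment: per-peptide fold change and strata.

Fold change is the ratio of a peptide's abundance after the third panning
round to its abundance in the unselected library (round 0).  Because
sequencing depths differ between rounds, the default compares frequencies
(counts normalized by pool totals); the raw count ratio is available as
``normalize=False``.  Selected and counter-selected peptides are divided
into mild/moderate/high strata at fold change 4, 7, 10 and the mirrored
0.25, 0.143, 0.1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .counting import EmptyPoolError, PoolCounts

UP_STRATA = ("mild", "moderate", "high")
DOWN_STRATA = ("mild_counter", "moderate_counter", "high_counter")
DEFAULT_THRESHOLDS_UP = (4.0, 7.0, 10.0)
DEFAULT_THRESHOLDS_DOWN = (0.25, 0.143, 0.1)


@dataclass
class EnrichmentRecord:
    """Per-peptide round-0/round-3 counts, frequencies, fold change, stratum."""

    peptide: str
    count_r0: int
    count_r3: int
    freq_r0: float
    freq_r3: float
    fold_change: float | None = None
    stratum: str | None = None


@dataclass
class FoldChangeResult:
    """Fold-change table plus the novel/lost side lists."""

    records: list[EnrichmentRecord]
    novel: list[EnrichmentRecord] = field(default_factory=list)
    lost: list[EnrichmentRecord] = field(default_factory=list)
    normalize: bool = True
    pseudocount: float = 0.0
    min_count_r0: int = 1


def fold_change_table(
    counts_r0: PoolCounts,
    counts_r3: PoolCounts,
    normalize: bool = True,
    pseudocount: float = 0.0,
    min_count_r0: int = 1,
) -> FoldChangeResult:
    """Compute per-peptide fold change between two rounds of one library.

    With pseudocount psi, ``normalize=True`` gives
    FC = ((c3+psi)/N3) / ((c0+psi)/N0) and ``normalize=False`` gives
    FC = (c3+psi)/(c0+psi).  Peptides absent from round 0 go to the
    ``novel`` list (they get a defined FC only when psi > 0 *and*
    ``min_count_r0`` is 0); peptides absent from round 3 get FC = 0 and are
    also listed in ``lost``.  ``min_count_r0`` guards against fold-change
    blow-up on round-0 singletons.
    """
    if not counts_r0.pep_counts:
        raise EmptyPoolError(f"round-0 pool {counts_r0.pool_id!r} is empty")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    n0 = sum(counts_r0.pep_counts.values())
    n3 = sum(counts_r3.pep_counts.values())
    peptides = sorted(set(counts_r0.pep_counts) | set(counts_r3.pep_counts))

    result = FoldChangeResult(
        records=[],
        normalize=normalize,
        pseudocount=pseudocount,
        min_count_r0=min_count_r0,
    )
    for pep in peptides:
        c0 = counts_r0.pep_counts.get(pep, 0)
        c3 = counts_r3.pep_counts.get(pep, 0)
        rec = EnrichmentRecord(
            peptide=pep,
            count_r0=c0,
            count_r3=c3,
            freq_r0=c0 / n0,
            freq_r3=c3 / n3 if n3 else 0.0,
        )
        denominator = c0 + pseudocount
        if denominator > 0:
            fc = (c3 + pseudocount) / denominator
            if normalize:
                fc *= n0 / n3
            rec.fold_change = fc
        if c0 == 0:
            result.novel.append(rec)
        if c3 == 0:
            result.lost.append(rec)
        if c0 >= min_count_r0 and rec.fold_change is not None:
            result.records.append(rec)
    return result


def stratify(
    records: Sequence[EnrichmentRecord],
    thresholds_up: tuple[float, float, float] = DEFAULT_THRESHOLDS_UP,
    thresholds_down: tuple[float, float, float] = DEFAULT_THRESHOLDS_DOWN,
    mode: str = "exclusive",
) -> dict[str, set[str]]:
    """Label records with selection strata and return per-stratum peptide sets.

    Exclusive mode assigns the bands [4,7), [7,10), [10,inf) and their
    mirrored counter-selection bands (boundaries inclusive on the selected
    side); cumulative mode puts every record beyond a threshold into that
    stratum, so a strongly selected peptide appears in up to three sets.
    Records between the innermost thresholds are neutral.  Each record's
    ``stratum`` attribute always gets its most extreme band.
    """
    if not (thresholds_up[0] < thresholds_up[1] < thresholds_up[2]):
        raise ValueError("thresholds_up must be strictly increasing")
    if not (thresholds_down[0] > thresholds_down[1] > thresholds_down[2]):
        raise ValueError("thresholds_down must be strictly decreasing")
    if mode not in ("exclusive", "cumulative"):
        raise ValueError(f"mode must be 'exclusive' or 'cumulative', got {mode!r}")

    sets: dict[str, set[str]] = {name: set() for name in UP_STRATA + DOWN_STRATA}
    sets["neutral"] = set()
    u1, u2, u3 = thresholds_up
    d1, d2, d3 = thresholds_down
    for rec in records:
        fc = rec.fold_change
        if fc is None:
            continue
        if fc >= u3:
            rec.stratum = "high"
        elif fc >= u2:
            rec.stratum = "moderate"
        elif fc >= u1:
            rec.stratum = "mild"
        elif fc <= d3:
            rec.stratum = "high_counter"
        elif fc <= d2:
            rec.stratum = "moderate_counter"
        elif fc <= d1:
            rec.stratum = "mild_counter"
        else:
            rec.stratum = "neutral"
        if mode == "exclusive":
            sets[rec.stratum].add(rec.peptide)
        else:
            if fc >= u1:
                sets["mild"].add(rec.peptide)
            if fc >= u2:
                sets["moderate"].add(rec.peptide)
            if fc >= u3:
                sets["high"].add(rec.peptide)
            if fc <= d1:
                sets["mild_counter"].add(rec.peptide)
            if fc <= d2:
                sets["moderate_counter"].add(rec.peptide)
            if fc <= d3:
                sets["high_counter"].add(rec.peptide)
            if d1 < fc < u1:
                sets["neutral"].add(rec.peptide)
    return sets


def ordered_series(records: Sequence[EnrichmentRecord]) -> pd.DataFrame:
    """Fold changes sorted descending (ties broken by peptide), with ranks.

    The plot-ready analogue of the sequentially plotted fold-change list;
    fold change is conventionally drawn on a log scale.
    """
    defined = [r for r in records if r.fold_change is not None]
    defined.sort(key=lambda r: (-r.fold_change, r.peptide))
    return pd.DataFrame(
        {
            "rank": range(1, len(defined) + 1),
            "peptide": [r.peptide for r in defined],
            "fold_change": [r.fold_change for r in defined],
        }
    )


def enrichment_frame(result: FoldChangeResult) -> pd.DataFrame:
    """Flatten a fold-change table (with strata, if assigned) to a DataFrame."""
    rows = [
        {
            "peptide": r.peptide,
            "count_r0": r.count_r0,
            "count_r3": r.count_r3,
            "freq_r0": r.freq_r0,
            "freq_r3": r.freq_r3,
            "fold_change": r.fold_change,
            "stratum": r.stratum,
        }
        for r in result.records
    ]
    frame = pd.DataFrame(
        rows,
        columns=[
            "peptide",
            "count_r0",
            "count_r3",
            "freq_r0",
            "freq_r3",
            "fold_change",
            "stratum",
        ],
    )
    return frame.sort_values(
        ["fold_change", "peptide"], ascending=[False, True]
    ).reset_index(drop=True)
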