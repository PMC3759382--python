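"""End-to-end orchestration: simulate -> filter -> classify -> count ->
enrich -> diversity, with a machine-readable run report.

The pipeline mirrors the three-step design of the original analysis
(filtering, classification, analysis) and adds the simulator in front so
the whole chain runs with no external data.  Every output table carries the
run seed and a configuration digest in its metadata header, and a rerun
with identical configuration produces byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diversity as div
from .classify import BarcodeTable, ClassificationSummary, classify_stream
from .counting import PoolCounts, accumulate, write_counts
from .enrichment import (
    enrichment_frame,
    fold_change_table,
    ordered_series,
    stratify,
)
from .fastq import (
    QualityPolicy,
    config_digest,
    stream_read_pairs,
    write_read_pairs,
    write_tsv,
)
from .scheme import (
    DEFAULT_BARCODES,
    DEFAULT_ROUND_PAIRS,
    DegenerateCodonScheme,
)
from .simulate import (
    FitnessLandscape,
    PoolComposition,
    ReadEmissionConfig,
    apply_selection,
    emit_reads,
    emitted_counts,
    make_initial_pool,
    write_ground_truth,
)


@dataclass
class SimulationSpec:
    """What to simulate for each V-gene context.

    Defaults emulate the study's libraries at desk scale: two dominant
    peptides (each coded by several synonymous sequences) carrying 96.7% of
    the round-0 mass over a random (NNS)6 KBG HTK GMT background, three
    rounds of selection in which each context favours one dominant clone
    and disfavours the other, and paired 77-bp reads with a realistic
    per-base substitution error rate.
    """

    n_variants: int = 500
    dominant_peptides: tuple[str, ...] = ("YLLSPLLLA", "VQQVNNALA")
    dominant_mass: float = 0.967
    encodings_per_dominant: int = 8
    rounds: int = 3
    fitness_log2_range: tuple[float, float] = (-2.0, 2.0)
    bottleneck: int | None = None
    depth: int = 25_000
    error_rate: float = 0.005
    quality_high: int = 40
    quality_low: int = 2


@dataclass
class RunConfig:
    """Full pipeline configuration."""

    outdir: Path
    r1_path: Path | None = None
    r2_path: Path | None = None
    simulate: SimulationSpec | None = None
    barcodes: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_BARCODES))
    max_mismatch: int = 1
    round_pairs: tuple[tuple[str, str], ...] = DEFAULT_ROUND_PAIRS
    min_mean_phred: float = 20.0
    min_base_phred: int = 10
    quality_region: str = "whole-read"
    normalize: bool = True
    pseudocount: float = 0.0
    min_count_r0: int = 1
    stratify_mode: str = "exclusive"
    diversity_weighting: str = "unique"
    kl_pseudocount: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        if self.r1_path is not None:
            self.r1_path = Path(self.r1_path)
        if self.r2_path is not None:
            self.r2_path = Path(self.r2_path)

    def validate(self) -> None:
        if self.simulate is None:
            for name, path in (("R1", self.r1_path), ("R2", self.r2_path)):
                if path is None:
                    raise ValueError(f"{name} FASTQ path missing and no simulation requested")
                if not Path(path).exists():
                    raise FileNotFoundError(f"{name} FASTQ not found: {path}")

    @property
    def quality_policy(self) -> QualityPolicy:
        return QualityPolicy(
            min_mean_phred=self.min_mean_phred,
            min_base_phred=self.min_base_phred,
            region=self.quality_region,
        )

    def digest(self) -> str:
        payload = dataclasses.asdict(self)
        payload.pop("outdir")
        return config_digest(payload)

    @classmethod
    def from_yaml(cls, path: str | Path, outdir: str | Path | None = None) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulate", None)
        if sim is not None:
            sim = SimulationSpec(**sim)
        if "round_pairs" in raw:
            raw["round_pairs"] = tuple(tuple(p) for p in raw["round_pairs"])
        if outdir is not None:
            raw["outdir"] = outdir
        return cls(simulate=sim, **raw)


@dataclass
class RunReport:
    """Summary of one pipeline run."""

    seed: int
    config_digest: str
    total_pairs: int
    classified: dict[str, int]
    unclassified: int
    rescued_by_r2: dict[str, int]
    discard_reasons: dict[str, int]
    unique_nt: dict[str, int]
    unique_pep: dict[str, int]
    unique_r2_only: dict[str, int]
    strata_sizes: dict[str, dict[str, int]]
    kl_total_bits: dict[str, dict[str, float]]
    outputs: dict[str, str]


def simulate_experiment(
    config: RunConfig, scheme: DegenerateCodonScheme
) -> tuple[Path, Path, dict[str, PoolComposition], dict[str, FitnessLandscape]]:
    """Build ground-truth pools per context, emit combined R1/R2 FASTQ.

    Returns the FASTQ paths, the per-pool compositions, and the per-context
    fitness landscapes.  Ground-truth TSVs are written under ``truth/``.
    """
    spec = config.simulate
    assert spec is not None
    fastq_dir = config.outdir / "fastq"
    truth_dir = config.outdir / "truth"
    fastq_dir.mkdir(parents=True, exist_ok=True)
    truth_dir.mkdir(parents=True, exist_ok=True)

    contexts = [
        (r0.rsplit("_", 1)[0], r0, r3) for r0, r3 in config.round_pairs
    ]
    seed_seq = np.random.SeedSequence(config.seed)
    children = seed_seq.spawn(len(contexts))

    pools: dict[str, PoolComposition] = {}
    landscapes: dict[str, FitnessLandscape] = {}
    all_pairs = []
    meta = {"seed": config.seed, "config": config.digest()}
    for (context, r0_id, r3_id), child in zip(contexts, children):
        rng_pool, rng_fit, rng_sel, rng_emit0, rng_emit3 = [
            np.random.default_rng(s) for s in child.spawn(5)
        ]
        pool0 = make_initial_pool(
            scheme,
            n_variants=spec.n_variants,
            dominant_peptides=spec.dominant_peptides,
            dominant_mass=spec.dominant_mass,
            rng_seed=rng_pool,
            encodings_per_dominant=spec.encodings_per_dominant,
            pool_id=r0_id,
        )
        lo, hi = spec.fitness_log2_range
        peptides = sorted(pool0.peptide_frequencies())
        fitness = {
            pep: float(2.0 ** rng_fit.uniform(lo, hi)) for pep in peptides
        }
        # Each context favours one dominant clone and disfavours the other,
        # mirroring the opposite selection directions seen for the two
        # dominant peptides in the two V-gene contexts.
        if len(spec.dominant_peptides) >= 2:
            first, second = spec.dominant_peptides[:2]
            favoured = first if context.endswith("10") else second
            disfavoured = second if favoured == first else first
            fitness[favoured] = 2.0
            fitness[disfavoured] = 0.5
        landscape = FitnessLandscape(fitness=fitness)
        pool3 = apply_selection(
            pool0,
            landscape,
            rounds=spec.rounds,
            bottleneck=spec.bottleneck,
            rng_seed=rng_sel,
            pool_id=r3_id,
        )
        pools[r0_id], pools[r3_id] = pool0, pool3
        landscapes[context] = landscape

        for pool, rng_emit in ((pool0, rng_emit0), (pool3, rng_emit3)):
            emit_cfg = ReadEmissionConfig(
                barcode=config.barcodes[pool.pool_id],
                depth=spec.depth,
                error_rate=spec.error_rate,
                quality_high=spec.quality_high,
                quality_low=spec.quality_low,
                seed=rng_emit,
            )
            pairs = emit_reads(pool, emit_cfg, scheme)
            write_ground_truth(
                pool,
                truth_dir / f"{pool.pool_id}.truth.tsv",
                landscape=landscape,
                emitted=emitted_counts(pairs),
                metadata=meta,
            )
            all_pairs.extend(pairs)

    r1_path = fastq_dir / "R1.fastq"
    r2_path = fastq_dir / "R2.fastq"
    write_read_pairs(all_pairs, r1_path, r2_path)
    return r1_path, r2_path, pools, landscapes


def run_pipeline(config: RunConfig, scheme: DegenerateCodonScheme | None = None) -> RunReport:
    """Execute all stages in order and write all outputs under ``outdir``."""
    scheme = scheme or DegenerateCodonScheme()
    config.validate()
    config.outdir.mkdir(parents=True, exist_ok=True)
    meta = {"seed": config.seed, "config": config.digest()}

    if config.simulate is not None:
        r1_path, r2_path, _, _ = simulate_experiment(config, scheme)
    else:
        r1_path, r2_path = config.r1_path, config.r2_path

    # Filtering + classification + extraction + counting, single streaming pass.
    table = BarcodeTable(entries=config.barcodes, max_mismatch=config.max_mismatch)
    summary = ClassificationSummary()
    pools = accumulate(
        classify_stream(
            stream_read_pairs(r1_path, r2_path),
            table,
            scheme,
            config.quality_policy,
            summary,
        )
    )

    # Classification report (classified counts and percentages per pool).
    total = summary.total_pairs
    rows = []
    for pool_id in config.barcodes:
        n = summary.classified.get(pool_id, 0)
        rows.append(
            {
                "pool": pool_id,
                "n_pairs": n,
                "percent": 100.0 * n / total if total else 0.0,
                "rescued_by_r2": summary.rescued_by_r2.get(pool_id, 0),
            }
        )
    rows.append(
        {
            "pool": "not_classified",
            "n_pairs": summary.unclassified,
            "percent": 100.0 * summary.unclassified / total if total else 0.0,
            "rescued_by_r2": 0,
        }
    )
    rows.append(
        {"pool": "total", "n_pairs": total, "percent": 100.0, "rescued_by_r2": 0}
    )
    class_report = pd.DataFrame(rows)
    write_tsv(class_report, config.outdir / "classification_report.tsv", meta)

    # Unique-sequence report and per-pool count tables.
    counts_dir = config.outdir / "counts"
    unique_rows = []
    for pool_id in config.barcodes:
        pc = pools.get(pool_id, PoolCounts(pool_id=pool_id))
        if pc.n_reads_valid:
            write_counts(pc, counts_dir, meta)
        unique_rows.append(
            {
                "pool": pool_id,
                "n_reads_valid": pc.n_reads_valid,
                "unique_nt": pc.n_unique_nt,
                "unique_pep": pc.n_unique_pep,
                "rescued_by_r2": pc.n_rescued_r2,
                "unique_r2_only": pc.n_unique_r2_only,
            }
        )
    write_tsv(
        pd.DataFrame(unique_rows), config.outdir / "unique_report.tsv", meta
    )

    # Enrichment per V-gene context.
    enrich_dir = config.outdir / "enrichment"
    strata_sizes: dict[str, dict[str, int]] = {}
    strata_sets: dict[str, dict[str, set]] = {}
    for r0_id, r3_id in config.round_pairs:
        if r0_id not in pools or r3_id not in pools:
            continue
        context = r0_id.rsplit("_", 1)[0]
        result = fold_change_table(
            pools[r0_id],
            pools[r3_id],
            normalize=config.normalize,
            pseudocount=config.pseudocount,
            min_count_r0=config.min_count_r0,
        )
        sets = stratify(result.records, mode=config.stratify_mode)
        strata_sets[context] = sets
        strata_sizes[context] = {name: len(s) for name, s in sorted(sets.items())}
        emeta = dict(meta, stratify_mode=config.stratify_mode)
        write_tsv(
            enrichment_frame(result),
            enrich_dir / f"{context}.enrichment.tsv",
            emeta,
        )
        write_tsv(
            ordered_series(result.records),
            enrich_dir / f"{context}.ordered_fc.tsv",
            dict(emeta, scale="log-recommended"),
        )
        for name, recs in (("novel", result.novel), ("lost", result.lost)):
            frame = pd.DataFrame(
                {
                    "peptide": [r.peptide for r in recs],
                    "count_r0": [r.count_r0 for r in recs],
                    "count_r3": [r.count_r3 for r in recs],
                }
            ).sort_values("peptide").reset_index(drop=True)
            write_tsv(frame, enrich_dir / f"{context}.{name}.tsv", emeta)

    # Diversity: entropy/IC per pool, KL round 3 vs round 0 per context.
    div_dir = config.outdir / "diversity"
    weighting = config.diversity_weighting
    kl_totals: dict[str, dict[str, float]] = {}
    pfms: dict[tuple[str, str], div.PositionFrequencyMatrix] = {}
    for pool_id, pc in pools.items():
        for level, alphabet in (("nt", "dna"), ("peptide", "protein")):
            table = pc.nt_counts if level == "nt" else pc.pep_counts
            if not table:
                continue
            pfm = div.build_pfm(table, alphabet=alphabet, weighting=weighting)
            pfms[(pool_id, level)] = pfm
            profile = div.information_content(pfm)
            write_tsv(
                profile.to_frame(),
                div_dir / f"{pool_id}.{level}.entropy.tsv",
                dict(meta, weighting=weighting),
            )
    theo = div.information_content(div.theoretical_pfm(scheme))
    write_tsv(theo.to_frame(), div_dir / "theoretical.nt.entropy.tsv", meta)
    for r0_id, r3_id in config.round_pairs:
        context = r0_id.rsplit("_", 1)[0]
        kl_totals[context] = {}
        for level in ("nt", "peptide"):
            if (r0_id, level) not in pfms or (r3_id, level) not in pfms:
                continue
            profile = div.kl_profile(
                pfms[(r3_id, level)],
                pfms[(r0_id, level)],
                pseudocount=config.kl_pseudocount,
            )
            kl_totals[context][level] = profile.total
            write_tsv(
                profile.to_frame(),
                div_dir / f"{context}.{level}.kl.tsv",
                dict(meta, weighting=weighting, pseudocount=config.kl_pseudocount),
            )

    report = RunReport(
        seed=config.seed,
        config_digest=config.digest(),
        total_pairs=total,
        classified=dict(sorted(summary.classified.items())),
        unclassified=summary.unclassified,
        rescued_by_r2=dict(sorted(summary.rescued_by_r2.items())),
        discard_reasons=dict(sorted(summary.discard_reasons.items())),
        unique_nt={p: pools[p].n_unique_nt for p in sorted(pools)},
        unique_pep={p: pools[p].n_unique_pep for p in sorted(pools)},
        unique_r2_only={p: pools[p].n_unique_r2_only for p in sorted(pools)},
        strata_sizes=strata_sizes,
        kl_total_bits=kl_totals,
        outputs={  # paths relative to outdir so reruns are byte-identical
            "classification_report": "classification_report.tsv",
            "unique_report": "unique_report.tsv",
            "counts_dir": "counts",
            "enrichment_dir": "enrichment",
            "diversity_dir": "diversity",
        },
    )
    with open(config.outdir / "report.json", "w") as fh:
        json.dump(dataclasses.asdict(report), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
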