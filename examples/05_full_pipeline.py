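"""Run the whole pipeline — simulate, filter, classify, count, enrich,
diversity — and read the run report.

Equivalent to ``phagepan all --outdir out --seed 1`` from the shell.
"""

import json
from pathlib import Path
from tempfile import TemporaryDirectory

from phagepan import RunConfig, SimulationSpec, run_pipeline

with TemporaryDirectory() as tmp:
    config = RunConfig(
        outdir=Path(tmp) / "run",
        simulate=SimulationSpec(depth=10_000),  # 4 pools x 10,000 pairs
        seed=1,
    )
    report = run_pipeline(config)
    print(f"total pairs        : {report.total_pairs}")
    print(f"classified per pool: {report.classified}")
    print(f"unclassified       : {report.unclassified}")
    print(f"rescued by R2      : {report.rescued_by_r2}")
    print(f"unique nt per pool : {report.unique_nt}")
    print(f"strata (vh10)      : {report.strata_sizes['vh10']}")
    print(f"KL totals (bits)   : {json.dumps(report.kl_total_bits)}")
    print(f"outputs under      : {sorted(report.outputs)}")
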