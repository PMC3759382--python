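"""Simulate a degenerate HCDR3 library and emit barcoded paired-end reads.

Builds a round-0 pool in which two dominant peptides — each coded by several
synonymous nucleotide sequences — carry 96.7% of the mass over a random
(NNS)6 KBG HTK GMT background, then emits 77-bp amplicon read pairs.
"""

from phagepan import (
    DegenerateCodonScheme,
    ReadEmissionConfig,
    emit_reads,
    make_initial_pool,
    translate_hcdr3,
)

scheme = DegenerateCodonScheme()
pool = make_initial_pool(
    scheme,
    n_variants=300,
    dominant_peptides=("YLLSPLLLA", "VQQVNNALA"),
    dominant_mass=0.967,
    rng_seed=1,
    pool_id="vh10_r0",
)
peptides = pool.peptide_frequencies()
print(f"pool has {len(pool.variants)} nucleotide variants, {len(peptides)} peptides")
print(f"dominant mass: {peptides['YLLSPLLLA'] + peptides['VQQVNNALA']:.3f}")

config = ReadEmissionConfig(barcode="GTAGTA", depth=5_000, error_rate=0.005, seed=2)
pairs = emit_reads(pool, config, scheme)
example = pairs[0]
print(f"emitted {len(pairs)} pairs of {len(example.r1_seq)}-bp reads")
print("R1 example:", example.r1_seq)
insert = example.r1_seq[6 + len(scheme.flank_upstream):][:27]
print("its HCDR3 :", insert, "->", translate_hcdr3(insert))
# The read layout is barcode + upstream anchor + 27-nt HCDR3 + downstream
# anchor; the translation uses the amber-suppressed code (TAG -> Q).
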