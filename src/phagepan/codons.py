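"""Genetic code with amber suppression.

The display host is a supE-type suppressor strain whose Gln-tRNA reads the
amber stop codon (TAG) as glutamine, so TAG-containing library members are
translated and displayed.  Ochre (TAA) and opal (TGA) are not suppressed and
terminate translation, which makes any HCDR3 containing them invalid.
"""

from __future__ import annotations

from Bio.Data import CodonTable

HCDR3_NT_LENGTH = 27
HCDR3_AA_LENGTH = 9

_STANDARD = CodonTable.unambiguous_dna_by_id[1]

#: DNA codon -> one-letter amino acid, with TAG read as Q (amber suppression).
CODON_TO_AA: dict[str, str] = dict(_STANDARD.forward_table)
CODON_TO_AA["TAG"] = "Q"

#: Stop codons that remain stops in the suppressor host.
UNSUPPRESSED_STOPS = frozenset({"TAA", "TGA"})

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def translate_hcdr3(hcdr3_nt: str) -> str | None:
    """Translate a 27-nt HCDR3 into its 9-residue peptide.

    TAG is read as glutamine (amber suppression); TAA or TGA anywhere, or any
    base outside {A,C,G,T} (including N), makes the sequence biologically
    invalid and ``None`` is returned.  A sequence of the wrong length is a
    caller bug and raises ``ValueError``.
    """
    if len(hcdr3_nt) != HCDR3_NT_LENGTH:
        raise ValueError(
            f"HCDR3 must be {HCDR3_NT_LENGTH} nt, got {len(hcdr3_nt)}"
        )
    residues = []
    for i in range(0, HCDR3_NT_LENGTH, 3):
        aa = CODON_TO_AA.get(hcdr3_nt[i : i + 3])
        if aa is None:
            return None
        residues.append(aa)
    return "".join(residues)
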