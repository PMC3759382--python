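"""Degenerate codon scheme of the synthetic HCDR3 library.

The library randomizes a nine-residue HCDR3 as six fully degenerate NNS
codons followed by three partially restricted codons (KBG, HTK, GMT), a
design that covers all twenty amino acids at positions 1-6 while mimicking
the natural amino-acid bias of the last three Kabat positions.  NNS (third
base G or C) excludes the unsuppressible TAA/TGA stops; the amber TAG is
reachable and is read as Gln by the suppressor host.

Flanking the 27-nt insert, the amplicon carries an upstream region ending in
the Val-Arg-Glu codons that contain the BsiWI cloning site (CGTACG) and a
downstream region encoding the fixed Tyr plus the WGQGT framework-4
consensus before the XbaI site.  These flanks are the literal anchors used
to locate the HCDR3 in a read.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from Bio.Data import IUPACData

from .codons import CODON_TO_AA, HCDR3_NT_LENGTH

#: IUPAC ambiguity code -> string of concrete bases, e.g. "K" -> "GT".
IUPAC_DNA: dict[str, str] = {
    code: "".join(sorted(bases))
    for code, bases in IUPACData.ambiguous_dna_values.items()
}

DEFAULT_CODON_TEMPLATES: tuple[str, ...] = ("NNS",) * 6 + ("KBG", "HTK", "GMT")

# Fixture anchors (the study's exact oligos are not public).  Upstream: a
# 12-nt primer stub, then C + GTA CGT GAG — the BsiWI site CGTACG overlapping
# the Val-Arg-Glu codons.  Downstream: TAT (fixed Tyr), TGG GGT CAG GGA ACC
# (WGQGT framework-4), then the first 4 nt of the XbaI site.  With a 6-nt
# barcode the amplicon is 6 + 22 + 27 + 22 = 77 bp.
DEFAULT_FLANK_UPSTREAM = "GCTGATTCAGGA" + "CGTACGTGAG"
DEFAULT_FLANK_DOWNSTREAM = "TAT" + "TGGGGTCAGGGAACC" + "TCTA"

#: Default pool barcodes: two V-gene contexts x rounds 0 and 3.
#: Pairwise Hamming distance 6, so one-mismatch demultiplexing is unambiguous.
DEFAULT_BARCODES: dict[str, str] = {
    "vh4_r0": "ACGACG",
    "vh4_r3": "CGTCGT",
    "vh10_r0": "GTAGTA",
    "vh10_r3": "TACTAC",
}

#: (round-0 pool, round-3 pool) pairs sharing a V-gene context.
DEFAULT_ROUND_PAIRS: tuple[tuple[str, str], ...] = (
    ("vh4_r0", "vh4_r3"),
    ("vh10_r0", "vh10_r3"),
)


class SchemeError(ValueError):
    """Invalid degenerate-codon scheme or unencodable peptide."""


@dataclass(frozen=True)
class DegenerateCodonScheme:
    """Positional IUPAC codon template of the HCDR3 library plus its anchors.

    Parameters
    ----------
    codon_templates
        Nine IUPAC codon strings, one per HCDR3 residue.
    flank_upstream, flank_downstream
        Unambiguous literal anchor sequences immediately flanking the 27-nt
        insert in the amplicon.
    """

    codon_templates: tuple[str, ...] = DEFAULT_CODON_TEMPLATES
    flank_upstream: str = DEFAULT_FLANK_UPSTREAM
    flank_downstream: str = DEFAULT_FLANK_DOWNSTREAM

    def __post_init__(self) -> None:
        if len(self.codon_templates) != 9:
            raise SchemeError(
                f"expected 9 codon templates, got {len(self.codon_templates)}"
            )
        object.__setattr__(self, "codon_templates", tuple(self.codon_templates))
        for j, tpl in enumerate(self.codon_templates):
            if len(tpl) != 3:
                raise SchemeError(f"codon template {j + 1} is not length 3: {tpl!r}")
            for ch in tpl:
                if ch not in IUPAC_DNA:
                    raise SchemeError(
                        f"codon template {j + 1} has non-IUPAC character {ch!r}"
                    )
        for name, flank in (
            ("flank_upstream", self.flank_upstream),
            ("flank_downstream", self.flank_downstream),
        ):
            if not flank or any(c not in "ACGT" for c in flank):
                raise SchemeError(
                    f"{name} must be a non-empty unambiguous ACGT string: {flank!r}"
                )

    # -- geometry ---------------------------------------------------------

    @property
    def hcdr3_nt_length(self) -> int:
        return HCDR3_NT_LENGTH

    def amplicon_length(self, barcode_length: int) -> int:
        return (
            barcode_length
            + len(self.flank_upstream)
            + HCDR3_NT_LENGTH
            + len(self.flank_downstream)
        )

    # -- expansions -------------------------------------------------------

    def position_choices(self, pos: int) -> str:
        """Concrete bases allowed at 0-based nucleotide position ``pos`` (0-26)."""
        tpl = self.codon_templates[pos // 3]
        return IUPAC_DNA[tpl[pos % 3]]

    def codon_expansion(self, codon_index: int) -> list[str]:
        """All concrete codons matching template ``codon_index`` (0-based)."""
        tpl = self.codon_templates[codon_index]
        return [
            "".join(bases)
            for bases in itertools.product(*(IUPAC_DNA[c] for c in tpl))
        ]

    def codons_for_residue(self, codon_index: int, aa: str) -> list[str]:
        """Concrete template-compatible codons encoding residue ``aa``.

        Translation uses the amber-suppressed code (TAG -> Q).
        """
        return [
            c for c in self.codon_expansion(codon_index) if CODON_TO_AA.get(c) == aa
        ]

    def peptide_codon_options(self, peptide: str) -> list[list[str]]:
        """Per-position codon options for a 9-residue peptide.

        Raises
        ------
        SchemeError
            If some residue cannot be encoded at its position, naming the
            offending residue and position.
        """
        if len(peptide) != 9:
            raise SchemeError(f"peptide must be 9 residues, got {len(peptide)}")
        options = []
        for j, aa in enumerate(peptide):
            codons = self.codons_for_residue(j, aa)
            if not codons:
                raise SchemeError(
                    f"residue {aa!r} at HCDR3 position {j + 1} is not encodable "
                    f"by codon template {self.codon_templates[j]!r}"
                )
            options.append(codons)
        return options

    def n_encodings(self, peptide: str) -> int:
        """Number of distinct nucleotide encodings of ``peptide`` under the scheme."""
        n = 1
        for codons in self.peptide_codon_options(peptide):
            n *= len(codons)
        return n

    def matches(self, hcdr3_nt: str) -> bool:
        """True if a 27-nt sequence conforms to the degenerate template."""
        if len(hcdr3_nt) != HCDR3_NT_LENGTH:
            return False
        return all(
            hcdr3_nt[i] in self.position_choices(i) for i in range(HCDR3_NT_LENGTH)
        )
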