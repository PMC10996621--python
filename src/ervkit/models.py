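"""Core domain types shared across the pipeline.

An ERV family is described by its consensus: a long terminal repeat (LTR)
sequence and an internal sequence. At integration a provirus has the structure
LTR–internal–LTR flanked by a short target-site duplication (TSD); ectopic
recombination between the two LTRs later collapses copies to solo LTRs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .seq import check_dna

# Structure classes of a genomic copy (also used by the synthetic truth table,
# which additionally records ABSENT / DELETED strain states).
FULL_PROVIRUS = "FULL_PROVIRUS"
SOLO_LTR = "SOLO_LTR"
TRUNCATED = "TRUNCATED"
ABSENT = "ABSENT"
DELETED = "DELETED"

STRUCTURE_CLASSES = (FULL_PROVIRUS, SOLO_LTR, TRUNCATED, ABSENT, DELETED)


@dataclass(frozen=True)
class ErvFamilyModel:
    """Consensus model of one ERV family.

    Parameters
    ----------
    family_name:
        Family label used in hit tables and truth tables.
    ltr_seq, internal_seq:
        Consensus LTR and internal DNA (upper-case ACGT).
    tsd_len:
        Expected target-site-duplication length in bp (0 allowed; many LTR
        retroelements duplicate 4-6 bp of host sequence at integration).
    expected_gag_aa:
        Length in amino acids of the full Gag protein encoded by the internal
        region; the reference against which copy ORFs are scored.
    """

    family_name: str
    ltr_seq: str
    internal_seq: str
    tsd_len: int = 5
    expected_gag_aa: int = 0

    def __post_init__(self) -> None:
        check_dna(self.ltr_seq, "ltr_seq")
        check_dna(self.internal_seq, "internal_seq")
        if self.tsd_len < 0:
            raise ValueError("tsd_len must be >= 0")

    @property
    def ltr_len(self) -> int:
        return len(self.ltr_seq)

    @property
    def internal_len(self) -> int:
        return len(self.internal_seq)

    @property
    def element_len(self) -> int:
        return 2 * len(self.ltr_seq) + len(self.internal_seq)

    @property
    def element_seq(self) -> str:
        """Full-length consensus element: LTR + internal + LTR."""
        return self.ltr_seq + self.internal_seq + self.ltr_seq

    def part_seq(self, part: str) -> str:
        if part == "LTR":
            return self.ltr_seq
        if part == "INTERNAL":
            return self.internal_seq
        raise ValueError(f"unknown element part {part!r}")
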