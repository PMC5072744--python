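"""Published summary numbers from the HIV-1 x *Schistosoma mansoni*
integration survey, used as worked-example inputs.

These are the printed per-chromosome assembly lengths and integration
counts of the draft *S. mansoni* assembly (eight chromosome pairs including
Z/W, the mitochondrion, and unplaced scaffolds), the non-redundant event
totals of the two LTR-end amplicon libraries, and the whole-genome
sequencing tallies that feed the per-nucleus burden estimate.  They are
inputs to the arithmetic modules, not outputs of this package.
"""

from __future__ import annotations

#: assembly length (bp) per chromosome; "Unplaced" aggregates scaffolds
CHROMOSOME_LENGTHS: dict[str, int] = {
    "1": 79_986_414,
    "2": 38_216_055,
    "3": 38_028_725,
    "4": 34_586_772,
    "5": 10_324_086,
    "6": 20_039_393,
    "7": 11_043_263,
    "ZW": 61_504_481,
    "MT": 19_871,
    "Unplaced": 70_778_700,
}

#: mapped integrations per chromosome, 5'-LTR-end library
INTEGRATIONS_5: dict[str, int] = {
    "1": 405, "2": 186, "3": 189, "4": 176, "5": 51,
    "6": 107, "7": 61, "ZW": 279, "MT": 8, "Unplaced": 291,
}

#: mapped integrations per chromosome, 3'-LTR-end library
INTEGRATIONS_3: dict[str, int] = {
    "1": 1363, "2": 710, "3": 676, "4": 594, "5": 181,
    "6": 332, "7": 180, "ZW": 930, "MT": 17, "Unplaced": 1082,
}

#: non-redundant integration positions per LTR-end library
UNIQUE_POSITIONS: dict[int, int] = {5: 1_827, 3: 6_258}

#: unique 250-bp clusters per LTR-end library
UNIQUE_CLUSTERS: dict[int, int] = {5: 1_753, 3: 6_065}

#: exon / intron / non-coding base fractions of the assembly
GENOME_REGION_FRACTIONS: tuple[float, float, float] = (0.04, 0.39, 0.57)

#: fraction of mapped integration sites falling in non-coding sequence
NONCODING_SITE_FRACTION: float = 0.62

# --- whole-genome sequencing burden inputs ---------------------------------

#: integrations detected in the WGS evidence categories (35 in-read + 25
#: mate-split events)
WGS_DETECTED_INTEGRATIONS: int = 60
#: properly mapped pair total of the WGS run
WGS_PROPER_PAIRS: int = 207_576_406
WGS_READ_LENGTH: int = 100
#: genomic DNA input to the WGS library (ng) and diploid genome mass (pg)
WGS_LIBRARY_DNA_NG: float = 1_700.0
DIPLOID_GENOME_MASS_PG: float = 0.79
#: nuclei in a 48-hour schistosomulum
NUCLEI_PER_ORGANISM: int = 1_000


def assembly_length() -> int:
    """Total assembly length in bp (364,527,760)."""
    return sum(CHROMOSOME_LENGTHS.values())


def total_unique_positions() -> int:
    """Non-redundant events summed over both LTR-end libraries."""
    return sum(UNIQUE_POSITIONS.values())
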