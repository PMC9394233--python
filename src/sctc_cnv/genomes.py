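"""Bundled reference-genome constants.

Chromosome lengths are the standard hg19 (GRCh37) primary-assembly lengths for
chr1-22, X and Y.  Centromere positions are cytoband-derived approximations
(rounded to 0.1 Mb); they determine p/q arm assignment for the arm-level QC and
do not need base-pair accuracy for that purpose.
"""

from __future__ import annotations

HG19_CHROM_LENGTHS: dict[str, int] = {
    "chr1": 249250621,
    "chr2": 243199373,
    "chr3": 198022430,
    "chr4": 191154276,
    "chr5": 180915260,
    "chr6": 171115067,
    "chr7": 159138663,
    "chr8": 146364022,
    "chr9": 141213431,
    "chr10": 135534747,
    "chr11": 135006516,
    "chr12": 133851895,
    "chr13": 115169878,
    "chr14": 107349540,
    "chr15": 102531392,
    "chr16": 90354753,
    "chr17": 81195210,
    "chr18": 78077248,
    "chr19": 59128983,
    "chr20": 63025520,
    "chr21": 48129895,
    "chr22": 51304566,
    "chrX": 155270560,
    "chrY": 59373566,
}

# Approximate centromere midpoints (hg19), bp.  Bins starting before the
# midpoint belong to the p arm, the rest to the q arm.
HG19_CENTROMERES: dict[str, int] = {
    "chr1": 125000000,
    "chr2": 93300000,
    "chr3": 91000000,
    "chr4": 50400000,
    "chr5": 48400000,
    "chr6": 61000000,
    "chr7": 59900000,
    "chr8": 45600000,
    "chr9": 49000000,
    "chr10": 40200000,
    "chr11": 53700000,
    "chr12": 35800000,
    "chr13": 17900000,
    "chr14": 17600000,
    "chr15": 19000000,
    "chr16": 36600000,
    "chr17": 24000000,
    "chr18": 17200000,
    "chr19": 26500000,
    "chr20": 27500000,
    "chr21": 13200000,
    "chr22": 14700000,
    "chrX": 60600000,
    "chrY": 12500000,
}

#: Arms dropped from the arm-distribution QC by default: the acrocentric p arms
#: (13p, 14p, 15p, 21p, 22p) carry almost no uniquely mappable sequence, and the
#: sex-chromosome arms are excluded so the reference panel can mix donors of
#: both sexes.
DEFAULT_EXCLUDED_ARMS: frozenset[str] = frozenset(
    {"13p", "14p", "15p", "21p", "22p", "Xp", "Xq", "Yp", "Yq"}
)

AUTOSOMES: tuple[str, ...] = tuple(f"chr{i}" for i in range(1, 23))
SEX_CHROMOSOMES: tuple[str, ...] = ("chrX", "chrY")


def strip_chr(name: str) -> str:
    """Return the chromosome name without a leading ``chr`` prefix."""
    return name[3:] if name.startswith("chr") else name


def add_chr(name: str) -> str:
    """Return the chromosome name with a leading ``chr`` prefix."""
    return name if name.startswith("chr") else f"chr{name}"


def arm_name(chrom: str, start: int) -> str:
    """Arm label (e.g. ``"1p"``) for a position on an hg19 chromosome."""
    cen = HG19_CENTROMERES[add_chr(chrom)]
    return f"{strip_chr(chrom)}{'p' if start < cen else 'q'}"


def all_arm_names() -> list[str]:
    """All 48 hg19 arm labels in karyotype order."""
    out = []
    for chrom in list(AUTOSOMES) + list(SEX_CHROMOSOMES):
        base = strip_chr(chrom)
        out.extend([f"{base}p", f"{base}q"])
    return out
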