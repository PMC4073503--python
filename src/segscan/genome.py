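"""Reference genome scaffold: the 16 S. cerevisiae nuclear chromosomes.

Chromosome sizes are the S288C reference lengths (bp).  They anchor the
synthetic marker map; nothing in the analysis depends on the exact values,
only on there being 16 linkage groups of realistic, unequal length.
"""

from __future__ import annotations

CHROMOSOME_SIZES_BP: dict[str, int] = {
    "chrI": 230_218,
    "chrII": 813_184,
    "chrIII": 316_620,
    "chrIV": 1_531_933,
    "chrV": 576_874,
    "chrVI": 270_161,
    "chrVII": 1_090_940,
    "chrVIII": 562_643,
    "chrIX": 439_888,
    "chrX": 745_751,
    "chrXI": 666_816,
    "chrXII": 1_078_177,
    "chrXIII": 924_431,
    "chrXIV": 784_333,
    "chrXV": 1_091_291,
    "chrXVI": 948_066,
}

CHROMOSOMES: tuple[str, ...] = tuple(CHROMOSOME_SIZES_BP)

_ORDER = {name: i for i, name in enumerate(CHROMOSOMES)}


def chrom_sort_key(label: str) -> tuple[int, str]:
    """Sort key placing the canonical 16 chromosomes first, in karyotype
    order, and any other label after them lexicographically."""
    return (_ORDER.get(label, len(_ORDER)), label)
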