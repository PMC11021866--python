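"""Published summary statistics of the jujube fruit-size QTL-seq study.

These printed values — parental and F1 trait moments, variant-calling
census counts, and the combined-index candidate interval — are inputs the
package consumes: the simulator anchors its trait scales to them and the
reproduction script recomputes the derived quantities (CV, mid-parent
values, heterosis rates, Ts/Tv, interval size) from them.
"""

from __future__ import annotations

#: Parental trait means for the cross ('JMS2' female x 'J5' male).
PARENT_TRAIT_MEANS: dict[str, tuple[float, float]] = {
    "single_fruit_weight_g": (11.40, 15.79),
    "fruit_length_mm": (35.78, 44.72),
    "fruit_diameter_mm": (24.83, 26.82),
    "fruit_shape_index": (1.44, 1.67),
}

#: F1 trait mean and SD on the measurement scale (n = 284 lines).
F1_TRAIT_SCALE: dict[str, tuple[float, float]] = {
    "single_fruit_weight_g": (10.50, 3.52),
    "fruit_length_mm": (35.69, 5.31),
    "fruit_diameter_mm": (23.83, 2.89),
    "fruit_shape_index": (1.50, 0.18),
}

#: SNP census from the variant-calling annotation of the four samples.
SNP_CENSUS = {
    "upstream": 191_893,
    "stopgain": 1_757,
    "stoploss": 274,
    "synonymous": 80_145,
    "nonsynonymous": 98_147,
    "intronic": 357_677,
    "splicing": 523,
    "downstream": 180_087,
    "upstream/downstream": 18_197,
    "intergenic": 2_622_790,
    "transitions": 2_260_594,
    "transversions": 1_292_240,
    "total": 3_552_834,
}

#: InDel census (same annotation run).
INDEL_CENSUS = {
    "upstream": 77_639,
    "stopgain": 122,
    "stoploss": 38,
    "frameshift deletion": 2_060,
    "frameshift insertion": 1_357,
    "non-frameshift deletion": 1_552,
    "non-frameshift insertion": 1_343,
    "intronic": 97_808,
    "splicing": 245,
    "downstream": 58_873,
    "upstream/downstream": 6_987,
    "intergenic": 570_664,
    "insertions": 398_001,
    "deletions": 420_787,
    "total": 818_788,
}

#: Candidate interval called by the combined (All-index) scan, in bp
#: (chromosome 1, 30.72 Mb to 32.23 Mb).
ALL_INDEX_INTERVAL = ("chr1", 30_720_000, 32_230_000)
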