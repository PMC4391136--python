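"""Normalize a tiny KO table into average genomic copy numbers.

Builds a three-sample table over four marker genes and two ordinary genes,
length-normalizes it, and divides each sample by the median marker
abundance. Marker genes occur once per genome, so after normalization their
median is exactly 1 in every sample and every other value reads as "copies
per genome of a typical community member".
"""

import pandas as pd

import scgnorm as sg

counts = pd.DataFrame(
    {
        # columns differ by a 10x / 100x depth factor on purpose
        "shallow": [120, 95, 110, 105, 240, 40],
        "medium": [1200, 950, 1100, 1050, 2400, 400],
        "deep": [12000, 9500, 11000, 10500, 24000, 4000],
    },
    index=["M1", "M2", "M3", "M4", "geneX", "geneY"],
)
lengths = pd.Series(
    {"M1": 1000.0, "M2": 800.0, "M3": 950.0, "M4": 900.0, "geneX": 1100.0, "geneY": 700.0}
)
markers = sg.MarkerSet(("M1", "M2", "M3", "M4"))

table = sg.AbundanceTable(counts.astype(float), sg.Stage.counts)
normalized = sg.marker_normalize(
    sg.length_normalize(table, lengths), markers, min_detected=4
)

print("average genomic copy numbers:")
print(normalized.data.round(3))
med = normalized.data.loc[list(markers)].median(axis=0)
print("\nmarker median per sample (always 1):", med.round(12).tolist())

# The three columns only differ by sequencing depth, so the corrected
# profiles are identical: marker normalization removes depth entirely.
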