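"""Reported summary counts from the original three-strain *Aedes
aegypti* transcriptome polymorphism survey this package re-implements.

These are inputs for worked-arithmetic checks (percentages, density
folds, strain-specific fractions recomputed from the published tables),
not outputs of this package.  Strains: LVP (the reference-genome
strain), CTM and RexD.
"""

from __future__ import annotations

from typing import Dict

import pandas as pd

STRAINS = ("LVP", "CTM", "RexD")

# Published per-strain effect-class summary: gene-level SNP occurrence
# counts, the strain-specific subset in parentheses in the original
# table, and the number of genes affected.
_EFFECT_ROWS = [
    # class, LVP snps, LVP spec, LVP genes, CTM snps, CTM spec, CTM genes,
    #        RexD snps, RexD spec, RexD genes
    ("NON_SYNONYMOUS", 6577, 1108, 2296, 11815, 3553, 3072, 12327, 3757, 3124),
    ("SPLICE_ACCEPTOR", 180, 91, 168, 160, 56, 146, 137, 39, 126),
    ("SPLICE_DONOR", 168, 89, 152, 128, 46, 115, 119, 32, 105),
    ("START_GAINED", 110, 13, 101, 214, 70, 194, 197, 52, 180),
    ("START_LOST", 10, 3, 10, 20, 6, 19, 17, 3, 17),
    ("STOP_GAINED", 34, 12, 33, 52, 20, 49, 58, 51, 42),
    ("STOP_LOST", 26, 3, 23, 38, 9, 35, 31, 7, 29),
    ("SYNONYMOUS", 29802, 3902, 3312, 55691, 15287, 4111, 57484, 15887, 4128),
    ("SYNONYMOUS_STOP", 23, 2, 23, 36, 11, 36, 42, 14, 42),
    ("UTR_3", 11354, 2100, 2625, 18349, 5111, 3003, 19065, 5283, 3054),
    ("UTR_5", 2844, 486, 1223, 5133, 1506, 1709, 5169, 1461, 1741),
]


def effect_summary_table() -> pd.DataFrame:
    """The published effect summary in summarize_effects' table shape."""
    cols = ["effect_class"]
    for s in STRAINS:
        cols += [f"{s}_snps", f"{s}_specific", f"{s}_genes"]
    return (
        pd.DataFrame(_EFFECT_ROWS, columns=cols)
        .set_index("effect_class")
        .sort_index()
    )


# Published strain-level PS/kb densities over SNP-genes.
PS_PER_KB: Dict[str, float] = {"LVP": 5.05, "CTM": 9.13, "RexD": 9.43}

# Published NTU distance-window totals: candidate NTUs overall and the
# subset outside the 1 kb exon window, plus the subset beyond 10 kb.
N_NTU_TOTAL = 10_321
N_NTU_OUTSIDE_1KB = 7_475
N_NTU_BEYOND_10KB = 2_482

# Published cumulative FPKM-bin counts over the beyond-10 kb NTUs.
NTU_FPKM_BIN_COUNTS = {"LT1": 1702, "GE1_LT10": 259, "GE10_LT100": 53, "GE100": 11}

# Published supercontig tallies: supercontigs with annotated genes, those
# carrying at least one SNP-gene, supercontigs with no SNP-gene, and the
# subset of the latter with a single annotated gene.
N_SUPERCONTIGS_WITH_GENES = 1_636
N_SUPERCONTIGS_WITH_SNP_GENES = 928
N_SUPERCONTIGS_NO_SNP_GENES = 708
N_SINGLE_GENE_NO_SNP_GENES = 392
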