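"""Derive protein consequences for the five exon-12 ARHGAP31 variants.

Builds the synthetic surrogate CDS (wild-type length 1444 residues),
applies each published coding variant, and prints the HGVS p. name,
category and truncation statistics, followed by the ACMG/ACGS point-based
classification of the novel frameshift.
"""

from aoskit import (
    SURROGATE_VARIANTS,
    acmg_classify,
    consequence_table,
    parse_cdna_variant,
    surrogate_cds,
)

cds = surrogate_cds()
variants = [parse_cdna_variant(raw) for raw in SURROGATE_VARIANTS]
table = consequence_table(cds, variants)
print(table.to_string(index=False))
# residues_lost counts wild-type residues missing from each truncated
# protein; stop_offset is the N of fs*N (stop position in the shifted
# frame, first changed residue = 1).

assessment = acmg_classify(
    [("PM2", "moderate"), ("PM4", "moderate"), ("PP3", "supporting")]
)
print(
    f"\nACMG/ACGS: {assessment.points} points -> "
    f"{assessment.classification} ({assessment.vus_tier} tier)"
)
# 5 points lands in the VUS band (0-5); 4-5 points is a 'hot' VUS.
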