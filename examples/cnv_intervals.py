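"""Size and gene content of the published LOH and copy-gain intervals.

Uses the printed GRCh37 coordinates of the chromosome 5 p14-p15 loss of
heterozygosity and the chromosome 14 q11 gain, with a small synthetic
OMIM-gene table, and prints the call report.
"""

from aoskit import (
    CnvCall,
    GenomicInterval,
    example_gene_table,
    size_report,
)

calls = [
    CnvCall(GenomicInterval("chr5", 18055380, 27253029), "LOH",
            subject="II-I"),
    CnvCall(GenomicInterval("chr5", 20021106, 26920010), "LOH",
            subject="II-II"),
    CnvCall(GenomicInterval("chr14", 19100682, 20421677), "gain",
            subject="II-II"),
]

report = size_report(calls, example_gene_table())
print(report.to_string(index=False))
# size_kb floors (end - start) to whole kb: 9197 kb for the proband's LOH;
# size_kb_floor100 gives the coarser "about 1300 kb" figure for the gain.
# The LOH spans six OMIM genes (cadherin cluster + PRDM9 + PMCHL1); the
# gain contains only POTEG.
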