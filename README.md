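# aoskit

Computational characterization of truncating **ARHGAP31** variants of the
kind associated with autosomal-dominant Adams–Oliver syndrome (AOS).
ARHGAP31 is a Rho GTPase-activating protein whose C-terminal domain
auto-inhibits its catalytic RhoGAP domain; frameshift and nonsense variants
in the last exon remove that domain and leave a constitutively active
protein. Characterizing such a variant computationally involves several
distinct analyses, and `aoskit` packages all of them behind one tested
Python API:

* **Variant consequences** (`aoskit.seq_variants`) — parse HGVS c.
  descriptions (substitution, deletion, insertion, duplication, delins),
  apply them to a validated CDS, translate, and derive the HGVS p. name and
  truncation statistics. A frameshift is named `p.(Xpos Y fs*N)` where `X`
  is the first changed wild-type residue, `Y` the mutant residue there, and
  `N` the stop position in the shifted frame counting the first changed
  residue as 1, so `mutant_length = (first_changed − 1) + (N − 1)`.
* **ACMG/ACGS classification** (`aoskit.acmg`) — point-based evidence
  aggregation (very strong/strong/moderate/supporting = 8/4/2/1, benign
  negative) with the VUS sub-tiers (hot 4–5, warm 2–3, cold 0–1).
* **Structure comparison** (`aoskit.superpose`, `aoskit.structure_io`) —
  Cα traces from PDB files (pLDDT in the B-factor column), Kabsch
  superposition (SVD with proper-rotation correction), an iterative
  weighted superposition with Gaussian down-weighting
  `w_i = exp(−d_i²/⟨d²⟩)`, RMSD, global distance test curves over 1–20 Å
  (plus 2.5 Å), per-residue distance profiles, and all-vs-all comparison
  matrices. Residue correspondence is strictly positional over the common
  prefix — the right convention for wild-type-versus-truncation
  comparisons.
* **CNV/LOH interval arithmetic** (`aoskit.intervals`) — interval sizes
  with the array-CGH reporting conventions (`end − start` floored to kb,
  "about N kb" floored to 100 kb) and gene content against a BED table.
* **qPCR normalization** (`aoskit.expression`) — relative quantities
  `Q = E^(minCt − Ct)`, the geNorm stability measure `M`, geometric-mean
  normalization factors, and an exact two-sided Wilcoxon rank-sum
  carriers-vs-controls comparison.
* **Synthetic data** (`aoskit.synthetic`) — generators for every input:
  helices, random coils, rigid-plus-noise perturbations,
  truncate-and-refold variant structures, random CDSs with planted
  variants of known category, and Ct tables with planted fold changes.
  Includes a deterministic **synthetic surrogate CDS** engineered so that
  the five published exon-12 variants reproduce their printed protein
  consequences exactly (see `docs/methods.md`).

## Worked example

```
python examples/variant_consequences.py
```

prints

```
             raw         kind             hgvs_p   category  wt_length  mutant_length  residues_lost  stop_offset
       c.2047C>T substitution        p.(Gln683*)   nonsense       1444            682            762          NaN
c.2063_2064insTT    insertion        p.(Ser689*) frameshift       1444            688            756          1.0
       c.2182C>T substitution        p.(Gln728*)   nonsense       1444            727            717          NaN
       c.2193del     deletion p.(Thr732Glnfs*26) frameshift       1444            756            688         26.0
       c.3260del     deletion p.(Lys1087Serfs*4) frameshift       1444           1089            355          4.0

ACMG/ACGS: 5 points -> VUS (hot tier)
```

The novel single-base deletion c.2193del shifts the frame at residue 732
(Thr→Gln) and meets a new stop 26 codons into the shifted frame, truncating
the 1444-residue protein to 756 residues — a loss of 688 C-terminal
residues including the auto-inhibitory domain. PM2_Moderate + PM4_Moderate
+ PP3_Supporting sums to 5 points: a variant of uncertain significance in
the "hot" sub-tier.

Other narrative examples: `examples/structure_comparison.py` (six-structure
RMSD matrix, 15 pairwise tests, GDT curves, pLDDT summaries),
`examples/cnv_intervals.py` (LOH/gain sizes and gene content from printed
coordinates), `examples/expression_normalization.py` (geNorm stability and
the null family-study comparison).

A thin CLI wraps the same stages for shell use:

```
aoskit simulate --seed 7 --outdir fixtures
aoskit consequence fixtures/cds.fasta fixtures/variants.txt \
    --acmg PM2:moderate,PM4:moderate,PP3:supporting
aoskit compare fixtures/*.pdb --outdir compare_out
aoskit cnv calls.tsv genes.bed
aoskit expression fixtures/ct_table.tsv
```

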