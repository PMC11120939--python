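# Methods

This note documents the models, conventions and design choices behind
`aoskit`, and what the synthetic generators do and do not emulate.

## Coding variants and protein consequences

Coordinates are coding-DNA (c.) coordinates: position 1 is the A of the
initiator ATG, ranges 1-based and inclusive. The supported HGVS subset is
substitution, deletion, insertion, duplication and delins at the coding
level; intronic/UTR offsets are rejected explicitly rather than silently
misparsed. A deletion written without an explicit base (`c.2193del`) takes
its reference base from the CDS; a spelled-out base is verified against the
CDS and a mismatch is an error that reports expected vs observed.

Consequence derivation is by comparison of full translations, not by local
codon inspection: wild-type and mutant alleles are translated with the
standard genetic code up to the first stop, the first differing residue is
located, and the category follows from the protein-level pattern plus
whether the nucleotide length change is divisible by 3. Frameshift naming
uses the `fs*N` convention in which the first changed residue counts as 1,
so `mutant_length = (first_changed − 1) + (N − 1)`; this identity is
asserted in the constructor and is what makes the arithmetic of a
732-Thr→Gln frameshift with `fs*26` equal a 756-residue product and a
688-residue loss from a 1444-residue protein. Two boundary conventions:

* a frameshift whose first changed codon is itself the new stop
  (`N = 1`) is rendered nonsense-style, e.g. `p.(Ser689*)`, matching how
  such variants are reported in the clinical literature, while the category
  stays `frameshift` (the mechanism is a frame shift);
* in-frame indels that are neither synonymous, missense nor truncating get
  the category `inframe_indel` (an extension of the basic category set —
  without it such edits would be unclassifiable) with best-effort
  `p.(XposDel)`-style names.

A mutant without an in-frame stop is `stop_loss` with a warning and no
`fs*N` (no extension nomenclature attempted); an edit changing residue 1 is
`no_protein`, `p.(Met1?)`. Nonsense-mediated decay is out of scope beyond a
caller-supplied last-exon flag carried through unchanged.

## The surrogate CDS

The real ARHGAP31 transcript sequence is not bundled;
`scripts/fetch_reference_cds.py` downloads it when network access exists.
For offline, reproducible work the package instead ships a **synthetic
surrogate CDS** (`aoskit.synthetic.surrogate_cds`): 4335 nt (1445 codons,
1444-residue product — the real wild-type length) consisting of an Ala
filler with twelve engineered codons. The engineering places Gln codons at
683 and 728 (so the known C>T transitions create stops), a Leu/Ser pair at
688/689 (so the TT insertion leaves Leu 688 intact and puts a TGA at the
next shifted codon), Gly-Thr at 731/732 with downstream shifted-frame
content (so deleting c.2193 reproduces Thr732Glnfs*26, stop offset 26), and
Lys at 1087 with a shifted-frame stop three codons later (Lys1087Serfs*4).
The filler codon GCT is chosen because its shifted readings (CTG, TGC)
contain no stop, so shifted frames terminate exactly where the engineered
stops are placed. The surrogate reproduces the published consequence
*arithmetic*; its protein sequence is otherwise meaningless, and any
analysis sensitive to real sequence content must use the fetched
transcript.

## ACMG/ACGS points

Strength weights are 8/4/2/1 (very strong/strong/moderate/supporting);
benign codes (BA/BS/BP) contribute negatively. Thresholds: ≥ 10
pathogenic, 6–9 likely pathogenic, 0–5 VUS, −6…−1 likely benign, ≤ −7
benign. Only the hot-VUS band (4–5 points) is externally fixed by the ACGS
sub-tiering; warm (2–3) and cold (0–1) complete the convention and are
documented here rather than attributed. The sum is order-invariant and
additive by construction (property-tested).

## Superposition and similarity metrics

Residue correspondence is positional over the common prefix
(`min(L_a, L_b)` pairs), ignoring residue identity: frameshift tails differ
in sequence but still occupy positions that should be compared. The GDT
denominator is the number of paired residues, not the full wild-type
length; the alternative (`denominator="reference"`) is exposed because the
choice is a genuine convention, and the choice used is recorded in run
metadata.

Kabsch superposition computes the weighted cross-covariance of centered
coordinate sets and takes the rotation from its SVD, flipping the sign of
the smallest singular vector when the determinant is negative so the result
is always a proper rotation. Degenerate inputs (< 3 points or collinear
sets, detected via the second singular value) still return the optimal
transform flagged `unique=False`.

The iterative weighted superposition starts from unit weights and
alternates (i) weighted Kabsch, (ii) per-pair distances `d_i`,
(iii) `w_i = exp(−d_i²/⟨d²⟩_w)` with `⟨d²⟩_w` the current weighted mean
squared distance, until the weighted RMSD moves by less than `tol`
(default 1e-6 Å) or `max_iter` (default 20) rounds; non-convergence is
reported, not raised. Weights are floored at 1e-12 to keep the weighted
problem well-posed; a weighted mean square below 1e-24 Å² (identical
structures) short-circuits to convergence. Both the plain RMSD under the
final transform and the weighted RMSD are reported, and the all-vs-all
matrix carries both, because which one a given figure shows is itself a
convention. Matrix symmetry is exact by construction: each unordered pair
is computed once with the longer trace as reference (ties broken
lexicographically by label).

GDT uses a single superposition for the whole threshold grid (default
integers 1–20 Å plus 2.5 Å) — one comparison at variable threshold, not
the CASP per-segment search; an optional `refit_per_threshold` greedy
inlier-refit exists and defaults off. The difference fraction
`1 − fit_fraction` is exported alongside the fit fraction since truncation
studies typically quote the complement ("differ by 90% at ≤ 2.5 Å").

## pLDDT handling

pLDDT is read from the PDB B-factor column. Bins: very high > 90,
confident [70, 90], low [50, 70), very low < 50 — i.e. 90 and 70 belong to
the middle "confident" bin and 50 to "low". Files whose B-factors fall
outside [0, 100] are treated as carrying no pLDDT. Only the first model
and first chain are read (monomer comparisons); extra chains produce a
logged warning.

## Interval conventions

`size_bp = end − start` for 1-based inclusive coordinates: this is the
convention under which the published chr5 LOH coordinates
(18055380–27253029) give exactly 9197 kb after flooring to kb. The
inclusive `+1` alternative is available (`convention="inclusive"`) and
changes none of the floored-kb outputs for intervals of this scale. Coarse
"about N kb" figures floor to the nearest 100 kb (1320 → 1300 for the
chr14 gain). Gene overlap converts the interval to half-open and
intersects with BED spans; an abutting gene is excluded. Note the sibling
LOH coordinates (20021106–26920010) yield 6898 kb, not the "about 6907 kb"
sometimes quoted for them; the computed value is reported as-is. The
packaged gene table (`example_gene_table`) is synthetic: representative
hg19 spans placing the six OMIM genes inside the chr5 interval and POTEG
inside the chr14 gain, not authoritative annotation.

## Expression normalization

Relative quantities use `Q = E^(minCt − Ct)` with efficiency E = 2.0 unless
provided (perfect doubling; no standard curves). The geNorm stability
`M_j` is the mean over other candidates k of the SD (n−1 denominator)
across samples of `log2(Q_j/Q_k)`; stepwise exclusion repeatedly removes
the max-M gene. The group comparison is an exact two-sided Wilcoxon
rank-sum per target gene (asymptotic with tie correction when ties occur):
at family-study sizes (4 vs 6) a rank test is the defensible default, and
the choice is this package's, not attributed to any study. P-values are
reported unadjusted across the four targets, flagged as such. Normalized
values are invariant to sample-wise Ct shifts (loading differences) when
efficiencies are equal — property-tested.

## Synthetic generators: what they emulate and what they do not

Structures: ideal α-helices (radius 2.3 Å, rise 1.5 Å, twist 100°/residue,
giving the canonical ~3.8 Å Cα spacing) and fixed-step random coils.
Variant structures keep the native prefix bit-identical and append a
random-coil tail one Cα step from the last kept residue, with UNK labels
and low pLDDT. This reproduces the *topology* of a truncated/frameshifted
prediction — shared native core, divergent low-confidence tail — but none
of the physics: no excluded volume, no secondary structure in tails, no
global conformational rearrangement of the core upon truncation. Passing
structural tests therefore demonstrate correctness of the metrics and
their calibration (e.g. RMSD → σ√3 under σ = 1 Å noise at n = 2000), not
that real predictor outputs would show any particular RMSD; headline
RMSD/GDT magnitudes from predictor-based studies depend on the predictor's
models and are deliberately out of scope.

Ct tables: reference genes share a per-sample loading offset
(SD 0.8 cycles) plus technical noise (SD 0.3 cycles); targets add group
fold changes on the log2 scale. Defaults mirror a small family study
(3 references, 4 targets, 4 carriers vs 6 controls). Calibration runs use
10 vs 10 so the exact rank test has a non-degenerate rejection region.
The generator does not emulate amplification-efficiency heterogeneity,
missing wells, or outlier replicates.

All generators take explicit integer seeds (numpy `default_rng`, PCG64)
and are deterministic given them.

## Problem sizes

The test suite and `scripts/acceptance.py` run the six-structure set at
quarter scale (wild type 361 residues), 200 random pairs for GDT
properties, 2000 residues for noise calibration, 200 CDS/variant pairs for
the translation oracle, and 500–1000 null replicates for rank-test
calibration — sizes chosen so every property is measured with comfortable
statistical margin while the whole suite stays fast on one CPU.

## Known limitations

* HGVS support is the coding-level subset only (no intronic, UTR,
  inversion, mosaic or allele syntax), and descriptions are taken at the
  position given — no 3'-normalization of the input string.
* No sequence-alignment-based correspondence; comparisons assume the
  shared prefix is structurally homologous position by position.
* No TM-score/lDDT metrics; no flexible superposition.
* CNV detection itself (probe-level calling) and the CNV scoring rubric
  are out of scope; only interval arithmetic on calls is provided.
* The surrogate CDS reproduces published consequence arithmetic, not real
  sequence content.
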