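# Methods

This note documents the models, the default parameters and the design
choices behind `polyarray`, and what the synthetic-data tests do and do
not demonstrate about real data.

## The allo-octoploid model

The genome is modelled as four diverged subgenomes (AABBCCDD), two
homologous copies each, all aligned to a single diploid reference
coordinate system. Subgenome 0 is reference-like; variation is planted
on subgenomes 1–3. Two variant classes are distinguished by their panel
behaviour, not their molecular nature:

* **HSV** — fixed in every panel member (both copies of its subgenome);
* **marker** — carried by 2 … n−2 accessions, homozygous within its
  subgenome in carriers, absent elsewhere.

Markers are planted homozygous-present within their subgenome rather
than heterozygous. This is one of the allelic configurations a real
subgenome-specific marker can take, and it makes the generator's
contract exact: every carrier contributes at least two supporting reads,
so a planted marker always clears the summed read-count minimum (3 for
SNPs, 2 for indels) and the presence ≥ 2 / absence ≥ 2 filters by
construction. Heterozygous-carrier configurations are exercised
separately in the cluster and pedigree simulators.

### Read-count model

Each surviving homoeologous copy contributes `max(Poisson(c/8), 1)`
reads, where `c` is the file's mean coverage. The clip-to-one guarantees
that a carried allele is always observed (the definition of "presence"
is at least one supporting read), which the 100%-recovery property
tests rely on; because the clip inflates per-copy depth identically
inside and outside deletion blocks, the proportionality
`depth(block deleting k of 4 subgenomes) = (1 − k/4) × depth(elsewhere)`
is preserved (verified to 5%). The cost is that sequencing dropout of a
carried allele is not modelled; on real data, low-coverage accessions
lose presence signal and the recovery rate would fall accordingly.

### Default panel conditions

The per-file coverages default to the twenty values of the study's
discovery panel (19 accessions, one sequenced twice), spanning 2× to
48.7×. This reproduces the subpanel structure used for filtration:
HD-16 = the ten files with ≥ 16× (including both files of the
twice-sequenced accession) and HD-20 = the eight files with ≥ 20×.
Presence/absence is counted per *file* by default (matching the
twenty-file panel definition); a `per_accession` switch collapses an
accession's files into one member.

Feature densities (per kb: HSV SNP 0.8, HSV indel 0.1, marker SNP 0.2,
marker indel 0.06, mSNP 0.04, SNP-SNP 0.08, indel-SNP 0.05,
SNP-in-insertion 0.05, diploid 0.08, decoys 0.02 each) are free
parameters of the simulation — the real inter-subgenome divergence is
far higher (tens of variants per kb), but these densities give every
pipeline tens-to-hundreds of truth cases on a desk-scale reference while
leaving the slot grid sparse. Planted features sit on an exclusive grid
(80 bp spacing, 60 bp contig margins) so their 24/30 bp probe-flank
windows are clean by construction; configurations denser than the grid
are rejected with an explicit error rather than silently violating
flank safety.

Deletion blocks (default two blocks of 10 kb, alternately removing one
and two subgenomes in all accessions) model localized biological ploidy
reduction; markers inside a block are assigned to a surviving subgenome.

## Discovery pipelines

All thresholds live in `PipelineConfig` and default to the filtering
rules of the array design: summed read count ≥ 3 (SNP) / ≥ 2 (indel);
presence ≥ 2 and absence ≥ 2 on the selected subpanel; A/T and G/C SNPs
excluded from single-probe categories; flank windows 24/24 bp for SNPs
and 24/30 bp for indels (the extra 6 bp because a 3–6 bp indel extends
the nominal downstream distance); indel candidates 3–6 bp.

HaploSNP search is two-phase: destabilization candidates are variants
present in *all* panel members (HSV-like), marker candidates are SNPs
passing presence/absence, and pairs must satisfy the per-strategy
geometry — HSV SNP within 6 bp; 4–6 bp HSV indel with its nearest edited
base within 14 bp; or a 3–6 bp insertion containing the marker
(implemented as two equal-length insertion alleles at one coordinate
differing at exactly one internal base, jointly present in all members,
with one form segregating). A 24 bp clean window around the marker
admits no variant except the destabilization site, and coupling is
checked at accession level: every file carrying the marker allele must
carry the critical form. Accession-level co-occurrence approximates
read-level phase coupling, which per-accession VCFs cannot express.

Offsets are measured from the marker base to the nearest edited base of
the destabilization site in reference coordinates, with indels at their
left-aligned minimal representation; the measuring convention matters at
the 6/14 bp boundaries and is fixed here once.

The codon-based pipeline scans CDS in reading frame for proline codons
(CCN, strand-aware) and emits the genome coordinate of the 4-fold
degenerate third position when its flanks are clean against the panel.
The speculative alternate allele is defined as the transition partner of
the reference base — the most frequent substitution class, and never an
A/T or G/C pair, so the A/T-G/C filter is applied but passes by
construction.

The mSNP pipeline evaluates presence/absence per non-reference allele; a
site qualifies when at least one allele behaves as a segregating marker
(the others are typically fixed HSV backgrounds). The allele inventory
counts the reference as detected, so di-allelic = one alternate allele.

`spread_selection` allocates a target count over chromosomes by largest
remainder and greedily maximizes the minimum spacing, starting from the
lowest coordinate with ties broken downward — deterministic, and within
a factor of two of the optimal max-min spacing (exact for two picks per
chromosome). Coordinate duplicates across categories resolve by the
array-fill priority: ploidy-reducing categories first, then octoploid
di-allelic SNPs and indels, then diploid-parent, then codon-based.

## Probe design and accounting

Probe geometry is not dictated by the accounting and defaults to 30
bases of the tiled strand ending immediately 5′ of the interrogated
position; allele-specific probes are 31-mers with the allele at the 3′
terminus. HaploSNP flanks carry the critical destabilization form
substituted into the reference sequence; SNP-SNP and indel-SNP sites can
only be tiled on the strand facing their destabilization site.

Accounting rules per tiled strand: standard non-A/T-G/C polymorphism —
one probe, one probeset; A/T or G/C — two allele-specific probes, one
probeset (`pair_as_two` is available per category because one published
category counts such pairs as two probesets); mSNP — four probes, six
pairwise di-allelic probesets (C(4,2) over the tiled bases). The
pairwise rule is a reconstruction: it is the unique simple convention
that reconciles the published mSNP totals (1,414 both-strand + 347
single-strand sites → 12,700 probes and 19,050 probesets). Chip features
are reported as 2 × distinct probes (two replicates each); the published
chip-level feature total is not reproducible from any of the printed
per-category counts and is not targeted.

## Cluster model and caller

Cluster centers follow `A = nA·I_A + bg`, `B = nB·I_B + bg` with all
three constants defaulting to 100 intensity units; simulated samples
multiply each channel by lognormal noise `exp(N(0, σ))` (default
σ = 0.05), keeping intensities positive. Contrast/size are the log-ratio
and mean-log — the standard MvA form, chosen because it reproduces the
qualitative geometry: diploid AB and tetraploid AABB at contrast 0,
B-fixed clusters negative, null-allele samples lowest in size.

The caller is deliberately simple and documented as this package's own
(production array genotyping uses proprietary clustering): per marker, a
1-D Gaussian mixture on contrast with 1–3 components chosen by BIC, EM
initialized from quantiles so repeated runs are identical; when the data
contain at most three distinct contrast values (noise-free simulations)
the unique values are used as clusters directly. Confidence is one minus
the assigned posterior; calls above the threshold become NoCall. The
default threshold is 0.01 — the stringent setting appropriate at high
ploidy where the heterozygous cluster approaches a homozygous one
(0.15 is the usual diploid default; both are exposed).

**Null-allele (OTV) detection.** Null-null samples show background-only
signal in *both* channels, so they sit below every hybridizing cluster
in size and near zero contrast. The detector splits the size
distribution at its largest low-half gap (minimum gap 0.2 size units)
and accepts the low group as a null cluster only if it is
contrast-neutral (mean |contrast| within the 90th percentile of the
remaining samples). The contrast-neutrality condition is essential: an
8x B-fixed locus has a legitimately low-size BB cluster, but at extreme
negative contrast, and a plain low-size rule would misclassify it. A
global-mean-offset rule was evaluated and rejected because no single
offset both catches true nulls and spares those homozygote clusters
under the equal-constants intensity model.

Quality classes follow a fixed decision order, so every marker lands in
exactly one class: call rate < 0.97 → CRBT; one cluster → MHR; a null
cluster present → OTV; two clusters → NMH; three clusters → PHR, which
then must pass the post-filters (100% replicate reproducibility; cluster
variance in either dimension no more than 4× the median same-marker
cluster variance, with a 1e-9 floor so exact simulated data never
trip it; minor-homozygote count ≥ 3) to remain in the filtered PHR set;
anything else → Other. The 4× variance ratio is a calibration on
synthetic data — the filters' purpose (flagging hidden extra clusters)
is specified, their numeric thresholds were not.

HomRO = min(contrast_AA, −contrast_BB) over the homozygous clusters
present, computed from empirical cluster means; ≥ 0.3 classifies a
marker as clustering like a diploid. This formula reconstructs the
verbal definition (displacement from zero of the homozygous cluster
nearest it, positive when the homozygotes flank zero).

OTV recalling recodes null-cluster samples to ∅∅ and, where a null
allele segregates, homozygote calls to A∅/B∅ — a four-cluster AA × BB
family becomes A∅ × B∅ with progeny classes {A∅, AB, B∅, ∅∅}.

## Validation statistics

Concordance: a progeny call is concordant iff producible from one allele
of each parent under disomic inheritance, with ∅ transmissible like any
allele. Markers with a parental NoCall are discarded; a non-concordant
fraction above 5% of informative progeny discards the marker; at or
below 5% the offending calls become missing and the marker is retained
(individual-sample miscalls are the more likely cause at that rate).

Sequence-derived genotypes use a one-sided lower-tail binomial test at
the least-favourable point (1/8) of the composite null "minor allele
frequency ≥ 1/8" — the expectation for a heterozygous subgenome-specific
SNP among eight homoeologous copies. With fewer than 20 reads no call is
made; p < 0.05 calls the major-allele homozygote, otherwise
heterozygous. Ties (k = n/2) are heterozygous by construction. The
sequence-vs-array comparison tabulates match, het-seq/hom-array,
hom-seq/het-array, opposite homozygotes, and the not-comparable reasons
(no array call, > 2 alleles, insufficient reads).

MAF is computed from dosage-collapsed calls (two allele observations per
sample; null alleles form their own class when present) as the frequency
of the rarest allele class, capped at 0.5; classes: monomorphic (0),
low (< 0.10), polymorphic (≥ 0.10), highly polymorphic (≥ 0.35).

## Problem sizes

The test suite runs the full discovery stack on a 500 kb, 19-accession
panel with ~280 planted markers across all categories (about 5 s), and
the shared fixtures use a 60 kb panel; cluster properties use 300-sample
markers. These sizes give every filter boundary multiple truth cases
while keeping the whole suite under a minute.

## Limitations

* No read-level simulation: alignment artifacts, PCR duplicates and
  mapping bias — major real-world sources of spurious variants — are
  absent, so 100% recovery on synthetic panels bounds the pipeline
  logic, not real-data sensitivity.
* Allele dropout is excluded by the clipped-Poisson read model (see
  above).
* Indel normalization is minimal-representation trimming; reference
  left-alignment is assumed to have happened upstream (realignment is
  out of scope).
* The mixture caller is a documented stand-in with no claim of numeric
  equivalence to production array-genotyping software; the
  vendor-style reproducibility score is a pluggable input (unscored
  candidates count as neutral), not a re-trained model.
* Coupling of marker and destabilization alleles is checked at
  accession, not read, level.
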