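# Methods

## The study system

The package models a diploid ~77 kb gene with 15 exons, of which exons
3–14 are coding (CDS 1416 bp; the ATG sits inside exon 3 after a 150 bp
exonic 5'UTR).  Four long-range PCR amplicons of 20,600 / 22,000 / 20,600 /
23,000 bp tile the locus with 3.0 / 3.0 / 4.0 kb overlaps, covering the
5'UTR–exon 1, intron 1, exons 2–3 and exons 4–14 respectively.  A recurrent
structural variant deletes 19,971 bp spanning the second half of intron 1
through 3,885 bp of intron 3 — removing exons 2 and 3 and with them the
translation start — and inserts 16 bp (`CCAATGCTAAGGTTGA`) at the junction.
On the deletion allele the forward primer of amplicon 3 and the reverse
primer of amplicon 2 are gone, so that haplotype fails exactly amplicons 2
and 3: the dropout signature the pipeline detects.

All coordinates are 1-based inclusive at the interface and 0-based
half-open internally.

### Coordinate conventions

Coding positions are standard HGVS `c.N`; intronic positions downstream of
the start-codon exon use nearest-exon offsets (`c.120+3887`, `c.430-1`);
exonic positions 5' of the ATG within exon 3 are `c.-N`.  Positions 5' of
exon 3 (exons 1–2, introns 1–2, promoter) use a *linear-genomic-offset*
convention, `c.1-K` with K the genomic distance to c.1.  Standard HGVS
would anchor such positions to the noncoding exons; the linear convention
is adopted because it is the one used in this gene's clinical literature
for the large deletion's left breakpoint, and the package's goal is to
produce names practitioners will recognise.  `docs`-level consequence: the
deletion-insertion renders as
`c.1-15966_c.120+3885delinsCCAATGCTAAGGTTGA`.  (Published descriptions of
such events sometimes print an interval two bases wider than the deleted
base count when junction-adjacent positions are counted inclusively at
both ends; this package always reports the net deleted length and the
interval consistent with it.)

### Variant model and normalization

A variant is a replacement edit (pos, ref, alt); insertions anchor after
`pos`.  Normalization trims the shared affix of ref/alt and shifts pure
indels to their 3'-most placement, so any two descriptions of one edit —
e.g. the repeat-context aliases `c.1227delTATTGTGCCTAT` and
`c.1228_1239delATTGTGCCTATT` — compare equal; the 5'-most alias is kept
available for reports.  Duplications are recognised when an insertion
copies the reference run immediately 5' of it.

## Synthetic data generation

The locus background is uniform random ACGT under a seed; every functional
feature is planted deterministically: primer sites (each verified unique
under the annealing model, with bounded regeneration on collision), exon
boundaries with canonical GT/AG dinucleotides, ATG/stop codons, the
reference alleles and repeat contexts of the cohort's variant catalogue
(each engineered so the printed variant name is already 3'-canonical), and
the SV junction.  The first and last 16 bases of the deleted segment are
planted to mismatch the insert base-for-base; without this guard a random
background can make an alternative alignment (insert bases absorbed into a
flank as substitutions) strictly cheaper than the intended junction, in
which case "the" breakpoints would not be well defined.  The guard makes
the truth junction the unique parsimony optimum, which is the regime the
assay itself assumes (the source assay reported base-exact, recurrent
breakpoints).

**Marker heterozygosity.** Real diploid loci carry roughly one
heterozygous SNV per kilobase; clustering and phasing live off that
diversity.  The generator plants a panel of 34 benign marker SNV positions
(every ~2.5 kb, all deep intronic or outside the transcript, > 100 bp from
any exon and clear of all primer sites) which `make_table2_cohort(...,
phasing_snvs=True)` places on haplotype 2.  Markers are never reportable
under the study's rule, so truth genotypes are untouched.  Without markers
(default), homozygous spans cannot be phased — the biologically honest
behaviour, reported as ambiguity flags.

**Reads.**  Flat per-base error models: amplicon reads substitution 2% /
insertion 1.5% / deletion 2.5%, lengths 8,000 ± 2,000 (nanopore-like);
whole-locus reads all rates 0.2%, lengths 12,000 ± 3,000 (HiFi-like);
`CORRECTED_ERROR_MODEL` (rates 0.2%, amplicon lengths) stands for reads
after the depth-based error-correction step that long-read pipelines apply
before base-exact breakpoint comparison.  Half of all amplicon reads are
anchored at a product end (adapter-ligated molecule ends), the rest start
uniformly; without end anchoring the product edges — exactly the phasing
overlaps — would be coverage-starved.  Whole-locus reads start uniformly
per haplotype with equal allele probability.  Every read carries its truth
provenance (sample, haplotype, amplicon, template span, strand) in its
FASTQ comment.

**PCR model.**  A primer anneals with ≤ 2 mismatches, none in the
3'-terminal 5 bases; a product forms when convergent sites exist within
the extension ceiling — 25 kb for long-range PCR (3.5-min extension), 2 kb
for the screening PCR (1-min extension).  That ceiling alone explains why
the wild-type deletion-flanking product (20,787 bp) never amplifies in the
screen while the deletion allele yields its 832-bp band
(555 bp retained flank + 16 bp insert + 261 bp flank).  The intron-7
control product is 333 bp.

## Read processing

Alignment is seed-and-extend: an 800 bp read prefix locates the read (both
orientations) and the full read is aligned inside a padded window; the
engine is edlib, the contract the `ReadAlignment` record.  Alignments below
70% identity are rejected (random placements score ~50%, the worst
credible reads ~88%).

**Pileups and event normalization.**  Each read is painted over the
amplicon interval as "reference where covered" overwritten by its
divergence events.  Events are extracted from the CIGAR and consolidated:
runs of events separated by ≤ 8 matched bases whose merged ref/alt trims
to a pure indel are one indel in an equivalent aligner decomposition
(inside repeats, optimal alignments are degenerate — the same 12-bp
deletion surfaces as `del`+`SNV`+`del` on some reads); balanced merges
(substitution blocks, e.g. an `ins`+`del` pair hiding an SNV) are painted
elementwise.  Events are then 3'-shifted so all reads carrying one indel
paint the same columns.

**Het sites.**  A column is heterozygous when two alleles each reach 20%
minor fraction and 5 reads, at ≥ 20 total depth; indel alleles shorter
than 5 bp are collapsed with the reference key (the long-read pileup noise
floor), longer ones keep a deletion key.  Site detection requires ≥ 20
reads, else an insufficient-coverage error.

**Clustering.**  Substitution sites are the clustering currency; indel
columns are used only when no SNV site exists (aligner gap degeneracy can
make a homozygous indel look heterozygous column-wise).  Site polarities
are phased by transitive adjacent-site linkage — reads covering two
neighbouring sites vote whether their alleles ride together — and reads
are assigned by agreement with the phased profile versus its mirror, then
refined with one majority-signature reassignment pass.  (A seed-pair
initialization from the two most dissimilar reads was tried first and
abandoned: on 20 kb amplicons the most dissimilar reads can cover disjoint
site subsets, letting distant site blocks lock in with switched polarity.)
Clusters below 10 reads are flagged low-support.

**Consensus.**  Per-column plurality over cluster members; ties and
columns below 4 reads fall back to the reference base (no-call-as-
reference: prefer missing a variant to inventing one).  Insertions enter
the consensus when a majority of covering reads record one.

**Indel adjudication by hypothesis realignment.**  Column votes degrade
next to indels (errors near the event make each read's decomposition
idiosyncratic), so every non-SNV candidate — from the consensus diff or
harvested directly as a recurrent read event (≥ 4 reads) — is re-decided
by per-read realignment: each member read spanning the site votes for the
local haplotype hypothesis (reference window, or the window with one
observed event applied) nearest in edit distance.  The winner replaces the
call; a reference win removes it.  The distance gap between hypotheses is
the event size, so votes are decisive even for reads carrying unrelated
errors.

## Phasing and dropout detection

At each junction the pairing of upstream and downstream clusters maximises
allele agreement over the overlap; a pairing is accepted only when it
strictly dominates the alternative, otherwise the junction takes an
arbitrary pairing plus an ambiguity flag — a homozygous overlap cannot be
phased by this design, and that is reported, never errored.  An exhaustive
2^(k−1) enumeration oracle (test-only) checks the chaining; because
junction scores are locally decomposable the greedy chain equals the
global optimum wherever it is unambiguous.

An amplicon whose aligned-base mass falls below 0.7 × the mean of the two
deepest amplicons amplified only one allele (expected ratio 0.5 versus
1.0); if noise split its reads into two "clusters" they are re-merged.
The surviving haplotype chains through the gap (flanking-consistency
rule); the other records DROPOUT.  A haplotype with a contiguous internal
DROPOUT run while the other haplotype covers the whole panel is flagged
`sv_candidate` with the amplicon list; both haplotypes dropping the same
amplicon is an assay failure, not an SV.

Variant calling per haplotype diffs each amplicon's consensus against the
reference with the anchored differ (stride-1 unique 32-mer exact runs;
inter-run gaps ≤ 50 bp aligned globally with adjacent events merged within
3 bp; larger gaps emitted as one delins so a 19,971-bp event never
fragments).  Each amplicon is responsible for calls up to its overlap
midpoints, where its coverage is deepest.  The reporting rule keeps exonic
and UTR variants, intronic variants within 10 bp of an exon boundary, and
all structural variants (≥ 50 bp).

## Structural-variant calling

Whole-locus reads are anchor-mapped with unique 24-mers at stride 8; a
read whose collinear segments leave a reference gap ≥ 50 bp (minus its
read gap) observes a junction.  Breakpoints are refined per read by a
changepoint scan between the flanking diagonals (mismatch cost 1, inserted
base cost 0.5; the two ends separate so the scan is linear, with a small
joint scan on conflict).  Observations cluster at ± 10 bp; satellite
clusters within ± 50 bp of a dominant one — reads whose refinement slid
because an error fell between anchor and junction — are absorbed, and
majority vote over all members fixes the breakpoints; the insert is a
per-column plurality over the modal-length observations.  Calls need ≥ 3
supporting reads; zygosity is `het` when junction-free reads also span the
left breakpoint into the deleted interval.  Windowed coverage (500 bp)
provides the orthogonal signal: a heterozygous deletion shows a ~half-depth
trough (measured 33× flank → 16× trough at depth 30).

## Gap-PCR screen

Each donor's two haplotypes run the multiplex assay; classification is a
pure function of the two bands (control+deletion → carrier; control only →
wildtype; deletion only → homozygous deletion; neither → invalid, kept in
the denominator).  Candidates are confirmed by simulating corrected-profile
reads of the deletion-spanning product and requiring junction-call
breakpoint identity with the index variant — a decoy deletion with
different breakpoints classifies as a band-pattern carrier but is demoted
here.  The carrier frequency is reported with a Wilson score 95% interval
(3/600 → 0.50%, CI 0.17–1.46%); Wilson is preferred over Wald for small
proportions and is cross-checked against an independent implementation in
the tests.

## Problem sizes and determinism

Default study conditions: 43-sample cohort (28 + 58 haplotypes), amplicon
depth 30 per haplotype per amplicon, whole-locus depth 30 total, 600-donor
screen with 3 carriers, junction-caller replicates at depth 25–30.  The
test suite exercises the full read-level pipeline on representative
samples covering every variant class and runs the truth-level analysis on
the complete cohort; `analysis/03_readlevel_reconstruction.py --all` runs
the read-level pipeline on all 43 samples.  Every stochastic step takes a
seed or a NumPy generator; identical seeds give byte-identical outputs
(checksummed manifests), and results are independent of thread count.

## Known limitations

- The generator models neither PCR chimeras/recombination artifacts, nor
  barcode demultiplexing, nor quality-score structure beyond a flat
  profile; error rates are position-independent, so homopolymer-biased
  error modes are only partially represented by the flat deletion rate.
- Unmarked homozygous spans cannot be phased (flagged, not resolved), and
  a heterozygous indel < 5 bp with no nearby het SNV can be missed — the
  designed cost of the site-level indel collapse.
- The dropout scan keys on relative amplicon read mass and assumes
  comparable per-allele amplification efficiency across amplicons; strong
  PCR bias between amplicons would need a calibration step the package
  does not model.
- Base-exact per-read breakpoint comparison at raw-nanopore error is not
  decidable (indels inside the junction window); confirmation therefore
  models post-correction reads, matching how real pipelines order
  error correction before breakpoint typing.
- Only deletion-type delins events are called; inversions, duplications
  and translocations are out of scope, as is genome-wide calling.
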