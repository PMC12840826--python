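# Methods

## Gene model and coordinates

A gene model is a plus-strand genomic sequence with ordered, non-overlapping
exon intervals, 1-based inclusive everywhere user-facing; BED input (0-based,
half-open) is converted at the I/O boundary. Minus-strand models are a
non-goal in v1: a coding gene is supplied on its sense strand. The CDS is the
concatenation of exon substrings in genomic order and must be a multiple of 3;
everything non-exonic (introns and any flanks) counts as intron length, so
exon + intron lengths always sum to the genomic length. Translation uses the
standard nuclear genetic code only; the terminal stop is rendered `*` and
**counts as a protein position** (the packaged 6414-nt CDS gives 2138
positions including the stop) — all residue indices in the package assume
this convention. Internal stop codons are reported on the
`ProteinSequence`, never silently truncated; codons containing non-ACGT bases
translate to `X` and are recorded. Genomic→CDS mapping is strictly
increasing and exactly invertible on exonic positions (verified by full
enumeration in the tests); intronic queries return a marker with the distance
to the nearest exon edge.

## Variant classification

Variants are biallelic SNPs with per-population pooled counts `(f, g)` —
observations without and with the change. A population absent from a
variant's count map means *not detected*, which is distinct from `g = 0`
(present but unchanged; the packaged dataset contains no such cell, and the
presence summary surfaces any that occur). Classification substitutes the
alternate base at the SNP's codon offset, assuming the other two positions
carry the reference base (single-SNP assumption, matching per-site
reporting), and compares translated amino acids: synonymous, nonsynonymous,
stop-gained or stop-lost; a stop-retained change (e.g. TAA>TAG) counts as
synonymous since the encoded protein is unchanged. Stop changes and intronic
variants are partitioned into "other" and never enter dN/dS. Multi-allelic
sites are separate records. One published alteration (V1845I, `GTT > ATA`)
changes two codon positions; such linked same-codon substitutions are carried
as an `alt_codon` override on a single primary SNP record (here the offset-0
G>A, which alone already encodes V→I). Plain SNPs always differ from the
reference codon at exactly one offset. SNPs within 2 bases of an exon edge
get a boundary flag; splice-disruption calling is out of scope. The
classifier is checked exhaustively against an independent
Biopython-translation oracle over all 64 codons × 9 substitutions (576
cases).

## Channel topology, canonical numbering, known sites

Topology is an ordered list of labelled protein intervals supplied by config;
positions outside every region label as `unassigned`. The packaged topology
places all 37 fixture variants in their published regions and respects the
published domain partition (415/614/531/578 residues); segment-level
boundaries inside those constraints are synthetic, since no numeric
boundaries are published.

Canonical (house-fly kdr) numbering is a piecewise-offset map supplied as
config, not computed by alignment (an alignment-derived map is a documented
extension). The packaged map encodes the published parentheticals verbatim:
922→918 and 1018→1014 (offset −4), 1845→1851 (offset +6, opposite in sign —
the source leaves the discrepancy unresolved and names no reference species
for either scheme), identity elsewhere. Because the offsets conflict, the
map's image intervals can overlap globally; inversion is therefore defined
per interval.

Known-site matching compares a catalog entry's position against **both** the
variant's canonical and native residue number, because some sites (the SCBI
site V1845I) are catalogued in the species' own numbering in the source
literature; a *full* match additionally requires ref and alt amino-acid
identity, and position-only hits are reported separately as partial matches,
with the matching numbering recorded on the hit. The shipped catalog holds
the four confirmed sites (M918T, L1014F — PyR1; T933I — PyR2; V1845I —
D IVS6/indoxacarb) plus literature-only variants at the same hot spots
(M918L/V, L1014S/H/C/W, T929C, T933C/V) flagged as such.

## Population statistics

The per-cell statistic is *e* = *g*/(*f*+*g*) as a percentage. Display
rounding is 2 dp, half away from zero, computed in exact decimal arithmetic
from the integer counts; statistics are computed on full precision. This
rounding reproduces 127 of the 128 populated cells of the packaged dataset
exactly; the single exception (Y866/TY, printed 22.23) is inconsistent with
its own printed counts (20/90 = 22.22 under any standard rounding) and is
pinned in the tests as a source typo. "Presence" means counts were reported
for the cell at all. dN/dS is the raw nsSNP/sSNP count ratio — deliberately
not a codon-model (NG86/GY94) estimator — with a qualitative flag
(purifying-/neutral-/positive-consistent, neutral band ±0.05 around 1) and a
caveat string, since interpreting count ratios from population SNP data as a
selection statistic requires caution. The latitude trend is formalised as a
Spearman rank correlation between population latitude and per-population
frequency (scipy implementation, mid-ranks for ties, pairwise exclusion of
missing populations; <3 points → insufficient, constant input → degenerate
with ρ = 0). This is an artifact-defined statistic reported without a
significance claim; negative ρ means frequency rises southward.

## Synthetic data

`simulate_gene` draws a clean ORF (ATG start, no internal stops, terminal
stop) and splits it over exons with seeded-random intron lengths; default
totals mirror the study gene (13 exons, 6414 nt CDS, 36,774 nt genomic).
`simulate_observations` plants SNPs whose class is Bernoulli(fraction
nonsynonymous) — rejection-sampling codon/offset/alternate until the codon
arithmetic yields the requested class, excluding stop-involving changes —
then draws each variant × population cell as `g ~ Binomial(depth, p)`,
`f = depth − g`, with depth uniform on the configured range and cells dropped
with the missing rate. Defaults are the study conditions: 37 variants, 6/37
nonsynonymous, five populations on the Hainan latitude gradient, depths
58–156 (the span of published per-cell totals, consistent with pools of
>250 individuals), missing rate 30/185 (the published fraction of undetected
cells). True frequencies are uniform on (0.05, 0.95) by default or, when a
slope is given, logistic in latitude with a per-variant random intercept —
an artifact choice, since the trend is posited verbally in the source without
a model. One seeded generator per simulation; no global random state. The
packaged fixture embeds the published 37-variant count table verbatim and
rebuilds a deterministic synthetic gene around it (fixed internal seed,
published reference codons pinned at the 37 positions, equal 2530-nt
introns).

What the generator does **not** emulate: read-level sequencing error, depth
heterogeneity along the gene, linkage/haplotype structure between sites, and
migration or drift between populations — cells are independent binomials. A
passing recovery test therefore shows the estimator and classifier are
correct under binomial sampling, not that real pooled resequencing is free of
those additional error sources.

## Numerical and design choices

- Exact decimal arithmetic for display rounding (no float ties); frequencies
  and correlations computed in double precision.
- Deterministic ordering: outputs sort by genomic position; CLI outputs are
  byte-identical across runs for identical inputs.
- Interval lookups by binary search; validation errors are specific
  exception types with file/line context at the I/O layer, and the CLI exits
  non-zero on them.
- TSV is the reference variant interchange format; the VCF path is a
  VCFv4.2 subset (SNPs only, counts as per-population `FG_*` INFO pairs)
  via pysam. FASTA I/O via Biopython.
- Simulation sizes used in tests and in the acceptance script (50 variants,
  depth 100, ≤20 seeds, 1000 cells for interval coverage) are the package's
  chosen defaults for calibration checks; they keep binomial standard errors
  small relative to the asserted tolerances.

## Known limitations

Plus-strand, single-gene, biallelic SNPs only; no indels/MNVs (beyond the
linked same-codon override), no phasing or haplotype analysis (the
co-occurrence question for double mutants is explicitly out of scope), no
alignment-based canonical mapping, no codon-model dN/dS, no selection tests,
and no read-level QC — observation counts are taken as given.
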