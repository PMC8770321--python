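# Methods

## Scope and data flow

The package turns aligned ribosome footprints (LTM = initiating ribosomes,
CHX = elongating ribosomes), a genome, a transcript annotation, an
N-terminal PSM table and transit-peptide prediction/localization tables
into: strand-aware P-site tracks and metagene densities; a called-TIS
table; a combined annotated + alternative proteoform FASTA; classified
protein N-termini; per-N-terminus NTA degrees and class summaries; and
cleavage matches, representatives and motif matrices. Read trimming,
alignment, database searching and FDR estimation are upstream concerns:
their outputs are consumed, never recomputed.

## Coordinates

Internally all coordinates are 0-based half-open; GFF3 I/O converts from
1-based inclusive and every report is 1-based. Transcript coordinates run
5′→3′, so position 0 of a minus-strand transcript is its rightmost genomic
base. This makes junction arithmetic uniform: P-site offsets and the ±1-nt
codon windows are applied in transcript space whenever a transcript model
covers the position, with a purely genomic fallback otherwise.

## P-site assignment and tracks

Lengths 26–30/31–33/34 nt map to offsets +12/+13/+14 from the read 5′ end;
anything outside 26–34 nt is rejected and tallied (count conservation:
accepted + rejected = input; track mass = accepted). Every alignment record
contributes one count — multimapped records are not down-weighted, matching
the positional-score definition the caller consumes. Metagene profiles
divide each position's count by the mean count over the CDS plus 20 nt of
flanking leader sequence; genes with fewer than 20 P-sites in the treatment
are excluded, as are zero-denominator genes (both reported). Nucleotide
bins are the default; codon binning is a flag.

## TIS calling

Candidates are LTM positions that hold the maximum count within their 7-nt
window and lie within ±1 nt of the first nucleotide of AUG or one of its
nine single-nucleotide neighbours. Two deliberate tie-breaks, applied
identically in the brute-force test oracle:

* ±1-nt anchoring ambiguity: prefer offset 0, then an ATG anchor over a
  near-cognate, then the most 5′ position.
* Equal-count peaks closer than 4 nt: same order (ATG first, then most 5′).

Scores use `R_k = (X_k/N_k)×10`. `X_k` is the summed P-site count over the
±1-nt codon window (the "combined" footprint count for the TIS) for both
treatments; `N_k` is the transcript total of P-site-assigned reads. A
transcript with zero reads in one treatment contributes `R = 0` for that
treatment rather than silently dropping the candidate. Intergenic
candidates are normalized over a ±500-nt pseudo-transcript (configurable).
Thresholds (count, R-difference) default to 5/0.01 for annotated starts,
10/0.05 for leader and intergenic TIS, 15/0.15 for CDS-internal TIS.
Annotated starts failing the criteria are emitted as `rescued_dbTIS` when
the CDS carries at least `rescue_min_chx` (default 10) CHX P-sites —
"elongating occupancy" has no canonical operational definition, so the
floor is exposed in configuration. Candidates matching several transcripts
take the dbTIS context if any, else the maximal R-difference; per
(gene, position) one record with maximal R-difference is kept.

## Proteoform database

Translation from a TIS always decodes residue 1 as Met (initiator tRNA),
then walks the codon table to the first in-frame stop; ORFs reaching the
transcript end without a stop are emitted with a `no_stop` flag. In-frame
CDS-internal TIS yield truncated proteoforms that are exact parent suffixes
apart from residue 1; 5′-leader TIS in frame with, and running into, the
CDS are labelled `extended`, other leader TIS `leader_ORF`, intergenic TIS
`intergenic_ORF` (translated from a bounded genomic window). Out-of-frame
CDS-internal TIS are called and reported but not translated — they encode
no proteoform of the annotated gene product. Entries shorter than 7
residues are dropped (mirroring the minimum peptide length the search
consumes). Exact duplicate sequences collapse onto the first accession with
a cross-reference in the mapping table; accessions are self-describing:
`GENE|TIS:<chrom>:<pos>:<codon>|<relation>`.

## N-terminus classification

PSMs are kept at q ≤ 0.01 (default), grouped by (protein, start), collapsed
to the longest peptide variant across enzymes and missed cleavages, and
flagged low-evidence below 2 PSMs. NME compliance: a start at iMet+1 needs
a small exposed residue (A, C, G, P, S, T, V — canonical MetAP
specificity, exposed in configuration); a retained iMet is compliant in
strict mode (default) only when residue 2 is *not* small, since MetAPs
would otherwise have removed it; lenient mode accepts any retained Met.
Strict mode is the default because every retained-Met entry in the shipped
benchmark has a non-small residue 2. NAT classes: exposed A/S/T/V/G/C →
NatA; M + D/E/N/Q → NatB; M + L/I/F/W/Y/K/H/R/M → NatC/E/F; exposed P →
refractory; everything else none. Acetylation observed on a refractory
N-terminus is flagged, not rejected — partial acetylation is documented
broadly and the rules act as a biological filter, not a hard veto.

Origins partition every record: starts 1/2 of an annotated entry are dbTIS
(this precedence also resolves a start matching a dTIS of one entry and
position 1/2 of another); a start at the iMet or iMet+1 of a called
in-frame dTIS that passes NME is dTIS; a start within the cleavage window
of a cTP/mTP prediction is a cTP/mTP neo-terminus; simultaneous dTIS and
cTP matches give the ambiguous `dual_dTIS_cTP` label; NME-failing dTIS
matches are demoted to `internal_neo`, as are all unmatched internal
starts. Shared peptides follow parsimony (the record's assigned accession).

## NTA degree

Degree = `100·L/(L+H)`, the acetylated fraction: the reported percentages
are bounded in [0, 100], which a literal light-over-heavy ratio is not; the
Δ5 Da pairing identifies the precursor pair, not the formula. Intensities
are summed across contributing pairs before the ratio (per-pair degrees and
their spread reported; a mean-of-pairs mode is available). Pairs come from
the PSM table's modification/intensity columns — mass-based pairing belongs
to the search engine. Class summaries suppress groups below five
observations.

## Cleavage annotation

The window is inclusive ≤ 5 residues around the predicted P1′ (the P5–P5′
region); an exclusive `< window` reading is available since both phrasings
circulate. Deviation is signed `start − P1′` (negative = upstream). Within
each protein, starts linked transitively at ≤ 5 residues form one cluster
whose most upstream member is the representative (primary processing site;
downstream members are aminopeptidase ragging). Representative selection is
restricted to proteins with the configured consensus compartment (default
chloroplast); proteins missing from the localization table are excluded and
reported. Motif matrices cover P5…P1/P1′…P5′ with a gap symbol for sites
too close to the protein start; columns are frequency-normalized including
the gap row, so they sum to 1. Mitochondrial-prediction matches observed
acetylated are flagged, as no mitochondrial NTA machinery is known.

## Synthetic data: what it emulates and what it does not

The generator defines the study conditions for all tests. Defaults: 20
genes (CDS 180–540 nt, leaders 60–180/40–120 nt), 30% intron-containing,
50% with an in-frame dTIS (70% AUG, otherwise a near-cognate), leaky
fraction 0.3, 20% of genes with an upstream ORF, 100 LTM initiation events
per TIS, 200 CHX reads per gene with decay constant 0.004 nt⁻¹ and 85%
frame-0 periodicity, read lengths peaked at 28 nt over 26–34 nt, 20% of
LTM P-sites jittered ±1 nt, 5% off-target reads. Proteomics side: trypsin
and Glu-C N-terminal peptides (no missed cleavages), 2–4 PSMs per enzyme
per N-terminus, co-translational degrees NatA 85 / NatB 95 / NatC-E-F 10 /
refractory 0 / none 5 percent, stromal residue-specific degrees A 34.9 /
S 36.3 / V 60.3 / T 45 percent, aminopeptidase ragging of 0–3 residues,
intensity CV 0.10 (log-normal), 10% decoy records with q > 0.01. Planted
transit peptides (30% cTP, 10% mTP) carry the (V/I)-X-(A/C)↓A cleavage
motif, except genes where the cleavage site deliberately coincides with
the dTIS (the ambiguous dual case), whose P1 stays the initiator Met. The
sequencing noise levels of real libraries are not published; these defaults
are stated placeholders, all exposed in `SimConfig`.

Simplifications to keep the truth well-defined: near-cognate dTIS are
always given an NME-permissive following residue (so the observed peptide
sequence matches the parent protein exactly); raw reads, sequencing error,
spectral peaks and retention times are not simulated; intensity pairs are
generated at the planted degree rather than from isotope envelopes. Passing
tests therefore demonstrate correctness of the coordinate arithmetic,
calling criteria, rule tables and stoichiometry estimators under the
planted model — not robustness to aligner artefacts or search-engine
errors.

## Numerical and testing choices

All randomness flows from one integer seed through per-stage `numpy`
substreams, so identical (seed, config) reproduce byte-identical outputs.
The TIS caller is validated against a brute-force position-enumeration
oracle (independent plumbing, naive loops) on simulated and random tracks;
translation against an independently keyed codon-table walk; collapsing,
aggregation and representative selection against naive group-by recounts.
Problem sizes in the test suite (2–60 genes, ≤ 50 kb tracks, 100 random
trials, 50 intensity pairs per planted degree) were chosen as the smallest
sizes at which the statistical checks have comfortable margins. Degenerate
inputs: zero-read transcripts score R = 0; both-zero intensity pairs are
skipped and reported; empty PSM tables propagate to empty proteomics
outputs with a successful exit.

## Known limitations

No machine-learning TIS rescoring or uORF functional analysis; no decoy
generation or FDR estimation; no transit-peptide prediction (TargetP-style
output is consumed); sequence-logo rendering is out of scope (frequency
matrices are produced). Genome-scale call sets from the public Arabidopsis
libraries require the deposited raw data and are outside desk scale.
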