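# Methods

## The detection model

A microProtein (miP) is operationally defined here by three sequence
properties: homology to at least one transcription factor (TF) of the
query class, absence of every *unwanted* domain accession (the DNA-binding
domains), and a length compatible with a truncation of its target
(≤ 1.1× the target length). Detection is therefore a homology search
followed by set- and length-based pruning; no structural or expression
evidence enters the model.

Candidate generation is two-tiered because a single cutoff cannot serve
both conserved and diverged miPs. The alignment length found in a search
is inversely related to the achievable E-value, so small diverged proteins
need a permissive cutoff — which would flood a one-tier search with noise.
The permissive tier is therefore restricted to proteins under 200 aa and
guarded by a reciprocal requirement: a forward hit only survives if the
candidate, used as a query, hits the TF set in a reverse search. The
reverse hits, not the forward ones, define the candidate's credited
targets: the forward hit establishes candidacy, while the reverse search
states which TFs the candidate resembles when the evidence is read in the
direction that matters. A protein found by both tiers keeps tier-1
provenance and the union of targets at the minimum E-value per pair.

## Thresholds and boundary conventions

| parameter | default | meaning |
|---|---|---|
| `max_mip_length` | 550 aa | tier-1 subject bound (exclusive) |
| `small_protein_length` | 200 aa | tier-2 subject bound (exclusive) |
| `tier1_cutoff` | 1e-7 | stringent forward E-value |
| `tier2_cutoff` | 0.5 | permissive forward E-value |
| `reverse_cutoff` | 0.1 | reverse-rescue E-value |
| `length_ratio` | 1.1 | candidate/target length tolerance (inclusive) |

"Shorter than 550/200 aa" is read strictly (a 550-aa protein is excluded;
a 549-aa one is not), and "larger than 1.1×" is read strictly (a 440-aa
candidate against a 400-aa target is exactly at the boundary and is
kept). A proteome record whose id equals a query-TF id is never a
candidate — without this rule every sub-550-aa TF would trivially report
itself. The length-ratio filter is applied per candidate–target pair, and
a candidate survives if at least one pair survives; the foreign-domain
filter then takes its target union over surviving targets only. Filter
order is fixed (unwanted-domain → length-ratio → foreign-domain) and each
stage's survivor count is logged.

## Homology engine and E-value statistics

The built-in engine computes optimal Smith–Waterman local alignments
under affine gaps (a gap of length *g* costs `gap_open + (g−1)·gap_extend`;
defaults BLOSUM62, 11/1) via Biopython's `PairwiseAligner`, and converts
raw scores to E-values with the Karlin–Altschul formula
`E = K·m·n·e^(−λS)`, where *m* is the query length and *n* the summed
residue count of the database partition. λ = 0.267 and K = 0.041 are the
published gapped BLOSUM62/11/1 constants, fixed rather than re-derived per
run for determinism. No finite-size (edge-effect) correction, length
adjustment, composition-based statistics, or low-complexity (SEG) masking
is applied, so absolute E-values differ somewhat from BLAST+'s; the
pipeline only relies on a calibrated, monotone E-value with the usual
cutoff semantics, and users who need BLAST-exact numbers can feed
precomputed 12-column tabular files through the replay backend, which
produces identical pipeline output for identical hits. The ambiguity
residue `X` is scored as the worst-case substitution (the matrix minimum),
so ambiguous stretches can never create signal. At most one hit per
(query, subject) pair is kept — no multi-HSP sum statistics — because the
pipeline consumes only pair membership and the best E-value.

## Domain annotation

Architectures are unordered accession sets; multiplicity and domain order
are ignored because every filter is a set-membership statement. Imported
InterProScan TSV rows are keyed on the integrated InterPro accession
(column 12); member-database signatures without one are skipped. The
built-in scanner matches exact consensus motifs (with `.` as a
single-residue wildcard, minimum length 6) and exists so that fixtures and
tests run without external annotation; it is not an HMM and cannot detect
degenerate domains — e.g. an HLH domain that has lost its basic residues
is invisible to it, exactly as such domains can be missed by real domain
mapping. A candidate with zero mapped domains is kept (the filters can
only act on mapped domains) and flagged with `-` in the output's domain
column.

## The synthetic benchmark

`FixtureSpec` defaults generate, from a single seed (42), 2 TF families ×
2 TFs (350–500 aa), each family with a unique 14-aa DBD motif near the
N terminus and a unique 16-aa PPI motif near the C terminus in random
uniform-composition flanking sequence. Planted classes:

* 6 tier-1 miPs (80–180 aa): C-terminal truncations retaining the intact
  PPI motif, diverged at 5% per residue outside motifs.
* 3 tier-2 miPs (< 200 aa): random sequences sharing only a ~36-aa PPI
  neighborhood diverged at 45% — calibrated so their best TF alignment
  falls between the tier-1 and tier-2 cutoffs. Because the alignment-score
  landscape is stochastic, the generator verifies detectability by
  actually searching, and redraws offending sequences (bounded rounds)
  rather than trusting a divergence calculation.
* 4 decoys per class: DBD-retaining truncations (killed by the
  unwanted-domain filter); oversized DBD-free paralogs at
  `1.1 × TF length + 2` aa (killed by the length-ratio filter — they are
  generated *without* the DBD motif precisely so that the length filter,
  not the DBD filter, is what removes them; if the required length would
  reach 550 aa they are generated above it and are partition-killed
  instead); truncations carrying an extra motif absent from all TFs
  (killed by the foreign-domain filter); and unrelated random sequences
  (redrawn if they ever hit a TF by chance).

What passing on this benchmark shows: every search branch, the reverse
rescue, and each filter is individually load-bearing, with exact boundary
behavior. What it does not show: performance on real proteomes — uniform
residue composition flatters E-value statistics, motifs are exact rather
than profile-degenerate, there are no splice isoforms, no low-complexity
regions, no convergent domains, and family sizes are tiny. Recall 1.0 /
precision 1.0 here is a correctness statement about the pipeline logic,
not an accuracy claim about biology.

## Threshold sweep

`sweep` evaluates a cutoff grid by running each search once at the loosest
cutoff of its axis and re-thresholding per grid point; hit sets are
monotone in the cutoff, so this shortcut is exact (and is itself tested
against naive full runs). The selected combination follows the
recall-driven rule: maximize recall, then take the most stringent cutoffs,
breaking ties lexicographically by (tier-1, tier-2, reverse) — the
tie-break order is a package choice, as is the default 3×3×3 grid.
Precision/target accuracy are reported as undefined (`-`/NaN) rather than
0 when their denominators are empty.

## Problem sizes and determinism

The default benchmark is 29 proteins (~7,000 residues), chosen so that a
full simulate + predict + sweep cycle completes in seconds on one CPU
while still exercising every code path; all randomness flows from the one
spec seed, and equal specs produce byte-identical FASTA/TSV outputs and
prediction tables.

## Known limitations

Tier-2 target credit ignores the forward hit's TF when the reverse search
credits a different one. Identical sequences under different ids are not
deduplicated. The 550-aa bound applies to subjects only, not to TF
queries. Nucleotide input, GFF/XML InterProScan dialects, compressed
files, and profile-based (PSI-BLAST-like) iteration are out of scope.
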