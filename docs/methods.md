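# Methods

## The classification model

A *family rule* is a pair of domain-id sets (mandatory M, forbidden X)
with M non-empty and M ∩ X = ∅. Given the set D of domains hit on one
(sequence, frame) at or below the acceptance E-value cutoff, family F is
**satisfied** iff M(F) ⊆ D and X(F) ∩ D = ∅. Classification then runs in
one of two modes:

- **strict** — assign iff exactly one canonical family is satisfied. Zero
  satisfied families yields `forbidden-domain-present` when some family
  failed only on a forbidden hit, else `no-rule-satisfied`; two or more
  yields `multi-family-conflict`. This reproduces the conservative
  behaviour of rule pipelines that refuse to choose among families such as
  CCAAT-HAP3 (requires NF-YB) and CCAAT-HAP5 (requires NF-YC) when a
  sequence hits both subunits' domains.
- **best-domain** — among satisfied families, the one whose
  mandatory-domain hit is strongest wins. "Strongest" is interpreted as
  lowest E-value, with bit score (higher first) and then lexicographic
  family name as deterministic tie-breaks. By construction this mode
  assigns a superset of what strict mode assigns.

Frames are classified independently: a nucleotide sequence may receive
assignments on several of its six reading frames.

Family names are canonicalised through a one-step synonym map (alias →
canonical) before counting, so a sequence whose satisfied families are
all aliases of one canonical family is not a conflict. The default hit
acceptance cutoff is E ≤ 1e-3, configurable; published workflows state
their per-search thresholds but not the HMM acceptance cutoff, so a
conventional permissive value is used.

## Consensus merge

Sources are ordered by priority, by default `ruleP` (rule-pipeline
proteins) > `TFcatT` > `iTAKT` > `ruleT` (transcript claims). Proteins
are processed first regardless of their slot in a custom priority order,
because protein presence for (sequence, family) suppresses that
sequence's transcript claims for the same family on any frame — the
per-family (not global) reading of the acceptance procedure; the
alternative is auditable through the dedup log, which records every
eliminated record with the surviving source. The dedup key for
transcripts is (sequence, frame, family): one sequence may legitimately
carry accepted records for two families (multi-domain loci), which is why
repertoire totals satisfy domains ≥ sequences ≥ genes rather than being
equal.

## Representation statistics

The query species is always the numerator. The similarity band
[lower, upper] = [0.9, 1.1] is closed ("between" read inclusively) and
"over"/"under" are strict inequalities. The band is deliberately not
reciprocal-symmetric (1/1.1 ≈ 0.909): swapping query and comparator can
change a call near the bounds, and a test pins this. Families absent from
exactly one species are flagged (`absent-query` / `absent-comparator`)
rather than given infinite or zero ratios, and are excluded from the
(n_under, n_similar, n_over) summary. Ploidy correction divides
comparator counts before ratio formation on the raw-count basis only
(shares are scale-invariant); halving uses half-away-from-zero rounding
so 13419/2 → 6710. Display rounding is 2 d.p. for shares and 1 d.p. for
percent differences; all comparisons run on unrounded values.

## Alignment curation

The filter order is fixed: duplicate/low-coverage rows (coverage
strictly < 0.30 removed), then gappy columns (gap fraction ≥ 0.90
removed), then near-duplicates (pairwise identity ≥ 0.95, greedy scan
keeping the first seen). Identity is computed on the current alignment —
matching non-gap positions over columns that are not gaps in both rows —
not on re-aligned pairs; whether "95% similarity" means identity or a
substitution-matrix score is ambiguous in the source workflows, and
identity is the cheapest faithful reading. The cycle
(align → filters → re-align) terminates when a cycle's filters change
neither the row nor the column count; since filters only remove, the
(rows, columns) pair is lexicographically non-increasing and termination
is guaranteed, with a `max_cycles` safety bound (default 20, warning on
hitting it). The aligner is an injected callable: MAFFT or any other tool
in production, a deterministic padding stub in tests. Motif-discovery
defaults are recorded in `MOTIF_DISCOVERY_DEFAULTS` (E ≤ 0.001, width
8–200, any-repeat mode, ≤ 100 motifs); curated sequences are rebuilt by
concatenating a sequence's motifs sorted by start (ties by end, then
motif id), with overlaps concatenated literally.

## Clade assignment

Default method is nearest-anchor: each query leaf takes the group of the
anchor minimising patristic distance, with ties broken by smaller
query-to-MRCA distance, then lexicographic group. The
smallest-anchored-clade alternative takes the group of the smallest
enclosing clade containing an anchor, provided its anchors agree;
otherwise the leaf stays unlabeled. Source studies never state their
rule, so both readings are implemented. Trees presenting a basal
multifurcation are treated as unrooted and rejected unless explicitly
midpoint-rooted at load time, because root placement changes the
root-to-tip group order. That order ranks groups by the edge-count depth
of each group's MRCA (branch-length depth as tie-break), with exact ties
reported as ties. Bootstrap supports are carried through but never used
in assignment.

## Expression linking

Best-hit links use an inclusive cutoff (E ≤ 1e-5) and the tie chain
lowest E-value → highest bit score → lexicographic subject id; homolog
rescue uses a strict cutoff (E < 1e-3) and counts distinct subjects.
The two cutoffs' strictness matches the respective procedure
descriptions, and both are configurable. Source texts state the rescue
threshold inconsistently as 1e-3 and 10e-3; 1e-3 is adopted. Heatmap
matrices preserve all-missing rows for unlinked queries so rows stay
aligned with tree tips; log10(x+1) transformation is off by default.

## What the synthetic generator emulates — and does not

Planted domains are fixed 15-residue motif strings derived
deterministically from the domain id, embedded in uniform-random
background residues, so a trivial exact-match scanner stands in for an
HMM caller in tests; synthetic E-values are 10^(−length/2) capped at
1e-300 (monotone in match length, realistic magnitudes). Transcripts
reverse-translate each protein with one codon per amino acid, add uniform
0–30 nt UTRs (enough to exercise all six frames without dominating
length) and a random strand, recording the true frame. Each family gets a
unique primary mandatory domain, so no family's mandatory set is a subset
of another family's planted architecture — the structural property that
makes zero-noise recovery well-defined, as in real curated rule sets.
Default generator conditions: ~60/40 mandatory/forbidden split of the
domain vocabulary (mirroring the published 134/89 rule mix), 1–2 mandatory
domains per family, 1–2 gene models per gene, and decoys carrying one of
their family's forbidden domains at the configured rate.

Deliberately not emulated: phylogenetic sequence evolution, codon-usage
bias, realistic domain-model emission probabilities, partial/degraded
domain matches, and alignment uncertainty. Passing tests therefore
demonstrate the correctness of the rule logic, merge semantics, counting
and statistics on architecturally faithful inputs — not robustness to
remote-homology noise in real genomes.

## Problem sizes and numerical choices

The end-to-end recovery checks run on a 500-gene genome (35 families × 14
genes + 10 background genes, 1–2 models per gene), large enough for every
count granularity to differ while keeping the default test run fast. The
rule-engine oracle enumerates all 2^6 hit subsets for 200 random rule
sets over six domains in both modes; the clade oracle checks 50 random
20-leaf trees against an exhaustive patristic-distance table computed
through an independent tree library. All generators are seeded; identical
seeds produce byte-identical FASTA/TSV outputs. Degenerate inputs are
defined, not errors: empty rule sets load with a warning, frames shorter
than one codon translate to empty peptides, empty hit tables classify to
empty assignment tables, and zero-denominator shares are reported as NaN.

## Known limitations

- The bundled rule file is a synthetic reconstruction with the published
  shape (111 families, 134 mandatory + 89 forbidden rules); real rule
  configs drop in unchanged.
- Real summary triples of over/similar/under-represented families depend
  on genome assemblies that are not shipped; the mechanism is validated
  on synthetic and published-count tables instead.
- The MEME text parser is deliberately lenient and targets the
  "sites sorted by position p-value" tables; the 5/6-column TSV is the
  robust interchange format.
- Alignment and similarity search are consumed as external contracts
  (callables/files), never re-implemented.
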