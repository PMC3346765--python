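# Methods

## The problem

N-linked glycans attach to asparagine residues in the sequon N-X-(S/T),
where X is any amino acid except proline. A single amino-acid substitution
(a non-synonymous SNV mapped to protein coordinates) can destroy an
existing sequon — by replacing the asparagine, replacing the serine or
threonine with something else, or placing a proline at the X position — or
create a new one by the converse changes. `glycosnv` classifies those
events across a proteome, aggregates them into survey tables, and tests
whether event-carrying proteins are enriched for functional categories,
carry more variants per residue than the background, or sit in particular
secondary-structure contexts.

## Sequon model and classifier

A sequon is anchored at its asparagine: anchor `a` (1-based) is a sequon
iff `seq[a] == N`, `seq[a+1] != P` and `seq[a+2] ∈ {S, T}`. Overlapping
occurrences are all counted (NNSS has anchors 1 and 2). Windows containing
any ambiguity code (B, Z, X, U, O) have unknown status and are treated as
non-sequons; since the same predicate is used before and after a
substitution, ambiguous windows can never generate events.

A variant at position `p` can only change anchors `p-2`, `p-1`, `p`. The
classifier checks exactly those three windows on the reference and the
mutated sequence; the mechanism follows from the offset `p - a`:

| offset | loss mechanism        | gain mechanism      |
|--------|-----------------------|---------------------|
| 0      | `N_SUBSTITUTED`       | `N_INTRODUCED`      |
| 1      | `PRO_INTRODUCED_AT_X` | `PRO_REMOVED_AT_X`  |
| 2      | `ST_SUBSTITUTED`      | `ST_INTRODUCED`     |

A full-rescan diff (`diff_sequons`) — scan both whole sequences, take the
anchor set differences — is kept as an independent oracle; the test suite
asserts exact agreement on tens of thousands of random (protein, variant)
pairs. Variants are evaluated one at a time against the reference sequence;
compound genotypes are out of scope.

**Loss scope.** Whether a sequon is actually occupied in vivo is unknown
for most sites, so losses can be counted either only at annotated
glycosites (`loss_scope="annotated"`, the default — the convention of a
survey that trusts curated glycosylation annotation) or at every detected
sequon (`"all"`). Gains are always counted proteome-wide. Every event
carries both its raw identity and the policy-filtered `counted` flag, so
the choice is auditable after the fact; under the annotated scope, a
`classify` run without a glycosite table is a hard configuration error
rather than a silent scope change.

## Survey aggregation

Headline counts are computed over counted events: sites are distinct
(accession, anchor) pairs per direction, variants are distinct
substitutions, and the union count deduplicates proteins with events in
both directions (which is why the union can be smaller than the sum).
Integer percentages are rounded to the nearest integer with halves away
from zero — the only convention consistent with ratios like 226/3680 → 6%
and 917/20242 → 5% appearing together in survey-style reporting.

The multiplicity distribution counts distinct affected sites per protein
and three narrative buckets: proteins whose single annotated site was lost,
proteins that lost all their annotated sites, and previously
non-glycosylated proteins gaining sites.

In the amino-acid frequency table, the motif role of N is the anchor and
the motif role of S/T is the third position only (an S at the X position is
inside a sequon but not part of its chemistry, so it is not counted as a
motif residue). Variants with `ref == letter` split into those causing a
counted loss at that role versus "abolishing outside"; variants with
`alt == letter` split likewise for gains. "Confirmed" glycoproteins are
those with ≥1 experimental-evidence site; "annotated" means any evidence
level — evidence stratification is carried through rather than collapsed
because occupancy knowledge is incomplete.

## Statistics

**Category enrichment.** For a category with `k` members among `N`
background proteins, the expected count in an `n`-protein dataset is
`n·k/N` (kept unrounded). The direction is *over* iff observed > expected,
and the p-value is the one-sided exact binomial tail at rate `k/N`
(PANTHER-style); an exact hypergeometric tail (sampling without
replacement) is available via `test="hypergeom"` and matters only when the
dataset is a large fraction of the background. Significance is judged on
the raw p-value at α = 0.05 by default; Benjamini–Hochberg q-values can be
reported alongside (`correction="bh"`) but do not change the significance
flag, so users can apply their own threshold. The discrete test is
conservative: its attainable size at n = 200, rate 0.1 is 0.0434, which the
calibration test verifies empirically over 500 null replicates.

**Variant density.** The background rate is total nsSNVs divided by total
residue count; the expected dataset count is that rate times the dataset's
summed protein lengths, with a one-sided binomial p-value in the observed
direction.

**Secondary structure.** DSSP's eight states are collapsed to five classes:
H/G/I → helix, E/B → strand, T → turn, S → bend, `-` → loop. Sites are
distinct (accession, variant position) pairs of counted events; positions
without SS coverage are excluded and their count reported. If background
positions are supplied, expected per-class counts proportional to the
background class frequencies are attached. Fractions sum to 1 over
classified sites.

## Synthetic data

The generator emulates the statistical structure the analysis assumes, not
any particular organism. Defaults (the study conditions used throughout the
tests unless stated): 200 proteins of uniform length 200–600, uniform
amino-acid composition (a human-like composition preset exists for realism;
tests use uniform for analyzability), sequons planted by direct motif
insertion at 2 per 100 residues plus whatever motifs arise by chance,
proline-blocked N-P-(S/T) triplets planted at 0.5 per 100 residues (real
proteomes are rich in these, and they supply eligible sites for the
proline-removal gain class), 30% of sequons annotated as glycosites with an
evidence mix of 25% experimental / 50% by-similarity / 25% predicted, and
500 variants drawn from an effect mix of 10/10/5% losses (N, S/T, proline),
15/10/2% gains (N, S/T, proline removal) and 48% motif-neutral.
Categories are Bernoulli labels at 5% baseline membership; designated
planted categories have that probability multiplied (capped at 1) for
proteins carrying at least one realized event. SS tracks are i.i.d.
per-residue draws with helix-heavy/loop-heavy frequencies (31% loop, 25% H).

Ground truth is defined by rescan, not intention: each planted variant's
realized effect is recomputed with `diff_sequons`, so accidental motifs
created or destroyed beyond the intended one are part of the truth and the
recovery comparison is exact (precision = recall = 1.0 is the pass
condition, not an approximation). Neutral variants are rejection-sampled
until the rescan confirms no change. One numpy `default_rng` stream drives
a run; the seed is recorded as a `#` comment line in the generated TSV and
truth files (FASTA has no comment syntax, so the seed is not embedded
there).

What the generator does *not* emulate: linkage between variants, allele
frequencies, codon-level mutational bias, sequence autocorrelation
(domains, low-complexity regions), or the correlation between secondary
structure and sequence. Passing tests therefore demonstrate the
correctness of the bookkeeping and statistics under the stated model, not
that real annotation databases are internally consistent.

## Numerical and I/O choices

- Coordinates are 1-based inclusive on the canonical sequence; isoforms
  are out of scope.
- Exact duplicate variants by (accession, position, ref, alt) are merged,
  pooling ids and sources ("unique variations" semantics).
- Ref-allele mismatches against the sequence are a hard error by default;
  `on_inconsistent="skip"` (CLI `--skip-inconsistent`) downgrades to a
  logged warning, because merged public sources routinely disagree. The
  package takes no position on which policy matches any upstream survey.
- Binomial tails come from `scipy.stats.binom` (log-space internally),
  verified against full pmf enumeration for all n ≤ 30 at 1e-12.
- `percent_of` uses exact rational arithmetic before rounding, so halves
  are never mis-rounded by floating point.
- Result writers sort rows (accession, position, anchor) and fix column
  order, so identical inputs give byte-identical files.
- Enrichment ties (observed == expected) are reported as *under* with the
  lower-tail p (≥ 0.5), i.e. never significant — a deliberate tie-break.

## Problem sizes

The default test-suite and acceptance-script runs use 200-protein /
500-variant simulations (plus one 1000-protein / 250-variant run for the
enrichment and density statistics, where the affected set must be a
minority of the background for the contrast to be meaningful); oracle
equivalence runs on 10,000 random pairs and calibration on 500 null /
100 planted replicates. These sizes give stable statistics while keeping a
full run in seconds.

## Known limitations

- Only the canonical NX(S/T), X ≠ P motif is detected; rarer acceptor
  motifs (e.g. N-X-C) are not, though the window predicate is the single
  point of extension.
- Loss/gain is motif arithmetic: no occupancy prediction, no accessibility
  or folding context, no O-glycosylation.
- Inputs are protein-level substitutions; DNA-level reasoning (codons,
  splice effects) is out of scope.
- The flat category model has no ontology structure; enrichment treats
  labels independently.
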