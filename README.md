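# glycosnv

Loss and gain of N-glycosylation sequons caused by missense variants.

N-linked glycans attach to asparagine in the sequon **N-X-(S/T)**, where X
is any amino acid except proline. A single amino-acid substitution can
destroy an existing sequon (replace the N, replace the S/T, or put a
proline at X) or create a new one by the converse changes — with real
functional consequences for secreted and membrane proteins. `glycosnv` is
for proteomics and glycobiology researchers who want to run that analysis
over a proteome: it scans sequences for sequons, classifies every
protein-level variant as a loss, gain or neutral event (with mechanism),
aggregates survey tables, and tests the affected protein set for category
enrichment, variant density and secondary-structure context. A seeded
synthetic-data generator with rescan-derived truth labels makes the whole
pipeline testable end to end.

## The model

A sequon anchored at 1-based position *a* of sequence *s* requires

```
s[a] = N,   s[a+1] ≠ P,   s[a+2] ∈ {S, T}
```

A variant at position *p* can only affect anchors *p−2, p−1, p*; the
classifier inspects those three windows before and after the substitution,
and a full-rescan diff over the whole sequence serves as an independent
oracle in the tests. Losses can be restricted to annotated glycosites
(`loss_scope=annotated`, the default) or counted at every sequon; gains
always count proteome-wide.

Category enrichment uses the classic expected count
*E = n·k/N* (dataset size *n*, category members *k* in a background of
*N* proteins) with a one-sided exact binomial tail at rate *k/N*
(hypergeometric available by flag); variant density compares per-residue
nsSNV rates the same way; secondary-structure context maps DSSP codes onto
helix / strand / turn / bend / loop.

## Worked example

Simulate a 50-protein proteome with truth-labeled variants, then run the
full pipeline on the generated files:

```
$ glycosnv simulate --seed 11 --n-proteins 50 --n-variants 100 --out sim
INFO glycosnv: simulated 50 proteins, 485 sequons, 100 variants

$ glycosnv all --fasta sim/proteome.fasta --variants sim/variants.tsv \
    --glycosites sim/glycosites.tsv --categories sim/categories.tsv \
    --ss sim/ss.tsv --truth sim/truth.tsv --loss-scope annotated --out run
truth recovery: precision=1.0000 recall=1.0000 (51 matched events)
INFO glycosnv: pipeline complete: 51 events, 23 proteins affected
```

`run/survey.json` then contains (abridged):

```json
{
  "n_proteome": 50,
  "n_annotated_glyco": 45,
  "n_loss_proteins": 10,  "n_loss_sites": 10,
  "n_gain_proteins": 16,  "n_gain_sites": 21,
  "n_affected_union": 23,
  "pct_loss_of_annotated": 22
}
```

Reading: of 50 proteins, 45 carry at least one annotated glycosite; 10
proteins lost 10 annotated sites, 16 proteins gained 21 new sequons, and
23 distinct proteins were affected overall (the union is smaller than
10 + 16 because some proteins have events in both directions). The truth
recovery line compares classified events against the generator's
rescan-derived ground truth — the pipeline is deterministic, so exact
agreement is the expected outcome, not an approximation.

`run/events.tsv` lists one row per (variant, anchor) event:

```
accession  variant_id  position  ref_aa  alt_aa  anchor  direction  mechanism      ...
SYN00001   sim00008    500       T       N       500     gain       N_INTRODUCED
SYN00001   sim00018    520       P       S       518     gain       ST_INTRODUCED
```

The same operations are importable directly:

```python
from glycosnv import ProteinRecord, VariantRecord, classify_variant

protein = ProteinRecord("P01008-like", "A" * 166 + "NKS" + "A" * 5)
variant = VariantRecord("P01008-like", 167, "N", "T")
[event] = classify_variant(protein, variant, loss_scope="all")
# event.anchor == 167, event.direction == "loss", event.mechanism == "N_SUBSTITUTED"
```

## Input formats

FASTA for sequences (bare or UniProt-style `db|ACC|NAME` headers); TSV
with header for variants (`accession position ref_aa alt_aa variant_id
source`), glycosites (`accession asn_position evidence`), categories
(`accession category_type category_id`) and per-residue secondary
structure (`accession codes`, DSSP alphabet). All positions are 1-based
on the canonical sequence; `.` marks missing values. Native UniProt flat
files, VCF and DSSP output are deliberately not parsed — convert to these
dialects first (UniProt CARBOHYD feature lines map directly onto the
glycosite table; any variant annotation tool that emits protein
coordinates can fill the variant table).

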