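"""Survey aggregation: headline counts, keyword tabulations, motif amino-acid
frequencies and per-protein multiplicity distributions.

Counts are computed over *counted* events only, so the active loss-scope
policy flows through unchanged from the classifier.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Optional, Sequence

from .io import (
    CategoryAnnotation,
    GlycositeAnnotation,
    ProteinRecord,
    VariantRecord,
)
from .sequon import (
    GAIN,
    LOSS,
    N_INTRODUCED,
    N_SUBSTITUTED,
    ST_INTRODUCED,
    ST_SUBSTITUTED,
    Sequon,
    SequonChangeEvent,
)


def percent_of(part: int, whole: int) -> int:
    """Integer percentage, rounded to nearest with halves away from zero.

    This is the rounding convention consistent with printed survey-style
    percentages such as 3680/20242 -> 18 and 226/3680 -> 6.
    """
    if whole == 0:
        raise ZeroDivisionError("percent_of undefined for whole == 0")
    if part < 0 or whole < 0:
        raise ValueError("counts must be non-negative")
    q = Fraction(100 * part, whole)
    return int(math.floor(q + Fraction(1, 2)))


@dataclass
class SurveySummary:
    """Headline counts of the loss/gain survey (Table-1 style)."""

    n_proteome: int
    n_annotated_glyco: int
    n_confirmed_glyco: int
    n_loss_proteins: int
    n_loss_sites: int
    n_loss_variants: int
    n_gain_proteins: int
    n_gain_sites: int
    n_gain_variants: int
    n_affected_union: int
    pct_annotated_of_proteome: Optional[int]
    pct_loss_of_annotated: Optional[int]
    pct_gain_of_proteome: Optional[int]
    keyword_tables: dict[str, dict[str, dict[str, int]]] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "n_proteome": self.n_proteome,
            "n_annotated_glyco": self.n_annotated_glyco,
            "n_confirmed_glyco": self.n_confirmed_glyco,
            "n_loss_proteins": self.n_loss_proteins,
            "n_loss_sites": self.n_loss_sites,
            "n_loss_variants": self.n_loss_variants,
            "n_gain_proteins": self.n_gain_proteins,
            "n_gain_sites": self.n_gain_sites,
            "n_gain_variants": self.n_gain_variants,
            "n_affected_union": self.n_affected_union,
            "pct_annotated_of_proteome": self.pct_annotated_of_proteome,
            "pct_loss_of_annotated": self.pct_loss_of_annotated,
            "pct_gain_of_proteome": self.pct_gain_of_proteome,
            "keyword_tables": self.keyword_tables,
        }


def summarize_dataset(
    proteome: Sequence[ProteinRecord],
    glycosites: Sequence[GlycositeAnnotation],
    events: Sequence[SequonChangeEvent],
    categories: Optional[Sequence[CategoryAnnotation]] = None,
) -> SurveySummary:
    """Aggregate counted events into the survey summary.

    Sites are distinct (accession, anchor) pairs per direction; variants are
    distinct substitutions per direction; the union count deduplicates
    proteins carrying events of both directions. Confirmed glycoproteins are
    those with >=1 experimental-evidence site; annotated means any evidence.
    """
    annotated = {g.accession for g in glycosites}
    confirmed = {g.accession for g in glycosites if g.evidence == "experimental"}
    counted = [e for e in events if e.counted]

    loss = [e for e in counted if e.direction == LOSS]
    gain = [e for e in counted if e.direction == GAIN]
    loss_prot = {e.variant.accession for e in loss}
    gain_prot = {e.variant.accession for e in gain}
    loss_sites = {(e.variant.accession, e.anchor) for e in loss}
    gain_sites = {(e.variant.accession, e.anchor) for e in gain}
    loss_vars = {e.variant.key for e in loss}
    gain_vars = {e.variant.key for e in gain}

    n_proteome = len(proteome)
    affected = loss_prot | gain_prot

    keyword_tables: dict[str, dict[str, dict[str, int]]] = {}
    if categories:
        # one count per (protein, category id): multi-location proteins are
        # multi-counted across ids, never within one id
        for ctype in ("keyword", "cellular_component"):
            table: dict[str, dict[str, int]] = {}
            for c in categories:
                if c.category_type != ctype:
                    continue
                cell = table.setdefault(c.category_id, {"proteome": 0, "affected": 0})
                cell["proteome"] += 1
                if c.accession in affected:
                    cell["affected"] += 1
            if table:
                keyword_tables[ctype] = dict(sorted(table.items()))

    return SurveySummary(
        n_proteome=n_proteome,
        n_annotated_glyco=len(annotated),
        n_confirmed_glyco=len(confirmed),
        n_loss_proteins=len(loss_prot),
        n_loss_sites=len(loss_sites),
        n_loss_variants=len(loss_vars),
        n_gain_proteins=len(gain_prot),
        n_gain_sites=len(gain_sites),
        n_gain_variants=len(gain_vars),
        n_affected_union=len(affected),
        pct_annotated_of_proteome=percent_of(len(annotated), n_proteome) if n_proteome else None,
        pct_loss_of_annotated=percent_of(len(loss_prot), len(annotated)) if annotated else None,
        pct_gain_of_proteome=percent_of(len(gain_prot), n_proteome) if n_proteome else None,
        keyword_tables=keyword_tables,
    )


@dataclass
class MultiplicityDistribution:
    """Histogram of counted events per protein for one direction, with the
    special buckets of the survey narrative: proteins that lost their only
    annotated site, proteins that lost all annotated sites, and previously
    non-glycosylated proteins gaining sites."""

    direction: str
    histogram: dict[int, int]
    lost_only_existing_site: int = 0
    lost_all_sites: int = 0
    nonglyco_gaining: int = 0

    @property
    def n_proteins(self) -> int:
        return sum(self.histogram.values())


def multiplicity_distribution(
    events: Sequence[SequonChangeEvent],
    glycosites: Sequence[GlycositeAnnotation],
    direction: str,
) -> MultiplicityDistribution:
    """Distribution of distinct affected sites per protein for one direction."""
    if direction not in (LOSS, GAIN):
        raise ValueError(f"direction must be {LOSS!r} or {GAIN!r}")
    ann_by_prot: dict[str, set[int]] = {}
    for g in glycosites:
        ann_by_prot.setdefault(g.accession, set()).add(g.asn_position)

    sites_by_prot: dict[str, set[int]] = {}
    for e in events:
        if e.counted and e.direction == direction:
            sites_by_prot.setdefault(e.variant.accession, set()).add(e.anchor)

    histogram: dict[int, int] = {}
    lost_only = lost_all = nonglyco = 0
    for acc, sites in sites_by_prot.items():
        k = len(sites)
        histogram[k] = histogram.get(k, 0) + 1
        ann = ann_by_prot.get(acc, set())
        if direction == LOSS and ann and ann <= sites:
            lost_all += 1
            if len(ann) == 1:
                lost_only += 1
        if direction == GAIN and not ann:
            nonglyco += 1
    return MultiplicityDistribution(
        direction=direction,
        histogram=dict(sorted(histogram.items())),
        lost_only_existing_site=lost_only,
        lost_all_sites=lost_all,
        nonglyco_gaining=nonglyco,
    )


@dataclass
class MotifAminoAcidFrequency:
    """Per-letter counts for the three motif amino acids N, S and T.

    ``n_motif`` counts the letter in its motif role only: N at sequon
    anchors, S/T at the third sequon position. Variants abolishing
    (ref == letter) or creating (alt == letter) the residue are split into
    those that cause a counted loss/gain of a sequon at that role versus
    those falling outside any such event.
    """

    counts: dict[str, dict[str, int]]

    def row(self, letter: str) -> dict[str, int]:
        return self.counts[letter]


def motif_aa_frequency(
    proteome: Sequence[ProteinRecord],
    sequons: Sequence[Sequon],
    variants: Sequence[VariantRecord],
    events: Sequence[SequonChangeEvent],
) -> MotifAminoAcidFrequency:
    """Tabulate N/S/T occurrence in and outside the motif, and how variants
    hitting each letter partition into motif-affecting vs outside (Table-3
    style)."""
    letters = "NST"
    counts = {
        aa: {
            "n_proteome": 0,
            "n_motif": 0,
            "abolishing_outside": 0,
            "creating_outside": 0,
            "loss_in_motif": 0,
            "gain_in_motif": 0,
        }
        for aa in letters
    }
    for p in proteome:
        for aa in letters:
            counts[aa]["n_proteome"] += p.sequence.count(aa)
    for s in sequons:
        counts["N"]["n_motif"] += 1
        if s.third_residue in letters:
            counts[s.third_residue]["n_motif"] += 1

    # variants whose substitution produced a counted loss (resp. gain) of the
    # letter in its motif role
    loss_keys: dict[str, set] = {aa: set() for aa in letters}
    gain_keys: dict[str, set] = {aa: set() for aa in letters}
    for e in events:
        if not e.counted:
            continue
        if e.direction == LOSS:
            if e.mechanism == N_SUBSTITUTED:
                loss_keys["N"].add(e.variant.key)
            elif e.mechanism == ST_SUBSTITUTED and e.variant.ref_aa in "ST":
                loss_keys[e.variant.ref_aa].add(e.variant.key)
        else:
            if e.mechanism == N_INTRODUCED:
                gain_keys["N"].add(e.variant.key)
            elif e.mechanism == ST_INTRODUCED and e.variant.alt_aa in "ST":
                gain_keys[e.variant.alt_aa].add(e.variant.key)

    for v in variants:
        if v.ref_aa in letters:
            aa = v.ref_aa
            if v.key in loss_keys[aa]:
                counts[aa]["loss_in_motif"] += 1
            else:
                counts[aa]["abolishing_outside"] += 1
        if v.alt_aa in letters:
            aa = v.alt_aa
            if v.key in gain_keys[aa]:
                counts[aa]["gain_in_motif"] += 1
            else:
                counts[aa]["creating_outside"] += 1

    return MotifAminoAcidFrequency(counts=counts)
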