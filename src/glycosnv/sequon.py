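"""N-glycosylation sequon detection and variant-effect classification.

The sequon is the tripeptide acceptor motif N-X-(S/T) anchored at the
asparagine, where X is any amino acid except proline. A missense variant
at position p can only create or destroy sequons anchored at p-2, p-1
or p, which gives the classifier its local three-window structure; the
full-rescan :func:`diff_sequons` serves as an independent oracle over
whole sequences.

Windows containing ambiguity codes (B, Z, X, U, O) have unknown sequon
status and are conservatively treated as non-sequons.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

from .io import (
    AMBIGUOUS_AA,
    GlycositeAnnotation,
    ProteinRecord,
    ValidationError,
    VariantRecord,
)

LOSS = "loss"
GAIN = "gain"

# loss mechanisms, by offset of the variant from the anchor (0, 1, 2)
N_SUBSTITUTED = "N_SUBSTITUTED"
PRO_INTRODUCED_AT_X = "PRO_INTRODUCED_AT_X"
ST_SUBSTITUTED = "ST_SUBSTITUTED"
# gain mechanisms, same offsets
N_INTRODUCED = "N_INTRODUCED"
PRO_REMOVED_AT_X = "PRO_REMOVED_AT_X"
ST_INTRODUCED = "ST_INTRODUCED"

_LOSS_BY_OFFSET = {0: N_SUBSTITUTED, 1: PRO_INTRODUCED_AT_X, 2: ST_SUBSTITUTED}
_GAIN_BY_OFFSET = {0: N_INTRODUCED, 1: PRO_REMOVED_AT_X, 2: ST_INTRODUCED}

LOSS_SCOPES = ("annotated", "all")


@dataclass(frozen=True, slots=True)
class Sequon:
    """One NX(S/T) occurrence, anchored at its asparagine (1-based)."""

    accession: str
    anchor: int
    x_residue: str
    third_residue: str
    annotated: bool = False
    evidence: Optional[str] = None

    @property
    def triplet(self) -> str:
        return "N" + self.x_residue + self.third_residue


@dataclass(frozen=True, slots=True)
class SequonChangeEvent:
    """The classified effect of one variant on one sequon anchor.

    ``counted`` records whether the event passes the active loss-scope
    policy (losses at unannotated anchors are flagged counted=False under
    the annotated scope; gains are always counted).
    """

    variant: VariantRecord
    anchor: int
    direction: str
    mechanism: str
    anchor_was_annotated: bool = False
    counted: bool = True


def _is_sequon_window(seq: str, i0: int) -> bool:
    """True if the 0-based window seq[i0:i0+3] is a well-defined sequon."""
    if i0 < 0 or i0 + 3 > len(seq):
        return False
    a, x, t = seq[i0], seq[i0 + 1], seq[i0 + 2]
    if a in AMBIGUOUS_AA or x in AMBIGUOUS_AA or t in AMBIGUOUS_AA:
        return False
    return a == "N" and x != "P" and t in "ST"


def find_anchors(sequence: str) -> list[int]:
    """All 1-based sequon anchors in *sequence*, ascending, overlaps included."""
    return [i0 + 1 for i0 in range(len(sequence) - 2) if _is_sequon_window(sequence, i0)]


def _annotation_map(
    glycosites: Optional[Iterable[GlycositeAnnotation]], accession: str
) -> dict[int, str]:
    if glycosites is None:
        return {}
    return {g.asn_position: g.evidence for g in glycosites if g.accession == accession}


def scan_sequons(
    protein: ProteinRecord,
    glycosites: Optional[Iterable[GlycositeAnnotation]] = None,
) -> list[Sequon]:
    """Detect every sequon in *protein*, flagging annotated glycosites.

    Overlapping occurrences (e.g. NNSS) are all reported; anchors ascend.
    """
    ann = _annotation_map(glycosites, protein.accession)
    seq = protein.sequence
    out = []
    for anchor in find_anchors(seq):
        out.append(
            Sequon(
                accession=protein.accession,
                anchor=anchor,
                x_residue=seq[anchor],          # anchor is 1-based: index anchor = pos anchor+1
                third_residue=seq[anchor + 1],
                annotated=anchor in ann,
                evidence=ann.get(anchor),
            )
        )
    return out


def apply_substitution(protein: ProteinRecord, variant: VariantRecord) -> str:
    """Return the sequence with the single substitution applied."""
    p = variant.position
    if not (1 <= p <= protein.length):
        raise ValidationError(
            f"{protein.accession}: variant position {p} out of range 1..{protein.length}"
        )
    if protein.sequence[p - 1] != variant.ref_aa:
        raise ValidationError(
            f"{protein.accession}:{p} ref_aa {variant.ref_aa} does not match "
            f"sequence residue {protein.sequence[p - 1]}"
        )
    return protein.sequence[: p - 1] + variant.alt_aa + protein.sequence[p:]


def diff_sequons(before: str, after: str) -> tuple[set[int], set[int]]:
    """Full-rescan diff: (lost anchors, gained anchors) between two sequences.

    This is the independent oracle for :func:`classify_variant`.
    """
    if len(before) != len(after):
        raise ValidationError(
            f"sequence length mismatch: {len(before)} vs {len(after)}"
        )
    b = set(find_anchors(before))
    a = set(find_anchors(after))
    return b - a, a - b


def classify_variant(
    protein: ProteinRecord,
    variant: VariantRecord,
    glycosites: Optional[Iterable[GlycositeAnnotation]] = None,
    loss_scope: str = "annotated",
) -> list[SequonChangeEvent]:
    """Classify the effect of one variant on the sequons it can touch.

    Only the three anchors p-2, p-1, p (p = variant position) are examined;
    a sequon present before and absent after the substitution is a loss,
    the converse a gain, and the mechanism follows from the offset p-anchor
    (0: the N itself, 1: the X position and proline, 2: the S/T position).

    Under ``loss_scope="annotated"`` (the default, matching a survey that
    assesses loss only at annotated glycosites while counting gains
    proteome-wide) loss events at unannotated anchors carry counted=False.
    Under ``loss_scope="all"`` every event is counted.
    """
    if loss_scope not in LOSS_SCOPES:
        raise ValueError(f"loss_scope must be one of {LOSS_SCOPES}, got {loss_scope!r}")
    before = protein.sequence
    after = apply_substitution(protein, variant)
    ann = _annotation_map(glycosites, protein.accession)
    p = variant.position
    events: list[SequonChangeEvent] = []
    for anchor in range(max(1, p - 2), min(p, protein.length - 2) + 1):
        was = _is_sequon_window(before, anchor - 1)
        now = _is_sequon_window(after, anchor - 1)
        if was == now:
            continue
        offset = p - anchor
        annotated = anchor in ann
        if was:
            events.append(
                SequonChangeEvent(
                    variant=variant,
                    anchor=anchor,
                    direction=LOSS,
                    mechanism=_LOSS_BY_OFFSET[offset],
                    anchor_was_annotated=annotated,
                    counted=(loss_scope == "all") or annotated,
                )
            )
        else:
            events.append(
                SequonChangeEvent(
                    variant=variant,
                    anchor=anchor,
                    direction=GAIN,
                    mechanism=_GAIN_BY_OFFSET[offset],
                    anchor_was_annotated=annotated,
                    counted=True,
                )
            )
    return events


def classify_all(
    proteome: Iterable[ProteinRecord],
    variants: Iterable[VariantRecord],
    glycosites: Optional[Iterable[GlycositeAnnotation]] = None,
    loss_scope: str = "annotated",
) -> list[SequonChangeEvent]:
    """Classify every variant against its protein; unknown accessions error."""
    by_acc: dict[str, ProteinRecord] = {p.accession: p for p in proteome}
    glyco_by_acc: dict[str, list[GlycositeAnnotation]] = {}
    for g in glycosites or ():
        glyco_by_acc.setdefault(g.accession, []).append(g)
    events: list[SequonChangeEvent] = []
    for v in variants:
        protein = by_acc.get(v.accession)
        if protein is None:
            raise ValidationError(f"variant references unknown accession {v.accession!r}")
        events.extend(
            classify_variant(protein, v, glyco_by_acc.get(v.accession), loss_scope)
        )
    return events
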