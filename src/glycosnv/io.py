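"""Readers and writers for the pipeline's file dialects.

All coordinates are 1-based, inclusive, on the canonical sequence (the
UniProt feature-line convention). One canonical sequence per accession;
isoforms are out of scope.

Tables are UTF-8 TSV with a header row and ``.`` for missing values.
Lines starting with ``#`` are comments (used to record the simulation
seed in generated tables).
"""

from __future__ import annotations

import io as _io
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from Bio import SeqIO

log = logging.getLogger(__name__)

#: The twenty standard amino-acid letters.
STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")
#: Ambiguity / rare codes legal in sequences but opaque to the sequon scanner.
AMBIGUOUS_AA = frozenset("BZXUO")
LEGAL_AA = STANDARD_AA | AMBIGUOUS_AA

EVIDENCE_LEVELS = ("experimental", "by_similarity", "predicted")
CATEGORY_TYPES = ("pfam", "keyword", "cellular_component", "cluster")
VARIANT_SOURCES = ("swissprot", "polyphen_dbsnp", "other")
SS_ALPHABET = frozenset("HGIEBTS-")

MISSING = "."


class ValidationError(ValueError):
    """Input data violates a documented invariant."""


class ParseError(ValueError):
    """Input file is not in the expected format."""


@dataclass(frozen=True, slots=True)
class ProteinRecord:
    """One canonical protein sequence; the positional frame for everything else."""

    accession: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValidationError("empty accession")
        if len(self.sequence) < 1:
            raise ValidationError(f"{self.accession}: empty sequence")
        for i, ch in enumerate(self.sequence, start=1):
            if ch not in LEGAL_AA:
                raise ValidationError(
                    f"{self.accession}: illegal residue {ch!r} at position {i}"
                )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True, slots=True)
class VariantRecord:
    """One protein-level missense substitution (nsSNV).

    Exact duplicates by (accession, position, ref, alt) are merged on load,
    pooling their ids and sources — the "unique variations" semantics.
    """

    accession: str
    position: int
    ref_aa: str
    alt_aa: str
    variant_ids: tuple[str, ...] = ()
    sources: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.ref_aa == self.alt_aa:
            raise ValidationError(
                f"{self.accession}:{self.position} synonymous row "
                f"({self.ref_aa}->{self.alt_aa})"
            )
        for aa, label in ((self.ref_aa, "ref_aa"), (self.alt_aa, "alt_aa")):
            if aa not in STANDARD_AA:
                raise ValidationError(
                    f"{self.accession}:{self.position} {label} {aa!r} is not a "
                    "standard amino acid"
                )
        if self.position < 1:
            raise ValidationError(f"{self.accession}: position {self.position} < 1")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.accession, self.position, self.ref_aa, self.alt_aa)


@dataclass(frozen=True, slots=True)
class GlycositeAnnotation:
    """An annotated N-glycosylation site (UniProt CARBOHYD-style feature)."""

    accession: str
    asn_position: int
    evidence: str

    def __post_init__(self) -> None:
        if self.evidence not in EVIDENCE_LEVELS:
            raise ValidationError(
                f"{self.accession}:{self.asn_position} unknown evidence "
                f"{self.evidence!r} (expected one of {EVIDENCE_LEVELS})"
            )


@dataclass(frozen=True, slots=True)
class CategoryAnnotation:
    """A flat category label (Pfam domain, keyword, cellular component, cluster)."""

    accession: str
    category_type: str
    category_id: str

    def __post_init__(self) -> None:
        if self.category_type not in CATEGORY_TYPES:
            raise ValidationError(
                f"{self.accession}: unknown category_type {self.category_type!r}"
            )


@dataclass(frozen=True, slots=True)
class SSTrack:
    """Per-residue secondary-structure codes (DSSP alphabet H/G/I/E/B/T/S/-)."""

    accession: str
    codes: str

    def __post_init__(self) -> None:
        bad = set(self.codes) - SS_ALPHABET
        if bad:
            raise ValidationError(
                f"{self.accession}: illegal SS codes {sorted(bad)}"
            )


# ---------------------------------------------------------------------------
# readers


def _accession_from_header(header_id: str) -> str:
    """Extract the accession from a FASTA id: bare, or UniProt 'db|ACC|NAME'."""
    if "|" in header_id:
        parts = header_id.split("|")
        if len(parts) >= 2 and parts[1]:
            return parts[1]
        raise ParseError(f"cannot extract accession from header {header_id!r}")
    return header_id


def read_fasta(path: str | os.PathLike) -> list[ProteinRecord]:
    """Read canonical protein sequences from a FASTA file.

    Sequences are upper-cased and a terminal ``*`` is stripped. Duplicate
    accessions and illegal residue characters are rejected.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
        if not first.startswith(">"):
            raise ParseError(f"{path}: line 1: expected FASTA header starting with '>'")
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        acc = _accession_from_header(rec.id)
        seq = str(rec.seq).upper().rstrip("*")
        if acc in seen:
            raise ValidationError(f"{path}: duplicate accession {acc!r}")
        seen.add(acc)
        records.append(ProteinRecord(accession=acc, sequence=seq))
    return records


def _read_tsv(path: str | os.PathLike, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#", keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    return df


def read_variant_table(
    path: str | os.PathLike,
    proteome: Iterable[ProteinRecord],
    on_inconsistent: str = "error",
) -> list[VariantRecord]:
    """Read and cross-validate a missense variant table.

    Each variant's ``ref_aa`` must match the proteome residue at ``position``.
    ``on_inconsistent`` controls what happens when it does not (or the position
    is out of range): ``"error"`` (default) raises, ``"skip"`` drops the row
    with a logged warning. Variants for unknown accessions are always dropped
    (their count is logged). Rows identical up to the id are merged.
    """
    if on_inconsistent not in ("error", "skip"):
        raise ValueError(f"on_inconsistent must be 'error' or 'skip', got {on_inconsistent!r}")
    seqs = {p.accession: p.sequence for p in proteome}
    df = _read_tsv(path, ["accession", "position", "ref_aa", "alt_aa", "variant_id", "source"])

    merged: dict[tuple[str, int, str, str], tuple[list[str], list[str]]] = {}
    order: list[tuple[str, int, str, str]] = []
    n_unknown = n_skipped = 0
    for row in df.itertuples(index=False):
        acc = row.accession
        try:
            pos = int(row.position)
        except ValueError as exc:
            raise ParseError(f"{path}: non-integer position {row.position!r}") from exc
        ref, alt = row.ref_aa, row.alt_aa
        source = row.source if row.source != MISSING else "other"
        if source not in VARIANT_SOURCES:
            raise ValidationError(f"{path}: unknown variant source {source!r}")
        if acc not in seqs:
            n_unknown += 1
            continue
        seq = seqs[acc]
        problem = None
        if not (1 <= pos <= len(seq)):
            problem = f"position {pos} out of range 1..{len(seq)}"
        elif seq[pos - 1] != ref:
            problem = f"ref_aa {ref} does not match sequence residue {seq[pos - 1]}"
        if problem:
            if on_inconsistent == "error":
                raise ValidationError(f"{acc}:{pos} {problem}")
            n_skipped += 1
            continue
        key = (acc, pos, ref, alt)
        if key not in merged:
            merged[key] = ([], [])
            order.append(key)
        ids, sources = merged[key]
        if row.variant_id and row.variant_id != MISSING:
            ids.append(row.variant_id)
        sources.append(source)
    if n_unknown:
        log.warning("dropped %d variant rows referencing unknown accessions", n_unknown)
    if n_skipped:
        log.warning("skipped %d inconsistent variant rows", n_skipped)

    out = []
    for key in order:
        ids, sources = merged[key]
        uniq_sources = tuple(dict.fromkeys(sources))
        out.append(
            VariantRecord(
                accession=key[0], position=key[1], ref_aa=key[2], alt_aa=key[3],
                variant_ids=tuple(dict.fromkeys(ids)), sources=uniq_sources,
            )
        )
    return out


def read_annotation_tables(
    glycosite_path: Optional[str | os.PathLike],
    category_path: Optional[str | os.PathLike],
    ss_path: Optional[str | os.PathLike],
    proteome: Iterable[ProteinRecord],
) -> tuple[list[GlycositeAnnotation], list[CategoryAnnotation], list[SSTrack]]:
    """Read the three optional annotation tables, validating against the proteome.

    Any path may be None, yielding the corresponding empty collection (the
    downstream analysis that needs it is then disabled).
    """
    seqs = {p.accession: p.sequence for p in proteome}

    glycosites: list[GlycositeAnnotation] = []
    if glycosite_path is not None:
        df = _read_tsv(glycosite_path, ["accession", "asn_position", "evidence"])
        for row in df.itertuples(index=False):
            pos = int(row.asn_position)
            g = GlycositeAnnotation(row.accession, pos, row.evidence)
            seq = seqs.get(g.accession)
            if seq is not None:
                if not (1 <= pos <= len(seq)):
                    raise ValidationError(
                        f"glycosite {g.accession}:{pos} out of range 1..{len(seq)}"
                    )
                if seq[pos - 1] != "N":
                    raise ValidationError(
                        f"glycosite {g.accession}:{pos} residue is "
                        f"{seq[pos - 1]!r}, not N"
                    )
            glycosites.append(g)

    categories: list[CategoryAnnotation] = []
    if category_path is not None:
        df = _read_tsv(category_path, ["accession", "category_type", "category_id"])
        seen_triples: set[tuple[str, str, str]] = set()
        for row in df.itertuples(index=False):
            triple = (row.accession, row.category_type, row.category_id)
            if triple in seen_triples:
                raise ValidationError(f"duplicate category annotation {triple}")
            seen_triples.add(triple)
            categories.append(CategoryAnnotation(*triple))

    ss_tracks: list[SSTrack] = []
    if ss_path is not None:
        df = _read_tsv(ss_path, ["accession", "codes"])
        for row in df.itertuples(index=False):
            track = SSTrack(row.accession, row.codes)
            seq = seqs.get(track.accession)
            if seq is not None and len(track.codes) != len(seq):
                raise ValidationError(
                    f"SS track {track.accession}: length {len(track.codes)} != "
                    f"protein length {len(seq)}"
                )
            ss_tracks.append(track)

    return glycosites, categories, ss_tracks


# ---------------------------------------------------------------------------
# writers


def _write_tsv(df: pd.DataFrame, path: Path, header_comment: str | None = None) -> None:
    buf = _io.StringIO()
    if header_comment:
        buf.write(f"# {header_comment}\n")
    df.to_csv(buf, sep="\t", index=False)
    path.write_text(buf.getvalue(), encoding="utf-8")


def write_fasta(proteins: Iterable[ProteinRecord], path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for p in proteins:
            fh.write(f">{p.accession}\n")
            for i in range(0, p.length, 60):
                fh.write(p.sequence[i : i + 60] + "\n")


def write_variant_table(
    variants: Iterable[VariantRecord], path: str | os.PathLike,
    header_comment: str | None = None,
) -> None:
    rows = [
        {
            "accession": v.accession, "position": v.position,
            "ref_aa": v.ref_aa, "alt_aa": v.alt_aa,
            "variant_id": ",".join(v.variant_ids) or MISSING,
            "source": ",".join(v.sources) or MISSING,
        }
        for v in sorted(variants, key=lambda v: v.key)
    ]
    df = pd.DataFrame(rows, columns=["accession", "position", "ref_aa", "alt_aa", "variant_id", "source"])
    _write_tsv(df, Path(path), header_comment)


def write_glycosite_table(
    glycosites: Iterable[GlycositeAnnotation], path: str | os.PathLike,
    header_comment: str | None = None,
) -> None:
    rows = [
        {"accession": g.accession, "asn_position": g.asn_position, "evidence": g.evidence}
        for g in sorted(glycosites, key=lambda g: (g.accession, g.asn_position))
    ]
    df = pd.DataFrame(rows, columns=["accession", "asn_position", "evidence"])
    _write_tsv(df, Path(path), header_comment)


def write_category_table(
    categories: Iterable[CategoryAnnotation], path: str | os.PathLike,
    header_comment: str | None = None,
) -> None:
    rows = [
        {"accession": c.accession, "category_type": c.category_type, "category_id": c.category_id}
        for c in sorted(categories, key=lambda c: (c.accession, c.category_type, c.category_id))
    ]
    df = pd.DataFrame(rows, columns=["accession", "category_type", "category_id"])
    _write_tsv(df, Path(path), header_comment)


def write_ss_table(
    tracks: Iterable[SSTrack], path: str | os.PathLike,
    header_comment: str | None = None,
) -> None:
    rows = [
        {"accession": t.accession, "codes": t.codes}
        for t in sorted(tracks, key=lambda t: t.accession)
    ]
    df = pd.DataFrame(rows, columns=["accession", "codes"])
    _write_tsv(df, Path(path), header_comment)


def write_results(
    out_dir: str | os.PathLike,
    events: Sequence = (),
    sequons: Sequence = (),
    summary: Optional[Mapping] = None,
    enrichments: Sequence = (),
    ss_distribution=None,
) -> list[Path]:
    """Write result tables with deterministic column order and row sort.

    Emits (as applicable) ``events.tsv``, ``sequons.tsv``, ``survey.json``,
    ``enrichment.tsv`` and ``ssdist.tsv`` into *out_dir*; reruns on identical
    input are byte-identical. Returns the written paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    ev_rows = [
        {
            "accession": e.variant.accession,
            "variant_id": ",".join(e.variant.variant_ids) or MISSING,
            "position": e.variant.position,
            "ref_aa": e.variant.ref_aa,
            "alt_aa": e.variant.alt_aa,
            "anchor": e.anchor,
            "direction": e.direction,
            "mechanism": e.mechanism,
            "anchor_was_annotated": e.anchor_was_annotated,
            "counted": e.counted,
        }
        for e in events
    ]
    ev_cols = ["accession", "variant_id", "position", "ref_aa", "alt_aa",
               "anchor", "direction", "mechanism", "anchor_was_annotated", "counted"]
    ev_df = pd.DataFrame(ev_rows, columns=ev_cols)
    ev_df = ev_df.sort_values(["accession", "position", "anchor"], kind="mergesort")
    path = out / "events.tsv"
    _write_tsv(ev_df, path)
    written.append(path)

    sq_rows = [
        {
            "accession": s.accession, "anchor": s.anchor, "triplet": s.triplet,
            "annotated": s.annotated, "evidence": s.evidence or MISSING,
        }
        for s in sequons
    ]
    sq_df = pd.DataFrame(sq_rows, columns=["accession", "anchor", "triplet", "annotated", "evidence"])
    sq_df = sq_df.sort_values(["accession", "anchor"], kind="mergesort")
    path = out / "sequons.tsv"
    _write_tsv(sq_df, path)
    written.append(path)

    if summary is not None:
        path = out / "survey.json"
        path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n", encoding="utf-8")
        written.append(path)

    if enrichments:
        en_rows = [
            {
                "category_type": r.category_type, "category_id": r.category_id,
                "observed": r.observed, "expected": f"{r.expected:.6g}",
                "direction": r.direction, "p_value": f"{r.p_value:.6g}",
                "q_value": f"{r.q_value:.6g}" if r.q_value is not None else MISSING,
                "significant": r.significant,
            }
            for r in enrichments
        ]
        en_df = pd.DataFrame(en_rows, columns=["category_type", "category_id", "observed",
                                               "expected", "direction", "p_value", "q_value",
                                               "significant"])
        path = out / "enrichment.tsv"
        _write_tsv(en_df, path)
        written.append(path)

    if ss_distribution is not None:
        d = ss_distribution
        rows = []
        for cls in ("helix", "strand", "turn", "bend", "loop"):
            row = {
                "class": cls,
                "observed": d.counts.get(cls, 0),
                "fraction": f"{d.fractions.get(cls, 0.0):.6g}",
            }
            if d.expected is not None:
                row["expected"] = f"{d.expected.get(cls, 0.0):.6g}"
            rows.append(row)
        cols = ["class", "observed", "fraction"] + (["expected"] if d.expected is not None else [])
        path = out / "ssdist.tsv"
        _write_tsv(pd.DataFrame(rows, columns=cols), path)
        written.append(path)

    return written
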