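"""Seeded synthetic proteome generator with truth-labeled sequon events.

The generator emulates the statistical structure the analysis assumes: a
proteome of random sequences with sequons planted by direct motif
insertion, glycosite annotations with an evidence mix, flat category
labels (optionally enriched among variant-carrying proteins), per-residue
secondary-structure tracks, and a variant table planted to realize known
loss/gain/neutral outcomes.

Ground truth is defined by rescan, not by intention: every variant's
realized effect is recomputed with the full-rescan diff, so accidental
motifs arising from the random background are legitimate sequons and are
part of the truth. A single numpy random stream drives the whole run.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import (
    STANDARD_AA,
    CategoryAnnotation,
    GlycositeAnnotation,
    ProteinRecord,
    SSTrack,
    VariantRecord,
)
from .sequon import Sequon, apply_substitution, diff_sequons, scan_sequons

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"

#: Approximate residue frequencies of the reviewed human proteome, for
#: realism; tests use the uniform default for analyzability.
HUMAN_COMPOSITION = {
    "A": 0.070, "C": 0.023, "D": 0.047, "E": 0.071, "F": 0.037,
    "G": 0.066, "H": 0.026, "I": 0.043, "K": 0.057, "L": 0.100,
    "M": 0.021, "N": 0.036, "P": 0.063, "Q": 0.048, "R": 0.056,
    "S": 0.083, "T": 0.054, "V": 0.060, "W": 0.012, "Y": 0.027,
}

EFFECT_CLASSES = (
    "loss_via_N",
    "loss_via_ST",
    "loss_via_proline",
    "gain_via_N",
    "gain_via_ST",
    "gain_via_proline_removal",
    "neutral",
)


@dataclass
class SimulationConfig:
    """Tunable study conditions for one synthetic run.

    Defaults describe a compact proteome that preserves the real survey's
    qualitative structure: ~2 sequons per 100 residues, roughly a quarter of
    sequons annotated as glycosites (with a confirmed/by-similarity/predicted
    evidence mix), a variant table dominated by motif-neutral substitutions,
    and flat category labels at 5% baseline membership.
    """

    seed: int = 0
    n_proteins: int = 200
    length_range: tuple[int, int] = (200, 600)
    composition: Optional[dict[str, float]] = None  # None -> uniform over 20
    sequon_rate_per_100: float = 2.0
    blocked_motif_rate_per_100: float = 0.5  # N-P-(S/T) triplets, never sequons
    glycosite_annotation_p: float = 0.3
    evidence_mix: dict[str, float] = field(
        default_factory=lambda: {"experimental": 0.25, "by_similarity": 0.5, "predicted": 0.25}
    )
    n_variants: int = 500
    effect_mix: dict[str, float] = field(
        default_factory=lambda: {
            "loss_via_N": 0.10,
            "loss_via_ST": 0.10,
            "loss_via_proline": 0.05,
            "gain_via_N": 0.15,
            "gain_via_ST": 0.10,
            "gain_via_proline_removal": 0.02,
            "neutral": 0.48,
        }
    )
    n_categories: int = 20
    category_baseline_p: float = 0.05
    planted_categories: dict[str, float] = field(default_factory=dict)
    ss_class_probs: dict[str, float] = field(
        default_factory=lambda: {
            "H": 0.25, "G": 0.04, "I": 0.01, "E": 0.15,
            "B": 0.03, "T": 0.12, "S": 0.09, "-": 0.31,
        }
    )

    def validate(self) -> None:
        lo, hi = self.length_range
        if not (3 <= lo <= hi):
            raise ValueError("length_range must satisfy 3 <= min <= max")
        if self.composition is not None:
            if set(self.composition) != set(AA_ORDER):
                raise ValueError("composition must cover exactly the 20 standard letters")
            if abs(sum(self.composition.values()) - 1.0) > 1e-9:
                raise ValueError("composition must sum to 1")
        for name, mix in (("effect_mix", self.effect_mix), ("evidence_mix", self.evidence_mix),
                          ("ss_class_probs", self.ss_class_probs)):
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1")
            if any(v < 0 for v in mix.values()):
                raise ValueError(f"{name} has negative entries")
        if set(self.effect_mix) - set(EFFECT_CLASSES):
            raise ValueError("unknown effect class in effect_mix")
        if not (0 <= self.glycosite_annotation_p <= 1):
            raise ValueError("glycosite_annotation_p must be a probability")
        expected_sequon_space = self.n_proteins * self.length_range[0]
        if self.sequon_rate_per_100 > 100 / 3:
            raise ValueError("sequon rate too high: sequons occupy 3 residues each")
        if self.n_variants > self.n_proteins * self.length_range[0]:
            raise ValueError("n_variants exceeds the number of mutable residues")


@dataclass(frozen=True, slots=True)
class TruthRecord:
    """Ground truth for one planted variant.

    ``realized_losses``/``realized_gains`` come from the full-rescan diff and
    are authoritative; ``agreement`` records whether the intended effect
    class alone explains them.
    """

    variant: VariantRecord
    intended: str
    realized_losses: tuple[int, ...]
    realized_gains: tuple[int, ...]
    agreement: bool


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    proteins: list[ProteinRecord]
    glycosites: list[GlycositeAnnotation]
    categories: list[CategoryAnnotation]
    ss_tracks: list[SSTrack]
    variants: list[VariantRecord]
    truth: list[TruthRecord]
    sequons: list[Sequon]


def _draw_sequence(rng: np.random.Generator, length: int, probs: np.ndarray,
                   rate_per_100: float, blocked_rate_per_100: float) -> str:
    letters = rng.choice(list(AA_ORDER), size=length, p=probs)
    seq = letters.tolist()
    n_plant = rng.binomial(length, rate_per_100 / 100.0)
    n_block = rng.binomial(length, blocked_rate_per_100 / 100.0)
    # sample non-overlapping 3-residue windows for the planted motifs;
    # blocked motifs are N-P-(S/T), which the scanner must never report
    taken: set[int] = set()
    attempts = 0
    planted = 0
    non_p = [aa for aa in AA_ORDER if aa != "P"]
    while planted < n_plant + n_block and attempts < 50 * max(n_plant + n_block, 1):
        attempts += 1
        i0 = int(rng.integers(0, length - 2))
        if any(j in taken for j in range(i0 - 2, i0 + 3)):
            continue
        seq[i0] = "N"
        if planted < n_plant:
            seq[i0 + 1] = non_p[int(rng.integers(0, len(non_p)))]
        else:
            seq[i0 + 1] = "P"
        seq[i0 + 2] = "ST"[int(rng.integers(0, 2))]
        taken.update(range(i0, i0 + 3))
        planted += 1
    return "".join(seq)


def generate_proteome(
    config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> tuple[list[ProteinRecord], list[GlycositeAnnotation], list[CategoryAnnotation], list[SSTrack], list[Sequon]]:
    """Generate sequences, glycosites, baseline categories, SS tracks.

    The returned sequon list is the post-generation full rescan, so it
    includes background motifs that arose by chance. Planted-category
    enrichment multipliers are applied later by :func:`simulate`, once the
    variant-carrying proteins are known.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    comp = config.composition or {aa: 1 / 20 for aa in AA_ORDER}
    probs = np.array([comp[aa] for aa in AA_ORDER])
    probs = probs / probs.sum()

    lo, hi = config.length_range
    proteins: list[ProteinRecord] = []
    for i in range(config.n_proteins):
        length = int(rng.integers(lo, hi + 1))
        seq = _draw_sequence(rng, length, probs, config.sequon_rate_per_100,
                             config.blocked_motif_rate_per_100)
        proteins.append(ProteinRecord(accession=f"SYN{i:05d}", sequence=seq))

    # truth sequons by rescan; annotate a fraction with an evidence mix
    glycosites: list[GlycositeAnnotation] = []
    all_sequons: list[Sequon] = []
    ev_levels = sorted(config.evidence_mix)
    ev_probs = np.array([config.evidence_mix[e] for e in ev_levels])
    ev_probs = ev_probs / ev_probs.sum()
    for p in proteins:
        for s in scan_sequons(p):
            if rng.random() < config.glycosite_annotation_p:
                evidence = ev_levels[int(rng.choice(len(ev_levels), p=ev_probs))]
                glycosites.append(GlycositeAnnotation(p.accession, s.anchor, evidence))
    glyco_by_acc: dict[str, dict[int, str]] = {}
    for g in glycosites:
        glyco_by_acc.setdefault(g.accession, {})[g.asn_position] = g.evidence
    for p in proteins:
        all_sequons.extend(scan_sequons(p, glycosites))

    categories = _draw_categories(config, rng, [p.accession for p in proteins], affected=None)

    ss_codes = sorted(config.ss_class_probs)
    ss_probs = np.array([config.ss_class_probs[c] for c in ss_codes])
    ss_probs = ss_probs / ss_probs.sum()
    ss_tracks = [
        SSTrack(
            p.accession,
            "".join(np.array(ss_codes)[rng.choice(len(ss_codes), size=p.length, p=ss_probs)]),
        )
        for p in proteins
    ]
    return proteins, glycosites, categories, ss_tracks, all_sequons


def _draw_categories(
    config: SimulationConfig,
    rng: np.random.Generator,
    accessions: Sequence[str],
    affected: Optional[set[str]],
) -> list[CategoryAnnotation]:
    """Bernoulli category membership; planted categories get their baseline
    probability multiplied for affected proteins (capped at 1)."""
    ids = [f"PF{i:04d}" for i in range(config.n_categories)] + sorted(config.planted_categories)
    out: list[CategoryAnnotation] = []
    for cid in ids:
        mult = config.planted_categories.get(cid, 1.0)
        for acc in accessions:
            p = config.category_baseline_p
            if affected is not None and acc in affected:
                p = min(1.0, p * mult)
            if rng.random() < p:
                out.append(CategoryAnnotation(acc, "pfam", cid))
    return out


def _intended_realized(effect: str, before: str, after: str) -> tuple[tuple[int, ...], tuple[int, ...], bool]:
    lost, gained = diff_sequons(before, after)
    losses, gains = tuple(sorted(lost)), tuple(sorted(gained))
    if effect == "neutral":
        ok = not losses and not gains
    elif effect.startswith("loss"):
        ok = len(losses) == 1 and not gains
    else:
        ok = len(gains) == 1 and not losses
    return losses, gains, ok


def plant_variants(
    proteins: Sequence[ProteinRecord],
    sequons: Sequence[Sequon],
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> tuple[list[VariantRecord], list[TruthRecord]]:
    """Plant a variant table realizing the configured effect-class mix.

    Each effect class samples an eligible site and a substitution that
    realizes it against the reference sequence; at most one variant per
    (accession, position). Exhaustion of eligible sites for a class raises,
    naming the class. Neutral variants are rejection-sampled until the
    rescan confirms no sequon change.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    seqs = {p.accession: p.sequence for p in proteins}
    prots = {p.accession: p for p in proteins}
    anchors_by_acc: dict[str, list[int]] = {}
    for s in sequons:
        anchors_by_acc.setdefault(s.accession, []).append(s.anchor)

    used: set[tuple[str, int]] = set()

    # eligible-position pools, 1-based positions
    pool_loss_N = [(s.accession, s.anchor) for s in sequons]
    pool_loss_ST = [(s.accession, s.anchor + 2) for s in sequons]
    pool_loss_P = [(s.accession, s.anchor + 1) for s in sequons]
    pool_gain_N: list[tuple[str, int]] = []
    pool_gain_ST: list[tuple[str, int]] = []
    pool_gain_P: list[tuple[str, int]] = []
    for p in proteins:
        seq = p.sequence
        anchor_set = set(anchors_by_acc.get(p.accession, []))
        for i0 in range(len(seq) - 2):
            a, x, t = seq[i0], seq[i0 + 1], seq[i0 + 2]
            if a != "N" and x != "P" and t in "ST":
                pool_gain_N.append((p.accession, i0 + 1))
            if a == "N" and x != "P" and t not in "ST":
                pool_gain_ST.append((p.accession, i0 + 3))
            if a == "N" and x == "P" and t in "ST":
                pool_gain_P.append((p.accession, i0 + 2))

    pools = {
        "loss_via_N": pool_loss_N,
        "loss_via_ST": pool_loss_ST,
        "loss_via_proline": pool_loss_P,
        "gain_via_N": pool_gain_N,
        "gain_via_ST": pool_gain_ST,
        "gain_via_proline_removal": pool_gain_P,
    }
    for pool in pools.values():
        rng.shuffle(pool)  # in-place; draw by popping

    classes = sorted(config.effect_mix)
    class_probs = np.array([config.effect_mix[c] for c in classes])
    class_probs = class_probs / class_probs.sum()
    requested = rng.multinomial(config.n_variants, class_probs)

    non_p = [aa for aa in AA_ORDER if aa != "P"]
    variants: list[VariantRecord] = []
    truth: list[TruthRecord] = []
    serial = 0

    def emit(acc: str, pos: int, alt: str, effect: str) -> None:
        nonlocal serial
        ref = seqs[acc][pos - 1]
        v = VariantRecord(
            accession=acc, position=pos, ref_aa=ref, alt_aa=alt,
            variant_ids=(f"sim{serial:05d}",), sources=("other",),
        )
        serial += 1
        after = apply_substitution(prots[acc], v)
        losses, gains, ok = _intended_realized(effect, seqs[acc], after)
        variants.append(v)
        truth.append(TruthRecord(v, effect, losses, gains, ok))
        used.add((acc, pos))

    for cls, n_req in zip(classes, requested):
        n_req = int(n_req)
        if cls == "neutral":
            placed = 0
            attempts = 0
            accs = [p.accession for p in proteins]
            while placed < n_req:
                attempts += 1
                if attempts > 200 * max(n_req, 1):
                    raise RuntimeError("exhausted eligible sites for effect class 'neutral'")
                acc = accs[int(rng.integers(0, len(accs)))]
                seq = seqs[acc]
                pos = int(rng.integers(1, len(seq) + 1))
                if (acc, pos) in used:
                    continue
                ref = seq[pos - 1]
                alts = [aa for aa in AA_ORDER if aa != ref]
                alt = alts[int(rng.integers(0, len(alts)))]
                v = VariantRecord(acc, pos, ref, alt, ("tmp",), ("other",))
                lost, gained = diff_sequons(seq, apply_substitution(prots[acc], v))
                if lost or gained:
                    continue
                emit(acc, pos, alt, "neutral")
                placed += 1
            continue

        pool = pools[cls]
        placed = 0
        while placed < n_req:
            if not pool:
                raise RuntimeError(f"exhausted eligible sites for effect class {cls!r}")
            acc, pos = pool.pop()
            if (acc, pos) in used:
                continue
            ref = seqs[acc][pos - 1]
            if cls == "loss_via_N":
                if ref != "N":
                    continue
                alts = [aa for aa in AA_ORDER if aa != "N"]
                alt = alts[int(rng.integers(0, len(alts)))]
            elif cls == "loss_via_ST":
                if ref not in "ST":
                    continue
                alts = [aa for aa in AA_ORDER if aa not in "ST"]
                alt = alts[int(rng.integers(0, len(alts)))]
            elif cls == "loss_via_proline":
                if ref == "P":
                    continue
                alt = "P"
            elif cls == "gain_via_N":
                if ref == "N":
                    continue
                alt = "N"
            elif cls == "gain_via_ST":
                if ref in "ST":
                    continue
                alt = "ST"[int(rng.integers(0, 2))]
            else:  # gain_via_proline_removal
                if ref != "P":
                    continue
                alts = [aa for aa in non_p]
                alt = alts[int(rng.integers(0, len(alts)))]
            emit(acc, pos, alt, cls)
            placed += 1

    order = np.argsort([f"{v.accession}\t{v.position:06d}" for v in variants], kind="stable")
    variants = [variants[i] for i in order]
    truth = [truth[i] for i in order]
    return variants, truth


def simulate(config: SimulationConfig) -> SimulatedDataset:
    """Run the full generator: proteome, annotations, variants, truth.

    Planted-category enrichment is applied here: membership in each planted
    category is re-drawn with probability baseline x multiplier for proteins
    carrying at least one realized sequon change.
    """
    rng = np.random.default_rng(config.seed)
    proteins, glycosites, categories, ss_tracks, sequons = generate_proteome(config, rng)
    variants, truth = plant_variants(proteins, sequons, config, rng)
    if config.planted_categories:
        affected = {
            t.variant.accession for t in truth if t.realized_losses or t.realized_gains
        }
        planted_ids = set(config.planted_categories)
        categories = [c for c in categories if c.category_id not in planted_ids]
        extra = SimulationConfig(**{**config.__dict__, "n_categories": 0})
        categories += _draw_categories(extra, rng, [p.accession for p in proteins], affected)
        categories.sort(key=lambda c: (c.accession, c.category_type, c.category_id))
    return SimulatedDataset(
        config=config, proteins=proteins, glycosites=glycosites,
        categories=categories, ss_tracks=ss_tracks,
        variants=variants, truth=truth, sequons=sequons,
    )


def write_truth(truth: Sequence[TruthRecord], out_dir: str | os.PathLike,
                seed: Optional[int] = None) -> Path:
    """Write truth.tsv (variant id, intended label, realized anchors/directions)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = [
        {
            "accession": t.variant.accession,
            "position": t.variant.position,
            "variant_id": ",".join(t.variant.variant_ids),
            "intended": t.intended,
            "realized_losses": ",".join(map(str, t.realized_losses)) or ".",
            "realized_gains": ",".join(map(str, t.realized_gains)) or ".",
            "agreement": t.agreement,
        }
        for t in truth
    ]
    df = pd.DataFrame(rows, columns=["accession", "position", "variant_id", "intended",
                                     "realized_losses", "realized_gains", "agreement"])
    df = df.sort_values(["accession", "position"], kind="mergesort")
    path = out / "truth.tsv"
    lines = []
    if seed is not None:
        lines.append(f"# seed={seed}")
    lines.append(df.to_csv(sep="\t", index=False))
    path.write_text("\n".join(lines), encoding="utf-8")
    return path
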