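"""Over/under-representation, variant-density and secondary-structure statistics.

The enrichment test follows the classic PANTHER-style scheme: the expected
count of a category in a dataset is the background frequency scaled to the
dataset size, and the p-value is the one-sided exact binomial tail at the
background rate. An exact hypergeometric alternative (sampling without
replacement from the finite background) is available; the two differ
visibly only for large sampling fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Optional, Sequence

from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import CategoryAnnotation, SSTrack
from .sequon import SequonChangeEvent

OVER = "over"
UNDER = "under"

#: DSSP 8-letter alphabet collapsed to the five classes reported by
#: structural surveys of glycosylation sites.
DSSP_CLASS_MAP = {
    "H": "helix", "G": "helix", "I": "helix",
    "E": "strand", "B": "strand",
    "T": "turn",
    "S": "bend",
    "-": "loop",
}
SS_CLASSES = ("helix", "strand", "turn", "bend", "loop")


def expected_count(n_dataset: int, k_category_background: int, n_background: int) -> float:
    """Background category frequency scaled to the dataset size, unrounded."""
    if n_background == 0:
        raise ZeroDivisionError("empty background")
    if not (0 <= k_category_background <= n_background):
        raise ValueError("k_category_background out of range")
    return n_dataset * k_category_background / n_background


def binomial_enrichment_pvalue(
    observed: int, n_dataset: int, rate: float, direction: str
) -> float:
    """One-sided exact binomial tail probability.

    over: P(X >= observed); under: P(X <= observed), X ~ Binomial(n, rate).
    scipy evaluates the tails in log space, so the result is stable for
    n up to at least 1e5.
    """
    if not (0.0 <= rate <= 1.0):
        raise ValueError(f"rate must be in [0, 1], got {rate}")
    if not (0 <= observed <= n_dataset):
        raise ValueError("observed out of range")
    if direction == OVER:
        return float(stats.binom.sf(observed - 1, n_dataset, rate))
    if direction == UNDER:
        return float(stats.binom.cdf(observed, n_dataset, rate))
    raise ValueError(f"direction must be {OVER!r} or {UNDER!r}")


def hypergeom_enrichment_pvalue(
    observed: int, n_dataset: int, k_category_background: int, n_background: int,
    direction: str,
) -> float:
    """One-sided exact hypergeometric tail (finite background, no replacement)."""
    rv = stats.hypergeom(n_background, k_category_background, n_dataset)
    if direction == OVER:
        return float(rv.sf(observed - 1))
    if direction == UNDER:
        return float(rv.cdf(observed))
    raise ValueError(f"direction must be {OVER!r} or {UNDER!r}")


@dataclass(frozen=True, slots=True)
class EnrichmentResult:
    """One category's observed/expected counts and one-sided p-value."""

    category_type: str
    category_id: str
    n_dataset: int
    n_background: int
    k_category_background: int
    observed: int
    expected: float
    direction: str
    p_value: float
    significant: bool
    q_value: Optional[float] = None


def enrich_categories(
    dataset_accessions: Iterable[str],
    categories: Sequence[CategoryAnnotation],
    background_accessions: Iterable[str],
    alpha: float = 0.05,
    correction: str = "none",
    test: str = "binomial",
    category_types: Optional[Sequence[str]] = None,
) -> list[EnrichmentResult]:
    """Test every category for over/under-representation in the dataset.

    The direction is over when observed > expected, otherwise under, and the
    p-value is the one-sided tail in that direction. Results are sorted by
    ascending p-value (ties by category id for determinism). ``correction``
    "bh" adds Benjamini-Hochberg q-values alongside the raw p-values;
    significance is always judged on the raw p at ``alpha``.
    """
    if correction not in ("none", "bh"):
        raise ValueError(f"correction must be 'none' or 'bh', got {correction!r}")
    if test not in ("binomial", "hypergeom"):
        raise ValueError(f"test must be 'binomial' or 'hypergeom', got {test!r}")
    dataset = set(dataset_accessions)
    background = set(background_accessions)
    if not dataset <= background:
        extra = sorted(dataset - background)[:5]
        raise ValueError(f"dataset is not a subset of the background (e.g. {extra})")
    n_bg = len(background)
    n_ds = len(dataset)

    members: dict[tuple[str, str], set[str]] = {}
    for c in categories:
        if category_types is not None and c.category_type not in category_types:
            continue
        if c.accession in background:
            members.setdefault((c.category_type, c.category_id), set()).add(c.accession)

    results: list[EnrichmentResult] = []
    for (ctype, cid), accs in members.items():
        k_bg = len(accs)
        obs = len(accs & dataset)
        exp = expected_count(n_ds, k_bg, n_bg)
        direction = OVER if obs > exp else UNDER
        if test == "binomial":
            p = binomial_enrichment_pvalue(obs, n_ds, k_bg / n_bg, direction)
        else:
            p = hypergeom_enrichment_pvalue(obs, n_ds, k_bg, n_bg, direction)
        results.append(
            EnrichmentResult(
                category_type=ctype, category_id=cid,
                n_dataset=n_ds, n_background=n_bg, k_category_background=k_bg,
                observed=obs, expected=exp, direction=direction,
                p_value=p, significant=p <= alpha,
            )
        )
    results.sort(key=lambda r: (r.p_value, r.category_type, r.category_id))
    if correction == "bh" and results:
        qvals = multipletests([r.p_value for r in results], method="fdr_bh")[1]
        results = [replace(r, q_value=float(q)) for r, q in zip(results, qvals)]
    return results


@dataclass(frozen=True, slots=True)
class DensityTestResult:
    """Per-residue variant density of a dataset against the proteome background."""

    background_residues: int
    background_snvs: int
    dataset_residues: int
    dataset_snvs: int
    background_rate: float
    dataset_rate: float
    expected_snvs: float
    direction: str
    p_value: float


def snv_density_test(
    background_residues: int,
    background_snvs: int,
    dataset_residues: int,
    dataset_snvs: int,
) -> DensityTestResult:
    """Compare a dataset's per-residue nsSNV rate with the proteome-wide rate.

    The background rate is total nsSNVs over total residue count; the
    expected dataset count is that rate times the dataset residue count, and
    the p-value is the one-sided binomial tail in the observed direction.
    """
    if background_residues <= 0 or dataset_residues <= 0:
        raise ValueError("residue counts must be positive")
    bg_rate = background_snvs / background_residues
    ds_rate = dataset_snvs / dataset_residues
    expected = bg_rate * dataset_residues
    direction = OVER if dataset_snvs > expected else UNDER
    p = binomial_enrichment_pvalue(dataset_snvs, dataset_residues, bg_rate, direction)
    return DensityTestResult(
        background_residues=background_residues,
        background_snvs=background_snvs,
        dataset_residues=dataset_residues,
        dataset_snvs=dataset_snvs,
        background_rate=bg_rate,
        dataset_rate=ds_rate,
        expected_snvs=expected,
        direction=direction,
        p_value=p,
    )


@dataclass
class SSDistribution:
    """Secondary-structure class distribution of variant sites."""

    counts: dict[str, int]
    fractions: dict[str, float]
    loop_plus_bend: float
    n_sites: int
    n_excluded: int
    expected: Optional[dict[str, float]] = None


def ss_distribution(
    events: Sequence[SequonChangeEvent],
    ss_tracks: Sequence[SSTrack],
    background_positions: Optional[Sequence[tuple[str, int]]] = None,
) -> SSDistribution:
    """Tally the secondary-structure classes at variant sites of counted events.

    Sites are distinct (accession, variant position) pairs; sites without SS
    coverage are excluded (their count reported). With background positions
    supplied, expected per-class counts proportional to the background class
    frequencies are included.
    """
    tracks = {t.accession: t.codes for t in ss_tracks}
    sites = {(e.variant.accession, e.variant.position) for e in events if e.counted}
    counts = {cls: 0 for cls in SS_CLASSES}
    n_excluded = 0
    for acc, pos in sorted(sites):
        codes = tracks.get(acc)
        if codes is None or not (1 <= pos <= len(codes)):
            n_excluded += 1
            continue
        counts[DSSP_CLASS_MAP[codes[pos - 1]]] += 1
    n_sites = sum(counts.values())
    fractions = {
        cls: (counts[cls] / n_sites if n_sites else 0.0) for cls in SS_CLASSES
    }
    expected = None
    if background_positions is not None:
        bg_counts = {cls: 0 for cls in SS_CLASSES}
        n_bg = 0
        for acc, pos in background_positions:
            codes = tracks.get(acc)
            if codes is None or not (1 <= pos <= len(codes)):
                continue
            bg_counts[DSSP_CLASS_MAP[codes[pos - 1]]] += 1
            n_bg += 1
        if n_bg:
            expected = {cls: n_sites * bg_counts[cls] / n_bg for cls in SS_CLASSES}
    return SSDistribution(
        counts=counts,
        fractions=fractions,
        loop_plus_bend=fractions["loop"] + fractions["bend"],
        n_sites=n_sites,
        n_excluded=n_excluded,
        expected=expected,
    )
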