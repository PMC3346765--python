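"""Survey aggregation: percentages, headline counts, multiplicity, Table-3
style amino-acid frequencies, with brute-force recount oracles."""

import random

import pytest

from glycosnv import (
    GlycositeAnnotation,
    ProteinRecord,
    VariantRecord,
    classify_all,
    motif_aa_frequency,
    multiplicity_distribution,
    percent_of,
    scan_sequons,
    summarize_dataset,
)
from glycosnv.sequon import GAIN, LOSS

AA20 = "ACDEFGHIKLMNPQRSTVWY"


class TestPercentOf:
    @pytest.mark.parametrize(
        "part, whole, expected",
        [
            (3680, 20242, 18),
            (4421, 20242, 22),
            (226, 3680, 6),
            (917, 20242, 5),
            (0, 100, 0),
            (1, 200, 1),   # 0.5% -> half rounds away from zero
            (3, 200, 2),   # 1.5% -> 2
        ],
    )
    def test_rounding_convention(self, part, whole, expected):
        assert percent_of(part, whole) == expected

    def test_zero_whole_errors(self):
        with pytest.raises(ZeroDivisionError):
            percent_of(1, 0)


def _mk_events():
    """Toy set: loss on A, one gained anchor on B from two variants, loss on C
    (plus one motif-neutral variant on C)."""
    proteins = [
        ProteinRecord("A", "MNKSAA"),
        ProteinRecord("B", "MNPSAA"),
        ProteinRecord("C", "MNKSNKSAA"),
    ]
    glyco = [GlycositeAnnotation("A", 2, "experimental"),
             GlycositeAnnotation("C", 2, "by_similarity")]
    variants = [
        VariantRecord("A", 2, "N", "T", ("v1",)),
        VariantRecord("B", 3, "P", "G", ("v2",)),
        VariantRecord("B", 3, "P", "A", ("v3",)),
        VariantRecord("C", 2, "N", "T", ("v4",)),
        VariantRecord("C", 6, "K", "T", ("v5",)),  # gain at anchor 4? build below
    ]
    return proteins, glyco, variants


class TestSummarizeDataset:
    def test_toy_counts(self):
        proteins, glyco, variants = _mk_events()
        events = classify_all(proteins, variants, glyco, loss_scope="annotated")
        s = summarize_dataset(proteins, glyco, events)
        assert s.n_proteome == 3
        assert s.n_annotated_glyco == 2
        assert s.n_confirmed_glyco == 1
        assert s.n_loss_proteins == 2          # A and C
        assert s.n_gain_proteins == 1          # B (two variants, one anchor)
        assert s.n_gain_sites == 1
        assert s.n_gain_variants == 2
        assert s.n_affected_union == 3

    def test_no_events(self):
        proteins, glyco, _ = _mk_events()
        s = summarize_dataset(proteins, glyco, [])
        assert s.n_loss_proteins == s.n_gain_sites == s.n_affected_union == 0

    def test_union_semantics_on_simulated_data(self, sim_dataset):
        events = classify_all(sim_dataset.proteins, sim_dataset.variants,
                              sim_dataset.glycosites, loss_scope="all")
        s = summarize_dataset(sim_dataset.proteins, sim_dataset.glycosites, events)
        loss_p = {e.variant.accession for e in events if e.direction == LOSS}
        gain_p = {e.variant.accession for e in events if e.direction == GAIN}
        assert s.n_affected_union == len(loss_p | gain_p)
        if s.n_loss_proteins:
            assert s.n_loss_sites >= s.n_loss_proteins
        if s.n_gain_proteins:
            assert s.n_gain_sites >= s.n_gain_proteins

    def test_recount_from_written_events(self, tmp_path, sim_dataset):
        """Summary recomputed from the written events.tsv equals in-memory."""
        import pandas as pd

        from glycosnv import write_results

        events = classify_all(sim_dataset.proteins, sim_dataset.variants,
                              sim_dataset.glycosites)
        s = summarize_dataset(sim_dataset.proteins, sim_dataset.glycosites, events)
        write_results(tmp_path, events=events)
        df = pd.read_csv(tmp_path / "events.tsv", sep="\t")
        counted = df[df.counted]
        assert len(counted[counted.direction == "loss"]
                   .groupby("accession")) == s.n_loss_proteins
        assert counted[counted.direction == "gain"][["accession", "anchor"]]\
            .drop_duplicates().shape[0] == s.n_gain_sites


class TestMultiplicity:
    def test_lost_only_existing_site_bucket(self):
        proteins = [ProteinRecord("A", "MNKSAA")]
        glyco = [GlycositeAnnotation("A", 2, "experimental")]
        variants = [VariantRecord("A", 2, "N", "T", ("v1",))]
        events = classify_all(proteins, variants, glyco)
        d = multiplicity_distribution(events, glyco, LOSS)
        assert d.histogram == {1: 1}
        assert d.lost_only_existing_site == 1
        assert d.lost_all_sites == 1

    def test_nonglyco_gaining_bucket(self):
        proteins = [ProteinRecord("A", "MNPSANPSANPSA")]
        variants = [
            VariantRecord("A", 3, "P", "G", ("v1",)),
            VariantRecord("A", 7, "P", "G", ("v2",)),
            VariantRecord("A", 11, "P", "G", ("v3",)),
        ]
        events = classify_all(proteins, variants, [], loss_scope="all")
        d = multiplicity_distribution(events, [], GAIN)
        assert d.histogram == {3: 1}
        assert d.nonglyco_gaining == 1

    def test_empty(self):
        d = multiplicity_distribution([], [], LOSS)
        assert d.histogram == {} and d.n_proteins == 0

    def test_histogram_sums_to_protein_count(self, sim_dataset):
        events = classify_all(sim_dataset.proteins, sim_dataset.variants,
                              sim_dataset.glycosites, loss_scope="all")
        for direction in (LOSS, GAIN):
            d = multiplicity_distribution(events, sim_dataset.glycosites, direction)
            prots = {e.variant.accession for e in events if e.direction == direction}
            assert d.n_proteins == len(prots)


class TestMotifAAFrequency:
    def test_single_protein_hand_count(self):
        proteins = [ProteinRecord("A", "MNKSA")]
        glyco = [GlycositeAnnotation("A", 2, "experimental")]
        variants = [VariantRecord("A", 2, "N", "T", ("v1",))]
        events = classify_all(proteins, variants, glyco)
        sequons = [s for p in proteins for s in scan_sequons(p, glyco)]
        f = motif_aa_frequency(proteins, sequons, variants, events)
        n = f.row("N")
        assert n["n_proteome"] == 1 and n["n_motif"] == 1
        assert n["loss_in_motif"] == 1 and n["abolishing_outside"] == 0
        t = f.row("T")
        assert t["creating_outside"] == 1  # alt T landed outside any gain role
        assert f.row("S")["n_motif"] == 1

    def test_no_asparagine_all_n_zero(self):
        proteins = [ProteinRecord("A", "MKLS")]
        f = motif_aa_frequency(proteins, [], [], [])
        assert all(v == 0 for v in f.row("N").values())

    def test_brute_force_recount_on_random_proteins(self):
        """Counts equal an independent recount built from raw sequences and
        the rescan diff, on seeded random proteins."""
        from glycosnv import apply_substitution, diff_sequons

        rng = random.Random(555)
        proteins, variants = [], []
        for i in range(10):
            seq = "".join(rng.choices(AA20, k=80))
            p = ProteinRecord(f"P{i}", seq)
            proteins.append(p)
            for _ in range(5):
                pos = rng.randint(1, 80)
                ref = seq[pos - 1]
                alt = rng.choice([a for a in AA20 if a != ref])
                variants.append(VariantRecord(f"P{i}", pos, ref, alt, (f"v{i}_{pos}",)))
        # dedupe (accession, position) collisions keeping the first
        seen, uniq = set(), []
        for v in variants:
            if (v.accession, v.position) not in seen:
                seen.add((v.accession, v.position))
                uniq.append(v)
        variants = uniq
        events = classify_all(proteins, variants, [], loss_scope="all")
        sequons = [s for p in proteins for s in scan_sequons(p)]
        f = motif_aa_frequency(proteins, sequons, variants, events)

        by_acc = {p.accession: p for p in proteins}
        for aa in "NST":
            assert f.row(aa)["n_proteome"] == sum(p.sequence.count(aa) for p in proteins)
            # recount motif-role loss/gain from the diff oracle
            loss = gain = 0
            for v in variants:
                before = by_acc[v.accession].sequence
                after = apply_substitution(by_acc[v.accession], v)
                lost, gained = diff_sequons(before, after)
                role_hit_loss = any(
                    (aa == "N" and v.position == a)
                    or (aa in "ST" and v.position == a + 2 and v.ref_aa == aa)
                    for a in lost
                )
                role_hit_gain = any(
                    (aa == "N" and v.position == a and v.alt_aa == "N")
                    or (aa in "ST" and v.position == a + 2 and v.alt_aa == aa)
                    for a in gained
                )
                loss += role_hit_loss and v.ref_aa == aa
                gain += role_hit_gain and v.alt_aa == aa
            assert f.row(aa)["loss_in_motif"] == loss
            assert f.row(aa)["gain_in_motif"] == gain
            n_ref = sum(1 for v in variants if v.ref_aa == aa)
            n_alt = sum(1 for v in variants if v.alt_aa == aa)
            assert f.row(aa)["abolishing_outside"] == n_ref - loss
            assert f.row(aa)["creating_outside"] == n_alt - gain
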