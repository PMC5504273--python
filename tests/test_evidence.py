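import pandas as pd
import pytest

from viromenet import (
    classify_contig_taxonomy,
    consolidate_predictions,
    host_by_crispr,
    host_by_genome_homology,
    host_by_trna,
)
from viromenet.containers import HostAssignment
from viromenet.evidence import OUTFMT6_COLUMNS


def hit(query="q1", subject="ref1", identity=90.0, length=1500, mismatches=0,
        gaps=0, e_value=1e-20, bitscore=1000.0, **extra):
    row = {
        "query_id": query, "subject_id": subject, "percent_identity": identity,
        "alignment_length": length, "mismatches": mismatches, "gaps": gaps,
        "q_start": 1, "q_end": length, "s_start": 1, "s_end": length,
        "e_value": e_value, "bitscore": bitscore,
    }
    row.update(extra)
    return row


def frame(*rows):
    cols = OUTFMT6_COLUMNS + [c for c in rows[0] if c not in OUTFMT6_COLUMNS]
    return pd.DataFrame(list(rows), columns=cols)


class TestGenomeHomology:
    def test_qualifying_hit_assigned(self, host_table):
        out = host_by_genome_homology(frame(hit(identity=85, length=1200)), host_table)
        assert out[0].predicted_taxon == "Prochlorococcus"

    def test_short_alignment_rejected(self, host_table):
        assert host_by_genome_homology(frame(hit(identity=85, length=900)), host_table) == []

    def test_identity_boundary_strict(self, host_table):
        assert host_by_genome_homology(frame(hit(identity=80.0)), host_table) == []
        assert host_by_genome_homology(frame(hit(identity=80.01)), host_table) != []

    def test_length_boundary_inclusive(self, host_table):
        assert host_by_genome_homology(frame(hit(length=1000)), host_table) != []
        assert host_by_genome_homology(frame(hit(length=999)), host_table) == []

    def test_best_bitscore_wins(self, host_table):
        out = host_by_genome_homology(
            frame(hit(subject="ref4", bitscore=900), hit(subject="ref1", bitscore=1500)),
            host_table,
        )
        assert len(out) == 1
        assert out[0].predicted_taxon == "Prochlorococcus"
        assert out[0].score == 1500

    def test_unknown_subject_skipped(self, host_table):
        assert host_by_genome_homology(frame(hit(subject="mystery")), host_table) == []

    def test_order_insensitive(self, host_table):
        rows = [hit(subject="ref1", bitscore=1500), hit(subject="ref4", bitscore=900)]
        a = host_by_genome_homology(frame(*rows), host_table)
        b = host_by_genome_homology(frame(*rows[::-1]), host_table)
        assert [x.predicted_taxon for x in a] == [x.predicted_taxon for x in b]


def protein_hit(contig="c1", protein="p1", lineage="Bacteria;Cyanobacteria",
                bitscore=500.0, e_value=1e-30, identity=60.0):
    return {
        "contig_id": contig, "protein_id": protein, "subject_lineage": lineage,
        "bitscore": bitscore, "e_value": e_value, "percent_identity": identity,
    }


class TestContigTaxonomy:
    def test_low_total_bitscore_unclassified(self):
        hits = pd.DataFrame([protein_hit(bitscore=900.0)])
        assert classify_contig_taxonomy(hits)["c1"] == []

    def test_eighty_percent_voting_rule(self):
        lin = "Bacteria;Cyanobacteria;Cyanophyceae;Synechococcales;Prochloraceae;"
        hits = pd.DataFrame([
            protein_hit(protein="p1", lineage=lin + "Prochlorococcus", bitscore=900.0),
            protein_hit(protein="p2", lineage=lin + "Synechococcus", bitscore=200.0),
        ])
        # genus share 900/1100 = 81.8% >= 80% -> classified at genus
        out = classify_contig_taxonomy(hits)["c1"]
        assert out[-1] == "Prochlorococcus"

    def test_split_genus_stops_above(self):
        lin = "Bacteria;Cyanobacteria;Cyanophyceae;Synechococcales;Prochloraceae;Prochlorococcus;"
        hits = pd.DataFrame([
            protein_hit(protein="p1", lineage=lin + "sp1", bitscore=600.0),
            protein_hit(protein="p2", lineage=lin + "sp2", bitscore=600.0),
        ])
        out = classify_contig_taxonomy(hits)["c1"]
        assert out[-1] == "Prochlorococcus"  # species vote splits 50/50

    def test_prefilters_apply_before_voting(self):
        hits = pd.DataFrame([
            protein_hit(bitscore=2000.0, e_value=1e-3),      # e-value fails
            protein_hit(protein="p2", bitscore=2000.0, identity=25.0),  # identity fails
        ])
        assert classify_contig_taxonomy(hits)["c1"] == []

    def test_lineage_is_contiguous_prefix_with_nonincreasing_share(self):
        hits = pd.DataFrame([
            protein_hit(protein="p1", lineage="Bacteria;Cyanobacteria;Cyanophyceae", bitscore=850.0),
            protein_hit(protein="p2", lineage="Bacteria;Proteobacteria", bitscore=150.0),
            protein_hit(protein="p3", lineage="Bacteria;Cyanobacteria;OtherClass", bitscore=100.0),
        ])
        out = classify_contig_taxonomy(hits, min_total_bitscore=1000.0)["c1"]
        assert out[0] == "Bacteria"
        # Cyanobacteria holds 950/1100 = 86% but neither class reaches 80%
        assert out == ["Bacteria", "Cyanobacteria"]


class TestCrispr:
    def spacers(self, mismatches, gaps=0, length=28, align=None):
        return frame(hit(query="sp1", subject="mvc1", mismatches=mismatches, gaps=gaps,
                         length=align if align is not None else length,
                         query_length=length))

    def test_two_errors_accepted(self, host_table):
        out = host_by_crispr(self.spacers(mismatches=2), host_table, {"sp1": "ref1"})
        assert out[0].predicted_taxon == "Prochlorococcus"

    def test_three_errors_rejected(self, host_table):
        assert host_by_crispr(self.spacers(mismatches=3), host_table, {"sp1": "ref1"}) == []

    def test_mismatches_plus_gaps_counted_together(self, host_table):
        assert host_by_crispr(self.spacers(mismatches=2, gaps=1), host_table, {"sp1": "ref1"}) == []

    def test_partial_spacer_match_rejected(self, host_table):
        out = host_by_crispr(self.spacers(mismatches=0, align=20), host_table, {"sp1": "ref1"})
        assert out == []

    def test_exact_match_support_one(self, host_table):
        out = host_by_crispr(self.spacers(mismatches=0), host_table, {"sp1": "ref1"})
        assert out[0].score == 1.0

    def test_conflicting_phyla_all_reported(self, host_table):
        hits = frame(
            hit(query="sp1", subject="mvc1", length=28, query_length=28),
            hit(query="sp2", subject="mvc1", length=28, query_length=28),
        )
        out = host_by_crispr(hits, host_table, {"sp1": "ref1", "sp2": "ref4"})
        assert len(out) == 2
        assert all("CONFLICT" in a.support for a in out)

    def test_missing_length_column_named(self, host_table):
        with pytest.raises(ValueError, match="query_length"):
            host_by_crispr(frame(hit()), host_table, {})


class TestTrna:
    def test_qualifying_hit_assigned(self, host_table):
        out = host_by_trna(frame(hit(identity=95, subject_coverage=0.95)), host_table)
        assert out[0].predicted_taxon == "Prochlorococcus"

    def test_low_coverage_rejected(self, host_table):
        assert host_by_trna(frame(hit(identity=95, subject_coverage=0.8)), host_table) == []

    def test_boundaries_inclusive(self, host_table):
        assert host_by_trna(frame(hit(identity=90.0, subject_coverage=0.9)), host_table) != []
        assert host_by_trna(frame(hit(identity=89.9, subject_coverage=0.9)), host_table) == []

    def test_missing_coverage_column_named(self, host_table):
        with pytest.raises(ValueError, match="subject_coverage"):
            host_by_trna(frame(hit()), host_table)

    def test_bitscore_tie_resolved_deterministically(self, host_table):
        hits = frame(
            hit(subject="ref1", bitscore=800, subject_coverage=0.95, identity=95),
            hit(subject="ref2", bitscore=800, subject_coverage=0.95, identity=95),
        )
        out = host_by_trna(hits, host_table)
        assert len(out) == 1
        assert out[0].predicted_taxon == "Prochlorococcus"  # same genus either way


class TestConsolidate:
    def test_counts_by_method(self):
        assignments = [
            HostAssignment(f"q{i}", "network", ["Bacteria", "Proteobacteria",
                                                "Alphaproteobacteria", "Pelagibacterales",
                                                "Pelagibacteraceae", "Pelagibacter"], 0.8)
            for i in range(3)
        ]
        table = consolidate_predictions(assignments)
        assert table.loc["Pelagibacter"].tolist() == [3, 0, 0, 0, 0]

    def test_methods_counted_independently(self):
        assignments = [
            HostAssignment("q1", "network", ["Bacteria", "Cyanobacteria"], 0.9),
            HostAssignment("q1", "crispr", ["Bacteria", "Proteobacteria"], 1.0),
        ]
        table = consolidate_predictions(assignments)
        assert table.loc["Cyanobacteria", "network"] == 1
        assert table.loc["Proteobacteria", "crispr"] == 1

    def test_empty_input(self):
        assert consolidate_predictions([]).empty

    def test_rows_sorted_by_total(self):
        assignments = [HostAssignment("q1", "network", ["A"], 1.0)]
        assignments += [HostAssignment(f"q{i}", "trna", ["B"], 1.0) for i in range(2, 5)]
        table = consolidate_predictions(assignments)
        assert list(table.index) == ["B", "A"]


def test_tightening_thresholds_never_adds_assignments(host_table):
    rows = [hit(query=f"q{i}", identity=80 + 3 * i, length=950 + 40 * i) for i in range(6)]
    base = host_by_genome_homology(frame(*rows), host_table)
    for min_id, min_len in [(85, 1000), (80, 1100), (90, 1200)]:
        tighter = host_by_genome_homology(frame(*rows), host_table,
                                          min_identity=min_id, min_length=min_len)
        assert {a.query_id for a in tighter} <= {a.query_id for a in base}
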