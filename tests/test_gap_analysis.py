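"""Barcode-gap partitioning, per-species MaxID/MinID and report formatting."""

import itertools
import math

import numpy as np
import pytest

from barcodegap.exceptions import MetadataError, UsageError
from barcodegap.gap_analysis import (
    format_gap_table,
    pair_assignments,
    partition_distances,
    species_gap_table,
)
from barcodegap.k2p import DistanceMatrix
from barcodegap.seqio import SpecimenRecord


def _meta(assignments):
    """{'a1': 'A', ...} -> metadata dict (status native)."""
    return {sid: SpecimenRecord(sid, sp) for sid, sp in assignments.items()}


def _matrix(labels, entries):
    n = len(labels)
    d = np.zeros((n, n))
    idx = {lab: i for i, lab in enumerate(labels)}
    for (a, b), v in entries.items():
        d[idx[a], idx[b]] = d[idx[b], idx[a]] = v
    return DistanceMatrix(labels, d)


@pytest.fixture
def four_specimens():
    labels = ["a1", "a2", "b1", "b2"]
    entries = {
        ("a1", "a2"): 0.002, ("b1", "b2"): 0.004,
        ("a1", "b1"): 0.010, ("a1", "b2"): 0.011,
        ("a2", "b1"): 0.012, ("a2", "b2"): 0.013,
    }
    return _matrix(labels, entries), _meta({"a1": "A", "a2": "A", "b1": "B", "b2": "B"})


class TestPartitionDistances:
    def test_two_species_assignment(self, four_specimens):
        matrix, meta = four_specimens
        intra, inter, skipped = partition_distances(matrix, meta)
        assert intra == {"A": [0.002], "B": [0.004]}
        assert sorted(inter[("A", "B")]) == [0.010, 0.011, 0.012, 0.013]
        assert skipped == 0

    def test_identical_sequences_give_zero_sets(self):
        labels = ["a1", "a2", "b1", "b2"]
        matrix = _matrix(labels, {})
        intra, inter, _ = partition_distances(
            matrix, _meta({"a1": "A", "a2": "A", "b1": "B", "b2": "B"}))
        assert intra == {"A": [0.0], "B": [0.0]}
        assert inter[("A", "B")] == [0.0] * 4

    def test_na_pair_skipped_and_counted(self, four_specimens):
        matrix, meta = four_specimens
        matrix.data[0, 2] = matrix.data[2, 0] = math.nan
        intra, inter, skipped = partition_distances(matrix, meta)
        assert skipped == 1
        assert len(inter[("A", "B")]) == 3

    def test_outgroup_in_neither_set(self, four_specimens):
        matrix, meta = four_specimens
        labels = matrix.labels + ["out"]
        d = np.zeros((5, 5))
        d[:4, :4] = matrix.data
        d[4, :4] = d[:4, 4] = 0.05
        meta = dict(meta, out=SpecimenRecord("out", "Outgroup sp.", "outgroup"))
        intra, inter, _ = partition_distances(DistanceMatrix(labels, d), meta)
        assert "Outgroup sp." not in intra
        assert all("Outgroup sp." not in pair for pair in inter)

    def test_unknown_label_rejected(self, four_specimens):
        matrix, _ = four_specimens
        with pytest.raises(MetadataError):
            partition_distances(matrix, _meta({"a1": "A"}))

    def test_set_conservation(self, rng):
        # every defined off-diagonal pair lands in exactly one set
        labels = [f"s{i}" for i in range(7)]
        d = np.round(rng.uniform(0.001, 0.05, (7, 7)), 6)
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        d[0, 3] = d[3, 0] = math.nan
        meta = _meta({lab: f"sp{i % 3}" for i, lab in enumerate(labels)})
        intra, inter, skipped = partition_distances(DistanceMatrix(labels, d), meta)
        total = sum(map(len, intra.values())) + sum(map(len, inter.values())) + skipped
        assert total == 7 * 6 // 2


def brute_force_gap_rows(matrix, meta):
    """Exhaustive pair-loop oracle for the per-species MaxID/MinID rows."""
    species = sorted({r.species for r in meta.values() if r.status != "outgroup"})
    labels = [l for l in matrix.labels if meta[l].status != "outgroup"]
    rows = {}
    for sp in species:
        mine = [l for l in labels if meta[l].species == sp]
        others = [l for l in labels if meta[l].species != sp]
        intra = [matrix[a, b] for a, b in itertools.combinations(mine, 2)
                 if not math.isnan(matrix[a, b])]
        inter = [matrix[a, b] for a in mine for b in others
                 if not math.isnan(matrix[a, b])]
        rows[sp] = (
            len(mine),
            max(intra) if intra else None,
            min(inter) if inter else None,
        )
    return rows


class TestSpeciesGapTable:
    def test_derived_global_statistics(self, four_specimens):
        matrix, meta = four_specimens
        s = species_gap_table(matrix, meta)
        assert s.global_max_intra == pytest.approx(0.004)
        assert s.global_min_inter == pytest.approx(0.010)
        assert s.gap_exists
        assert s.row("A").nearest_heterospecific == "B"
        assert s.row("B").max_intra == pytest.approx(0.004)

    def test_identical_species_pair_reported_and_blocks_gap(self):
        labels = ["a1", "a2", "b1", "b2", "c1"]
        entries = {("a1", "c1"): 0.02, ("a2", "c1"): 0.02,
                   ("b1", "c1"): 0.02, ("b2", "c1"): 0.02}
        # A and B sequences identical across species: all A-B distances 0
        matrix = _matrix(labels, entries)
        meta = _meta({"a1": "A", "a2": "A", "b1": "B", "b2": "B", "c1": "C"})
        s = species_gap_table(matrix, meta)
        assert s.zero_separation_pairs == [("A", "B")]
        assert not s.gap_exists

    def test_exclusion_restores_gap_but_keeps_overlap_report(self):
        labels = ["a1", "a2", "b1", "b2", "c1", "c2"]
        entries = {("a1", "a2"): 0.001, ("b1", "b2"): 0.001,
                   ("c1", "c2"): 0.002}
        for x in ("a1", "a2", "b1", "b2"):
            for c in ("c1", "c2"):
                entries[(x, c)] = 0.02
        matrix = _matrix(labels, entries)
        meta = _meta({"a1": "A", "a2": "A", "b1": "B", "b2": "B",
                      "c1": "C", "c2": "C"})
        without = species_gap_table(matrix, meta)
        assert not without.gap_exists  # A-B distances are all zero
        s = species_gap_table(matrix, meta, exclude=["B"])
        assert s.gap_exists
        assert s.excluded_species == ["B"]
        assert s.zero_separation_pairs == [("A", "B")]  # computed before exclusion
        assert s.global_min_inter == pytest.approx(0.02)

    def test_singleton_species_max_intra_na(self):
        labels = ["a1", "a2", "c1"]
        matrix = _matrix(labels, {("a1", "a2"): 0.004, ("a1", "c1"): 0.02,
                                  ("a2", "c1"): 0.02})
        s = species_gap_table(matrix, _meta({"a1": "A", "a2": "A", "c1": "C"}))
        assert math.isnan(s.row("C").max_intra)
        assert s.row("C").n_individuals == 1
        assert s.global_max_intra == pytest.approx(0.004)

    def test_fewer_than_two_species_rejected(self):
        labels = ["a1", "a2"]
        matrix = _matrix(labels, {("a1", "a2"): 0.001})
        with pytest.raises(UsageError):
            species_gap_table(matrix, _meta({"a1": "A", "a2": "A"}))

    def test_matches_brute_force_on_random_small_datasets(self, rng):
        for _ in range(25):
            n = int(rng.integers(4, 7))
            labels = [f"s{i}" for i in range(n)]
            d = rng.uniform(0.0, 0.05, (n, n))
            d = np.round((d + d.T) / 2, 6)
            np.fill_diagonal(d, 0)
            meta = _meta({lab: f"sp{int(rng.integers(0, 3))}" for lab in labels})
            if len({r.species for r in meta.values()}) < 2:
                continue
            matrix = DistanceMatrix(labels, d)
            s = species_gap_table(matrix, meta)
            oracle = brute_force_gap_rows(matrix, meta)
            for row in s.rows:
                n_ind, max_i, min_i = oracle[row.species]
                assert row.n_individuals == n_ind
                if max_i is None:
                    assert math.isnan(row.max_intra)
                else:
                    assert row.max_intra == pytest.approx(max_i)
                assert row.min_inter == pytest.approx(min_i)

    def test_adding_specimen_monotone(self, four_specimens):
        # a new conspecific can only raise MaxID and lower MinID for its species
        matrix, meta = four_specimens
        before = species_gap_table(matrix, meta)
        labels = matrix.labels + ["a3"]
        d = np.zeros((5, 5))
        d[:4, :4] = matrix.data
        d[4, :4] = d[:4, 4] = [0.006, 0.006, 0.009, 0.009, 0][:4]
        meta = dict(meta, a3=SpecimenRecord("a3", "A"))
        after = species_gap_table(DistanceMatrix(labels, d), meta)
        assert after.row("A").max_intra >= before.row("A").max_intra
        assert after.row("A").min_inter <= before.row("A").min_inter


class TestFormatting:
    def test_min_id_percent_cell(self, four_specimens):
        matrix, meta = four_specimens
        s = species_gap_table(matrix, meta)
        s.global_min_inter = 0.0071
        table = format_gap_table({"ITS": s})
        assert table.loc["Min ID %", "ITS"] == "0.71"

    def test_zero_prints_as_zero_not_blank(self, four_specimens):
        matrix, meta = four_specimens
        s = species_gap_table(matrix, meta)
        s.rows[0] = s.rows[0].__class__("A", 2, 0.0, 0.01, "B")
        table = format_gap_table({"ITS": s})
        assert table.loc["A", "ITS"] == "0.00"

    def test_na_prints_as_dash(self):
        labels = ["a1", "a2", "c1"]
        matrix = _matrix(labels, {("a1", "a2"): 0.004, ("a1", "c1"): 0.02,
                                  ("a2", "c1"): 0.02})
        s = species_gap_table(matrix, _meta({"a1": "A", "a2": "A", "c1": "C"}))
        table = format_gap_table({"ITS": s})
        assert table.loc["C", "ITS"] == "–"

    def test_rounding_is_half_up(self, four_specimens):
        matrix, meta = four_specimens
        s = species_gap_table(matrix, meta)
        s.global_min_inter = 0.00125  # 0.125% rounds half-up to 0.13
        table = format_gap_table({"ITS": s})
        assert table.loc["Min ID %", "ITS"] == "0.13"


def test_pair_assignments_long_format(four_specimens):
    matrix, meta = four_specimens
    df = pair_assignments(matrix, meta)
    assert len(df) == 6
    assert set(df["class"]) == {"intra", "inter"}
    assert (df[df["class"] == "intra"]["species_a"] ==
            df[df["class"] == "intra"]["species_b"]).all()
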