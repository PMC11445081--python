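import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neostate.tables import (
    AbundanceTable,
    DEFAULT_TIMEPOINT_MAP,
    derive_timepoint_labels,
    parse_gene_field,
    read_abundance_table,
    read_genome_annotations,
    read_sample_metadata,
    reconcile_samples,
    to_counts,
)


def _write_table(tmp_path, rows, samples=None, species=None):
    rows = np.asarray(rows, dtype=float)
    samples = samples or [f"s{i}" for i in range(rows.shape[0])]
    species = species or [f"sp{i}" for i in range(rows.shape[1])]
    df = pd.DataFrame(rows, index=samples, columns=species)
    path = tmp_path / "abund.tsv"
    df.to_csv(path, sep="\t")
    return path


class TestReadAbundance:
    def test_normalized_input_is_preserved(self, tmp_path):
        path = _write_table(tmp_path, [[0.6, 0.4], [1.0, 0.0]])
        table = read_abundance_table(path)
        assert np.allclose(table.values, [[0.6, 0.4], [1.0, 0.0]])
        assert table.sample_ids == ["s0", "s1"]

    def test_small_deviation_renormalized_with_warning(self, tmp_path):
        path = _write_table(tmp_path, [[0.30, 0.69]])
        with pytest.warns(UserWarning, match="renormalized"):
            table = read_abundance_table(path)
        assert np.allclose(table.values[0], [0.30 / 0.99, 0.69 / 0.99])

    def test_count_like_rows_rejected(self, tmp_path):
        path = _write_table(tmp_path, [[3.0, 1.0]])
        with pytest.raises(ValueError, match="not relative abundances"):
            read_abundance_table(path)

    def test_negative_and_duplicate_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="negative"):
            read_abundance_table(_write_table(tmp_path, [[-0.1, 1.1]]))
        path = _write_table(tmp_path, [[0.5, 0.5], [0.5, 0.5]], samples=["a", "a"])
        with pytest.raises(ValueError, match="duplicate"):
            read_abundance_table(path)

    def test_species_as_rows_orientation(self, tmp_path):
        df = pd.DataFrame([[0.6, 1.0], [0.4, 0.0]],
                          index=["spA", "spB"], columns=["s0", "s1"])
        path = tmp_path / "t.tsv"
        df.to_csv(path, sep="\t")
        table = read_abundance_table(path, orientation="species_as_rows")
        assert table.sample_ids == ["s0", "s1"]
        assert np.allclose(table.values, [[0.6, 0.4], [1.0, 0.0]])

    def test_roundtrip_bit_identical(self, tmp_path):
        path = _write_table(tmp_path, [[0.25, 0.75], [0.5, 0.5]])
        table = read_abundance_table(path)
        out = tmp_path / "out.tsv"
        table.to_tsv(out)
        assert read_abundance_table(out).data.equals(table.data)


class TestToCounts:
    def test_exact_halves(self):
        table = AbundanceTable(pd.DataFrame([[0.5, 0.5]], index=["s"], columns=["a", "b"]))
        counts = to_counts(table, depth=1000)
        assert counts.values.tolist() == [[500, 500]]

    def test_depth_below_100_rejected(self):
        table = AbundanceTable(pd.DataFrame([[1 / 3, 2 / 3]], index=["s"], columns=["a", "b"]))
        with pytest.raises(ValueError, match=">= 100"):
            to_counts(table, depth=9)

    def test_exact_rounding(self):
        table = AbundanceTable(
            pd.DataFrame([[0.176, 0.434, 0.390]], index=["s"], columns=list("abc")))
        counts = to_counts(table, depth=10_000)
        assert counts.values.tolist() == [[1760, 4340, 3900]]

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.floats(0.01, 1.0), min_size=2, max_size=8), st.integers(100, 50_000))
    def test_renormalized_counts_recover_fractions_within_rounding_bound(self, raw, depth):
        p = np.array(raw) / np.sum(raw)
        s = len(p)
        table = AbundanceTable(pd.DataFrame([p], index=["s"],
                                            columns=[f"x{i}" for i in range(s)]))
        counts = to_counts(table, depth=depth)
        # each entry is off by <= 1/2 and the row total by <= s/2, so the
        # renormalized fraction is within (1/2 + s/2) / (depth - s/2)
        recovered = counts.to_fractions().values[0]
        bound = (0.5 + 0.5 * s) / (depth - 0.5 * s)
        assert np.all(np.abs(recovered - p) <= bound + 1e-12)


class TestSampleMetadata:
    def _path(self, tmp_path, rows):
        df = pd.DataFrame(rows)
        path = tmp_path / "meta.tsv"
        df.to_csv(path, sep="\t", index=False)
        return path

    def test_day_of_life_maps_to_timepoints(self, tmp_path):
        path = self._path(tmp_path, [
            {"sample_id": "a", "participant_id": "p1", "day_of_life": 4, "birth_mode": "VD"},
            {"sample_id": "b", "participant_id": "p1", "day_of_life": 21, "birth_mode": "VD"},
            {"sample_id": "c", "participant_id": "p2", "day_of_life": 260, "birth_mode": "CS"},
        ])
        meta = read_sample_metadata(path)
        assert list(meta["timepoint_label"]) == ["day4", "day21", "infancy"]

    def test_unknown_birth_mode_rejected(self, tmp_path):
        path = self._path(tmp_path, [
            {"sample_id": "a", "participant_id": "p1", "day_of_life": 4, "birth_mode": "XX"}])
        with pytest.raises(ValueError, match="birth_mode"):
            read_sample_metadata(path)

    def test_missing_covariates_kept_as_explicit_marker(self, tmp_path):
        path = self._path(tmp_path, [
            {"sample_id": "a", "participant_id": "p1", "day_of_life": 7,
             "birth_mode": "VD", "feeding": None},
            {"sample_id": "b", "participant_id": "p2", "day_of_life": 7,
             "birth_mode": "CS", "feeding": "breast"},
        ])
        meta = read_sample_metadata(path)
        assert meta.loc["a", "feeding"] == "missing"
        assert meta.loc["b", "feeding"] == "breast"

    def test_reconciliation_lists_unmatched_samples(self, tmp_path):
        table = AbundanceTable(pd.DataFrame([[1.0], [1.0]], index=["a", "zzz"], columns=["sp"]))
        path = self._path(tmp_path, [
            {"sample_id": "a", "participant_id": "p1", "day_of_life": 7, "birth_mode": "VD"}])
        meta = read_sample_metadata(path)
        listing = reconcile_samples(table, meta)
        assert listing == {"abundance_only": ["zzz"], "metadata_only": [], "shared": 1}

    def test_out_of_window_days_labelled_other(self):
        labels = derive_timepoint_labels(pd.Series([0, 100, 400]), DEFAULT_TIMEPOINT_MAP)
        assert list(labels) == ["other", "other", "other"]


class TestGenomeAnnotations:
    def test_gene_fields_parsed_and_deduplicated(self, tmp_path):
        df = pd.DataFrame([{
            "genome_id": "g1", "species": "B_breve", "completeness": 95.0,
            "contamination": 1.0, "gene_families": "GH95;GH2;GH95",
            "amr_genes": "tetW|tetracycline", "virulence_genes": "",
        }])
        path = tmp_path / "anno.tsv"
        df.to_csv(path, sep="\t", index=False)
        anno = read_genome_annotations(path)
        assert anno.loc["g1", "gene_families"] == ("GH95", "GH2")
        assert anno.loc["g1", "amr_genes"] == ("tetW|tetracycline",)
        assert anno.loc["g1", "virulence_genes"] == ()

    def test_out_of_range_percentages_rejected(self, tmp_path):
        df = pd.DataFrame([{"genome_id": "g1", "completeness": 120.0, "contamination": 0.0}])
        path = tmp_path / "anno.tsv"
        df.to_csv(path, sep="\t", index=False)
        with pytest.raises(ValueError, match="completeness"):
            read_genome_annotations(path)

    def test_parse_gene_field_handles_missing(self):
        assert parse_gene_field(float("nan")) == ()
        assert parse_gene_field("a; b ;a") == ("a", "b")
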