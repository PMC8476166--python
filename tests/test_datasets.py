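"""Dataset model: validation, on-disk round-trips and construction."""

from __future__ import annotations

import numpy as np
import pytest

from orthocomplete.datasets import (
    DatasetConsistencyError,
    DatasetFormatError,
    DatasetTree,
    MarkerDataset,
    MarkerFamily,
    build_dataset,
    load_dataset,
    write_dataset,
)
from orthocomplete.profile import build_profile, score_sequence


def small_dataset(name="tiny", domain="bacteria", codes=(11, 4)):
    markers = tuple(
        MarkerFamily(f"m{i}", (f"ACDEFGHIK{'LMW'[i]}",) * 2, 20.0 + i, 10.0, 0.0)
        for i in range(3)
    )
    return MarkerDataset(name=name, domain=domain, markers=markers, genetic_codes=codes)


class TestInvariants:
    def test_family_rejects_ragged_alignment(self):
        with pytest.raises(ValueError):
            MarkerFamily("m", ("ACD", "AC"), 10.0, 3.0, 0.0)

    def test_family_rejects_whitespace_id(self):
        with pytest.raises(ValueError):
            MarkerFamily("m 1", ("ACD",), 10.0, 3.0, 0.0)

    @pytest.mark.parametrize("field,value", [("score_cutoff", 0.0), ("length_mean", -1.0),
                                             ("length_sigma", -0.1)])
    def test_family_rejects_bad_stats(self, field, value):
        kwargs = dict(marker_id="m", seed_alignment=("ACD",), score_cutoff=10.0,
                      length_mean=3.0, length_sigma=0.0)
        kwargs[field] = value
        with pytest.raises(ValueError):
            MarkerFamily(**kwargs)

    def test_dataset_requires_codes_for_prokaryotes(self):
        with pytest.raises(ValueError):
            small_dataset(domain="bacteria", codes=())

    def test_eukaryote_dataset_needs_no_codes(self):
        ds = small_dataset(domain="eukaryota", codes=())
        assert ds.genetic_codes == ()

    def test_duplicate_marker_ids_rejected(self):
        m = MarkerFamily("m", ("ACD",), 10.0, 3.0, 0.0)
        with pytest.raises(ValueError):
            MarkerDataset("x", "bacteria", (m, m), genetic_codes=(11,))


class TestRoundTrip:
    def test_write_then_load_is_identity(self, tmp_path):
        ds = small_dataset()
        write_dataset(ds, tmp_path / "ds")
        loaded = load_dataset(tmp_path / "ds")
        assert loaded.name == ds.name
        assert loaded.domain == ds.domain
        assert loaded.genetic_codes == (11, 4)
        assert loaded.n_markers == 3
        assert loaded.markers == ds.markers

    def test_roundtrip_of_built_dataset(self, tmp_path, star_bundle):
        ds = star_bundle.build_dataset("rt", species=star_bundle.species[:3])
        write_dataset(ds, tmp_path / "rt")
        loaded = load_dataset(tmp_path / "rt")
        assert loaded.n_markers == ds.n_markers
        for a, b in zip(loaded.markers, ds.markers):
            assert a.marker_id == b.marker_id
            assert a.seed_alignment == b.seed_alignment
            # cutoffs pass through the 2-decimal on-disk format
            assert a.score_cutoff == pytest.approx(b.score_cutoff, abs=0.005)
            assert a.length_mean == pytest.approx(b.length_mean, abs=0.005)
            assert a.length_sigma == pytest.approx(b.length_sigma, abs=0.005)

    def test_two_writes_are_byte_identical(self, tmp_path):
        ds = small_dataset()
        p1 = write_dataset(ds, tmp_path / "a")
        p2 = write_dataset(ds, tmp_path / "b")
        for rel in ["dataset.cfg", "scores_cutoff.tsv", "lengths_cutoff.tsv", "seeds/m0.faa"]:
            assert (p1 / rel).read_bytes() == (p2 / rel).read_bytes()

    def test_refuses_empty_dataset(self, tmp_path):
        ds = small_dataset(domain="eukaryota", codes=())
        object.__setattr__(ds, "markers", ())
        with pytest.raises(ValueError):
            write_dataset(ds, tmp_path / "empty")

    def test_missing_cutoff_row_is_consistency_error(self, tmp_path):
        write_dataset(small_dataset(), tmp_path / "ds")
        scores = tmp_path / "ds" / "scores_cutoff.tsv"
        lines = scores.read_text().splitlines()
        scores.write_text("\n".join(lines[:-1]) + "\n")
        with pytest.raises(DatasetConsistencyError):
            load_dataset(tmp_path / "ds")

    def test_malformed_config_names_file_and_line(self, tmp_path):
        write_dataset(small_dataset(), tmp_path / "ds")
        cfg = tmp_path / "ds" / "dataset.cfg"
        cfg.write_text(cfg.read_text() + "not a key value pair\n")
        with pytest.raises(DatasetFormatError, match=r"dataset\.cfg:\d+"):
            load_dataset(tmp_path / "ds")


class TestBuildDataset:
    def make_table(self, pattern):
        # pattern: orthogroup -> list of per-species copy numbers
        return {
            og: {f"sp{i}": c for i, c in enumerate(copies)}
            for og, copies in pattern.items()
        }

    ALN = {
        "og1": ["MACDEFGHIKLMNPQRSTVW"] * 5,
        "og2": ["MWYVTSRQPNMLKIHGFEDCA"] * 5,
    }

    def test_threshold_inclusion_boundary(self):
        table = self.make_table({"og1": [1, 1, 1, 1, 1], "og2": [1, 1, 1, 1, 2]})
        ds = build_dataset(table, self.ALN, 0.9, name="t", domain="bacteria",
                           genetic_codes=(11,))
        assert ds.marker_ids == ("og1",)  # 0.8 < 0.9 excludes og2

    def test_monotone_in_threshold(self):
        table = self.make_table({"og1": [1, 1, 1, 1, 1], "og2": [1, 1, 1, 1, 0]})
        kept = []
        for thr in (0.5, 0.8, 0.9, 1.0):
            ds = build_dataset(table, self.ALN, thr, name="t", domain="bacteria",
                               genetic_codes=(11,))
            kept.append(set(ds.marker_ids))
        for hi, lo in zip(kept, kept[1:]):
            assert lo <= hi

    def test_no_survivor_is_error(self):
        table = self.make_table({"og1": [2, 2, 2, 2, 2]})
        with pytest.raises(ValueError, match="empty dataset"):
            build_dataset(table, self.ALN, 0.9, name="t", domain="bacteria",
                          genetic_codes=(11,))

    def test_cutoff_is_ninety_percent_of_min_self_score(self):
        seeds = ["MACDEFGHIKLMNPQRSTVW", "MACDEFGHIKLMNPQRSTVY", "MACDEFGHIKLMNPQRSTAW"]
        table = self.make_table({"og1": [1, 1, 1]})
        ds = build_dataset(table, {"og1": seeds}, 0.9, name="t", domain="bacteria",
                           genetic_codes=(11,))
        fam = ds.markers[0]
        prof = build_profile(fam)
        self_scores = [score_sequence(prof, s).bit_score for s in seeds]
        assert fam.score_cutoff == pytest.approx(0.9 * min(self_scores))

    def test_length_stats_match_direct_recomputation(self, star_bundle):
        ds = star_bundle.build_dataset("stats", species=star_bundle.species[:4])
        for fam in ds.markers:
            lengths = np.array([len(s.replace("-", "")) for s in fam.seed_alignment])
            assert fam.length_mean == pytest.approx(lengths.mean())
            assert fam.length_sigma == pytest.approx(lengths.std())


class TestDatasetTree:
    def make_tree(self):
        root = small_dataset("root")
        child = small_dataset("child")
        object.__setattr__(child, "parent", "root")
        leaf = small_dataset("leaf")
        object.__setattr__(leaf, "parent", "child")
        return DatasetTree({"root": root, "child": child, "leaf": leaf})

    def test_roots_and_paths(self):
        tree = self.make_tree()
        assert [ds.name for ds in tree.roots] == ["root"]
        assert tree.path_to_root("leaf") == ("leaf", "child", "root")
        assert tree.is_ancestor("root", "leaf")
        assert tree.is_ancestor("leaf", "leaf")
        assert not tree.is_ancestor("leaf", "child")

    def test_unknown_parent_rejected(self):
        orphan = small_dataset("orphan")
        object.__setattr__(orphan, "parent", "ghost")
        with pytest.raises(ValueError, match="unknown parent"):
            DatasetTree({"orphan": orphan})

    def test_two_roots_per_domain_rejected(self):
        with pytest.raises(ValueError, match="two roots"):
            DatasetTree({"a": small_dataset("a"), "b": small_dataset("b")})
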