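"""Site-aligned matrices, normalization, composites, scoring and grouping."""

import numpy as np
import pandas as pd
import pytest

import nucruler as nr
from nucruler.alignment import sort_matrix_rows, write_matrix_npz, read_matrix_npz
from nucruler.coverage import CoverageTrack
from nucruler.genome import BarrierSite, GenomeDef


@pytest.fixture
def delta_track():
    genome = GenomeDef(("chrT",), (10_000,))
    track = CoverageTrack(genome)
    track["chrT"][5_080] = 1.0
    return genome, track


def _site(center, strand="+", kind="GRF", sid="s0", score=None):
    width = 8
    return BarrierSite("chrT", center - width // 2, center + width - width // 2,
                       strand if kind != "DSB" else ".", kind,
                       score=score, site_id=sid)


class TestExtractAlignedMatrix:
    def test_plus_site_sees_delta_at_positive_offset(self, delta_track):
        _, track = delta_track
        mat = nr.extract_aligned_matrix(track, [_site(5_000, "+")])
        assert mat.values[0, 1000 + 80] == 1.0
        assert mat.values.sum() == 1.0

    def test_minus_site_mirrors_offset(self, delta_track):
        _, track = delta_track
        mat = nr.extract_aligned_matrix(track, [_site(5_000, "-")])
        assert mat.values[0, 1000 - 80] == 1.0

    def test_strand_flip_mirrors_row_exactly(self, small_dataset):
        genome, sites, _, _, reads = small_dataset
        track = nr.compute_coverage(
            nr.shift_reads_to_dyads(reads, genome).fragments, genome)
        site = sites[0]
        flipped = BarrierSite(site.chrom, site.start, site.end,
                              "-" if site.strand == "+" else "+",
                              site.kind, site_id=site.site_id)
        row = nr.extract_aligned_matrix(track, [site]).values[0]
        row_flipped = nr.extract_aligned_matrix(track, [flipped]).values[0]
        assert np.array_equal(row, row_flipped[::-1])

    def test_truncated_window_excluded_and_counted(self, delta_track):
        _, track = delta_track
        mat = nr.extract_aligned_matrix(track, [_site(500, "+"), _site(5_000, "+")])
        assert mat.n_sites == 1
        assert mat.n_excluded == 1

    def test_empty_site_list_raises(self, delta_track):
        _, track = delta_track
        with pytest.raises(ValueError):
            nr.extract_aligned_matrix(track, [])


class TestNormalizePerSite:
    def _matrix(self, values):
        n = values.shape[0]
        meta = pd.DataFrame({
            "site_id": [f"s{i}" for i in range(n)],
            "kind": "GRF", "strand": "+", "score": np.nan,
        })
        return nr.AlignedMatrix(values=values, offsets=np.arange(-1000, 1001),
                                row_meta=meta)

    def test_constant_row_becomes_ones(self):
        mat = self._matrix(np.full((1, 2001), 2.0))
        assert np.allclose(nr.normalize_per_site(mat).values, 1.0)

    def test_zero_rows_dropped_and_counted(self):
        values = np.zeros((2, 2001))
        values[0] = 3.0
        out = nr.normalize_per_site(self._matrix(values))
        assert out.n_sites == 1
        assert out.n_zero_dropped == 1

    def test_all_zero_raises(self):
        with pytest.raises(ValueError):
            nr.normalize_per_site(self._matrix(np.zeros((2, 2001))))

    def test_row_means_exactly_one_and_idempotent(self):
        rng = np.random.default_rng(0)
        mat = self._matrix(rng.random((20, 2001)))
        out = nr.normalize_per_site(mat)
        assert np.allclose(out.values.mean(axis=1), 1.0, atol=1e-12)
        again = nr.normalize_per_site(out)
        assert np.allclose(again.values, out.values, atol=1e-12)


class TestCompositeProfile:
    def test_identical_rows_equal_composite(self):
        row = np.arange(2001, dtype=float)
        meta = pd.DataFrame({"site_id": ["a", "b"], "kind": "GRF",
                             "strand": "+", "score": np.nan})
        mat = nr.AlignedMatrix(np.vstack([row, row]), np.arange(-1000, 1001), meta)
        prof = nr.composite_profile(mat)
        assert np.array_equal(prof.values, row)
        assert prof.n_sites == 2

    def test_row_plus_mirror_is_symmetric(self):
        rng = np.random.default_rng(1)
        row = rng.random(2001)
        meta = pd.DataFrame({"site_id": ["a", "b"], "kind": "GRF",
                             "strand": "+", "score": np.nan})
        mat = nr.AlignedMatrix(np.vstack([row, row[::-1]]),
                               np.arange(-1000, 1001), meta)
        prof = nr.composite_profile(mat)
        assert np.allclose(prof.values, prof.values[::-1])

    def test_synthetic_composite_peak_at_phasing_plus_half_footprint(
            self, jitter_free_dataset):
        genome, sites, params, _, reads = jitter_free_dataset
        res = nr.quantify_reads(reads, genome, sites)
        # brute-force argmax over the first search window, with the plateau
        # of the noise-free boxcar resolved to its center
        assert res.peaks.downstream[0] == params.phasing_distance + 73


class TestScoreSites:
    def _score_matrix(self, scores):
        n = len(scores)
        values = np.zeros((n, 2001))
        values[:, 1000 - 280: 1000 - 160] = np.asarray(scores)[:, None]
        meta = pd.DataFrame({"site_id": [f"s{i}" for i in range(n)],
                             "kind": "GRF", "strand": "+", "score": np.nan})
        return nr.AlignedMatrix(values, np.arange(-1000, 1001), meta)

    def test_top_eighth_selects_single_best_of_eight(self):
        scores, selected = nr.score_sites_by_window(self._score_matrix(range(1, 9)))
        assert selected == ["s7"]
        assert scores["s7"] == 8.0

    def test_equal_scores_tie_broken_by_site_id(self):
        _, selected = nr.score_sites_by_window(self._score_matrix([5.0] * 8))
        assert selected == ["s0"]

    def test_selection_invariant_under_permutation(self):
        rng = np.random.default_rng(3)
        base = list(rng.random(16))
        _, sel_a = nr.score_sites_by_window(self._score_matrix(base), top_fraction=0.25)
        mat = self._score_matrix(base)
        perm = rng.permutation(16)
        permuted = nr.AlignedMatrix(mat.values[perm], mat.offsets,
                                    mat.row_meta.loc[perm].reset_index(drop=True))
        _, sel_b = nr.score_sites_by_window(permuted, top_fraction=0.25)
        assert set(sel_a) == set(sel_b)

    def test_window_outside_matrix_raises(self):
        with pytest.raises(ValueError):
            nr.score_sites_by_window(self._score_matrix([1.0]),
                                     window_start_offset=-1500)


class TestGroupSites:
    def test_sense_gene_is_group1(self):
        site = _site(5_000, "+", sid="s0")
        groups = nr.group_sites_by_orientation([site], [("chrT", 5_200, "+")])
        assert groups.group1 == ["s0"]

    def test_antisense_gene_is_group2(self):
        site = _site(5_000, "+", sid="s0")
        groups = nr.group_sites_by_orientation([site], [("chrT", 4_800, "-")])
        assert groups.group2 == ["s0"]

    def test_divergent_genes_are_group3(self):
        site = _site(5_000, "+", sid="s0")
        genes = [("chrT", 5_200, "+"), ("chrT", 4_800, "-")]
        assert nr.group_sites_by_orientation([site], genes).group3 == ["s0"]

    def test_distant_gene_is_other(self):
        site = _site(5_000, "+", sid="s0")
        groups = nr.group_sites_by_orientation([site], [("chrT", 6_000, "+")])
        assert groups.other == ["s0"]


class TestMatrixIO:
    def test_npz_round_trip(self, tmp_path, delta_track):
        _, track = delta_track
        mat = nr.extract_aligned_matrix(track, [_site(5_000, "+", score=1.5)])
        path = tmp_path / "matrix.npz"
        write_matrix_npz(mat, path)
        back = read_matrix_npz(path)
        assert np.array_equal(back.values, mat.values)
        assert list(back.row_meta["site_id"]) == list(mat.row_meta["site_id"])

    def test_sort_rows_by_score_descending(self, delta_track):
        _, track = delta_track
        sites = [_site(4_000, "+", sid="a", score=1.0),
                 _site(5_000, "+", sid="b", score=3.0),
                 _site(6_000, "+", sid="c", score=2.0)]
        mat = nr.extract_aligned_matrix(track, sites)
        ordered = sort_matrix_rows(mat, by="score")
        assert list(ordered.row_meta["site_id"]) == ["b", "c", "a"]
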