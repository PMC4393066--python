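"""N-island mapping, stripping and the mask/split restoration rule."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from isoseg.nislands import map_n_islands, restore_domains, strip_ns
from isoseg.sequences import GenomicSequence, Interval


def ivs(pairs):
    return [Interval(a, b) for a, b in pairs]


class TestMapNIslands:
    @pytest.mark.parametrize(
        "residues,expected",
        [
            ("ACGT", []),
            ("ANNGT", [(1, 3)]),
            ("NNACGNN", [(0, 2), (5, 7)]),
            ("NNNN", [(0, 4)]),
        ],
    )
    def test_maximal_runs(self, residues, expected):
        nmap = map_n_islands(GenomicSequence("s", residues))
        assert [(i.start, i.end) for i in nmap.islands] == expected

    @given(st.text(alphabet="AN", min_size=1, max_size=200))
    def test_islands_cover_exactly_the_ns(self, residues):
        seq = GenomicSequence("s", residues)
        covered = np.zeros(len(residues), dtype=bool)
        for isl in map_n_islands(seq).islands:
            assert residues[isl.start:isl.end] == "N" * isl.length
            covered[isl.start:isl.end] = True
        assert all(covered[i] == (c == "N") for i, c in enumerate(residues))


class TestStripNs:
    def test_interior_island(self):
        stripped, cmap = strip_ns(GenomicSequence("s", "ANNGT"))
        assert stripped.residues == "AGT"
        assert cmap.to_original(0) == 0
        assert cmap.to_original(1) == 3
        assert cmap.to_original(2) == 4

    def test_leading_n(self):
        stripped, cmap = strip_ns(GenomicSequence("s", "NA"))
        assert stripped.residues == "A"
        assert cmap.to_original(0) == 1

    def test_n_free_is_identity(self):
        stripped, cmap = strip_ns(GenomicSequence("s", "ACGT"))
        assert stripped.residues == "ACGT"
        assert [cmap.to_original(i) for i in range(4)] == [0, 1, 2, 3]

    def test_all_n_errors(self):
        with pytest.raises(ValueError, match="entirely N"):
            strip_ns(GenomicSequence("s", "NNN"))

    @given(st.text(alphabet="ACGTN", min_size=1, max_size=300).filter(lambda s: set(s) != {"N"}))
    def test_round_trip_restores_non_n_positions(self, residues):
        seq = GenomicSequence("s", residues)
        stripped, cmap = strip_ns(seq)
        assert stripped.residues == residues.replace("N", "")
        for pos in range(stripped.length):
            assert residues[cmap.to_original(pos)] == stripped.residues[pos]


class TestRestoreDomains:
    def test_large_island_splits_domain(self):
        # 200 kb sequence, one 150 kb stripped domain, 50 kb island at its centre
        nmap_islands = ivs([(75_000, 125_000)])
        from isoseg.nislands import NIslandMap, CoordinateMap

        cmap = CoordinateMap(
            np.array([0, 75_000]), np.array([75_000, 150_000]),
            np.array([0, 125_000]), 200_000,
        )
        nmap = NIslandMap("s", nmap_islands, 200_000)
        segs = restore_domains(ivs([(0, 150_000)]), cmap, nmap, max_mask=50_000)
        spans = [(s.interval.start, s.interval.end, s.is_n_segment) for s in segs]
        assert spans == [(0, 75_000, False), (75_000, 125_000, True), (125_000, 200_000, False)]

    def _setup(self, residues):
        seq = GenomicSequence("s", residues)
        stripped, cmap = strip_ns(seq)
        nmap = map_n_islands(seq)
        return stripped, cmap, nmap

    def test_small_island_is_masked(self):
        stripped, cmap, nmap = self._setup("ACGT" * 5 + "N" * 4 + "ACGT" * 5)
        segs = restore_domains([Interval(0, 40)], cmap, nmap, max_mask=10)
        assert [(s.interval.start, s.interval.end, s.is_n_segment) for s in segs] == [(0, 44, False)]

    def test_junction_island_appends_upstream(self):
        # two stripped domains meeting exactly at a masked island
        stripped, cmap, nmap = self._setup("AAAA" + "NN" + "GGGG")
        segs = restore_domains([Interval(0, 4), Interval(4, 8)], cmap, nmap, max_mask=10)
        spans = [(s.interval.start, s.interval.end) for s in segs]
        assert spans == [(0, 6), (6, 10)]

    def test_junction_island_splits_when_large(self):
        stripped, cmap, nmap = self._setup("AAAA" + "NN" + "GGGG")
        segs = restore_domains([Interval(0, 4), Interval(4, 8)], cmap, nmap, max_mask=2)
        spans = [(s.interval.start, s.interval.end, s.is_n_segment) for s in segs]
        assert spans == [(0, 4, False), (4, 6, True), (6, 10, False)]

    def test_leading_and_trailing_masked_islands(self):
        stripped, cmap, nmap = self._setup("NN" + "ACGT" + "N")
        segs = restore_domains([Interval(0, 4)], cmap, nmap, max_mask=10)
        assert [(s.interval.start, s.interval.end) for s in segs] == [(0, 7)]

    def test_non_tiling_domains_error(self):
        stripped, cmap, nmap = self._setup("ACGTACGT")
        with pytest.raises(ValueError, match="does not tile"):
            restore_domains([Interval(0, 3)], cmap, nmap)

    @given(
        st.text(alphabet="ACGTN", min_size=4, max_size=400).filter(lambda s: set(s) != {"N"}),
        st.integers(min_value=0, max_value=20),
        st.data(),
    )
    def test_tiling_and_max_mask_monotonicity(self, residues, max_mask, data):
        seq = GenomicSequence("s", residues)
        stripped, cmap = strip_ns(seq)
        nmap = map_n_islands(seq)
        # random tiling segmentation of the stripped axis
        n_cuts = data.draw(st.integers(0, min(5, stripped.length - 1)))
        cuts = sorted(data.draw(
            st.lists(st.integers(1, stripped.length - 1), min_size=n_cuts,
                     max_size=n_cuts, unique=True)
        )) if stripped.length > 1 else []
        edges = [0] + cuts + [stripped.length]
        domains = ivs(zip(edges, edges[1:]))
        segs = restore_domains(domains, cmap, nmap, max_mask=max_mask)
        # tiling conservation on the original axis
        pos = 0
        for s in segs:
            assert s.interval.start == pos
            pos = s.interval.end
        assert pos == seq.length
        # raising max_mask never increases the segment count
        more = restore_domains(domains, cmap, nmap, max_mask=max_mask + 5)
        assert len(more) <= len(segs)
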