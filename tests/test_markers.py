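import numpy as np
import pytest

from cryptclock.markers import (
    NA,
    CharacterMatrix,
    build_character_matrix,
    clonal_markers,
    crypt_biopsy_divergence,
    extract_breakpoints,
    phase_alleles,
    window_distance,
)
from cryptclock.profiles_io import Segment, SegmentProfile, ValidationError
from cryptclock.synthetic_data import SimConfig, simulate_patient

from conftest import normal_profile, profile_with


class TestExtractBreakpoints:
    def test_all_normal_profile_empty(self, tiny_grid):
        assert extract_breakpoints(normal_profile("s", tiny_grid)) == set()

    def test_unphased_rejected(self, tiny_grid):
        with pytest.raises(ValidationError, match="phased"):
            extract_breakpoints(normal_profile("s", tiny_grid, phased=False))

    def test_partial_loss_emits_start_and_internal_marker(self):
        # chr 9-like: first 40 Mb one allele lost, rest diploid
        segs = [Segment("9", 0, 40_000_000, 0, 1),
                Segment("9", 40_000_000, 100_000_000, 1, 1)]
        markers = extract_breakpoints(SegmentProfile("s", segs, phased=True))
        keys = {(m.chromosome, m.boundary_position, m.allele_label) for m in markers}
        assert keys == {("9", 0, 1), ("9", 40_000_000, 1)}
        trans = {m.boundary_position: m.transition for m in markers}
        assert trans[0] == (1, 0)
        assert trans[40_000_000] == (0, 1)

    def test_whole_chromosome_cnloh_emits_four_edge_markers(self):
        segs = [Segment("5", 0, 50_000_000, 2, 0)]
        markers = extract_breakpoints(SegmentProfile("s", segs, phased=True))
        keys = {(m.boundary_position, m.allele_label) for m in markers}
        assert keys == {(0, 1), (50_000_000, 1), (0, 2), (50_000_000, 2)}


class TestPhasing:
    def test_single_sample_is_flagged_phased(self, tiny_grid):
        out = phase_alleles([normal_profile("s", tiny_grid, phased=False)], 0)
        assert out[0].phased

    def test_shared_loss_gets_shared_label(self, tiny_grid):
        # same haplotype lost in both samples; second sample scrambled
        a = profile_with("a", tiny_grid, {("1", 0): (0, 1)}, phased=False)
        b = profile_with("b", tiny_grid, {("1", 0): (1, 0)}, phased=False)
        phased = phase_alleles([a, b], 0)
        ka = {m.key for m in extract_breakpoints(phased[0])}
        kb = {m.key for m in extract_breakpoints(phased[1])}
        assert ka == kb

    def test_opposite_haplotype_losses_stay_distinct(self, tiny_grid):
        # loss of opposite alleles on the same segment plus a shared
        # anchoring loss elsewhere on the chromosome fixes orientation
        a = profile_with("a", tiny_grid,
                         {("1", 0): (0, 1), ("1", 4_000_000): (0, 1)},
                         phased=False)
        b = profile_with("b", tiny_grid,
                         {("1", 0): (0, 1), ("1", 4_000_000): (1, 0)},
                         phased=False)
        phased = phase_alleles([a, b], 0)
        ka = {m.key for m in extract_breakpoints(phased[0])}
        kb = {m.key for m in extract_breakpoints(phased[1])}
        shared = ka & kb
        # anchor segment [0, 2Mb) markers agree on allele; the opposite-allele
        # segment [4, 6 Mb) boundaries remain sample-specific
        assert {(c, p) for c, p, _ in shared} == {("1", 0), ("1", 2_000_000)}
        assert ka != kb  # the second locus differs by allele

    def test_global_flip_leaves_shared_private_counts(self, tiny_grid):
        a = profile_with("a", tiny_grid, {("1", 0): (0, 1)}, phased=False)
        b = profile_with("b", tiny_grid, {("1", 0): (0, 1), ("2", 0): (2, 1)},
                         phased=False)
        flip = lambda p: SegmentProfile(
            p.sample_id,
            [Segment(s.chrom, s.start, s.end, s.cn2, s.cn1) for s in p.segments],
            phased=p.phased)
        pa = phase_alleles([a, b], 0)
        pb = phase_alleles([flip(a), flip(b)], 0)
        def counts(pair):
            ka = {m.key for m in extract_breakpoints(pair[0])}
            kb = {m.key for m in extract_breakpoints(pair[1])}
            return len(ka & kb), len(ka ^ kb)
        assert counts(pa) == counts(pb)


class TestCharacterMatrix:
    def test_identical_profiles_all_ones(self, tiny_grid):
        profs = [profile_with(s, tiny_grid, {("1", 0): (0, 1)}) for s in "abc"]
        _, matrix = build_character_matrix(profs)
        assert (matrix.values == 1).all()

    def test_disjoint_events_identity_pattern(self, tiny_grid):
        a = profile_with("a", tiny_grid, {("1", 0): (0, 1)})
        b = profile_with("b", tiny_grid, {("2", 0): (0, 1)})
        _, matrix = build_character_matrix([a, b])
        df = matrix.to_dataframe()
        chr1_cols = [c for c in df.columns if c.startswith("1:")]
        chr2_cols = [c for c in df.columns if c.startswith("2:")]
        assert (df.loc["a", chr1_cols] == 1).all() and (df.loc["a", chr2_cols] == 0).all()
        assert (df.loc["b", chr2_cols] == 1).all() and (df.loc["b", chr1_cols] == 0).all()

    def test_simulator_incidence_oracle(self):
        from conftest import markers_match_up_to_chromosome_flips

        config = SimConfig(biopsies_np=(1, 1), lambda_true=0.003)
        profiles, _, truth = simulate_patient(config, seed=5, progressor=False)
        crypts = [p for p in profiles if not p.sample_id.endswith("epi")]
        _, matrix = build_character_matrix(crypts)
        df = matrix.to_dataframe()

        def parse_id(mid):
            c, p, a = mid.rsplit(":", 2)
            return (c, int(p), int(a[1]))

        found = {sid: {parse_id(m) for m in df.columns[df.loc[sid] == 1]}
                 for sid in df.index}
        expected = {sid: {(c, p, a + 1) for c, p, a in truth.marker_truth[sid]}
                    for sid in df.index}
        assert markers_match_up_to_chromosome_flips(found, expected)

    def test_no_all_na_column(self):
        with pytest.raises(ValidationError):
            CharacterMatrix(["a", "b"], ["m1"], np.array([[NA], [NA]]))

    def test_nexus_export(self, tiny_grid):
        a = profile_with("a", tiny_grid, {("1", 0): (0, 1)})
        b = profile_with("b", tiny_grid, {})
        _, matrix = build_character_matrix([a, b])
        nexus = matrix.to_nexus()
        assert "DATATYPE=STANDARD" in nexus and "NTAX=2" in nexus


class TestClonalMarkers:
    def test_all_one_column_returned_partial_excluded(self, tiny_grid):
        shared = {("1", 0): (2, 0)}  # cnLOH clonal marker
        a = profile_with("a", tiny_grid, shared)
        b = profile_with("b", tiny_grid, {**shared, ("2", 0): (0, 1)})
        _, matrix = build_character_matrix([a, b])
        clonal = clonal_markers(matrix)
        assert all(m.startswith("1:") for m in clonal)
        assert len(clonal) == 4  # cnLOH start/end x both alleles

    def test_ubiquitous_cnloh_fixture(self, tiny_grid):
        # one ubiquitous cnLOH pair plus private markers per sample
        shared = {("1", 0): (2, 0)}
        profs = [
            profile_with("a", tiny_grid, shared),
            profile_with("b", tiny_grid, {**shared, ("2", 0): (1, 0)}),
            profile_with("c", tiny_grid, {**shared, ("2", 4_000_000): (2, 1)}),
        ]
        _, matrix = build_character_matrix(profs)
        # the cnLOH covers the first grid segment: markers at 0 and 2 Mb
        assert set(clonal_markers(matrix)) == {
            "1:0:a1", "1:0:a2", "1:2000000:a1", "1:2000000:a2",
        }


class TestDivergence:
    def _metas(self, crypt_meta_factory, biopsy_meta_factory, crypts):
        metas = [crypt_meta_factory(c, "B1", section=1 + i // 2, slot="ab"[i % 2])
                 for i, c in enumerate(crypts)]
        metas.append(biopsy_meta_factory("epi", "B1"))
        return metas

    def test_identical_crypt_zero_divergence(self, tiny_grid, crypt_meta_factory,
                                             biopsy_meta_factory):
        ov = {("1", 0): (0, 1)}
        profs = [profile_with("c1", tiny_grid, ov), profile_with("epi", tiny_grid, ov)]
        _, matrix = build_character_matrix(profs)
        recs = crypt_biopsy_divergence(
            matrix, self._metas(crypt_meta_factory, biopsy_meta_factory, ["c1"]))
        assert recs[0].pct_divergent == 0.0
        assert recs[0].informative

    def test_private_markers_percentage(self, toy_grid, crypt_meta_factory,
                                        biopsy_meta_factory):
        # biopsy has 4 lesions -> 8 markers; crypt adds one more lesion (+2)
        shared = {(str(c), 10_000_000): (0, 1) for c in range(1, 5)}
        crypt = profile_with("c1", toy_grid, {**shared, ("1", 30_000_000): (2, 1)})
        epi = profile_with("epi", toy_grid, shared)
        _, matrix = build_character_matrix([crypt, epi])
        recs = crypt_biopsy_divergence(
            matrix, self._metas(crypt_meta_factory, biopsy_meta_factory, ["c1"]))
        assert recs[0].n_private_to_crypt == 2
        assert recs[0].n_missing_from_crypt == 0
        assert recs[0].pct_divergent == pytest.approx(100 * 2 / 10)

    def test_empty_crypt_fully_divergent(self, tiny_grid, crypt_meta_factory,
                                         biopsy_meta_factory):
        crypt = profile_with("c1", tiny_grid, {})
        epi = profile_with("epi", tiny_grid, {("1", 0): (0, 1), ("1", 4_000_000): (2, 1)})
        _, matrix = build_character_matrix([crypt, epi])
        recs = crypt_biopsy_divergence(
            matrix, self._metas(crypt_meta_factory, biopsy_meta_factory, ["c1"]))
        assert recs[0].n_missing_from_crypt == matrix.shape[1]
        assert recs[0].pct_divergent == 100.0

    def test_missing_parent_rejected(self, tiny_grid, crypt_meta_factory):
        crypt = profile_with("c1", tiny_grid, {("1", 0): (0, 1)})
        _, matrix = build_character_matrix([crypt])
        with pytest.raises(ValidationError, match="biopsy"):
            crypt_biopsy_divergence(matrix, [crypt_meta_factory("c1", "B1")])


class TestWindowDistance:
    def test_identical_zero(self, tiny_grid):
        a = profile_with("a", tiny_grid, {("1", 0): (3, 1)})
        assert window_distance(a, a) == 0.0

    def test_one_window_of_twenty(self):
        # two 10 Mb chromosomes -> 20 windows of 1 Mb; alter one window
        segs_a = [Segment("1", 0, 10_000_000, 1, 1),
                  Segment("2", 0, 10_000_000, 1, 1)]
        segs_b = [Segment("1", 0, 1_000_000, 2, 1),
                  Segment("1", 1_000_000, 10_000_000, 1, 1),
                  Segment("2", 0, 10_000_000, 1, 1)]
        a = SegmentProfile("a", segs_a, phased=True)
        b = SegmentProfile("b", segs_b, phased=True)
        assert window_distance(a, b) == pytest.approx(5.0)

    def test_symmetry_and_range_random(self, toy_grid):
        rng = np.random.default_rng(3)
        for _ in range(10):
            sa = rng.integers(0, 4, size=(toy_grid.total_segments, 2))
            sb = rng.integers(0, 4, size=(toy_grid.total_segments, 2))
            a = SegmentProfile.from_grid_states("a", toy_grid, sa, phased=True)
            b = SegmentProfile.from_grid_states("b", toy_grid, sb, phased=True)
            d_ab = window_distance(a, b)
            assert d_ab == window_distance(b, a)
            assert 0.0 <= d_ab <= 100.0
            if np.array_equal(sa.sum(axis=1), sb.sum(axis=1)):
                assert d_ab == 0.0
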