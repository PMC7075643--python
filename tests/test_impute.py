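import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from admixgwas import impute, simulate
from admixgwas.impute import (ORIGIN_D, OriginCalls, call_parental_origin,
                              impute_admixed_panel, segment_mosaic,
                              selection_bias_scan, smooth_origins)
from admixgwas.io_core import MISSING, GenotypeMatrix, MarkerMap


def _map(positions, chrom="1"):
    return MarkerMap([f"m{i}" for i in range(len(positions))],
                     [chrom] * len(positions), positions)


class TestOriginCalls:
    def test_informative_marker_gives_matching_parent(self):
        mm = _map([10, 20, 30])
        calls = call_parental_origin([1, 1, MISSING], [1, 1, 1], [0, 1, 0], mm)
        assert calls.origins[0] == ORIGIN_D        # parents differ, matches D
        assert calls.origins[1] == MISSING         # parents agree
        assert calls.origins[2] == MISSING         # admixed missing
        assert calls.n_missing == 1

    def test_mendelian_inconsistency_counted(self):
        mm = _map([10])
        calls = call_parental_origin([0], [1], [1], mm)
        assert calls.origins[0] == MISSING
        assert calls.n_mendelian == 1


class TestSmoothing:
    def _calls(self, origins):
        return OriginCalls("x", _map(list(range(10, 10 * (len(origins) + 1), 10))),
                           np.array(origins, dtype=np.int8))

    def test_lone_discordant_call_removed(self):
        c = self._calls([0, 0, 0, 1, 0, 0, 0])
        out = smooth_origins(c, max_discordant=1, min_flank=2)
        assert list(out.origins) == [0, 0, 0, MISSING, 0, 0, 0]

    def test_long_run_kept(self):
        c = self._calls([0, 0, 1, 1, 1, 0])
        out = smooth_origins(c, max_discordant=1, min_flank=2)
        assert list(out.origins) == [0, 0, 1, 1, 1, 0]

    def test_uniform_sequence_unchanged(self):
        c = self._calls([0] * 6)
        out = smooth_origins(c)
        assert list(out.origins) == [0] * 6

    def test_short_flank_prevents_smoothing(self):
        c = self._calls([0, 1, 0, 0, 0])
        out = smooth_origins(c, max_discordant=1, min_flank=2)
        # left flank has a single call: the 1 stays
        assert list(out.origins) == [0, 1, 0, 0, 0]

    @settings(deadline=None, max_examples=60)
    @given(st.lists(st.sampled_from([-1, 0, 1]), min_size=1, max_size=40))
    def test_idempotent(self, origins):
        c = self._calls(origins)
        once = smooth_origins(c)
        twice = smooth_origins(once)
        np.testing.assert_array_equal(once.origins, twice.origins)


class TestSegmentMosaic:
    def test_half_split_rule(self):
        shared = _map([100_000, 200_000])
        dense = _map([100_000, 120_000, 140_000, 160_000, 180_000, 200_000])
        calls = OriginCalls("x", shared, np.array([0, 1], dtype=np.int8))
        track, ivs = segment_mosaic(calls, dense, "pd", "pf")
        assert len(ivs) == 1
        assert ivs[0].breakpoint == 150_000
        v = track.origin_codes("1", dense.positions)
        np.testing.assert_array_equal(v, [0, 0, 0, 1, 1, 1])

    def test_empty_interval_midpoint(self):
        shared = _map([100, 200])
        dense = _map([100, 200])
        calls = OriginCalls("x", shared, np.array([0, 1], dtype=np.int8))
        _track, ivs = segment_mosaic(calls, dense, "pd", "pf")
        assert ivs[0].breakpoint == 150

    def test_no_recombination_single_segment(self):
        shared = _map([100, 200, 300])
        dense = _map([50, 150, 250, 350])
        calls = OriginCalls("x", shared, np.array([1, 1, 1], dtype=np.int8))
        track, ivs = segment_mosaic(calls, dense, "pd", "pf")
        assert ivs == []
        assert track.segments["1"] == [(1, 350, "F", "pf")]

    def test_all_undetermined_chromosome_errors(self):
        shared = _map([100])
        dense = _map([100])
        calls = OriginCalls("bad", shared, np.array([MISSING], dtype=np.int8))
        with pytest.raises(Exception, match="bad"):
            segment_mosaic(calls, dense)

    def test_track_always_tiles(self):
        rng = np.random.default_rng(4)
        shared = _map(sorted(rng.choice(10_000, 30, replace=False) + 1))
        dense = _map(sorted(rng.choice(100_000, 300, replace=False) + 1))
        calls = OriginCalls("x", shared,
                            rng.integers(0, 2, 30).astype(np.int8))
        track, _ = segment_mosaic(calls, dense, "pd", "pf")
        track.validate()  # tiling invariant
        assert (track.origin_vector(dense) != MISSING).all()


@pytest.fixture(scope="module")
def dh_world():
    """Simulated DHs with a fully informative shared sub-panel."""
    cfg = simulate.SimConfig(seed=42, n_dent=6, n_flint=6, n_admixed=12,
                             n_markers=600, n_chromosomes=3)
    rng = np.random.default_rng(cfg.seed)
    G_pure, ped_pure, _ = simulate.simulate_founders(cfg, rng)
    shared_idx = np.arange(0, 600, 10)
    calls = G_pure.calls.copy()
    bg = ped_pure.background_of(G_pure.lines)
    calls[np.ix_(bg == "D", shared_idx)] = 1   # parents differ at every
    calls[np.ix_(bg == "F", shared_idx)] = 0   # shared marker
    G_pure = GenotypeMatrix(G_pure.lines, G_pure.markers, calls)
    G, ped, tracks = simulate.simulate_dh(G_pure, ped_pure, cfg, rng)
    admixed = [l for l in G.lines if l.startswith("A")]
    G_adm_shared = simulate.shared_panel(G.subset_lines(admixed), every=10)
    return G, ped, tracks, G_pure, G_adm_shared


class TestFullPipeline:
    def test_exact_recovery_outside_recombination_intervals(self, dh_world):
        """Between the outermost informative markers, every error lies
        strictly inside a recombination interval; a crossover beyond the
        terminal informative marker is invisible to any method."""
        G, ped, tracks, G_pure, G_adm_shared = dh_world
        # the simulated calls carry no genotyping errors, so the
        # discordant-call smoothing is disabled for the exactness claim
        result = impute_admixed_panel(G_adm_shared, G_pure, ped,
                                      max_discordant=0)
        dense = G_pure.markers
        shared = G_adm_shared.markers
        covered = np.zeros(len(dense), bool)
        for chrom in np.unique(dense.chromosomes):
            spos = shared.positions[shared.chromosomes == chrom]
            covered |= ((dense.chromosomes == chrom)
                        & (dense.positions >= spos.min())
                        & (dense.positions <= spos.max()))
        for line in result.genotypes.lines:
            truth = G.row(line)
            imputed = result.genotypes.row(line)
            inside = np.zeros(len(dense), bool)
            for iv in result.intervals[line]:
                inside |= ((dense.chromosomes == iv.chromosome)
                           & (dense.positions > iv.left_pos)
                           & (dense.positions < iv.right_pos))
            errors = imputed != truth
            assert errors[covered & ~inside].sum() == 0
            assert errors[covered].mean() <= inside.mean()

    def test_interval_fraction_reported(self, dh_world):
        _G, ped, _tracks, G_pure, G_adm_shared = dh_world
        result = impute_admixed_panel(G_adm_shared, G_pure, ped)
        for s in result.stats.values():
            assert 0 <= s["interval_marker_fraction"] < 0.5


class TestSelectionBias:
    def test_fixed_families_zero_bias(self):
        mm = _map([10, 20])
        Gp = GenotypeMatrix(["D1", "F1"], mm, np.array([[1, 1], [1, 1]]))
        Ga = GenotypeMatrix(["A1", "A2"], mm, np.array([[1, 1], [1, 1]]))
        from admixgwas.io_core import LineInfo, Pedigree
        ped = Pedigree([LineInfo("D1", "D"), LineInfo("F1", "F"),
                        LineInfo("A1", "A", "D1", "F1"),
                        LineInfo("A2", "A", "D1", "F1")])
        np.testing.assert_allclose(selection_bias_scan(Ga, ped, Gp), [0, 0])

    def test_matches_bruteforce_on_random_pedigree(self):
        rng = np.random.default_rng(7)
        M = 25
        mm = _map(list(range(10, 10 * M + 10, 10)))
        from admixgwas.io_core import LineInfo, Pedigree
        dents = [f"D{i}" for i in range(4)]
        flints = [f"F{i}" for i in range(4)]
        Gp = GenotypeMatrix(dents + flints, mm,
                            rng.integers(0, 2, (8, M)).astype(np.int8))
        entries = [LineInfo(d, "D") for d in dents] + \
                  [LineInfo(f, "F") for f in flints]
        adm, rows = [], []
        for i in range(10):
            d = dents[rng.integers(4)]
            f = flints[rng.integers(4)]
            entries.append(LineInfo(f"A{i}", "A", d, f))
            adm.append((f"A{i}", d, f))
            rows.append(rng.integers(0, 2, M).astype(np.int8))
        Ga = GenotypeMatrix([a[0] for a in adm], mm, np.stack(rows))
        ped = Pedigree(entries)
        got = selection_bias_scan(Ga, ped, Gp)
        # independent brute-force oracle, marker by marker
        for m in range(M):
            fo = np.mean([Ga.row(a)[m] for a, _, _ in adm])
            fe = np.mean([(Gp.row(d)[m] + Gp.row(f)[m]) / 2
                          for _, d, f in adm])
            assert got[m] == pytest.approx(abs(fo - fe), abs=1e-12)
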