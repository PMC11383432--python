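"""Origin loading/filtering and origin-centered aggregation."""

import numpy as np
import pandas as pd
import pytest

from xscar import (
    OriginSet,
    StrandedReadSet,
    density_profile,
    filter_origins,
    heatmap_matrix,
    load_origins,
    metaprofile,
)
from xscar.partition import PartitionTrack


def _origin_set(rows):
    return OriginSet(pd.DataFrame(rows, columns=["contig", "center", "score"]))


class TestLoadAndFilter:
    def test_center_and_score_from_bedgraph_record(self, tmp_path):
        path = tmp_path / "o.bedgraph"
        path.write_text("chrI\t1000\t2000\t35.5\n")
        origins = load_origins(path)
        assert origins.df.iloc[0].tolist() == ["chrI", 1500, 35.5]

    def test_bed_with_score_column(self, tmp_path):
        path = tmp_path / "o.bed"
        path.write_text("chrI\t100\t301\tori1\t88.8\t+\n")
        origins = load_origins(path)
        assert origins.df.iloc[0].tolist() == ["chrI", 200, 88.8]

    def test_empty_file_gives_empty_set(self, tmp_path):
        path = tmp_path / "empty.bedgraph"
        path.write_text("")
        assert len(load_origins(path)) == 0

    def test_duplicate_center_rejected(self, tmp_path):
        path = tmp_path / "dup.bedgraph"
        path.write_text("chrI\t1000\t2000\t30\nchrI\t1200\t1800\t40\n")
        with pytest.raises(ValueError, match="duplicate"):
            load_origins(path)

    def test_malformed_line_reported_with_number(self, tmp_path):
        path = tmp_path / "bad.bedgraph"
        path.write_text("chrI\t0\t100\t5\nchrI\tten\t100\t5\n")
        with pytest.raises(ValueError, match="line 2"):
            load_origins(path)

    def test_strict_score_filter_boundary(self):
        origins = _origin_set(
            [("c", 1000, 10.0), ("c", 2000, 20.0), ("c", 3000, 21.0), ("c", 4000, 88.8)]
        )
        kept = filter_origins(origins, 20.0)
        assert len(kept) == 2
        assert kept.df["score"].tolist() == [21.0, 88.8]  # score == 20 excluded

    def test_filter_matches_brute_force_scan(self, rng):
        scores = np.round(rng.uniform(0, 40, size=100), 3)
        origins = _origin_set([("c", 1000 + 100 * i, s) for i, s in enumerate(scores)])
        for threshold in (-np.inf, 10.0, 20.0, float(scores[7])):
            kept = filter_origins(origins, threshold)
            brute = [s for s in scores if s > threshold]
            assert len(kept) == len(brute)
        assert len(filter_origins(origins, -np.inf)) == 100  # identity
        assert len(filter_origins(origins, 40.0)) == 0


def _partition_track(values, bin_size=500):
    v = np.asarray(values, float)
    return PartitionTrack({"c": v}, bin_size, {"c": len(v) * bin_size})


class TestMetaprofileAndHeatmap:
    def test_constant_window_gives_constant_profile(self):
        p = _partition_track(np.full(40, 0.4))
        prof = metaprofile(p, _origin_set([("c", 10_000, 50.0)]), flank=2500)
        np.testing.assert_allclose(prof.mean, 0.4)
        assert (prof.n == 1).all()
        assert prof.offsets.tolist() == [-2250, -1750, -1250, -750, -250, 250, 750, 1250, 1750, 2250]

    def test_opposite_windows_average_to_zero(self):
        v = np.zeros(80)
        v[10:30] = 0.7   # window of origin at 10_000
        v[50:70] = -0.7  # window of origin at 30_000
        p = _partition_track(v)
        prof = metaprofile(p, _origin_set([("c", 10_000, 50.0), ("c", 30_000, 50.0)]), flank=2500)
        np.testing.assert_allclose(prof.mean, 0.0, atol=1e-15)
        assert (prof.n == 2).all()

    def test_heatmap_shape_and_column_mean_consistency(self, rng):
        v = rng.uniform(-1, 1, size=200)
        v[rng.random(200) < 0.1] = np.nan
        p = _partition_track(v)
        origins = _origin_set([("c", 20_000, 30.0), ("c", 50_000, 60.0), ("c", 80_000, 90.0)])
        m = heatmap_matrix(p, origins, flank=2500)
        assert m.values.shape == (3, 10)
        prof = metaprofile(p, origins, flank=2500)
        col_n = (~np.isnan(m.values)).sum(axis=0)
        col_means = np.nansum(m.values, axis=0) / np.maximum(col_n, 1)
        col_means[col_n == 0] = np.nan
        np.testing.assert_allclose(prof.mean, col_means, atol=1e-12, equal_nan=True)
        np.testing.assert_array_equal(prof.n, col_n)

    def test_origin_near_contig_edge_dropped_and_counted(self):
        p = _partition_track(np.zeros(40))
        origins = _origin_set([("c", 1000, 50.0), ("c", 10_000, 50.0)])
        m = heatmap_matrix(p, origins, flank=2500)
        assert len(m.origin_ids) == 1 and m.n_dropped == 1
        prof = metaprofile(p, origins, flank=2500)
        assert prof.n_origins_used == 1 and prof.n_origins_dropped == 1

    def test_no_usable_origins_errors(self):
        p = _partition_track(np.zeros(10))
        with pytest.raises(ValueError, match="usable"):
            metaprofile(p, _origin_set([("c", 100, 50.0)]), flank=2500)

    def test_flank_must_be_bin_multiple(self):
        p = _partition_track(np.zeros(40))
        with pytest.raises(ValueError, match="multiple"):
            metaprofile(p, _origin_set([("c", 10_000, 50.0)]), flank=2400)

    def test_missing_bins_ignored_per_offset(self):
        v = np.full(40, np.nan)
        v[16:24] = 0.5  # only part of the window carries signal
        p = _partition_track(v)
        prof = metaprofile(p, _origin_set([("c", 10_000, 50.0)]), flank=2500)
        assert np.isnan(prof.mean[0]) and prof.n[0] == 0
        assert prof.mean[5] == 0.5 and prof.n[5] == 1

    def test_leading_orientation_negates_left_flank(self):
        v = np.zeros(40)
        v[15:20] = -0.6  # left flank of origin at 10_000
        v[20:25] = 0.6   # right flank
        p = _partition_track(v)
        prof = metaprofile(p, _origin_set([("c", 10_000, 50.0)]), flank=2500, orient="leading")
        np.testing.assert_allclose(prof.mean, 0.6)


def _uniform_reads(rng, origins_df, flank, n, strand_probs=(0.5, 0.5)):
    pick = rng.integers(0, len(origins_df), size=n)
    off = rng.integers(-flank, flank, size=n)
    mids = origins_df["center"].to_numpy()[pick] + off
    strands = rng.choice(["+", "-"], size=n, p=strand_probs)
    return StrandedReadSet(
        pd.DataFrame(
            {
                "contig": origins_df["contig"].to_numpy()[pick],
                "start": mids - 50,
                "end": mids + 50,
                "strand": strands,
            }
        )
    )


class TestDensityProfile:
    def test_identity_reads_give_ratio_one(self, rng):
        origins = _origin_set([("c", 20_000, 30.0), ("c", 60_000, 80.0)])
        reads = _uniform_reads(rng, origins.df, 2500, 4000)
        prof = density_profile(reads, reads, origins, flank=2500, bin_size=500)
        for stratum in (prof.leading, prof.lagging, prof.unstranded):
            defined = stratum[~np.isnan(stratum)]
            np.testing.assert_allclose(defined, 1.0, atol=1e-12)

    def test_ratio_is_depth_invariant_and_linear_in_concentration(self, rng):
        origins = _origin_set([("c", 20_000, 30.0)])
        base = _uniform_reads(rng, origins.df, 2500, 3000)
        # duplicating the whole ChIP library doubles counts and library size:
        # the CPM/CPM ratio is unchanged
        doubled = StrandedReadSet(pd.concat([base.df, base.df], ignore_index=True))
        prof = density_profile(doubled, base, origins, flank=2500, bin_size=500)
        np.testing.assert_allclose(
            prof.unstranded[~np.isnan(prof.unstranded)], 1.0, atol=1e-12
        )
        # halving the in-window concentration (same window reads, library
        # padded with off-window reads) halves the ratio exactly
        pad = base.df.copy()
        pad["start"] += 30_000
        pad["end"] += 30_000
        diluted = StrandedReadSet(pd.concat([base.df, pad], ignore_index=True))
        ref = density_profile(base, base, origins, flank=2500, bin_size=500)
        half = density_profile(diluted, base, origins, flank=2500, bin_size=500)
        np.testing.assert_allclose(half.unstranded, 0.5 * ref.unstranded, atol=1e-12)

    def test_pure_leading_bias_zeroes_lagging_stratum(self):
        from xscar import SimConfig, build_fork_map, simulate_origins, simulate_scar_experiment

        cfg = SimConfig(seed=31, p_lead=1.0, contig_lengths={"chrA": 200_000},
                        n_origins=3, n_chip_fragments=30_000, n_input_fragments=30_000,
                        flank=2500)
        origins = simulate_origins(cfg)
        forks = build_fork_map(origins, cfg.contig_lengths)
        parental, _, input_reads = simulate_scar_experiment(cfg, forks, origins)
        prof = density_profile(parental, input_reads, origins, flank=2500, bin_size=500)
        lagging = prof.lagging[~np.isnan(prof.lagging)]
        np.testing.assert_allclose(lagging, 0.0, atol=1e-12)
        # leading stratum ~ 2x unstranded when the input is strand-balanced
        ratio = prof.leading / prof.unstranded
        ratio = ratio[np.isfinite(ratio)]
        assert abs(np.mean(ratio) - 2.0) < 0.2

    def test_total_input_stratification_halves_stranded_ratio(self, rng):
        origins = _origin_set([("c", 20_000, 30.0)])
        chip = _uniform_reads(rng, origins.df, 2500, 5000, strand_probs=(1.0, 0.0))
        inp = _uniform_reads(rng, origins.df, 2500, 5000)
        matching = density_profile(chip, inp, origins, input_stratification="matching")
        total = density_profile(chip, inp, origins, input_stratification="total")
        # with a balanced input, matching-strand denominators are ~half of total
        m = np.nanmean(matching.leading) / np.nanmean(total.leading)
        assert 1.6 < m < 2.5

    def test_zero_in_window_input_errors(self, rng):
        origins = _origin_set([("c", 20_000, 30.0)])
        chip = _uniform_reads(rng, origins.df, 2500, 100)
        far = StrandedReadSet(
            pd.DataFrame({"contig": ["c"], "start": [50_000], "end": [50_100], "strand": ["+"]})
        )
        with pytest.raises(ValueError, match="input"):
            density_profile(chip, far, origins, flank=2500)
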