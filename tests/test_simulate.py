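"""Simulator: determinism, fork conventions, strand-draw statistics."""

import numpy as np
import pandas as pd
import pytest

from xscar import (
    OriginSet,
    SimConfig,
    build_fork_map,
    read_alignments,
    simulate_origins,
    simulate_scar_experiment,
    write_reads,
)
from xscar.origins import nearest_center_indices

from conftest import TINY_SIM


def _origin_set(rows):
    return OriginSet(pd.DataFrame(rows, columns=["contig", "center", "score"]))


class TestSimulateOrigins:
    def test_deterministic_given_seed(self):
        cfg = SimConfig(seed=7, **TINY_SIM)
        a, b = simulate_origins(cfg), simulate_origins(cfg)
        pd.testing.assert_frame_equal(a.df, b.df)

    def test_counts_scores_and_spacing(self):
        cfg = SimConfig(seed=3, contig_lengths={"chrA": 120_000}, n_origins=3,
                        origin_score_range=(21.0, 100.0), flank=2500)
        origins = simulate_origins(cfg)
        assert len(origins) == 3
        assert ((origins.df["score"] > 21.0) & (origins.df["score"] < 100.0)).all()
        centers = origins.centers("chrA")
        assert (np.diff(centers) >= 4 * cfg.flank).all()
        # scores forced above threshold: strict filter retains all
        from xscar import filter_origins
        assert len(filter_origins(origins, 20.0)) == 3

    def test_contig_too_short_raises_sizing_error(self):
        cfg = SimConfig(seed=1, contig_lengths={"tiny": 5_000}, n_origins=3, flank=2500)
        with pytest.raises(ValueError, match="tiny"):
            simulate_origins(cfg)

    def test_invalid_p_lead_rejected(self):
        with pytest.raises(ValueError, match="p_lead"):
            SimConfig(seed=1, p_lead=1.5, **TINY_SIM).validate()


class TestForkMap:
    def test_side_and_leading_strand_convention(self):
        forks = build_fork_map(_origin_set([("c", 5000, 50.0)]), {"c": 10_000})
        assert forks.leading_strand("c", np.array([6000]))[0] == "+"
        assert forks.leading_strand("c", np.array([4000]))[0] == "-"
        # a position exactly at the center counts as right of it
        assert forks.leading_strand("c", np.array([5000]))[0] == "+"

    def test_equidistant_tie_goes_to_leftmost_origin(self):
        forks = build_fork_map(
            _origin_set([("c", 1000, 1.0), ("c", 3000, 1.0)]), {"c": 10_000}
        )
        idx, side = forks.assign("c", np.array([2000]))
        assert idx[0] == 0 and side[0] == 1  # origin at 1000, right side

    def test_contig_without_origin_rejected(self):
        with pytest.raises(ValueError, match="chrB"):
            build_fork_map(_origin_set([("chrA", 1000, 1.0)]), {"chrA": 5000, "chrB": 5000})

    def test_nearest_center_brute_force(self, rng):
        centers = np.sort(rng.choice(10_000, size=8, replace=False))
        positions = rng.integers(0, 10_000, size=300)
        got = nearest_center_indices(centers, positions)
        for pos, idx in zip(positions, got):
            dists = np.abs(centers - pos)
            assert dists[idx] == dists.min()
            assert idx == np.flatnonzero(dists == dists.min())[0]  # leftmost tie


def _fractions(config, reads, origins):
    """Empirical fraction of leading-strand fragments, by direct counting."""
    forks = build_fork_map(origins, config.contig_lengths)
    mids = reads.midpoints()
    lead_total = 0
    for contig, sub in reads.df.groupby("contig"):
        m = ((sub["start"] + sub["end"]) // 2).to_numpy()
        lead = forks.leading_strand(contig, m)
        lead_total += (sub["strand"].to_numpy() == lead).sum()
    return lead_total / len(mids)


class TestScarExperiment:
    def test_limit_case_all_parental_on_leading_strand(self):
        cfg = SimConfig(seed=5, p_lead=1.0, **TINY_SIM)
        origins = simulate_origins(cfg)
        forks = build_fork_map(origins, cfg.contig_lengths)
        parental, new, _ = simulate_scar_experiment(cfg, forks, origins)
        assert _fractions(cfg, parental, origins) == 1.0
        assert _fractions(cfg, new, origins) == 0.0

    @pytest.mark.parametrize("p_lead", [0.5, 0.8])
    def test_leading_fraction_matches_binomial_oracle(self, p_lead):
        cfg = SimConfig(seed=9, p_lead=p_lead, n_chip_fragments=200_000)
        origins = simulate_origins(cfg)
        forks = build_fork_map(origins, cfg.contig_lengths)
        parental, new, _ = simulate_scar_experiment(cfg, forks, origins)
        n = cfg.n_chip_fragments
        sigma = np.sqrt(p_lead * (1 - p_lead) / n)
        assert abs(_fractions(cfg, parental, origins) - p_lead) < 3 * sigma
        # mirror construction: leading fractions of parental and new sum to 1
        assert abs(
            _fractions(cfg, parental, origins) + _fractions(cfg, new, origins) - 1.0
        ) < 3 * np.sqrt(2) * sigma

    def test_requested_counts_and_determinism(self, tiny_sim_config):
        cfg = tiny_sim_config
        origins = simulate_origins(cfg)
        forks = build_fork_map(origins, cfg.contig_lengths)
        a = simulate_scar_experiment(cfg, forks, origins)
        b = simulate_scar_experiment(cfg, forks, origins)
        assert [len(x) for x in a] == [
            cfg.n_chip_fragments, cfg.n_chip_fragments, cfg.n_input_fragments
        ]
        for x, y in zip(a, b):
            pd.testing.assert_frame_equal(x.df, y.df)

    def test_input_is_strand_balanced(self):
        cfg = SimConfig(seed=2, n_input_fragments=50_000, **{
            k: v for k, v in TINY_SIM.items() if k != "n_input_fragments"
        })
        origins = simulate_origins(cfg)
        forks = build_fork_map(origins, cfg.contig_lengths)
        _, _, input_reads = simulate_scar_experiment(cfg, forks, origins)
        n_fwd = (input_reads.df["strand"] == "+").sum()
        n = cfg.n_input_fragments
        assert abs(n_fwd - n / 2) < 4 * np.sqrt(n * 0.25)

    def test_fragments_stay_within_contigs(self, tiny_sim_config):
        cfg = tiny_sim_config
        origins = simulate_origins(cfg)
        forks = build_fork_map(origins, cfg.contig_lengths)
        for reads in simulate_scar_experiment(cfg, forks, origins):
            for contig, sub in reads.df.groupby("contig"):
                assert (sub["start"] >= 0).all()
                assert (sub["end"] <= cfg.contig_lengths[contig]).all()


class TestWriteReads:
    def test_round_trip_bed(self, tiny_sim_config, tmp_path):
        cfg = tiny_sim_config
        origins = simulate_origins(cfg)
        forks = build_fork_map(origins, cfg.contig_lengths)
        parental, _, _ = simulate_scar_experiment(cfg, forks, origins)
        path = tmp_path / "p.bed"
        write_reads(parental, path, "bed")
        back = read_alignments(str(path), contig_lengths=cfg.contig_lengths)
        pd.testing.assert_frame_equal(back.sorted().df, parental.sorted().df)

    def test_empty_set_round_trips(self, tmp_path):
        from xscar import StrandedReadSet

        path = tmp_path / "empty.bed"
        write_reads(StrandedReadSet(), path, "bed")
        assert read_alignments(str(path), format="bed").library_size == 0

    def test_record_count(self, tmp_path):
        from xscar.readio import AlignedFragment, StrandedReadSet

        reads = StrandedReadSet.from_fragments(
            [AlignedFragment("c", i, i + 10, "+") for i in range(10)]
        )
        path = tmp_path / "r.bed"
        write_reads(reads, path, "bed")
        assert len(path.read_text().splitlines()) == 10
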