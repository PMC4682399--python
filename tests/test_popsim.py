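import numpy as np
import pytest

from argwalker import (
    Scenario,
    classify_nodes,
    make_scenario_grid,
    read_sample,
    simulate_sample,
    write_sample,
)
from argwalker.popsim import read_hapmap_phased


class TestScenario:
    def test_defaults_validate(self):
        Scenario().validate()

    @pytest.mark.parametrize(
        "kw",
        [
            {"mode": "lukewarm"},
            {"bgc_rate": 0.7},
            {"hot_cold_ratio": 0.5},
            {"causal_maf": 0.0},
            {"base_crossover": 0.2, "hot_cold_ratio": 10.0},
            {"n_individuals": 600},
        ],
    )
    def test_invalid_scenarios_rejected(self, kw):
        with pytest.raises(ValueError):
            Scenario(**kw).validate()


class TestSimulateSample:
    def test_all_cold_mode_labels(self):
        s = simulate_sample(Scenario(seed=3, mode="all-cold", pop_size=60,
                                     n_individuals=20, generations=40))
        assert set(s.truth.values()) == {"cold"}

    def test_determinism_same_seed(self):
        kw = dict(seed=9, pop_size=80, n_individuals=25, generations=50)
        a = simulate_sample(Scenario(**kw))
        b = simulate_sample(Scenario(**kw))
        assert np.array_equal(a.matrix, b.matrix)
        assert np.array_equal(a.positions, b.positions)
        assert a.truth == b.truth
        assert a.true_arg.edges == b.true_arg.edges
        assert a.true_arg.leaf_labels == b.true_arg.leaf_labels

    def test_sample_shape_and_positions(self, default_sample):
        s = default_sample
        assert s.n_hap == 180
        assert s.matrix.shape[0] == 180
        assert set(np.unique(s.matrix)) <= {0, 1}
        assert np.all(np.diff(s.positions) > 0)
        assert s.positions[0] >= 1 and s.positions[-1] <= s.scenario.span_bp
        # matrix holds segregating sites only
        assert np.all(s.matrix.min(axis=0) != s.matrix.max(axis=0))

    def test_true_arg_validates_with_sample_leaves(self, default_sample):
        g = default_sample.true_arg
        cls = classify_nodes(g)
        assert set(g.leaf_labels.values()) == set(default_sample.hap_ids)
        assert cls.leaves == set(g.leaf_labels)
        assert len(cls.roots) >= 1

    def test_causal_maf_is_conditioned_near_target(self):
        for seed in range(5):
            s = simulate_sample(Scenario(seed=100 + seed))
            hot = np.mean([v == "hot" for v in s.truth.values()])
            assert abs(min(hot, 1 - hot) - 0.5) <= 0.1 + 1e-12

    def test_realized_crossover_ratio_tracks_scenario(self):
        """Generative law check: hot meioses cross over ~ratio times more."""
        hot_x = cold_x = hot_m = cold_m = 0
        for seed in range(25):
            s = simulate_sample(Scenario(seed=3000 + seed))
            st = s.stats
            hot_x += st["hot_crossovers"]
            cold_x += st["cold_crossovers"]
            hot_m += st["hot_meioses"]
            cold_m += st["cold_meioses"]
        realized = (hot_x / hot_m) / (cold_x / cold_m)
        assert realized == pytest.approx(10.0, rel=0.3)

    def test_retry_cap_reported(self):
        sc = Scenario(seed=0, causal_maf=0.5, pop_size=30, n_individuals=10,
                      generations=400, n_founders=4)
        with pytest.raises(RuntimeError, match="drift"):
            simulate_sample(sc, max_retries=2)


class TestSampleIO:
    def test_round_trip(self, tmp_path, default_sample):
        write_sample(default_sample, tmp_path)
        back = read_sample(tmp_path)
        assert np.array_equal(back.matrix, default_sample.matrix)
        assert np.array_equal(back.positions, default_sample.positions)
        assert back.truth == default_sample.truth
        assert back.true_arg.edges == default_sample.true_arg.edges
        assert back.scenario == default_sample.scenario
        assert back.causal_snp_index == default_sample.causal_snp_index

    def test_writes_180_haplotype_rows(self, tmp_path, default_sample):
        write_sample(default_sample, tmp_path)
        lines = (tmp_path / "haplotypes.tsv").read_text().splitlines()
        assert len(lines) == 1 + 2 * 90

    def test_truncated_matrix_errors_with_line(self, tmp_path, default_sample):
        write_sample(default_sample, tmp_path)
        p = tmp_path / "haplotypes.tsv"
        lines = p.read_text().splitlines()
        lines[3] = "\t".join(lines[3].split("\t")[:5])
        p.write_text("\n".join(lines) + "\n")
        with pytest.raises(Exception, match="haplotypes.tsv:4"):
            read_sample(tmp_path)


class TestScenarioGrid:
    def test_ratio_sweep_has_5x50_scenarios(self):
        grid = make_scenario_grid(reps=50)
        ratio = [s for s in grid if s.tag.startswith("ratio=")]
        assert len(ratio) == 5 * 50
        assert sorted({s.hot_cold_ratio for s in ratio}) == [1, 5, 10, 15, 20]

    def test_every_scenario_validates_and_grid_is_deterministic(self):
        g1 = make_scenario_grid(reps=3)
        g2 = make_scenario_grid(reps=3)
        assert g1 == g2
        for s in g1:
            s.validate()

    def test_sweeps_cover_position_maf_bgc_and_controls(self):
        tags = {s.tag.split("=")[0] for s in make_scenario_grid(reps=1)}
        assert {"ratio", "position", "maf", "bgc", "all-hot", "all-cold"} <= tags


def test_hapmap_phased_reader(tmp_path):
    p = tmp_path / "phased.txt"
    p.write_text(
        "rsID position NA1_A NA1_B NA2_A NA2_B\n"
        "rs1 101 A A G G\n"
        "rs2 205 C T C C\n"
    )
    matrix, positions, hap_ids, snp_ids = read_hapmap_phased(p)
    assert matrix.shape == (4, 2)
    assert list(positions) == [101, 205]
    assert hap_ids == ("NA1_A", "NA1_B", "NA2_A", "NA2_B")
    # alphabetically smaller base is 0: rs1 A<G, rs2 C<T
    assert list(matrix[:, 0]) == [0, 0, 1, 1]
    assert list(matrix[:, 1]) == [0, 1, 0, 0]
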