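import math
from dataclasses import replace

import numpy as np
import pytest

from tagport.panel_io import population_panel
from tagport.synthetic_data import generate_panel
from tagport.tagging_sim import (
    StudyConfig,
    derive_seed,
    enumerate_candidates,
    evaluate_exact,
    evaluate_monte_carlo,
    read_results,
    run_study,
    write_results,
)

from conftest import two_pop_scenario


def study_cfg(panel, sc, **kw):
    tag = panel.variants[sc.tag_index]
    defaults = dict(
        tag_vid=tag.vid,
        tag_pos=tag.pos,
        ref_pop=sc.reference_pop(),
        windows_kb=sc.windows_kb,
        r2_threshold=sc.r2_threshold,
        seed=123,
    )
    defaults.update(kw)
    return StudyConfig(**defaults)


@pytest.fixture(scope="module")
def planted_study():
    """Two populations; 3 of 4 planted proxies keep LD in population B."""
    sc = two_pop_scenario(seed=11, preserved_in_b=(0, 1, 2), n_proxies=4)
    panel, pmap, truth = generate_panel(sc)
    return sc, panel, pmap, truth


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            {"windows_kb": (10, 5)},
            {"windows_kb": ()},
            {"windows_kb": (5, 5)},
            {"r2_threshold": 0.0},
            {"r2_threshold": 1.2},
            {"n_sims": 0},
            {"ld_mode": "mystery"},
            {"eval_mode": "sometimes"},
        ],
    )
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            StudyConfig(tag_vid="rsX", tag_pos=100, **kw)


class TestEnumerateCandidates:
    def test_planted_proxies_recovered(self, planted_study):
        sc, panel, pmap, truth = planted_study
        ref = population_panel(panel, pmap, "A")
        cfg = study_cfg(panel, sc)
        cands = enumerate_candidates(ref, cfg, 5)
        assert set(cands.candidates) == set(truth.candidates[5])
        planted_5kb = {idx for idx, _ in sc.planted_proxies if abs(idx - sc.tag_index) * 1000 <= 5000}
        assert planted_5kb <= set(cands.candidates)
        # ordered by position, tag excluded
        assert list(cands.candidates) == sorted(cands.candidates)
        assert sc.tag_index not in cands.candidates

    def test_threshold_one_with_no_perfect_neighbor_is_empty(self):
        sc = two_pop_scenario(seed=13, n_proxies=0)
        panel, pmap, _ = generate_panel(sc)
        ref = population_panel(panel, pmap, "A")
        cfg = study_cfg(panel, sc, r2_threshold=1.0)
        assert enumerate_candidates(ref, cfg, 5).n_candidates == 0

    def test_threshold_monotonicity(self, planted_study):
        sc, panel, pmap, _ = planted_study
        ref = population_panel(panel, pmap, "A")
        counts = [
            enumerate_candidates(ref, study_cfg(panel, sc, r2_threshold=t), 10).n_candidates
            for t in (0.2, 0.5, 0.8, 0.95)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_window_containment(self, planted_study):
        sc, panel, pmap, _ = planted_study
        ref = population_panel(panel, pmap, "A")
        cfg = study_cfg(panel, sc)
        c5 = enumerate_candidates(ref, cfg, 5)
        c10 = enumerate_candidates(ref, cfg, 10)
        assert set(c5.candidates) <= set(c10.candidates)

    def test_tag_absent_raises_naming_id(self, planted_study):
        sc, panel, pmap, _ = planted_study
        ref = population_panel(panel, pmap, "A")
        cfg = study_cfg(panel, sc, tag_vid="rsMISSING")
        with pytest.raises(KeyError, match="rsMISSING"):
            enumerate_candidates(ref, cfg, 5)

    def test_monomorphic_tag_in_reference_raises(self):
        sc = two_pop_scenario(seed=11, monomorphic_b=True)
        panel, pmap, _ = generate_panel(sc)
        sub = population_panel(panel, pmap, "B")
        cfg = study_cfg(panel, sc, ref_pop="B")
        with pytest.raises(ValueError, match="monomorphic"):
            enumerate_candidates(sub, cfg, 5)


class TestEvaluateExact:
    def test_reference_population_tags_itself(self, planted_study):
        sc, panel, pmap, _ = planted_study
        ref = population_panel(panel, pmap, "A")
        cfg = study_cfg(panel, sc)
        cands = enumerate_candidates(ref, cfg, 5)
        res = evaluate_exact(cands, ref, cfg, target_pop="A")
        assert res.proportion == 1.0 and res.n_tagged == res.n_candidates

    def test_three_of_four_planted_proxies_give_075(self, planted_study):
        sc, panel, pmap, truth = planted_study
        ref = population_panel(panel, pmap, "A")
        tgt = population_panel(panel, pmap, "B")
        cfg = study_cfg(panel, sc)
        cands = enumerate_candidates(ref, cfg, 5)
        res = evaluate_exact(cands, tgt, cfg, target_pop="B")
        assert res.proportion == truth.proportion("B", 5) == 0.75
        assert res.mode == "exact" and not res.tag_monomorphic

    def test_monomorphic_tag_population_reports_zero_with_flag(self):
        sc = two_pop_scenario(seed=17, monomorphic_b=True)
        panel, pmap, truth = generate_panel(sc)
        ref = population_panel(panel, pmap, "A")
        tgt = population_panel(panel, pmap, "B")
        cfg = study_cfg(panel, sc)
        cands = enumerate_candidates(ref, cfg, 5)
        res = evaluate_exact(cands, tgt, cfg, target_pop="B")
        assert res.tag_monomorphic and res.n_tagged == 0 and res.proportion == 0.0
        assert truth.tag_monomorphic["B"]

    def test_empty_candidate_set_rejected(self):
        sc = two_pop_scenario(seed=13, n_proxies=0)
        panel, pmap, _ = generate_panel(sc)
        ref = population_panel(panel, pmap, "A")
        cfg = study_cfg(panel, sc, r2_threshold=1.0)
        cands = enumerate_candidates(ref, cfg, 5)
        with pytest.raises(ValueError, match="empty"):
            evaluate_exact(cands, ref, cfg)

    def test_column_misalignment_detected(self, planted_study):
        sc, panel, pmap, _ = planted_study
        ref = population_panel(panel, pmap, "A")
        cfg = study_cfg(panel, sc)
        cands = enumerate_candidates(ref, cfg, 5)
        shifted = replace(cands, tag_index=cands.tag_index + 1)
        with pytest.raises(ValueError, match="aligned"):
            evaluate_exact(shifted, ref, cfg)


class TestEvaluateMonteCarlo:
    def test_all_tagged_gives_one_for_any_seed(self, planted_study):
        sc, panel, pmap, _ = planted_study
        ref = population_panel(panel, pmap, "A")
        cfg = study_cfg(panel, sc, n_sims=2000)
        cands = enumerate_candidates(ref, cfg, 5)
        for seed in (0, 1, 999):
            res = evaluate_monte_carlo(cands, ref, cfg, target_pop="A", seed=seed)
            assert res.proportion == 1.0

    def test_same_seed_reproduces_exactly(self, planted_study):
        sc, panel, pmap, _ = planted_study
        ref = population_panel(panel, pmap, "A")
        tgt = population_panel(panel, pmap, "B")
        cfg = study_cfg(panel, sc, n_sims=5000)
        cands = enumerate_candidates(ref, cfg, 5)
        r1 = evaluate_monte_carlo(cands, tgt, cfg, seed=42)
        r2 = evaluate_monte_carlo(cands, tgt, cfg, seed=42)
        assert r1.proportion == r2.proportion

    def test_binomial_sampling_bound(self, planted_study):
        """2 tagged of 4 candidates at n_sims=1e5: MC proportion within
        5*sqrt(0.25/1e5) of the exact 0.5 across seeds."""
        sc = two_pop_scenario(seed=11, preserved_in_b=(0, 1), n_proxies=4)
        panel, pmap, truth = generate_panel(sc)
        assert truth.proportion("B", 5) == 0.5
        ref = population_panel(panel, pmap, "A")
        tgt = population_panel(panel, pmap, "B")
        cfg = study_cfg(panel, sc, n_sims=10**5)
        cands = enumerate_candidates(ref, cfg, 5)
        bound = 5 * math.sqrt(0.25 / cfg.n_sims)
        for seed in range(10):
            res = evaluate_monte_carlo(cands, tgt, cfg, seed=seed)
            assert abs(res.proportion - 0.5) <= bound


class TestRunStudy:
    def test_cardinality_ordering_and_reference_control(self, paperlike_study):
        sc, panel, pmap, truth = paperlike_study
        cfg = study_cfg(panel, sc)
        results = run_study(panel, pmap, cfg)
        assert len(results) == 26 * 4  # populations x windows
        keys = [(r.window_kb, r.region, r.target_pop) for r in results]
        assert keys == sorted(keys, key=lambda k: (sc.windows_kb.index(k[0]), k[1], k[2]))
        for r in results:
            if r.target_pop == sc.reference_pop():
                assert r.proportion == 1.0

    def test_both_mode_doubles_rows(self, planted_study):
        sc, panel, pmap, _ = planted_study
        cfg = study_cfg(panel, sc, eval_mode="both", n_sims=1000)
        results = run_study(panel, pmap, cfg)
        assert len(results) == 2 * 2 * len(sc.windows_kb)
        modes = {r.mode for r in results}
        assert modes == {"exact", "monte_carlo"}

    def test_per_population_seeds_are_stable(self):
        s1 = derive_seed(7, "rsX", 5, "CEU")
        assert s1 == derive_seed(7, "rsX", 5, "CEU")
        assert s1 != derive_seed(7, "rsX", 5, "TSI")
        assert s1 != derive_seed(7, "rsX", 10, "CEU")
        assert 0 <= s1 < 2**31


class TestWriteResults:
    def test_round_trip_preserves_fields(self, planted_study, tmp_path):
        sc, panel, pmap, _ = planted_study
        cfg = study_cfg(panel, sc, eval_mode="both", n_sims=1000)
        results = run_study(panel, pmap, cfg)
        path = tmp_path / "results.tsv"
        write_results(results, str(path))
        df = read_results(str(path))
        assert len(df) == len(results)
        for r, row in zip(results, df.itertuples(index=False)):
            assert row.population == r.target_pop
            assert row.window_kb == r.window_kb
            assert row.n_candidates == r.n_candidates
            assert row.n_tagged == r.n_tagged
            assert row.proportion == pytest.approx(r.proportion, abs=5e-5)
            assert bool(row.tag_monomorphic) == r.tag_monomorphic
            assert row.mode == r.mode

    def test_empty_candidates_written_as_na(self, tmp_path):
        sc = two_pop_scenario(seed=13, n_proxies=0)
        panel, pmap, _ = generate_panel(sc)
        cfg = study_cfg(panel, sc, r2_threshold=1.0)
        results = run_study(panel, pmap, cfg)
        assert all(r.n_candidates == 0 for r in results)
        path = tmp_path / "results.tsv"
        write_results(results, str(path))
        df = read_results(str(path))
        assert df["proportion"].isna().all()
        assert (df["n_candidates"] == 0).all()

    def test_header_plus_one_row_per_result(self, paperlike_study, tmp_path):
        sc, panel, pmap, _ = paperlike_study
        results = run_study(panel, pmap, study_cfg(panel, sc))
        path = tmp_path / "results.tsv"
        write_results(results, str(path))
        lines = path.read_text().splitlines()
        assert len(lines) == 104 + 1
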