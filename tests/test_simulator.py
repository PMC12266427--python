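"""Birth-death process mechanics: step semantics, stopping, conditioning."""

import numpy as np
import pytest

from mutburden import (
    PopulationState,
    SimulationConfig,
    dd_from_state,
    mbd_from_state,
    run,
    run_trajectory_sizes,
    step,
)


def _cfg(**kw):
    defaults = dict(beta=1.0, mu=0.0, stop=("size", 10), track_matrix=True)
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestConfig:
    def test_delta_is_derived(self):
        assert _cfg(beta=0.75).delta == 0.25

    @pytest.mark.parametrize("kw", [
        dict(beta=0.5),            # beta must exceed delta
        dict(beta=0.0),
        dict(beta=1.2),
        dict(mu=-1.0),
        dict(n0=0),
        dict(n0=5, stop=("size", 3)),  # target below n0
        dict(stop=("whenever", 5)),
    ])
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            _cfg(**kw)


class TestStep:
    def test_birth_without_mutations_duplicates_cell(self):
        state = PopulationState(1)
        state.apply_birth(0, 0, 0)
        assert state.size == 2
        assert [c.divisions for c in state.cells] == [1, 1]
        assert [c.burden for c in state.cells] == [0, 0]
        assert state.unique_mutation_count == 0
        # placeholder blocks exist even with zero mutations
        assert len(state.block_registry) == 2
        assert all(v == () for v in state.block_registry.values())

    def test_birth_inherits_and_adds_disjoint_mutations(self):
        state = PopulationState(1)
        state.cells[0].mutations = {100, 101, 102}
        state.abundance = {100: 1, 101: 1, 102: 1}
        state.next_mutation_id = 103
        state.apply_birth(0, 2, 1)
        burdens = sorted(c.burden for c in state.cells)
        assert burdens == [4, 5]
        assert state.unique_mutation_count == 6  # 3 inherited + 3 new
        d1, d2 = state.cells
        assert d1.mutations & d2.mutations == {100, 101, 102}
        new1 = d1.mutations - {100, 101, 102}
        new2 = d2.mutations - {100, 101, 102}
        assert new1.isdisjoint(new2)

    def test_death_removes_cell_and_lost_mutations(self):
        state = PopulationState(1)
        state.apply_birth(0, 3, 0)
        assert state.unique_mutation_count == 3
        # kill the daughter carrying the 3 mutations
        idx = 0 if state.cells[0].burden == 3 else 1
        state.apply_death(idx)
        assert state.size == 1
        assert state.unique_mutation_count == 0
        assert state.step_count == 2

    def test_step_counter_increments_by_one_either_way(self):
        cfg = _cfg(beta=0.6, stop=("steps", 5))
        state = PopulationState(3)
        rng = np.random.default_rng(0)
        for expect in range(1, 6):
            if state.size == 0:
                break
            step(state, cfg, rng)
            assert state.step_count == expect

    def test_empty_population_cannot_step(self):
        state = PopulationState(1)
        state.apply_death(0)
        with pytest.raises(RuntimeError):
            step(state, _cfg(), np.random.default_rng(0))


class TestRun:
    def test_pure_birth_is_deterministic_in_size(self):
        res = run(_cfg(stop=("size", 5)), rng=np.random.default_rng(0))
        assert res.state.step_count == 4
        assert res.state.size == 5
        assert res.discarded == 0

    def test_pure_birth_no_mutations(self):
        res = run(_cfg(stop=("size", 100), mu=0.0), np.random.default_rng(1))
        st = res.state
        assert st.unique_mutation_count == 0
        assert all(c.burden == 0 for c in st.cells)
        # every division produced two block records
        assert sum(c.divisions for c in st.cells) == sum(
            len(rows) for rows in _members(st).values()
        )

    def test_size_stop_fires_on_first_hit(self):
        cfg = _cfg(beta=0.7, stop=("size", 30))
        res = run(cfg, np.random.default_rng(3))
        assert res.state.size == 30

    def test_step_stop_runs_exact_step_count(self):
        cfg = _cfg(beta=0.7, stop=("steps", 40))
        res = run(cfg, np.random.default_rng(4))
        assert res.state.step_count == 40
        assert res.state.size > 0

    def test_n0_greater_than_one_starts_mutation_free(self):
        cfg = _cfg(n0=4, stop=("size", 12))
        res = run(cfg, np.random.default_rng(5))
        assert res.state.step_count == 8  # pure birth: N - N0 steps
        assert res.state.unique_mutation_count == 0

    def test_mutation_ids_never_reused(self):
        cfg = _cfg(beta=2 / 3, mu=2.0, stop=("size", 40))
        res = run(cfg, np.random.default_rng(6))
        st = res.state
        seen = {}
        for c in st.cells:
            for b in c.blocks:
                for m in st.block_registry[b]:
                    seen.setdefault(m, b)
                    assert seen[m] == b  # each id assigned exactly once
        assert all(m < st.next_mutation_id for m in seen)
        assert st.unique_mutation_count == len(
            set().union(*(c.mutations for c in st.cells))
        )

    def test_compact_and_full_modes_agree_on_same_seed(self):
        for beta in (1.0, 2 / 3):
            cfg = _cfg(beta=beta, mu=1.5, stop=("size", 60))
            full = run(cfg, np.random.default_rng(11)).state
            compact = run(
                cfg.with_(track_matrix=False), np.random.default_rng(11)
            ).state
            assert dd_from_state(full) == dd_from_state(compact)
            assert mbd_from_state(full) == mbd_from_state(compact)

    def test_restart_fraction_matches_extinction_probability(self):
        """Rejection conditioning: discarded fraction ~ delta/beta."""
        cfg = SimulationConfig(beta=2 / 3, mu=0.0, stop=("size", 60),
                               track_matrix=False)
        rng = np.random.default_rng(42)
        survivors = 400
        discarded = sum(run(cfg, rng).discarded for _ in range(survivors))
        attempts = survivors + discarded
        p_hat = discarded / attempts
        se = np.sqrt(0.5 * 0.5 / attempts)
        assert abs(p_hat - 0.5) < 3 * se


class TestTrajectory:
    def test_pure_birth_sizes_and_monotone_tmb(self):
        cfg = _cfg(mu=2.0, stop=("size", 50))
        res = run_trajectory_sizes(cfg, np.random.default_rng(8))
        steps, sizes, tmb = zip(*res.trajectory)
        assert list(steps) == list(range(50))
        assert all(n == i + 1 for i, n in zip(steps, sizes))
        assert all(b >= a for a, b in zip(tmb, tmb[1:]))

    def test_sizes_change_by_one_per_step(self):
        cfg = _cfg(beta=0.7, mu=0.5, stop=("steps", 60))
        res = run_trajectory_sizes(cfg, np.random.default_rng(9))
        sizes = [n for _, n, _ in res.trajectory]
        assert all(abs(b - a) == 1 for a, b in zip(sizes, sizes[1:]))

    def test_mu_zero_keeps_tmb_zero(self):
        res = run_trajectory_sizes(_cfg(stop=("size", 30)),
                                   np.random.default_rng(10))
        assert all(m == 0 for _, _, m in res.trajectory)


def _members(state):
    members = {b: [] for b in state.block_registry}
    for r, c in enumerate(state.cells):
        for b in c.blocks:
            members[b].append(r)
    return members
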