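"""Sessions: parallel loading, snapshots, pickling, direct-API regeneration."""

import pickle

import numpy as np
import pytest

from kinsim import (Session, StateSnapshot, compile_model, fixtures,
                    load_many, write_sbml)
from kinsim.engine import artifact_cache_info
from kinsim.errors import SnapshotError, StaleModelError
from kinsim.session import _FORMAT_VERSION, _MAGIC


def corpus_sources(n=20):
    return [write_sbml(m).xml_text for m in fixtures.corpus(n, seed=4)]


class TestModelMap:
    def test_loads_all_entries(self):
        mm = load_many(corpus_sources(20), workers=3)
        assert len(mm) == 20
        assert not mm.diagnostics

    def test_results_independent_of_worker_count(self):
        sources = corpus_sources(12)
        maps = {w: load_many(sources, workers=w) for w in (1, 2, 4)}
        keys = {w: maps[w].keys() for w in maps}
        assert keys[1] == keys[2] == keys[4]
        for key in keys[1]:
            ref = maps[1][key].simulate(0, 1, 11).values
            for w in (2, 4):
                maps[w][key].reset()
                assert np.array_equal(maps[w][key].simulate(0, 1, 11).values, ref)

    def test_malformed_document_recorded_not_fatal(self):
        sources = corpus_sources(5) + ["<sbml><broken"]
        mm = load_many(sources, workers=2)
        assert len(mm) == 5
        assert len(mm.diagnostics) == 1

    def test_iteration_order_is_sorted(self):
        mm = load_many(corpus_sources(8), workers=2)
        assert list(mm) == sorted(mm.keys())

    def test_invalid_worker_count(self):
        with pytest.raises(ValueError):
            load_many([], workers=0)


class TestSnapshots:
    def test_mid_simulation_round_trip_is_bit_identical(self):
        sess = Session(fixtures.two_step_chain(), seed=5)
        sess.simulate(0, 5, 11)
        snap = sess.save_state()
        restored = Session.load_state(snap)
        a = sess.simulate(5, 10, 11).values
        b = restored.simulate(5, 10, 11).values
        assert np.array_equal(a, b)

    def test_snapshot_after_load_equals_fresh_compile(self):
        sess = Session(fixtures.michaelis_menten(), seed=1)
        restored = Session.load_state(sess.save_state())
        fresh = Session(fixtures.michaelis_menten(), seed=1)
        assert np.array_equal(restored.simulate(0, 10, 11).values,
                              fresh.simulate(0, 10, 11).values)

    def test_corrupted_checksum_rejected(self):
        data = bytearray(Session(fixtures.two_step_chain()).save_state().data)
        data[-1] ^= 0xFF
        with pytest.raises(SnapshotError, match="checksum"):
            Session.load_state(bytes(data))

    def test_unsupported_version_rejected(self):
        snap = Session(fixtures.two_step_chain()).save_state()
        data = bytearray(snap.data)
        data[len(_MAGIC)] = 0
        with pytest.raises(SnapshotError, match="version"):
            Session.load_state(bytes(data))

    def test_save_load_save_is_byte_stable(self):
        sess = Session(fixtures.two_step_chain(), seed=2)
        first = sess.save_state()
        second = Session.load_state(first).save_state()
        assert first.data == second.data

    def test_two_restored_sessions_are_isolated(self):
        snap = Session(fixtures.two_step_chain()).save_state()
        a = Session.load_state(snap)
        b = Session.load_state(snap)
        a.exec.set_value("k1", 99.0)
        assert b.exec.get_value("k1") == 0.1

    def test_file_round_trip(self, tmp_path):
        path = tmp_path / "model.rrstate"
        sess = Session(fixtures.two_step_chain())
        sess.save_state(path)
        snap = StateSnapshot.from_file(path)
        assert snap.format_version == _FORMAT_VERSION
        restored = Session.load_state(snap)
        assert np.array_equal(restored.exec.state, sess.exec.state)

    def test_loading_reuses_cached_artifacts(self):
        sess = Session(fixtures.linear_chain(5, seed=77))
        snap = sess.save_state()
        before = artifact_cache_info()["compiles"]
        Session.load_state(snap)
        assert artifact_cache_info()["compiles"] == before  # cache hit, no compile

    def test_stale_session_refuses_snapshot(self):
        sess = Session(fixtures.two_step_chain())
        sess.ir.add_parameter("extra", 1.0)
        with pytest.raises(StaleModelError):
            sess.save_state()


class TestPickle:
    def test_pickled_session_passes_round_trip(self):
        sess = Session(fixtures.two_step_chain(), seed=8)
        sess.simulate(0, 3, 7)
        clone = pickle.loads(pickle.dumps(sess))
        assert np.array_equal(clone.simulate(3, 10, 8).values,
                              sess.simulate(3, 10, 8).values)

    def test_stochastic_replicas_are_seedable(self):
        """Pickled replicas reproduce an ensemble member exactly."""
        from kinsim import IntegratorOptions, gillespie
        sess = Session(fixtures.immigration_death(), seed=0)
        clone = pickle.loads(pickle.dumps(sess))
        opts = IntegratorOptions(name="gillespie", seed=123)
        a = gillespie(sess.exec, 0, 10, 11, opts)
        b = gillespie(clone.exec, 0, 10, 11, opts)
        assert np.array_equal(a.values, b.values)


class TestDirectApiRegeneration:
    def test_deferred_regeneration_marks_stale(self):
        sess = Session(fixtures.two_step_chain())
        sess.add_parameter("knew", 2.0, force_regenerate=False)
        assert sess.stale
        with pytest.raises(StaleModelError):
            sess.exec.rhs(0.0, np.zeros(2))
        sess.regenerate()
        assert not sess.stale

    def test_add_species_and_degradation_reaction(self):
        sess = Session(fixtures.two_step_chain())
        sess.add_species("A", "default_compartment", 5.0,
                         force_regenerate=False)
        sess.add_reaction("ADeg", ["A"], [], "0.5*A")
        assert "A" in sess.exec.floating_species_ids
        i = sess.exec.state_ids.index("A")
        assert sess.exec.rhs(0.0, sess.exec.state)[i] == pytest.approx(-2.5)
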