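import filecmp
import json
from pathlib import Path

import numpy as np
import pytest

import cablenet as cn
from cablenet.errors import ArchiveError, IntegrityError
from cablenet.serialization import collapse_pending_events
from conftest import make_ring


def archive_files(path):
    return sorted(p.name for p in Path(path).iterdir())


def same_bytes(a, b):
    names = archive_files(a)
    if names != archive_files(b):
        return False
    match, mismatch, errors = filecmp.cmpfiles(a, b, names, shallow=False)
    return not mismatch and not errors


def fresh_ring_state(seed=1, n_groups=1, **kw):
    return cn.SimState(make_ring(seed=seed, **kw), seed=seed,
                       n_groups=n_groups)


class TestModelArchive:
    def test_roundtrip_structural_equality(self, tmp_path):
        st = fresh_ring_state(n_groups=2)
        cn.write_model(st, tmp_path / "arch")
        model, manifest = cn.read_model(tmp_path / "arch")
        ref = st.model
        assert model.net.n_cells == ref.net.n_cells
        for a, b in zip(model.net.cells, ref.net.cells):
            assert a.identical_to(b)
        assert model.net.gids == ref.net.gids
        assert model.net.group_of_cell == ref.net.group_of_cell
        assert len(model.netcons) == len(ref.netcons)
        assert manifest["seed"] == 1

    def test_roundtrip_simulates_identically(self, tmp_path):
        st = fresh_ring_state(n_types=2, cells_per_type=8, ring_size=16)
        cn.write_model(st, tmp_path / "arch")
        model, manifest = cn.read_model(tmp_path / "arch")
        st2 = cn.SimState(model, seed=manifest["seed"])
        r_mem = cn.run(
            fresh_ring_state(n_types=2, cells_per_type=8, ring_size=16), 50.0
        )
        assert cn.run(st2, 50.0) == r_mem

    def test_write_is_byte_deterministic(self, tmp_path):
        cn.write_model(fresh_ring_state(), tmp_path / "a")
        cn.write_model(fresh_ring_state(), tmp_path / "b")
        assert same_bytes(tmp_path / "a", tmp_path / "b")

    def test_unknown_semantic_tag_named_in_error(self, tmp_path):
        st = fresh_ring_state()
        cn.write_model(st, tmp_path / "arch")
        mpath = tmp_path / "arch" / "manifest.json"
        manifest = json.loads(mpath.read_text())
        manifest["netcon_table"]["target_group"]["tag"] = "mystery_tag"
        mpath.write_text(json.dumps(manifest))
        with pytest.raises(ArchiveError, match="mystery_tag"):
            cn.read_model(tmp_path / "arch")

    def test_registry_digest_mismatch_rejected(self, tmp_path):
        st = fresh_ring_state()
        cn.write_model(st, tmp_path / "arch")
        mpath = tmp_path / "arch" / "manifest.json"
        manifest = json.loads(mpath.read_text())
        manifest["registry_digest"] = "0" * 64
        mpath.write_text(json.dumps(manifest))
        with pytest.raises(ArchiveError, match="digest"):
            cn.read_model(tmp_path / "arch")

    def test_truncated_dataset_rejected(self, tmp_path):
        st = fresh_ring_state()
        cn.write_model(st, tmp_path / "arch")
        np.save(tmp_path / "arch" / "group0_parent.npy", np.zeros(1, np.int64))
        with pytest.raises(ArchiveError, match="truncated|expected"):
            cn.read_model(tmp_path / "arch")

    def test_empty_network_roundtrip(self, tmp_path):
        net = cn.NetworkModel(cells=[], gids=[], type_of_cell=[])
        st = cn.SimState(cn.Model(net=net))
        cn.write_model(st, tmp_path / "empty")
        model, manifest = cn.read_model(tmp_path / "empty")
        st2 = cn.SimState(model)
        assert cn.run(st2, 5.0) == []
        assert st2.t == pytest.approx(5.0)

    def test_permuted_state_archives_identically(self, tmp_path):
        from cablenet.ordering import apply_permutation, constant_depth_order

        st = fresh_ring_state()
        cn.write_model(st, tmp_path / "plain")
        stp = fresh_ring_state()
        apply_permutation(stp, constant_depth_order(stp.model.net))
        cn.write_model(stp, tmp_path / "perm")
        assert same_bytes(tmp_path / "plain", tmp_path / "perm")


def netstim_fanout_model():
    """One HH+ExpSyn compartment driven by a netstim through 3 delays."""
    m = cn.single_compartment(mechs=[("hh", {}), ("expsyn", dict(tau=2.0))])
    ns = m.add_netstim(start=9.0, interval=100.0, number=1)
    for delay in (1.0, 2.0, 3.0):
        m.connect(ns.gid, 1, weight=0.02, delay=delay)
    return m


class TestCheckpoint:
    def test_collapses_deliveries_to_single_source_event(self, tmp_path):
        st = cn.SimState(netstim_fanout_model(), seed=3)
        cn.run(st, 10.5)  # delay-1 delivered; delays 2,3 still pending
        assert len(st.queue) == 2
        cn.save_checkpoint(st, tmp_path / "ck")
        gids = np.load(tmp_path / "ck" / "event_gid.npy")
        times = np.load(tmp_path / "ck" / "event_time.npy")
        assert len(gids) == 1 and times[0] == 9.0

    def test_no_pending_events_empty_table(self, tmp_path):
        st = cn.SimState(cn.single_compartment(mechs=[("pas", {})]))
        cn.run(st, 1.0)
        cn.save_checkpoint(st, tmp_path / "ck")
        assert len(np.load(tmp_path / "ck" / "event_gid.npy")) == 0

    def test_restore_regenerates_pending_deliveries(self, tmp_path):
        st = cn.SimState(netstim_fanout_model(), seed=3)
        cn.run(st, 10.5)
        before = [(e.delivery_time, e.netcon) for e in st.queue.pending()]
        cn.save_checkpoint(st, tmp_path / "ck")
        st2 = cn.SimState(netstim_fanout_model(), seed=3)
        cn.restore_checkpoint(tmp_path / "ck", st2)
        after = [(e.delivery_time, e.netcon) for e in st2.queue.pending()]
        assert before == after  # multiset equality incl. exact times

    def test_checkpoint_after_restore_is_byte_identical(self, tmp_path):
        st = cn.SimState(netstim_fanout_model(), seed=3)
        cn.run(st, 10.5)
        cn.save_checkpoint(st, tmp_path / "a")
        st2 = cn.SimState(netstim_fanout_model(), seed=3)
        cn.restore_checkpoint(tmp_path / "a", st2)
        cn.save_checkpoint(st2, tmp_path / "b")
        names = sorted(p.name for p in (tmp_path / "a").iterdir())
        match, mismatch, errors = filecmp.cmpfiles(
            tmp_path / "a", tmp_path / "b", names, shallow=False
        )
        assert not mismatch and not errors

    def test_restore_into_mismatched_model_rejected(self, tmp_path):
        st = cn.SimState(netstim_fanout_model(), seed=3)
        cn.run(st, 10.0)
        cn.save_checkpoint(st, tmp_path / "ck")
        other = cn.SimState(make_ring(), seed=3)
        with pytest.raises(IntegrityError):
            cn.restore_checkpoint(tmp_path / "ck", other)

    @pytest.mark.parametrize("build", [
        pytest.param(lambda: cn.single_compartment(
            mechs=[("pas", dict(g=0.001, e=-60.0))]), id="passive"),
        pytest.param(lambda: _hh_clamped(), id="hh"),
        pytest.param(lambda: make_ring(seed=5), id="synaptic-ring"),
        pytest.param(lambda: _netstim_driven(), id="netstim"),
        pytest.param(lambda: cn.gap_pair(g_gap=0.01, v_kick=0.3), id="gap"),
    ])
    def test_split_run_equivalence(self, tmp_path, build):
        full = cn.SimState(build(), seed=5)
        r_full = cn.run(full, 60.0)
        first = cn.SimState(build(), seed=5)
        r1 = cn.run(first, 30.0)
        cn.save_checkpoint(first, tmp_path / "ck")
        second = cn.SimState(build(), seed=5)
        cn.restore_checkpoint(tmp_path / "ck", second)
        r2 = cn.run(second, 60.0)
        assert r_full == sorted(r1 + r2)
        assert np.array_equal(full.solver.v, second.solver.v)

    def test_restore_with_new_stimulus_seed_diverges_after_restore(
            self, tmp_path):
        def build():
            m = cn.single_compartment(mechs=[("hh", {}),
                                             ("expsyn", dict(tau=2.0))])
            ns = m.add_netstim(start=2.0, interval=4.0, number=200, noise=1.0)
            m.connect(ns.gid, 1, weight=0.05, delay=1.0)
            return m

        full = cn.SimState(build(), seed=5)
        r_full = cn.run(full, 80.0)
        first = cn.SimState(build(), seed=5)
        r1 = cn.run(first, 40.0)
        cn.save_checkpoint(first, tmp_path / "ck")
        second = cn.SimState(build(), seed=5)
        cn.restore_checkpoint(tmp_path / "ck", second, netstim_seed=99)
        r2 = cn.run(second, 80.0)
        # identical history up to the restore time...
        assert sorted(t for t, _ in r1) == \
               sorted(t for t, _ in r_full if t <= 40.0)
        # ...but a different future
        assert sorted(r1 + r2) != r_full

    def test_mid_interval_save_matches_continuous(self, tmp_path):
        # checkpoint not aligned with an exchange boundary
        full = cn.SimState(make_ring(seed=7), seed=7)
        r_full = cn.run(full, 40.0)
        # save half a synaptic delay after a spike: deliveries are in flight
        t_spike = next(t for t, _ in r_full if t > 15.0)
        t_save = t_spike + 0.5
        first = cn.SimState(make_ring(seed=7), seed=7)
        r1 = cn.run(first, t_save)
        assert collapse_pending_events(first)  # something is in flight
        cn.save_checkpoint(first, tmp_path / "ck")
        second = cn.SimState(make_ring(seed=7), seed=7)
        cn.restore_checkpoint(tmp_path / "ck", second)
        r2 = cn.run(second, 40.0)
        assert r_full == sorted(r1 + r2)


def _hh_clamped():
    m = cn.single_compartment(mechs=[("hh", {})])
    m.insert("iclamp", 0, 0, amp=0.12, start=5.0, dur=100.0)
    return m


def _netstim_driven():
    m = cn.single_compartment(mechs=[("hh", {}), ("expsyn", dict(tau=2.0))])
    ns = m.add_netstim(start=3.0, interval=7.0, number=50, noise=1.0)
    m.connect(ns.gid, 1, weight=0.05, delay=1.0)
    return m
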