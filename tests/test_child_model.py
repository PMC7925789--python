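"""Bundled child-agent model: structure, printed values, ledger, scenarios."""

import pytest

import reifnet.child_model as cm
from reifnet.errors import SpecificationError

# the reified connection of every W-state, as listed in the model description
W_WIRING = {
    "W_1": ("srs_h", "eval_h"),
    "W_2": ("cbs_plus", "cfs_love"),
    "W_3": ("cfs_love", "cbs_plus"),
    "W_4": ("cstriatum", "cinsula"),
    "W_5": ("cfs_reward", "cstriatum"),
    "W_6": ("cfs_love", "cstriatum"),
    "W_7": ("cps_act", "hipp_1"),
    "W_8": ("fs_sat", "cps_act"),
    "W_9": ("ps_share", "exp"),
    "W_10": ("fs_nov", "ps_share"),
    "W_11": ("fs_em", "ps_share"),
    "W_12": ("fs_urge", "ps_share"),
    "W_13": ("cbs_minus", "dep"),
    "W_14": ("dep", "cbs_minus"),
    "W_15": ("cbs_minus", "stress"),
    "W_16": ("stress", "cbs_minus"),
    "W_17": ("dep", "ps_iso"),
    "W_18": ("stress", "ps_iso"),
    "W_19": ("srs_u", "eval_d"),
    "W_20": ("ps_avd", "hipp_2"),
    "W_21": ("fs_per", "ps_avd"),
}

EUCL_STATES = {
    "ss_h", "srs_h", "ces_happy", "fs_sat", "ss_s",
    "srs_s", "ss_u", "srs_u", "fs_per", "es_avd",
}


class TestStructure:
    def test_level_cardinalities(self, child_spec):
        roles = [s.role for s in child_spec.states]
        assert len(child_spec.states) == 84
        assert roles.count("base") == 39
        assert roles.count("W") == 21
        assert roles.count("M") == 12
        assert roles.count("H") == 12

    def test_w_states_reify_the_listed_connections(self, child_spec):
        for wid, conn in W_WIRING.items():
            st = child_spec.state(wid)
            assert st.role == "W"
            assert st.reifies == conn, wid
            # the reified connection exists as an mb slot of its target
            assert conn[0] in child_spec.matrices.mb[conn[1]]
            # and the W-state's own inputs are exactly that connection
            assert tuple(child_spec.matrices.mb[wid]) == conn

    def test_metaplasticity_covers_first_twelve_w_states(self, child_spec):
        for k in range(1, 13):
            assert child_spec.state(f"M_{k}").reifies == f"W_{k}"
            assert child_spec.state(f"H_{k}").reifies == f"W_{k}"
            assert child_spec.matrices.msa[f"W_{k}"] == f"H_{k}"
            assert child_spec.matrices.mcfpa[f"W_{k}"]["hebb"]["mu"] == f"M_{k}"
        for k in range(13, 22):
            # learning rate and persistence are constant above W_12
            assert child_spec.matrices.msa.get(f"W_{k}") is None
            assert "mu" in child_spec.matrices.mcfpv[f"W_{k}"]["hebb"]

    def test_euclidean_function_assignment(self, child_spec):
        eucl_states = {
            sid
            for sid, entry in child_spec.matrices.mcfwv.items()
            if "eucl" in entry
        }
        assert eucl_states == EUCL_STATES
        hebb_states = {
            sid
            for sid, entry in child_spec.matrices.mcfwv.items()
            if "hebb" in entry
        }
        assert len(hebb_states) == 21
        alogistic_states = {
            sid
            for sid, entry in child_spec.matrices.mcfwv.items()
            if "alogistic" in entry
        }
        assert len(alogistic_states) == 53

    def test_printed_ps_share_parameters(self, child_spec):
        m = child_spec.matrices
        assert child_spec.in_degree("ps_share") == 4
        slot = m.mb["ps_share"].index("eval_s")
        assert m.mcwv["ps_share"][slot] == pytest.approx(0.5)
        adaptive = [w for w in m.mcwa["ps_share"] if w is not None]
        assert sorted(adaptive) == ["W_10", "W_11", "W_12"]
        assert m.msv["ps_share"] == pytest.approx(0.6)
        assert m.mcfpv["ps_share"]["alogistic"]["sigma"] == pytest.approx(10.0)
        assert m.mcfpv["ps_share"]["alogistic"]["tau"] == pytest.approx(0.2)

    def test_both_profiles_validate_cleanly(self, child_spec, resistant_spec):
        assert child_spec.validate().errors == []
        assert resistant_spec.validate().errors == []


class TestLedger:
    def test_ledger_covers_every_numeric_cell_exactly_once(self, child_spec):
        ledger = cm.parameter_ledger()
        keys = [e.key for e in ledger.entries]
        assert len(keys) == len(set(keys)), "duplicate ledger entries"
        assert set(keys) == ledger.numeric_cells_of(child_spec)

    def test_printed_entries_are_tagged(self):
        ledger = cm.parameter_ledger()
        printed = {e.key for e in ledger.printed()}
        assert ("mcwv", "ps_share", "eval_s") in printed
        assert ("msv", "ps_share", "speed") in printed
        assert ("mcfpv", "ps_share", "alogistic.sigma") in printed
        assert ("mcfpv", "ps_share", "alogistic.tau") in printed

    def test_profiles_differ_only_in_reconstructed_cells(self):
        base = cm.parameter_ledger("narcissistic-prone")
        res = cm.parameter_ledger("resistant")
        printed_both = {e.key for e in base.printed()} & {
            e.key for e in res.printed()
        }
        for key in printed_both:
            assert base.lookup(*key).value == res.lookup(*key).value

    def test_resistant_starts_satisfaction_persistence_at_one(self, resistant_spec):
        assert resistant_spec.state("M_7").initial_value == 1.0
        assert resistant_spec.state("M_8").initial_value == 1.0
        ledger = cm.parameter_ledger("resistant")
        assert ledger.lookup("iv", "M_7", "value").provenance == "printed"


class TestVariant:
    def test_idempotent_per_profile(self, child_spec):
        v1 = cm.variant(child_spec, "resistant")
        v2 = cm.variant(v1, "resistant")
        assert v1.to_json() == v2.to_json()
        back = cm.variant(v1, "narcissistic-prone")
        assert back.to_json() == child_spec.to_json()

    def test_rejects_foreign_specs(self):
        import reifnet.model_spec as ms

        other = ms.random_network(3, 0, 0.5, seed=1)
        with pytest.raises(SpecificationError):
            cm.variant(other, "resistant")

    def test_unknown_profile(self, child_spec):
        with pytest.raises(SpecificationError, match="resistant"):
            cm.variant(child_spec, "zen")


class TestScenarios:
    def test_social_media_episode_geometry(self):
        sched = cm.scenario("happy_social")
        assert sched.value_at("ws_s", 30.0) == 0.0
        assert sched.value_at("ws_s", 90.0) == 1.0
        assert sched.value_at("ws_s", 130.0) == 0.0
        assert sched.horizon == 480.0

    def test_offline_scenario_has_no_social_media(self):
        sched = cm.scenario("happy_offline")
        for t in (0.0, 100.0, 320.0):
            assert sched.value_at("ws_s", t) == 0.0
        assert sched.value_at("es_happy", 10.0) == 1.0  # ramped on by t=5

    def test_unhappy_stimulus_on_before_t10(self):
        for name in ("unhappy_isolation", "unhappy_coping", "coping_relief"):
            sched = cm.scenario(name)
            assert sched.value_at("es_unhappy", 9.0) == 1.0
            assert sched.value_at("es_happy", 100.0) == 0.0

    def test_coping_overlay(self):
        sched = cm.scenario("unhappy_coping")
        assert sched.overlay == {"hipp_2": 0.6, "W_19": 0.3}
        assert cm.scenario("unhappy_isolation").overlay == {}

    def test_unknown_scenario_lists_valid_names(self):
        with pytest.raises(SpecificationError, match="happy_offline"):
            cm.scenario("nonexistent")

    def test_signal_values_in_unit_interval(self):
        for name in cm.SCENARIOS:
            sched = cm.scenario(name)
            for sid, bps in sched.signals.items():
                assert bps[0][0] == 0.0
                assert all(0.0 <= v <= 1.0 for _, v in bps)


class TestModelFiles:
    def test_write_model_round_trips_and_is_deterministic(self, tmp_path, child_spec):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        cm.write_model(d1)
        cm.write_model(d2)
        for f in sorted(d1.iterdir()):
            assert (d2 / f.name).read_bytes() == f.read_bytes(), f.name
        import reifnet.model_spec as ms

        loaded = ms.load_role_matrices(d1, metadata=child_spec.metadata)
        assert loaded.to_json() == child_spec.to_json()
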