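"""Strategy encoding, named strategies, and automaton handling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from friendlyrivals import (
    DeterministicMemoryStrategy,
    MemoryOneStrategy,
    ZDParams,
    capri,
    make_named,
    parse_strategy,
    trigger_automaton,
)
from friendlyrivals.strategies import (
    C,
    D,
    JointState,
    prescriptions,
    shift_state,
    state_histories,
    state_index,
    swap_state,
)

# CAPRI's action table transcribed by hand from its published form, row by
# row (own history ccc..ddd, co-player history ccc..ddd within each row).
# Independent of the five-rule construction in the package.
CAPRI_TABLE_TRANSCRIPTION = (
    "cdddcddd"  # ccc
    "cdcddddd"  # ccd
    "dcddcddd"  # cdc
    "dddddddd"  # cdd
    "cdcdcdcd"  # dcc
    "dddddddd"  # dcd
    "ddddcdcc"  # ddc
    "ddddddcd"  # ddd
)


class TestStateArithmetic:
    def test_swap_is_involution(self):
        for m in (1, 2, 3):
            for s in range(1 << (2 * m)):
                assert swap_state(swap_state(s, m), m) == s

    def test_shift_drops_oldest_and_appends(self):
        s = state_index("cdc", "dcc")
        assert state_histories(shift_state(s, D, C, 3), 3) == ("dcd", "ccc")

    def test_full_cooperation_is_state_zero(self):
        for m in (1, 2, 3):
            assert state_index("c" * m, "c" * m) == 0

    def test_joint_state_roundtrip(self):
        js = JointState("cdd", "dcc")
        assert JointState.from_index(js.index, 3) == js


class TestEncoding:
    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**16 - 1))
    def test_id_roundtrip_m2(self, sid):
        assert DeterministicMemoryStrategy.from_id(2, sid).id == sid

    def test_id_roundtrip_all_m1(self):
        for sid in range(16):
            assert DeterministicMemoryStrategy.from_id(1, sid).id == sid

    def test_alld_and_allc_ids(self):
        assert make_named("AllD").id == 15  # m=1, all four states defect
        assert make_named("AllC").embed(2).id == 0

    def test_bit_convention(self):
        # bit i of the id is 1 iff the table defects at state i
        s = DeterministicMemoryStrategy.from_id(2, 0b1010)
        assert [int(a) for a in s.table[:4]] == [0, 1, 0, 1]

    def test_text_format_roundtrip(self):
        s = capri()
        assert DeterministicMemoryStrategy.from_string(s.to_string()) == s

    def test_parse_strategy_forms(self):
        assert parse_strategy("m=1 cccc").id == 0
        assert parse_strategy("0xF", m=1).id == 15
        assert parse_strategy("tft").id == make_named("TFT").id
        with pytest.raises(ValueError):
            parse_strategy("12345")  # id without memory length


class TestNamedStrategies:
    @pytest.mark.parametrize(
        "name,tuple5",
        [
            ("AllC", (1, 1, 1, 1, 1)),
            ("AllD", (0, 0, 0, 0, 0)),
            ("TFT", (1, 1, 0, 1, 0)),
            ("WSLS", (1, 1, 0, 0, 1)),
        ],
    )
    def test_memory_one_rows_agree_with_tables(self, name, tuple5):
        table = make_named(name)
        via_tuple = MemoryOneStrategy(*tuple5).to_deterministic()
        assert table.id == via_tuple.id

    def test_tf2t_defects_only_after_two_defections(self):
        s = make_named("TF2T")
        assert s.m == 2
        for st_ in range(16):
            assert int(s.table[st_]) == (D if (st_ & 0b11) == 0b11 else C)

    def test_gtft_is_probabilistic(self):
        g = make_named("GTFT", q=0.3)
        assert not g.deterministic
        assert g.tuple == (1, 1, 0.3, 1, 0.3)

    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError):
            make_named("copycat")


class TestZD:
    def test_generous_probabilities_feasible(self, pd_payoffs):
        zd = ZDParams(phi=0.1, eta=0.5, flavor="generous").to_memory_one(pd_payoffs)
        assert zd.p0 == 1.0 and zd.pR == 1.0
        assert all(0.0 <= v <= 1.0 for v in zd.tuple)

    def test_extortionate_boundary_entries(self, pd_payoffs):
        zd = ZDParams(phi=0.1, eta=0.5, flavor="extortionate").to_memory_one(pd_payoffs)
        assert zd.p0 == 0.0 and zd.pP == 0.0

    def test_infeasible_phi_rejected(self, pd_payoffs):
        with pytest.raises(ValueError):
            ZDParams(phi=5.0, eta=0.5, flavor="generous").to_memory_one(pd_payoffs)


class TestCapri:
    def test_five_rules_match_transcribed_table(self, capri_strategy):
        assert capri_strategy.to_string() == f"m=3 {CAPRI_TABLE_TRANSCRIPTION}"
        # and the id round-trips
        assert DeterministicMemoryStrategy.from_id(3, capri_strategy.id) == capri_strategy

    def test_common_prescriptions_of_successful_strategies(self, capri_strategy):
        states = [("ccc", "ccc"), ("ccc", "ddd"), ("cdd", "ddd"), ("ddd", "ddd")]
        actions = [capri_strategy.action(state_index(a, b)) for a, b in states]
        assert actions == [C, D, D, D]


class TestAutomata:
    def test_constant_strategies_minimize_to_one_state(self):
        assert make_named("AllD").to_automaton().minimize().n == 1
        assert make_named("AllC").embed(3).to_automaton().minimize().n == 1

    def test_tft_minimizes_to_two_states(self):
        assert make_named("TFT").to_automaton().minimize().n == 2

    def test_minimization_is_idempotent(self, capri_strategy):
        m1 = capri_strategy.to_automaton().minimize()
        m2 = m1.minimize()
        assert m2.n == m1.n

    def test_minimized_automaton_plays_identically(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            s = DeterministicMemoryStrategy.from_id(2, int(rng.integers(0, 2**16)))
            aut = s.to_automaton().minimize()
            for _ in range(100):
                seq = [(int(a), int(b)) for a, b in rng.integers(0, 2, size=(12, 2))]
                assert prescriptions(s, seq) == prescriptions(aut, seq)

    def test_exhaustive_equivalence_short_sequences(self):
        import itertools

        s = make_named("TFT")
        aut = s.to_automaton().minimize()
        for seq in itertools.product([(a, b) for a in (0, 1) for b in (0, 1)], repeat=4):
            assert prescriptions(s, list(seq)) == prescriptions(aut, list(seq))

    def test_capri_automaton_has_exploitation_self_loop(self, capri_strategy):
        # some state defects forever while the co-player keeps cooperating
        aut = capri_strategy.to_automaton().minimize()
        assert any(
            aut.output[u] == D and aut.delta[u, D, C] == u for u in range(aut.n)
        )

    def test_trigger_never_returns_to_cooperation(self):
        t = trigger_automaton()
        assert t.output[t.initial] == C
        u = t.step(t.initial, C, D)
        for a in (C, D):
            for b in (C, D):
                assert t.step(u, a, b) == u
        assert t.output[u] == D


class TestEmbedding:
    def test_embedded_strategy_plays_identically(self):
        rng = np.random.default_rng(11)
        tft = make_named("TFT")
        tft3 = tft.embed(3)
        for _ in range(200):
            seq = [(int(a), int(b)) for a, b in rng.integers(0, 2, size=(10, 2))]
            assert prescriptions(tft, seq) == prescriptions(tft3, seq)
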