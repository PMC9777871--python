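"""Unit and property tests for the rule-fact network and its training step."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vitalsid.network import (
    CHANNELS,
    Fact,
    Rule,
    RuleFactNetwork,
    TrainingParams,
    build_network,
)

DESIGN_PAIRINGS = {
    1: [{"blood_pressure", "heart_rate"}, {"resp_rate", "etco2"}],
    2: [{"heart_rate", "resp_rate"}, {"blood_pressure", "etco2"}],
    3: [{"heart_rate", "etco2"}, {"resp_rate", "blood_pressure"}],
}


def first_layer_pairings(net):
    """The channel-name pairs feeding the two first-layer rules."""
    final = net._order[-1]
    pairs = []
    for r in net._order[:-1]:
        names = {net.facts[g].name for g in r.input_fact_guids}
        pairs.append(names)
        assert r.output_fact_guid in final.input_fact_guids
    return pairs


class TestBuildNetwork:
    @pytest.mark.parametrize("design_id", [1, 2, 3])
    def test_structure(self, design_id):
        net = build_network(design_id)
        assert len(net.facts) == 7
        assert len(net.rules) == 3
        kinds = [f.kind for f in net.facts.values()]
        assert kinds.count("input") == 4
        assert kinds.count("intermediate") == 2
        assert kinds.count("output") == 1
        # acyclicity is established by the toposort succeeding
        assert len(net._order) == 3
        assert net.start_fact_guid == net.channel_map["blood_pressure"]
        guids = list(net.facts) + list(net.rules)
        assert len(set(guids)) == len(guids)

    @pytest.mark.parametrize("design_id", [1, 2, 3])
    def test_design_pairings(self, design_id):
        net = build_network(design_id)
        pairs = first_layer_pairings(net)
        assert pairs == DESIGN_PAIRINGS[design_id] or (
            pairs[::-1] == DESIGN_PAIRINGS[design_id]
        )

    def test_initial_state(self):
        net = build_network(2, default_fact_value=0.6)
        assert all(f.value == 0.6 for f in net.facts.values())
        assert all(r.weights == [0.5, 0.5] for r in net.rules.values())

    def test_unknown_design_rejected(self):
        with pytest.raises(ValueError, match="design"):
            build_network(4)

    def test_seeded_guids_reproducible(self):
        a = build_network(1, rng=np.random.default_rng(5))
        b = build_network(1, rng=np.random.default_rng(5))
        assert list(a.facts) == list(b.facts)
        assert list(a.rules) == list(b.rules)


class TestSetFact:
    def test_set_and_read(self):
        net = build_network(1)
        g = net.channel_map["heart_rate"]
        net.set_fact(g, 0.393)
        assert net.facts[g].value == 0.393
        net.set_fact(g, 0.0)
        assert net.facts[g].value == 0.0

    def test_clamping_warns(self):
        net = build_network(1)
        g = net.channel_map["heart_rate"]
        with pytest.warns(UserWarning, match="clamp"):
            net.set_fact(g, 1.7)
        assert net.facts[g].value == 1.0

    def test_unknown_guid_named_in_error(self):
        net = build_network(1)
        with pytest.raises(KeyError, match="nonexistent"):
            net.set_fact("nonexistent", 0.5)


class TestPresent:
    def test_equal_inputs_pass_through(self):
        net = build_network(3)
        for ch in CHANNELS:
            net.set_fact(net.channel_map[ch], 0.37)
        assert net.present(net.start_fact_guid, 0.37) == pytest.approx(0.37)

    def test_two_level_mean(self):
        net = build_network(1)
        for ch, v in zip(CHANNELS, [0.2, 0.4, 0.6, 0.8]):
            net.set_fact(net.channel_map[ch], v)
        assert net.evaluate() == pytest.approx(0.5)

    def test_convexity(self, rng):
        net = build_network(2)
        for _ in range(50):
            vals = rng.uniform(0, 1, 4)
            for ch, v in zip(CHANNELS, vals):
                net.set_fact(net.channel_map[ch], v)
            out = net.evaluate()
            assert vals.min() - 1e-12 <= out <= vals.max() + 1e-12

    def test_cycle_detected(self):
        facts = [Fact(f"f{i}" * 8, f"f{i}", 0.5, "input") for i in range(3)]
        facts[2].kind = "output"
        with pytest.raises(ValueError, match="cycle"):
            RuleFactNetwork(
                facts,
                [
                    Rule("r1" * 16, (facts[0].guid, facts[2].guid), [0.5, 0.5],
                         facts[1].guid),
                    Rule("r2" * 16, (facts[0].guid, facts[1].guid), [0.5, 0.5],
                         facts[2].guid),
                ],
            )


def random_layered_network(rng, n_levels):
    """Random DAG of two-input convex rules with <= 4 levels, plus a naive
    recursive oracle for its output."""
    facts = []
    level_facts = []
    counter = 0

    def new_fact(kind, value=0.0):
        nonlocal counter
        f = Fact(f"{counter:032d}"[:32], f"n{counter}", value, kind)
        counter += 1
        facts.append(f)
        return f

    inputs = [new_fact("input", rng.uniform(0, 1)) for _ in range(4)]
    level_facts.append(inputs)
    rules = []
    for level in range(n_levels - 1):
        width = max(1, 4 - 2 * (level + 1)) if level < n_levels - 2 else 1
        new_level = []
        for _ in range(width):
            kind = "output" if level == n_levels - 2 and width == 1 else "intermediate"
            outf = new_fact(kind)
            pool = [f for lv in level_facts for f in lv]
            pair = rng.choice(len(pool), size=2, replace=False)
            w = rng.uniform(0.05, 0.95)
            rules.append(
                Rule(
                    f"{counter:032d}"[:32],
                    (pool[pair[0]].guid, pool[pair[1]].guid),
                    [w, 1 - w],
                    outf.guid,
                )
            )
            counter += 1
            new_level.append(outf)
        level_facts.append(new_level)
    out_guid = level_facts[-1][0].guid
    net = RuleFactNetwork(facts, rules, output_fact_guid=out_guid)

    values = {f.guid: f.value for f in facts}
    by_output = {r.output_fact_guid: r for r in rules}

    def oracle(guid):
        r = by_output.get(guid)
        if r is None:
            return values[guid]
        (g1, g2), (w1, w2) = r.input_fact_guids, r.weights
        return w1 * oracle(g1) + w2 * oracle(g2)

    return net, oracle(out_guid)


def test_present_matches_recursive_oracle():
    """Forward inference equals naive recursive evaluation on >=100 random
    small networks, to 1e-12."""
    rng = np.random.default_rng(99)
    for i in range(120):
        net, expected = random_layered_network(rng, n_levels=int(rng.integers(2, 5)))
        assert net.evaluate() == pytest.approx(expected, abs=1e-12)


def single_rule_update_oracle(v1, v2, w1, target, velocity):
    """Standalone one-rule training update, written independently of the
    network code: output o = w1*v1 + (1-w1)*v2; the full signed error is
    apportioned to the only rule; weight moves toward the larger input for
    positive error."""
    o = w1 * v1 + (1 - w1) * v2
    e = target - o
    if v1 == v2 or e == 0:
        return w1
    delta = velocity * e
    w1_new = w1 + delta if v1 > v2 else w1 - delta
    return min(max(w1_new, 0.0), 1.0)


def make_single_rule_net(v1, v2, w1):
    f1 = Fact("a" * 32, "x1", v1, "input")
    f2 = Fact("b" * 32, "x2", v2, "input")
    fo = Fact("c" * 32, "out", 0.5, "output")
    rule = Rule("d" * 32, (f1.guid, f2.guid), [w1, 1 - w1], fo.guid)
    return RuleFactNetwork([f1, f2, fo], [rule]), rule, f1


class TestTrainStep:
    def test_single_rule_matches_oracle(self, rng):
        for _ in range(100):
            v1, v2 = rng.uniform(0, 1, 2)
            w1 = rng.uniform(0, 1)
            target = rng.uniform(0, 1)
            vel = rng.uniform(0.01, 1.0)
            net, rule, f1 = make_single_rule_net(v1, v2, w1)
            before, after = net.train_step(
                f1.guid, v1, "c" * 32, TrainingParams(target, vel)
            )
            expected_w1 = single_rule_update_oracle(v1, v2, w1, target, vel)
            assert rule.weights[0] == pytest.approx(expected_w1, abs=1e-12)
            assert after <= before + 1e-12

    def test_single_rule_error_strictly_reduced(self):
        net, rule, f1 = make_single_rule_net(0.2, 0.6, 0.5)
        before, after = net.train_step(
            f1.guid, 0.2, "c" * 32, TrainingParams(0.5, 0.1)
        )
        assert after < before

    def test_zero_error_leaves_weights(self):
        net, rule, f1 = make_single_rule_net(0.2, 0.8, 0.5)
        # output = 0.5 exactly
        before, after = net.train_step(
            f1.guid, 0.2, "c" * 32, TrainingParams(0.5, 0.3)
        )
        assert before == after == 0.0
        assert rule.weights == [0.5, 0.5]

    def test_equal_inputs_never_move(self):
        net = build_network(1)
        for ch in CHANNELS:
            net.set_fact(net.channel_map[ch], 0.3)
        w_before = net.weight_state()
        for _ in range(5):
            net.train_step(
                net.start_fact_guid, 0.3, net.output_fact_guid,
                TrainingParams(0.9, 0.5),
            )
        assert net.weight_state() == w_before
        assert net.facts[net.output_fact_guid].value == pytest.approx(0.3)

    def test_weights_sum_to_one_after_training(self, rng):
        net = build_network(3)
        params = TrainingParams(0.5, 0.4)
        for _ in range(200):
            vals = rng.uniform(0, 1, 4)
            for ch, v in zip(CHANNELS, vals):
                net.set_fact(net.channel_map[ch], v)
            net.train_step(
                net.start_fact_guid, vals[3], net.output_fact_guid, params
            )
            for r in net.rules.values():
                assert 0.0 <= r.weights[0] <= 1.0
                assert 0.0 <= r.weights[1] <= 1.0
                assert abs(sum(r.weights) - 1.0) < 1e-9

    def test_monotone_error_on_fixed_input(self):
        net = build_network(2)
        vals = [0.15, 0.85, 0.4, 0.7]
        for ch, v in zip(CHANNELS, vals):
            net.set_fact(net.channel_map[ch], v)
        params = TrainingParams(0.5, 0.05)
        errors = []
        for _ in range(60):
            before, after = net.train_step(
                net.start_fact_guid, vals[3], net.output_fact_guid, params
            )
            errors.append(after)
        assert all(b >= a - 1e-12 for b, a in zip(errors, errors[1:]))

    def test_unreachable_end_fact_rejected(self):
        net = build_network(1)
        hr = net.channel_map["heart_rate"]
        with pytest.raises(ValueError, match="not produced"):
            net.train_step(net.start_fact_guid, 0.5, hr, TrainingParams())


class TestResetFacts:
    def test_reset_intermediates(self):
        net = build_network(1)
        for ch, v in zip(CHANNELS, [0.1, 0.9, 0.3, 0.7]):
            net.set_fact(net.channel_map[ch], v)
        net.evaluate()
        net.reset_facts({"intermediate"}, 0.5)
        mids = [f for f in net.facts.values() if f.kind == "intermediate"]
        assert [f.value for f in mids] == [0.5, 0.5]

    def test_empty_kind_set_noop(self):
        net = build_network(1)
        net.set_fact(net.channel_map["etco2"], 0.9)
        state = {g: f.value for g, f in net.facts.items()}
        net.reset_facts(set(), 0.0)
        assert {g: f.value for g, f in net.facts.items()} == state

    def test_reset_then_present_equals_fresh_network(self, rng):
        net = build_network(3, rng=np.random.default_rng(3))
        params = TrainingParams(0.5, 0.2)
        for _ in range(30):
            vals = rng.uniform(0, 1, 4)
            for ch, v in zip(CHANNELS, vals):
                net.set_fact(net.channel_map[ch], v)
            net.train_step(net.start_fact_guid, vals[3], net.output_fact_guid, params)
        net.reset_facts({"intermediate", "output"}, 0.5)
        fresh = build_network(3, rng=np.random.default_rng(3))
        for g, r in net.rules.items():
            fresh.rules[g].weights = list(r.weights)
        test_vals = [0.3, 0.6, 0.2, 0.9]
        for n in (net, fresh):
            for ch, v in zip(CHANNELS, test_vals):
                n.set_fact(n.channel_map[ch], v)
        assert net.evaluate() == fresh.evaluate()


@settings(max_examples=50, deadline=None)
@given(
    vals=st.lists(st.floats(0, 1, allow_nan=False), min_size=4, max_size=4),
    velocity=st.floats(0.01, 1.0),
    design=st.sampled_from([1, 2, 3]),
)
def test_train_step_never_increases_error(vals, velocity, design):
    """For velocity <= 1 the post-update error never exceeds the pre-update
    error, for any inputs and any design."""
    net = build_network(design)
    for ch, v in zip(CHANNELS, vals):
        net.set_fact(net.channel_map[ch], v)
    before, after = net.train_step(
        net.start_fact_guid, vals[3], net.output_fact_guid,
        TrainingParams(0.5, velocity),
    )
    assert after <= before + 1e-12
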