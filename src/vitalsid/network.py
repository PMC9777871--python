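"""Rule-fact expert system with gradient-descent weight training.

The model is a small acyclic network of *facts* (nodes holding a value in
[0, 1]) connected by two-input *rules*.  A rule computes a convex combination
``w1*f1 + w2*f2`` of its two input facts (weights are non-negative and sum to
one) and assigns the result to its output fact.  Inference ("present") is a
single topologically ordered forward pass; the output is therefore always a
convex combination of the input-fact values.

Training does not create or remove associations.  A single training step
compares the network output against a target value and apportions the signed
error across the rules that feed the output, proportionally to each rule's
contribution to the output (the partial derivative of the output with respect
to the rule's output fact, i.e. the product of downstream weights).  Each
rule then shifts weight mass toward the input whose value moves the rule
output in the error-reducing direction, by ``velocity`` times its apportioned
error, and the two weights are clamped to [0, 1] and renormalised to sum to
one.  Because the output is a convex combination of inputs, a target outside
the span of the input values can only be approached, never reached.

Three fixed seven-fact / three-rule topologies are provided, differing only
in how the four vital-sign input facts (heart rate, end-tidal CO2,
respiratory rate, blood pressure) are paired at the first layer:

=======  ==========================  ==========================
design   first rule                  second rule
=======  ==========================  ==========================
1        blood pressure + heart rate  resp. rate + end-tidal CO2
2        heart rate + resp. rate      blood pressure + end-tidal CO2
3        heart rate + end-tidal CO2   resp. rate + blood pressure
=======  ==========================  ==========================

Both intermediate facts always feed a final rule producing the output fact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "CHANNELS",
    "Fact",
    "Rule",
    "RuleFactNetwork",
    "TrainingParams",
    "build_network",
]

#: Canonical channel order used throughout the package.
CHANNELS = ("heart_rate", "etco2", "resp_rate", "blood_pressure")

_DESIGN_PAIRS = {
    1: ((("blood_pressure", "heart_rate"), "heart"),
        (("resp_rate", "etco2"), "oxygen")),
    2: ((("heart_rate", "resp_rate"), "rate"),
        (("blood_pressure", "etco2"), "pressure-gas")),
    3: ((("heart_rate", "etco2"), "cardio-gas"),
        (("resp_rate", "blood_pressure"), "resp-pressure")),
}


def _new_guid(rng: np.random.Generator | None = None) -> str:
    """Random version-4-style GUID (8-4-4-4-12 hex grouping).

    When ``rng`` is given the identifier stream is reproducible, which keeps
    emitted command scripts stable across re-runs of a seeded experiment.
    """
    if rng is None:
        import uuid

        return str(uuid.uuid4())
    b = bytearray(rng.bytes(16))
    b[6] = (b[6] & 0x0F) | 0x40  # version 4
    b[8] = (b[8] & 0x3F) | 0x80  # variant
    h = bytes(b).hex()
    return f"{h[:8]}-{h[8:12]}-{h[12:16]}-{h[16:20]}-{h[20:]}"


def _clamp01(x: float) -> float:
    return 0.0 if x < 0.0 else (1.0 if x > 1.0 else x)


@dataclass
class Fact:
    """A node holding a dimensionless value in [0, 1]."""

    guid: str
    name: str
    value: float = 0.5
    kind: str = "input"  # input | intermediate | output

    def __post_init__(self) -> None:
        if self.kind not in ("input", "intermediate", "output"):
            raise ValueError(f"unknown fact kind {self.kind!r}")
        self.value = _clamp01(float(self.value))


@dataclass
class Rule:
    """A two-input convex-combination rule.

    Weights are non-negative, each in [0, 1], and sum to one; they are the
    only trainable state of the network.
    """

    guid: str
    input_fact_guids: tuple[str, str]
    weights: list[float]
    output_fact_guid: str

    def __post_init__(self) -> None:
        if len(self.input_fact_guids) != 2:
            raise ValueError("a rule takes exactly two input facts")
        if self.output_fact_guid in self.input_fact_guids:
            raise ValueError("rule output fact must differ from its inputs")
        self.weights = [float(w) for w in self.weights]
        if len(self.weights) != 2 or any(w < 0 for w in self.weights):
            raise ValueError("weights must be two non-negative reals")
        s = sum(self.weights)
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1, got {s}")


@dataclass
class TrainingParams:
    """Scalars governing one training update.

    ``target_value`` is the value the output fact is driven toward (the
    experiment protocol fixes it at 0.500, the midpoint of the valid range).
    ``velocity`` scales how much weight mass moves per step; values in (0, 1]
    guarantee the post-update error never exceeds the pre-update error.
    """

    target_value: float = 0.5
    velocity: float = 0.1

    def __post_init__(self) -> None:
        if not (0.0 <= self.target_value <= 1.0):
            raise ValueError("target_value must lie in [0, 1]")
        if self.velocity <= 0:
            raise ValueError("velocity must be positive")


class RuleFactNetwork:
    """GUID-addressed rule-fact network with forward inference and training."""

    def __init__(
        self,
        facts: Iterable[Fact],
        rules: Iterable[Rule],
        design_id: int | None = None,
        channel_map: Mapping[str, str] | None = None,
        start_fact_guid: str | None = None,
        output_fact_guid: str | None = None,
    ) -> None:
        self.facts: dict[str, Fact] = {}
        for f in facts:
            if f.guid in self.facts:
                raise ValueError(f"duplicate fact guid {f.guid}")
            self.facts[f.guid] = f
        self.rules: dict[str, Rule] = {}
        for r in rules:
            if r.guid in self.rules:
                raise ValueError(f"duplicate rule guid {r.guid}")
            for g in (*r.input_fact_guids, r.output_fact_guid):
                if g not in self.facts:
                    raise ValueError(f"rule {r.guid} references unknown fact {g}")
            self.rules[r.guid] = r
        self.design_id = design_id
        self.channel_map = dict(channel_map or {})
        self.start_fact_guid = start_fact_guid
        if output_fact_guid is None:
            outs = [f.guid for f in self.facts.values() if f.kind == "output"]
            output_fact_guid = outs[0] if len(outs) == 1 else None
        self.output_fact_guid = output_fact_guid
        self._order = self._toposort()

    # -- structure ---------------------------------------------------------

    def _toposort(self) -> list[Rule]:
        """Topological order of rules; raises on cycles."""
        produced_by = {r.output_fact_guid: r for r in self.rules.values()}
        if len(produced_by) != len(self.rules):
            raise ValueError("two rules assign the same output fact")
        order: list[Rule] = []
        state: dict[str, int] = {}  # 0 visiting, 1 done

        def visit(rule: Rule) -> None:
            st = state.get(rule.guid)
            if st == 1:
                return
            if st == 0:
                raise ValueError("rule graph contains a cycle")
            state[rule.guid] = 0
            for g in rule.input_fact_guids:
                up = produced_by.get(g)
                if up is not None:
                    visit(up)
            state[rule.guid] = 1
            order.append(rule)

        for r in self.rules.values():
            visit(r)
        return order

    def fact(self, guid: str) -> Fact:
        try:
            return self.facts[guid]
        except KeyError:
            raise KeyError(f"no fact with guid {guid}") from None

    # -- fact mutation -----------------------------------------------------

    def set_fact(self, fact_guid: str, value: float) -> None:
        """Assign ``value`` to a fact, clamping into [0, 1] (SF command)."""
        f = self.fact(fact_guid)
        v = float(value)
        if v < 0.0 or v > 1.0:
            warnings.warn(
                f"fact value {v} outside [0, 1]; clamping", stacklevel=2
            )
        f.value = _clamp01(v)

    def reset_facts(self, kinds: Iterable[str], value: float = 0.5) -> None:
        """Set every fact of the given kinds to ``value``; weights untouched."""
        if not (0.0 <= value <= 1.0):
            raise ValueError("reset value must lie in [0, 1]")
        kinds = set(kinds)
        for f in self.facts.values():
            if f.kind in kinds:
                f.value = float(value)

    # -- inference ---------------------------------------------------------

    def evaluate(self) -> float:
        """Forward pass in topological order; returns the output fact value."""
        if self.output_fact_guid is None:
            raise ValueError("network has no output fact")
        facts = self.facts
        for r in self._order:
            g1, g2 = r.input_fact_guids
            w1, w2 = r.weights
            facts[r.output_fact_guid].value = (
                w1 * facts[g1].value + w2 * facts[g2].value
            )
        return facts[self.output_fact_guid].value

    def present(self, start_fact_guid: str, start_value: float) -> float:
        """PR command: set the start fact, evaluate, return the output value."""
        self.set_fact(start_fact_guid, start_value)
        return self.evaluate()

    # -- training ----------------------------------------------------------

    def _contributions(self, end_fact_guid: str) -> dict[str, float]:
        """∂(end fact)/∂(rule output fact) for every rule, by reverse pass."""
        adj: dict[str, float] = {end_fact_guid: 1.0}
        for r in reversed(self._order):
            a = adj.get(r.output_fact_guid, 0.0)
            if a == 0.0:
                continue
            for g, w in zip(r.input_fact_guids, r.weights):
                adj[g] = adj.get(g, 0.0) + a * w
        return {
            r.guid: adj.get(r.output_fact_guid, 0.0) for r in self._order
        }

    def _upstream_rules(self, end_fact_guid: str) -> set[str]:
        """Rules whose output fact can reach ``end_fact_guid``."""
        produced_by = {r.output_fact_guid: r for r in self.rules.values()}
        reach: set[str] = set()

        def walk(fact_guid: str) -> None:
            r = produced_by.get(fact_guid)
            if r is None or r.guid in reach:
                return
            reach.add(r.guid)
            for g in r.input_fact_guids:
                walk(g)

        walk(end_fact_guid)
        return reach

    def train_step(
        self,
        start_fact_guid: str,
        start_value: float,
        end_fact_guid: str,
        params: TrainingParams,
    ) -> tuple[float, float]:
        """One TR command: evaluate, apportion error, update rule weights.

        Returns ``(error_before, error_after)`` as absolute errors against
        ``params.target_value``.  Rules whose two input values are equal are
        left unchanged (no weight change can alter their output).
        """
        if end_fact_guid not in self.facts:
            raise KeyError(f"no fact with guid {end_fact_guid}")
        reachable = self._upstream_rules(end_fact_guid)
        # Topological iteration keeps the apportionment arithmetic
        # deterministic (and bit-stable across runs).
        path_rules = [r.guid for r in self._order if r.guid in reachable]
        if not path_rules:
            raise ValueError(
                f"end fact {end_fact_guid} is not produced by any rule"
            )
        self.set_fact(start_fact_guid, start_value)
        self.evaluate()
        output = self.facts[end_fact_guid].value
        error = params.target_value - output
        err_before = abs(error)
        if error == 0.0:
            return err_before, err_before
        contrib = self._contributions(end_fact_guid)
        total = sum(contrib[g] for g in path_rules)
        if total > 0.0:
            # Snapshot input values before any update so all rules see the
            # same forward pass.
            snapshot = {
                g: (
                    self.facts[self.rules[g].input_fact_guids[0]].value,
                    self.facts[self.rules[g].input_fact_guids[1]].value,
                )
                for g in path_rules
            }
            for g in path_rules:
                share = contrib[g] / total
                apportioned = error * share
                v1, v2 = snapshot[g]
                if v1 == v2:
                    continue  # output is weight-invariant: no defined direction
                rule = self.rules[g]
                delta = params.velocity * apportioned
                # Positive apportioned error: output must rise, so move
                # weight mass toward the larger-valued input (and vice versa).
                if v1 > v2:
                    w1 = rule.weights[0] + delta
                else:
                    w1 = rule.weights[0] - delta
                w1 = _clamp01(w1)
                w2 = _clamp01(1.0 - w1)
                s = w1 + w2
                rule.weights[0] = w1 / s
                rule.weights[1] = w2 / s
        self.evaluate()
        err_after = abs(params.target_value - self.facts[end_fact_guid].value)
        return err_before, err_after

    # -- convenience -------------------------------------------------------

    def input_fact_guids(self) -> list[str]:
        return [f.guid for f in self.facts.values() if f.kind == "input"]

    def weight_state(self) -> dict[str, tuple[float, float]]:
        return {g: (r.weights[0], r.weights[1]) for g, r in self.rules.items()}

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"RuleFactNetwork(design={self.design_id}, "
            f"facts={len(self.facts)}, rules={len(self.rules)})"
        )


def build_network(
    design_id: int,
    default_fact_value: float = 0.5,
    rng: np.random.Generator | None = None,
) -> RuleFactNetwork:
    """Construct one of the three fixed seven-fact, three-rule topologies.

    All fact values start at ``default_fact_value`` and every rule starts at
    weights (0.5, 0.5).  Fresh GUIDs are assigned (reproducibly when ``rng``
    is provided).  The blood-pressure input fact is the designated start fact
    for TR/PR commands.
    """
    if design_id not in _DESIGN_PAIRS:
        raise ValueError(
            f"unknown network design {design_id!r}; expected 1, 2 or 3"
        )
    facts: list[Fact] = []
    channel_map: dict[str, str] = {}
    for ch in CHANNELS:
        f = Fact(_new_guid(rng), ch, default_fact_value, "input")
        channel_map[ch] = f.guid
        facts.append(f)
    rules: list[Rule] = []
    mid_guids: list[str] = []
    for (pair, mid_name) in _DESIGN_PAIRS[design_id]:
        mid = Fact(_new_guid(rng), mid_name, default_fact_value, "intermediate")
        facts.append(mid)
        mid_guids.append(mid.guid)
        rules.append(
            Rule(
                _new_guid(rng),
                (channel_map[pair[0]], channel_map[pair[1]]),
                [0.5, 0.5],
                mid.guid,
            )
        )
    out = Fact(_new_guid(rng), "output", default_fact_value, "output")
    facts.append(out)
    rules.append(Rule(_new_guid(rng), tuple(mid_guids), [0.5, 0.5], out.guid))
    return RuleFactNetwork(
        facts,
        rules,
        design_id=design_id,
        channel_map=channel_map,
        start_fact_guid=channel_map["blood_pressure"],
        output_fact_guid=out.guid,
    )
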