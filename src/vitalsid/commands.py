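"""Textual SF/TR/PR command protocol for rule-fact networks.

Grammar (one command per line, UTF-8):

    SF:{<guid>}=DDD.DDD                 set a fact to a value
    TR:{<start>}:{<end>}=DDD.DDD        one training step; the value is
                                        assigned to the start fact
    PR:{<start>}:{<end>}=DDD.DDD        evaluate; the value is assigned to
                                        the start fact

GUIDs are 32 hex characters in 8-4-4-4-12 grouping.  Values are fixed-point
with three integer and three fractional digits (e.g. ``000.393``); the
engine only ever emits values in [0, 1].  The training target value and
velocity are properties of the replay session (:class:`TrainingParams`), not
of the command line, so a script plus its parameters fully determines the
resulting network state.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

from .network import RuleFactNetwork, TrainingParams

__all__ = [
    "Command",
    "parse_command",
    "format_command",
    "format_value",
    "quantize",
    "replay_script",
]

_GUID_RE = r"[0-9a-f]{8}-[0-9a-f]{4}-[0-9a-f]{4}-[0-9a-f]{4}-[0-9a-f]{12}"
_VALUE_RE = r"\d{3}\.\d{3}"
_SF_RE = re.compile(rf"^SF:\{{({_GUID_RE})\}}=({_VALUE_RE})$")
_TRPR_RE = re.compile(
    rf"^(TR|PR):\{{({_GUID_RE})\}}:\{{({_GUID_RE})\}}=({_VALUE_RE})$"
)


class CommandParseError(ValueError):
    """Raised for malformed command lines; carries the failure position."""

    def __init__(self, message: str, line: str, position: int = 0) -> None:
        super().__init__(f"{message} at position {position}: {line!r}")
        self.line = line
        self.position = position


@dataclass(frozen=True)
class Command:
    """One parsed protocol command."""

    kind: str  # SF | TR | PR
    fact_guids: tuple[str, ...]  # (fact,) for SF; (start, end) for TR/PR
    value: float

    def __post_init__(self) -> None:
        if self.kind not in ("SF", "TR", "PR"):
            raise ValueError(f"unknown command kind {self.kind!r}")
        n = 1 if self.kind == "SF" else 2
        if len(self.fact_guids) != n:
            raise ValueError(f"{self.kind} takes {n} fact guid(s)")
        if not (0.0 <= self.value <= 999.999):
            raise ValueError("value outside the representable range")


def format_value(value: float) -> str:
    """Fixed-point ``DDD.DDD`` rendering, e.g. ``0.393 -> '000.393'``."""
    return f"{value:07.3f}"


def quantize(value: float) -> float:
    """The value a ``DDD.DDD`` round trip preserves (3-decimal precision)."""
    return float(format_value(value))


def format_command(cmd: Command) -> str:
    if cmd.kind == "SF":
        return f"SF:{{{cmd.fact_guids[0]}}}={format_value(cmd.value)}"
    g1, g2 = cmd.fact_guids
    return f"{cmd.kind}:{{{g1}}}:{{{g2}}}={format_value(cmd.value)}"


def parse_command(line: str) -> Command:
    """Parse one command line; raises :class:`CommandParseError` if malformed."""
    line = line.strip()
    if not line:
        raise CommandParseError("empty command line", line)
    m = _SF_RE.match(line)
    if m:
        return Command("SF", (m.group(1),), float(m.group(2)))
    m = _TRPR_RE.match(line)
    if m:
        return Command(m.group(1), (m.group(2), m.group(3)), float(m.group(4)))
    # Produce a position-bearing diagnostic for the common failure modes.
    kind = line.split(":", 1)[0]
    if kind not in ("SF", "TR", "PR"):
        raise CommandParseError(f"unknown command kind {kind!r}", line, 0)
    for gm in re.finditer(r"\{([^}]*)\}", line):
        if not re.fullmatch(_GUID_RE, gm.group(1)):
            raise CommandParseError("malformed GUID", line, gm.start(1))
    eq = line.find("=")
    raise CommandParseError("malformed value", line, eq + 1 if eq >= 0 else 0)


def replay_script(
    lines: Iterable[str],
    network: RuleFactNetwork,
    params: TrainingParams | None = None,
) -> list[float]:
    """Execute a command script against a network.

    Returns the outputs produced by the PR commands, in order.  Replaying the
    script a second time on a freshly built network with the same parameters
    yields bit-identical fact values and weights.
    """
    params = params or TrainingParams()
    outputs: list[float] = []
    for raw in lines:
        if not raw.strip():
            continue
        cmd = parse_command(raw)
        if cmd.kind == "SF":
            network.set_fact(cmd.fact_guids[0], cmd.value)
        elif cmd.kind == "TR":
            start, end = cmd.fact_guids
            network.train_step(start, cmd.value, end, params)
        else:  # PR
            start, end = cmd.fact_guids
            network.present(start, cmd.value)
            outputs.append(network.facts[end].value)
    return outputs


def script_for_rows(
    network: RuleFactNetwork,
    rows: Sequence[Sequence[float]],
    kind: str = "TR",
) -> list[str]:
    """Render the four-SF-plus-one-TR/PR command block for each data row.

    ``rows`` holds normalized values in the canonical channel order
    (heart rate, ETCO2, respiratory rate, blood pressure).  One of the SF
    commands (blood pressure) is vestigial, since the TR/PR command re-assigns
    the start fact; it is emitted anyway so the command block is uniform.
    """
    from .network import CHANNELS

    lines: list[str] = []
    bp_guid = network.channel_map["blood_pressure"]
    out_guid = network.output_fact_guid
    for row in rows:
        for ch, v in zip(CHANNELS, row):
            lines.append(
                format_command(Command("SF", (network.channel_map[ch],), quantize(v)))
            )
        lines.append(
            format_command(Command(kind, (bp_guid, out_guid), quantize(row[3])))
        )
    return lines
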