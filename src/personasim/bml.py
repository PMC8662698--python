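"""Serialization of scheduled behaviour to a Behavior Markup Language subset.

Each scheduled command becomes one ``<bml>`` block carrying a single
behaviour element (``gaze``, ``head``, ``face`` or ``gesture``) with
``start``/``end`` attributes in seconds from session start.  This is the
hand-off boundary to an animation engine; no rendering happens here.
"""
from __future__ import annotations

from lxml import etree

from .executive import ScheduledCommand
from .gaze import GazeEvent
from .gesture import GestureEvent

__all__ = ["command_to_bml", "commands_to_bml", "write_bml"]

_NS = "http://www.bml-initiative.org/bml/bml-1.0"


def command_to_bml(cmd: ScheduledCommand, index: int = 1) -> etree._Element:
    bml = etree.Element("bml", id=f"bml{index}", xmlns=_NS)
    start, end = cmd.scheduled_onset, cmd.end
    payload = cmd.request.payload
    if isinstance(payload, GazeEvent):
        if payload.kind == "blink":
            el = etree.SubElement(bml, "faceLexeme", lexeme="BLINK", amount="1.0")
        else:
            el = etree.SubElement(
                bml, "gaze",
                direction=payload.direction,
                eyeAmplitude=f"{payload.eye_amplitude:.2f}",
            )
            if payload.head_rotation > 0:
                etree.SubElement(
                    bml, "head",
                    rotation=f"{payload.head_rotation:.2f}",
                    speed=f"{payload.head_speed:.1f}",
                    start=f"{start:.2f}", end=f"{end:.2f}",
                )
    elif isinstance(payload, GestureEvent):
        el = etree.SubElement(
            bml, "gesture", lexeme=payload.kind.upper(),
            speed=f"{payload.speed_multiplier:.2f}",
            spacious=str(payload.spacious).lower(),
        )
    elif isinstance(payload, dict):  # face AU vector
        el = etree.SubElement(bml, "face")
        for unit, intensity in sorted(payload.items()):
            etree.SubElement(el, "faceLexeme", lexeme=f"AU{unit}",
                             amount=f"{intensity:.3f}")
    else:
        el = etree.SubElement(bml, "wait")
    el.set("id", f"b{cmd.request.id}")
    el.set("start", f"{start:.2f}")
    el.set("end", f"{end:.2f}")
    return bml


def commands_to_bml(commands: list[ScheduledCommand]) -> str:
    root = etree.Element("bmlSequence")
    for i, cmd in enumerate(commands, start=1):
        root.append(command_to_bml(cmd, i))
    return etree.tostring(root, pretty_print=True, encoding="unicode")


def write_bml(commands: list[ScheduledCommand], path) -> None:
    with open(path, "w") as fh:
        fh.write(commands_to_bml(commands))
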