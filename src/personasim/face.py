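"""Facial expression: affect to FACS action units, with personality modulation.

Valence and arousal are each quantized to five levels and looked up in a
level-pair table of action-unit (AU) activations.  Personality then
modulates the raw expression three ways: an intensity scaling
(``au_amount``), a filter that drops units whose scaled intensity falls
below a threshold (the "philtre"), and — for the low-stability
categories — transient involuntary twitches.

The shipped level-pair table is a synthetic stand-in constructed from
common smile/frown AU conventions; it is a plain TSV and fully
replaceable.
"""
from __future__ import annotations

import enum
import importlib.resources

import numpy as np

from .core import FaceParams

__all__ = [
    "VALevel",
    "quantize_va",
    "load_au_map",
    "va_to_au",
    "apply_personality_face",
    "FaceTwitcher",
]

#: equal-width quantization bins over [-1, 1]
BIN_EDGES = (-0.6, -0.2, 0.2, 0.6)

TWITCH_RATE_PER_MIN = 2.0
TWITCH_AMPLITUDE = 0.15
TWITCH_DURATION_S = 0.2


class VALevel(enum.IntEnum):
    LOW = 0
    MEDIUM_LOW = 1
    MEDIUM = 2
    MEDIUM_HIGH = 3
    HIGH = 4

    @property
    def label(self) -> str:
        return self.name.lower()


def quantize_va(value: float) -> VALevel:
    """Quantize a valence or arousal value in [-1, 1] to one of five levels."""
    if not (-1.0 <= value <= 1.0):
        raise ValueError(f"value must lie in [-1, 1], got {value}")
    for i, edge in enumerate(BIN_EDGES):
        if value < edge:
            return VALevel(i)
    return VALevel.HIGH


def load_au_map(path=None) -> dict[tuple[str, str], dict[int, float]]:
    """Load a level-pair -> AU-intensity table from TSV.

    Cells are space-separated ``AU:intensity`` pairs; ``-`` marks a
    neutral (empty) cell.
    """
    if path is None:
        text = (
            importlib.resources.files("personasim.data")
            .joinpath("au_map_synthetic.tsv")
            .read_text()
        )
    else:
        with open(path) as fh:
            text = fh.read()
    table: dict[tuple[str, str], dict[int, float]] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("valence_level"):
            continue
        v, a, cell = line.split("\t")
        aus: dict[int, float] = {}
        if cell != "-":
            for pair in cell.split():
                au, intensity = pair.split(":")
                aus[int(au)] = float(intensity)
        table[(v, a)] = aus
    return table


_DEFAULT_MAP: dict | None = None


def _default_map() -> dict:
    global _DEFAULT_MAP
    if _DEFAULT_MAP is None:
        _DEFAULT_MAP = load_au_map()
    return _DEFAULT_MAP


def va_to_au(
    valence_level: VALevel,
    arousal_level: VALevel,
    mapping: dict | None = None,
) -> dict[int, float]:
    """Look up the AU activation vector for a quantized affect pair."""
    table = mapping if mapping is not None else _default_map()
    key = (VALevel(valence_level).label, VALevel(arousal_level).label)
    if key not in table:
        raise KeyError(f"AU mapping table has no cell for {key}")
    return dict(table[key])


def apply_personality_face(
    au: dict[int, float],
    params: FaceParams,
    twitch: tuple[int, float] | None = None,
) -> dict[int, float]:
    """Scale, filter and optionally perturb an AU vector.

    Intensities are scaled by ``au_amount`` and clipped to [0, 1]; units
    whose scaled intensity falls below ``filter_threshold`` are removed.
    ``twitch`` is an (AU id, amplitude) perturbation added after
    filtering — the caller's twitch process decides when one is live.
    """
    out = {}
    for unit, intensity in au.items():
        scaled = float(np.clip(intensity * params.au_amount, 0.0, 1.0))
        if scaled >= params.filter_threshold:
            out[unit] = scaled
    if twitch is not None and params.twitch_enabled:
        unit, amplitude = twitch
        out[unit] = float(np.clip(out.get(unit, 0.0) + amplitude, 0.0, 1.0))
    return out


class FaceTwitcher:
    """Poisson process of transient AU perturbations for twitching categories."""

    TWITCHABLE_AUS = (1, 2, 4, 14, 17, 20)

    def __init__(self, params: FaceParams, rng: np.random.Generator,
                 rate_per_min: float = TWITCH_RATE_PER_MIN,
                 amplitude: float = TWITCH_AMPLITUDE,
                 duration: float = TWITCH_DURATION_S):
        self.params = params
        self.rng = rng
        self.amplitude = amplitude
        self.duration = duration
        self.rate = rate_per_min
        self._next = rng.exponential(60.0 / rate_per_min) if params.twitch_enabled else np.inf
        self._live: tuple[int, float] | None = None
        self._live_until = -np.inf
        self.count = 0

    def current(self, clock: float) -> tuple[int, float] | None:
        """The live perturbation at ``clock``, starting new ones as due."""
        if not self.params.twitch_enabled:
            return None
        while clock >= self._next:
            unit = int(self.rng.choice(self.TWITCHABLE_AUS))
            self._live = (unit, self.amplitude)
            self._live_until = self._next + self.duration
            self._next += self.rng.exponential(60.0 / self.rate)
            self.count += 1
        if self._live is not None and clock < self._live_until:
            return self._live
        return None
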