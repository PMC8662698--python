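"""Personality categories, model constants, and parameter resolution.

The behaviour model distinguishes five discrete personality categories on
the Extraversion x Emotional-Stability plane: the four corners (HELS, HEHS,
LELS, LEHS) plus a Neutral midpoint.  Every downstream controller (affect
dynamics, face, gaze, gesture) is parameterized per category by a table of
ordinal labels (high/normal/low and friends); this module resolves those
labels into numeric parameter sets from a structured config file, so the
whole parameterization is overridable without code changes.
"""
from __future__ import annotations

import copy
import enum
import importlib.resources
from dataclasses import dataclass, field, asdict
from typing import Any, Mapping

import yaml

__all__ = [
    "PersonalityCategory",
    "PersonalityProfile",
    "AffectDynamicsParams",
    "FaceParams",
    "GazeParams",
    "GestureParams",
    "category_from_traits",
    "load_config",
    "load_parameters",
]


class ConfigError(KeyError):
    """A required label or section is missing from the model config."""


class PersonalityCategory(str, enum.Enum):
    HELS = "HELS"  # high extraversion, low stability
    HEHS = "HEHS"  # high extraversion, high stability
    LELS = "LELS"  # low extraversion, low stability
    LEHS = "LEHS"  # low extraversion, high stability
    NEUTRAL = "Neutral"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


def category_from_traits(
    extraversion: float, stability: float, neutral_band: float = 0.2
) -> PersonalityCategory:
    """Map continuous trait scores in [-1, 1] to a discrete category.

    Scores within ``neutral_band`` of zero on *both* axes (inclusive at the
    band edge) map to Neutral; otherwise the quadrant decides.
    """
    if not (-1.0 <= extraversion <= 1.0 and -1.0 <= stability <= 1.0):
        raise ValueError(
            f"trait scores must lie in [-1, 1], got ({extraversion}, {stability})"
        )
    if not (0.0 < neutral_band < 1.0):
        raise ValueError(f"neutral_band must lie in (0, 1), got {neutral_band}")
    if abs(extraversion) <= neutral_band and abs(stability) <= neutral_band:
        return PersonalityCategory.NEUTRAL
    e = "H" if extraversion > 0 else "L"
    s = "H" if stability > 0 else "L"
    return PersonalityCategory(f"{e}E{s}S")


@dataclass(frozen=True)
class PersonalityProfile:
    """Continuous trait pair plus the derived discrete category."""

    extraversion: float
    stability: float
    neutral_band: float = 0.2
    category: PersonalityCategory = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "category",
            category_from_traits(self.extraversion, self.stability, self.neutral_band),
        )

    @classmethod
    def from_category(cls, category: PersonalityCategory | str) -> "PersonalityProfile":
        """Canonical profile at the centre of a category's trait region."""
        category = PersonalityCategory(category)
        corners = {
            PersonalityCategory.HELS: (0.8, -0.8),
            PersonalityCategory.HEHS: (0.8, 0.8),
            PersonalityCategory.LELS: (-0.8, -0.8),
            PersonalityCategory.LEHS: (-0.8, 0.8),
            PersonalityCategory.NEUTRAL: (0.0, 0.0),
        }
        return cls(*corners[category])


@dataclass(frozen=True)
class AffectDynamicsParams:
    """Personality-dependent constants of the valence-arousal dynamics.

    ``gain_pos``/``gain_neg`` scale the valence response to positive and
    negative triggers; ``lability`` is the intensity of spontaneous
    zero-mean valence fluctuation; ``decay_rate`` (1/s) pulls the state
    back toward its baselines.
    """

    baseline_valence: float
    baseline_arousal: float
    gain_pos: float
    gain_neg: float
    lability: float
    arousal_gain: float
    decay_rate: float

    def __post_init__(self) -> None:
        for name in ("gain_pos", "gain_neg", "lability", "arousal_gain"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.decay_rate <= 0:
            raise ValueError("decay_rate must be positive")


@dataclass(frozen=True)
class FaceParams:
    au_amount: float          # intensity scaling of activated action units
    filter_threshold: float   # AUs with scaled intensity below this are filtered out
    twitch_enabled: bool

    def __post_init__(self) -> None:
        if self.au_amount <= 0:
            raise ValueError("au_amount must be positive")
        if not (0.0 <= self.filter_threshold <= 1.0):
            raise ValueError("filter_threshold must lie in [0, 1]")


@dataclass(frozen=True)
class GazeParams:
    mutual_bias: float                       # P(idle episode is mutual gaze)
    mutual_duration_range: tuple[float, float]
    avert_duration_range: tuple[float, float]
    avert_frequency: float                   # idle re-decisions per minute
    direction_weights: dict[str, float]      # over {U, D, L, R, C}
    blink_factor: float                      # multiplier on the baseline blink rate
    head_speed: float                        # deg/s

    def __post_init__(self) -> None:
        total = sum(self.direction_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"direction weights must sum to 1, got {total}")
        if not (0.0 <= self.mutual_bias <= 1.0):
            raise ValueError("mutual_bias must lie in [0, 1]")
        if self.blink_factor <= 0:
            raise ValueError("blink_factor must be positive")


@dataclass(frozen=True)
class GestureParams:
    idle_rate: float                 # idle gesture events per minute
    lean: str                        # forward | none | backward
    posture_shift_prob: float
    self_adaptor_prob: float
    posture_shift_speed: float       # playback-rate multiplier
    self_adaptor_speed: float
    twitch_enabled: bool
    spacious: bool

    def __post_init__(self) -> None:
        if self.lean not in ("forward", "none", "backward"):
            raise ValueError(f"invalid lean {self.lean!r}")
        if abs(self.posture_shift_prob + self.self_adaptor_prob - 1.0) > 1e-9:
            raise ValueError("posture-shift and self-adaptor probabilities must sum to 1")


def _deep_merge(base: dict, override: Mapping) -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if isinstance(value, Mapping) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = copy.deepcopy(value)
    return out


def default_config() -> dict[str, Any]:
    """The shipped model constants (a fresh deep copy)."""
    text = (
        importlib.resources.files("personasim.data")
        .joinpath("default_config.yaml")
        .read_text()
    )
    return yaml.safe_load(text)


def load_config(path: str | None = None, overrides: Mapping | None = None) -> dict:
    """Load the shipped config, optionally merged with a YAML file and overrides."""
    cfg = default_config()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        cfg = _deep_merge(cfg, user)
    if overrides:
        cfg = _deep_merge(cfg, overrides)
    return cfg


def _ordinal(config: dict, table: str, label: Any) -> Any:
    try:
        return config["ordinal"][table][label]
    except KeyError as exc:
        raise ConfigError(f"no numeric value for ordinal label {label!r} in {table!r}") from exc


def _row(config: dict, section: str, category: PersonalityCategory) -> dict:
    try:
        return config[section][category.value]
    except KeyError as exc:
        raise ConfigError(f"config section {section!r} has no row for {category}") from exc


def load_parameters(
    category: PersonalityCategory | str, config: dict | None = None
) -> tuple[AffectDynamicsParams, FaceParams, GazeParams, GestureParams]:
    """Resolve the per-category ordinal tables into numeric parameter sets."""
    category = PersonalityCategory(category)
    cfg = config if config is not None else default_config()

    a = _row(cfg, "affect", category)
    affect = AffectDynamicsParams(
        baseline_valence=_ordinal(cfg, "baseline", a["baseline_valence"]),
        baseline_arousal=_ordinal(cfg, "baseline", a["baseline_arousal"]),
        gain_pos=_ordinal(cfg, "gain", a["gain_pos"]),
        gain_neg=_ordinal(cfg, "gain", a["gain_neg"]),
        lability=_ordinal(cfg, "lability", a["lability"]),
        arousal_gain=_ordinal(cfg, "gain", a["arousal_gain"]),
        decay_rate=cfg["emotion_options"]["decay_rate"],
    )

    f = _row(cfg, "face", category)
    face = FaceParams(
        au_amount=_ordinal(cfg, "au_amount", f["au_amount"]),
        filter_threshold=_ordinal(cfg, "filter_threshold", f["filter_threshold"]),
        twitch_enabled=bool(f["twitch"]),
    )

    g = _row(cfg, "gaze", category)
    directions = list(g["directions"])
    weights = {d: (1.0 / len(directions) if d in directions else 0.0)
               for d in ("U", "D", "L", "R", "C")}
    gaze = GazeParams(
        mutual_bias=_ordinal(cfg, "mutual_bias", g["mutual_bias"]),
        mutual_duration_range=tuple(_ordinal(cfg, "duration_range", g["mutual_duration"])),
        avert_duration_range=tuple(_ordinal(cfg, "duration_range", g["avert_duration"])),
        avert_frequency=_ordinal(cfg, "avert_frequency", g["avert_frequency"]),
        direction_weights=weights,
        blink_factor=_ordinal(cfg, "blink_factor", g["blink_factor"]),
        head_speed=_ordinal(cfg, "head_speed", g["head_speed"]),
    )

    ge = _row(cfg, "gesture", category)
    twitch = bool(ge["twitch"])
    if cfg.get("gesture_options", {}).get("table_literal_twitches") and category is PersonalityCategory.LEHS:
        twitch = True
    p_shift = float(ge["posture_shift_prob"])
    gesture = GestureParams(
        idle_rate=_ordinal(cfg, "idle_rate", ge["idle_rate"]),
        lean=str(ge["lean"]),
        posture_shift_prob=p_shift,
        self_adaptor_prob=1.0 - p_shift,
        posture_shift_speed=_ordinal(cfg, "speed_multiplier", ge["posture_shift_speed"]),
        self_adaptor_speed=_ordinal(cfg, "speed_multiplier", ge["self_adaptor_speed"]),
        twitch_enabled=twitch,
        spacious=bool(ge["spacious"]),
    )
    return affect, face, gaze, gesture


def params_to_dict(params) -> dict:
    """Serialize any parameter dataclass to plain builtins (round-trip safe)."""
    return asdict(params)
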