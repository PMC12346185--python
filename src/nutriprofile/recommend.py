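"""Two-level dietary recommendation engine.

Level 1 compares weekly portions of five animal-protein food groups to
reference portions and routes to M1 (below reference: encourage more fish
and poultry, with profile-specific food options), M2 (at reference:
maintain) or M3 (above reference: reduce red and processed meat, with
profile-specific options).

Level 2 acts on the six target nutrients.  Users at or below the risk
threshold (predicted CVD probability P <= 0.41 by default) receive a
single reassurance message (M4).  Above the threshold, each nutrient is
compared to its per-profile optimal range [min_val, max_val]: below range
-> M5 with an increase, within -> M6, above -> M7 with a decrease.  The
adjusted intake moves toward the range by the magnitude of the published
required change |delta_n|, clamped so it never overshoots past the
violated bound:

    I' = I + |delta_n|  if P > threshold and I < min_val
    I' = I - |delta_n|  if P > threshold and I > max_val
    I' = I              otherwise

The published delta_n values are negative (every profile must reduce
intake to reduce risk); applying the magnitude toward the range is the
only reading under which both branches move the intake into the optimal
interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import yaml

from .limits import NutrientParams, ParamsTable, packaged_params

DEFAULT_THRESHOLD = 0.41

PROFILE_VARIANT = {"health_conscious": "HC", "omnivore": "O", "sweet_tooth": "ST"}


def _load_yaml(name: str) -> dict:
    with resources.files("nutriprofile.data").joinpath(name).open() as fh:
        return yaml.safe_load(fh)


def load_messages() -> dict:
    return _load_yaml("messages.yaml")


def load_portion_references() -> dict[str, dict]:
    """Reference weekly portions per food group."""
    return _load_yaml("portions.yaml")["references"]


@dataclass
class UserState:
    """Inputs the engine needs for one user."""

    profile: str
    p_cvd: float | None = None
    intakes: dict[str, float] = field(default_factory=dict)
    portions: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.p_cvd is not None and not 0.0 <= self.p_cvd <= 1.0:
            raise ValueError("p_cvd must be a probability")
        if any(v < 0 for v in self.portions.values()):
            raise ValueError("portions must be non-negative")


@dataclass
class Level1Message:
    food_group: str
    message_id: str          # M1 | M2 | M3
    profile_variant: str     # HC | O | ST
    text: str


@dataclass
class Level2Message:
    nutrient: str
    message_id: str          # M4 | M5 | M6 | M7
    adjusted_intake: float | None
    delta_applied: float     # adjusted - reported (0 when no rule fired)
    text: str


@dataclass
class AdviceBundle:
    level1: list[Level1Message] = field(default_factory=list)
    level2: list[Level2Message] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Level 2: nutrient adjustment and routing
# ---------------------------------------------------------------------------

def adjust_intake(user: UserState, params: NutrientParams,
                  threshold: float = DEFAULT_THRESHOLD) -> tuple[float, str | None]:
    """Apply the adjustment rule to one nutrient.

    Returns (adjusted intake, rule fired) where the rule is "increase",
    "decrease" or None.  Fires only when P > threshold and the intake lies
    outside [min_val, max_val]; the step is |delta_n| toward the range,
    clamped at the violated bound so the advice never creates the opposite
    violation.
    """
    nutrient = params.nutrient
    if nutrient not in user.intakes:
        raise KeyError(f"user has no intake recorded for '{nutrient}'")
    intake = float(user.intakes[nutrient])
    if user.p_cvd is None:
        raise ValueError("p_cvd is required for level-2 adjustment")
    if user.p_cvd <= threshold:
        return intake, None
    step = abs(params.delta_n)
    if intake < params.min_val:
        adjusted = intake + step
        if adjusted > params.max_val:      # step crosses the whole range
            adjusted = params.min_val      # settle at the violated bound
        return adjusted, "increase"
    if intake > params.max_val:
        adjusted = intake - step
        if adjusted < params.min_val:
            adjusted = params.max_val
        return adjusted, "decrease"
    return intake, None


def route_level2(user: UserState, params_table: ParamsTable | None = None,
                 threshold: float = DEFAULT_THRESHOLD,
                 messages: dict | None = None) -> tuple[list[Level2Message], list[str]]:
    """Route level-2 messages M4-M7 for every nutrient with parameters.

    P <= threshold yields the single low-risk message M4 (the inequality
    in the adjustment rule is strict, so P equal to the threshold counts
    as low risk).  Above it, each nutrient maps to exactly one of M5
    (below range), M6 (within) or M7 (above); nutrients missing from the
    user's intakes are skipped with a warning.
    """
    if user.p_cvd is None:
        raise ValueError("p_cvd must be computed before level-2 advice")
    params_table = params_table or packaged_params()
    messages = messages or load_messages()
    texts = messages["level2"]
    out: list[Level2Message] = []
    warns: list[str] = []
    if user.p_cvd <= threshold:
        return [Level2Message(nutrient="", message_id="M4", adjusted_intake=None,
                              delta_applied=0.0, text=texts["M4"]["text"])], warns
    for nutrient in params_table.nutrients():
        try:
            params = params_table.lookup(user.profile, nutrient)
        except KeyError:
            continue
        if nutrient not in user.intakes or user.intakes[nutrient] is None:
            warns.append(f"intake for '{nutrient}' missing; nutrient skipped")
            continue
        intake = float(user.intakes[nutrient])
        adjusted, rule = adjust_intake(user, params, threshold)
        if rule == "increase":
            mid = "M5"
        elif rule == "decrease":
            mid = "M7"
        else:
            mid = "M6"
        text = texts[mid]["text"].format(nutrient=nutrient, target=round(adjusted, 2),
                                         units=params.units)
        out.append(Level2Message(nutrient=nutrient, message_id=mid,
                                 adjusted_intake=adjusted,
                                 delta_applied=adjusted - intake, text=text))
    return out, warns


# ---------------------------------------------------------------------------
# Level 1: portion routing
# ---------------------------------------------------------------------------

def route_level1(user: UserState, references: dict[str, dict] | None = None,
                 messages: dict | None = None) -> tuple[list[Level1Message], list[str]]:
    """Route level-1 messages M1-M3 per food group.

    Portion below its reference -> M1 with the user's profile variant
    (zero animal-protein portions — e.g. vegetarian users — also land
    here; the M1 text includes plant-based options); above -> M3; exactly
    at the reference -> M2 maintenance.
    """
    references = references or load_portion_references()
    messages = messages or load_messages()
    texts = messages["level1"]
    variant = PROFILE_VARIANT[user.profile]
    out: list[Level1Message] = []
    warns: list[str] = []
    if not user.portions:
        warns.append("no portion entries supplied; level-1 advice is empty")
        return out, warns
    for food_group, portion in user.portions.items():
        if portion < 0:
            raise ValueError(f"negative portion for '{food_group}'")
        if food_group not in references:
            warns.append(f"no portion reference for '{food_group}'; skipped")
            continue
        ref = float(references[food_group]["portions_per_week"])
        if portion < ref:
            mid = "M1"
        elif portion > ref:
            mid = "M3"
        else:
            mid = "M2"
        text = texts[mid][user.profile].format(food_group=food_group.replace("_", " "))
        out.append(Level1Message(food_group=food_group, message_id=mid,
                                 profile_variant=variant, text=text))
    return out, warns


# ---------------------------------------------------------------------------
# Composition
# ---------------------------------------------------------------------------

def compose_advice(user: UserState, params_table: ParamsTable | None = None,
                   references: dict | None = None, level: str = "both",
                   threshold: float = DEFAULT_THRESHOLD) -> AdviceBundle:
    """Build the advice bundle for the requested level(s).

    Levels are independent: level 2 does not require level-1 inputs and
    vice versa.  Requesting level 2 without a computed CVD probability is
    an error instructing the caller to run the risk model first.
    """
    if level not in ("1", "2", "both", 1, 2):
        raise ValueError("level must be '1', '2' or 'both'")
    level = str(level)
    bundle = AdviceBundle()
    if level in ("1", "both"):
        msgs, warns = route_level1(user, references)
        bundle.level1 = msgs
        bundle.warnings += warns
    if level in ("2", "both"):
        if user.p_cvd is None:
            raise ValueError("level-2 advice requires a CVD probability; "
                             "run the risk model first")
        msgs, warns = route_level2(user, params_table, threshold)
        bundle.level2 = msgs
        bundle.warnings += warns
    return bundle


def bundle_to_dict(bundle: AdviceBundle) -> dict:
    return {
        "level1": [vars(m) for m in bundle.level1],
        "level2": [vars(m) for m in bundle.level2],
        "warnings": list(bundle.warnings),
    }


def render_text(bundle: AdviceBundle) -> str:
    lines = []
    for m in bundle.level1:
        lines.append(f"[{m.message_id}-{m.profile_variant}] {m.food_group}: {m.text}")
    for m in bundle.level2:
        tag = m.message_id if not m.nutrient else f"{m.message_id} {m.nutrient}"
        lines.append(f"[{tag}] {m.text}")
    for w in bundle.warnings:
        lines.append(f"(warning) {w}")
    return "\n".join(lines)
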