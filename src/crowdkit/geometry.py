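"""Units, spacing conventions, and task arithmetic for crowding experiments.

Everything spatial is expressed in degrees of visual angle, and every
logarithm in this package is base 10. Target-flanker separation can be
stated in three conventions found across the crowding literature:

``center_to_center``
    distance between target and flanker centers (canonical here — the
    critical spacing is best understood as an integration zone anchored
    at stimulus centers);
``edge_to_edge``
    empty gap between nearest contours; differs from center-to-center by
    exactly one letter size;
``nominal_multiple``
    unitless separation in multiples of the letter size, the convention
    of flanked-acuity (clinical chart-like) paradigms.

Unflanked (isolated-target) conditions are represented by the reserved
sentinel :data:`UNFLANKED` (``math.inf``), mirroring the "infinity"
abscissa point on crowding-function plots.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

from scipy.special import ndtr, ndtri

__all__ = [
    "UNFLANKED",
    "SpacingConvention",
    "SpacingValue",
    "TaskSpec",
    "CriterionSpec",
    "CriterionUnattainableError",
    "slots_to_edge_gap",
    "center_to_center",
    "nominal_to_absolute",
    "absolute_to_nominal",
    "criterion_level",
    "convert_guess_rate",
    "correct_for_guessing",
    "bouma_fraction",
]

#: Sentinel spacing for unflanked (isolated target) conditions.
UNFLANKED: float = math.inf


class CriterionUnattainableError(ValueError):
    """Raised when a criterion maps outside the attainable (guess, asymptote] range."""


class SpacingConvention(str, Enum):
    CENTER_TO_CENTER = "center_to_center"
    EDGE_TO_EDGE = "edge_to_edge"
    NOMINAL_MULTIPLE = "nominal_multiple"


@dataclass(frozen=True)
class SpacingValue:
    """A target-flanker separation in one of the three field conventions.

    Parameters
    ----------
    value : float
        Separation; degrees for the two absolute conventions, unitless
        for ``nominal_multiple``. ``math.inf`` denotes unflanked.
    convention : SpacingConvention
    letter_size : float, optional
        Letter size in degrees; required to convert edge or nominal
        values to center-to-center.
    """

    value: float
    convention: SpacingConvention = SpacingConvention.CENTER_TO_CENTER
    letter_size: float | None = None

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError(f"spacing must be nonnegative, got {self.value}")
        if self.letter_size is not None and self.letter_size < 0:
            raise ValueError("letter_size must be nonnegative")

    @property
    def is_unflanked(self) -> bool:
        return math.isinf(self.value)

    def to_center_to_center(self) -> float:
        """Express this spacing as center-to-center degrees."""
        if self.is_unflanked:
            return UNFLANKED
        conv = SpacingConvention(self.convention)
        if conv is SpacingConvention.CENTER_TO_CENTER:
            return self.value
        if self.letter_size is None:
            raise ValueError(f"letter_size required to convert from {conv.value}")
        if conv is SpacingConvention.EDGE_TO_EDGE:
            return center_to_center(self.value, self.letter_size)
        return nominal_to_absolute(self.value, self.letter_size)


@dataclass(frozen=True)
class TaskSpec:
    """An n-alternative forced-choice identification task.

    The guess rate g = 1/n_alternatives is the floor of every
    psychometric function for the task (e.g. 1/25 for Bouma's lowercase
    letter set, 1/4 for a four-orientation tumbling-E task).
    """

    n_alternatives: int

    def __post_init__(self) -> None:
        if int(self.n_alternatives) != self.n_alternatives or self.n_alternatives < 2:
            raise ValueError("n_alternatives must be an integer >= 2")

    @property
    def guess_rate(self) -> float:
        return 1.0 / self.n_alternatives


@dataclass(frozen=True)
class CriterionSpec:
    """Rule mapping a fitted crowding function to a raw performance level.

    families
    --------
    absolute
        ``level`` is the raw proportion correct itself.
    proportion_of_asymptote
        level q in (0, 1): raw level = g + q (A - g), a proportion of
        the guessing-corrected amplitude above chance.
    amplitude_fraction_drop
        level f in (0, 1): raw level = A - f (A - g), a drop of a
        fraction f of the guessing-corrected amplitude (f = 1/e is the
        classic Tripathy & Cavanagh style criterion).
    z_drop
        level in z units: the guessing-corrected asymptote is mapped
        through the probit, lowered by ``level`` z units, and mapped
        back to a raw proportion.
    """

    family: str
    level: float

    _FAMILIES = ("absolute", "proportion_of_asymptote", "amplitude_fraction_drop", "z_drop")

    def __post_init__(self) -> None:
        if self.family not in self._FAMILIES:
            raise ValueError(f"unknown criterion family {self.family!r}; expected one of {self._FAMILIES}")
        if self.family in ("proportion_of_asymptote", "amplitude_fraction_drop"):
            if not 0.0 < self.level < 1.0:
                raise ValueError(f"{self.family} level must lie in (0, 1), got {self.level}")
        elif self.family == "absolute":
            if not 0.0 < self.level < 1.0:
                raise ValueError(f"absolute level must lie in (0, 1), got {self.level}")
        elif self.level <= 0:
            raise ValueError("z_drop level must be positive")


def slots_to_edge_gap(n_slots: float, slot_deg: float) -> float:
    """Edge-to-edge gap for ``n_slots`` empty letter slots of width ``slot_deg``.

    Bouma expressed flanker separation in multiples of empty letter
    slots; the edge gap is simply the slot count times the slot width
    (0.29 degrees in his geometry).
    """
    if n_slots < 0:
        raise ValueError("n_slots must be nonnegative")
    if slot_deg <= 0:
        raise ValueError("slot_deg must be positive")
    return n_slots * slot_deg


def center_to_center(edge_gap: float, letter_size: float) -> float:
    """Convert an edge-to-edge gap to center-to-center spacing (degrees)."""
    if edge_gap < 0 or letter_size < 0:
        raise ValueError("edge_gap and letter_size must be nonnegative")
    return edge_gap + letter_size


def nominal_to_absolute(m: float, letter_size: float) -> float:
    """Center-to-center spacing for a nominal multiple ``m`` of ``letter_size``."""
    if m <= 0 or letter_size <= 0:
        raise ValueError("nominal multiple and letter_size must be positive")
    if math.isinf(m):
        return UNFLANKED
    return m * letter_size


def absolute_to_nominal(spacing: float, letter_size: float) -> float:
    """Inverse of :func:`nominal_to_absolute`."""
    if spacing <= 0 or letter_size <= 0:
        raise ValueError("spacing and letter_size must be positive")
    if math.isinf(spacing):
        return UNFLANKED
    return spacing / letter_size


def criterion_level(spec: CriterionSpec, guess_rate: float, asymptote: float) -> float:
    """Raw proportion-correct level at which a criterion reads off critical spacing.

    Parameters
    ----------
    spec : CriterionSpec
    guess_rate : float
        Chance performance g of the task.
    asymptote : float
        Upper asymptote A of the fitted or modelled crowding function.

    Returns
    -------
    float
        Raw proportion correct in (guess_rate, asymptote].

    Raises
    ------
    CriterionUnattainableError
        If the resulting level falls outside (guess_rate, asymptote].
    """
    if not guess_rate < asymptote <= 1.0:
        raise ValueError(f"need guess_rate < asymptote <= 1, got g={guess_rate}, A={asymptote}")
    amplitude = asymptote - guess_rate
    if spec.family == "absolute":
        level = spec.level
    elif spec.family == "proportion_of_asymptote":
        level = guess_rate + spec.level * amplitude
    elif spec.family == "amplitude_fraction_drop":
        level = asymptote - spec.level * amplitude
    else:  # z_drop
        z_asym = ndtri(correct_for_guessing(asymptote, guess_rate, clip=True))
        level = guess_rate + (1.0 - guess_rate) * float(ndtr(z_asym - spec.level))
    if not guess_rate < level <= asymptote:
        raise CriterionUnattainableError(
            f"criterion {spec.family}={spec.level} maps to raw level {level:.4f}, "
            f"outside attainable range ({guess_rate:.4f}, {asymptote:.4f}]"
        )
    return level


def correct_for_guessing(p: float, guess_rate: float, clip: bool = False, eps: float = 1e-6) -> float:
    """High-threshold guessing correction (p - g) / (1 - g)."""
    corrected = (p - guess_rate) / (1.0 - guess_rate)
    if clip:
        return min(max(corrected, eps), 1.0 - eps)
    if corrected < 0:
        raise ValueError(f"proportion {p} is below the chance level {guess_rate}")
    return corrected


def convert_guess_rate(p: float, from_task: TaskSpec, to_task: TaskSpec) -> float:
    """Re-express a proportion correct under a task with a different guess rate.

    The guessing-corrected proportion (p - g1)/(1 - g1) is preserved, so
    chance maps to chance and 1 maps to 1. Used to overlay studies with
    different numbers of response alternatives (e.g. 26-letter vs
    4-orientation tasks) on one performance scale.
    """
    g1 = from_task.guess_rate
    g2 = to_task.guess_rate
    if p > 1.0:
        raise ValueError("proportion correct cannot exceed 1")
    corrected = correct_for_guessing(p, g1)
    return g2 + (1.0 - g2) * corrected


def bouma_fraction(critical_spacing: float, eccentricity: float) -> float:
    """Ratio of critical spacing to eccentricity (undefined at the fovea)."""
    if eccentricity <= 0:
        raise ValueError("Bouma fraction is undefined at eccentricity <= 0")
    if critical_spacing < 0:
        raise ValueError("critical spacing must be nonnegative")
    return critical_spacing / eccentricity
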