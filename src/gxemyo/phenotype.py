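"""Refractive-error phenotyping.

Turns per-eye autorefractor readings (sphere, cylinder, in diopters) into the
spherical-equivalent (SE) phenotype used throughout the analysis, assigns each
subject one of seven refraction categories, applies clinical-history exclusion
rules, and maps SE onto case/control status for the myopia analyses.

Conventions
-----------
* SE = sphere + cylinder / 2.
* The seven categories partition the real line; each boundary belongs to the
  more myopic bin on the negative side (−6 is high myopia, −3 moderate,
  −0.75 low myopia) and to the more hyperopic bin on the positive side
  (0.75 is low hyperopia, 3 medium, 6 high).
* Cases are moderate-to-high myopes (SE ≤ −3 D). Controls are either
  moderate-to-high hyperopes (SE ≥ +3 D, the primary scheme) or emmetropes
  (−0.75 < SE < 0.75 D, the sensitivity scheme).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .exceptions import ConfigError, InvalidMeasurementError

HIGH_MYOPIA = "high_myopia"
MODERATE_MYOPIA = "moderate_myopia"
LOW_MYOPIA = "low_myopia"
EMMETROPIA = "emmetropia"
LOW_HYPEROPIA = "low_hyperopia"
MEDIUM_HYPEROPIA = "medium_hyperopia"
HIGH_HYPEROPIA = "high_hyperopia"

#: Refraction categories ordered from most myopic to most hyperopic.
CATEGORIES = (
    HIGH_MYOPIA,
    MODERATE_MYOPIA,
    LOW_MYOPIA,
    EMMETROPIA,
    LOW_HYPEROPIA,
    MEDIUM_HYPEROPIA,
    HIGH_HYPEROPIA,
)

#: Closed vocabulary of exclusion flags, in priority order: the first flag
#: present is reported as the exclusion reason.
EXCLUSION_FLAGS = (
    "cataract_surgery_no_prior_refraction",
    "laser_refractive_no_prior_refraction",
    "other_iop_procedure",
    "keratoconus",
    "syndrome",
)


@dataclass(frozen=True)
class EyeRefraction:
    """A single eye's refraction measurement; ``available=False`` means the
    eye was not measured and sphere/cylinder are absent."""

    sphere: float | None = None
    cylinder: float | None = None
    available: bool = True

    def __post_init__(self):
        if self.available:
            if self.sphere is None or self.cylinder is None:
                raise InvalidMeasurementError("available eye requires sphere and cylinder")
        elif self.sphere is not None or self.cylinder is not None:
            raise InvalidMeasurementError("unavailable eye must not carry measurements")

    @classmethod
    def from_values(cls, sphere: float | None, cylinder: float | None) -> "EyeRefraction":
        """Build from raw cells: a missing sphere marks the eye unavailable;
        a missing cylinder with a measured sphere is read as cylinder 0."""
        if sphere is None or (isinstance(sphere, float) and math.isnan(sphere)):
            return cls(available=False)
        if cylinder is None or (isinstance(cylinder, float) and math.isnan(cylinder)):
            cylinder = 0.0
        return cls(sphere=float(sphere), cylinder=float(cylinder))

    @property
    def spherical_equivalent(self) -> float | None:
        if not self.available:
            return None
        return spherical_equivalent(self.sphere, self.cylinder)


def spherical_equivalent(
    sphere: float,
    cylinder: float,
    *,
    max_sphere: float | None = None,
    max_cylinder: float | None = None,
) -> float:
    """Spherical equivalent SE = sphere + cylinder/2, in diopters.

    Optional ``max_sphere`` / ``max_cylinder`` enable sanity bounds on the
    absolute values (off by default; intended only as a guard against
    corrupted input files).
    """
    sphere = float(sphere)
    cylinder = float(cylinder)
    if not (math.isfinite(sphere) and math.isfinite(cylinder)):
        raise InvalidMeasurementError("sphere and cylinder must be finite")
    if max_sphere is not None and abs(sphere) > max_sphere:
        raise InvalidMeasurementError(f"|sphere| = {abs(sphere)} exceeds bound {max_sphere}")
    if max_cylinder is not None and abs(cylinder) > max_cylinder:
        raise InvalidMeasurementError(f"|cylinder| = {abs(cylinder)} exceeds bound {max_cylinder}")
    return sphere + cylinder / 2.0


def mean_se(right: EyeRefraction, left: EyeRefraction) -> float | None:
    """Per-subject SE: the mean of the two eyes' SEs; the single available
    eye's SE when the other is missing; ``None`` when both are missing."""
    se_r = right.spherical_equivalent
    se_l = left.spherical_equivalent
    if se_r is None and se_l is None:
        return None
    if se_r is None:
        return se_l
    if se_l is None:
        return se_r
    return (se_r + se_l) / 2.0


def classify_refraction(se_mean):
    """Map SE (diopters) onto the seven-category refraction scale.

    Accepts a scalar or array; returns a string or an object array of
    strings.  Bins: high myopia (≤−6], moderate myopia (−6,−3], low myopia
    (−3,−0.75], emmetropia (−0.75,0.75), low hyperopia [0.75,3), medium
    hyperopia [3,6), high hyperopia [6,∞).
    """
    arr = np.asarray(se_mean, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise InvalidMeasurementError("spherical equivalent must be finite")
    conditions = [
        arr <= -6.0,
        arr <= -3.0,
        arr <= -0.75,
        arr < 0.75,
        arr < 3.0,
        arr < 6.0,
    ]
    labels = CATEGORIES[:-1]
    out = np.select(conditions, labels, default=HIGH_HYPEROPIA)
    if arr.ndim == 0:
        return str(out[()])
    return out.astype(object)


def apply_exclusions(flags) -> tuple[bool, str | None]:
    """Decide exclusion from a set of clinical-history flags.

    ``flags`` is any iterable of strings drawn from :data:`EXCLUSION_FLAGS`;
    an unknown flag raises :class:`ConfigError`.  Returns ``(excluded,
    reason)`` where the reason is the first matching flag in vocabulary
    order, or ``None``.
    """
    flagset = set(flags)
    unknown = flagset.difference(EXCLUSION_FLAGS)
    if unknown:
        raise ConfigError(f"unknown exclusion flag(s): {sorted(unknown)}")
    for flag in EXCLUSION_FLAGS:
        if flag in flagset:
            return True, flag
    return False, None


@dataclass(frozen=True)
class CaseControlScheme:
    """Case and control definitions on the SE scale.

    Cases are always SE ≤ ``case_max``.  Controls fall in
    ``control_interval`` = (low, high) with per-end closedness given by
    ``control_closed``.  The two intervals must be disjoint.
    """

    name: str
    case_max: float = -3.0
    control_interval: tuple[float, float] = (3.0, math.inf)
    control_closed: tuple[bool, bool] = (True, False)

    def __post_init__(self):
        lo = self.control_interval[0]
        if lo < self.case_max or (lo == self.case_max and self.control_closed[0]):
            raise ConfigError("case and control intervals overlap")


HYPEROPIA_CONTROL = CaseControlScheme(
    name="hyperopia_control",
    control_interval=(3.0, math.inf),
    control_closed=(True, False),
)

EMMETROPIA_CONTROL = CaseControlScheme(
    name="emmetropia_control",
    control_interval=(-0.75, 0.75),
    control_closed=(False, False),
)

_SCHEMES = {s.name: s for s in (HYPEROPIA_CONTROL, EMMETROPIA_CONTROL)}
_SCHEMES["hyperopia"] = HYPEROPIA_CONTROL
_SCHEMES["emmetropia"] = EMMETROPIA_CONTROL


def scheme_from_name(name: str) -> CaseControlScheme:
    try:
        return _SCHEMES[name]
    except KeyError:
        raise ConfigError(
            f"unknown case/control scheme {name!r}; choose from {sorted(set(_SCHEMES))}"
        ) from None


def assign_case_control(se_mean, scheme: CaseControlScheme):
    """Assign ``case`` / ``control`` / ``neither`` status from SE.

    Vectorized: scalar in, string out; array in, object array out.
    """
    arr = np.asarray(se_mean, dtype=float)
    is_case = arr <= scheme.case_max
    lo, hi = scheme.control_interval
    lo_ok = arr >= lo if scheme.control_closed[0] else arr > lo
    hi_ok = arr <= hi if scheme.control_closed[1] else arr < hi
    is_control = lo_ok & hi_ok & ~is_case
    out = np.where(is_case, "case", np.where(is_control, "control", "neither"))
    if arr.ndim == 0:
        return str(out[()])
    return out.astype(object)
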