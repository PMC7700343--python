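"""Percentile mannequins: stature quantiles and proportional segment lengths.

Stature within each sex is modelled as normally distributed, so the p-th
percentile mannequin has stature ``mean + z(p) * sd``.  Landmark heights
(shoulder, eye) and arm-segment lengths are fixed fractions of stature,
in the spirit of the classic stature-proportion diagrams used throughout
occupational biomechanics.  The bundled default population is synthetic
and illustrative - the anthropometric surveys behind commercial DHM
population databases are not public - but any population can be supplied
as mean/SD per sex plus a coefficient map.

A "combined" 50th-percentile individual is defined as the median of the
50/50 male/female stature mixture, solved numerically from the mixture CDF.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Mapping

from scipy import optimize, stats

#: Landmark/segment keys every population must define, as fractions of stature.
REQUIRED_COEFFICIENTS = (
    "shoulder_height",
    "eye_height",
    "upper_arm_length",
    "forearm_length",
    "hand_length",
)


class Sex(str, enum.Enum):
    FEMALE = "female"
    MALE = "male"
    COMBINED = "combined"


class PopulationError(ValueError):
    """Inconsistent or incomplete population specification."""


@dataclass(frozen=True)
class Population:
    """A (two-sex) population: stature distribution plus proportion coefficients.

    Parameters
    ----------
    name:
        Free-text identifier, echoed into reports.
    stature_mean_mm, stature_sd_mm:
        Per-sex normal stature parameters in millimetres, keyed by
        ``"female"`` / ``"male"``.
    proportion_coefficients:
        Dimensionless fractions of stature for each landmark in
        :data:`REQUIRED_COEFFICIENTS`.
    """

    name: str
    stature_mean_mm: Mapping[str, float]
    stature_sd_mm: Mapping[str, float]
    proportion_coefficients: Mapping[str, float]

    def __post_init__(self) -> None:
        for sex, sd in self.stature_sd_mm.items():
            if sd <= 0:
                raise PopulationError(f"stature SD for {sex!r} must be > 0, got {sd}")
        missing = set(REQUIRED_COEFFICIENTS) - set(self.proportion_coefficients)
        if missing:
            raise PopulationError(f"missing proportion coefficients: {sorted(missing)}")
        coeff = self.proportion_coefficients
        for key, c in coeff.items():
            if not 0 < c < 1:
                raise PopulationError(f"coefficient {key!r} must be in (0, 1), got {c}")
        if not coeff["shoulder_height"] < coeff["eye_height"]:
            raise PopulationError("shoulder_height coefficient must be below eye_height")

    def _params(self, sex: Sex) -> tuple[float, float]:
        try:
            return float(self.stature_mean_mm[sex.value]), float(self.stature_sd_mm[sex.value])
        except KeyError:
            raise PopulationError(
                f"population {self.name!r} does not define sex {sex.value!r}"
            ) from None

    def stature_at(self, sex: Sex | str, percentile: float) -> float:
        """Stature (mm) at a percentile, per sex or for the 50/50 mixture."""
        sex = Sex(sex)
        if not 0 < percentile < 100:
            raise PopulationError(f"percentile must be in (0, 100), got {percentile}")
        q = percentile / 100.0
        if sex is not Sex.COMBINED:
            mean, sd = self._params(sex)
            return float(stats.norm.ppf(q, loc=mean, scale=sd))
        mf, sf = self._params(Sex.FEMALE)
        mm, sm = self._params(Sex.MALE)

        def cdf(x: float) -> float:
            return 0.5 * stats.norm.cdf(x, mf, sf) + 0.5 * stats.norm.cdf(x, mm, sm)

        lo = min(mf, mm) - 8 * max(sf, sm)
        hi = max(mf, mm) + 8 * max(sf, sm)
        return float(optimize.brentq(lambda x: cdf(x) - q, lo, hi, xtol=1e-6))

    def percentile_of(self, sex: Sex | str, stature_mm: float) -> float:
        """Inverse of :meth:`stature_at` (per-sex only)."""
        sex = Sex(sex)
        if sex is Sex.COMBINED:
            mf, sf = self._params(Sex.FEMALE)
            mm, sm = self._params(Sex.MALE)
            q = 0.5 * stats.norm.cdf(stature_mm, mf, sf) + 0.5 * stats.norm.cdf(stature_mm, mm, sm)
            return 100.0 * float(q)
        mean, sd = self._params(sex)
        return 100.0 * float(stats.norm.cdf(stature_mm, loc=mean, scale=sd))


@dataclass(frozen=True)
class Mannequin:
    """A digital human model reduced to the lengths the planar arm chain needs."""

    sex: Sex
    percentile: float
    stature: float
    shoulder_height: float
    eye_height: float
    upper_arm: float
    forearm: float
    hand: float

    @property
    def label(self) -> str:
        return f"{self.sex.value}_p{self.percentile:g}"

    def to_dict(self) -> dict:
        return {
            "sex": self.sex.value,
            "percentile": self.percentile,
            "stature_mm": self.stature,
            "shoulder_height_mm": self.shoulder_height,
            "eye_height_mm": self.eye_height,
            "upper_arm_mm": self.upper_arm,
            "forearm_mm": self.forearm,
            "hand_mm": self.hand,
        }


def build_mannequin(population: Population, sex: Sex | str, percentile: float) -> Mannequin:
    """Build the percentile mannequin of a population.

    Stature is the normal quantile ``mean + z(percentile) * sd`` (or the
    mixture median machinery for the combined sex); every segment length is
    exactly its proportion coefficient times stature.
    """
    sex = Sex(sex)
    stature = population.stature_at(sex, percentile)
    c = population.proportion_coefficients
    return Mannequin(
        sex=sex,
        percentile=float(percentile),
        stature=stature,
        shoulder_height=c["shoulder_height"] * stature,
        eye_height=c["eye_height"] * stature,
        upper_arm=c["upper_arm_length"] * stature,
        forearm=c["forearm_length"] * stature,
        hand=c["hand_length"] * stature,
    )


def boundary_pair(population: Population) -> tuple[Mannequin, Mannequin]:
    """The classic boundary mannequins: (female 5th, male 95th percentile)."""
    return (
        build_mannequin(population, Sex.FEMALE, 5.0),
        build_mannequin(population, Sex.MALE, 95.0),
    )
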