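"""Follicle scoring rules and per-fragment density outcomes.

Scoring conventions
-------------------
* Transitional follicles are counted as primordial; primary and secondary
  follicles are retained in the records but excluded from every density
  outcome (their numbers in cortical sections are too low to analyse).
* A follicle is *degenerated* if it shows disorganized granulosa cells,
  shrunken ooplasm or a pyknotic oocyte — a logical OR of the three flags.
* A follicle is *proliferative* if at least one granulosa cell is
  Ki-67 positive.

Densities are follicles per mm^2, pooled over sections as
``sum(counts) / sum(areas)`` (robust to unequal section areas), and
reported on the ``log10(X + 1)`` scale.  Each 2-mm punch contributes 12
sections scored for density/morphology and 3 sections scored for
proliferation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .exceptions import ConfigError, DataError, VocabularyError

STAGES = ("primordial", "transitional", "primary", "secondary")
CONDITIONS = ("F", "F-T", "D2", "D6")
ROLES = ("density", "proliferation")

#: Density outcomes computable from annotation records alone.
OUTCOMES = ("total_primordial", "normal_primordial", "proliferative_primordial")

#: Outcome supplied by pixel-level quantification (``ihc`` module) on
#: proliferation-role sections; it has no annotation-based counterpart.
GLOBAL_PROLIFERATION = "global_proliferation"

_OUTCOME_ROLE = {
    "total_primordial": "density",
    "normal_primordial": "density",
    "proliferative_primordial": "proliferation",
}


@dataclass
class FollicleAnnotation:
    follicle_id: str
    stage: str
    granulosa_disorganized: bool = False
    ooplasm_shrunken: bool = False
    oocyte_pyknotic: bool = False
    ki67_pos_granulosa_count: int = 0

    def __post_init__(self):
        if self.stage not in STAGES:
            raise VocabularyError(
                f"unknown follicle stage {self.stage!r}; expected one of {STAGES}"
            )
        if self.ki67_pos_granulosa_count < 0:
            raise DataError("ki67_pos_granulosa_count must be >= 0")


@dataclass
class SectionRecord:
    section_id: str
    area_mm2: float
    analysis_role: str = "density"
    follicles: list[FollicleAnnotation] = field(default_factory=list)

    def __post_init__(self):
        if self.area_mm2 <= 0:
            raise DataError("section area_mm2 must be > 0")
        if self.analysis_role not in ROLES:
            raise VocabularyError(
                f"unknown analysis_role {self.analysis_role!r}; expected one of {ROLES}"
            )


@dataclass
class FragmentRecord:
    """One 2-mm ovarian cortex punch with its scored sections."""

    fragment_id: str
    arm: str
    condition: str
    sections: list[SectionRecord] = field(default_factory=list)

    def __post_init__(self):
        if self.condition not in CONDITIONS:
            raise VocabularyError(
                f"unknown condition {self.condition!r}; expected one of {CONDITIONS}"
            )


@dataclass(frozen=True)
class DensityObservation:
    fragment_id: str
    outcome: str
    raw_per_mm2: float
    log_value: float


def is_primordial_for_analysis(f: FollicleAnnotation) -> bool:
    """True for primordial and transitional follicles.

    Transitional follicles are pooled with primordial ones for every
    density outcome.
    """
    if f.stage not in STAGES:
        raise VocabularyError(f"unknown follicle stage {f.stage!r}")
    return f.stage in ("primordial", "transitional")


def classify_morphology(f: FollicleAnnotation) -> str:
    """``"degenerated"`` if any degeneration flag is set, else ``"normal"``."""
    degenerated = (
        f.granulosa_disorganized or f.ooplasm_shrunken or f.oocyte_pyknotic
    )
    return "degenerated" if degenerated else "normal"


def is_proliferative(f: FollicleAnnotation) -> bool:
    """True iff at least one granulosa cell is Ki-67 positive."""
    return f.ki67_pos_granulosa_count >= 1


def _qualifies(f: FollicleAnnotation, outcome: str) -> bool:
    if not is_primordial_for_analysis(f):
        return False
    if outcome == "total_primordial":
        return True
    if outcome == "normal_primordial":
        return classify_morphology(f) == "normal"
    if outcome == "proliferative_primordial":
        return is_proliferative(f)
    raise ConfigError(f"unknown outcome {outcome!r}; expected one of {OUTCOMES}")


def fragment_density(frag: FragmentRecord, outcome: str) -> DensityObservation:
    """Pooled density of one outcome over a fragment's qualifying sections.

    ``raw_per_mm2 = (sum of qualifying follicles) / (sum of section areas)``
    over the sections whose ``analysis_role`` matches the outcome, and
    ``log_value = log10(raw_per_mm2 + 1)``.
    """
    if outcome not in _OUTCOME_ROLE:
        raise ConfigError(
            f"unknown outcome {outcome!r}; expected one of {OUTCOMES}"
        )
    role = _OUTCOME_ROLE[outcome]
    sections = [s for s in frag.sections if s.analysis_role == role]
    if not sections:
        raise DataError(
            f"no sections for outcome {outcome!r} "
            f"(fragment {frag.fragment_id!r} has no {role!r}-role sections)"
        )
    count = sum(
        1 for s in sections for f in s.follicles if _qualifies(f, outcome)
    )
    area = sum(s.area_mm2 for s in sections)
    raw = count / area
    return DensityObservation(
        fragment_id=frag.fragment_id,
        outcome=outcome,
        raw_per_mm2=raw,
        log_value=math.log10(raw + 1.0),
    )


def section_density(section: SectionRecord, outcome: str) -> tuple[float, float]:
    """(raw_per_mm2, log_value) of one outcome for a single section."""
    count = sum(1 for f in section.follicles if _qualifies(f, outcome))
    raw = count / section.area_mm2
    return raw, math.log10(raw + 1.0)


def observations_table(
    fragments: list[FragmentRecord],
    outcomes=OUTCOMES,
    level: str = "section",
) -> pd.DataFrame:
    """Tidy observation table for the mixed-model analysis.

    ``level="section"`` emits one row per section per outcome (the analysis
    unit — the fragment random intercept is identified by the replicate
    sections within each punch); ``level="fragment"`` emits the pooled
    per-fragment densities.
    """
    if level not in ("section", "fragment"):
        raise ConfigError("level must be 'section' or 'fragment'")
    rows = []
    for frag in fragments:
        for outcome in outcomes:
            role = _OUTCOME_ROLE.get(outcome)
            if role is None:
                raise ConfigError(f"unknown outcome {outcome!r}")
            if level == "fragment":
                obs = fragment_density(frag, outcome)
                rows.append(
                    {
                        "fragment_id": frag.fragment_id,
                        "arm": frag.arm,
                        "condition": frag.condition,
                        "outcome": outcome,
                        "raw_per_mm2": obs.raw_per_mm2,
                        "log_value": obs.log_value,
                    }
                )
            else:
                sections = [s for s in frag.sections if s.analysis_role == role]
                if not sections:
                    raise DataError(
                        f"no sections for outcome {outcome!r} on fragment "
                        f"{frag.fragment_id!r}"
                    )
                for s in sections:
                    raw, logv = section_density(s, outcome)
                    rows.append(
                        {
                            "fragment_id": frag.fragment_id,
                            "arm": frag.arm,
                            "condition": frag.condition,
                            "section_id": s.section_id,
                            "outcome": outcome,
                            "raw_per_mm2": raw,
                            "log_value": logv,
                        }
                    )
    return pd.DataFrame(rows)


def proliferation_observation(
    fragment_id: str, density: float
) -> DensityObservation:
    """Global-proliferation observation from a pixel-level cell density.

    ``density`` is the dimensionless DAB+ area fraction produced by
    :func:`cortiquant.ihc.cell_density` on a proliferation-role section;
    it is carried onto the same log10(X + 1) outcome scale.
    """
    if density < 0:
        raise DataError("density must be >= 0")
    return DensityObservation(
        fragment_id=fragment_id,
        outcome=GLOBAL_PROLIFERATION,
        raw_per_mm2=density,
        log_value=math.log10(density + 1.0),
    )
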