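"""Radiological severity scoring: diameter-ratio grading, modified Reiff, BRICS.

Bronchiectasis severity on CT is graded per finding from the ratio of the
dilated airway's lumen diameter to the diameter of the adjacent pulmonary
vessel: 1–2x is mild (grade 1), 2–3x moderate (grade 2), more than 3x severe
(grade 3). Two slice-level composites are computed from per-lobe grades:

* **modified Reiff** — each scored lung region contributes its grade (the
  grade of its most dilated finding); the total over the six-region scheme
  (five lobes plus lingula) has a maximum of 18 points.
* **BRICS** (Bronchiectasis Radiologically Indexed CT Score) — the worst
  bronchiectasis grade anywhere (0–3) plus an emphysema-range band (0–2),
  maximum 5 points. The emphysema component defaults to zero, matching
  scoring pipelines that do not measure emphysema extent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "LOBE_SCHEMES",
    "LobeFindings",
    "SeverityScore",
    "grade_from_ratio",
    "reiff_score",
    "emphysema_band",
    "brics_score",
    "severity_report",
]

#: Lobe id -> name tables. Ids are positive; 0 is background everywhere.
LOBE_SCHEMES: dict[str, dict[int, str]] = {
    "lobes4": {1: "left_upper", 2: "left_lower", 3: "right_upper", 4: "right_lower"},
    "lobes6": {
        1: "left_upper",
        2: "lingula",
        3: "left_lower",
        4: "right_upper",
        5: "right_middle",
        6: "right_lower",
    },
}

_VALID_GRADES = frozenset({0, 1, 2, 3})


@dataclass
class LobeFindings:
    """Per-lobe bronchiectasis severity grades for one slice.

    ``grades`` maps lobe id to grade 0–3; lobes absent from the map count as
    grade 0. ``scheme`` names the lobe layout ("lobes4" or "lobes6").
    """

    grades: dict[int, int] = field(default_factory=dict)
    scheme: str = "lobes4"

    def __post_init__(self) -> None:
        if self.scheme not in LOBE_SCHEMES:
            raise ValueError(f"unknown lobe scheme {self.scheme!r}")
        table = LOBE_SCHEMES[self.scheme]
        for lobe, grade in self.grades.items():
            if lobe not in table:
                raise ValueError(f"lobe id {lobe} not in scheme {self.scheme!r}")
            if grade not in _VALID_GRADES:
                raise ValueError(f"grade {grade!r} for lobe {lobe} outside 0..3")

    @property
    def lobe_table(self) -> dict[int, str]:
        return LOBE_SCHEMES[self.scheme]

    def grade(self, lobe_id: int) -> int:
        return int(self.grades.get(lobe_id, 0))

    def named(self) -> dict[str, int]:
        """Grades keyed by lobe name, including implicit zeros."""
        return {name: self.grade(i) for i, name in self.lobe_table.items()}


@dataclass
class SeverityScore:
    """Slice-level severity report: Reiff and BRICS totals plus inputs."""

    reiff: int
    brics: int
    per_lobe: dict[int, int]
    emphysema_band: int
    scheme: str

    def to_dict(self) -> dict:
        table = LOBE_SCHEMES[self.scheme]
        return {
            "per_lobe": {table[i]: int(self.per_lobe.get(i, 0)) for i in table},
            "reiff": int(self.reiff),
            "brics": int(self.brics),
            "emphysema_band": int(self.emphysema_band),
            "scheme": self.scheme,
        }


def grade_from_ratio(lumen_diameter: float, vessel_diameter: float) -> int:
    """Severity grade 0–3 from lumen/vessel diameter ratio.

    r <= 1 is not dilated (grade 0); 1 < r <= 2 mild; 2 < r <= 3 moderate;
    r > 3 severe. Boundary ratios of exactly 2 or 3 take the lower grade
    (closed upper bound).
    """
    if lumen_diameter <= 0 or vessel_diameter <= 0:
        raise ValueError("diameters must be positive")
    r = lumen_diameter / vessel_diameter
    if r <= 1.0:
        return 0
    if r <= 2.0:
        return 1
    if r <= 3.0:
        return 2
    return 3


def reiff_score(findings: LobeFindings) -> int:
    """Modified Reiff total: sum of per-lobe grades over the scheme's lobes.

    Maximum 12 on the 4-lobe scheme, 18 on the six-region scheme.
    """
    return sum(findings.grade(i) for i in findings.lobe_table)


def emphysema_band(emphysema_extent: float) -> int:
    """BRICS emphysema-range band: none -> 0, 1–5 -> 1, more than 5 -> 2."""
    if emphysema_extent < 0:
        raise ValueError("emphysema extent must be non-negative")
    if emphysema_extent == 0:
        return 0
    if emphysema_extent <= 5:
        return 1
    return 2


def brics_score(findings: LobeFindings, emphysema_extent: float = 0) -> int:
    """BRICS total: worst lobe grade plus the emphysema band (max 5)."""
    worst = max((findings.grade(i) for i in findings.lobe_table), default=0)
    return worst + emphysema_band(emphysema_extent)


def severity_report(findings: LobeFindings, emphysema_extent: float = 0) -> SeverityScore:
    """Bundle Reiff + BRICS into a :class:`SeverityScore`."""
    return SeverityScore(
        reiff=reiff_score(findings),
        brics=brics_score(findings, emphysema_extent),
        per_lobe={i: findings.grade(i) for i in findings.lobe_table},
        emphysema_band=emphysema_band(emphysema_extent),
        scheme=findings.scheme,
    )
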