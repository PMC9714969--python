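"""Individual handedness indices, z-score classification, and group summaries.

The tube task scores, for every subject, the number of left-hand (L) and
right-hand (R) bimanual insertions.  The handedness index

    HI = (R - L) / (R + L)

ranges from -1 (exclusively left-handed) to +1 (exclusively right-handed) and
measures the *direction* of an individual's preference; |HI| measures its
*strength*.  Whether an individual bias is statistically meaningful is judged
by the binomial z score against an even-split null: subjects with z > 1.96
are classed right-handed, z < -1.96 left-handed, the rest ambipreferent.

Group (species or genus) summaries carry the mean signed HI (direction), the
mean absolute HI (strength), and the tally of the three preference classes.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import pandas as pd

Z_CRITICAL = 1.96

Category = Literal["left", "right", "ambipreferent"]


class UndefinedIndexError(ValueError):
    """Raised when L + R = 0 so no laterality index exists."""


@dataclass(frozen=True)
class IndividualLaterality:
    """Per-subject laterality scores and preference class."""

    subject_id: str
    species: str
    hi: float
    z: float
    category: Category

    @property
    def abs_hi(self) -> float:
        return abs(self.hi)


@dataclass(frozen=True)
class GroupSummary:
    """Species- or genus-level laterality summary.

    ``mean_hi`` is the unweighted mean of subject HIs (direction);
    ``mean_abs_hi`` the mean of |HI| (strength).  By Jensen's inequality
    ``|mean_hi| <= mean_abs_hi <= 1`` always holds.
    """

    group_id: str
    clade: str
    n: int
    n_left: int
    n_right: int
    n_ambi: int
    mean_hi: float
    mean_abs_hi: float
    level: Literal["species", "genus"] = "species"

    def __post_init__(self) -> None:
        if self.n_left + self.n_right + self.n_ambi != self.n:
            raise ValueError(
                f"{self.group_id}: category counts "
                f"{self.n_left}+{self.n_right}+{self.n_ambi} != n={self.n}"
            )

    @property
    def ambi_fraction(self) -> float:
        return self.n_ambi / self.n

    def percentages(self, ndigits: int = 1) -> tuple[float, float, float]:
        """Category percentages, rounded half-up to ``ndigits`` decimals."""
        return tuple(
            round_half_up(100.0 * k / self.n, ndigits)
            for k in (self.n_left, self.n_right, self.n_ambi)
        )


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal rounding with ties away from zero (0.05 -> 0.1)."""
    factor = 10.0**ndigits
    return math.floor(abs(x) * factor + 0.5) / factor * math.copysign(1.0, x)


def handedness_index(right: int, left: int) -> float:
    """HI = (R - L) / (R + L); positive iff right-hand insertions dominate."""
    n = right + left
    if n < 1:
        raise UndefinedIndexError("handedness index undefined for R + L = 0")
    if right < 0 or left < 0:
        raise ValueError("insertion counts must be non-negative")
    return (right - left) / n


def binomial_z(right: int, left: int) -> float:
    """Normal-approximation z for R successes out of R + L fair trials.

    z = (R - n/2) / sqrt(n/4), without continuity correction.  The source
    criterion compares z against +/-1.96, i.e. a two-sided test at alpha=0.05.
    """
    n = right + left
    if n < 1:
        raise UndefinedIndexError("binomial z undefined for R + L = 0")
    return (right - n / 2.0) / math.sqrt(n / 4.0)


def classify(z: float) -> Category:
    """Preference class from z; the +/-1.96 boundaries are ambipreferent."""
    if not math.isfinite(z):
        raise ValueError(f"non-finite z score: {z!r}")
    if z > Z_CRITICAL:
        return "right"
    if z < -Z_CRITICAL:
        return "left"
    return "ambipreferent"


def score_subjects(subjects: Iterable) -> list[IndividualLaterality]:
    """Score a collection of SubjectRecord into per-subject laterality."""
    out = []
    for s in subjects:
        z = binomial_z(s.right_insertions, s.left_insertions)
        out.append(
            IndividualLaterality(
                subject_id=s.subject_id,
                species=s.species,
                hi=handedness_index(s.right_insertions, s.left_insertions),
                z=z,
                category=classify(z),
            )
        )
    return out


def summarize_group(
    records: Sequence[IndividualLaterality],
    group_id: str,
    clade: str = "",
    level: Literal["species", "genus"] = "species",
) -> GroupSummary:
    """Unweighted summary over subjects of one species or genus."""
    if not records:
        raise ValueError(f"empty group: {group_id}")
    n = len(records)
    tally = {"left": 0, "right": 0, "ambipreferent": 0}
    for r in records:
        tally[r.category] += 1
    return GroupSummary(
        group_id=group_id,
        clade=clade,
        n=n,
        n_left=tally["left"],
        n_right=tally["right"],
        n_ambi=tally["ambipreferent"],
        mean_hi=sum(r.hi for r in records) / n,
        mean_abs_hi=sum(r.abs_hi for r in records) / n,
        level=level,
    )


def summarize_by(
    subjects: Sequence,
    laterality: Sequence[IndividualLaterality],
    level: Literal["species", "genus"] = "species",
) -> list[GroupSummary]:
    """Group per-subject scores by species or genus (pooling subjects).

    Genus summaries pool subjects rather than averaging species summaries, so
    a genus n equals the sum of its species n.
    """
    by_id = {s.subject_id: s for s in subjects}
    groups: dict[str, list[IndividualLaterality]] = defaultdict(list)
    clades: dict[str, str] = {}
    for rec in laterality:
        subj = by_id[rec.subject_id]
        key = subj.species if level == "species" else subj.genus
        groups[key].append(rec)
        clades.setdefault(key, subj.clade)
    return [
        summarize_group(groups[k], k, clade=clades[k], level=level)
        for k in sorted(groups)
    ]


def laterality_frame(records: Sequence[IndividualLaterality]) -> pd.DataFrame:
    """Per-subject output table: subject_id, species, hi, z, category."""
    return pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "species": [r.species for r in records],
            "hi": [r.hi for r in records],
            "z": [r.z for r in records],
            "category": [r.category for r in records],
        }
    )


def summary_frame(summaries: Sequence[GroupSummary]) -> pd.DataFrame:
    """Per-group output table mirroring the species summary columns."""
    return pd.DataFrame(
        {
            "group_id": [s.group_id for s in summaries],
            "level": [s.level for s in summaries],
            "clade": [s.clade for s in summaries],
            "n": [s.n for s in summaries],
            "n_left": [s.n_left for s in summaries],
            "n_right": [s.n_right for s in summaries],
            "n_ambi": [s.n_ambi for s in summaries],
            "mean_hi": [s.mean_hi for s in summaries],
            "mean_abs_hi": [s.mean_abs_hi for s in summaries],
        }
    )
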