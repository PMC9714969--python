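"""Population-level significance tests on laterality summaries.

Two tests are run per species (and per genus):

* a two-sided one-sample t-test of the subject HIs against zero
  (population-level *direction* bias), and
* a Pearson chi-square goodness-of-fit test of the left/right/ambipreferent
  tally against a clade-specific baseline (*distribution* bias).

The baseline is bespoke: within each major clade (Platyrrhini,
Cercopithecoidea, Hominoidea) the expected share of ambipreferent individuals
is the clade's mean ambipreferent frequency, and the remaining "handed" mass
is split evenly between left and right.  Humans are excluded from the
hominoid baseline so that their extreme right bias does not define the null
their own row is tested against.  Bonferroni correction handles the multiple
tests within each family.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import stats

from .laterality import GroupSummary, IndividualLaterality

ALPHA = 0.05
HUMAN = "Homo sapiens"


class DegenerateSampleError(ValueError):
    """Sample admits no test (zero variance or too few observations)."""


@dataclass(frozen=True)
class CladeBaseline:
    """Null category probabilities for one clade.

    ``p_left = p_right = (1 - p_ambi) / 2`` by construction: handed
    individuals are assumed equally likely to be left- or right-handed.
    """

    clade: str
    p_ambi: float
    n_species: int
    weighting: str = "individuals"

    @property
    def p_left(self) -> float:
        return (1.0 - self.p_ambi) / 2.0

    @property
    def p_right(self) -> float:
        return (1.0 - self.p_ambi) / 2.0

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.p_left, self.p_right, self.p_ambi)


@dataclass(frozen=True)
class TestResult:
    group_id: str
    test: Literal["t_direction", "gof_distribution"]
    statistic: float
    df: float
    p: float
    family_size: int = 1
    below_min_n: bool = False

    @property
    def p_bonferroni(self) -> float:
        return bonferroni_adjust(self.p, self.family_size)

    @property
    def significant_raw(self) -> bool:
        return self.p < ALPHA

    @property
    def significant_corrected(self) -> bool:
        return self.p_bonferroni < ALPHA


def one_sample_t(his: Sequence[float], group_id: str = "") -> TestResult:
    """Two-sided one-sample t-test of mean(HI) against zero."""
    x = np.asarray(his, dtype=float)
    if x.size < 2:
        raise DegenerateSampleError(f"{group_id}: need >= 2 HI values, got {x.size}")
    if np.ptp(x) == 0.0:
        raise DegenerateSampleError(f"{group_id}: zero variance in HI values")
    t, p = stats.ttest_1samp(x, 0.0)
    return TestResult(group_id, "t_direction", float(t), float(x.size - 1), float(p))


def clade_baseline(
    summaries: Iterable[GroupSummary],
    clade: str,
    exclude: frozenset[str] | set[str] = frozenset({HUMAN}),
    weighting: Literal["individuals", "species"] = "individuals",
) -> CladeBaseline:
    """Mean ambipreferent frequency of a clade, handed mass split evenly.

    ``weighting="individuals"`` pools subjects across the clade's species
    (this reproduces the published per-species test results);
    ``weighting="species"`` takes the unweighted mean of species-level
    frequencies.
    """
    rows = [s for s in summaries if s.clade == clade and s.group_id not in exclude]
    if not rows:
        raise ValueError(f"no species available for clade {clade!r}")
    if weighting == "individuals":
        p_ambi = sum(s.n_ambi for s in rows) / sum(s.n for s in rows)
    elif weighting == "species":
        p_ambi = float(np.mean([s.ambi_fraction for s in rows]))
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    return CladeBaseline(clade=clade, p_ambi=p_ambi, n_species=len(rows),
                         weighting=weighting)


def gof_chi_square(
    observed: tuple[int, int, int],
    baseline: CladeBaseline,
    group_id: str = "",
) -> TestResult:
    """Pearson chi-square of (n_left, n_right, n_ambi) against the baseline."""
    obs = np.asarray(observed, dtype=float)
    n = obs.sum()
    if n < 1:
        raise DegenerateSampleError(f"{group_id}: empty observation vector")
    probs = np.asarray(baseline.as_tuple())
    if np.any((probs == 0.0) & (obs > 0)):
        raise ValueError(f"{group_id}: positive count in zero-probability category")
    expected = n * probs
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    p = float(stats.chi2.sf(chi2, df=2))
    return TestResult(group_id, "gof_distribution", chi2, 2.0, p)


def bonferroni_adjust(p: float, m: int) -> float:
    """min(1, p * m) for a declared family of m tests."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p out of range: {p}")
    if m < 1:
        raise ValueError(f"family size must be >= 1, got {m}")
    return min(1.0, p * m)


def run_population_battery(
    summaries: Sequence[GroupSummary],
    laterality_by_group: dict[str, Sequence[IndividualLaterality]] | None = None,
    min_n: int = 15,
    weighting: Literal["individuals", "species"] = "individuals",
    exclude_from_baseline: frozenset[str] = frozenset({HUMAN}),
    include_below_min_n: bool = False,
) -> list[TestResult]:
    """Both tests for every qualifying group.

    The distribution test needs only the category tallies and is computed for
    every group.  The direction t-test needs per-subject HIs and is computed
    when ``laterality_by_group`` supplies them; groups below ``min_n`` are
    skipped unless ``include_below_min_n`` (results are then flagged).
    The declared Bonferroni family is the number of groups tested per test
    type.
    """
    baselines = {
        c: clade_baseline(summaries, c, exclude=exclude_from_baseline,
                          weighting=weighting)
        for c in sorted({s.clade for s in summaries})
    }
    results: list[TestResult] = []

    m_dist = len(summaries)
    for s in summaries:
        r = gof_chi_square((s.n_left, s.n_right, s.n_ambi), baselines[s.clade],
                           group_id=s.group_id)
        results.append(
            TestResult(r.group_id, r.test, r.statistic, r.df, r.p,
                       family_size=m_dist, below_min_n=s.n < min_n)
        )

    if laterality_by_group is not None:
        eligible = [s for s in summaries
                    if s.n >= min_n or include_below_min_n]
        m_dir = sum(s.n >= min_n for s in summaries)
        for s in eligible:
            recs = laterality_by_group.get(s.group_id)
            if recs is None:
                continue
            r = one_sample_t([rec.hi for rec in recs], group_id=s.group_id)
            results.append(
                TestResult(r.group_id, r.test, r.statistic, r.df, r.p,
                           family_size=max(m_dir, 1),
                           below_min_n=s.n < min_n)
            )
    return results


def results_frame(results: Sequence[TestResult], level: str = "species"):
    """Results as a DataFrame matching the documented CSV columns."""
    import pandas as pd

    return pd.DataFrame(
        {
            "group_id": [r.group_id for r in results],
            "level": level,
            "test": [r.test for r in results],
            "statistic": [r.statistic for r in results],
            "df": [r.df for r in results],
            "p": [r.p for r in results],
            "p_bonferroni": [r.p_bonferroni for r in results],
            "sig_raw": [r.significant_raw for r in results],
            "sig_corrected": [r.significant_corrected for r in results],
            "family_size": [r.family_size for r in results],
            "below_min_n": [r.below_min_n for r in results],
        }
    )
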