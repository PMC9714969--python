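"""Reading, writing, and filtering of subject/predictor tables.

Input CSVs are UTF-8, comma-separated, with a header row.  Species names are
exact binomials matching the tips of the phylogeny.  Two inclusion filters
mirror the study protocol: subjects need at least 30 bimanual insertions
scored in at least 6 bouts, and species-level inference requires at least 15
subjects per species.

The packaged ``table1.csv`` resource transcribes the published species-level
summary (38 anthropoid species, 1786 subjects) and is integrity-checked on
load.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .laterality import GroupSummary

logger = logging.getLogger(__name__)

CLADES = ("Platyrrhini", "Cercopithecoidea", "Hominoidea")
SUBJECT_COLUMNS = (
    "subject_id",
    "species",
    "clade",
    "sex",
    "age_class",
    "left_insertions",
    "right_insertions",
    "bouts",
)
PREDICTOR_COLUMNS = ("species", "ecology", "tool_use", "brain_size_ml")

# Age labels pooled to "subadult" on read: the study distinguishes only
# sexually mature adults from everyone younger.
_SUBADULT_ALIASES = {"subadult", "infant", "juvenile"}

_TABLE1_SHA256 = "b04611680c930a6554e88f3e2e0bb64a2c73564b2d9585166a6e47db4c035640"


class SchemaError(ValueError):
    """A required column is missing or mis-typed."""


class IntegrityError(RuntimeError):
    """Packaged resource does not match its recorded checksum."""


@dataclass(frozen=True)
class SubjectRecord:
    """One tested individual with insertion counts and metadata."""

    subject_id: str
    species: str
    clade: str
    sex: str  # "F", "M", or "unknown"
    age_class: str  # "adult", "subadult", or "unknown"
    left_insertions: int
    right_insertions: int
    bouts: int
    genus: str = ""
    row: int | None = None  # 1-based source row for error reporting

    def __post_init__(self) -> None:
        if self.left_insertions < 0 or self.right_insertions < 0:
            raise ValueError(f"{self.subject_id}: negative insertion count")
        if self.bouts < 1:
            raise ValueError(f"{self.subject_id}: bouts must be positive")
        if not self.genus:
            object.__setattr__(self, "genus", self.species.split()[0])

    @property
    def total_insertions(self) -> int:
        return self.left_insertions + self.right_insertions


@dataclass(frozen=True)
class PredictorRecord:
    """Species-level ecological covariates.

    ``brain_size_ml`` is the raw female endocranial volume in ml; the log10
    transform is applied downstream by the regression code, never here.
    """

    species: str
    ecology: str  # "arboreal" or "terrestrial"
    tool_use: bool
    brain_size_ml: float

    def __post_init__(self) -> None:
        if self.ecology not in ("arboreal", "terrestrial"):
            raise ValueError(f"{self.species}: ecology {self.ecology!r}")
        if self.brain_size_ml <= 0:
            raise ValueError(f"{self.species}: brain size must be positive")


@dataclass
class Dataset:
    """Bundle of subjects, species predictors, and (optionally) a tree."""

    subjects: list[SubjectRecord]
    predictors: list[PredictorRecord] = field(default_factory=list)
    tree: object | None = None

    def species(self) -> list[str]:
        return sorted({s.species for s in self.subjects})


def _parse_int(value, column: str, row: int) -> int:
    try:
        out = int(value)
    except (TypeError, ValueError):
        raise SchemaError(
            f"row {row}: column {column!r} is not an integer: {value!r}"
        ) from None
    return out


def read_subjects(path: str | Path, *, genus_column: bool = True) -> list[SubjectRecord]:
    """Read a subjects CSV into records; row numbers are preserved.

    Unknown sex and missing age are permitted (flagged "unknown" and logged).
    Age labels "infant"/"juvenile" are pooled to "subadult".
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in SUBJECT_COLUMNS if c != "clade" and c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")
    if df.empty:
        logger.warning("%s: no subject rows (header only)", path)
        return []
    records = []
    for i, rec in enumerate(df.to_dict("records")):
        row = i + 2  # header is line 1
        sex = (rec.get("sex") or "unknown").strip() or "unknown"
        if sex not in ("F", "M"):
            if sex != "unknown":
                raise SchemaError(f"row {row}: sex must be F, M or unknown, got {sex!r}")
            logger.info("row %d: subject %s has unknown sex", row, rec["subject_id"])
        age = (rec.get("age_class") or "unknown").strip().lower() or "unknown"
        if age in _SUBADULT_ALIASES:
            age = "subadult"
        elif age not in ("adult", "unknown"):
            raise SchemaError(f"row {row}: unrecognized age class {age!r}")
        if age == "unknown":
            logger.info("row %d: subject %s has no age class", row, rec["subject_id"])
        genus = rec.get("genus", "").strip() if genus_column else ""
        records.append(
            SubjectRecord(
                subject_id=rec["subject_id"],
                species=rec["species"],
                clade=rec.get("clade", "").strip(),
                sex=sex,
                age_class=age,
                left_insertions=_parse_int(rec["left_insertions"], "left_insertions", row),
                right_insertions=_parse_int(rec["right_insertions"], "right_insertions", row),
                bouts=_parse_int(rec["bouts"], "bouts", row),
                genus=genus,
                row=row,
            )
        )
    _check_clade_consistency(records)
    return records


def _check_clade_consistency(records: Sequence[SubjectRecord]) -> None:
    seen: dict[str, str] = {}
    for r in records:
        if not r.clade:
            continue
        prior = seen.setdefault(r.species, r.clade)
        if prior != r.clade:
            raise SchemaError(
                f"species {r.species}: inconsistent clades {prior!r} vs {r.clade!r}"
            )


def write_subjects(records: Sequence[SubjectRecord], path: str | Path) -> None:
    """Write records in the canonical dialect (round-trips read_subjects)."""
    df = pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "species": [r.species for r in records],
            "genus": [r.genus for r in records],
            "clade": [r.clade for r in records],
            "sex": [r.sex for r in records],
            "age_class": [r.age_class for r in records],
            "left_insertions": [r.left_insertions for r in records],
            "right_insertions": [r.right_insertions for r in records],
            "bouts": [r.bouts for r in records],
        }
    )
    df.to_csv(path, index=False)


def read_predictors(path: str | Path) -> list[PredictorRecord]:
    """Read the species-level predictor table (ecology, tool use, brain size)."""
    df = pd.read_csv(path)
    missing = [c for c in PREDICTOR_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")
    out = []
    for rec in df.to_dict("records"):
        tool = rec["tool_use"]
        if isinstance(tool, str):
            tool = tool.strip().lower() in ("1", "true", "yes", "present")
        out.append(
            PredictorRecord(
                species=rec["species"],
                ecology=str(rec["ecology"]).strip().lower(),
                tool_use=bool(tool),
                brain_size_ml=float(rec["brain_size_ml"]),
            )
        )
    return out


def write_predictors(records: Sequence[PredictorRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "species": [r.species for r in records],
            "ecology": [r.ecology for r in records],
            "tool_use": [int(r.tool_use) for r in records],
            "brain_size_ml": [r.brain_size_ml for r in records],
        }
    ).to_csv(path, index=False)


def filter_subjects(
    subjects: Iterable[SubjectRecord],
    min_insertions: int = 30,
    min_bouts: int = 6,
) -> list[SubjectRecord]:
    """Apply the study's inclusion thresholds (both boundaries inclusive)."""
    if min_insertions < 1 or min_bouts < 1:
        raise ValueError("inclusion thresholds must be >= 1")
    kept, dropped = [], 0
    for s in subjects:
        if s.total_insertions >= min_insertions and s.bouts >= min_bouts:
            kept.append(s)
        else:
            dropped += 1
            logger.info(
                "excluded subject %s (%d insertions, %d bouts)",
                s.subject_id,
                s.total_insertions,
                s.bouts,
            )
    if dropped:
        logger.warning("excluded %d of %d subjects below inclusion thresholds",
                       dropped, dropped + len(kept))
    return kept


def filter_species_min_n(
    summaries: Iterable[GroupSummary], min_n: int = 15
) -> list[GroupSummary]:
    """Retain groups with at least ``min_n`` subjects."""
    return [s for s in summaries if s.n >= min_n]


def load_table1_fixture(check_integrity: bool = True) -> list[GroupSummary]:
    """Load the packaged species-level summary table (38 species).

    Returns GroupSummary objects carrying the published counts and the
    published MeanHI / MeanAbsHI values.
    """
    ref = resources.files("tubetask") / "resources" / "table1.csv"
    raw = ref.read_bytes()
    if check_integrity:
        digest = hashlib.sha256(raw).hexdigest()
        if digest != _TABLE1_SHA256:
            raise IntegrityError(
                f"table1.csv checksum mismatch: {digest} != {_TABLE1_SHA256}"
            )
    df = table1_frame()
    return [
        GroupSummary(
            group_id=r.species,
            clade=r.clade,
            n=int(r.n),
            n_left=int(r.n_left),
            n_right=int(r.n_right),
            n_ambi=int(r.n_ambi),
            mean_hi=float(r.mean_hi),
            mean_abs_hi=float(r.mean_abs_hi),
        )
        for r in df.itertuples()
    ]


def table1_frame() -> pd.DataFrame:
    """The packaged summary table as a DataFrame (includes published p strings)."""
    ref = resources.files("tubetask") / "resources" / "table1.csv"
    with ref.open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh, dtype={"p_direction": str, "p_distribution": str})
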