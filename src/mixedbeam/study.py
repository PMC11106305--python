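"""Domain types, sample-sheet semantics and CSV I/O for the two-donor study.

The study design is a 2-donor x 3-season x 3-week factorial in which whole
blood is exposed to X-rays, alpha particles or a 1:1 mixed beam at total
doses of 0, 0.5, 1 and 2 Gy, with a shared sham-exposed (0 Gy) control per
collection.  Two long-format CSV layouts carry the raw measurements:

ct table          donor,season,week,radiation,dose_gy,target,replicate,ct
metaphase table   donor,season,week,radiation,dose_gy,object_count

Doses are not restricted to the study grid and replicate counts are not
enforced at two; deviations are reported, not rejected.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd


class Radiation(str, enum.Enum):
    """Radiation condition of one exposure."""

    CONTROL = "control"
    XRAY = "xray"
    ALPHA = "alpha"
    MIXED = "mixed"


#: qPCR targets: two transcript-variant primer pairs per gene plus the
#: 18S reference.
TARGETS = (
    "FDXR_PP1",
    "FDXR_PP2",
    "CDKN1A_V1",
    "CDKN1A_V4",
    "MDM2_303_304",
    "MDM2_315",
    "REF_18S",
)
REFERENCE_TARGET = "REF_18S"
GENE_TARGETS = tuple(t for t in TARGETS if t != REFERENCE_TARGET)

CT_COLUMNS = ["donor", "season", "week", "radiation", "dose_gy", "target", "replicate", "ct"]
METAPHASE_COLUMNS = ["donor", "season", "week", "radiation", "dose_gy", "object_count"]

#: Diploid human chromosome number; objects counted in excess of this per
#: metaphase are scored as aberrations (fragments).
DIPLOID_COUNT = 46


class SchemaError(ValueError):
    """A table is missing required columns."""


class TableParseError(ValueError):
    """A table row could not be parsed; the message names the row."""


@dataclass(frozen=True)
class ExposureCondition:
    """One radiation condition: type, total dose, and mixture composition.

    For a mixed beam with X-ray share ``f`` the X-ray component dose is
    ``f * dose`` and the alpha component dose is ``(1 - f) * dose``; the
    study used a 1:1 mixture (half the dose each).
    """

    radiation: Radiation
    dose_gy: float
    mixture_share_xray: float = 0.5

    def __post_init__(self) -> None:
        if self.dose_gy < 0:
            raise ValueError(f"dose must be non-negative, got {self.dose_gy}")
        if self.radiation is Radiation.CONTROL and self.dose_gy != 0:
            raise ValueError("control condition implies dose 0 Gy")
        if not 0.0 <= self.mixture_share_xray <= 1.0:
            raise ValueError("mixture_share_xray must lie in [0, 1]")

    @property
    def component_doses(self) -> tuple[float, float]:
        """(X-ray dose, alpha dose) delivered by this condition."""
        if self.radiation is Radiation.XRAY:
            return self.dose_gy, 0.0
        if self.radiation is Radiation.ALPHA:
            return 0.0, self.dose_gy
        if self.radiation is Radiation.MIXED:
            f = self.mixture_share_xray
            return f * self.dose_gy, (1.0 - f) * self.dose_gy
        return 0.0, 0.0


@dataclass(frozen=True)
class SampleKey:
    """Identifies one biological sample: donor, collection time, exposure."""

    donor: str
    season: int
    week: int
    condition: ExposureCondition

    def __post_init__(self) -> None:
        if self.season < 1 or self.week < 1:
            raise ValueError("season and week are 1-based positive integers")


@dataclass(frozen=True)
class CtRecord:
    """One technical-replicate Ct measurement."""

    sample: SampleKey
    target: str
    replicate: int
    ct: float

    def __post_init__(self) -> None:
        if self.target not in TARGETS:
            raise ValueError(f"unknown target {self.target!r}")
        if self.replicate < 1:
            raise ValueError("replicate is a 1-based positive integer")
        if not math.isfinite(self.ct):
            raise ValueError("ct must be finite")


@dataclass(frozen=True)
class MetaphaseRecord:
    """Total chromosomes + fragments counted in one metaphase plate."""

    sample: SampleKey
    object_count: int

    def __post_init__(self) -> None:
        if not isinstance(self.object_count, int) or isinstance(self.object_count, bool):
            raise ValueError("object_count must be an integer")
        if self.object_count < 0:
            raise ValueError("object_count must be non-negative")


@dataclass(frozen=True)
class PanelConfig:
    """The qPCR panel: gene -> primer pairs, reference, and the fixed
    numerator:denominator orientation of each transcript-variant ratio."""

    genes: tuple[tuple[str, tuple[str, str]], ...] = (
        ("FDXR", ("FDXR_PP1", "FDXR_PP2")),
        ("CDKN1A", ("CDKN1A_V1", "CDKN1A_V4")),
        ("MDM2", ("MDM2_315", "MDM2_303_304")),
    )
    reference_target: str = REFERENCE_TARGET

    @property
    def pair_ratio_orientation(self) -> tuple[tuple[str, str, str], ...]:
        """(pair id, numerator target, denominator target) per gene."""
        return tuple(
            (f"{gene} {num.split('_', 1)[1]}:{den.split('_', 1)[1]}", num, den)
            for gene, (num, den) in self.genes
        )


DEFAULT_PANEL = PanelConfig()


def _condition_from_row(radiation: str, dose_gy: float) -> ExposureCondition:
    try:
        rad = Radiation(radiation)
    except ValueError as exc:
        raise TableParseError(f"unknown radiation {radiation!r}") from exc
    return ExposureCondition(rad, float(dose_gy))


def _require_columns(df: pd.DataFrame, columns: Sequence[str], path: Path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}; found {list(df.columns)}")


def read_ct_table(path: str | Path) -> list[CtRecord]:
    """Read a long-format Ct table into CtRecords.

    Raises SchemaError on a missing column and TableParseError naming the
    offending line for unparseable values.  An empty data section yields an
    empty list.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, CT_COLUMNS, path)
    records: list[CtRecord] = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):  # line 1 = header
        try:
            sample = SampleKey(
                donor=str(row.donor),
                season=int(row.season),
                week=int(row.week),
                condition=_condition_from_row(row.radiation, float(row.dose_gy)),
            )
            records.append(
                CtRecord(sample=sample, target=row.target, replicate=int(row.replicate), ct=float(row.ct))
            )
        except (ValueError, TypeError) as exc:
            raise TableParseError(f"{path}, line {idx}: {exc}") from exc
    return records


def read_metaphase_table(path: str | Path) -> list[MetaphaseRecord]:
    """Read a long-format metaphase table into MetaphaseRecords.

    Fractional or negative object counts raise TableParseError naming the
    line.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, METAPHASE_COLUMNS, path)
    records: list[MetaphaseRecord] = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        try:
            count_f = float(row.object_count)
            if count_f != int(count_f):
                raise ValueError(f"object_count must be an integer, got {row.object_count}")
            sample = SampleKey(
                donor=str(row.donor),
                season=int(row.season),
                week=int(row.week),
                condition=_condition_from_row(row.radiation, float(row.dose_gy)),
            )
            records.append(MetaphaseRecord(sample=sample, object_count=int(count_f)))
        except (ValueError, TypeError) as exc:
            raise TableParseError(f"{path}, line {idx}: {exc}") from exc
    return records


def ct_records_to_frame(records: Iterable[CtRecord]) -> pd.DataFrame:
    rows = [
        {
            "donor": r.sample.donor,
            "season": r.sample.season,
            "week": r.sample.week,
            "radiation": r.sample.condition.radiation.value,
            "dose_gy": r.sample.condition.dose_gy,
            "target": r.target,
            "replicate": r.replicate,
            "ct": r.ct,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=CT_COLUMNS)


def metaphase_records_to_frame(records: Iterable[MetaphaseRecord]) -> pd.DataFrame:
    rows = [
        {
            "donor": r.sample.donor,
            "season": r.sample.season,
            "week": r.sample.week,
            "radiation": r.sample.condition.radiation.value,
            "dose_gy": r.sample.condition.dose_gy,
            "object_count": r.object_count,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=METAPHASE_COLUMNS)


def write_ct_table(records: Iterable[CtRecord], path: str | Path) -> None:
    ct_records_to_frame(records).to_csv(path, index=False)


def write_metaphase_table(records: Iterable[MetaphaseRecord], path: str | Path) -> None:
    metaphase_records_to_frame(records).to_csv(path, index=False)


@dataclass
class DesignReport:
    """Report-only design check: flags incomplete blocks, notes oddities."""

    blocks: pd.DataFrame = field(default_factory=pd.DataFrame)
    flags: list[str] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.flags


def validate_design(
    ct_records: Iterable[CtRecord] | None = None,
    metaphase_records: Iterable[MetaphaseRecord] | None = None,
    expected_radiations: Sequence[str] = ("xray", "alpha", "mixed"),
    expected_replicates: int = 2,
) -> DesignReport:
    """Check each (donor, season, week) block for completeness.

    Flags a block that lacks its 0 Gy control or any expected irradiated
    condition; replicate counts differing from the study standard are
    recorded as informational notes only.  Order-independent; never raises.
    """
    frames = []
    if ct_records is not None:
        f = ct_records_to_frame(ct_records)
        if len(f):
            frames.append(f[["donor", "season", "week", "radiation", "dose_gy"]].assign(kind="ct"))
    if metaphase_records is not None:
        f = metaphase_records_to_frame(metaphase_records)
        if len(f):
            frames.append(f[["donor", "season", "week", "radiation", "dose_gy"]].assign(kind="metaphase"))
    report = DesignReport()
    if not frames:
        report.notes.append("no records supplied")
        return report
    df = pd.concat(frames, ignore_index=True)

    rows = []
    for (donor, season, week), block in sorted(df.groupby(["donor", "season", "week"]),
                                               key=lambda kv: kv[0]):
        present = set(block["radiation"])
        has_control = bool(((block["radiation"] == "control") & (block["dose_gy"] == 0)).any())
        if not has_control:
            report.flags.append(f"block ({donor}, s{season}, w{week}): no control (0 Gy)")
        for rad in expected_radiations:
            if rad not in present:
                report.flags.append(f"block ({donor}, s{season}, w{week}): missing {rad}")
        rows.append(
            {
                "donor": donor,
                "season": season,
                "week": week,
                "has_control": has_control,
                "radiations": ",".join(sorted(present)),
                "n_rows": len(block),
            }
        )
    report.blocks = pd.DataFrame(rows)

    if ct_records is not None:
        ct = ct_records_to_frame(ct_records)
        if len(ct):
            reps = ct.groupby(["donor", "season", "week", "radiation", "dose_gy", "target"])[
                "replicate"
            ].nunique()
            odd = reps[reps != expected_replicates]
            for key, n in odd.items():
                report.notes.append(f"{key}: {n} replicates (study standard {expected_replicates})")
    return report
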