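"""Complementation-experiment summary statistics.

Takes a per-stage experiment log (blastocysts transferred, embryos recovered,
GFP-positive embryos at each embryonic day) and reproduces the standard
summary table: recovery and GFP-positivity rates per stage plus a totals row,
and survival counts beyond a given stage. Stage labels are embryonic days
("E9.5", "E10.5", ...) ordered numerically.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .display import format_percent, round_half_up
from .errors import ConfigurationError

_STAGE_RE = re.compile(r"^E(\d+(?:\.\d+)?)$")


@dataclass(frozen=True)
class StageRecord:
    stage_label: str
    blastocysts_transferred: int
    embryos_recovered: int
    gfp_positive: int

    def __post_init__(self) -> None:
        if not 0 <= self.gfp_positive <= self.embryos_recovered <= self.blastocysts_transferred:
            raise ConfigurationError(
                f"{self.stage_label}: counts must satisfy "
                "0 <= gfp <= recovered <= transferred"
            )
        stage_day(self.stage_label)  # validate early


def stage_day(label: str) -> float:
    m = _STAGE_RE.match(label.strip())
    if not m:
        raise ConfigurationError(f"unparseable stage label {label!r}")
    return float(m.group(1))


#: printed per-stage counts of the mouse complementation experiments
MOUSE_COMPLEMENTATION_LOG: tuple[StageRecord, ...] = (
    StageRecord("E9.5", 106, 17, 10),
    StageRecord("E10.5", 14, 6, 4),
    StageRecord("E11.5", 32, 7, 6),
    StageRecord("E12.5", 81, 2, 2),
)


@dataclass(frozen=True)
class SummaryRow:
    stage_label: str
    blastocysts_transferred: int
    embryos_recovered: int
    gfp_positive: int
    recovered_pct_of_transferred: float
    gfp_pct_of_transferred: float
    gfp_pct_of_recovered: Optional[float]  # None when nothing was recovered


@dataclass(frozen=True)
class SummaryTable:
    rows: tuple[SummaryRow, ...]
    totals: SummaryRow

    def to_dataframe(self, display: bool = False) -> pd.DataFrame:
        def fmt(x: Optional[float]):
            if x is None:
                return "NA" if display else float("nan")
            return format_percent(x) if display else round_half_up(x, 1)

        records = [
            {
                "stage": r.stage_label,
                "transferred": r.blastocysts_transferred,
                "recovered": r.embryos_recovered,
                "gfp_positive": r.gfp_positive,
                "recovered_pct": fmt(r.recovered_pct_of_transferred),
                "gfp_pct_of_transferred": fmt(r.gfp_pct_of_transferred),
                "gfp_pct_of_recovered": fmt(r.gfp_pct_of_recovered),
            }
            for r in (*self.rows, self.totals)
        ]
        return pd.DataFrame(records)


def _make_row(
    label: str, transferred: int, recovered: int, gfp: int
) -> SummaryRow:
    if transferred == 0:
        raise ConfigurationError(f"{label}: zero blastocysts transferred")
    return SummaryRow(
        stage_label=label,
        blastocysts_transferred=transferred,
        embryos_recovered=recovered,
        gfp_positive=gfp,
        recovered_pct_of_transferred=100.0 * recovered / transferred,
        gfp_pct_of_transferred=100.0 * gfp / transferred,
        gfp_pct_of_recovered=(100.0 * gfp / recovered) if recovered else None,
    )


def summarize(records: Sequence[StageRecord]) -> SummaryTable:
    """Per-stage recovery/GFP percentages plus a totals row.

    Percentages are computed at full precision; ``to_dataframe`` rounds
    half-up to one decimal for display. The totals row is computed from summed
    counts (not from averaging row percentages) and is invariant under row
    permutation.
    """
    if not records:
        raise ConfigurationError("no stage records")
    rows = tuple(
        _make_row(
            r.stage_label,
            r.blastocysts_transferred,
            r.embryos_recovered,
            r.gfp_positive,
        )
        for r in sorted(records, key=lambda r: stage_day(r.stage_label))
    )
    totals = _make_row(
        "total",
        sum(r.blastocysts_transferred for r in records),
        sum(r.embryos_recovered for r in records),
        sum(r.gfp_positive for r in records),
    )
    return SummaryTable(rows=rows, totals=totals)


def survival_beyond(records: Sequence[StageRecord], stage_threshold: str) -> int:
    """GFP-positive embryos recovered at ``stage_threshold`` or later."""
    threshold = stage_day(stage_threshold)
    return sum(
        r.gfp_positive for r in records if stage_day(r.stage_label) >= threshold
    )


def read_experiment_log(path) -> tuple[StageRecord, ...]:
    """Read a TSV/CSV experiment log (stage, transferred, recovered, gfp_positive)."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    cols = ["stage", "transferred", "recovered", "gfp_positive"]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ConfigurationError(f"experiment log missing columns {missing}")
    return tuple(
        StageRecord(
            str(r.stage), int(r.transferred), int(r.recovered), int(r.gfp_positive)
        )
        for r in df.itertuples(index=False)
    )
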