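"""ADME-rule triage of herbal compound tables.

Each compound carries four pharmacokinetic parameters — oral bioavailability
(OB, %), drug-likeness (DL, unitless in [0, 1]), Caco-2 monolayer permeability
(a signed transport-rate score) and half-life (HL, hours).  A compound is
retained when all four meet their thresholds (inclusive), the convention used
in systems-pharmacology triage of traditional-medicine formulas.  Compounds
that fail the rule can be rescued by id on external (literature) evidence;
rescue bypasses all four criteria.

Cross-herb deduplication is by case-folded compound *name*: the same
ingredient commonly appears in several herbs of a formula, and those
multiplicities are reported rather than collapsed away.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from . import io

logger = logging.getLogger(__name__)

#: Default herb vocabulary (abbreviations of the formula's ten constituent herbs).
DEFAULT_HERBS: tuple[str, ...] = (
    "RRR", "RA", "CM", "RSF", "RAM", "POR", "RPA", "RPM", "RSM", "HP",
)

_ADME_FIELDS = ("ob", "dl", "caco2", "hl")


class ValidationError(ValueError):
    """Raised for malformed compound records (missing/non-finite ADME values,
    duplicate (id, herb) rows) — never silently coerced to a screen failure."""


@dataclass(frozen=True)
class CompoundRecord:
    """One herb ingredient with its four ADME parameters."""

    compound_id: str
    name: str
    herb: str
    ob: float      # oral bioavailability, percent
    dl: float      # drug-likeness, [0, 1]
    caco2: float   # Caco-2 permeability score (signed)
    hl: float      # half-life, hours
    rescued: bool = False


@dataclass(frozen=True)
class AdmeThresholds:
    """Inclusive lower bounds on the four ADME parameters."""

    ob_min: float = 30.0
    dl_min: float = 0.18
    caco2_min: float = -0.4
    hl_min: float = 4.0


@dataclass
class ScreenReport:
    """Partition of the input table into ADME passes, rescues and rejects."""

    passing: list[CompoundRecord]
    rescued: list[CompoundRecord]
    rejected: list[CompoundRecord]
    per_herb_counts: dict[str, int]
    n_cross_herb_duplicates: int
    unknown_rescue_ids: list[str] = field(default_factory=list)

    @property
    def retained(self) -> list[CompoundRecord]:
        """Passing plus rescued — the active-compound set fed downstream."""
        return self.passing + self.rescued

    @property
    def n_retained_unique_names(self) -> int:
        """Distinct (case-folded) ingredient names among retained compounds."""
        return len({r.name.casefold() for r in self.retained})


def _validate_record(rec: CompoundRecord) -> None:
    for fname in _ADME_FIELDS:
        value = getattr(rec, fname)
        if value is None or not isinstance(value, (int, float)) or not math.isfinite(value):
            raise ValidationError(
                f"compound {rec.compound_id!r} ({rec.herb}): ADME field {fname!r} "
                f"is missing or non-finite ({value!r})"
            )


def passes_adme(record: CompoundRecord, thresholds: AdmeThresholds | None = None) -> bool:
    """True iff all four ADME parameters meet their thresholds (inclusive)."""
    t = thresholds or AdmeThresholds()
    _validate_record(record)
    return (
        record.ob >= t.ob_min
        and record.dl >= t.dl_min
        and record.caco2 >= t.caco2_min
        and record.hl >= t.hl_min
    )


def screen_compounds(
    table: Sequence[CompoundRecord],
    thresholds: AdmeThresholds | None = None,
    rescue_ids: Iterable[str] = (),
) -> ScreenReport:
    """Partition a compound table into ADME passes, rescues and rejects.

    ``rescue_ids`` are compound ids whose records are retained on literature
    evidence even when they fail the ADME rule.  Rescue ids not present in the
    table are logged and reported, not fatal.
    """
    t = thresholds or AdmeThresholds()
    rescue = set(rescue_ids)

    seen: set[tuple[str, str]] = set()
    for rec in table:
        key = (rec.compound_id, rec.herb)
        if key in seen:
            raise ValidationError(f"duplicate (compound_id, herb) row: {key}")
        seen.add(key)

    table_ids = {rec.compound_id for rec in table}
    unknown = sorted(rescue - table_ids)
    if unknown:
        logger.warning("rescue list has %d unknown compound ids: %s", len(unknown), unknown)

    passing: list[CompoundRecord] = []
    rescued: list[CompoundRecord] = []
    rejected: list[CompoundRecord] = []
    for rec in table:
        if passes_adme(rec, t):
            passing.append(rec)
        elif rec.compound_id in rescue:
            rescued.append(replace(rec, rescued=True))
        else:
            rejected.append(rec)

    retained = passing + rescued
    per_herb: dict[str, int] = {}
    for rec in retained:
        per_herb[rec.herb] = per_herb.get(rec.herb, 0) + 1

    # "Duplicate components": extra cross-herb occurrences of the same
    # ingredient name among retained compounds (sum of multiplicity - 1).
    herbs_by_name: dict[str, set[str]] = {}
    for rec in retained:
        herbs_by_name.setdefault(rec.name.casefold(), set()).add(rec.herb)
    n_dup = sum(len(h) - 1 for h in herbs_by_name.values() if len(h) > 1)

    return ScreenReport(
        passing=passing,
        rescued=rescued,
        rejected=rejected,
        per_herb_counts=per_herb,
        n_cross_herb_duplicates=n_dup,
        unknown_rescue_ids=unknown,
    )


def shared_ingredients(table: Sequence[CompoundRecord]) -> pd.DataFrame:
    """Ingredient names occurring under two or more distinct herbs.

    Returns a table with columns ``name``, ``herbs`` (comma-joined, in
    first-appearance order of the input) and ``multiplicity``.
    """
    herb_order: dict[str, int] = {}
    display_name: dict[str, str] = {}
    herbs_by_name: dict[str, list[str]] = {}
    for rec in table:
        if rec.herb not in herb_order:
            herb_order[rec.herb] = len(herb_order)
        key = rec.name.casefold()
        display_name.setdefault(key, rec.name)
        bucket = herbs_by_name.setdefault(key, [])
        if rec.herb not in bucket:
            bucket.append(rec.herb)

    rows = []
    for key in sorted(herbs_by_name):
        herbs = sorted(herbs_by_name[key], key=herb_order.__getitem__)
        if len(herbs) >= 2:
            rows.append(
                {"name": display_name[key], "herbs": ",".join(herbs), "multiplicity": len(herbs)}
            )
    return pd.DataFrame(rows, columns=["name", "herbs", "multiplicity"])


# ---------------------------------------------------------------------------
# I/O

def read_compound_table(path) -> list[CompoundRecord]:
    """TSV with columns compound_id, name, herb, ob, dl, caco2, hl."""
    df = io.read_tsv(path)
    required = {"compound_id", "name", "herb", *_ADME_FIELDS}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for idx, row in df.iterrows():
        vals = {}
        for fname in _ADME_FIELDS:
            raw = row[fname]
            try:
                vals[fname] = float(raw)
            except (TypeError, ValueError):
                raise ValidationError(
                    f"{path}: row {idx + 2}: ADME field {fname!r} is not numeric ({raw!r})"
                ) from None
        records.append(
            CompoundRecord(
                compound_id=row["compound_id"], name=row["name"], herb=row["herb"], **vals
            )
        )
    return records


def write_screen_report(report: ScreenReport, outdir) -> None:
    """Per-compound verdict TSV plus a JSON count summary."""
    outdir = Path(outdir)
    rows = []
    for verdict, recs in (
        ("pass", report.passing),
        ("rescued", report.rescued),
        ("rejected", report.rejected),
    ):
        for r in recs:
            rows.append(
                {
                    "compound_id": r.compound_id, "name": r.name, "herb": r.herb,
                    "ob": r.ob, "dl": r.dl, "caco2": r.caco2, "hl": r.hl,
                    "verdict": verdict,
                }
            )
    df = pd.DataFrame(
        rows, columns=["compound_id", "name", "herb", "ob", "dl", "caco2", "hl", "verdict"]
    ).sort_values(["herb", "compound_id"], kind="stable")
    io.write_tsv(df, outdir / "screen_verdicts.tsv")
    io.write_json(
        {
            "n_input": len(report.passing) + len(report.rescued) + len(report.rejected),
            "n_passing": len(report.passing),
            "n_rescued": len(report.rescued),
            "n_rejected": len(report.rejected),
            "n_retained": len(report.retained),
            "n_retained_unique_names": report.n_retained_unique_names,
            "n_cross_herb_duplicates": report.n_cross_herb_duplicates,
            "per_herb_counts": dict(sorted(report.per_herb_counts.items())),
            "unknown_rescue_ids": report.unknown_rescue_ids,
        },
        outdir / "screen_summary.json",
    )
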