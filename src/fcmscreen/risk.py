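"""TTC-based risk screening of identified substances.

Substances lacking toxicity data are screened with the threshold of
toxicological concern: each is assigned a Cramer structural hazard class
mapping to a tolerable daily intake (TDI, mg per person per day) —
Class I 1.80, Class II 0.54, Class III 0.09.  The estimated daily intake
(EDI) follows the European default that one person eats 1 kg of packed
food per day: EDI = migration (mg/kg) x 1 kg/day.

Screening rules per EU plastics regulation conventions:

* substances migrating at or below 0.00015 mg/kg (the limit when
  genotoxicity has not been discarded) are excluded from assessment;
* non-authorized substances (NIAS) pass when EDI <= TDI; migration at or
  above the 0.01 mg/kg functional-barrier ceiling is flagged for report;
* authorized substances (IAS) are compared against their specific
  migration limit (SML) instead; an authorized substance without a listed
  SML passes with a note.

Cramer classes are consumed from an annotation table (external structural
classification), never derived from structure here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CRAMER_TDI",
    "RiskConfig",
    "SubstanceRecord",
    "RiskRecord",
    "tdi_for_class",
    "edi",
    "screen",
    "report",
    "records_from_tables",
]

# TDI per Cramer class, mg per person per day.
CRAMER_TDI = {"I": 1.80, "II": 0.54, "III": 0.09}

_EPS = 1e-12


@dataclass(frozen=True)
class RiskConfig:
    """Thresholds for the screen, mg/kg food unless noted.

    ``consideration_threshold`` is strict ("over 0.00015"); the
    functional-barrier comparison is inclusive at printed precision, so a
    substance printed at exactly 0.010 counts as reaching 0.01.
    """

    consideration_threshold: float = 0.00015
    functional_barrier: float = 0.01
    daily_food_intake: float = 1.0  # kg/day

    def __post_init__(self) -> None:
        if min(self.consideration_threshold, self.functional_barrier, self.daily_food_intake) <= 0:
            raise ValueError("risk thresholds must be positive")


@dataclass
class SubstanceRecord:
    """Screen input: one identified substance with its annotations.

    ``migration`` None means below the quantifiable consideration cut-off.
    ``sml`` None on an IAS means authorized without a listed SML.
    """

    compound: str
    cas: Optional[str] = None
    migration: Optional[float] = None  # mg/kg food
    ias_flag: bool = False
    sml: Optional[float] = None  # mg/kg food
    cramer_class: Optional[str] = None  # I | II | III


@dataclass
class RiskRecord:
    compound: str
    cas: Optional[str]
    migration: Optional[float]
    ias_flag: bool
    sml: Optional[float]
    cramer_class: Optional[str]
    tdi: Optional[float]
    edi: Optional[float]
    considered: bool
    above_functional_barrier: bool
    verdict: str  # pass | exceed | excluded_below_threshold
    note: str = ""


def tdi_for_class(cramer_class: str) -> float:
    """Tolerable daily intake (mg/person/day) for a Cramer class."""
    try:
        return CRAMER_TDI[cramer_class]
    except KeyError:
        raise ValueError(
            f"unknown Cramer class {cramer_class!r}; expected one of {sorted(CRAMER_TDI)}"
        ) from None


def edi(migration: float, daily_food_intake: float = 1.0) -> float:
    """Estimated daily intake: migration (mg/kg) x food intake (kg/day)."""
    if migration < 0:
        raise ValueError("migration cannot be negative")
    return migration * daily_food_intake


def screen(records: Sequence[SubstanceRecord], cfg: RiskConfig = RiskConfig()) -> list[RiskRecord]:
    """Apply the TTC / SML screen to every substance."""
    out: list[RiskRecord] = []
    for rec in records:
        considered = rec.migration is not None and rec.migration > cfg.consideration_threshold
        above_fb = (
            rec.migration is not None
            and rec.migration >= cfg.functional_barrier - _EPS
        )
        if not considered:
            out.append(
                RiskRecord(
                    compound=rec.compound, cas=rec.cas, migration=rec.migration,
                    ias_flag=rec.ias_flag, sml=rec.sml, cramer_class=rec.cramer_class,
                    tdi=None, edi=None, considered=False, above_functional_barrier=above_fb,
                    verdict="excluded_below_threshold",
                    note="migration not over the 0.00015 mg/kg consideration cut-off",
                )
            )
            continue
        if rec.ias_flag:
            if rec.sml is None:
                verdict, note = "pass", "authorized, no SML listed"
            elif rec.migration <= rec.sml + _EPS:
                verdict, note = "pass", "migration within SML"
            else:
                verdict, note = "exceed", "migration above SML"
            tdi_val = edi_val = None
        else:
            if rec.cramer_class is None:
                raise ValueError(
                    f"considered NIAS {rec.compound!r} lacks a Cramer class annotation"
                )
            tdi_val = tdi_for_class(rec.cramer_class)
            edi_val = edi(rec.migration, cfg.daily_food_intake)
            if edi_val <= tdi_val + _EPS:
                verdict, note = "pass", "EDI within TDI"
            else:
                verdict, note = "exceed", "EDI above TDI"
        if above_fb and not rec.ias_flag:
            note += "; above 0.01 mg/kg functional-barrier level"
        out.append(
            RiskRecord(
                compound=rec.compound, cas=rec.cas, migration=rec.migration,
                ias_flag=rec.ias_flag, sml=rec.sml, cramer_class=rec.cramer_class,
                tdi=tdi_val, edi=edi_val, considered=True,
                above_functional_barrier=above_fb, verdict=verdict, note=note,
            )
        )
    return out


def report(records: Sequence[RiskRecord]) -> tuple[pd.DataFrame, dict]:
    """Assessment table sorted by migration descending, plus summary counts."""
    rows = [
        {
            "compound": r.compound,
            "cas": r.cas,
            "migration_mg_per_kg": r.migration,
            "ias": r.ias_flag,
            "sml_mg_per_kg": r.sml,
            "cramer_class": r.cramer_class,
            "tdi_mg_per_person_day": r.tdi,
            "edi_mg_per_person_day": r.edi,
            "considered": r.considered,
            "above_functional_barrier": r.above_functional_barrier,
            "verdict": r.verdict,
            "note": r.note,
        }
        for r in records
    ]
    df = pd.DataFrame(
        rows,
        columns=[
            "compound", "cas", "migration_mg_per_kg", "ias", "sml_mg_per_kg",
            "cramer_class", "tdi_mg_per_person_day", "edi_mg_per_person_day",
            "considered", "above_functional_barrier", "verdict", "note",
        ],
    )
    df = df.sort_values(
        ["migration_mg_per_kg", "compound"],
        ascending=[False, True], kind="stable", na_position="last",
    ).reset_index(drop=True)
    summary = {
        "n_substances": len(records),
        "n_considered": int(sum(r.considered for r in records)),
        "n_above_functional_barrier": int(sum(r.above_functional_barrier for r in records)),
        "n_exceedances": int(sum(r.verdict == "exceed" for r in records)),
    }
    logger.info(
        "risk screen: %(n_substances)d substances, %(n_considered)d considered, "
        "%(n_above_functional_barrier)d at/above the functional-barrier level, "
        "%(n_exceedances)d exceedances", summary,
    )
    return df, summary


def records_from_tables(
    identifications: pd.DataFrame, risk_table: pd.DataFrame
) -> list[SubstanceRecord]:
    """Join an identification table to a migration/annotation table by CAS.

    Identified substances absent from the migration table carry no
    migration value and screen as excluded_below_threshold.
    """
    by_cas = {row.cas: row for row in risk_table.itertuples(index=False)}
    records = []
    for row in identifications.itertuples(index=False):
        ann = by_cas.get(row.cas)
        records.append(
            SubstanceRecord(
                compound=row.compound,
                cas=row.cas,
                migration=float(ann.migration) if ann is not None else None,
                ias_flag=bool(row.ias),
                sml=_parse_sml(ann.sml) if ann is not None else None,
                cramer_class=(ann.cramer_class if ann is not None and isinstance(ann.cramer_class, str) and ann.cramer_class else None),
            )
        )
    return records


def _parse_sml(value) -> Optional[float]:
    """SML cell: a number, '-' (authorized, none listed), or blank (NIAS)."""
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    text = str(value).strip()
    if text in ("", "-"):
        return None
    return float(text)
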