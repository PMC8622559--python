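"""Tentative-identification gate and reporting.

A ranked candidate is *tentatively identified* when it clears every
criterion, all strict inequalities as printed in the identification
criteria:

* library match Total score > 90,
* exact-mass agreement < 2 ppm for at least 3 annotated fragments, or for
  2 fragments when the molecular ion is also observed,
* |delta RI| < 50 units against the library retention index, when the
  library provides one (absent RI makes the criterion vacuous and the most
  probable candidate by the ranking order is taken).

Identified features from replicate injections are merged per compound: a
compound is reported when identified in at least ``min_replicates``
replicates, keeping the best-scoring instance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd

from .matching import MatchConfig, MatchResult, rank_candidates
from .msdata import Feature, LibraryRecord, format_formula
from .rindex import AlkaneLadder, compute_ri

logger = logging.getLogger(__name__)

__all__ = [
    "GateConfig",
    "Identification",
    "apply_gate",
    "flag_ias",
    "build_identification_table",
]


@dataclass(frozen=True)
class GateConfig:
    """Identification thresholds; defaults are the screening criteria.

    All score/RI comparisons are strict: a candidate at exactly
    ``min_total_score`` or ``max_delta_ri`` fails.
    """

    min_total_score: float = 90.0  # exclusive
    max_delta_mass_ppm: float = 2.0  # exclusive, applied during annotation
    min_annotated_fragments: int = 3
    fragments_with_molion: int = 2
    max_delta_ri: float = 50.0  # exclusive
    ambiguity_margin: float = 1.0  # top-two total gap below which both are ambiguous
    min_replicates: int = 2

    def __post_init__(self) -> None:
        if min(self.min_total_score, self.max_delta_mass_ppm, self.max_delta_ri) <= 0:
            raise ValueError("gate thresholds must be positive")
        if self.fragments_with_molion > self.min_annotated_fragments:
            raise ValueError(
                "fragments_with_molion cannot exceed min_annotated_fragments"
            )
        if self.min_replicates < 1:
            raise ValueError("min_replicates must be >= 1")


@dataclass
class Identification:
    feature: Feature
    best: MatchResult
    status: str  # identified | rejected | ambiguous
    failed_criteria: list[str] = field(default_factory=list)
    ias_flag: bool = False
    sml: Optional[float] = None

    def __post_init__(self) -> None:
        if self.status == "identified" and self.failed_criteria:
            raise ValueError("identified status with non-empty failed criteria")


def apply_gate(m: MatchResult, cfg: GateConfig = GateConfig()) -> tuple[str, list[str]]:
    """Judge one scored candidate; returns (status, failed_criteria)."""
    failed: list[str] = []
    if not m.total > cfg.min_total_score:
        failed.append("total_score")
    frag_ok = m.n_fragments_within_tol >= cfg.min_annotated_fragments or (
        m.n_fragments_within_tol >= cfg.fragments_with_molion and m.molecular_ion_observed
    )
    if not frag_ok:
        failed.append("annotated_fragments")
    if m.delta_ri is not None and not m.delta_ri < cfg.max_delta_ri:
        failed.append("delta_ri")
    return ("identified" if not failed else "rejected"), failed


def flag_ias(
    identifications: Sequence[Identification],
    union_list: Mapping[str, Optional[float]],
) -> list[Identification]:
    """Mark authorized substances (IAS) and attach their SML in mg/kg.

    ``union_list`` maps CAS number to SML; a None value means the substance
    is authorized without a listed SML.  Identifications lacking a CAS are
    never IAS and are logged.
    """
    for ident in identifications:
        cas = ident.best.record.cas
        if cas is None:
            logger.warning(
                "identification %s has no CAS number; cannot check Union list",
                ident.best.record.name,
            )
            ident.ias_flag = False
            continue
        ident.ias_flag = cas in union_list
        ident.sml = union_list.get(cas)
    return list(identifications)


def _identify_feature(
    feature: Feature,
    library: Sequence[LibraryRecord],
    ladder: Optional[AlkaneLadder],
    cfg: GateConfig,
    match_cfg: MatchConfig,
    mass_list: Optional[Sequence[LibraryRecord]] = None,
) -> Optional[Identification]:
    query_ri = compute_ri(feature.rt, ladder) if ladder is not None else None
    ranked = rank_candidates(
        feature, library, match_cfg, query_ri=query_ri, mass_list=mass_list
    )
    best = ranked[0]
    status, failed = apply_gate(best, cfg)
    if (
        status == "identified"
        and len(ranked) > 1
        and best.total - ranked[1].total < cfg.ambiguity_margin
    ):
        runner_status, _ = apply_gate(ranked[1], cfg)
        if runner_status == "identified":
            status = "ambiguous"
    return Identification(feature=feature, best=best, status=status, failed_criteria=failed)


def build_identification_table(
    features: Sequence[Feature],
    library: Sequence[LibraryRecord],
    ladder: Optional[AlkaneLadder] = None,
    cfg: GateConfig = GateConfig(),
    match_cfg: MatchConfig = MatchConfig(),
    union_list: Optional[Mapping[str, Optional[float]]] = None,
    mass_list: Optional[Sequence[LibraryRecord]] = None,
) -> pd.DataFrame:
    """Run the gate over all features and merge replicates into one table.

    One row per reported compound: best-scoring identified instance across
    replicates, kept only when seen in >= ``cfg.min_replicates`` replicates.
    Deterministic: sorted by total score descending, then compound name.
    """
    idents: list[Identification] = []
    n_gated = 0
    for feat in features:
        ident = _identify_feature(feat, library, ladder, cfg, match_cfg, mass_list)
        if ident is None:
            continue
        if ident.status == "identified":
            n_gated += 1
            idents.append(ident)
    logger.info("gate: %d features in, %d identified", len(features), n_gated)
    if union_list:
        flag_ias(idents, union_list)

    by_compound: dict[str, list[Identification]] = {}
    for ident in idents:
        by_compound.setdefault(ident.best.record.name, []).append(ident)

    rows = []
    for name, group in by_compound.items():
        replicates = {i.feature.replicate_id for i in group}
        if len(replicates) < cfg.min_replicates:
            logger.info(
                "compound %s seen in %d replicate(s) < %d required; dropped",
                name, len(replicates), cfg.min_replicates,
            )
            continue
        best = max(group, key=lambda i: i.best.total)
        rec = best.best.record
        rows.append(
            {
                "compound": name,
                "cas": rec.cas,
                "formula": format_formula(rec.formula) if rec.formula else None,
                "total_score": round(best.best.total, 1),
                "si_score": round(best.best.si, 1),
                "hrf_score": round(best.best.hrf, 1) if best.best.hrf is not None else None,
                "delta_ri": round(best.best.delta_ri) if best.best.delta_ri is not None else None,
                "n_fragments": best.best.n_fragments_within_tol,
                "molecular_ion": best.best.molecular_ion_observed,
                "mass_list_hit": best.best.mass_list_hit,
                "ias": best.ias_flag,
                "sml": best.sml,
                "n_replicates": len(replicates),
                "feature_id": best.feature.feature_id,
                "replicate_id": best.feature.replicate_id,
                "rt_min": best.feature.rt,
                "area": best.feature.area,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "compound", "cas", "formula", "total_score", "si_score", "hrf_score",
            "delta_ri", "n_fragments", "molecular_ion", "mass_list_hit", "ias",
            "sml", "n_replicates", "feature_id", "replicate_id", "rt_min", "area",
        ],
    )
    return df.sort_values(
        ["total_score", "compound"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
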