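"""Spectral scoring of query EI spectra against library records.

Three scores drive identification:

* **SI (search index)** — the Stein-Scott composite spectral similarity:
  a weighted dot product over peaks paired within an m/z tolerance, with
  weight vectors w = intensity^0.6 * mz^3, blended with a paired-peak
  intensity-ratio term, scaled to 0-100.
* **HRF (high-resolution filtering)** — the fraction of spectral intensity
  explainable by exact-mass subformulas of the candidate molecular formula
  at a ppm tolerance, scaled to 0-100.  This is where high resolution
  separates true candidates from spectra that merely look similar.
* **Total** — a configurable weighted mean of SI and HRF (default 0.5/0.5).
  When a record carries no molecular formula the HRF is undefined and the
  total degrades to SI with an ``si_only`` flag; such candidates can never
  satisfy the exact-mass fragment criterion downstream.

Fragment annotation assigns each intense query peak the subformula of the
candidate whose radical-cation exact mass lies closest in ppm; EI cations
are charged, so every theoretical m/z subtracts one electron mass.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .msdata import (
    ELECTRON_MASS,
    ISOTOPE_MASSES,
    ElementalFormula,
    Feature,
    LibraryRecord,
    Spectrum,
    monoisotopic_mass,
    ppm_error,
)
from .rindex import RIValue, delta_ri as _delta_ri

__all__ = [
    "MatchConfig",
    "FragmentAnnotation",
    "MatchResult",
    "pair_peaks",
    "si_score",
    "enumerate_subformulas",
    "hrf_score",
    "total_score",
    "annotate_fragments",
    "rank_candidates",
]

MAX_PARENT_ATOMS = 120  # subformula enumeration is combinatorial beyond this


@dataclass(frozen=True)
class MatchConfig:
    """Tolerances and weights for spectral matching.

    mz_tol_pairing : Th, peak-pairing tolerance for the SI dot product
        (HRMS centroids; ppm tolerances apply to annotation, not pairing).
    tol_ppm : ppm tolerance for subformula assignment and molecular-ion
        detection (identification criterion: < 2 ppm).
    si_weight, hrf_weight : contributions to the Total score; must sum to 1.
    intensity_floor_frac : fraction of the base peak below which peaks are
        ignored by HRF (deconvolution leaves low-level noise centroids).
    top_n_fragments : how many of the most intense peaks to annotate.
    """

    mz_tol_pairing: float = 0.005
    tol_ppm: float = 2.0
    si_weight: float = 0.5
    hrf_weight: float = 0.5
    intensity_floor_frac: float = 0.001
    top_n_fragments: int = 10

    def __post_init__(self) -> None:
        if self.si_weight < 0 or self.hrf_weight < 0 or abs(
            self.si_weight + self.hrf_weight - 1.0
        ) > 1e-9:
            raise ValueError(
                f"si_weight + hrf_weight must equal 1 "
                f"(got {self.si_weight} + {self.hrf_weight})"
            )
        if self.top_n_fragments < 3:
            raise ValueError("top_n_fragments must be >= 3 (identification needs 3 fragments)")
        if self.mz_tol_pairing <= 0 or self.tol_ppm <= 0:
            raise ValueError("tolerances must be positive")


@dataclass
class FragmentAnnotation:
    """A query peak assigned an exact-mass subformula of the candidate."""

    mz: float
    intensity: float
    subformula: ElementalFormula
    theoretical_mz: float
    delta_ppm: float  # signed, recorded as computed
    is_molecular_ion: bool = False
    alternatives: list[ElementalFormula] = field(default_factory=list)


@dataclass
class MatchResult:
    record: LibraryRecord
    si: float
    hrf: Optional[float]
    total: float
    si_only: bool
    annotations: list[FragmentAnnotation]
    n_fragments_within_tol: int
    molecular_ion_observed: bool
    delta_ri: Optional[float] = None
    mass_list_hit: bool = False


# ---------------------------------------------------------------------------
# Search-index similarity
# ---------------------------------------------------------------------------


def pair_peaks(query: Spectrum, library: Spectrum, mz_tol: float) -> list[tuple[int, int]]:
    """Greedy one-to-one peak pairing within ``mz_tol`` Th.

    Candidate pairs are taken in order of ascending |delta m/z|; each peak
    is used at most once.  Deterministic for tied distances (query index,
    then library index).
    """
    candidates: list[tuple[float, int, int]] = []
    j0 = 0
    for i, mq in enumerate(query.mz):
        while j0 < len(library.mz) and library.mz[j0] < mq - mz_tol:
            j0 += 1
        j = j0
        while j < len(library.mz) and library.mz[j] <= mq + mz_tol:
            candidates.append((abs(mq - library.mz[j]), i, j))
            j += 1
    candidates.sort()
    used_q: set[int] = set()
    used_l: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for _, i, j in candidates:
        if i not in used_q and j not in used_l:
            pairs.append((i, j))
            used_q.add(i)
            used_l.add(j)
    pairs.sort()
    return pairs


def _si_weights(s: Spectrum) -> np.ndarray:
    return s.intensities**0.6 * s.mz**3


def si_score(query: Spectrum, library: Spectrum, mz_tol: float = 0.005) -> float:
    """Stein-Scott composite similarity, scaled to 0-100.

    F_dot is the squared cosine between the weighted vectors restricted to
    paired peaks (unpaired peaks contribute only to the norms); F_ratio
    averages min(r, 1/r) over consecutive paired-peak intensity ratios
    r_i = (Q_i/Q_{i-1}) (L_{i-1}/L_i).  The composite is the peak-count
    weighted blend (N_q F_dot + N_pairs F_ratio) / (N_q + N_pairs).
    Invariant under uniform intensity scaling of either spectrum.
    """
    if len(query) == 0 or len(library) == 0:
        raise ValueError("cannot score an empty spectrum")
    pairs = pair_peaks(query, library, mz_tol)
    wq, wl = _si_weights(query), _si_weights(library)
    norm = wq @ wq * (wl @ wl)
    if norm == 0:
        raise ValueError("cannot score an all-zero-intensity spectrum")
    if not pairs:
        return 0.0
    dot = float(sum(wq[i] * wl[j] for i, j in pairs))
    f_dot = dot * dot / norm
    ratio_pairs = [
        (query.intensities[i], library.intensities[j])
        for i, j in pairs
        if query.intensities[i] > 0 and library.intensities[j] > 0
    ]
    if len(ratio_pairs) >= 2:
        terms = []
        for (q1, l1), (q0, l0) in zip(ratio_pairs[1:], ratio_pairs[:-1]):
            r = (q1 / q0) * (l0 / l1)
            terms.append(min(r, 1.0 / r))
        f_ratio = float(np.mean(terms))
        composite = (len(query) * f_dot + len(pairs) * f_ratio) / (len(query) + len(pairs))
    else:
        composite = f_dot
    return 100.0 * composite


# ---------------------------------------------------------------------------
# Subformula enumeration and high-resolution filtering
# ---------------------------------------------------------------------------


def enumerate_subformulas(
    parent: ElementalFormula,
    target_mz: float,
    tol_ppm: float = 2.0,
    max_atoms: int = MAX_PARENT_ATOMS,
) -> list[tuple[ElementalFormula, float]]:
    """All subformulas of ``parent`` whose cation exact mass hits ``target_mz``.

    A subformula f satisfies 0 <= f <= parent elementwise and
    |ppm(mass(f) - m_e, target)| <= tol_ppm.  Results are ordered by
    ascending |delta ppm|, ties by fewer heteroatoms (non-CH atoms) then by
    formula string, making downstream assignment deterministic.

    Depth-first search over per-element counts, heaviest element first,
    pruned by the attainable mass window; exact for any parent, capped at
    ``max_atoms`` atoms because the worst case is combinatorial.
    """
    if parent.is_empty:
        raise ValueError("parent formula is empty")
    if parent.n_atoms > max_atoms:
        raise ValueError(
            f"parent has {parent.n_atoms} atoms; enumeration capped at {max_atoms}"
        )
    lo = target_mz * (1.0 - tol_ppm * 1e-6)
    hi = target_mz * (1.0 + tol_ppm * 1e-6)
    elems = sorted(parent.counts.items(), key=lambda kv: -ISOTOPE_MASSES[kv[0]])
    masses = [ISOTOPE_MASSES[sym] for sym, _ in elems]
    # suffix_max[i]: largest mass attainable from elements i..end
    suffix_max = [0.0] * (len(elems) + 1)
    for i in range(len(elems) - 1, -1, -1):
        suffix_max[i] = suffix_max[i + 1] + masses[i] * elems[i][1]

    hits: list[tuple[ElementalFormula, float]] = []
    counts = [0] * len(elems)

    def descend(i: int, acc: float) -> None:
        if acc - ELECTRON_MASS > hi:
            return
        if acc + suffix_max[i] - ELECTRON_MASS < lo:
            return
        if i == len(elems):
            mz = acc - ELECTRON_MASS
            if lo <= mz <= hi and any(counts):
                hits.append(
                    (ElementalFormula(dict(zip((s for s, _ in elems), counts)), charge=1), mz)
                )
            return
        sym, cmax = elems[i]
        for k in range(cmax + 1):
            counts[i] = k
            descend(i + 1, acc + k * masses[i])
        counts[i] = 0

    descend(0, 0.0)

    def sort_key(item: tuple[ElementalFormula, float]):
        f, mz = item
        hetero = sum(n for s, n in f.counts.items() if s not in ("C", "H"))
        return (abs(ppm_error(target_mz, mz)), hetero, str(f))

    hits.sort(key=sort_key)
    return hits


def hrf_score(
    query: Spectrum,
    candidate_formula: ElementalFormula,
    tol_ppm: float = 2.0,
    intensity_floor_frac: float = 0.001,
) -> float:
    """Intensity-weighted explained fraction of the spectrum, 0-100.

    Peaks below ``intensity_floor_frac`` of the base peak are ignored.  A
    peak is explained when at least one subformula of the candidate has a
    cation exact mass within ``tol_ppm``.  Monotone non-decreasing in
    ``tol_ppm``.
    """
    base = query.base_peak_intensity
    if base <= 0:
        raise ValueError("cannot score an all-zero-intensity spectrum")
    floor = intensity_floor_frac * base
    keep = query.intensities >= floor
    total = float(query.intensities[keep].sum())
    explained = 0.0
    for mz, inten in zip(query.mz[keep], query.intensities[keep]):
        if enumerate_subformulas(candidate_formula, float(mz), tol_ppm):
            explained += float(inten)
    return 100.0 * explained / total


def total_score(
    si: float, hrf: Optional[float], weights: tuple[float, float] = (0.5, 0.5)
) -> tuple[float, bool]:
    """Weighted mean of SI and HRF; (score, si_only).

    With HRF unavailable (record without a molecular formula) the score
    degrades to SI and ``si_only`` is True.
    """
    w_si, w_hrf = weights
    if w_si < 0 or w_hrf < 0 or abs(w_si + w_hrf - 1.0) > 1e-9:
        raise ValueError(f"weights must be non-negative and sum to 1, got {weights}")
    for name, val in (("si", si), ("hrf", hrf)):
        if val is not None and not 0.0 <= val <= 100.0 + 1e-9:
            raise ValueError(f"{name} score out of [0, 100]: {val}")
    if hrf is None:
        return si, True
    return w_si * si + w_hrf * hrf, False


def annotate_fragments(
    query: Spectrum,
    candidate_formula: ElementalFormula,
    tol_ppm: float = 2.0,
    top_n: int = 10,
) -> tuple[list[FragmentAnnotation], bool]:
    """Assign exact-mass subformulas to the ``top_n`` most intense peaks.

    Each annotated peak carries the best (lowest |ppm|) subformula; near-tie
    alternatives are kept in a diagnostics field.  Returns the annotations
    and whether the molecular ion (radical-cation mass of the full formula)
    is observed within tolerance anywhere in the spectrum.
    """
    if top_n < 3:
        raise ValueError("top_n must be >= 3")
    mol_mz = monoisotopic_mass(candidate_formula, as_radical_cation=True)
    molecular_ion_observed = bool(
        np.any(np.abs(query.mz - mol_mz) <= mol_mz * tol_ppm * 1e-6)
    )
    order = np.argsort(-query.intensities, kind="stable")[:top_n]
    annotations: list[FragmentAnnotation] = []
    for idx in sorted(order):
        mz = float(query.mz[idx])
        hits = enumerate_subformulas(candidate_formula, mz, tol_ppm)
        if not hits:
            continue
        best_f, best_mz = hits[0]
        annotations.append(
            FragmentAnnotation(
                mz=mz,
                intensity=float(query.intensities[idx]),
                subformula=best_f,
                theoretical_mz=best_mz,
                delta_ppm=ppm_error(mz, best_mz),
                is_molecular_ion=(best_f.counts == candidate_formula.counts),
                alternatives=[f for f, _ in hits[1:]],
            )
        )
    return annotations, molecular_ion_observed


# ---------------------------------------------------------------------------
# Candidate ranking
# ---------------------------------------------------------------------------


def score_candidate(
    query: Spectrum,
    record: LibraryRecord,
    cfg: MatchConfig = MatchConfig(),
    query_ri: Optional[RIValue] = None,
    mass_list_formulas: Optional[set[ElementalFormula]] = None,
) -> MatchResult:
    """Full scoring of one library record against one query spectrum."""
    si = si_score(query, record.spectrum, cfg.mz_tol_pairing)
    if record.usable_for_hrf:
        hrf = hrf_score(query, record.formula, cfg.tol_ppm, cfg.intensity_floor_frac)
        annotations, mol_ion = annotate_fragments(
            query, record.formula, cfg.tol_ppm, cfg.top_n_fragments
        )
    else:
        hrf, annotations, mol_ion = None, [], False
    total, si_only = total_score(si, hrf, (cfg.si_weight, cfg.hrf_weight))
    n_frag = sum(1 for a in annotations if not a.is_molecular_ion)
    dri = None
    if query_ri is not None:
        dri = _delta_ri(query_ri, record.library_ri)
    neutral_formula = (
        ElementalFormula(record.formula.counts) if record.formula is not None else None
    )
    hit = bool(
        mass_list_formulas
        and neutral_formula is not None
        and neutral_formula in mass_list_formulas
        and mol_ion
    )
    return MatchResult(
        record=record,
        si=si,
        hrf=hrf,
        total=total,
        si_only=si_only,
        annotations=annotations,
        n_fragments_within_tol=n_frag,
        molecular_ion_observed=mol_ion,
        delta_ri=dri,
        mass_list_hit=hit,
    )


def rank_candidates(
    query: Feature | Spectrum,
    library: Sequence[LibraryRecord],
    cfg: MatchConfig = MatchConfig(),
    query_ri: Optional[RIValue] = None,
    mass_list: Optional[Sequence[LibraryRecord]] = None,
) -> list[MatchResult]:
    """Score every library record and sort best-first.

    Order: total score descending; ties by more fragments within tolerance,
    then smaller |delta RI| (absent RI sorts last), then record name — fully
    deterministic.
    """
    if not library:
        raise ValueError("library must be non-empty")
    spectrum = query.spectrum if isinstance(query, Feature) else query
    ml_formulas = (
        {ElementalFormula(r.formula.counts) for r in mass_list if r.formula is not None}
        if mass_list
        else None
    )
    results = [
        score_candidate(spectrum, rec, cfg, query_ri=query_ri, mass_list_formulas=ml_formulas)
        for rec in library
    ]
    results.sort(
        key=lambda m: (
            -m.total,
            -m.n_fragments_within_tol,
            m.delta_ri if m.delta_ri is not None else float("inf"),
            m.record.name,
        )
    )
    return results
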