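"""Hermetic synthetic fixtures and the packaged reference dataset.

Two jobs live here:

1. A seeded generator that emulates deconvoluted GC-EI-HRMS screening data:
   a spectral library whose fragment peaks sit at exact radical-cation
   subformula masses (random atom-subset deletion, not bond-aware
   chemistry), triplicate feature tables with planted compounds, shuffled
   decoys and spiked internal standards, and an n-alkane ladder whose
   piecewise-linear retention model the RI calculation inverts exactly.
   Everything is byte-deterministic under a fixed seed and ground truth is
   persisted alongside, so recovery can be scored without external data.

2. Loaders for the packaged reference tables transcribed from a published
   screening study of a post-consumer recycled LDPE film: 83 tentatively
   identified substances (12 of them authorized/IAS) and the 45-substance
   migration/risk table.  Checksums guard the transcriptions against
   accidental edits.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .msdata import (
    ElementalFormula,
    Feature,
    LibraryRecord,
    Spectrum,
    monoisotopic_mass,
    parse_formula,
    write_feature_table,
    write_msp,
)
from .quantify import NG_PER_ML_TO_MG_PER_ML, ExtractGeometry, InternalStandard, concentration_to_migration
from .rindex import AlkaneLadder

__all__ = [
    "SimulationConfig",
    "SimulatedStudy",
    "default_ladder",
    "rt_for_ri",
    "make_library",
    "simulate_runs",
    "simulate_study",
    "write_study",
    "load_reference_identifications",
    "load_reference_risk_table",
    "reference_union_list",
]

_DATA_CHECKSUMS = {
    "recycled_ldpe_identifications.csv": "54b7e590d049059ffe9b5eed3f2e07dd4868075b1fc2793f9130fb07b21cea4f",
    "recycled_ldpe_risk.csv": "ed084a2e86353566f8dabf4606207cf2acdf82339febd07de554eb9a8adc1902",
}

# Spiked isotope-labelled internal standards (name, CAS, formula, ng/mL).
INTERNAL_STANDARD_DEFS = [
    ("Phenol-13C6", "89059-34-7", "[13C]6 H6 O", 200.0),
    ("Benzophenone-D10", "22583-75-1", "C13 D10 O", 200.0),
    ("Bis(2-ethylhexyl) phthalate-D4", "93951-87-2", "C24 H34 D4 O4", 200.0),
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic screening experiment.

    Defaults mirror the emulated acquisition: triplicate injections,
    200 ng/mL internal standards, m/z 40-500 acquisition window, and a
    70-minute temperature-programmed run.  Noise scales (1 ppm m/z, 5%
    intensity) sit at the instrument-performance level the identification
    tolerances are designed around.
    """

    seed: int = 1
    n_planted: int = 20
    n_decoys: int = 20
    n_replicates: int = 3
    mz_noise_ppm: float = 1.0
    intensity_noise_frac: float = 0.05
    rt_jitter_min: float = 0.02
    run_duration: float = 70.0  # min
    mass_range: tuple[float, float] = (40.0, 500.0)
    n_fragments: tuple[int, int] = (8, 20)
    is_spiked_conc: float = 200.0  # ng/mL
    true_response_factor: float = 5000.0  # area per ng/mL
    conc_range: tuple[float, float] = (5.0, 500.0)  # ng/mL, log-uniform

    def __post_init__(self) -> None:
        if min(self.mz_noise_ppm, self.intensity_noise_frac, self.rt_jitter_min) < 0:
            raise ValueError("noise scales must be >= 0")
        if self.n_planted < 0 or self.n_decoys < 0 or self.n_replicates < 1:
            raise ValueError("invalid simulation sizes")


@dataclass
class SimulatedStudy:
    """Everything one simulated screening study produced."""

    library: list[LibraryRecord]
    features: list[Feature]  # all replicates pooled; replicate_id distinguishes
    ladder: AlkaneLadder
    internal_standards: list[InternalStandard]
    truth: pd.DataFrame  # compound, formula, ri, conc ng/mL, migration mg/kg
    decoy_ids: set[str] = field(default_factory=set)
    geometry: ExtractGeometry = field(default_factory=ExtractGeometry)


def default_ladder(run_duration: float = 70.0) -> AlkaneLadder:
    """C8-C20 plus even C22-C40 anchors on a mildly convex retention model."""
    carbons = list(range(8, 21)) + list(range(22, 41, 2))
    scale = (run_duration - 10.0) / (40.0 - 8.0 + 0.4 * np.sqrt(32.0))
    anchors = [
        (c, 3.0 + scale * ((c - 8) + 0.4 * np.sqrt(c - 8))) for c in carbons
    ]
    return AlkaneLadder(anchors)


def rt_for_ri(ri: float, ladder: AlkaneLadder) -> float:
    """Invert the ladder's piecewise-linear RI model (exact at anchors)."""
    c, t = ladder.carbons, ladder.rts
    ris = [100.0 * x for x in c]
    if ri <= ris[0]:
        lo, hi = 0, 1
    elif ri >= ris[-1]:
        lo, hi = len(c) - 2, len(c) - 1
    else:
        lo = max(i for i in range(len(c) - 1) if ris[i] <= ri)
        hi = lo + 1
    return t[lo] + (ri - ris[lo]) / (ris[hi] - ris[lo]) * (t[hi] - t[lo])


def _reference_formula_pool() -> list[str]:
    """Molecular formulas of the packaged reference identifications."""
    return sorted(set(load_reference_identifications()["formula"]))


def _random_subformula(
    parent: ElementalFormula, rng: np.random.Generator, mass_range: tuple[float, float]
) -> Optional[tuple[ElementalFormula, float]]:
    """Delete a random atom subset; None when the cation mass misses the window."""
    counts = {sym: int(rng.integers(0, n + 1)) for sym, n in parent.counts.items()}
    if not any(counts.values()):
        return None
    sub = ElementalFormula(counts, charge=1)
    mz = monoisotopic_mass(sub, as_radical_cation=True)
    if not mass_range[0] <= mz <= mass_range[1]:
        return None
    return sub, mz


def make_library(
    formulas: Sequence[ElementalFormula | str],
    cfg: SimulationConfig = SimulationConfig(),
    rng: Optional[np.random.Generator] = None,
) -> tuple[list[LibraryRecord], pd.DataFrame]:
    """Generate one library record per formula, plus a ground-truth table.

    Each record gets 8-20 fragment peaks at exact radical-cation subformula
    masses with log-normal intensities, the molecular ion when it falls in
    the acquisition window, and a library retention index drawn over the
    ladder range.  Formulas too small for the requested fragment count get
    fewer fragments.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    records: list[LibraryRecord] = []
    truth_rows = []
    for i, f in enumerate(formulas):
        parent = parse_formula(f) if isinstance(f, str) else f
        name = f"SYN-{i:03d} {parent}"
        want = int(rng.integers(cfg.n_fragments[0], cfg.n_fragments[1] + 1))
        frags: dict[float, ElementalFormula] = {}
        for _ in range(60 * want):
            hit = _random_subformula(parent, rng, cfg.mass_range)
            if hit is not None:
                sub, mz = hit
                frags.setdefault(round(mz, 6), sub)
            if len(frags) >= want:
                break
        mol_mz = monoisotopic_mass(parent, as_radical_cation=True)
        has_mol_ion = cfg.mass_range[0] <= mol_mz <= cfg.mass_range[1]
        if has_mol_ion:
            frags[round(mol_mz, 6)] = ElementalFormula(parent.counts, charge=1)
        if len(frags) < cfg.n_fragments[0]:
            warnings.warn(
                f"{name}: only {len(frags)} fragments fit the acquisition window "
                f"(requested {want})",
                stacklevel=2,
            )
        mzs = sorted(frags)
        intensities = rng.lognormal(mean=4.0, sigma=1.0, size=len(mzs))
        ri = float(rng.uniform(850.0, 3800.0))
        records.append(
            LibraryRecord(
                name=name,
                spectrum=Spectrum(mzs, intensities),
                formula=parent,
                cas=f"SYN-{i:03d}",
                library_ri=ri,
                source_tag="synthetic-library",
            )
        )
        truth_rows.append(
            {
                "compound": name,
                "formula": str(parent),
                "library_ri": ri,
                "molecular_ion_in_range": has_mol_ion,
                "n_library_peaks": len(mzs),
            }
        )
    return records, pd.DataFrame(truth_rows)


def _perturb_spectrum(
    s: Spectrum, rng: np.random.Generator, mz_noise_ppm: float, intensity_noise_frac: float
) -> Spectrum:
    # bounded perturbations: instrument mass accuracy is specified as a
    # bound, so every peak stays within +-mz_noise_ppm of its exact mass
    mz = s.mz * (1.0 + rng.uniform(-mz_noise_ppm, mz_noise_ppm, size=len(s)) * 1e-6)
    inten = s.intensities * (
        1.0 + rng.uniform(-intensity_noise_frac, intensity_noise_frac, size=len(s))
    )
    return Spectrum(mz, inten)


def _decoy_spectrum(
    library: Sequence[LibraryRecord], rng: np.random.Generator
) -> Spectrum:
    """Shuffle m/z values across compounds: realistic peak statistics,
    wrong exact-mass structure for every library formula."""
    pool = np.concatenate([rec.spectrum.mz for rec in library])
    template = library[int(rng.integers(len(library)))].spectrum
    n = len(template)
    mz = rng.choice(pool, size=n, replace=False) if len(pool) >= n else pool
    # break exact-mass structure: shift each m/z by 30-80 ppm, above any
    # annotation tolerance but far below the 0.005 Th pairing scale at low m/z
    mz = np.sort(mz) * (1.0 + rng.uniform(30e-6, 80e-6, size=len(mz)) * rng.choice([-1, 1], size=len(mz)))
    mz = np.unique(mz)
    inten = rng.permutation(template.intensities)[: len(mz)]
    if len(inten) < len(mz):
        mz = mz[: len(inten)]
    return Spectrum(mz, inten)


def simulate_runs(
    library: Sequence[LibraryRecord],
    cfg: SimulationConfig = SimulationConfig(),
    geometry: ExtractGeometry = ExtractGeometry(),
) -> SimulatedStudy:
    """Simulate triplicate injections of planted compounds plus decoys.

    Retention times come from inverting the ladder's RI model at each
    compound's library RI (plus jitter); areas follow the configured true
    response factor and a log-uniform concentration per compound; spectra
    are the library spectra perturbed by the configured m/z and intensity
    noise.  Internal-standard areas are consistent with the same response
    factor.  Ground truth (true concentration and migration per compound)
    is carried on the returned study.
    """
    rng = np.random.default_rng(cfg.seed)
    ladder = default_ladder(cfg.run_duration)
    planted = list(library[: cfg.n_planted])
    concs = np.exp(
        rng.uniform(np.log(cfg.conc_range[0]), np.log(cfg.conc_range[1]), size=len(planted))
    )
    features: list[Feature] = []
    decoy_ids: set[str] = set()
    for rep in range(1, cfg.n_replicates + 1):
        rep_id = f"r{rep}"
        for i, (rec, conc) in enumerate(zip(planted, concs)):
            rt = rt_for_ri(rec.library_ri, ladder) + rng.normal(0.0, cfg.rt_jitter_min)
            area = conc * cfg.true_response_factor * np.exp(
                rng.normal(0.0, cfg.intensity_noise_frac)
            )
            features.append(
                Feature(
                    feature_id=f"{rep_id}-P{i:03d}",
                    rt=float(max(rt, 0.1)),
                    area=float(area),
                    spectrum=_perturb_spectrum(
                        rec.spectrum, rng, cfg.mz_noise_ppm, cfg.intensity_noise_frac
                    ),
                    replicate_id=rep_id,
                )
            )
        for j in range(cfg.n_decoys):
            fid = f"{rep_id}-D{j:03d}"
            decoy_ids.add(fid)
            features.append(
                Feature(
                    feature_id=fid,
                    rt=float(rng.uniform(ladder.rts[0], ladder.rts[-1])),
                    area=float(rng.lognormal(11.0, 1.0)),
                    spectrum=_decoy_spectrum(library, rng),
                    replicate_id=rep_id,
                )
            )
    standards = []
    for name, cas, formula, _ in INTERNAL_STANDARD_DEFS:
        f = parse_formula(formula)
        areas = [
            float(
                cfg.is_spiked_conc
                * cfg.true_response_factor
                * np.exp(rng.normal(0.0, cfg.intensity_noise_frac))
            )
            for _ in range(cfg.n_replicates)
        ]
        mz_theo = monoisotopic_mass(f, as_radical_cation=True)
        standards.append(
            InternalStandard(
                name=name,
                cas=cas,
                formula=f,
                spiked_conc=cfg.is_spiked_conc,
                areas=areas,
                rts=[float(rng.uniform(5, 60)) for _ in range(cfg.n_replicates)],
                observed_mzs=[
                    mz_theo * (1.0 + rng.uniform(-cfg.mz_noise_ppm, cfg.mz_noise_ppm) * 1e-6)
                    for _ in range(cfg.n_replicates)
                ],
            )
        )
    truth = pd.DataFrame(
        {
            "compound": [rec.name for rec in planted],
            "cas": [rec.cas for rec in planted],
            "formula": [str(rec.formula) for rec in planted],
            "library_ri": [rec.library_ri for rec in planted],
            "true_conc_ng_ml": concs,
            "true_migration_mg_kg": [
                concentration_to_migration(c * NG_PER_ML_TO_MG_PER_ML, geometry)
                for c in concs
            ],
            # external structural classification stands behind these in real
            # studies; here classes are drawn at plausible frequencies
            "cramer_class": rng.choice(
                ["I", "II", "III"], size=len(planted), p=[0.6, 0.15, 0.25]
            ),
        }
    )
    return SimulatedStudy(
        library=list(library),
        features=features,
        ladder=ladder,
        internal_standards=standards,
        truth=truth,
        decoy_ids=decoy_ids,
        geometry=geometry,
    )


def simulate_study(cfg: SimulationConfig = SimulationConfig()) -> SimulatedStudy:
    """Library + runs in one call, with formulas drawn from the packaged
    reference identifications (a realistic plastic-related formula pool)."""
    rng = np.random.default_rng(cfg.seed)
    pool = _reference_formula_pool()
    n = min(cfg.n_planted + cfg.n_decoys, len(pool))
    chosen = list(rng.choice(pool, size=n, replace=False))
    library, _ = make_library(chosen, cfg, rng)
    return simulate_runs(library, cfg)


def write_study(study: SimulatedStudy, outdir: str | Path) -> dict[str, Path]:
    """Persist a simulated study in the formats the pipeline consumes."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "library": out / "library.msp",
        "features_csv": out / "features.csv",
        "features_msp": out / "features.msp",
        "ladder": out / "ladder.csv",
        "standards": out / "internal_standards.csv",
        "truth": out / "ground_truth.csv",
    }
    write_msp(study.library, paths["library"])
    write_feature_table(study.features, paths["features_csv"], paths["features_msp"])
    pd.DataFrame(
        {"carbon_number": study.ladder.carbons, "rt_min": study.ladder.rts}
    ).to_csv(paths["ladder"], index=False)
    pd.DataFrame(
        [
            {
                "name": s.name,
                "cas": s.cas,
                "formula": str(s.formula) if s.formula else "",
                "spiked_conc_ng_ml": s.spiked_conc,
                "replicate": f"r{i + 1}",
                "area": a,
                "rt_min": rt,
                "observed_mz": mz,
            }
            for s in study.internal_standards
            for i, (a, rt, mz) in enumerate(zip(s.areas, s.rts, s.observed_mzs))
        ]
    ).to_csv(paths["standards"], index=False)
    study.truth.to_csv(paths["truth"], index=False)
    paths["annotations"] = out / "annotations.csv"
    study.truth[["compound", "cas", "cramer_class"]].assign(ias=0, sml="").to_csv(
        paths["annotations"], index=False
    )
    return paths


# ---------------------------------------------------------------------------
# Packaged reference dataset (recycled LDPE screening study)
# ---------------------------------------------------------------------------


def _load_packaged_csv(filename: str, **kwargs) -> pd.DataFrame:
    ref = resources.files("fcmscreen") / "data" / filename
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _DATA_CHECKSUMS[filename]:
        raise RuntimeError(
            f"packaged table {filename} is corrupted (checksum {digest[:12]}… unexpected)"
        )
    from io import BytesIO

    return pd.read_csv(BytesIO(raw), **kwargs)


def load_reference_identifications() -> pd.DataFrame:
    """83 tentatively identified substances from the recycled LDPE film.

    Columns: category, compound, cas, formula, total_score, delta_ri
    (blank where no library RI existed), ias (1 for Union-list substances).
    """
    return _load_packaged_csv(
        "recycled_ldpe_identifications.csv", dtype={"cas": str}
    )


def load_reference_risk_table() -> pd.DataFrame:
    """45-substance migration/risk table for the recycled LDPE film.

    Migration, SML, TDI and EDI in mg-based units as printed in the source
    dataset; SML '-' means authorized with no listed SML.
    """
    return _load_packaged_csv(
        "recycled_ldpe_risk.csv",
        dtype={"cas": str, "sml": str, "cramer_class": str},
        keep_default_na=True,
    )


def reference_union_list() -> dict[str, Optional[float]]:
    """CAS → SML (mg/kg) for the packaged Union-list (IAS) subset."""
    ident = load_reference_identifications()
    risk = load_reference_risk_table()
    sml_by_cas: dict[str, Optional[float]] = {}
    for row in risk.itertuples(index=False):
        text = "" if pd.isna(row.sml) else str(row.sml).strip()
        if text and text != "-":
            sml_by_cas[row.cas] = float(text)
    return {
        row.cas: sml_by_cas.get(row.cas)
        for row in ident.itertuples(index=False)
        if row.ias == 1
    }
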