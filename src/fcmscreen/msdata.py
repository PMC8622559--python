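"""Elemental-formula algebra, exact-mass arithmetic, and spectral/tabular IO.

Every downstream stage (library matching, fragment annotation, retention
indexing, quantification) consumes the containers defined here: centroided
EI spectra, library records in NIST MSP text format, and deconvoluted
feature tables in CSV.

Masses come from an embedded table of principal-isotope masses so that
2 ppm mass gating is hermetic and cannot drift with dependency versions.
All retention times are minutes; retention indices are dimensionless.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ELECTRON_MASS",
    "ISOTOPE_MASSES",
    "FormulaError",
    "MSPFormatError",
    "ValidationError",
    "ElementalFormula",
    "parse_formula",
    "monoisotopic_mass",
    "ppm_error",
    "Peak",
    "Spectrum",
    "LibraryRecord",
    "Feature",
    "read_msp",
    "write_msp",
    "read_feature_table",
    "write_feature_table",
]


class FormulaError(ValueError):
    """Malformed or chemically invalid elemental formula."""


class MSPFormatError(ValueError):
    """Structurally invalid MSP library file."""


class ValidationError(ValueError):
    """Tabular input violating the documented contract."""


# Principal-isotope (most abundant) masses in Da, CODATA/AME2020 values.
# "D" is deuterium; bracketed tokens such as "[13C]" select a specific
# isotope, which the labelled internal standards require.
ISOTOPE_MASSES: Mapping[str, float] = {
    "H": 1.00782503207,
    "D": 2.01410177812,
    "B": 11.00930536,
    "C": 12.0,
    "[13C]": 13.00335483507,
    "N": 14.0030740048,
    "[15N]": 15.0001088989,
    "O": 15.9949146196,
    "F": 18.99840316273,
    "Na": 22.9897692820,
    "Mg": 23.985041697,
    "Al": 26.98153853,
    "Si": 27.97692653465,
    "P": 30.97376199842,
    "S": 31.9720711744,
    "Cl": 34.968852682,
    "K": 38.9637064864,
    "Ca": 39.962590863,
    "Ti": 47.94794198,
    "Cr": 51.94050623,
    "Fe": 55.93493633,
    "Ni": 57.93534241,
    "Cu": 62.92959772,
    "Zn": 63.92914201,
    "As": 74.92159457,
    "Se": 79.9165218,
    "Br": 78.9183376,
    "Sn": 119.90220163,
    "Sb": 120.9038120,
    "I": 126.9044719,
}

ELECTRON_MASS = 5.48579909065e-4  # Da

_TOKEN_RE = re.compile(r"(\[\d+[A-Z][a-z]?\]|[A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class ElementalFormula:
    """Element → count mapping with an integer charge state (default 0).

    Counts are non-negative integers; a valid formula has at least one
    positive count.  Instances are hashable and compare by content.
    """

    counts: Mapping[str, int]
    charge: int = 0

    def __post_init__(self) -> None:
        clean = {}
        for sym, n in self.counts.items():
            if not isinstance(n, (int, np.integer)) or n < 0:
                raise FormulaError(f"count for {sym!r} must be a non-negative integer, got {n!r}")
            if sym not in ISOTOPE_MASSES:
                raise FormulaError(f"unknown element symbol {sym!r}")
            if n > 0:
                clean[sym] = int(n)
        object.__setattr__(self, "counts", dict(clean))

    @property
    def is_empty(self) -> bool:
        return not self.counts

    @property
    def n_atoms(self) -> int:
        return sum(self.counts.values())

    def __getitem__(self, sym: str) -> int:
        return self.counts.get(sym, 0)

    def __le__(self, other: "ElementalFormula") -> bool:
        """Elementwise containment: self is a subformula of other."""
        return all(n <= other[sym] for sym, n in self.counts.items())

    def __sub__(self, other: "ElementalFormula") -> "ElementalFormula":
        if not other <= self:
            raise FormulaError("subtrahend is not elementwise contained in minuend")
        return ElementalFormula(
            {sym: self[sym] - other[sym] for sym in self.counts}, self.charge
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ElementalFormula):
            return NotImplemented
        return self.counts == other.counts and self.charge == other.charge

    def __hash__(self) -> int:
        return hash((frozenset(self.counts.items()), self.charge))

    def __str__(self) -> str:
        return format_formula(self)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"ElementalFormula({format_formula(self)!r}, charge={self.charge})"


def parse_formula(text: str, charge: int = 0) -> ElementalFormula:
    """Parse a formula string such as ``"C15 H24 O"`` or ``"C15H24O"``.

    Whitespace is ignored.  Bracketed isotope tokens (``"[13C]6"``) and
    deuterium (``"D10"``) are accepted for labelled standards.  An unknown
    element symbol or any leftover text raises :class:`FormulaError`
    naming the offending token.
    """
    compact = re.sub(r"\s+", "", text)
    if not compact:
        raise FormulaError("empty formula string")
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(compact):
        m = _TOKEN_RE.match(compact, pos)
        if m is None:
            raise FormulaError(f"malformed token at {compact[pos:]!r} in formula {text!r}")
        sym, digits = m.group(1), m.group(2)
        if sym not in ISOTOPE_MASSES:
            raise FormulaError(f"unknown element symbol {sym!r} in formula {text!r}")
        counts[sym] = counts.get(sym, 0) + (int(digits) if digits else 1)
        pos = m.end()
    return ElementalFormula(counts, charge)


def format_formula(f: ElementalFormula) -> str:
    """Hill-order string (C, H, then alphabetical), single-space separated.

    ``parse_formula(format_formula(f)) == f`` for every valid formula.
    """
    syms = sorted(f.counts)
    ordered = [s for s in ("C", "H") if s in f.counts]
    ordered += [s for s in syms if s not in ("C", "H")]
    return " ".join(f"{s}{f.counts[s]}" if f.counts[s] != 1 else s for s in ordered)


def monoisotopic_mass(f: ElementalFormula, as_radical_cation: bool = False) -> float:
    """Sum of principal-isotope masses in Da.

    EI produces odd-electron molecular ions (M+.), so ``as_radical_cation``
    subtracts one electron mass; at m/z 200 the electron is ~2.7 ppm and is
    not negligible against a 2 ppm gate.
    """
    if f.is_empty:
        raise FormulaError("cannot compute the mass of an empty formula")
    mass = sum(ISOTOPE_MASSES[sym] * n for sym, n in f.counts.items())
    if as_radical_cation:
        mass -= ELECTRON_MASS
    return mass


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed mass error in parts per million: 1e6 (obs - theo) / theo."""
    if theoretical <= 0:
        raise ValueError(f"theoretical m/z must be positive, got {theoretical}")
    return 1e6 * (observed - theoretical) / theoretical


@dataclass(frozen=True)
class Peak:
    """A centroided peak: m/z in Th (> 0), intensity >= 0 (arbitrary units)."""

    mz: float
    intensity: float

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValidationError(f"peak m/z must be positive, got {self.mz}")
        if self.intensity < 0:
            raise ValidationError(f"peak intensity must be >= 0, got {self.intensity}")


class Spectrum:
    """Centroided EI spectrum: strictly increasing m/z with intensities.

    Backed by two aligned numpy arrays; construction sorts and rejects
    duplicate m/z values.
    """

    __slots__ = ("mz", "intensities")

    def __init__(self, mz: Sequence[float], intensities: Sequence[float]):
        mz_arr = np.asarray(mz, dtype=float)
        int_arr = np.asarray(intensities, dtype=float)
        if mz_arr.ndim != 1 or mz_arr.shape != int_arr.shape:
            raise ValidationError("mz and intensity arrays must be 1-D and aligned")
        if mz_arr.size == 0:
            raise ValidationError("a spectrum must contain at least one peak")
        order = np.argsort(mz_arr, kind="stable")
        mz_arr, int_arr = mz_arr[order], int_arr[order]
        if np.any(mz_arr <= 0):
            raise ValidationError("all m/z values must be positive")
        if np.any(int_arr < 0):
            raise ValidationError("all intensities must be >= 0")
        if np.any(np.diff(mz_arr) <= 0):
            raise ValidationError("duplicate m/z values in spectrum")
        self.mz = mz_arr
        self.intensities = int_arr

    @classmethod
    def from_peaks(cls, peaks: Iterable[Peak]) -> "Spectrum":
        pk = list(peaks)
        return cls([p.mz for p in pk], [p.intensity for p in pk])

    def peaks(self) -> list[Peak]:
        return [Peak(m, i) for m, i in zip(self.mz, self.intensities)]

    def __len__(self) -> int:
        return int(self.mz.size)

    @property
    def base_peak_intensity(self) -> float:
        return float(self.intensities.max())

    @property
    def total_intensity(self) -> float:
        return float(self.intensities.sum())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Spectrum):
            return NotImplemented
        return np.array_equal(self.mz, other.mz) and np.array_equal(
            self.intensities, other.intensities
        )

    def __repr__(self) -> str:  # pragma: no cover
        return f"Spectrum({len(self)} peaks, base m/z {self.mz[np.argmax(self.intensities)]:.4f})"


@dataclass
class LibraryRecord:
    """Reference compound: name, CAS, formula, EI spectrum, optional RI."""

    name: str
    spectrum: Spectrum
    formula: Optional[ElementalFormula] = None
    cas: Optional[str] = None
    library_ri: Optional[float] = None
    source_tag: str = "library"

    def __post_init__(self) -> None:
        if self.library_ri is not None and self.library_ri <= 0:
            raise ValidationError(
                f"library RI must be positive if present ({self.name}: {self.library_ri})"
            )

    @property
    def usable_for_hrf(self) -> bool:
        """High-resolution filtering needs a molecular formula."""
        return self.formula is not None


@dataclass
class Feature:
    """One deconvoluted chromatographic feature from one injection."""

    feature_id: str
    rt: float  # minutes
    area: float
    spectrum: Spectrum
    replicate_id: str = "r1"

    def __post_init__(self) -> None:
        if self.rt <= 0:
            raise ValidationError(f"feature {self.feature_id}: rt must be positive")
        if self.area <= 0:
            raise ValidationError(f"feature {self.feature_id}: area must be positive")


# ---------------------------------------------------------------------------
# MSP (NIST text dialect) reader / writer
# ---------------------------------------------------------------------------

_NUM_PEAKS_RE = re.compile(r"^num\s*peaks\s*:\s*(\d+)\s*$", re.IGNORECASE)
_META_RE = re.compile(r"^([A-Za-z_][A-Za-z0-9 _/#-]*?)\s*:\s*(.*)$")
_PAIR_SPLIT_RE = re.compile(r"[;\n]")


def _parse_peak_lines(lines: Sequence[str], name: str, n_declared: int) -> Spectrum:
    pairs: list[tuple[float, float]] = []
    for raw in lines:
        for chunk in _PAIR_SPLIT_RE.split(raw):
            chunk = chunk.strip().strip("()")
            if not chunk:
                continue
            parts = chunk.replace(",", " ").split()
            if len(parts) < 2:
                raise MSPFormatError(f"record {name!r}: malformed peak line {raw!r}")
            pairs.append((float(parts[0]), float(parts[1])))
    if len(pairs) != n_declared:
        raise MSPFormatError(
            f"record {name!r} declares Num Peaks: {n_declared} but has {len(pairs)} peaks"
        )
    return Spectrum([p[0] for p in pairs], [p[1] for p in pairs])


def read_msp(path: str | Path) -> list[LibraryRecord]:
    """Read a NIST-dialect MSP library.

    Accepts ``Num Peaks``/``NumPeaks`` (case-insensitive) and peak pairs
    separated by whitespace or semicolons.  A record whose declared peak
    count disagrees with its peak lines is rejected with the record name in
    the error.  Records without a ``Formula`` field load with ``formula``
    absent and are flagged unusable for HRF scoring.
    """
    text = Path(path).read_text(encoding="utf-8")
    records: list[LibraryRecord] = []
    # Records are separated by blank lines; a trailing record needs no blank.
    blocks = [b for b in re.split(r"\n\s*\n", text) if b.strip()]
    for block in blocks:
        meta: dict[str, str] = {}
        peak_lines: list[str] = []
        n_peaks: Optional[int] = None
        for line in block.splitlines():
            if not line.strip():
                continue
            if n_peaks is None:
                m = _NUM_PEAKS_RE.match(line.strip())
                if m:
                    n_peaks = int(m.group(1))
                    continue
                m = _META_RE.match(line.strip())
                if m:
                    meta[m.group(1).strip().lower()] = m.group(2).strip()
                    continue
                raise MSPFormatError(f"unexpected line before Num Peaks: {line!r}")
            else:
                peak_lines.append(line)
        name = meta.get("name", "<unnamed>")
        if n_peaks is None:
            raise MSPFormatError(f"record {name!r}: missing Num Peaks declaration")
        spectrum = _parse_peak_lines(peak_lines, name, n_peaks)
        formula_text = meta.get("formula", "")
        formula = parse_formula(formula_text) if formula_text else None
        ri_text = meta.get("ri") or meta.get("retentionindex") or meta.get("retention_index")
        records.append(
            LibraryRecord(
                name=name,
                spectrum=spectrum,
                formula=formula,
                cas=meta.get("cas") or meta.get("casno") or meta.get("cas#") or None,
                library_ri=float(ri_text) if ri_text else None,
                source_tag=meta.get("source", "library"),
            )
        )
    return records


def write_msp(records: Iterable[LibraryRecord], path: str | Path) -> None:
    """Emit NIST-style MSP: ``Num Peaks:`` then one ``mz intensity`` per line."""
    lines: list[str] = []
    for rec in records:
        lines.append(f"Name: {rec.name}")
        if rec.cas:
            lines.append(f"CAS: {rec.cas}")
        if rec.formula is not None:
            lines.append(f"Formula: {format_formula(rec.formula)}")
        if rec.library_ri is not None:
            lines.append(f"RI: {rec.library_ri:g}")
        lines.append(f"Source: {rec.source_tag}")
        lines.append(f"Num Peaks: {len(rec.spectrum)}")
        for mz, inten in zip(rec.spectrum.mz, rec.spectrum.intensities):
            lines.append(f"{mz:.5f} {inten:.6g}")
        lines.append("")
    Path(path).write_text("\n".join(lines), encoding="utf-8")


# ---------------------------------------------------------------------------
# Feature tables (CSV + companion MSP holding the deconvoluted spectra)
# ---------------------------------------------------------------------------

FEATURE_COLUMNS = ["feature_id", "rt_min", "area", "replicate_id", "spectrum_ref"]


def read_feature_table(csv_path: str | Path, msp_path: str | Path) -> list[Feature]:
    """Load a deconvoluted feature table and join each row to its spectrum.

    The CSV must carry the documented header; ``spectrum_ref`` values are
    resolved against record names in the companion MSP.  Dangling
    references raise :class:`ValidationError` listing every unmatched id.
    """
    df = pd.read_csv(csv_path, dtype={"feature_id": str, "replicate_id": str, "spectrum_ref": str})
    missing_cols = [c for c in FEATURE_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValidationError(f"feature table missing columns: {missing_cols}")
    spectra = {rec.name: rec.spectrum for rec in read_msp(msp_path)}
    dangling = sorted(set(df["spectrum_ref"]) - set(spectra)) if len(df) else []
    if dangling:
        raise ValidationError(f"spectrum_ref values with no MSP record: {dangling}")
    bad_area = df[df["area"] <= 0]
    if len(bad_area):
        raise ValidationError(
            f"non-positive areas for features: {list(bad_area['feature_id'])}"
        )
    return [
        Feature(
            feature_id=row.feature_id,
            rt=float(row.rt_min),
            area=float(row.area),
            spectrum=spectra[row.spectrum_ref],
            replicate_id=row.replicate_id,
        )
        for row in df.itertuples(index=False)
    ]


def write_feature_table(features: Sequence[Feature], csv_path: str | Path, msp_path: str | Path) -> None:
    """Inverse of :func:`read_feature_table`; spectrum_ref == feature_id."""
    rows = [
        {
            "feature_id": f.feature_id,
            "rt_min": f.rt,
            "area": f.area,
            "replicate_id": f.replicate_id,
            "spectrum_ref": f.feature_id,
        }
        for f in features
    ]
    pd.DataFrame(rows, columns=FEATURE_COLUMNS).to_csv(csv_path, index=False)
    write_msp(
        [LibraryRecord(name=f.feature_id, spectrum=f.spectrum, source_tag="feature") for f in features],
        msp_path,
    )
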