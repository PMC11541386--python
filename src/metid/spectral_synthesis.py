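"""In silico MS2 spectral-library synthesis and MSP serialization.

Known-structure candidates get their predicted spectra merged across
collision energies (CE 10 + 20 eV by default; CE 40 eV is dropped because
its small unspecific fragments inflate false matches).  Tentative
candidates — defined only by parent + reaction delta — get a transplanted
spectrum: the parent's fragments plus the parent's precursor ion appended
as a fragment, under a precursor m/z shifted by the reaction mass delta.
Conjugates tend to cleave the conjugated moiety early, so the intact
parent ion and its fragments dominate their MS2 spectra; that observation
is what makes the transplanted spectrum a usable library entry.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, NamedTuple

from .chem_registry import (
    AdductSpec,
    CandidateMetabolite,
    adduct_for_polarity,
    adduct_mz,
)

__all__ = [
    "Peak",
    "SpectrumRecord",
    "SpectralLibrary",
    "MspFormatError",
    "merge_energy_levels",
    "synthesize_tentative_spectrum",
    "build_library",
    "write_msp",
    "read_msp",
]

#: m/z tolerance (Da) below which peaks are collapsed when merging CE levels.
MERGE_TOLERANCE = 0.005


class Peak(NamedTuple):
    mz: float
    intensity: float


class MspFormatError(ValueError):
    """Malformed MSP input; carries the offending line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


@dataclass(frozen=True)
class SpectrumRecord:
    """One library entry: precursor + peak list for a compound/adduct pair."""

    compound_id: str
    adduct: AdductSpec
    precursor_mz: float
    peaks: tuple[Peak, ...]
    energy_provenance: frozenset[float] = frozenset()
    tentative: bool = False
    formula: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "peaks", tuple(sorted(self.peaks, key=lambda p: p.mz)))
        for p in self.peaks:
            if p.mz <= 0:
                raise ValueError(f"non-positive peak m/z: {p.mz}")
            if p.intensity < 0:
                raise ValueError(f"negative peak intensity: {p.intensity}")
            # Transplanted (tentative) spectra keep every parent fragment even
            # when a loss reaction puts the candidate precursor below some of
            # them; only exact-structure records must respect the bound.
            if not self.tentative and p.mz > self.precursor_mz + MERGE_TOLERANCE:
                raise ValueError(
                    f"peak {p.mz} above precursor {self.precursor_mz} in {self.compound_id}"
                )

    @property
    def polarity(self) -> str:
        return self.adduct.polarity


@dataclass
class SpectralLibrary:
    polarity: str
    records: list[SpectrumRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        keys = [(r.compound_id, r.adduct.name) for r in self.records]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (compound, adduct) in library")
        for r in self.records:
            if r.polarity != self.polarity:
                raise ValueError(
                    f"record {r.compound_id} polarity {r.polarity} != library {self.polarity}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def by_id(self, compound_id: str) -> SpectrumRecord:
        for r in self.records:
            if r.compound_id == compound_id:
                return r
        raise KeyError(compound_id)


def _collapse_peaks(peaks: Iterable[Peak], tolerance: float) -> tuple[Peak, ...]:
    """Collapse peaks closer than ``tolerance``, keeping the most intense."""
    merged: list[Peak] = []
    for p in sorted(peaks, key=lambda p: p.mz):
        if merged and p.mz - merged[-1].mz < tolerance:
            if p.intensity > merged[-1].intensity:
                merged[-1] = p
        else:
            merged.append(p)
    return tuple(merged)


def merge_energy_levels(
    spectra: Mapping[float, SpectrumRecord],
    include: Iterable[float],
    tolerance: float = MERGE_TOLERANCE,
) -> SpectrumRecord:
    """Union the peak lists of the included CE levels into one record.

    ``spectra`` maps collision energy (eV) to the spectrum predicted at that
    energy.  All inputs must share compound, adduct and precursor.  Peaks
    closer than ``tolerance`` collapse to the more intense member.
    """
    include = frozenset(float(e) for e in include)
    chosen = [spectra[e] for e in sorted(include) if e in spectra]
    if not chosen:
        raise ValueError("no spectra at the requested collision energies")
    ref = chosen[0]
    for s in chosen[1:]:
        if s.compound_id != ref.compound_id or s.adduct.name != ref.adduct.name:
            raise ValueError("cannot merge spectra of different compounds/adducts")
        if abs(s.precursor_mz - ref.precursor_mz) > tolerance:
            raise ValueError("cannot merge spectra with differing precursors")
    peaks = _collapse_peaks((p for s in chosen for p in s.peaks), tolerance)
    return replace(ref, peaks=peaks, energy_provenance=include)


def synthesize_tentative_spectrum(
    parent_record: SpectrumRecord,
    candidate: CandidateMetabolite,
    adduct: AdductSpec | None = None,
) -> SpectrumRecord:
    """Transplant a parent spectrum onto a tentative (CMP) candidate.

    The synthesized record keeps every parent fragment, appends the parent
    precursor m/z as an additional fragment (at the maximum parent fragment
    intensity, so dot-product scoring cannot ignore it), and sets the
    precursor to the candidate's own adduct m/z.
    """
    if candidate.source != "CMP":
        raise ValueError(
            f"{candidate.id} has an exact structure; use its own predicted spectrum"
        )
    if adduct is None:
        adduct = parent_record.adduct
    top = max((p.intensity for p in parent_record.peaks), default=100.0)
    peaks = parent_record.peaks + (Peak(parent_record.precursor_mz, top),)
    return SpectrumRecord(
        compound_id=candidate.id,
        adduct=adduct,
        precursor_mz=adduct_mz(candidate.neutral_mass, adduct),
        peaks=peaks,
        energy_provenance=parent_record.energy_provenance,
        tentative=True,
        formula=candidate.formula.to_hill(),
    )


def build_library(
    candidates: Iterable[CandidateMetabolite],
    parent_spectra: Mapping[str, SpectrumRecord],
    exact_spectra: Mapping[str, SpectrumRecord] | None = None,
    polarity: str = "positive",
    extra_records: Iterable[SpectrumRecord] = (),
) -> SpectralLibrary:
    """Assemble a one-polarity library: one record per candidate.

    ``parent_spectra`` maps parent_id to the CE-merged parent record in this
    polarity (used for tentative candidates); ``exact_spectra`` maps
    candidate_id to its own CE-merged record (used for SP/LS candidates).
    Candidates with no usable spectrum source are skipped.  ``extra_records``
    (e.g. the parents' own entries) are prepended verbatim.
    """
    adduct = adduct_for_polarity(polarity)
    exact_spectra = exact_spectra or {}
    records: list[SpectrumRecord] = list(extra_records)
    skipped: list[str] = []
    for cand in candidates:
        if not cand.tentative and cand.id in exact_spectra:
            rec = exact_spectra[cand.id]
            records.append(
                replace(
                    rec,
                    compound_id=cand.id,
                    tentative=False,
                    formula=cand.formula.to_hill(),
                )
            )
        elif cand.tentative and cand.parent_id in parent_spectra:
            records.append(
                synthesize_tentative_spectrum(parent_spectra[cand.parent_id], cand, adduct)
            )
        elif cand.parent_id in parent_spectra:
            # exact structure but no predicted spectrum supplied: fall back to
            # the transplanted parent spectrum, flagged tentative.
            tent = replace(cand, smiles=None)
            records.append(
                synthesize_tentative_spectrum(parent_spectra[cand.parent_id], tent, adduct)
            )
        else:
            skipped.append(cand.id)
    lib = SpectralLibrary(polarity=polarity, records=records)
    lib.skipped = skipped  # type: ignore[attr-defined]
    return lib


# ---------------------------------------------------------------------------
# MSP serialization
# ---------------------------------------------------------------------------

def _normalize(peaks: tuple[Peak, ...]) -> tuple[Peak, ...]:
    top = max((p.intensity for p in peaks), default=0.0)
    if top <= 0:
        return peaks
    return tuple(Peak(p.mz, 100.0 * p.intensity / top) for p in peaks)


def write_msp(library: SpectralLibrary, destination) -> None:
    """Serialize a library to MSP text (intensities normalized to max 100).

    ``destination`` is a path or a text file object.  Dialect: NAME,
    PRECURSORMZ, PRECURSORTYPE, IONMODE, FORMULA, COMMENT, ``Num Peaks:``,
    then mz<TAB>intensity lines, records separated by a blank line.
    """
    own = isinstance(destination, (str, bytes)) or hasattr(destination, "__fspath__")
    fh = open(destination, "w") if own else destination
    try:
        for rec in library.records:
            peaks = _normalize(rec.peaks)
            fh.write(f"NAME: {rec.compound_id}\n")
            fh.write(f"PRECURSORMZ: {rec.precursor_mz:.5f}\n")
            fh.write(f"PRECURSORTYPE: {rec.adduct.name}\n")
            fh.write(f"IONMODE: {rec.polarity.capitalize()}\n")
            if rec.formula:
                fh.write(f"FORMULA: {rec.formula}\n")
            comment = f"tentative={'true' if rec.tentative else 'false'}"
            if rec.energy_provenance:
                ces = ",".join(f"{e:g}" for e in sorted(rec.energy_provenance))
                comment += f"; CE={ces}"
            fh.write(f"COMMENT: {comment}\n")
            fh.write(f"Num Peaks: {len(peaks)}\n")
            for p in peaks:
                fh.write(f"{p.mz:.5f}\t{p.intensity:.4f}\n")
            fh.write("\n")
    finally:
        if own:
            fh.close()


def read_msp(source) -> SpectralLibrary:
    """Parse MSP text back into a library (inverse of :func:`write_msp`).

    Raises :class:`MspFormatError` with the line number for records missing
    PRECURSORMZ or whose peak count disagrees with the ``Num Peaks`` header.
    Per-CE input files (one record per compound and energy, CE in COMMENT)
    are read with the same function.
    """
    own = isinstance(source, (str, bytes)) or hasattr(source, "__fspath__")
    fh = open(source) if own else source
    try:
        lines = fh.read().splitlines()
    finally:
        if own:
            fh.close()

    records: list[SpectrumRecord] = []
    meta: dict[str, str] = {}
    peaks: list[Peak] = []
    n_declared: int | None = None
    start_line = 1

    def _flush(end_line: int) -> None:
        nonlocal meta, peaks, n_declared
        if not meta and not peaks:
            return
        if "NAME" not in meta:
            raise MspFormatError("record missing NAME", start_line)
        if "PRECURSORMZ" not in meta:
            raise MspFormatError(f"record {meta.get('NAME')!r} missing PRECURSORMZ", start_line)
        if n_declared is not None and n_declared != len(peaks):
            raise MspFormatError(
                f"record {meta['NAME']!r}: Num Peaks {n_declared} but {len(peaks)} peak lines",
                end_line,
            )
        adduct = adduct_for_polarity(meta.get("IONMODE", "positive").lower())
        comment = meta.get("COMMENT", "")
        tent = "tentative=true" in comment
        energies: frozenset[float] = frozenset()
        for part in comment.split(";"):
            part = part.strip()
            if part.startswith("CE="):
                energies = frozenset(float(x) for x in part[3:].split(",") if x)
        records.append(
            SpectrumRecord(
                compound_id=meta["NAME"],
                adduct=adduct,
                precursor_mz=float(meta["PRECURSORMZ"]),
                peaks=tuple(peaks),
                energy_provenance=energies,
                tentative=tent,
                formula=meta.get("FORMULA", ""),
            )
        )
        meta, peaks, n_declared = {}, [], None

    for i, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            _flush(i)
            start_line = i + 1
            continue
        if ":" in line and not line[0].isdigit():
            key, _, value = line.partition(":")
            key = key.strip().upper()
            if key == "NUM PEAKS":
                try:
                    n_declared = int(value.strip())
                except ValueError:
                    raise MspFormatError(f"bad Num Peaks value {value.strip()!r}", i)
            else:
                meta[key] = value.strip()
        else:
            fields = line.replace("\t", " ").split()
            if len(fields) < 2:
                raise MspFormatError(f"bad peak line {line!r}", i)
            try:
                peaks.append(Peak(float(fields[0]), float(fields[1])))
            except ValueError:
                raise MspFormatError(f"bad peak line {line!r}", i)
    _flush(len(lines) + 1)

    polarity = records[0].polarity if records else "positive"
    return SpectralLibrary(polarity=polarity, records=records)


def read_msp_by_energy(source) -> dict[str, dict[float, SpectrumRecord]]:
    """Read a per-CE MSP file into {compound_id: {CE: record}}."""
    lib = read_msp(source)
    out: dict[str, dict[float, SpectrumRecord]] = {}
    for rec in lib.records:
        if len(rec.energy_provenance) != 1:
            raise ValueError(
                f"record {rec.compound_id!r} must carry exactly one CE in COMMENT"
            )
        (ce,) = rec.energy_provenance
        out.setdefault(rec.compound_id, {})[ce] = rec
    return out
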