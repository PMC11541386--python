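"""Matching aligned LC-MS features against an in silico spectral library.

Features come from an alignment export (one row per aligned feature with an
embedded MS2 peak string and per-sample areas).  Matching is two-stage:
precursor m/z within the MS1 tolerance (default 1 mDa), then MS2 similarity
(cosine on square-root intensities over greedily paired fragments, default
5 mDa tolerance).  Accepted matches carry an identification confidence
level: 1 = confirmed by reference standard, 2 = probable structure
(exact-structure library record), 3 = tentative structure supported by an
in silico library match.  Features without MS2 support are never reported
(levels 4-5 are excluded).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .spectral_synthesis import Peak, SpectralLibrary, SpectrumRecord

__all__ = [
    "FeatureRecord",
    "SampleMetadata",
    "MatchConfig",
    "MatchResult",
    "read_feature_table",
    "read_sample_metadata",
    "match_precursor",
    "score_ms2",
    "assign_confidence",
    "delta_rt",
    "match_features",
    "matches_to_frame",
]

ACQUISITION_MODES = ("DDA+", "DDA-", "DIA+", "DIA-")


@dataclass(frozen=True)
class FeatureRecord:
    """One aligned feature: m/z, Rt, MS2 peaks and per-sample areas."""

    feature_id: str
    mz: float
    rt: float
    ms2_peaks: tuple[Peak, ...] = ()
    acquisition_mode: str = "DDA+"
    areas: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.rt < 0:
            raise ValueError("negative retention time")
        if self.acquisition_mode not in ACQUISITION_MODES:
            raise ValueError(f"unknown acquisition mode {self.acquisition_mode!r}")

    @property
    def polarity(self) -> str:
        return "positive" if self.acquisition_mode.endswith("+") else "negative"


@dataclass(frozen=True)
class SampleMetadata:
    sample_id: str
    role: str  # treated | control | QC
    matrix: str = "lettuce_root"
    timepoint: float = 14.0
    environment: str = "hydroponic"

    def __post_init__(self) -> None:
        if self.role not in ("treated", "control", "QC"):
            raise ValueError(f"unknown sample role {self.role!r}")


@dataclass(frozen=True)
class MatchConfig:
    """Identification tolerances; defaults follow common HRMS practice."""

    ms1_tol: float = 0.001   # Da
    ms2_tol: float = 0.005   # Da
    rt_tol: float = 0.1      # min (alignment tolerance; carried for reporting)
    min_similarity: float = 0.80
    min_matched_fragments: int = 2

    def __post_init__(self) -> None:
        if min(self.ms1_tol, self.ms2_tol, self.rt_tol, self.min_similarity) <= 0:
            raise ValueError("tolerances must be positive")
        if self.min_matched_fragments < 1:
            raise ValueError("min_matched_fragments must be >= 1")


@dataclass(frozen=True)
class MatchResult:
    feature_id: str
    candidate_id: str
    precursor_error: float
    matched_fragment_count: int
    similarity: float
    confidence_level: int
    delta_rt: float | None = None
    acquisition_mode: str = "DDA+"
    tentative: bool = True


# ---------------------------------------------------------------------------
# Table IO
# ---------------------------------------------------------------------------

_REQUIRED_COLUMNS = ("feature_id", "mz", "rt", "acquisition_mode", "ms2")


def _parse_ms2(text: object) -> tuple[Peak, ...]:
    """Parse an embedded MS2 string: 'mz:intensity' pairs separated by spaces."""
    if text is None or (isinstance(text, float) and pd.isna(text)):
        return ()
    text = str(text).strip()
    if not text:
        return ()
    peaks = []
    for token in text.split():
        mz_s, _, int_s = token.partition(":")
        peaks.append(Peak(float(mz_s), float(int_s) if int_s else 1.0))
    return tuple(sorted(peaks, key=lambda p: p.mz))


def read_feature_table(source, metadata: Sequence[SampleMetadata]) -> list[FeatureRecord]:
    """Read an aligned feature TSV against its sample metadata.

    The table must carry feature_id, mz, rt, acquisition_mode and ms2
    columns; every remaining column is a per-sample area column and must
    map to a metadata entry.  Rows with an unparseable m/z are rejected
    with their row number.
    """
    df = pd.read_csv(source, sep="\t", dtype=str)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"feature table missing required column(s): {', '.join(missing)}")
    known = {m.sample_id for m in metadata}
    area_cols = [c for c in df.columns if c not in _REQUIRED_COLUMNS and c != "adduct"]
    unknown = [c for c in area_cols if c not in known]
    if unknown:
        raise ValueError(f"area column(s) not in sample metadata: {', '.join(unknown)}")
    records = []
    for i, row in enumerate(df.to_dict("records")):
        try:
            mz = float(row["mz"])
            rt = float(row["rt"])
        except (TypeError, ValueError):
            raise ValueError(f"row {i + 2}: unparseable m/z or Rt") from None
        areas = {c: float(row[c]) if pd.notna(row[c]) else 0.0 for c in area_cols}
        records.append(
            FeatureRecord(
                feature_id=str(row["feature_id"]),
                mz=mz,
                rt=rt,
                ms2_peaks=_parse_ms2(row["ms2"]),
                acquisition_mode=str(row["acquisition_mode"]),
                areas=areas,
            )
        )
    return records


def read_sample_metadata(source) -> list[SampleMetadata]:
    df = pd.read_csv(source, sep="\t")
    out = [
        SampleMetadata(
            sample_id=str(r["sample_id"]),
            role=str(r["role"]),
            matrix=str(r.get("matrix", "lettuce_root")),
            timepoint=float(r.get("timepoint", 14)),
            environment=str(r.get("environment", "hydroponic")),
        )
        for r in df.to_dict("records")
    ]
    ids = [m.sample_id for m in out]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample ids in metadata")
    return out


# ---------------------------------------------------------------------------
# Matching
# ---------------------------------------------------------------------------

def match_precursor(
    feature: FeatureRecord,
    library: SpectralLibrary,
    config: MatchConfig = MatchConfig(),
) -> list[SpectrumRecord]:
    """Library records within the MS1 tolerance, sorted by absolute error."""
    if library.polarity != feature.polarity:
        raise ValueError(
            f"library polarity {library.polarity} does not match "
            f"feature acquisition mode {feature.acquisition_mode}"
        )
    hits = [
        r for r in library.records if abs(r.precursor_mz - feature.mz) <= config.ms1_tol
    ]
    return sorted(hits, key=lambda r: abs(r.precursor_mz - feature.mz))


def _greedy_pairs(
    a: Sequence[Peak], b: Sequence[Peak], tol: float
) -> list[tuple[int, int]]:
    """Greedy closest-first peak pairing; each peak used once.

    Ties on distance break toward the lower library (second argument) m/z.
    """
    cands = []
    for i, pa in enumerate(a):
        for j, pb in enumerate(b):
            d = abs(pa.mz - pb.mz)
            if d <= tol:
                cands.append((d, pb.mz, i, j))
    cands.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs = []
    for _, _, i, j in cands:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pairs.append((i, j))
    return pairs


def score_ms2(
    feature_peaks: Sequence[Peak],
    record_peaks: Sequence[Peak],
    config: MatchConfig = MatchConfig(),
) -> tuple[float, int]:
    """Spectral similarity in [0, 1] and the matched-fragment count.

    Fragments are paired greedily (closest first, single use) within the
    MS2 tolerance; the score is the cosine of the square-root-intensity
    vectors laid out over the union of paired and unpaired peaks, so
    unmatched peaks on either side dilute the score.  An empty feature
    spectrum scores (0, 0).
    """
    if not feature_peaks or not record_peaks:
        return 0.0, 0
    pairs = _greedy_pairs(feature_peaks, record_peaks, config.ms2_tol)
    fa = np.sqrt([p.intensity for p in feature_peaks])
    fb = np.sqrt([p.intensity for p in record_peaks])
    dot = sum(fa[i] * fb[j] for i, j in pairs)
    norm = math.sqrt(float(np.sum(fa**2)) * float(np.sum(fb**2)))
    if norm == 0:
        return 0.0, 0
    return float(dot / norm), len(pairs)


def assign_confidence(
    record: SpectrumRecord,
    has_experimental_ms2: bool,
    has_reference_standard: bool = False,
) -> int | None:
    """Identification confidence level, or None when the match is unreportable.

    Level 1 needs a reference standard; level 2 is an exact-structure
    library match; level 3 a tentative-structure match.  Without MS2
    support there is no reportable identification.
    """
    if not has_experimental_ms2:
        return None
    if has_reference_standard:
        return 1
    return 3 if record.tentative else 2


def delta_rt(feature: FeatureRecord, parent_feature: FeatureRecord | None) -> float | None:
    """Signed Rt change of the metabolite vs its parent (minutes).

    Conjugations that increase polarity elute earlier (negative shift);
    acetylation and similar lipophilicity gains elute later.  Reported as
    supporting evidence; None when the parent feature is absent.
    """
    if parent_feature is None:
        return None
    return feature.rt - parent_feature.rt


def match_features(
    features: Iterable[FeatureRecord],
    libraries: Mapping[str, SpectralLibrary],
    config: MatchConfig = MatchConfig(),
    parent_of: Mapping[str, str] | None = None,
    reference_standards: frozenset[str] = frozenset(),
) -> list[MatchResult]:
    """Match every feature against the library of its polarity.

    Keeps the best accepted record per feature (highest similarity, then
    smallest precursor error).  ``parent_of`` maps candidate_id to the
    parent compound's library id so delta-Rt can be derived from the
    parent's own matched feature.  ``reference_standards`` lists library
    ids confirmed by an authentic standard (level 1).
    """
    features = list(features)
    prelim: list[tuple[FeatureRecord, SpectrumRecord, float, int, float]] = []
    for feat in features:
        lib = libraries.get(feat.polarity)
        if lib is None:
            continue
        best = None
        for rec in match_precursor(feat, lib, config):
            sim, nfrag = score_ms2(feat.ms2_peaks, rec.peaks, config)
            if sim < config.min_similarity or nfrag < config.min_matched_fragments:
                continue
            err = rec.precursor_mz - feat.mz
            key = (-sim, abs(err))
            if best is None or key < best[0]:
                best = (key, rec, sim, nfrag, err)
        if best is not None:
            _, rec, sim, nfrag, err = best
            prelim.append((feat, rec, sim, nfrag, err))

    # Rt of each matched parent compound (per polarity), for delta-Rt.
    parent_rt: dict[tuple[str, str], float] = {}
    for feat, rec, *_ in prelim:
        parent_rt.setdefault((rec.compound_id, feat.polarity), feat.rt)

    results = []
    for feat, rec, sim, nfrag, err in prelim:
        level = assign_confidence(
            rec,
            has_experimental_ms2=len(feat.ms2_peaks) > 0,
            has_reference_standard=rec.compound_id in reference_standards,
        )
        if level is None:
            continue
        drt = None
        if parent_of and rec.compound_id in parent_of:
            key = (parent_of[rec.compound_id], feat.polarity)
            if key in parent_rt:
                drt = feat.rt - parent_rt[key]
        results.append(
            MatchResult(
                feature_id=feat.feature_id,
                candidate_id=rec.compound_id,
                precursor_error=err,
                matched_fragment_count=nfrag,
                similarity=sim,
                confidence_level=level,
                delta_rt=drt,
                acquisition_mode=feat.acquisition_mode,
                tentative=rec.tentative,
            )
        )
    return results


def matches_to_frame(matches: Iterable[MatchResult]) -> pd.DataFrame:
    rows = [
        {
            "feature_id": m.feature_id,
            "candidate_id": m.candidate_id,
            "precursor_error_mDa": round(m.precursor_error * 1000, 4),
            "matched_fragments": m.matched_fragment_count,
            "similarity": round(m.similarity, 4),
            "confidence_level": m.confidence_level,
            "delta_rt_min": "" if m.delta_rt is None else round(m.delta_rt, 3),
            "acquisition_mode": m.acquisition_mode,
            "tentative": m.tentative,
        }
        for m in matches
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "feature_id", "candidate_id", "precursor_error_mDa", "matched_fragments",
            "similarity", "confidence_level", "delta_rt_min", "acquisition_mode",
            "tentative",
        ],
    )
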