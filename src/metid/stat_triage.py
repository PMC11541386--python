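"""Statistical funnel: QC prefilter, volcano selection, PCA, reporting.

The funnel mirrors standard untargeted-metabolomics practice: features are
first screened on pooled-QC repeatability and presence (QC %RSD < 30,
present in > 50% of QCs, present in > 70% of some biological group — all
strict inequalities), then treatment-elevated features are selected on a
volcano criterion (Welch t-test p < 0.05 on log10 areas AND fold change
> 3 in the treated direction only; metabolites of an added drug should not
appear in controls, and FC 3 mirrors a limit-of-detection-style margin).
Selected features are finally cross-referenced with the spectral-library
matches; only features that are both significant and matched enter the
identification report.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .feature_matching import FeatureRecord, MatchResult, SampleMetadata

__all__ = [
    "PrefilterThresholds",
    "FeatureStats",
    "qc_prefilter",
    "volcano_select",
    "pca_overview",
    "crossref_and_report",
    "mode_venn",
    "stats_to_frame",
]


@dataclass(frozen=True)
class PrefilterThresholds:
    max_qc_rsd: float = 30.0      # percent
    min_qc_presence: float = 0.5  # fraction, strict >
    min_group_presence: float = 0.7
    presence_floor: float = 0.0   # area must exceed this to count as present


@dataclass
class FeatureStats:
    feature_id: str
    qc_rsd: float
    qc_presence: float
    group_presence: dict[str, float]
    passes_prefilter: bool
    p_value: float | None = None
    fold_change: float | None = None
    significant: bool = False


def _sample_ids(metadata: Sequence[SampleMetadata], role: str) -> list[str]:
    return [m.sample_id for m in metadata if m.role == role]


def qc_prefilter(
    features: Iterable[FeatureRecord],
    metadata: Sequence[SampleMetadata],
    thresholds: PrefilterThresholds = PrefilterThresholds(),
) -> dict[str, FeatureStats]:
    """Screen every feature on QC repeatability and presence.

    %RSD is the sample (n-1) standard deviation over QC areas divided by
    their mean, in percent; a zero or undefined QC mean fails the RSD
    criterion.  Presence is the fraction of samples with area above the
    presence floor.  All three criteria are strict inequalities.
    """
    qc_ids = _sample_ids(metadata, "QC")
    if len(qc_ids) < 2:
        raise ValueError("prefilter needs at least 2 QC samples")
    groups = {
        role: _sample_ids(metadata, role)
        for role in ("treated", "control")
        if _sample_ids(metadata, role)
    }
    floor = thresholds.presence_floor
    out: dict[str, FeatureStats] = {}
    for feat in features:
        qc = np.array([feat.areas.get(s, 0.0) for s in qc_ids], dtype=float)
        mean = qc.mean()
        if mean > 0:
            rsd = float(qc.std(ddof=1) / mean * 100.0)
        else:
            rsd = float("inf")
        qc_presence = float(np.mean(qc > floor))
        group_presence = {}
        for role, ids in groups.items():
            areas = np.array([feat.areas.get(s, 0.0) for s in ids], dtype=float)
            group_presence[role] = float(np.mean(areas > floor))
        passes = (
            rsd < thresholds.max_qc_rsd
            and qc_presence > thresholds.min_qc_presence
            and max(group_presence.values(), default=0.0) > thresholds.min_group_presence
        )
        out[feat.feature_id] = FeatureStats(
            feature_id=feat.feature_id,
            qc_rsd=rsd,
            qc_presence=qc_presence,
            group_presence=group_presence,
            passes_prefilter=passes,
        )
    return out


def _half_min_positive(features: Sequence[FeatureRecord]) -> float:
    """Half the smallest positive area in the table (zero-imputation offset)."""
    positives = [a for f in features for a in f.areas.values() if a > 0]
    return min(positives) / 2.0 if positives else 1.0


def volcano_select(
    features: Iterable[FeatureRecord],
    metadata: Sequence[SampleMetadata],
    alpha: float = 0.05,
    fc_threshold: float = 3.0,
    stats: Mapping[str, FeatureStats] | None = None,
    fdr: bool = False,
) -> dict[str, FeatureStats]:
    """Volcano selection of treatment-elevated features.

    Fold change is the ratio of raw group means (treated / control); the
    p-value comes from a Welch two-sample t-test on log10(area + half the
    smallest positive area in the table).  A feature is significant iff
    p < alpha AND FC > fc_threshold — elevated in treated only, so a
    feature 10x higher in controls is excluded regardless of p.  When
    prefilter ``stats`` are given, only passing features are tested and
    the returned stats are updated in place; ``fdr`` applies an optional
    Benjamini-Hochberg correction (off by default).
    """
    features = list(features)
    treated = _sample_ids(metadata, "treated")
    control = _sample_ids(metadata, "control")
    if len(treated) < 2 or len(control) < 2:
        missing = "treated" if len(treated) < 2 else "control"
        raise ValueError(f"volcano selection needs >= 2 samples in group {missing!r}")
    offset = _half_min_positive(features)

    if stats is None:
        stats = {
            f.feature_id: FeatureStats(f.feature_id, 0.0, 1.0, {}, True)
            for f in features
        }
    tested: list[str] = []
    pvals: list[float] = []
    for feat in features:
        st = stats.get(feat.feature_id)
        if st is None or not st.passes_prefilter:
            continue
        t_areas = np.array([feat.areas.get(s, 0.0) for s in treated], dtype=float)
        c_areas = np.array([feat.areas.get(s, 0.0) for s in control], dtype=float)
        c_mean = c_areas.mean()
        st.fold_change = float(t_areas.mean() / c_mean) if c_mean > 0 else float("inf")
        with warnings.catch_warnings():
            # near-constant groups (e.g. a compound absent from every control)
            # are expected inputs, not numerical accidents
            warnings.simplefilter("ignore", RuntimeWarning)
            _, p = sps.ttest_ind(
                np.log10(t_areas + offset), np.log10(c_areas + offset), equal_var=False
            )
        st.p_value = float(p)
        tested.append(feat.feature_id)
        pvals.append(float(p))
    if fdr and pvals:
        from statsmodels.stats.multitest import multipletests

        _, adj, _, _ = multipletests(pvals, method="fdr_bh")
        for fid, q in zip(tested, adj):
            stats[fid].p_value = float(q)
    for fid in tested:
        st = stats[fid]
        st.significant = (
            st.p_value is not None
            and np.isfinite(st.p_value)
            and st.p_value < alpha
            and st.fold_change is not None
            and st.fold_change > fc_threshold
        )
    return dict(stats)


def pca_overview(
    features: Sequence[FeatureRecord],
    metadata: Sequence[SampleMetadata],
    n_components: int = 2,
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of the log10, autoscaled area matrix (samples x features).

    Returns per-sample scores (with role annotation) and the explained
    variance fraction per component.  Constant features are dropped.  The
    SVD sign is fixed by forcing each component's largest-magnitude
    loading positive, so scores are deterministic.
    """
    if len(metadata) < 3:
        raise ValueError("PCA needs at least 3 samples")
    features = list(features)
    if len(features) < 2:
        raise ValueError("PCA needs at least 2 features")
    sample_ids = [m.sample_id for m in metadata]
    offset = _half_min_positive(features)
    X = np.log10(
        np.array(
            [[f.areas.get(s, 0.0) for f in features] for s in sample_ids], dtype=float
        )
        + offset
    )
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    X = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    k = min(n_components, len(S))
    for i in range(k):
        j = np.argmax(np.abs(Vt[i]))
        if Vt[i, j] < 0:
            Vt[i] *= -1
            U[:, i] *= -1
    scores = U[:, :k] * S[:k]
    explained = (S**2 / np.sum(S**2))[:k]
    df = pd.DataFrame(
        scores, columns=[f"PC{i + 1}" for i in range(k)], index=sample_ids
    )
    df.insert(0, "sample_id", sample_ids)
    df["role"] = [m.role for m in metadata]
    return df.reset_index(drop=True), explained


def crossref_and_report(
    stats: Mapping[str, FeatureStats],
    matches: Iterable[MatchResult],
    metadata: Sequence[SampleMetadata],
    features: Sequence[FeatureRecord],
    compound_info: Mapping[str, Mapping[str, object]] | None = None,
) -> pd.DataFrame:
    """Inner join of significant features with library matches.

    One report row per (compound, matrix, environment, timepoint) with the
    best confidence level and a treated-mean abundance normalized to the
    most abundant reported compound (100).  Significant-but-unmatched
    features are metabolome changes, not drug metabolites, and are
    excluded; matched-but-non-significant features are excluded too.
    """
    compound_info = compound_info or {}
    treated = _sample_ids(metadata, "treated")
    ctx = {
        (m.matrix, m.environment, m.timepoint)
        for m in metadata
        if m.role == "treated"
    }
    context = sorted(ctx)[0] if len(ctx) == 1 else ("mixed", "mixed", float("nan"))
    feat_by_id = {f.feature_id: f for f in features}
    rows: dict[tuple, dict] = {}
    for m in matches:
        st = stats.get(m.feature_id)
        if st is None or not st.significant:
            continue
        feat = feat_by_id.get(m.feature_id)
        if feat is None:
            continue
        abundance = float(np.mean([feat.areas.get(s, 0.0) for s in treated]))
        info = compound_info.get(m.candidate_id, {})
        key = (m.candidate_id, *context)
        row = rows.get(key)
        if row is None or m.confidence_level < row["confidence_level"]:
            rows[key] = {
                "compound": m.candidate_id,
                "sources": str(info.get("sources", "CMP" if m.tentative else "")),
                "matrix": context[0],
                "environment": context[1],
                "timepoint": context[2],
                "present": True,
                "confidence_level": m.confidence_level,
                "abundance": abundance,
                "acquisition_modes": {m.acquisition_mode},
                "feature_ids": {m.feature_id},
            }
        else:
            row["acquisition_modes"].add(m.acquisition_mode)
            row["feature_ids"].add(m.feature_id)
            row["abundance"] = max(row["abundance"], abundance)
    out = sorted(rows.values(), key=lambda r: (-r["abundance"], r["compound"]))
    top = max((r["abundance"] for r in out), default=0.0)
    for r in out:
        r["normalized_abundance"] = round(100.0 * r["abundance"] / top, 2) if top > 0 else 0.0
        r["acquisition_modes"] = ",".join(sorted(r["acquisition_modes"]))
        r["feature_ids"] = ",".join(sorted(r["feature_ids"]))
        del r["abundance"]
    return pd.DataFrame(
        out,
        columns=[
            "compound", "sources", "matrix", "environment", "timepoint", "present",
            "confidence_level", "normalized_abundance", "acquisition_modes",
            "feature_ids",
        ],
    )


def mode_venn(matches: Iterable[MatchResult], sample_type: str = "") -> dict[str, int]:
    """Region counts of identified elements across acquisition modes.

    An element is one (compound, sample type) pair; each element belongs
    to the set of every mode that identified it.  Returns exclusive region
    counts keyed by '&'-joined mode names, plus per-mode totals prefixed
    'total:' and the overall element count.
    """
    elements: dict[tuple[str, str], set[str]] = {}
    for m in matches:
        elements.setdefault((m.candidate_id, sample_type), set()).add(m.acquisition_mode)
    modes = sorted({mode for s in elements.values() for mode in s})
    out: dict[str, int] = {"elements": len(elements)}
    for mode in modes:
        out[f"total:{mode}"] = sum(1 for s in elements.values() if mode in s)
    for r in range(1, len(modes) + 1):
        for combo in combinations(modes, r):
            region = sum(1 for s in elements.values() if s == set(combo))
            out["&".join(combo)] = region
    return out


def stats_to_frame(stats: Mapping[str, FeatureStats]) -> pd.DataFrame:
    rows = []
    for st in stats.values():
        rows.append(
            {
                "feature_id": st.feature_id,
                "qc_rsd": round(st.qc_rsd, 4) if np.isfinite(st.qc_rsd) else "",
                "qc_presence": round(st.qc_presence, 4),
                "max_group_presence": round(max(st.group_presence.values(), default=0.0), 4),
                "passes_prefilter": st.passes_prefilter,
                "p_value": "" if st.p_value is None else f"{st.p_value:.6g}",
                "fold_change": "" if st.fold_change is None else f"{st.fold_change:.6g}",
                "significant": st.significant,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "feature_id", "qc_rsd", "qc_presence", "max_group_presence",
            "passes_prefilter", "p_value", "fold_change", "significant",
        ],
    )
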