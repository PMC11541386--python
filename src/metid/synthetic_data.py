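"""Simulated uptake experiments for end-to-end testing of the pipeline.

Real suspect-screening inputs (vendor raw files, alignment exports) are not
shippable, so this module fabricates them: the six packaged parent
pharmaceuticals with their characteristic ESI+/ESI- ions, per-collision-
energy parent spectra, and aligned feature tables with the study's
treated / control / pooled-QC structure, spiked metabolite features and
decoys.  Areas follow a lognormal model with a multiplicative treatment
effect, the simplest generative model consistent with the log-transform
used in triage.  Every draw comes from one seeded generator, so identical
configurations give identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .chem_registry import (
    CandidateMetabolite,
    ParentCompound,
    adduct_for_polarity,
    adduct_mz,
    load_parents,
)
from .feature_matching import SampleMetadata
from .spectral_synthesis import Peak, SpectralLibrary, SpectrumRecord, merge_energy_levels

__all__ = [
    "SimConfig",
    "packaged_parents",
    "parent_fragment_ions",
    "parent_energy_spectra",
    "parent_merged_spectra",
    "simulate_feature_table",
    "make_decoys",
]

#: Collision energies emulating a fragmentation-prediction run.
ENERGY_LEVELS = (10.0, 20.0, 40.0)
#: Energies merged into the library (the 40 eV level is dropped).
ENERGIES_INCLUDED = frozenset({10.0, 20.0})

# unspecific low-mass fragments present only at the highest energy
_JUNK_FRAGMENTS = (51.0233, 55.0178)


def packaged_parents() -> list[ParentCompound]:
    """The six packaged parent pharmaceuticals."""
    return load_parents()


def parent_fragment_ions() -> dict[tuple[str, str], list[float]]:
    """Characteristic precursor/product ions per (parent_id, polarity).

    These are the shared diagnostic ions of each parent and its
    metabolites; they stand in for fragmentation-prediction output when
    building the demo libraries.
    """
    with resources.files("metid.data").joinpath("parent_fragments.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    out: dict[tuple[str, str], list[float]] = {}
    for row in df.to_dict("records"):
        out[(str(row["parent_id"]), str(row["polarity"]))] = [
            float(x) for x in str(row["ions"]).split()
        ]
    return out


def _ranked_intensities(n: int, top: float) -> list[float]:
    return [top * 0.85**k for k in range(n)]


def parent_energy_spectra(
    polarity: str = "positive",
) -> dict[str, dict[float, SpectrumRecord]]:
    """Per-collision-energy parent spectra, {parent_id: {CE: record}}.

    Low energy (10 eV) keeps the larger fragments, 20 eV shows the full
    ion set, and 40 eV is dominated by small fragments plus unspecific
    low-mass ions — the reason that level is excluded from libraries.
    """
    adduct = adduct_for_polarity(polarity)
    ions = parent_fragment_ions()
    out: dict[str, dict[float, SpectrumRecord]] = {}
    for parent in packaged_parents():
        key = (parent.id, polarity)
        if key not in ions:
            continue
        mzs = sorted(ions[key], reverse=True)
        precursor = adduct_mz(parent.neutral_mass, adduct)
        half = max(1, (len(mzs) + 1) // 2)
        ce10 = [Peak(m, i) for m, i in zip(mzs[:half], _ranked_intensities(half, 100.0))]
        ce20 = [Peak(m, i) for m, i in zip(mzs, _ranked_intensities(len(mzs), 80.0))]
        low = mzs[half:] if len(mzs) > half else mzs
        ce40 = [Peak(m, i) for m, i in zip(low, _ranked_intensities(len(low), 90.0))]
        ce40 += [Peak(m, 60.0) for m in _JUNK_FRAGMENTS]
        out[parent.id] = {
            ce: SpectrumRecord(
                compound_id=parent.name,
                adduct=adduct,
                precursor_mz=precursor,
                peaks=tuple(peaks),
                energy_provenance=frozenset({ce}),
                tentative=False,
                formula=parent.formula.to_hill(),
            )
            for ce, peaks in ((10.0, ce10), (20.0, ce20), (40.0, ce40))
        }
    return out


def parent_merged_spectra(polarity: str = "positive") -> dict[str, SpectrumRecord]:
    """CE-merged (10 + 20 eV) parent spectra keyed by parent_id."""
    return {
        pid: merge_energy_levels(levels, ENERGIES_INCLUDED)
        for pid, levels in parent_energy_spectra(polarity).items()
    }


@dataclass(frozen=True)
class SimConfig:
    """Study-design knobs of the simulated uptake experiment.

    Defaults mirror the emulated study at desk scale: 3 treated + 3
    control biological samples, 8 pooled-QC injections, ~15% biological
    and ~10% QC area CV, sub-mDa mass error and small Rt jitter.
    """

    seed: int
    n_treated: int = 3
    n_control: int = 3
    n_qc: int = 8
    n_background_features: int = 100
    spike_list: tuple[tuple[str, float, float], ...] = ()  # (candidate_id, FC, base area)
    noise_cv: float = 15.0     # percent, biological replicates
    qc_cv: float = 10.0        # percent, pooled-QC injections
    mz_error_sd: float = 0.0003  # Da
    rt_jitter_sd: float = 0.02   # minutes
    missing_rate: float = 0.0    # applied to background features
    acquisition_mode: str = "DDA+"
    matrix: str = "lettuce_root"
    timepoint: float = 14.0
    environment: str = "hydroponic"
    include_parents: bool = True
    mz_range: tuple[float, float] = (60.0, 800.0)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if min(self.n_treated, self.n_control, self.n_qc, self.n_background_features) < 0:
            raise ValueError("counts must be non-negative")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must be in [0, 1]")


def _sigma(cv_percent: float) -> float:
    """Lognormal shape parameter for a given coefficient of variation."""
    cv = cv_percent / 100.0
    return float(np.sqrt(np.log1p(cv * cv)))


def _lognormal_noise(rng: np.random.Generator, cv_percent: float, n: int) -> np.ndarray:
    s = _sigma(cv_percent)
    return rng.lognormal(mean=-0.5 * s * s, sigma=s, size=n)


def _ms2_string(peaks: Iterable[Peak]) -> str:
    return " ".join(f"{p.mz:.5f}:{p.intensity:.2f}" for p in peaks)


def build_metadata(config: SimConfig) -> list[SampleMetadata]:
    meta = []
    for role, prefix, n in (
        ("treated", "T", config.n_treated),
        ("control", "C", config.n_control),
        ("QC", "QC", config.n_qc),
    ):
        for i in range(1, n + 1):
            meta.append(
                SampleMetadata(
                    sample_id=f"{prefix}{i}",
                    role=role,
                    matrix=config.matrix,
                    timepoint=config.timepoint,
                    environment=config.environment,
                )
            )
    return meta


def _feature_row(
    rng: np.random.Generator,
    config: SimConfig,
    meta: Sequence[SampleMetadata],
    feature_id: str,
    mz: float,
    rt: float,
    peaks: Sequence[Peak],
    base_area: float,
    fc: float,
    in_control: bool,
) -> dict[str, object]:
    row: dict[str, object] = {
        "feature_id": feature_id,
        "mz": f"{mz:.5f}",
        "rt": f"{rt:.3f}",
        "adduct": "[M+H]+" if config.acquisition_mode.endswith("+") else "[M-H]-",
        "acquisition_mode": config.acquisition_mode,
        "ms2": _ms2_string(peaks),
    }
    treated = base_area * fc * _lognormal_noise(rng, config.noise_cv, config.n_treated)
    control = (
        base_area * _lognormal_noise(rng, config.noise_cv, config.n_control)
        if in_control
        else np.zeros(config.n_control)
    )
    pooled = (base_area * fc + (base_area if in_control else 0.0)) / 2.0
    qc = pooled * _lognormal_noise(rng, config.qc_cv, config.n_qc)
    values = np.concatenate([treated, control, qc])
    for m, v in zip(meta, values):
        row[m.sample_id] = f"{v:.1f}"
    return row


def _jittered_peaks(rng: np.random.Generator, peaks: Sequence[Peak], sd: float) -> list[Peak]:
    return [
        Peak(max(p.mz + rng.normal(0.0, sd), 1.0), max(p.intensity * (1 + rng.normal(0, 0.05)), 0.1))
        for p in peaks
    ]


def _rt_shift(rng: np.random.Generator, reaction_label: str) -> float:
    """Conjugation-dependent Rt shift sign: polar conjugates elute earlier,
    acetyl/methyl later."""
    label = reaction_label.lower()
    if any(k in label for k in ("glucose", "glucuronic", "sulfate", "glycine",
                                "alanine", "glutam", "taurine", "cysteine", "glutathione")):
        return -0.7 + rng.normal(0.0, 0.1)
    if "acetyl" in label or "methyl" in label:
        return +1.1 + rng.normal(0.0, 0.1)
    return float(rng.uniform(-0.5, 0.5))


def simulate_feature_table(
    config: SimConfig,
    library: SpectralLibrary,
    candidates: Mapping[str, CandidateMetabolite] | None = None,
    reaction_labels: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, list[SampleMetadata], pd.DataFrame]:
    """Simulate an aligned feature table against a spectral library.

    Returns (feature table, sample metadata, ground-truth ledger).  Spiked
    candidate features take their m/z and MS2 from the library record
    (with Gaussian mass error and peak jitter) and their areas are
    elevated by the spike's true fold change in treated samples only;
    parents of spiked candidates are injected as treated-only features;
    background features carry areas with no group effect and m/z kept
    >= 3 mDa away from every library precursor.
    """
    rng = np.random.default_rng(config.seed)
    meta = build_metadata(config)
    parents = {p.id: p for p in packaged_parents()}
    rows: list[dict[str, object]] = []
    ledger: list[dict[str, object]] = []
    counter = 0

    def next_id() -> str:
        nonlocal counter
        counter += 1
        return f"F{counter:04d}"

    for cand_id, fc, base in config.spike_list:
        try:
            rec = library.by_id(cand_id)
        except KeyError:
            raise ValueError(f"spike references unknown library candidate {cand_id!r}")
        if fc <= 0 or base <= 0:
            raise ValueError(f"spike {cand_id}: FC and base area must be positive")

    # parent compounds of the spiked metabolites, as treated-only features
    spiked_parent_ids: list[str] = []
    if config.include_parents and candidates is not None:
        seen = set()
        for cand_id, _, _ in config.spike_list:
            cand = candidates.get(cand_id)
            if cand is None or cand.parent_id in seen:
                continue
            seen.add(cand.parent_id)
            parent = parents.get(cand.parent_id)
            try:
                rec = library.by_id(parent.name)
            except (KeyError, AttributeError):
                continue
            fid = next_id()
            spiked_parent_ids.append(parent.id)
            rt = (parent.rt_min or rng.uniform(2, 10)) + rng.normal(0, config.rt_jitter_sd)
            rows.append(
                _feature_row(
                    rng, config, meta, fid,
                    mz=rec.precursor_mz + rng.normal(0.0, config.mz_error_sd),
                    rt=max(rt, 0.1),
                    peaks=_jittered_peaks(rng, rec.peaks, 0.001),
                    base_area=10.0 ** rng.uniform(5.5, 6.5),
                    fc=30.0,
                    in_control=False,
                )
            )
            ledger.append(
                {"feature_id": fid, "kind": "parent", "candidate_id": parent.name,
                 "true_fc": np.inf, "base_area": np.nan}
            )

    for cand_id, fc, base in config.spike_list:
        rec = library.by_id(cand_id)
        fid = next_id()
        rt = rng.uniform(1.0, 12.0)
        if candidates is not None and cand_id in candidates:
            cand = candidates[cand_id]
            parent = parents.get(cand.parent_id)
            if parent is not None and parent.rt_min is not None:
                label = (reaction_labels or {}).get(cand.reaction_id or "", "")
                rt = parent.rt_min + _rt_shift(rng, label)
        rt = max(rt + rng.normal(0.0, config.rt_jitter_sd), 0.1)
        rows.append(
            _feature_row(
                rng, config, meta, fid,
                mz=rec.precursor_mz + rng.normal(0.0, config.mz_error_sd),
                rt=rt,
                peaks=_jittered_peaks(rng, rec.peaks, 0.001),
                base_area=base,
                fc=fc,
                in_control=True,
            )
        )
        ledger.append(
            {"feature_id": fid, "kind": "spike", "candidate_id": cand_id,
             "true_fc": fc, "base_area": base}
        )

    # background features: no group effect, precursors kept off-library
    precursors = np.array(sorted(r.precursor_mz for r in library.records))
    lo, hi = config.mz_range
    for _ in range(config.n_background_features):
        while True:
            mz = float(rng.uniform(lo, hi))
            if precursors.size == 0:
                break
            i = np.searchsorted(precursors, mz)
            near = min(
                abs(mz - precursors[j]) for j in (max(i - 1, 0), min(i, len(precursors) - 1))
            )
            if near > 0.003:
                break
        fid = next_id()
        n_pk = int(rng.integers(3, 8))
        peaks = sorted(
            Peak(float(rng.uniform(50.0, max(mz - 1.0, 51.0))), float(rng.uniform(5, 100)))
            for _ in range(n_pk)
        )
        row = _feature_row(
            rng, config, meta, fid,
            mz=mz,
            rt=float(rng.uniform(0.5, 13.0)),
            peaks=peaks,
            base_area=10.0 ** rng.uniform(4.0, 6.0),
            fc=1.0,
            in_control=True,
        )
        if config.missing_rate > 0:
            for m in meta:
                if rng.uniform() < config.missing_rate:
                    row[m.sample_id] = "0.0"
        rows.append(row)
        ledger.append(
            {"feature_id": fid, "kind": "background", "candidate_id": "",
             "true_fc": 1.0, "base_area": np.nan}
        )

    columns = ["feature_id", "mz", "rt", "adduct", "acquisition_mode", "ms2"] + [
        m.sample_id for m in meta
    ]
    table = pd.DataFrame(rows, columns=columns)
    return table, meta, pd.DataFrame(ledger)


def make_decoys(
    library: SpectralLibrary,
    offset: float,
    config: SimConfig | None = None,
    n: int = 10,
    ms1_tol: float = 0.001,
) -> pd.DataFrame:
    """Decoy features: library precursors shifted by ``offset`` (Da) with
    shuffled MS2 intensities and treatment-elevated areas.

    Decoys pass the statistical funnel but sit outside the mass tolerance,
    so a correct matcher reports none of them; requires
    ``offset > 2 x ms1_tol`` for an unambiguous negative control.
    """
    if offset <= 2 * ms1_tol:
        raise ValueError(f"decoy offset {offset} must exceed 2 x ms1_tol = {2 * ms1_tol}")
    if config is None:
        config = SimConfig(seed=0)
    rng = np.random.default_rng(config.seed + 7)
    meta = build_metadata(config)
    rows = []
    for k, rec in enumerate(library.records[:n]):
        intensities = [p.intensity for p in rec.peaks]
        rng.shuffle(intensities)
        peaks = [Peak(p.mz, i) for p, i in zip(rec.peaks, intensities)]
        rows.append(
            _feature_row(
                rng, config, meta, f"DECOY{k + 1:03d}",
                mz=rec.precursor_mz + offset,
                rt=float(rng.uniform(1.0, 12.0)),
                peaks=peaks,
                base_area=10.0 ** rng.uniform(4.5, 5.5),
                fc=10.0,
                in_control=True,
            )
        )
    columns = ["feature_id", "mz", "rt", "adduct", "acquisition_mode", "ms2"] + [
        m.sample_id for m in meta
    ]
    return pd.DataFrame(rows, columns=columns)
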