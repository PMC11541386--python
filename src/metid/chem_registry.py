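"""Parent compounds, biotransformation reactions and candidate metabolites.

This module is the chemical bookkeeping layer of the suspect-screening
pipeline: elemental formulas and their monoisotopic masses, [M+H]+/[M-H]-
adduct m/z values, and the enumeration of candidate metabolites by applying
signed elemental-formula deltas (common metabolic pathways, CMP) to parent
pharmaceuticals.  Candidates from external predictors (SP) or literature
searches (LS) carry exact structures and are ingested from tables; CMP
candidates are tentative (formula only, no SMILES) because the site of
metabolism is not resolved.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "ATOMIC_MASSES",
    "ElementalFormula",
    "ParentCompound",
    "ReactionPathway",
    "CandidateMetabolite",
    "AdductSpec",
    "ADDUCT_M_PLUS_H",
    "ADDUCT_M_MINUS_H",
    "UnknownElementError",
    "ReactionNotApplicableError",
    "monoisotopic_mass",
    "adduct_mz",
    "apply_reaction",
    "enumerate_cmp",
    "ingest_candidate_table",
    "mz_cutoff_filter",
    "venn_by_isomer_group",
    "load_parents",
    "load_reactions",
    "candidates_to_frame",
]

# element order used for canonical (Hill) formula strings
_HILL_ORDER = ("C", "H", "Cl", "F", "N", "O", "P", "S")

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")
_DELTA_SEGMENT = re.compile(r"([+\-−])\s*([A-Za-z0-9]+)")


class UnknownElementError(ValueError):
    """Raised when a formula contains an element outside the supported set."""


class ReactionNotApplicableError(ValueError):
    """Raised when applying a reaction would remove atoms the parent lacks."""


def _load_atomic_masses() -> dict[str, float]:
    with resources.files("metid.data").joinpath("atomic_masses.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    return dict(zip(df["element"], df["monoisotopic_mass"]))


#: Packaged monoisotopic atomic-mass table (IUPAC values, fixed).
ATOMIC_MASSES: dict[str, float] = _load_atomic_masses()

#: Monoisotopic mass of a hydrogen atom; the [M+H]+/[M-H]- adduct shift.
HYDROGEN_MASS = ATOMIC_MASSES["H"]


@dataclass(frozen=True)
class ElementalFormula:
    """A signed element-count map.

    Compound formulas have all counts >= 0; reaction deltas may carry
    negative counts (atoms removed by the transformation).
    """

    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        clean = {}
        for sym, n in self.counts.items():
            if sym not in ATOMIC_MASSES:
                raise UnknownElementError(f"unsupported element symbol: {sym!r}")
            if not float(n).is_integer():
                raise ValueError(f"non-integer count for {sym}: {n}")
            if n != 0:
                clean[sym] = int(n)
        object.__setattr__(self, "counts", dict(clean))

    @classmethod
    def from_string(cls, text: str) -> "ElementalFormula":
        """Parse a Hill-notation formula string such as ``C6H10O5``."""
        text = text.strip()
        counts: dict[str, int] = {}
        pos = 0
        for m in _FORMULA_TOKEN.finditer(text):
            if m.start() != pos:
                raise ValueError(f"cannot parse formula {text!r} at {text[pos:]!r}")
            pos = m.end()
            sym, num = m.group(1), m.group(2)
            counts[sym] = counts.get(sym, 0) + (int(num) if num else 1)
        if pos != len(text):
            raise ValueError(f"cannot parse formula {text!r} at {text[pos:]!r}")
        return cls(counts)

    @classmethod
    def from_delta_string(cls, text: str) -> "ElementalFormula":
        """Parse a signed delta expression such as ``+C6H10O5`` or ``-H2O+SO3``.

        A leading sign is required on every segment; the Unicode minus is
        accepted alongside ASCII ``-``.
        """
        text = text.strip()
        if not text:
            return cls({})
        counts: dict[str, int] = {}
        pos = 0
        for m in _DELTA_SEGMENT.finditer(text):
            if m.start() != pos:
                raise ValueError(f"cannot parse delta {text!r} at {text[pos:]!r}")
            pos = m.end()
            sign = -1 if m.group(1) in "-−" else 1
            part = cls.from_string(m.group(2))
            for sym, n in part.counts.items():
                counts[sym] = counts.get(sym, 0) + sign * n
        if pos != len(text):
            raise ValueError(f"cannot parse delta {text!r} at {text[pos:]!r}")
        return cls(counts)

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        counts = dict(self.counts)
        for sym, n in other.counts.items():
            counts[sym] = counts.get(sym, 0) + n
        return ElementalFormula(counts)

    @property
    def is_compound(self) -> bool:
        """True if all element counts are non-negative."""
        return all(n >= 0 for n in self.counts.values())

    def to_hill(self) -> str:
        """Canonical formula string (C, H, then other elements alphabetically)."""
        parts = []
        for sym in _HILL_ORDER:
            n = self.counts.get(sym, 0)
            if n == 0:
                continue
            if n < 0:
                raise ValueError("cannot render a signed delta in Hill notation")
            parts.append(sym if n == 1 else f"{sym}{n}")
        return "".join(parts)

    def to_delta_string(self) -> str:
        gain = ElementalFormula({s: n for s, n in self.counts.items() if n > 0})
        loss = ElementalFormula({s: -n for s, n in self.counts.items() if n < 0})
        out = ""
        if gain.counts:
            out += "+" + gain.to_hill()
        if loss.counts:
            out += "-" + loss.to_hill()
        return out


def monoisotopic_mass(formula: ElementalFormula) -> float:
    """Signed sum of count x monoisotopic atomic mass over the formula."""
    return float(sum(n * ATOMIC_MASSES[sym] for sym, n in formula.counts.items()))


@dataclass(frozen=True)
class AdductSpec:
    """A singly charged ESI adduct: name, polarity, mass shift and charge."""

    name: str
    polarity: str
    shift: float
    charge: int


#: Protonated molecule, positive mode.  Shift is the hydrogen-atom mass.
ADDUCT_M_PLUS_H = AdductSpec("[M+H]+", "positive", +HYDROGEN_MASS, +1)
#: Deprotonated molecule, negative mode.
ADDUCT_M_MINUS_H = AdductSpec("[M-H]-", "negative", -HYDROGEN_MASS, -1)


def adduct_for_polarity(polarity: str) -> AdductSpec:
    if polarity == "positive":
        return ADDUCT_M_PLUS_H
    if polarity == "negative":
        return ADDUCT_M_MINUS_H
    raise ValueError(f"unknown polarity: {polarity!r}")


def adduct_mz(neutral_mass: float, adduct: AdductSpec) -> float:
    """m/z of the singly charged adduct of a neutral of the given mass."""
    if neutral_mass < 0:
        raise ValueError("neutral mass must be non-negative")
    return neutral_mass + adduct.shift


@dataclass(frozen=True)
class ParentCompound:
    id: str
    name: str
    formula: ElementalFormula
    smiles: str | None = None
    drug_class: str = ""
    rt_min: float | None = None

    @property
    def neutral_mass(self) -> float:
        return monoisotopic_mass(self.formula)


@dataclass(frozen=True)
class ReactionPathway:
    """A biotransformation expressed as a signed elemental-formula delta."""

    id: str
    label: str
    phase: str  # "I", "II" or "combination"
    delta: ElementalFormula

    @property
    def mass_delta(self) -> float:
        return monoisotopic_mass(self.delta)


@dataclass(frozen=True)
class CandidateMetabolite:
    """A predicted metabolite of a parent pharmaceutical.

    ``source`` is SP (software prediction), LS (literature search) or CMP
    (common metabolic pathway).  CMP candidates are tentative: no SMILES,
    and ``reaction_id`` records the generating pathway.
    """

    id: str
    parent_id: str
    source: str
    formula: ElementalFormula
    smiles: str | None = None
    reaction_id: str | None = None
    name: str = ""

    def __post_init__(self) -> None:
        if self.source not in ("SP", "LS", "CMP"):
            raise ValueError(f"unknown candidate source: {self.source!r}")
        if not self.formula.is_compound:
            raise ValueError("candidate formula has negative element counts")

    @property
    def neutral_mass(self) -> float:
        return monoisotopic_mass(self.formula)

    @property
    def tentative(self) -> bool:
        return self.smiles is None

    @property
    def isomer_group_key(self) -> tuple[str, str]:
        """Structural isomers collapse to (parent, canonical formula)."""
        return (self.parent_id, self.formula.to_hill())


def apply_reaction(parent: ParentCompound, reaction: ReactionPathway) -> CandidateMetabolite:
    """Apply one reaction delta to a parent, yielding a tentative candidate.

    Raises :class:`ReactionNotApplicableError` when the resulting formula
    would carry a negative element count (a loss the parent cannot supply);
    such pairs are rejected, never clamped.
    """
    formula = parent.formula + reaction.delta
    if not formula.is_compound:
        raise ReactionNotApplicableError(
            f"{reaction.id} not applicable to {parent.id}: "
            f"negative count in {formula.counts}"
        )
    return CandidateMetabolite(
        id=f"{parent.name}-{reaction.id}",
        parent_id=parent.id,
        source="CMP",
        formula=formula,
        smiles=None,
        reaction_id=reaction.id,
        name=f"{parent.name}-{reaction.id}",
    )


def enumerate_cmp(
    parents: Iterable[ParentCompound],
    reactions: Iterable[ReactionPathway],
    rejections: list[tuple[str, str]] | None = None,
) -> list[CandidateMetabolite]:
    """One candidate per (parent, reaction) pair, in parent-major order.

    Pairs whose formula would go negative are skipped; pass a list as
    ``rejections`` to collect the rejected (parent_id, reaction_id) pairs.
    """
    out: list[CandidateMetabolite] = []
    for parent in parents:
        for reaction in reactions:
            try:
                out.append(apply_reaction(parent, reaction))
            except ReactionNotApplicableError:
                if rejections is not None:
                    rejections.append((parent.id, reaction.id))
    return out


def ingest_candidate_table(
    rows: pd.DataFrame | Iterable[Mapping[str, object]],
    source: str,
    parents: Mapping[str, ParentCompound] | None = None,
) -> list[CandidateMetabolite]:
    """Ingest an external candidate table (SP or LS source).

    Each row needs ``name``, ``parent`` and a ``formula`` or ``smiles``;
    the formula is derived from the SMILES (rdkit) when absent.  Duplicate
    names get a disambiguating suffix so candidate ids stay unique.
    """
    if source not in ("SP", "LS"):
        raise ValueError("source must be SP or LS")
    if isinstance(rows, pd.DataFrame):
        records = rows.to_dict("records")
    else:
        records = [dict(r) for r in rows]

    def _blank(v: object) -> bool:
        return v is None or (isinstance(v, float) and pd.isna(v)) or str(v).strip() == ""

    out: list[CandidateMetabolite] = []
    seen: dict[str, int] = {}
    for i, row in enumerate(records):
        name = None if _blank(row.get("name")) else str(row["name"]).strip()
        parent_id = None if _blank(row.get("parent")) else str(row["parent"]).strip()
        if name is None or parent_id is None:
            raise ValueError(f"row {i}: missing name or parent id")
        if parents is not None and parent_id not in parents:
            raise ValueError(f"row {i}: unknown parent {parent_id!r}")
        smiles = None if _blank(row.get("smiles")) else str(row["smiles"]).strip()
        if not _blank(row.get("formula")):
            formula = ElementalFormula.from_string(str(row["formula"]).strip())
        elif smiles is not None:
            formula = _formula_from_smiles(smiles, i)
        else:
            raise ValueError(f"row {i}: neither formula nor SMILES given")
        n = seen.get(name, 0)
        seen[name] = n + 1
        cand_id = name if n == 0 else f"{name}.{n + 1}"
        out.append(
            CandidateMetabolite(
                id=cand_id,
                parent_id=parent_id,
                source=source,
                formula=formula,
                smiles=smiles,
                name=name,
            )
        )
    return out


def _formula_from_smiles(smiles: str, row_index: int) -> ElementalFormula:
    from rdkit import Chem
    from rdkit.Chem.rdMolDescriptors import CalcMolFormula

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"row {row_index}: unparseable SMILES {smiles!r}")
    raw = CalcMolFormula(mol)  # may carry charge suffixes like "+"
    return ElementalFormula.from_string(raw.rstrip("+-0123456789") if raw[-1] in "+-" else raw)


def mz_cutoff_filter(
    candidates: Iterable[CandidateMetabolite],
    cutoff: float,
    adduct: AdductSpec = ADDUCT_M_PLUS_H,
) -> list[CandidateMetabolite]:
    """Keep candidates whose adduct m/z is below the scan-range cutoff."""
    if cutoff < 0:
        raise ValueError("cutoff must be non-negative")
    return [c for c in candidates if adduct_mz(c.neutral_mass, adduct) < cutoff]


def venn_by_isomer_group(
    sp: Iterable[CandidateMetabolite],
    ls: Iterable[CandidateMetabolite],
    cmp: Iterable[CandidateMetabolite],
) -> dict[str, object]:
    """Seven-region overlap of the three prediction sources.

    Exact-structure sources (SP, LS) distinguish structural isomers; CMP
    does not, so candidates are first collapsed onto their isomer group
    (parent, canonical formula) before the set algebra.  Raw per-source
    structure counts are reported alongside the region counts.
    """
    sp, ls, cmp = list(sp), list(ls), list(cmp)
    s = {c.isomer_group_key for c in sp}
    l = {c.isomer_group_key for c in ls}
    m = {c.isomer_group_key for c in cmp}
    return {
        "raw_counts": {"SP": len(sp), "LS": len(ls), "CMP": len(cmp)},
        "group_counts": {"SP": len(s), "LS": len(l), "CMP": len(m)},
        "regions": {
            "SP_only": len(s - l - m),
            "LS_only": len(l - s - m),
            "CMP_only": len(m - s - l),
            "SP_LS": len((s & l) - m),
            "SP_CMP": len((s & m) - l),
            "LS_CMP": len((l & m) - s),
            "SP_LS_CMP": len(s & l & m),
        },
    }


def load_parents(path: object | None = None) -> list[ParentCompound]:
    """Load a parent-compound TSV (packaged six-pharmaceutical table by default)."""
    if path is None:
        with resources.files("metid.data").joinpath("parents.tsv").open() as fh:
            df = pd.read_csv(fh, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.to_dict("records"):
        smiles = row.get("smiles")
        out.append(
            ParentCompound(
                id=str(row["id"]),
                name=str(row["name"]),
                formula=ElementalFormula.from_string(str(row["formula"])),
                smiles=None if pd.isna(smiles) or str(smiles) == "" else str(smiles),
                drug_class=str(row.get("drug_class", "")),
                rt_min=float(row["rt_min"]) if "rt_min" in row and pd.notna(row["rt_min"]) else None,
            )
        )
    ids = [p.id for p in out]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate parent ids in registry")
    return out


def load_reactions(path: object | None = None) -> list[ReactionPathway]:
    """Load a reaction-pathway TSV (packaged 144-entry CMP library by default)."""
    if path is None:
        with resources.files("metid.data").joinpath("reactions_cmp.tsv").open() as fh:
            df = pd.read_csv(fh, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    return [
        ReactionPathway(
            id=str(r["id"]),
            label=str(r["label"]),
            phase=str(r["phase"]),
            delta=ElementalFormula.from_delta_string(str(r["delta"])),
        )
        for r in df.to_dict("records")
    ]


def candidates_to_frame(candidates: Iterable[CandidateMetabolite]) -> pd.DataFrame:
    """Candidate export table: masses and both adduct m/z per candidate."""
    rows = []
    for c in candidates:
        mass = c.neutral_mass
        rows.append(
            {
                "id": c.id,
                "parent": c.parent_id,
                "source": c.source,
                "formula": c.formula.to_hill(),
                "smiles": c.smiles or "",
                "reaction": c.reaction_id or "",
                "neutral_mass": round(mass, 5),
                "mz_pos": round(adduct_mz(mass, ADDUCT_M_PLUS_H), 5),
                "mz_neg": round(adduct_mz(mass, ADDUCT_M_MINUS_H), 5),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "id", "parent", "source", "formula", "smiles", "reaction",
            "neutral_mass", "mz_pos", "mz_neg",
        ],
    )
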