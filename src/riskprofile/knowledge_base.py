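"""Substance-risk knowledge base.

Each active substance (ATC 5th level) carries an integer risk value in
``{0, 1, 2, 3}`` for each of nine pharmacological adverse-drug-event (ADE)
categories.  The knowledge base is the rule set that drives all downstream
scoring: a patient's per-category risk level is derived from the sum of the
risk values of their unique concurrent substances.

The on-disk formats are a small JSON schema (primary) and a flat TSV
(secondary); both round-trip losslessly.  Substances absent from the base
score 0 in every category — a regional formulary always exceeds the
risk-annotated set, so unknown codes are not an error.
"""

from __future__ import annotations

import enum
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "RiskCategory",
    "SubstanceRiskRecord",
    "KnowledgeBase",
    "KnowledgeBaseError",
    "load_kb",
    "write_kb",
    "validate_kb",
    "reference_fixture",
    "ATC_PATTERN",
]

#: ATC 5th-level code: letter, two digits, two letters, two digits (e.g. N06AA09).
ATC_PATTERN = re.compile(r"^[A-Z]\d{2}[A-Z]{2}\d{2}$")

MIN_RISK_VALUE = 0
MAX_RISK_VALUE = 3


class KnowledgeBaseError(ValueError):
    """Raised for malformed or invalid knowledge-base content."""


class RiskCategory(enum.Enum):
    """The nine ADE categories, numbered 1-9 in their conventional order."""

    ANTICHOLINERGIC = 1
    BLEEDING = 2
    CONSTIPATION = 3
    ORTHOSTATISM = 4
    QT_PROLONGATION = 5
    RENAL_TOXICITY = 6
    SEDATION = 7
    SEIZURES = 8
    SEROTONERGIC = 9

    @property
    def index(self) -> int:
        return self.value

    @property
    def key(self) -> str:
        """Machine name used in file formats and column headers."""
        return self.name.lower()

    @property
    def label(self) -> str:
        return _LABELS[self]

    @classmethod
    def from_key(cls, key: str) -> "RiskCategory":
        try:
            return cls[key.upper()]
        except KeyError:
            raise KnowledgeBaseError(f"unknown risk category: {key!r}") from None


_LABELS = {
    RiskCategory.ANTICHOLINERGIC: "Anticholinergic effect",
    RiskCategory.BLEEDING: "Risk of bleeding",
    RiskCategory.CONSTIPATION: "Constipation",
    RiskCategory.ORTHOSTATISM: "Orthostatism",
    RiskCategory.QT_PROLONGATION: "QT prolongation",
    RiskCategory.RENAL_TOXICITY: "Renal toxicity",
    RiskCategory.SEDATION: "Sedation",
    RiskCategory.SEIZURES: "Risk of seizures",
    RiskCategory.SEROTONERGIC: "Serotonergic effect",
}

#: Category keys in index order — the canonical column order everywhere.
CATEGORY_KEYS = [c.key for c in RiskCategory]


@dataclass(frozen=True)
class SubstanceRiskRecord:
    """Risk values of one substance across all nine categories.

    Parameters
    ----------
    substance_id
        ATC 5th-level code, unless ``non_atc`` is set (substance identifiers
        in the source rule base are similar to 5th-level ATC but can differ).
    name
        Human-readable substance name.
    risk_values
        Mapping category -> integer risk value in {0,1,2,3}.  Categories not
        supplied default to 0.
    components
        For combination products: per-category tuple of the printed component
        risk values.  The scoring value in ``risk_values`` is their maximum.
    """

    substance_id: str
    name: str = ""
    risk_values: Mapping[RiskCategory, int] = field(default_factory=dict)
    non_atc: bool = False
    components: Mapping[RiskCategory, tuple[int, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        full = {c: int(self.risk_values.get(c, 0)) for c in RiskCategory}
        object.__setattr__(self, "risk_values", full)

    def risk(self, category: RiskCategory) -> int:
        return self.risk_values[category]

    def violations(self) -> list[str]:
        out = []
        if not self.non_atc and not ATC_PATTERN.match(self.substance_id):
            out.append(f"{self.substance_id}: not a valid ATC 5th-level code")
        for cat, v in self.risk_values.items():
            if not (MIN_RISK_VALUE <= v <= MAX_RISK_VALUE):
                out.append(f"{self.substance_id}: risk value {v} for {cat.key} outside 0-3")
        return out


@dataclass
class KnowledgeBase:
    """Collection of :class:`SubstanceRiskRecord` keyed by substance id."""

    records: dict[str, SubstanceRiskRecord]
    version_tag: str = ""

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, substance_id: str) -> bool:
        return substance_id in self.records

    def risk(self, substance_id: str, category: RiskCategory) -> int:
        """Risk value r(s, c); unknown substances score 0."""
        rec = self.records.get(substance_id)
        return rec.risk(category) if rec is not None else 0

    def substance_ids(self) -> list[str]:
        return sorted(self.records)

    @classmethod
    def from_records(
        cls, records: Iterable[SubstanceRiskRecord], version_tag: str = ""
    ) -> "KnowledgeBase":
        out: dict[str, SubstanceRiskRecord] = {}
        for rec in records:
            if rec.substance_id in out:
                raise KnowledgeBaseError(f"duplicate substance_id: {rec.substance_id}")
            out[rec.substance_id] = rec
        kb = cls(records=out, version_tag=version_tag)
        problems = validate_kb(kb)
        if problems:
            raise KnowledgeBaseError("; ".join(problems))
        return kb


def validate_kb(kb: KnowledgeBase) -> list[str]:
    """Report every invariant violation; empty list means the base is valid."""
    problems: list[str] = []
    if not kb.records:
        problems.append("empty knowledge base")
    for sid, rec in kb.records.items():
        if sid != rec.substance_id:
            problems.append(f"key {sid} does not match record id {rec.substance_id}")
        problems.extend(rec.violations())
    return problems


# ---------------------------------------------------------------------------
# I/O


def load_kb(path: str | Path, format: str | None = None) -> KnowledgeBase:
    """Load a knowledge base from JSON or TSV.

    ``format`` may be ``"json"`` or ``"tsv"``; when omitted it is inferred
    from the file suffix.  Raises :class:`KnowledgeBaseError` for malformed
    content (naming the offending record or line) and ``FileNotFoundError``
    for a missing file.
    """
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower()
    if fmt == "json":
        return _load_json(path)
    if fmt == "tsv":
        return _load_tsv(path)
    raise KnowledgeBaseError(f"unknown knowledge-base format: {fmt!r}")


def write_kb(kb: KnowledgeBase, path: str | Path, format: str | None = None) -> None:
    """Write ``kb`` so that :func:`load_kb` round-trips it exactly."""
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower()
    if fmt == "json":
        _write_json(kb, path)
    elif fmt == "tsv":
        _write_tsv(kb, path)
    else:
        raise KnowledgeBaseError(f"unknown knowledge-base format: {fmt!r}")


def _load_json(path: Path) -> KnowledgeBase:
    with open(path, encoding="utf-8") as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise KnowledgeBaseError(f"{path}: malformed JSON at line {exc.lineno}") from exc
    if not isinstance(doc, dict) or "substances" not in doc:
        raise KnowledgeBaseError(f"{path}: expected object with a 'substances' list")
    records = []
    for i, entry in enumerate(doc["substances"]):
        try:
            risk = {RiskCategory.from_key(k): _checked_value(v, entry.get("atc", f"record {i}"))
                    for k, v in entry.get("risk", {}).items()}
            components = {
                RiskCategory.from_key(k): tuple(int(x) for x in v)
                for k, v in entry.get("components", {}).items()
            }
            records.append(
                SubstanceRiskRecord(
                    substance_id=entry["atc"],
                    name=entry.get("name", ""),
                    risk_values=risk,
                    non_atc=bool(entry.get("non_atc", False)),
                    components=components,
                )
            )
        except KeyError as exc:
            raise KnowledgeBaseError(f"{path}: record {i} missing field {exc}") from exc
    return KnowledgeBase.from_records(records, version_tag=doc.get("version", ""))


def _checked_value(v: object, where: str) -> int:
    try:
        iv = int(v)  # type: ignore[arg-type]
    except (TypeError, ValueError):
        raise KnowledgeBaseError(f"{where}: risk value {v!r} is not an integer") from None
    if not (MIN_RISK_VALUE <= iv <= MAX_RISK_VALUE):
        raise KnowledgeBaseError(f"{where}: risk value {iv} outside 0-3")
    return iv


def _write_json(kb: KnowledgeBase, path: Path) -> None:
    doc = {
        "version": kb.version_tag,
        "substances": [
            {
                "atc": rec.substance_id,
                "name": rec.name,
                "risk": {c.key: rec.risk(c) for c in RiskCategory},
                **({"non_atc": True} if rec.non_atc else {}),
                **(
                    {"components": {c.key: list(v) for c, v in rec.components.items()}}
                    if rec.components
                    else {}
                ),
            }
            for rec in (kb.records[sid] for sid in kb.substance_ids())
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


_TSV_HEADER = ["atc", "name"] + CATEGORY_KEYS


def _load_tsv(path: Path) -> KnowledgeBase:
    records = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _TSV_HEADER:
            raise KnowledgeBaseError(f"{path}: bad TSV header {header!r}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(_TSV_HEADER):
                raise KnowledgeBaseError(f"{path}: line {lineno}: expected {len(_TSV_HEADER)} fields")
            risk = {
                RiskCategory.from_key(key): _checked_value(v, f"{path} line {lineno}")
                for key, v in zip(CATEGORY_KEYS, fields[2:])
            }
            records.append(SubstanceRiskRecord(fields[0], fields[1], risk))
    return KnowledgeBase.from_records(records)


def _write_tsv(kb: KnowledgeBase, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_TSV_HEADER) + "\n")
        for sid in kb.substance_ids():
            rec = kb.records[sid]
            row = [sid, rec.name] + [str(rec.risk(c)) for c in RiskCategory]
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# Reference fixture: the top-10 substances per category among highest-risk
# patients, with their published per-category risk values.  Categories not
# listed for a substance default to 0 (only published values are trusted;
# the full proprietary rule base assigns more).

_A = RiskCategory.ANTICHOLINERGIC
_B = RiskCategory.BLEEDING
_C = RiskCategory.CONSTIPATION
_O = RiskCategory.ORTHOSTATISM
_Q = RiskCategory.QT_PROLONGATION
_R = RiskCategory.RENAL_TOXICITY
_SE = RiskCategory.SEDATION
_SZ = RiskCategory.SEIZURES
_ST = RiskCategory.SEROTONERGIC

# (atc, name, {category: value})
_FIXTURE_ROWS: list[tuple[str, str, dict[RiskCategory, int]]] = [
    ("N06AA09", "Amitriptyline", {_A: 3, _C: 2, _O: 3, _ST: 2}),
    ("R06AD02", "Promethazine", {_A: 3, _O: 2}),
    ("N05BB01", "Hydroxyzine", {_A: 2, _Q: 2}),
    ("N02AA05", "Oxycodone", {_A: 1, _C: 3, _O: 2, _Q: 1, _SE: 2, _SZ: 1, _ST: 1}),
    ("R03BB04", "Tiotropium", {_A: 2}),
    ("N05AH03", "Olanzapine", {_A: 3, _SZ: 2}),
    ("R06AD01", "Alimemazine", {_A: 2, _SZ: 1}),
    ("N06AX11", "Mirtazapine", {_A: 1, _Q: 1, _SE: 2}),
    ("N05CM06", "Propiomazine", {_A: 1, _SE: 2, _SZ: 1}),
    ("N05AH04", "Quetiapine", {_A: 2, _SZ: 2}),
    ("B01AC06", "Acetylsalicylic acid, low-dose", {_B: 2}),
    ("B01AF02", "Apixaban", {_B: 3}),
    ("B01AB10", "Tinzaparin", {_B: 3}),
    ("B01AC04", "Clopidogrel", {_B: 3}),
    ("M01AE02", "Naproxen", {_B: 2, _R: 1}),
    ("B01AA03", "Warfarin", {_B: 3}),
    ("M01AE01", "Ibuprofen", {_B: 2, _R: 1}),
    ("M01AB05", "Diclofenac", {_B: 2, _R: 1}),
    ("H02AB06", "Prednisolone", {_B: 1}),
    ("B01AC24", "Ticagrelor", {_B: 3}),
    ("N02AA01", "Morphine", {_C: 3, _SE: 2}),
    ("C10AA05", "Atorvastatin", {_C: 1}),
    ("N02AJ06", "Paracetamol, codeine", {_C: 2}),
    ("A07DA03", "Loperamide", {_C: 3}),
    ("B03AA07", "Iron", {_C: 3}),
    ("C03CA01", "Furosemide", {_C: 1}),
    ("N02AB01", "Ketobemidone", {_C: 3}),
    ("C07AB07", "Bisoprolol", {_C: 1}),
    ("C09CA01", "Losartan", {_O: 2}),
    ("C01DA14", "Isosorbide mononitrate", {_O: 3}),
    ("C01DA02", "Glyceryl trinitrate", {_O: 3}),
    ("C07AG02", "Carvedilol", {_O: 3}),
    ("C09AA02", "Enalapril", {_O: 1}),
    ("C02CA04", "Doxazosin", {_O: 3}),
    ("A04AA01", "Ondansetron", {_Q: 2}),
    ("J01MA02", "Ciprofloxacin", {_Q: 2}),
    ("N06AB10", "Escitalopram", {_Q: 2, _ST: 3}),
    ("N06AB06", "Sertraline", {_Q: 1, _ST: 3}),
    ("N06AB04", "Citalopram", {_Q: 2, _ST: 3}),
    ("A03FA01", "Metoclopramide", {_Q: 1, _ST: 2}),
    ("J02AC01", "Fluconazole", {_Q: 2}),
    ("A02BC01", "Omeprazole", {_R: 1}),
    ("A02BC05", "Esomeprazole", {_R: 1}),
    ("L04AX03", "Methotrexate", {_R: 1}),
    ("M01AE03", "Ketoprofen", {_R: 1}),
    ("M01AH05", "Etoricoxib", {_R: 1}),
    ("J05AB11", "Valaciclovir", {_R: 1}),
    ("A07EC01", "Sulfasalazine", {_R: 1}),
    ("N05CF01", "Zopiclone", {_SE: 2}),
    ("N05BA04", "Oxazepam", {_SE: 3}),
    ("N05BA01", "Diazepam", {_SE: 3}),
    ("N05CF02", "Zolpidem", {_SE: 2}),
    ("N05CD08", "Midazolam", {_SE: 3}),
    ("N03AX12", "Gabapentin", {_SE: 2}),
    ("N05AA02", "Levomepromazine", {_SZ: 3}),
    ("L04AD01", "Ciclosporin", {_SZ: 3}),
    ("N05AH02", "Clozapine", {_SZ: 3}),
    ("N05AF05", "Zuclopenthixol", {_SZ: 2}),
    ("L04AA06", "Mycophenolic acid", {_SZ: 1}),
    ("N06AX16", "Venlafaxine", {_ST: 3}),
    ("N02AX02", "Tramadol", {_ST: 3}),
    ("N06AX21", "Duloxetine", {_ST: 3}),
    ("N06AB03", "Fluoxetine", {_ST: 3}),
]

# Combination product: components 2 (losartan) / 1 (hydrochlorothiazide) for
# orthostatism; scored as their maximum, components kept as metadata.
_COMBINATION_ROWS: list[tuple[str, str, dict[RiskCategory, tuple[int, ...]]]] = [
    ("C09DA01", "Losartan/hydrochlorothiazide", {_O: (2, 1)}),
]


def reference_fixture() -> KnowledgeBase:
    """Deterministic reference knowledge base of published substance risk values.

    Contains every published (substance, category, value) triple from the
    top-10-per-category ranking; unprinted categories default to 0.
    """
    records = [
        SubstanceRiskRecord(atc, name, dict(risk)) for atc, name, risk in _FIXTURE_ROWS
    ]
    for atc, name, comps in _COMBINATION_ROWS:
        records.append(
            SubstanceRiskRecord(
                atc,
                name,
                {c: max(vals) for c, vals in comps.items()},
                components={c: tuple(vals) for c, vals in comps.items()},
            )
        )
    return KnowledgeBase.from_records(records, version_tag="reference-top10")
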