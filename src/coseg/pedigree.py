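"""Pedigrees in CanRisk tabular format: reading, writing, validation, trimming.

The CanRisk exchange format (used by the CanRisk/BOADICEA risk tool) carries
family structure, per-cancer diagnosis ages, vital status and gene-test
results in a whitespace-separated table headed by a ``##CanRisk`` version
line and a ``##``-prefixed column row.  This module maps that table onto an
in-memory :class:`Pedigree` of :class:`Individual` records suitable for
co-segregation analysis of a single rare variant.
"""

from __future__ import annotations

import copy
import io
import os
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional

import networkx as nx

__all__ = [
    "Sex",
    "Genotype",
    "CancerType",
    "CancerEvent",
    "Individual",
    "Pedigree",
    "Finding",
    "PedigreeError",
    "ParseError",
    "ValidationError",
    "read_canrisk",
    "write_canrisk",
    "validate_pedigree",
    "trim_pedigree",
    "ANALYSIS_GENES",
]

MAX_AGE = 130.0

#: Genes supported for the variant under analysis.
ANALYSIS_GENES = ("BRCA1", "BRCA2", "PALB2")


class PedigreeError(ValueError):
    """Base class for pedigree-level errors."""


class ParseError(PedigreeError):
    """Malformed CanRisk input; carries the offending row/column when known."""

    def __init__(self, message: str, row: Optional[int] = None, column: Optional[str] = None):
        loc = []
        if row is not None:
            loc.append(f"row {row}")
        if column is not None:
            loc.append(f"column {column!r}")
        super().__init__(message + (f" ({', '.join(loc)})" if loc else ""))
        self.row = row
        self.column = column


class ValidationError(PedigreeError):
    """A pedigree violating structural invariants; carries the findings."""

    def __init__(self, findings: list["Finding"]):
        self.findings = findings
        super().__init__("; ".join(f.message for f in findings))


class Sex(str, Enum):
    FEMALE = "F"
    MALE = "M"


class Genotype(str, Enum):
    CARRIER = "carrier"
    NONCARRIER = "noncarrier"
    UNTESTED = "untested"


class CancerType(str, Enum):
    BC = "BC"      # first primary breast cancer
    CBC = "CBC"    # contralateral (second primary) breast cancer
    OC = "OC"      # ovarian cancer
    PANC = "PANC"  # pancreatic cancer


@dataclass(frozen=True)
class CancerEvent:
    """One cancer diagnosis: type and age at onset (years)."""

    cancer_type: CancerType
    age: float

    def __post_init__(self):
        if not (0 <= self.age <= MAX_AGE):
            raise PedigreeError(f"event age {self.age} outside [0, {MAX_AGE}]")


@dataclass
class Individual:
    """One pedigree member with phenotype history and test result.

    ``censor_age`` is the age at last examination (or death); 0 encodes an
    unknown age, whose survival contribution is 1 (uninformative).
    """

    id: str
    father_id: Optional[str] = None
    mother_id: Optional[str] = None
    sex: Sex = Sex.FEMALE
    is_proband: bool = False
    genotype: Genotype = Genotype.UNTESTED
    events: list[CancerEvent] = field(default_factory=list)
    censor_age: float = 0.0
    is_dead: bool = False
    mz_twin_group: Optional[str] = None
    name: Optional[str] = None
    yob: Optional[int] = None
    extras: dict[str, str] = field(default_factory=dict)

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None

    @property
    def affected(self) -> bool:
        return bool(self.events)

    def event_age(self, cancer_type: CancerType) -> Optional[float]:
        for ev in self.events:
            if ev.cancer_type == cancer_type:
                return ev.age
        return None


@dataclass
class Pedigree:
    """A family: members keyed by id plus the proband (index case)."""

    family_id: str
    members: dict[str, Individual]
    proband_id: str

    @property
    def proband(self) -> Individual:
        return self.members[self.proband_id]

    def children_of(self, individual_id: str) -> list[Individual]:
        return [m for m in self.members.values()
                if individual_id in (m.father_id, m.mother_id)]

    def copy(self) -> "Pedigree":
        return copy.deepcopy(self)

    def graph(self) -> nx.DiGraph:
        """Parent → child directed graph over member ids."""
        g = nx.DiGraph()
        g.add_nodes_from(self.members)
        for m in self.members.values():
            for pid in (m.father_id, m.mother_id):
                if pid is not None:
                    g.add_edge(pid, m.id)
        return g


@dataclass(frozen=True)
class Finding:
    """A validation finding: ``level`` is 'error' or 'warning'."""

    level: str
    code: str
    message: str
    individual_id: Optional[str] = None


# ---------------------------------------------------------------------------
# CanRisk reading
# ---------------------------------------------------------------------------

# Canonical CanRisk v2 column order, used when writing from scratch.
_CANONICAL_COLUMNS = [
    "FamID", "Name", "Target", "IndivID", "FathID", "MothID", "Sex", "MZtwin",
    "Dead", "Age", "Yob", "BC1", "BC2", "OC", "PRO", "PAN", "Ashkn",
    "BRCA1", "BRCA2", "PALB2", "ATM", "CHEK2", "BARD1", "RAD51B", "RAD51C",
    "RAD51D", "ER:PR:HER2:CK14:CK56",
]

_STRUCTURAL = {"FamID", "Name", "Target", "IndivID", "FathID", "MothID", "Sex",
               "MZtwin", "Dead", "Age", "Yob", "BC1", "BC2", "OC", "PAN"}

_AGE_COLUMNS = {"BC1": CancerType.BC, "BC2": CancerType.CBC,
                "OC": CancerType.OC, "PAN": CancerType.PANC}


def _parse_gene_result(token: str) -> Genotype:
    """Map a CanRisk gene-test cell (``testtype:result`` or bare result)."""
    result = token.split(":")[-1].strip().upper()
    if result == "P":
        return Genotype.CARRIER
    if result == "N":
        return Genotype.NONCARRIER
    return Genotype.UNTESTED


def _format_gene_result(genotype: Genotype) -> str:
    return {Genotype.CARRIER: "S:P", Genotype.NONCARRIER: "S:N",
            Genotype.UNTESTED: "0:0"}[genotype]


def _as_text(path_or_text) -> str:
    if isinstance(path_or_text, io.TextIOBase):
        return path_or_text.read()
    if isinstance(path_or_text, os.PathLike):
        return open(path_or_text).read()
    if isinstance(path_or_text, str):
        if "\n" not in path_or_text and os.path.exists(path_or_text):
            return open(path_or_text).read()
        return path_or_text
    raise TypeError(f"cannot read pedigree from {type(path_or_text)!r}")


def read_canrisk(path_or_text, gene: Optional[str] = None) -> Pedigree:
    """Read a CanRisk pedigree file (path, text, or open handle).

    Parameters
    ----------
    path_or_text:
        File path, file object, or the file contents themselves.
    gene:
        Gene whose test-result column defines the per-individual genotype of
        the variant under study (one VUS per analysis).  When omitted, the
        single analysis gene with any recorded results is auto-detected.

    Returns a validated :class:`Pedigree`.  Raises :class:`ParseError` for
    malformed rows and :class:`ValidationError` for structural violations
    (missing proband, proband not a carrier, CBC before BC, ...).
    """
    text = _as_text(path_or_text)
    lines = [ln.rstrip("\n") for ln in text.splitlines() if ln.strip()]
    if not lines or not lines[0].startswith("##CanRisk"):
        raise ParseError("not a CanRisk file: first line must start with '##CanRisk'", row=1)

    header_idx = None
    for i, ln in enumerate(lines[1:], start=1):
        if ln.startswith("##"):
            header_idx = i
        else:
            break
    if header_idx is None:
        raise ParseError("missing '##'-prefixed column header row")
    columns = lines[header_idx].lstrip("#").split()
    if "IndivID" not in columns:
        raise ParseError("column header row lacks 'IndivID'", row=header_idx + 1)
    col_index = {c: i for i, c in enumerate(columns)}

    if gene is None:
        gene = _detect_gene(lines[header_idx + 1:], columns, col_index)
    gene = gene.upper()
    if gene not in ANALYSIS_GENES:
        raise PedigreeError(
            f"unsupported gene {gene!r}; supported: {', '.join(ANALYSIS_GENES)}")
    if gene not in col_index:
        raise ParseError(f"pedigree file has no test-result column for {gene}")

    members: dict[str, Individual] = {}
    family_id = None
    proband_id = None
    for rowno, ln in enumerate(lines[header_idx + 1:], start=header_idx + 2):
        tokens = ln.split()
        if len(tokens) != len(columns):
            raise ParseError(
                f"expected {len(columns)} fields, found {len(tokens)}", row=rowno)
        cell = lambda c: tokens[col_index[c]]

        iid = cell("IndivID")
        if iid in members:
            raise ParseError(f"duplicate individual id {iid!r}", row=rowno, column="IndivID")
        fam = cell("FamID") if "FamID" in col_index else "FAM"
        family_id = family_id or fam

        sex_code = cell("Sex").upper()
        if sex_code not in ("F", "M"):
            raise ParseError(f"unknown sex code {sex_code!r}", row=rowno, column="Sex")

        events = []
        for col, ctype in _AGE_COLUMNS.items():
            if col not in col_index:
                continue
            raw = cell(col)
            try:
                age = float(raw)
            except ValueError:
                # CanRisk allows AU (affected, age unknown); not modelable here
                raise ParseError(f"unparseable age {raw!r}", row=rowno, column=col)
            if age > 0:
                events.append(CancerEvent(ctype, age))
        events.sort(key=lambda e: (e.age, e.cancer_type != CancerType.BC))

        try:
            censor_age = float(cell("Age")) if "Age" in col_index else 0.0
        except ValueError:
            raise ParseError(f"unparseable age {cell('Age')!r}", row=rowno, column="Age")

        genotype = _parse_gene_result(cell(gene))
        for other in ANALYSIS_GENES:
            if other != gene and other in col_index and \
                    _parse_gene_result(cell(other)) != Genotype.UNTESTED:
                warnings.warn(
                    f"{iid}: test result for {other} ignored (analysis gene is {gene})",
                    stacklevel=2)

        is_proband = cell("Target") == "1" if "Target" in col_index else False
        if is_proband:
            if proband_id is not None:
                raise ParseError("more than one proband (Target=1)", row=rowno, column="Target")
            proband_id = iid

        yob_raw = cell("Yob") if "Yob" in col_index else "0"
        extras = {c: tokens[col_index[c]] for c in columns
                  if c not in _STRUCTURAL and c not in ANALYSIS_GENES}

        members[iid] = Individual(
            id=iid,
            father_id=None if cell("FathID") == "0" else cell("FathID"),
            mother_id=None if cell("MothID") == "0" else cell("MothID"),
            sex=Sex(sex_code),
            is_proband=is_proband,
            genotype=genotype,
            events=events,
            censor_age=censor_age,
            is_dead=("Dead" in col_index and cell("Dead") == "1"),
            mz_twin_group=None if "MZtwin" not in col_index or cell("MZtwin") == "0"
                          else cell("MZtwin"),
            name=cell("Name") if "Name" in col_index else None,
            yob=None if yob_raw in ("0", "") else int(float(yob_raw)),
            extras=extras,
        )

    if proband_id is None:
        raise ParseError("missing proband: no row with Target=1")
    if members[proband_id].genotype != Genotype.CARRIER:
        raise ValidationError([Finding(
            "error", "proband-not-carrier",
            "proband must carry the variant (positive test result required)",
            proband_id)])

    ped = Pedigree(family_id=family_id or "FAM", members=members, proband_id=proband_id)
    _synthesize_missing_coparents(ped)
    _lift_unknown_censor_ages(ped)

    errors = [f for f in validate_pedigree(ped) if f.level == "error"]
    if errors:
        raise ValidationError(errors)
    return ped


def _detect_gene(rows: list[str], columns: list[str], col_index: dict) -> str:
    candidates = []
    for g in ANALYSIS_GENES:
        if g not in col_index:
            continue
        for ln in rows:
            tokens = ln.split()
            if len(tokens) == len(columns) and \
                    _parse_gene_result(tokens[col_index[g]]) != Genotype.UNTESTED:
                candidates.append(g)
                break
    if len(candidates) == 1:
        return candidates[0]
    if not candidates:
        raise PedigreeError("no gene-test results found; pass gene= explicitly")
    raise PedigreeError(
        f"test results present for several genes ({', '.join(candidates)}); "
        "pass gene= to select the variant under study")


def _synthesize_missing_coparents(ped: Pedigree) -> None:
    """Give every single-parent individual an untested, unaffected co-parent."""
    for m in list(ped.members.values()):
        if (m.father_id is None) != (m.mother_id is None):
            if m.father_id is None:
                new_id = f"{m.mother_id}.p"
                if new_id not in ped.members:
                    ped.members[new_id] = Individual(id=new_id, sex=Sex.MALE)
                m.father_id = new_id
            else:
                new_id = f"{m.father_id}.p"
                if new_id not in ped.members:
                    ped.members[new_id] = Individual(id=new_id, sex=Sex.FEMALE)
                m.mother_id = new_id


def _lift_unknown_censor_ages(ped: Pedigree) -> None:
    """censor_age must bound event ages; lift it when the age column was 0."""
    for m in ped.members.values():
        if m.events:
            last = max(e.age for e in m.events)
            if m.censor_age < last:
                m.censor_age = last


# ---------------------------------------------------------------------------
# CanRisk writing
# ---------------------------------------------------------------------------

def write_canrisk(pedigree: Pedigree, path=None, gene: str = "BRCA1") -> str:
    """Serialize a pedigree back to CanRisk text; returns the text.

    Unknown columns preserved in ``Individual.extras`` are written back
    verbatim; the analysis gene's column is regenerated from ``genotype``.
    """
    extra_cols: list[str] = []
    for m in pedigree.members.values():
        for c in m.extras:
            if c not in extra_cols:
                extra_cols.append(c)
    columns = [c for c in _CANONICAL_COLUMNS
               if c in _STRUCTURAL or c in ANALYSIS_GENES or c in extra_cols]
    columns += [c for c in extra_cols if c not in columns]

    out = ["##CanRisk 2.0", "##" + "\t".join(columns)]
    for m in pedigree.members.values():
        row = []
        for c in columns:
            if c == "FamID":
                row.append(pedigree.family_id)
            elif c == "Name":
                row.append(m.name or m.id)
            elif c == "Target":
                row.append("1" if m.is_proband else "0")
            elif c == "IndivID":
                row.append(m.id)
            elif c == "FathID":
                row.append(m.father_id or "0")
            elif c == "MothID":
                row.append(m.mother_id or "0")
            elif c == "Sex":
                row.append(m.sex.value)
            elif c == "MZtwin":
                row.append(m.mz_twin_group or "0")
            elif c == "Dead":
                row.append("1" if m.is_dead else "0")
            elif c == "Age":
                row.append(_fmt_age(m.censor_age))
            elif c == "Yob":
                row.append(str(m.yob) if m.yob else "0")
            elif c in _AGE_COLUMNS:
                age = m.event_age(_AGE_COLUMNS[c])
                row.append(_fmt_age(age) if age is not None else "0")
            elif c == gene:
                row.append(_format_gene_result(m.genotype))
            else:
                row.append(m.extras.get(c, "0:0" if c in ANALYSIS_GENES else "0"))
        out.append("\t".join(row))
    text = "\n".join(out) + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def _fmt_age(age: float) -> str:
    return str(int(age)) if float(age).is_integer() else str(age)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate_pedigree(pedigree: Pedigree) -> list[Finding]:
    """Structural and clinical-plausibility checks; never mutates the input.

    Errors: parent cycles, unknown parent ids, father/mother sex mismatch,
    CBC without or before BC, male ovarian cancer, censor age below an event
    age, ages beyond 130, missing/non-carrier proband.
    Warnings: uninformative genotyped set (LR will equal 1), unknown censor
    ages, individuals older than 100, MZ twins with different parents.
    """
    f: list[Finding] = []
    members = pedigree.members

    if pedigree.proband_id not in members:
        f.append(Finding("error", "no-proband", "proband id not among members"))
        return f
    if members[pedigree.proband_id].genotype != Genotype.CARRIER:
        f.append(Finding("error", "proband-not-carrier",
                         "proband must carry the variant", pedigree.proband_id))

    for m in members.values():
        for pid, role, want in ((m.father_id, "father", Sex.MALE),
                                (m.mother_id, "mother", Sex.FEMALE)):
            if pid is None:
                continue
            if pid not in members:
                f.append(Finding("error", "unknown-parent",
                                 f"{role} id {pid!r} of {m.id} not in pedigree", m.id))
            elif members[pid].sex != want:
                f.append(Finding("error", "parent-sex",
                                 f"{role} {pid} of {m.id} is not {want.name.lower()}", m.id))

        bc_age = m.event_age(CancerType.BC)
        cbc_age = m.event_age(CancerType.CBC)
        if cbc_age is not None:
            if bc_age is None:
                f.append(Finding("error", "cbc-without-bc",
                                 f"{m.id}: CBC recorded without a first BC", m.id))
            elif cbc_age < bc_age:
                f.append(Finding("error", "cbc-precedes-bc",
                                 f"{m.id}: CBC at {cbc_age} precedes BC at {bc_age}", m.id))
        if m.sex == Sex.MALE and m.event_age(CancerType.OC) is not None:
            f.append(Finding("error", "male-oc", f"{m.id}: ovarian cancer in a male", m.id))
        if m.events and m.censor_age < max(e.age for e in m.events):
            f.append(Finding("error", "censor-before-event",
                             f"{m.id}: censor age {m.censor_age} below an event age", m.id))
        if m.censor_age > MAX_AGE or any(e.age > MAX_AGE for e in m.events):
            f.append(Finding("error", "age-range", f"{m.id}: age beyond {MAX_AGE}", m.id))
        if m.censor_age > 100:
            f.append(Finding("warning", "very-old",
                             f"{m.id}: censor age {m.censor_age} exceeds 100", m.id))
        if m.censor_age == 0 and not m.events:
            f.append(Finding("warning", "unknown-age",
                             f"{m.id}: unknown age; contributes no information", m.id))

    g = pedigree.graph()
    if not nx.is_directed_acyclic_graph(g.subgraph(members)):
        f.append(Finding("error", "cycle", "parent links form a cycle"))

    twins: dict[str, list[Individual]] = {}
    for m in members.values():
        if m.mz_twin_group:
            twins.setdefault(m.mz_twin_group, []).append(m)
    for group, ms in twins.items():
        if len({(m.father_id, m.mother_id) for m in ms}) > 1:
            f.append(Finding("warning", "mz-parents",
                             f"MZ twin group {group!r} spans different parent pairs"))

    informative = [m for m in members.values()
                   if not m.is_proband and m.genotype != Genotype.UNTESTED]
    if not informative:
        f.append(Finding("warning", "uninformative",
                         "no genotyped relatives besides the proband: LR will equal 1"))
    return f


# ---------------------------------------------------------------------------
# Trimming
# ---------------------------------------------------------------------------

def trim_pedigree(pedigree: Pedigree, max_untested_age: float = 20.0) -> Pedigree:
    """Drop leaf branches of young, unaffected, untested relatives.

    Large pedigrees can exceed the genotype-enumeration budget; branches that
    contain only unaffected and untested individuals censored before
    ``max_untested_age`` carry almost no likelihood information and can be
    removed.  The proband and every affected or genotyped member are always
    retained; only childless leaves are removed (iterated to a fixed point),
    so retained members never lose their ancestors.  Idempotent.
    """
    ped = pedigree.copy()
    changed = True
    while changed:
        changed = False
        parent_ids = {pid for m in ped.members.values()
                      for pid in (m.father_id, m.mother_id) if pid is not None}
        for iid, m in list(ped.members.items()):
            if iid in parent_ids or m.is_proband:
                continue
            if (m.genotype == Genotype.UNTESTED and not m.events
                    and m.censor_age < max_untested_age):
                del ped.members[iid]
                changed = True
    return ped
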