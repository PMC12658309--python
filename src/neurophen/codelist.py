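"""Neurodisability diagnosis/procedure code list: loading, validation, matching.

A code list maps normalized ICD-10 and OPCS-4 codes to neurodisability
subgroups (e.g. "autistic spectrum disorders", "cerebral palsy"), each
belonging to one of eight condition categories.  Hospital records store
undotted 4-character ICD-10 codes, so list entries default to prefix
matching: a 3-character entry captures all of its coded children.

The code list shipped with the package (``default_codelist``) is an
illustrative re-derivation of the published subgroup taxonomy from
representative ICD-10 chapters and OPCS procedure codes; it is NOT the
clinically curated list used in the original study.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import pandas as pd

logger = logging.getLogger("neurophen.codelist")

ICD10 = "ICD10"
OPCS4 = "OPCS4"
SYSTEMS = (ICD10, OPCS4)

#: The eight condition categories of the subgroup taxonomy.
CATEGORIES = (
    "neurodevelopmental",
    "complex neurologic",
    "inherited/congenital",
    "high-risk brain",
    "visual impairment",
    "hearing impairment",
    "motor function",
    "perinatal",
)

# Subgroups whose evidence can come from structured birth fields as well as codes.
SUBGROUP_ELBW = "extremely low birth weight"
SUBGROUP_EXTREME_PREMATURITY = "extreme prematurity"

_ICD10_RE = re.compile(r"^[A-Z][0-9]{2}[0-9A-Z]{0,2}$")
_OPCS_RE = re.compile(r"^[A-Z][0-9]{2}[0-9A-Z]?$")

_CSV_COLUMNS = ["code", "system", "subgroup", "category", "match_mode", "notes"]


class CodelistError(ValueError):
    """Raised for malformed codes or invalid code-list files."""


def normalize_code(raw: str, system: str = ICD10) -> str:
    """Normalize a clinical code: strip whitespace and dots, uppercase.

    ICD-10 codes must match ``letter + 2 digits + up to 2 alphanumerics``;
    OPCS-4 codes ``letter + 2 digits + up to 1 alphanumeric``.  Codes longer
    than the maximum are truncated with a warning (fifth-character dialects).
    """
    if system not in SYSTEMS:
        raise CodelistError(f"unknown code system: {system!r}")
    code = str(raw).strip().upper().replace(".", "")
    if not code:
        raise CodelistError("empty code string")
    maxlen = 5 if system == ICD10 else 4
    if len(code) > maxlen:
        logger.warning("truncating over-long %s code %r to %d characters", system, code, maxlen)
        code = code[:maxlen]
    pattern = _ICD10_RE if system == ICD10 else _OPCS_RE
    if not pattern.match(code):
        raise CodelistError(f"malformed {system} code: {raw!r}")
    return code


@dataclass(frozen=True)
class CodeEntry:
    """One normalized code mapped to a neurodisability subgroup."""

    code: str
    system: str
    subgroup: str
    category: str
    match_mode: str = "prefix"  # "prefix" or "exact"
    notes: str = ""

    def __post_init__(self):
        if self.system not in SYSTEMS:
            raise CodelistError(f"unknown system {self.system!r} for code {self.code}")
        if self.category not in CATEGORIES:
            raise CodelistError(f"unknown category {self.category!r} for code {self.code}")
        if self.match_mode not in ("prefix", "exact"):
            raise CodelistError(f"unknown match_mode {self.match_mode!r} for code {self.code}")
        if not (3 <= len(self.code) <= 5) or not self.code.isalnum():
            raise CodelistError(f"invalid normalized code {self.code!r}")

    def matches(self, observed: str, system: str) -> bool:
        if system != self.system:
            return False
        if self.match_mode == "exact":
            return observed == self.code
        return observed.startswith(self.code)


@dataclass
class CodeList:
    """A validated collection of :class:`CodeEntry` with fast matching."""

    entries: list[CodeEntry]
    version: str = "unversioned"
    source: str = "in-memory"
    _prefix_maps: dict = field(default_factory=dict, repr=False, compare=False)
    _exact_maps: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        self._build_index()

    def _build_index(self):
        # per system: prefix entries keyed by code length, exact entries by code
        self._prefix_maps = {s: {} for s in SYSTEMS}
        self._exact_maps = {s: {} for s in SYSTEMS}
        for e in self.entries:
            target = (
                self._exact_maps[e.system]
                if e.match_mode == "exact"
                else self._prefix_maps[e.system].setdefault(len(e.code), {})
            )
            target.setdefault(e.code, set()).add(e.subgroup)

    @property
    def subgroups(self) -> set[str]:
        return {e.subgroup for e in self.entries}

    def category_of(self, subgroup: str) -> str:
        for e in self.entries:
            if e.subgroup == subgroup:
                return e.category
        raise KeyError(subgroup)

    def entries_for(self, subgroup: str) -> list[CodeEntry]:
        return [e for e in self.entries if e.subgroup == subgroup]

    def match(self, observed: str, system: str) -> set[str]:
        """Subgroups matched by an already-normalized observed code."""
        out: set[str] = set()
        out |= self._exact_maps[system].get(observed, set())
        for length, table in self._prefix_maps[system].items():
            if length <= len(observed):
                out |= table.get(observed[:length], set())
        return out

    def match_series(self, codes: pd.Series, system: str) -> pd.Series:
        """Vectorised matching: a Series of normalized codes -> Series of subgroup sets.

        Returns a Series aligned with ``codes`` whose values are (possibly
        empty) frozensets of subgroup labels.
        """
        s = codes.astype("string")
        acc = pd.Series([frozenset()] * len(s), index=s.index, dtype=object)

        def _merge(acc, mapped):
            mask = mapped.notna()
            if mask.any():
                acc = acc.copy()
                acc[mask] = [a | b for a, b in zip(acc[mask], mapped[mask])]
            return acc

        exact = {k: frozenset(v) for k, v in self._exact_maps[system].items()}
        if exact:
            acc = _merge(acc, s.map(exact))
        for length, table in self._prefix_maps[system].items():
            mapped = s.str[:length].map({k: frozenset(v) for k, v in table.items()})
            acc = _merge(acc, mapped)
        return acc


def match_code(observed: str, system: str, codelist: CodeList) -> set[str]:
    """Union of subgroups over all entries matching ``observed``.

    An empty set is a valid no-match outcome.
    """
    return codelist.match(observed, system)


def _collapse_prefix_redundancy(entries: list[CodeEntry]) -> tuple[list[CodeEntry], int]:
    """Drop entries shadowed, within the same (system, subgroup), by a
    shorter prefix-mode entry; also drop exact duplicate rows."""
    seen = set()
    unique: list[CodeEntry] = []
    dup = 0
    for e in entries:
        key = (e.code, e.system, e.subgroup, e.match_mode)
        if key in seen:
            dup += 1
            continue
        seen.add(key)
        unique.append(e)
    prefixes: dict[tuple[str, str], list[str]] = {}
    for e in unique:
        if e.match_mode == "prefix":
            prefixes.setdefault((e.system, e.subgroup), []).append(e.code)
    kept: list[CodeEntry] = []
    collapsed = dup
    for e in unique:
        shadowing = [
            p
            for p in prefixes.get((e.system, e.subgroup), [])
            if p != e.code and e.code.startswith(p)
        ]
        if shadowing:
            collapsed += 1
            continue
        kept.append(e)
    return kept, collapsed


def load_codelist(path: str | Path, version: str | None = None) -> CodeList:
    """Load and validate a code-list CSV (columns ``code,system,subgroup,
    category,match_mode,notes``).

    Codes are normalized; rows with unknown subgroup/category labels or
    malformed codes are rejected naming the row; redundant descendants of a
    prefix entry (same system and subgroup) are collapsed with a logged count.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str).fillna("")
    missing = [c for c in _CSV_COLUMNS[:5] if c not in df.columns]
    if missing:
        raise CodelistError(f"code-list file {path} is missing columns: {missing}")

    known_subgroup_category: dict[str, str] = {}
    entries: list[CodeEntry] = []
    for i, row in df.iterrows():
        rowno = i + 2  # header is line 1
        try:
            code = normalize_code(row["code"], row["system"])
            entry = CodeEntry(
                code=code,
                system=row["system"],
                subgroup=row["subgroup"].strip(),
                category=row["category"].strip(),
                match_mode=(row["match_mode"].strip() or "prefix"),
                notes=row.get("notes", ""),
            )
        except CodelistError as err:
            raise CodelistError(f"{path}, row {rowno}: {err}") from err
        prev = known_subgroup_category.setdefault(entry.subgroup, entry.category)
        if prev != entry.category:
            raise CodelistError(
                f"{path}, row {rowno}: subgroup {entry.subgroup!r} mapped to two "
                f"categories ({prev!r}, {entry.category!r})"
            )
        entries.append(entry)

    entries, collapsed = _collapse_prefix_redundancy(entries)
    if collapsed:
        logger.info("collapsed %d redundant/duplicate code-list rows from %s", collapsed, path)

    pairs: dict[tuple[str, str], str] = {}
    for e in entries:
        prev = pairs.setdefault((e.code, e.system), e.subgroup)
        if prev != e.subgroup:
            raise CodelistError(
                f"{path}: code {e.code} ({e.system}) mapped to two subgroups "
                f"({prev!r}, {e.subgroup!r})"
            )
    if not entries:
        raise CodelistError(f"{path}: empty code list")
    return CodeList(entries=entries, version=version or path.stem, source=str(path))


def default_codelist() -> CodeList:
    """The illustrative code list shipped with the package."""
    with resources.as_file(
        resources.files("neurophen.data") / "neurodisability_codes.csv"
    ) as p:
        cl = load_codelist(p, version="illustrative-0.1")
    cl.source = "neurophen built-in illustrative list"
    return cl


def codelist_from_rows(rows: Iterable[dict], **kwargs) -> CodeList:
    """Build a CodeList from dict rows (codes are normalized)."""
    entries = [
        CodeEntry(
            code=normalize_code(r["code"], r.get("system", ICD10)),
            system=r.get("system", ICD10),
            subgroup=r["subgroup"],
            category=r["category"],
            match_mode=r.get("match_mode", "prefix"),
        )
        for r in rows
    ]
    return CodeList(entries=entries, **kwargs)
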