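"""External knowledge resources.

Two resources back the nominal algorithms:

* a **public-persons database** (algorithm A5) — known persons with date-ranged
  positions held, so that a noun like "kardiologas" can be tied to the person
  who held the cardiologist post on the document's publication date;
* a **profession taxonomy** (algorithm A4) — profession concepts with name
  variants (possibly multiword lemma sequences) and broader/narrower links.

Both are immutable inputs for a run; lookups are pure functions of
(resource, query).
"""

from __future__ import annotations

import csv
import datetime as _dt
import enum
import json
from dataclasses import dataclass, field
from typing import IO, Iterable

import yaml

from .model import Gender, NamedEntity, NeClass, ValidationError


@dataclass(frozen=True)
class PositionHeld:
    title_lemma: str
    from_date: _dt.date
    to_date: _dt.date

    def __post_init__(self) -> None:
        if not self.title_lemma:
            raise ValidationError("PositionHeld.title_lemma must be non-empty")
        if self.from_date > self.to_date:
            raise ValidationError(
                f"PositionHeld({self.title_lemma}): from_date after to_date"
            )

    def active_on(self, date: _dt.date) -> bool:
        """Inclusive on both ends: fd <= d and td >= d."""
        return self.from_date <= date <= self.to_date


@dataclass(frozen=True)
class KnownPerson:
    person_id: str
    gender: Gender
    name_forms: tuple[str, ...]  # lemma-level name variants
    positions: tuple[PositionHeld, ...]

    def __post_init__(self) -> None:
        if not self.name_forms:
            raise ValidationError(f"KnownPerson {self.person_id}: no name forms")
        if self.gender == Gender.Common:
            raise ValidationError(
                f"KnownPerson {self.person_id}: gender must be determinate"
            )


def _parse_date(value: str, context: str) -> _dt.date:
    try:
        return _dt.date.fromisoformat(value)
    except (TypeError, ValueError):
        raise ValidationError(
            f"{context}: unparseable date {value!r} (ISO-8601 expected)"
        ) from None


class PersonsKB:
    """Database of public persons, keyed by lemma-level name forms."""

    def __init__(self, persons: Iterable[KnownPerson]):
        self.persons = tuple(persons)
        self._by_name: dict[str, list[KnownPerson]] = {}
        for p in self.persons:
            for form in p.name_forms:
                self._by_name.setdefault(form.casefold(), []).append(p)

    @classmethod
    def from_json(cls, source: IO[str] | str) -> "PersonsKB":
        if isinstance(source, str):
            with open(source, encoding="utf-8") as fh:
                data = json.load(fh)
        else:
            data = json.load(source)
        persons = []
        for i, pd in enumerate(data):
            ctx = f"persons[{i}]"
            persons.append(KnownPerson(
                person_id=str(pd["person_id"]),
                gender=Gender(pd["gender"]),
                name_forms=tuple(pd["name_forms"]),
                positions=tuple(
                    PositionHeld(
                        title_lemma=str(h["title_lemma"]),
                        from_date=_parse_date(h["from_date"], ctx),
                        to_date=_parse_date(h["to_date"], ctx),
                    )
                    for h in pd.get("positions", [])
                ),
            ))
        return cls(persons)

    @classmethod
    def from_csv(cls, source: IO[str] | str) -> "PersonsKB":
        """Flat CSV: person_id, gender, name_form, title_lemma, from_date,
        to_date — one row per (name form x position); name forms may repeat."""
        if isinstance(source, str):
            fh = open(source, encoding="utf-8", newline="")
            close = True
        else:
            fh, close = source, False
        try:
            rows = list(csv.DictReader(fh))
        finally:
            if close:
                fh.close()
        by_id: dict[str, dict] = {}
        for i, row in enumerate(rows):
            ctx = f"row[{i}]"
            rec = by_id.setdefault(row["person_id"], {
                "gender": Gender(row["gender"]),
                "name_forms": set(), "positions": set(),
            })
            rec["name_forms"].add(row["name_form"])
            if row.get("title_lemma"):
                rec["positions"].add(PositionHeld(
                    title_lemma=row["title_lemma"],
                    from_date=_parse_date(row["from_date"], ctx),
                    to_date=_parse_date(row["to_date"], ctx),
                ))
        return cls(
            KnownPerson(pid, rec["gender"], tuple(sorted(rec["name_forms"])),
                        tuple(sorted(rec["positions"],
                                     key=lambda h: (h.title_lemma, h.from_date))))
            for pid, rec in sorted(by_id.items())
        )

    def persons_for_ne(self, ne: NamedEntity) -> list[KnownPerson]:
        """Persons whose name forms match the NE head lemma (lemma-level)."""
        return list(self._by_name.get(ne.head_lemma.casefold(), []))

    def lookup_person(
        self, ne: NamedEntity, date: _dt.date
    ) -> list[tuple[KnownPerson, PositionHeld]]:
        """Positions active on ``date`` for persons the Person NE may denote.

        The interval check is inclusive on both ends.
        """
        if ne.ne_class != NeClass.Person:
            raise ValidationError("lookup_person requires a Person named entity")
        hits = []
        for person in self.persons_for_ne(ne):
            for held in person.positions:
                if held.active_on(date):
                    hits.append((person, held))
        return hits

    def titles_active_on(self, date: _dt.date) -> set[str]:
        return {
            h.title_lemma.casefold()
            for p in self.persons
            for h in p.positions
            if h.active_on(date)
        }


class ProfessionRelation(str, enum.Enum):
    Same = "Same"
    BroaderNarrower = "BroaderNarrower"
    Unrelated = "Unrelated"


@dataclass(frozen=True)
class ProfessionName:
    lemmas: tuple[str, ...]  # contiguous lemma sequence; last noun is the head
    profession_id: str


class ProfessionTaxonomy:
    """Profession concepts, their name variants, and broader/narrower links.

    ``broadens`` is held as a set of directed edges over profession ids; only
    *direct* edges relate two professions by default (the hypernym rule applies
    a single predicate), with transitive closure available behind a flag.
    """

    def __init__(
        self,
        names: Iterable[ProfessionName],
        broadens: Iterable[tuple[str, str]] = (),
        transitive: bool = False,
    ):
        self.names = tuple(names)
        self.broadens = frozenset(broadens)
        self.transitive = transitive
        self.professions = {n.profession_id for n in self.names}
        self._by_lemmas: dict[tuple[str, ...], str] = {}
        for n in self.names:
            key = tuple(l.casefold() for l in n.lemmas)
            if not key:
                raise ValidationError("profession name with empty lemma sequence")
            prior = self._by_lemmas.get(key)
            if prior is not None and prior != n.profession_id:
                raise ValidationError(
                    f"name {' '.join(n.lemmas)!r} maps to two professions"
                )
            self._by_lemmas[key] = n.profession_id
        for a, b in self.broadens:
            if a not in self.professions or b not in self.professions:
                raise ValidationError(f"broadens edge ({a}, {b}) names unknown profession")
        self._check_acyclic()
        self._closure = self._transitive_closure() if transitive else None
        self.max_name_len = max((len(k) for k in self._by_lemmas), default=0)

    def _check_acyclic(self) -> None:
        adj: dict[str, list[str]] = {}
        for a, b in self.broadens:
            adj.setdefault(a, []).append(b)
        state: dict[str, int] = {}

        def visit(u: str) -> None:
            state[u] = 1
            for v in adj.get(u, []):
                if state.get(v) == 1:
                    raise ValidationError("broadens relation contains a cycle")
                if state.get(v, 0) == 0:
                    visit(v)
            state[u] = 2

        for node in self.professions:
            if state.get(node, 0) == 0:
                visit(node)

    def _transitive_closure(self) -> frozenset[tuple[str, str]]:
        adj: dict[str, set[str]] = {}
        for a, b in self.broadens:
            adj.setdefault(a, set()).add(b)
        closure = set()
        for start in self.professions:
            stack = list(adj.get(start, ()))
            seen = set()
            while stack:
                v = stack.pop()
                if v in seen:
                    continue
                seen.add(v)
                closure.add((start, v))
                stack.extend(adj.get(v, ()))
        return frozenset(closure)

    @classmethod
    def from_mapping(cls, data: dict, transitive: bool = False) -> "ProfessionTaxonomy":
        names = []
        for pd in data.get("professions", []):
            pid = str(pd["id"])
            for variant in pd.get("names", []):
                if isinstance(variant, str):
                    variant = variant.split()
                names.append(ProfessionName(tuple(str(v) for v in variant), pid))
        broadens = [tuple(edge) for edge in data.get("broadens", [])]
        return cls(names, broadens, transitive=transitive)

    @classmethod
    def load(cls, source: IO[str] | str, transitive: bool = False) -> "ProfessionTaxonomy":
        """Load from YAML or JSON (YAML is a superset of JSON)."""
        if isinstance(source, str):
            with open(source, encoding="utf-8") as fh:
                data = yaml.safe_load(fh)
        else:
            data = yaml.safe_load(source)
        return cls.from_mapping(data, transitive=transitive)

    def profession_of(self, lemmas: tuple[str, ...]) -> str | None:
        return self._by_lemmas.get(tuple(l.casefold() for l in lemmas))

    def _related(self, p1: str, p2: str) -> bool:
        if self.transitive:
            assert self._closure is not None
            return (p1, p2) in self._closure or (p2, p1) in self._closure
        return (p1, p2) in self.broadens or (p2, p1) in self.broadens

    def profession_relation(
        self, lemmas_a: tuple[str, ...] | str, lemmas_b: tuple[str, ...] | str
    ) -> ProfessionRelation:
        """Relation between two profession names (morphological agreement is
        the caller's job).  A lemma absent from the taxonomy is Unrelated."""
        if isinstance(lemmas_a, str):
            lemmas_a = (lemmas_a,)
        if isinstance(lemmas_b, str):
            lemmas_b = (lemmas_b,)
        pa = self.profession_of(lemmas_a)
        pb = self.profession_of(lemmas_b)
        if pa is None or pb is None:
            return ProfessionRelation.Unrelated
        if pa == pb:
            return ProfessionRelation.Same
        if self._related(pa, pb):
            return ProfessionRelation.BroaderNarrower
        return ProfessionRelation.Unrelated


__all__ = [
    "KnownPerson", "PositionHeld", "PersonsKB",
    "ProfessionName", "ProfessionTaxonomy", "ProfessionRelation",
]
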