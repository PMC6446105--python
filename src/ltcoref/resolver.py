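"""The resolution engine: dispatch + algorithms A1-A5 over one document."""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

from .dispatch import Algorithm, dispatch
from .kb import PersonsKB, ProfessionTaxonomy
from .model import (
    AnnotatedDocument, ConfigurationError, CoreferenceLink,
    canonical_link_order,
)
from .nominals import (
    ACRONYM_DIALECTS, resolve_feature, resolve_profession, resolve_repetition,
)
from .pronouns import resolve_general_pronoun, resolve_relative

log = logging.getLogger(__name__)

ALL_ALGORITHMS = ("A1", "A2", "A3", "A4", "A5")


@dataclass
class ResolverConfig:
    """Tunable knobs of the engine.

    algorithms
        which of A1..A5 run; resolved link sets are additive (unioned).
    acronym_dialect
        "default" enables partial person forms and organisation acronyms in
        A3; "off" restricts A3 to exact lemma repetition.
    taxonomy_transitive
        whether A4 relates professions through transitive broader/narrower
        chains; off by default (only direct links qualify).
    nominal_orientation
        span orientation for A4 links: "fol" (referent = earlier noun) or
        "anaphor" (referent = later noun).
    """

    algorithms: tuple[str, ...] = ALL_ALGORITHMS
    acronym_dialect: str = "default"
    taxonomy_transitive: bool = False
    nominal_orientation: str = "fol"

    def __post_init__(self) -> None:
        bad = set(self.algorithms) - set(ALL_ALGORITHMS)
        if bad:
            raise ConfigurationError(f"unknown algorithms: {sorted(bad)}")
        if not self.algorithms:
            raise ConfigurationError("algorithm subset must be non-empty")
        if self.acronym_dialect not in ACRONYM_DIALECTS:
            raise ConfigurationError(
                f"unknown acronym dialect {self.acronym_dialect!r}")


class CoreferenceResolver:
    """Rule-based resolver over preannotated documents.

    Parameters
    ----------
    persons_kb : PersonsKB, required when A5 is enabled
    taxonomy : ProfessionTaxonomy, required when A4 is enabled
    config : ResolverConfig
    """

    def __init__(
        self,
        persons_kb: PersonsKB | None = None,
        taxonomy: ProfessionTaxonomy | None = None,
        config: ResolverConfig | None = None,
    ):
        self.config = config or ResolverConfig()
        self.persons_kb = persons_kb
        self.taxonomy = taxonomy
        algs = self.config.algorithms
        if "A4" in algs and taxonomy is None:
            raise ConfigurationError("A4 enabled but no profession taxonomy given")
        if "A5" in algs and persons_kb is None:
            raise ConfigurationError("A5 enabled but no persons KB given")
        if taxonomy is not None and self.config.taxonomy_transitive != taxonomy.transitive:
            self.taxonomy = ProfessionTaxonomy(
                taxonomy.names, taxonomy.broadens,
                transitive=self.config.taxonomy_transitive,
            )

    def resolve(self, doc: AnnotatedDocument) -> list[CoreferenceLink]:
        """All links the enabled algorithms produce, in canonical order."""
        algs = set(self.config.algorithms)
        if "A5" in algs and doc.publication_date is None:
            raise ConfigurationError(
                f"document {doc.doc_id!r}: A5 enabled but no publication date"
            )
        decisions = dispatch(doc, taxonomy=self.taxonomy,
                             persons_kb=self.persons_kb)
        by_algorithm = {a: [d.lexeme_ref for d in decisions
                            if d.algorithm == Algorithm(a)]
                        for a in ALL_ALGORITHMS}
        all_lex = doc.lexemes()
        links: list[CoreferenceLink] = []

        if "A1" in algs:
            for ref in by_algorithm["A1"]:
                lx = all_lex[ref]
                link = resolve_relative(doc, doc.sentence_of_lexeme(ref), lx)
                if link is not None:
                    links.append(link)
        if "A2" in algs:
            for ref in by_algorithm["A2"]:
                lx = all_lex[ref]
                link = resolve_general_pronoun(doc, doc.sentence_of_lexeme(ref), lx)
                if link is not None:
                    links.append(link)
        if "A3" in algs:
            links.extend(resolve_repetition(doc, self.config.acronym_dialect))
        if "A4" in algs:
            assert self.taxonomy is not None
            links.extend(resolve_profession(
                doc, self.taxonomy, orientation=self.config.nominal_orientation))
        if "A5" in algs:
            assert self.persons_kb is not None
            links.extend(resolve_feature(doc, self.persons_kb))

        counts = Counter(l.rule_id for l in links)
        if counts:
            log.info("%s: fired %s", doc.doc_id,
                     ", ".join(f"{r}x{n}" for r, n in sorted(
                         counts.items(), key=lambda kv: int(kv[0][1:]))))
        return canonical_link_order(links)
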