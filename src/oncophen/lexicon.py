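"""Bundled concept lexicon and attribute value-set configuration.

The lexicon is a small, editable vocabulary of NCI-Thesaurus-style concept
codes with the per-concept metadata the pipeline needs: semantic class,
trigger/member categories for episode segmentation, the phenotype attribute
a concept supports, its assay-method qualifier (IHC/FISH), whether a
manifestation derived from it is Clinical or Molecular, and an associated
gene symbol for genetic tests. Attribute value sets and TNM patterns for
validation live alongside.
"""

from __future__ import annotations

import re
from functools import lru_cache
from importlib import resources
from typing import Any, Iterable, Optional

import yaml

__all__ = ["LexiconError", "Concept", "Lexicon", "default_lexicon"]


class LexiconError(ValueError):
    """Raised for malformed lexicon files or unknown concept references."""


class Concept:
    """One lexicon entry."""

    __slots__ = ("code", "label", "semantic_class", "categories",
                 "attribute", "method", "manifestation_kind", "gene")

    def __init__(self, entry: dict[str, Any]) -> None:
        try:
            self.code: str = entry["code"]
            self.label: str = entry["label"]
            self.semantic_class: str = entry["semantic_class"]
        except KeyError as exc:  # pragma: no cover - config authoring error
            raise LexiconError(f"lexicon entry missing field {exc}") from exc
        self.categories: tuple[str, ...] = tuple(entry.get("categories", ()))
        self.attribute: Optional[str] = entry.get("attribute")
        self.method: Optional[str] = entry.get("method")
        self.manifestation_kind: Optional[str] = entry.get("manifestation_kind")
        self.gene: Optional[str] = entry.get("gene")


class Lexicon:
    def __init__(self, data: dict[str, Any]) -> None:
        self._concepts: dict[str, Concept] = {}
        for entry in data.get("concepts", []):
            c = Concept(entry)
            if c.code in self._concepts:
                raise LexiconError(f"duplicate concept code {c.code!r}")
            self._concepts[c.code] = c
        self._by_category: dict[str, list[str]] = {}
        for c in self._concepts.values():
            for cat in c.categories:
                self._by_category.setdefault(cat, []).append(c.code)
        for codes in self._by_category.values():
            codes.sort()
        self.value_sets: dict[str, list[str]] = dict(data.get("value_sets", {}))
        self.patterns: dict[str, str] = dict(data.get("patterns", {}))

    @classmethod
    def from_path(cls, path) -> "Lexicon":
        with open(path, encoding="utf-8") as fh:
            return cls(yaml.safe_load(fh) or {})

    # -- concept lookups --------------------------------------------------

    def __contains__(self, code: str) -> bool:
        return code in self._concepts

    def get(self, code: str) -> Optional[Concept]:
        return self._concepts.get(code)

    def __getitem__(self, code: str) -> Concept:
        try:
            return self._concepts[code]
        except KeyError:
            raise LexiconError(f"unknown concept code {code!r}") from None

    def codes(self) -> list[str]:
        return sorted(self._concepts)

    def category(self, name: str) -> list[str]:
        """Concept codes in a category (empty list if the category is unused)."""
        return list(self._by_category.get(name, ()))

    def expand(self, refs: Iterable[str]) -> set[str]:
        """Expand a mixed list of codes and ``category:<name>`` references.

        Unknown codes or empty categories raise :class:`LexiconError`, so
        configuration errors surface at load time rather than as silently
        empty trigger sets.
        """
        out: set[str] = set()
        for ref in refs:
            if ref.startswith("category:"):
                name = ref.split(":", 1)[1]
                codes = self.category(name)
                if not codes:
                    raise LexiconError(f"category {name!r} matches no concept")
                out.update(codes)
            else:
                if ref not in self._concepts:
                    raise LexiconError(f"unknown concept code {ref!r}")
                out.add(ref)
        return out

    # -- attribute validation ---------------------------------------------

    def value_allowed(self, attribute: str, value: Any) -> bool:
        allowed = self.value_sets.get(attribute)
        return allowed is None or value in allowed

    def pattern_match(self, attribute: str, value: Any) -> bool:
        pattern = self.patterns.get(attribute)
        if pattern is None:
            return True
        return isinstance(value, str) and re.fullmatch(pattern, value) is not None


@lru_cache(maxsize=1)
def default_lexicon() -> Lexicon:
    """The bundled breast-cancer lexicon."""
    ref = resources.files("oncophen.data").joinpath("lexicon.yaml")
    with ref.open(encoding="utf-8") as fh:
        return Lexicon(yaml.safe_load(fh))
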