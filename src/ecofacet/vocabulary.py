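"""Controlled-vocabulary management.

A :class:`Vocabulary` is a flat table of :class:`Term` objects organised by
slash-separated *facet paths* (e.g. ``time/geological/epoch``).  Hierarchy is
expressed through ``parent_id`` links; term lifecycle goes through the states
``core`` (curated backbone), ``candidate`` (user-proposed, awaiting curation)
and ``deprecated`` (merged into another term).

The packaged default vocabulary lives in ``data/vocabulary`` as UTF-8
tab-separated term tables (one header line; columns ``id``, ``label``,
``facet_path``, ``parent_id``, ``definition``, ``uri``, ``status``,
``synonyms`` — pipe-separated — plus optional extra columns such as numeric
boundaries, kept verbatim in :attr:`Term.extra`).  ``paths.tsv`` registers the
valid facet paths together with their content policy (``open`` fields accept
new candidate terms, ``closed`` fields are restricted to the packaged list).
"""

from __future__ import annotations

import csv
import io
import re
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator

from .errors import (
    ClosedFieldError,
    CurationError,
    DuplicateLabelError,
    UnknownPathError,
    UnknownTermError,
    VocabularyLoadError,
)

__all__ = [
    "Term",
    "Vocabulary",
    "load_vocabulary",
    "make_term_id",
    "normalize_label",
]

_CORE_COLUMNS = ("id", "label", "facet_path", "parent_id", "definition",
                 "uri", "status", "synonyms")
_STATUSES = frozenset({"core", "candidate", "deprecated"})


def normalize_label(label: str) -> str:
    """Whitespace-normalized, case-folded form used for label matching."""
    return " ".join(label.split()).casefold()


def make_term_id(facet_path: str, label: str) -> str:
    slug = re.sub(r"[^a-z0-9]+", "-", label.casefold()).strip("-")
    return facet_path.replace("/", "-") + "-" + slug


@dataclass
class Term:
    """One controlled-vocabulary concept."""

    id: str
    label: str
    facet_path: str
    parent_id: str | None = None
    definition: str = ""
    uri: str | None = None
    status: str = "core"
    synonyms: tuple[str, ...] = ()
    merged_into: str | None = None
    #: extra table columns (e.g. ``start_ma``/``end_ma`` on geological units,
    #: ``lower_m2``/``upper_m2`` on spatial scale classes), kept as strings.
    extra: dict = field(default_factory=dict)
    #: stable position from the source table; drives canonical ordering.
    order: int = 10**9

    @property
    def deprecated(self) -> bool:
        return self.status == "deprecated"

    def extra_float(self, key: str) -> float | None:
        raw = self.extra.get(key, "")
        return float(raw) if raw not in ("", None) else None


class Vocabulary:
    """Term store with hierarchy navigation, suggestion and curation."""

    def __init__(self, terms: Iterable[Term] = (), version: str = "0",
                 paths: dict[str, str] | None = None,
                 provenance: dict[str, str] | None = None):
        self.version = version
        self.provenance = dict(provenance or {})
        self._paths: dict[str, str] = dict(paths or {})
        self._terms: dict[str, Term] = {}
        self._by_path: dict[str, list[Term]] | None = None
        self._label_idx: dict[tuple[str, str], list[str]] | None = None
        for t in terms:
            self._add(t)
        self._check_integrity()

    def _invalidate(self) -> None:
        self._by_path = None
        self._label_idx = None

    # ------------------------------------------------------------ plumbing
    @property
    def terms(self) -> dict[str, Term]:
        return self._terms

    @property
    def paths(self) -> dict[str, str]:
        """Registered facet paths mapped to their policy (open/closed)."""
        return dict(self._paths)

    def __len__(self) -> int:
        return len(self._terms)

    def __contains__(self, term_id: str) -> bool:
        return term_id in self._terms

    def __iter__(self) -> Iterator[Term]:
        return iter(sorted(self._terms.values(), key=_canonical_key))

    def _add(self, t: Term) -> None:
        if t.id in self._terms:
            raise VocabularyLoadError(f"duplicate term id {t.id!r}", t.id)
        if t.status not in _STATUSES:
            raise VocabularyLoadError(
                f"term {t.id!r} has unknown status {t.status!r}", t.id)
        self._terms[t.id] = t
        self._paths.setdefault(t.facet_path, "closed")
        self._invalidate()

    def _check_integrity(self) -> None:
        labels: dict[tuple[str, str], str] = {}
        for t in self._terms.values():
            if t.parent_id:
                parent = self._terms.get(t.parent_id)
                if parent is None:
                    raise VocabularyLoadError(
                        f"term {t.id!r} has dangling parent {t.parent_id!r}", t.id)
                if parent.facet_path.split("/")[0] != t.facet_path.split("/")[0]:
                    raise VocabularyLoadError(
                        f"term {t.id!r} has parent {parent.id!r} outside its "
                        f"facet subtree", t.id)
            if t.deprecated != (t.merged_into is not None):
                raise VocabularyLoadError(
                    f"term {t.id!r}: status {t.status!r} inconsistent with "
                    f"merged_into={t.merged_into!r}", t.id)
            if t.merged_into is not None and t.merged_into not in self._terms:
                raise VocabularyLoadError(
                    f"term {t.id!r} merged into unknown term {t.merged_into!r}",
                    t.id)
            if (t.status == "core" and self._paths.get(t.facet_path) == "closed"
                    and not t.definition.strip()):
                raise VocabularyLoadError(
                    f"core term {t.id!r} of closed field {t.facet_path!r} "
                    f"lacks a definition", t.id)
            if not t.deprecated:
                key = (t.facet_path, normalize_label(t.label))
                if key in labels:
                    raise VocabularyLoadError(
                        f"label {t.label!r} duplicated at {t.facet_path!r} "
                        f"(terms {labels[key]!r} and {t.id!r})", t.id)
                labels[key] = t.id
        # cycle check over parent links
        state: dict[str, int] = {}
        for t in self._terms.values():
            tid, seen = t.id, []
            while tid is not None and state.get(tid) != 2:
                if state.get(tid) == 1:
                    raise VocabularyLoadError(
                        f"cycle in parent links at term {tid!r}", tid)
                state[tid] = 1
                seen.append(tid)
                tid = self._terms[tid].parent_id
            for s in seen:
                state[s] = 2

    def _children_index(self) -> dict[str, list[str]]:
        idx: dict[str, list[str]] = {}
        for t in sorted(self._terms.values(), key=_canonical_key):
            if t.parent_id:
                idx.setdefault(t.parent_id, []).append(t.id)
        return idx

    # ------------------------------------------------------------- lookups
    def get(self, term_id: str) -> Term:
        try:
            return self._terms[term_id]
        except KeyError:
            raise UnknownTermError(term_id) from None

    def resolve(self, term_id: str) -> Term:
        """Return the term, following merge redirects of deprecated terms."""
        t = self.get(term_id)
        hops = 0
        while t.merged_into is not None:
            t = self.get(t.merged_into)
            hops += 1
            if hops > len(self._terms):
                raise VocabularyLoadError("cycle in merge redirects", term_id)
        return t

    def require_path(self, facet_path: str) -> None:
        if facet_path not in self._paths:
            raise UnknownPathError(facet_path, self._paths)

    def is_open(self, facet_path: str) -> bool:
        self.require_path(facet_path)
        return self._paths[facet_path] == "open"

    def terms_at(self, facet_path: str) -> list[Term]:
        """Non-deprecated terms with exactly this facet path, in canonical
        order (position in the packaged hierarchy, then label)."""
        self.require_path(facet_path)
        if self._by_path is None:
            self._by_path = {}
            for t in sorted(self._terms.values(), key=_canonical_key):
                if not t.deprecated:
                    self._by_path.setdefault(t.facet_path, []).append(t)
        return list(self._by_path.get(facet_path, ()))

    def find_label(self, facet_path: str, label: str) -> Term | None:
        """Match ``label`` (or a synonym) at ``facet_path``; merge redirects
        are followed so deprecated labels resolve to their targets."""
        if self._label_idx is None:
            self._label_idx = {}
            for t in sorted(self._terms.values(), key=_canonical_key):
                for name in (t.label, *t.synonyms):
                    key = (t.facet_path, normalize_label(name))
                    ids = self._label_idx.setdefault(key, [])
                    if t.id not in ids:
                        ids.append(t.id)
        hit = None
        for tid in self._label_idx.get((facet_path, normalize_label(label)), ()):
            t = self._terms.get(tid)
            if t is None:
                continue
            t = self.resolve(t.id) if t.deprecated else t
            if hit is None or _STATUS_RANK[t.status] < _STATUS_RANK[hit.status]:
                hit = t
        return hit

    # ----------------------------------------------------------- hierarchy
    def ancestors(self, term_id: str) -> list[Term]:
        """Parent chain, nearest first.  Deprecated terms are redirected to
        their merge target before walking up."""
        t = self.resolve(term_id)
        chain: list[Term] = []
        while t.parent_id is not None:
            t = self.get(t.parent_id)
            chain.append(t)
        return chain

    def descendants(self, term_id: str) -> list[Term]:
        """Transitive closure of child links, excluding the term itself,
        in deterministic canonical order."""
        t = self.resolve(term_id)
        idx = self._children_index()
        out: list[Term] = []
        stack = list(reversed(idx.get(t.id, [])))
        while stack:
            cur = self.get(stack.pop())
            out.append(cur)
            stack.extend(reversed(idx.get(cur.id, [])))
        return out

    # ---------------------------------------------------------- suggestion
    def suggest(self, facet_path: str, prefix: str) -> list[Term]:
        """Case-insensitive prefix match on labels and synonyms; core terms
        rank before candidates, ties break alphabetically."""
        if facet_path not in self._paths:
            return []
        want = normalize_label(prefix)
        hits = []
        for t in self.terms_at(facet_path):
            names = (t.label, *t.synonyms)
            if any(normalize_label(n).startswith(want) for n in names):
                hits.append(t)
        hits.sort(key=lambda t: (_STATUS_RANK[t.status], normalize_label(t.label)))
        return hits

    # ------------------------------------------------------------ curation
    def propose_term(self, label: str, facet_path: str,
                     definition: str = "") -> Term:
        """Add a user-proposed candidate term to an open field."""
        if not label or not label.strip():
            raise ValueError("label must be non-empty")
        if not self.is_open(facet_path):
            raise ClosedFieldError(
                f"field {facet_path!r} is content-restricted; "
                f"new terms are not accepted")
        want = normalize_label(label)
        for t in self._terms.values():
            if (t.facet_path == facet_path and not t.deprecated
                    and normalize_label(t.label) == want):
                raise DuplicateLabelError(label, facet_path, t.id)
        tid = make_term_id(facet_path, label)
        if tid in self._terms:  # label variants slugging to an existing id
            n = 2
            while f"{tid}-{n}" in self._terms:
                n += 1
            tid = f"{tid}-{n}"
        term = Term(id=tid, label=" ".join(label.split()),
                    facet_path=facet_path, definition=definition,
                    status="candidate")
        self._add(term)
        return term

    def curate_term(self, term_id: str, action: str,
                    target_id: str | None = None) -> "Vocabulary":
        """Curator decision on a candidate term: ``accept``, ``merge``
        (into a core target) or ``reject``."""
        t = self.get(term_id)
        if t.status != "candidate":
            raise CurationError(
                f"term {term_id!r} has status {t.status!r}; only candidate "
                f"terms can be curated")
        if action == "accept":
            self._terms[term_id] = replace(t, status="core")
        elif action == "merge":
            if target_id is None:
                raise CurationError("merge requires a target term id")
            target = self.get(target_id)
            if target.status != "core":
                raise CurationError(
                    f"merge target {target_id!r} must be core, "
                    f"not {target.status!r}")
            self._terms[term_id] = replace(t, status="deprecated",
                                           merged_into=target_id)
            if normalize_label(t.label) not in {
                    normalize_label(s) for s in (target.label, *target.synonyms)}:
                self._terms[target_id] = replace(
                    target, synonyms=target.synonyms + (t.label,))
        elif action == "reject":
            del self._terms[term_id]
        else:
            raise CurationError(f"unknown curation action {action!r}")
        self._invalidate()
        self._check_integrity()
        return self

    # ----------------------------------------------------------------- io
    def extend_from(self, source) -> "Vocabulary":
        """Load an additional term table into this vocabulary."""
        for row, order in _read_table(source):
            self._add(_term_from_row(row, order + len(self._terms)))
        self._check_integrity()
        return self


_STATUS_RANK = {"core": 0, "candidate": 1, "deprecated": 2}


def _canonical_key(t: Term):
    return (t.order, normalize_label(t.label), t.id)


def _term_from_row(row: dict, order: int) -> Term:
    missing = [c for c in ("id", "label", "facet_path") if not row.get(c)]
    if missing:
        raise VocabularyLoadError(
            f"term table row missing required column(s) {missing}: {row!r}",
            row.get("id"))
    synonyms = tuple(s for s in (row.get("synonyms") or "").split("|") if s)
    extra = {k: v for k, v in row.items()
             if k not in _CORE_COLUMNS + ("merged_into",) and v not in (None, "")}
    return Term(
        id=row["id"],
        label=row["label"],
        facet_path=row["facet_path"],
        parent_id=row.get("parent_id") or None,
        definition=row.get("definition") or "",
        uri=row.get("uri") or None,
        status=row.get("status") or "core",
        synonyms=synonyms,
        merged_into=row.get("merged_into") or None,
        extra=extra,
        order=order,
    )


def _read_table(source) -> list[tuple[dict, int]]:
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = Path(source).read_text(encoding="utf-8")
    if isinstance(text, bytes):
        text = text.decode("utf-8")
    reader = csv.DictReader(io.StringIO(text), delimiter="\t")
    return [(row, i) for i, row in enumerate(reader)]


def _read_paths(text: str) -> dict[str, str]:
    reader = csv.DictReader(io.StringIO(text), delimiter="\t")
    return {row["path"]: row["policy"] for row in reader}


_TABLE_FILES = ("geological.tsv", "time.tsv", "space.tsv", "sphere.tsv",
                "biome.tsv", "organism.tsv", "process.tsv", "chemical.tsv",
                "method.tsv")


def load_vocabulary(source=None) -> Vocabulary:
    """Load a vocabulary from a term table (path or file-like), or the
    packaged default when called without arguments."""
    if source is not None:
        rows = _read_table(source)
        return Vocabulary((_term_from_row(r, i) for r, i in rows),
                          version="custom")
    root = resources.files("ecofacet").joinpath("data/vocabulary")
    version = root.joinpath("VERSION").read_text(encoding="utf-8").strip()
    paths = _read_paths(root.joinpath("paths.tsv").read_text(encoding="utf-8"))
    provenance = {}
    reader = csv.DictReader(
        io.StringIO(root.joinpath("provenance.tsv").read_text(encoding="utf-8")),
        delimiter="\t")
    for row in reader:
        provenance[row["subtree"]] = row["source"]
    terms: list[Term] = []
    order = 0
    for name in _TABLE_FILES:
        for row, _ in _read_table(io.StringIO(
                root.joinpath(name).read_text(encoding="utf-8"))):
            terms.append(_term_from_row(row, order))
            order += 1
    return Vocabulary(terms, version=version, paths=paths,
                      provenance=provenance)


# Module-level functional aliases mirroring the operation names.
def terms_at(vocab: Vocabulary, facet_path: str) -> list[Term]:
    return vocab.terms_at(facet_path)


def ancestors(vocab: Vocabulary, term_id: str) -> list[Term]:
    return vocab.ancestors(term_id)


def descendants(vocab: Vocabulary, term_id: str) -> list[Term]:
    return vocab.descendants(term_id)


def suggest(vocab: Vocabulary, facet_path: str, prefix: str) -> list[Term]:
    return vocab.suggest(facet_path, prefix)


def propose_term(vocab: Vocabulary, label: str, facet_path: str,
                 definition: str = "") -> Term:
    return vocab.propose_term(label, facet_path, definition)


def curate_term(vocab: Vocabulary, term_id: str, action: str,
                target_id: str | None = None) -> Vocabulary:
    return vocab.curate_term(term_id, action, target_id)
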