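"""Faceted navigation: inverted index, combined text + facet queries,
incremental refinement and facet value counts.

Query semantics (the standard faceted-navigation contract):

* conjunction (AND) across distinct fields and the text clause;
* disjunction (OR) among the selected values of one field;
* hierarchy-expanded postings — a record annotated with a term also
  matches filters on any of the term's ancestors;
* interactions match as a unit (name, partners, direction, quality on the
  same interaction); a stored ``Mutual`` direction matches either partner
  order, and ``Affects``/``Is Affected By`` are each other's reverse;
* result ordering: descending text score (term frequency), then record id.

Facet counts use multi-select semantics: when counting the values of a
field, that field's own filter is removed, so checkbox counts stay
informative after selection.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field as dfield, replace

from . import model as M
from .errors import EcofacetError, UnknownPathError
from .vocabulary import Vocabulary, normalize_label

__all__ = ["TermFilter", "InteractionFilter", "ScaleRange", "Query",
           "QueryResult", "Index", "build_index", "query", "refine",
           "facet_counts", "extract_values"]

_TOKEN_RE = re.compile(r"[a-z0-9]+")

#: fields indexed for faceting, with the vocabulary subtrees used for
#: hierarchy expansion (open fields expand only when the value is a
#: vocabulary concept)
_FACET_FIELDS: dict[str, tuple[str, ...]] = {
    f.path: f.closed_list_ref
    for f in M.field_registry() if f.kind in ("closed_term", "open_term")
}
_FACET_FIELDS["space/location/name"] = ()

#: vocabulary subtree -> facet fields drawing values from it, so a record
#: annotated at a fine rank is also posted under the coarser-rank fields
_PATH_TO_FIELDS: dict[str, list[str]] = {}
for _f, _paths in _FACET_FIELDS.items():
    for _p in _paths:
        _PATH_TO_FIELDS.setdefault(_p, []).append(_f)

#: ordered-scale fields -> vocabulary path providing the total order
_SCALE_FIELDS = {
    "space/resolution": "space/resolution",
    "space/extent": "space/resolution",
    "time/resolution": "time/unit",
    "time/extent": "time/unit",
    "sphere/organization": "sphere/organization",
}

_DIRECTION_REVERSE = {"affects": "is affected by",
                      "is affected by": "affects",
                      "mutual": "mutual"}


# ------------------------------------------------------------------ query
@dataclass(frozen=True)
class TermFilter:
    """OR over ``values`` (labels or term ids) of one field."""
    field: str
    values: tuple[str, ...]

    def __init__(self, field: str, values):
        object.__setattr__(self, "field", field)
        if isinstance(values, str):
            values = (values,)
        object.__setattr__(self, "values", tuple(values))


@dataclass(frozen=True)
class InteractionFilter:
    """Conjunctive constraints on a single interaction entry."""
    partner_a: str | None = None
    partner_b: str | None = None
    direction: str | None = None
    quality: str | None = None
    name: str | None = None


@dataclass(frozen=True)
class ScaleRange:
    """Inclusive range on an ordered-scale field, by class label."""
    field: str
    minimum: str | None = None
    maximum: str | None = None


@dataclass(frozen=True)
class Query:
    text: str | None = None
    filters: tuple = ()

    def __init__(self, text=None, filters=()):
        object.__setattr__(self, "text", text)
        object.__setattr__(self, "filters", tuple(filters))


@dataclass(frozen=True)
class QueryResult:
    matched_ids: tuple[str, ...]
    counts: dict
    query: Query


# ------------------------------------------------------------------ index
@dataclass
class Index:
    vocab: Vocabulary
    records: dict = dfield(default_factory=dict)      # id -> AnnotationRecord
    postings: dict = dfield(default_factory=dict)     # field -> key -> set(ids)
    direct: dict = dfield(default_factory=dict)       # field -> id -> [labels]
    text_tokens: dict = dfield(default_factory=dict)  # id -> {token: tf}
    scale_pos: dict = dfield(default_factory=dict)    # field -> id -> position
    interactions: dict = dfield(default_factory=dict) # id -> [normal forms]

    @property
    def corpus_size(self) -> int:
        return len(self.records)

    def all_ids(self) -> list[str]:
        return sorted(self.records)


def _tokens(text: str) -> list[str]:
    return _TOKEN_RE.findall(text.lower())


def _value_keys(ref: M.TermRef, subtree_paths, vocab: Vocabulary) -> set[str]:
    """Normalized match keys for one annotated value: its label, plus the
    term id and all ancestor ids/labels when it is a vocabulary concept."""
    keys = {normalize_label(ref.label)}
    term = None
    if ref.id is not None and ref.id in vocab:
        term = vocab.resolve(ref.id)
    else:
        for p in subtree_paths:
            if p in vocab.paths:
                term = vocab.find_label(p, ref.label)
                if term is not None:
                    break
    if term is not None:
        keys.add(term.id)
        keys.add(normalize_label(term.label))
        for anc in vocab.ancestors(term.id):
            keys.add(anc.id)
            keys.add(normalize_label(anc.label))
    return keys


def extract_values(record: M.AnnotationRecord) -> dict[str, list[M.TermRef]]:
    """Facet field -> directly annotated values of one record (no
    hierarchy expansion); free-text location names appear as label-only
    refs under ``space/location/name``."""
    out: dict[str, list[M.TermRef]] = {}
    for path, _h, _k, ref in M._walk_refs(record):
        out.setdefault(path, []).append(ref)
    if record.space is not None:
        for loc in record.space.locations:
            out.setdefault("space/location/name", []).append(M.TermRef(loc.name))
    return out


def _interaction_forms(ia: M.Interaction, vocab: Vocabulary):
    def klabel(ref):
        return None if ref is None else normalize_label(ref.label)

    a, b = klabel(ia.partner_a), klabel(ia.partner_b)
    d = klabel(ia.direction)
    q, n = klabel(ia.quality), klabel(ia.name)
    forms = [(a, b, d, q, n)]
    rev = _DIRECTION_REVERSE.get(d or "")
    if rev is not None:
        forms.append((b, a, rev, q, n))
    return forms


def build_index(records, vocab: Vocabulary) -> Index:
    """Index a corpus of validated records.  Deterministic; duplicate
    record ids are refused."""
    idx = Index(vocab=vocab)
    for rec in records:
        if rec.record_id in idx.records:
            raise EcofacetError(f"duplicate record id {rec.record_id!r}")
        idx.records[rec.record_id] = rec
    scale_orders = {
        f: [normalize_label(t.label) for t in vocab.terms_at(p)]
        for f, p in _SCALE_FIELDS.items()
    }
    for rid in idx.all_ids():
        rec = idx.records[rid]
        text = f"{rec.general.title} {rec.general.abstract}"
        tf: dict[str, int] = {}
        for tok in _tokens(text):
            tf[tok] = tf.get(tok, 0) + 1
        idx.text_tokens[rid] = tf
        for fld, refs in extract_values(rec).items():
            subtrees = _FACET_FIELDS.get(fld, ())
            for ref in refs:
                for key in _value_keys(ref, subtrees, vocab):
                    idx.postings.setdefault(fld, {}).setdefault(
                        key, set()).add(rid)
                idx.direct.setdefault(fld, {}).setdefault(rid, []).append(
                    ref.label)
                # cross-post under coarser-rank fields of the same hierarchy
                term = None
                if ref.id is not None and ref.id in vocab:
                    term = vocab.resolve(ref.id)
                else:
                    for p in subtrees:
                        if p in vocab.paths:
                            term = vocab.find_label(p, ref.label)
                            if term is not None:
                                break
                if term is not None:
                    for anc in vocab.ancestors(term.id):
                        for other in _PATH_TO_FIELDS.get(anc.facet_path, ()):
                            if other == fld:
                                continue
                            table = idx.postings.setdefault(other, {})
                            table.setdefault(anc.id, set()).add(rid)
                            table.setdefault(
                                normalize_label(anc.label), set()).add(rid)
            if fld in scale_orders and refs:
                order = scale_orders[fld]
                lbl = normalize_label(refs[0].label)
                if lbl in order:
                    idx.scale_pos.setdefault(fld, {})[rid] = order.index(lbl)
        if rec.process is not None and rec.process.interactions:
            idx.interactions[rid] = []
            for ia in rec.process.interactions:
                idx.interactions[rid].extend(_interaction_forms(ia, vocab))
    return idx


# ------------------------------------------------------------- evaluation
def _norm_value(index: Index, fld: str, value: str) -> set[str]:
    """Match keys for one requested filter value (id or label; ancestors
    are not added — hierarchy works through the posting expansion)."""
    keys = {normalize_label(value)}
    if value in index.vocab:
        t = index.vocab.resolve(value)
        keys.add(t.id)
        keys.add(normalize_label(t.label))
    else:
        for p in _FACET_FIELDS.get(fld, ()):
            if p in index.vocab.paths:
                t = index.vocab.find_label(p, value)
                if t is not None:
                    keys.add(t.id)
                    keys.add(normalize_label(t.label))
                    break
    return keys


def _apply_term_filter(index: Index, flt: TermFilter) -> set[str]:
    if flt.field not in _FACET_FIELDS:
        raise UnknownPathError(flt.field, _FACET_FIELDS)
    closed = M.registry_field(flt.field).kind == "closed_term"
    matched: set[str] = set()
    table = index.postings.get(flt.field, {})
    for value in flt.values:
        keys = _norm_value(index, flt.field, value)
        if closed and not any(
                index.vocab.find_label(p, value) for p in
                _FACET_FIELDS[flt.field] if p in index.vocab.paths) \
                and value not in index.vocab:
            raise EcofacetError(
                f"unknown value {value!r} for closed field {flt.field!r}")
        for k in keys:
            matched |= table.get(k, set())
    return matched


def _apply_interaction_filter(index: Index, flt: InteractionFilter) -> set[str]:
    want = (None if flt.partner_a is None else normalize_label(flt.partner_a),
            None if flt.partner_b is None else normalize_label(flt.partner_b),
            None if flt.direction is None else normalize_label(flt.direction),
            None if flt.quality is None else normalize_label(flt.quality),
            None if flt.name is None else normalize_label(flt.name))
    out = set()
    for rid, forms in index.interactions.items():
        for form in forms:
            if all(w is None or w == f for w, f in zip(want, form)):
                out.add(rid)
                break
    return out


def _apply_scale_range(index: Index, flt: ScaleRange) -> set[str]:
    if flt.field not in _SCALE_FIELDS:
        raise UnknownPathError(flt.field, _SCALE_FIELDS)
    order = [normalize_label(t.label)
             for t in index.vocab.terms_at(_SCALE_FIELDS[flt.field])]
    lo = order.index(normalize_label(flt.minimum)) if flt.minimum else 0
    hi = (order.index(normalize_label(flt.maximum)) if flt.maximum
          else len(order) - 1)
    positions = index.scale_pos.get(flt.field, {})
    return {rid for rid, pos in positions.items() if lo <= pos <= hi}


def _apply_filter(index: Index, flt) -> set[str]:
    if isinstance(flt, TermFilter):
        return _apply_term_filter(index, flt)
    if isinstance(flt, InteractionFilter):
        return _apply_interaction_filter(index, flt)
    if isinstance(flt, ScaleRange):
        return _apply_scale_range(index, flt)
    raise EcofacetError(f"unknown filter type {type(flt).__name__}")


def _match_set(index: Index, q: Query, skip_field: str | None = None) -> set[str]:
    matched = set(index.records)
    if q.text:
        toks = _tokens(q.text)
        matched = {rid for rid in matched
                   if all(index.text_tokens[rid].get(t) for t in toks)}
    for flt in q.filters:
        if skip_field is not None and getattr(flt, "field", None) == skip_field:
            continue
        matched &= _apply_filter(index, flt)
    return matched


def _score(index: Index, rid: str, text: str | None) -> int:
    if not text:
        return 0
    return sum(index.text_tokens[rid].get(t, 0) for t in _tokens(text))


def query(index: Index, q: Query) -> QueryResult:
    """Evaluate a query; the result carries per-field value counts over
    the matched set for driving the next refinement step."""
    matched = _match_set(index, q)
    ordered = sorted(matched, key=lambda r: (-_score(index, r, q.text), r))
    return QueryResult(matched_ids=tuple(ordered),
                       counts=facet_counts(index, q),
                       query=q)


def refine(index: Index, previous: QueryResult, extra_filter) -> QueryResult:
    """Add one filter to a previous result; equivalent to re-running the
    combined query (refinement never grows the matched set)."""
    filters = previous.query.filters
    if extra_filter not in filters:
        filters = filters + (extra_filter,)
    return query(index, replace(previous.query, filters=filters))


def facet_counts(index: Index, q: Query | QueryResult) -> dict:
    """Per-field counts of directly annotated values over the matched set,
    with each field's own filter excluded while counting that field
    (multi-select semantics)."""
    if isinstance(q, QueryResult):
        q = q.query
    counts: dict[str, dict[str, int]] = {}
    cache: dict[str | None, set[str]] = {}

    def matched_excluding(fld):
        skip = fld if any(getattr(f, "field", None) == fld
                          for f in q.filters) else None
        if skip not in cache:
            cache[skip] = _match_set(index, q, skip_field=skip)
        return cache[skip]

    for fld, per_record in sorted(index.direct.items()):
        matched = matched_excluding(fld)
        table: dict[str, int] = {}
        for rid, labels in per_record.items():
            if rid not in matched:
                continue
            for lbl in set(labels):
                table[lbl] = table.get(lbl, 0) + 1
        if table:
            counts[fld] = dict(sorted(table.items()))
    return counts


# -------------------------------------------------------------- persistence
def save_index(index: Index, path) -> None:
    """Persist postings and text index as JSON (documented on-disk layout);
    records themselves are stored alongside as annotation XML by the CLI."""
    payload = {
        "corpus_size": index.corpus_size,
        "record_ids": index.all_ids(),
        "postings": {f: {k: sorted(v) for k, v in sorted(t.items())}
                     for f, t in sorted(index.postings.items())},
        "text_tokens": {rid: index.text_tokens[rid]
                        for rid in index.all_ids()},
        "scale_pos": {f: dict(sorted(t.items()))
                      for f, t in sorted(index.scale_pos.items())},
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
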