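"""Faceted-search tests, including equivalence with an independent
linear-scan oracle that re-implements the documented query semantics
record-by-record (no inverted index, explicit attribute walking)."""

import random
import re

import pytest

from ecofacet import facetsearch as FS
from ecofacet import fixtures as FX
from ecofacet import model as M
from ecofacet.errors import EcofacetError, UnknownPathError
from ecofacet.vocabulary import normalize_label as norm

TOKEN = re.compile(r"[a-z0-9]+")


# ------------------------------------------------------------------ oracle
def direct_values(rec):
    """Explicit, walker-free extraction: field -> list of TermRef/labels."""
    out = {}

    def add(field, value):
        if value is not None:
            out.setdefault(field, []).append(value)

    if rec.time:
        add("time/timezone", rec.time.timezone)
        if rec.time.geological:
            g = rec.time.geological
            add("time/geological/eon", g.eon)
            add("time/geological/era", g.era)
            add("time/geological/period", g.period)
            add("time/geological/epoch", g.epoch)
            add("time/geological/age", g.age)
        add("time/resolution", rec.time.resolution)
        add("time/extent", rec.time.extent)
    if rec.space:
        for loc in rec.space.locations:
            add("space/location/name", M.TermRef(loc.name))
            add("space/location/type", loc.location_type)
            add("space/location/country", loc.country)
            add("space/location/continent", loc.continent)
        add("space/resolution", rec.space.resolution)
        add("space/extent", rec.space.extent)
    if rec.sphere:
        for s in rec.sphere.spheres:
            add("sphere/layer", s)
        add("sphere/organization", rec.sphere.organization)
    if rec.biome:
        b = rec.biome
        for attr in ("latitudinal", "altitudinal", "moisture",
                     "continentality", "physiognomy", "special", "condition"):
            add(f"biome/{attr}", getattr(b, attr))
        for u in b.usage:
            add("biome/usage", u)
    if rec.organism:
        for n in rec.organism.names:
            add("organism/code", n.code)
    if rec.process:
        for p in rec.process.processes:
            add("process/name", p.name)
            for iv in p.involved:
                add("process/involved", iv)
            add("process/characterization", p.characterization)
        for ia in rec.process.interactions:
            add("process/interaction/name", ia.name)
            add("process/interaction/partner_a", ia.partner_a)
            add("process/interaction/partner_b", ia.partner_b)
            add("process/interaction/direction", ia.direction)
            add("process/interaction/quality", ia.quality)
    if rec.chemical:
        for e in rec.chemical.elements:
            add("chemical/element", e)
        for c in rec.chemical.compounds:
            add("chemical/compound", c)
        for f in rec.chemical.functions:
            add("chemical/function", f)
    if rec.method:
        add("method/approach", rec.method.approach)
        add("method/context", rec.method.context)
        for v in rec.method.variables:
            add("method/variable", v)
    return out


def resolve(vocab, field, ref):
    if ref.id is not None and ref.id in vocab:
        return vocab.resolve(ref.id)
    fld = M.registry_field(field)
    for p in fld.closed_list_ref:
        if p in vocab.paths:
            t = vocab.find_label(p, ref.label)
            if t is not None:
                return t
    return None


def oracle_matches_term(vocab, rec, flt):
    fld = M.registry_field(flt.field)
    values = direct_values(rec)
    for want in flt.values:
        t_want = None
        for p in fld.closed_list_ref:
            if p in vocab.paths:
                t_want = vocab.find_label(p, want)
                if t_want is not None:
                    break
        if t_want is None and want in vocab:
            t_want = vocab.resolve(want)
        for g, refs in values.items():
            for ref in refs:
                t_v = resolve(vocab, g, ref)
                if g == flt.field:
                    if norm(ref.label) == norm(want):
                        return True
                    if t_want is not None and t_v is not None:
                        if t_v.id == t_want.id:
                            return True
                        if t_want.id in {a.id for a in vocab.ancestors(t_v.id)}:
                            return True
                elif t_want is not None and t_v is not None:
                    if (t_want.facet_path in fld.closed_list_ref
                            and t_want.id in
                            {a.id for a in vocab.ancestors(t_v.id)}):
                        return True
    return False


REVERSE = {"affects": "is affected by", "is affected by": "affects",
           "mutual": "mutual"}


def oracle_matches_interaction(rec, flt):
    if not rec.process:
        return False
    want = (flt.partner_a, flt.partner_b, flt.direction, flt.quality, flt.name)
    want = tuple(None if w is None else norm(w) for w in want)
    for ia in rec.process.interactions:
        lbl = lambda r: None if r is None else norm(r.label)
        forms = [(lbl(ia.partner_a), lbl(ia.partner_b), lbl(ia.direction),
                  lbl(ia.quality), lbl(ia.name))]
        d = lbl(ia.direction)
        if d in REVERSE:
            forms.append((lbl(ia.partner_b), lbl(ia.partner_a), REVERSE[d],
                          lbl(ia.quality), lbl(ia.name)))
        for form in forms:
            if all(w is None or w == f for w, f in zip(want, form)):
                return True
    return False


def oracle_matches_scale(vocab, rec, flt):
    order = [norm(t.label)
             for t in vocab.terms_at(FS._SCALE_FIELDS[flt.field])]
    refs = direct_values(rec).get(flt.field, [])
    if not refs:
        return False
    lbl = norm(refs[0].label)
    if lbl not in order:
        return False
    lo = order.index(norm(flt.minimum)) if flt.minimum else 0
    hi = order.index(norm(flt.maximum)) if flt.maximum else len(order) - 1
    return lo <= order.index(lbl) <= hi


def oracle_match_set(vocab, records, q, skip_field=None):
    matched = set()
    for rec in records:
        ok = True
        if q.text:
            toks = TOKEN.findall(q.text.lower())
            text = TOKEN.findall(
                f"{rec.general.title} {rec.general.abstract}".lower())
            ok = all(t in text for t in toks)
        for flt in q.filters:
            if not ok:
                break
            if skip_field is not None and getattr(flt, "field", None) == skip_field:
                continue
            if isinstance(flt, FS.TermFilter):
                ok = oracle_matches_term(vocab, rec, flt)
            elif isinstance(flt, FS.InteractionFilter):
                ok = oracle_matches_interaction(rec, flt)
            else:
                ok = oracle_matches_scale(vocab, rec, flt)
        if ok:
            matched.add(rec.record_id)
    return matched


def random_queries(vocab, rng, n):
    def label(path):
        refs = M.registry_field(path).closed_list_ref if path in {
            f.path for f in M.field_registry()} else (path,)
        terms = [t for p in refs for t in vocab.terms_at(p)]
        return terms[rng.randrange(len(terms))].label

    pools = ["biome/latitudinal", "method/approach", "chemical/element",
             "time/geological/period", "time/geological/epoch",
             "sphere/organization", "process/name", "organism/code",
             "space/location/country", "biome/usage", "chemical/function",
             "process/interaction/quality", "space/location/type"]
    out = []
    for _ in range(n):
        text = rng.choice([None, None, "soil", "forest", "carbon",
                           "nutrient dynamics"])
        filters = []
        for _ in range(rng.randrange(3)):
            path = pools[rng.randrange(len(pools))]
            values = tuple(label(path) for _ in range(rng.randint(1, 2)))
            filters.append(FS.TermFilter(path, values))
        if rng.random() < 0.25:
            order = [t.label for t in vocab.terms_at("space/resolution")]
            i = rng.randrange(len(order))
            j = rng.randrange(i, len(order))
            filters.append(FS.ScaleRange("space/resolution", order[i],
                                         order[j]))
        if rng.random() < 0.25:
            filters.append(FS.InteractionFilter(
                partner_a=rng.choice([None, "Fungi", "Plantae", "Animalia"]),
                direction=rng.choice([None, "Affects", "Mutual",
                                      "Is Affected By"]),
                quality=rng.choice([None, label("process/interaction/quality")])))
        out.append(FS.Query(text=text, filters=tuple(filters)))
    return out


@pytest.fixture(scope="module")
def index_500(vocab, corpus_500):
    return FS.build_index(corpus_500, vocab)


# ------------------------------------------------------------ basic cases
class TestBuildIndex:
    def test_empty_corpus(self, vocab):
        idx = FS.build_index([], vocab)
        res = FS.query(idx, FS.Query(text="anything"))
        assert res.matched_ids == ()
        assert res.counts == {}

    def test_duplicate_record_ids_refused(self, vocab, carbon_corpus):
        with pytest.raises(EcofacetError, match="duplicate"):
            FS.build_index(carbon_corpus + carbon_corpus[:1], vocab)

    def test_rebuild_identical_postings(self, vocab, carbon_corpus):
        a = FS.build_index(carbon_corpus, vocab)
        b = FS.build_index(carbon_corpus, vocab)
        assert a.postings == b.postings
        assert a.text_tokens == b.text_tokens

    def test_epoch_retrievable_by_ancestor_period(self, vocab, carbon_corpus):
        # expected chain read from the packaged table via ancestors()
        idx = FS.build_index(carbon_corpus, vocab)
        hol = vocab.find_label("time/geological/epoch", "Holocene")
        period = [a for a in vocab.ancestors(hol.id)
                  if a.facet_path.endswith("/period")][0]
        res = FS.query(idx, FS.Query(filters=(
            FS.TermFilter("time/geological/period", period.label),)))
        assert res.matched_ids == ("carbon-tree-rings",)


class TestQueryScenarios:
    def test_carbon_text_matches_all_four(self, vocab, carbon_corpus):
        idx = FS.build_index(carbon_corpus, vocab)
        res = FS.query(idx, FS.Query(text="carbon"))
        assert set(res.matched_ids) == {r.record_id for r in carbon_corpus}

    def test_carbon_filter_isolates_treatment_study(self, vocab,
                                                    carbon_corpus):
        idx = FS.build_index(carbon_corpus, vocab)
        res = FS.query(idx, FS.Query(
            text="carbon",
            filters=(FS.TermFilter("method/variable",
                                   "Elevated carbon dioxide concentration"),)))
        assert res.matched_ids == ("carbon-co2-treatment",)

    def test_fungi_parasitism_not_symbiosis(self, vocab, fungi_corpus):
        idx = FS.build_index(fungi_corpus, vocab)
        res = FS.query(idx, FS.Query(filters=(FS.InteractionFilter(
            partner_a="Fungi", partner_b="Plantae", direction="Affects",
            quality="Antagonism"),)))
        assert res.matched_ids == ("fungi-parasitism",)

    def test_mutual_matches_either_partner_order(self, vocab, fungi_corpus):
        idx = FS.build_index(fungi_corpus, vocab)
        for a, b in (("Fungi", "Plantae"), ("Plantae", "Fungi")):
            res = FS.query(idx, FS.Query(filters=(FS.InteractionFilter(
                partner_a=a, partner_b=b, direction="Mutual"),)))
            assert res.matched_ids == ("fungi-symbiosis",)

    def test_empty_query_returns_all(self, vocab, carbon_corpus):
        idx = FS.build_index(carbon_corpus, vocab)
        res = FS.query(idx, FS.Query())
        assert len(res.matched_ids) == 4
        assert res.counts  # full facet counts present

    def test_unknown_field(self, index_500):
        with pytest.raises(UnknownPathError):
            FS.query(index_500, FS.Query(filters=(
                FS.TermFilter("nope/nope", "x"),)))

    def test_unknown_closed_value(self, index_500):
        with pytest.raises(EcofacetError):
            FS.query(index_500, FS.Query(filters=(
                FS.TermFilter("method/approach", "Magical"),)))

    def test_text_ordering_by_score_then_id(self, vocab):
        recs = [
            M.AnnotationRecord("b-two", M.GeneralInfo(
                "carbon carbon", "", [M.Party("P")])),
            M.AnnotationRecord("a-one", M.GeneralInfo(
                "carbon", "", [M.Party("P")])),
            M.AnnotationRecord("c-two", M.GeneralInfo(
                "carbon study", "more carbon", [M.Party("P")])),
        ]
        idx = FS.build_index(recs, vocab)
        res = FS.query(idx, FS.Query(text="carbon"))
        assert res.matched_ids == ("b-two", "c-two", "a-one")


class TestRefine:
    def test_equivalence_with_combined_query(self, vocab, index_500):
        base = FS.query(index_500, FS.Query())
        flt = FS.TermFilter("method/approach", "Observational")
        refined = FS.refine(index_500, base, flt)
        direct = FS.query(index_500, FS.Query(filters=(flt,)))
        assert refined.matched_ids == direct.matched_ids
        assert refined.counts == direct.counts

    def test_commutative(self, vocab, index_500):
        f1 = FS.TermFilter("method/approach", "Observational")
        f2 = FS.TermFilter("biome/condition", "Natural")
        base = FS.query(index_500, FS.Query())
        ab = FS.refine(index_500, FS.refine(index_500, base, f1), f2)
        ba = FS.refine(index_500, FS.refine(index_500, base, f2), f1)
        assert ab.matched_ids == ba.matched_ids
        assert ab.counts == ba.counts

    def test_idempotent(self, index_500):
        flt = FS.TermFilter("method/context", "Mesocosm")
        once = FS.query(index_500, FS.Query(filters=(flt,)))
        again = FS.refine(index_500, once, flt)
        assert again == once

    def test_monotone_non_increasing(self, vocab, index_500, corpus_500):
        rng = random.Random(5)
        for q in random_queries(vocab, rng, 30):
            res = FS.query(index_500, FS.Query(text=q.text))
            for flt in q.filters:
                new = FS.refine(index_500, res, flt)
                assert set(new.matched_ids) <= set(res.matched_ids)
                res = new


class TestFacetCounts:
    def test_single_record_counts_one_per_value(self, vocab, fungi_corpus):
        idx = FS.build_index(fungi_corpus[:1], vocab)
        res = FS.query(idx, FS.Query())
        for table in res.counts.values():
            assert set(table.values()) == {1}

    def test_absent_value_omitted(self, vocab, carbon_corpus):
        idx = FS.build_index(carbon_corpus, vocab)
        res = FS.query(idx, FS.Query(text="village"))
        assert "Manipulative" not in res.counts.get("method/approach", {})

    def test_multi_select_own_filter_excluded(self, vocab, carbon_corpus):
        idx = FS.build_index(carbon_corpus, vocab)
        res = FS.query(idx, FS.Query(filters=(
            FS.TermFilter("method/approach", "Manipulative"),)))
        assert res.matched_ids == ("carbon-co2-treatment",)
        # counts for method/approach ignore that field's own filter
        assert res.counts["method/approach"] == {"Manipulative": 1,
                                                 "Observational": 3}

    def test_counts_against_bruteforce(self, vocab, corpus_500, index_500):
        rng = random.Random(99)
        recs_by_id = {r.record_id: r for r in corpus_500}
        for q in random_queries(vocab, rng, 25):
            got = FS.facet_counts(index_500, q)
            for fld in got:
                matched = oracle_match_set(vocab, corpus_500, q,
                                           skip_field=fld if any(
                                               getattr(f, "field", None) == fld
                                               for f in q.filters) else None)
                expect = {}
                for rid in matched:
                    vals = direct_values(recs_by_id[rid]).get(fld, [])
                    for lbl in {v.label for v in vals}:
                        expect[lbl] = expect.get(lbl, 0) + 1
                assert got[fld] == expect, (q, fld)

    def test_single_valued_counts_sum_bounded(self, index_500):
        res = FS.query(index_500, FS.Query())
        for fld in ("method/approach", "biome/condition", "space/resolution"):
            if fld in res.counts:
                assert sum(res.counts[fld].values()) <= len(res.matched_ids)


class TestOracleEquivalence:
    def test_200_random_queries_match_linear_scan(self, vocab, corpus_500,
                                                  index_500):
        rng = random.Random(1234)
        queries = random_queries(vocab, rng, 200)
        for q in queries:
            got = set(FS.query(index_500, q).matched_ids)
            expected = oracle_match_set(vocab, corpus_500, q)
            assert got == expected, q

    def test_hierarchy_soundness(self, vocab, corpus_500, index_500):
        # filtering on t returns exactly records annotated with t or a
        # member of descendants(t)
        for label in ("Quaternary", "Cenozoic", "Phanerozoic"):
            path = {"Quaternary": "time/geological/period",
                    "Cenozoic": "time/geological/era",
                    "Phanerozoic": "time/geological/eon"}[label]
            t = vocab.find_label(path, label)
            allowed = {t.id} | {d.id for d in vocab.descendants(t.id)}
            got = set(FS.query(index_500, FS.Query(filters=(
                FS.TermFilter(path, label),))).matched_ids)
            expected = set()
            for rec in corpus_500:
                for fld, refs in direct_values(rec).items():
                    if not fld.startswith("time/geological/"):
                        continue
                    for ref in refs:
                        if ref.id in allowed:
                            expected.add(rec.record_id)
            assert got == expected

    def test_scale_range_respects_total_order(self, vocab, corpus_500,
                                              index_500):
        res = FS.query(index_500, FS.Query(filters=(
            FS.ScaleRange("space/resolution", "Plot", "Region"),)))
        for rid in res.matched_ids:
            rec = [r for r in corpus_500 if r.record_id == rid][0]
            assert rec.space.resolution.label in ("Plot", "Region")
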