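"""Lexicon pipeline: tokenization, dtm, sparsity filter, fusion, network."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import senslex as sl
from senslex.lexicon import FusionMap


class TestPreprocess:
    @pytest.mark.parametrize(
        "text, expected",
        [
            ("Sweetness, 12 apples!", ["sweetness", "apples"]),
            ("", []),
            ("THE the The", []),  # stopwords, case-folded
            ("pH7 4ever", []),  # digit-bearing tokens dropped entirely
        ],
    )
    def test_removals(self, text, expected):
        assert sl.preprocess(text) == expected

    def test_hyphenated_tuple_kept(self):
        assert sl.preprocess("green-apple note", keep_hyphenated_tuples=True) == [
            "green-apple",
            "note",
        ]

    def test_hyphenated_tuple_split_when_off(self):
        assert sl.preprocess("green-apple", keep_hyphenated_tuples=False) == ["green", "apple"]

    def test_explicit_bigram_merge(self):
        out = sl.preprocess("ripe apple flavor", bigrams={("ripe", "apple")})
        assert out == ["ripe-apple", "flavor"]

    def test_lemmatization_off_by_default(self):
        assert sl.preprocess("sourness") == ["sourness"]
        assert sl.preprocess("sourness", lemmatize=True) == ["sour"]


class TestDtm:
    def test_counts_and_doc_frequency(self):
        corpus = sl.Corpus.from_texts({"a": "sour sour sweet", "b": "sweet"})
        dtm = sl.build_dtm(corpus)
        frame = dtm.to_frame()
        assert frame.loc["a", "sour"] == 2
        assert frame.loc["a", "sweet"] == 1
        assert frame.loc["b", "sour"] == 0
        assert dict(zip(dtm.terms, dtm.doc_frequency)) == {"sour": 1, "sweet": 2}

    def test_single_doc_full_sparsity_zero(self):
        dtm = sl.build_dtm(sl.Corpus.from_texts({"only": "sweet sour bitter"}))
        assert dtm.sparsity == 0.0

    def test_row_sums_match_independent_tally(self):
        corpus = sl.gen_corpus(
            12, {t: 0.6 for t in ["sweet", "sour", "pear", "honey", "musty"]}, seed=5
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # rare all-silent documents excluded
            dtm = sl.build_dtm(corpus)
        rows = {doc_id: i for i, doc_id in enumerate(dtm.doc_ids)}
        for doc_id, text in corpus.documents:
            # oracle: independent token tally, bypassing the dtm path
            expected = len([w for w in text.split() if w])
            if doc_id in rows:
                assert dtm.counts[rows[doc_id]].sum() == expected
            else:
                assert expected == 0

    def test_empty_documents_are_excluded_with_warning(self):
        corpus = sl.Corpus.from_texts({"a": "sweet", "b": "12 34 the"})
        with pytest.warns(UserWarning, match="'b'"):
            dtm = sl.build_dtm(corpus)
        assert dtm.doc_ids == ("a",)

    def test_all_empty_corpus_errors(self):
        with pytest.raises(ValueError), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sl.build_dtm(sl.Corpus.from_texts({"a": "12 34"}))

    def test_duplicate_doc_ids_rejected(self):
        with pytest.raises(ValueError):
            sl.Corpus((("a", "x"), ("a", "y")))


class TestSparsityFilter:
    def _dtm(self, n_docs, present_in):
        counts = np.zeros((n_docs, 1), dtype=np.int64)
        counts[:present_in, 0] = 1
        return sl.DocumentTermMatrix(
            tuple(f"d{i}" for i in range(n_docs)), ("term",), counts
        )

    def test_at_least_ten_percent_rounds_up(self):
        # 17 docs: need ceil(1.7) = 2 documents
        assert sl.filter_sparse_terms(self._dtm(17, 2), 0.10).terms == ("term",)
        assert sl.filter_sparse_terms(self._dtm(17, 1), 0.10).terms == ()

    def test_fraction_one_keeps_ubiquitous_terms_only(self):
        assert sl.filter_sparse_terms(self._dtm(5, 5), 1.0).terms == ("term",)
        assert sl.filter_sparse_terms(self._dtm(5, 4), 1.0).terms == ()

    def test_idempotent(self):
        corpus = sl.gen_corpus(10, {t: 0.3 for t in "abcdefgh"}, seed=2)
        dtm = sl.build_dtm(corpus)
        once = sl.filter_sparse_terms(dtm, 0.3)
        twice = sl.filter_sparse_terms(once, 0.3)
        assert once.terms == twice.terms
        assert np.array_equal(once.counts, twice.counts)

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            sl.filter_sparse_terms(self._dtm(5, 5), 0.0)


class TestCorrelations:
    def test_identical_and_opposite_vectors(self):
        counts = np.array([[1, 1, 0], [0, 0, 1], [1, 1, 0], [0, 0, 1]])
        dtm = sl.DocumentTermMatrix(("d1", "d2", "d3", "d4"), ("a", "b", "c"), counts)
        corr = sl.term_correlations(dtm)
        assert corr.loc["a", "b"] == pytest.approx(1.0)
        assert corr.loc["a", "c"] == pytest.approx(-1.0)

    def test_matches_definitional_two_pass_pearson(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 5, size=(5, 4))
        dtm = sl.DocumentTermMatrix(
            tuple(f"d{i}" for i in range(5)), tuple("wxyz"), counts
        )
        corr = sl.term_correlations(dtm)
        for i in range(4):
            for j in range(4):
                x, y = counts[:, i].astype(float), counts[:, j].astype(float)
                cov = np.sum((x - x.mean()) * (y - y.mean())) / 4
                r = cov / (x.std(ddof=1) * y.std(ddof=1))
                assert corr.iloc[i, j] == pytest.approx(r)

    def test_zero_variance_terms_flagged_not_silent(self):
        counts = np.array([[1, 2], [1, 3], [1, 1]])
        dtm = sl.DocumentTermMatrix(("d1", "d2", "d3"), ("flat", "var"), counts)
        corr = sl.term_correlations(dtm)
        assert corr.attrs["zero_variance_terms"] == ["flat"]
        assert np.isnan(corr.loc["flat", "var"])


class TestFusions:
    def _corr(self, terms, pairs):
        corr = pd.DataFrame(np.eye(len(terms)), index=terms, columns=terms)
        for a, b, v in pairs:
            corr.loc[a, b] = corr.loc[b, a] = v
        return corr

    def test_transitive_component(self):
        corr = self._corr(["a", "b", "c"], [("a", "b", 0.6), ("b", "c", 0.7), ("a", "c", 0.1)])
        fmap = sl.propose_fusions(corr, 0.50)
        assert len(fmap.entries) == 1
        (members,) = [sorted(fmap.members(k)) for k in fmap.entries]
        assert members == ["a", "b", "c"]

    def test_strict_threshold_all_singletons(self):
        corr = self._corr(["a", "b"], [("a", "b", 0.50)])
        fmap = sl.propose_fusions(corr, 0.50)
        assert set(fmap.entries) == {"a", "b"}

    def test_threshold_one_always_singletons(self):
        corr = self._corr(["a", "b"], [("a", "b", 1.0)])
        assert set(sl.propose_fusions(corr, 1.0).entries) == {"a", "b"}

    def test_representative_by_frequency_then_lexicographic(self):
        corr = self._corr(["x", "y"], [("x", "y", 0.9)])
        assert set(sl.propose_fusions(corr, 0.5, {"x": 1, "y": 5}).entries) == {"y"}
        assert set(sl.propose_fusions(corr, 0.5, {"x": 5, "y": 5}).entries) == {"x"}

    def test_planted_pair_lands_in_one_component(self):
        vocab = {t: 0.4 for t in ["sweet", "sour", "pear", "honey"]}
        vocab.update({"acid": 0.5, "tart": 0.5})
        corpus = sl.gen_corpus(25, vocab, planted_pairs=[("acid", "tart")], seed=9)
        dtm = sl.build_dtm(corpus)
        corr = sl.term_correlations(dtm)
        fmap = sl.propose_fusions(corr, 0.50)
        comp = next(set(fmap.members(k)) for k in fmap.entries if "acid" in fmap.members(k))
        assert "tart" in comp


class TestNormalization:
    def test_published_arithmetic_on_supplied_totals(self):
        # three columns with totals 100 + 30 + 35 fuse to a single 165 entry
        counts = np.array([[60, 20, 15], [40, 10, 20]])
        dtm = sl.DocumentTermMatrix(
            ("d1", "d2"), ("sweet", "sweeter", "sweetness"), counts
        )
        fmap = FusionMap({"sweet": {"similar_terms": ["sweet", "sweeter", "sweetness"]}})
        _, lex = sl.apply_normalization(dtm, fmap)
        assert lex.entries == (("sweet", 165),)

    def test_identity_map_leaves_dtm_unchanged(self):
        corpus = sl.gen_corpus(8, {t: 0.5 for t in "abcd"}, seed=3)
        dtm = sl.build_dtm(corpus)
        dtm2, _ = sl.apply_normalization(dtm, FusionMap({}))
        assert dtm2.terms == dtm.terms
        assert np.array_equal(dtm2.counts, dtm.counts)

    def test_all_terms_fused_gives_grand_total(self):
        corpus = sl.gen_corpus(8, {t: 0.5 for t in "abcd"}, seed=3)
        dtm = sl.build_dtm(corpus)
        fmap = FusionMap({"all": {"similar_terms": list(dtm.terms)}})
        dtm2, lex = sl.apply_normalization(dtm, fmap)
        assert lex.entries == (("all", int(dtm.counts.sum())),)
        assert dtm2.counts.sum() == dtm.counts.sum()

    def test_absent_member_skipped_with_warning(self):
        dtm = sl.build_dtm(sl.Corpus.from_texts({"a": "sweet sweet"}))
        fmap = FusionMap({"sweet": {"similar_terms": ["sweet", "ghost"]}})
        with pytest.warns(UserWarning, match="ghost"):
            _, lex = sl.apply_normalization(dtm, fmap)
        assert lex.frequency("sweet") == 2

    @settings(max_examples=25, deadline=None)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_token_mass_conserved_under_any_auto_fusion(self, seed):
        vocab = {t: 0.5 for t in ["sweet", "sour", "pear", "musty", "honey"]}
        corpus = sl.gen_corpus(10, vocab, planted_pairs=[("sweet", "sour")], seed=seed)
        dtm = sl.build_dtm(corpus)
        corr = sl.term_correlations(dtm)
        fmap = sl.propose_fusions(corr, 0.5, dict(zip(dtm.terms, dtm.term_frequency.tolist())))
        dtm2, lex = sl.apply_normalization(dtm, fmap)
        assert dtm2.counts.sum() == dtm.counts.sum()
        assert sum(f for _, f in lex.entries) == dtm.counts.sum()


class TestCooccurrenceNetwork:
    def test_weights_match_brute_force_intersection(self):
        corpus = sl.gen_corpus(10, {t: 0.5 for t in "abcde"}, seed=4)
        dtm = sl.build_dtm(corpus)
        net = sl.cooccurrence_network(dtm, min_edge_weight=1)
        present = dtm.counts > 0
        terms = list(dtm.terms)
        for _, row in net.iterrows():
            i, j = terms.index(row.term_a), terms.index(row.term_b)
            assert row.weight == int((present[:, i] & present[:, j]).sum())

    def test_disjoint_supports_give_no_edge(self):
        counts = np.array([[1, 0], [1, 0], [0, 1]])
        dtm = sl.DocumentTermMatrix(("d1", "d2", "d3"), ("a", "b"), counts)
        assert sl.cooccurrence_network(dtm, 1).empty

    def test_min_edge_weight_drops_light_edges(self):
        counts = np.array([[1, 1], [1, 1], [1, 0]])
        dtm = sl.DocumentTermMatrix(("d1", "d2", "d3"), ("a", "b"), counts)
        assert len(sl.cooccurrence_network(dtm, 3)) == 0
        net = sl.cooccurrence_network(dtm, 2)
        assert net.iloc[0].weight == 2


def test_pipeline_is_deterministic(tmp_path):
    """Same corpus + options must yield byte-identical lexicon output."""
    vocab = {t: 0.5 for t in ["sweet", "sour", "pear", "honey", "musty"]}
    outputs = []
    for run in range(2):
        corpus = sl.gen_corpus(12, vocab, planted_pairs=[("sweet", "sour")], seed=42)
        dtm = sl.filter_sparse_terms(sl.build_dtm(corpus), 0.10)
        corr = sl.term_correlations(dtm)
        fmap = sl.propose_fusions(corr, 0.5, dict(zip(dtm.terms, dtm.term_frequency.tolist())))
        _, lex = sl.apply_normalization(dtm, fmap)
        path = tmp_path / f"lex{run}.csv"
        lex.to_csv(path)
        outputs.append(path.read_bytes())
    assert outputs[0] == outputs[1]
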