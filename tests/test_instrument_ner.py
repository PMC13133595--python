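import numpy as np
import pytest

from promscan import instrument_ner as ner
from promscan import lexicon_matcher as lm


class TestBio:
    def test_forced_example(self):
        text = "Assessed by EORTC QLQ-C30 at baseline"
        span = (text.index("EORTC"), text.index("EORTC") + len("EORTC QLQ-C30"))
        bio = ner.spans_to_bio(text, [span])
        # module tokenizer splits "QLQ-C30" into QLQ / - / C30
        assert bio.tokens == ("Assessed", "by", "EORTC", "QLQ", "-", "C30", "at", "baseline")
        assert bio.tags == ("O", "O", "B", "I", "I", "I", "O", "O")

    def test_no_spans_all_o(self):
        bio = ner.spans_to_bio("no instruments here", [])
        assert set(bio.tags) == {"O"}

    def test_overlapping_spans_error(self):
        with pytest.raises(ner.NerError):
            ner.spans_to_bio("a b c d", [(0, 3), (2, 5)])

    def test_out_of_bounds_error(self):
        with pytest.raises(ner.NerError):
            ner.spans_to_bio("ab", [(0, 5)])

    def test_invalid_sequences_rejected(self):
        with pytest.raises(ner.NerError):
            ner.BioSequence(tokens=("a", "b"), tags=("O", "I"), token_spans=((0, 1), (2, 3)))
        with pytest.raises(ner.NerError):
            ner.BioSequence(tokens=("a",), tags=("B", "I"), token_spans=((0, 1),))

    def test_round_trip_randomized(self):
        """bio_to_spans(spans_to_bio(text, S)) == S over 1000 random span sets."""
        rng = np.random.default_rng(12345)
        words = ["alpha", "beta", "gamma", "delta", "epsilon", "zeta", "eta", "theta"]
        for _ in range(1000):
            n = int(rng.integers(1, 9))
            text = " ".join(words[int(rng.integers(len(words)))] for _ in range(n))
            tokens = ner.tokenize(text)
            # choose disjoint token-aligned spans
            k = int(rng.integers(0, min(3, len(tokens)) + 1))
            starts = sorted(rng.choice(len(tokens), size=k, replace=False)) if k else []
            spans = []
            for si, token_i in enumerate(starts):
                limit = starts[si + 1] if si + 1 < len(starts) else len(tokens)
                length = int(rng.integers(1, limit - token_i + 1))
                spans.append((tokens[token_i][1], tokens[token_i + length - 1][2]))
            bio = ner.spans_to_bio(text, spans)
            assert ner.bio_to_spans(bio) == sorted(spans)


class TestExtraction:
    def test_lexicon_seeded_span(self, lexicon):
        extractor = ner.rule_assisted_extractor(lexicon)
        text = "Change from baseline in EORTC QLQ-C30 total score."
        mentions = ner.extract_mentions(text, extractor)
        assert any(m.surface_text == "EORTC QLQ-C30" for m in mentions)

    def test_no_instrument_tokens(self, lexicon):
        extractor = ner.rule_assisted_extractor(lexicon)
        assert ner.extract_mentions("Time to disease progression.", extractor) == []

    def test_fragmented_multiword_merged(self):
        # a weak extractor tags the head and tail of one long name separately
        text = "Measured with the Short Form 36 Health Survey at month 6"
        head = (text.index("Short"), text.index("Short") + len("Short Form"))
        tail = (text.index("Health"), text.index("Health") + len("Health Survey"))

        def weak_extractor(_text):
            return [head, tail]

        mentions = ner.extract_mentions(text, weak_extractor)
        assert len(mentions) == 1
        assert mentions[0].surface_text == "Short Form 36 Health Survey"

    def test_distant_mentions_not_merged(self):
        text = "HADS score first and much later in the visit the BPI form"
        spans = [(0, 4), (text.index("BPI"), text.index("BPI") + 3)]
        mentions = ner.extract_mentions(text, lambda _t: spans)
        assert len(mentions) == 2

    def test_every_planted_mention_recovered(self, lexicon, small_corpus):
        studies, gt = small_corpus
        extractor = ner.rule_assisted_extractor(lexicon)
        for study in studies:
            for outcome in study.outcomes:
                truth = gt.outcomes[outcome.key]
                if not truth.contains_named_instrument:
                    continue
                mentions = ner.extract_mentions(outcome.full_text, extractor, outcome.key)
                s, e = truth.span
                assert any(m.start <= s and e <= m.end for m in mentions), outcome.full_text


class TestNormalization:
    def test_exact_canonical_name(self, lexicon):
        mention = ner.EntityMention(("S", 1), "Brief Pain Inventory", 0, 20)
        out = ner.normalize_mention(mention, lexicon)
        assert out.similarity == pytest.approx(1.0)
        assert out.normalized_instrument_id == "I020"

    def test_hyphen_dropped_variant_assigned(self, lexicon):
        # independent brute-force check: after hyphen/space unification the
        # two strings are identical, so trigram cosine is exactly 1
        assert ner.trigram_cosine("EORTC QLQ C30", "EORTC QLQ-C30") == pytest.approx(1.0)
        mention = ner.EntityMention(("S", 1), "EORTC QLQ C30", 0, 13)
        out = ner.normalize_mention(mention, lexicon)
        assert out.normalized_instrument_id == "I001"
        assert out.similarity >= ner.DEFAULT_SIMILARITY_THRESHOLD

    def test_pain_below_threshold(self, lexicon):
        # brute-force oracle: max trigram cosine of "pain" over every surface
        best = max(
            ner.trigram_cosine("PAIN", surface)
            for surface, _, _ in lexicon.surface_forms()
        )
        assert best < ner.DEFAULT_SIMILARITY_THRESHOLD
        mention = ner.EntityMention(("S", 1), "PAIN", 0, 4)
        out = ner.normalize_mention(mention, lexicon)
        assert out.normalized_instrument_id is None

    def test_similarity_case_and_whitespace_invariant(self):
        assert ner.trigram_cosine("  HADS  ", "hads") == pytest.approx(1.0)
        assert ner.trigram_cosine("Brief  Pain Inventory", "brief pain inventory") == (
            pytest.approx(1.0)
        )

    def test_empty_lexicon_errors(self):
        mention = ner.EntityMention(("S", 1), "HADS", 0, 4)
        with pytest.raises(ner.NerError):
            ner.normalize_mention(mention, lm.InstrumentLexicon(entries=[]))

    def test_threshold_validation(self, lexicon):
        mention = ner.EntityMention(("S", 1), "HADS", 0, 4)
        with pytest.raises(ner.NerError):
            ner.normalize_mention(mention, lexicon, threshold=0.0)

    def test_assignment_iff_threshold(self, lexicon):
        mention = ner.EntityMention(("S", 1), "EORTC QLQ", 0, 9)
        out = ner.normalize_mention(mention, lexicon)
        assert (out.normalized_instrument_id is not None) == (
            out.similarity >= ner.DEFAULT_SIMILARITY_THRESHOLD
        )


class TestFrequencies:
    def mention(self, study, iid):
        return ner.EntityMention((study, 1), "x", 0, 1, normalized_instrument_id=iid,
                                 similarity=1.0)

    def test_per_study_dedup(self):
        mentions = [
            ner.EntityMention(("S1", 1), "x", 0, 1, "I001", 1.0),
            ner.EntityMention(("S1", 2), "x", 0, 1, "I001", 1.0),
        ]
        rows = ner.instrument_frequencies(mentions)
        assert rows == [{"instrument_id": "I001", "n_studies": 1, "proportion": 1.0}]

    def test_empty(self):
        assert ner.instrument_frequencies([]) == []

    def test_unnormalized_ignored(self):
        mentions = [ner.EntityMention(("S1", 1), "x", 0, 1, None, 0.2)]
        assert ner.instrument_frequencies(mentions) == []

    def test_planted_frequencies_recovered(self, lexicon, small_corpus):
        studies, gt = small_corpus
        from promscan.synthetic_corpus import corpus_report

        expected = corpus_report(gt)["instrument_study_counts"]
        extractor = ner.rule_assisted_extractor(lexicon)
        mentions = []
        for study in studies:
            for outcome in study.outcomes:
                for m in ner.extract_mentions(outcome.full_text, extractor, outcome.key):
                    mentions.append(ner.normalize_mention(m, lexicon))
        rows = ner.instrument_frequencies(mentions)
        got = {r["instrument_id"]: r["n_studies"] for r in rows}
        assert got == expected

    def test_conservation(self, lexicon, small_corpus):
        studies, gt = small_corpus
        mentions = [
            ner.EntityMention((sid, idx), t.surface or "", 0, 1,
                              t.instrument_id, 1.0)
            for (sid, idx), t in gt.outcomes.items()
            if t.contains_named_instrument
        ]
        rows = ner.instrument_frequencies(mentions)
        n_studies_with_any = len({m.outcome_key[0] for m in mentions})
        assert sum(r["n_studies"] for r in rows) >= n_studies_with_any
        assert all(r["n_studies"] <= n_studies_with_any for r in rows)


def test_annotations_jsonl_round_trip(tmp_path):
    data = [("HADS at baseline", [(0, 4)]), ("no spans", [])]
    path = tmp_path / "annotations.jsonl"
    ner.write_annotations_jsonl(data, path)
    assert ner.read_annotations_jsonl(path) == [(t, list(s)) for t, s in data]
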