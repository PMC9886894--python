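"""Corpus data model, JSONL round-trips, and composition statistics."""

import json

import pytest
from hypothesis import given, settings, strategies as st

from cogdep import (
    CorpusStats,
    DistortionCategory,
    Post,
    TaxonomyError,
    UserRecord,
    corpus_statistics,
    read_posts,
    read_users,
    write_posts,
    write_users,
)
from cogdep.corpus import CorpusFormatError
from cogdep.taxonomy import DISTORTIONS, N_CLASSES


class TestTaxonomy:
    def test_exactly_twelve_categories_with_normal_last(self):
        cats = list(DistortionCategory)
        assert len(cats) == N_CLASSES == 12
        assert cats[-1] is DistortionCategory.NORMAL
        assert DistortionCategory.NORMAL.index == 11
        assert len(DISTORTIONS) == 11

    def test_codes_unique_and_stable(self):
        codes = [c.code for c in DistortionCategory]
        assert len(set(codes)) == 12
        for c in DistortionCategory:
            assert DistortionCategory.from_code(c.code) is c
            assert DistortionCategory.from_index(c.index) is c

    def test_unknown_code_raises(self):
        with pytest.raises(TaxonomyError):
            DistortionCategory.from_code("catastrophizing")


class TestPostModel:
    def test_empty_text_rejected(self):
        with pytest.raises(ValueError):
            Post(post_id="p", user_id="u", text="   ")

    def test_pseudo_requires_confidence(self):
        with pytest.raises(ValueError):
            Post(post_id="p", user_id="u", text="hi there",
                 label="mindreading", label_source="pseudo")
        p = Post(post_id="p", user_id="u", text="hi there",
                 label="mindreading", label_source="pseudo", confidence=0.95)
        assert p.label is DistortionCategory.MINDREADING

    def test_gold_confidence_must_be_absent_or_one(self):
        with pytest.raises(ValueError):
            Post(post_id="p", user_id="u", text="hi", label="normal",
                 label_source="gold", confidence=0.7)


class TestUserModel:
    def test_posts_must_share_user_id(self):
        with pytest.raises(ValueError):
            UserRecord(user_id="u1", posts=[
                Post(post_id="p", user_id="other", text="hi")
            ])

    def test_cohort_label_consistency(self):
        with pytest.raises(ValueError):
            UserRecord(
                user_id="u",
                posts=[Post(post_id="p", user_id="u", text="hi")],
                depression_label=1,
                cohort="control",
            )

    def test_chronological_order_when_timestamped(self):
        posts = [
            Post(post_id="b", user_id="u", text="later",
                 timestamp="2021-02-01T00:00:00"),
            Post(post_id="a", user_id="u", text="earlier",
                 timestamp="2021-01-01T00:00:00"),
        ]
        u = UserRecord(user_id="u", posts=posts)
        assert [p.post_id for p in u.posts] == ["a", "b"]


class TestJsonlIO:
    def test_read_preserves_file_order_and_labels(self, tmp_path):
        f = tmp_path / "posts.jsonl"
        f.write_text(
            '{"post_id":"1","user_id":"u","text":"aa"}\n'
            '{"post_id":"2","user_id":"u","text":"bb","label":"mindreading"}\n'
            '{"post_id":"3","user_id":"u","text":"cc"}\n'
        )
        posts = read_posts(f)
        assert [p.post_id for p in posts] == ["1", "2", "3"]
        assert posts[1].label is DistortionCategory.MINDREADING

    def test_unknown_label_is_taxonomy_error_naming_line(self, tmp_path):
        f = tmp_path / "posts.jsonl"
        f.write_text('{"post_id":"1","user_id":"u","text":"x",'
                     '"label":"catastrophizing"}\n')
        with pytest.raises(TaxonomyError, match=r":1:"):
            read_posts(f)

    def test_malformed_line_names_line_number(self, tmp_path):
        f = tmp_path / "posts.jsonl"
        f.write_text('{"post_id":"1","user_id":"u","text":"x"}\nnot json\n')
        with pytest.raises(CorpusFormatError, match=r":2:"):
            read_posts(f)

    def test_empty_sequence_roundtrip(self, tmp_path):
        path = write_posts([], tmp_path / "empty.jsonl")
        assert read_posts(path) == []

    @settings(max_examples=25, deadline=None)
    @given(st.data())
    def test_post_roundtrip_identity(self, data):
        import tempfile
        from pathlib import Path

        cats = list(DistortionCategory)
        posts = []
        n = data.draw(st.integers(1, 10))
        for i in range(n):
            label = data.draw(st.sampled_from(cats + [None]))
            posts.append(Post(
                post_id=f"p{i}",
                user_id="u",
                text=data.draw(st.text(alphabet="abc xyz", min_size=1).filter(
                    lambda s: s.strip())),
                label=label,
                label_source="gold" if label else "none",
            ))
        with tempfile.TemporaryDirectory() as d:
            path = Path(d) / "posts.jsonl"
            write_posts(posts, path)
            assert read_posts(path) == posts

    def test_user_roundtrip_preserves_post_order(self, tmp_path, small_corpus):
        path = write_users(small_corpus, tmp_path / "users.jsonl")
        back = read_users(path)
        assert back == list(small_corpus)


class TestCorpusStatistics:
    def _user(self, uid, n_posts, cohort=None, label=None):
        posts = [Post(post_id=f"{uid}p{i}", user_id=uid, text="one two three")
                 for i in range(n_posts)]
        return UserRecord(user_id=uid, posts=posts, cohort=cohort,
                          depression_label=label)

    def test_average_posts_per_user(self):
        st_ = corpus_statistics([self._user("a", 3), self._user("b", 5)])
        assert st_.avg_posts_per_user["unknown"] == 4.0
        assert st_.avg_tokens_per_post["unknown"] == 3.0

    def test_category_counts_on_labeled_fixture(self):
        posts = []
        for cat in DISTORTIONS:
            for j in range(2):
                posts.append(Post(post_id=f"{cat.code}{j}", user_id="u",
                                  text="hello world", label=cat,
                                  label_source="gold"))
        for j in range(4):
            posts.append(Post(post_id=f"n{j}", user_id="u", text="hello",
                              label=DistortionCategory.NORMAL,
                              label_source="gold"))
        st_ = corpus_statistics([UserRecord(user_id="u", posts=posts)])
        for cat in DISTORTIONS:
            assert st_.label_counts[cat.code] == 2
        assert st_.label_counts["normal"] == 4
        assert st_.n_labeled == 26

    def test_per_cohort_keys(self):
        st_ = corpus_statistics([
            self._user("a", 3, cohort="depression", label=1),
            self._user("b", 5, cohort="control", label=0),
        ])
        assert st_.n_users_per_cohort == {"depression": 1, "control": 1}
        assert st_.n_posts_per_cohort == {"depression": 3, "control": 5}

    def test_empty_corpus_reports_absent_averages(self):
        st_ = corpus_statistics([])
        assert st_.n_users == 0 and st_.n_posts == 0
        assert st_.avg_posts_per_user == {}

    def test_matches_bruteforce_recount(self, small_corpus):
        st_ = corpus_statistics(small_corpus)
        n_posts = sum(len(u.posts) for u in small_corpus)
        assert st_.n_posts == n_posts
        assert st_.n_labeled == n_posts  # generator gold-labels every post
        brute = {}
        for u in small_corpus:
            for p in u.posts:
                brute[p.label.code] = brute.get(p.label.code, 0) + 1
        assert st_.label_counts == brute
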