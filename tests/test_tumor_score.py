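import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from genesig.tumor_score import (
    DirectionProfile,
    ScoringEntry,
    ScoringTable,
    classify,
    compute_coefficients,
    count_category_hits,
    gene_contribution,
    ideal_scores,
    read_profile,
    read_scoring_table,
    score_profile,
    write_profile,
    write_scoring_table,
)

SIGN_DIR = {1: "up", -1: "down"}
OPP = {"up": "down", "down": "up"}


def brute_force_scores(profile, table):
    """Independent per-gene loop oracle (no shared code with score_profile)."""
    out = {}
    for cat in {e.category for e in table.entries}:
        entries = [e for e in table.entries if e.category == cat]
        hr = max(e.rank for e in entries)
        s = s_not = ideal = 0.0
        for e in entries:
            b = 1.0 - e.rank / hr
            ideal += b
            d = profile.directions.get(e.gene, "unchanged")
            if d == SIGN_DIR[e.sign]:
                s += b
            elif d != "unchanged" and d == OPP[SIGN_DIR[e.sign]]:
                s_not += b
        out[cat] = (s, s_not, ideal)
    return out


def random_table(rng, n_categories=3, max_entries=20, max_rank=50):
    entries = []
    gid = 0
    for c in range(n_categories):
        n = int(rng.integers(1, max_entries + 1))
        ranks = rng.choice(np.arange(1, max_rank + 1), size=n, replace=False)
        for r in ranks:
            gid += 1
            entries.append(
                ScoringEntry(f"g{gid}", f"cat{c}", int(rng.choice([1, -1])), int(r))
            )
    return ScoringTable(entries)


def random_profile(rng, table):
    return DirectionProfile({
        e.gene: str(rng.choice(["up", "down", "unchanged"]))
        for e in table.entries
    })


class TestCoefficients:
    def test_two_ranks(self):
        t = ScoringTable([ScoringEntry("a", "X", 1, 1), ScoringEntry("b", "X", 1, 2)])
        assert compute_coefficients(t) == {"X": 0.5}

    def test_large_category_rounds_like_report(self):
        entries = [ScoringEntry(f"g{r}", "BLlike", 1, r) for r in range(1, 1021)]
        c = compute_coefficients(ScoringTable(entries))["BLlike"]
        assert round(c, 6) == 0.000980

    def test_per_category_independent(self, toy_table):
        coeffs = compute_coefficients(toy_table)
        assert coeffs["X"] == pytest.approx(1 / 3)
        assert coeffs["Y"] == pytest.approx(1 / 4)


class TestGeneContribution:
    def test_match(self):
        assert gene_contribution(True, 0.25, 1) == pytest.approx(0.75)

    def test_top_rank_contributes_zero(self):
        assert gene_contribution(True, 1 / 7, 7) == pytest.approx(0.0)

    def test_no_match_is_zero(self):
        assert gene_contribution(False, 0.25, 3) == 0.0

    def test_rank_beyond_maximum_errors(self):
        with pytest.raises(ValueError, match="exceeds"):
            gene_contribution(True, 0.5, 3)

    @given(hr=st.integers(1, 500), r=st.integers(1, 500))
    def test_bounded_in_unit_interval(self, hr, r):
        if r > hr:
            return
        b = gene_contribution(True, 1.0 / hr, r)
        assert 0.0 <= b < 1.0 or (b == 0.0 and r == hr)
        if r == hr:
            assert b == pytest.approx(0.0)


class TestIdealScores:
    def test_hand_sum(self):
        t = ScoringTable([
            ScoringEntry("a", "X", 1, 1),
            ScoringEntry("b", "X", -1, 2),
            ScoringEntry("c", "X", 1, 4),
        ])
        # HR = 4, C = 0.25: 0.75 + 0.5 + 0 = 1.25
        assert ideal_scores(t)["X"] == pytest.approx(1.25)

    def test_single_entry_degenerate(self):
        t = ScoringTable([ScoringEntry("a", "X", 1, 1)])
        assert ideal_scores(t)["X"] == 0.0

    def test_complement_equals_category(self):
        # invert every direction: the complement accumulates the same B sum
        rng = np.random.default_rng(3)
        for _ in range(10):
            table = random_table(rng)
            ideal = ideal_scores(table)
            all_match = DirectionProfile(
                {e.gene: SIGN_DIR[e.sign] for e in table.entries}
            )
            inverted = DirectionProfile(
                {g: OPP[d] for g, d in all_match.directions.items()}
            )
            report = score_profile(inverted, table)
            for cat in table.categories:
                assert report.scores[cat].raw_complement == pytest.approx(ideal[cat])


class TestScoreProfile:
    def test_all_matching_profile_is_exactly_one(self, toy_table):
        profile = DirectionProfile(
            {e.gene: SIGN_DIR[e.sign] for e in toy_table.entries}
        )
        report = score_profile(profile, toy_table)
        for cat in toy_table.categories:
            assert report.scores[cat].relative == pytest.approx(1.0, abs=1e-15)

    def test_all_unchanged_profile_is_zero(self, toy_table):
        profile = DirectionProfile({e.gene: "unchanged" for e in toy_table.entries})
        report = score_profile(profile, toy_table)
        for cat in toy_table.categories:
            s = report.scores[cat]
            assert s.raw == 0.0 and s.relative == 0.0

    def test_partial_match_hand_computation(self):
        t = ScoringTable([
            ScoringEntry("a", "X", 1, 1),
            ScoringEntry("b", "X", 1, 2),
            ScoringEntry("c", "X", 1, 3),
        ])
        # C = 1/3; B = 2/3, 1/3, 0; ideal = 1.0; matching only rank-1:
        profile = DirectionProfile({"a": "up", "b": "unchanged", "c": "unchanged"})
        report = score_profile(profile, t)
        assert report.scores["X"].raw == pytest.approx(2 / 3)
        assert report.scores["X"].relative == pytest.approx(2 / 3)

    def test_opposite_direction_feeds_complement(self):
        t = ScoringTable([
            ScoringEntry("a", "X", 1, 1),
            ScoringEntry("b", "X", 1, 2),
        ])
        profile = DirectionProfile({"a": "down", "b": "up"})
        report = score_profile(profile, t)
        assert report.scores["X"].raw == pytest.approx(0.0)
        assert report.scores["X"].raw_complement == pytest.approx(0.5)

    def test_profile_genes_absent_from_table_are_ignored(self, toy_table):
        profile = DirectionProfile({"zz": "up"})
        report = score_profile(profile, toy_table)
        assert report.ignored_genes == ["zz"]
        assert report.scores["X"].raw == 0.0

    def test_monotone_in_added_matches(self):
        rng = np.random.default_rng(11)
        table = random_table(rng, n_categories=1)
        cat = table.categories[0]
        entries = table.entries_for(cat)
        directions = {e.gene: "unchanged" for e in entries}
        prev = 0.0
        for e in entries:
            directions[e.gene] = SIGN_DIR[e.sign]
            rel = score_profile(DirectionProfile(dict(directions)), table).scores[cat].relative
            assert rel >= prev - 1e-12
            prev = rel

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(99)
        for _ in range(30):
            table = random_table(rng)
            profile = random_profile(rng, table)
            report = score_profile(profile, table)
            expected = brute_force_scores(profile, table)
            for cat, (s, s_not, ideal) in expected.items():
                got = report.scores[cat]
                assert got.raw == pytest.approx(s, abs=1e-9)
                assert got.raw_complement == pytest.approx(s_not, abs=1e-9)
                assert got.ideal == pytest.approx(ideal, abs=1e-9)


class TestClassify:
    @pytest.mark.parametrize("rel,flag", [(0.45, True), (0.124, False),
                                          (0.0, False), (0.4, True), (1.0, True)])
    def test_threshold(self, rel, flag, toy_table):
        profile = DirectionProfile({})
        report = score_profile(profile, toy_table)
        report.scores["X"].relative = rel
        assert classify(report)["X"] is flag


class TestCountCategoryHits:
    def test_basic(self):
        t = ScoringTable([
            ScoringEntry("a", "EWS", 1, 1, "EWS"),
            ScoringEntry("b", "RMS", 1, 1, "RMS"),
            ScoringEntry("x", "NB", 1, 1, "NB"),
            ScoringEntry("y", "BL", 1, 1, "BL"),
        ])
        counts = count_category_hits({"a", "b"}, t)
        assert counts == {"BL": 0, "EWS": 1, "NB": 0, "RMS": 1, "unassigned": 0}

    def test_empty_gene_set(self):
        t = ScoringTable([ScoringEntry("a", "X", 1, 1)])
        assert all(v == 0 for v in count_category_hits(set(), t).values())

    def test_myoblast_style_counting(self):
        # 12 genes against a map placing 5/2/2/3 in the four categories
        entries, genes = [], []
        layout = [("EWS", 5), ("RMS", 2), ("NB", 2), ("BL", 3)]
        i = 0
        for cat, n in layout:
            for _ in range(n):
                i += 1
                entries.append(ScoringEntry(f"g{i}", cat, 1, i, cat))
                genes.append(f"g{i}")
        counts = count_category_hits(genes, ScoringTable(entries))
        assert counts == {"EWS": 5, "RMS": 2, "NB": 2, "BL": 3, "unassigned": 0}

    def test_unassigned_bucket(self):
        t = ScoringTable([ScoringEntry("a", "X", 1, 1)])
        assert count_category_hits({"zz"}, t)["unassigned"] == 1

    def test_multi_category_gene_without_explicit_specificity(self):
        t = ScoringTable([
            ScoringEntry("a", "X", 1, 1),
            ScoringEntry("a", "Y", 1, 2),
        ])
        assert count_category_hits({"a"}, t)["unassigned"] == 1


class TestValidation:
    def test_duplicate_gene_category_pair(self):
        with pytest.raises(ValueError, match="duplicate"):
            ScoringTable([ScoringEntry("a", "X", 1, 1), ScoringEntry("a", "X", -1, 2)])

    def test_bad_sign(self):
        with pytest.raises(ValueError, match="sign"):
            ScoringEntry("a", "X", 2, 1)

    def test_bad_rank(self):
        with pytest.raises(ValueError, match="rank"):
            ScoringEntry("a", "X", 1, 0)

    def test_tied_ranks_permitted(self):
        t = ScoringTable([ScoringEntry("a", "X", 1, 3), ScoringEntry("b", "X", 1, 3)])
        assert compute_coefficients(t)["X"] == pytest.approx(1 / 3)

    def test_bad_profile_direction(self):
        with pytest.raises(ValueError):
            DirectionProfile({"a": "sideways"})


class TestIO:
    def test_scoring_table_roundtrip(self, tmp_path, toy_table):
        path = tmp_path / "table.tsv"
        write_scoring_table(toy_table, path, header_comment="seed=1")
        back = read_scoring_table(path)
        assert back.entries == toy_table.entries

    def test_profile_roundtrip(self, tmp_path):
        profile = DirectionProfile({"a": "up", "b": "down", "c": "unchanged"})
        path = tmp_path / "profile.tsv"
        write_profile(profile, path)
        assert read_profile(path).directions == profile.directions

    def test_report_json_and_radar(self, tmp_path, toy_table):
        profile = DirectionProfile(
            {e.gene: SIGN_DIR[e.sign] for e in toy_table.entries}
        )
        report = score_profile(profile, toy_table)
        report.write_json(tmp_path / "r.json")
        report.write_radar_csv(tmp_path / "radar.csv")
        radar = (tmp_path / "radar.csv").read_text().splitlines()
        assert radar[0].startswith("category,")
        assert len(radar) == 1 + len(toy_table.categories)
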