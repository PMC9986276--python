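"""Information content, trimming, stringency, motif similarity, scanning,
enrichment, the expression rule and the seven-criterion filter."""

import numpy as np
import pytest

from emotifre.postprocess import (
    CRITERIA,
    ExpressionTable,
    apply_filters,
    column_ic,
    enrichment_test,
    expression_status,
    match_known,
    motif_similarity,
    pwm_ic,
    scan_hits,
    stringent_fraction,
    trim_motif,
)
from emotifre.meme_io import KnownMotif, KnownMotifDB
from emotifre.simulate import (
    FILTER_CASE_NAMES,
    consensus_to_pwm,
    make_expression_fixture,
    make_filter_case,
    random_background,
)


def random_pwm(rng, width, sharp=0.6):
    """Random PWM mixing informative and flat columns."""
    pwm = rng.dirichlet(np.ones(4) * 0.5, size=width)
    flat = rng.random(width) < 0.3
    pwm[flat] = 0.25
    return pwm


class TestInformationContent:
    def test_closed_forms(self):
        assert column_ic([0.25, 0.25, 0.25, 0.25]) == pytest.approx(0.0)
        assert column_ic([1, 0, 0, 0]) == pytest.approx(2.0)
        assert column_ic([0.5, 0.5, 0, 0]) == pytest.approx(1.0)

    def test_non_normalized_rejected(self):
        with pytest.raises(ValueError):
            column_ic([0.5, 0.5, 0.5, 0.5])

    def test_range(self):
        rng = np.random.default_rng(0)
        ics = pwm_ic(rng.dirichlet(np.ones(4), size=50))
        assert np.all((ics >= 0) & (ics <= 2))


def brute_force_trim(pwm, threshold=0.3):
    """Independent both-ends scan oracle."""
    ics = pwm_ic(pwm)
    start = None
    for j, ic in enumerate(ics):
        if ic > threshold:
            start = j
            break
    if start is None:
        return None
    end = None
    for j in range(len(ics) - 1, -1, -1):
        if ics[j] > threshold:
            end = j
            break
    return start, end


class TestTrim:
    def test_scan_from_both_ends(self):
        # columns with IC approximately (0, 0, 2, 2, 1, 0, 0)
        cols = [[0.25] * 4, [0.25] * 4, [1, 0, 0, 0], [0, 1, 0, 0],
                [0.5, 0.5, 0, 0], [0.25] * 4, [0.25] * 4]
        res = trim_motif(np.array(cols))
        assert (res.start, res.end) == (2, 4) and res.pwm.shape[0] == 3

    def test_uniform_is_degenerate(self):
        res = trim_motif(np.full((5, 4), 0.25))
        assert res.degenerate and res.pwm.shape[0] == 0

    def test_fully_informative_untouched(self):
        pwm = np.eye(4)[[0, 1, 2, 3]].astype(float)
        res = trim_motif(pwm)
        assert (res.start, res.end) == (0, 3)

    def test_matches_bruteforce_on_random_pwms(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            pwm = random_pwm(rng, int(rng.integers(1, 25)))
            res = trim_motif(pwm)
            oracle = brute_force_trim(pwm)
            if oracle is None:
                assert res.degenerate
            else:
                assert (res.start, res.end) == oracle


class TestStringency:
    def test_one_hot_is_fully_stringent(self):
        assert stringent_fraction(np.eye(4)[[0, 1, 2]].astype(float)) == 1.0

    def test_097_column_is_not_stringent(self):
        ic = column_ic([0.97, 0.01, 0.01, 0.01])
        assert ic == pytest.approx(1.758, abs=0.005)
        assert stringent_fraction(np.array([[0.97, 0.01, 0.01, 0.01]])) == 0.0

    def test_0997_column_is_stringent(self):
        ic = column_ic([0.997, 0.001, 0.001, 0.001])
        assert ic == pytest.approx(1.966, abs=0.005)
        assert stringent_fraction(np.array([[0.997, 0.001, 0.001, 0.001]])) == 1.0


class TestSimilarity:
    def test_self_match(self):
        rng = np.random.default_rng(1)
        q = consensus_to_pwm("CAGCTGC", rng=rng)
        r = motif_similarity(q, q, n_shuffles=500, seed=0)
        assert r.score == pytest.approx(1.0)
        assert r.offset == 0 and r.orientation == "+" and r.overlap_frac == 1.0

    def test_reverse_complement_orientation(self):
        rng = np.random.default_rng(2)
        q = consensus_to_pwm("CCAGGTGA", rng=rng)
        r = motif_similarity(q, q[::-1, ::-1].copy(), n_shuffles=500, seed=0)
        assert r.score == pytest.approx(1.0) and r.orientation == "-"

    def test_uniform_columns_degenerate(self):
        q = np.full((5, 4), 0.25)
        t = consensus_to_pwm("CAGTC")
        r = motif_similarity(q, t, n_shuffles=200, seed=0)
        assert r.score == 0.0 and r.degenerate and r.p_value == 1.0

    def test_too_narrow_rejected(self):
        with pytest.raises(ValueError):
            motif_similarity(np.full((1, 4), 0.25), np.full((4, 4), 0.25))


class TestMatchKnown:
    def test_query_in_db_ranks_first(self, toy_db):
        rng = np.random.default_rng(3)
        q = consensus_to_pwm("GTCATATG", rng=rng)  # NEUROG2-like core
        matches = match_known(q, toy_db, n_shuffles=1000, seed=0)
        assert matches[0].name == "NEUROG2"
        assert matches[0].q_value <= matches[-1].q_value

    def test_q_values_monotone_along_ranking(self, toy_db):
        rng = np.random.default_rng(4)
        q = consensus_to_pwm("CCTTTGT", rng=rng)
        matches = match_known(q, toy_db, n_shuffles=500, seed=1)
        qs = [m.q_value for m in matches]
        assert qs == sorted(qs)

    def test_empty_db_rejected(self):
        with pytest.raises(ValueError):
            match_known(np.full((4, 4), 0.25), KnownMotifDB([]))


def brute_force_hits(pwm, sequences, threshold_frac=0.8):
    """Per-window rescan oracle for scan_hits."""
    from emotifre.postprocess import LOG_ODDS_FLOOR

    lo = np.log2(np.maximum(pwm, LOG_ODDS_FLOOR) / 0.25)
    lo_rc = lo[::-1, ::-1]
    max_score = lo.max(axis=1).sum()
    w = pwm.shape[0]
    hits = []
    for seq in sequences:
        best = -np.inf
        for i in range(len(seq) - w + 1):
            window = seq[i : i + w]
            for mat in (lo, lo_rc):
                s = sum(mat[j, "ACGT".index(b)] for j, b in enumerate(window))
                best = max(best, s)
        hits.append(best >= threshold_frac * max_score)
    return np.array(hits)


class TestScanHits:
    def test_consensus_is_a_hit(self):
        pwm = consensus_to_pwm("CAGCTGC")
        seqs = random_background(5, 60, 0.5, seed=5)
        planted = [s[:20] + "CAGCTGC" + s[27:] for s in seqs]
        hits, _ = scan_hits(pwm, planted)
        assert hits.all()

    def test_pwm_wider_than_sequence_rejected(self):
        with pytest.raises(ValueError):
            scan_hits(consensus_to_pwm("CAGCTGC"), ["ACGT"])

    def test_agrees_with_bruteforce(self):
        rng = np.random.default_rng(6)
        pwm = consensus_to_pwm("GAGGTCAA", rng=rng)
        seqs = random_background(40, 50, 0.5, seed=6)
        # plant in some so both hit outcomes occur
        seqs = [s[:10] + "GAGGTCAA" + s[18:] if i % 3 == 0 else s
                for i, s in enumerate(seqs)]
        hits, _ = scan_hits(pwm, seqs)
        assert np.array_equal(hits, brute_force_hits(pwm, seqs))
        assert hits.any() and not hits.all()


class TestEnrichment:
    def test_null_construction_gives_or_near_one(self):
        pwm = consensus_to_pwm("CAGCTGC")
        seqs = random_background(200, 80, 0.5, seed=7)
        planted = [s[:30] + "CAGCTGC" + s[37:] for s in seqs]
        table, odds, p = enrichment_test(pwm, planted[:100], planted[100:])
        assert odds == pytest.approx(1.0, abs=0.5)
        assert p > 0.05

    def test_label_swap_inverts_odds_ratio(self):
        pwm = consensus_to_pwm("CCTTTGT")
        pos = [s[:10] + "CCTTTGT" + s[17:] for s in random_background(60, 60, 0.5, seed=8)]
        neg = random_background(60, 60, 0.5, seed=9)
        _, odds_ab, p_ab = enrichment_test(pwm, pos, neg)
        _, odds_ba, p_ba = enrichment_test(pwm, neg, pos)
        assert odds_ab == pytest.approx(1.0 / odds_ba)
        assert p_ab == pytest.approx(p_ba)


class TestExpressionRule:
    @pytest.fixture()
    def table(self):
        import pandas as pd

        frame = pd.DataFrame(
            {"day0": [10.0, 10.0, 0.0], "day26": [25.0, 15.0, 8.0],
             "day39": [20.0, 5.0, 8.0]},
            index=["UP_STABLE", "WEAK_UP", "FROM_ZERO"],
        )
        return ExpressionTable(frame)

    def test_two_fold_rise_then_plateau(self, table):
        transcribed, vals = expression_status("UP_STABLE", table)
        assert transcribed and vals["fold_day0_to_day26"] > 2

    def test_weak_rise_rejected(self, table):
        transcribed, _ = expression_status("WEAK_UP", table)
        assert not transcribed

    def test_pseudocount_guards_zero_day0(self, table):
        transcribed, vals = expression_status("FROM_ZERO", table)
        assert transcribed and vals["fold_day0_to_day26"] == pytest.approx(9.0)

    def test_unknown_tf_rejected(self, table):
        with pytest.raises(KeyError):
            expression_status("NOPE", table)

    def test_tsv_round_trip(self, tmp_path, table):
        path = str(tmp_path / "expr.tsv")
        table.to_tsv(path)
        back = ExpressionTable.from_tsv(path)
        assert "UP_STABLE" in back
        assert expression_status("UP_STABLE", back)[0]

    def test_fixture_patterns(self):
        expr = make_expression_fixture()
        assert expression_status("ASCL1", expr)[0]
        assert expression_status("SOX11", expr)[0]
        assert not expression_status("CTCF", expr)[0]  # high but flat
        assert not expression_status("NR2F1", expr)[0]  # rises into Day 39
        assert not expression_status("DECOY0", expr)[0]


class TestFilterLedger:
    @pytest.mark.parametrize("case_name", FILTER_CASE_NAMES)
    def test_each_fixture_fails_exactly_its_criterion(self, case_name):
        case = make_filter_case(case_name, seed=0)
        verdict = apply_filters(case["pwm"], case["db"], case["expression"], seed=0)
        failed = [c for c in CRITERIA if not verdict.passes[c]]
        if case["fails"] is None:
            assert failed == [] and verdict.overall
        else:
            assert failed == [case["fails"]] and not verdict.overall

    def test_overall_is_conjunction(self):
        for name in FILTER_CASE_NAMES:
            case = make_filter_case(name, seed=0)
            v = apply_filters(case["pwm"], case["db"], case["expression"],
                              n_shuffles=500, seed=0)
            assert v.overall == all(v.passes[c] for c in CRITERIA)

    def test_enrichment_recorded_when_sequences_given(self):
        case = make_filter_case("pass", seed=0)
        pos = [s[:20] + "CAGCTGC" + s[27:]
               for s in random_background(50, 60, 0.5, seed=10)]
        neg = random_background(50, 60, 0.5, seed=11)
        v = apply_filters(case["pwm"], case["db"], case["expression"],
                          positives=pos, negatives=neg, n_shuffles=500, seed=0)
        assert v.values["enrichment_odds_ratio"] > 1
        assert v.values["enrichment_p"] < 0.05
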