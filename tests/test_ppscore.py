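import io
import math

import numpy as np
import pytest

from archpp.annotation import AnnotatableUniverse, Term
from archpp.ppscore import (
    DEGENERATE_NULL,
    NOT_SCOREABLE,
    SCORED,
    ConfigError,
    EnumerationCapError,
    InfeasibleNullError,
    NullSummary,
    ScoreConfig,
    bh_fdr,
    empirical_pvalue,
    exact_null,
    pp_median,
    pp_score,
    results_to_tsv,
    sample_null,
    score_terms,
)
from archpp.genome_model import GenomeAssignmentTable, build_arch_count_matrix
from archpp.synthetic_data import build_genome_from_counts


def _matrix(counts):
    return build_arch_count_matrix(build_genome_from_counts(counts))


@pytest.mark.parametrize(
    "counts, dset, expected",
    [
        ({"A": 7, "B": 5, "C": 3, "D": 6}, "ABC", 5.0),  # odd: central value
        ({"A": 7, "B": 5, "C": 3, "D": 6}, "AD", 6.5),  # even: midpoint
        ({"A": 9}, "A", 9.0),  # singleton
    ],
)
def test_pp_median(counts, dset, expected):
    assert pp_median(set(dset), "G1", _matrix(counts)) == expected


def test_pp_median_empty_set_is_not_scoreable():
    assert pp_median(set(), "G1", _matrix({"A": 1})) is None


def test_pp_median_rejects_absent_members():
    m = _matrix({"A": 2, "B": 0})
    with pytest.raises(ValueError):
        pp_median({"A", "B"}, "G1", m)


def test_pp_median_order_invariant(fig_matrix):
    assert pp_median(["C", "A", "B"], "G1", fig_matrix) == \
        pp_median(["A", "B", "C"], "G1", fig_matrix)


# --- exact enumeration null: universe counts {d1:1, d2:2, d3:3}, k=2 ---

@pytest.fixture(scope="module")
def tiny_null():
    m = _matrix({"d1": 1, "d2": 2, "d3": 3})
    u = AnnotatableUniverse("G1", frozenset({"d1", "d2", "d3"}))
    return m, u


def test_exact_null_hand_enumeration(tiny_null):
    m, u = tiny_null
    en = exact_null(2, u, m)
    assert sorted(en.medians) == [1.5, 2.0, 2.5]
    assert en.mu == 2.0
    assert en.sigma == pytest.approx(math.sqrt(1 / 6), abs=1e-12)
    assert en.upper_tail(2.5) == pytest.approx(1 / 3)
    assert en.lower_tail(1.5) == pytest.approx(1 / 3)


def test_exact_null_full_universe_degenerate(tiny_null):
    m, u = tiny_null
    en = exact_null(3, u, m)
    assert en.sigma == 0.0
    assert en.upper_tail(en.mu) == 1.0


def test_exact_null_enumeration_cap(tiny_null):
    m, u = tiny_null
    with pytest.raises(EnumerationCapError):
        exact_null(2, u, m, cap=2)


def test_sample_null_converges_to_exact(tiny_null):
    m, u = tiny_null
    cfg = ScoreConfig(B=20000, seed=11)
    rng = np.random.default_rng(11)
    ns = sample_null(2, u, m, cfg, rng)
    en = exact_null(2, u, m)
    tol = 4 * en.sigma / math.sqrt(cfg.B)
    assert abs(ns.mu - en.mu) < tol
    assert ns.sigma == pytest.approx(en.sigma, abs=0.02)


def test_sample_null_full_universe_is_degenerate(tiny_null):
    m, u = tiny_null
    ns = sample_null(3, u, m, ScoreConfig(B=50), np.random.default_rng(0))
    assert ns.degenerate and ns.mu == 2.0


def test_sample_null_infeasible_k(tiny_null):
    m, u = tiny_null
    with pytest.raises(InfeasibleNullError):
        sample_null(4, u, m, ScoreConfig(B=10), np.random.default_rng(0))


def test_config_rejects_nonpositive_B():
    with pytest.raises(ConfigError):
        ScoreConfig(B=0)


def test_pp_score_arithmetic(tiny_null):
    m, u = tiny_null
    en = exact_null(2, u, m)
    assert pp_score(2.5, en) == pytest.approx(1.2247, abs=1e-4)
    assert pp_score(en.mu, en) == 0.0
    assert pp_score(1.5, en) < 0


def test_pp_score_degenerate_null_is_undefined(tiny_null):
    m, u = tiny_null
    with pytest.raises(ZeroDivisionError):
        pp_score(2.0, exact_null(3, u, m))


# --- directional empirical p-values on frozen replicate sets ---

def _null(samples):
    s = np.asarray(samples, dtype=float)
    return NullSummary(mu=float(s.mean()), sigma=float(s.std(ddof=1)),
                       samples=s, k=2)


def test_empirical_pvalue_upper_tail_raw_and_add_one():
    null = _null([1.5, 2, 2.5, 2, 1.5])  # mu = 1.9
    assert empirical_pvalue(2.5, null, "raw") == pytest.approx(1 / 5)
    assert empirical_pvalue(2.5, null, "add-one") == pytest.approx(2 / 6)


def test_empirical_pvalue_below_all_replicates():
    null = _null([1.5, 2, 2.5, 2, 1.5])
    assert empirical_pvalue(1.0, null, "raw") == 0.0
    assert empirical_pvalue(1.0, null, "add-one") == pytest.approx(1 / 6)


def test_empirical_pvalue_at_null_mean_is_one():
    null = _null([1.0, 2.0, 3.0])
    assert empirical_pvalue(2.0, null) == 1.0


@pytest.mark.parametrize(
    "p, expected",
    [
        ((0.01, 0.02, 0.03, 0.04), (0.04, 0.04, 0.04, 0.04)),
        ((0.005, 0.1), (0.01, 0.1)),
        ((0.3,), (0.3,)),
    ],
)
def test_bh_fdr_step_up(p, expected):
    assert bh_fdr(p) == pytest.approx(expected)


def test_bh_fdr_rejects_out_of_range():
    with pytest.raises(ValueError):
        bh_fdr([0.5, 1.5])


def test_bh_fdr_dominates_p_and_caps_at_one():
    rng = np.random.default_rng(3)
    p = rng.random(50)
    q = bh_fdr(p)
    assert np.all(q >= p) and np.all(q <= 1)


# --- whole-genome term scoring ---

@pytest.fixture(scope="module")
def scored_setup():
    counts = {f"SF{i:03d}": c for i, c in
              enumerate([1] * 10 + [2] * 5 + [3, 4, 5, 8, 13])}
    m = _matrix(counts)
    terms = [
        Term("GO:top", "most diverse", "specific",
             frozenset(["SF015", "SF016", "SF017", "SF018", "SF019"])),
        Term("GO:absent", "no members present", "general", frozenset(["ZZ"])),
        Term("GO:all", "whole universe", "general", frozenset(counts)),
        Term("GO:some", "a mixed handful", "general",
             frozenset(["SF000", "SF011", "SF016"])),
        Term("GO:five", "another five-set", "general",
             frozenset(["SF000", "SF005", "SF010", "SF011", "SF012"])),
    ]
    return m, terms


def test_score_terms_statuses_and_planted_sign(scored_setup):
    m, terms = scored_setup
    res = score_terms(terms, "G1", m, ScoreConfig(B=500, seed=5))
    res = res.set_index("term_id")
    assert res.loc["GO:absent", "status"] == NOT_SCOREABLE
    assert res.loc["GO:all", "status"] == DEGENERATE_NULL
    assert res.loc["GO:top", "status"] == SCORED
    # the top-diversity set must beat any equal-size random set
    assert res.loc["GO:top", "pp_score"] > 0
    assert res.loc["GO:top", "p_value"] <= res.loc["GO:some", "p_value"]
    scored = res[res["status"] == SCORED]
    assert np.all(scored["fdr"] >= scored["p_value"] - 1e-12)


def test_score_terms_deterministic_and_order_independent(scored_setup):
    m, terms = scored_setup
    cfg = ScoreConfig(B=300, seed=9)
    a, b = io.StringIO(), io.StringIO()
    results_to_tsv(score_terms(terms, "G1", m, cfg), a)
    rev = score_terms(list(reversed(terms)), "G1", m, cfg)
    results_to_tsv(rev.iloc[::-1].reset_index(drop=True), b)
    assert a.getvalue() == b.getvalue()


def test_score_terms_shared_null_per_k(scored_setup):
    m, terms = scored_setup
    cfg = ScoreConfig(B=300, seed=9, share_null_per_k=True)
    res = score_terms(terms, "G1", m, cfg).set_index("term_id")
    # equal-size terms share mu/sigma under the shared-stream option
    t5 = [t.term_id for t in terms
          if len(t.members) == 5 and t.term_id != "GO:absent"]
    mus = res.loc[t5, "null_mu"]
    assert len(set(mus.round(12))) == 1
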