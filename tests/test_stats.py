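"""Statistics layer against closed forms and brute-force oracles."""

import itertools
import json
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

import villistereo as vs
from villistereo.stats import report_from_json, report_to_json


# -- Student's t ------------------------------------------------------------

def test_identical_groups_give_t0_p1():
    r = vs.students_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert r.statistic == 0.0
    assert r.p_value == 1.0


def test_shifted_groups_match_closed_form():
    """{1,2,3} vs {11,12,13}: pooled s2=1, se=sqrt(2/3), t=-12.247, df=4."""
    r = vs.students_t([1.0, 2.0, 3.0], [11.0, 12.0, 13.0])
    t_expected = -10.0 / math.sqrt(2.0 / 3.0)
    assert r.statistic == pytest.approx(t_expected, rel=1e-12)
    assert r.df == 4
    p_expected = 2 * sps.t.sf(abs(t_expected), 4)
    assert r.p_value == pytest.approx(p_expected, rel=1e-9)
    assert r.p_value < 0.001


def test_t_is_antisymmetric_in_group_order():
    rng = np.random.default_rng(0)
    for _ in range(50):
        a = rng.normal(size=rng.integers(2, 10))
        b = rng.normal(loc=rng.normal(), size=rng.integers(2, 10))
        r_ab = vs.students_t(a, b)
        r_ba = vs.students_t(b, a)
        assert r_ab.statistic == pytest.approx(-r_ba.statistic, rel=1e-12)
        assert r_ab.p_value == pytest.approx(r_ba.p_value, rel=1e-12)


def test_zero_variance_unequal_means_is_flagged():
    r = vs.students_t([5.0, 5.0], [7.0, 7.0])
    assert r.p_value == 0.0
    assert "p_below_machine_precision" in r.flags
    assert r.statistic == -math.inf


def _permutation_p(a, b):
    """Exact permutation two-sided p on the mean difference."""
    pooled = np.concatenate([a, b])
    obs = abs(a.mean() - b.mean())
    n = len(a)
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n):
        mask = np.zeros(len(pooled), dtype=bool)
        mask[list(idx)] = True
        d = abs(pooled[mask].mean() - pooled[~mask].mean())
        total += 1
        if d >= obs - 1e-12:
            count += 1
    return count / total


def test_t_direction_and_significance_track_permutation_oracle():
    rng = np.random.default_rng(42)
    p_t, p_perm = [], []
    for _ in range(200):
        a = rng.normal(size=4)
        b = rng.normal(loc=rng.uniform(-3, 3), size=4)
        r = vs.students_t(a, b)
        assert np.sign(r.statistic) == np.sign(a.mean() - b.mean())
        p_t.append(r.p_value)
        p_perm.append(_permutation_p(a, b))
    rho = sps.spearmanr(p_t, p_perm).statistic
    assert rho > 0.8  # the two tests agree on which instances are extreme


def test_small_groups_rejected():
    with pytest.raises(ValueError):
        vs.students_t([1.0], [1.0, 2.0])


# -- Spearman ---------------------------------------------------------------

def test_monotone_pairs_give_extreme_rho():
    up = vs.spearman_rho([1, 2, 3, 4, 5], [10, 20, 40, 80, 160])
    assert up.statistic == pytest.approx(1.0)
    down = vs.spearman_rho([1, 2, 3, 4, 5], [5, 4, 3, 2, 1])
    assert down.statistic == pytest.approx(-1.0)


def test_rho_matches_rank_then_pearson_oracle():
    """500 random tied instances against the brute-force definition."""
    rng = np.random.default_rng(7)
    for _ in range(500):
        n = int(rng.integers(4, 40))
        x = rng.integers(0, 6, size=n).astype(float)  # heavy ties
        y = x * rng.choice([-1, 1]) + rng.integers(0, 4, size=n)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            continue
        rho = vs.spearman_rho(x, y)
        rx, ry = sps.rankdata(x), sps.rankdata(y)
        brute = np.corrcoef(rx, ry)[0, 1]
        assert rho.statistic == pytest.approx(brute, abs=1e-12)
        if abs(brute) < 1.0:
            t = brute * math.sqrt((n - 2) / (1 - brute**2))
            assert rho.p_value == pytest.approx(2 * sps.t.sf(abs(t), n - 2), abs=1e-9)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    data=st.lists(
        st.tuples(st.integers(0, 30), st.integers(0, 30)), min_size=4, max_size=25
    ),
    scale=st.floats(0.1, 10.0),
)
def test_rho_invariant_under_monotone_transform(data, scale):
    x = np.array([a for a, _ in data], dtype=float)
    y = np.array([b for _, b in data], dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return
    base = vs.spearman_rho(x, y).statistic
    assert vs.spearman_rho(np.exp(scale * x / 30.0), y).statistic == pytest.approx(
        base, abs=1e-12
    )
    assert vs.spearman_rho(x, scale * y + 2.0).statistic == pytest.approx(
        base, abs=1e-12
    )


def test_constant_input_is_missing_not_zero():
    r = vs.spearman_rho([1, 1, 1, 1], [1, 2, 3, 4])
    assert r.statistic is None
    assert "undefined_constant_input" in r.flags


def test_exact_permutation_p_small_n():
    r = vs.spearman_rho([1, 2, 3, 4], [1, 2, 3, 4], exact=True)
    assert r.statistic == pytest.approx(1.0)
    assert r.p_value == pytest.approx(2 / 24)  # only the two perfect orderings
    with pytest.raises(ValueError):
        vs.spearman_rho(list(range(12)), list(range(12)), exact=True)


# -- summaries --------------------------------------------------------------

@pytest.mark.parametrize(
    "values, expected",
    [
        ([1.74], (1.74, 1.74, 1.74)),
        ([0.2, 1.74, 5.2], (1.74, 0.2, 5.2)),
        ([1, 2, 3, 4], (2.5, 1, 4)),
    ],
)
def test_median_range(values, expected):
    assert vs.median_range(values) == pytest.approx(expected)


def test_median_range_rejects_empty():
    with pytest.raises(ValueError):
        vs.median_range([])


def test_mean_sd_uses_sample_sd():
    m, s = vs.mean_sd([2.0, 4.0, 6.0])
    assert m == 4.0
    assert s == pytest.approx(2.0)
    assert vs.mean_sd([3.0]) == (3.0, 0.0)


# -- report assembly --------------------------------------------------------

def test_report_keeps_explicit_nulls(tmp_path):
    report = vs.assemble_report()
    assert set(report) == {
        "coverage", "iep_summary", "density", "profiles", "tests", "config"
    }
    assert all(v is None for v in report.values())


def test_report_round_trips_bit_exactly(tmp_path):
    density = vs.DensityEstimate(n_iep=89, tissue_volume_nm3=6.41e14)
    tests = [vs.students_t([1.0, 2.0, 3.0], [11.0, 12.0, 13.0])]
    report = vs.assemble_report(
        density=density, tests=tests, config={"seed": 1, "threshold": 4.0}
    )
    path = tmp_path / "report.json"
    report_to_json(report, path)
    assert report_from_json(path) == report


def test_density_section_prints_paper_precision():
    d = vs.DensityEstimate(n_iep=89, tissue_volume_nm3=6.41e14,
                           f_ivs=0.35, f_tv=0.39).to_dict()
    assert d["raw_label"] == "139 million per cm^3"
    assert d["adjusted_label"] == "35 million per cm^3"
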