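"""Ks distributions, peak detection, group tests, divergence metrics, PWM scan."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from duporigin.divergence import (
    compare_groups,
    detect_secondary_peak,
    expression_divergence,
    ks_distribution,
    promoter_window,
    regulation_divergence,
    scan_pwms,
)


# ---------------------------------------------------------------------------
# Ks distribution + peaks
# ---------------------------------------------------------------------------

def test_histogram_arithmetic():
    values = [0.1 * i for i in range(1, 11)]
    d = ks_distribution(values, bin_width=0.5, cap=3.0)
    assert d.counts[:2].tolist() == [5, 5]
    assert d.counts.sum() == 10


def test_values_above_cap_excluded():
    d = ks_distribution([0.5, 3.5, 4.0], cap=3.0)
    assert d.n_excluded == 2
    assert d.counts.sum() == 1
    empty = ks_distribution([5.0, 6.0], cap=3.0)
    assert empty.n_excluded == 2 and empty.counts.sum() == 0


def test_empty_input_yields_empty_distribution():
    d = ks_distribution([])
    assert d.counts.sum() == 0
    assert detect_secondary_peak(d) is None


def test_strictly_decreasing_density_has_no_secondary_peak(rng):
    values = rng.exponential(scale=0.3, size=4000)
    d = ks_distribution(values, cap=3.0)
    assert detect_secondary_peak(d, (1.5, 2.2)) is None


def test_mixture_peak_detected_near_two(rng):
    values = np.concatenate([
        rng.exponential(scale=0.5, size=3500),
        rng.normal(2.0, 0.2, size=1500),
    ])
    values = values[(values >= 0) & (values <= 3.0)]
    d = ks_distribution(values, cap=3.0)
    loc = detect_secondary_peak(d, (1.5, 2.2))
    assert loc is not None
    assert abs(loc - 2.0) < max(0.5 * d.bandwidth, 0.1) + 0.1


def test_peak_outside_search_range_is_ignored(rng):
    values = np.concatenate([
        rng.exponential(scale=0.2, size=2000),
        rng.normal(0.5, 0.05, size=2000),
    ])
    d = ks_distribution(values[values >= 0], cap=3.0)
    assert detect_secondary_peak(d, (1.5, 2.2)) is None
    with pytest.raises(ValueError):
        detect_secondary_peak(d, (2.2, 1.5))


def test_peak_location_stable_under_bin_phase(rng):
    values = np.concatenate([
        rng.exponential(scale=0.5, size=3000),
        rng.normal(2.0, 0.2, size=1200),
    ])
    values = values[(values >= 0) & (values <= 3.0)]
    locs = []
    for width in (0.04, 0.05, 0.06):
        d = ks_distribution(values, bin_width=width, cap=3.0)
        locs.append(detect_secondary_peak(d, (1.5, 2.2)))
    bw = ks_distribution(values).bandwidth
    assert max(locs) - min(locs) <= 0.5 * bw + 1e-9


# ---------------------------------------------------------------------------
# Group comparison
# ---------------------------------------------------------------------------

def test_identical_groups_t_zero_p_one():
    res = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert res.t == pytest.approx(0.0)
    assert res.p == pytest.approx(1.0)


def test_minimal_groups_finite():
    res = compare_groups([1.0, 2.0], [3.0, 5.0])
    assert np.isfinite(res.t) and np.isfinite(res.p) and res.n_a == res.n_b == 2


def test_degenerate_variance_rejected():
    with pytest.raises(ValueError, match="group b"):
        compare_groups([1.0, 2.0], [3.0, 3.0])


def permutation_p(a, b, n_perm, rng):
    pooled = np.concatenate([a, b])
    obs = abs(a.mean() - b.mean())
    hits = 0
    for _ in range(n_perm):
        rng.shuffle(pooled)
        if abs(pooled[: len(a)].mean() - pooled[len(a):].mean()) >= obs - 1e-12:
            hits += 1
    return hits / n_perm


@pytest.mark.parametrize("trial", range(5))
def test_welch_p_matches_permutation_oracle(trial):
    """Welch two-sided p agrees with a permutation test within MC error."""
    rng = np.random.default_rng(800 + trial)
    a = rng.normal(0.0, 1.0, size=30)
    b = rng.normal(0.4 * (trial % 3), 1.1, size=35)
    res = compare_groups(a, b)
    p_perm = permutation_p(a.copy(), b.copy(), 4000, rng)
    se = np.sqrt(max(p_perm * (1 - p_perm), 1e-4) / 4000)
    assert abs(res.p - p_perm) < 5 * se + 0.02


# ---------------------------------------------------------------------------
# Expression divergence
# ---------------------------------------------------------------------------

def test_expression_divergence_hand_values():
    a = [1.0, 2.0, 3.0, 4.0]
    assert expression_divergence(a, a) == pytest.approx(0.0)
    assert expression_divergence(a, [-x for x in a]) == pytest.approx(2.0)
    b = [1.0, 2.0, 3.0, 5.0]
    r = np.corrcoef(a, b)[0, 1]
    assert expression_divergence(a, b) == pytest.approx(1 - r)


def test_expression_divergence_flags_zero_variance():
    assert np.isnan(expression_divergence([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]))
    with pytest.raises(ValueError):
        expression_divergence([1.0, 2.0], [1.0, 2.0])


@given(
    st.lists(st.floats(-50, 50), min_size=4, max_size=12),
    st.floats(0.1, 5.0),
    st.floats(-10, 10),
)
@settings(max_examples=300, deadline=None)
def test_expression_divergence_affine_invariant_and_bounded(vals, slope, shift):
    a = np.asarray(vals)
    if a.std() == 0:
        return
    b = np.sin(a) + 0.5  # arbitrary second profile
    if b.std() == 0:
        return
    d = expression_divergence(a, b)
    assert -1e-9 <= d <= 2 + 1e-9
    assert expression_divergence(slope * a + shift, b) == pytest.approx(d, abs=1e-6)
    assert expression_divergence(b, a) == pytest.approx(d, abs=1e-9)


# ---------------------------------------------------------------------------
# Regulation divergence (Jaccard distance metric axioms)
# ---------------------------------------------------------------------------

def test_regulation_divergence_forced_arithmetic():
    assert regulation_divergence({"m1"}, {"m1"}) == 0.0
    assert regulation_divergence({"m1"}, {"m2"}) == 1.0
    assert regulation_divergence({"m1", "m2", "m3"}, {"m2", "m3", "m4"}) == pytest.approx(0.5)
    assert np.isnan(regulation_divergence(set(), set()))


sets = st.sets(st.integers(0, 12), max_size=8)


@given(sets, sets, sets)
@settings(max_examples=1000, deadline=None)
def test_regulation_divergence_is_a_metric(a, b, c):
    if not (a | b | c):
        return
    pairs = [(a, b), (b, c), (a, c)]
    if any(not (x | y) for x, y in pairs):
        return
    dab = regulation_divergence(a, b)
    dbc = regulation_divergence(b, c)
    dac = regulation_divergence(a, c)
    for d in (dab, dbc, dac):
        assert -1e-12 <= d <= 1 + 1e-12
    assert dab == regulation_divergence(b, a)
    assert (dab == 0) == (a == b)
    assert dac <= dab + dbc + 1e-12


# ---------------------------------------------------------------------------
# Promoter windows and PWM scanning
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "tss, strand, expected",
    [(1000, "+", (400, 1200, False)), (1000, "-", (800, 1600, False)),
     (100, "+", (0, 300, True))],
)
def test_promoter_window(tss, strand, expected):
    assert promoter_window(tss, strand) == expected


def test_promoter_window_errors():
    with pytest.raises(ValueError):
        promoter_window(None, "+")
    with pytest.raises(ValueError):
        promoter_window(100, "*")


def consensus_pwm(seq):
    m = np.full((4, len(seq)), 0.0)
    for j, c in enumerate(seq):
        m["ACGT".index(c), j] = 1.0
    return m


def test_consensus_pwm_hits_and_all_n_sequence():
    pwm = [("M1", consensus_pwm("ACGTAC"))]
    assert scan_pwms("TTTACGTACTTT", pwm) == {"M1"}
    assert scan_pwms("N" * 30, pwm) == set()
    # reverse-complement strand is scanned too
    assert scan_pwms("TTTGTACGTTTT", pwm) == {"M1"}
    with pytest.raises(ValueError):
        scan_pwms("ACGTX", pwm)


def brute_best_score(seq, lom):
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    best = -np.inf
    for s in (seq, "".join(comp[c] for c in reversed(seq))):
        for off in range(len(s) - lom.shape[1] + 1):
            score = 0.0
            for j in range(lom.shape[1]):
                c = s[off + j]
                score += lom["ACGT".index(c), j] if c != "N" else 0.0
            best = max(best, score)
    return best


@pytest.mark.parametrize("trial", range(10))
def test_pwm_best_score_matches_offset_oracle(trial):
    from duporigin.divergence import _best_score, _logodds

    rng = np.random.default_rng(300 + trial)
    seq = "".join(rng.choice(list("ACGTN"), size=30, p=[0.24, 0.24, 0.24, 0.24, 0.04]))
    m = rng.dirichlet(np.ones(4), size=8).T  # 4 x 8 column-stochastic
    lom = _logodds(m)
    got = max(_best_score(seq, lom),
              _best_score(seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1], lom))
    assert got == pytest.approx(brute_best_score(seq, lom), abs=1e-9)
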