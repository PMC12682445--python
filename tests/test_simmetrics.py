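import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import nirsim as ns
from nirsim import (
    METRICS,
    METRIC_IDS,
    ConfigurationError,
    InputError,
    PairValue,
    SpectralDataset,
    Spectrum,
    UndefinedValueError,
    WavenumberAxis,
    base_metric,
    combined_metric,
    hd_metric,
    metric_value,
    normalize_batch,
    pairwise_matrix,
    sid,
)

# ---------------------------------------------------------------------------
# naive oracles: direct double-loop transcriptions of the metric formulas,
# independent of the package implementation
# ---------------------------------------------------------------------------

EPS = 1e-12


def naive_prob(x):
    shifted = [v - min(x) + EPS for v in x]
    total = sum(shifted)
    return [v / total for v in shifted]


def naive_kl(p, q):
    return sum(pi * math.log(pi / qi) for pi, qi in zip(p, q))


def naive_metric(mid, x, y, m=None):
    n = len(x)
    if mid == "pearson":
        mx, my = sum(x) / n, sum(y) / n
        num = sum((a - mx) * (b - my) for a, b in zip(x, y))
        den = math.sqrt(
            sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y)
        )
        return num / den
    if mid == "euclidean":
        return math.sqrt(sum((a - b) ** 2 for a, b in zip(x, y)))
    if mid == "sam":
        num = sum(a * b for a, b in zip(x, y))
        den = math.sqrt(sum(a * a for a in x) * sum(b * b for b in y))
        return num / den
    if mid == "manhattan":
        return sum(abs(a - b) for a, b in zip(x, y))
    if mid == "sid":
        p, q = naive_prob(x), naive_prob(y)
        return naive_kl(p, q) + naive_kl(q, p)
    if mid == "ed_cod":
        return (1 - naive_metric("pearson", x, y)) * naive_metric("euclidean", x, y)
    if mid == "ss_cs":
        return (
            naive_metric("sid", x, y)
            * naive_metric("euclidean", x, y)
            * (1 - naive_metric("pearson", x, y))
        )
    if mid == "hsim":
        return sum(1.0 / (1.0 + abs(a - b)) for a, b in zip(x, y)) / n
    if mid == "close":
        return sum(math.exp(-abs(a - b)) for a, b in zip(x, y)) / n
    if mid == "gsim":
        return sum(
            1.0 - abs(a - b) / (abs(a - b) + mi) for a, b, mi in zip(x, y, m)
        ) / n
    if mid == "esim":
        total = 0.0
        for a, b in zip(x, y):
            d, s = abs(a - b), abs(a + b)
            ratio = 0.0 if d + s == 0.0 else d / (d + s)
            total += (1.0 / n) * math.exp(ratio / 2.0)
        return total
    raise AssertionError(mid)


def call_metric(mid, x, y, m=None):
    if mid in ("hsim", "close", "gsim", "esim"):
        return hd_metric(mid, x, y, m=m)
    return metric_value(mid, x, y)


vectors = arrays(
    np.float64,
    st.shared(st.integers(2, 10), key="len"),
    elements=st.floats(-50, 50, allow_nan=False, width=64),
)


# ---------------------------------------------------------------------------
# metric axioms and oracle equivalence
# ---------------------------------------------------------------------------

class TestAxioms:
    @pytest.mark.parametrize("mid", METRIC_IDS)
    def test_symmetry(self, mid, rng):
        for _ in range(5):
            x = rng.normal(size=8)
            y = rng.normal(size=8)
            m = rng.uniform(0.5, 2.0, size=8)
            assert call_metric(mid, x, y, m) == pytest.approx(
                call_metric(mid, y, x, m), abs=1e-12
            )

    @pytest.mark.parametrize(
        "mid,expected",
        [
            ("pearson", 1.0),
            ("sam", 1.0),
            ("euclidean", 0.0),
            ("manhattan", 0.0),
            ("sid", 0.0),
            ("ed_cod", 0.0),
            ("ss_cs", 0.0),
            ("hsim", 1.0),
            ("close", 1.0),
            ("gsim", 1.0),
            ("esim", 1.0),
        ],
    )
    def test_identity_values(self, mid, expected, rng):
        x = rng.normal(size=9)
        m = rng.uniform(0.5, 2.0, size=9)
        assert call_metric(mid, x, x.copy(), m) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("mid", METRIC_IDS)
    def test_matches_naive_oracle(self, mid, rng):
        for _ in range(10):
            n = int(rng.integers(2, 11))
            x = rng.normal(scale=5.0, size=n)
            y = rng.normal(scale=5.0, size=n)
            m = rng.uniform(0.5, 2.0, size=n)
            got = call_metric(mid, x, y, m)
            want = naive_metric(mid, list(x), list(y), list(m))
            assert got == pytest.approx(want, abs=1e-12, rel=1e-12)

    @settings(deadline=None, max_examples=60)
    @given(x=vectors, c=st.floats(1e-3, 1e3))
    def test_sam_scale_invariance(self, x, c):
        if np.linalg.norm(x) < 1e-6:
            return  # zero (or numerically zero) vectors are outside SAM's domain
        assert base_metric("sam", x, c * x) == pytest.approx(1.0, abs=1e-9)


class TestExamples:
    def test_pearson_extremes(self):
        assert base_metric("pearson", [1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)
        assert base_metric("pearson", [1, 2, 4], [1, 2, 4]) == pytest.approx(1.0)

    def test_three_four_five_triangle(self):
        assert base_metric("euclidean", [0, 0], [3, 4]) == pytest.approx(5.0)
        assert base_metric("manhattan", [0, 0], [3, 4]) == pytest.approx(7.0)

    def test_sam_orthogonal(self):
        assert base_metric("sam", [1, 0], [0, 1]) == pytest.approx(0.0)

    def test_close_single_term(self):
        assert hd_metric("close", [0.0], [1.0]) == pytest.approx(math.exp(-1))

    def test_hsim_hand_value(self):
        assert hd_metric("hsim", [0, 0], [1, 3]) == pytest.approx(0.375)

    def test_sid_symmetric_and_zero_on_self(self, rng):
        x = rng.normal(size=12)
        assert sid(x, x) == pytest.approx(0.0, abs=1e-12)
        assert sid([1, 2, 3], [3, 2, 1]) == pytest.approx(sid([3, 2, 1], [1, 2, 3]))

    def test_sid_against_double_loop_kl(self):
        x = [0.5 + 1e-3, 0.5 - 1e-3, 0.25, 0.25]
        y = [0.375] * 4
        p, q = naive_prob(x), naive_prob(y)
        assert sid(x, y) == pytest.approx(naive_kl(p, q) + naive_kl(q, p), abs=1e-12)

    def test_combined_composition(self, rng):
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        expected = (
            sid(x, y)
            * base_metric("euclidean", x, y)
            * (1 - base_metric("pearson", x, y))
        )
        assert combined_metric("ss_cs", x, y) == pytest.approx(expected, abs=1e-12)
        assert combined_metric("ed_cod", x, y) == pytest.approx(
            (1 - base_metric("pearson", x, y)) * base_metric("euclidean", x, y),
            abs=1e-12,
        )


class TestErrors:
    def test_length_mismatch(self):
        with pytest.raises(InputError):
            base_metric("euclidean", [1, 2], [1, 2, 3])

    def test_pearson_constant_vector(self):
        with pytest.raises(UndefinedValueError):
            base_metric("pearson", [2.0, 2.0, 2.0], [1.0, 2.0, 3.0])

    def test_sam_zero_vector(self):
        with pytest.raises(UndefinedValueError):
            base_metric("sam", [0.0, 0.0], [1.0, 2.0])

    def test_ed_cod_propagates_pearson_precondition(self):
        with pytest.raises(UndefinedValueError):
            combined_metric("ed_cod", [0.0, 0.0], [3.0, 4.0])

    def test_gsim_needs_context_or_scale(self):
        with pytest.raises(ConfigurationError):
            hd_metric("gsim", [1.0, 2.0], [2.0, 3.0])


# ---------------------------------------------------------------------------
# batch normalization and the pairwise matrix
# ---------------------------------------------------------------------------

def make_pairs(raws):
    return [PairValue(f"a{i}", f"b{i}", r) for i, r in enumerate(raws)]


class TestNormalizeBatch:
    def test_dissimilarity_reversal(self):
        out = normalize_batch(make_pairs([0.0, 5.0, 10.0]), METRICS["euclidean"])
        assert [p.normalized for p in out] == [1.0, 0.5, 0.0]

    def test_similarity_minmax(self):
        out = normalize_batch(make_pairs([-1.0, 0.0, 1.0]), METRICS["pearson"])
        assert [p.normalized for p in out] == [0.0, 0.5, 1.0]

    def test_native_unit_interval_passthrough(self):
        out = normalize_batch(make_pairs([0.4, 0.9]), METRICS["hsim"])
        assert [p.normalized for p in out] == [0.4, 0.9]

    def test_degenerate_batch_maps_to_one(self):
        out = normalize_batch(make_pairs([3.0, 3.0]), METRICS["euclidean"])
        assert [p.normalized for p in out] == [1.0, 1.0]

    def test_empty_batch_rejected(self):
        with pytest.raises(InputError):
            normalize_batch([], METRICS["euclidean"])

    @pytest.mark.parametrize("mid", METRIC_IDS)
    def test_outputs_in_unit_interval(self, mid, rng):
        raws = (
            rng.uniform(0.01, 1.0, size=12)
            if METRICS[mid].native_unit_interval
            else rng.normal(size=12)
        )
        out = normalize_batch(make_pairs(raws), METRICS[mid])
        for p in out:
            assert 0.0 <= p.normalized <= 1.0


def toy_dataset(rows, ids=None):
    rows = np.asarray(rows, dtype=float)
    axis = WavenumberAxis(np.arange(rows.shape[1], dtype=float)[::-1])
    ids = ids or [f"s{i:02d}" for i in range(rows.shape[0])]
    return SpectralDataset(axis, [Spectrum(i, r) for i, r in zip(ids, rows)])


class TestPairwiseMatrix:
    def test_two_samples_one_pair(self, rng):
        ds = toy_dataset(rng.normal(size=(2, 6)))
        pairs = pairwise_matrix(ds, "euclidean")
        assert len(pairs) == 1
        assert (pairs[0].id_a, pairs[0].id_b) == ("s00", "s01")

    def test_pair_count_is_n_choose_2(self, rng):
        ds = toy_dataset(rng.normal(size=(9, 6)))
        assert len(pairwise_matrix(ds, "manhattan")) == 36

    @pytest.mark.parametrize("mid", METRIC_IDS)
    def test_matches_scalar_double_loop(self, mid, rng):
        ds = toy_dataset(rng.normal(size=(6, 8)))
        pairs = {(p.id_a, p.id_b): p.raw for p in pairwise_matrix(ds, mid)}
        ids = ds.sample_ids
        X = ds.values_matrix()
        for i in range(6):
            for j in range(i + 1, 6):
                want = metric_value(mid, X[i], X[j], context=ds)
                assert pairs[(ids[i], ids[j])] == pytest.approx(
                    want, abs=1e-12, rel=1e-12
                )

    @pytest.mark.parametrize("mid", METRIC_IDS)
    def test_identical_pair_is_batch_extreme(self, mid, rng):
        x = rng.normal(size=7)
        ds = toy_dataset([x, x.copy(), rng.normal(size=7), rng.normal(size=7)])
        pairs = pairwise_matrix(ds, mid)
        value = {(p.id_a, p.id_b): p.normalized for p in pairs}[("s00", "s01")]
        assert value == pytest.approx(1.0, abs=1e-12)

    def test_pearson_error_names_pair(self):
        ds = toy_dataset([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]], ids=["flat", "ramp"])
        with pytest.raises(UndefinedValueError, match="flat"):
            pairwise_matrix(ds, "pearson")
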