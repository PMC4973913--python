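import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from surfaceome import (
    ObservabilityParams,
    RtModel,
    count_observable,
    digest,
    estimate_rt_limits,
    gravy,
    params_from_ini,
)
from surfaceome.digest import NO_FILTERS, cleavage_sites

AA = "ACDEFGHIKLMNPQRSTVWY"
seqs = st.text(alphabet=AA, min_size=1, max_size=200)


def brute_force_observable(sequence, params, distinct=True):
    """Independent oracle: enumerate fragment runs between cleavage sites."""
    sites = [
        i
        for i in range(len(sequence) - 1)
        if sequence[i] in "KR" and not (params.proline_rule and sequence[i + 1] == "P")
    ]
    bounds = [0] + [s + 1 for s in sites] + [len(sequence)]
    frags = [sequence[bounds[i]: bounds[i + 1]] for i in range(len(bounds) - 1)]
    products = []
    for i in range(len(frags)):
        for j in range(i, min(i + params.max_missed_cleavages + 1, len(frags))):
            products.append("".join(frags[i: j + 1]))
    if distinct:
        products = set(products)
    return sum(1 for p in products if params.passes(p))


class TestDigest:
    def test_simple_two_fragments(self):
        assert [p.sequence for p in digest("AAAAAAKCCCCCCR", 0)] == [
            "AAAAAAK",
            "CCCCCCR",
        ]

    def test_proline_suppresses_cleavage(self):
        assert [p.sequence for p in digest("AAAKPAAAR", 0)] == ["AAAKPAAAR"]

    def test_proline_rule_can_be_disabled(self):
        assert [p.sequence for p in digest("AAAKPAAAR", 0, proline_rule=False)] == [
            "AAAK",
            "PAAAR",
        ]

    def test_no_cleavage_sites_returns_sequence(self):
        assert [p.sequence for p in digest("ACDEFGHILM", 2)] == ["ACDEFGHILM"]

    def test_empty_sequence_errors(self):
        with pytest.raises(ValueError):
            digest("", 0)

    def test_terminal_kr_does_not_split(self):
        # cleavage after the final residue produces no extra fragment
        assert [p.sequence for p in digest("AAAK", 0)] == ["AAAK"]

    def test_positions_and_missed_counts(self):
        prods = digest("AAKCCKDD", 1)
        by_seq = {p.sequence: p for p in prods}
        assert by_seq["AAK"].start == 0 and by_seq["AAK"].missed_cleavages == 0
        assert by_seq["AAKCCK"].missed_cleavages == 1
        assert by_seq["CCKDD"].start == 3

    @given(seqs)
    @settings(deadline=None, max_examples=100)
    def test_mc0_products_partition_the_sequence(self, seq):
        prods = [p.sequence for p in digest(seq, 0)]
        assert "".join(prods) == seq

    @given(seqs, st.integers(0, 3))
    @settings(deadline=None, max_examples=100)
    def test_closed_form_product_count_without_proline_rule(self, seq, mc):
        c = len(cleavage_sites(seq, proline_rule=False))
        expected = sum(max(c + 1 - m, 0) for m in range(mc + 1))
        assert len(digest(seq, mc, proline_rule=False)) == expected

    @given(seqs, st.integers(0, 2))
    @settings(deadline=None, max_examples=100)
    def test_matches_pyteomics_cleave(self, seq, mc):
        parser = pytest.importorskip("pyteomics.parser")
        ours = {p.sequence for p in digest(seq, mc)}
        theirs = parser.cleave(seq, r"[KR](?!P)", mc)
        assert ours == set(theirs)


class TestCountObservable:
    def test_default_filters_example(self):
        # two length-7 products plus the length-14 missed-cleavage product
        assert count_observable("AAAAAAKCCCCCCR") == 3

    def test_too_short_protein_has_zero(self):
        assert count_observable("AAAK") == 0

    def test_filters_off_counts_mc0_fragments(self):
        params = ObservabilityParams(
            min_length=1, max_length=10 ** 9, max_missed_cleavages=0
        )
        seq = "AAKCCRDDKEE"
        assert count_observable(seq, params) == len(digest(seq, 0))

    def test_duplicate_peptides_counted_once(self):
        params = ObservabilityParams(min_length=1, max_length=99, max_missed_cleavages=0)
        assert count_observable("AAKAAK", params) == 1  # 'AAK' occurs twice
        assert count_observable("AAKAAK", params, distinct=False) == 2

    @given(seqs)
    @settings(deadline=None, max_examples=100)
    def test_equals_brute_force_on_random_sequences(self, seq):
        for params in (ObservabilityParams(), NO_FILTERS,
                       ObservabilityParams(gravy_range=(-2, 2), charge_range=(1, 3))):
            assert count_observable(seq, params) == brute_force_observable(seq, params)

    @given(seqs)
    @settings(deadline=None, max_examples=50)
    def test_monotone_under_tightening_filters(self, seq):
        loose = ObservabilityParams(min_length=4, max_length=50, max_missed_cleavages=2)
        tighter = [
            ObservabilityParams(min_length=6, max_length=50, max_missed_cleavages=2),
            ObservabilityParams(min_length=4, max_length=30, max_missed_cleavages=2),
            ObservabilityParams(min_length=4, max_length=50, max_missed_cleavages=1),
            ObservabilityParams(
                min_length=4, max_length=50, max_missed_cleavages=2, gravy_range=(-1, 1)
            ),
            ObservabilityParams(
                min_length=4, max_length=50, max_missed_cleavages=2, charge_range=(1, 2)
            ),
        ]
        base = count_observable(seq, loose)
        for p in tighter:
            assert count_observable(seq, p) <= base


class TestRtLimits:
    def test_perfect_fit_recovers_gravy_percentiles(self):
        rng = np.random.default_rng(0)
        peps = ["".join(rng.choice(list(AA), 10)) for _ in range(200)]
        table = [(p, gravy(p)) for p in peps]
        (lo, hi), model = estimate_rt_limits(table)
        g = np.array([gravy(p) for p in peps])
        assert lo == pytest.approx(np.quantile(g, 0.01), abs=1e-9)
        assert hi == pytest.approx(np.quantile(g, 0.99), abs=1e-9)
        assert model.slope == pytest.approx(1.0)

    def test_constant_rt_warns_degenerate(self):
        table = [(p, 5.0) for p in ["AAAAAA", "CCCCCC", "DDDDDD", "KKKKKK"] * 3]
        with pytest.warns(UserWarning, match="constant"):
            (lo, hi), _ = estimate_rt_limits(table)
        assert lo == hi == 5.0

    def test_noisy_linear_rt_recovered_within_2_percent(self):
        rng = np.random.default_rng(1)
        peps = ["".join(rng.choice(list(AA), 12)) for _ in range(1000)]
        g = np.array([gravy(p) for p in peps])
        rt = 40.0 + 10.0 * g + rng.normal(0, 0.5, len(g))
        (lo, hi), model = estimate_rt_limits(list(zip(peps, rt)))
        true_pred = 40.0 + 10.0 * g
        span = np.quantile(true_pred, 0.99) - np.quantile(true_pred, 0.01)
        assert lo == pytest.approx(np.quantile(true_pred, 0.01), abs=0.02 * span)
        assert hi == pytest.approx(np.quantile(true_pred, 0.99), abs=0.02 * span)
        assert model.slope == pytest.approx(10.0, rel=0.05)

    def test_too_few_observations_error(self):
        with pytest.raises(ValueError, match="at least 10"):
            estimate_rt_limits([("AAAAAA", 1.0)] * 9)


class TestSettingsIni:
    def test_round_trip_of_all_sections(self, tmp_path):
        ini = tmp_path / "settings.ini"
        ini.write_text(
            "[length]\nmin = 7\nmax = 30\n"
            "[cleavage]\nmax_missed = 1\nproline_rule = no\n"
            "[gravy]\nmin = -1.5\nmax = 1.5\n"
            "[charge]\nmin = 1\nmax = 4\n"
            "[rt]\nmin = 10\nmax = 90\nintercept = 40\nslope = 10\n"
        )
        p = params_from_ini(ini)
        assert (p.min_length, p.max_length) == (7, 30)
        assert p.max_missed_cleavages == 1 and p.proline_rule is False
        assert p.gravy_range == (-1.5, 1.5)
        assert p.charge_range == (1, 4)
        assert p.rt_range == (10, 90)
        assert p.rt_model == RtModel(40.0, 10.0)

    def test_missing_file_errors(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            params_from_ini(tmp_path / "nope.ini")

    def test_invalid_length_order_rejected(self):
        with pytest.raises(ValueError):
            ObservabilityParams(min_length=10, max_length=5)
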