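"""Spearman matrix, background median, relatedness cells, binomial test,
centrality, coordination call and the table rendering."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from photocoord.coordination import (
    CorrelationMatrix,
    background_median,
    binomial_coordination_test,
    call_coordination,
    centrality,
    coordination_percentage,
    group_relatedness,
    groups_from_annotations,
    parse_table1,
    spearman_matrix,
    table1_report,
)
from photocoord.types import ExpressionMatrix, TranscriptAnnotation


def _expr(rows: dict[str, list[float]]):
    n = len(next(iter(rows.values())))
    cols = [f"s{i}" for i in range(n)]
    site_of = {c: ("JH" if i < n // 2 else "QG") for i, c in enumerate(cols)}
    return ExpressionMatrix(pd.DataFrame(rows, index=cols).T, site_of)


class TestSpearman:
    def test_monotone_transform_gives_one(self):
        x = [0.1, 0.7, 1.3, 2.0, 3.5, 4.0]
        corr = spearman_matrix(_expr({"a": x, "b": list(np.exp(x))}))
        assert corr.pair_rho("a", "b") == pytest.approx(1.0)

    def test_reversal_gives_minus_one(self):
        x = [1.0, 2, 3, 4, 5, 6]
        corr = spearman_matrix(_expr({"a": x, "b": x[::-1]}))
        assert corr.pair_rho("a", "b") == pytest.approx(-1.0)

    def test_ties_match_rank_pearson_oracle(self):
        x = [1.0, 2, 2, 3, 4, 4]
        y = [2.0, 1, 3, 3, 5, 4]
        corr = spearman_matrix(_expr({"a": x, "b": y}))
        rx, ry = stats.rankdata(x), stats.rankdata(y)
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert corr.pair_rho("a", "b") == pytest.approx(oracle, abs=1e-12)

    def test_matches_scipy_on_random_tied_data(self):
        rng = np.random.default_rng(0)
        data = {f"t{i}": list(rng.integers(0, 6, 12).astype(float)) for i in range(6)}
        expr = _expr(data)
        corr = spearman_matrix(expr)
        ref = stats.spearmanr(expr.values.to_numpy(), axis=1).statistic
        np.testing.assert_allclose(corr.rho, ref, atol=1e-12)

    def test_constant_transcript_recorded_missing(self):
        corr = spearman_matrix(
            _expr({"a": [1.0, 2, 3, 4], "c": [5.0, 5, 5, 5], "b": [2.0, 1, 4, 3]})
        )
        assert corr.n_constant == 1
        assert math.isnan(corr.pair_rho("a", "c"))
        assert corr.pair_rho("c", "c") == 1.0  # diagonal stays defined
        b, signed = background_median(corr)  # excludes missing pairs
        assert b == pytest.approx(abs(corr.pair_rho("a", "b")))


def _corr_from_rhos(pair_rhos: dict[tuple[str, str], float], ids):
    n = len(ids)
    rho = np.eye(n)
    idx = {t: i for i, t in enumerate(ids)}
    for (a, b), r in pair_rhos.items():
        rho[idx[a], idx[b]] = rho[idx[b], idx[a]] = r
    return CorrelationMatrix(list(ids), rho)


class TestBackground:
    def test_three_transcript_median(self):
        corr = _corr_from_rhos(
            {("a", "b"): 0.5, ("a", "c"): -0.5, ("b", "c"): 0.1}, ["a", "b", "c"]
        )
        b, signed = background_median(corr)
        assert b == 0.5 and signed == 0.1

    def test_identical_rhos(self):
        corr = _corr_from_rhos(
            {("a", "b"): -0.3, ("a", "c"): -0.3, ("b", "c"): -0.3}, ["a", "b", "c"]
        )
        b, signed = background_median(corr)
        assert b == pytest.approx(0.3) and signed == pytest.approx(-0.3)

    def test_two_transcripts(self):
        corr = _corr_from_rhos({("a", "b"): -0.7}, ["a", "b"])
        assert background_median(corr)[0] == pytest.approx(0.7)


class TestBinomialTest:
    def test_all_exceed(self):
        assert binomial_coordination_test(10, 10) == pytest.approx(0.5 ** 10)

    def test_partial_tail_sum(self):
        assert binomial_coordination_test(10, 7) == pytest.approx(176 / 1024)

    def test_none_exceed(self):
        assert binomial_coordination_test(10, 0) == 1.0

    def test_bad_input(self):
        with pytest.raises(ValueError):
            binomial_coordination_test(0, 0)
        with pytest.raises(ValueError):
            binomial_coordination_test(5, 6)


class TestGroupRelatedness:
    def test_singleton_groups_between_cell(self):
        corr = _corr_from_rhos(
            {("a", "b"): -0.4, ("a", "c"): 0.2, ("b", "c"): 0.1}, ["a", "b", "c"]
        )
        report = group_relatedness(corr, {"G1": ["a"], "G2": ["b"], "G3": ["c"]})
        cell = report.cell("G1", "G2")
        assert cell.n_pairs == 1
        assert cell.mean_abs_rho == pytest.approx(0.4)

    def test_within_cell_matches_loop_oracle(self):
        rng = np.random.default_rng(1)
        ids = [f"t{i}" for i in range(8)]
        pair_rhos = {}
        for i in range(8):
            for j in range(i + 1, 8):
                pair_rhos[(ids[i], ids[j])] = float(rng.uniform(-1, 1))
        corr = _corr_from_rhos(pair_rhos, ids)
        groups = {"A": ids[:5], "B": ids[5:]}
        report = group_relatedness(corr, groups)
        within = report.cell("A", "A")
        assert within.n_pairs == 10  # 5*4/2
        vals = [abs(pair_rhos[(ids[i], ids[j])]) for i in range(5) for j in range(i + 1, 5)]
        assert within.mean_abs_rho == pytest.approx(np.mean(vals))
        assert within.n_exceeding == sum(v > report.background for v in vals)
        between = report.cell("A", "B")
        assert between.n_pairs == 5 * 3

    def test_study_sized_groups_pair_counts(self):
        rng = np.random.default_rng(2)
        ids = [f"c4_{i}" for i in range(5)] + [f"cal_{i}" for i in range(18)]
        pair_rhos = {}
        for i in range(23):
            for j in range(i + 1, 23):
                pair_rhos[(ids[i], ids[j])] = float(rng.uniform(-1, 1))
        corr = _corr_from_rhos(pair_rhos, ids)
        report = group_relatedness(corr, {"C4": ids[:5], "Calvin": ids[5:]})
        assert report.cell("C4", "Calvin").n_pairs == 5 * 18  # 90 cross pairs
        assert report.cell("C4", "C4").n_pairs == 10
        assert report.cell("Calvin", "Calvin").n_pairs == 18 * 17 // 2

    def test_overlapping_groups_rejected(self):
        corr = _corr_from_rhos({("a", "b"): 0.1}, ["a", "b"])
        with pytest.raises(ValueError):
            group_relatedness(corr, {"A": ["a"], "B": ["a", "b"]})


class TestCentrality:
    def test_perfect_correlation_gives_one(self):
        corr = _corr_from_rhos(
            {("a", "b"): 1.0, ("a", "c"): 1.0, ("b", "c"): 1.0}, ["a", "b", "c"]
        )
        assert centrality(corr)["a"] == pytest.approx(1.0)

    def test_matches_row_mean_oracle(self):
        rng = np.random.default_rng(3)
        ids = [f"t{i}" for i in range(5)]
        pair_rhos = {
            (ids[i], ids[j]): float(rng.uniform(-1, 1))
            for i in range(5) for j in range(i + 1, 5)
        }
        corr = _corr_from_rhos(pair_rhos, ids)
        cent = centrality(corr)
        for t in ids:
            vals = [abs(r) for (a, b), r in pair_rhos.items() if t in (a, b)]
            assert cent[t] == pytest.approx(np.mean(vals))
        assert list(cent.values) == sorted(cent.values, reverse=True)


class TestCoordinationCall:
    def _report(self, p_within: dict[str, float], groups):
        """Relatedness report with prescribed within-group p-values and
        non-significant between cells."""
        from photocoord.coordination import RelatednessCell, RelatednessReport

        report = RelatednessReport(groups=groups, background=0.2, signed_median=0.1)
        names = list(groups)
        for i, a in enumerate(names):
            for b in names[i:]:
                if a == b:
                    p = p_within[a]
                else:
                    p = 0.9
                report.cells[(a, b)] = RelatednessCell(a, b, 10, 0.3, 5, p)
        return report

    def test_percentage_arithmetic(self):
        assert round(coordination_percentage(61, 2, 78), 1) == 80.8

    def test_within_significant_group_is_coordinated(self):
        groups = {"A": ["a1", "a2"], "B": ["b1", "b2", "b3"]}
        report = self._report({"A": 0.01, "B": 0.5}, groups)
        call = call_coordination(report, [], None)
        assert call.coordinated_groups == {"A"}
        assert call.coordinated_transcripts == {"a1", "a2"}
        assert call.percentage == pytest.approx(100 * 2 / 5)

    def test_between_significance_also_coordinates(self):
        from photocoord.coordination import RelatednessCell, RelatednessReport

        groups = {"A": ["a1"], "B": ["b1"]}
        report = RelatednessReport(groups=groups, background=0.2, signed_median=0.0)
        report.cells[("A", "A")] = RelatednessCell("A", "A", 0, math.nan, 0, math.nan)
        report.cells[("B", "B")] = RelatednessCell("B", "B", 0, math.nan, 0, math.nan)
        report.cells[("A", "B")] = RelatednessCell("A", "B", 10, 0.5, 9, 0.01)
        call = call_coordination(report, [], None)
        assert call.coordinated_groups == {"A", "B"}

    def test_chloroplast_transcripts_join_via_common_branch(self):
        groups = {"A": ["a1", "a2"], "B": ["b1", "b2"]}
        report = self._report({"A": 0.01, "B": 0.5}, groups)
        ann = [
            TranscriptAnnotation("b1", compartment="chloroplast", functional_group="Psb"),
            TranscriptAnnotation("b2", compartment="chloroplast", functional_group="Psb"),
        ]
        branches = {"a1": 1, "a2": 1, "b1": 2, "b2": 2}
        call = call_coordination(report, ann, branches)
        assert call.extra_chloroplast_members == {"b1", "b2"}
        assert call.percentage == 100.0
        # split across branches -> not added
        call2 = call_coordination(report, ann, {"a1": 1, "a2": 1, "b1": 2, "b2": 3})
        assert call2.extra_chloroplast_members == set()

    def test_invariant_to_group_enumeration_order(self):
        groups = {"A": ["a1", "a2"], "B": ["b1"], "C": ["c1"]}
        p = {"A": 0.01, "B": 0.9, "C": 0.02}
        r1 = self._report(p, groups)
        r2 = self._report(p, dict(reversed(list(groups.items()))))
        c1 = call_coordination(r1, [], None)
        c2 = call_coordination(r2, [], None)
        assert c1.coordinated_groups == c2.coordinated_groups
        assert c1.percentage == c2.percentage

    def test_power_on_planted_factor_group(self):
        """lambda = 1, sigma = 0.5, 39+39 samples: detected in >= 95% of seeds."""
        from photocoord.simulate import (
            PopulationSimConfig, simulate_population_expression,
        )

        detected = 0
        n_seeds = 20
        for seed in range(n_seeds):
            tr = pd.DataFrame({
                "transcript_id": [f"g{i}" for i in range(20)],
                "group": ["Psa"] * 5 + [f"bg{i}" for i in range(15)],
                "base_log2": [6.0] * 20,
                "shift_log2": [0.0] * 20,
                "loading": [1.0] * 5 + [0.0] * 15,
            })
            expr, _ = simulate_population_expression(
                PopulationSimConfig(tr, n_samples_per_site=39, noise_sd=0.5, seed=seed)
            )
            corr = spearman_matrix(expr)
            groups = {"Psa": [f"g{i}" for i in range(5)],
                      "rest": [f"g{i}" for i in range(5, 20)]}
            report = group_relatedness(corr, groups)
            call = call_coordination(report, [], None)
            detected += "Psa" in call.coordinated_groups
        assert detected >= 0.95 * n_seeds


class TestTableRendering:
    def _small_report(self):
        rng = np.random.default_rng(5)
        ids = [f"t{i}" for i in range(6)]
        pair_rhos = {
            (ids[i], ids[j]): float(rng.uniform(-1, 1))
            for i in range(6) for j in range(i + 1, 6)
        }
        corr = _corr_from_rhos(pair_rhos, ids)
        return group_relatedness(corr, {"A": ids[:2], "B": ids[2:4], "C": ids[4:]})

    def test_star_thresholds(self):
        from photocoord.coordination import RelatednessCell

        assert RelatednessCell("a", "b", 10, 0.5, 9, 0.0075).stars == "**"
        assert RelatednessCell("a", "b", 10, 0.5, 9, 0.05).stars == ""
        assert RelatednessCell("a", "b", 10, 0.5, 9, 0.0009).stars == "***"
        assert RelatednessCell("a", "b", 10, 0.5, 9, 0.049).stars == "*"

    def test_round_trip(self):
        report = self._small_report()
        text = table1_report(report)
        names, means, ps = parse_table1(text)
        assert names == ["A", "B", "C"]
        for i, a in enumerate(names):
            for j, b in enumerate(names):
                cell = report.cell(a, b)
                if j >= i:
                    assert means[i, j] == pytest.approx(cell.mean_abs_rho, abs=5e-3)
                else:
                    assert ps[i, j] == pytest.approx(cell.p_value, abs=5e-5)


class TestGroupsFromAnnotations:
    def test_other_excluded(self):
        ann = [
            TranscriptAnnotation("a", functional_group="Psa"),
            TranscriptAnnotation("b", functional_group="other"),
            TranscriptAnnotation("c", reaction_class="dark", functional_group="C4"),
        ]
        groups = groups_from_annotations(ann)
        assert groups == {"Psa": ["a"], "C4": ["c"]}
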