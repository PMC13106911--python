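"""Quantitation: centering, SVD imputation, MaxLFQ, digestion, iBAQ."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from _oracles import digest_count_oracle, maxlfq_oracle, random_maxlfq_instance
from scprot import (
    FormatError,
    ParameterError,
    PipelineError,
    PrecursorMatrix,
    ProteinAnnotation,
    compute_ibaq,
    digest_tryptic,
    maxlfq,
    median_center_rows,
    summarize_all_proteins,
    svd_impute,
    theoretical_tryptic_peptides,
)


def frame(arr, prefix="p"):
    arr = np.asarray(arr, dtype=float)
    return pd.DataFrame(
        arr,
        index=[f"{prefix}{i}/2" for i in range(arr.shape[0])],
        columns=[f"c{j}" for j in range(arr.shape[1])],
    )


class TestMedianCenter:
    def test_odd_row_and_missing(self):
        out = median_center_rows(frame([[4.0, 6.0, 8.0], [4.0, np.nan, 8.0]]))
        assert out.iloc[0].tolist() == [-2.0, 0.0, 2.0]
        assert out.iloc[1, 0] == -2.0 and np.isnan(out.iloc[1, 1]) and out.iloc[1, 2] == 2.0

    def test_idempotent(self, rng):
        values = frame(rng.normal(10, 3, (20, 8)))
        values[values > 12] = np.nan
        values = values.dropna(how="all")
        once = median_center_rows(values)
        twice = median_center_rows(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_all_missing_row_rejected(self):
        with pytest.raises(PipelineError):
            median_center_rows(frame([[1.0, 2.0], [np.nan, np.nan]]))


class TestSvdImpute:
    def test_complete_matrix_unchanged(self, rng):
        values = frame(rng.normal(size=(10, 6)))
        result = svd_impute(values, n_components=2)
        pd.testing.assert_frame_equal(result.values, values)
        assert result.converged and result.n_iter == 0

    def test_rank1_noiseless_recovery(self, rng):
        u = rng.normal(1.0, 0.3, 20)
        v = rng.normal(2.0, 0.5, 10)
        truth = np.outer(u, v)
        masked = truth.copy()
        holes = rng.random(truth.shape) < 0.10
        holes[:, holes.all(axis=0)] = False  # keep every column partly observed
        masked[holes] = np.nan
        result = svd_impute(frame(masked), n_components=1, tol=1e-9, max_iter=1000)
        rmse = np.sqrt(np.mean((result.values.to_numpy()[holes] - truth[holes]) ** 2))
        assert rmse < 1e-6
        # observed entries never modified
        assert np.array_equal(
            result.values.to_numpy()[~holes], masked[~holes]
        )

    def test_single_missing_entry_closed_form(self):
        u = np.array([1.0, 2.0, 3.0])
        v = np.array([4.0, 5.0, 6.0])
        truth = np.outer(u, v)
        masked = truth.copy()
        masked[1, 2] = np.nan
        result = svd_impute(frame(masked), n_components=1, tol=1e-10, max_iter=2000)
        assert result.values.iloc[1, 2] == pytest.approx(u[1] * v[2], abs=1e-6)

    def test_rank3_noisy_rmse_below_data_sd(self, rng):
        n, m, k = 60, 30, 3
        signal = rng.normal(size=(n, k)) @ rng.normal(size=(k, m))
        noise = rng.normal(0, signal.std() / np.sqrt(10), (n, m))  # SNR 10
        truth = signal + noise
        masked = truth.copy()
        holes = rng.random((n, m)) < 0.2
        masked[holes] = np.nan
        result = svd_impute(frame(masked), n_components=3)
        rmse = np.sqrt(np.mean((result.values.to_numpy()[holes] - truth[holes]) ** 2))
        assert rmse < truth.std()

    def test_parameter_validation(self):
        values = frame(np.ones((4, 3)))
        with pytest.raises(ParameterError, match="n_components"):
            svd_impute(values, n_components=3)
        empty_col = frame([[1.0, np.nan], [2.0, np.nan]])
        with pytest.raises(ParameterError, match="observed"):
            svd_impute(empty_col, n_components=1)


class TestMaxLFQ:
    def test_single_precursor_identity(self):
        np.testing.assert_allclose(maxlfq(np.array([[10.0, 12.0]])), [10.0, 12.0])

    def test_two_precursor_worked_example(self):
        x = np.array([[10.0, 12.0, 11.0], [13.0, 15.0, 14.0]])
        np.testing.assert_allclose(maxlfq(x), [11.5, 13.5, 12.5], atol=1e-10)

    def test_disconnected_components_anchored_independently(self):
        x = np.array(
            [
                [10.0, 12.0, np.nan, np.nan],
                [np.nan, np.nan, 20.0, 22.0],
            ]
        )
        w = maxlfq(x)
        np.testing.assert_allclose(w, [10.0, 12.0, 20.0, 22.0])

    def test_unobserved_cell_is_missing(self):
        x = np.array([[10.0, 12.0, np.nan]])
        w = maxlfq(x)
        assert np.isnan(w[2]) and not np.isnan(w[:2]).any()

    def test_shift_equivariance(self, rng):
        for _ in range(50):
            x = random_maxlfq_instance(rng)
            c = float(rng.normal(0, 5))
            np.testing.assert_allclose(maxlfq(x + c), maxlfq(x) + c, atol=1e-10)

    def test_precursor_offset_invariance(self, rng):
        for _ in range(50):
            x = random_maxlfq_instance(rng)
            beta = rng.normal(0, 2, (x.shape[0], 1))
            w0, w1 = maxlfq(x), maxlfq(x + beta)
            d0 = w0 - np.nanmean(w0)
            d1 = w1 - np.nanmean(w1)
            np.testing.assert_allclose(d0, d1, atol=1e-10)

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(60):
            x = random_maxlfq_instance(rng)
            mine, ref = maxlfq(x), maxlfq_oracle(x)
            np.testing.assert_allclose(
                mine - np.nanmean(mine), ref - np.nanmean(ref), atol=1e-8
            )

    def test_empty_input_rejected(self):
        with pytest.raises(ParameterError):
            maxlfq(np.empty((0, 3)))


class TestSummarizeAllProteins:
    def make_matrix(self, values, groups):
        f = frame(values)
        meta = pd.DataFrame(
            {
                "modified_sequence": [i.split("/")[0] for i in f.index],
                "charge": 2,
                "protein_group": groups,
                "genes": [g.split(";")[0] for g in groups],
            },
            index=f.index,
        )
        return PrecursorMatrix(f, meta)

    def test_two_complete_groups(self):
        matrix = self.make_matrix(
            [[10.0, 12.0], [11.0, 13.0], [5.0, 6.0]], ["PA", "PA", "PB"]
        )
        out = summarize_all_proteins(matrix)
        assert out.values.shape == (2, 2)
        assert out.values.index.tolist() == ["PA", "PB"]  # sorted by lead accession

    def test_all_precursors_missing_in_cell_gives_missing_protein(self):
        matrix = self.make_matrix([[10.0, np.nan], [11.0, np.nan]], ["PA", "PA"])
        out = summarize_all_proteins(matrix)
        assert np.isnan(out.values.loc["PA"].iloc[1])

    def test_matches_per_group_oracle(self, rng):
        values = rng.normal(12, 2, (15, 5))
        values[rng.random(values.shape) < 0.2] = np.nan
        values[0] = rng.normal(12, 2, 5)  # keep graph connected per group
        groups = [f"P{i % 5}" for i in range(15)]
        matrix = self.make_matrix(values, groups)
        out = summarize_all_proteins(matrix)
        for g in sorted(set(groups)):
            rows = [i for i, gg in enumerate(groups) if gg == g]
            ref = maxlfq_oracle(values[rows])
            got = out.values.loc[g].to_numpy()
            both = ~(np.isnan(ref) | np.isnan(got))
            np.testing.assert_allclose(
                got[both] - got[both].mean(), ref[both] - ref[both].mean(), atol=1e-8
            )


class TestDigestion:
    def test_worked_example(self):
        assert theoretical_tryptic_peptides("MAAAAAKGGGGGGRTTTTTTK") == 3
        assert digest_tryptic("MAAAAAKGGGGGGRTTTTTTK") == [
            "MAAAAAK",
            "GGGGGGR",
            "TTTTTTK",
        ]

    def test_short_and_unclevable(self):
        assert theoretical_tryptic_peptides("MK") == 0
        assert theoretical_tryptic_peptides("A" * 20) == 1

    def test_proline_rule(self):
        # K followed by P is not cleaved under the proline rule
        seq = "AAAAAKPAAAAK"
        assert digest_tryptic(seq, proline_rule=True) == ["AAAAAKPAAAAK"]
        assert digest_tryptic(seq, proline_rule=False) == ["AAAAAK", "PAAAAK"]

    def test_missed_cleavages(self):
        seq = "AAAAAKCCCCCKDDDDDK"
        assert theoretical_tryptic_peptides(seq, missed_cleavages=1) == 5
        assert theoretical_tryptic_peptides(seq, missed_cleavages=2) == 6

    def test_invalid_residue(self):
        with pytest.raises(FormatError):
            theoretical_tryptic_peptides("MAXXB1")

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        seq=st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=300),
        mc=st.integers(min_value=0, max_value=2),
        proline=st.booleans(),
    )
    def test_matches_character_walk_oracle(self, seq, mc, proline):
        assert theoretical_tryptic_peptides(
            seq, missed_cleavages=mc, proline_rule=proline
        ) == digest_count_oracle(seq, missed_cleavages=mc, proline_rule=proline)


class TestIbaq:
    def make_matrix(self, linear, groups):
        values = np.log2(np.asarray(linear, dtype=float))
        f = frame(values)
        meta = pd.DataFrame(
            {"modified_sequence": "s", "charge": 2, "protein_group": groups,
             "genes": [g.split(";")[0] for g in groups]},
            index=f.index,
        )
        return PrecursorMatrix(f, meta)

    def test_sum_divided_by_peptide_count(self):
        matrix = self.make_matrix([[100.0, 300.0]], ["PA"])
        anns = {"PA": ProteinAnnotation("PA", "GA", "Homo sapiens",
                                        "AAAAAAKBBBBBBKCCCCCCKDDDDDDK".replace("B", "G").replace("C", "S").replace("D", "T"))}
        table = compute_ibaq(matrix, anns)
        per_cell = table.attrs["ibaq_per_cell"].loc["PA"]
        np.testing.assert_allclose(per_cell.to_numpy(), [25.0, 75.0])
        assert table.loc["PA", "theoretical_peptides"] == 4

    def test_doubling_intensities_doubles_ibaq(self, rng):
        linear = rng.uniform(10, 1000, (4, 3))
        m1 = self.make_matrix(linear, ["PA"] * 4)
        m2 = self.make_matrix(2 * linear, ["PA"] * 4)
        seq = "AAAAAAK" * 5
        anns = {"PA": ProteinAnnotation("PA", "GA", "Homo sapiens", seq)}
        t1 = compute_ibaq(m1, anns).attrs["ibaq_per_cell"]
        t2 = compute_ibaq(m2, anns).attrs["ibaq_per_cell"]
        np.testing.assert_allclose(t2.to_numpy(), 2 * t1.to_numpy(), rtol=1e-12)

    def test_no_observable_peptides_is_missing(self, caplog):
        matrix = self.make_matrix([[100.0, 300.0]], ["PA"])
        anns = {"PA": ProteinAnnotation("PA", "GA", "Homo sapiens", "MK")}
        table = compute_ibaq(matrix, anns)
        assert table.loc["PA", "theoretical_peptides"] == 0
        assert np.isnan(table.loc["PA", "median_log10_ibaq"])
        assert table.loc["PA", "rank"] is pd.NA

    def test_top_n_larger_than_table_keeps_all(self, rng):
        linear = rng.uniform(10, 1000, (8, 4))
        groups = [f"P{i}" for i in range(8)]
        matrix = self.make_matrix(linear, groups)
        seq = "AAAAAAK" * 3
        anns = {g: ProteinAnnotation(g, f"G{g}", "Homo sapiens", seq) for g in groups}
        table = compute_ibaq(matrix, anns, top_n=500)
        assert len(table) == 8

    def test_random_fixture_matches_bruteforce(self, rng):
        linear = rng.uniform(10, 1000, (9, 4))
        linear[rng.random(linear.shape) < 0.25] = np.nan
        groups = [f"P{i % 3}" for i in range(9)]
        values = frame(np.log2(linear))
        meta = pd.DataFrame(
            {"modified_sequence": "s", "charge": 2, "protein_group": groups,
             "genes": groups},
            index=values.index,
        )
        matrix = PrecursorMatrix(values, meta)
        seq = "AAAAAAK" * 6
        anns = {f"P{i}": ProteinAnnotation(f"P{i}", f"G{i}", "Homo sapiens", seq)
                for i in range(3)}
        table = compute_ibaq(matrix, anns)
        per_cell = table.attrs["ibaq_per_cell"]
        for g in sorted(set(groups)):
            rows = [i for i, gg in enumerate(groups) if gg == g]
            expected = np.nansum(linear[rows], axis=0) / 6
            observed_any = ~np.all(np.isnan(linear[rows]), axis=0)
            expected[~observed_any] = np.nan
            np.testing.assert_allclose(
                per_cell.loc[g].to_numpy(), expected, rtol=1e-9, equal_nan=True
            )
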