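"""I/O layer: validation on read, round-trips, auxiliary tables."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dietmr.estimators import MrResult
from dietmr.sumstats import (
    ConfigError,
    GroupSpec,
    InputError,
    LdTable,
    SumStats,
    read_correlation_matrix,
    read_ld_table,
    read_results_table,
    read_sumstats,
    write_correlation_matrix,
    write_ld_table,
    write_results_table,
)

HEADER = "snp_id\teffect_allele\tother_allele\teaf\tbeta\tse\tpvalue\tn\n"


def _write(tmp_path, body, header=HEADER):
    path = tmp_path / "stats.tsv"
    path.write_text(header + body)
    return path


class TestReadSumstats:
    def test_well_formed_table_read_identically(self, tmp_path):
        path = _write(
            tmp_path,
            "rs1\tA\tG\t0.2\t0.05\t0.01\t1e-8\t1000\n"
            "rs2\tC\tT\t0.5\t-0.02\t0.02\t0.5\t1000\n"
            "rs3\tg\ta\t0.9\t0.00\t0.03\t1.0\t1000\n",
        )
        ss = read_sumstats(path)
        assert len(ss) == 3
        # alleles uppercased on read
        assert ss.df.loc["rs3", "effect_allele"] == "G"
        assert ss.df.loc["rs1", "beta"] == pytest.approx(0.05)

    @pytest.mark.parametrize(
        "row",
        [
            "rsbad\tA\tG\t0.2\t0.05\t0.0\t1e-8\t1000",    # se = 0
            "rsbad\tA\tA\t0.2\t0.05\t0.01\t1e-8\t1000",   # identical alleles
            "rsbad\tA\tG\t0.2\t0.05\t0.01\t0.0\t1000",    # p = 0
            "rsbad\tA\tG\t0.2\t0.05\t0.01\t1.5\t1000",    # p > 1
            "rsbad\tA\tG\t1.7\t0.05\t0.01\t1e-8\t1000",   # eaf > 1
            "rsbad\tAT\tG\t0.2\t0.05\t0.01\t1e-8\t1000",  # indel rejected
        ],
    )
    def test_invalid_rows_are_dropped(self, tmp_path, row):
        good = "rs1\tA\tG\t0.2\t0.05\t0.01\t1e-8\t1000\n"
        ss = read_sumstats(_write(tmp_path, good + row + "\n"))
        assert list(ss.df.index) == ["rs1"]

    def test_missing_required_column_is_config_error(self, tmp_path):
        path = _write(
            tmp_path,
            "rs1\tA\t0.05\t0.01\t1e-8\n",
            header="snp_id\teffect_allele\tbeta\tse\tpvalue\n",
        )
        with pytest.raises(ConfigError, match="other_allele"):
            read_sumstats(path)

    def test_column_map_resolves_foreign_headers(self, tmp_path):
        path = _write(
            tmp_path,
            "rs1\tA\tG\t0.05\t0.01\t1e-8\n",
            header="rsid\tEA\tNEA\tEffect\tStdErr\tP\n",
        )
        ss = read_sumstats(
            path,
            column_map={
                "snp_id": "rsid",
                "effect_allele": "EA",
                "other_allele": "NEA",
                "beta": "Effect",
                "se": "StdErr",
                "pvalue": "P",
            },
        )
        assert len(ss) == 1
        assert np.isnan(ss.df.loc["rs1", "eaf"])  # optional columns tolerated as missing

    def test_zero_valid_rows_is_input_error(self, tmp_path):
        path = _write(tmp_path, "rs1\tA\tA\t0.2\t0.05\t0.01\t1e-8\t1000\n")
        with pytest.raises(InputError):
            read_sumstats(path)

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(
            st.tuples(
                st.sampled_from(["A", "C", "G", "T", "N", "AT"]),
                st.sampled_from(["A", "C", "G", "T", "N"]),
                st.floats(-0.5, 1.5),            # eaf, possibly invalid
                st.floats(-1, 1),                # beta
                st.floats(-0.01, 0.05),          # se, possibly invalid
                st.floats(0, 1.2),               # pvalue, possibly invalid
            ),
            min_size=1,
            max_size=30,
        )
    )
    def test_no_invalid_record_survives_read(self, tmp_path_factory, rows):
        """Randomized malformed tables: every surviving row satisfies the invariants."""
        body = "".join(
            f"rs{i}\t{ea}\t{oa}\t{eaf}\t{beta}\t{se}\t{p}\t100\n"
            for i, (ea, oa, eaf, beta, se, p) in enumerate(rows)
        )
        path = tmp_path_factory.mktemp("fuzz") / "t.tsv"
        path.write_text(HEADER + body)
        try:
            ss = read_sumstats(path)
        except InputError:
            return
        df = ss.df
        assert (df["se"] > 0).all()
        assert ((df["pvalue"] > 0) & (df["pvalue"] <= 1)).all()
        assert (df["effect_allele"] != df["other_allele"]).all()
        assert df["effect_allele"].isin(list("ACGT")).all()
        eaf = df["eaf"].dropna()
        assert ((eaf >= 0) & (eaf <= 1)).all()


def _result(**kw):
    base = dict(
        exposure="beer",
        outcome="DHA",
        method="ivw",
        nsnp=12,
        beta=0.8412345678901,
        se=0.21,
        ci_low=0.8412345678901 - 1.96 * 0.21,
        ci_high=0.8412345678901 + 1.96 * 0.21,
        pvalue=6.2e-5,
        Q=13.1,
        Q_df=11,
        Q_pvalue=0.287,
        variance_model="fixed",
    )
    base.update(kw)
    return MrResult(**base)


class TestResultsTable:
    def test_single_result_single_row(self, tmp_path):
        path = tmp_path / "res.tsv"
        write_results_table([_result()], path)
        assert len(path.read_text().strip().splitlines()) == 2

    def test_round_trip_preserves_values(self, tmp_path):
        path = tmp_path / "res.tsv"
        res = _result()
        write_results_table([res], path, qvalues={("beer", "DHA", "ivw"): 0.012})
        back = read_results_table(path)
        row = back.iloc[0]
        assert row["exposure"] == "beer" and row["method"] == "ivw"
        assert row["beta"] == pytest.approx(res.beta, rel=1e-12)
        assert row["qvalue"] == pytest.approx(0.012, rel=1e-12)
        assert row["Q"] == pytest.approx(13.1, rel=1e-12)

    def test_empty_collection_is_error(self, tmp_path):
        with pytest.raises(InputError):
            write_results_table([], tmp_path / "res.tsv")


class TestAuxTables:
    def test_ld_table_symmetric_and_sparse(self, tmp_path):
        t = LdTable()
        t.set("rs1", "rs2", 0.7)
        assert t.r2("rs2", "rs1") == 0.7
        assert t.r2("rs1", "rs3") == 0.0        # absent pair = independent
        assert t.r2("rs1", "rs1") == 1.0
        path = tmp_path / "ld.tsv"
        write_ld_table(t, path)
        assert read_ld_table(path).r2("rs1", "rs2") == 0.7

    def test_ld_r2_out_of_range_rejected(self):
        with pytest.raises(InputError):
            LdTable().set("a", "b", 1.2)

    @pytest.mark.parametrize(
        "members,pc_index",
        [(["a"], 1), (["a", "b"], 3), (["a", "a"], 1)],
    )
    def test_bad_group_spec_rejected(self, members, pc_index):
        with pytest.raises(ConfigError):
            GroupSpec("g", members, pc_index)

    def test_correlation_matrix_round_trip(self, tmp_path):
        mat = pd.DataFrame(
            [[1.0, 0.6], [0.6, 1.0]], index=["tea", "coffee"], columns=["tea", "coffee"]
        )
        path = tmp_path / "corr.tsv"
        write_correlation_matrix(mat, path)
        back = read_correlation_matrix(path)
        pd.testing.assert_frame_equal(mat, back)

    def test_duplicate_snp_ids_rejected(self):
        df = pd.DataFrame(
            {
                "effect_allele": ["A", "A"],
                "other_allele": ["G", "G"],
                "eaf": [0.1, 0.1],
                "beta": [0.1, 0.1],
                "se": [0.1, 0.1],
                "pvalue": [0.5, 0.5],
                "n": [10, 10],
            },
            index=["rs1", "rs1"],
        )
        with pytest.raises(InputError):
            SumStats("t", df)
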