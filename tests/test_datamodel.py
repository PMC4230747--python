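"""Domain types and delimited-text round trips."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from asepg.datamodel import (
    AlleleCounts,
    BiasSpec,
    BinomialResult,
    DnaCounts,
    PosteriorResult,
    read_counts_table,
    read_results,
    write_counts_table,
    write_results,
)
from asepg.exceptions import DomainError, TableFormatError, ValidationError


def _write(tmp_path, text, name="counts.tsv"):
    path = tmp_path / name
    path.write_text(text)
    return path


HEADER = "exon_id\treplicate\tmaternal_count\tpaternal_count\n"


class TestReadCountsTable:
    def test_parses_one_exon_with_three_replicates(self, tmp_path):
        path = _write(
            tmp_path,
            HEADER + "e1\t1\t10\t12\ne1\t2\t11\t9\ne1\t3\t8\t10\n",
        )
        recs = read_counts_table(path, kind="RNA")
        assert len(recs) == 1
        rec = recs[0]
        assert rec.n_replicates == 3
        np.testing.assert_array_equal(rec.x, [10, 11, 8])
        np.testing.assert_array_equal(rec.y, [12, 9, 10])

    def test_header_only_file_gives_empty_list(self, tmp_path):
        assert read_counts_table(_write(tmp_path, HEADER)) == []

    def test_non_integer_count_is_rejected_with_row_number(self, tmp_path):
        path = _write(tmp_path, HEADER + "e1\t1\t3.5\t4\n")
        with pytest.raises(ValidationError, match="row 2"):
            read_counts_table(path)

    def test_negative_count_is_rejected(self, tmp_path):
        path = _write(tmp_path, HEADER + "e1\t1\t-3\t4\n")
        with pytest.raises(ValidationError, match="negative"):
            read_counts_table(path)

    def test_missing_column_names_the_column(self, tmp_path):
        path = _write(tmp_path, "exon_id\treplicate\tmaternal_count\ne1\t1\t3\n")
        with pytest.raises(TableFormatError, match="paternal_count"):
            read_counts_table(path)

    def test_duplicate_exon_replicate_pair_is_rejected(self, tmp_path):
        path = _write(tmp_path, HEADER + "e1\t1\t3\t4\ne1\t1\t5\t6\n")
        with pytest.raises(ValidationError, match="duplicate"):
            read_counts_table(path)

    def test_replicates_sorted_by_index_regardless_of_row_order(self, tmp_path):
        path = _write(tmp_path, HEADER + "e1\t2\t11\t9\ne1\t1\t10\t12\n")
        rec = read_counts_table(path)[0]
        np.testing.assert_array_equal(rec.x, [10, 11])

    def test_dna_kind_returns_dna_records(self, tmp_path):
        path = _write(tmp_path, HEADER + "e1\t1\t7\t5\n")
        rec = read_counts_table(path, kind="DNA")[0]
        assert isinstance(rec, DnaCounts)
        np.testing.assert_array_equal(rec.x_star, [7])


@given(
    st.lists(
        st.tuples(st.integers(0, 500), st.integers(0, 500)),
        min_size=1,
        max_size=6,
    )
)
def test_counts_round_trip_preserves_everything(tmp_path_factory, pairs):
    """read(write(counts)) reproduces counts and replicate order exactly."""
    tmp = tmp_path_factory.mktemp("rt")
    rec = AlleleCounts("e1", x=[p[0] for p in pairs], y=[p[1] for p in pairs])
    path = tmp / "c.tsv"
    write_counts_table([rec], path)
    back = read_counts_table(path)[0]
    np.testing.assert_array_equal(back.x, rec.x)
    np.testing.assert_array_equal(back.y, rec.y)


class TestTypes:
    def test_mismatched_replicate_lengths_rejected(self):
        with pytest.raises(ValidationError):
            AlleleCounts("e", x=[1, 2], y=[3])

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            DnaCounts("e", x_star=[-1], y_star=[2])

    def test_bias_spec_fixed_requires_open_interval(self):
        with pytest.raises(DomainError):
            BiasSpec.fixed(1.0)
        assert BiasSpec.fixed(0.5).q == 0.5

    def test_bias_spec_random_phi_requires_reads(self):
        with pytest.raises(DomainError):
            BiasSpec.from_dna(DnaCounts("e", x_star=[0], y_star=[0]))

    def test_posterior_ai_flag_matches_alpha_and_theta_intervals(self, rng):
        draws = rng.lognormal(0.3, 0.1, size=4000)
        res = PosteriorResult("e", "pg", draws, ci_level=0.95,
                              n_draws=4000, n_burnin=0, seed=0)
        lo, hi = res.ci_alpha
        tlo, thi = res.ci_theta
        assert res.ai_flag == (not lo <= 1.0 <= hi) == (not tlo <= 0.5 <= thi)
        np.testing.assert_allclose(res.theta_draws, draws / (1 + draws))


class TestWriteResults:
    def _posterior(self, draws):
        return PosteriorResult("e1", "pg_fixed_q[0.5]", np.asarray(draws),
                               ci_level=0.95, n_draws=len(draws), n_burnin=0, seed=1)

    def test_interval_containing_one_writes_no_ai(self, tmp_path, rng):
        res = self._posterior(rng.uniform(0.8, 1.3, 1000))
        path = tmp_path / "r.tsv"
        write_results([res], path)
        df = read_results(path)
        assert not df.loc[0, "ai_flag"]

    def test_interval_excluding_one_writes_ai(self, tmp_path, rng):
        res = self._posterior(rng.uniform(1.2, 1.9, 1000))
        path = tmp_path / "r.tsv"
        write_results([res], path)
        assert read_results(path).loc[0, "ai_flag"].item()

    def test_empty_results_write_header_only(self, tmp_path):
        path = tmp_path / "r.tsv"
        write_results([], path)
        assert read_results(path).empty

    def test_binomial_rows_round_trip_at_full_precision(self, tmp_path):
        res = BinomialResult("e1", n=100, p_hat=0.7, z=4.0,
                             p_value=0.0000633, ai_flag=True, variant="z")
        path = tmp_path / "r.tsv"
        write_results([res], path)
        df = read_results(path)
        assert df.loc[0, "p_value"] == pytest.approx(0.0000633, abs=0)
        assert df.loc[0, "ai_flag"].item()

    def test_mixing_result_kinds_is_rejected(self, tmp_path, rng):
        bad = [
            self._posterior(rng.uniform(0.8, 1.3, 100)),
            BinomialResult("e2", n=10, p_hat=0.5, z=0.0, p_value=1.0,
                           ai_flag=False, variant="exact"),
        ]
        with pytest.raises(ValidationError):
            write_results(bad, tmp_path / "r.tsv")
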