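import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mrmediate import harmonize, read_sumstats, write_sumstats
from mrmediate.sumstats import (
    EmptyInputError,
    EmptyOverlapError,
    SumstatsFormatError,
    VariantAssociation,
)

from conftest import make_table

HEADER = "SNP\teffect_allele\tother_allele\teaf\tbeta\tse\tpval\tn\n"


def write_tsv(path, rows):
    with open(path, "w") as fh:
        fh.write(HEADER)
        for r in rows:
            fh.write("\t".join(str(x) for x in r) + "\n")
    return path


class TestReadWrite:
    def test_parses_valid_rows(self, tmp_path):
        p = write_tsv(tmp_path / "x.tsv", [
            ("rs1", "A", "G", 0.3, 0.1, 0.02, 1e-9, 1000),
            ("rs2", "C", "T", 0.5, -0.2, 0.03, 1e-10, 1000),
        ])
        table, log = read_sumstats(p, "t2dm", "binary")
        assert len(table) == 2 and not log
        assert table.records[0].beta == pytest.approx(0.1)

    def test_rejects_invalid_rows_with_reason(self, tmp_path):
        p = write_tsv(tmp_path / "x.tsv", [
            ("rs1", "A", "G", 0.3, 0.1, -0.1, 1e-9, 1000),
            ("rs2", "C", "T", 0.5, -0.2, 0.03, 1e-10, 1000),
        ])
        table, log = read_sumstats(p, "t2dm", "binary")
        assert len(table) == 1
        assert log == [("rs1", "nonpositive se")]

    def test_missing_column_names_it(self, tmp_path):
        p = tmp_path / "x.tsv"
        p.write_text("SNP\teffect_allele\tother_allele\teaf\tse\tpval\tn\nrs1\tA\tG\t0.3\t0.01\t0.5\t10\n")
        with pytest.raises(SumstatsFormatError, match="beta"):
            read_sumstats(p, "t2dm", "binary")

    def test_duplicate_snp_keeps_smallest_p(self, tmp_path):
        p = write_tsv(tmp_path / "x.tsv", [
            ("rs1", "A", "G", 0.3, 0.1, 0.02, 1e-4, 1000),
            ("rs1", "A", "G", 0.3, 0.2, 0.02, 1e-9, 1000),
        ])
        table, log = read_sumstats(p, "t2dm", "binary")
        assert len(table) == 1
        assert table.records[0].beta == pytest.approx(0.2)
        assert log

    def test_round_trip_identity(self, tmp_path):
        table = make_table([
            ("rs1", "A", "G", 0.1, 0.02, 1e-9, 0.3),
            ("rs2", "C", "T", -0.2, 0.03, 1e-10, 0.5),
            ("rs3", "G", "C", 0.0, 0.01, 0.5, 0.42),
        ])
        path = write_sumstats(table, tmp_path / "rt.tsv")
        back, _ = read_sumstats(path, table.trait_name, table.trait_type)
        assert [r.__dict__ for r in back.records] == [r.__dict__ for r in table.records]

    def test_missing_eaf_round_trips_to_missing(self, tmp_path):
        rec = VariantAssociation("rs1", "A", "G", 0.1, 0.02, 1e-9, eaf=None)
        table = make_table([])
        table.records = [rec]
        path = write_sumstats(table, tmp_path / "m.tsv")
        assert "." in path.read_text()
        back, _ = read_sumstats(path, "trait", "binary")
        assert back.records[0].eaf is None

    def test_refuses_empty_table(self, tmp_path):
        table = make_table([("rs1", "A", "G", 0.1, 0.02, 1e-9)])
        table.records = []
        with pytest.raises(EmptyInputError):
            write_sumstats(table, tmp_path / "e.tsv")


class TestHarmonize:
    def test_swapped_alleles_flip_sign(self):
        exp = make_table([("rs1", "A", "G", 0.10, 0.01, 1e-9, 0.3)], "exp")
        out = make_table([("rs1", "G", "A", 0.05, 0.01, 1e-3, 0.7)], "out")
        h = harmonize(exp, out)
        assert h.by[0] == pytest.approx(-0.05)
        assert h.bx[0, 0] == pytest.approx(0.10)

    def test_strand_complement_aligns_without_flip(self):
        # outcome on the other strand: T/C complements to A/G, same orientation
        exp = make_table([("rs1", "A", "G", 0.10, 0.01, 1e-9, 0.3)], "exp")
        out = make_table([("rs1", "T", "C", 0.05, 0.01, 1e-3, 0.3)], "out")
        h = harmonize(exp, out)
        assert h.by[0] == pytest.approx(0.05)

    def test_palindromic_ambiguous_frequency_dropped(self):
        exp = make_table([
            ("rs1", "A", "T", 0.10, 0.01, 1e-9, 0.50),
            ("rs2", "A", "G", 0.10, 0.01, 1e-9, 0.30),
        ], "exp")
        out = make_table([
            ("rs1", "A", "T", 0.05, 0.01, 1e-3, 0.50),
            ("rs2", "A", "G", 0.05, 0.01, 1e-3, 0.30),
        ], "out")
        h = harmonize(exp, out, palindrome_policy="infer")
        assert h.snp_ids == ["rs2"]
        assert ("rs1", "palindromic, ambiguous frequency") in h.dropped

    def test_palindromic_oriented_by_frequency(self):
        exp = make_table([("rs1", "A", "T", 0.10, 0.01, 1e-9, 0.2)], "exp")
        # outcome frequency on the opposite side of 0.5: effect must flip
        out = make_table([("rs1", "A", "T", 0.05, 0.01, 1e-3, 0.8)], "out")
        h = harmonize(exp, out, palindrome_policy="infer")
        assert h.by[0] == pytest.approx(-0.05)

    def test_incompatible_alleles_dropped(self):
        exp = make_table([
            ("rs1", "A", "G", 0.10, 0.01, 1e-9),
            ("rs2", "A", "G", 0.10, 0.01, 1e-9),
        ], "exp")
        out = make_table([
            ("rs1", "A", "C", 0.05, 0.01, 1e-3),
            ("rs2", "A", "G", 0.05, 0.01, 1e-3),
        ], "out")
        h = harmonize(exp, out)
        assert ("rs1", "incompatible alleles") in h.dropped

    def test_empty_overlap_raises(self):
        exp = make_table([("rs1", "A", "G", 0.1, 0.01, 1e-9)], "exp")
        out = make_table([("rs9", "A", "G", 0.1, 0.01, 1e-9)], "out")
        with pytest.raises(EmptyOverlapError):
            harmonize(exp, out)

    def test_harmonization_idempotent(self):
        exp = make_table([
            ("rs1", "A", "G", 0.10, 0.01, 1e-9, 0.3),
            ("rs2", "C", "T", -0.07, 0.02, 1e-8, 0.6),
        ], "exp")
        out = make_table([
            ("rs1", "G", "A", 0.05, 0.01, 1e-3, 0.7),
            ("rs2", "T", "C", 0.02, 0.01, 1e-2, 0.4),
        ], "out")
        h1 = harmonize(exp, out)
        aligned_out = make_table(
            [
                (s, "A" if i == 0 else "C", "G" if i == 0 else "T",
                 h1.by[i], h1.sy[i], 0.5)
                for i, s in enumerate(h1.snp_ids)
            ],
            "out",
        )
        h2 = harmonize(exp.subset(h1.snp_ids), aligned_out)
        np.testing.assert_allclose(h2.by, h1.by)
        np.testing.assert_allclose(h2.bx, h1.bx)

    @settings(derandomize=True, max_examples=30)
    @given(st.lists(st.floats(-0.5, 0.5).filter(lambda x: abs(x) > 1e-3),
                    min_size=2, max_size=6))
    def test_sign_consistency_under_allele_relabel(self, betas):
        """Negating exposure betas and swapping allele labels leaves bx*by invariant."""
        exp = make_table(
            [(f"rs{i}", "A", "G", b, 0.01, 1e-9, 0.3) for i, b in enumerate(betas)],
            "exp",
        )
        flipped = make_table(
            [(f"rs{i}", "G", "A", -b, 0.01, 1e-9, 0.7) for i, b in enumerate(betas)],
            "exp",
        )
        out = make_table(
            [(f"rs{i}", "A", "G", 0.3 * b, 0.02, 1e-3, 0.3) for i, b in enumerate(betas)],
            "out",
        )
        h1, h2 = harmonize(exp, out), harmonize(flipped, out)
        np.testing.assert_allclose(h1.bx[0] * h1.by, h2.bx[0] * h2.by, atol=1e-12)
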