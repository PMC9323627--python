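import numpy as np
import pandas as pd
import pytest

from owasjoint.data_io import (
    ConfigurationError,
    GwasRecord,
    HarmonizationError,
    OpennessWeightTable,
    harmonize,
    read_gwas,
    read_weights,
)
from conftest import make_panel


def _write(tmp_path, name, text):
    path = tmp_path / name
    path.write_text(text)
    return path


class TestReadGwas:
    def test_z_from_beta_se(self, tmp_path):
        path = _write(
            tmp_path,
            "g.tsv",
            "SNP\tCHR\tBP\tA1\tA2\tBETA\tSE\n" "rs1\t1\t100\tA\tG\t0.2\t0.1\n",
        )
        (rec,) = read_gwas(path)
        assert rec.z == pytest.approx(2.0)

    def test_z_column_passthrough_and_wins_over_beta(self, tmp_path):
        path = _write(
            tmp_path,
            "g.tsv",
            "SNP\tCHR\tBP\tA1\tA2\tZ\tBETA\tSE\n" "rs1\t1\t100\tA\tG\t-1.3\t9.9\t0.1\n",
        )
        (rec,) = read_gwas(path)
        assert rec.z == -1.3

    def test_unparseable_rows_dropped(self, tmp_path):
        rows = [f"rs{i}\t1\t{100*i}\tA\tG\t{z}" for i, z in enumerate(
            ["1.0", "nan_oops", "0.5", "-2.0", "0.1"], start=1)]
        path = _write(tmp_path, "g.tsv", "SNP\tCHR\tBP\tA1\tA2\tZ\n" + "\n".join(rows) + "\n")
        records = read_gwas(path)
        assert len(records) == 4
        assert [r.variant_id for r in records] == ["rs1", "rs3", "rs4", "rs5"]

    def test_missing_mandatory_column_is_config_error(self, tmp_path):
        path = _write(tmp_path, "g.tsv", "SNP\tCHR\tBP\tA1\tA2\n" "rs1\t1\t100\tA\tG\n")
        with pytest.raises(ConfigurationError):
            read_gwas(path)

    @pytest.mark.parametrize("bad", [("A", "A"), ("A", "N")])
    def test_invalid_alleles_rejected(self, bad):
        with pytest.raises(ValueError):
            GwasRecord("rs1", "1", 1, bad[0], bad[1], 0.0)


class TestReadWeights:
    def test_table_size_and_parse(self, tmp_path):
        path = _write(
            tmp_path,
            "ct.tsv",
            "CHR\tBP\tA1\tA2\tW\n1\t100\tA\tG\t0.731\n1\t200\tC\tT\t-0.2\n1\t300\tG\tA\t0.1\n",
        )
        table = read_weights(path, "ct")
        assert len(table) == 3
        assert table.entries[("1", 100, "A", "G")] == 0.731

    def test_duplicate_key_keeps_first(self, tmp_path):
        path = _write(
            tmp_path,
            "ct.tsv",
            "CHR\tBP\tA1\tA2\tW\n1\t100\tA\tG\t0.5\n1\t100\tA\tG\t0.9\n1\t200\tC\tT\t0.1\n",
        )
        table = read_weights(path, "ct")
        assert len(table) == 2
        assert table.entries[("1", 100, "A", "G")] == 0.5

    def test_empty_file_errors(self, tmp_path):
        path = _write(tmp_path, "ct.tsv", "CHR\tBP\tA1\tA2\tW\n")
        with pytest.raises(ConfigurationError):
            read_weights(path, "ct")

    def test_lookup_flips_sign_on_swapped_alleles(self):
        table = OpennessWeightTable("ct", {("1", 100, "A", "G"): 0.4})
        assert table.lookup("1", 100, "A", "G") == 0.4
        assert table.lookup("1", 100, "G", "A") == -0.4
        assert table.lookup("1", 999, "A", "G") is None


class TestPlinkPanel:
    def test_roundtrip_and_sd(self, small_panel):
        # dosage columns survive the 2-bit pack/unpack byte-exactly
        got = small_panel.dosages([0, 1, 2, 3])
        expected = np.array(
            [[0, 1, 2, 2], [1, 0, 1, 2], [2, 2, 0, 2], [0, 1, 1, 2], [1, 2, 2, 2], [2, 0, 0, 2]],
            dtype=float,
        )
        np.testing.assert_array_equal(got, expected)
        np.testing.assert_allclose(small_panel.sd([0]), expected[:, 0].std(ddof=1))
        assert small_panel.monomorphic.tolist() == [False, False, False, True]

    def test_missing_dosage_mean_imputed(self, tmp_path):
        variants = pd.DataFrame(
            {"variant_id": ["rs1"], "chrom": ["1"], "pos": [100], "a1": ["A"], "a2": ["G"]}
        )
        dosages = np.array([[0.0], [2.0], [np.nan], [2.0]])
        panel = make_panel(tmp_path, variants, dosages)
        np.testing.assert_allclose(panel.dosages([0])[:, 0], [0, 2, 4 / 3, 2])


def _mk_gwas(n, chrom="1", z=1.0):
    return [
        GwasRecord(f"rs{i+1}", chrom, 100 * (i + 1), "A", "G", z) for i in range(n)
    ]


def _mk_weights(records, cell_type="ct", w=0.5):
    return OpennessWeightTable(
        cell_type,
        {(r.chrom, r.pos, r.effect_allele, r.other_allele): w for r in records},
    )


def _mk_panel_for(tmp_path, records, n_ref=20, seed=0):
    rng = np.random.default_rng(seed)
    variants = pd.DataFrame(
        {
            "variant_id": [r.variant_id for r in records],
            "chrom": [r.chrom for r in records],
            "pos": [r.pos for r in records],
            "a1": [r.effect_allele for r in records],
            "a2": [r.other_allele for r in records],
        }
    )
    dosages = rng.integers(0, 3, size=(n_ref, len(records))).astype(float)
    return make_panel(tmp_path, variants, dosages)


class TestHarmonize:
    def test_allele_flip_negates_z(self, tmp_path):
        # GWAS effect allele is the panel's A2 -> z flips sign
        gwas = [GwasRecord("rs1", "1", 100, "G", "A", 2.0)]
        panel = _mk_panel_for(tmp_path, [GwasRecord("rs1", "1", 100, "A", "G", 0.0)])
        weights = [_mk_weights(gwas)]
        (hv,) = harmonize(gwas, weights, panel)
        assert hv.z == -2.0
        assert hv.effect_allele == "A"
        # the weight was keyed on (G, A), so it flips too
        assert hv.w_by_cell_type == (-0.5,)

    def test_double_flip_restores_z(self, tmp_path):
        gwas_fwd = [GwasRecord("rs1", "1", 100, "A", "G", 2.0)]
        gwas_rev = [GwasRecord("rs1", "1", 100, "G", "A", -2.0)]
        panel = _mk_panel_for(tmp_path, gwas_fwd)
        weights = [_mk_weights(gwas_fwd)]
        hv_fwd = harmonize(gwas_fwd, weights, panel)[0]
        hv_rev = harmonize(gwas_rev, weights, panel)[0]
        assert hv_fwd.z == hv_rev.z == 2.0

    def test_strand_ambiguous_dropped(self, tmp_path):
        gwas = [
            GwasRecord("rs1", "1", 100, "A", "T", 1.0),
            GwasRecord("rs2", "1", 200, "C", "G", 1.0),
            GwasRecord("rs3", "1", 300, "A", "G", 1.0),
        ]
        panel = _mk_panel_for(tmp_path, gwas)
        out = harmonize(gwas, [_mk_weights(gwas)], panel)
        assert [v.variant_id for v in out] == ["rs3"]

    def test_intersection_counts(self, tmp_path):
        # 10 GWAS, weights for 8, panel has 9; overlap of all three = 7
        gwas = _mk_gwas(10)
        weights = [_mk_weights(gwas[:8])]
        panel = _mk_panel_for(tmp_path, gwas[1:])  # rs2..rs10
        out = harmonize(gwas, weights, panel)
        assert len(out) == 7
        assert {v.variant_id for v in out} == {f"rs{i}" for i in range(2, 9)}

    def test_output_subset_of_inputs_and_positive_sd(self, tmp_path):
        gwas = _mk_gwas(10)
        weights = [_mk_weights(gwas)]
        panel = _mk_panel_for(tmp_path, gwas)
        out = harmonize(gwas, weights, panel)
        gwas_ids = {r.variant_id for r in gwas}
        assert {v.variant_id for v in out} <= gwas_ids
        assert all(v.sd_ref > 0 for v in out)

    def test_idempotent(self, tmp_path):
        gwas = _mk_gwas(6)
        weights = [_mk_weights(gwas)]
        panel = _mk_panel_for(tmp_path, gwas)
        once = harmonize(gwas, weights, panel)
        again_in = [
            GwasRecord(v.variant_id, v.chrom, v.pos, v.effect_allele, v.other_allele, v.z, v.n)
            for v in once
        ]
        twice = harmonize(again_in, weights, panel)
        assert [(v.variant_id, v.z, v.w_by_cell_type) for v in once] == [
            (v.variant_id, v.z, v.w_by_cell_type) for v in twice
        ]

    def test_empty_intersection_errors(self, tmp_path):
        gwas = _mk_gwas(3)
        other = [GwasRecord("rsX", "2", 999, "A", "G", 0.0)]
        panel = _mk_panel_for(tmp_path, other)
        with pytest.raises(HarmonizationError):
            harmonize(gwas, [_mk_weights(gwas)], panel)
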