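import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gendiv.genotype_qc import (
    GenotypeError,
    GenotypePanel,
    QCThresholds,
    hwe_exact_test,
    mendel_mismatch_rates,
    qc_filter,
    read_plink,
    write_plink,
)

from conftest import make_panel, pedigree_from_parents
from oracles import hwe_enumeration


def write_plink_files(tmp_path, map_lines, ped_lines):
    map_f = tmp_path / "g.map"
    ped_f = tmp_path / "g.ped"
    map_f.write_text("".join(line + "\n" for line in map_lines))
    ped_f.write_text("".join(line + "\n" for line in ped_lines))
    return ped_f, map_f


class TestReadPlink:
    def test_small_fixture_with_missing(self, tmp_path):
        ped_f, map_f = write_plink_files(
            tmp_path,
            ["1 s1 0 100", "1 s2 0 200", "2 s3 0 150"],
            [
                "F1 A1 0 0 1 -9 A A A G G G",
                "F2 A2 0 0 2 -9 A G 0 0 G G",
            ],
        )
        panel = read_plink(ped_f, map_f)
        assert panel.n_samples == 2 and panel.n_snps == 3
        assert (panel.calls == np.int8(-1)).sum() == 1
        # dosage counts lexicographically smaller allele (A at s1/s2, G at s3)
        assert panel.calls[0, 0] == 2  # A A
        assert panel.calls[1, 0] == 1  # A G

    def test_non_autosomal_dropped(self, tmp_path):
        ped_f, map_f = write_plink_files(
            tmp_path,
            ["1 s1 0 100", "30 sX 0 200", "2 s3 0 150"],
            ["F1 A1 0 0 1 -9 A A C C G G"],
        )
        panel = read_plink(ped_f, map_f)
        assert panel.n_snps == 2
        assert set(panel.snps["snp_id"]) == {"s1", "s3"}

    def test_triallelic_error(self, tmp_path):
        ped_f, map_f = write_plink_files(
            tmp_path,
            ["1 s1 0 100"],
            ["F1 A1 0 0 1 -9 A C", "F2 A2 0 0 1 -9 G G"],
        )
        with pytest.raises(GenotypeError, match="s1"):
            read_plink(ped_f, map_f)

    def test_ragged_row_error(self, tmp_path):
        ped_f, map_f = write_plink_files(
            tmp_path,
            ["1 s1 0 100", "1 s2 0 200"],
            ["F1 A1 0 0 1 -9 A A"],
        )
        with pytest.raises(GenotypeError, match="ragged"):
            read_plink(ped_f, map_f)

    def test_round_trip_identity(self, tmp_path, rng):
        calls = rng.integers(-1, 3, size=(5, 8)).astype(np.int8)
        # ensure every SNP has at least one het so both alleles are observed
        calls[0] = 1
        panel = make_panel(calls, positions=np.arange(1, 9) * 250_000)
        write_plink(panel, tmp_path / "o.ped", tmp_path / "o.map")
        back = read_plink(tmp_path / "o.ped", tmp_path / "o.map")
        assert back.sample_ids == panel.sample_ids
        np.testing.assert_array_equal(back.calls, panel.calls)
        pd.testing.assert_frame_equal(back.snps, panel.snps)

    def test_unsorted_positions_rejected(self):
        with pytest.raises(GenotypeError, match="increasing"):
            make_panel(np.zeros((2, 3)), positions=[300, 200, 100])


class TestHWE:
    def test_monomorphic(self):
        assert hwe_exact_test(5, 0, 0) == 1.0
        assert hwe_exact_test(0, 0, 7) == 1.0

    def test_two_het_classes_enumeration(self):
        # 1 hom + 1 hom, alleles 2+2: het counts {0, 2}
        assert hwe_exact_test(1, 0, 1) == pytest.approx(
            hwe_enumeration(1, 0, 1), abs=1e-12
        )

    def test_equilibrium_configuration(self):
        p = hwe_exact_test(20, 40, 20)
        assert p == pytest.approx(hwe_enumeration(20, 40, 20), rel=1e-9)
        assert p > 0.5

    def test_extreme_deficit_small_p(self):
        assert hwe_exact_test(30, 0, 30) < 1e-10

    def test_midp_smaller(self):
        full = hwe_exact_test(8, 10, 7)
        mid = hwe_exact_test(8, 10, 7, midp=True)
        assert mid < full

    @given(
        st.integers(0, 12), st.integers(0, 12), st.integers(0, 12)
    )
    @settings(max_examples=300, deadline=None)
    def test_matches_enumeration_oracle(self, a, h, b):
        if a + h + b == 0:
            return
        assert hwe_exact_test(a, h, b) == pytest.approx(
            hwe_enumeration(a, h, b), rel=1e-9, abs=1e-12
        )


class TestMendel:
    def _pedigree(self):
        return pedigree_from_parents(
            {"S": (None, None), "O1": ("S", None), "O2": ("S", None)}
        )

    def test_opposing_homozygotes(self):
        # offspring dosage 2, sire dosage 0 -> mismatch rate 1
        panel = make_panel([[0], [2], [1]], sample_ids=["S", "O1", "O2"])
        rates = mendel_mismatch_rates(panel, self._pedigree())
        assert rates[0] == pytest.approx(0.5)  # O1 mismatch, O2 consistent

    def test_het_consistent(self):
        panel = make_panel([[0], [1]], sample_ids=["S", "O1"])
        rates = mendel_mismatch_rates(panel, self._pedigree())
        assert rates[0] == 0.0

    def test_no_pairs_warns_all_na(self):
        panel = make_panel([[0], [2]], sample_ids=["X", "Y"])
        with pytest.warns(UserWarning, match="no genotyped"):
            rates = mendel_mismatch_rates(panel, self._pedigree())
        assert np.isnan(rates).all()

    def test_random_fixture_matches_brute_force(self, rng):
        n_off, n_snps = 50, 12
        sample_ids = ["SIRE"] + [f"O{i}" for i in range(n_off)]
        parents = {"SIRE": (None, None)}
        parents.update({f"O{i}": ("SIRE", None) for i in range(n_off)})
        ped = pedigree_from_parents(parents)
        calls = rng.integers(-1, 3, size=(n_off + 1, n_snps)).astype(np.int8)
        panel = make_panel(calls, sample_ids=sample_ids)
        rates = mendel_mismatch_rates(panel, ped)
        for j in range(n_snps):
            num = den = 0
            for i in range(1, n_off + 1):
                o, s = calls[i, j], calls[0, j]
                if o < 0 or s < 0:
                    continue
                den += 1
                if {o, s} == {0, 2}:
                    num += 1
            expected = num / den if den else np.nan
            if den:
                assert rates[j] == pytest.approx(expected)
            else:
                assert np.isnan(rates[j])


class TestQCFilter:
    def _clean_calls(self, rng, n_samples, n_snps, maf=0.25):
        # HWE-ish genotypes at the given MAF
        p = np.full(n_snps, maf)
        a = rng.random((n_samples, n_snps)) < p
        b = rng.random((n_samples, n_snps)) < p
        return (a.astype(np.int8) + b.astype(np.int8)).astype(np.int8)

    def test_low_maf_snps_dropped(self, rng):
        calls = self._clean_calls(rng, 400, 10)
        # force SNPs 3 and 7 to tiny MAF (2 copies in 800 alleles = 0.0025)
        for j in (3, 7):
            calls[:, j] = 0
            calls[0, j] = 1
            calls[1, j] = 1
        panel = make_panel(calls)
        filtered, report = qc_filter(panel, thresholds=QCThresholds(
            min_genotype_freq=0.0))
        assert filtered.n_snps == 8
        dropped = report[report.verdict != "kept"]
        assert set(dropped.snp_id) == {"snp3", "snp7"}
        assert (dropped.verdict == "dropped:maf").all()

    def test_order_call_rate_before_maf(self, rng):
        calls = self._clean_calls(rng, 100, 3)
        calls[:7, 0] = -1  # call rate 0.93
        calls[:, 0][calls[:, 0] > 0] = 0  # also kill MAF
        panel = make_panel(calls)
        _, report = qc_filter(panel, thresholds=QCThresholds(
            min_genotype_freq=0.0))
        assert report.loc[0, "verdict"] == "dropped:call_rate"

    def test_randomized_violations_match_recount(self, rng):
        n, m = 300, 50
        calls = self._clean_calls(rng, n, m)
        for j in range(m):
            r = rng.random()
            if r < 0.2:
                calls[: rng.integers(16, 40), j] = -1  # kill call rate
            elif r < 0.4:
                calls[:, j] = 0  # monomorphic -> MAF fail
            elif r < 0.55:
                calls[:, j] = rng.permutation(
                    np.array([1] * (n // 2) + [0] * (n - n // 2))
                ).astype(np.int8)  # het excess -> HWE fail
        panel = make_panel(calls)
        t = QCThresholds()
        filtered, report = qc_filter(panel, thresholds=t)

        # independent re-scan
        from oracles import hwe_enumeration

        keep_expected = []
        for j in range(m):
            col = calls[:, j]
            obs = col[col >= 0]
            cr = len(obs) / n
            if cr < t.min_call_rate:
                continue
            counts = [(obs == 2).sum(), (obs == 1).sum(), (obs == 0).sum()]
            p_freq = (2 * counts[0] + counts[1]) / (2 * len(obs))
            if min(p_freq, 1 - p_freq) < t.min_maf:
                continue
            observed_classes = [c for c in counts if c > 0]
            if min(observed_classes) / len(obs) < t.min_genotype_freq:
                continue
            if hwe_enumeration(*counts) < t.min_hwe_p:
                continue
            keep_expected.append(f"snp{j}")
        assert list(filtered.snps["snp_id"]) == keep_expected

    def test_idempotent(self, rng):
        calls = self._clean_calls(rng, 200, 30)
        calls[:20, 4] = -1
        panel = make_panel(calls)
        once, _ = qc_filter(panel)
        twice, report = qc_filter(once)
        assert twice.n_snps == once.n_snps
        assert (report.verdict == "kept").all()

    def test_threshold_monotonicity(self, rng):
        calls = self._clean_calls(rng, 150, 40)
        calls[:10, 2] = -1
        calls[:, 5] = 0
        panel = make_panel(calls)
        base_kept, _ = qc_filter(panel)
        relaxed = [
            QCThresholds(min_call_rate=0.5),
            QCThresholds(max_mendel_mismatch=0.5),
            QCThresholds(min_maf=0.001),
            QCThresholds(min_genotype_freq=0.0),
            QCThresholds(min_hwe_p=1e-6),
        ]
        for t in relaxed:
            kept, _ = qc_filter(panel, thresholds=t)
            assert kept.n_snps >= base_kept.n_snps

    def test_empty_panel_error(self):
        calls = np.zeros((10, 2), dtype=np.int8)  # monomorphic everywhere
        panel = make_panel(calls)
        with pytest.raises(GenotypeError, match="every SNP"):
            qc_filter(panel)


def test_orientation_invariance_of_maf_and_r2(rng):
    # flipping which allele is counted must not change MAF or r2
    from gendiv.ne_ld import pairwise_r2

    calls = rng.integers(0, 3, size=(50, 6)).astype(np.int8)
    panel = make_panel(calls, positions=np.arange(1, 7) * 200_000)
    flipped = make_panel((2 - calls).astype(np.int8),
                         positions=np.arange(1, 7) * 200_000)
    np.testing.assert_allclose(panel.maf(), flipped.maf())
    r2a = pairwise_r2(panel, 10_000_000, min_maf=0.0)
    r2b = pairwise_r2(flipped, 10_000_000, min_maf=0.0)
    np.testing.assert_allclose(r2a["r2"], r2b["r2"], atol=1e-12)
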