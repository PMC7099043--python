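import logging

import numpy as np
import pytest

from mr2sample import (
    ConfigurationError,
    LDReference,
    SelectionConfig,
    SelectionError,
    SummaryDataset,
    VariantAssociation,
    exclude_outcome_associated,
    filter_exposure_significant,
    ld_clump,
    select_instruments,
)


def _assoc(snp, p=None, beta=0.1, se=0.01, chrom="1", pos=None):
    return VariantAssociation(
        snp_id=snp, effect_allele="A", beta=beta, se=se,
        chromosome=chrom, position=pos, pvalue=p,
    )


def _dataset(assocs, name="exposure"):
    return SummaryDataset(name, assocs)


# ---------------------------------------------------------------- LDReference

class TestLDReference:
    def test_symmetry_unit_diagonal_and_defaults(self):
        ld = LDReference(
            {"a": ("1", 100), "b": ("1", 200), "c": ("2", 100)},
            {frozenset(("a", "b")): 0.7},
        )
        assert ld.r2("a", "a") == 1.0
        assert ld.r2("a", "b") == ld.r2("b", "a") == 0.7
        assert ld.r2("a", "c") == 0.0          # cross-chromosome, unlisted
        assert ld.r2("b", "c") == 0.0
        ld2 = LDReference({"a": ("1", 100), "d": ("1", 900)})
        assert ld2.r2("a", "d") is None        # same-chromosome, unknown

    def test_invalid_r2_rejected(self):
        with pytest.raises(Exception):
            LDReference({"a": ("1", 1), "b": ("1", 2)}, {frozenset(("a", "b")): 1.5})

    def test_file_round_trip(self, tmp_path):
        ld = LDReference(
            {"a": ("1", 100), "b": ("1", 200)}, {frozenset(("a", "b")): 0.25}
        )
        ld.to_files(tmp_path / "ld.tsv", tmp_path / "pos.tsv")
        again = LDReference.from_files(tmp_path / "ld.tsv", tmp_path / "pos.tsv")
        assert again.positions == ld.positions
        assert again.r2("a", "b") == 0.25


# ---------------------------------------------------------- exposure filter

class TestExposureFilter:
    def test_strict_boundary(self):
        ds = _dataset([
            _assoc("rs1", p=1e-9), _assoc("rs2", p=4.9e-8), _assoc("rs3", p=6e-8),
        ])
        kept = filter_exposure_significant(ds, 5e-8)
        assert kept.snp_ids == ["rs1", "rs2"]

    def test_threshold_one_is_identity(self):
        ds = _dataset([_assoc("rs1", p=0.5), _assoc("rs2", p=0.99)])
        assert filter_exposure_significant(ds, 1.0).snp_ids == ds.snp_ids

    def test_p_derived_from_beta_se(self):
        """A SNP with beta=0.08, se=0.01 (z=8) passes genome-wide significance
        even without a stated p-value."""
        ds = _dataset([_assoc("rs1", p=None, beta=0.08, se=0.01)])
        assert filter_exposure_significant(ds, 5e-8).snp_ids == ["rs1"]
        from scipy import stats
        assert 2 * stats.norm.sf(8) < 5e-8   # the derived two-sided tail

    def test_empty_result_is_error(self):
        ds = _dataset([_assoc("rs1", p=0.5)])
        with pytest.raises(SelectionError, match="threshold"):
            filter_exposure_significant(ds, 5e-8)


# ------------------------------------------------------- outcome exclusion

class TestOutcomeExclusion:
    def test_strictly_greater_kept(self):
        instruments = _dataset([_assoc("rs1"), _assoc("rs2")])
        outcome = _dataset(
            [_assoc("rs1", p=0.02), _assoc("rs2", p=0.06)], name="outcome"
        )
        kept = exclude_outcome_associated(instruments, outcome, 0.05)
        assert kept.snp_ids == ["rs2"]

    def test_fixture_all_retained(self, fixture_datasets):
        exposure, outcome = fixture_datasets
        kept = exclude_outcome_associated(exposure, outcome, 0.05)
        assert kept.snp_ids == exposure.snp_ids

    def test_missing_from_outcome_dropped_and_logged(self, caplog):
        instruments = _dataset([_assoc("rs1"), _assoc("rs_missing")])
        outcome = _dataset([_assoc("rs1", p=0.5)], name="outcome")
        with caplog.at_level(logging.INFO, logger="mr2sample.iv_selection"):
            kept = exclude_outcome_associated(instruments, outcome, 0.05)
        assert kept.snp_ids == ["rs1"]
        assert any("rs_missing" in rec.message for rec in caplog.records)


# ------------------------------------------------------------------ clumping

def _conflicts(ld, a, b, r2_max, window_kb, unknown_ld):
    ca, pa = ld.positions[a]
    cb, pb = ld.positions[b]
    if ca != cb or abs(pa - pb) > window_kb * 1000:
        return False
    r2 = ld.r2(a, b)
    if r2 is None:
        return unknown_ld == "conservative"
    return r2 > r2_max


def _check_greedy_dominance(instruments, ld, result_ids, r2_max=0.001,
                            window_kb=10_000.0, unknown_ld="conservative"):
    """Independent check of the clumping contract: retained SNPs are mutually
    compatible, and every removed SNP conflicts with a better-ranked
    retained one."""
    from mr2sample.iv_selection import _pvalue

    rank = {a.snp_id: (_pvalue(a), a.snp_id) for a in instruments}
    retained = set(result_ids)
    assert retained <= set(a.snp_id for a in instruments)
    for a in retained:
        for b in retained:
            if a < b:
                assert not _conflicts(ld, a, b, r2_max, window_kb, unknown_ld)
    for a in instruments:
        if a.snp_id in retained:
            continue
        assert any(
            rank[r] < rank[a.snp_id]
            and _conflicts(ld, r, a.snp_id, r2_max, window_kb, unknown_ld)
            for r in retained
        ), f"removed SNP {a.snp_id} conflicts with no better retained SNP"


class TestLDClump:
    def test_tight_pair_keeps_best_p(self):
        ds = _dataset([_assoc("rs1", p=1e-10, pos=1000),
                       _assoc("rs2", p=1e-9, pos=6000)])
        ld = LDReference({"rs1": ("1", 1000), "rs2": ("1", 6000)},
                         {frozenset(("rs1", "rs2")): 0.9})
        assert ld_clump(ds, ld).snp_ids == ["rs1"]

    def test_cross_chromosome_independent(self):
        ds = _dataset([_assoc("rs1", p=1e-10), _assoc("rs2", p=1e-9)])
        ld = LDReference({"rs1": ("1", 1000), "rs2": ("2", 1000)})
        assert sorted(ld_clump(ds, ld).snp_ids) == ["rs1", "rs2"]

    def test_two_block_structure_keeps_per_block_minima(self):
        """Six SNPs in two tight LD blocks collapse to the two per-block
        p-minima, and the result satisfies the dominance contract."""
        snps = [
            ("a1", 1e-10, 1_000), ("a2", 1e-8, 6_000), ("a3", 1e-7, 11_000),
            ("b1", 1e-9, 20_001_000), ("b2", 1e-8, 20_006_000), ("b3", 1e-6, 20_011_000),
        ]
        ds = _dataset([_assoc(s, p=p, pos=pos) for s, p, pos in snps])
        positions = {s: ("1", pos) for s, p, pos in snps}
        pairs = {}
        for i, (si, _, _) in enumerate(snps):
            for sj, _, _ in snps[i + 1:]:
                same_block = si[0] == sj[0]
                pairs[frozenset((si, sj))] = 0.8 if same_block else 0.0005
        ld = LDReference(positions, pairs)
        result = ld_clump(ds, ld)
        assert sorted(result.snp_ids) == ["a1", "b1"]
        _check_greedy_dominance(ds, ld, result.snp_ids)

    def test_missing_snp_in_reference_is_error(self):
        ds = _dataset([_assoc("rs1", p=1e-10)])
        with pytest.raises(SelectionError, match="rs1"):
            ld_clump(ds, LDReference({}))

    def test_result_sorted_by_position(self):
        ds = _dataset([_assoc("rs2", p=1e-10, pos=9_000_000),
                       _assoc("rs1", p=1e-9, pos=1_000)])
        ld = LDReference({"rs1": ("1", 1_000), "rs2": ("1", 9_000_000)},
                         {frozenset(("rs1", "rs2")): 0.0})
        assert ld_clump(ds, ld).snp_ids == ["rs1", "rs2"]

    def test_row_order_invariance(self):
        rng = np.random.default_rng(11)
        snps = [(f"rs{i}", float(rng.uniform(1e-12, 1e-6)),
                 int(rng.integers(1, 30_000_000))) for i in range(8)]
        assocs = [_assoc(s, p=p, pos=pos) for s, p, pos in snps]
        positions = {s: ("1", pos) for s, p, pos in snps}
        pairs = {
            frozenset((a, b)): float(rng.uniform(0, 1))
            for i, (a, _, _) in enumerate(snps) for b, _, _ in snps[i + 1:]
        }
        ld = LDReference(positions, pairs)
        forward = ld_clump(_dataset(assocs), ld)
        backward = ld_clump(_dataset(assocs[::-1]), ld)
        assert forward.snp_ids == backward.snp_ids

    @pytest.mark.parametrize("seed", range(12))
    def test_random_instances_satisfy_dominance_oracle(self, seed):
        """Greedy clumping agrees with the brute-force dominance check on
        random instances of up to 10 SNPs, including unknown-LD pairs."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 11))
        snps = []
        positions = {}
        for i in range(n):
            snp = f"rs{i}"
            chrom = str(rng.integers(1, 3))
            pos = int(rng.integers(1, 25_000_000))
            snps.append(_assoc(snp, p=float(rng.uniform(1e-12, 1e-6)),
                               chrom=chrom, pos=pos))
            positions[snp] = (chrom, pos)
        pairs = {}
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < 0.7:   # leave ~30% of pairs unknown
                    pairs[frozenset((snps[i].snp_id, snps[j].snp_id))] = float(
                        rng.choice([0.0, 0.0005, 0.05, 0.5, 0.95])
                    )
        ld = LDReference(positions, pairs)
        unknown_ld = "conservative" if seed % 2 == 0 else "permissive"
        result = ld_clump(_dataset(snps), ld, unknown_ld=unknown_ld)
        _check_greedy_dominance(_dataset(snps), ld, result.snp_ids,
                                unknown_ld=unknown_ld)


# --------------------------------------------------------- full selection

def _selection_scenario():
    """10 SNPs with known fates: 2 fail exposure significance, 1 lost to
    clumping, 1 outcome-associated -> counts 10, 8, 7, 6."""
    exposure_rows, outcome_rows, positions, pairs = [], [], {}, {}
    for i in range(10):
        snp = f"rs{i:02d}"
        p_exp = 1e-3 if i in (8, 9) else 1e-10 * (i + 1)
        pos = 1_000 + i * 100_000
        exposure_rows.append(_assoc(snp, p=p_exp, pos=pos))
        outcome_rows.append(_assoc(snp, p=0.01 if i == 7 else 0.5, pos=pos))
        positions[snp] = ("1", pos)
    for i in range(10):
        for j in range(i + 1, 10):
            pairs[frozenset((f"rs{i:02d}", f"rs{j:02d}"))] = (
                0.9 if {i, j} == {0, 1} else 0.0
            )
    return (
        _dataset(exposure_rows),
        _dataset(outcome_rows, name="outcome"),
        LDReference(positions, pairs),
    )


class TestSelectInstruments:
    def test_permissive_thresholds_identity(self):
        exposure, outcome, ld = _selection_scenario()
        cfg = SelectionConfig(
            exposure_p_max=1.0, outcome_p_min=1e-9, r2_max=0.999, window_kb=0.001
        )
        kept = select_instruments(exposure, outcome, ld, cfg)
        assert sorted(kept.snp_ids) == sorted(exposure.snp_ids)

    def test_stage_counts_logged(self, caplog):
        exposure, outcome, ld = _selection_scenario()
        with caplog.at_level(logging.INFO, logger="mr2sample.iv_selection"):
            kept = select_instruments(exposure, outcome, ld, SelectionConfig())
        assert len(kept) == 6
        count_logs = [r.message for r in caplog.records if "counts" in r.message]
        assert count_logs and "input=10" in count_logs[-1]
        assert "significant=8" in count_logs[-1]
        assert "clumped=7" in count_logs[-1]
        assert "outcome_excluded=6" in count_logs[-1]

    def test_idempotent(self):
        exposure, outcome, ld = _selection_scenario()
        once = select_instruments(exposure, outcome, ld, SelectionConfig())
        twice = select_instruments(once, outcome, ld, SelectionConfig())
        assert twice.snp_ids == once.snp_ids

    def test_config_validation(self):
        with pytest.raises(ConfigurationError):
            SelectionConfig(r2_max=0.0)
        with pytest.raises(ConfigurationError):
            SelectionConfig(outcome_p_min=1.5)
        with pytest.raises(ConfigurationError):
            SelectionConfig(unknown_ld="optimistic")
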