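"""Quantification contracts: the K2P closed form and its properties,
read mapping, abundance arithmetic, landscape conservation and the
sex-bias table."""

import math

import numpy as np
import pytest

from satellitome._align import AlignedReadHit
from satellitome._seq import Read, revcomp
from satellitome.quantification import (
    build_landscape,
    family_abundance,
    k2p_distance,
    k2p_from_counts,
    library_size_bp,
    library_totals,
    map_reads,
    sex_bias_table,
    subtract_landscapes,
)
from satellitome.synthetic_data import (
    FamilySpec,
    LibrarySpec,
    make_consensus,
    mutate_copy,
    plant_genome,
    simulate_library,
    _family_consensus,
)


def _hit(family="f", library_cols=100, ts=0, tv=0, read_id="r"):
    h = AlignedReadHit(
        read_id=read_id,
        family_id=family,
        strand="+",
        aligned_columns=library_cols,
        matches=library_cols - ts - tv,
        transitions=ts,
        transversions=tv,
        identity=(library_cols - ts - tv) / library_cols,
        gap_columns=0,
        blocks=((0, library_cols, 0, library_cols),),
        read_seq="A" * library_cols,
        rul=36,
    )
    h.k2p = k2p_from_counts(ts, tv, library_cols)
    h.saturated = math.isnan(h.k2p)
    return h


class TestK2P:
    def test_zero_distance(self):
        assert k2p_distance(0.0, 0.0) == 0.0
        assert k2p_from_counts(0, 0, 100) == 0.0

    def test_worked_value(self):
        # direct evaluation of K = -1/2 ln[(1-2P-Q) sqrt(1-2Q)]
        assert k2p_distance(0.1, 0.05) == pytest.approx(0.17018, abs=5e-6)

    def test_matches_direct_evaluation_on_grid(self):
        ps = np.linspace(0.0, 0.35, 36)
        qs = np.linspace(0.0, 0.35, 36)
        for p in ps:
            for q in qs:
                if 1 - 2 * p - q <= 0 or 1 - 2 * q <= 0:
                    continue
                direct = -0.5 * math.log((1 - 2 * p - q) * math.sqrt(1 - 2 * q))
                assert abs(k2p_distance(p, q) - direct) < 1e-12

    def test_correction_inflates_raw_distance(self):
        rng = np.random.default_rng(0)
        for _ in range(300):
            p, q = rng.uniform(0, 0.3, 2)
            if 1 - 2 * p - q <= 0 or 1 - 2 * q <= 0:
                continue
            if p + q == 0:
                continue
            assert k2p_distance(p, q) > p + q

    def test_monotone_in_each_argument(self):
        grid = np.linspace(0.0, 0.2, 21)
        for q in (0.0, 0.05, 0.1):
            vals = k2p_distance(grid, q)
            assert (np.diff(vals) > 0).all()
        for p in (0.0, 0.05, 0.1):
            vals = k2p_distance(p, grid)
            assert (np.diff(vals) > 0).all()

    def test_saturation_flagged_as_nan(self):
        assert math.isnan(k2p_distance(0.5, 0.1))
        assert math.isnan(k2p_distance(0.1, 0.5))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            k2p_from_counts(-1, 0, 10)


class TestMapReads:
    def test_exact_monomer_copy(self):
        cons = make_consensus(36, 0.6, 1)
        hits = map_reads([Read("r0", cons)], cons, min_aligned=30)
        assert len(hits) == 1
        h = hits[0]
        assert h.transitions == 0 and h.transversions == 0
        assert h.k2p == 0.0 and h.identity == 1.0

    def test_junction_read_gets_full_length_hit(self):
        cons = make_consensus(36, 0.6, 2)
        # read starting mid-monomer spans three junctions
        read = (cons * 4)[20:120]
        hits = map_reads([Read("j", read)], cons)
        assert len(hits) == 1
        assert hits[0].aligned_columns == 100

    def test_reverse_strand_hit(self):
        cons = make_consensus(36, 0.6, 3)
        read = revcomp((cons * 4)[10:110])
        hits = map_reads([Read("m", read)], cons)
        assert len(hits) == 1 and hits[0].strand == "-"
        assert hits[0].identity == 1.0

    def test_planted_divergence_recovered(self):
        spec = FamilySpec(
            "d8", rul=36, divergence_target=0.08, copies_female=300, n_loci_female=2
        )
        genome, _ = plant_genome([spec], 150_000, "female", 4)
        reads = simulate_library(
            genome, LibrarySpec("L", n_reads=10_000, seed=5, error_rate=0.0)
        )
        hits = map_reads(reads, _family_consensus(spec, 4))
        w = np.array([h.aligned_columns for h in hits], dtype=float)
        k = np.array([h.k2p for h in hits])
        assert 0.07 <= (w * k).sum() / w.sum() <= 0.09


class TestFamilyAbundance:
    def test_abundance_arithmetic(self):
        hits = [_hit(read_id=f"r{i}") for i in range(100)]
        rec = family_abundance(hits, 10_000_000)
        assert rec.abundance == pytest.approx(0.001)
        assert rec.aligned_nt == 10_000
        assert rec.mean_divergence == 0.0

    def test_no_hits_is_zero_abundance_missing_divergence(self):
        rec = family_abundance([], 1_000_000)
        assert rec.abundance == 0.0
        assert rec.mean_divergence is None

    def test_planted_family_recovered_within_15pct(self):
        spec = FamilySpec(
            "p3", rul=33, divergence_target=0.05, copies_female=300, n_loci_female=2
        )
        genome, truth = plant_genome([spec], 150_000, "female", 6)
        reads = simulate_library(
            genome, LibrarySpec("L", n_reads=15_000, seed=7, error_rate=0.0)
        )
        hits = map_reads(reads, _family_consensus(spec, 6))
        rec = family_abundance(hits, library_size_bp(reads))
        want = truth.proportion("p3", "female")
        assert abs(rec.abundance - want) / want < 0.15


class TestLandscapes:
    def test_zero_divergence_lands_in_first_bin(self):
        hits = [_hit(read_id=f"r{i}") for i in range(10)]
        ls = build_landscape(hits, 1_000_000)
        assert ls.bins[0] == pytest.approx(1000 / 1_000_000)
        assert ls.bins[1:].sum() == 0

    def test_bins_sum_to_abundance(self):
        rng = np.random.default_rng(8)
        hits = []
        for i in range(500):
            ts = int(rng.integers(0, 12))
            tv = int(rng.integers(0, 8))
            hits.append(_hit(ts=ts, tv=tv, read_id=f"r{i}"))
        ls = build_landscape(hits, 3_333_331)
        rec = family_abundance(hits, 3_333_331)
        assert ls.total() == pytest.approx(rec.abundance, abs=1e-12)

    def test_modal_bin_tracks_planted_divergence(self):
        cons = make_consensus(5000, 0.6, 9)
        hits = []
        for i in range(200):
            copy = mutate_copy(cons[:100], 0.10, 2.0, 500 + i)
            ts = sum(
                1 for a, b in zip(cons[:100], copy)
                if a != b and (a in "AG") == (b in "AG")
            )
            tv = sum(
                1 for a, b in zip(cons[:100], copy)
                if a != b and (a in "AG") != (b in "AG")
            )
            hits.append(_hit(ts=ts, tv=tv, read_id=f"r{i}"))
        ls = build_landscape(hits, 100_000)
        assert int(np.argmax(ls.bins)) in (9, 10, 11)

    def test_subtract_antisymmetric_and_identity(self):
        hits = [_hit(ts=3, read_id=f"r{i}") for i in range(50)]
        f = build_landscape(hits, 1_000_000, "fam", "female")
        m = build_landscape(hits[:30], 1_000_000, "fam", "male")
        zero = subtract_landscapes(f, f)
        assert (zero.bins == 0).all()
        ab = subtract_landscapes(f, m)
        ba = subtract_landscapes(m, f)
        assert np.allclose(ab.bins, -ba.bins)

    def test_mismatched_families_rejected(self):
        f = build_landscape([], 1000, "famA", "female")
        m = build_landscape([], 1000, "famB", "male")
        with pytest.raises(ValueError):
            subtract_landscapes(f, m)


class TestSexBias:
    def _rec(self, fam, lib, abundance):
        from satellitome.quantification import AbundanceRecord

        return AbundanceRecord(fam, lib, abundance, 5.0, int(abundance * 1e7), 10)

    def test_ratio_and_classes(self):
        table = sex_bias_table(
            [self._rec("a", "f", 0.02), self._rec("b", "f", 0.01), self._rec("c", "f", 0.0)],
            [self._rec("a", "m", 0.01), self._rec("b", "m", 0.01), self._rec("c", "m", 0.005)],
        )
        t = table.set_index("family_id")
        assert t.loc["a", "fm_ratio"] == 2.0
        assert t.loc["a", "bias_class"] == "female-biased"
        assert t.loc["b", "bias_class"] == "balanced"
        assert t.loc["c", "bias_class"] == "male-exclusive"

    def test_female_exclusive_sentinel(self):
        table = sex_bias_table([self._rec("x", "f", 0.001)], [self._rec("x", "m", 0.0)])
        assert table.iloc[0]["bias_class"] == "female-exclusive"
        assert table.iloc[0]["fm_ratio"] == math.inf

    def test_ratio_monotone_in_female_abundance(self):
        ratios = [
            sex_bias_table([self._rec("x", "f", a)], [self._rec("x", "m", 0.01)])
            .iloc[0]["fm_ratio"]
            for a in (0.005, 0.01, 0.02, 0.04)
        ]
        assert ratios == sorted(ratios) and len(set(ratios)) == 4

    def test_absent_from_both_dropped(self):
        table = sex_bias_table([self._rec("x", "f", 0.0)], [self._rec("x", "m", 0.0)])
        assert table.empty


class TestLibraryTotals:
    def _recs(self, lib, values):
        from satellitome.quantification import AbundanceRecord

        return [
            AbundanceRecord(f"f{i}", lib, v, None, 0, 0) for i, v in enumerate(values)
        ]

    def test_enrichment_from_percent_totals(self):
        totals = library_totals(
            {"female": self._recs("female", [0.03, 0.0183]),
             "male": self._recs("male", [0.03, 0.0123])}
        )
        assert totals.totals["female"] == pytest.approx(0.0483)
        assert totals.totals["male"] == pytest.approx(0.0423)
        assert totals.enrichment_percent_rounded == 14

    def test_equal_totals_zero_enrichment(self):
        totals = library_totals(
            {"female": self._recs("female", [0.01]), "male": self._recs("male", [0.01])}
        )
        assert totals.enrichment_percent == 0.0

    def test_zero_male_total_flagged_undefined(self):
        totals = library_totals(
            {"female": self._recs("female", [0.01]), "male": self._recs("male", [0.0])}
        )
        assert totals.enrichment_percent is None
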