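import math

import numpy as np
import pytest

from panevo.io import GeneRecord
from panevo.hgt import (
    HGTFlags,
    call_hchtg,
    codon_metrics,
    mobile_context,
    nearest_rank_percentile,
    _FAMILIES,
)
from panevo.simulate import AA_TO_CODONS, CodonSimParams, simulate_cds


def gene_from_codons(gene_id, codons, start=1):
    seq = "".join(codons)
    return GeneRecord("contig_1", gene_id, start, start + len(seq) - 1, "+",
                      ["hypothetical protein"], seq)


def uniform_gene(gene_id, repeat=10):
    """Every degenerate sense codon used `repeat` times."""
    codons = []
    for fam in _FAMILIES.values():
        codons.extend(fam * repeat)
    return gene_from_codons(gene_id, codons)


def one_codon_per_family_gene(gene_id, repeat=10):
    codons = []
    for fam in _FAMILIES.values():
        codons.extend([fam[0]] * (len(fam) * repeat))
    return gene_from_codons(gene_id, codons)


class TestClosedForms:
    def test_uniform_usage_gene(self):
        genes = [uniform_gene(f"g{i}") for i in range(3)]
        profiles, _ = codon_metrics(genes)
        p = profiles[0]
        assert p.enc == 61.0
        assert all(v == pytest.approx(1.0) for v in p.rscu.values())
        assert p.rscu_deviation == pytest.approx(0.0, abs=1e-12)

    def test_single_codon_per_family_gene(self):
        genes = [one_codon_per_family_gene(f"g{i}") for i in range(3)]
        profiles, _ = codon_metrics(genes)
        assert profiles[0].enc == 20.0

    def test_reference_optimal_gene_has_cai_one(self):
        opt = one_codon_per_family_gene("opt", repeat=20)
        filler = [uniform_gene(f"g{i}") for i in range(3)]
        profiles, _ = codon_metrics([opt] + filler,
                                    reference_gene_ids=["opt"])
        by_id = {p.gene_id: p for p in profiles}
        assert by_id["opt"].cai == pytest.approx(1.0, abs=1e-12)

    def test_two_fold_family_worked_example(self):
        # Phe (TTT/TTC) with counts (3, 1): RSCU = (1.5, 0.5),
        # F = (4*(9/16 + 1/16) - 1)/3 = 0.5
        from panevo.hgt import _CODON_INDEX, _rscu
        counts = np.zeros(61)
        for c in ["TTT"] * 3 + ["TTC"]:
            counts[_CODON_INDEX[c]] += 1
        rscu = _rscu(counts)
        assert rscu["TTT"] == pytest.approx(1.5)
        assert rscu["TTC"] == pytest.approx(0.5)
        n, p2 = 4, (3 / 4) ** 2 + (1 / 4) ** 2
        assert (n * p2 - 1) / (n - 1) == pytest.approx(0.5)

    def test_gc_fraction(self):
        g = gene_from_codons("g", ["GGG", "AAA"])
        profiles, _ = codon_metrics([g, uniform_gene("u")])
        by_id = {p.gene_id: p for p in profiles}
        assert by_id["g"].gc == pytest.approx(0.5)


class TestInvariances:
    def test_rscu_family_sums_equal_family_size(self, rng):
        genes, _ = simulate_cds(CodonSimParams(n_native=5, n_alien=0,
                                               seed=8))
        profiles, _ = codon_metrics(genes)
        for p in profiles:
            for aa, fam in _FAMILIES.items():
                vals = [p.rscu[c] for c in fam]
                if any(math.isnan(v) for v in vals):
                    continue
                assert sum(vals) == pytest.approx(len(fam))

    def test_self_concatenation_leaves_metrics_unchanged(self):
        genes, _ = simulate_cds(CodonSimParams(n_native=5, n_alien=0,
                                               seed=9))
        ref = uniform_gene("ref")  # fixed CAI reference in both runs
        p1, _ = codon_metrics(genes + [ref], reference_gene_ids=["ref"])
        # doubling a CDS would introduce an internal stop; double the
        # stop-free body instead
        bodies = [g.cds_sequence[:-3] for g in genes]
        doubled = [GeneRecord("c", g.gene_id, 1, 2 * len(b), "+",
                              g.product_labels, b + b)
                   for g, b in zip(genes, bodies)]
        p2, _ = codon_metrics(doubled + [ref], reference_gene_ids=["ref"])
        for a, b in zip(p1, p2):
            # Wright's F carries a finite-sample correction, so ENC moves
            # slightly toward its asymptote when counts double
            assert b.enc == pytest.approx(a.enc, abs=2.0)
            assert b.cai == pytest.approx(a.cai, abs=1e-9)
            for c in a.rscu:
                if not math.isnan(a.rscu[c]):
                    assert b.rscu[c] == pytest.approx(a.rscu[c], abs=1e-9)

    def test_synonymous_permutation_preserves_enc(self, rng):
        genes, _ = simulate_cds(CodonSimParams(n_native=3, n_alien=0,
                                               seed=10))
        from panevo.hgt import _CODON_INDEX, _enc, _codon_counts
        for g in genes:
            counts, _ = _codon_counts(g.cds_sequence)
            permuted = counts.copy()
            for fam in _FAMILIES.values():
                idx = [_CODON_INDEX[c] for c in fam]
                permuted[idx] = counts[list(np.random.default_rng(1)
                                            .permutation(idx))]
            assert _enc(permuted) == pytest.approx(_enc(counts))

    def test_internal_stop_and_bad_length_excluded(self, caplog):
        bad_len = GeneRecord("c", "bad_len", 1, 7, "+", [], "ATGAAAT")
        internal_stop = gene_from_codons("stopgene",
                                         ["ATG", "TAA", "AAA", "CCC"])
        ok = uniform_gene("ok")
        with caplog.at_level("WARNING", logger="panevo"):
            profiles, _ = codon_metrics([bad_len, internal_stop, ok])
        assert {p.gene_id for p in profiles} == {"ok"}
        assert "not divisible by 3" in caplog.text
        assert "internal stop" in caplog.text


class TestScreen:
    def test_nearest_rank_percentile(self):
        vals = list(range(1, 101))
        assert nearest_rank_percentile(vals, 0.90) == 90
        assert nearest_rank_percentile(vals, 0.10) == 10

    def test_rank_arithmetic_flags(self):
        genes, _ = simulate_cds(CodonSimParams(n_native=100, n_alien=0,
                                               seed=11))
        profiles, thr = codon_metrics(genes)
        flags = {f.gene_id: f for f in call_hchtg(profiles, thr)}
        ranked_gc = sorted(profiles, key=lambda p: p.gc)
        top = ranked_gc[-1]
        assert flags[top.gene_id].flag_gc
        bottom = ranked_gc[0]
        assert not flags[bottom.gene_id].flag_gc

    def test_flag_rate_is_ten_percent_by_construction(self):
        genes, _ = simulate_cds(CodonSimParams(n_native=200, n_alien=0,
                                               seed=12))
        profiles, thr = codon_metrics(genes)
        flags = call_hchtg(profiles, thr)
        n = len(flags)
        for attr in ("flag_gc", "flag_rscu", "flag_enc", "flag_cai"):
            rate = sum(getattr(f, attr) for f in flags) / n
            assert rate <= 0.10 + 1e-9
            assert rate >= 0.10 - 2 / n  # nearest-rank granularity
        hchtg_rate = sum(f.is_hchtg for f in flags) / n
        assert hchtg_rate <= 0.10

    def test_planted_alien_recovery(self):
        genes, truth = simulate_cds(CodonSimParams(seed=13))
        profiles, thr = codon_metrics(genes)
        flags = call_hchtg(profiles, thr)
        tp = sum(f.is_hchtg for f in flags if truth[f.gene_id] == "alien")
        fp = sum(f.is_hchtg for f in flags if truth[f.gene_id] == "native")
        assert tp / 50 >= 0.8
        assert fp / 950 <= 0.05

    def test_mixed_genome_rejected(self):
        genes, _ = simulate_cds(CodonSimParams(n_native=60, n_alien=0,
                                               seed=14))
        profiles, thr = codon_metrics(genes, genome_id="genomeA")
        with pytest.raises(ValueError, match="mixed-genome"):
            call_hchtg(profiles, thr, genome_id="genomeB")

    def test_abs_deviation_mode_flags_low_gc(self):
        genes, truth = simulate_cds(CodonSimParams(
            n_native=190, n_alien=10, native_gc=0.55, alien_gc=0.45,
            seed=15))
        profiles, thr = codon_metrics(genes)
        raw = {f.gene_id: f for f in call_hchtg(profiles, thr)}
        dev = {f.gene_id: f
               for f in call_hchtg(profiles, thr, mode="abs_deviation")}
        aliens = [g for g, k in truth.items() if k == "alien"]
        # low-GC aliens are invisible to the raw upper tail but not to the
        # absolute-deviation variant
        assert sum(raw[a].flag_gc for a in aliens) == 0
        assert sum(dev[a].flag_gc for a in aliens) >= 8


class TestMobileContext:
    def make_flags(self, gene_ids):
        return [HGTFlags(g, True, True, True, True, True) for g in gene_ids]

    def test_window_boundaries(self):
        focal = GeneRecord("c1", "focal", 5000, 6000, "+", ["x"], "")
        for start, expect in [(6500, True),   # gap 499
                              (8001, True),   # gap 2000, inclusive
                              (8002, False)]: # gap 2001
            tn = GeneRecord("c1", "tn", start, start + 999, "+",
                            ["IS3 family transposase"], "")
            out = mobile_context(self.make_flags(["focal"]), [focal, tn])
            assert out[0].near_transposase is expect, start

    def test_overlap_counts_as_zero_gap(self):
        focal = GeneRecord("c1", "focal", 5000, 6000, "+", ["x"], "")
        tn = GeneRecord("c1", "tn", 5500, 7000, "+", ["transposase"], "")
        out = mobile_context(self.make_flags(["focal"]), [focal, tn])
        assert out[0].near_transposase is True

    def test_other_contig_never_near(self):
        focal = GeneRecord("c1", "focal", 5000, 6000, "+", ["x"], "")
        tn = GeneRecord("c2", "tn", 6100, 6500, "+", ["transposase"], "")
        out = mobile_context(self.make_flags(["focal"]), [focal, tn])
        assert out[0].near_transposase is False

    def test_gene_without_coordinates_undefined(self):
        tn = GeneRecord("c1", "tn", 100, 400, "+", ["transposase"], "")
        out = mobile_context(self.make_flags(["ghost"]), [tn])
        assert out[0].near_transposase is None
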