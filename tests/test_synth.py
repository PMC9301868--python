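"""Generator determinism, planted-signal calibration, truth serialization."""

import numpy as np
import pytest

from ernascape.motifs import scan_wbox
from ernascape.synth import (
    SyntheticTruth,
    generate_accessibility,
    generate_coexpression,
    generate_genome,
    generate_methylome,
    generate_stranded_rna,
)

SMALL = dict(n_chroms=1, chrom_len=400_000, n_genes=30, n_enhancers=18)


@pytest.fixture(scope="module")
def small_genome():
    return generate_genome(seed=7, **SMALL)


class TestGenome:
    def test_deterministic_for_fixed_seed(self):
        a1, s1, t1 = generate_genome(seed=3, **SMALL)
        a2, s2, t2 = generate_genome(seed=3, **SMALL)
        assert all(np.array_equal(s1[c], s2[c]) for c in s1)
        assert t1.to_json() == t2.to_json()
        assert [g.name for g in a1.genes] == [g.name for g in a2.genes]

    def test_no_genes_still_valid(self):
        ann, seqs, _ = generate_genome(n_chroms=1, chrom_len=50_000, n_genes=0,
                                       n_enhancers=3, seed=0)
        assert ann.genes == []
        assert seqs["chr1"].size == 50_000

    def test_gene_layout_respects_spacers(self, small_genome):
        ann, _, _ = small_genome
        genes = sorted(ann.genes, key=lambda g: g.start)
        gaps = [b.start - a.end for a, b in zip(genes, genes[1:])]
        assert min(gaps) >= 3000

    def test_planted_wbox_counts_match_scan_of_emitted_sequence(self, small_genome):
        _, seqs, truth = small_genome
        for e in truth.enhancers:
            text = seqs[e.interval.chrom][e.interval.start:e.interval.end].tobytes().decode()
            assert len(scan_wbox(text)) == e.wbox_count

    def test_enhancers_clear_of_genes(self, small_genome):
        ann, _, truth = small_genome
        for e in truth.enhancers:
            for g in ann.genes:
                assert not e.interval.expanded(1500).overlaps(g)


class TestTruthSerialization:
    def test_json_round_trip_lossless(self, small_genome, tmp_path):
        _, _, truth = small_genome
        path = tmp_path / "truth.json"
        truth.save(path)
        back = SyntheticTruth.load(path)
        assert back.to_json() == truth.to_json()


class TestAccessibility:
    def test_in_peak_coverage_mean(self, small_genome):
        ann, _, truth = small_genome
        rep1, _ = generate_accessibility(ann, truth, background_rate=0.02, fold=10)
        in_peak = np.concatenate([rep1[iv.chrom][iv.start:iv.end]
                                  for iv, _ in truth.planted_peaks])
        mean = in_peak.mean()
        se = np.sqrt(0.2 / in_peak.size)
        assert abs(mean - 0.2) < 3 * se

    def test_replicates_reproducible_and_independent(self, small_genome):
        ann, _, truth = small_genome
        a1, a2 = generate_accessibility(ann, truth, seed=5)
        b1, _ = generate_accessibility(ann, truth, seed=5)
        assert np.array_equal(a1["chr1"], b1["chr1"])
        assert not np.array_equal(a1["chr1"], a2["chr1"])


@pytest.fixture(scope="module")
def rna(small_genome):
    ann, _, truth = small_genome
    return generate_stranded_rna(ann, truth, ["mock", "flg22"],
                                 background_rate=0.0005, erna_reads=100.0,
                                 induction_fold=4.0, seed=21)


class TestStrandedRna:
    def test_uni_plus_antisense_share_near_five_percent(self, small_genome, rna):
        _, _, truth = small_genome
        tracks, _ = rna
        sense = anti = 0
        for e in truth.enhancers:
            if e.direction != "uni+":
                continue
            sense += tracks["mock"]["+"][e.erna.chrom][e.erna.start:e.erna.end].sum()
            anti += tracks["mock"]["-"][e.erna.chrom][e.erna.start:e.erna.end].sum()
        total = sense + anti
        assert total > 0
        share = anti / total
        se = np.sqrt(0.05 * 0.95 / total)
        assert abs(share - 0.05) < 4 * se

    def test_induction_fold_recovered_as_log2fc(self, small_genome, rna):
        _, _, truth = small_genome
        tracks, _ = rna
        ratios = []
        for e in truth.enhancers:
            if "flg22" not in e.induced_by or not e.transcribed:
                continue
            mock = sum(tracks["mock"][s][e.erna.chrom][e.erna.start:e.erna.end].sum()
                       for s in "+-")
            tr = sum(tracks["flg22"][s][e.erna.chrom][e.erna.start:e.erna.end].sum()
                     for s in "+-")
            if mock > 0:
                ratios.append(np.log2(tr / mock))
        assert ratios and abs(np.mean(ratios) - 2.0) < 0.35

    def test_nontranscribed_enhancer_background_only(self, small_genome, rna):
        ann, _, truth = small_genome
        tracks, _ = rna
        quiet = [e for e in truth.enhancers if not e.transcribed]
        reads = sum(tracks["mock"][s][e.interval.chrom]
                    [e.interval.start - 400:e.interval.end + 400].sum()
                    for e in quiet for s in "+-")
        bases = sum(e.interval.length + 800 for e in quiet) * 2
        lam = bases * 0.0005
        assert reads < lam + 5 * np.sqrt(lam)


class TestMethylome:
    def test_zero_coverage_empty_table(self, small_genome):
        ann, seqs, truth = small_genome
        assert generate_methylome(ann, seqs, truth, coverage_mean=0).empty

    def test_planted_umr_windows_hypomethylated(self, small_genome):
        ann, seqs, truth = small_genome
        meth = generate_methylome(ann, seqs, truth, coverage_mean=30, seed=9)
        chrom_calls = meth[meth.chrom == "chr1"]
        ok = total = 0
        for u in truth.umrs[:20]:
            for w0 in range(u.start, u.end - 99, 100):
                win = chrom_calls[(chrom_calls.pos >= w0) & (chrom_calls.pos < w0 + 100)]
                if win.total.sum() == 0 or win.total.mean() < 10:
                    continue  # planted missing-data stretch
                total += 1
                ok += win.meth.sum() / win.total.sum() < 0.10
        assert total > 20 and ok / total > 0.99

    def test_reproducible(self, small_genome):
        ann, seqs, truth = small_genome
        m1 = generate_methylome(ann, seqs, truth, 12.0, seed=4)
        m2 = generate_methylome(ann, seqs, truth, 12.0, seed=4)
        assert m1.equals(m2)


class TestCoexpression:
    def test_zero_noise_gives_perfect_module_correlation(self, small_genome):
        _, _, truth = small_genome
        expr = generate_coexpression(truth, n_samples=8, r_target=0.5,
                                     noise_sd=0.0, seed=2)
        m = truth.modules[0]
        members = [m["enhancer"], *m["genes"]]
        corr = np.corrcoef(expr.loc[members].to_numpy())
        assert np.allclose(corr, 1.0)

    def test_calibration_hits_target_correlation(self, rng):
        # 50 modules of 4 features, no genome needed: exercise the calibration
        truth = SyntheticTruth(
            modules=[{"enhancer": f"e{m}", "genes": [f"g{m}_{j}" for j in range(3)],
                      "r_target": 0.95} for m in range(50)],
            seeds={"coexpr": 77},
        )
        expr = generate_coexpression(truth, n_samples=12, r_target=0.95)
        within = []
        for m in truth.modules:
            members = [m["enhancer"], *m["genes"]]
            corr = np.corrcoef(expr.loc[members].to_numpy())
            iu = np.triu_indices(len(members), k=1)
            within.extend(corr[iu])
        assert 0.90 <= np.mean(within) <= 0.99

    def test_between_module_correlation_low(self):
        truth = SyntheticTruth(
            modules=[{"enhancer": f"e{m}", "genes": [f"g{m}_{j}" for j in range(3)],
                      "r_target": 0.95} for m in range(20)],
            seeds={"coexpr": 5},
        )
        expr = generate_coexpression(truth, n_samples=12, r_target=0.95)
        firsts = expr.loc[[m["enhancer"] for m in truth.modules]].to_numpy()
        corr = np.corrcoef(firsts)
        iu = np.triu_indices(len(firsts), k=1)
        assert np.median(np.abs(corr[iu])) < 0.35

    def test_invalid_target_rejected(self):
        with pytest.raises(ValueError):
            generate_coexpression(SyntheticTruth(seeds={"coexpr": 1}), r_target=1.0)
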