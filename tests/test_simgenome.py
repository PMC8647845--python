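"""Generator behavior: compartment structure, Hi-C statistics, LTR pairs."""

import numpy as np
import pytest
from scipy import stats

from centel import io, teevo
from centel.simgenome import (
    FamilyConfig,
    SimConfig,
    expected_cis,
    expected_pair_identity,
    k2p_substitution_probs,
    mutate_sequence,
    simulate_genome,
    simulate_hic,
    simulate_ltr_loci,
)


def _cen_interval(cfg, model, chrom):
    half = cfg.centromere_width // 2
    lo = model.true_centromeres[chrom] - half + 1
    return lo, lo + cfg.centromere_width - 1


class TestConfigValidation:
    def test_centromere_wider_than_chromosome_rejected(self):
        with pytest.raises(ValueError, match="centromere width"):
            SimConfig(chrom_lengths=(400_000,), centromere_width=500_000)

    def test_bad_hic_parameters_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(hic_alpha=0.0)
        with pytest.raises(ValueError):
            SimConfig(hic_sigma=-1.0)

    def test_proportions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="proportions"):
            SimConfig(ist_proportions=(0.5, 0.5, 0.5))


class TestGenomeSimulation:
    def test_zero_outside_density_confines_family(self):
        fams = {"LINE1": FamilyConfig(density_in=80.0, density_out=0.0,
                                      has_sequence=False)}
        cfg = SimConfig(chrom_lengths=(3_000_000,) * 3, families=fams, seed=5)
        model, elements = simulate_genome(cfg)
        assert elements
        for el in elements:
            lo, hi = _cen_interval(cfg, model, el.chrom)
            assert lo <= el.midpoint <= hi

    def test_equal_densities_give_length_proportional_fraction(self):
        # pooled over 20 seeds the inside fraction is binomial with
        # p = centromere span / genome span
        fams = {"X": FamilyConfig(density_in=30.0, density_out=30.0,
                                  has_sequence=False)}
        inside = total = 0
        for seed in range(20):
            cfg = SimConfig(chrom_lengths=(2_000_000,) * 3, families=fams,
                            seed=seed)
            model, elements = simulate_genome(cfg)
            total += len(elements)
            inside += sum(e.compartment == "cen" for e in elements)
        p = cfg.centromere_width * 3 / model.genome_length
        sd = np.sqrt(total * p * (1 - p))
        assert abs(inside - total * p) < 3 * sd

    def test_compartment_density_contrast_recovered(self):
        fams = {"LINE1": FamilyConfig(density_in=200.0, density_out=20.0,
                                      has_sequence=False)}
        cfg = SimConfig(chrom_lengths=(5_000_000,) * 3, families=fams, seed=3)
        model, elements = simulate_genome(cfg)
        assert len(elements) >= 500
        n_in = sum(e.compartment == "cen" for e in elements)
        n_out = len(elements) - n_in
        span_in = cfg.centromere_width * 3
        span_out = model.genome_length - span_in
        ratio = (n_in / span_in) / (n_out / span_out)
        assert 0.8 * 10 <= ratio <= 1.2 * 10

    def test_same_seed_gives_byte_identical_bed(self, tmp_path):
        cfg = SimConfig(chrom_lengths=(2_000_000,) * 2, seed=9)
        for k in (1, 2):
            _, elements = simulate_genome(cfg)
            io.write_bed(tmp_path / f"run{k}.bed", elements, {"seed": cfg.seed})
        assert (tmp_path / "run1.bed").read_bytes() == (tmp_path / "run2.bed").read_bytes()

    def test_genes_depleted_and_gc_elevated_in_centromere(self, small_genome,
                                                          small_config):
        model, elements = small_genome
        genes = [e for e in elements if e.family == "gene"]
        frac_cen = sum(e.compartment == "cen" for e in genes) / len(genes)
        span_frac = small_config.centromere_width * 3 / model.genome_length
        assert frac_cen < span_frac  # depleted relative to span

        def gc(e):
            return (e.sequence.count("G") + e.sequence.count("C")) / len(e.sequence)

        line1 = [e for e in elements if e.family == "LINE1" and e.sequence]
        gc_in = np.mean([gc(e) for e in line1 if e.compartment == "cen"])
        gc_out = np.mean([gc(e) for e in line1 if e.compartment == "arm"])
        assert gc_in > gc_out


class TestHiCSimulation:
    def test_cis_decay_closed_form(self):
        # alpha = 1, no noise floor: distance 2 has half the expectation of 1
        cfg = SimConfig(hic_alpha=1.0, hic_trans_background=0.0)
        e = expected_cis(np.array([1, 2]), cfg)
        assert e[1] == pytest.approx(e[0] / 2)

    def test_map_is_symmetric(self, small_hic):
        assert np.array_equal(small_hic.counts, small_hic.counts.T)

    def test_same_seed_same_map(self, small_config, small_genome):
        model, _ = small_genome
        m1 = simulate_hic(model, small_config)
        m2 = simulate_hic(model, small_config)
        assert np.array_equal(m1.counts, m2.counts)

    def test_total_count_matches_poisson_expectation(self, small_config,
                                                     small_genome):
        model, _ = small_genome
        cmap = simulate_hic(model, small_config)
        # reconstruct the expected upper-triangle total independently
        exp_total = 0.0
        names = model.chrom_names
        cen_bin = {c: (model.true_centromeres[c] - 1) // model.bin_size
                   for c in names}
        from centel.simgenome import expected_trans

        for i, a in enumerate(names):
            na = model.n_bins(a)
            idx = np.arange(na)
            dist = np.abs(idx[:, None] - idx[None, :])
            cis = expected_cis(dist, small_config)
            exp_total += np.triu(cis).sum()
            for b in names[i + 1 :]:
                nb = model.n_bins(b)
                block = expected_trans(np.arange(na) - cen_bin[a],
                                       np.arange(nb) - cen_bin[b], small_config)
                exp_total += block.sum()
        obs_total = np.triu(cmap.counts).sum()
        assert abs(obs_total - exp_total) < 4 * np.sqrt(exp_total)

    def test_trans_uniform_without_bump(self):
        # bump 0 -> homogeneous Poisson trans block; chi-square uniformity
        # non-significant at 0.01 in >= 18 of 20 seeds
        ok = 0
        for seed in range(20):
            cfg = SimConfig(chrom_lengths=(2_000_000,) * 2, hic_bump=0.0,
                            hic_trans_background=5.0, seed=seed)
            model, _ = simulate_genome(cfg)
            cmap = simulate_hic(model, cfg)
            block = cmap.trans_block("Chr01", "Chr02").ravel()
            stat = ((block - block.mean()) ** 2 / block.mean()).sum()
            p = stats.chi2.sf(stat, len(block) - 1)
            ok += p > 0.01
        assert ok >= 18


class TestLTRSimulation:
    def test_age_zero_pairs_identical(self):
        cfg = SimConfig(seed=2, n_ltr_loci=20, ltr_age_mya=0.0,
                        ist_proportions=(1, 0, 0))
        for lc in simulate_ltr_loci(cfg):
            assert lc.ltr5_seq == lc.ltr3_seq
            est = teevo.k2p_divergence(lc.ltr5_seq, lc.ltr3_seq)
            assert est.K == 0.0

    def test_mean_estimated_age_unbiased_at_one_mya(self):
        # 200 loci at T = 1 MYA, kappa = 2: mean estimated age in [0.9, 1.1]
        # pooled over 20 seeds
        ages = []
        for seed in range(20):
            cfg = SimConfig(seed=seed, n_ltr_loci=200, ltr_age_mya=1.0,
                            kappa=2.0, ist_proportions=(1, 0, 0))
            df = teevo.date_elements(loci=simulate_ltr_loci(cfg))
            ages.extend(df[df.status == "ok"].t_mya)
        assert 0.9 <= np.mean(ages) <= 1.1

    def test_all_intact_when_proportions_degenerate(self):
        from centel.ltrdem import classify_ltr_locus

        cfg = SimConfig(seed=4, n_ltr_loci=30, ist_proportions=(1, 0, 0))
        loci = simulate_ltr_loci(cfg)
        assert all(classify_ltr_locus(lc) == "I" for lc in loci)

    def test_old_age_warns_and_flags(self):
        # expected pair identity <= 80% at this age and rate
        age = 12.0
        assert expected_pair_identity(age, 1.3e-8, 2.0) <= 0.80
        cfg = SimConfig(seed=1, n_ltr_loci=5, ltr_age_mya=age)
        with pytest.warns(UserWarning, match="identity"):
            loci = simulate_ltr_loci(cfg)
        assert all(lc.flagged for lc in loci)

    def test_seed_determinism_across_all_outputs(self, tmp_path):
        cfg = SimConfig(seed=17, n_ltr_loci=25)
        for k in (1, 2):
            loci = simulate_ltr_loci(cfg)
            io.write_ltr_loci(tmp_path / f"l{k}.gff3", tmp_path / f"l{k}.fa",
                              tmp_path / f"l{k}.hits", tmp_path / f"l{k}.scf",
                              loci, {"seed": cfg.seed})
        for ext in ("gff3", "fa", "hits", "scf"):
            assert (tmp_path / f"l1.{ext}").read_bytes() == \
                (tmp_path / f"l2.{ext}").read_bytes()


class TestMutationProcess:
    def test_substitution_probs_sum_to_one_and_jc_limit(self):
        p_same, p_ts, p_tv = k2p_substitution_probs(0.3, kappa=0.5)
        assert p_same + p_ts + p_tv == pytest.approx(1.0)
        # kappa = 0.5 (alpha = beta) is Jukes-Cantor: transitions are one of
        # three equally likely substitution types
        assert p_ts == pytest.approx(p_tv / 2, rel=1e-9)

    def test_mutation_rate_matches_expectation(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 30_000))
        d = 0.1
        mut = mutate_sequence(seq, d, kappa=2.0, rng=rng)
        diff = sum(a != b for a, b in zip(seq, mut)) / len(seq)
        p_same, _, _ = k2p_substitution_probs(d, 2.0)
        assert diff == pytest.approx(1 - p_same, abs=0.01)
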