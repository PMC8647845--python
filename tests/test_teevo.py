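"""ORF finding, K2P divergence, insertion dating, rank-sum statistics."""

import math
import re

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from centel.core import CentromereRegion, ElementRecord
from centel.simgenome import SimConfig, mutate_sequence, simulate_ltr_loci
from centel.teevo import (
    SaturationError,
    classify_intact_line1,
    compare_compartments,
    date_elements,
    find_orfs,
    insertion_time,
    k2p_divergence,
    rank_sum_test,
)

_COMP = str.maketrans("ACGT", "TGCA")


def _oracle_orfs(seq: str, min_len: int) -> set[tuple[str, int, int]]:
    """Independent regex-based six-frame scan (strand, start, end)."""
    found = set()
    n = len(seq)
    for strand in ("+", "-"):
        s = seq if strand == "+" else seq.translate(_COMP)[::-1]
        for frame in range(3):
            codons = [s[i : i + 3] for i in range(frame, n - 2, 3)]
            text = "".join("s" if c in ("TAA", "TAG", "TGA")
                           else "n" if "N" in c
                           else "m" if c == "ATG" else "." for c in codons)
            # first start after a stop/N/sequence edge, up to the next stop
            # (lookahead keeps the stop available as the next boundary)
            for match in re.finditer(r"(?:^|[sn])[.]*?(m[m.]*?)(?=s)", text):
                i0 = match.start(1)
                i1 = match.end(1)
                length = (i1 - i0) * 3
                if length < min_len:
                    continue
                a = frame + i0 * 3
                b = frame + i1 * 3 - 1
                if strand == "+":
                    found.add((strand, a + 1, b + 1))
                else:
                    found.add((strand, n - b, n - a))
    return found


class TestFindOrfs:
    def test_single_long_orf_found(self):
        seq = "CC" + "ATG" + "GCT" * 298 + "TAA" + "GG"
        orfs = find_orfs(seq)
        assert len(orfs) == 1
        assert orfs[0].length == 897

    def test_below_minsize_excluded(self):
        seq = "ATG" + "GCT" * 264 + "TAA"  # 792-nt coding stretch
        assert find_orfs(seq) == []

    def test_n_breaks_orf(self):
        seq = "ATG" + "GCT" * 150 + "NNN" + "GCT" * 150 + "TAA"
        assert find_orfs(seq, min_len=400) == []

    def test_matches_brute_force_six_frame_scan(self, rng):
        seq = "".join(rng.choice(list("ACGT"), p=[0.3, 0.2, 0.2, 0.3], size=10_000))
        for min_len in (60, 150):
            mine = {(o.strand, o.start, o.end) for o in find_orfs(seq, min_len)}
            assert mine == _oracle_orfs(seq, min_len)


class TestIntactLine1:
    def _orfs(self):
        seq = "ATG" + "GCA" * 300 + "TAG"
        return find_orfs(seq, element_id="el1")

    def test_rt_and_en_make_intact(self):
        orfs = self._orfs()
        hits = pd.DataFrame(
            [{"element": "el1", "orf": orfs[0].orf_id, "domain": "RVT_1"},
             {"element": "el1", "orf": orfs[0].orf_id, "domain": "Exo_endo_phos"}]
        )
        assert classify_intact_line1("el1", orfs, hits)

    def test_rt_only_not_intact(self):
        orfs = self._orfs()
        hits = pd.DataFrame([{"element": "el1", "orf": orfs[0].orf_id,
                              "domain": "RVT_1"}])
        assert not classify_intact_line1("el1", orfs, hits)

    def test_no_qualifying_orf_never_intact(self):
        hits = pd.DataFrame(columns=["element", "orf", "domain"])
        assert not classify_intact_line1("el1", [], hits)

    def test_unknown_orf_reference_errors(self):
        orfs = self._orfs()
        hits = pd.DataFrame([{"element": "el1", "orf": "ghost", "domain": "RVT_1"}])
        with pytest.raises(ValueError, match="unknown ORFs"):
            classify_intact_line1("el1", orfs, hits)


class TestK2P:
    def test_identical_sequences_zero(self):
        est = k2p_divergence("ACGTACGT", "ACGTACGT")
        assert (est.P, est.Q, est.K) == (0.0, 0.0, 0.0)

    def test_closed_form_one_transition_one_transversion(self):
        # 10 sites, 1 transition (A->G), 1 transversion (C->G)
        a = "AAAAACCCCC"
        b = "GAAAACCCCG"
        est = k2p_divergence(a, b)
        assert est.P == pytest.approx(0.1)
        assert est.Q == pytest.approx(0.1)
        assert est.K == pytest.approx(0.23412, abs=1e-5)

    def test_closed_form_p01_q005(self):
        # 20 sites: 2 transitions, 1 transversion
        a = "A" * 20
        b = "GG" + "T" + "A" * 17
        est = k2p_divergence(a, b)
        assert (est.P, est.Q) == (0.1, 0.05)
        assert est.K == pytest.approx(0.17018, abs=1e-5)

    def test_gap_and_ambiguous_columns_excluded(self):
        # gap and N columns drop out; T vs A is one transversion over 4 sites
        est = k2p_divergence("ACGT-N", "ACGAAA")
        assert est.sites == 4
        assert est.P == 0.0
        assert est.Q == pytest.approx(0.25)

    def test_saturation_raises(self):
        with pytest.raises(SaturationError):
            k2p_divergence("A" * 10, "G" * 10)  # P = 1

    def test_reduces_to_jukes_cantor_at_kappa_half(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 40_000))
        other = mutate_sequence(seq, 0.2, kappa=0.5, rng=rng)
        est = k2p_divergence(seq, other)
        p_diff = 1 - sum(a == b for a, b in zip(seq, other)) / len(seq)
        jc = -0.75 * math.log(1 - 4 * p_diff / 3)
        assert est.K == pytest.approx(jc, rel=0.02)


class TestInsertionTime:
    def test_zero_divergence_zero_age(self):
        assert insertion_time(0.0) == 0.0

    def test_known_arithmetic(self):
        assert insertion_time(0.026) / 1e6 == pytest.approx(1.0)
        assert insertion_time(0.17018) / 1e6 == pytest.approx(6.545, abs=1e-3)

    @settings(deadline=None, derandomize=True)
    @given(st.floats(min_value=0, max_value=2), st.floats(min_value=0.1, max_value=10))
    def test_linearity_in_k(self, K, a):
        assert insertion_time(a * K) == pytest.approx(a * insertion_time(K))

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ValueError):
            insertion_time(0.1, rate=0.0)


class TestDateElements:
    def test_zero_age_loci_date_to_zero(self):
        cfg = SimConfig(seed=8, n_ltr_loci=15, ltr_age_mya=0.0,
                        ist_proportions=(1, 0, 0))
        df = date_elements(loci=simulate_ltr_loci(cfg))
        assert (df.status == "ok").all()
        assert (df.t_mya == 0).all()

    def test_age_ordering_preserved(self):
        medians = {}
        for age in (0.5, 2.0):
            cfg = SimConfig(seed=12, n_ltr_loci=100, ltr_age_mya=age,
                            ist_proportions=(1, 0, 0))
            df = date_elements(loci=simulate_ltr_loci(cfg))
            medians[age] = df.t_mya.median()
        assert medians[0.5] < medians[2.0]

    def test_missing_partner_flagged_not_dropped(self):
        cfg = SimConfig(seed=8, n_ltr_loci=30, ist_proportions=(0, 1, 0))
        df = date_elements(loci=simulate_ltr_loci(cfg))
        assert len(df) == 30
        assert (df.status == "missing_partner").all()

    def test_saturated_pair_censored(self):
        pairs = {"x": ("A" * 300, "G" * 300)}
        df = date_elements(pairs=pairs, mode="best_hit")
        assert df.status.iloc[0] == "saturated"
        assert np.isnan(df.t_mya.iloc[0])

    def test_best_hit_mode_with_indels(self):
        rng = np.random.default_rng(5)
        a = "".join(rng.choice(list("ACGT"), 500))
        b = a[:200] + a[230:]  # 30-bp deletion, otherwise identical
        df = date_elements(pairs={"x": (a, b)}, mode="best_hit")
        assert df.status.iloc[0] == "ok"
        assert df.K.iloc[0] == pytest.approx(0.0, abs=1e-6)


class TestRankSum:
    def test_identical_samples_give_p_one(self):
        res = rank_sum_test([1, 2, 3], [1, 2, 3])
        assert res.z == 0.0
        assert res.p == 1.0

    def test_all_values_identical_degenerate(self):
        res = rank_sum_test([5, 5, 5], [5, 5, 5])
        assert res.degenerate
        assert res.p == 1.0

    def test_complete_separation_exact_p(self):
        res = rank_sum_test([1, 2, 3], [4, 5, 6], alternative="less")
        assert res.U == 0.0
        assert res.p == pytest.approx(0.05)  # 1 of C(6,3)=20 splits

    def test_exact_matches_permutation_oracle(self, rng):
        from itertools import combinations

        for trial in range(15):
            n1, n2 = rng.integers(3, 9, size=2)
            vals = rng.normal(size=n1 + n2)
            if trial % 3 == 0:
                vals = np.round(vals)
            res = rank_sum_test(vals[:n1], vals[n1:])
            ranks = stats.rankdata(vals)
            obs = abs(res.U - n1 * n2 / 2)
            cnt = tot = 0
            for idx in combinations(range(n1 + n2), int(n1)):
                u = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2
                cnt += abs(u - n1 * n2 / 2) >= obs - 1e-9
                tot += 1
            assert res.p == pytest.approx(cnt / tot, abs=1e-12)

    def test_normal_approximation_close_to_exact_at_moderate_n(self, rng):
        for _ in range(10):
            a = rng.normal(size=15)
            b = rng.normal(0.5, size=15)
            p_norm = rank_sum_test(a, b, method="normal").p
            p_mc = stats.mannwhitneyu(a, b, method="exact").pvalue
            assert p_norm == pytest.approx(p_mc, abs=0.01)


class TestCompareCompartments:
    def _elements(self, rng, n_in=200, n_out=200, med_in=3000, med_out=1500):
        regions = [CentromereRegion("Chr01", 1_000_001, 2_000_000)]
        els = []
        for i in range(n_in):
            L = int(rng.lognormal(math.log(med_in), 0.3))
            els.append(ElementRecord("Chr01", 1_500_000, 1_500_000 + L,
                                     "LINE1", f"in{i}"))
        for i in range(n_out):
            L = int(rng.lognormal(math.log(med_out), 0.3))
            els.append(ElementRecord("Chr01", 5_000_000, 5_000_000 + L,
                                     "LINE1", f"out{i}"))
        return els, regions

    def test_length_effect_detected(self, rng):
        els, regions = self._elements(rng)
        df = compare_compartments(els, regions)
        assert df.len_p.iloc[0] < 0.01
        assert df.len_median_in.iloc[0] > df.len_median_out.iloc[0]

    def test_empty_compartment_flagged(self, rng):
        els, _ = self._elements(rng, n_in=0)
        df = compare_compartments(els, [])
        assert bool(df.flagged.iloc[0])
        assert np.isnan(df.len_p.iloc[0])

    def test_ages_compared_when_supplied(self, rng):
        els, regions = self._elements(rng, n_in=50, n_out=50)
        dates = {e.element_id: (0.5 if e.element_id.startswith("in") else 2.0)
                 + rng.uniform(0, 0.1) for e in els}
        df = compare_compartments(els, regions, dates)
        assert df.age_median_in.iloc[0] < df.age_median_out.iloc[0]
        assert df.age_p.iloc[0] < 0.01
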