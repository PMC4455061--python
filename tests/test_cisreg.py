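"""TRAP affinity scoring, SNP motif impact, density and enrichment tests."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from riboflow.cisreg import (
    PWM,
    affinity_pvalue,
    default_r0,
    ora_hypergeometric,
    pwm_class_test,
    snp_density_compare,
    snp_motif_impact,
    toy_pwms,
    trap_affinity,
)

RC = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def _poly_a_pwm(width=6, info=0.9):
    m = np.full((4, width), (1 - info) / 3)
    m[0] = info
    return PWM("polyA", m)


class TestTrapAffinity:
    def test_consensus_single_window_closed_form(self):
        pwm = _poly_a_pwm(6)
        r0 = default_r0(6)
        # forward window has E=0 -> occupancy r0/(1+r0); the reverse strand
        # (all T against a poly-A PWM) contributes essentially nothing
        aff = trap_affinity("A" * 6, pwm)
        assert aff == pytest.approx(r0 / (1 + r0), rel=1e-6)

    def test_uniform_pwm_ignores_sequence(self):
        m = np.full((4, 5), 0.25)
        pwm = PWM("uniform", m)
        assert trap_affinity("ACGTACGTA", pwm) == pytest.approx(
            trap_affinity("TTTTTTTTT", pwm), abs=1e-12
        )

    def test_two_window_toy_hand_computed(self):
        mat = np.array([[0.6, 0.1], [0.2, 0.5], [0.1, 0.3], [0.1, 0.1]])  # A,C,G,T x 2
        pwm = PWM("toy", mat)
        lam, r0 = 0.7, float(np.e**4)
        seq = "ACG"
        # manual enumeration over both strands' windows
        base_idx = {"A": 0, "C": 1, "G": 2, "T": 3}
        pmax = pwm.matrix.max(axis=0)
        total = 0.0
        for s in (seq, "".join(RC[b] for b in reversed(seq))):
            for i in range(2):
                e = sum(
                    np.log(pmax[j] / pwm.matrix[base_idx[s[i + j]], j]) for j in range(2)
                ) / lam
                x = r0 * np.exp(-e)
                total += x / (1 + x)
        assert trap_affinity(seq, pwm, lam, r0) == pytest.approx(total, abs=1e-12)

    def test_n_base_uses_column_average(self):
        pwm = _poly_a_pwm(4)
        a_n = trap_affinity("ANAA", pwm)
        # an N contributes the column-average probability, so the score lies
        # between the worst and best single-base variants
        vals = [trap_affinity(f"A{b}AA", pwm) for b in "ACGT"]
        assert min(vals) <= a_n <= max(vals)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_strand_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGT"), 30))
        rc = "".join(RC[b] for b in reversed(seq))
        pwm = toy_pwms(1, 6, seed=seed).pwms[0]
        assert trap_affinity(seq, pwm) == pytest.approx(trap_affinity(rc, pwm), rel=1e-9)

    def test_too_short_sequence_rejected(self):
        with pytest.raises(ValueError, match="short"):
            trap_affinity("ACG", _poly_a_pwm(6))


class TestAffinityPvalue:
    def test_uniform_pwm_ties_give_one(self):
        pwm = PWM("uniform", np.full((4, 5), 0.25))
        p = affinity_pvalue("ACGTACGTACGTACGT", pwm, n_shuffles=200, seed=0)
        assert p == pytest.approx(1.0)

    def test_consensus_site_is_extreme(self):
        pwm = toy_pwms(1, 8, seed=3).pwms[0]
        rng = np.random.default_rng(4)
        seq = "".join(rng.choice(list("ACGT"), 60)) + pwm.consensus() + "".join(
            rng.choice(list("ACGT"), 33)
        )
        assert affinity_pvalue(seq, pwm, n_shuffles=400, seed=5) <= 5 / 401

    def test_deterministic_and_minimum_shuffles_enforced(self):
        pwm = toy_pwms(1, 6, seed=1).pwms[0]
        seq = "ACGTACGTACGTACGTACGT"
        a = affinity_pvalue(seq, pwm, n_shuffles=200, seed=2)
        b = affinity_pvalue(seq, pwm, n_shuffles=200, seed=2)
        assert a == b
        with pytest.raises(ValueError, match="n_shuffles"):
            affinity_pvalue(seq, pwm, n_shuffles=50, seed=0)


class TestSnpImpact:
    def _variant(self, flank5, ref, alt, flank3):
        return {"flank5": flank5, "ref": ref, "alt": alt, "flank3": flank3,
                "pos": len(flank5) + 1, "gene": "g1"}

    def test_degenerate_ref_equals_alt(self):
        pwm = toy_pwms(1, 6, seed=6).pwms[0]
        v = self._variant("ACGT" * 12 + "AC", "A", "A", "GT" + "ACGT" * 12)
        out = snp_motif_impact(v, pwm, n_shuffles=200, seed=0)
        assert out["impact"] == 0.0

    def test_uniform_pwm_impact_near_zero(self):
        pwm = PWM("uniform", np.full((4, 6), 0.25))
        v = self._variant("ACGT" * 12 + "AC", "A", "T", "GT" + "ACGT" * 12)
        out = snp_motif_impact(v, pwm, n_shuffles=200, seed=1)
        assert out["impact"] == pytest.approx(0.0, abs=1e-9)

    def test_symmetry_in_alleles(self):
        pwm = toy_pwms(1, 6, seed=7).pwms[0]
        v1 = self._variant("ACGT" * 12 + "AC", "A", "T", "GT" + "ACGT" * 12)
        v2 = self._variant("ACGT" * 12 + "AC", "T", "A", "GT" + "ACGT" * 12)
        a = snp_motif_impact(v1, pwm, n_shuffles=200, seed=2)["impact"]
        b = snp_motif_impact(v2, pwm, n_shuffles=200, seed=2)["impact"]
        assert a == pytest.approx(b, abs=1e-12)

    def test_reference_mismatch_detected(self):
        pwm = toy_pwms(1, 6, seed=8).pwms[0]
        v = self._variant("AC", "A", "T", "GTAC")
        with pytest.raises(ValueError, match="reference mismatch"):
            snp_motif_impact(v, pwm, utr_seq="ACCGTAC", n_shuffles=200, seed=0)

    def test_motif_disruption_beats_off_motif_snp(self):
        rng = np.random.default_rng(9)
        pwm = toy_pwms(1, 8, seed=9).pwms[0]
        cons = pwm.consensus()
        wins = 0
        n_trials = 20
        for i in range(n_trials):
            bg = "".join(rng.choice(list("ACGT"), 101))
            seq = bg[:46] + cons + bg[54:]
            worst = "ACGT"[int(pwm.matrix[:, 4].argmin())]
            v_hit = {"flank5": seq[:50], "ref": seq[50], "alt": worst,
                     "flank3": seq[51:]}
            off = seq[10]
            v_off = {"flank5": seq[:10], "ref": off,
                     "alt": rng.choice([b for b in "ACGT" if b != off]),
                     "flank3": seq[11:61]}
            hit = snp_motif_impact(v_hit, pwm, n_shuffles=200, seed=100 + i)["impact"]
            miss = snp_motif_impact(v_off, pwm, n_shuffles=200, seed=100 + i)["impact"]
            wins += hit > miss
        assert wins / n_trials >= 0.95


class TestPwmClassTest:
    def test_single_pwm_q_equals_p(self):
        imp = pd.DataFrame({
            "snp_id": [f"s{i}" for i in range(8)],
            "pwm_id": "pwm00",
            "impact": [3.0, 2.5, 2.8, 3.2, 0.1, 0.2, 0.15, 0.1],
        })
        classes = pd.Series(["RIBO_only"] * 4 + ["RNA+RIBO"] * 4,
                            index=[f"s{i}" for i in range(8)])
        out = pwm_class_test(imp, classes)
        assert out["qvalue"].iloc[0] == pytest.approx(out["pvalue"].iloc[0])

    def test_small_class_skipped(self):
        imp = pd.DataFrame({"snp_id": ["s0", "s1", "s2"], "pwm_id": "pwm00",
                            "impact": [1.0, 2.0, 3.0]})
        classes = pd.Series(["RIBO_only", "RNA+RIBO", "RNA+RIBO"],
                            index=["s0", "s1", "s2"])
        out = pwm_class_test(imp, classes)
        assert out["skipped"].iloc[0]


class TestSnpDensity:
    def test_density_arithmetic(self):
        variants = pd.DataFrame({"gene": ["g1"] * 3}, index=["s0", "s1", "s2"])
        lengths = pd.Series({"g1": 1500.0, "g2": 1000.0})
        classes = pd.Series({"g1": "RIBO_only", "g2": "RNA+RIBO"})
        out = snp_density_compare(variants, lengths, classes)
        assert out["median_a"].iloc[0] == pytest.approx(2.0)
        assert out["median_b"].iloc[0] == pytest.approx(0.0)

    def test_missing_utr_reported(self):
        variants = pd.DataFrame({"gene": ["g1", "gX"]}, index=["s0", "s1"])
        lengths = pd.Series({"g1": 1000.0, "g2": 1000.0})
        classes = pd.Series({"g1": "RIBO_only", "g2": "RNA+RIBO"})
        out = snp_density_compare(variants, lengths, classes)
        assert out["n_excluded_no_utr"].iloc[0] == 1


class TestORA:
    def test_full_overlap_combinatorial_value(self):
        universe = [f"g{i}" for i in range(20)]
        out = ora_hypergeometric(universe[:5], {"p": universe[:5]}, universe)
        assert out.loc["p", "pvalue"] == pytest.approx(1.0 / 15504, rel=1e-9)

    def test_agrees_with_exhaustive_enumeration(self):
        rng = np.random.default_rng(10)
        universe = [f"g{i}" for i in range(12)]
        gene_set = list(rng.choice(universe, 5, replace=False))
        pathway = set(rng.choice(universe, 6, replace=False))
        k_obs = len(pathway & set(gene_set))
        if k_obs < 2:
            gene_set = list(pathway)[:3] + [g for g in universe if g not in pathway][:2]
            k_obs = len(pathway & set(gene_set))
        count = sum(
            1 for comb in itertools.combinations(universe, len(gene_set))
            if len(pathway & set(comb)) >= k_obs
        )
        exact = count / len(list(itertools.combinations(universe, len(gene_set))))
        out = ora_hypergeometric(gene_set, {"p": pathway}, universe)
        assert out.loc["p", "pvalue"] == pytest.approx(exact, rel=1e-9)

    def test_min_overlap_filter(self):
        universe = [f"g{i}" for i in range(20)]
        out = ora_hypergeometric(universe[:1], {"p": universe[:5]}, universe)
        assert len(out) == 0

    def test_gene_set_equals_universe(self):
        universe = [f"g{i}" for i in range(15)]
        out = ora_hypergeometric(universe, {"p": universe[:6]}, universe)
        assert out["pvalue"].iloc[0] == pytest.approx(1.0)

    def test_empty_universe_errors(self):
        with pytest.raises(ValueError, match="universe"):
            ora_hypergeometric(["g1"], {"p": {"g1"}}, [])
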