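"""Column profiles: backgrounds, Gaussian relative entropy, conservation tiers."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from csmotif.column_profiling import (
    SIGMA_FLOOR,
    build_background,
    classify_tier,
    gaussian_kl,
    profile_columns,
)
from csmotif.msa_io import Alignment, AlignmentContentError
from csmotif.pcp_space import STANDARD_RESIDUES
from csmotif.synthetic_data import SyntheticSpec, generate_msa


class TestClassifyTier:
    @pytest.mark.parametrize("f,tier", [
        (0.95, "high"),        # > 90% identical
        (0.80, "intermediate"),  # inside 75-90%
        (0.90, "intermediate"),  # closed upper boundary
        (0.75, "intermediate"),  # closed lower boundary
        (0.74, "low"),
        (1.0, "high"),
        (0.0, "low"),
    ])
    def test_thresholds(self, f, tier):
        assert classify_tier(f) == tier

    def test_agrees_with_three_way_oracle_on_fine_grid(self):
        for i in range(1001):
            f = i / 1000
            if f > 0.90:
                expected = "high"
            elif f < 0.75:
                expected = "low"
            else:
                expected = "intermediate"
            assert classify_tier(f) == expected

    @given(st.floats(min_value=0, max_value=1, allow_nan=False))
    @settings(derandomize=True)
    def test_total_on_unit_interval(self, f):
        assert classify_tier(f) in {"high", "intermediate", "low"}

    @pytest.mark.parametrize("f", [-0.1, 1.1, 2.0])
    def test_out_of_range_rejected(self, f):
        with pytest.raises(ValueError):
            classify_tier(f)


class TestBackground:
    def test_flat_background_is_table_mean(self, table):
        aln = Alignment((("a", "W"), ("b", "W")))
        bg = build_background(aln, table, "flat_composition")
        mat = table.matrix()
        np.testing.assert_allclose(bg.mean, mat.mean(axis=0), atol=1e-12)
        np.testing.assert_allclose(bg.sd, mat.std(axis=0, ddof=0), atol=1e-12)

    def test_one_copy_of_each_residue_pools_to_flat(self, table):
        half = len(STANDARD_RESIDUES) // 2
        aln = Alignment((
            ("a", STANDARD_RESIDUES[:half]),
            ("b", STANDARD_RESIDUES[half:]),
        ))
        pooled = build_background(aln, table, "pooled_alignment")
        flat = build_background(aln, table, "flat_composition")
        np.testing.assert_allclose(pooled.mean, flat.mean, atol=1e-12)
        np.testing.assert_allclose(pooled.sd, flat.sd, atol=1e-12)

    def test_pooled_background_matches_bruteforce_over_flat_residue_list(self, table):
        aln, _ = generate_msa(SyntheticSpec(n_seqs=200, n_cols=50, seed=11,
                                            gap_rate=0.05))
        bg = build_background(aln, table, "pooled_alignment")
        # independent single pass: flatten, look up, accumulate
        vecs = [table.vector(c) for _, seq in aln.records for c in seq if c != "-"]
        stack = np.stack(vecs)
        np.testing.assert_allclose(bg.mean, stack.mean(axis=0), atol=1e-10)
        np.testing.assert_allclose(bg.sd, stack.std(axis=0, ddof=0), atol=1e-10)

    def test_all_gap_alignment_rejected(self, table):
        aln = Alignment((("a", "--"), ("b", "--")))
        with pytest.raises(AlignmentContentError):
            build_background(aln, table, "pooled_alignment")


def _kl_quadrature(mu, sd, mu_bg, sd_bg):
    """Numerical-integration oracle for KL of two univariate Gaussians.

    Works in log densities so tail underflow of the reference density
    cannot blow up the integrand.
    """
    from scipy.stats import norm

    def integrand(x):
        logp = norm.logpdf(x, mu, sd)
        return np.exp(logp) * (logp - norm.logpdf(x, mu_bg, sd_bg))

    val, _ = quad(integrand, mu - 12 * sd, mu + 12 * sd, limit=200)
    return val


class TestRelativeEntropy:
    def test_closed_form_matches_quadrature_on_random_pairs(self, rng):
        for _ in range(50):
            mu, mu_bg = rng.normal(0, 0.3, size=2)
            sd, sd_bg = rng.uniform(0.05, 0.6, size=2)
            assert gaussian_kl(mu, sd, mu_bg, sd_bg) == pytest.approx(
                _kl_quadrature(mu, sd, mu_bg, sd_bg), abs=1e-6
            )

    def test_column_equal_to_background_pool_has_zero_re(self, table):
        # one column holding one copy of each residue, pooled background
        aln = Alignment(tuple((f"s{i}", r) for i, r in enumerate(STANDARD_RESIDUES)))
        bg = build_background(aln, table, "pooled_alignment")
        prof = profile_columns(aln, table, bg)[0]
        assert np.all(prof.re_components <= 1e-9)
        assert prof.re <= 1e-9

    def test_specified_column_against_flat_background_matches_oracle(self, table):
        residues = "DDDDEEKKNQ"  # 10-residue column, fixed by hand
        aln = Alignment(tuple((f"s{i}", r) for i, r in enumerate(residues)))
        bg = build_background(aln, table, "flat_composition")
        prof = profile_columns(aln, table, bg)[0]
        vecs = np.stack([table.vector(r) for r in residues])
        for k in range(5):
            expect = _kl_quadrature(vecs[:, k].mean(), vecs[:, k].std(ddof=0),
                                    bg.mean[k], bg.sd[k])
            assert prof.re_components[k] == pytest.approx(expect, abs=1e-6)

    def test_invariant_column_is_fully_conserved(self, table):
        aln = Alignment((("a", "W"), ("b", "W"), ("c", "W")))
        bg = build_background(aln, table, "flat_composition")
        prof = profile_columns(aln, table, bg)[0]
        assert prof.identity_fraction == 1.0
        assert prof.tier == "high"
        assert np.all(prof.sds == SIGMA_FLOOR)

    def test_re_invariant_to_sequence_order(self, table, tiny_alignment):
        bg = build_background(tiny_alignment, table, "flat_composition")
        shuffled = Alignment(tuple(reversed(tiny_alignment.records)))
        a = [p.re for p in profile_columns(tiny_alignment, table, bg)]
        b = [p.re for p in profile_columns(shuffled, table, bg)]
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_gap_rows_do_not_shift_column_statistics(self, table):
        with_gaps = Alignment((
            ("a", "DK"), ("b", "DW"), ("c", "-A"), ("d", "DC"), ("e", "-G"),
        ))
        without = Alignment((("a", "DK"), ("b", "DW"), ("d", "DC")))
        bg = build_background(with_gaps, table, "flat_composition")
        pg = profile_columns(with_gaps, table, bg)[0]
        pn = profile_columns(without, table, bg)[0]
        np.testing.assert_allclose(pg.means, pn.means, atol=1e-12)
        np.testing.assert_allclose(pg.sds, pn.sds, atol=1e-12)
        assert pg.identity_fraction == pn.identity_fraction == 1.0

    def test_all_gap_column_flagged_not_fatal(self, table):
        aln = Alignment((("a", "A-"), ("b", "C-"), ("c", "D-")))
        bg = build_background(aln, table, "pooled_alignment")
        prof = profile_columns(aln, table, bg)[1]
        assert prof.gap_fraction == 1.0
        assert prof.re == 0.0
        assert prof.tier == "low"
        assert prof.modal_residue is None

    def test_unknown_residue_excluded_like_gap(self, table):
        aln = Alignment((("a", "D"), ("b", "D"), ("c", "X")))
        bg = build_background(aln, table, "flat_composition")
        prof = profile_columns(aln, table, bg)[0]
        assert prof.identity_fraction == 1.0  # X not in the denominator
        assert prof.gap_fraction == pytest.approx(1 / 3)

    def test_mean_re_strictly_increases_with_planted_conservation(self, table):
        # sharpening a column raises its divergence from a flat background
        from csmotif.synthetic_data import PlantedBlock

        for seed in range(20):
            res = []
            for f in (0.5, 0.7, 0.9, 1.0):
                spec = SyntheticSpec(
                    n_seqs=500, n_cols=1,
                    planted=(PlantedBlock(0, "W", f),), seed=seed,
                )
                aln, _ = generate_msa(spec)
                bg = build_background(aln, table, "flat_composition")
                res.append(profile_columns(aln, table, bg)[0].re)
            assert all(b > a for a, b in zip(res, res[1:])), (seed, res)

    def test_binned_method_agrees_on_ordering(self, table, tiny_alignment):
        bg = build_background(tiny_alignment, table, "flat_composition")
        gaussian = profile_columns(tiny_alignment, table, bg, method="gaussian")
        binned = profile_columns(tiny_alignment, table, bg, method="binned")
        # the conserved block (columns 1-6) outranks the variable flanks
        for profs in (gaussian, binned):
            block = np.mean([profs[c].re for c in range(1, 7)])
            flank = np.mean([profs[c].re for c in (0, 9)])
            assert block > flank

    def test_sum_aggregation_is_five_times_mean(self, table, tiny_alignment):
        bg = build_background(tiny_alignment, table, "flat_composition")
        mean_profs = profile_columns(tiny_alignment, table, bg, aggregate="mean")
        sum_profs = profile_columns(tiny_alignment, table, bg, aggregate="sum")
        for pm, ps in zip(mean_profs, sum_profs):
            assert ps.re == pytest.approx(5 * pm.re, rel=1e-12)
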