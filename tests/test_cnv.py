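import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from triorecess.cnv import (
    CnvCall,
    DepthProfile,
    call_cnv,
    copy_score,
    depth_qc_summary,
    filter_common_cnv,
    pool_median,
    reference_correlation,
)
from triorecess.model import PipelineConfig


def profile(depths, sample_id="s", chrom="1"):
    depths = np.asarray(depths, float)
    targets = [(chrom, i * 1000, i * 1000 + 200) for i in range(len(depths))]
    return DepthProfile(sample_id, targets, depths)


class TestReferenceCorrelation:
    def test_self_correlation_is_one(self):
        p = profile([10, 50, 20, 80, 40])
        res = reference_correlation(p, [p])
        assert res.r == pytest.approx(1.0)
        assert res.valid

    def test_constructed_correlation_below_gate_is_invalid(self):
        """A sample built to correlate at exactly 0.95 with the pool median
        (Gram-Schmidt construction, verified against a direct oracle) fails
        the 0.97 gate."""
        rng = np.random.default_rng(0)
        m = rng.uniform(20, 150, size=100)
        noise = rng.normal(size=100)
        mc = m - m.mean()
        noise -= noise.mean()
        noise -= noise @ mc / (mc @ mc) * mc  # orthogonal to signal
        target_r = 0.95
        lam = np.linalg.norm(mc) / np.linalg.norm(noise) * np.tan(np.arccos(target_r))
        x = mc + lam * noise
        x += -x.min() + 1.0  # shift positive; Pearson is shift-invariant
        oracle = np.corrcoef(x, m)[0, 1]
        assert oracle == pytest.approx(target_r, abs=1e-9)
        res = reference_correlation(profile(x), [profile(m)])
        assert res.r == pytest.approx(oracle)
        assert not res.valid

    def test_zero_variance_sample_invalid(self):
        flat = profile([50, 50, 50])
        varying = profile([10, 50, 90])
        res = reference_correlation(flat, [varying])
        assert np.isnan(res.r)
        assert not res.valid

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            reference_correlation(profile([1, 2]), [])


class TestCopyScore:
    def test_identity_scores_one(self):
        p = profile([30, 60, 90, 120])
        assert copy_score(p, [p]) == pytest.approx(np.ones(4))

    def test_half_normalized_depth_scores_half(self):
        """A target whose normalized depth is half the reference's
        normalized depth scores exactly 0.5."""
        m = np.array([10.0, 30.0, 60.0])
        ref = profile(m)
        # choose x so that x / (x + rest) == 0.5 * m_t / M
        rest, m_t, M = 90.0, 10.0, 100.0
        x = 0.5 * m_t / M * rest / (1 - 0.5 * m_t / M)
        sample = profile([x, 30.0, 60.0])
        scores = copy_score(sample, [ref])
        assert scores[0] == pytest.approx(0.5)

    def test_zero_pool_median_target_undefined(self):
        sample = profile([10, 20, 30])
        ref = profile([10, 0, 30])
        scores = copy_score(sample, [ref])
        assert np.isnan(scores[1])
        assert not np.isnan(scores[0])

    @settings(max_examples=40, deadline=None)
    @given(
        depths=st.lists(st.floats(1, 500), min_size=3, max_size=30),
        scale=st.floats(0.01, 100),
    )
    def test_scale_invariance(self, depths, scale):
        """Library size cancels: scaling a sample leaves scores unchanged."""
        rng = np.random.default_rng(1)
        ref = profile(rng.uniform(10, 100, len(depths)))
        base = copy_score(profile(depths), [ref])
        scaled = copy_score(profile(np.asarray(depths) * scale), [ref])
        assert scaled == pytest.approx(base, rel=1e-9)

    def test_planted_heterozygous_deletion_score_range(self):
        """Seeded 200-target profile with one planted 0.5-ratio deletion:
        the planted score lands in [0.3, 0.7] and the genome-wide median
        stays in [0.95, 1.05]."""
        from triorecess.simulate import DepthSpec, SimulationSpec, simulate_depth

        spec = SimulationSpec(
            seed=11, depth=DepthSpec(planted_cnvs=((25, 0.5),))
        )
        sim = simulate_depth(spec)
        pool = [sim.profiles[s] for s in sim.pool_samples]
        scores = copy_score(sim.profiles["proband"], pool)
        assert 0.3 <= scores[25] <= 0.7
        assert 0.95 <= np.nanmedian(scores) <= 1.05


class TestCallCnv:
    def test_threshold_sides(self):
        p = profile([1, 1, 1])
        calls = call_cnv(np.array([0.4, 1.0, 1.6]), p.targets, PipelineConfig())
        assert [(c.target[1] // 1000, c.call) for c in calls] == [
            (0, "deletion"), (2, "duplication")
        ]

    def test_boundaries_inclusive(self):
        p = profile([1, 1])
        calls = call_cnv(np.array([0.5, 1.5]), p.targets, PipelineConfig())
        assert [c.call for c in calls] == ["deletion", "duplication"]

    def test_diploid_scores_yield_no_calls(self):
        p = profile([1, 1, 1])
        assert call_cnv(np.array([0.51, 1.0, 1.49]), p.targets, PipelineConfig()) == []

    def test_nan_scores_skipped(self):
        p = profile([1, 1])
        assert call_cnv(np.array([np.nan, 1.0]), p.targets, PipelineConfig()) == []

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_threshold_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 200))
        scores = rng.uniform(0, 2, n)
        p = profile(np.ones(n))
        config = PipelineConfig()
        got = {(c.target, c.call) for c in call_cnv(scores, p.targets, config)}
        expected = set()
        for t, s in zip(p.targets, scores):
            if s <= 0.5:
                expected.add((t, "deletion"))
            elif s >= 1.5:
                expected.add((t, "duplication"))
        assert got == expected


class TestCommonCnvExclusion:
    def call(self, chrom, start, end, score=0.4):
        return CnvCall(target=(chrom, start, end), score=score, call="deletion")

    def test_common_overlap_removed_rare_kept(self):
        table = [("1", 0, 1000, 0.01), ("1", 5000, 6000, 0.001)]
        calls = [self.call("1", 500, 700), self.call("1", 5500, 5600)]
        kept = filter_common_cnv(calls, table, max_freq=0.005)
        assert [c.target[1] for c in kept] == [5500]
        assert kept[0].population_freq == 0.001

    def test_unknown_frequency_retained(self):
        kept = filter_common_cnv([self.call("2", 0, 100)], [("1", 0, 1000, 0.5)])
        assert len(kept) == 1
        assert kept[0].population_freq is None

    @pytest.mark.parametrize("seed", range(15))
    def test_matches_overlap_oracle(self, seed):
        rng = np.random.default_rng(seed)
        calls = [
            self.call(str(rng.integers(1, 3)), s := int(rng.integers(0, 5000)),
                      s + int(rng.integers(50, 500)))
            for _ in range(5)
        ]
        table = [
            (str(rng.integers(1, 3)), s := int(rng.integers(0, 5000)),
             s + int(rng.integers(50, 2000)), float(rng.choice([0.001, 0.02])))
            for _ in range(3)
        ]
        kept = {c.target for c in filter_common_cnv(calls, table, 0.005)}
        expected = set()
        for c in calls:
            chrom, cs, ce = c.target
            common = any(
                chrom == tc and cs < te and ts < ce and f > 0.005
                for tc, ts, te, f in table
            )
            if not common:
                expected.add(c.target)
        assert kept == expected


class TestDepthQc:
    def test_two_target_example(self):
        p = profile([5, 30])
        qc = depth_qc_summary(p, (10, 25))
        assert qc["fraction_ge"] == {10: 0.5, 25: 0.5}
        assert qc["mean_depth"] == pytest.approx(17.5)

    def test_uniform_coverage(self):
        p = profile([82, 82, 82])
        qc = depth_qc_summary(p, (10, 25))
        assert qc["fraction_ge"] == {10: 1.0, 25: 1.0}
        assert qc["mean_depth"] == pytest.approx(82.0)

    def test_matches_per_base_recount(self):
        """Length-weighted summary equals a literal per-base recount."""
        rng = np.random.default_rng(5)
        lengths = rng.integers(10, 60, size=300)
        depths = rng.uniform(0, 120, size=300)
        targets, start = [], 0
        for L in lengths:
            targets.append(("1", start, start + int(L)))
            start += int(L) + 10
        p = DepthProfile("s", targets, depths)
        qc = depth_qc_summary(p, (10, 25))
        base_depths = np.concatenate(
            [np.full(int(L), d) for L, d in zip(lengths, depths)]
        )
        assert qc["mean_depth"] == pytest.approx(base_depths.mean())
        for t in (10, 25):
            assert qc["fraction_ge"][t] == pytest.approx(
                (base_depths >= t).mean()
            )

    def test_empty_profile_undefined(self):
        with pytest.raises(ValueError):
            depth_qc_summary(DepthProfile("s", [], np.array([])))


def test_pool_median_is_robust_to_one_outlier_member():
    base = profile([10.0, 20.0, 30.0])
    outlier = profile([10.0, 200.0, 30.0])
    med = pool_median([base, base, outlier])
    assert med == pytest.approx([10, 20, 30])
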