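"""Decay stratification by seed class / site count, and the ddCt utility."""

import numpy as np
import pandas as pd
import pytest

from mirutr.kinetics import (
    CtRecord,
    TargetAnnotation,
    annotate_targets,
    class_trend_summary,
    ddct_fold_change,
    relative_abundance,
)
from mirutr.seedscan import UtrRecord
from mirutr.synthetic_data import gen_decay_matrix, gen_utrs


class TestAnnotate:
    def test_strongest_class_wins(self, mir1):
        # one 8mer + one 6mer, separated by site-free flank
        seq = "CATCATTATAACGGACATTCCA" + "GTGTGTGTGT" + "GGGCATTCCTGGG"
        ann = annotate_targets([UtrRecord("g1", seq)], mir1)["g1"]
        assert ann.seed_class == "8mer"
        assert ann.n_sites == 2

    def test_no_sites_is_none_class(self, mir1):
        ann = annotate_targets([UtrRecord("g1", "GTGTGTGTGTGT")], mir1)["g1"]
        assert ann.seed_class == "none" and ann.n_sites == 0

    def test_duplicate_ids_rejected(self, mir1):
        utrs = [UtrRecord("g1", "ACGTACGT"), UtrRecord("g1", "TTTTAAAA")]
        with pytest.raises(ValueError, match="duplicate"):
            annotate_targets(utrs, mir1)

    def test_planted_cohort_matches_truth(self, mir1):
        utrs, truth = gen_utrs(20, (200, 400), mir1, {"7mer-m8": 2}, seed=17)
        anns = annotate_targets(utrs, mir1)
        for tid, grp in truth.groupby("transcript_id"):
            assert anns[tid].seed_class == "7mer-m8"
            assert anns[tid].n_sites == len(grp)

    def test_inconsistent_annotation_rejected(self):
        with pytest.raises(ValueError, match="none"):
            TargetAnnotation("g", "none", 2)


def _matrix(means_by_cond_time, n_reps=2):
    """Exact-mean matrix: genes x (cond x time x rep) with no noise."""
    genes = list(next(iter(means_by_cond_time.values())).keys())
    cols, meta = {}, []
    for cond, by_time in means_by_cond_time.items():
        times = sorted({t for g in by_time.values() for t in g})
        for t in times:
            for r in range(1, n_reps + 1):
                sid = f"{cond}_t{t}_r{r}"
                cols[sid] = [by_time[g][t] for g in genes]
                meta.append({"sample": sid, "condition": cond, "time": t, "replicate": r})
    matrix = pd.DataFrame(cols, index=genes)
    return matrix, pd.DataFrame(meta).set_index("sample")


class TestRelativeAbundance:
    def test_equal_means_give_zero(self):
        by_time = {"g1": {0: 100, 4: 100}, "g2": {0: 40, 4: 40}}
        matrix, meta = _matrix({"mir": by_time, "control": by_time})
        ratios = relative_abundance(matrix, meta)
        assert np.allclose(ratios.to_numpy(), 0.0)

    def test_halving_gives_minus_one(self):
        mir = {"g1": {0: 199, 4: 99}}
        ctl = {"g1": {0: 199, 4: 199}}
        matrix, meta = _matrix({"mir": mir, "control": ctl})
        ratios = relative_abundance(matrix, meta)
        assert ratios.loc["g1", 0] == pytest.approx(0.0)
        assert ratios.loc["g1", 4] == pytest.approx(-1.0)

    def test_global_scale_invariance(self):
        rng = np.random.default_rng(8)
        vals = {f"g{i}": {0: v, 2: v * 0.8, 4: v * 0.5}
                for i, v in enumerate(rng.uniform(50, 500, 10))}
        ctl = {g: {0: d[0], 2: d[0], 4: d[0]} for g, d in vals.items()}
        m1, meta = _matrix({"mir": vals, "control": ctl})
        r1 = relative_abundance(m1, meta, pseudocount=0.0)
        r2 = relative_abundance(m1 * 3.7, meta, pseudocount=0.0)
        assert np.allclose(r1.to_numpy(), r2.to_numpy())

    def test_missing_condition_rejected(self):
        matrix, meta = _matrix({"mir": {"g1": {0: 1, 4: 1}}})
        with pytest.raises(ValueError, match="both conditions"):
            relative_abundance(matrix, meta)


class TestClassTrends:
    def _cohort(self, lambda_class, seed, n_per_class=20, lambda_site=0.0,
                n_sites=1, dispersion=0.05):
        anns = {}
        i = 0
        for cls in lambda_class:
            for _ in range(n_per_class):
                ns = 0 if cls == "none" else n_sites
                anns[f"g{i:04d}"] = TargetAnnotation(f"g{i:04d}", cls, ns)
                i += 1
        matrix, meta, _ = gen_decay_matrix(
            anns, base_level=500.0, lambda_class=lambda_class,
            lambda_site=lambda_site, seed=seed, dispersion=dispersion,
        )
        return relative_abundance(matrix, meta), anns

    def test_seed_class_ordering_recovered(self):
        """Stronger seed classes decay faster: at 4 h the 8mer stratum mean
        sits lowest and 6mer highest, in >=95% of replicates."""
        lam = {"8mer": 0.5, "7mer-m8": 0.35, "7mer-A1": 0.2, "6mer": 0.08}
        hits = 0
        n_reps = 20
        for rep in range(n_reps):
            ratios, anns = self._cohort(lam, seed=300 + rep)
            summary, _ = class_trend_summary(ratios, anns, "seed_class")
            at4 = summary[summary["time"] == 4.0].set_index("stratum")["mean"]
            hits += (
                at4["8mer"] < at4["7mer-m8"] < at4["7mer-A1"] < at4["6mer"]
            )
        assert hits / n_reps >= 0.95

    def test_site_count_ordering_recovered(self):
        """Decay rate rising with site count orders the 4-h means
        3 sites < 2 sites < 1 site."""
        anns = {}
        for i in range(60):
            ns = (i % 3) + 1
            anns[f"g{i:04d}"] = TargetAnnotation(f"g{i:04d}", "7mer-A1", ns)
        matrix, meta, _ = gen_decay_matrix(
            anns, base_level=500.0, lambda_class={"7mer-A1": 0.15},
            lambda_site=0.2, seed=55,
        )
        ratios = relative_abundance(matrix, meta)
        summary, _ = class_trend_summary(ratios, anns, "n_sites")
        at4 = summary[summary["time"] == 4.0].set_index("stratum")["mean"]
        assert at4[">2"] < at4["2"] < at4["1"]

    def test_null_type_one_error_calibrated(self):
        """With identical decay across strata the between-stratum ANOVA at
        4 h rejects at ~nominal 0.05 (within [0.025, 0.075] over 500 reps)."""
        lam = {"8mer": 0.3, "7mer-m8": 0.3, "7mer-A1": 0.3, "6mer": 0.3}
        rejections = 0
        n_reps = 500
        for rep in range(n_reps):
            ratios, anns = self._cohort(lam, seed=10_000 + rep, n_per_class=8)
            _, tests = class_trend_summary(ratios, anns, "seed_class")
            p = tests.loc[tests["time"] == 4.0, "anova_p"].iloc[0]
            rejections += p < 0.05
        assert 0.025 <= rejections / n_reps <= 0.075

    def test_rate_difference_matches_closed_form(self):
        """lambda difference maps to a 4-h log2-ratio gap of
        -(lam_a - lam_b) * 4 / ln 2."""
        lam = {"8mer": 0.5, "6mer": 0.1}
        gaps = []
        for rep in range(10):
            ratios, anns = self._cohort(lam, seed=700 + rep, n_per_class=40)
            summary, _ = class_trend_summary(ratios, anns, "seed_class")
            at4 = summary[summary["time"] == 4.0].set_index("stratum")["mean"]
            gaps.append(at4["8mer"] - at4["6mer"])
        expected = -(0.5 - 0.1) * 4 / np.log(2)
        assert np.mean(gaps) == pytest.approx(expected, abs=0.15)

    def test_small_stratum_dropped_with_warning(self):
        lam = {"8mer": 0.3, "6mer": 0.1}
        ratios, anns = self._cohort(lam, seed=77, n_per_class=5)
        lone = TargetAnnotation("lonely", "7mer-m8", 1)
        anns["lonely"] = lone
        ratios.loc["lonely"] = 0.0
        with pytest.warns(UserWarning, match="7mer-m8"):
            summary, _ = class_trend_summary(ratios, anns, "seed_class")
        assert "7mer-m8" not in set(summary["stratum"])


class TestDdct:
    @pytest.mark.parametrize(
        "cts, expected",
        [
            ((20, 20, 20, 20), 1.0),      # all equal
            ((21, 20, 20, 20), 0.5),      # ddCt = +1
            ((18, 20, 20, 20), 4.0),      # ddCt = -2
        ],
    )
    def test_closed_form(self, cts, expected):
        rec = CtRecord(*[float(c) for c in cts])
        assert ddct_fold_change(rec) == pytest.approx(expected)

    def test_nonpositive_ct_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            CtRecord(0.0, 20.0, 20.0, 20.0)
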