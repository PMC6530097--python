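"""Depletion-success statistics: fractions, FPKM, quartiles, deltas, depth."""

import numpy as np
import pandas as pd
import pytest

from rnadep.evaluate import (DepthModel, de_sensitivity, detection_delta,
                             exon_profile, expression_correlation, fpkm,
                             group_summary, quartile_categories,
                             reduction_percent, required_depth, round_half_up,
                             target_fraction, three_prime_bias)
from rnadep.panel import TARGET_GENES, benchmark_fractions
from rnadep.simulate import CountMatrix


def matrix_from_counts(counts: dict[str, list[int]], sample_meta=None,
                       lengths=None, exons_per_gene=1) -> CountMatrix:
    """Tiny CountMatrix builder: each gene one exon unless requested."""
    genes = list(counts)
    n_samples = len(next(iter(counts.values())))
    sample_ids = [f"s{i}" for i in range(n_samples)]
    cdf = pd.DataFrame(counts, index=sample_ids).T
    cdf.index.name = "gene_id"
    lengths = pd.Series(lengths or {g: 1000 for g in genes}, name="length")
    info_rows, exon_rows = [], {}
    for g in genes:
        L = lengths[g]
        step = L // exons_per_gene
        for ei in range(exons_per_gene):
            info_rows.append((g, ei, ei * step, (ei + 1) * step, step))
            base = np.asarray(cdf.loc[g]) // exons_per_gene
            if ei == 0:
                base = np.asarray(cdf.loc[g]) - base * (exons_per_gene - 1)
            exon_rows[(g, ei)] = base
    info = pd.DataFrame(info_rows, columns=["gene_id", "exon_index", "start",
                                            "end", "length"])
    idx = pd.MultiIndex.from_frame(info[["gene_id", "exon_index"]])
    edf = pd.DataFrame([exon_rows[k] for k in idx], index=idx,
                       columns=sample_ids)
    meta = sample_meta or {"animal": [1] * n_samples,
                           "condition": ["non_challenged"] * n_samples,
                           "treatment": ["0"] * n_samples}
    samples = pd.DataFrame(meta, index=pd.Index(sample_ids, name="sample_id"))
    return CountMatrix(counts=cdf, lengths=lengths, exon_counts=edf,
                       exon_info=info, samples=samples)


def benchmark_matrix() -> tuple[CountMatrix, list[str]]:
    """Counts reproducing the published per-sample target percentages.

    Each sample gets 1000 fragments: target genes receive their published
    per-mille share, one background gene absorbs the rest.
    """
    bench = benchmark_fractions()
    counts = {g: [int(round(v * 10)) for v in bench[g]] for g in TARGET_GENES}
    used = np.sum([counts[g] for g in TARGET_GENES], axis=0)
    counts["BACKGROUND"] = list(1000 - used)
    meta = {"animal": list(bench["animal"]),
            "condition": list(bench["condition"]),
            "treatment": list(bench["treatment"])}
    cm = matrix_from_counts(counts, sample_meta=meta)
    cm.samples.index = [f"cow{a}_{c}_{t}" for a, c, t in
                        zip(bench["animal"], bench["condition"],
                            bench["treatment"])]
    cm.counts.columns = cm.samples.index
    cm.exon_counts.columns = cm.samples.index
    return cm, list(TARGET_GENES)


class TestTargetFraction:
    def test_published_first_sample_sums_to_70_7(self):
        cm, targets = benchmark_matrix()
        frac = target_fraction(cm, targets)
        assert frac["cow1_non_challenged_0"] == pytest.approx(70.7)

    def test_zero_target_sample_is_zero(self):
        cm = matrix_from_counts({"T": [0], "B": [500]})
        assert target_fraction(cm, ["T"]).item() == 0.0

    def test_equals_direct_ratio_on_random_counts(self):
        rng = np.random.default_rng(0)
        vals = rng.integers(0, 500, 10)
        cm = matrix_from_counts({f"g{i}": [int(v)] for i, v in enumerate(vals)})
        got = target_fraction(cm, ["g0", "g3"]).item()
        assert got == pytest.approx(100 * (vals[0] + vals[3]) / vals.sum())

    def test_scale_invariance(self):
        cm1 = matrix_from_counts({"T": [30], "B": [70]})
        cm2 = matrix_from_counts({"T": [300], "B": [700]})
        assert target_fraction(cm1, ["T"]).item() == \
            target_fraction(cm2, ["T"]).item()

    def test_empty_sample_rejected(self):
        cm = matrix_from_counts({"T": [0], "B": [0]})
        with pytest.raises(ValueError):
            target_fraction(cm, ["T"])

    def test_unknown_target_rejected(self):
        cm = matrix_from_counts({"T": [1]})
        with pytest.raises(KeyError):
            target_fraction(cm, ["X"])


class TestGroupSummary:
    def test_published_group_means(self):
        cm, targets = benchmark_matrix()
        gm = group_summary(target_fraction(cm, targets), cm.samples)
        printed = {
            ("non_challenged", "0"): 61, ("non_challenged", "A"): 29,
            ("non_challenged", "B"): 24, ("challenged", "0"): 30,
            ("challenged", "A"): 11, ("challenged", "B"): 9}
        for key, want in printed.items():
            assert round_half_up(gm.loc[key, "mean"]) == want
        row = gm.loc[("non_challenged", "0")]
        assert round_half_up(row["min"]) == 52
        assert round_half_up(row["max"]) == 71

    def test_single_sample_group_degenerate_range(self):
        cm = matrix_from_counts({"T": [30], "B": [70]})
        gm = group_summary(target_fraction(cm, ["T"]), cm.samples)
        row = gm.iloc[0]
        assert row["mean"] == row["min"] == row["max"] == 30.0


class TestReduction:
    def test_worked_example(self):
        assert reduction_percent(61.3, 29.0) == pytest.approx(52.69, abs=0.01)

    def test_boundaries(self):
        assert reduction_percent(40.0, 40.0) == 0.0
        assert reduction_percent(40.0, 0.0) == 100.0
        with pytest.raises(ValueError):
            reduction_percent(0.0, 0.0)


class TestFpkm:
    def test_unit_case(self):
        cm = matrix_from_counts({"g": [1000], "fill": [999_000]})
        assert fpkm(cm).loc["g"].item() == pytest.approx(1000.0)

    def test_doubling_library_halves_fpkm(self):
        cm1 = matrix_from_counts({"g": [100], "fill": [900]})
        cm2 = matrix_from_counts({"g": [100], "fill": [1900]})
        assert fpkm(cm1).loc["g"].item() == \
            pytest.approx(2 * fpkm(cm2).loc["g"].item())

    def test_matches_formula_on_random_matrix(self):
        rng = np.random.default_rng(1)
        counts = {f"g{i}": list(map(int, rng.integers(1, 1000, 3)))
                  for i in range(8)}
        lengths = {f"g{i}": int(rng.integers(200, 5000)) for i in range(8)}
        cm = matrix_from_counts(counts, lengths=lengths)
        got = fpkm(cm)
        lib = cm.counts.sum(axis=0)
        for g in counts:
            for j, s in enumerate(cm.counts.columns):
                want = counts[g][j] / (lengths[g] / 1e3) / (lib[s] / 1e6)
                assert got.loc[g, s] == pytest.approx(want)


class TestQuartiles:
    def _matrix(self, values, lengths=None):
        # library padded to 1e6 fragments; at L=1kb, FPKM == count
        counts = {f"g{i}": [int(v)] for i, v in enumerate(values)}
        counts["fill"] = [1_000_000 - int(sum(values))]
        return matrix_from_counts(counts, lengths=lengths)

    def test_bounds_match_sorted_percentiles(self):
        values = list(range(1, 101))  # FPKM 1..100
        cm = self._matrix(values)
        mat = fpkm(cm)
        bounds, cats, _ = quartile_categories(mat, cm.samples, ["fill"])
        assert bounds == pytest.approx(
            np.percentile(sorted(float(v) for v in values), [25, 50, 75]))
        # partition: every surviving locus in exactly one category
        assert cats.notna().all()
        assert len(cats) == len(values)

    def test_all_below_threshold_is_error(self):
        # long genes push every FPKM below 1
        lengths = {f"g{i}": 1_000_000 for i in range(4)}
        lengths["fill"] = 1000
        cm = self._matrix([100, 200, 300, 400], lengths=lengths)
        with pytest.raises(ValueError):
            quartile_categories(fpkm(cm), cm.samples, ["fill"])

    def test_depletion_renormalization_shifts_categories_up(self):
        rng = np.random.default_rng(2)
        base = rng.integers(1500, 80_000, 40)
        target = 1_500_000
        lib = int(base.sum() + target)
        counts, meta = {}, {"animal": [1, 1],
                            "condition": ["non_challenged"] * 2,
                            "treatment": ["0", "A"]}
        # depleted sample: half the target fragments removed, library
        # re-filled proportionally from the background
        scale = lib / (base.sum() + target / 2)
        for i, v in enumerate(base):
            counts[f"g{i}"] = [int(v), int(round(v * scale))]
        counts["TGT"] = [target, lib - int(np.sum(
            [counts[f"g{i}"][1] for i in range(40)]))]
        cm = matrix_from_counts(counts, sample_meta=meta)
        mat = fpkm(cm)
        bounds, cats, means = quartile_categories(mat, cm.samples, ["TGT"])
        assert (means["A"] >= means["0"]).all()
        assert (means["A"] > means["0"]).any()


class TestDetectionDelta:
    def test_published_net_surpluses(self):
        # vectors realizing the published gained/lost pairs
        for gained, lost, net in ((554, 315, 239), (582, 304, 278)):
            n = 13_500
            ref = pd.Series(0.5, index=[f"g{i}" for i in range(n)])
            dep = pd.Series(0.5, index=ref.index)
            ref.iloc[:12_000] = 5.0
            dep.iloc[:12_000 - lost] = 5.0          # stay above
            dep.iloc[12_000:12_000 + gained] = 5.0  # newly above
            g, l, d = detection_delta(ref, dep)
            assert (g, l, d) == (gained, lost, net)

    def test_identity_and_antisymmetry(self):
        rng = np.random.default_rng(3)
        x = pd.Series(rng.uniform(0, 3, 20), index=[f"g{i}" for i in range(20)])
        y = pd.Series(rng.uniform(0, 3, 20), index=x.index)
        assert detection_delta(x, x) == (0, 0, 0)
        g, l, n = detection_delta(x, y)
        g2, l2, n2 = detection_delta(y, x)
        assert (g, l, n) == (l2, g2, -n2)

    def test_threshold_is_strict(self):
        x = pd.Series({"a": 1.0, "b": 2.0})
        y = pd.Series({"a": 1.0, "b": 1.0})
        assert detection_delta(x, y) == (0, 1, -1)

    def test_matches_set_oracle(self):
        rng = np.random.default_rng(4)
        idx = [f"g{i}" for i in range(20)]
        x = pd.Series(rng.uniform(0, 2, 20), index=idx)
        y = pd.Series(rng.uniform(0, 2, 20), index=idx)
        above_x = {g for g in idx if x[g] > 1}
        above_y = {g for g in idx if y[g] > 1}
        assert detection_delta(x, y) == (
            len(above_y - above_x), len(above_x - above_y),
            len(above_y - above_x) - len(above_x - above_y))

    def test_mismatched_universe_rejected(self):
        with pytest.raises(ValueError):
            detection_delta(pd.Series({"a": 1.0}), pd.Series({"b": 1.0}))


class TestRequiredDepth:
    def test_flagship_75_million(self):
        raw, rounded = required_depth(DepthModel(30e6, 0.60))
        assert raw == pytest.approx(75e6)
        assert rounded == 75e6

    def test_no_targets_needs_exactly_r(self):
        raw, _ = required_depth(DepthModel(30e6, 0.0))
        assert raw == pytest.approx(30e6)

    def test_thirty_percent_case(self):
        raw, _ = required_depth(DepthModel(30e6, 0.30))
        assert raw == pytest.approx(30e6 / 0.7)
        assert raw / 1e6 == pytest.approx(42.86, abs=0.01)

    def test_strictly_increasing_in_target_fraction(self):
        depths = [required_depth(DepthModel(30e6, p))[0]
                  for p in np.linspace(0, 0.95, 20)]
        assert all(b > a for a, b in zip(depths, depths[1:]))

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            DepthModel(30e6, 1.0)


class TestExonProfiles:
    def test_uniform_coverage_bias_ratio_one(self):
        cm = matrix_from_counts({"g": [800], "fill": [200]}, exons_per_gene=4)
        ratio = three_prime_bias(cm, "g", five_prime_exon=1,
                                 three_prime_exon=2)
        assert ratio.item() == pytest.approx(1.0)

    def test_single_exon_profile_equals_gene_fpkm(self):
        cm = matrix_from_counts({"g": [800], "fill": [200]})
        prof = exon_profile(cm, "g")
        assert prof.iloc[0].item() == pytest.approx(fpkm(cm).loc["g"].item())

    def test_missing_gene_rejected(self):
        cm = matrix_from_counts({"g": [800]})
        with pytest.raises(KeyError):
            exon_profile(cm, "nope")


class TestCorrelation:
    def test_identical_columns_give_r_one(self):
        rng = np.random.default_rng(5)
        vals = list(map(int, rng.integers(10, 10_000, 30)))
        counts = {f"g{i}": [v, v] for i, v in enumerate(vals)}
        meta = {"animal": [1, 1], "condition": ["non_challenged"] * 2,
                "treatment": ["0", "A"]}
        cm = matrix_from_counts(counts, sample_meta=meta)
        out = expression_correlation(fpkm(cm), cm.samples)
        assert out["r"].item() == pytest.approx(1.0)

    def test_pure_renormalization_gives_r_one_on_nontargets(self):
        rng = np.random.default_rng(6)
        vals = rng.integers(10, 10_000, 30)
        counts = {f"g{i}": [int(v), int(v * 3)] for i, v in enumerate(vals)}
        counts["TGT"] = [int(vals.sum() * 2), 0]
        meta = {"animal": [1, 1], "condition": ["non_challenged"] * 2,
                "treatment": ["0", "B"]}
        cm = matrix_from_counts(counts, sample_meta=meta)
        out = expression_correlation(fpkm(cm), cm.samples, exclude=["TGT"])
        assert out["r"].item() == pytest.approx(1.0)


class TestDeSensitivity:
    def _study_matrix(self, rng, fold=1.0, n_genes=30, lib=50_000,
                      n_animals=3):
        fracs = rng.dirichlet(np.ones(n_genes))
        cols, meta_rows = {}, []
        for cond in ("non_challenged", "challenged"):
            f = fracs.copy()
            if cond == "challenged":
                f[0] *= fold
                f = f / f.sum()
            for a in range(n_animals):
                cols[f"{cond}{a}"] = rng.multinomial(lib, f)
                meta_rows.append((a + 1, cond, "0"))
        counts = {f"g{i}": [int(cols[c][i]) for c in cols]
                  for i in range(n_genes)}
        meta = {"animal": [r[0] for r in meta_rows],
                "condition": [r[1] for r in meta_rows],
                "treatment": [r[2] for r in meta_rows]}
        cm = matrix_from_counts(counts, sample_meta=meta)
        cm.samples.index = list(cols)
        cm.counts.columns = list(cols)
        cm.exon_counts.columns = list(cols)
        return cm

    def test_null_detections_rare(self):
        rng = np.random.default_rng(7)
        n_det = [de_sensitivity(self._study_matrix(rng, fold=1.0), ["g0"])
                 .loc["0", "n_detected"] for _ in range(10)]
        assert np.mean(n_det) <= 0.05 * 30

    def test_strong_fold_change_detected(self):
        rng = np.random.default_rng(8)
        cm = self._study_matrix(rng, fold=8.0, lib=200_000)
        out = de_sensitivity(cm, ["g0"])
        assert out.loc["0", "power"] == 1.0

    def test_missing_condition_rejected(self):
        cm = matrix_from_counts({"g": [5, 6]})
        with pytest.raises(ValueError):
            de_sensitivity(cm, ["g"])
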