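"""Evaluation statistics for depletion experiments over fragment counts.

All statistics operate on a :class:`~rnadep.simulate.CountMatrix`, whether it
came from the simulator or was imported from a featureCounts-style table:

* **target fraction** -- percent of all assigned fragments mapping to the
  depletion targets (the headline depletion-success number), per sample and
  per gene, with group means and ranges over animals;
* **FPKM** -- fragments per kilobase of feature per million assigned
  fragments, per gene and per exon;
* **expression quartiles** -- category bounds computed on non-depleted
  samples only (after dropping targets and FPKM < 1 loci), then per-category
  mean FPKM per treatment to show the sensitivity gain depletion buys;
* **detection delta** -- genes crossing the FPKM > 1 threshold only after
  (gained) or only before (lost) depletion;
* **depth model** -- raw sequencing depth required for a given yield of
  informative non-target fragments at target fraction p: R / ((1-p) u);
* **exon profiles and 3' bias** -- per-exon FPKM and the terminal/5' FPKM
  ratio that exposes the polyA+ retention artifact;
* **correlation** -- Pearson r of log10 FPKM between depleted and
  non-depleted samples on jointly expressed genes;
* **DE sensitivity** -- power and observed FDR for recovering ground-truth
  differential expression between challenged and control samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .simulate import CountMatrix

QUARTILE_LABELS = ("very_low", "low", "medium", "high")


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal-style rounding for report presentation (0.5 rounds up)."""
    factor = 10 ** ndigits
    return math.floor(x * factor + 0.5) / factor


@dataclass
class DepthModel:
    """Sequencing-depth requirement for a given informative yield.

    ``required_nontarget_fragments`` is the number of non-target fragments
    the study needs; ``target_fraction`` the expected share of fragments
    the targets absorb (0-1); ``usable_fraction`` discounts additional
    losses (unmapped, filtered).
    """

    required_nontarget_fragments: float
    target_fraction: float
    usable_fraction: float = 1.0

    def __post_init__(self) -> None:
        if not 0 <= self.target_fraction < 1:
            raise ValueError("target_fraction must be in [0,1)")
        if self.required_nontarget_fragments <= 0:
            raise ValueError("required_nontarget_fragments must be positive")
        if not 0 < self.usable_fraction <= 1:
            raise ValueError("usable_fraction must be in (0,1]")


def required_depth(model: DepthModel) -> tuple[float, float]:
    """Raw fragments needed; returns (exact, rounded-to-nearest-million)."""
    raw = model.required_nontarget_fragments / (
        (1.0 - model.target_fraction) * model.usable_fraction)
    return raw, round_half_up(raw / 1e6) * 1e6


# ---------------------------------------------------------------------------
# Fractions
# ---------------------------------------------------------------------------

def target_fraction(cm: CountMatrix, targets: Sequence[str],
                    per_gene: bool = False) -> pd.Series | pd.DataFrame:
    """Percent of assigned fragments on the target genes, per sample.

    With ``per_gene`` each target's own percentage is returned
    (genes x samples).
    """
    missing = set(targets) - set(cm.counts.index)
    if missing:
        raise KeyError(f"targets not in count matrix: {sorted(missing)}")
    totals = cm.counts.sum(axis=0)
    if (totals == 0).any():
        empty = list(totals.index[totals == 0])
        raise ValueError(f"sample(s) with zero assigned fragments: {empty}")
    sub = cm.counts.loc[list(targets)]
    if per_gene:
        return 100.0 * sub / totals
    return 100.0 * sub.sum(axis=0) / totals


def group_summary(fractions: pd.Series, samples: pd.DataFrame) -> pd.DataFrame:
    """Mean and range of a per-sample statistic per (condition, treatment).

    Means average the per-animal values (not pooled fragments); full
    precision is kept, rounding is presentation-only.
    """
    df = samples.join(fractions.rename("value"))
    if df["value"].isna().any():
        raise KeyError("fractions missing for some samples in the sheet")
    out = df.groupby(["condition", "treatment"])["value"].agg(
        mean="mean", min="min", max="max", n="size")
    return out


def reduction_percent(p0: float, p_depleted: float) -> float:
    """Relative reduction 100 (p0 - pd) / p0 of the target fraction."""
    if p0 <= 0:
        raise ValueError("reduction undefined for p0 <= 0")
    return 100.0 * (p0 - p_depleted) / p0


# ---------------------------------------------------------------------------
# FPKM and derived statistics
# ---------------------------------------------------------------------------

def fpkm(cm: CountMatrix) -> pd.DataFrame:
    """Fragments per kilobase of union-exon length per million fragments."""
    if (cm.lengths <= 0).any():
        raise ValueError("non-positive gene length")
    lib_m = cm.counts.sum(axis=0) / 1e6
    if (lib_m == 0).any():
        raise ValueError("zero library size")
    len_kb = cm.lengths.loc[cm.counts.index] / 1e3
    return cm.counts.div(lib_m, axis=1).div(len_kb, axis=0)


def exon_fpkm(cm: CountMatrix) -> pd.DataFrame:
    """Per-exon FPKM using exon length and the whole-sample library size."""
    info = cm.exon_info.set_index(["gene_id", "exon_index"])
    if (info["length"] <= 0).any():
        raise ValueError("non-positive exon length")
    lib_m = cm.counts.sum(axis=0) / 1e6
    len_kb = info["length"].loc[cm.exon_counts.index] / 1e3
    return cm.exon_counts.div(lib_m, axis=1).div(len_kb, axis=0)


def quartile_categories(fpkm_mat: pd.DataFrame, samples: pd.DataFrame,
                        targets: Sequence[str], min_fpkm: float = 1.0
                        ) -> tuple[np.ndarray, pd.Series, pd.DataFrame]:
    """Expression quartiles fixed on non-depleted samples.

    Loci are filtered on their average FPKM over all non-depleted samples
    (both conditions): targets and loci averaging below ``min_fpkm`` are
    dropped.  The 25/50/75 percentiles of the surviving averages define four
    categories; assignment is fixed thereafter.  Returns (bounds, category
    labels per locus, per-category mean FPKM per treatment pooling
    conditions).
    """
    ref_samples = list(samples.index[samples["treatment"] == "0"])
    if not ref_samples:
        raise ValueError("no non-depleted (treatment 0) samples")
    avg = fpkm_mat[ref_samples].mean(axis=1)
    keep = avg.index[(avg >= min_fpkm) & ~avg.index.isin(targets)]
    if len(keep) < 4:
        raise ValueError(
            f"only {len(keep)} loci survive the FPKM filter; need >= 4")
    bounds = np.percentile(avg.loc[keep], [25, 50, 75])
    cats = pd.Series(
        pd.cut(avg.loc[keep], [-np.inf, *bounds, np.inf],
               labels=QUARTILE_LABELS),
        index=keep, name="category")
    rows = {}
    for trt, grp in samples.groupby("treatment"):
        per_gene = fpkm_mat.loc[keep, list(grp.index)].mean(axis=1)
        rows[trt] = per_gene.groupby(cats, observed=True).mean()
    means = pd.DataFrame(rows).reindex(list(QUARTILE_LABELS))
    return bounds, cats, means


def detection_delta(fpkm_ref: pd.Series, fpkm_dep: pd.Series,
                    threshold: float = 1.0) -> tuple[int, int, int]:
    """Genes crossing the FPKM threshold only after / only before depletion.

    Returns (gained, lost, net).  The threshold is strict: a locus at
    exactly ``threshold`` does not count as exceeding it.
    """
    if set(fpkm_ref.index) != set(fpkm_dep.index):
        raise ValueError("gene universes differ between matrices")
    dep = fpkm_dep.loc[fpkm_ref.index]
    gained = int(((fpkm_ref <= threshold) & (dep > threshold)).sum())
    lost = int(((fpkm_ref > threshold) & (dep <= threshold)).sum())
    return gained, lost, gained - lost


# ---------------------------------------------------------------------------
# Exon profiles / 3' bias
# ---------------------------------------------------------------------------

def exon_profile(cm: CountMatrix, gene_id: str) -> pd.DataFrame:
    """Per-exon FPKM for one gene (exons in transcript order)."""
    if gene_id not in cm.counts.index:
        raise KeyError(f"gene {gene_id!r} not in count matrix")
    prof = exon_fpkm(cm).loc[gene_id]
    if prof.empty:
        raise ValueError(f"gene {gene_id!r} has no exon counts")
    return prof


def three_prime_bias(cm: CountMatrix, gene_id: str,
                     five_prime_exon: int, three_prime_exon: int) -> pd.Series:
    """Terminal/5' coverage ratio per sample for one gene.

    ``five_prime_exon`` and ``three_prime_exon`` delimit the oligo block in
    exon indices (transcript order): the ratio is mean exon FPKM strictly 3'
    of ``three_prime_exon`` over mean exon FPKM strictly 5' of
    ``five_prime_exon``.  Ratios > 1 indicate the residual polyA-proximal
    signal the depletion mechanism leaves behind.
    """
    prof = exon_profile(cm, gene_id)
    five = prof.loc[prof.index < five_prime_exon]
    three = prof.loc[prof.index > three_prime_exon]
    if five.empty or three.empty:
        raise ValueError("no exons on one side of the oligo block")
    denom = five.mean(axis=0)
    ratio = three.mean(axis=0) / denom.where(denom > 0, np.nan)
    return ratio


def oligo_exon_span(cm: CountMatrix, assay, gene_id: str,
                    canonical) -> tuple[int, int]:
    """Exon indices (transcript order) of the 5'-most and 3'-most oligo."""
    recs = assay.by_gene().get(gene_id, [])
    if not recs:
        raise KeyError(f"no oligos for gene {gene_id!r}")
    idx = []
    for rec in recs:
        idx.append(canonical.exon_index_of_mrna_pos(rec.candidate.mrna_start))
        idx.append(canonical.exon_index_of_mrna_pos(rec.candidate.mrna_end - 1))
    return min(idx), max(idx)


# ---------------------------------------------------------------------------
# Correlation
# ---------------------------------------------------------------------------

def expression_correlation(fpkm_mat: pd.DataFrame, samples: pd.DataFrame,
                           exclude: Sequence[str] = ()) -> pd.DataFrame:
    """Pearson r of log10 FPKM: depleted vs non-depleted, within condition.

    Per (condition, variant) the per-gene mean FPKM across animals is
    compared between treatment 0 and the variant on genes positive in both
    (no pseudocount).  r is NaN when fewer than 3 genes remain or a side is
    constant.
    """
    rows = []
    for condition, grp in samples.groupby("condition"):
        ref_cols = list(grp.index[grp["treatment"] == "0"])
        if not ref_cols:
            continue
        ref = fpkm_mat[ref_cols].mean(axis=1)
        for variant in sorted(set(grp["treatment"]) - {"0"}):
            dep = fpkm_mat[list(grp.index[grp["treatment"] == variant])].mean(axis=1)
            ok = (ref > 0) & (dep > 0) & ~ref.index.isin(exclude)
            x, y = np.log10(ref[ok]), np.log10(dep[ok])
            if ok.sum() < 3 or x.std() == 0 or y.std() == 0:
                r = float("nan")
            else:
                r = float(stats.pearsonr(x, y).statistic)
            rows.append({"condition": condition, "comparison": f"0_vs_{variant}",
                         "r": r, "n_genes": int(ok.sum())})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Ground-truth DE sensitivity
# ---------------------------------------------------------------------------

def de_sensitivity(cm: CountMatrix, truth: Sequence[str],
                   alpha: float = 0.05) -> pd.DataFrame:
    """Power and observed FDR for challenge-vs-control DE, per treatment.

    Per gene and treatment, challenged and control counts are pooled across
    animals and compared with a conditional binomial test (gene count in the
    challenged pool vs the library-size split), then Benjamini-Hochberg
    corrected at q < ``alpha``.  ``truth`` lists the genes simulated as
    differentially expressed.
    """
    truth = set(truth)
    rows = []
    for trt in sorted(set(cm.samples["treatment"])):
        chal = cm.sample_ids(treatment=trt, condition="challenged")
        ctrl = cm.sample_ids(treatment=trt, condition="non_challenged")
        if not chal or not ctrl:
            raise ValueError(f"treatment {trt!r} lacks replicates in one "
                             f"condition")
        k1 = cm.counts[chal].sum(axis=1)
        k0 = cm.counts[ctrl].sum(axis=1)
        n1, n0 = int(k1.sum()), int(k0.sum())
        p_null = n1 / (n1 + n0)
        pvals = np.array([
            stats.binomtest(int(a), int(a + b), p_null).pvalue
            if a + b > 0 else 1.0
            for a, b in zip(k1.values, k0.values)])
        sig = multipletests(pvals, alpha=alpha, method="fdr_bh")[0]
        detected = set(k1.index[sig])
        tp = len(detected & truth)
        power = tp / len(truth) if truth else float("nan")
        fdr = ((len(detected) - tp) / len(detected)) if detected else 0.0
        rows.append({"treatment": trt, "n_detected": len(detected),
                     "true_positives": tp, "power": power,
                     "observed_fdr": fdr})
    return pd.DataFrame(rows).set_index("treatment")


# ---------------------------------------------------------------------------
# Report bundle
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    """Bundle of all evaluation outputs for one study."""

    per_sample_fraction: pd.Series
    per_gene_fraction: pd.DataFrame
    group_means: pd.DataFrame
    reductions: pd.DataFrame
    quartile_bounds: np.ndarray | None
    quartile_means: pd.DataFrame | None
    detection: pd.DataFrame
    correlation: pd.DataFrame
    depth: pd.DataFrame
    power: pd.DataFrame | None = None

    def to_json_dict(self) -> dict:
        out = {
            "per_sample_fraction": self.per_sample_fraction.round(3).to_dict(),
            "group_means": {
                f"{c}/{t}": {k: round_half_up(v, 2) for k, v in row.items()}
                for (c, t), row in self.group_means.iterrows()},
            "reductions": self.reductions.round(2).to_dict(orient="records"),
            "detection": {f"{c}/{t}": {k: int(v) for k, v in row.items()}
                          for (c, t), row in self.detection.iterrows()}
            if len(self.detection) else {},
            "correlation": self.correlation.round(4).to_dict(orient="records"),
            "depth": self.depth.round(2).to_dict(orient="records"),
        }
        if self.quartile_bounds is not None:
            out["quartile_bounds"] = [round(float(b), 3)
                                      for b in self.quartile_bounds]
            out["quartile_means"] = self.quartile_means.round(3).to_dict()
        if self.power is not None:
            out["power"] = self.power.round(4).to_dict(orient="index")
        return out


def evaluate_study(cm: CountMatrix, targets: Sequence[str],
                   required_nontarget: float = 30e6,
                   truth: Sequence[str] | None = None) -> EvalReport:
    """Compute the full evaluation report over a study count matrix."""
    frac = target_fraction(cm, targets)
    per_gene = target_fraction(cm, targets, per_gene=True)
    gm = group_summary(frac, cm.samples)
    red_rows = []
    for condition in sorted(set(cm.samples["condition"])):
        if ("0" not in gm.loc[condition].index):
            continue
        p0 = gm.loc[(condition, "0"), "mean"]
        for trt in gm.loc[condition].index:
            if trt == "0" or p0 <= 0:
                continue
            red_rows.append({
                "condition": condition, "treatment": trt,
                "reduction_percent": reduction_percent(
                    p0, gm.loc[(condition, trt), "mean"])})
    reductions = pd.DataFrame(red_rows)

    fpkm_mat = fpkm(cm)
    try:
        bounds, _, qmeans = quartile_categories(fpkm_mat, cm.samples, targets)
    except ValueError:
        bounds, qmeans = None, None

    det_rows = []
    for condition in sorted(set(cm.samples["condition"])):
        ref_cols = cm.sample_ids(condition=condition, treatment="0")
        if not ref_cols:
            continue
        ref = fpkm_mat[ref_cols].mean(axis=1)
        for trt in sorted(set(cm.samples["treatment"]) - {"0"}):
            cols = cm.sample_ids(condition=condition, treatment=trt)
            if not cols:
                continue
            g, l, n = detection_delta(ref, fpkm_mat[cols].mean(axis=1))
            det_rows.append({"condition": condition, "treatment": trt,
                             "gained": g, "lost": l, "net": n})
    detection = pd.DataFrame(det_rows).set_index(["condition", "treatment"]) \
        if det_rows else pd.DataFrame()

    corr = expression_correlation(fpkm_mat, cm.samples, exclude=targets)

    depth_rows = []
    for (condition, trt), row in gm.iterrows():
        p = min(row["mean"] / 100.0, 0.999)
        raw, rounded = required_depth(DepthModel(required_nontarget, p))
        depth_rows.append({"condition": condition, "treatment": trt,
                           "target_fraction_pct": row["mean"],
                           "required_raw_fragments": raw,
                           "required_raw_Mfragments": rounded / 1e6})
    depth = pd.DataFrame(depth_rows)

    power = None
    if truth is not None:
        try:
            power = de_sensitivity(cm, truth)
        except ValueError:
            power = None
    return EvalReport(per_sample_fraction=frac, per_gene_fraction=per_gene,
                      group_means=gm, reductions=reductions,
                      quartile_bounds=bounds, quartile_means=qmeans,
                      detection=detection, correlation=corr, depth=depth,
                      power=power)
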