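"""Generative model of RNase H-mediated depletion followed by polyA+ RNA-seq.

The mechanism chain per transcript molecule:

1. each hybridized oligo independently directs an RNase H cut at the midpoint
   of its binding window (probability = its cleavage efficiency);
2. polyA+ selection keeps only the fragment carrying the polyA site, i.e. the
   piece from the 3'-most realized cut to the mRNA 3' end (whole molecule if
   no cut landed);
3. retained molecules shorter than ``min_retained_length`` are lost in
   library preparation; surviving molecules yield fragments in proportion to
   their retained length, with fragment start positions uniform on the
   retained interval.

This minimal model reproduces the two artifacts observed in the validating
experiment: residual 3'-terminal signal on depleted targets (coverage decline
5' of the oligo, enrichment of the terminal exons) and isoform escape
(isoforms in which an oligo's window is interrupted by splicing are not cut
by it).

Counts are fragment (pair) counts per gene and per union exon; column sums
equal the library size exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .design import DepletionAssay
from .reference import GeneModel

TREATMENTS = ("0", "A", "B")
CONDITIONS = ("non_challenged", "challenged")


@dataclass
class PoolProfile:
    """Per-gene abundance composition of the transcript pool.

    ``fractions`` must sum to 1.  ``isoform_mix`` optionally sets per-gene
    isoform proportions (default: uniform over the gene's isoforms).
    ``de_genes`` carries ground-truth differential-expression labels applied
    to the challenged condition as fold changes.
    """

    fractions: dict[str, float]
    isoform_mix: dict[str, dict[str, float]] = field(default_factory=dict)
    condition: str = "non_challenged"
    challenge_target_scale: float = 0.27
    de_genes: list[tuple[str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if any(f < 0 for f in self.fractions.values()):
            raise ValueError("abundance fractions must be non-negative")
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"fractions sum to {total}, expected 1")
        for g, fc in self.de_genes:
            if fc <= 0:
                raise ValueError(f"fold change for {g} must be positive")

    @classmethod
    def from_tsv(cls, path: str | Path, **kwargs) -> "PoolProfile":
        df = pd.read_csv(path, sep="\t")
        fr = dict(zip(df["gene_id"], df["fraction"].astype(float)))
        total = sum(fr.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"profile fractions sum to {total}, expected 1")
        fr = {g: v / total for g, v in fr.items()}  # absorb text round-off
        return cls(fractions=fr, **kwargs)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("gene_id\tfraction\n")
            for g, f in self.fractions.items():
                fh.write(f"{g}\t{f:.10g}\n")

    def rescaled(self, scale_genes: Mapping[str, float]) -> "PoolProfile":
        """Scale the named genes' fractions and renormalize."""
        f = {g: v * scale_genes.get(g, 1.0) for g, v in self.fractions.items()}
        total = sum(f.values())
        return PoolProfile(
            fractions={g: v / total for g, v in f.items()},
            isoform_mix=self.isoform_mix, condition=self.condition,
            challenge_target_scale=self.challenge_target_scale,
            de_genes=self.de_genes)


@dataclass
class SimParams:
    """Stochastic parameters of the library simulation."""

    cleavage_efficiency: float = 0.95
    efficiency_by_oligo: dict[str, float] = field(default_factory=dict)
    efficiency_by_treatment: dict[str, float] = field(
        default_factory=lambda: {"A": 0.85, "B": 0.95})
    library_size: int = 1_000_000
    fragment_length_mean: float = 250.0
    fragment_length_sd: float = 60.0
    min_retained_length: int = 150
    read_length: int = 100
    seed: int = 0
    n_animals: int = 3
    animal_sigma: float = 0.25      # lognormal jitter on target abundance
    shutdown_animal: int | None = 3  # 1-based; near-total challenge shutdown
    shutdown_scale: float = 0.002

    def __post_init__(self) -> None:
        if not 0 <= self.cleavage_efficiency <= 1:
            raise ValueError("cleavage_efficiency must be in [0,1]")
        if self.library_size <= 0:
            raise ValueError("library_size must be positive")

    def efficiency_for(self, treatment: str) -> float:
        if treatment == "0":
            return 0.0
        return self.efficiency_by_treatment.get(treatment,
                                                self.cleavage_efficiency)


# ---------------------------------------------------------------------------
# Closed-form retention
# ---------------------------------------------------------------------------

def effective_retention(length: int, cleavage_points: Sequence[int],
                        efficiencies: Sequence[float] | float,
                        min_retained_length: int = 0) -> float:
    """Expected retained-length fraction after cleavage + polyA+ selection.

    With independent per-oligo cuts at points ``c_1..c_k`` (mRNA
    coordinates) and efficiencies ``e_i``, the retained molecule spans from
    the 3'-most realized cut to the 3' end.  The expectation over the 2^k
    binding configurations collapses to a sorted-product form: the 3'-most
    cut is c_j with probability e_j * prod_{i>j} (1 - e_i), and no cut
    happens with probability prod_i (1 - e_i).  Retained pieces shorter than
    ``min_retained_length`` are lost entirely.
    """
    cps = list(cleavage_points)
    if np.isscalar(efficiencies):
        effs = [float(efficiencies)] * len(cps)
    else:
        effs = [float(e) for e in efficiencies]
    if len(effs) != len(cps):
        raise ValueError("one efficiency per cleavage point required")
    for c in cps:
        if not 0 <= c < length:
            raise ValueError(f"cleavage point {c} outside [0,{length})")
    order = np.argsort(cps)
    cps = [cps[i] for i in order]
    effs = [effs[i] for i in order]
    expected = 0.0
    p_no_cut_above = 1.0  # prob that no oligo 3' of the current one cut
    for j in range(len(cps) - 1, -1, -1):
        retained = length - cps[j]
        p = effs[j] * p_no_cut_above
        if retained >= min_retained_length:
            expected += p * retained
        p_no_cut_above *= 1.0 - effs[j]
    if length >= min_retained_length:
        expected += p_no_cut_above * length
    return expected / length


def infer_cleavage_efficiency(p0: float, p_dep: float, cleavage_point: int,
                              length: int) -> float:
    """Invert the single-oligo retention model from observed target fractions.

    ``p0`` and ``p_dep`` are the target gene's fragment fractions (0-1)
    without and with depletion.  Because the library is compositional, the
    retention factor equals the odds ratio of the two fractions; for one
    oligo with cut at ``cleavage_point``, retention r = 1 - e * c / L.
    """
    if not (0 < p0 < 1) or not (0 <= p_dep < 1):
        raise ValueError("fractions must lie in (0,1) / [0,1)")
    odds0 = p0 / (1 - p0)
    odds_d = p_dep / (1 - p_dep)
    r = odds_d / odds0
    e = (1.0 - r) / (cleavage_point / length)
    return float(np.clip(e, 0.0, 1.0))


# ---------------------------------------------------------------------------
# Count container
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    """Fragment counts per gene and per union exon, with sample metadata."""

    counts: pd.DataFrame          # genes x samples
    lengths: pd.Series            # union-exon nt per gene
    exon_counts: pd.DataFrame     # (gene_id, exon_index) x samples
    exon_info: pd.DataFrame       # gene_id, exon_index, start, end, length
    samples: pd.DataFrame         # sample_id index: animal, condition, treatment

    def validate(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")
        per_gene = self.exon_counts.groupby(level="gene_id").sum()
        if not np.array_equal(per_gene.loc[self.counts.index].values,
                              self.counts.values):
            raise ValueError("per-gene counts != sum of per-exon counts")

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def sample_ids(self, **criteria) -> list[str]:
        mask = pd.Series(True, index=self.samples.index)
        for k, v in criteria.items():
            mask &= self.samples[k] == v
        return list(self.samples.index[mask])

    @classmethod
    def concat(cls, mats: Sequence["CountMatrix"]) -> "CountMatrix":
        return cls(counts=pd.concat([m.counts for m in mats], axis=1),
                   lengths=mats[0].lengths,
                   exon_counts=pd.concat([m.exon_counts for m in mats], axis=1),
                   exon_info=mats[0].exon_info,
                   samples=pd.concat([m.samples for m in mats], axis=0))

    def to_tsv(self, outdir: str | Path, header_lines: Sequence[str] = ()) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)

        def _write(df: pd.DataFrame, name: str) -> None:
            with open(outdir / name, "w") as fh:
                for line in header_lines:
                    fh.write(f"# {line}\n")
                df.to_csv(fh, sep="\t")

        gene_tab = self.counts.copy()
        gene_tab.insert(0, "length", self.lengths)
        gene_tab.index.name = "gene_id"
        _write(gene_tab, "gene_counts.tsv")
        exon_tab = self.exon_info.set_index(["gene_id", "exon_index"]).join(
            self.exon_counts)
        _write(exon_tab, "exon_counts.tsv")
        samp = self.samples.copy()
        samp.index.name = "sample_id"
        _write(samp, "samples.tsv")

    @classmethod
    def from_tsv(cls, outdir: str | Path) -> "CountMatrix":
        outdir = Path(outdir)
        gene_tab = pd.read_csv(outdir / "gene_counts.tsv", sep="\t",
                               comment="#", index_col="gene_id")
        exon_tab = pd.read_csv(outdir / "exon_counts.tsv", sep="\t",
                               comment="#")
        samples = pd.read_csv(outdir / "samples.tsv", sep="\t", comment="#",
                              index_col="sample_id")
        samples = samples.astype({"treatment": str})
        lengths = gene_tab["length"]
        counts = gene_tab.drop(columns="length").astype(int)
        exon_info = exon_tab[["gene_id", "exon_index", "start", "end",
                              "length"]].copy()
        exon_counts = exon_tab.set_index(["gene_id", "exon_index"]).drop(
            columns=["start", "end", "length"]).astype(int)
        return cls(counts=counts, lengths=lengths, exon_counts=exon_counts,
                   exon_info=exon_info, samples=samples)


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def _gene_categories(gene: GeneModel, profile: PoolProfile,
                     assay: DepletionAssay | None, efficiency: float,
                     params: SimParams):
    """Per-gene sampling machinery: (iso, 3'-most-cut) categories.

    Returns (weight, cats) where cats is a list of
    (transcript, retained_start, retained_len, prob_mass).
    """
    mix = profile.isoform_mix.get(gene.gene_id)
    if mix is None:
        mix = {t.transcript_id: 1.0 / len(gene.transcripts)
               for t in gene.transcripts}
    recs = assay.by_gene().get(gene.gene_id, []) if assay is not None else []
    cats = []
    for t in gene.transcripts:
        w_iso = mix.get(t.transcript_id, 0.0)
        if w_iso <= 0:
            continue
        L = t.mrna_length
        pairs = []
        for rec in recs:
            site = rec.candidate.cleavage_site(t.transcript_id)
            if site is not None:
                pairs.append((site, params.efficiency_by_oligo.get(
                    rec.name, efficiency)))
        pairs.sort()
        sites = [p[0] for p in pairs]
        effs = [p[1] for p in pairs]
        # category j = index of the 3'-most realized cut (None for no cut)
        # the retention floor applies to cleavage remnants only: intact
        # molecules in the pool are taken as sequenceable by construction
        p_above = 1.0
        for j in range(len(sites) - 1, -1, -1):
            retained = L - sites[j]
            p = effs[j] * p_above
            if retained >= params.min_retained_length and p > 0:
                cats.append((t, sites[j], retained, w_iso * p * retained))
            p_above *= 1.0 - effs[j]
        if p_above > 0:
            cats.append((t, 0, L, w_iso * p_above * L))
    # Profile fractions are fragment shares of the *undepleted* library, so
    # the sampling weight is abundance x mean retention: the expected
    # retained length normalized by the undepleted expected length.
    full_len = sum(mix.get(t.transcript_id, 0.0) * t.mrna_length
                   for t in gene.transcripts)
    if full_len <= 0:
        return 0.0, cats
    weight = (profile.fractions.get(gene.gene_id, 0.0)
              * sum(c[3] for c in cats) / full_len)
    return weight, cats


def _union_exon_index_map(gene: GeneModel, transcript) -> np.ndarray:
    """For each exon of ``transcript`` (transcript order), the index of the
    union exon (transcript order) containing it."""
    union = gene.union_exons()
    out = []
    for s, e in transcript.exons_transcript_order:
        for ui, (us, ue) in enumerate(union):
            if us <= s and e <= ue:
                out.append(ui)
                break
        else:
            raise AssertionError("isoform exon outside union exons")
    return np.asarray(out)


def simulate_counts(genes: Sequence[GeneModel], profile: PoolProfile,
                    assay: DepletionAssay | None, params: SimParams,
                    treatment: str, rng: np.random.Generator | None = None,
                    sample_id: str = "sample", animal: int = 1) -> CountMatrix:
    """Draw one library: multinomial fragments over genes, positions within.

    Treatment "0" skips depletion entirely.  Deterministic for a fixed
    generator state.
    """
    if not profile.fractions or sum(profile.fractions.values()) == 0:
        raise ValueError("empty abundance profile")
    if treatment not in TREATMENTS:
        raise ValueError(f"unknown treatment {treatment!r}")
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    eff = params.efficiency_for(treatment)
    use_assay = assay if treatment != "0" else None

    gene_list = [g for g in genes if profile.fractions.get(g.gene_id, 0) > 0]
    weights = np.empty(len(gene_list))
    cat_table = []
    for i, g in enumerate(gene_list):
        w, cats = _gene_categories(g, profile, use_assay, eff, params)
        weights[i] = w
        cat_table.append(cats)
    if weights.sum() <= 0:
        raise ValueError("no sequenceable material in the pool")
    gene_counts = rng.multinomial(params.library_size,
                                  weights / weights.sum())

    union_info_rows = []
    exon_count_rows = {}
    per_gene_total = {}
    for g, n_g, cats in zip(gene_list, gene_counts, cat_table):
        union = g.union_exons()
        cum = np.cumsum([e - s for s, e in union])
        n_union = len(union)
        exon_counts = np.zeros(n_union, dtype=int)
        if n_g > 0 and cats:
            probs = np.array([c[3] for c in cats])
            probs = probs / probs.sum()
            cat_draw = rng.multinomial(n_g, probs)
            for (t, c_start, retained, _), n_c in zip(cats, cat_draw):
                if n_c == 0:
                    continue
                u = rng.random(n_c)
                starts = (c_start + np.floor(u * retained)).astype(int)
                # map isoform mRNA start -> union exon index
                iso_cum = np.cumsum(
                    [e - s for s, e in t.exons_transcript_order])
                iso_exon = np.searchsorted(iso_cum, starts, side="right")
                uidx = _union_exon_index_map(g, t)[iso_exon]
                exon_counts += np.bincount(uidx, minlength=n_union)
        per_gene_total[g.gene_id] = int(exon_counts.sum())
        for ei, ((s, e), cnt) in enumerate(zip(union, exon_counts)):
            union_info_rows.append((g.gene_id, ei, s, e, e - s))
            exon_count_rows[(g.gene_id, ei)] = int(cnt)

    gene_ids = [g.gene_id for g in gene_list]
    counts = pd.DataFrame({sample_id: [per_gene_total[g] for g in gene_ids]},
                          index=pd.Index(gene_ids, name="gene_id"))
    lengths = pd.Series({g.gene_id: g.union_length() for g in gene_list},
                        name="length").loc[gene_ids]
    exon_info = pd.DataFrame(union_info_rows,
                             columns=["gene_id", "exon_index", "start", "end",
                                      "length"])
    idx = pd.MultiIndex.from_frame(exon_info[["gene_id", "exon_index"]])
    exon_counts_df = pd.DataFrame(
        {sample_id: [exon_count_rows[k] for k in idx]}, index=idx)
    samples = pd.DataFrame(
        {"animal": [animal], "condition": [profile.condition],
         "treatment": [treatment]},
        index=pd.Index([sample_id], name="sample_id"))
    return CountMatrix(counts=counts, lengths=lengths,
                       exon_counts=exon_counts_df, exon_info=exon_info,
                       samples=samples)


def make_study(genes: Sequence[GeneModel], profile_template: PoolProfile,
               assay: DepletionAssay, params: SimParams,
               treatments: Sequence[str] = TREATMENTS) -> CountMatrix:
    """Full factorial study: animals x {non_challenged, challenged} x
    treatments, one library each.

    Animal-level lognormal jitter is applied to the target-gene fractions so
    that per-animal target shares spread around the template (as real cows
    do); the challenged profile scales targets by ``challenge_target_scale``
    and applies the ground-truth ``de_genes`` fold changes.  One animal can
    be designated a near-total challenge shutdown (``shutdown_animal``),
    mimicking an individual whose target synthesis has effectively ceased.
    """
    if params.n_animals < 1:
        raise ValueError("need at least one animal")
    rng = np.random.default_rng(params.seed)
    target_genes = sorted({rec.gene_id for rec in assay.oligos})
    mats = []
    for animal in range(1, params.n_animals + 1):
        jitter = {g: float(rng.lognormal(0.0, params.animal_sigma))
                  for g in target_genes}
        base = profile_template.rescaled(jitter)
        for condition in CONDITIONS:
            if condition == "challenged":
                scale = (params.shutdown_scale
                         if animal == params.shutdown_animal
                         else profile_template.challenge_target_scale)
                scales = {g: scale for g in target_genes}
                scales.update({g: scales.get(g, 1.0) * fc
                               for g, fc in profile_template.de_genes})
                prof = base.rescaled(scales)
            else:
                prof = base
            prof = PoolProfile(fractions=prof.fractions,
                               isoform_mix=prof.isoform_mix,
                               condition=condition,
                               challenge_target_scale=prof.challenge_target_scale,
                               de_genes=prof.de_genes)
            for trt in treatments:
                sid = f"cow{animal}_{condition}_{trt}"
                mats.append(simulate_counts(
                    genes, prof, assay, params, trt, rng=rng,
                    sample_id=sid, animal=animal))
    return CountMatrix.concat(mats)
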