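"""Synthetic reference fixtures: genome, annotation, variants, masks, profile.

Generates a small single-contig genome whose gene set mimics the situation the
depletion assay is built for: a handful of extremely abundant target genes
(default: named after the six bovine milk-protein genes) on a background of
moderately expressed genes.  The generator deliberately plants the two
failure modes the designer must handle:

* one multi-isoform target whose second isoform skips an internal exon, so a
  junction-spanning oligo would miss it (isoform escape);
* one target with an internal run of >7 A's, which would compromise polyA+
  selection and must be reported by QC.

It also plants masked low-complexity/repeat intervals and variant positions
both inside and outside plausible oligo windows.  Output is deterministic for
a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .reference import (GeneModel, MaskSet, TranscriptModel, VariantSet,
                        reverse_complement, write_bed, write_fasta, write_gtf,
                        write_vcf)

MILK_PROTEIN_GENES = ("CSN1S1", "CSN1S2", "CSN2", "CSN3", "LALBA", "PAEP")

# Per-gene share of total fragments among the six targets, shaped like the
# non-challenged bovine mammary profile (caseins dominate, CSN2 on top).
_DEFAULT_TARGET_FRACTIONS = {
    "CSN1S1": 0.170, "CSN1S2": 0.047, "CSN2": 0.223,
    "CSN3": 0.102, "LALBA": 0.015, "PAEP": 0.056,
}


@dataclass
class FixtureConfig:
    n_genes: int = 50
    n_targets: int = 6
    target_names: tuple[str, ...] = MILK_PROTEIN_GENES
    target_total_fraction: float = 0.613
    exon_length_range: tuple[int, int] = (100, 400)
    intron_length_range: tuple[int, int] = (80, 300)
    n_exons_range: tuple[int, int] = (2, 6)
    target_n_exons_range: tuple[int, int] = (4, 8)
    contig: str = "chr1"
    escape_isoform_target: int = 0   # index into targets; gets a skipped exon
    a_run_target: int = 2            # index into targets; gets internal A-run
    a_run_length: int = 9


@dataclass
class FixturePaths:
    fasta: Path
    gtf: Path
    vcf: Path
    bed: Path
    profile: Path


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def make_fixture(config: FixtureConfig, seed: int,
                 outdir: str | Path) -> FixturePaths:
    """Write fasta/gtf/vcf/bed/profile files for a synthetic study genome."""
    if config.n_targets > config.n_genes:
        raise ValueError(
            f"n_targets ({config.n_targets}) exceeds n_genes ({config.n_genes})")
    if config.n_targets > len(config.target_names):
        raise ValueError("not enough target_names for n_targets")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    targets = list(config.target_names[: config.n_targets])
    gene_names = targets + [f"BG{i:04d}" for i in range(config.n_genes - config.n_targets)]

    contig_parts: list[str] = []
    cursor = 0
    genes: list[GeneModel] = []
    masks: list[tuple[str, int, int, str]] = []
    variants: list[tuple[str, int, str, tuple[str, ...]]] = []

    for gi, name in enumerate(gene_names):
        is_target = gi < config.n_targets
        gap = int(rng.integers(100, 300))
        contig_parts.append(_random_seq(rng, gap))
        cursor += gap

        lo, hi = (config.target_n_exons_range if is_target
                  else config.n_exons_range)
        n_exons = int(rng.integers(lo, hi + 1))
        if is_target and gi == config.escape_isoform_target:
            n_exons = max(n_exons, 4)
        # targets are built on the plus strand so planted motifs read off the
        # genome directly; background genes get a random strand
        strand = "+" if is_target else ("+" if rng.random() < 0.5 else "-")

        exons: list[tuple[int, int]] = []
        for ei in range(n_exons):
            elen = int(rng.integers(*config.exon_length_range))
            eseq = _random_seq(rng, elen)
            if is_target and gi == config.a_run_target and ei == n_exons // 2:
                mid = elen // 2
                eseq = (eseq[:mid] + "A" * config.a_run_length
                        + eseq[mid + config.a_run_length:])
            exons.append((cursor, cursor + len(eseq)))
            contig_parts.append(eseq)
            cursor += len(eseq)
            if ei < n_exons - 1:
                ilen = int(rng.integers(*config.intron_length_range))
                contig_parts.append(_random_seq(rng, ilen))
                cursor += ilen

        transcripts = [TranscriptModel(
            transcript_id=f"{name}.t1", gene_id=name, contig=config.contig,
            strand=strand, exons=exons)]
        if is_target and gi == config.escape_isoform_target:
            skipped = exons[:2] + exons[3:]  # second isoform drops exon 3
            transcripts.append(TranscriptModel(
                transcript_id=f"{name}.t2", gene_id=name, contig=config.contig,
                strand=strand, exons=skipped))
        genes.append(GeneModel(gene_id=name, name=name, transcripts=transcripts,
                               canonical_id=f"{name}.t1"))

    # low-complexity stretch inside the terminal exon of the first target,
    # masked, so the designer must route around it
    g0 = genes[0]
    term_s, term_e = g0.canonical.exons_transcript_order[-1]
    lc_start = term_s + 10
    lc_len = 40
    masks.append((config.contig, lc_start, lc_start + lc_len, "low_complexity"))
    # a repeat mask over part of an internal exon of the second target
    g1 = genes[1]
    mid_s, mid_e = g1.canonical.exons_transcript_order[len(g1.canonical.exons) // 2]
    masks.append((config.contig, mid_s, min(mid_s + 60, mid_e), "repeat"))

    contig_parts.append(_random_seq(rng, int(rng.integers(100, 300))))
    contig_seq = "".join(contig_parts)
    # splice the low-complexity run into the already-built sequence
    contig_seq = (contig_seq[:lc_start] + "AT" * (lc_len // 2)
                  + contig_seq[lc_start + lc_len:])

    # variants: one inside the 3'-terminal exon of target 3 (inside candidate
    # windows), a couple in introns/intergenic space (outside any window)
    gv = genes[3]
    vt_s, vt_e = gv.canonical.exons_transcript_order[-1]
    vpos = (vt_s + vt_e) // 2
    for pos in (vpos, 5, len(contig_seq) - 10):
        ref = contig_seq[pos]
        alt = {"A": "G", "C": "T", "G": "A", "T": "C"}[ref]
        variants.append((config.contig, pos, ref, (alt,)))

    # abundance profile
    fracs: dict[str, float] = {}
    tw = np.array([_DEFAULT_TARGET_FRACTIONS.get(n, 0.1) for n in targets])
    tw = tw / tw.sum() * config.target_total_fraction
    for n, f in zip(targets, tw):
        fracs[n] = float(f)
    bg = rng.lognormal(0.0, 1.0, config.n_genes - config.n_targets)
    bg = bg / bg.sum() * (1.0 - config.target_total_fraction)
    for n, f in zip(gene_names[config.n_targets:], bg):
        fracs[n] = float(f)

    # attach mRNA sequences from the final contig
    for g in genes:
        for t in g.transcripts:
            spliced = "".join(contig_seq[s:e] for s, e in t.exons)
            t.mrna_seq = (spliced if t.strand == "+"
                          else reverse_complement(spliced))

    paths = FixturePaths(
        fasta=outdir / "genome.fa", gtf=outdir / "annotation.gtf",
        vcf=outdir / "variants.vcf", bed=outdir / "masks.bed",
        profile=outdir / "profile.tsv")
    write_fasta({config.contig: contig_seq}, paths.fasta)
    if (outdir / "genome.fa.fai").exists():
        (outdir / "genome.fa.fai").unlink()  # stale index would shadow new fasta
    write_gtf(genes, paths.gtf)
    write_vcf(VariantSet(variants), {config.contig: contig_seq}, paths.vcf)
    write_bed(MaskSet(masks), paths.bed)
    with open(paths.profile, "w") as fh:
        fh.write("gene_id\tfraction\n")
        for n in gene_names:
            fh.write(f"{n}\t{fracs[n]:.17g}\n")
    return paths
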