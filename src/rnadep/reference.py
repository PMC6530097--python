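"""Gene models, annotation I/O and genome<->mRNA coordinate conversion.

The depletion designer works in mRNA space (capture oligos are placed at a
distance from the transcript 3' end) while masks and variants live in genome
space, so the central object here is :class:`TranscriptModel`, which owns the
exon structure of one isoform and converts coordinates both ways.

Conventions: all intervals are 0-based half-open internally; GTF I/O converts
to/from the 1-based inclusive GTF convention at the boundary.  mRNA
coordinates run 5'->3' in transcript orientation, i.e. position 0 is the cap
end even on the minus strand.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from pyfaidx import Fasta

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class NotExonicError(ValueError):
    """Raised when a genomic position does not fall in any exon."""


class AnnotationError(ValueError):
    """Raised for malformed or inconsistent annotation input."""


@dataclass
class TranscriptModel:
    """One isoform: an ordered set of exons on a contig plus its mRNA view.

    ``exons`` are genomic intervals sorted by genomic coordinate ascending,
    non-overlapping.  ``mrna_seq`` is the spliced sequence in transcript
    orientation (reverse-complemented for minus-strand transcripts) and is
    populated by :func:`load_reference` / the fixture generator.
    """

    transcript_id: str
    gene_id: str
    contig: str
    strand: str
    exons: list[tuple[int, int]]
    has_polya: bool = True
    mrna_seq: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"strand must be + or -, got {self.strand!r}")
        self.exons = sorted((int(s), int(e)) for s, e in self.exons)
        for (s, e) in self.exons:
            if s >= e:
                raise AnnotationError(f"empty exon interval [{s},{e})")
        for (_, e1), (s2, _) in zip(self.exons, self.exons[1:]):
            if s2 < e1:
                raise AnnotationError("overlapping exons in transcript "
                                      f"{self.transcript_id}")

    @property
    def mrna_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def exons_transcript_order(self) -> list[tuple[int, int]]:
        """Exons ordered 5'->3' along the transcript."""
        return self.exons if self.strand == "+" else self.exons[::-1]

    # -- coordinate conversion -------------------------------------------

    def genome_to_mrna(self, genomic_pos: int) -> int:
        offset = 0
        for s, e in self.exons_transcript_order:
            if s <= genomic_pos < e:
                if self.strand == "+":
                    return offset + (genomic_pos - s)
                return offset + (e - 1 - genomic_pos)
            offset += e - s
        raise NotExonicError(
            f"position {genomic_pos} is not exonic in {self.transcript_id}")

    def mrna_to_genome(self, mrna_pos: int) -> int:
        if not 0 <= mrna_pos < self.mrna_length:
            raise NotExonicError(
                f"mRNA position {mrna_pos} outside [0,{self.mrna_length})")
        offset = mrna_pos
        for s, e in self.exons_transcript_order:
            if offset < e - s:
                return s + offset if self.strand == "+" else e - 1 - offset
            offset -= e - s
        raise AssertionError("unreachable")

    def mrna_interval_to_genomic(self, start: int, end: int) -> list[tuple[int, int]]:
        """Map an mRNA interval [start, end) to genomic intervals.

        Returns one interval per exon touched, sorted by genomic coordinate.
        """
        if not 0 <= start < end <= self.mrna_length:
            raise NotExonicError(f"mRNA interval [{start},{end}) out of range")
        pieces = []
        offset = 0
        for s, e in self.exons_transcript_order:
            exon_len = e - s
            lo = max(start, offset)
            hi = min(end, offset + exon_len)
            if lo < hi:
                if self.strand == "+":
                    pieces.append((s + (lo - offset), s + (hi - offset)))
                else:
                    pieces.append((e - (hi - offset), e - (lo - offset)))
            offset += exon_len
        return sorted(pieces)

    def exon_index_of_mrna_pos(self, mrna_pos: int) -> int:
        """Index (transcript order, 0-based) of the exon containing mrna_pos."""
        if not 0 <= mrna_pos < self.mrna_length:
            raise NotExonicError(f"mRNA position {mrna_pos} out of range")
        offset = 0
        for i, (s, e) in enumerate(self.exons_transcript_order):
            if mrna_pos < offset + (e - s):
                return i
            offset += e - s
        raise AssertionError("unreachable")


@dataclass
class GeneModel:
    """A gene: one or more isoforms sharing gene_id, strand and contig."""

    gene_id: str
    name: str
    transcripts: list[TranscriptModel]
    canonical_id: str | None = None

    def __post_init__(self) -> None:
        if not self.transcripts:
            return
        strands = {t.strand for t in self.transcripts}
        contigs = {t.contig for t in self.transcripts}
        if len(strands) > 1 or len(contigs) > 1:
            raise AnnotationError(
                f"transcripts of {self.gene_id} disagree on strand/contig")
        for t in self.transcripts:
            if t.gene_id != self.gene_id:
                raise AnnotationError(
                    f"transcript {t.transcript_id} has gene_id {t.gene_id}, "
                    f"expected {self.gene_id}")
        if self.canonical_id is None:
            # longest isoform, ties by id, as a stable default
            self.canonical_id = max(
                self.transcripts, key=lambda t: (t.mrna_length, t.transcript_id)
            ).transcript_id
        elif self.canonical_id not in {t.transcript_id for t in self.transcripts}:
            raise AnnotationError(
                f"canonical_id {self.canonical_id} not among transcripts of "
                f"{self.gene_id}")

    @property
    def canonical(self) -> TranscriptModel:
        return next(t for t in self.transcripts
                    if t.transcript_id == self.canonical_id)

    @property
    def strand(self) -> str:
        return self.transcripts[0].strand

    @property
    def contig(self) -> str:
        return self.transcripts[0].contig

    def union_exons(self) -> list[tuple[int, int]]:
        """Merged exonic intervals over all isoforms, transcript order."""
        ivals = sorted(iv for t in self.transcripts for iv in t.exons)
        merged: list[list[int]] = []
        for s, e in ivals:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        out = [(s, e) for s, e in merged]
        return out if self.strand == "+" else out[::-1]

    def union_length(self) -> int:
        return sum(e - s for s, e in self.union_exons())


@dataclass
class VariantSet:
    """Known variant sites: (contig, 0-based position, ref, alts)."""

    records: list[tuple[str, int, str, tuple[str, ...]]] = field(default_factory=list)

    @classmethod
    def from_vcf(cls, path: str | Path) -> "VariantSet":
        from cyvcf2 import VCF

        recs = []
        for v in VCF(str(path)):
            recs.append((v.CHROM, v.start, v.REF, tuple(v.ALT)))
        return cls(recs)

    def positions_in(self, contig: str, start: int, end: int) -> list[int]:
        return [p for c, p, _, _ in self.records if c == contig and start <= p < end]

    def validate_against(self, fasta: Fasta) -> None:
        for c, p, ref, _ in self.records:
            seq = str(fasta[c][p:p + len(ref)]).upper()
            if seq != ref.upper():
                raise AnnotationError(
                    f"variant ref mismatch at {c}:{p}: VCF says {ref}, "
                    f"reference has {seq}")


@dataclass
class MaskSet:
    """Repeat / low-complexity intervals, 0-based half-open, labelled."""

    intervals: list[tuple[str, int, int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for c, s, e, lab in self.intervals:
            if s >= e:
                raise AnnotationError(f"empty mask interval {c}:{s}-{e}")

    @classmethod
    def from_bed(cls, path: str | Path) -> "MaskSet":
        ivals = []
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track")):
                    continue
                parts = line.rstrip("\n").split("\t")
                label = parts[3] if len(parts) > 3 else "repeat"
                ivals.append((parts[0], int(parts[1]), int(parts[2]), label))
        return cls(ivals)

    def labels_overlapping(self, contig: str, start: int, end: int) -> set[str]:
        return {lab for c, s, e, lab in self.intervals
                if c == contig and s < end and start < e}


# ---------------------------------------------------------------------------
# GTF I/O (minimal dialect: exon features with gene_id/transcript_id)
# ---------------------------------------------------------------------------

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_gtf_exons(gtf_path: str | Path):
    """Yield (contig, start0, end0, strand, attrs, lineno) for exon features."""
    with open(gtf_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise AnnotationError(
                    f"malformed GTF line {lineno}: expected 9 tab-separated "
                    f"fields, got {len(fields)}")
            contig, _, feature, start, end, _, strand, _, attr_str = fields
            if feature != "exon":
                continue
            try:
                s0, e0 = int(start) - 1, int(end)
            except ValueError as exc:
                raise AnnotationError(f"malformed GTF line {lineno}: "
                                      f"non-integer coordinates") from exc
            attrs = dict(_ATTR_RE.findall(attr_str))
            if "gene_id" not in attrs or "transcript_id" not in attrs:
                raise AnnotationError(
                    f"malformed GTF line {lineno}: missing gene_id or "
                    f"transcript_id attribute")
            yield contig, s0, e0, strand, attrs, lineno


def load_reference(fasta_path: str | Path, gtf_path: str | Path) -> list[GeneModel]:
    """Load gene models from FASTA + GTF and attach spliced mRNA sequences.

    Minus-strand mRNA is the reverse complement of the concatenated exon
    sequence.  Fatal errors name the offending contig or GTF line.
    """
    fasta = Fasta(str(fasta_path), as_raw=True, sequence_always_upper=True)
    tx_exons: dict[str, dict] = {}
    order: list[str] = []
    for contig, s0, e0, strand, attrs, lineno in _parse_gtf_exons(gtf_path):
        tid = attrs["transcript_id"]
        rec = tx_exons.setdefault(tid, {
            "gene_id": attrs["gene_id"],
            "gene_name": attrs.get("gene_name", attrs["gene_id"]),
            "contig": contig, "strand": strand, "exons": [],
        })
        rec["exons"].append((s0, e0))
        if tid not in order:
            order.append(tid)

    genes: dict[str, GeneModel] = {}
    gene_order: list[str] = []
    gene_tx: dict[str, list[TranscriptModel]] = {}
    gene_name: dict[str, str] = {}
    for tid in order:
        rec = tx_exons[tid]
        if rec["contig"] not in fasta:
            raise AnnotationError(
                f"contig {rec['contig']!r} of transcript {tid} missing from "
                f"FASTA")
        tm = TranscriptModel(transcript_id=tid, gene_id=rec["gene_id"],
                             contig=rec["contig"], strand=rec["strand"],
                             exons=rec["exons"])
        contig_len = len(fasta[rec["contig"]])
        if tm.exons[-1][1] > contig_len:
            raise AnnotationError(
                f"exon of {tid} extends past end of contig {rec['contig']} "
                f"({tm.exons[-1][1]} > {contig_len})")
        spliced = "".join(str(fasta[rec["contig"]][s:e]) for s, e in tm.exons)
        tm.mrna_seq = spliced if tm.strand == "+" else reverse_complement(spliced)
        gene_tx.setdefault(rec["gene_id"], []).append(tm)
        gene_name.setdefault(rec["gene_id"], rec["gene_name"])
        if rec["gene_id"] not in gene_order:
            gene_order.append(rec["gene_id"])
    for gid in gene_order:
        genes[gid] = GeneModel(gene_id=gid, name=gene_name[gid],
                               transcripts=gene_tx[gid])
    return [genes[g] for g in gene_order]


def write_gtf(genes: Iterable[GeneModel], path: str | Path,
              source: str = "rnadep") -> None:
    with open(path, "w") as fh:
        for g in genes:
            for t in g.transcripts:
                for s, e in t.exons:
                    attrs = (f'gene_id "{g.gene_id}"; '
                             f'transcript_id "{t.transcript_id}"; '
                             f'gene_name "{g.name}";')
                    fh.write("\t".join([
                        t.contig, source, "exon", str(s + 1), str(e), ".",
                        t.strand, ".", attrs]) + "\n")


def write_fasta(contigs: dict[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_vcf(variants: VariantSet, contigs: dict[str, str],
              path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, seq in contigs.items():
            fh.write(f"##contig=<ID={name},length={len(seq)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c, p, ref, alts in sorted(variants.records):
            fh.write(f"{c}\t{p + 1}\t.\t{ref}\t{','.join(alts)}\t.\tPASS\t.\n")


def write_bed(masks: MaskSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for c, s, e, lab in sorted(masks.intervals):
            fh.write(f"{c}\t{s}\t{e}\t{lab}\n")
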