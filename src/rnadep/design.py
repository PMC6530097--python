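"""Antisense capture-oligo design for RNase H-mediated transcript depletion.

Candidate oligos are enumerated as every window of every allowed length on
the canonical isoform's mRNA, scored thermodynamically (nearest-neighbor
duplex Tm) and flagged against the design constraints the assay imposes:

* Tm above a floor (default 65 C) so the DNA:RNA hybrid survives the
  hybridization temperature;
* outside repeat / low-complexity sequence (annotation masks plus a
  DUST-style triplet score), known variant positions and, by default,
  splice junctions that are absent from any isoform (an oligo spanning a
  junction that some isoforms lack leaves those isoforms undepleted);
* as close as practical to the 3' end, because after RNase H cleavage only
  the 3'-terminal fragment still carries the polyA site and survives polyA+
  selection -- a residual signal that shrinks with the oligo's distance to
  the 3' end.

Selection takes the best non-overlapping ``n_per_gene`` candidates per gene
(default two, as in the validated bovine milk-protein assay) and attaches a
concentration scheme: A (abundance-informed, fixed per-gene values) or B
(equimolar 25 uM).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.SeqUtils import MeltingTemp as _mt

from .panel import CONCENTRATIONS_UM
from .reference import GeneModel, MaskSet, TranscriptModel, VariantSet, \
    reverse_complement

DISQUALIFYING_FLAGS = ("repeat_overlap", "low_complexity", "variant_overlap")


@dataclass
class DesignParams:
    """Tunable constraints for oligo enumeration and selection."""

    length_range: tuple[int, int] = (24, 30)
    tm_min: float = 65.0
    na_mM: float = 250.0        # monovalent salt for the Tm model
    oligo_nM: float = 250.0     # oligo strand concentration for the Tm model
    max_mismatches: int = 2     # off-target scan sensitivity
    max_offtarget_hits: int = 0
    dust_threshold: float = 2.0
    max_internal_A_run: int = 7
    n_per_gene: int = 2
    min_isoform_coverage: float = 1.0  # junction oligos must cover all isoforms

    def __post_init__(self) -> None:
        if self.tm_min <= 0:
            raise ValueError("tm_min must be positive")
        if self.length_range[0] > self.length_range[1] or self.length_range[0] < 8:
            raise ValueError(f"invalid length_range {self.length_range}")


@dataclass
class OligoCandidate:
    """An antisense oligo candidate with placement and QC metadata.

    ``mrna_start``/``mrna_end`` locate the sense window on the canonical
    isoform; ``placements`` maps transcript_id to (start, end,
    distance_to_3prime) or None where the window is not a contiguous
    substring of that isoform (isoform escape).
    """

    target_gene: str
    sequence: str               # antisense DNA, 5'->3'
    mrna_start: int
    mrna_end: int
    distance_to_3prime: int     # canonical mrna_length - mrna_end
    tm: float
    placements: dict[str, tuple[int, int, int] | None]
    isoform_coverage: float
    flags: set[str] = field(default_factory=set)
    offtarget_hits: int = 0

    @property
    def length(self) -> int:
        return len(self.sequence)

    def cleavage_site(self, transcript_id: str) -> int | None:
        """RNase H cleavage point on an isoform: hybrid midpoint, rounded 3'."""
        p = self.placements.get(transcript_id)
        if p is None:
            return None
        s, e, _ = p
        return (s + e + 1) // 2


@dataclass
class OligoRecord:
    gene_id: str
    name: str
    candidate: OligoCandidate
    concentration_uM: float


@dataclass
class DepletionAssay:
    """Selected oligos per gene plus the concentration scheme."""

    scheme: str
    oligos: list[OligoRecord]
    failures: dict[str, str] = field(default_factory=dict)
    qc_warnings: dict[str, str] = field(default_factory=dict)

    def by_gene(self) -> dict[str, list[OligoRecord]]:
        out: dict[str, list[OligoRecord]] = {}
        for rec in self.oligos:
            out.setdefault(rec.gene_id, []).append(rec)
        return out

    def to_frame(self):
        import pandas as pd

        rows = []
        for rec in self.oligos:
            c = rec.candidate
            rows.append({
                "gene_id": rec.gene_id, "oligo_name": rec.name,
                "sequence": c.sequence, "length": c.length,
                "tm": round(c.tm, 2), "mrna_start": c.mrna_start,
                "mrna_end": c.mrna_end,
                "distance_to_3prime": c.distance_to_3prime,
                "isoform_coverage": c.isoform_coverage,
                "flags": ",".join(sorted(c.flags)) or ".",
                "offtarget_hits": c.offtarget_hits,
                "concentration_uM": rec.concentration_uM,
                "scheme": self.scheme,
            })
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Thermodynamics and sequence QC
# ---------------------------------------------------------------------------

def melting_temperature(duplex_seq: str, na_mM: float = 250.0,
                        oligo_nM: float = 250.0) -> float:
    """Nearest-neighbor duplex Tm (C) with monovalent-salt correction.

    Uses the unified DNA/DNA nearest-neighbor parameter set with the
    Owczarzy monovalent correction; the DNA:RNA hybrid is approximated by
    its DNA/DNA proxy.  Non-symmetric duplex with the oligo in excess.
    """
    seq = duplex_seq.upper()
    if len(seq) < 8:
        raise ValueError(f"duplex shorter than 8 nt: {len(seq)}")
    if set(seq) - set("ACGT"):
        raise ValueError(f"ambiguity codes not supported: {set(seq) - set('ACGT')}")
    return float(_mt.Tm_NN(seq, nn_table=_mt.DNA_NN3, Na=na_mM,
                           dnac1=oligo_nM, dnac2=0, saltcorr=5))


def low_complexity_score(window_seq: str) -> float:
    """DUST-style triplet-repetition score; 0 for all-distinct triplets.

    score = sum_t c_t (c_t - 1) / 2 / (k - 1) over triplet counts c_t,
    where k is the number of overlapping triplets in the window.
    Homopolymers score maximally, and complementing a homopolymer leaves
    the score unchanged.
    """
    seq = window_seq.upper()
    if len(seq) < 3:
        raise ValueError("window shorter than 3 nt")
    counts: dict[str, int] = {}
    for i in range(len(seq) - 2):
        t = seq[i:i + 3]
        counts[t] = counts.get(t, 0) + 1
    k = len(seq) - 2
    s = sum(c * (c - 1) // 2 for c in counts.values())
    return s / max(k - 1, 1)


def polya_run_check(mrna_seq: str, max_run: int = 7,
                    has_polya_tail: bool = False) -> list[tuple[int, int]]:
    """Maximal internal runs of 'A' longer than ``max_run``.

    Returns [start, end) intervals.  If ``has_polya_tail`` a run that
    terminates the sequence is treated as the annotated tail and skipped.
    """
    out = []
    for m in re.finditer(r"A+", mrna_seq.upper()):
        if m.end() - m.start() > max_run:
            if has_polya_tail and m.end() == len(mrna_seq):
                continue
            out.append((m.start(), m.end()))
    return out


# ---------------------------------------------------------------------------
# Candidate enumeration
# ---------------------------------------------------------------------------

def enumerate_candidates(gene: GeneModel, params: DesignParams,
                         masks: MaskSet | None = None,
                         variants: VariantSet | None = None
                         ) -> list[OligoCandidate]:
    """All (window, length) antisense candidates on the canonical isoform.

    Each candidate carries its Tm, QC flags, and a placement on every
    isoform (by exact substring search of the sense window; a window whose
    sequence is interrupted by alternative splicing in an isoform is marked
    incompatible with it).
    """
    canonical = gene.canonical
    mrna = canonical.mrna_seq
    if not canonical.exons or not mrna:
        return []
    isoform_seqs = {t.transcript_id: t.mrna_seq for t in gene.transcripts}
    L = len(mrna)
    lo, hi = params.length_range
    candidates: list[OligoCandidate] = []
    for length in range(lo, hi + 1):
        for start in range(0, L - length + 1):
            end = start + length
            sense = mrna[start:end]
            if set(sense) - set("ACGT"):
                continue
            placements: dict[str, tuple[int, int, int] | None] = {}
            for tid, iso_seq in isoform_seqs.items():
                pos = iso_seq.find(sense)
                if pos < 0:
                    placements[tid] = None
                else:
                    placements[tid] = (pos, pos + length,
                                       len(iso_seq) - (pos + length))
            coverage = (sum(p is not None for p in placements.values())
                        / len(placements))
            flags: set[str] = set()
            genomic = canonical.mrna_interval_to_genomic(start, end)
            if len(genomic) > 1:
                flags.add("junction_spanning")
            if masks is not None:
                labels: set[str] = set()
                for gs, ge in genomic:
                    labels |= masks.labels_overlapping(canonical.contig, gs, ge)
                if "repeat" in labels:
                    flags.add("repeat_overlap")
                if "low_complexity" in labels:
                    flags.add("low_complexity")
            if low_complexity_score(sense) > params.dust_threshold:
                flags.add("low_complexity")
            if variants is not None and any(
                    variants.positions_in(canonical.contig, gs, ge)
                    for gs, ge in genomic):
                flags.add("variant_overlap")
            candidates.append(OligoCandidate(
                target_gene=gene.gene_id,
                sequence=reverse_complement(sense),
                mrna_start=start, mrna_end=end,
                distance_to_3prime=L - end,
                tm=melting_temperature(sense, params.na_mM, params.oligo_nM),
                placements=placements, isoform_coverage=coverage,
                flags=flags))
    return candidates


def offtarget_scan(candidate: OligoCandidate,
                   transcriptome: Mapping[str, tuple[str, str]],
                   max_mismatches: int = 0) -> int:
    """Count non-target transcripts matching the oligo's sense window.

    ``transcriptome`` maps transcript_id -> (gene_id, mRNA sequence).  A
    transcript is a hit when the sense window occurs at any position with at
    most ``max_mismatches`` mismatches; the target gene's own isoforms are
    excluded.  Sliding-window Hamming comparison over byte arrays.
    """
    sense = reverse_complement(candidate.sequence)
    w = np.frombuffer(sense.encode(), dtype=np.uint8)
    k = len(w)
    hits = 0
    for tid, (gene_id, seq) in transcriptome.items():
        if gene_id == candidate.target_gene:
            continue
        if seq is None or len(seq) < k:
            continue
        if max_mismatches == 0:
            hits += sense in seq
            continue
        a = np.frombuffer(seq.encode(), dtype=np.uint8)
        windows = np.lib.stride_tricks.sliding_window_view(a, k)
        mism = (windows != w).sum(axis=1)
        hits += bool((mism <= max_mismatches).any())
    return hits


# ---------------------------------------------------------------------------
# Selection
# ---------------------------------------------------------------------------

def _passes_filters(c: OligoCandidate, params: DesignParams) -> bool:
    if c.tm < params.tm_min:
        return False
    if any(f in c.flags for f in DISQUALIFYING_FLAGS):
        return False
    if c.offtarget_hits > params.max_offtarget_hits:
        return False
    if ("junction_spanning" in c.flags
            and c.isoform_coverage < params.min_isoform_coverage):
        return False
    return True


def _score_key(c: OligoCandidate, params: DesignParams):
    """Lexicographic ranking: fewest flags, max isoform coverage, closest to
    the 3' end, Tm closest above the floor; deterministic tie-break."""
    tm_excess = c.tm - params.tm_min if c.tm >= params.tm_min else math.inf
    return (len(c.flags), -c.isoform_coverage, c.distance_to_3prime,
            tm_excess, c.mrna_start, c.sequence)


def select_for_gene(candidates: Sequence[OligoCandidate],
                    params: DesignParams) -> list[OligoCandidate]:
    """Greedy pick of the n_per_gene best, pairwise non-overlapping on the
    canonical isoform."""
    ranked = sorted((c for c in candidates if _passes_filters(c, params)),
                    key=lambda c: _score_key(c, params))
    chosen: list[OligoCandidate] = []
    for c in ranked:
        if len(chosen) >= params.n_per_gene:
            break
        if all(c.mrna_end <= o.mrna_start or o.mrna_end <= c.mrna_start
               for o in chosen):
            chosen.append(c)
    return chosen


def select_assay(candidates_by_gene: Mapping[str, Sequence[OligoCandidate]],
                 params: DesignParams, scheme: str = "B",
                 concentration_map: Mapping[str, float] | None = None
                 ) -> DepletionAssay:
    """Assemble the assay sheet with scheme A/B concentrations.

    Scheme B is equimolar 25 uM.  Scheme A uses the validated bovine
    milk-protein concentrations where the gene name matches that panel and a
    user-supplied map otherwise (falling back to 25 uM).
    """
    if scheme not in ("A", "B"):
        raise ValueError(f"scheme must be A or B, got {scheme!r}")
    oligos: list[OligoRecord] = []
    failures: dict[str, str] = {}
    for gene_id in candidates_by_gene:
        cands = candidates_by_gene[gene_id]
        chosen = select_for_gene(cands, params)
        if not chosen:
            n_tm = sum(c.tm < params.tm_min for c in cands)
            n_flag = sum(any(f in c.flags for f in DISQUALIFYING_FLAGS)
                         for c in cands)
            failures[gene_id] = (
                "design failed: no candidate passed filters "
                f"({len(cands)} enumerated, {n_tm} below Tm floor, "
                f"{n_flag} flagged)")
            continue
        if scheme == "B":
            conc = 25.0
        else:
            conc = CONCENTRATIONS_UM["A"].get(gene_id)
            if conc is None and concentration_map is not None:
                conc = concentration_map.get(gene_id)
            if conc is None:
                conc = 25.0
        for i, c in enumerate(chosen, 1):
            oligos.append(OligoRecord(gene_id=gene_id,
                                      name=f"{gene_id}_R{i}",
                                      candidate=c, concentration_uM=conc))
    return DepletionAssay(scheme=scheme, oligos=oligos, failures=failures)


def design_assay(genes: Iterable[GeneModel], target_ids: Sequence[str],
                 params: DesignParams | None = None,
                 masks: MaskSet | None = None,
                 variants: VariantSet | None = None,
                 scheme: str = "B",
                 concentration_map: Mapping[str, float] | None = None
                 ) -> DepletionAssay:
    """End-to-end design: enumerate, off-target-scan and select per target."""
    params = params or DesignParams()
    genes = list(genes)
    by_id = {g.gene_id: g for g in genes}
    transcriptome = {t.transcript_id: (g.gene_id, t.mrna_seq)
                     for g in genes for t in g.transcripts}
    cands: dict[str, list[OligoCandidate]] = {}
    qc: dict[str, str] = {}
    for gid in target_ids:
        if gid not in by_id:
            raise KeyError(f"target gene {gid!r} not in annotation")
        gene = by_id[gid]
        runs = polya_run_check(gene.canonical.mrna_seq or "",
                               params.max_internal_A_run,
                               has_polya_tail=gene.canonical.has_polya)
        if runs:
            # internal A-runs would survive cleavage as false polyA signals
            # during polyA+ selection; the target remains designable but the
            # caller should know depletion may be compromised
            qc[gid] = (f"internal polyA run(s) > {params.max_internal_A_run}"
                       f" nt at {runs}")
        cc = enumerate_candidates(gene, params, masks, variants)
        for c in cc:
            c.offtarget_hits = offtarget_scan(c, transcriptome, 0)
        cands[gid] = cc
    assay = select_assay(cands, params, scheme, concentration_map)
    assay.qc_warnings = qc
    return assay
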