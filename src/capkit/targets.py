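"""Identification of on-target contigs by local alignment against a
reference library of target loci (typically bait exons), with paralog
exclusion and multi-locus contig handling.

A locus hit by two or more distinct contigs in one sample suggests gene
duplication (paralogy) and is excluded from that sample's accepted set.
A long contig spanning several adjacent reference exons is flagged as a
multi-locus contig and can be kept (assigned to each locus it hits, with
its full sequence including interspersed introns) or excluded.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from ._align import sw_affine
from .assembly import Contig
from .dna import revcomp
from .io import SeqRecord, read_fasta, write_fasta

DEFAULT_SCORING = (1, -2, -5, -1)
SW_EXACT_LIMIT = 5000  # above this, seed-and-extend
SEED_LEN = 15
BAND = 31


@dataclass
class LocusMatch:
    contig_id: str
    locus_id: str
    score: int
    identity: float
    strand: str
    contig_interval: tuple[int, int]  # 0-based half-open, forward contig coords
    reference_interval: tuple[int, int]


@dataclass
class TargetContigTable:
    sample_id: str
    accepted: dict[str, str] = field(default_factory=dict)  # locus -> contig id
    excluded_paralog_loci: list[tuple[str, list[str]]] = field(default_factory=list)
    multilocus_contigs: list[tuple[str, list[str]]] = field(default_factory=list)


def _align_oriented(query: str, target: str, scoring) -> tuple[int, tuple, tuple, float]:
    score, qiv, tiv, matches, columns = sw_affine(query, target, scoring)
    identity = matches / columns if columns else 0.0
    return score, qiv, tiv, identity


def _seed_and_extend(query: str, target: str, scoring):
    """Seed-and-extend local alignment for long sequence pairs.

    Exact SEED_LEN-mer seeds anchor a banded Smith-Waterman restricted to
    a window around the seed diagonal; the best-scoring window wins.
    """
    index: dict[str, list[int]] = defaultdict(list)
    for i in range(len(target) - SEED_LEN + 1):
        index[target[i : i + SEED_LEN]].append(i)
    diagonals: set[int] = set()
    for i in range(len(query) - SEED_LEN + 1):
        for j in index.get(query[i : i + SEED_LEN], ()):
            diagonals.add(j - i)
    if not diagonals:
        return 0, (0, 0), (0, 0), 0.0
    # merge nearby diagonals into bands and run exact SW on each window
    best = (0, (0, 0), (0, 0), 0.0)
    merged: list[tuple[int, int]] = []
    for d in sorted(diagonals):
        if merged and d - merged[-1][1] <= BAND:
            merged[-1] = (merged[-1][0], d)
        else:
            merged.append((d, d))
    for dlo, dhi in merged:
        tlo = max(0, dlo - BAND)
        thi = min(len(target), dhi + len(query) + BAND)
        score, qiv, tiv, ident = _align_oriented(query, target[tlo:thi], scoring)
        if score > best[0]:
            best = (score, qiv, (tiv[0] + tlo, tiv[1] + tlo), ident)
    return best


def local_align(query: str, target: str, scoring=DEFAULT_SCORING) -> LocusMatch:
    """Best local alignment of query against target, both strands tried.

    Sequence pairs up to SW_EXACT_LIMIT use exact Smith-Waterman with
    affine gaps; longer pairs use seed-and-extend. Intervals are 0-based
    half-open; the contig interval always refers to forward query
    coordinates.
    """
    if not query or not target:
        raise ValueError("local_align requires non-empty sequences")
    use_exact = max(len(query), len(target)) <= SW_EXACT_LIMIT
    align = _align_oriented if use_exact else _seed_and_extend
    results = {}
    for strand, q in (("+", query), ("-", revcomp(query))):
        score, qiv, tiv, ident = align(q, target, scoring)
        if strand == "-":
            qiv = (len(query) - qiv[1], len(query) - qiv[0])
        results[strand] = (score, qiv, tiv, ident)
    strand = "+" if results["+"][0] >= results["-"][0] else "-"
    score, qiv, tiv, ident = results[strand]
    return LocusMatch("query", "target", score, ident, strand, qiv, tiv)


def find_target_contigs(
    contigs: list[Contig],
    reference: list[SeqRecord],
    min_identity: float = 0.85,
    min_coverage_of_locus: float = 0.5,
    paralog_evidence_coverage: float = 0.25,
    keep_multilocus: bool = True,
) -> tuple[TargetContigTable, dict[str, SeqRecord]]:
    """Match one sample's contigs against the reference loci.

    Two hit tiers share the identity threshold but differ in how much of
    the locus the match must span. A *full* hit (span >=
    ``min_coverage_of_locus`` x locus length) is required to assign a
    contig to a locus. A weaker *evidence* hit (span >=
    ``paralog_evidence_coverage`` x locus length) counts toward the
    paralogy rule: diverged gene duplicates often assemble into
    fragmentary contigs whose partial matches are exactly the signal the
    exclusion rule exists for, so a locus with evidence hits from two or
    more distinct contigs is excluded as potentially paralogous.

    Returns the keep/exclude table and the extracted per-locus sequences
    (``<sample>_<locus>`` ids, contig oriented to reference strand; a
    multi-locus contig contributes its full sequence to every locus it
    fully hits).
    """
    ids = [r.id for r in reference]
    if len(set(ids)) != len(ids):
        raise ValueError("reference locus ids must be unique")
    sample_id = contigs[0].sample_id if contigs else ""

    # best hit per (contig, locus) at the evidence tier
    hits: dict[tuple[str, str], LocusMatch] = {}
    full: set[tuple[str, str]] = set()
    for contig in contigs:
        for locus in reference:
            match = local_align(contig.sequence, locus.sequence)
            ref_span = match.reference_interval[1] - match.reference_interval[0]
            if match.identity < min_identity:
                continue
            if ref_span < paralog_evidence_coverage * len(locus):
                continue
            match.contig_id = contig.id
            match.locus_id = locus.id
            key = (contig.id, locus.id)
            if key not in hits or _hit_rank(match) > _hit_rank(hits[key]):
                hits[key] = match
            if ref_span >= min_coverage_of_locus * len(locus):
                full.add(key)

    by_contig: dict[str, list[LocusMatch]] = defaultdict(list)
    for match in hits.values():
        by_contig[match.contig_id].append(match)

    table = TargetContigTable(sample_id)
    surviving: list[LocusMatch] = []
    for contig_id in sorted(by_contig):
        matches = by_contig[contig_id]
        full_loci = sorted(
            m.locus_id for m in matches if (contig_id, m.locus_id) in full
        )
        if len(full_loci) >= 2:
            table.multilocus_contigs.append((contig_id, full_loci))
            if not keep_multilocus:
                continue  # rule (b): excluded before the paralogy check
        surviving.extend(matches)

    by_locus: dict[str, list[LocusMatch]] = defaultdict(list)
    for match in surviving:
        by_locus[match.locus_id].append(match)

    contig_seqs = {c.id: c.sequence for c in contigs}
    extracted: dict[str, SeqRecord] = {}
    for locus_id in sorted(by_locus):
        matches = by_locus[locus_id]
        paralogous = _paralogy_evidence(matches)
        if paralogous:
            table.excluded_paralog_loci.append((locus_id, paralogous))
            continue
        best = max(matches, key=_hit_rank)
        if (best.contig_id, locus_id) not in full:
            continue  # partial evidence only: neither accepted nor flagged
        table.accepted[locus_id] = best.contig_id
        seq = contig_seqs[best.contig_id]
        if best.strand == "-":
            seq = revcomp(seq)
        extracted[locus_id] = SeqRecord(f"{sample_id}_{locus_id}", seq)
    return table, extracted


def _paralogy_evidence(matches: list[LocusMatch]) -> list[str]:
    """Contigs whose matches make a locus look paralogous.

    Two distinct contigs are evidence of paralogy only when their matched
    reference intervals overlap by at least half of the shorter interval:
    duplicate gene copies align to the SAME stretch of the locus, whereas
    complementary fragments of one broken assembly tile it side by side.
    Returns the sorted contig ids involved, empty if the locus is clean.
    """
    flagged: set[str] = set()
    for i, a in enumerate(matches):
        for b in matches[i + 1 :]:
            if a.contig_id == b.contig_id:
                continue
            (a_start, a_end), (b_start, b_end) = (
                a.reference_interval, b.reference_interval
            )
            overlap = min(a_end, b_end) - max(a_start, b_start)
            shorter = min(a_end - a_start, b_end - b_start)
            if shorter > 0 and overlap >= 0.5 * shorter:
                flagged.update((a.contig_id, b.contig_id))
    return sorted(flagged)


def _hit_rank(match: LocusMatch):
    span = match.reference_interval[1] - match.reference_interval[0]
    # higher score, then longer reference interval, then lexicographic locus
    return (match.score, span, _NegStr(match.locus_id))


class _NegStr(str):
    """Reverses string comparison so max() prefers the smaller id."""

    def __lt__(self, other):  # type: ignore[override]
        return str.__gt__(self, other)

    def __gt__(self, other):  # type: ignore[override]
        return str.__lt__(self, other)


def run_sample_file(
    contig_fasta,
    reference: list[SeqRecord],
    out_dir,
    sample_id: str,
    **kwargs,
) -> TargetContigTable:
    """File-level wrapper: read a sample's contig FASTA, write the
    extracted target-contig FASTA and return the flag table."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    contigs = [
        Contig(rec.id, rec.sequence, 0.0, sample_id) for rec in read_fasta(contig_fasta)
    ]
    table, extracted = find_target_contigs(contigs, reference, **kwargs)
    write_fasta(
        [extracted[locus] for locus in sorted(extracted)],
        out_dir / f"{sample_id}_target_contigs.fasta",
    )
    return table


def recovery_matrix(
    tables: list[TargetContigTable], reference: list[SeqRecord]
) -> tuple[pd.DataFrame, pd.Series]:
    """Sample x locus boolean recovery table plus per-sample counts."""
    loci = [r.id for r in reference]
    data = {
        t.sample_id: [int(locus in t.accepted) for locus in loci] for t in tables
    }
    matrix = pd.DataFrame(data, index=loci).T
    return matrix, matrix.sum(axis=1)


def write_flag_report(tables: list[TargetContigTable], path) -> None:
    """Tab-separated report of paralog-excluded loci and multi-locus contigs."""
    with open(path, "wt") as out:
        out.write("sample\tflag\tid\tdetails\n")
        for t in sorted(tables, key=lambda t: t.sample_id):
            for locus, contig_ids in t.excluded_paralog_loci:
                out.write(f"{t.sample_id}\tparalog_excluded\t{locus}\t{','.join(contig_ids)}\n")
            for contig, loci in t.multilocus_contigs:
                out.write(f"{t.sample_id}\tmultilocus_contig\t{contig}\t{','.join(loci)}\n")
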