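"""Per-locus multiple sequence alignment and consensus calling.

Alignment is progressive: all pairwise global alignments give a
(1 - identity) distance matrix, a UPGMA guide tree orders the merges, and
profiles are merged by profile-profile global alignment with
sum-of-pairs column scoring. Deterministic throughout: ties in tree
joining break by lexicographic id.
"""

from __future__ import annotations

import re
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np

from ._align import nw_affine_path, pairwise_global_identity
from .dna import IUPAC_TO_BASES, iupac_code
from .io import SeqRecord, read_fasta, write_fasta

PAIRWISE_SCORING = (1, -1, -3, -1)  # match, mismatch, gap open, gap extend


@dataclass
class LocusAlignment:
    locus_id: str
    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("alignment rows must have equal length")

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def column(self, j: int) -> list[str]:
        return [row[j] for row in self.rows]


@dataclass
class ConsensusConfig:
    mode: str = "majority"  # or "ambiguity"
    min_base_fraction: float = 0.5
    gap_rule: str = "skip"  # "skip" (omit gap-majority columns) or "absent"
    ambiguity_fraction: float = 0.25

    def __post_init__(self) -> None:
        if self.mode not in ("majority", "ambiguity"):
            raise ValueError(f"unknown consensus mode {self.mode!r}")
        if not 0.5 <= self.min_base_fraction <= 1:
            raise ValueError("min_base_fraction must be in [0.5, 1]")
        if self.gap_rule not in ("skip", "absent"):
            raise ValueError(f"unknown gap rule {self.gap_rule!r}")


# ---------------------------------------------------------------------------
# profiles

_CHANNELS = "ACGT"


def _profile(rows: list[str]) -> np.ndarray:
    """L x 4 base-frequency profile; IUPAC codes spread uniformly over the
    bases they cover, gaps contribute nothing."""
    L = len(rows[0])
    prof = np.zeros((L, 4))
    for row in rows:
        for j, ch in enumerate(row):
            if ch == "-":
                continue
            bases = IUPAC_TO_BASES.get(ch)
            if bases:
                w = 1.0 / len(bases)
                for b in bases:
                    prof[j, _CHANNELS.index(b)] += w
    totals = prof.sum(axis=1, keepdims=True)
    np.divide(prof, totals, out=prof, where=totals > 0)
    return prof


def _merge(rows_a: list[str], rows_b: list[str], scoring=PAIRWISE_SCORING) -> tuple[list[str], list[str]]:
    match, mismatch, go, ge = scoring
    pa, pb = _profile(rows_a), _profile(rows_b)
    K = np.full((4, 4), float(mismatch))
    np.fill_diagonal(K, float(match))
    S = pa @ K @ pb.T
    _, path = nw_affine_path(S, go, ge)
    new_a = ["".join(row[i] if i >= 0 else "-" for i, _ in path) for row in rows_a]
    new_b = ["".join(row[j] if j >= 0 else "-" for _, j in path) for row in rows_b]
    return new_a, new_b


def _upgma_order(ids: list[str], dist: np.ndarray) -> list[tuple[int, int]]:
    """UPGMA join order over cluster indices; new clusters get fresh
    indices n, n+1, ... Ties break by the lexicographically smallest
    member id of each cluster."""
    n = len(ids)
    active: dict[int, tuple[list[int], str]] = {
        i: ([i], ids[i]) for i in range(n)
    }
    d: dict[tuple[int, int], float] = {
        (i, j): float(dist[i, j]) for i in range(n) for j in range(i + 1, n)
    }
    joins: list[tuple[int, int]] = []
    nxt = n
    while len(active) > 1:
        best_key = min(
            d,
            key=lambda k: (d[k], min(active[k[0]][1], active[k[1]][1]),
                           max(active[k[0]][1], active[k[1]][1])),
        )
        a, b = best_key
        members = active[a][0] + active[b][0]
        label = min(active[a][1], active[b][1])
        joins.append((a, b))
        size_a, size_b = len(active[a][0]), len(active[b][0])
        del active[a], active[b]
        new_d = {}
        for c in active:
            da = d.get((min(a, c), max(a, c)))
            db = d.get((min(b, c), max(b, c)))
            new_d[(c, nxt)] = (da * size_a + db * size_b) / (size_a + size_b)
        d = {k: v for k, v in d.items() if a not in k and b not in k}
        d.update(new_d)
        active[nxt] = (members, label)
        nxt += 1
    return joins


def align_locus(seqs: list[SeqRecord], locus_id: str = "") -> LocusAlignment:
    """Progressive multiple alignment of >= 2 sequences."""
    if len(seqs) < 2:
        raise ValueError("align_locus requires at least 2 sequences")
    seqs = sorted(seqs, key=lambda s: s.id)
    n = len(seqs)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ident = pairwise_global_identity(seqs[i].sequence, seqs[j].sequence,
                                             PAIRWISE_SCORING)
            dist[i, j] = dist[j, i] = 1.0 - ident
    joins = _upgma_order([s.id for s in seqs], dist)

    clusters: dict[int, tuple[list[str], list[str]]] = {
        i: ([s.id], [s.sequence]) for i, s in enumerate(seqs)
    }
    nxt = n
    for a, b in joins:
        ids_a, rows_a = clusters.pop(a)
        ids_b, rows_b = clusters.pop(b)
        rows_a, rows_b = _merge(rows_a, rows_b)
        clusters[nxt] = (ids_a + ids_b, rows_a + rows_b)
        nxt += 1
    ids, rows = clusters.popitem()[1]
    order = sorted(range(len(ids)), key=lambda i: ids[i])
    return LocusAlignment(locus_id, [ids[i] for i in order], [rows[i] for i in order])


def sum_of_pairs_score(rows: list[str], scoring=PAIRWISE_SCORING) -> float:
    """Sum-of-pairs score of an alignment layout (gap-gap columns free;
    a gap paired with a base costs gap_open for the first base of a run,
    gap_extend after)."""
    match, mismatch, go, ge = scoring
    total = 0.0
    n = len(rows)
    for i in range(n):
        for j in range(i + 1, n):
            in_gap = False
            for a, b in zip(rows[i], rows[j]):
                if a == "-" and b == "-":
                    continue
                if a == "-" or b == "-":
                    total += ge if in_gap else go
                    in_gap = True
                else:
                    total += match if a == b else mismatch
                    in_gap = False
    return total


# ---------------------------------------------------------------------------
# grouping contig files into per-locus MSAs


def build_locus_msas(
    fasta_paths: Iterable, min_samples: int = 3
) -> dict[str, LocusAlignment]:
    """Group ``<sample>_<locus>`` records by locus and align every locus
    recovered for at least ``min_samples`` distinct samples."""
    by_locus: dict[str, list[tuple[str, SeqRecord]]] = defaultdict(list)
    for path in fasta_paths:
        for rec in read_fasta(path):
            sample, locus = split_seq_id(rec.id)
            by_locus[locus].append((sample, rec))
    out: dict[str, LocusAlignment] = {}
    for locus in sorted(by_locus):
        entries = by_locus[locus]
        samples = {sample for sample, _ in entries}
        if len(samples) < min_samples or len(entries) < 2:
            continue
        out[locus] = align_locus([rec for _, rec in entries], locus)
    return out


_ALLELE_RE = re.compile(r"^(?P<locus>.+)_allele\d+$")


def split_seq_id(seq_id: str) -> tuple[str, str]:
    """Split a ``<sample>_<locus>`` (or ``<sample>_<locus>_allele<N>``) id
    at the first underscore; an allele suffix stays out of the locus key
    so both alleles of a sample group into the same locus."""
    sample, _, locus = seq_id.partition("_")
    if not locus:
        raise ValueError(f"sequence id {seq_id!r} is not of the form <sample>_<locus>")
    m = _ALLELE_RE.match(locus)
    if m:
        locus = m.group("locus")
    return sample, locus


def write_msas(msas: dict[str, LocusAlignment], out_dir) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for locus in sorted(msas):
        aln = msas[locus]
        write_fasta(
            [SeqRecord(i, r) for i, r in zip(aln.ids, aln.rows)],
            out_dir / f"{locus}.fasta",
        )


def read_msa(path, locus_id: str) -> LocusAlignment:
    records = list(read_fasta(path))
    return LocusAlignment(locus_id, [r.id for r in records], [r.sequence for r in records])


# ---------------------------------------------------------------------------
# consensus


def consensus(aln: LocusAlignment, cfg: ConsensusConfig | None = None) -> SeqRecord:
    """Column-wise consensus of an alignment.

    Majority mode emits the most frequent base when its non-gap fraction
    reaches ``min_base_fraction``, else 'N'. Ambiguity mode emits the
    minimal IUPAC code covering all bases at fraction >=
    ``ambiguity_fraction``. Columns where gaps hold a strict majority are
    omitted under the ``skip`` gap rule. Base ties break alphabetically.
    """
    cfg = cfg or ConsensusConfig()
    if not aln.rows:
        raise ValueError("cannot take consensus of an empty alignment")
    out: list[str] = []
    for j in range(aln.length):
        col = aln.column(j)
        gaps = col.count("-")
        if cfg.gap_rule == "skip" and gaps > len(col) - gaps:
            continue
        counts: dict[str, float] = {b: 0.0 for b in "ACGT"}
        for ch in col:
            if ch == "-":
                continue
            bases = IUPAC_TO_BASES.get(ch)
            if bases:
                for b in bases:
                    counts[b] += 1.0 / len(bases)
        total = sum(counts.values())
        if total == 0:
            out.append("N")
            continue
        if cfg.mode == "majority":
            best = max("ACGT", key=lambda b: counts[b])  # ties: alphabetical
            out.append(best if counts[best] / total >= cfg.min_base_fraction else "N")
        else:
            chosen = {b for b in "ACGT" if counts[b] / total >= cfg.ambiguity_fraction}
            if not chosen:
                chosen = {max("ACGT", key=lambda b: counts[b])}
            out.append(iupac_code(chosen))
    return SeqRecord(aln.locus_id or "consensus", "".join(out))
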