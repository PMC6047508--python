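"""Reference-based assembly: build a reference library (three modes), map
cleaned reads to it, mark PCR duplicates, compute per-locus pileups and
variant sites, call a consensus per locus, and select best-covered loci.

The mapper is seed-and-extend: exact 19-mer seeds vote for (locus,
strand, diagonal) placements and the best candidate window is verified by
banded edit-distance alignment. A read maps if its edit distance is at
most ``max_edit_rate`` x read length; ambiguous best placements (score
ties across loci or positions) leave the read unmapped, which avoids
chimeric consensus sequences built from non-orthologous reads.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import edlib
import numpy as np
import pandas as pd

from .dna import IUPAC_TO_BASES, iupac_code, revcomp
from .io import MappedRead, Read, SeqRecord, iter_cigar, read_fasta
from .msa import ConsensusConfig, LocusAlignment, consensus as msa_consensus

SEED_LEN = 19

# reference IUPAC codes match any base they cover, at zero cost
_EQUALITIES = [
    (code, base)
    for code, bases in IUPAC_TO_BASES.items()
    if code not in "ACGT"
    for base in bases
]

PILEUP_CHANNELS = "ACGTN"  # + del as channel 5


@dataclass
class ReferenceLibrary:
    mode: str  # alignment-consensus | sample-specific | user-ref-lib
    loci: dict[str, SeqRecord]  # locus id -> sequence

    def __post_init__(self) -> None:
        if self.mode not in ("alignment-consensus", "sample-specific", "user-ref-lib"):
            raise ValueError(f"unknown reference mode {self.mode!r}")

    def lengths(self) -> dict[str, int]:
        return {locus: len(rec) for locus, rec in self.loci.items()}


def build_reference(
    mode: str,
    msas: dict[str, LocusAlignment] | None = None,
    fasta_path=None,
    samples: Sequence[str] | None = None,
) -> dict[str, ReferenceLibrary]:
    """Build the reference library for reference-based assembly.

    Returns one library keyed by '' for dataset-wide modes, or one per
    sample in sample-specific mode (each holding that sample's own
    ungapped contig per locus).
    """
    if mode == "user-ref-lib":
        loci = {rec.id: rec for rec in read_fasta(fasta_path)}
        return {"": ReferenceLibrary(mode, loci)}
    if not msas:
        raise ValueError("reference construction from MSAs requires a non-empty MSA set")
    if mode == "alignment-consensus":
        cfg = ConsensusConfig(mode="ambiguity")
        loci = {}
        for locus in sorted(msas):
            rec = msa_consensus(msas[locus], cfg)
            loci[locus] = SeqRecord(locus, rec.sequence)
        return {"": ReferenceLibrary(mode, loci)}
    if mode == "sample-specific":
        if samples is None:
            raise ValueError("sample-specific mode requires the sample list")
        libs: dict[str, ReferenceLibrary] = {}
        for sample in samples:
            loci = {}
            for locus in sorted(msas):
                aln = msas[locus]
                for seq_id, row in zip(aln.ids, aln.rows):
                    if seq_id.partition("_")[0] == sample:
                        loci[locus] = SeqRecord(locus, row.replace("-", ""))
                        break
            libs[sample] = ReferenceLibrary(mode, loci)
        return libs
    raise ValueError(f"unknown reference mode {mode!r}")


# ---------------------------------------------------------------------------
# mapping


class _SeedIndex:
    def __init__(self, library: ReferenceLibrary):
        self.index: dict[str, list[tuple[str, int]]] = defaultdict(list)
        self.library = library
        for locus in sorted(library.loci):
            seq = library.loci[locus].sequence
            for i in range(len(seq) - SEED_LEN + 1):
                kmer = seq[i : i + SEED_LEN]
                if all(b in "ACGT" for b in kmer):
                    self.index[kmer].append((locus, i))


@dataclass
class _Placement:
    locus_id: str
    strand: str
    start: int
    cigar: str
    edit_distance: int
    clip_left: int
    clip_right: int


def _normalize_cigar(ed_cigar: str, clip_left: int, clip_right: int) -> str:
    """Collapse edlib's =/X ops into M and add soft clips."""
    ops: list[tuple[int, str]] = []
    for n, op in iter_cigar(ed_cigar):
        op = "M" if op in "=X" else op
        if ops and ops[-1][1] == op:
            ops[-1] = (ops[-1][0] + n, op)
        else:
            ops.append((n, op))
    if clip_left:
        ops.insert(0, (clip_left, "S"))
    if clip_right:
        ops.append((clip_right, "S"))
    return "".join(f"{n}{op}" for n, op in ops)


def _extend(
    oriented: str, locus_seq: str, diag: int, max_edits: int
) -> _Placement | None:
    """Banded verification of a candidate diagonal placement."""
    L = len(locus_seq)
    n = len(oriented)
    clip_left = max(0, -diag)
    clip_right = max(0, diag + n - L)
    core = oriented[clip_left : n - clip_right]
    if len(core) < max(SEED_LEN, n // 2):
        return None
    pad = max_edits + 2
    wlo = max(0, diag + clip_left - pad)
    whi = min(L, diag + n - clip_right + pad)
    result = edlib.align(
        core,
        locus_seq[wlo:whi],
        mode="HW",
        task="path",
        k=max_edits,
        additionalEqualities=_EQUALITIES,
    )
    if result["editDistance"] < 0:
        return None
    start = wlo + result["locations"][0][0]
    cigar = _normalize_cigar(result["cigar"], clip_left, clip_right)
    return _Placement("", "", start, cigar, result["editDistance"], clip_left, clip_right)


def map_read(
    read: Read,
    index: _SeedIndex,
    max_edit_rate: float = 0.10,
) -> MappedRead | None:
    """Map one read against the indexed library; None if unmapped or
    ambiguous (two equally good placements)."""
    library = index.library
    max_edits = int(max_edit_rate * len(read))
    votes: Counter[tuple[str, str, int]] = Counter()
    for strand, seq in (("+", read.sequence), ("-", revcomp(read.sequence))):
        for i in range(0, len(seq) - SEED_LEN + 1):
            for locus, pos in index.index.get(seq[i : i + SEED_LEN], ()):
                votes[(locus, strand, pos - i)] += 1
    if not votes:
        return None
    # rank candidate placements by seed support; verify the strongest few
    ranked = sorted(votes.items(), key=lambda kv: (-kv[1], kv[0]))
    placements: list[_Placement] = []
    seen: set[tuple[str, str, int]] = set()
    for (locus, strand, diag), _count in ranked[:8]:
        key = (locus, strand, diag)
        if key in seen:
            continue
        seen.add(key)
        oriented = read.sequence if strand == "+" else revcomp(read.sequence)
        placement = _extend(oriented, library.loci[locus].sequence, diag, max_edits)
        if placement is not None:
            placement.locus_id = locus
            placement.strand = strand
            placements.append(placement)
    if not placements:
        return None
    placements.sort(key=lambda p: (p.edit_distance, p.locus_id, p.start, p.strand))
    best = placements[0]
    tied = {
        (p.locus_id, p.strand, p.start): p
        for p in placements
        if p.edit_distance == best.edit_distance
    }
    if len(tied) > 1:
        # Ties across duplicate reference entries (one multi-locus contig
        # feeding several per-exon entries gives identical sequences)
        # carry no distinguishing information: keep the deterministic
        # first. Any other tie is a genuine ambiguity and stays unmapped.
        def entry(p: _Placement) -> tuple[str, int, str]:
            return (p.strand, p.start, library.loci[p.locus_id].sequence)

        if len({entry(p) for p in tied.values()}) > 1:
            return None  # ambiguous placement: drop rather than guess
    return MappedRead(
        read_id=read.id,
        locus_id=best.locus_id,
        start=best.start,
        strand=best.strand,
        cigar=best.cigar,
        edit_distance=best.edit_distance,
        sequence=read.sequence,
        qualities=read.qualities,
        mate=read.mate,
        fragment_id=_fragment_id(read.id),
    )


def _fragment_id(read_id: str) -> str:
    for suffix in ("/1", "/2"):
        if read_id.endswith(suffix):
            return read_id[: -len(suffix)]
    return read_id


def map_reads(
    reads: Iterable[Read],
    library: ReferenceLibrary,
    max_edit_rate: float = 0.10,
) -> list[MappedRead]:
    index = _SeedIndex(library)
    out = []
    for read in reads:
        rec = map_read(read, index, max_edit_rate)
        if rec is not None:
            out.append(rec)
    return out


# ---------------------------------------------------------------------------
# duplicate marking


def mark_duplicates(records: list[MappedRead]) -> list[MappedRead]:
    """Flag PCR/optical duplicates.

    Fragments sharing (locus, strand, leftmost position) — and, for pairs
    with both mates mapped to the same locus, the mate's leftmost position
    — form a duplicate group; the member with the highest summed base
    quality is kept.
    """
    by_fragment: dict[str, list[MappedRead]] = defaultdict(list)
    for rec in records:
        by_fragment[rec.fragment_id].append(rec)

    groups: dict[tuple, list[list[MappedRead]]] = defaultdict(list)
    for fragment_id in sorted(by_fragment):
        recs = sorted(by_fragment[fragment_id], key=lambda r: (r.start, r.mate))
        if len(recs) == 2 and recs[0].locus_id == recs[1].locus_id:
            key = (
                "pair",
                recs[0].locus_id,
                recs[0].start,
                recs[0].strand,
                recs[1].start,
                recs[1].strand,
            )
            groups[key].append(recs)
        else:
            for rec in recs:
                groups[("single", rec.locus_id, rec.strand, rec.start)].append([rec])

    for members in groups.values():
        if len(members) < 2:
            continue
        scored = sorted(
            members,
            key=lambda recs: (-sum(sum(r.qualities) for r in recs),
                              recs[0].fragment_id),
        )
        for recs in scored[1:]:
            for rec in recs:
                rec.is_duplicate = True
    return records


# ---------------------------------------------------------------------------
# pileup / variants / consensus


@dataclass
class LocusPileup:
    locus_id: str
    counts: np.ndarray  # L x 6 (A, C, G, T, N, del)
    reads: list[MappedRead]  # non-duplicate reads covering the locus

    @property
    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=1)


@dataclass
class VariantSite:
    locus_id: str
    position: int  # 0-based
    ref_base: str
    alleles: list[tuple[str, int]]  # (base, depth), depth-descending
    is_heterozygous: bool


def pileup_and_variants(
    records: list[MappedRead],
    library: ReferenceLibrary,
    min_allele_depth: int = 3,
    min_allele_fraction: float = 0.2,
    min_base_quality: int = 20,
) -> tuple[dict[str, LocusPileup], list[VariantSite]]:
    """Tally base counts per reference position and call variant sites.

    Only bases with quality >= ``min_base_quality`` are tallied; deleted
    positions count in the 'del' channel. A site is a variant when >= 2
    base alleles each reach ``min_allele_depth`` and
    ``min_allele_fraction`` of the site's base depth; exactly two passing
    alleles flag the site heterozygous.
    """
    pileups: dict[str, LocusPileup] = {}
    for locus in sorted(library.loci):
        pileups[locus] = LocusPileup(
            locus, np.zeros((len(library.loci[locus]), 6), dtype=np.int64), []
        )
    for rec in records:
        if rec.is_duplicate:
            continue
        pile = pileups[rec.locus_id]
        pile.reads.append(rec)
        seq = rec.oriented_sequence()
        quals = rec.oriented_qualities()
        rpos = rec.start
        qpos = 0
        for n, op in iter_cigar(rec.cigar):
            if op == "M":
                for i in range(n):
                    if quals[qpos + i] >= min_base_quality:
                        base = seq[qpos + i]
                        ch = PILEUP_CHANNELS.find(base)
                        pile.counts[rpos + i, ch if ch >= 0 else 4] += 1
                rpos += n
                qpos += n
            elif op == "D":
                pile.counts[rpos : rpos + n, 5] += 1
                rpos += n
            elif op in "IS":
                qpos += n

    sites: list[VariantSite] = []
    for locus in sorted(pileups):
        pile = pileups[locus]
        ref_seq = library.loci[locus].sequence
        base_counts = pile.counts[:, :4]
        base_depth = base_counts.sum(axis=1)
        for pos in np.nonzero(base_depth > 0)[0]:
            depths = {b: int(base_counts[pos, i]) for i, b in enumerate("ACGT")}
            total = int(base_depth[pos])
            passing = [
                (b, d)
                for b, d in depths.items()
                if d >= min_allele_depth and d / total >= min_allele_fraction
            ]
            if len(passing) < 2:
                continue
            passing.sort(key=lambda bd: (-bd[1], bd[0]))
            sites.append(
                VariantSite(
                    locus_id=locus,
                    position=int(pos),
                    ref_base=ref_seq[pos],
                    alleles=passing,
                    is_heterozygous=len(passing) == 2,
                )
            )
    return pileups, sites


def assembly_consensus(
    pileup: LocusPileup,
    sites: list[VariantSite],
    min_depth: int = 3,
) -> SeqRecord | None:
    """Per-locus consensus from the pileup.

    Positions below ``min_depth`` become 'N'; heterozygous sites get the
    IUPAC code of their two alleles; positions where deletions hold the
    majority are omitted. Leading/trailing N runs are trimmed. Returns
    None when nothing above the depth floor remains.
    """
    het_at = {s.position: s for s in sites if s.locus_id == pileup.locus_id and s.is_heterozygous}
    out: list[str] = []
    counts = pileup.counts
    for pos in range(counts.shape[0]):
        base_depth = int(counts[pos, :4].sum())
        dels = int(counts[pos, 5])
        if dels > base_depth:
            continue
        if base_depth < min_depth:
            out.append("N")
            continue
        site = het_at.get(pos)
        if site is not None:
            out.append(iupac_code({b for b, _ in site.alleles[:2]}))
        else:
            col = counts[pos, :4]
            out.append("ACGT"[int(np.argmax(col))])  # argmax ties: alphabetical
        # N channel contributes to neither depth nor the called base
    seq = "".join(out).strip("N")
    if not seq:
        return None
    return SeqRecord(pileup.locus_id, seq)


# ---------------------------------------------------------------------------
# coverage and locus selection


def coverage_summary(
    pileups_by_sample: dict[str, dict[str, LocusPileup]],
) -> tuple[pd.DataFrame, pd.Series]:
    """(sample x locus mean-depth table, per-sample mapped-read counts).

    Mean depth averages over every reference position (zero-depth
    positions included); read counts exclude duplicates.
    """
    loci = sorted({locus for piles in pileups_by_sample.values() for locus in piles})
    depth = pd.DataFrame(0.0, index=sorted(pileups_by_sample), columns=loci)
    mapped = pd.Series(0, index=sorted(pileups_by_sample), dtype=int)
    for sample, piles in pileups_by_sample.items():
        for locus, pile in piles.items():
            depth.loc[sample, locus] = float(pile.depth.mean()) if len(pile.depth) else 0.0
        mapped[sample] = sum(len(p.reads) for p in piles.values())
    return depth, mapped


def locus_selection(
    coverage: pd.DataFrame, n: int, min_mean_depth: float = 0.0
) -> list[str]:
    """Top-n loci by cross-sample mean depth (missing samples count 0);
    ties break by lexicographic locus id; loci below ``min_mean_depth``
    never qualify."""
    if n <= 0:
        raise ValueError("n must be positive")
    means = coverage.mean(axis=0)
    eligible = means[means >= min_mean_depth]
    ranked = sorted(eligible.items(), key=lambda kv: (-kv[1], kv[0]))
    return [locus for locus, _ in ranked[:n]]
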