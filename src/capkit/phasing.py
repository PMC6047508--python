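"""Read-backed diploid phasing of heterozygous sites per locus.

Read pairs connect heterozygous sites: two sites co-covered by one
fragment carry evidence about whether their alleles sit on the same
haplotype. Per connected component of that graph, phases are assigned
greedily (breadth-first from the highest-depth site) and then refined by
single-site flips until the minimum-error-correction (MEC) count stops
improving. Reads are assigned to the haplotype they conflict with least;
ties stay unassigned. Sites where more than two alleles pass the variant
thresholds raise an excess-haplotype flag — such loci are still phased as
the best two-haplotype fit but should be viewed critically (possible
paralogy or polyploidy).
"""

from __future__ import annotations

from collections import defaultdict, deque
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .dna import iupac_code
from .io import MappedRead, SeqRecord, write_fasta, write_sam
from .refassembly import LocusPileup, VariantSite


@dataclass
class PhasedLocus:
    locus_id: str
    sample_id: str
    h0: SeqRecord
    h1: SeqRecord
    phase_blocks: list[tuple[int, int]]  # (first, last) het-site position per block
    unassigned_read_count: int
    excess_haplotype_flag: bool
    mec: int = 0
    h0_reads: list[MappedRead] = field(default_factory=list)
    h1_reads: list[MappedRead] = field(default_factory=list)
    unassigned_reads: list[MappedRead] = field(default_factory=list)


def fragment_alleles(
    reads: list[MappedRead], sites: list[VariantSite]
) -> dict[str, dict[int, int]]:
    """Allele observations per fragment: fragment id -> {site position ->
    allele index (0 = alphabetically smaller of the two passing alleles)}.

    Bases other than the site's two alleles are ignored. Mates of a pair
    share a fragment id, so pairs link sites jointly.
    """
    site_alleles = {
        s.position: tuple(sorted(b for b, _ in s.alleles[:2])) for s in sites
    }
    out: dict[str, dict[int, int]] = defaultdict(dict)
    for read in reads:
        seq = read.oriented_sequence()
        for rpos, qpos in read.aligned_pairs():
            alleles = site_alleles.get(rpos)
            if alleles is None:
                continue
            base = seq[qpos]
            if base == alleles[0]:
                out[read.fragment_id][rpos] = 0
            elif base == alleles[1]:
                out[read.fragment_id][rpos] = 1
    return dict(out)


def _mec(fragments: dict[str, dict[int, int]], phase: dict[int, int]) -> int:
    """MEC of a phase assignment: each fragment goes to its better
    haplotype; conflicts with that haplotype are counted."""
    total = 0
    for obs in fragments.values():
        c0 = sum(1 for pos, a in obs.items() if a != phase[pos])
        c1 = len(obs) - c0
        total += min(c0, c1)
    return total


def _connected_components(positions: list[int], fragments) -> list[list[int]]:
    adj: dict[int, set[int]] = {p: set() for p in positions}
    for obs in fragments.values():
        covered = sorted(obs)
        for a, b in zip(covered, covered[1:]):
            adj[a].add(b)
            adj[b].add(a)
    seen: set[int] = set()
    components: list[list[int]] = []
    for p in sorted(positions):
        if p in seen:
            continue
        comp = []
        queue = deque([p])
        seen.add(p)
        while queue:
            q = queue.popleft()
            comp.append(q)
            for r in sorted(adj[q]):
                if r not in seen:
                    seen.add(r)
                    queue.append(r)
        components.append(sorted(comp))
    return components


def phase_sites(
    sites: list[VariantSite], fragments: dict[str, dict[int, int]]
) -> tuple[dict[int, int], list[tuple[int, int]], int]:
    """Assign a phase (0/1) to every heterozygous site.

    Returns (phase by position, phase blocks, final MEC). phase[p] is the
    allele index haplotype 0 carries at p. Each block is canonicalized so
    haplotype 0 carries the alphabetically smaller allele (index 0) at
    the block's first site.
    """
    positions = [s.position for s in sites]
    if not positions:
        return {}, [], 0
    depth = {s.position: sum(d for _, d in s.alleles) for s in sites}

    # pairwise co-observation counts
    eq: dict[tuple[int, int], int] = defaultdict(int)
    ne: dict[tuple[int, int], int] = defaultdict(int)
    for obs in fragments.values():
        covered = sorted(obs)
        for i, a in enumerate(covered):
            for b in covered[i + 1 :]:
                if obs[a] == obs[b]:
                    eq[(a, b)] += 1
                else:
                    ne[(a, b)] += 1

    def counts(a: int, b: int) -> tuple[int, int]:
        key = (min(a, b), max(a, b))
        return eq.get(key, 0), ne.get(key, 0)

    components = _connected_components(positions, fragments)
    phase: dict[int, int] = {}
    blocks: list[tuple[int, int]] = []
    for comp in components:
        start = max(comp, key=lambda p: (depth[p], -p))
        phase[start] = 0
        assigned = {start}
        queue = deque([start])
        comp_set = set(comp)
        while queue:
            cur = queue.popleft()
            for nxt in sorted(comp_set - assigned):
                n_eq, n_ne = counts(cur, nxt)
                if n_eq == 0 and n_ne == 0:
                    continue
                same = sum(
                    (counts(t, nxt)[0] if phase[t] == 0 else counts(t, nxt)[1])
                    for t in assigned
                )
                diff = sum(
                    (counts(t, nxt)[1] if phase[t] == 0 else counts(t, nxt)[0])
                    for t in assigned
                )
                # "same" votes support nxt sharing phase orientation 0
                phase[nxt] = 0 if same >= diff else 1
                assigned.add(nxt)
                queue.append(nxt)
        # any stragglers (connected only through ignored evidence)
        for p in comp:
            phase.setdefault(p, 0)
        blocks.append((comp[0], comp[-1]))

    # single-flip refinement to a MEC fixed point
    best = _mec(fragments, phase)
    improved = True
    while improved:
        improved = False
        for p in sorted(phase):
            phase[p] ^= 1
            m = _mec(fragments, phase)
            if m < best:
                best = m
                improved = True
            else:
                phase[p] ^= 1

    # canonicalize each block: allele 0 on haplotype 0 at the first site
    for comp in components:
        first = comp[0]
        if phase[first] == 1:
            for p in comp:
                phase[p] ^= 1
    return phase, sorted(blocks), _mec(fragments, phase)


def phase_locus(
    pileup: LocusPileup,
    sites: list[VariantSite],
    sample_id: str,
    min_depth: int = 3,
) -> PhasedLocus:
    """Phase one locus and build the two per-allele consensus sequences.

    ``sites`` are this locus's variant sites (all passing alleles); only
    heterozygous ones are phased. With no heterozygous sites both
    haplotype sequences equal the unphased consensus.
    """
    locus_sites = [s for s in sites if s.locus_id == pileup.locus_id]
    het_sites = [s for s in locus_sites if s.is_heterozygous]
    excess = any(len(s.alleles) > 2 for s in locus_sites)
    reads = [r for r in pileup.reads if not r.is_duplicate]
    fragments = fragment_alleles(reads, het_sites)
    phase, blocks, mec = phase_sites(het_sites, fragments)
    allele_at = {
        s.position: tuple(sorted(b for b, _ in s.alleles[:2])) for s in het_sites
    }

    # read assignment
    by_fragment: dict[str, list[MappedRead]] = defaultdict(list)
    for r in reads:
        by_fragment[r.fragment_id].append(r)
    h0_reads: list[MappedRead] = []
    h1_reads: list[MappedRead] = []
    unassigned: list[MappedRead] = []
    for frag_id in sorted(by_fragment):
        obs = fragments.get(frag_id, {})
        c0 = sum(1 for pos, a in obs.items() if a != phase[pos])
        c1 = len(obs) - c0
        bucket = h0_reads if c0 < c1 else h1_reads if c1 < c0 else unassigned
        bucket.extend(by_fragment[frag_id])

    # haplotype consensus: unphased consensus everywhere except phased hets
    counts = pileup.counts
    het_pos = {s.position for s in het_sites}
    h0_chars: list[str] = []
    h1_chars: list[str] = []
    for pos in range(counts.shape[0]):
        base_depth = int(counts[pos, :4].sum())
        dels = int(counts[pos, 5])
        if dels > base_depth:
            continue
        if base_depth < min_depth:
            h0_chars.append("N")
            h1_chars.append("N")
            continue
        if pos in het_pos:
            a0, a1 = allele_at[pos]
            if phase[pos] == 0:
                h0_chars.append(a0)
                h1_chars.append(a1)
            else:
                h0_chars.append(a1)
                h1_chars.append(a0)
        else:
            col = counts[pos, :4]
            h0_chars.append("ACGT"[int(np.argmax(col))])
            h1_chars.append(h0_chars[-1])

    h0_seq = "".join(h0_chars)
    h1_seq = "".join(h1_chars)
    lead = len(h0_seq) - len(h0_seq.lstrip("N"))
    trail = len(h0_seq) - len(h0_seq.rstrip("N"))
    end = len(h0_seq) - trail
    h0_seq, h1_seq = h0_seq[lead:end], h1_seq[lead:end]

    return PhasedLocus(
        locus_id=pileup.locus_id,
        sample_id=sample_id,
        h0=SeqRecord(f"{sample_id}_{pileup.locus_id}_allele0", h0_seq or "N"),
        h1=SeqRecord(f"{sample_id}_{pileup.locus_id}_allele1", h1_seq or "N"),
        phase_blocks=blocks,
        unassigned_read_count=len(unassigned),
        excess_haplotype_flag=excess,
        mec=mec,
        h0_reads=h0_reads,
        h1_reads=h1_reads,
        unassigned_reads=unassigned,
    )


def phase_sample(
    pileups: dict[str, LocusPileup],
    sites: list[VariantSite],
    sample_id: str,
    out_dir,
    locus_lengths: dict[str, int],
    min_depth: int = 3,
) -> list[PhasedLocus]:
    """Phase every locus of one sample; write per-allele SAM files, a
    cumulative allele FASTA and a per-locus phasing report."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    phased: list[PhasedLocus] = []
    for locus in sorted(pileups):
        if not pileups[locus].reads:
            continue
        phased.append(phase_locus(pileups[locus], sites, sample_id, min_depth))

    for hap in (0, 1):
        records = []
        for p in phased:
            assigned = p.h0_reads if hap == 0 else p.h1_reads
            records.extend(assigned)
            records.extend(p.unassigned_reads)  # written to both, flagged by tie
        write_sam(records, locus_lengths, out_dir / f"{sample_id}_allele{hap}.sam")

    write_fasta(
        [rec for p in phased for rec in (p.h0, p.h1)],
        out_dir / f"{sample_id}_alleles.fasta",
    )
    with open(out_dir / f"{sample_id}_phasing_report.tsv", "wt") as out:
        out.write("locus\tn_blocks\tmec\tunassigned_reads\texcess_haplotypes\n")
        for p in phased:
            out.write(
                f"{p.locus_id}\t{len(p.phase_blocks)}\t{p.mec}\t"
                f"{p.unassigned_read_count}\t{int(p.excess_haplotype_flag)}\n"
            )
    return phased
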