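"""De novo contig assembly from cleaned reads via a de Bruijn graph.

The assembler counts canonical k-mers (a k-mer and its reverse complement
are collapsed to the lexicographic minimum), drops low-count k-mers,
removes short dead-end tips, pops simple substitution bubbles by keeping
the higher-coverage branch, and emits maximal non-branching paths as
contigs. Paired-end information is not used (no scaffolding): downstream
stages need contig-level sequence only.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Iterator

from .dna import canonical, revcomp
from .io import Read

_BASES = "ACGT"


@dataclass
class AssemblyConfig:
    k: int = 31
    min_kmer_count: int = 2
    min_contig_length: int = 100
    # tips shorter than tip_length_factor * k are trimmed; 4*k exceeds one
    # read length at k=31, which is the longest artifact a PCR-duplicated
    # erroneous read (whose k-mers pass min_kmer_count twice over) can leave
    tip_length_factor: int = 4

    def __post_init__(self) -> None:
        if not (15 <= self.k <= 127) or self.k % 2 == 0:
            raise ValueError("k must be odd and in [15, 127]")


@dataclass
class Contig:
    id: str
    sequence: str
    mean_kmer_coverage: float
    sample_id: str

    def __len__(self) -> int:
        return len(self.sequence)


class _Graph:
    """De Bruijn graph over the surviving canonical k-mer set.

    Nodes are oriented k-mers; membership and coverage are looked up via
    the canonical form, so the graph is reverse-complement symmetric.
    """

    def __init__(self, counts: dict[str, int], k: int):
        self.counts = counts
        self.k = k

    def has(self, kmer: str) -> bool:
        return canonical(kmer) in self.counts

    def coverage(self, kmer: str) -> int:
        return self.counts[canonical(kmer)]

    def successors(self, kmer: str) -> list[str]:
        suffix = kmer[1:]
        return [suffix + b for b in _BASES if self.has(suffix + b)]

    def predecessors(self, kmer: str) -> list[str]:
        prefix = kmer[:-1]
        return [b + prefix for b in _BASES if self.has(b + prefix)]

    def remove(self, kmers: Iterable[str]) -> None:
        for kmer in kmers:
            self.counts.pop(canonical(kmer), None)

    def unitigs(self) -> list[tuple[str, list[str]]]:
        """Maximal non-branching paths, deduplicated across orientations.

        Returns (sequence, oriented k-mer list) pairs; each unitig is
        reported once, in its canonical orientation.
        """
        visited: set[str] = set()
        out: list[tuple[str, list[str]]] = []

        def walk_back(kmer: str) -> str:
            node = kmer
            seen = {canonical(kmer)}
            while True:
                preds = self.predecessors(node)
                if len(preds) != 1:
                    return node
                pred = preds[0]
                if len(self.successors(pred)) != 1 or canonical(pred) in seen:
                    return node
                node = pred
                seen.add(canonical(node))

        for canon in sorted(self.counts):
            if canon in visited:
                continue
            start = walk_back(canon)
            path = [start]
            visited.add(canonical(start))
            node = start
            while True:
                succs = self.successors(node)
                if len(succs) != 1:
                    break
                nxt = succs[0]
                if len(self.predecessors(nxt)) != 1 or canonical(nxt) in visited:
                    break
                path.append(nxt)
                visited.add(canonical(nxt))
                node = nxt
            seq = path[0] + "".join(p[-1] for p in path[1:])
            out.append((seq, path))
        return out


def _count_kmers(reads: Iterable[Read], k: int) -> Counter[str]:
    counts: Counter[str] = Counter()
    for read in reads:
        seq = read.sequence
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if "N" in kmer:
                continue
            counts[canonical(kmer)] += 1
    return counts


def _remove_tips(graph: _Graph, max_tip_len: int) -> bool:
    """Remove short dead-end unitigs that compete with another path.

    A tip is only removed when every junction node it feeds into (or out
    of) has an alternative edge on the tip's side, so deleting the tip
    cannot disconnect real sequence: a fragment that is the sole support
    of its junction (e.g. one flanking a coverage hole) is kept.
    """
    removed = False
    for seq, path in graph.unitigs():
        if len(seq) >= max_tip_len:
            continue
        start, end = path[0], path[-1]
        dead_start = len(graph.predecessors(start)) == 0
        dead_end = len(graph.successors(end)) == 0
        if dead_start == dead_end:
            continue  # isolated island or internal path, not a tip
        if dead_start:
            junctions = graph.successors(end)
            expendable = all(len(graph.predecessors(j)) >= 2 for j in junctions)
        else:
            junctions = graph.predecessors(start)
            expendable = all(len(graph.successors(j)) >= 2 for j in junctions)
        if expendable:
            graph.remove(path)
            removed = True
    return removed


def _pop_bubbles(graph: _Graph, max_mismatches: int) -> bool:
    """Pop substitution bubbles by branch walking.

    From every node with two (or more) successors, each branch is walked
    along its unique-successor chain until the walks reconverge on a
    shared node. Walking ignores incoming side paths (in-degree > 1), so
    a sequencing-error stub merging into one haplotype branch cannot hide
    the bubble. Equal-length branch pairs differing by a few
    substitutions collapse onto the higher-coverage branch; the orphaned
    side paths become tips for the next cleanup round.
    """
    k = graph.k
    limit = 3 * k

    def walk(start: str) -> list[str]:
        nodes = [start]
        cur = start
        while len(nodes) < limit:
            nxt = graph.successors(cur)
            if len(nxt) != 1 or nxt[0] == start:
                break
            cur = nxt[0]
            nodes.append(cur)
        return nodes

    def spell(prefix: str, path: list[str]) -> str:
        return prefix + "".join(p[-1] for p in path)

    removed = False
    for canon in sorted(graph.counts):
        if canon not in graph.counts:
            continue  # removed earlier this round
        for node in (canon, revcomp(canon)):
            succs = graph.successors(node)
            if len(succs) < 2:
                continue
            paths = {s: walk(s) for s in succs}
            for ia in range(len(succs)):
                for ib in range(ia + 1, len(succs)):
                    a, b = succs[ia], succs[ib]
                    if not graph.has(a) or not graph.has(b):
                        continue  # already removed this round
                    pos_in_a = {n: i for i, n in enumerate(paths[a])}
                    merge = next(
                        ((pos_in_a[n], j) for j, n in enumerate(paths[b])
                         if n in pos_in_a),
                        None,
                    )
                    if merge is None:
                        continue
                    i, j = merge
                    if i != j:
                        continue  # indel bubble: left to the caller's model
                    branch_a = paths[a][:i]
                    branch_b = paths[b][:j]
                    if not branch_a:
                        continue
                    seq_a = spell(node, branch_a)
                    seq_b = spell(node, branch_b)
                    mismatches = sum(x != y for x, y in zip(seq_a, seq_b))
                    if mismatches > max_mismatches:
                        continue
                    cov_a = _mean_cov(graph, branch_a)
                    cov_b = _mean_cov(graph, branch_b)
                    drop = branch_b if (cov_a, seq_b) > (cov_b, seq_a) else branch_a
                    graph.remove(drop)
                    removed = True
    return removed


def _mean_cov(graph: _Graph, path: list[str]) -> float:
    return sum(graph.coverage(p) for p in path) / len(path)


def assemble_sample(reads: Iterable[Read], cfg: AssemblyConfig, sample_id: str) -> list[Contig]:
    """Assemble one sample's cleaned reads into contigs.

    Deterministic: identical reads and config give byte-identical output.
    Contig orientation is normalized to the lexicographically smaller of
    sequence / reverse complement; output is sorted by descending length,
    ties by sequence.
    """
    k = cfg.k
    counts = _count_kmers(reads, k)
    counts = {km: c for km, c in counts.items() if c >= cfg.min_kmer_count}
    graph = _Graph(counts, k)
    if not counts:
        return []

    max_tip_len = cfg.tip_length_factor * k
    max_bubble_mm = -(-k // 10)  # ceil(k/10)
    for _ in range(6):
        changed = _remove_tips(graph, max_tip_len)
        changed |= _pop_bubbles(graph, max_bubble_mm)
        if not changed:
            break

    contigs = []
    for seq, path in graph.unitigs():
        if len(seq) < cfg.min_contig_length:
            continue
        contigs.append((canonical(seq), _mean_cov(graph, path)))
    contigs.sort(key=lambda c: (-len(c[0]), c[0]))
    return [
        Contig(f"{sample_id}_contig{i + 1}", seq, cov, sample_id)
        for i, (seq, cov) in enumerate(contigs)
    ]


def count_contigs(contigs: list[Contig]) -> int:
    return len(contigs)
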