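"""Read-backed phasing: MEC optimality against exhaustive search, block
structure and haplotype consensus."""

from itertools import product

import numpy as np
import pytest

from capkit.io import MappedRead, SeqRecord
from capkit.refassembly import (
    ReferenceLibrary,
    pileup_and_variants,
)
from capkit.phasing import fragment_alleles, phase_locus, phase_sample, phase_sites


def _random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def _alt(b):
    return {"A": "C", "C": "G", "G": "T", "T": "A"}[b]


def _diploid_locus(rng, length=200, het_positions=(), read_len=80, n_reads=30,
                   locus="L", switch_reads=0):
    """Synthetic mapped reads over a diploid locus with planted het sites.

    Returns (library, reads, h0, h1). Reads alternate haplotypes and tile
    the locus densely so adjacent het sites are linked.
    """
    ref = _random_dna(rng, length)
    h0 = list(ref)
    h1 = list(ref)
    for p in het_positions:
        h1[p] = _alt(h1[p])
    h0, h1 = "".join(h0), "".join(h1)
    # even tiling, four reads per start (two per haplotype), so every
    # position has depth >= 4 and adjacent het sites are linked
    n_starts = max(n_reads // 4, 2)
    span = length - read_len
    starts = [round(j * span / (n_starts - 1)) for j in range(n_starts)]
    reads = []
    i = 0
    for start in starts:
        for hap_seq in (h0, h0, h1, h1):
            seq = hap_seq[start : start + read_len]
            reads.append(
                MappedRead(
                    read_id=f"r{i}", locus_id=locus, start=start, strand="+",
                    cigar=f"{read_len}M", edit_distance=0, sequence=seq,
                    qualities=[38] * read_len, fragment_id=f"r{i}",
                )
            )
            i += 1
    lib = ReferenceLibrary("user-ref-lib", {locus: SeqRecord(locus, ref)})
    return lib, reads, h0, h1


def mec_oracle(fragments, positions):
    """Exhaustive minimum error correction over all 2^k phase vectors."""
    best = None
    for bits in product((0, 1), repeat=len(positions)):
        phase = dict(zip(positions, bits))
        total = 0
        for obs in fragments.values():
            c0 = sum(1 for p, a in obs.items() if a != phase[p])
            total += min(c0, len(obs) - c0)
        if best is None or total < best:
            best = total
    return best


def test_two_linked_het_sites_phase_cleanly():
    rng = np.random.default_rng(50)
    lib, reads, h0, h1 = _diploid_locus(rng, het_positions=(60, 100), n_reads=40)
    pileups, sites = pileup_and_variants(reads, lib)
    phased = phase_locus(pileups["L"], sites, "s")
    assert phased.mec == 0
    assert len(phased.phase_blocks) == 1
    assert {phased.h0.sequence, phased.h1.sequence} == {h0, h1}


def test_no_het_sites_gives_identical_haplotypes():
    rng = np.random.default_rng(51)
    lib, reads, h0, _ = _diploid_locus(rng, het_positions=())
    pileups, sites = pileup_and_variants(reads, lib)
    phased = phase_locus(pileups["L"], sites, "s")
    assert phased.phase_blocks == []
    assert phased.h0.sequence == phased.h1.sequence == h0


def test_three_alleles_raise_excess_haplotype_flag():
    rng = np.random.default_rng(52)
    ref = _random_dna(rng, 100)
    variants = sorted({ref[50], "A", "C", "G"})[:3]
    reads = []
    for i in range(30):
        base = variants[i % 3]
        seq = ref[:50] + base + ref[51:]
        reads.append(
            MappedRead(f"r{i}", "L", 0, "+", "100M", 1, seq, [38] * 100,
                       fragment_id=f"r{i}")
        )
    lib = ReferenceLibrary("user-ref-lib", {"L": SeqRecord("L", ref)})
    pileups, sites = pileup_and_variants(reads, lib)
    assert any(len(s.alleles) > 2 for s in sites)
    phased = phase_locus(pileups["L"], sites, "s")
    assert phased.excess_haplotype_flag


def test_unlinked_sites_form_separate_blocks():
    rng = np.random.default_rng(53)
    # reads only 30 long, het sites 150 apart: never co-covered
    lib, reads, h0, h1 = _diploid_locus(
        rng, length=300, het_positions=(30, 250), read_len=40, n_reads=120
    )
    pileups, sites = pileup_and_variants(reads, lib)
    phased = phase_locus(pileups["L"], sites, "s")
    assert len(phased.phase_blocks) == 2


def test_read_partition_is_complete():
    rng = np.random.default_rng(54)
    lib, reads, _, _ = _diploid_locus(rng, het_positions=(60, 100), n_reads=40)
    pileups, sites = pileup_and_variants(reads, lib)
    phased = phase_locus(pileups["L"], sites, "s")
    n = len(phased.h0_reads) + len(phased.h1_reads) + len(phased.unassigned_reads)
    assert n == len(pileups["L"].reads)
    assert phased.unassigned_read_count == len(phased.unassigned_reads)


def test_assigned_reads_consistent_with_their_haplotype_when_mec_zero():
    rng = np.random.default_rng(55)
    lib, reads, h0, h1 = _diploid_locus(rng, het_positions=(40, 90, 140), n_reads=60)
    pileups, sites = pileup_and_variants(reads, lib)
    phased = phase_locus(pileups["L"], sites, "s")
    assert phased.mec == 0
    het_pos = [s.position for s in sites if s.is_heterozygous]
    for hap_reads, hap_seq in ((phased.h0_reads, phased.h0.sequence),
                               (phased.h1_reads, phased.h1.sequence)):
        for read in hap_reads:
            seq = read.oriented_sequence()
            for rpos, qpos in read.aligned_pairs():
                if rpos in het_pos:
                    assert seq[qpos] == hap_seq[rpos]


def test_final_mec_matches_exhaustive_optimum():
    """Greedy + flip refinement reaches the exhaustive MEC optimum on
    small instances, including noisy ones."""
    rng = np.random.default_rng(56)
    optimal = 0
    total = 30
    for trial in range(total):
        k = int(rng.integers(2, 6))
        positions = sorted(rng.choice(np.arange(20, 180, 10), size=k, replace=False))
        lib, reads, _, _ = _diploid_locus(
            rng, het_positions=tuple(int(p) for p in positions), n_reads=50
        )
        # inject noise: flip a couple of read bases at het sites
        for read in reads[:3]:
            seq = list(read.sequence)
            for p in positions:
                if read.start <= p < read.start + len(seq):
                    seq[p - read.start] = _alt(seq[p - read.start])
            read.sequence = "".join(seq)
        pileups, sites = pileup_and_variants(reads, lib)
        het = [s for s in sites if s.is_heterozygous]
        fragments = fragment_alleles(pileups["L"].reads, het)
        _, _, mec = phase_sites(het, fragments)
        oracle = mec_oracle(fragments, [s.position for s in het])
        assert mec >= oracle
        if mec == oracle:
            optimal += 1
    assert optimal >= 0.95 * total


def test_haplotype_labels_deterministic():
    rng = np.random.default_rng(57)
    lib, reads, _, _ = _diploid_locus(rng, het_positions=(60, 100), n_reads=40)
    pileups, sites = pileup_and_variants(reads, lib)
    a = phase_locus(pileups["L"], sites, "s")
    b = phase_locus(pileups["L"], sites, "s")
    assert a.h0.sequence == b.h0.sequence and a.h1.sequence == b.h1.sequence
    # canonical rule: h0 carries the smaller allele at the first het site
    first = min(s.position for s in sites if s.is_heterozygous)
    assert a.h0.sequence[first] < a.h1.sequence[first]


def test_phase_sample_outputs(tmp_path):
    rng = np.random.default_rng(58)
    lib, reads, _, _ = _diploid_locus(rng, het_positions=(60, 100), n_reads=40)
    pileups, sites = pileup_and_variants(reads, lib)
    phased = phase_sample(pileups, sites, "s", tmp_path, lib.lengths())
    assert len(phased) == 1
    fasta = (tmp_path / "s_alleles.fasta").read_text()
    assert ">s_L_allele0" in fasta and ">s_L_allele1" in fasta
    assert (tmp_path / "s_allele0.sam").exists()
    assert (tmp_path / "s_allele1.sam").exists()
    report = (tmp_path / "s_phasing_report.tsv").read_text().splitlines()
    assert report[0].startswith("locus\t") and len(report) == 2
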