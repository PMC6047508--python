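"""Reference library construction, read mapping, duplicate marking,
pileup/variant calling, consensus and locus selection."""

import numpy as np
import pandas as pd
import pytest

from capkit.dna import revcomp
from capkit.io import MappedRead, Read, SeqRecord, write_fasta
from capkit.msa import LocusAlignment
from capkit.refassembly import (
    LocusPileup,
    ReferenceLibrary,
    VariantSite,
    assembly_consensus,
    build_reference,
    coverage_summary,
    locus_selection,
    map_reads,
    mark_duplicates,
    pileup_and_variants,
)


def _random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def _library(loci: dict[str, str]) -> ReferenceLibrary:
    return ReferenceLibrary("user-ref-lib", {k: SeqRecord(k, v) for k, v in loci.items()})


# ---------------------------------------------------------------------------
# reference construction


def test_alignment_consensus_reference_of_identical_rows():
    aln = LocusAlignment("L1", ["a_L1", "b_L1", "c_L1"], ["ACGTACGT"] * 3)
    lib = build_reference("alignment-consensus", msas={"L1": aln})[""]
    assert lib.loci["L1"].sequence == "ACGTACGT"


def test_sample_specific_reference_extracts_own_row():
    aln = LocusAlignment("L1", ["sa_L1", "sb_L1"], ["AC-GT", "ACGGT"])
    libs = build_reference("sample-specific", msas={"L1": aln}, samples=["sa", "sb"])
    assert libs["sa"].loci["L1"].sequence == "ACGT"
    assert libs["sb"].loci["L1"].sequence == "ACGGT"


def test_user_reference_passthrough(tmp_path):
    records = [SeqRecord("L1", "ACGTACGT"), SeqRecord("L2", "TTTTACGT")]
    p = tmp_path / "ref.fasta"
    write_fasta(records, p)
    lib = build_reference("user-ref-lib", fasta_path=p)[""]
    assert {k: v.sequence for k, v in lib.loci.items()} == {
        "L1": "ACGTACGT", "L2": "TTTTACGT"
    }


# ---------------------------------------------------------------------------
# mapping


def test_exact_substring_maps_at_offset():
    rng = np.random.default_rng(30)
    locus = _random_dna(rng, 200)
    lib = _library({"L": locus})
    read = Read("r/1", locus[10:60], [38] * 50, "R1")
    (rec,) = map_reads([read], lib)
    assert (rec.locus_id, rec.start, rec.cigar, rec.edit_distance) == ("L", 10, "50M", 0)
    assert rec.strand == "+"


def test_reverse_complement_read_maps_same_position():
    rng = np.random.default_rng(31)
    locus = _random_dna(rng, 200)
    lib = _library({"L": locus})
    read = Read("r/1", revcomp(locus[10:60]), [38] * 50, "R1")
    (rec,) = map_reads([read], lib)
    assert (rec.start, rec.strand) == (10, "-")


def test_read_with_mismatches_maps_within_budget():
    rng = np.random.default_rng(32)
    locus = _random_dna(rng, 300)
    lib = _library({"L": locus})
    raw = list(locus[50:150])
    raw[20] = {"A": "C", "C": "G", "G": "T", "T": "A"}[raw[20]]
    raw[70] = {"A": "C", "C": "G", "G": "T", "T": "A"}[raw[70]]
    read = Read("r/1", "".join(raw), [38] * 100, "R1")
    (rec,) = map_reads([read], lib, max_edit_rate=0.1)
    assert rec.start == 50 and rec.edit_distance == 2


def test_ambiguous_read_between_two_loci_unmapped():
    rng = np.random.default_rng(33)
    shared = _random_dna(rng, 120)
    lib = _library({"L1": shared + _random_dna(rng, 50),
                    "L2": shared + _random_dna(rng, 50)})
    read = Read("r/1", shared[:80], [38] * 80, "R1")
    assert map_reads([read], lib) == []


def test_reference_ambiguity_codes_match_free():
    rng = np.random.default_rng(34)
    locus = list(_random_dna(rng, 120))
    read_seq = "".join(locus[20:80])
    locus[40] = "R" if locus[40] in "AG" else "Y"
    lib = _library({"L": "".join(locus)})
    (rec,) = map_reads([Read("r/1", read_seq, [38] * 60, "R1")], lib)
    assert rec.edit_distance == 0


def test_simulated_reads_map_to_planted_positions():
    """>=99% of clean reads drawn from a locus map back to their origin."""
    rng = np.random.default_rng(35)
    loci = {f"L{i}": _random_dna(rng, 600) for i in range(4)}
    lib = _library(loci)
    reads = []
    truth = []
    for i in range(500):
        locus = f"L{int(rng.integers(4))}"
        start = int(rng.integers(0, 500))
        seq = list(loci[locus][start : start + 100])
        for _ in range(int(rng.integers(0, 3))):  # up to 2 mismatches
            p = int(rng.integers(100))
            seq[p] = "ACGT"[int(rng.integers(4))]
        s = "".join(seq)
        if rng.random() < 0.5:
            s = revcomp(s)
        reads.append(Read(f"r{i}/1", s, [38] * 100, "R1"))
        truth.append((locus, start))
    mapped = {r.read_id: r for r in map_reads(reads, lib, max_edit_rate=0.1)}
    hits = sum(
        1
        for i, (locus, start) in enumerate(truth)
        if f"r{i}/1" in mapped
        and (mapped[f"r{i}/1"].locus_id, mapped[f"r{i}/1"].start) == (locus, start)
    )
    assert hits >= 0.99 * len(reads)


# ---------------------------------------------------------------------------
# duplicates


def _mapped(rid, locus="L", start=0, strand="+", quals=None, mate="R1", frag=None):
    return MappedRead(
        read_id=rid, locus_id=locus, start=start, strand=strand,
        cigar="50M", edit_distance=0, sequence="A" * 50,
        qualities=quals or [30] * 50, mate=mate, fragment_id=frag or rid,
    )


def test_identical_single_end_placements_one_flagged():
    a = _mapped("a", quals=[30] * 50)
    b = _mapped("b", quals=[20] * 50)
    mark_duplicates([a, b])
    assert not a.is_duplicate and b.is_duplicate  # higher quality kept


def test_offset_placements_not_duplicates():
    a = _mapped("a", start=0)
    b = _mapped("b", start=1)
    mark_duplicates([a, b])
    assert not a.is_duplicate and not b.is_duplicate


def test_pair_duplicates_require_both_mate_positions():
    p1 = [_mapped("x/1", start=0, frag="x", mate="R1"),
          _mapped("x/2", start=120, strand="-", frag="x", mate="R2")]
    p2 = [_mapped("y/1", start=0, frag="y", mate="R1", quals=[10] * 50),
          _mapped("y/2", start=120, strand="-", frag="y", mate="R2", quals=[10] * 50)]
    p3 = [_mapped("z/1", start=0, frag="z", mate="R1"),
          _mapped("z/2", start=150, strand="-", frag="z", mate="R2")]
    mark_duplicates(p1 + p2 + p3)
    assert all(not r.is_duplicate for r in p1)  # highest quality pair kept
    assert all(r.is_duplicate for r in p2)
    assert all(not r.is_duplicate for r in p3)  # different mate position


def test_planted_duplicate_fraction_recovered():
    """Duplicate flagging recovers the simulator's planted PCR rate."""
    from capkit.simulate import SimulationConfig, simulate

    rate = 0.2
    cfg = SimulationConfig(n_loci=6, n_samples=1, duplicate_fraction=rate,
                           error_rate=0.0, seed=40)
    reads, truth = simulate(cfg)
    r1s, r2s = reads["s1"]
    lib = ReferenceLibrary(
        "user-ref-lib",
        {g.gene_id: SeqRecord(g.gene_id, truth.sample_haplotypes["s1"][g.gene_id][0])
         for g in truth.genes},
    )
    mapped = mark_duplicates(map_reads(r1s + r2s, lib, 0.1))
    flagged = sum(r.is_duplicate for r in mapped) / len(mapped)
    # ground truth: fragments sharing (gene, start, insert) — planted
    # copies plus coincidental position collisions — leave one survivor
    from collections import Counter

    placements = Counter((p.gene, p.start, p.insert) for p in truth.provenance)
    n_pairs = sum(placements.values())
    realized = (n_pairs - len(placements)) / n_pairs
    assert abs(flagged - realized) <= 0.03
    assert abs(flagged - rate) <= 0.08  # collisions inflate the planted 20%


# ---------------------------------------------------------------------------
# pileup / variants / consensus


def _reads_at(locus, base_seq, n, start=0, quals=38):
    return [
        MappedRead(
            read_id=f"r{i}", locus_id=locus, start=start, strand="+",
            cigar=f"{len(base_seq)}M", edit_distance=0, sequence=base_seq,
            qualities=[quals] * len(base_seq), fragment_id=f"r{i}",
        )
        for i in range(n)
    ]


def test_uniform_coverage_no_variant():
    lib = _library({"L": "AAAA"})
    recs = _reads_at("L", "AAAA", 10)
    pileups, sites = pileup_and_variants(recs, lib)
    assert sites == []
    assert pileups["L"].depth.tolist() == [10, 10, 10, 10]


def test_balanced_het_site_called():
    lib = _library({"L": "AACC"})
    recs = _reads_at("L", "AACC", 10) + [
        MappedRead(f"g{i}", "L", 0, "+", "4M", 1, "AGCC", [38] * 4,
                   fragment_id=f"g{i}")
        for i in range(9)
    ]
    _, sites = pileup_and_variants(recs, lib)
    (site,) = sites
    assert site.position == 1 and site.is_heterozygous
    assert dict(site.alleles) == {"A": 10, "G": 9}


def test_low_fraction_allele_not_variant():
    lib = _library({"L": "AACC"})
    recs = _reads_at("L", "AACC", 10) + [
        MappedRead("g", "L", 0, "+", "4M", 1, "AGCC", [38] * 4, fragment_id="g")
    ]
    _, sites = pileup_and_variants(recs, lib)  # 1/11 = 0.09 < 0.2
    assert sites == []


def test_low_quality_bases_not_tallied():
    lib = _library({"L": "AAAA"})
    recs = _reads_at("L", "AAAA", 5, quals=10)
    pileups, _ = pileup_and_variants(recs, lib, min_base_quality=20)
    assert pileups["L"].depth.tolist() == [0, 0, 0, 0]


def test_consensus_majority_het_and_depth_floor():
    lib = _library({"L": "A" * 30})
    recs = _reads_at("L", "A" * 30, 10)
    pileups, sites = pileup_and_variants(recs, lib)
    rec = assembly_consensus(pileups["L"], sites)
    assert rec.sequence == "A" * 30

    # het site becomes an IUPAC code
    recs = _reads_at("L", "A" * 30, 10) + [
        MappedRead(f"g{i}", "L", 0, "+", "30M", 1,
                   "A" * 15 + "G" + "A" * 14, [38] * 30, fragment_id=f"g{i}")
        for i in range(9)
    ]
    pileups, sites = pileup_and_variants(recs, lib)
    rec = assembly_consensus(pileups["L"], sites)
    assert rec.sequence[15] == "R"
    assert set(rec.sequence) <= {"A", "R"}


def test_consensus_depth_below_floor_is_n():
    lib = _library({"L": "A" * 10 + "C" * 10})
    recs = _reads_at("L", "A" * 10, 2)  # only first half, depth 2 < 3
    recs += _reads_at("L", "C" * 10, 5, start=10)
    pileups, sites = pileup_and_variants(recs, lib)
    rec = assembly_consensus(pileups["L"], sites, min_depth=3)
    # leading N run (depth 2) is trimmed; C half survives
    assert rec.sequence == "C" * 10


def test_coverage_mean_counts_zero_positions():
    lib = _library({"L": "A" * 100})
    recs = _reads_at("L", "A" * 50, 1)
    pileups, _ = pileup_and_variants(recs, lib, min_base_quality=0)
    table, mapped = coverage_summary({"s": pileups})
    assert table.loc["s", "L"] == pytest.approx(0.5)
    assert mapped["s"] == 1
    empty, _ = pileup_and_variants([], lib)
    table2, mapped2 = coverage_summary({"s": empty})
    assert table2.loc["s", "L"] == 0.0


def test_locus_selection_ranking_and_ties():
    table = pd.DataFrame(
        {"L1": [10.0], "L2": [8.0], "L3": [6.0], "L4": [4.0], "L5": [2.0]},
        index=["s"],
    )
    assert locus_selection(table, 3) == ["L1", "L2", "L3"]
    tie = pd.DataFrame({"La": [8.0], "Lb": [8.0], "Lc": [1.0]}, index=["s"])
    assert locus_selection(tie, 1) == ["La"]
    assert locus_selection(tie, 5) == ["La", "Lb", "Lc"]
    assert locus_selection(tie, 2, min_mean_depth=3.0) == ["La", "Lb"]
    assert locus_selection(tie, 3, min_mean_depth=3.0) == ["La", "Lb"]
    with pytest.raises(ValueError):
        locus_selection(tie, 0)
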