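"""Adapter/quality trimming semantics and the QC battery."""

import pytest
from hypothesis import given, settings, strategies as st

from capkit.cleaning import (
    CleaningConfig,
    clean_sample,
    qc_battery,
    qc_dataset_summary,
    trim_read,
)
from capkit.io import Read, SeqRecord, read_fastq, write_fastq
from capkit.simulate import SimulationConfig, simulate

ADAPTER = SeqRecord("ad", "AGATCGGAAGAGC")


def _read(seq, quals, rid="r"):
    return Read(rid, seq, quals)


def _window_oracle(quals, w, q):
    """Exhaustive scan: the cut point is the first bad window's start,
    extended over leading bases that are individually still good."""
    for start in range(len(quals) - w + 1):
        if sum(quals[start : start + w]) / w < q:
            cut = start
            while cut < len(quals) and quals[cut] >= q:
                cut += 1
            return cut
    return len(quals)


def test_sliding_window_truncates_at_first_bad_window():
    quals = [40] * 10 + [5] * 4
    cfg = CleaningConfig(window=4, window_quality=20, leading_q=0, trailing_q=0,
                         min_length=1)
    trimmed = trim_read(_read("A" * 14, quals), cfg)
    cut = _window_oracle(quals, 4, 20)
    assert cut == 10
    assert len(trimmed) == cut
    assert trimmed.qualities == quals[:cut]


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.lists(st.integers(2, 41), min_size=8, max_size=60))
def test_sliding_window_matches_exhaustive_scan(quals):
    cfg = CleaningConfig(window=4, window_quality=20, leading_q=0, trailing_q=0,
                         min_length=1)
    trimmed = trim_read(_read("A" * len(quals), quals), cfg)
    cut = _window_oracle(quals, 4, 20)
    assert (len(trimmed) if trimmed else 0) == cut


def test_adapter_suffix_clipped():
    insert = "TTTTCCCCGGGGAAAA"
    seq = insert + ADAPTER.sequence[:8]
    cfg = CleaningConfig(adapters=[ADAPTER], min_length=5, leading_q=0,
                         trailing_q=0, window_quality=0)
    trimmed = trim_read(_read(seq, [35] * len(seq)), cfg)
    assert trimmed.sequence == insert


def test_low_quality_read_discarded():
    cfg = CleaningConfig(min_length=36)
    assert trim_read(_read("A" * 50, [2] * 50), cfg) is None


def test_trimming_never_lengthens_and_is_idempotent():
    cfg = CleaningConfig(adapters=[ADAPTER])
    quals = [38] * 60 + [12] * 20 + [30] * 20
    read = _read("ACGT" * 25, quals)
    once = trim_read(read, cfg)
    assert len(once) <= len(read)
    twice = trim_read(once, cfg)
    assert twice.sequence == once.sequence and twice.qualities == once.qualities


def test_pairing_rules(tmp_path):
    cfg = CleaningConfig(min_length=36)
    good = ("G" * 50, [38] * 50)
    bad = ("G" * 50, [2] * 50)
    r1 = [Read("p1/1", *good), Read("p2/1", *good)]
    r2 = [Read("p1/2", *good), Read("p2/2", *bad)]  # p2's mate dies
    write_fastq(r1, tmp_path / "s_R1.fastq")
    write_fastq(r2, tmp_path / "s_R2.fastq")
    counts = clean_sample(tmp_path / "s_R1.fastq", tmp_path / "s_R2.fastq",
                          cfg, tmp_path / "out", "s")
    assert (counts.raw_pairs, counts.cleaned_pairs, counts.unpaired) == (2, 1, 1)
    unpaired = list(read_fastq(tmp_path / "out/s_unpaired.fastq"))
    assert [r.id for r in unpaired] == ["p2/1"]


def test_mate_id_mismatch_is_hard_error(tmp_path):
    cfg = CleaningConfig()
    write_fastq([Read("a/1", "A" * 40, [38] * 40)], tmp_path / "s_R1.fastq")
    write_fastq([Read("b/2", "A" * 40, [38] * 40)], tmp_path / "s_R2.fastq")
    with pytest.raises(ValueError, match="mismatch"):
        clean_sample(tmp_path / "s_R1.fastq", tmp_path / "s_R2.fastq",
                     cfg, tmp_path / "out", "s")


def test_readthrough_clip_recovers_insert_lengths():
    """Reads with planted adapter read-through trim back to the insert."""
    cfg = SimulationConfig(n_loci=4, n_samples=1, adapter_readthrough_fraction=0.3,
                           duplicate_fraction=0.0, error_rate=0.0, seed=5)
    reads, truth = simulate(cfg)
    clean_cfg = CleaningConfig(
        adapters=[SeqRecord("a1", cfg.adapter_r1), SeqRecord("a2", cfg.adapter_r2)]
    )
    r1s, _ = reads["s1"]
    by_id = {p.read_id: p for p in truth.provenance}
    checked = 0
    min_overlap = clean_cfg.adapter_min_overlap

    def suffix_mimics_adapter(seq: str) -> bool:
        # an insert whose own tail matches an adapter prefix is clipped
        # early by construction of overlap-based trimming
        for adapter in (cfg.adapter_r1, cfg.adapter_r2):
            for o in range(min_overlap, min(len(adapter), len(seq)) + 1):
                tail = seq[-o:]
                mm = sum(a != b for a, b in zip(tail, adapter))
                if mm <= 0.1 * o:
                    return True
        return False

    for read in r1s:
        prov = by_id[read.id.rsplit("/", 1)[0]]
        # adapter overlaps shorter than the minimum are unclippable
        if prov.insert > cfg.read_length - min_overlap or prov.is_duplicate:
            continue
        trimmed = trim_read(read, clean_cfg)
        assert trimmed is not None
        insert_seq = read.sequence[: prov.insert]
        assert insert_seq.startswith(trimmed.sequence)
        if not suffix_mimics_adapter(insert_seq):
            assert len(trimmed) == prov.insert
            checked += 1
    assert checked > 5


def test_qc_clean_reads_all_pass(tmp_path):
    reads = [
        Read(f"r{i}", "ACGTACGTACGTACGTACGTACGTACGTACGTACGT"[i % 4:][:32], [40] * 32)
        for i in range(50)
    ]
    # keep sequences distinct and GC-flat: rotate a fixed pattern
    reads = [Read(f"r{i}", ("ACGT" * 10)[:36], [40] * 36) for i in range(50)]
    write_fastq(reads, tmp_path / "x.fastq")
    report = qc_battery(tmp_path / "x.fastq", "s")
    assert report.results["per_base_quality"] == "pass"
    assert report.results["per_base_n_content"] == "pass"
    assert report.results["adapter_content"] == "pass"


def test_qc_planted_adapter_fails_adapter_content(tmp_path):
    clean = ("ACGT" * 20)[:60]
    with_adapter = clean[:30] + ADAPTER.sequence + clean[: 60 - 30 - len(ADAPTER)]
    reads = [
        Read(f"r{i}", with_adapter if i % 3 == 0 else clean, [38] * 60)
        for i in range(60)
    ]
    write_fastq(reads, tmp_path / "x.fastq")
    report = qc_battery(tmp_path / "x.fastq", "s", adapters=[ADAPTER])
    assert report.results["adapter_content"] == "fail"


def test_qc_deterministic(tmp_path, small_dataset):
    root, cfg, truth = small_dataset
    path = root / "raw" / "s1_R1.fastq"
    a = qc_battery(path, "s1")
    b = qc_battery(path, "s1")
    assert a == b


def test_qc_empty_file_errors(tmp_path):
    p = tmp_path / "e.fastq"
    p.write_text("")
    with pytest.raises(ValueError):
        qc_battery(p, "s")


def test_dataset_summary_counts():
    from capkit.cleaning import QC_TESTS, QCReport

    all_pass = {t: "pass" for t in QC_TESTS}
    one_fail = dict(all_pass, duplication_level="fail")
    reports = [QCReport(f"s{i}", dict(all_pass), 10) for i in range(3)]
    reports.append(QCReport("s3", one_fail, 10))
    counts, matrix = qc_dataset_summary(reports)
    assert counts.loc["duplication_level", "pass"] == 3
    assert counts.loc["duplication_level", "fail"] == 1
    assert counts.loc["per_base_quality", "pass"] == 4
    assert matrix.shape == (4, len(QC_TESTS))
    with pytest.raises(ValueError):
        qc_dataset_summary([])
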