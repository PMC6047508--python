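"""Adapter removal and quality trimming of raw paired reads, plus a
per-sample quality-control battery and dataset-wide summary.

Trimming follows the common convention for short-read cleaners: adapter
clipping first, then LEADING / TRAILING quality cuts, a sliding-window
truncation, and finally a minimum-length filter. Qualities stay
index-aligned with bases throughout.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from .io import Read, SeqRecord, read_fastq, write_fastq


@dataclass
class CleaningConfig:
    adapters: list[SeqRecord] = field(default_factory=list)
    window: int = 4
    window_quality: float = 20.0
    leading_q: int = 3
    trailing_q: int = 3
    min_length: int = 36
    adapter_min_overlap: int = 5
    adapter_max_mismatch_rate: float = 0.1

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window length must be >= 1")
        if not 0 <= self.window_quality <= 93:
            raise ValueError("window quality must be in [0, 93]")
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")
        if not 0 <= self.adapter_max_mismatch_rate <= 0.5:
            raise ValueError("adapter mismatch rate must be in [0, 0.5]")


def _find_adapter_start(seq: str, adapter: str, min_overlap: int, max_mm_rate: float) -> int | None:
    """Leftmost start of the best semi-global adapter match at the 3' end.

    Considers every placement where the adapter begins inside the read and
    runs to the read's 3' end (possibly truncated); returns the clip
    position or None.
    """
    n = len(seq)
    best: int | None = None
    for start in range(0, n - min_overlap + 1):
        overlap = min(len(adapter), n - start)
        if overlap < min_overlap:
            break
        mismatches = sum(1 for i in range(overlap) if seq[start + i] != adapter[i])
        if mismatches <= max_mm_rate * overlap:
            best = start
            break  # leftmost (longest-overlap) acceptable match wins
    return best


def trim_read(read: Read, cfg: CleaningConfig) -> Read | None:
    """Clean one read; returns None when it is discarded."""
    seq = read.sequence
    quals = read.qualities

    # 1. adapter clip
    for adapter in cfg.adapters:
        start = _find_adapter_start(seq, adapter.sequence, cfg.adapter_min_overlap,
                                    cfg.adapter_max_mismatch_rate)
        if start is not None:
            seq = seq[:start]
            quals = quals[:start]

    # 2. LEADING
    i = 0
    while i < len(seq) and quals[i] < cfg.leading_q:
        i += 1
    seq, quals = seq[i:], quals[i:]

    # 3. TRAILING
    j = len(seq)
    while j > 0 and quals[j - 1] < cfg.trailing_q:
        j -= 1
    seq, quals = seq[:j], quals[:j]

    # 4. SLIDINGWINDOW: at the first window whose mean quality drops below
    # the threshold, cut there but keep leading bases of the window that
    # are individually still good (Trimmomatic semantics)
    w = cfg.window
    if len(seq) >= w:
        for start in range(0, len(seq) - w + 1):
            if sum(quals[start : start + w]) / w < cfg.window_quality:
                cut = start
                while cut < len(seq) and quals[cut] >= cfg.window_quality:
                    cut += 1
                seq, quals = seq[:cut], quals[:cut]
                break

    # 5. MINLEN
    if len(seq) < cfg.min_length:
        return None
    return Read(read.id, seq, quals, read.mate)


@dataclass
class CleaningCounts:
    raw_pairs: int
    cleaned_pairs: int
    unpaired: int


def clean_sample(r1_path, r2_path, cfg: CleaningConfig, out_dir, sample_id: str) -> CleaningCounts:
    """Clean one sample's paired FASTQ files.

    A pair survives only if both mates survive trimming; a surviving
    singleton goes to the unpaired file. Mate ids must match in order.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    r1_out: list[Read] = []
    r2_out: list[Read] = []
    unpaired: list[Read] = []
    raw = 0

    r2_iter = read_fastq(r2_path, "R2")
    for r1 in read_fastq(r1_path, "R1"):
        try:
            r2 = next(r2_iter)
        except StopIteration:
            raise ValueError(f"{r2_path} has fewer records than {r1_path}") from None
        raw += 1
        if _pair_key(r1.id) != _pair_key(r2.id):
            raise ValueError(
                f"mate id mismatch at record {raw}: {r1.id!r} vs {r2.id!r}"
            )
        t1 = trim_read(r1, cfg)
        t2 = trim_read(r2, cfg)
        if t1 is not None and t2 is not None:
            r1_out.append(t1)
            r2_out.append(t2)
        elif t1 is not None:
            unpaired.append(t1)
        elif t2 is not None:
            unpaired.append(t2)
    if next(r2_iter, None) is not None:
        raise ValueError(f"{r2_path} has more records than {r1_path}")

    write_fastq(r1_out, out_dir / f"{sample_id}_R1.fastq")
    write_fastq(r2_out, out_dir / f"{sample_id}_R2.fastq")
    write_fastq(unpaired, out_dir / f"{sample_id}_unpaired.fastq")
    return CleaningCounts(raw, len(r1_out), len(unpaired))


def _pair_key(read_id: str) -> str:
    for suffix in ("/1", "/2"):
        if read_id.endswith(suffix):
            return read_id[: -len(suffix)]
    return read_id


# ---------------------------------------------------------------------------
# QC battery

QC_TESTS = (
    "per_base_quality",
    "per_sequence_quality",
    "per_base_n_content",
    "sequence_length_distribution",
    "duplication_level",
    "adapter_content",
    "per_base_gc_deviation",
)

ADAPTER_KMER = 12


@dataclass
class QCReport:
    sample_id: str
    results: dict[str, str]  # test -> pass|warning|fail
    n_reads: int

    def __post_init__(self) -> None:
        if set(self.results) != set(QC_TESTS):
            raise ValueError("QC report must contain every test exactly once")


def qc_battery(path, sample_id: str, adapters: Iterable[SeqRecord] = ()) -> QCReport:
    """Run the reduced quality battery on one FASTQ file.

    Seven tests with fixed pass/warning/fail thresholds covering per-base
    and per-read quality, N content, length uniformity, duplication,
    adapter k-mer content and per-position GC deviation.
    """
    reads = list(read_fastq(path))
    if not reads:
        raise ValueError(f"{path}: empty FASTQ file, cannot run QC")

    max_len = max(len(r) for r in reads)
    qual_cols: list[list[int]] = [[] for _ in range(max_len)]
    n_counts = np.zeros(max_len)
    gc_counts = np.zeros(max_len)
    col_depth = np.zeros(max_len)
    adapter_hits = np.zeros(max_len)
    mean_quals = []
    seq_counter: Counter[str] = Counter()
    lengths: Counter[int] = Counter()

    kmers = set()
    for a in adapters:
        for i in range(len(a.sequence) - ADAPTER_KMER + 1):
            kmers.add(a.sequence[i : i + ADAPTER_KMER])

    for r in reads:
        mean_quals.append(sum(r.qualities) / len(r))
        seq_counter[r.sequence] += 1
        lengths[len(r)] += 1
        for i, (b, q) in enumerate(zip(r.sequence, r.qualities)):
            qual_cols[i].append(q)
            col_depth[i] += 1
            if b == "N":
                n_counts[i] += 1
            elif b in "GC":
                gc_counts[i] += 1
        if kmers:
            for i in range(len(r) - ADAPTER_KMER + 1):
                if r.sequence[i : i + ADAPTER_KMER] in kmers:
                    adapter_hits[i:len(r)] += 1
                    break

    results: dict[str, str] = {}

    # per-base quality: quartiles of each position
    status = "pass"
    for col in qual_cols:
        arr = np.asarray(col)
        lq, med = np.percentile(arr, 25), np.median(arr)
        if lq < 5 or med < 20:
            status = "fail"
            break
        if lq < 10 or med < 25:
            status = "warning"
    results["per_base_quality"] = status

    # per-sequence quality: mode of per-read mean quality
    mode = Counter(int(q) for q in mean_quals).most_common(1)[0][0]
    results["per_sequence_quality"] = "fail" if mode < 20 else ("warning" if mode < 27 else "pass")

    n_frac = np.divide(n_counts, col_depth, out=np.zeros(max_len), where=col_depth > 0)
    results["per_base_n_content"] = (
        "fail" if n_frac.max() > 0.20 else ("warning" if n_frac.max() > 0.05 else "pass")
    )

    if 0 in lengths:
        results["sequence_length_distribution"] = "fail"
    elif len(lengths) > 1:
        results["sequence_length_distribution"] = "warning"
    else:
        results["sequence_length_distribution"] = "pass"

    dup_frac = 1 - len(seq_counter) / len(reads)
    results["duplication_level"] = (
        "fail" if dup_frac > 0.50 else ("warning" if dup_frac > 0.20 else "pass")
    )

    adapter_frac = np.divide(adapter_hits, col_depth, out=np.zeros(max_len), where=col_depth > 0)
    results["adapter_content"] = (
        "fail" if adapter_frac.max() > 0.10 else ("warning" if adapter_frac.max() > 0.05 else "pass")
    )

    gc_frac = 100 * np.divide(gc_counts, col_depth, out=np.zeros(max_len), where=col_depth > 0)
    gc_mean = 100 * gc_counts.sum() / col_depth.sum()
    deviation = np.abs(gc_frac - gc_mean).max()
    results["per_base_gc_deviation"] = (
        "fail" if deviation > 10 else ("warning" if deviation > 5 else "pass")
    )

    return QCReport(sample_id, results, len(reads))


def qc_dataset_summary(reports: list[QCReport]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aggregate QC reports into (per-test count table, sample x test matrix)."""
    if not reports:
        raise ValueError("no QC reports to summarize")
    matrix = pd.DataFrame(
        {r.sample_id: [r.results[t] for t in QC_TESTS] for r in reports},
        index=list(QC_TESTS),
    ).T
    counts = pd.DataFrame(
        {
            status: (matrix == status).sum(axis=0)
            for status in ("pass", "warning", "fail")
        }
    )
    return counts, matrix
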