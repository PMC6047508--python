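"""Cumulative per-sample summary log and recovery/coverage matrix export.

The summary file is tab-separated with one row per sample and the five
per-stage count columns; each pipeline stage overwrites only its own
column, so the file accumulates across stages and reruns are idempotent.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

COLUMNS = [
    "FASTQ read pairs (raw)",
    "FASTQ read pairs (cleaned)",
    "Total contig count",
    "Recovered target contigs",
    "Reads on target regions",
]
SAMPLE_COLUMN = "Sample ID"


def read_summary(path) -> pd.DataFrame:
    path = Path(path)
    if path.exists():
        df = pd.read_csv(path, sep="\t", dtype={SAMPLE_COLUMN: str})
        df = df.set_index(SAMPLE_COLUMN)
    else:
        df = pd.DataFrame(columns=COLUMNS)
        df.index.name = SAMPLE_COLUMN
    return df


def update_summary(path, sample_id: str, column: str, value: int) -> None:
    """Set one cell of the summary log; creates file/row as needed."""
    if column not in COLUMNS:
        raise ValueError(f"unknown summary column {column!r}; expected one of {COLUMNS}")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df = read_summary(path)
    df.loc[str(sample_id), column] = value
    df = df.reindex(columns=COLUMNS)
    out = df.reset_index()
    # counts are integers; absent cells stay empty
    for col in COLUMNS:
        out[col] = out[col].map(lambda v: "" if pd.isna(v) else str(int(v)))
    out.to_csv(path, sep="\t", index=False)


def validate_summary(path) -> pd.DataFrame:
    """Check the row invariants of a completed summary file."""
    df = read_summary(path)
    num = df.apply(pd.to_numeric, errors="coerce")
    if (num < 0).any().any():
        raise ValueError("summary contains negative counts")
    bad = num[num[COLUMNS[1]] > num[COLUMNS[0]]]
    if len(bad):
        raise ValueError(f"cleaned pairs exceed raw pairs for samples {list(bad.index)}")
    bad = num[num[COLUMNS[3]] > num[COLUMNS[2]]]
    if len(bad):
        raise ValueError(f"recovered target contigs exceed total contigs for {list(bad.index)}")
    return num


def export_matrices(
    recovery: pd.DataFrame,
    msa_loci: set[str],
    coverage: pd.DataFrame,
    out_dir,
) -> None:
    """Write the sample x locus recovery matrix (0 absent / 1 contig
    recovered / 2 in an MSA) and the sample x locus mean-depth matrix."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    coded = recovery.copy()
    for locus in coded.columns:
        if locus in msa_loci:
            coded[locus] = coded[locus].map(lambda v: 2 if v else 0)
    coded.to_csv(out_dir / "locus_recovery_matrix.tsv", sep="\t")
    coverage.round(3).to_csv(out_dir / "locus_coverage_matrix.tsv", sep="\t")


def plot_matrices(recovery: pd.DataFrame, coverage: pd.DataFrame, out_dir) -> None:
    """Optional heatmap rendering of the two matrices."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 1, figsize=(10, 6))
    axes[0].imshow(recovery.values, aspect="auto", cmap="Blues", vmin=0, vmax=1)
    axes[0].set_title("contig recovery")
    axes[0].set_yticks(range(len(recovery.index)), recovery.index)
    im = axes[1].imshow(coverage.values, aspect="auto", cmap="viridis")
    axes[1].set_title("mean read depth")
    axes[1].set_yticks(range(len(coverage.index)), coverage.index)
    fig.colorbar(im, ax=axes[1])
    fig.tight_layout()
    fig.savefig(Path(out_dir) / "matrices.png", dpi=100)
    plt.close(fig)
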