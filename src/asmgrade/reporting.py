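"""Persistence and comparison of evaluation runs.

One run = one assembly of an A/B dataset pair. The flat schema mirrors the
original study's relational layout: run metadata (dataset ids, assembler,
parameters, resource usage — nullable, since no assembler is bundled),
the assembly statistics block, and one row per genome region of fidelity
metrics. Three interchangeable formats (TSV, JSON, SQLite) round-trip
losslessly; SQLite replaces the original MySQL deployment with the same
relational shape.
"""

from __future__ import annotations

import json
import math
import sqlite3
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .assembly_stats import AssemblyStats
from .fidelity_metrics import MetricRecord

RUN_FIELDS = [
    "dataset_id_a",
    "dataset_id_b",
    "assembler",
    "assembler_parameters",
    "k_value",
    "processors_used",
    "runtime",
    "processor_time",
    "max_memory_used",
    "final_disk_space_used",
]

# assembly-stats columns under their schema names
STATS_COLUMNS = {
    "contigs": "n_contigs",
    "total_contig_length": "total_contig_length",
    "average_contig_length": "average_contig_length",
    "contig_n50": "contig_n50",
    "largest_contig_length": "largest_contig_length",
    "contigs_gt_1000": "contigs_gt_1000",
    "contigs_gt_5000": "contigs_gt_5000",
    "scaffolds": "n_scaffolds",
    "total_scaffold_length": "total_scaffold_length",
    "average_scaffold_length": "average_scaffold_length",
    "scaffold_n50": "scaffold_n50",
    "largest_scaffold_length": "largest_scaffold_length",
}

METRIC_FIELDS = list(MetricRecord.__dataclass_fields__)

COLUMNS = ["run_index"] + RUN_FIELDS + list(STATS_COLUMNS) + METRIC_FIELDS

SCHEMA_DDL = (
    "CREATE TABLE IF NOT EXISTS runs (\n    "
    + ",\n    ".join(
        f"{col} {'TEXT' if col in ('dataset_id_a', 'dataset_id_b', 'assembler', 'assembler_parameters', 'genome_region') else 'REAL'}"
        for col in COLUMNS
    )
    + "\n);"
)


@dataclass
class RunRecord:
    dataset_id_a: str
    dataset_id_b: str = ""
    assembler: str = ""
    assembler_parameters: str = ""
    k_value: int | None = None
    processors_used: int | None = None
    runtime: float | None = None
    processor_time: float | None = None
    max_memory_used: float | None = None
    final_disk_space_used: float | None = None
    stats: AssemblyStats | None = None
    metrics: list[MetricRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.dataset_id_a:
            raise ValueError("dataset_id_a must be non-empty")


def _flatten(records: Sequence[RunRecord]) -> pd.DataFrame:
    rows = []
    for idx, rec in enumerate(records):
        base: dict = {"run_index": idx}
        for f in RUN_FIELDS:
            base[f] = getattr(rec, f)
        for col, attr in STATS_COLUMNS.items():
            base[col] = getattr(rec.stats, attr) if rec.stats else None
        metric_rows = rec.metrics or [None]
        for m in metric_rows:
            row = dict(base)
            for f in METRIC_FIELDS:
                row[f] = getattr(m, f) if m is not None else None
            rows.append(row)
    return pd.DataFrame(rows, columns=COLUMNS)


_INT_RUN_FIELDS = {"k_value", "processors_used"}
_INT_STATS = {
    "contigs",
    "total_contig_length",
    "contig_n50",
    "largest_contig_length",
    "contigs_gt_1000",
    "contigs_gt_5000",
    "scaffolds",
    "total_scaffold_length",
    "scaffold_n50",
    "largest_scaffold_length",
}
_INT_METRICS = {
    "ambiguous_bases",
    "misassembled_contigs",
    "misassembled_contig_bases",
    "internal_overlaps",
    "internal_gaps",
    "n_gaps",
    "n_negative_gaps",
    "total_gap_bases",
    "n_captured_gaps",
    "total_captured_gap_bases",
    "unaligned_contigs",
    "unaligned_bases",
    "ambiguously_aligned_contigs",
    "ambiguously_aligned_bases",
}


def _unflatten(df: pd.DataFrame) -> list[RunRecord]:
    def clean(value, as_int: bool = False):
        if value is None or (isinstance(value, float) and math.isnan(value)):
            return None
        if as_int:
            return int(value)
        return value

    records: list[RunRecord] = []
    for _, group in df.groupby("run_index", sort=True):
        first = group.iloc[0]
        kwargs = {
            f: clean(first[f], as_int=f in _INT_RUN_FIELDS) for f in RUN_FIELDS
        }
        for f in ("dataset_id_b", "assembler", "assembler_parameters"):
            if kwargs[f] is None:
                kwargs[f] = ""
        stats = None
        if clean(first["contigs"]) is not None:
            stats = AssemblyStats(
                **{
                    attr: (
                        int(first[col]) if col in _INT_STATS else float(first[col])
                    )
                    for col, attr in STATS_COLUMNS.items()
                }
            )
        metrics = []
        for _, row in group.iterrows():
            if clean(row["genome_region"]) is None:
                continue
            metrics.append(
                MetricRecord(
                    **{
                        f: (
                            int(row[f])
                            if f in _INT_METRICS
                            else (row[f] if f == "genome_region" else float(row[f]))
                        )
                        for f in METRIC_FIELDS
                    }
                )
            )
        records.append(RunRecord(stats=stats, metrics=metrics, **kwargs))
    return records


def write_records(
    records: Sequence[RunRecord], path: str | Path, format: str | None = None
) -> Path:
    """Write runs as TSV, JSON or SQLite (format inferred from the suffix
    when not given). One flat row per (run, genome_region); lossless."""
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").replace("db", "sqlite")
    df = _flatten(records)
    if fmt == "tsv":
        df.to_csv(path, sep="\t", index=False)
    elif fmt == "json":
        payload = df.where(df.notna(), None).to_dict(orient="records")
        path.write_text(json.dumps(payload, indent=1) + "\n")
    elif fmt == "sqlite":
        with sqlite3.connect(path) as con:
            con.execute("DROP TABLE IF EXISTS runs")
            con.execute(SCHEMA_DDL)
            placeholders = ",".join("?" for _ in COLUMNS)
            rows = [
                tuple(None if pd.isna(v) else v for v in row)
                for row in df.itertuples(index=False, name=None)
            ]
            con.executemany(f"INSERT INTO runs VALUES ({placeholders})", rows)
        con.close()
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return path


def read_records(path: str | Path, format: str | None = None) -> list[RunRecord]:
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").replace("db", "sqlite")
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    elif fmt == "json":
        df = pd.DataFrame(json.loads(path.read_text()), columns=COLUMNS)
    elif fmt == "sqlite":
        with sqlite3.connect(path) as con:
            df = pd.read_sql("SELECT * FROM runs", con)
        con.close()
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if df.empty:
        return []
    return _unflatten(df)


def records_frame(records: Sequence[RunRecord]) -> pd.DataFrame:
    """The flat one-row-per-(run, region) table as a DataFrame."""
    return _flatten(records)


def compare_runs(
    records: Sequence[RunRecord],
    group_by: str,
    metric: str,
    genome_region: str = "all",
) -> pd.DataFrame:
    """Mean/sd/n of one numeric metric per group (the figure-style summary
    of platform/assembler combinations).

    Groups with a single run report sd as null; group ordering is
    deterministic (sorted by key)."""
    df = _flatten(records)
    if group_by not in df.columns:
        raise ValueError(f"unknown group-by field {group_by!r}")
    if metric not in df.columns:
        raise ValueError(f"unknown metric field {metric!r}")
    if genome_region is not None and "genome_region" in df.columns:
        df = df[df["genome_region"] == genome_region]
    if df.empty:
        return pd.DataFrame(columns=[group_by, "mean", "sd", "n"])
    if not pd.api.types.is_numeric_dtype(df[metric]):
        raise ValueError(f"metric {metric!r} is not numeric")
    out = (
        df.groupby(group_by)[metric]
        .agg(mean="mean", sd="std", n="count")
        .reset_index()
        .sort_values(group_by, kind="stable")
        .reset_index(drop=True)
    )
    return out


def plot_comparison(
    table: pd.DataFrame, metric_name: str, path: str | Path
) -> Path:
    """Static bar plot of a compare_runs table (one bar per group)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    group_col = table.columns[0]
    ax.bar(
        table[group_col].astype(str),
        table["mean"],
        yerr=table["sd"].fillna(0.0),
        capsize=4,
    )
    ax.set_ylabel(metric_name)
    ax.set_xlabel(group_col)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
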