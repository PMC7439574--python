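"""Readers and writers for the package's file formats.

FASTA/FASTQ parsing is delegated to Biopython; tables go through pandas with
a deterministic row/column order and 6-significant-digit floats so reruns are
byte-identical. The cohort CSV schema is shared by the clock and telomere
stages: ``subject_id, age_years, group, beta_<marker>..., telomere_kb,
cell_fraction`` with empty cells for missing values.
"""

from __future__ import annotations

import gzip
import json
from pathlib import Path
from typing import Iterator

import pandas as pd
import yaml
from Bio import SeqIO

from .amplicon import Amplicon
from .clock import ClockModel
from .cohort import CellFraction, Group, SubjectRecord
from .patterns import PatternTable

__all__ = [
    "read_fasta",
    "read_amplicon",
    "read_fastq",
    "write_fastq",
    "read_cohort_csv",
    "write_cohort_csv",
    "write_table",
    "pattern_table_frame",
    "load_clock_model",
    "save_clock_model",
]

FLOAT_FORMAT = "%.6g"


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Named, uppercased sequences in file order; errors on empty or
    malformed input with the offending line number."""
    with _open_text(path) as handle:
        lines = handle.readlines()
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        if not line.startswith(">"):
            raise ValueError(f"{path}: line {lineno}: expected FASTA header '>'")
        break
    else:
        raise ValueError(f"{path}: empty FASTA file")
    with _open_text(path) as handle:
        records = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(handle, "fasta")}
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    return records


def read_amplicon(path: str | Path, name: str | None = None) -> Amplicon:
    """First (or named) FASTA record as an Amplicon with auto-detected CpGs."""
    records = read_fasta(path)
    if name is None:
        name = next(iter(records))
    if name not in records:
        raise ValueError(f"{path}: no record named {name!r}")
    return Amplicon.from_sequence(name, records[name])


def read_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Yield (id, sequence, quality-string) per record; gzip transparent."""
    with _open_text(path) as handle:
        for i, rec in enumerate(SeqIO.parse(handle, "fastq")):
            quals = rec.letter_annotations["phred_quality"]
            yield rec.id, str(rec.seq).upper(), "".join(chr(q + 33) for q in quals)


def write_fastq(records, path: str | Path) -> None:
    with _open_text(path, "wt") as handle:
        SeqIO.write(records, handle, "fastq")


def read_cohort_csv(path: str | Path) -> list[SubjectRecord]:
    df = pd.read_csv(path)
    required = {"subject_id", "age_years", "group"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing cohort columns {sorted(missing)}")
    beta_cols = [c for c in df.columns if c.startswith("beta_")]
    subjects = []
    for _, row in df.iterrows():
        betas = {
            c[len("beta_") :]: float(row[c])
            for c in beta_cols
            if pd.notna(row[c])
        }
        telomere = float(row["telomere_kb"]) if "telomere_kb" in df.columns and pd.notna(row.get("telomere_kb")) else None
        fraction = (
            CellFraction(row["cell_fraction"])
            if "cell_fraction" in df.columns and pd.notna(row.get("cell_fraction"))
            else None
        )
        subjects.append(
            SubjectRecord(
                subject_id=str(row["subject_id"]),
                chronological_age=float(row["age_years"]),
                group=Group(row["group"]),
                betas=betas,
                telomere_kb=telomere,
                cell_fraction=fraction,
            )
        )
    return subjects


def write_cohort_csv(subjects, path: str | Path) -> None:
    markers = sorted({m for s in subjects for m in s.betas})
    rows = []
    for s in subjects:
        row = {
            "subject_id": s.subject_id,
            "age_years": s.chronological_age,
            "group": s.group.value,
        }
        for m in markers:
            row[f"beta_{m}"] = s.betas.get(m)
        row["telomere_kb"] = s.telomere_kb
        row["cell_fraction"] = s.cell_fraction.value if s.cell_fraction else None
        rows.append(row)
    write_table(pd.DataFrame(rows), path, sort_by=["subject_id"])


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    sort_by: list[str] | None = None,
    fmt: str | None = None,
) -> None:
    """Deterministic table writer: sorted rows, fixed column order as given,
    floats at 6 significant digits, UTF-8, header always present."""
    path = Path(path)
    if fmt is None:
        fmt = "tsv" if path.suffix in {".tsv", ".txt"} else "csv"
    out = df.copy()
    if sort_by:
        out = out.sort_values(sort_by, kind="mergesort")
    out.to_csv(
        path,
        sep="\t" if fmt == "tsv" else ",",
        index=False,
        float_format=FLOAT_FORMAT,
        encoding="utf-8",
    )


def pattern_table_frame(table: PatternTable) -> pd.DataFrame:
    """Pattern rows sorted by descending frequency, ties by pattern string."""
    rows = [
        {"pattern": p, "count": c, "frequency": c / table.total_reads}
        for p, c in table.counts.items()
    ]
    df = pd.DataFrame(rows, columns=["pattern", "count", "frequency"])
    return df.sort_values(
        ["frequency", "pattern"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)


def load_clock_model(path: str | Path) -> ClockModel:
    """Clock model from a YAML/JSON config: ``intercept`` plus a ``weights``
    marker->coefficient map (insertion order preserved)."""
    with open(path) as handle:
        data = yaml.safe_load(handle)
    return ClockModel(
        intercept=float(data["intercept"]),
        coefficients=tuple((str(m), float(w)) for m, w in data["weights"].items()),
    )


def save_clock_model(model: ClockModel, path: str | Path) -> None:
    data = {"intercept": model.intercept, "weights": dict(model.coefficients)}
    with open(path, "w") as handle:
        if str(path).endswith(".json"):
            json.dump(data, handle, indent=2)
        else:
            yaml.safe_dump(data, handle, sort_keys=False)
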