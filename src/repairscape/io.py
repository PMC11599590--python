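"""Reading and writing the package's on-disk formats.

All tabular formats are TSV with ``#``-prefixed header comments stating the
coordinate conventions.  The target library is a FASTA of full sequences
plus a ``targets.tsv`` sidecar with the protospacer/PAM coordinates.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .indel_core import TargetSite

__all__ = [
    "write_library",
    "read_library",
    "write_counts",
    "read_counts",
    "write_tsv",
    "read_tsv",
]

_COORD_COMMENT = (
    "# coordinates: 0-based half-open on the stored target sequence; "
    "the cut is a gap index (pam_start - 3)\n"
)

COUNT_COLUMNS = ["target", "line", "replicate", "timepoint", "outcome", "count"]


def write_library(targets: list[TargetSite], fasta_path: str | Path, tsv_path: str | Path) -> None:
    """Write a target library as FASTA plus a coordinate sidecar TSV."""
    records = [
        SeqRecord(Seq(t.sequence), id=t.id, description="") for t in targets
    ]
    with open(fasta_path, "w") as fh:
        SeqIO.write(records, fh, "fasta")
    df = pd.DataFrame(
        {
            "id": [t.id for t in targets],
            "protospacer_start": [t.protospacer_start for t in targets],
            "pam_start": [t.pam_start for t in targets],
        }
    )
    with open(tsv_path, "w") as fh:
        fh.write(_COORD_COMMENT)
        df.to_csv(fh, sep="\t", index=False)


def read_library(fasta_path: str | Path, tsv_path: str | Path) -> list[TargetSite]:
    """Read a target library written by :func:`write_library`."""
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    df = pd.read_csv(tsv_path, sep="\t", comment="#")
    targets = []
    for row in df.itertuples(index=False):
        if row.id not in seqs:
            raise ValueError(f"target {row.id} present in TSV but missing from FASTA")
        targets.append(
            TargetSite(str(row.id), seqs[row.id], int(row.protospacer_start), int(row.pam_start))
        )
    return targets


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    """Write a long-format outcome read-count table."""
    missing = set(COUNT_COLUMNS) - set(counts.columns)
    if missing:
        raise ValueError(f"counts table missing columns: {sorted(missing)}")
    with open(path, "w") as fh:
        fh.write(_COORD_COMMENT)
        fh.write("# outcome descriptors: D:<del_start>-<del_end> and/or I:<gap>:<seq>, canonical form\n")
        counts[COUNT_COLUMNS].to_csv(fh, sep="\t", index=False)


def read_counts(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"target": str, "outcome": str})
    missing = set(COUNT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"counts table missing columns: {sorted(missing)}")
    return df


def write_tsv(df: pd.DataFrame, path: str | Path, *, comments: list[str] | None = None, index: bool = False) -> None:
    """Write a TSV with optional ``#`` header comment lines."""
    with open(path, "w") as fh:
        for line in comments or []:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=index)


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)
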