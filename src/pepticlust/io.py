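"""Readers and writers for the pipeline's plain-text interchange formats.

All tables are UTF-8 TSV with '.' decimal separators:

* peak list  — ``mass_da  time_min  intensity``, one file per sample
* design     — ``sample_id  animal_id  strain  time_point``
* protein DB — FASTA (Bio.SeqIO)
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

PEAK_COLUMNS = ["mass_da", "time_min", "intensity"]
DESIGN_COLUMNS = ["sample_id", "animal_id", "strain", "time_point"]


class FormatError(ValueError):
    """A file does not conform to its declared schema."""


def read_peak_list(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != PEAK_COLUMNS:
        raise FormatError(
            f"{path}: expected columns {PEAK_COLUMNS}, found {list(df.columns)}"
        )
    for col in PEAK_COLUMNS:
        if not pd.api.types.is_numeric_dtype(df[col]):
            raise FormatError(f"{path}: column {col!r} is not numeric")
    if (df["intensity"] < 0).any():
        row = int(df.index[df["intensity"] < 0][0]) + 2  # 1-based + header
        raise FormatError(f"{path}: negative intensity at row {row}")
    if (df["mass_da"] <= 0).any():
        row = int(df.index[df["mass_da"] <= 0][0]) + 2
        raise FormatError(f"{path}: non-positive mass at row {row}")
    return df.astype(float)


def write_peak_list(df: pd.DataFrame, path: str | Path) -> None:
    df.loc[:, PEAK_COLUMNS].to_csv(path, sep="\t", index=False)


def read_design(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns) != DESIGN_COLUMNS:
        raise FormatError(
            f"{path}: expected columns {DESIGN_COLUMNS}, found {list(df.columns)}"
        )
    dup = df.duplicated(subset=["animal_id", "time_point"])
    if dup.any():
        pair = df.loc[dup, ["animal_id", "time_point"]].iloc[0].tolist()
        raise FormatError(f"{path}: duplicate (animal_id, time_point) pair {pair}")
    strains_per_animal = df.groupby("animal_id")["strain"].nunique()
    if (strains_per_animal > 1).any():
        animal = strains_per_animal.index[strains_per_animal > 1][0]
        raise FormatError(f"{path}: animal {animal!r} assigned to multiple strains")
    return df


def write_design(df: pd.DataFrame, path: str | Path) -> None:
    df.loc[:, DESIGN_COLUMNS].to_csv(path, sep="\t", index=False)


def read_fasta(path: str | Path) -> list[SeqRecord]:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path) -> None:
    SeqIO.write(list(records), str(path), "fasta")


def make_record(name: str, sequence: str, description: str = "") -> SeqRecord:
    return SeqRecord(Seq(sequence), id=name, name=name, description=description)


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Clusters × samples intensity matrix; rows indexed by peptide_id."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "peptide_id"
    return df


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="peptide_id")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
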