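"""Readers and writers for the pipeline's plain-text formats.

See ``docs/formats.md`` for the column schemas.  Fluorescence comes in as
long-format CSV (well, cycle, channel, fluorescence); plate metadata as a
sample-sheet CSV mapping wells to roles (STANDARD with known mixture
fraction, or UNKNOWN with sample and tissue labels); promoter alleles as
multi-record FASTA.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .promoter import PromoterSequence
from .sigmoid import CHANNELS, FluorescenceCurve

__all__ = [
    "SampleSheetEntry",
    "read_fluorescence_csv",
    "read_sample_sheet",
    "read_promoter_fasta",
    "write_promoter_fasta",
    "read_kprime_tsv",
]

FLUOR_COLUMNS = ["well", "cycle", "channel", "fluorescence"]
SHEET_COLUMNS = ["well", "role", "x_true", "sample_id", "tissue", "replicate"]


class ParseError(ValueError):
    """Malformed input file."""


@dataclass(frozen=True)
class SampleSheetEntry:
    well: str
    role: str  # STANDARD | UNKNOWN
    x_true: float | None
    sample_id: str | None
    tissue: str | None
    replicate: int

    def __post_init__(self) -> None:
        if self.role not in ("STANDARD", "UNKNOWN"):
            raise ParseError(f"well {self.well}: unknown role {self.role!r}")
        if self.role == "STANDARD":
            if self.x_true is None or not 0.0 <= self.x_true <= 1.0:
                raise ParseError(f"well {self.well}: STANDARD needs x_true in [0, 1]")
        else:
            if not self.sample_id or not self.tissue:
                raise ParseError(f"well {self.well}: UNKNOWN needs sample_id and tissue")


def read_fluorescence_csv(path: str | Path) -> dict[tuple[str, str], FluorescenceCurve]:
    """Parse long-format fluorescence CSV into curves keyed by (well, channel)."""
    df = pd.read_csv(path, dtype={"well": str})
    missing = [c for c in FLUOR_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    if not np.issubdtype(df["fluorescence"].dtype, np.number):
        bad = df[pd.to_numeric(df["fluorescence"], errors="coerce").isna()].index[0]
        raise ParseError(f"{path}: non-numeric fluorescence at row {bad + 2}")
    df["channel"] = df["channel"].astype(str).str.upper()
    bad_channel = ~df["channel"].isin(CHANNELS)
    if bad_channel.any():
        row = df.index[bad_channel][0]
        raise ParseError(f"{path}: unknown channel {df.loc[row, 'channel']!r} at row {row + 2}")
    dup = df.duplicated(subset=["well", "channel", "cycle"])
    if dup.any():
        row = df.index[dup][0]
        raise ParseError(
            f"{path}: duplicate (well, channel, cycle) = "
            f"({df.loc[row, 'well']}, {df.loc[row, 'channel']}, {df.loc[row, 'cycle']}) "
            f"at row {row + 2}"
        )
    curves: dict[tuple[str, str], FluorescenceCurve] = {}
    for (well, channel), grp in df.groupby(["well", "channel"], sort=True):
        grp = grp.sort_values("cycle")
        curves[(str(well), str(channel))] = FluorescenceCurve(
            well_id=str(well), channel=str(channel),
            cycles=grp["cycle"].to_numpy(),
            fluorescence=grp["fluorescence"].to_numpy(dtype=float),
        )
    return curves


def read_sample_sheet(path: str | Path) -> list[SampleSheetEntry]:
    """Parse and validate the sample-sheet CSV."""
    df = pd.read_csv(path, dtype={"well": str, "sample_id": str, "tissue": str})
    missing = [c for c in SHEET_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    if df["well"].duplicated().any():
        well = df.loc[df["well"].duplicated(), "well"].iloc[0]
        raise ParseError(f"{path}: duplicate well {well!r}")
    entries = []
    for row in df.itertuples():
        x_true = None if pd.isna(row.x_true) or row.x_true == "" else float(row.x_true)
        sample_id = None if pd.isna(row.sample_id) else str(row.sample_id)
        tissue = None if pd.isna(row.tissue) else str(row.tissue)
        entries.append(SampleSheetEntry(
            well=str(row.well), role=str(row.role).upper(), x_true=x_true,
            sample_id=sample_id or None, tissue=tissue or None,
            replicate=int(row.replicate),
        ))
    return entries


def read_promoter_fasta(path: str | Path) -> list[PromoterSequence]:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ParseError(f"{path}: no FASTA records")
    return [PromoterSequence(id=r.id, residues=str(r.seq),
                             species_or_allele=r.description)
            for r in records]


def write_promoter_fasta(path: str | Path, sequences: Sequence[PromoterSequence]) -> None:
    with open(path, "w") as fh:
        for s in sequences:
            fh.write(f">{s.id} {s.species_or_allele}\n")
            for i in range(0, len(s.residues), 70):
                fh.write(s.residues[i:i + 70] + "\n")


def read_kprime_tsv(path: str | Path) -> pd.DataFrame:
    """Read a precomputed k' table (columns x_true, k; one row per replicate).

    x_true may be given as a fraction in [0, 1] or as a percentage.
    """
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    if "x_true" not in cols or not ({"k", "k_mean"} & set(cols)):
        raise ParseError(f"{path}: need columns x_true and k (or k_mean)")
    kcol = cols.get("k", cols.get("k_mean"))
    out = pd.DataFrame({"x_true": df[cols["x_true"]].astype(float),
                        "k": df[kcol].astype(float)})
    if (out["x_true"] > 1.0).any():
        out["x_true"] = out["x_true"] / 100.0
    return out
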