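"""Readers, writers and validated in-memory containers for every pipeline input.

One in-memory representation per input kind: sequences as :class:`GenomeRecord`,
annotation as :class:`FeatureTable`, and the tabular inputs (qPCR plates,
infection time series, fluorescence, virion composition) as thin validated
wrappers around :class:`pandas.DataFrame` with fixed column names.

All genomic coordinates are 1-based and inclusive, from file to memory and
back (the GFF3 convention); conversions to offsets happen only inside
algorithms that need them.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GenomeRecord",
    "FeatureTable",
    "QpcrPlate",
    "TimeSeriesTable",
    "FluorescenceTable",
    "CompositionTable",
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
    "read_table",
    "write_results",
    "SCHEMA_COLUMNS",
]

_DNA_ALPHABET = set("ACGTN")
_AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")

#: exact lower-case header expected for each delimiter-separated schema
SCHEMA_COLUMNS = {
    "qpcr": ["well_id", "sample_id", "assay_id", "ct", "role", "known_copies", "replicate"],
    "timeseries": ["time_h", "condition", "replicate", "compartment", "copies_per_ml"],
    "fluorescence": ["time_h", "condition", "replicate", "infected", "f0", "fm"],
    "composition": ["protein_id", "aa_sequence", "copies_per_virion"],
}


class FormatError(ValueError):
    """Raised when an input file violates its format or an invariant."""


@dataclass
class GenomeRecord:
    """A named nucleotide sequence with a circularity flag.

    The sequence is upper-cased on construction and restricted to the
    alphabet {A, C, G, T, N}.
    """

    id: str
    sequence: str
    circular: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("GenomeRecord id must be non-empty")
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise FormatError(f"GenomeRecord {self.id!r}: sequence is empty")
        for offset, base in enumerate(self.sequence, start=1):
            if base not in _DNA_ALPHABET:
                raise FormatError(
                    f"GenomeRecord {self.id!r}: illegal character {base!r} at offset {offset}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class FeatureTable:
    """Genomic features with 1-based inclusive coordinates.

    Columns: feature_id, start, end, strand (+/-), ftype, attributes (dict).
    """

    df: pd.DataFrame

    COLUMNS = ["feature_id", "start", "end", "strand", "ftype", "attributes"]

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.df.columns]
        if missing:
            raise FormatError(f"FeatureTable missing columns: {missing}")
        df = self.df.reset_index(drop=True)
        if df["feature_id"].duplicated().any():
            dup = df.loc[df["feature_id"].duplicated(), "feature_id"].iloc[0]
            raise FormatError(f"duplicate feature_id {dup!r}")
        bad = df[(df["start"] < 1) | (df["start"] > df["end"])]
        if not bad.empty:
            row = bad.index[0]
            raise FormatError(
                f"feature {df.loc[row, 'feature_id']!r}: invalid coordinates "
                f"start={df.loc[row, 'start']} end={df.loc[row, 'end']}"
            )
        if not df["strand"].isin(["+", "-"]).all():
            raise FormatError("strand must be '+' or '-'")
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    def sorted_by_start(self) -> pd.DataFrame:
        return self.df.sort_values(["start", "end"], kind="mergesort").reset_index(drop=True)

    def get(self, feature_id: str) -> pd.Series:
        hit = self.df[self.df["feature_id"] == feature_id]
        if hit.empty:
            raise KeyError(f"feature {feature_id!r} not found")
        return hit.iloc[0]


def _require_columns(df: pd.DataFrame, schema: str) -> pd.DataFrame:
    expected = SCHEMA_COLUMNS[schema]
    got = list(df.columns)
    if got != expected:
        raise FormatError(f"{schema} table: expected columns {expected}, got {got}")
    return df.reset_index(drop=True)


@dataclass
class QpcrPlate:
    """qPCR wells: CT values plus standard-dilution wells with known copies.

    Missing CT ("Undetermined" in instrument exports) is NaN, never 0.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = _require_columns(self.df, "qpcr")
        if not df["role"].isin(["standard", "unknown"]).all():
            bad = df.loc[~df["role"].isin(["standard", "unknown"])].index[0]
            raise FormatError(f"qpcr row {bad + 1}: role must be 'standard' or 'unknown'")
        std = df[df["role"] == "standard"]
        if (std["known_copies"].isna() | (std["known_copies"] <= 0)).any():
            bad = std[(std["known_copies"].isna()) | (std["known_copies"] <= 0)].index[0]
            raise FormatError(f"qpcr row {bad + 1}: standard wells need known_copies > 0")
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    def standards(self) -> pd.DataFrame:
        return self.df[self.df["role"] == "standard"]

    def unknowns(self) -> pd.DataFrame:
        return self.df[self.df["role"] == "unknown"]


@dataclass
class TimeSeriesTable:
    """Genome copies per ml by (time, condition, replicate, compartment)."""

    df: pd.DataFrame

    KEY = ["time_h", "condition", "replicate", "compartment"]

    def __post_init__(self) -> None:
        df = _require_columns(self.df, "timeseries")
        if (df["time_h"] < 0).any():
            raise FormatError("timeseries: time_h must be >= 0")
        vals = df["copies_per_ml"].to_numpy(dtype=float)
        if not np.isfinite(vals).all() or (vals < 0).any():
            raise FormatError("timeseries: copies_per_ml must be finite and >= 0")
        if not df["compartment"].isin(["intracellular", "extracellular"]).all():
            raise FormatError("timeseries: compartment must be intracellular/extracellular")
        dup = df.duplicated(subset=self.KEY)
        if dup.any():
            key = tuple(df.loc[dup.idxmax(), self.KEY])
            raise FormatError(f"timeseries: duplicated key {key}")
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    def select(self, condition: str | None = None, compartment: str | None = None) -> pd.DataFrame:
        out = self.df
        if condition is not None:
            out = out[out["condition"] == condition]
        if compartment is not None:
            out = out[out["compartment"] == compartment]
        return out.reset_index(drop=True)


@dataclass
class FluorescenceTable:
    """Dark-adapted PAM fluorescence pairs (F0, Fm) per sample."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = _require_columns(self.df, "fluorescence")
        f0 = df["f0"].to_numpy(dtype=float)
        fm = df["fm"].to_numpy(dtype=float)
        bad = np.flatnonzero(~((f0 > 0) & (fm >= f0)))
        if bad.size:
            raise FormatError(
                f"fluorescence row {bad[0] + 1}: requires fm >= f0 > 0 "
                f"(got f0={f0[bad[0]]}, fm={fm[bad[0]]})"
            )
        df["infected"] = df["infected"].astype(bool)
        self.df = df

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class CompositionTable:
    """Structural proteins of the virion: sequence and copies per particle."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = _require_columns(self.df, "composition")
        if df["protein_id"].duplicated().any():
            dup = df.loc[df["protein_id"].duplicated(), "protein_id"].iloc[0]
            raise FormatError(f"composition: duplicate protein_id {dup!r}")
        for i, seq in enumerate(df["aa_sequence"]):
            if not seq:
                raise FormatError(f"composition row {i + 1}: empty aa_sequence")
            extra = set(str(seq).upper()) - _AA_ALPHABET
            if extra:
                raise FormatError(
                    f"composition row {i + 1}: illegal residue(s) {sorted(extra)}"
                )
        if (df["copies_per_virion"] < 1).any():
            bad = df[df["copies_per_virion"] < 1].index[0]
            raise FormatError(f"composition row {bad + 1}: copies_per_virion must be >= 1")
        df["aa_sequence"] = df["aa_sequence"].str.upper()
        self.df = df

    def __len__(self) -> int:
        return len(self.df)


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> list[GenomeRecord]:
    """Read a FASTA file into validated :class:`GenomeRecord` objects.

    Sequences are upper-cased; the alphabet {A,C,G,T,N} is enforced and an
    illegal character is reported with its 1-based offset within the record.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: empty or not FASTA")
    out: list[GenomeRecord] = []
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        out.append(GenomeRecord(id=rec.id, sequence=str(rec.seq)))
    return out


def write_fasta(path: str | Path, records: Iterable[GenomeRecord]) -> None:
    """Write records as FASTA, wrapped at 70 columns."""
    seqs = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=70)
        writer.write_file(seqs)


# ---------------------------------------------------------------------------
# GFF3

def _parse_gff_attributes(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in str(text).split(";"):
        chunk = chunk.strip()
        if not chunk or chunk == ".":
            continue
        if "=" not in chunk:
            raise FormatError(f"malformed GFF3 attribute {chunk!r}")
        key, value = chunk.split("=", 1)
        attrs[key] = value
    return attrs


def read_gff3(path: str | Path, keep_types: set[str]) -> FeatureTable:
    """Read GFF3 features of the requested types (e.g. ``{"CDS"}``).

    Coordinates are kept 1-based inclusive as in the file. Features without
    an ``ID`` attribute get a synthetic ``<type>_<n>`` identifier.
    """
    if not keep_types:
        raise ValueError("keep_types must be non-empty")
    path = Path(path)
    rows = []
    auto = 0
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 tab-separated columns")
            _seqid, _source, ftype, start_s, end_s, _score, strand, _phase, attr_s = fields
            if ftype not in keep_types:
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if end < start:
                raise FormatError(f"{path}:{lineno}: end ({end}) < start ({start})")
            if strand not in "+-":
                raise FormatError(f"{path}:{lineno}: strand must be + or -")
            attrs = _parse_gff_attributes(attr_s)
            fid = attrs.get("ID")
            if fid is None:
                auto += 1
                fid = f"{ftype}_{auto}"
            rows.append((fid, start, end, strand, ftype, attrs))
    if not rows:
        raise FormatError(f"{path}: no features of type {sorted(keep_types)}")
    return FeatureTable(pd.DataFrame(rows, columns=FeatureTable.COLUMNS))


def write_gff3(path: str | Path, features: FeatureTable, seqid: str, source: str = "phagelight") -> None:
    """Write a FeatureTable as GFF3 (1-based inclusive, as held in memory)."""
    with open(path, "w") as handle:
        handle.write("##gff-version 3\n")
        for _, row in features.df.iterrows():
            attrs = dict(row["attributes"])
            attrs.setdefault("ID", row["feature_id"])
            attr_s = ";".join(f"{k}={v}" for k, v in attrs.items())
            handle.write(
                f"{seqid}\t{source}\t{row['ftype']}\t{row['start']}\t{row['end']}"
                f"\t.\t{row['strand']}\t.\t{attr_s}\n"
            )


# ---------------------------------------------------------------------------
# Delimiter-separated tables

_SCHEMA_TYPES = {
    "qpcr": QpcrPlate,
    "timeseries": TimeSeriesTable,
    "fluorescence": FluorescenceTable,
    "composition": CompositionTable,
}

_MISSING_CT = {"", "undetermined", "nan"}


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_table(path: str | Path, schema_name: str):
    """Read a delimiter-separated table into its typed, validated container.

    The delimiter is chosen by extension (.csv comma, anything else tab).
    Missing CT values — empty cells or the literal "Undetermined"
    (case-insensitive) — become NaN; any other non-numeric CT is an error.
    """
    if schema_name not in _SCHEMA_TYPES:
        raise ValueError(f"unknown schema {schema_name!r}; choose from {sorted(_SCHEMA_TYPES)}")
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
    df.columns = [c.strip().lower() for c in df.columns]
    df = _require_columns(df, schema_name)

    def to_float(col: str, allow_missing: bool = False) -> None:
        out = []
        for i, raw in enumerate(df[col]):
            txt = str(raw).strip()
            if txt.lower() in _MISSING_CT:
                if allow_missing:
                    out.append(math.nan)
                    continue
                raise FormatError(f"{path} row {i + 1}: missing value in {col!r}")
            try:
                out.append(float(txt))
            except ValueError as exc:
                raise FormatError(
                    f"{path} row {i + 1}: cannot parse {col}={txt!r} as a number"
                ) from exc
        df[col] = out

    if schema_name == "qpcr":
        to_float("ct", allow_missing=True)
        to_float("known_copies", allow_missing=True)
        df["replicate"] = df["replicate"].astype(int)
    elif schema_name == "timeseries":
        to_float("time_h")
        to_float("copies_per_ml")
        df["replicate"] = df["replicate"].astype(int)
    elif schema_name == "fluorescence":
        to_float("time_h")
        to_float("f0")
        to_float("fm")
        df["replicate"] = df["replicate"].astype(int)
        df["infected"] = df["infected"].str.strip().str.lower().map(
            {"true": True, "false": False, "1": True, "0": False}
        )
        if df["infected"].isna().any():
            bad = df[df["infected"].isna()].index[0]
            raise FormatError(f"{path} row {bad + 1}: infected must be true/false")
    elif schema_name == "composition":
        df["copies_per_virion"] = df["copies_per_virion"].astype(int)
    return _SCHEMA_TYPES[schema_name](df)


def _format_value(value) -> str:
    if isinstance(value, (bool, np.bool_)):
        return "true" if value else "false"
    if isinstance(value, (float, np.floating)):
        if math.isnan(value):
            return ""
        return format(float(value), ".9g")
    return str(value)


def write_results(path: str | Path, result) -> None:
    """Write any pipeline result as a delimiter-separated text table.

    Accepts the typed tables (their underlying frame is written with stable
    column order so that ``read_table`` round-trips them), bare DataFrames,
    or any dataclass-like object with scalar fields (one-row table). Floats
    carry 9 significant digits.
    """
    path = Path(path)
    sep = _sep_for(path)
    if isinstance(result, (QpcrPlate, TimeSeriesTable, FluorescenceTable, CompositionTable, FeatureTable)):
        df = result.df
        if isinstance(result, FeatureTable):
            df = df.drop(columns=["attributes"]).assign(
                attributes=[
                    ";".join(f"{k}={v}" for k, v in a.items()) or "."
                    for a in result.df["attributes"]
                ]
            )
    elif isinstance(result, pd.DataFrame):
        df = result
    elif hasattr(result, "__dataclass_fields__"):
        fields = list(result.__dataclass_fields__)
        df = pd.DataFrame([{f: getattr(result, f) for f in fields}])
    elif isinstance(result, Sequence) and result and hasattr(result[0], "__dataclass_fields__"):
        fields = list(result[0].__dataclass_fields__)
        df = pd.DataFrame([{f: getattr(r, f) for f in fields} for r in result])
    elif isinstance(result, Sequence) and not result:
        path.write_text("")
        return
    else:
        raise TypeError(f"cannot serialise {type(result).__name__}")

    buf = io.StringIO()
    buf.write(sep.join(df.columns) + "\n")
    for _, row in df.iterrows():
        buf.write(sep.join(_format_value(v) for v in row) + "\n")
    path.write_text(buf.getvalue())
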