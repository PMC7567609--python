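"""Readers and writers for every pipeline artifact.

All tabular formats are tab-delimited UTF-8 text with a header line, so
artifacts are diff-able and spreadsheet-safe; counts are always explicit
(no missing-value markers).  Round-trip identity (``write`` then ``read``)
holds for every format.

Formats
-------
- sequences: FASTA (header = variant id); lower-case bases upper-cased on
  read
- barcode map: TSV ``barcode<TAB>variant_id``
- counts: TSV ``barcode, variant_id, dna_ct, mrna_ct``
- energy matrix: TSV ``pos, val_A, val_C, val_G, val_T`` with ``#key=value``
  metadata header lines (gauge, units, start, wildtype)
- regions: BED-like TSV (0-based half-open) ``template, start, end,
  polarity, mean_info, evidence, score``
- config: JSON or YAML mapping
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .matrix import EnergyMatrix
from .seqs import validate_dna
from .sites import BindingRegion
from .synth import CountTable

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_counts",
    "write_counts",
    "read_barcode_map",
    "write_barcode_map",
    "read_matrix",
    "write_matrix",
    "read_regions",
    "write_regions",
    "read_config",
    "write_config",
    "write_true_sites",
]

_MATRIX_COLS = ["pos", "val_A", "val_C", "val_G", "val_T"]


def read_fasta(path) -> dict[str, str]:
    """Read named DNA sequences; bases are upper-cased and alphabet-checked."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate FASTA record id {rec.id!r}")
        out[rec.id] = validate_dna(str(rec.seq), f"record {rec.id!r}")
    if not out:
        raise ValueError(f"no FASTA records found in {path}")
    return out


def write_fasta(path, sequences: dict[str, str]) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_counts(path) -> CountTable:
    """Read a per-barcode count table; validation errors name the offender."""
    df = pd.read_csv(path, sep="\t", dtype={"barcode": str, "variant_id": str})
    missing = [c for c in ("barcode", "variant_id", "dna_ct", "mrna_ct") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    for col in ("dna_ct", "mrna_ct"):
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
        if len(bad):
            # +2: one for the header line, one for 1-based numbering
            raise ValueError(f"{path}: malformed {col} on line {bad[0] + 2}")
        df[col] = df[col].astype(np.int64)
    return CountTable(df)


def write_counts(path, counts: CountTable) -> None:
    counts.df[["barcode", "variant_id", "dna_ct", "mrna_ct"]].to_csv(
        path, sep="\t", index=False
    )


def read_barcode_map(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns) != ["barcode", "variant_id"]:
        raise ValueError(f"{path}: expected columns barcode, variant_id")
    dup = df["barcode"].duplicated()
    if dup.any():
        raise ValueError(f"{path}: duplicated barcode {df.loc[dup, 'barcode'].iloc[0]!r}")
    return dict(zip(df["barcode"], df["variant_id"]))


def write_barcode_map(path, mapping: dict[str, str]) -> None:
    pd.DataFrame(
        {"barcode": list(mapping.keys()), "variant_id": list(mapping.values())}
    ).to_csv(path, sep="\t", index=False)


def read_matrix(path) -> EnergyMatrix:
    """Read an energy matrix TSV with ``#key=value`` metadata lines."""
    meta: dict[str, str] = {}
    rows: list[list[float]] = []
    positions: list[int] = []
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    header_seen = False
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        if line.startswith("#"):
            key, _, value = line[1:].strip().partition("=")
            meta[key.strip()] = value.strip()
            continue
        fields = line.split("\t")
        if not header_seen:
            if fields != _MATRIX_COLS:
                raise ValueError(f"{path}: bad header on line {lineno}: {fields}")
            header_seen = True
            continue
        if len(fields) != 5:
            raise ValueError(f"{path}: expected 5 fields on line {lineno}, got {len(fields)}")
        try:
            positions.append(int(fields[0]))
            rows.append([float(x) for x in fields[1:]])
        except ValueError as exc:
            raise ValueError(f"{path}: malformed value on line {lineno}") from exc
    if not rows:
        raise ValueError(f"{path}: no matrix rows")
    if positions != list(range(len(rows))):
        raise ValueError(f"{path}: positions must run 0..{len(rows) - 1} in order")
    start = meta.get("start")
    wildtype = meta.get("wildtype") or None
    matrix = EnergyMatrix(
        np.asarray(rows, dtype=float),
        gauge=meta.get("gauge", "none"),
        wildtype=wildtype,
        start=int(start) if start not in (None, "") else None,
        units=meta.get("units", "A.U."),
    )
    if matrix.gauge == "wildtype-zero" and wildtype is not None:
        from .seqs import encode

        wt_vals = matrix.values[np.arange(len(matrix)), encode(wildtype)]
        if not np.allclose(wt_vals, 0.0, atol=1e-9):
            raise ValueError(f"{path}: gauge says wildtype-zero but wild-type entries differ from 0")
    return matrix


def write_matrix(path, matrix: EnergyMatrix) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"#gauge={matrix.gauge}\n")
        fh.write(f"#units={matrix.units}\n")
        if matrix.start is not None:
            fh.write(f"#start={matrix.start}\n")
        if matrix.wildtype is not None:
            fh.write(f"#wildtype={matrix.wildtype}\n")
        fh.write("\t".join(_MATRIX_COLS) + "\n")
        for pos, row in enumerate(matrix.values):
            vals = "\t".join(format(v, ".10g") for v in row)
            fh.write(f"{pos}\t{vals}\n")


def write_regions(path, regions: list[BindingRegion], template: str) -> None:
    """Write called regions as BED-like TSV (0-based half-open intervals)."""
    rows = [
        {
            "template": template,
            "start": r.start,
            "end": r.end,
            "polarity": r.polarity,
            "mean_info": r.mean_info,
            "evidence": r.evidence,
            "score": "" if r.score is None else r.score,
        }
        for r in regions
    ]
    pd.DataFrame(
        rows, columns=["template", "start", "end", "polarity", "mean_info", "evidence", "score"]
    ).to_csv(path, sep="\t", index=False)


def read_regions(path) -> list[BindingRegion]:
    df = pd.read_csv(path, sep="\t")
    regions = []
    for _, row in df.iterrows():
        score = row.get("score")
        regions.append(
            BindingRegion(
                start=int(row["start"]),
                end=int(row["end"]),
                polarity=str(row["polarity"]),
                mean_info=float(row["mean_info"]),
                evidence=str(row["evidence"]),
                score=None if pd.isna(score) else float(score),
            )
        )
    return regions


def write_true_sites(path, template) -> None:
    """Ground-truth planted sites as BED-like TSV, for test harnesses."""
    rows = [
        {
            "template": template.name,
            "start": s.interval[0],
            "end": s.interval[1],
            "role": s.role,
            "strength": s.interaction_strength,
        }
        for s in template.planted_sites
    ]
    pd.DataFrame(rows, columns=["template", "start", "end", "role", "strength"]).to_csv(
        path, sep="\t", index=False
    )


def read_config(path) -> dict:
    """Read a JSON or YAML configuration mapping (by file extension)."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    cfg = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def write_config(path, config: dict) -> None:
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(config, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    else:
        path.write_text(yaml.safe_dump(config, sort_keys=True), encoding="utf-8")
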