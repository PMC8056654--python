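"""Readers and writers for the plain-text formats used throughout the package.

Formats: TSV tables with a mandatory header, GCT v1.2 matrices, GMT gene-set
collections, fingerprint tables (0/1 strings or hex), and one-id-per-line
group files.  Writers can prepend ``#``-comment header lines carrying the
tool version, seed and config hash; all readers skip ``#`` comments.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, SchemaError

__all__ = [
    "read_tsv",
    "write_tsv",
    "read_reports",
    "read_synonym_map",
    "read_atc_map",
    "read_cell_organ_map",
    "read_matrix",
    "read_gct",
    "write_gct",
    "read_gmt",
    "write_gmt",
    "read_fingerprints",
    "write_fingerprints",
    "read_group_file",
    "write_group_file",
    "config_hash",
    "output_header",
]


def config_hash(config: Mapping) -> str:
    """Stable short hash of a (nested, YAML-serializable) config mapping."""
    import yaml

    blob = yaml.safe_dump(config, sort_keys=True).encode()
    return hashlib.sha1(blob).hexdigest()[:12]


def output_header(version: str, seed=None, cfg_hash=None) -> str:
    parts = [f"dignet v{version}"]
    if seed is not None:
        parts.append(f"seed={seed}")
    if cfg_hash is not None:
        parts.append(f"config={cfg_hash}")
    return "# " + " | ".join(parts)


def read_tsv(path, required: Sequence[str] = ()) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    return df


def write_tsv(df: pd.DataFrame, path, header_comment: str | None = None,
              index: bool = False, index_label=None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(header_comment.rstrip("\n") + "\n")
        df.to_csv(fh, sep="\t", index=index, index_label=index_label)


def read_reports(path) -> pd.DataFrame:
    """Adverse-event report table: ``report_id, drug, adr, source``."""
    df = read_tsv(path, required=("report_id", "drug", "adr", "source"))
    return df[["report_id", "drug", "adr", "source"]]


def read_synonym_map(path) -> dict[str, str]:
    """Two-column TSV ``raw_term, preferred_term`` -> dict."""
    df = read_tsv(path, required=("raw_term", "preferred_term"))
    return dict(zip(df["raw_term"], df["preferred_term"]))


def read_atc_map(path) -> dict[str, list[str]]:
    """TSV ``drug, atc_code`` (one row per code) -> drug -> list of codes."""
    df = read_tsv(path, required=("drug", "atc_code"))
    out: dict[str, list[str]] = {}
    for drug, code in zip(df["drug"], df["atc_code"]):
        out.setdefault(drug, []).append(code)
    return out


def read_cell_organ_map(path) -> dict[str, str]:
    df = read_tsv(path, required=("cell_type", "organ_letter"))
    dup = df["cell_type"][df["cell_type"].duplicated()]
    if len(dup):
        raise SchemaError(f"cell types mapped to more than one organ: {sorted(set(dup))}")
    return dict(zip(df["cell_type"], df["organ_letter"]))


# ---------------------------------------------------------------- matrices

def read_gct(path) -> pd.DataFrame:
    """GCT v1.2 -> genes x samples float DataFrame (Description column dropped)."""
    path = Path(path)
    with open(path) as fh:
        version = fh.readline().strip()
        if not version.startswith("#1.2"):
            raise ParseError(f"{path}: not a GCT v1.2 file (first line {version!r})")
        dims = fh.readline().split()
        if len(dims) < 2:
            raise ParseError(f"{path}: malformed GCT dimension line")
        nrow, ncol = int(dims[0]), int(dims[1])
        df = pd.read_csv(fh, sep="\t", index_col=0)
    df = df.drop(columns=[c for c in df.columns if c.lower() == "description"])
    df.index.name = None
    if df.shape != (nrow, ncol):
        raise ParseError(f"{path}: GCT dimensions {df.shape} disagree with header {(nrow, ncol)}")
    return df.astype(float)


def write_gct(df: pd.DataFrame, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("#1.2\n")
        fh.write(f"{df.shape[0]}\t{df.shape[1]}\n")
        out = df.copy()
        out.insert(0, "Description", "na")
        out.to_csv(fh, sep="\t", index_label="NAME")


def read_matrix(path) -> pd.DataFrame:
    """Matrix loader: GCT if the extension is .gct, else TSV with gene first column.

    Missing values are rejected -- downstream correlation code assumes dense data.
    """
    path = Path(path)
    if path.suffix.lower() == ".gct":
        df = read_gct(path)
    else:
        df = pd.read_csv(path, sep="\t", comment="#", index_col=0).astype(float)
    if df.isna().any().any():
        raise SchemaError(f"{path}: matrix contains missing values; dense input required")
    if df.index.duplicated().any():
        raise SchemaError(f"{path}: duplicated gene ids")
    return df


# ---------------------------------------------------------------- gene sets

def read_gmt(path) -> dict[str, tuple[str, list[str]]]:
    """GMT -> ``term_id -> (description, [genes])``."""
    sets: dict[str, tuple[str, list[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields")
            term, desc, genes = fields[0], fields[1], [g for g in fields[2:] if g]
            if term in sets:
                raise ParseError(f"{path}:{lineno}: duplicate term id {term!r}")
            sets[term] = (desc, genes)
    return sets


def write_gmt(sets: Mapping[str, tuple[str, Iterable[str]]], path) -> None:
    with open(path, "w") as fh:
        for term, (desc, genes) in sets.items():
            fh.write("\t".join([term, desc, *genes]) + "\n")


# ---------------------------------------------------------------- chemistry

def read_fingerprints(path, hex_encoded: bool = False) -> pd.DataFrame:
    """Fingerprint TSV ``drug, bits`` -> drugs x bits 0/1 int DataFrame."""
    df = read_tsv(path, required=("drug", "bits"))
    rows, n_bits = [], None
    for lineno, (drug, bits) in enumerate(zip(df["drug"], df["bits"]), 2):
        if hex_encoded:
            vec = np.array(list(bin(int(bits, 16))[2:].zfill(len(bits) * 4)), dtype=int)
        else:
            if set(bits) - {"0", "1"}:
                raise ParseError(f"{path}:{lineno}: bits must be a 0/1 string")
            vec = np.array(list(bits), dtype=int)
        if n_bits is None:
            n_bits = len(vec)
        elif len(vec) != n_bits:
            raise SchemaError(f"{path}:{lineno}: fingerprint length {len(vec)} != {n_bits}")
        rows.append((drug, vec))
    return pd.DataFrame({d: v for d, v in rows}).T


def write_fingerprints(fps: pd.DataFrame, path) -> None:
    out = pd.DataFrame({
        "drug": fps.index,
        "bits": ["".join(map(str, row.astype(int))) for _, row in fps.iterrows()],
    })
    write_tsv(out, path)


def read_group_file(path) -> list[str]:
    with open(path) as fh:
        return [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]


def write_group_file(ids: Iterable[str], path) -> None:
    with open(path, "w") as fh:
        for i in ids:
            fh.write(f"{i}\n")
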