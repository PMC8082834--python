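"""Plain-text format readers and writers (BED, TSV matrices, chrom sizes).

All writes are atomic (temp file + rename) so an interrupted run never
leaves a truncated file that still parses.
"""

from __future__ import annotations

import contextlib
import hashlib
import os
import pathlib
import tempfile

import pandas as pd

__all__ = [
    "atomic_write",
    "read_bed",
    "write_bed",
    "read_matrix",
    "write_matrix",
    "read_chrom_sizes",
    "sha256_file",
    "parse_feature_id",
]

BED3 = ["chrom", "start", "end"]
BED6 = BED3 + ["name", "score", "strand"]


@contextlib.contextmanager
def atomic_write(path, mode: str = "w"):
    """Write to a temp file in the target directory, then rename into place."""
    path = pathlib.Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, mode) as fh:
            yield fh
        os.replace(tmp, path)
    except BaseException:
        with contextlib.suppress(OSError):
            os.unlink(tmp)
        raise


def read_bed(path, expected_columns: int | None = None) -> pd.DataFrame:
    """BED3/BED6 reader; skips track/browser/comment lines; 0-based half-open.

    Rows with end <= start raise with the offending line number.
    """
    rows = []
    ncols = None
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: fewer than 3 BED columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise ValueError(f"{path}:{ln}: non-integer coordinates") from None
            if end <= start:
                raise ValueError(f"{path}:{ln}: end <= start ({start}, {end})")
            ncols = min(len(parts), 6) if ncols is None else min(ncols, len(parts), 6)
            rows.append(parts[:6])
    if expected_columns not in (None, 3, 6):
        raise ValueError("expected_columns must be 3 or 6")
    ncols = ncols or (expected_columns or 3)
    if expected_columns and ncols < expected_columns:
        raise ValueError(f"{path}: expected {expected_columns} columns, found {ncols}")
    use = expected_columns or ncols
    cols = BED6[:use]
    df = pd.DataFrame([r[:use] for r in rows], columns=cols)
    if df.empty:
        df = pd.DataFrame(columns=cols)
    else:
        df["start"] = df["start"].astype(int)
        df["end"] = df["end"].astype(int)
        if "score" in df.columns:
            df["score"] = pd.to_numeric(df["score"], errors="coerce")
    return df


def write_bed(df: pd.DataFrame, path) -> None:
    cols = [c for c in BED6 if c in df.columns]
    with atomic_write(path) as fh:
        df[cols].to_csv(fh, sep="\t", index=False, header=False)


def read_matrix(path, counts: bool = True) -> pd.DataFrame:
    """Feature x sample TSV with a header row and feature ids in column 0."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any():
            feat = df.index[bad.argmax()]
            raise ValueError(f"{path}: non-numeric value at ({feat}, {col})")
        df[col] = vals
    if counts and not df.empty:
        arr = df.to_numpy()
        if not (arr == arr.astype("int64")).all() or (arr < 0).any():
            raise ValueError(f"{path}: counts must be non-negative integers")
        df = df.astype("int64")
    return df


def write_matrix(matrix: pd.DataFrame, path, index_label: str = "feature") -> None:
    with atomic_write(path) as fh:
        matrix.to_csv(fh, sep="\t", index_label=index_label)


def read_chrom_sizes(path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t")
    if not {"chrom", "size"} <= set(df.columns):
        df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"])
    return {str(c): int(s) for c, s in zip(df["chrom"], df["size"])}


def parse_feature_id(feature: str) -> tuple[str, int, int]:
    """'chr1:2000-4000' -> ('chr1', 2000, 4000)."""
    chrom, rest = feature.rsplit(":", 1)
    s, e = rest.split("-")
    return chrom, int(s), int(e)


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
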