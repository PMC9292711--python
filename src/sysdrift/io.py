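"""Plain-text serialization of systems, matrices and locus maps.

A *system file* holds the three named blocks::

    A:
    0 1
    -1 0
    B:
    1
    1
    C:
    1 0

Rows are whitespace- or comma-delimited; blank lines and ``#`` comments are
ignored.  Values are written with 17 significant digits, so a write/read
round trip is bit-exact for double precision.  Single matrices use the same
row format without headers.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .genetics import Locus, LocusMap
from .systems import LinearSystem

__all__ = [
    "read_system",
    "write_system",
    "read_matrix",
    "write_matrix",
    "read_locus_map",
    "write_locus_map",
    "ParseError",
]

FLOAT_FMT = "%.17g"


class ParseError(ValueError):
    """A malformed system/matrix/locus file; carries the offending line number."""

    def __init__(self, message: str, path=None, line: int | None = None):
        loc = f"{path}:{line}: " if line is not None else (f"{path}: " if path else "")
        super().__init__(f"{loc}{message}")
        self.line = line


def _parse_row(text: str, path, lineno: int) -> list[float]:
    parts = text.replace(",", " ").split()
    try:
        return [float(p) for p in parts]
    except ValueError as e:
        raise ParseError(f"could not parse matrix row: {e}", path, lineno) from None


def read_matrix(path) -> np.ndarray:
    """A delimited matrix: one row per line, comma or whitespace separated."""
    rows, widths = [], set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            row = _parse_row(line, path, lineno)
            rows.append(row)
            widths.add(len(row))
    if not rows:
        raise ParseError("file contains no matrix rows", path)
    if len(widths) > 1:
        raise ParseError(f"ragged rows: widths {sorted(widths)}", path)
    return np.array(rows)


def write_matrix(M: np.ndarray, path) -> None:
    M = np.atleast_2d(np.asarray(M, dtype=float))
    with open(path, "w") as fh:
        for row in M:
            fh.write(" ".join(FLOAT_FMT % v for v in row) + "\n")


def _parse_blocks(path):
    blocks: dict[str, list[list[float]]] = {}
    current = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if line.endswith(":") and line[:-1].strip() in ("A", "B", "C"):
                current = line[:-1].strip()
                if current in blocks:
                    raise ParseError(f"duplicate block {current!r}", path, lineno)
                blocks[current] = []
                continue
            if current is None:
                raise ParseError("matrix row before any block header", path, lineno)
            blocks[current].append(_parse_row(line, path, lineno))
    for name, rows in blocks.items():
        if not rows:
            raise ParseError(f"block {name!r} is empty", path)
        if len({len(r) for r in rows}) > 1:
            raise ParseError(f"ragged rows in block {name!r}", path)
    return blocks


def read_system(path) -> LinearSystem:
    """Read an (A, B, C) triple from a named-block system file."""
    blocks = _parse_blocks(path)
    missing = [name for name in ("A", "B", "C") if name not in blocks]
    if missing:
        raise ParseError(f"missing block(s): {', '.join(missing)}", path)
    return LinearSystem(
        np.array(blocks["A"]), np.array(blocks["B"]), np.array(blocks["C"])
    )


def write_system(sys: LinearSystem, path) -> None:
    """Write a system file; round-trips bit-exactly through read_system."""
    with open(path, "w") as fh:
        for name, M in (("A", sys.A), ("B", sys.B), ("C", sys.C)):
            fh.write(f"{name}:\n")
            for row in np.atleast_2d(M):
                fh.write(" ".join(FLOAT_FMT % v for v in row) + "\n")


def write_locus_map(lmap: LocusMap, path) -> None:
    """TSV with columns locus, matrix, row, col, chromosome (1-based indices);
    multi-coefficient loci span several lines sharing the locus name.  A
    header comment records the system dimensions."""
    with open(path, "w") as fh:
        fh.write(f"# dims n={lmap.n} m={lmap.m} l={lmap.l}\n")
        fh.write("locus\tmatrix\trow\tcol\tchromosome\n")
        for locus in lmap.loci:
            for tag, i, j in locus.addresses:
                fh.write(f"{locus.name}\t{tag}\t{i + 1}\t{j + 1}\t{locus.chromosome}\n")


def read_locus_map(path) -> LocusMap:
    dims = None
    records: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if line.startswith("# dims"):
                try:
                    kv = dict(tok.split("=") for tok in line[6:].split())
                    dims = (int(kv["n"]), int(kv["m"]), int(kv["l"]))
                except Exception:
                    raise ParseError("malformed dims header", path, lineno) from None
                continue
            if not line or line.startswith("#") or line.startswith("locus\t"):
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise ParseError(f"expected 5 tab-separated fields, got {len(parts)}", path, lineno)
            name, tag, i, j, chrom = parts
            try:
                addr = (tag, int(i) - 1, int(j) - 1)
            except ValueError:
                raise ParseError("row/col must be integers", path, lineno) from None
            rec = records.setdefault(name, {"addresses": [], "chromosome": chrom})
            if rec["chromosome"] != chrom:
                raise ParseError(f"locus {name!r} listed on multiple chromosomes", path, lineno)
            rec["addresses"].append(addr)
            if name not in order:
                order.append(name)
    if dims is None:
        raise ParseError("missing '# dims n=.. m=.. l=..' header", path)
    if not records:
        raise ParseError("no locus records found", path)
    loci = tuple(
        Locus(name, tuple(records[name]["addresses"]), records[name]["chromosome"])
        for name in order
    )
    return LocusMap(loci=loci, n=dims[0], m=dims[1], l=dims[2])
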