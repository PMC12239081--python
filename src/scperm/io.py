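"""Readers and writers for the text formats the pipeline touches.

Supported inputs are two-column (or wider) XVG force tables in the GROMACS
dialect ('#' comments, '@' plot metadata) and fixed-column GRO coordinate
frames.  All tabular outputs go through :func:`write_table`, which pairs a
TSV with a sidecar JSON of metadata so every artifact records its units,
grid and provenance.

Internal units are fixed at nm / ps / kJ/mol; any conversion happens here
and nowhere else.
"""
from __future__ import annotations

import io as _io
import json
import re
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import Snapshot, Trajectory
from .errors import (
    EmptyInputError,
    FormatError,
    ParseError,
    SelectionSyntaxError,
)

__all__ = [
    "read_xvg",
    "write_xvg",
    "read_gro",
    "read_gro_frames",
    "write_gro",
    "select_atoms",
    "write_table",
    "read_table",
    "load_trajectory",
]

_LEGEND_RE = re.compile(r'@\s*s(\d+)\s+legend\s+"([^"]*)"')


# ----------------------------------------------------------------------
# XVG
# ----------------------------------------------------------------------
def read_xvg(path) -> pd.DataFrame:
    """Read an XVG table into a DataFrame.

    Lines starting with ``#`` or ``@`` are metadata and skipped; everything
    else must be whitespace-separated numbers with a constant column count.
    The first column is named ``time``; further columns take names from
    ``@ sN legend`` metadata when available, else ``f0``, ``f1``, ...

    Raises
    ------
    ParseError
        On a ragged or non-numeric data row (the message names the line).
    EmptyInputError
        If the file contains no data rows at all.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    legends: dict[int, str] = {}
    data: list[tuple[int, str]] = []
    for lineno, line in enumerate(lines, start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith("@"):
            m = _LEGEND_RE.match(stripped)
            if m:
                legends[int(m.group(1))] = m.group(2)
            continue
        if stripped.startswith("#"):
            continue
        data.append((lineno, stripped))
    if not data:
        raise EmptyInputError(f"{path}: no data rows (metadata only)")

    try:
        arr = np.loadtxt(_io.StringIO("\n".join(s for _, s in data)), ndmin=2)
    except ValueError:
        ncols = len(data[0][1].split())
        for lineno, s in data:
            parts = s.split()
            if len(parts) != ncols:
                raise ParseError(
                    f"{path}: line {lineno}: expected {ncols} fields, got {len(parts)}"
                ) from None
            for p in parts:
                try:
                    float(p)
                except ValueError:
                    raise ParseError(
                        f"{path}: line {lineno}: non-numeric field {p!r}"
                    ) from None
        raise  # unreachable in practice; loadtxt failure implies one of the above

    if arr.shape[0] != len(data):  # pragma: no cover - defensive
        raise ParseError(f"{path}: parsed {arr.shape[0]} rows, file has {len(data)}")

    ncols = arr.shape[1]
    names = ["time"]
    for j in range(1, ncols):
        names.append(legends.get(j - 1, f"f{j - 1}"))
    return pd.DataFrame(arr, columns=names)


def write_xvg(path, times, columns: Mapping[str, Sequence[float]], *,
              title: str = "", xaxis: str = "Time (ps)",
              yaxis: str = "Force (kJ/mol/nm)",
              comments: Sequence[str] = ()) -> None:
    """Write a pull-force style XVG file (full float precision)."""
    path = Path(path)
    times = np.asarray(times, dtype=float)
    cols = {k: np.asarray(v, dtype=float) for k, v in columns.items()}
    for k, v in cols.items():
        if len(v) != len(times):
            raise ValueError(f"column {k!r} length {len(v)} != {len(times)} times")
    with path.open("w") as fh:
        for c in comments:
            fh.write(f"# {c}\n")
        if title:
            fh.write(f'@    title "{title}"\n')
        fh.write(f'@    xaxis  label "{xaxis}"\n')
        fh.write(f'@    yaxis  label "{yaxis}"\n')
        for j, name in enumerate(cols):
            fh.write(f'@ s{j} legend "{name}"\n')
        block = np.column_stack([times, *cols.values()])
        np.savetxt(fh, block, fmt="%.17g")


# ----------------------------------------------------------------------
# GRO
# ----------------------------------------------------------------------
_TIME_RE = re.compile(r"\bt=\s*([-+0-9.eE]+)")


def _parse_gro_frame(lines: list[str], start: int, path) -> tuple[Snapshot, int]:
    """Parse one frame starting at ``lines[start]``; return (snapshot, next)."""
    if start + 2 > len(lines):
        raise FormatError(f"{path}: truncated frame header at line {start + 1}")
    title = lines[start]
    m = _TIME_RE.search(title)
    time = float(m.group(1)) if m else 0.0
    try:
        n_atoms = int(lines[start + 1].strip())
    except ValueError:
        raise FormatError(
            f"{path}: line {start + 2}: atom count is not an integer"
        ) from None
    if n_atoms <= 0:
        raise FormatError(f"{path}: line {start + 2}: nonpositive atom count")
    box_line = start + 2 + n_atoms
    if box_line >= len(lines):
        raise FormatError(
            f"{path}: header claims {n_atoms} atoms but only "
            f"{len(lines) - start - 2} atom/box lines follow"
        )
    resids = np.empty(n_atoms, dtype=int)
    resnames = np.empty(n_atoms, dtype="U5")
    names = np.empty(n_atoms, dtype="U5")
    pos = np.empty((n_atoms, 3), dtype=float)
    for i in range(n_atoms):
        line = lines[start + 2 + i]
        lineno = start + 3 + i
        if len(line) < 44:
            raise FormatError(f"{path}: line {lineno}: atom line too short")
        try:
            resids[i] = int(line[0:5])
            resnames[i] = line[5:10].strip()
            names[i] = line[10:15].strip()
            pos[i, 0] = float(line[20:28])
            pos[i, 1] = float(line[28:36])
            pos[i, 2] = float(line[36:44])
        except ValueError:
            raise FormatError(
                f"{path}: line {lineno}: malformed atom record "
                f"(atom count in header may be wrong)"
            ) from None
        # velocity fields (columns 44-68), if present, are parsed and dropped
    try:
        box_fields = [float(x) for x in lines[box_line].split()]
    except ValueError:
        raise FormatError(f"{path}: line {box_line + 1}: malformed box line") from None
    if len(box_fields) not in (3, 9):
        raise FormatError(
            f"{path}: line {box_line + 1}: box line must have 3 or 9 fields"
        )
    if len(box_fields) == 9 and any(abs(v) > 1e-12 for v in box_fields[3:]):
        raise FormatError(f"{path}: only orthorhombic boxes are supported")
    snap = Snapshot(
        resids=resids, resnames=resnames, names=names,
        positions=pos, box=np.array(box_fields[:3]), time=time,
    )
    return snap, box_line + 1


def read_gro(path) -> Snapshot:
    """Read the first frame of a GRO file."""
    path = Path(path)
    lines = path.read_text().splitlines()
    snap, _ = _parse_gro_frame(lines, 0, path)
    return snap


def read_gro_frames(path) -> Trajectory:
    """Read all concatenated frames of a (multi-frame) GRO file."""
    path = Path(path)
    lines = path.read_text().splitlines()
    frames = []
    cursor = 0
    while cursor < len(lines):
        if not lines[cursor].strip() and cursor == len(lines) - 1:
            break
        snap, cursor = _parse_gro_frame(lines, cursor, path)
        frames.append(snap)
    return Trajectory(frames)


def write_gro(obj, path, *, title: str = "scperm frame") -> None:
    """Write a Snapshot or Trajectory as (multi-frame) GRO, 3-decimal nm."""
    path = Path(path)
    frames = obj.frames if isinstance(obj, Trajectory) else [obj]
    with path.open("w") as fh:
        for snap in frames:
            fh.write(f"{title} t= {snap.time:.5f}\n")
            fh.write(f"{snap.n_atoms:5d}\n")
            for i in range(snap.n_atoms):
                fh.write(
                    "%5d%-5s%5s%5d%8.3f%8.3f%8.3f\n"
                    % (
                        int(snap.resids[i]) % 100000,
                        snap.resnames[i],
                        snap.names[i],
                        (i + 1) % 100000,
                        snap.positions[i, 0],
                        snap.positions[i, 1],
                        snap.positions[i, 2],
                    )
                )
            fh.write("%10.5f%10.5f%10.5f\n" % tuple(snap.box))


# ----------------------------------------------------------------------
# Atom selections
# ----------------------------------------------------------------------
# Mini-language: `resname`/`name` equality terms (one or more values each)
# combined with and / or / not and parentheses, e.g.
#   "resname CER and name N"     "not (name H1 or name H2)"     "all"
_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


class _SelParser:
    def __init__(self, expr: str, snapshot: Snapshot):
        self.expr = expr
        self.snapshot = snapshot
        self.tokens = [(m.group(0), m.start()) for m in _TOKEN_RE.finditer(expr)]
        self.pos = 0

    def peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else (None, len(self.expr))

    def next(self):
        tok = self.peek()
        self.pos += 1
        return tok

    def parse(self) -> np.ndarray:
        if not self.tokens:
            raise SelectionSyntaxError("empty selection", 0)
        mask = self.or_expr()
        tok, at = self.peek()
        if tok is not None:
            raise SelectionSyntaxError(f"unexpected token {tok!r}", at)
        return mask

    def or_expr(self) -> np.ndarray:
        mask = self.and_expr()
        while self.peek()[0] == "or":
            self.next()
            mask = mask | self.and_expr()
        return mask

    def and_expr(self) -> np.ndarray:
        mask = self.unary()
        while self.peek()[0] == "and":
            self.next()
            mask = mask & self.unary()
        return mask

    def unary(self) -> np.ndarray:
        tok, _ = self.peek()
        if tok == "not":
            self.next()
            return ~self.unary()
        return self.primary()

    def primary(self) -> np.ndarray:
        tok, at = self.next()
        if tok is None:
            raise SelectionSyntaxError("unexpected end of expression", at)
        if tok == "(":
            mask = self.or_expr()
            closer, cat = self.next()
            if closer != ")":
                raise SelectionSyntaxError("expected ')'", cat)
            return mask
        if tok == "all":
            return np.ones(self.snapshot.n_atoms, dtype=bool)
        if tok in ("resname", "name"):
            values = []
            while True:
                nxt, _ = self.peek()
                if nxt is None or nxt in ("and", "or", "not", ")", "(", "resname", "name", "all"):
                    break
                values.append(self.next()[0])
            if not values:
                raise SelectionSyntaxError(f"{tok} requires at least one value", at)
            field = self.snapshot.resnames if tok == "resname" else self.snapshot.names
            return np.isin(field, values)
        raise SelectionSyntaxError(f"unknown keyword {tok!r}", at)


def select_atoms(snapshot: Snapshot, expr: str) -> np.ndarray:
    """Evaluate a selection expression; return sorted atom indices.

    An expression matching nothing returns an empty index array (not an
    error); a malformed expression raises :class:`SelectionSyntaxError`
    carrying the character position of the problem.
    """
    mask = _SelParser(expr, snapshot).parse()
    return np.flatnonzero(mask)


# ----------------------------------------------------------------------
# Tabular outputs (TSV + sidecar metadata JSON)
# ----------------------------------------------------------------------
def _meta_path(path: Path) -> Path:
    return path.with_name(path.name + ".meta.json")


def write_table(df: pd.DataFrame, path, metadata: Mapping | None = None) -> None:
    """Write a DataFrame as TSV (one header line, full float precision so
    re-reading reproduces values exactly) plus a ``<name>.meta.json`` sidecar
    of units/grid/provenance metadata."""
    path = Path(path)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g", lineterminator="\n")
    if metadata is not None:
        _meta_path(path).write_text(json.dumps(dict(metadata), indent=2, sort_keys=True) + "\n")


def read_table(path) -> tuple[pd.DataFrame, dict | None]:
    """Read a TSV written by :func:`write_table` and its sidecar, if any."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    meta = None
    mp = _meta_path(path)
    if mp.exists():
        meta = json.loads(mp.read_text())
    return df, meta


# ----------------------------------------------------------------------
# Trajectory import through an established reader
# ----------------------------------------------------------------------
def load_trajectory(topology, trajectory=None) -> Trajectory:
    """Load coordinate frames via MDAnalysis (XTC/TRR/GRO/...).

    Converts positions and box lengths from Å to nm and returns the
    package's plain :class:`Trajectory`.  Requires the optional
    ``MDAnalysis`` dependency; only orthorhombic boxes are accepted.
    """
    import MDAnalysis as mda  # deferred: optional heavy dependency

    args = (str(topology),) if trajectory is None else (str(topology), str(trajectory))
    u = mda.Universe(*args)
    frames = []
    for ts in u.trajectory:
        dims = ts.dimensions
        if dims is None or not np.allclose(dims[3:6], 90.0, atol=1e-3):
            raise FormatError("only orthorhombic boxes are supported")
        frames.append(
            Snapshot(
                resids=u.atoms.resids,
                resnames=u.atoms.resnames,
                names=u.atoms.names,
                positions=u.atoms.positions / 10.0,
                box=np.asarray(dims[:3], dtype=float) / 10.0,
                time=float(ts.time),
            )
        )
    return Trajectory(frames)
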