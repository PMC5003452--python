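"""Affymetrix-style CEL/CDF input and output.

Supports the text CEL dialect (version 3), the little-endian binary CEL
dialect (version 4), and the text CDF dialect.  Cell coordinates ``(x, y)``
are 0-based column/row indices.  A probe cell is classified as perfect
match (PM) when ``PBASE != TBASE`` and as mismatch (MM) otherwise.

PM probes are identified by the string ``"<setid>_<x>_<y>"`` built from the
raw cell coordinates.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from probekit.errors import FormatError

__all__ = [
    "ProbePair",
    "ProbeSet",
    "ChipLayout",
    "IntensityArray",
    "ProbeMatrix",
    "read_cel_text",
    "write_cel_text",
    "read_cel_binary",
    "write_cel_binary",
    "read_cdf_text",
    "write_cdf_text",
    "write_masked_cdf",
    "extract_pm",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProbePair:
    """A PM cell and its optional MM partner, as (col, row) coordinates."""

    pm_xy: tuple[int, int]
    mm_xy: tuple[int, int] | None = None


@dataclass
class ProbeSet:
    id: str
    pairs: list[ProbePair]

    def __len__(self) -> int:  # number of probe pairs
        return len(self.pairs)


@dataclass
class ChipLayout:
    """Probe-set -> probe-pair map of one chip type."""

    chip_name: str
    n_rows: int
    n_cols: int
    probe_sets: list[ProbeSet]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise FormatError("chip dimensions must be positive")
        seen_pm: set[tuple[int, int]] = set()
        for ps in self.probe_sets:
            if not ps.pairs:
                raise FormatError(f"probe-set {ps.id!r} has no probe pairs")
            for pair in ps.pairs:
                for xy in (pair.pm_xy, pair.mm_xy):
                    if xy is None:
                        continue
                    x, y = xy
                    if not (0 <= x < self.n_cols and 0 <= y < self.n_rows):
                        raise FormatError(
                            f"cell ({x},{y}) of probe-set {ps.id!r} outside "
                            f"{self.n_cols}x{self.n_rows} grid"
                        )
                if pair.pm_xy in seen_pm:
                    raise FormatError(
                        f"PM cell {pair.pm_xy} used twice (probe-set {ps.id!r})"
                    )
                seen_pm.add(pair.pm_xy)

    @property
    def n_sets(self) -> int:
        return len(self.probe_sets)

    @property
    def n_pairs(self) -> int:
        return sum(len(ps) for ps in self.probe_sets)

    def iter_pairs(self) -> Iterable[tuple[ProbeSet, ProbePair]]:
        """Pairs in canonical order: CDF probe-set order, then pair order."""
        for ps in self.probe_sets:
            for pair in ps.pairs:
                yield ps, pair

    def pm_probe_ids(self) -> list[str]:
        return [
            f"{ps.id}_{pair.pm_xy[0]}_{pair.pm_xy[1]}"
            for ps, pair in self.iter_pairs()
        ]

    def set_ids_per_pair(self) -> list[str]:
        return [ps.id for ps, _ in self.iter_pairs()]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ChipLayout):
            return NotImplemented
        return (
            self.chip_name == other.chip_name
            and self.n_rows == other.n_rows
            and self.n_cols == other.n_cols
            and self.probe_sets == other.probe_sets
        )


@dataclass
class IntensityArray:
    """Per-cell fluorescence of one hybridised chip.

    ``values`` is indexed ``[row, col]`` i.e. ``values[y, x]``.
    """

    chip_id: str
    n_rows: int
    n_cols: int
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.n_rows, self.n_cols):
            raise FormatError(
                f"chip {self.chip_id!r}: value grid {self.values.shape} does "
                f"not match declared {self.n_rows}x{self.n_cols}"
            )
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise FormatError(
                f"chip {self.chip_id!r}: intensities must be finite and >= 0"
            )

    def value_at(self, x: int, y: int) -> float:
        return float(self.values[y, x])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntensityArray):
            return NotImplemented
        return (
            self.chip_id == other.chip_id
            and self.n_rows == other.n_rows
            and self.n_cols == other.n_cols
            and np.array_equal(self.values, other.values)
        )


@dataclass
class ProbeMatrix:
    """PM intensities arranged probes x chips in canonical probe order."""

    probe_ids: list[str]
    chip_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.probe_ids), len(self.chip_ids)):
            raise FormatError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.probe_ids)} probes x {len(self.chip_ids)} chips"
            )

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def n_chips(self) -> int:
        return len(self.chip_ids)

    def set_ids(self) -> list[str]:
        """Probe-set id of each row, parsed from ``<setid>_<x>_<y>``."""
        return [pid.rsplit("_", 2)[0] for pid in self.probe_ids]

    def with_values(self, values: np.ndarray) -> "ProbeMatrix":
        return ProbeMatrix(list(self.probe_ids), list(self.chip_ids), values)

    # -- TSV round trip -----------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("probe_id\t" + "\t".join(self.chip_ids) + "\n")
            for pid, row in zip(self.probe_ids, self.values):
                fh.write(pid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ProbeMatrix":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if not header or header[0] != "probe_id":
                raise FormatError(f"{path}: expected 'probe_id' header column")
            chip_ids = header[1:]
            probe_ids: list[str] = []
            rows: list[list[float]] = []
            for lineno, line in enumerate(fh, start=2):
                parts = line.rstrip("\n").split("\t")
                if len(parts) != len(header):
                    raise FormatError(f"{path}:{lineno}: wrong column count")
                probe_ids.append(parts[0])
                rows.append([float(v) for v in parts[1:]])
        return cls(probe_ids, chip_ids, np.asarray(rows, dtype=float))


# ---------------------------------------------------------------------------
# CEL version 3 (text)
# ---------------------------------------------------------------------------

def _parse_sections(lines: Sequence[str], path: str) -> dict[str, list[tuple[int, str]]]:
    """Split an INI-style file into sections keeping line numbers."""
    sections: dict[str, list[tuple[int, str]]] = {}
    current: list[tuple[int, str]] | None = None
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        stripped = line.strip()
        if stripped.startswith("[") and stripped.endswith("]"):
            name = stripped[1:-1]
            current = sections.setdefault(name, [])
            continue
        if current is not None and stripped:
            current.append((lineno, line))
    return sections


def _section_keyvals(body: list[tuple[int, str]]) -> dict[str, str]:
    out: dict[str, str] = {}
    for _, line in body:
        if "=" in line:
            key, _, val = line.partition("=")
            out[key.strip()] = val.strip()
    return out


def read_cel_text(path: str | Path) -> IntensityArray:
    """Read a version-3 text CEL file; the MEAN column becomes the value."""
    path = Path(path)
    lines = path.read_text().splitlines()
    sections = _parse_sections(lines, str(path))
    if "CEL" not in sections:
        raise FormatError(f"{path}: missing [CEL] section")
    cel_kv = _section_keyvals(sections["CEL"])
    if cel_kv.get("Version") != "3":
        raise FormatError(
            f"{path}: unsupported CEL version {cel_kv.get('Version')!r} "
            "(only text version 3 is supported here)"
        )
    if "HEADER" not in sections:
        raise FormatError(f"{path}: missing [HEADER] section")
    head = _section_keyvals(sections["HEADER"])
    try:
        n_cols = int(head["Cols"])
        n_rows = int(head["Rows"])
    except (KeyError, ValueError) as exc:
        raise FormatError(f"{path}: [HEADER] must declare integer Cols/Rows") from exc
    if "INTENSITY" not in sections:
        raise FormatError(f"{path}: missing [INTENSITY] section")

    body = sections["INTENSITY"]
    kv = _section_keyvals(body)
    declared = int(kv.get("NumberCells", n_rows * n_cols))
    grid = np.full((n_rows, n_cols), np.nan)
    n_seen = 0
    for lineno, line in body:
        stripped = line.strip()
        if "=" in stripped and not stripped[0].isdigit() and not stripped[0] == "-":
            continue  # NumberCells= / CellHeader= rows
        parts = stripped.split()
        if len(parts) < 3:
            raise FormatError(f"{path}:{lineno}: malformed intensity row")
        try:
            x, y = int(parts[0]), int(parts[1])
            mean = float(parts[2])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: malformed intensity row") from exc
        if x < 0 or y < 0 or x >= n_cols or y >= n_rows:
            raise FormatError(f"{path}:{lineno}: cell ({x},{y}) outside grid")
        if not np.isnan(grid[y, x]):
            raise FormatError(f"{path}:{lineno}: duplicate cell ({x},{y})")
        grid[y, x] = mean
        n_seen += 1
    if n_seen != declared or n_seen != n_rows * n_cols:
        raise FormatError(
            f"{path}: expected {n_rows * n_cols} cells "
            f"(declared {declared}), found {n_seen}"
        )
    return IntensityArray(path.stem, n_rows, n_cols, grid)


def write_cel_text(array: IntensityArray, path: str | Path) -> None:
    """Write a version-3 text CEL file (STDV/NPIXELS filled with stubs)."""
    with open(path, "w") as fh:
        fh.write("[CEL]\nVersion=3\n\n")
        fh.write(
            f"[HEADER]\nCols={array.n_cols}\nRows={array.n_rows}\n"
            f"TotalX={array.n_cols}\nTotalY={array.n_rows}\n\n"
        )
        fh.write("[INTENSITY]\n")
        fh.write(f"NumberCells={array.n_rows * array.n_cols}\n")
        fh.write("CellHeader=X\tY\tMEAN\tSTDV\tNPIXELS\n")
        for y in range(array.n_rows):
            for x in range(array.n_cols):
                fh.write(f"{x:3d}\t{y:3d}\t{float(array.values[y, x])!r}\t0.0\t9\n")
        fh.write("\n[MASKS]\nNumberCells=0\nCellHeader=X\tY\n\n")
        fh.write("[OUTLIERS]\nNumberCells=0\nCellHeader=X\tY\n\n")
        fh.write("[MODIFIED]\nNumberCells=0\nCellHeader=X\tY\tORIGMEAN\n")


# ---------------------------------------------------------------------------
# CEL version 4 (binary, little-endian)
# ---------------------------------------------------------------------------

_CEL4_MAGIC = 64
_CEL4_VERSION = 4


def read_cel_binary(path: str | Path) -> IntensityArray:
    """Read a version-4 little-endian binary CEL file."""
    path = Path(path)
    data = path.read_bytes()
    if len(data) < 24:
        raise FormatError(f"{path}: truncated or empty binary CEL file")
    magic, version, n_cols, n_rows, n_cells = struct.unpack_from("<5i", data, 0)
    if magic != _CEL4_MAGIC:
        raise FormatError(f"{path}: bad magic {magic} (expected {_CEL4_MAGIC})")
    if version != _CEL4_VERSION:
        raise FormatError(f"{path}: unsupported binary CEL version {version}")
    if n_cells != n_rows * n_cols:
        raise FormatError(
            f"{path}: cell count {n_cells} != {n_rows}x{n_cols} grid"
        )
    offset = 20
    # three length-prefixed strings: header, algorithm, algorithm parameters
    for _ in range(3):
        (slen,) = struct.unpack_from("<i", data, offset)
        offset += 4 + slen
    offset += 4  # cell margin
    n_outliers, n_masked, n_subgrids = struct.unpack_from("<IIi", data, offset)
    offset += 12
    need = offset + n_cells * 10
    if len(data) < need:
        raise FormatError(f"{path}: truncated intensity block")
    raw = np.frombuffer(
        data,
        dtype=np.dtype([("mean", "<f4"), ("stdv", "<f4"), ("npix", "<i2")]),
        count=n_cells,
        offset=offset,
    )
    grid = raw["mean"].astype(float).reshape(n_rows, n_cols)
    return IntensityArray(path.stem, n_rows, n_cols, grid)


def write_cel_binary(array: IntensityArray, path: str | Path) -> None:
    """Write a version-4 little-endian binary CEL file.

    Values are stored as float32, so a text->binary->text round trip is exact
    only for float32-representable intensities.
    """
    n_cells = array.n_rows * array.n_cols
    header = (
        f"Cols={array.n_cols}\nRows={array.n_rows}\n".encode()
    )
    alg = b"Percentile"
    params = b""
    with open(path, "wb") as fh:
        fh.write(struct.pack("<5i", _CEL4_MAGIC, _CEL4_VERSION,
                             array.n_cols, array.n_rows, n_cells))
        for blob in (header, alg, params):
            fh.write(struct.pack("<i", len(blob)))
            fh.write(blob)
        fh.write(struct.pack("<i", 2))  # cell margin
        fh.write(struct.pack("<IIi", 0, 0, 0))
        cells = np.empty(
            n_cells,
            dtype=np.dtype([("mean", "<f4"), ("stdv", "<f4"), ("npix", "<i2")]),
        )
        cells["mean"] = array.values.reshape(-1)
        cells["stdv"] = 0.0
        cells["npix"] = 9
        fh.write(cells.tobytes())


# ---------------------------------------------------------------------------
# CDF (text)
# ---------------------------------------------------------------------------

def read_cdf_text(path: str | Path) -> ChipLayout:
    """Read a text CDF file into a :class:`ChipLayout`.

    Cells are grouped into probe pairs by their EXPOS value within each unit
    block; pairs are ordered by EXPOS.  A cell is PM iff PBASE != TBASE.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    sections = _parse_sections(lines, str(path))
    if "CDF" not in sections:
        raise FormatError(f"{path}: missing [CDF] section")
    if "Chip" not in sections:
        raise FormatError(f"{path}: missing [Chip] section")
    chip_kv = _section_keyvals(sections["Chip"])
    try:
        n_rows = int(chip_kv["Rows"])
        n_cols = int(chip_kv["Cols"])
        n_units = int(chip_kv["NumberOfUnits"])
    except (KeyError, ValueError) as exc:
        raise FormatError(
            f"{path}: [Chip] must declare integer Rows/Cols/NumberOfUnits"
        ) from exc
    chip_name = chip_kv.get("Name", path.stem)

    probe_sets: list[ProbeSet] = []
    for unit_no in range(1, n_units + 1):
        unit_name = f"Unit{unit_no}"
        block_names = sorted(
            (s for s in sections if s.startswith(unit_name + "_Block")),
            key=lambda s: int(s.rsplit("Block", 1)[1]),
        )
        if not block_names:
            raise FormatError(f"{path}: missing blocks for [{unit_name}]")
        for block_name in block_names:
            body = sections[block_name]
            kv = _section_keyvals(body)
            set_id = kv.get("Name", block_name)
            header_cols: list[str] | None = None
            # expos -> {"PM": (x,y), "MM": (x,y)}
            atoms: dict[int, dict[str, tuple[int, int]]] = {}
            for lineno, line in body:
                stripped = line.strip()
                if stripped.startswith("CellHeader="):
                    header_cols = stripped[len("CellHeader="):].split("\t")
                    continue
                if not stripped.startswith("Cell") or "=" not in stripped:
                    continue
                if header_cols is None:
                    raise FormatError(
                        f"{path}:{lineno}: cell row before CellHeader"
                    )
                fields = stripped.split("=", 1)[1].split("\t")
                if len(fields) < len(header_cols):
                    raise FormatError(f"{path}:{lineno}: short cell row")
                rec = dict(zip(header_cols, fields))
                try:
                    x = int(rec["X"])
                    y = int(rec["Y"])
                    expos = int(rec["EXPOS"])
                    pbase = rec["PBASE"].upper()
                    tbase = rec["TBASE"].upper()
                except (KeyError, ValueError) as exc:
                    raise FormatError(
                        f"{path}:{lineno}: cell row missing X/Y/EXPOS/PBASE/TBASE"
                    ) from exc
                if not (0 <= x < n_cols and 0 <= y < n_rows):
                    raise FormatError(
                        f"{path}:{lineno}: cell ({x},{y}) outside grid"
                    )
                kind = "PM" if pbase != tbase else "MM"
                atoms.setdefault(expos, {})[kind] = (x, y)
            if not atoms:
                raise FormatError(
                    f"{path}: unit block [{block_name}] declares no cells"
                )
            pairs = []
            for expos in sorted(atoms):
                cells = atoms[expos]
                if "PM" not in cells:
                    raise FormatError(
                        f"{path}: [{block_name}] EXPOS {expos} has no PM cell"
                    )
                pairs.append(ProbePair(cells["PM"], cells.get("MM")))
            declared_atoms = kv.get("NumAtoms")
            if declared_atoms is not None and int(declared_atoms) != len(pairs):
                raise FormatError(
                    f"{path}: [{block_name}] declares NumAtoms={declared_atoms} "
                    f"but has {len(pairs)} pairs"
                )
            probe_sets.append(ProbeSet(set_id, pairs))
    return ChipLayout(chip_name, n_rows, n_cols, probe_sets)


def write_cdf_text(layout: ChipLayout, path: str | Path) -> None:
    """Write a :class:`ChipLayout` as a text CDF file."""
    with open(path, "w") as fh:
        fh.write("[CDF]\nVersion=GC3.0\n\n")
        fh.write(
            f"[Chip]\nName={layout.chip_name}\nRows={layout.n_rows}\n"
            f"Cols={layout.n_cols}\nNumberOfUnits={layout.n_sets}\n"
            f"MaxUnit={layout.n_sets}\nNumQCUnits=0\n\n"
        )
        for unit_no, ps in enumerate(layout.probe_sets, start=1):
            n_cells = sum(2 if p.mm_xy is not None else 1 for p in ps.pairs)
            fh.write(
                f"[Unit{unit_no}]\nName={ps.id}\nDirection=1\n"
                f"NumAtoms={len(ps.pairs)}\nNumCells={n_cells}\n"
                f"UnitNumber={unit_no}\nUnitType=3\nNumberBlocks=1\n\n"
            )
            fh.write(
                f"[Unit{unit_no}_Block1]\nName={ps.id}\nBlockNumber=1\n"
                f"NumAtoms={len(ps.pairs)}\nNumCells={n_cells}\n"
                f"StartPosition=0\nStopPosition={len(ps.pairs) - 1}\n"
            )
            fh.write(
                "CellHeader=X\tY\tPROBE\tFEAT\tQUAL\tEXPOS\tPOS\tCBASE\t"
                "PBASE\tTBASE\tATOM\tINDEX\n"
            )
            cell_no = 1
            for expos, pair in enumerate(ps.pairs):
                x, y = pair.pm_xy
                index = y * layout.n_cols + x + 1
                fh.write(
                    f"Cell{cell_no}={x}\t{y}\tN\tcontrol\t{ps.id}\t{expos}\t"
                    f"13\tC\tC\tG\t{expos}\t{index}\n"
                )
                cell_no += 1
                if pair.mm_xy is not None:
                    mx, my = pair.mm_xy
                    mindex = my * layout.n_cols + mx + 1
                    fh.write(
                        f"Cell{cell_no}={mx}\t{my}\tN\tcontrol\t{ps.id}\t"
                        f"{expos}\t13\tC\tG\tG\t{expos}\t{mindex}\n"
                    )
                    cell_no += 1
            fh.write("\n")


def write_masked_cdf(
    layout: ChipLayout,
    retained: Sequence[bool] | np.ndarray,
    path: str | Path,
) -> ChipLayout:
    """Write a masked CDF keeping only flagged probe pairs.

    ``retained`` is aligned to the canonical pair order of ``layout``.  A
    probe-set is dropped only when none of its pairs are retained.  Returns
    the masked in-memory layout that was written.
    """
    retained = np.asarray(retained, dtype=bool)
    if retained.shape != (layout.n_pairs,):
        raise FormatError(
            f"expected {layout.n_pairs} retention flags, got {retained.shape}"
        )
    masked_sets: list[ProbeSet] = []
    pos = 0
    for ps in layout.probe_sets:
        kept = [
            pair for pair, flag in zip(ps.pairs, retained[pos:pos + len(ps)])
            if flag
        ]
        pos += len(ps)
        if kept:
            masked_sets.append(ProbeSet(ps.id, kept))
    masked = ChipLayout(layout.chip_name, layout.n_rows, layout.n_cols,
                        masked_sets)
    write_cdf_text(masked, path)
    return masked


# ---------------------------------------------------------------------------
# PM extraction
# ---------------------------------------------------------------------------

def extract_pm(
    layout: ChipLayout,
    arrays: Sequence[IntensityArray],
    include_mm: bool = False,
) -> ProbeMatrix:
    """Collect PM intensities into a probes x chips matrix.

    MM rows can be appended with ``include_mm=True`` (ids suffixed ``_mm``);
    all downstream analysis uses PM rows only.
    """
    if not arrays:
        raise FormatError("extract_pm requires at least one intensity array")
    for arr in arrays:
        if (arr.n_rows, arr.n_cols) != (layout.n_rows, layout.n_cols):
            raise FormatError(
                f"chip {arr.chip_id!r} is {arr.n_rows}x{arr.n_cols}, layout "
                f"expects {layout.n_rows}x{layout.n_cols}"
            )
    probe_ids: list[str] = []
    rows: list[list[float]] = []
    for ps, pair in layout.iter_pairs():
        x, y = pair.pm_xy
        probe_ids.append(f"{ps.id}_{x}_{y}")
        rows.append([arr.values[y, x] for arr in arrays])
    if include_mm:
        for ps, pair in layout.iter_pairs():
            if pair.mm_xy is None:
                continue
            x, y = pair.mm_xy
            probe_ids.append(f"{ps.id}_{x}_{y}_mm")
            rows.append([arr.values[y, x] for arr in arrays])
    chip_ids = [arr.chip_id for arr in arrays]
    return ProbeMatrix(probe_ids, chip_ids, np.asarray(rows, dtype=float))
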