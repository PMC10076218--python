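"""Cobarcoding chemistry schema and the spatial pixel grid.

A tissue section is addressed by two orthogonal sets of ligated spatial
barcodes: barcodes A (one per microfluidic channel of the first flow) and
barcodes B (perpendicular flow). Every pixel is the unique combination
(Ai, Bj), so an ``n_a x n_b`` device yields ``n_a * n_b`` addressable
pixels (2,500 for 50x50 chips, 10,000 for 100x100 chips).

The read-2 layout of the sequencing library is a fixed concatenation of
segments (barcode B, ligation linker 2, barcode A, ligation linker 1 and,
for the RNA library, a UMI). Linker sequences and whitelists are supplied
by configuration, never hard-coded.
"""

from __future__ import annotations

import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "BarcodeSchema",
    "PixelGrid",
    "SchemaError",
    "build_pixel_grid",
    "pixel_coordinates",
    "pixel_id",
    "parse_pixel_id",
    "apply_tissue_mask",
    "load_schema",
    "load_whitelist",
    "load_mask",
    "random_whitelist",
]

MODALITIES = ("atac", "cuttag", "rna")

#: segment names understood by the default layout builder
_SEGMENTS = ("barcode_b", "linker2", "barcode_a", "linker1", "umi")


class SchemaError(ValueError):
    """Raised for invalid barcode schemas (duplicates, bad layout...)."""


def _check_whitelist(name: str, entries: Sequence[str], length: int) -> tuple[str, ...]:
    entries = tuple(s.upper() for s in entries)
    if not entries:
        raise SchemaError(f"{name} whitelist is empty")
    if len(set(entries)) != len(entries):
        raise SchemaError(f"{name} whitelist contains duplicate sequences")
    for s in entries:
        if len(s) != length:
            raise SchemaError(
                f"{name} whitelist entry {s!r} has length {len(s)}, expected {length}"
            )
    return entries


@dataclass(frozen=True)
class BarcodeSchema:
    """Read-2 layout plus the two spatial-barcode whitelists.

    Parameters
    ----------
    barcode_a_whitelist, barcode_b_whitelist
        Ordered barcode sequences; barcode indices are 1-based positions
        in these lists (A1..An, B1..Bn).
    linker1_seq, linker2_seq
        Ligation-linker sequences checked at fixed offsets in read 2.
    modality
        ``"atac"``, ``"cuttag"`` or ``"rna"``; only RNA reads carry a UMI.
    layout
        Optional explicit ordered segment names; defaults to
        ``barcode_b, linker2, barcode_a, linker1`` (+ ``umi`` for RNA).
    """

    barcode_a_whitelist: tuple[str, ...]
    barcode_b_whitelist: tuple[str, ...]
    linker1_seq: str
    linker2_seq: str
    modality: str = "atac"
    barcode_len: int = 8
    umi_len: int = 10
    layout_order: tuple[str, ...] = ()
    layout: tuple[tuple[str, int, int], ...] = field(init=False)

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise SchemaError(f"unknown modality {self.modality!r}")
        object.__setattr__(
            self,
            "barcode_a_whitelist",
            _check_whitelist("barcode A", self.barcode_a_whitelist, self.barcode_len),
        )
        object.__setattr__(
            self,
            "barcode_b_whitelist",
            _check_whitelist("barcode B", self.barcode_b_whitelist, self.barcode_len),
        )
        order = self.layout_order or self.default_layout_order(self.modality)
        if self.modality != "rna" and "umi" in order:
            raise SchemaError("UMI segment is only valid in RNA mode")
        seen = set()
        segments = []
        offset = 0
        for name in order:
            if name not in _SEGMENTS:
                raise SchemaError(f"unknown layout segment {name!r}")
            if name in seen:
                raise SchemaError(f"duplicate layout segment {name!r}")
            seen.add(name)
            length = self.segment_length(name)
            segments.append((name, offset, length))
            offset += length
        required = {"barcode_a", "barcode_b", "linker1", "linker2"}
        if self.modality == "rna":
            required.add("umi")
        if missing := required - seen:
            raise SchemaError(f"layout missing segments: {sorted(missing)}")
        object.__setattr__(self, "layout_order", tuple(order))
        object.__setattr__(self, "layout", tuple(segments))

    @staticmethod
    def default_layout_order(modality: str) -> tuple[str, ...]:
        base = ("barcode_b", "linker2", "barcode_a", "linker1")
        return base + ("umi",) if modality == "rna" else base

    def segment_length(self, name: str) -> int:
        if name in ("barcode_a", "barcode_b"):
            return self.barcode_len
        if name == "linker1":
            return len(self.linker1_seq)
        if name == "linker2":
            return len(self.linker2_seq)
        if name == "umi":
            return self.umi_len
        raise SchemaError(f"unknown segment {name!r}")

    def segment(self, name: str) -> tuple[int, int]:
        """(offset, length) of a named read-2 segment."""
        for seg, off, length in self.layout:
            if seg == name:
                return off, length
        raise SchemaError(f"segment {name!r} not in layout")

    @property
    def read2_length(self) -> int:
        name, off, length = self.layout[-1]
        return off + length

    @property
    def n_a(self) -> int:
        return len(self.barcode_a_whitelist)

    @property
    def n_b(self) -> int:
        return len(self.barcode_b_whitelist)


@dataclass
class PixelGrid:
    """The two-dimensional grid of spatially barcoded tissue pixels.

    Barcode A indexes rows, barcode B indexes columns; external
    coordinates are 0-based ``(row, col)``. ``on_tissue`` restricts
    downstream matrices to pixels under the tissue section.
    """

    n_a: int
    n_b: int
    on_tissue: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.n_a < 1 or self.n_b < 1:
            raise SchemaError("grid dimensions must be positive")
        if self.on_tissue is None:
            self.on_tissue = np.ones((self.n_a, self.n_b), dtype=bool)
        else:
            self.on_tissue = np.asarray(self.on_tissue, dtype=bool)
            if self.on_tissue.shape != (self.n_a, self.n_b):
                raise SchemaError(
                    f"mask shape {self.on_tissue.shape} != grid shape "
                    f"({self.n_a}, {self.n_b})"
                )

    @property
    def n_pixels(self) -> int:
        return self.n_a * self.n_b

    @property
    def n_on_tissue(self) -> int:
        return int(self.on_tissue.sum())

    def contains(self, a_index: int, b_index: int) -> bool:
        return 1 <= a_index <= self.n_a and 1 <= b_index <= self.n_b

    def addresses(self) -> Iterator[tuple[int, int]]:
        """All (a_index, b_index) addresses in deterministic A-major order."""
        for a in range(1, self.n_a + 1):
            for b in range(1, self.n_b + 1):
                yield (a, b)

    def pixel_ids(self, on_tissue_only: bool = False) -> list[str]:
        return [
            pixel_id(a, b)
            for a, b in self.addresses()
            if not on_tissue_only or self.on_tissue[a - 1, b - 1]
        ]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "n_a": self.n_a,
            "n_b": self.n_b,
            "on_tissue": self.on_tissue.astype(int).tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "PixelGrid":
        payload = json.loads(Path(path).read_text())
        return cls(payload["n_a"], payload["n_b"], np.array(payload["on_tissue"]))


def build_pixel_grid(schema: BarcodeSchema) -> PixelGrid:
    """Grid of all N_A x N_B pixel addresses defined by the whitelists."""
    return PixelGrid(schema.n_a, schema.n_b)


def pixel_id(a_index: int, b_index: int) -> str:
    """Canonical pixel identifier ``"AxB"`` with 1-based barcode indices."""
    return f"{a_index}x{b_index}"


def parse_pixel_id(pid: str) -> tuple[int, int]:
    a, b = pid.split("x")
    return int(a), int(b)


def pixel_coordinates(
    a_index: int,
    b_index: int,
    grid: PixelGrid,
    *,
    flip_rows: bool = False,
    flip_cols: bool = False,
    transpose: bool = False,
) -> tuple[int, int]:
    """Map a 1-based barcode address to a 0-based (row, col) coordinate.

    The flip/transpose flags support registration against a tissue image
    whose orientation differs from the flow-direction convention.
    """
    if not grid.contains(a_index, b_index):
        raise KeyError(f"address ({a_index}, {b_index}) outside {grid.n_a}x{grid.n_b} grid")
    row, col = a_index - 1, b_index - 1
    if flip_rows:
        row = grid.n_a - 1 - row
    if flip_cols:
        col = grid.n_b - 1 - col
    return (col, row) if transpose else (row, col)


def coordinates_to_address(row: int, col: int, grid: PixelGrid) -> tuple[int, int]:
    """Inverse of :func:`pixel_coordinates` under the default orientation."""
    a, b = row + 1, col + 1
    if not grid.contains(a, b):
        raise KeyError(f"coordinate ({row}, {col}) outside grid")
    return a, b


def apply_tissue_mask(grid: PixelGrid, mask: np.ndarray) -> PixelGrid:
    """Return a new grid whose on-tissue set is ``mask``.

    The mask is typically derived from a brightfield image of the section;
    here it is consumed as a plain 0/1 matrix of grid shape.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (grid.n_a, grid.n_b):
        raise SchemaError(
            f"mask shape {mask.shape} does not match grid ({grid.n_a}, {grid.n_b})"
        )
    return PixelGrid(grid.n_a, grid.n_b, mask.copy())


# ---------------------------------------------------------------------------
# configuration file loading


def load_whitelist(path: str | Path) -> list[str]:
    """Barcode whitelist from a TSV (index<TAB>sequence or one per line) or FASTA."""
    path = Path(path)
    text = path.read_text()
    entries: list[str] = []
    if text.lstrip().startswith(">"):
        seq: list[str] = []
        for line in text.splitlines():
            if line.startswith(">"):
                if seq:
                    entries.append("".join(seq))
                    seq = []
            elif line.strip():
                seq.append(line.strip())
        if seq:
            entries.append("".join(seq))
    else:
        for line in text.splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            entries.append(fields[-1].strip() if len(fields) > 1 else fields[0].strip())
    return entries


def load_mask(path: str | Path) -> np.ndarray:
    """0/1 tissue mask from CSV or TSV."""
    text = Path(path).read_text()
    sep = "," if "," in text.splitlines()[0] else None
    rows = [
        [int(float(v)) for v in (line.split(sep) if sep else line.split())]
        for line in text.splitlines()
        if line.strip()
    ]
    return np.array(rows, dtype=bool)


def load_schema(path: str | Path) -> BarcodeSchema:
    """Load a :class:`BarcodeSchema` from a TOML config.

    Expected keys: ``modality``, ``linker1``, ``linker2``, optional
    ``barcode_len``, ``umi_len``, ``layout`` (list of segment names) and a
    ``[whitelists]`` table with ``a``/``b`` file paths (relative to the
    config file) or inline sequence lists.
    """
    path = Path(path)
    cfg = tomllib.loads(path.read_text())
    wl = cfg.get("whitelists", {})

    def _resolve(value) -> list[str]:
        if isinstance(value, list):
            return list(value)
        return load_whitelist(path.parent / value)

    return BarcodeSchema(
        barcode_a_whitelist=tuple(_resolve(wl["a"])),
        barcode_b_whitelist=tuple(_resolve(wl["b"])),
        linker1_seq=cfg["linker1"].upper(),
        linker2_seq=cfg["linker2"].upper(),
        modality=cfg.get("modality", "atac"),
        barcode_len=cfg.get("barcode_len", 8),
        umi_len=cfg.get("umi_len", 10),
        layout_order=tuple(cfg.get("layout", ())),
    )


def random_whitelist(
    n: int,
    length: int = 8,
    min_distance: int = 3,
    seed: int | np.random.Generator = 0,
) -> list[str]:
    """Random DNA whitelist with pairwise Hamming distance >= ``min_distance``.

    Greedy rejection sampling; with 8-mers and n <= 100 the constraint is
    easily satisfiable. Used by the simulators and tests; real chips load
    their published barcode tables instead.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    alphabet = np.array(list("ACGT"))
    chosen: list[np.ndarray] = []
    attempts = 0
    while len(chosen) < n:
        cand = rng.integers(0, 4, size=length)
        if all(int((cand != prev).sum()) >= min_distance for prev in chosen):
            chosen.append(cand)
        attempts += 1
        if attempts > 1000 * n:
            raise RuntimeError(
                f"could not draw {n} barcodes of length {length} at distance {min_distance}"
            )
    return ["".join(alphabet[c]) for c in chosen]
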