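"""Gridded, print-tip-blocked placement of probes on the spotted array.

Every signal probe pair is spotted eight times (octuplicates) as two
spatially separated quadruplicates: four replicates go to blocks in the
first half of the block list, four to the second half, so that a local
hybridization artifact cannot wipe out (or fabricate) a whole probe.  The
PM oligo always sits immediately left of its MM partner in the same row
(adjacent columns), the geometry the analysis pipeline relies on for the
PM>MM specificity filter.  Probes without an MM partner (control-region,
spike-in and snRNA probes) occupy single cells, also 4 + 4 across halves.

Within a block, successive allocations visit even rows first and odd rows
second, so the replicates a probe places in one block land on non-adjacent
rows whenever capacity allows.

Layouts are written in a GAL-like tab-separated dialect (Block, Row,
Column, ID, Name; all 1-based) with the grid dimensions on a leading
comment line, and can be validated independently of how they were made.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .probe_design import ProbePair

__all__ = [
    "Spot",
    "ArrayDesign",
    "layout_array",
    "write_layout",
    "read_layout",
    "validate_layout",
]


@dataclass(frozen=True)
class Spot:
    block: int  # 1-based print-tip group
    row: int  # 1-based within block
    col: int  # 1-based within block
    probe_id: str
    replicate_index: int  # 1-8
    pair_role: str  # PM | MM | single


@dataclass
class ArrayDesign:
    n_blocks: int
    block_rows: int
    block_cols: int
    spots: list[Spot] = field(default_factory=list)

    @property
    def n_spots(self) -> int:
        return len(self.spots)

    def spotted_species_count(self) -> dict[str, int]:
        """Distinct PM-type probes vs total spotted oligo species.

        ``pm_type`` counts one per probe (PM plus MM-less singles);
        ``spotted`` additionally counts each MM partner as its own species.
        """
        pm_type = {s.probe_id for s in self.spots if s.pair_role in ("PM", "single")}
        mm = {s.probe_id for s in self.spots if s.pair_role == "MM"}
        return {"pm_type": len(pm_type), "spotted": len(pm_type) + len(mm)}


class _BlockAllocator:
    """Hands out free cells of one block, even rows first, then odd rows."""

    def __init__(self, rows: int, cols: int):
        self.cols = cols
        self.row_order = list(range(0, rows, 2)) + list(range(1, rows, 2))
        self.row_idx = 0
        self.col = 0
        self.leftovers: list[tuple[int, int]] = []  # cells skipped by pair allocation

    def _advance_row(self) -> None:
        self.row_idx += 1
        self.col = 0

    def take_pair(self):
        """Two horizontally adjacent free cells, or None when full."""
        while self.row_idx < len(self.row_order):
            if self.col + 1 < self.cols:
                row = self.row_order[self.row_idx]
                cells = ((row, self.col), (row, self.col + 1))
                self.col += 2
                return cells
            if self.col < self.cols:  # dangling last column -> save for singles
                self.leftovers.append((self.row_order[self.row_idx], self.col))
            self._advance_row()
        return None

    def take_single(self):
        if self.leftovers:
            return self.leftovers.pop(0)
        while self.row_idx < len(self.row_order):
            if self.col < self.cols:
                cell = (self.row_order[self.row_idx], self.col)
                self.col += 1
                return cell
            self._advance_row()
        return None


def layout_array(
    probes: Sequence[ProbePair],
    n_blocks: int,
    block_rows: int,
    block_cols: int,
    seed: int = 0,
) -> ArrayDesign:
    """Place probes on the grid with octuplicate spotting and PM/MM adjacency.

    Deterministic given ``seed`` (the seed shuffles block order within each
    half, spreading probes across print tips).  Raises ``ValueError`` when
    the grid cannot hold the required spots or the block list cannot be
    split into two halves.
    """
    pairs = [p for p in probes if p.has_mm]
    singles = [p for p in probes if not p.has_mm]

    if n_blocks < 2:
        raise ValueError(
            "octuplicate spotting needs at least 2 blocks to separate the two "
            f"quadruplicates into different array halves (got {n_blocks})"
        )
    half_a = list(range(1, n_blocks // 2 + 1))
    half_b = list(range(n_blocks // 2 + 1, n_blocks + 1))
    cells_per_block = block_rows * block_cols
    for half, blocks in (("first", half_a), ("second", half_b)):
        needed = len(pairs) * 8 + len(singles) * 4
        available = len(blocks) * cells_per_block
        if needed > available:
            raise ValueError(
                f"grid capacity exceeded in the {half} block half: "
                f"{needed} cells required, {available} available"
            )
        pair_slots = len(blocks) * block_rows * (block_cols // 2)
        if len(pairs) * 4 > pair_slots:
            raise ValueError(
                f"not enough adjacent-cell slots in the {half} block half: "
                f"{len(pairs) * 4} PM/MM slots required, {pair_slots} available"
            )

    rng = np.random.default_rng(seed)
    half_a = list(rng.permutation(half_a))
    half_b = list(rng.permutation(half_b))
    allocators = {b: _BlockAllocator(block_rows, block_cols) for b in range(1, n_blocks + 1)}

    def _alloc(blocks: list[int], start: int, what: str):
        """Try blocks round-robin from ``start``; fall through to any block
        in the half that still has room."""
        for shift in range(len(blocks)):
            block = int(blocks[(start + shift) % len(blocks)])
            cell = allocators[block].take_pair() if what == "pair" else allocators[block].take_single()
            if cell is not None:
                return block, cell
        raise ValueError(f"grid capacity exceeded while placing a {what}")

    spots: list[Spot] = []
    for what, plist in (("pair", pairs), ("single", singles)):
        for idx, probe in enumerate(plist):
            for rep in range(1, 9):
                blocks = half_a if rep <= 4 else half_b
                block, cell = _alloc(blocks, idx + (rep - 1) % 4, what)
                if what == "pair":
                    (r1, c1), (r2, c2) = cell
                    spots.append(Spot(block, r1 + 1, c1 + 1, probe.probe_id, rep, "PM"))
                    spots.append(Spot(block, r2 + 1, c2 + 1, probe.probe_id, rep, "MM"))
                else:
                    r, c = cell
                    spots.append(Spot(block, r + 1, c + 1, probe.probe_id, rep, "single"))

    design = ArrayDesign(n_blocks, block_rows, block_cols, spots)
    problems = validate_layout(design)
    if problems:  # defensive: the allocator should never produce these
        raise AssertionError("layout violates its own invariants: " + "; ".join(problems))
    return design


def validate_layout(design: ArrayDesign) -> list[str]:
    """Check the layout invariants; returns a list of violations (empty = ok).

    Checked: cells within the grid and used at most once; every PM spot has
    its MM partner in the adjacent column of the same row; every probe
    appears exactly 8 times with 4 replicates in each block half.
    """
    problems = []
    seen_cells = {}
    for s in design.spots:
        if not (1 <= s.block <= design.n_blocks):
            problems.append(f"{s.probe_id}: block {s.block} out of range")
        if not (1 <= s.row <= design.block_rows and 1 <= s.col <= design.block_cols):
            problems.append(f"{s.probe_id}: cell ({s.row},{s.col}) out of range")
        key = (s.block, s.row, s.col)
        if key in seen_cells:
            problems.append(f"cell {key} used twice ({seen_cells[key]} and {s.probe_id})")
        seen_cells[key] = s.probe_id

    by_probe: dict[str, list[Spot]] = {}
    for s in design.spots:
        by_probe.setdefault(s.probe_id, []).append(s)

    half_a_max = design.n_blocks // 2
    for probe_id, spots in by_probe.items():
        roles = {s.pair_role for s in spots}
        if roles == {"single"}:
            if len(spots) != 8:
                problems.append(f"{probe_id}: {len(spots)} spots, expected 8")
            reps = spots
        else:
            pm = {s.replicate_index: s for s in spots if s.pair_role == "PM"}
            mm = {s.replicate_index: s for s in spots if s.pair_role == "MM"}
            if len(pm) != 8 or len(mm) != 8:
                problems.append(f"{probe_id}: expected 8 PM and 8 MM spots")
            for rep, s in pm.items():
                partner = mm.get(rep)
                if partner is None or (partner.block, partner.row, partner.col) != (
                    s.block,
                    s.row,
                    s.col + 1,
                ):
                    problems.append(f"{probe_id} rep {rep}: MM not adjacent to PM")
            reps = list(pm.values())
        in_a = sum(1 for s in reps if s.block <= half_a_max)
        if len(reps) == 8 and in_a != 4:
            problems.append(f"{probe_id}: quadruplicates not split 4/4 across halves ({in_a} in first half)")
    return problems


def write_layout(design: ArrayDesign, path: str | Path) -> None:
    spots = sorted(design.spots, key=lambda s: (s.block, s.row, s.col))
    with open(path, "w") as fh:
        fh.write(f"# blocks={design.n_blocks} rows={design.block_rows} cols={design.block_cols}\n")
        fh.write("Block\tRow\tColumn\tID\tName\n")
        for s in spots:
            spot_id = s.probe_id if s.pair_role == "single" else f"{s.probe_id}.{s.pair_role}"
            fh.write(f"{s.block}\t{s.row}\t{s.col}\t{spot_id}.{s.replicate_index}\t{s.probe_id}\n")


def read_layout(path: str | Path) -> ArrayDesign:
    n_blocks = rows = cols = None
    spots: list[Spot] = []
    seen = set()
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                meta = dict(kv.split("=") for kv in line[1:].split())
                n_blocks, rows, cols = int(meta["blocks"]), int(meta["rows"]), int(meta["cols"])
                continue
            if not line or line.startswith("Block\t"):
                continue
            block, row, col, spot_id, name = line.split("\t")
            key = (int(block), int(row), int(col))
            if key in seen:
                raise ValueError(f"duplicate cell {key} in layout file")
            seen.add(key)
            parts = spot_id.rsplit(".", 2)
            if len(parts) == 3 and parts[1] in ("PM", "MM"):
                role, rep = parts[1], int(parts[2])
            else:
                role, rep = "single", int(parts[-1])
            spots.append(Spot(*key, name, rep, role))
    if n_blocks is None:
        n_blocks = max(s.block for s in spots)
        rows = max(s.row for s in spots)
        cols = max(s.col for s in spots)
    return ArrayDesign(n_blocks, rows, cols, spots)
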