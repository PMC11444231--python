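"""Sliding-tile 2048 game core: the "everyday life" engagement task.

Deterministic given a seeded :class:`numpy.random.Generator`.  Conventions of
the open-source original are adopted: a new game spawns two tiles, each spawn
is value 2 with probability 0.9 and value 4 with probability 0.1 on a
uniformly chosen empty cell, and a move that changes nothing spawns no tile.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

GRID_SIZE = 4
SPAWN_P4 = 0.1  # probability a spawned tile is a 4 rather than a 2


class MoveDirection(str, Enum):
    UP = "up"
    DOWN = "down"
    LEFT = "left"
    RIGHT = "right"


@dataclass
class GameState:
    """Grid, score and bookkeeping for one play of the tile game."""

    grid: np.ndarray
    score: int = 0
    move_count: int = 0
    over: bool = False

    def copy(self) -> "GameState":
        return GameState(self.grid.copy(), self.score, self.move_count, self.over)


def _validate_grid(grid: np.ndarray) -> None:
    if grid.shape != (GRID_SIZE, GRID_SIZE):
        raise ValueError(f"grid must be {GRID_SIZE}x{GRID_SIZE}, got {grid.shape}")
    vals = grid[grid != 0]
    if np.any(vals < 2) or np.any(vals & (vals - 1)):
        raise ValueError("nonzero cells must be powers of two >= 2")


def _spawn_tile(grid: np.ndarray, rng: np.random.Generator) -> None:
    """Place a 2 (90%) or 4 (10%) on a uniformly chosen empty cell, in place."""
    empties = np.argwhere(grid == 0)
    if len(empties) == 0:
        raise RuntimeError("no empty cell to spawn on")
    r, c = empties[rng.integers(len(empties))]
    grid[r, c] = 4 if rng.random() < SPAWN_P4 else 2


def new_game(rng: np.random.Generator) -> GameState:
    """Start a fresh game: empty grid plus exactly two spawned tiles, score 0."""
    grid = np.zeros((GRID_SIZE, GRID_SIZE), dtype=np.int64)
    _spawn_tile(grid, rng)
    _spawn_tile(grid, rng)
    return GameState(grid=grid, score=0, move_count=0, over=False)


def slide_merge_row(row: np.ndarray) -> tuple[np.ndarray, int]:
    """Slide a row toward index 0, merging equal pairs nearest the edge first.

    Each result tile participates in at most one merge.  Returns the new row
    and the score gained (sum of created tile values).
    """
    tiles = [int(v) for v in row if v != 0]
    out: list[int] = []
    gained = 0
    i = 0
    while i < len(tiles):
        if i + 1 < len(tiles) and tiles[i] == tiles[i + 1]:
            merged = tiles[i] * 2
            out.append(merged)
            gained += merged
            i += 2
        else:
            out.append(tiles[i])
            i += 1
    out.extend([0] * (len(row) - len(out)))
    return np.array(out, dtype=row.dtype), gained


def _slide_grid(grid: np.ndarray, direction: MoveDirection) -> tuple[np.ndarray, int]:
    # Orient so every move becomes "slide rows left", then undo.
    if direction == MoveDirection.LEFT:
        oriented = grid
    elif direction == MoveDirection.RIGHT:
        oriented = grid[:, ::-1]
    elif direction == MoveDirection.UP:
        oriented = grid.T
    elif direction == MoveDirection.DOWN:
        oriented = grid.T[:, ::-1]
    else:  # pragma: no cover - closed enum
        raise ValueError(direction)

    rows = []
    gained = 0
    for row in oriented:
        new_row, g = slide_merge_row(row)
        rows.append(new_row)
        gained += g
    result = np.stack(rows)

    if direction == MoveDirection.RIGHT:
        result = result[:, ::-1]
    elif direction == MoveDirection.UP:
        result = result.T
    elif direction == MoveDirection.DOWN:
        result = result[:, ::-1].T
    return np.ascontiguousarray(result), gained


def is_over(state: GameState) -> bool:
    """True iff the grid is full and no equal orthogonally-adjacent pair exists."""
    grid = state.grid
    if np.any(grid == 0):
        return False
    if np.any(grid[:, :-1] == grid[:, 1:]):
        return False
    if np.any(grid[:-1, :] == grid[1:, :]):
        return False
    return True


def apply_move(state: GameState, direction: MoveDirection, rng: np.random.Generator) -> GameState:
    """Apply one move.  A move that changes nothing spawns no tile and does
    not increment ``move_count``; an effective move spawns exactly one tile.
    """
    if state.over:
        raise ValueError("cannot move a finished game")
    direction = MoveDirection(direction)
    new_grid, gained = _slide_grid(state.grid, direction)
    if np.array_equal(new_grid, state.grid):
        return state.copy()
    _spawn_tile(new_grid, rng)
    new_state = GameState(
        grid=new_grid,
        score=state.score + gained,
        move_count=state.move_count + 1,
        over=False,
    )
    new_state.over = is_over(new_state)
    return new_state


def legal_moves(state: GameState) -> list[MoveDirection]:
    """Directions in which a move would change the grid."""
    moves = []
    for d in MoveDirection:
        new_grid, _ = _slide_grid(state.grid, d)
        if not np.array_equal(new_grid, state.grid):
            moves.append(d)
    return moves


def restart_if_over(state: GameState, rng: np.random.Generator) -> GameState:
    """Fresh game when the current one is finished; identity otherwise.

    The caller owns cumulative session score accounting across restarts.
    """
    if state.over:
        return new_game(rng)
    return state


def grid_to_list(state: GameState) -> list[list[int]]:
    """Plain nested-list form of the grid for the JSON event log."""
    return [[int(v) for v in row] for row in state.grid]


def grid_from_list(cells: list[list[int]]) -> np.ndarray:
    grid = np.array(cells, dtype=np.int64)
    _validate_grid(grid)
    return grid
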