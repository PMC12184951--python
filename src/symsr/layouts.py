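"""ASCII grid-world layouts used by the navigation experiments.

``#`` is a wall, ``.`` a free cell.  States are enumerated in reading order
(row-major, 0-based) over the free cells.  The layouts emulate the style of
open-room / four-room / obstacle / hairpin arenas and a multi-chamber
training maze with blocked-path test variants; they are synthetic stand-ins
drawn in the same spirit, not copies of any published asset.
"""

from __future__ import annotations

EMPTY_ROOM = """
#############
#...........#
#...........#
#...........#
#...........#
#...........#
#...........#
#...........#
#...........#
#...........#
#...........#
#...........#
#############
"""

FOUR_ROOMS = """
#############
#.....#.....#
#.....#.....#
#...........#
#.....#.....#
#.....#.....#
##.######.###
#.....#.....#
#.....#.....#
#...........#
#.....#.....#
#.....#.....#
#############
"""

OBSTACLE_ROOM = """
###########
#.........#
#.........#
#.........#
#...###...#
#...###...#
#...###...#
#.........#
#.........#
#.........#
###########
"""

HAIRPIN = """
###########
#.#...#...#
#.#.#.#.#.#
#.#.#.#.#.#
#.#.#.#.#.#
#.#.#.#.#.#
#.#.#.#.#.#
#.#.#.#.#.#
#...#...#.#
###########
"""

MAZE_TRAIN = """
#############
#...#...#...#
#.#.#.#.#.#.#
#.#...#...#.#
#.#####.###.#
#.....#.....#
#####.#.#####
#.....#.....#
#.###.#####.#
#.#...#...#.#
#.#.#.#.#.#.#
#...#...#...#
#############
"""


def _block(layout: str, cells: list[tuple[int, int]]) -> str:
    rows = [list(line) for line in layout.strip("\n").splitlines()]
    for r, c in cells:
        if rows[r][c] != ".":
            raise ValueError(f"cell ({r},{c}) is not free in the base layout")
        rows[r][c] = "#"
    return "\n" + "\n".join("".join(r) for r in rows) + "\n"


# Test variants of the training maze: previously open corridors are blocked,
# forcing detours (connectivity is preserved; shortest paths lengthen).
MAZE_BLOCKED_A = _block(MAZE_TRAIN, [(3, 7)])
MAZE_BLOCKED_B = _block(MAZE_TRAIN, [(7, 5)])
MAZE_BLOCKED_C = _block(MAZE_TRAIN, [(1, 6)])

SYMMETRIC_FIXTURES = {
    "empty_room": EMPTY_ROOM,
    "four_rooms": FOUR_ROOMS,
    "obstacle_room": OBSTACLE_ROOM,
    "hairpin": HAIRPIN,
}

MAZE_FIXTURES = {
    "maze_train": MAZE_TRAIN,
    "maze_blocked_a": MAZE_BLOCKED_A,
    "maze_blocked_b": MAZE_BLOCKED_B,
    "maze_blocked_c": MAZE_BLOCKED_C,
}
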