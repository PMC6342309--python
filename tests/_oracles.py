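"""Independent brute-force oracles used only by the test suite.

These deliberately avoid scipy/sklearn and the package's own code paths:
plain BFS flood fill for components and holes, and exhaustive case-control
pair counting for the AUC.
"""

from collections import deque


def _neighbors(r, c, connectivity):
    if connectivity == 4:
        return ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1))
    return (
        (r - 1, c - 1), (r - 1, c), (r - 1, c + 1),
        (r, c - 1), (r, c + 1),
        (r + 1, c - 1), (r + 1, c), (r + 1, c + 1),
    )


def _components(cells, connectivity):
    """Partition a set of (r, c) cells into connected components by BFS."""
    cells = set(cells)
    comps = []
    while cells:
        seed = cells.pop()
        comp = {seed}
        queue = deque([seed])
        while queue:
            r, c = queue.popleft()
            for nb in _neighbors(r, c, connectivity):
                if nb in cells:
                    cells.remove(nb)
                    comp.add(nb)
                    queue.append(nb)
        comps.append(comp)
    return comps


def flood_fill_betti(grid, connectivity=(8, 4)):
    """(b0, b1) of the 0-pixel set of a {0,1} grid by exhaustive flood fill.

    b0: components of the 0 set under ``connectivity[0]``. b1: components of
    the 1 set under ``connectivity[1]`` that touch no grid border (such a
    component is enclosed by 0 pixels).
    """
    n_rows = len(grid)
    n_cols = len(grid[0])
    zeros = [(r, c) for r in range(n_rows) for c in range(n_cols) if grid[r][c] == 0]
    ones = [(r, c) for r in range(n_rows) for c in range(n_cols) if grid[r][c] == 1]
    b0 = len(_components(zeros, connectivity[0]))
    holes = 0
    for comp in _components(ones, connectivity[1]):
        touches = any(
            r == 0 or r == n_rows - 1 or c == 0 or c == n_cols - 1 for r, c in comp
        )
        if not touches:
            holes += 1
    return b0, holes


def pair_counting_auc(scores, labels):
    """AUC by enumerating every case-control pair; ties count one half."""
    cases = [s for s, y in zip(scores, labels) if y == 1]
    controls = [s for s, y in zip(scores, labels) if y == 0]
    wins = 0.0
    for x in cases:
        for w in controls:
            if x > w:
                wins += 1.0
            elif x == w:
                wins += 0.5
    return wins / (len(cases) * len(controls))
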