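"""Repair of invalid pairwise translations from row/column averages.

Links that failed registration or were discarded by the stage-model filter
are replaced by direction-specific averages of the valid ones: an invalid
north link takes the component-wise mean of the valid north links in its grid
row (tiles in one row share the same vertical stepping error of the stage);
if the whole row is invalid, the mean over all valid north links.  West links
are repaired symmetrically by grid column.  Repaired links keep a sentinel
match count so the alignment graph assigns them the penalty weight.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import List

import numpy as np
import pandas as pd

from .registration import NORTH, WEST, PairwiseLink, Translation

__all__ = ["LinkTable", "repair_links"]


@dataclass
class LinkTable:
    """All pairwise links of an M x N grid, organized by position/direction.

    ``north[r][c]`` links reference tile (r, c) to moving tile (r+1, c) for
    r < M-1; ``west[r][c]`` links (r, c) to (r, c+1) for c < N-1.  The total
    link count is 2MN - (M + N).
    """

    M: int
    N: int
    north: List[List[PairwiseLink]]  # (M-1) x N
    west: List[List[PairwiseLink]]  # M x (N-1)

    def __post_init__(self) -> None:
        if len(self.north) != max(self.M - 1, 0) or any(
            len(row) != self.N for row in self.north
        ):
            raise ValueError("north links must form an (M-1) x N array")
        if len(self.west) != self.M or any(
            len(row) != self.N - 1 for row in self.west
        ):
            raise ValueError("west links must form an M x (N-1) array")

    @property
    def n_links(self) -> int:
        return 2 * self.M * self.N - (self.M + self.N)

    def all_links(self) -> List[PairwiseLink]:
        out = [l for row in self.north for l in row]
        out += [l for row in self.west for l in row]
        return out

    # -- CSV round trip (inspection / fixtures) -----------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = []
        for link in self.all_links():
            rows.append(
                dict(
                    ref_row=link.reference[0],
                    ref_col=link.reference[1],
                    direction=link.direction,
                    t_x=link.translation.t_x,
                    t_y=link.translation.t_y,
                    n_matched=link.n_matched,
                    status=link.status,
                    stage_used=link.stage_used or "",
                )
            )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, M: int, N: int) -> "LinkTable":
        df = pd.read_csv(Path(path), keep_default_na=False, na_values=[""])
        north = [[None] * N for _ in range(M - 1)]
        west = [[None] * (N - 1) for _ in range(M)]
        for rec in df.itertuples(index=False):
            r, c = int(rec.ref_row), int(rec.ref_col)
            stage = rec.stage_used if isinstance(rec.stage_used, str) and rec.stage_used else None
            tx, ty = float(rec.t_x), float(rec.t_y)
            link = PairwiseLink(
                reference=(r, c),
                moving=(r + 1, c) if rec.direction == NORTH else (r, c + 1),
                direction=rec.direction,
                translation=Translation(tx, ty),
                n_matched=float(rec.n_matched),
                stage_used=stage,
                status=str(rec.status),
            )
            if rec.direction == NORTH:
                north[r][c] = link
            else:
                west[r][c] = link
        if any(l is None for row in north for l in row) or any(
            l is None for row in west for l in row
        ):
            raise ValueError("CSV does not cover every link of the grid")
        return cls(M=M, N=N, north=north, west=west)


def _mean_translation(links) -> Translation:
    ts = np.array(
        [(l.translation.t_x, l.translation.t_y) for l in links], dtype=np.float64
    )
    m = ts.mean(axis=0)
    return Translation(float(m[0]), float(m[1]))


def _repaired(link: PairwiseLink, t: Translation) -> PairwiseLink:
    return replace(
        link,
        translation=t,
        n_matched=float("nan"),  # excluded from graph weights -> penalty edge
        stage_used="repaired",
        status="valid",
    )


def repair_links(table: LinkTable) -> LinkTable:
    """Replace invalid links by row (north) / column (west) averages.

    Averages are component-wise arithmetic means over status-valid links
    only; repaired links never feed back into averages (single pass), so the
    operation is idempotent.  Raises if a direction with links has no valid
    link at all — the grid is unstitchable by this rule.
    """
    north_valid = [l for row in table.north for l in row if l.is_valid]
    west_valid = [l for row in table.west for l in row if l.is_valid]
    n_north = sum(len(row) for row in table.north)
    n_west = sum(len(row) for row in table.west)
    if n_north > 0 and not north_valid:
        raise ValueError(
            "no valid north link in the grid: cannot repair north direction"
        )
    if n_west > 0 and not west_valid:
        raise ValueError(
            "no valid west link in the grid: cannot repair west direction"
        )

    north_global = _mean_translation(north_valid) if north_valid else None
    west_global = _mean_translation(west_valid) if west_valid else None

    new_north = []
    for row in table.north:
        valid_row = [l for l in row if l.is_valid]
        fallback = _mean_translation(valid_row) if valid_row else north_global
        new_north.append([l if l.is_valid else _repaired(l, fallback) for l in row])

    # west links in grid column c are west[r][c] across rows r
    new_west = [list(row) for row in table.west]
    for c in range(table.N - 1):
        col = [table.west[r][c] for r in range(table.M)]
        valid_col = [l for l in col if l.is_valid]
        fallback = _mean_translation(valid_col) if valid_col else west_global
        for r in range(table.M):
            if not col[r].is_valid:
                new_west[r][c] = _repaired(col[r], fallback)

    return LinkTable(M=table.M, N=table.N, north=new_north, west=new_west)
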