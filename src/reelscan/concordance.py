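"""Cross-library agreement between the two offset tilings.

The two libraries interrogate the same region with shifted fragment
boundaries, so a genuine regulatory element should be called in both.  Each
Library 2 tile is paired to the Library 1 tile it overlaps most (ties break
toward the left, i.e. smaller-start, tile); agreement is then the number of
Library 2 candidates whose partner is also a Library 1 candidate.  Under
independence of the two call sets the expected count is n2 * n1 / N1, and a
Pearson chi-squared test on the 2x2 pairing table (Library 2 candidate
yes/no x partner candidate yes/no) measures the excess.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd
from scipy import stats

from .library_design import TileLibrary

__all__ = ["OverlapResult", "pair_tiles", "overlap_stats", "PVALUE_FLOOR"]

#: Reporting floor for vanishing p-values ("< 2.2e-16").
PVALUE_FLOOR = 2.2e-16


@dataclass(frozen=True)
class OverlapResult:
    n1: int  # Library 1 candidates
    N1: int  # Library 1 tiles
    n2: int  # Library 2 candidates
    N2: int  # Library 2 tiles
    observed: int  # candidate-candidate pairs
    expected: float  # n2 * n1 / N1
    chi2: float
    pvalue: float

    @property
    def pvalue_text(self) -> str:
        if self.pvalue < PVALUE_FLOOR:
            return f"< {PVALUE_FLOOR:.1e}"
        return f"{self.pvalue:.3g}"


def pair_tiles(lib1: TileLibrary, lib2: TileLibrary) -> pd.DataFrame:
    """Pair each Library 2 tile to its maximally overlapping Library 1 tile.

    Returns a DataFrame with columns lib2_tile_id, lib1_tile_id,
    overlap_bp.  Ties in overlap length break toward the tile with the
    smaller start.  Raises if no Library 2 tile overlaps any Library 1
    tile.
    """
    t1 = sorted(lib1.tiles, key=lambda t: t.start)
    t2_sorted = sorted(lib2.tiles, key=lambda t: t.start)
    rows = []
    i0 = 0  # both tilings sorted: sweep once
    for t2 in t2_sorted:
        while i0 < len(t1) and t1[i0].end <= t2.start:
            i0 += 1
        best_id, best_ov, best_start = None, 0, None
        for t in t1[i0:]:
            if t.start >= t2.end:
                break
            ov = min(t.end, t2.end) - max(t.start, t2.start)
            if ov > best_ov or (ov == best_ov and ov > 0 and t.start < best_start):
                best_id, best_ov, best_start = t.tile_id, ov, t.start
        if best_id is not None:
            rows.append(
                {"lib2_tile_id": t2.tile_id, "lib1_tile_id": best_id, "overlap_bp": best_ov}
            )
    if not rows:
        raise ValueError("libraries are disjoint: no overlapping tiles")
    return pd.DataFrame(rows)


def overlap_stats(
    pairing: pd.DataFrame,
    calls1: Mapping[str, bool] | pd.Series,
    calls2: Mapping[str, bool] | pd.Series,
    continuity_correction: bool = False,
) -> OverlapResult:
    """Observed vs independence-expected candidate-candidate pair count.

    ``calls1``/``calls2`` map every tile id of each library to its
    candidate status; ``pairing`` comes from :func:`pair_tiles`.  The
    chi-squared statistic is computed from the 2x2 table over all paired
    Library 2 tiles, without continuity correction by default.
    """
    c1 = pd.Series(dict(calls1), dtype=bool)
    c2 = pd.Series(dict(calls2), dtype=bool)
    N1, N2 = len(c1), len(c2)
    if N1 == 0 or N2 == 0:
        raise ValueError("call sets must be non-empty")
    n1, n2 = int(c1.sum()), int(c2.sum())

    lib2_cand = c2.reindex(pairing["lib2_tile_id"]).to_numpy()
    partner_cand = c1.reindex(pairing["lib1_tile_id"]).to_numpy()
    observed = int((lib2_cand & partner_cand).sum())
    expected = n2 * n1 / N1

    table = [
        [observed, int((lib2_cand & ~partner_cand).sum())],
        [int((~lib2_cand & partner_cand).sum()), int((~lib2_cand & ~partner_cand).sum())],
    ]
    row_sums = [sum(r) for r in table]
    col_sums = [table[0][0] + table[1][0], table[0][1] + table[1][1]]
    if 0 in row_sums or 0 in col_sums:
        chi2, pvalue = float("nan"), float("nan")
    else:
        res = stats.chi2_contingency(table, correction=continuity_correction)
        chi2, pvalue = float(res.statistic), float(res.pvalue)
    return OverlapResult(
        n1=n1, N1=N1, n2=n2, N2=N2,
        observed=observed, expected=expected, chi2=chi2, pvalue=pvalue,
    )
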