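"""Read counting and QC: reads → counts → per-sub-library percentages.

A read contributes to a tile's count only if its sequence matches the
tile's full adapter-flanked construct exactly (optionally also its reverse
complement, for sequencers that read either strand); everything else is
tallied as unmatched.  The matched fraction is the recovery rate.  Counts
are converted to within-sub-library percentages with a small pseudocount so
that downstream NE/buffer ratios are always defined.

Replicate concordance is summarized as the pairwise Pearson R² between
same-condition, same-round replicate percentage vectors; a well-behaved
screen shows R² > 0.99.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import reverse_complement
from scipy import stats

from .library_design import TileLibrary, build_constructs
from .sim_selection import CountMatrix, ScreenDesign

__all__ = [
    "PercentageMatrix",
    "QCReport",
    "assign_reads",
    "to_percentages",
    "replicate_concordance",
]


@dataclass
class PercentageMatrix:
    """Per-sub-library tile fractions (each column sums to 1)."""

    fractions: pd.DataFrame
    pseudocount: float
    source: CountMatrix | None = None

    def __post_init__(self) -> None:
        sums = self.fractions.sum(axis=0).to_numpy()
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("each sub-library column must sum to 1")

    def column(self, condition: str, round_: int, replicate: int) -> pd.Series:
        return self.fractions[(condition, round_, replicate)]

    def to_tidy(self) -> pd.DataFrame:
        tidy = (
            self.fractions.stack([0, 1, 2], future_stack=True)
            .rename("fraction")
            .reset_index()
        )
        tidy.columns = ["tile_id", "condition", "round", "replicate", "fraction"]
        return tidy

    def to_tsv(self, path: str | Path) -> None:
        self.to_tidy().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, pseudocount: float = float("nan")) -> "PercentageMatrix":
        tidy = pd.read_csv(path, sep="\t")
        wide = tidy.pivot_table(
            index="tile_id",
            columns=["condition", "round", "replicate"],
            values="fraction",
        )
        wide = wide.loc[tidy["tile_id"].drop_duplicates().to_list()]
        return cls(fractions=wide, pseudocount=pseudocount)


@dataclass
class QCReport:
    """Per-sub-library recovery statistics plus replicate concordance."""

    sublibraries: pd.DataFrame  # condition, round, replicate, total/matched reads, recovery_rate
    concordance: pd.DataFrame | None = None
    flags: list[str] = field(default_factory=list)

    @property
    def overall_recovery_rate(self) -> float:
        total = self.sublibraries["total_reads"].sum()
        if total == 0:
            return float("nan")
        return float(self.sublibraries["matched_reads"].sum() / total)


def assign_reads(
    fastq_manifest: pd.DataFrame,
    lib: TileLibrary,
    accept_reverse_complement: bool = True,
) -> tuple[CountMatrix, QCReport]:
    """Count exact construct matches per sub-library.

    ``fastq_manifest`` needs columns condition, round, replicate, path (one
    row per sub-library FASTQ, as produced by
    :func:`reelscan.sim_selection.simulate_reads`).  A read counts for a
    tile iff it equals the construct (or, by default, its reverse
    complement) over the full length; no alignment, no partial matches.
    """
    required = {"condition", "round", "replicate", "path"}
    missing = required - set(fastq_manifest.columns)
    if missing:
        raise ValueError(f"fastq manifest missing columns: {sorted(missing)}")

    lookup: dict[str, str] = {}
    for c in build_constructs(lib):
        seq = c.full_sequence
        lookup[seq] = c.tile.tile_id
        if accept_reverse_complement:
            lookup.setdefault(reverse_complement(seq), c.tile.tile_id)

    tile_ids = lib.tile_ids
    columns: dict[tuple[str, int, int], pd.Series] = {}
    qc_rows = []
    flags: list[str] = []
    for row in fastq_manifest.itertuples():
        key = (row.condition, int(row.round), int(row.replicate))
        counts = dict.fromkeys(tile_ids, 0)
        total = matched = 0
        for rec in SeqIO.parse(str(row.path), "fastq"):
            total += 1
            tile = lookup.get(str(rec.seq).upper())
            if tile is not None:
                counts[tile] += 1
                matched += 1
        if total == 0:
            flags.append(f"empty FASTQ for sub-library {key}")
            warnings.warn(f"empty FASTQ for sub-library {key}", stacklevel=2)
        columns[key] = pd.Series(counts)
        qc_rows.append(
            {
                "condition": key[0],
                "round": key[1],
                "replicate": key[2],
                "total_reads": total,
                "matched_reads": matched,
                "recovery_rate": matched / total if total else float("nan"),
            }
        )

    wide = pd.DataFrame(columns)
    wide.index.name = "tile_id"
    wide.columns = pd.MultiIndex.from_tuples(
        wide.columns, names=["condition", "round", "replicate"]
    )
    rounds = tuple(sorted({k[1] for k in columns}))
    design = ScreenDesign(
        rounds_total=max(rounds),
        rounds_sequenced=rounds,
        replicates=max(2, len({k[2] for k in columns})),
        depth=max(int(wide.sum(axis=0).max()), 1),
    )
    cm = CountMatrix(counts=wide, design=design, library_id=lib.library_id)
    qc = QCReport(sublibraries=pd.DataFrame(qc_rows), flags=flags)
    return cm, qc


def to_percentages(cm: CountMatrix, pseudocount: float = 0.5) -> PercentageMatrix:
    """Normalize each sub-library column to fractions after adding
    ``pseudocount`` to every tile (keeps downstream ratios finite)."""
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    padded = cm.counts.astype(float) + pseudocount
    sums = padded.sum(axis=0)
    if (sums == 0).any():
        raise ValueError("empty sub-library: all-zero column with pseudocount 0")
    frac = padded / sums
    return PercentageMatrix(fractions=frac, pseudocount=pseudocount, source=cm)


def replicate_concordance(
    pct: PercentageMatrix, threshold: float = 0.99
) -> pd.DataFrame:
    """Pairwise Pearson R² between replicate percentage vectors.

    One row per (condition, round, replicate pair) with the correlation,
    its square, and a flag when R² falls below ``threshold`` or when the
    correlation is negative despite a passing R² (sign anomaly).  Constant
    vectors leave R² undefined (NaN, flagged).
    """
    cols = pct.fractions.columns
    out = []
    for (cond, rnd), group in itertools.groupby(
        sorted(cols), key=lambda c: (c[0], c[1])
    ):
        reps = [c[2] for c in group]
        for ra, rb in itertools.combinations(reps, 2):
            x = pct.fractions[(cond, rnd, ra)].to_numpy()
            y = pct.fractions[(cond, rnd, rb)].to_numpy()
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                warnings.warn(
                    f"constant replicate vector in ({cond}, {rnd}); R² undefined",
                    stacklevel=2,
                )
                r, r2, flag = float("nan"), float("nan"), "undefined"
            else:
                r = float(stats.pearsonr(x, y).statistic)
                r2 = r * r
                if r2 < threshold:
                    flag = "low_r2"
                elif r < 0:
                    flag = "sign_anomaly"
                else:
                    flag = ""
            out.append(
                {
                    "condition": cond,
                    "round": rnd,
                    "replicate_a": ra,
                    "replicate_b": rb,
                    "pearson_r": r,
                    "r_squared": r2,
                    "flag": flag,
                }
            )
    return pd.DataFrame(out)
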