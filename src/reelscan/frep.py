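"""Specific-binder calling from duplicate pulldown spectral counts.

A DNA-pulldown/mass-spectrometry experiment for one regulatory element is
run in duplicate alongside two negative controls, giving each detected
protein four peptide spectral counts (sample1, sample2, control1,
control2).  The decision rule is strict presence/absence: a protein is a
specific binder iff it has peptide counts in **both** samples and in
**neither** control.  Any count in a control, or absence from either
sample, rejects the protein.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = [
    "PeptideCountTable",
    "call_binders",
    "summarize_binders",
    "load_example_table",
    "REASON_SPECIFIC",
    "REASON_CONTROL",
    "REASON_SINGLE_SAMPLE",
]

REASON_SPECIFIC = "both-samples-positive-controls-zero"
REASON_CONTROL = "control-positive"
REASON_SINGLE_SAMPLE = "single-sample-only"

_COUNT_COLS = ["sample1", "sample2", "control1", "control2"]


@dataclass
class PeptideCountTable:
    """Spectral counts for one element: protein x (2 samples, 2 controls)."""

    element: str
    counts: pd.DataFrame  # index: protein id; columns: _COUNT_COLS

    def __post_init__(self) -> None:
        missing = set(_COUNT_COLS) - set(self.counts.columns)
        if missing:
            raise ValueError(f"missing count columns: {sorted(missing)}")
        if self.counts.index.duplicated().any():
            dupes = self.counts.index[self.counts.index.duplicated()].tolist()
            raise ValueError(f"duplicate protein ids: {dupes}")
        if (self.counts[_COUNT_COLS].to_numpy() < 0).any():
            raise ValueError("spectral counts must be non-negative")

    @classmethod
    def from_tsv(cls, path: str | Path, element: str | None = None) -> list["PeptideCountTable"]:
        """Load one table per element from a TSV with columns protein,
        sample1, sample2, control1, control2, element."""
        df = pd.read_csv(path, sep="\t")
        if element is not None:
            df = df[df["element"] == element]
        return [
            cls(element=el, counts=grp.set_index("protein")[_COUNT_COLS])
            for el, grp in df.groupby("element", sort=False)
        ]


def call_binders(table: PeptideCountTable) -> pd.DataFrame:
    """Apply the presence/absence rule to every protein.

    Returns a DataFrame indexed by protein id with ``is_specific`` and a
    ``reason`` column: control-positive proteins (background binders) are
    eliminated first; of the rest, only proteins seen in both samples are
    kept.
    """
    c = table.counts
    control_pos = (c["control1"] > 0) | (c["control2"] > 0)
    both_samples = (c["sample1"] > 0) & (c["sample2"] > 0)
    is_specific = both_samples & ~control_pos
    reason = pd.Series(REASON_SINGLE_SAMPLE, index=c.index, name="reason")
    reason[control_pos] = REASON_CONTROL
    reason[is_specific] = REASON_SPECIFIC
    return pd.DataFrame({"is_specific": is_specific, "reason": reason})


def summarize_binders(tables: list[PeptideCountTable]) -> pd.DataFrame:
    """Per-element specific-binder count and sorted identities."""
    if not tables:
        raise ValueError("need at least one peptide count table")
    rows = []
    for t in tables:
        calls = call_binders(t)
        binders = sorted(calls.index[calls["is_specific"]])
        rows.append(
            {"element": t.element, "n_specific": len(binders), "binders": binders}
        )
    return pd.DataFrame(rows).set_index("element")


def load_example_table() -> list[PeptideCountTable]:
    """The packaged worked example: spectral counts for the two elements
    S1606 and S961 characterized in the source screen."""
    path = resources.files("reelscan.data") / "frep_s1606_s961_table.tsv"
    return PeptideCountTable.from_tsv(str(path))
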