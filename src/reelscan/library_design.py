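"""Dual-offset tiling library design for EMSA depletion screens.

A target genomic region is covered twice by short synthesizable fragments:
Library 1 tiles the region end to end with abutting, fixed-length (default
35 bp) fragments, and Library 2 repeats the tiling shifted by a fixed
offset (default 17 bp) so that every junction between two adjacent
Library 1 fragments falls well inside a Library 2 fragment.  A regulatory
protein footprint (~6-12 bp) broken across a Library 1 junction is then
intact in the overlapping Library 2 tile, so no binding site is lost to
fragment boundaries.

Each tile insert is flanked by two constant adapters that serve both as PCR
amplification primers between selection rounds and as sequencing primers.

Coordinates are 0-based half-open (BED convention) throughout.  Tile
coordinates are relative to the supplied region; absolute genome coordinates
are obtained by adding the region start and appear in BED/FASTA output.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GenomicRegion",
    "Tile",
    "Construct",
    "TileLibrary",
    "design_tiling",
    "build_constructs",
    "write_library",
    "read_library",
    "read_region_fasta",
    "DEFAULT_ADAPTER5",
    "DEFAULT_ADAPTER3",
]

_VALID_REGION = re.compile(r"^[ACGTN]*$")
_VALID_ADAPTER = re.compile(r"^[ACGT]+$")

#: Placeholder amplification/sequencing adapters.  The screen protocol uses
#: library-specific primer pairs; supply the real ones via configuration.
DEFAULT_ADAPTER5 = "GTAAAACGACGGCCAGTGCC"
DEFAULT_ADAPTER3 = "GGCACTGGCCGTCGTTTTAC"


@dataclass(frozen=True)
class GenomicRegion:
    """A contiguous genomic interval with its sequence.

    ``start``/``end`` are absolute, 0-based half-open chromosome
    coordinates; ``sequence`` must have length ``end - start`` and contain
    only A/C/G/T/N.
    """

    chrom: str
    start: int
    end: int
    sequence: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"end ({self.end}) must exceed start ({self.start})")
        if len(self.sequence) != self.end - self.start:
            raise ValueError(
                f"sequence length {len(self.sequence)} != end - start "
                f"({self.end - self.start})"
            )
        if not _VALID_REGION.match(self.sequence):
            raise ValueError("invalid sequence: alphabet must be A/C/G/T/N (uppercase)")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Tile:
    """One library fragment: a fixed-length slice of the region."""

    tile_id: str
    library_id: int
    start: int  # region-relative, 0-based
    end: int  # region-relative, half-open
    insert: str

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.insert):
            raise ValueError(
                f"{self.tile_id}: insert length {len(self.insert)} != "
                f"interval length {self.end - self.start}"
            )

    @property
    def contains_n(self) -> bool:
        return "N" in self.insert


@dataclass(frozen=True)
class Construct:
    """A synthesizable oligo: adapter5 + insert + adapter3."""

    tile: Tile
    adapter5: str
    adapter3: str

    @property
    def full_sequence(self) -> str:
        return self.adapter5 + self.tile.insert + self.adapter3

    def __len__(self) -> int:
        return len(self.adapter5) + len(self.tile.insert) + len(self.adapter3)


@dataclass
class TileLibrary:
    """An ordered tiling of one region by one library.

    Library 1 tiles abut; Library 2 tiles abut among themselves but are
    shifted relative to Library 1 so each covers a Library 1 junction.
    """

    library_id: int
    tiles: list[Tile]
    chrom: str
    region_start: int
    region_end: int
    adapter5: str = DEFAULT_ADAPTER5
    adapter3: str = DEFAULT_ADAPTER3

    def __post_init__(self) -> None:
        ids = [t.tile_id for t in self.tiles]
        if len(set(ids)) != len(ids):
            raise ValueError("tile_ids must be unique within a library")

    def __len__(self) -> int:
        return len(self.tiles)

    def __iter__(self) -> Iterator[Tile]:
        return iter(self.tiles)

    @property
    def tile_ids(self) -> list[str]:
        return [t.tile_id for t in self.tiles]


def design_tiling(
    region: GenomicRegion, tile_len: int = 35, offset: int = 17
) -> tuple[TileLibrary, TileLibrary]:
    """Tile ``region`` into two offset libraries of ``tile_len`` fragments.

    Library 1 tiles start at 0, tile_len, 2*tile_len, ...; Library 2 tiles
    start at ``offset``, offset + tile_len, ....  A trailing residue shorter
    than ``tile_len`` is dropped (inserts must be exactly tile_len for
    synthesis and exact-match counting).  Tile ids are ``S1, S2, ...``
    within each library.
    """
    if tile_len < 6:
        raise ValueError(f"tile_len must be >= 6, got {tile_len}")
    if not 0 < offset < tile_len:
        raise ValueError(f"offset must lie in (0, tile_len), got {offset}")
    if len(region) < tile_len:
        raise ValueError(
            f"region too short: {len(region)} bp < tile_len {tile_len} bp"
        )

    def _tiles(first_start: int, library_id: int) -> list[Tile]:
        out: list[Tile] = []
        i = 1
        for s in range(first_start, len(region) - tile_len + 1, tile_len):
            out.append(
                Tile(
                    tile_id=f"S{i}",
                    library_id=library_id,
                    start=s,
                    end=s + tile_len,
                    insert=region.sequence[s : s + tile_len],
                )
            )
            i += 1
        return out

    common = dict(
        chrom=region.chrom, region_start=region.start, region_end=region.end
    )
    lib1 = TileLibrary(library_id=1, tiles=_tiles(0, 1), **common)
    lib2 = TileLibrary(library_id=2, tiles=_tiles(offset, 2), **common)
    return lib1, lib2


def build_constructs(
    lib: TileLibrary,
    adapter5: str | None = None,
    adapter3: str | None = None,
    include_n: bool = False,
) -> list[Construct]:
    """Flank each tile insert with adapters, preserving tile order.

    Tiles containing N are excluded by default: an ambiguous base cannot be
    synthesized as a definite EMSA probe.  Pass ``include_n=True`` to keep
    them.
    """
    a5 = lib.adapter5 if adapter5 is None else adapter5
    a3 = lib.adapter3 if adapter3 is None else adapter3
    for name, a in (("adapter5", a5), ("adapter3", a3)):
        if not a or not _VALID_ADAPTER.match(a):
            raise ValueError(f"{name} must be a non-empty A/C/G/T string")
    return [
        Construct(tile=t, adapter5=a5, adapter3=a3)
        for t in lib.tiles
        if include_n or not t.contains_n
    ]


def write_library(lib: TileLibrary, prefix: str | Path) -> dict[str, Path]:
    """Write a library as ``<prefix>.fasta`` (constructs), ``<prefix>.bed``
    (absolute tile coordinates) and ``<prefix>.tsv`` (lossless manifest).

    N-containing tiles are flagged in the manifest and omitted from the
    synthesis FASTA.  Returns the written paths.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    fasta_path = prefix.with_suffix(".fasta")
    bed_path = prefix.with_suffix(".bed")
    tsv_path = prefix.with_suffix(".tsv")

    records = []
    for c in build_constructs(lib):
        t = c.tile
        abs_s, abs_e = lib.region_start + t.start, lib.region_start + t.end
        records.append(
            SeqRecord(
                Seq(c.full_sequence),
                id=t.tile_id,
                description=(
                    f"library={lib.library_id} "
                    f"region={lib.chrom}:{abs_s}-{abs_e} rel={t.start}-{t.end}"
                ),
            )
        )
    SeqIO.write(records, str(fasta_path), "fasta")

    with open(bed_path, "w") as fh:
        for t in lib.tiles:
            fh.write(
                f"{lib.chrom}\t{lib.region_start + t.start}\t"
                f"{lib.region_start + t.end}\t{t.tile_id}\t0\t+\n"
            )

    manifest = pd.DataFrame(
        {
            "tile_id": [t.tile_id for t in lib.tiles],
            "library_id": lib.library_id,
            "chrom": lib.chrom,
            "start": [t.start for t in lib.tiles],
            "end": [t.end for t in lib.tiles],
            "insert": [t.insert for t in lib.tiles],
            "contains_n": [t.contains_n for t in lib.tiles],
        }
    )
    with open(tsv_path, "w") as fh:
        fh.write(f"# library_id={lib.library_id}\n")
        fh.write(f"# chrom={lib.chrom}\n")
        fh.write(f"# region_start={lib.region_start}\n")
        fh.write(f"# region_end={lib.region_end}\n")
        fh.write(f"# adapter5={lib.adapter5}\n")
        fh.write(f"# adapter3={lib.adapter3}\n")
        manifest.to_csv(fh, sep="\t", index=False)
    return {"fasta": fasta_path, "bed": bed_path, "tsv": tsv_path}


def read_library(path: str | Path) -> TileLibrary:
    """Reconstruct a :class:`TileLibrary` from a manifest TSV (or prefix).

    Round-trips losslessly with :func:`write_library`.
    """
    path = Path(path)
    if path.suffix != ".tsv":
        path = path.with_suffix(".tsv")
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            try:
                key, value = line[1:].strip().split("=", 1)
            except ValueError as exc:
                raise ValueError(f"malformed manifest header line: {line!r}") from exc
            meta[key.strip()] = value
    required = {"library_id", "chrom", "region_start", "region_end", "adapter5", "adapter3"}
    missing = required - meta.keys()
    if missing:
        raise ValueError(f"manifest {path} missing header keys: {sorted(missing)}")

    df = pd.read_csv(path, sep="\t", comment="#", dtype={"tile_id": str, "insert": str})
    library_id = int(meta["library_id"])
    tiles = [
        Tile(
            tile_id=row.tile_id,
            library_id=library_id,
            start=int(row.start),
            end=int(row.end),
            insert=row.insert,
        )
        for row in df.itertuples()
    ]
    return TileLibrary(
        library_id=library_id,
        tiles=tiles,
        chrom=meta["chrom"],
        region_start=int(meta["region_start"]),
        region_end=int(meta["region_end"]),
        adapter5=meta["adapter5"],
        adapter3=meta["adapter3"],
    )


def read_region_fasta(
    path: str | Path, chrom: str | None = None, start: int = 0
) -> GenomicRegion:
    """Load a region from FASTA.  With a multi-record file, ``chrom``
    selects the record; ``start`` is the absolute coordinate of base 0."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    if chrom is None:
        rec = records[0]
    else:
        matches = [r for r in records if r.id == chrom]
        if not matches:
            raise ValueError(f"record {chrom!r} not found in {path}")
        rec = matches[0]
    seq = str(rec.seq).upper()
    return GenomicRegion(chrom=rec.id, start=start, end=start + len(seq), sequence=seq)
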