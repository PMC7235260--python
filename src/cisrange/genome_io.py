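"""Genomic interval I/O and coordinate bookkeeping.

All coordinates are BED-style 0-based half-open internally; conversion, if any,
happens only at I/O boundaries.  TADs (topologically associating domains) are
the unit of chromatin context: genes and peaks are assigned to the unique TAD
whose interval contains their representative point.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

DEFAULT_PEAK_CAP = 20_000
DEFAULT_PEAK_MINIMUM = 20_000


class GenomeFormatError(ValueError):
    """Raised when an input file violates the expected tabular/BED contract."""


@dataclass(frozen=True)
class Gene:
    gene_id: str
    chrom: str
    tss: int
    strand: str


@dataclass(frozen=True)
class Tad:
    tad_id: str
    chrom: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GenomeLayout:
    """Genes (TSS + strand) and TADs, with the gene→TAD assignment.

    Genes whose TSS falls in no TAD stay in ``genes`` but are absent from
    ``gene_to_tad``; they are reported, never silently dropped.
    """

    genes: list[Gene]
    tads: list[Tad]
    gene_to_tad: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for tad in self.tads:
            if tad.start >= tad.end:
                raise GenomeFormatError(
                    f"TAD {tad.tad_id}: start {tad.start} >= end {tad.end}"
                )
        self._trees = _build_tad_trees(self.tads)
        if not self.gene_to_tad:
            self.gene_to_tad = {
                g.gene_id: tid
                for g in self.genes
                if (tid := self.tad_of_point(g.chrom, g.tss)) is not None
            }
        unmapped = [g.gene_id for g in self.genes if g.gene_id not in self.gene_to_tad]
        if unmapped:
            logger.info(
                "%d/%d genes have a TSS outside all TADs and are excluded from "
                "TAD-restricted computations",
                len(unmapped),
                len(self.genes),
            )
        self.unmapped_genes = unmapped

    def tad_of_point(self, chrom: str, pos: int) -> str | None:
        tree = self._trees.get(chrom)
        if tree is None:
            return None
        hits = tree[pos]
        if not hits:
            return None
        return next(iter(hits)).data

    @property
    def tad_ids(self) -> list[str]:
        return [t.tad_id for t in self.tads]

    def tad_by_id(self, tad_id: str) -> Tad:
        return self._tad_index[tad_id]

    @property
    def _tad_index(self) -> dict[str, Tad]:
        return {t.tad_id: t for t in self.tads}

    def mapped_genes(self) -> list[Gene]:
        return [g for g in self.genes if g.gene_id in self.gene_to_tad]


def _build_tad_trees(tads: Sequence[Tad]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for tad in tads:
        tree = trees.setdefault(tad.chrom, IntervalTree())
        overlapping = tree[tad.start:tad.end]
        if overlapping:
            other = next(iter(overlapping)).data
            raise GenomeFormatError(
                f"overlapping TADs on {tad.chrom}: {tad.tad_id} and {other}"
            )
        tree[tad.start:tad.end] = tad.tad_id
    return trees


@dataclass
class PeakSet:
    """One TF ChIP-seq sample: intervals with intensities.

    ``peaks`` is a DataFrame with columns chrom, start, end, intensity.
    """

    tf_id: str
    sample_id: str
    peaks: pd.DataFrame
    discarded: bool = False

    def __post_init__(self) -> None:
        required = {"chrom", "start", "end"}
        missing = required - set(self.peaks.columns)
        if missing:
            raise GenomeFormatError(f"peak table missing columns: {sorted(missing)}")
        bad = self.peaks["start"] >= self.peaks["end"]
        if bad.any():
            idx = int(np.flatnonzero(bad.to_numpy())[0])
            raise GenomeFormatError(
                f"peak {idx} of sample {self.sample_id}: start >= end"
            )

    def __len__(self) -> int:
        return len(self.peaks)

    def representative_points(self, use_summit: bool = False) -> np.ndarray:
        """Per-peak representative bp coordinate (midpoint, or summit column)."""
        if use_summit:
            if "summit" not in self.peaks.columns:
                raise GenomeFormatError("summit column requested but absent")
            return self.peaks["summit"].to_numpy(dtype=np.int64)
        start = self.peaks["start"].to_numpy(dtype=np.int64)
        end = self.peaks["end"].to_numpy(dtype=np.int64)
        return (start + end) // 2


def peak_representative_point(start: int, end: int) -> int:
    """Midpoint of a half-open interval, floored: [100,201) -> 150."""
    return (start + end) // 2


def read_intervals(path: str | Path, kind: str = "tad") -> pd.DataFrame:
    """Read a BED-like file into a validated interval table.

    Returns a DataFrame with chrom/start/end plus name and intensity (from the
    BED name and score columns) when present.  Coordinates are kept 0-based
    half-open as in the file.
    """
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise GenomeFormatError(f"{path}:{lineno}: fewer than 3 columns")
            chrom, s, e = parts[0], parts[1], parts[2]
            try:
                start, end = int(s), int(e)
            except ValueError as exc:
                raise GenomeFormatError(
                    f"{path}:{lineno}: non-integer coordinates {s!r}, {e!r}"
                ) from exc
            if end <= start:
                raise GenomeFormatError(
                    f"{path}:{lineno}: end {end} <= start {start}"
                )
            row: dict = {"chrom": chrom, "start": start, "end": end}
            if len(parts) >= 4:
                row["name"] = parts[3]
            if len(parts) >= 5:
                try:
                    row["intensity"] = float(parts[4])
                except ValueError as exc:
                    raise GenomeFormatError(
                        f"{path}:{lineno}: non-numeric score {parts[4]!r}"
                    ) from exc
            rows.append(row)
    df = pd.DataFrame(rows)
    if df.empty:
        df = pd.DataFrame(columns=["chrom", "start", "end"])
    df.attrs["kind"] = kind
    return df


def write_intervals(df: pd.DataFrame, path: str | Path, comments: Iterable[str] = ()) -> None:
    """Write an interval table as BED (tab-separated, no header, '#' comments)."""
    cols = [c for c in ("chrom", "start", "end", "name", "intensity") if c in df.columns]
    with open(path, "w") as fh:
        for c in comments:
            fh.write(f"# {c}\n")
        df[cols].to_csv(fh, sep="\t", header=False, index=False)


def read_gene_annotation(path: str | Path) -> list[Gene]:
    """Read a gene table (gene_id, chrom, start, end, strand) into TSS records.

    TSS is ``start`` on the '+' strand and ``end - 1`` on the '−' strand
    (0-based, half-open input intervals).
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"gene_id", "chrom", "start", "end", "strand"}
    missing = required - set(df.columns)
    if missing:
        raise GenomeFormatError(f"gene annotation missing columns: {sorted(missing)}")
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise GenomeFormatError(f"duplicate gene_id {dup!r}")
    genes = []
    for row in df.itertuples(index=False):
        if row.strand == "+":
            tss = int(row.start)
        elif row.strand in ("-", "−"):
            tss = int(row.end) - 1
        else:
            raise GenomeFormatError(
                f"gene {row.gene_id}: unknown strand symbol {row.strand!r}"
            )
        genes.append(Gene(str(row.gene_id), str(row.chrom), tss, "+" if row.strand == "+" else "-"))
    return genes


def write_gene_annotation(genes: Sequence[Gene], path: str | Path) -> None:
    # 1-bp intervals anchored at the TSS round-trip the TSS on either strand:
    # '+' reads back start, '-' reads back end-1, both equal tss.
    df = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "chrom": [g.chrom for g in genes],
            "start": [g.tss for g in genes],
            "end": [g.tss + 1 for g in genes],
            "strand": [g.strand for g in genes],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def assign_to_tads(
    points: Mapping[str, tuple[str, int]] | Sequence[tuple[str, str, int]],
    tads: Sequence[Tad],
) -> dict[str, str | None]:
    """Map named points to the unique containing TAD (or None).

    ``points`` is either a mapping name -> (chrom, pos) or a sequence of
    (name, chrom, pos) triples.  Overlapping TADs on one chromosome raise at
    index-build time.
    """
    trees = _build_tad_trees(tads)
    if isinstance(points, Mapping):
        items = [(k, v[0], v[1]) for k, v in points.items()]
    else:
        items = list(points)
    out: dict[str, str | None] = {}
    for name, chrom, pos in items:
        tree = trees.get(chrom)
        hits = tree[pos] if tree is not None else set()
        out[name] = next(iter(hits)).data if hits else None
    return out


def filter_peaks(
    peakset: PeakSet,
    cap: int = DEFAULT_PEAK_CAP,
    minimum: int | None = None,
) -> PeakSet:
    """Apply the sample-level peak-count rules.

    Samples with fewer than ``minimum`` peaks (default: the cap) are flagged
    discarded; otherwise exactly the ``cap`` highest-intensity peaks are kept.
    Ties at the cutoff break deterministically by (intensity desc, chrom, start).
    Idempotent: filtering an already-filtered sample changes nothing.
    """
    if minimum is None:
        minimum = cap
    if "intensity" not in peakset.peaks.columns:
        raise GenomeFormatError("peak filtering requires an intensity column")
    n = len(peakset)
    if n < minimum:
        return replace(peakset, discarded=True)
    if n <= cap:
        return peakset
    ordered = peakset.peaks.sort_values(
        by=["intensity", "chrom", "start"],
        ascending=[False, True, True],
        kind="mergesort",
    ).head(cap)
    kept = ordered.sort_index().reset_index(drop=True)
    return replace(peakset, peaks=kept)
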