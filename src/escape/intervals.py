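"""Genomic interval data model, interval-set algebra, and text-format I/O.

Coordinates are BED-native throughout: 0-based, half-open ``[start, end)``.
Two intervals on the same chromosome overlap when they share at least one
base; strand is ignored for all interval algebra and only used for TSS
placement and read 5' ends.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "GenomicInterval",
    "RegionSet",
    "GeneModel",
    "ReadTrack",
    "overlaps",
    "merge_intervals",
    "subset_overlapping",
    "read_bed",
    "write_bed",
    "read_reads",
    "write_reads",
    "read_genome",
    "write_genome",
    "read_gene_table",
    "write_gene_table",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic span ``[start, end)`` with optional score/name."""

    chrom: str
    start: int
    end: int
    score: float | None = None
    name: str | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chromosome name must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff ``a`` and ``b`` share at least one base."""
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


@dataclass
class RegionSet:
    """An ordered collection of intervals, optionally bound to a genome.

    ``genome`` maps chromosome name to length; when present, every interval
    must lie within its chromosome. :meth:`normalize` sorts by
    (chrom, start) and merges intervals that share bases, so a normalized
    set is non-overlapping within itself.
    """

    intervals: list[GenomicInterval] = field(default_factory=list)
    name: str = ""
    genome: dict[str, int] | None = None

    def __post_init__(self) -> None:
        self.intervals = list(self.intervals)
        if self.genome is not None:
            for iv in self.intervals:
                self._check_bounds(iv)

    def _check_bounds(self, iv: GenomicInterval) -> None:
        assert self.genome is not None
        if iv.chrom not in self.genome:
            raise ValueError(f"interval chromosome {iv.chrom!r} not in genome")
        if iv.end > self.genome[iv.chrom]:
            raise ValueError(
                f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds chromosome "
                f"length {self.genome[iv.chrom]}"
            )

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self.intervals[i]

    def sorted(self) -> "RegionSet":
        ivs = sorted(self.intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
        return RegionSet(ivs, name=self.name, genome=self.genome)

    def normalize(self) -> "RegionSet":
        """Sort and merge overlapping (>=1 shared base) intervals."""
        out: list[GenomicInterval] = []
        for iv in self.sorted():
            if out and iv.chrom == out[-1].chrom and iv.start < out[-1].end:
                prev = out[-1]
                if iv.end > prev.end:
                    out[-1] = GenomicInterval(prev.chrom, prev.start, iv.end)
            else:
                out.append(GenomicInterval(iv.chrom, iv.start, iv.end,
                                           score=iv.score, name=iv.name))
        return RegionSet(out, name=self.name, genome=self.genome)

    def by_chrom(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """(starts, ends) arrays per chromosome, in set order per chrom."""
        per: dict[str, tuple[list[int], list[int]]] = {}
        for iv in self.intervals:
            s, e = per.setdefault(iv.chrom, ([], []))
            s.append(iv.start)
            e.append(iv.end)
        return {
            c: (np.asarray(s, dtype=np.int64), np.asarray(e, dtype=np.int64))
            for c, (s, e) in per.items()
        }

    def total_bases(self) -> int:
        return sum(len(iv) for iv in self.intervals)


def _check_genomes(a: RegionSet, b: RegionSet) -> None:
    if a.genome is not None and b.genome is not None and a.genome != b.genome:
        raise ValueError("region sets are bound to different genome assemblies")


def overlap_flags(a: RegionSet, b: RegionSet) -> np.ndarray:
    """Boolean flag per interval of ``a``: overlaps >=1 member of ``b``.

    ``b`` should be normalized; with a sorted non-overlapping ``b`` the test
    per query reduces to a binary search on the start coordinates.
    """
    _check_genomes(a, b)
    b_norm = b.normalize()
    per_b = b_norm.by_chrom()
    flags = np.zeros(len(a), dtype=bool)
    for i, iv in enumerate(a.intervals):
        if iv.chrom not in per_b:
            continue
        starts, ends = per_b[iv.chrom]
        j = int(np.searchsorted(starts, iv.end, side="left"))
        flags[i] = j > 0 and ends[j - 1] > iv.start
    return flags


def subset_overlapping(a: RegionSet, b: RegionSet) -> RegionSet:
    """Members of ``a`` that overlap at least one member of ``b``.

    The result keeps ``a``'s coordinates (intersection never reshapes the
    anchor set), so counts are anchorable to ``a``.
    """
    flags = overlap_flags(a, b)
    ivs = [iv for iv, f in zip(a.intervals, flags) if f]
    return RegionSet(ivs, name=a.name, genome=a.genome)


def subset_nonoverlapping(a: RegionSet, b: RegionSet) -> RegionSet:
    """Complement of :func:`subset_overlapping` within ``a``."""
    flags = overlap_flags(a, b)
    ivs = [iv for iv, f in zip(a.intervals, flags) if not f]
    return RegionSet(ivs, name=a.name, genome=a.genome)


def union(*sets: RegionSet, name: str = "") -> RegionSet:
    """Normalized union of several region sets."""
    genome = None
    for s in sets:
        if s.genome is not None:
            if genome is not None and s.genome != genome:
                raise ValueError("region sets are bound to different genome assemblies")
            genome = s.genome
    ivs = [iv for s in sets for iv in s.intervals]
    return RegionSet(ivs, name=name, genome=genome).normalize()


def merge_intervals(a: RegionSet, max_gap: int = 0) -> RegionSet:
    """Merge intervals that overlap or are separated by <= ``max_gap`` bases."""
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    out: list[GenomicInterval] = []
    for iv in a.sorted():
        if out and iv.chrom == out[-1].chrom and iv.start - out[-1].end <= max_gap:
            prev = out[-1]
            if iv.end > prev.end:
                out[-1] = GenomicInterval(prev.chrom, prev.start, iv.end)
        else:
            out.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return RegionSet(out, name=a.name, genome=a.genome)


@dataclass(frozen=True)
class GeneModel:
    """A gene reduced to what expression and promoter analysis need."""

    gene_id: str
    chrom: str
    tss: int
    strand: str
    exonic_length: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.exonic_length < 1:
            raise ValueError("exonic_length must be >= 1")


class ReadTrack:
    """Per-chromosome read 5' positions with strand, plus library metadata.

    Positions are the 5' ends of sequenced tags (plus-strand start,
    minus-strand ``end - 1``). Signal extraction shifts each 5' end by
    ``shift`` bases toward 3' (strand-aware) to approximate fragment
    midpoints; the shift is applied lazily and cached.
    """

    def __init__(
        self,
        positions: Mapping[str, np.ndarray],
        strands: Mapping[str, np.ndarray],
        genome: Mapping[str, int] | None = None,
        spikein_reads: int | None = None,
        library_size: int | None = None,
    ) -> None:
        self.positions: dict[str, np.ndarray] = {}
        self.strands: dict[str, np.ndarray] = {}
        for chrom, pos in positions.items():
            pos = np.asarray(pos, dtype=np.int64)
            st = np.asarray(strands[chrom], dtype=np.int8)
            if pos.shape != st.shape:
                raise ValueError("positions and strands must align per chromosome")
            order = np.argsort(pos, kind="stable")
            self.positions[chrom] = pos[order]
            self.strands[chrom] = st[order]
        self.genome = dict(genome) if genome is not None else None
        n = int(sum(p.size for p in self.positions.values()))
        self.library_size = n if library_size is None else int(library_size)
        self.spikein_reads = spikein_reads
        self._shift_cache: dict[int, dict[str, np.ndarray]] = {}
        if n == 0:
            warnings.warn("read track is empty (library size 0)", stacklevel=2)

    @property
    def n_reads(self) -> int:
        return int(sum(p.size for p in self.positions.values()))

    def chroms(self) -> list[str]:
        return list(self.positions)

    def shifted_positions(self, chrom: str, shift: int = 0) -> np.ndarray:
        """Sorted strand-aware shifted positions for one chromosome."""
        if chrom not in self.positions:
            return np.empty(0, dtype=np.int64)
        if shift == 0:
            return self.positions[chrom]
        cache = self._shift_cache.setdefault(shift, {})
        if chrom not in cache:
            pos = self.positions[chrom] + shift * self.strands[chrom].astype(np.int64)
            hi = None if self.genome is None else self.genome.get(chrom)
            pos = np.clip(pos, 0, None if hi is None else hi - 1)
            pos.sort(kind="stable")
            cache[chrom] = pos
        return cache[chrom]

    def count_in(self, chrom: str, start: int, end: int, shift: int = 0) -> int:
        """Number of (shifted) read positions in ``[start, end)``."""
        pos = self.shifted_positions(chrom, shift)
        return int(np.searchsorted(pos, end, "left") - np.searchsorted(pos, start, "left"))

    def counts_for(
        self, regions: Sequence[GenomicInterval] | RegionSet, shift: int = 0
    ) -> np.ndarray:
        out = np.empty(len(regions), dtype=np.int64)
        for i, iv in enumerate(regions):
            out[i] = self.count_in(iv.chrom, iv.start, iv.end, shift)
        return out


# ---------------------------------------------------------------------------
# Text-format I/O. BED3/BED6 (tab-separated, no header), tagAlign (BED6 with
# 5'-end semantics), genome file = "chrom<TAB>length", gene table = TSV with
# header gene_id/chrom/tss/strand/exonic_length.
# ---------------------------------------------------------------------------

def _parse_int(text: str, what: str, path: str, lineno: int) -> int:
    try:
        return int(text)
    except ValueError:
        raise ValueError(f"{path}:{lineno}: malformed {what} {text!r}") from None


def read_bed(path: str, genome: Mapping[str, int] | None = None,
             name: str = "") -> RegionSet:
    """Read a 3+ column BED file; column 5 carries the score when present."""
    ivs: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 tab-separated columns")
            start = _parse_int(cols[1], "start", path, lineno)
            end = _parse_int(cols[2], "end", path, lineno)
            if end <= start or start < 0:
                raise ValueError(
                    f"{path}:{lineno}: invalid coordinates start={start} end={end}"
                )
            iv_name = cols[3] if len(cols) > 3 and cols[3] != "." else None
            score = None
            if len(cols) > 4 and cols[4] != ".":
                try:
                    score = float(cols[4])
                except ValueError:
                    raise ValueError(f"{path}:{lineno}: malformed score {cols[4]!r}") from None
            ivs.append(GenomicInterval(cols[0], start, end, score=score, name=iv_name))
    return RegionSet(ivs, name=name, genome=dict(genome) if genome else None)


def write_bed(regions: RegionSet, path: str) -> None:
    with open(path, "w") as fh:
        for iv in regions:
            if iv.name is None and iv.score is None:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                nm = iv.name if iv.name is not None else "."
                sc = "." if iv.score is None else f"{iv.score:g}"
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{nm}\t{sc}\n")


def read_reads(path: str, genome: Mapping[str, int] | None = None) -> ReadTrack:
    """Read a tagAlign/BED6 file into a :class:`ReadTrack`.

    The 5' position is the start for plus-strand tags and ``end - 1`` for
    minus-strand tags.
    """
    pos: dict[str, list[int]] = {}
    strand: dict[str, list[int]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) < 6:
                raise ValueError(f"{path}:{lineno}: tagAlign requires 6 columns")
            start = _parse_int(cols[1], "start", path, lineno)
            end = _parse_int(cols[2], "end", path, lineno)
            if cols[5] == "+":
                p, s = start, 1
            elif cols[5] == "-":
                p, s = end - 1, -1
            else:
                raise ValueError(f"{path}:{lineno}: unknown strand symbol {cols[5]!r}")
            pos.setdefault(cols[0], []).append(p)
            strand.setdefault(cols[0], []).append(s)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        track = ReadTrack(
            {c: np.asarray(v, dtype=np.int64) for c, v in pos.items()},
            {c: np.asarray(v, dtype=np.int8) for c, v in strand.items()},
            genome=genome,
        )
    if track.n_reads == 0:
        warnings.warn(f"{path}: empty read file (library size 0)", stacklevel=2)
    return track


def write_reads(track: ReadTrack, path: str, tag_length: int = 50) -> None:
    """Write a track as tagAlign (stylized fixed-length tags)."""
    with open(path, "w") as fh:
        for chrom in sorted(track.positions):
            pos = track.positions[chrom]
            st = track.strands[chrom]
            for p, s in zip(pos, st):
                if s >= 0:
                    start, end, sym = int(p), int(p) + tag_length, "+"
                else:
                    start, end, sym = int(p) - tag_length + 1, int(p) + 1, "-"
                start = max(start, 0)
                fh.write(f"{chrom}\t{start}\t{end}\t.\t0\t{sym}\n")


def read_genome(path: str) -> dict[str, int]:
    genome: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) != 2:
                raise ValueError(f"{path}:{lineno}: expected 'chrom<TAB>length'")
            genome[cols[0]] = _parse_int(cols[1], "length", path, lineno)
    return genome


def write_genome(genome: Mapping[str, int], path: str) -> None:
    with open(path, "w") as fh:
        for chrom, length in genome.items():
            fh.write(f"{chrom}\t{length}\n")


def read_gene_table(path: str) -> list[GeneModel]:
    genes: list[GeneModel] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {col: i for i, col in enumerate(header)}
        required = ("gene_id", "chrom", "tss", "strand", "exonic_length")
        for col in required:
            if col not in idx:
                raise ValueError(f"{path}: missing column {col!r}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            genes.append(GeneModel(
                gene_id=cols[idx["gene_id"]],
                chrom=cols[idx["chrom"]],
                tss=_parse_int(cols[idx["tss"]], "tss", path, lineno),
                strand=cols[idx["strand"]],
                exonic_length=_parse_int(cols[idx["exonic_length"]],
                                         "exonic_length", path, lineno),
            ))
    return genes


def write_gene_table(genes: Iterable[GeneModel], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\ttss\tstrand\texonic_length\n")
        for g in genes:
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.tss}\t{g.strand}\t{g.exonic_length}\n")
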