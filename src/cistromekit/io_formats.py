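"""Domain types and readers/writers for the external formats the pipeline touches.

All coordinates are normalized to a single internal convention: 0-based,
half-open intervals, as in BED. Only the readers and writers in this module
convert; everything downstream assumes the internal convention.

Sequence case is meaningful: lowercase bases are soft-masked (repeats) and
``N`` is hard-masked. Both are excluded from the "effective length" used by
the motif-enrichment statistics.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "GenomicRegion",
    "GeneModel",
    "PSFM",
    "ScoreTrack",
    "read_sequences",
    "write_sequences",
    "read_regions",
    "write_regions",
    "read_gene_models",
    "write_gene_models",
    "read_score_track",
    "write_score_track",
    "read_psfm",
    "read_chrom_sizes",
]

ALPHABET = "ACGT"
_LETTER_INDEX = {c: i for i, c in enumerate(ALPHABET)}


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class GenomicRegion:
    """A genomic interval (0-based, half-open), optionally with a ChIP summit.

    ``summit`` is an absolute base position (``start <= summit < end``) and
    ``fold`` the peak caller's fold enrichment; both may be absent.
    """

    chrom: str
    start: int
    end: int
    summit: int | None = None
    fold: float | None = None
    name: str | None = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"empty/inverted interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.summit is not None and not (self.start <= self.summit < self.end):
            raise ValueError(
                f"summit {self.summit} outside {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def anchor(self) -> int:
        """Summit if present, else interval midpoint (rounded down)."""
        if self.summit is not None:
            return self.summit
        return (self.start + self.end) // 2


@dataclass
class GeneModel:
    """A transcript record with strand-aware TSS/TES.

    On ``+`` the TSS is ``tx_start`` and the TES is ``tx_end - 1``; on ``-``
    the roles are swapped. Coordinates are 0-based half-open.
    """

    name: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r} for gene {self.name}")
        if self.tx_end <= self.tx_start:
            raise ValueError(f"empty gene {self.name}")

    @property
    def tss(self) -> int:
        return self.tx_start if self.strand == "+" else self.tx_end - 1

    @property
    def tes(self) -> int:
        return self.tx_end - 1 if self.strand == "+" else self.tx_start


class PSFM:
    """Position-specific frequency matrix over {A, C, G, T}.

    ``freq`` has shape (length, 4) with columns (matrix rows here) summing
    to 1; ``background`` is the expected letter frequency Q_i, uniform 0.25
    by default.
    """

    def __init__(self, name: str, freq: np.ndarray, background=None):
        freq = np.asarray(freq, dtype=float)
        if freq.ndim != 2 or freq.shape[1] != 4:
            raise ValueError("freq must have shape (length, 4)")
        if np.any(freq < 0) or np.any(freq > 1):
            raise ValueError("frequencies must lie in [0, 1]")
        sums = freq.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("every PSFM column must sum to 1")
        if background is None:
            background = np.full(4, 0.25)
        background = np.asarray(background, dtype=float)
        if background.shape != (4,) or not math.isclose(background.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("background must be 4 frequencies summing to 1")
        self.name = name
        self.freq = freq
        self.background = background

    def __len__(self) -> int:
        return self.freq.shape[0]

    @property
    def length(self) -> int:
        return self.freq.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.freq.argmax(axis=1))

    def reverse_complement(self) -> "PSFM":
        # complement = swap A<->T and C<->G, i.e. reverse the letter axis
        return PSFM(self.name + "_rc", self.freq[::-1, ::-1], self.background[::-1])

    @classmethod
    def from_counts(cls, name: str, counts, background=None, pseudocount: float = 0.0) -> "PSFM":
        counts = np.asarray(counts, dtype=float)
        if np.any(counts < 0):
            raise ValueError("negative matrix entries")
        counts = counts + pseudocount
        sums = counts.sum(axis=1, keepdims=True)
        if np.any(sums == 0):
            raise ValueError("zero-sum PSFM column")
        return cls(name, counts / sums, background)

    def __repr__(self) -> str:
        return f"PSFM({self.name!r}, length={self.length}, consensus={self.consensus!r})"


class ScoreTrack:
    """Sparse per-base score track (e.g. phastCons conservation).

    Positions without a score are *missing* — represented as NaN internally —
    and distinct from 0. Stored densely per chromosome, which is ample at
    desk scale.
    """

    def __init__(self) -> None:
        self._data: dict[str, np.ndarray] = {}

    def set_interval(self, chrom: str, start: int, end: int, score: float) -> None:
        if start < 0 or end <= start:
            raise ValueError(f"bad interval {chrom}:{start}-{end}")
        if not np.isfinite(score):
            raise ValueError("scores must be finite")
        arr = self._data.get(chrom)
        if arr is None or len(arr) < end:
            new = np.full(max(end, 2 * len(arr) if arr is not None else end), np.nan)
            if arr is not None:
                new[: len(arr)] = arr
            self._data[chrom] = arr = new
        arr[start:end] = score

    def set_array(self, chrom: str, values: np.ndarray) -> None:
        self._data[chrom] = np.asarray(values, dtype=float)

    def get(self, chrom: str, pos: int) -> float:
        """Score at one position; NaN when missing."""
        arr = self._data.get(chrom)
        if arr is None or pos < 0 or pos >= len(arr):
            return float("nan")
        return float(arr[pos])

    def window(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Scores for [start, end); out-of-bounds positions come back NaN."""
        out = np.full(end - start, np.nan)
        arr = self._data.get(chrom)
        if arr is None:
            return out
        lo = max(start, 0)
        hi = min(end, len(arr))
        if hi > lo:
            out[lo - start : hi - start] = arr[lo:hi]
        return out

    @property
    def chroms(self) -> list[str]:
        return list(self._data)

    def items(self):
        return self._data.items()


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_sequences(path) -> dict[str, str]:
    """Read a FASTA file into {name: sequence}, preserving case.

    The name is the first whitespace-delimited token of each header.
    Duplicate names and empty files raise ``ValueError``.
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate sequence name {rec.id!r}")
        seqs[rec.id] = str(rec.seq)
    if not seqs:
        raise ValueError(f"no FASTA records in {path}")
    return seqs


def write_sequences(seqs: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Region tables (BED and MACS-style peak tables)
# ---------------------------------------------------------------------------

#: default column-name aliases accepted by the peak_table dialect
PEAK_TABLE_ALIASES = {
    "chrom": ("chrom", "chr", "chromosome", "#chrom", "#chr"),
    "start": ("start", "chromstart"),
    "end": ("end", "chromend"),
    "summit": ("summit", "abs_summit"),
    "fold": ("fold", "fold_enrichment", "fold_change"),
    "name": ("name", "id", "peak_id"),
}


def _resolve_columns(columns, overrides=None):
    aliases = {k: tuple(v) for k, v in PEAK_TABLE_ALIASES.items()}
    if overrides:
        for key, col in overrides.items():
            aliases[key] = (col,)
    lower = {c.lower(): c for c in columns}
    resolved = {}
    for key, names in aliases.items():
        for cand in names:
            if cand.lower() in lower:
                resolved[key] = lower[cand.lower()]
                break
    return resolved


def read_regions(path, dialect: str = "bed", columns=None) -> list[GenomicRegion]:
    """Read regions from ``bed`` (0-based half-open) or ``peak_table``
    (tab-delimited with header, 1-based inclusive start/end, summit as an
    offset from start — the MACS convention).

    ``columns`` optionally maps {chrom,start,end,summit,fold,name} to actual
    header names for nonstandard peak tables; extra columns are ignored.
    """
    if dialect == "bed":
        return _read_bed(path)
    if dialect == "peak_table":
        return _read_peak_table(path, columns)
    raise ValueError(f"unknown region dialect {dialect!r}")


def _read_bed(path) -> list[GenomicRegion]:
    regions = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: BED needs >=3 columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if end <= start:
                raise ValueError(f"{path}:{ln}: end <= start")
            name = parts[3] if len(parts) > 3 and parts[3] != "." else None
            regions.append(GenomicRegion(chrom, start, end, name=name))
    return regions


def _read_peak_table(path, columns=None) -> list[GenomicRegion]:
    df = pd.read_csv(path, sep="\t", comment=None)
    cols = _resolve_columns(df.columns, columns)
    for required in ("chrom", "start", "end"):
        if required not in cols:
            raise ValueError(f"peak table {path} lacks a {required!r} column")
    regions = []
    for idx, row in enumerate(df.itertuples(index=False), 1):
        rec = dict(zip(df.columns, row))
        start1 = int(rec[cols["start"]])
        end1 = int(rec[cols["end"]])
        start = start1 - 1  # 1-based inclusive -> 0-based half-open
        end = end1
        if end <= start:
            raise ValueError(f"{path} row {idx}: end <= start after conversion")
        summit = None
        if "summit" in cols and not pd.isna(rec[cols["summit"]]):
            summit = start + int(rec[cols["summit"]])  # offset from start
        fold = None
        if "fold" in cols and not pd.isna(rec[cols["fold"]]):
            fold = float(rec[cols["fold"]])
        name = None
        if "name" in cols and not pd.isna(rec[cols["name"]]):
            name = str(rec[cols["name"]])
        regions.append(GenomicRegion(rec[cols["chrom"]], start, end, summit, fold, name))
    return regions


def write_regions(regions, path, dialect: str = "bed") -> None:
    """Write regions; ``read_regions`` on the output round-trips (same dialect).

    The peak_table dialect preserves summit and fold (fold to 2 decimals).
    """
    if dialect == "bed":
        with open(path, "w") as fh:
            for r in regions:
                name = r.name if r.name is not None else "."
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{name}\n")
    elif dialect == "peak_table":
        with open(path, "w") as fh:
            fh.write("chrom\tstart\tend\tsummit\tfold\tname\n")
            for r in regions:
                summit = "" if r.summit is None else str(r.summit - r.start)
                fold = "" if r.fold is None else f"{r.fold:.2f}"
                name = "" if r.name is None else r.name
                fh.write(f"{r.chrom}\t{r.start + 1}\t{r.end}\t{summit}\t{fold}\t{name}\n")
    else:
        raise ValueError(f"unknown region dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------

def read_gene_models(path, dialect: str = "refflat") -> list[GeneModel]:
    """Read gene models from refFlat (UCSC, 0-based txStart) or a BED-like
    file with strand in column 6."""
    genes = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if dialect == "refflat":
                # geneName, name, chrom, strand, txStart, txEnd, ...
                name, _tx, chrom, strand = parts[0], parts[1], parts[2], parts[3]
                tx_start, tx_end = int(parts[4]), int(parts[5])
            elif dialect == "bed":
                if len(parts) < 6:
                    raise ValueError(f"{path}:{ln}: BED gene file needs >=6 columns")
                chrom, tx_start, tx_end = parts[0], int(parts[1]), int(parts[2])
                name, strand = parts[3], parts[5]
            else:
                raise ValueError(f"unknown gene dialect {dialect!r}")
            if strand not in ("+", "-"):
                raise ValueError(f"{path}:{ln}: bad strand {strand!r}")
            genes.append(GeneModel(name, chrom, strand, tx_start, tx_end))
    return genes


def write_gene_models(genes, path, dialect: str = "refflat") -> None:
    with open(path, "w") as fh:
        for g in genes:
            if dialect == "refflat":
                fh.write(
                    f"{g.name}\t{g.name}\t{g.chrom}\t{g.strand}\t{g.tx_start}\t{g.tx_end}"
                    f"\t{g.tx_start}\t{g.tx_end}\t1\t{g.tx_start},\t{g.tx_end},\n"
                )
            elif dialect == "bed":
                fh.write(f"{g.chrom}\t{g.tx_start}\t{g.tx_end}\t{g.name}\t0\t{g.strand}\n")
            else:
                raise ValueError(f"unknown gene dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Score tracks
# ---------------------------------------------------------------------------

def read_score_track(path, dialect: str = "bedgraph") -> ScoreTrack:
    """Read a per-base score track from bedGraph (0-based half-open intervals,
    which must not overlap) or fixed-step WIG (1-based start declarations)."""
    track = ScoreTrack()
    if dialect == "bedgraph":
        seen: dict[str, list[tuple[int, int]]] = {}
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith(("#", "track")):
                    continue
                chrom, s, e, v = line.split()[:4]
                start, end, score = int(s), int(e), float(v)
                for a, b in seen.setdefault(chrom, []):
                    if start < b and a < end:
                        raise ValueError(f"{path}:{ln}: overlapping bedGraph intervals")
                seen[chrom].append((start, end))
                track.set_interval(chrom, start, end, score)
    elif dialect == "fixedstep_wig":
        chrom, pos, step = None, 0, 1
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track")):
                    continue
                if line.startswith("fixedStep"):
                    fields = dict(kv.split("=") for kv in line.split()[1:])
                    chrom = fields["chrom"]
                    pos = int(fields["start"]) - 1  # 1-based -> 0-based
                    step = int(fields.get("step", 1))
                else:
                    if chrom is None:
                        raise ValueError("wig data before fixedStep declaration")
                    track.set_interval(chrom, pos, pos + 1, float(line))
                    pos += step
    else:
        raise ValueError(f"unknown track dialect {dialect!r}")
    return track


def write_score_track(track: ScoreTrack, path) -> None:
    """Write as bedGraph, merging runs of equal score and omitting missing."""
    with open(path, "w") as fh:
        for chrom, arr in track.items():
            present = np.where(np.isfinite(arr))[0]
            if len(present) == 0:
                continue
            run_start = present[0]
            prev = present[0]
            score = arr[run_start]
            for p in present[1:]:
                if p == prev + 1 and arr[p] == score:
                    prev = p
                    continue
                fh.write(f"{chrom}\t{run_start}\t{prev + 1}\t{score:g}\n")
                run_start, prev, score = p, p, arr[p]
            fh.write(f"{chrom}\t{run_start}\t{prev + 1}\t{score:g}\n")


# ---------------------------------------------------------------------------
# PSFM files
# ---------------------------------------------------------------------------

def read_psfm(path, dialect: str = "transfac", pseudocount: float = 0.0) -> PSFM:
    """Read a motif matrix.

    ``transfac``: count-matrix rows ``01  7  1  1  1  A`` between a P0 header
    and ``//``; counts are normalized per column. ``plain_matrix``: one
    whitespace-separated A C G T frequency row per position, optional
    ``>name`` header line. Background defaults to uniform 0.25.
    """
    if dialect == "transfac":
        name = "motif"
        rows = []
        with open(path) as fh:
            for line in fh:
                parts = line.split()
                if not parts:
                    continue
                tag = parts[0]
                if tag in ("ID", "NA") and len(parts) > 1:
                    name = parts[1]
                elif tag == "P0" or tag == "PO" or tag == "//" or tag == "XX":
                    continue
                elif tag.isdigit():
                    vals = [float(x) for x in parts[1:5]]
                    rows.append(vals)
        if not rows:
            raise ValueError(f"no matrix rows in {path}")
        return PSFM.from_counts(name, np.array(rows), pseudocount=pseudocount)
    if dialect == "plain_matrix":
        name = "motif"
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith((">", "#")):
                    name = line[1:].strip() or name
                    continue
                rows.append([float(x) for x in line.split()[:4]])
        if not rows:
            raise ValueError(f"no matrix rows in {path}")
        return PSFM.from_counts(name, np.array(rows), pseudocount=pseudocount)
    raise ValueError(f"unknown PSFM dialect {dialect!r}")


def read_chrom_sizes(path) -> dict[str, int]:
    """Two-column name/length text file."""
    sizes = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            name, length = line.split()[:2]
            sizes[name] = int(length)
    return sizes
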