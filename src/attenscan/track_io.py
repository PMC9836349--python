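"""Genome annotation, signal-track and point-site I/O with window queries.

All internal coordinates are 0-based half-open (bedGraph/BED native); GFF3
input is converted from 1-based closed on load. Occupancy tracks (Pol II and
RNA-binding factors) are unstranded; site tracks (pA, TSS) are stranded.
Tracks are sparse: any query outside covered runs returns 0.
"""

from __future__ import annotations

import gzip
import io
import logging
import os
import tempfile
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import numpy as np

logger = logging.getLogger("attenscan")

VALID_STRANDS = ("+", "-")


class TrackParseError(ValueError):
    """Malformed track/annotation input (reported with file and line number)."""


class TrackValidationError(ValueError):
    """Structurally parseable input violating a semantic contract."""


def _open_text(path) -> io.TextIOWrapper:
    """Open a possibly gzip-compressed text file."""
    path = os.fspath(path)
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path, "rt")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomicWindow:
    """Half-open genomic interval with an orientation."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if self.start >= self.end:
            raise TrackValidationError(
                f"window start must be < end, got [{self.start}, {self.end})"
            )
        if self.strand not in VALID_STRANDS:
            raise TrackValidationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneModel:
    """Oriented gene with ORF bounds and optional TSS.

    ``atg_pos`` is the genome coordinate of the first base of the +1 ATG:
    ``orf_start`` on the + strand, ``orf_end - 1`` on the − strand.
    ``tss_pos``, when known, lies 5′ of the ATG in gene orientation.
    """

    gene_id: str
    chrom: str
    strand: str
    orf_start: int
    orf_end: int
    tss_pos: Optional[int] = None

    def __post_init__(self):
        if self.strand not in VALID_STRANDS:
            raise TrackValidationError(
                f"gene {self.gene_id}: invalid strand {self.strand!r}"
            )
        if not self.orf_start < self.orf_end:
            raise TrackValidationError(
                f"gene {self.gene_id}: ORF start must be < end "
                f"({self.orf_start} >= {self.orf_end})"
            )
        if self.tss_pos is not None:
            if self.strand == "+" and self.tss_pos > self.atg_pos:
                raise TrackValidationError(
                    f"gene {self.gene_id}: TSS must be 5' of the ATG"
                )
            if self.strand == "-" and self.tss_pos < self.atg_pos:
                raise TrackValidationError(
                    f"gene {self.gene_id}: TSS must be 5' of the ATG"
                )

    @property
    def atg_pos(self) -> int:
        return self.orf_start if self.strand == "+" else self.orf_end - 1

    @property
    def anchor(self) -> int:
        """5′ anchor for promoter-proximal windows: TSS if known, else ATG."""
        return self.tss_pos if self.tss_pos is not None else self.atg_pos


class SignalTrack:
    """Per-base nonnegative occupancy as sorted, non-overlapping runs.

    Runs are stored per chromosome as parallel arrays (starts, ends, values);
    adjacent runs with equal value are merged so the representation is
    canonical. Uncovered positions implicitly hold 0.
    """

    def __init__(self, runs: Optional[dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]] = None):
        self._runs: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        if runs:
            for chrom, (s, e, v) in runs.items():
                self._set_chrom(chrom, np.asarray(s), np.asarray(e), np.asarray(v))

    # -- construction -------------------------------------------------------

    def _set_chrom(self, chrom: str, starts: np.ndarray, ends: np.ndarray,
                   values: np.ndarray) -> None:
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        values = np.asarray(values, dtype=np.float64)
        if np.any(values < 0):
            raise TrackValidationError(f"{chrom}: negative occupancy value")
        order = np.argsort(starts, kind="stable")
        starts, ends, values = starts[order], ends[order], values[order]
        if np.any(starts >= ends):
            raise TrackValidationError(f"{chrom}: run with start >= end")
        if np.any(starts[1:] < ends[:-1]):
            raise TrackValidationError(f"{chrom}: overlapping runs")
        s, e, v = _merge_runs(starts, ends, values)
        if len(s):
            self._runs[chrom] = (s, e, v)

    @classmethod
    def from_intervals(cls, intervals: Iterable[tuple[str, int, int, float]]) -> "SignalTrack":
        """Build a track from (chrom, start, end, value) tuples."""
        per_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, value in intervals:
            per_chrom.setdefault(chrom, []).append((int(start), int(end), float(value)))
        track = cls()
        for chrom, runs in per_chrom.items():
            arr = np.array(runs, dtype=np.float64).reshape(-1, 3)
            track._set_chrom(chrom, arr[:, 0], arr[:, 1], arr[:, 2])
        return track

    # -- introspection ------------------------------------------------------

    @property
    def chroms(self) -> list[str]:
        return sorted(self._runs)

    def runs(self, chrom: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Canonical (starts, ends, values) arrays for one chromosome."""
        if chrom not in self._runs:
            empty_i = np.empty(0, dtype=np.int64)
            return empty_i, empty_i.copy(), np.empty(0, dtype=np.float64)
        return self._runs[chrom]

    def iter_runs(self) -> Iterator[tuple[str, int, int, float]]:
        for chrom in self.chroms:
            s, e, v = self._runs[chrom]
            for i in range(len(s)):
                yield chrom, int(s[i]), int(e[i]), float(v[i])

    # -- queries ------------------------------------------------------------

    def window_values(self, window: GenomicWindow) -> np.ndarray:
        """Per-base values over ``window``, 5′→3′ in window orientation.

        Uncovered bases are 0; an absent chromosome yields all zeros with a
        warning (tracks are sparse).
        """
        out = np.zeros(len(window), dtype=np.float64)
        if window.chrom not in self._runs:
            warnings.warn(
                f"chromosome {window.chrom!r} absent from track; returning zeros",
                stacklevel=2,
            )
            return out
        s, e, v = self._runs[window.chrom]
        lo = int(np.searchsorted(e, window.start, side="right"))
        hi = int(np.searchsorted(s, window.end, side="left"))
        for i in range(lo, hi):
            a = max(int(s[i]), window.start) - window.start
            b = min(int(e[i]), window.end) - window.start
            out[a:b] = v[i]
        if window.strand == "-":
            out = out[::-1]
        return out

    def __eq__(self, other) -> bool:
        if not isinstance(other, SignalTrack):
            return NotImplemented
        if self.chroms != other.chroms:
            return False
        return all(
            all(np.array_equal(a, b) for a, b in zip(self._runs[c], other._runs[c]))
            for c in self.chroms
        )


def _merge_runs(starts: np.ndarray, ends: np.ndarray, values: np.ndarray):
    """Merge abutting runs with equal value into canonical form."""
    if len(starts) == 0:
        return starts, ends, values
    out_s, out_e, out_v = [int(starts[0])], [int(ends[0])], [float(values[0])]
    for s, e, v in zip(starts[1:], ends[1:], values[1:]):
        if int(s) == out_e[-1] and float(v) == out_v[-1]:
            out_e[-1] = int(e)
        else:
            out_s.append(int(s))
            out_e.append(int(e))
            out_v.append(float(v))
    return (np.array(out_s, dtype=np.int64), np.array(out_e, dtype=np.int64),
            np.array(out_v, dtype=np.float64))


class SiteTrack:
    """Stranded point sites (pA or TSS) with read counts.

    Sites are keyed by (chrom, strand) and kept position-sorted; duplicate
    positions on the same strand have their counts summed.
    """

    def __init__(self):
        self._sites: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}

    @classmethod
    def from_sites(cls, sites: Iterable[tuple[str, int, str, float]]) -> "SiteTrack":
        """Build from (chrom, position, strand, count) tuples."""
        acc: dict[tuple[str, str], dict[int, float]] = {}
        for chrom, pos, strand, count in sites:
            if strand not in VALID_STRANDS:
                raise TrackValidationError(f"invalid site strand {strand!r}")
            if count <= 0:
                raise TrackValidationError(
                    f"site {chrom}:{pos}({strand}) has non-positive count {count}"
                )
            key = (chrom, strand)
            acc.setdefault(key, {})
            acc[key][int(pos)] = acc[key].get(int(pos), 0.0) + float(count)
        track = cls()
        for key, posmap in acc.items():
            pos = np.array(sorted(posmap), dtype=np.int64)
            counts = np.array([posmap[p] for p in pos], dtype=np.float64)
            track._sites[key] = (pos, counts)
        return track

    @property
    def keys(self) -> list[tuple[str, str]]:
        return sorted(self._sites)

    def sites(self, chrom: str, strand: str) -> tuple[np.ndarray, np.ndarray]:
        if (chrom, strand) not in self._sites:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.float64)
        return self._sites[(chrom, strand)]

    def iter_sites(self) -> Iterator[tuple[str, int, str, float]]:
        for chrom, strand in self.keys:
            pos, counts = self._sites[(chrom, strand)]
            for p, c in zip(pos, counts):
                yield chrom, int(p), strand, float(c)

    def in_window(self, window: GenomicWindow) -> tuple[np.ndarray, np.ndarray]:
        """Positions and counts inside ``window`` on the window's strand."""
        pos, counts = self.sites(window.chrom, window.strand)
        lo = int(np.searchsorted(pos, window.start, side="left"))
        hi = int(np.searchsorted(pos, window.end, side="left"))
        return pos[lo:hi], counts[lo:hi]

    def __eq__(self, other) -> bool:
        if not isinstance(other, SiteTrack):
            return NotImplemented
        if self.keys != other.keys:
            return False
        return all(
            all(np.array_equal(a, b) for a, b in zip(self._sites[k], other._sites[k]))
            for k in self.keys
        )


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def load_signal_track(path) -> SignalTrack:
    """Read a 4-column bedGraph into a canonical :class:`SignalTrack`.

    Adjacent equal-value runs are merged; negative values and start >= end
    are rejected with the offending line number.
    """
    intervals: list[tuple[str, int, int, float]] = []
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) != 4:
                raise TrackParseError(
                    f"{path}:{lineno}: expected 4 bedGraph columns, got {len(fields)}"
                )
            chrom, s, e, v = fields
            try:
                start, end, value = int(s), int(e), float(v)
            except ValueError as err:
                raise TrackParseError(f"{path}:{lineno}: {err}") from None
            if start >= end:
                raise TrackParseError(
                    f"{path}:{lineno}: start ({start}) must be < end ({end})"
                )
            if value < 0:
                raise TrackValidationError(
                    f"{path}:{lineno}: negative occupancy value {value}"
                )
            intervals.append((chrom, start, end, value))
    return SignalTrack.from_intervals(intervals)


def write_signal_track(track: SignalTrack, path) -> None:
    """Write a track as bedGraph in canonical merged, sorted form."""
    with _atomic_writer(path) as handle:
        for chrom, start, end, value in track.iter_runs():
            handle.write(f"{chrom}\t{start}\t{end}\t{value:g}\n")


def load_sites(path) -> SiteTrack:
    """Read a BED6 file whose score column holds the site read count."""
    sites: list[tuple[str, int, str, float]] = []
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise TrackParseError(
                    f"{path}:{lineno}: expected 6 BED columns, got {len(fields)}"
                )
            chrom, s, e, _name, score, strand = fields[:6]
            try:
                start, end, count = int(s), int(e), float(score)
            except ValueError as err:
                raise TrackParseError(f"{path}:{lineno}: {err}") from None
            if end != start + 1:
                raise TrackParseError(
                    f"{path}:{lineno}: point sites must span exactly 1 bp"
                )
            if strand not in VALID_STRANDS:
                raise TrackParseError(f"{path}:{lineno}: invalid strand {strand!r}")
            if count <= 0:
                raise TrackValidationError(
                    f"{path}:{lineno}: non-positive count {count}"
                )
            sites.append((chrom, start, strand, count))
    return SiteTrack.from_sites(sites)


def write_sites(track: SiteTrack, path, name_prefix: str = "site") -> None:
    """Write sites as BED6 (score = count), sorted by chrom/strand/position."""
    with _atomic_writer(path) as handle:
        for i, (chrom, pos, strand, count) in enumerate(track.iter_sites()):
            handle.write(
                f"{chrom}\t{pos}\t{pos + 1}\t{name_prefix}{i}\t{count:g}\t{strand}\n"
            )


def load_annotation(path) -> list[GeneModel]:
    """Load gene models from GFF3 (``gene`` features, ``ID`` attribute) or
    from a TSV with columns gene_id, chrom, strand, orf_start, orf_end, tss.

    GFF3 coordinates (1-based closed) are converted to 0-based half-open.
    The TSV ``tss`` column may be '.' or empty when unknown.
    """
    path = os.fspath(path)
    with _open_text(path) as handle:
        head = handle.readline()
    if head.startswith("##gff") or path.endswith((".gff", ".gff3", ".gff.gz", ".gff3.gz")):
        return _load_gff3(path)
    return _load_annotation_tsv(path)


def _load_gff3(path) -> list[GeneModel]:
    import gffutils

    db = gffutils.create_db(
        os.fspath(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        if feat.strand not in VALID_STRANDS:
            raise TrackValidationError(
                f"gene {gene_id}: missing or invalid strand {feat.strand!r}"
            )
        tss = feat.attributes.get("tss", [None])[0]
        genes.append(GeneModel(
            gene_id=gene_id,
            chrom=feat.seqid,
            strand=feat.strand,
            orf_start=feat.start - 1,  # 1-based closed -> 0-based half-open
            orf_end=feat.end,
            tss_pos=int(tss) if tss is not None else None,
        ))
    return genes


_TSV_COLUMNS = ("gene_id", "chrom", "strand", "orf_start", "orf_end", "tss")


def _load_annotation_tsv(path) -> list[GeneModel]:
    genes: list[GeneModel] = []
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[:6] == list(_TSV_COLUMNS):
                continue  # header
            if len(fields) < 5:
                raise TrackParseError(
                    f"{path}:{lineno}: expected >=5 annotation columns"
                )
            gene_id, chrom, strand = fields[0], fields[1], fields[2]
            if not gene_id or not chrom:
                raise TrackValidationError(
                    f"{path}:{lineno}: gene record missing id or chromosome"
                )
            if strand not in VALID_STRANDS:
                raise TrackValidationError(
                    f"gene {gene_id}: missing or invalid strand {strand!r}"
                )
            try:
                orf_start, orf_end = int(fields[3]), int(fields[4])
            except ValueError as err:
                raise TrackParseError(f"{path}:{lineno}: {err}") from None
            tss_field = fields[5] if len(fields) > 5 else ""
            tss = int(tss_field) if tss_field not in ("", ".") else None
            genes.append(GeneModel(gene_id, chrom, strand, orf_start, orf_end, tss))
    return genes


def write_annotation(genes: Iterable[GeneModel], path) -> None:
    """Write gene models as the 6-column annotation TSV (with header)."""
    with _atomic_writer(path) as handle:
        handle.write("\t".join(_TSV_COLUMNS) + "\n")
        for g in genes:
            tss = "." if g.tss_pos is None else str(g.tss_pos)
            handle.write(
                f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{g.orf_start}\t{g.orf_end}\t{tss}\n"
            )


class _atomic_writer:
    """Write to a temp file and rename into place so failures leave no partial file."""

    def __init__(self, path):
        self.path = os.fspath(path)

    def __enter__(self):
        fd, self._tmp = tempfile.mkstemp(
            dir=os.path.dirname(self.path) or ".", suffix=".tmp"
        )
        self._handle = os.fdopen(fd, "w")
        return self._handle

    def __exit__(self, exc_type, exc, tb):
        self._handle.close()
        if exc_type is None:
            os.replace(self._tmp, self.path)
        else:
            os.unlink(self._tmp)
        return False


def window_values(track: SignalTrack, window: GenomicWindow) -> np.ndarray:
    """Functional alias for :meth:`SignalTrack.window_values`."""
    return track.window_values(window)
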