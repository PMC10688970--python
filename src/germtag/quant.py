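"""Fragment counting and library-size scaling.

Counts mapped fragments over intervals (promoter windows, gene bodies,
transposon consensi, fixed-width genomic bins) and scales raw counts to
counts per million mapped fragments (CPM = counts × 1e6 / library size)
or counts per kilobase per million (CPKM = CPM / interval length in kb).
A fragment is counted once in every interval it overlaps by at least 1 bp
under the half-open convention; abutting intervals share no base and share
no fragment.

Cross-genotype z-scores standardize each interval's CPM over a designated
library triple (e.g. bam / aly / wildtype testes) with the population SD,
so the three z-values of an interval always sum to zero.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import normalize_chrom

log = logging.getLogger(__name__)

__all__ = [
    "FragmentLibrary",
    "BinnedTrack",
    "load_fragments",
    "count_overlaps",
    "cpm",
    "cpkm",
    "genotype_zscores",
    "transposon_scores",
    "binned_coverage",
    "log2_bin_ratio",
    "score_table",
    "write_bedgraph",
    "write_fragments_bed",
]


class BedParseError(ValueError):
    def __init__(self, lineno: int, message: str):
        self.lineno = lineno
        super().__init__(f"BED line {lineno}: {message}")


@dataclass
class FragmentLibrary:
    """A labeled set of mapped fragment intervals.

    ``library_size`` is the total mapped fragment count used for scaling;
    by default the number of stored fragments.
    """

    label: str
    fragments: pd.DataFrame  # columns chrom, start, end (0-based half-open)
    chrom_sizes: dict[str, int]
    library_size: int = -1
    n_rejected: int = 0
    _by_chrom: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if self.library_size < 0:
            self.library_size = len(self.fragments)

    def __len__(self) -> int:
        return len(self.fragments)

    def _sorted_chrom(self, chrom: str):
        """(sorted starts, sorted ends) for one chromosome, cached."""
        if chrom not in self._by_chrom:
            sub = self.fragments[self.fragments["chrom"] == chrom]
            self._by_chrom[chrom] = (
                np.sort(sub["start"].to_numpy()),
                np.sort(sub["end"].to_numpy()),
            )
        return self._by_chrom[chrom]


def load_fragments(bed, label: str, chrom_sizes: dict[str, int]) -> FragmentLibrary:
    """Load a fragment BED3+ file (or iterable of lines) into a library.

    Records outside chromosome bounds are rejected and counted in
    ``n_rejected`` (reported in the log); malformed lines raise
    :class:`BedParseError` with the line number.
    """
    if isinstance(bed, str) and ("\n" in bed or "\t" in bed):
        lines = bed.splitlines()
    elif isinstance(bed, (list, tuple)):
        lines = bed
    else:
        with open(bed) as fh:
            lines = fh.read().splitlines()
    chroms, starts, ends = [], [], []
    rejected = 0
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise BedParseError(lineno, "fewer than 3 fields")
        chrom = normalize_chrom(fields[0])
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError:
            raise BedParseError(lineno, f"non-integer coordinates {fields[1]!r}, {fields[2]!r}") from None
        if start < 0 or start >= end:
            raise BedParseError(lineno, f"bad interval [{start}, {end})")
        size = chrom_sizes.get(chrom)
        if size is None or end > size:
            rejected += 1
            continue
        chroms.append(chrom)
        starts.append(start)
        ends.append(end)
    if rejected:
        log.warning("%s: rejected %d out-of-bounds fragment(s)", label, rejected)
    frame = pd.DataFrame({"chrom": chroms, "start": starts, "end": ends})
    return FragmentLibrary(label=label, fragments=frame, chrom_sizes=dict(chrom_sizes), n_rejected=rejected)


def count_overlaps(lib: FragmentLibrary, intervals: pd.DataFrame) -> np.ndarray:
    """Raw fragment count per interval (≥1 bp half-open overlap).

    ``intervals`` needs columns chrom, start, end.  A fragment overlapping
    two intervals contributes to both.  Counting uses the sorted-endpoint
    identity: overlaps of [s, e) = #(frag_start < e) − #(frag_end ≤ s).
    """
    counts = np.zeros(len(intervals), dtype=np.int64)
    if len(intervals) == 0 or len(lib.fragments) == 0:
        return counts
    chrom_arr = intervals["chrom"].to_numpy()
    s_arr = intervals["start"].to_numpy()
    e_arr = intervals["end"].to_numpy()
    for chrom in pd.unique(chrom_arr):
        mask = chrom_arr == chrom
        starts_sorted, ends_sorted = lib._sorted_chrom(chrom)
        n_start_lt_e = np.searchsorted(starts_sorted, e_arr[mask], side="left")
        n_end_le_s = np.searchsorted(ends_sorted, s_arr[mask], side="right")
        counts[mask] = n_start_lt_e - n_end_le_s
    return counts


def cpm(raw, library_size: int):
    """Counts per million: (counts × 1,000,000) / library size."""
    if library_size <= 0:
        raise ValueError("library_size must be positive for CPM scaling")
    return np.asarray(raw, dtype=float) * 1_000_000.0 / library_size


def cpkm(raw, library_size: int, length_bp):
    """Counts per kilobase per million: CPM / (length in kb)."""
    length_bp = np.asarray(length_bp, dtype=float)
    if np.any(length_bp <= 0):
        raise ValueError("interval length must be positive for CPKM scaling")
    return cpm(raw, library_size) / (length_bp / 1000.0)


def genotype_zscores(
    table: pd.DataFrame, triple: tuple[str, str, str] = ("bam", "aly", "wildtype")
) -> pd.DataFrame:
    """Per-interval z-scores across a genotype triple of CPM columns.

    ``table`` holds one column per library label.  Standardization uses the
    population SD over the three values; zero-variance intervals get all
    three z = 0.  Missing labels are an error.
    """
    missing = [t for t in triple if t not in table.columns]
    if missing:
        raise KeyError(f"genotype label(s) missing from table: {missing}")
    x = table[list(triple)].to_numpy(dtype=float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)  # population SD (n = 3)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (x - mu) / sd, 0.0)
    return pd.DataFrame(z, index=table.index, columns=[f"z_{t}" for t in triple])


def transposon_scores(
    lib: FragmentLibrary, consensus_lengths: pd.Series | dict[str, int]
) -> pd.DataFrame:
    """CPKM over each transposon consensus scored as one full-length interval."""
    lengths = pd.Series(consensus_lengths, dtype=int)
    unknown = [c for c in lengths.index if c not in lib.chrom_sizes]
    if unknown:
        raise KeyError(f"consensus id(s) not in chromosome table: {unknown[:5]}")
    intervals = pd.DataFrame(
        {"chrom": lengths.index, "start": 0, "end": lengths.to_numpy()}
    )
    raw = count_overlaps(lib, intervals)
    return pd.DataFrame(
        {
            "length": lengths.to_numpy(),
            "raw": raw,
            "cpkm": cpkm(raw, lib.library_size, lengths.to_numpy()),
        },
        index=lengths.index.rename("consensus"),
    )


@dataclass
class BinnedTrack:
    """Consecutive fixed-width bins tiling each chromosome from 0."""

    bins: pd.DataFrame  # chrom, start, end, value
    bin_size: int

    def chrom_values(self, chrom: str) -> np.ndarray:
        return self.bins.loc[self.bins["chrom"] == chrom, "value"].to_numpy()


def binned_coverage(
    lib: FragmentLibrary,
    chrom_sizes: dict[str, int] | None = None,
    bin_size: int = 20_000,
) -> BinnedTrack:
    """Per-bin fragment-overlap counts scaled by 1e6/library_size.

    Bins tile each chromosome in consecutive windows from position 0; the
    last bin may be short.  A fragment spanning a bin boundary contributes
    to every bin it overlaps.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    if lib.library_size <= 0:
        raise ValueError("empty library: no scaling basis for coverage")
    chrom_sizes = chrom_sizes or lib.chrom_sizes
    scale = 1_000_000.0 / lib.library_size
    frames = []
    for chrom, size in chrom_sizes.items():
        nbins = math.ceil(size / bin_size)
        counts = np.zeros(nbins, dtype=np.int64)
        sub = lib.fragments[lib.fragments["chrom"] == chrom]
        if len(sub):
            b0 = sub["start"].to_numpy() // bin_size
            b1 = (sub["end"].to_numpy() - 1) // bin_size
            offset = 0
            active = np.ones(len(sub), dtype=bool)
            while active.any():
                np.add.at(counts, b0[active] + offset, 1)
                offset += 1
                active = b1 >= b0 + offset
        starts = np.arange(nbins, dtype=np.int64) * bin_size
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": np.minimum(starts + bin_size, size),
                    "value": counts * scale,
                }
            )
        )
    return BinnedTrack(bins=pd.concat(frames, ignore_index=True), bin_size=bin_size)


def log2_bin_ratio(track_a: BinnedTrack, track_b: BinnedTrack, pseudocount: float = 1.0) -> BinnedTrack:
    """Per-bin log2((a + ρ)/(b + ρ)) between two identically binned tracks."""
    a, b = track_a.bins, track_b.bins
    if track_a.bin_size != track_b.bin_size or len(a) != len(b) or not (
        (a["chrom"].to_numpy() == b["chrom"].to_numpy()).all()
        and (a["start"].to_numpy() == b["start"].to_numpy()).all()
        and (a["end"].to_numpy() == b["end"].to_numpy()).all()
    ):
        raise ValueError("tracks are not identically binned")
    out = a.copy()
    out["value"] = np.log2((a["value"].to_numpy() + pseudocount) / (b["value"].to_numpy() + pseudocount))
    return BinnedTrack(bins=out, bin_size=track_a.bin_size)


def score_table(
    libs: list[FragmentLibrary],
    intervals: pd.DataFrame,
    lengths: bool = False,
) -> pd.DataFrame:
    """Interval × library score table.

    Adds per-library columns raw_<label> and cpm_<label>; with
    ``lengths=True`` also cpkm_<label> (using end − start as the length).
    The interval columns (chrom, start, end, plus any annotation columns the
    caller included) are carried through.
    """
    out = intervals.reset_index(drop=True).copy()
    out["length"] = out["end"] - out["start"]
    for lib in libs:
        raw = count_overlaps(lib, out)
        out[f"raw_{lib.label}"] = raw
        out[f"cpm_{lib.label}"] = cpm(raw, lib.library_size)
        if lengths:
            out[f"cpkm_{lib.label}"] = cpkm(raw, lib.library_size, out["length"].to_numpy())
    return out


def write_bedgraph(track: BinnedTrack, path) -> None:
    """Write a 4-column bedGraph (0-based half-open)."""
    track.bins.to_csv(path, sep="\t", header=False, index=False, float_format="%.6g")


def write_fragments_bed(lib: FragmentLibrary, path) -> None:
    lib.fragments.to_csv(path, sep="\t", header=False, index=False)
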