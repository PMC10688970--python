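"""Gene models, promoters, and chromosome classification.

This module turns a GTF annotation into the tables the quantification
pipeline scores against: one record per transcript (the union span of its
features), one promoter per distinct (gene, TSS) pair, and a strand-aware
scoring window around each TSS.  TSS derivation follows the convention used
for *Drosophila* promoter tables: the minimum feature coordinate of a
'+'-strand transcript is its TSS, the maximum coordinate of a '−'-strand
transcript is its TSS; duplicate TSSs of the same gene are collapsed while
a coordinate shared by two distinct genes yields one promoter per gene.

Coordinates: GTF input is 1-based inclusive and is converted exactly once
to 0-based half-open on parse; every downstream structure (promoter TSS,
windows, BED/bedGraph output) is 0-based half-open.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TranscriptRecord",
    "PromoterRecord",
    "Interval",
    "ChromosomeClass",
    "GtfParseError",
    "parse_gene_models",
    "derive_promoters",
    "promoter_window",
    "upstream_promoter_flags",
    "classify_chromosome",
    "normalize_chrom",
    "gene_spans",
    "promoter_table",
    "read_chrom_sizes",
]

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


class GtfParseError(ValueError):
    """A GTF line that could not be interpreted, with its line number."""

    def __init__(self, lineno: int, message: str):
        self.lineno = lineno
        super().__init__(f"GTF line {lineno}: {message}")


@dataclass(frozen=True)
class TranscriptRecord:
    """One transcript model; coordinates are 1-based inclusive as in GTF."""

    transcript_id: str
    gene_id: str
    gene_name: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"{self.transcript_id}: start {self.start} > end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.transcript_id}: strand {self.strand!r}")
        if not self.chrom:
            raise ValueError(f"{self.transcript_id}: empty chromosome name")


@dataclass(frozen=True)
class PromoterRecord:
    """One promoter: a distinct (gene, TSS) pair.  ``tss`` is 0-based."""

    gene_id: str
    gene_name: str
    chrom: str
    tss: int
    strand: str


@dataclass(frozen=True)
class Interval:
    """Half-open genomic interval, 0-based."""

    chrom: str
    start: int
    end: int
    name: str = ""
    strand: str | None = None

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad interval [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start


class ChromosomeClass(str, Enum):
    MAJOR_AUTOSOME = "major_autosome"  # 2L, 2R, 3L, 3R
    FOURTH = "fourth"
    SEX_X = "sex_X"
    SEX_Y = "sex_Y"
    OTHER = "other"  # scaffolds, transposon consensi, mitochondrion


def normalize_chrom(name: str) -> str:
    """Strip a UCSC-style ``chr`` prefix, leaving bare FlyBase names."""
    if name.lower().startswith("chr") and len(name) > 3:
        return name[3:]
    return name


def classify_chromosome(name: str) -> ChromosomeClass:
    """Map a chromosome name to its dosage class.

    The second and third chromosome arms are the diploid reference set; the
    fourth chromosome is diploid but quasi-heterochromatic; X and Y are
    hemizygous in males.  Everything else (transposon consensus scaffolds,
    the mitochondrion, unplaced contigs) is ``other``.
    """
    n = normalize_chrom(name)
    if n in ("2L", "2R", "3L", "3R"):
        return ChromosomeClass.MAJOR_AUTOSOME
    if n == "4":
        return ChromosomeClass.FOURTH
    if n == "X":
        return ChromosomeClass.SEX_X
    if n == "Y":
        return ChromosomeClass.SEX_Y
    return ChromosomeClass.OTHER


def _iter_lines(source) -> Iterator[str]:
    if isinstance(source, (str, Path)):
        text = str(source)
        if "\n" in text or "\t" in text:
            yield from text.splitlines()
        else:
            with open(source) as fh:
                yield from fh
    else:
        yield from source


def parse_gene_models(gtf: Iterable[str] | str | Path) -> list[TranscriptRecord]:
    """Parse a GTF stream into one record per transcript.

    ``gtf`` may be a path, an open file, an iterable of lines, or GTF text.
    A transcript's span is the min/max over all its feature lines.  Lines
    that cannot be parsed raise :class:`GtfParseError` with the 1-based line
    number; nothing is silently dropped.
    """
    spans: dict[str, dict] = {}
    for lineno, line in enumerate(_iter_lines(gtf), start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise GtfParseError(lineno, f"expected 9 tab-separated fields, got {len(fields)}")
        chrom, _source, _feature, start_s, end_s, _score, strand, _frame, attrs = fields
        try:
            start, end = int(start_s), int(end_s)
        except ValueError:
            raise GtfParseError(lineno, f"non-integer coordinates {start_s!r}..{end_s!r}") from None
        if strand not in ("+", "-"):
            # gene-level or strandless features cannot seed a transcript
            if strand == ".":
                continue
            raise GtfParseError(lineno, f"bad strand {strand!r}")
        attr = dict(_ATTR_RE.findall(attrs))
        gene_id = attr.get("gene_id")
        tx_id = attr.get("transcript_id")
        if gene_id is None:
            raise GtfParseError(lineno, "missing mandatory attribute gene_id")
        if tx_id is None:
            # gene feature lines carry no transcript_id; they do not define spans
            if _feature == "gene":
                continue
            raise GtfParseError(lineno, "missing mandatory attribute transcript_id")
        gene_name = attr.get("gene_symbol") or attr.get("gene_name") or gene_id
        rec = spans.get(tx_id)
        if rec is None:
            spans[tx_id] = {
                "gene_id": gene_id,
                "gene_name": gene_name,
                "chrom": normalize_chrom(chrom),
                "start": start,
                "end": end,
                "strand": strand,
            }
        else:
            rec["start"] = min(rec["start"], start)
            rec["end"] = max(rec["end"], end)
    return [
        TranscriptRecord(transcript_id=tx_id, **rec) for tx_id, rec in spans.items()
    ]


def derive_promoters(transcripts: Sequence[TranscriptRecord]) -> list[PromoterRecord]:
    """Derive the promoter (TSS) table from transcript models.

    TSS = minimum coordinate for '+' transcripts, maximum for '−'.  Within a
    gene, duplicate TSS coordinates collapse to one record (the one from the
    lexicographically smallest transcript_id, which is immaterial since all
    collapsed records are identical).  The same coordinate shared by two
    distinct genes is retained once per gene.  Output order is sorted by
    (chrom, tss, gene_id) and is independent of input order.
    """
    seen: dict[tuple, str] = {}
    for t in sorted(transcripts, key=lambda t: t.transcript_id):
        tss_1based = t.start if t.strand == "+" else t.end
        key = (t.gene_id, t.chrom, tss_1based - 1, t.strand)
        if key not in seen:
            seen[key] = t.gene_name
    records = [
        PromoterRecord(gene_id=g, gene_name=name, chrom=c, tss=tss, strand=s)
        for (g, c, tss, s), name in seen.items()
    ]
    records.sort(key=lambda p: (p.chrom, p.tss, p.gene_id))
    return records


def promoter_window(
    p: PromoterRecord,
    up: int = 200,
    down: int = 500,
    chrom_len: int | None = None,
    oriented: bool = True,
) -> Interval:
    """Scoring window spanning ``up`` bp upstream through ``down`` bp
    downstream of the TSS, inclusive of the TSS itself (701 bp at the
    defaults, unless clipped to the chromosome).

    ``oriented=False`` ignores strand and always takes the genomic
    left-to-right window (−up..+down in reference coordinates).
    """
    if chrom_len is not None and not (0 <= p.tss < chrom_len):
        raise ValueError(f"TSS {p.tss} outside chromosome {p.chrom} (length {chrom_len})")
    if p.strand == "+" or not oriented:
        start, end = p.tss - up, p.tss + down + 1
    else:
        start, end = p.tss - down, p.tss + up + 1
    start = max(start, 0)
    if chrom_len is not None:
        end = min(end, chrom_len)
    return Interval(p.chrom, start, end, name=p.gene_id, strand=p.strand)


def _promoters_frame(promoters: Sequence[PromoterRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [p.gene_id for p in promoters],
            "gene_name": [p.gene_name for p in promoters],
            "chrom": [p.chrom for p in promoters],
            "tss": [p.tss for p in promoters],
            "strand": [p.strand for p in promoters],
        }
    )


def upstream_promoter_flags(
    promoters: Sequence[PromoterRecord], max_dist: int = 1000
) -> pd.DataFrame:
    """For each promoter, the closest promoter of a *different* gene lying
    5′ of it in its own orientation.

    Returns a frame aligned to the input order with columns
    ``upstream_gene`` (or None), ``upstream_distance`` (bp, non-negative;
    NaN when there is no qualifying neighbor) and ``upstream_within``
    (distance ≤ ``max_dist``).  A different-gene promoter at the identical
    coordinate counts as upstream at distance 0.  Promoters of the same gene
    never qualify.
    """
    df = _promoters_frame(promoters)
    n = len(df)
    up_gene = np.full(n, None, dtype=object)
    up_dist = np.full(n, np.nan)
    for _, grp in df.groupby("chrom", sort=False):
        tss = grp["tss"].to_numpy()
        genes = grp["gene_id"].to_numpy()
        strands = grp["strand"].to_numpy()
        idx = grp.index.to_numpy()
        for j in range(len(grp)):
            other = genes != genes[j]
            if strands[j] == "+":
                cand = other & (tss <= tss[j])
                if not cand.any():
                    continue
                dists = tss[j] - tss[cand]
            else:
                cand = other & (tss >= tss[j])
                if not cand.any():
                    continue
                dists = tss[cand] - tss[j]
            cand_genes = genes[cand]
            best = np.min(dists)
            # tie-break on gene_id for determinism
            winners = sorted(cand_genes[dists == best])
            up_gene[idx[j]] = winners[0]
            up_dist[idx[j]] = best
    return pd.DataFrame(
        {
            "upstream_gene": up_gene,
            "upstream_distance": up_dist,
            "upstream_within": (up_dist <= max_dist) & ~np.isnan(up_dist),
        }
    )


def gene_spans(transcripts: Sequence[TranscriptRecord]) -> pd.DataFrame:
    """Union span per gene (min start, max end over its transcripts),
    0-based half-open, for gene-body scoring."""
    rows: dict[str, dict] = {}
    for t in transcripts:
        r = rows.get(t.gene_id)
        if r is None:
            rows[t.gene_id] = {
                "gene_id": t.gene_id,
                "gene_name": t.gene_name,
                "chrom": t.chrom,
                "start": t.start - 1,
                "end": t.end,
                "strand": t.strand,
            }
        else:
            r["start"] = min(r["start"], t.start - 1)
            r["end"] = max(r["end"], t.end)
    df = pd.DataFrame(list(rows.values()))
    if not df.empty:
        df = df.sort_values(["chrom", "start", "gene_id"]).reset_index(drop=True)
        df["length"] = df["end"] - df["start"]
    return df


def read_chrom_sizes(path) -> dict[str, int]:
    """Read a two-column (name, length) chrom.sizes TSV into a dict."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"], comment="#")
    return {normalize_chrom(str(c)): int(l) for c, l in zip(df["chrom"], df["length"])}


def promoter_table(
    promoters: Sequence[PromoterRecord],
    chrom_sizes: dict[str, int],
    up: int = 200,
    down: int = 500,
    max_dist: int = 1000,
    oriented: bool = True,
) -> pd.DataFrame:
    """Assemble the full promoter table: windows plus upstream-neighbor
    relations.  ``tss`` in the output is 1-based for human consumption;
    ``window_start``/``window_end`` stay 0-based half-open."""
    flags = upstream_promoter_flags(promoters, max_dist=max_dist)
    rows = []
    for p in promoters:
        w = promoter_window(p, up=up, down=down, chrom_len=chrom_sizes.get(p.chrom), oriented=oriented)
        rows.append(
            {
                "gene_id": p.gene_id,
                "gene_name": p.gene_name,
                "chrom": p.chrom,
                "tss": p.tss + 1,
                "strand": p.strand,
                "window_start": w.start,
                "window_end": w.end,
            }
        )
    out = pd.DataFrame(rows)
    out["upstream_neighbor"] = flags["upstream_gene"]
    out["upstream_distance"] = flags["upstream_distance"]
    out["upstream_within_1kb"] = flags["upstream_within"]
    return out
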