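"""Read counting at intron boundaries/junctions and mis-splicing indices.

Per intron and sample this module counts:

* ``n5`` / ``n3`` — exon-intron boundary reads: one contiguous aligned block
  covering the splice site with at least ``min_overhang`` bases on each side;
* ``n_canonical`` — spliced reads whose alignment gap equals the annotated
  intron exactly, with sufficient overhang in both flanking blocks;
* ``aberrant`` — spliced reads whose gap shares exactly one endpoint with the
  canonical junction (cryptic splice site) or spans the locus while skipping
  a flanking exon;
* per-base intron coverage and depth.

From these it computes MSI_ret, MSI_AS and the IR ratio.  Two denominator
conventions are provided: ``fraction`` (bounded, boundary evidence over total
evidence) and ``literal`` (ratio to canonical junction reads); and the two
boundary counts may be combined by ``mean`` (default) or ``sum``.
"""

from __future__ import annotations

import bisect
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from misplice.catalog import IntronRecord

logger = logging.getLogger(__name__)

DEFAULT_MIN_OVERHANG = 6

#: fraction of positions trimmed from each extreme when averaging intron depth
TRIM_PROPORTION = 0.05


@dataclass
class AlignedSegmentLite:
    """Minimal alignment: reference blocks with spliced-out gaps between them."""

    chrom: str
    blocks: list[tuple[int, int]]
    sample_id: str = ""
    strand: str | None = None

    def validate(self) -> None:
        for s, e in self.blocks:
            if e <= s:
                raise ValueError(f"empty block ({s},{e})")
        for (_, e1), (s2, _) in zip(self.blocks, self.blocks[1:]):
            if s2 < e1:
                raise ValueError("blocks overlap or are unsorted")

    @property
    def reference_span(self) -> tuple[int, int]:
        return self.blocks[0][0], self.blocks[-1][1]

    def gaps(self) -> list[tuple[int, int]]:
        return [(e1, s2) for (_, e1), (s2, _) in zip(self.blocks, self.blocks[1:])]


@dataclass
class IntronSampleCounts:
    """Per-intron per-sample read-class counts and coverage summaries."""

    intron_id: str
    sample_id: str
    n5: int = 0
    n3: int = 0
    n_canonical: int = 0
    aberrant: dict[tuple[int, int], int] = field(default_factory=dict)
    coverage: float = 0.0
    depth: int = 0
    intronic_abundance: float = 0.0

    @property
    def n_aberrant(self) -> int:
        return sum(self.aberrant.values())


@dataclass
class MsiValue:
    intron_id: str
    sample_id: str
    msi_ret: float
    msi_as: float
    ir_ratio: float


def blocks_from_cigar(pos: int, cigartuples: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Reference-aligned blocks from a SAM CIGAR starting at 0-based ``pos``.

    M/=/X and D consume reference within a block; N closes the block and
    opens a gap; I/S/H/P consume no reference.
    """
    blocks: list[tuple[int, int]] = []
    cur_start = pos
    cur = pos
    for op, length in cigartuples:
        if op in (0, 2, 7, 8):  # M, D, =, X
            cur += length
        elif op == 3:  # N
            if cur > cur_start:
                blocks.append((cur_start, cur))
            cur += length
            cur_start = cur
        # 1=I, 4=S, 5=H, 6=P: no reference consumed
    if cur > cur_start:
        blocks.append((cur_start, cur))
    return blocks


def iter_alignments(path: str | Path, sample_id: str | None = None) -> Iterator[AlignedSegmentLite]:
    """Stream mapped reads from a SAM/BAM file as AlignedSegmentLite."""
    import pysam

    path = str(path)
    sample = sample_id if sample_id is not None else Path(path).stem
    with pysam.AlignmentFile(path, check_sq=False) as fh:
        for read in fh:
            if read.is_unmapped or read.cigartuples is None:
                continue
            yield AlignedSegmentLite(
                chrom=read.reference_name,
                blocks=blocks_from_cigar(read.reference_start, read.cigartuples),
                sample_id=sample,
                strand="-" if read.is_reverse else "+",
            )


class IntronAccumulator:
    """Streaming evidence counter for one intron in one sample."""

    def __init__(
        self,
        intron: IntronRecord,
        sample_id: str,
        min_overhang: int = DEFAULT_MIN_OVERHANG,
        stranded: str | None = None,
    ):
        if min_overhang < 1:
            raise ValueError("min_overhang must be >= 1")
        self.intron = intron
        self.sample_id = sample_id
        self.m = min_overhang
        self.stranded = stranded
        self.n5 = 0
        self.n3 = 0
        self.n_canonical = 0
        self.aberrant: dict[tuple[int, int], int] = {}
        self.depth = 0
        self._base_depth = np.zeros(intron.length, dtype=np.int32)
        # genomic-left/right flanking exons regardless of strand
        if intron.strand == "+":
            self._left_exon, self._right_exon = intron.upstream_exon, intron.downstream_exon
        else:
            self._left_exon, self._right_exon = intron.downstream_exon, intron.upstream_exon

    def _concordant(self, read: AlignedSegmentLite) -> bool:
        if self.stranded is None or read.strand is None:
            return True
        want = self.intron.strand if self.stranded == "fr" else ("-" if self.intron.strand == "+" else "+")
        return read.strand == want

    def add(self, read: AlignedSegmentLite) -> None:
        if read.chrom != self.intron.chrom or not self._concordant(read):
            return
        start, end, m = self.intron.start, self.intron.end, self.m
        hit = False
        blocks = read.blocks
        for bs, be in blocks:
            if bs <= start - m and be >= start + m:
                self.n5 += 1
                hit = True
            if bs <= end - m and be >= end + m:
                self.n3 += 1
                hit = True
            lo, hi = max(bs, start), min(be, end)
            if hi > lo:
                self._base_depth[lo - start : hi - start] += 1
                hit = True
        for gi, (gs, ge) in enumerate(read.gaps()):
            left_len = blocks[gi][1] - blocks[gi][0]
            right_len = blocks[gi + 1][1] - blocks[gi + 1][0]
            if left_len < m or right_len < m:
                continue
            if (gs, ge) == (start, end):
                self.n_canonical += 1
                hit = True
            elif (gs == start) != (ge == end):
                self.aberrant[(gs, ge)] = self.aberrant.get((gs, ge), 0) + 1
                hit = True
            elif gs < start and ge > end:
                skips_left = gs <= self._left_exon[0]
                skips_right = ge >= self._right_exon[1]
                if skips_left or skips_right:
                    self.aberrant[(gs, ge)] = self.aberrant.get((gs, ge), 0) + 1
                    hit = True
        span = read.reference_span
        if hit or (span[0] < end + m and span[1] > start - m):
            self.depth += 1

    def finish(self) -> IntronSampleCounts:
        covered = int(np.count_nonzero(self._base_depth))
        n = self.intron.length
        abundance = float(stats.trim_mean(self._base_depth, TRIM_PROPORTION)) if n else 0.0
        return IntronSampleCounts(
            intron_id=self.intron.intron_id,
            sample_id=self.sample_id,
            n5=self.n5,
            n3=self.n3,
            n_canonical=self.n_canonical,
            aberrant=self.aberrant,
            coverage=covered / n if n else 0.0,
            depth=self.depth,
            intronic_abundance=abundance,
        )


def count_intron_evidence(
    intron: IntronRecord,
    reads: Iterable[AlignedSegmentLite],
    min_overhang: int = DEFAULT_MIN_OVERHANG,
    stranded: str | None = None,
    sample_id: str = "",
) -> IntronSampleCounts:
    """Count boundary, canonical-junction and aberrant-junction evidence.

    Empty read streams produce all-zero counts; ``min_overhang < 1`` raises.
    """
    acc = IntronAccumulator(intron, sample_id, min_overhang=min_overhang, stranded=stranded)
    for read in reads:
        read.validate()
        acc.add(read)
    return acc.finish()


def msi_ret(counts: IntronSampleCounts, mode: str = "fraction", boundary: str = "mean") -> float:
    """Retention mis-splicing index as a percentage.

    ``boundary`` combines n5 and n3 by arithmetic mean (default) or sum.
    ``fraction`` mode returns 100*B/(B+C) in [0,100]; ``literal`` returns
    100*B/C with +inf when C=0 and B>0.  B=0 returns 0.
    """
    if boundary == "mean":
        b = (counts.n5 + counts.n3) / 2.0
    elif boundary == "sum":
        b = float(counts.n5 + counts.n3)
    else:
        raise ValueError(f"unknown boundary aggregation {boundary!r}")
    return _msi(b, float(counts.n_canonical), mode)


def msi_as(counts: IntronSampleCounts, mode: str = "fraction") -> float:
    """Alternative-splicing mis-splicing index as a percentage."""
    return _msi(float(counts.n_aberrant), float(counts.n_canonical), mode)


def _msi(numer: float, canonical: float, mode: str) -> float:
    if numer == 0:
        return 0.0
    if mode == "fraction":
        return 100.0 * numer / (numer + canonical)
    if mode == "literal":
        return math.inf if canonical == 0 else 100.0 * numer / canonical
    raise ValueError(f"unknown MSI mode {mode!r}")


def ir_ratio(intronic_abundance: float, spliced: float) -> float:
    """IR ratio: intronic abundance over intronic + spliced; 0 when both 0."""
    if intronic_abundance < 0 or spliced < 0:
        raise ValueError("ir_ratio inputs must be non-negative")
    total = intronic_abundance + spliced
    return intronic_abundance / total if total > 0 else 0.0


class _IntronIndex:
    """Overlap lookup of intron windows, per chromosome."""

    def __init__(self, introns: list[IntronRecord], pad: int):
        self._by_chrom: dict[str, tuple[list[int], list[tuple[int, int, int]]]] = {}
        self._max_len: dict[str, int] = {}
        per_chrom: dict[str, list[tuple[int, int, int]]] = {}
        for idx, intron in enumerate(introns):
            ws = min(intron.start - pad, intron.upstream_exon[0], intron.downstream_exon[0])
            we = max(intron.end + pad, intron.upstream_exon[1], intron.downstream_exon[1])
            per_chrom.setdefault(intron.chrom, []).append((ws, we, idx))
        for chrom, rows in per_chrom.items():
            rows.sort()
            self._by_chrom[chrom] = ([r[0] for r in rows], rows)
            self._max_len[chrom] = max(r[1] - r[0] for r in rows)

    def overlapping(self, chrom: str, start: int, end: int) -> list[int]:
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return []
        starts, rows = entry
        lo = bisect.bisect_left(starts, start - self._max_len[chrom])
        hi = bisect.bisect_right(starts, end)
        return [rows[i][2] for i in range(lo, hi) if rows[i][1] > start and rows[i][0] < end]


def quantify_sample(
    introns: list[IntronRecord],
    reads: Iterable[AlignedSegmentLite],
    sample_id: str,
    min_overhang: int = DEFAULT_MIN_OVERHANG,
    stranded: str | None = None,
) -> list[IntronSampleCounts]:
    """Single pass over a read stream, counting evidence for every intron."""
    accs = [
        IntronAccumulator(i, sample_id, min_overhang=min_overhang, stranded=stranded)
        for i in introns
    ]
    index = _IntronIndex(introns, pad=min_overhang)
    for read in reads:
        span = read.reference_span
        for idx in index.overlapping(read.chrom, span[0], span[1]):
            accs[idx].add(read)
    return [acc.finish() for acc in accs]


def quantify(
    introns: list[IntronRecord],
    sam_paths: Mapping[str, str | Path],
    min_overhang: int = DEFAULT_MIN_OVERHANG,
    mode: str = "fraction",
    boundary: str = "mean",
    stranded: str | None = None,
) -> pd.DataFrame:
    """Quantify MSI/IR over several samples; returns the long-format table.

    ``sam_paths`` maps sample id -> SAM/BAM path.  Output columns:
    intron_id, sample, n5, n3, n_canonical, n_aberrant, coverage, depth,
    intronic_abundance, msi_ret, msi_as, ir_ratio.
    """
    rows = []
    for sample, path in sam_paths.items():
        counts = quantify_sample(
            introns,
            iter_alignments(path, sample),
            sample,
            min_overhang=min_overhang,
            stranded=stranded,
        )
        for c in counts:
            rows.append(
                {
                    "intron_id": c.intron_id,
                    "sample": sample,
                    "n5": c.n5,
                    "n3": c.n3,
                    "n_canonical": c.n_canonical,
                    "n_aberrant": c.n_aberrant,
                    "coverage": c.coverage,
                    "depth": c.depth,
                    "intronic_abundance": c.intronic_abundance,
                    "msi_ret": msi_ret(c, mode=mode, boundary=boundary),
                    "msi_as": msi_as(c, mode=mode),
                    "ir_ratio": ir_ratio(c.intronic_abundance, c.n_canonical),
                }
            )
    return pd.DataFrame(rows)
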