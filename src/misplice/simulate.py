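"""Synthetic genome, annotation and spliced-read generator with ground truth.

Builds a toy reference in which a configurable fraction of introns carry the
minor-type (U12) 5' splice-site and branch-point consensus while all others
carry plain GT..AG ends, then emits two-condition replicated SAM read sets
with known per-intron retention (rho) and aberrant-splicing (alpha)
fractions.

Sampling model, per intron and sample: D ~ Poisson(depth); each of the D
transcript molecules is retained with probability rho (emitting one
boundary-spanning read at EACH of the 5' and 3' boundaries, so the
mean-of-boundaries MSI_ret estimator is unbiased for rho), aberrant with
probability alpha (one read across a fixed cryptic junction 50 nt into the
downstream exon), and canonical otherwise (one exact-junction spliced read).
Retained molecules additionally tile the intron body so the 100%-coverage
filter is satisfiable (disable with ``tile_retained=False``).  Every emitted
read respects the configured minimum overhang by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from misplice.catalog import (
    BPS_CONSENSUS,
    FIVE_SS_CONSENSUS,
    SpliceMotifModel,
    make_intron_id,
    motif_scores,
    revcomp,
)

CHROM = "chrT"
_GENE_GAP = 200
_ALT_JUNCTION_OFFSET = 50  # cryptic 3'ss this far into the downstream exon
_BPS_OFFSET = 25  # branch point planted this far upstream of the intron 3' end


@dataclass
class ConditionSim:
    """True splicing parameters for one condition.

    ``rho``/``alpha`` may be scalars or sequences; sequences are cycled over
    introns in reference order.
    """

    rho: float | Sequence[float] = 0.0
    alpha: float | Sequence[float] = 0.0


@dataclass
class SimConfig:
    n_genes: int = 10
    exons_per_gene: tuple[int, int] = (2, 4)
    exon_length: tuple[int, int] = (160, 240)
    intron_length: tuple[int, int] = (110, 160)
    minor_intron_fraction: float = 0.3
    read_length: int = 100
    min_overhang: int = 6
    depth: float = 100.0  # Poisson mean per intron per sample
    conditions: dict[str, ConditionSim] = field(
        default_factory=lambda: {"treated": ConditionSim(), "control": ConditionSim()}
    )
    replicates: int = 4
    tile_retained: bool = True
    minus_strand_fraction: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.read_length <= 2 * self.min_overhang:
            raise ValueError("read_length must exceed twice the minimum overhang")
        if self.n_genes < 1 or self.replicates < 1:
            raise ValueError("n_genes and replicates must be positive")
        for lo, hi in (self.exons_per_gene, self.exon_length, self.intron_length):
            if lo <= 0 or hi < lo:
                raise ValueError("length/count ranges must be positive and ordered")
        l, m = self.read_length, self.min_overhang
        if self.exon_length[0] < _ALT_JUNCTION_OFFSET + l - m:
            raise ValueError(
                f"minimum exon length must be >= {_ALT_JUNCTION_OFFSET + l - m} "
                "to place cryptic-junction reads"
            )
        if self.exon_length[0] < l:
            raise ValueError("minimum exon length must be >= read_length")
        if self.intron_length[0] <= l - 2 * m:
            raise ValueError("minimum intron length must exceed read_length - 2*min_overhang")
        if self.intron_length[0] < _BPS_OFFSET + 20:
            raise ValueError(f"minimum intron length must be >= {_BPS_OFFSET + 20}")
        for name, cond in self.conditions.items():
            rho = np.atleast_1d(np.asarray(cond.rho, dtype=float))
            alpha = np.atleast_1d(np.asarray(cond.alpha, dtype=float))
            if (rho < 0).any() or (alpha < 0).any():
                raise ValueError(f"condition {name}: rho/alpha must be >= 0")
            if (np.resize(rho, max(rho.size, alpha.size)) + np.resize(alpha, max(rho.size, alpha.size)) > 1).any():
                raise ValueError(f"condition {name}: rho + alpha must be <= 1")


@dataclass
class SimIntron:
    """One planted intron, genomic coordinates plus oriented structure."""

    intron_id: str
    gene_id: str
    transcript_id: str
    start: int
    end: int
    strand: str
    is_minor: bool
    up_exon: tuple[int, int]  # genomic-left exon
    down_exon: tuple[int, int]  # genomic-right exon
    alt_junction: tuple[int, int]  # genomic gap of the fixed aberrant event


@dataclass
class ToyReference:
    fasta: Path
    gtf: Path
    minor_list: Path
    chrom: str
    sequence: str
    introns: list[SimIntron]


@dataclass
class SimTruth:
    """Realized per-intron per-sample read-class counts plus parameters."""

    table: pd.DataFrame
    seed: int

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        self.table.to_csv(path, sep="\t", index=False)
        return path

    @classmethod
    def read(cls, path: str | Path, seed: int = -1) -> "SimTruth":
        return cls(pd.read_csv(path, sep="\t"), seed)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def _plant_intron(rng: np.random.Generator, length: int, minor: bool, motif: SpliceMotifModel) -> str:
    """Oriented intronic sequence; major introns are re-rolled until they do
    not satisfy the minor motif thresholds (guarantees clean truth labels)."""
    if minor:
        mid_len = length - len(FIVE_SS_CONSENSUS) - _BPS_OFFSET
        tail_len = _BPS_OFFSET - len(BPS_CONSENSUS) - 2
        seq = (
            FIVE_SS_CONSENSUS
            + _random_seq(rng, mid_len)
            + BPS_CONSENSUS
            + _random_seq(rng, tail_len)
            + "AG"
        )
        assert len(seq) == length
        return seq
    while True:
        seq = "GT" + _random_seq(rng, length - 4) + "AG"
        s5, sb = motif_scores(seq, motif)
        if not (s5 >= motif.min_score_5ss and sb >= motif.min_score_bps):
            return seq


def make_toy_reference(config: SimConfig, out_dir: str | Path) -> ToyReference:
    """Write genome FASTA, annotation GTF and minor-intron TSV; deterministic
    for a fixed seed."""
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    motif = SpliceMotifModel.from_consensus()

    chrom_parts: list[str] = [_random_seq(rng, _GENE_GAP)]
    cursor = _GENE_GAP
    gtf_lines: list[str] = []
    minor_rows: list[tuple[str, int, int, str]] = []
    introns: list[SimIntron] = []

    for g in range(config.n_genes):
        gene_id = f"gene{g:04d}"
        tx_id = f"tx{g:04d}"
        strand = "-" if rng.random() < config.minus_strand_fraction else "+"
        k = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        exon_lens = rng.integers(config.exon_length[0], config.exon_length[1] + 1, k)
        intron_lens = rng.integers(config.intron_length[0], config.intron_length[1] + 1, k - 1)
        minor_flags = rng.random(k - 1) < config.minor_intron_fraction

        # build the gene in transcript orientation
        parts: list[str] = []
        oriented_exons: list[tuple[int, int]] = []
        oriented_introns: list[tuple[int, int]] = []
        pos = 0
        for i in range(k):
            parts.append(_random_seq(rng, int(exon_lens[i])))
            oriented_exons.append((pos, pos + int(exon_lens[i])))
            pos += int(exon_lens[i])
            if i < k - 1:
                parts.append(_plant_intron(rng, int(intron_lens[i]), bool(minor_flags[i]), motif))
                oriented_introns.append((pos, pos + int(intron_lens[i])))
                pos += int(intron_lens[i])
        gene_seq = "".join(parts)
        glen = len(gene_seq)
        g0 = cursor

        def to_genomic(interval: tuple[int, int]) -> tuple[int, int]:
            a, b = interval
            if strand == "+":
                return (g0 + a, g0 + b)
            return (g0 + glen - b, g0 + glen - a)

        chrom_parts.append(gene_seq if strand == "+" else revcomp(gene_seq))
        chrom_parts.append(_random_seq(rng, _GENE_GAP))
        cursor += glen + _GENE_GAP

        genomic_exons = sorted(to_genomic(e) for e in oriented_exons)
        gtf_lines.append(_gtf_line("gene", genomic_exons[0][0], genomic_exons[-1][1], strand, gene_id, None))
        gtf_lines.append(_gtf_line("transcript", genomic_exons[0][0], genomic_exons[-1][1], strand, gene_id, tx_id))
        for es, ee in genomic_exons:
            gtf_lines.append(_gtf_line("exon", es, ee, strand, gene_id, tx_id))

        for i, (oi_s, oi_e) in enumerate(oriented_introns):
            gs, ge = to_genomic((oi_s, oi_e))
            up_or = oriented_exons[i]  # transcript-upstream exon
            down_or = oriented_exons[i + 1]
            up_g, down_g = to_genomic(up_or), to_genomic(down_or)
            alt_or = (oi_s, oi_e + _ALT_JUNCTION_OFFSET)
            alt_g = to_genomic(alt_or)
            left_exon = min(up_g, down_g)
            right_exon = max(up_g, down_g)
            introns.append(
                SimIntron(
                    intron_id=make_intron_id(CHROM, gs, ge, strand),
                    gene_id=gene_id,
                    transcript_id=tx_id,
                    start=gs,
                    end=ge,
                    strand=strand,
                    is_minor=bool(minor_flags[i]),
                    up_exon=left_exon,
                    down_exon=right_exon,
                    alt_junction=alt_g,
                )
            )
            if minor_flags[i]:
                minor_rows.append((CHROM, gs, ge, strand))

    sequence = "".join(chrom_parts)
    fasta_path = out_dir / "genome.fa"
    with open(fasta_path, "w") as fh:
        fh.write(f">{CHROM}\n")
        for i in range(0, len(sequence), 60):
            fh.write(sequence[i : i + 60] + "\n")
    gtf_path = out_dir / "annotation.gtf"
    with open(gtf_path, "w") as fh:
        fh.writelines(gtf_lines)
    minor_path = out_dir / "minor_introns.tsv"
    with open(minor_path, "w") as fh:
        fh.write("chrom\tstart\tend\tstrand\n")
        for row in sorted(minor_rows):
            fh.write("\t".join(map(str, row)) + "\n")
    introns.sort(key=lambda i: (i.start, i.end))
    return ToyReference(fasta_path, gtf_path, minor_path, CHROM, sequence, introns)


def _gtf_line(feature: str, start0: int, end0: int, strand: str, gene_id: str, tx_id: str | None) -> str:
    attrs = f'gene_id "{gene_id}";'
    if tx_id is not None:
        attrs += f' transcript_id "{tx_id}";'
    return f"{CHROM}\tmisplice_sim\t{feature}\t{start0 + 1}\t{end0}\t.\t{strand}\t.\t{attrs}\n"


def _per_intron(value: float | Sequence[float], n: int) -> np.ndarray:
    arr = np.atleast_1d(np.asarray(value, dtype=float))
    return np.resize(arr, n)


def simulate_reads(
    reference: ToyReference, config: SimConfig, out_dir: str | Path
) -> tuple[dict[str, Path], SimTruth]:
    """Emit one coordinate-sorted SAM per sample plus the realized truth.

    Sample ids are ``{condition}_{replicate}``.  Each sample uses an RNG
    stream keyed by (seed, sample index) so replicates are independent but
    reproducible.
    """
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    n_introns = len(reference.introns)
    l, m = config.read_length, config.min_overhang
    seq = reference.sequence
    header = f"@HD\tVN:1.6\tSO:coordinate\n@SQ\tSN:{reference.chrom}\tLN:{len(seq)}\n"

    sam_paths: dict[str, Path] = {}
    truth_rows: list[dict] = []
    sample_index = 0
    for cond_name, cond in config.conditions.items():
        rho = _per_intron(cond.rho, n_introns)
        alpha = _per_intron(cond.alpha, n_introns)
        for rep in range(config.replicates):
            sample = f"{cond_name}_{rep + 1}"
            rng = np.random.default_rng([config.seed, sample_index])
            sample_index += 1
            reads: list[tuple[int, str, str]] = []  # (pos, cigar, read sequence)
            for idx, intron in enumerate(reference.introns):
                counts = _simulate_intron(
                    rng, intron, rho[idx], alpha[idx], config, reads, seq, l, m
                )
                truth_rows.append(
                    {
                        "intron_id": intron.intron_id,
                        "sample": sample,
                        "condition": cond_name,
                        "intron_class": "minor" if intron.is_minor else "major",
                        "rho": rho[idx],
                        "alpha": alpha[idx],
                        **counts,
                    }
                )
            reads.sort(key=lambda r: r[0])
            path = out_dir / f"{sample}.sam"
            with open(path, "w") as fh:
                fh.write(header)
                for i, (pos, cigar, rseq) in enumerate(reads):
                    fh.write(
                        f"r{i:07d}\t0\t{reference.chrom}\t{pos + 1}\t255\t{cigar}\t*\t0\t0\t{rseq}\t*\n"
                    )
            sam_paths[sample] = path

    truth = SimTruth(pd.DataFrame(truth_rows), config.seed)
    truth.write(out_dir / "truth.tsv")
    return sam_paths, truth


def _simulate_intron(
    rng: np.random.Generator,
    intron: SimIntron,
    rho: float,
    alpha: float,
    config: SimConfig,
    reads: list[tuple[int, str, str]],
    seq: str,
    l: int,
    m: int,
) -> dict[str, int]:
    depth = int(rng.poisson(config.depth))
    n_ret, n_ab, n_can = (
        rng.multinomial(depth, [rho, alpha, 1.0 - rho - alpha]) if depth else (0, 0, 0)
    )
    start, end = intron.start, intron.end

    def spliced(gap_start: int, gap_end: int, n: int) -> None:
        splits = rng.integers(m, l - m + 1, n)
        for s in splits:
            s = int(s)
            b1 = (gap_start - s, gap_start)
            b2 = (gap_end, gap_end + l - s)
            cigar = f"{s}M{gap_end - gap_start}N{l - s}M"
            reads.append((b1[0], cigar, seq[b1[0] : b1[1]] + seq[b2[0] : b2[1]]))

    def boundary(site: int, n: int) -> None:
        offs = rng.integers(m, l - m + 1, n)
        for o in offs:
            p = site - int(o)
            reads.append((p, f"{l}M", seq[p : p + l]))

    spliced(start, end, int(n_can))
    boundary(start, int(n_ret))
    boundary(end, int(n_ret))
    ab_start, ab_end = intron.alt_junction
    spliced(ab_start, ab_end, int(n_ab))

    n_tile = 0
    if config.tile_retained and n_ret > 0:
        length = end - start
        step = max(1, l - 10)
        det_positions = list(range(start, end, step))
        target = max(len(det_positions), round(n_ret * length / l))
        extra = rng.integers(start, end, max(0, target - len(det_positions)))
        for p in det_positions + [int(e) for e in extra]:
            hi = min(p + l, end)
            blen = hi - p
            reads.append((p, f"{blen}M", seq[p:hi]))
            n_tile += 1
    return {
        "n5": int(n_ret),
        "n3": int(n_ret),
        "n_canonical": int(n_can),
        "n_aberrant": int(n_ab),
        "n_tile": n_tile,
        "depth_drawn": depth,
    }


def verify_truth(
    sam_paths: Mapping[str, str | Path],
    truth: SimTruth,
    reference: ToyReference,
    min_overhang: int | None = None,
) -> tuple[bool, pd.DataFrame]:
    """Re-count read classes from the SAM files and compare with the truth.

    Returns (ok, mismatch table); the comparison is keyed by
    (intron_id, sample) so row order in the truth is irrelevant.
    """
    from misplice import quant
    from misplice.catalog import IntronRecord

    m = min_overhang if min_overhang is not None else 6
    records = [
        IntronRecord(
            intron_id=i.intron_id,
            gene_id=i.gene_id,
            transcript_ids={i.transcript_id},
            chrom=CHROM,
            start=i.start,
            end=i.end,
            strand=i.strand,
            ordinal=0,
            upstream_exon=i.up_exon if i.strand == "+" else i.down_exon,
            downstream_exon=i.down_exon if i.strand == "+" else i.up_exon,
            intron_class="minor" if i.is_minor else "major",
        )
        for i in reference.introns
    ]
    mismatches = []
    truth_idx = truth.table.set_index(["intron_id", "sample"])
    per_sample_truth = truth.table.groupby("sample")[
        ["n5", "n3", "n_canonical", "n_aberrant", "n_tile"]
    ].sum()
    for sample, path in sam_paths.items():
        n_seen = 0

        def counted(stream):
            nonlocal n_seen
            for r in stream:
                n_seen += 1
                yield r

        counts = quant.quantify_sample(
            records, counted(quant.iter_alignments(path, sample)), sample, min_overhang=m
        )
        expected_total = int(per_sample_truth.loc[sample].sum())
        if n_seen != expected_total:
            mismatches.append(
                {
                    "intron_id": "*",
                    "sample": sample,
                    "field": "total_reads",
                    "expected": expected_total,
                    "observed": n_seen,
                }
            )
        for c in counts:
            try:
                row = truth_idx.loc[(c.intron_id, sample)]
            except KeyError:
                mismatches.append({"intron_id": c.intron_id, "sample": sample, "field": "missing"})
                continue
            for fld, got in (
                ("n5", c.n5),
                ("n3", c.n3),
                ("n_canonical", c.n_canonical),
                ("n_aberrant", c.n_aberrant),
            ):
                expected = int(row[fld])
                if got != expected:
                    mismatches.append(
                        {
                            "intron_id": c.intron_id,
                            "sample": sample,
                            "field": fld,
                            "expected": expected,
                            "observed": got,
                        }
                    )
    report = pd.DataFrame(mismatches)
    return (report.empty, report)
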