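"""Intron cataloging and minor/major classification.

Builds an intron catalog from transcript models (parsed from GTF/GFF3),
collapses identical-coordinate introns across transcripts, and assigns each
intron a class — ``minor`` (U12-type) or ``major`` (U2-type) — either by
lookup in a user-supplied minor-intron list or by position-weight-matrix
scoring of the 5' splice-site and branch-point windows.

All coordinates are 0-based half-open internally; GTF/GFF3 input is
converted from 1-based inclusive on parse, and BED output is written
0-based half-open.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: Default 5' splice-site consensus for U12-type introns, intron positions +1..+8.
FIVE_SS_CONSENSUS = "GTATCCTT"
#: Default branch-point consensus for U12-type introns (9 nt).
BPS_CONSENSUS = "TTCCTTAAC"
#: Branch-point search window, offsets relative to the intron 3' end.
BPS_SEARCH_WINDOW = (-40, -5)

_MAJORITY_P = 0.91
_MINORITY_P = 0.03
PWM_FLOOR = 1e-3


def revcomp(seq: str) -> str:
    """Reverse-complement a nucleotide string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class TranscriptModel:
    """One transcript: ordered, non-overlapping exons on a single chromosome."""

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]

    def validate(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.transcript_id}: strand must be '+' or '-'")
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript has no exons")
        exons = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 < e1:
                raise ValueError(
                    f"{self.transcript_id}: overlapping exons ({s1},{e1}) and ({s2},{e2})"
                )
        for s, e in exons:
            if e <= s:
                raise ValueError(f"{self.transcript_id}: empty exon ({s},{e})")
        self.exons = exons


@dataclass
class IntronRecord:
    """One intron, possibly shared by several transcripts of a gene.

    ``ordinal`` is the 1-based position of the intron within its first-seen
    transcript, counted 5'->3' in transcript orientation.  ``upstream_exon``
    and ``downstream_exon`` are likewise transcript-oriented: the upstream
    exon abuts the intron's transcript-5' end.
    """

    intron_id: str
    gene_id: str
    transcript_ids: set[str]
    chrom: str
    start: int
    end: int
    strand: str
    ordinal: int
    upstream_exon: tuple[int, int]
    downstream_exon: tuple[int, int]
    intron_class: str = "unclassified"

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def coords(self) -> tuple[str, int, int, str]:
        return (self.chrom, self.start, self.end, self.strand)


def make_intron_id(chrom: str, start: int, end: int, strand: str) -> str:
    return f"{chrom}:{start}-{end}:{strand}"


@dataclass
class SpliceMotifModel:
    """PWMs and thresholds for motif-based minor-intron calling.

    Matrices are (width, 4) position-probability arrays over A,C,G,T.
    Scores are log2 odds against ``background``; an intron is called minor
    iff both the 5'ss score and the best branch-point placement score reach
    their thresholds.
    """

    pwm_5ss: np.ndarray
    pwm_bps: np.ndarray
    bps_search_window: tuple[int, int] = BPS_SEARCH_WINDOW
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    min_score_5ss: float | None = None
    min_score_bps: float | None = None

    def __post_init__(self) -> None:
        self.pwm_5ss = np.asarray(self.pwm_5ss, dtype=float)
        self.pwm_bps = np.asarray(self.pwm_bps, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        for name, pwm in (("pwm_5ss", self.pwm_5ss), ("pwm_bps", self.pwm_bps)):
            if pwm.ndim != 2 or pwm.shape[1] != 4:
                raise ValueError(f"{name} must have shape (width, 4)")
            if not np.allclose(pwm.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError(f"{name} columns must each sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-9):
            raise ValueError("background frequencies must sum to 1")
        # default thresholds: half of each motif's maximal attainable score
        if self.min_score_5ss is None:
            self.min_score_5ss = 0.5 * max_score(self.pwm_5ss, self.background)
        if self.min_score_bps is None:
            self.min_score_bps = 0.5 * max_score(self.pwm_bps, self.background)

    @classmethod
    def from_consensus(
        cls,
        five_ss: str = FIVE_SS_CONSENSUS,
        bps: str = BPS_CONSENSUS,
        **kwargs,
    ) -> "SpliceMotifModel":
        """Build default matrices from consensus strings (0.91 majority /
        0.03 minority per column)."""
        return cls(pwm_from_consensus(five_ss), pwm_from_consensus(bps), **kwargs)


def pwm_from_consensus(consensus: str) -> np.ndarray:
    pwm = np.full((len(consensus), 4), _MINORITY_P)
    for i, base in enumerate(consensus.upper()):
        if base not in _BASE_INDEX:
            raise ValueError(f"consensus base {base!r} not in ACGT")
        pwm[i, _BASE_INDEX[base]] = _MAJORITY_P
    return pwm


def max_score(pwm: np.ndarray, background: np.ndarray) -> float:
    """Maximal attainable log-odds score (per-position argmax path)."""
    p = np.maximum(np.asarray(pwm, dtype=float), PWM_FLOOR)
    return float(np.sum(np.log2(p.max(axis=1) / np.asarray(background)[p.argmax(axis=1)])))


def score_motif(seq: str, pwm: np.ndarray, background: np.ndarray | Sequence[float]) -> float:
    """Log2-odds score of ``seq`` under a position-probability matrix.

    ``seq`` must match the PWM width; ``N`` positions contribute 0.
    Probabilities are floored at ``PWM_FLOOR`` before taking logs.
    """
    pwm = np.asarray(pwm, dtype=float)
    background = np.asarray(background, dtype=float)
    if len(seq) != pwm.shape[0]:
        raise ValueError(f"sequence length {len(seq)} != PWM width {pwm.shape[0]}")
    score = 0.0
    for i, base in enumerate(seq.upper()):
        if base == "N":
            continue
        if base not in _BASE_INDEX:
            raise ValueError(f"unexpected base {base!r}")
        j = _BASE_INDEX[base]
        score += np.log2(max(pwm[i, j], PWM_FLOOR) / background[j])
    return float(score)


def extract_introns(transcripts: Iterable[TranscriptModel]) -> list[IntronRecord]:
    """Enumerate introns from transcript models.

    Each transcript with k exons yields k-1 introns; introns with identical
    (chrom, start, end, strand) are collapsed into one record carrying the
    union of transcript ids.  Transcripts failing validation are rejected
    with a diagnostic (ValueError).
    """
    by_coords: dict[tuple[str, int, int, str], IntronRecord] = {}
    for tx in transcripts:
        tx.validate()
        n = len(tx.exons)
        if n < 2:
            continue
        # genomic-order gaps; transcript orientation flips ordinal and flanks
        for gi in range(n - 1):
            start = tx.exons[gi][1]
            end = tx.exons[gi + 1][0]
            key = (tx.chrom, start, end, tx.strand)
            if tx.strand == "+":
                ordinal = gi + 1
                up_exon, down_exon = tx.exons[gi], tx.exons[gi + 1]
            else:
                ordinal = (n - 1) - gi
                up_exon, down_exon = tx.exons[gi + 1], tx.exons[gi]
            if key in by_coords:
                by_coords[key].transcript_ids.add(tx.transcript_id)
            else:
                by_coords[key] = IntronRecord(
                    intron_id=make_intron_id(*key),
                    gene_id=tx.gene_id,
                    transcript_ids={tx.transcript_id},
                    chrom=tx.chrom,
                    start=start,
                    end=end,
                    strand=tx.strand,
                    ordinal=ordinal,
                    upstream_exon=up_exon,
                    downstream_exon=down_exon,
                )
    return sorted(by_coords.values(), key=lambda r: (r.chrom, r.start, r.end, r.strand))


def intron_sequence(intron: IntronRecord, genome: Mapping[str, object]) -> str | None:
    """Transcript-oriented intronic sequence, or None if unavailable."""
    try:
        seq = str(genome[intron.chrom][intron.start : intron.end])
    except (KeyError, IndexError):
        return None
    if len(seq) != intron.length:
        return None
    return revcomp(seq).upper() if intron.strand == "-" else seq.upper()


def motif_scores(seq: str, motif: SpliceMotifModel) -> tuple[float, float]:
    """(5'ss score, best branch-point placement score) for an intron sequence.

    The branch-point PWM is slid over the configured window upstream of the
    3' end and the best-scoring placement is kept.  Returns -inf for windows
    that do not fit.
    """
    w5 = motif.pwm_5ss.shape[0]
    if len(seq) < w5:
        return (float("-inf"), float("-inf"))
    s5 = score_motif(seq[:w5], motif.pwm_5ss, motif.background)
    wb = motif.pwm_bps.shape[0]
    lo, hi = motif.bps_search_window
    first = max(0, len(seq) + lo)
    last = len(seq) + hi - wb  # last allowed placement start
    best = float("-inf")
    for pos in range(first, last + 1):
        if pos + wb > len(seq):
            break
        best = max(best, score_motif(seq[pos : pos + wb], motif.pwm_bps, motif.background))
    return (s5, best)


def classify_introns(
    introns: list[IntronRecord],
    minor_list: set[tuple[str, int, int, str]] | None = None,
    genome: Mapping[str, object] | None = None,
    motif: SpliceMotifModel | None = None,
) -> list[IntronRecord]:
    """Assign ``minor``/``major`` to every intron in place (and return them).

    List lookup takes precedence; introns absent from a provided minor list
    are major.  Without a list, motif scoring over ``genome`` sequence is
    used: minor iff both 5'ss and branch-point scores reach their
    thresholds.  Unfetchable sequence classifies as major with a log entry.
    """
    if minor_list is None and (motif is None or genome is None):
        raise ValueError("without a minor list, both a genome and a motif model are required")
    if minor_list is not None:
        catalog_coords = {i.coords for i in introns}
        for coords in minor_list - catalog_coords:
            logger.warning("minor-list intron %s not found in catalog", coords)
        for intron in introns:
            intron.intron_class = "minor" if intron.coords in minor_list else "major"
        return introns
    assert motif is not None and genome is not None
    for intron in introns:
        seq = intron_sequence(intron, genome)
        if seq is None:
            logger.warning("no sequence for %s; classifying as major", intron.intron_id)
            intron.intron_class = "major"
            continue
        s5, sb = motif_scores(seq, motif)
        is_minor = s5 >= motif.min_score_5ss and sb >= motif.min_score_bps
        intron.intron_class = "minor" if is_minor else "major"
    return introns


# ---------------------------------------------------------------------------
# annotation / minor-list / catalog I/O
# ---------------------------------------------------------------------------


def load_transcripts(annotation_path: str | Path) -> list[TranscriptModel]:
    """Parse transcript models from a GTF or GFF3 file.

    Exons are grouped by ``transcript_id`` (GTF) or ``Parent`` (GFF3);
    gene ids come from ``gene_id`` or are resolved through the parent
    feature chain.  Coordinates convert 1-based inclusive -> 0-based
    half-open.
    """
    import gffutils

    db = gffutils.create_db(
        str(annotation_path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    grouped: dict[str, TranscriptModel] = {}
    for exon in db.features_of_type("exon"):
        if "transcript_id" in exon.attributes:
            tid = exon.attributes["transcript_id"][0]
        elif "Parent" in exon.attributes:
            tid = exon.attributes["Parent"][0]
        else:
            raise ValueError(f"exon at {exon.seqid}:{exon.start} has no transcript attribute")
        if "gene_id" in exon.attributes:
            gid = exon.attributes["gene_id"][0]
        else:
            gid = _resolve_gene_id(db, tid)
        model = grouped.get(tid)
        if model is None:
            model = grouped[tid] = TranscriptModel(
                transcript_id=tid, gene_id=gid, chrom=exon.seqid, strand=exon.strand, exons=[]
            )
        model.exons.append((exon.start - 1, exon.end))
    return list(grouped.values())


def _resolve_gene_id(db, tid: str) -> str:
    try:
        parent = db[tid]
    except Exception:
        return tid
    if "gene_id" in parent.attributes:
        return parent.attributes["gene_id"][0]
    if "Parent" in parent.attributes:
        return parent.attributes["Parent"][0]
    return tid


def load_minor_list(path: str | Path) -> set[tuple[str, int, int, str]]:
    """Read a minor-intron list: 4-column TSV (chrom,start,end,strand,
    0-based half-open) or BED6 (strand in column 6).  Dialect auto-detected
    by column count; header lines starting with '#' or 'chrom' skipped."""
    coords: set[tuple[str, int, int, str]] = set()
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if fields[0].lower() == "chrom":
                continue
            if len(fields) >= 6:
                chrom, start, end, strand = fields[0], fields[1], fields[2], fields[5]
            elif len(fields) == 4:
                chrom, start, end, strand = fields
            else:
                raise ValueError(f"minor list line has {len(fields)} columns: {line!r}")
            coords.add((chrom, int(start), int(end), strand))
    return coords


_SIDECAR_COLUMNS = [
    "intron_id",
    "chrom",
    "start",
    "end",
    "strand",
    "gene_id",
    "transcript_ids",
    "ordinal",
    "intron_class",
    "up_exon_start",
    "up_exon_end",
    "down_exon_start",
    "down_exon_end",
]


def write_catalog(introns: list[IntronRecord], out_dir: str | Path) -> tuple[Path, Path]:
    """Write the catalog as BED6 plus a TSV sidecar; returns both paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bed_path = out_dir / "introns.bed"
    tsv_path = out_dir / "introns.tsv"
    with open(bed_path, "w") as bed:
        for i in introns:
            bed.write(f"{i.chrom}\t{i.start}\t{i.end}\t{i.intron_id}\t0\t{i.strand}\n")
    with open(tsv_path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_SIDECAR_COLUMNS)
        for i in introns:
            writer.writerow(
                [
                    i.intron_id,
                    i.chrom,
                    i.start,
                    i.end,
                    i.strand,
                    i.gene_id,
                    ",".join(sorted(i.transcript_ids)),
                    i.ordinal,
                    i.intron_class,
                    i.upstream_exon[0],
                    i.upstream_exon[1],
                    i.downstream_exon[0],
                    i.downstream_exon[1],
                ]
            )
    return bed_path, tsv_path


def read_catalog(path: str | Path) -> list[IntronRecord]:
    """Read a catalog from its TSV sidecar (or the directory holding it)."""
    path = Path(path)
    if path.is_dir():
        path = path / "introns.tsv"
    introns = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            introns.append(
                IntronRecord(
                    intron_id=row["intron_id"],
                    gene_id=row["gene_id"],
                    transcript_ids=set(row["transcript_ids"].split(",")),
                    chrom=row["chrom"],
                    start=int(row["start"]),
                    end=int(row["end"]),
                    strand=row["strand"],
                    ordinal=int(row["ordinal"]),
                    upstream_exon=(int(row["up_exon_start"]), int(row["up_exon_end"])),
                    downstream_exon=(int(row["down_exon_start"]), int(row["down_exon_end"])),
                    intron_class=row["intron_class"],
                )
            )
    return introns


def build_catalog(
    gtf: str | Path,
    fasta: str | Path | None = None,
    minor_list_path: str | Path | None = None,
    motif: SpliceMotifModel | None = None,
) -> list[IntronRecord]:
    """End-to-end: parse annotation, extract and classify introns."""
    transcripts = load_transcripts(gtf)
    introns = extract_introns(transcripts)
    minor = load_minor_list(minor_list_path) if minor_list_path is not None else None
    genome = None
    if minor is None:
        if fasta is None:
            raise ValueError("classification needs either a minor list or a FASTA genome")
        from pyfaidx import Fasta

        genome = Fasta(str(fasta), sequence_always_upper=True)
        motif = motif or SpliceMotifModel.from_consensus()
    return classify_introns(introns, minor_list=minor, genome=genome, motif=motif)
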