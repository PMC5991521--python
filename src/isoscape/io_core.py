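"""Coordinate-safe domain types and file-format plumbing.

All genomic intervals are 0-based, half-open, stored in genomic order;
conversion to/from 1-based inclusive conventions happens only at file
boundaries (GTF/GFF3).  Transcription order is derived from the strand on
demand.  The types here are the shared currency of every analysis stage:
exon-chain transcript models, gene models, genome assemblies, expression
matrices and ortholog maps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

Interval = tuple[int, int]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class AnnotationParseError(ValueError):
    """Raised for malformed GTF/GFF3 input; names the offending line."""


class Bed12FormatError(ValueError):
    """Raised for inconsistent BED12 block fields; names the offending line."""


class CoordinateError(ValueError):
    """Raised when a feature's coordinates fall outside its chromosome."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class TranscriptModel:
    """An exon-chain transcript on a genome.

    Parameters
    ----------
    transcript_id, gene_id : str
        Feature identifiers; ``gene_id`` may be empty for unassigned reads.
    chrom : str
    strand : str
        ``"+"`` or ``"-"``.
    exons : tuple of (start, end)
        0-based half-open genomic intervals, sorted by start, disjoint.
    cds : optional (start, stop)
        Transcript-coordinate interval of the coding sequence; ``stop`` is
        the position one past the stop codon (half-open, stop codon
        included).
    tissue_support : dict mapping tissue label -> supporting read count
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[Interval, ...]
    cds: Interval | None = None
    tissue_support: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        exons = tuple((int(s), int(e)) for s, e in self.exons)
        if not exons:
            raise ValueError(f"{self.transcript_id}: transcript needs >=1 exon")
        for s, e in exons:
            if e <= s:
                raise ValueError(f"{self.transcript_id}: empty exon ({s},{e})")
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 < e1:
                raise ValueError(
                    f"{self.transcript_id}: exons overlap or unsorted "
                    f"({s1},{e1}) then ({s2},{e2})"
                )
        self.exons = exons

    # -- derived geometry ---------------------------------------------------

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def span(self) -> Interval:
        return (self.start, self.end)

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def is_multi_exon(self) -> bool:
        return len(self.exons) > 1

    @property
    def intron_chain(self) -> tuple[Interval, ...]:
        """Ordered (donor-side end, acceptor-side start) pairs in genomic order."""
        return tuple(
            (e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])
        )

    @property
    def splice_sites(self) -> frozenset[int]:
        """All intron boundary coordinates (donors and acceptors)."""
        sites: set[int] = set()
        for a, b in self.intron_chain:
            sites.add(a)
            sites.add(b)
        return frozenset(sites)

    def exons_transcription_order(self) -> tuple[Interval, ...]:
        return self.exons if self.strand == "+" else tuple(reversed(self.exons))

    def first_exon(self) -> Interval:
        """First exon in transcription order."""
        return self.exons_transcription_order()[0]

    def last_exon(self) -> Interval:
        return self.exons_transcription_order()[-1]

    def three_prime_end(self) -> int:
        """Genomic position of the 3'-terminal transcribed base."""
        return self.end - 1 if self.strand == "+" else self.start

    def five_prime_end(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    def genomic_to_transcript(self, pos: int) -> int:
        """Map a genomic position inside an exon to transcript coordinates."""
        offset = 0
        for s, e in self.exons_transcription_order():
            if s <= pos < e:
                if self.strand == "+":
                    return offset + (pos - s)
                return offset + (e - 1 - pos)
            offset += e - s
        raise CoordinateError(f"position {pos} not exonic in {self.transcript_id}")

    def total_support(self) -> int:
        return sum(self.tissue_support.values())


@dataclass
class GeneModel:
    """A set of transcripts sharing a gene id, chromosome, and strand."""

    gene_id: str
    chrom: str
    strand: str
    transcripts: list[TranscriptModel]

    def __post_init__(self) -> None:
        for t in self.transcripts:
            if t.chrom != self.chrom or t.strand != self.strand:
                raise ValueError(
                    f"{self.gene_id}: transcript {t.transcript_id} on "
                    f"{t.chrom}{t.strand}, gene on {self.chrom}{self.strand}"
                )

    @property
    def span(self) -> Interval:
        return (
            min(t.start for t in self.transcripts),
            max(t.end for t in self.transcripts),
        )


Genome = Mapping[str, str]  # chrom id -> uppercase DNA


@dataclass
class OrthologMap:
    """Directed ortholog links from species A genes to species B genes."""

    pairs: list[tuple[str, str]]

    def b_to_a(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for a, b in self.pairs:
            out.setdefault(b, []).append(a)
        for v in out.values():
            v.sort()
        return out

    def a_to_b(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for a, b in self.pairs:
            out.setdefault(a, []).append(b)
        for v in out.values():
            v.sort()
        return out

    def one_to_one(self) -> list[tuple[str, str]]:
        """Links whose A and B genes each occur in exactly one pair."""
        a2b, b2a = self.a_to_b(), self.b_to_a()
        return sorted(
            (a, b)
            for a, b in self.pairs
            if len(a2b[a]) == 1 and len(b2a[b]) == 1
        )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    genome: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in genome:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        genome[rec.id] = str(rec.seq).upper()
    return genome


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def extract_transcript_sequence(t: TranscriptModel, genome: Genome) -> str:
    """Spliced transcript sequence, 5'->3' in transcription order."""
    if t.chrom not in genome:
        raise CoordinateError(f"{t.transcript_id}: chromosome {t.chrom!r} absent")
    chrom_seq = genome[t.chrom]
    n = len(chrom_seq)
    parts = []
    for s, e in t.exons:
        if s < 0 or e > n:
            raise CoordinateError(
                f"{t.transcript_id}: exon ({s},{e}) outside {t.chrom} (len {n})"
            )
        parts.append(chrom_seq[s:e])
    seq = "".join(parts)
    return seq if t.strand == "+" else reverse_complement(seq)


# ---------------------------------------------------------------------------
# GTF / GFF3
# ---------------------------------------------------------------------------

def _validate_annotation_lines(path: Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 8:
                raise AnnotationParseError(
                    f"{path}:{lineno}: expected >=8 tab-separated fields"
                )
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise AnnotationParseError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            if start < 1 or end < start:
                raise AnnotationParseError(
                    f"{path}:{lineno}: invalid coordinate range {start}-{end}"
                )


def _feature_transcript_and_gene(feat, db) -> tuple[str | None, str | None]:
    attrs = feat.attributes
    tid = attrs.get("transcript_id", [None])[0]
    gid = attrs.get("gene_id", [None])[0]
    if tid is None:  # GFF3 dialect: exon -> Parent transcript -> Parent gene
        parents = attrs.get("Parent", [])
        tid = parents[0] if parents else None
        if tid is not None and gid is None:
            try:
                parent = db[tid]
                gid = (
                    parent.attributes.get("gene_id", [None])[0]
                    or parent.attributes.get("Parent", [None])[0]
                )
            except gffutils.FeatureNotFoundError:
                gid = None
    return tid, gid


def read_annotation(path: str | Path) -> list[GeneModel]:
    """Read a GTF (Ensembl dialect) or GFF3 annotation into gene models.

    File coordinates (1-based inclusive) are converted to internal 0-based
    half-open intervals.  Exons are grouped per transcript; transcripts with
    no exon record are skipped with a warning.  Output order is
    deterministic: genes by (chrom, start, gene_id), transcripts by
    (start, transcript_id).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _validate_annotation_lines(path)
    if path.stat().st_size == 0:
        return []
    try:
        db = gffutils.create_db(
            str(path),
            ":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except Exception as exc:  # pragma: no cover - gffutils internal failures
        raise AnnotationParseError(f"{path}: {exc}") from exc

    exons_by_tid: dict[str, list[Interval]] = {}
    meta: dict[str, tuple[str, str, str]] = {}  # tid -> (gene, chrom, strand)
    for feat in db.features_of_type("exon"):
        tid, gid = _feature_transcript_and_gene(feat, db)
        if tid is None:
            raise AnnotationParseError(
                f"{path}: exon at {feat.seqid}:{feat.start} lacks a "
                "transcript_id/Parent attribute"
            )
        gid = gid or tid
        exons_by_tid.setdefault(tid, []).append((feat.start - 1, feat.end))
        meta.setdefault(tid, (gid, feat.seqid, feat.strand))

    declared = {
        f.attributes.get("transcript_id", [f.id])[0]
        for kind in ("transcript", "mRNA")
        for f in db.features_of_type(kind)
    }
    for tid in sorted(declared - set(exons_by_tid)):
        logger.warning("transcript %s has no exon records; skipped", tid)

    genes: dict[str, list[TranscriptModel]] = {}
    for tid, exons in exons_by_tid.items():
        gid, chrom, strand = meta[tid]
        model = TranscriptModel(tid, gid, chrom, strand, tuple(sorted(exons)))
        genes.setdefault(gid, []).append(model)

    out = []
    for gid, transcripts in genes.items():
        transcripts.sort(key=lambda t: (t.start, t.transcript_id))
        out.append(GeneModel(gid, transcripts[0].chrom, transcripts[0].strand, transcripts))
    out.sort(key=lambda g: (g.chrom, g.span[0], g.gene_id))
    return out


def write_gtf(transcripts: Iterable[TranscriptModel], path: str | Path,
              source: str = "isoscape") -> None:
    """Write transcript models as Ensembl-dialect GTF (transcript + exon rows)."""
    with open(path, "w") as fh:
        for t in transcripts:
            attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
            fh.write(
                f"{t.chrom}\t{source}\ttranscript\t{t.start + 1}\t{t.end}\t.\t"
                f"{t.strand}\t.\t{attrs}\n"
            )
            for s, e in t.exons:
                fh.write(
                    f"{t.chrom}\t{source}\texon\t{s + 1}\t{e}\t.\t"
                    f"{t.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# BED12
# ---------------------------------------------------------------------------

def read_bed12(path: str | Path, tissue: str | None = None) -> list[TranscriptModel]:
    """Read BED12 transcript alignments.

    The record name field is either ``transcript_id`` or
    ``transcript_id|gene_id``.  If ``tissue`` is given, every model gets one
    supporting read in that tissue.
    """
    models = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise Bed12FormatError(f"{path}:{lineno}: expected 12 fields")
            chrom, chrom_start, chrom_end, name = (
                fields[0], int(fields[1]), int(fields[2]), fields[3],
            )
            strand = fields[5]
            block_count = int(fields[9])
            sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
            starts = [int(x) for x in fields[11].rstrip(",").split(",")]
            if len(sizes) != block_count or len(starts) != block_count:
                raise Bed12FormatError(
                    f"{path}:{lineno}: blockCount {block_count} inconsistent "
                    f"with blockSizes/blockStarts"
                )
            if starts[0] != 0 or chrom_start + starts[-1] + sizes[-1] != chrom_end:
                raise Bed12FormatError(
                    f"{path}:{lineno}: blocks do not tile chromStart..chromEnd"
                )
            exons = tuple(
                (chrom_start + st, chrom_start + st + sz)
                for st, sz in zip(starts, sizes)
            )
            tid, _, gid = name.partition("|")
            support = {tissue: 1} if tissue else {}
            models.append(
                TranscriptModel(tid, gid, chrom, strand, exons,
                                tissue_support=support)
            )
    return models


def write_bed12(models: Iterable[TranscriptModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in models:
            name = t.transcript_id if not t.gene_id else f"{t.transcript_id}|{t.gene_id}"
            sizes = ",".join(str(e - s) for s, e in t.exons)
            starts = ",".join(str(s - t.start) for s, _ in t.exons)
            fh.write(
                f"{t.chrom}\t{t.start}\t{t.end}\t{name}\t0\t{t.strand}\t"
                f"{t.start}\t{t.end}\t0\t{len(t.exons)}\t{sizes}\t{starts}\n"
            )


# ---------------------------------------------------------------------------
# Expression matrices and simple TSV tables
# ---------------------------------------------------------------------------

def validate_expression(df: pd.DataFrame) -> pd.DataFrame:
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate feature ids: {dupes[:5]}")
    if df.columns.has_duplicates:
        raise ValueError("duplicate tissue labels")
    if (df.to_numpy() < 0).any():
        raise ValueError("expression matrix contains negative values")
    return df


def read_expression(path: str | Path) -> pd.DataFrame:
    """Feature x tissue abundance TSV (first column = feature id, header = tissues)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return validate_expression(df)


def write_expression(df: pd.DataFrame, path: str | Path) -> None:
    validate_expression(df).to_csv(path, sep="\t", index_label="feature_id")


def read_orthologs(path: str | Path) -> OrthologMap:
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = list(df.columns[:2])
    pairs = [tuple(row) for row in df[cols].itertuples(index=False)]
    return OrthologMap(pairs=pairs)


def write_orthologs(orth: OrthologMap, path: str | Path,
                    col_a: str = "gene_a", col_b: str = "gene_b") -> None:
    pd.DataFrame(orth.pairs, columns=[col_a, col_b]).to_csv(path, sep="\t", index=False)
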