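"""Alternative polyadenylation: cleavage sites, 5-nt clusters, NUE motifs.

The cleavage site (CS) of a transcript is its 3'-terminal transcribed
genomic base.  Sites of a gene are clustered when consecutive sorted
positions lie within 5 nt (single linkage by default; a max-diameter mode
is available).  The near-upstream element (NUE) is scanned as hexamer
occurrence counts over the 40-nt window ending 1 nt before each CS.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .io_core import Genome, TranscriptModel, reverse_complement

logger = logging.getLogger(__name__)

NUE_WINDOW_NT = 40
CLUSTER_GAP_NT = 5


@dataclass(frozen=True)
class CleavageSite:
    gene_id: str
    chrom: str
    strand: str
    position: int  # genomic position of the 3'-terminal base
    tissue: str
    isoform_id: str


@dataclass
class PolyACluster:
    cluster_id: str
    gene_id: str
    strand: str
    members: tuple[CleavageSite, ...]
    representative: int = field(init=False)
    tissues: frozenset[str] = field(init=False)

    def __post_init__(self) -> None:
        positions = [m.position for m in self.members]
        counts = Counter(positions)
        top = max(counts.values())
        modes = [p for p, c in counts.items() if c == top]
        # tie -> 3'-most position (strand-aware)
        self.representative = max(modes) if self.strand == "+" else min(modes)
        self.tissues = frozenset(m.tissue for m in self.members)

    @property
    def tissue_specific(self) -> bool:
        return len(self.tissues) == 1


def extract_cleavage_sites(
    isoforms: Iterable[TranscriptModel],
) -> list[CleavageSite]:
    """One CS record per (isoform, supporting tissue)."""
    sites = []
    for t in isoforms:
        pos = t.three_prime_end()
        for tissue, count in sorted(t.tissue_support.items()):
            if count > 0:
                sites.append(
                    CleavageSite(t.gene_id, t.chrom, t.strand, pos, tissue,
                                 t.transcript_id)
                )
    return sites


def cluster_polya(
    sites: Sequence[CleavageSite],
    max_gap: int = CLUSTER_GAP_NT,
    max_diameter: int | None = None,
) -> list[PolyACluster]:
    """Cluster one gene's cleavage sites.

    Default single-linkage semantics: consecutive sorted positions within
    ``max_gap`` nt chain into one cluster (so 100-105-110 merges).  Passing
    ``max_diameter`` instead bounds the cluster span.  Deterministic and
    idempotent; every site lands in exactly one cluster.
    """
    if not sites:
        return []
    genes = {s.gene_id for s in sites}
    if len(genes) > 1:
        raise ValueError(f"sites span multiple genes: {sorted(genes)}")
    strands = {s.strand for s in sites}
    if len(strands) > 1:
        raise ValueError("sites on both strands of one gene")
    gene, strand = sites[0].gene_id, sites[0].strand

    ordered = sorted(sites, key=lambda s: (s.position, s.tissue, s.isoform_id))
    groups: list[list[CleavageSite]] = [[ordered[0]]]
    for site in ordered[1:]:
        if max_diameter is not None:
            joined = site.position - groups[-1][0].position <= max_diameter
        else:
            joined = site.position - groups[-1][-1].position <= max_gap
        if joined:
            groups[-1].append(site)
        else:
            groups.append([site])
    return [
        PolyACluster(f"{gene}:pa{i}", gene, strand, tuple(g))
        for i, g in enumerate(groups, 1)
    ]


def cluster_all_polya(
    sites: Sequence[CleavageSite], **kwargs
) -> list[PolyACluster]:
    by_gene: dict[str, list[CleavageSite]] = {}
    for s in sites:
        by_gene.setdefault(s.gene_id, []).append(s)
    out: list[PolyACluster] = []
    for gene in sorted(by_gene):
        out.extend(cluster_polya(by_gene[gene], **kwargs))
    return out


# ---------------------------------------------------------------------------
# NUE motif scanning
# ---------------------------------------------------------------------------

def nue_window(genome: Genome, chrom: str, strand: str, cs_position: int,
               width: int = NUE_WINDOW_NT) -> str:
    """The 1..``width`` nt region upstream of the CS, read 5'->3'.

    The CS base itself is excluded.  Windows truncated by the chromosome
    start are returned as-is.
    """
    seq = genome[chrom]
    if strand == "+":
        return seq[max(0, cs_position - width):cs_position]
    return reverse_complement(seq[cs_position + 1:cs_position + 1 + width])


def build_nue_windows(
    isoforms: Iterable[TranscriptModel], genome: Genome,
    width: int = NUE_WINDOW_NT,
) -> dict[str, list[str]]:
    """One upstream window per nonredundant isoform per supporting tissue."""
    windows: dict[str, list[str]] = {}
    for t in isoforms:
        win = nue_window(genome, t.chrom, t.strand, t.three_prime_end(), width)
        for tissue, count in sorted(t.tissue_support.items()):
            if count > 0:
                windows.setdefault(tissue, []).append(win)
    return windows


def scan_nue(
    windows_by_tissue: Mapping[str, Sequence[str]],
    k: int = 6,
    per_window_presence: bool = False,
) -> dict[str, Counter]:
    """Hexamer occurrence counts per tissue over sliding window positions.

    Overlapping occurrences count; k-mers containing N are excluded.  With
    ``per_window_presence`` each motif counts at most once per window.
    Windows shorter than ``k`` are skipped with a warning.
    """
    tables: dict[str, Counter] = {}
    for tissue in sorted(windows_by_tissue):
        counts: Counter = Counter()
        for win in windows_by_tissue[tissue]:
            win = win.upper()
            if len(win) < k:
                logger.warning("window shorter than k=%d skipped in %s", k, tissue)
                continue
            kmers = (win[i:i + k] for i in range(len(win) - k + 1))
            kmers = (m for m in kmers if "N" not in m)
            counts.update(set(kmers) if per_window_presence else kmers)
        tables[tissue] = counts
    return tables


def rank_motifs(counts: Counter, top: int | None = None) -> list[tuple[str, int]]:
    """Motifs by descending count; ties broken lexicographically."""
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:top] if top else ranked


def pooled_motif_table(tables: Mapping[str, Counter]) -> Counter:
    pooled: Counter = Counter()
    for counts in tables.values():
        pooled.update(counts)
    return pooled
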