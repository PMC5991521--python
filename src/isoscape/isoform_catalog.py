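"""Nonredundant isoform collapse and reference-based classification.

Full-length transcript reads are collapsed by exact intron-chain identity:
reads differing only at the 5' start within the first exon are redundant and
the longest version is retained; 3' ends are merged within a small tolerance
(default 5 nt, the poly(A)-site clustering radius).  Collapsed isoforms are
then classified against a reference annotation into eight categories under
a fixed precedence.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .io_core import GeneModel, TranscriptModel

#: classification categories, most to least specific (evaluation precedence)
CATEGORY_PRECEDENCE = (3, 7, 2, 4, 5, 6, 1, 8)

CATEGORY_LABELS = {
    1: "novel locus",
    2: "novel isoform sharing splice sites",
    3: "reference intron chain match",
    4: "exonic overlap, no shared splice sites",
    5: "within reference intron",
    6: "antisense exonic overlap",
    7: "partial reference match",
    8: "other",
}


@dataclass
class IsoformRecord:
    isoform_id: str
    model: TranscriptModel
    category: int | None = None
    matched_reference_transcript: str | None = None
    member_reads: tuple[str, ...] = ()

    @property
    def tissue_support(self) -> dict[str, int]:
        return self.model.tissue_support

    def total_support(self) -> int:
        return self.model.total_support()


# ---------------------------------------------------------------------------
# Collapse
# ---------------------------------------------------------------------------

def _merge_support(reads: Sequence[TranscriptModel]) -> dict[str, int]:
    support: Counter = Counter()
    for r in reads:
        support.update(r.tissue_support)
    return dict(sorted(support.items()))


def _longest_read(reads: Sequence[TranscriptModel]) -> TranscriptModel:
    return min(reads, key=lambda r: (-r.length, r.start, r.transcript_id))


def _cluster_ends(reads: list[TranscriptModel], tol3: int) -> list[list[TranscriptModel]]:
    """Single-linkage clustering of same-intron-chain reads by 3'-end position."""
    reads = sorted(reads, key=lambda r: (r.three_prime_end(), r.transcript_id))
    clusters: list[list[TranscriptModel]] = []
    for r in reads:
        if clusters and r.three_prime_end() - clusters[-1][-1].three_prime_end() <= tol3:
            clusters[-1].append(r)
        else:
            clusters.append([r])
    return clusters


def _reciprocal_overlap(a: TranscriptModel, b: TranscriptModel, frac: float) -> bool:
    ov = min(a.end, b.end) - max(a.start, b.start)
    return ov >= frac * a.length and ov >= frac * b.length


def _mono_exon_components(
    reads: list[TranscriptModel], frac: float
) -> list[list[TranscriptModel]]:
    """Connected components of the reciprocal-overlap graph (union-find)."""
    reads = sorted(reads, key=lambda r: (r.start, r.end, r.transcript_id))
    parent = list(range(len(reads)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(reads)):
        for j in range(i + 1, len(reads)):
            if reads[j].start >= reads[i].end:
                break
            if _reciprocal_overlap(reads[i], reads[j], frac):
                parent[find(j)] = find(i)
    comps: dict[int, list[TranscriptModel]] = {}
    for i, r in enumerate(reads):
        comps.setdefault(find(i), []).append(r)
    return [comps[k] for k in sorted(comps)]


def collapse_isoforms(
    reads: Iterable[TranscriptModel],
    tol3: int = 5,
    mono_min_overlap: float = 0.5,
    known_chroms: set[str] | None = None,
) -> list[IsoformRecord]:
    """Collapse mapped full-length reads into nonredundant isoforms.

    Multi-exon reads group by (chrom, strand, exact intron chain), then by
    3' end within ``tol3`` nt (single linkage); the longest member is
    retained as representative and per-tissue read support accumulates.
    Mono-exon reads collapse by >=``mono_min_overlap`` reciprocal overlap on
    the same strand, iterated to a fixpoint so the operation is idempotent.
    Output is order-invariant.
    """
    reads = list(reads)
    if known_chroms is not None:
        unknown = sorted(r.transcript_id for r in reads if r.chrom not in known_chroms)
        if unknown:
            raise ValueError(f"reads on unknown chromosomes: {unknown[:10]}")

    multi: dict[tuple, list[TranscriptModel]] = {}
    mono: dict[tuple, list[TranscriptModel]] = {}
    for r in reads:
        if r.is_multi_exon:
            multi.setdefault((r.chrom, r.strand, r.intron_chain), []).append(r)
        else:
            mono.setdefault((r.chrom, r.strand), []).append(r)

    representatives: list[tuple[TranscriptModel, dict[str, int], tuple[str, ...]]] = []
    for key in sorted(multi):
        for cluster in _cluster_ends(multi[key], tol3):
            members = tuple(sorted(r.transcript_id for r in cluster))
            representatives.append(
                (_longest_read(cluster), _merge_support(cluster), members)
            )

    for key in sorted(mono):
        group = mono[key]
        members_of = {r.transcript_id: (r.transcript_id,) for r in group}
        # iterate to fixpoint: representatives of merged components may
        # themselves satisfy the overlap rule
        while True:
            comps = _mono_exon_components(group, mono_min_overlap)
            if len(comps) == len(group):
                break
            merged = []
            for c in comps:
                rep = _longest_read(c)
                merged.append(
                    TranscriptModel(rep.transcript_id, rep.gene_id, rep.chrom,
                                    rep.strand, rep.exons,
                                    tissue_support=_merge_support(c))
                )
                members_of[rep.transcript_id] = tuple(sorted(
                    m for r in c for m in members_of[r.transcript_id]
                ))
            group = merged
        for c in comps:
            rep = _longest_read(c)
            members = tuple(sorted(
                m for r in c for m in members_of[r.transcript_id]
            ))
            representatives.append((rep, _merge_support(c), members))

    representatives.sort(
        key=lambda x: (x[0].chrom, x[0].start, x[0].end, x[0].intron_chain,
                       x[0].strand)
    )
    records = []
    for i, (rep, support, members) in enumerate(representatives, 1):
        iso_id = f"iso{i:06d}"
        model = TranscriptModel(iso_id, rep.gene_id, rep.chrom, rep.strand,
                                rep.exons, cds=rep.cds, tissue_support=support)
        records.append(
            IsoformRecord(isoform_id=iso_id, model=model, member_reads=members)
        )
    return records


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def _is_contiguous_subchain(sub: tuple, chain: tuple) -> bool:
    n, m = len(sub), len(chain)
    if n == 0 or n >= m:
        return False
    return any(chain[i:i + n] == sub for i in range(m - n + 1))


def _exonic_overlap(a: TranscriptModel, b: TranscriptModel) -> bool:
    for s1, e1 in a.exons:
        for s2, e2 in b.exons:
            if max(s1, s2) < min(e1, e2):
                return True
    return False


def _within_an_intron(iso: TranscriptModel, ref: TranscriptModel) -> bool:
    s, e = iso.span
    return any(istart <= s and e <= iend for istart, iend in ref.intron_chain)


def classify_isoform(
    iso: TranscriptModel, ref: Sequence[GeneModel]
) -> tuple[int, str | None]:
    """Assign one of eight categories against the reference annotation.

    Precedence 3 -> 7 -> 2 -> 4 -> 5 -> 6 -> 1 -> 8 (most to least specific)
    guarantees a deterministic partition when several predicates hold.
    Returns (category, matched reference transcript id or None).
    """
    overlapping = [
        g for g in ref
        if g.chrom == iso.chrom and max(g.span[0], iso.start) < min(g.span[1], iso.end)
    ]
    same = [t for g in overlapping if g.strand == iso.strand for t in g.transcripts]
    anti = [t for g in overlapping if g.strand != iso.strand for t in g.transcripts]

    # 3: identical intron chain (mono-exon: reciprocal-overlap match to a
    # mono-exon reference transcript)
    for t in same:
        if iso.is_multi_exon:
            if t.intron_chain == iso.intron_chain:
                return 3, t.transcript_id
        elif not t.is_multi_exon and _reciprocal_overlap(iso, t, 0.5):
            return 3, t.transcript_id
    # 7: all splice sites match a contiguous sub-chain; strictly shorter
    if iso.is_multi_exon:
        for t in same:
            if _is_contiguous_subchain(iso.intron_chain, t.intron_chain):
                return 7, t.transcript_id
    # 2: shares >=1 splice site with a same-strand annotated transcript
    for t in same:
        if iso.splice_sites & t.splice_sites:
            return 2, t.transcript_id
    # 4: same-strand exonic overlap without shared splice sites
    for t in same:
        if _exonic_overlap(iso, t):
            return 4, t.transcript_id
    # 5: entirely within an intron of an annotated isoform (either strand)
    for t in same + anti:
        if _within_an_intron(iso, t):
            return 5, t.transcript_id
    # 6: exonic overlap only with an opposite-strand locus
    for t in anti:
        if _exonic_overlap(iso, t):
            return 6, t.transcript_id
    # 1: no overlap with any annotated locus
    if not overlapping:
        return 1, None
    return 8, None


def classify_catalog(
    isoforms: Sequence[IsoformRecord], ref: Sequence[GeneModel]
) -> None:
    """Classify every isoform in place."""
    for rec in isoforms:
        rec.category, rec.matched_reference_transcript = classify_isoform(rec.model, ref)


# ---------------------------------------------------------------------------
# Tissue sharing
# ---------------------------------------------------------------------------

def tissue_sharing(
    isoforms: Sequence[IsoformRecord], tissues: Sequence[str] | None = None
) -> dict:
    """Tissue-specific and shared-by-all isoform tallies.

    "Specific" isoforms are supported in exactly one tissue; "shared-by-all"
    isoforms are supported in every tissue of ``tissues`` (default: the
    union of observed tissues).
    """
    if not isoforms:
        return {"tissues": [], "specific": {}, "specific_fraction": {},
                "expressed": {}, "shared_by_all": 0, "shared_by_all_ids": []}
    if tissues is None:
        tissues = sorted({t for rec in isoforms for t in rec.tissue_support})
    tissues = list(tissues)
    specific: Counter = Counter()
    expressed: Counter = Counter()
    shared: list[str] = []
    for rec in isoforms:
        supported = [t for t, c in rec.tissue_support.items() if c > 0]
        for t in supported:
            expressed[t] += 1
        if len(supported) == 1:
            specific[supported[0]] += 1
        if set(tissues) <= set(supported):
            shared.append(rec.isoform_id)
    return {
        "tissues": tissues,
        "specific": {t: specific.get(t, 0) for t in tissues},
        "expressed": {t: expressed.get(t, 0) for t in tissues},
        "specific_fraction": {
            t: (specific.get(t, 0) / expressed[t] if expressed.get(t) else 0.0)
            for t in tissues
        },
        "shared_by_all": len(shared),
        "shared_by_all_ids": sorted(shared),
    }
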