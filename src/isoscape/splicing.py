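"""Alternative-splicing event enumeration, PSI, activity scores, conservation.

Six local event types are recognised from pairwise transcript comparison
within a gene, with labels oriented by the transcription strand:

* ``ES`` exon skipping: an internal exon present in one form, spliced out in
  the other, with both flanking introns shared.
* ``A5``/``A3`` alternative 5'/3' splice site: two introns sharing one
  boundary and differing at the other (donor side -> A5, acceptor -> A3).
* ``IR`` intron retention: one form's intron fully exonic in the other.
* ``AF``/``AL`` alternative first/last exon: distinct, non-overlapping
  terminal exons spliced to a shared internal splice site.

Events are deduplicated by (type, canonical genomic coordinates); the
inclusion and exclusion transcript sets are aggregated over every
transcript of the gene consistent with each form.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align

from .io_core import GeneModel, Interval, TranscriptModel

EVENT_TYPES = ("ES", "A5", "A3", "IR", "AF", "AL")


@dataclass(frozen=True)
class ASEvent:
    event_id: str
    gene_id: str
    type: str
    coords: tuple
    inclusion_transcripts: frozenset[str]
    exclusion_transcripts: frozenset[str]

    def __post_init__(self) -> None:
        if self.type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.type!r}")
        if not self.inclusion_transcripts or not self.exclusion_transcripts:
            raise ValueError(f"{self.event_id}: empty form")
        if self.inclusion_transcripts & self.exclusion_transcripts:
            raise ValueError(f"{self.event_id}: forms overlap")


@dataclass
class PSIRecord:
    event_id: str
    tissue: str
    psi: float | None  # None when total event expression is 0 (undefined)

    @property
    def defined(self) -> bool:
        return self.psi is not None


# ---------------------------------------------------------------------------
# Event enumeration
# ---------------------------------------------------------------------------

def _exon_strictly_containing(t: TranscriptModel, intron: Interval) -> bool:
    s, e = intron
    return any(es < s and ee > e for es, ee in t.exons)


def _has_flanked_exon(t: TranscriptModel, d1: int, s: int, e: int, d2: int) -> bool:
    """Does ``t`` contain exon (s,e) with flanking introns (d1,s) and (e,d2)?"""
    return (
        (s, e) in t.exons
        and (d1, s) in t.intron_chain
        and (e, d2) in t.intron_chain
    )


def _leftmost_intron(t: TranscriptModel) -> Interval | None:
    chain = t.intron_chain
    return chain[0] if chain else None


def _rightmost_intron(t: TranscriptModel) -> Interval | None:
    chain = t.intron_chain
    return chain[-1] if chain else None


def _overlap(a: Interval, b: Interval) -> bool:
    return max(a[0], b[0]) < min(a[1], b[1])


def _pair_event_keys(a: TranscriptModel, b: TranscriptModel) -> set[tuple]:
    """Canonical (type, coords) keys of local events between one transcript pair."""
    keys: set[tuple] = set()
    strand = a.strand
    introns_a, introns_b = set(a.intron_chain), set(b.intron_chain)

    # IR: intron of one, exonic in the other (both directions)
    for x, y in ((a, b), (b, a)):
        for intron in x.intron_chain:
            if _exon_strictly_containing(y, intron):
                keys.add(("IR", intron))

    # ES: internal exon of one, skipped via a single intron in the other
    for x, y in ((a, b), (b, a)):
        chain = x.intron_chain
        for k in range(1, len(x.exons) - 1):
            s, e = x.exons[k]
            d1, d2 = chain[k - 1][0], chain[k][1]
            if (d1, d2) in (introns_b if y is b else introns_a):
                keys.add(("ES", (d1, s, e, d2)))

    # Boundary events: intron pairs sharing exactly one boundary
    for s1, e1 in introns_a:
        for s2, e2 in introns_b:
            if e1 == e2 and s1 != s2:  # variable genomic-left boundary
                keys.add(_left_variable_key(a, b, s1, s2, e1, strand))
            elif s1 == s2 and e1 != e2:  # variable genomic-right boundary
                keys.add(_right_variable_key(a, b, e1, e2, s1, strand))
    keys.discard(None)
    return keys


def _left_variable_key(a, b, s_a, s_b, e, strand):
    exon_a = next((ex for ex in a.exons if ex[1] == s_a), None)
    exon_b = next((ex for ex in b.exons if ex[1] == s_b), None)
    if exon_a is None or exon_b is None:
        return None
    terminal = (
        _leftmost_intron(a) == (s_a, e)
        and _leftmost_intron(b) == (s_b, e)
        and exon_a == a.exons[0]
        and exon_b == b.exons[0]
        and not _overlap(exon_a, exon_b)
    )
    lo, hi = min(s_a, s_b), max(s_a, s_b)
    if terminal:
        etype = "AF" if strand == "+" else "AL"
        return (etype, ("L", lo, hi, e))
    if not _overlap(exon_a, exon_b):
        return None  # disjoint internal exons: an ES/complex pattern, not A5/A3
    etype = "A5" if strand == "+" else "A3"
    return (etype, ("L", lo, hi, e))


def _right_variable_key(a, b, e_a, e_b, s, strand):
    exon_a = next((ex for ex in a.exons if ex[0] == e_a), None)
    exon_b = next((ex for ex in b.exons if ex[0] == e_b), None)
    if exon_a is None or exon_b is None:
        return None
    terminal = (
        _rightmost_intron(a) == (s, e_a)
        and _rightmost_intron(b) == (s, e_b)
        and exon_a == a.exons[-1]
        and exon_b == b.exons[-1]
        and not _overlap(exon_a, exon_b)
    )
    lo, hi = min(e_a, e_b), max(e_a, e_b)
    if terminal:
        etype = "AL" if strand == "+" else "AF"
        return (etype, ("R", s, lo, hi))
    if not _overlap(exon_a, exon_b):
        return None  # disjoint internal exons: an ES/complex pattern, not A5/A3
    etype = "A3" if strand == "+" else "A5"
    return (etype, ("R", s, lo, hi))


def _form_members(etype: str, coords: tuple,
                  transcripts: Sequence[TranscriptModel]) -> tuple[set, set]:
    """(inclusion ids, exclusion ids) of all transcripts consistent with a form.

    Conventions: for ES inclusion keeps the exon; for IR inclusion retains
    the intron; for A5/A3 inclusion carries the shorter intron (more exonic
    sequence); for AF/AL inclusion uses the genomically outer terminal exon.
    """
    inc: set[str] = set()
    exc: set[str] = set()
    if etype == "ES":
        d1, s, e, d2 = coords
        for t in transcripts:
            if _has_flanked_exon(t, d1, s, e, d2):
                inc.add(t.transcript_id)
            elif (d1, d2) in t.intron_chain:
                exc.add(t.transcript_id)
    elif etype == "IR":
        s, e = coords
        for t in transcripts:
            if _exon_strictly_containing(t, (s, e)):
                inc.add(t.transcript_id)
            elif (s, e) in t.intron_chain:
                exc.add(t.transcript_id)
    elif coords[0] == "L":
        _, lo, hi, e = coords
        short, long = (hi, e), (lo, e)
        terminal = etype in ("AF", "AL")
        for t in transcripts:
            chain = t.intron_chain
            if terminal and _leftmost_intron(t) == long:
                inc.add(t.transcript_id)  # outer (leftmost) first/last exon
            elif terminal and _leftmost_intron(t) == short:
                exc.add(t.transcript_id)
            elif not terminal and short in chain:
                inc.add(t.transcript_id)
            elif not terminal and long in chain:
                exc.add(t.transcript_id)
    else:
        _, s, lo, hi = coords
        short, long = (s, lo), (s, hi)
        terminal = etype in ("AF", "AL")
        for t in transcripts:
            chain = t.intron_chain
            if terminal and _rightmost_intron(t) == long:
                inc.add(t.transcript_id)  # outer (rightmost) terminal exon
            elif terminal and _rightmost_intron(t) == short:
                exc.add(t.transcript_id)
            elif not terminal and short in chain:
                inc.add(t.transcript_id)
            elif not terminal and long in chain:
                exc.add(t.transcript_id)
    return inc, exc


def _coords_str(coords: tuple) -> str:
    return "-".join(str(c) for c in coords)


def enumerate_as_events(gene: GeneModel) -> list[ASEvent]:
    """Canonical local AS events from all transcript pairs of one gene."""
    if not gene.transcripts:
        raise ValueError(f"{gene.gene_id}: gene has no transcripts")
    keys: set[tuple] = set()
    for a, b in combinations(gene.transcripts, 2):
        keys |= _pair_event_keys(a, b)
    events = []
    for etype, coords in sorted(keys, key=lambda k: (k[0], _coords_str(k[1]))):
        inc, exc = _form_members(etype, coords, gene.transcripts)
        inc -= exc & inc  # defensive; forms are disjoint by construction
        if not inc or not exc:
            continue
        events.append(
            ASEvent(
                event_id=f"{gene.gene_id};{etype};{_coords_str(coords)}",
                gene_id=gene.gene_id,
                type=etype,
                coords=coords,
                inclusion_transcripts=frozenset(inc),
                exclusion_transcripts=frozenset(exc),
            )
        )
    return events


def enumerate_all_events(genes: Iterable[GeneModel]) -> list[ASEvent]:
    out: list[ASEvent] = []
    for g in genes:
        if len(g.transcripts) > 1:
            out.extend(enumerate_as_events(g))
    return out


# ---------------------------------------------------------------------------
# PSI and splicing activity
# ---------------------------------------------------------------------------

def compute_psi(event: ASEvent, expr: pd.DataFrame, tissue: str) -> PSIRecord:
    """PSI = inclusion abundance / total event abundance in one tissue."""
    tids = sorted(event.inclusion_transcripts | event.exclusion_transcripts)
    missing = [t for t in tids if t not in expr.index]
    if missing:
        raise KeyError(f"{event.event_id}: transcripts absent from expression "
                       f"matrix: {missing[:5]}")
    inc = float(expr.loc[sorted(event.inclusion_transcripts), tissue].sum())
    tot = float(expr.loc[tids, tissue].sum())
    if tot == 0:
        return PSIRecord(event.event_id, tissue, None)
    return PSIRecord(event.event_id, tissue, inc / tot)


def psi_table(events: Sequence[ASEvent], expr: pd.DataFrame) -> pd.DataFrame:
    """Events x tissues PSI matrix (NaN where undefined)."""
    data = {
        ev.event_id: [
            (r.psi if (r := compute_psi(ev, expr, tis)).defined else np.nan)
            for tis in expr.columns
        ]
        for ev in events
    }
    return pd.DataFrame.from_dict(data, orient="index", columns=list(expr.columns))


def psi_zscores(psi: pd.DataFrame) -> pd.DataFrame:
    """Row-standardize PSI across tissues (sample SD); drops rows with <2
    defined tissues or zero variance."""
    if psi.shape[1] < 2:
        raise ValueError("need >=2 tissues to standardize PSI")
    defined = psi.notna().sum(axis=1) >= 2
    sd = psi.std(axis=1, ddof=1)
    keep = defined & (sd > 0)
    sub = psi.loc[keep]
    return sub.sub(sub.mean(axis=1), axis=0).div(sub.std(axis=1, ddof=1), axis=0)


def splicing_activity(
    psi: pd.DataFrame,
    event_types: Mapping[str, str] | None = None,
) -> tuple[pd.Series, pd.DataFrame | None]:
    """Per-tissue splicing activity = mean |Z| of PSI across retained events.

    Returns the overall activity series and, when ``event_types`` maps
    event_id -> type, a per-type activity table (types x tissues).
    """
    z = psi_zscores(psi)
    if z.empty:
        return pd.Series(dtype=float, index=psi.columns), None
    activity = z.abs().mean(axis=0, skipna=True)
    per_type = None
    if event_types is not None:
        types = pd.Series({eid: event_types[eid] for eid in z.index})
        per_type = z.abs().groupby(types).mean()
    return activity, per_type


# ---------------------------------------------------------------------------
# Cross-species conservation
# ---------------------------------------------------------------------------

def _tx_order_index(idx: int, n: int, strand: str) -> int:
    return idx if strand == "+" else n - 1 - idx


def event_architecture(
    event: ASEvent, transcripts: Mapping[str, TranscriptModel]
) -> tuple[str, int] | None:
    """(type, ordinal) signature used for cross-species event matching.

    Ordinals are in transcription order: retained-intron index within the
    spliced (exclusion) form for IR; skipped-exon index within the inclusion
    form for ES; index of the longer intron for A5/A3; 0 for AF/AL (they are
    terminal by definition).
    """
    if event.type in ("AF", "AL"):
        return (event.type, 0)
    if event.type == "IR":
        ords = []
        for tid in event.exclusion_transcripts:
            t = transcripts[tid]
            chain = t.intron_chain
            if event.coords in chain:
                idx = chain.index(event.coords)
                ords.append(_tx_order_index(idx, len(chain), t.strand))
        return (event.type, min(ords)) if ords else None
    if event.type == "ES":
        _, s, e, _ = event.coords
        ords = []
        for tid in event.inclusion_transcripts:
            t = transcripts[tid]
            if (s, e) in t.exons:
                idx = t.exons.index((s, e))
                ords.append(_tx_order_index(idx, len(t.exons), t.strand))
        return (event.type, min(ords)) if ords else None
    # A5/A3: ordinal of the long-intron form's intron
    if event.coords[0] == "L":
        _, lo, _, e = event.coords
        intron = (lo, e)
    else:
        _, s, _, hi = event.coords
        intron = (s, hi)
    ords = []
    for tid in event.exclusion_transcripts:
        t = transcripts[tid]
        chain = t.intron_chain
        if intron in chain:
            idx = chain.index(intron)
            ords.append(_tx_order_index(idx, len(chain), t.strand))
    return (event.type, min(ords)) if ords else None


def conserved_events(
    events_a: Sequence[ASEvent],
    events_b: Sequence[ASEvent],
    ortholog_pairs: Iterable[tuple[str, str]],
    transcripts_a: Mapping[str, TranscriptModel],
    transcripts_b: Mapping[str, TranscriptModel],
) -> list[tuple[ASEvent, ASEvent]]:
    """Event pairs conserved between species.

    A pair matches iff the genes are orthologous, types are equal, and the
    architecture signature (type + ordinal) agrees.
    """
    by_gene_a: dict[str, list[ASEvent]] = {}
    for ev in events_a:
        by_gene_a.setdefault(ev.gene_id, []).append(ev)
    by_gene_b: dict[str, list[ASEvent]] = {}
    for ev in events_b:
        by_gene_b.setdefault(ev.gene_id, []).append(ev)

    matched: list[tuple[ASEvent, ASEvent]] = []
    for ga, gb in ortholog_pairs:
        for ev_a in by_gene_a.get(ga, []):
            sig_a = event_architecture(ev_a, transcripts_a)
            if sig_a is None:
                continue
            for ev_b in by_gene_b.get(gb, []):
                if ev_b.type != ev_a.type:
                    continue
                if event_architecture(ev_b, transcripts_b) == sig_a:
                    matched.append((ev_a, ev_b))
    return matched


def conserved_event_counts(matched: Sequence[tuple[ASEvent, ASEvent]]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for ev_a, _ in matched:
        counts[ev_a.type] = counts.get(ev_a.type, 0) + 1
    return counts


def _dna_aligner() -> Align.PairwiseAligner:
    """Global DNA aligner with free end gaps.

    Internal gaps are penalized strongly relative to mismatches so that
    substitutions are never re-expressed as insertion/deletion pairs (which
    would inflate the gap-excluded identity); free end gaps let a fragment
    align to the interior of a longer sequence at full coverage.
    """
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -2
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -2
    aligner.target_end_gap_score = 0
    aligner.query_end_gap_score = 0
    return aligner


def conserved_isoforms(seq_a: str, seq_b: str,
                       min_coverage: float = 0.70,
                       min_identity: float = 0.80) -> tuple[bool, float, float]:
    """Cross-species isoform conservation via global alignment.

    Coverage = fraction of the shorter sequence aligned to bases of the
    other; identity = matches / aligned (both-non-gap) columns.  Conserved
    iff coverage >= 0.70 and identity >= 0.80 (the thresholds used for
    lncRNA conservation, reused as the generic test).
    """
    if not seq_a or not seq_b:
        raise ValueError("both sequences must be nonempty")
    aln = _dna_aligner().align(seq_a.upper(), seq_b.upper())[0]
    row_a, row_b = str(aln[0]), str(aln[1])
    matches = aligned = 0
    for ca, cb in zip(row_a, row_b):
        if ca != "-" and cb != "-":
            aligned += 1
            if ca == cb:
                matches += 1
    coverage = aligned / min(len(seq_a), len(seq_b))
    identity = matches / aligned if aligned else 0.0
    return (coverage >= min_coverage and identity >= min_identity,
            coverage, identity)
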