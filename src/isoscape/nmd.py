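"""Longest-ORF prediction and nonsense-mediated-decay candidate calling.

A transcript is an NMD candidate under the 50-nt rule when the stop codon of
its longest ORF lies more than 50 nt upstream of the last exon-exon
junction; mono-exonic transcripts are never candidates.  At the event level,
an alternative-splicing event is NMD-producing when one of its forms yields
a candidate (distance > 50 nt) while the other form does not (distance
< 50 nt).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .io_core import Genome, TranscriptModel, extract_transcript_sequence
from .splicing import ASEvent

logger = logging.getLogger(__name__)

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
NMD_DISTANCE_NT = 50  # strict ">50" threshold


@dataclass
class OrfCall:
    """Longest open reading frame of one transcript.

    ``orf_start``/``orf_stop`` are 0-based transcript coordinates;
    ``orf_stop`` is the first base of the stop codon.
    ``distance_stop_to_last_junction`` is positive when the stop codon lies
    upstream of the last junction and is None for mono-exonic transcripts.
    """

    transcript_id: str
    orf_start: int
    orf_stop: int
    distance_stop_to_last_junction: int | None = None
    nmd_candidate: bool = False
    mono_exonic: bool = False

    @property
    def orf_length(self) -> int:
        """ORF length in nt including the stop codon."""
        return self.orf_stop + 3 - self.orf_start


def longest_orf(seq: str, min_codons: int = 1,
                include_open_ended: bool = False,
                transcript_id: str = "") -> OrfCall | None:
    """Scan the three forward frames for the longest ATG..stop ORF.

    Ties are broken by the 5'-most start.  ORFs running off the 3' end
    without a stop codon are excluded unless ``include_open_ended``;
    ``min_codons`` counts the start codon but not the stop.  Returns None
    when no qualifying ORF exists.
    """
    seq = seq.upper()
    best: tuple[int, int, int] | None = None  # (-length, start, stop_start)
    n = len(seq)
    for frame in range(3):
        start: int | None = None
        for pos in range(frame, n - 2, 3):
            codon = seq[pos:pos + 3]
            if start is None:
                if codon == "ATG":
                    start = pos
            elif codon in STOP_CODONS:
                length = pos - start  # nt, stop excluded
                if length >= 3 * min_codons:
                    cand = (-(length + 3), start, pos)
                    if best is None or cand < best:
                        best = cand
                start = None
        if include_open_ended and start is not None:
            length = ((n - start) // 3) * 3
            if length >= 3 * min_codons:
                cand = (-length, start, start + length)  # no stop codon
                if best is None or cand < best:
                    best = cand
    if best is None:
        return None
    _, start, stop = best
    return OrfCall(transcript_id=transcript_id, orf_start=start, orf_stop=stop)


def last_junction_position(t: TranscriptModel) -> int | None:
    """Transcript coordinate of the last exon-exon junction (nt upstream of it)."""
    if not t.is_multi_exon:
        return None
    exons = t.exons_transcription_order()
    return sum(e - s for s, e in exons[:-1])


def classify_nmd(t: TranscriptModel, orf: OrfCall) -> bool:
    """Apply the 50-nt rule; fills distance/candidacy fields on ``orf`` in place."""
    if orf is None:
        raise ValueError(f"{t.transcript_id}: no ORF call supplied")
    junction = last_junction_position(t)
    if junction is None:
        orf.mono_exonic = True
        orf.distance_stop_to_last_junction = None
        orf.nmd_candidate = False
        return False
    orf.mono_exonic = False
    orf.distance_stop_to_last_junction = junction - orf.orf_stop
    orf.nmd_candidate = orf.distance_stop_to_last_junction > NMD_DISTANCE_NT
    return orf.nmd_candidate


def call_transcript_nmd(
    transcripts: list[TranscriptModel],
    genome: Genome,
    min_codons: int = 30,
) -> dict[str, OrfCall]:
    """Longest ORF + NMD candidacy for every transcript with a qualifying ORF.

    The 30-codon default floor mimics common ORF-finder behaviour;
    transcripts without a qualifying ORF are omitted from the result.
    """
    calls: dict[str, OrfCall] = {}
    for t in transcripts:
        seq = extract_transcript_sequence(t, genome)
        orf = longest_orf(seq, min_codons=min_codons, transcript_id=t.transcript_id)
        if orf is None:
            continue
        classify_nmd(t, orf)
        calls[t.transcript_id] = orf
    return calls


def event_nmd_coupling(event: ASEvent, orf_calls: dict[str, OrfCall]) -> dict | None:
    """Pairwise NMD call for one AS event.

    The event is NMD-producing iff some isoform of one form has
    distance > 50 nt while some isoform of the other form has
    distance < 50 nt.  Events whose forms lack ORF calls (or are all
    mono-exonic) are skipped with a logged reason.
    """
    def distances(tids):
        out = []
        for tid in tids:
            call = orf_calls.get(tid)
            if call is not None and call.distance_stop_to_last_junction is not None:
                out.append(call.distance_stop_to_last_junction)
        return out

    inc = distances(event.inclusion_transcripts)
    exc = distances(event.exclusion_transcripts)
    if not inc or not exc:
        logger.info("event %s skipped: a form lacks ORF-bearing multi-exon "
                    "isoforms", event.event_id)
        return None
    nmd_producing = (
        (max(inc) > NMD_DISTANCE_NT and min(exc) < NMD_DISTANCE_NT)
        or (max(exc) > NMD_DISTANCE_NT and min(inc) < NMD_DISTANCE_NT)
    )
    return {
        "event_id": event.event_id,
        "type": event.type,
        "nmd_producing": nmd_producing,
        "inclusion_distances": inc,
        "exclusion_distances": exc,
    }


def nmd_fraction_by_event_type(
    events, orf_calls: dict[str, OrfCall]
) -> dict[str, float]:
    """Fraction of NMD-producing events per AS event type."""
    totals: dict[str, int] = {}
    hits: dict[str, int] = {}
    for ev in events:
        res = event_nmd_coupling(ev, orf_calls)
        if res is None:
            continue
        totals[ev.type] = totals.get(ev.type, 0) + 1
        if res["nmd_producing"]:
            hits[ev.type] = hits.get(ev.type, 0) + 1
    return {k: hits.get(k, 0) / v for k, v in totals.items()}
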