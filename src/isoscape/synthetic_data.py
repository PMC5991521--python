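"""Deterministic two-species synthetic benchmark with planted truth.

The generator emulates a pair of related grass-like species: an ancestral,
unduplicated species ("b") and a derived species ("a") in which a fraction
of genes exists as duplicate pairs carrying subgenome labels.  Eleven
matched tissues are simulated.  Planted, fully recorded structure includes:

* multi-exon gene models with one reference (base) isoform per gene;
* alternative-splicing variants of six types (IR-heavy, AL-light mix), a
  fraction of which is conserved between orthologs at the same ordinal
  position;
* premature-termination IR isoforms: with probability ``nmd_fraction`` the
  retained intron carries an in-frame stop, making the isoform an NMD
  candidate under the 50-nt rule;
* 1-3 poly(A) cleavage sites per gene with near-upstream-element hexamers
  planted 14-28 nt upstream of each site (AATAAA-dominant mix; one
  pollen-preferred site per multi-site gene carries the pollen motif and
  receives the gene's entire pollen usage);
* 13 phylostrata with young-gene pollen-biased expression, and per-ortholog
  coding divergence targeting a drawn Ka/Ks ratio;
* per-tissue full-length "reads" (BED12 exon chains) sampled from the
  expression matrix, with optional 5' truncation inside the first exon.

Sequences are engineered so that every isoform's longest ORF is the planted
one: 5' UTRs, introns and intergenic margins avoid adenine (hence contain
no start or stop codons), internal coding codons exclude both stops and
ATG (no internal in-frame starts), and 3' UTRs are scrubbed of ATG.  Every
emitted isoform's NMD label is verified against an independent ORF scan at
generation time; genes failing the check (rare frame-shifted spurious ORFs)
are resampled.
"""

from __future__ import annotations

import json
import re
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .evo_indices import STOP_CODONS, synonymous_sites, translate_codon
from .io_core import (
    OrthologMap,
    TranscriptModel,
    reverse_complement,
    write_bed12,
    write_expression,
    write_fasta,
    write_gtf,
    write_orthologs,
)

DEFAULT_TISSUES = (
    "root", "shoot", "leaf", "seedling", "embryo", "endosperm",
    "pericarp", "pollen", "tassel", "ear", "silk",
)

EVENT_TYPES = ("ES", "A5", "A3", "IR", "AF", "AL")

_SAFE = np.array(list("CGT"))  # adenine-free: no ATG, no stop codons
_ACGT = np.array(list("ACGT"))

#: internal coding codons: no stops (premature termination) and no ATG
#: (no internal in-frame start sites competing with the planted ORF)
_INTERNAL_CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in STOP_CODONS and a + b + c != "ATG"
]

MARGIN_UP = 300
MARGIN_DOWN = 400
APA_SITE_SPACING = 30


@dataclass
class SimConfig:
    """Study conditions of the synthetic benchmark (defaults are the
    conditions that every planted-truth recovery test assumes)."""

    seed: int = 0
    n_genes: int = 150                      # ancestral (species b) genes
    duplication_fraction: float = 0.3
    tissues: tuple[str, ...] = DEFAULT_TISSUES
    as_gene_fraction: float = 0.7
    as_event_mix: dict = field(default_factory=lambda: {
        "IR": 0.34, "A3": 0.22, "A5": 0.15, "ES": 0.13, "AF": 0.11, "AL": 0.05,
    })
    conserved_as_fraction: float = 0.5
    nmd_fraction: float = 0.5
    nmd_expression_penalty: float = 0.3
    polya_sites_per_gene: tuple[int, int] = (1, 3)
    nue_motif_mix: dict = field(default_factory=lambda: {
        "AATAAA": 0.50, "ATATAT": 0.14, "ATTAAA": 0.12,
        "TATAAA": 0.10, "AATATA": 0.09, "AATACA": 0.05,
    })
    pollen_nue_motif: str = "ATATAT"
    n_phylostrata: int = 13
    old_fraction: float = 0.60              # PS1-3
    young_fraction: float = 0.15            # PS11-13
    pollen_bias: float = 4.0                # young-gene pollen multiplier
    kaks_targets: dict = field(default_factory=lambda: {
        "old": 0.15, "intermediate": 0.30, "young": 0.60,
    })
    kaks_sigma: float = 0.25                # lognormal jitter on the target
    read_depth: int = 1200                  # reads per tissue per species
    five_prime_truncation_fraction: float = 0.5
    min_expressed_tpm: float = 1.0          # sampling floor
    ts_variant_fraction: float = 0.35       # AS variants that are single-tissue
    ts_variant_pollen_share: float = 0.35

    def __post_init__(self) -> None:
        for name in ("as_event_mix", "nue_motif_mix"):
            probs = getattr(self, name)
            total = sum(probs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} probabilities sum to {total}, not 1")
        for name in ("n_genes", "read_depth", "n_phylostrata"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if len(set(self.tissues)) != len(self.tissues):
            raise ValueError("tissue labels must be unique")


@dataclass
class TruthTables:
    isoforms: pd.DataFrame      # per-isoform planted structure and labels
    events: pd.DataFrame        # planted AS events per species gene
    reads: pd.DataFrame         # read -> truth isoform map
    orthologs: pd.DataFrame     # links with subgenome + Ka/Ks targets
    phylostrata: dict[str, pd.DataFrame]          # species -> presence table
    gene_expression: dict[str, pd.DataFrame]
    transcript_expression: dict[str, pd.DataFrame]
    breadth: dict[str, pd.Series]                 # planted breadth class
    transcripts: dict[str, dict[str, TranscriptModel]]
    cds: dict[str, dict[str, str]]                # species -> gene -> CDS
    genomes: dict[str, dict[str, str]]
    reads_by_tissue: dict[tuple[str, str], list[TranscriptModel]]


# ---------------------------------------------------------------------------
# Random sequence helpers
# ---------------------------------------------------------------------------

def _safe_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_SAFE, size=n)) if n else ""


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_ACGT, size=n)) if n else ""


def _scrub_atg(seq: str) -> str:
    while "ATG" in seq:
        seq = seq.replace("ATG", "ACG")
    return seq


def _random_cds_body(rng: np.random.Generator, n_codons: int) -> str:
    """ATG followed by internal codons (stop- and ATG-free)."""
    idx = rng.integers(0, len(_INTERNAL_CODONS), size=n_codons - 1)
    return "ATG" + "".join(_INTERNAL_CODONS[i] for i in idx)


_STOP_RE = re.compile(r"(?=(TAA|TAG|TGA))")
_ATG_RE = re.compile(r"(?=(ATG))")


def _truth_longest_orf(seq: str) -> tuple[int, int] | None:
    """Independent longest-ORF scan used only for truth labelling.

    Returns (start, stop_codon_start) of the longest closed ATG..stop ORF,
    ties to the 5'-most start.
    """
    stops: dict[int, list[int]] = {0: [], 1: [], 2: []}
    for m in _STOP_RE.finditer(seq):
        stops[m.start() % 3].append(m.start())
    best = None
    for m in _ATG_RE.finditer(seq):
        a = m.start()
        frame_stops = stops[a % 3]
        i = int(np.searchsorted(frame_stops, a + 3))
        if i == len(frame_stops):
            continue
        stop = frame_stops[i]
        cand = (-(stop + 3 - a), a, stop)
        if best is None or cand < best:
            best = cand
    return (best[1], best[2]) if best else None


def _truth_nmd_label(
    seq: str, exon_lens: Sequence[int]
) -> tuple[bool, int | None, int]:
    """(nmd_candidate, distance, orf_length) from the independent scan."""
    orf = _truth_longest_orf(seq)
    if orf is None:
        return False, None, 0
    orf_len = orf[1] + 3 - orf[0]
    if len(exon_lens) < 2:
        return False, None, orf_len
    junction = sum(exon_lens[:-1])
    distance = junction - orf[1]
    return distance > 50, distance, orf_len


# ---------------------------------------------------------------------------
# Coding divergence
# ---------------------------------------------------------------------------

def mutate_coding_pair(
    cds: str, target_kaks: float, rng: np.random.Generator | int
) -> tuple[str, dict]:
    """Diverge a CDS so the Nei-Gojobori estimate targets ``target_kaks``.

    Synonymous and nonsynonymous single-site substitutions (at most one per
    codon) are applied at rates derived by inverting the Jukes-Cantor
    correction for a baseline synonymous divergence dS = 0.2 and
    dN = target * dS.  Stop codons are never created.  Returns the diverged
    sequence and the realized substitution counts.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    if len(cds) % 3:
        raise ValueError("CDS length must be divisible by 3")
    codons = [cds[i:i + 3] for i in range(0, len(cds), 3)]
    body = list(codons)
    keep_stop = None
    if body and body[-1] in STOP_CODONS:
        keep_stop = body.pop()
    if any(c in STOP_CODONS for c in body):
        raise ValueError("internal stop codon in CDS")

    syn_sites = np.array([synonymous_sites(c) for c in body])
    S = float(syn_sites.sum())
    N = float(3 * len(body) - S)
    if S == 0:
        raise ValueError("no synonymous sites: target unreachable")

    d_s = 0.2
    d_n = target_kaks * d_s
    p_s = 0.75 * (1 - np.exp(-4 * d_s / 3))
    p_n = 0.75 * (1 - np.exp(-4 * d_n / 3))
    # stochastically rounded counts: expectation stays exactly on target
    # while avoiding the upward Jensen bias of the ratio of two noisy
    # divergence estimates that fully Poisson counts would incur
    def _stochastic_round(x: float) -> int:
        base = int(np.floor(x))
        return base + int(rng.random() < (x - base))

    n_syn = _stochastic_round(p_s * S)
    n_non = _stochastic_round(p_n * N)

    def one_step_changes(codon: str, synonymous: bool) -> list[str]:
        aa = translate_codon(codon)
        out = []
        for pos in range(3):
            for base in "ACGT":
                if base == codon[pos]:
                    continue
                mut = codon[:pos] + base + codon[pos + 1:]
                if mut in STOP_CODONS:
                    continue
                if (translate_codon(mut) == aa) == synonymous:
                    out.append(mut)
        return out

    touched: set[int] = set()
    realized = {"synonymous": 0, "nonsynonymous": 0}
    for synonymous, count, weights in (
        (True, n_syn, syn_sites),
        (False, n_non, 3 - syn_sites),
    ):
        w = weights.astype(float).copy()
        for _ in range(count):
            w_eff = w.copy()
            if touched:
                w_eff[list(touched)] = 0.0
            total = w_eff.sum()
            if total <= 0:
                break
            idx = int(rng.choice(len(body), p=w_eff / total))
            options = one_step_changes(body[idx], synonymous)
            if not options:
                w[idx] = 0.0
                continue
            body[idx] = options[int(rng.integers(len(options)))]
            touched.add(idx)
            realized["synonymous" if synonymous else "nonsynonymous"] += 1
    if keep_stop is not None:
        body.append(keep_stop)
    return "".join(body), {
        "target_kaks": target_kaks, "S": S, "N": N, **realized,
    }


# ---------------------------------------------------------------------------
# Gene plans
# ---------------------------------------------------------------------------

@dataclass
class _GenePlan:
    index: int
    ps: int
    age: str                    # old | intermediate | young
    archetype: str              # housekeeping | tissue_specific | broad
    ts_tissue: str | None
    broad_tissues: tuple[str, ...]
    exon_lens: tuple[int, ...]
    intron_lens: tuple[int, ...]
    utr5: int
    utr3: int
    n_polya: int
    site_motifs: tuple[str, ...]        # distal-first
    pollen_site: int | None             # index into sites, or None
    as_type: str | None
    as_params: dict
    nmd_intended: bool
    variant_single_tissue: str | None
    conserved: bool

    @property
    def tx_len(self) -> int:
        return sum(self.exon_lens)

    @property
    def cds_len(self) -> int:
        return self.tx_len - self.utr5 - self.utr3

    def event_key(self) -> tuple | None:
        """(type, location) identity used to avoid chance conservation."""
        if self.as_type is None:
            return None
        loc = self.as_params.get("exon", self.as_params.get("intron", 0))
        return (self.as_type, loc)


def _draw_age(rng, cfg: SimConfig) -> tuple[int, str]:
    r = rng.random()
    if r < cfg.old_fraction:
        return int(rng.integers(1, 4)), "old"
    if r < cfg.old_fraction + cfg.young_fraction:
        return int(rng.integers(11, cfg.n_phylostrata + 1)), "young"
    return int(rng.integers(4, 11)), "intermediate"


def _draw_from_mix(rng, mix: dict) -> str:
    keys = list(mix)
    probs = np.array([mix[k] for k in keys], dtype=float)
    return keys[int(rng.choice(len(keys), p=probs / probs.sum()))]


def _plan_event(rng, cfg, exon_lens, utr5, cds_len):
    """Choose an AS event type and its location within the gene geometry."""
    n = len(exon_lens)
    m = n - 1  # introns
    etype = _draw_from_mix(rng, cfg.as_event_mix)
    nmd = False
    params: dict = {}
    if etype == "ES" and n >= 4:
        params = {"exon": int(rng.integers(2, n - 1))}  # 0-based; keeps ATG exon
    elif etype == "A5" and n >= 4:
        j = int(rng.integers(2, n - 1))  # donor-shifted internal exon
        delta = 3 * int(rng.integers(3, min(11, (exon_lens[j] - 30) // 3)))
        params = {"exon": j, "delta": delta}
    elif etype == "A3" and n >= 4:
        j = int(rng.integers(2, n - 1))  # acceptor-shifted internal exon
        delta = 3 * int(rng.integers(3, min(11, (exon_lens[j] - 30) // 3)))
        params = {"exon": j, "delta": delta}
    elif etype == "AF":
        params = {"len": int(rng.integers(70, 110)),
                  "offset": int(rng.integers(30, 90))}
    elif etype == "AL":
        params = {"n_codons": int(rng.integers(4, 9)),
                  "utr": int(rng.integers(120, 160)),
                  "gap": int(rng.integers(40, 90))}
    else:
        etype = "IR"
    if etype == "IR":
        # never the first or last intron: the PTC must sit downstream of the
        # start codon and upstream of the variant's last junction
        cum_cds = np.cumsum(exon_lens) - utr5  # CDS nt upstream of intron j
        eligible = [j for j in range(1, m - 1) if cum_cds[j] >= 210]
        if eligible:
            j = int(eligible[int(rng.integers(len(eligible)))])
            nmd = bool(rng.random() < cfg.nmd_fraction)
        else:
            j = max(1, m - 2)
        params = {"intron": j, "ptc": nmd}
    return etype, params, nmd


def _plan_gene(rng: np.random.Generator, cfg: SimConfig, index: int) -> _GenePlan:
    ps, age = _draw_age(rng, cfg)
    # old genes: more exons and longer CDS (hence longer ORFs, more isoforms)
    if age == "old":
        n_exons = int(rng.integers(5, 8))
        internal = lambda: 3 * int(rng.integers(40, 81))   # 120-240 nt
    elif age == "young":
        n_exons = int(rng.integers(4, 6))
        internal = lambda: 3 * int(rng.integers(30, 51))   # 90-150 nt
    else:
        n_exons = int(rng.integers(4, 7))
        internal = lambda: 3 * int(rng.integers(34, 66))
    exon_lens = [int(rng.integers(60, 101))]               # first: pure 5' UTR
    exon_lens += [internal() for _ in range(n_exons - 2)]
    exon_lens.append(int(rng.integers(330, 421)))          # last: stop + 3' UTR
    intron_lens = [3 * int(rng.integers(24, 61)) for _ in range(n_exons - 1)]

    utr5 = exon_lens[0] + int(rng.integers(21, 45))
    tx_len = sum(exon_lens)
    utr3 = int(rng.integers(170, 240))
    cds_len = tx_len - utr5 - utr3
    cds_len -= cds_len % 3
    utr3 = tx_len - utr5 - cds_len

    n_polya = int(rng.integers(cfg.polya_sites_per_gene[0],
                               cfg.polya_sites_per_gene[1] + 1))
    pollen_site = 1 if n_polya >= 2 else None
    motifs = tuple(
        cfg.pollen_nue_motif if i == pollen_site
        else _draw_from_mix(rng, cfg.nue_motif_mix)
        for i in range(n_polya)
    )

    r = rng.random()
    if r < 0.25:
        archetype, ts_tissue, broad = "housekeeping", None, cfg.tissues
    elif r < 0.40:
        archetype = "tissue_specific"
        if age == "young" and rng.random() < 0.5:
            ts_tissue = "pollen"
        else:
            ts_tissue = cfg.tissues[int(rng.integers(len(cfg.tissues)))]
        broad = (ts_tissue,)
    else:
        archetype, ts_tissue = "broad", None
        k = int(rng.integers(4, 9))
        pool = [t for t in cfg.tissues if t != "pollen"]
        if age == "young":  # young broad genes always cover pollen
            chosen = ["pollen"] + list(rng.choice(pool, size=k - 1, replace=False))
        else:
            chosen = list(rng.choice(list(cfg.tissues), size=k, replace=False))
        broad = tuple(t for t in cfg.tissues if t in chosen)

    p_as = cfg.as_gene_fraction * {"old": 1.2, "intermediate": 1.0,
                                   "young": 0.5}[age]
    as_type, as_params, nmd_intended = None, {}, False
    if rng.random() < min(p_as, 1.0):
        as_type, as_params, nmd_intended = _plan_event(
            rng, cfg, exon_lens, utr5, cds_len
        )
    variant_single_tissue = None
    if as_type is not None and rng.random() < cfg.ts_variant_fraction:
        if archetype == "tissue_specific":
            variant_single_tissue = ts_tissue  # keep breadth truth exact
        elif rng.random() < cfg.ts_variant_pollen_share:
            variant_single_tissue = "pollen"
        else:
            variant_single_tissue = cfg.tissues[int(rng.integers(len(cfg.tissues)))]

    return _GenePlan(
        index=index, ps=ps, age=age, archetype=archetype, ts_tissue=ts_tissue,
        broad_tissues=broad, exon_lens=tuple(exon_lens),
        intron_lens=tuple(intron_lens), utr5=utr5, utr3=utr3,
        n_polya=n_polya, site_motifs=motifs, pollen_site=pollen_site,
        as_type=as_type, as_params=as_params, nmd_intended=nmd_intended,
        variant_single_tissue=variant_single_tissue,
        conserved=bool(rng.random() < cfg.conserved_as_fraction),
    )


# ---------------------------------------------------------------------------
# Gene realization (sequences + isoform exon chains in local sense coords)
# ---------------------------------------------------------------------------

@dataclass
class _Isoform:
    local_id: str               # base | apaK | var
    kind: str                   # base | apa | as_variant
    exons_local: tuple[tuple[int, int], ...]
    tx_seq: str
    nmd: bool
    distance: int | None
    orf_len: int
    cleavage_site_idx: int      # index into the gene's planted site list
    event_type: str | None = None
    event_ordinal: int | None = None


@dataclass
class _GeneRealization:
    plan: _GenePlan
    local_seq: str
    isoforms: list[_Isoform]
    cds_body: str               # ATG..body, terminal stop excluded
    site_offsets: tuple[int, ...]   # local coord of each CS 3'-terminal base
    al_site_offset: int | None      # CS of the AL variant, if planted


def _realize_gene(
    rng: np.random.Generator,
    plan: _GenePlan,
    cds_body_factory: Callable[[np.random.Generator], str],
    max_tries: int = 50,
) -> _GeneRealization:
    for _ in range(max_tries):
        real = _attempt_gene(rng, plan, cds_body_factory)
        if real is not None:
            return real
    raise RuntimeError(f"gene {plan.index}: could not realize planted NMD labels")


def _attempt_gene(rng, plan: _GenePlan, cds_body_factory) -> _GeneRealization | None:
    exon_lens, intron_lens = list(plan.exon_lens), list(plan.intron_lens)
    utr5, utr3, cds_len = plan.utr5, plan.utr3, plan.cds_len

    cds_body = cds_body_factory(rng)
    assert len(cds_body) == cds_len - 3, "factory must supply CDS minus stop"
    cds = cds_body + "TAA"
    utr5_seq = _safe_seq(rng, utr5)
    utr3_list = list(_scrub_atg(_random_seq(rng, utr3)))

    # planted poly(A) sites: distal first; site i ends APA_SITE_SPACING*i nt
    # before the transcript end
    site_ends_utr3 = [utr3 - APA_SITE_SPACING * i for i in range(plan.n_polya)]
    for end, motif in zip(site_ends_utr3, plan.site_motifs):
        d = 14 + int(rng.integers(0, 15))  # motif inside the 1-40 nt window
        utr3_list[end - d:end - d + 6] = list(motif)
    utr3_seq = "".join(utr3_list)
    tx = utr5_seq + cds + utr3_seq

    bounds = np.cumsum([0] + exon_lens)
    exon_seqs = [tx[bounds[i]:bounds[i + 1]] for i in range(len(exon_lens))]

    intron_seqs = [_safe_seq(rng, L) for L in intron_lens]
    if plan.as_type == "IR" and plan.as_params.get("ptc"):
        j = plan.as_params["intron"]
        p = int(bounds[j + 1])  # transcript position where intron j opens
        phase = (p - utr5) % 3
        o = (3 - phase) % 3 + 6  # first in-frame codon start >= 6 nt in
        s = list(intron_seqs[j])
        s[o:o + 3] = list("TAA")
        s[o + 3:o + 5] = list("CC")  # guard against ATG across the stop
        intron_seqs[j] = "".join(s)

    parts = [_safe_seq(rng, MARGIN_UP)]
    exon_local: list[tuple[int, int]] = []
    pos = MARGIN_UP
    for i, es in enumerate(exon_seqs):
        exon_local.append((pos, pos + len(es)))
        parts.append(es)
        pos += len(es)
        if i < len(intron_seqs):
            parts.append(intron_seqs[i])
            pos += len(intron_seqs[i])
    gene_end = pos
    margin_down = _safe_seq(rng, MARGIN_DOWN)

    af_exon = al_exon = None
    al_site_offset = None
    if plan.as_type == "AF":
        L, off = plan.as_params["len"], plan.as_params["offset"]
        af_exon = (off, off + L)  # upstream margin is adenine-free already
    if plan.as_type == "AL":
        pr = plan.as_params
        phase = (int(bounds[-2]) + sum(intron_lens[:-1]) - utr5) % 3
        filler = _safe_seq(rng, (3 - phase) % 3)
        codons = _random_cds_body(rng, pr["n_codons"])[3:]  # no extra ATG
        al_utr = list(_scrub_atg(_random_seq(rng, pr["utr"])))
        d = 14 + int(rng.integers(0, 15))
        al_utr[len(al_utr) - d:len(al_utr) - d + 6] = list("AATAAA")
        al_seq = filler + codons + "TAA" + "".join(al_utr)
        start = gene_end + pr["gap"]
        al_exon = (start, start + len(al_seq))
        md = list(margin_down)
        md[pr["gap"]:pr["gap"] + len(al_seq)] = list(al_seq)
        margin_down = "".join(md)
        al_site_offset = al_exon[1] - 1
    local_seq = "".join(parts) + margin_down

    site_offsets = tuple(
        exon_local[-1][1] - (utr3 - e) - 1 for e in site_ends_utr3
    )

    isoforms: list[_Isoform] = []

    def add(local_id, kind, exons, site_idx, intended_nmd,
            etype=None, ordinal=None) -> bool:
        exons = tuple(exons)
        seq = "".join(local_seq[s:e] for s, e in exons)
        lens = [e - s for s, e in exons]
        nmd, dist, orf_len = _truth_nmd_label(seq, lens)
        if nmd != intended_nmd:
            return False
        isoforms.append(_Isoform(local_id, kind, exons, seq, nmd, dist,
                                 orf_len, site_idx, etype, ordinal))
        return True

    if not add("base", "base", exon_local, 0, False):
        return None
    for i in range(1, plan.n_polya):
        exons = list(exon_local[:-1]) + [(exon_local[-1][0], site_offsets[i] + 1)]
        if not add(f"apa{i}", "apa", exons, i, False):
            return None
    if plan.as_type is not None:
        et, pr = plan.as_type, plan.as_params
        if et == "ES":
            k = pr["exon"]
            exons = [e for i, e in enumerate(exon_local) if i != k]
            ok = add("var", "as_variant", exons, 0, False, et, k)
        elif et == "IR":
            j = pr["intron"]
            merged = (exon_local[j][0], exon_local[j + 1][1])
            exons = exon_local[:j] + [merged] + exon_local[j + 2:]
            ok = add("var", "as_variant", exons, 0, plan.nmd_intended, et, j)
        elif et == "A5":
            j, delta = pr["exon"], pr["delta"]
            exons = list(exon_local)
            s, e = exons[j]
            exons[j] = (s, e - delta)
            ok = add("var", "as_variant", exons, 0, False, et, j)
        elif et == "A3":
            j, delta = pr["exon"], pr["delta"]
            exons = list(exon_local)
            s, e = exons[j]
            exons[j] = (s + delta, e)
            # the varied boundary belongs to intron j-1 (transcription order)
            ok = add("var", "as_variant", exons, 0, False, et, j - 1)
        elif et == "AF":
            exons = [af_exon] + list(exon_local[1:])
            ok = add("var", "as_variant", exons, 0, False, et, 0)
        else:  # AL
            exons = list(exon_local[:-1]) + [al_exon]
            ok = add("var", "as_variant", exons, plan.n_polya, False, et, 0)
        if not ok:
            return None
    return _GeneRealization(plan, local_seq, isoforms, cds_body,
                            site_offsets, al_site_offset)


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def _gene_profile(rng, cfg: SimConfig, plan: _GenePlan) -> np.ndarray:
    base = float(rng.lognormal({"old": np.log(8), "intermediate": np.log(5),
                                "young": np.log(3)}[plan.age], 0.8))
    profile = np.zeros(len(cfg.tissues))
    idx = {t: i for i, t in enumerate(cfg.tissues)}
    if plan.archetype == "housekeeping":
        base = max(base, 5.0)
        profile[:] = base * rng.uniform(0.6, 1.4, size=len(cfg.tissues))
    elif plan.archetype == "tissue_specific":
        profile[idx[plan.ts_tissue]] = max(base, 5.0)
    else:
        base = max(base, 3.0)
        for t in plan.broad_tissues:
            profile[idx[t]] = base * rng.uniform(0.5, 1.5)
    if plan.ps >= 11:
        profile[idx["pollen"]] *= cfg.pollen_bias
    return profile


def _isoform_rows(rng, cfg: SimConfig, plan: _GenePlan,
                  real: _GeneRealization) -> dict[str, np.ndarray]:
    """Per-isoform tissue expression rows; gene expression is their sum."""
    tissues = list(cfg.tissues)
    idx = {t: i for i, t in enumerate(tissues)}
    gene = _gene_profile(rng, cfg, plan)
    body = [iso for iso in real.isoforms if iso.kind in ("base", "apa")]
    variant = next((i for i in real.isoforms if i.kind == "as_variant"), None)

    w_var = 0.25 if variant is not None else 0.0
    if plan.pollen_site is None:
        w_body = np.asarray(rng.dirichlet(np.full(len(body), 3.0))) * (1 - w_var)
        rows = {iso.local_id: gene * w for w, iso in zip(w_body, body)}
    else:
        # the pollen-preferred site is strictly tissue-specific: it carries
        # the gene's entire base/APA usage in pollen and is silent elsewhere,
        # while the remaining 3' isoforms carry the gene in all other tissues
        p = idx["pollen"]
        others = [iso for iso in body
                  if iso.cleavage_site_idx != plan.pollen_site]
        pollen_iso = next(iso for iso in body
                          if iso.cleavage_site_idx == plan.pollen_site)
        w_others = np.asarray(rng.dirichlet(np.full(len(others), 3.0))) \
            * (1 - w_var)
        rows = {iso.local_id: gene * w for w, iso in zip(w_others, others)}
        pollen_row = np.zeros(len(tissues))
        pollen_row[p] = gene[p] * (1 - w_var)
        for iso in others:
            rows[iso.local_id][p] = 0.0
        rows[pollen_iso.local_id] = pollen_row
    if variant is not None:
        if plan.variant_single_tissue is not None:
            row = np.zeros(len(tissues))
            row[idx[plan.variant_single_tissue]] = max(gene.max(), 5.0) * 0.6
        else:
            row = gene * w_var
        if variant.nmd:
            row = row * cfg.nmd_expression_penalty
        rows[variant.local_id] = row
    return rows


# ---------------------------------------------------------------------------
# Simulation driver
# ---------------------------------------------------------------------------

def _mirror_exons(exons, local_len, offset):
    return tuple(sorted(
        (offset + local_len - e, offset + local_len - s) for s, e in exons
    ))


def _shift_exons(exons, offset):
    return tuple((offset + s, offset + e) for s, e in exons)


def _truncate_five_prime(rng, model: TranscriptModel):
    """Move the 5' start uniformly into the first exon (>=25 nt kept)."""
    exons = list(model.exons)
    if model.strand == "+":
        s, e = exons[0]
        room = e - s - 25
        if room > 0:
            exons[0] = (s + int(rng.integers(0, room + 1)), e)
    else:
        s, e = exons[-1]
        room = e - s - 25
        if room > 0:
            exons[-1] = (s, e - int(rng.integers(0, room + 1)))
    return tuple(exons)


def _presence_table(entries, cfg: SimConfig) -> pd.DataFrame:
    """Gene x node homolog-presence table: present from its PS node onward."""
    cols = [f"node{i:02d}" for i in range(1, cfg.n_phylostrata + 1)]
    data = {
        e["gene_id"]: [1 if i + 1 >= e["plan"].ps else 0
                       for i in range(cfg.n_phylostrata)]
        for e in entries
    }
    df = pd.DataFrame.from_dict(data, orient="index", columns=cols).sort_index()
    df.index.name = "gene_id"
    return df


def simulate(cfg: SimConfig, outdir: str | Path | None = None) -> TruthTables:
    """Run the full two-species simulation; optionally write all files."""
    rng = np.random.default_rng(cfg.seed)
    tissues = list(cfg.tissues)

    plans = [_plan_gene(rng, cfg, i) for i in range(cfg.n_genes)]

    species_genes: dict[str, list[dict]] = {"a": [], "b": []}
    ortho_rows = []
    cds_store: dict[str, dict[str, str]] = {"a": {}, "b": {}}

    for plan in plans:
        gene_b = f"GB{plan.index:04d}"
        real_b = _realize_gene(
            rng, plan, lambda r, _n=plan.cds_len // 3 - 1: _random_cds_body(r, _n)
        )
        cds_store["b"][gene_b] = real_b.cds_body + "TAA"
        species_genes["b"].append({"gene_id": gene_b, "plan": plan, "real": real_b})

        n_copies = 2 if rng.random() < cfg.duplication_fraction else 1
        for copy in range(n_copies):
            suffix = "" if n_copies == 1 else f"_{'AB'[copy]}"
            gene_a = f"GA{plan.index:04d}{suffix}"
            target = cfg.kaks_targets[plan.age] * float(
                rng.lognormal(0.0, cfg.kaks_sigma)
            )
            plan_a = plan
            if plan.as_type is not None and not plan.conserved:
                etype, params, nmd = _plan_event(
                    rng, cfg, list(plan.exon_lens), plan.utr5, plan.cds_len
                )
                plan_a = replace(plan, as_type=etype, as_params=params,
                                 nmd_intended=nmd)
                if plan_a.event_key() == plan.event_key():
                    # avoid chance conservation: drop the variant entirely
                    plan_a = replace(plan, as_type=None, as_params={},
                                     nmd_intended=False,
                                     variant_single_tissue=None)

            def factory(r, _body=real_b.cds_body, _t=target):
                mutated, _ = mutate_coding_pair(_body[3:], _t, r)
                return "ATG" + mutated

            real_a = _realize_gene(rng, plan_a, factory)
            cds_store["a"][gene_a] = real_a.cds_body + "TAA"
            species_genes["a"].append({"gene_id": gene_a, "plan": plan_a,
                                       "real": real_a})
            ortho_rows.append({
                "gene_a": gene_a, "gene_b": gene_b,
                "subgenome": "A" if (n_copies == 1 or copy == 0) else "B",
                "multiplicity": "1:1" if n_copies == 1 else "1:2",
                "target_kaks": target,
                "conserved_as": bool(
                    plan.as_type is not None and plan.conserved
                    and plan_a.as_type == plan.as_type
                ),
                "ps": plan.ps, "age": plan.age,
            })

    genomes: dict[str, dict[str, str]] = {}
    transcripts: dict[str, dict[str, TranscriptModel]] = {"a": {}, "b": {}}
    iso_rows, event_rows = [], []
    tx_expr: dict[str, pd.DataFrame] = {}
    gene_expr: dict[str, pd.DataFrame] = {}
    breadth: dict[str, pd.Series] = {}

    for sp in ("b", "a"):
        chrom_parts: dict[str, list[str]] = {f"{sp}_chr1": [], f"{sp}_chr2": []}
        offsets = {c: 0 for c in chrom_parts}
        expr_rows: dict[str, np.ndarray] = {}
        gene_rows: dict[str, np.ndarray] = {}
        breadth_rows: dict[str, str] = {}
        for k, entry in enumerate(species_genes[sp]):
            gene_id, plan, real = entry["gene_id"], entry["plan"], entry["real"]
            chrom = f"{sp}_chr{1 + k % 2}"
            strand = "+" if rng.random() < 0.5 else "-"
            offset = offsets[chrom]
            local_len = len(real.local_seq)
            chrom_parts[chrom].append(
                real.local_seq if strand == "+"
                else reverse_complement(real.local_seq)
            )
            chrom_parts[chrom].append("N" * 200)
            offsets[chrom] += local_len + 200

            rows = _isoform_rows(rng, cfg, plan, real)
            gene_rows[gene_id] = sum(rows.values())
            breadth_rows[gene_id] = (
                plan.archetype if plan.archetype != "broad" else "other"
            )

            all_sites = list(real.site_offsets)
            if real.al_site_offset is not None:
                all_sites.append(real.al_site_offset)
            for iso in real.isoforms:
                iso_id = f"{gene_id}.{iso.local_id}"
                if strand == "+":
                    exons = _shift_exons(iso.exons_local, offset)
                    cs = offset + all_sites[iso.cleavage_site_idx]
                else:
                    exons = _mirror_exons(iso.exons_local, local_len, offset)
                    cs = offset + local_len - 1 - all_sites[iso.cleavage_site_idx]
                model = TranscriptModel(iso_id, gene_id, chrom, strand, exons)
                transcripts[sp][iso_id] = model
                expr_rows[iso_id] = rows[iso.local_id]
                motif = (
                    plan.site_motifs[iso.cleavage_site_idx]
                    if iso.cleavage_site_idx < len(plan.site_motifs) else "AATAAA"
                )
                iso_rows.append({
                    "species": sp, "gene_id": gene_id, "isoform_id": iso_id,
                    "kind": iso.kind, "nmd": iso.nmd,
                    "distance_to_last_junction":
                        -(10 ** 9) if iso.distance is None else iso.distance,
                    "orf_len": iso.orf_len,
                    "event_type": iso.event_type or "",
                    "event_ordinal":
                        -1 if iso.event_ordinal is None else iso.event_ordinal,
                    "cleavage_site": cs, "nue_motif": motif,
                    "single_tissue": (plan.variant_single_tissue or "")
                        if iso.kind == "as_variant" else "",
                    "ps": plan.ps, "age": plan.age,
                    "n_exons": len(iso.exons_local),
                })
            if plan.as_type is not None:
                var = next(i for i in real.isoforms if i.kind == "as_variant")
                event_rows.append({
                    "species": sp, "gene_id": gene_id, "type": plan.as_type,
                    "ordinal": var.event_ordinal, "nmd": plan.nmd_intended,
                })
        genomes[sp] = {c: "".join(p) for c, p in chrom_parts.items()}
        tx_expr[sp] = pd.DataFrame.from_dict(
            expr_rows, orient="index", columns=tissues).sort_index()
        gene_expr[sp] = pd.DataFrame.from_dict(
            gene_rows, orient="index", columns=tissues).sort_index()
        breadth[sp] = pd.Series(breadth_rows).sort_index().rename("breadth")

    # ---- reads ----
    read_rows = []
    reads_by_tissue: dict[tuple[str, str], list[TranscriptModel]] = {}
    for sp in ("b", "a"):
        expr = tx_expr[sp]
        ids = list(expr.index)
        counts = np.zeros((len(ids), len(tissues)), dtype=int)
        for ti, tissue in enumerate(tissues):
            col = expr[tissue].to_numpy(dtype=float)
            if col.sum() > 0:
                counts[:, ti] = rng.multinomial(cfg.read_depth, col / col.sum())
        # sampling-floor guarantee: an isoform above the floor gets a read
        expr_np = expr.to_numpy(dtype=float)
        orphan = (counts.sum(axis=1) == 0) & (
            expr_np.max(axis=1) >= cfg.min_expressed_tpm
        )
        for gi in np.flatnonzero(orphan):
            counts[gi, int(expr_np[gi].argmax())] = 1
        for ti, tissue in enumerate(tissues):
            bucket = reads_by_tissue.setdefault((sp, tissue), [])
            for gi in np.flatnonzero(counts[:, ti]):
                model = transcripts[sp][ids[gi]]
                for r in range(int(counts[gi, ti])):
                    read_id = f"r{sp}_{tissue}_{ids[gi]}_{r}"
                    exons = model.exons
                    if rng.random() < cfg.five_prime_truncation_fraction:
                        exons = _truncate_five_prime(rng, model)
                    bucket.append(
                        TranscriptModel(read_id, model.gene_id, model.chrom,
                                        model.strand, exons,
                                        tissue_support={tissue: 1})
                    )
                    read_rows.append({
                        "read_id": read_id, "species": sp, "tissue": tissue,
                        "truth_isoform": ids[gi], "gene_id": model.gene_id,
                    })

    truth = TruthTables(
        isoforms=pd.DataFrame(iso_rows),
        events=pd.DataFrame(event_rows),
        reads=pd.DataFrame(read_rows),
        orthologs=pd.DataFrame(ortho_rows),
        phylostrata={sp: _presence_table(species_genes[sp], cfg)
                     for sp in ("a", "b")},
        gene_expression=gene_expr,
        transcript_expression=tx_expr,
        breadth=breadth,
        transcripts=transcripts,
        cds=cds_store,
        genomes=genomes,
        reads_by_tissue=reads_by_tissue,
    )
    if outdir is not None:
        _write_outputs(cfg, truth, Path(outdir))
    return truth


def _write_outputs(cfg, truth: TruthTables, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    for sp in ("a", "b"):
        spdir = outdir / f"species_{sp}"
        spdir.mkdir(exist_ok=True)
        write_fasta(truth.genomes[sp], spdir / "genome.fa")
        # reference annotation: base isoforms only, so novel-isoform
        # discovery stays testable
        base = [
            truth.transcripts[sp][row.isoform_id]
            for row in truth.isoforms.itertuples()
            if row.species == sp and row.kind == "base"
        ]
        write_gtf(sorted(base, key=lambda t: (t.chrom, t.start, t.transcript_id)),
                  spdir / "annotation.gtf")
        for tissue in cfg.tissues:
            write_bed12(truth.reads_by_tissue[(sp, tissue)],
                        spdir / f"reads_{tissue}.bed12")
        write_expression(truth.transcript_expression[sp],
                         spdir / "transcript_tpm.tsv")
        write_expression(truth.gene_expression[sp], spdir / "gene_tpm.tsv")
        truth.phylostrata[sp].to_csv(spdir / "phylostrata.tsv", sep="\t")
        write_fasta(truth.cds[sp], spdir / "cds.fa")
    write_orthologs(
        OrthologMap([(r.gene_a, r.gene_b) for r in truth.orthologs.itertuples()]),
        outdir / "orthologs.tsv",
    )
    truth.orthologs.to_csv(outdir / "ortholog_details.tsv", sep="\t", index=False)
    tdir = outdir / "truth"
    tdir.mkdir(exist_ok=True)
    truth.isoforms.to_csv(tdir / "isoforms.tsv", sep="\t", index=False)
    truth.events.to_csv(tdir / "events.tsv", sep="\t", index=False)
    truth.reads.to_csv(tdir / "reads.tsv", sep="\t", index=False)
    for sp in ("a", "b"):
        truth.breadth[sp].to_csv(tdir / f"breadth_{sp}.tsv", sep="\t")
    with open(outdir / "config.json", "w") as fh:
        json.dump(asdict(cfg), fh, indent=1, default=str)
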