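"""Phylostratigraphy, Nei-Gojobori Ka/Ks, and transcriptome age/divergence.

The phylostratum (PS) of a gene is the rank of the oldest phylogenetic node
(1 = oldest of 13) at which a homolog is detected.  The transcriptome age
index of tissue s is the expression-weighted mean phylostratum,

    TAI_s = sum_i ps_i * e_is / sum_i e_is ,

and the divergence index (TDI) replaces ps_i with the gene's Ka/Ks ratio.
Ka/Ks is estimated by the Nei-Gojobori (1986) site-counting method with
Jukes-Cantor correction on a codon alignment obtained from a global protein
alignment back-mapped to nucleotides.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import permutations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Data.CodonTable import unambiguous_dna_by_id

logger = logging.getLogger(__name__)

N_PHYLOSTRATA = 13
OLD_MAX_PS = 3     # PS1-3 -> "old"
YOUNG_MIN_PS = 11  # PS11-13 -> "young"

_TABLE = unambiguous_dna_by_id[1]
STOP_CODONS = frozenset(_TABLE.stop_codons)
_BASES = "ACGT"


def translate_codon(codon: str) -> str:
    if codon in STOP_CODONS:
        return "*"
    return _TABLE.forward_table[codon]


# ---------------------------------------------------------------------------
# Phylostratigraphy
# ---------------------------------------------------------------------------

@dataclass
class PhyloProfile:
    gene_id: str
    ps: int

    @property
    def age_class(self) -> str:
        if self.ps <= OLD_MAX_PS:
            return "old"
        if self.ps >= YOUNG_MIN_PS:
            return "young"
        return "intermediate"

    @property
    def orphan_class(self) -> str:
        """SSOG for species-specific genes, TSOG for taxon-restricted ones."""
        if self.ps == N_PHYLOSTRATA:
            return "SSOG"
        if self.ps >= YOUNG_MIN_PS:
            return "TSOG"
        return ""


def assign_phylostrata(presence: pd.DataFrame) -> list[PhyloProfile]:
    """PS = smallest node index (1-based) with a detected homolog.

    ``presence`` is a gene x node table of booleans/0-1 with columns ordered
    oldest to youngest.  A gene absent at every node is an error.
    """
    values = presence.to_numpy().astype(bool)
    profiles = []
    for gene, row in zip(presence.index, values):
        hits = np.flatnonzero(row)
        if hits.size == 0:
            raise ValueError(f"gene {gene}: no homolog detected at any node")
        profiles.append(PhyloProfile(str(gene), int(hits[0]) + 1))
    return profiles


# ---------------------------------------------------------------------------
# Codon alignment
# ---------------------------------------------------------------------------

def _check_cds(cds: str, name: str) -> str:
    cds = cds.upper()
    if len(cds) % 3:
        raise ValueError(f"{name}: CDS length {len(cds)} not divisible by 3")
    codons = [cds[i:i + 3] for i in range(0, len(cds), 3)]
    body = codons[:-1] if codons and codons[-1] in STOP_CODONS else codons
    for i, c in enumerate(body):
        if c in STOP_CODONS:
            raise ValueError(f"{name}: internal stop codon {c} at codon {i}")
    return cds


def _strip_terminal_stop(cds: str) -> str:
    return cds[:-3] if cds[-3:] in STOP_CODONS else cds


@dataclass
class CodonAlignment:
    pairs: list[tuple[str, str]]  # aligned codon pairs, gap columns excluded
    protein_identity: float
    low_confidence: bool


def make_protein_aligner(matrix: str = "BLOSUM62",
                         open_gap: float = 10.0,
                         extend_gap: float = 0.5) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -open_gap
    aligner.extend_gap_score = -extend_gap
    return aligner


def align_codon_pair(cds_a: str, cds_b: str,
                     aligner: Align.PairwiseAligner | None = None,
                     min_identity: float = 0.3) -> CodonAlignment:
    """Globally align translations, back-map residue pairs to codons.

    Gap columns are excluded from the returned codon pairs.  The alignment
    is flagged low-confidence when protein identity over aligned columns
    falls below ``min_identity``.
    """
    cds_a = _strip_terminal_stop(_check_cds(cds_a, "cds_a"))
    cds_b = _strip_terminal_stop(_check_cds(cds_b, "cds_b"))
    codons_a = [cds_a[i:i + 3] for i in range(0, len(cds_a), 3)]
    codons_b = [cds_b[i:i + 3] for i in range(0, len(cds_b), 3)]
    prot_a = "".join(translate_codon(c) for c in codons_a)
    prot_b = "".join(translate_codon(c) for c in codons_b)
    if aligner is None:
        aligner = make_protein_aligner()
    aln = aligner.align(prot_a, prot_b)[0]
    row_a, row_b = str(aln[0]), str(aln[1])
    i = j = 0
    pairs: list[tuple[str, str]] = []
    matches = columns = 0
    for ca, cb in zip(row_a, row_b):
        if ca != "-" and cb != "-":
            pairs.append((codons_a[i], codons_b[j]))
            columns += 1
            if ca == cb:
                matches += 1
        if ca != "-":
            i += 1
        if cb != "-":
            j += 1
    identity = matches / columns if columns else 0.0
    return CodonAlignment(pairs, identity, identity < min_identity)


# ---------------------------------------------------------------------------
# Nei-Gojobori (1986)
# ---------------------------------------------------------------------------

@dataclass
class KaKsResult:
    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    dS: float
    dN: float
    ratio: float | None  # None when dS == 0 (undefined)
    n_codons: int


def synonymous_sites(codon: str) -> float:
    """Per-codon synonymous site count under the NG86 convention.

    Each position contributes (synonymous one-step changes) / (one-step
    changes not producing a stop codon); contributions sum with the
    nonsynonymous complement to exactly 3 sites per codon.
    """
    aa = translate_codon(codon)
    total = 0.0
    for pos in range(3):
        syn = valid = 0
        for base in _BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1:]
            if mutant in STOP_CODONS:
                continue
            valid += 1
            if translate_codon(mutant) == aa:
                syn += 1
        if valid:
            total += syn / valid
    return total


def _pathway_differences(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two codons.

    Multi-difference codons average over all minimal substitution pathways
    that avoid stop-codon intermediates (unweighted); if every pathway hits
    a stop, all pathways are used.
    """
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    if len(diff) == 1:
        pos = diff[0]
        same = translate_codon(c1) == translate_codon(c2)
        return (1.0, 0.0) if same else (0.0, 1.0)

    def walk(order: tuple[int, ...]) -> tuple[int, int, bool]:
        cur = c1
        syn = non = 0
        clean = True
        for step, pos in enumerate(order):
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS and step < len(order) - 1:
                clean = False
            if translate_codon(cur) == translate_codon(nxt):
                syn += 1
            else:
                non += 1
            cur = nxt
        return syn, non, clean

    paths = [walk(order) for order in permutations(diff)]
    clean_paths = [(s, n) for s, n, ok in paths if ok]
    use = clean_paths if clean_paths else [(s, n) for s, n, _ in paths]
    syn = sum(s for s, _ in use) / len(use)
    non = sum(n for _, n in use) / len(use)
    return syn, non


def jukes_cantor(p: float) -> float:
    if p >= 0.75:
        raise ValueError(f"substitution proportion {p:.3f} >= 3/4: saturated")
    return -0.75 * math.log(1 - 4 * p / 3)


def nei_gojobori(pairs: Sequence[tuple[str, str]]) -> KaKsResult:
    """Nei-Gojobori Ka/Ks from aligned codon pairs.

    Site counts are averaged between the two sequences; codon pairs
    containing a stop codon are excluded from counting.
    """
    if not pairs:
        raise ValueError("empty codon alignment")
    S = N = Sd = Nd = 0.0
    n_codons = 0
    for c1, c2 in pairs:
        c1, c2 = c1.upper(), c2.upper()
        if c1 in STOP_CODONS or c2 in STOP_CODONS:
            continue
        n_codons += 1
        s = (synonymous_sites(c1) + synonymous_sites(c2)) / 2
        S += s
        N += 3 - s
        sd, nd = _pathway_differences(c1, c2)
        Sd += sd
        Nd += nd
    if n_codons == 0 or S == 0:
        raise ValueError("no countable codon sites (S == 0)")
    pS, pN = Sd / S, Nd / N
    dS, dN = jukes_cantor(pS), jukes_cantor(pN)
    ratio = dN / dS if dS > 0 else None
    return KaKsResult(S, N, Sd, Nd, pS, pN, dS, dN, ratio, n_codons)


def kaks_for_pair(cds_a: str, cds_b: str, **align_kwargs) -> KaKsResult:
    aln = align_codon_pair(cds_a, cds_b, **align_kwargs)
    return nei_gojobori(aln.pairs)


# ---------------------------------------------------------------------------
# TAI / TDI
# ---------------------------------------------------------------------------

def _weighted_index(expr: pd.DataFrame, weights: Mapping[str, float],
                    what: str) -> pd.Series:
    genes = [g for g in expr.index if g in weights]
    missing = expr.index.difference(genes)
    expressed_missing = [
        g for g in missing if float(expr.loc[g].sum()) > 0
    ]
    if what == "ps" and expressed_missing:
        raise ValueError(
            f"expressed genes without phylostratum: {expressed_missing[:5]}"
        )
    if expressed_missing:
        logger.info("%d expressed genes lack %s values; excluded",
                    len(expressed_missing), what)
    if not genes:
        raise ValueError(f"no gene with defined {what} values")
    sub = expr.loc[genes]
    w = np.array([weights[g] for g in genes], dtype=float)
    totals = sub.sum(axis=0)
    if (totals == 0).any():
        bad = list(totals.index[totals == 0])
        raise ValueError(f"all-zero expression in tissues: {bad}")
    return (sub.mul(w, axis=0).sum(axis=0) / totals).astype(float)


def compute_tai(expr: pd.DataFrame, ps: Mapping[str, int]) -> pd.Series:
    """Per-tissue transcriptome age index (expression-weighted mean PS).

    Invariant to rescaling any tissue's expression column.
    """
    return _weighted_index(expr, ps, "ps")


def compute_tdi(expr: pd.DataFrame, kaks: Mapping[str, float]) -> pd.Series:
    """Per-tissue transcriptome divergence index (weighted mean Ka/Ks).

    Genes with undefined ratios must already be absent from ``kaks``; they
    are excluded, not imputed.
    """
    defined = {g: r for g, r in kaks.items() if r is not None and np.isfinite(r)}
    return _weighted_index(expr, defined, "kaks")
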