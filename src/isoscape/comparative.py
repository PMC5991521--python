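"""Cross-species ortholog-based utilities.

Duplication typing against an ancestral (unduplicated) gene set, expression
correlation matrices within and between species, group-wise expression
contrasts, expression-breadth gene classes, and rarefaction of gene/isoform
discovery.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import squareform
from scipy.stats import mannwhitneyu, pearsonr, spearmanr
from statsmodels.stats.multitest import multipletests

from .io_core import OrthologMap


# ---------------------------------------------------------------------------
# Duplication calls
# ---------------------------------------------------------------------------

@dataclass
class DuplicationCall:
    ancestral_gene: str
    derived_genes: tuple[str, ...]
    type: str  # singleton | duplicate_pair | other


def call_duplications(
    orth: OrthologMap, all_ancestral: Iterable[str] | None = None
) -> list[DuplicationCall]:
    """Partition ancestral genes by derived-ortholog multiplicity.

    One derived ortholog -> singleton; exactly two -> duplicate_pair;
    anything else (including zero, when ``all_ancestral`` supplies genes
    absent from the map) -> other.
    """
    if not orth.pairs:
        raise ValueError("empty ortholog map")
    b2a = orth.b_to_a()
    ancestral = sorted(set(b2a) | set(all_ancestral or []))
    calls = []
    for gene in ancestral:
        derived = tuple(b2a.get(gene, []))
        if len(derived) == 1:
            kind = "singleton"
        elif len(derived) == 2:
            kind = "duplicate_pair"
        else:
            kind = "other"
        calls.append(DuplicationCall(gene, derived, kind))
    return calls


def duplication_counts(calls: Sequence[DuplicationCall]) -> dict[str, int]:
    out = {"singleton": 0, "duplicate_pair": 0, "other": 0}
    for c in calls:
        out[c.type] += 1
    return out


# ---------------------------------------------------------------------------
# Correlation matrices
# ---------------------------------------------------------------------------

@dataclass
class CorrelationMatrix:
    matrix: pd.DataFrame  # rows = species-A tissues, cols = species-B tissues
    method: str
    row_order: list[str]
    col_order: list[str]


def _corr(x: np.ndarray, y: np.ndarray, method: str) -> float:
    if np.all(x == x[0]) or np.all(y == y[0]):
        return np.nan  # constant vector -> undefined
    if method == "spearman":
        return float(spearmanr(x, y).statistic)
    if method == "pearson-on-log1p":
        return float(pearsonr(np.log1p(x), np.log1p(y)).statistic)
    raise ValueError(f"unknown correlation method {method!r}")


def _cluster_order(matrix: pd.DataFrame, axis: int) -> list[str]:
    """Average-linkage leaf order using 1 - r distance between rows/cols."""
    data = matrix.to_numpy() if axis == 0 else matrix.to_numpy().T
    labels = list(matrix.index if axis == 0 else matrix.columns)
    if len(labels) < 3:
        return labels
    with np.errstate(invalid="ignore"):
        r = np.corrcoef(np.nan_to_num(data))
    dist = np.clip(1.0 - r, 0.0, 2.0)
    dist = np.where(np.isnan(dist), 2.0, dist)  # undefined -> max distance
    np.fill_diagonal(dist, 0.0)
    order = leaves_list(average(squareform(dist, checks=False)))
    return [labels[i] for i in order]


def cross_species_correlation(
    expr_a: pd.DataFrame,
    expr_b: pd.DataFrame,
    orth: OrthologMap | Sequence[tuple[str, str]],
    method: str = "spearman",
) -> CorrelationMatrix:
    """Tissue x tissue correlation across one-to-one ortholog pairs.

    Cell (s, t) correlates species-A expression in tissue s with species-B
    expression in tissue t over the shared ortholog pairs.  Default
    statistic is Spearman (robust to cross-species scale); Pearson on
    log1p(TPM) is available.
    """
    pairs = orth.one_to_one() if isinstance(orth, OrthologMap) else list(orth)
    pairs = [
        (a, b) for a, b in pairs if a in expr_a.index and b in expr_b.index
    ]
    if len(pairs) < 3:
        raise ValueError("need >=3 shared ortholog pairs with expression")
    a_mat = expr_a.loc[[a for a, _ in pairs]].to_numpy(dtype=float)
    b_mat = expr_b.loc[[b for _, b in pairs]].to_numpy(dtype=float)
    out = pd.DataFrame(
        index=list(expr_a.columns), columns=list(expr_b.columns), dtype=float
    )
    for i, s in enumerate(expr_a.columns):
        for j, t in enumerate(expr_b.columns):
            out.loc[s, t] = _corr(a_mat[:, i], b_mat[:, j], method)
    return CorrelationMatrix(
        matrix=out,
        method=method,
        row_order=_cluster_order(out, axis=0),
        col_order=_cluster_order(out, axis=1),
    )


def within_species_correlation(expr: pd.DataFrame,
                               method: str = "spearman") -> CorrelationMatrix:
    ident = [(g, g) for g in expr.index]
    return cross_species_correlation(expr, expr, ident, method=method)


# ---------------------------------------------------------------------------
# Group-wise expression contrast
# ---------------------------------------------------------------------------

def gene_class_expression_compare(
    expr: pd.DataFrame,
    groups: Mapping[str, str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-group per-tissue contrast: medians, rank test, BH correction.

    ``groups`` maps gene -> label; exactly two labels are compared with a
    Mann-Whitney U test per tissue.  With more than one tissue, p-values
    are Benjamini-Hochberg adjusted across tissues.
    """
    labels = sorted(set(groups.values()))
    if len(labels) != 2:
        raise ValueError(f"expected exactly 2 groups, got {labels}")
    members = {
        lab: [g for g in expr.index if groups.get(g) == lab] for lab in labels
    }
    for lab, genes in members.items():
        if len(genes) < 2:
            raise ValueError(f"group {lab!r} has <2 genes with expression")
    rows = []
    for tissue in expr.columns:
        x = expr.loc[members[labels[0]], tissue].to_numpy(dtype=float)
        y = expr.loc[members[labels[1]], tissue].to_numpy(dtype=float)
        stat, p = mannwhitneyu(x, y, alternative="two-sided")
        rows.append({
            "tissue": tissue,
            f"median_{labels[0]}": float(np.median(x)),
            f"median_{labels[1]}": float(np.median(y)),
            "median_diff": float(np.median(x) - np.median(y)),
            "u_statistic": float(stat),
            "p_value": float(p),
        })
    df = pd.DataFrame(rows).set_index("tissue")
    if len(df) > 1:
        df["p_adjusted"] = multipletests(df["p_value"], method="fdr_bh")[1]
    else:
        df["p_adjusted"] = df["p_value"]
    df["significant"] = df["p_adjusted"] < alpha
    return df


# ---------------------------------------------------------------------------
# Expression breadth classes
# ---------------------------------------------------------------------------

def classify_gene_breadth(expr: pd.DataFrame, t_on: float = 1.0) -> pd.Series:
    """housekeeping = expressed (>= t_on) in all tissues; tissue_specific =
    expressed in exactly one; everything else = other."""
    on = (expr >= t_on)
    n_on = on.sum(axis=1)
    labels = pd.Series("other", index=expr.index, dtype=object)
    labels[n_on == expr.shape[1]] = "housekeeping"
    labels[n_on == 1] = "tissue_specific"
    return labels


# ---------------------------------------------------------------------------
# Rarefaction
# ---------------------------------------------------------------------------

@dataclass
class RarefactionCurve:
    depths: list[int]
    mean_genes: list[float]
    sd_genes: list[float]
    mean_isoforms: list[float]
    sd_isoforms: list[float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "depth": self.depths,
            "mean_genes": self.mean_genes,
            "sd_genes": self.sd_genes,
            "mean_isoforms": self.mean_isoforms,
            "sd_isoforms": self.sd_isoforms,
        })


def rarefaction(
    assignments: Sequence[tuple[str, str]],
    depths: Sequence[int],
    n_reps: int = 100,
    seed: int = 0,
) -> RarefactionCurve:
    """Discovery curves by subsampling reads without replacement.

    ``assignments`` lists one (gene_id, isoform_id) pair per read.  At each
    depth, ``n_reps`` subsamples are drawn and distinct genes/isoforms
    counted; means are non-decreasing in depth in expectation, and the full
    depth returns the total distinct counts with zero SD.
    """
    total = len(assignments)
    if any(d > total for d in depths):
        raise ValueError(f"depth exceeds total read count {total}")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    genes = np.array([g for g, _ in assignments])
    isos = np.array([i for _, i in assignments])
    rng = np.random.default_rng(seed)
    mg, sg, mi, si = [], [], [], []
    for d in depths:
        g_counts, i_counts = [], []
        for _ in range(n_reps):
            idx = rng.choice(total, size=d, replace=False)
            g_counts.append(len(np.unique(genes[idx])))
            i_counts.append(len(np.unique(isos[idx])))
        mg.append(float(np.mean(g_counts)))
        sg.append(float(np.std(g_counts)))
        mi.append(float(np.mean(i_counts)))
        si.append(float(np.std(i_counts)))
    return RarefactionCurve(list(depths), mg, sg, mi, si)
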