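"""Phylostratigraphy, Nei-Gojobori Ka/Ks, and TAI/TDI."""

import math
from itertools import permutations

import numpy as np
import pandas as pd
import pytest

from isoscape.evo_indices import (
    STOP_CODONS,
    align_codon_pair,
    assign_phylostrata,
    compute_tai,
    compute_tdi,
    kaks_for_pair,
    nei_gojobori,
    synonymous_sites,
    translate_codon,
)


# ---------------------------------------------------------------------------
# Phylostrata
# ---------------------------------------------------------------------------

def presence_frame(rows):
    return pd.DataFrame(rows, index=[f"g{i}" for i in range(len(rows))],
                        columns=[f"n{j}" for j in range(1, 14)])


class TestPhylostrata:
    def test_present_everywhere_is_ps1_old(self):
        (p,) = assign_phylostrata(presence_frame([[1] * 13]))
        assert p.ps == 1 and p.age_class == "old" and p.orphan_class == ""

    def test_only_youngest_node_is_ssog(self):
        (p,) = assign_phylostrata(presence_frame([[0] * 12 + [1]]))
        assert p.ps == 13 and p.age_class == "young" and p.orphan_class == "SSOG"

    def test_node11_is_tsog(self):
        (p,) = assign_phylostrata(presence_frame([[0] * 10 + [1, 1, 1]]))
        assert p.ps == 11 and p.orphan_class == "TSOG"

    def test_absent_everywhere_raises(self):
        with pytest.raises(ValueError):
            assign_phylostrata(presence_frame([[0] * 13]))

    def test_matches_brute_force_min_index(self):
        rng = np.random.default_rng(3)
        rows = (rng.random((50, 13)) < 0.3).astype(int)
        rows[:, 12] = 1  # every gene present at the youngest node
        profiles = assign_phylostrata(presence_frame(list(rows)))
        for p, row in zip(profiles, rows):
            assert p.ps == min(j + 1 for j, v in enumerate(row) if v)


# ---------------------------------------------------------------------------
# Codon alignment
# ---------------------------------------------------------------------------

class TestAlignCodonPair:
    def test_identical_cds_all_codons_paired(self):
        cds = "ATGGCCGTTAAAGGG"
        aln = align_codon_pair(cds, cds)
        assert len(aln.pairs) == 5
        assert all(a == b for a, b in aln.pairs)
        assert aln.protein_identity == 1.0 and not aln.low_confidence

    def test_single_codon_deletion_gap_excluded(self):
        a = "ATGGCCGTTAAAGGGTTC"
        b = "ATGGCCAAAGGGTTC"  # GTT codon deleted
        aln = align_codon_pair(a, b)
        assert len(aln.pairs) == 5  # gap column dropped
        assert [p[1] for p in aln.pairs] == ["ATG", "GCC", "AAA", "GGG", "TTC"]

    def test_internal_stop_rejected(self):
        with pytest.raises(ValueError, match="stop"):
            align_codon_pair("ATGTAAGGG", "ATGGCCGGG")

    def test_unrelated_sequences_flagged_low_confidence(self):
        rng = np.random.default_rng(5)
        codons = [c for c in
                  ("".join(t) for t in __import__("itertools").product("ACGT",
                                                                       repeat=3))
                  if c not in STOP_CODONS]
        a = "".join(rng.choice(codons, size=60))
        b = "".join(rng.choice(codons, size=60))
        aln = align_codon_pair(a, b, min_identity=0.9)
        assert aln.low_confidence


# ---------------------------------------------------------------------------
# Nei-Gojobori
# ---------------------------------------------------------------------------

def brute_force_ng(pairs):
    """Independent recount of S, N, Sd, Nd with explicit enumeration."""
    def site_fractions(codon):
        aa = translate_codon(codon)
        s = 0.0
        for pos in range(3):
            syn = ok = 0
            for b in "ACGT":
                if b == codon[pos]:
                    continue
                mut = codon[:pos] + b + codon[pos + 1:]
                if mut in STOP_CODONS:
                    continue
                ok += 1
                syn += translate_codon(mut) == aa
            if ok:
                s += syn / ok
        return s

    S = N = Sd = Nd = 0.0
    for c1, c2 in pairs:
        if c1 in STOP_CODONS or c2 in STOP_CODONS:
            continue
        s = (site_fractions(c1) + site_fractions(c2)) / 2
        S += s
        N += 3 - s
        diff = [i for i in range(3) if c1[i] != c2[i]]
        if not diff:
            continue
        path_counts = []
        for order in permutations(diff):
            cur, syn, non, blocked = c1, 0, 0, False
            for step, pos in enumerate(order):
                nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
                if nxt in STOP_CODONS and step < len(order) - 1:
                    blocked = True
                if translate_codon(cur) == translate_codon(nxt):
                    syn += 1
                else:
                    non += 1
                cur = nxt
            path_counts.append((syn, non, blocked))
        clean = [(s_, n_) for s_, n_, b in path_counts if not b]
        use = clean if clean else [(s_, n_) for s_, n_, _ in path_counts]
        Sd += sum(x for x, _ in use) / len(use)
        Nd += sum(y for _, y in use) / len(use)
    return S, N, Sd, Nd


class TestNeiGojobori:
    def test_sites_sum_to_three_per_codon(self):
        for codon in ("GGG", "ATG", "TGG", "CGA", "TTA"):
            s = synonymous_sites(codon)
            assert 0 <= s <= 3

    def test_identical_codons_zero_divergence(self):
        res = nei_gojobori([("ATG", "ATG"), ("GCC", "GCC")])
        assert res.Sd == res.Nd == 0
        assert res.dN == res.dS == 0
        assert res.ratio is None  # 0/0 flagged undefined

    def test_synonymous_only_divergence_ratio_zero(self):
        """100 GGT codons, 10 third-position GGT->GGC (all glycine)."""
        pairs = [("GGT", "GGC")] * 10 + [("GGT", "GGT")] * 90
        res = nei_gojobori(pairs)
        assert res.Nd == 0 and res.dN == 0
        assert res.Sd == 10 and res.dS > 0
        assert res.ratio == 0

    @staticmethod
    def random_diverged_pairs(rng, n_codons=50, max_changes=2):
        """Codon pairs where the second member carries 0..max_changes
        random non-stop substitutions of the first."""
        codons = [c for c in
                  ("".join(t) for t in __import__("itertools").product("ACGT",
                                                                       repeat=3))
                  if c not in STOP_CODONS]
        pairs = []
        for _ in range(n_codons):
            c1 = str(rng.choice(codons))
            c2 = c1
            for _ in range(int(rng.integers(0, max_changes + 1))):
                pos = int(rng.integers(3))
                c2 = c2[:pos] + str(rng.choice(list("ACGT"))) + c2[pos + 1:]
            if c2 in STOP_CODONS:
                c2 = c1
            pairs.append((c1, c2))
        return pairs

    def test_site_conservation_invariant(self):
        rng = np.random.default_rng(7)
        res = nei_gojobori(self.random_diverged_pairs(rng, max_changes=1))
        assert res.S + res.N == pytest.approx(3 * res.n_codons, abs=1e-6)

    def test_matches_brute_force_oracle_on_random_pairs(self):
        rng = np.random.default_rng(19)
        for _ in range(20):
            pairs = self.random_diverged_pairs(rng)
            res = nei_gojobori(pairs)
            S, N, Sd, Nd = brute_force_ng(pairs)
            assert res.S == pytest.approx(S)
            assert res.N == pytest.approx(N)
            assert res.Sd == pytest.approx(Sd)
            assert res.Nd == pytest.approx(Nd)

    def test_close_to_reference_implementation(self):
        """Loose cross-check against Biopython's NG86 (its stop-codon
        convention differs slightly in site counting)."""
        pytest.importorskip("Bio.codonalign")
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds
        from isoscape.synthetic_data import _random_cds_body, mutate_coding_pair
        rng = np.random.default_rng(4)
        a = _random_cds_body(rng, 200)
        b, _ = mutate_coding_pair(a, 0.4, rng)
        res = nei_gojobori([(a[i:i + 3], b[i:i + 3])
                            for i in range(0, len(a), 3)])
        dn, ds = cal_dn_ds(CodonSeq(a), CodonSeq(b), method="NG86")
        assert res.dN == pytest.approx(dn, rel=0.1)
        assert res.dS == pytest.approx(ds, rel=0.1)

    def test_saturation_raises(self):
        with pytest.raises(ValueError, match="saturat"):
            nei_gojobori([("GGT", "GGA")] * 10)  # pS = 1 at synonymous sites

    def test_alignment_plus_counting_roundtrip(self):
        a = "ATGGCCGTTAAAGGGTTCTAA"
        res = kaks_for_pair(a, a)
        assert res.n_codons == 6 and res.ratio is None


# ---------------------------------------------------------------------------
# TAI / TDI
# ---------------------------------------------------------------------------

def expr_frame(values, tissues=("leaf", "pollen")):
    return pd.DataFrame(values, index=[f"g{i}" for i in range(len(values))],
                        columns=list(tissues), dtype=float)


class TestTaiTdi:
    def test_constant_ps_returns_that_ps_exactly(self):
        expr = expr_frame([[1, 9], [4, 2], [7, 3]])
        tai = compute_tai(expr, {"g0": 4, "g1": 4, "g2": 4})
        assert (tai == 4).all()

    def test_equal_expression_ps1_ps13_gives_seven(self):
        expr = expr_frame([[5, 2], [5, 2]])
        tai = compute_tai(expr, {"g0": 1, "g1": 13})
        assert (tai == 7).all()

    def test_rescaling_invariance(self):
        rng = np.random.default_rng(12)
        expr = expr_frame(rng.uniform(0.1, 10, size=(30, 2)))
        ps = {f"g{i}": int(rng.integers(1, 14)) for i in range(30)}
        tai = compute_tai(expr, ps)
        scaled = expr.copy()
        scaled["pollen"] *= 137.5
        tai2 = compute_tai(scaled, ps)
        assert abs(tai["pollen"] - tai2["pollen"]) < 1e-12
        assert abs(tai["leaf"] - tai2["leaf"]) < 1e-12

    def test_bounded_by_input_range(self):
        rng = np.random.default_rng(14)
        expr = expr_frame(rng.uniform(0, 5, size=(20, 2)))
        ps = {f"g{i}": int(rng.integers(2, 9)) for i in range(20)}
        tai = compute_tai(expr, ps)
        assert ((tai >= 2) & (tai <= 8)).all()

    def test_expressed_gene_without_ps_raises(self):
        expr = expr_frame([[1, 1], [2, 2]])
        with pytest.raises(ValueError, match="phylostratum"):
            compute_tai(expr, {"g0": 1})

    def test_all_zero_tissue_raises(self):
        expr = expr_frame([[1, 0], [2, 0]])
        with pytest.raises(ValueError, match="all-zero"):
            compute_tai(expr, {"g0": 1, "g1": 2})

    def test_tdi_weighted_mean(self):
        expr = expr_frame([[3, 1], [1, 3]])
        tdi = compute_tdi(expr, {"g0": 0.1, "g1": 0.9})
        assert tdi["leaf"] == pytest.approx(0.3)
        assert tdi["pollen"] == pytest.approx(0.7)

    def test_tdi_constant_ratio(self):
        expr = expr_frame([[1, 2], [5, 1]])
        tdi = compute_tdi(expr, {"g0": 0.5, "g1": 0.5})
        assert (tdi == 0.5).all()

    def test_undefined_ratios_excluded_not_imputed(self):
        expr = expr_frame([[3, 1], [1, 3], [10, 10]])
        tdi = compute_tdi(expr, {"g0": 0.1, "g1": 0.9, "g2": None})
        assert tdi["leaf"] == pytest.approx(0.3)

    def test_no_defined_ratio_raises(self):
        with pytest.raises(ValueError):
            compute_tdi(expr_frame([[1, 1]]), {"g0": None})


class TestPlantedEvolutionRecovery:
    def test_pollen_has_max_tai(self, truth_default):
        truth = truth_default
        for sp in ("a", "b"):
            profiles = assign_phylostrata(truth.phylostrata[sp])
            ps = {p.gene_id: p.ps for p in profiles}
            tai = compute_tai(truth.gene_expression[sp], ps)
            assert tai.idxmax() == "pollen"
            # young-gene pollen bias shows directly in the matrix
            young = [g for g, v in ps.items() if v >= 11]
            expr = truth.gene_expression[sp]
            assert expr.loc[young, "pollen"].mean() > expr.loc[young, "leaf"].mean()

    def test_old_genes_longer_orfs_more_isoforms(self, truth_default):
        iso = truth_default.isoforms
        b = iso[iso.species == "b"]
        old = b[b.age == "old"]
        young = b[b.age == "young"]
        assert old.orf_len.median() > young.orf_len.median()
        assert (old.groupby("gene_id").size().mean()
                > young.groupby("gene_id").size().mean())

    def test_kaks_recovery_and_tai_tdi_coupling(self, truth_default):
        """Estimated ratios track the planted age-dependent targets, and
        TDI correlates positively with TAI across tissues."""
        truth = truth_default
        orth = truth.orthologs
        sub = orth.groupby("age").head(12)
        ratios = {}
        for row in sub.itertuples():
            res = kaks_for_pair(truth.cds["a"][row.gene_a],
                                truth.cds["b"][row.gene_b])
            if res.ratio is not None:
                ratios[row.gene_a] = (row.age, res.ratio, row.target_kaks)
        by_age = {}
        for age, est, _ in ratios.values():
            by_age.setdefault(age, []).append(est)
        assert np.mean(by_age["young"]) > np.mean(by_age["old"])
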