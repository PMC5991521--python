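"""AS event enumeration (six types), PSI, activity Z-scores, conservation."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from isoscape.io_core import GeneModel, TranscriptModel
from isoscape.splicing import (
    compute_psi,
    conserved_events,
    conserved_isoforms,
    enumerate_as_events,
    event_architecture,
    psi_table,
    psi_zscores,
    splicing_activity,
)


def gene(transcript_exons, strand="+", gene_id="g", chrom="chr1"):
    models = [
        TranscriptModel(f"{gene_id}.t{i}", gene_id, chrom, strand,
                        tuple(sorted(ex)))
        for i, ex in enumerate(transcript_exons)
    ]
    return GeneModel(gene_id, chrom, strand, models)


# ---------------------------------------------------------------------------
# Independent oracle: enumerate events in transcription orientation
# ---------------------------------------------------------------------------

def _mirror(exons, m):
    return tuple(sorted((m - e, m - s) for s, e in exons))


def oracle_events(g: GeneModel) -> set:
    """Enumerate events on the transcription ('+'-oriented) image of the
    gene, then map coordinates back to genomic space.  Independent of the
    implementation's strand logic."""
    m = max(t.end for t in g.transcripts) + 17
    if g.strand == "-":
        chains = [_mirror(t.exons, m) for t in g.transcripts]
    else:
        chains = [t.exons for t in g.transcripts]

    def introns(exons):
        return [(a[1], b[0]) for a, b in zip(exons, exons[1:])]

    keys = set()
    for ea, eb in combinations(chains, 2):
        ia, ib = introns(ea), introns(eb)
        for x_ex, x_in, y_ex, y_in in ((ea, ia, eb, ib), (eb, ib, ea, ia)):
            for s, e in x_in:  # intron retention: intron exonic in the other
                if any(es < s and e < ee for es, ee in y_ex):
                    keys.add(("IR", (s, e)))
            for k in range(1, len(x_ex) - 1):  # exon skipping
                s, e = x_ex[k]
                d1, d2 = x_ex[k - 1][1], x_ex[k + 1][0]
                if (d1, d2) in y_in:
                    keys.add(("ES", (d1, s, e, d2)))
        for s1, e1 in ia:
            for s2, e2 in ib:
                if e1 == e2 and s1 != s2:
                    # variable donor side (5' in transcription orientation)
                    xa = next(x for x in ea if x[1] == s1)
                    xb = next(x for x in eb if x[1] == s2)
                    disjoint = min(xa[1], xb[1]) <= max(xa[0], xb[0])
                    first = xa == ea[0] and xb == eb[0] and \
                        ia[0] == (s1, e1) and ib[0] == (s2, e2)
                    if first and disjoint:
                        keys.add(("AF", ("L", min(s1, s2), max(s1, s2), e1)))
                    elif not disjoint:
                        keys.add(("A5", ("L", min(s1, s2), max(s1, s2), e1)))
                if s1 == s2 and e1 != e2:
                    xa = next(x for x in ea if x[0] == e1)
                    xb = next(x for x in eb if x[0] == e2)
                    disjoint = min(xa[1], xb[1]) <= max(xa[0], xb[0])
                    last = xa == ea[-1] and xb == eb[-1] and \
                        ia[-1] == (s1, e1) and ib[-1] == (s2, e2)
                    if last and disjoint:
                        keys.add(("AL", ("R", s1, min(e1, e2), max(e1, e2))))
                    elif not disjoint:
                        keys.add(("A3", ("R", s1, min(e1, e2), max(e1, e2))))

    if g.strand == "+":
        return keys
    # map back to genomic coordinates; A5<->A3 and AF<->AL labels flip with
    # the side marker
    flip = {"A5": "A3", "A3": "A5", "AF": "AL", "AL": "AF"}
    out = set()
    for etype, coords in keys:
        if etype == "IR":
            s, e = coords
            out.add(("IR", (m - e, m - s)))
        elif etype == "ES":
            d1, s, e, d2 = coords
            out.add(("ES", (m - d2, m - e, m - s, m - d1)))
        else:
            side, a, b, c = coords
            if side == "L":
                mapped = ("R", m - c, m - b, m - a)
            else:
                mapped = ("L", m - c, m - b, m - a)
            genomic_type = {"A5": "A5", "A3": "A3", "AF": "AF", "AL": "AL"}[etype]
            # the oracle labelled in transcription orientation, which is what
            # the implementation reports too; only coordinates mirror
            out.add((genomic_type, mapped))
    return out


def random_gene(rng, strand, max_tx=4, max_exons=6):
    """A gene whose transcripts are structured perturbations of a master."""
    n_exons = int(rng.integers(3, max_exons + 1))
    pos = int(rng.integers(0, 50)) + 300
    master = []
    for _ in range(n_exons):
        length = int(rng.integers(60, 180))
        master.append((pos, pos + length))
        pos += length + int(rng.integers(60, 160))
    transcripts = [list(master)]
    for _ in range(int(rng.integers(1, max_tx))):
        ex = [list(e) for e in master]
        op = rng.choice(["skip", "donor", "acceptor", "retain", "first", "last"])
        if op == "skip" and len(ex) >= 3:
            del ex[int(rng.integers(1, len(ex) - 1))]
        elif op == "donor" and len(ex) >= 2:
            k = int(rng.integers(0, len(ex) - 1))
            ex[k][1] -= int(rng.integers(5, 40))
        elif op == "acceptor" and len(ex) >= 2:
            k = int(rng.integers(1, len(ex)))
            ex[k][0] += int(rng.integers(5, 40))
        elif op == "retain" and len(ex) >= 2:
            k = int(rng.integers(0, len(ex) - 1))
            ex[k] = [ex[k][0], ex[k + 1][1]]
            del ex[k + 1]
        elif op == "first" and len(ex) >= 2:
            length = int(rng.integers(40, 100))
            start = master[0][0] - int(rng.integers(120, 280))
            ex[0] = [start, start + length]
        elif op == "last" and len(ex) >= 2:
            length = int(rng.integers(40, 100))
            start = master[-1][1] + int(rng.integers(50, 200))
            ex[-1] = [start, start + length]
        exons = [tuple(e) for e in ex]
        if all(b[0] > a[1] for a, b in zip(exons, exons[1:])):
            transcripts.append(exons)
    return gene(transcripts, strand=strand)


class TestEnumerateEvents:
    def test_single_transcript_yields_no_events(self):
        g = gene([[(0, 100), (200, 300)]])
        assert enumerate_as_events(g) == []

    def test_exon_skipping_hand_constructed(self):
        """B lacks internal exon [300,400) of A, sharing introns (200,300)
        and (400,500)."""
        g = gene([
            [(100, 200), (300, 400), (500, 600)],
            [(100, 200), (500, 600)],
        ])
        events = enumerate_as_events(g)
        assert len(events) == 1
        ev = events[0]
        assert ev.type == "ES"
        assert ev.coords == (200, 300, 400, 500)
        assert ev.inclusion_transcripts == {"g.t0"}
        assert ev.exclusion_transcripts == {"g.t1"}

    def test_intron_retention(self):
        g = gene([
            [(100, 200), (300, 400)],
            [(100, 400)],
        ])
        (ev,) = enumerate_as_events(g)
        assert ev.type == "IR" and ev.coords == (200, 300)
        assert ev.inclusion_transcripts == {"g.t1"}  # retained form

    def test_alt_donor_becomes_a3_on_minus_strand(self):
        exons_a = [(100, 200), (300, 400)]
        exons_b = [(100, 180), (300, 400)]
        (plus_ev,) = enumerate_as_events(gene([exons_a, exons_b], strand="+"))
        (minus_ev,) = enumerate_as_events(gene([exons_a, exons_b], strand="-"))
        assert plus_ev.type == "A5"
        assert minus_ev.type == "A3"

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_matches_transcription_orientation_oracle(self, strand):
        """Enumeration equals an independent oracle computed on the
        '+'-oriented image of each gene (sweep over random gene models with
        <=4 transcripts, <=6 exons)."""
        rng = np.random.default_rng(17 if strand == "+" else 23)
        for _ in range(150):
            g = random_gene(rng, strand)
            got = {(e.type, e.coords) for e in enumerate_as_events(g)}
            assert got == oracle_events(g)

    def test_strand_flip_swaps_a5_a3_and_af_al(self):
        """Placing the same exon structures on the opposite strand swaps
        A5<->A3 and AF<->AL labels and preserves ES/IR counts."""
        rng = np.random.default_rng(99)
        swap = {"A5": "A3", "A3": "A5", "AF": "AL", "AL": "AF",
                "ES": "ES", "IR": "IR"}
        for _ in range(60):
            g = random_gene(rng, "+")
            flipped = gene([t.exons for t in g.transcripts], strand="-")
            counts = lambda evs: pd.Series(
                [e.type for e in evs]).value_counts().to_dict()
            a = counts(enumerate_as_events(g))
            b = counts(enumerate_as_events(flipped))
            assert a == {swap[k]: v for k, v in b.items()}

    def test_ir_heavy_al_light_mix_under_study_conditions(self, truth_default):
        """With the default event mix, IR is the most and AL the least
        frequent planted type in both species."""
        for sp in ("a", "b"):
            counts = truth_default.events[
                truth_default.events.species == sp].type.value_counts()
            assert counts.idxmax() == "IR"
            assert counts.idxmin() == "AL"

    def test_truth_consistency_on_synthetic_genes(self, truth_small):
        """Every planted AS event is recovered by enumerating the emitted
        truth isoforms, with matching type and ordinal."""
        truth = truth_small
        for sp in ("a", "b"):
            tx = truth.transcripts[sp]
            by_gene = {}
            for m in tx.values():
                by_gene.setdefault(m.gene_id, []).append(m)
            planted = truth.events[truth.events.species == sp]
            for row in planted.itertuples():
                models = by_gene[row.gene_id]
                g = GeneModel(row.gene_id, models[0].chrom, models[0].strand,
                              models)
                events = enumerate_as_events(g)
                assert len(events) == 1
                sig = event_architecture(events[0], tx)
                assert sig == (row.type, row.ordinal)


# ---------------------------------------------------------------------------
# PSI and activity
# ---------------------------------------------------------------------------

def two_form_gene():
    return gene([
        [(100, 200), (300, 400), (500, 600)],
        [(100, 200), (500, 600)],
    ])


class TestPsi:
    def expr(self, inc, exc):
        return pd.DataFrame({"leaf": [inc, exc]}, index=["g.t0", "g.t1"],
                            dtype=float)

    def test_values(self):
        (ev,) = enumerate_as_events(two_form_gene())
        assert compute_psi(ev, self.expr(0, 5), "leaf").psi == 0
        assert compute_psi(ev, self.expr(3, 1), "leaf").psi == 0.75
        assert compute_psi(ev, self.expr(2, 0), "leaf").psi == 1

    def test_zero_total_flagged_undefined(self):
        (ev,) = enumerate_as_events(two_form_gene())
        rec = compute_psi(ev, self.expr(0, 0), "leaf")
        assert rec.psi is None and not rec.defined

    def test_missing_transcript_raises(self):
        (ev,) = enumerate_as_events(two_form_gene())
        with pytest.raises(KeyError):
            compute_psi(ev, pd.DataFrame({"leaf": [1.0]}, index=["g.t0"]),
                        "leaf")

    def test_complement_property(self):
        """PSI(inclusion) + PSI(exclusion) = 1 for a binary event."""
        rng = np.random.default_rng(4)
        (ev,) = enumerate_as_events(two_form_gene())
        for _ in range(20):
            e = self.expr(rng.uniform(0.1, 9), rng.uniform(0.1, 9))
            p_inc = compute_psi(ev, e, "leaf").psi
            flipped = type(ev)(
                ev.event_id + "_flip", ev.gene_id, ev.type, ev.coords,
                ev.exclusion_transcripts, ev.inclusion_transcripts)
            p_exc = compute_psi(flipped, e, "leaf").psi
            assert p_inc + p_exc == pytest.approx(1.0)


class TestActivity:
    def test_single_event_zscores_sample_sd(self):
        psi = pd.DataFrame([[0.0, 0.0, 1.0]], index=["e1"],
                           columns=["t1", "t2", "t3"])
        z = psi_zscores(psi)
        assert np.allclose(z.loc["e1"], [-0.57735, -0.57735, 1.15470],
                           atol=1e-4)
        activity, _ = splicing_activity(psi)
        assert activity.idxmax() == "t3"

    def test_zero_variance_events_dropped(self):
        psi = pd.DataFrame([[0.5, 0.5, 0.5]], index=["e1"],
                           columns=["t1", "t2", "t3"])
        activity, _ = splicing_activity(psi)
        assert len(activity) == 0 or activity.isna().all()

    def test_fewer_than_two_tissues_raises(self):
        with pytest.raises(ValueError):
            psi_zscores(pd.DataFrame([[0.5]], index=["e"], columns=["t"]))

    def test_zscore_rows_sum_to_zero(self):
        rng = np.random.default_rng(8)
        psi = pd.DataFrame(rng.uniform(size=(10, 5)),
                           columns=list("abcde"))
        z = psi_zscores(psi)
        assert np.allclose(z.sum(axis=1), 0, atol=1e-10)


# ---------------------------------------------------------------------------
# Conservation
# ---------------------------------------------------------------------------

class TestConservedEvents:
    def make_pair(self, ordinal_a, ordinal_b):
        """Two orthologous 4-exon genes with an IR event at given introns."""
        genes = []
        for name, k in (("ga", ordinal_a), ("gb", ordinal_b)):
            master = [(100, 200), (300, 400), (500, 600), (700, 800)]
            retained = list(master)
            retained[k] = (master[k][0], master[k + 1][1])
            del retained[k + 1]
            genes.append(gene([master, retained], gene_id=name))
        return genes

    def test_same_intron_ordinal_is_conserved(self):
        ga, gb = self.make_pair(1, 1)
        ev_a, ev_b = enumerate_as_events(ga), enumerate_as_events(gb)
        tx_a = {t.transcript_id: t for t in ga.transcripts}
        tx_b = {t.transcript_id: t for t in gb.transcripts}
        matched = conserved_events(ev_a, ev_b, [("ga", "gb")], tx_a, tx_b)
        assert len(matched) == 1

    def test_different_intron_ordinal_not_conserved(self):
        ga, gb = self.make_pair(0, 2)
        matched = conserved_events(
            enumerate_as_events(ga), enumerate_as_events(gb), [("ga", "gb")],
            {t.transcript_id: t for t in ga.transcripts},
            {t.transcript_id: t for t in gb.transcripts})
        assert matched == []


class TestConservedIsoforms:
    def test_identical_sequences_conserved(self):
        ok, cov, ident = conserved_isoforms("ACGT" * 50, "ACGT" * 50)
        assert ok and cov == 1.0 and ident == 1.0

    def test_thirty_percent_substitution_not_conserved(self):
        rng = np.random.default_rng(2)
        seq = "".join(rng.choice(list("ACGT"), size=300))
        mutated = list(seq)
        pos = rng.choice(300, size=90, replace=False)  # 30% substituted
        for p in pos:
            mutated[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[p]]
        ok, cov, ident = conserved_isoforms(seq, "".join(mutated))
        assert not ok
        assert ident == pytest.approx(0.70, abs=0.02)

    def test_central_fragment_full_coverage(self):
        rng = np.random.default_rng(6)
        seq = "".join(rng.choice(list("ACGT"), size=1000))
        frag = seq[200:800]
        ok, cov, ident = conserved_isoforms(seq, frag)
        assert ok and cov == 1.0 and ident == 1.0

    def test_verdict_symmetric(self):
        rng = np.random.default_rng(9)
        a = "".join(rng.choice(list("ACGT"), size=400))
        b = a[:150] + "".join(rng.choice(list("ACGT"), size=100)) + a[250:]
        assert conserved_isoforms(a, b)[0] == conserved_isoforms(b, a)[0]

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            conserved_isoforms("", "ACGT")
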