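import random

import pytest

from slseeker.records import SequenceRecord, revcomp
from slseeker.simulate import _gene_strand_seq, _to_local
from slseeker.validate import (
    GeneModel,
    locate_acceptor,
    decide_cis_trans,
    count_introns,
    excise,
    virtual_pcr,
    evidence_report,
)


def _rand(n, rng):
    return "".join(rng.choice("ACGT") for _ in range(n))


def _gene_local(ds, row):
    seq = _gene_strand_seq(ds.contig_by_id[row.contig], row.strand)
    L = len(ds.contig_by_id[row.contig])
    loc = lambda p: _to_local(p, row.strand, L)
    return seq, loc


def _mature_tx(ds, gene_id):
    return next(
        t for t in ds.transcripts
        if t.id.startswith(f"tx_{gene_id}_") and t.meta["kind"] == "mature_trans"
    )


class TestLocateAcceptor:
    def test_noiseless_genes_all_called_at_truth(self, default_noiseless):
        ds = default_noiseless
        leader = ds.cfg.sl_exon
        for row in ds.truth.genes.itertuples():
            seq, loc = _gene_local(ds, row)
            model = GeneModel(
                SequenceRecord(row.contig, seq), loc(row.atg_pos),
                mrna=_mature_tx(ds, row.gene_id),
            )
            call = locate_acceptor(model, leader)
            assert call.acceptor_index == loc(row.acceptor_pos)
            assert call.verdict == "trans"
            assert call.pyrimidine_tracts  # outron tract detected
            # ATG-relative coordinate convention: acceptor upstream => negative
            assert call.acceptor_rel < 0

    def test_mutated_acceptor_ag_gives_indeterminate(self, default_noiseless):
        ds = default_noiseless
        row = ds.truth.genes.iloc[0]
        seq, loc = _gene_local(ds, row)
        acc = loc(row.acceptor_pos)
        mutated = seq[: acc - 1] + "C" + seq[acc:]  # AG -> AC
        model = GeneModel(SequenceRecord("m", mutated), loc(row.atg_pos),
                          mrna=_mature_tx(ds, row.gene_id))
        call = locate_acceptor(model, ds.cfg.sl_exon)
        assert call.verdict == "indeterminate"
        assert any("not AG" in n for n in call.notes)

    def test_leaderless_mrna_rejected(self, default_noiseless):
        ds = default_noiseless
        row = ds.truth.genes.iloc[0]
        seq, loc = _gene_local(ds, row)
        rng = random.Random(0)
        model = GeneModel(SequenceRecord("m", seq), loc(row.atg_pos),
                          mrna=SequenceRecord("x", _rand(200, rng)))
        with pytest.raises(ValueError, match="not leader-bearing"):
            locate_acceptor(model, ds.cfg.sl_exon)


class TestDecideCisTrans:
    def test_leader_planted_upstream_gives_cis_possible(self, default_noiseless):
        ds = default_noiseless
        row = ds.truth.genes.iloc[1]
        seq, loc = _gene_local(ds, row)
        acc = loc(row.acceptor_pos)
        leader = ds.cfg.sl_exon
        # adversarial genome: a leader copy sits upstream of the acceptor
        doctored = leader + seq
        model = GeneModel(SequenceRecord("m", doctored), loc(row.atg_pos) + len(leader),
                          mrna=_mature_tx(ds, row.gene_id))
        call = locate_acceptor(model, leader)
        assert call.verdict == "cis_possible"

    def test_no_capped_reads_notes_missing_tss_evidence(self, default_noiseless):
        ds = default_noiseless
        row = ds.truth.genes.iloc[2]
        seq, loc = _gene_local(ds, row)
        notes = []
        verdict = decide_cis_trans(
            GeneModel(SequenceRecord("m", seq), loc(row.atg_pos)),
            ds.cfg.sl_exon, loc(row.acceptor_pos), notes=notes,
        )
        assert verdict == "trans"
        assert any("TSS evidence absent" in n for n in notes)

    def test_capped_reads_confirm_trans(self, default_noiseless):
        ds = default_noiseless
        row = ds.truth.genes.iloc[3]
        seq, loc = _gene_local(ds, row)
        tss = loc(row.tss_pos)
        reads = [SequenceRecord(f"c{i}", seq[tss - 1 : tss - 1 + 100])
                 for i in range(5)]
        model = GeneModel(SequenceRecord("m", seq), loc(row.atg_pos),
                          mrna=_mature_tx(ds, row.gene_id), capped_reads=reads)
        call = locate_acceptor(model, ds.cfg.sl_exon)
        assert call.verdict == "trans"

    def test_upstream_start_evidence_gives_indeterminate(self, default_noiseless):
        ds = default_noiseless
        row = ds.truth.genes.iloc[4]
        seq, loc = _gene_local(ds, row)
        tss = loc(row.tss_pos)
        reads = [SequenceRecord(f"c{i}", seq[tss - 1 : tss + 99]) for i in range(4)]
        # one read starts far upstream of the outron TSS cluster
        reads.append(SequenceRecord("up", seq[max(0, tss - 80) : tss + 40]))
        model = GeneModel(SequenceRecord("m", seq), loc(row.atg_pos),
                          mrna=_mature_tx(ds, row.gene_id), capped_reads=reads)
        call = locate_acceptor(model, ds.cfg.sl_exon)
        assert call.verdict == "indeterminate"


class TestCountIntrons:
    def test_simulated_two_intron_genes(self, default_noiseless):
        ds = default_noiseless
        ll = ds.truth.transcripts.set_index("tx_id").leader_len
        for row in ds.truth.genes.itertuples():
            seq, loc = _gene_local(ds, row)
            tx = _mature_tx(ds, row.gene_id)
            body = tx.seq[int(ll[tx.id]) : -ds.cfg.polya_tail_length]
            found = count_introns(SequenceRecord("g", seq), SequenceRecord("c", body))
            expected = sorted(
                tuple(sorted((loc(int(s)), loc(int(e)))))
                for s, e in (p.split("-") for p in row.introns.split(";"))
            )
            assert found == expected
            for s, e in found:
                assert seq[s - 1 : s + 1] == "GT" and seq[e - 2 : e] == "AG"

    def test_intervals_disjoint_ordered_and_reconstruct_cdna(self, default_noiseless):
        ds = default_noiseless
        row = ds.truth.genes.iloc[5]
        seq, loc = _gene_local(ds, row)
        tx = _mature_tx(ds, row.gene_id)
        ll = int(ds.truth.transcripts.set_index("tx_id").leader_len[tx.id])
        body = tx.seq[ll : -ds.cfg.polya_tail_length]
        found = count_introns(SequenceRecord("g", seq), SequenceRecord("c", body))
        for (s1, e1), (s2, e2) in zip(found, found[1:]):
            assert e1 < s2
        assert body in excise(seq, found)

    def test_intronless_gene_empty(self):
        rng = random.Random(1)
        exon = _rand(400, rng)
        assert count_introns(SequenceRecord("g", exon),
                             SequenceRecord("c", exon[50:350])) == []

    def test_no_shared_anchor_errors(self):
        rng = random.Random(2)
        with pytest.raises(ValueError, match="no alignment"):
            count_introns(SequenceRecord("g", _rand(300, rng)),
                          SequenceRecord("c", _rand(200, rng)))


class TestVirtualPCR:
    def _brute(self, seq, fwd, rev, max_product):
        """All-pairs enumeration oracle."""
        rc = revcomp(rev)
        fs = [i for i in range(len(seq) - len(fwd) + 1)
              if seq[i : i + len(fwd)] == fwd]
        rs = [i for i in range(len(seq) - len(rc) + 1)
              if seq[i : i + len(rc)] == rc]
        out = []
        for f in fs:
            for r in rs:
                start, end = f + 1, r + len(rc)
                if start < end and end - start + 1 <= max_product and f + len(fwd) <= end:
                    out.append((start, end, end - start + 1))
        return sorted(out)

    def test_agrees_with_brute_force_on_random_templates(self):
        rng = random.Random(3)
        for _ in range(200):
            seq = _rand(2000, rng)
            # draw primers from the template to guarantee occasional products
            f0 = rng.randint(0, 900)
            r0 = rng.randint(f0, 1960)
            fwd = seq[f0 : f0 + 20]
            rev = revcomp(seq[r0 : r0 + 20])
            t = SequenceRecord("t", seq)
            res = virtual_pcr(t, fwd, rev, max_product=1500)
            assert res.products == self._brute(seq, fwd, rev, 1500)

    def test_primer_matching_nowhere_absent(self):
        rng = random.Random(4)
        res = virtual_pcr(SequenceRecord("t", _rand(500, rng)),
                          "A" * 20, "C" * 20)
        assert res.products == [] and not res.present

    def test_short_primer_rejected(self):
        with pytest.raises(ValueError, match="15"):
            virtual_pcr(SequenceRecord("t", "ACGT" * 30), "ACGTACGT", "A" * 20)

    def test_fig2c_pattern_on_simulated_gene(self, default_noiseless):
        """Leader-junction pair amplifies only cDNA; upstream-of-TSS pair
        amplifies only genomic DNA; outron pair needs premature cDNA."""
        ds = default_noiseless
        row = ds.truth.genes.iloc[0]
        seq, loc = _gene_local(ds, row)
        tss, cleav = loc(row.tss_pos), loc(row.cleavage_pos)
        tx = _mature_tx(ds, row.gene_id)
        a = ds.cfg.sl_exon[10:30]                 # in the leader
        b = seq[tss + 19 : tss + 39]              # outron, downstream of TSS
        c = seq[tss - 41 : tss - 21]              # upstream of TSS
        d = revcomp(seq[cleav - 45 : cleav - 25])  # 3' UTR (single exon)
        genomic = SequenceRecord("genomic", seq)
        cdna = SequenceRecord("cdna", tx.seq)
        assert not virtual_pcr(genomic, a, d, "a-d").present
        assert virtual_pcr(cdna, a, d, "a-d").present
        assert virtual_pcr(genomic, b, d, "b-d").present
        assert not virtual_pcr(cdna, b, d, "b-d").present
        assert virtual_pcr(genomic, c, d, "c-d").present
        assert not virtual_pcr(cdna, c, d, "c-d").present


class TestEvidenceReport:
    def test_one_row_per_gene_with_verdicts(self, default_noiseless):
        ds = default_noiseless
        leader = ds.cfg.sl_exon
        calls, introns = {}, {}
        ll = ds.truth.transcripts.set_index("tx_id").leader_len
        for row in ds.truth.genes.itertuples():
            seq, loc = _gene_local(ds, row)
            tx = _mature_tx(ds, row.gene_id)
            model = GeneModel(SequenceRecord(row.contig, seq), loc(row.atg_pos),
                              mrna=tx)
            calls[row.gene_id] = locate_acceptor(model, leader)
            body = tx.seq[int(ll[tx.id]) : -ds.cfg.polya_tail_length]
            introns[row.gene_id] = count_introns(
                SequenceRecord("g", seq), SequenceRecord("c", body)
            )
        df = evidence_report(calls, introns, {})
        assert len(df) == len(ds.truth.genes)
        assert set(df.verdict) == {"trans"}
        assert set(df.n_introns) == {2}

    def test_gene_without_leader_bearing_mrna(self):
        df = evidence_report({"gene_x": None}, {}, {})
        assert df.iloc[0].verdict == "not_trans_spliced"

    def test_empty_input_gives_empty_frame(self):
        assert len(evidence_report({}, {}, {})) == 0
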