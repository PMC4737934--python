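"""Read processing: demultiplex, merge, filter, chimera, parse, collapse."""

import numpy as np
import pytest

from epicpcr.construct import FusionConstructSpec
from epicpcr.iupac import reverse_complement
from epicpcr.readproc import (
    CollapsedPair,
    MergedRead,
    ParsedFusion,
    Rejection,
    collapse_barcode_pairs,
    demultiplex,
    dereplicate,
    detect_chimeras,
    merge_pairs,
    quality_filter,
    trim_v4,
    validate_structure,
)
from epicpcr.simulate import SimConfig, SimReadPair, simulate_experiment


def _pair(read_id, r1, r2, q=38):
    return SimReadPair(
        read_id=read_id,
        sample_id="",
        r1_seq=r1,
        r1_qual=np.full(len(r1), q, dtype=np.int16),
        r2_seq=r2,
        r2_qual=np.full(len(r2), q, dtype=np.int16),
    )


class TestDemultiplex:
    TABLE = {"A": "ACGTACGT", "B": "TGCATGCA"}

    def test_exact_match_assigned(self):
        pairs = [_pair("r1", "ACGTACGT" + "G" * 30, "C" * 30)]
        out = demultiplex(pairs, self.TABLE)
        assert len(out["A"]) == 1
        assert out["A"][0].r1_seq == "G" * 30  # barcode stripped

    def test_two_mismatches_unassigned_at_max_one(self):
        r1 = "TCGTACGA" + "G" * 30  # 2 subs vs A, worse vs B
        out = demultiplex([_pair("r1", r1, "C" * 30)], self.TABLE, max_mm=1)
        assert len(out["unassigned"]) == 1

    def test_duplicate_barcodes_rejected(self):
        with pytest.raises(ValueError):
            demultiplex([], {"A": "ACGT", "B": "ACGT"})

    def test_two_sample_counts_match_truth(self, community):
        runs = {}
        for sample, (seed, bc) in {
            "S2m": (41, "ACGTGACT"),
            "S21m": (42, "TGACTCGA"),
        }.items():
            cfg = SimConfig(
                seed=seed, n_droplets=400, assay="target16s",
                sample_id=sample, sample_barcode=bc,
            )
            runs[sample] = simulate_experiment(community, cfg)
        pairs = runs["S2m"].read_pairs + runs["S21m"].read_pairs
        out = demultiplex(pairs, {"S2m": "ACGTGACT", "S21m": "TGACTCGA"})
        for sample in ("S2m", "S21m"):
            assert len(out[sample]) == len(runs[sample].read_pairs)
        assert not out["unassigned"]


class TestMergePairs:
    def test_error_free_pair_reconstructs_amplicon(self):
        rng = np.random.default_rng(0)
        amp = "".join(rng.choice(list("ACGT"), 120))
        r1, r2 = amp[:80], reverse_complement(amp)[:80]
        m = merge_pairs(r1, np.full(80, 38), r2, np.full(80, 38), read_id="r")
        assert isinstance(m, MergedRead)
        assert m.seq == amp

    def test_non_overlapping_rejected(self):
        rng = np.random.default_rng(1)
        a = "".join(rng.choice(list("ACGT"), 60))
        b = "".join(rng.choice(list("ACGT"), 60))
        m = merge_pairs(a, np.full(60, 38), b, np.full(60, 38), read_id="r")
        assert isinstance(m, Rejection) and m.reason == "no_overlap"

    def test_disagreement_resolves_to_higher_quality(self):
        amp = "ACGTACGTACGTACGTACGTACGTACGTACGT"  # 32 bp
        r1 = amp
        r2_src = list(amp)
        r2_src[10] = "T" if amp[10] != "T" else "A"
        r2 = reverse_complement("".join(r2_src))
        q_hi, q_lo = np.full(32, 40), np.full(32, 10)
        m = merge_pairs(r1, q_hi, r2, q_lo, read_id="r", min_overlap=10)
        assert m.seq[10] == amp[10]  # forward (high-Q) wins
        m2 = merge_pairs(r1, q_lo, r2, q_hi, read_id="r", min_overlap=10)
        assert m2.seq[10] == "".join(r2_src)[10]  # reverse (high-Q) wins


class TestQualityFilter:
    def test_high_quality_kept(self):
        assert quality_filter(MergedRead("r", "ACGT", np.full(4, 40)))

    def test_low_quality_discarded(self):
        assert not quality_filter(MergedRead("r", "ACGT", np.full(4, 10)))

    def test_ambiguous_bases_discarded(self):
        assert not quality_filter(MergedRead("r", "ACNT", np.full(4, 40)))

    def test_degraded_fraction_recovered(self, community):
        frac = 0.10
        cfg = SimConfig(
            seed=55, n_droplets=2000, assay="target16s", degraded_frac=frac,
            subst_error_rate=0.0, chimera_rate=0.0,
        )
        sim = simulate_experiment(community, cfg)
        merged = []
        bclen = len(cfg.sample_barcode)
        for rp in sim.read_pairs:
            m = merge_pairs(
                rp.r1_seq[bclen:], rp.r1_qual[bclen:], rp.r2_seq, rp.r2_qual,
                read_id=rp.read_id,
            )
            if isinstance(m, MergedRead):
                merged.append(m)
        discarded = sum(not quality_filter(m) for m in merged)
        n = len(merged)
        se = np.sqrt(frac * (1 - frac) / n)
        assert abs(discarded / n - frac) < 3 * se


class TestChimeraDetection:
    def test_even_concatenation_flagged(self):
        rng = np.random.default_rng(7)
        a = "".join(rng.choice(list("ACGT"), 120))
        b = "".join(rng.choice(list("ACGT"), 120))
        q = a[:60] + b[60:]
        res = detect_chimeras([("pa", a, 40.0), ("pb", b, 40.0), ("q", q, 10.0)])
        res = res.set_index("seq_id")
        assert bool(res.loc["q", "flagged"])

    def test_parents_not_flagged(self):
        rng = np.random.default_rng(8)
        a = "".join(rng.choice(list("ACGT"), 120))
        b = "".join(rng.choice(list("ACGT"), 120))
        q = a[:60] + b[60:]
        res = detect_chimeras([("pa", a, 40.0), ("pb", b, 40.0), ("q", q, 10.0)])
        res = res.set_index("seq_id")
        assert not res.loc["pa", "flagged"]
        assert not res.loc["pb", "flagged"]

    def test_simulation_benchmark(self, community):
        """Detectable chimeras are recovered; clean reads stay unflagged.

        A crossover that lands within ~5 bases of one parent is
        indistinguishable from that parent under a 2-point divergence
        rule, so recall is measured over chimeras at >= 2% divergence
        from every co-droplet fusion; the false-positive rate is measured
        over reads from droplets with a single fusion species, where no
        genuine composite exists.
        """
        cfg = SimConfig(
            seed=77, n_droplets=3000, assay="barcode16s", chimera_rate=0.05,
            mean_reads_per_droplet=40,
        )
        sim = simulate_experiment(community, cfg)
        bclen = len(cfg.sample_barcode)
        merged = []
        for rp in sim.read_pairs:
            m = merge_pairs(
                rp.r1_seq[bclen:], rp.r1_qual[bclen:], rp.r2_seq, rp.r2_qual,
                read_id=rp.read_id,
            )
            if isinstance(m, MergedRead) and quality_filter(m):
                merged.append(m)
        uniq = dereplicate((m.read_id, m.seq) for m in merged)
        flags = detect_chimeras(uniq).set_index("seq_id")
        id_by_seq = {u[1]: u[0] for u in uniq}
        flagged_seqs = {
            u[1] for u in uniq if bool(flags.loc[u[0], "flagged"])
        }

        fulls_by_d: dict[int, list[str]] = {}
        for a in sim.amplicons:
            if a.klass == "full_fusion":
                fulls_by_d.setdefault(a.droplet_id, []).append(a.seq)

        detectable = hits = 0
        for a in sim.amplicons:
            if a.klass != "chimera" or a.seq not in id_by_seq:
                continue
            L = len(a.seq)
            dmin = int(np.ceil(0.02 * L))
            qarr = np.frombuffer(a.seq.encode(), dtype=np.uint8)
            dists = [
                int((np.frombuffer(s.encode(), dtype=np.uint8) != qarr).sum())
                for s in fulls_by_d[a.droplet_id]
                if len(s) == L
            ]
            if min(dists) >= dmin:
                detectable += 1
                hits += a.seq in flagged_seqs
        assert detectable >= 10
        assert hits / detectable >= 0.8

        # FPR over reads from single-fusion droplets
        single_d = {d for d, fl in fulls_by_d.items() if len(set(fl)) == 1}
        truth = sim.truth.set_index("read_id")
        fp = n = 0
        for m in merged:
            row = truth.loc[m.read_id]
            if row["class"] == "full_fusion" and row["droplet_id"] in single_d:
                n += 1
                fp += m.seq in flagged_seqs
        assert n > 100
        assert fp / n <= 0.02


class TestStructureValidation:
    @pytest.fixture()
    def fusion_read(self, construct, community):
        carrier = next(t for t in community if t.has_target)
        seq = construct.f1 + carrier.target_seq + construct.bridge + carrier.ssu_seq
        return MergedRead("r0", seq, np.full(len(seq), 38), "S1")

    def test_clean_read_parses(self, fusion_read, construct, community):
        carrier = next(t for t in community if t.has_target)
        parsed = validate_structure(fusion_read, construct)
        assert isinstance(parsed, ParsedFusion)
        assert parsed.bridge_mismatches == 0
        assert parsed.target_segment == carrier.target_seq
        assert parsed.ssu_segment == carrier.ssu_seq[: len(parsed.ssu_segment)]

    def test_partial_read_rejected_missing_ssu(self, construct, community):
        carrier = next(t for t in community if t.has_target)
        seq = construct.f1 + carrier.target_seq + construct.bridge
        res = validate_structure(
            MergedRead("r1", seq, np.full(len(seq), 38)), construct
        )
        assert isinstance(res, Rejection) and res.reason == "missing_ssu"

    def test_ssu_only_partial_rejected(self, construct, community):
        seq = community[0].ssu_seq
        res = validate_structure(
            MergedRead("r2", seq, np.full(len(seq), 38)), construct
        )
        assert isinstance(res, Rejection) and res.reason == "f1"

    def test_two_bridge_substitutions_rejected(self, fusion_read, construct):
        seq = list(fusion_read.seq)
        bstart = len(construct.f1) + 60  # bridge position in this construct
        assert fusion_read.seq[bstart : bstart + len(construct.bridge)] == construct.bridge
        for off in (2, 5):
            seq[bstart + off] = "A" if seq[bstart + off] != "A" else "C"
        res = validate_structure(
            MergedRead("r3", "".join(seq), fusion_read.quals), construct,
            max_mm_per_element=1,
        )
        assert isinstance(res, Rejection) and res.reason == "bridge"

    def test_one_bridge_substitution_tolerated(self, fusion_read, construct):
        seq = list(fusion_read.seq)
        bstart = len(construct.f1) + 60
        seq[bstart + 2] = "A" if seq[bstart + 2] != "A" else "C"
        res = validate_structure(
            MergedRead("r4", "".join(seq), fusion_read.quals), construct,
            max_mm_per_element=1,
        )
        assert isinstance(res, ParsedFusion) and res.bridge_mismatches == 1

    def test_barcode_assay_length_check(self, construct, community):
        t = community[0]
        good = construct.f1 + "A" * construct.barcode_len + construct.bridge + t.ssu_seq
        res = validate_structure(
            MergedRead("r5", good, np.full(len(good), 38)), construct,
            assay="barcode16s",
        )
        assert isinstance(res, ParsedFusion) and res.barcode == "A" * 20
        bad = construct.f1 + "A" * 15 + construct.bridge + t.ssu_seq
        res = validate_structure(
            MergedRead("r6", bad, np.full(len(bad), 38)), construct,
            assay="barcode16s",
        )
        assert isinstance(res, Rejection) and res.reason == "barcode_len"


class TestTrimV4:
    def _parsed(self, ssu):
        return ParsedFusion("r", "S1", "T" * 10, ssu, None, 0)

    def test_trims_to_121(self, construct, community):
        res = trim_v4(self._parsed(community[0].ssu_seq), construct)
        assert isinstance(res, ParsedFusion)
        assert len(res.ssu_segment) == 121

    def test_short_span_rejected(self, construct):
        anchor = "GTGCCAGCAGCCGCGGTAA"
        res = trim_v4(self._parsed(anchor + "A" * 100), construct)
        assert isinstance(res, Rejection) and res.reason == "short_ssu"

    def test_anchor_with_one_substitution(self, construct, community):
        ssu = community[0].ssu_seq
        mut = list(ssu)
        mut[3] = "A" if ssu[3] != "A" else "C"  # inside the anchor
        res = trim_v4(self._parsed("".join(mut)), construct)
        assert isinstance(res, ParsedFusion)
        assert res.ssu_segment == ssu[19 : 19 + 121]

    def test_no_anchor_rejected(self, construct):
        res = trim_v4(self._parsed("A" * 200), construct)
        assert isinstance(res, Rejection) and res.reason == "anchor"


class TestCollapse:
    def _pf(self, rid, bc, ssu, q=30.0):
        return ParsedFusion(rid, "S1", bc, ssu, bc, 0, mean_quality=q)

    def test_single_droplet_collapses_to_one(self):
        reads = [self._pf(f"r{i}", "A" * 20, "C" * 121) for i in range(1000)]
        pairs = collapse_barcode_pairs(reads)
        assert len(pairs) == 1
        assert pairs[0].read_count == 1000

    def test_same_taxon_two_barcodes_two_pairs(self):
        reads = [self._pf("r0", "A" * 20, "C" * 121), self._pf("r1", "G" * 20, "C" * 121)]
        assert len(collapse_barcode_pairs(reads)) == 2

    def test_representative_is_best_quality_then_id(self):
        reads = [
            self._pf("r2", "A" * 20, "C" * 121, q=30),
            self._pf("r1", "A" * 20, "C" * 121, q=35),
            self._pf("r0", "A" * 20, "C" * 121, q=35),
        ]
        assert collapse_barcode_pairs(reads)[0].representative_read_id == "r0"

    def test_order_invariance(self):
        rng = np.random.default_rng(3)
        reads = [
            self._pf(f"r{i}", rng.choice(["A" * 20, "G" * 20]), "C" * 121,
                     q=float(rng.integers(20, 40)))
            for i in range(50)
        ]
        fwd = collapse_barcode_pairs(reads)
        rev = collapse_barcode_pairs(reads[::-1])
        assert fwd == rev

    def test_idempotent(self):
        reads = [self._pf(f"r{i}", "A" * 20, "C" * 121) for i in range(5)]
        once = collapse_barcode_pairs(reads)
        again = collapse_barcode_pairs(
            [
                ParsedFusion(c.representative_read_id, "S1", c.barcode,
                             c.ssu_segment, c.barcode, 0)
                for c in once
            ]
        )
        assert [(c.barcode, c.ssu_segment) for c in again] == [
            (c.barcode, c.ssu_segment) for c in once
        ]

    def test_requires_barcode(self):
        with pytest.raises(ValueError):
            collapse_barcode_pairs(
                [ParsedFusion("r", "S1", "T" * 10, "C" * 121, None, 0)]
            )
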