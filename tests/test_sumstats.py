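"""Summary-statistics I/O, instrument selection, clumping, harmonization."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from metabomr.sumstats import (
    DROPPED_INCOMPATIBLE,
    DROPPED_MISSING,
    DROPPED_PALINDROMIC,
    FLIPPED,
    KEPT,
    EmptyInstrumentSetError,
    InstrumentSet,
    SumstatsError,
    harmonize,
    harmonize_multi,
    read_sumstats,
    select_instruments,
    write_sumstats,
)

from conftest import make_record


class TestReadWrite:
    def test_round_trip(self, tmp_path):
        records = [make_record(vid=f"rs{i}", beta=0.1 * i + 0.01) for i in range(3)]
        path = tmp_path / "sumstats.tsv"
        write_sumstats(records, path)
        back = read_sumstats(path)
        assert len(back) == 3
        for a, b in zip(records, back):
            assert a == b

    def test_rejects_bad_se_with_row_number(self, tmp_path):
        df = pd.DataFrame(
            {
                "variant_id": ["rs1", "rs2"],
                "effect_allele": ["A", "A"],
                "other_allele": ["G", "G"],
                "eaf": [0.3, 0.3],
                "beta": [0.1, 0.1],
                "se": [0.01, 0.0],
                "pval": [1e-9, 1e-9],
                "n": [1000, 1000],
                "trait_id": ["t", "t"],
            }
        )
        path = tmp_path / "bad.tsv"
        df.to_csv(path, sep="\t", index=False)
        with pytest.raises(SumstatsError, match="row 1.*se"):
            read_sumstats(path)

    def test_missing_column_and_duplicates(self, tmp_path):
        path = tmp_path / "x.tsv"
        pd.DataFrame({"variant_id": ["rs1"]}).to_csv(path, sep="\t", index=False)
        with pytest.raises(SumstatsError, match="missing mandatory"):
            read_sumstats(path)
        records = [make_record(vid="rs1"), make_record(vid="rs1")]
        write_sumstats(records, path)
        with pytest.raises(SumstatsError, match="duplicate"):
            read_sumstats(path)

    def test_column_map(self, tmp_path):
        path = tmp_path / "mapped.tsv"
        df = pd.DataFrame(
            {
                "SNP": ["rs1"], "effect_allele": ["A"], "other_allele": ["G"],
                "eaf": [0.2], "b": [0.1], "se": [0.01], "pval": [1e-9],
                "n": [500], "trait_id": ["t"],
            }
        )
        df.to_csv(path, sep="\t", index=False)
        recs = read_sumstats(path, column_map={"variant_id": "SNP", "beta": "b"})
        assert recs[0].variant_id == "rs1" and recs[0].beta == 0.1

    def test_indels_rejected(self):
        rec = make_record(ea="AT", oa="G")
        with pytest.raises(SumstatsError, match="single base"):
            rec.validate()


class TestSelectInstruments:
    def test_p_threshold(self):
        records = [
            make_record(vid="rs1", pval=1e-10),
            make_record(vid="rs2", pval=1e-9),
            make_record(vid="rs3", pval=0.01),
        ]
        out = select_instruments(records, 5e-9)
        assert out.variant_ids == ["rs1", "rs2"]

    def test_ld_clump_discards_weaker(self):
        records = [
            make_record(vid="rs1", pval=1e-12),
            make_record(vid="rs2", pval=1e-10),
        ]
        ld = pd.DataFrame({"id_a": ["rs1"], "id_b": ["rs2"], "r2": [0.5]})
        out = select_instruments(records, 5e-8, ld_info=ld, r2_threshold=0.001)
        assert out.variant_ids == ["rs1"]

    def test_mean_f(self):
        records = [
            make_record(vid="rs1", beta=0.06, se=0.01),
            make_record(vid="rs2", beta=0.08, se=0.01),
        ]
        out = select_instruments(records, 1.0)
        assert out.mean_f == pytest.approx(50.0)  # (36 + 64) / 2

    def test_empty_is_explicit(self):
        records = [make_record(pval=0.5)]
        with pytest.raises(EmptyInstrumentSetError):
            select_instruments(records, 5e-8)
        out = select_instruments(records, 5e-8, allow_empty=True)
        assert len(out) == 0

    def test_greedy_matches_bruteforce_on_small_sets(self, rng):
        """Greedy clumping equals sequential-p maximal-independent-set choice."""
        for trial in range(20):
            n = int(rng.integers(4, 11))
            ids = [f"rs{i}" for i in range(n)]
            pvals = rng.uniform(1e-12, 1e-9, n)
            pairs = list(itertools.combinations(range(n), 2))
            in_ld = rng.random(len(pairs)) < 0.3
            ld = pd.DataFrame(
                {
                    "id_a": [ids[a] for (a, b), f in zip(pairs, in_ld) if f],
                    "id_b": [ids[b] for (a, b), f in zip(pairs, in_ld) if f],
                    "r2": [0.9] * int(in_ld.sum()),
                }
            )
            records = [make_record(vid=i, pval=p) for i, p in zip(ids, pvals)]
            got = select_instruments(records, 1.0, ld_info=ld).variant_ids

            # oracle: walk variants in (p, id) order, keep if independent of kept
            adj = {i: set() for i in ids}
            for a, b in zip(ld["id_a"], ld["id_b"]):
                adj[a].add(b)
                adj[b].add(a)
            kept = []
            for vid in sorted(ids, key=lambda v: (pvals[ids.index(v)], v)):
                if not adj[vid] & set(kept):
                    kept.append(vid)
            assert sorted(got) == sorted(kept)


class TestHarmonize:
    def _iset(self, *records):
        return InstrumentSet("x", list(records), 1.0, 0.001)

    def test_same_alleles_kept(self):
        exp = make_record(ea="A", oa="G", beta=0.1)
        out = make_record(ea="A", oa="G", beta=0.05, trait="y")
        h = harmonize(self._iset(exp), [out])
        assert h.actions["rs1"] == KEPT
        assert h.by[0] == 0.05

    def test_swapped_alleles_flipped(self):
        exp = make_record(ea="A", oa="G", beta=0.1)
        out = make_record(ea="G", oa="A", beta=0.05, trait="y")
        h = harmonize(self._iset(exp), [out])
        assert h.actions["rs1"] == FLIPPED
        assert h.by[0] == -0.05

    def test_strand_flip_resolved(self):
        exp = make_record(ea="A", oa="G", beta=0.1)
        out = make_record(ea="T", oa="C", beta=0.05, trait="y")
        h = harmonize(self._iset(exp), [out])
        assert h.actions["rs1"] == KEPT and h.by[0] == 0.05

    def test_palindrome_ambiguous_dropped(self):
        exp = make_record(ea="A", oa="T", eaf=0.50, beta=0.1)
        out = make_record(ea="A", oa="T", eaf=0.50, beta=0.05, trait="y")
        with pytest.raises(EmptyInstrumentSetError):
            harmonize(self._iset(exp), [out])
        h = harmonize(self._iset(exp), [out], allow_empty=True)
        assert h.actions["rs1"] == DROPPED_PALINDROMIC

    def test_palindrome_oriented_by_frequency(self):
        exp = make_record(ea="A", oa="T", eaf=0.2, beta=0.1)
        keep = make_record(ea="A", oa="T", eaf=0.25, beta=0.05, trait="y")
        flip = make_record(ea="A", oa="T", eaf=0.75, beta=0.05, trait="y")
        assert harmonize(self._iset(exp), [keep]).by[0] == 0.05
        assert harmonize(self._iset(exp), [flip]).by[0] == -0.05

    def test_incompatible_and_missing(self):
        exp1 = make_record(vid="rs1", ea="A", oa="G")
        exp2 = make_record(vid="rs2", ea="A", oa="G")
        out = make_record(vid="rs1", ea="A", oa="C", trait="y")
        h = harmonize(self._iset(exp1, exp2), [out], allow_empty=True)
        assert h.actions == {"rs1": DROPPED_INCOMPATIBLE, "rs2": DROPPED_MISSING}

    def test_every_variant_accounted_once(self, rng):
        exps = [make_record(vid=f"rs{i}") for i in range(6)]
        outs = [make_record(vid=f"rs{i}", trait="y") for i in range(4)]
        h = harmonize(self._iset(*exps), outs)
        assert set(h.actions) == {f"rs{i}" for i in range(6)}

    def test_idempotence(self):
        """Harmonizing an already-aligned set changes nothing."""
        exps = [make_record(vid=f"rs{i}", beta=0.1) for i in range(4)]
        outs = [make_record(vid=f"rs{i}", beta=0.05, trait="y") for i in range(4)]
        h1 = harmonize(self._iset(*exps), outs)
        aligned = [
            make_record(vid=v, beta=b, trait="y")
            for v, b in zip(h1.variant_ids, h1.by)
        ]
        h2 = harmonize(self._iset(*exps), aligned)
        assert np.array_equal(h1.by, h2.by)
        assert all(a == KEPT for a in h2.actions.values())

    @given(flip_mask=st.lists(st.booleans(), min_size=5, max_size=5))
    @settings(max_examples=25, deadline=None)
    def test_orientation_invariance(self, flip_mask):
        """Flipping outcome alleles and beta sign leaves the result identical."""
        exps = [make_record(vid=f"rs{i}", ea="A", oa="G", beta=0.1) for i in range(5)]
        outs = []
        for i, flip in enumerate(flip_mask):
            if flip:
                outs.append(make_record(vid=f"rs{i}", ea="G", oa="A", eaf=0.7,
                                        beta=-0.05, trait="y"))
            else:
                outs.append(make_record(vid=f"rs{i}", ea="A", oa="G", eaf=0.3,
                                        beta=0.05, trait="y"))
        h = harmonize(self._iset(*exps), outs)
        assert np.allclose(h.by, 0.05)


class TestHarmonizeMulti:
    def test_union_with_availability_intersection(self):
        x_inst = InstrumentSet("x", [make_record(vid="rs1", trait="x")], 1.0, 0.001)
        m_inst = InstrumentSet("m", [make_record(vid="rs2", trait="m")], 1.0, 0.001)
        x_records = [make_record(vid="rs1", beta=0.2, trait="x"),
                     make_record(vid="rs2", beta=0.01, trait="x")]
        m_records = [make_record(vid="rs1", beta=0.05, trait="m"),
                     make_record(vid="rs2", beta=0.3, trait="m")]
        y_records = [make_record(vid="rs1", beta=0.1, trait="y"),
                     make_record(vid="rs2", beta=0.15, trait="y")]
        h = harmonize_multi([x_inst, m_inst], {"x": x_records, "m": m_records}, y_records)
        assert h.variant_ids == ["rs1", "rs2"]
        assert h.bx.shape == (2, 2)
        assert np.allclose(h.bx[:, 0], [0.2, 0.01])
        assert np.allclose(h.bx[:, 1], [0.05, 0.3])

    def test_variant_missing_from_one_exposure_dropped(self):
        x_inst = InstrumentSet("x", [make_record(vid="rs1", trait="x"),
                                     make_record(vid="rs3", trait="x")], 1.0, 0.001)
        m_inst = InstrumentSet("m", [make_record(vid="rs2", trait="m")], 1.0, 0.001)
        x_records = [make_record(vid=v, trait="x") for v in ("rs1", "rs2", "rs3")]
        m_records = [make_record(vid=v, trait="m") for v in ("rs1", "rs2")]  # no rs3
        y_records = [make_record(vid=v, trait="y") for v in ("rs1", "rs2", "rs3")]
        h = harmonize_multi([x_inst, m_inst], {"x": x_records, "m": m_records}, y_records)
        assert h.variant_ids == ["rs1", "rs2"]
        assert h.actions["rs3"] == DROPPED_MISSING
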