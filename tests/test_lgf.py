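"""LGF encoding: per-kind semantics, published-case vectors, round-trips."""

import numpy as np
import pytest

from karyolgf import parse_karyotype
from karyolgf.lgf import (
    LGFError,
    build_matrix,
    map_karyotype,
    read_matrix_tsv,
    write_matrix_tsv,
    write_matrix_triplets,
)


def chrom_mask(ref, chrom, arm=None):
    return np.array(
        [b.chromosome == chrom and (arm is None or b.arm == arm) for b in ref.bands]
    )


def band_positions(ref, chrom, labels):
    return [ref.position(chrom, lab) for lab in labels]


def test_balanced_tetraploid_is_all_zero(ref, records_by_id):
    v = map_karyotype(records_by_id["27"], ref=ref)
    assert not v.loss.any() and not v.gain.any() and not v.fusion.any()


def test_whole_chromosome_gain_case9(ref, records_by_id):
    v = map_karyotype(records_by_id["9"], ref=ref)
    m13 = chrom_mask(ref, "13")
    assert v.gain[m13].all() and not v.gain[~m13].any()
    assert not v.loss.any() and not v.fusion.any()


def test_case21_fusions_and_losses(ref, records_by_id):
    # 73~87<4n>,XXXX,-7,-7,t(8;21)(q22;q22)x2,-11,-14,-16,-20
    v = map_karyotype(records_by_id["21"], ref=ref)
    for chrom, band in (("8", "q22.1"), ("8", "q22.3"), ("21", "q22.11"), ("21", "q22.3")):
        assert v.fusion[ref.position(chrom, band)] == 1
    assert not v.fusion[ref.position("8", "q21.3")]
    for chrom in ("7", "11", "14", "16", "20"):
        assert v.loss[chrom_mask(ref, chrom)].all()
    assert not v.loss[chrom_mask(ref, "8")].any()


def test_two_breakpoint_deletion_interval(ref):
    rec = parse_karyotype("x", "46,XX,del(5)(q13q33)[10]")
    v = map_karyotype(rec, ref=ref)
    flagged = {str(b) for b, f in zip(ref.bands, v.loss) if f}
    all5 = [b.band_label for b in ref.chromosome_bands("5")]
    expect = {
        "5" + lab for lab in all5[all5.index("q13.1") : all5.index("q33.3") + 1]
    }
    assert flagged == expect


def test_isochromosome_gains_q_and_loses_p(ref):
    rec = parse_karyotype("x", "92<4n>,XXYY,i(17)(q10)[10]")
    v = map_karyotype(rec, ref=ref)
    assert v.gain[chrom_mask(ref, "17", "q")].all()
    assert v.loss[chrom_mask(ref, "17", "p")].all()
    assert not v.gain[chrom_mask(ref, "17", "p")].any()


def test_balanced_events_yield_fusion_only(ref):
    rec = parse_karyotype("x", "46,XY,t(9;22)(q34;q11.2),inv(3)(q21.3q26.2)[10]")
    v = map_karyotype(rec, ref=ref)
    assert not v.loss.any() and not v.gain.any()
    assert v.fusion[ref.position("9", "q34.11")] and v.fusion[ref.position("9", "q34.3")]
    assert v.fusion[ref.position("22", "q11.21")]
    assert v.fusion[ref.position("3", "q21.3")] and v.fusion[ref.position("3", "q26.2")]


def test_add_maps_to_distal_loss_without_gain(ref):
    rec = parse_karyotype("x", "46,XY,add(11)(p15)[10]")
    v = map_karyotype(rec, ref=ref)
    flagged = {str(b) for b, f in zip(ref.bands, v.loss) if f}
    assert flagged == {"11p15.1", "11p15.2", "11p15.3", "11p15.4", "11p15.5"}
    assert not v.gain.any()


def test_one_breakpoint_deletion_runs_to_telomere(ref):
    rec = parse_karyotype("x", "46,XY,del(7)(q22)[10]")
    v = map_karyotype(rec, ref=ref)
    all7q = [b for b in ref.chromosome_bands("7") if b.arm == "q"]
    labels = [b.band_label for b in all7q]
    expect = {"7" + lab for lab in labels[labels.index("q22.1"):]}
    assert {str(b) for b, f in zip(ref.bands, v.loss) if f} == expect


def test_whole_arm_derivative_loses_complementary_arms(ref):
    rec = parse_karyotype("x", "45,XY,der(13;14)(q10;q10)[10]")
    v = map_karyotype(rec, ref=ref)
    assert v.loss[chrom_mask(ref, "13", "p")].all()
    assert v.loss[chrom_mask(ref, "14", "p")].all()
    assert not v.loss[chrom_mask(ref, "13", "q")].any()


def test_constitutional_abnormality_excluded(ref):
    rec = parse_karyotype("x", "45,XY,der(13;14)(q10;q10)c[10]")
    v = map_karyotype(rec, ref=ref)
    assert not v.loss.any() and not v.gain.any() and not v.fusion.any()


def test_sex_chromosome_loss_flags_y(ref):
    rec = parse_karyotype("14", "90<4n>,XX,-Y,-Y,del(5)(q14)[15]")
    v = map_karyotype(rec, ref=ref)
    assert v.loss[chrom_mask(ref, "Y")].all()
    assert not v.loss[chrom_mask(ref, "X")].any()


def test_multiplicity_idempotence(ref):
    """Doubling every abnormality's multiplicity never changes a set flag."""
    single = parse_karyotype("a", "46,XY,del(5)(q13q33),-7,+8,t(9;22)(q34;q11.2)[10]")
    double = parse_karyotype(
        "a", "46,XY,del(5)(q13q33)x2,-7,-7,+8,+8,t(9;22)(q34;q11.2)x2[10]"
    )
    v1, v2 = map_karyotype(single, ref=ref), map_karyotype(double, ref=ref)
    assert (v1.loss == v2.loss).all()
    assert (v1.gain == v2.gain).all()
    assert (v1.fusion == v2.fusion).all()


def test_whole_chromosome_oracle_equivalence(ref):
    """For purely numerical karyotypes the encoding equals a per-chromosome
    count oracle computed independently from the parsed tokens."""
    texts = {
        "a": "47,XY,+8[10]",
        "b": "45,XX,-7[10]",
        "c": "94<4n>,XXYY,+13,+13,-5[cp8]",
        "d": "44,XY,-16,-17[5]/45,sl,+21[4]",
    }
    for cid, text in texts.items():
        rec = parse_karyotype(cid, text)
        v = map_karyotype(rec, ref=ref)
        # oracle: walk raw tokens per clone, net signs per chromosome
        gain_chroms, loss_chroms = set(), set()
        for clone in rec.clones:
            per = {}
            for ab in clone.abnormalities:
                if ab.kind in ("gain_chromosome", "loss_chromosome"):
                    c = ab.chromosomes[0]
                    per[c] = per.get(c, 0) + (ab.multiplicity if ab.kind == "gain_chromosome" else -ab.multiplicity)
            if clone.lineage_ref:  # inherit stemline tokens (tests use sl only)
                for ab in rec.clones[0].abnormalities:
                    c = ab.chromosomes[0]
                    per[c] = per.get(c, 0) + (
                        ab.multiplicity if ab.kind == "gain_chromosome" else -ab.multiplicity
                    )
            gain_chroms |= {c for c, d in per.items() if d > 0}
            loss_chroms |= {c for c, d in per.items() if d < 0}
        for chrom in [str(i) for i in range(1, 23)]:
            m = chrom_mask(ref, chrom)
            assert v.gain[m].all() == (chrom in gain_chroms), (cid, chrom)
            assert v.loss[m].all() == (chrom in loss_chroms), (cid, chrom)
            assert v.gain[m].any() == (chrom in gain_chroms), (cid, chrom)


def test_build_matrix_37_cases(osu_matrix):
    assert osu_matrix.n_cases == 37
    assert osu_matrix.loss.shape == (37, 868)


def test_build_matrix_rejects_duplicates_and_empty(ref, records):
    with pytest.raises(LGFError, match="duplicate"):
        build_matrix([records[0], records[0]], ref=ref)
    with pytest.raises(LGFError):
        build_matrix([], ref=ref)


def test_identical_records_identical_vectors(ref):
    r1 = parse_karyotype("a", "46,XY,del(5)(q13q33)[10]")
    r2 = parse_karyotype("b", "46,XY,del(5)(q13q33)[10]")
    m = build_matrix([r1, r2], ref=ref)
    assert (m.loss[0] == m.loss[1]).all()


def test_tnt_scope_restricts_to_tnt_clones(ref):
    rec = parse_karyotype("x", "46,XY,del(6)(p23)[17]/92<4n>,XXYY,+13,+13[5]")
    full = map_karyotype(rec, ref=ref, scope="all_abnormal_clones")
    tnt = map_karyotype(rec, ref=ref, scope="tnt_clones_only")
    assert full.loss.any() and not tnt.loss.any()
    assert tnt.gain[chrom_mask(ref, "13")].all()


def test_matrix_tsv_round_trip(tmp_path, ref, records):
    m = build_matrix(records[:5], ref=ref)
    p = tmp_path / "m.tsv"
    write_matrix_tsv(m, p)
    again = read_matrix_tsv(p, ref=ref)
    assert again.cases == m.cases
    assert (again.loss == m.loss).all()
    assert (again.gain == m.gain).all()
    assert (again.fusion == m.fusion).all()
    write_matrix_triplets(m, tmp_path / "t.tsv")
    n_flags = int(m.loss.sum() + m.gain.sum() + m.fusion.sum())
    assert len((tmp_path / "t.tsv").read_text().splitlines()) == n_flags + 1
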