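"""PSM filtering/collapsing and NME/NAT-rule classification of N-termini."""

from __future__ import annotations

import pytest

from riboproteo.nterm_classifier import (
    NATA_RESIDUES,
    NATB_SECOND,
    NATCEF_SECOND,
    NME_SMALL,
    NtPSM,
    OriginContext,
    classify_origin,
    collapse,
    filter_psms,
    nat_class,
    nme_compliant,
)
from riboproteo.reference import classify_benchmark, load_dtis_benchmark, parse_dtis, parse_nterm

AA20 = "ACDEFGHIKLMNPQRSTVWY"


def _psm(peptide="TDTKDAGMDAVQR", protein="P1", start=2, mod="light_acetyl",
         enzyme="trypsin", q=0.001):
    return NtPSM(peptide, protein, start, mod, enzyme, q)


# ---------------------------------------------------------------- filtering
def test_q_value_filter_removes_high_q_psms():
    kept, rejected = filter_psms([_psm(q=0.02), _psm(q=0.01), _psm(q=0.0)])
    assert len(kept) == 2 and rejected == 1


def test_all_retained_with_thresholds_off():
    psms = [_psm(q=0.5) for _ in range(10)]
    kept, rejected = filter_psms(psms, q_max=1.0)
    assert len(kept) == 10 and rejected == 0


def test_single_psm_nterm_flagged_low_evidence():
    records = collapse([_psm()])
    assert len(records) == 1
    assert records[0].low_evidence
    assert records[0].psm_count_total == 1


# ---------------------------------------------------------------- collapsing
def test_collapse_keeps_longest_peptide_variant_across_enzymes():
    peptides = ["TDTKDAGMDAVQR", "TDTKDAGMDAVQRRL", "TDTKDAGMDAVQRRLFE"]
    psms = [
        _psm(peptide=p, enzyme=e)
        for p, e in zip(peptides, ["trypsin", "chymotrypsin", "gluc"])
    ]
    records = collapse(psms)
    assert len(records) == 1
    assert records[0].peptide == "TDTKDAGMDAVQRRLFE"
    assert records[0].psm_count_total == 3
    assert records[0].psm_count_nta == 3


def test_collapse_conflicting_residues_raise():
    with pytest.raises(ValueError, match="conflicting"):
        collapse([_psm(peptide="TDTK"), _psm(peptide="TETKDA")])


def test_collapse_counts_match_brute_force_group_by(clean_psms):
    psms_df, _, _ = clean_psms
    psms = [
        NtPSM(r.peptide, r.protein, int(r.start), r.modification, r.enzyme,
              float(r.q_value))
        for r in psms_df.itertuples()
    ]
    records = collapse(psms)
    # naive group-by recount
    expected: dict[tuple[str, int], list] = {}
    for p in psms:
        expected.setdefault((p.protein, p.start), []).append(p)
    assert len(records) == len(expected)
    for rec in records:
        group = expected[(rec.protein, rec.start)]
        assert rec.psm_count_total == len(group)
        assert rec.psm_count_nta == sum(
            1 for p in group if p.modification == "light_acetyl"
        )
        assert rec.psm_count_total == rec.psm_count_nta + rec.psm_count_free


# ---------------------------------------------------------------- NME rules
@pytest.mark.parametrize(
    "start,parent,expected",
    [
        (2, "MTDTK", True),    # exposed Thr after iMet removal
        (2, "MKDTK", False),   # bulky Lys cannot be exposed by MetAPs
        (1, "MDAVQ", True),    # retained Met before Asp
        (1, "MSAVQ", False),   # Met before Ser would have been excised
    ],
)
def test_nme_compliance_worked_examples(start, parent, expected):
    assert nme_compliant(start, parent, strict=True) is expected


def test_nme_lenient_mode_accepts_any_retained_met():
    assert nme_compliant(1, "MSAVQ", strict=False) is True


def test_nme_rule_table_total_over_all_residues():
    """Enumeration over the 20 amino acids at P2 matches the configured sets."""
    for aa in AA20:
        assert nme_compliant(2, "M" + aa, strict=True) is (aa in NME_SMALL)
        assert nme_compliant(1, "M" + aa, strict=True) is (aa not in NME_SMALL)
    assert nme_compliant(5, "MXXXX") is None


# ---------------------------------------------------------------- NAT rules
@pytest.mark.parametrize(
    "residues,retained,expected",
    [
        ("SDTK", False, "NatA"),
        ("MEAVQ", True, "NatB"),
        ("MKAVQ", True, "NatCEF"),
        ("PAVQ", False, "refractory"),
        ("DAVQ", False, "none"),
    ],
)
def test_nat_class_worked_examples(residues, retained, expected):
    assert nat_class(residues, imet_retained=retained) == expected


def test_nat_rule_table_total_over_all_residues():
    for aa in AA20:
        exposed = nat_class(aa + "XX", imet_retained=False)
        if aa == "P":
            assert exposed == "refractory"
        elif aa in NATA_RESIDUES:
            assert exposed == "NatA"
        else:
            assert exposed == "none"
        retained = nat_class("M" + aa, imet_retained=True)
        if aa in NATB_SECOND:
            assert retained == "NatB"
        elif aa in NATCEF_SECOND:
            assert retained == "NatCEF"
        else:
            assert retained == "none"


# ---------------------------------------------------------------- origins
def _record(start, nta=1):
    from riboproteo.nterm_classifier import NTermRecord

    return NTermRecord("P1", start, "PEPTIDE", 2, nta, 2 - nta)


def test_annotated_start_two_is_dbtis():
    ctx = OriginContext(parent="MTDTKDA", annotated=True)
    rec = classify_origin(_record(2), ctx)
    assert rec.origin == "dbTIS"
    assert rec.nme_compliant is True
    assert rec.nat_class == "NatA"


def test_dtis_match_at_imet_plus_one_with_exposed_thr():
    parent = "X" * 50 + "MTDTKDAGMDAVQR"
    ctx = OriginContext(parent=parent, annotated=True, dtis_starts=frozenset({51}))
    rec = classify_origin(_record(52), ctx)
    assert rec.origin == "dTIS"
    assert rec.supporting_tis == "iMet51"
    assert rec.nat_class == "NatA"


def test_dtis_match_with_bulky_exposed_residue_demoted_to_neo_terminus():
    parent = "X" * 50 + "MKDTKDAG"
    ctx = OriginContext(parent=parent, annotated=True, dtis_starts=frozenset({51}))
    rec = classify_origin(_record(52), ctx)
    assert rec.origin == "internal_neo"


def test_dual_dtis_ctp_label_when_both_match():
    parent = "X" * 62 + "MADTKDAG"
    ctx = OriginContext(
        parent=parent, annotated=True, dtis_starts=frozenset({63}),
        cleavage=(("cTP", 64),),
    )
    rec = classify_origin(_record(64), ctx)
    assert rec.origin == "dual_dTIS_cTP"
    assert rec.supporting_tis == "iMet63"
    assert rec.supporting_cleavage == "cTP:P1'=64"


def test_cleavage_window_match_gives_ctp_neo():
    parent = "X" * 40 + "ASDTKDAG"
    ctx = OriginContext(parent=parent, annotated=True, cleavage=(("cTP", 41),))
    rec = classify_origin(_record(43), ctx)
    assert rec.origin == "cTP_neo"


def test_unmatched_internal_start_is_internal_neo():
    ctx = OriginContext(parent="M" + "X" * 100, annotated=True)
    rec = classify_origin(_record(60), ctx)
    assert rec.origin == "internal_neo"


def test_refractory_nterm_observed_acetylated_is_flagged_not_rejected():
    parent = "X" * 40 + "PSDTKDAG"
    ctx = OriginContext(parent=parent, annotated=True, cleavage=(("cTP", 41),))
    rec = classify_origin(_record(41, nta=1), ctx)
    assert rec.origin == "cTP_neo"
    assert rec.nat_class == "refractory"
    assert rec.nta_conflict


def test_every_record_gets_exactly_one_origin(clean_psms, clean_sim):
    psms_df, targetp, _ = clean_psms
    genome, models, truth = clean_sim
    valid = {
        "dbTIS", "dTIS", "cTP_neo", "mTP_neo", "dual_dTIS_cTP", "internal_neo",
    }
    preds = {
        r.protein: (r.prediction, int(r.site) + 1)
        for r in targetp.itertuples() if r.prediction != "noTP"
    }
    psms = [
        NtPSM(r.peptide, r.protein, int(r.start), r.modification, r.enzyme,
              float(r.q_value))
        for r in psms_df.itertuples()
    ]
    kept, _ = filter_psms(psms)
    for rec in collapse(kept):
        ctx = OriginContext(
            parent=truth.proteoforms.get(rec.protein, ""),
            annotated=rec.protein in truth.proteoforms,
            dtis_starts=frozenset(
                {truth.dtis_imet[rec.protein]} if rec.protein in truth.dtis_imet else set()
            ),
            cleavage=(preds[rec.protein],) if rec.protein in preds else (),
        )
        classify_origin(rec, ctx)
        assert rec.origin in valid


# ---------------------------------------------------------------- benchmark
def test_benchmark_all_rows_nme_compliant_with_consistent_nat_class():
    """Every curated dTIS/N-terminus pair passes the compliance rules."""
    result = classify_benchmark()
    assert len(result) == 68
    assert result["nme_compliant"].all()
    # acetylated N-termini must belong to an acetylatable NAT class
    acetylated = result[result["observed_nta"]]
    assert (acetylated["nat_class"] != "refractory").all()
    assert (acetylated["nat_class"] != "none").all()


def test_benchmark_codon_census():
    df = load_dtis_benchmark()
    codons = [parse_dtis(s)[1] for s in df["dtis"]]
    assert len(codons) == 68
    assert codons.count("ATG") == 61
    assert codons.count("AGG") == 2
    assert codons.count("CTG") == 2
    assert codons.count("ATA") == 1
    assert codons.count("ACG") == 1
    assert codons.count("TTG") == 1


def test_benchmark_parsers():
    assert parse_dtis("Met45") == (45, "ATG")
    assert parse_dtis("Thr105(ACG)->Met") == (105, "ACG")
    assert parse_nterm("Ac-T") == (frozenset({"acetyl"}), "T")
    assert parse_nterm("NH2/Ac-MK") == (frozenset({"free", "acetyl"}), "MK")
    with pytest.raises(ValueError):
        parse_dtis("Xyz12")
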