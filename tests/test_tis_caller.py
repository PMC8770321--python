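"""TIS calling: scores, peak finding, categories, thresholds, oracle equivalence."""

from __future__ import annotations

import numpy as np
import pytest

from riboproteo.footprints import PSiteTrack
from riboproteo.models import TranscriptIndex, TranscriptModel
from riboproteo.synthetic_data import SimConfig, simulate_footprints, simulate_genome
from riboproteo.tis_caller import (
    START_CODONS,
    CalledTIS,
    TISThresholds,
    call_tis,
    categorize,
    find_peaks,
    normalized_score,
)
from riboproteo.footprints import build_track

from _oracles import called_tis_tuples, oracle_call_tis, raw_models


# ---------------------------------------------------------------- R scores
@pytest.mark.parametrize("x,n,expected", [(5, 1000, 0.05), (100, 100, 10.0), (0, 7, 0.0)])
def test_normalized_score(x, n, expected):
    assert normalized_score(x, n) == pytest.approx(expected)


def test_normalized_score_undefined_without_reads():
    with pytest.raises(ValueError):
        normalized_score(1, 0)


# ---------------------------------------------------------------- fixtures
def _toy_gene(seq_parts: dict) -> tuple[dict, list[TranscriptModel]]:
    """Plus-strand single-exon gene: 60 nt leader, CDS, 40 nt trailer."""
    rng = np.random.default_rng(4)
    utr5 = "".join("ACGT"[i] for i in rng.integers(0, 4, 60))
    utr3 = "".join("ACGT"[i] for i in rng.integers(0, 4, 40))
    cds = seq_parts["cds"]
    genome = {"chr1": "C" * 20 + utr5 + cds + utr3 + "C" * 20}
    model = TranscriptModel(
        "g1", "g1.1", "chr1", "+", [(20, 20 + 60 + len(cds) + 40)],
        80, 80 + len(cds),
    )
    return genome, [model]


def _track(treatment: str, spikes: dict[int, int]) -> PSiteTrack:
    track = PSiteTrack(treatment)
    for pos, n in spikes.items():
        track.add("chr1", "+", pos, n)
    return track


CDS = "ATG" + "GCT" * 30 + "TAA"  # M + 30xA + stop, starts at genomic 80


def test_find_peaks_spike_on_start_codon():
    genome, models = _toy_gene({"cds": CDS})
    ltm = _track("LTM", {80: 10})
    cands = find_peaks(ltm, TranscriptIndex(models), genome)
    assert len(cands) == 1
    assert cands[0].anchor == 80 and cands[0].codon == "ATG"


def test_find_peaks_one_nt_upstream_assigned_to_codon():
    genome, models = _toy_gene({"cds": CDS})
    ltm = _track("LTM", {79: 10})
    cands = find_peaks(ltm, TranscriptIndex(models), genome)
    assert len(cands) == 1
    assert cands[0].anchor == 80


def test_find_peaks_seven_nt_window_keeps_maximum():
    # two spikes 3 nt apart on eligible codons: only the larger survives
    cds = "ATG" + "ATG" + "GCT" * 29 + "TAA"  # ATG at 80 and 83
    genome, models = _toy_gene({"cds": cds})
    ltm = _track("LTM", {80: 10, 83: 7})
    cands = find_peaks(ltm, TranscriptIndex(models), genome)
    assert [(c.anchor, c.peak_count) for c in cands] == [(80, 10)]


def test_find_peaks_discards_spike_away_from_any_start_codon():
    # CCC codons surround position 95 (inside the poly-GCT CDS); GCT/CTG..
    cds = "ATG" + "CCC" * 30 + "TAA"
    genome, models = _toy_gene({"cds": cds})
    ltm = _track("LTM", {95: 50})
    assert find_peaks(ltm, TranscriptIndex(models), genome) == []


def test_find_peaks_tie_prefers_atg_over_near_cognate():
    cds = "ATG" + "CTG" + "GCT" * 29 + "TAA"  # ATG at 80, CTG at 83
    genome, models = _toy_gene({"cds": cds})
    ltm = _track("LTM", {80: 10, 83: 10})
    cands = find_peaks(ltm, TranscriptIndex(models), genome)
    assert [(c.anchor, c.codon) for c in cands] == [(80, "ATG")]


# ---------------------------------------------------------------- categories
def test_categorize_positions():
    genome, models = _toy_gene({"cds": CDS})
    m = models[0]
    assert categorize(80, m) == "dbTIS"
    assert categorize(86, m) == "cds_dTIS_inframe"  # +6 nt, in frame
    assert categorize(87, m) == "cds_other_frame"
    assert categorize(60, m) == "leader5"
    assert categorize(80 + len(CDS) + 5, m) == "leader3"


# ---------------------------------------------------------------- thresholds
def _paired_tracks(ltm_spikes, chx_spikes):
    return _track("LTM", ltm_spikes), _track("CHX", chx_spikes)


def test_dbtis_called_at_exact_threshold():
    genome, models = _toy_gene({"cds": CDS})
    # 5 LTM counts; r_ltm = 5/5*10 = 10 with no other reads; rdiff 10 >= 0.01
    ltm, chx = _paired_tracks({80: 5}, {100: 50})
    called = call_tis(ltm, chx, models, genome)
    assert len(called) == 1
    rec = called[0]
    assert rec.category == "dbTIS" and rec.status == "called"
    assert rec.ltm_count == 5
    assert rec.rdiff == pytest.approx(rec.r_ltm - rec.r_chx)


def test_cds_internal_candidate_below_count_threshold_rejected():
    cds = "ATG" + "GCT" * 10 + "ATG" + "GCT" * 19 + "TAA"  # in-frame dTIS at 113
    genome, models = _toy_gene({"cds": cds})
    ltm, chx = _paired_tracks({113: 14}, {100: 10})
    called = call_tis(ltm, chx, models, genome)
    assert all(r.position != 113 for r in called)
    # at 15 counts the same candidate passes
    ltm2, _ = _paired_tracks({113: 15}, {})
    called2 = call_tis(ltm2, _track("CHX", {100: 10}), models, genome)
    assert any(r.position == 113 and r.category == "cds_dTIS_inframe" for r in called2)


def test_dbtis_rescued_by_elongating_occupancy():
    genome, models = _toy_gene({"cds": CDS})
    # no LTM peak at all; 10 CHX P-sites inside the CDS
    ltm = _track("LTM", {})
    chx = _track("CHX", {90 + 3 * i: 1 for i in range(10)})
    called = call_tis(ltm, chx, models, genome)
    assert len(called) == 1
    assert called[0].status == "rescued_dbTIS"
    assert called[0].category == "dbTIS"
    # below the occupancy floor nothing is emitted
    chx_low = _track("CHX", {90 + 3 * i: 1 for i in range(9)})
    assert call_tis(ltm, chx_low, models, genome) == []


def test_threshold_monotonicity_never_adds_calls(clean_sim, clean_tracks):
    genome, models, _ = clean_sim
    ltm, chx, _, _ = clean_tracks
    base = call_tis(ltm, chx, models, genome)
    strict = TISThresholds()
    for cat in strict.min_count:
        strict.min_count[cat] += 5
        strict.min_rdiff[cat] += 0.05
    strict.rescue_min_chx += 10
    harder = call_tis(ltm, chx, models, genome, strict)
    base_keys = {(r.chrom, r.position, r.strand) for r in base}
    assert {(r.chrom, r.position, r.strand) for r in harder} <= base_keys


def test_at_most_one_call_per_seven_nt_window(clean_sim, clean_tracks):
    genome, models, _ = clean_sim
    ltm, chx, _, _ = clean_tracks
    called = call_tis(ltm, chx, models, genome)
    by_strand: dict[tuple[str, str], list[int]] = {}
    for r in called:
        by_strand.setdefault((r.chrom, r.strand), []).append(r.position)
    for positions in by_strand.values():
        positions.sort()
        assert all(b - a > 3 for a, b in zip(positions, positions[1:]))


# ---------------------------------------------------------------- oracle
def _tracks_to_dicts(track: PSiteTrack) -> dict:
    return {k: dict(v) for k, v in track.counts.items()}


def test_caller_equals_brute_force_on_simulated_tracks(clean_sim, clean_tracks):
    genome, models, _ = clean_sim
    ltm, chx, _, _ = clean_tracks
    thresholds = TISThresholds()
    called = call_tis(ltm, chx, models, genome, thresholds)
    expected = oracle_call_tis(
        genome, raw_models(models), _tracks_to_dicts(ltm), _tracks_to_dicts(chx),
        thresholds,
    )
    assert called_tis_tuples(called) == expected


def test_caller_equals_brute_force_on_random_tracks():
    """Random spike patterns (not only at planted TIS) on small genomes."""
    thresholds = TISThresholds()
    rng = np.random.default_rng(2024)
    for trial in range(20):
        cfg = SimConfig(seed=3000 + trial, n_genes=3)
        genome, models, truth = simulate_genome(cfg)
        glen = len(genome["chr1"])
        ltm = PSiteTrack("LTM")
        chx = PSiteTrack("CHX")
        for _ in range(rng.integers(30, 120)):
            ltm.add("chr1", "+-"[rng.integers(2)], int(rng.integers(10, glen - 10)),
                    int(rng.integers(1, 30)))
        for _ in range(rng.integers(30, 200)):
            chx.add("chr1", "+-"[rng.integers(2)], int(rng.integers(10, glen - 10)),
                    int(rng.integers(1, 10)))
        for t in truth.tis:  # guarantee some eligible peaks as well
            strand = next(m.strand for m in models if m.transcript_id == t.transcript)
            ltm.add("chr1", strand, t.genomic_pos, int(rng.integers(5, 40)))
        called = call_tis(ltm, chx, models, genome, thresholds)
        expected = oracle_call_tis(
            genome, raw_models(models), _tracks_to_dicts(ltm),
            _tracks_to_dicts(chx), thresholds,
        )
        assert called_tis_tuples(called) == expected, f"trial {trial}"


def test_noise_free_recovery_and_no_false_calls(clean_sim, clean_tracks):
    genome, models, truth = clean_sim
    ltm, chx, _, _ = clean_tracks
    called = call_tis(ltm, chx, models, genome)
    planted = {(t.genomic_pos, t.category) for t in truth.tis}
    got = {(r.position, r.category) for r in called if r.status == "called"}
    assert got == planted
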