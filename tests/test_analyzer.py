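"""Tests for split alignment, junction calling, CGH segmentation, and friends."""

import numpy as np
import pandas as pd
import pytest

from foldback.analyze import (
    JunctionCall,
    SeedIndex,
    call_junction,
    classify_insertion_origin,
    cluster_discordant_pairs,
    detect_hybrid_repeat,
    infer_parental_origin,
    segment_cgh,
    split_align,
)
from foldback.genome import generate_reference, mito_window, plant_repeat_pair
from foldback.sequence import revcomp
from foldback.simulate import (
    Derivative,
    FoldbackEvent,
    RearrangementTruth,
    Segment,
    add_complex_insertion,
    break_dicentric,
    emit_amplicon,
    form_dicentric,
    resolve_derivative,
    simulate_cgh,
    simulate_paired_end_reads,
)


def _pipeline(genome, event, p, mode, **kw):
    dic = form_dicentric(genome, event)
    invdup, _ = break_dicentric(genome, dic, p)
    truth = RearrangementTruth(event, p, mode, genome.length(event.chrom))
    return resolve_derivative(genome, invdup, truth, mode, **kw)


# ---------------------------------------------------------------------------
# split alignment

def test_split_alignment_recovers_overlap_and_strands(designed, designed_index):
    genome, event, p = designed
    der, truth = _pipeline(genome, event, p, "telomere")
    amp, _ = emit_amplicon(genome, der, truth.junctions[0])
    split = split_align(amp, designed_index)
    assert split.resolved
    assert split.left.strand == "+" and split.right.strand == "-"
    assert split.left.qend - split.right.qstart == event.mh_len == 4
    assert split.left.qstart == 0 and split.right.qend == len(amp)


def test_split_alignment_reports_insertion_gap(designed, designed_index):
    genome, event, p = designed
    der, truth = _pipeline(genome, event, p, "telomere")
    der, truth = add_complex_insertion(genome, der, truth, 0, "untemplated",
                                       length=70, seed=3)
    amp, _ = emit_amplicon(genome, der, truth.junctions[0])
    split = split_align(amp, designed_index)
    assert split.resolved
    assert split.right.qstart - split.left.qend == 70


def test_contiguous_sequence_is_unresolved(designed, designed_index):
    genome, _event, _p = designed
    amp = genome["chrA"][1_000_000:1_000_800]
    split = split_align(amp, designed_index)
    assert split.right is None
    call = call_junction(split, genome)
    assert call.junction_type == "unresolved"


def test_split_alignment_rejects_short_amplicons(designed_index):
    with pytest.raises(ValueError):
        split_align("ACGT" * 5, designed_index)


# ---------------------------------------------------------------------------
# junction calling round trips (small scale; acceptance tests scale up)

def test_disomy_inversion_call_matches_truth(designed, designed_index):
    genome, event, p = designed
    der, truth = _pipeline(genome, event, p, "telomere")
    amp, _ = emit_amplicon(genome, der, truth.junctions[0])
    call = call_junction(split_align(amp, designed_index), genome)
    assert call.junction_type == "disomy_inversion"
    assert (call.e, call.d) == (event.e, event.d)
    assert call.spacer_size == event.spacer_size == 2_047
    assert call.mh_len == event.mh_len


def test_telomere_junction_call_matches_truth(designed, designed_index):
    genome, event, p = designed
    der, truth = _pipeline(genome, event, p, "telomere")
    j = truth.junctions[1]
    amp, _ = emit_amplicon(genome, der, j)
    call = call_junction(split_align(amp, designed_index), genome)
    assert call.junction_type == "inversion_telomere"
    assert call.d == j.left[1]
    assert call.mh_len == j.mh_len


def test_translocation_junction_call_matches_truth(designed, designed_index):
    genome, event, p = designed
    der, truth = _pipeline(genome, event, p, "translocation",
                           donor_chrom="chrB", donor_break=1_200_000)
    j = truth.junctions[1]
    amp, _ = emit_amplicon(genome, der, j)
    call = call_junction(split_align(amp, designed_index), genome)
    assert call.junction_type == "inversion_translocation"
    assert call.chrom_forward == "chrB" and call.chrom_reverse == "chrA"
    assert call.e == j.right[1] and call.d == j.left[1]
    assert call.mh_len == j.mh_len


def test_ring_fusion_junction_is_flagged_not_miscalled(designed, designed_index):
    genome, event, p = designed
    der, truth = _pipeline(genome, event, p, "ring")
    ring_j = next(j for j in truth.junctions if j.junction_type == "ring_fusion")
    amp, _ = emit_amplicon(genome, der, ring_j)
    call = call_junction(split_align(amp, designed_index), genome)
    assert call.junction_type == "unresolved"
    assert "ring" in call.diagnostic


# ---------------------------------------------------------------------------
# insertion origin

def test_insertion_origin_classification(designed, designed_index):
    genome, event, p = designed
    bps = [("chrA", event.e), ("chrA", event.d)]
    # templated, direct: copy 20 bases from just proximal of e
    t = genome["chrA"][event.e - 500:event.e - 480]
    kind, loc = classify_insertion_origin(t, genome, bps)
    assert kind == "templated_direct" and loc[0] == "chrA"
    kind, loc = classify_insertion_origin(revcomp(t), genome, bps)
    assert kind == "templated_inverted"
    # mitochondrial, spanning the circular origin
    m = mito_window(genome.mito_donor, len(genome.mito_donor) - 30, 70)
    kind, loc = classify_insertion_origin(m, genome, bps)
    assert kind == "mitochondrial" and loc[0] == "mito_donor"
    # untemplated: a 30-mer vanishingly unlikely to occur in 5 Mb
    rng = np.random.default_rng(0)
    u = "".join(rng.choice(list("ACGT"), 30))
    assert u not in genome["chrA"] and u not in genome["chrB"]
    kind, loc = classify_insertion_origin(u, genome, bps)
    assert kind == "untemplated" and loc is None
    # too short to place
    kind, loc = classify_insertion_origin("CAT", genome, bps)
    assert kind == "unclassifiable_short"


def test_insertion_origin_tolerates_divergence(designed):
    genome, event, _p = designed
    t = list(genome["chrA"][event.e - 300:event.e - 260])   # 40 bp template
    t[10] = {"A": "C"}.get(t[10], "A")                      # 1 mismatch (97.5% id)
    kind, _ = classify_insertion_origin("".join(t), genome, [("chrA", event.e)])
    assert kind == "templated_direct"


# ---------------------------------------------------------------------------
# hybrid repeats

def test_hybrid_repeat_detection():
    g = generate_reference({"chr1": 400_000}, seed=31, telomere_units=50)
    g = plant_repeat_pair(g, "chr1", "AluY", (200_000, 260_000), 296,
                          identity=0.90, orientation="inverted", seed=2)
    g = plant_repeat_pair(g, "chr1", "L1", (100_000, 150_000), 330,
                          identity=0.95, orientation="inverted", seed=3)
    call = JunctionCall("disomy_inversion", e=260_100, d=200_150,
                        chrom_forward="chr1", chrom_reverse="chr1")
    hit = detect_hybrid_repeat(call, g)
    assert hit is not None
    assert hit.family == "AluY" and hit.homology_length == 296
    assert 0.88 <= hit.identity <= 0.92

    call2 = JunctionCall("disomy_inversion", e=150_200, d=100_100,
                         chrom_forward="chr1", chrom_reverse="chr1")
    hit2 = detect_hybrid_repeat(call2, g)
    assert hit2.family == "L1" and hit2.identity >= 0.94

    # breakpoints outside any annotated pair: no call
    call3 = JunctionCall("disomy_inversion", e=350_000, d=320_000,
                         chrom_forward="chr1", chrom_reverse="chr1")
    assert detect_hybrid_repeat(call3, g) is None


# ---------------------------------------------------------------------------
# CGH segmentation (pure profile arithmetic; no genome needed)

def _profile(spacer, probe_spacing, *, L=8_000_000, dup=1_000_000,
             deletion=2_000_000, noise_sd=0.05, seed=17):
    e = L - deletion
    d = e - spacer
    p = d - dup
    event = FoldbackEvent("chr1", e, 0, e, d, 2)
    truth = RearrangementTruth(event, p, "telomere", L)
    genome = None   # simulate_cgh reads only the truth record
    return truth, simulate_cgh(genome, truth, probe_spacing=probe_spacing,
                               noise_sd=noise_sd, seed=seed)


def test_cgh_resolves_typical_spacer_at_fine_probe_spacing():
    truth, profile = _profile(3_428, 200)
    result = segment_cgh(profile)
    assert result.spacer_detected
    assert abs(result.spacer_estimate - 3_428) <= 2 * 200
    states = [s.state for s in result.segments]
    assert states == ["disomic", "duplicated", "disomic", "deleted"]


def test_cgh_misses_typical_spacer_at_clinical_array_spacing():
    truth, profile = _profile(3_428, 75_000)
    result = segment_cgh(profile)
    assert not result.spacer_detected


def test_cgh_resolves_the_largest_cohort_spacer_either_way():
    truth, profile = _profile(70_466, 200)
    result = segment_cgh(profile)
    assert result.spacer_detected
    assert abs(result.spacer_estimate - 70_466) <= 2 * 200


def test_cgh_requires_minimum_probes():
    profile = pd.DataFrame({"chrom": "c", "pos": range(5), "log2": [0.0] * 5})
    with pytest.raises(ValueError):
        segment_cgh(profile)


def test_cgh_flat_profile_has_no_spacer():
    rng = np.random.default_rng(1)
    profile = pd.DataFrame({"chrom": "c", "pos": np.arange(0, 20_000, 100),
                            "log2": rng.normal(0, 0.05, 200)})
    result = segment_cgh(profile)
    assert not result.spacer_detected and result.spacer_estimate is None


# ---------------------------------------------------------------------------
# discordant read pairs

def test_inversion_junction_yields_inverted_clusters(designed):
    genome, event, p = designed
    der = Derivative([
        Segment("ref", "chrA", event.e - 6_000, event.e, "+"),
        Segment("ref", "chrA", event.d - 6_000, event.d, "-"),
    ])
    reads = simulate_paired_end_reads(genome, der, coverage=40, seed=4)
    clusters = cluster_discordant_pairs(reads)
    inverted = [c for c in clusters if c.signature == "inverted"]
    assert len(inverted) >= 1
    assert any(c.n_pairs >= 5 for c in inverted)


def test_concordant_library_produces_no_clusters(designed):
    genome, _event, _p = designed
    der = Derivative([Segment("ref", "chrA", 1_000_000, 1_030_000, "+")])
    reads = simulate_paired_end_reads(genome, der, coverage=30, seed=5)
    assert cluster_discordant_pairs(reads) == []


def test_translocation_junction_yields_interchromosomal_cluster(designed):
    genome, _event, _p = designed
    der = Derivative([
        Segment("ref", "chrA", 1_000_000, 1_006_000, "+"),
        Segment("ref", "chrB", 500_000, 506_000, "+"),
    ])
    reads = simulate_paired_end_reads(genome, der, coverage=40, seed=6)
    clusters = cluster_discordant_pairs(reads)
    assert any(c.signature == "interchromosomal" and c.n_pairs >= 5
               for c in clusters)


# ---------------------------------------------------------------------------
# parent-of-origin inference

def _marker(marker, region, child, doubled, mother, father):
    return {"marker": marker, "region": region, "child_alleles": child,
            "child_doubled": doubled, "mother_alleles": mother,
            "father_alleles": father}


def test_parental_origin_rules():
    table = pd.DataFrame([
        # duplicated region, doubled allele only in father -> paternal
        _marker("m1", "duplicated", "150,154", "154", "148,150", "154,158"),
        # deleted region, hemizygous child allele only in mother -> deletion paternal
        _marker("m2", "deleted", "201", "", "201,205", "209,213"),
        # identical parental genotypes -> uninformative
        _marker("m3", "duplicated", "100,102", "100", "100,102", "100,102"),
    ])
    per_marker, summary = infer_parental_origin(table)
    assert list(per_marker["origin"]) == ["paternal", "paternal", "U"]
    assert summary == {"origin": "paternal", "n_informative": 2, "caveat": False}


def test_parental_origin_maternal_and_exclusion():
    table = pd.DataFrame([
        _marker("m1", "duplicated", "150,154", "150", "148,150", "154,158"),
        # child allele in neither parent: Mendelian inconsistency, excluded
        _marker("m2", "deleted", "999", "", "201,205", "209,213"),
    ])
    per_marker, summary = infer_parental_origin(table)
    assert list(per_marker["origin"]) == ["maternal", "excluded"]
    assert list(per_marker["flag"]) == ["", "mendelian_inconsistency"]
    assert summary["origin"] == "maternal" and summary["n_informative"] == 1


def test_parental_origin_single_parent_carries_caveat():
    table = pd.DataFrame([
        # father untested; doubled allele absent in mother -> paternal, caveated
        _marker("m1", "duplicated", "150,154", "154", "148,150", ""),
    ])
    per_marker, summary = infer_parental_origin(table)
    assert list(per_marker["origin"]) == ["paternal"]
    assert summary == {"origin": "paternal", "n_informative": 1, "caveat": True}
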