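"""Edit-model operations: protospacer search, cut prediction, allele
construction, premature-stop detection and restriction digestion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import amplichim as ac
from amplichim.edit_models import (
    BUILTIN_ENZYMES,
    PIG_HHEX_GUIDES,
    STOP_CODONS,
    STOP_HINDIII_INSERT,
    RestrictionEnzyme,
    apply_edit_ops,
    cut_positions,
    lift_coordinate,
)
from amplichim.errors import (
    AmbiguousDesignError,
    ConfigurationError,
    DegenerateDesignError,
    UndiagnosableDesignError,
)
from amplichim.sequences import IUPAC_EXPAND, NucleotideSequence, reverse_complement


def _rand_dna(rng, n):
    return "".join(rng.choice(list("ACGT")) for _ in range(n))


def _guide(proto):
    return ac.Guide(NucleotideSequence(proto))


# ---------------------------------------------------------------------------
# protospacer location and cut prediction

def _brute_protospacer(ref, guide):
    """Independent all-offsets scan on both strands."""
    pat = guide.protospacer.bases + guide.pam
    hits = []
    for p in range(len(ref) - len(pat) + 1):
        if all(ref[p + i] in IUPAC_EXPAND[c] for i, c in enumerate(pat)):
            hits.append((p, "+"))
    rc = reverse_complement(ref)
    for p in range(len(rc) - len(pat) + 1):
        if all(rc[p + i] in IUPAC_EXPAND[c] for i, c in enumerate(pat)):
            # protospacer span on the forward strand
            start = len(ref) - (p + len(guide.protospacer))
            hits.append((start, "-"))
    return sorted(hits)


def test_locate_protospacer_forward_constructed():
    proto = "ACGTACGTACGTACGTACGT"
    ref = NucleotideSequence(proto + "AGG")
    assert ac.locate_protospacer(ref, _guide(proto)) == [(0, "+")]


def test_locate_protospacer_reverse_constructed():
    proto = "ACGTTTGCACGTACGAACGT"
    ref = NucleotideSequence(reverse_complement(proto + "TGG"))
    hits = ac.locate_protospacer(ref, _guide(proto))
    assert hits == [(3, "-")]  # PAM occupies the first three forward bases


def test_locate_protospacer_matches_bruteforce():
    rng = np.random.default_rng(5)
    for _ in range(30):
        ref = _rand_dna(rng, 150)
        # a guide sampled from the reference itself plus a foreign one
        p = int(rng.integers(0, 120))
        for proto in (ref[p:p + 20], _rand_dna(rng, 20)):
            g = _guide(proto)
            assert ac.locate_protospacer(
                NucleotideSequence(ref), g
            ) == _brute_protospacer(ref, g)


def test_embedded_pig_guide_hits_once(hhex_like):
    design, _, _, _ = hhex_like
    for g in PIG_HHEX_GUIDES:
        hits = ac.locate_protospacer(design.reference, g)
        assert len(hits) == 1
        assert hits == _brute_protospacer(design.reference.bases, g)


def test_predict_cut_site_forward_definition():
    g = _guide("A" * 20)
    assert ac.predict_cut_site((0, "+"), g) == 17


def test_predict_cut_site_cut_and_rejoin_identity():
    proto = "ACGTTTGCACGTACGAACGT"
    ref = reverse_complement(proto + "TGG") + "CCCC"
    g = _guide(proto)
    (hit,) = ac.locate_protospacer(NucleotideSequence(ref), g)
    cut = ac.predict_cut_site(hit, g)
    assert 0 <= cut <= len(ref)
    assert ref[:cut] + ref[cut:] == ref


def test_predict_cut_site_mirror_symmetry():
    """Reverse-strand cuts re-derived independently by mirroring the whole
    reference and cutting on the forward strand there."""
    rng = np.random.default_rng(9)
    for _ in range(20):
        ref = _rand_dna(rng, 90)
        p = int(rng.integers(0, 60))
        g = _guide(ref[p:p + 20])
        for hit in ac.locate_protospacer(NucleotideSequence(ref), g):
            cut = ac.predict_cut_site(hit, g)
            mirrored_ref = reverse_complement(ref)
            mirrored_hits = ac.locate_protospacer(NucleotideSequence(mirrored_ref), g)
            mirrored_cuts = {
                len(ref) - ac.predict_cut_site(h, g) for h in mirrored_hits
            }
            assert cut in mirrored_cuts


# ---------------------------------------------------------------------------
# dual-guide deletion

def _design_with_cuts(rng, length, cut1, cut2):
    """Random reference engineered so two guides cut exactly at cut1/cut2."""
    while True:
        ref = list(_rand_dna(rng, length))
        for cut in (cut1, cut2):
            ref[cut + 4], ref[cut + 5] = "G", "G"  # NGG PAM 3 bp 3' of the cut
        s = "".join(ref)
        guides = tuple(_guide(s[c - 17:c + 3]) for c in (cut1, cut2))
        design = ac.EditDesign(reference=NucleotideSequence(s), guides=guides)
        try:
            for g in guides:
                hits = ac.locate_protospacer(design.reference, g)
                assert len(hits) == 1 and hits[0][1] == "+"
        except AssertionError:
            continue  # rare duplicate placement; redraw
        return design


def test_dual_guide_deletion_arithmetic():
    rng = np.random.default_rng(3)
    design = _design_with_cuts(rng, 100, 30, 60)
    allele = ac.predict_dual_guide_deletion(design)
    assert len(allele.sequence) == 70
    assert allele.edit_ops == ((30, 30, ""),)
    assert allele.sequence.bases == design.reference.bases[:30] + design.reference.bases[60:]


@pytest.mark.parametrize("cut1,cut2", [(20, 28), (20, 35), (25, 44), (18, 50), (30, 41)])
def test_dual_guide_deletion_length_rule(cut1, cut2):
    rng = np.random.default_rng(cut1 * 100 + cut2)
    design = _design_with_cuts(rng, 80, cut1, cut2)
    allele = ac.predict_dual_guide_deletion(design)
    assert len(allele.sequence) == 80 - (cut2 - cut1)


def test_dual_guide_deletion_ambiguous_and_degenerate():
    rng = np.random.default_rng(8)
    base = _design_with_cuts(rng, 100, 30, 60)
    doubled = ac.EditDesign(
        reference=NucleotideSequence(base.reference.bases + base.reference.bases),
        guides=base.guides,
    )
    with pytest.raises(AmbiguousDesignError):
        ac.predict_dual_guide_deletion(doubled)
    same = ac.EditDesign(reference=base.reference, guides=(base.guides[0],) * 2)
    with pytest.raises(DegenerateDesignError):
        ac.predict_dual_guide_deletion(same)


def test_pig_like_deletion_stops_in_exon3(hhex_like):
    """The dual-guide deletion allele of the HHEX-like gene carries a
    premature stop codon inside the designated exon-3 interval."""
    design, allele, stop, lifted_e3 = hhex_like
    assert stop is not None and stop.codon in STOP_CODONS
    assert lifted_e3[0] <= stop.allele_position < lifted_e3[1]
    # and the unedited gene does not
    wt = ac.EditedAllele(design.reference, (), "WT", design.reference)
    assert ac.find_premature_stop(wt, design.coding_frames) is None


# ---------------------------------------------------------------------------
# HDR insertion

def test_hdr_insertion_creates_single_hindiii_site():
    rng = np.random.default_rng(12)
    while True:
        ref = _rand_dna(rng, 120)
        if "AAGCTT" not in ref and "AAGCTT" not in reverse_complement(ref):
            break
    design = ac.EditDesign(
        reference=NucleotideSequence(ref), hdr_insert=STOP_HINDIII_INSERT
    )
    allele = ac.apply_hdr_insertion(design, 60)
    assert allele.sequence.bases.count("AAGCTT") == 1
    fragments = ac.digest(allele.sequence, BUILTIN_ENZYMES["HindIII"])
    assert len(fragments) == 2 and sum(fragments) == len(allele.sequence)


def test_hdr_insertion_empty_insert_is_identity():
    ref = NucleotideSequence("ACGTACGTAC")
    design = ac.EditDesign(reference=ref, hdr_insert="")
    allele = ac.apply_hdr_insertion(design, 4)
    assert allele.sequence.bases == ref.bases


def test_hdr_insertion_missing_insert_errors():
    design = ac.EditDesign(reference=NucleotideSequence("ACGTACGT"))
    with pytest.raises(ConfigurationError):
        ac.apply_hdr_insertion(design, 2)


@given(
    st.text(alphabet="ACGT", min_size=10, max_size=80),
    st.text(alphabet="ACGT", min_size=1, max_size=12),
    st.integers(min_value=0, max_value=200),
)
@settings(max_examples=80, deadline=None)
def test_hdr_insertion_length_conservation(ref, ins, point):
    point = point % (len(ref) + 1)
    design = ac.EditDesign(reference=NucleotideSequence(ref), hdr_insert=ins)
    allele = ac.apply_hdr_insertion(design, point)
    assert len(allele.sequence) == len(ref) + len(ins)


# ---------------------------------------------------------------------------
# edit-op round trip

@given(st.data())
@settings(max_examples=60, deadline=None)
def test_edit_ops_round_trip(data):
    """EditedAllele construction re-applies edit_ops and must reproduce the
    allele byte-for-byte (enforced by its invariant check)."""
    rng_ref = data.draw(st.text(alphabet="ACGT", min_size=20, max_size=60))
    pos = data.draw(st.integers(0, len(rng_ref) - 5))
    dl = data.draw(st.integers(0, min(4, len(rng_ref) - pos)))
    ins = data.draw(st.text(alphabet="ACGT", max_size=5))
    if dl == 0 and not ins:
        ops = ()
    else:
        ops = ((pos, dl, ins),)
    seq = apply_edit_ops(rng_ref, ops)
    allele = ac.EditedAllele(
        NucleotideSequence(seq) if seq else NucleotideSequence("A"),
        ops if seq else (),
        "x",
        NucleotideSequence(rng_ref),
    )
    assert apply_edit_ops(rng_ref, allele.edit_ops) == allele.sequence.bases


# ---------------------------------------------------------------------------
# premature stop detection

def test_stop_insert_at_codon_boundary():
    # CDS: ATG + 5 benign codons + TAA; knock TAAGCTT in after codon 1
    cds = "ATG" + "GCAGGAGCAGGAGCA" + "TAA"
    ref = "CC" + cds + "GG"
    frames = ((2, 2 + len(cds), 0),)
    design = ac.EditDesign(
        reference=NucleotideSequence(ref),
        hdr_insert=STOP_HINDIII_INSERT,
        coding_frames=frames,
    )
    allele = ac.apply_hdr_insertion(design, 2 + 3)  # after ATG
    stop = ac.find_premature_stop(allele, frames)
    assert stop is not None
    assert stop.codon == "TAA" and stop.codon_index == 1


def test_no_stop_in_unedited_orf():
    cds = "ATGGCAGGAGCATAA"
    ref = "AA" + cds + "TT"
    frames = ((2, 2 + len(cds), 0),)
    wt = ac.EditedAllele(
        NucleotideSequence(ref), (), "WT", NucleotideSequence(ref)
    )
    assert ac.find_premature_stop(wt, frames) is None


def _brute_first_stop(cds):
    for i in range(0, len(cds) - 2, 3):
        if cds[i:i + 3] in STOP_CODONS:
            return i
    return None


@pytest.mark.parametrize("del_len", [1, 2])
@pytest.mark.parametrize("del_at", [6, 9, 18])
def test_frameshift_stop_matches_bruteforce_translation(del_len, del_at):
    """Frameshifting deletions: stop position equals brute-force translation
    of the mutated coding string."""
    rng = np.random.default_rng(del_len * 31 + del_at)
    benign = ["GCA", "GGA", "CTT", "ACC", "CTA", "AAC", "TCA"]
    while True:
        cds = "ATG" + "".join(rng.choice(benign) for _ in range(30)) + "TAA"
        if _brute_first_stop(cds) == len(cds) - 3:
            break
    ref = "GG" + cds + "CC"
    frames = ((2, 2 + len(cds), 0),)
    ops = ((2 + del_at, del_len, ""),)
    allele = ac.EditedAllele(
        NucleotideSequence(apply_edit_ops(ref, ops)), ops, "del",
        NucleotideSequence(ref),
    )
    stop = ac.find_premature_stop(allele, frames)
    # independent oracle: splice the deletion into the CDS string directly
    mut_cds = cds[:del_at] + cds[del_at + del_len:]
    oracle_off = _brute_first_stop(mut_cds)
    natural_in_mut = (len(cds) - 3) - del_len  # old stop slid left
    if oracle_off is not None and oracle_off < natural_in_mut:
        assert stop is not None and stop.codon_index == oracle_off // 3
        assert stop.codon == mut_cds[oracle_off:oracle_off + 3]
    else:
        assert stop is None


# ---------------------------------------------------------------------------
# digestion

def test_digest_single_site_arithmetic():
    k = 50
    seq = NucleotideSequence("G" * k + "AAGCTT" + "C" * 44)
    assert ac.digest(seq, BUILTIN_ENZYMES["HindIII"]) == [k + 1, 100 - k - 1]


def test_digest_no_site_returns_whole_sequence():
    seq = NucleotideSequence("G" * 60)
    assert ac.digest(seq, BUILTIN_ENZYMES["HindIII"]) == [60]


def test_digest_empty_sequence_errors():
    with pytest.raises(ValueError):
        NucleotideSequence("")


def _brute_cut_positions(seq, enzyme):
    """Independent positional scanner with the same site-dedup convention."""
    m = len(enzyme.recognition)

    def matches(pattern, s, p):
        return all(
            s[p + i] in IUPAC_EXPAND[c] + ("N" if c == "N" else "")
            for i, c in enumerate(pattern)
        )

    fwd = {p for p in range(len(seq) - m + 1) if matches(enzyme.recognition, seq, p)}
    cuts = {p + enzyme.cut_index for p in fwd}
    rc_pat = reverse_complement(enzyme.recognition)
    for p in range(len(seq) - m + 1):
        if matches(rc_pat, seq, p) and p not in fwd:
            cuts.add(p + m - enzyme.cut_index)
    return sorted(c for c in cuts if 0 < c < len(seq))


@pytest.mark.parametrize(
    "enzyme",
    [
        BUILTIN_ENZYMES["HindIII"],
        RestrictionEnzyme("BslI-like", "CCNNNNNNNGG", 7),
        RestrictionEnzyme("nonpal", "GGTCTC", 1),
    ],
)
def test_digest_matches_bruteforce(enzyme):
    rng = np.random.default_rng(hash(enzyme.name) % 2**31)
    for _ in range(40):
        s = _rand_dna(rng, 200)
        assert cut_positions(s, enzyme) == _brute_cut_positions(s, enzyme)
        frags = ac.digest(NucleotideSequence(s), enzyme)
        assert sum(frags) == len(s)


def test_digest_agrees_with_biopython_restriction():
    from Bio.Restriction import HindIII as BioHindIII
    from Bio.Seq import Seq

    rng = np.random.default_rng(17)
    for _ in range(20):
        s = _rand_dna(rng, 300)
        ours = ac.digest(NucleotideSequence(s), BUILTIN_ENZYMES["HindIII"])
        theirs = [len(f) for f in BioHindIII.catalyse(Seq(s))]
        assert ours == theirs


@given(st.text(alphabet="ACGTN", min_size=1, max_size=120))
@settings(max_examples=80, deadline=None)
def test_digest_length_conservation(s):
    for enzyme in BUILTIN_ENZYMES.values():
        assert sum(ac.digest(NucleotideSequence(s), enzyme)) == len(s)


# ---------------------------------------------------------------------------
# RFLP genotyping

def test_rflp_genotype_cases():
    assert ac.rflp_genotype([187], [95, 99], [95, 99]) == "bi-allelic edited"
    assert ac.rflp_genotype([187], [95, 99], [187, 95, 99]) == "heterozygous"
    assert ac.rflp_genotype([187], [95, 99], [150]) == "inconclusive"
    assert ac.rflp_genotype([187], [95, 99], [187]) == "WT"


def test_rflp_genotype_tolerance():
    assert ac.rflp_genotype([187], [95, 99], [93, 101], tolerance_bp=2) == "bi-allelic edited"


def test_locate_talen_window():
    arms = ac.PIG_HHEX_TALEN
    rng = np.random.default_rng(21)
    filler = _rand_dna(rng, 40)
    spacer = _rand_dna(rng, 16)
    ref = NucleotideSequence(
        filler + arms.left_arm.bases + spacer
        + reverse_complement(arms.right_arm.bases) + filler[:30]
    )
    start, end = ac.locate_talen_window(ref, arms)
    assert (start, end) == (40 + len(arms.left_arm), 40 + len(arms.left_arm) + 16)
    with pytest.raises(AmbiguousDesignError):
        ac.locate_talen_window(NucleotideSequence(_rand_dna(rng, 80)), arms)


def test_rflp_undiagnosable_design():
    with pytest.raises(UndiagnosableDesignError):
        ac.rflp_genotype([100, 87], [99, 88], [100], tolerance_bp=5)


# ---------------------------------------------------------------------------
# coordinate lifting

def test_lift_coordinate_through_indels():
    ops = ((10, 5, ""), (30, 0, "AAA"))
    assert lift_coordinate(ops, 5) == 5
    assert lift_coordinate(ops, 12) == 10   # inside the deletion collapses
    assert lift_coordinate(ops, 20) == 15
    assert lift_coordinate(ops, 40) == 38   # -5 +3
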