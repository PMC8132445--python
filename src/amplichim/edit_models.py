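"""Engineered-allele prediction and PCR-RFLP genotyping.

This module models the three editing strategies used to knock out HHEX in the
HHEX knockout systems this package was built around:

* dual-guide SpCas9 cutting with a stitch repair oligo that fuses the two cut
  ends, producing one large deletion (pig zygote microinjection);
* TALEN-mediated HDR knocking a stop-codon cassette (``TAAGCTT``, which
  completes a HindIII site against a downstream template T) into the target
  exon (pig fibroblast editing for SCNT);
* single-guide Cas9 indels (mouse zygotes), whose outcomes are represented
  directly as edit operations.

Predicted alleles are checked for premature stop codons against a coding-frame
annotation, and an enzyme-agnostic in-silico digest supports RFLP genotyping
(HindIII for the knock-in, BslI or any user-supplied enzyme for the mouse
locus).

Coordinates are 0-based, half-open; cut sites are inter-base gap indices.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .errors import (
    AmbiguousDesignError,
    AnnotationError,
    ConfigurationError,
    DegenerateDesignError,
    UndiagnosableDesignError,
)
from .sequences import NucleotideSequence, iupac_find, reverse_complement

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

#: (position, deleted_length, inserted_sequence) in reference coordinates
EditOp = tuple[int, int, str]


# ---------------------------------------------------------------------------
# design types

@dataclass(frozen=True)
class Guide:
    """An SpCas9-style guide: 20-nt protospacer, PAM pattern, blunt cut offset.

    ``cut_offset`` is counted in bases 5' of the PAM-proximal protospacer end
    (3 for SpCas9, i.e. a cut between protospacer positions 17 and 18).
    """

    protospacer: NucleotideSequence
    pam: str = "NGG"
    cut_offset: int = 3

    def __post_init__(self) -> None:
        if len(self.protospacer) != 20:
            raise ConfigurationError(
                f"protospacer must be 20 nt, got {len(self.protospacer)}"
            )
        if not 0 <= self.cut_offset <= len(self.protospacer):
            raise ConfigurationError("cut_offset outside protospacer")


@dataclass(frozen=True)
class TalenPair:
    """Two TALEN arms binding opposite strands around a spacer."""

    left_arm: NucleotideSequence
    right_arm: NucleotideSequence
    spacer_min: int = 12
    spacer_max: int = 25

    def __post_init__(self) -> None:
        if self.spacer_min > self.spacer_max:
            raise ConfigurationError("spacer_min > spacer_max")


@dataclass(frozen=True)
class EditDesign:
    """A reference plus the editing reagents targeted at it.

    ``coding_frames`` lists (start, end, frame) intervals of coding sequence in
    reference coordinates, in transcript order.
    """

    reference: NucleotideSequence
    guides: tuple[Guide, ...] = ()
    talen: Optional[TalenPair] = None
    #: repair-template payload; a plain (possibly empty) string is accepted,
    #: None means the design has no HDR component
    hdr_insert: NucleotideSequence | str | None = None
    coding_frames: tuple[tuple[int, int, int], ...] = ()

    def __post_init__(self) -> None:
        for start, end, frame in self.coding_frames:
            if not (0 <= start < end <= len(self.reference)):
                raise AnnotationError(
                    f"coding interval [{start}, {end}) outside reference"
                )
            if frame not in (0, 1, 2):
                raise AnnotationError(f"invalid frame {frame}")


@dataclass(frozen=True)
class EditedAllele:
    """A concrete edited sequence plus the operations that produced it."""

    sequence: NucleotideSequence
    edit_ops: tuple[EditOp, ...]
    description: str
    reference: NucleotideSequence

    def __post_init__(self) -> None:
        rebuilt = apply_edit_ops(self.reference.bases, self.edit_ops)
        if rebuilt != self.sequence.bases:
            raise ValueError("edit_ops do not reproduce allele sequence")


@dataclass(frozen=True)
class RestrictionEnzyme:
    """IUPAC recognition pattern with the top-strand cut offset into the site."""

    name: str
    recognition: str
    cut_index: int

    def __post_init__(self) -> None:
        if not self.recognition:
            raise ConfigurationError("empty recognition pattern")


#: enzymes bundled with the package; extend via read_enzyme_table()
BUILTIN_ENZYMES: dict[str, RestrictionEnzyme] = {
    "HindIII": RestrictionEnzyme("HindIII", "AAGCTT", 1),
    "EcoRI": RestrictionEnzyme("EcoRI", "GAATTC", 1),
}


def read_enzyme_table(path) -> dict[str, RestrictionEnzyme]:
    """Parse a TSV enzyme table (name, IUPAC site, top-strand cut index)."""
    table: dict[str, RestrictionEnzyme] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, site, cut = line.split("\t")[:3]
            table[name] = RestrictionEnzyme(name, site, int(cut))
    return table


# ---------------------------------------------------------------------------
# published HHEX knockout reagents (DNA-transliterated where printed as RNA)

MOUSE_HHEX_GUIDE = Guide(NucleotideSequence("CCACAGGCAAGCCCTTGCTC", "mmHHEX_g2.1"))
PIG_HHEX_GUIDES = (
    Guide(NucleotideSequence("CAATGACCAGACCATTGAGC", "ssHHEX_g2.4")),
    Guide(NucleotideSequence("AGGCAGGTGAGCTCGCTCAG", "ssHHEX_g2.5")),
)
PIG_HHEX_TALEN = TalenPair(
    left_arm=NucleotideSequence("TGGAGCCCCTTCCTTC", "talen_left"),
    right_arm=NucleotideSequence("AGCCACTCTTGCCCAC", "talen_right"),
)
#: stop-codon knock-in cassette; completes AAGCTT when the 3' flank starts with T
STOP_HINDIII_INSERT = NucleotideSequence("TAAGCTT", "stop_hindiii")


# ---------------------------------------------------------------------------
# edit-op plumbing

def apply_edit_ops(reference: str, ops: Sequence[EditOp]) -> str:
    """Apply (position, deleted_length, insertion) ops to a reference string."""
    out = reference
    for pos, dl, ins in sorted(ops, reverse=True):
        if not (0 <= pos <= len(reference) and pos + dl <= len(reference)):
            raise ValueError(f"edit op ({pos}, {dl}, {ins!r}) outside reference")
        out = out[:pos] + ins + out[pos + dl:]
    return out


def lift_coordinate(ops: Sequence[EditOp], x: int) -> int:
    """Map a reference coordinate onto the edited allele.

    Coordinates inside a deletion collapse to the deletion point. An insertion
    exactly at ``x`` is placed after the mapped coordinate (so interval ends at
    an insertion point exclude the inserted bases, interval interiors include
    them).
    """
    delta = 0
    for pos, dl, ins in sorted(ops):
        if x <= pos:
            break
        if x >= pos + dl:
            delta += len(ins) - dl
        else:  # inside the deleted span
            return pos + delta
    return x + delta


# ---------------------------------------------------------------------------
# protospacer search and cut prediction

def locate_protospacer(
    reference: NucleotideSequence, guide: Guide
) -> list[tuple[int, str]]:
    """Every exact protospacer+PAM occurrence on either strand.

    Positions are 0-based forward-strand coordinates of the protospacer span's
    leftmost base. Returns an empty list when the guide does not anchor.
    """
    ref = reference.bases
    proto = guide.protospacer.bases
    hits: list[tuple[int, str]] = []
    fwd = proto + guide.pam
    for p in iupac_find(fwd, ref):
        hits.append((p, "+"))
    # reverse-strand site: the forward strand carries revcomp(PAM)+revcomp(proto)
    rc_pattern = reverse_complement(guide.pam) + reverse_complement(proto)
    for p in iupac_find(rc_pattern, ref):
        hits.append((p + len(guide.pam), "-"))
    return sorted(hits)


def predict_cut_site(hit: tuple[int, str], guide: Guide) -> int:
    """Blunt-cut inter-base coordinate for a protospacer hit.

    For a forward hit the cut falls ``cut_offset`` bases 5' of the PAM, i.e. at
    gap index ``position + len(protospacer) - cut_offset``; reverse-strand hits
    mirror this geometry.
    """
    pos, strand = hit
    n = len(guide.protospacer)
    if strand == "+":
        cut = pos + n - guide.cut_offset
    elif strand == "-":
        cut = pos + guide.cut_offset
    else:
        raise ValueError(f"invalid strand {strand!r}")
    if pos < 0:
        raise IndexError("hit outside reference")
    return cut


def locate_talen_window(
    reference: NucleotideSequence, talen: TalenPair
) -> tuple[int, int]:
    """Locate the TALEN spacer as (start, end) between the two arm sites.

    The left arm binds the forward strand; the right arm binds the reverse
    strand (matched as its reverse complement on the forward strand). Exactly
    one geometry-compatible placement is required.
    """
    ref = reference.bases
    lefts = iupac_find(talen.left_arm.bases, ref)
    rights = iupac_find(reverse_complement(talen.right_arm.bases), ref)
    placements = [
        (l + len(talen.left_arm), r)
        for l in lefts
        for r in rights
        if talen.spacer_min <= r - (l + len(talen.left_arm)) <= talen.spacer_max
    ]
    if len(placements) != 1:
        raise AmbiguousDesignError(
            f"{len(placements)} compatible TALEN placements (need exactly 1)"
        )
    return placements[0]


# ---------------------------------------------------------------------------
# allele prediction

def _single_hit(reference: NucleotideSequence, guide: Guide) -> tuple[int, str]:
    hits = locate_protospacer(reference, guide)
    if len(hits) != 1:
        name = guide.protospacer.name or guide.protospacer.bases
        raise AmbiguousDesignError(
            f"guide {name}: {len(hits)} hits on reference (need exactly 1)"
        )
    return hits[0]


def predict_dual_guide_deletion(design: EditDesign) -> EditedAllele:
    """Deletion allele from two guides with a stitch oligo fusing the cut ends.

    The stitch repair template joins the two blunt cut ends directly (no
    micro-homology trimming), so the allele is
    ``reference[:min_cut] + reference[max_cut:]``.
    """
    if len(design.guides) != 2:
        raise ConfigurationError("dual-guide deletion needs exactly two guides")
    cuts = [
        predict_cut_site(_single_hit(design.reference, g), g)
        for g in design.guides
    ]
    lo, hi = min(cuts), max(cuts)
    if lo == hi:
        raise DegenerateDesignError("guides cut at the same position")
    ops: tuple[EditOp, ...] = ((lo, hi - lo, ""),)
    seq = apply_edit_ops(design.reference.bases, ops)
    return EditedAllele(
        sequence=NucleotideSequence(seq, f"{design.reference.name}_del"),
        edit_ops=ops,
        description=f"del[{lo},{hi})",
        reference=design.reference,
    )


def apply_hdr_insertion(design: EditDesign, insertion_point: int) -> EditedAllele:
    """Splice the HDR cassette into the reference at ``insertion_point``."""
    if design.hdr_insert is None:
        raise ConfigurationError("design has no hdr_insert")
    if not 0 <= insertion_point <= len(design.reference):
        raise IndexError("insertion point outside reference")
    ins = str(design.hdr_insert)
    ops: tuple[EditOp, ...] = ((insertion_point, 0, ins),) if ins else ()
    seq = apply_edit_ops(design.reference.bases, ops)
    return EditedAllele(
        sequence=NucleotideSequence(seq, f"{design.reference.name}_hdr"),
        edit_ops=ops,
        description=f"ins{len(ins)}@{insertion_point}",
        reference=design.reference,
    )


# ---------------------------------------------------------------------------
# premature stop detection

@dataclass(frozen=True)
class PrematureStop:
    codon_index: int      # 0-based codon position within the coding sequence
    allele_position: int  # allele coordinate of the codon's first base
    codon: str


def _coding_segments(
    seq: str, intervals: Sequence[tuple[int, int]]
) -> tuple[str, list[tuple[int, int]]]:
    """Concatenate coding intervals; return (cds, list of (cds_offset, seq_start))."""
    parts: list[str] = []
    index: list[tuple[int, int]] = []
    off = 0
    for start, end in intervals:
        if not (0 <= start <= end <= len(seq)):
            raise AnnotationError(f"interval [{start}, {end}) outside sequence")
        index.append((off, start))
        parts.append(seq[start:end])
        off += end - start
    return "".join(parts), index


def _cds_offset_to_coord(index: list[tuple[int, int]], intervals, off: int) -> int:
    for (o, s), (start, end) in zip(reversed(index), reversed(list(intervals))):
        if off >= o:
            return s + (off - o)
    raise AnnotationError("offset outside coding sequence")


def _first_stop(cds: str, frame: int) -> Optional[int]:
    """CDS offset of the first in-frame stop codon, or None."""
    for i in range(frame, len(cds) - 2, 3):
        if cds[i:i + 3] in STOP_CODONS:
            return i
    return None


def find_premature_stop(
    allele: EditedAllele,
    coding_frames: Sequence[tuple[int, int, int]],
) -> Optional[PrematureStop]:
    """First in-frame stop codon arising before the annotated natural stop.

    The coding intervals (given in reference coordinates) are lifted through
    the allele's edit operations, concatenated and translated in frame. A stop
    is premature when its allele coordinate precedes the lifted position of
    the reference's own first in-frame stop (or, when the annotation contains
    no stop, the end of the coding region). Returns None when translation is
    unchanged through the annotated region.
    """
    if not coding_frames:
        raise AnnotationError("no coding intervals supplied")
    frame = coding_frames[0][2]
    ref = allele.reference.bases
    ref_intervals = [(s, e) for s, e, _ in coding_frames]
    ref_cds, ref_index = _coding_segments(ref, ref_intervals)

    lifted = [
        (lift_coordinate(allele.edit_ops, s), lift_coordinate(allele.edit_ops, e))
        for s, e in ref_intervals
    ]
    alle_cds, alle_index = _coding_segments(allele.sequence.bases, lifted)
    if len(alle_cds) < 3:
        raise AnnotationError("coding region vanished after editing")

    nat_off = _first_stop(ref_cds, frame)
    if nat_off is not None:
        nat_ref_coord = _cds_offset_to_coord(ref_index, ref_intervals, nat_off)
        boundary = lift_coordinate(allele.edit_ops, nat_ref_coord)
    else:
        boundary = lifted[-1][1]

    off = _first_stop(alle_cds, frame)
    if off is None:
        return None
    coord = _cds_offset_to_coord(alle_index, lifted, off)
    if coord < boundary:
        return PrematureStop(
            codon_index=(off - frame) // 3,
            allele_position=coord,
            codon=alle_cds[off:off + 3],
        )
    return None


# ---------------------------------------------------------------------------
# restriction digest and RFLP genotyping

def cut_positions(seq: str, enzyme: RestrictionEnzyme) -> list[int]:
    """Deduplicated top-strand cut coordinates for every double-strand site.

    The recognition pattern is matched on both strands; a reverse-strand match
    coinciding with a forward match (palindromic site) counts once, cut at the
    forward geometry. Cuts falling on the molecule ends are dropped.
    """
    m = len(enzyme.recognition)
    fwd = set(iupac_find(enzyme.recognition, seq))
    cuts = {p + enzyme.cut_index for p in fwd}
    rc_pattern = reverse_complement(enzyme.recognition)
    for p in iupac_find(rc_pattern, seq):
        if p in fwd:
            continue  # same double-strand site as a forward match
        cuts.add(p + m - enzyme.cut_index)
    return sorted(c for c in cuts if 0 < c < len(seq))


def digest(seq: NucleotideSequence, enzyme: RestrictionEnzyme) -> list[int]:
    """Fragment lengths (5'->3') of a linear digest; lengths sum to len(seq)."""
    s = seq.bases
    cuts = cut_positions(s, enzyme)
    bounds = [0] + cuts + [len(s)]
    return [b - a for a, b in zip(bounds, bounds[1:])]


def _band_match(observed: Sequence[int], expected: Sequence[int], tol: int) -> bool:
    """Do two band patterns coincide within +/- tol bp (set semantics)?"""
    return all(any(abs(o - e) <= tol for e in expected) for o in observed) and all(
        any(abs(o - e) <= tol for o in observed) for e in expected
    )


def rflp_genotype(
    wt_fragments: Sequence[int],
    edited_fragments: Sequence[int],
    observed_fragments: Sequence[int],
    tolerance_bp: int = 5,
) -> str:
    """Classify an observed band pattern against WT and edited expectations.

    Returns one of ``"WT"``, ``"heterozygous"``, ``"bi-allelic edited"`` or
    ``"inconclusive"``. Band patterns are compared as sets within
    ``tolerance_bp`` (gel logic: co-migrating fragments are one band).
    """
    if _band_match(wt_fragments, edited_fragments, tolerance_bp):
        raise UndiagnosableDesignError(
            "WT and edited alleles give indistinguishable fragment patterns"
        )
    both = list(wt_fragments) + list(edited_fragments)
    if _band_match(observed_fragments, wt_fragments, tolerance_bp):
        return "WT"
    if _band_match(observed_fragments, edited_fragments, tolerance_bp):
        return "bi-allelic edited"
    if _band_match(observed_fragments, both, tolerance_bp):
        return "heterozygous"
    return "inconclusive"
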