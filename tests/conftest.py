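"""Shared fixtures: a study-like marker panel, small simulated runs, and a
synthetic HHEX-like gene carrying the published pig guide sites."""

from __future__ import annotations

import numpy as np
import pytest

import amplichim as ac
from amplichim.edit_models import PIG_HHEX_GUIDES
from amplichim.sequences import NucleotideSequence

_STOP_FREE_CODONS = ["GCT", "GGA", "CTT", "ACC", "GAC", "TTC", "CCA", "GTC"]


def _build_hhex_like(seed: int):
    """A three-exon gene with both pig guide sites embedded in exon 2 so the
    dual-guide deletion frameshifts and the first new stop lands in exon 3.

    Deterministic search over filler seeds; mirrors how a real knockout is
    designed around a fixed reference.
    """
    g1 = PIG_HHEX_GUIDES[0].protospacer.bases
    g2 = PIG_HHEX_GUIDES[1].protospacer.bases
    rng = np.random.default_rng(seed)

    def codons(n):
        return "".join(rng.choice(_STOP_FREE_CODONS) for _ in range(n))

    # exon-2 layout: pad | g1+AGG | spacer | g2+TGG | pad. Pad/spacer lengths
    # phase both guides so the WT reading frame is stop-free, and size the
    # inter-cut deletion at 41 bp (not a multiple of 3): the frameshift makes
    # the exon-3 cassette GCTAAC (benign in frame: Ala-Asn) read ...T AAC ->
    # TAA, i.e. the knockout is *designed* to stop in the middle of exon 3.
    for attempt in range(200):
        e1 = "ATG" + codons(9)                      # 30 bp, frame-0 start
        pad_a = codons(4) + "C"                     # 13 bp: g1 at codon phase 1
        spacer = codons(6)                          # 18 bp: 41-bp deletion
        pad_b = codons(4) + "C"                     # 13 bp: exon2 = 90 bp
        e2 = pad_a + g1 + "AGG" + spacer + g2 + "TGG" + pad_b
        e3 = codons(8) + "GCTAAC" + codons(29) + "TAA"
        i1 = codons(10)
        i2 = codons(10)
        ref = codons(3) + e1 + i1 + e2 + i2 + e3 + codons(3)
        s1 = 9
        s2 = s1 + len(e1) + len(i1)
        s3 = s2 + len(e2) + len(i2)
        frames = (
            (s1, s1 + len(e1), 0),
            (s2, s2 + len(e2), (3 - len(e1) % 3) % 3),
            (s3, s3 + len(e3), (3 - (len(e1) + len(e2)) % 3) % 3),
        )
        design = ac.EditDesign(
            reference=NucleotideSequence(ref, "hhex_like"),
            guides=PIG_HHEX_GUIDES,
            coding_frames=frames,
        )
        # WT coding sequence must translate cleanly up to its terminal TAA
        wt_cds = e1 + e2 + e3
        stops = [
            i for i in range(0, len(wt_cds) - 2, 3)
            if wt_cds[i:i + 3] in ac.edit_models.STOP_CODONS
        ]
        if stops != [len(wt_cds) - 3]:
            continue  # filler drew an internal stop; re-draw
        try:
            allele = ac.predict_dual_guide_deletion(design)
        except ac.errors.AmplichimError:
            continue
        stop = ac.find_premature_stop(allele, frames)
        if stop is None:
            continue
        lifted_e3 = (
            ac.edit_models.lift_coordinate(allele.edit_ops, s3),
            ac.edit_models.lift_coordinate(allele.edit_ops, s3 + len(e3)),
        )
        if lifted_e3[0] <= stop.allele_position < lifted_e3[1]:
            return design, allele, stop, lifted_e3
        rng = np.random.default_rng(seed + attempt + 1)
    raise RuntimeError("could not construct hhex-like fixture")


@pytest.fixture(scope="session")
def hhex_like():
    """(design, deletion_allele, premature_stop, lifted_exon3_interval)."""
    return _build_hhex_like(seed=11)


@pytest.fixture(scope="session")
def panel():
    return ac.default_panel()


@pytest.fixture(scope="session")
def small_run(panel):
    """A 4-sample multiplexed run at modest depth with 0.5% error, processed
    through demux; returns (samples, demux result)."""
    samples = ac.make_samples(
        panel, [0.0, 0.23, 0.87, 1.0], depth=3000, error_rate=0.005, seed=42
    )
    batch = ac.simulate_run(ac.SimConfig(panel=panel, samples=samples))
    result = ac.demultiplex(batch, ac.barcode_pairs_from_truth(samples))
    return samples, result
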