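"""Synthetic barcoded dual-amplicon read sets with known ground truth.

The generator emulates the data-generating process of a chimerism assay on
complemented embryos: every cell in a sample is either donor-derived or
host-derived. Two amplicons are sequenced per sample,

* an informative-SNP amplicon (257-bp class) where donor cells are
  heterozygous at two positions (e.g. G/A and C/T) and host cells are
  homozygous for the reference base, and
* an edited-locus amplicon (187-bp class) where host cells carry one or two
  distinct knockout indel alleles while donor cells are wild type.

Reads are full-amplicon single-end, flanked by 32-bp barcoded primers (20-bp
template homology, which is simply the amplicon's own terminus, plus a 12-bp
sample tag), with uniform substitution errors applied across the whole read
including the tags. Each sample carries its own seed so it can be regenerated
independently; identical truth + seed yields byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .edit_models import EditOp, apply_edit_ops
from .errors import ConfigurationError
from .reads import ReadBatch, read_fastq, write_fastq  # noqa: F401  (re-export)
from .sequences import NucleotideSequence, reverse_complement

BARCODE_LENGTH = 12
PRIMER_HOMOLOGY_LENGTH = 20
#: full barcoded primer length asserted by the primer constructor
PRIMER_LENGTH = BARCODE_LENGTH + PRIMER_HOMOLOGY_LENGTH

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_TO_IDX = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_TO_IDX[_b] = _i


# ---------------------------------------------------------------------------
# contracts

@dataclass(frozen=True)
class MarkerPanel:
    """Everything that makes chimerism computable for one host/donor pairing."""

    snp_amplicon: NucleotideSequence
    snp_positions: tuple[int, int]
    host_alleles: tuple[str, str]
    donor_alleles: tuple[str, str]
    edit_amplicon: NucleotideSequence
    donor_zygosity: float = 0.5

    def __post_init__(self) -> None:
        for p, host, donor in zip(
            self.snp_positions, self.host_alleles, self.donor_alleles
        ):
            if not 0 <= p < len(self.snp_amplicon):
                raise ConfigurationError(f"SNP position {p} outside amplicon")
            if host == donor:
                raise ConfigurationError(
                    f"host and donor alleles identical at position {p}"
                )
            if self.snp_amplicon.bases[p] != host:
                raise ConfigurationError(
                    f"reference base at {p} is not the host allele"
                )
        if not 0 < self.donor_zygosity <= 1:
            raise ConfigurationError("donor_zygosity must be in (0, 1]")


@dataclass(frozen=True)
class SampleTruth:
    """Ground truth for one simulated sample."""

    sample_id: str
    donor_fraction: float
    host_indel_alleles: tuple[EditOp, ...]
    host_allele_proportions: tuple[float, ...]
    barcode_pair: tuple[str, str]
    depth: int = 50_000
    error_rate: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.donor_fraction <= 1.0:
            raise ConfigurationError("donor_fraction outside [0, 1]")
        if len(self.host_indel_alleles) != len(self.host_allele_proportions):
            raise ConfigurationError("allele/proportion length mismatch")
        if self.host_indel_alleles and not np.isclose(
            sum(self.host_allele_proportions), 1.0
        ):
            raise ConfigurationError("host allele proportions must sum to 1")
        for tag in self.barcode_pair:
            if len(tag) != BARCODE_LENGTH:
                raise ConfigurationError(f"barcode {tag!r} is not 12 bp")
        if self.depth < 1:
            raise ConfigurationError("depth must be >= 1")


@dataclass(frozen=True)
class SimConfig:
    panel: MarkerPanel
    samples: tuple[SampleTruth, ...]
    primer_homology_length: int = PRIMER_HOMOLOGY_LENGTH
    read_layout: str = "single"

    def __post_init__(self) -> None:
        pairs = [s.barcode_pair for s in self.samples]
        if len(set(pairs)) != len(pairs):
            raise ConfigurationError("barcode pairs must be unique across samples")
        if self.read_layout != "single":
            raise ConfigurationError(
                "only single-end full-amplicon reads are implemented"
            )


def build_primer(homology: str, barcode: str) -> str:
    """Assemble a barcoded primer (12-bp tag + 20-bp template homology)."""
    if len(barcode) != BARCODE_LENGTH:
        raise ConfigurationError("barcode must be 12 bp")
    if len(homology) != PRIMER_HOMOLOGY_LENGTH:
        raise ConfigurationError("primer homology must be 20 bp")
    primer = barcode + homology
    assert len(primer) == PRIMER_LENGTH
    return primer


# ---------------------------------------------------------------------------
# defaults: an assay-like panel and samples

def _random_bases(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, n)].tobytes().decode()


def default_panel(seed: int = 20_26) -> MarkerPanel:
    """An assay-like marker panel on pseudo-random amplicon references.

    257-bp SNP amplicon with host G/C and donor-informative A/T alleles at two
    interior positions, and a 187-bp edited-locus amplicon; polymorphic and
    edited positions sit >= 30 bp from the amplicon edges.
    """
    rng = np.random.default_rng(seed)
    snp = list(_random_bases(rng, 257))
    p1, p2 = 110, 170
    snp[p1], snp[p2] = "G", "C"
    edit = _random_bases(rng, 187)
    return MarkerPanel(
        snp_amplicon=NucleotideSequence("".join(snp), "snp_amplicon"),
        snp_positions=(p1, p2),
        host_alleles=("G", "C"),
        donor_alleles=("A", "T"),
        edit_amplicon=NucleotideSequence(edit, "edit_amplicon"),
    )


def default_host_alleles(panel: MarkerPanel) -> tuple[EditOp, ...]:
    """Two distinct KO alleles at the edited locus: a 2-bp deletion and a 1-bp
    insertion near the nominal cut site, insertion base chosen to avoid
    extending a homopolymer (keeps the truth signature left-aligned)."""
    ref = panel.edit_amplicon.bases
    cut = len(ref) // 2
    ins_base = "A" if ref[cut - 1] != "A" else "G"
    return ((cut, 2, ""), (cut, 0, ins_base))


def generate_barcode_pairs(
    n: int, seed: int = 7, min_distance: int = 3
) -> list[tuple[str, str]]:
    """Random 12-bp tag pairs with pairwise Hamming distance >= min_distance
    within the forward set and within the reverse set."""
    rng = np.random.default_rng(seed)

    def tag_set(k: int) -> list[str]:
        tags: list[str] = []
        while len(tags) < k:
            cand = _random_bases(rng, BARCODE_LENGTH)
            if all(
                sum(a != b for a, b in zip(cand, t)) >= min_distance for t in tags
            ):
                tags.append(cand)
        return tags

    return list(zip(tag_set(n), tag_set(n)))


def make_samples(
    panel: MarkerPanel,
    donor_fractions: Sequence[float],
    depth: int = 50_000,
    error_rate: float = 0.005,
    seed: int = 1,
    host_alleles: Optional[tuple[EditOp, ...]] = None,
) -> tuple[SampleTruth, ...]:
    """One sample per donor fraction, with unique barcodes and per-sample seeds."""
    if host_alleles is None:
        host_alleles = default_host_alleles(panel)
    pairs = generate_barcode_pairs(len(donor_fractions), seed=seed)
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, len(donor_fractions))
    props = tuple(1.0 / len(host_alleles) for _ in host_alleles)
    return tuple(
        SampleTruth(
            sample_id=f"s{i:03d}",
            donor_fraction=float(f),
            host_indel_alleles=host_alleles,
            host_allele_proportions=props,
            barcode_pair=pairs[i],
            depth=depth,
            error_rate=error_rate,
            seed=int(seeds[i]),
        )
        for i, f in enumerate(donor_fractions)
    )


# ---------------------------------------------------------------------------
# simulation core

def _apply_substitutions(
    mat: np.ndarray, rate: float, rng: np.random.Generator
) -> None:
    """Uniform substitution errors in place; each error replaces the base with
    one of the three alternatives uniformly. Positions are drawn with
    replacement (collisions are negligible at the rates modeled)."""
    if rate <= 0:
        return
    n, width = mat.shape
    per_read = rng.binomial(width, rate, n)
    total = int(per_read.sum())
    if total == 0:
        return
    rows = np.repeat(np.arange(n), per_read)
    cols = rng.integers(0, width, total)
    old = mat[rows, cols]
    shift = rng.integers(1, 4, total)
    new = _BASES[(_BASE_TO_IDX[old] + shift) % 4]
    new[old == ord("N")] = ord("N")  # unknown bases stay unknown
    mat[rows, cols] = new


def _tile(seq: str, n: int) -> np.ndarray:
    row = np.frombuffer(seq.encode(), dtype=np.uint8)
    return np.tile(row, (n, 1))


def _with_tags(amplicon_rows: np.ndarray, truth: SampleTruth) -> np.ndarray:
    n, L = amplicon_rows.shape
    fwd, rev = truth.barcode_pair
    out = np.empty((n, L + 2 * BARCODE_LENGTH), dtype=np.uint8)
    out[:, :BARCODE_LENGTH] = np.frombuffer(fwd.encode(), dtype=np.uint8)
    out[:, BARCODE_LENGTH:BARCODE_LENGTH + L] = amplicon_rows
    out[:, BARCODE_LENGTH + L:] = np.frombuffer(
        reverse_complement(rev).encode(), dtype=np.uint8
    )
    return out


def _rows_to_strings(mat: np.ndarray) -> list[str]:
    n, width = mat.shape
    big = mat.tobytes().decode("ascii")
    return [big[i * width:(i + 1) * width] for i in range(n)]


def simulate_sample(
    panel: MarkerPanel, truth: SampleTruth
) -> tuple[ReadBatch, ReadBatch]:
    """Simulate one sample's (SNP-amplicon, edit-amplicon) read sets.

    Each read is donor-derived with probability ``donor_fraction``. Donor SNP
    reads carry the informative allele independently at each SNP with
    probability ``donor_zygosity``; host SNP reads never do (before error).
    Donor edit reads are the wild-type reference; host edit reads draw one of
    the KO indel alleles. Reads are barcoded and substitution errors applied
    uniformly across the full read, tags included.
    """
    rng = np.random.default_rng(truth.seed)
    f = truth.donor_fraction

    # --- SNP amplicon
    n = truth.depth
    mat = _tile(panel.snp_amplicon.bases, n)
    donor = rng.random(n) < f
    for pos, allele in zip(panel.snp_positions, panel.donor_alleles):
        informative = donor & (rng.random(n) < panel.donor_zygosity)
        mat[informative, pos] = ord(allele)
    full = _with_tags(mat, truth)
    _apply_substitutions(full, truth.error_rate, rng)
    order = rng.permutation(n)
    strings = _rows_to_strings(full)
    snp_batch = ReadBatch(
        ids=[f"{truth.sample_id}|snp|{i}" for i in range(n)],
        sequences=[strings[j] for j in order],
    )

    # --- edit amplicon
    ref = panel.edit_amplicon.bases
    alleles: list[tuple[str, str]] = [("WT", ref)]
    probs = [f]
    for i, (ops, prop) in enumerate(
        zip(truth.host_indel_alleles, truth.host_allele_proportions)
    ):
        alleles.append((f"KO{i + 1}", apply_edit_ops(ref, [ops])))
        probs.append((1.0 - f) * prop)
    probs_arr = np.asarray(probs)
    if probs_arr.sum() == 0:  # donor_fraction 0 with no host alleles
        raise ConfigurationError("sample has neither donor nor host alleles")
    counts = rng.multinomial(truth.depth, probs_arr / probs_arr.sum())
    seqs: list[str] = []
    labels: list[str] = []
    for (label, seq), k in zip(alleles, counts):
        if k == 0:
            continue
        rows = _tile(seq, int(k))
        full = _with_tags(rows, truth)
        _apply_substitutions(full, truth.error_rate, rng)
        seqs.extend(_rows_to_strings(full))
        labels.extend([label] * int(k))
    order = rng.permutation(len(seqs))
    edit_batch = ReadBatch(
        ids=[f"{truth.sample_id}|edit|{labels[j]}|{i}" for i, j in enumerate(order)],
        sequences=[seqs[j] for j in order],
    )
    return snp_batch, edit_batch


def simulate_run(config: SimConfig) -> ReadBatch:
    """Pooled multiplexed run: both amplicons of every sample in one batch."""
    pooled = ReadBatch()
    for truth in config.samples:
        snp_batch, edit_batch = simulate_sample(config.panel, truth)
        pooled.extend(snp_batch)
        pooled.extend(edit_batch)
    return pooled


# ---------------------------------------------------------------------------
# truth-table serialization

def _encode_alleles(truth: SampleTruth) -> str:
    parts = [
        f"{pos}:{dl}:{ins or '-'}:{prop:.10g}"
        for (pos, dl, ins), prop in zip(
            truth.host_indel_alleles, truth.host_allele_proportions
        )
    ]
    return ";".join(parts) or "-"


def _decode_alleles(text: str) -> tuple[tuple[EditOp, ...], tuple[float, ...]]:
    if text == "-" or not text:
        return (), ()
    ops: list[EditOp] = []
    props: list[float] = []
    for part in text.split(";"):
        pos, dl, ins, prop = part.split(":")
        ops.append((int(pos), int(dl), "" if ins == "-" else ins))
        props.append(float(prop))
    return tuple(ops), tuple(props)


def panel_to_json(panel: MarkerPanel, path) -> None:
    import json

    with open(path, "w") as fh:
        json.dump(
            {
                "snp_amplicon": panel.snp_amplicon.bases,
                "snp_positions": list(panel.snp_positions),
                "host_alleles": list(panel.host_alleles),
                "donor_alleles": list(panel.donor_alleles),
                "edit_amplicon": panel.edit_amplicon.bases,
                "donor_zygosity": panel.donor_zygosity,
            },
            fh,
            indent=1,
        )


def panel_from_json(path) -> MarkerPanel:
    import json

    with open(path) as fh:
        d = json.load(fh)
    return MarkerPanel(
        snp_amplicon=NucleotideSequence(d["snp_amplicon"], "snp_amplicon"),
        snp_positions=tuple(d["snp_positions"]),
        host_alleles=tuple(d["host_alleles"]),
        donor_alleles=tuple(d["donor_alleles"]),
        edit_amplicon=NucleotideSequence(d["edit_amplicon"], "edit_amplicon"),
        donor_zygosity=d.get("donor_zygosity", 0.5),
    )


def write_truth(samples: Sequence[SampleTruth], path) -> None:
    """Lossless TSV of the per-sample ground truth."""
    rows = [
        {
            "sample_id": t.sample_id,
            "donor_fraction": t.donor_fraction,
            "host_alleles": _encode_alleles(t),
            "barcode_fwd": t.barcode_pair[0],
            "barcode_rev": t.barcode_pair[1],
            "depth": t.depth,
            "error_rate": t.error_rate,
            "seed": t.seed,
        }
        for t in samples
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_truth(path) -> tuple[SampleTruth, ...]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    out = []
    for row in df.itertuples(index=False):
        ops, props = _decode_alleles(str(row.host_alleles))
        out.append(
            SampleTruth(
                sample_id=str(row.sample_id),
                donor_fraction=float(row.donor_fraction),
                host_indel_alleles=ops,
                host_allele_proportions=props,
                barcode_pair=(str(row.barcode_fwd), str(row.barcode_rev)),
                depth=int(row.depth),
                error_rate=float(row.error_rate),
                seed=int(row.seed),
            )
        )
    return tuple(out)
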