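"""Donor-fraction estimation and host-genotype inference.

The chimerism readout rests on two informative SNPs where the donor line is
heterozygous (only half its chromosomes carry the informative base) and the
host is homozygous. The estimator therefore measures the informative-allele
read fraction at each SNP, averages the SNPs, and doubles the mean — the
"doubling rule" — to obtain the donor-cell percentage.

Sequencing substitution errors put a floor of about e/3 under every base
fraction, which both biases the doubled estimate and breaks interval coverage
near 0% and 100% donor. By default the estimator corrects for this using an
internal control: at each SNP the two bases that are neither the host nor the
donor allele can only arise from error, so their mean frequency estimates the
per-base error floor, which is subtracted and rescaled,

    f = (p_inf - b) / (1 - 4 b),   b = mean frequency of the two
                                       non-allele bases  (~ e/3)

an estimate that is unbiased under the uniform substitution model. The
uncertainty of b is propagated into the Wilson interval. Set
``error_correction="none"`` for the raw read fraction.

The host compartment is read off the edited-locus spectrum: every non-WT
allele signature is host-derived (donor cells are unedited), so the non-WT
fraction estimates 100 - donor% and the number of distinct signatures
genotypes the host (two signatures, or one at the full host fraction, imply
a bi-allelic knockout).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .display import round_half_up
from .errors import InsufficientDataError
from .pipeline import AlleleEntry, AlleleSpectrum
from .synthetic_reads import MarkerPanel


def binomial_ci(
    successes: int, trials: int, level: float = 0.95
) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    if trials < 1:
        raise InsufficientDataError("Wilson interval needs trials >= 1")
    if not 0 <= successes <= trials:
        raise ValueError("successes outside [0, trials]")
    z = norm.ppf(0.5 + level / 2.0)
    p = successes / trials
    denom = 1.0 + z * z / trials
    center = (p + z * z / (2 * trials)) / denom
    half = (z / denom) * np.sqrt(p * (1 - p) / trials + z * z / (4 * trials * trials))
    lo = 0.0 if successes == 0 else max(0.0, center - half)
    hi = 1.0 if successes == trials else min(1.0, center + half)
    return (lo, hi)


# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChimerismEstimate:
    """Donor-cell percentage for one sample, with per-SNP detail."""

    sample_id: str
    per_snp_informative_fraction: tuple[float, ...]  # fractions used (corrected)
    per_snp_raw_fraction: tuple[float, ...]          # observed read fractions
    mean_fraction: float
    donor_percent: float                              # clamp(200 * mean, 0, 100)
    ci_low: float
    ci_high: float
    n_called_reads: tuple[int, ...]
    flags: tuple[str, ...] = ()

    @property
    def donor_percent_rounded(self) -> int:
        """Integer report value (the printed convention, e.g. 87)."""
        return int(round_half_up(self.donor_percent))


def donor_fraction_from_snps(
    spectrum: AlleleSpectrum,
    panel: MarkerPanel,
    min_depth: int = 100,
    error_correction: str = "background",
    ci_level: float = 0.95,
) -> ChimerismEstimate:
    """Apply the doubling rule to the SNP-amplicon spectrum.

    Per-SNP informative fraction = informative-base count / called reads
    (no-calls excluded from the denominator); SNPs with fewer than
    ``min_depth`` called reads are skipped; the unweighted mean across SNPs is
    doubled and clamped to [0, 100]. The confidence interval is a Wilson
    interval on the pooled informative reads, background-corrected in the same
    way as the point estimate, then doubled and clamped.
    """
    raw: list[float] = []
    used: list[float] = []
    called_n: list[int] = []
    flags: list[str] = []
    pooled_inf = pooled_called = pooled_other = 0

    for j, (pos, host, donor) in enumerate(
        zip(panel.snp_positions, panel.host_alleles, panel.donor_alleles)
    ):
        counts = spectrum.snp_counts[j]
        called = sum(c for b, c in counts.items() if b in "ACGT")
        if called < min_depth:
            flags.append(f"snp{j}_below_min_depth")
            continue
        n_inf = counts.get(donor, 0)
        n_other = sum(
            counts.get(b, 0) for b in "ACGT" if b not in (host, donor)
        )
        p = n_inf / called
        raw.append(p)
        called_n.append(called)
        pooled_inf += n_inf
        pooled_called += called
        pooled_other += n_other
        if error_correction == "background":
            b = n_other / (2 * called)
            used.append((p - b) / (1.0 - 4.0 * b))
        else:
            used.append(p)

    if not used:
        raise InsufficientDataError(
            f"no SNP with >= {min_depth} called reads in sample "
            f"{spectrum.sample_id!r}"
        )

    mean = float(np.mean(used))
    donor_raw = 2.0 * mean * 100.0
    donor_percent = min(100.0, max(0.0, donor_raw))
    if donor_raw > 100.0:
        flags.append("over_range")
    elif donor_raw < 0.0:
        flags.append("under_range")

    lo, hi = binomial_ci(pooled_inf, pooled_called, ci_level)
    if error_correction == "background":
        b = pooled_other / (2 * pooled_called)
        z = norm.ppf(0.5 + ci_level / 2.0)
        se_b = float(np.sqrt(max(b * (1 - b), 1e-12) / (2 * pooled_called)))
        lo, hi = lo - z * se_b, hi + z * se_b
        lo = (lo - b) / (1.0 - 4.0 * b)
        hi = (hi - b) / (1.0 - 4.0 * b)
    ci_low = min(100.0, max(0.0, 2.0 * lo * 100.0))
    ci_high = min(100.0, max(0.0, 2.0 * hi * 100.0))
    # the unweighted-mean point estimate can sit just outside the pooled
    # interval when depths differ; widen to keep the contract ci_low <= d <= ci_high
    ci_low = min(ci_low, donor_percent)
    ci_high = max(ci_high, donor_percent)

    return ChimerismEstimate(
        sample_id=spectrum.sample_id,
        per_snp_informative_fraction=tuple(used),
        per_snp_raw_fraction=tuple(raw),
        mean_fraction=mean,
        donor_percent=donor_percent,
        ci_low=ci_low,
        ci_high=ci_high,
        n_called_reads=tuple(called_n),
        flags=tuple(flags),
    )


# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HostEstimate:
    """Host compartment seen through the edited locus."""

    sample_id: str
    host_percent: float          # 100 * (1 - WT fraction)
    distinct_host_alleles: int   # retained non-WT signatures (noise excluded)
    host_reads: int              # non-WT read count
    entries: tuple[AlleleEntry, ...]


def host_fraction_from_edits(spectrum: AlleleSpectrum) -> HostEstimate:
    if not spectrum.edit_entries or spectrum.edit_reads == 0:
        raise InsufficientDataError("no edit-amplicon reads")
    wt = sum(e.count for e in spectrum.edit_entries if e.signature == ())
    non_wt = spectrum.edit_reads - wt
    distinct = sum(
        1 for e in spectrum.edit_entries if e.signature not in ((), None)
    )
    return HostEstimate(
        sample_id=spectrum.sample_id,
        host_percent=100.0 * non_wt / spectrum.edit_reads,
        distinct_host_alleles=distinct,
        host_reads=non_wt,
        entries=spectrum.edit_entries,
    )


# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenotypeThresholds:
    gap_tolerance: float = 10.0       # percentage points
    wt_noise: float = 2.0             # host% below this = unedited host
    min_host_compartment: float = 2.0  # 100 - donor% below this = no host to call
    min_host_reads: int = 200
    homozygous_frac: float = 0.8      # single signature covering this much of
                                      # the host compartment = homozygous KO


DEFAULT_THRESHOLDS = GenotypeThresholds()


@dataclass(frozen=True)
class HostGenotypeCall:
    sample_id: str
    host_percent: float
    distinct_host_alleles: int
    call: str  # "bi-allelic KO" | "mono-allelic/mosaic" | "WT" | "indeterminate"
    consistency_gap: float  # |donor% + host% - 100|
    notes: tuple[str, ...] = ()


def infer_host_genotype(
    donor: ChimerismEstimate,
    host: HostEstimate,
    thresholds: GenotypeThresholds = DEFAULT_THRESHOLDS,
) -> HostGenotypeCall:
    """Joint donor/host call for one sample.

    A fully donor-derived sample leaves no host compartment to genotype and is
    flagged indeterminate; two distinct host indel signatures (or one covering
    essentially the whole host compartment, since two cuts can resolve to one
    deletion allele) consistent with 100 - donor% imply a bi-allelic KO host.
    """
    t = thresholds
    gap = abs(donor.donor_percent + host.host_percent - 100.0)
    compartment = 100.0 - donor.donor_percent
    notes: list[str] = []

    if compartment <= t.min_host_compartment:
        return HostGenotypeCall(
            host.sample_id, host.host_percent, host.distinct_host_alleles,
            "indeterminate", gap, ("no host compartment to genotype",),
        )
    if host.host_percent <= t.wt_noise:
        return HostGenotypeCall(
            host.sample_id, host.host_percent, host.distinct_host_alleles,
            "WT", gap, (),
        )
    if host.host_reads < t.min_host_reads:
        return HostGenotypeCall(
            host.sample_id, host.host_percent, host.distinct_host_alleles,
            "indeterminate", gap, ("insufficient host reads",),
        )

    top_non_wt = max(
        (e.fraction * 100.0 for e in host.entries if e.signature not in ((), None)),
        default=0.0,
    )
    biallelic_pattern = host.distinct_host_alleles >= 2 or (
        host.distinct_host_alleles == 1
        and top_non_wt >= t.homozygous_frac * compartment
    )
    if biallelic_pattern and gap <= t.gap_tolerance:
        if host.distinct_host_alleles == 1:
            notes.append("single-signature (homozygous or shared deletion)")
        return HostGenotypeCall(
            host.sample_id, host.host_percent, host.distinct_host_alleles,
            "bi-allelic KO", gap, tuple(notes),
        )
    if (
        host.distinct_host_alleles >= 1
        and abs(host.host_percent - compartment / 2.0) <= t.gap_tolerance / 2.0
    ):
        return HostGenotypeCall(
            host.sample_id, host.host_percent, host.distinct_host_alleles,
            "mono-allelic/mosaic", gap, (),
        )
    if gap > t.gap_tolerance:
        notes.append("consistency warning: donor% + host% far from 100")
    return HostGenotypeCall(
        host.sample_id, host.host_percent, host.distinct_host_alleles,
        "indeterminate", gap, tuple(notes),
    )


# ---------------------------------------------------------------------------

def estimate_sample(
    spectrum: AlleleSpectrum,
    panel: MarkerPanel,
    min_depth: int = 100,
    error_correction: str = "background",
    thresholds: GenotypeThresholds = DEFAULT_THRESHOLDS,
) -> tuple[ChimerismEstimate, Optional[HostEstimate], Optional[HostGenotypeCall]]:
    donor = donor_fraction_from_snps(
        spectrum, panel, min_depth=min_depth, error_correction=error_correction
    )
    try:
        host = host_fraction_from_edits(spectrum)
    except InsufficientDataError:
        return donor, None, None
    call = infer_host_genotype(donor, host, thresholds)
    return donor, host, call


def report_table(
    results: Sequence[
        tuple[ChimerismEstimate, Optional[HostEstimate], Optional[HostGenotypeCall]]
    ],
) -> pd.DataFrame:
    """Flat per-sample report (full precision; display rounding is separate)."""
    rows = []
    for donor, host, call in results:
        row = {
            "sample_id": donor.sample_id,
            "donor_percent": donor.donor_percent,
            "donor_percent_rounded": donor.donor_percent_rounded,
            "ci_low": donor.ci_low,
            "ci_high": donor.ci_high,
            "mean_informative_fraction": donor.mean_fraction,
            "flags": ";".join(donor.flags),
        }
        for j, (f, n) in enumerate(
            zip(donor.per_snp_raw_fraction, donor.n_called_reads)
        ):
            row[f"snp{j}_fraction"] = f
            row[f"snp{j}_called"] = n
        if host is not None:
            row["host_percent"] = host.host_percent
            row["distinct_host_alleles"] = host.distinct_host_alleles
        if call is not None:
            row["genotype_call"] = call.call
            row["consistency_gap"] = call.consistency_gap
            row["notes"] = ";".join(call.notes)
        rows.append(row)
    return pd.DataFrame(rows)
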