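"""Karyotype signal-site tables, cross-accession comparison, summary stats.

A signal site is one cataloged probe signal on a karyotype: chromosome
label, arm, region class, probe (or channel), intensity class.  Two
karyotypes are compared by matching sites on the key
(chrom_label, arm, region, probe_id); a reference site with no
key-and-intensity-compatible query site is a mismatch.  The module also
carries the summary-statistics arithmetic used for phenotype group
comparisons: pooled-variance two-sample t from (mean, sd, n) triples and
ratios of group means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

ARMS = ("short", "long")
REGIONS = ("centromere", "terminal", "interstitial")
INTENSITIES = ("strong", "weak", "absent-on-one-homolog")

_FIELDS = ("chrom_label", "arm", "region", "probe_id", "intensity")


@dataclass(frozen=True)
class SignalSite:
    chrom_label: str
    arm: str
    region: str
    probe_id: str
    intensity: str

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise ValueError(f"bad arm {self.arm!r}")
        if self.region not in REGIONS:
            raise ValueError(f"bad region {self.region!r}")
        if self.intensity not in INTENSITIES:
            raise ValueError(f"bad intensity {self.intensity!r}")
        if not self.chrom_label or not self.probe_id:
            raise ValueError("chrom_label and probe_id must be non-empty")

    @property
    def key(self) -> tuple[str, str, str, str]:
        return (self.chrom_label, self.arm, self.region, self.probe_id)


@dataclass(frozen=True)
class ComparisonReport:
    total_ref_sites: int
    mismatched: int
    mismatch_percent: float  # one decimal, half-up
    mismatch_list: tuple[tuple[str, str, str, str], ...]


@dataclass(frozen=True)
class GroupSummary:
    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.n < 2:
            raise ValueError("n must be >= 2")


def round_half_up(x: float, decimals: int = 1) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# table I/O
# ---------------------------------------------------------------------------


def load_signal_table(text: str) -> list[SignalSite]:
    """Parse a TSV signal table (header + one site per row, order kept).

    Malformed rows raise with their 1-based line number.
    """
    lines = text.splitlines()
    if not lines or [h.strip() for h in lines[0].split("\t")] != list(_FIELDS):
        raise ValueError(
            "signal table must start with header: " + "\t".join(_FIELDS)
        )
    sites: list[SignalSite] = []
    for ln, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = [p.strip() for p in line.split("\t")]
        if len(parts) != len(_FIELDS):
            raise ValueError(f"line {ln}: expected {len(_FIELDS)} columns")
        try:
            sites.append(SignalSite(*parts))
        except ValueError as e:
            raise ValueError(f"line {ln}: {e}") from e
    return sites


def write_signal_table(sites: list[SignalSite]) -> str:
    rows = ["\t".join(_FIELDS)]
    rows += [
        "\t".join((s.chrom_label, s.arm, s.region, s.probe_id, s.intensity))
        for s in sites
    ]
    return "\n".join(rows) + "\n"


# ---------------------------------------------------------------------------
# comparison
# ---------------------------------------------------------------------------


def _intensity_compatible(ref: str, query: str) -> bool:
    # a site absent on one homolog never corroborates the other accession
    if ref == "absent-on-one-homolog" or query == "absent-on-one-homolog":
        return False
    return True


def compare_karyotypes(
    reference: list[SignalSite], query: list[SignalSite],
    use_region: bool = True,
) -> ComparisonReport:
    """Count reference sites with no matching query site.

    Match = same key (chromosome, arm, region, probe; region optional via
    ``use_region``) and compatible intensity.  Duplicate keys within one
    table error.  mismatch_percent is rounded half-up to one decimal.
    """

    def key_of(s: SignalSite):
        return s.key if use_region else (s.chrom_label, s.arm, s.probe_id)

    for name, table in (("reference", reference), ("query", query)):
        keys = [key_of(s) for s in table]
        if len(keys) != len(set(keys)):
            dup = next(k for k in keys if keys.count(k) > 1)
            raise ValueError(f"duplicate site key in {name} table: {dup}")
    qmap = {key_of(s): s for s in query}
    mismatches = []
    for s in reference:
        q = qmap.get(key_of(s))
        if q is None or not _intensity_compatible(s.intensity, q.intensity):
            mismatches.append(s.key)
    total = len(reference)
    pct = round_half_up(100.0 * len(mismatches) / total, 1) if total else 0.0
    return ComparisonReport(
        total_ref_sites=total,
        mismatched=len(mismatches),
        mismatch_percent=pct,
        mismatch_list=tuple(mismatches),
    )


def count_probe_chromosomes(sites: list[SignalSite], probe_id: str) -> int:
    """Distinct chromosome labels on which a probe has at least one site."""
    return len({s.chrom_label for s in sites if s.probe_id == probe_id})


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------


def pooled_t_from_summary(g1: GroupSummary, g2: GroupSummary) -> float:
    """Pooled-variance two-sample t from summary triples (sign: mean1-mean2).

    sp^2 = ((n1-1) sd1^2 + (n2-1) sd2^2) / (n1+n2-2);
    t = (mean1 - mean2) / sqrt(sp^2 (1/n1 + 1/n2)).
    Both sds zero with equal means gives t = 0 by convention.
    """
    sp2 = ((g1.n - 1) * g1.sd**2 + (g2.n - 1) * g2.sd**2) / (g1.n + g2.n - 2)
    se = math.sqrt(sp2 * (1 / g1.n + 1 / g2.n))
    diff = g1.mean - g2.mean
    if se == 0:
        if diff == 0:
            return 0.0
        raise ValueError("zero pooled SD with unequal means: t undefined")
    return diff / se


def welch_t_from_summary(g1: GroupSummary, g2: GroupSummary) -> float:
    """Welch (unequal-variance) t, available as an alternative."""
    se = math.sqrt(g1.sd**2 / g1.n + g2.sd**2 / g2.n)
    diff = g1.mean - g2.mean
    if se == 0:
        if diff == 0:
            return 0.0
        raise ValueError("zero SE with unequal means: t undefined")
    return diff / se


def ratio_of_means(g1: GroupSummary, g2: GroupSummary) -> tuple[float, float]:
    """(mean1/mean2, value rounded half-up to one decimal)."""
    if g2.mean == 0:
        raise ValueError("zero denominator mean")
    r = g1.mean / g2.mean
    return r, round_half_up(r, 1)
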