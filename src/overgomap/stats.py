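"""Coverage arithmetic and screen summary statistics.

Reproduces the standard quantitative summaries of a pooled BAC-library
screen: C-value to kilobase conversion, fold coverage of the library and
of a screened filter subset, mean probe spacing per chromosome, screen
success rates overall / per chromosome / per stratum (probe sequence
class or donor species).

All printed-style rounding goes through one function
(:func:`round_half_up`) so table reproductions share a single rounding
convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional, Sequence

import pandas as pd

__all__ = [
    "round_half_up",
    "genome_kb_from_cvalue",
    "library_coverage",
    "subset_coverage",
    "overgo_interval",
    "global_coverage_summary",
    "screen_totals",
    "summarize_screen",
    "success_by_stratum",
    "stratum_rates",
    "ChromosomeInfo",
]

#: Mb of double-stranded DNA per picogram (standard C-value conversion).
MB_PER_PG = 978.0

CHROMOSOME_CLASSES = frozenset(
    {"macro", "intermediate", "micro", "sex", "linkage_group", "unplaced"}
)

SEQUENCE_CLASSES = ("coding", "utr", "intron", "other_noncoding", "boundary")
DONOR_SPECIES = ("chicken", "turkey", "zebra_finch")


def round_half_up(x: float, ndigits: int) -> float:
    """Round half away from zero at ``ndigits`` decimals.

    Operates on the shortest decimal repr of ``x`` so that values like
    20.54/4 behave as the printed decimal 5.135 -> 5.14 rather than as
    their binary floating-point neighbours.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(str(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ChromosomeInfo:
    name: str
    length_mb: float
    chrom_class: str
    n_overgos: int = 0
    flag: str = ""

    def __post_init__(self) -> None:
        if self.length_mb <= 0:
            raise ValueError(f"{self.name}: length must be positive")
        if self.n_overgos < 0:
            raise ValueError(f"{self.name}: n_overgos must be >= 0")
        if self.chrom_class not in CHROMOSOME_CLASSES:
            raise ValueError(f"{self.name}: unknown class {self.chrom_class!r}")


def _chrom_frame(chroms) -> pd.DataFrame:
    if isinstance(chroms, pd.DataFrame):
        return chroms
    return pd.DataFrame(
        [(c.name, c.length_mb, c.chrom_class, c.n_overgos, c.flag) for c in chroms],
        columns=["name", "length_mb", "class", "n_overgos", "flag"],
    )


# -- genome and coverage arithmetic ----------------------------------

def genome_kb_from_cvalue(pg: float) -> float:
    """Genome size in Kb from a C-value in pg (978 Mb per pg)."""
    if pg <= 0:
        raise ValueError(f"C-value must be positive, got {pg}")
    return round_half_up(pg * MB_PER_PG * 1000.0, 0)


@dataclass(frozen=True)
class CoverageEstimate:
    fold: float            # rounded to 1 decimal
    fold_unrounded: float
    library_kb: float      # total clone length


def library_coverage(n_clones: int, mean_insert_kb: float, genome_kb: float) -> CoverageEstimate:
    """Fold coverage = clones x mean insert / genome size."""
    if n_clones <= 0 or mean_insert_kb <= 0:
        raise ValueError("clone count and insert size must be positive")
    if genome_kb <= 0:
        raise ValueError("genome size must be positive")
    library_kb = n_clones * mean_insert_kb
    fold = library_kb / genome_kb
    return CoverageEstimate(round_half_up(fold, 1), fold, library_kb)


def subset_coverage(full_fold: float, filters_used: int, filters_total: int) -> float:
    """Fold coverage of a screened filter subset (computed from the
    unrounded full-library fold)."""
    if not (0 < filters_used <= filters_total):
        raise ValueError(
            f"need 0 < filters_used <= filters_total, got {filters_used}/{filters_total}"
        )
    return round_half_up(full_fold * filters_used / filters_total, 1)


def overgo_interval(length_mb: float, n_overgos: int) -> float:
    """Mean probe spacing on a chromosome: ``length / (n + 1)``, 2 dp.

    n probes split a chromosome into n + 1 intervals; with no probes the
    whole chromosome is one interval.
    """
    if length_mb <= 0:
        raise ValueError("length must be positive")
    if n_overgos < 0:
        raise ValueError("n_overgos must be >= 0")
    return round_half_up(length_mb / (n_overgos + 1), 2)


def global_coverage_summary(
    chroms,
    exclude: Iterable[str] = ("GGAUn_random",),
) -> tuple[float, float]:
    """Total covered length (Mb) and pooled mean probe interval (Mb).

    The pooled mean divides the total length by the summed interval
    count sum(n_i + 1); this is not the mean of per-chromosome
    intervals. Unplaced sequence bins are excluded by default.
    """
    df = _chrom_frame(chroms)
    keep = df[~df["name"].isin(set(exclude))]
    if keep.empty:
        raise ValueError("no chromosomes left after exclusion")
    # sum on Decimal: printed per-chromosome lengths are 2-dp decimals
    total = sum(Decimal(str(x)) for x in keep["length_mb"])
    denom = int((keep["n_overgos"] + 1).sum())
    mean = float(total) / denom
    return round_half_up(float(total), 1), round_half_up(mean, 1)


# -- screen summaries ------------------------------------------------

def screen_totals(n_probes: int, n_successful: int, n_clones: int) -> dict:
    """Global screen ratios: success %, clones/probe, clones/successful probe."""
    if n_successful > n_probes:
        raise ValueError("successful probes cannot exceed probes used")
    return {
        "n_probes_used": n_probes,
        "n_successful": n_successful,
        "success_rate_pct": round_half_up(100.0 * n_successful / n_probes, 1) if n_probes else 0.0,
        "n_positive_bacs": n_clones,
        "bacs_per_probe": round_half_up(n_clones / n_probes, 1) if n_probes else 0.0,
        "bacs_per_successful_probe": (
            round_half_up(n_clones / n_successful, 1) if n_successful else 0.0
        ),
    }


@dataclass
class ScreenSummary:
    per_chromosome: pd.DataFrame
    totals: dict


def summarize_screen(report, probes: pd.DataFrame, chroms) -> ScreenSummary:
    """Per-chromosome and total screen results.

    ``report`` is a :class:`~overgomap.decode.DecodeReport` (or any
    object with an ``accepted`` clone/probe frame). Probes are attributed
    to their primary chromosome (``gga_chrom`` column). Counts are of
    distinct clones per probe.
    """
    cdf = _chrom_frame(chroms)
    unknown = set(probes["gga_chrom"]) - set(cdf["name"])
    if unknown:
        raise ValueError(f"probes on chromosomes absent from the table: {sorted(unknown)}")
    accepted = report.accepted if hasattr(report, "accepted") else report
    counts = (
        accepted.groupby("probe_id")["clone_id"].nunique()
        if len(accepted) else pd.Series(dtype=int)
    )
    per = probes[["probe_id", "gga_chrom"]].copy()
    per["n_clones"] = per["probe_id"].map(counts).fillna(0).astype(int)
    rows = []
    for name in cdf["name"]:
        sub = per[per["gga_chrom"] == name]
        used = len(sub)
        succ = int((sub["n_clones"] > 0).sum())
        bacs = int(sub["n_clones"].sum())
        rows.append(
            (
                name,
                used,
                succ,
                round_half_up(100.0 * succ / used, 1) if used else 0.0,
                bacs,
                round_half_up(bacs / used, 1) if used else 0.0,
            )
        )
    per_chrom = pd.DataFrame(
        rows,
        columns=[
            "name", "n_overgos_used", "n_successful", "success_rate_pct",
            "n_positive_bacs", "bacs_per_probe",
        ],
    )
    totals = screen_totals(
        int(per_chrom["n_overgos_used"].sum()),
        int(per_chrom["n_successful"].sum()),
        int(per_chrom["n_positive_bacs"].sum()),
    )
    return ScreenSummary(per_chrom, totals)


def stratum_rates(
    counts: Sequence[tuple[str, int, int]],
    total_successful: Optional[int] = None,
) -> pd.DataFrame:
    """Success rates per stratum from ``(stratum, n_probes, n_successful)``.

    ``pct_within`` is the success rate inside the stratum;
    ``pct_of_successful`` is the stratum's share of all successes
    (denominator ``total_successful``, by default the summed successes).
    """
    if total_successful is None:
        total_successful = sum(k for _, _, k in counts)
    rows = []
    for stratum, n, k in counts:
        if k > n:
            raise ValueError(f"{stratum}: successes exceed probes")
        rows.append(
            (
                stratum, n, k,
                round_half_up(100.0 * k / n, 1) if n else 0.0,
                round_half_up(100.0 * k / total_successful, 1) if total_successful else 0.0,
            )
        )
    return pd.DataFrame(
        rows,
        columns=["stratum", "n_probes", "n_successful", "pct_within", "pct_of_successful"],
    )


def success_by_stratum(
    probes: pd.DataFrame,
    successful: Iterable[str],
    stratify_by: str,
) -> pd.DataFrame:
    """Stratified success rates from a probe table.

    ``stratify_by`` is ``"sequence_class"`` (column ``seq_class``) or
    ``"donor_species"`` (column ``species``); stratum order follows the
    field's conventional table order.
    """
    column, order = {
        "sequence_class": ("seq_class", SEQUENCE_CLASSES),
        "donor_species": ("species", DONOR_SPECIES),
    }.get(stratify_by, (None, None))
    if column is None:
        raise ValueError(f"unknown stratification: {stratify_by!r}")
    succ = set(map(str, successful))
    missing = succ - set(probes["probe_id"].astype(str))
    if missing:
        raise ValueError(f"successful ids not in probe table: {sorted(missing)}")
    bad = set(probes[column]) - set(order)
    if bad:
        raise ValueError(f"unknown {column} labels: {sorted(bad)}")
    counts = []
    for stratum in order:
        sub = probes[probes[column] == stratum]
        if sub.empty:
            continue
        counts.append(
            (stratum, len(sub), int(sub["probe_id"].astype(str).isin(succ).sum()))
        )
    return stratum_rates(counts, total_successful=len(succ))


def render_table(df: pd.DataFrame) -> str:
    """Aligned plain-text rendering for logs and reports."""
    return df.to_string(index=False)
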