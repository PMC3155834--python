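"""Decode clone x pool positivity calls into clone-probe assignments.

A clone that truly carries the target of a probe should be positive in
all four of that probe's pools. The decoder accepts candidates supported
by at least three of the four dimensions, which tolerates one dropped
pool call per assignment; two missing dimensions always reject. Clones
whose positive pools are consistent with more than one probe at equal
top support are routed to an explicit ambiguity queue (the machine
analogue of manual review of filter images) rather than resolved by
fiat.

Note one structural asymmetry of the 4-dimensional layout: row, column
and diagonal determine the cell within a plate, so losing any one of
those three calls still leaves a unique candidate, while losing the
plate call leaves one tied candidate per plate. ``accept_ambiguous=True``
keeps such tied candidates in the accepted set, flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .design import DIMENSIONS, Dimension, PoolId, PoolingDesign

__all__ = [
    "Assignment",
    "DecodeReport",
    "candidate_probes",
    "decode_screen",
    "assignment_counts",
    "read_calls_tsv",
    "write_calls_tsv",
]

MIN_SUPPORT = 3  # "at least three of four" dimensions

ASSIGNMENT_COLUMNS = ["clone_id", "probe_id", "support", "missing_dimension", "ambiguous"]


class ValidationError(ValueError):
    """Call matrix does not conform to the design."""


@dataclass(frozen=True)
class Assignment:
    clone_id: str
    probe_id: str
    support: int
    missing_dimension: Optional[Dimension]
    ambiguous: bool = False

    def __post_init__(self) -> None:
        if self.support not in (3, 4):
            raise ValueError("support must be 3 or 4")
        if self.support == 4 and self.missing_dimension is not None:
            raise ValueError("support 4 implies no missing dimension")


@dataclass
class DecodeReport:
    """Decoder output, split into accepted / ambiguous / rejected.

    ``accepted``: clone-probe assignments (columns ``clone_id, probe_id,
    support, missing_dimension, ambiguous``). ``ambiguity_groups``: all
    tied top-support candidates per ambiguous clone, same columns minus
    the flag; these are also in ``accepted`` iff the decoder ran with
    ``accept_ambiguous=True``. ``rejected``: clones with at least one
    positive pool but best support <= 2.
    """

    accepted: pd.DataFrame
    ambiguity_groups: pd.DataFrame
    rejected: pd.DataFrame
    accept_ambiguous: bool = False

    @property
    def n_accepted(self) -> int:
        return len(self.accepted)

    def summary(self) -> dict:
        return {
            "n_accepted": int(len(self.accepted)),
            "n_accepted_clones": int(self.accepted["clone_id"].nunique()),
            "n_ambiguous_clones": int(self.ambiguity_groups["clone_id"].nunique()),
            "n_rejected_clones": int(len(self.rejected)),
            "accept_ambiguous": self.accept_ambiguous,
        }


def _empty_assignments() -> pd.DataFrame:
    return pd.DataFrame(columns=ASSIGNMENT_COLUMNS).astype(
        {"support": int, "ambiguous": bool}, errors="ignore"
    )


def _validate_calls(calls: pd.DataFrame, design: PoolingDesign) -> pd.DataFrame:
    """Check the call matrix against the design and order its columns."""
    expected = [p.label for p in design.pools]
    have = set(calls.columns)
    missing = [c for c in expected if c not in have]
    extra = sorted(have - set(expected))
    if missing or extra:
        raise ValidationError(
            f"call matrix does not match design pools; missing={missing}, extra={extra}"
        )
    return calls[expected].astype(bool)


def candidate_probes(
    clone_calls: Iterable[PoolId | str],
    design: PoolingDesign,
    min_support: int = MIN_SUPPORT,
) -> list[tuple[str, int, Optional[Dimension]]]:
    """Probes consistent with a clone's positive pools.

    For every occupied address, support is the number of its four pools
    present in the positive set. Returns ``(probe_id, support,
    missing_dimension)`` for all probes with support >= ``min_support``,
    sorted by support descending then probe id; ``missing_dimension`` is
    the single unsupported dimension when support is 3, else None.
    """
    positives: set[PoolId] = set()
    known = set(design.pools)
    for p in clone_calls:
        pool = PoolId.parse(p) if isinstance(p, str) else p
        if pool not in known:
            raise ValidationError(f"pool {pool.label} not in design")
        positives.add(pool)
    out: list[tuple[str, int, Optional[Dimension]]] = []
    for pid in design.probe_order:
        pools = design.pools_for_probe(pid)
        hit = pools & positives
        support = len(hit)
        if support >= min_support:
            missing = None
            if support == 3:
                (missing,) = [p.dimension for p in pools - hit]
            out.append((pid, support, missing))
    out.sort(key=lambda t: (-t[1], t[0]))
    return out


def decode_screen(
    calls: pd.DataFrame,
    design: PoolingDesign,
    accept_ambiguous: bool = False,
    min_support: int = MIN_SUPPORT,
) -> DecodeReport:
    """Decode a full clone x pool Boolean matrix.

    ``calls`` is indexed by clone id with one Boolean column per pool
    label; its column set must equal the design's pools (missing columns
    are an error, not implicit negatives). Clones with a unique
    top-support candidate (support >= ``min_support``) are accepted;
    tied top candidates form ambiguity groups, accepted with the
    ``ambiguous`` flag only when ``accept_ambiguous`` is set. Output
    rows are ordered by clone id then probe id.
    """
    calls = _validate_calls(calls, design)
    m = design.membership_matrix()  # (n_probes, n_pools)
    b = calls.to_numpy(dtype=np.uint8)  # (n_clones, n_pools)
    support = b @ m.T  # (n_clones, n_probes)

    # missing dimension per probe given a clone's calls, only needed at support 3
    pool_dims = np.array([p.dimension.value for p in design.pools])
    probe_ids = np.asarray(design.probe_order, dtype=object)

    accepted_rows: list[tuple] = []
    ambiguous_rows: list[tuple] = []
    rejected_rows: list[tuple] = []

    clone_ids = calls.index.astype(str)
    any_positive = b.any(axis=1)
    best = support.max(axis=1) if design.n_probes else np.zeros(len(calls), int)

    for ci in np.flatnonzero(any_positive):
        clone = clone_ids[ci]
        top = int(best[ci])
        if top < min_support:
            rejected_rows.append((clone, top))
            continue
        cand = np.flatnonzero(support[ci] == top)
        tied = len(cand) > 1
        for pi in sorted(cand, key=lambda i: probe_ids[i]):
            missing = None
            if top == 3:
                pools = design.pools_for_probe(probe_ids[pi])
                lit = {design.pools[j] for j in np.flatnonzero(b[ci])}
                (missing_pool,) = pools - lit
                missing = missing_pool.dimension.value
            row = (clone, probe_ids[pi], top, missing)
            if tied:
                ambiguous_rows.append(row)
                if accept_ambiguous:
                    accepted_rows.append(row + (True,))
            else:
                accepted_rows.append(row + (False,))

    accepted = pd.DataFrame(accepted_rows, columns=ASSIGNMENT_COLUMNS)
    ambiguity = pd.DataFrame(
        ambiguous_rows, columns=["clone_id", "probe_id", "support", "missing_dimension"]
    )
    rejected = pd.DataFrame(rejected_rows, columns=["clone_id", "max_support"])
    for df, keys in ((accepted, ["clone_id", "probe_id"]),
                     (ambiguity, ["clone_id", "probe_id"]),
                     (rejected, ["clone_id"])):
        if len(df):
            df.sort_values(keys, inplace=True, kind="stable", ignore_index=True)
    return DecodeReport(accepted, ambiguity, rejected, accept_ambiguous)


def assignment_counts(report: DecodeReport, probes: pd.DataFrame) -> dict:
    """Per-probe positive-clone counts and screen-level totals.

    ``probes`` needs a ``probe_id`` column; probes without any accepted
    clone count as zero. Reports both the number of clone-probe pairs
    and the number of distinct clones (these differ when one clone is
    assigned to several probes).
    """
    ids = probes["probe_id"].astype(str)
    if len(report.accepted):
        per_probe = (
            report.accepted.groupby("probe_id")["clone_id"].nunique()
            .reindex(ids, fill_value=0)
        )
    else:
        per_probe = pd.Series(0, index=ids, name="clone_id")
    per_probe.index.name = "probe_id"
    n_success = int((per_probe > 0).sum())
    total_pairs = int(per_probe.sum())
    return {
        "per_probe": per_probe,
        "n_probes": int(len(ids)),
        "n_successful_probes": n_success,
        "success_rate_pct": 100.0 * n_success / len(ids) if len(ids) else 0.0,
        "total_assignments": total_pairs,
        "total_clones": int(report.accepted["clone_id"].nunique()) if len(report.accepted) else 0,
        "min_count": int(per_probe.min()) if len(per_probe) else 0,
        "max_count": int(per_probe.max()) if len(per_probe) else 0,
    }


# -- long-form TSV interchange ---------------------------------------

def write_calls_tsv(calls: pd.DataFrame, path: str | Path) -> None:
    """Write a call matrix as long-form TSV ``clone_id  pool_id  call``."""
    long = calls.astype(int).stack().rename("call").reset_index()
    long.columns = ["clone_id", "pool_id", "call"]
    long.to_csv(path, sep="\t", index=False)


def read_calls_tsv(path: str | Path, design: PoolingDesign) -> pd.DataFrame:
    """Read long-form calls; absent (clone, pool) cells are negative."""
    long = pd.read_csv(path, sep="\t", comment="#", dtype={"clone_id": str})
    mat = (
        long.pivot_table(index="clone_id", columns="pool_id", values="call",
                         aggfunc="max", fill_value=0)
        .astype(bool)
    )
    for pool in design.pools:  # absent columns = never called positive
        if pool.label not in mat.columns:
            mat[pool.label] = False
    return _validate_calls(mat, design)


def write_report_tsv(report: DecodeReport, path: str | Path) -> None:
    report.accepted.to_csv(path, sep="\t", index=False)
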