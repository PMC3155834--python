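"""First-generation comparative map construction and export.

Every successfully screened locus (a probe with at least one decoded
clone) is anchored at its position on the chicken reference chromosome,
annotated with the orthologous zebra finch chromosome and position when
known, and linked to its supporting sparrow BAC clones. Loci without a
finch match are parked on the non-specific chromosome "TGUUn" and
starred; loci whose finch coordinate was lifted over from a chicken
alignment rather than matched directly are starred too, per the usual
figure-legend convention.

Exports: a full annotated TSV (round-trips losslessly), a MapChart-style
text format of per-chromosome ``locus position`` blocks, and BED point
features (0-based half-open, Mb x 1e6 start, width 1).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional

import pandas as pd

__all__ = [
    "MapLocus",
    "MapTrack",
    "build_map",
    "annotate_finch",
    "export_map",
    "read_map_tsv",
    "read_mapchart",
]

UNPLACED_FINCH = "TGUUn"

TSV_COLUMNS = [
    "gga_chrom", "gga_length_mb", "symbol", "gga_pos_mb",
    "tgu_chrom", "tgu_pos_mb", "placement", "starred", "clones",
]


@dataclass(frozen=True)
class MapLocus:
    symbol: str
    chrom: str
    pos_mb: float
    clones: tuple[str, ...]
    tgu_chrom: Optional[str] = None
    tgu_pos_mb: Optional[float] = None
    placement: str = "unannotated"  # matched | lifted_from_chicken_alignment | unplaced
    starred: bool = False


@dataclass
class MapTrack:
    chrom: str
    length_mb: float
    loci: list[MapLocus]

    def __post_init__(self) -> None:
        for locus in self.loci:
            if locus.pos_mb > self.length_mb:
                raise ValueError(
                    f"{locus.symbol} at {locus.pos_mb} Mb exceeds "
                    f"{self.chrom} length {self.length_mb} Mb"
                )
        self.loci = sorted(self.loci, key=lambda l: (l.pos_mb, l.symbol))

    @property
    def n_loci(self) -> int:
        return len(self.loci)


def build_map(report, probes: pd.DataFrame, chroms: pd.DataFrame) -> list[MapTrack]:
    """One chicken-anchored track per chromosome with >= 1 successful locus.

    ``report`` is a DecodeReport (or a bare accepted-assignments frame
    with ``clone_id``/``probe_id``). Only probes with at least one
    accepted clone become map loci; tracks follow the chromosome-table
    order and loci are position-sorted.
    """
    accepted = report.accepted if hasattr(report, "accepted") else report
    if len(accepted) == 0:
        return []
    clones_by_probe = accepted.groupby("probe_id")["clone_id"].agg(
        lambda s: tuple(sorted(set(s)))
    )
    lengths = dict(zip(chroms["name"], chroms["length_mb"]))
    loci_by_chrom: dict[str, list[MapLocus]] = {}
    indexed = probes.set_index(probes["probe_id"].astype(str))
    for pid, clone_ids in clones_by_probe.items():
        if pid not in indexed.index:
            raise ValueError(f"decoded probe {pid!r} absent from probe table")
        row = indexed.loc[pid]
        chrom = row["gga_chrom"]
        if chrom not in lengths:
            raise ValueError(f"chromosome {chrom!r} absent from chromosome table")
        locus = MapLocus(
            symbol=str(row["symbol"]),
            chrom=chrom,
            pos_mb=float(row["gga_pos_mb"]),
            clones=clone_ids,
        )
        loci_by_chrom.setdefault(chrom, []).append(locus)
    return [
        MapTrack(name, float(lengths[name]), loci_by_chrom[name])
        for name in chroms["name"]
        if name in loci_by_chrom
    ]


def annotate_finch(locus: MapLocus, finch_lookup: pd.DataFrame) -> MapLocus:
    """Attach the orthologous finch position, or park the locus on TGUUn.

    ``finch_lookup`` columns: ``symbol, tgu_chrom, tgu_pos_mb`` and an
    optional ``lifted`` flag. A locus absent from the lookup (or with an
    empty chromosome) is placed on the non-specific chromosome and
    starred; a lifted coordinate keeps its position but is starred.
    """
    hit = finch_lookup[finch_lookup["symbol"] == locus.symbol]
    if len(hit) == 0 or not str(hit.iloc[0]["tgu_chrom"]):
        return replace(
            locus, tgu_chrom=UNPLACED_FINCH, tgu_pos_mb=None,
            placement="unplaced", starred=True,
        )
    row = hit.iloc[0]
    lifted = bool(row["lifted"]) if "lifted" in hit.columns else False
    return replace(
        locus,
        tgu_chrom=str(row["tgu_chrom"]),
        tgu_pos_mb=float(row["tgu_pos_mb"]),
        placement="lifted_from_chicken_alignment" if lifted else "matched",
        starred=lifted,
    )


def annotate_tracks(tracks: list[MapTrack], finch_lookup: pd.DataFrame) -> list[MapTrack]:
    return [
        MapTrack(t.chrom, t.length_mb, [annotate_finch(l, finch_lookup) for l in t.loci])
        for t in tracks
    ]


# -- export / import -------------------------------------------------

def _tracks_frame(tracks: list[MapTrack]) -> pd.DataFrame:
    rows = []
    for t in tracks:
        for l in t.loci:
            rows.append(
                (
                    t.chrom, t.length_mb, l.symbol, l.pos_mb,
                    "" if l.tgu_chrom is None else l.tgu_chrom,
                    "" if l.tgu_pos_mb is None else repr(float(l.tgu_pos_mb)),
                    l.placement, int(l.starred), ",".join(l.clones),
                )
            )
    return pd.DataFrame(rows, columns=TSV_COLUMNS)


def export_map(tracks: list[MapTrack], fmt: str, path: str | Path) -> None:
    """Write tracks as ``tsv``, ``mapchart_text`` or ``bed``.

    Outputs are byte-deterministic for identical tracks. BED positions
    are point features: start = round(pos_mb * 1e6), end = start + 1.
    """
    path = Path(path)
    if fmt == "tsv":
        _tracks_frame(tracks).to_csv(path, sep="\t", index=False)
    elif fmt == "mapchart_text":
        lines = []
        for t in tracks:
            lines.append(f"group {t.chrom} ; length_mb={t.length_mb!r}")
            for l in t.loci:
                star = "*" if l.starred else ""
                lines.append(f"{l.symbol}{star}\t{l.pos_mb!r}")
            lines.append("")
        path.write_text("\n".join(lines))
    elif fmt == "bed":
        lines = []
        for t in tracks:
            for l in t.loci:
                start = int(round(l.pos_mb * 1e6))
                lines.append(f"{t.chrom}\t{start}\t{start + 1}\t{l.symbol}")
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
    else:
        raise ValueError(f"unknown export format: {fmt!r}")


def read_map_tsv(path: str | Path) -> list[MapTrack]:
    """Inverse of the tsv export (lossless round-trip)."""
    df = pd.read_csv(path, sep="\t", comment="#", keep_default_na=False)
    tracks: list[MapTrack] = []
    for chrom, sub in df.groupby("gga_chrom", sort=False):
        loci = [
            MapLocus(
                symbol=str(r["symbol"]),
                chrom=chrom,
                pos_mb=float(r["gga_pos_mb"]),
                clones=tuple(str(r["clones"]).split(",")) if r["clones"] else (),
                tgu_chrom=str(r["tgu_chrom"]) if str(r["tgu_chrom"]) else None,
                tgu_pos_mb=float(r["tgu_pos_mb"]) if str(r["tgu_pos_mb"]) else None,
                placement=str(r["placement"]),
                starred=bool(int(r["starred"])),
            )
            for _, r in sub.iterrows()
        ]
        tracks.append(MapTrack(chrom, float(sub.iloc[0]["gga_length_mb"]), loci))
    return tracks


def read_mapchart(path: str | Path) -> list[MapTrack]:
    """Read the mapchart_text export (chromosome, length, symbol, position).

    Finch annotations and clone lists are not part of this format; only
    the star survives, recorded on ``starred``.
    """
    tracks: list[MapTrack] = []
    chrom, length, loci = None, None, []
    for line in Path(path).read_text().splitlines():
        if line.startswith("group "):
            if chrom is not None:
                tracks.append(MapTrack(chrom, length, loci))
            head, _, tail = line[len("group "):].partition(";")
            chrom = head.strip()
            length = float(tail.split("=", 1)[1])
            loci = []
        elif line.strip():
            sym, pos = line.split("\t")
            starred = sym.endswith("*")
            loci.append(
                MapLocus(sym.rstrip("*"), chrom, float(pos), (), starred=starred)
            )
    if chrom is not None:
        tracks.append(MapTrack(chrom, length, loci))
    return tracks
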