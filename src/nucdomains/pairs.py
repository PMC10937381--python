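"""Chimeric ligation-pair processing.

A Micro-C read pair reports two ligation-junction sides, each a
(contig, coordinate, read direction) triple where the direction says
whether the read extends upstream or downstream of the junction.  This
module implements the post-mapping steps: orientation classification
into the four read-direction combinations (inward, outward, tandem
entry, tandem exit), the 80 bp shift from junction to nucleosome dyad,
and removal of interchromosomal pairs and pairs closer than 147 bp
(undigested or self-ligated material).

Pairs live in a pandas DataFrame with columns
``chrom1 pos1 dir1 chrom2 pos2 dir2 orientation``; a ``LigationPair``
namedtuple is provided for single-pair work.  Files are tab-separated
pairs-text with ``#``-prefixed headers; directions are encoded ``+``
(downstream of the junction) / ``-`` (upstream).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

PAIR_COLUMNS = ["chrom1", "pos1", "dir1", "chrom2", "pos2", "dir2",
                "orientation"]
DIR_TOKENS = {"+": "downstream", "-": "upstream"}
DIR_ENCODE = {v: k for k, v in DIR_TOKENS.items()}

#: (dir1, dir2) of a canonicalized pair -> orientation class
ORIENTATION_OF_DIRS = {
    ("downstream", "upstream"): "inward",
    ("upstream", "downstream"): "outward",
    ("downstream", "downstream"): "tandem_entry",
    ("upstream", "upstream"): "tandem_exit",
}


class LigationPair(NamedTuple):
    chrom1: str
    pos1: int
    dir1: str
    chrom2: str
    pos2: int
    dir2: str
    orientation: str = "unset"


@dataclass
class PairFilterConfig:
    """Distance/contig filter and dyad-shift settings.

    ``min_distance_bp`` removes pairs strictly closer than the length of
    nucleosomal DNA (147 bp), i.e. material that was never digested
    apart; the junction-to-dyad shift is 80 bp.
    """

    min_distance_bp: int = 147
    drop_interchromosomal: bool = True
    dyad_shift_bp: int = 80

    def __post_init__(self) -> None:
        if self.min_distance_bp < 0:
            raise ValueError("min_distance_bp must be >= 0")


@dataclass
class FilterStats:
    """Per-reason removal counts plus orientation-class tallies."""

    n_input: int = 0
    n_interchromosomal: int = 0
    n_short: int = 0
    n_negative_shift: int = 0
    n_kept: int = 0
    orientation_counts: dict = field(default_factory=dict)

    def orientation_fractions(self) -> dict:
        tot = sum(self.orientation_counts.values())
        if tot == 0:
            return {}
        return {k: v / tot for k, v in self.orientation_counts.items()}


class PairsParseError(ValueError):
    pass


def canonicalize(pairs: pd.DataFrame) -> pd.DataFrame:
    """Order each pair's sides so (contig1, pos1) <= (contig2, pos2)."""
    out = pairs.copy()
    flip = (out["chrom1"] > out["chrom2"]) | (
        (out["chrom1"] == out["chrom2"]) & (out["pos1"] > out["pos2"]))
    f = flip.to_numpy()
    if f.any():
        for a, b in (("chrom1", "chrom2"), ("pos1", "pos2"), ("dir1", "dir2")):
            va, vb = out[a].to_numpy().copy(), out[b].to_numpy().copy()
            out.loc[f, a] = vb[f]
            out.loc[f, b] = va[f]
    return out


def classify_orientation(pairs) -> pd.DataFrame | LigationPair:
    """Assign each pair its read-orientation class.

    Both read directions are interpreted relative to the ligation
    junction after canonical side ordering: (downstream, upstream) is an
    inward-facing contact, (upstream, downstream) outward, and the two
    equal-direction combinations are tandem entry / tandem exit.  The
    four classes are exhaustive and mutually exclusive, and invariant
    under swapping the two sides of a pair.
    """
    if isinstance(pairs, LigationPair):
        df = classify_orientation(pd.DataFrame([pairs], columns=PAIR_COLUMNS))
        return LigationPair(*df.iloc[0])
    bad = ~pairs["dir1"].isin(DIR_ENCODE) | ~pairs["dir2"].isin(DIR_ENCODE)
    if bad.any():
        raise ValueError(
            f"{int(bad.sum())} pair(s) have unset/unknown read direction")
    out = canonicalize(pairs)
    key = out["dir1"].astype(str) + "|" + out["dir2"].astype(str)
    mapping = {f"{a}|{b}": c for (a, b), c in ORIENTATION_OF_DIRS.items()}
    out["orientation"] = key.map(mapping)
    return out


def shift_to_dyad(pairs, cfg: PairFilterConfig | None = None):
    """Move each junction coordinate 80 bp into the nucleosome it enters.

    A downstream-reading side advances by the shift, an upstream-reading
    side retreats, so inward-pair distances shrink by twice the shift
    and tandem distances are unchanged.  Sides that would go negative
    mark the pair for dropping (counted by :func:`filter_pairs`).
    """
    cfg = cfg or PairFilterConfig()
    single = isinstance(pairs, LigationPair)
    if single:
        pairs = pd.DataFrame([pairs], columns=PAIR_COLUMNS)
    if pairs.attrs.get("dyad_shifted"):
        return pairs.copy()  # already on dyad coordinates
    out = pairs.copy()
    s = cfg.dyad_shift_bp
    for pos, dr in (("pos1", "dir1"), ("pos2", "dir2")):
        down = (out[dr] == "downstream").to_numpy()
        out[pos] = out[pos].to_numpy() + np.where(down, s, -s)
    out = canonicalize(out)
    out.attrs["dyad_shifted"] = True
    if single:
        row = out.iloc[0]
        if row["pos1"] < 0 or row["pos2"] < 0:
            raise ValueError("shift produced a negative coordinate")
        return LigationPair(*row)
    return out


def filter_pairs(pairs: pd.DataFrame, cfg: PairFilterConfig | None = None
                 ) -> tuple[pd.DataFrame, FilterStats]:
    """Drop interchromosomal and sub-147 bp pairs; report statistics.

    The distance cut is strict (< 147 removed, 147 kept).  Stats carry
    counts per removal reason and the orientation-class tallies of the
    kept pairs.
    """
    cfg = cfg or PairFilterConfig()
    stats = FilterStats(n_input=len(pairs))
    if len(pairs) == 0:
        return pairs.copy(), stats
    inter = (pairs["chrom1"] != pairs["chrom2"]).to_numpy()
    dist = np.abs(pairs["pos2"].to_numpy() - pairs["pos1"].to_numpy())
    short = ~inter & (dist < cfg.min_distance_bp)
    negative = (pairs["pos1"].to_numpy() < 0) | (pairs["pos2"].to_numpy() < 0)
    drop = negative.copy()
    stats.n_negative_shift = int(negative.sum())
    if cfg.drop_interchromosomal:
        stats.n_interchromosomal = int((inter & ~drop).sum())
        drop |= inter
    stats.n_short = int((short & ~drop).sum())
    drop |= short
    kept = pairs.loc[~drop].reset_index(drop=True)
    stats.n_kept = len(kept)
    if "orientation" in kept:
        stats.orientation_counts = (
            kept["orientation"].value_counts().to_dict())
    return kept, stats


def process_pairs(pairs: pd.DataFrame, cfg: PairFilterConfig | None = None
                  ) -> tuple[pd.DataFrame, FilterStats]:
    """classify -> shift to dyad -> filter, the standard pipeline."""
    cfg = cfg or PairFilterConfig()
    out = classify_orientation(pairs)
    out = shift_to_dyad(out, cfg)
    return filter_pairs(out, cfg)


def read_pairs(path) -> pd.DataFrame:
    """Read tab-separated pairs-text; headers are '#'-prefixed.

    Malformed lines raise :class:`PairsParseError` naming the line
    number.  Headers are preserved on ``df.attrs['headers']`` for
    bit-exact round-trips.
    """
    headers: list[str] = []
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                headers.append(line)
                continue
            fields = line.split("\t")
            if len(fields) != 7:
                raise PairsParseError(
                    f"{path}:{lineno}: expected 7 tab-separated fields, "
                    f"got {len(fields)}")
            c1, p1, d1, c2, p2, d2, ori = fields
            try:
                p1, p2 = int(p1), int(p2)
            except ValueError:
                raise PairsParseError(
                    f"{path}:{lineno}: non-integer coordinate") from None
            if p1 < 0 or p2 < 0:
                raise PairsParseError(f"{path}:{lineno}: negative coordinate")
            if d1 not in DIR_TOKENS or d2 not in DIR_TOKENS:
                raise PairsParseError(
                    f"{path}:{lineno}: unknown direction token "
                    f"{d1!r}/{d2!r} (expected +/-)")
            rows.append((c1, p1, DIR_TOKENS[d1], c2, p2, DIR_TOKENS[d2], ori))
    df = pd.DataFrame(rows, columns=PAIR_COLUMNS)
    if not rows:
        df = df.astype({"pos1": np.int64, "pos2": np.int64})
    df.attrs["headers"] = headers
    if any(h.startswith("#shifted: yes") for h in headers):
        df.attrs["dyad_shifted"] = True
    return df


def write_pairs(pairs: pd.DataFrame, path, headers: list[str] | None = None
                ) -> None:
    """Write pairs-text with a direction legend in the header."""
    if headers is None:
        headers = pairs.attrs.get("headers") or [
            "## pairs-text v1",
            "#legend: dir + = read downstream of junction, "
            "- = read upstream of junction",
            "#columns: contig1 pos1 dir1 contig2 pos2 dir2 orientation",
        ]
        shifted = "yes" if pairs.attrs.get("dyad_shifted") else "no"
        if not any(h.startswith("#shifted:") for h in headers):
            headers = headers + [f"#shifted: {shifted}"]
    with open(path, "w") as fh:
        for h in headers:
            fh.write(h + "\n")
        enc1 = pairs["dir1"].map(DIR_ENCODE)
        enc2 = pairs["dir2"].map(DIR_ENCODE)
        for c1, p1, d1, c2, p2, d2, o in zip(
                pairs["chrom1"], pairs["pos1"], enc1,
                pairs["chrom2"], pairs["pos2"], enc2, pairs["orientation"]):
            fh.write(f"{c1}\t{p1}\t{d1}\t{c2}\t{p2}\t{d2}\t{o}\n")
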