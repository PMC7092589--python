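"""Readers and writers for the plain-text formats the tool touches.

Counts come in as 4-column bedGraph-like TSVs (chrom, start, end, value),
one per fraction, or as a single wide table; heatmaps round-trip through a
wide TSV; feature calls are written as BED6+1.
"""

from __future__ import annotations

import logging
import os
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    DEFAULT_BIN_SIZE,
    FRACTION_NAMES,
    N_FRACTIONS,
    SEX_CHROMOSOMES,
    BinIndex,
    BinnedTrack,
    FeatureCall,
    FractionStack,
    Heatmap,
    RepliSeqError,
)

log = logging.getLogger("replitempo")

_TRACK_NAMES = FRACTION_NAMES + ("G1",)


def _read_bedgraph_table(path, value_name: str) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["chrom", "start", "end", value_name],
        dtype={"chrom": str},
    )
    if df[value_name].isna().any():
        raise RepliSeqError(f"{path}: missing values in column 4")
    return df


def _drop_sex_chroms(df: pd.DataFrame, origin: str) -> pd.DataFrame:
    sexy = df["chrom"].isin(SEX_CHROMOSOMES)
    n = int(sexy.sum())
    if n:
        log.info("%s: dropped %d sex-chromosome bins", origin, n)
        df = df.loc[~sexy].reset_index(drop=True)
    return df


def _index_from_frame(df: pd.DataFrame, bin_size: int) -> BinIndex:
    df = df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    return BinIndex(
        tuple(df["chrom"]),
        df["start"].to_numpy(np.int64),
        df["end"].to_numpy(np.int64),
        bin_size,
    )


def read_fraction_counts(
    source, bin_size: int = DEFAULT_BIN_SIZE
) -> FractionStack:
    """Load 16 S-fraction count tracks plus the G1 control.

    ``source`` may be

    * a mapping ``{"S1": path, ..., "S16": path, "G1": path}``,
    * a directory containing files named ``S1.*`` .. ``S16.*`` and ``G1.*``,
    * a single wide TSV with columns chrom, start, end, S1..S16, G1.

    Rows on sex chromosomes are dropped (with a logged count). All tracks
    must share an identical bin grid; a mismatch is an error, never a
    silent intersection. Negative counts are rejected.
    """
    if isinstance(source, (str, Path)) and os.path.isdir(source):
        source = _discover_tracks(Path(source))
    if isinstance(source, Mapping):
        frames = {}
        for name in _TRACK_NAMES:
            if name not in source:
                raise RepliSeqError(f"fraction {name} absent")
            frames[name] = _drop_sex_chroms(
                _read_bedgraph_table(source[name], name), str(source[name])
            )
        wide = frames["S1"][["chrom", "start", "end"]].copy()
        ref = wide.sort_values(["chrom", "start"], kind="mergesort")
        for name in _TRACK_NAMES:
            df = frames[name].sort_values(["chrom", "start"], kind="mergesort")
            if len(df) != len(ref) or not (
                (df["chrom"].to_numpy() == ref["chrom"].to_numpy()).all()
                and (df["start"].to_numpy() == ref["start"].to_numpy()).all()
                and (df["end"].to_numpy() == ref["end"].to_numpy()).all()
            ):
                raise RepliSeqError(f"bin grid of {name} disagrees with S1")
            ref[name] = df[name].to_numpy()
        wide = ref
    else:
        wide = pd.read_csv(source, sep="\t", comment="#", dtype={"chrom": str})
        missing = [n for n in _TRACK_NAMES if n not in wide.columns]
        if missing:
            raise RepliSeqError(f"fraction {missing[0]} absent")
        wide = _drop_sex_chroms(wide, str(source))
        wide = wide.sort_values(["chrom", "start"], kind="mergesort")

    values = wide[list(_TRACK_NAMES)].to_numpy(float)
    if values.min() < 0:
        raise RepliSeqError("negative counts in input")
    index = _index_from_frame(wide[["chrom", "start", "end"]], bin_size)
    return FractionStack(index, values[:, :N_FRACTIONS].T, values[:, N_FRACTIONS])


def _discover_tracks(directory: Path) -> dict:
    out = {}
    for p in directory.iterdir():
        stem = p.name.split(".")[0]
        if stem in _TRACK_NAMES:
            out[stem] = p
    return out


# ---------------------------------------------------------------------------
# Feature BED


def write_features(features: Sequence[FeatureCall], path) -> None:
    """Write feature calls as BED6+1 (name=class, score=peak fraction or 0,
    strand='.', column 7 = timing class)."""
    _check_sorted_disjoint(features)
    with open(path, "w") as fh:
        fh.write("# replitempo feature calls (BED6+timing_class)\n")
        for f in features:
            fh.write(
                f"{f.chrom}\t{f.start}\t{f.end}\t{f.feature_class}\t"
                f"{f.peak_fraction or 0}\t.\t{f.timing_class}\n"
            )


def _check_sorted_disjoint(features: Sequence[FeatureCall]) -> None:
    by_class: dict = {}
    for f in features:
        by_class.setdefault((f.chrom, f.feature_class), []).append((f.start, f.end))
    for (chrom, cls), ivs in by_class.items():
        ivs.sort()
        for (s0, e0), (s1, e1) in zip(ivs, ivs[1:]):
            if s1 < e0:
                raise RepliSeqError(
                    f"overlapping {cls} intervals on {chrom}: "
                    f"[{s0},{e0}) and [{s1},{e1})"
                )


def read_features(path) -> list:
    """Inverse of :func:`write_features`."""
    out = []
    for chrom, start, end, rest in _iter_bed(path, min_cols=4):
        name = rest[0]
        score = int(rest[1]) if len(rest) > 1 else 0
        timing = rest[3] if len(rest) > 3 else "NA"
        out.append(
            FeatureCall(
                chrom, start, end, name, timing, score if score > 0 else None
            )
        )
    return out


def read_intervals(path) -> list:
    """Read a BED3+ file as a list of (chrom, start, end, name) in file order.

    Header lines (``#``, ``track``, ``browser``) are skipped; malformed
    lines are reported with their line number.
    """
    return [
        (chrom, start, end, rest[0] if rest else "")
        for chrom, start, end, rest in _iter_bed(path, min_cols=3)
    ]


def _iter_bed(path, min_cols: int):
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < min_cols:
                raise RepliSeqError(f"{path}: malformed line {lineno}: {line!r}")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise RepliSeqError(
                    f"{path}: non-integer coordinates at line {lineno}"
                ) from None
            if start >= end:
                raise RepliSeqError(
                    f"{path}: start >= end at line {lineno}: {line!r}"
                )
            yield parts[0], start, end, parts[3:]


# ---------------------------------------------------------------------------
# Heatmap TSV

_HEATMAP_COLS = ["chrom", "start", "end", *FRACTION_NAMES, "mask"]


def write_heatmap(heatmap: Heatmap, path) -> None:
    """Serialise a heatmap to a wide TSV (chrom, start, end, S1..S16, mask).

    Round-trips losslessly to < 1e-9 through :func:`read_heatmap`; the
    processing stage is recorded in a header comment.
    """
    df = pd.DataFrame(
        {
            "chrom": list(heatmap.index.chroms),
            "start": heatmap.index.starts,
            "end": heatmap.index.ends,
        }
    )
    for i, name in enumerate(FRACTION_NAMES):
        df[name] = heatmap.matrix[i]
    df["mask"] = heatmap.mask.astype(int)
    with open(path, "w") as fh:
        fh.write(f"# stage={heatmap.stage} bin_size={heatmap.index.bin_size}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.12g")


def read_heatmap(path) -> Heatmap:
    stage, bin_size = "normalized", DEFAULT_BIN_SIZE
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#"):
        for token in first[1:].split():
            key, _, val = token.partition("=")
            if key == "stage":
                stage = val
            elif key == "bin_size":
                bin_size = int(val)
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    if list(df.columns) != _HEATMAP_COLS:
        raise RepliSeqError(
            f"heatmap TSV must have columns {_HEATMAP_COLS}, got {list(df.columns)}"
        )
    index = BinIndex(
        tuple(df["chrom"]),
        df["start"].to_numpy(np.int64),
        df["end"].to_numpy(np.int64),
        bin_size,
    )
    return Heatmap(
        index,
        df[list(FRACTION_NAMES)].to_numpy(float).T,
        df["mask"].to_numpy(bool),
        stage,
    )


def read_signal_track(path, index: BinIndex) -> BinnedTrack:
    """Read a bedGraph-like per-bin signal onto an existing BinIndex."""
    df = _drop_sex_chroms(_read_bedgraph_table(path, "value"), str(path))
    df = df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    got = _index_from_frame(df[["chrom", "start", "end"]], index.bin_size)
    if got != index:
        raise RepliSeqError(f"{path}: bin grid disagrees with analysis index")
    return BinnedTrack(index, df["value"].to_numpy(float))


def write_track(track: BinnedTrack, path) -> None:
    df = pd.DataFrame(
        {
            "chrom": list(track.index.chroms),
            "start": track.index.starts,
            "end": track.index.ends,
            "value": track.values,
        }
    )
    df.to_csv(path, sep="\t", index=False, header=False, float_format="%.6g")
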