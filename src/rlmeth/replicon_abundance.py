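"""Replicon copy-number estimation from read coverage.

Because nanopore libraries here are native (unamplified) DNA, per-replicon
read depth is proportional to replicon copy number per cell.  The relative
abundance of each replicon is its mean depth divided by the chromosome's
mean depth, per condition.
"""

from __future__ import annotations

from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AnalysisError, InputError
from .genome_model import GenomeAssembly

__all__ = [
    "summarize_depth",
    "read_depth_bedgraph",
    "read_mean_depth_table",
    "relative_copy_number",
]


def read_depth_bedgraph(path: str | Path) -> pd.DataFrame:
    """Load a bedGraph depth track (chrom, start, end, depth)."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"depth track not found: {path}")
    df = pd.read_csv(path, sep=r"\s+", comment="#", header=None,
                     names=["replicon", "start", "end", "depth"],
                     dtype={"replicon": str})
    if (df["depth"] < 0).any():
        raise InputError(f"{path}: negative depth values")
    return df


def read_mean_depth_table(path: str | Path) -> pd.DataFrame:
    """Load precomputed per-replicon means (condition, replicon, mean_depth)."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"depth summary not found: {path}")
    df = pd.read_csv(path, sep="\t", comment="#",
                     dtype={"condition": str, "replicon": str})
    missing = [c for c in ("condition", "replicon", "mean_depth")
               if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing column(s) {missing}")
    return df


def summarize_depth(depth: Union[pd.DataFrame, str, Path],
                    assembly: GenomeAssembly, condition: str,
                    trim_fraction: float = 0.0) -> pd.DataFrame:
    """Per-replicon arithmetic mean depth from a per-position track.

    ``depth`` is a bedGraph path or DataFrame (replicon, start, end,
    depth); positions absent from the track count as depth 0.  With
    ``trim_fraction`` > 0 a symmetric trimmed mean over per-position
    values is used instead (robust option, off by default).

    Returns columns: condition, replicon, mean_depth, n_positions.
    """
    if isinstance(depth, (str, Path)):
        depth = read_depth_bedgraph(depth)
    if not (0.0 <= trim_fraction < 0.5):
        raise InputError("trim_fraction must be in [0, 0.5)")
    if (depth["depth"] < 0).any():
        raise InputError("negative depth values")
    rows = []
    for rep in assembly:
        sub = depth[depth["replicon"] == rep.name]
        if ((sub["start"] < 0) | (sub["end"] > rep.length)).any():
            raise InputError(f"depth interval outside replicon {rep.name!r}")
        lengths = (sub["end"] - sub["start"]).to_numpy()
        if trim_fraction == 0.0:
            mean = float((sub["depth"].to_numpy() * lengths).sum() / rep.length)
        else:
            values = np.repeat(sub["depth"].to_numpy(float), lengths)
            values = np.concatenate(
                [values, np.zeros(rep.length - lengths.sum())])
            mean = float(stats.trim_mean(values, trim_fraction))
        rows.append({"condition": condition, "replicon": rep.name,
                     "mean_depth": mean, "n_positions": rep.length})
    return pd.DataFrame(rows)


def relative_copy_number(summaries: pd.DataFrame,
                         chromosome_name: str) -> pd.DataFrame:
    """Replicon mean depth relative to the chromosome, per condition.

    ``summaries`` columns: condition, replicon, mean_depth.  The
    chromosome's ratio is exactly 1 by construction.
    """
    for col in ("condition", "replicon", "mean_depth"):
        if col not in summaries.columns:
            raise InputError(f"summaries missing column {col!r}")
    out = []
    for cond, grp in summaries.groupby("condition", sort=False):
        chrom = grp[grp["replicon"] == chromosome_name]
        if chrom.empty:
            raise AnalysisError(
                f"{cond}: no summary for chromosome {chromosome_name!r}")
        denom = float(chrom["mean_depth"].iloc[0])
        if denom <= 0:
            raise AnalysisError(f"{cond}: chromosome mean depth is 0")
        for row in grp.itertuples(index=False):
            ratio = (1.0 if row.replicon == chromosome_name
                     else float(row.mean_depth) / denom)
            out.append({"condition": cond, "replicon": row.replicon,
                        "ratio": ratio})
    return pd.DataFrame(out)
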