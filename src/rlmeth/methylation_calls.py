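"""Per-site modified-base call aggregation.

Ingests per-condition tables of nanopore modified-base calls (one row
per genomic base per strand, with read coverage and modified-read
count), and computes genome-wide base-type methylation averages,
sliding-window methylation profiles, and per-motif methylation
summaries.

Aggregation convention: every summary is an UNWEIGHTED mean of per-site
methylated-read percentages (each site one vote); sites below the
coverage threshold are excluded.  A palindromic motif locus contributes
its two strand calls as two separate observations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import AnalysisError, InputError
from .genome_model import GenomeAssembly
from .motif_scan import IUPACMotif, MotifOccurrence

logger = logging.getLogger(__name__)

DEFAULT_MIN_COVERAGE = 5

SIMPLE_TSV_COLUMNS = ["replicon", "position", "strand", "base",
                      "mod_type", "coverage", "modified"]

# bedMethyl 'name' column codes -> (base, mod_type)
_BEDMETHYL_NAMES: Mapping[str, tuple[str, str]] = {
    "6mA": ("A", "6mA"), "a": ("A", "6mA"),
    "4mC": ("C", "4mC"), "21839": ("C", "4mC"),
    "5mC": ("C", "5mC"), "m": ("C", "5mC"),
    "C": ("C", "any"), "A": ("A", "6mA"),
}

__all__ = [
    "MethylationTable",
    "read_calls",
    "site_fraction",
    "genome_base_methylation",
    "window_profile",
    "motif_methylation",
    "compare_conditions",
    "windows_to_bedgraph",
    "DEFAULT_MIN_COVERAGE",
]


@dataclass
class MethylationTable:
    """Per-site modified-base calls for one condition.

    ``sites`` columns: replicon, position (0-based forward-strand),
    strand (+/-), base (A/C: the base on that strand), mod_type
    (6mA/4mC/5mC/any), coverage, modified.
    """

    condition: str
    sites: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in SIMPLE_TSV_COLUMNS if c not in self.sites.columns]
        if missing:
            raise InputError(f"call table missing columns: {missing}")
        self.sites = self.sites.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.sites)

    def validate(self, assembly: GenomeAssembly) -> "MethylationTable":
        """Drop records on unknown replicons or with modified > coverage.

        Rejected record counts are logged; duplicate
        (replicon, position, strand, mod_type) keys raise.
        """
        df = self.sites
        known = df["replicon"].isin(assembly.names)
        sane = df["modified"] <= df["coverage"]
        bad = int((~known).sum() + (known & ~sane).sum())
        if bad:
            logger.warning("%s: rejected %d call record(s) "
                           "(unknown replicon or modified > coverage)",
                           self.condition, bad)
        df = df[known & sane]
        if df.duplicated(["replicon", "position", "strand", "mod_type"]).any():
            raise InputError(
                f"{self.condition}: duplicate (replicon, position, strand, "
                f"mod_type) records"
            )
        return MethylationTable(condition=self.condition, sites=df)

    def to_simple_tsv(self, path: str | Path) -> None:
        self.sites[SIMPLE_TSV_COLUMNS].to_csv(path, sep="\t", index=False)


def _read_simple_tsv(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#",
                     dtype={"replicon": str, "strand": str, "base": str,
                            "mod_type": str})
    missing = [c for c in SIMPLE_TSV_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing column(s) {missing}")
    for col, line in (("position", None), ("coverage", None), ("modified", None)):
        bad = pd.to_numeric(df[col], errors="coerce").isna()
        if bad.any():
            # +2: header line plus 1-based numbering
            raise InputError(
                f"{path}: malformed {col!r} at line {int(bad.idxmax()) + 2}"
            )
        df[col] = df[col].astype(np.int64)
    return df


def _read_bedmethyl(path: Path) -> pd.DataFrame:
    names = ["replicon", "start", "end", "name", "score", "strand",
             "thick_start", "thick_end", "rgb", "coverage", "percent"]
    try:
        df = pd.read_csv(path, sep=r"\s+", comment="#", header=None,
                         names=names, usecols=range(11))
    except (pd.errors.ParserError, ValueError) as exc:
        raise InputError(f"{path}: malformed bedMethyl ({exc})")
    unknown = ~df["name"].astype(str).isin(_BEDMETHYL_NAMES)
    if unknown.any():
        raise InputError(
            f"{path}: unknown modification code at line "
            f"{int(unknown.idxmax()) + 1}"
        )
    base_mod = df["name"].astype(str).map(_BEDMETHYL_NAMES)
    out = pd.DataFrame({
        "replicon": df["replicon"].astype(str),
        "position": df["start"].astype(np.int64),
        "strand": df["strand"].astype(str),
        "base": [bm[0] for bm in base_mod],
        "mod_type": [bm[1] for bm in base_mod],
        "coverage": df["coverage"].astype(np.int64),
        # modified-read count recovered from the percent column
        "modified": np.rint(df["coverage"].to_numpy()
                            * df["percent"].to_numpy() / 100.0).astype(np.int64),
    })
    return out


def read_calls(path: str | Path, assembly: GenomeAssembly,
               dialect: str = "simple_tsv",
               condition: str | None = None) -> MethylationTable:
    """Read a per-site modified-base call table.

    Dialects: ``simple_tsv`` (columns replicon, position, strand, base,
    mod_type, coverage, modified; 0-based positions) or ``bedmethyl``
    (BED9+2 with coverage and percent-modified columns; the modified
    count is recovered by rounding coverage x percent / 100).
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"call table not found: {path}")
    if dialect == "simple_tsv":
        df = _read_simple_tsv(path)
    elif dialect == "bedmethyl":
        df = _read_bedmethyl(path)
    else:
        raise InputError(f"unknown call-table dialect {dialect!r}")
    table = MethylationTable(condition=condition or path.stem, sites=df)
    return table.validate(assembly)


def site_fraction(coverage: int, modified: int,
                  min_coverage: int = DEFAULT_MIN_COVERAGE) -> float | None:
    """Percent methylated reads at one site, or None if under-covered."""
    if coverage < min_coverage:
        return None
    return 100.0 * modified / coverage


def _included(table: MethylationTable, base: str,
              min_coverage: int) -> pd.DataFrame:
    df = table.sites
    df = df[(df["base"] == base) & (df["coverage"] >= min_coverage)]
    return df


def genome_base_methylation(table: MethylationTable,
                            assembly: GenomeAssembly, base: str,
                            min_coverage: int = DEFAULT_MIN_COVERAGE,
                            ) -> pd.DataFrame:
    """Mean per-site methylation percentage for one base type.

    Returns one row per replicon plus a ``genome`` row: columns
    replicon, base, mean_percent, n_sites.  Unweighted across sites.
    """
    if base not in ("A", "C"):
        raise InputError(f"base must be 'A' or 'C', got {base!r}")
    df = _included(table, base, min_coverage)
    if df.empty:
        raise AnalysisError(
            f"{table.condition}: no {base} sites at coverage >= {min_coverage}"
        )
    frac = 100.0 * df["modified"] / df["coverage"]
    rows = []
    for rep in assembly.names:
        mask = df["replicon"] == rep
        n = int(mask.sum())
        rows.append({
            "replicon": rep, "base": base,
            "mean_percent": float(frac[mask].mean()) if n else float("nan"),
            "n_sites": n,
        })
    rows.append({"replicon": "genome", "base": base,
                 "mean_percent": float(frac.mean()), "n_sites": int(len(df))})
    return pd.DataFrame(rows)


def window_profile(table: MethylationTable, assembly: GenomeAssembly,
                   base: str, width: int = 5000, step: int = 1000,
                   min_coverage: int = DEFAULT_MIN_COVERAGE) -> pd.DataFrame:
    """Sliding-window mean methylation profile for one base type.

    Windows start every ``step`` bases and span ``width`` bases (clipped
    at the replicon end); empty windows are emitted with ``n_sites`` 0
    and NaN percent.  Columns: replicon, window_start, window_end, base,
    percent_methylated, n_sites.
    """
    if width <= 0 or step <= 0:
        raise InputError("window width and step must be positive")
    df = _included(table, base, min_coverage)
    out_frames = []
    for rep in assembly:
        sub = df[df["replicon"] == rep.name]
        pos = np.sort(sub["position"].to_numpy())
        order = np.argsort(sub["position"].to_numpy())
        frac = (100.0 * sub["modified"].to_numpy()
                / sub["coverage"].to_numpy())[order]
        csum = np.concatenate([[0.0], np.cumsum(frac)])
        starts = np.arange(0, rep.length, step, dtype=np.int64)
        ends = np.minimum(starts + width, rep.length)
        lo = np.searchsorted(pos, starts, side="left")
        hi = np.searchsorted(pos, ends, side="left")
        n = hi - lo
        with np.errstate(invalid="ignore"):
            mean = np.where(n > 0, (csum[hi] - csum[lo]) / np.maximum(n, 1),
                            np.nan)
        out_frames.append(pd.DataFrame({
            "replicon": rep.name, "window_start": starts, "window_end": ends,
            "base": base, "percent_methylated": mean, "n_sites": n,
        }))
    return pd.concat(out_frames, ignore_index=True)


def windows_to_bedgraph(profile: pd.DataFrame, path: str | Path) -> None:
    """Write a window profile as bedGraph (NaN windows skipped)."""
    df = profile.dropna(subset=["percent_methylated"])
    with open(path, "w") as fh:
        for row in df.itertuples(index=False):
            fh.write(f"{row.replicon}\t{row.window_start}\t{row.window_end}\t"
                     f"{row.percent_methylated:.2f}\n")


def _mod_type_matches(table_types: pd.Series, motif_type: str) -> pd.Series:
    return (table_types == motif_type) | (table_types == "any")


def motif_methylation(table: MethylationTable,
                      occurrences: Sequence[MotifOccurrence],
                      assembly: GenomeAssembly,
                      min_coverage: int = DEFAULT_MIN_COVERAGE,
                      ) -> pd.DataFrame:
    """Mean methylation over the modified sites of each motif.

    Each strand call of a palindromic locus is a separate observation.
    Returns one row per (motif, replicon) plus a ``genome`` row per
    motif: columns motif, condition, replicon, mean_percent,
    n_sites_used, total_modified, total_coverage, background_percent.
    The background is the same-base genome-wide average, attached for
    context.
    """
    if not occurrences:
        raise AnalysisError("no motif occurrences supplied")
    motifs: list[IUPACMotif] = []
    for occ in occurrences:
        if occ.motif not in motifs:
            motifs.append(occ.motif)

    backgrounds: dict[str, float] = {}
    for motif_base in {m.modified_base for m in motifs}:
        try:
            gbm = genome_base_methylation(table, assembly, motif_base,
                                          min_coverage)
            backgrounds[motif_base] = float(
                gbm.loc[gbm["replicon"] == "genome", "mean_percent"].iloc[0])
        except AnalysisError:
            backgrounds[motif_base] = float("nan")

    rows = []
    for motif in motifs:
        lookup = pd.DataFrame(
            [(occ.replicon, site, strand)
             for occ in occurrences if occ.motif == motif
             for site, strand in occ.modified_sites()],
            columns=["replicon", "position", "strand"],
        ).drop_duplicates()
        calls = table.sites[
            (table.sites["base"] == motif.modified_base)
            & _mod_type_matches(table.sites["mod_type"],
                                motif.modified_base_type)
        ]
        if calls.empty:
            raise AnalysisError(
                f"{table.condition}: no {motif.modified_base_type} calls "
                f"for motif {motif.pattern}"
            )
        obs = lookup.merge(calls, on=["replicon", "position", "strand"],
                           how="inner")
        obs = obs[obs["coverage"] >= min_coverage]
        frac = 100.0 * obs["modified"] / obs["coverage"]
        for rep in [*assembly.names, "genome"]:
            mask = (slice(None) if rep == "genome"
                    else (obs["replicon"] == rep).to_numpy())
            sub_frac = frac if rep == "genome" else frac[mask]
            sub = obs if rep == "genome" else obs[mask]
            rows.append({
                "motif": motif.pattern, "condition": table.condition,
                "replicon": rep,
                "mean_percent": (float(sub_frac.mean()) if len(sub)
                                 else float("nan")),
                "n_sites_used": int(len(sub)),
                "total_modified": int(sub["modified"].sum()),
                "total_coverage": int(sub["coverage"].sum()),
                "background_percent": backgrounds[motif.modified_base],
            })
    return pd.DataFrame(rows)


def compare_conditions(summaries_by_condition: Mapping[str, pd.DataFrame],
                       ) -> pd.DataFrame:
    """Side-by-side per-motif means across conditions plus differences.

    Expects :func:`motif_methylation` outputs keyed by condition label.
    Reports, per (motif, replicon): each condition's unweighted mean, the
    pairwise difference (first condition minus second, in listed order),
    and a pooled-read two-proportion effect size (difference of pooled
    modified/total fractions, percentage points).
    """
    conditions = list(summaries_by_condition)
    if len(conditions) < 2:
        raise AnalysisError("compare_conditions needs >= 2 conditions")
    frames = []
    for cond in conditions:
        df = summaries_by_condition[cond].set_index(["motif", "replicon"])
        if df.index.duplicated().any():
            raise InputError(f"{cond}: duplicate (motif, replicon) rows")
        frames.append(df)
    common = frames[0].index
    for df in frames[1:]:
        common = common.intersection(df.index)
    if common.empty:
        raise AnalysisError("conditions share no (motif, replicon) rows")

    a, b = conditions[0], conditions[1]
    out = pd.DataFrame(index=common)
    for cond, df in zip(conditions, frames):
        out[f"mean_percent_{cond}"] = df.loc[common, "mean_percent"]
        out[f"n_sites_{cond}"] = df.loc[common, "n_sites_used"]
    out["difference"] = (out[f"mean_percent_{a}"] - out[f"mean_percent_{b}"])
    pooled = {}
    for cond, df in zip((a, b), frames[:2]):
        with np.errstate(invalid="ignore", divide="ignore"):
            pooled[cond] = (100.0 * df.loc[common, "total_modified"]
                            / df.loc[common, "total_coverage"])
    out["pooled_difference"] = pooled[a] - pooled[b]
    return out.reset_index()
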