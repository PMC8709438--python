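"""Degenerate IUPAC motif scanning and interval intersection.

Finds every occurrence of restriction–modification target motifs (e.g.
GANTC, GATC, GGCGCC) on both strands of a multi-replicon assembly and
intersects them with gene or promoter intervals.

Palindromic-site convention
---------------------------
All three canonical study motifs are palindromic under IUPAC reverse
complement.  A palindromic match is reported as ONE occurrence (strand
"+") carrying the modified-base coordinate on each strand; methylation
of the two strands is still tracked separately downstream.  Overlapping
matches are all reported, and on circular replicons matches spanning
the origin are included.
"""

from __future__ import annotations

import re
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import pandas as pd
from intervaltree import IntervalTree

from .errors import InputError
from .genome_model import GeneFeature, GenomeAssembly, PromoterRegion

# IUPAC degenerate nucleotide codes -> the set of concrete bases matched.
# Genome positions holding ambiguity codes (including N) never match.
IUPAC_EXPAND: Mapping[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

IUPAC_COMPLEMENT: Mapping[str, str] = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W",
    "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D",
    "N": "N",
}

__all__ = [
    "IUPACMotif",
    "MotifOccurrence",
    "STUDY_MOTIFS",
    "reverse_complement",
    "is_palindromic",
    "scan",
    "count_by_replicon",
    "intersect_with_regions",
    "IntersectionResult",
    "occurrences_to_bed",
]


def reverse_complement(pattern: str) -> str:
    """IUPAC-aware reverse complement of a degenerate pattern."""
    try:
        return "".join(IUPAC_COMPLEMENT[c] for c in reversed(pattern.upper()))
    except KeyError as exc:
        raise InputError(f"invalid IUPAC code {exc.args[0]!r} in {pattern!r}")


@dataclass(frozen=True)
class IUPACMotif:
    """A degenerate target motif with a designated modified base.

    ``modified_position`` is the 1-based index of the methylated base in
    the pattern (e.g. GANTC / 6mA at position 2 is the CcrM target in
    alpha-proteobacteria).
    """

    pattern: str
    modified_position: int
    modified_base_type: str  # 6mA | 4mC | 5mC

    def __post_init__(self) -> None:
        pat = self.pattern.upper()
        for c in pat:
            if c not in IUPAC_EXPAND:
                raise InputError(f"invalid IUPAC code {c!r} in motif {pat!r}")
        object.__setattr__(self, "pattern", pat)
        if not (1 <= self.modified_position <= len(pat)):
            raise InputError(
                f"modified_position {self.modified_position} outside "
                f"pattern {pat!r}"
            )
        if self.modified_base_type not in ("6mA", "4mC", "5mC"):
            raise InputError(
                f"unknown modification type {self.modified_base_type!r}"
            )
        want = "A" if self.modified_base_type == "6mA" else "C"
        if want not in IUPAC_EXPAND[pat[self.modified_position - 1]]:
            raise InputError(
                f"motif {pat!r}: position {self.modified_position} "
                f"({pat[self.modified_position - 1]!r}) is not "
                f"{want}-compatible for {self.modified_base_type}"
            )

    @property
    def length(self) -> int:
        return len(self.pattern)

    @property
    def modified_base(self) -> str:
        """The canonical base carrying the modification ('A' or 'C')."""
        return "A" if self.modified_base_type == "6mA" else "C"

    @property
    def is_palindromic(self) -> bool:
        return self.pattern == reverse_complement(self.pattern)


#: Target motifs of the characterized R–M / orphan methyltransferase
#: systems: CcrM-type GANTC (6mA at 2), Dam-like GATC (4mC at 4), and the
#: GGCGCC R–M target (4mC at 3).
STUDY_MOTIFS: tuple[IUPACMotif, ...] = (
    IUPACMotif("GANTC", 2, "6mA"),
    IUPACMotif("GATC", 4, "4mC"),
    IUPACMotif("GGCGCC", 3, "4mC"),
)


def is_palindromic(motif: Union[IUPACMotif, str]) -> bool:
    """True iff the pattern equals its IUPAC reverse complement."""
    pattern = motif.pattern if isinstance(motif, IUPACMotif) else motif.upper()
    return pattern == reverse_complement(pattern)


@dataclass(frozen=True)
class MotifOccurrence:
    """One located motif match.

    ``start`` is the 0-based forward-strand coordinate of the leftmost
    matched base (modulo replicon length for origin-spanning matches on
    circular replicons).  For palindromic motifs ``strand`` is "+" and
    ``modified_site_minus`` carries the second strand's modified-base
    coordinate; for non-palindromic motifs it is ``None``.
    """

    replicon: str
    start: int
    strand: str
    motif: IUPACMotif
    modified_site: int
    modified_site_minus: int | None = None

    @property
    def end(self) -> int:
        return self.start + self.motif.length

    def modified_sites(self) -> list[tuple[int, str]]:
        """(forward coordinate, strand) of every modified base to look up."""
        sites = [(self.modified_site, self.strand)]
        if self.modified_site_minus is not None:
            sites.append((self.modified_site_minus, "-"))
        return sites


def _pattern_regex(pattern: str) -> re.Pattern:
    # lookahead so overlapping matches are all reported
    parts = []
    for c in pattern:
        bases = IUPAC_EXPAND[c]
        parts.append(bases if len(bases) == 1 else f"[{bases}]")
    return re.compile(f"(?=({''.join(parts)}))")


def _scan_strand(seq: str, length: int, circular: bool,
                 pattern: str) -> list[int]:
    """All match start positions of ``pattern`` on the given sequence."""
    L = len(pattern)
    if circular and length >= L:
        seq = seq + seq[: L - 1]
    rx = _pattern_regex(pattern)
    return [m.start() for m in rx.finditer(seq) if m.start() < length]


def scan(assembly: GenomeAssembly,
         motif: IUPACMotif) -> list[MotifOccurrence]:
    """Find all occurrences of ``motif`` on both strands of the assembly.

    Palindromic motifs yield one occurrence per genomic locus with both
    strand-specific modified-site coordinates; non-palindromic motifs
    yield separate "+" and "-" occurrences.
    """
    L = motif.length
    mp = motif.modified_position
    occs: list[MotifOccurrence] = []
    palindromic = motif.is_palindromic
    rc = reverse_complement(motif.pattern)
    for rep in assembly:
        fwd_starts = _scan_strand(rep.sequence, rep.length,
                                  rep.is_circular, motif.pattern)
        if palindromic:
            for s in fwd_starts:
                occs.append(MotifOccurrence(
                    replicon=rep.name, start=s, strand="+", motif=motif,
                    modified_site=(s + mp - 1) % rep.length,
                    modified_site_minus=(s + L - mp) % rep.length,
                ))
        else:
            for s in fwd_starts:
                occs.append(MotifOccurrence(
                    replicon=rep.name, start=s, strand="+", motif=motif,
                    modified_site=(s + mp - 1) % rep.length,
                ))
            rev_starts = _scan_strand(rep.sequence, rep.length,
                                      rep.is_circular, rc)
            for s in rev_starts:
                occs.append(MotifOccurrence(
                    replicon=rep.name, start=s, strand="-", motif=motif,
                    modified_site=(s + L - mp) % rep.length,
                ))
    return occs


def count_by_replicon(occurrences: Iterable[MotifOccurrence],
                      assembly: GenomeAssembly) -> pd.DataFrame:
    """Count distinct occurrence sites per motif per replicon.

    Returns a motif-pattern x replicon-name integer table including
    zero-count cells for every replicon of the assembly.
    """
    counts: dict[tuple[str, str], int] = defaultdict(int)
    patterns: list[str] = []
    for occ in occurrences:
        pat = occ.motif.pattern
        if pat not in patterns:
            patterns.append(pat)
        counts[(pat, occ.replicon)] += 1
    table = pd.DataFrame(0, index=patterns, columns=assembly.names, dtype=int)
    for (pat, rep), n in counts.items():
        table.loc[pat, rep] = n
    table.index.name = "motif"
    return table


@dataclass
class IntersectionResult:
    """Occurrence/region overlap summary.

    ``counts``: motif x replicon table of distinct occurrences that
    overlap at least one region by >= 1 base. ``gene_hits``: gene_id x
    motif boolean table ("has this motif in its region"), for the
    enrichment module.
    """

    counts: pd.DataFrame
    gene_hits: pd.DataFrame


def _region_segments(region: Union[PromoterRegion, GeneFeature],
                     replicon_length: int) -> list[tuple[int, int]]:
    if isinstance(region, PromoterRegion):
        return region.segments(replicon_length)
    return [(region.start, region.end)]


def intersect_with_regions(
    occurrences: Sequence[MotifOccurrence],
    regions: Sequence[Union[PromoterRegion, GeneFeature]],
    assembly: GenomeAssembly,
) -> IntersectionResult:
    """Overlap motif occurrences with promoter (or gene) intervals.

    An occurrence is inside a region iff its full match interval overlaps
    the region by at least one base (half-open semantics); each occurrence
    counts at most once per region and at most once in the per-replicon
    table even if it touches several regions.
    """
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    region_ids: list[str] = []
    for idx, region in enumerate(regions):
        rep_len = assembly.get(region.replicon).length
        gene_id = getattr(region, "gene_id")
        if gene_id not in region_ids:
            region_ids.append(gene_id)
        for seg_start, seg_end in _region_segments(region, rep_len):
            if seg_end > seg_start:
                trees[region.replicon].addi(seg_start, seg_end, gene_id)

    patterns: list[str] = []
    for occ in occurrences:
        if occ.motif.pattern not in patterns:
            patterns.append(occ.motif.pattern)

    counts = pd.DataFrame(0, index=patterns, columns=assembly.names, dtype=int)
    counts.index.name = "motif"
    hits: dict[tuple[str, str], bool] = {}
    for occ in occurrences:
        rep_len = assembly.get(occ.replicon).length
        span = [(occ.start, occ.start + occ.motif.length)]
        if span[0][1] > rep_len:  # origin-spanning match on circular replicon
            span = [(occ.start, rep_len), (0, span[0][1] - rep_len)]
        genes_touched: set[str] = set()
        for seg_start, seg_end in span:
            for iv in trees[occ.replicon].overlap(seg_start, seg_end):
                genes_touched.add(iv.data)
        if genes_touched:
            counts.loc[occ.motif.pattern, occ.replicon] += 1
            for g in genes_touched:
                hits[(g, occ.motif.pattern)] = True

    gene_hits = pd.DataFrame(False, index=region_ids, columns=patterns, dtype=bool)
    for (g, pat), v in hits.items():
        gene_hits.loc[g, pat] = v
    gene_hits.index.name = "gene_id"
    return IntersectionResult(counts=counts, gene_hits=gene_hits)


def occurrences_to_bed(occurrences: Iterable[MotifOccurrence],
                       path: str | Path) -> None:
    """Export occurrences as BED6 (name = pattern; palindromic sites "+")."""
    with open(path, "w") as fh:
        for occ in occurrences:
            fh.write(
                f"{occ.replicon}\t{occ.start}\t{occ.end}\t"
                f"{occ.motif.pattern}\t0\t{occ.strand}\n"
            )
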