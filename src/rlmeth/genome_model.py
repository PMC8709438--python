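"""Genome assembly and annotation model.

Represents a multi-replicon bacterial assembly (one chromosome plus
plasmids), gene features carrying COG functional categories, and
strand-aware promoter regions (the window immediately upstream of each
gene's start codon).

Coordinate conventions
----------------------
All internal coordinates are 0-based half-open on the forward strand;
GFF3 input (1-based inclusive) is converted on read, and report output
is converted back for display.  Promoters on circular replicons wrap
around the origin: a wrapped interval is stored with ``end > replicon
length`` and is split into two segments only at intersection/export
time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import AnalysisError, InputError

# Full IUPAC nucleotide alphabet accepted in assembly sequences.
IUPAC_ALPHABET = frozenset("ACGTRYSWKMBDHVN")

__all__ = [
    "Replicon",
    "GenomeAssembly",
    "GeneFeature",
    "PromoterRegion",
    "read_assembly",
    "write_assembly",
    "read_genes",
    "extract_promoters",
    "gc_content",
    "promoters_to_bed",
]


@dataclass(frozen=True)
class Replicon:
    """One independently replicating sequence (chromosome or plasmid)."""

    name: str
    sequence: str
    topology: str = "circular"

    def __post_init__(self) -> None:
        if not self.name:
            raise InputError("replicon name must be non-empty")
        if self.topology not in ("circular", "linear"):
            raise InputError(f"unknown topology {self.topology!r}")
        seq = self.sequence.upper()
        if len(seq) == 0:
            raise InputError(f"replicon {self.name!r} has an empty sequence")
        for i, ch in enumerate(seq):
            if ch not in IUPAC_ALPHABET:
                raise InputError(
                    f"replicon {self.name!r}: non-nucleotide character "
                    f"{ch!r} at position {i}"
                )
        object.__setattr__(self, "sequence", seq)

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def is_circular(self) -> bool:
        return self.topology == "circular"


@dataclass(frozen=True)
class GenomeAssembly:
    """Ordered collection of replicons with a designated chromosome.

    The chromosome serves as the normalization reference for relative
    replicon copy-number estimates.
    """

    replicons: tuple[Replicon, ...]
    chromosome_name: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "replicons", tuple(self.replicons))
        names = [r.name for r in self.replicons]
        if len(names) != len(set(names)):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise InputError(f"duplicate replicon name(s): {', '.join(dup)}")
        if self.chromosome_name not in names:
            raise InputError(
                f"chromosome {self.chromosome_name!r} not among replicons "
                f"{names}"
            )

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.replicons]

    def __iter__(self):
        return iter(self.replicons)

    def __len__(self) -> int:
        return len(self.replicons)

    def get(self, name: str) -> Replicon:
        for r in self.replicons:
            if r.name == name:
                return r
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(r.name == name for r in self.replicons)

    @property
    def chromosome(self) -> Replicon:
        return self.get(self.chromosome_name)

    @property
    def total_length(self) -> int:
        return sum(r.length for r in self.replicons)


@dataclass(frozen=True)
class GeneFeature:
    """A stranded gene interval with optional COG category letters."""

    gene_id: str
    replicon: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    strand: str
    cog_categories: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise InputError(f"gene {self.gene_id!r}: bad strand {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise InputError(
                f"gene {self.gene_id!r}: degenerate interval "
                f"[{self.start}, {self.end})"
            )
        object.__setattr__(self, "cog_categories", frozenset(self.cog_categories))

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class PromoterRegion:
    """Strand-aware upstream window of a gene.

    ``end`` may exceed the replicon length for windows that wrap around
    the origin of a circular replicon; segment arithmetic is handled by
    consumers via :meth:`segments`.
    """

    gene_id: str
    replicon: str
    start: int
    end: int
    strand: str

    @property
    def width(self) -> int:
        return self.end - self.start

    def segments(self, replicon_length: int) -> list[tuple[int, int]]:
        """Decompose into non-wrapping [start, end) pieces on the replicon."""
        if self.end <= replicon_length:
            return [(self.start, self.end)]
        return [(self.start, replicon_length), (0, self.end - replicon_length)]


def read_assembly(fasta_path: str | Path, chromosome_name: str | None = None,
                  topology: str = "circular") -> GenomeAssembly:
    """Load a multi-record FASTA as a :class:`GenomeAssembly`.

    Parameters
    ----------
    fasta_path
        Path to a multi-record nucleotide FASTA, one record per replicon.
    chromosome_name
        Record id of the chromosome; defaults to the first record.
    topology
        Topology assigned to every replicon (bacterial assemblies here
        are circular by default).
    """
    path = Path(fasta_path)
    if not path.exists():
        raise InputError(f"FASTA file not found: {path}")
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise InputError(f"no FASTA records in {path}")
    replicons = tuple(
        Replicon(name=rec.id, sequence=str(rec.seq), topology=topology)
        for rec in records
    )
    if chromosome_name is None:
        chromosome_name = replicons[0].name
    return GenomeAssembly(replicons=replicons, chromosome_name=chromosome_name)


def write_assembly(assembly: GenomeAssembly, fasta_path: str | Path) -> None:
    """Write the assembly back to multi-record FASTA (round-trip safe)."""
    records = [
        SeqRecord(Seq(r.sequence), id=r.name, description="")
        for r in assembly
    ]
    SeqIO.write(records, str(fasta_path), "fasta")


def _cog_letters(values: Iterable[str]) -> frozenset[str]:
    letters: set[str] = set()
    for v in values:
        for part in v.replace(",", "").strip():
            if part.isalpha():
                letters.add(part.upper())
    return frozenset(letters)


def read_genes(gff3_path: str | Path, assembly: GenomeAssembly,
               cog_attribute: str = "COG",
               feature_types: Sequence[str] = ("gene", "CDS")) -> list[GeneFeature]:
    """Load gene features from GFF3, converting to 0-based half-open.

    Uses ``gene`` records when present, else ``CDS``.  COG categories are
    read from the attribute named ``cog_attribute``; multi-letter values
    contribute one category per letter.
    """
    path = Path(gff3_path)
    if not path.exists():
        raise InputError(f"GFF3 file not found: {path}")
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique", sort_attribute_values=False,
    )
    available = set(db.featuretypes())
    use_type = None
    for ft in feature_types:
        if ft in available:
            use_type = ft
            break
    if use_type is None:
        raise InputError(
            f"no {'/'.join(feature_types)} features in {path} "
            f"(found: {sorted(available)})"
        )
    genes: list[GeneFeature] = []
    for feat in db.features_of_type(use_type, order_by=("seqid", "start")):
        if feat.seqid not in assembly:
            raise InputError(
                f"feature {feat.id!r} on unknown replicon {feat.seqid!r}"
            )
        rep = assembly.get(feat.seqid)
        start, end = feat.start - 1, feat.end  # GFF3 is 1-based inclusive
        if end < feat.start:
            raise InputError(f"feature {feat.id!r}: end < start")
        if not (0 <= start < end <= rep.length):
            raise InputError(
                f"feature {feat.id!r} outside replicon {rep.name!r} bounds "
                f"[{start}, {end}) vs length {rep.length}"
            )
        strand = feat.strand if feat.strand in ("+", "-") else "+"
        cogs = _cog_letters(feat.attributes.get(cog_attribute, []))
        genes.append(GeneFeature(
            gene_id=feat.id, replicon=feat.seqid, start=start, end=end,
            strand=strand, cog_categories=cogs,
        ))
    return genes


def extract_promoters(genes: Iterable[GeneFeature], assembly: GenomeAssembly,
                      upstream_len: int = 100) -> list[PromoterRegion]:
    """Derive the ``upstream_len``-bp window upstream of each gene start.

    For a + strand gene [s, e) the promoter is [s - upstream_len, s); for
    a - strand gene it is [e, e + upstream_len).  On circular replicons
    the window wraps around the origin; on linear replicons it is clipped
    at the sequence boundary.
    """
    if upstream_len <= 0:
        raise InputError("upstream_len must be positive")
    promoters: list[PromoterRegion] = []
    for gene in genes:
        rep = assembly.get(gene.replicon)
        if gene.strand == "+":
            start, end = gene.start - upstream_len, gene.start
        else:
            start, end = gene.end, gene.end + upstream_len
        if rep.is_circular:
            # canonicalize so 0 <= start < length; end may wrap past length
            start_mod = start % rep.length
            end = start_mod + (end - start)
            start = start_mod
        else:
            start = max(start, 0)
            end = min(end, rep.length)
        if end <= start:
            continue  # window entirely off a linear replicon
        promoters.append(PromoterRegion(
            gene_id=gene.gene_id, replicon=gene.replicon,
            start=start, end=end, strand=gene.strand,
        ))
    return promoters


def gc_content(replicon_or_sequence: Replicon | str) -> float:
    """Percent G+C over unambiguous bases (N and other codes excluded)."""
    seq = (replicon_or_sequence.sequence
           if isinstance(replicon_or_sequence, Replicon)
           else replicon_or_sequence.upper())
    gc = seq.count("G") + seq.count("C")
    total = gc + seq.count("A") + seq.count("T")
    if total == 0:
        raise AnalysisError("GC content undefined: no unambiguous bases")
    return 100.0 * gc / total


def promoters_to_bed(promoters: Iterable[PromoterRegion],
                     assembly: GenomeAssembly, path: str | Path) -> None:
    """Export promoters as BED6 (0-based half-open, score 0).

    Wrapped promoters on circular replicons are emitted as two lines
    sharing the gene id.
    """
    with open(path, "w") as fh:
        for p in promoters:
            rep_len = assembly.get(p.replicon).length
            for seg_start, seg_end in p.segments(rep_len):
                fh.write(
                    f"{p.replicon}\t{seg_start}\t{seg_end}\t{p.gene_id}\t0\t{p.strand}\n"
                )
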