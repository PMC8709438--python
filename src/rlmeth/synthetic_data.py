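"""Synthetic multi-replicon methylome generator.

Generates genomes with set GC content and replicon copy-number ratios,
COG-annotated gene rosters, per-position read-depth tracks, and per-site
modified-base call tables with the statistical structure the analysis
assumes: coverage is Poisson around (mean depth x replicon copy ratio),
and the modified-read count at each A/C site is Binomial with a per-site
probability — a motif-specific probability at the modified sites of
scanned motif occurrences, a base-specific background elsewhere.

Two packaged "emulation" condition profiles (``bacteroid`` and
``cell_culture``) encode the free-living vs. symbiotic parameter sets
this package is organized around; see ``docs/methods.md`` for their
provenance and the handful of invented values.

All generators are bit-reproducible given (seed, parameters).  Phase
variation and Ori->Ter replication gradients are not modelled: sites
are i.i.d.  A ``position_effect`` hook on :func:`simulate_calls` allows
a position-dependent probability modifier.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from importlib import resources
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import AnalysisError, InputError
from .genome_model import GeneFeature, GenomeAssembly, Replicon, write_assembly
from .methylation_calls import MethylationTable
from .motif_scan import IUPACMotif, STUDY_MOTIFS, scan

__all__ = [
    "ConditionProfile",
    "SimulationBundle",
    "load_profile",
    "packaged_profile",
    "EMULATION_REPLICONS",
    "emulation_assembly",
    "make_genome",
    "make_genes",
    "simulate_calls",
    "simulate_depth",
    "simulate_depth_track",
    "simulate_bundle",
    "DEFAULT_COG_FREQUENCIES",
]

#: Scaled-down emulation replicon roster: name -> (length, GC percent).
#: Lengths total 500 kb, keeping the chromosome dominant and the
#: symbiotic plasmid the smallest replicon; GC values follow the real
#: assembly's per-replicon composition.
EMULATION_REPLICONS: dict[str, tuple[int, float]] = {
    "Chromosome": (300_000, 61.09),
    "pRL10": (40_000, 60.61),
    "pRL11": (40_000, 60.89),
    "pRL12": (50_000, 60.40),
    "pSym": (70_000, 58.12),
}

#: Rough single-letter COG frequencies for a rhizobial genome; "None"
#: weight is the unannotated fraction.
DEFAULT_COG_FREQUENCIES: dict[str | None, float] = {
    None: 0.25,
    "E": 0.09, "G": 0.08, "K": 0.08, "R": 0.07, "S": 0.07, "C": 0.06,
    "M": 0.05, "P": 0.05, "T": 0.05, "J": 0.04, "L": 0.04, "H": 0.03,
    "I": 0.03, "O": 0.03, "F": 0.02, "N": 0.02, "U": 0.02, "Q": 0.01,
    "V": 0.01,
}


@dataclass(frozen=True)
class ConditionProfile:
    """Ground-truth parameter set for one simulated condition.

    ``motif_meth_prob`` maps a motif pattern to either a single
    probability or a per-replicon map (key ``default`` for unlisted
    replicons) that a read at the motif's modified site is called
    modified.  ``background_prob`` gives the same for non-motif A and C
    sites.  ``replicon_copy_ratio`` scales ``mean_depth`` per replicon
    (chromosome fixed at 1).
    """

    label: str
    motif_meth_prob: Mapping[str, float | Mapping[str, float]]
    background_prob: Mapping[str, float]
    replicon_copy_ratio: Mapping[str, float]
    mean_depth: float
    seed: int | None = None

    def __post_init__(self) -> None:
        for base in ("A", "C"):
            if base not in self.background_prob:
                raise InputError(f"background_prob missing base {base!r}")
        for p in self._all_probs():
            if not (0.0 <= p <= 1.0):
                raise InputError(f"probability {p} outside [0, 1]")
        for rep, ratio in self.replicon_copy_ratio.items():
            if ratio <= 0:
                raise InputError(f"copy ratio for {rep!r} must be positive")
        if self.mean_depth <= 0:
            raise InputError("mean_depth must be positive")

    def _all_probs(self):
        for v in self.motif_meth_prob.values():
            if isinstance(v, Mapping):
                yield from v.values()
            else:
                yield v
        yield from self.background_prob.values()

    def motif_prob(self, pattern: str, replicon: str) -> float:
        """Resolve the methylation probability for a motif on a replicon."""
        v = self.motif_meth_prob[pattern]
        if isinstance(v, Mapping):
            if replicon in v:
                return float(v[replicon])
            if "default" in v:
                return float(v["default"])
            raise InputError(
                f"profile {self.label!r}: no probability for motif "
                f"{pattern!r} on replicon {replicon!r}"
            )
        return float(v)

    def copy_ratio(self, replicon: str) -> float:
        return float(self.replicon_copy_ratio.get(replicon, 1.0))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["motif_meth_prob"] = {k: (dict(v) if isinstance(v, Mapping) else v)
                                for k, v in self.motif_meth_prob.items()}
        d["background_prob"] = dict(self.background_prob)
        d["replicon_copy_ratio"] = dict(self.replicon_copy_ratio)
        return d


def load_profile(path: str | Path) -> ConditionProfile:
    """Load a :class:`ConditionProfile` from a JSON file."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"profile not found: {path}")
    with open(path) as fh:
        data = json.load(fh)
    try:
        return ConditionProfile(**data)
    except TypeError as exc:
        raise InputError(f"{path}: bad profile schema ({exc})")


def packaged_profile(name: str) -> ConditionProfile:
    """Load a packaged emulation profile (``bacteroid`` / ``cell_culture``)."""
    ref = resources.files("rlmeth.profiles").joinpath(f"{name}.json")
    if not ref.is_file():
        raise InputError(f"no packaged profile named {name!r}")
    return ConditionProfile(**json.loads(ref.read_text()))


def make_genome(lengths: Mapping[str, int] | Sequence[int],
                gc_percent: float | Mapping[str, float],
                seed: int | np.random.SeedSequence,
                chromosome_name: str | None = None) -> GenomeAssembly:
    """Random i.i.d. genome with the requested GC composition.

    ``lengths`` maps replicon name -> length (or is a plain sequence of
    lengths, auto-named ``chr``, ``p1``, ...).  Per-base probabilities
    are P(G) = P(C) = gc/200, P(A) = P(T) = (100-gc)/200.
    """
    if not isinstance(lengths, Mapping):
        names = ["chr"] + [f"p{i}" for i in range(1, len(lengths))]
        lengths = dict(zip(names, lengths))
    if not lengths:
        raise InputError("need at least one replicon")
    rng = np.random.default_rng(seed)
    bases = np.frombuffer(b"ACGT", dtype="S1")
    replicons = []
    for name, length in lengths.items():
        if length <= 0:
            raise InputError(f"replicon {name!r}: length must be positive")
        gc = (gc_percent[name] if isinstance(gc_percent, Mapping)
              else gc_percent)
        if not (0.0 < gc < 100.0):
            raise InputError(f"GC percent {gc} outside (0, 100)")
        p_gc = gc / 200.0
        p_at = (100.0 - gc) / 200.0
        draw = rng.choice(bases, size=length, p=[p_at, p_gc, p_gc, p_at])
        replicons.append(Replicon(name=name,
                                  sequence=draw.tobytes().decode("ascii")))
    if chromosome_name is None:
        chromosome_name = replicons[0].name
    return GenomeAssembly(replicons=tuple(replicons),
                          chromosome_name=chromosome_name)


def emulation_assembly(seed: int | np.random.SeedSequence) -> GenomeAssembly:
    """The scaled-down (500 kb) five-replicon emulation genome."""
    return make_genome({n: l for n, (l, _) in EMULATION_REPLICONS.items()},
                       {n: gc for n, (_, gc) in EMULATION_REPLICONS.items()},
                       seed, chromosome_name="Chromosome")


def make_genes(assembly: GenomeAssembly, n_genes: int,
               mean_len: int = 900,
               cog_frequencies: Mapping[str | None, float] | None = None,
               seed: int | np.random.SeedSequence = 0) -> list[GeneFeature]:
    """Place non-overlapping stranded genes with COG labels.

    Genes are allotted to replicons proportionally to length and placed
    left to right with exponential gaps; COG letters are drawn from
    ``cog_frequencies`` (key ``None`` = unannotated weight).
    """
    if n_genes < 1:
        raise InputError("n_genes must be >= 1")
    if cog_frequencies is None:
        cog_frequencies = DEFAULT_COG_FREQUENCIES
    letters = list(cog_frequencies)
    weights = np.asarray([cog_frequencies[l] for l in letters], dtype=float)
    weights = weights / weights.sum()
    rng = np.random.default_rng(seed)
    total = assembly.total_length
    genes: list[GeneFeature] = []
    gene_no = 0
    for rep in assembly:
        n_rep = max(1, round(n_genes * rep.length / total))
        body = int(n_rep * mean_len * 1.1)
        if body >= rep.length:
            raise AnalysisError(
                f"replicon {rep.name!r} too small for {n_rep} genes of "
                f"mean length {mean_len}"
            )
        mean_gap = max((rep.length - n_rep * mean_len) / (n_rep + 1), 1.0)
        pos = 0
        for _ in range(n_rep):
            pos += int(rng.exponential(mean_gap)) + 1
            length = max(90, int(rng.normal(mean_len, mean_len / 4)))
            if pos + length > rep.length:
                break
            strand = "+" if rng.random() < 0.5 else "-"
            letter = letters[rng.choice(len(letters), p=weights)]
            cogs = frozenset() if letter is None else frozenset({letter})
            gene_no += 1
            genes.append(GeneFeature(
                gene_id=f"gene_{gene_no:05d}", replicon=rep.name,
                start=pos, end=pos + length, strand=strand,
                cog_categories=cogs,
            ))
            pos += length
    return genes


_BASE_TO_CALL = {
    # forward base -> (strand of the called base, called base)
    "A": ("+", "A"), "T": ("-", "A"), "C": ("+", "C"), "G": ("-", "C"),
}


def simulate_calls(assembly: GenomeAssembly,
                   motifs: Sequence[IUPACMotif],
                   profile: ConditionProfile,
                   seed: int | np.random.SeedSequence | None = None,
                   position_effect: Callable[[str, np.ndarray, np.ndarray],
                                             np.ndarray] | None = None,
                   ) -> MethylationTable:
    """Simulate a per-site modified-base call table for one condition.

    Every A and C on each strand gets one call row: coverage ~
    Poisson(mean_depth x copy ratio) and modified ~ Binomial(coverage,
    p), where p is the motif probability at scanned modified sites (the
    longer motif wins when sites of two motifs coincide) and the
    base-specific background elsewhere.  ``position_effect(replicon,
    positions, p)`` may return a modified probability vector (hook for
    replication-gradient models).
    """
    if seed is None:
        seed = profile.seed if profile.seed is not None else 0
    rng = np.random.default_rng(seed)
    frames = []
    for rep in assembly:
        seq = np.frombuffer(rep.sequence.encode("ascii"), dtype="S1")
        seq = seq.astype("U1")
        callable_mask = np.isin(seq, list(_BASE_TO_CALL))
        positions = np.nonzero(callable_mask)[0]
        fwd_base = seq[positions]
        strand = np.empty(positions.shape, dtype="U1")
        base = np.empty(positions.shape, dtype="U1")
        for b, (s, c) in _BASE_TO_CALL.items():
            m = fwd_base == b
            strand[m] = s
            base[m] = c
        p = np.where(base == "A",
                     profile.background_prob["A"],
                     profile.background_prob["C"]).astype(float)
        mod_type = np.where(base == "A", "6mA", "4mC").astype(object)
        # position index within the `positions` array, for motif overrides
        pos_to_idx = np.full(rep.length, -1, dtype=np.int64)
        pos_to_idx[positions] = np.arange(len(positions))
        sub_assembly = GenomeAssembly(replicons=(rep,),
                                      chromosome_name=rep.name)
        for motif in sorted(motifs, key=lambda m: m.length):
            prob = profile.motif_prob(motif.pattern, rep.name)
            for occ in scan(sub_assembly, motif):
                for site, _site_strand in occ.modified_sites():
                    idx = pos_to_idx[site]
                    if idx >= 0:
                        p[idx] = prob
                        mod_type[idx] = motif.modified_base_type
        if position_effect is not None:
            p = np.clip(position_effect(rep.name, positions, p), 0.0, 1.0)
        depth_mean = profile.mean_depth * profile.copy_ratio(rep.name)
        coverage = rng.poisson(depth_mean, size=len(positions))
        modified = rng.binomial(coverage, p)
        frames.append(pd.DataFrame({
            "replicon": rep.name, "position": positions, "strand": strand,
            "base": base, "mod_type": mod_type.astype(str),
            "coverage": coverage, "modified": modified,
        }))
    sites = pd.concat(frames, ignore_index=True)
    return MethylationTable(condition=profile.label, sites=sites)


def simulate_depth_track(assembly: GenomeAssembly,
                         profile: ConditionProfile,
                         seed: int | np.random.SeedSequence | None = None,
                         ) -> pd.DataFrame:
    """Per-position Poisson depth track (bedGraph-shaped DataFrame)."""
    if seed is None:
        seed = profile.seed if profile.seed is not None else 0
    rng = np.random.default_rng(seed)
    frames = []
    for rep in assembly:
        mean = profile.mean_depth * profile.copy_ratio(rep.name)
        depth = rng.poisson(mean, size=rep.length)
        # collapse runs of equal depth into bedGraph intervals
        change = np.nonzero(np.diff(depth))[0] + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [rep.length]])
        frames.append(pd.DataFrame({
            "replicon": rep.name, "start": starts, "end": ends,
            "depth": depth[starts],
        }))
    return pd.concat(frames, ignore_index=True)


def simulate_depth(assembly: GenomeAssembly, profile: ConditionProfile,
                   seed: int | np.random.SeedSequence | None = None,
                   ) -> pd.DataFrame:
    """Per-replicon mean-depth summaries from a simulated track."""
    track = simulate_depth_track(assembly, profile, seed)
    rows = []
    for rep in assembly:
        sub = track[track["replicon"] == rep.name]
        lengths = (sub["end"] - sub["start"]).to_numpy()
        mean = float((sub["depth"].to_numpy() * lengths).sum() / rep.length)
        rows.append({"condition": profile.label, "replicon": rep.name,
                     "mean_depth": mean, "n_positions": rep.length})
    return pd.DataFrame(rows)


@dataclass
class SimulationBundle:
    """Everything one simulated study produces, plus its ground truth."""

    assembly: GenomeAssembly
    genes: list[GeneFeature]
    tables: dict[str, MethylationTable]
    coverage: pd.DataFrame
    ground_truth: dict[str, ConditionProfile]
    motifs: tuple[IUPACMotif, ...] = STUDY_MOTIFS

    def write(self, outdir: str | Path) -> None:
        """Write FASTA, GFF3, call TSVs, depth TSV and ground truth JSON."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_assembly(self.assembly, outdir / "genome.fasta")
        write_gff3(self.genes, self.assembly, outdir / "genes.gff3")
        for cond, table in self.tables.items():
            table.to_simple_tsv(outdir / f"calls_{cond}.tsv")
        self.coverage.to_csv(outdir / "depth_summary.tsv", sep="\t",
                             index=False)
        truth = {
            "profiles": {c: p.to_dict() for c, p in self.ground_truth.items()},
            "motifs": [{"pattern": m.pattern,
                        "modified_position": m.modified_position,
                        "modified_base_type": m.modified_base_type}
                       for m in self.motifs],
        }
        with open(outdir / "ground_truth.json", "w") as fh:
            json.dump(truth, fh, indent=2)


def write_gff3(genes: Sequence[GeneFeature], assembly: GenomeAssembly,
               path: str | Path, cog_attribute: str = "COG") -> None:
    """Write gene features as GFF3 (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for rep in assembly:
            fh.write(f"##sequence-region {rep.name} 1 {rep.length}\n")
        for g in genes:
            attrs = f"ID={g.gene_id}"
            if g.cog_categories:
                attrs += f";{cog_attribute}={''.join(sorted(g.cog_categories))}"
            fh.write(f"{g.replicon}\trlmeth_sim\tgene\t{g.start + 1}\t{g.end}"
                     f"\t.\t{g.strand}\t.\t{attrs}\n")


def simulate_bundle(profiles: Sequence[ConditionProfile],
                    seed: int,
                    assembly: GenomeAssembly | None = None,
                    motifs: Sequence[IUPACMotif] = STUDY_MOTIFS,
                    n_genes: int = 500) -> SimulationBundle:
    """Generate a full synthetic study: genome, genes, calls, depth.

    All randomness derives from ``seed`` via spawned child generators,
    so a bundle is bit-reproducible.
    """
    ss = np.random.SeedSequence(seed)
    children = iter(ss.spawn(2 + 2 * len(profiles)))
    if assembly is None:
        assembly = emulation_assembly(next(children))
    else:
        next(children)
    genes = make_genes(assembly, n_genes=n_genes, seed=next(children))
    tables: dict[str, MethylationTable] = {}
    coverage_frames = []
    for profile in profiles:
        tables[profile.label] = simulate_calls(assembly, motifs, profile,
                                               seed=next(children))
        coverage_frames.append(simulate_depth(assembly, profile,
                                              seed=next(children)))
    return SimulationBundle(
        assembly=assembly, genes=genes, tables=tables,
        coverage=pd.concat(coverage_frames, ignore_index=True),
        ground_truth={p.label: p for p in profiles},
        motifs=tuple(motifs),
    )
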