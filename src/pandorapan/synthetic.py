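"""Synthetic multi-genome protein sets and scaffolds with planted truth.

The generator emulates the structure of a giant-virus pangenome: a set of
gene families partitioned into *core* (present in every genome), *shell*
(present in each genome with probability ``shell_p``) and *cloud* families
(unique to one genome, the ORFan-like fraction), with optional within-genome
paralog duplications and controlled amino-acid divergence. Protein lengths
follow a truncated gamma distribution with mean ≈ 250 aa and a heavy right
tail (SD ≈ 200), floored at the 50-aa minimum that the annotation pipeline
enforces. Nucleotide scaffolds carry planted MITE-like elements bounded by
exact terminal inverted repeats (TIRs) and flanked by identical target-site
duplications (TSDs).

Divergence model: members of a family derive from a common ancestral
sequence by independent per-site substitution (no indels), with the per-site
rate μ chosen so that the *expected pairwise identity between members*
equals the requested ``identity``: two members agree at a site if neither
mutated, (1−μ)², or if both mutated to the same of the 19 alternative
residues, μ²/19, giving μ = (19/20)·(1 − sqrt(1 − (20/19)(1−identity))).
Paralogs are duplicated from a genome's member and re-mutated at μ/2, so
within-genome copies are detectably more similar than cross-genome
orthologs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from pandorapan.records import GeneRecord
from pandorapan.utils import reverse_complement

AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
NT = np.array(list("ACGT"))

# gamma length model: mean 250 aa, SD 200 aa, truncated to [50, 2500]
LENGTH_SHAPE = (250.0 / 200.0) ** 2
LENGTH_SCALE = 200.0 ** 2 / 250.0
MIN_LENGTH = 50
MAX_LENGTH = 2500


@dataclass(frozen=True)
class FamilySpec:
    """Planted gene family: occupancy class and divergence parameters."""

    family_id: str
    occupancy: str  # "core" | "shell" | "cloud"
    shell_p: float = 1.0
    ancestral_length: int = 250
    target_identity: float = 0.8
    paralog_prob: float = 0.0

    def __post_init__(self) -> None:
        if self.occupancy not in ("core", "shell", "cloud"):
            raise ValueError(f"unknown occupancy {self.occupancy!r}")
        if not 0.0 < self.target_identity <= 1.0:
            raise ValueError("target_identity must be in (0, 1]")
        if self.ancestral_length < MIN_LENGTH:
            raise ValueError(f"ancestral_length must be >= {MIN_LENGTH}")


@dataclass
class MitePlant:
    """One planted MITE-like element (coordinates 0-based half-open)."""

    genome_id: str
    start: int
    end: int
    tsd: str
    tir_length: int


@dataclass
class SyntheticTruth:
    """Ground truth recorded while generating a synthetic dataset."""

    gene_to_family: dict[str, str] = field(default_factory=dict)
    family_genomes: dict[str, set[str]] = field(default_factory=dict)
    planted_core: int = 0
    genome_ids: list[str] = field(default_factory=list)
    paralog_genes: set[str] = field(default_factory=set)
    mites: list[MitePlant] = field(default_factory=list)
    mite_consensus: str | None = None

    def families_in_all_genomes(self) -> int:
        """Number of families with at least one member in every genome."""
        all_g = set(self.genome_ids)
        return sum(1 for g in self.family_genomes.values() if g >= all_g)


def _mutation_rate(identity: float) -> float:
    """Per-site substitution rate giving expected pairwise identity ``identity``."""
    disc = 1.0 - (20.0 / 19.0) * (1.0 - identity)
    if disc < 0:
        raise ValueError("target identity too low for the substitution model (< 0.05)")
    return (19.0 / 20.0) * (1.0 - math.sqrt(disc))


def _random_length(rng: np.random.Generator) -> int:
    while True:
        ln = int(rng.gamma(LENGTH_SHAPE, LENGTH_SCALE))
        if MIN_LENGTH <= ln <= MAX_LENGTH:
            return ln


def _random_protein(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 20, size=length)


def _mutate(rng: np.random.Generator, seq: np.ndarray, mu: float) -> np.ndarray:
    """Substitute each site with probability mu, uniformly to another residue."""
    out = seq.copy()
    mask = rng.random(seq.shape[0]) < mu
    n = int(mask.sum())
    if n:
        # draw from the 19 alternatives by offsetting 1..19 modulo 20
        out[mask] = (out[mask] + rng.integers(1, 20, size=n)) % 20
    return out


def _decode(seq: np.ndarray) -> str:
    return "".join(AA[seq])


def generate_pangenome(
    n_genomes: int,
    n_core: int,
    n_shell: int = 0,
    shell_p: float = 0.5,
    n_cloud_per_genome: int = 0,
    identity: float = 0.8,
    paralog_prob: float = 0.0,
    seed: int = 0,
) -> tuple[dict[str, list[GeneRecord]], SyntheticTruth]:
    """Generate per-genome protein sets with known family structure.

    Returns ``(genomes, truth)`` where ``genomes`` maps genome id to its
    list of :class:`GeneRecord` and ``truth`` records the planted
    gene-to-family map. Deterministic for a given seed.
    """
    if n_genomes < 1:
        raise ValueError("n_genomes must be >= 1")
    for name, v in (("shell_p", shell_p), ("paralog_prob", paralog_prob)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be a probability in [0, 1]")
    if not 0.0 < identity <= 1.0:
        raise ValueError("identity must be in (0, 1]")
    for name, v in (
        ("n_core", n_core),
        ("n_shell", n_shell),
        ("n_cloud_per_genome", n_cloud_per_genome),
    ):
        if v < 0:
            raise ValueError(f"{name} must be >= 0")

    rng = np.random.default_rng(seed)
    mu = _mutation_rate(identity)
    genome_ids = [f"G{i + 1}" for i in range(n_genomes)]
    genomes: dict[str, list[GeneRecord]] = {g: [] for g in genome_ids}
    counters = {g: 0 for g in genome_ids}
    truth = SyntheticTruth(genome_ids=list(genome_ids), planted_core=n_core)

    def emit(genome: str, seq: np.ndarray, family: str, paralog: bool = False) -> None:
        counters[genome] += 1
        gid = f"{genome}_orf{counters[genome]:05d}"
        genomes[genome].append(GeneRecord(genome, gid, _decode(seq)))
        truth.gene_to_family[gid] = family
        truth.family_genomes.setdefault(family, set()).add(genome)
        if paralog:
            truth.paralog_genes.add(gid)

    # core and shell families
    family_plan = [(f"core{i + 1:05d}", "core", 1.0) for i in range(n_core)]
    family_plan += [(f"shell{i + 1:05d}", "shell", shell_p) for i in range(n_shell)]
    for fam_id, occupancy, p in family_plan:
        length = _random_length(rng)
        spec = FamilySpec(fam_id, occupancy, p, length, identity, paralog_prob)
        ancestral = _random_protein(rng, length)
        if spec.occupancy == "core":
            present = genome_ids
        else:
            mask = rng.random(n_genomes) < spec.shell_p
            present = [g for g, keep in zip(genome_ids, mask) if keep]
        for genome in present:
            member = _mutate(rng, ancestral, mu)
            emit(genome, member, spec.family_id)
            if rng.random() < spec.paralog_prob:
                emit(genome, _mutate(rng, member, mu / 2.0), spec.family_id, paralog=True)
        truth.family_genomes.setdefault(spec.family_id, set())

    # cloud families: unique to one genome, fresh random sequences
    cloud_i = 0
    for genome in genome_ids:
        for _ in range(n_cloud_per_genome):
            cloud_i += 1
            fam = f"cloud{cloud_i:05d}"
            emit(genome, _random_protein(rng, _random_length(rng)), fam)
    return genomes, truth


# --- MITE planting -----------------------------------------------------------


def _random_nuc(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length)


def _decode_nt(seq: np.ndarray) -> str:
    return "".join(NT[seq])


def _mutate_nt(rng: np.random.Generator, seq: np.ndarray, mu: float) -> np.ndarray:
    out = seq.copy()
    mask = rng.random(seq.shape[0]) < mu
    n = int(mask.sum())
    if n:
        out[mask] = (out[mask] + rng.integers(1, 4, size=n)) % 4
    return out


def plant_mites(
    scaffold_length: int,
    n_mites: int,
    mite_length: int,
    tir_length: int,
    tsd_length: int,
    seed: int = 0,
    genome_id: str = "G1",
    copy_identity: float = 1.0,
) -> tuple[str, SyntheticTruth]:
    """Random scaffold with ``n_mites`` planted MITE-like elements.

    Each element is ``mite_length`` bp, begins with a TIR whose exact
    reverse complement ends it, and is flanked by two identical
    ``tsd_length``-bp direct repeats. With ``copy_identity`` < 1, each
    copy's internal region (between the TIRs) is mutated so the whole
    element diverges from the consensus by roughly that amount; TIRs and
    TSDs stay exact. The consensus element is recorded in the truth for use
    as a scan query.
    """
    if not 100 <= mite_length <= 600:
        raise ValueError("mite_length must be within [100, 600] bp")
    if n_mites < 0:
        raise ValueError("n_mites must be >= 0")
    if tir_length < 1 or 2 * tir_length >= mite_length:
        raise ValueError("tir_length must satisfy 0 < 2*tir_length < mite_length")
    if not 0.0 < copy_identity <= 1.0:
        raise ValueError("copy_identity must be in (0, 1]")
    slot = mite_length + 2 * tsd_length
    if n_mites and scaffold_length <= n_mites * slot:
        raise ValueError(
            f"cannot place {n_mites} elements of {slot} bp (with TSDs) "
            f"in a {scaffold_length} bp scaffold"
        )
    rng = np.random.default_rng(seed)
    scaffold = _random_nuc(rng, scaffold_length)
    truth = SyntheticTruth(genome_ids=[genome_id])
    if n_mites == 0:
        return _decode_nt(scaffold), truth

    # consensus element: TIR + internal + revcomp(TIR)
    tir = _decode_nt(_random_nuc(rng, tir_length))
    internal_len = mite_length - 2 * tir_length
    internal = _random_nuc(rng, internal_len)
    consensus = tir + _decode_nt(internal) + reverse_complement(tir)
    truth.mite_consensus = consensus

    # non-overlapping slot placement: n sorted offsets into the free space
    free = scaffold_length - n_mites * slot
    offsets = np.sort(rng.integers(0, free + 1, size=n_mites))
    # mutation rate on the internal region, scaled so whole-element identity
    # to the consensus is ~copy_identity despite the exact TIRs
    mu = min(0.75, (1.0 - copy_identity) * mite_length / max(internal_len, 1))

    parts: list[str] = []
    prev = 0
    for i in range(n_mites):
        slot_start = int(offsets[i]) + i * slot
        parts.append(_decode_nt(scaffold[prev:slot_start]))
        tsd = _decode_nt(_random_nuc(rng, tsd_length)) if tsd_length else ""
        body = internal if copy_identity >= 1.0 else _mutate_nt(rng, internal, mu)
        element = tir + _decode_nt(body) + reverse_complement(tir)
        parts.append(tsd + element + tsd)
        start = slot_start + tsd_length
        truth.mites.append(
            MitePlant(genome_id, start, start + mite_length, tsd, tir_length)
        )
        prev = slot_start + slot
    parts.append(_decode_nt(scaffold[prev:]))
    return "".join(parts), truth


# --- file output -------------------------------------------------------------


def write_synthetic_dataset(
    outdir: str | Path,
    genomes: dict[str, list[GeneRecord]],
    truth: SyntheticTruth,
    params: dict | None = None,
) -> None:
    """Write per-genome protein FASTA files, truth tables, and a sidecar config."""
    from pandorapan import seqio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for genome_id in sorted(genomes):
        seqio.write_proteome_fasta(genomes[genome_id], outdir / f"{genome_id}.faa")
    with open(outdir / "truth_families.tsv", "w") as fh:
        fh.write("gene_id\tfamily_id\tparalog\n")
        for gid in sorted(truth.gene_to_family):
            par = "1" if gid in truth.paralog_genes else "0"
            fh.write(f"{gid}\t{truth.gene_to_family[gid]}\t{par}\n")
    if truth.mites:
        with open(outdir / "truth_mites.tsv", "w") as fh:
            fh.write("genome_id\tstart\tend\ttsd\ttir_length\n")
            for mp in truth.mites:
                fh.write(f"{mp.genome_id}\t{mp.start}\t{mp.end}\t{mp.tsd}\t{mp.tir_length}\n")
    if params is not None:
        import yaml

        with open(outdir / "simulation_params.yaml", "w") as fh:
            yaml.safe_dump(params, fh, sort_keys=True)
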