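"""Synthetic multi-strain communities with known ground truth.

The generator emulates the statistical structure the curation pipeline
assumes: species are independent random genomes (background identity far
below 80%), strains within a species diverge from a common ancestor by
per-site substitutions plus sparse short indels, assembly-graph components
follow a planned topology class with depth proportional to abundance, rRNA
operons and tRNA complements are positional fixtures, and gene families have
a known redundancy structure.  Every operation is deterministic for a fixed
seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import AssemblyGraph, FeatureAnnotation, GenomeMetadata, Link, Segment, SequenceRecord

_BASES = np.frombuffer(b"ACGT", dtype="S1")
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# approximate full-length prokaryotic rRNA gene sizes (bp)
RRNA_LENGTHS = {"rRNA_16S": 1500, "rRNA_23S": 2900, "rRNA_5S": 120}
TRNA_LENGTH = 75


@dataclass
class CommunityTruth:
    """Ground-truth bookkeeping for a simulated community."""

    genomes: list[tuple[str, str, str, float]]  # (genome, species, strain, target ANI)
    species_partition: dict[str, list[str]]
    strain_partition: dict[str, list[str]]
    abundances: dict[str, float]
    ancestors: dict[str, str] = field(default_factory=dict)  # species -> ancestor sequence

    def species_of(self, genome_id: str) -> str:
        for gid, sp, _st, _ani in self.genomes:
            if gid == genome_id:
                return sp
        raise KeyError(genome_id)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "genomes": self.genomes,
                    "species_partition": self.species_partition,
                    "strain_partition": self.strain_partition,
                    "abundances": self.abundances,
                    "ancestors": self.ancestors,
                },
                fh,
                indent=1,
            )

    @classmethod
    def from_json(cls, path: str | Path) -> "CommunityTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            genomes=[tuple(g) for g in d["genomes"]],
            species_partition=d["species_partition"],
            strain_partition=d["strain_partition"],
            abundances=d["abundances"],
            ancestors=d.get("ancestors", {}),
        )


@dataclass(frozen=True)
class PlannedComponent:
    """A simulated graph component with its intended topology class."""

    label: str
    topology: str  # circular | tangled | linear
    segment_ids: tuple[str, ...]


def _random_genome(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def _mutate(
    rng: np.random.Generator, seq: str, sub_rate: float, indel_rate: float
) -> str:
    """Per-site substitutions at ``sub_rate`` plus indels at ``indel_rate``
    (insertions and deletions equally likely, lengths 1-5)."""
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    n = len(arr)
    sub_sites = np.flatnonzero(rng.random(n) < sub_rate)
    if len(sub_sites):
        # substitute with a uniformly chosen *different* base
        shifts = rng.integers(1, 4, size=len(sub_sites))
        idx = np.searchsorted(_BASES, arr[sub_sites])
        arr[sub_sites] = _BASES[(idx + shifts) % 4]
    if indel_rate > 0:
        out: list[bytes] = []
        indel_sites = set(np.flatnonzero(rng.random(n) < indel_rate).tolist())
        pieces: list[bytes] = []
        prev = 0
        for site in sorted(indel_sites):
            length = int(rng.integers(1, 6))
            if rng.random() < 0.5:  # deletion starting at site
                pieces.append(arr[prev:site].tobytes())
                prev = min(site + length, n)
            else:  # insertion before site
                pieces.append(arr[prev:site].tobytes())
                pieces.append(rng.choice(_BASES, size=length).tobytes())
                prev = site
        pieces.append(arr[prev:].tobytes())
        return b"".join(pieces).decode()
    return arr.tobytes().decode()


def simulate_genomes(
    n_species: int,
    strains_per_species: int,
    genome_length_bp: int = 50_000,
    intra_species_ani: float = 99.3,
    inter_species_ani_max: float = 90.0,
    indel_rate: float | None = None,
    seed: int | None = None,
) -> tuple[list[SequenceRecord], CommunityTruth]:
    """Simulate a community of ``n_species`` x ``strains_per_species`` genomes.

    Each species descends from an independent random ancestor; strains are
    derived from it by substitutions at rate (100 - intra_species_ani)/100,
    so strain-vs-ancestor identity targets ``intra_species_ani`` and pairwise
    strain identity is about twice as far from 100.  Indels default to 1/10
    of the substitution rate; pass ``indel_rate=0`` for substitution-only
    genomes with closed-form identities.  A single strain per species is the
    ancestor itself.
    """
    if not 95.0 < intra_species_ani < 100.0:
        raise ValueError("intra_species_ani must lie in (95, 100)")
    if inter_species_ani_max >= 95.0:
        raise ValueError("inter_species_ani_max must be below 95")
    if intra_species_ani <= inter_species_ani_max:
        raise ValueError("intra-species ANI must exceed inter-species ANI")
    sub_rate = (100.0 - intra_species_ani) / 100.0
    if indel_rate is None:
        indel_rate = sub_rate / 10.0
    rng = np.random.default_rng(seed)

    records: list[SequenceRecord] = []
    genomes: list[tuple[str, str, str, float]] = []
    species_partition: dict[str, list[str]] = {}
    strain_partition: dict[str, list[str]] = {}
    ancestors: dict[str, str] = {}
    for s in range(n_species):
        species_id = f"sp{s + 1:02d}"
        ancestor = _random_genome(rng, genome_length_bp)
        ancestors[species_id] = ancestor
        species_partition[species_id] = []
        for t in range(strains_per_species):
            strain_id = f"{species_id}.st{t + 1:02d}"
            genome_id = strain_id
            if strains_per_species == 1:
                seq = ancestor
            else:
                seq = _mutate(rng, ancestor, sub_rate, indel_rate)
            records.append(SequenceRecord(genome_id, seq, description=f"species={species_id}"))
            genomes.append((genome_id, species_id, strain_id, intra_species_ani))
            species_partition[species_id].append(genome_id)
            strain_partition[strain_id] = [genome_id]

    raw = rng.lognormal(mean=0.0, sigma=1.0, size=len(records))
    abundances = {rec.id: float(a / raw.sum()) for rec, a in zip(records, raw)}
    truth = CommunityTruth(genomes, species_partition, strain_partition, abundances, ancestors)
    return records, truth


def mutate_genome(
    sequence: str,
    substitution_rate: float,
    indel_rate: float = 0.0,
    seed: int | None = None,
) -> str:
    """Mutant of ``sequence`` with per-site substitutions at
    ``substitution_rate`` and optional indels (lengths 1-5).  With
    ``indel_rate=0`` coordinates are preserved, so the true identity is the
    position-wise match fraction."""
    rng = np.random.default_rng(seed)
    return _mutate(rng, sequence, substitution_rate, indel_rate)


def random_genome(length_bp: int, seed: int | None = None) -> str:
    """A uniform-random DNA sequence (the inter-species background model)."""
    return _random_genome(np.random.default_rng(seed), length_bp)


def simulate_graph(
    genomes: list[SequenceRecord],
    truth: CommunityTruth,
    topology_plan: dict[str, str],
    depth_scale: float = 300.0,
    seed: int | None = None,
) -> tuple[AssemblyGraph, list[PlannedComponent]]:
    """Build an assembly graph realising a topology plan.

    circular: the genome is one segment closed by a (+,+) self-link.
    tangled: all strains of the species are cut into 4-8 pieces each; the
    first piece of the first strain is shared and every strain's path is
    closed through it, so the component is multi-segment and cyclic.
    linear: 1-3 segments in an open path.  Segment depth is the genome
    abundance times ``depth_scale``; a shared segment accumulates the depth
    of every strain passing through it.
    """
    rng = np.random.default_rng(seed)
    by_id = {g.id: g for g in genomes}
    unknown = set(topology_plan) - set(by_id)
    if unknown:
        raise ValueError(f"topology plan names unknown genomes {sorted(unknown)}")

    graph = AssemblyGraph()
    planned: list[PlannedComponent] = []
    handled_species: set[str] = set()

    def depth_of(gid: str) -> float:
        return truth.abundances[gid] * depth_scale

    for gid in sorted(topology_plan):
        topo = topology_plan[gid]
        seq = by_id[gid].sequence
        if topo == "circular":
            graph.segments[gid] = Segment(gid, len(seq), seq, depth_of(gid))
            graph.links.append(Link(gid, "+", gid, "+"))
            planned.append(PlannedComponent(gid, "circular", (gid,)))
        elif topo == "linear":
            n_parts = int(rng.integers(1, 4))
            ids = _cut(graph, gid, seq, n_parts, depth_of(gid))
            for a, b in zip(ids, ids[1:]):
                graph.links.append(Link(a, "+", b, "+"))
            planned.append(PlannedComponent(gid, "linear", tuple(ids)))
        elif topo == "tangled":
            species = truth.species_of(gid)
            if species in handled_species:
                continue
            handled_species.add(species)
            members = [
                g for g in truth.species_partition[species] if topology_plan.get(g) == "tangled"
            ]
            if len(members) < 2:
                raise ValueError(
                    f"tangled topology for species {species!r} needs >= 2 strains"
                )
            seg_ids: list[str] = []
            shared_id = f"{species}.shared"
            for i, member in enumerate(sorted(members)):
                n_parts = int(rng.integers(4, 9))
                ids = _cut(graph, member, by_id[member].sequence, n_parts, depth_of(member))
                if i == 0:
                    # promote the first piece to the shared junction segment
                    first = graph.segments.pop(ids[0])
                    graph.segments[shared_id] = Segment(
                        shared_id, first.length, first.sequence, first.depth
                    )
                    ids[0] = shared_id
                    seg_ids.extend(ids)
                else:
                    # drop this strain's first piece; route through the shared one
                    removed = graph.segments.pop(ids[0])
                    old = graph.segments[shared_id]
                    graph.segments[shared_id] = Segment(
                        shared_id, old.length, old.sequence, old.depth + removed.depth
                    )
                    ids[0] = shared_id
                    seg_ids.extend(ids[1:])
                for a, b in zip(ids, ids[1:]):
                    graph.links.append(Link(a, "+", b, "+"))
                graph.links.append(Link(ids[-1], "+", shared_id, "+"))
            planned.append(PlannedComponent(species, "tangled", tuple(seg_ids)))
        else:
            raise ValueError(f"unknown topology {topo!r} for genome {gid!r}")
    return graph.validate(), planned


def _cut(
    graph: AssemblyGraph, gid: str, seq: str, n_parts: int, depth: float
) -> list[str]:
    bounds = np.linspace(0, len(seq), n_parts + 1).astype(int)
    ids = []
    for i in range(n_parts):
        sid = gid if n_parts == 1 else f"{gid}.{i + 1}"
        piece = seq[bounds[i] : bounds[i + 1]]
        graph.segments[sid] = Segment(sid, len(piece), piece, depth)
        ids.append(sid)
    return ids


def simulate_annotations(
    genome: SequenceRecord,
    n_operons: int,
    n_trnas: int,
    operon_intact: bool = True,
    seed: int | None = None,
) -> list[FeatureAnnotation]:
    """Place rRNA operons and tRNA genes on a genome.

    An intact operon carries full-length 16S, 23S and 5S genes on one strand
    with inter-gene gaps <= 500 bp.  With ``operon_intact=False`` every operon
    is broken: one of its three genes is either dropped or flagged
    full_length=false.  tRNAs (all full-length) fall uniformly outside the
    operons with isotypes cycling through the 20 amino acids.
    """
    if not 0 <= n_operons <= 6:
        raise ValueError("n_operons must lie in [0, 6]")
    if not 0 <= n_trnas <= 80:
        raise ValueError("n_trnas must lie in [0, 80]")
    rng = np.random.default_rng(seed)
    L = len(genome.sequence)
    feats: list[FeatureAnnotation] = []
    operon_spans: list[tuple[int, int]] = []

    max_operon_span = sum(RRNA_LENGTHS.values()) + 2 * 500
    if n_operons and n_operons * (max_operon_span + 1000) > L:
        raise ValueError(f"genome {genome.id!r} too short for {n_operons} operons")

    slot = L // n_operons if n_operons else 0
    for i in range(n_operons):
        start = i * slot + int(rng.integers(0, max(1, slot - max_operon_span)))
        strand = "+" if rng.random() < 0.5 else "-"
        genes = []
        pos = start
        for ftype in ("rRNA_16S", "rRNA_23S", "rRNA_5S"):
            glen = RRNA_LENGTHS[ftype]
            genes.append([genome.id, pos + 1, pos + glen, strand, ftype, True])
            pos += glen + int(rng.integers(50, 501))
        if not operon_intact:
            victim = genes[int(rng.integers(0, 3))]
            if rng.random() < 0.5:
                genes.remove(victim)
            else:
                victim[5] = False
        for contig, s, e, st, ft, full in genes:
            if e > L:
                raise ValueError(f"operon feature exceeds genome {genome.id!r}")
            feats.append(FeatureAnnotation(contig, s, e, st, ft, full_length=full))
        operon_spans.append((start + 1, pos))

    placed = 0
    attempts = 0
    while placed < n_trnas:
        attempts += 1
        if attempts > 100 * max(n_trnas, 1):
            raise ValueError(f"could not place {n_trnas} tRNAs on genome {genome.id!r}")
        s = int(rng.integers(1, max(2, L - TRNA_LENGTH)))
        e = s + TRNA_LENGTH - 1
        if e > L:
            continue
        if any(s <= oe and e >= os_ for os_, oe in operon_spans):
            continue
        feats.append(
            FeatureAnnotation(
                genome.id,
                s,
                e,
                "+" if rng.random() < 0.5 else "-",
                "tRNA",
                full_length=True,
                isotype=AMINO_ACIDS[placed % len(AMINO_ACIDS)],
            )
        )
        placed += 1
    feats.sort(key=lambda f: (f.start, f.end, f.feature_type))
    return feats


def simulate_gene_families(
    n_families: int,
    members_per_family: int,
    within_family_identity: float = 98.0,
    partial_fraction: float = 0.0,
    base_length_bp: int = 900,
    seed: int | None = None,
) -> tuple[list[SequenceRecord], dict[str, str], list[set[str]]]:
    """Gene families with known redundancy structure.

    ``within_family_identity`` is the expected pairwise identity between
    members (each member diverges from the family founder at half that rate).
    Member lengths vary within +-10% of ``base_length_bp`` (prefixes of a
    longer founder, so the shorter of any pair is fully covered).  A
    ``partial_fraction`` of genes get partial flags other than "00".

    Returns (gene records, partial flags per gene, truth clusters).
    """
    if within_family_identity <= 95.0:
        raise ValueError(
            "within_family_identity <= 95 makes truth clusters ambiguous at the "
            "95% criterion"
        )
    rng = np.random.default_rng(seed)
    divergence = (100.0 - within_family_identity) / 200.0
    founder_len = int(round(base_length_bp * 1.1))

    records: list[SequenceRecord] = []
    truth: list[set[str]] = []
    for f in range(n_families):
        founder = _random_genome(rng, founder_len)
        members: set[str] = set()
        for m in range(members_per_family):
            gid = f"fam{f + 1:03d}.g{m + 1:02d}"
            length = int(round(base_length_bp * rng.uniform(0.9, 1.1)))
            length = min(length, founder_len)
            seq = _mutate(rng, founder[:length], divergence, 0.0)
            records.append(SequenceRecord(gid, seq))
            members.add(gid)
        truth.append(members)

    n_partial = int(round(partial_fraction * len(records)))
    partial_ids = rng.choice(len(records), size=n_partial, replace=False)
    flags = {rec.id: "00" for rec in records}
    for i in partial_ids:
        flags[records[int(i)].id] = str(rng.choice(["01", "10", "11"]))
    return records, flags, truth


def simulate_metadata(
    truth: CommunityTruth,
    topology_plan: dict[str, str],
    genome_sizes: dict[str, int],
    compartment: str = "cecum",
    seed: int | None = None,
) -> dict[str, GenomeMetadata]:
    """Plausible CheckM-style metadata consistent with a topology plan.

    Circular genomes draw completeness/contamination near the high values
    reported for complete replicons; linear/tangled assemblies are noisier.
    """
    rng = np.random.default_rng(seed)
    out: dict[str, GenomeMetadata] = {}
    for gid, _sp, _st, _ani in truth.genomes:
        topo = topology_plan.get(gid, "linear")
        circular = topo == "circular"
        if circular:
            comp = float(np.clip(rng.normal(95.5, 2.0), 90.0, 100.0))
            cont = float(np.clip(rng.normal(0.85, 0.5), 0.0, 4.9))
            n_contigs = 1
        else:
            comp = float(np.clip(rng.normal(76.4, 8.0), 50.0, 100.0))
            cont = float(np.clip(rng.normal(1.59, 1.0), 0.0, 9.9))
            n_contigs = int(rng.integers(2, 9))
        out[gid] = GenomeMetadata(
            genome_id=gid,
            is_circular=circular,
            assembly_size=genome_sizes[gid],
            n_contigs=n_contigs,
            completeness=round(comp, 2),
            contamination=round(cont, 2),
            compartment=compartment,
        )
    return out
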