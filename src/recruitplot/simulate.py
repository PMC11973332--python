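"""Ground-truthed synthetic community generator.

Builds random reference genomes (with subspecies variants at controlled
divergence), cuts genome copies into fragments with species-specific
lognormal length distributions, emits shotgun short reads and long reads
(= fragments) with full per-read provenance, and simulates amplicon counts
governed by target intactness and 16S copy number.

Fragmentation model: fragment lengths are drawn i.i.d. from
lognormal(ln(median), sigma); the first fragment of each genome copy is
truncated by a uniform random phase and the last at the genome end, so the
cut process is stationary and exactly conserving.  With sigma = 0 this
reduces to the uniform fragment size S of the closed-form intactness model.
Divergence is substitution-only (no indels) so the built-in ungapped
aligner remains a valid oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .abundance import AbundanceTable
from .alignment_io import AlignmentHit, Genome, Read, ReferenceDB, reverse_complement
from .errors import ConfigError, DataError

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SpeciesSpec:
    name: str
    abundance: float
    genome_length: int = 200_000
    fragment_median_bp: float = 4000.0
    fragment_sigma: float = 0.5
    n_subspecies: int = 1
    subspecies_divergence: float = 0.01
    copy_number: int = 1  # 16S-like target copies per genome

    def __post_init__(self) -> None:
        if self.abundance < 0:
            raise ConfigError(f"{self.name}: negative abundance")
        if self.genome_length < 1000:
            raise ConfigError(f"{self.name}: genome_length too small")
        if self.fragment_median_bp < 200:
            raise ConfigError(f"{self.name}: fragment median must be >= 200 bp")
        if not 0 <= self.subspecies_divergence <= 0.3:
            raise ConfigError(f"{self.name}: subspecies divergence out of [0, 0.3]")
        if self.n_subspecies < 1:
            raise ConfigError(f"{self.name}: n_subspecies must be >= 1")


@dataclass
class HostSpec:
    """Decoy host genome contributing reads that the pipeline must remove."""

    name: str = "host"
    genome_length: int = 200_000
    abundance: float = 0.05  # fraction of total simulated bases
    fragment_median_bp: float = 2000.0
    fragment_sigma: float = 0.5


@dataclass
class SimulationConfig:
    seed: int
    species: list[SpeciesSpec]
    interspecies_divergence: float | None = 0.15
    target_length: int = 1500
    target_offset: int = 10_000  # 0-based start of the 16S-like locus
    host: HostSpec | None = None
    depth_bases: int = 20_000_000
    short_reads_per_kb: float = 2.5
    insert_min: int = 500
    insert_max: int = 1500
    merged_read_max: int = 500
    short_error_rate: float = 0.0
    long_error_rate: float = 0.0

    def __post_init__(self) -> None:
        total = sum(s.abundance for s in self.species)
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"species abundances must sum to 1, got {total!r}")
        if self.interspecies_divergence is not None and not 0 <= self.interspecies_divergence <= 0.3:
            raise ConfigError("interspecies divergence out of [0, 0.3]")
        if self.depth_bases <= 0:
            raise ConfigError("depth_bases must be positive")
        for s in self.species:
            if self.target_offset + self.target_length > s.genome_length:
                raise ConfigError(
                    f"{s.name}: target interval exceeds genome length {s.genome_length}"
                )


@dataclass
class ReadProvenance:
    genome_id: str
    species: str
    start: int  # 1-based inclusive genome coordinates of the read
    end: int
    strand: str  # '+' or '-'
    fragment_length: int


@dataclass
class SyntheticTruth:
    """Everything the simulator knows that the pipeline must recover."""

    species_abundance: dict[str, float] = field(default_factory=dict)  # realized base fractions
    copy_fraction: dict[str, float] = field(default_factory=dict)  # realized genome-copy fractions
    fragment_params: dict[str, tuple[float, float]] = field(default_factory=dict)
    target_intervals: dict[str, tuple[int, int]] = field(default_factory=dict)
    provenance: dict[str, ReadProvenance] = field(default_factory=dict)
    genome_copies: dict[str, int] = field(default_factory=dict)
    host_genome: Genome | None = None
    requested_abundance: dict[str, float] = field(default_factory=dict)

    def source_species(self, read_id: str) -> str:
        return self.provenance[read_id].species


# ---------------------------------------------------------------------------
# Reference construction


def _random_genome(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length, dtype=np.uint8)


def _mutate(rng: np.random.Generator, codes: np.ndarray, divergence: float) -> np.ndarray:
    """Substitute a ``divergence`` fraction of sites, always to a different base."""
    out = codes.copy()
    if divergence <= 0:
        return out
    mask = rng.random(codes.size) < divergence
    n = int(mask.sum())
    # adding 1..3 mod 4 guarantees the base changes
    out[mask] = (out[mask] + rng.integers(1, 4, size=n, dtype=np.uint8)) % 4
    return out


def _to_seq(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode()


def make_reference(cfg: SimulationConfig) -> tuple[ReferenceDB, SyntheticTruth]:
    """Generate the community reference genomes and initialize the truth.

    The first species' ancestor is a fresh random genome; later species are
    derived from it with substitutions at ``interspecies_divergence`` (or
    fully independent when that is ``None``).  Within a species, the first
    subspecies genome is the ancestor itself and further subspecies carry
    substitutions at ``subspecies_divergence``, so the first pair's
    divergence equals the configured value exactly in expectation.
    """
    rng = np.random.default_rng([cfg.seed, 0])
    truth = SyntheticTruth()
    max_len = max(s.genome_length for s in cfg.species)
    base = _random_genome(rng, max_len)
    genomes: list[Genome] = []
    for i, spec in enumerate(cfg.species):
        if cfg.interspecies_divergence is None:
            ancestor = _random_genome(rng, spec.genome_length)
        elif i == 0:
            ancestor = base[: spec.genome_length].copy()
        else:
            ancestor = _mutate(rng, base[: spec.genome_length], cfg.interspecies_divergence)
        for j in range(spec.n_subspecies):
            codes = ancestor if j == 0 else _mutate(rng, ancestor, spec.subspecies_divergence)
            gid = f"{spec.name}_s{j + 1}"
            subsp = f"subsp{j + 1}" if spec.n_subspecies > 1 else None
            genomes.append(Genome(gid, spec.name, subsp, sequence=_to_seq(codes)))
            truth.target_intervals[gid] = (
                cfg.target_offset + 1,
                cfg.target_offset + cfg.target_length,
            )
        truth.fragment_params[spec.name] = (spec.fragment_median_bp, spec.fragment_sigma)
        truth.requested_abundance[spec.name] = spec.abundance
    if cfg.host is not None:
        host_codes = _random_genome(rng, cfg.host.genome_length)
        truth.host_genome = Genome(
            cfg.host.name, cfg.host.name, None, sequence=_to_seq(host_codes)
        )
    return ReferenceDB(genomes), truth


def host_reference(truth: SyntheticTruth) -> ReferenceDB:
    """Single-genome reference holding the simulated host decoy."""
    if truth.host_genome is None:
        raise DataError("no host genome was simulated")
    return ReferenceDB([truth.host_genome])


# ---------------------------------------------------------------------------
# Fragmentation and read generation


def _draw_lengths(rng: np.random.Generator, median: float, sigma: float, n: int) -> np.ndarray:
    if sigma == 0.0:
        return np.full(n, max(1, int(round(median))), dtype=np.int64)
    lens = rng.lognormal(np.log(median), sigma, n)
    return np.maximum(1, np.rint(lens)).astype(np.int64)


def _cut_copy(
    rng: np.random.Generator, genome_length: int, median: float, sigma: float
) -> np.ndarray:
    """Fragment lengths tiling one genome copy (sum == genome_length).

    The first fragment is truncated by a uniform phase so that cut
    positions are stationary along the genome; the last fragment is
    truncated at the genome end.
    """
    first = _draw_lengths(rng, median, sigma, 1)[0]
    phase = int(rng.random() * first) + 1  # uniform in 1..first
    boundaries = [min(phase, genome_length)]
    est = max(8, int(genome_length / median * 1.5) + 4)
    while boundaries[-1] < genome_length:
        chunk = _draw_lengths(rng, median, sigma, est)
        pos = boundaries[-1] + np.cumsum(chunk)
        take = int(np.searchsorted(pos, genome_length)) + 1
        boundaries.extend(pos[:take].tolist())
    bounds = np.asarray(boundaries, dtype=np.int64)
    bounds = bounds[: int(np.searchsorted(bounds, genome_length)) + 1]
    bounds[-1] = genome_length
    return np.diff(np.concatenate(([0], bounds)))


def _apply_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    codes = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    lookup = np.zeros(256, dtype=np.uint8)
    lookup[np.frombuffer(b"ACGT", dtype=np.uint8)] = np.arange(4)
    num = lookup[codes]
    mask = rng.random(codes.size) < rate
    n = int(mask.sum())
    if n:
        num[mask] = (num[mask] + rng.integers(1, 4, size=n, dtype=np.uint8)) % 4
        return _to_seq(num)
    return seq


def _genome_copy_allocation(cfg: SimulationConfig, refdb: ReferenceDB) -> dict[str, int]:
    """Copies per genome implied by the base-depth budget and abundances."""
    host_frac = cfg.host.abundance if cfg.host is not None else 0.0
    alloc: dict[str, int] = {}
    for spec in cfg.species:
        bases = cfg.depth_bases * (1.0 - host_frac) * spec.abundance
        copies = max(1, int(round(bases / spec.genome_length)))
        gids = [g.genome_id for g in refdb if g.species == spec.name]
        per, extra = divmod(copies, len(gids))
        for idx, gid in enumerate(gids):
            alloc[gid] = per + (1 if idx < extra else 0)
    return alloc


def fragment_and_read(
    refdb: ReferenceDB, cfg: SimulationConfig, truth: SyntheticTruth
) -> tuple[list[Read], list[Read], SyntheticTruth]:
    """Cut genome copies into fragments and emit short + long reads.

    Long reads are the fragments themselves (optionally with i.i.d.
    substitution errors).  Short reads emulate merged paired-end reads: a
    Poisson number of inserts per fragment proportional to its length, an
    insert of 500-1500 bp (capped at the fragment), and a single merged
    read of at most 500 bp on a random strand.  Every read gets a
    provenance record in the truth.
    """
    if cfg.depth_bases <= 0:
        raise DataError("simulation depth must be positive")
    rng = np.random.default_rng([cfg.seed, 1])
    alloc = _genome_copy_allocation(cfg, refdb)
    truth.genome_copies = dict(alloc)

    spec_by_name = {s.name: s for s in cfg.species}
    jobs: list[tuple[Genome, int, float, float]] = []
    for genome in refdb:
        spec = spec_by_name[genome.species]
        jobs.append((genome, alloc[genome.genome_id], spec.fragment_median_bp, spec.fragment_sigma))
    if cfg.host is not None and truth.host_genome is not None:
        host_copies = max(
            1, int(round(cfg.depth_bases * cfg.host.abundance / cfg.host.genome_length))
        )
        jobs.append(
            (truth.host_genome, host_copies, cfg.host.fragment_median_bp, cfg.host.fragment_sigma)
        )
        truth.genome_copies[truth.host_genome.genome_id] = host_copies

    short_reads: list[Read] = []
    long_reads: list[Read] = []
    sr_counter = lr_counter = 0
    rate = cfg.short_reads_per_kb / 1000.0
    for genome, copies, median, sigma in jobs:
        seq = genome.sequence
        glen = genome.length
        for _ in range(copies):
            frag_lens = _cut_copy(rng, glen, median, sigma)
            starts = np.concatenate(([0], np.cumsum(frag_lens)[:-1]))
            n_inserts = rng.poisson(frag_lens * rate)
            for flen, fstart, n_ins in zip(frag_lens, starts, n_inserts):
                flen = int(flen)
                fstart = int(fstart)
                # long read = the fragment itself
                lr_counter += 1
                rid = f"lr{lr_counter:08d}"
                frag_seq = seq[fstart : fstart + flen]
                long_reads.append(
                    Read(rid, _apply_errors(rng, frag_seq, cfg.long_error_rate))
                )
                truth.provenance[rid] = ReadProvenance(
                    genome.genome_id, genome.species, fstart + 1, fstart + flen, "+", flen
                )
                for _ in range(int(n_ins)):
                    ins_len = min(int(rng.integers(cfg.insert_min, cfg.insert_max + 1)), flen)
                    ins_start = fstart + int(rng.integers(0, flen - ins_len + 1))
                    rlen = min(cfg.merged_read_max, ins_len)
                    strand = "+" if rng.random() < 0.5 else "-"
                    if strand == "+":
                        r_start = ins_start
                    else:
                        r_start = ins_start + ins_len - rlen
                    raw = seq[r_start : r_start + rlen]
                    if strand == "-":
                        raw = reverse_complement(raw)
                    sr_counter += 1
                    rid = f"sr{sr_counter:08d}"
                    short_reads.append(
                        Read(rid, _apply_errors(rng, raw, cfg.short_error_rate))
                    )
                    truth.provenance[rid] = ReadProvenance(
                        genome.genome_id,
                        genome.species,
                        r_start + 1,
                        r_start + rlen,
                        strand,
                        flen,
                    )

    # realized truth fractions over microbial species (host excluded)
    total_bases = sum(
        refdb.get(gid).length * n for gid, n in alloc.items()
    )
    total_copies = sum(alloc.values())
    by_species_bases: dict[str, float] = {}
    by_species_copies: dict[str, float] = {}
    for gid, n in alloc.items():
        sp = refdb.species_of(gid)
        by_species_bases[sp] = by_species_bases.get(sp, 0.0) + refdb.get(gid).length * n
        by_species_copies[sp] = by_species_copies.get(sp, 0.0) + n
    truth.species_abundance = {sp: b / total_bases for sp, b in by_species_bases.items()}
    truth.copy_fraction = {sp: c / total_copies for sp, c in by_species_copies.items()}
    return short_reads, long_reads, truth


# ---------------------------------------------------------------------------
# Amplicon simulation


def _simulate_intact(
    rng: np.random.Generator,
    n_copies: int,
    s: int,
    e: int,
    genome_length: int,
    median: float,
    sigma: float,
) -> int:
    """Number of genome copies whose target [s, e] has no cut strictly inside.

    A cut after position p breaks the target iff s <= p < e; boundaries are
    simulated with a uniform phase, vectorized over copies.
    """
    first = _draw_lengths(rng, median, sigma, n_copies)
    b = (rng.random(n_copies) * first).astype(np.int64) + 1
    np.minimum(b, genome_length, out=b)
    broken = (b >= s) & (b <= e - 1)
    active = b < min(e, genome_length)
    while active.any():
        idx = np.flatnonzero(active)
        step = _draw_lengths(rng, median, sigma, idx.size)
        b[idx] += step
        np.minimum(b, genome_length, out=b)
        broken[idx] |= (b[idx] >= s) & (b[idx] <= e - 1)
        active[idx] = b[idx] < min(e, genome_length)
    return int(n_copies - broken.sum())


def simulate_amplicon_counts(
    refdb: ReferenceDB,
    cfg: SimulationConfig,
    L: int,
    n_copies: int = 100_000,
    use_copy_number: bool = False,
    seed: int | None = None,
    sample_id: str = "amplicon_sim",
) -> tuple[AbundanceTable, dict[str, int]]:
    """Empirical amplicon counts from simulated fragmentation.

    ``n_copies`` total genome copies are allotted to species by their
    configured abundances; each copy's target of length L (anchored at the
    configured target offset) is amplifiable iff no cut falls strictly
    inside it.  Counts are multiplied by the species 16S copy number when
    requested, then converted to relative abundances.
    """
    rng = np.random.default_rng([cfg.seed, 2] if seed is None else seed)
    s = cfg.target_offset + 1
    e = s + L - 1
    counts: dict[str, int] = {}
    for spec in cfg.species:
        if e > spec.genome_length or L > spec.genome_length:
            raise DataError(
                f"{spec.name}: target of length {L} at offset {cfg.target_offset} "
                f"does not fit in genome of {spec.genome_length} bp"
            )
        n_sp = int(round(n_copies * spec.abundance))
        if n_sp == 0:
            counts[spec.name] = 0
            continue
        intact = _simulate_intact(
            rng, n_sp, s, e, spec.genome_length, spec.fragment_median_bp, spec.fragment_sigma
        )
        counts[spec.name] = intact * (spec.copy_number if use_copy_number else 1)
    total = sum(counts.values())
    if total == 0:
        raise DataError(f"no intact targets at L={L}; community yields no amplicons")
    table = AbundanceTable(
        sample_id=sample_id,
        mode="amplicon",
        entries={sp: c / total for sp, c in counts.items()},
    )
    return table, counts


def count_intact_targets(
    fragments: Iterable[Sequence[int]], target_interval: tuple[int, int]
) -> float:
    """Brute-force oracle: fraction of genome copies whose target interval
    lies wholly within a single fragment.

    ``fragments`` is one fragment-length list per genome copy; each list
    must tile the same genome length (a partition).
    """
    s, e = target_interval
    if not 1 <= s <= e:
        raise DataError(f"bad target interval ({s}, {e})")
    copies = [np.asarray(c, dtype=np.int64) for c in fragments]
    if not copies:
        raise DataError("no genome copies supplied")
    totals = {int(c.sum()) for c in copies}
    if len(totals) != 1:
        raise DataError(f"fragment lists tile different genome lengths: {sorted(totals)}")
    glen = totals.pop()
    if e > glen:
        raise DataError(f"target end {e} beyond genome length {glen}")
    intact = 0
    for c in copies:
        if (c <= 0).any():
            raise DataError("fragment lengths must be positive (not a partition)")
        bounds = np.cumsum(c)
        if not ((bounds >= s) & (bounds <= e - 1)).any():
            intact += 1
    return intact / len(copies)


# ---------------------------------------------------------------------------
# Truth-based oracle alignments


def truth_alignments(reads: Sequence[Read], truth: SyntheticTruth) -> list[AlignmentHit]:
    """Perfect alignments reconstructed from provenance (an oracle aligner).

    Used to test downstream stages independently of any real aligner:
    identity is reported as 100, bitscore as twice the read length.
    """
    hits = []
    for r in reads:
        prov = truth.provenance[r.id]
        if prov.strand == "+":
            s_start, s_end = prov.start, prov.end
        else:
            s_start, s_end = prov.end, prov.start
        n = len(r.sequence)
        hits.append(
            AlignmentHit(
                query_id=r.id,
                subject_id=prov.genome_id,
                percent_identity=100.0,
                alignment_length=n,
                query_start=1,
                query_end=n,
                subject_start=s_start,
                subject_end=s_end,
                bitscore=float(2 * n),
                evalue=0.0,
                query_length=n,
            )
        )
    return hits


# ---------------------------------------------------------------------------
# Preset community


def default_community(
    seed: int,
    depth_bases: int = 20_000_000,
    genome_length: int = 200_000,
    with_host: bool = False,
) -> SimulationConfig:
    """Five-species low-diversity community with one heavily fragmented
    species (two near-identical subspecies genomes) emulating a starter
    culture, plus an optional host decoy."""
    scale = genome_length / 200_000
    species = [
        SpeciesSpec(
            "Fragmentococcus_cremoris",
            abundance=0.40,
            genome_length=genome_length,
            fragment_median_bp=1000.0,
            fragment_sigma=0.5,
            n_subspecies=2,
            subspecies_divergence=0.01,
            copy_number=6,
        ),
        SpeciesSpec(
            "Integribacter_major",
            abundance=0.25,
            genome_length=genome_length,
            fragment_median_bp=6000.0,
            fragment_sigma=0.5,
            copy_number=5,
        ),
        SpeciesSpec(
            "Integribacter_minor",
            abundance=0.15,
            genome_length=genome_length,
            fragment_median_bp=8000.0,
            fragment_sigma=0.5,
            copy_number=5,
        ),
        SpeciesSpec(
            "Halotolerans_medius",
            abundance=0.12,
            genome_length=genome_length,
            fragment_median_bp=5000.0,
            fragment_sigma=0.5,
            copy_number=4,
        ),
        SpeciesSpec(
            "Minoribacter_rarus",
            abundance=0.08,
            genome_length=genome_length,
            fragment_median_bp=7000.0,
            fragment_sigma=0.5,
            copy_number=5,
        ),
    ]
    host = HostSpec(genome_length=genome_length) if with_host else None
    return SimulationConfig(
        seed=seed,
        species=species,
        interspecies_divergence=0.15,
        target_offset=int(10_000 * scale),
        host=host,
        depth_bases=depth_bases,
    )
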