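"""Recruitment-plot decision rules.

Host-read removal, identity/overlap filtering, best-hit selection with
seeded random tie-breaking, per-genome recruitment profiles, species
retention (read count + breadth of coverage), coverage-gap fingerprints,
and within-species (subspecies) read-count ratios.

Boundary conventions are applied literally to the wording of the source
procedure: hits are *removed* when identity is strictly lower / overlap
strictly shorter than the thresholds, so values exactly at a threshold are
kept; host reads are *deleted* when identity and query coverage are
strictly higher than 60, so exactly 60 is kept.
"""

from __future__ import annotations

import logging
import random
import statistics
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .alignment_io import AlignmentHit, ReferenceDB
from .errors import DataError, InsufficientDepthError

logger = logging.getLogger(__name__)


@dataclass
class FilterConfig:
    """Thresholds for the recruitment pipeline (defaults are the published ones)."""

    min_identity_short: float = 60.0
    min_overlap_short: int = 50
    min_identity_long: float = 70.0
    min_read_length_long: int = 500
    host_min_identity: float = 60.0
    host_min_qcov: float = 60.0
    min_reads_retain: int = 300
    spread_bins: int = 100
    spread_min_breadth: float = 0.5
    tie_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("min_identity_short", "min_identity_long", "host_min_identity", "host_min_qcov"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise DataError(f"{name} out of [0, 100]: {v}")
        if self.spread_bins < 10:
            raise DataError(f"spread_bins must be >= 10, got {self.spread_bins}")
        if not 0 <= self.spread_min_breadth <= 1:
            raise DataError(f"spread_min_breadth out of [0, 1]: {self.spread_min_breadth}")


@dataclass
class RecruitmentProfile:
    """Post-filter, best-hit-unique recruitment of one reference genome."""

    genome_id: str
    species: str
    hits: list[AlignmentHit]
    bin_coverage: np.ndarray  # per-bin read counts, length = spread_bins
    retained: bool = False

    @property
    def read_count(self) -> int:
        return len(self.hits)

    @property
    def base_count(self) -> int:
        """Sum of full query lengths of recruited reads."""
        return sum(_qlen(h) for h in self.hits)


@dataclass
class GapProfile:
    genome_id: str
    gap_bins: set[int]  # 1-based bin indices with zero coverage
    n_bins: int

    def __post_init__(self) -> None:
        bad = [b for b in self.gap_bins if not 1 <= b <= self.n_bins]
        if bad:
            raise DataError(f"gap bins out of range 1..{self.n_bins}: {bad}")


@dataclass
class RetentionVerdict:
    species: str
    read_count: int
    breadth: float
    best_genome: str | None
    retained: bool
    reason: str


def _qlen(hit: AlignmentHit) -> int:
    if hit.query_length is None:
        raise DataError(f"hit for {hit.query_id!r} lacks query_length")
    return hit.query_length


def remove_host_hits(hits: Iterable[AlignmentHit], cfg: FilterConfig) -> set[str]:
    """Read ids to exclude as host-derived.

    A read is flagged iff at least one of its hits against the host genome
    has identity strictly above ``host_min_identity`` and query coverage
    strictly above ``host_min_qcov``.
    """
    excluded: set[str] = set()
    for h in hits:
        if h.percent_identity > cfg.host_min_identity and h.query_coverage > cfg.host_min_qcov:
            excluded.add(h.query_id)
    return excluded


def filter_hits(
    hits: Sequence[AlignmentHit], platform: str, cfg: FilterConfig
) -> list[AlignmentHit]:
    """Apply the platform's identity/overlap (short) or identity/length (long)
    thresholds, preserving input order.  Values exactly at a threshold pass.
    """
    if platform == "short":
        return [
            h
            for h in hits
            if h.percent_identity >= cfg.min_identity_short
            and h.alignment_length >= cfg.min_overlap_short
        ]
    if platform == "long":
        return [
            h
            for h in hits
            if h.percent_identity >= cfg.min_identity_long
            and _qlen(h) >= cfg.min_read_length_long
        ]
    raise DataError(f"platform must be 'short' or 'long', got {platform!r}")


def _tie_key(hit: AlignmentHit) -> tuple:
    return (hit.subject_id, hit.subject_start, hit.subject_end, hit.query_start, hit.query_end)


def select_best_hits(hits: Sequence[AlignmentHit], cfg: FilterConfig) -> list[AlignmentHit]:
    """Keep the single highest-bitscore hit per read.

    Exact bitscore ties are broken uniformly at random by a generator
    seeded from ``(tie_seed, query_id)``, so the choice is deterministic
    for a given config, independent of input order, and re-randomized per
    read when the seed changes.
    """
    by_query: dict[str, list[AlignmentHit]] = {}
    for h in hits:
        by_query.setdefault(h.query_id, []).append(h)
    out: list[AlignmentHit] = []
    for query_id, group in by_query.items():
        best = max(h.bitscore for h in group)
        tied = [h for h in group if h.bitscore == best]
        if len(tied) == 1:
            out.append(tied[0])
        else:
            tied.sort(key=_tie_key)
            rng = random.Random(f"{cfg.tie_seed}|{query_id}")
            out.append(tied[rng.randrange(len(tied))])
    return out


def build_profiles(
    best_hits: Sequence[AlignmentHit], ref: ReferenceDB, cfg: FilterConfig
) -> dict[str, RecruitmentProfile]:
    """Group best hits by subject genome and compute bin coverage.

    A hit's bin is the one containing the midpoint of its subject span.
    Hits against subjects absent from the reference are dropped (counted
    in the log).  Every genome in the reference gets a profile, possibly
    empty.
    """
    nbins = cfg.spread_bins
    grouped: dict[str, list[AlignmentHit]] = {g.genome_id: [] for g in ref}
    dropped = 0
    for h in best_hits:
        if h.subject_id not in ref:
            dropped += 1
            continue
        grouped[h.subject_id].append(h)
    if dropped:
        logger.warning("dropped %d best hits with subjects absent from the reference", dropped)
    profiles: dict[str, RecruitmentProfile] = {}
    for genome in ref:
        hits = grouped[genome.genome_id]
        cov = np.zeros(nbins, dtype=np.int64)
        glen = genome.length
        if glen <= 0 and hits:
            raise DataError(f"genome {genome.genome_id!r} has no length; cannot bin")
        for h in hits:
            lo, hi = h.subject_span
            mid = (lo + hi) / 2.0
            b = int((mid - 1) * nbins / glen)  # 0-based bin
            cov[min(max(b, 0), nbins - 1)] += 1
        profiles[genome.genome_id] = RecruitmentProfile(
            genome_id=genome.genome_id,
            species=genome.species,
            hits=hits,
            bin_coverage=cov,
        )
    return profiles


def retain_species(
    profiles: Mapping[str, RecruitmentProfile], cfg: FilterConfig
) -> dict[str, RetentionVerdict]:
    """Decide which species survive the recruitment checks.

    A species is retained iff its read count pooled over same-species
    genomes is strictly greater than ``min_reads_retain`` AND the breadth
    of coverage (fraction of bins with at least one read) on its
    best-recruiting genome reaches ``spread_min_breadth``.  Breadth is
    evaluated on a single genome so that subspecies cross-recruitment does
    not dilute it.  Also marks ``retained`` on the member profiles.
    """
    by_species: dict[str, list[RecruitmentProfile]] = {}
    for p in profiles.values():
        by_species.setdefault(p.species, []).append(p)
    verdicts: dict[str, RetentionVerdict] = {}
    for species, members in by_species.items():
        total = sum(p.read_count for p in members)
        best = max(members, key=lambda p: p.read_count)
        breadth = float(np.count_nonzero(best.bin_coverage)) / cfg.spread_bins
        if total <= cfg.min_reads_retain:
            retained, reason = False, (
                f"read count {total} not above {cfg.min_reads_retain}"
            )
        elif breadth < cfg.spread_min_breadth:
            retained, reason = False, (
                f"breadth {breadth:.2f} below {cfg.spread_min_breadth} on {best.genome_id}"
            )
        else:
            retained, reason = True, "passed read-count and spread checks"
        for p in members:
            p.retained = retained
        verdicts[species] = RetentionVerdict(
            species=species,
            read_count=total,
            breadth=breadth,
            best_genome=best.genome_id if total else None,
            retained=retained,
            reason=reason,
        )
    return verdicts


def detect_coverage_gaps(profile: RecruitmentProfile, cfg: FilterConfig) -> GapProfile:
    """Bins with zero recruited reads, for genomes with adequate depth.

    Gap calls on under-recruited genomes are meaningless, so profiles with
    fewer than ``min_reads_retain`` reads raise.
    """
    if profile.read_count < cfg.min_reads_retain:
        raise InsufficientDepthError(
            f"{profile.genome_id}: {profile.read_count} reads < {cfg.min_reads_retain}; "
            "too few for gap detection"
        )
    gaps = {i + 1 for i in np.flatnonzero(profile.bin_coverage == 0)}
    return GapProfile(profile.genome_id, gaps, len(profile.bin_coverage))


def gap_concordance(a: GapProfile, b: GapProfile) -> float:
    """Jaccard index of two gap fingerprints of the same genome/binning.

    Defined as 1.0 when both gap sets are empty.
    """
    if a.genome_id != b.genome_id:
        raise DataError(f"gap profiles for different genomes: {a.genome_id!r} vs {b.genome_id!r}")
    if a.n_bins != b.n_bins:
        raise DataError(f"gap profiles with different binnings: {a.n_bins} vs {b.n_bins}")
    union = a.gap_bins | b.gap_bins
    if not union:
        return 1.0
    return len(a.gap_bins & b.gap_bins) / len(union)


@dataclass
class SpeciesRatioReport:
    species: str
    counts: dict[str, int]  # genome_id -> read count
    ratios: dict[tuple[str, str], float | None]  # (g1, g2) -> count(g1)/count(g2)


def subspecies_ratios(
    profiles: Mapping[str, RecruitmentProfile], ref: ReferenceDB
) -> dict[str, SpeciesRatioReport]:
    """Read-count ratios between genomes sharing a species label.

    Species with a single genome are skipped.  A zero denominator yields
    ``None`` (undefined), never an exception.
    """
    reports: dict[str, SpeciesRatioReport] = {}
    for species, genome_ids in ref.species_index.items():
        if len(genome_ids) < 2:
            continue
        counts = {gid: profiles[gid].read_count if gid in profiles else 0 for gid in genome_ids}
        ratios: dict[tuple[str, str], float | None] = {}
        for g1 in genome_ids:
            for g2 in genome_ids:
                if g1 == g2:
                    continue
                ratios[(g1, g2)] = counts[g1] / counts[g2] if counts[g2] else None
        reports[species] = SpeciesRatioReport(species, counts, ratios)
    return reports


def summarize_ratios(
    per_sample: Sequence[Mapping[str, SpeciesRatioReport]],
) -> list[dict]:
    """Mean and standard deviation of each genome-pair ratio across samples.

    Undefined (None) ratios are dropped pairwise; rows report how many
    samples contributed.
    """
    acc: dict[tuple[str, str, str], list[float]] = {}
    for sample in per_sample:
        for species, rep in sample.items():
            for (g1, g2), r in rep.ratios.items():
                if r is not None:
                    acc.setdefault((species, g1, g2), []).append(r)
    rows = []
    for (species, g1, g2), values in sorted(acc.items()):
        rows.append(
            {
                "species": species,
                "genome_a": g1,
                "genome_b": g2,
                "mean_ratio": statistics.fmean(values),
                "sd_ratio": statistics.stdev(values) if len(values) > 1 else 0.0,
                "n_samples": len(values),
            }
        )
    return rows


def select_reference_genera(
    genus_table: Mapping[str, float], cutoff: float = 0.001
) -> list[str]:
    """Genera whose assigned-read fraction is strictly above ``cutoff``.

    Mirrors the custom-database construction rule (default: more than 0.1%
    of all sequences assigned).
    """
    total = 0.0
    for genus, frac in genus_table.items():
        if frac < 0:
            raise DataError(f"negative fraction for genus {genus!r}: {frac}")
        total += frac
    if total > 1 + 1e-9:
        raise DataError(f"genus fractions sum to {total} > 1")
    return [g for g, frac in genus_table.items() if frac > cutoff]
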