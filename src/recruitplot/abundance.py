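"""Relative-abundance tables and method comparison.

Read-count abundances for short reads, base-weighted abundances for long
reads, the minimum-read-length threshold sweep, recruited read-length
densities, minority pooling, and paired method-comparison statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, InsufficientDepthError
from .recruitment import RecruitmentProfile

MINORITIES_LABEL = "Minorities"

#: Default threshold grid for the read-length sweep: the base 500 bp filter
#: then 1-10 kbp in 1 kbp steps.
DEFAULT_SWEEP_THRESHOLDS = (500, 1000, 2000, 3000, 4000, 5000, 6000, 7000, 8000, 9000, 10000)


@dataclass
class AbundanceTable:
    """Per-sample relative abundances over retained species."""

    sample_id: str
    mode: str  # read_count | base_weighted | amplicon
    entries: dict[str, float]
    min_read_length: int = 0
    minorities_cutoff: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("read_count", "base_weighted", "amplicon"):
            raise DataError(f"unknown abundance mode {self.mode!r}")
        if any(v < 0 for v in self.entries.values()):
            raise DataError("abundance fractions must be non-negative")
        total = sum(self.entries.values())
        if self.entries and abs(total - 1.0) > 1e-9:
            raise DataError(f"abundances must sum to 1, got {total!r}")

    def fraction(self, species: str) -> float:
        return self.entries.get(species, 0.0)

    def percent(self, species: str) -> float:
        return 100.0 * self.fraction(species)

    def as_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "sample_id": self.sample_id,
                "species": sp,
                "mode": self.mode,
                "min_read_length": self.min_read_length,
                "fraction": frac,
                "percent": 100.0 * frac,
            }
            for sp, frac in sorted(self.entries.items())
        ]
        return pd.DataFrame(
            rows,
            columns=["sample_id", "species", "mode", "min_read_length", "fraction", "percent"],
        )


@dataclass
class SweepResult:
    """Base-weighted abundance tables across a grid of minimum read lengths."""

    thresholds: tuple[int, ...]
    tables: list[AbundanceTable]
    retained_bp_fraction: list[float]

    def as_dataframe(self) -> pd.DataFrame:
        frames = [t.as_dataframe() for t in self.tables]
        df = pd.concat(frames, ignore_index=True)
        bp = dict(zip(self.thresholds, self.retained_bp_fraction))
        df["retained_bp_fraction"] = df["min_read_length"].map(bp)
        return df


@dataclass
class LengthDistribution:
    """Normalized read-length density plus summary statistics."""

    species: str
    grid: np.ndarray  # bin centers (histogram) or evaluation points (kde)
    density: np.ndarray
    n_reads: int
    median: float
    mean: float
    n50: int


def _species_profiles(
    profiles: Mapping[str, RecruitmentProfile], retained: Sequence[str]
) -> dict[str, list[RecruitmentProfile]]:
    by_species: dict[str, list[RecruitmentProfile]] = {sp: [] for sp in retained}
    for p in profiles.values():
        if p.species in by_species:
            by_species[p.species].append(p)
    return by_species


def abundance_short(
    profiles: Mapping[str, RecruitmentProfile],
    retained: Sequence[str],
    sample_id: str = "sample",
) -> AbundanceTable:
    """Read-count relative abundances over retained species."""
    if not retained:
        raise DataError("no retained species; cannot compute abundances")
    counts = {
        sp: sum(p.read_count for p in members)
        for sp, members in _species_profiles(profiles, retained).items()
    }
    total = sum(counts.values())
    if total == 0:
        raise DataError("retained species recruited zero reads")
    return AbundanceTable(
        sample_id=sample_id,
        mode="read_count",
        entries={sp: c / total for sp, c in counts.items()},
    )


def abundance_long(
    profiles: Mapping[str, RecruitmentProfile],
    retained: Sequence[str],
    min_read_length: int = 500,
    sample_id: str = "sample",
) -> AbundanceTable:
    """Base-weighted relative abundances: summed full read lengths of
    recruited reads at least ``min_read_length`` long, normalized over
    retained species."""
    if not retained:
        raise DataError("no retained species; cannot compute abundances")
    bases: dict[str, int] = {}
    for sp, members in _species_profiles(profiles, retained).items():
        bases[sp] = sum(
            h.query_length
            for p in members
            for h in p.hits
            if h.query_length is not None and h.query_length >= min_read_length
        )
    total = sum(bases.values())
    if total == 0:
        raise DataError(
            f"no recruited reads of length >= {min_read_length}; nothing to weight"
        )
    return AbundanceTable(
        sample_id=sample_id,
        mode="base_weighted",
        min_read_length=min_read_length,
        entries={sp: b / total for sp, b in bases.items()},
    )


def length_sweep(
    profiles: Mapping[str, RecruitmentProfile],
    retained: Sequence[str],
    thresholds: Sequence[int] = DEFAULT_SWEEP_THRESHOLDS,
    sample_id: str = "sample",
) -> SweepResult:
    """Base-weighted abundances at each minimum-read-length threshold.

    Species whose reads all fall below a threshold stay in the table with
    fraction 0.  ``retained_bp_fraction`` is relative to the first
    (default-filter) threshold.
    """
    thresholds = tuple(int(t) for t in thresholds)
    if list(thresholds) != sorted(set(thresholds)):
        raise DataError(f"thresholds must be strictly increasing, got {thresholds}")
    tables: list[AbundanceTable] = []
    totals: list[int] = []
    by_species = _species_profiles(profiles, retained)
    for t in thresholds:
        bases = {
            sp: sum(
                h.query_length
                for p in members
                for h in p.hits
                if h.query_length is not None and h.query_length >= t
            )
            for sp, members in by_species.items()
        }
        total = sum(bases.values())
        if total == 0:
            raise DataError(f"threshold {t} bp excludes every recruited read")
        totals.append(total)
        tables.append(
            AbundanceTable(
                sample_id=sample_id,
                mode="base_weighted",
                min_read_length=t,
                entries={sp: b / total for sp, b in bases.items()},
            )
        )
    base_total = totals[0]
    return SweepResult(
        thresholds=thresholds,
        tables=tables,
        retained_bp_fraction=[t / base_total for t in totals],
    )


def compute_n50(lengths: Sequence[int]) -> int:
    """N50 of a set of read lengths: the length at which the cumulative sum
    of descending-sorted lengths first reaches half the total."""
    if not lengths:
        raise DataError("N50 of an empty length set is undefined")
    arr = np.sort(np.asarray(lengths))[::-1]
    half = arr.sum() / 2.0
    idx = int(np.searchsorted(np.cumsum(arr), half))
    return int(arr[min(idx, len(arr) - 1)])


def read_length_distribution(
    profile: RecruitmentProfile,
    bins: int = 50,
    bandwidth: float | None = None,
    min_reads: int = 30,
) -> LengthDistribution:
    """Density estimate of recruited read lengths for one genome.

    Histogram by default; a Gaussian KDE when ``bandwidth`` is given.
    The density is normalized so that it integrates to 1.
    """
    lengths = np.asarray([h.query_length for h in profile.hits if h.query_length is not None])
    if lengths.size < min_reads:
        raise InsufficientDepthError(
            f"{profile.genome_id}: {lengths.size} reads < {min_reads}; too few for a density"
        )
    if bandwidth is not None and np.ptp(lengths) > 0:
        kde = stats.gaussian_kde(lengths.astype(float), bw_method=bandwidth)
        grid = np.linspace(lengths.min(), lengths.max(), 512)
        density = kde(grid)
        density = density / np.trapezoid(density, grid)
    else:
        counts, edges = np.histogram(lengths, bins=bins, density=True)
        grid = 0.5 * (edges[:-1] + edges[1:])
        density = counts
    return LengthDistribution(
        species=profile.species,
        grid=grid,
        density=density,
        n_reads=int(lengths.size),
        median=float(np.median(lengths)),
        mean=float(lengths.mean()),
        n50=compute_n50(lengths.tolist()),
    )


def l1_distance(a: AbundanceTable, b: AbundanceTable) -> float:
    """Sum of absolute abundance differences over the union species set."""
    union = set(a.entries) | set(b.entries)
    if not (set(a.entries) & set(b.entries)):
        raise DataError("abundance tables share no species; distance is meaningless")
    return sum(abs(a.fraction(sp) - b.fraction(sp)) for sp in union)


def closest_threshold(
    sweep: SweepResult, reference: AbundanceTable
) -> tuple[int, list[float]]:
    """Sweep threshold whose table is closest (L1) to a reference table.

    Returns the argmin threshold (smallest on ties) and the full
    distance-per-threshold profile.
    """
    distances = [l1_distance(t, reference) for t in sweep.tables]
    best = int(np.argmin(distances))  # argmin takes the first on ties
    return sweep.thresholds[best], distances


def group_minorities(
    tables: AbundanceTable | Sequence[AbundanceTable], cutoff: float
) -> AbundanceTable | list[AbundanceTable]:
    """Pool species below ``cutoff`` in *all* compared tables into a single
    "Minorities" entry.  Accepts one table or several; sums are preserved."""
    if not 0 < cutoff < 0.5:
        raise DataError(f"minorities cutoff must be in (0, 0.5), got {cutoff}")
    single = isinstance(tables, AbundanceTable)
    tlist = [tables] if single else list(tables)
    all_species = set().union(*(t.entries for t in tlist))
    minor = {
        sp for sp in all_species if all(t.fraction(sp) < cutoff for t in tlist)
    }
    out = []
    for t in tlist:
        entries = {sp: f for sp, f in t.entries.items() if sp not in minor}
        pooled = sum(t.fraction(sp) for sp in minor)
        if pooled > 0 or (minor & set(t.entries)):
            entries[MINORITIES_LABEL] = pooled
        out.append(
            AbundanceTable(
                sample_id=t.sample_id,
                mode=t.mode,
                min_read_length=t.min_read_length,
                entries=entries,
                minorities_cutoff=cutoff,
            )
        )
    return out[0] if single else out


def method_comparison_stats(
    tables_a: Sequence[AbundanceTable],
    tables_b: Sequence[AbundanceTable],
    covariate: Mapping[str, float] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-species paired comparison of two abundance-table collections.

    Tables are paired by ``sample_id``.  For each species in the union the
    paired differences (a - b) give a mean difference, a paired t statistic
    and a two-sided p-value; ``significant`` flags p < ``alpha``.  No
    multiplicity correction is applied (flagged in the column name
    ``p_value_uncorrected``).  With a per-sample covariate, a Spearman rank
    correlation of the method-a abundances against the covariate is added.
    """
    ids_a = [t.sample_id for t in tables_a]
    ids_b = [t.sample_id for t in tables_b]
    if sorted(ids_a) != sorted(ids_b) or len(set(ids_a)) != len(ids_a):
        raise DataError("tables are not paired one-to-one by sample_id")
    if len(ids_a) < 3:
        raise DataError(f"need >= 3 paired samples, got {len(ids_a)}")
    a_by_id = {t.sample_id: t for t in tables_a}
    b_by_id = {t.sample_id: t for t in tables_b}
    sample_ids = sorted(a_by_id)
    species = sorted(set().union(*(t.entries for t in tables_a + list(tables_b))))
    rows = []
    for sp in species:
        av = np.array([a_by_id[s].fraction(sp) for s in sample_ids])
        bv = np.array([b_by_id[s].fraction(sp) for s in sample_ids])
        diffs = av - bv
        if np.allclose(diffs, 0.0):
            tstat, pval = 0.0, 1.0
        else:
            tstat, pval = stats.ttest_rel(av, bv)
        row = {
            "species": sp,
            "mean_diff": float(diffs.mean()),
            "t_stat": float(tstat),
            "p_value_uncorrected": float(pval),
            "significant": bool(pval < alpha),
        }
        if covariate is not None:
            missing = [s for s in sample_ids if s not in covariate]
            if missing:
                raise DataError(f"covariate missing for samples: {missing}")
            cov = np.array([covariate[s] for s in sample_ids])
            if np.ptp(av) == 0 or np.ptp(cov) == 0:
                rho, rho_p = float("nan"), float("nan")
            else:
                rho, rho_p = stats.spearmanr(av, cov)
            row["spearman_rho"] = float(rho)
            row["spearman_p"] = float(rho_p)
        rows.append(row)
    return pd.DataFrame(rows)
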