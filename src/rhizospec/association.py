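"""Realized association specificity: link-strength matrices and the PDI.

The link strength of a host-genotype pair is the proportion of the host's
sampled nodules occupied by that symbiont genotype,

    P_ij = n_ij / n_i,

where ``n_ij`` counts nodules of host *i* occupied by genotype *j* and
``n_i`` is the host's genotyped-nodule total.  Specialization of each host is
summarised by the Paired Differences Index (PDI): the mean difference between
the host's strongest link strength and each of its other link strengths.
With proportions and the partner-categories denominator, PDI is 0 for a
perfect generalist (uniform links) and 1 for a perfect specialist.

Observed PDIs are compared against a simulated null in which hosts sample
nodules multinomially from the pooled genotype frequency distribution; each
replicate's joint PDI (the PDI of the across-host average link profile) forms
the null distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotyping import VALID_LOCI

TABLE_COLUMNS = [
    "isolate_id",
    "host_species",
    "host_genus",
    "plant_id",
    "nodule_id",
    "genotype_ITS",
    "genotype_NifD",
]

#: denominator mode: divide the paired-difference sum by (number of partner
#: categories - 1).  An explicit numeric denominator reproduces alternative
#: printed conventions (e.g. nodule counts).
PARTNERS_MINUS_1 = "partners_minus_1"


class NoduleTableError(ValueError):
    """Nodule-isolate table violates its invariants."""


def validate_nodule_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check nodule-table invariants and return the (unmodified) table.

    Invariants: required columns present; the host_species -> host_genus
    mapping is single-valued; (plant_id, nodule_id) pairs are unique.
    """
    missing = [c for c in TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise NoduleTableError(f"nodule table missing columns: {missing}")
    if table.empty:
        raise NoduleTableError("nodule table is empty")
    genus_map = table.groupby("host_species")["host_genus"].nunique()
    bad = genus_map[genus_map > 1]
    if not bad.empty:
        raise NoduleTableError(
            f"host_species mapped to multiple genera: {list(bad.index)}"
        )
    dupes = table.duplicated(subset=["plant_id", "nodule_id"])
    if dupes.any():
        pairs = table.loc[dupes, ["plant_id", "nodule_id"]].values.tolist()
        raise NoduleTableError(f"duplicate (plant_id, nodule_id) pairs: {pairs}")
    return table


@dataclass
class LinkStrengthMatrix:
    """Host x genotype association counts and proportions."""

    hosts: list[str]
    genotypes: list[str]
    counts: np.ndarray  # integer, hosts x genotypes
    locus: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.hosts), len(self.genotypes)):
            raise ValueError("counts shape does not match hosts x genotypes")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def totals(self) -> np.ndarray:
        """Genotyped-nodule totals n_i per host."""
        return self.counts.sum(axis=1)

    @property
    def proportions(self) -> np.ndarray:
        """Link strengths P_ij = n_ij / n_i."""
        return self.counts / self.totals[:, None]

    def counts_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.hosts, columns=self.genotypes)

    def proportions_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.proportions, index=self.hosts, columns=self.genotypes
        )


@dataclass
class PDIResult:
    host: str
    value: float
    n_partners: int
    denominator: float


@dataclass
class NullDistribution:
    """Replicate joint-PDI values from the multinomial sampling null."""

    replicates: np.ndarray
    seed: int | None
    n_hosts: int
    nodules_per_host: int
    genotype_freqs: np.ndarray
    denominator: object = PARTNERS_MINUS_1
    sampling: str = "per_host"

    @property
    def reps(self) -> int:
        return self.replicates.size

    @property
    def mean(self) -> float:
        return float(self.replicates.mean())

    @property
    def sd(self) -> float:
        """Standard deviation of the replicate joint PDIs."""
        return float(self.replicates.std(ddof=1)) if self.reps > 1 else 0.0

    @property
    def ci_halfwidth(self) -> float:
        """95% half-width for the null mean (1.96 x sd / sqrt(reps))."""
        return 1.96 * self.sd / np.sqrt(self.reps)

    @property
    def ci(self) -> tuple[float, float]:
        h = self.ci_halfwidth
        return (self.mean - h, self.mean + h)

    @property
    def percentiles(self) -> tuple[float, float]:
        """Empirical 2.5/97.5 percentiles of the replicate distribution."""
        lo, hi = np.percentile(self.replicates, [2.5, 97.5])
        return (float(lo), float(hi))

    def to_dict(self) -> dict:
        return {
            "reps": self.reps,
            "mean": self.mean,
            "sd": self.sd,
            "ci_low": self.ci[0],
            "ci_high": self.ci[1],
            "percentile_2.5": self.percentiles[0],
            "percentile_97.5": self.percentiles[1],
            "seed": self.seed,
            "n_hosts": self.n_hosts,
            "nodules_per_host": self.nodules_per_host,
            "sampling": self.sampling,
            "genotype_freqs": list(map(float, self.genotype_freqs)),
        }


@dataclass
class PDIComparison:
    observed: float
    null_mean: float
    ci: tuple[float, float]
    significant: bool
    tail_probability: float


def build_link_matrix(table: pd.DataFrame, locus: str) -> LinkStrengthMatrix:
    """Tabulate host x genotype nodule counts for one locus.

    One row per host, one column per genotype observed in *any* host (the
    union defines the available-partner universe).  Nodules lacking a
    genotype at this locus are excluded from both n_ij and n_i.  A host left
    with zero genotyped nodules raises :class:`NoduleTableError`.
    """
    if locus not in VALID_LOCI:
        raise ValueError(f"locus must be one of {VALID_LOCI}, got {locus!r}")
    validate_nodule_table(table)
    col = f"genotype_{locus}"
    genotyped = table[table[col].notna() & (table[col].astype(str) != "")]
    hosts = sorted(table["host_species"].unique())
    empty = sorted(set(hosts) - set(genotyped["host_species"].unique()))
    if empty:
        raise NoduleTableError(
            f"hosts with zero genotyped nodules at {locus}: {empty}"
        )
    counts = pd.crosstab(genotyped["host_species"], genotyped[col])
    counts = counts.reindex(index=hosts, columns=sorted(counts.columns))
    return LinkStrengthMatrix(
        hosts=list(counts.index),
        genotypes=[str(c) for c in counts.columns],
        counts=counts.to_numpy(),
        locus=locus,
    )


def _resolve_denominator(n: int, denominator) -> float:
    if denominator == PARTNERS_MINUS_1:
        return float(n - 1)
    d = float(denominator)
    if d <= 0:
        raise ValueError(f"explicit denominator must be positive, got {d}")
    return d


def pdi(values, denominator=PARTNERS_MINUS_1) -> float:
    """Paired Differences Index of a vector of link strengths.

    Sums the differences between the largest entry and every other entry,
    divided by the denominator (default: number of entries - 1).  Ties at
    the maximum contribute zero terms.  Negative entries are permitted (with
    a warning) for fitness-effect applications where link strengths are
    replaced by per-block fitness effects.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise ValueError("pdi requires a 1-d vector of length >= 2")
    if not np.all(np.isfinite(v)):
        raise ValueError("pdi requires finite values")
    if (v < 0).any():
        warnings.warn("pdi input contains negative values", stacklevel=2)
    denom = _resolve_denominator(v.size, denominator)
    top = v.max()
    return float((top * (v.size - 1) - (v.sum() - top)) / denom)


def pdi_per_host(
    matrix: LinkStrengthMatrix, denominator=PARTNERS_MINUS_1
) -> dict[str, PDIResult]:
    """Per-host PDI over the matrix's full genotype universe."""
    out = {}
    for host, row in zip(matrix.hosts, matrix.proportions):
        denom = _resolve_denominator(row.size, denominator)
        out[host] = PDIResult(host, pdi(row, denominator), row.size, denom)
    return out


def joint_pdi(matrix, denominator=PARTNERS_MINUS_1) -> float:
    """PDI of the across-host average link profile.

    Accepts a :class:`LinkStrengthMatrix` or a 2-d array of link strengths
    (hosts x genotypes).  With a single host this reduces to that host's PDI.
    """
    if isinstance(matrix, LinkStrengthMatrix):
        rows = matrix.proportions
    else:
        rows = np.atleast_2d(np.asarray(matrix, dtype=float))
    return pdi(rows.mean(axis=0), denominator)


def _joint_pdi_vectorized(profiles: np.ndarray, denom: float) -> np.ndarray:
    # profiles: reps x genotypes, already averaged across hosts
    g = profiles.shape[1]
    top = profiles.max(axis=1)
    return (top * (g - 1) - (profiles.sum(axis=1) - top)) / denom


def genotype_frequencies(table: pd.DataFrame, locus: str):
    """Pooled genotype frequencies over all genotyped nodules at a locus."""
    col = f"genotype_{locus}"
    counts = table[col].dropna()
    counts = counts[counts.astype(str) != ""].value_counts().sort_index()
    freqs = counts / counts.sum()
    return list(counts.index), freqs.to_numpy()


def simulate_null_joint_pdi(
    genotype_freqs,
    n_hosts: int,
    nodules_per_host: int,
    reps: int = 1000,
    seed: int | None = None,
    denominator=PARTNERS_MINUS_1,
    sampling: str = "per_host",
) -> NullDistribution:
    """Simulated null distribution of the joint PDI.

    Per replicate, each of ``n_hosts`` hosts draws ``nodules_per_host``
    nodules multinomially from ``genotype_freqs`` (the pooled availability
    distribution); per-host link strengths are averaged across hosts and the
    joint PDI recorded.  ``sampling="shared"`` draws a single population per
    replicate used by all hosts.  Fully reproducible under ``seed``.
    """
    freqs = np.asarray(genotype_freqs, dtype=float)
    if freqs.ndim != 1 or freqs.size < 1:
        raise ValueError("genotype_freqs must be a 1-d probability vector")
    if abs(freqs.sum() - 1.0) > 1e-9:
        raise ValueError(f"genotype_freqs must sum to 1, got {freqs.sum()}")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if sampling not in ("per_host", "shared"):
        raise ValueError("sampling must be 'per_host' or 'shared'")
    rng = np.random.default_rng(seed)
    if freqs.size == 1:
        replicates = np.zeros(reps)
    else:
        if sampling == "per_host":
            counts = rng.multinomial(
                nodules_per_host, freqs, size=(reps, n_hosts)
            )
            profiles = counts.mean(axis=1) / nodules_per_host
        else:
            counts = rng.multinomial(nodules_per_host, freqs, size=reps)
            profiles = counts / nodules_per_host
        denom = _resolve_denominator(freqs.size, denominator)
        replicates = _joint_pdi_vectorized(profiles, denom)
    return NullDistribution(
        replicates=replicates,
        seed=seed,
        n_hosts=n_hosts,
        nodules_per_host=nodules_per_host,
        genotype_freqs=freqs,
        denominator=denominator,
        sampling=sampling,
    )


def compare_pdi_to_null(observed, null: NullDistribution) -> PDIComparison:
    """Compare an observed PDI with the simulated null.

    Significance = observed falls outside the null mean's 95% limits; the
    empirical upper-tail proportion uses the add-one permutation convention
    (count of replicates >= observed, + 1) / (reps + 1).
    """
    if null.reps < 2:
        raise ValueError("null distribution needs >= 2 replicates")
    obs = observed.value if isinstance(observed, PDIResult) else float(observed)
    lo, hi = null.ci
    tail = (int((null.replicates >= obs).sum()) + 1) / (null.reps + 1)
    return PDIComparison(
        observed=obs,
        null_mean=null.mean,
        ci=(lo, hi),
        significant=bool(obs < lo or obs > hi),
        tail_probability=tail,
    )
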