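"""Sequence-based population structure: diversity, Phi_st, and AMOVA.

Populations are the host species from which nodule isolates were collected;
groups are host genera.  All statistics operate on a matrix of raw pairwise
nucleotide differences between isolate sequences.

The variance partition follows the analysis-of-molecular-variance framework:
sums of squared deviations are computed from squared pairwise distances,

    SSD(S) = (1 / n_S) * sum_{i<j in S} d_ij^2,

partitioned hierarchically (between groups / between populations within
groups / within populations), and converted to variance components via the
expected mean squares of the unbalanced nested design.  Phi statistics are
ratios of variance components; significance comes from permutation tests
with the add-one correction.  Negative variance components are reported as
computed, never truncated.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotyping import DistanceMatrix


class PartitionError(ValueError):
    """Population partition inconsistent with the distance matrix."""


@dataclass
class PopulationPartition:
    """Isolate -> population (host species) and population -> group (genus)."""

    populations: dict[str, str]  # isolate_id -> population label
    groups: dict[str, str] | None = None  # population label -> group label

    def __post_init__(self) -> None:
        if self.groups is not None:
            missing = set(self.populations.values()) - set(self.groups)
            if missing:
                raise PartitionError(
                    f"populations without a group assignment: {sorted(missing)}"
                )

    @property
    def population_labels(self) -> list[str]:
        return sorted(set(self.populations.values()))

    def isolates_of(self, population: str) -> list[str]:
        return [i for i, p in self.populations.items() if p == population]

    @classmethod
    def from_table(cls, table: pd.DataFrame) -> "PopulationPartition":
        """Build from a nodule table (host_species = population, host_genus = group)."""
        pops = dict(zip(table["isolate_id"], table["host_species"]))
        groups = dict(
            zip(table["host_species"], table["host_genus"])
        )
        return cls(pops, groups)


@dataclass
class PhiStResult:
    phi_st: float | None
    p_value: float
    sigma_among: float
    sigma_within: float
    perms: int
    seed: int | None


@dataclass
class AmovaLevel:
    df: int
    ssd: float
    sigma2: float | None
    pct_variance: float | None
    p_value: float | None


@dataclass
class AmovaResult:
    """Hierarchical variance partition over groups / populations / isolates."""

    between_groups: AmovaLevel
    between_pops_within_groups: AmovaLevel
    within_pops: AmovaLevel
    total_df: int
    total_ssd: float
    phi_ct: float | None
    phi_sc: float | None
    phi_st: float | None
    perms: int
    seed: int | None
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        def level(l: AmovaLevel) -> dict:
            return {
                "df": l.df,
                "ssd": l.ssd,
                "sigma2": l.sigma2,
                "pct_variance": l.pct_variance,
                "p_value": l.p_value,
            }

        return {
            "between_groups": level(self.between_groups),
            "between_pops_within_groups": level(self.between_pops_within_groups),
            "within_pops": level(self.within_pops),
            "total": {"df": self.total_df, "ssd": self.total_ssd},
            "phi_ct": self.phi_ct,
            "phi_sc": self.phi_sc,
            "phi_st": self.phi_st,
            "perms": self.perms,
            "seed": self.seed,
            "warnings": self.warnings,
        }


def _check_partition(dist: DistanceMatrix, part: PopulationPartition) -> None:
    missing = set(dist.labels) - set(part.populations)
    if missing:
        raise PartitionError(f"isolates without a population: {sorted(missing)}")


def _ssd_within_sets(d2: np.ndarray, index_sets: list[np.ndarray]) -> float:
    """Sum over sets S of (1/|S|) * sum_{i<j in S} d2_ij."""
    total = 0.0
    for idx in index_sets:
        if idx.size > 1:
            total += d2[np.ix_(idx, idx)].sum() / (2.0 * idx.size)
    return total


def _pop_indices(labels: list[str], pop_of: dict[str, str]) -> dict[str, np.ndarray]:
    pops: dict[str, list[int]] = {}
    for i, iso in enumerate(labels):
        pops.setdefault(pop_of[iso], []).append(i)
    return {p: np.asarray(ix) for p, ix in sorted(pops.items())}


def diversity_matrix(
    dist: DistanceMatrix,
    part: PopulationPartition,
    perms: int = 10_000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Square population summary of diversity and differentiation.

    Diagonal: mean within-population pairwise differences.  Below diagonal:
    corrected mean between-population differences (raw cross-population mean
    minus the average of the two within-population means).  Above diagonal:
    pairwise Phi_st.  Singleton populations get missing within values.
    A long-format companion is available from :func:`diversity_long`.
    """
    _check_partition(dist, part)
    pops = _pop_indices(dist.labels, part.populations)
    names = list(pops)
    n = len(names)
    d = dist.values
    within = {}
    for p, idx in pops.items():
        if idx.size < 2:
            within[p] = np.nan
        else:
            within[p] = d[np.ix_(idx, idx)].sum() / (idx.size * (idx.size - 1))
    out = pd.DataFrame(np.nan, index=names, columns=names)
    for p in names:
        out.loc[p, p] = within[p]
    rng_seed = seed
    for a, b in itertools.combinations(names, 2):
        ia, ib = pops[a], pops[b]
        raw = d[np.ix_(ia, ib)].mean()
        corrected = raw - (within[a] + within[b]) / 2.0
        out.loc[max(a, b), min(a, b)] = corrected  # below diagonal (row later)
        if ia.size < 2 or ib.size < 2:
            continue  # Phi_st needs >= 2 isolates per population
        sub_labels = [dist.labels[i] for i in np.concatenate([ia, ib])]
        sub = dist.subset(sub_labels)
        two_pop = PopulationPartition(
            {l: part.populations[l] for l in sub_labels}
        )
        res = phi_st(sub, two_pop, perms=perms, seed=rng_seed)
        out.loc[min(a, b), max(a, b)] = res.phi_st
    return out


def diversity_long(
    dist: DistanceMatrix,
    part: PopulationPartition,
    perms: int = 10_000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Long-format diversity summary: one row per population pair."""
    _check_partition(dist, part)
    pops = _pop_indices(dist.labels, part.populations)
    d = dist.values
    within = {
        p: (
            d[np.ix_(ix, ix)].sum() / (ix.size * (ix.size - 1))
            if ix.size > 1
            else np.nan
        )
        for p, ix in pops.items()
    }
    rows = []
    for a, b in itertools.combinations(pops, 2):
        ia, ib = pops[a], pops[b]
        raw = d[np.ix_(ia, ib)].mean()
        corrected = raw - (within[a] + within[b]) / 2.0
        if ia.size >= 2 and ib.size >= 2:
            sub_labels = [dist.labels[i] for i in np.concatenate([ia, ib])]
            res = phi_st(
                dist.subset(sub_labels),
                PopulationPartition(
                    {l: part.populations[l] for l in sub_labels}
                ),
                perms=perms,
                seed=seed,
            )
        else:
            res = PhiStResult(None, np.nan, np.nan, np.nan, perms, seed)
        rows.append(
            {
                "pop_a": a,
                "pop_b": b,
                "within_a": within[a],
                "within_b": within[b],
                "raw_between": raw,
                "corrected_between": corrected,
                "phi_st": res.phi_st,
                "phi_st_p": res.p_value,
            }
        )
    return pd.DataFrame(rows)


def _one_level_components(
    d2: np.ndarray, index_sets: list[np.ndarray]
) -> tuple[float, float]:
    """(sigma_among, sigma_within) for a flat population partition."""
    n_total = d2.shape[0]
    sizes = np.array([ix.size for ix in index_sets], dtype=float)
    p = len(index_sets)
    ssd_total = d2.sum() / (2.0 * n_total)
    ssd_within = _ssd_within_sets(d2, index_sets)
    ssd_among = ssd_total - ssd_within
    df_within = n_total - p
    df_among = p - 1
    ms_within = ssd_within / df_within if df_within > 0 else 0.0
    sigma_w = ms_within
    n_prime = (n_total - (sizes**2).sum() / n_total) / df_among
    ms_among = ssd_among / df_among
    sigma_a = (ms_among - sigma_w) / n_prime
    return sigma_a, sigma_w


def phi_st(
    dist: DistanceMatrix,
    part: PopulationPartition,
    perms: int = 10_000,
    seed: int | None = None,
) -> PhiStResult:
    """Pairwise Phi_st between exactly two populations, with permutation p.

    Phi_st = sigma_among / (sigma_among + sigma_within), the analogue of
    Wright's F_ST that weights haplotypes by their sequence divergence.  The
    p-value permutes isolates between the two populations (add-one
    correction, one-sided: permuted Phi_st >= observed).  When all sequences
    are identical the statistic is undefined (None) with p = 1.
    """
    _check_partition(dist, part)
    pops = _pop_indices(dist.labels, part.populations)
    if len(pops) != 2:
        raise PartitionError(f"phi_st requires exactly 2 populations, got {len(pops)}")
    for p, ix in pops.items():
        if ix.size < 2:
            raise PartitionError(f"population {p!r} has fewer than 2 isolates")
    d2 = dist.values**2
    sets = list(pops.values())
    sigma_a, sigma_w = _one_level_components(d2, sets)
    denom = sigma_a + sigma_w
    if denom == 0.0:
        return PhiStResult(None, 1.0, sigma_a, sigma_w, perms, seed)
    observed = sigma_a / denom

    rng = np.random.default_rng(seed)
    n = d2.shape[0]
    n_a = sets[0].size
    count = 0
    for _ in range(perms):
        perm = rng.permutation(n)
        pa, pb = perm[:n_a], perm[n_a:]
        s_a, s_w = _one_level_components(d2, [pa, pb])
        den = s_a + s_w
        stat = s_a / den if den != 0 else -np.inf
        if stat >= observed:
            count += 1
    p_value = (count + 1) / (perms + 1)
    return PhiStResult(float(observed), p_value, sigma_a, sigma_w, perms, seed)


def _two_level_ssds(
    d2: np.ndarray,
    pop_sets: list[np.ndarray],
    group_of_pop: list[int],
    n_groups: int,
) -> tuple[float, float, float]:
    """(ssd_groups, ssd_pops_within, ssd_within) by the nested partition."""
    n_total = d2.shape[0]
    ssd_total = d2.sum() / (2.0 * n_total)
    ssd_within = _ssd_within_sets(d2, pop_sets)
    group_sets = [
        np.concatenate([ix for ix, g in zip(pop_sets, group_of_pop) if g == gi])
        for gi in range(n_groups)
    ]
    ssd_within_groups = _ssd_within_sets(d2, group_sets)
    ssd_pops = ssd_within_groups - ssd_within
    ssd_groups = ssd_total - ssd_within_groups
    return ssd_groups, ssd_pops, ssd_within


def _two_level_components(
    d2: np.ndarray, pop_sets: list[np.ndarray], group_of_pop: list[int], n_groups: int
):
    """Variance components (sigma_a, sigma_b, sigma_c) and SSDs."""
    n_total = d2.shape[0]
    p = len(pop_sets)
    sizes = np.array([ix.size for ix in pop_sets], dtype=float)
    group_sizes = np.array(
        [sizes[[i for i, g in enumerate(group_of_pop) if g == gi]].sum()
         for gi in range(n_groups)]
    )
    ssd_a, ssd_b, ssd_c = _two_level_ssds(d2, pop_sets, group_of_pop, n_groups)
    df_a, df_b, df_c = n_groups - 1, p - n_groups, n_total - p

    sigma_c = ssd_c / df_c if df_c > 0 else 0.0
    # sum over groups of (sum of n_p^2 within group) / n_g
    sum_np2_over_ng = sum(
        (sizes[[i for i, g in enumerate(group_of_pop) if g == gi]] ** 2).sum()
        / group_sizes[gi]
        for gi in range(n_groups)
    )
    if df_b > 0:
        n1 = (n_total - sum_np2_over_ng) / df_b
        sigma_b = (ssd_b / df_b - sigma_c) / n1
    else:
        sigma_b = 0.0
    if df_a > 0:
        n2 = (sum_np2_over_ng - (sizes**2).sum() / n_total) / df_a
        n3 = (n_total - (group_sizes**2).sum() / n_total) / df_a
        sigma_a = (ssd_a / df_a - sigma_c - n2 * sigma_b) / n3
    else:
        sigma_a = 0.0
    return (sigma_a, sigma_b, sigma_c), (ssd_a, ssd_b, ssd_c), (df_a, df_b, df_c)


def amova_two_level(
    dist: DistanceMatrix,
    part: PopulationPartition,
    perms: int = 10_000,
    seed: int | None = None,
) -> AmovaResult:
    """Two-level hierarchical AMOVA: genera / species within genus / isolates.

    Partitions the total squared-distance SSD into between-group,
    between-population-within-group and within-population levels and solves
    the unbalanced-design expected mean squares for the variance components.
    Percentages are computed on the raw (possibly negative) components.

    Permutation tests (add-one corrected, one-sided on the matching Phi
    statistic): Phi_st (within level) permutes isolates across everything;
    Phi_sc permutes isolates among populations within their group; Phi_ct
    permutes whole populations among groups, preserving the number of
    populations per group.
    """
    _check_partition(dist, part)
    if part.groups is None:
        raise PartitionError("two-level AMOVA requires a population -> group map")
    pops = _pop_indices(dist.labels, part.populations)
    pop_names = list(pops)
    group_names = sorted(set(part.groups[p] for p in pop_names))
    group_of_pop = [group_names.index(part.groups[p]) for p in pop_names]
    n_groups = len(group_names)
    n_total = len(dist.labels)
    warns: list[str] = []
    if n_total < 4:
        raise PartitionError("AMOVA requires at least 4 isolates")
    for gi, g in enumerate(group_names):
        if group_of_pop.count(gi) == 1:
            warns.append(
                f"group {g!r} contains a single population; its "
                "population-within-group variance uses the pooled estimator"
            )

    d2 = dist.values**2
    pop_sets = list(pops.values())
    (sigma_a, sigma_b, sigma_c), (ssd_a, ssd_b, ssd_c), (df_a, df_b, df_c) = (
        _two_level_components(d2, pop_sets, group_of_pop, n_groups)
    )
    total = sigma_a + sigma_b + sigma_c
    if total != 0:
        pcts = [100 * s / total for s in (sigma_a, sigma_b, sigma_c)]
        phi_ct_obs = sigma_a / total
        phi_st_obs = (sigma_a + sigma_b) / total
    else:
        pcts = [0.0, 0.0, 0.0]
        phi_ct_obs = phi_st_obs = None
    bc = sigma_b + sigma_c
    phi_sc_obs = sigma_b / bc if bc != 0 else None

    rng = np.random.default_rng(seed)
    sizes = [ix.size for ix in pop_sets]

    def components_for(sets):
        return _two_level_components(d2, sets, group_of_pop, n_groups)[0]

    # Phi_st: permute isolates across everything
    p_within = None
    if phi_st_obs is not None:
        count = 0
        for _ in range(perms):
            perm = rng.permutation(n_total)
            sets, off = [], 0
            for s in sizes:
                sets.append(perm[off : off + s])
                off += s
            sa, sb, sc = components_for(sets)
            tot = sa + sb + sc
            stat = (sa + sb) / tot if tot != 0 else -np.inf
            if stat >= phi_st_obs:
                count += 1
        p_within = (count + 1) / (perms + 1)

    # Phi_sc: permute isolates among populations within their group
    p_pops = None
    if phi_sc_obs is not None and df_b > 0:
        group_members = [
            np.concatenate(
                [pop_sets[i] for i, g in enumerate(group_of_pop) if g == gi]
            )
            for gi in range(n_groups)
        ]
        count = 0
        for _ in range(perms):
            sets = [None] * len(pop_sets)
            for gi in range(n_groups):
                pool = rng.permutation(group_members[gi])
                off = 0
                for i, g in enumerate(group_of_pop):
                    if g == gi:
                        sets[i] = pool[off : off + sizes[i]]
                        off += sizes[i]
            sa, sb, sc = components_for(sets)
            den = sb + sc
            stat = sb / den if den != 0 else -np.inf
            if stat >= phi_sc_obs:
                count += 1
        p_pops = (count + 1) / (perms + 1)

    # Phi_ct: permute whole populations among groups (group sizes in
    # numbers of populations preserved)
    p_groups = None
    n_assignments = math.factorial(len(pop_sets)) // math.prod(
        math.factorial(group_of_pop.count(gi)) for gi in range(n_groups)
    )
    if phi_ct_obs is not None and df_a > 0:
        if n_assignments <= 20:
            warns.append(
                f"group-level test has only {n_assignments} distinct "
                f"population-to-group assignments; minimum attainable "
                f"p ~ {1.0 / n_assignments:.3g}"
            )
        count = 0
        for _ in range(perms):
            order = rng.permutation(len(pop_sets))
            permuted_group = [0] * len(pop_sets)
            slot = 0
            for gi in range(n_groups):
                k = group_of_pop.count(gi)
                for j in order[slot : slot + k]:
                    permuted_group[j] = gi
                slot += k
            sa, sb, sc = _two_level_components(
                d2, pop_sets, permuted_group, n_groups
            )[0]
            tot = sa + sb + sc
            stat = sa / tot if tot != 0 else -np.inf
            if stat >= phi_ct_obs:
                count += 1
        p_groups = (count + 1) / (perms + 1)

    return AmovaResult(
        between_groups=AmovaLevel(df_a, ssd_a, sigma_a, pcts[0], p_groups),
        between_pops_within_groups=AmovaLevel(
            df_b, ssd_b, sigma_b, pcts[1], p_pops
        ),
        within_pops=AmovaLevel(df_c, ssd_c, sigma_c, pcts[2], p_within),
        total_df=n_total - 1,
        total_ssd=ssd_a + ssd_b + ssd_c,
        phi_ct=phi_ct_obs,
        phi_sc=phi_sc_obs,
        phi_st=phi_st_obs,
        perms=perms,
        seed=seed,
        warnings=warns,
    )
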