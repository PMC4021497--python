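"""Blocked single-strain inoculation experiment: response and effect specificity.

Two test hosts were each grown in ten spatial blocks; within a block each of
31 *Bradyrhizobium* strains was inoculated onto one seedling, with five
sterile-water control seedlings per block.  Measured traits: shoot dry
weight (g, a host fitness component), nodule count and total projected nodule
area (cm^2, multiplicative symbiont fitness components).

Response specificity (variation in benefit the host receives) is quantified
per block by converting each strain's shoot weight into a fitness effect

    p_jk = (w_jk - w_Ck) / w_jk,

(w_Ck = block mean of surviving conspecific controls) and applying the
Paired Differences Index across strains within the block.  Effect
specificity (variation in fitness the host confers) applies the same
block-PDI machinery to transformed nodule traits (ln counts, sqrt area);
controls carry no nodules, so no control normalisation is meaningful there.

Genotype-mean summaries feed fitness-feedback correlations (Pearson, across
strain means) and Mantel tests of association between marker genetic
distances and phenotypic difference matrices.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .association import PARTNERS_MINUS_1, _resolve_denominator, pdi
from .genotyping import DistanceMatrix

CONTROL = "CONTROL"

GREENHOUSE_COLUMNS = [
    "plant_id",
    "host_species",
    "block",
    "treatment",
    "origin_species",
    "origin_genus",
    "shoot_dry_weight_g",
    "nodule_count",
    "total_nodule_area_cm2",
]

TRAIT_COLUMNS = {
    "shoot_weight": "shoot_dry_weight_g",
    "nodule_count": "nodule_count",
    "total_nodule_area": "total_nodule_area_cm2",
}

#: default variance-stabilising transforms for the symbiont fitness traits
DEFAULT_TRANSFORMS = {"nodule_count": "ln", "total_nodule_area": "sqrt"}


class GreenhouseError(ValueError):
    """Greenhouse table violates a precondition (e.g. a block with no controls)."""


@dataclass
class ContaminationReport:
    excluded: pd.DataFrame  # the excluded control records
    n_controls: int
    n_excluded: int

    def by_host_block(self) -> pd.DataFrame:
        if self.excluded.empty:
            return pd.DataFrame(columns=["host_species", "block", "n_excluded"])
        return (
            self.excluded.groupby(["host_species", "block"])
            .size()
            .rename("n_excluded")
            .reset_index()
        )


@dataclass
class BlockPDISummary:
    """Per-block PDI values for one host, with across-block summary.

    The 95% CI uses the t distribution on the among-block variance
    (mean +/- t_{0.975, k-1} * sd / sqrt(k)).
    """

    host: str
    trait: str
    block_values: dict  # block id -> PDI_ik
    n_strains_by_block: dict  # block id -> N used
    denominator: object = PARTNERS_MINUS_1

    @property
    def values(self) -> np.ndarray:
        return np.asarray(list(self.block_values.values()), dtype=float)

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def se(self) -> float:
        v = self.values
        return float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else np.nan

    @property
    def ci(self) -> tuple[float, float]:
        v = self.values
        if v.size < 2:
            return (np.nan, np.nan)
        tcrit = stats.t.ppf(0.975, v.size - 1)
        return (self.mean - tcrit * self.se, self.mean + tcrit * self.se)

    def to_dict(self) -> dict:
        return {
            "host": self.host,
            "trait": self.trait,
            "block_values": {str(k): float(v) for k, v in self.block_values.items()},
            "n_strains_by_block": {
                str(k): int(v) for k, v in self.n_strains_by_block.items()
            },
            "mean": self.mean,
            "se": self.se,
            "ci_low": self.ci[0],
            "ci_high": self.ci[1],
        }


@dataclass
class CorrelationResult:
    host: str
    x: str
    y: str
    r: float | None
    p_value: float | None
    n: int


@dataclass
class MantelResult:
    r: float
    p_value: float
    perms: int
    seed: int | None
    labels: list[str]


def validate_greenhouse_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in GREENHOUSE_COLUMNS if c not in table.columns]
    if missing:
        raise GreenhouseError(f"greenhouse table missing columns: {missing}")
    controls = table["treatment"] == CONTROL
    w = table["shoot_dry_weight_g"]
    if (w.dropna() <= 0).any():
        raise GreenhouseError("shoot dry weights must be positive where measured")
    nc = table["nodule_count"].dropna()
    if (nc < 0).any():
        raise GreenhouseError("nodule counts must be non-negative")
    bad = table.loc[
        controls & table["origin_species"].notna() & (table["origin_species"] != ""),
        "plant_id",
    ]
    if not bad.empty:
        raise GreenhouseError(
            f"control records carry origin labels: {list(bad)}"
        )
    return table


def filter_contaminated(
    table: pd.DataFrame,
) -> tuple[pd.DataFrame, ContaminationReport]:
    """Exclude cross-contaminated controls (controls that formed nodules).

    Treatment records are never excluded by this rule.  A (host, block) cell
    left with zero usable controls raises :class:`GreenhouseError`, since
    the block's fitness effects would be undefined.
    """
    validate_greenhouse_table(table)
    is_control = table["treatment"] == CONTROL
    contaminated = is_control & (table["nodule_count"].fillna(0) > 0)
    excluded = table[contaminated].copy()
    kept = table[~contaminated].copy()
    remaining = kept[kept["treatment"] == CONTROL].groupby(
        ["host_species", "block"]
    ).size()
    for (host, block), _ in table[is_control].groupby(["host_species", "block"]):
        if (host, block) not in remaining.index:
            raise GreenhouseError(
                f"block {block!r} of host {host!r} has no uncontaminated controls"
            )
    report = ContaminationReport(
        excluded=excluded,
        n_controls=int(is_control.sum()),
        n_excluded=int(contaminated.sum()),
    )
    return kept, report


def fitness_effect(w: float, w_control: float) -> float:
    """Fitness effect p = (w - w_control) / w; bounded above by 1."""
    if w <= 0 or w_control <= 0:
        raise ValueError("weights must be positive")
    return (w - w_control) / w


def fold_increase(w: float, w_control: float) -> float:
    """Growth response (w - w_control) / w_control; bounded below by -1."""
    if w <= 0 or w_control <= 0:
        raise ValueError("weights must be positive")
    return (w - w_control) / w_control


def block_pdi(values_by_strain, denominator=PARTNERS_MINUS_1) -> float:
    """PDI of one block's per-strain values (fitness effects or traits).

    Identical to the link-strength PDI but routinely applied to signed,
    unnormalised values, so results may exceed 1.
    """
    v = np.asarray(list(values_by_strain), dtype=float)
    if v.size < 2:
        raise ValueError("block_pdi requires >= 2 strain values")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # negative effects are expected here
        return pdi(v, denominator)


def _apply_transform(values: np.ndarray, transform: str | None) -> np.ndarray:
    if transform in (None, "none"):
        return values
    if transform == "sqrt":
        if (values < 0).any():
            raise ValueError("sqrt transform requires non-negative values")
        return np.sqrt(values)
    if transform == "ln":
        if (values <= 0).any():
            warnings.warn(
                "non-positive values under ln transform; using ln(x + 1)",
                stacklevel=2,
            )
            return np.log(values + 1.0)
        return np.log(values)
    raise ValueError(f"unknown transform {transform!r}")


def block_control_weights(table: pd.DataFrame, host: str) -> dict:
    """Block -> mean shoot weight of surviving conspecific controls."""
    sub = table[
        (table["host_species"] == host) & (table["treatment"] == CONTROL)
    ]
    ctrl = sub.groupby("block")["shoot_dry_weight_g"].mean()
    if ctrl.empty:
        raise GreenhouseError(f"no control plants for host {host!r}")
    return ctrl.to_dict()


def response_pdi(
    table: pd.DataFrame,
    host: str,
    denominator=PARTNERS_MINUS_1,
) -> BlockPDISummary:
    """Response-specificity PDI from within-block shoot-weight fitness effects.

    Expects a contamination-filtered table.  Per block: each strain's
    p_jk = (w_jk - w_Ck)/w_jk against the block control mean, then the PDI
    across strains; blocks with fewer than two strain values are skipped
    with a warning.
    """
    ctrl = block_control_weights(table, host)
    strains = table[
        (table["host_species"] == host) & (table["treatment"] != CONTROL)
    ]
    strains = strains[strains["shoot_dry_weight_g"].notna()]
    block_values, n_by_block = {}, {}
    for block, sub in strains.groupby("block"):
        if block not in ctrl:
            raise GreenhouseError(
                f"block {block!r} of host {host!r} has no usable controls"
            )
        per_strain = sub.groupby("treatment")["shoot_dry_weight_g"].mean()
        if per_strain.size < 2:
            warnings.warn(
                f"block {block!r} of host {host!r}: fewer than 2 strain "
                "values; block skipped",
                stacklevel=2,
            )
            continue
        effects = [fitness_effect(w, ctrl[block]) for w in per_strain]
        block_values[block] = block_pdi(effects, denominator)
        n_by_block[block] = per_strain.size
    if not block_values:
        raise GreenhouseError(f"no usable blocks for host {host!r}")
    return BlockPDISummary(host, "fitness_effect", block_values, n_by_block, denominator)


def effect_pdi(
    table: pd.DataFrame,
    host: str,
    trait: str,
    transform: str | None = "default",
    denominator=PARTNERS_MINUS_1,
) -> BlockPDISummary:
    """Effect-specificity PDI over a transformed symbiont fitness trait.

    ``trait`` is ``nodule_count`` or ``total_nodule_area``; the default
    transforms are ln for counts and sqrt for area.  Trait values enter the
    block PDI directly (controls have no nodules, so no control
    normalisation applies).
    """
    if trait not in ("nodule_count", "total_nodule_area"):
        raise ValueError(f"unsupported trait {trait!r}")
    if transform == "default":
        transform = DEFAULT_TRANSFORMS[trait]
    col = TRAIT_COLUMNS[trait]
    strains = table[
        (table["host_species"] == host) & (table["treatment"] != CONTROL)
    ]
    strains = strains[strains[col].notna()]
    block_values, n_by_block = {}, {}
    for block, sub in strains.groupby("block"):
        per_strain = sub.groupby("treatment")[col].mean()
        if per_strain.size < 2:
            warnings.warn(
                f"block {block!r} of host {host!r}: fewer than 2 strain "
                f"values for {trait}; block skipped",
                stacklevel=2,
            )
            continue
        values = _apply_transform(per_strain.to_numpy(dtype=float), transform)
        block_values[block] = block_pdi(values, denominator)
        n_by_block[block] = per_strain.size
    if not block_values:
        raise GreenhouseError(f"no usable blocks for host {host!r} trait {trait!r}")
    return BlockPDISummary(host, trait, block_values, n_by_block, denominator)


def genotype_means(
    table: pd.DataFrame,
    transform_map: dict | None = None,
) -> pd.DataFrame:
    """Per (host, strain) trait means and standard errors over replicates.

    Mean individual nodule area is total area / count per plant before
    averaging.  Only non-control records with a measured trait contribute;
    strains with zero surviving replicates are absent (warned).
    """
    strains = table[table["treatment"] != CONTROL].copy()
    strains["mean_nodule_area"] = np.where(
        strains["nodule_count"].fillna(0) > 0,
        strains["total_nodule_area_cm2"] / strains["nodule_count"],
        np.nan,
    )
    traits = {
        "shoot_weight": "shoot_dry_weight_g",
        "nodule_count": "nodule_count",
        "total_nodule_area": "total_nodule_area_cm2",
        "mean_nodule_area": "mean_nodule_area",
    }
    rows = []
    for (host, strain), sub in strains.groupby(["host_species", "treatment"]):
        row = {"host_species": host, "strain": strain}
        for name, col in traits.items():
            vals = sub[col].dropna().to_numpy(dtype=float)
            if transform_map and name in transform_map:
                vals = _apply_transform(vals, transform_map[name])
            row[f"{name}_mean"] = vals.mean() if vals.size else np.nan
            row[f"{name}_se"] = (
                vals.std(ddof=1) / np.sqrt(vals.size) if vals.size > 1 else np.nan
            )
            row[f"{name}_n"] = vals.size
        rows.append(row)
    out = pd.DataFrame(rows)
    all_strains = set(table.loc[table["treatment"] != CONTROL, "treatment"])
    for host in table["host_species"].unique():
        seen = set(out.loc[out["host_species"] == host, "strain"])
        lost = all_strains - seen
        if lost:
            warnings.warn(
                f"host {host!r}: strains with zero surviving replicates: "
                f"{sorted(lost)}",
                stacklevel=2,
            )
    return out


def feedback_correlations(
    means: pd.DataFrame,
    host: str,
    transform_map: dict | None = None,
) -> list[CorrelationResult]:
    """Pearson correlations between strain-mean shoot weight and nodule traits.

    ``transform_map`` optionally ln-transforms a nodule variable (the
    generalist host's analyses used natural-log nodule area/number).  The
    two-sided p comes from the t distribution with n - 2 df.
    """
    sub = means[means["host_species"] == host]
    out = []
    for trait in ("nodule_count", "total_nodule_area", "mean_nodule_area"):
        pair = sub[["shoot_weight_mean", f"{trait}_mean"]].dropna()
        n = len(pair)
        if n < 3:
            out.append(CorrelationResult(host, trait, "shoot_weight", None, None, n))
            continue
        x = pair[f"{trait}_mean"].to_numpy(dtype=float)
        if transform_map and trait in transform_map:
            x = _apply_transform(x, transform_map[trait])
        y = pair["shoot_weight_mean"].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(y) == 0:
            out.append(CorrelationResult(host, trait, "shoot_weight", None, None, n))
            continue
        r, p = stats.pearsonr(x, y)
        out.append(CorrelationResult(host, trait, "shoot_weight", float(r), float(p), n))
    return out


def phenotype_difference_matrix(
    means: pd.DataFrame,
    trait: str,
    host: str,
    exclude: tuple = (),
) -> DistanceMatrix:
    """Pairwise |mean difference| matrix between strains for one trait.

    ``exclude`` drops strains from the comparison (e.g. reference addenda,
    or strains unsequenced at the genetic locus being tested).
    """
    sub = means[means["host_species"] == host]
    sub = sub[~sub["strain"].isin(exclude)]
    sub = sub[sub[f"{trait}_mean"].notna()]
    if len(sub) < 3:
        raise GreenhouseError(
            f"need >= 3 strains with {trait} means for host {host!r}"
        )
    labels = list(sub["strain"])
    vals = sub[f"{trait}_mean"].to_numpy(dtype=float)
    return DistanceMatrix(labels, np.abs(vals[:, None] - vals[None, :]))


def mantel(
    genetic: DistanceMatrix,
    phenotypic: DistanceMatrix,
    perms: int = 10_000,
    seed: int | None = None,
) -> MantelResult:
    """Mantel test of association between two distance matrices.

    r = Pearson correlation over strictly-lower-triangle entries; the
    one-sided p permutes the rows and columns of the phenotypic matrix
    jointly, with the add-one correction.  Matrices must share labels (order
    is reconciled here).  Constant off-diagonal entries make r undefined and
    raise ``ValueError``.
    """
    if set(genetic.labels) != set(phenotypic.labels):
        only_g = sorted(set(genetic.labels) - set(phenotypic.labels))
        only_p = sorted(set(phenotypic.labels) - set(genetic.labels))
        raise ValueError(
            f"matrices must share labels (only genetic: {only_g}; "
            f"only phenotypic: {only_p})"
        )
    n = len(genetic.labels)
    if n < 4:
        raise ValueError("mantel requires >= 4 labels")
    phen = phenotypic.subset(genetic.labels)
    tri = np.tril_indices(n, k=-1)
    x = genetic.values[tri]
    if np.std(x) == 0 or np.std(phen.values[tri]) == 0:
        raise ValueError("constant off-diagonal entries: Mantel r undefined")
    xc = x - x.mean()
    xnorm = np.sqrt((xc**2).sum())

    def corr(mat: np.ndarray) -> float:
        y = mat[tri]
        yc = y - y.mean()
        return float((xc * yc).sum() / (xnorm * np.sqrt((yc**2).sum())))

    observed = corr(phen.values)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(perms):
        perm = rng.permutation(n)
        if corr(phen.values[np.ix_(perm, perm)]) >= observed:
            count += 1
    p = (count + 1) / (perms + 1)
    return MantelResult(observed, p, perms, seed, list(genetic.labels))
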