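"""Synthetic data generators for every pipeline stage.

Three generators emulate the statistical structure the analyses assume,
so the whole pipeline is testable without field or greenhouse data:

* :func:`simulate_association` — multi-host nodule sampling from skewed
  genotype pools (per-host Dirichlet preference profiles over a
  genus-partitioned genotype universe), emulating a four-host field survey.
* :func:`simulate_sequences` — two-cluster haplotype alignments (cluster =
  host genus) with optional shared-indel columns, emulating marker
  alignments whose between-cluster divergence exceeds the within-cluster
  divergence.
* :func:`simulate_greenhouse` — a blocked 2-host x 31-strain x 10-block
  single-inoculation experiment with gamma-distributed shoot weights on a
  log-scale linear predictor, negative-binomial nodule counts, log-normal
  per-nodule areas, control cross-contamination and host-specific missing
  nodule data.

Every generator is bit-reproducible under its seed and returns its ground
truth alongside the data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotyping import HaplotypeAlignment, SequenceRecord

_BASES = np.array([b"A", b"C", b"G", b"T"], dtype="S1")

#: study-shaped defaults: four hosts in two genera with the survey's
#: genotyped-nodule totals
DEFAULT_NODULES_PER_HOST = {"ACHE": 19, "ACST": 18, "LUAR": 21, "LUBI": 23}
DEFAULT_HOST_GENUS = {
    "ACHE": "Acmispon",
    "ACST": "Acmispon",
    "LUAR": "Lupinus",
    "LUBI": "Lupinus",
}


@dataclass
class AssociationSimParams:
    """Generative parameters for the field nodule-association table."""

    n_genotypes: int = 22
    nodules_per_host: dict = field(
        default_factory=lambda: dict(DEFAULT_NODULES_PER_HOST)
    )
    host_genus: dict = field(default_factory=lambda: dict(DEFAULT_HOST_GENUS))
    profiles: dict | None = None  # host -> explicit probability vector
    alpha: float = 0.2  # Dirichlet concentration for random profiles
    genus_bias: bool = True  # concentrate each host on its genus's genotypes
    cross_genus_rate: float = 0.02
    nodules_per_plant: int = 5
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_genotypes < 2:
            raise ValueError("n_genotypes must be >= 2")
        if any(n < 1 for n in self.nodules_per_host.values()):
            raise ValueError("every host needs >= 1 nodule")
        missing = set(self.nodules_per_host) - set(self.host_genus)
        if missing:
            raise ValueError(f"hosts without a genus: {sorted(missing)}")
        if self.profiles is not None:
            for host, prof in self.profiles.items():
                prof = np.asarray(prof, dtype=float)
                if prof.size != self.n_genotypes:
                    raise ValueError(f"profile for {host!r} has wrong length")
                if abs(prof.sum() - 1.0) > 1e-9:
                    raise ValueError(f"profile for {host!r} does not sum to 1")


@dataclass
class SequenceSimParams:
    """Generative parameters for clustered haplotype alignments."""

    n_clusters: int = 2
    genotypes_per_cluster: int = 11
    length: int = 756
    within_divergence: float = 6.0  # expected pairwise differences in-cluster
    between_divergence: float = 25.0  # expected differences across clusters
    indel_column_rate: float = 0.0
    locus: str = "NifD"
    ensure_unique: bool = True
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.length < 50:
            raise ValueError("sequence length must be >= 50")
        if self.between_divergence < self.within_divergence:
            raise ValueError(
                "between-cluster divergence must be >= within-cluster"
            )
        if self.between_divergence > self.length:
            raise ValueError("requested divergence exceeds sequence length")


@dataclass
class GreenhouseSimParams:
    """Generative parameters for the blocked inoculation experiment.

    Shoot weight ~ Gamma(shape, mean) with a log-scale linear predictor
    (host baseline + inoculation + conspecific-origin bonus + strain +
    host x strain + block).  Nodule count ~ negative binomial with a
    host x strain mean; total area = sum of log-normal per-nodule areas.
    """

    hosts: tuple = ("A_strigosus", "L_bicolor")
    host_genus: dict = field(
        default_factory=lambda: {"A_strigosus": "Acmispon", "L_bicolor": "Lupinus"}
    )
    n_strains: int = 31
    n_blocks: int = 10
    controls_per_block: int = 5
    # log-scale linear predictor pieces for shoot weight
    baseline_weight: dict = field(
        default_factory=lambda: {"A_strigosus": 0.05, "L_bicolor": 0.15}
    )
    inoculation_effect: dict = field(
        default_factory=lambda: {
            "A_strigosus": math.log(2.8),
            "L_bicolor": math.log(2.9),
        }
    )
    origin_effect: float = 0.25  # conspecific-genus origin bonus
    strain_sd: float = 0.15
    interaction_sd: dict = field(
        default_factory=lambda: {"A_strigosus": 0.5, "L_bicolor": 0.08}
    )
    block_sd: float = 0.1
    gamma_shape: float = 10.0
    # symbiont fitness components
    count_mean: dict = field(
        default_factory=lambda: {"A_strigosus": 15.0, "L_bicolor": 25.0}
    )
    count_strain_sd: float = 0.3
    count_dispersion: float = 5.0
    nodule_area_log_mean: float = math.log(0.015)
    nodule_area_log_sd: float = 0.4
    contamination_p: float = 0.07
    missing_nodule_p: dict = field(
        default_factory=lambda: {"A_strigosus": 0.0, "L_bicolor": 0.04}
    )
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("strain_sd", "block_sd", "count_strain_sd", "origin_effect"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if any(v < 0 for v in self.interaction_sd.values()):
            raise ValueError("interaction sds must be >= 0")
        if self.gamma_shape <= 0 or self.count_dispersion <= 0:
            raise ValueError("gamma shape and count dispersion must be > 0")
        if not 0 <= self.contamination_p <= 1:
            raise ValueError("contamination_p must be in [0, 1]")

    def strain_ids(self) -> list[str]:
        return [f"T{i + 1}" for i in range(self.n_strains)]

    def strain_origin(self) -> dict:
        """Strain -> (origin species, origin genus); first ~40% of strains
        originate from the *Acmispon* genus, the rest from *Lupinus*."""
        ids = self.strain_ids()
        n_a = max(1, round(self.n_strains * 12 / 31))
        out = {}
        for i, sid in enumerate(ids):
            if i < n_a:
                sp = "A_strigosus" if i < n_a // 2 else "A_heermannii"
                out[sid] = (sp, "Acmispon")
            else:
                j = i - n_a
                sp = "L_bicolor" if j < (self.n_strains - n_a) // 2 else "L_arboreus"
                out[sid] = (sp, "Lupinus")
        return out


def _genus_blocks(params: AssociationSimParams) -> dict:
    """Genus -> indices of its genotype block (universe split in half)."""
    genera = sorted(set(params.host_genus[h] for h in params.nodules_per_host))
    g = params.n_genotypes
    if len(genera) == 1:
        return {genera[0]: np.arange(g)}
    half = g // 2
    return {genera[0]: np.arange(half), genera[1]: np.arange(half, g)}


def simulate_association(params: AssociationSimParams):
    """Draw a nodule-isolate table from per-host preference profiles.

    Each host's nodules are drawn multinomially from its profile (explicit,
    or Dirichlet-random with concentration ``alpha``; with ``genus_bias``
    the profile places 1 - cross_genus_rate of its mass on the host's own
    genus block).  Returns ``(table, truth)`` where truth carries the
    generating profiles and genotype labels.
    """
    rng = np.random.default_rng(params.seed)
    g = params.n_genotypes
    genotypes = [f"G{i + 1}" for i in range(g)]
    hosts = sorted(params.nodules_per_host)
    blocks = _genus_blocks(params)

    profiles = {}
    for host in hosts:
        if params.profiles is not None:
            prof = np.asarray(params.profiles[host], dtype=float)
        elif params.genus_bias and len(blocks) > 1:
            own = blocks[params.host_genus[host]]
            other = np.setdiff1d(np.arange(g), own)
            prof = np.zeros(g)
            prof[own] = rng.dirichlet(np.full(own.size, params.alpha)) * (
                1.0 - params.cross_genus_rate
            )
            prof[other] = (
                rng.dirichlet(np.full(other.size, params.alpha))
                * params.cross_genus_rate
            )
        else:
            prof = rng.dirichlet(np.full(g, params.alpha))
        profiles[host] = prof

    rows = []
    iso = 0
    for host in hosts:
        n = params.nodules_per_host[host]
        counts = rng.multinomial(n, profiles[host])
        drawn = np.repeat(np.arange(g), counts)
        rng.shuffle(drawn)
        for k, gi in enumerate(drawn):
            iso += 1
            plant = k // params.nodules_per_plant + 1
            rows.append(
                {
                    "isolate_id": f"ISO{iso:04d}",
                    "host_species": host,
                    "host_genus": params.host_genus[host],
                    "plant_id": f"{host}_P{plant}",
                    "nodule_id": f"{host}_P{plant}_N{k % params.nodules_per_plant + 1}",
                    "genotype_ITS": genotypes[gi],
                    "genotype_NifD": genotypes[gi],
                }
            )
    table = pd.DataFrame(rows)
    truth = {
        "profiles": {h: profiles[h].tolist() for h in hosts},
        "genotypes": genotypes,
        "seed": params.seed,
    }
    return table, truth


def _mutate(seq: np.ndarray, n_sites: int, rng) -> np.ndarray:
    out = seq.copy()
    if n_sites <= 0:
        return out
    sites = rng.choice(seq.size, size=min(n_sites, seq.size), replace=False)
    for s in sites:
        choices = _BASES[_BASES != out[s]]
        out[s] = rng.choice(choices)
    return out


def simulate_sequences(params: SequenceSimParams):
    """Generate a clustered haplotype alignment.

    A random root sequence spawns per-cluster consensus sequences at the
    between-cluster divergence; each genotype mutates its consensus at the
    within-cluster divergence (expected pairwise in-cluster difference =
    ``within_divergence``).  Gap columns, shared within a random cluster,
    are injected at ``indel_column_rate``.  Returns ``(alignment, truth)``
    with truth mapping genotype id -> cluster label.
    """
    rng = np.random.default_rng(params.seed)
    root = rng.choice(_BASES, size=params.length)
    records: list[SequenceRecord] = []
    cluster_of: dict[str, str] = {}
    seen: set[bytes] = set()
    gid = 0
    for ci in range(params.n_clusters):
        consensus = _mutate(
            root, rng.poisson(params.between_divergence / 2.0), rng
        )
        for _ in range(params.genotypes_per_cluster):
            gid += 1
            name = f"G{gid}"
            for _attempt in range(100):
                m = rng.poisson(params.within_divergence / 2.0)
                if params.ensure_unique and params.within_divergence > 0:
                    m = max(m, 1)
                seq = _mutate(consensus, m, rng)
                key = seq.tobytes()
                if not (params.ensure_unique and key in seen):
                    break
            seen.add(key)
            records.append(
                SequenceRecord(name, params.locus, key.decode())
            )
            cluster_of[name] = f"C{ci + 1}"

    if params.indel_column_rate > 0:
        mat = np.array(
            [np.frombuffer(r.residues.encode(), dtype="S1") for r in records]
        )
        gap_cols = rng.random(params.length) < params.indel_column_rate
        clusters = np.array([int(cluster_of[r.isolate_id][1:]) for r in records])
        for col in np.where(gap_cols)[0]:
            target = rng.integers(1, params.n_clusters + 1)
            mat[clusters == target, col] = b"-"
        records = [
            SequenceRecord(r.isolate_id, r.locus, mat[i].tobytes().decode())
            for i, r in enumerate(records)
        ]

    aln = HaplotypeAlignment(params.locus, records)
    truth = {"cluster_of": cluster_of, "seed": params.seed}
    return aln, truth


def isolate_alignment_from_table(
    table: pd.DataFrame, genotype_aln: HaplotypeAlignment, locus: str
) -> HaplotypeAlignment:
    """Expand a per-genotype alignment to one record per isolate.

    Each isolate receives the sequence of its genotype label at ``locus``;
    isolates without a label at the locus are omitted.
    """
    seq_of = {r.isolate_id: r.residues for r in genotype_aln.records}
    col = f"genotype_{locus}"
    records = []
    for _, row in table.iterrows():
        label = row[col]
        if pd.isna(label) or label == "":
            continue
        if label not in seq_of:
            raise KeyError(f"genotype label {label!r} absent from alignment")
        records.append(SequenceRecord(row["isolate_id"], locus, seq_of[label]))
    return HaplotypeAlignment(locus, records)


def simulate_greenhouse(params: GreenhouseSimParams):
    """Generate a blocked single-inoculation experiment table.

    Returns ``(table, truth)``; truth carries every drawn effect (strain,
    interaction, block, count effects) plus contamination and missingness
    outcomes, so parameter-recovery tests can compare against it.
    """
    rng = np.random.default_rng(params.seed)
    strains = params.strain_ids()
    origin = params.strain_origin()

    strain_eff = {s: rng.normal(0.0, params.strain_sd) for s in strains}
    inter_eff = {
        (h, s): rng.normal(0.0, params.interaction_sd[h])
        for h in params.hosts
        for s in strains
    }
    block_eff = {
        (h, b): rng.normal(0.0, params.block_sd)
        for h in params.hosts
        for b in range(1, params.n_blocks + 1)
    }
    count_eff = {
        (h, s): rng.normal(0.0, params.count_strain_sd)
        for h in params.hosts
        for s in strains
    }

    def gamma_draw(mean: float) -> float:
        return float(rng.gamma(params.gamma_shape, mean / params.gamma_shape))

    def nodule_draws(host: str, strain: str) -> tuple[int, float]:
        m = params.count_mean[host] * math.exp(count_eff[(host, strain)])
        k = params.count_dispersion
        count = int(rng.negative_binomial(k, k / (k + m)))
        if count == 0:
            return 0, 0.0
        areas = rng.lognormal(
            params.nodule_area_log_mean, params.nodule_area_log_sd, size=count
        )
        return count, float(areas.sum())

    rows = []
    pid = 0
    contaminated_controls = []
    for host in params.hosts:
        genus = params.host_genus[host]
        for b in range(1, params.n_blocks + 1):
            for s in strains:
                pid += 1
                log_mean = (
                    math.log(params.baseline_weight[host])
                    + params.inoculation_effect[host]
                    + (params.origin_effect if origin[s][1] == genus else 0.0)
                    + strain_eff[s]
                    + inter_eff[(host, s)]
                    + block_eff[(host, b)]
                )
                w = gamma_draw(math.exp(log_mean))
                count, area = nodule_draws(host, s)
                if rng.random() < params.missing_nodule_p.get(host, 0.0):
                    count_val, area_val = np.nan, np.nan
                else:
                    count_val, area_val = count, area
                rows.append(
                    {
                        "plant_id": f"P{pid:04d}",
                        "host_species": host,
                        "block": b,
                        "treatment": s,
                        "origin_species": origin[s][0],
                        "origin_genus": origin[s][1],
                        "shoot_dry_weight_g": w,
                        "nodule_count": count_val,
                        "total_nodule_area_cm2": area_val,
                    }
                )
            for _c in range(params.controls_per_block):
                pid += 1
                log_mean = math.log(params.baseline_weight[host]) + block_eff[
                    (host, b)
                ]
                w = gamma_draw(math.exp(log_mean))
                if rng.random() < params.contamination_p:
                    count = 1 + int(rng.poisson(1.5))
                    area = float(
                        rng.lognormal(
                            params.nodule_area_log_mean - 1.0,
                            params.nodule_area_log_sd,
                            size=count,
                        ).sum()
                    )
                    contaminated_controls.append(f"P{pid:04d}")
                else:
                    count, area = 0, 0.0
                rows.append(
                    {
                        "plant_id": f"P{pid:04d}",
                        "host_species": host,
                        "block": b,
                        "treatment": "CONTROL",
                        "origin_species": np.nan,
                        "origin_genus": np.nan,
                        "shoot_dry_weight_g": w,
                        "nodule_count": count,
                        "total_nodule_area_cm2": area,
                    }
                )
    table = pd.DataFrame(rows)
    truth = {
        "strain_effects": strain_eff,
        "interaction_effects": {f"{h}|{s}": v for (h, s), v in inter_eff.items()},
        "block_effects": {f"{h}|{b}": v for (h, b), v in block_eff.items()},
        "count_effects": {f"{h}|{s}": v for (h, s), v in count_eff.items()},
        "strain_origin": {s: origin[s] for s in strains},
        "contaminated_controls": contaminated_controls,
        "seed": params.seed,
    }
    return table, truth
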