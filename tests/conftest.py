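from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from rhizospec.genotyping import (
    DistanceMatrix,
    HaplotypeAlignment,
    SequenceRecord,
    pairwise_differences,
)


def make_alignment(pairs, locus="NifD") -> HaplotypeAlignment:
    return HaplotypeAlignment(
        locus, [SequenceRecord(i, locus, s) for i, s in pairs]
    )


def random_sequences(rng, n: int, length: int = 120) -> list[str]:
    return [
        "".join(rng.choice(list("ACGT"), size=length)) for _ in range(n)
    ]


def random_distance_matrix(rng, n: int, length: int = 120) -> DistanceMatrix:
    """Distances between iid random sequences (exchangeable null)."""
    aln = make_alignment(
        [(f"i{k}", s) for k, s in enumerate(random_sequences(rng, n, length))]
    )
    return pairwise_differences(aln)


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def nodule_table() -> pd.DataFrame:
    """Tiny two-genus nodule table with one nodule missing a NifD label."""
    rows = []
    layout = {
        ("ACST", "Acmispon"): ["G1", "G1", "G1", "G2"],
        ("LUBI", "Lupinus"): ["G2", "G3", "G3", None],
    }
    iso = 0
    for (host, genus), labels in layout.items():
        for k, g in enumerate(labels):
            iso += 1
            rows.append(
                {
                    "isolate_id": f"I{iso:02d}",
                    "host_species": host,
                    "host_genus": genus,
                    "plant_id": f"{host}_P1",
                    "nodule_id": f"{host}_N{k + 1}",
                    "genotype_ITS": g or "G9",
                    "genotype_NifD": g,
                }
            )
    return pd.DataFrame(rows)


def greenhouse_frame(
    hosts=("HA",),
    strains=("T1", "T2", "T3"),
    blocks=(1, 2),
    control_weight=0.1,
    strain_weights=None,
    nodule_counts=None,
    total_areas=None,
) -> pd.DataFrame:
    """Deterministic greenhouse table builder for hand-computable cases."""
    rows = []
    pid = 0
    for host in hosts:
        for b in blocks:
            for s in strains:
                pid += 1
                w = (
                    strain_weights[(host, s, b)]
                    if strain_weights
                    else control_weight
                )
                nc = nodule_counts[(host, s, b)] if nodule_counts else 5
                ta = total_areas[(host, s, b)] if total_areas else 0.05
                rows.append(
                    {
                        "plant_id": f"P{pid:03d}",
                        "host_species": host,
                        "block": b,
                        "treatment": s,
                        "origin_species": "A_strigosus",
                        "origin_genus": "Acmispon",
                        "shoot_dry_weight_g": w,
                        "nodule_count": nc,
                        "total_nodule_area_cm2": ta,
                    }
                )
            for c in range(2):
                pid += 1
                rows.append(
                    {
                        "plant_id": f"P{pid:03d}",
                        "host_species": host,
                        "block": b,
                        "treatment": "CONTROL",
                        "origin_species": np.nan,
                        "origin_genus": np.nan,
                        "shoot_dry_weight_g": control_weight,
                        "nodule_count": 0,
                        "total_nodule_area_cm2": 0.0,
                    }
                )
    return pd.DataFrame(rows)
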