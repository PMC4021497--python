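"""End-to-end pipelines chaining the analysis stages, with run manifests.

Two entry points mirror the two halves of the study design:

* :func:`run_field_pipeline` — alignments + nodule table -> genotypes,
  link-strength matrix, per-host PDIs with simulated null, diversity /
  Phi_st / AMOVA reports.
* :func:`run_greenhouse_pipeline` — greenhouse table (+ optional genetic
  distance matrices) -> contamination report, response / effect PDIs,
  genotype means, fitness-feedback correlations, Mantel tests.

Every stochastic stage gets an explicit sub-seed derived from the run seed;
the manifest records versions, seeds, parameters and input checksums so any
number in any report is regenerable from manifest + inputs alone.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, association, genotyping, greenhouse, popgen
from .io import (
    read_greenhouse_table,
    read_nodule_table,
    sha256_of,
    write_json,
    write_link_matrix,
)


class PipelineError(ValueError):
    """Configuration or cross-reference failure (e.g. orphan isolate ids)."""


def _stage_seeds(seed: int | None, names: list[str]) -> dict[str, int | None]:
    if seed is None:
        return {n: None for n in names}
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(names))
    return {
        n: int(c.generate_state(1)[0] % (2**31)) for n, c in zip(names, children)
    }


def _denominator(config: dict):
    d = config.get("denominator", association.PARTNERS_MINUS_1)
    if d in (association.PARTNERS_MINUS_1, "partners", None):
        return association.PARTNERS_MINUS_1
    return float(d)


def run_field_pipeline(config: dict) -> dict:
    """Run the field-survey analysis; returns the manifest dict.

    Config keys: ``nodule_table`` (TSV path), ``alignments`` (mapping locus
    -> aligned FASTA of isolates; optional per locus — a locus without an
    alignment uses the table's genotype column), ``locus`` (primary locus
    for the PDI analysis, default NifD), ``reps``, ``perms``, ``seed``,
    ``null_nodules_per_host`` (default 20), ``denominator``, ``out``.
    """
    out = Path(config["out"])
    out.mkdir(parents=True, exist_ok=True)
    table = read_nodule_table(config["nodule_table"])
    locus = config.get("locus", "NifD")
    reps = int(config.get("reps", 1000))
    perms = int(config.get("perms", 10_000))
    nodules_per_host = int(config.get("null_nodules_per_host", 20))
    denominator = _denominator(config)
    seeds = _stage_seeds(config.get("seed"), ["null", "phist", "amova"])

    inputs = {"nodule_table": sha256_of(config["nodule_table"])}
    filters: dict = {}
    alignments = config.get("alignments", {}) or {}
    isolate_aln = None
    for loc, fasta in sorted(alignments.items()):
        inputs[f"alignment_{loc}"] = sha256_of(fasta)
        aln = genotyping.read_alignment(fasta, loc)
        orphans = sorted(set(aln.isolate_ids) - set(table["isolate_id"]))
        if orphans:
            raise PipelineError(
                f"{loc}: FASTA isolates absent from the nodule table: {orphans}"
            )
        stripped, n_removed = genotyping.strip_indel_columns(aln)
        filters[f"{loc}_indel_columns_removed"] = n_removed
        assignment = genotyping.call_genotypes(stripped)
        assignment.to_frame().to_csv(
            out / f"genotypes_{loc}.tsv", sep="\t", index=False
        )
        col = f"genotype_{loc}"
        table[col] = table["isolate_id"].map(assignment.labels)
        dist = genotyping.pairwise_differences(stripped)
        dist.write_tsv(out / f"distances_{loc}.tsv")
        if loc == locus:
            isolate_aln = stripped

    col = f"genotype_{locus}"
    if col not in table.columns or table[col].isna().all():
        raise PipelineError(
            f"no genotype labels available at locus {locus!r} "
            "(missing genotype column and no alignment supplied)"
        )
    n_before = len(table)
    n_genotyped = int(table[col].notna().sum())
    filters[f"{locus}_nodules_without_genotype"] = n_before - n_genotyped

    matrix = association.build_link_matrix(table, locus)
    write_link_matrix(
        matrix, out / "link_counts.tsv", out / "link_proportions.tsv"
    )
    host_pdis = association.pdi_per_host(matrix, denominator)
    labels, freqs = association.genotype_frequencies(table, locus)
    null = association.simulate_null_joint_pdi(
        freqs,
        n_hosts=len(matrix.hosts),
        nodules_per_host=nodules_per_host,
        reps=reps,
        seed=seeds["null"],
        denominator=denominator,
    )
    comparisons = {
        host: dataclasses.asdict(association.compare_pdi_to_null(res, null))
        for host, res in host_pdis.items()
    }
    observed_joint = association.joint_pdi(matrix, denominator)
    pdi_report = {
        "locus": locus,
        "denominator": denominator,
        "per_host": {
            h: dataclasses.asdict(r) for h, r in host_pdis.items()
        },
        "joint_observed": observed_joint,
        "null": null.to_dict(),
        "comparisons": comparisons,
        "genotype_frequencies": dict(zip(labels, map(float, freqs))),
    }
    write_json(pdi_report, out / "pdi_report.json")

    popgen_done = False
    if isolate_aln is not None:
        keep = [i for i in isolate_aln.isolate_ids]
        dist = genotyping.pairwise_differences(isolate_aln).subset(keep)
        sub = table[table["isolate_id"].isin(keep)]
        part = popgen.PopulationPartition.from_table(sub)
        long = popgen.diversity_long(dist, part, perms=perms, seed=seeds["phist"])
        long.to_csv(out / "diversity_long.tsv", sep="\t", index=False)
        square = popgen.diversity_matrix(
            dist, part, perms=perms, seed=seeds["phist"]
        )
        square.to_csv(out / "diversity_matrix.tsv", sep="\t", index_label="")
        amova = popgen.amova_two_level(
            dist, part, perms=perms, seed=seeds["amova"]
        )
        write_json(amova.to_dict(), out / "amova.json")
        popgen_done = True

    manifest = {
        "pipeline": "field",
        "version": __version__,
        "config": {
            k: (str(v) if isinstance(v, Path) else v) for k, v in config.items()
        },
        "stage_seeds": seeds,
        "inputs": inputs,
        "filters": filters,
        "n_isolates": n_before,
        "n_genotyped": n_genotyped,
        "popgen_computed": popgen_done,
    }
    write_json(manifest, out / "manifest.json")
    return manifest


def run_greenhouse_pipeline(config: dict) -> dict:
    """Run the inoculation-experiment analysis; returns the manifest dict.

    Config keys: ``greenhouse_table`` (TSV path), ``perms``, ``seed``,
    ``denominator``, ``out``, optional ``genetic_distances`` (mapping locus
    -> distance-matrix TSV over strain ids), optional ``mantel_exclude``
    (strains dropped from Mantel matrices, e.g. reference addenda), and
    optional ``feedback_ln_hosts`` (hosts whose feedback correlations
    ln-transform the nodule variables).
    """
    out = Path(config["out"])
    out.mkdir(parents=True, exist_ok=True)
    table = read_greenhouse_table(config["greenhouse_table"])
    perms = int(config.get("perms", 10_000))
    denominator = _denominator(config)
    seeds = _stage_seeds(config.get("seed"), ["mantel"])
    inputs = {"greenhouse_table": sha256_of(config["greenhouse_table"])}

    filtered, report = greenhouse.filter_contaminated(table)
    contamination = {
        "n_controls": report.n_controls,
        "n_excluded": report.n_excluded,
        "by_host_block": report.by_host_block().to_dict(orient="records"),
        "excluded_plants": sorted(report.excluded["plant_id"]),
    }
    write_json(contamination, out / "contamination.json")

    hosts = sorted(filtered["host_species"].unique())
    response = {
        h: greenhouse.response_pdi(filtered, h, denominator).to_dict()
        for h in hosts
    }
    write_json(response, out / "response_pdi.json")
    effect = {
        h: {
            trait: greenhouse.effect_pdi(filtered, h, trait, "default", denominator).to_dict()
            for trait in ("nodule_count", "total_nodule_area")
        }
        for h in hosts
    }
    write_json(effect, out / "effect_pdi.json")

    means = greenhouse.genotype_means(filtered)
    means.to_csv(out / "genotype_means.tsv", sep="\t", index=False)

    ln_hosts = set(config.get("feedback_ln_hosts", []))
    feedback = {
        h: [
            dataclasses.asdict(c)
            for c in greenhouse.feedback_correlations(
                means,
                h,
                transform_map=(
                    {"nodule_count": "ln", "total_nodule_area": "ln"}
                    if h in ln_hosts
                    else None
                ),
            )
        ]
        for h in hosts
    }
    write_json(feedback, out / "feedback_correlations.json")

    mantel_report = {}
    genetic = config.get("genetic_distances", {}) or {}
    exclude = tuple(config.get("mantel_exclude", ()))
    for loc, path in sorted(genetic.items()):
        inputs[f"genetic_distances_{loc}"] = sha256_of(path)
        gdist = genotyping.DistanceMatrix.read_tsv(path)
        for host in hosts:
            for trait in ("shoot_weight", "mean_nodule_area"):
                try:
                    pmat = greenhouse.phenotype_difference_matrix(
                        means, trait, host, exclude=exclude
                    )
                except greenhouse.GreenhouseError:
                    continue
                common = [l for l in gdist.labels if l in pmat.labels]
                if len(common) < 4:
                    continue
                res = greenhouse.mantel(
                    gdist.subset(common),
                    pmat.subset(common),
                    perms=perms,
                    seed=seeds["mantel"],
                )
                mantel_report[f"{loc}|{host}|{trait}"] = {
                    "r": res.r,
                    "p_value": res.p_value,
                    "perms": res.perms,
                    "n_strains": len(common),
                }
    if mantel_report:
        write_json(mantel_report, out / "mantel.json")

    manifest = {
        "pipeline": "greenhouse",
        "version": __version__,
        "config": {
            k: (str(v) if isinstance(v, Path) else v) for k, v in config.items()
        },
        "stage_seeds": seeds,
        "inputs": inputs,
        "filters": {
            "controls_total": report.n_controls,
            "controls_excluded": report.n_excluded,
            "plants_in": len(table),
            "plants_out": len(filtered),
        },
        "mantel_tests": sorted(mantel_report),
    }
    write_json(manifest, out / "manifest.json")
    return manifest
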