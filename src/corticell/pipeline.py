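"""End-to-end orchestration: read inputs, run every stage, write results.

Stage order: normative charts (healthy) -> deviation scoring (all subjects)
-> cell-type maps + mean-CTh association -> coupling + permutation/dispersion
test (patients) -> PCA/Ward/gap subtyping -> polygenic validation.  Outputs
are deterministic for identical (inputs, seed): every random stage draws
from a child of one seed sequence, and JSON is written with sorted keys.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import cellmaps, coupling as coupling_mod, genetics, io as cio, normative, subtypes
from .config import RunConfig
from .containers import GROUP_HEALTHY, GROUP_PATIENT
from .errors import InputError

log = logging.getLogger(__name__)


def _stage_seeds(seed: int) -> dict[str, int]:
    """Independent per-stage seeds derived from the run seed."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(3)
    names = ("permutation", "gap", "bootstrap")
    return {n: int(c.generate_state(1)[0] % (2**31)) for n, c in zip(names, children)}


def _json_ready(obj):
    if isinstance(obj, dict):
        return {str(k): _json_ready(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_ready(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return _json_ready(obj.to_dict(orient="index"))
    if isinstance(obj, pd.Series):
        return _json_ready(obj.to_dict())
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if not np.isfinite(f) else f
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    return obj


def _write_json(payload: dict, path: Path) -> None:
    path.write_text(json.dumps(_json_ready(payload), indent=2, sort_keys=True) + "\n")


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict[str, Path]:
    """Run every stage and write the result bundle into ``outdir``.

    Returns a mapping of logical output names to paths: deviations and
    coupling TSVs, subtype assignments TSV, test-results and validation
    JSONs, and the run log.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("corticell")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    seeds = _stage_seeds(config.seed)
    outputs: dict[str, Path] = {"log": log_path}

    def stage(name):
        def wrap(fn):
            t0 = time.perf_counter()
            try:
                result = fn()
            except Exception as exc:
                log.error("stage %s failed: %s", name, exc)
                raise type(exc)(f"stage {name}: {exc}") from exc
            log.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
            return result
        return wrap

    try:
        # ---- inputs -------------------------------------------------------
        def load():
            cohort = cio.read_cohort(config.cohort_path)
            expression = cio.read_expression(config.expression_path)
            cio.check_regions(expression, cohort)
            expression = expression.loc[cohort.regions]
            gene_sets = cio.read_gmt(config.gmt_path)
            bundle = cio.read_genotypes(
                config.genotype_path, config.annotation_path, config.weights_path,
                config.gene_spans_path, config.relatedness_path,
            )
            log.info(
                "inputs: %d subjects x %d regions, %d genes, %d sets, %d SNPs, seed %d",
                cohort.n, len(cohort.regions), expression.shape[1],
                len(gene_sets.names), bundle.dosages.shape[1], config.seed,
            )
            return cohort, expression, gene_sets, bundle

        cohort, expression, gene_sets, bundle = stage("read-inputs")(load)

        healthy = cohort.subset(GROUP_HEALTHY)
        patients = cohort.subset(GROUP_PATIENT)
        if healthy.n == 0 or patients.n == 0:
            raise InputError("cohort must contain both healthy and patient subjects")

        # ---- normative ----------------------------------------------------
        model = stage("normative-fit")(
            lambda: normative.fit_normative_model(healthy, config.quantiles)
        )
        deviations = stage("deviation-scores")(
            lambda: normative.deviation_scores(model, cohort)
        )
        dev_path = outdir / "deviations.tsv"
        deviations.to_long_frame(cohort.demographics["group"]).to_csv(
            dev_path, sep="\t", index=False
        )
        outputs["deviations"] = dev_path

        # ---- transcriptomic maps -----------------------------------------
        cell_map = stage("cell-maps")(lambda: cellmaps.build_cell_map(expression, gene_sets))
        map_path = outdir / "cell_map.tsv"
        cell_map.rename_axis("region").to_csv(map_path, sep="\t")
        outputs["cell_map"] = map_path
        mean_cth = healthy.cth.mean(axis=0)
        map_assoc = stage("map-vs-cth")(
            lambda: cellmaps.map_vs_mean_cth(cell_map, mean_cth)
        )

        # ---- coupling + dispersion test ----------------------------------
        patient_dz = deviations.delta_z.loc[patients.subjects]
        coupling = stage("coupling")(
            lambda: coupling_mod.compute_coupling(patient_dz, cell_map)
        )
        coupling_path = outdir / "coupling.tsv"
        coupling.rename_axis("subject_id").to_csv(coupling_path, sep="\t")
        outputs["coupling"] = coupling_path
        disp = stage("dispersion-test")(
            lambda: coupling_mod.dispersion_test(
                coupling, patient_dz, cell_map,
                n_perm=config.n_permutations, seed=seeds["permutation"],
                fdr_alpha=config.fdr_alpha,
            )
        )

        tests_path = outdir / "test_results.json"
        _write_json(
            {
                "map_vs_mean_cth": map_assoc,
                "dispersion": {
                    "per_cell_type": disp.table,
                    "n_permutations": disp.n_permutations,
                    "significant_cell_types": disp.significant_cell_types,
                },
                "normative": {
                    "training_n": model.training_n,
                    "healthy_coverage": normative.coverage(model, healthy),
                },
                "seed": config.seed,
            },
            tests_path,
        )
        outputs["test_results"] = tests_path

        # ---- subtyping ----------------------------------------------------
        solution = stage("subtyping")(
            lambda: subtypes.solve_subtypes(
                coupling.dropna(), n_pcs=config.n_pcs, k_max=config.k_max,
                gap_B=config.gap_B, seed=seeds["gap"],
            )
        )
        sub_path = outdir / "subtypes.tsv"
        solution.to_frame().rename_axis("subject_id").to_csv(sub_path, sep="\t")
        outputs["subtypes"] = sub_path
        gap_path = outdir / "gap_curve.tsv"
        pd.DataFrame(
            {"gap": solution.gap.gap, "se": solution.gap.se, "log_wk": solution.gap.log_wk}
        ).to_csv(gap_path, sep="\t")
        outputs["gap_curve"] = gap_path
        profile = stage("subtype-profiles")(
            lambda: subtypes.subtype_profiles(
                coupling.loc[solution.hard_labels.index],
                patient_dz.loc[solution.hard_labels.index],
                solution.hard_labels, config.fdr_alpha,
            )
        )

        # ---- polygenic validation ----------------------------------------
        validation = stage("validation")(
            lambda: genetics.validate_subtypes(
                patient_dz, solution, bundle, gene_sets, profile,
                sex=cohort.demographics["sex"],
                boundary_kb=config.genic_boundary_kb,
                fdr_alpha=config.fdr_alpha,
            )
        )
        val_path = outdir / "validation.json"
        _write_json(
            {
                "chosen_k": solution.chosen_k,
                "explained_variance": list(solution.explained_variance),
                "subtype_sizes": profile.sizes,
                "subtype_proportions": profile.proportions,
                "profiles": profile.stats.to_dict(orient="records"),
                "mean_wholebrain_deviation": profile.mean_wholebrain_deviation,
                "primary": validation.primary.to_dict(orient="records"),
                "specificity_grid": validation.grid.to_dict(orient="records"),
                "membership_sweep": validation.sweep.to_dict(orient="records"),
                "skipped_subtypes": validation.skipped,
                "seed": config.seed,
            },
            val_path,
        )
        outputs["validation"] = val_path
        log.info("pipeline complete: %d outputs in %s", len(outputs), outdir)
        return outputs
    finally:
        root.removeHandler(handler)
        handler.close()
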