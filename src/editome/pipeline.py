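"""End-to-end orchestration: simulate -> pileup -> call -> hyper -> stats ->
diff -> recode, with a machine-readable run manifest.

A run is driven by a single :class:`RunConfig`; every effective parameter is
echoed into the manifest together with filter accounting (reads used and
rejected by reason), per-stage site counts, and md5 checksums of every file
written.  Identical configs and seeds reproduce identical manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import differential, hyper, recoding, stats
from .calling import KmerIndex, call_sites, realignment_check
from .pileup import build_pileup, mask_dna_variants
from .reference import GenomeSpec, ReferenceBundle, build_reference
from .simulate import (
    ReadSimParams,
    ScenarioTruth,
    plant_truth,
    random_scenario,
    simulate_dna_reads,
    simulate_rna_reads,
)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """All parameters of a pipeline run, serialisable to YAML."""

    seed: int = 7
    simulate: bool = True
    # paths used when simulate is False
    fasta: str | None = None
    gtf: str | None = None
    repeats_bed: str | None = None
    genome: dict = field(default_factory=dict)
    scenario: dict = field(default_factory=dict)
    reads: dict = field(default_factory=dict)
    pileup: dict = field(default_factory=dict)
    calling: dict = field(default_factory=dict)
    hyper: dict = field(default_factory=dict)
    differential: dict = field(default_factory=dict)
    conditions: list[str] | None = None  # None = all scenario conditions
    replicates: int | None = None  # None = scenario replicate count
    tissue: str | None = None  # None = first scenario tissue

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def _md5(path: str | Path) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def evaluate_calls(
    calls: pd.DataFrame,
    truth: ScenarioTruth,
    condition: str,
    tissue: str | None = None,
) -> dict:
    """Precision/recall and level fidelity of a call set against the planted
    truth.

    Recall is measured against planted normal edits active in the tissue;
    precision counts a call as true if it matches any planted edit or
    hyper-cluster position.  Level error is summarised at true-positive
    sites as mean |estimated - true| alongside the mean of twice the
    binomial standard error at each site's A+G depth.
    """
    edits = truth.edits
    if tissue is not None and len(edits):
        active = edits[
            edits["tissues"].fillna("").apply(lambda s: tissue in str(s).split(","))
        ]
    else:
        active = edits
    true_keys = {
        (r["chrom"], int(r["pos"]), r["strand"]): float(r[f"level_{condition}"])
        for _, r in active.iterrows()
    }
    hyper_keys = {
        (r["chrom"], int(r["pos"]), r["strand"]) for _, r in truth.hyper_sites.iterrows()
    }
    called_keys = {}
    for _, r in calls.iterrows():
        called_keys[(r["chrom"], int(r["pos"]), r["strand"])] = r

    tp = [k for k in called_keys if k in true_keys]
    tp_hyper_only = [k for k in called_keys if k not in true_keys and k in hyper_keys]
    fp = [k for k in called_keys if k not in true_keys and k not in hyper_keys]
    fn = [k for k in true_keys if k not in called_keys]

    abs_err = []
    two_se = []
    for k in tp:
        r = called_keys[k]
        true_level = true_keys[k]
        ag = int(r["n_edited"]) + int(r["n_ref"])
        abs_err.append(abs(float(r["level"]) - true_level))
        two_se.append(2.0 * np.sqrt(max(true_level * (1 - true_level), 1e-12) / max(ag, 1)))
    n_called = len(called_keys)
    return {
        "n_called": n_called,
        "n_true": len(true_keys),
        "tp": len(tp),
        "tp_hyper_only": len(tp_hyper_only),
        "fp": len(fp),
        "fn": len(fn),
        "precision": (len(tp) + len(tp_hyper_only)) / n_called if n_called else float("nan"),
        "recall": len(tp) / len(true_keys) if true_keys else float("nan"),
        "level_mae": float(np.mean(abs_err)) if abs_err else float("nan"),
        "level_mean_2se": float(np.mean(two_se)) if two_se else float("nan"),
    }


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Execute the full pipeline and return the run manifest (also written
    to ``manifest.json``)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": dataclasses.asdict(config),
        "stages": {},
        "outputs": {},
    }

    def record(name: str, path: str | Path):
        manifest["outputs"][str(Path(path).name)] = _md5(path)

    # ---- reference -----------------------------------------------------
    try:
        if config.simulate:
            spec = GenomeSpec(**{**config.genome, "seed": config.genome.get("seed", config.seed)})
            ref = build_reference(spec)
            paths = ref.save(outdir)
            for p in paths.values():
                record("reference", p)
        else:
            if not config.fasta or not config.gtf:
                raise ValueError("fasta and gtf paths required when simulate is false")
            ref = ReferenceBundle.from_files(config.fasta, config.gtf, config.repeats_bed)
    except Exception as e:  # noqa: BLE001
        raise StageError("reference", e) from e

    # ---- scenario / truth ---------------------------------------------
    try:
        scen_args = {**config.scenario}
        scen_args.setdefault("seed", config.seed)
        scenario = random_scenario(ref, **scen_args)
        truth = plant_truth(ref, scenario)
        for p in truth.write_tsv(outdir).values():
            record("truth", p)
        manifest["stages"]["scenario"] = {
            "n_edit_sites": int(len(truth.edits)),
            "n_snps": int(len(truth.snps)),
            "n_hyper_clusters": len(truth.hyper_clusters),
            "rejected_collisions": truth.n_rejected_collisions,
        }
    except Exception as e:  # noqa: BLE001
        raise StageError("scenario", e) from e

    conditions = list(config.conditions or truth.conditions)
    n_reps = config.replicates or truth.replicates_per_condition
    tissue = config.tissue or (truth.tissues[0] if truth.tissues else None)
    params = ReadSimParams(**{**config.reads, "seed": config.reads.get("seed", config.seed)})

    # ---- DNA: simulate, pileup, SNP mask -------------------------------
    try:
        dna = simulate_dna_reads(ref, truth, params, outdir)
        record("dna", dna.dna_sam)
        dna_pile = build_pileup(dna.dna_sam, ref, source="DNA", **config.pileup)
        snp_mask = mask_dna_variants(dna_pile, ref)
        manifest["stages"]["dna"] = {
            "reads": dna.counts,
            "reads_used": dna_pile.n_reads_used,
            "reads_rejected": dna_pile.n_reads_rejected,
            "positions_masked": snp_mask.n_masked(),
        }
    except Exception as e:  # noqa: BLE001
        raise StageError("dna", e) from e

    kidx = KmerIndex(ref, k=int(config.calling.get("realign_k", 16)))
    tidx = hyper.TransformedIndex(ref, k=int(config.hyper.get("k", 16)))

    per_library: dict[tuple[str, int], pd.DataFrame] = {}
    merged_tables: dict[str, pd.DataFrame] = {}
    for cond in conditions:
        for rep in range(1, n_reps + 1):
            stage = f"rna.{cond}.r{rep}"
            try:
                lib = simulate_rna_reads(ref, truth, params, cond, rep, tissue, outdir)
                record(stage, lib.rna_sam)
                record(stage, lib.unmapped_sam)
                pile = build_pileup(lib.rna_sam, ref, source="RNA", **config.pileup)
                call_args = {
                    k: v
                    for k, v in config.calling.items()
                    if k in ("min_rna_depth", "min_edited_reads", "error_rate", "fdr", "noise_alt_threshold")
                }
                res = call_sites(pile, snp_mask, ref, **call_args)
                res = realignment_check(
                    res,
                    lib.rna_sam,
                    ref,
                    margin_frac=config.calling.get("realign_margin", 0.95),
                    min_unique_support=config.calling.get("min_edited_reads", 3),
                    index=kidx,
                )
                hits = hyper.transform_and_realign(
                    lib.unmapped_sam,
                    ref,
                    max_other_mm=int(config.hyper.get("max_other_mm", 1)),
                    index=tidx,
                )
                rhes = hyper.cluster_filter(
                    hits,
                    ref,
                    min_edits_per_read=int(config.hyper.get("min_edits_per_read", 5)),
                    min_edit_fraction=float(config.hyper.get("min_edit_fraction", 0.05)),
                    read_length=params.read_length,
                )
                unified, overlap = hyper.merge_modes(res, rhes)
                site_path = outdir / f"sites.{cond}.r{rep}.tsv"
                unified.to_csv(site_path, sep="\t", index=False)
                record(stage, site_path)
                per_library[(cond, rep)] = res
                merged_tables.setdefault(cond, unified)
                eval_norm = evaluate_calls(res, truth, cond, tissue)
                manifest["stages"][stage] = {
                    "reads": lib.counts,
                    "reads_used": pile.n_reads_used,
                    "reads_rejected": pile.n_reads_rejected,
                    "sites_normal": int(len(res)),
                    "sites_hyper": int(len(rhes)),
                    "overlap": overlap,
                    "evaluation": eval_norm,
                }
            except StageError:
                raise
            except Exception as e:  # noqa: BLE001
                raise StageError(stage, e) from e

    # ---- stats on the first condition's unified table ------------------
    try:
        first_cond = conditions[0]
        unified = merged_tables[first_cond]
        annotated, fractions = stats.annotate_features(unified, ref)
        annotated.to_csv(outdir / "sites.annotated.tsv", sep="\t", index=False)
        record("stats", outdir / "sites.annotated.tsv")
        motif = stats.motif_matrix(unified[unified["edit_type"] == "A-to-G"], ref)
        motif.to_csv(outdir / "motif_matrix.tsv", sep="\t")
        record("stats", outdir / "motif_matrix.tsv")
        a2g = unified[unified["edit_type"] == "A-to-G"]
        mapped_bases = manifest["stages"][f"rna.{first_cond}.r1"]["reads"]["mapped_bases"]
        manifest["stages"]["stats"] = {
            "region_fractions": fractions,
            "overall_editing_level": stats.overall_editing_level(a2g) if len(a2g) else None,
            "sites_per_mb": stats.sites_per_mb(len(a2g), mapped_bases),
            "a2g_fraction": float((unified["edit_type"] == "A-to-G").mean()) if len(unified) else None,
        }
    except Exception as e:  # noqa: BLE001
        raise StageError("stats", e) from e

    # ---- differential (first vs last condition) ------------------------
    if len(conditions) >= 2 and n_reps >= 1:
        try:
            ga, gb = conditions[0], conditions[-1]
            counts = differential.counts_from_site_tables(per_library, ga, gb)
            dd = config.differential
            results = differential.test_differential(
                counts,
                fdr=float(dd.get("fdr", 0.05)),
                diffs=tuple(dd.get("diffs", (0.10, 0.20))),
                min_coverage=int(dd.get("min_coverage", 10)),
            )
            results.to_csv(outdir / f"differential.{ga}_vs_{gb}.tsv", sep="\t", index=False)
            record("differential", outdir / f"differential.{ga}_vs_{gb}.tsv")
            manifest["stages"]["differential"] = {
                "comparison": f"{ga}_vs_{gb}",
                "n_tested": int(len(results)),
                "classes": differential.classify_sites(results, fdr=float(dd.get("fdr", 0.05))),
            }
        except Exception as e:  # noqa: BLE001
            raise StageError("differential", e) from e

    # ---- recoding ------------------------------------------------------
    try:
        events = recoding.events_for_sites(merged_tables[conditions[0]], ref)
        events.to_csv(outdir / "recoding_events.tsv", sep="\t", index=False)
        record("recoding", outdir / "recoding_events.tsv")
        mat = recoding.substitution_matrix(events)
        mat.to_csv(outdir / "substitution_matrix.tsv", sep="\t")
        record("recoding", outdir / "substitution_matrix.tsv")
        manifest["stages"]["recoding"] = {
            "n_events": int(len(events)),
            "n_synonymous": int(events["synonymous"].sum()) if len(events) else 0,
        }
    except Exception as e:  # noqa: BLE001
        raise StageError("recoding", e) from e

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest
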