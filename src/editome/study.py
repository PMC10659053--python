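"""Reference validation study: the default planted-truth benchmark.

Runs the complete detection chain — simulation, pileups, SNP masking,
calling, support realignment, hyper-editing recovery and mode merging — on
the default synthetic scenario (200 kb genome, 1,000 planted edits at levels
0.1-0.9, 50x RNA / 30x DNA coverage, 0.1% base error) and evaluates every
stage against the planted truth.  This is the package's own end-to-end
benchmark; all thresholds are the module defaults.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from . import stats
from .calling import call_sites, realignment_check
from .hyper import cluster_filter, merge_modes, transform_and_realign
from .pileup import build_pileup, mask_dna_variants
from .pipeline import evaluate_calls
from .reference import GenomeSpec, build_reference
from .simulate import (
    ReadSimParams,
    plant_truth,
    random_scenario,
    simulate_dna_reads,
    simulate_rna_reads,
)


def run_default_study(
    seed: int = 7,
    workdir: str | Path = "study",
    condition: str = "T27",
    tissue: str = "brain",
) -> dict:
    """Execute the default benchmark and return all intermediate objects.

    The returned dict holds the reference, truth tables, called site tables
    per mode, the merged table with overlap counts, and the truth-based
    evaluation summary.
    """
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)

    ref = build_reference(GenomeSpec(seed=seed))
    scenario = random_scenario(ref, seed=seed, tissues=(tissue,))
    truth = plant_truth(ref, scenario)
    params = ReadSimParams(seed=seed)

    rna = simulate_rna_reads(ref, truth, params, condition, 1, tissue, workdir)
    dna = simulate_dna_reads(ref, truth, params, workdir)

    dna_pile = build_pileup(dna.dna_sam, ref, source="DNA")
    snp_mask = mask_dna_variants(dna_pile, ref)
    rna_pile = build_pileup(rna.rna_sam, ref, source="RNA")

    called = call_sites(rna_pile, snp_mask, ref)
    called = realignment_check(called, rna.rna_sam, ref)

    hits = transform_and_realign(rna.unmapped_sam, ref)
    rhes = cluster_filter(hits, ref, read_length=params.read_length)
    unified, overlap = merge_modes(called, rhes)

    evaluation = evaluate_calls(called, truth, condition, tissue)

    a2g = unified[unified["edit_type"] == "A-to-G"]
    summary = {
        "n_normal": int(len(called)),
        "n_hyper": int(len(rhes)),
        "overlap": overlap,
        "a2g_fraction": float((called["edit_type"] == "A-to-G").mean()) if len(called) else float("nan"),
        "overall_editing_level": stats.overall_editing_level(a2g) if len(a2g) else float("nan"),
        "sites_per_mb": stats.sites_per_mb(len(a2g), rna.counts["mapped_bases"]),
    }

    # hyper-cluster recovery: planted cluster positions found by the hyper
    # route (hyper-only or common)
    hyper_truth = {
        (r["chrom"], int(r["pos"]), r["strand"]) for _, r in truth.hyper_sites.iterrows()
    }
    hyper_found = {
        (r["chrom"], int(r["pos"]), r["strand"])
        for _, r in unified[unified["mode"].isin(["hyper", "common"])].iterrows()
    }
    summary["hyper_recovery"] = (
        len(hyper_truth & hyper_found) / len(hyper_truth) if hyper_truth else float("nan")
    )

    # planted SNP positions must never surface as edit calls
    snp_positions = {(r["chrom"], int(r["pos"])) for _, r in truth.snps.iterrows()}
    called_positions = {(r["chrom"], int(r["pos"])) for _, r in called.iterrows()}
    summary["snp_positions_called"] = len(snp_positions & called_positions)

    return {
        "ref": ref,
        "truth": truth,
        "params": params,
        "rna": rna,
        "dna": dna,
        "rna_pileup": rna_pile,
        "snp_mask": snp_mask,
        "called": called,
        "rhes": rhes,
        "unified": unified,
        "overlap": overlap,
        "evaluation": evaluation,
        "summary": summary,
    }
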