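"""End-to-end orchestration of the seven tandem-simulation steps.

1. align input reads; 2. build the input model; 3. simulate tandem reads;
4. align the tandem reads with the same aligner and parameters;
5. convert tandem alignments to labeled training records; 6. train one
model per category; 7. rewrite the MAPQ of every input alignment.

The builtin toy aligner is used by default; an external aligner can be
plugged in as a shell command template with {reads}/{reads1}/{reads2},
{ref} and {out} placeholders, provided it emits the ZT feature tag.
"""

from __future__ import annotations

import json
import random
import shlex
import subprocess
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Optional, Tuple, Union

from . import evaluation, input_model as im, mapq_model as mm, tandem_sim as ts
from .core import Category, Genome, read_sam, write_fastq
from .fixture_aligner import ToyAligner


@dataclass
class PipelineConfig:
    seed: int = 0
    reservoir_size: int = im.DEFAULT_RESERVOIR_CAPACITY
    sim_factor: float = im.DEFAULT_SIM_FACTOR
    sim_function: str = im.DEFAULT_SIM_FUNCTION
    minimums: Optional[Dict[Category, int]] = None
    trees: int = mm.DEFAULT_TREES
    max_depth: Optional[int] = None
    min_leaf: int = mm.DEFAULT_MIN_LEAF
    q_cap: float = mm.DEFAULT_Q_CAP
    correct_threshold: int = evaluation.DEFAULT_CORRECT_THRESHOLD
    n_policy: str = "redraw"
    max_redraws: int = 1000


class PipelineError(RuntimeError):
    pass


def _run_external(cmd_template: str, subs: Dict[str, str]) -> None:
    cmd = cmd_template.format(**subs)
    proc = subprocess.run(
        shlex.split(cmd), capture_output=True, text=True
    )
    if proc.returncode != 0:
        raise PipelineError(
            f"external aligner failed (exit {proc.returncode}): {cmd}\n{proc.stderr}"
        )


def run_tandem_pipeline(
    reads: Union[str, Path, Tuple],
    genome: Union[Genome, str, Path],
    outdir: Union[str, Path],
    paired: bool = False,
    aligner: Union[ToyAligner, str, None] = None,
    conc_range: Optional[Tuple[int, int]] = None,
    config: PipelineConfig = PipelineConfig(),
    evaluate: bool = False,
    input_sam: Union[str, Path, None] = None,
) -> Dict[str, object]:
    """Run steps 1-7 and return the run report (also written as JSON).

    ``reads`` is a FASTQ path, or a (R1, R2) pair of paths when
    ``paired``.  ``aligner`` is a ToyAligner (default: one is built from
    the genome), or a shell command template for an external aligner, in
    which case ``genome`` must be a FASTA path.  All randomness derives
    from ``config.seed``; identical inputs and seed give byte-identical
    outputs.

    ``input_sam`` may point to an existing step-1 SAM, in which case the
    input alignment step is skipped and trials repeat from the input
    modeling step onward (the protocol used to measure prediction
    variability across seeds).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = config
    if isinstance(genome, (str, Path)):
        genome_path: Optional[Path] = Path(genome)
        genome_obj = Genome.from_fasta(genome_path)
    else:
        genome_path = None
        genome_obj = genome
    external = isinstance(aligner, str)
    if external and genome_path is None:
        raise PipelineError("an external aligner needs the genome as a FASTA path")
    if aligner is None:
        aligner = ToyAligner(genome_obj)
    if paired and conc_range is None:
        raise PipelineError("paired mode requires an explicit conc_range")

    # -- step 1: align input reads --------------------------------------
    precomputed = input_sam
    input_sam = Path(input_sam) if precomputed is not None else outdir / "input.sam"
    align_cmd_log = []

    def align_unp(fastq, out):
        if external:
            subs = {"reads": str(fastq), "ref": str(genome_path), "out": str(out)}
            align_cmd_log.append(aligner.format(**subs))
            _run_external(aligner, subs)
        else:
            aligner.align_fastq(fastq, out)
            align_cmd_log.append(f"builtin:unpaired:{fastq}")

    def align_pair(fq1, fq2, out):
        if external:
            subs = {
                "reads1": str(fq1), "reads2": str(fq2),
                "ref": str(genome_path), "out": str(out),
            }
            align_cmd_log.append(aligner.format(**subs))
            _run_external(aligner, subs)
        else:
            aligner.align_fastq_pair(fq1, fq2, out, conc_range)
            align_cmd_log.append(f"builtin:paired:{fq1}:{fq2}")

    if precomputed is None:
        if paired:
            align_pair(reads[0], reads[1], input_sam)
        else:
            align_unp(reads, input_sam)

    # -- step 2: input model --------------------------------------------
    _, input_records = read_sam(input_sam)
    model = im.build_input_model(
        input_records, capacity=cfg.reservoir_size, seed=cfg.seed
    )
    im.save_input_model(model, outdir / "input_model.jsonl")

    # -- step 3: simulate tandem reads ----------------------------------
    targets = model.targets(cfg.sim_factor, cfg.sim_function, cfg.minimums)
    sim_rng = random.Random((cfg.seed + 10) % 2**31)
    unp_reads = []
    for cat in (Category.UNP, Category.BAD_END):
        if targets[cat] and model.reservoirs[cat].items:
            for r in ts.simulate_category(
                model, genome_obj, cat, targets[cat], sim_rng,
                cfg.n_policy, cfg.max_redraws,
            ):
                unp_reads.append((r.name, r.seq, r.quals))
    pair_reads = []
    for cat in (Category.CONC, Category.DISC):
        if targets[cat] and model.reservoirs[cat].items:
            for r1, r2 in ts.simulate_category(
                model, genome_obj, cat, targets[cat], sim_rng,
                cfg.n_policy, cfg.max_redraws,
            ):
                pair_reads.append(
                    ((r1.name, r1.seq, r1.quals), (r2.name, r2.seq, r2.quals))
                )

    # -- step 4: align tandem reads (same aligner, same parameters) -----
    tandem_sams = []
    if unp_reads:
        fq = outdir / "tandem_unp.fastq"
        write_fastq(unp_reads, fq)
        sam = outdir / "tandem_unp.sam"
        align_unp(fq, sam)
        tandem_sams.append(sam)
    if pair_reads:
        fq1 = outdir / "tandem_1.fastq"
        fq2 = outdir / "tandem_2.fastq"
        write_fastq([p[0] for p in pair_reads], fq1)
        write_fastq([p[1] for p in pair_reads], fq2)
        sam = outdir / "tandem_pair.sam"
        align_pair(fq1, fq2, sam)
        tandem_sams.append(sam)

    # -- steps 5-6: training records and per-category models ------------
    training: Dict[Category, list] = {c: [] for c in Category}
    for sam in tandem_sams:
        for cat, recs in mm.build_training_records(sam, cfg.correct_threshold).items():
            training[cat].extend(recs)
    models: Dict[Category, Optional[mm.CategoryModel]] = {}
    for i, cat in enumerate(Category):
        models[cat] = mm.train(
            training[cat],
            trees=cfg.trees,
            max_depth=cfg.max_depth,
            min_leaf=cfg.min_leaf,
            seed=(cfg.seed + 20 + i) % 2**31,
            q_cap=cfg.q_cap,
        )

    # -- step 7: predict and rewrite MAPQ --------------------------------
    final_sam = outdir / "final.sam"
    rewrite_report = mm.rewrite_mapq(
        input_sam, models, final_sam, cfg.correct_threshold
    )

    report: Dict[str, object] = {
        "seed": cfg.seed,
        "input_counts": {c.value: model.counts[c] for c in Category},
        "tandem_targets": {c.value: targets[c] for c in Category},
        "training_sizes": {c.value: len(training[c]) for c in Category},
        "training_frac_correct": {
            c.value: (
                sum(1 for f in training[c] if f.label) / len(training[c])
                if training[c] else None
            )
            for c in Category
        },
        "feature_importances": {
            c.value: mm.feature_importances(models[c]) if models[c] else None
            for c in Category
        },
        "rewrite": rewrite_report,
        "aligner_invocations": align_cmd_log,
        "files": {
            "input_sam": str(input_sam),
            "final_sam": str(final_sam),
            "input_model": str(outdir / "input_model.jsonl"),
        },
    }
    if evaluate:
        series = evaluation.series_from_sams(input_sam, final_sam)
        report["evaluation"] = {
            "n": len(series),
            "rca_pct": evaluation.compare(series.correctness, series.Q, series.Qp)["rca_pct"],
            "rce_pct": evaluation.rce(series.correctness, series.P, series.Pp) * 100.0,
        }
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    return report
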