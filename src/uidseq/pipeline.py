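"""End-to-end pipeline: simulate -> collapse -> saturate -> metrics.

A single :class:`PipelineConfig` drives every stage; the one seed in its
:class:`~uidseq.simulate.SimConfig` makes the full run reproducible
bit-for-bit.  The report bundle is a nested dict (written as JSON with
sorted keys) plus per-stage TSVs when an output directory is given.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
import pandas as pd

from . import io as uio
from .consensus import collapse_reads, family_statistics
from .metrics import base_counts, error_rate, track_mutations
from .saturation import fit_sqrt_model, predict_unique, subsample_curve
from .simulate import SimConfig, amplify, reference_sequence, sample_fragments, sequence_reads, truth_recovery

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass(frozen=True)
class PipelineConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    collapse_mode: str = "directional"
    min_family_size: int = 3
    run_saturation: bool = True
    saturation_step: int | None = None          # default: reads_sequenced // 5
    predict_at: tuple[int, ...] = ()            # extra raw-read allocations
    min_unique_depth: int = 20
    min_raw_depth: int = 200
    max_position_error: float = 0.10
    detection_threshold: int = 1


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> dict:
    """Execute all stages in dependency order and return the report dict."""
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": {"sim": dataclasses.asdict(config.sim),
                               "collapse_mode": config.collapse_mode,
                               "min_family_size": config.min_family_size}}

    stage = "simulate"
    try:
        fragments = sample_fragments(config.sim)
        pool = amplify(fragments, config.sim)
        reads, truth = sequence_reads(pool, config.sim)
        report["simulate"] = {
            "n_fragments": len(fragments),
            "pool_size": len(pool),
            "n_reads": len(reads),
        }
        if out is not None:
            uio.write_reads_tsv(reads, out / "reads.tsv")
            uio.write_truth_tsv(truth, out / "truth.tsv")

        stage = "collapse"
        families, consensus = collapse_reads(
            reads, mode=config.collapse_mode, min_family_size=config.min_family_size
        )
        stats = family_statistics(families, len(reads))
        recovery = truth_recovery(families, truth)
        report["collapse"] = {
            **dataclasses.asdict(stats),
            "truth_recovery_rate": recovery.rate,
        }
        if out is not None:
            uio.write_consensus_tsv(consensus, out / "consensus.tsv")

        stage = "saturate"
        if config.run_saturation and len(reads):
            step = config.saturation_step or max(1, len(reads) // 5)
            curve = subsample_curve(
                reads, step=step, seed=config.sim.seed,
                mode=config.collapse_mode, min_family_size=config.min_family_size,
            )
            model = fit_sqrt_model(curve)
            predictions = {
                str(t): predict_unique(model, t)
                for t in (*config.predict_at, 2 * len(reads))
            }
            report["saturate"] = {
                "totals": list(curve.totals),
                "uniques": list(curve.uniques),
                "sqrt_a": model.a,
                "sqrt_b": model.b,
                "rmse": model.rmse,
                "predicted_unique": predictions,
            }
            if out is not None:
                pd.DataFrame({"total": curve.totals, "unique": curve.uniques}).to_csv(
                    out / "saturation.tsv", sep="\t", index=False
                )

        stage = "metrics"
        ref = reference_sequence(config.sim)
        table = base_counts(consensus, config.sim.panel_regions, ref, raw_reads=reads)
        err = error_rate(
            table,
            min_unique_depth=config.min_unique_depth,
            min_raw_depth=config.min_raw_depth,
            max_position_error=config.max_position_error,
        )
        panel_bp = sum(e - s for s, e in config.sim.panel_regions)
        mean_unique_cov = float(table["unique_depth"].mean())
        report["metrics"] = {
            "panel_bp": panel_bp,
            "mean_unique_coverage": mean_unique_cov,
            "mean_raw_coverage": float(table["raw_depth"].mean()),
            "consensus_error_rate": err.sample_rate,
            "n_error_positions": err.n_retained,
            "mean_detection_limit": float(
                (1.0 / table.loc[table["unique_depth"] > 0, "unique_depth"]).mean()
            ),
        }
        if out is not None:
            table.to_csv(out / "base_counts.tsv", sep="\t", index=False)

        stage = "track"
        if config.sim.spiked_mutations:
            mutations = [
                (config.sim.chrom, m.pos, m.ref, m.alt)
                for m in config.sim.spiked_mutations
            ]
            tracked = track_mutations(
                table, mutations, detection_threshold=config.detection_threshold
            )
            report["track"] = tracked.to_dict(orient="records")
            if out is not None:
                tracked.to_csv(out / "tracked.tsv", sep="\t", index=False)
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    if out is not None:
        uio.write_json_report(report, out / "report.json")
    return report
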