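"""End-to-end analysis pipeline: design → data → EM fit → sensitivity report.

``run_pipeline`` chains the stages behind a single seeded configuration and
writes a reproducible artifact bundle:

* ``observations.csv``   — the ingested or simulated dataset
* ``fitted_network.yaml``— EM-fitted network (bn serialization format)
* ``loglik_trace.csv``   — per-iteration log-likelihood
* ``sensitivity.csv``    — ranking-table layout (per-state variations, abs
  mean, mutual information, rank)
* ``conditionals.csv``   — P(target=adverse | each predictor state)
* ``report.md``          — human-readable summary
* ``run.log``            — stage-by-stage audit trail (parameters and SHA-256
  checksums of every input and output)

Reruns with the same configuration are byte-identical, so the persisted run
log carries no wall-clock timestamps; timestamped progress goes to the
console logger instead.  A stage failure aborts with the stage name and
removes partial outputs.
"""
from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .em import EMConfig, EMResult, fit_em
from .network import (
    BayesianNetwork,
    default_study_network,
    load_network,
    marginals,
    save_network,
)
from .scheme import ObservationDataset, default_scheme, read_observations, write_observations
from .sensitivity import SensitivityReport, analyze
from .simulate import DEFAULT_N, default_ground_truth, sample_dataset

__all__ = ["PipelineError", "RunConfig", "run_pipeline", "render_report"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failure, tagged with the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    With ``data`` unset, a dataset of ``n_simulate`` records is simulated
    from the packaged ground-truth network; otherwise the CSV at ``data`` is
    ingested.  ``structure`` may name a serialized network/structure file;
    by default the study DAG is used.
    """

    outdir: Path = Path("hrubnet-run")
    data: Path | None = None
    structure: Path | None = None
    n_simulate: int = DEFAULT_N
    missing_rate: float = 0.0
    seed: int = 0
    em: EMConfig = field(default_factory=EMConfig)
    target: str | None = None
    adverse_state: str | None = None
    mi_base: float = 2.0


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def render_report(net: BayesianNetwork, report: SensitivityReport) -> str:
    """Markdown summary: baseline, ranked drivers, per-state conditionals."""
    lines = [
        "# Behavioral-safety sensitivity report",
        "",
        f"Target: {report.target} = {report.adverse_state!r}",
        f"Baseline P({report.target}={report.adverse_state}) = {report.baseline:.4f}",
        "",
        "## Variable ranking",
        "",
        "| rank | variable | variations (%) | abs mean (%) | mutual info | MI rank |",
        "|---|---|---|---|---|---|",
    ]
    for e in sorted(report.entries, key=lambda e: e.rank or 0):
        var_cells = ", ".join(f"{v:+.2f}" for v in e.variations)
        lines.append(
            f"| {e.rank} | {e.variable} | {var_cells} | "
            f"{e.abs_mean_variation:.2f} | {e.mutual_information:.5f} | {e.mi_rank} |"
        )
    if report.spearman is not None:
        lines += [
            "",
            f"Spearman agreement of the two rankings: {report.spearman:.3f}",
        ]
    lines += ["", "## Conditional probabilities", ""]
    lines.append(f"| variable | state | P({report.target}={report.adverse_state}) |")
    lines.append("|---|---|---|")
    for e in report.entries:
        for s, v in zip(e.states, e.variations):
            p = report.baseline * (1.0 + v / 100.0)
            lines.append(f"| {e.variable} | {s} | {p:.4f} |")
    lines.append("")
    return "\n".join(lines)


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute the full chain and return the paths of the written bundle."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    audit: list[str] = []

    def emit(path: Path, writer) -> Path:
        writer(path)
        written.append(path)
        audit.append(f"wrote {path.name} sha256={_sha256(path)}")
        return path

    try:
        scheme = default_scheme()
        audit.append(f"seed = {config.seed}")

        # --- structure -----------------------------------------------------
        if config.structure is not None:
            stage = "structure"
            spath = Path(config.structure)
            if not spath.exists():
                raise PipelineError(stage, f"structure file not found: {spath}")
            loaded = load_network(spath)
            structure, scheme = loaded.structure, loaded.scheme
            audit.append(f"structure from {spath} sha256={_sha256(spath)}")
        else:
            structure = default_study_network()
            audit.append("structure = default study DAG")

        # --- ingest / simulate --------------------------------------------
        if config.data is not None:
            stage = "ingest"
            dpath = Path(config.data)
            if not dpath.exists():
                raise PipelineError(stage, f"observation CSV not found: {dpath}")
            try:
                dataset = read_observations(dpath, scheme)
            except Exception as exc:
                raise PipelineError(stage, str(exc)) from exc
            audit.append(
                f"ingested {len(dataset)} records from {dpath} sha256={_sha256(dpath)}"
            )
        else:
            stage = "simulate"
            try:
                truth = default_ground_truth()
                dataset = sample_dataset(
                    truth,
                    n=config.n_simulate,
                    missing_rate=config.missing_rate,
                    seed=config.seed,
                )
            except Exception as exc:
                raise PipelineError(stage, str(exc)) from exc
            audit.append(
                f"simulated n={config.n_simulate} missing_rate={config.missing_rate} "
                f"seed={config.seed}"
            )
        logger.info("dataset ready: %d records", len(dataset))
        obs_path = emit(
            outdir / "observations.csv", lambda p: write_observations(dataset, p)
        )

        # --- fit -----------------------------------------------------------
        stage = "fit"
        try:
            result: EMResult = fit_em(structure, scheme, dataset, config.em)
        except Exception as exc:
            raise PipelineError(stage, str(exc)) from exc
        audit.append(
            f"EM: iterations={result.iterations} converged={result.converged} "
            f"final_loglik={result.loglik_trace[-1]!r} em_config={config.em}"
        )
        logger.info("EM converged=%s after %d iterations", result.converged, result.iterations)
        net_path = emit(
            outdir / "fitted_network.yaml", lambda p: save_network(result.network, p)
        )
        trace_path = emit(
            outdir / "loglik_trace.csv",
            lambda p: pd.DataFrame(
                {
                    "iteration": range(1, len(result.loglik_trace) + 1),
                    "loglik": result.loglik_trace,
                }
            ).to_csv(p, index=False),
        )

        # --- analyze -------------------------------------------------------
        stage = "analyze"
        try:
            report = analyze(
                result.network,
                target=config.target,
                adverse_state=config.adverse_state,
                mi_base=config.mi_base,
            )
        except Exception as exc:
            raise PipelineError(stage, str(exc)) from exc
        audit.append(
            f"sensitivity: target={report.target} adverse={report.adverse_state} "
            f"baseline={report.baseline!r} mi_base={config.mi_base}"
        )
        sens_path = emit(
            outdir / "sensitivity.csv",
            lambda p: report.to_dataframe().to_csv(p, index=False),
        )
        cond_path = emit(
            outdir / "conditionals.csv",
            lambda p: report.conditionals_dataframe().to_csv(p, index=False),
        )

        # --- report --------------------------------------------------------
        stage = "report"
        text = render_report(result.network, report)
        report_path = emit(outdir / "report.md", lambda p: p.write_text(text))
        log_path = outdir / "run.log"
        log_path.write_text("\n".join(audit) + "\n")
        return {
            "observations": obs_path,
            "fitted_network": net_path,
            "loglik_trace": trace_path,
            "sensitivity": sens_path,
            "conditionals": cond_path,
            "report": report_path,
            "run_log": log_path,
        }
    except PipelineError:
        for p in written:
            p.unlink(missing_ok=True)
        raise
    except Exception as exc:  # pragma: no cover - safety net
        for p in written:
            p.unlink(missing_ok=True)
        raise PipelineError(stage, str(exc)) from exc
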