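"""Performance sheets and the end-to-end benchmark orchestrator.

A *sheet* is the shareable record of one model on one test set: overall
AUROC/AUPRC, the same metrics per overlap and topology stratum, pointers to
exported curve coordinates (so later models can be compared without
retraining), training time and its energy/carbon estimate, plus the config
fingerprint and the seed registry.  Sheets are written as machine-readable
JSON and a human-readable markdown table; rendering is idempotent (same
inputs, byte-identical output).

``run_benchmark`` drives the whole pipeline — simulate, curate, sample,
split, featurize, train, evaluate, report — from a single master seed, and
writes a checksum manifest of every artifact for auditability.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .core import NEGATIVE, POSITIVE, EvidenceRecord, PPIBenchError
from . import evaluation, features, goldstandard, models, splits, synthetic

STAGES = (
    "simulate",
    "curate",
    "sample",
    "split",
    "featurize",
    "train",
    "evaluate",
    "report",
)


class PipelineStageError(PPIBenchError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class BenchmarkConfig:
    """One self-contained benchmark run on a synthetic universe."""

    synthetic: synthetic.SyntheticConfig = field(default_factory=synthetic.SyntheticConfig)
    split: splits.SplitConfig = field(default_factory=splits.SplitConfig)
    negative_scheme: str = "balanced"
    negative_ratio: float = 1.0
    model_families: tuple[str, ...] = ("logistic", "gradient_boosting", "kmer_logistic")
    feature_groups: tuple[str, ...] = (features.FG, features.EXPR, features.SEQ)
    seed: int = 0

    def stage_seeds(self) -> dict[str, int]:
        """Fan the master seed out to one deterministic seed per stage."""
        state = np.random.SeedSequence(self.seed).generate_state(len(STAGES))
        return {stage: int(s) % (2**31 - 1) for stage, s in zip(STAGES, state)}

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["synthetic"]["seq_length_range"] = list(self.synthetic.seq_length_range)
        d["model_families"] = list(self.model_families)
        d["feature_groups"] = list(self.feature_groups)
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "BenchmarkConfig":
        d = json.loads(text)
        d["synthetic"] = synthetic.SyntheticConfig.from_json(json.dumps(d["synthetic"]))
        d["split"] = splits.SplitConfig(**d["split"])
        d["model_families"] = tuple(d["model_families"])
        d["feature_groups"] = tuple(d["feature_groups"])
        return cls(**d)

    def fingerprint(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


def _not_evaluable_cell(value) -> str:
    return f"{value:.4f}" if isinstance(value, float) else "not-evaluable"


def render_sheet(
    eval_report: evaluation.EvalReport,
    fit_result: Optional[models.FitResult],
    metadata: dict,
    outdir: str | Path,
) -> dict[str, Path]:
    """Write ``<model>_<dataset>_sheet.{json,md}``; returns the path map.

    ``metadata`` should carry at least ``model`` and ``dataset`` names; any
    extra keys (seed registry, config fingerprint, curve CSV paths) are
    embedded verbatim so every number on the sheet can be recomputed from
    the referenced artifacts.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    model_name = metadata.get("model", "model")
    dataset = metadata.get("dataset", "dataset")
    stem = f"{model_name}_{dataset}_sheet"

    payload = {
        "model": model_name,
        "dataset": dataset,
        "metrics": eval_report.to_dict(),
        "training": {
            "wall_time_s": fit_result.wall_time_s if fit_result else None,
            "family": fit_result.spec.family if fit_result else None,
            "schema_fingerprint": fit_result.schema_fingerprint if fit_result else None,
        },
        "metadata": {k: v for k, v in metadata.items() if k not in ("model", "dataset")},
    }
    json_path = outdir / f"{stem}.json"
    json_path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=str))

    lines = [
        f"# Performance sheet: {model_name} on {dataset}",
        "",
        f"- AUROC: {eval_report.auroc:.4f}",
        f"- AUPRC: {eval_report.auprc:.4f}",
        f"- n = {eval_report.n}, positive fraction = {eval_report.positive_fraction:.4f}",
    ]
    if fit_result is not None:
        lines.append(f"- training wall time: {fit_result.wall_time_s:.2f} s")
    if "energy_kWh" in eval_report.resources:
        lines.append(
            f"- training energy: {eval_report.resources['energy_kWh']:.6f} kWh, "
            f"carbon: {eval_report.resources['carbon_gCO2e']:.4f} gCO2e"
        )
    for title, table in (
        ("protein-level overlap", eval_report.by_overlap),
        ("network topology", eval_report.by_topology),
    ):
        if not table:
            continue
        lines += ["", f"## Breakdown by {title}", ""]
        lines.append("| stratum | n | % positive | AUROC | AUPRC |")
        lines.append("|---|---|---|---|---|")
        for stratum, entry in table.items():
            lines.append(
                f"| {stratum} | {entry['n']} | {100 * entry['positive_fraction']:.1f} "
                f"| {_not_evaluable_cell(entry['auroc'])} "
                f"| {_not_evaluable_cell(entry['auprc'])} |"
            )
    md_path = outdir / f"{stem}.md"
    md_path.write_text("\n".join(lines) + "\n")
    return {"json": json_path, "markdown": md_path}


def plot_curves(eval_report: evaluation.EvalReport, path: str | Path, title: str = "") -> None:
    """Side-by-side ROC and PR plots for one report."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax_roc, ax_pr) = plt.subplots(1, 2, figsize=(9, 4))
    ax_roc.plot(eval_report.roc.x, eval_report.roc.y)
    ax_roc.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
    ax_roc.set(xlabel="FPR", ylabel="TPR", title=f"ROC (AUROC={eval_report.auroc:.3f})")
    ax_pr.plot(eval_report.pr.x, eval_report.pr.y)
    ax_pr.axhline(eval_report.positive_fraction, ls="--", c="grey", lw=0.8)
    ax_pr.set(
        xlabel="recall", ylabel="precision", title=f"PR (AUPRC={eval_report.auprc:.3f})"
    )
    fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    digest.update(path.read_bytes())
    return digest.hexdigest()


def write_manifest(outdir: Path) -> Path:
    """Checksum every artifact under ``outdir`` into ``manifest.json``."""
    entries = {
        str(p.relative_to(outdir)): _sha256(p)
        for p in sorted(outdir.rglob("*"))
        if p.is_file() and p.name != "manifest.json"
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(entries, indent=2, sort_keys=True))
    return path


def verify_manifest(outdir: str | Path) -> list[str]:
    """Return the artifacts whose checksum no longer matches the manifest."""
    outdir = Path(outdir)
    entries = json.loads((outdir / "manifest.json").read_text())
    mismatches = []
    for rel, expected in entries.items():
        target = outdir / rel
        if not target.is_file() or _sha256(target) != expected:
            mismatches.append(rel)
    return mismatches


def _log(stage: str, message: str) -> None:
    print(f"[ppibench:{stage}] {message}", file=sys.stderr)


def _select_feature_columns(table: pd.DataFrame, family: str) -> pd.DataFrame:
    """FG families must not see sequence columns; kmer_logistic selects its own."""
    if family == "kmer_logistic":
        return table
    drop = [c for c in table.columns if c in features.SEQ_COLUMNS or c == "miss_seq"]
    return table.drop(columns=drop)


def run_benchmark(config: BenchmarkConfig, outdir: str | Path) -> dict:
    """Execute the full pipeline; returns a summary dict of key results.

    Any stage failure is re-raised as :class:`PipelineStageError` naming the
    stage.  Rerunning with the same config and seed reproduces every
    artifact checksum.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = config.stage_seeds()
    (outdir / "config.json").write_text(config.to_json())
    summary: dict = {"seeds": seeds, "config_fingerprint": config.fingerprint()}

    def run_stage(stage, fn):
        _log(stage, "starting")
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 - rewrap with stage context
            raise PipelineStageError(stage, exc) from exc

    def _simulate():
        cfg = dataclasses.replace(config.synthetic, seed=seeds["simulate"])
        universe = synthetic.generate_universe(cfg)
        synthetic.write_universe(universe, outdir / "universe")
        return universe

    universe = run_stage("simulate", _simulate)

    def _curate():
        evidence = [
            EvidenceRecord(a, b, "binary-physical") for a, b in sorted(universe.positive_pairs)
        ]
        return goldstandard.curate_positives(evidence)

    positives = run_stage("curate", _curate)

    def _sample():
        negatives = goldstandard.sample_negatives(
            positives,
            universe.protein_ids,
            scheme=config.negative_scheme,
            ratio=config.negative_ratio,
            seed=seeds["sample"],
        )
        gold = goldstandard.assemble_gold_standard(positives, negatives)
        goldstandard.write_gold_tsv(gold, outdir / "gold.tsv")
        return gold

    gold = run_stage("sample", _sample)

    def _split():
        heldout = splits.hold_out_proteins(
            universe.protein_ids, config.split.heldout_protein_fraction, seeds["split"]
        )
        split_cfg = dataclasses.replace(config.split, seed=seeds["split"])
        degrees = goldstandard.degree_table(
            [p.key for p in positives], proteome=universe.protein_ids
        )
        assignment = splits.make_splits(
            gold, heldout, split_cfg, proteome=universe.protein_ids, degrees=degrees
        )
        splits.write_split_tsv(assignment, outdir / "split.tsv")
        return assignment

    assignment = run_stage("split", _split)

    def _featurize():
        index = universe.protein_index
        tables = {}
        for name in ("train", "T1", "T2"):
            part = assignment[assignment["split"] == name]
            table = features.build_feature_table(
                zip(part["idA"], part["idB"]), index, config.feature_groups
            )
            features.write_feature_tsv(table, outdir / f"features_{name}.tsv")
            tables[name] = (table, part["label"].to_numpy(), part)
        return tables

    tables = run_stage("featurize", _featurize)

    def _train():
        fits = {}
        train_table, train_labels, _ = tables["train"]
        for family in config.model_families:
            spec = models.ModelSpec(family=family, seed=seeds["train"])
            fit_result = models.fit(
                spec, _select_feature_columns(train_table, family), train_labels
            )
            models.save_model(fit_result, outdir / f"model_{family}.joblib")
            fits[family] = fit_result
            _log("train", f"{family}: {fit_result.wall_time_s:.2f} s")
        return fits

    fits = run_stage("train", _train)

    def _evaluate():
        reports: dict = {}
        scores_cache: dict = {}
        for dataset in ("T1", "T2"):
            table, labels, part = tables[dataset]
            y = (labels == POSITIVE).astype(int)
            for family, fit_result in fits.items():
                scores = models.predict_scores(
                    fit_result, _select_feature_columns(table, family)
                )
                scores_cache[(family, dataset)] = (y, scores)
                energy, carbon = evaluation.estimate_carbon(fit_result.wall_time_s)
                report = evaluation.evaluate_model(
                    y,
                    scores,
                    overlap_strata=part["overlap_stratum"].to_numpy(),
                    topology_strata=part["topology_stratum"].to_numpy(),
                    resources={
                        "wall_time_s": fit_result.wall_time_s,
                        "energy_kWh": energy,
                        "carbon_gCO2e": carbon,
                    },
                )
                curves_dir = outdir / "curves"
                curves_dir.mkdir(exist_ok=True)
                report.roc.write_csv(curves_dir / f"{family}_{dataset}_roc.csv")
                report.pr.write_csv(curves_dir / f"{family}_{dataset}_pr.csv")
                reports[(family, dataset)] = report
        # Pairwise ROC comparisons on T1 across model families.
        families = list(fits)
        for i, fam_a in enumerate(families):
            for fam_b in families[i + 1 :]:
                y, sa = scores_cache[(fam_a, "T1")]
                _, sb = scores_cache[(fam_b, "T1")]
                try:
                    test = evaluation.compare_roc(y, sa, sb)
                except evaluation.DegenerateComparisonError as exc:
                    test = {"p": None, "note": str(exc)}
                reports[(fam_a, "T1")].comparisons.append(
                    {"models": [fam_a, fam_b], **test}
                )
        return reports

    reports = run_stage("evaluate", _evaluate)

    def _report():
        for (family, dataset), report in reports.items():
            metadata = {
                "model": family,
                "dataset": dataset,
                "config_fingerprint": config.fingerprint(),
                "seed_registry": seeds,
                "curve_csvs": [
                    str(Path("curves") / f"{family}_{dataset}_roc.csv"),
                    str(Path("curves") / f"{family}_{dataset}_pr.csv"),
                ],
            }
            render_sheet(report, fits[family], metadata, outdir / "sheets")
            plot_curves(
                report,
                outdir / "sheets" / f"{family}_{dataset}_curves.png",
                title=f"{family} on {dataset}",
            )
        return None

    run_stage("report", _report)
    write_manifest(outdir)

    summary["auroc"] = {
        f"{family}_{dataset}": report.auroc for (family, dataset), report in reports.items()
    }
    summary["auprc"] = {
        f"{family}_{dataset}": report.auprc for (family, dataset), report in reports.items()
    }
    summary["reports"] = reports
    summary["assignment"] = assignment
    return summary
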