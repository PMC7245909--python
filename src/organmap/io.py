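"""Readers/writers, run configuration and the pipeline orchestrator.

Tables are TSV by default (tab-separated, UTF-8, Unix newlines) with the
header row holding sample IDs and the first column feature IDs; CSV is
accepted on read, with the dialect picked by file extension.  Group labels
come either from a sidecar two-column table (sample, group) or from an
embedded first row whose feature ID is ``group``.

``run_pipeline`` chains the two synthetic-study branches —
simulate -> DEG calling -> organ effect radar, and
simulate -> benchmark/ROC -> OPLS-DA -> screen -> correlation network —
and writes a JSON run report recording versions, seeds, parameters and
per-stage output paths, so every output is reproducible from the report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd

from . import __version__
from .containers import ExpressionMatrix, FeatureMatrix, MetaboliteMatrix
from .simulate import SimulationConfig

logger = logging.getLogger(__name__)

LABEL_ROW_ID = "group"


def _sep_for(path: str | Path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def write_matrix(matrix: FeatureMatrix, path: str | Path) -> None:
    """Write a feature matrix with an embedded group-label first row."""
    path = Path(path)
    sep = _sep_for(path)
    out = pd.concat(
        [matrix.group_labels.to_frame().T.set_axis([LABEL_ROW_ID]), matrix.values]
    )
    out.to_csv(path, sep=sep, lineterminator="\n")


def write_labels(matrix: FeatureMatrix, path: str | Path) -> None:
    """Write the sidecar (sample, group) label table."""
    sep = _sep_for(path)
    pd.DataFrame(
        {"sample": matrix.sample_ids, "group": list(matrix.group_labels)}
    ).to_csv(path, sep=sep, index=False, lineterminator="\n")


def _read_labels(path: str | Path) -> pd.Series:
    table = pd.read_csv(path, sep=_sep_for(path))
    if not {"sample", "group"} <= set(table.columns):
        raise ValueError(f"label file {path} needs 'sample' and 'group' columns")
    return pd.Series(table["group"].to_numpy(), index=table["sample"].astype(str))


def read_matrix(
    path: str | Path,
    kind: str = "metabolite",
    labels_path: str | Path | None = None,
    organ: str | None = None,
) -> FeatureMatrix:
    """Read a feature table into a typed matrix.

    ``kind`` is 'expression' or 'metabolite'.  Labels come from
    ``labels_path`` if given, else from an embedded first row with feature
    ID ``group``.  Ragged rows, duplicate feature IDs and non-numeric cells
    raise errors naming the offending line or ID.
    """
    path = Path(path)
    sep = _sep_for(path)
    try:
        raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed table ({exc})") from exc

    if raw.index.has_duplicates:
        dupes = raw.index[raw.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate feature ID(s): {dupes}")

    if labels_path is not None:
        labels = _read_labels(labels_path).reindex(raw.columns)
        if labels.isna().any():
            missing = labels.index[labels.isna()].tolist()
            raise ValueError(f"{labels_path}: no label for sample(s) {missing}")
    elif LABEL_ROW_ID in raw.index:
        labels = raw.loc[LABEL_ROW_ID]
        raw = raw.drop(index=LABEL_ROW_ID)
    else:
        raise ValueError(
            f"{path}: no embedded '{LABEL_ROW_ID}' row and no labels file given"
        )

    values = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for line_offset, (fid, row) in enumerate(raw.iterrows()):
        try:
            values.loc[fid] = row.astype(float)
        except ValueError as exc:
            # +2: header line plus 1-based counting (+1 more if labels embedded)
            lineno = line_offset + 2 + (1 if labels_path is None else 0)
            raise ValueError(f"{path}: non-numeric cell at line {lineno} ({fid!r})") from exc

    if kind == "expression":
        return ExpressionMatrix(
            values=values, group_labels=labels, organ=organ or path.stem
        )
    if kind == "metabolite":
        return MetaboliteMatrix(values=values, group_labels=labels)
    raise ValueError(f"unknown matrix kind {kind!r}; use 'expression' or 'metabolite'")


# --------------------------------------------------------------------------
# run configuration and orchestration
# --------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Parameters for a full synthetic-study run."""

    outdir: str = "organmap_run"
    seed: int = 0
    simulation: dict[str, Any] = field(default_factory=dict)
    fc_cutoff: float = 1.5
    fdr_cutoff: float = 0.05
    vip_threshold: float = 1.0
    alpha: float = 0.05
    n_ortho: int = 1
    oplsda_folds: int = 7
    benchmark_k: int = 2
    benchmark_folds: int = 3
    benchmark_repeats: int = 5
    roc_n_features: int = 20
    corr_r_threshold: float = 0.6
    run_benchmark: bool = True
    log_level: str = "INFO"

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            payload = json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    def simulation_config(self) -> SimulationConfig:
        sim = dict(self.simulation)
        sim.setdefault("seed", self.seed)
        return SimulationConfig(**sim)


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute the full synthetic pipeline; return the JSON-able run report."""
    from . import benchmark as bench
    from . import degs as degs_mod
    from . import oplsda as opls
    from . import organ_effect as oe
    from . import simulate as sim

    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim_config = config.simulation_config()
    report: dict[str, Any] = {
        "version": __version__,
        "seed": config.seed,
        "parameters": dataclasses.asdict(config),
        "outputs": {},
    }

    # --- transcriptome branch -------------------------------------------
    logger.info("simulating %d organs", len(sim_config.organs))
    matrices, truths = sim.simulate_all_organs(sim_config)
    summaries = []
    deg_rows = []
    for organ, matrix in matrices.items():
        write_matrix(matrix, outdir / f"expr_{organ}.tsv")
        records = degs_mod.call_degs(
            matrix, fc_cutoff=config.fc_cutoff, fdr_cutoff=config.fdr_cutoff
        )
        degs_mod.records_to_frame(records).to_csv(
            outdir / f"degs_{organ}.tsv", sep="\t", index=False, lineterminator="\n"
        )
        deg_sum = degs_mod.summarize_organ(records, organ)
        deg_rows.append(
            {"organ": organ, "n_up": deg_sum.n_up, "n_down": deg_sum.n_down,
             "n_total": deg_sum.n_total}
        )
        summaries.append((oe.pc01_summary(matrix), deg_sum))
        logger.info("%s: %d up / %d down DEGs", organ, deg_sum.n_up, deg_sum.n_down)
    pd.DataFrame(deg_rows).to_csv(
        outdir / "deg_summary.tsv", sep="\t", index=False, lineterminator="\n"
    )

    results = oe.organ_effect_scores(summaries)
    oe.results_to_frame(results).to_csv(
        outdir / "organ_effect.tsv", sep="\t", index=False, lineterminator="\n"
    )
    oe.render_radar(results, str(outdir / "radar.svg"))
    report["outputs"]["organ_effect"] = str(outdir / "organ_effect.tsv")
    report["outputs"]["radar"] = str(outdir / "radar.svg")
    report["outputs"]["deg_summary"] = str(outdir / "deg_summary.tsv")

    # --- metabolome branch ----------------------------------------------
    metab, metab_truth = sim.simulate_metabolome(sim_config)
    write_matrix(metab, outdir / "metabolome.tsv")
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(
            {
                "organs": {o: t.signed_effects for o, t in truths.items()},
                "metabolome": metab_truth.signed_effects,
            },
            fh,
            indent=2,
        )

    if config.run_benchmark:
        table = bench.benchmark_all_reductions(
            metab,
            k=config.benchmark_k,
            cv_folds=config.benchmark_folds,
            repeats=config.benchmark_repeats,
            seed=config.seed,
        )
        table.accuracy.to_csv(outdir / "benchmark.tsv", sep="\t", lineterminator="\n")
        roc = bench.fit_roc_model(
            metab,
            n_features=min(config.roc_n_features, metab.n_features),
            cv_folds=config.benchmark_folds,
            repeats=config.benchmark_repeats,
            seed=config.seed,
        )
        pd.DataFrame({"FPR": roc.fpr, "TPR": roc.tpr}).to_csv(
            outdir / "roc_curve.csv", index=False, lineterminator="\n"
        )
        report["outputs"]["benchmark"] = str(outdir / "benchmark.tsv")
        report["outputs"]["roc_curve"] = str(outdir / "roc_curve.csv")
        report["roc_auc"] = roc.auc

    model = opls.fit_oplsda(
        metab, n_ortho=config.n_ortho, cv_folds=config.oplsda_folds
    )
    hits = opls.screen_metabolites(
        model, metab, vip_threshold=config.vip_threshold, alpha=config.alpha
    )
    opls.screen_to_frame(hits).to_csv(
        outdir / "screen.tsv", sep="\t", index=False, lineterminator="\n"
    )
    network = opls.correlation_network(
        metab, r_threshold=config.corr_r_threshold, alpha=config.alpha
    )
    network.edge_frame().to_csv(
        outdir / "corr_network.tsv", sep="\t", index=False, lineterminator="\n"
    )
    report["outputs"]["screen"] = str(outdir / "screen.tsv")
    report["outputs"]["corr_network"] = str(outdir / "corr_network.tsv")
    report["oplsda"] = {"r2x": model.r2x, "r2y": model.r2y, "q2": model.q2}

    with open(outdir / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    logger.info("run complete; report at %s", outdir / "run_report.json")
    return report
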