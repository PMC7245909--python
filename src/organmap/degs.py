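"""Per-organ differential expression calling.

A gene is called a DEG when BOTH criteria hold: linear-scale fold change
(treated / control group means) above 1.5 or below 1/1.5, and
Benjamini–Hochberg FDR below 0.05.  Testing is Welch's t on
log2(FPKM + 1), which tolerates the unequal variances typical of
small-n bulk RNA-seq; the per-organ up/down totals feed the fuzzy-weight
stage of the organ effect model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import CONTROL_LABEL, TREATED_LABEL, ExpressionMatrix

DEFAULT_FC_CUTOFF = 1.5
DEFAULT_FDR_CUTOFF = 0.05
DEFAULT_PSEUDOCOUNT = 1.0


@dataclass(frozen=True)
class DEGRecord:
    gene_id: str
    fold_change: float  # linear-scale RPA/CON ratio of group means
    p_value: float
    fdr: float
    direction: str  # "up" | "down"


@dataclass(frozen=True)
class OrganDegSummary:
    organ: str
    n_up: int
    n_down: int

    @property
    def n_total(self) -> int:
        return self.n_up + self.n_down


def differential_table(
    expr: ExpressionMatrix,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Per-gene statistics table: fold_change, p_value, fdr for every gene.

    Welch's t-test (pooled-variance optional) on log2(x + pseudocount),
    BH adjustment across all genes of the organ.
    """
    con = expr.group_columns(CONTROL_LABEL).to_numpy(dtype=float)
    rpa = expr.group_columns(TREATED_LABEL).to_numpy(dtype=float)
    for name, grp in ((CONTROL_LABEL, con), (TREATED_LABEL, rpa)):
        if grp.shape[1] < 2:
            raise ValueError(
                f"group {name} has {grp.shape[1]} sample(s); "
                "need >= 2 for a variance estimate"
            )

    log_con = np.log2(con + pseudocount)
    log_rpa = np.log2(rpa + pseudocount)
    res = stats.ttest_ind(log_rpa, log_con, axis=1, equal_var=equal_var)
    pvals = np.asarray(res.pvalue, dtype=float)
    # genes constant across every sample produce nan p; they can never be
    # differential, so give them p = 1
    pvals = np.where(np.isnan(pvals), 1.0, pvals)
    fdr = multipletests(pvals, method="fdr_bh")[1]

    mean_con = con.mean(axis=1)
    mean_rpa = rpa.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.where(mean_con > 0, mean_rpa / mean_con, np.inf)
        fc = np.where((mean_con == 0) & (mean_rpa == 0), 1.0, fc)

    return pd.DataFrame(
        {"fold_change": fc, "p_value": pvals, "fdr": fdr},
        index=expr.values.index,
    )


def call_degs(
    expr: ExpressionMatrix,
    fc_cutoff: float = DEFAULT_FC_CUTOFF,
    fdr_cutoff: float = DEFAULT_FDR_CUTOFF,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> list[DEGRecord]:
    """Genes passing fold change > fc_cutoff (or < 1/fc_cutoff) AND FDR < fdr_cutoff."""
    if fc_cutoff <= 1:
        raise ValueError("fc_cutoff must be > 1")
    table = differential_table(expr, pseudocount=pseudocount)
    records: list[DEGRecord] = []
    for gene_id, row in table.iterrows():
        fc = float(row["fold_change"])
        if not (fc > fc_cutoff or fc < 1.0 / fc_cutoff):
            continue
        if not float(row["fdr"]) < fdr_cutoff:
            continue
        records.append(
            DEGRecord(
                gene_id=str(gene_id),
                fold_change=fc,
                p_value=float(row["p_value"]),
                fdr=float(row["fdr"]),
                direction="up" if fc > 1.0 else "down",
            )
        )
    return records


def summarize_organ(records: list[DEGRecord], organ: str) -> OrganDegSummary:
    """Count DEGs by direction for one organ."""
    n_up = sum(1 for r in records if r.direction == "up")
    n_down = sum(1 for r in records if r.direction == "down")
    return OrganDegSummary(organ=organ, n_up=n_up, n_down=n_down)


def records_to_frame(records: list[DEGRecord]) -> pd.DataFrame:
    """DEG records as a gene, FC, p, FDR, direction table."""
    return pd.DataFrame(
        [
            {
                "gene": r.gene_id,
                "fold_change": r.fold_change,
                "p_value": r.p_value,
                "fdr": r.fdr,
                "direction": r.direction,
            }
            for r in records
        ],
        columns=["gene", "fold_change", "p_value", "fdr", "direction"],
    )
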