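"""Disease-target assembly: differential expression plus database lists.

Differentially expressed genes (DEGs) are called from a two-group, log2-scale
expression matrix with a per-gene Welch two-sample t-test; a gene is
significant when p < 0.01 and |log2 fold change| >= 1 (i.e. linear |FC| >= 2).
The raw-p cutoff is deliberate — no multiple-testing correction enters the
verdict — but a Benjamini-Hochberg column is emitted for information.

Database-exported target lists are merged by case-folded union with per-source
provenance, and the disease set is intersected with the drug-target set to
give the overlap that seeds downstream network construction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import io

logger = logging.getLogger(__name__)


class ValidationError(ValueError):
    pass


@dataclass
class ExpressionMatrix:
    """Gene x sample matrix of log2 intensities with case/control labels."""

    genes: list[str]
    samples: list[str]
    values: np.ndarray           # shape (n_genes, n_samples), log2 scale
    labels: dict[str, str]       # sample -> "case" | "control"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("expression matrix contains non-finite values")
        unknown = set(self.labels.values()) - {"case", "control"}
        if unknown:
            raise ValidationError(f"unknown group labels: {sorted(unknown)}")

    def group_columns(self, group: str) -> list[int]:
        return [i for i, s in enumerate(self.samples) if self.labels.get(s) == group]


def call_degs(
    matrix: ExpressionMatrix,
    p_cut: float = 0.01,
    fc_cut: float = 2.0,
    strict_fc: bool = False,
    linear: bool = False,
) -> pd.DataFrame:
    """Per-gene Welch t-test between case and control columns.

    Returns a DataFrame with one row per gene: ``gene``, ``log2fc``
    (case mean - control mean), ``p_value``, ``bh_adjusted_p`` (informational)
    and ``significant``.  ``strict_fc`` switches the fold-change comparison
    from >= to >; ``linear`` declares the matrix linear-scale and log2s it
    first.  Genes where both groups have zero variance get p = 1 when the
    means agree and p = 0 when they differ (the test is degenerate there).
    """
    case_ix = matrix.group_columns("case")
    ctrl_ix = matrix.group_columns("control")
    if len(case_ix) < 2 or len(ctrl_ix) < 2:
        raise ValidationError(
            f"need >=2 samples per group, got {len(case_ix)} case / {len(ctrl_ix)} control"
        )
    values = matrix.values
    if linear:
        if np.any(values <= 0):
            raise ValidationError("linear-scale matrix must be positive to take log2")
        values = np.log2(values)

    case = values[:, case_ix]
    ctrl = values[:, ctrl_ix]
    log2fc = case.mean(axis=1) - ctrl.mean(axis=1)

    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = stats.ttest_ind(case, ctrl, axis=1, equal_var=False)
    p = np.asarray(p, dtype=float)
    degenerate = ~np.isfinite(p)   # both variances zero -> nan statistic
    if degenerate.any():
        p[degenerate] = np.where(np.isclose(log2fc[degenerate], 0.0), 1.0, 0.0)

    lfc_cut = math.log2(fc_cut)
    fc_ok = np.abs(log2fc) > lfc_cut if strict_fc else np.abs(log2fc) >= lfc_cut
    significant = (p < p_cut) & fc_ok
    bh = multipletests(p, method="fdr_bh")[1]

    return pd.DataFrame(
        {
            "gene": matrix.genes,
            "log2fc": log2fc,
            "p_value": p,
            "bh_adjusted_p": bh,
            "significant": significant,
        }
    )


def significant_genes(deg_table: pd.DataFrame) -> list[str]:
    """Upper-cased, sorted symbols of the significant rows."""
    return sorted(str(g).upper() for g in deg_table.loc[deg_table["significant"], "gene"])


def merge_disease_targets(
    lists: Mapping[str, Sequence[str]],
) -> tuple[set[str], pd.DataFrame]:
    """Case-folded union of named symbol lists with per-source provenance.

    Returns (union of upper-cased symbols, provenance table with one row per
    symbol and a 0/1 column per source).
    """
    if not lists:
        raise ValidationError("need at least one target list")
    sources = list(lists)
    membership: dict[str, set[str]] = {}
    for src, symbols in lists.items():
        for s in symbols:
            membership.setdefault(str(s).strip().upper(), set()).add(src)
    if not membership:
        logger.warning("merged disease-target union is empty")
    rows = [
        {"symbol": sym, **{src: int(src in membership[sym]) for src in sources}}
        for sym in sorted(membership)
    ]
    prov = pd.DataFrame(rows, columns=["symbol", *sources])
    return set(membership), prov


def intersect_targets(disease: set[str], drug: set[str]) -> list[str]:
    """Sorted intersection of two upper-cased symbol sets."""
    return sorted({s.upper() for s in disease} & {s.upper() for s in drug})


# ---------------------------------------------------------------------------
# I/O

def read_expression(matrix_path, labels_path) -> ExpressionMatrix:
    """Matrix: TSV with genes in rows, first column = gene symbol.
    Labels: two-column TSV (sample, group) without reliance on ordering."""
    df = pd.read_csv(matrix_path, sep="\t", index_col=0)
    if df.empty:
        raise ValidationError(f"{matrix_path}: empty expression matrix")
    if not np.issubdtype(np.asarray(df.values).dtype, np.number):
        raise ValidationError(f"{matrix_path}: non-numeric cells in expression matrix")
    lab = pd.read_csv(labels_path, sep="\t", dtype=str)
    labels = dict(zip(lab.iloc[:, 0], lab.iloc[:, 1]))
    return ExpressionMatrix(
        genes=[str(g) for g in df.index],
        samples=[str(s) for s in df.columns],
        values=df.values,
        labels=labels,
    )


def write_deg_table(deg_table: pd.DataFrame, path) -> None:
    io.write_tsv(deg_table.sort_values(["p_value", "gene"], kind="stable"), path)
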