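"""qRT-PCR relative expression on the 2^-ΔCt scale.

ΔCt for a gene in one biological replicate is the mean of its technical
threshold cycles minus the reference mean of the endogenous control genes
(by default the controls' technical Cts are pooled into one arithmetic
mean on the Ct scale; a geometric-mean-of-relative-quantity combination is
available as an alternative).  Relative expression is 2^-ΔCt per
biological replicate; genes are summarized per condition by the mean of
these values with the standard error of the mean as the dispersion
estimate.  Fold changes between conditions are signed ratios of means:
+r for r >= 1, else -(1/r), so a 427-fold induction prints as +427 and a
13.2-fold repression as -13.2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "CtTable",
    "RelExpr",
    "read_ct_table",
    "delta_ct",
    "relative_expression",
    "summarize",
    "signed_fold",
]

CT_COLUMNS = ["gene", "condition", "bio_rep", "tech_rep", "ct"]


@dataclass
class CtTable:
    """Long-format Ct measurements plus the endogenous control gene set."""

    data: pd.DataFrame
    controls: frozenset[str]

    def __post_init__(self) -> None:
        missing = [c for c in CT_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"Ct table missing columns: {missing}")
        self.controls = frozenset(self.controls)
        absent = self.controls - set(self.data["gene"])
        if absent:
            raise ValueError(f"control genes absent from table: {sorted(absent)}")

    @property
    def genes(self) -> list[str]:
        return sorted(set(self.data["gene"]) - self.controls)

    @property
    def conditions(self) -> list[str]:
        return sorted(set(self.data["condition"]))

    def bio_reps(self, condition: str) -> list:
        sel = self.data[self.data["condition"] == condition]
        return sorted(set(sel["bio_rep"]))


@dataclass(frozen=True)
class RelExpr:
    gene: str
    condition: str
    values: tuple[float, ...]  # per-biological-replicate 2^-ΔCt
    mean: float
    sem: float


def read_ct_table(path_or_handle, controls: Iterable[str]) -> CtTable:
    """Read a TSV with columns gene, condition, bio_rep, tech_rep, ct."""
    df = pd.read_csv(path_or_handle, sep="\t")
    return CtTable(df, frozenset(controls))


def _tech_mean(table: CtTable, genes: Sequence[str], condition, bio_rep) -> float:
    d = table.data
    sel = d[
        d["gene"].isin(genes)
        & (d["condition"] == condition)
        & (d["bio_rep"] == bio_rep)
    ]
    if sel.empty:
        raise ValueError(
            f"no Ct measurements for {list(genes)} in condition "
            f"{condition!r}, biological replicate {bio_rep!r}"
        )
    return float(sel["ct"].mean())


def delta_ct(
    table: CtTable,
    gene: str,
    condition: str,
    bio_rep,
    control_mode: str = "pooled",
) -> float:
    """ΔCt of a gene against the endogenous controls in one replicate."""
    gene_ct = _tech_mean(table, [gene], condition, bio_rep)
    if control_mode == "pooled":
        ref_ct = _tech_mean(table, sorted(table.controls), condition, bio_rep)
        return gene_ct - ref_ct
    if control_mode == "geometric":
        # geometric mean of per-control relative quantities == arithmetic
        # mean of per-control ΔCt on the log2 (cycle) scale
        dcts = [
            gene_ct - _tech_mean(table, [c], condition, bio_rep)
            for c in sorted(table.controls)
        ]
        return sum(dcts) / len(dcts)
    raise ValueError(f"unknown control_mode {control_mode!r}")


def relative_expression(
    table: CtTable, gene: str, condition: str, bio_rep, control_mode: str = "pooled"
) -> float:
    """2^-ΔCt for one gene in one biological replicate."""
    return 2.0 ** -delta_ct(table, gene, condition, bio_rep, control_mode)


def summarize(table: CtTable, control_mode: str = "pooled") -> list[RelExpr]:
    """Per gene x condition: replicate 2^-ΔCt values, their mean and SEM."""
    out: list[RelExpr] = []
    for gene in table.genes:
        for condition in table.conditions:
            values = tuple(
                relative_expression(table, gene, condition, rep, control_mode)
                for rep in table.bio_reps(condition)
            )
            n = len(values)
            mean = sum(values) / n
            if n > 1:
                var = sum((v - mean) ** 2 for v in values) / (n - 1)
                sem = math.sqrt(var) / math.sqrt(n)
            else:
                sem = 0.0
            out.append(RelExpr(gene, condition, values, mean, sem))
    return out


def signed_fold(rel_control: RelExpr, rel_infected: RelExpr) -> float:
    """Signed fold change between condition means: +r if r >= 1 else -(1/r)."""
    if rel_control.mean <= 0 or rel_infected.mean <= 0:
        raise ValueError("signed fold requires positive condition means")
    r = rel_infected.mean / rel_control.mean
    return r if r >= 1.0 else -1.0 / r


def summary_frame(
    table: CtTable, control: str = "control", infected: str = "infected",
    control_mode: str = "pooled",
) -> pd.DataFrame:
    """Tidy per-gene summary with means, SEMs and the signed fold change."""
    rel = {(r.gene, r.condition): r for r in summarize(table, control_mode)}
    rows = []
    for gene in table.genes:
        rc, ri = rel[(gene, control)], rel[(gene, infected)]
        rows.append(
            {
                "gene": gene,
                "mean_control": rc.mean,
                "sem_control": rc.sem,
                "mean_infected": ri.mean,
                "sem_infected": ri.sem,
                "signed_fold": signed_fold(rc, ri),
            }
        )
    return pd.DataFrame(rows)
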