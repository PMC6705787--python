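"""Phylum x domain-count census of a filtered dataset.

Groups records by the number of annotated S1 domains, tabulates occupancy
per (phylum, domain count) cell with sequence-length statistics, and
reports each domain-count class's share of the dataset. Domain counts above
six are legal but flagged: the real family ranges strictly from one to six.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import pandas as pd

from .errors import InsufficientDataError
from .records_io import Dataset, ProteinRecord

logger = logging.getLogger("s1census")

MAX_EXPECTED_DOMAINS = 6


def domain_count(rec: ProteinRecord) -> int:
    """Number of annotated S1 domains; warns above the observed 1-6 range."""
    k = rec.domain_count
    if k > MAX_EXPECTED_DOMAINS:
        logger.warning(
            "%s has %d S1 domains, outside the observed 1-%d range",
            rec.accession, k, MAX_EXPECTED_DOMAINS,
        )
    return k


@dataclass
class CensusTable:
    """Long-format occupancy table plus reconciled marginals.

    ``cells`` has one row per occupied (phylum, domain_count) cell with
    columns n, pct_of_total, mean_len, min_len, max_len.
    """

    cells: pd.DataFrame
    grand_total: int

    def cell(self, phylum: str, k: int) -> int:
        sel = self.cells[(self.cells.phylum == phylum) & (self.cells.domain_count == k)]
        return int(sel.n.iloc[0]) if len(sel) else 0

    def totals_by_phylum(self) -> dict[str, int]:
        return self.cells.groupby("phylum").n.sum().to_dict()

    def totals_by_domain_count(self) -> dict[int, int]:
        return {int(k): int(v) for k, v in self.cells.groupby("domain_count").n.sum().items()}

    def fraction_by_domain_count(self) -> dict[int, float]:
        """Share (%) of records per domain-count class."""
        return {
            k: 100.0 * v / self.grand_total
            for k, v in self.totals_by_domain_count().items()
        }

    def to_tsv(self, path, header_lines: list[str] | None = None) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for line in header_lines or []:
                fh.write(f"# {line}\n")
            out = self.cells.copy()
            out["pct_of_total"] = out["pct_of_total"].map(lambda v: f"{v:.1f}")
            out.to_csv(fh, sep="\t", index=False)

    def to_json(self, path) -> None:
        payload = {
            "grand_total": self.grand_total,
            "cells": self.cells.to_dict(orient="records"),
            "totals_by_phylum": self.totals_by_phylum(),
            "totals_by_domain_count": {
                str(k): v for k, v in self.totals_by_domain_count().items()
            },
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


def build_census(ds: Dataset) -> CensusTable:
    """Tabulate (phylum, domain count) occupancy and length statistics.

    The phylum comes from the explicit metadata column, not from lineage
    parsing. Marginals reconcile exactly by construction; record order does
    not matter.
    """
    rows = [
        {
            "phylum": rec.phylum,
            "domain_count": domain_count(rec),
            "length": len(rec.sequence),
        }
        for rec in ds
    ]
    if not rows:
        cells = pd.DataFrame(
            columns=["phylum", "domain_count", "n", "pct_of_total",
                     "mean_len", "min_len", "max_len"]
        )
        return CensusTable(cells, 0)
    df = pd.DataFrame(rows)
    grouped = df.groupby(["phylum", "domain_count"], as_index=False).agg(
        n=("length", "size"),
        mean_len=("length", "mean"),
        min_len=("length", "min"),
        max_len=("length", "max"),
    )
    total = len(df)
    grouped["pct_of_total"] = 100.0 * grouped["n"] / total
    grouped = grouped.sort_values(["domain_count", "phylum"], kind="mergesort")
    cells = grouped[
        ["phylum", "domain_count", "n", "pct_of_total", "mean_len", "min_len", "max_len"]
    ].reset_index(drop=True)
    return CensusTable(cells, total)


def length_summary(ds: Dataset, group: int) -> tuple[float, int, int]:
    """(mean, min, max) sequence length over records with *group* domains."""
    lengths = [len(rec.sequence) for rec in ds if rec.domain_count == group]
    if not lengths:
        raise InsufficientDataError(f"no records with domain count {group}")
    return sum(lengths) / len(lengths), min(lengths), max(lengths)


def plot_census(table: CensusTable, path) -> None:
    """Stacked bar chart of domain-count composition per phylum (optional)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pivot = table.cells.pivot_table(
        index="phylum", columns="domain_count", values="n", fill_value=0
    )
    ax = pivot.plot(kind="bar", stacked=True, figsize=(10, 5), width=0.8)
    ax.set_ylabel("records")
    ax.set_xlabel("phylum")
    ax.legend(title="S1 domains")
    plt.tight_layout()
    plt.savefig(path, dpi=150)
    plt.close()
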