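"""Cohort-level association statistics.

Utility for testing whether fusion-positive samples are enriched in a
mutation stratum (e.g. oncogenic fusions in KRAS wild-type tumors) with
a two-sided Fisher's exact test on a 2x2 contingency table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import IO, Iterable

import numpy as np
import pandas as pd
from scipy.special import gammaln

KRAS_STATUSES = {"wild_type", "mutant"}
FUSION_STATUSES = {"fusion", "none"}


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Rows: wild-type / mutant; columns: fusion-positive / negative."""

    a: int  # wild-type, fusion-positive
    b: int  # wild-type, fusion-negative
    c: int  # mutant, fusion-positive
    d: int  # mutant, fusion-negative

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency-table entries must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("contingency table is empty")

    @property
    def grand_total(self) -> int:
        return self.a + self.b + self.c + self.d


#: relative slack when comparing hypergeometric masses, absorbing
#: floating-point ties between equally likely tables
_TIE_EPS = 1e-7


def fisher_exact_2x2(table: ContingencyTable2x2) -> tuple[float, float]:
    """Two-sided Fisher's exact test.

    The two-sided p-value follows the probability-mass convention: the
    sum of hypergeometric probabilities, over all tables with the
    observed margins, that do not exceed the probability of the
    observed table.  The enumeration is evaluated in log space over the
    full support of the hypergeometric distribution, so the result is
    exact up to floating point for any table size.  The odds ratio is
    the sample odds ratio ``(a*d)/(b*c)`` (infinite when ``b*c == 0``).
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    n_total, row1, col1 = a + b + c + d, a + b, a + c
    k = np.arange(max(0, col1 - (c + d)), min(row1, col1) + 1)
    log_pmf = (
        gammaln(row1 + 1) - gammaln(k + 1) - gammaln(row1 - k + 1)
        + gammaln(n_total - row1 + 1) - gammaln(col1 - k + 1)
        - gammaln(n_total - row1 - (col1 - k) + 1)
        - (gammaln(n_total + 1) - gammaln(col1 + 1) - gammaln(n_total - col1 + 1))
    )
    pmf = np.exp(log_pmf)
    p_obs = pmf[np.searchsorted(k, a)]
    p_value = float(min(1.0, pmf[pmf <= p_obs * (1 + _TIE_EPS)].sum()))
    if b * c == 0:
        odds = math.inf if a * d > 0 else math.nan
    else:
        odds = (a * d) / (b * c)
    return p_value, odds


def tabulate_samples(
    rows: Iterable[tuple[str, str, str]]
) -> ContingencyTable2x2:
    """Count per-sample (sample_id, kras_status, fusion_status) rows."""
    counts = {"a": 0, "b": 0, "c": 0, "d": 0}
    n = 0
    for sample_id, kras_status, fusion_status in rows:
        if kras_status not in KRAS_STATUSES:
            raise ValueError(
                f"sample {sample_id}: unknown mutation status {kras_status!r}"
            )
        if fusion_status not in FUSION_STATUSES:
            raise ValueError(
                f"sample {sample_id}: unknown fusion status {fusion_status!r}"
            )
        key = {
            ("wild_type", "fusion"): "a",
            ("wild_type", "none"): "b",
            ("mutant", "fusion"): "c",
            ("mutant", "none"): "d",
        }[(kras_status, fusion_status)]
        counts[key] += 1
        n += 1
    if n == 0:
        raise ValueError("no samples provided")
    return ContingencyTable2x2(**counts)


def enrichment_report(
    rows: Iterable[tuple[str, str, str]], stream: IO[str] | None = None
) -> tuple[pd.DataFrame, float, float]:
    """Tabulate sample annotations and run the enrichment test.

    Returns the 2x2 table as a DataFrame plus (p_value, odds_ratio);
    optionally writes a small TSV report.
    """
    table = tabulate_samples(rows)
    p_value, odds = fisher_exact_2x2(table)
    frame = pd.DataFrame(
        [[table.a, table.b], [table.c, table.d]],
        index=["wild_type", "mutant"],
        columns=["fusion", "none"],
    )
    if stream is not None:
        stream.write("stratum\tfusion\tnone\n")
        for name, row in frame.iterrows():
            stream.write(f"{name}\t{row['fusion']}\t{row['none']}\n")
        stream.write(f"p_value\t{p_value:.6g}\n")
        stream.write(f"odds_ratio\t{odds:.6g}\n")
    return frame, p_value, odds
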