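"""qPCR relative quantification and group comparison.

Relative transcript quantity follows the amplification-efficiency model:
with efficiency E per cycle (E = 2 for perfect doubling) and threshold
cycle Ct, the amount of starting template is proportional to E^(-Ct), so
the target-to-reference ratio in one sample is

    ratio = E_target^(-Ct_target) / E_reference^(-Ct_reference)

which for E = 2 on both genes reduces to the familiar 2^(-dCt) with
dCt = Ct_target - Ct_reference.  Per-gene ratios are then rescaled so
the highest sample equals 10 arbitrary units (a.u.), and tissue groups
are compared with a two-tailed Mann-Whitney U test (exact by full
enumeration for small untied samples, normal approximation with tie and
continuity correction otherwise).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "QpcrMeasurement",
    "RelativeExpression",
    "relative_quantity",
    "normalize_to_max",
    "mann_whitney_u",
    "relative_expression_table",
]

#: largest pooled sample size for which the exact MWU null is enumerated
EXACT_MWU_LIMIT = 20


@dataclass(frozen=True)
class QpcrMeasurement:
    """One well: threshold cycle Ct of one gene in one sample."""

    sample_id: str
    tissue: str
    gene: str
    ct: float
    efficiency: float = 2.0

    def __post_init__(self) -> None:
        if not math.isfinite(self.ct):
            raise ValueError("Ct must be finite")
        if not (1.0 <= self.efficiency <= 2.0):
            raise ValueError(f"efficiency must be in [1, 2], got {self.efficiency}")


@dataclass(frozen=True)
class RelativeExpression:
    sample_id: str
    gene: str
    value_au: float


def relative_quantity(
    target: QpcrMeasurement, reference: QpcrMeasurement
) -> float:
    """Target/reference transcript ratio under the efficiency model."""
    if target.sample_id != reference.sample_id:
        raise ValueError(
            f"sample mismatch: {target.sample_id!r} vs {reference.sample_id!r}"
        )
    if target.gene == reference.gene:
        raise ValueError("reference gene must differ from target gene")
    return (target.efficiency ** -target.ct) / (reference.efficiency ** -reference.ct)


def normalize_to_max(
    values: Sequence[float], sample_ids: Sequence[str] | None = None,
    gene: str = "", scale: float = 10.0,
) -> list[RelativeExpression]:
    """Rescale per-gene values so the maximum equals ``scale`` a.u."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0 or not np.any(arr > 0):
        raise ValueError("need at least one positive value")
    if np.any(arr < 0):
        raise ValueError("negative expression values")
    out = arr * (scale / arr.max())
    ids = list(sample_ids) if sample_ids is not None else [str(i) for i in range(arr.size)]
    return [RelativeExpression(s, gene, float(v)) for s, v in zip(ids, out)]


def mann_whitney_u(
    group_a: Sequence[float], group_b: Sequence[float]
) -> dict:
    """Two-tailed Mann-Whitney U test.

    Exact null by enumeration of all C(nA+nB, nA) group labelings when
    the pooled sample has at most 20 observations and no ties; otherwise
    the normal approximation with midrank tie correction and continuity
    correction.  Returns the U statistic of group A, the two-tailed p and
    the method used.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups need at least one value")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < pooled.size
    exact = (pooled.size <= EXACT_MWU_LIMIT) and not has_ties
    res = stats.mannwhitneyu(
        a, b,
        alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    return dict(
        u=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        method="exact" if exact else "normal_approx",
        n_a=int(a.size),
        n_b=int(b.size),
    )


def relative_expression_table(
    table: pd.DataFrame, reference_gene: str, scale: float = 10.0
) -> pd.DataFrame:
    """Full relative-quantification pipeline over a long-format Ct table.

    ``table`` needs columns ``sample_id, tissue, gene, ct`` and optional
    ``efficiency`` (default 2.0).  Every non-reference gene is quantified
    relative to the reference gene of the same sample and max-normalized
    to ``scale`` a.u. per gene.
    """
    df = table.copy()
    if "efficiency" not in df.columns:
        df["efficiency"] = 2.0
    df["efficiency"] = df["efficiency"].fillna(2.0)
    ref = df[df["gene"] == reference_gene].set_index("sample_id")
    if ref.empty:
        raise ValueError(f"reference gene {reference_gene!r} not in table")
    rows = []
    for gene, sub in df[df["gene"] != reference_gene].groupby("gene", sort=True):
        ratios, ids, tissues = [], [], []
        for r in sub.itertuples():
            if r.sample_id not in ref.index:
                raise ValueError(
                    f"sample {r.sample_id!r} has no {reference_gene} measurement"
                )
            rr = ref.loc[r.sample_id]
            ratios.append(
                relative_quantity(
                    QpcrMeasurement(r.sample_id, r.tissue, gene, r.ct, r.efficiency),
                    QpcrMeasurement(
                        r.sample_id, r.tissue, reference_gene,
                        float(rr["ct"]), float(rr["efficiency"]),
                    ),
                )
            )
            ids.append(r.sample_id)
            tissues.append(r.tissue)
        for expr, tissue in zip(
            normalize_to_max(ratios, ids, gene=gene, scale=scale), tissues
        ):
            rows.append(
                dict(sample_id=expr.sample_id, tissue=tissue,
                     gene=gene, value_au=expr.value_au)
            )
    return pd.DataFrame(rows, columns=["sample_id", "tissue", "gene", "value_au"])
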