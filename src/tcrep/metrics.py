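"""Per-sample and per-group repertoire summaries.

V-J combination frequency matrices (percent of in-frame reads per gene-pair
cell, averaged element-wise across replicates) and the Shannon clonal
diversity index H = -sum p_i ln p_i over in-frame clonotype read proportions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .calling import RepertoireSample


class MetricsError(ValueError):
    pass


@dataclass
class VJMatrix:
    """Average percent read frequency per (V gene, J gene) combination."""

    chain: str
    matrix: pd.DataFrame  # rows: V genes, columns: J genes, values: percent
    provenance: list = field(default_factory=list)

    def to_long(self) -> pd.DataFrame:
        long = (
            self.matrix.stack()
            .rename("frequency_pct")
            .rename_axis(["v_call", "j_call"])
            .reset_index()
        )
        return long.sort_values(["v_call", "j_call"]).reset_index(drop=True)


@dataclass
class DiversityResult:
    sample_id: str
    chain: str
    shannon_index: float | None
    clonotype_count: int
    base: str = "e"


def vj_matrix(samples: Sequence[RepertoireSample]) -> VJMatrix:
    """Element-wise mean of per-sample V-J percent-frequency matrices.

    All samples must be on the same chain; per sample, the cell (V, J) holds
    the summed percent frequency of in-frame clonotypes using that gene pair
    (so each per-sample matrix totals 100%), and cells absent from a sample
    contribute zero to the average.
    """
    if not samples:
        raise MetricsError("no samples given")
    chains = {s.chain for s in samples}
    if len(chains) != 1:
        raise MetricsError(f"mixed chains in vj_matrix: {sorted(chains)}")
    per_sample = []
    for s in samples:
        p = s.productive()
        if p.empty:
            per_sample.append(pd.DataFrame())
            continue
        m = p.pivot_table(
            index="v_call",
            columns="j_call",
            values="frequency_pct",
            aggfunc="sum",
            fill_value=0.0,
        )
        per_sample.append(m)
    v_genes = sorted(set().union(*(m.index for m in per_sample if not m.empty)))
    j_genes = sorted(set().union(*(m.columns for m in per_sample if not m.empty)))
    acc = pd.DataFrame(0.0, index=v_genes, columns=j_genes)
    for m in per_sample:
        acc = acc.add(m.reindex(index=v_genes, columns=j_genes, fill_value=0.0), fill_value=0.0)
    acc /= len(samples)
    return VJMatrix(
        chain=samples[0].chain,
        matrix=acc,
        provenance=[s.sample_id for s in samples],
    )


def shannon_index(sample: RepertoireSample, base: str = "e") -> DiversityResult:
    """Shannon diversity of in-frame clonotype proportions.

    Proportions are read-weighted: p_i = copy_count_i / total in-frame reads.
    ``base`` is "e" (nats, default) or "2" (bits); an empty sample yields a
    missing (None) index rather than zero.
    """
    if base not in ("e", "2"):
        raise MetricsError(f"unknown log base {base!r}")
    p = sample.productive()
    k = len(p)
    if k == 0:
        return DiversityResult(sample.sample_id, sample.chain, None, 0, base)
    counts = p["duplicate_count"].to_numpy(dtype=float)
    probs = counts / counts.sum()
    h = float(-(probs * np.log(probs)).sum())
    if base == "2":
        h /= math.log(2.0)
    return DiversityResult(sample.sample_id, sample.chain, h, k, base)


def diversity_table(
    samples: Sequence[RepertoireSample], base: str = "e"
) -> pd.DataFrame:
    rows = []
    for s in samples:
        r = shannon_index(s, base=base)
        rows.append(
            {
                "sample_id": r.sample_id,
                "chain": r.chain,
                "shannon_index": r.shannon_index,
                "clonotype_count": r.clonotype_count,
                "log_base": r.base,
            }
        )
    return pd.DataFrame(rows)


def plot_vj_matrix(vjm: VJMatrix, path) -> None:
    """3-D bar rendering of a V-J combination matrix (percent on the y axis)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    m = vjm.matrix
    fig = plt.figure(figsize=(10, 7))
    ax = fig.add_subplot(111, projection="3d")
    xs, zs = np.meshgrid(np.arange(len(m.index)), np.arange(len(m.columns)), indexing="ij")
    heights = m.to_numpy().ravel()
    ax.bar3d(xs.ravel(), zs.ravel(), 0, 0.8, 0.8, heights, shade=True)
    ax.set_xticks(np.arange(len(m.index)) + 0.4)
    ax.set_xticklabels(m.index, fontsize=4, rotation=90)
    ax.set_yticks(np.arange(len(m.columns)) + 0.4)
    ax.set_yticklabels(m.columns, fontsize=4)
    ax.set_zlabel("% frequency")
    ax.set_title(f"{vjm.chain} V-J combinations")
    fig.savefig(path, dpi=150)
    plt.close(fig)
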