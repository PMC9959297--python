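"""Cross-sample clonotype sharing and gene-usage skew.

Group repertoires pool a sample type's replicates: the clonotype set is the
union of the replicates' unique-read triples and each clonotype's mean
percent frequency averages its in-frame frequency over all replicates (zero
where absent).  On top of these the module computes top-N commonality tables,
Venn-style pairwise sharing counts with two narrowing filters ("increased in
ACM Ly over ICM" and "present only in ACM Ly"), per-gene usage counts of a
filtered clonotype set with the mean + 2*SD over-usage rule, and detection of
the invariant murine iNKT rearrangement TRAV11/TRAV11D-TRAJ18 with junction
CVVGDRGSALGRLHF.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .calling import RepertoireSample
from .reference import GermlineReference

Triple = tuple[str, str, str]

INKT_V_GENES = ("TRAV11", "TRAV11D")
INKT_J_GENE = "TRAJ18"
INKT_JUNCTION_AA = "CVVGDRGSALGRLHF"

GENE_AXES = ("TRAV", "TRAJ", "TRBV", "TRBJ")


class CommonalityError(ValueError):
    pass


@dataclass
class GroupRepertoire:
    """Replicate-pooled repertoire of one (group, tissue, chain)."""

    group: str
    tissue: str
    chain: str
    n_replicates: int
    #: mean in-frame %frequency per triple, averaged over replicates with
    #: zero where absent
    mean_frequency: dict = field(default_factory=dict)

    @property
    def label(self) -> str:
        return f"{self.group}_{self.tissue}"

    @property
    def clonotypes(self) -> set[Triple]:
        return set(self.mean_frequency)

    def frequency(self, triple: Triple) -> float:
        return self.mean_frequency.get(triple, 0.0)


def build_group_repertoire(samples: Sequence[RepertoireSample]) -> GroupRepertoire:
    """Pool replicates of one sample type into a GroupRepertoire."""
    if not samples:
        raise CommonalityError("no replicate samples given")
    meta = {(s.group, s.tissue, s.chain) for s in samples}
    if len(meta) != 1:
        raise CommonalityError(f"mixed group/tissue/chain in replicates: {sorted(meta)}")
    group, tissue, chain = next(iter(meta))
    n = len(samples)
    total: dict[Triple, float] = {}
    for s in samples:
        p = s.productive()
        for v, j, aa, f in zip(
            p["v_call"], p["j_call"], p["junction_aa"], p["frequency_pct"]
        ):
            key = (v, j, aa)
            total[key] = total.get(key, 0.0) + float(f)
    return GroupRepertoire(
        group=group,
        tissue=tissue,
        chain=chain,
        n_replicates=n,
        mean_frequency={k: v / n for k, v in total.items()},
    )


def detect_inkt(v_name: str, j_name: str, cdr3_aa: str, chain: str = "TRA") -> bool:
    """True iff the clonotype is the invariant iNKT rearrangement.

    Non-TRA input is never iNKT (returns False rather than raising).
    """
    if chain != "TRA":
        import warnings

        warnings.warn("detect_inkt called on a non-TRA clonotype", stacklevel=2)
        return False
    return (
        v_name in INKT_V_GENES
        and j_name == INKT_J_GENE
        and cdr3_aa == INKT_JUNCTION_AA
    )


def inkt_frequency(sample: RepertoireSample) -> float:
    """Summed in-frame %frequency of iNKT clonotypes in one sample (0 if absent)."""
    if sample.chain != "TRA":
        return 0.0
    p = sample.productive()
    total = 0.0
    for v, j, aa, f in zip(
        p["v_call"], p["j_call"], p["junction_aa"], p["frequency_pct"]
    ):
        if detect_inkt(v, j, aa, chain="TRA"):
            total += float(f)
    return total


def top_commonality(
    reference_group: GroupRepertoire,
    others: Sequence[GroupRepertoire],
    n: int = 20,
) -> pd.DataFrame:
    """Top-n reference clonotypes by mean %frequency, annotated with their
    presence/frequency in every other group-tissue and an iNKT flag.

    Ties on mean %frequency break by the clonotype triple lexicographically;
    if fewer than n clonotypes exist, all are returned.
    """
    chains = {reference_group.chain} | {g.chain for g in others}
    if len(chains) != 1:
        raise CommonalityError(f"mixed chains in commonality: {sorted(chains)}")
    ranked = sorted(
        reference_group.mean_frequency.items(), key=lambda kv: (-kv[1], kv[0])
    )[:n]
    rows = []
    for rank, (triple, freq) in enumerate(ranked, start=1):
        v, j, aa = triple
        row = {
            "rank": rank,
            "v_call": v,
            "j_call": j,
            "junction_aa": aa,
            f"freq_{reference_group.label}": freq,
        }
        for g in others:
            row[f"freq_{g.label}"] = g.frequency(triple)
            row[f"shared_{g.label}"] = triple in g.clonotypes
        row["is_inkt"] = detect_inkt(v, j, aa, chain=reference_group.chain) \
            if reference_group.chain == "TRA" else False
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class VennCounts:
    """Sharing of ACM OM unique reads with the other three sample types,
    plus the two narrowed subsets."""

    chain: str
    acm_om_size: int
    shared_acm_ly: int
    shared_icm_ly: int
    shared_icm_om: int
    increased_in_acm_ly: int
    only_in_acm_ly: int

    def as_dict(self) -> dict:
        return {
            "chain": self.chain,
            "acm_om_size": self.acm_om_size,
            "shared_acm_ly": self.shared_acm_ly,
            "shared_icm_ly": self.shared_icm_ly,
            "shared_icm_om": self.shared_icm_om,
            "increased_in_acm_ly": self.increased_in_acm_ly,
            "only_in_acm_ly": self.only_in_acm_ly,
        }


def venn_counts(
    acm_om: GroupRepertoire,
    acm_ly: GroupRepertoire,
    icm_ly: GroupRepertoire,
    icm_om: GroupRepertoire,
    increased_comparator: str = "icm_ly",
) -> VennCounts:
    """Pairwise sharing counts and the two narrowing filters.

    ``increased_in_acm_ly`` counts clonotypes shared between ACM OM and ACM Ly
    whose mean %frequency in ACM Ly strictly exceeds the comparator (ICM Ly by
    default, or the max over both ICM samples with
    ``increased_comparator="icm_both"``; absence counts as zero frequency).
    ``only_in_acm_ly`` additionally requires absence from both ICM samples.
    The set nesting only <= increased <= shared holds for every input.
    """
    if increased_comparator not in ("icm_ly", "icm_both"):
        raise CommonalityError(f"unknown comparator {increased_comparator!r}")
    chains = {g.chain for g in (acm_om, acm_ly, icm_ly, icm_om)}
    if len(chains) != 1:
        raise CommonalityError(f"mixed chains in venn_counts: {sorted(chains)}")
    ref = acm_om.clonotypes
    with_ly = ref & acm_ly.clonotypes
    increased = 0
    only = 0
    for c in with_ly:
        cmp_freq = icm_ly.frequency(c)
        if increased_comparator == "icm_both":
            cmp_freq = max(cmp_freq, icm_om.frequency(c))
        if acm_ly.frequency(c) > cmp_freq:
            increased += 1
        if c not in icm_ly.clonotypes and c not in icm_om.clonotypes:
            only += 1
    return VennCounts(
        chain=acm_om.chain,
        acm_om_size=len(ref),
        shared_acm_ly=len(with_ly),
        shared_icm_ly=len(ref & icm_ly.clonotypes),
        shared_icm_om=len(ref & icm_om.clonotypes),
        increased_in_acm_ly=increased,
        only_in_acm_ly=only,
    )


def increased_set(
    acm_om: GroupRepertoire,
    acm_ly: GroupRepertoire,
    icm_ly: GroupRepertoire,
    icm_om: GroupRepertoire,
    increased_comparator: str = "icm_ly",
) -> set[Triple]:
    """The clonotype set behind ``increased_in_acm_ly``."""
    out = set()
    for c in acm_om.clonotypes & acm_ly.clonotypes:
        cmp_freq = icm_ly.frequency(c)
        if increased_comparator == "icm_both":
            cmp_freq = max(cmp_freq, icm_om.frequency(c))
        if acm_ly.frequency(c) > cmp_freq:
            out.add(c)
    return out


def only_set(
    acm_om: GroupRepertoire,
    acm_ly: GroupRepertoire,
    icm_ly: GroupRepertoire,
    icm_om: GroupRepertoire,
) -> set[Triple]:
    """The clonotype set behind ``only_in_acm_ly``."""
    return {
        c
        for c in acm_om.clonotypes & acm_ly.clonotypes
        if c not in icm_ly.clonotypes and c not in icm_om.clonotypes
    }


@dataclass
class SkewReport:
    """Per-gene unique-read counts of a filtered clonotype set with the
    mean + 2*SD over-usage threshold."""

    gene_axis: str
    counts: dict
    occupied: int
    total_genes: int
    mean: float
    sd: float | None
    threshold: float | None
    flagged: list

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            sorted(self.counts.items()), columns=["gene", "unique_read_count"]
        )
        df["mean"] = self.mean
        df["sd"] = self.sd if self.sd is not None else np.nan
        df["threshold"] = self.threshold if self.threshold is not None else np.nan
        df["flagged"] = df["gene"].isin(self.flagged)
        return df


def gene_usage_skew(
    clonotypes: Iterable[Triple],
    reference: GermlineReference,
    gene_axis: str,
) -> SkewReport:
    """Tabulate per-gene usage of a filtered clonotype set and flag over-used
    genes.

    The count of a gene is the number of unique reads (triples) carrying it
    on the requested axis.  The mean is total count / number of OCCUPIED genes
    (count >= 1); the SD is the sample (n-1) standard deviation over occupied
    genes; a gene is flagged when its count strictly exceeds mean + 2*SD.
    With a single occupied gene the SD and threshold are undefined (None) and
    nothing is flagged.
    """
    if gene_axis not in GENE_AXES:
        raise CommonalityError(f"unknown gene axis {gene_axis!r}")
    triples = list(clonotypes)
    if not triples:
        raise CommonalityError("nothing to tabulate: empty clonotype set")
    chain, seg_type = gene_axis[:3], gene_axis[3]
    idx = 0 if seg_type == "V" else 1
    counts: dict[str, int] = {}
    for t in triples:
        gene = t[idx]
        counts[gene] = counts.get(gene, 0) + 1
    occupied = len(counts)
    total_genes = len(reference.segments(chain, seg_type))
    values = np.array(sorted(counts.values()), dtype=float)
    mean = float(values.sum() / occupied)
    if occupied >= 2:
        sd = float(np.std(values, ddof=1))
        threshold = mean + 2.0 * sd
        flagged = sorted(g for g, c in counts.items() if c > threshold)
    else:
        sd = None
        threshold = None
        flagged = []
    return SkewReport(
        gene_axis=gene_axis,
        counts=counts,
        occupied=occupied,
        total_genes=total_genes,
        mean=mean,
        sd=sd,
        threshold=threshold,
        flagged=flagged,
    )
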