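"""Ground-truth repertoire and amplicon-read simulator.

Emulates a two-group (allergic vs. irritant contact mucositis; ACM/ICM),
two-tissue (oral mucosa OM vs. cervical lymph node Ly) murine study with
replicate animals per sample type.  Each sample type gets its own clone pool
with a Zipf-like clone-size law (expanded head, uniform tail); the ACM OM and
ACM Ly pools share a configurable top-biased clone fraction (with optional
V/J usage skew planted in the shared clones), smaller fractions are shared
with the ICM pools, the ICM OM pool is deliberately smaller (lower clonal
diversity), and the invariant iNKT rearrangement
(TRAV11D-TRAJ18, junction CVVGDRGSALGRLHF) is spiked into every sample type
at a configurable in-frame read frequency.

Every emitted read records its ground-truth clone id in its identifier, so
exact-recovery tests need no auxiliary files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .calling import RepertoireSample, build_sample_table, translate_cdr3
from .reference import GeneSegment, GermlineReference

SAMPLE_TYPES = ("ACM_OM", "ACM_LY", "ICM_OM", "ICM_LY")

INKT_V_GENE = "TRAV11D"
INKT_J_GENE = "TRAJ18"
INKT_JUNCTION_AA = "CVVGDRGSALGRLHF"
_INKT_INSERT = "GGA"

_BASES = np.frombuffer(b"ACGT", dtype="S1").astype("U1")


class SimulationError(ValueError):
    pass


class CloneSpaceExhausted(SimulationError):
    """Requested clone count exceeds what the junction model can make unique."""


class ChainMismatch(SimulationError):
    pass


class UnknownGene(SimulationError):
    pass


@dataclass
class StudyDesign:
    """All knobs of the simulated study; defaults define the study conditions.

    ``inkt_frequency`` values are target fractions of IN-FRAME reads (the
    scale on which repertoire %frequencies are reported); the generator
    solves for the raw clone abundance that achieves them.
    """

    chains: tuple[str, ...] = ("TRA", "TRB")
    replicates: int = 3
    reads_per_sample: int = 50_000  # per chain
    clone_counts: dict = field(
        default_factory=lambda: {
            "ACM_OM": 2000,
            "ACM_LY": 2000,
            "ICM_OM": 300,
            "ICM_LY": 1200,
        }
    )
    share_acm_ly: float = 0.30
    share_icm_ly: float = 0.05
    share_icm_om: float = 0.01
    skew_genes: tuple[str, ...] = (
        "TRAV7D-2",
        "TRAV14-1",
        "TRAJ18",
        "TRBV5",
        "TRBJ2-7",
    )
    skew_factor: float = 5.0
    inkt_frequency: dict = field(
        default_factory=lambda: {
            "ACM_OM": 0.0002,
            "ACM_LY": 0.002,
            "ICM_OM": 0.01,
            "ICM_LY": 0.002,
        }
    )
    out_of_frame_fraction: float = 0.2
    zipf_exponent: float = 1.2
    zipf_head: int = 50
    max_insert_codons: int = 4
    error_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.replicates < 1:
            raise SimulationError("replicates must be >= 1")
        if self.reads_per_sample < 1:
            raise SimulationError("reads_per_sample must be >= 1")
        for st in SAMPLE_TYPES:
            if self.clone_counts.get(st, 0) < 1:
                raise SimulationError(f"clone count for {st} must be >= 1")
        for name, val in (
            ("share_acm_ly", self.share_acm_ly),
            ("share_icm_ly", self.share_icm_ly),
            ("share_icm_om", self.share_icm_om),
            ("out_of_frame_fraction", self.out_of_frame_fraction),
        ):
            if not 0.0 <= val <= 1.0:
                raise SimulationError(f"{name} must be in [0, 1]")
        for st, f in self.inkt_frequency.items():
            if not 0.0 <= f < 1.0:
                raise SimulationError(f"inkt_frequency[{st}] must be in [0, 1)")
        if not 0.0 <= self.error_rate < 1.0:
            raise SimulationError("error_rate must be in [0, 1)")

    def sample_ids(self) -> list[tuple[str, str]]:
        """(sample_type, sample_id) pairs in the fixed enumeration order."""
        out = []
        for st in SAMPLE_TYPES:
            for rep in range(1, self.replicates + 1):
                out.append((st, f"{st}_{rep}"))
        return out

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["chains"] = list(self.chains)
        d["skew_genes"] = list(self.skew_genes)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "StudyDesign":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["chains"] = tuple(d.get("chains", ("TRA", "TRB")))
        d["skew_genes"] = tuple(d.get("skew_genes", ()))
        return cls(**d)


@dataclass
class SimulatedClone:
    """Ground-truth clone: a V-J rearrangement with its junction and abundances."""

    clone_id: str
    chain: str
    v_name: str
    j_name: str
    junction_insert: str
    cdr3_nt: str
    cdr3_aa: str
    in_frame: bool
    #: expected read fraction per sample type
    abundance: dict = field(default_factory=dict)

    @property
    def triple(self) -> tuple[str, str, str]:
        return (self.v_name, self.j_name, self.cdr3_aa)


def build_clone_read(v_segment: GeneSegment, j_segment: GeneSegment, junction_insert: str) -> str:
    """Amplicon read for a rearrangement: full V, the junction insert, full J.

    The derived CDR3 is the stretch from the V segment's Cys104 codon through
    the J segment's Phe118 codon inclusive.
    """
    if v_segment.chain != j_segment.chain:
        raise ChainMismatch(
            f"{v_segment.name} ({v_segment.chain}) and {j_segment.name} "
            f"({j_segment.chain}) are from different chains"
        )
    return v_segment.sequence + junction_insert + j_segment.sequence


def clone_cdr3(v_segment: GeneSegment, j_segment: GeneSegment, junction_insert: str) -> str:
    v_tail = v_segment.sequence[v_segment.anchor_offset :]
    j_head = j_segment.sequence[: j_segment.anchor_offset + 3]
    return v_tail + junction_insert + j_head


def apply_sequencing_error(reads: Sequence[str], rate: float, seed: int) -> list[str]:
    """Substitute each base independently with probability ``rate``.

    Substitutions are uniform over the three alternative bases and
    deterministic given the seed.  The same uniform draw decides both whether
    a base is hit and which alternative replaces it, so runs at a lower rate
    corrupt a subset of the positions corrupted at a higher rate under the
    same seed (monotone coupling).
    """
    if not 0.0 <= rate < 1.0:
        raise SimulationError("rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    out = []
    for read in reads:
        u = rng.random(len(read))
        if rate == 0.0:
            out.append(read)
            continue
        hit = np.flatnonzero(u < rate)
        if hit.size == 0:
            out.append(read)
            continue
        arr = np.frombuffer(read.encode(), dtype="S1").astype("U1").copy()
        # which of the 3 alternatives, from the same uniform draw
        alt_idx = np.minimum((u[hit] / rate * 3).astype(int), 2)
        for pos, k in zip(hit, alt_idx):
            alts = [b for b in "ACGT" if b != arr[pos]]
            arr[pos] = alts[k]
        out.append("".join(arr))
    return out


@dataclass
class SimulatedStudy:
    """Everything the simulator knows: design, truth tables and reads."""

    design: StudyDesign
    reference: GermlineReference
    clones: list[SimulatedClone]
    #: realized read counts: DataFrame [sample_id, chain, clone_id, count]
    truth_counts: pd.DataFrame
    #: per sample_id: list of (read_id, sequence), chains mixed
    reads: dict | None

    def clone_by_id(self, clone_id: str) -> SimulatedClone:
        return self._index[clone_id]

    def __post_init__(self):
        self._index = {c.clone_id: c for c in self.clones}

    def truth_sample(self, sample_id: str, chain: str) -> RepertoireSample:
        """Ground-truth clonotype table for one (sample, chain), built from
        the realized read counts."""
        sub = self.truth_counts[
            (self.truth_counts["sample_id"] == sample_id)
            & (self.truth_counts["chain"] == chain)
        ]
        counts: dict[tuple, int] = {}
        junctions: dict[tuple, str] = {}
        for row in sub.itertuples():
            clone = self.clone_by_id(row.clone_id)
            key = (clone.v_name, clone.j_name, clone.cdr3_aa, clone.in_frame)
            counts[key] = counts.get(key, 0) + int(row.count)
            junctions[key] = clone.cdr3_nt
        table = build_sample_table(counts, junctions, sample_id)
        group, tissue, rep = sample_id.split("_")
        return RepertoireSample(
            sample_id=sample_id,
            chain=chain,
            group=group,
            tissue=tissue,
            replicate=int(rep),
            clonotypes=table,
            assigned_reads=int(sum(counts.values())),
            inframe_reads=int(sum(n for (v, j, aa, f), n in counts.items() if f)),
        )

    def truth_samples(self, chain: str) -> dict[str, RepertoireSample]:
        return {
            sid: self.truth_sample(sid, chain)
            for _st, sid in self.design.sample_ids()
        }


def _zipf_weights(k: int, exponent: float, head: int) -> np.ndarray:
    """Zipf-law weights for the expanded head, uniform for the tail."""
    ranks = np.arange(1, k + 1, dtype=float)
    w = np.minimum(ranks, head) ** (-exponent)
    return w / w.sum()


def _draw_insert(rng: np.random.Generator, in_frame: bool, max_codons: int) -> str:
    if in_frame:
        n = 3 * int(rng.integers(0, max_codons + 1))
    else:
        n = int(rng.integers(0, 3 * max_codons + 1))
        if n % 3 == 0:
            n += int(rng.integers(1, 3))
    return "".join(rng.choice(_BASES, size=n)) if n else ""


def _gene_weights(names: list[str], skew: dict[str, float]) -> np.ndarray:
    w = np.array([skew.get(nm, 1.0) for nm in names], dtype=float)
    return w / w.sum()


class _CloneFactory:
    """Draws unique clones (unique (V, J, CDR3aa) triples) for one chain."""

    def __init__(self, reference: GermlineReference, chain: str, design: StudyDesign,
                 rng: np.random.Generator):
        self.ref = reference
        self.chain = chain
        self.design = design
        self.rng = rng
        self.v_names = reference.gene_names(chain, "V")
        self.j_names = reference.gene_names(chain, "J")
        skew = {
            g: design.skew_factor
            for g in design.skew_genes
            if g in reference and reference[g].chain == chain
        }
        for g in design.skew_genes:
            if g not in reference:
                raise UnknownGene(f"skew gene {g} not in reference")
        self.w_v_plain = _gene_weights(self.v_names, {})
        self.w_j_plain = _gene_weights(self.j_names, {})
        self.w_v_skew = _gene_weights(self.v_names, {g: f for g, f in skew.items() if self.ref[g].segment_type == "V"})
        self.w_j_skew = _gene_weights(self.j_names, {g: f for g, f in skew.items() if self.ref[g].segment_type == "J"})
        self.used: set[tuple[str, str, str]] = set()
        self.serial = 0

    def reserve(self, triple: tuple[str, str, str]) -> None:
        self.used.add(triple)

    def make(self, skewed: bool) -> SimulatedClone:
        d = self.design
        for _attempt in range(500):
            v = self.rng.choice(self.v_names, p=self.w_v_skew if skewed else self.w_v_plain)
            j = self.rng.choice(self.j_names, p=self.w_j_skew if skewed else self.w_j_plain)
            in_frame = bool(self.rng.random() >= d.out_of_frame_fraction)
            insert = _draw_insert(self.rng, in_frame, d.max_insert_codons)
            cdr3 = clone_cdr3(self.ref[v], self.ref[j], insert)
            aa, frame_ok = translate_cdr3(cdr3)
            if in_frame and not frame_ok:
                continue  # stop codon landed in the junction; redraw
            triple = (str(v), str(j), aa)
            if triple in self.used:
                continue
            self.used.add(triple)
            self.serial += 1
            return SimulatedClone(
                clone_id=f"{self.chain}c{self.serial:05d}",
                chain=self.chain,
                v_name=str(v),
                j_name=str(j),
                junction_insert=insert,
                cdr3_nt=cdr3,
                cdr3_aa=aa,
                in_frame=frame_ok,
            )
        raise CloneSpaceExhausted(
            f"could not draw a new unique clone for chain {self.chain} "
            f"after 500 attempts ({len(self.used)} clones taken)"
        )


def _inkt_clone(reference: GermlineReference, chain: str) -> SimulatedClone:
    v = reference[INKT_V_GENE]
    j = reference[INKT_J_GENE]
    cdr3 = clone_cdr3(v, j, _INKT_INSERT)
    aa, in_frame = translate_cdr3(cdr3)
    if aa != INKT_JUNCTION_AA or not in_frame:  # pragma: no cover - reference contract
        raise SimulationError(
            f"reference iNKT genes do not produce {INKT_JUNCTION_AA}: got {aa}"
        )
    return SimulatedClone(
        clone_id=f"{chain}ciNKT",
        chain=chain,
        v_name=INKT_V_GENE,
        j_name=INKT_J_GENE,
        junction_insert=_INKT_INSERT,
        cdr3_nt=cdr3,
        cdr3_aa=aa,
        in_frame=True,
    )


def _spiked_abundances(
    order: list[SimulatedClone],
    weights: np.ndarray,
    inkt: SimulatedClone | None,
    inkt_target: float,
) -> dict[str, float]:
    """Abundance per clone_id, with the iNKT clone inserted so that its
    expected fraction of in-frame reads equals ``inkt_target``."""
    ab = {c.clone_id: float(w) for c, w in zip(order, weights)}
    if inkt is None or inkt_target <= 0.0:
        return ab
    inframe_mass = sum(w for c, w in zip(order, weights) if c.in_frame)
    f = inkt_target
    a = f * inframe_mass / (1.0 - f * (1.0 - inframe_mass))
    ab = {cid: w * (1.0 - a) for cid, w in ab.items()}
    ab[inkt.clone_id] = a
    return ab


def simulate_study(
    design: StudyDesign,
    reference: GermlineReference,
    emit_reads: bool = True,
) -> SimulatedStudy:
    """Draw the ground-truth clone table and (optionally) per-sample reads.

    All randomness flows from ``design.seed``; each sample's multinomial draw
    uses a seed derived from the global seed and a fixed sample index, so
    adding replicates never reshuffles existing samples.
    """
    design.validate()
    if INKT_V_GENE not in reference or INKT_J_GENE not in reference:
        raise UnknownGene(
            f"reference must contain {INKT_V_GENE} and {INKT_J_GENE}"
        )
    all_clones: list[SimulatedClone] = []
    type_pools: dict[str, dict[str, list[SimulatedClone]]] = {st: {} for st in SAMPLE_TYPES}
    type_abund: dict[str, dict[str, dict[str, float]]] = {st: {} for st in SAMPLE_TYPES}

    for chain_idx, chain in enumerate(design.chains):
        rng = np.random.default_rng(np.random.SeedSequence((design.seed, 1, chain_idx)))
        factory = _CloneFactory(reference, chain, design, rng)
        spike = chain == "TRA" and any(f > 0 for f in design.inkt_frequency.values())
        inkt = _inkt_clone(reference, chain) if spike else None
        if inkt is not None:
            factory.reserve(inkt.triple)

        k_om = design.clone_counts["ACM_OM"]
        n_share_ly = int(round(design.share_acm_ly * k_om))
        acm_om = [factory.make(skewed=(i < n_share_ly)) for i in range(k_om)]
        shared_ly = acm_om[:n_share_ly]  # top-biased: the most-expanded clones
        n_icm_ly = int(round(design.share_icm_ly * k_om))
        n_icm_om = int(round(design.share_icm_om * k_om))
        shared_icm_ly = list(
            rng.choice(acm_om, size=n_icm_ly, replace=False)
        ) if n_icm_ly else []
        shared_icm_om = list(
            rng.choice(acm_om, size=n_icm_om, replace=False)
        ) if n_icm_om else []

        def _fill(shared: list[SimulatedClone], total: int) -> list[SimulatedClone]:
            if total < len(shared):
                raise SimulationError(
                    f"clone count {total} smaller than its shared-clone set "
                    f"({len(shared)})"
                )
            return shared + [factory.make(skewed=False) for _ in range(total - len(shared))]

        pools = {
            "ACM_OM": acm_om,
            "ACM_LY": _fill(shared_ly, design.clone_counts["ACM_LY"]),
            "ICM_LY": _fill(shared_icm_ly, design.clone_counts["ICM_LY"]),
            "ICM_OM": _fill(shared_icm_om, design.clone_counts["ICM_OM"]),
        }
        new_ids = {c.clone_id for c in all_clones}
        for st in SAMPLE_TYPES:
            order = pools[st]
            weights = _zipf_weights(len(order), design.zipf_exponent, design.zipf_head)
            ab = _spiked_abundances(
                order, weights, inkt, design.inkt_frequency.get(st, 0.0)
            )
            pool = list(order) + ([inkt] if inkt is not None and inkt.clone_id in ab else [])
            type_pools[st][chain] = pool
            type_abund[st][chain] = ab
            for c in pool:
                if c.clone_id not in new_ids:
                    new_ids.add(c.clone_id)
                    all_clones.append(c)

    for clone in all_clones:
        clone.abundance = {
            st: type_abund[st].get(clone.chain, {}).get(clone.clone_id, 0.0)
            for st in SAMPLE_TYPES
        }

    # realized counts and reads, per sample
    count_rows = []
    reads: dict[str, list[tuple[str, str]]] | None = {} if emit_reads else None
    seq_cache: dict[str, str] = {}
    for st_idx, st in enumerate(SAMPLE_TYPES):
        for rep in range(1, design.replicates + 1):
            sample_id = f"{st}_{rep}"
            sample_reads: list[tuple[str, str]] = []
            for chain_idx, chain in enumerate(design.chains):
                sample_key = (design.seed, 2, st_idx * 100 + rep, chain_idx)
                rng_s = np.random.default_rng(np.random.SeedSequence(sample_key))
                pool = type_pools[st][chain]
                ab = type_abund[st][chain]
                p = np.array([ab[c.clone_id] for c in pool], dtype=float)
                p = p / p.sum()
                counts = rng_s.multinomial(design.reads_per_sample, p)
                for clone, n in zip(pool, counts):
                    if n == 0:
                        continue
                    count_rows.append(
                        {
                            "sample_id": sample_id,
                            "chain": chain,
                            "clone_id": clone.clone_id,
                            "count": int(n),
                        }
                    )
                    if emit_reads:
                        seq = seq_cache.get(clone.clone_id)
                        if seq is None:
                            seq = build_clone_read(
                                reference[clone.v_name],
                                reference[clone.j_name],
                                clone.junction_insert,
                            )
                            seq_cache[clone.clone_id] = seq
                        sample_reads.extend(
                            (f"{sample_id}|{chain}|{clone.clone_id}|{k}", seq)
                            for k in range(int(n))
                        )
            if emit_reads:
                if design.error_rate > 0.0:
                    err_seed = int(
                        np.random.SeedSequence(
                            (design.seed, 4, st_idx * 100 + rep)
                        ).generate_state(1)[0]
                        % (2**31)
                    )
                    seqs = apply_sequencing_error(
                        [s for _i, s in sample_reads], design.error_rate, err_seed
                    )
                    sample_reads = [
                        (rid, s) for (rid, _), s in zip(sample_reads, seqs)
                    ]
                reads[sample_id] = sample_reads

    truth_counts = pd.DataFrame(
        count_rows, columns=["sample_id", "chain", "clone_id", "count"]
    )
    return SimulatedStudy(
        design=design,
        reference=reference,
        clones=all_clones,
        truth_counts=truth_counts,
        reads=reads,
    )


def write_study(study: SimulatedStudy, out_dir) -> dict[str, Path]:
    """Write one FASTA per sample plus ground truth, sample sheet and design."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if study.reads is None:
        raise SimulationError("study was simulated with emit_reads=False")
    paths: dict[str, Path] = {}
    sheet_rows = []
    for st, sample_id in study.design.sample_ids():
        group, tissue = st.split("_")
        fasta = out / f"{sample_id}.fasta"
        with open(fasta, "w") as fh:
            for rid, seq in study.reads[sample_id]:
                fh.write(f">{rid}\n{seq}\n")
        paths[sample_id] = fasta
        sheet_rows.append(
            {
                "sample_id": sample_id,
                "group": group,
                "tissue": tissue,
                "replicate": int(sample_id.rsplit("_", 1)[1]),
                "filename": fasta.name,
            }
        )
    pd.DataFrame(sheet_rows).to_csv(out / "samples.tsv", sep="\t", index=False)
    clone_rows = []
    for c in study.clones:
        row = {
            "clone_id": c.clone_id,
            "chain": c.chain,
            "v_name": c.v_name,
            "j_name": c.j_name,
            "junction_insert": c.junction_insert,
            "cdr3_nt": c.cdr3_nt,
            "cdr3_aa": c.cdr3_aa,
            "in_frame": c.in_frame,
        }
        row.update({f"abundance_{st}": c.abundance.get(st, 0.0) for st in SAMPLE_TYPES})
        clone_rows.append(row)
    pd.DataFrame(clone_rows).to_csv(out / "clones.tsv", sep="\t", index=False)
    study.truth_counts.to_csv(out / "truth_counts.tsv", sep="\t", index=False)
    study.design.to_yaml(out / "design.yaml")
    paths["samples"] = out / "samples.tsv"
    paths["clones"] = out / "clones.tsv"
    paths["truth_counts"] = out / "truth_counts.tsv"
    paths["design"] = out / "design.yaml"
    return paths
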