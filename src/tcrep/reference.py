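"""Germline V/J segment reference: loading, validation and indexing.

A reference is the set of germline gene segments that reads are aligned
against.  Each V segment carries the 0-based offset of its conserved Cys104
codon and each J segment the offset of its conserved Phe118 codon (with the
following Gly119 codon used as a validation anchor).  The CDR3 junction of a
rearranged read runs from the first base of the projected Cys104 codon
through the last base of the projected Phe118 codon, inclusive.

On disk a reference is a plain multi-FASTA of segment nucleotide sequences
plus a tab-separated anchor table with columns ``name``, ``chain``,
``segment_type`` and ``anchor_offset`` (offsets are 0-based positions of the
codon's first base).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

CHAINS = ("TRA", "TRB")
SEGMENT_TYPES = ("V", "J")

_ANCHOR_RESIDUE = {"V": "C", "J": "F"}
ANCHOR_TABLE_COLUMNS = ("name", "chain", "segment_type", "anchor_offset")


class ReferenceValidationError(ValueError):
    """Raised when one or more reference records violate an invariant.

    Carries every problem found, not only the first, in ``problems``.
    """

    def __init__(self, problems: Sequence[str]):
        self.problems = list(problems)
        super().__init__(
            f"{len(self.problems)} reference validation problem(s):\n"
            + "\n".join(f"  - {p}" for p in self.problems)
        )


def collapse_allele(name: str) -> str:
    """Strip an IMGT allele suffix (``*01``) down to the gene-level name.

    Hyphenated gene names (TRAV7D-2, TRBJ2-7) are gene-level already and are
    left intact.
    """
    return name.split("*", 1)[0]


def _translate_codon(codon: str) -> str:
    if "N" in codon:
        return "X"
    return str(Seq(codon).translate())


@dataclass(frozen=True)
class GeneSegment:
    """One germline V or J segment with its CDR3 anchor coordinate."""

    name: str
    chain: str
    segment_type: str
    sequence: str
    anchor_offset: int

    @property
    def gly119_offset(self) -> int | None:
        """Offset of the Gly119 codon (J segments only); always anchor + 3."""
        return self.anchor_offset + 3 if self.segment_type == "J" else None

    @property
    def anchor_codon(self) -> str:
        return self.sequence[self.anchor_offset : self.anchor_offset + 3]

    def problems(self) -> list[str]:
        """Return all invariant violations for this segment (empty if valid)."""
        out: list[str] = []
        if self.chain not in CHAINS:
            out.append(f"{self.name}: unknown chain {self.chain!r}")
        if self.segment_type not in SEGMENT_TYPES:
            out.append(f"{self.name}: unknown segment_type {self.segment_type!r}")
            return out
        bad = set(self.sequence) - set("ACGT")
        if bad:
            out.append(
                f"{self.name}: ambiguity/invalid characters {sorted(bad)} in "
                "reference sequence (only A/C/G/T allowed in the reference)"
            )
            return out
        min_len = self.anchor_offset + 3
        if self.segment_type == "J":
            min_len += 3  # room for Gly119
        if self.anchor_offset < 0 or len(self.sequence) < min_len:
            out.append(
                f"{self.name}: sequence length {len(self.sequence)} too short "
                f"for anchor_offset {self.anchor_offset}"
            )
            return out
        want = _ANCHOR_RESIDUE[self.segment_type]
        got = _translate_codon(self.anchor_codon)
        if got != want:
            out.append(
                f"{self.name}: anchor residue mismatch — codon "
                f"{self.anchor_codon} encodes {got!r}, expected {want!r}"
            )
        if self.segment_type == "J":
            gly = self.sequence[self.gly119_offset : self.gly119_offset + 3]
            if _translate_codon(gly) != "G":
                out.append(
                    f"{self.name}: Gly119 codon {gly} does not encode glycine"
                )
        return out


class GermlineReference:
    """An indexed collection of validated GeneSegments."""

    def __init__(self, segments: Iterable[GeneSegment]):
        self._segments: dict[str, GeneSegment] = {}
        problems: list[str] = []
        for seg in segments:
            seg = GeneSegment(
                name=collapse_allele(seg.name),
                chain=seg.chain,
                segment_type=seg.segment_type,
                sequence=seg.sequence.upper(),
                anchor_offset=seg.anchor_offset,
            )
            if seg.name in self._segments:
                problems.append(f"{seg.name}: duplicate gene name")
                continue
            probs = seg.problems()
            if probs:
                problems.extend(probs)
                continue
            self._segments[seg.name] = seg
        for chain in CHAINS:
            present = {s.segment_type for s in self._segments.values() if s.chain == chain}
            if present and present != set(SEGMENT_TYPES):
                missing = set(SEGMENT_TYPES) - present
                problems.append(
                    f"chain {chain}: no {'/'.join(sorted(missing))} segments loaded"
                )
        if problems:
            raise ReferenceValidationError(problems)
        if not self._segments:
            raise ReferenceValidationError(["reference is empty"])

    def __len__(self) -> int:
        return len(self._segments)

    def __contains__(self, name: str) -> bool:
        return collapse_allele(name) in self._segments

    def __getitem__(self, name: str) -> GeneSegment:
        return self._segments[collapse_allele(name)]

    def __iter__(self):
        return iter(self._segments.values())

    def segments(self, chain: str, segment_type: str) -> list[GeneSegment]:
        return [
            s
            for s in self._segments.values()
            if s.chain == chain and s.segment_type == segment_type
        ]

    def gene_names(self, chain: str, segment_type: str) -> list[str]:
        return sorted(s.name for s in self.segments(chain, segment_type))

    def counts(self) -> dict[tuple[str, str], int]:
        """Segment counts per (chain, segment_type)."""
        out: dict[tuple[str, str], int] = {}
        for s in self._segments.values():
            key = (s.chain, s.segment_type)
            out[key] = out.get(key, 0) + 1
        return out


def load_reference(segment_fasta_path, anchor_table_path) -> GermlineReference:
    """Load and validate a germline reference from FASTA + anchor TSV.

    Every violation (missing anchor rows, anchor-residue mismatches,
    duplicates, ambiguity codes) is collected and reported together in a
    single :class:`ReferenceValidationError`.
    """
    problems: list[str] = []
    anchors: dict[str, dict] = {}
    with open(anchor_table_path, newline="") as fh:
        lines = [ln for ln in fh if not ln.startswith("#")]
        reader = csv.DictReader(lines, delimiter="\t")
        cols = tuple(reader.fieldnames or ())
        missing_cols = set(ANCHOR_TABLE_COLUMNS) - set(cols)
        if missing_cols:
            raise ReferenceValidationError(
                [f"anchor table missing columns: {sorted(missing_cols)}"]
            )
        for row in reader:
            name = collapse_allele(row["name"].strip())
            if name in anchors:
                problems.append(f"{name}: duplicate row in anchor table")
            anchors[name] = row

    segments: list[GeneSegment] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(segment_fasta_path), "fasta"):
        name = collapse_allele(rec.id)
        if name in seen:
            problems.append(f"{name}: duplicate gene name")
            continue
        seen.add(name)
        row = anchors.get(name)
        if row is None:
            problems.append(f"{name}: no row in anchor table for FASTA record")
            continue
        try:
            offset = int(row["anchor_offset"])
        except ValueError:
            problems.append(f"{name}: non-integer anchor_offset {row['anchor_offset']!r}")
            continue
        segments.append(
            GeneSegment(
                name=name,
                chain=row["chain"].strip(),
                segment_type=row["segment_type"].strip(),
                sequence=str(rec.seq).upper(),
                anchor_offset=offset,
            )
        )
    for name in anchors:
        if name not in seen:
            problems.append(f"{name}: anchor row has no FASTA record")
    try:
        ref = GermlineReference(segments)
    except ReferenceValidationError as err:
        raise ReferenceValidationError(problems + err.problems) from None
    if problems:
        raise ReferenceValidationError(problems)
    return ref


def write_reference(reference: GermlineReference, segment_fasta_path, anchor_table_path) -> None:
    """Write a reference back to FASTA + anchor TSV (round-trip safe)."""
    records = [
        SeqRecord(Seq(s.sequence), id=s.name, description="")
        for s in reference
    ]
    SeqIO.write(records, str(segment_fasta_path), "fasta")
    with open(anchor_table_path, "w", newline="") as fh:
        fh.write(
            "# anchor_offset: 0-based offset of the first base of the anchor "
            "codon (Cys104 for V, Phe118 for J; Gly119 follows at +3)\n"
        )
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(ANCHOR_TABLE_COLUMNS)
        for s in reference:
            writer.writerow([s.name, s.chain, s.segment_type, s.anchor_offset])


# ---------------------------------------------------------------------------
# Synthetic full-gene-space reference
# ---------------------------------------------------------------------------

#: murine gene-space sizes per locus (full "of N genes" denominators)
FULL_GENE_SPACE = {"TRAV": 112, "TRAJ": 51, "TRBV": 23, "TRBJ": 13}

#: genes that must exist in every synthetic reference: the invariant iNKT
#: rearrangement (TRAV11/TRAV11D-TRAJ18) and the default skew-spike genes.
REQUIRED_GENES = {
    "TRAV": ("TRAV11", "TRAV11D", "TRAV7D-2", "TRAV14-1"),
    "TRAJ": ("TRAJ18",),
    "TRBV": ("TRBV5",),
    "TRBJ": ("TRBJ2-7",),
}

# All V segments share one length (likewise J) so that an exact full-length
# substring hit is provably the unique alignment optimum among candidates.
_V_LEN = 81
_J_LEN = 48
_STOPS = {"TAA", "TAG", "TGA"}

# TRAJ18 germline head encoding DRGSALGRLH, so that TRAV11D's CVV tail plus a
# single glycine insert yields the canonical murine iNKT junction
# CVVGDRGSALGRLHF.
_TRAJ18_HEAD = "GATAGAGGAAGCGCCCTGGGAAGACTCCAC"
_TRAV11D_TAIL = "TGTGTGGTG"  # CVV


def _axis_names(axis: str, n: int) -> list[str]:
    """Deterministic IMGT-style name list for one gene axis."""
    required = list(REQUIRED_GENES[axis])
    names: list[str] = []
    if axis == "TRAV":
        for fam in range(1, 24):
            for suf in ("", "-1", "-2", "D-1", "D-2"):
                names.append(f"TRAV{fam}{suf}")
    elif axis == "TRAJ":
        names = [f"TRAJ{i}" for i in range(2, 62)]
    elif axis == "TRBV":
        names = [f"TRBV{i}" for i in range(1, 32)]
    elif axis == "TRBJ":
        names = [f"TRBJ1-{i}" for i in range(1, 8)] + [f"TRBJ2-{i}" for i in range(1, 8)]
    else:  # pragma: no cover - guarded by callers
        raise ValueError(f"unknown gene axis {axis!r}")
    out = list(required)
    for nm in names:
        if len(out) >= n:
            break
        if nm not in out:
            out.append(nm)
    if len(out) < n:
        raise ValueError(f"cannot make {n} names for axis {axis}")
    return sorted(out)


def _random_codons(rng: np.random.Generator, n: int) -> str:
    """n random non-stop codons."""
    out = []
    while len(out) < n:
        codon = "".join(rng.choice(list("ACGT"), size=3))
        if codon not in _STOPS:
            out.append(codon)
    return "".join(out)


def synthetic_reference(
    n_trav: int | None = None,
    n_traj: int | None = None,
    n_trbv: int | None = None,
    n_trbj: int | None = None,
    seed: int = 2023,
) -> GermlineReference:
    """Build a self-contained synthetic germline reference.

    A synthetic stand-in for a curated germline download: random segment
    sequences with valid Cys104 / Phe118 / Gly119 anchors, the canonical
    iNKT genes (TRAV11, TRAV11D, TRAJ18) wired so that the invariant
    CVVGDRGSALGRLHF junction is constructible, and full murine gene-space
    sizes by default so "of N genes" denominators are meaningful.

    Axis sizes are configurable to produce small toy references for tests.
    """
    sizes = {
        "TRAV": n_trav or FULL_GENE_SPACE["TRAV"],
        "TRAJ": n_traj or FULL_GENE_SPACE["TRAJ"],
        "TRBV": n_trbv or FULL_GENE_SPACE["TRBV"],
        "TRBJ": n_trbj or FULL_GENE_SPACE["TRBJ"],
    }
    rng = np.random.default_rng(np.random.SeedSequence((seed, 7001)))
    segments: list[GeneSegment] = []
    seen_seqs: set[str] = set()
    for axis, n in sizes.items():
        chain, seg_type = axis[:3], axis[3]
        for name in _axis_names(axis, n):
            while True:
                if seg_type == "V":
                    if name == "TRAV11D":
                        tail = _TRAV11D_TAIL
                    else:
                        # Cys104 codon plus 0 or 3 nt of germline past the anchor
                        extra = int(rng.integers(0, 2)) * 3
                        tail = "TGT" + _random_codons(rng, extra // 3)
                    body_len = _V_LEN - len(tail)
                    seq = _random_codons(rng, body_len // 3) + tail
                    anchor = len(seq) - len(tail)
                else:
                    if name == "TRAJ18":
                        head = _TRAJ18_HEAD
                    else:
                        head_len = int(rng.choice([9, 12, 15, 18]))
                        head = _random_codons(rng, head_len // 3)
                    tail_len = _J_LEN - len(head) - 6
                    seq = head + "TTT" + "GGT" + _random_codons(rng, tail_len // 3)
                    anchor = len(head)
                if seq not in seen_seqs:
                    seen_seqs.add(seq)
                    break
            segments.append(
                GeneSegment(
                    name=name,
                    chain=chain,
                    segment_type=seg_type,
                    sequence=seq,
                    anchor_offset=anchor,
                )
            )
    return GermlineReference(segments)


def toy_reference(seed: int = 2023) -> GermlineReference:
    """A small reference (8 TRAV, 6 TRAJ, 5 TRBV, 4 TRBJ) for tests/demos."""
    return synthetic_reference(n_trav=8, n_traj=6, n_trbv=5, n_trbj=4, seed=seed)
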