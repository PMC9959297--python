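# tcrep

TCR repertoire analysis for amplicon sequencing of the murine allergic /
irritant contact-mucositis study design, with a ground-truth read simulator.

`tcrep` is aimed at immunologists comparing T-cell receptor (TCR) repertoires
between an allergic group (sensitized + challenged; **ACM**) and an irritant
control group (challenged only; **ICM**) across two tissues — buccal oral
mucosa (**OM**) and cervical lymph node (**Ly**) — with replicate animals per
sample type. It covers the complete path from raw TRA/TRB amplicon reads to
the repertoire-level statistics such studies report:

- **Clonotype calling.** Reads are locally aligned against a germline V/J
  segment reference (match +1 / mismatch −1 / gap −2; best gene wins, ties
  break to the lexicographically smaller name). The CDR3 junction is excised
  between the conserved Cys104 codon of the V segment and the conserved
  Phe118 codon of the J segment (both inclusive; the following Gly119 is used
  as a validation anchor), translated with the standard genetic code, and
  reads are aggregated into **unique reads** (clonotypes) keyed by the
  (V gene, J gene, CDR3 amino-acid sequence) triple, with copy counts, ranks
  and percent frequencies over in-frame reads.
- **Diversity.** The Shannon index H = −Σᵢ pᵢ ln pᵢ over in-frame clonotype
  read proportions (nats by default, bits optional), and replicate-averaged
  V–J combination frequency matrices.
- **Commonality.** Replicate-pooled group repertoires (union of triples; mean
  %frequency with absence as zero), top-N commonality tables, Venn-style
  sharing counts of ACM OM unique reads with the other three sample types,
  and two narrowing filters: clonotypes *increased in ACM Ly over ICM*
  (strictly higher mean frequency) and clonotypes *present only in ACM Ly*.
  The identity `only ⊆ increased ⊆ shared` holds by construction.
- **Gene-usage skew.** Per-gene unique-read counts of a filtered clonotype
  set; the mean is taken over *occupied* genes (count ≥ 1), the SD is the
  sample (n−1) standard deviation over occupied genes, and genes whose count
  exceeds mean + 2·SD are flagged as over-used.
- **Invariant iNKT detection.** A TRA clonotype is the canonical murine
  invariant NKT rearrangement iff V ∈ {TRAV11, TRAV11D}, J = TRAJ18 and the
  junction is `CVVGDRGSALGRLHF`; its summed in-frame %frequency is reported
  per sample.
- **Simulation.** `simulate_study` draws per-sample-type clone pools with a
  Zipf-like clone-size law, configurable top-biased sharing between ACM OM
  and ACM Ly (with optional 5× V/J usage skew planted in shared clones), a
  deliberately smaller ICM OM pool (lower diversity), iNKT spike-ins at
  configurable in-frame frequencies, and an optional per-base substitution
  error model. Reads carry their ground-truth clone id, so exact-recovery
  tests need no auxiliary files.

## Worked example

```python
from tcrep import (StudyDesign, simulate_study, synthetic_reference, call_sample,
                   shannon_index, build_group_repertoire, venn_counts, inkt_frequency)

reference = synthetic_reference()          # full murine gene space, synthetic sequences
design = StudyDesign(chains=("TRA",), reads_per_sample=5000,
                     clone_counts={"ACM_OM": 400, "ACM_LY": 400,
                                   "ICM_OM": 80, "ICM_LY": 250},
                     seed=7)
study = simulate_study(design, reference)

samples = {}
for _type, sid in design.sample_ids():
    group, tissue, rep = sid.split("_")
    res = call_sample(study.reads[sid], reference, sid, group, tissue, int(rep))
    samples[sid] = res.samples["TRA"]

print(samples["ACM_OM_1"].productive().head(3)
      [["v_call", "j_call", "junction_aa", "duplicate_count",
        "frequency_pct", "rank"]].to_string(index=False))

h_acm = shannon_index(samples["ACM_OM_1"]).shannon_index
h_icm = shannon_index(samples["ICM_OM_1"]).shannon_index
print(f"Shannon H: ACM OM {h_acm:.3f} vs ICM OM {h_icm:.3f}")

groups = {t: build_group_repertoire([samples[f"{t}_{r}"] for r in (1, 2, 3)])
          for t in ("ACM_OM", "ACM_LY", "ICM_LY", "ICM_OM")}
vc = venn_counts(groups["ACM_OM"], groups["ACM_LY"],
                 groups["ICM_LY"], groups["ICM_OM"])
print(f"ACM OM unique reads: {vc.acm_om_size}; shared with ACM Ly: "
      f"{vc.shared_acm_ly}; increased in ACM Ly: {vc.increased_in_acm_ly}; "
      f"only in ACM Ly: {vc.only_in_acm_ly}")
print(f"iNKT frequency: ICM OM {inkt_frequency(samples['ICM_OM_1']):.2f}%, "
      f"ACM OM {inkt_frequency(samples['ACM_OM_1']):.3f}%")
```

Output:

```
   v_call j_call junction_aa  duplicate_count  frequency_pct  rank
    TRAV2  TRAJ9  CTGVPPRGCF              315       9.229417     2
 TRAV10-1 TRAJ46      CPPYTF              209       6.123645     3
TRAV16D-1 TRAJ24 CSYAGNEPCCF              157       4.600059     4
Shannon H: ACM OM 5.115 vs ICM OM 2.815
ACM OM unique reads: 322; shared with ACM Ly: 93; increased in ACM Ly: 90; only in ACM Ly: 87
iNKT frequency: ICM OM 0.89%, ACM OM 0.059%
```

Reading the numbers: the most-expanded productive ACM OM clonotype holds 9.2%
of that sample's in-frame reads (rank 1 here is an out-of-frame clonotype,
retained but excluded from frequencies). The allergic mucosa is far more
diverse than the irritant mucosa (H 5.1 vs 2.8 nats). Of the 322 unique reads
pooled over the three ACM OM replicates, 93 also occur in the draining lymph
node; narrowing to those with strictly higher frequency in ACM Ly than ICM Ly
leaves 90, and requiring absence from both ICM samples leaves 87 — the
nesting 87 ≤ 90 ≤ 93 always holds. The iNKT spike comes back close to its
planted in-frame frequencies (1% in ICM OM, 0.05% in ACM OM for this design).

## Command line

```bash
tcrep simulate --out study/ --seed 1           # synthetic study (reads + truth)
tcrep analyze --reference study/reference.fasta --anchors study/anchors.tsv \
              --reads-dir study/ --samples study/samples.tsv --out analysis/
tcrep full --config run.yaml --out run/        # simulate + analyze
tcrep fixture --preset small --seed 0 --out fx/  # <=1000-read test fixture
```

`analyze` accepts FASTA/FASTQ reads from any source; supply your own germline
reference as a multi-FASTA plus an anchor TSV (`name  chain  segment_type
anchor_offset`, 0-based offsets of the Cys104/Phe118 codons). The bundled
synthetic reference is used when no reference is given.

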