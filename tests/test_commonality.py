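"""Cross-sample sharing, Venn narrowing, gene-usage skew, iNKT detection."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tcrep.calling import aggregate_clonotypes
from tcrep.commonality import (
    CommonalityError,
    GroupRepertoire,
    build_group_repertoire,
    detect_inkt,
    gene_usage_skew,
    increased_set,
    inkt_frequency,
    only_set,
    top_commonality,
    venn_counts,
)
from tcrep.simulate import SAMPLE_TYPES, StudyDesign, simulate_study


def make_sample(clone_counts, sample_id="s1", group="ACM", tissue="OM",
                replicate=1, chain="TRA"):
    """clone_counts: {(v, j, aa): copies}."""
    records = []
    for (v, j, aa), n in clone_counts.items():
        records.extend([(v, j, "TGT" + "GCA" * (len(aa) - 2) + "TTT", aa, True)] * n)
    return aggregate_clonotypes(records, sample_id=sample_id, group=group,
                                tissue=tissue, replicate=replicate, chain=chain)


def group_from_freqs(freqs, group="ACM", tissue="OM", chain="TRA"):
    return GroupRepertoire(group=group, tissue=tissue, chain=chain,
                           n_replicates=3, mean_frequency=dict(freqs))


T = lambda i: (f"TRAV{i}", "TRAJ18", f"CA{i}F")  # noqa: E731


# -- build_group_repertoire ---------------------------------------------------

def test_disjoint_singletons_union_of_three():
    reps = [make_sample({T(i): 5}, sample_id=f"r{i}", replicate=i) for i in (1, 2, 3)]
    g = build_group_repertoire(reps)
    assert len(g.clonotypes) == 3
    # each clonotype was at 100% in its own replicate, absent in the others
    for t in g.clonotypes:
        assert g.frequency(t) == pytest.approx(100.0 / 3)


def test_mean_frequency_counts_absence_as_zero():
    a = make_sample({T(1): 3, T(2): 97}, replicate=1)
    b = make_sample({T(2): 100}, replicate=2)
    c = make_sample({T(1): 3, T(2): 97}, replicate=3)
    g = build_group_repertoire([a, b, c])
    assert g.frequency(T(1)) == pytest.approx((3 + 0 + 3) / 3)


def test_identical_replicates_union_is_idempotent():
    reps = [make_sample({T(1): 5, T(2): 5}, replicate=i) for i in (1, 2, 3)]
    g = build_group_repertoire(reps)
    assert len(g.clonotypes) == 2


def test_mixed_group_tissue_rejected():
    a = make_sample({T(1): 5}, group="ACM")
    b = make_sample({T(1): 5}, group="ICM")
    with pytest.raises(CommonalityError, match="mixed"):
        build_group_repertoire([a, b])


# -- detect_inkt / inkt_frequency ---------------------------------------------

@pytest.mark.parametrize(
    "v,j,aa,expected",
    [
        ("TRAV11D", "TRAJ18", "CVVGDRGSALGRLHF", True),
        ("TRAV11", "TRAJ18", "CVVGDRGSALGRLHF", True),
        ("TRAV11D", "TRAJ18", "CVVGDRGSALGRLHG", False),
        ("TRAV14-1", "TRAJ18", "CVVGDRGSALGRLHF", False),
        ("TRAV11D", "TRAJ2", "CVVGDRGSALGRLHF", False),
    ],
)
def test_detect_inkt_truth_table(v, j, aa, expected):
    assert detect_inkt(v, j, aa) is expected


def test_detect_inkt_warns_on_trb():
    with pytest.warns(UserWarning):
        assert detect_inkt("TRAV11D", "TRAJ18", "CVVGDRGSALGRLHF", chain="TRB") is False


def test_inkt_frequency_zero_when_absent_and_100_when_pure():
    s = make_sample({T(1): 10})
    assert inkt_frequency(s) == 0.0
    pure = make_sample({("TRAV11D", "TRAJ18", "CVVGDRGSALGRLHF"): 10})
    assert inkt_frequency(pure) == pytest.approx(100.0)


# -- top_commonality -----------------------------------------------------------

def test_top_commonality_returns_all_when_fewer_than_n():
    ref = group_from_freqs({T(1): 5.0, T(2): 3.0})
    other = group_from_freqs({T(1): 1.0}, tissue="LY")
    tab = top_commonality(ref, [other], n=20)
    assert len(tab) == 2
    assert list(tab["rank"]) == [1, 2]
    assert bool(tab.loc[0, "shared_ACM_LY"]) is True
    assert bool(tab.loc[1, "shared_ACM_LY"]) is False
    assert tab.loc[1, "freq_ACM_LY"] == 0.0


def test_top_commonality_flags_inkt_row():
    inkt = ("TRAV11D", "TRAJ18", "CVVGDRGSALGRLHF")
    ref = group_from_freqs({T(1): 5.0, inkt: 1.0})
    others = [group_from_freqs({inkt: 2.0}, tissue="LY"),
              group_from_freqs({inkt: 0.5}, group="ICM", tissue="LY")]
    tab = top_commonality(ref, others, n=20)
    row = tab[tab["is_inkt"]]
    assert len(row) == 1
    assert row["junction_aa"].iloc[0] == "CVVGDRGSALGRLHF"
    assert (row[["freq_ACM_LY", "freq_ICM_LY"]].to_numpy() > 0).all()


# -- venn_counts --------------------------------------------------------------

def test_all_disjoint_sets_share_nothing():
    g = lambda freqs, gr, ti: group_from_freqs(freqs, group=gr, tissue=ti)  # noqa: E731
    vc = venn_counts(
        g({T(1): 1.0}, "ACM", "OM"),
        g({T(2): 1.0}, "ACM", "LY"),
        g({T(3): 1.0}, "ICM", "LY"),
        g({T(4): 1.0}, "ICM", "OM"),
    )
    assert (vc.shared_acm_ly, vc.shared_icm_ly, vc.shared_icm_om) == (0, 0, 0)
    assert vc.increased_in_acm_ly == 0 and vc.only_in_acm_ly == 0


def test_toy_membership_enumeration():
    # ACM OM {a,b,c}; ACM Ly {a,b}; ICM Ly {b}; ICM OM {}; freq(b) higher in
    # ACM Ly than ICM Ly.  By hand: shared=2, increased=2 (a vs 0; b 2>1),
    # only=1 (a alone; b sits in ICM Ly).
    a, b, c = T(1), T(2), T(3)
    vc = venn_counts(
        group_from_freqs({a: 5.0, b: 4.0, c: 1.0}, "ACM", "OM"),
        group_from_freqs({a: 3.0, b: 2.0}, "ACM", "LY"),
        group_from_freqs({b: 1.0}, "ICM", "LY"),
        group_from_freqs({}, "ICM", "OM"),
    )
    assert vc.acm_om_size == 3
    assert vc.shared_acm_ly == 2
    assert vc.increased_in_acm_ly == 2
    assert vc.only_in_acm_ly == 1


def test_equal_frequency_is_not_increased():
    a = T(1)
    vc = venn_counts(
        group_from_freqs({a: 5.0}, "ACM", "OM"),
        group_from_freqs({a: 2.0}, "ACM", "LY"),
        group_from_freqs({a: 2.0}, "ICM", "LY"),  # equal, strict rule excludes
        group_from_freqs({}, "ICM", "OM"),
    )
    assert vc.increased_in_acm_ly == 0
    assert vc.only_in_acm_ly == 0


def test_icm_both_comparator_is_stricter():
    a = T(1)
    args = (
        group_from_freqs({a: 5.0}, "ACM", "OM"),
        group_from_freqs({a: 2.0}, "ACM", "LY"),
        group_from_freqs({a: 1.0}, "ICM", "LY"),
        group_from_freqs({a: 3.0}, "ICM", "OM"),
    )
    assert venn_counts(*args, increased_comparator="icm_ly").increased_in_acm_ly == 1
    assert venn_counts(*args, increased_comparator="icm_both").increased_in_acm_ly == 0


@settings(derandomize=True, max_examples=40, deadline=None)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_set_identity_only_within_increased_within_shared(seed):
    """only_in_acm_ly <= increased_in_acm_ly <= shared for arbitrary random
    group repertoires (the 524 <= 683 <= 829 nesting pattern)."""
    rng = np.random.default_rng(seed)
    def rand_group(gr, ti):
        keys = [T(i) for i in rng.choice(30, size=rng.integers(1, 20), replace=False)]
        return group_from_freqs(
            {k: float(rng.uniform(0, 10)) for k in keys}, group=gr, tissue=ti
        )
    om, ly = rand_group("ACM", "OM"), rand_group("ACM", "LY")
    ily, iom = rand_group("ICM", "LY"), rand_group("ICM", "OM")
    vc = venn_counts(om, ly, ily, iom)
    only = only_set(om, ly, ily, iom)
    inc = increased_set(om, ly, ily, iom)
    assert only <= inc <= (om.clonotypes & ly.clonotypes)
    assert vc.only_in_acm_ly == len(only) and vc.increased_in_acm_ly == len(inc)
    assert vc.only_in_acm_ly <= vc.increased_in_acm_ly <= vc.shared_acm_ly


# -- gene_usage_skew ----------------------------------------------------------

def _triples_on_genes(axis_genes, sizes, other_gene="TRAJ18"):
    """One triple per unique read; gene i gets sizes[i] reads."""
    triples = []
    k = 0
    for gene, n in zip(axis_genes, sizes):
        for _ in range(n):
            triples.append((gene, other_gene, f"CA{k}F"))
            k += 1
    return triples


def test_skew_counts_conserve_set_size(full_ref):
    genes = full_ref.gene_names("TRA", "V")[:10]
    triples = _triples_on_genes(genes, [3] * 10)
    rep = gene_usage_skew(triples, full_ref, "TRAV")
    assert sum(rep.counts.values()) == len(triples)
    assert rep.occupied == 10 and rep.total_genes == 112


def test_skew_direct_arithmetic_oracle(full_ref):
    genes = full_ref.gene_names("TRA", "V")[:5]
    rep = gene_usage_skew(_triples_on_genes(genes, [1, 1, 1, 1, 16]), full_ref, "TRAV")
    assert rep.mean == pytest.approx(4.0)
    assert rep.sd == pytest.approx(math.sqrt(180 / 4), abs=1e-9)  # 6.7082
    assert rep.threshold == pytest.approx(4 + 2 * math.sqrt(45), abs=1e-9)  # 17.416
    assert rep.flagged == []

    rep = gene_usage_skew(_triples_on_genes(genes, [1, 1, 1, 1, 40]), full_ref, "TRAV")
    # mean 44/5 = 8.8; sample SD sqrt(1216.8/4) = 17.4413; threshold 43.683
    assert rep.mean == pytest.approx(8.8)
    assert rep.sd == pytest.approx(math.sqrt(1216.8 / 4), abs=1e-6)
    assert rep.threshold == pytest.approx(8.8 + 2 * math.sqrt(1216.8 / 4), abs=1e-6)
    assert rep.flagged == []  # 40 < 43.68: a single outlier among 5 genes stays


def test_skew_single_occupied_gene_degenerate(full_ref):
    triples = _triples_on_genes([full_ref.gene_names("TRA", "V")[0]], [12])
    rep = gene_usage_skew(triples, full_ref, "TRAV")
    assert rep.occupied == 1 and rep.mean == 12.0
    assert rep.sd is None and rep.threshold is None and rep.flagged == []


def test_skew_empty_set_rejected(full_ref):
    with pytest.raises(CommonalityError, match="nothing to tabulate"):
        gene_usage_skew([], full_ref, "TRAV")


def test_skew_j_axis_counts_j_genes(full_ref):
    triples = [("TRAV1", "TRAJ18", "CAAF"), ("TRAV2", "TRAJ18", "CACF"),
               ("TRAV1", "TRAJ21", "CADF")]
    rep = gene_usage_skew(triples, full_ref, "TRAJ")
    assert rep.counts == {"TRAJ18": 2, "TRAJ21": 1}
    assert rep.total_genes == 51


def test_planted_fivefold_skew_flagged_over_seeds(full_ref):
    """A single V gene at 5x baseline usage among ACM-shared clones is flagged
    by the mean + 2SD rule in >= 95% of 20 seeds."""
    flagged = 0
    for seed in range(20):
        design = StudyDesign(chains=("TRA",), skew_genes=("TRAV13-1",),
                             reads_per_sample=8000, seed=seed)
        study = simulate_study(design, full_ref, emit_reads=False)
        groups = {
            st_: build_group_repertoire(
                [study.truth_sample(f"{st_}_{r}", "TRA") for r in (1, 2, 3)]
            )
            for st_ in SAMPLE_TYPES
        }
        inc = increased_set(groups["ACM_OM"], groups["ACM_LY"],
                            groups["ICM_LY"], groups["ICM_OM"])
        rep = gene_usage_skew(inc, full_ref, "TRAV")
        flagged += "TRAV13-1" in rep.flagged
    assert flagged >= 19


def test_sharing_flags_agree_with_brute_force_membership(full_ref):
    """Commonality-table sharing flags equal direct set membership recomputed
    from the per-replicate clonotype tables."""
    design = StudyDesign(
        chains=("TRA",), replicates=2, reads_per_sample=1500,
        clone_counts={"ACM_OM": 80, "ACM_LY": 80, "ICM_OM": 20, "ICM_LY": 50},
        seed=31,
    )
    study = simulate_study(design, full_ref, emit_reads=False)
    samples = {st_: [study.truth_sample(f"{st_}_{r}", "TRA") for r in (1, 2)]
               for st_ in SAMPLE_TYPES}
    groups = {st_: build_group_repertoire(reps) for st_, reps in samples.items()}
    tab = top_commonality(groups["ACM_OM"],
                          [groups[s] for s in ("ACM_LY", "ICM_LY", "ICM_OM")])
    for row in tab.itertuples():
        triple = (row.v_call, row.j_call, row.junction_aa)
        for st_ in ("ACM_LY", "ICM_LY", "ICM_OM"):
            brute = any(triple in rs.triples() for rs in samples[st_])
            assert getattr(row, f"shared_{st_}") == brute
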