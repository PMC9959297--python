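# anchor_offset: 0-based offset of the first base of the anchor codon (Cys104 for V, Phe118 for J; Gly119 follows at +3)
name	chain	segment_type	anchor_offset
TRAV1	TRA	V	78
TRAV1-1	TRA	V	78
TRAV1-2	TRA	V	75
TRAV11	TRA	V	75
TRAV11D	TRA	V	72
TRAV14-1	TRA	V	78
TRAV1D-1	TRA	V	75
TRAV7D-2	TRA	V	78
TRAJ18	TRA	J	30
TRAJ2	TRA	J	15
TRAJ3	TRA	J	9
TRAJ4	TRA	J	9
TRAJ5	TRA	J	15
TRAJ6	TRA	J	18
TRBV1	TRB	V	75
TRBV2	TRB	V	75
TRBV3	TRB	V	75
TRBV4	TRB	V	75
TRBV5	TRB	V	75
TRBJ1-1	TRB	J	12
TRBJ1-2	TRB	J	15
TRBJ1-3	TRB	J	18
TRBJ2-7	TRB	J	9
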