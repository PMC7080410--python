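locus: alpha
v_segments:
- - TRAV1
  - TGTTTTTT
  - 0.03761296617076392
- - TRAV2
  - TGTGATGT
  - 0.014013676818414518
- - TRAV3
  - TGTACACG
  - 0.048822434783941535
- - TRAV4
  - TGTAGTCG
  - 0.05801754161434306
- - TRAV5
  - TGTCGCTT
  - 0.08048329577690841
- - TRAV6
  - TGTTTCGG
  - 0.03380867450173435
- - TRAV7
  - TGTCGGGT
  - 0.09482704567118914
- - TRAV8
  - TGTGCTTA
  - 0.05152409422458805
- - TRAV9
  - TGTGGTAC
  - 0.018506461766163863
- - TRAV10
  - TGTATGAC
  - 0.043321857487852986
- - TRAV11
  - TGTAGGAT
  - 0.12644995921204316
- - TRAV12
  - TGTACAAA
  - 0.062331971555895226
- - TRAV13
  - TGTAGGTA
  - 0.04270694849577318
- - TRAV14
  - TGTGCCTG
  - 0.02604115774267724
- - TRAV15
  - TGTATATG
  - 0.038041781229383585
- - TRAV16
  - TGTCTCAC
  - 0.03883120976117162
- - TRAV17
  - TGTCCTGA
  - 0.06746990386955033
- - TRAV18
  - TGTGCTGA
  - 0.04078093305477387
- - TRAV19
  - TGTACTCT
  - 0.053435514384736885
- - TRAV20
  - TGTGCCTT
  - 0.022972571878095156
j_segments:
- - TRAJ1
  - CATAGTTC
  - 0.021344912961134645
- - TRAJ2
  - TTTACTTC
  - 0.04458817071229235
- - TRAJ3
  - CAAGATTC
  - 0.040577300867280015
- - TRAJ4
  - CCCGATTC
  - 0.04342725760293209
- - TRAJ5
  - CCAGCTTC
  - 0.053801446028106124
- - TRAJ6
  - GCGCATTC
  - 0.05661298847819327
- - TRAJ7
  - GGTCATTC
  - 0.05121829368689977
- - TRAJ8
  - AGATATTC
  - 0.06783459486663776
- - TRAJ9
  - AGATGTTC
  - 0.025676366426605216
- - TRAJ10
  - TACCGTTC
  - 0.09165107390124771
- - TRAJ11
  - GCCCATTC
  - 0.08254836394224624
- - TRAJ12
  - CGGCGTTC
  - 0.03436674581360615
- - TRAJ13
  - ATCCGTTC
  - 0.06363784522476336
- - TRAJ14
  - TTTCCTTC
  - 0.018775726526760076
- - TRAJ15
  - ATGATTTC
  - 0.06767168303616806
- - TRAJ16
  - GCGCTTTC
  - 0.030759450469479546
- - TRAJ17
  - TGGAATTC
  - 0.06691191222581118
- - TRAJ18
  - ACTAGTTC
  - 0.0419961022697116
- - TRAJ19
  - ATGGCTTC
  - 0.06860076925931971
- - TRAJ20
  - GGCCCTTC
  - 0.02799899570080502
deletion_probs:
- 0.4
- 0.3
- 0.2
- 0.1
insertion_probs:
- 0.4569568724317997
- 0.25132627983748984
- 0.13822945391061944
- 0.0760261996508407
- 0.04181440980796238
- 0.022997925394379313
- 0.012648858966908623
base_probs:
- 0.2
- 0.3
- 0.32
- 0.18
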