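locus: beta
v_segments:
- - TRBV1
  - TGTCTAAT
  - 0.053054060107111715
- - TRBV2
  - TGTCGTTG
  - 0.06953188409048404
- - TRBV3
  - TGTAAAGC
  - 0.05464744912119413
- - TRBV4
  - TGTGGGAC
  - 0.04795142459418595
- - TRBV5
  - TGTGCCGC
  - 0.03930475627362803
- - TRBV6
  - TGTACTTT
  - 0.04948263370454638
- - TRBV7
  - TGTAAATT
  - 0.05080238462970335
- - TRBV8
  - TGTTCCGA
  - 0.03905469925307287
- - TRBV9
  - TGTCCACG
  - 0.056792122203424965
- - TRBV10
  - TGTCCGTT
  - 0.049812748720042
- - TRBV11
  - TGTATCAT
  - 0.0372059029700509
- - TRBV12
  - TGTATGGA
  - 0.04961355884547254
- - TRBV13
  - TGTACCTA
  - 0.04574140786066053
- - TRBV14
  - TGTGGCCT
  - 0.0460197796334192
- - TRBV15
  - TGTCCCAT
  - 0.05048866744819396
- - TRBV16
  - TGTCTATC
  - 0.06120009096989424
- - TRBV17
  - TGTAACGT
  - 0.045029432713662915
- - TRBV18
  - TGTGGGGA
  - 0.053614318087433624
- - TRBV19
  - TGTTTTGA
  - 0.04454460022408997
- - TRBV20
  - TGTTTAAC
  - 0.05610807854972868
j_segments:
- - TRBJ1
  - CAAAATTC
  - 0.0560883305125749
- - TRBJ2
  - GCTACTTC
  - 0.04470966367730461
- - TRBJ3
  - TATCATTC
  - 0.04715518762386726
- - TRBJ4
  - ATGAATTC
  - 0.046950939461171154
- - TRBJ5
  - GCTGATTC
  - 0.04206173384205658
- - TRBJ6
  - ATGCGTTC
  - 0.049609945609722615
- - TRBJ7
  - TCCGTTTC
  - 0.053430062354442226
- - TRBJ8
  - TTAAATTC
  - 0.061229984751442465
- - TRBJ9
  - ACAAATTC
  - 0.04766712080376643
- - TRBJ10
  - GTGATTTC
  - 0.05091407070156013
- - TRBJ11
  - CGATTTTC
  - 0.0446125397605066
- - TRBJ12
  - GTATTTTC
  - 0.049189581725249204
- - TRBJ13
  - CAGTGTTC
  - 0.05348140466993305
- - TRBJ14
  - GTGCTTTC
  - 0.046117379150926736
- - TRBJ15
  - CACCGTTC
  - 0.0519457734056134
- - TRBJ16
  - CTGCATTC
  - 0.05195659056925766
- - TRBJ17
  - GGTAATTC
  - 0.04910202015431033
- - TRBJ18
  - GGGACTTC
  - 0.046953069821659414
- - TRBJ19
  - TTAATTTC
  - 0.051107480599113346
- - TRBJ20
  - TTTAATTC
  - 0.05571712080552177
deletion_probs:
- 0.4
- 0.3
- 0.2
- 0.1
insertion_probs:
- 0.0
- 0.0
- 0.051541645302619885
- 0.06828158613672004
- 0.08497780693731075
- 0.09934912160544086
- 0.10911366396189087
- 0.11257730346075333
- 0.10911366396189087
- 0.09934912160544086
- 0.08497780693731075
- 0.06828158613672004
- 0.051541645302619885
- 0.036548499337083255
- 0.02434654931419867
base_probs:
- 0.2
- 0.3
- 0.32
- 0.18
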