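- name: '38502'
  forward: GATAGTGAATCTCCGGGAGCG
  reverse: ATCACTGATTGTTACTGTGTCCCC
  expected_size_bp: 1002
  label: I/38502
- name: Tuc2009U
  forward: CATGCGGATGTCAATAGTCAAGCC
  reverse: GTATCAAATCCATTCGCTTCGGTTC
  expected_size_bp: null
  label: II/Tuc2009U
- name: '53801'
  forward: CAAAGATGGGAAGATAGAGAGTA
  reverse: CCTCGTGGTGCGCCGGT
  expected_size_bp: 554
  label: II/53801
- name: '98101'
  forward: GACAGAACATTTTATAACACTATCCAC
  reverse: CAAACTGTAACGCATTATCACTGGC
  expected_size_bp: 268
  label: II/98101
- name: '98204'
  forward: GCCTTTGGAGCTTTTTCGGTTGAT
  reverse: GCGCCGTTAGGTATATTATCC
  expected_size_bp: 412
  label: II/98204
- name: LC3
  forward: CGTTGAAGTAAATGGAAGCTTAAC
  reverse: GAGGATATTTCCCCACCAATTG
  expected_size_bp: 128
  label: III/LC3
- name: '62503'
  forward: GACCGTGAATATAGTTCTGATGAAT
  reverse: GTAGTAATTCCGATTTCCCATTCTC
  expected_size_bp: 784
  label: IV/62503
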